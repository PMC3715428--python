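"""Readers and writers for the plain-text formats used by the pipeline.

Internally everything is 0-based half-open.  BED is read and written
natively in that convention; GFF3 (1-based, end-inclusive) is converted at
the boundary.
"""

from __future__ import annotations

from typing import Dict, List, Sequence

import gffutils
import pandas as pd
from Bio import SeqIO

from .targets import GeneModel

BED6_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def read_bed(path: str) -> pd.DataFrame:
    """Read a BED file (>=3 columns); missing BED6 columns are filled."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    df = df.iloc[:, : len(BED6_COLUMNS)]
    df.columns = BED6_COLUMNS[: df.shape[1]]
    if "name" not in df:
        df["name"] = [f"iv{i}" for i in range(len(df))]
    if "score" not in df:
        df["score"] = 0
    if "strand" not in df:
        df["strand"] = "."
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    return df


def write_bed(df: pd.DataFrame, path: str) -> None:
    cols = [c for c in BED6_COLUMNS if c in df.columns]
    extra = [c for c in df.columns if c not in cols]
    df[cols + extra].to_csv(path, sep="\t", header=False, index=False)


def read_chrom_sizes(path: str) -> Dict[str, int]:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"])
    return dict(zip(df["chrom"].astype(str), df["length"].astype(int)))


def write_chrom_sizes(sizes: Dict[str, int], path: str) -> None:
    with open(path, "w") as fh:
        for chrom, length in sizes.items():
            fh.write(f"{chrom}\t{length}\n")


def write_gff3(genes: Sequence[GeneModel], path: str) -> None:
    """Write gene/mRNA/exon records, converting to 1-based inclusive."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.chrom}\tpeakstate\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}\n"
            )
            for ti, exons in enumerate(g.transcripts):
                tid = f"{g.gene_id}.t{ti + 1}"
                fh.write(
                    f"{g.chrom}\tpeakstate\tmRNA\t{exons[0][0] + 1}\t"
                    f"{exons[-1][1]}\t.\t{g.strand}\t.\tID={tid};Parent={g.gene_id}\n"
                )
                for ei, (a, b) in enumerate(exons):
                    fh.write(
                        f"{g.chrom}\tpeakstate\texon\t{a + 1}\t{b}\t.\t"
                        f"{g.strand}\t.\tID={tid}.e{ei + 1};Parent={tid}\n"
                    )


def read_gff3(path: str) -> List[GeneModel]:
    """Parse gene models from GFF3 via gffutils (in-memory database)."""
    db = gffutils.create_db(
        path, ":memory:", force=True, keep_order=True, merge_strategy="error"
    )
    genes: List[GeneModel] = []
    for g in db.features_of_type("gene", order_by="start"):
        transcripts = []
        for t in db.children(g, featuretype="mRNA", order_by="start"):
            exons = [
                (e.start - 1, e.end)
                for e in db.children(t, featuretype="exon", order_by="start")
            ]
            if exons:
                transcripts.append(exons)
        genes.append(
            GeneModel(gene_id=g.id, chrom=g.seqid, strand=g.strand, transcripts=transcripts)
        )
    return genes


def read_expression(path: str) -> pd.DataFrame:
    """Read a probe_set_id/gene_id x sample log2 expression TSV."""
    df = pd.read_csv(path, sep="\t")
    required = {"probe_set_id", "gene_id"}
    if not required.issubset(df.columns):
        raise ValueError(f"expression table must contain columns {sorted(required)}")
    return df


def write_expression(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_fasta(path: str) -> Dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def write_fasta(seqs: Dict[str, str], path: str) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def write_wig(coverage: Dict[str, "np.ndarray"], path: str, step: int = 1) -> None:
    """Dump per-base coverage as fixed-step WIG (for browser inspection)."""
    with open(path, "w") as fh:
        for chrom, cov in coverage.items():
            fh.write(f"fixedStep chrom={chrom} start=1 step={step}\n")
            for v in cov[::step]:
                fh.write(f"{int(v)}\n")
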