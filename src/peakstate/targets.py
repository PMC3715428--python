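"""Peak-to-gene assignment.

A gene is considered a candidate target of the immunoprecipitated factor in
a given ChIP condition when at least one significant peak overlaps either
its promoter (the window from the transcription start site to
``promoter_upstream`` bp upstream, 500 bp by default) or any of its introns.
Coordinates are 0-based half-open throughout; GFF input is converted from
1-based inclusive at the boundary (see :mod:`peakstate.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence, Tuple

import pandas as pd
from intervaltree import IntervalTree

Interval = Tuple[int, int]


@dataclass
class AssignmentConfig:
    """Parameters of the peak-to-gene rule."""

    promoter_upstream: int = 500
    #: require only >=1 bp of overlap ("within" read in its weakest sense);
    #: set to True to require the peak midpoint to fall inside the feature.
    midpoint_within: bool = False

    def validate(self) -> None:
        if self.promoter_upstream <= 0:
            raise ValueError("promoter_upstream must be positive")


@dataclass
class GeneModel:
    """A gene with one or more transcripts, each an ordered exon list.

    Exons are 0-based half-open and disjoint within a transcript.
    """

    gene_id: str
    chrom: str
    strand: str
    transcripts: List[List[Interval]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"unknown strand {self.strand!r} for {self.gene_id}")
        for exons in self.transcripts:
            for (a, b), (c, d) in zip(exons, exons[1:]):
                if not (a < b <= c < d):
                    raise ValueError(
                        f"exons of {self.gene_id} not ordered/disjoint: {exons}"
                    )

    @property
    def start(self) -> int:
        return min(ex[0][0] for ex in self.transcripts)

    @property
    def end(self) -> int:
        return max(ex[-1][1] for ex in self.transcripts)


def introns_of(exons: Sequence[Interval]) -> List[Interval]:
    """Gaps between consecutive exons of one transcript (half-open).

    A single-exon transcript has no introns and yields an empty list.
    """
    return [(a_end, b_start) for (_, a_end), (b_start, _) in zip(exons, exons[1:])]


def promoter_regions(
    gene: GeneModel,
    cfg: AssignmentConfig | None = None,
    chrom_length: int | None = None,
) -> List[Interval]:
    """Promoter windows of a gene: one per transcript TSS, deduplicated.

    For a + strand transcript with TSS t (its leftmost coordinate) the
    promoter is ``[max(0, t - u), t)``; for a - strand transcript with TSS at
    the rightmost base t the promoter is ``[t + 1, t + 1 + u)`` clipped to the
    chromosome, where u = promoter_upstream.
    """
    cfg = cfg or AssignmentConfig()
    cfg.validate()
    u = cfg.promoter_upstream
    out: List[Interval] = []
    for exons in gene.transcripts:
        if gene.strand == "+":
            t = exons[0][0]
            iv = (max(0, t - u), t)
        else:
            t = exons[-1][1] - 1  # rightmost transcribed base
            hi = t + 1 + u
            if chrom_length is not None:
                hi = min(chrom_length, hi)
            iv = (t + 1, hi)
        if iv[0] < iv[1] and iv not in out:
            out.append(iv)
    return out


def gene_feature_intervals(
    gene: GeneModel,
    cfg: AssignmentConfig | None = None,
    chrom_length: int | None = None,
) -> List[Interval]:
    """Union of a gene's promoter windows and introns over all transcripts."""
    feats = list(promoter_regions(gene, cfg, chrom_length))
    for exons in gene.transcripts:
        feats.extend(introns_of(exons))
    return feats


def _feature_trees(
    genes: Iterable[GeneModel],
    cfg: AssignmentConfig,
    chrom_lengths: Dict[str, int] | None,
) -> Dict[str, IntervalTree]:
    trees: Dict[str, IntervalTree] = {}
    for gene in genes:
        clen = chrom_lengths.get(gene.chrom) if chrom_lengths else None
        tree = trees.setdefault(gene.chrom, IntervalTree())
        for a, b in gene_feature_intervals(gene, cfg, clen):
            tree.addi(a, b, gene.gene_id)
    return trees


def assign_condition(
    peaks: pd.DataFrame,
    genes: Sequence[GeneModel],
    cfg: AssignmentConfig | None = None,
    chrom_lengths: Dict[str, int] | None = None,
) -> pd.DataFrame:
    """Flag genes overlapped by >=1 peak of one condition.

    ``peaks`` needs columns chrom/start/end and optionally ``name``; a peak
    may support several genes. Peaks on chromosomes absent from the gene
    models are skipped. Returns a frame indexed like ``genes`` with columns
    ``gene_id``, ``has_peak`` and ``supporting_peaks`` (list of peak names).
    """
    cfg = cfg or AssignmentConfig()
    cfg.validate()
    trees = _feature_trees(genes, cfg, chrom_lengths)
    support: Dict[str, List[str]] = {g.gene_id: [] for g in genes}
    for row in peaks.itertuples(index=False):
        tree = trees.get(row.chrom)
        if tree is None:
            continue
        name = getattr(row, "name", None) or f"{row.chrom}:{row.start}-{row.end}"
        if cfg.midpoint_within:
            mid = (row.start + row.end) // 2
            hits = tree.at(mid)
        else:
            hits = tree.overlap(row.start, row.end)
        for hit in hits:
            if name not in support[hit.data]:
                support[hit.data].append(name)
    return pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "has_peak": [len(support[g.gene_id]) > 0 for g in genes],
            "supporting_peaks": [support[g.gene_id] for g in genes],
        }
    )


def assign_targets(
    peaks_by_condition: Dict[str, pd.DataFrame],
    genes: Sequence[GeneModel],
    cfg: AssignmentConfig | None = None,
    chrom_lengths: Dict[str, int] | None = None,
) -> pd.DataFrame:
    """Per-gene target flags for every ChIP condition.

    Returns one row per gene with ``has_peak_<cond>`` and ``peaks_<cond>``
    columns for each condition in ``peaks_by_condition``.
    """
    out = pd.DataFrame({"gene_id": [g.gene_id for g in genes]})
    for cond, peaks in peaks_by_condition.items():
        flags = assign_condition(peaks, genes, cfg, chrom_lengths)
        out[f"has_peak_{cond}"] = flags["has_peak"].to_numpy()
        out[f"peaks_{cond}"] = flags["supporting_peaks"].to_numpy()
    return out
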