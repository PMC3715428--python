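"""Synthetic study generator with planted ground truth.

Emulates the structure of the study the pipeline is built for: a
three-genotype (control, factor-overexpressing, tumourigenic) expression
array in triplicate with occasional multi-probe-set genes, two ChIP
conditions plus an input control as stranded read 5' positions, peak-like
sequences with planted motif instances, and qPCR Ct tables.  Every planted
signal (deregulation direction per gene, peak site per condition, expected
class label, motif position) is recorded in a :class:`GroundTruth` object
so each downstream stage can be tested against a known answer.

All outputs are deterministic functions of the configuration, including
its seed.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Tuple

import numpy as np
import pandas as pd

from . import io as pio
from .classify import class_of, peak_pattern
from .targets import GeneModel, introns_of

CONDITIONS = ("ab", "scrib_ab")
GENOTYPES = ("control", "ab", "scrib_ab")

# stable spawn keys for the per-stage random generators
_STAGES = {"annotation": 0, "truth": 1, "expression": 2, "reads": 3,
           "sequences": 4, "ct": 5}


@dataclass
class SimConfig:
    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 600_000
    n_genes: int = 200
    #: fraction of genes interrogated by two probe sets
    frac_multi_probe: float = 0.10
    #: fraction of deregulated multi-probe genes whose second probe set
    #: shifts in the opposite direction (discordant-transcript mimic)
    frac_conflicting: float = 0.33
    n_replicates: int = 3
    #: fraction of genes deregulated per pattern (directions split evenly)
    de_fractions: Dict[str, float] = field(
        default_factory=lambda: {"both": 0.12, "ab_only": 0.04, "tumour_only": 0.06}
    )
    effect_size: float = 2.0
    noise_sd: float = 0.25
    #: fraction of genes given a promoter/intron binding site per pattern
    planted_target_fractions: Dict[str, float] = field(
        default_factory=lambda: {"both": 0.15, "ab_only": 0.04, "tumour_only": 0.05}
    )
    #: optional exact joint planting: class number (1-6) -> gene count.
    #: Overrides de_fractions/planted_target_fractions when set.
    class_plan: Optional[Dict[int, int]] = None
    background_read_rate: float = 0.02  # reads per bp of genome
    reads_per_peak: int = 120
    fragment_length: int = 500
    read_length: int = 40
    motif_plant_rate: float = 0.8
    n_sequences: int = 100
    sequence_length: int = 100
    baseline_log2_range: Tuple[float, float] = (6.0, 12.0)

    def validate(self) -> None:
        fracs = [self.frac_multi_probe, self.frac_conflicting,
                 self.motif_plant_rate, *self.de_fractions.values(),
                 *self.planted_target_fractions.values()]
        if any(not 0 <= f <= 1 for f in fracs):
            raise ValueError("all fractions must lie in [0,1]")
        if sum(self.de_fractions.values()) > 1 or sum(
            self.planted_target_fractions.values()
        ) > 1:
            raise ValueError("pattern fractions must sum to at most 1")
        for name in ("n_chroms", "chrom_length", "n_genes", "n_replicates",
                     "reads_per_peak", "fragment_length", "read_length",
                     "n_sequences", "sequence_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.background_read_rate < 0 or self.noise_sd < 0:
            raise ValueError("rates and noise must be non-negative")

    def rng(self, stage: str) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence(self.seed, spawn_key=(_STAGES[stage],))
        )

    @property
    def chrom_sizes(self) -> Dict[str, int]:
        return {f"chr{i + 1}": self.chrom_length for i in range(self.n_chroms)}


@dataclass
class GroundTruth:
    """Planted signals of one simulated study."""

    #: per-gene deregulation directions (+1/-1/0) per contrast
    dereg: pd.DataFrame
    #: per-gene planted binding per condition, with the site coordinate
    targets: pd.DataFrame
    #: per-gene expected class label (0 = unclassified)
    expected_class: pd.DataFrame
    #: genes whose second probe set was planted with the opposite sign
    conflicting_genes: List[str] = field(default_factory=list)
    #: planted motif start per sequence id (absent = no instance)
    motif_positions: Dict[str, int] = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "dereg": self.dereg.to_dict(orient="records"),
            "targets": self.targets.to_dict(orient="records"),
            "expected_class": self.expected_class.to_dict(orient="records"),
            "conflicting_genes": self.conflicting_genes,
            "motif_positions": self.motif_positions,
        }
        return json.dumps(payload, indent=1, sort_keys=True)


def _split_counts(n: int, fractions: Mapping[str, float]) -> Dict[str, int]:
    return {k: int(round(f * n)) for k, f in fractions.items()}


def generate_annotation(cfg: SimConfig) -> Tuple[List[GeneModel], pd.DataFrame]:
    """Place non-overlapping multi-exon genes and map probe sets to them.

    Genes are laid out left to right per chromosome with randomized exon,
    intron and intergenic lengths; each gene has one transcript of three
    exons, so two introns always exist.  A configured fraction of genes is
    measured by two probe sets.  Raises when the requested gene count does
    not fit the genome.
    """
    cfg.validate()
    rng = cfg.rng("annotation")
    chroms = list(cfg.chrom_sizes)
    genes: List[GeneModel] = []
    ci, cursor = 0, 2000
    for gi in range(cfg.n_genes):
        exon_lens = rng.integers(200, 501, size=3)
        intron_lens = rng.integers(300, 801, size=2)
        # intergenic gap > 2x the 500 bp promoter window, so neighbouring
        # genes' promoters never overlap and a planted peak flags one gene
        gap = int(rng.integers(1200, 2001))
        strand = "+" if rng.random() < 0.5 else "-"
        length = int(exon_lens.sum() + intron_lens.sum())
        while cursor + length + 1000 > cfg.chrom_length:
            ci += 1
            cursor = 2000
            if ci >= cfg.n_chroms:
                raise ValueError(
                    "cannot place genes without overlap at this density; "
                    "increase chrom_length/n_chroms or reduce n_genes"
                )
        pos = cursor
        exons = []
        for k in range(3):
            exons.append((pos, pos + int(exon_lens[k])))
            pos += int(exon_lens[k])
            if k < 2:
                pos += int(intron_lens[k])
        genes.append(
            GeneModel(
                gene_id=f"g{gi + 1:04d}",
                chrom=chroms[ci],
                strand=strand,
                transcripts=[exons],
            )
        )
        cursor += length + gap
    n_multi = int(round(cfg.frac_multi_probe * cfg.n_genes))
    multi = set(rng.permutation([g.gene_id for g in genes])[:n_multi])
    rows = []
    for g in genes:
        rows.append({"probe_set_id": f"ps_{g.gene_id}_1", "gene_id": g.gene_id})
        if g.gene_id in multi:
            rows.append({"probe_set_id": f"ps_{g.gene_id}_2", "gene_id": g.gene_id})
    return genes, pd.DataFrame(rows)


def _binding_site(gene: GeneModel, rng: np.random.Generator) -> int:
    """A promoter- or intron-located binding site coordinate for a gene."""
    exons = gene.transcripts[0]
    if rng.random() < 0.5:
        # promoter: 250 bp upstream of the TSS
        if gene.strand == "+":
            return max(60, exons[0][0] - 250)
        return exons[-1][1] - 1 + 250
    a, b = introns_of(exons)[0]
    return (a + b) // 2


def simulate_truth(genes: List[GeneModel], cfg: SimConfig) -> GroundTruth:
    """Plant deregulation patterns and binding sites; derive class labels."""
    cfg.validate()
    rng = cfg.rng("truth")
    gene_ids = [g.gene_id for g in genes]
    by_id = {g.gene_id: g for g in genes}
    n = len(gene_ids)

    dir_ab = {g: 0 for g in gene_ids}
    dir_t = {g: 0 for g in gene_ids}
    t_ab = {g: False for g in gene_ids}
    t_t = {g: False for g in gene_ids}
    site = {g: -1 for g in gene_ids}

    if cfg.class_plan is not None:
        # joint planting: one (dereg, peak) pattern combination per class
        combos = {1: ("both", "both"), 2: ("tumour_only", "both"),
                  3: ("both", "tumour_only"), 4: ("tumour_only", "tumour_only"),
                  5: ("tumour_only", "none"), 6: ("tumour_only", "ab_only")}
        if sum(cfg.class_plan.values()) > n:
            raise ValueError("class_plan requires more genes than simulated")
        perm = list(rng.permutation(gene_ids))
        i = 0
        for cls, count in sorted(cfg.class_plan.items()):
            dereg, peaks = combos[cls]
            block = perm[i : i + count]
            i += count
            for j, g in enumerate(block):
                d = 1 if j % 2 == 0 else -1
                if dereg in ("both", "ab_only"):
                    dir_ab[g] = d
                if dereg in ("both", "tumour_only"):
                    dir_t[g] = d
                if peaks in ("both", "ab_only"):
                    t_ab[g] = True
                if peaks in ("both", "tumour_only"):
                    t_t[g] = True
                if peaks != "none":
                    site[g] = _binding_site(by_id[g], rng)
    else:
        de_counts = _split_counts(n, cfg.de_fractions)
        perm = list(rng.permutation(gene_ids))
        i = 0
        for pattern in ("both", "ab_only", "tumour_only"):
            block = perm[i : i + de_counts.get(pattern, 0)]
            i += len(block)
            for j, g in enumerate(block):
                d = 1 if j < (len(block) + 1) // 2 else -1
                if pattern in ("both", "ab_only"):
                    dir_ab[g] = d
                if pattern in ("both", "tumour_only"):
                    dir_t[g] = d

        tgt_counts = _split_counts(n, cfg.planted_target_fractions)
        perm2 = list(rng.permutation(gene_ids))
        i = 0
        for pattern in ("both", "ab_only", "tumour_only"):
            block = perm2[i : i + tgt_counts.get(pattern, 0)]
            i += len(block)
            for g in block:
                if pattern in ("both", "ab_only"):
                    t_ab[g] = True
                if pattern in ("both", "tumour_only"):
                    t_t[g] = True
                site[g] = _binding_site(by_id[g], rng)

    def dereg_pattern(g: str) -> str:
        a, t = dir_ab[g] != 0, dir_t[g] != 0
        if a and t:
            return "both"
        if a:
            return "ab_only"
        if t:
            return "tumour_only"
        return "none"

    dereg = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "dir_ab": [dir_ab[g] for g in gene_ids],
            "dir_tumour": [dir_t[g] for g in gene_ids],
            "pattern": [dereg_pattern(g) for g in gene_ids],
        }
    )
    targets = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "target_ab": [t_ab[g] for g in gene_ids],
            "target_tumour": [t_t[g] for g in gene_ids],
            "chrom": [by_id[g].chrom for g in gene_ids],
            "site": [site[g] for g in gene_ids],
        }
    )
    expected = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "expected_class": [
                class_of(dereg_pattern(g), peak_pattern(t_ab[g], t_t[g]))
                for g in gene_ids
            ],
        }
    )
    return GroundTruth(dereg=dereg, targets=targets, expected_class=expected)


def generate_expression(
    probe_map: pd.DataFrame, cfg: SimConfig, truth: GroundTruth
) -> pd.DataFrame:
    """Log2 intensity matrix with planted genotype shifts.

    Baselines are uniform in the configured log2 range; planted genes shift
    by +/- effect_size in the corresponding genotype; every probe set of a
    gene shares the gene's shift except the second probe set of
    "conflicting" genes, which gets the opposite sign.  Gaussian noise of
    sd ``noise_sd`` is added to every measurement.  Mutates ``truth`` by
    recording the conflicting gene list.
    """
    cfg.validate()
    rng = cfg.rng("expression")
    known = set(truth.dereg["gene_id"])
    unknown = set(probe_map["gene_id"]) - known
    if unknown:
        raise ValueError(f"probe map contains genes absent from truth: {sorted(unknown)[:5]}")
    dirs = truth.dereg.set_index("gene_id")

    probe_counts = probe_map.groupby("gene_id").size()
    multi_dereg = [
        g
        for g in probe_counts[probe_counts > 1].index
        if dirs.at[g, "dir_ab"] != 0 or dirs.at[g, "dir_tumour"] != 0
    ]
    n_conf = int(round(cfg.frac_conflicting * len(multi_dereg)))
    conflicting = sorted(rng.permutation(multi_dereg)[:n_conf]) if n_conf else []
    truth.conflicting_genes = list(conflicting)
    conflicting = set(conflicting)

    lo, hi = cfg.baseline_log2_range
    cols: Dict[str, list] = {f"{g}_{r + 1}": [] for g in GENOTYPES
                             for r in range(cfg.n_replicates)}
    for row in probe_map.itertuples(index=False):
        base = float(rng.uniform(lo, hi))
        flip = -1 if (row.gene_id in conflicting
                      and row.probe_set_id.endswith("_2")) else 1
        shift = {
            "control": 0.0,
            "ab": flip * dirs.at[row.gene_id, "dir_ab"] * cfg.effect_size,
            "scrib_ab": flip * dirs.at[row.gene_id, "dir_tumour"] * cfg.effect_size,
        }
        for g in GENOTYPES:
            for r in range(cfg.n_replicates):
                noise = float(rng.normal(0, cfg.noise_sd)) if cfg.noise_sd else 0.0
                cols[f"{g}_{r + 1}"].append(base + shift[g] + noise)
    out = probe_map.copy()
    for c, vals in cols.items():
        out[c] = vals
    return out


def generate_reads(
    genes: List[GeneModel], cfg: SimConfig, truth: GroundTruth
) -> Dict[str, pd.DataFrame]:
    """Stranded read 5' positions (1 bp BED intervals) per condition.

    Every condition, including the input control, receives an independent
    uniform background of ``background_read_rate`` reads per bp; each ChIP
    condition additionally receives ``reads_per_peak`` reads flanking the
    planted binding site of each of its target genes (5' ends 5-45 bp from
    the site, so that 40 bp extension piles up over the site).
    """
    cfg.validate()
    rng = cfg.rng("reads")
    sizes = cfg.chrom_sizes
    chroms = list(sizes)
    lengths = np.array([sizes[c] for c in chroms], float)
    weights = lengths / lengths.sum()
    n_bg = int(round(cfg.background_read_rate * lengths.sum()))
    tgt = truth.targets.set_index("gene_id")

    out: Dict[str, pd.DataFrame] = {}
    for cond in (*CONDITIONS, "input"):
        rows = []
        bg_chroms = rng.choice(len(chroms), size=n_bg, p=weights)
        bg_pos = rng.integers(0, lengths[bg_chroms].astype(int))
        bg_strand = rng.random(n_bg) < 0.5
        for k in range(n_bg):
            rows.append((chroms[bg_chroms[k]], int(bg_pos[k]),
                         "+" if bg_strand[k] else "-"))
        if cond != "input":
            flag = "target_ab" if cond == "ab" else "target_tumour"
            for gene_id in tgt.index[tgt[flag]]:
                c = int(tgt.at[gene_id, "site"])
                chrom = tgt.at[gene_id, "chrom"]
                clen = sizes[chrom]
                for k in range(cfg.reads_per_peak):
                    off = int(rng.integers(5, 46))
                    if k % 2 == 0:
                        pos = max(0, min(clen - 1, c - off))
                        rows.append((chrom, pos, "+"))
                    else:
                        pos = max(0, min(clen - 1, c + off))
                        rows.append((chrom, pos, "-"))
        df = pd.DataFrame(rows, columns=["chrom", "start", "strand"])
        df.insert(2, "end", df["start"] + 1)
        df.insert(3, "name", [f"{cond}_r{i}" for i in range(len(df))])
        df.insert(4, "score", 0)
        out[cond] = df
    return out


DEFAULT_MOTIF_CONSENSUS = "TGACTCAG"


def default_pwm(consensus: str = DEFAULT_MOTIF_CONSENSUS, strength: float = 85.0):
    """A sharply peaked count matrix around a consensus (for simulations)."""
    from .motifs import BASES, PWM

    counts = np.full((4, len(consensus)), 5.0)
    for j, b in enumerate(consensus):
        counts[BASES.index(b), j] = strength
    return PWM(matrix_id="planted", counts=counts)


def generate_sequences(
    cfg: SimConfig, pwm=None
) -> Tuple[Dict[str, str], Dict[str, int]]:
    """Peak-like sequences with motif instances planted at motif_plant_rate.

    Background bases are uniform (25% each).  Returns the sequences and the
    planted consensus start positions (also recorded in GroundTruth by
    :func:`simulate_study`).
    """
    cfg.validate()
    pwm = pwm or default_pwm()
    rng = cfg.rng("sequences")
    bases = np.array(list("ACGT"))
    seqs: Dict[str, str] = {}
    planted: Dict[str, int] = {}
    w = pwm.width
    for i in range(cfg.n_sequences):
        letters = rng.integers(0, 4, size=cfg.sequence_length)
        seq = "".join(bases[letters])
        if rng.random() < cfg.motif_plant_rate:
            pos = int(rng.integers(0, cfg.sequence_length - w + 1))
            seq = seq[:pos] + pwm.consensus + seq[pos + w :]
            planted[f"seq{i + 1}"] = pos
        seqs[f"seq{i + 1}"] = seq
    return seqs, planted


def generate_motif_study(
    cfg: SimConfig,
    pwm=None,
    n_decoys: int = 24,
    genome_factor: int = 4,
) -> Tuple[Dict[str, str], Dict[str, str], object, List[object]]:
    """Peak-set and genome-background sequences for rank-shift analysis.

    The peak set carries the factor's own motif at ``motif_plant_rate``;
    the genome background (``genome_factor`` times more sequence) carries
    instances of the decoy matrices — other factors' sites — at the same
    per-sequence rate, round-robin over decoys, but none of the factor's
    motif beyond chance.  Returns (peak_seqs, genome_seqs, pwm, decoys).
    """
    from .motifs import shuffled_decoys

    cfg.validate()
    pwm = pwm or default_pwm()
    rng = cfg.rng("sequences")
    decoys = shuffled_decoys(pwm, n_decoys, rng)
    bases = np.array(list("ACGT"))

    def draw(n_seqs: int, length: int, consensus_for) -> Dict[str, str]:
        out = {}
        for i in range(n_seqs):
            seq = "".join(bases[rng.integers(0, 4, size=length)])
            motif = consensus_for(i)
            if motif is not None and rng.random() < cfg.motif_plant_rate:
                pos = int(rng.integers(0, length - len(motif) + 1))
                seq = seq[:pos] + motif + seq[pos + len(motif):]
            out[f"s{i + 1}"] = seq
        return out

    peak_seqs = draw(cfg.n_sequences, cfg.sequence_length, lambda i: pwm.consensus)
    genome_seqs = draw(
        cfg.n_sequences * genome_factor,
        cfg.sequence_length,
        lambda i: decoys[i % len(decoys)].consensus,
    )
    return peak_seqs, genome_seqs, pwm, decoys


def generate_ct_table(
    fold_changes: Mapping[str, float],
    cfg: Optional[SimConfig] = None,
    assay: str = "expression",
    condition: str = "scrib_ab",
    reference: str = "control",
    normalizer: str = "CG6044",
    n_technical: int = 2,
    noise_sd: float = 0.0,
) -> pd.DataFrame:
    """Ct table whose 2^(-ddCt) (or IgG-relative) analysis recovers the
    requested fold changes.

    For expression assays the normalizer sits at Ct 20 everywhere and a
    target's condition Ct is shifted by -log2(fold) relative to its
    reference Ct, so ddCt = -log2(fold).  For ChIP assays the control-IP Ct
    is fixed and the antibody-IP Ct is Ct_control - log2(fold).
    """
    cfg = cfg or SimConfig()
    cfg.validate()
    rng = cfg.rng("ct")
    n_rep = cfg.n_replicates
    rows = []

    def add(gene: str, cond: str, ct0: float) -> None:
        for rep in range(1, n_rep + 1):
            for tech in range(1, n_technical + 1):
                noise = float(rng.normal(0, noise_sd)) if noise_sd else 0.0
                rows.append(
                    {
                        "assay": assay,
                        "target_gene": gene,
                        "sample_id": f"{cond}_{rep}",
                        "condition": cond,
                        "replicate": rep,
                        "technical_rep": tech,
                        "ct": ct0 + noise,
                    }
                )

    if assay == "expression":
        add(normalizer, reference, 20.0)
        add(normalizer, condition, 20.0)
        for gene, fold in fold_changes.items():
            if fold <= 0:
                raise ValueError("fold changes must be positive")
            add(gene, reference, 24.0)
            add(gene, condition, 24.0 - float(np.log2(fold)))
    elif assay == "chip":
        for gene, fold in fold_changes.items():
            if fold <= 0:
                raise ValueError("fold changes must be positive")
            add(gene, "control_ip", 28.0)
            add(gene, "antibody_ip", 28.0 - float(np.log2(fold)))
    else:
        raise ValueError("assay must be 'expression' or 'chip'")
    return pd.DataFrame(rows)


@dataclass
class SimulatedStudy:
    cfg: SimConfig
    genes: List[GeneModel]
    probe_map: pd.DataFrame
    truth: GroundTruth
    expression: pd.DataFrame
    reads: Dict[str, pd.DataFrame]
    sequences: Dict[str, str]
    pwm: object
    ct: pd.DataFrame

    @property
    def chrom_sizes(self) -> Dict[str, int]:
        return self.cfg.chrom_sizes


#: fold changes planted in the default validation Ct table
DEFAULT_CT_FOLDS = {"v_quarter": 0.25, "v_unit": 1.0, "v_double": 2.0, "v_eight": 8.0}


def simulate_study(cfg: SimConfig) -> SimulatedStudy:
    """Generate one complete synthetic study from a configuration."""
    genes, probe_map = generate_annotation(cfg)
    truth = simulate_truth(genes, cfg)
    expr = generate_expression(probe_map, cfg, truth)
    reads = generate_reads(genes, cfg, truth)
    pwm = default_pwm()
    seqs, planted = generate_sequences(cfg, pwm)
    truth.motif_positions = planted
    ct = generate_ct_table(DEFAULT_CT_FOLDS, cfg)
    return SimulatedStudy(
        cfg=cfg, genes=genes, probe_map=probe_map, truth=truth,
        expression=expr, reads=reads, sequences=seqs, pwm=pwm, ct=ct,
    )


def simulate_to_dir(cfg: SimConfig, outdir: str) -> SimulatedStudy:
    """Run :func:`simulate_study` and write all standard output files."""
    study = simulate_study(cfg)
    os.makedirs(outdir, exist_ok=True)
    pio.write_gff3(study.genes, os.path.join(outdir, "annotation.gff3"))
    pio.write_chrom_sizes(study.chrom_sizes, os.path.join(outdir, "chrom.sizes"))
    pio.write_expression(study.expression, os.path.join(outdir, "expr.tsv"))
    for cond, df in study.reads.items():
        name = "input.bed" if cond == "input" else f"reads_{cond}.bed"
        pio.write_bed(df, os.path.join(outdir, name))
    study.truth.targets.to_csv(
        os.path.join(outdir, "peaks_truth.tsv"), sep="\t", index=False
    )
    pio.write_fasta(study.sequences, os.path.join(outdir, "sequences.fasta"))
    study.ct.to_csv(os.path.join(outdir, "ct.tsv"), sep="\t", index=False)
    with open(os.path.join(outdir, "truth.json"), "w") as fh:
        fh.write(study.truth.to_json())
    return study


# ---------------------------------------------------------------------------
# Builders for bookkeeping tables given only marginal pattern counts.  These
# let the counting/classification routines run on published summary numbers
# (pattern counts) without per-gene data.

def probe_table_from_pattern_counts(
    unique_ab: int, unique_tumour: int, shared: int, none: int
) -> pd.DataFrame:
    """A minimal probe-level direction table realizing given pattern counts."""
    rows = []
    spec = [
        ("uab", unique_ab, 1, 0),
        ("utu", unique_tumour, 0, 1),
        ("sh", shared, 1, 1),
        ("no", none, 0, 0),
    ]
    for tag, count, da, dt in spec:
        for i in range(count):
            rows.append(
                {
                    "probe_set_id": f"{tag}{i + 1}",
                    "gene_id": f"gene_{tag}{i + 1}",
                    "dir_ab": da,
                    "dir_scrib_ab": dt,
                }
            )
    return pd.DataFrame(rows)


def gene_tables_from_pattern_counts(
    counts: Mapping[Tuple[str, str], int]
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Gene-call and target-flag tables realizing (dereg, peak) pattern counts.

    ``counts`` maps (dereg_pattern, peak_pattern) pairs to gene counts.
    Returns ``(gene_calls, target_flags)`` frames in the column conventions
    of :mod:`peakstate.expression` and :mod:`peakstate.targets`.
    """
    calls, flags = [], []
    gi = 0
    for (dereg, peaks), count in counts.items():
        for _ in range(count):
            gi += 1
            gene = f"G{gi:05d}"
            calls.append(
                {
                    "gene_id": gene,
                    "n_probes": 1,
                    "dereg_ab": dereg in ("both", "ab_only"),
                    "dereg_tumour": dereg in ("both", "tumour_only"),
                    "assignment": dereg,
                    "conflict_ab": False,
                    "conflict_tumour": False,
                    "mixed_evidence": False,
                }
            )
            flags.append(
                {
                    "gene_id": gene,
                    "has_peak_ab": peaks in ("both", "ab_only"),
                    "has_peak_scrib_ab": peaks in ("both", "tumour_only"),
                }
            )
    return pd.DataFrame(calls), pd.DataFrame(flags)
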