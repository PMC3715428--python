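"""PWM scanning and normalized rank-shift motif overrepresentation.

Every matrix of a PWM collection is scanned over the peak-derived sequence
set and over a genome-background sequence set at the same log-odds score
threshold.  Hit counts are normalized by the total length of each set
(hits per bp, with a pseudo-hit to avoid zero densities), matrices are
ranked by density separately within each set (densest = rank 1), and the
rank shift of a matrix is its genome rank minus its peak-set rank.  A
matrix is called overrepresented when its rank shift reaches ``min_shift``
(200 by default, calibrated to collections of several hundred matrices)
and its normalized log2 fold change is positive — in every supplied
experiment when rankings from more than one ChIP condition are given.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import motifs as bio_motifs

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass
class PWM:
    """A position count matrix with scoring parameters.

    ``counts`` is a 4 x width array over A/C/G/T rows.  Scores are log2
    odds of the pseudocount-regularised column probabilities against the
    background base composition.
    """

    matrix_id: str
    counts: np.ndarray
    pseudocount: float = 0.5
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, float)
        self.background = np.asarray(self.background, float)
        if self.counts.shape[0] != 4:
            raise ValueError("counts must have 4 rows (A,C,G,T)")
        if np.any(self.background <= 0):
            raise ValueError("background frequencies must be positive")

    @property
    def width(self) -> int:
        return self.counts.shape[1]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.counts.argmax(axis=0))


def pwm_logodds(pwm: PWM) -> np.ndarray:
    """4 x width log2-odds score matrix of a PWM vs its background."""
    c = pwm.counts + pwm.pseudocount
    probs = c / c.sum(axis=0, keepdims=True)
    return np.log2(probs / pwm.background[:, None])


def max_score(pwm: PWM) -> float:
    return float(pwm_logodds(pwm).max(axis=0).sum())


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    out = np.full(arr.shape, 4, dtype=np.int8)  # 4 = N / unknown
    for b, i in _BASE_INDEX.items():
        out[arr == ord(b)] = i
    return out


def _window_scores(encoded: np.ndarray, lod: np.ndarray) -> np.ndarray:
    """Log-odds score of every window; windows containing N score -inf."""
    w = lod.shape[1]
    L = encoded.size
    if L < w:
        return np.empty(0)
    lut = np.vstack([lod, np.full((1, w), -np.inf)])  # row 4 for N
    scores = np.zeros(L - w + 1)
    for j in range(w):
        scores += lut[encoded[j : L - w + 1 + j], j]
    return scores


def scan_sequence(seq: str, pwm: PWM, threshold_frac: float = 0.8) -> List[dict]:
    """Hits of a PWM on both strands of one sequence.

    A window is a hit when its score reaches ``threshold_frac`` times the
    maximum achievable score.  Positions are 0-based on the forward strand
    (leftmost base of the matched window).
    """
    lod = pwm_logodds(pwm)
    thr = threshold_frac * max_score(pwm)
    w = pwm.width
    hits = []
    fwd = _window_scores(_encode(seq), lod)
    for pos in np.flatnonzero(fwd >= thr):
        hits.append({"pos": int(pos), "strand": "+", "score": float(fwd[pos])})
    rev = _window_scores(_encode(reverse_complement(seq)), lod)
    L = len(seq)
    for pos in np.flatnonzero(rev >= thr):
        hits.append(
            {"pos": int(L - pos - w), "strand": "-", "score": float(rev[pos])}
        )
    return hits


def scan_sequences(
    seqs: Mapping[str, str], pwm: PWM, threshold_frac: float = 0.8
) -> pd.DataFrame:
    """Hit table (seq_id, pos, strand, score) of one PWM over a set."""
    rows = []
    for seq_id, seq in seqs.items():
        for h in scan_sequence(seq, pwm, threshold_frac):
            rows.append({"seq_id": seq_id, **h})
    return pd.DataFrame(rows, columns=["seq_id", "pos", "strand", "score"])


def count_hits(
    seqs: Mapping[str, str], pwms: Sequence[PWM], threshold_frac: float = 0.8
) -> Dict[str, int]:
    """Total hit count per matrix over a sequence set."""
    return {
        p.matrix_id: len(scan_sequences(seqs, p, threshold_frac)) for p in pwms
    }


def total_length(seqs: Mapping[str, str]) -> int:
    return sum(len(s) for s in seqs.values())


def rank_matrices(
    hits_set: Mapping[str, int],
    set_length: int,
    hits_genome: Mapping[str, int],
    genome_length: int,
    pseudo_hits: float = 0.5,
) -> pd.DataFrame:
    """Normalized densities, ranks and rank shifts for every matrix.

    Density = (hits + pseudo_hits) / total length, per set.  Ranks are
    assigned within each set with 1 for the densest matrix; ties are broken
    by matrix id for determinism.  rank_shift = rank_genome - rank_set, and
    fold_change = log2(density_set / density_genome).
    """
    if set_length <= 0 or genome_length <= 0:
        raise ValueError("sequence set lengths must be positive")
    if set(hits_set) != set(hits_genome):
        raise ValueError("matrix collections differ between the two scans")
    ids = sorted(hits_set)
    df = pd.DataFrame(
        {
            "matrix_id": ids,
            "hits_set": [int(hits_set[i]) for i in ids],
            "hits_genome": [int(hits_genome[i]) for i in ids],
        }
    )
    df["set_length"] = set_length
    df["genome_length"] = genome_length
    df["norm_density_set"] = (df["hits_set"] + pseudo_hits) / set_length
    df["norm_density_genome"] = (df["hits_genome"] + pseudo_hits) / genome_length
    df["fold_change"] = np.log2(df["norm_density_set"] / df["norm_density_genome"])
    # densest first; ties resolved by matrix_id (already the sort order)
    for col, rank_col in (
        ("norm_density_set", "rank_set"),
        ("norm_density_genome", "rank_genome"),
    ):
        order = df.sort_values([col, "matrix_id"], ascending=[False, True]).index
        ranks = pd.Series(np.arange(1, len(df) + 1), index=order)
        df[rank_col] = ranks.reindex(df.index).astype(int)
    df["rank_shift"] = df["rank_genome"] - df["rank_set"]
    return df


def select_overrepresented(
    rankings: pd.DataFrame | Sequence[pd.DataFrame], min_shift: int = 200
) -> List[str]:
    """Matrices with rank_shift >= min_shift and positive fold change.

    With rankings from several ChIP experiments the criterion must hold in
    each of them.  Returns matrix ids sorted by decreasing rank shift in
    the first ranking.
    """
    if isinstance(rankings, pd.DataFrame):
        rankings = [rankings]
    if min_shift >= len(rankings[0]):
        import warnings

        warnings.warn(
            "min_shift is not attainable with this collection size",
            RuntimeWarning,
            stacklevel=2,
        )
    selected = None
    for df in rankings:
        ok = set(
            df.loc[(df["rank_shift"] >= min_shift) & (df["fold_change"] > 0),
                   "matrix_id"]
        )
        selected = ok if selected is None else selected & ok
    first = rankings[0].set_index("matrix_id")
    return sorted(selected, key=lambda m: (-first.at[m, "rank_shift"], m))


def read_jaspar(path: str) -> List[PWM]:
    """Load a JASPAR-format count-matrix file into PWM objects."""
    with open(path) as fh:
        records = bio_motifs.parse(fh, "jaspar")
    out = []
    for m in records:
        counts = np.array([m.counts[b] for b in BASES], float)
        out.append(PWM(matrix_id=m.matrix_id or m.name, counts=counts))
    return out


def write_jaspar(pwms: Sequence[PWM], path: str) -> None:
    with open(path, "w") as fh:
        for p in pwms:
            fh.write(f">{p.matrix_id} {p.matrix_id}\n")
            for bi, b in enumerate(BASES):
                vals = " ".join(f"{v:.2f}" for v in p.counts[bi])
                fh.write(f"{b}  [ {vals} ]\n")


def shuffled_decoys(pwm: PWM, n: int, rng: np.random.Generator) -> List[PWM]:
    """Column-shuffled variants of a PWM, used as a decoy collection."""
    out = []
    for i in range(n):
        perm = rng.permutation(pwm.width)
        out.append(
            PWM(
                matrix_id=f"{pwm.matrix_id}_shuf{i + 1}",
                counts=pwm.counts[:, perm].copy(),
                pseudocount=pwm.pseudocount,
                background=pwm.background.copy(),
            )
        )
    return out
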