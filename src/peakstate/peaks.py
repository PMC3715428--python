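"""Input-normalised ChIP peak calling and coverage utilities.

This is a deliberately simple, fully documented caller: reads (stranded 5'
positions) are extended to ``read_length`` bases, candidate segments are
maximal runs of pileup depth >= ``seed_depth``, segments closer than
``max_gap`` are merged, and each merged region is tested against the
scaled input control with a sign-test-style binomial: with k_s sample reads
and k_i input reads overlapping the region (input scaled by the ratio of
total read counts), the enrichment p-value is the upper tail of
Binomial(k_s + round(r*k_i), 1/2) at k_s.  Regions are kept when
p < ``pval_thresh`` and the BH-adjusted q < ``min_fdr``.  The defaults
(read_length=40, max_gap=40, min_fdr=0.01, pval_thresh=1e-4) mirror common
practice for short-read ChIP of a sequence-specific factor.

Peak ``height`` is the maximum per-base extended-read depth inside the
region; the strongest peaks can be selected with ``height >= 40``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .expression import bh_adjust

Interval = Tuple[int, int]


@dataclass
class PeakCallerConfig:
    read_length: int = 40
    max_gap: int = 40
    min_fdr: float = 0.01
    pval_thresh: float = 1e-4
    #: minimum pileup depth to seed a candidate segment
    seed_depth: int = 2

    def validate(self) -> None:
        if self.read_length <= 0:
            raise ValueError("read_length must be positive")
        if self.max_gap < 0:
            raise ValueError("max_gap must be >= 0")
        if not 0 < self.min_fdr < 1:
            raise ValueError("min_fdr must be in (0,1)")
        if not 0 < self.pval_thresh < 1:
            raise ValueError("pval_thresh must be in (0,1)")
        if self.seed_depth < 1:
            raise ValueError("seed_depth must be >= 1")


def extended_intervals(
    reads: pd.DataFrame, chrom_length: int, read_length: int
) -> Tuple[np.ndarray, np.ndarray]:
    """Clipped [start, end) of each read extended read_length bases 3'-ward.

    A + read with 5' end at p covers [p, p+L); a - read covers (p-L, p],
    i.e. [p-L+1, p+1).  Intervals are clipped to [0, chrom_length).
    """
    pos = reads["start"].to_numpy(int)
    minus = (reads["strand"] == "-").to_numpy()
    start = np.where(minus, pos - read_length + 1, pos)
    end = np.where(minus, pos + 1, pos + read_length)
    start = np.clip(start, 0, chrom_length)
    end = np.clip(end, 0, chrom_length)
    keep = end > start
    return start[keep], end[keep]


def extend_and_pileup(
    reads: pd.DataFrame, chrom_sizes: Dict[str, int], read_length: int = 40
) -> Dict[str, np.ndarray]:
    """Per-base coverage of strand-wise extended reads, per chromosome."""
    cov = {c: np.zeros(n, dtype=np.int64) for c, n in chrom_sizes.items()}
    for chrom, grp in reads.groupby("chrom"):
        if chrom not in cov:
            continue
        n = chrom_sizes[chrom]
        start, end = extended_intervals(grp, n, read_length)
        delta = np.zeros(n + 1, dtype=np.int64)
        np.add.at(delta, start, 1)
        np.add.at(delta, end, -1)
        cov[chrom] = np.cumsum(delta[:-1])
    return cov


def candidate_segments(cov: np.ndarray, seed_depth: int) -> List[Interval]:
    """Maximal runs of coverage >= seed_depth, as half-open intervals."""
    above = cov >= seed_depth
    if not above.any():
        return []
    padded = np.concatenate(([False], above, [False]))
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return list(zip(starts.tolist(), ends.tolist()))


def merge_segments(segments: Sequence[Interval], max_gap: int) -> List[Interval]:
    """Chain segments whose gap is <= max_gap into single regions."""
    if not segments:
        return []
    segs = sorted(segments)
    merged = [list(segs[0])]
    for a, b in segs[1:]:
        if a - merged[-1][1] <= max_gap:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    return [tuple(m) for m in merged]


def _overlap_counts(
    starts: np.ndarray, ends: np.ndarray, regions: Sequence[Interval]
) -> np.ndarray:
    """Number of [start,end) intervals overlapping each region (>=1 bp)."""
    s = np.sort(starts)
    e = np.sort(ends)
    out = np.empty(len(regions), dtype=np.int64)
    for i, (a, b) in enumerate(regions):
        # overlap iff start < b and end > a
        out[i] = np.searchsorted(s, b, side="left") - np.searchsorted(e, a, side="right")
    return out


def call_peaks(
    sample_reads: pd.DataFrame,
    input_reads: pd.DataFrame,
    chrom_sizes: Dict[str, int],
    cfg: PeakCallerConfig | None = None,
) -> pd.DataFrame:
    """FDR-filtered enriched regions of a ChIP sample vs its input control.

    Returns a BED-like frame (chrom, start, end, name, height, sample_count,
    scaled_input_count, p, q) sorted by position.  Raises if the input
    sample is empty, since the scaling factor would be undefined.
    """
    cfg = cfg or PeakCallerConfig()
    cfg.validate()
    if len(input_reads) == 0:
        raise ValueError("empty input control: read-count scaling undefined")
    scale = len(sample_reads) / len(input_reads)
    cov = extend_and_pileup(sample_reads, chrom_sizes, cfg.read_length)

    rows = []
    for chrom, n in chrom_sizes.items():
        regions = merge_segments(
            candidate_segments(cov[chrom], cfg.seed_depth), cfg.max_gap
        )
        if not regions:
            continue
        s_grp = sample_reads[sample_reads["chrom"] == chrom]
        i_grp = input_reads[input_reads["chrom"] == chrom]
        s_start, s_end = extended_intervals(s_grp, n, cfg.read_length)
        i_start, i_end = extended_intervals(i_grp, n, cfg.read_length)
        k_s = _overlap_counts(s_start, s_end, regions)
        k_i = _overlap_counts(i_start, i_end, regions)
        for (a, b), ks, ki in zip(regions, k_s, k_i):
            ki_scaled = ki * scale
            n_trials = int(ks + np.round(ki_scaled))
            p = stats.binom.sf(ks - 1, n_trials, 0.5) if n_trials > 0 else 1.0
            rows.append(
                {
                    "chrom": chrom,
                    "start": int(a),
                    "end": int(b),
                    "height": int(cov[chrom][a:b].max()),
                    "sample_count": int(ks),
                    "scaled_input_count": float(ki_scaled),
                    "p": float(p),
                }
            )
    peaks = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "height", "sample_count",
                       "scaled_input_count", "p"],
    )
    if len(peaks) == 0:
        peaks["q"] = pd.Series(dtype=float)
        peaks["name"] = pd.Series(dtype=str)
        return peaks
    peaks["q"] = bh_adjust(peaks["p"])
    peaks = peaks[(peaks["p"] < cfg.pval_thresh) & (peaks["q"] < cfg.min_fdr)]
    peaks = peaks.sort_values(["chrom", "start"]).reset_index(drop=True)
    peaks.insert(3, "name", [f"peak_{i + 1}" for i in range(len(peaks))])
    return peaks


def sample_correlation(
    cov_a: Dict[str, np.ndarray], cov_b: Dict[str, np.ndarray], bin_size: int = 1000
) -> float:
    """Pearson correlation of binned genome-wide coverage of two samples."""
    if set(cov_a) != set(cov_b):
        raise ValueError("coverage tracks span different chromosomes")
    xs, ys = [], []
    for chrom in sorted(cov_a):
        a, b = cov_a[chrom], cov_b[chrom]
        if len(a) != len(b):
            raise ValueError(f"coverage length mismatch on {chrom}")
        nbins = int(np.ceil(len(a) / bin_size))
        pad = nbins * bin_size - len(a)
        xs.append(np.pad(a.astype(float), (0, pad)).reshape(nbins, bin_size).sum(axis=1))
        ys.append(np.pad(b.astype(float), (0, pad)).reshape(nbins, bin_size).sum(axis=1))
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance: correlation undefined")
    return float(stats.pearsonr(x, y)[0])


def select_top_peaks(peaks: pd.DataFrame, min_height: int = 40) -> pd.DataFrame:
    """Peaks whose height reaches min_height (inclusive), order preserved."""
    return peaks[peaks["height"] >= min_height].reset_index(drop=True)
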