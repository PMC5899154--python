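"""Locus-level comparative statistics.

Inter-TAD interaction frequency with a Wilcoxon rank-sum comparison,
peak-density sliding windows (CTCF-style), a 2x2 chi-square colocalization
test, the 2^(-ddCt) qPCR fold change, and deletion-interval arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .contact_map import BinnedContactMap, snap_to_bins
from .regions import GenomicRegion, PeakRecord


@dataclass(frozen=True)
class PairSampleComparison:
    """Result of a two-group comparison."""

    test_name: str
    statistic: float
    p_value: float
    n_a: int
    n_b: int
    degenerate: bool = False
    ratio: float | None = None  # group-b / group-a mean ratio when meaningful

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")
        if self.n_a < 1 or self.n_b < 1:
            raise ValueError("both groups need at least one observation")


@dataclass(frozen=True)
class WindowDensityTrack:
    """Per-window peak counts over an extent."""

    extent: GenomicRegion
    window_size: int
    step: int
    counts: np.ndarray

    @property
    def n_windows(self) -> int:
        return self.counts.size

    def window_start(self, t: int) -> int:
        return self.extent.start + t * self.step

    def window_of(self, position: float) -> int:
        """Index of the last window whose span contains ``position``."""
        t = int((position - self.extent.start) // self.step)
        t = min(t, self.n_windows - 1)
        while t >= 0 and not (
            self.window_start(t) <= position < self.window_start(t) + self.window_size
        ):
            t -= 1
        if t < 0:
            raise ValueError(f"position {position} not covered by any window")
        return t


def inter_tad_values(cmap: BinnedContactMap, tad_a: GenomicRegion,
                     tad_b: GenomicRegion) -> list[float]:
    """Unmasked contact values of the rectangular block tad_a x tad_b.

    Measures how often the two domains touch each other across their shared
    boundary; values are flattened row-major.
    """
    if tad_a.overlaps(tad_b):
        raise ValueError("TADs must be disjoint")
    r0, r1 = snap_to_bins(cmap.row_region, cmap.bin_size, tad_a)
    c0, c1 = snap_to_bins(cmap.col_region, cmap.bin_size, tad_b)
    block = cmap.values[r0:r1, c0:c1]
    return [float(v) for v in block.ravel() if not np.isnan(v)]


def compare_inter_tad(wt: list[float], ko: list[float]) -> PairSampleComparison:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) comparison of two pools."""
    if not wt or not ko:
        raise ValueError("both samples must be non-empty")
    a, b = np.asarray(wt, float), np.asarray(ko, float)
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return PairSampleComparison("wilcoxon-rank-sum", 0.0, 1.0,
                                    a.size, b.size, degenerate=True)
    res = sps.mannwhitneyu(a, b, alternative="two-sided")
    return PairSampleComparison("wilcoxon-rank-sum", float(res.statistic),
                                float(res.pvalue), a.size, b.size)


def peak_density_windows(peaks: list[PeakRecord], extent: GenomicRegion,
                         window_size: int, step: int | None = None
                         ) -> WindowDensityTrack:
    """Count peak midpoints per sliding window across ``extent``.

    The default step equals the window size (non-overlapping tiling), which
    conserves counts; a smaller step yields overlapping windows.  A peak is
    assigned to a window when its midpoint lies in [window_start, window_end).
    """
    step = window_size if step is None else step
    if step <= 0:
        raise ValueError("step must be positive")
    if window_size > len(extent):
        raise ValueError("window larger than extent")
    n_windows = (len(extent) - window_size) // step + 1
    mids = np.array(sorted(
        p.region.midpoint for p in peaks
        if p.region.chrom == extent.chrom
    ))
    counts = np.zeros(n_windows, dtype=int)
    for t in range(n_windows):
        ws = extent.start + t * step
        counts[t] = np.searchsorted(mids, ws + window_size, "left") - \
            np.searchsorted(mids, ws, "left")
    return WindowDensityTrack(extent, window_size, step, counts)


def window_rank(track: WindowDensityTrack,
                region: GenomicRegion) -> tuple[int, float]:
    """Descending rank and empirical quantile of the window holding ``region``.

    The rank is a competition rank (1 = highest count); the quantile uses the
    mid-rank tie rule, so a track of all-equal counts sits near 0.5 and a
    unique maximum at exactly 1.0.
    """
    if region.chrom != track.extent.chrom:
        raise ValueError("region on a different chromosome than the track")
    t = track.window_of(region.midpoint)
    counts = track.counts
    rank = int(1 + np.sum(counts > counts[t]))
    mid_rank = float(sps.rankdata(-counts, method="average")[t])
    quantile = 1.0 - (mid_rank - 1.0) / counts.size
    return rank, quantile


def colocalization_test(k_wt: int, n_wt: int, k_ko: int, n_ko: int,
                        continuity: bool = False) -> PairSampleComparison:
    """Pearson chi-square test on a 2x2 colocalized/not table.

    No continuity correction by default; ``continuity=True`` applies Yates'.
    """
    for k, n in ((k_wt, n_wt), (k_ko, n_ko)):
        if n <= 0:
            raise ValueError("group sizes must be positive")
        if not 0 <= k <= n:
            raise ValueError(f"count {k} outside [0, {n}]")
    table = np.array([[k_wt, n_wt - k_wt], [k_ko, n_ko - k_ko]], float)
    if (table.sum(axis=0) == 0).any():
        # a zero column margin forces equal proportions: no association
        return PairSampleComparison("chi-square", 0.0, 1.0, n_wt, n_ko,
                                    degenerate=True)
    chi2, p, _, _ = sps.chi2_contingency(table, correction=continuity)
    return PairSampleComparison("chi-square", float(chi2), float(p),
                                n_wt, n_ko)


def ddct_fold_change(ct_target_case: float, ct_ref_case: float,
                     ct_target_ctrl: float, ct_ref_ctrl: float) -> float:
    """Relative expression by the 2^(-ddCt) method.

    ddCt = (Ct_target - Ct_reference)_case - (Ct_target - Ct_reference)_control.
    """
    for ct in (ct_target_case, ct_ref_case, ct_target_ctrl, ct_ref_ctrl):
        if not np.isfinite(ct):
            raise ValueError("Ct values must be finite")
    ddct = (ct_target_case - ct_ref_case) - (ct_target_ctrl - ct_ref_ctrl)
    return float(2.0 ** (-ddct))


def deletion_span(cut5: GenomicRegion, cut3: GenomicRegion) -> tuple[int, int]:
    """Deleted interval between two cassette insertion points.

    Measured from the downstream edge of the 5' cut point to the upstream
    edge of the 3' cut point.  Returns (bp, kb) with kb rounded half-up.
    """
    if cut5.chrom != cut3.chrom:
        raise ValueError("cut sites must be on the same chromosome")
    if cut3.start < cut5.end:
        raise ValueError("3' cut site precedes 5' cut site")
    bp = cut3.start - cut5.end
    kb = int((bp + 500) // 1000)
    return bp, kb
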