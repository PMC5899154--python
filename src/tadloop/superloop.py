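"""Long-range (super-loop) interaction significance machinery.

The core procedure: fix a small window of bin pairs anchored on two distant
loci (the putative loop), then slide a window of the same shape bin-by-bin
across the whole heatmap and Welch-t-test each position's values against the
target window's values.  A condition carrying a genuine focal interaction
yields a sliding grid dominated by small p-values; the per-position p-value
distributions of several conditions are then compared by one-way ANOVA.

A second, coarser quantification flattens the bin-pair rectangles between
each pair of anchor loci (padded, typically +/- 100 kb at 100 kb bins) and
compares conditions pairwise by t-test.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import stats as sps

from .contact_map import BinnedContactMap, bin_index, snap_to_bins
from .regions import GenomicRegion
from .stats import PairSampleComparison

_EPS_VAR = 1e-300


@dataclass(frozen=True)
class WindowSpec:
    """Shape and anchoring of the target window (e.g. 6 x 7 bins at 40 kb)."""

    n_rows: int = 6
    n_cols: int = 7
    anchor_row: GenomicRegion | None = None
    anchor_col: GenomicRegion | None = None

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("window dimensions must be >= 1")
        if self.n_rows * self.n_cols < 2:
            raise ValueError("a t-test needs at least 2 window values")

    @property
    def size(self) -> int:
        return self.n_rows * self.n_cols


def _window_origin(cmap: BinnedContactMap, spec: WindowSpec) -> tuple[int, int]:
    """Top-left bin of the window centered on the anchor midpoints.

    The center is the bin containing each anchor's midpoint; for even window
    dimensions the extra row/column goes downstream of the center.
    """
    if spec.anchor_row is None or spec.anchor_col is None:
        raise ValueError("window spec has no anchors")
    r = bin_index(cmap.row_region, cmap.bin_size, spec.anchor_row.midpoint)
    c = bin_index(cmap.col_region, cmap.bin_size, spec.anchor_col.midpoint)
    return r - (spec.n_rows - 1) // 2, c - (spec.n_cols - 1) // 2


def extract_target_window(cmap: BinnedContactMap,
                          spec: WindowSpec) -> list[float]:
    """Row-major values of the anchored target window (NaN kept in place)."""
    r0, c0 = _window_origin(cmap, spec)
    nr, nc = cmap.shape
    if r0 < 0 or c0 < 0 or r0 + spec.n_rows > nr or c0 + spec.n_cols > nc:
        raise ValueError("anchored window exceeds the map extent")
    block = cmap.values[r0:r0 + spec.n_rows, c0:c0 + spec.n_cols]
    return [float(v) for v in block.ravel()]


@dataclass
class SlidingWindowResult:
    """Per-position Welch t statistics and p-values over a heatmap."""

    row_region: GenomicRegion
    col_region: GenomicRegion
    bin_size: int
    spec: WindowSpec
    target: np.ndarray
    t: np.ndarray        # grid (R - n_rows + 1) x (C - n_cols + 1)
    p: np.ndarray
    valid: np.ndarray    # bool grid

    @property
    def n_positions(self) -> int:
        return self.p.size

    def valid_pvalues(self) -> np.ndarray:
        return self.p[self.valid]

    def to_table(self) -> "np.ndarray":
        """(row_bin, col_bin, t, p, valid) rows for TSV export."""
        rr, cc = np.meshgrid(np.arange(self.t.shape[0]),
                             np.arange(self.t.shape[1]), indexing="ij")
        return np.column_stack([rr.ravel(), cc.ravel(), self.t.ravel(),
                                self.p.ravel(), self.valid.ravel()])


def _welch_grid(m1, v1, n1, m2, v2, n2):
    """Vectorized two-sided Welch t-test; zero-variance positions get
    p = 1 on equal means and p = 0 otherwise."""
    se2 = v1 / n1 + v2 / n2
    degenerate = se2 <= _EPS_VAR
    se2_safe = np.where(degenerate, 1.0, se2)
    t = (m1 - m2) / np.sqrt(se2_safe)
    df_num = se2_safe ** 2
    df_den = (v1 / n1) ** 2 / np.maximum(n1 - 1, 1) + \
        (v2 / n2) ** 2 / np.maximum(n2 - 1, 1)
    df = df_num / np.where(df_den <= 0, 1.0, df_den)
    p = 2.0 * sps.t.sf(np.abs(t), df)
    equal = np.isclose(m1, m2, rtol=0, atol=1e-12)
    signed_inf = np.where(np.asarray(m1) > m2, np.inf, -np.inf)
    t = np.where(degenerate, np.where(equal, 0.0, signed_inf), t)
    p = np.where(degenerate, np.where(equal, 1.0, 0.0), p)
    return t, p


def slide_window_test(cmap: BinnedContactMap, spec: WindowSpec,
                      target: list[float] | np.ndarray,
                      exclude_target: bool = False,
                      max_masked_fraction: float = 0.5) -> SlidingWindowResult:
    """Welch-t-test every window position of the heatmap against the target.

    Positions whose window is more than ``max_masked_fraction`` masked, has
    fewer than 2 present values, or (on a square intra map) touches the
    diagonal — where distance decay would dominate the comparison — are
    flagged invalid.  With ``exclude_target`` the target's own position is
    flagged invalid as well; by default it is kept and scores p = 1 against
    itself.
    """
    target = np.asarray(target, float)
    if target.size != spec.size:
        raise ValueError(
            f"target has {target.size} values, window holds {spec.size}"
        )
    nr, nc = cmap.shape
    if nr < spec.n_rows or nc < spec.n_cols:
        raise ValueError("map smaller than the sliding window")
    tvals = target[~np.isnan(target)]
    if tvals.size < 2:
        raise ValueError("target window needs >= 2 present values")
    m2, v2, n2 = tvals.mean(), tvals.var(ddof=1), tvals.size

    windows = sliding_window_view(cmap.values, (spec.n_rows, spec.n_cols))
    flat = windows.reshape(windows.shape[0], windows.shape[1], -1)
    present = ~np.isnan(flat)
    n1 = present.sum(axis=2)
    safe_n = np.maximum(n1, 1)
    filled = np.where(present, flat, 0.0)
    m1 = filled.sum(axis=2) / safe_n
    ss = (filled ** 2).sum(axis=2)
    v1 = np.maximum(ss - safe_n * m1 ** 2, 0.0) / np.maximum(n1 - 1, 1)
    valid = (n1 >= np.maximum(2, spec.size * (1 - max_masked_fraction)))

    if cmap.is_square:
        # a window at origin (i, j) spans rows i..i+nr-1, cols j..j+nc-1;
        # it touches the diagonal iff those ranges intersect
        ii = np.arange(windows.shape[0])[:, None]
        jj = np.arange(windows.shape[1])[None, :]
        touches = (ii <= jj + spec.n_cols - 1) & (jj <= ii + spec.n_rows - 1)
        valid &= ~touches

    m1s = np.where(valid, m1, 0.0)
    v1s = np.where(valid, np.nan_to_num(v1), 0.0)
    t, p = _welch_grid(m1s, v1s, np.maximum(n1, 2), m2, v2, n2)
    t = np.where(valid, t, np.nan)
    p = np.where(valid, p, np.nan)

    if exclude_target and spec.anchor_row is not None:
        r0, c0 = _window_origin(cmap, spec)
        if 0 <= r0 < valid.shape[0] and 0 <= c0 < valid.shape[1]:
            valid[r0, c0] = False
            t[r0, c0] = np.nan
            p[r0, c0] = np.nan

    return SlidingWindowResult(cmap.row_region, cmap.col_region, cmap.bin_size,
                               spec, target, t, p, valid)


@dataclass(frozen=True)
class AnovaComparison:
    """One-way ANOVA across conditions plus density summaries for plotting."""

    labels: tuple[str, ...]
    f_statistic: float
    p_value: float
    grid: np.ndarray                 # p-value support for the densities
    densities: tuple[np.ndarray | None, ...]  # None for degenerate samples


def compare_pvalue_densities(results: list[SlidingWindowResult],
                             labels: list[str],
                             valid_only: bool = True) -> AnovaComparison:
    """One-way ANOVA on per-position p-value samples across conditions.

    Also evaluates a Gaussian kernel density of each condition's p-values on
    a [0, 1] grid for plotting; conditions with (near-)constant samples get
    no density.
    """
    if len(results) < 2 or len(results) != len(labels):
        raise ValueError("need >= 2 conditions with matching labels")
    samples = []
    for res, label in zip(results, labels):
        sample = res.valid_pvalues() if valid_only else res.p[~np.isnan(res.p)]
        if sample.size < 2:
            raise ValueError(f"condition {label!r} has < 2 valid positions")
        samples.append(sample)
    f_stat, p = sps.f_oneway(*samples)
    grid = np.linspace(0.0, 1.0, 101)
    densities: list[np.ndarray | None] = []
    for sample in samples:
        if np.std(sample) < 1e-12:
            densities.append(None)
        else:
            densities.append(sps.gaussian_kde(sample)(grid))
    return AnovaComparison(tuple(labels), float(f_stat), float(p),
                           grid, tuple(densities))


@dataclass(frozen=True)
class SuperLoopQuant:
    """Flattened bin-pair values between one padded anchor-locus pair."""

    label_a: str
    label_b: str
    pad: int
    values: tuple[float, ...]

    @property
    def n(self) -> int:
        return len(self.values)


def superloop_quant(cmap: BinnedContactMap,
                    regions: dict[str, GenomicRegion],
                    pad: int = 100_000) -> list[SuperLoopQuant]:
    """Quantify every unordered pair among labeled anchor loci.

    Each locus is padded by ``pad`` bp on both sides and snapped outward to
    the bin grid; the rectangle between the two padded spans is flattened.
    At 100 kb bins with the default pad, a 2-bin locus vs a 1-bin locus
    yields n = 4 x 3 = 12 values and two 1-bin loci yield n = 9.
    """
    if pad < 0:
        raise ValueError("pad must be >= 0")
    padded = {label: region.pad(pad) for label, region in regions.items()}
    for (la, ra), (lb, rb) in combinations(padded.items(), 2):
        if ra.overlaps(rb):
            raise ValueError(f"padded regions {la} and {lb} overlap")
    out = []
    for la, lb in combinations(regions, 2):
        r0, r1 = snap_to_bins(cmap.row_region, cmap.bin_size, padded[la])
        c0, c1 = snap_to_bins(cmap.col_region, cmap.bin_size, padded[lb])
        block = cmap.values[r0:r1, c0:c1]
        out.append(SuperLoopQuant(la, lb, pad,
                                  tuple(float(v) for v in block.ravel())))
    return out


def compare_superloop(wt: SuperLoopQuant, ko: SuperLoopQuant
                      ) -> PairSampleComparison:
    """Two-sided Welch t-test between conditions for one anchor pair.

    Reports the KO/WT mean ratio alongside the test.  Constant-and-equal
    vectors give a degenerate p = 1; constant-and-unequal give p = 0.
    """
    if {wt.label_a, wt.label_b} != {ko.label_a, ko.label_b} or wt.n != ko.n:
        raise ValueError("quantifications are not for the same anchor pair")
    a = np.array([v for v in wt.values if not np.isnan(v)])
    b = np.array([v for v in ko.values if not np.isnan(v)])
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 present values per condition")
    ratio = float(b.mean() / a.mean()) if a.mean() != 0 else float("inf")
    if a.var(ddof=1) <= _EPS_VAR and b.var(ddof=1) <= _EPS_VAR:
        if np.isclose(a.mean(), b.mean()):
            return PairSampleComparison("welch-t", 0.0, 1.0, a.size, b.size,
                                        degenerate=True, ratio=ratio)
        return PairSampleComparison("welch-t", float("inf"), 0.0,
                                    a.size, b.size, degenerate=True,
                                    ratio=ratio)
    res = sps.ttest_ind(a, b, equal_var=False)
    return PairSampleComparison("welch-t", float(res.statistic),
                                float(res.pvalue), a.size, b.size, ratio=ratio)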