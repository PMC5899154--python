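"""Insulation score, delta vector, and TAD boundary calling.

For each bin *i* a square of the contact map spanning the *w* bins upstream
by the *w* bins downstream of *i* (excluding bin *i* itself) is aggregated;
the log2 ratio of that aggregate to its mean over the analyzed extent is the
insulation score.  TAD boundaries are local minima of the score, located via
zero crossings of a delta vector (right-flank mean minus left-flank mean of
the score), and each boundary's strength is the amplitude of the delta
excursion across the crossing.

Defaults reproduce the canonical perl-script parameterization used for
mammalian 40 kb maps: 480 kb square, 320 kb delta span, iqrMean aggregation,
zero noise threshold, 160 kb smoothing, zero boundary margin.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .contact_map import BinnedContactMap
from .regions import GenomicRegion

MISSING_STRENGTH = float("nan")


@dataclass(frozen=True)
class InsulationParams:
    """Tunable parameters of the insulation method (bp units)."""

    square_size: int = 480_000       # -is
    delta_span: int = 320_000        # -ids
    aggregation_mode: str = "iqrMean"  # -im: mean | median | iqrMean
    noise_threshold: float = 0.0     # -nt
    smooth_span: int = 160_000       # -ss (0 disables smoothing)
    boundary_margin: int = 0         # -bmoe, in bins
    strength_cutoff: float = 0.1
    max_missing_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.aggregation_mode not in ("mean", "median", "iqrMean"):
            raise ValueError(f"unknown aggregation mode {self.aggregation_mode!r}")
        if self.square_size <= 0 or self.delta_span <= 0:
            raise ValueError("square_size and delta_span must be positive")
        if self.boundary_margin < 0:
            raise ValueError("boundary_margin must be >= 0")

    def square_bins(self, bin_size: int) -> int:
        return max(1, round(self.square_size / bin_size))

    def delta_bins(self, bin_size: int) -> int:
        return max(1, round(self.delta_span / bin_size))

    def smooth_bins(self, bin_size: int) -> int:
        if self.smooth_span <= 0:
            return 1
        k = max(1, round(self.smooth_span / bin_size))
        return k if k % 2 == 1 else k + 1  # centered window


@dataclass
class InsulationProfile:
    """Per-bin insulation score, delta vector, and validity mask."""

    region: GenomicRegion
    bin_size: int
    raw_insulation: np.ndarray
    score: np.ndarray
    mask: np.ndarray            # True where the score is valid
    delta: np.ndarray | None = None
    delta_mask: np.ndarray | None = None

    def bin_region(self, i: int) -> GenomicRegion:
        start = self.region.start + i * self.bin_size
        return GenomicRegion(self.region.chrom, start,
                             min(start + self.bin_size, self.region.end))


@dataclass(frozen=True)
class Boundary:
    """A called TAD boundary: its bin and delta-excursion strength."""

    bin: int
    region: GenomicRegion
    strength: float


@dataclass(frozen=True)
class TADSet:
    """Ordered, contiguous domains tiling an extent between boundaries."""

    domains: tuple[GenomicRegion, ...]

    def __post_init__(self) -> None:
        for a, b in zip(self.domains, self.domains[1:]):
            if a.end != b.start:
                raise ValueError("domains must be contiguous and ordered")


def _aggregate(values: np.ndarray, mode: str) -> float:
    """Aggregate a square's unmasked values; iqrMean keeps [Q1, Q3]."""
    if mode == "mean":
        return float(np.mean(values))
    if mode == "median":
        return float(np.median(values))
    q1, q3 = np.percentile(values, [25, 75])
    kept = values[(values >= q1) & (values <= q3)]
    return float(np.mean(kept)) if kept.size else float(np.mean(values))


def _smooth(raw: np.ndarray, mask: np.ndarray, k: int) -> np.ndarray:
    """Centered running mean over k bins, NaN-aware, masked bins stay masked."""
    if k <= 1:
        return raw.copy()
    half = k // 2
    out = np.full_like(raw, np.nan)
    for i in np.flatnonzero(mask):
        lo, hi = max(0, i - half), min(raw.size, i + half + 1)
        window = raw[lo:hi][mask[lo:hi]]
        out[i] = window.mean()
    return out


def insulation_score(cmap: BinnedContactMap,
                     params: InsulationParams | None = None) -> InsulationProfile:
    """Compute the per-bin insulation profile of a square intra map.

    Bins whose square is truncated by the matrix edge, or contains more than
    ``max_missing_fraction`` masked entries, or aggregates to a non-positive
    value, are masked.  The score is the log2 ratio of the (optionally
    smoothed) square aggregate to its mean over unmasked bins, which makes it
    invariant under global rescaling of the matrix.
    """
    params = params or InsulationParams()
    if not cmap.is_square:
        raise ValueError("insulation requires a square intra-chromosomal map")
    w = params.square_bins(cmap.bin_size)
    n = cmap.shape[0]
    if n < 2 * w:
        raise ValueError(
            f"extent of {n} bins too small for a {w}-bin insulation square"
        )
    raw = np.full(n, np.nan)
    mask = np.zeros(n, dtype=bool)
    for i in range(w, n - w):
        square = cmap.values[i - w:i, i + 1:i + 1 + w]
        present = square[~np.isnan(square)]
        if present.size < square.size * (1 - params.max_missing_fraction):
            continue
        agg = _aggregate(present, params.aggregation_mode)
        if agg > 0:
            raw[i] = agg
            mask[i] = True
    smoothed = _smooth(raw, mask, params.smooth_bins(cmap.bin_size))
    mask &= ~np.isnan(smoothed) & (np.nan_to_num(smoothed) > 0)
    score = np.full(n, np.nan)
    if mask.any():
        reference = smoothed[mask].mean()
        score[mask] = np.log2(smoothed[mask] / reference)
    return InsulationProfile(cmap.row_region, cmap.bin_size, smoothed, score, mask)


def delta_vector(profile: InsulationProfile,
                 params: InsulationParams | None = None) -> InsulationProfile:
    """Attach delta(i) = mean(score over (i, i+s]) - mean(score over [i-s, i)).

    Delta is masked wherever either flank is incomplete (runs off the extent
    or touches a masked score).
    """
    params = params or InsulationParams()
    s = params.delta_bins(profile.bin_size)
    n = profile.score.size
    delta = np.full(n, np.nan)
    dmask = np.zeros(n, dtype=bool)
    for i in range(s, n - s):
        left = slice(i - s, i)
        right = slice(i + 1, i + 1 + s)
        if profile.mask[left].all() and profile.mask[right].all():
            delta[i] = profile.score[right].mean() - profile.score[left].mean()
            dmask[i] = True
    profile.delta = delta
    profile.delta_mask = dmask
    return profile


def _extremum(delta: np.ndarray, valid: np.ndarray, i: int, step: int) -> int:
    """Walk from i in direction step to the nearest local delta extremum."""
    j = i
    while valid[j + step] if 0 <= j + step < delta.size else False:
        nxt = delta[j + step]
        if step < 0 and nxt > delta[j]:
            break
        if step > 0 and nxt < delta[j]:
            break
        j += step
    return j


def call_boundaries(profile: InsulationProfile,
                    params: InsulationParams | None = None) -> list[Boundary]:
    """Call boundaries at negative-to-positive delta zero crossings.

    The strength of a crossing is the delta amplitude between the local delta
    minimum on its falling (left) side and the local delta maximum on its
    rising (right) side; the boundary bin is the score minimum between those
    two extrema.  Crossings weaker than ``strength_cutoff``, below the noise
    threshold at either extremum, or within ``boundary_margin`` bins of a
    masked bin are discarded.
    """
    params = params or InsulationParams()
    if profile.delta is None:
        delta_vector(profile, params)
    delta, dmask = profile.delta, profile.delta_mask
    assert delta is not None and dmask is not None
    boundaries: list[Boundary] = []
    n = delta.size
    for i in range(n - 1):
        if not (dmask[i] and dmask[i + 1]):
            continue
        if not (delta[i] < 0 <= delta[i + 1]):
            continue
        trough = _extremum(delta, dmask, i, -1)
        peak = _extremum(delta, dmask, i + 1, +1)
        strength = float(delta[peak] - delta[trough])
        if strength < params.strength_cutoff:
            continue
        if min(abs(delta[trough]), abs(delta[peak])) < params.noise_threshold:
            continue
        segment = profile.score[trough:peak + 1]
        b = trough + int(np.nanargmin(segment))
        lo = max(0, b - params.boundary_margin)
        hi = min(profile.mask.size, b + params.boundary_margin + 1)
        if not profile.mask[lo:hi].all():
            continue
        boundaries.append(Boundary(b, profile.bin_region(b), strength))
    # noisy deltas can re-cross within one excursion; keep one call per bin
    by_bin: dict[int, Boundary] = {}
    for b in boundaries:
        if b.bin not in by_bin or b.strength > by_bin[b.bin].strength:
            by_bin[b.bin] = b
    return [by_bin[k] for k in sorted(by_bin)]


def boundary_strength_at(profile: InsulationProfile, region: GenomicRegion,
                         params: InsulationParams | None = None,
                         pad: int = 500_000) -> float:
    """Strength of the called boundary nearest ``region`` within ``pad`` bp.

    Returns NaN when no boundary falls inside the search pad.
    """
    params = params or InsulationParams()
    boundaries = call_boundaries(profile, params)
    target = region.midpoint
    best, best_dist = MISSING_STRENGTH, float(pad)
    for b in boundaries:
        dist = abs(b.region.midpoint - target)
        if dist <= best_dist:
            best, best_dist = b.strength, dist
    return best


def tads_from_boundaries(boundaries: list[Boundary],
                         extent: GenomicRegion) -> TADSet:
    """Partition ``extent`` into domains split at each boundary bin start."""
    cuts = []
    for b in sorted(boundaries, key=lambda b: b.bin):
        if not extent.contains(b.region):
            raise ValueError(f"boundary {b.region} outside extent {extent}")
        if extent.start < b.region.start < extent.end:
            cuts.append(b.region.start)
    edges = [extent.start] + cuts + [extent.end]
    domains = tuple(
        GenomicRegion(extent.chrom, a, b) for a, b in zip(edges, edges[1:])
    )
    return TADSet(domains)
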