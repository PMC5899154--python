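"""Synthetic Hi-C ground truth: decayed contact maps with TADs, loops,
deletions, insertion pileups, and peak tracks.

The contact model is deliberately minimal: expected contacts between bins at
genomic distance d follow a power law ``diagonal_level * d^-alpha`` (in bin
units, distance-0 pinned to the distance-1 level), multiplied by a factor in
(0, 1] for every TAD boundary the pair straddles and by a fold >= 1 for every
loop window covering the pair, then globally rescaled to a target sequencing
depth.  Observed maps are independent Poisson draws around that expectation
(upper triangle mirrored for intra maps), which emulates shot noise from
finite read depth.  Only the relative structure matters for the statistics
the package tests; no polymer mechanics are simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .contact_map import BinnedContactMap, bin_index, n_bins
from .insertions import CassetteContactProfile
from .regions import GenomicRegion, PeakRecord


@dataclass(frozen=True)
class LoopSpec:
    """A focal long-range interaction: a fold-enriched window of bin pairs."""

    region_a: GenomicRegion
    region_b: GenomicRegion
    fold: float = 5.0
    n_rows: int = 6
    n_cols: int = 7

    def __post_init__(self) -> None:
        if self.fold < 1:
            raise ValueError("loop fold enrichment must be >= 1")


@dataclass(frozen=True)
class SyntheticSpec:
    """Full parameterization of one simulated contact map."""

    extent: GenomicRegion
    bin_size: int
    depth: float = 5e5               # total expected contacts
    decay_exponent: float = 1.0
    diagonal_level: float = 1.0      # pre-scaling shape level at distance 1
    tad_boundaries: tuple[int, ...] = ()          # bp positions within extent
    boundary_insulation: tuple[float, ...] = ()   # factor in (0, 1] each
    loops: tuple[LoopSpec, ...] = ()
    deletion: GenomicRegion | None = None
    col_extent: GenomicRegion | None = None  # set for off-diagonal rectangles
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.tad_boundaries) != len(self.boundary_insulation):
            raise ValueError("one insulation factor per boundary required")
        if any(b2 <= b1 for b1, b2 in zip(self.tad_boundaries,
                                          self.tad_boundaries[1:])):
            raise ValueError("boundary positions must be strictly increasing")
        for pos in self.tad_boundaries:
            if not self.extent.start < pos < self.extent.end:
                raise ValueError(f"boundary {pos} outside extent {self.extent}")
        for f in self.boundary_insulation:
            if not 0 < f <= 1:
                raise ValueError("insulation factors must lie in (0, 1]")
        if self.depth <= 0 or self.decay_exponent <= 0:
            raise ValueError("depth and decay exponent must be positive")


def _bin_mids(region: GenomicRegion, bin_size: int) -> np.ndarray:
    n = n_bins(region, bin_size)
    return region.start + (np.arange(n) + 0.5) * bin_size


def _loop_block(spec: SyntheticSpec, loop: LoopSpec,
                row_region: GenomicRegion, col_region: GenomicRegion
                ) -> tuple[slice, slice] | None:
    """Window slices of a loop on the (row_region x col_region) grid."""
    if (loop.region_a.chrom != row_region.chrom
            or loop.region_b.chrom != col_region.chrom):
        return None
    r = bin_index(row_region, spec.bin_size, loop.region_a.midpoint)
    c = bin_index(col_region, spec.bin_size, loop.region_b.midpoint)
    r0 = r - (loop.n_rows - 1) // 2
    c0 = c - (loop.n_cols - 1) // 2
    nr = n_bins(row_region, spec.bin_size)
    nc = n_bins(col_region, spec.bin_size)
    if r0 < 0 or c0 < 0 or r0 + loop.n_rows > nr or c0 + loop.n_cols > nc:
        return None
    return slice(r0, r0 + loop.n_rows), slice(c0, c0 + loop.n_cols)


def _deleted_bins(spec: SyntheticSpec, region: GenomicRegion) -> np.ndarray:
    n = n_bins(region, spec.bin_size)
    dead = np.zeros(n, dtype=bool)
    if spec.deletion is not None and spec.deletion.chrom == region.chrom:
        lo = max(spec.deletion.start, region.start)
        hi = min(spec.deletion.end, region.end)
        if lo < hi:
            i0 = (lo - region.start) // spec.bin_size
            i1 = -((region.start - hi) // spec.bin_size)
            dead[i0:i1] = True
    return dead


def expected_map(spec: SyntheticSpec) -> BinnedContactMap:
    """Deterministic expectation matrix of the model (seed-independent).

    Square when ``col_extent`` is unset, otherwise the off-diagonal
    rectangle rows x cols.  The sum of all entries equals ``depth``.
    """
    row_region = spec.extent
    col_region = spec.col_extent or spec.extent
    mids_r = _bin_mids(row_region, spec.bin_size)
    mids_c = _bin_mids(col_region, spec.bin_size)
    if row_region.chrom == col_region.chrom:
        dist = np.abs(mids_r[:, None] - mids_c[None, :]) / spec.bin_size
        dist = np.maximum(dist, 1.0)  # pin the diagonal to the distance-1 level
        values = spec.diagonal_level * dist ** (-spec.decay_exponent)
        for pos, factor in zip(spec.tad_boundaries, spec.boundary_insulation):
            crosses = ((np.minimum(mids_r[:, None], mids_c[None, :]) < pos)
                       & (pos <= np.maximum(mids_r[:, None], mids_c[None, :])))
            values[crosses] *= factor
    else:
        # inter-chromosomal rectangle: no distance structure, flat base
        values = np.full((mids_r.size, mids_c.size), spec.diagonal_level)

    square = spec.col_extent is None
    for loop in spec.loops:
        block = _loop_block(spec, loop, row_region, col_region)
        if block is not None:
            values[block] *= loop.fold
            if square:
                values[block[1], block[0]] *= loop.fold
        elif square:
            # anchors may come in (b, a) order relative to the grid
            swapped = _loop_block(
                spec, replace(loop, region_a=loop.region_b,
                              region_b=loop.region_a), row_region, col_region)
            if swapped is not None:
                values[swapped] *= loop.fold
                values[swapped[1], swapped[0]] *= loop.fold

    if square:
        values = (values + values.T) / 2
    dead_r = _deleted_bins(spec, row_region)
    dead_c = _deleted_bins(spec, col_region)
    values[dead_r, :] = 0.0
    values[:, dead_c] = 0.0

    total = values.sum()
    if total > 0:
        values *= spec.depth / total
    return BinnedContactMap(row_region, col_region, spec.bin_size, values)


def sample_map(spec: SyntheticSpec) -> BinnedContactMap:
    """Poisson-sampled integer contact map; deterministic given the seed.

    For square maps each upper-triangle entry (including the diagonal) is
    drawn once and mirrored, preserving symmetry.
    """
    expected = expected_map(spec)
    rng = np.random.default_rng(spec.seed)
    if expected.is_square:
        n = expected.shape[0]
        iu, ju = np.triu_indices(n)
        draws = rng.poisson(expected.values[iu, ju]).astype(float)
        values = np.zeros((n, n))
        values[iu, ju] = draws
        values[ju, iu] = draws
    else:
        values = rng.poisson(expected.values).astype(float)
    return BinnedContactMap(expected.row_region, expected.col_region,
                            spec.bin_size, values)


def ko_spec(spec: SyntheticSpec, region: GenomicRegion,
            remove_loops_touching: bool = True) -> SyntheticSpec:
    """Knockout scenario: delete a locus, optionally losing loops anchored in it.

    TAD boundaries are left untouched — boundary loss or weakening, when
    wanted, is modeled explicitly through ``boundary_insulation``.
    """
    loops = spec.loops
    if remove_loops_touching:
        loops = tuple(
            lp for lp in spec.loops
            if not (lp.region_a.overlaps(region) or lp.region_b.overlaps(region))
        )
    return replace(spec, deletion=region, loops=loops)


def sample_cassette_profile(chrom_lengths: dict[str, int], bin_size: int,
                            insertions: list[tuple[str, int, float]],
                            background_mean: float, seed: int,
                            condition: str = "sim") -> CassetteContactProfile:
    """Simulate cassette-vs-genome contact vectors with insertion pileups.

    Each bin draws Poisson(background_mean); each insertion adds an
    independent Poisson(pileup_mean) at its bin and Poisson(pileup_mean / 2)
    at the two flanking bins, emulating the spread of a Hi-C pileup.
    """
    rng = np.random.default_rng(seed)
    counts = {
        chrom: rng.poisson(background_mean, n_bins(
            GenomicRegion(chrom, 0, length), bin_size)).astype(float)
        for chrom, length in chrom_lengths.items()
    }
    for chrom, position, pileup_mean in insertions:
        if chrom not in counts:
            raise ValueError(f"insertion on unknown chromosome {chrom}")
        vec = counts[chrom]
        b = int(position // bin_size)
        if not 0 <= b < vec.size:
            raise ValueError(f"insertion at {chrom}:{position} outside extent")
        vec[b] += rng.poisson(pileup_mean)
        for nb in (b - 1, b + 1):
            if 0 <= nb < vec.size:
                vec[nb] += rng.poisson(pileup_mean / 2)
    return CassetteContactProfile(condition, bin_size, counts)


def sample_peaks(extent: GenomicRegion, background_rate: float,
                 hotspot: GenomicRegion, hotspot_count: int,
                 seed: int, peak_width: int = 200) -> list[PeakRecord]:
    """Uniform Poisson-process background peaks plus a dense hotspot.

    ``background_rate`` is in peaks per Mb; ``hotspot_count`` peaks are
    placed uniformly within the hotspot (a CTCF-dense locus stand-in).
    All peaks have a fixed width.
    """
    if not extent.contains(hotspot):
        raise ValueError("hotspot must lie within the extent")
    rng = np.random.default_rng(seed)
    n_bg = rng.poisson(background_rate * len(extent) / 1e6)
    starts = rng.integers(extent.start, extent.end - peak_width,
                          size=n_bg).tolist()
    starts += rng.integers(hotspot.start,
                           max(hotspot.start + 1, hotspot.end - peak_width),
                           size=hotspot_count).tolist()
    return [
        PeakRecord(GenomicRegion(extent.chrom, int(s), int(s) + peak_width))
        for s in sorted(starts)
    ]
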