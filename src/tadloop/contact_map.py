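"""Binned Hi-C contact maps: data model, text I/O, normalization, views.

Two plain-text dialects are supported:

* *dense*: TSV with one header row and one header column, each header cell
  encoding a bin as ``name|assembly|chrom:start-end``; body cells are numeric
  or ``NA`` (masked).
* *sparse triplet*: whitespace-delimited ``bin_i bin_j count`` records with
  ``bin_i <= bin_j`` (upper-triangle convention), accompanied by a BED4 bin
  table ``chrom start end id``.

Masked bins are carried as NaN, never zero, so that depleted bins (e.g. a
deleted locus) drop out of downstream statistics instead of dragging them
down.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .regions import GenomicRegion

_SYMMETRY_TOL = 1e-9

RAW = "raw"
RPM = "rpm"
BALANCED = "balanced"


def n_bins(region: GenomicRegion, bin_size: int) -> int:
    return math.ceil(len(region) / bin_size)


def bin_index(region: GenomicRegion, bin_size: int, position: float) -> int:
    """Bin containing a point: floor((position - start) / bin_size)."""
    return int((position - region.start) // bin_size)


def bin_region(region: GenomicRegion, bin_size: int, i: int) -> GenomicRegion:
    start = region.start + i * bin_size
    return GenomicRegion(region.chrom, start, min(start + bin_size, region.end))


def snap_to_bins(extent: GenomicRegion, bin_size: int,
                 request: GenomicRegion) -> tuple[int, int]:
    """Outward-snapped half-open bin range covering ``request``.

    Returns ``(i0, i1)`` such that bins ``i0..i1-1`` cover every base of the
    requested interval.
    """
    if request.chrom != extent.chrom:
        raise ValueError(f"chromosome mismatch: {request.chrom} vs {extent.chrom}")
    if request.start < extent.start or request.end > extent.end:
        raise ValueError(f"region {request} outside extent {extent}")
    i0 = (request.start - extent.start) // bin_size
    i1 = -((extent.start - request.end) // bin_size)  # ceil division
    return int(i0), int(i1)


@dataclass
class BinnedContactMap:
    """Square (intra) or rectangular (inter-anchor) binned contact matrix."""

    row_region: GenomicRegion
    col_region: GenomicRegion
    bin_size: int
    values: np.ndarray  # float matrix, NaN = masked
    normalization_state: str = RAW
    assembly: str = "unknown"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        expected = (n_bins(self.row_region, self.bin_size),
                    n_bins(self.col_region, self.bin_size))
        if self.values.shape != expected:
            raise ValueError(
                f"matrix shape {self.values.shape} != bin grid {expected}"
            )
        with np.errstate(invalid="ignore"):
            if np.nanmin(self.values, initial=0.0) < 0:
                raise ValueError("contact counts must be non-negative")
        if self.is_square:
            diff = self.values - self.values.T
            if np.nanmax(np.abs(diff), initial=0.0) > _SYMMETRY_TOL:
                raise ValueError("intra-chromosomal map must be symmetric")

    @property
    def is_square(self) -> bool:
        return self.row_region == self.col_region

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def row_bin(self, i: int) -> GenomicRegion:
        return bin_region(self.row_region, self.bin_size, i)

    def col_bin(self, j: int) -> GenomicRegion:
        return bin_region(self.col_region, self.bin_size, j)

    def copy(self) -> "BinnedContactMap":
        return replace(self, values=self.values.copy())


# ---------------------------------------------------------------------------
# dense dialect


def _format_header(name: str, assembly: str, region: GenomicRegion) -> str:
    return f"{name}|{assembly}|{region}"


def _parse_header(cell: str) -> tuple[str, GenomicRegion]:
    parts = cell.split("|")
    if len(parts) != 3:
        raise ValueError(f"bad bin header {cell!r}")
    return parts[1], GenomicRegion.parse(parts[2])


def _bins_to_axis(bins: list[GenomicRegion]) -> tuple[GenomicRegion, int]:
    chroms = {b.chrom for b in bins}
    if len(chroms) != 1:
        raise ValueError("bin headers span multiple chromosomes")
    starts = [b.start for b in bins]
    if any(b2 <= b1 for b1, b2 in zip(starts, starts[1:])):
        raise ValueError("bin coordinates not strictly increasing")
    if len(bins) > 1:
        sizes = {b2 - b1 for b1, b2 in zip(starts, starts[1:])}
        if len(sizes) != 1:
            raise ValueError("non-uniform bin size in headers")
        bin_size = sizes.pop()
    else:
        bin_size = len(bins[0])
    return GenomicRegion(bins[0].chrom, bins[0].start, bins[-1].end), bin_size


def read_dense_matrix(path: str | Path) -> BinnedContactMap:
    """Read the dense TSV dialect (header row + header column)."""
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if len(lines) < 2:
        raise ValueError("dense matrix file needs a header row and >= 1 data row")
    header = lines[0].split("\t")
    col_headers = header[1:]
    assembly, _ = _parse_header(col_headers[0])
    col_bins = [_parse_header(c)[1] for c in col_headers]
    row_bins: list[GenomicRegion] = []
    rows: list[list[float]] = []
    for ln in lines[1:]:
        cells = ln.split("\t")
        if len(cells) != len(col_headers) + 1:
            raise ValueError(
                f"ragged row: {len(cells) - 1} cells, expected {len(col_headers)}"
            )
        row_bins.append(_parse_header(cells[0])[1])
        rows.append([float("nan") if c.upper() == "NA" else float(c)
                     for c in cells[1:]])
    col_region, col_bs = _bins_to_axis(col_bins)
    row_region, row_bs = _bins_to_axis(row_bins)
    if col_bs != row_bs:
        raise ValueError("row/column bin sizes differ")
    return BinnedContactMap(row_region, col_region, row_bs,
                            np.array(rows, dtype=float), assembly=assembly)


def write_dense_matrix(cmap: BinnedContactMap, path: str | Path) -> None:
    """Write the dense TSV dialect; NaN is serialized as ``NA``."""
    nr, nc = cmap.shape
    with open(path, "w") as fh:
        cols = "\t".join(
            _format_header(f"bin{j}", cmap.assembly, cmap.col_bin(j))
            for j in range(nc)
        )
        fh.write(f"{nr}x{nc}\t{cols}\n")
        for i in range(nr):
            cells = "\t".join(
                "NA" if np.isnan(v) else repr(float(v)) for v in cmap.values[i]
            )
            fh.write(
                f"{_format_header(f'bin{i}', cmap.assembly, cmap.row_bin(i))}\t{cells}\n"
            )


# ---------------------------------------------------------------------------
# sparse triplet dialect


def read_sparse_triplet(matrix_path: str | Path,
                        bed_path: str | Path) -> BinnedContactMap:
    """Densify an upper-triangle triplet listing over its BED bin table.

    Counts are mirrored to both (i, j) and (j, i); absent pairs are zero.
    """
    bed = pd.read_csv(bed_path, sep=r"\s+", header=None,
                      names=["chrom", "start", "end", "id"], comment="#")
    chroms = bed["chrom"].unique()
    if len(chroms) != 1:
        raise ValueError("sparse bin table must cover a single chromosome")
    bed = bed.sort_values("start").reset_index(drop=True)
    bins = [GenomicRegion(str(r.chrom), int(r.start), int(r.end))
            for r in bed.itertuples()]
    region, bin_size = _bins_to_axis(bins)
    id_to_idx = {int(r.id): i for i, r in enumerate(bed.itertuples())}

    values = np.zeros((len(bins), len(bins)))
    try:
        trip = pd.read_csv(matrix_path, sep=r"\s+", header=None,
                           names=["a", "b", "n"], comment="#")
    except pd.errors.EmptyDataError:
        trip = pd.DataFrame(columns=["a", "b", "n"])
    for a, b, count in trip.to_numpy():
        if count < 0:
            raise ValueError(f"negative count at ids ({int(a)}, {int(b)})")
        try:
            i, j = id_to_idx[int(a)], id_to_idx[int(b)]
        except KeyError as exc:
            raise ValueError(f"triplet bin id {exc} absent from bin table") from exc
        values[i, j] = count
        values[j, i] = count
    return BinnedContactMap(region, region, bin_size, values)


def write_sparse_triplet(cmap: BinnedContactMap, matrix_path: str | Path,
                         bed_path: str | Path) -> None:
    """Write the upper triangle (including diagonal) plus a BED4 bin table."""
    if not cmap.is_square:
        raise ValueError("sparse triplet output requires a square map")
    with open(bed_path, "w") as fh:
        for i in range(cmap.shape[0]):
            b = cmap.row_bin(i)
            fh.write(f"{b.chrom}\t{b.start}\t{b.end}\t{i + 1}\n")
    with open(matrix_path, "w") as fh:
        iu, ju = np.triu_indices(cmap.shape[0])
        for i, j in zip(iu, ju):
            v = cmap.values[i, j]
            if not np.isnan(v) and v != 0:
                fh.write(f"{i + 1}\t{j + 1}\t{v:g}\n")


# ---------------------------------------------------------------------------
# normalization and views


def normalize_rpm(cmap: BinnedContactMap, total_valid_pairs: int) -> BinnedContactMap:
    """Scale counts to reads per million valid pairs."""
    if total_valid_pairs <= 0:
        raise ValueError("total_valid_pairs must be positive")
    if cmap.normalization_state != RAW:
        raise ValueError(f"map already normalized ({cmap.normalization_state})")
    out = cmap.copy()
    out.values *= 1e6 / total_valid_pairs
    out.normalization_state = RPM
    return out


def balance_ice(cmap: BinnedContactMap, max_iter: int = 200,
                tol: float = 1e-4) -> BinnedContactMap:
    """Iterative row/column scaling (ICE-style matrix balancing).

    Scales until the coefficient of variation of unmasked row sums drops
    below ``tol`` or ``max_iter`` is reached.  All-zero rows are auto-masked;
    masked bins are left untouched.
    """
    if not cmap.is_square:
        raise ValueError("balancing requires a square map")
    values = cmap.values.copy()
    with np.errstate(invalid="ignore"):
        row_tot = np.nansum(values, axis=1)
    dead = (row_tot == 0) | np.all(np.isnan(values), axis=1)
    if dead.all():
        raise ValueError("cannot balance an all-zero matrix")
    values[dead, :] = np.nan
    values[:, dead] = np.nan
    alive = ~dead
    for _ in range(max_iter):
        sums = np.nansum(values[alive][:, alive], axis=1)
        mean = sums.mean()
        cv = sums.std() / mean if mean > 0 else 0.0
        if cv < tol:
            break
        bias = np.ones(values.shape[0])
        bias[alive] = sums / mean
        values /= np.outer(bias, bias)
    out = cmap.copy()
    out.values = values
    out.normalization_state = BALANCED
    return out


def extract_submatrix(cmap: BinnedContactMap, rows: GenomicRegion,
                      cols: GenomicRegion) -> BinnedContactMap:
    """Copy a sub-view, with requests snapped outward to the bin grid."""
    r0, r1 = snap_to_bins(cmap.row_region, cmap.bin_size, rows)
    c0, c1 = snap_to_bins(cmap.col_region, cmap.bin_size, cols)
    row_region = GenomicRegion(
        cmap.row_region.chrom,
        cmap.row_region.start + r0 * cmap.bin_size,
        min(cmap.row_region.start + r1 * cmap.bin_size, cmap.row_region.end),
    )
    col_region = GenomicRegion(
        cmap.col_region.chrom,
        cmap.col_region.start + c0 * cmap.bin_size,
        min(cmap.col_region.start + c1 * cmap.bin_size, cmap.col_region.end),
    )
    return BinnedContactMap(row_region, col_region, cmap.bin_size,
                            cmap.values[r0:r1, c0:c1].copy(),
                            cmap.normalization_state, cmap.assembly)


def mask_locus(cmap: BinnedContactMap, region: GenomicRegion) -> BinnedContactMap:
    """Mask (NaN) all rows and columns of bins overlapping ``region``.

    Represents a genetic deletion at matrix level while preserving the bin
    grid, so wild-type and knockout maps stay directly comparable.
    """
    if not cmap.is_square:
        raise ValueError("mask_locus expects an intra-chromosomal map")
    out = cmap.copy()
    if region.chrom != cmap.row_region.chrom:
        return out
    lo = max(region.start, cmap.row_region.start)
    hi = min(region.end, cmap.row_region.end)
    if lo >= hi:
        return out
    i0 = (lo - cmap.row_region.start) // cmap.bin_size
    i1 = -((cmap.row_region.start - hi) // cmap.bin_size)
    out.values[i0:i1, :] = np.nan
    out.values[:, i0:i1] = np.nan
    return out
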