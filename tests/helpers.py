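"""Shared builders and independent oracles used across the test suite."""

from __future__ import annotations

import math

import numpy as np

from tadloop import BinnedContactMap, GenomicRegion

BIN = 40_000


def make_map(values, bin_size: int = BIN, chrom: str = "chrX",
             start: int = 0, col_start: int | None = None) -> BinnedContactMap:
    """Wrap a raw array as a contact map anchored at ``start``."""
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    row = GenomicRegion(chrom, start, start + n * bin_size)
    if col_start is None and n == m:
        col = row
    else:
        cs = start if col_start is None else col_start
        col = GenomicRegion(chrom, cs, cs + m * bin_size)
    return BinnedContactMap(row, col, bin_size, values)


def block_matrix(sizes: list[int], within: float = 10.0,
                 between: float = 0.0) -> np.ndarray:
    """Block-diagonal TAD caricature: ``within`` inside blocks, ``between``
    across; ``between`` may be a list with one value per junction gap."""
    n = sum(sizes)
    if not isinstance(between, (list, tuple)):
        between = [between] * (len(sizes) * (len(sizes) - 1) // 2)
    values = np.empty((n, n))
    edges = np.cumsum([0] + sizes)
    pair = 0
    for a in range(len(sizes)):
        ra = slice(edges[a], edges[a + 1])
        values[ra, ra] = within
        for b in range(a + 1, len(sizes)):
            rb = slice(edges[b], edges[b + 1])
            values[ra, rb] = between[pair]
            values[rb, ra] = between[pair]
            pair += 1
    return values


def brute_insulation_raw(values: np.ndarray, w: int, mode: str,
                         max_missing: float = 0.5) -> np.ndarray:
    """Direct O(n * w^2) evaluation of the square aggregate definition.

    Independent of the production code path: explicit double loops over the
    upstream-x-downstream square of each bin.
    """
    n = values.shape[0]
    raw = np.full(n, math.nan)
    for i in range(w, n - w):
        square = []
        n_total = 0
        for r in range(i - w, i):
            for c in range(i + 1, i + 1 + w):
                n_total += 1
                v = values[r, c]
                if not math.isnan(v):
                    square.append(v)
        if len(square) < n_total * (1 - max_missing) or not square:
            continue
        if mode == "mean":
            agg = sum(square) / len(square)
        elif mode == "median":
            agg = float(np.median(square))
        else:  # iqrMean: mean of values within [Q1, Q3] inclusive
            q1, q3 = np.percentile(square, [25, 75])
            kept = [v for v in square if q1 <= v <= q3]
            agg = sum(kept) / len(kept)
        if agg > 0:
            raw[i] = agg
    return raw


def brute_insulation_score(values: np.ndarray, w: int, mode: str,
                           smooth_bins: int = 1) -> np.ndarray:
    """Full independent pipeline: raw -> running mean -> log2 normalization."""
    raw = brute_insulation_raw(values, w, mode)
    n = raw.size
    if smooth_bins > 1:
        half = smooth_bins // 2
        sm = np.full(n, math.nan)
        for i in range(n):
            if math.isnan(raw[i]):
                continue
            window = [raw[j] for j in range(max(0, i - half),
                                            min(n, i + half + 1))
                      if not math.isnan(raw[j])]
            sm[i] = sum(window) / len(window)
        raw = sm
    present = [v for v in raw if not math.isnan(v) and v > 0]
    if not present:
        return np.full(n, math.nan)
    ref = sum(present) / len(present)
    return np.array([math.log2(v / ref)
                     if not math.isnan(v) and v > 0 else math.nan
                     for v in raw])
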