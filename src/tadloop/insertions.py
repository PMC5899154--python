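"""Transgene insertion-site detection from inter-chromosomal contacts.

When Hi-C reads are mapped to a genome carrying an extra "cassette"
chromosome (the transgene construct), the cassette's inter-chromosomal
contact vector piles up sharply at the genomic bins where copies of the
cassette are physically integrated.  Enriched bins are detected against a
per-chromosome Poisson background (rate = median bin count, robust to the
pileups themselves) with Benjamini-Hochberg control across all bins, merged
into sites, and filtered for consistency across two experimental conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .regions import GenomicRegion

_MIN_TOTAL_BINS = 100
_P_FLOOR = 1e-300


@dataclass
class CassetteContactProfile:
    """Per-chromosome cassette-contact bin counts for one condition."""

    condition: str
    bin_size: int
    counts: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        self.counts = {c: np.asarray(v, dtype=float)
                       for c, v in self.counts.items()}
        for chrom, vec in self.counts.items():
            if vec.ndim != 1 or (vec < 0).any():
                raise ValueError(f"bad count vector for {chrom}")

    @property
    def total_bins(self) -> int:
        return sum(v.size for v in self.counts.values())


@dataclass(frozen=True)
class InsertionCall:
    """A merged run of enriched bins supporting one integration site."""

    region: GenomicRegion
    score: float                      # -log10 BH-adjusted tail p of peak bin
    support: tuple[str, ...] = ()     # conditions in which the site was seen


def _poisson_tail(counts: np.ndarray, lam: float) -> np.ndarray:
    """Upper-tail P(X >= count) under Poisson(lam)."""
    if lam <= 0:
        return np.where(counts > 0, 0.0, 1.0)
    return sps.poisson.sf(counts - 1, lam)


def call_enriched_bins(profile: CassetteContactProfile,
                       alpha: float = 1e-6,
                       merge_gap: int = 1) -> list[InsertionCall]:
    """Single-condition enriched-bin calling.

    Per chromosome, the background rate is the median bin count; a bin is
    enriched when its BH-adjusted Poisson upper-tail probability (adjusted
    across all bins of all chromosomes) falls below ``alpha``.  Runs of
    enriched bins separated by at most ``merge_gap`` quiet bins are merged;
    the site score is -log10 of the adjusted p of the run's highest bin.
    """
    if profile.total_bins < _MIN_TOTAL_BINS:
        raise ValueError(
            f"need >= {_MIN_TOTAL_BINS} bins to estimate the background"
        )
    chroms = list(profile.counts)
    pvals = np.concatenate([
        _poisson_tail(profile.counts[c], float(np.median(profile.counts[c])))
        for c in chroms
    ])
    adj = sps.false_discovery_control(np.clip(pvals, _P_FLOOR, 1.0),
                                      method="bh")
    calls: list[InsertionCall] = []
    offset = 0
    for chrom in chroms:
        vec = profile.counts[chrom]
        padj = adj[offset:offset + vec.size]
        offset += vec.size
        enriched = np.flatnonzero(padj < alpha)
        if enriched.size == 0:
            continue
        run = [enriched[0]]
        for b in enriched[1:]:
            if b - run[-1] <= merge_gap + 1:
                run.append(b)
            else:
                calls.append(_make_call(chrom, run, vec, padj, profile))
                run = [b]
        calls.append(_make_call(chrom, run, vec, padj, profile))
    return calls


def _make_call(chrom: str, run: list[int], vec: np.ndarray,
               padj: np.ndarray, profile: CassetteContactProfile
               ) -> InsertionCall:
    peak = run[int(np.argmax(vec[run]))]
    region = GenomicRegion(chrom, run[0] * profile.bin_size,
                           (run[-1] + 1) * profile.bin_size)
    score = float(-np.log10(max(padj[peak], _P_FLOOR)))
    return InsertionCall(region, score, (profile.condition,))


def consistent_insertions(calls_a: list[InsertionCall],
                          calls_b: list[InsertionCall]) -> list[InsertionCall]:
    """Sites from ``calls_a`` confirmed by >= 1 bp overlap in ``calls_b``.

    Emitted sites carry both supports and the more conservative (minimum)
    of the two scores.
    """
    out = []
    for a in calls_a:
        hits = [b for b in calls_b if a.region.overlaps(b.region)]
        if not hits:
            continue
        best = max(hits, key=lambda b: b.score)
        out.append(InsertionCall(a.region, min(a.score, best.score),
                                 tuple(dict.fromkeys(a.support + best.support))))
    return out


def insertion_summary(calls: list[InsertionCall]
                      ) -> tuple[dict[str, int], int]:
    """Per-chromosome site counts and the number of chromosomes with sites."""
    per_chrom: dict[str, int] = {}
    for call in calls:
        per_chrom[call.region.chrom] = per_chrom.get(call.region.chrom, 0) + 1
    return per_chrom, len(per_chrom)
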