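# Methods

## Coordinate and matrix conventions

All genomic intervals are 0-based half-open; bin `i` of a map anchored at
`start` covers `[start + i*b, start + (i+1)*b)` for bin size `b`. A point
position belongs to bin `floor((pos - start) / b)`; a region snaps
*outward* to the bin grid (every overlapped bin is included), so views are
loss-free and deterministic.

Masked entries are carried as NaN, never zero. A deleted locus in a
knockout map has near-zero sequencing coverage; treating those bins as
zeros would drag down every mean they enter (insulation squares, inter-TAD
blocks, sliding windows), whereas missing values simply drop out of the
statistics. `mask_locus` applies this representation to whole rows/columns
while keeping the bin grid identical between genotypes.

Two text dialects are read and written: a dense TSV with
`name|assembly|chrom:start-end` headers on both axes (`NA` = masked), and
the sparse upper-triangle triplet listing `bin_i bin_j count` with a BED4
bin table. Triplet counts are mirrored to both `(i,j)` and `(j,i)` on
densification.

`normalize_rpm` scales by `1e6 / total_valid_pairs` (reads per million).
`balance_ice` iteratively divides rows and columns by their normalized
unmasked row sums until the coefficient of variation of row sums falls
below `tol` (default 1e-4) or `max_iter` (200); all-zero rows are
auto-masked first. This is plain iterative correction without coverage-
percentile filtering — adequate as plumbing, not a reimplementation of a
production balancing pipeline.

## Insulation and boundary calling

For bin `i`, the raw insulation is the aggregate of the square
`M[i-w .. i-1, i+1 .. i+w]`, `w = square_size / bin_size` (default 480 kb).
Aggregation modes: `mean`, `median`, and `iqrMean` — the mean of the
square's values lying within `[Q1, Q3]` inclusive (quartiles by linear
interpolation), which discards outlier pixels symmetrically. Squares
truncated by the matrix edge are masked rather than partially aggregated
(edge-biased scores would otherwise dominate view margins), as are squares
with more than 50 % missing entries or a non-positive aggregate (the log
is undefined there; an all-zero square carries no insulation signal).

The raw vector is smoothed by a centered running mean over
`smooth_span / bin_size` bins (rounded up to odd; default 160 kb → 5 bins
at 40 kb, set `smooth_span=0` to disable), then normalized:
`score(i) = log2(raw(i) / mean(raw over unmasked bins))`. The reference
mean is taken over the supplied matrix (the analyzed extent), not a whole
chromosome, because operations act on region views; this preserves the
defining invariance `score(a·M) = score(M)` for any `a > 0` and forces
`mean(2^score) = 1` exactly.

The delta vector is
`Δ(i) = mean(score(i .. i+s]) − mean(score[i−s .. i))`,
`s = delta_span / bin_size` (default 320 kb), masked wherever either flank
is incomplete or touches a masked score. At a score minimum Δ crosses zero
from below. For each such crossing the caller walks left to the local Δ
minimum (trough) and right to the local Δ maximum (peak); the **boundary
strength** is `Δ(peak) − Δ(trough)` and the boundary bin is the score
minimum between the two extrema. Crossings are discarded when the strength
falls below `strength_cutoff` (default 0.1 — the method itself exposes no
cutoff, but float-level noise on near-constant matrices produces spurious
zero crossings of vanishing amplitude; planted boundaries in realistic
maps score well above 1), when either extremum's |Δ| is below the noise
threshold (default 0, a no-op), or when a masked bin lies within
`boundary_margin` bins of the boundary (default 0). Noisy deltas can
re-cross within one excursion; duplicate calls on the same bin are
collapsed to the strongest.

Minimal extents: the score needs `2w` bins; boundary calling additionally
needs the delta flanks, so roughly `2(w + s)` bins plus the structure of
interest. `boundary_strength_at` looks up the called boundary nearest a
query region within a search pad (default 500 kb) and returns NaN when
none exists — distinguishing "boundary lost" from "boundary weakened".

## Comparative statistics

* Inter-TAD frequency: all unmasked values of the rectangular block
  between two disjoint domains, compared across genotypes with the
  two-sided Wilcoxon rank-sum test (`scipy.stats.mannwhitneyu`); an
  all-identical pooled sample short-circuits to a degenerate p = 1.
* Peak density: peaks are assigned to windows by midpoint, which under the
  default non-overlapping tiling (step = window size) conserves counts;
  overlapping windows are available via `step`. Window rank of a locus is
  the competition rank of its window's count (descending); the quantile
  uses the mid-rank tie rule, `1 − (midrank − 1)/N`, so a unique maximum
  scores exactly 1.0 and an all-tied track ≈ 0.5.
* Colocalization: Pearson chi-square on the 2x2 table without continuity
  correction (Yates' available as a flag); a zero column margin means both
  groups have identical proportions and returns a degenerate p = 1 rather
  than an undefined expected count.
* qPCR fold change: `2^(−ΔΔCt)` with
  `ΔΔCt = (Ct_tgt − Ct_ref)_case − (Ct_tgt − Ct_ref)_control`.
* Deletion span: measured from the downstream edge of the 5′ cut point to
  the upstream edge of the 3′ cut point, with kb rounded half-up — this is
  the arithmetic that turns two printed single-bp cassette insertion
  coordinates into the conventional "~N kb deletion" figure.

## Super-loop significance

`slide_window_test` compares every window position against the target by a
two-sided **Welch** t-test (the unequal-variance form; distance decay makes
window variances heterogeneous, and Welch reduces to Student when variances
happen to agree). The grid covers every top-left position —
`(R−n_r+1)(C−n_c+1)` positions, e.g. 45·44 = 1980 for a 6x7 window on a
50x50 heatmap — including the target's own position, which scores p = 1
exactly by self-comparison (a useful positional sanity anchor;
`exclude_target=True` drops it). Zero-variance degeneracies: both samples
constant and equal → p = 1; constant and unequal → p = 0; one side
constant falls through to Welch. Positions are flagged invalid when the
window is more than half masked, has fewer than two present values, or (on
a square intra-chromosomal map) intersects the diagonal, where decay
dominates any comparison. The intended use is an off-diagonal rectangle
between two distant anchors, which never touches the diagonal.

`compare_pvalue_densities` runs one-way ANOVA (`scipy.stats.f_oneway`)
across the per-position p-value samples of ≥ 2 conditions and attaches
Gaussian kernel-density summaries on a [0, 1] grid for plotting. For two
conditions the ANOVA F equals the squared pooled t statistic, which the
test suite uses as a closed-form identity check.

On calibration: with a within-chromosome rectangle the power-law decay
gradient (±8 % in expectation across a 2 Mb window 25 Mb off-diagonal)
makes distant positions *genuinely* different from the target, so the
per-position p-values are not uniform under "no loop" — that is power, not
miscalibration. The suite therefore checks uniformity (KS distance < 0.1)
on an inter-chromosomal rectangle, whose expectation is flat, and
separately documents the non-uniformity induced by the decay trend.

`superloop_quant` pads each labeled anchor locus (default ± 100 kb), snaps
outward to the bin grid, and flattens each pair's rectangle; at 100 kb
bins a 2-bin locus vs a 1-bin locus yields n = 4·3 = 12 bin pairs and two
1-bin loci n = 9. `compare_superloop` Welch-tests the two conditions'
vectors and reports the KO/WT mean ratio; swapping conditions inverts the
ratio and leaves p unchanged.

## Insertion-site detection

The background rate λ of cassette contacts is estimated per chromosome by
the **median** bin count — robust to the insertion pileups themselves,
which would inflate a mean. Each bin gets the Poisson upper-tail
probability `P(X ≥ count | λ)` (λ = 0 degenerates to p = 0 for any
positive count), Benjamini–Hochberg adjusted across all bins of all
chromosomes; bins with adjusted p < `alpha` (default 1e-6) are enriched.
Runs of enriched bins separated by ≤ 1 quiet bin are merged (Hi-C pileups
spread into neighboring bins); the site score is `−log10` of the adjusted
p at the run's highest bin, floored at 1e-300 to keep scores finite. At
least 100 bins are required for the background to be estimable.
Cross-condition consistency is ≥ 1 bp overlap between independently called
sites; a consistent site carries both condition flags and the minimum of
the two scores. "Consistent interactions" is often judged by eye from plotted profiles;
this formalizes it into a reproducible rule, with `alpha` and the merge
gap exposed.

## Synthetic data

The generator emulates exactly the structures the analyses measure:

* `E[i,j] = L · max(|i−j|, 1)^(−α) · Π(boundary factors straddled) ·
  Π(loop folds covering (i,j))`, symmetrized and rescaled so `ΣE = depth`;
  deleted rows/columns are set to zero expectation. Defaults α = 1.0 (the
  generic mammalian decay regime) with the diagonal pinned to the
  distance-1 level; only relative structure matters for the statistics
  under test. Boundary factors multiply contacts whose bins lie on
  opposite sides of the boundary position; loop folds multiply an
  `n_r x n_c` window centered on the anchor-midpoint bins (even dimensions
  extend downstream, matching the analysis window placement).
* Rectangular (off-diagonal) maps are produced by setting `col_extent`;
  when its chromosome differs from the row extent the base expectation is
  flat (no distance structure) — the true-null configuration used for
  calibration tests.
* Sampling is an independent Poisson draw per upper-triangle entry
  (mirrored) from `numpy.random.default_rng(seed)`; `expected_map` is
  seed-independent.
* `ko_spec` sets the deletion and optionally drops loops anchored in the
  deleted region; TAD boundaries are never altered implicitly — boundary
  weakening is modeled explicitly through `boundary_insulation`, keeping
  the "locus deleted, boundary preserved" scenario expressible.
* Cassette profiles: Poisson(background) per bin plus Poisson(pileup) at
  each insertion bin and Poisson(pileup/2) at its two neighbors. Peak
  tracks: a uniform Poisson process (peaks/Mb) plus a fixed count uniform
  in a hotspot, all peaks 200 bp wide.

What the generator does *not* emulate: balancing artifacts, copy-number
and mappability biases, A/B compartment checkerboards, loop-extrusion
stripes and corner peaks, or read-level noise. Passing tests therefore
demonstrate the statistical machinery's correctness and calibration under
a clean decay + Poisson model, not robustness to every artifact of real
Hi-C libraries.

## Problem sizes and defaults used in the test suite

Simulated designs mirror the study conditions: 40 kb bins with the 6x7
(42-bin) target window slid over 2 Mb x 2 Mb (1980 positions), depth
5·10⁵ contacts per rectangle, loop fold 5; 100 kb bins with ± 100 kb pads
(n = 12 / n = 9) for super-loop quantification; boundary scenarios use
factor 0.2 (strong) vs 0.5 (weakened) with an ~80 kb two-bin deletion;
insertion scenarios plant four sites on four chromosomes at 20–30x
background. Small-matrix unit tests shrink the insulation square to 5–6
bins to keep planted structure and flanks inside 30–60-bin matrices.

## Known limitations

* Boundary calling reports single-bin boundaries; no nested/hierarchical
  domain structure, directionality index, or HMM callers.
* The ICE implementation has no coverage-percentile filtering and is not
  intended for genome-wide production balancing.
* Insertion detection is bin-resolution; no split-read breakpoint
  refinement or copy-number estimation.
* Binary formats (.cool/.hic) are out of scope; maps are text dialects.
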