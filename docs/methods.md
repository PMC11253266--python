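# Methods

This note records the models, conventions and numerical choices behind
`propseq`, in the order data flows through the package.

## Encoding

An alignment is an *n* × *m* grid of uppercase letters over the 20 standard
residues, the gap `-`, and the ambiguity codes `B J O U X Z`. Input `.` and
`*` are normalized to `-` and lowercase is uppercased, matching common
alignment dialects. Two encodings are produced per taxon:

* a **property wave**: `table[residue]` per position, exactly 0 at gaps;
* a **factor matrix** (*m* × 5): the residue's coordinates in the five-factor
  amino-acid state space, an exactly zero row at gaps.

Ambiguity codes encode as zero, like gaps, because they carry no property
information; a `strict=True` mode raises instead for pipelines that must not
silently drop residues. Property and factor tables are replaceable data:
every algorithm takes them as arguments, and CSV readers/writers are
provided.

**Shipped constants.** Three property tables (side-chain volume in Å³,
isoelectric point in pH units, octanol partition free energy in kcal/mol)
and the 20 × 5 factor solution. The published factor scores are standardized
over their source protein dataset, not over the 20 residues; the shipped
default re-standardizes each axis over the 20 letters (mean 0, sd 1), which
makes the zero-vector gap encoding coincide with the residue centroid. The
raw transcription remains available (`factor_table(raw=True)`). A known
artifact follows from this convention: against the "average amino acid"
reference (the centroid, ≈ 0), gap rows score ≈ 0 — i.e. gaps look
maximally average, not maximally different. This is inherent to the
zero-gap encoding and is documented rather than patched.

**Gap fraction.** The zero-row treatment degrades distance quality when gaps
dominate; `gap_fraction` flags alignments above 25% gaps as a warning, not
an error.

## Distances

For factor matrices X, Y of shape *m* × 5:

* positional distance: Σⱼ ‖Xⱼ − Yⱼ‖₂ (per-position Euclidean norms,
  summed) — the default for tree building;
* Frobenius distance: √(ΣⱼΣₖ (xⱼₖ − yⱼₖ)²), identically
  √tr((X−Y)ᵀ(X−Y)); both forms are implemented and cross-checked.

The ambiguity of where the radical sits in a "summed Euclidean" formula is
resolved as: the per-position norm carries the square root, the positional
distance is the plain sum of those norms, and the Frobenius distance takes a
single square root over the double sum. Under this reading the two distances
genuinely differ — by the triangle inequality the positional form dominates,
with equality exactly when at most one position differs — which is why both
are offered. For single-property waves the analogue is the L1
**sum-difference** Σⱼ|xⱼ − yⱼ|.

All-gap positions in both sequences contribute zero distance (a direct
consequence of the zero encoding); no gap-pair exclusion option exists in
this version.

## Similarity statistics

* **Correlation** ("autocorrelation" in the tree-building context): the
  lag-0 normalized cross-covariance, i.e. the Pearson coefficient between
  two taxa's waves; a lag parameter (default 0) is exposed. Algebraically
  exact endpoints are returned exactly: the implementation detects
  num² = dxx·dyy and zero covariance before dividing, so self-comparison is
  +1.0, mirrored waves are −1.0 and constructed zero-covariance pairs are
  0.0 without rounding residue. Zero-variance input is an error, not a
  silent 0.
* **Entropy / AMI**: plug-in Shannon entropy over nonzero cells, natural log
  by default (a bits option exists). AMI = H(X) + H(Y) − H(X,Y) from an
  empirical contingency table. The default discretization is categorical on
  distinct values — property waves take at most 21 distinct values (20
  residues + gap 0), so the table is well-defined without binning; an
  equal-width binning mode (default ⌈√m⌉ bins, clamped to [2, 20]) serves
  continuous inputs. No bias correction (Miller–Madow etc.) is applied.
* **Box-counting dimension**: the (xⱼ, yⱼ) scatter is covered by its
  bounding square; at subdivision *g* = 1..n_scales (default 6) boxes have
  side `range/2^g`; the dimension is the least-squares slope of ln N_g on
  ln 2^g, optionally over a `fit_range` subrange. An `offsets` knob slides
  the grid origin over a uniform lattice of the box side and keeps the
  minimum count per scale, a pattern-search-style reduction of the
  quantization error of arbitrary grid placement. A both-constant scatter
  short-circuits to 0 with a degenerate flag. Note that waves encoded from
  20-letter sequences live on a ≤ 20 × 20 value lattice, so counts saturate
  at fine scales and independent sequence pairs estimate slightly below the
  ideal plane-filling value; continuous waves do not saturate this way.
* **Cross-property averaging** is elementwise over statistic tables (the
  statistics are averaged, not the waves). The inverse transform
  d = 1/stat (ε = 1e−9 floor for non-positive entries, clamps reported in
  `meta["clamped"]`) turns similarity tables into tree-ready distances.

## Wavelet analysis

The Morlet mother wavelet ψ(t) = π^(−1/4) e^(iωt) e^(−t²/2) with ω = 6
(approximately analytic; Fourier period ≈ 1.033 × scale). Input series are
centered and scaled to unit variance — property units differ by orders of
magnitude and cross-property comparison must not be dominated by scale. The
CWT is computed in the Fourier domain with zero padding to the next power of
two, per-scale L2 normalization, on a geometric scale grid (s_min = 2
positions, s_max = m/3, 12 voices per octave).

Coherence requires smoothing to be non-trivial; the smoothing operator is a
moving average over positions with window 2·round(0.6·scale)+1, followed by
a boxcar over round(0.6 · voices) scale rows. With identical nonnegative
weights across the three smoothed spectra, Cauchy–Schwarz bounds coherence
in [0, 1] for every input, and self-comparison attains 1 identically (the
package's self-coherence deviates from 1 only by ~1e−13 of floating-point
noise). Phase is the argument of the smoothed cross spectrum; the sign
convention makes a series that *lags* its partner by a quarter cycle show
phase −π/2 (tests assert the magnitude). The cone of influence uses the
e-folding distance √2·s; cells beyond it are flagged (`outside_coi`), never
removed.

Significance uses white-noise surrogates: pairs of independent unit-variance
Gaussian series analyzed identically, pointwise p = fraction of surrogates
exceeding the observed statistic, deterministic under the configured seed.
White noise is the simplest defensible null for property strings with no
strong positional autocorrelation model; an AR(1) alternative is a natural
extension and deliberately not implemented here.

## Tree building

All trees are rooted dendrograms with node heights; merge height is half the
merge distance (the standard agglomerative convention — no height convention
is canonical for the stepwise procedures, so the UPGMA one is reused
throughout). Ties are broken deterministically: among minimal pairs, the
pair whose sorted pair of representative labels (lexicographically smallest
leaf per cluster) is smallest merges first; children are ordered by the same
representatives. This makes every builder invariant to input permutation.

* **UPGMA/WPGMA**: size-weighted or simple arithmetic-mean updates. UPGMA on
  an exactly ultrametric matrix reproduces it cophenetically (tested), and
  both variants are cross-checked against SciPy's average/weighted linkage.
* **String-merge**: merge the pair of waves with the smallest sum-difference
  and replace it with the positionwise mean of the two numeric strings.
* **Stat-merge**: invert the statistic table (1/stat) and merge stepwise,
  averaging the merged pair's transformed distances (the *distances* are
  averaged, not the raw statistics — the inverse is taken first).

The stepwise procedures can produce merge distances smaller than an earlier
merge; heights are clamped monotone (parent ≥ children) and Newick branch
lengths are floored at 0 rather than emitting negative branches.

Evaluation: `is_monophyletic` checks an exact leaf-set match;
`ranking_match` formalizes "the tree matches an expected ranking" as (a)
every declared group monophyletic and (b) some planar rotation (independent
child flips) lists the leaves in the expected order, within-group order
free. The rotation check is exact: a subtree is feasible iff at each node
one child's maximum expectation index is ≤ the other's minimum, which is
verified in tests against brute-force enumeration of all rotations.

## Simulation

`random_tree(n, seed)` draws merge-height increments as 0.5 + U(0,1) and
rescales the root to height 1, so consecutive merge levels are always well
separated (no increment below a third of the largest); cluster pairs merge
uniformly at random. `evolve_alignment` draws a uniform root sequence;
along each branch every site substitutes with probability 1 − exp(−rate·bl),
the replacement drawn over the other 19 residues with weights
exp(−‖Δfactor‖/τ) (uniform at τ = 0); gap blocks arrive as Poisson events
per branch with geometric lengths and are inherited by the whole subtree,
preserving homology so rows need no re-alignment. This is deliberately
simple machinery for exercising the analysis stages — it has no empirical
substitution matrix, no among-site rate variation, no insertions (only
deletions), and no selection beyond the τ bias — so passing tests
demonstrate correctness of the machinery, not biological realism.

Defaults (n = 8, m = 300, rate = 0.15/site/unit branch) put roughly 15
expected substitutions on an average branch. At that signal level, full
topology recovery by UPGMA over positional distances runs near 55% over 50
replicates: failures are single misplaced clades, and the expected distance
gap between a true merge and its nearest competitor is only ~2 standard
deviations of the distance noise per step. Recovery rises with more sites
or substitution signal (a rate sweep peaks near 82% at rate 1.0 before
saturation takes over) — a useful calibration point when choosing alignment
lengths for real analyses. These problem sizes (and the test suite's 50-seed
benchmark) were chosen to characterize the method at moderate, realistic
family sizes.

## Known limitations

* The gap/centroid collision described under *Encoding*.
* Correlation, AMI and box-counting compare whole waves; they are blind to
  which positions drive similarity (that is the wavelet module's job).
* The box-counting estimator is scale-limited by the 20-value lattice of
  residue-encoded waves (see above).
* The stepwise merge procedures are the field's historical recipes, kept for
  comparability; UPGMA on matrix distances is the better-behaved default.
* No alignment is performed; inputs must be pre-aligned, and alignments with
  more than ~25% gaps are flagged as unreliable for the zero-gap encoding.
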