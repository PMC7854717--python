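# Methods

## Input model and filtering

The raw unit is a spot measured in every condition × replica sample:
foreground and background fluorescence plus a corrupted-pixel flag,
in a long tab-delimited table (one row per spot × sample; column names
mapped by a schema config). A spot is removed **globally** — from all
samples — if in *any* sample it is corrupted or its foreground is
strictly less than twice its background; foreground exactly equal to
2× background is retained. Filtering is idempotent and scale-invariant,
and the removal report lists each offending (spot, sample, reason).

## Normalization

The original protocol is not fully specified by its source, so the
package adopts a minimal, contract-driven recipe:

1. background subtraction, floored at `1e-6 ×` the sample median of the
   net intensities (all values stay strictly positive);
2. per-sample median scaling (each chamber × replica sample → median 1),
   which makes the pipeline invariant to per-sample multiplicative
   rescaling of the raw intensities;
3. one global rescale so that the median over all genes and samples of
   the per-gene (spot-averaged) sample values equals 1.

Step 3 fixes the unit in which AVE is reported: multiples of the median
gene. The normalization contract (`median = 1` within 1e-6) is checked
by `ExpressionSet.normalization_deviation()`. Dye structure (Cy3/Cy5)
is flattened to one value per (spot, chamber, replica); dye-swap or
loess corrections are out of scope.

## Expression level, variability, control

AVE averages first over the four replicas of each spot, then over the
gene's `R_i` spots. REV pools the per-spot CVs in quadrature and applies
the mid-interval chi-square correction at `r = 4R_i − 1` df. Two notes:

* **Correction values.** The formula gives 2.1475 at R = 1 and 1.0391 at
  R = 13. Prose accounts of the same estimator sometimes quote 1.566 and
  1.05; those values are not reproducible from the printed formula under
  any tail convention we tried, so the package follows the formula as
  printed. Because the correction multiplies both REVs in CUT and the
  numerator and denominator of REC/PREC are medians of equally-corrected
  REVs (for same-R genes), the discrepancy mostly rescales REV rather
  than reordering genes.
* **Units in CUT.** REV is defined in percent, but the adaptive cut-off
  `CUT = 1 + √(2(REV_A² + REV_B²))` consumes REV as a *fraction*
  (percent/100). Percent units would produce cut-offs of 30× and more
  for ordinary 20%-variable genes, incompatible with any observed
  regulation percentages; fractional units give cut-offs of ≈1.2–2×,
  the intended regime.

REC and PREC use the **median** REV (midpoint of the middle two for even
counts). A zero-variance gene has REV = 0 and an unbounded REC; the
scalar API returns +inf with a warning, while chamber tables cap it at
10× the chamber's largest finite REC so rankings stay finite. Real noisy
data never hits this branch; exactly-degenerate synthetic data does.

## Differential expression

The signed ratio `x` divides the summed spot means of the referred
chamber by the reference chamber (or the negative reciprocal), so
`|x| ≥ 1` and `x(A→B) = −x(B→A)` exactly. Significance is the two-tail
Welch (unequal-variance) t-test on the per-replica gene means, linear
scale, 4 vs 4, with replicas treated as unpaired between chambers; a
log-scale variant exists behind a flag but is off by default. No
multiple-testing correction is applied by default, matching the
original procedure; a Benjamini–Hochberg gate is available
(`regulation_table(..., fdr=True)`). The zero-variance degenerate case
(both chambers constant) returns p = 1 for equal means and p = 0
otherwise.

The Welch–Satterthwaite reference is itself approximate at n = 4: under
an exactly normal null its p-values deviate from uniform by a small,
bounded amount (KS distance ≈ 0.02 at 10,000 simulations, conservative
near 0) while the size at α = 0.05 stays essentially nominal. The
acceptance suite asserts this calibration as a bound (KS D < 0.03,
size in [0.03, 0.07]) rather than literal uniformity.

WPR weights each above-cut-off gene by its reference-chamber AVE, its
excess ratio `|x| − CUT` and its confidence `1 − p`; the weight does not
additionally require p < 0.05 (the piecewise definition switches only on
`|x| > CUT`), while the *percent regulated* column does. Where the
weight's μ term is under-specified with respect to spot aggregation, the
package uses the AVE aggregate.

## Coordination, synchrony, classification

Correlation is Pearson's, on log2 normalized expression. With equal
spot redundancy R the 4R (replica, spot) points are paired in spot-index
order within replicas, giving df = 4R − 2 (1 spot → 2, 2 → 6, 3 → 10);
with unequal redundancy each gene's spots are averaged per replica on
the linear scale and the 4 values give df = 2. Significance is
`t = ρ√(df/(1 − ρ²))`, two-tail.

Classes: significant positive → *synergistic*; significant negative →
*antagonistic*; |ρ| ≤ 0.05 (configurable band) → *independent*;
everything else → *undecided*. The independence band is a design choice:
at df = 2 non-significance is the norm, so counting every non-significant
pair as independent would inflate that class; only near-zero
correlations qualify. Zero-variance vectors yield an undefined ρ and an
*undecided* class with a warning.

Synchrony correlates the same gene across two chambers with replicas
paired by animal (and spots paired when redundancy matches; same df
rule). The four adjacent pairings of the four-chamber design are
LA–RA, LV–RV, LA–LV, RA–RV, giving 4n evaluations for n genes, and the
within-chamber enumeration yields n(n−1)/2 pairs — both counts exposed
as arithmetic helpers (at the study's 16,866 quantified unigenes:
142,222,545 pairs and 67,464 evaluations). The all-pairs computation is
tiled by redundancy group but is deterministic and identical to the
single-pair path.

## Gene hierarchy

`GCH = (REC + 1) · exp(4 · mean ρ²)`, the mean running over all other
quantified genes (a `partners` restriction exists for exploratory runs;
the full universe is the default and the acceptance setting). Undefined
correlations are excluded from the mean and counted. Ranks are
deterministic: descending GCH, ties broken by higher REC then
lexicographic symbol; rank 1 is the chamber's GMR. Pathway-level GCH
panels use the arithmetic mean over members (labelled as such; the
aggregation is not dictated by the definition).

## Synthetic data: what it emulates, what it does not

Per gene: baseline log2 mean ~ N(0, σ_base = 2) (median gene = 1);
chamber means shifted by planted folds; per replica a biological
deviate with per-gene CV drawn uniformly from (0.10, 0.50) by default;
per spot an independent technical log-normal noise (CV 0.05 default);
redundancy drawn from a mostly-single-spot law over R ∈ {1,…,13}.
Planted coordination uses one shared latent factor per module per
chamber: `log2 a = log2 m + σ(λF + √(1−λ²)z)`, so every same-module
pair has log-scale correlation exactly λ² (equicorrelation) —
analytically checkable, and verified empirically at 1,000 replicas.
Synchrony planting shares the factor across two chambers instead.
Foreground/background columns are synthesized so that net = fg − bg is
exact in floating point (Sterbenz), and a configurable fraction of spots
violates the 2× filter in one random sample. Identical configs (with
seed) are byte-identical on disk.

Not emulated: dye bias, spatial array artifacts, probe-sequence
effects, intensity-dependent variance, cross-hybridization, or any
real covariance structure beyond equicorrelated modules. Passing
planted-truth tests therefore demonstrates correctness of the
estimators and their calibration under the declared noise model, not
robustness to real microarray artifacts.

One interaction worth knowing: per-sample median scaling estimates the
median from the genes at hand, adding a shared per-sample noise of
relative magnitude ≈ 1.25σ/√n_genes. At study scale (thousands of
genes) this is negligible; on tiny fixtures it measurably attenuates
planted correlations, which is why recovery tests embed their truth
genes in a full-size background.

## Problem sizes and numerical choices

The simulated study uses 2,000 genes × 4 chambers × 4 replicas
(`analysis/01`), the package's default scale; a paper-scale pair count
(16,866 genes) is exercised in the enumeration arithmetic only.
Recovery tests use: 200 planted fold-4 genes at 5% CV among 1,000
(sensitivity ≥ 0.95, FPR ≤ 0.07); a 10-gene module at loading 0.999
among 500 nulls over 20 seeds (≥ 95% of the 45 pairs synergistic, ≤ 7%
null significance); 30 synchronous genes at loading 0.995 over 20
seeds (sensitivity ≥ 0.9). Oracle agreement is asserted at 1e-10 on a
20-gene mixed-redundancy fixture. All result tables are written with 12
significant digits and round-trip losslessly at that precision; medians
use the even-count midpoint convention; seeds are explicit everywhere
randomness exists.

## Limitations

* The variability estimator is reproduced as defined — no
  empirical-Bayes moderation, shrinkage, or paired designs; with 4
  replicas the correlation test at df = 2 has very low power, and the
  *undecided* class is accordingly large on null data.
* Normalization is a pragmatic reconstruction; absolute REV/PREC levels
  (not the machinery) would shift under a different protocol.
* The CLI's all-pairs edge listing refuses >500 genes unless restricted
  to a gene set; the correlation matrix itself scales fine, but
  2M-row edge tables rarely serve a purpose on disk.
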