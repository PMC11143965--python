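# Methods

This note records the models, estimators and design choices behind
`cocomix`, and what the synthetic benchmarks do and do not demonstrate.

## The mixture null

A coculture of two cell types with (flow-cytometry-measured) SC fraction
*p* has, under the hypothesis of *no heterotypic interaction*, expected gene
proportions `p·q_SC + (1−p)·q_FB`, where `q_SC`, `q_FB` are the single-
culture profiles. The package realises this null at two levels.

**Read level.** `plan_mixture(p, N)` splits a total of `N` reads (default
38,500,000, the emulated study's stated depth) deterministically as
`n_SC = round(p·N)` (round-half-to-even) and `n_FB = N − n_SC`; a stochastic
binomial split is available behind a flag but is not the default — the
deterministic split implements "the exact measured proportion".
`sample_virtual_reads` draws each quota uniformly **without replacement**
from the corresponding FASTQ pool. Implementation: a counting pass over the
pool (records are strictly 4-line), then a streaming selection pass against
a boolean index mask drawn with `Generator.choice(replace=False)`. This
replaces a classical single-pass reservoir scheme: two cheap sequential
passes vectorise far better at 4×10⁷-read scale, preserve input order, and
are exactly reproducible. A pool smaller than its quota raises an error; an
explicit `with_replacement=True` fallback exists because the sampling
policy of the original pipeline is not documented and deep pools cannot
always be guaranteed.

**Count level.** `mix_counts` returns either the exact expectation
`round(N·(p·q_SC + (1−p)·q_FB))` (*expected* mode; column totals match `N`
up to rounding) or a multivariate-hypergeometric draw matching the read-
level operation in distribution (*sampled* mode; totals exact). Virtual
cohorts are built in expected mode by default: the virtual sample is a
*null expectation*, and adding resampling noise to it only dilutes power.

FASTQ reads carry their gene of origin in the read name, so quantification
is exact name-based tallying. The original study's aligner/quantifier stage
is deliberately out of scope: the contribution under test is the mixture
null, not the quantifier, and coupling the benchmark to an alignment stack
would only add noise that the generator cannot ground-truth.

## Differential expression

A minimal, self-contained negative-binomial Wald analysis in the tradition
of the standard count-based DE tools (numerical identity with any external
package is a non-goal; on a simulated cohort the log2 fold changes agree
with an independent NB implementation to r > 0.999, see
`tests/test_de.py`):

1. **Filter.** Remove genes with fewer than 5 counts in more than 2 samples
   (`filter_low_counts`), applied over the supplied matrix before
   normalization. The rule is the study's stated pre-filter; which sample
   universe it originally referred to is ambiguous, so the operation takes
   the matrix it is given.
2. **Size factors.** Median-of-ratios: for genes positive in all samples,
   `s_j = median_g K_gj / geomean_g`, rescaled to geometric mean 1.
3. **Dispersions.** Per gene, a method-of-moments estimate on normalized
   counts within each condition group: `α̂ = (var − ξ·μ)/μ²` with
   `ξ = mean(1/s_j)` propagating the Poisson term through normalization,
   pooled across groups by degrees of freedom. The trend `α(μ) = a0/μ + a1`
   is fitted by ordinary least squares on the **raw** (unfloored, possibly
   negative) moment estimates with a symmetric 1% residual trim — the raw
   estimator is nearly unbiased, whereas flooring at zero plus one-sided
   outlier trimming biases the trend low and inflates Wald tails. The final
   per-gene dispersion shrinks one-sidedly toward the trend: values *below*
   the trend are indistinguishable from estimation noise at a dozen
   replicates and are raised to it; values above are blended in log space
   with trend weight 0.8 (configurable), preserving genuinely
   extra-dispersed genes.
4. **Test.** Per gene, an NB GLM with log link,
   `log μ = log s_j + pair effects + β·1[real]`, fitted by IRLS (max 100
   iterations, deviance tolerance 1e-8, zeros handled by the link without
   pseudocounts). All genes share the design matrix, so IRLS is batched
   across genes with einsum-built normal equations — a 10,000 × 32 cohort
   fits in well under a second. Wald statistic `β/se` against the standard
   normal, `log2FC = β/ln 2`; non-converged genes get `p = NA` and are
   excluded from adjustment. Pairing is the default (the study compared
   "each real coculture and its virtual counterpart"); an unpaired
   two-group mode exists behind a flag.
5. **Adjustment and signature.** Benjamini–Hochberg at α = 0.05 (NAs do not
   count toward the number of tests); significant genes partitioned by
   fold-change sign, ordered by adjusted p then |log2FC|.

## Synthetic data: what it emulates

`SimulationConfig` defaults mirror the emulated design: 4 SC and 4 FB
single cultures, all 16 pairings as cocultures, SC fractions uniform in
[0.6, 0.7]. Counts are gamma-Poisson: per-sample gene rates are gamma-
perturbed around the sample's expected proportions with dispersion
`α(μ) = a0/μ + a1` (defaults a0 = 2, a1 = 0.02, i.e. ~14% biological CV for
well-expressed genes — typical for cell-culture bulk RNA-seq), then
allocated multinomially at an exact library size drawn from
[1.5M, 2.5M] reads (a deliberately desk-scale depth; the mixing arithmetic
is depth-agnostic). Interaction effects multiply the mixture expectation of
a configurable fraction of genes (default 2%) by `2^log2FC` (magnitude
fixed or drawn from a range, sign randomised), only in real cocultures.
Interaction genes are drawn from genes with expected count ≥ 20 at
reference depth: a gene silent in both cell types cannot carry an
interaction signal. Because the perturbed vector is renormalised for
multinomial allocation, the realised fold change is `2^lfc/Z` with
`Z = Σ q·2^lfc ≈ 1` for sparse perturbations; tests account for this.

Two anchoring regimes control what a real coculture's expectation mixes:

* `anchor="celltype"` (default): every sample — single or coculture — is an
  independent replicate of its cell-type state. Real and virtual samples
  are then exchangeable across pairs, and with **matched** pairing (each
  single used in exactly one coculture) the paired test's independence
  assumptions hold exactly. This is the regime for the calibration
  benchmarks.
* `anchor="singles"`: a real coculture inherits the realized expression
  state of the very cultures measured as singles — the situation in the
  actual experiment, where cocultures were assembled from the same
  cultures. The mixture null is then *exactly* true given the singles, for
  any pairing structure, and the test is conservative (the condition-wise
  dispersion estimate includes between-pair expectation spread that the
  paired contrast cancels). The analysis scripts use this regime with the
  full 4×4 design.

**Known limitation.** Under `anchor="celltype"` with the cartesian 4×4
design, virtual columns built from shared singles are correlated across
pairs while real columns are not; the paired GLM (like any iid-based test,
including the one in the original pipeline) does not model this, and the
null is anticonservative. This is a property of in-silico nulls built from
few shared singles, not of the estimator; the calibration benchmarks
therefore use matched pairs, and the cartesian default should be read as a
design emulation, not a calibrated null. Other realism gaps: no sequence
content, error models or mapping ambiguity in read pools; no
between-individual expression heterogeneity beyond the NB dispersion; no
batch effects. Passing benchmarks therefore demonstrate correctness of the
mixture/testing machinery under the stated noise model, not robustness to
everything real data can do.

Secretome panels reuse the same design (lognormal analyte baselines,
measurement CV 20% by default, mean-preserving noise); spheroid images are
disk-based phantoms (one main body plus disjoint fragment disks, margin 6 px
so smoothing cannot merge structures, Gaussian background noise clipped at
zero) whose mask areas and channel sums are the ground truth.

## Secretome testing

Virtual concentrations are the exact linear mixture `p·c_SC + (1−p)·c_FB`
(NaN propagates; pairwise deletion per analyte). Real vs virtual is tested
per analyte with a one-tailed paired *t* (default direction real > virtual,
matching the expectation that interaction-driven secretion is induced;
configurable per analyte). Unadjusted p-values drive the significance flag
— mirroring per-analyte reporting conventions — with an optional BH column.
An identically-zero difference vector (the exact no-effect, no-noise case)
is reported as `t = 0, p = 0.5` rather than an error; zero variance with
nonzero mean raises.

## Imaging

Segmentation is Gaussian blur (σ = 2 px) → global Otsu threshold (manual
value optional) → 8-connected components → area filter (min 20 px). The
original workflow's exact blur and threshold settings are unstated;
defaults are declared, logged, and exposed. The disaggregation index is
`(total area − main area)/main area` with the largest structure as the main
body; "normalized by spheroid area" is ambiguous between main-body and
total area, and main-body was chosen as the stricter fragmentation measure
(DI = 0 for an intact spheroid under either reading; `denominator="total"`
is available). RawIntDen is the intensity sum over segmented structures
(structure-restricted by default; whole-frame optional), the live/dead
ratio their quotient. Nuclei counting reuses the segmenter with an optional
distance-transform watershed (peak separation 5 px) to split touching
nuclei. Group comparisons: one-tailed unpaired *t* (pooled variance by
default, Welch behind a flag) with Holm–Bonferroni adjustment;
median-across-spheroids summarisation with n ≥ 3.

## Numerical and reproducibility choices

All randomness flows from `numpy.random.SeedSequence` with fixed per-stage
substreams; every generator and the pipeline are byte-reproducible given
(config, seed). Dispersions are floored at 1e-8; IRLS linear systems get a
1e-10 ridge; linear predictors are clipped at ±30 to keep `exp` finite.
Benchmark problem sizes (2,000-gene null cohorts, 10,000-gene signal
cohorts, 40M-read pools, 20-image batteries) were chosen as the smallest
sizes at which the measured quantities stabilise; all complete in minutes
on one CPU.
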