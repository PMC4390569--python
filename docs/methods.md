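# Methods

## Observation model

The unit of observation is one male scanned every 30 s for 15 min, giving
T = 30 ordinal scores in 1–8; the first scan is indexed t = 0 (either
convention yields 30 scans over the window; we fix t = 0). The MMP summary
score is the plain sum of the 30 scores, so its attainable range is
[30, 240]. The condensed categories A–E merge behaviors that scan sampling
can conflate (not-moving with moving-without-engaging; orienting with
pursuing; attempted with achieved copulation), leaving wing vibration and
genital licking as their own states. A *noninitiator* is a male whose
maximum score over the whole assay is ≤ 2. Noninitiating males are retained
in all downstream analyses by default; exclusion is an option, not the
default, because noninitiation is itself line-dependent. An optional
per-male `exclude` column (injured/dead animals) is honored at read time.
Under strict parsing, males with missing or non-contiguous timepoints are
dropped and reported; duplicated (male, timepoint) rows and out-of-range
scores are fatal.

## Transition phenotypes

Each male's condensed sequence yields a 5×5 count matrix over successive
scans (self-transitions included) with exactly T − 1 = 29 transitions.
Probabilities are **joint**: counts divided by the total transition count,
so each individual's 25 entries sum to 1 and line means (unweighted
averages over males) do too. This whole-matrix normalization — not the
row-stochastic conditional form — defines the 25 analyzed phenotypes; the
conditional view is provided only for inspection and simulation. Cells
never visited are 0; no pseudocounts, and no imputation for bouts shorter
than the scan interval (scan sampling gives a lower bound on transitions —
an acknowledged censoring, not corrected). Ethograms are exported as
GraphViz DOT (edge penwidth = scale × probability; edges below a minimum
weight omitted) or GraphML.

## Variance decomposition

"Line after block" is implemented as sequential residualization: a one-way
fixed-effect ANOVA on block gives %B = 100·SS_block/SS_total with
F_B = MS_block/MS_within, and the block-mean-centered residuals feed a
one-way random-effects ANOVA on line. The between-line component uses
expected mean squares with the unbalanced coefficient
n₀ = (N − Σnᵢ²/N)/(a − 1); H² = σ̂²_L/(σ̂²_L + σ̂²_ε) is **not** truncated
at zero — a joint mixed model or REML would be statistically tidier but
pins small estimates to zero, hiding the sampling behavior of weak signals
(negative estimates occur with positive probability under the null and are
informative). A two-stage decomposition also reproduces the conventional
two-column presentation (%B alongside H²). F_L = MS_line/MS_error is tested
against the F distribution. The arcsine-square-root transform for
proportion-valued traits is a config switch; both raw and transformed
tables can be emitted. Bonferroni families always take an explicit test
count (the transition family is 25 tests at α = 0.05, critical P = 0.002);
no family size is ever inferred.

Calibration checks (in the test suite): on 166-line × 12-male panels the
estimator's mean is within ±0.02 of generating H² ∈ {0, 0.05, 0.10} over
500 replicate traits, and the line test holds its nominal 5% type-I rate.
These replicate-trait studies use the generator's Gaussian trait simulator
(additive line + block + error), which isolates estimator behavior from
the behavioral chain; chain-level recovery is tested separately at smaller
replicate counts.

## Noninitiator mixture

Per-line noninitiator proportions are fitted by (a) an exponential
distribution, MLE rate = 1/mean, k = 1, and (b) a two-component Gaussian
mixture by EM, k = 5, components relabeled so µ₁ ≤ µ₂. The zero spike
drives one component's variance toward 0 and the unrestricted likelihood
toward +∞, so variances are floored (default 1e−6); with the floor active
the reported maximum is a constrained one. Initialization is a median
split (k-means optional); the EM trace is checked non-decreasing every
iteration and fits are deterministic given (data, seed). Models are
compared by continuous-density AIC = 2k − 2 logL; because proportions live
on [0, 1], densities can exceed 1 and log-likelihoods be positive, so AIC
values are often negative — only differences are meaningful. Both candidate
models ignore the bounded support; truncated variants would be a natural
extension but are not part of the comparison menu.

## Factor analysis

PCA is performed on the **correlation** matrix of the 25 line-mean
phenotypes (the factor-analytic convention; covariance PCA would let the
two large cells E→E and A→A dominate). Components with eigenvalue > 1 are
retained (Kaiser), loadings are eigvec·√eigval, and varimax rotation is
applied with Kaiser row normalization (toggleable). Rotation uses classical
pairwise planar rotations with the closed-form optimal angle per pair, so
the criterion is non-decreasing by construction; convergence is declared
when the largest angle in a sweep falls below tolerance (default 1e−10,
up to 1000 sweeps). Communalities and total variance explained are
invariant under rotation (conserved to 1e−8 in tests; cross-checked
against an independent rotation implementation). Sign convention: each
factor's largest-magnitude loading is positive. Factor scores use the
regression (Thurstone) method on standardized inputs, giving zero-mean
score columns. Constant phenotype columns are dropped with a warning
before PCA.

## Association scan

Inbred-panel genotypes are dosages 0/2 (heterozygous calls missing by
default, dosage 1 optionally), read from wide TSV or VCF. Variants whose
minor genotype is carried by fewer than 4 lines (configurable) are
filtered. The scan regresses per-line phenotype means on dosage by OLS
with an intercept and optional user-supplied per-line covariates —
relatedness proxies, inversion and endosymbiont status enter as generic
covariate columns rather than a mixed model, preserving the scan's simple
structure. Implementation: phenotype and all complete-call variants are
residualized on the covariate design once, then closed-form simple
regression per variant (equal to full OLS by Frisch–Waugh–Lovell; verified
against an independent OLS implementation to 1e−10); variants with missing
calls are refitted on their complete lines. Two-sided t tests with
df = n − n_covariates − 2. Hits use a strict Bonferroni threshold
α/n_tests plus a suggestive tier (default P ≤ 10⁻⁵); QQ points compare
−log10 sorted P against uniform (i − 0.5)/n quantiles, and a
genomic-control λ is reported.

## Synthetic-study generator

The generator emulates the targeted study design: 166 lines, 10–15 males
per line, 5 blocks, T = 30.

* **Base matrix** — the panel-average joint transition matrix (heaviest
  cells E→E ≈ 0.54 and A→A ≈ 0.18 after renormalizing the stored means to
  sum to 1). Line-specific **conditional** rows are Dirichlet draws
  centered on the base conditional rows with a common concentration.
  Because lines vary on conditional rows while the analyzed phenotypes are
  joint probabilities, the concentration → realized-H² map is calibrated
  numerically: concentration 57 gives pipeline-estimated H²(E→E) ≈ 0.095
  (8-seed average; 55 → 0.107, 60 → 0.088). This calibration was run once
  and stored; it is a generator design constant, not a fitted quantity.
* **Blocks** — each block carries a Gaussian tilt offset (SD 0.05) applied
  as exponential tilting of the conditional rows along the category order;
  this sizes block variance shares of the MMP score at a few percent,
  matching the scale the two-stage decomposition is meant to absorb.
* **Males** — first-order chains started in A (flies begin separated by an
  opaque divider, so "no engagement" is the physically forced initial
  state; configurable). Categories map back to ordinal scores uniformly
  within each preimage, except that an advancing chain takes the higher
  ordinal of a two-score category, emulating the scoring rule that a male
  caught mid-transition is scored closest to copulation. Noninitiator
  males (two-group structure: 20% of lines at within-line rate 0.122,
  the rest at 0) draw uniform scores in {1, 2} instead.
* **Genotypes** — biallelic variants with line-level alt frequencies
  uniform on [0.05, 0.5], no linkage disequilibrium; one designated causal
  variant adds 0.05 to carriers' conditional E→A rate (taken from E→E).
  Two inert binary line covariates are included to exercise covariate
  plumbing.
* **Durations** — for a 35-line subset, line-mean copulation durations are
  drawn with population correlation −0.35 to the line's true E→A rate
  (mean 20 min, SD 4 min), then ≥10 per-pair durations per line (SD 3
  min); the <5 min analysis filter sees realistic casualties.

Everything is reproducible byte-for-byte from a single seed, and the
ground truth (per-line matrices, noninitiator rates, block offsets, causal
variant, duration means) is serialized beside every generated bundle,
explicitly labeled as generator choices.

What the generator does **not** emulate: dwell-time (semi-Markov)
structure, female behavior and rejection dynamics, linkage disequilibrium,
genotype–block interactions, and real measurement error in scan scoring.
Passing recovery tests therefore demonstrates estimator correctness under
the stated generative model, not robustness to these real-data features.

## Numerical choices and limitations

* Default problem sizes in tests (e.g. 500 replicate traits for estimator
  calibration, 10,000-variant null scans, 100–200 seeds for mixture and
  power studies) were chosen to make Monte-Carlo error comfortably smaller
  than the tolerances being checked while keeping the suite quick to run.
* Transition phenotypes are compositional (each male's 25 sum to 1), so
  one direction of variation is structurally constrained; the factor
  analysis makes no simplex correction, matching standard practice for
  this design.
* The heritability estimator assumes males are exchangeable within line
  after block centering; trial and arena are randomized within block and
  not modeled.
* EM can in principle converge to a local optimum; with the median-split
  initialization and well-separated noninitiator structure this has not
  been observed, and a k-means initialization is available as a check.
* With very few blocks the realized between-block variance has large
  sampling spread; %B estimates on any single panel scatter accordingly.
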