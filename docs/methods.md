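# Methods

`neodemic` implements two statistical tracks that address the same
question — how farming spread into Neolithic Europe — from opposite ends:
a drift-aware admixture model for present-day haplogroup frequencies, and
a serial-coalescent simulation framework that confronts ancient and
modern mitochondrial sequences with three demographic scenarios.  This
note records the models, their assumptions, the defaults, and the design
choices that were genuinely open.

## 1. Admixture inference from haplogroup counts

### Model

An admixed population H is founded at time T in the past by a mixture of
two parental populations P1 (hunter-gatherer, Palaeolithic) and P2
(farmer, Neolithic), with proportions p₁ and p₂ = 1 − p₁.  After
founding, the three populations evolve in isolation under pure genetic
drift.  Drift in population *i* is summarised by the scaled time
tᵢ = T/Nᵢ (generations over haploid effective size): the data cannot
separate T from Nᵢ, only their ratio.  The observed data are haplogroup
counts (K ≥ 2 classes) from samples of sizes n₁, n₂, n_h.

The sampling distribution of drifted counts is handled exactly through
the coalescent.  A sample of n lineages observed a scaled time t after
founding descends from m ≤ n founder lineages, where m follows the
ancestral-lineage-count distribution of the pure-death process (each
pair coalescing at rate 1 per unit t).  Given m, founder types are iid
draws from the ancestral frequency vector x, and the m family sizes are
uniform over the C(n−1, m−1) ordered compositions of n.  Summing over
founder configurations gives

P(c | x, t) = Σₘ P(m | n, t) · [Σ_{m₁..m_K} m!/∏ m_k! · ∏ x_k^{m_k} C(c_k−1, m_k−1)] / C(n−1, m−1),

where the inner sum runs over per-haplogroup founder counts m_k summing
to m.  The inner sum is the coefficient of z^m in a product of K small
polynomials, computed by convolution in O(n·K·max c_k); all terms are
non-negative, so the computation is stable with running rescaling.
Because this marginal likelihood is available in closed form for every
n, the sampler does not need latent genealogy variables at all: an
earlier plan to switch from exact enumeration (small n) to
latent-variable augmentation (large n) was dropped in favour of exact
marginalisation everywhere, with brute-force enumeration retained purely
as a test oracle.  This improves mixing (no latent-state autocorrelation)
at no cost in correctness.

Boundary behaviour follows from the formula: t = 0 reduces to the
multinomial; t → ∞ reduces to a single founder drawn from x; an observed
haplogroup with zero ancestral frequency has probability zero at t = 0
(−∞ log-likelihood, legal and flagged by the return value).

### Lineage-count distribution: numerics

The pure-death eigen-expansion (the classical alternating series in k
with rates k(k−1)/2) is used whenever it is numerically safe.  Safety is
assessed per evaluation by comparing the log-magnitude of the summed
absolute terms with machine precision: when the estimated absolute error
exceeds 10⁻¹², the series has cancelled catastrophically (small t, large
n) and the implementation switches to scaling-and-squaring of the
transition matrix of the death chain.  That route is cancellation-free —
the matrix is non-negative — at cost O(J n³), J ≈ log₂(n²t), and remains
accurate at n = 1000.

Inside the MCMC the pmf is needed at arbitrary t thousands of times per
chain.  A per-sample-size cache tabulates the pmf on a geometric grid of
drift times (12 points per octave over [5·10⁻⁴, 20], built by repeated
matrix squaring along interleaved doubling chains) and interpolates
log-probabilities monotonically (PCHIP) in log t.  The interpolation
error is below 2·10⁻³ in log-likelihood, i.e. far below the posterior's
own Monte-Carlo noise; the standalone `drift_lineage_pmf` function never
interpolates.

### Sampler

Metropolis-within-Gibbs over (p₁, t₁, t₂, t_h, x₁, x₂):

* p₁ — logit-scale Gaussian random walk, flat U(0,1) prior;
* tᵢ — log-scale Gaussian random walks, log-uniform prior on
  [10⁻³, 10] by default (the scale spans mtDNA-like weak drift and
  NRY-like strong drift; configurable);
* x₁, x₂ — Dirichlet neighbourhood proposals x′ ~ Dir(κx + 1) with the
  exact Hastings ratio; flat Dirichlet priors.

Step sizes (and κ) adapt towards standard acceptance targets during
burn-in only, so the post-burn-in chain is a fixed-kernel Markov chain.
Defaults for production runs are 2·10⁵ iterations, 5·10⁴ burn-in,
thinning 10; the test suite and examples use 6·10³/2·10³/3, which is
sufficient for the single-locus posteriors involved (effective sample
sizes of order 10²).  Diagnostics (per-block acceptance rates,
autocorrelation-based ESS) are attached to the returned posterior.
With the likelihood switched off the same kernel reproduces its priors
(Kolmogorov–Smirnov distance < 0.05 at 10⁴ draws), which is checked in
the test suite.

Posterior summaries use a boundary-reflected Gaussian KDE on [0,1] for
the mode and the shortest-interval estimator for HPD regions.

## 2. Geographic trends

Great-circle (haversine) distances are measured from a Near East origin
at 36°N 40°E — the paper-style "distance from the Near East" without a
stated origin; the default is configurable and sits in northern
Mesopotamia.  Posterior uncertainty is propagated into the regression by
resampling: per replicate, one draw per population is taken from its
posterior and an unweighted OLS line of value on distance is fitted;
1,000 replicates give an ensemble of slopes summarised by the median and
5–95% envelope.  Fitted values may leave [0,1] and are deliberately not
clipped.  Point-mass posteriors make every replicate identical to the
single-fit `stat_distance_trend`, which is asserted exactly in the
tests.  Effective sizes of admixed populations are derived per draw as
N_h = T/t_h with T = date/generation-time (25 years per generation by
default) and non-positive draws excluded with a warning.

## 3. Serial coalescent and the three demographies

The simulator is a backwards-in-time haploid (mitochondrial) coalescent:
k lineages in a deme of current size N(g) coalesce pairwise at rate
1/N(g) per generation; samples activate at their sampling ages; deme
sizes are piecewise-exponential with closed-form time-rescaled waiting
times within each segment (memorylessness justifies redrawing the unit
exponential across segment boundaries); forward joins are backward
splits that assign each lineage independently to a source deme with
probability proportional to that deme's size at the join.  Event and
sampling times live on a whole-generation grid (years floor-divided by
the generation time); coalescence times are continuous.

The three demographies share the boundary times 45,000 / 10,000 / 7,500
years BP (1800 / 400 / 300 generations):

* **TP (total panmixia)** — one deme, exponential growth N_UP → N_N over
  the Palaeolithic phase and N_N → N_M after the Neolithic transition,
  founded from a constant-size ancestral deme N_A.
* **S (split)** — two demes of size N_UP/2 at 1800, growing
  independently without gene flow to N_N1 and N_N2 (equal shares by
  default), joining at 300 into one deme of size N_N = N_N1 + N_N2.
* **SDG (split with differential growth)** — as S, but deme 2 (the
  farmers' ancestors) holds its initial size until generation 400 and
  then grows to N_N2 inside the 10,000–7,500 y window, while deme 1 (the
  hunter-gatherers) grows — possibly at a near-zero rate — across the
  whole phase.  Deme 2's share of N_N is φ ~ U(0.5, 0.95), the single
  SDG nuisance parameter: with N_N1 + N_N2 = N_N fixed, the deme-1
  growth rate is determined by φ, so no separate growth-rate prior is
  needed.

Defaults (all configurable): N_M = 10⁵, N_A = 10⁴, sequence length
L = 360 with Jukes–Cantor mutations at 5·10⁻⁶ per site per generation
(HVS-I-like), and an emulated sampling design of 20 hunter-gatherers at
330 generations BP, 25 early farmers at 290 (just after the join, hence
from the merged deme) and 100 moderns at 0.  These stand in for the real
ancient panel, whose exact sizes and ages the source study does not
print.

Calibration is checked against theory (pair TMRCA = N; serial pairs are
memoryless; pairwise differences ≈ 2NμL) and against msprime as an
independent simulator on identical constant-size configurations.

## 4. Summary statistics

Gene diversity is the unbiased H_e = n/(n−1)(1 − Σp²) on haplotype
frequencies.  Pairwise F_ST defaults to the pairwise-difference form
F_ST = 1 − H_w/H_b (mean within-population pairwise nucleotide
differences averaged over the two samples, over mean between-population
differences), the common choice for HVS-I ancient-DNA work; a haplotype
(0/1 identity) mode is kept for sensitivity analysis.  Negative
estimates are retained — the ABC machinery needs the raw statistic
distribution — and H_b = 0 is defined as F_ST = 0 (degenerate,
undifferentiated).  The ABC statistic vector is the three pairwise F_ST
values in fixed order: HG–farmer, HG–modern, farmer–modern.

## 5. ABC model choice and estimation

Rejection retains the ⌈tolerance·M⌉ simulations nearest the observed
vector in Euclidean distance after scaling each statistic by its
reference-table median absolute deviation (robust to the heavy-tailed
F_ST distributions; zero MADs fall back to the standard deviation), with
Epanechnikov weights on a bandwidth equal to the largest accepted
distance.  Defaults: M = 50,000 and tolerance 0.01 for production runs;
M = 20,000 for the validation analysis below.

Model choice offers two post-rejection adjustments with one contract:

* **MLR** — a kernel-weighted multinomial logistic regression of model
  label on the standardised statistics over the accepted set, evaluated
  at the observation (essentially unregularised, C = 10⁶).
* **NCH** — a single-hidden-layer feed-forward classifier; kernel
  weights enter by weighted resampling of the accepted set, since the
  scikit-learn MLP takes no per-sample weights.

Models absent from the accepted set receive probability zero with a
warning; probabilities always renormalise to one.

Parameter estimation under SDG uses the non-linear heteroscedastic
regression adjustment θ* = m(s_obs) + (θ − m(s))·σ(s_obs)/σ(s).  The
conditional mean m is an exact linear term plus an ensemble of five
early-stopped MLPs on the residuals: the linear term makes the
deterministic-linear case collapse exactly (a tested contract), the
ensemble suppresses single-net initialisation noise, and early stopping
prevents the nets from inventing structure when the statistics carry no
information — in that case the adjusted quantiles reproduce the prior.
log σ is fitted the same way on the log squared residuals; σ is floored
at its 5% quantile to keep the ratio bounded; positive size parameters
are adjusted on the log scale and back-transformed.  If the residual
variance is numerically zero, the variance scaling is skipped (the
spec'd fallback to unadjusted quantiles is then equivalent).  Reported
summaries are kernel-weighted 5/50/95% quantiles.

### Validation harness

`validate_model_choice` simulates K pseudo-observed panels per model
with parameters from the priors (N_UP ~ U(10, 5000),
N_N ~ U(1000, 100000), φ ~ U(0.5, 0.95) under SDG), assigns each by the
highest MLR posterior probability against one fresh shared reference
table of M simulations, breaking exact ties uniformly at random
(seeded), and reports the row-normalised 3×3 confusion matrix in
percent.  MLR (not NCH) is the assignment engine, matching the
procedure the validation is meant to mirror.

At the desk scale used here (K = 150 per model, M = 20,000, tolerance
0.01) the matrix shows a stable qualitative structure: the SDG model is
by far the most identifiable (self-assignment 70–75% across seeds);
pseudo-data from S are misassigned most often, predominantly to TP
(17–23%); and the three-statistic procedure is biased towards TP.  The
exact percentages are properties of the whole study design — the
ancient panel's sample ages and sizes, the mutation rate, the
reference-table size and the tolerance — so they transfer across
designs only in this qualitative sense, not digit by digit; the design
here is the declared emulated one, fixed in advance.  Monte-Carlo error
at K = 150 is about ±3.5 points per entry.

## 6. Exceedance-probability grids

For a grid over (N_UP, N_N) — 50 equally spaced values per axis over the
priors in the full analysis, 2,500 cells; linear spacing by default with
log spacing available — R panels are simulated per cell and
P_S>O = P(simulated F_ST ≥ observed) is estimated per comparison, with
the two-tailed variant p₂ = min(1, 2·min(P(≥), P(≤))).  Simulated F_ST
draws are cached per cell, so re-thresholding against a different
observed value is exact (asserted in the tests: re-thresholding equals
re-running with the same seed) and both tails come from the same sample.
Replicates default to 1,000 per cell for production; tests use 30–200.
Under SDG the nuisance share φ is drawn per replicate from its prior.

## 7. Synthetic data

The generator produces every input with known ground truth: drifted
count tables (flat-Dirichlet parental frequencies, founder counts from
the lineage-death distribution, Pólya-urn family sizes — the exact
forward counterpart of the likelihood), sequence panels under the three
demographies, and a geography fixture with populations placed along a
meridian so that great-circle distance is exactly proportional to the
latitude offset.  Every generator returns (and optionally writes) a
truth record; recovery tests read truth only from it, and regeneration
with the same seed is byte-identical.

What the generator does *not* emulate: real haplogroup nomenclature,
radiocarbon-date heterogeneity within sampling horizons, sequencing or
haplogroup-calling error, rate heterogeneity across HVS-I sites, and
population structure within the sampled populations.  Passing recovery
tests therefore show that the estimators are correct and calibrated
under the stated models, not that the models capture every feature of
the real datasets.

## 8. Problem sizes and numerical conventions

* Admixture recovery tests: 20 datasets, samples of 200 per population,
  K = 10, drift 0.05, chains 6,000 + 2,000 burn-in — a deliberate
  reduction of the production chain lengths that keeps posterior
  summaries stable to well within the tested tolerances.
* Model-choice validation: K = 150 per model against M = 20,000
  reference simulations.
* Grid analyses in tests: single cells to 2×2 grids at 30–200
  replicates.
* Ties on the maximum model probability are broken uniformly at random
  with the run's seed; degenerate F_ST (H_b = 0) is 0; negative drift
  draws are excluded from N_h with a warning; ages floor-convert from
  years to generations.

## 9. Known limitations

* The admixture model is single-locus; posteriors are intentionally wide
  and the geographic signal emerges only jointly across populations.
* The serial coalescent has no migration between demes (the split models
  assume none), no recombination and no selection.
* The NCH classifier/regressors inherit scikit-learn MLP limitations
  (no native sample weights — handled by resampling; finite-ensemble
  seed noise of a few percent).
* Validation percentages are scale- and design-dependent, as discussed
  in §5; only their ordering and rough magnitudes are portable.
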