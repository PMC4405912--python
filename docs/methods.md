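# Methods

This note documents the models and procedures implemented in `microtime`,
the choices made where the design was genuinely open, and what the
simulation-based validation does and does not establish.

## Data model

An `OtuTimeSeries` is a (days × OTUs) matrix of non-negative integer read
counts indexed by integer study day (day 0 = first sample), with optional
per-OTU lineage strings and optional sum-to-one fractions. Calendar
parsing is a reader concern: ISO-dated columns are converted to day
offsets on input. Sample QC removes days with fewer than 10,000 total
reads; the boundary is strict, so a 10,000-read day is kept. QC is
idempotent. Host metadata are long-format `date,variable,value` tables
split into one series per variable; exclusion lists for protocol-deviant
samples (e.g. differently stored aliquots) must be supplied by the user —
storage metadata are not modelled.

Fractional abundances below the per-subject detection limit are treated
as unobserved. The default limit is 10⁻⁵·⁸, appropriate for daily gut
surveys at ~10⁵ reads; it is a per-series attribute because it depends on
sequencing depth.

## Community stability

Between-day dissimilarity is the Jensen-Shannon distance: the square root
of the Jensen-Shannon divergence with base-2 logarithms, a true metric
bounded by 1 (0·log 0 := 0). Base and root matter here because the
normalization weights are (1 − j)², which requires j ∈ [0, 1]. The
median-JSD-versus-temporal-separation curve summarizes drift: for a
stationary community it asymptotes near the overall median (operationally:
the median over the latter half of the curve falls within 10% of the
overall median), while a drifting community yields a monotonically rising
curve. Core-OTU persistence uses an inclusive threshold (present on
≥ the given fraction of days). Phylum-level ratios
(e.g. Bacteroidetes/Firmicutes) return NaN on days where the denominator
phylum is absent rather than raising.

## Robust load normalization

Per target day: (1) the abundant set is the smallest abundance-sorted
prefix of OTUs whose median daily fractions sum to ≥ 90% of all OTUs'
summed medians; (2) the reference value for OTU *i* is the *lower*
weighted median of its fraction across all days — the smallest value at
which the cumulative normalized weight reaches 0.5 — with day weights
(1 − j)²; the target day participates in its own reference with weight 1;
(3) m = 10^median(log10 y − log10 x) over OTUs nonzero in both vectors
(zero pairs are dropped, not pseudocounted; fewer than three usable pairs
is an error); (4) the day is kept iff the median absolute log10 residual
is ≤ 0.4 (≈ 2.5-fold). The residual rule operates in log10 space: linear
fractions could never reach 0.4, and the fit itself is performed in log
space because abundance data are heteroscedastic.

Days are normalized independently and deterministically; reference
construction is a single non-iterative pass (discarded days still
contribute to other days' references). The median gives the estimator a
50% breakdown point: as long as fewer than half of the abundant OTUs
change between sample and reference, m equals the true common fold-change
exactly, which is what removes compositional artifacts. Because rescaled
days no longer sum to one, m doubles as a per-day estimate of relative
total bacterial load.

`RobustLoadNormalizer` exposes this as a sklearn transformer: `fit`
learns the reference system and per-day factors of the fitted matrix;
`transform` on unseen rows normalizes them against the fitted days only
(the new row cannot be part of its own reference in that path).

## Synthetic communities

The generator is first-class code: it defines the conditions under which
the pipeline is validated. Each OTU's log10 fractional abundance follows
an OU process via the exact discretization

    S_{i+1} = S_i e^{−λδ} + μ(1 − e^{−λδ}) + σ √((1 − e^{−2λδ})/(2λ)) ε_i

with δ = 1 day and S_0 drawn from the stationary law N(μ, σ²/(2λ)).
Default parameter ranges are λ ~ U(0.1, 1) (reversion time scales of 1–10
days), μ ~ U(−6, −1) (the span from detection limit to dominant taxa),
σ ~ U(0.05, 0.5) (up to ~3-fold daily fluctuations), ~3,000 OTUs, and two
independently parameterized 50-point regimes joined into a 100-point
series to emulate a community shift. Sequencing is plain multinomial
sampling at per-day depths drawn uniformly from 10,000–100,000 (the
generator also accepts an explicit pool of observed depths to resample).
OU parameter recovery uses the Gaussian AR(1) equivalence: a = e^(−λδ)
by least squares with intercept b, then λ = −ln(a)/δ, μ = b/(1 − a),
σ² = Var(resid)·2λ/(1 − a²). A fitted a outside (0, 1) has no OU
counterpart and raises.

What the generator does not emulate: overdispersed counting noise (PCR
and library effects), taxon-taxon interactions, irregular sampling gaps,
and OTU-calling artifacts. Passing validation therefore shows the
pipeline's statistics behave correctly under mean-reverting log-linear
dynamics with multinomial noise — not that real data satisfy those
assumptions.

The planted-effect harness draws a daily Bernoulli driver and shifts the
log10 abundance of chosen target OTUs by a fixed effect (default studies
use 0.5 log10 units ≈ 3.2-fold) at a fixed lag before read re-sampling,
providing ground truth for end-to-end association recovery.

## Stationarity screening

ADF tests run on log10-transformed, mean-centered series (zeros floored
at the detection limit before the transform, flooring before centering),
with no deterministic trend and lag order chosen by the t-statistic rule
up to ⌊12(n/100)^0.25⌋ lags. Because the equilibrium level is estimated
(the centering), p-values use the Dickey-Fuller distribution for an
estimated mean: pairing a centered series with the zero-mean null
distribution rejects ~30% of true random walks at α = 0.05. With the
estimated-mean null the size is ~5% and power against OU dynamics
(λ = 0.5, σ = 0.3, n = 200) exceeds 0.9, both verified by simulation.
Screening targets the 100 most abundant OTUs in a window (less-abundant
OTUs hug the detection limit and test noisily); constant-after-flooring
series are skipped with a warning rather than guessed at.

The P-test measures phylogenetic clustering of the stationary /
non-stationary labelling: the observed Fitch parsimony score (Hartigan's
generalization on multifurcating nodes) is compared with scores under
random leaf-label permutations, with the corrected estimator
p = (#{null ≤ observed} + 1)/(n + 1). This estimator is valid but
super-uniform under the null — permutation p-values on a small discrete
statistic are conservative, not uniform.

## Detrending

Continuous series: exhaustive maximum-likelihood ARIMA grid over p ≤ 2,
q ≤ 2, d ∈ {0, 1} (intercept included for d = 0), minimum BIC; residuals
for d = 1 models drop the first (diffuse-prior) value. Binary-dominant
series (≥ 75% exact zeros, boundary inclusive): logistic regression of
y_t on its previous one or two values, chosen by AIC; perfect separation
falls back to a small ridge penalty with a warning. In both cases, if the
residuals' absolute lag-1 autocorrelation exceeds the raw series', the
model is discarded and the raw (centered) series is used. Series are
aligned on observed dates and treated as regularly spaced; gaps are not
interpolated. Residuals keep their own date index; pairwise operations
align on shared dates.

## Clustering and association

OTU distances are max(0, 1 − ρ) with ρ the Spearman correlation
(average ranks on ties) on pairwise-shared dates (≥ 3 required); WPGMA
('weighted') linkage; flat clusters by cutting at 80% (association) or
90% (disturbance) of the maximum merge height; labels are deterministic,
ordered by first member. Association clustering consumes detrended OTU
residuals; disturbance clustering consumes standardly normalized
fractions. Cluster dynamics are the per-date median over members, and the
median series are detrended again before correlation — the median of
individually whitened members can retain serial structure when members
share an ARMA leftover.

Cross-correlation pairs metadata(t) with cluster(t + L) for L ∈ [−7, 7]
(positive lag = microbiota follows the host factor), requiring ≥ 30
shared dates per lag. Series with significant residual lag-1
autocorrelation (normal approximation z = r₁√n, p < 0.01) are excluded
first. Benjamini-Hochberg q-values are computed within each (lag, body
site) family; BH replaces the empirical-null FDR estimator sometimes used
for such screens — q-values can differ slightly, but BH is exact,
assumption-light and oracle-checkable. Significant pairs then face a
Durbin-Watson check: OLS of one residual series on the other, DW
statistic against a two-sided permutation null (1,000 order shuffles,
p < 0.01 excludes). Prewhitening smears a genuinely white exogenous
effect across neighbouring lags, so the DW stage is conservative: it can
veto true lagged effects along with spurious ones.

## Disturbance analysis

Pre-perturbation core OTUs (present on ≥ 95% of pre-window days) are
categorized by post-window fate: lost (post median 0), extinct (lost and
never detected after the window), retained (post median > 0); gained OTUs
are post-core with zero pre-window median. Medians use all window days.
Category read fractions within each window segment sum to 1 once the
residual "other" class is included. Major clusters are those whose summed
fraction exceeds 10% on strictly more than 3 days. For phylogenetic
coherence, subtrees whose leaves share a cluster assignment and have all
pairwise patristic distances (branch-length sums) below 0.2 are collapsed
to a single leaf — guarding against strain-level sequencing variants of
one organism masquerading as a coherent clade — before a two-sided Fisher
exact test on the (focal cluster × subtree) 2×2 table of collapsed
leaves. The subtree under test is an explicit argument; an exploratory
all-internal-nodes scan with Bonferroni adjustment is provided but
flagged as exploratory. Host metadata shifts around a window are tested
variable-by-variable with two-sided Mann-Whitney U on ±30-day spans, BH
across variables.

## Validation sizes and numerical choices

The shipped validation uses problem sizes chosen to exercise the
pipeline at realistic scale while remaining quick to re-run: load
recovery on four independent 3,000-OTU × 100-day datasets (minimum
true-vs-inferred load correlation reported; the same computation backs
`scripts/acceptance.py`); ADF size on 1,000 random walks and power on 300
OU series; OU parameter recovery over 100 replicates of n = 10⁴;
end-to-end planted-effect recovery over 50 replicates of a 10-OTU,
300-day community with a 3-OTU target cluster (small communities keep the
ARIMA grids cheap without changing what the test demonstrates); and a
6-replicate null run for family-wise FDR control. Oracle equivalences
(weighted median, BH, Fisher, Fitch/P-test, WPGMA) are exact.

Tie-breaking and degenerate-input rules throughout: lower weighted
median; stable sorts; 0·log 0 = 0; constant series raise where a test
statistic would be undefined and are screened out (with a flag or
warning) where the surrounding pipeline can proceed; days or pairs with
insufficient data are omitted with a recorded reason rather than
imputed.

## Known limitations

- The normalization assumes fewer than half of the abundant OTUs change
  between a day and its reference; coordinated whole-community blooms
  violate this and bias m toward hiding the shared component.
- Inferred load is relative, not absolute; it is only defined for days
  passing the residual-spread rule, and both diarrheal episodes in the
  motivating study are examples where it cannot be confidently inferred.
- The binary serial-dependence model is a plain Markov logistic
  likelihood; it does not model covariates or random effects.
- The DW stage can veto true effects (see above); analyses aimed at
  discovery may reasonably report both screened and unscreened tables.
- P-test p-values are conservative on small trees; with < ~8 labelled
  tips the attainable significance floor is coarse.
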