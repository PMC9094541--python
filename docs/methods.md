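# Methods

## Response model and fitting

Each site-year's grain yield (kg/ha, dry basis) is modelled as a
quadratic-plateau in fertilizer N rate: `y = c + bN + aN²` up to the join
point `x₀ = −b/(2a)`, constant at the plateau `c − b²/(4a)` beyond. The
C¹ constraint `b = −2a·x₀` ties the three parameters together, so for a
*fixed* join point the model is linear in `(c, a)`. The fitter exploits
this: it profiles x₀ on a 1 kg grid over `(0, 1.5 × max rate]`, solves an
ordinary least-squares problem per candidate, and polishes the winning
candidate with a bounded derivative-free scalar minimisation (absolute
tolerance 1e-8 on x₀). Ties on the grid break toward the smallest x₀ for
reproducibility. This avoids the non-convergence pathologies of free
nonlinear least squares on segmented models and is auditable against a
brute-force grid (the test suite holds the profiled SSE to within 0.1 %
of a dense 0.5 kg grid search, and to exact interpolation on noiseless
data).

Diagnostics: r² = 1 − SSE/SST about the mean; the inclusion F test is
the overall regression F of the 3-parameter model against an
intercept-only model with (2, n−3) degrees of freedom. A trial whose
yields are all identical is rejected as degenerate rather than fitted.
Yields are assumed dry-basis throughout; moisture conversion is the
caller's responsibility.

Screens (all three must hold for a site-year to enter the analysis):
F significant at α = 0.10, r² ≥ 0.30 (boundary inclusive), and join
point strictly below the highest N rate applied in that trial.

## Economics

Prices default to grain $0.158/kg and N $0.88/kg. The price ratio used
for the optimum is the fixed 5.6 kg grain per kg N rather than the raw
quotient 0.88/0.158 = 5.5696; a raw-price mode (`PriceSet.from_prices`)
derives the ratio instead. Both round to the same 6.4 % terminal iNUE.
Profit calculations always use the raw prices.

* EONR = (ratio − b)/(2a); always below x₀ when b > ratio. When b ≤ ratio
  the optimum is 0 with a warning (fertilization never profitable).
* iNUE(N) = (b + 2aN)·k with grain N content k = 0.0115 kg grain-N per
  kg grain. Initial iNUE is reported at N = 1 kg/ha because average NUE
  is undefined at 0; the gap to the true N→0 derivative is ≤ |2a|·k
  (≈ 0.006 percentage points at typical curvature) and is ignored.
* Average NUE(N) = (y(N) − c)·k/N, which is (b + aN)·k on the quadratic
  branch and exactly the mean of the per-increment iNUE values taken at
  increment midpoints. It is proportional to k, so sensitivity to the
  grain N content is a pure rescaling (`grain_n_sensitivity`).
* Forgone profit is the *difference* profit(EONR) − profit(N) in $/ha.
  A quotient form (profit share relative to EONR) is exposed separately
  as `forgone_profit_ratio` for auditability, but the difference is the
  primary definition: it is what the $/ha unit and the step summaries
  require. Inversion (which N rate forgoes exactly $s/ha?) is solved
  from the closed-form quadratic, taking the root nearest EONR; the
  round trip is exact to well under $0.001/ha.
* The endpoint ("chord") rate of iNUE decline is
  100·(initial − terminal)/EONR, in percentage points per kg N. Subgroup
  rates can be computed either this way from subgroup means or as means
  of per-site slopes 2a·k; both are available (`rate_of_decrease` and
  the `slope_grain_n_pct` field).
* Step summaries evaluate iNUE, average NUE, N saved and yield reduction
  at the rates where forgone profit equals each step value (default $0
  to $240/ha in $20 steps). A site whose whole forgone-profit range lies
  below a step is excluded from that step and counted; a step reachable
  by no site is still reported with NaN statistics. Distribution
  statistics are quartiles, Tukey 1.5×IQR whisker bounds, mean and
  median, plus across-dataset means weighted by site-year counts.

Percentages are reported as percentage points in tables; internal
computation is in fractions.

## Weather features

Windows (inclusive): season Apr 15 – Sep 15 (154 days), establishment
Apr 15 – Jun 1 (48), growth Jun 2 – Jul 15 (44), grain fill
Jul 16 – Sep 15 (62); the three phases tile the season exactly, so PPT
and GDD are additive across them. Per window: total precipitation; the
Shannon Diversity Index of daily rainfall shares, normalised by ln(window
length) with 0·ln 0 ≡ 0 so it lies in [0, 1] (1 = perfectly even, 0 =
single event or fully dry window); AWDR = PPT × SDI; growing degree days
max(0, (Tmin+Tmax)/2 − 10) with no upper cap; and Ontario-form corn heat
units, daily (Ymax + Ymin)/2 with Ymax = 3.33(Tmax−10) − 0.084(Tmax−10)²
and Ymin = 1.8(Tmin−4.44), each floored at zero. Missing days inside the
season window are an error (no imputation). Civil-date arithmetic only;
the chosen windows avoid February, so leap years do not change window
lengths.

## Slope classification

The per-kg decline of iNUE at a site is 2a·k (×100: percentage points
per kg N, a negative number). Sites are labelled High (fast decline)
when |slope| exceeds the threshold magnitude, Low otherwise — ties to
Low. The default threshold is the ensemble median of magnitudes, which
balances classes to within one site; the signed value is stored with the
negative convention. The protocol splits 60/40 by seed (simple random;
a stratified option exists but is off by default, matching a plain
random split), tunes hyperparameters by 10-fold CV repeated 5 times on
the training portion (exactly 50 tuning folds; each training observation
serves as a test case in 5 of them), selects the highest mean CV
accuracy, and reports accuracy = correct/total on the held-out 40 %.
The random forest tunes the number of features per split; the decision
tree tunes depth, minimum split/leaf sizes and cost-complexity pruning,
and also emits its rules as text. Importance is mean Gini decrease.
Categorical covariates are one-hot encoded deterministically.

## Synthetic data generator

The generator emulates replicated small-plot N trials: six rates
{0, 45, 90, 135, 180, 225} kg N/ha × 4 replicates, yields on a true
quadratic-plateau curve plus i.i.d. homoscedastic Gaussian noise
(default SD 300 kg/ha). Replication matters: with single observations
per rate the curvature is poorly identified at realistic noise (median
relative error of â ≈ 26 %), while the replicated design recovers the
median â to well under 15 %. True coefficients are drawn uniformly from
a ∈ (−0.35, −0.15), b ∈ (55, 95), c ∈ (4000, 9000): these ranges centre
the ensemble on the coefficient scale implied by published maize
responses (join points near 150 kg N/ha, economic optima ~80–200 kg
N/ha, initial iNUE ~65–110 % with a minority of sites above 100 %,
median grain-N slope magnitude ~0.6 percentage points per kg).

Daily weather is an occurrence × amount mixture: wet days Bernoulli,
amounts Gamma, with profile presets (`even`, `uneven`, `wet`, `dry`)
steering evenness and totals — `even` yields mean SDI ≈ 0.86, `uneven`
≈ 0.38. Temperatures ride a seasonal sinusoid with a strictly positive
diurnal range. Soil texture (sand + clay ≤ 100, silt implied), a
six-level drainage class, taxonomic order, irrigation/tillage flags and
rotation are drawn per site.

`covariate_effect` (ce) plants a recoverable signal:
log|a| = log|a₀| + ce·(0.4·evenness_z − 0.3·clay_z), so more even
rainfall steepens the iNUE decline and heavier (clay-rich) soils flatten
it and raise EONR; ce = 0 severs the association. The moderate
coefficients keep the curvature spread realistic at ce near 1. All draws
descend from one seed via per-site seed sequences (separate streams for
truth, yield noise, weather and soil), so identical configurations are
byte-identical and the trial/weather/soil generators share each site's
latents.

What the generator does *not* emulate: within-field spatial correlation,
block effects, heteroscedastic or skewed yield noise, real weather
autocorrelation beyond the seasonal cycle, and any process-based N
cycling. Tests passing on this ensemble therefore demonstrate that the
estimators and the protocol behave correctly under the stated
assumptions — not that those assumptions hold for any particular field
dataset.

## Analysis scale and numerical choices

The analysis scripts run a 189-site-year ensemble (the scale of the
combined published datasets); the heavier test-suite experiments use
200–500 site-years for recovery and 100–120 for classifier checks, sizes
at which the Monte-Carlo margins on the asserted properties are
comfortable. Join-point profiling uses a 1 kg grid plus local polish;
the brute-force oracles in tests use 0.5 kg (fit SSE) and 0.01 kg (EONR
profit grid). Forgone-profit inversion tolerates $0.001/ha. Degenerate
inputs fail loudly: all-identical yields, missing weather days,
single-class training splits, unreachable step values and sub-1-kg
optima each raise a specific error rather than producing silent output.

## Known limitations

* The published three-dataset workbook is an external download; the
  ingestion path (`read_s1_dataset`) maps sheets and columns by name
  pattern and is exercised on a synthetic stand-in workbook in the
  tests. Real-data summaries (screened site-year counts, step-wise
  weighted means) therefore depend on the user supplying the file.
* The F screen uses the overall-regression form; a replicate-based
  lack-of-fit test is not implemented.
* No alternative response forms (linear-plateau, quadratic-only): the
  analysis is committed to the quadratic-plateau.
* EONR here is deterministic given a fit; no uncertainty interval is
  propagated from the fit to EONR or to the step summaries.
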