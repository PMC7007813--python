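# Methods

This note documents the models, defaults and design choices behind
`befthermal`, in the spirit of a statistical-software methods appendix.
Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The experimental design

`design.generate_full_design` implements the balanced random-partition
design: at each richness level S that divides the pool size N, the pool is
shuffled and chunked into N/S disjoint assemblages that jointly cover the
pool; this is repeated for P independent partitions, each assemblage is
replicated K times, and the whole layout is crossed with the T temperature
treatments. Totals follow the counting identity

    units = T · K · P · Σ_S (N/S),

which for the default N = 16, S ∈ {1, 2, 4, 8, 16}, P = 5, K = 3, T = 3
gives 3 · 3 · 5 · 31 = 1395 wells, 465 per temperature. Partitions at
different richness levels are drawn independently (nothing in the design
requires nesting levels within a partition). `validate_design` checks
layer disjointness/coverage, replicate counts, and per-species balance
(each species in exactly P assemblages per level); note the three checks
are not independent — per-layer disjointness + coverage implies balance —
but the validator reports each separately so a corrupted table pinpoints
its own failure mode.

## Thermal performance

The acute TPC of gross photosynthesis uses the modified Sharpe–Schoolfield
model with high-temperature deactivation, fitted on ln rate (lognormal
measurement error is the natural model for rate assays). Parameters and
defaults:

| parameter | meaning | units | default / range |
|---|---|---|---|
| `tc_ref` | reference temperature for ln b(T_c) | K | 291.15 (18 °C, mid-assay-range; affects only ln b's meaning, not T_opt) |
| k | Boltzmann constant | eV K⁻¹ | 8.62 × 10⁻⁵ (the precision conventional in this literature) |
| E | activation energy | eV | fitted; multi-start grid 0.3/0.7/1.2 |
| E_h | deactivation energy | eV | fitted; grid 1.5/3.0/5.0 |
| T_h | inflection temperature | K | fitted; grid at the empirical peak −1/+4/+9 K |

The likelihood is multi-modal, so the fit is a 27-start nonlinear least
squares (`scipy.optimize.least_squares`, trust-region reflective, bounds
keeping E, E_h positive); the converged start with the lowest residual SS
wins, ties broken by lowest E. ln b is profiled out for initialisation.
Fits with all observed rates peaking at an end of the temperature range
are flagged `one_sided` (E_h poorly identified). Non-positive rates are
excluded from the log-scale fit and counted (`n_dropped`), never silently
coerced. Temperatures may be supplied in °C or K; values below 200 are
treated as °C.

The closed-form optimum T_opt = E_h T_h / (E_h + k T_h ln(E_h/E − 1)) is
exposed separately and cross-checked against a dense (0.01 K) grid argmax
of each fitted curve. Two regime caveats, verified numerically in the
tests: T_opt < T_h requires E_h > 2E, and T_opt is monotone increasing in
E_h only in the strongly deactivated regime (ln(E_h/E − 1) > E_h/(E_h − E)).
All fitted and simulated curves here live inside both regimes.

Photosynthesis–irradiance curves default to the hyperbolic-tangent
saturating model NP(I) = NP_max tanh(αI/NP_max) (exponential form
available via `model="exponential"`); NP_max is insensitive to this choice
at saturating irradiance. Gross photosynthesis is GP = NP_max + R with R
supplied as a positive magnitude of dark O₂ consumption. Replicate assay
points are weighted equally.

## Cytometry

Gating uses three fixed thresholds: an event is live iff
log₁₀ FSC ≥ 5, log₁₀ SSC ≥ 5 and log₁₀ FL3 ≥ 3.5. Boundary events exactly
at a threshold are **kept** (the gate removes strictly smaller values).
Abundance = kept events / counted volume × dilution; per-cell chlorophyll
comes from a log-log calibration, log₁₀ chl = slope·log₁₀ FL3 + intercept,
with an identity slope and intercept −5 as the synthetic default (a real
instrument calibration is supplied via config). Species assignment uses a
scikit-learn random forest (200 trees) on the three log₁₀ channels,
trained on gated monoculture events per temperature, with out-of-bag
accuracy reported per class. Each event is assigned to exactly one
species, so assigned abundances partition the community total exactly.
Communities whose mean max-class-probability falls below 0.5 are flagged
low-confidence rather than dropped. FCS binary files are out of scope;
event tables enter as CSV with channel-name mapping
(`cytometry.load_events_csv`).

## The statistical engine

The response is ln total chlorophyll *a* (pg mL⁻¹) by default; ln total
abundance is the alternate. Temperature always enters as an unordered
factor. The sequential table fits the nested models {1}, {T}, {T, log₂R},
{T, log₂R, T:log₂R}; each added term's F is tested against the *current*
step's residual mean square (the classic sequential-ANOVA convention —
treatment SS match a type-I decomposition, which the tests verify against
statsmodels). AIC uses the Gaussian profile form
n ln(RSS/n) + 2(k+1) + n(ln 2π + 1), counting the error variance as a
parameter — the R convention, so tables are comparable with mainstream
output (statsmodels' `OLS.aic` is exactly 2 lower; a test pins this).

Per-temperature richness slopes come from the interaction model; pairwise
slope differences use the Tukey studentized-range adjustment,
p = P(q_{k,df} > √2·|t|), which reduces to the unadjusted t-test when only
two levels are compared.

Species coefficients follow the residual-regression recipe: residuals of
ln production ~ log₂ richness within one temperature are regressed jointly
on the 16 presence indicators *without an intercept* (the intercept would
be collinear with the indicators at the full-richness level), and the
coefficients are centred to mean zero so sign encodes above/below-average
contribution. Species absent from all wells at a temperature get NaN and a
flag. Trait regressions (coefficient ~ T_opt, coefficient ~ ln cell
volume) and monoculture–polyculture regressions are ordinary least
squares; mono/poly abundances are first averaged over the biological
replicates of each community, and the regression is on log-transformed
means (the log choice is ours; shares and capacities are multiplicative).

Overyielding is computed on the ln-production scale: net = mean
full-mixture production − mean of per-species monoculture means;
transgressive = mean full-mixture production − the best species'
monoculture mean. CIs bootstrap replicate wells (within species for
monocultures; 1000 resamples by default).

## The synthetic generator

The generator emulates the study conditions so every stage is testable
with known truth. All randomness flows through named substreams of one
master seed (`traits.substream`), making every output bit-reproducible and
stages independently re-runnable.

**Species pool.** 16 species with thermal optima evenly spaced over
21.5–33.2 °C (an 11.7 °C span, the scale of variation reported for marine
phytoplankton pools at local-to-regional scales), E ~ U(0.5, 0.9) eV and
E_h ~ U(3, 6) eV (acute-TPC ranges; large E_h makes performance collapse
quickly above the optimum), with T_h solved so the closed form reproduces
the intended optimum. Cell volume spans 2–1500 µm³ in a random order
relative to the optima, so size and thermal tolerance are uncorrelated
traits. Cytometry cluster centres follow volume (FSC, SSC) and chlorophyll
(FL3) with independent jitter and are then deterministically repelled to a
minimum pairwise distance of 0.5 log₁₀ units (≈5σ at the default cluster
sd 0.1), giving a separable-but-not-trivial classification task;
per-cell chlorophyll is defined to be exactly consistent with the
calibration curve applied downstream.

**Assays.** 15 assay temperatures (7–49 °C in 3 °C steps); simulated rates
are the Sharpe–Schoolfield expectation times lognormal noise with log-sd
0.10 ("10 % noise"). Raw PI assays put respiration at 30 % of GP and a
saturation irradiance of 150 µmol m⁻² s⁻¹.

**Community outcomes.** No population dynamics — the experiment measures a
single endpoint. Each species has a monoculture *biomass* capacity
C_i(T) = C₀ · g_i(T) · exp(−λ(T − 15)), with g_i the TPC normalised to the
species' own peak (a 0–1 thermal suitability; normalising keeps per-cell
metabolic rate, which scales with cell size, out of the biomass ceiling)
and λ = 0.10 /°C the equilibrium-biomass decline with temperature
(resource-limited systems support less standing biomass when metabolism
runs faster). Community biomass is the dominance-weighted average of
member capacities with weights ∝ g_i(T)^θ, θ = 2 by default: θ → ∞ is a
pure selection effect (tests use this to produce net-but-not-transgressive
overyielding), θ = 0 even allocation. Per-species cells mL⁻¹ divide each
biomass share by that species' chlorophyll per cell. One lognormal noise
factor (sd 0.5 ln units) per well. The within-community dominance
structure is a free parameter of the generator, not calibrated to any
dataset. By construction the richness slope is positive at every
temperature and steeper at 30 °C than 15 °C *in expectation* (warm
treatments spread the g_i much further apart than cool ones); across
random pools the fitted 30 − 15 slope difference is positive in ~95 % of
seeds, so fixed-seed tests check direction, not a magnitude.

**Cytometry events.** Per-species event counts are Poisson(abundance ×
counted volume), channels lognormal around the species' cluster; debris
events (default 20 % of the stream) are uniform on the sub-threshold
region of log-channel space — only their rejection matters.

**Calibration responses.** For studies where the linear-model truth must
be exact (type-I error, power, coefficient recovery),
`simulate_bef_response` draws ln production = a(T) + b(T)·log₂R + ε
directly over the design. Paper-scale defaults: intercepts (8.5, 7.5, 6.5)
declining with warming, interaction slopes (1.5, 2.25, 3.0) — the 30 °C
slope double the 15 °C slope — and residual sd 3.7 ln units, the
well-to-well scatter scale of this kind of microcosm experiment. At these
conditions the interaction F test has analytical power ≈ 1 (noncentrality
≈ 45 at n = 1395), so the >95 % power requirement probes correctness, not
luck. The coefficient-recovery study uses a +1.0 ln-unit constructed
species effect with sd 0.5 replicate noise: composition effects are
explicit there, so only within-assemblage noise belongs in ε (re-using the
3.7 total sd would double-count composition variance).

## What the synthetic tests do and do not show

Passing the suite demonstrates the *machinery* is correct: balanced
designs, exact df/SS/AIC arithmetic, calibrated tests, unbiased optimum
recovery under the stated noise model, correct gating arithmetic, and a
classifier pipeline that conserves totals. It does not demonstrate that
real communities follow the dominance-weighted capacity model, that real
cytometry clusters are lognormal and stationary, or that real residuals
are Gaussian — the generator has no plate/incubator structure, no
acclimation, no species interactions beyond dominance, and endpoint-only
dynamics. Real-data conclusions inherit those caveats.

## Numerical choices and degenerate inputs

- Deactivation overflow is avoided with `logaddexp`; fits run identically
  for °C or K inputs.
- Rank-deficient designs (empty factor cells, constant covariates) raise
  with a diagnosis rather than returning pseudo-inverse estimates.
- Empty event tables yield zero metrics and all-zero assignments, not
  errors; non-positive channels are dropped and counted.
- Bootstrap and forest seeds are explicit arguments; nothing draws from
  global RNG state.
- Problem sizes in the calibration studies (200 species, 500 null and 200
  power simulations, 200 coefficient simulations, 1000 bootstrap
  resamples) are the package's standard verification sizes; they complete
  in a few minutes on one CPU.

## Known limitations

- No Loreau–Héctor additive partition of selection vs complementarity;
  overyielding only.
- No mixed-effects (plate, incubator) models; fixed effects only, as the
  monoculture design is balanced.
- FCS binary ingestion is out of scope (CSV channel tables only).
- The species classifier is trained per temperature and assumes the
  monoculture clusters represent the polyculture phenotypes (no plasticity
  in mixtures).
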