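# Methods

## The tri-phase model

The model treats hourly leaf elongation rate (LER, mm h⁻¹) of a single
growing grass leaf as

    LER(t) = a · T(t) · g(Ψ(t)),

where T is meristem temperature (°C), Ψ is soil matric potential on the
log₁₀ hPa scale, *a* is the genotype's thermal growth rate, and g is the
piecewise-linear stress response

    g(Ψ) = 1                      Ψ ≤ Σ      (normal phase)
         = (σ − Ψ)/(σ − Σ)        Σ < Ψ < σ  (slow phase)
         = 0                      Ψ ≥ σ      (arrest phase).

Assumptions inherited from the estimation procedure:

- **Steady-state elongation.** The leaf is in its linear growth window;
  ontogenetic rise and decay of LER (as captured by Beta-sigmoid
  whole-leaf models) are ignored. Over a ~160 h experiment on the youngest
  growing leaf this is a good approximation; over longer windows a slow
  decline of LER/aT appears even in well-watered plants.
- **Water non-limiting in the thermal window.** *a* is fitted on the first
  24 h, so drying must not reach Σ before then. The drying protocol (and
  the simulator's default drying curve) is designed to honour this.
- **Zero-intercept thermal response.** LER = a·T encodes elongation
  stopping at 0 °C. Within the 15–25 °C regime the through-origin line is
  statistically indistinguishable from a free-intercept fit on clean data,
  but the zero intercept is what gives *a* its physiological meaning.
- **Temperature-independent g.** Stress and temperature act
  multiplicatively; no T×Ψ interaction.

## Estimation stages and their constants

| constant | default | meaning |
|---|---|---|
| thermal window | 24 h | hours used for the through-origin fit of *a* |
| normal threshold | 0.9 | bin mean RGRa above → normal |
| arrest threshold | 0.2 | bin mean RGRa below → arrest |
| bin width | 0.25 log₁₀ hPa | quarter bins on absolute boundaries (2.00–2.25, …) |
| loess span / degree | 0.75 / 2 | soil-moisture imputation (R `loess` defaults) |
| retention | on | keep the highest-Ψ normal bin in the slow-phase fit |

Stage notes:

- **Hourly LER** uses the in-hour length extrema: (L₁−L₀)/(t₁−t₀)·60 with
  t in minutes. On a noisy trace the maximum can precede the minimum; the
  rate is then reported signed and the hour flagged `ler_reversed` rather
  than silently absolute-valued. Hours with fewer than two registrations
  are marked missing, never zero-filled. Hour windows are half-open
  [h, h+1) from experiment start.
- **Imputation** log₁₀-transforms the soil readings first, then evaluates
  a tricube-weighted local-quadratic fit at hour midpoints. Only
  observations before re-watering enter the fit — post-watering readings
  would drag the smooth down and badly underestimate the final soil
  moisture — and by default no value is produced outside the observed time
  range (no extrapolation). The smoother reproduces exactly collinear data
  to 1e−6 and matches R's `loess` (span 0.75, degree 2, direct surface)
  to < 0.02 on a noisy drying curve. Its absolute accuracy on the default
  simulated drying curve is ~0.03 log₁₀ hPa (hold-one-out median), worst
  ~0.08 where the curve rises fastest.
- **Phase classification** averages RGRa per quarter bin. Thresholds are
  applied as: normal iff mean > 0.9, arrest iff mean < 0.2, slow otherwise
  — boundary values are slow. The rebound rule relabels a slow bin as
  normal when the next non-empty bin is normal (single-increment dips are
  treated as noise); it never rescues an arrest bin. Arrest is terminal:
  bins drier than the first arrest bin are excluded from fitting even if
  their mean drifts back above 0.2.
- **Slow-phase regression** fits RGRa = i + cΨ by ordinary least squares
  on all hours in slow bins plus all hours of the highest-Ψ normal bin.
  The retained bin anchors the upper end of the line, which stabilises Σ;
  the response variable is RGRa (a config switch reproduces a raw-LER
  variant). A non-negative ĉ raises an error: the model presumes growth
  declines with drying, and a well-watered control is instead reported as
  the distinct no-response outcome "normal throughout" (thermal fit only,
  breakpoints NaN).
- **Breakpoints** are the line's crossings of RGRa = 1 and 0:
  Σ = (1−i)/c, σ = −i/c, so σ − Σ = −1/c exactly. Estimates outside the
  observed Ψ range are returned but flagged `extrapolated`, never clamped.
- Hours flagged after re-watering are excluded from every stage.

Reported units: *a* is stored in mm h⁻¹ °C⁻¹ and reported as μm °C⁻¹ h⁻¹
(×1000), the conventional unit; Σ, σ in log₁₀ hPa.

## The synthetic-experiment generator

The generator emulates the growth-cabinet protocol that motivates the
defaults: 16/8 h photoperiod at 25/15 °C day/night, 130 h of water
deprivation followed by instantaneous re-watering and 35 h of continued
tracking, leaf length registered every 2 min, temperature every 10 min,
soil matric potential every 4 h, seven clonal replicates.

- **Temperature** is the square wave, optionally smoothed by a first-order
  lag (meristem thermal inertia; default 0 so that simple cases stay
  analytic), integrated exactly per segment.
- **Drying** follows a saturating Weibull rise in the log₁₀ domain,
  ψ(t) = ψ_plateau − (ψ_plateau − ψ_start)·exp(−(t/λ)^k), default
  ψ_start = 1.8, ψ_plateau = 4.3, λ = 60 h, k = 3. With k = 1 this is a
  plain exponential approach. k = 3 starts nearly flat — the wet end of
  the soil retention curve, where suction barely responds to water loss —
  which reproduces the reference trajectory (mean Ψ below 2 log₁₀ hPa
  over the first 24 h, below 3 over the next 24 h, plateau ≈ 4.3 by 96 h)
  while keeping Ψ strictly increasing and the thermal window unstressed
  for every realistic Σ.
- **Growth** integrates a·T·g(ψ) on the tracker grid, holding temperature
  from its most recent reading (a cabinet regime switches stepwise) and
  interpolating ψ log-linearly between soil readings (drying is
  continuous; the sensor merely samples it). Gaussian noise with sd
  `noise_sd_ler` is added to the instantaneous rate; a `no_shrink` flag
  truncates it so cumulative length never decreases (default off — real
  tracker jitter does produce small apparent shrinkage). All randomness
  comes from `SimConfig.seed`; replicates use independent child streams,
  so runs are bit-reproducible.
- `noise_sd_for_fraction(cfg, x)` converts "x % rate noise" into a
  per-sample sd such that the *hourly* LER scatters with sd equal to x %
  of the mean unstressed rate (per-sample noise averages down by
  √(samples/hour) under integration). The default `noise_sd_ler = 0.3`
  mm h⁻¹ corresponds to ~5 % hourly noise for the default thermal rate —
  a plausible tracker figure; no within-day variance estimate exists to
  calibrate it against.

What the generator does **not** emulate — and hence what passing recovery
tests do not show about real data: ontogenetic LER decay under prolonged
well-watered growth, sensor calibration drift and dropouts, leaf-to-leaf
transitions within a tiller, pot-to-pot variation in the drying curve
(replicates share one soil trace), and any deviation of the true stress
response from the piecewise-linear g the fitter assumes. Because the
generative model is exactly the fitted model, recovery tests validate the
estimation machinery, not the biological adequacy of the model.

## Accuracy of parameter recovery

On noiseless simulations at the default conditions the thermal rate is
recovered to machine precision and both breakpoints to within 0.1 log₁₀
hPa across truths Σ ∈ [2.0, 3.2] with slow-phase span σ−Σ ∈ {1.0, 1.5} —
the physiological range (observed genotypes span 1.0–1.2). Two biases are
worth knowing:

- **Retention bias.** Including the last normal bin's hours flattens ĉ
  slightly, since those hours sit at RGRa ≈ 1 above the extrapolated
  line. For spans ≥ 1 log₁₀ hPa the effect is well inside 0.1; for very
  steep responses (span ≈ 0.5, only two occupied slow bins) it can move σ
  by up to ~0.4. Disabling retention
  (`FitConfig(retain_last_normal_bin=False)`) removes the bias when
  enough slow bins remain — with the exact Ψ curve a 0.5-span truth is
  then recovered to ±0.02 — but often leaves too little spread to fit at
  all, which is why retention is the default.
- **Imputation bias.** Loess error in Ψ (worst ~0.08 where drying is
  fastest) propagates into the breakpoints; it is the second-order term
  behind the retention bias under the default conditions.

With 10 % hourly rate noise the 20-seed mean |Σ̂−Σ| is ≈ 0.08 (single
tiller), growing monotonically with the noise level; at 20 % noise an
occasional seed fails the slow-phase sign check outright, which is
reported as an error rather than a silently bad fit.

## Cohort statistics

Per-group means and standard deviations of *a*, Σ and σ, and a classical
one-way fixed-effects ANOVA per parameter (matching R's `aov`, which the
original analysis used); p-values are reported raw per parameter, without
multiple-testing correction. All-identical values yield F = 0, p = 1.
Replicates are treated as independent.

## Degenerate inputs and tie-breaks

- Constant in-hour length: rate 0 (not a division by zero).
- Hours with T ≤ 0 are excluded from the thermal fit and carry no RGRa.
- Slow-phase fits require ≥ 3 points spanning ≥ one bin width.
- A soil reading ≤ 0 hPa is a domain error (log₁₀ undefined).
- RWC outside [0, 100] (mis-weighed samples) is returned flagged, not
  clamped; TW ≤ DW is an error.
- Re-watering detection: first drop ≥ 0.5 log₁₀ hPa between consecutive
  soil readings; an explicit time always takes precedence.

## Problem sizes

Default simulations track one leaf for 165 h (≈ 4 950 length samples,
990 temperature readings, 42 soil readings) and fit in ~20 ms per tiller;
the full test suite and the acceptance script each run in seconds.
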