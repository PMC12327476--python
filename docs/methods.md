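# Methods

This note documents the models, parameter choices and limitations of the
`rorqualfmr` pipeline in enough detail to judge what a passing test suite
does and does not establish.

## The metabolic model

Energy expenditure is reconstructed from respiration.  For a deployment
or bout with `N` breaths observed over `T` seconds, each Monte Carlo
iteration draws one per-breath oxygen uptake

    VO₂ = V_T · E_O₂ · 0.2095   [L O₂]

and converts it to a daily rate

    FMR_i = N · VO₂_i · 20.08 kJ/L · (86 400 / T)   [kJ/day].

The reported estimate is the median of the iterations, with 2.5/25/75/
97.5 percentiles retained.  Parameters, with defaults:

| parameter | default | units | rationale |
|---|---|---|---|
| V_T mean | 0.60 · V_C | L | respirometry of smaller cetaceans and baleen-whale calves |
| V_T SD | 0.15 · mean (= 0.09 · V_C) | L | spread of published measurements |
| V_T support | (0, V_C] | L | a breath cannot exceed vital capacity |
| E_O₂ mean ± SD | 0.35 ± 0.03 | — | stable arterial P_CO₂ across mammals |
| E_O₂ support | [0.24, 0.45] | — | range implied by the alveolar gas equations |
| O₂ in air | 0.2095 | — | physical constant |
| energy per L O₂ | 20.08 | kJ/L | oxycaloric equivalent |
| iterations | 10 000 | — | median stable to ≪ 2% across seeds |

One draw per iteration applies to *all* breaths of the bout.  The
alternative — independent draws per breath — would shrink the output
spread by roughly √N and is the single largest interpretation risk in
this class of model; the choice here keeps the full physiological
uncertainty in the reported quantiles.  Sensitivity scenarios pin V_T at
0.95·V_C or 0.15·V_C (the extreme published tidal volumes, killer whales
and gray whale calves respectively) with E_O₂ still stochastic; by
linearity they scale the default estimate by 0.95/0.60 and 0.15/0.60.

Daily extrapolation multiplies the observed breath rate out to 86 400 s,
i.e. it assumes the tagged period is representative of the day.
Deployment-level FMR uses the deployment-average rate; bout-level FMR
pools breath counts and durations per bout type before estimating.

The morphometric chain is `TL → M_b → TLC → V_C`: power laws
`M_b = a·TL^b` (species-specific) and `TLC = 0.135·M_b^0.92` (the
classical marine-mammal lung allometry), and `V_C = 0.85·TLC`.  The
shipped coefficients are rounded literature-style values; every test
uses explicit synthetic coefficients, so correctness never rests on a
literature lookup, and real-data results will depend on the values
configured.

## Breath detection

Surfacings are maximal runs with depth ≤ 1 m (runs under 2 samples are
sensor blips and discarded).  Durations count samples/fs; a run of
exactly 10 s is treated as short, reading the "longer than 10 s" rule
for multi-breath surfacings strictly.

*Short pathway.*  One breath at the depth minimum of the surfacing iff
|roll| stays within 45° (inclusive) throughout.  The within-surfacing
timing rule (depth minimum) and the inclusive boundary are conventions;
nothing downstream is sensitive to either at 10 Hz.

*Long pathway.*  Each acceleration channel is first-differenced
(removing gravity and mounting offsets exactly) and the differenced
channels are collapsed to their Euclidean norm — the "norm jerk" widely
used in biologging event detection.  The norm is discretised into 16
equal-width bins spanning its range over the record, and Shannon entropy
of the bin histogram is computed in a centred 2-s sliding window.
Record-wide bin edges make the statistic amplitude-sensitive: a
quiescent baseline collapses into one or two bins (SE ≈ 0) while the
broadband transient of a blow spreads across many (SE ≈ 1.5–3 bits).
Peaks qualify as breaths when their prominence exceeds
max(4 × MAD, 0.8 bits), where the MAD is a record-wide estimate of
baseline SE variability — a surfacing-local MAD breaks down precisely in
the breath-dense surfacings it is meant to serve.  Peaks closer than the
5-s minimum inter-breath interval resolve to the higher peak.  Window
length, bin count, prominence constants and the separation are config
values; they are declared operating points, not estimates of any real
tag's optimum.

The union of both pathways is time-sorted with the separation enforced
globally; conflicts resolve toward the breath backed by the longer
surfacing, so a 2-sample stub at a noisy 1-m crossing cannot displace
the breath of the surfacing it fringes.  Deployments where at least half
of long surfacings yield no peaks despite above-floor SE variance are
flagged for review — the automated stand-in for the field practice of
manually inspecting detections and dropping uninterpretable tags.

## Bout segmentation

A dive is a maximal excursion below 2 m (the same depth cut used for
bout speed, keeping one constant); a foraging dive contains ≥ 1 lunge
annotation.  Post-foraging-dive surface intervals are fit by iterative
trimmed maximum likelihood: fit a Gaussian, drop intervals above
μ + 3σ, refit, to convergence (10⁻⁶ in both parameters or 50 passes).
The converged μ + 3σ is the species threshold.  Whether the original
protocol fit histograms by least squares or raw intervals by ML is not
something this package takes a position on; ML on raw intervals is
reproducible and, in simulation, recovers the bulk threshold within 2%
under 10% long-gap contamination.  If trimming collapses σ to zero the
untrimmed fit is returned with a warning flag.

Foraging bouts are maximal chains of foraging dives with
inter-foraging-dive gaps ≤ threshold, spanning first dive start to last
dive end; the record's complement forms non-foraging bouts.  An optional
transition period (0/15/30/60 min, default 0) is excluded from the start
of non-foraging bouts that follow a foraging bout — the record's leading
segment is not a recovery period, so nothing is excluded there.  Bouts
are retained only if strictly longer than one hour; bouts truncated by
the record boundary follow the same rule (a truncated bout that already
exceeds an hour is kept).  Bout speed integrates speed over samples
deeper than 2 m and divides by the full bout duration (surface time
deliberately dilutes the mean); angular velocity sums wrapped heading
steps over the duration.

## Statistics

Scaling fits regress log₁₀(outcome) on log₁₀(M_b) by REML with
species-level random effects.  The primary structure is a correlated
random intercept + slope; on non-convergence (checked as optimizer
convergence plus finite estimates, retried with a second optimizer) the
model falls back to uncorrelated effects, then intercept-only, logging
each step.  Exactly collinear data (zero residual variance) short-
circuits to the OLS line with a degenerate CI, since REML has no
variance to apportion.  The marginal R² follows Nakagawa,
var_f / (var_f + var_r + var_e), with the random-effect variance
evaluated at the design's mean covariate; only the marginal (fixed-
effects) R² is reported.  The slope CI is Wald, ±1.96 SE.

The feeding-status comparison is fixed-effects OLS on log₁₀ values:
`log₁₀FMR ~ log₁₀M × status` against the additive model for the
interaction (slope difference), and the additive against mass-only for
the status main effect (intercept difference), α = 0.05.  Running it
with species random effects is a defensible alternative; fixed effects
keep the test exact and calibrated (type-I error 3–7% in 1000-replicate
null simulations).

Wilcoxon rank-sum comparisons use an exact two-sided p-value when
min(n) ≤ 8 with no ties, from a dynamic-programming enumeration of the
rank-sum null distribution (validated against brute-force enumeration
for every size pair up to 8 vs 8); otherwise a tie-corrected normal
approximation without continuity correction, so identical samples give
z = 0, p = 1.

## The synthetic generator

The generator produces the statistical structure the chain assumes, not
whale biomechanics.  A record alternates foraging bouts (9–20 deep
dives, species-dependent, with ≥ 1 Poisson-distributed lunges each,
separated by Gaussian surface intervals, e.g. 90 ± 15 s for the blue
preset) with non-foraging gaps (≥ 90 min, shifted-exponential) of slow
shallow dives and sparser breathing (0.75 × the surface breath rate).
Surface intervals are filled with V-shaped single-breath surfacings
(~4–6 s) at the species breath rate, a quarter of breath groups becoming
10–60-s multi-breath surfacings with ≥ 5.5-s spacing.  Depth carries
0.05-m i.i.d. sensor noise and is clipped to [−0.5 m, mean + 4 SD of
dive depth].

Acceleration is modelled as band-limited Gaussian motion noise (Gaussian
kernel, σ = 0.8 s, rescaled to the configured SD, 0.05 g by default):
at 10 Hz after anti-alias decimation, real tag baselines are dominated
by slow body and swell motion, and a band-limited baseline is what makes
a 5×-noise transient detectable at all — against white noise of the same
SD the differenced transient would sit ~2 SD above the differenced-noise
floor, which no windowed statistic can recover at 95% fidelity.  Each
breath injects a 0.5-s half-sine heave (default 0.25 g = 5 × noise SD)
along the gravity axis plus a bounded broadband burst (uniform, 0.6 ×
amplitude) on all axes under the same envelope, mimicking the jerky,
spectrally rich signature of a real blow.  Heading follows a bounded
random walk with larger steps inside foraging bouts; speed is elevated
during foraging dives with bursts at lunges — together these make the
speed/turning contrasts between bout types real rather than assumed.

What the generator does **not** emulate: sea-state-dependent splash
noise, tag slip and re-orientation, mixed-rate channel ingestion,
pressure-sensor temperature drift, lunges' own acceleration transients,
or any prey-field structure.  Passing tests therefore demonstrate that
the chain recovers what it assumes — breaths co-occur with surfacings,
surface intervals are Gaussian-plus-tail, bouts are separated by gaps
beyond the threshold — not that the detector thresholds transfer to real
tags; on real data the QC flag and the config surface exist precisely
because those constants would need revisiting.

Ground truth per record: breath times (strictly increasing, ≥ 5 s
apart), lunge times, bout intervals, the morphometric profile drawn
uniformly from the species length range, and the expected daily FMR at
mean physiology (breath rate × 86 400 × 0.6·V_C·0.35·0.2095 × 20.08),
which the Monte Carlo median should and does match within Monte Carlo
error.

## Numerical choices and degenerate inputs

* Zero-SD configurations are honoured exactly (truncated normals
  degenerate to their clipped means), which is what makes the energy
  arithmetic testable to machine precision.
* Zero breaths give an exactly zero estimate with zero quantiles.
* Entropy windows are clipped at record edges; a constant record yields
  an all-zero trace rather than an error.
* Decimation uses polyphase FIR resampling with line padding (constants
  survive; no edge ringing); angles are unwrapped before filtering and
  re-wrapped, so the ±π seam cannot ring.
* Heading steps are wrapped to [−π, π] before summing, so turning counts
  the short way around the circle.
* All generators and estimators are deterministic under a fixed seed;
  the CLI pipeline reproduces byte-identical CSVs.

## Problem sizes

Test and acceptance runs use six-hour single-deployment records
(216 000 samples), 10⁴ intervals for threshold recovery, 10⁵ draws for
distribution moments, 100 replicate populations (3 species × 15 whales)
for CI coverage and 1000 replicates for ANOVA calibration — sizes at
which every Monte Carlo check resolves its tolerance with a comfortable
margin while the whole suite runs in about a minute.

## Known limitations

* The breath-detection operating point (window, bins, prominence) is
  tuned to the generator's signal model by construction; real tags need
  their own verification, which the QC flag supports but does not
  replace.
* Daily FMR extrapolates the tagged period's breath rate; diel behaviour
  outside the deployment window is invisible.
* The deployment-level estimate uses the deployment-average breath rate
  rather than a bout-weighted rate; with long records dominated by one
  behavioural state the two can differ.
* Allometric coefficients ship as editable defaults; absolute FMR values
  on real animals inherit their uncertainty directly.
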