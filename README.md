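# rorqualfmr

Respiration-based field metabolic rate (FMR) estimation for lunge-feeding
baleen whales, from biologging-tag time series to allometric scaling
statistics.

Free-ranging whales cannot be put in a respirometer, but suction-cup tags
record every surfacing and every breath.  Because cetaceans exchange a
large, reasonably well-characterised volume of gas per breath, counting
breaths is a practical route to daily energy expenditure — provided the
breaths can be detected reliably, behaviour can be split into foraging
and non-foraging time, and the physiological uncertainty is propagated
honestly.  This package implements that full chain for researchers in
biologging ecophysiology: a tested, reusable pipeline plus a synthetic
tag-data generator with exact ground truth, so every stage is verifiable
without access to proprietary tag deployments.

## The model

Daily energy expenditure of a deployment or bout follows from its breath
count:

    FMR = N_breaths · VO₂_breath · 20.08 kJ/L O₂
    VO₂_breath = V_T · E_O₂ · 0.2095

where V_T is tidal volume, E_O₂ the oxygen extraction fraction and
0.2095 the O₂ fraction of air.  A Monte Carlo model draws
V_T ~ N(0.6·V_C, 0.09·V_C) truncated to (0, V_C] and
E_O₂ ~ N(0.35, 0.03) truncated to [0.24, 0.45], one draw per iteration
applied to all breaths; the reported FMR is the median of the iteration
distribution.  Vital capacity V_C is 85% of total lung capacity, which
comes from body mass by the allometric law TLC = a·M_b^b, and mass from
photogrammetric length by M_b = a'·TL^b'.

Upstream of the model:

* **Breath detection** — one breath per brief surfacing (< 10 s within
  1 m of the surface, roll within 45° of the surface plane), and for
  longer surfacings, peaks in the sliding-window Shannon entropy of the
  differenced triaxial acceleration, which mark the broadband transient
  of each blow.
* **Bout segmentation** — surface intervals after lunge-bearing dives
  are fit with an iteratively trimmed Gaussian; μ + 3σ of the bulk is
  the species threshold separating within-bout breathing pauses from
  genuine breaks in foraging.  Bouts over one hour are retained.
* **Scaling statistics** — log₁₀FMR against log₁₀M_b with species-level
  mixed-effects models (random intercept and slope), Nakagawa marginal
  R², a two-way ANOVA on mass × feeding status, and exact small-sample
  Wilcoxon rank-sum comparisons.

## Worked example

```sh
python examples/02_detect_breaths.py
```

```
230 breaths detected vs 230 true (230 matched within 1 s)
pathways: 134 single-breath surfacings, 96 entropy peaks in 41 long surfacings
deployment respiration rate: 0.64 breaths/min
QC flag raised: False
```

Every true breath of a six-hour synthetic humpback record is recovered
within one second: brief surfacings through the roll-gated depth-minimum
rule, multi-breath logging surfacings through entropy peaks.  The rate
(0.64 breaths/min) is what the metabolic model converts to energy:

```sh
python examples/04_estimate_fmr.py
```

```
24-m blue whale: 88.7 t, TLC 4813 L, VC 4091 L
690 breaths in 12 h -> median FMR 4.961e+06 kJ/day (95% band 3.38e+06-6.78e+06)
mass-specific: 55.9 kJ/kg/day
V_T pinned high (0.95 VC): median 7.898e+06 kJ/day
V_T pinned low (0.15 VC): median 1.247e+06 kJ/day
```

The 95% band reflects the tidal-volume and extraction uncertainty; the
pinned-V_T scenarios bracket the dominant physiological unknown.  The
other examples cover record simulation (`01`), bout segmentation (`03`)
and the scaling statistics (`05`).

The same pipeline is scriptable from the shell:

```sh
rorqualfmr simulate --species blue --duration 21600 --seed 1 --out dep/
rorqualfmr detect-breaths --channels dep/channels.csv --meta dep/meta.json --out dep/breaths.csv
rorqualfmr segment-bouts --channels dep/channels.csv --meta dep/meta.json \
    --lunges dep/lunges.csv --breaths dep/breaths.csv --out dep/bouts.csv
rorqualfmr estimate-fmr --bouts dep/bouts.csv --breaths dep/breaths.csv \
    --meta dep/meta.json --out dep/fmr.csv
rorqualfmr fit-scaling --fmr dep/fmr.csv ... --out scaling.csv
```

Stages communicate through CSV tables; `--config` accepts a YAML file
overriding any constant (thresholds, windows, physiological parameters,
allometric coefficients).

## Layout

```
src/rorqualfmr/
  synthetic.py    tag-record generator with ground truth
  tag_io.py       data model, CSV I/O, decimation, first-hour trim
  respiration.py  surfacing detection and both breath pathways
  bouts.py        dives, Gaussian threshold, bout segmentation, kinematics
  allometry.py    length → mass → lung-volume chain
  fmr.py          Monte Carlo FMR model and sensitivity scenarios
  scaling.py      mixed-effects scaling, ANOVA, Wilcoxon, metabolic scope
  config.py       YAML-loadable constants
  cli.py          thin click CLI over the library
docs/methods.md   model assumptions, parameters, limitations
examples/         one narrative script per capability
```
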