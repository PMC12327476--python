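"""Synthetic tag-deployment generator with known ground truth.

The generator emulates the statistical structure the analysis chain
assumes, not whale biomechanics: a deployment alternates foraging bouts
(chains of deep lunge-bearing dives separated by short Gaussian surface
intervals) with long non-foraging gaps (slow shallow dives, sparser
breathing).  While at the surface the whale breathes once per brief
(< 10 s) surfacing, or several times during an occasional long
(10-60 s) logging surfacing; each breath leaves a short transient on the
acceleration channels (a half-sine heave along gravity plus a broadband
burst), which is what the entropy-based detector keys on.  Acceleration
baseline noise is band-limited (smoothed Gaussian), as tag records are
after anti-alias decimation; depth carries i.i.d. sensor noise.

Every generated record comes with its ground truth — breath times, lunge
times, bout intervals, the morphometric profile and the expected daily
FMR implied by the mean physiological parameters — so detection,
segmentation and estimation can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .allometry import AllometricCoefficients, MorphometricProfile, build_profile
from .tag_io import AnnotationTable, TagDeployment, lunge_annotations


@dataclass
class SpeciesParams:
    """Behavioural and allometric parameters of one simulated species."""

    name: str
    length_range: tuple[float, float]  # m
    mass_coeff_a: float
    mass_coeff_b: float
    dive_depth: tuple[float, float]  # m (mean, sd)
    foraging_dive_duration: tuple[float, float]  # s (mean, sd)
    lunges_per_dive_extra: float  # Poisson mean beyond the guaranteed 1
    within_bout_surface_interval: tuple[float, float]  # s (mu_s, sigma_s)
    between_bout_gap: tuple[float, float]  # s (minimum, exponential scale)
    breath_rate_surface: float  # breaths/min while at the surface, foraging
    resting_dive_depth: tuple[float, float]  # m
    resting_dive_duration: tuple[float, float]  # s
    dives_per_bout: tuple[int, int]  # inclusive range
    rest_breath_rate_factor: float = 0.75  # surface breath-rate multiplier at rest

    def validate(self) -> None:
        if not self.length_range[0] < self.length_range[1]:
            raise ValueError("length_range must satisfy min < max")
        for nm in ("dive_depth", "foraging_dive_duration", "within_bout_surface_interval", "resting_dive_depth", "resting_dive_duration"):
            if getattr(self, nm)[1] < 0:
                raise ValueError(f"{nm} sd must be >= 0")
        mu_s, sigma_s = self.within_bout_surface_interval
        if self.between_bout_gap[0] <= mu_s + 3 * sigma_s:
            raise ValueError(
                "between_bout_gap minimum must exceed mu_s + 3 sigma_s so that "
                "ground-truth bouts are recoverable"
            )
        if self.breath_rate_surface <= 0:
            raise ValueError("breath_rate_surface must be > 0")

    @property
    def max_dive_depth(self) -> float:
        """Depth cap applied to the generated record (mean + 4 sd)."""
        return self.dive_depth[0] + 4 * self.dive_depth[1]


#: Species presets.  Values are round numbers representative of published
#: foraging behaviour for each species, scaled so that every foraging
#: bout comfortably exceeds the one-hour retention rule.
SPECIES_PRESETS: dict[str, SpeciesParams] = {
    "blue": SpeciesParams(
        name="blue",
        length_range=(21.0, 26.0),
        mass_coeff_a=2.899,
        mass_coeff_b=3.25,
        dive_depth=(120.0, 20.0),
        foraging_dive_duration=(330.0, 30.0),
        lunges_per_dive_extra=2.5,
        within_bout_surface_interval=(90.0, 15.0),
        between_bout_gap=(5400.0, 1800.0),
        breath_rate_surface=4.0,
        resting_dive_depth=(15.0, 3.0),
        resting_dive_duration=(420.0, 40.0),
        dives_per_bout=(9, 13),
    ),
    "humpback": SpeciesParams(
        name="humpback",
        length_range=(11.0, 15.0),
        mass_coeff_a=15.5,
        mass_coeff_b=2.95,
        dive_depth=(80.0, 15.0),
        foraging_dive_duration=(270.0, 25.0),
        lunges_per_dive_extra=3.0,
        within_bout_surface_interval=(75.0, 12.0),
        between_bout_gap=(5400.0, 1800.0),
        breath_rate_surface=4.0,
        resting_dive_depth=(12.0, 3.0),
        resting_dive_duration=(360.0, 40.0),
        dives_per_bout=(11, 15),
    ),
    "minke": SpeciesParams(
        name="minke",
        length_range=(5.0, 9.0),
        mass_coeff_a=12.0,
        mass_coeff_b=3.05,
        dive_depth=(60.0, 12.0),
        foraging_dive_duration=(180.0, 20.0),
        lunges_per_dive_extra=2.0,
        within_bout_surface_interval=(60.0, 10.0),
        between_bout_gap=(5400.0, 1500.0),
        breath_rate_surface=5.0,
        resting_dive_depth=(10.0, 2.0),
        resting_dive_duration=(300.0, 30.0),
        dives_per_bout=(16, 20),
    ),
}


@dataclass
class SimConfig:
    """Record-level simulation settings."""

    seed: int = 0
    fs: float = 10.0  # Hz
    duration: float = 21_600.0  # s
    breath_pulse_amplitude: float = 0.25  # acceleration units (g)
    noise_sd: float = 0.05  # acceleration units (g)
    include_multibreath_surfacings: bool = True
    depth_noise_sd: float = 0.05  # m
    multibreath_fraction: float = 0.25  # P(a surface group becomes a long surfacing)

    def validate(self) -> None:
        if self.fs <= 0 or self.duration <= 0:
            raise ValueError("fs and duration must be > 0")
        if self.noise_sd < 0 or self.depth_noise_sd < 0:
            raise ValueError("noise sds must be >= 0")


@dataclass
class GroundTruth:
    """Everything the analysis chain should recover from one record."""

    breath_times: np.ndarray
    lunge_times: np.ndarray
    bout_intervals: list[tuple[float, float, str]]  # (start, end, type)
    true_profile: MorphometricProfile
    true_expected_daily_fmr: float  # kJ/day at mean V_T and E_O2

    def to_annotations(self) -> AnnotationTable:
        return lunge_annotations(self.lunge_times)


# ---------------------------------------------------------------------------
# deployment generator internals

_BREATH_PULSE_S = 0.5  # half-sine transient length
_SURFACE_BASE_M = 1.6  # inter-event depth: below the 1-m surfacing line,
#                        above the 2-m dive line
_SHORT_HALF_S = 3.0  # half-width of the V-shaped short surfacing


class _Plan:
    """Accumulates the event plan before rasterisation."""

    def __init__(self) -> None:
        self.waypoints: list[tuple[float, float]] = [(0.0, _SURFACE_BASE_M)]
        self.breaths: list[float] = []
        self.lunges: list[float] = []
        self.bouts: list[tuple[float, float, str]] = []
        self.dives: list[tuple[float, float, str]] = []  # (t0, t1, kind)


def _fill_surface_interval(plan: _Plan, t0: float, t1: float, rate_per_min: float, sim: SimConfig, rng) -> None:
    """Plan breaths and surfacings across a surface interval [t0, t1]."""
    L = t1 - t0
    if L < 2 * _SHORT_HALF_S + 1.0:
        return
    dt_b = 60.0 / rate_per_min
    n_b = max(1, int(L // dt_b))
    spacing = L / n_b
    times = t0 + (np.arange(n_b) + 0.5) * spacing
    times += rng.uniform(-0.4, 0.4, size=n_b)
    i = 0
    while i < n_b:
        remaining = n_b - i
        k_span = max(1, int(56.0 // spacing) + 1)  # keep long surfacings < 60 s
        k_max = min(6, remaining, k_span)
        if (
            sim.include_multibreath_surfacings
            and k_max >= 2
            and spacing >= 5.5
            and rng.random() < sim.multibreath_fraction
        ):
            k = int(rng.integers(2, k_max + 1))
            ts, te = times[i] - 2.0, times[i + k - 1] + 2.0
            plan.waypoints += [
                (ts - 1.5, _SURFACE_BASE_M),
                (ts, 0.45),
                (te, 0.45),
                (te + 1.5, _SURFACE_BASE_M),
            ]
            plan.breaths.extend(times[i : i + k])
            i += k
        else:
            tb = times[i]
            plan.waypoints += [
                (tb - _SHORT_HALF_S, _SURFACE_BASE_M),
                (tb, 0.12),
                (tb + _SHORT_HALF_S, _SURFACE_BASE_M),
            ]
            plan.breaths.append(tb)
            i += 1


def _add_dive(plan: _Plan, t0: float, dur: float, depth: float, kind: str, lunges_extra: float, rng) -> None:
    plan.waypoints += [
        (t0, _SURFACE_BASE_M),
        (t0 + 0.2 * dur, depth),
        (t0 + 0.8 * dur, depth),
        (t0 + dur, _SURFACE_BASE_M),
    ]
    plan.dives.append((t0, t0 + dur, kind))
    if kind == "foraging":
        k = 1 + int(rng.poisson(lunges_extra))
        lt = np.sort(rng.uniform(t0 + 0.25 * dur, t0 + 0.75 * dur, size=k))
        plan.lunges.extend(lt)


def _truncnorm_pos(mean: float, sd: float, rng, lo: float = 1.0) -> float:
    if sd == 0:
        return max(mean, lo)
    a = (lo - mean) / sd
    return float(stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, random_state=rng))


def simulate_deployment(species: SpeciesParams, sim: SimConfig) -> tuple[TagDeployment, GroundTruth]:
    """Generate one tag deployment and its ground truth.

    The record alternates foraging bouts and resting gaps until the
    configured duration is reached; construction is fully determined by
    ``sim.seed``.  Raises if the duration cannot hold one dive cycle.
    """
    species.validate()
    sim.validate()
    fdd_mean, fdd_sd = species.foraging_dive_duration
    mu_s, sigma_s = species.within_bout_surface_interval
    if sim.duration < fdd_mean + mu_s + 120.0:
        raise ValueError(
            f"duration {sim.duration:.0f} s too short for one dive cycle "
            f"(~{fdd_mean + mu_s + 120.0:.0f} s)"
        )
    rng = np.random.default_rng(sim.seed)
    plan = _Plan()
    t = 60.0  # brief settling period at the surface before the first dive
    exhausted = False
    while not exhausted:
        # ---- foraging bout: a chain of lunge-bearing dives
        n_dives = int(rng.integers(species.dives_per_bout[0], species.dives_per_bout[1] + 1))
        bout_start = None
        bout_end = None
        for i in range(n_dives):
            dur = _truncnorm_pos(fdd_mean, fdd_sd, rng, lo=60.0)
            if t + dur > sim.duration - 1.0:
                exhausted = True
                break
            depth = float(np.clip(rng.normal(*species.dive_depth), 5.0, species.max_dive_depth - 1.0))
            if bout_start is None:
                bout_start = t
            _add_dive(plan, t, dur, depth, "foraging", species.lunges_per_dive_extra, rng)
            t += dur
            bout_end = t
            if i < n_dives - 1:
                si = _truncnorm_pos(mu_s, sigma_s, rng, lo=2 * _SHORT_HALF_S + 2.0)
                if t + si > sim.duration - 1.0:
                    exhausted = True
                    break
                _fill_surface_interval(plan, t, t + si, species.breath_rate_surface, sim, rng)
                t += si
        if bout_start is not None and bout_end is not None:
            plan.bouts.append((bout_start, bout_end, "foraging"))
        if exhausted:
            break
        # ---- non-foraging gap: slow shallow dives, sparser breathing
        gap = species.between_bout_gap[0] + rng.exponential(species.between_bout_gap[1])
        gap_end = min(t + gap, sim.duration)
        nf_start = t
        rest_rate = species.rest_breath_rate_factor * species.breath_rate_surface
        while True:
            rsi = _truncnorm_pos(1.3 * mu_s, sigma_s, rng, lo=2 * _SHORT_HALF_S + 2.0)
            rdur = _truncnorm_pos(*species.resting_dive_duration, rng, lo=60.0)
            if t + rsi + rdur > gap_end:
                break
            _fill_surface_interval(plan, t, t + rsi, rest_rate, sim, rng)
            t += rsi
            rdepth = float(np.clip(rng.normal(*species.resting_dive_depth), 3.0, species.max_dive_depth - 1.0))
            _add_dive(plan, t, rdur, rdepth, "resting", 0.0, rng)
            t += rdur
        plan.bouts.append((nf_start, gap_end, "non-foraging"))
        t = gap_end
        if sim.duration - t < fdd_mean + 60.0:
            break

    # ---- rasterise ---------------------------------------------------------
    n = int(round(sim.duration * sim.fs))
    tgrid = np.arange(n) / sim.fs
    wp = sorted(p for p in plan.waypoints if 0.0 <= p[0] <= sim.duration)
    wp_t = np.array([p[0] for p in wp])
    wp_d = np.array([p[1] for p in wp])
    depth = np.interp(tgrid, wp_t, wp_d, left=_SURFACE_BASE_M, right=_SURFACE_BASE_M)
    depth = depth + rng.normal(0.0, sim.depth_noise_sd, n)
    depth = np.clip(depth, -0.5, species.max_dive_depth)

    # band-limited acceleration noise: tag acceleration at 10 Hz is
    # dominated by slow body/swell motion (sensor noise is filtered out by
    # the anti-alias decimation), so the baseline is smooth relative to
    # the fast breath transient
    from scipy.ndimage import gaussian_filter1d

    smooth_sigma = 8.0  # samples (~0.8 s), i.e. ~0.2 Hz motion bandwidth
    accel = gaussian_filter1d(rng.standard_normal((3, n)), smooth_sigma, axis=1)
    accel *= sim.noise_sd * np.sqrt(2 * np.sqrt(np.pi) * smooth_sigma)
    accel[2] -= 1.0  # gravity along z, units of g
    # breath transient: a half-sine heave along the gravity axis plus a
    # broadband burst on all axes under the same envelope (fast airflow
    # and thoracic movement shake the tag at many frequencies, which is
    # what makes the differenced signal entropy-rich)
    pulse_len = max(2, int(round(_BREATH_PULSE_S * sim.fs)))
    pulse = np.sin(np.pi * (np.arange(pulse_len) + 0.5) / pulse_len)
    breath_times = np.sort(np.asarray(plan.breaths))
    for tb in breath_times:
        j = int(round((tb - _BREATH_PULSE_S / 2) * sim.fs))
        j = max(0, min(j, n - pulse_len))
        accel[2, j : j + pulse_len] -= sim.breath_pulse_amplitude * pulse
        accel[:, j : j + pulse_len] += (
            0.6 * sim.breath_pulse_amplitude * pulse * rng.uniform(-1.0, 1.0, (3, pulse_len))
        )

    roll = rng.normal(0.0, 0.05, n)
    pitch = -np.arctan2(np.gradient(depth, 1.0 / sim.fs), 2.0) * 0.8 + rng.normal(0.0, 0.02, n)

    step_sd = np.full(n, 0.008)
    for b0, b1, kind in plan.bouts:
        if kind == "foraging":
            step_sd[(tgrid >= b0) & (tgrid < b1)] = 0.03
    heading = np.cumsum(rng.normal(0.0, 1.0, n) * step_sd)
    heading = np.mod(heading + np.pi, 2 * np.pi) - np.pi

    speed = np.full(n, 0.3)
    for d0, d1, kind in plan.dives:
        m = (tgrid >= d0) & (tgrid < d1)
        speed[m] = 1.8 if kind == "foraging" else 1.0
    burst_len = int(8 * sim.fs)
    burst = 1.7 * np.sin(np.pi * (np.arange(burst_len) + 0.5) / burst_len)
    for tl in plan.lunges:
        j = int(round((tl - 4.0) * sim.fs))
        j = max(0, min(j, n - burst_len))
        speed[j : j + burst_len] += burst
    speed = np.clip(speed + rng.normal(0.0, 0.05, n), 0.0, None)

    TL = float(rng.uniform(*species.length_range))
    coeffs = AllometricCoefficients(mass_a=species.mass_coeff_a, mass_b=species.mass_coeff_b)
    profile = build_profile(species.name, TL, coeffs)
    breath_rate = breath_times.size / sim.duration  # breaths per second
    mean_vo2 = 0.6 * profile.VC * 0.35 * 0.2095
    expected_fmr = breath_rate * 86_400.0 * mean_vo2 * 20.08

    dep = TagDeployment(
        id=f"{species.name}-{sim.seed:04d}",
        species=species.name,
        fs=sim.fs,
        time=tgrid,
        depth=depth,
        pitch=pitch,
        roll=roll,
        heading=heading,
        speed=speed,
        accel=accel,
        total_length=TL,
    )
    truth = GroundTruth(
        breath_times=breath_times,
        lunge_times=np.sort(np.asarray(plan.lunges)),
        bout_intervals=plan.bouts,
        true_profile=profile,
        true_expected_daily_fmr=expected_fmr,
    )
    return dep, truth


def simulate_surface_intervals(
    n: int,
    mu_s: float,
    sigma_s: float,
    contamination: float = 0.0,
    gap_scale: float = 600.0,
    seed: int = 0,
) -> np.ndarray:
    """Draw post-foraging-dive surface intervals with a long-gap tail.

    ``(1 - contamination) * n`` values come from a Gaussian(mu_s, sigma_s)
    truncated at > 0; the remaining ``floor(contamination * n)`` are long
    gaps of at least ``gap_scale`` seconds (shifted exponential).  Order
    is shuffled.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if mu_s <= 0:
        raise ValueError("mu_s must be > 0")
    if sigma_s < 0:
        raise ValueError("sigma_s must be >= 0")
    if not (0 <= contamination < 1):
        raise ValueError("contamination must be in [0, 1)")
    rng = np.random.default_rng(seed)
    n_gap = int(np.floor(contamination * n))
    n_gauss = n - n_gap
    if sigma_s == 0:
        bulk = np.full(n_gauss, mu_s)
    else:
        a = (0.0 - mu_s) / sigma_s
        bulk = stats.truncnorm.rvs(a, np.inf, loc=mu_s, scale=sigma_s, size=n_gauss, random_state=rng)
    gaps = gap_scale * (1.0 + rng.exponential(1.0, size=n_gap))
    out = np.concatenate([bulk, gaps])
    rng.shuffle(out)
    return out


def simulate_population(
    species_list,
    n_per_species: int,
    scaling_exponent: float | None,
    intercept: float = 100.0,
    noise_sd_log10: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a multi-species population with a known FMR scaling law.

    Per whale: total length uniform over the species range, mass from the
    species power law, FMR ``intercept * M**b`` with multiplicative
    lognormal noise of SD ``noise_sd_log10`` on the log10 scale.  Returns
    a tidy scaling dataset (whale_id, species, mass_kg, outcome,
    outcome_kind, feeding_status).
    """
    if scaling_exponent is None:
        raise ValueError("scaling_exponent must be set")
    if n_per_species < 2:
        raise ValueError("n_per_species must be >= 2")
    rng = np.random.default_rng(seed)
    rows = []
    for sp in species_list:
        params = SPECIES_PRESETS[sp] if isinstance(sp, str) else sp
        for i in range(n_per_species):
            TL = rng.uniform(*params.length_range)
            M = params.mass_coeff_a * TL**params.mass_coeff_b
            fmr = intercept * M**scaling_exponent * 10.0 ** rng.normal(0.0, noise_sd_log10)
            rows.append(
                {
                    "whale_id": f"{params.name}-{i:03d}",
                    "species": params.name,
                    "mass_kg": M,
                    "outcome": fmr,
                    "outcome_kind": "FMR",
                    "feeding_status": "combined",
                }
            )
    return pd.DataFrame(rows)
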