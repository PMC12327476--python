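"""Foraging-bout segmentation and per-bout kinematic summaries.

A dive is a maximal excursion below a shallow depth threshold; a dive is
a *foraging* dive if it contains at least one lunge annotation.  The
surface intervals that follow foraging dives have a Gaussian bulk (the
breathing pause between consecutive dives of one feeding bout) plus a
long-interval tail produced by genuine breaks in foraging.  An
iteratively trimmed Gaussian fit to those intervals yields a species
threshold mu + 3 sigma: gaps between foraging dives at or below it chain
dives into one foraging bout, larger gaps split bouts.  Time not inside a
foraging bout forms non-foraging bouts, optionally with a transition
period excluded from their start.  Only bouts longer than one hour are
retained for analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)


@dataclass
class Dive:
    start: float
    end: float
    max_depth: float
    lunge_count: int = 0
    post_dive_surface_interval: float | None = None  # to next dive start

    @property
    def duration(self) -> float:
        return self.end - self.start

    @property
    def foraging(self) -> bool:
        return self.lunge_count >= 1


@dataclass
class BoutThreshold:
    """Gaussian surface-interval threshold for one species group."""

    species_group: str
    mu: float
    sigma: float
    threshold: float  # mu + 3 sigma
    n_intervals_used: int
    warning: str | None = None


@dataclass
class Bout:
    type: str  # "foraging" | "non-foraging"
    start: float
    end: float
    n_breaths: int | None = None
    mean_speed: float | None = None
    angular_velocity: float | None = None
    transition_excluded: float = 0.0  # minutes excluded from the bout start
    retained: bool = True

    @property
    def duration(self) -> float:
        return self.end - self.start


def find_dives(
    depth: np.ndarray,
    fs: float,
    dive_threshold_m: float = 2.0,
    time0: float = 0.0,
    lunge_times=None,
) -> list[Dive]:
    """Maximal excursions below ``dive_threshold_m``.

    Excursions separated by fewer than 2 samples are merged.  Lunge
    annotations are assigned to the containing dive, and the post-dive
    surface interval runs from each dive's end to the next dive's start.
    """
    depth = np.asarray(depth, dtype=float)
    if depth.size == 0:
        return []
    under = depth > dive_threshold_m
    edges = np.flatnonzero(np.diff(under.astype(np.int8)))
    starts = np.r_[0, edges + 1]
    ends = np.r_[edges + 1, depth.size]
    runs = [(i0, i1) for i0, i1 in zip(starts, ends) if under[i0]]
    # merge runs separated by < 2 samples of surface
    merged: list[list[int]] = []
    for i0, i1 in runs:
        if merged and i0 - merged[-1][1] < 2:
            merged[-1][1] = i1
        else:
            merged.append([i0, i1])
    dives = [
        Dive(
            start=time0 + i0 / fs,
            end=time0 + i1 / fs,
            max_depth=float(depth[i0:i1].max()),
        )
        for i0, i1 in merged
    ]
    if lunge_times is not None:
        lt = np.asarray(lunge_times, dtype=float)
        for d in dives:
            d.lunge_count = int(np.sum((lt >= d.start) & (lt < d.end)))
    for d, nxt in zip(dives, dives[1:]):
        d.post_dive_surface_interval = nxt.start - d.end
    return dives


def fit_bout_threshold(
    post_foraging_intervals,
    species_group: str = "",
    tol: float = 1e-6,
    max_iter: int = 50,
) -> BoutThreshold:
    """Iteratively trimmed Gaussian fit of post-foraging surface intervals.

    Maximum-likelihood mean/SD are fit to the intervals, intervals beyond
    mu + 3 sigma are discarded, and the fit repeats until mu and sigma
    change by less than ``tol`` (or ``max_iter`` passes).  The trimming
    isolates the Gaussian bulk from the long-gap contaminant so that the
    returned threshold mu + 3 sigma describes within-bout behaviour.
    """
    x = np.asarray(post_foraging_intervals, dtype=float)
    if x.size < 10:
        raise ValueError(f"need >= 10 intervals to fit a bout threshold, got {x.size}")
    full = x
    mu, sigma = float(np.mean(x)), float(np.std(x))
    for _ in range(max_iter):
        keep = x[x <= mu + 3 * sigma]
        if keep.size < 2:
            break
        mu_new, sigma_new = float(np.mean(keep)), float(np.std(keep))
        if sigma_new == 0.0 and keep.size < full.size:
            # trimming collapsed the distribution; fall back to the
            # untrimmed fit so the threshold stays data-driven
            mu0, s0 = float(np.mean(full)), float(np.std(full))
            return BoutThreshold(
                species_group=species_group,
                mu=mu0,
                sigma=s0,
                threshold=mu0 + 3 * s0,
                n_intervals_used=full.size,
                warning="sigma-collapse",
            )
        converged = abs(mu_new - mu) < tol and abs(sigma_new - sigma) < tol
        mu, sigma, x = mu_new, sigma_new, keep
        if converged:
            break
    return BoutThreshold(
        species_group=species_group,
        mu=mu,
        sigma=sigma,
        threshold=mu + 3 * sigma,
        n_intervals_used=int(x.size),
    )


def segment_bouts(
    dives: list[Dive],
    threshold: float,
    min_bout_s: float = 3600.0,
    transition_min: float = 0.0,
    record_span: tuple[float, float] | None = None,
) -> list[Bout]:
    """Chain foraging dives into bouts and tile the rest as non-foraging.

    Foraging bouts are maximal chains of foraging dives whose
    inter-foraging-dive gaps are at most ``threshold`` seconds, spanning
    first dive start to last dive end.  The remaining record (within
    ``record_span``, default first dive start to last dive end) forms
    non-foraging bouts; the first ``transition_min`` minutes following a
    foraging bout are excluded from the start of the next non-foraging
    bout.  All bouts are returned; those not longer than ``min_bout_s``
    carry ``retained=False``.
    """
    if transition_min not in (0, 15, 30, 60):
        raise ValueError("transition_min must be one of {0, 15, 30, 60}")
    dives = sorted(dives, key=lambda d: d.start)
    for a, b in zip(dives, dives[1:]):
        if b.start < a.end:
            raise ValueError("overlapping dives")
    foraging = [d for d in dives if d.foraging]
    bouts: list[Bout] = []
    # chain foraging dives
    chains: list[list[Dive]] = []
    for d in foraging:
        if chains and d.start - chains[-1][-1].end <= threshold:
            chains[-1].append(d)
        else:
            chains.append([d])
    fbouts = [Bout(type="foraging", start=c[0].start, end=c[-1].end) for c in chains]
    if record_span is None:
        if not dives:
            return []
        record_span = (dives[0].start, dives[-1].end)
    t0, t1 = record_span
    # complement -> non-foraging bouts; transition excluded only after a
    # preceding foraging bout (the record start is not a recovery period)
    gaps: list[tuple[float, float, bool]] = []
    prev_end = t0
    prev_was_foraging = False
    for fb in fbouts:
        if fb.start > prev_end:
            gaps.append((prev_end, fb.start, prev_was_foraging))
        prev_end = max(prev_end, fb.end)
        prev_was_foraging = True
    if t1 > prev_end:
        gaps.append((prev_end, t1, prev_was_foraging))
    nfbouts = []
    for g0, g1, after_foraging in gaps:
        excl = transition_min * 60.0 if after_foraging else 0.0
        start = g0 + excl
        if start >= g1:
            continue
        nfbouts.append(
            Bout(
                type="non-foraging",
                start=start,
                end=g1,
                transition_excluded=excl / 60.0,
            )
        )
    bouts = sorted(fbouts + nfbouts, key=lambda b: b.start)
    for b in bouts:
        b.retained = b.duration > min_bout_s
    return bouts


def assign_breaths(bouts: list[Bout], breath_times) -> None:
    """Count breaths into bouts by time containment (in place)."""
    bt = np.asarray(breath_times, dtype=float)
    for b in bouts:
        b.n_breaths = int(np.sum((bt >= b.start) & (bt < b.end)))


def bout_speed(
    bout: Bout, time: np.ndarray, depth: np.ndarray, speed: np.ndarray, fs: float
) -> float:
    """Mean bout speed: distance accumulated at depth > 2 m over duration.

    Speed is integrated only over samples deeper than 2 m (the speed
    sensor is unreliable in surface splash), but the divisor is the full
    bout duration, so surface time dilutes the mean by convention.
    """
    in_bout = (time >= bout.start) & (time < bout.end)
    if not np.any(in_bout):
        raise ValueError("no samples within bout")
    active = in_bout & (depth > 2.0)
    distance = float(np.sum(speed[active])) / fs
    return distance / bout.duration


def bout_angular_velocity(
    bout: Bout, time: np.ndarray, heading: np.ndarray, fs: float
) -> float:
    """Radians of heading swept within the bout divided by its duration.

    Heading steps are wrapped to [-pi, pi] so a crossing of the +/-pi
    seam counts its short way around.
    """
    in_bout = (time >= bout.start) & (time < bout.end)
    h = heading[in_bout]
    if h.size < 2:
        return 0.0
    d = np.diff(h)
    d = np.mod(d + np.pi, 2 * np.pi) - np.pi
    return float(np.sum(np.abs(d))) / bout.duration


def summarize_bouts(bouts: list[Bout], deployment, breath_times) -> None:
    """Fill breath counts and kinematic summaries for each bout (in place)."""
    assign_breaths(bouts, breath_times)
    for b in bouts:
        b.mean_speed = bout_speed(
            b, deployment.time, deployment.depth, deployment.speed, deployment.fs
        )
        b.angular_velocity = bout_angular_velocity(
            b, deployment.time, deployment.heading, deployment.fs
        )
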