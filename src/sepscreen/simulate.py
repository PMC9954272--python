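"""Synthetic data generation at two levels.

Trial level: a seeded agent steers an inert sphere through the evaluation
scene (waypoint pursuit with bounded acceleration, velocity damping, angular
steering noise, spurious detours and optional loitering above the obstacle),
producing 60 Hz :class:`~sepscreen.trajectory.TrajectoryLog` objects that
exercise the biomarker extractor. The agent emulates the task, not real
touch biomechanics; its impairment knobs are behavioral abstractions.

Cohort level: group-wise marker/MMSE marginals calibrated to published
median/quartile summaries (log-normal for times, distances and ratios;
rounded, truncated normal for integer scores), coupled through a Gaussian
copula, yielding reproducible case-control tables with exact marginal
control. Packaged presets carry the calibration numbers for the full cohort
(46 NC / 46 MCI) and the basic-education subgroup (29 NC / 31 MCI).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .scene import CUBE_IDS, SceneConfig, DEFAULT_SCENE, validate_scene
from .trajectory import EliminationEvent, TrajectoryLog

_Z75 = float(norm.ppf(0.75))  # 0.6744897...


# --------------------------------------------------------------------------
# Trial-level simulation
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class AgentProfile:
    """Behavioral parameters of the simulated participant.

    max_accel_px_s2 — acceleration budget of the steering controller;
    damping_per_s — velocity damping of the inert sphere (terminal speed is
    max_accel / damping); steering_noise_sd_rad — SD of the angular error
    applied to the commanded acceleration, resampled at each replan tick;
    replan_interval_s — time between waypoint re-evaluations;
    detour_prob — probability per replan of inserting a spurious waypoint;
    dwell_above_s — extra loiter time above the obstacle after the first
    crossing; route_order — fixed cube order, or None for the default.
    """

    max_accel_px_s2: float = 900.0
    damping_per_s: float = 2.5
    steering_noise_sd_rad: float = 0.10
    replan_interval_s: float = 0.25
    detour_prob: float = 0.0
    dwell_above_s: float = 0.0
    route_order: Optional[tuple[str, ...]] = None

    def validate(self) -> "AgentProfile":
        if min(self.max_accel_px_s2, self.damping_per_s, self.steering_noise_sd_rad,
               self.replan_interval_s, self.dwell_above_s) < 0:
            raise ValueError("profile rates must be >= 0")
        if not 0.0 <= self.detour_prob <= 1.0:
            raise ValueError("detour_prob must lie in [0, 1]")
        if self.route_order is not None and sorted(self.route_order) != sorted(CUBE_IDS):
            raise ValueError("route_order must be a permutation of the four cube ids")
        return self


# Unimpaired vs impaired default profiles: the impaired agent steers with
# more angular noise, replans less often, wanders more and loiters above the
# obstacle — behavioral proxies for spatial-navigation / execution deficits.
NC_PROFILE = AgentProfile(detour_prob=0.03)
MCI_PROFILE = AgentProfile(
    max_accel_px_s2=800.0,
    damping_per_s=2.8,
    steering_noise_sd_rad=0.28,
    replan_interval_s=0.40,
    detour_prob=0.08,
    dwell_above_s=1.5,
)

DEFAULT_ROUTE = ("left", "right", "bottom", "top")

_ARRIVE_PX = 150.0  # arrival radius for intermediate waypoints
_WAYPOINT_TIMEOUT_S = 4.0
_GAP_CLEARANCE_PX = 120.0


def _gap_waypoint(scene: SceneConfig, x_from: float, x_to: float) -> tuple[float, float]:
    """Waypoint just beyond the nearer obstacle end, used to route around it."""
    mid = 0.5 * (x_from + x_to)
    left_gap = scene.obstacle_x_min_px - _GAP_CLEARANCE_PX
    right_gap = scene.obstacle_x_max_px + _GAP_CLEARANCE_PX
    gx = left_gap if abs(mid - left_gap) <= abs(mid - right_gap) else right_gap
    return (gx, scene.obstacle_y_px)


def simulate_trial(
    profile: AgentProfile,
    scene: SceneConfig = DEFAULT_SCENE,
    seed: int | np.random.SeedSequence = 0,
    participant_id: str = "sim",
) -> TrajectoryLog:
    """Simulate one trial; returns a validated 60 Hz log.

    The sphere integrates v <- (1 - damping*dt) v + a*dt with |a| bounded by
    the profile's acceleration budget and directed at the current waypoint
    (rotated by the held steering-noise angle). A cube is eliminated when
    the center distance falls within sphere radius + cube half-size. The
    obstacle segment is impassable: the controller routes around its ends,
    and a step that would pierce it is stopped at the midline. The trial
    ends at the fourth elimination or at the time cap, whichever is first;
    a profile too weak to finish yields a valid incomplete log.
    """
    profile.validate()
    validate_scene(scene)
    rng = np.random.default_rng(seed)
    dt = 1.0 / scene.sample_rate_hz
    decay = 1.0 - profile.damping_per_s * dt
    if decay < 0:
        raise ValueError("damping too strong for the sampling interval")
    replan_ticks = max(1, int(round(profile.replan_interval_s * scene.sample_rate_hz)))
    contact = scene.contact_distance_px
    obs_y = scene.obstacle_y_px

    x, y = scene.sphere_start
    vx = vy = 0.0
    xs = [x]
    ys = [y]
    events: list[EliminationEvent] = []
    remaining = list(profile.route_order or DEFAULT_ROUTE)
    waypoints: list[tuple[float, float]] = []  # transient detour/gap points
    noise_angle = 0.0
    waypoint_deadline = _WAYPOINT_TIMEOUT_S * scene.sample_rate_hz
    hover_until_tick: Optional[int] = None
    hover_point: Optional[tuple[float, float]] = None
    dwell_pending = profile.dwell_above_s > 0
    ticks_on_waypoint = 0

    def current_target() -> tuple[float, float]:
        if hover_point is not None:
            return hover_point
        if waypoints:
            return waypoints[0]
        cx, cy = scene.cube_centers[remaining[0]]
        if (y - obs_y) * (cy - obs_y) < 0:  # crossing needed: route via a gap
            gap = _gap_waypoint(scene, x, cx)
            waypoints.insert(0, gap)
            return gap
        return (cx, cy)

    for i in range(1, scene.count_max):
        if i % replan_ticks == 1 or replan_ticks == 1:
            noise_angle = rng.normal(0.0, profile.steering_noise_sd_rad)
            if profile.detour_prob > 0 and rng.random() < profile.detour_prob and hover_point is None:
                waypoints.insert(0, (
                    rng.uniform(200.0, scene.screen_width_px - 200.0),
                    rng.uniform(100.0, scene.screen_height_px - 100.0),
                ))
                ticks_on_waypoint = 0

        tx, ty = current_target()
        dx, dy = tx - x, ty - y
        dist = math.hypot(dx, dy)
        if dist > 1e-9:
            ca, sa = math.cos(noise_angle), math.sin(noise_angle)
            ux, uy = dx / dist, dy / dist
            ax = profile.max_accel_px_s2 * (ca * ux - sa * uy)
            ay = profile.max_accel_px_s2 * (sa * ux + ca * uy)
        else:
            ax = ay = 0.0
        vx = decay * vx + ax * dt
        vy = decay * vy + ay * dt
        nx, ny = x + vx * dt, y + vy * dt

        # obstacle segment is impassable within its horizontal extent
        if (y - obs_y) * (ny - obs_y) < 0:
            x_at = x + (obs_y - y) / (ny - y) * (nx - x)
            if scene.obstacle_x_min_px <= x_at <= scene.obstacle_x_max_px:
                ny = obs_y + math.copysign(1e-6, y - obs_y)
                vy = 0.0
        x, y = nx, ny
        xs.append(x)
        ys.append(y)

        # loiter above the obstacle once, if the profile asks for it
        if dwell_pending and y > obs_y:
            dwell_pending = False
            hover_until_tick = i + int(round(profile.dwell_above_s * scene.sample_rate_hz))
            hover_point = (x, min(obs_y + 200.0, scene.screen_height_px - 100.0))
        if hover_until_tick is not None and i >= hover_until_tick:
            hover_until_tick = None
            hover_point = None

        # waypoint housekeeping
        if waypoints and hover_point is None:
            ticks_on_waypoint += 1
            wx, wy = waypoints[0]
            if math.hypot(wx - x, wy - y) <= _ARRIVE_PX or ticks_on_waypoint > waypoint_deadline:
                waypoints.pop(0)
                ticks_on_waypoint = 0

        # elimination (at most one per tick; cubes are far apart)
        for cid in remaining:
            cx, cy = scene.cube_centers[cid]
            if math.hypot(cx - x, cy - y) <= contact:
                events.append(EliminationEvent(cid, i, i / scene.sample_rate_hz))
                remaining.remove(cid)
                waypoints.clear()
                ticks_on_waypoint = 0
                break
        if not remaining:
            break

    log = TrajectoryLog(
        participant_id=participant_id,
        scene=scene,
        positions=np.column_stack([xs, ys]),
        events=events,
    )
    return log.validate()


def random_profile(rng: np.random.Generator) -> AgentProfile:
    """Random plausible agent, spanning unimpaired through impaired behavior."""
    route = list(CUBE_IDS)
    rng.shuffle(route)
    return AgentProfile(
        max_accel_px_s2=rng.uniform(600.0, 1400.0),
        damping_per_s=rng.uniform(2.0, 3.0),
        steering_noise_sd_rad=rng.uniform(0.0, 0.35),
        replan_interval_s=rng.uniform(0.15, 0.5),
        detour_prob=rng.uniform(0.0, 0.12),
        dwell_above_s=rng.uniform(0.0, 3.0),
        route_order=tuple(route),
    )


# --------------------------------------------------------------------------
# Cohort-level generation
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Marginal:
    """One variable's per-group summary: median [P25, P75] plus family.

    family 'lognormal' fits a log-normal by matching the printed quartiles
    exactly; 'normal' a normal; 'discrete_normal' a normal subsequently
    rounded to integers and clipped to [lo, hi] (MMSE-style scores).
    """

    median: float
    p25: float
    p75: float
    family: str = "lognormal"
    lo: Optional[float] = None
    hi: Optional[float] = None

    def validate(self) -> "Marginal":
        if not self.p25 < self.median < self.p75:
            raise ValueError(f"quartiles must satisfy p25 < median < p75, got {self}")
        if self.family == "lognormal" and self.p25 <= 0:
            raise ValueError("lognormal marginal requires positive quartiles")
        if self.family not in ("lognormal", "normal", "discrete_normal"):
            raise ValueError(f"unknown family {self.family!r}")
        return self


def calibrate_lognormal(median: float, p25: float, p75: float) -> tuple[float, float]:
    """Log-normal (mu, sigma) matching a printed median and quartiles.

    mu = ln(median); sigma = (ln p75 - ln p25) / (2 * z_0.75) with
    z_0.75 = Phi^-1(0.75) ≈ 0.67449, so the fitted law reproduces all
    three summaries exactly.
    """
    if not 0 < p25 < median < p75:
        raise ValueError("require 0 < p25 < median < p75")
    mu = math.log(median)
    sigma = (math.log(p75) - math.log(p25)) / (2.0 * _Z75)
    return mu, sigma


def calibrate_normal(median: float, p25: float, p75: float) -> tuple[float, float]:
    """Normal (mu, sigma) matching a printed median and quartiles."""
    if not p25 < median < p75:
        raise ValueError("require p25 < median < p75")
    return median, (p75 - p25) / (2.0 * _Z75)


def _transform(marg: Marginal, z: np.ndarray) -> np.ndarray:
    if marg.family == "lognormal":
        mu, sigma = calibrate_lognormal(marg.median, marg.p25, marg.p75)
        x = np.exp(mu + sigma * z)
    else:
        mu, sigma = calibrate_normal(marg.median, marg.p25, marg.p75)
        x = mu + sigma * z
        if marg.family == "discrete_normal":
            x = np.rint(x)
    if marg.lo is not None or marg.hi is not None:
        x = np.clip(x, marg.lo, marg.hi)
    return x


@dataclass(frozen=True)
class GroupSpec:
    """Marginals and demographics for one diagnostic group."""

    label: str
    n: int
    marginals: Mapping[str, Marginal]
    female_fraction: float = 0.5


@dataclass(frozen=True)
class MarkerDistributionSpec:
    """Calibrated two-group cohort description.

    ``copula_corr`` is the latent-normal correlation among the variables in
    marginal order (None = independent). The correlation structure between
    markers is not published anywhere; any nonzero choice is a modeling
    assumption and is flagged as such in outputs.
    """

    nc: GroupSpec
    mci: GroupSpec
    copula_corr: Optional[np.ndarray] = None

    @property
    def variables(self) -> tuple[str, ...]:
        return tuple(self.nc.marginals)

    def validate(self) -> "MarkerDistributionSpec":
        if tuple(self.nc.marginals) != tuple(self.mci.marginals):
            raise ValueError("both groups must define the same variables in the same order")
        for g in (self.nc, self.mci):
            if g.n <= 0:
                raise ValueError("group sizes must be positive")
            if not 0.0 <= g.female_fraction <= 1.0:
                raise ValueError("female_fraction must lie in [0, 1]")
            for m in g.marginals.values():
                m.validate()
        if self.copula_corr is not None:
            c = np.asarray(self.copula_corr, float)
            k = len(self.variables)
            if c.shape != (k, k) or not np.allclose(c, c.T) or not np.allclose(np.diag(c), 1.0):
                raise ValueError("copula_corr must be symmetric with unit diagonal")
            if np.linalg.eigvalsh(c).min() < -1e-10:
                raise ValueError("copula_corr must be positive semi-definite")
        return self

    def with_group_sizes(self, n_nc: int, n_mci: int) -> "MarkerDistributionSpec":
        return replace(self, nc=replace(self.nc, n=n_nc), mci=replace(self.mci, n=n_mci))

    def subset(self, variables: Sequence[str]) -> "MarkerDistributionSpec":
        """Restrict to a subset of variables (drops any copula structure)."""
        return MarkerDistributionSpec(
            nc=replace(self.nc, marginals={v: self.nc.marginals[v] for v in variables}),
            mci=replace(self.mci, marginals={v: self.mci.marginals[v] for v in variables}),
            copula_corr=None,
        )


def _latent_draws(rng: np.random.Generator, n: int, k: int,
                  corr: Optional[np.ndarray]) -> np.ndarray:
    z = rng.standard_normal((n, k))
    if corr is None:
        return z
    w, v = np.linalg.eigh(np.asarray(corr, float))
    factor = v * np.sqrt(np.clip(w, 0.0, None))
    return z @ factor.T


def sample_cohort(spec: MarkerDistributionSpec, seed: int | np.random.SeedSequence) -> pd.DataFrame:
    """Draw a synthetic cohort table from a validated spec.

    Per-group sub-streams are spawned from the master seed (group order NC,
    MCI), so the same seed always reproduces the identical table. Sex is
    assigned to match the calibrated female fraction up to rounding, then
    shuffled within group.
    """
    spec.validate()
    master = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    streams = master.spawn(2)
    frames = []
    for g, ss in zip((spec.nc, spec.mci), streams):
        rng = np.random.default_rng(ss)
        z = _latent_draws(rng, g.n, len(spec.variables), spec.copula_corr)
        data = {
            "participant_id": [f"{g.label}{i:04d}" for i in range(g.n)],
            "group": g.label,
        }
        n_female = int(round(g.female_fraction * g.n))
        sex = np.array(["female"] * n_female + ["male"] * (g.n - n_female))
        data["sex"] = rng.permutation(sex)
        for j, var in enumerate(spec.variables):
            data[var] = _transform(g.marginals[var], z[:, j])
        frames.append(pd.DataFrame(data))
    return pd.concat(frames, ignore_index=True)


# --------------------------------------------------------------------------
# Packaged calibration presets (published cohort summary tables)
# --------------------------------------------------------------------------

def _score(median, p25, p75):  # MMSE-style integer score, ceiling 30
    return Marginal(median, p25, p75, family="discrete_normal", lo=0, hi=30)


def _years(median, p25, p75, hi):
    return Marginal(median, p25, p75, family="discrete_normal", lo=0, hi=hi)


def _rate(median, p25, p75):  # time-rate markers are capped at 1 by the paradigm
    return Marginal(median, p25, p75, family="lognormal", hi=1.0)


def _ln(median, p25, p75):
    return Marginal(median, p25, p75, family="lognormal")


def full_cohort_spec() -> MarkerDistributionSpec:
    """Calibration preset for the full published cohort (46 NC / 46 MCI)."""
    nc = {
        "age": _years(68.00, 60.75, 79.00, hi=110),
        "education_years": _years(12.00, 9.00, 15.25, hi=25),
        "mmse": _score(29.00, 28.00, 29.25),
        "metr_total": _rate(0.26, 0.21, 0.38),
        "med_total_px": _ln(8676.08, 7406.04, 10324.11),
        "met_first_s": _ln(1.12, 0.78, 1.75),
        "mee_first": _ln(1.04, 1.01, 1.06),
        "et_crossing_s": _ln(25.32, 19.00, 33.52),
        "ed_crossing_px": _ln(7292.46, 5331.37, 8750.32),
        "et_above_s": _ln(16.51, 12.99, 25.22),
        "ed_above_px": _ln(4497.86, 3567.56, 6036.56),
    }
    mci = {
        "age": _years(70.00, 64.75, 80.00, hi=110),
        "education_years": _years(12.00, 9.00, 14.25, hi=25),
        "mmse": _score(26.00, 24.00, 29.00),
        "metr_total": _rate(0.31, 0.25, 0.50),
        "med_total_px": _ln(10963.08, 9156.78, 12672.55),
        "met_first_s": _ln(1.08, 0.82, 1.96),
        "mee_first": _ln(1.03, 1.01, 1.10),
        "et_crossing_s": _ln(32.18, 22.83, 43.30),
        "ed_crossing_px": _ln(8606.23, 6675.84, 10861.47),
        "et_above_s": _ln(18.27, 13.40, 29.00),
        "ed_above_px": _ln(4279.95, 3508.07, 5780.54),
    }
    return MarkerDistributionSpec(
        nc=GroupSpec("NC", 46, nc, female_fraction=29 / 46),
        mci=GroupSpec("MCI", 46, mci, female_fraction=31 / 46),
    ).validate()


def basic_education_spec() -> MarkerDistributionSpec:
    """Calibration preset for the basic-education subgroup (29 NC / 31 MCI,
    more than 9 years of schooling)."""
    nc = {
        "age": _years(68.00, 61.00, 83.00, hi=110),
        "education_years": _years(12.00, 9.00, 16.00, hi=25),
        "mmse": _score(29.00, 28.00, 30.00),
        "metr_total": _rate(0.24, 0.20, 0.28),
        "med_total_px": _ln(8469.29, 7071.54, 9285.65),
        "met_first_s": _ln(0.95, 0.77, 1.56),
        "mee_first": _ln(1.04, 1.01, 1.08),
        "et_crossing_s": _ln(22.65, 18.37, 28.17),
        "ed_crossing_px": _ln(6515.23, 5128.11, 8748.07),
        "et_above_s": _ln(14.03, 12.45, 17.53),
        "ed_above_px": _ln(4040.34, 2928.82, 5167.38),
    }
    mci = {
        "age": _years(72.00, 64.00, 80.00, hi=110),
        "education_years": _years(12.00, 6.00, 15.00, hi=25),
        "mmse": _score(27.00, 24.00, 29.00),
        "metr_total": _rate(0.30, 0.26, 0.50),
        "med_total_px": _ln(10473.75, 9189.11, 12848.72),
        "met_first_s": _ln(1.25, 0.85, 2.30),
        "mee_first": _ln(1.03, 1.01, 1.09),
        "et_crossing_s": _ln(30.40, 22.98, 43.30),
        "ed_crossing_px": _ln(8391.10, 6912.21, 11023.95),
        "et_above_s": _ln(17.72, 12.75, 29.02),
        "ed_above_px": _ln(4260.67, 3579.10, 5640.59),
    }
    return MarkerDistributionSpec(
        nc=GroupSpec("NC", 29, nc, female_fraction=17 / 29),
        mci=GroupSpec("MCI", 31, mci, female_fraction=17 / 31),
    ).validate()


PRESETS = {"full": full_cohort_spec, "basic_education": basic_education_spec}


def spec_to_dict(spec: MarkerDistributionSpec) -> dict:
    def group(g: GroupSpec) -> dict:
        return {
            "label": g.label,
            "n": g.n,
            "female_fraction": g.female_fraction,
            "marginals": {
                k: {f: getattr(m, f) for f in ("median", "p25", "p75", "family", "lo", "hi")}
                for k, m in g.marginals.items()
            },
        }
    return {
        "nc": group(spec.nc),
        "mci": group(spec.mci),
        "copula_corr": None if spec.copula_corr is None else np.asarray(spec.copula_corr).tolist(),
    }


def spec_from_dict(d: Mapping) -> MarkerDistributionSpec:
    def group(gd: Mapping) -> GroupSpec:
        return GroupSpec(
            label=gd["label"],
            n=int(gd["n"]),
            female_fraction=float(gd.get("female_fraction", 0.5)),
            marginals={k: Marginal(**m) for k, m in gd["marginals"].items()},
        )
    corr = d.get("copula_corr")
    return MarkerDistributionSpec(
        nc=group(d["nc"]),
        mci=group(d["mci"]),
        copula_corr=None if corr is None else np.asarray(corr, float),
    ).validate()


def load_spec(path: str | Path) -> MarkerDistributionSpec:
    return spec_from_dict(json.loads(Path(path).read_text()))
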