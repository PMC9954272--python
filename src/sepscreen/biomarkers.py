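"""The eight spatial-execution-process (SEP) digital biomarkers.

Four time-related markers — total mission execution time rate (METRtotal),
mission execution time of the first task (METfirst), execution time after
crossing the transverse obstacle (ETcrossing) and execution time above the
obstacle (ETabove) — and four distance-related markers — total mission
execution distance (MEDtotal), mission execution efficiency of the first
task (MEEfirst), execution distance after crossing (EDcrossing) and
execution distance above the obstacle (EDabove).

Conventions (documented in docs/methods.md):

* The inter-sample step distance is plain Euclidean: d_i = ||p_{i+1} - p_i||.
* All step sums are truncated at the Te sample index; drift logged after the
  fourth elimination is excluded.
* The crossing discriminant uses only the sphere-center y coordinate
  against the obstacle midline: the first step i -> i+1 with
  y_i <= y_obstacle < y_{i+1} is the crossing, Tcrossing = t_{i+1}.
* "Above" quantities count steps whose BOTH endpoints are above the
  midline; each such step contributes 1/SR to ETabove and d_i to EDabove.
  This makes ETabove <= ETcrossing and EDabove <= EDcrossing exact
  identities rather than approximations.
* A biomarker whose defining event never happened (no elimination, no
  crossing) is reported missing (None), never zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .scene import SceneConfig
from .trajectory import TrajectoryLog, compute_te, te_sample_index

BIOMARKER_NAMES = (
    "metr_total",
    "met_first_s",
    "et_crossing_s",
    "et_above_s",
    "med_total_px",
    "mee_first",
    "ed_crossing_px",
    "ed_above_px",
)


class GeometryError(ValueError):
    """Degenerate geometry (start inside the contact zone of a cube)."""


@dataclass
class BiomarkerVector:
    """The eight SEP biomarkers for one trial, plus context fields.

    ``None`` marks a missing value (defining event absent). ``crossing_t_s``
    is Tcrossing, the time of the first upward crossing of the obstacle
    midline; ``complete`` records whether all four cubes were eliminated.
    """

    metr_total: float
    met_first_s: Optional[float]
    et_crossing_s: Optional[float]
    et_above_s: float
    med_total_px: float
    mee_first: Optional[float]
    ed_crossing_px: Optional[float]
    ed_above_px: float
    crossing_t_s: Optional[float]
    complete: bool

    def to_dict(self) -> dict:
        return asdict(self)


def step_distance(p: tuple[float, float], q: tuple[float, float]) -> float:
    """Euclidean distance between two adjacent sample positions (px)."""
    return math.hypot(q[0] - p[0], q[1] - p[1])


def _step_lengths(log: TrajectoryLog, stop: int) -> np.ndarray:
    """d_i for i = 0..stop-1 (pairs with both indices <= stop)."""
    pos = log.positions[: stop + 1]
    return np.hypot(np.diff(pos[:, 0]), np.diff(pos[:, 1]))


def metr_total(log: TrajectoryLog) -> float:
    """Total mission execution time rate: Te / T, in (0, 1]."""
    return compute_te(log) / log.scene.t_max_s


def med_total(log: TrajectoryLog) -> float:
    """Total mission execution distance: sum of d_i up to the Te index (px)."""
    return float(_step_lengths(log, te_sample_index(log)).sum())


def met_first(log: TrajectoryLog) -> Optional[float]:
    """Time to eliminate the first target cube (s); missing without events."""
    if not log.events:
        return None
    return log.events[0].t_s


def mee_first(log: TrajectoryLog, scene: SceneConfig | None = None) -> Optional[float]:
    """Mission execution efficiency of the first task.

    Ratio of the distance travelled before the first elimination to the
    shortest start-to-cube distance. The denominator is contact-adjusted —
    ||cube_center - sphere_start|| minus (sphere radius + cube half-size) —
    so an ideal straight constant-speed approach scores exactly 1.
    """
    scene = scene or log.scene
    if not log.events:
        return None
    first = log.events[0]
    cx, cy = scene.cube_centers[first.cube_id]
    sx, sy = scene.sphere_start
    shortest = math.hypot(cx - sx, cy - sy) - scene.contact_distance_px
    if shortest <= 0:
        raise GeometryError(
            "degenerate geometry: sphere start within contact distance of the first cube"
        )
    travelled = float(_step_lengths(log, first.sample_index).sum())
    return travelled / shortest


def detect_crossing(
    log: TrajectoryLog, scene: SceneConfig | None = None
) -> Optional[tuple[float, int]]:
    """First upward crossing of the obstacle midline, or None.

    Returns ``(crossing_t_s, crossing_index)`` where ``crossing_index`` is
    the first sample strictly above the midline (the step i -> i+1 with
    y_i <= y_obs < y_{i+1}); Tcrossing is that sample's time. Later dips
    below the midline do not reset it. Only samples within the task
    (index <= Te index) are considered.
    """
    scene = scene or log.scene
    stop = te_sample_index(log)
    y = log.positions[: stop + 1, 1]
    up = (y[:-1] <= scene.obstacle_y_px) & (y[1:] > scene.obstacle_y_px)
    idx = np.flatnonzero(up)
    if idx.size == 0:
        return None
    ci = int(idx[0]) + 1
    return log.t(ci), ci


def crossing_metrics(
    log: TrajectoryLog, scene: SceneConfig | None = None
) -> tuple[Optional[float], Optional[float]]:
    """ETcrossing and EDcrossing: time and distance after the first crossing.

    ETcrossing = Te - Tcrossing; EDcrossing sums d_i over steps from the
    crossing sample through the Te index. Both missing if no crossing.
    """
    scene = scene or log.scene
    crossing = detect_crossing(log, scene)
    if crossing is None:
        return None, None
    t_cross, ci = crossing
    stop = te_sample_index(log)
    et = log.t(stop) if log.complete else compute_te(log)
    et_crossing = et - t_cross
    d = _step_lengths(log, stop)
    ed_crossing = float(d[ci:].sum())
    return et_crossing, ed_crossing


def above_metrics(
    log: TrajectoryLog, scene: SceneConfig | None = None
) -> tuple[float, float]:
    """ETabove and EDabove: dwell time and distance above the obstacle.

    A step counts only when both endpoints are above the midline; each
    counted step contributes one sampling period to ETabove and its length
    to EDabove. Zero (not missing) when the sphere never goes above.
    """
    scene = scene or log.scene
    stop = te_sample_index(log)
    y = log.positions[: stop + 1, 1]
    both_above = (y[:-1] > scene.obstacle_y_px) & (y[1:] > scene.obstacle_y_px)
    et_above = float(both_above.sum()) / scene.sample_rate_hz
    d = _step_lengths(log, stop)
    ed_above = float(d[both_above].sum())
    return et_above, ed_above


def extract_biomarkers(log: TrajectoryLog, scene: SceneConfig | None = None) -> BiomarkerVector:
    """Compute all eight biomarkers for one validated trial.

    Per-biomarker missingness propagates (e.g. a trial that never crosses
    the obstacle yields missing ETcrossing/EDcrossing); extraction never
    aborts on an event-free trial.
    """
    scene = scene or log.scene
    crossing = detect_crossing(log, scene)
    et_c, ed_c = crossing_metrics(log, scene)
    et_a, ed_a = above_metrics(log, scene)
    return BiomarkerVector(
        metr_total=metr_total(log),
        met_first_s=met_first(log),
        et_crossing_s=et_c,
        et_above_s=et_a,
        med_total_px=med_total(log),
        mee_first=mee_first(log, scene),
        ed_crossing_px=ed_c,
        ed_above_px=ed_a,
        crossing_t_s=None if crossing is None else crossing[0],
        complete=log.complete,
    )


def extract_batch(logs: Iterable[TrajectoryLog], scene: SceneConfig | None = None) -> pd.DataFrame:
    """One row per trial: participant_id, the 8 biomarkers, crossing_t_s, complete."""
    rows = []
    for log in logs:
        vec = extract_biomarkers(log, scene)
        row = {"participant_id": log.participant_id}
        row.update(vec.to_dict())
        rows.append(row)
    return pd.DataFrame(rows)
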