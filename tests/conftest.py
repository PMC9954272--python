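import math

import numpy as np
import pytest

from sepscreen.scene import DEFAULT_SCENE, SceneConfig
from sepscreen.trajectory import EliminationEvent, TrajectoryLog


@pytest.fixture(scope="session")
def scene() -> SceneConfig:
    return DEFAULT_SCENE


def make_log(positions, event_indices=None, scene=DEFAULT_SCENE, pid="t") -> TrajectoryLog:
    """Build a trial log from raw positions and {cube_id: sample_index}."""
    events = [
        EliminationEvent(cid, i, i / scene.sample_rate_hz)
        for cid, i in sorted((event_indices or {}).items(), key=lambda kv: kv[1])
    ]
    return TrajectoryLog(pid, scene, np.asarray(positions, float), events)


def brute_extract(log, scene=None):
    """Independent brute-force biomarker extractor (plain Python loops).

    Used as the oracle against the production extractor; shares no code
    with it beyond the data model.
    """
    scene = scene or log.scene
    sr = scene.sample_rate_hz
    T = scene.t_max_s
    oy = scene.obstacle_y_px
    pts = [(float(x), float(y)) for x, y in log.positions]
    events = log.events
    complete = len(events) == 4
    te = events[-1].sample_index / sr if complete else T
    stop = events[-1].sample_index if complete else len(pts) - 1

    def d(i):
        return math.dist(pts[i], pts[i + 1])

    out = {
        "metr_total": te / T,
        "med_total_px": sum(d(i) for i in range(stop)),
        "met_first_s": events[0].sample_index / sr if events else None,
        "complete": complete,
    }
    if events:
        fi = events[0].sample_index
        cx, cy = scene.cube_centers[events[0].cube_id]
        shortest = math.dist((cx, cy), scene.sphere_start) - (
            scene.sphere_radius_px + scene.cube_half_size_px
        )
        out["mee_first"] = sum(d(i) for i in range(fi)) / shortest
    else:
        out["mee_first"] = None

    ci = None
    for i in range(stop):
        if pts[i][1] <= oy < pts[i + 1][1]:
            ci = i + 1
            break
    if ci is None:
        out.update(crossing_t_s=None, et_crossing_s=None, ed_crossing_px=None)
    else:
        out["crossing_t_s"] = ci / sr
        out["et_crossing_s"] = te - ci / sr
        out["ed_crossing_px"] = sum(d(i) for i in range(ci, stop))
    above = [i for i in range(stop) if pts[i][1] > oy and pts[i + 1][1] > oy]
    out["et_above_s"] = len(above) / sr
    out["ed_above_px"] = sum(d(i) for i in above)
    return out
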