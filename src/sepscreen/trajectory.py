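"""Per-trial evaluation logs: the sampled sphere trajectory plus cube
elimination events, with a streamable JSON Lines serialization.

Dialect: line 1 is a header object ``{"participant_id", "sample_rate_hz",
"scene"}``; each subsequent line is either a sample ``{"i", "x", "y"}`` or an
inline elimination event ``{"event": <cube_id>, "i": <sample_index>}`` placed
immediately after the sample it refers to. Coordinates are written as full
precision decimal text, so a round-trip preserves them bit-exactly.
"""

from __future__ import annotations

import io
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .scene import CUBE_IDS, SceneConfig, validate_scene

logger = logging.getLogger(__name__)


class LogFormatError(ValueError):
    """Malformed or invariant-violating evaluation log."""


@dataclass(frozen=True)
class Sample:
    """One 60 Hz sample: index i, derived time i/SR, sphere-center position."""

    index: int
    t_s: float
    pos: tuple[float, float]


@dataclass(frozen=True)
class EliminationEvent:
    """Elimination of one target cube at a given sample index."""

    cube_id: str
    sample_index: int
    t_s: float


@dataclass
class TrajectoryLog:
    """One trial: ordered sphere positions plus 0-4 elimination events.

    ``positions`` holds the sphere-center coordinates for contiguous sample
    indices 0..n-1. The trial is complete iff all four cubes were eliminated
    within the time cap.
    """

    participant_id: str
    scene: SceneConfig
    positions: np.ndarray  # (n, 2) float64
    events: list[EliminationEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)

    @property
    def n_samples(self) -> int:
        return len(self.positions)

    @property
    def complete(self) -> bool:
        return len(self.events) == 4

    def t(self, index: int) -> float:
        return index / self.scene.sample_rate_hz

    def samples(self) -> Iterable[Sample]:
        for i, (x, y) in enumerate(self.positions):
            yield Sample(i, self.t(i), (float(x), float(y)))

    def validate(self) -> "TrajectoryLog":
        validate_scene(self.scene)
        if self.positions.ndim != 2 or self.positions.shape[1] != 2:
            raise LogFormatError("positions must be an (n, 2) array")
        if self.n_samples == 0:
            raise LogFormatError("empty log: at least one sample required")
        if self.n_samples > self.scene.count_max:
            raise LogFormatError("too many samples: last t_s exceeds t_max_s")
        if not np.isfinite(self.positions).all():
            raise LogFormatError("non-finite coordinate")
        seen: set[str] = set()
        prev = -1
        for ev in self.events:
            if ev.cube_id not in CUBE_IDS:
                raise LogFormatError(f"unknown cube id {ev.cube_id!r}")
            if ev.cube_id in seen:
                raise LogFormatError(f"duplicate elimination of cube {ev.cube_id!r}")
            seen.add(ev.cube_id)
            if not 0 <= ev.sample_index < self.n_samples:
                raise LogFormatError("event sample_index outside the sample range")
            if ev.sample_index <= prev:
                raise LogFormatError("events not strictly increasing in time")
            prev = ev.sample_index
            expected_t = self.t(ev.sample_index)
            if abs(ev.t_s - expected_t) > 1e-9:
                raise LogFormatError("event t_s inconsistent with sample_index")
        return self


def make_event(cube_id: str, sample_index: int, scene: SceneConfig) -> EliminationEvent:
    return EliminationEvent(cube_id, sample_index, sample_index / scene.sample_rate_hz)


def compute_te(log: TrajectoryLog) -> float:
    """Total task execution time Te in seconds.

    Complete trials: the time of the fourth elimination event. Incomplete
    trials are capped by the paradigm, so Te equals the maximum evaluation
    time and downstream event-dependent biomarkers are reported missing.
    """
    if log.complete:
        return log.events[-1].t_s
    return log.scene.t_max_s


def te_sample_index(log: TrajectoryLog) -> int:
    """Last sample index belonging to the task (Te truncation point)."""
    if log.complete:
        return log.events[-1].sample_index
    return log.n_samples - 1


def write_log(log: TrajectoryLog, sink) -> None:
    """Serialize a validated log to ``sink`` (path or text file object)."""
    log.validate()
    if isinstance(sink, (str, Path)):
        with open(sink, "w") as fh:
            write_log(log, fh)
        return
    header = {
        "participant_id": log.participant_id,
        "sample_rate_hz": log.scene.sample_rate_hz,
        "scene": log.scene.to_dict(),
    }
    sink.write(json.dumps(header) + "\n")
    ev_by_index: dict[int, list[EliminationEvent]] = {}
    for ev in log.events:
        ev_by_index.setdefault(ev.sample_index, []).append(ev)
    for i, (x, y) in enumerate(log.positions):
        sink.write(json.dumps({"i": i, "x": float(x), "y": float(y)}) + "\n")
        for ev in ev_by_index.get(i, ()):
            sink.write(json.dumps({"event": ev.cube_id, "i": ev.sample_index}) + "\n")


_SAMPLE_KEYS = {"i", "x", "y"}
_EVENT_KEYS = {"event", "i"}


def read_log(source) -> TrajectoryLog:
    """Parse the JSONL dialect into a validated :class:`TrajectoryLog`.

    Unknown keys are ignored with a logged warning; structural problems
    (missing header, duplicate events, non-contiguous sample indices) raise
    :class:`LogFormatError` with the offending line number.
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            return read_log(fh)
    if isinstance(source, str):  # pragma: no cover - convenience
        source = io.StringIO(source)

    lines = [ln for ln in source]
    if not lines:
        raise LogFormatError("missing header: empty stream")
    try:
        header = json.loads(lines[0])
    except json.JSONDecodeError as exc:
        raise LogFormatError(f"malformed line 1: {exc}") from exc
    if not isinstance(header, dict) or "participant_id" not in header or "scene" not in header:
        raise LogFormatError("missing header: first line must carry participant_id and scene")
    scene = SceneConfig.from_dict(header["scene"])

    xs: list[float] = []
    ys: list[float] = []
    events: list[EliminationEvent] = []
    for lineno, raw in enumerate(lines[1:], start=2):
        if not raw.strip():
            continue
        try:
            rec = json.loads(raw)
        except json.JSONDecodeError as exc:
            raise LogFormatError(f"malformed line {lineno}: {exc}") from exc
        if "event" in rec:
            unknown = set(rec) - _EVENT_KEYS
            cube = rec["event"]
            if any(ev.cube_id == cube for ev in events):
                raise LogFormatError(f"duplicate elimination of cube {cube!r} at line {lineno}")
            events.append(make_event(cube, int(rec["i"]), scene))
        elif "x" in rec and "y" in rec:
            unknown = set(rec) - _SAMPLE_KEYS
            if int(rec["i"]) != len(xs):
                raise LogFormatError(
                    f"non-contiguous samples at line {lineno}: expected i={len(xs)}, got {rec['i']}"
                )
            xs.append(float(rec["x"]))
            ys.append(float(rec["y"]))
        else:
            raise LogFormatError(f"malformed line {lineno}: neither sample nor event")
        if unknown:
            logger.warning("line %d: ignoring unknown keys %s", lineno, sorted(unknown))

    log = TrajectoryLog(
        participant_id=str(header["participant_id"]),
        scene=scene,
        positions=np.column_stack([xs, ys]) if xs else np.empty((0, 2)),
        events=events,
    )
    return log.validate()
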