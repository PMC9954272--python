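"""Paradigm geometry and acquisition constants.

The evaluation scene is a 2D tablet screen holding an inert sphere, four
target cubes (top / bottom / left / right of the start position) and one
transverse (horizontal) obstacle that must be crossed to reach the top cube.
Every other module consumes a validated :class:`SceneConfig`.

Coordinate convention: origin at the bottom-left of the screen, x rightward,
y upward; "above the obstacle" means ``y > obstacle_y_px``. All distances
are in pixels, all times in seconds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import yaml

CUBE_IDS = ("top", "bottom", "left", "right")


class SceneError(ValueError):
    """A scene invariant is violated; the message names the invariant."""


def _default_cubes() -> dict[str, tuple[float, float]]:
    return {
        "left": (480.0, 500.0),
        "right": (2080.0, 500.0),
        "bottom": (1280.0, 150.0),
        "top": (1280.0, 1250.0),
    }


@dataclass(frozen=True)
class SceneConfig:
    """Geometry and sampling constants of the 2-minute evaluation scene.

    Defaults describe a 2560x1600 px tablet screen with the sphere starting
    below the obstacle and the top cube above it. The screen resolution and
    the acquisition constants (120 s cap, 60 Hz sampling) are fixed by the
    paradigm; the cube/obstacle placement is a configurable package default.
    """

    screen_width_px: float = 2560.0
    screen_height_px: float = 1600.0
    sphere_start: tuple[float, float] = (1280.0, 500.0)
    sphere_radius_px: float = 40.0
    cube_centers: Mapping[str, tuple[float, float]] = field(default_factory=_default_cubes)
    cube_half_size_px: float = 50.0
    obstacle_y_px: float = 850.0
    obstacle_x_min_px: float = 880.0
    obstacle_x_max_px: float = 1680.0
    obstacle_thickness_px: float = 20.0
    t_max_s: float = 120.0
    sample_rate_hz: float = 60.0

    @property
    def count_max(self) -> int:
        """Maximum cumulative number of samples, T * SR (7200 by default)."""
        return int(round(self.t_max_s * self.sample_rate_hz))

    @property
    def contact_distance_px(self) -> float:
        """Center distance at which the sphere eliminates a cube."""
        return self.sphere_radius_px + self.cube_half_size_px

    def to_dict(self) -> dict:
        d = asdict(self)
        d["sphere_start"] = list(self.sphere_start)
        d["cube_centers"] = {k: list(v) for k, v in self.cube_centers.items()}
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SceneConfig":
        d = dict(d)
        if "sphere_start" in d:
            d["sphere_start"] = tuple(float(v) for v in d["sphere_start"])
        if "cube_centers" in d:
            d["cube_centers"] = {
                k: tuple(float(x) for x in v) for k, v in d["cube_centers"].items()
            }
        return cls(**d)


def validate_scene(cfg: SceneConfig) -> SceneConfig:
    """Validate every scene invariant; return ``cfg`` unchanged if all hold.

    Raises :class:`SceneError` naming the first violated invariant.
    Idempotent: validating a validated scene is a no-op.
    """
    if cfg.t_max_s <= 0 or cfg.sample_rate_hz <= 0:
        raise SceneError("count-max-not-positive: t_max_s and sample_rate_hz must be > 0")
    n = cfg.t_max_s * cfg.sample_rate_hz
    if abs(n - round(n)) > 1e-9 or round(n) <= 0:
        raise SceneError("count-max-not-integer: t_max_s * sample_rate_hz must be a positive integer")
    if cfg.sphere_radius_px <= 0:
        raise SceneError("sphere-radius-not-positive")
    if cfg.cube_half_size_px <= 0:
        raise SceneError("cube-half-size-not-positive")
    if not cfg.obstacle_x_min_px < cfg.obstacle_x_max_px:
        raise SceneError("obstacle-extent-empty: obstacle_x_min_px must be < obstacle_x_max_px")

    if set(cfg.cube_centers) != set(CUBE_IDS):
        raise SceneError(f"cube-ids-wrong: expected exactly {CUBE_IDS}")
    centers = list(cfg.cube_centers.values())
    for i, a in enumerate(centers):
        for b in centers[i + 1 :]:
            if a == b:
                raise SceneError("cube-centers-coincide")
    for cid, (x, y) in cfg.cube_centers.items():
        if not (0 < x < cfg.screen_width_px and 0 < y < cfg.screen_height_px):
            raise SceneError(f"cube-outside-screen: {cid}")

    if not cfg.cube_centers["top"][1] > cfg.obstacle_y_px:
        raise SceneError("crossing-impossible: top cube must lie strictly above the obstacle")
    if not cfg.sphere_start[1] < cfg.obstacle_y_px:
        raise SceneError("crossing-impossible: sphere start must lie strictly below the obstacle")
    return cfg


def load_scene(path: str | Path) -> SceneConfig:
    """Load a scene from a JSON or YAML file with a top-level ``scene`` block
    (or the fields directly at top level)."""
    text = Path(path).read_text()
    data = yaml.safe_load(text) if not str(path).endswith(".json") else json.loads(text)
    if isinstance(data, dict) and "scene" in data:
        data = data["scene"]
    return validate_scene(SceneConfig.from_dict(data))


DEFAULT_SCENE = validate_scene(SceneConfig())
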