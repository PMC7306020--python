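"""Station-indexed fetal-head descent trajectories.

The head pose (anterior and caudal displacement, internal rotation, flexion)
is parameterised by obstetric station — centimetres relative to the
ischial-spine plane, negative above — and interpolated piecewise-linearly
between configured waypoints.  Linear progression between stations is a
deliberate simplification of real labour kinetics.

Two default configurations ship with the package: occiput posterior (OP),
entering at 45 deg internal rotation that completes at station +3, with 20
deg flexion reached in the midpelvis; and occiput anterior (OA), whose
rotation completes at station 0.  Intermediate displacement magnitudes are
documented placeholders (see the data file) — the module's contract is the
interpolation, not anatomical ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "Waypoint",
    "StationPose",
    "TrajectoryConfig",
    "default_trajectory",
    "pose_at_station",
    "trajectory_table",
    "load_trajectory_config",
]

_POSE_FIELDS = ("anterior_mm", "caudal_mm", "internal_rotation_deg", "flexion_deg")


@dataclass(frozen=True)
class Waypoint:
    station: float                # cm, obstetric scale
    anterior_mm: float
    caudal_mm: float
    internal_rotation_deg: float
    flexion_deg: float


@dataclass(frozen=True)
class StationPose:
    station: float
    anterior_mm: float
    caudal_mm: float
    internal_rotation_deg: float
    flexion_deg: float


@dataclass(frozen=True)
class TrajectoryConfig:
    """Waypoint table for one presentation (OP or OA)."""

    presentation: str
    waypoints: tuple[Waypoint, ...]
    rotation_complete_station: float

    def __post_init__(self) -> None:
        if self.presentation not in ("OP", "OA"):
            raise ValueError("presentation must be 'OP' or 'OA'")
        wps = tuple(w if isinstance(w, Waypoint) else Waypoint(**w)
                    for w in self.waypoints)
        object.__setattr__(self, "waypoints", wps)
        stations = [w.station for w in wps]
        if len(wps) < 2 or np.any(np.diff(stations) <= 0):
            raise ValueError("waypoint stations must be strictly increasing "
                             "with at least two waypoints")
        if stations[0] > -3 or stations[-1] < 8:
            raise ValueError("trajectory must cover stations -3 through +8")
        if self.presentation == "OP":
            if wps[0].internal_rotation_deg != 45.0:
                raise ValueError("OP descent starts at 45 deg internal rotation")
            if abs(pose_at_station(self, self.rotation_complete_station,
                                   _validate=False).internal_rotation_deg) > 1e-9:
                raise ValueError(
                    "internal rotation must reach 0 at rotation_complete_station")

    @property
    def station_range(self) -> tuple[float, float]:
        return (self.waypoints[0].station, self.waypoints[-1].station)

    @property
    def total_anterior_displacement_mm(self) -> float:
        return self.waypoints[-1].anterior_mm - self.waypoints[0].anterior_mm

    def to_dict(self) -> dict:
        return {
            "presentation": self.presentation,
            "rotation_complete_station": self.rotation_complete_station,
            "waypoints": [asdict(w) for w in self.waypoints],
        }


def default_trajectory(presentation: str = "OP") -> TrajectoryConfig:
    """The packaged default OP or OA waypoint table."""
    data = json.loads(
        resources.files("pelvimech.data").joinpath("trajectories.json")
        .read_text())
    if presentation not in data:
        raise ValueError(f"no default trajectory for {presentation!r}")
    return _config_from_dict(data[presentation])


def _config_from_dict(d: dict) -> TrajectoryConfig:
    return TrajectoryConfig(
        presentation=d["presentation"],
        waypoints=tuple(Waypoint(**w) for w in d["waypoints"]),
        rotation_complete_station=float(d["rotation_complete_station"]))


def load_trajectory_config(path: str | Path) -> TrajectoryConfig:
    """Read a TrajectoryConfig from a YAML or JSON file."""
    text = Path(path).read_text()
    d = yaml.safe_load(text)  # YAML is a superset of JSON
    return _config_from_dict(d)


def pose_at_station(config: TrajectoryConfig, station: float,
                    _validate: bool = True) -> StationPose:
    """Component-wise linear interpolation between the bracketing waypoints."""
    stations = np.array([w.station for w in config.waypoints])
    if _validate and not (stations[0] <= station <= stations[-1]):
        raise ValueError(
            f"station {station} outside trajectory range "
            f"[{stations[0]}, {stations[-1]}]")
    values = {f: float(np.interp(station,
                                 stations,
                                 [getattr(w, f) for w in config.waypoints]))
              for f in _POSE_FIELDS}
    return StationPose(station=float(station), **values)


def trajectory_table(config: TrajectoryConfig, step: float) -> list[StationPose]:
    """Poses from the range start to its end inclusive, at the given step (cm)."""
    if step <= 0:
        raise ValueError("step must be positive")
    lo, hi = config.station_range
    n = int(round((hi - lo) / step))
    stations = lo + step * np.arange(n + 1)
    stations = stations[stations <= hi + 1e-9]
    if stations[-1] < hi - 1e-9:
        stations = np.append(stations, hi)
    return [pose_at_station(config, float(s)) for s in stations]


def trajectory_dataframe(config: TrajectoryConfig, step: float) -> pd.DataFrame:
    return pd.DataFrame([asdict(p) for p in trajectory_table(config, step)])
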