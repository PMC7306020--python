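"""Reduction of raw uniaxial tensile records to nominal stress-stretch curves.

Nominal (engineering) conventions throughout: stress is the measured force
divided by the *initial* cross-section (N/mm^2 = MPa, so no unit constants
appear), strain is elongation over the initial gauge length, and the stretch
is lambda = 1 + strain.  Records that contain preconditioning cycles are
reduced from their final monotone loading ramp only (the longest suffix with
non-decreasing elongation).  Rupture is detected as a drop of the stress
below a fraction of its running maximum and the curve truncated there.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SpecimenGeometry",
    "SpecimenRecord",
    "StressStrainCurve",
    "cross_section_area",
    "to_stress_strain",
    "truncate_at_rupture",
    "final_loading_ramp",
    "read_specimen_csv",
    "write_specimen_csv",
    "read_curve_csv",
    "write_curve_csv",
]


@dataclass(frozen=True)
class SpecimenGeometry:
    """Cuboid specimen dimensions in mm (typical: 6 wide, 4 thick, 5 or 10 long)."""

    width_mm: float
    thickness_mm: float
    gauge_length_mm: float

    def __post_init__(self) -> None:
        for name in ("width_mm", "thickness_mm", "gauge_length_mm"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be strictly positive, got {v!r}")


def cross_section_area(geometry: SpecimenGeometry) -> float:
    """Initial cross-sectional area in mm^2 (rectangular cuboid: width x thickness)."""
    return geometry.width_mm * geometry.thickness_mm


@dataclass(frozen=True)
class SpecimenRecord:
    """One raw uniaxial test: time (s), grip elongation (mm), force (N)."""

    specimen_id: str
    geometry: SpecimenGeometry
    time_s: np.ndarray
    elongation_mm: np.ndarray
    force_n: np.ndarray

    def __post_init__(self) -> None:
        for name in ("time_s", "elongation_mm", "force_n"):
            object.__setattr__(self, name,
                               np.asarray(getattr(self, name), dtype=float))
        n = len(self.time_s)
        if n < 2 or len(self.elongation_mm) != n or len(self.force_n) != n:
            raise ValueError("series must have equal length >= 2")
        if np.any(np.diff(self.time_s) <= 0):
            raise ValueError("time must be strictly increasing")
        if self.elongation_mm[0] < 0:
            raise ValueError("elongation must be non-negative at the start")


@dataclass(frozen=True)
class StressStrainCurve:
    """Reduced curve: stretch lambda = 1 + strain vs nominal stress (MPa)."""

    specimen_id: str
    stretch: np.ndarray
    strain: np.ndarray
    nominal_stress_mpa: np.ndarray

    def __post_init__(self) -> None:
        for name in ("stretch", "strain", "nominal_stress_mpa"):
            object.__setattr__(self, name,
                               np.asarray(getattr(self, name), dtype=float))
        n = len(self.stretch)
        if len(self.strain) != n or len(self.nominal_stress_mpa) != n or n == 0:
            raise ValueError("curve series must be non-empty and of equal length")
        if not np.allclose(self.stretch, 1.0 + self.strain, rtol=0, atol=1e-12):
            raise ValueError("stretch must equal 1 + strain element-wise")
        if self.stretch[0] < 1.0 - 1e-12:
            raise ValueError("curve must start at or above the reference stretch 1")

    def __len__(self) -> int:
        return len(self.stretch)

    @property
    def max_stress_mpa(self) -> float:
        return float(np.max(self.nominal_stress_mpa))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "stretch": self.stretch,
            "strain": self.strain,
            "nominal_stress_mpa": self.nominal_stress_mpa,
        })


def final_loading_ramp(record: SpecimenRecord) -> SpecimenRecord:
    """Longest suffix of the record with non-decreasing elongation.

    Preconditioning cycles (e.g. 20 triangular cycles to 15% strain) are
    thereby discarded; for a plain monotone ramp this is the identity.
    """
    elong = record.elongation_mm
    start = 0
    for i in range(len(elong) - 1, 0, -1):
        if elong[i] < elong[i - 1]:
            start = i
            break
    if start == 0:
        return record
    return replace(record,
                   time_s=record.time_s[start:],
                   elongation_mm=record.elongation_mm[start:],
                   force_n=record.force_n[start:])


def to_stress_strain(record: SpecimenRecord) -> StressStrainCurve:
    """Reduce a raw record to a nominal stress-stretch curve.

    stress_i = force_i / (width * thickness) in MPa, strain_i = elongation_i /
    gauge length, always against the *initial* geometry.  Only the final
    monotone loading ramp is reduced.
    """
    ramp = final_loading_ramp(record)
    area = cross_section_area(record.geometry)
    if area <= 0:
        raise ValueError("cross-sectional area must be positive")
    strain = ramp.elongation_mm / record.geometry.gauge_length_mm
    stress = ramp.force_n / area
    return StressStrainCurve(record.specimen_id, 1.0 + strain, strain, stress)


def truncate_at_rupture(curve: StressStrainCurve,
                        drop_fraction: float = 0.2) -> StressStrainCurve:
    """Cut the curve at rupture.

    Rupture is the first sample from which the stress never again recovers
    above ``(1 - drop_fraction) * running maximum``; the returned curve is
    the prefix strictly before that sample.  Without such a permanent drop
    the curve is returned unchanged.  Idempotent.  Demanding that the drop
    be permanent (suffix maximum below the threshold, not just the sample
    itself) keeps isolated noise dips from registering as failure — rupture
    is a collapse, not a one-sample excursion.
    """
    if not (0.0 < drop_fraction < 1.0):
        raise ValueError("drop_fraction must lie in (0, 1)")
    stress = curve.nominal_stress_mpa
    running_max = np.maximum.accumulate(stress)
    suffix_max = np.maximum.accumulate(stress[::-1])[::-1]
    below = suffix_max < (1.0 - drop_fraction) * running_max
    if not np.any(below):
        return curve
    cut = int(np.argmax(below))
    return StressStrainCurve(curve.specimen_id,
                             curve.stretch[:cut],
                             curve.strain[:cut],
                             curve.nominal_stress_mpa[:cut])


# ---------------------------------------------------------------------------
# CSV interfaces.  A specimen file carries its geometry in '#'-comment header
# lines ahead of the time/elongation/force columns; one file per specimen.

def write_specimen_csv(record: SpecimenRecord, path: str | Path) -> None:
    path = Path(path)
    meta = {
        "specimen_id": record.specimen_id,
        "width_mm": record.geometry.width_mm,
        "thickness_mm": record.geometry.thickness_mm,
        "gauge_length_mm": record.geometry.gauge_length_mm,
    }
    with open(path, "w") as fh:
        for k, v in meta.items():
            fh.write(f"# {k} = {v!r}\n" if isinstance(v, str) else f"# {k} = {v}\n")
        pd.DataFrame({
            "time_s": record.time_s,
            "elongation_mm": record.elongation_mm,
            "force_n": record.force_n,
        }).to_csv(fh, index=False)


def _read_commented_csv(path: Path) -> tuple[dict, pd.DataFrame]:
    meta: dict = {}
    lines = path.read_text().splitlines(keepends=True)
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            key, _, value = line.lstrip("# ").partition("=")
            meta[key.strip()] = value.strip().strip("'\"")
        else:
            body_start = i
            break
    df = pd.read_csv(io.StringIO("".join(lines[body_start:])))
    return meta, df


def read_specimen_csv(path: str | Path) -> SpecimenRecord:
    path = Path(path)
    meta, df = _read_commented_csv(path)
    sidecar = path.with_suffix(".json")
    if not meta and sidecar.exists():
        meta = json.loads(sidecar.read_text())
    required = {"specimen_id", "width_mm", "thickness_mm", "gauge_length_mm"}
    missing = required - meta.keys()
    if missing:
        raise ValueError(f"specimen metadata missing {sorted(missing)} in {path}")
    geom = SpecimenGeometry(float(meta["width_mm"]), float(meta["thickness_mm"]),
                            float(meta["gauge_length_mm"]))
    return SpecimenRecord(str(meta["specimen_id"]), geom,
                          df["time_s"].to_numpy(),
                          df["elongation_mm"].to_numpy(),
                          df["force_n"].to_numpy())


def write_curve_csv(curve: StressStrainCurve, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# specimen_id = {curve.specimen_id}\n")
        fh.write("# units: nominal_stress_mpa in MPa; stretch, strain dimensionless\n")
        curve.to_dataframe().to_csv(fh, index=False)


def read_curve_csv(path: str | Path) -> StressStrainCurve:
    meta, df = _read_commented_csv(Path(path))
    return StressStrainCurve(meta.get("specimen_id", Path(path).stem),
                             df["stretch"].to_numpy(),
                             df["strain"].to_numpy(),
                             df["nominal_stress_mpa"].to_numpy())
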