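"""Synthetic uniaxial tensile-test cohorts with a known ground truth.

The generator runs the measurement forward: a cuboid levator specimen
(nominally 6 x 4 mm cross-section, 5 or 10 mm gauge) is extended at constant
velocity (6 mm/min) while force is sampled on a uniform time grid, with

    elongation(t) = v t,     force(t) = P(lambda(t)) * A0 + noise,

where P is the two-term Ogden nominal stress of the specimen's ground-truth
parameters and A0 the initial cross-section.  Noise is additive Gaussian on
the force with standard deviation ``force_noise_rel`` times the peak
noiseless force.  The record ends with a sharp post-rupture force drop so
the rupture-truncation stage has something to cut.  Ground truth defaults to
the packaged 20-specimen cohort table, so the full pipeline (generate ->
reduce -> fit -> summarise) can be exercised against known parameters.

Everything is deterministic under the spec's seed: per-specimen seeds are
spawned from the cohort seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .cohort_data import load_cohort_parameters
from .ogden import OgdenParameters, uniaxial_nominal_stress
from .tensile import SpecimenGeometry, SpecimenRecord, cross_section_area

__all__ = ["CohortSpec", "generate_specimen", "generate_cohort"]

_POST_RUPTURE_FORCE_FRACTIONS = (0.45, 0.15, 0.05)


@dataclass(frozen=True)
class CohortSpec:
    """Study design of a synthetic tensile cohort.

    Defaults mirror the physical experiment being emulated: 20 specimens,
    ~6 x 4 mm cross-sections with 10 mm gauge, 6 mm/min loading, ground
    truth fixed to the packaged cohort table.  The 10 Hz sampling rate,
    the (1.4, 2.0) rupture-stretch window and the 0.5% relative force noise
    are generator choices (the experiment reports none of the three).
    """

    n_specimens: int = 20
    geometry_mean: SpecimenGeometry = SpecimenGeometry(6.0, 4.0, 10.0)
    geometry_sd: tuple[float, float, float] = (0.3, 0.2, 0.0)
    truth_mode: str = "fixed-table"          # or "sampled"
    truth_table: tuple[OgdenParameters, ...] | None = None
    loading_velocity_mm_per_min: float = 6.0
    sample_rate_hz: float = 10.0
    rupture_stretch_range: tuple[float, float] = (1.4, 2.0)
    force_noise_rel: float = 0.005
    include_preconditioning: bool = False
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_specimens < 1:
            raise ValueError("n_specimens must be >= 1")
        if self.force_noise_rel < 0:
            raise ValueError("force_noise_rel must be >= 0")
        lo, hi = self.rupture_stretch_range
        if not (1.0 < lo <= hi < 4.0):
            raise ValueError("rupture_stretch_range must lie within (1, 4)")
        if self.truth_mode not in ("fixed-table", "sampled"):
            raise ValueError("truth_mode must be 'fixed-table' or 'sampled'")
        if self.loading_velocity_mm_per_min <= 0 or self.sample_rate_hz <= 0:
            raise ValueError("velocity and sample rate must be positive")

    def resolved_truth_table(self) -> tuple[OgdenParameters, ...]:
        if self.truth_table is not None:
            return tuple(self.truth_table)
        return tuple(load_cohort_parameters())


def _preconditioning(geometry: SpecimenGeometry, truth: OgdenParameters,
                     velocity_mm_s: float, dt: float) -> tuple[np.ndarray, np.ndarray]:
    """20 triangular elongation cycles to 15% strain at the loading velocity."""
    peak = 0.15 * geometry.gauge_length_mm
    half = max(2, int(round(peak / (velocity_mm_s * dt))))
    up = np.linspace(0.0, peak, half, endpoint=False)
    down = np.linspace(peak, 0.0, half, endpoint=False)
    cycle = np.concatenate([up, down])
    elong = np.tile(cycle, 20)
    area = cross_section_area(geometry)
    lam = 1.0 + elong / geometry.gauge_length_mm
    force = uniaxial_nominal_stress(truth, lam) * area
    return elong, force


def generate_specimen(truth: OgdenParameters, geometry: SpecimenGeometry,
                      spec: CohortSpec, seed: int | np.random.SeedSequence,
                      specimen_id: str = "synthetic") -> SpecimenRecord:
    """Forward-simulate one uniaxial test record.

    The ramp samples lie on a uniform grid at ``sample_rate_hz`` from t = 0
    (zero force) until the rupture stretch — drawn uniformly from
    ``rupture_stretch_range`` — is reached; three post-rupture samples with
    sharply dropping force follow.
    """
    rng = np.random.default_rng(seed)
    v = spec.loading_velocity_mm_per_min / 60.0       # mm/s
    dt = 1.0 / spec.sample_rate_hz
    area = cross_section_area(geometry)
    l0 = geometry.gauge_length_mm

    lam_rupture = rng.uniform(*spec.rupture_stretch_range)
    t_rupture = (lam_rupture - 1.0) * l0 / v
    n_ramp = int(np.floor(t_rupture / dt)) + 1        # includes t = 0
    t = dt * np.arange(n_ramp)
    elong = v * t
    lam = 1.0 + elong / l0
    force = uniaxial_nominal_stress(truth, lam) * area

    # post-rupture tail: elongation keeps ramping, force collapses
    n_tail = len(_POST_RUPTURE_FORCE_FRACTIONS)
    t_tail = dt * (np.arange(n_tail) + n_ramp)
    elong_tail = v * t_tail
    force_tail = force[-1] * np.asarray(_POST_RUPTURE_FORCE_FRACTIONS)

    t = np.concatenate([t, t_tail])
    elong = np.concatenate([elong, elong_tail])
    force = np.concatenate([force, force_tail])

    if spec.force_noise_rel > 0:
        sd = spec.force_noise_rel * float(np.max(force))
        force = force + rng.normal(0.0, sd, size=len(force))

    if spec.include_preconditioning:
        pe, pf = _preconditioning(geometry, truth, v, dt)
        pt = dt * np.arange(len(pe))
        t = np.concatenate([pt, pt[-1] + dt + t])
        elong = np.concatenate([pe, elong])
        force = np.concatenate([pf, force])

    return SpecimenRecord(specimen_id, geometry, t, elong, force)


def generate_cohort(spec: CohortSpec) -> tuple[list[SpecimenRecord],
                                               dict[str, OgdenParameters]]:
    """Generate ``spec.n_specimens`` records plus a ground-truth manifest.

    Per-specimen randomness (geometry jitter, rupture stretch, noise) is
    spawned deterministically from ``spec.rng_seed``.  In ``fixed-table``
    mode specimen i takes row i of the truth table; ``sampled`` mode draws
    rows with replacement.
    """
    table = spec.resolved_truth_table()
    if spec.truth_mode == "fixed-table" and len(table) < spec.n_specimens:
        raise ValueError(
            f"truth table has {len(table)} rows but {spec.n_specimens} "
            "specimens were requested in fixed-table mode")

    root = np.random.SeedSequence(spec.rng_seed)
    picker_seed, *specimen_seeds = root.spawn(spec.n_specimens + 1)
    picker = np.random.default_rng(picker_seed)

    records: list[SpecimenRecord] = []
    manifest: dict[str, OgdenParameters] = {}
    gm, gsd = spec.geometry_mean, spec.geometry_sd
    for i, sseq in enumerate(specimen_seeds):
        rng = np.random.default_rng(sseq)
        dims = [
            max(0.2, rng.normal(m, s)) if s > 0 else m
            for m, s in zip((gm.width_mm, gm.thickness_mm, gm.gauge_length_mm),
                            gsd)
        ]
        geometry = SpecimenGeometry(*dims)
        truth = (table[i] if spec.truth_mode == "fixed-table"
                 else table[picker.integers(len(table))])
        sid = f"specimen_{i + 1:02d}"
        records.append(generate_specimen(truth, geometry, spec,
                                         rng.integers(2 ** 31), sid))
        manifest[sid] = truth
    return records, manifest
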