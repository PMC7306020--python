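"""Incompressible N-term Ogden hyperelastic model and stress utilities.

The strain-energy density is expressed in principal stretches with a
``2 mu_j / alpha_j`` prefactor per term,

    W = sum_i sum_j 2 (mu_j / alpha_j) ((J^(-1/3) lambda_i)^alpha_j - 1)
        + (K / 2) (J - 1)^2,

which differs from the classical Ogden convention (``mu_j / alpha_j``) by a
factor of two in each shear modulus; :func:`to_classical` and
:func:`from_classical` convert between the two.  All stresses are in MPa
(N/mm^2), stretches are dimensionless.  Under exact incompressibility
(J = 1) the volumetric penalty K plays no role, and the uniaxial nominal
(first Piola-Kirchhoff) stress has the closed form

    P(lambda) = sum_j 2 mu_j (lambda^(alpha_j - 1) - lambda^(-alpha_j/2 - 1)).

The small-strain shear modulus of the model is sum_j mu_j alpha_j; material
stability requires it to be positive, and the uniaxial tangent stiffness at
lambda = 1 is 3 sum_j mu_j alpha_j.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "OgdenTerm",
    "OgdenParameters",
    "DeformationState",
    "strain_energy",
    "uniaxial_nominal_stress",
    "initial_tangent_modulus",
    "von_mises",
    "to_classical",
    "from_classical",
]

_INCOMPRESSIBILITY_TOL = 1e-12


@dataclass(frozen=True)
class OgdenTerm:
    """One (mu_j, alpha_j) pair; mu in MPa, alpha dimensionless."""

    mu_mpa: float
    alpha: float

    def __post_init__(self) -> None:
        if self.alpha == 0.0:
            raise ZeroDivisionError(
                "Ogden exponent alpha must be nonzero: the strain energy "
                "carries a mu/alpha prefactor and alpha = 0 divides by zero"
            )
        if not np.isfinite(self.mu_mpa) or not np.isfinite(self.alpha):
            raise ValueError("Ogden term parameters must be finite")


@dataclass(frozen=True)
class OgdenParameters:
    """Constitutive constants of one material.

    Parameters
    ----------
    terms
        The (mu_j, alpha_j) pairs.  Two terms is the working default for
        passive levator ani tissue.
    bulk_k_mpa
        Volumetric penalty modulus K.  Unused on the exactly incompressible
        uniaxial path; carried for completeness.
    """

    terms: tuple[OgdenTerm, ...]
    bulk_k_mpa: float = 0.0
    check_stability: bool = field(default=True, compare=False, repr=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "terms", tuple(
            t if isinstance(t, OgdenTerm) else OgdenTerm(*t) for t in self.terms
        ))
        if len(self.terms) == 0:
            raise ValueError("at least one Ogden term is required")
        if self.check_stability and self.shear_stability_sum <= 0.0:
            raise ValueError(
                "unstable Ogden parameters: sum(mu_j * alpha_j) = "
                f"{self.shear_stability_sum:g} must be > 0 (positive "
                "small-strain shear modulus)"
            )

    @property
    def n_terms(self) -> int:
        return len(self.terms)

    @property
    def mus(self) -> np.ndarray:
        return np.array([t.mu_mpa for t in self.terms])

    @property
    def alphas(self) -> np.ndarray:
        return np.array([t.alpha for t in self.terms])

    @property
    def shear_stability_sum(self) -> float:
        """sum_j mu_j alpha_j; must be positive for a stable material."""
        return float(sum(t.mu_mpa * t.alpha for t in self.terms))

    @classmethod
    def from_arrays(cls, mus: Sequence[float], alphas: Sequence[float],
                    bulk_k_mpa: float = 0.0) -> "OgdenParameters":
        if len(mus) != len(alphas):
            raise ValueError("mus and alphas must have equal length")
        return cls(tuple(OgdenTerm(float(m), float(a))
                         for m, a in zip(mus, alphas)), bulk_k_mpa)

    def sorted_by_alpha(self) -> "OgdenParameters":
        """Terms reordered by ascending alpha (low-exponent term first)."""
        return OgdenParameters(
            tuple(sorted(self.terms, key=lambda t: t.alpha)), self.bulk_k_mpa)

    # -- JSON round trip (lossless via repr-level float serialisation) ------

    def to_dict(self) -> dict:
        return {
            "terms": [{"mu_mpa": t.mu_mpa, "alpha": t.alpha} for t in self.terms],
            "bulk_k_mpa": self.bulk_k_mpa,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "OgdenParameters":
        return cls(tuple(OgdenTerm(t["mu_mpa"], t["alpha"]) for t in d["terms"]),
                   float(d.get("bulk_k_mpa", 0.0)))

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, s: str) -> "OgdenParameters":
        return cls.from_dict(json.loads(s))


@dataclass(frozen=True)
class DeformationState:
    """A homogeneous principal-stretch deformation, F = diag(l1, l2, l3)."""

    principal_stretches: tuple[float, float, float]

    def __post_init__(self) -> None:
        ls = tuple(float(x) for x in self.principal_stretches)
        if len(ls) != 3 or any(x <= 0 for x in ls):
            raise ValueError("principal stretches must be three positive numbers")
        object.__setattr__(self, "principal_stretches", ls)

    @property
    def deformation_gradient(self) -> np.ndarray:
        return np.diag(self.principal_stretches)

    @property
    def jacobian(self) -> float:
        l1, l2, l3 = self.principal_stretches
        return l1 * l2 * l3

    @property
    def is_incompressible(self) -> bool:
        return abs(self.jacobian - 1.0) <= _INCOMPRESSIBILITY_TOL

    @classmethod
    def uniaxial(cls, stretch: float) -> "DeformationState":
        """Incompressible uniaxial extension: l2 = l3 = stretch^(-1/2)."""
        if stretch <= 0:
            raise ValueError("stretch must be positive")
        lat = stretch ** -0.5
        return cls((float(stretch), lat, lat))


def strain_energy(params: OgdenParameters, state: DeformationState) -> float:
    """Strain-energy density W in MPa for the given deformation.

    The deviatoric part sums ``2 mu_j/alpha_j ((J^(-1/3) lambda_i)^alpha_j - 1)``
    over the three principal stretches and all terms; the volumetric penalty
    ``(K/2)(J-1)^2`` vanishes for incompressible states.
    """
    j = state.jacobian
    lam_bar = np.asarray(state.principal_stretches) * j ** (-1.0 / 3.0)
    w = 0.0
    for t in params.terms:
        w += 2.0 * t.mu_mpa / t.alpha * float(np.sum(lam_bar ** t.alpha - 1.0))
    w += 0.5 * params.bulk_k_mpa * (j - 1.0) ** 2
    return float(w)


def uniaxial_nominal_stress(params: OgdenParameters, stretch):
    """Nominal (first Piola) stress P = dW/dlambda on the incompressible
    uniaxial path, in MPa.

    Accepts a scalar stretch or an array; vectorised closed form

        P = sum_j 2 mu_j (lambda^(alpha_j - 1) - lambda^(-alpha_j/2 - 1)).
    """
    lam = np.asarray(stretch, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("stretch must be positive")
    p = np.zeros_like(lam)
    for t in params.terms:
        p = p + 2.0 * t.mu_mpa * (lam ** (t.alpha - 1.0)
                                  - lam ** (-t.alpha / 2.0 - 1.0))
    if np.isscalar(stretch) or np.ndim(stretch) == 0:
        return float(p)
    return p


def initial_tangent_modulus(params: OgdenParameters) -> float:
    """Uniaxial tangent stiffness dP/dlambda at lambda = 1: 3 sum_j mu_j alpha_j."""
    return 3.0 * params.shear_stability_sum


def von_mises(principal_stresses) -> float:
    """von Mises equivalent of a principal stress triple (MPa).

    sqrt(0.5 [(s1-s2)^2 + (s2-s3)^2 + (s3-s1)^2]); zero iff hydrostatic.
    """
    s1, s2, s3 = (float(s) for s in principal_stresses)
    if not all(np.isfinite([s1, s2, s3])):
        raise ValueError("principal stresses must be finite")
    return float(np.sqrt(0.5 * ((s1 - s2) ** 2 + (s2 - s3) ** 2 + (s3 - s1) ** 2)))


def to_classical(params: OgdenParameters) -> OgdenParameters:
    """Convert to the classical Ogden convention (classical mu = 2 mu)."""
    return OgdenParameters.from_arrays(2.0 * params.mus, params.alphas,
                                       params.bulk_k_mpa)


def from_classical(params: OgdenParameters) -> OgdenParameters:
    """Convert classical-convention parameters into this package's convention."""
    return OgdenParameters.from_arrays(params.mus / 2.0, params.alphas,
                                       params.bulk_k_mpa)
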