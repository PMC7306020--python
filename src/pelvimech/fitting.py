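"""Constrained least-squares identification of Ogden parameters.

The objective is the unweighted half-sum-of-squares stress error

    E = 1/2 sum_i (P_i^test - P_i^model)^2        [MPa^2]

over the reduced stress-stretch samples, minimised over (mu_j, alpha_j)
within box bounds by trust-region-reflective nonlinear least squares with
seeded multistarts.  The default bounds keep every parameter positive, so
the material-stability inequality sum_j mu_j alpha_j > 0 holds automatically
at every feasible point.  Ogden parameters are only weakly identifiable from
a single uniaxial curve — different (mu, alpha) pairs can produce nearly
identical stresses — so fit quality is judged on the predicted stress (RMSE),
not on parameter recovery, except in the one-term case.

The public surface follows the Model/Results pattern: build an
:class:`OgdenModel` from a curve (or DataFrame), call :meth:`OgdenModel.fit`,
and read estimates, diagnostics and a ``summary()`` table off the returned
:class:`OgdenFitResults`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .ogden import OgdenParameters, uniaxial_nominal_stress
from .tensile import StressStrainCurve

__all__ = [
    "FitConfig",
    "OgdenModel",
    "OgdenFitResults",
    "CohortSummary",
    "objective_e",
    "fit_ogden",
    "fit_cohort",
    "cohort_summary",
]

#: Default parameter box, wide enough to bracket every identified passive
#: levator ani value with >= 2x margin while keeping the feasible set
#: all-positive (stability automatic).
DEFAULT_MU_BOUNDS = (1e-6, 0.5)      # MPa
DEFAULT_ALPHA_BOUNDS = (1e-3, 50.0)  # dimensionless


@dataclass(frozen=True)
class FitConfig:
    """Configuration of the bounded multistart least-squares identification."""

    n_terms: int = 2
    mu_bounds: tuple[float, float] = DEFAULT_MU_BOUNDS
    alpha_bounds: tuple[float, float] = DEFAULT_ALPHA_BOUNDS
    n_multistarts: int = 32
    rng_seed: int = 0
    convergence_tol: float = 1e-12

    def __post_init__(self) -> None:
        if self.n_terms < 1:
            raise ValueError("n_terms must be >= 1")
        for name, (lo, hi) in (("mu_bounds", self.mu_bounds),
                               ("alpha_bounds", self.alpha_bounds)):
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ValueError(f"{name} must be finite with lower < upper")
        if self.mu_bounds[0] <= 0 or self.alpha_bounds[0] <= 0:
            raise ValueError(
                "lower bounds must be positive so that every feasible point "
                "satisfies the stability inequality sum(mu_j alpha_j) > 0")
        if self.n_multistarts < 1:
            raise ValueError("n_multistarts must be >= 1")

    @property
    def lower(self) -> np.ndarray:
        n = self.n_terms
        return np.r_[np.full(n, self.mu_bounds[0]),
                     np.full(n, self.alpha_bounds[0])]

    @property
    def upper(self) -> np.ndarray:
        n = self.n_terms
        return np.r_[np.full(n, self.mu_bounds[1]),
                     np.full(n, self.alpha_bounds[1])]


def objective_e(params: OgdenParameters, curve: StressStrainCurve) -> float:
    """The half-sum-of-squares stress error E in MPa^2."""
    resid = curve.nominal_stress_mpa - uniaxial_nominal_stress(params, curve.stretch)
    return 0.5 * float(np.dot(resid, resid))


def _unpack(x: np.ndarray, n: int) -> tuple[np.ndarray, np.ndarray]:
    return x[:n], x[n:]


def _residuals(x: np.ndarray, n: int, lam: np.ndarray,
               p_test: np.ndarray) -> np.ndarray:
    mus, alphas = _unpack(x, n)
    p = np.zeros_like(lam)
    for m, a in zip(mus, alphas):
        p += 2.0 * m * (lam ** (a - 1.0) - lam ** (-a / 2.0 - 1.0))
    return p - p_test


def _jacobian(x: np.ndarray, n: int, lam: np.ndarray,
              p_test: np.ndarray) -> np.ndarray:
    mus, alphas = _unpack(x, n)
    cols = []
    loglam = np.log(lam)
    for m, a in zip(mus, alphas):
        hi, lo = lam ** (a - 1.0), lam ** (-a / 2.0 - 1.0)
        cols.append(2.0 * (hi - lo))                      # d/d mu
    for m, a in zip(mus, alphas):
        hi, lo = lam ** (a - 1.0), lam ** (-a / 2.0 - 1.0)
        cols.append(2.0 * m * loglam * (hi + 0.5 * lo))   # d/d alpha
    return np.column_stack(cols)


class OgdenModel:
    """Ogden material model to be identified from one uniaxial curve.

    Parameters
    ----------
    curve
        Reduced nominal stress-stretch data for one specimen.
    config
        Fit configuration; defaults to the two-term setup with 32 seeded
        multistarts.
    """

    def __init__(self, curve: StressStrainCurve, config: FitConfig | None = None):
        self.config = config or FitConfig()
        n = self.config.n_terms
        if len(curve) < 2 * n + 1:
            raise ValueError(
                f"curve has {len(curve)} points; need >= {2 * n + 1} "
                f"for an {n}-term fit")
        span = float(np.max(curve.stretch) - np.min(curve.stretch))
        if span < 0.05:
            raise ValueError(
                f"stretch range {span:.4f} too narrow to identify parameters "
                "(need >= 0.05)")
        self.curve = curve

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, specimen_id: str = "specimen",
                       config: FitConfig | None = None) -> "OgdenModel":
        """Build from a DataFrame with a ``nominal_stress_mpa`` column and
        either a ``stretch`` or a ``strain`` column."""
        if "stretch" in df.columns:
            stretch = df["stretch"].to_numpy(dtype=float)
            strain = stretch - 1.0
        elif "strain" in df.columns:
            strain = df["strain"].to_numpy(dtype=float)
            stretch = 1.0 + strain
        else:
            raise ValueError("DataFrame needs a 'stretch' or 'strain' column")
        curve = StressStrainCurve(specimen_id, stretch, strain,
                                  df["nominal_stress_mpa"].to_numpy(dtype=float))
        return cls(curve, config)

    def _starting_points(self, k: int) -> np.ndarray:
        """k feasible starts, log-uniform per parameter, from the seeded rng.

        Draws are sequential from a single stream, so the start list for a
        larger ``n_multistarts`` extends (never reshuffles) the smaller one.
        """
        cfg = self.config
        rng = np.random.default_rng(cfg.rng_seed)
        lo, hi = np.log(cfg.lower), np.log(cfg.upper)
        return np.exp(rng.uniform(lo, hi, size=(k, 2 * cfg.n_terms)))

    def fit(self) -> "OgdenFitResults":
        """Identify the parameters; returns the best multistart solution."""
        cfg = self.config
        lam = self.curve.stretch
        p_test = self.curve.nominal_stress_mpa
        n = cfg.n_terms
        args = (n, lam, p_test)

        best = None
        best_index = -1
        any_converged = False
        for i, x0 in enumerate(self._starting_points(cfg.n_multistarts)):
            sol = least_squares(
                _residuals, x0, jac=_jacobian, args=args,
                bounds=(cfg.lower, cfg.upper), method="trf",
                xtol=cfg.convergence_tol, ftol=cfg.convergence_tol,
                gtol=cfg.convergence_tol, max_nfev=400)
            any_converged = any_converged or sol.status > 0
            if best is None or sol.cost < best.cost:
                best, best_index = sol, i

        mus, alphas = _unpack(best.x, n)
        params = OgdenParameters.from_arrays(mus, alphas).sorted_by_alpha()
        error_e = objective_e(params, self.curve)
        nd = len(self.curve)
        return OgdenFitResults(
            model=self, params=params, error_e=error_e,
            rmse_mpa=float(np.sqrt(2.0 * error_e / nd)), n_data=nd,
            converged=bool(any_converged), start_index=best_index)


@dataclass(frozen=True)
class OgdenFitResults:
    """Identified parameters plus diagnostics for one specimen."""

    model: OgdenModel
    params: OgdenParameters
    error_e: float        # MPa^2, = 1/2 sum residual^2
    rmse_mpa: float       # sqrt(2 E / ND)
    n_data: int
    converged: bool
    start_index: int      # which multistart won

    @property
    def specimen_id(self) -> str:
        return self.model.curve.specimen_id

    def predict(self, stretch=None):
        """Model stress at the given stretches (default: the fitted data's)."""
        if stretch is None:
            stretch = self.model.curve.stretch
        return uniaxial_nominal_stress(self.params, stretch)

    def summary(self) -> str:
        """Plain-text summary table of the identified material."""
        lines = [
            "Ogden material identification (uniaxial, incompressible)",
            "=" * 58,
            f"specimen:        {self.specimen_id}",
            f"data points ND:  {self.n_data}",
            f"terms N:         {self.params.n_terms}",
            f"objective E:     {self.error_e:.6e} MPa^2",
            f"stress RMSE:     {self.rmse_mpa:.6e} MPa",
            f"converged:       {self.converged}  (start #{self.start_index})",
            f"stability sum:   {self.params.shear_stability_sum:.6e} MPa (> 0)",
            "-" * 58,
            f"{'term':>4} {'mu [MPa]':>14} {'alpha [-]':>14}",
        ]
        for j, t in enumerate(self.params.terms, start=1):
            lines.append(f"{j:>4} {t.mu_mpa:>14.6g} {t.alpha:>14.6g}")
        lines.append("=" * 58)
        return "\n".join(lines)

    def plot_fit(self, ax=None):
        """Data vs fitted stress-stretch curve on a matplotlib axis."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        c = self.model.curve
        ax.plot(c.stretch, c.nominal_stress_mpa, ".", ms=3, label="data")
        grid = np.linspace(c.stretch.min(), c.stretch.max(), 200)
        ax.plot(grid, self.predict(grid), "-", label="Ogden fit")
        ax.set_xlabel("stretch $\\lambda$ [-]")
        ax.set_ylabel("nominal stress $P$ [MPa]")
        ax.set_title(self.specimen_id)
        ax.legend()
        return ax

    def to_dict(self) -> dict:
        return {
            "specimen_id": self.specimen_id,
            "params": self.params.to_dict(),
            "error_e_mpa2": self.error_e,
            "rmse_mpa": self.rmse_mpa,
            "n_data": self.n_data,
            "converged": self.converged,
            "start_index": self.start_index,
        }


def fit_ogden(curve: StressStrainCurve,
              config: FitConfig | None = None) -> OgdenFitResults:
    """Functional entry point: fit an Ogden material to one curve."""
    return OgdenModel(curve, config).fit()


def fit_cohort(curves: Sequence[StressStrainCurve],
               config: FitConfig | None = None) -> list[OgdenFitResults]:
    return [fit_ogden(c, config) for c in curves]


@dataclass(frozen=True)
class CohortSummary:
    """Per-parameter mean and population SD (divisor n) over a cohort."""

    mean_mus: np.ndarray
    sd_mus: np.ndarray
    mean_alphas: np.ndarray
    sd_alphas: np.ndarray
    n_specimens: int

    def to_dataframe(self) -> pd.DataFrame:
        n = len(self.mean_mus)
        rows = {}
        for j in range(n):
            rows[f"mu{j + 1}_mpa"] = [self.mean_mus[j], self.sd_mus[j]]
            rows[f"alpha{j + 1}"] = [self.mean_alphas[j], self.sd_alphas[j]]
        return pd.DataFrame(rows, index=["mean", "sd"])


def _as_params(obj) -> OgdenParameters:
    if isinstance(obj, OgdenParameters):
        return obj
    return obj.params


def cohort_summary(results: Iterable) -> CohortSummary:
    """Arithmetic mean and population SD per parameter over specimens.

    Accepts fit results or bare parameter sets.  The population convention
    (divisor n, not n-1) is the one under which the cohort statistics of the
    identified levator ani parameters reproduce their published summary row.
    """
    params = [_as_params(r) for r in results]
    if not params:
        raise ValueError("need at least one result")
    n_terms = params[0].n_terms
    if any(p.n_terms != n_terms for p in params):
        raise ValueError("all results must have the same number of terms")
    mus = np.array([p.mus for p in params])
    alphas = np.array([p.alphas for p in params])
    return CohortSummary(
        mean_mus=mus.mean(axis=0), sd_mus=mus.std(axis=0, ddof=0),
        mean_alphas=alphas.mean(axis=0), sd_alphas=alphas.std(axis=0, ddof=0),
        n_specimens=len(params))
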