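import numpy as np
import pytest

from pelvimech import (OgdenParameters, SpecimenGeometry, StressStrainCurve,
                       uniaxial_nominal_stress)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20190613)


@pytest.fixture(scope="session")
def standard_geometry():
    return SpecimenGeometry(6.0, 4.0, 10.0)


@pytest.fixture(scope="session")
def specimen9_params():
    """A representative identified two-term parameter set from the cohort."""
    return OgdenParameters.from_arrays([0.0029, 0.0584], [0.2267, 14.055])


def make_curve(params: OgdenParameters, lam_max: float = 1.6, n: int = 50,
               specimen_id: str = "synthetic") -> StressStrainCurve:
    """Noiseless stress-stretch curve generated directly from the law."""
    lam = np.linspace(1.0, lam_max, n)
    return StressStrainCurve(specimen_id, lam, lam - 1.0,
                             uniaxial_nominal_stress(params, lam))


def random_stable_params(rng, n_terms: int = 2) -> OgdenParameters:
    """Random all-positive (hence stable) parameter set in physiological ranges."""
    mus = rng.uniform(1e-4, 0.1, n_terms)
    alphas = rng.uniform(0.05, 25.0, n_terms)
    return OgdenParameters.from_arrays(mus, alphas)


@pytest.fixture(scope="session")
def regular_tet():
    """Positively oriented regular tetrahedron with edge length 2*sqrt(2)."""
    return np.array([[1.0, 1.0, 1.0], [1.0, -1.0, -1.0],
                     [-1.0, 1.0, -1.0], [-1.0, -1.0, 1.0]])[[0, 2, 1, 3]]


def regular_tet_with_edge(edge: float) -> np.ndarray:
    base = np.array([[1.0, 1.0, 1.0], [-1.0, 1.0, -1.0],
                     [1.0, -1.0, -1.0], [-1.0, -1.0, 1.0]])
    return base * (edge / (2.0 * np.sqrt(2.0)))
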