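"""The packaged per-specimen Ogden constants of the porcine levator cohort."""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .ogden import OgdenParameters

__all__ = ["load_cohort_table", "load_cohort_parameters"]


def load_cohort_table() -> pd.DataFrame:
    """The 20-specimen parameter table (mu in MPa, alpha dimensionless)."""
    with resources.files("pelvimech.data").joinpath(
            "levator_ogden_cohort.csv").open() as fh:
        return pd.read_csv(fh, comment="#")


def load_cohort_parameters() -> list[OgdenParameters]:
    """The cohort as two-term parameter sets, one per specimen."""
    df = load_cohort_table()
    return [
        OgdenParameters.from_arrays([row.mu1_mpa, row.mu2_mpa],
                                    [row.alpha1, row.alpha2])
        for row in df.itertuples()
    ]
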