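"""Bundled reference tables.

Two small published tables travel with the package: the 2016 regional
snakebite statistics for South Korea's 16 mainland cities and provinces
(population in millions, area, patient counts, and the printed
per-10,000 rate), and the reported per-species mean-decrease-Gini
importance values for the seven retained predictors. They power worked
examples and the regression checks on the incidence-rate and
median-importance arithmetic.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_snakebite_regions", "load_reported_importance"]


def _read(name: str) -> pd.DataFrame:
    with resources.files("habrisk.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_snakebite_regions() -> pd.DataFrame:
    """Regional snakebite statistics for South Korea, 2016.

    Columns: id, region, population_million, area_km2, snakebites,
    snakebites_per_10k (the published 2-decimal rate).
    """
    return _read("korea_snakebite_2016.csv")


def load_reported_importance() -> pd.DataFrame:
    """Published per-species mean decrease Gini for the retained predictors."""
    return _read("mdg_importance_reported.csv")
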