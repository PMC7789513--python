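"""Area-year mortality panels: ingest, validation, rates, descriptive summaries.

A panel holds live births ``n_it`` and child deaths ``y_it`` for every
area *i* and calendar year *t*.  All downstream modules index areas in the
lexicographic order of their ids, fixed here at ingest.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MortalityPanel",
    "DescriptiveSummary",
    "PanelValidationError",
    "read_panel",
    "compute_rates",
    "yearly_summary",
]


class PanelValidationError(ValueError):
    """Raised when a panel violates its structural invariants."""


@dataclass(frozen=True)
class MortalityPanel:
    """Complete area x year table of live births and child deaths.

    Parameters
    ----------
    area_ids
        N area identifiers, lexicographically sorted; this order is the
        canonical area index used by the adjacency matrix and every
        model vector.
    years
        T strictly increasing, consecutive calendar years.
    births
        (N, T) non-negative integers, every cell >= 1.
    deaths
        (N, T) non-negative integers with ``deaths <= births`` cellwise.
    """

    area_ids: tuple
    years: tuple
    births: np.ndarray = field(repr=False)
    deaths: np.ndarray = field(repr=False)

    def __post_init__(self):
        births = np.asarray(self.births, dtype=np.int64)
        deaths = np.asarray(self.deaths, dtype=np.int64)
        object.__setattr__(self, "area_ids", tuple(self.area_ids))
        object.__setattr__(self, "years", tuple(int(y) for y in self.years))
        object.__setattr__(self, "births", births)
        object.__setattr__(self, "deaths", deaths)
        n, t = len(self.area_ids), len(self.years)
        if births.shape != (n, t) or deaths.shape != (n, t):
            raise PanelValidationError(
                f"count matrices must be ({n}, {t}); got births {births.shape}, "
                f"deaths {deaths.shape}"
            )
        if len(set(self.area_ids)) != n:
            raise PanelValidationError("duplicate area ids")
        yrs = np.asarray(self.years)
        if t > 1 and not np.all(np.diff(yrs) == 1):
            raise PanelValidationError("years must be strictly increasing and consecutive")
        if np.any(births < 1):
            i, j = np.argwhere(births < 1)[0]
            raise PanelValidationError(
                f"zero-birth cell at (area={self.area_ids[i]}, year={self.years[j]}); "
                "a binomial cell with n=0 carries no information"
            )
        if np.any(deaths < 0):
            raise PanelValidationError("negative death counts")
        if np.any(deaths > births):
            i, j = np.argwhere(deaths > births)[0]
            raise PanelValidationError(
                f"deaths exceed births at (area={self.area_ids[i]}, year={self.years[j]}): "
                f"{deaths[i, j]} > {births[i, j]}"
            )

    @property
    def n_areas(self) -> int:
        return len(self.area_ids)

    @property
    def n_years(self) -> int:
        return len(self.years)

    def to_frame(self) -> pd.DataFrame:
        """Long-format view with columns area_id, year, births, deaths."""
        idx = pd.MultiIndex.from_product(
            [self.area_ids, self.years], names=["area_id", "year"]
        )
        return pd.DataFrame(
            {"births": self.births.ravel(), "deaths": self.deaths.ravel()}, index=idx
        ).reset_index()


@dataclass(frozen=True)
class DescriptiveSummary:
    """Per-year descriptive statistics of area-level mortality rates.

    Rates are deaths per 1000 births.  ``rate_var`` alongside ``rate_mean``
    supports overdispersion inspection: under pure binomial sampling the
    across-area variance of rates is close to ``1000 * mean_rate / n`` and
    much smaller than what spatially heterogeneous risk produces.
    """

    years: tuple
    rate_mean: np.ndarray
    rate_sd: np.ndarray
    rate_min: np.ndarray
    rate_max: np.ndarray
    rate_var: np.ndarray
    overall_rate: float

    def to_frame(self) -> pd.DataFrame:
        """Table-style layout: one row per statistic, one column per year."""
        return pd.DataFrame(
            [self.rate_mean, self.rate_sd, self.rate_min, self.rate_max],
            index=["mean", "sd", "min", "max"],
            columns=list(self.years),
        )


_DEFAULT_SCHEMA = {
    "area_id": "area_id",
    "year": "year",
    "births": "births",
    "deaths": "deaths",
}


def read_panel(path, schema: dict | None = None) -> MortalityPanel:
    """Read and validate an area-year panel from CSV.

    Parameters
    ----------
    path
        CSV with header; one row per (area, year) cell.
    schema
        Optional map from canonical names (``area_id``, ``year``, ``births``,
        ``deaths``) to the file's column names.

    Raises
    ------
    PanelValidationError
        On missing cells, duplicate cells, or deaths > births.
    """
    cols = dict(_DEFAULT_SCHEMA)
    if schema:
        cols.update(schema)
    df = pd.read_csv(path)
    missing = [c for c in cols.values() if c not in df.columns]
    if missing:
        raise PanelValidationError(f"columns not found in {path}: {missing}")
    df = df.rename(columns={v: k for k, v in cols.items()})
    df["area_id"] = df["area_id"].astype(str)

    dup = df.duplicated(subset=["area_id", "year"])
    if dup.any():
        r = df[dup].iloc[0]
        raise PanelValidationError(
            f"duplicate (area, year) cell: ({r['area_id']}, {r['year']})"
        )
    area_ids = sorted(df["area_id"].unique())
    years = sorted(int(y) for y in df["year"].unique())
    wide_b = df.pivot(index="area_id", columns="year", values="births")
    wide_d = df.pivot(index="area_id", columns="year", values="deaths")
    if wide_b.isna().any().any():
        a = wide_b.index[wide_b.isna().any(axis=1)][0]
        y = wide_b.columns[wide_b.loc[a].isna()][0]
        raise PanelValidationError(f"incomplete panel: missing cell (area={a}, year={y})")
    wide_b = wide_b.loc[area_ids, years]
    wide_d = wide_d.loc[area_ids, years]
    return MortalityPanel(
        area_ids=tuple(area_ids),
        years=tuple(years),
        births=wide_b.to_numpy(dtype=np.int64),
        deaths=wide_d.to_numpy(dtype=np.int64),
    )


def compute_rates(panel: MortalityPanel) -> np.ndarray:
    """Observed mortality rate per 1000 births, cellwise: 1000 * y / n."""
    return 1000.0 * panel.deaths / panel.births


def yearly_summary(panel: MortalityPanel) -> DescriptiveSummary:
    """Per-year mean/sd/min/max of area rates plus the pooled overall rate.

    Uses the sample (N-1 denominator) standard deviation.  With a single
    area the sd is reported as 0 with a warning.
    """
    rates = compute_rates(panel)
    if panel.n_areas < 2:
        warnings.warn("single-area panel: standard deviation reported as 0", stacklevel=2)
        sd = np.zeros(panel.n_years)
        var = np.zeros(panel.n_years)
    else:
        sd = rates.std(axis=0, ddof=1)
        var = rates.var(axis=0, ddof=1)
    return DescriptiveSummary(
        years=panel.years,
        rate_mean=rates.mean(axis=0),
        rate_sd=sd,
        rate_min=rates.min(axis=0),
        rate_max=rates.max(axis=0),
        rate_var=var,
        overall_rate=1000.0 * panel.deaths.sum() / panel.births.sum(),
    )
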