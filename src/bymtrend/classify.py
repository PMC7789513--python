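"""Posterior exceedance probabilities and risk / trend classification.

An area's risk level is judged by the posterior probability that its
combined spatial effect exceeds the regional average,
p(exp(u_i + s_i) > 1 | data): above 0.8 the area is high risk, below 0.2
low risk, otherwise medium (boundary values fall in the middle class).
The local trend is judged the same way through p(d1_i > 0 | data):
increasing, decreasing, or stable relative to the overall trend.
Risk categories carry the conventional coding 1 = high, 2 = low,
3 = medium.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .model import TimeIndex
from .panel import MortalityPanel
from .sampler import PosteriorSamples

__all__ = [
    "RISK_CODES",
    "RiskClassification",
    "RiskSurface",
    "excess_risk_probability",
    "classify_risk",
    "trend_probability",
    "classify_trend",
    "classify_areas",
    "risk_surface",
    "classification_report",
]

RISK_CODES = {"high": 1, "low": 2, "medium": 3}


def excess_risk_probability(samples: PosteriorSamples, i: int) -> float:
    """Fraction of pooled draws with u_i + s_i > 0, i.e. exp(u_i + s_i) > 1."""
    a = samples.area_ids[i]
    su = samples.pooled(f"s[{a}]") + samples.pooled(f"u[{a}]")
    return float(np.mean(su > 0))


def classify_risk(excess_prob: float) -> str:
    """>0.8 -> high; <0.2 -> low; otherwise (boundaries included) medium."""
    if not 0.0 <= excess_prob <= 1.0:
        raise ValueError("probability must lie in [0, 1]")
    if excess_prob > 0.8:
        return "high"
    if excess_prob < 0.2:
        return "low"
    return "medium"


def trend_probability(samples: PosteriorSamples, i: int) -> float:
    """Fraction of pooled draws with d1_i > 0."""
    return float(np.mean(samples.pooled(f"d1[{samples.area_ids[i]}]") > 0))


def classify_trend(trend_prob: float) -> str:
    """>0.8 -> increasing; <0.2 -> decreasing; otherwise stable."""
    if not 0.0 <= trend_prob <= 1.0:
        raise ValueError("probability must lie in [0, 1]")
    if trend_prob > 0.8:
        return "increasing"
    if trend_prob < 0.2:
        return "decreasing"
    return "stable"


@dataclass(frozen=True)
class RiskClassification:
    """Per-area exceedance probabilities, categories, and posterior summaries."""

    table: pd.DataFrame = field(repr=False)

    def counts(self) -> pd.DataFrame:
        return classification_report(self)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False, float_format="%.17g")


def classify_areas(samples: PosteriorSamples) -> RiskClassification:
    """Apply both classification rules to every area.

    Reports, per area: the exceedance probabilities, the risk and trend
    categories, and posterior mean / 95% CI of the spatial relative odds
    exp(u_i + s_i) and of the local slope d1_i.
    """
    rows = []
    for i, a in enumerate(samples.area_ids):
        su = samples.pooled(f"s[{a}]") + samples.pooled(f"u[{a}]")
        d1 = samples.pooled(f"d1[{a}]")
        ep = float(np.mean(su > 0))
        tp = float(np.mean(d1 > 0))
        rr = np.exp(su)
        rows.append({
            "area_id": a,
            "excess_prob": ep,
            "risk_category": classify_risk(ep),
            "risk_code": RISK_CODES[classify_risk(ep)],
            "trend_prob": tp,
            "trend_category": classify_trend(tp),
            "rr_mean": float(rr.mean()),
            "rr_lo": float(np.quantile(rr, 0.025)),
            "rr_hi": float(np.quantile(rr, 0.975)),
            "d1_mean": float(d1.mean()),
            "d1_lo": float(np.quantile(d1, 0.025)),
            "d1_hi": float(np.quantile(d1, 0.975)),
        })
    return RiskClassification(table=pd.DataFrame(rows))


@dataclass(frozen=True)
class RiskSurface:
    """Posterior risk per cell (per 1000) and the overall relative trend."""

    cells: pd.DataFrame = field(repr=False)   # area_id, year, risk_mean_per1000, lo, hi
    trend: pd.DataFrame = field(repr=False)   # year, rel_trend, lo, hi


def risk_surface(samples: PosteriorSamples, panel: MortalityPanel,
                 time_index: TimeIndex) -> RiskSurface:
    """Posterior mean and 95% CI of mu_it (per 1000) and of exp(d0*t* + v_t)."""
    areas, years = samples.area_ids, samples.years
    ts = time_index.t_star
    alpha = samples.pooled("alpha")
    d0 = samples.pooled("d0")
    v = samples.pooled_matrix([f"v[{y}]" for y in years])
    s = samples.pooled_matrix([f"s[{a}]" for a in areas])
    u = samples.pooled_matrix([f"u[{a}]" for a in areas])
    d1 = samples.pooled_matrix([f"d1[{a}]" for a in areas])
    eps = samples.pooled_matrix(
        [f"eps[{a},{y}]" for a in areas for y in years]
    ).reshape(-1, len(areas), len(years))
    eta = (
        alpha[:, None, None] + (s + u)[:, :, None]
        + (d0[:, None] * ts[None, :] + v * 1.0)[:, None, :]
        + d1[:, :, None] * ts[None, None, :] + eps
    )
    mu = 1000.0 * expit(eta)  # draws x N x T
    lo, hi = np.quantile(mu, [0.025, 0.975], axis=0)
    mean = mu.mean(axis=0)
    cells = pd.DataFrame(
        [(a, y, mean[i, t], lo[i, t], hi[i, t])
         for i, a in enumerate(areas) for t, y in enumerate(years)],
        columns=["area_id", "year", "risk_mean_per1000", "risk_lo", "risk_hi"],
    )
    rel = np.exp(d0[:, None] * ts[None, :] + v)
    tlo, thi = np.quantile(rel, [0.025, 0.975], axis=0)
    trend = pd.DataFrame({
        "year": list(years), "rel_trend": rel.mean(axis=0), "lo": tlo, "hi": thi,
    })
    return RiskSurface(cells=cells, trend=trend)


def attach_to_geojson(classification: RiskClassification, feature_collection: dict,
                      id_property: str = "area_id") -> dict:
    """Return a copy of a GeoJSON FeatureCollection with classification
    columns merged into each feature's properties (for external mapping)."""
    import copy

    by_area = classification.table.set_index("area_id")
    out = copy.deepcopy(feature_collection)
    for feat in out.get("features", []):
        props = feat.setdefault("properties", {})
        aid = str(props.get(id_property))
        if aid in by_area.index:
            row = by_area.loc[aid]
            props.update({
                "excess_prob": float(row["excess_prob"]),
                "risk_category": row["risk_category"],
                "risk_code": int(row["risk_code"]),
                "trend_prob": float(row["trend_prob"]),
                "trend_category": row["trend_category"],
            })
    return out


def classification_report(classification: RiskClassification) -> pd.DataFrame:
    """Counts and integer percentages per risk category and, nested, per trend.

    Percentages of risk categories are relative to the number of areas;
    trend percentages are relative to their risk category's count.
    """
    tab = classification.table
    n = len(tab)
    rows = []
    for risk in ("high", "medium", "low"):
        sub = tab[tab["risk_category"] == risk]
        rows.append({
            "risk_category": risk, "trend_category": "all",
            "count": len(sub), "percent": int(round(100 * len(sub) / n)),
        })
        for trend in ("increasing", "stable", "decreasing"):
            k = int((sub["trend_category"] == trend).sum())
            rows.append({
                "risk_category": risk, "trend_category": trend, "count": k,
                "percent": int(round(100 * k / len(sub))) if len(sub) else 0,
            })
    return pd.DataFrame(rows)
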