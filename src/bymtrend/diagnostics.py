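"""Preliminary spatial and serial autocorrelation diagnostics.

Global Moran's I with a one-sided permutation test (positive
autocorrelation alternative), and the mean lag-1 autocorrelation of each
area's rate series — the two checks used to motivate a joint
spatio-temporal model before fitting one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import MortalityPanel, compute_rates
from .spatial import AdjacencyStructure

__all__ = [
    "MoranResult",
    "morans_i",
    "morans_i_permutation_test",
    "mean_lag1_acf",
    "moran_table",
]


@dataclass(frozen=True)
class MoranResult:
    statistic: float
    expected_null: float  # -1/(N-1)
    p_value: float
    n_permutations: int
    seed: int | None = None


def morans_i(values, adj: AdjacencyStructure) -> float:
    """Global Moran's I over a binary contiguity weighting.

    I = (N/S0) * [sum_ij w_ij (x_i - xbar)(x_j - xbar)] / sum_i (x_i - xbar)^2
    with S0 = sum_ij w_ij.
    """
    x = np.asarray(values, dtype=np.float64)
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 areas")
    z = x - x.mean()
    denom = z @ z
    if denom == 0:
        raise ValueError("zero variance: Moran's I undefined for a constant vector")
    W = adj.W
    s0 = W.sum()
    return float(n / s0 * (z @ (W @ z)) / denom)


def morans_i_permutation_test(
    values, adj: AdjacencyStructure, n_permutations: int = 999, seed: int | None = None
) -> MoranResult:
    """One-sided (positive autocorrelation) permutation test for Moran's I.

    p = (1 + #{permuted I >= observed I}) / (n_permutations + 1); values are
    shuffled over areas with a seeded generator.
    """
    if n_permutations < 99:
        raise ValueError("n_permutations must be >= 99")
    x = np.asarray(values, dtype=np.float64)
    n = x.size
    observed = morans_i(x, adj)
    rng = np.random.default_rng(seed)
    W = adj.W
    s0 = W.sum()
    count = 0
    for _ in range(n_permutations):
        z = rng.permutation(x)
        z = z - z.mean()
        i_perm = n / s0 * (z @ (W @ z)) / (z @ z)
        if i_perm >= observed:
            count += 1
    return MoranResult(
        statistic=observed,
        expected_null=-1.0 / (n - 1),
        p_value=(1 + count) / (n_permutations + 1),
        n_permutations=n_permutations,
        seed=seed,
    )


def mean_lag1_acf(panel: MortalityPanel) -> float:
    """Mean over areas of the lag-1 autocorrelation of each rate series.

    Per area the plug-in estimator
    sum_{t<T} (x_t - xbar)(x_{t+1} - xbar) / sum_t (x_t - xbar)^2
    is used; constant series are skipped with a warning.
    """
    if panel.n_years < 3:
        raise ValueError("need at least 3 years for a lag-1 autocorrelation")
    rates = compute_rates(panel)
    z = rates - rates.mean(axis=1, keepdims=True)
    denom = (z**2).sum(axis=1)
    num = (z[:, :-1] * z[:, 1:]).sum(axis=1)
    ok = denom > 0
    if not ok.any():
        raise ValueError("all rate series are constant: lag-1 ACF undefined")
    if not ok.all():
        skipped = [panel.area_ids[i] for i in np.nonzero(~ok)[0]]
        warnings.warn(f"skipping constant rate series for areas {skipped}", stacklevel=2)
    return float((num[ok] / denom[ok]).mean())


def moran_table(
    panel: MortalityPanel,
    adj: AdjacencyStructure,
    n_permutations: int = 999,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-year Moran's I of the observed rates with permutation p-values."""
    rates = compute_rates(panel)
    ss = np.random.SeedSequence(seed).spawn(panel.n_years)
    rows = []
    for t, year in enumerate(panel.years):
        res = morans_i_permutation_test(
            rates[:, t], adj, n_permutations=n_permutations,
            seed=int(ss[t].generate_state(1)[0] % (2**31)),
        )
        rows.append(
            {"year": year, "I": res.statistic, "expected": res.expected_null,
             "p_value": res.p_value}
        )
    return pd.DataFrame(rows)
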