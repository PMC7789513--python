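"""Binomial-logit spatio-temporal risk model and its joint log-posterior.

For deaths y_it out of n_it births in area i and period t,

    y_it ~ Binomial(n_it, mu_it)
    logit(mu_it) = alpha + (s_i + u_i) + d0*t* + v_t + d1_i*t* + eps_it

with: alpha the overall logit risk; s (ICAR) and u (exchangeable Gaussian)
the structured and unstructured spatial effects (the BYM convolution);
d0*t* + v_t the overall linear-plus-wiggle time trend; d1_i*t* the
area-specific linear departure from the common trend, ICAR across areas;
and eps_it an i.i.d. Gaussian cell effect absorbing extra-binomial
variation.  t* is the time index centred at the middle of the observation
window.  s, v and d1 carry sum-to-zero identification constraints.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import expit, gammaln

from .panel import MortalityPanel
from .spatial import AdjacencyStructure, icar_pairwise_quadform

__all__ = [
    "TimeIndex",
    "PriorConfig",
    "HalfGaussianSD",
    "GammaPrecision",
    "ModelState",
    "VARIANCE_COMPONENTS",
    "logit_risk",
    "linear_predictor",
    "log_likelihood",
    "log_prior",
    "log_posterior",
]

VARIANCE_COMPONENTS = ("s", "u", "v", "d", "eps")


@dataclass(frozen=True)
class TimeIndex:
    """Calendar years and their centred indices t* = t - midpoint."""

    years: tuple
    t_star: np.ndarray = field(repr=False)

    @classmethod
    def from_years(cls, years) -> "TimeIndex":
        years = tuple(int(y) for y in years)
        idx = np.arange(len(years), dtype=np.float64)
        # odd T with consecutive years: integer offsets from the median year;
        # otherwise centred at the mean
        t_star = idx - idx.mean()
        return cls(years=years, t_star=t_star)

    @property
    def n_years(self) -> int:
        return len(self.years)


@dataclass(frozen=True)
class HalfGaussianSD:
    """Half-Gaussian prior N+(0, scale2) on a standard deviation."""

    scale2: float = 10.0

    def log_density_sd(self, sd: float) -> float:
        if sd <= 0:
            return -np.inf
        return float(0.5 * np.log(2.0 / (np.pi * self.scale2)) - sd**2 / (2 * self.scale2))


@dataclass(frozen=True)
class GammaPrecision:
    """Gamma(shape, rate) prior on a precision tau = 1/sigma^2.

    Exposed here as a density over the standard deviation so that all
    hyperpriors share one coordinate.
    """

    shape: float = 0.001
    rate: float = 0.001

    def log_density_sd(self, sd: float) -> float:
        if sd <= 0:
            return -np.inf
        tau = sd**-2
        log_tau_density = (
            self.shape * np.log(self.rate)
            - gammaln(self.shape)
            + (self.shape - 1) * np.log(tau)
            - self.rate * tau
        )
        return float(log_tau_density + np.log(2.0) - 3 * np.log(sd))


@dataclass(frozen=True)
class PriorConfig:
    """One hyperprior per variance component (s, u, v, d, eps).

    Default: half-Gaussian N+(0, 10) on every standard deviation.  A
    Gamma-on-precision alternative reproduces classic WinBUGS-style runs
    and enables conjugate variance updates in the sampler.
    """

    s: object = HalfGaussianSD()
    u: object = HalfGaussianSD()
    v: object = HalfGaussianSD()
    d: object = HalfGaussianSD()
    eps: object = HalfGaussianSD()

    def component(self, name: str):
        if name not in VARIANCE_COMPONENTS:
            raise KeyError(name)
        return getattr(self, name)

    @classmethod
    def gamma_on_precisions(cls, shape: float = 0.001, rate: float = 0.001) -> "PriorConfig":
        g = GammaPrecision(shape, rate)
        return cls(s=g, u=g, v=g, d=g, eps=g)


@dataclass(frozen=True)
class ModelState:
    """One full set of model parameters."""

    alpha: float
    d0: float
    s: np.ndarray = field(repr=False)
    u: np.ndarray = field(repr=False)
    v: np.ndarray = field(repr=False)
    d1: np.ndarray = field(repr=False)
    eps: np.ndarray = field(repr=False)
    sigma2_s: float = 1.0
    sigma2_u: float = 1.0
    sigma2_v: float = 1.0
    sigma2_d: float = 1.0
    sigma2_eps: float = 1.0

    def __post_init__(self):
        for name in ("s", "u", "v", "d1", "eps"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=np.float64))

    def validate(self, tol: float = 1e-8) -> None:
        n = self.s.size
        t = self.v.size
        if self.u.shape != (n,) or self.d1.shape != (n,) or self.eps.shape != (n, t):
            raise ValueError("inconsistent component shapes")
        for name in ("s", "d1", "v"):
            total = float(np.sum(getattr(self, name)))
            if abs(total) > tol:
                raise ValueError(f"sum-to-zero constraint violated for {name}: sum={total}")
        for name in VARIANCE_COMPONENTS:
            if self.variance(name) <= 0:
                raise ValueError(f"non-positive variance sigma2_{name}")

    def variance(self, name: str) -> float:
        return getattr(self, f"sigma2_{name}" if name != "eps" else "sigma2_eps")

    def with_variance(self, name: str, value: float) -> "ModelState":
        return replace(self, **{f"sigma2_{name}": value})

    @classmethod
    def zeros(cls, n_areas: int, n_years: int, **kwargs) -> "ModelState":
        return cls(
            alpha=kwargs.pop("alpha", 0.0),
            d0=kwargs.pop("d0", 0.0),
            s=np.zeros(n_areas),
            u=np.zeros(n_areas),
            v=np.zeros(n_years),
            d1=np.zeros(n_areas),
            eps=np.zeros((n_areas, n_years)),
            **kwargs,
        )


def linear_predictor(state: ModelState, time_index: TimeIndex) -> np.ndarray:
    """The (N, T) logit-scale surface of the model."""
    ts = time_index.t_star
    return (
        state.alpha
        + (state.s + state.u)[:, None]
        + state.d0 * ts[None, :]
        + state.v[None, :]
        + state.d1[:, None] * ts[None, :]
        + state.eps
    )


def logit_risk(state: ModelState, time_index: TimeIndex, i: int, t: int) -> float:
    """Cell risk mu_it = inverse-logit of the linear predictor; in (0, 1)."""
    return float(expit(linear_predictor(state, time_index)[i, t]))


def log_likelihood(panel: MortalityPanel, state: ModelState, time_index: TimeIndex) -> float:
    """Binomial log-likelihood summed over all cells (with binomial coefficients)."""
    if state.s.size != panel.n_areas or state.v.size != panel.n_years:
        raise ValueError(
            f"state dimensions ({state.s.size}, {state.v.size}) do not match "
            f"panel ({panel.n_areas}, {panel.n_years})"
        )
    y = panel.deaths
    n = panel.births
    eta = linear_predictor(state, time_index)
    log_c = gammaln(n + 1) - gammaln(y + 1) - gammaln(n - y + 1)
    # y*eta - n*log(1 + e^eta) is the stable form of y*log(mu) + (n-y)*log(1-mu)
    return float(np.sum(log_c + y * eta - n * np.logaddexp(0.0, eta)))


def _icar_log_density(x, adj: AdjacencyStructure, sigma2: float) -> float:
    """Sum-to-zero ICAR log-density, rank N-1 normalisation included."""
    n = x.size
    quad = icar_pairwise_quadform(x, adj)
    lam = np.linalg.eigvalsh(adj.laplacian)[1:]
    return float(
        -0.5 * (n - 1) * np.log(2 * np.pi * sigma2)
        + 0.5 * np.sum(np.log(lam))
        - quad / (2 * sigma2)
    )


def _gaussian_log_density(x, sigma2: float) -> float:
    x = np.asarray(x)
    return float(-0.5 * x.size * np.log(2 * np.pi * sigma2) - np.sum(x**2) / (2 * sigma2))


def log_prior(state: ModelState, adj: AdjacencyStructure, config: PriorConfig) -> float:
    """Joint log-prior of all random effects and variance hyperparameters.

    ICAR for s and d1; i.i.d. Gaussians for u, v and eps; flat (improper)
    priors on alpha and d0 contribute zero; hyperprior densities evaluated
    on the standard-deviation coordinate.
    """
    for name in VARIANCE_COMPONENTS:
        if state.variance(name) <= 0:
            raise ValueError(f"non-positive variance sigma2_{name}")
    total = _icar_log_density(state.s, adj, state.sigma2_s)
    total += _icar_log_density(state.d1, adj, state.sigma2_d)
    total += _gaussian_log_density(state.u, state.sigma2_u)
    total += _gaussian_log_density(state.v, state.sigma2_v)
    total += _gaussian_log_density(state.eps, state.sigma2_eps)
    for name in VARIANCE_COMPONENTS:
        total += config.component(name).log_density_sd(np.sqrt(state.variance(name)))
    return float(total)


def log_posterior(
    panel: MortalityPanel,
    state: ModelState,
    adj: AdjacencyStructure,
    time_index: TimeIndex,
    config: PriorConfig,
) -> float:
    return log_likelihood(panel, state, time_index) + log_prior(state, adj, config)
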