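"""Metropolis-within-Gibbs sampler for the spatio-temporal binomial model.

Each iteration sweeps the blocks in a fixed order: the fixed effects
(alpha, d0) by scalar random-walk Metropolis; the random-effect fields
(s, u, v, d1, eps) by single-site random-walk Metropolis — vectorised over
sites whose full conditionals are mutually independent (a graph colouring
for the ICAR fields s and d1; all sites at once for u, v and eps); and the
five variance components either by random-walk Metropolis on log-sigma
(half-Gaussian SD prior) or by exact conjugate Gibbs draws (Gamma
precision prior).  s, v and d1 are re-centred to sum to zero after every
sweep, with the removed means absorbed into alpha and d0 so the likelihood
is untouched.

A likelihood-invariant "ridge" move proposes a joint shift
(alpha + delta, u - delta): the intercept and the mean of the unstructured
heterogeneity field are confounded in the likelihood, and this move lets
the chain traverse that ridge at the cost of only a prior ratio.

Proposal scales adapt toward a 20-50% acceptance rate during the first
``adapt_until`` iterations only (``adapt_until <= n_burnin``), so retained
draws come from a fixed transition kernel.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.special import logit

from .model import (
    GammaPrecision,
    HalfGaussianSD,
    ModelState,
    PriorConfig,
    TimeIndex,
    VARIANCE_COMPONENTS,
)
from .panel import MortalityPanel
from .spatial import AdjacencyStructure

logger = logging.getLogger(__name__)

__all__ = [
    "SamplerConfig",
    "PosteriorSamples",
    "run_chain",
    "run_chains",
    "gelman_rubin",
    "summarize",
    "default_init",
]

_ALL_BLOCKS = ("alpha", "d0", "ridge", "s", "u", "v", "d1", "eps", "sigmas")
_ADAPT_TARGET = 0.35
_ADAPT_WINDOW = 50


@dataclass(frozen=True)
class SamplerConfig:
    n_iterations: int = 100_000
    n_burnin: int = 30_000
    n_chains: int = 2
    thin: int = 1
    seed: int = 0
    adapt_until: int | None = None  # defaults to n_burnin
    rhat_threshold: float = 1.04

    def __post_init__(self):
        if self.n_burnin >= self.n_iterations:
            raise ValueError("n_burnin must be < n_iterations")
        if self.n_chains < 1 or self.thin < 1:
            raise ValueError("n_chains >= 1 and thin >= 1 required")
        if self.adapt_until is None:
            object.__setattr__(self, "adapt_until", self.n_burnin)
        if self.adapt_until > self.n_burnin:
            raise ValueError("adapt_until must be <= n_burnin")

    @property
    def n_retained(self) -> int:
        return (self.n_iterations - self.n_burnin) // self.thin


def _greedy_coloring(W: np.ndarray) -> list:
    """Partition areas into independent sets of the contiguity graph."""
    import networkx as nx

    g = nx.from_numpy_array(W)
    colors = nx.coloring.greedy_color(g, strategy="largest_first")
    n_colors = max(colors.values()) + 1 if colors else 1
    classes = [[] for _ in range(n_colors)]
    for node, c in colors.items():
        classes[c].append(node)
    return [np.array(sorted(c), dtype=np.int64) for c in classes if c]


def _parameter_names(area_ids, years) -> tuple:
    names = ["alpha", "d0"]
    names += [f"s[{a}]" for a in area_ids]
    names += [f"u[{a}]" for a in area_ids]
    names += [f"v[{y}]" for y in years]
    names += [f"d1[{a}]" for a in area_ids]
    names += [f"eps[{a},{y}]" for a in area_ids for y in years]
    names += [f"sigma2_{c}" for c in VARIANCE_COMPONENTS]
    return tuple(names)


class _Chain:
    """Mutable single-chain state with incremental likelihood bookkeeping."""

    def __init__(self, panel, adj, time_index, prior_config, init: ModelState,
                 rng, flat_likelihood, sample_blocks, fixed_variances):
        self.y = panel.deaths.astype(np.float64)
        self.n = panel.births.astype(np.float64)
        self.ts = time_index.t_star
        self.W = adj.W
        self.m = adj.neighbor_counts
        self.Q = adj.laplacian
        self.colors = _greedy_coloring(self.W)
        self.prior = prior_config
        self.rng = rng
        self.flat = flat_likelihood
        self.blocks = set(sample_blocks) if sample_blocks else set(_ALL_BLOCKS)
        self.fixed_variances = dict(fixed_variances or {})
        self.N, self.T = self.y.shape

        init.validate()
        self.alpha = float(init.alpha)
        self.d0 = float(init.d0)
        self.s = init.s.copy()
        self.u = init.u.copy()
        self.v = init.v.copy()
        self.d1 = init.d1.copy()
        self.eps = init.eps.copy()
        self.sig2 = {c: float(init.variance(c)) for c in VARIANCE_COMPONENTS}
        self.sig2.update(self.fixed_variances)

        with np.errstate(invalid="ignore"):  # non-finite inits diagnosed below
            self.eta = self._full_eta()
            self.ll = self._cell_ll(self.eta)
        bad = ~np.isfinite(self.ll)
        if bad.any():
            i, t = np.argwhere(bad)[0]
            raise ValueError(f"non-finite log-posterior at init (cell {i},{t})")

        self.scales = {
            "alpha": 0.05, "d0": 0.02, "ridge": 0.05, "s": 0.1, "u": 0.1,
            "v": 0.05, "d1": 0.05, "eps": 0.1,
            **{f"sigma_{c}": 0.5 for c in VARIANCE_COMPONENTS},
            **{f"scale_{c}": 0.3 for c in VARIANCE_COMPONENTS},
        }
        self._win = {k: [0, 0] for k in self.scales}     # adaptation window
        self._acc = {k: [0, 0] for k in self.scales}     # post-burn-in totals

    # -- likelihood helpers ------------------------------------------------

    def _full_eta(self):
        return (
            self.alpha + (self.s + self.u)[:, None] + self.d0 * self.ts[None, :]
            + self.v[None, :] + self.d1[:, None] * self.ts[None, :] + self.eps
        )

    def _cell_ll(self, eta, rows=None, cols=None):
        if self.flat:
            return np.zeros_like(eta)
        y, n = self.y, self.n
        if rows is not None:
            y, n = y[rows], n[rows]
        if cols is not None:
            y, n = y[:, cols], n[:, cols]
        return y * eta - n * np.logaddexp(0.0, eta)

    def _tally(self, block, accepted, proposed, record):
        w = self._win[block]
        w[0] += accepted
        w[1] += proposed
        if record:
            a = self._acc[block]
            a[0] += accepted
            a[1] += proposed

    # -- block updates -----------------------------------------------------

    def _update_scalar(self, block, record):
        delta = self.scales[block] * self.rng.standard_normal()
        if block == "alpha":
            cand_eta = self.eta + delta
        else:  # d0
            cand_eta = self.eta + delta * self.ts[None, :]
        cand_ll = self._cell_ll(cand_eta)
        log_r = cand_ll.sum() - self.ll.sum()
        acc = np.log(self.rng.uniform()) < log_r
        if acc:
            if block == "alpha":
                self.alpha += delta
            else:
                self.d0 += delta
            self.eta, self.ll = cand_eta, cand_ll
        self._tally(block, int(acc), 1, record)

    def _update_ridge(self, record):
        # (alpha, u) -> (alpha + delta, u - delta): likelihood invariant
        delta = self.scales["ridge"] * self.rng.standard_normal()
        u_new = self.u - delta
        dlp = -(np.sum(u_new**2) - np.sum(self.u**2)) / (2 * self.sig2["u"])
        acc = np.log(self.rng.uniform()) < dlp
        if acc:
            self.alpha += delta
            self.u = u_new
        self._tally("ridge", int(acc), 1, record)

    def _update_icar_field(self, block, record):
        """Single-site Metropolis for s or d1, vectorised per colour class."""
        x = self.s if block == "s" else self.d1
        sig2 = self.sig2["s" if block == "s" else "d"]
        scale = self.scales[block]
        for c in self.colors:
            z = scale * self.rng.standard_normal(c.size)
            x_new = x[c] + z
            wx = self.W[c] @ x
            dprior = -(self.m[c] * (x_new**2 - x[c] ** 2) - 2 * z * wx) / (2 * sig2)
            if block == "s":
                cand_eta = self.eta[c] + z[:, None]
            else:
                cand_eta = self.eta[c] + z[:, None] * self.ts[None, :]
            cand_ll = self._cell_ll(cand_eta, rows=c)
            dll = (cand_ll - self.ll[c]).sum(axis=1)
            acc = np.log(self.rng.uniform(size=c.size)) < dprior + dll
            idx = c[acc]
            x[idx] = x_new[acc]
            self.eta[idx] = cand_eta[acc]
            self.ll[idx] = cand_ll[acc]
            self._tally(block, int(acc.sum()), int(c.size), record)

    def _update_u(self, record):
        z = self.scales["u"] * self.rng.standard_normal(self.N)
        u_new = self.u + z
        dprior = -(u_new**2 - self.u**2) / (2 * self.sig2["u"])
        cand_eta = self.eta + z[:, None]
        cand_ll = self._cell_ll(cand_eta)
        dll = (cand_ll - self.ll).sum(axis=1)
        acc = np.log(self.rng.uniform(size=self.N)) < dprior + dll
        self.u[acc] = u_new[acc]
        self.eta[acc] = cand_eta[acc]
        self.ll[acc] = cand_ll[acc]
        self._tally("u", int(acc.sum()), self.N, record)

    def _update_v(self, record):
        # block move within the sum-to-zero subspace: the iid Gaussian prior
        # of v is not shift-invariant, so (unlike s and d1) post-hoc
        # recentering would distort it; a projected symmetric proposal with a
        # single accept/reject targets the constrained prior exactly
        z = self.scales["v"] * self.rng.standard_normal(self.T)
        z -= z.mean()
        v_new = self.v + z
        dprior = -(np.sum(v_new**2) - np.sum(self.v**2)) / (2 * self.sig2["v"])
        cand_eta = self.eta + z[None, :]
        cand_ll = self._cell_ll(cand_eta)
        acc = np.log(self.rng.uniform()) < dprior + (cand_ll - self.ll).sum()
        if acc:
            self.v = v_new
            self.eta, self.ll = cand_eta, cand_ll
        self._tally("v", int(acc), 1, record)

    def _update_eps(self, record):
        z = self.scales["eps"] * self.rng.standard_normal((self.N, self.T))
        eps_new = self.eps + z
        dprior = -(eps_new**2 - self.eps**2) / (2 * self.sig2["eps"])
        cand_eta = self.eta + z
        cand_ll = self._cell_ll(cand_eta)
        acc = np.log(self.rng.uniform(size=(self.N, self.T))) < dprior + (cand_ll - self.ll)
        self.eps[acc] = eps_new[acc]
        self.eta[acc] = cand_eta[acc]
        self.ll[acc] = cand_ll[acc]
        self._tally("eps", int(acc.sum()), self.N * self.T, record)

    def _update_group_scales(self, record):
        """Joint rescale (field, sigma) -> (e^z field, e^z sigma) per component.

        The prior quadratic form and the sigma^-rank normalisation cancel
        against the transform's Jacobian exactly, so the accept ratio is the
        likelihood change plus the hyperprior ratio plus z.  This move
        traverses the variance-field "funnel" that single-site updates
        cannot, which is what makes the variance components mix.
        """
        fields = {
            "s": (self.s, lambda f, k: k * f[:, None]),
            "u": (self.u, lambda f, k: k * f[:, None]),
            "v": (self.v, lambda f, k: k * f[None, :]),
            "d": (self.d1, lambda f, k: k * f[:, None] * self.ts[None, :]),
            "eps": (self.eps, lambda f, k: k * f),
        }
        for c in VARIANCE_COMPONENTS:
            if c in self.fixed_variances:
                continue
            block = f"scale_{c}"
            z = self.scales[block] * self.rng.standard_normal()
            sd = np.sqrt(self.sig2[c])
            sd_new = sd * np.exp(z)
            if not (1e-6 < sd_new < 1e3):
                self._tally(block, 0, 1, record)
                continue
            field, eta_delta = fields[c]
            cand_eta = self.eta + eta_delta(field, np.exp(z) - 1.0)
            cand_ll = self._cell_ll(cand_eta)
            prior = self.prior.component(c)
            log_r = ((cand_ll - self.ll).sum()
                     + prior.log_density_sd(sd_new) - prior.log_density_sd(sd) + z)
            acc = np.log(self.rng.uniform()) < log_r
            if acc:
                field *= np.exp(z)  # in place: updates the state array
                self.sig2[c] = sd_new**2
                self.eta, self.ll = cand_eta, cand_ll
            self._tally(block, int(acc), 1, record)

    def _component_quads(self):
        return {
            "s": (self.N - 1, float(self.s @ (self.Q @ self.s))),
            "u": (self.N, float(np.sum(self.u**2))),
            "v": (self.T - 1, float(np.sum(self.v**2))),  # sum-to-zero: rank T-1
            "d": (self.N - 1, float(self.d1 @ (self.Q @ self.d1))),
            "eps": (self.N * self.T, float(np.sum(self.eps**2))),
        }

    def _update_sigmas(self, record):
        quads = self._component_quads()
        for c in VARIANCE_COMPONENTS:
            if c in self.fixed_variances:
                continue
            rank, quad = quads[c]
            prior = self.prior.component(c)
            block = f"sigma_{c}"
            if isinstance(prior, GammaPrecision):
                # exact conjugate draw for the precision
                tau = self.rng.gamma(prior.shape + rank / 2.0, 1.0 / (prior.rate + quad / 2.0))
                self.sig2[c] = 1.0 / tau
                self._tally(block, 1, 1, record)
            else:
                sd = np.sqrt(self.sig2[c])
                log_sd_new = np.log(sd) + self.scales[block] * self.rng.standard_normal()
                sd_new = np.exp(log_sd_new)
                if not (1e-6 < sd_new < 1e3):
                    self._tally(block, 0, 1, record)
                    continue

                def target(x):
                    return (
                        -rank * np.log(x) - quad / (2 * x**2)
                        + prior.log_density_sd(x) + np.log(x)  # log-scale Jacobian
                    )

                acc = np.log(self.rng.uniform()) < target(sd_new) - target(sd)
                if acc:
                    self.sig2[c] = sd_new**2
                self._tally(block, int(acc), 1, record)

    def _recenter(self):
        ms = self.s.mean()
        self.s -= ms
        mv = self.v.mean()
        self.v -= mv
        self.alpha += ms + mv
        md = self.d1.mean()
        self.d1 -= md
        self.d0 += md

    def _adapt(self):
        for block, (a, p) in self._win.items():
            if p == 0:
                continue
            rate = a / p
            self.scales[block] = float(
                np.clip(self.scales[block] * np.exp(0.8 * (rate - _ADAPT_TARGET)), 1e-5, 20.0)
            )
            self._win[block] = [0, 0]

    def sweep(self, record: bool):
        b = self.blocks
        if "alpha" in b:
            self._update_scalar("alpha", record)
        if "d0" in b:
            self._update_scalar("d0", record)
        if "ridge" in b:
            self._update_ridge(record)
        if "s" in b:
            self._update_icar_field("s", record)
        if "u" in b:
            self._update_u(record)
        if "v" in b:
            self._update_v(record)
        if "d1" in b:
            self._update_icar_field("d1", record)
        if "eps" in b:
            self._update_eps(record)
        if "sigmas" in b:
            self._update_sigmas(record)
            self._update_group_scales(record)
        self._recenter()

    def pack(self, out: np.ndarray):
        out[0] = self.alpha
        out[1] = self.d0
        k = 2
        for arr in (self.s, self.u, self.v, self.d1):
            out[k : k + arr.size] = arr
            k += arr.size
        out[k : k + self.eps.size] = self.eps.ravel()
        k += self.eps.size
        for c in VARIANCE_COMPONENTS:
            out[k] = self.sig2[c]
            k += 1

    def acceptance_rates(self) -> dict:
        return {k: (a / p if p else float("nan")) for k, (a, p) in self._acc.items()}

    def log_posterior_quick(self) -> float:
        quads = self._component_quads()
        lp = float(self.ll.sum())
        for c in VARIANCE_COMPONENTS:
            rank, quad = quads[c]
            lp += -0.5 * rank * np.log(self.sig2[c]) - quad / (2 * self.sig2[c])
        return lp


def run_chain(
    panel: MortalityPanel,
    adj: AdjacencyStructure,
    time_index: TimeIndex,
    prior_config: PriorConfig,
    sampler_config: SamplerConfig,
    chain_seed: int,
    init: ModelState,
    flat_likelihood: bool = False,
    sample_blocks=None,
    fixed_variances=None,
):
    """Run one chain; returns (draws array, acceptance-rate dict, scales).

    ``flat_likelihood`` replaces the likelihood with a constant (prior
    sampling mode, for sampler validation); ``sample_blocks`` restricts the
    sweep to a subset of blocks; ``fixed_variances`` pins variance
    components at given values instead of sampling them.
    """
    rng = np.random.default_rng(chain_seed)
    chain = _Chain(panel, adj, time_index, prior_config, init, rng,
                   flat_likelihood, sample_blocks, fixed_variances)
    cfg = sampler_config
    n_params = 2 + 3 * chain.N + chain.T + chain.N * chain.T + 5
    draws = np.empty((cfg.n_retained, n_params))
    kept = 0
    for it in range(1, cfg.n_iterations + 1):
        record = it > cfg.n_burnin
        chain.sweep(record)
        if it <= cfg.adapt_until and it % _ADAPT_WINDOW == 0:
            chain._adapt()
        if record and (it - cfg.n_burnin) % cfg.thin == 0 and kept < cfg.n_retained:
            chain.pack(draws[kept])
            kept += 1
        if it % 1000 == 0 and logger.isEnabledFor(logging.INFO):
            logger.info("iteration %d: log-posterior %.2f", it, chain.log_posterior_quick())
    return draws[:kept], chain.acceptance_rates(), dict(chain.scales)


@dataclass
class PosteriorSamples:
    """Multi-chain retained draws with convergence metadata."""

    draws: np.ndarray  # (n_chains, n_retained, n_params)
    names: tuple
    area_ids: tuple
    years: tuple
    config: SamplerConfig
    rhat: np.ndarray
    acceptance: list
    chain_seeds: tuple

    def __post_init__(self):
        self._index = {n: k for k, n in enumerate(self.names)}

    @property
    def n_chains(self) -> int:
        return self.draws.shape[0]

    def get(self, name: str) -> np.ndarray:
        """(n_chains, n_retained) draws of one scalar parameter."""
        return self.draws[:, :, self._index[name]]

    def pooled(self, name: str) -> np.ndarray:
        return self.get(name).reshape(-1)

    def pooled_matrix(self, names) -> np.ndarray:
        idx = [self._index[n] for n in names]
        return self.draws[:, :, idx].reshape(-1, len(idx))

    def rhat_table(self) -> pd.DataFrame:
        return pd.DataFrame({"parameter": self.names, "rhat": self.rhat})

    def to_frame(self) -> pd.DataFrame:
        c, m, p = self.draws.shape
        df = pd.DataFrame(self.draws.reshape(c * m, p), columns=list(self.names))
        df.insert(0, "chain", np.repeat(np.arange(c), m))
        return df

    def save(self, draws_path, meta_path) -> None:
        # default float repr is shortest-round-trip: reload is bit-exact
        self.to_frame().to_csv(draws_path, index=False)
        meta = {
            "config": asdict(self.config),
            "area_ids": list(self.area_ids),
            "years": list(self.years),
            "chain_seeds": list(self.chain_seeds),
            "rhat": {n: (None if not np.isfinite(r) else float(r))
                     for n, r in zip(self.names, self.rhat)},
            "acceptance": self.acceptance,
        }
        with open(meta_path, "w") as fh:
            json.dump(meta, fh, indent=1)

    @classmethod
    def load(cls, draws_path, meta_path) -> "PosteriorSamples":
        df = pd.read_csv(draws_path, float_precision="round_trip")
        with open(meta_path) as fh:
            meta = json.load(fh)
        names = tuple(c for c in df.columns if c != "chain")
        chains = sorted(df["chain"].unique())
        draws = np.stack([df[df["chain"] == c][list(names)].to_numpy() for c in chains])
        rhat = np.array([
            meta["rhat"].get(n) if meta["rhat"].get(n) is not None else np.nan
            for n in names
        ])
        return cls(
            draws=draws, names=names,
            area_ids=tuple(meta["area_ids"]), years=tuple(meta["years"]),
            config=SamplerConfig(**meta["config"]), rhat=rhat,
            acceptance=meta["acceptance"], chain_seeds=tuple(meta["chain_seeds"]),
        )


def default_init(panel: MortalityPanel, chain: int) -> ModelState:
    """Overdispersed per-chain initial values.

    alpha starts at the empirical logit of the pooled rate plus a
    chain-indexed offset; random effects start at zero; initial SDs
    alternate between 0.1 and 1 by chain.
    """
    pooled = panel.deaths.sum() / panel.births.sum()
    offset = 0.08 * ((-1) ** chain) * (1 + chain // 2)
    sig = 0.01 if chain % 2 == 0 else 1.0
    return ModelState.zeros(
        panel.n_areas, panel.n_years,
        alpha=float(logit(pooled)) + offset,
        sigma2_s=sig, sigma2_u=sig, sigma2_v=sig, sigma2_d=sig, sigma2_eps=sig,
    )


def run_chains(
    panel: MortalityPanel,
    adj: AdjacencyStructure,
    time_index: TimeIndex,
    prior_config: PriorConfig = PriorConfig(),
    sampler_config: SamplerConfig = SamplerConfig(),
    inits=None,
    **chain_kwargs,
) -> PosteriorSamples:
    """Run ``n_chains`` independent chains from distinct seeds and inits."""
    cfg = sampler_config
    ss = np.random.SeedSequence(cfg.seed).spawn(cfg.n_chains)
    seeds = tuple(int(s.generate_state(1)[0] % (2**31)) for s in ss)
    names = _parameter_names(panel.area_ids, panel.years)
    all_draws, acceptance = [], []
    for c in range(cfg.n_chains):
        init = inits[c] if inits is not None else default_init(panel, c)
        d, acc, _ = run_chain(panel, adj, time_index, prior_config, cfg,
                              seeds[c], init, **chain_kwargs)
        all_draws.append(d)
        acceptance.append(acc)
    draws = np.stack(all_draws)
    rhat = np.full(len(names), np.nan)
    if cfg.n_chains >= 2 and draws.shape[1] >= 10:
        means = draws.mean(axis=1)
        within = draws.var(axis=1, ddof=1).mean(axis=0)
        m = draws.shape[1]
        between = m * means.var(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            rhat = np.sqrt(((m - 1) / m * within + between / m) / within)
    return PosteriorSamples(
        draws=draws, names=names, area_ids=tuple(panel.area_ids),
        years=tuple(panel.years), config=cfg, rhat=rhat,
        acceptance=acceptance, chain_seeds=seeds,
    )


def gelman_rubin(draws: np.ndarray) -> float:
    """Plain (non-split) Gelman-Rubin potential scale reduction factor.

    ``draws`` is a (n_chains, n_iterations) array for one scalar
    parameter; requires >= 2 chains of >= 10 retained iterations.
    """
    draws = np.asarray(draws, dtype=np.float64)
    if draws.ndim != 2 or draws.shape[0] < 2 or draws.shape[1] < 10:
        raise ValueError("need a (chains >= 2, iterations >= 10) array")
    m = draws.shape[1]
    within = draws.var(axis=1, ddof=1).mean()
    if within == 0:
        raise ValueError("degenerate chains: all draws identical")
    between = m * draws.mean(axis=1).var(ddof=1)
    return float(np.sqrt(((m - 1) / m * within + between / m) / within))


def summarize(samples: PosteriorSamples, probs=(0.025, 0.5, 0.975)) -> pd.DataFrame:
    """Pooled-chain posterior mean, sd and equal-tailed quantiles."""
    c, m, p = samples.draws.shape
    if c * m == 0:
        raise ValueError("no retained draws")
    flat = samples.draws.reshape(c * m, p)
    out = pd.DataFrame(index=list(samples.names))
    out["mean"] = flat.mean(axis=0)
    out["sd"] = flat.std(axis=0, ddof=1) if c * m > 1 else 0.0
    qs = np.quantile(flat, probs, axis=0)
    for q, col in zip(probs, qs):
        out[f"q{100 * q:g}"] = col
    out["rhat"] = samples.rhat
    return out
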