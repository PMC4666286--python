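"""Gibbs sampler for grouped whole-genome regression.

One scan updates, in fixed order: the group intercepts, every effect block
(markers in index order, single-site updates), the block-level prior
parameters, and the group-specific residual variances.  The residual vector is
maintained incrementally and recomputed from scratch every 1000 iterations to
bound floating-point drift.

Full conditionals
-----------------
* intercepts: Gaussian, ``N(mean of group residual, sigma2_k / n_k)`` (flat
  prior);
* BRR effects: Gaussian with precision ``sum_k x_kj'x_kj / sigma2_k +
  1 / var_term`` — for the main block the sum runs over all groups so the
  update is a precision-weighted least-squares coordinate step, for a group
  block only that group's rows contribute;
* BayesB effects: Bernoulli inclusion with the effect integrated out, then a
  Gaussian draw if included, then the per-marker variance from its
  scaled-inverse-chi-square conditional;
* block variance (BRR): scaled-inv-chi2(df + p, (S df + sum b^2)/(df + p));
* slab scale (BayesB): Gamma conditional given ``sum_j 1/sigma2_j``;
  inclusion probability: Beta conditional from the indicator counts;
* residual variances: scaled-inv-chi2(df_k + n_k,
  (S_k df_k + SSE_k)/(df_k + n_k)) from group-k residuals only.

All randomness flows from one ``numpy.random.Generator`` seeded by the config,
so identical seed + config + data give a bit-identical chain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernels
from .datatypes import GroupedPhenotypes
from .model import (
    BRRPrior,
    BayesBPrior,
    DesignLayout,
    ModelConfig,
    default_hyperparameters,
)

__all__ = [
    "MCMCState",
    "PosteriorSummary",
    "fit",
    "predict",
    "update_intercepts",
    "update_effect_brr",
    "update_effect_bayesb",
    "update_variances",
    "spike_slab_log_odds",
]

logger = logging.getLogger(__name__)

_RESIDUAL_REFRESH = 1000       # full residual recomputation interval
_RESIDUAL_DRIFT_TOL = 1e-8


def spike_slab_log_odds(
    c0: float, rhs0: float, marker_var: float, pi: float
) -> float:
    """Posterior log-odds of inclusion for one marker.

    ``c0`` and ``rhs0`` are the precision-weighted squared column norm and
    residual inner product with the marker's effect removed; ``marker_var`` is
    the current slab variance and ``pi`` the inclusion probability.
    """
    return float(
        np.log(pi / (1.0 - pi))
        + _kernels.spike_logodds(float(c0), float(rhs0), float(marker_var))
    )


class MCMCState:
    """Mutable sampler state: all unknowns plus the incremental residual."""

    def __init__(self, y: GroupedPhenotypes, layout: DesignLayout, cfg: ModelConfig):
        self.layout = layout
        self.cfg = cfg
        self.prior = cfg.prior
        q, p = layout.q, layout.p
        # responses in sorted (grouped) order
        self.y = np.ascontiguousarray(y.values[layout.order])
        self.XT = np.ascontiguousarray(layout.X.T)
        self.gs = layout.group_starts
        self.n_k = layout.n_k.astype(np.float64)
        # per-group squared column norms
        self.xtx = np.empty((q, p))
        for k in range(q):
            sl = slice(self.gs[k], self.gs[k + 1])
            self.xtx[k] = np.einsum("ij,ij->j", layout.X[sl], layout.X[sl])
        # initial values
        self.mu = np.array(
            [self.y[self.gs[k]:self.gs[k + 1]].mean() for k in range(q)]
        )
        self.sigma2 = np.empty(q)
        for k, ep in enumerate(cfg.error_priors):
            self.sigma2[k] = (
                ep.fixed if ep.fixed is not None else ep.S * ep.df / (ep.df + 2.0)
            )
        self.beta = {name: np.zeros(p) for name, _ in layout.terms}
        self.block_var: dict[str, float] = {}
        self.delta: dict[str, np.ndarray] = {}
        self.s2j: dict[str, np.ndarray] = {}
        self.scale: dict[str, float] = {}
        self.pi: dict[str, float] = {}
        for name, _ in layout.terms:
            tp = cfg.effect_priors[name]
            if isinstance(tp, BRRPrior):
                self.block_var[name] = (
                    tp.fixed if tp.fixed is not None
                    else tp.S * tp.df / (tp.df + 2.0)
                )
            else:
                s0 = tp.scale_shape / tp.scale_rate  # prior mean of the scale
                self.scale[name] = s0
                self.pi[name] = tp.pi_a / (tp.pi_a + tp.pi_b)
                self.s2j[name] = np.full(p, s0 * tp.marker_df / max(tp.marker_df - 2.0, 0.5))
                self.delta[name] = np.ones(p, dtype=np.int64)
        self.e = self.y - self.mu[layout.labels_sorted - 1]
        self._zero_flagged: set[str] = set()

    # -- helpers ----------------------------------------------------------
    def _term_groups(self, name: str) -> tuple[int, int]:
        for tname, grp in self.layout.terms:
            if tname == name:
                return (0, self.layout.q) if grp is None else (grp - 1, grp)
        raise KeyError(name)

    def genetic_values_sorted(self) -> np.ndarray:
        """Current fitted genetic values (sorted order) from the state."""
        return self.y - self.mu[self.layout.labels_sorted - 1] - self.e

    def exact_residual(self) -> np.ndarray:
        pred = self.mu[self.layout.labels_sorted - 1].copy()
        X = self.layout.X
        for name, grp in self.layout.terms:
            b = self.beta[name]
            if grp is None:
                pred += X @ b
            else:
                sl = self.layout.group_rows(grp)
                pred[sl] += X[sl] @ b
        return self.y - pred


def update_intercepts(state: MCMCState, rng: np.random.Generator) -> None:
    """Draw each group intercept from its Gaussian full conditional."""
    for k in range(state.layout.q):
        sl = slice(state.gs[k], state.gs[k + 1])
        nk = state.n_k[k]
        old = state.mu[k]
        mean = old + state.e[sl].mean()
        new = rng.normal(mean, np.sqrt(state.sigma2[k] / nk))
        state.e[sl] -= new - old
        state.mu[k] = new


def _sweep_term(
    state: MCMCState,
    name: str,
    rng: np.random.Generator,
    j0: int = 0,
    j1: int | None = None,
) -> None:
    """Run single-site updates for markers ``j0..j1`` of block ``name``."""
    p = state.layout.p
    if j1 is None:
        j1 = p
    kfrom, kto = state._term_groups(name)
    winv = 1.0 / state.sigma2
    beta = state.beta[name]
    if state.prior == "BRR":
        var = state.block_var[name]
        if var == 0.0:
            if name not in state._zero_flagged:
                logger.warning("block %r has zero prior variance; effects pinned at 0", name)
                state._zero_flagged.add(name)
            nz = beta[j0:j1] != 0.0
            if nz.any():
                # restore residual contribution of the zeroed coefficients
                idx = np.nonzero(nz)[0] + j0
                for j in idx:
                    for k in range(kfrom, kto):
                        sl = slice(state.gs[k], state.gs[k + 1])
                        state.e[sl] += state.XT[j, sl] * beta[j]
                    beta[j] = 0.0
            _ = rng.standard_normal(p)  # keep the draw stream aligned
            return
        prior_prec = 0.0 if np.isinf(var) else 1.0 / var
        z = rng.standard_normal(p)
        _kernels.sweep_brr(
            state.XT, state.xtx, state.e, state.gs, kfrom, kto, winv,
            beta, prior_prec, z, j0, j1,
        )
    else:
        tp: BayesBPrior = state.cfg.effect_priors[name]
        pi = state.pi[name]
        pi = min(max(pi, 1e-12), 1.0 - 1e-12)
        z = rng.standard_normal(p)
        u = rng.random(p)
        chi_in = rng.chisquare(tp.marker_df + 1.0, p)
        chi_out = rng.chisquare(tp.marker_df, p)
        _kernels.sweep_bayesb(
            state.XT, state.xtx, state.e, state.gs, kfrom, kto, winv,
            beta, state.delta[name], state.s2j[name],
            state.scale[name], tp.marker_df, np.log(pi / (1.0 - pi)),
            z, u, chi_in, chi_out, j0, j1,
        )


def update_effect_brr(
    state: MCMCState, name: str, j: int, rng: np.random.Generator
) -> None:
    """Single Gaussian coordinate update for marker ``j`` of block ``name``."""
    _sweep_term(state, name, rng, j0=j, j1=j + 1)


def update_effect_bayesb(
    state: MCMCState, name: str, j: int, rng: np.random.Generator
) -> None:
    """Single spike-slab update for marker ``j`` of block ``name``."""
    _sweep_term(state, name, rng, j0=j, j1=j + 1)


def update_variances(state: MCMCState, rng: np.random.Generator) -> None:
    """Draw block-level prior parameters and residual variances."""
    cfg = state.cfg
    p = state.layout.p
    for name, _ in state.layout.terms:
        tp = cfg.effect_priors[name]
        if isinstance(tp, BRRPrior):
            if tp.fixed is not None:
                continue
            ssq = float(state.beta[name] @ state.beta[name])
            state.block_var[name] = (tp.S * tp.df + ssq) / rng.chisquare(tp.df + p)
        else:
            inv_sum = float(np.sum(1.0 / np.maximum(state.s2j[name], 1e-300)))
            shape = tp.scale_shape + 0.5 * p * tp.marker_df
            rate = tp.scale_rate + 0.5 * tp.marker_df * inv_sum
            state.scale[name] = rng.gamma(shape, 1.0 / rate)
            nin = int(state.delta[name].sum())
            state.pi[name] = rng.beta(tp.pi_a + nin, tp.pi_b + p - nin)
    for k, ep in enumerate(cfg.error_priors):
        if ep.fixed is not None:
            continue
        nk = state.n_k[k]
        if nk == 0:
            raise ValueError(f"group {k + 1} has no samples")
        sl = slice(state.gs[k], state.gs[k + 1])
        sse = float(state.e[sl] @ state.e[sl])
        state.sigma2[k] = max(
            (ep.S * ep.df + sse) / rng.chisquare(ep.df + nk), 1e-12
        )


@dataclass
class PosteriorSummary:
    """Posterior means/SDs of all unknowns plus thinned variance-level draws.

    ``samples`` holds one row per retained draw with columns ``sigma2_k``,
    per-term ``var_*`` (BRR) or ``scale_*``/``probin_*`` (BayesB), and
    ``genvar_*`` — the term's genomic variance on the total scale (``p`` times
    the BRR block variance; the sum of squared sampled effects under BayesB).
    """

    mode: str
    prior: str
    q: int
    p: int
    terms: list
    markers: list
    config: ModelConfig
    n_draws: int
    mu_mean: np.ndarray
    mu_sd: np.ndarray
    sigma2_mean: np.ndarray
    sigma2_sd: np.ndarray
    effect_mean: dict
    effect_sd: dict
    inclusion_prob: dict | None
    samples: pd.DataFrame
    genetic_value_mean: np.ndarray   # original sample order
    genetic_value_sd: np.ndarray
    sample_ids: list | None = None

    def to_frame(self) -> pd.DataFrame:
        """Tidy (term, parameter, mean, sd) table of variance-level summaries."""
        rows = []
        for k in range(self.q):
            rows.append(("intercept", f"mu_{k + 1}", self.mu_mean[k], self.mu_sd[k]))
        for k in range(self.q):
            rows.append(
                ("residual", f"sigma2_{k + 1}", self.sigma2_mean[k], self.sigma2_sd[k])
            )
        for name, _ in self.terms:
            for stem in ("var", "scale", "probin", "genvar"):
                col = f"{stem}_{name}"
                if col in self.samples.columns:
                    v = self.samples[col].to_numpy()
                    rows.append((name, stem, v.mean(), v.std(ddof=1) if len(v) > 1 else 0.0))
        return pd.DataFrame(rows, columns=["term", "parameter", "mean", "sd"])

    def effects_frame(self) -> pd.DataFrame:
        """Per-marker posterior effect means/SDs (and inclusion probabilities)."""
        out = {"marker": self.markers}
        for name, _ in self.terms:
            out[f"mean_{name}"] = self.effect_mean[name]
            out[f"sd_{name}"] = self.effect_sd[name]
            if self.inclusion_prob is not None:
                out[f"pip_{name}"] = self.inclusion_prob[name]
        return pd.DataFrame(out)


def predict(summary: PosteriorSummary, X: np.ndarray, group_labels) -> np.ndarray:
    """Point predictions from posterior-mean intercepts and effects.

    ``X`` must be on the same (standardized) scale as the training genotypes;
    ``group_labels`` are 1-based group indices for the new samples.
    """
    X = np.asarray(X, dtype=np.float64)
    labels = np.asarray(group_labels, dtype=np.int64)
    yhat = summary.mu_mean[labels - 1].copy()
    if summary.mode in ("across", "interaction"):
        yhat += X @ summary.effect_mean["main"]
    if summary.mode in ("stratified", "interaction"):
        for k in range(1, summary.q + 1):
            rows = labels == k
            if rows.any():
                yhat[rows] += X[rows] @ summary.effect_mean[f"group_{k}"]
    return yhat


def fit(
    y: GroupedPhenotypes, layout: DesignLayout, cfg: ModelConfig
) -> PosteriorSummary:
    """Run the Gibbs sampler and summarize the posterior.

    Missing priors in ``cfg`` are resolved from the data via
    :func:`wgreg.model.default_hyperparameters`; the fully resolved config is
    attached to the returned summary.  Deterministic given
    ``cfg.mcmc.seed``.
    """
    if y.n != layout.n:
        raise ValueError("phenotypes and design are not row-aligned")
    if y.q != layout.q:
        raise ValueError("phenotype group count does not match the design")
    cfg.validate()
    if cfg.mode != layout.mode:
        raise ValueError(
            f"config mode {cfg.mode!r} does not match layout mode {layout.mode!r}"
        )
    if cfg.error_priors is None or cfg.effect_priors is None:
        defaults = default_hyperparameters(y, layout, prior=cfg.prior, mcmc=cfg.mcmc)
        cfg = ModelConfig(
            mode=cfg.mode,
            prior=cfg.prior,
            error_priors=(
                cfg.error_priors if cfg.error_priors is not None
                else defaults.error_priors
            ),
            effect_priors=(
                cfg.effect_priors if cfg.effect_priors is not None
                else defaults.effect_priors
            ),
            mcmc=cfg.mcmc,
        )
    if len(cfg.error_priors) != layout.q:
        raise ValueError("need one error prior per group")
    missing = [n for n, _ in layout.terms if n not in cfg.effect_priors]
    if missing:
        raise ValueError(f"missing effect priors for terms: {missing}")

    rng = np.random.default_rng(cfg.mcmc.seed)
    state = MCMCState(y, layout, cfg)
    m = cfg.mcmc
    q, p, n = layout.q, layout.p, layout.n
    term_names = layout.term_names()
    is_bayesb = cfg.prior == "BayesB"

    # accumulators over retained draws
    eff_sum = {t: np.zeros(p) for t in term_names}
    eff_ssq = {t: np.zeros(p) for t in term_names}
    pip_sum = {t: np.zeros(p) for t in term_names} if is_bayesb else None
    mu_sum = np.zeros(q)
    mu_ssq = np.zeros(q)
    g_sum = np.zeros(n)
    g_ssq = np.zeros(n)
    rows = []
    n_draws = 0

    logger.info(
        "Gibbs: mode=%s prior=%s n=%d p=%d q=%d iterations=%d seed=%d",
        cfg.mode, cfg.prior, n, p, q, m.iterations, m.seed,
    )
    for it in range(m.iterations):
        update_intercepts(state, rng)
        for t in term_names:
            _sweep_term(state, t, rng)
        update_variances(state, rng)
        if not np.isfinite(state.e).all():
            raise RuntimeError(f"non-finite residual at iteration {it}")
        if (it + 1) % _RESIDUAL_REFRESH == 0:
            exact = state.exact_residual()
            drift = float(np.max(np.abs(state.e - exact)))
            if drift > _RESIDUAL_DRIFT_TOL:
                logger.warning("residual drift %.3e at iteration %d", drift, it)
            state.e = exact
        if it >= m.burnin and (it - m.burnin) % m.thin == 0:
            n_draws += 1
            mu_sum += state.mu
            mu_ssq += state.mu**2
            g = state.genetic_values_sorted()
            g_sum += g
            g_ssq += g**2
            row = {f"sigma2_{k + 1}": state.sigma2[k] for k in range(q)}
            for t in term_names:
                b = state.beta[t]
                eff_sum[t] += b
                eff_ssq[t] += b**2
                if is_bayesb:
                    pip_sum[t] += state.delta[t]
                    row[f"scale_{t}"] = state.scale[t]
                    row[f"probin_{t}"] = state.pi[t]
                    row[f"genvar_{t}"] = float(b @ b)
                else:
                    row[f"var_{t}"] = state.block_var[t]
                    row[f"genvar_{t}"] = p * state.block_var[t]
            rows.append(row)
    if n_draws == 0:
        raise ValueError("MCMC settings retain zero draws")
    logger.info("Gibbs finished: %d retained draws", n_draws)

    def _msd(s, ss, n_):
        mean = s / n_
        var = np.maximum(ss / n_ - mean**2, 0.0)
        sd = np.sqrt(var * n_ / max(n_ - 1, 1))
        return mean, sd

    mu_mean, mu_sd = _msd(mu_sum, mu_ssq, n_draws)
    g_mean_sorted, g_sd_sorted = _msd(g_sum, g_ssq, n_draws)
    g_mean = np.empty(n)
    g_sd = np.empty(n)
    g_mean[layout.order] = g_mean_sorted
    g_sd[layout.order] = g_sd_sorted
    samples = pd.DataFrame(rows)
    sig_cols = [f"sigma2_{k + 1}" for k in range(q)]
    sigma2_mean = samples[sig_cols].mean().to_numpy()
    sigma2_sd = samples[sig_cols].std(ddof=1).fillna(0.0).to_numpy()
    effect_mean = {}
    effect_sd = {}
    for t in term_names:
        effect_mean[t], effect_sd[t] = _msd(eff_sum[t], eff_ssq[t], n_draws)
    inclusion = (
        {t: pip_sum[t] / n_draws for t in term_names} if is_bayesb else None
    )
    return PosteriorSummary(
        mode=cfg.mode, prior=cfg.prior, q=q, p=p,
        terms=list(layout.terms), markers=list(layout.markers),
        config=cfg, n_draws=n_draws,
        mu_mean=mu_mean, mu_sd=mu_sd,
        sigma2_mean=sigma2_mean, sigma2_sd=sigma2_sd,
        effect_mean=effect_mean, effect_sd=effect_sd,
        inclusion_prob=inclusion, samples=samples,
        genetic_value_mean=g_mean, genetic_value_sd=g_sd,
    )
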