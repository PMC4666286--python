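"""Variance decomposition of fitted interaction models.

Under the interaction model the genomic variance of group k splits into the
main-effect variance shared by every group and the group's interaction
variance.  Two scalar summaries follow directly from the variance components:

* the proportion of genomic variance attributed to the main effect,
  ``var_main / (var_main + mean(var_int))`` (average form) or
  ``var_main / (var_main + var_int_k)`` (per-group form);
* the between-group correlation of total marker effects,
  ``var_main / sqrt((var_main + var_int_j)(var_main + var_int_j'))``,
  which is non-negative by construction (the shared main effect is the only
  source of covariance).

Both are reported as plug-in ratios of posterior means and as posterior means
of the per-draw ratios (with posterior SDs); the two agree on well-identified
fits but can differ when the variance posteriors are skewed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "correlation_of_effects",
    "main_effect_proportion",
    "VarianceDecomposition",
    "decompose",
    "decompose_from_samples",
]


def correlation_of_effects(var_main, var_int_j, var_int_jp):
    """Between-group correlation of total effects from variance components.

    Accepts scalars or aligned arrays (vectorized over posterior draws).
    """
    var_main = np.asarray(var_main, dtype=np.float64)
    var_int_j = np.asarray(var_int_j, dtype=np.float64)
    var_int_jp = np.asarray(var_int_jp, dtype=np.float64)
    if (var_main < 0).any() or (var_int_j < 0).any() or (var_int_jp < 0).any():
        raise ValueError("variance components must be non-negative")
    den2 = (var_main + var_int_j) * (var_main + var_int_jp)
    if (den2 <= 0).any():
        raise ValueError("both group totals are zero; correlation undefined")
    out = var_main / np.sqrt(den2)
    return float(out) if out.ndim == 0 else out


def main_effect_proportion(var_main, var_int, per_group: bool = False):
    """Share of genomic variance attributed to the main effect.

    ``var_int`` is the list of per-group interaction variances.  The average
    form uses their mean in the denominator; the per-group form returns one
    share per group.
    """
    var_int = np.atleast_1d(np.asarray(var_int, dtype=np.float64))
    if var_int.size == 0:
        raise ValueError("var_int must contain at least one group")
    var_main = np.asarray(var_main, dtype=np.float64)
    if (var_main < 0).any() or (var_int < 0).any():
        raise ValueError("variance components must be non-negative")
    if per_group:
        den = var_main + var_int
        if (den <= 0).any():
            raise ValueError("all components zero; proportion undefined")
        return var_main / den
    den = var_main + var_int.mean(axis=0 if var_int.ndim == 1 else -1)
    if np.any(den <= 0):
        raise ValueError("all components zero; proportion undefined")
    out = var_main / den
    return float(out) if np.ndim(out) == 0 else out


@dataclass
class VarianceDecomposition:
    """Plug-in and per-draw summaries of the interaction-model decomposition."""

    var_main: float
    var_int: np.ndarray                  # (q,)
    prop_main_avg: float                 # plug-in, average form
    prop_main_group: np.ndarray          # (q,) plug-in, per-group form
    cor_effects: np.ndarray              # (q, q) plug-in correlation matrix
    prop_main_avg_draws: tuple           # (mean, sd) of per-draw ratios
    prop_main_group_draws: tuple         # ((q,) means, (q,) sds)
    cor_effects_draws: tuple             # ((q,q) means, (q,q) sds)

    @property
    def q(self) -> int:
        return len(self.var_int)

    def to_frame(self) -> pd.DataFrame:
        """Tidy table keyed by (quantity, group/pair, estimator)."""
        rows = []
        rows.append(("var_main", "", "plug-in", self.var_main, np.nan))
        for k in range(self.q):
            rows.append((f"var_int", f"g{k + 1}", "plug-in", self.var_int[k], np.nan))
        rows.append(("prop_main_avg", "", "plug-in", self.prop_main_avg, np.nan))
        m, s = self.prop_main_avg_draws
        rows.append(("prop_main_avg", "", "per-draw", m, s))
        gm, gs = self.prop_main_group_draws
        for k in range(self.q):
            rows.append((f"prop_main", f"g{k + 1}", "plug-in", self.prop_main_group[k], np.nan))
            rows.append((f"prop_main", f"g{k + 1}", "per-draw", gm[k], gs[k]))
        cm, cs = self.cor_effects_draws
        for j in range(self.q):
            for jp in range(j + 1, self.q):
                pair = f"g{j + 1}-g{jp + 1}"
                rows.append(("cor_effects", pair, "plug-in", self.cor_effects[j, jp], np.nan))
                rows.append(("cor_effects", pair, "per-draw", cm[j, jp], cs[j, jp]))
        return pd.DataFrame(rows, columns=["quantity", "where", "estimator", "value", "sd"])


def decompose_from_samples(samples: pd.DataFrame, mode: str) -> VarianceDecomposition:
    """Decomposition from thinned genomic-variance draws (``genvar_*`` columns)."""
    if mode != "interaction":
        raise ValueError(
            f"variance decomposition is defined only for the interaction model, got {mode!r}"
        )
    if "genvar_main" not in samples.columns:
        raise ValueError("samples lack a genvar_main column")
    group_cols = sorted(
        (c for c in samples.columns if c.startswith("genvar_group_")),
        key=lambda c: int(c.rsplit("_", 1)[1]),
    )
    if not group_cols:
        raise ValueError("samples lack genvar_group_* columns")
    vm_draws = samples["genvar_main"].to_numpy()
    vi_draws = samples[group_cols].to_numpy()        # (draws, q)
    q = vi_draws.shape[1]
    vm = float(vm_draws.mean())
    vi = vi_draws.mean(axis=0)

    prop_avg = main_effect_proportion(vm, vi)
    prop_grp = main_effect_proportion(vm, vi, per_group=True)
    cor = np.ones((q, q))
    for j in range(q):
        for jp in range(q):
            if j != jp:
                cor[j, jp] = correlation_of_effects(vm, vi[j], vi[jp])

    # per-draw versions
    pa = vm_draws / (vm_draws + vi_draws.mean(axis=1))
    pg = vm_draws[:, None] / (vm_draws[:, None] + vi_draws)
    cd = np.ones((vi_draws.shape[0], q, q))
    for j in range(q):
        for jp in range(q):
            if j != jp:
                cd[:, j, jp] = correlation_of_effects(
                    vm_draws, vi_draws[:, j], vi_draws[:, jp]
                )

    def msd(a, axis=0):
        return a.mean(axis=axis), a.std(axis=axis, ddof=1)

    return VarianceDecomposition(
        var_main=vm, var_int=vi,
        prop_main_avg=float(prop_avg), prop_main_group=prop_grp,
        cor_effects=cor,
        prop_main_avg_draws=(float(pa.mean()), float(pa.std(ddof=1))),
        prop_main_group_draws=msd(pg),
        cor_effects_draws=msd(cd),
    )


def decompose(summary) -> VarianceDecomposition:
    """Variance decomposition of a fitted interaction-model posterior.

    Works for BRR fits (block-variance draws) and BayesB fits (genomic
    variances computed from the sampled effects).
    """
    return decompose_from_samples(summary.samples, summary.mode)
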