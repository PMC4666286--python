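"""Prediction-accuracy experiments and the stratified-ridge permutation test.

Two evaluation tools:

* replicated training-testing partitions with within-group Pearson accuracy —
  per partition, a test set of fixed size is drawn per group without
  replacement, each candidate model is fitted on the remaining samples, and
  predictions from posterior-mean effects are correlated with the held-out
  phenotypes within each group;
* a permutation diagnostic for heterogeneity of effects between two groups —
  ridge-estimated within-group marker-effect vectors are correlated under the
  true labels, and the same statistic is recomputed under label permutations
  (phenotypes and genotypes stay attached to their samples) to build a null
  in which the labels carry no information about the genetic architecture.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import Ridge

from .datatypes import GenotypeMatrix, GroupAssignment, GroupedPhenotypes
from .gibbs import fit, predict
from .model import ModelConfig, build_design

__all__ = [
    "TrnTstPlan",
    "AccuracyReport",
    "run_trn_tst",
    "ridge_within_cluster",
    "default_ridge_penalty",
    "PermutationResult",
    "permutation_effect_correlation",
]

logger = logging.getLogger(__name__)


@dataclass
class TrnTstPlan:
    """Replicated training-testing partition plan.

    ``tst_sizes[k]`` samples of group ``k+1`` are held out per partition;
    partitions are reproducible from ``seed``.
    """

    n_partitions: int
    tst_sizes: list
    seed: int = 0

    def partitions(self, groups: GroupAssignment):
        """Yield ``(trn_idx, tst_idx)`` index arrays per partition."""
        sizes = np.asarray(self.tst_sizes, dtype=np.int64)
        if len(sizes) != groups.q:
            raise ValueError("need one test-set size per group")
        if (sizes >= groups.sizes).any():
            raise ValueError("test-set size must be smaller than the group")
        rng = np.random.default_rng(self.seed)
        group_idx = [np.nonzero(groups.labels == k)[0] for k in range(1, groups.q + 1)]
        out = []
        for _ in range(self.n_partitions):
            tst = np.concatenate(
                [rng.choice(gi, size=s, replace=False) for gi, s in zip(group_idx, sizes)]
            )
            mask = np.ones(groups.n, dtype=bool)
            mask[tst] = False
            out.append((np.nonzero(mask)[0], np.sort(tst)))
        return out


@dataclass
class AccuracyReport:
    """Within-group accuracies per (partition, group, model) plus aggregates."""

    table: pd.DataFrame  # columns: partition, group, model, accuracy

    def aggregate(self) -> pd.DataFrame:
        """Mean (SD) accuracy per (model, group), undefined cells excluded."""
        g = self.table.groupby(["model", "group"])["accuracy"]
        out = g.agg(mean="mean", sd="std", n="count").reset_index()
        return out


def run_trn_tst(
    geno_std: GenotypeMatrix,
    y: GroupedPhenotypes,
    groups: GroupAssignment,
    plan: TrnTstPlan,
    configs: dict[str, ModelConfig],
) -> AccuracyReport:
    """Replicated training-testing evaluation of one or more model configs.

    For every partition each config is fitted on the training rows only
    (data-dependent default priors are re-derived per training set when the
    config leaves them unset) and held-out samples are predicted from
    posterior-mean effects.  Cells where the correlation is undefined
    (zero-variance predictions or phenotypes) are recorded as missing and
    excluded from aggregates.
    """
    rows = []
    X = geno_std.dosages
    for part, (trn, tst) in enumerate(plan.partitions(groups)):
        g_trn = GroupAssignment(labels=groups.labels[trn], q=groups.q)
        geno_trn = geno_std.reorder_samples(trn)
        y_trn = GroupedPhenotypes(
            values=y.values[trn], group=groups.labels[trn], q=groups.q
        )
        for label, cfg in configs.items():
            layout = build_design(geno_trn, g_trn, cfg.mode)
            summary = fit(y_trn, layout, cfg)
            yhat = predict(summary, X[tst], groups.labels[tst])
            for k in range(1, groups.q + 1):
                sel = groups.labels[tst] == k
                obs = y.values[tst][sel]
                pred = yhat[sel]
                if obs.std() == 0 or pred.std() == 0:
                    logger.warning(
                        "undefined correlation (zero variance) in partition %d, "
                        "group %d, model %s", part, k, label,
                    )
                    acc = np.nan
                else:
                    acc = float(np.corrcoef(pred, obs)[0, 1])
                rows.append((part, k, label, acc))
    return AccuracyReport(
        table=pd.DataFrame(rows, columns=["partition", "group", "model", "accuracy"])
    )


def default_ridge_penalty(p: int, h2: float = 0.5) -> float:
    """Ridge penalty ``p (1 - h2) / h2`` for standardized markers.

    With unit-variance markers and heritability ``h2`` split over ``p``
    markers, the mixed-model shrinkage parameter is sigma2_e / sigma2_b =
    p (1 - h2) / h2; the default assumes h2 = 0.5, giving ``p``.
    """
    if not (0.0 < h2 < 1.0):
        raise ValueError("h2 must lie in (0, 1)")
    return p * (1.0 - h2) / h2


def ridge_within_cluster(
    geno_std: GenotypeMatrix,
    y: GroupedPhenotypes,
    groups: GroupAssignment,
    ridge_penalty: float | None = None,
) -> dict[int, np.ndarray]:
    """Penalized least-squares marker effects estimated per group.

    Each group is solved independently with its own intercept; the penalty
    defaults to :func:`default_ridge_penalty`.  Returns ``{k: (p,) effects}``.
    """
    lam = default_ridge_penalty(geno_std.p) if ridge_penalty is None else ridge_penalty
    if lam < 0:
        raise ValueError("ridge penalty must be non-negative")
    out: dict[int, np.ndarray] = {}
    for k in range(1, groups.q + 1):
        rows = groups.labels == k
        if rows.sum() < 2:
            raise ValueError(f"group {k} needs at least 2 samples")
        Xk = geno_std.dosages[rows]
        yk = y.values[rows]
        if lam == 0.0:
            XtX = Xk.T @ Xk
            if np.linalg.matrix_rank(XtX) < geno_std.p:
                raise ValueError("singular system: a positive penalty is required")
        model = Ridge(alpha=lam, fit_intercept=True, solver="cholesky")
        model.fit(Xk, yk)
        out[k] = model.coef_.copy()
    return out


@dataclass
class PermutationResult:
    """Observed correlation of within-group effect estimates and its null."""

    observed: float
    null_samples: np.ndarray
    p_value: float = field(init=False)

    def __post_init__(self) -> None:
        ns = self.null_samples
        self.p_value = float((1 + np.sum(ns <= self.observed)) / (len(ns) + 1))

    @property
    def null_mean(self) -> float:
        return float(self.null_samples.mean())

    @property
    def null_median(self) -> float:
        return float(np.median(self.null_samples))

    @property
    def null_p2(self) -> float:
        """2nd percentile of the permutation null."""
        return float(np.percentile(self.null_samples, 2))


def permutation_effect_correlation(
    geno_std: GenotypeMatrix,
    y: GroupedPhenotypes,
    groups: GroupAssignment,
    n_perm: int = 1000,
    seed: int = 0,
    ridge_penalty: float | None = None,
) -> PermutationResult:
    """Permutation null for the correlation of within-group effect estimates.

    Defined for exactly two groups.  The observed statistic is the Pearson
    correlation between the two groups' ridge-estimated effect vectors under
    the true labels; the null re-shuffles the group labels (preserving group
    sizes) so labels become independent of the genetic architecture.  The
    empirical p-value is the fraction of null draws at or below the observed
    value (add-one corrected).
    """
    if groups.q != 2:
        raise ValueError("the permutation diagnostic is defined for two groups")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")

    def stat(assign: GroupAssignment) -> float:
        eff = ridge_within_cluster(geno_std, y, assign, ridge_penalty)
        return float(np.corrcoef(eff[1], eff[2])[0, 1])

    observed = stat(groups)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for b in range(n_perm):
        perm = GroupAssignment(labels=rng.permutation(groups.labels), q=2)
        null[b] = stat(perm)
    return PermutationResult(observed=observed, null_samples=null)
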