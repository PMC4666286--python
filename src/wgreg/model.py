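"""Model configuration and design assembly for grouped whole-genome regression.

Three analysis modes share one machinery:

* ``across``     — one set of marker effects ``b0`` for the whole sample;
* ``stratified`` — an independent set ``b_k`` per group (no shared component);
* ``interaction``— both: a sample in group k has marker effect
  ``b0_j + b_kj``, so effects decompose into an across-group main component
  and group-specific deviations.

All modes use group-specific intercepts ``mu_k`` (flat priors) and
group-specific residual variances ``sigma2_k`` with scaled-inverse-chi-square
priors.  Marker-effect blocks take either a Gaussian prior with an unknown
common variance (BRR) or a spike-slab prior with a scaled-t slab (BayesB:
per-marker variances with fixed df, random scale, random inclusion
probability).

The block design of the interaction model — ``[X1;X2] b0 + [X1;0] b1 +
[0;X2] b2`` for two groups, extended with one more deviation block per extra
group — is never materialized with its zero blocks: :class:`DesignLayout`
stores the genotype matrix once, with samples sorted by group, and each block
records which group's rows it touches.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from .datatypes import GenotypeMatrix, GroupAssignment, GroupedPhenotypes

__all__ = [
    "MODES",
    "PRIORS",
    "MCMCSettings",
    "ErrorPrior",
    "BRRPrior",
    "BayesBPrior",
    "ModelConfig",
    "DesignLayout",
    "build_design",
    "default_hyperparameters",
]

MODES = ("across", "stratified", "interaction")
PRIORS = ("BRR", "BayesB")


@dataclass
class MCMCSettings:
    """Gibbs-sampler run length.  Defaults favour full-data inference runs;
    cross-validation loops typically use shorter chains."""

    iterations: int = 15000
    burnin: int = 5000
    thin: int = 5
    seed: int = 0

    def validate(self) -> None:
        if self.iterations <= self.burnin:
            raise ValueError("iterations must exceed burnin")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")


@dataclass
class ErrorPrior:
    """Scaled-inverse-chi-square prior for one group's residual variance."""

    S: float
    df: float = 5.0
    fixed: float | None = None  # pin sigma2_k at this value (no sampling)

    def validate(self) -> None:
        if self.S <= 0 or self.df <= 0:
            raise ValueError("error prior requires S > 0 and df > 0")


@dataclass
class BRRPrior:
    """Gaussian effects with a common variance; the variance itself gets a
    scaled-inverse-chi-square hyperprior (mode ``S * df / (df + 2)``)."""

    S: float
    df: float = 5.0
    fixed: float | None = None  # pin the block variance (BLUP-style runs)

    def validate(self) -> None:
        if self.fixed is None and (self.S <= 0 or self.df <= 0):
            raise ValueError("BRR prior requires S > 0 and df > 0")


@dataclass
class BayesBPrior:
    """Spike-slab with a scaled-t slab: per-marker variances sigma2_j ~
    scaled-inv-chi2(scale, marker_df) with ``marker_df`` fixed (default 5), the
    common scale random with a Gamma(shape, rate) hyperprior, and the inclusion
    probability pi random with a Beta(pi_a, pi_b) prior."""

    scale_shape: float
    scale_rate: float
    marker_df: float = 5.0
    pi_a: float = 5.0
    pi_b: float = 5.0

    def validate(self) -> None:
        if min(self.scale_shape, self.scale_rate, self.marker_df) <= 0:
            raise ValueError("BayesB hyperparameters must be positive")
        if min(self.pi_a, self.pi_b) <= 0:
            raise ValueError("Beta prior counts must be positive")


@dataclass
class ModelConfig:
    """Everything needed to reproduce one fit.

    ``error_priors`` / ``effect_priors`` may be left ``None``: the sampler then
    resolves them from the data via :func:`default_hyperparameters` and echoes
    the fully resolved configuration in the returned summary.
    """

    mode: str = "interaction"
    prior: str = "BRR"
    error_priors: list[ErrorPrior] | None = None            # one per group
    effect_priors: dict[str, BRRPrior | BayesBPrior] | None = None  # per term
    mcmc: MCMCSettings = field(default_factory=MCMCSettings)

    def validate(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}; expected one of {MODES}")
        if self.prior not in PRIORS:
            raise ValueError(f"unknown prior {self.prior!r}; expected one of {PRIORS}")
        self.mcmc.validate()
        if self.error_priors is not None:
            for ep in self.error_priors:
                ep.validate()
        if self.effect_priors is not None:
            for tp in self.effect_priors.values():
                tp.validate()

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        def pyify(x):
            if isinstance(x, dict):
                return {k: pyify(v) for k, v in x.items()}
            if isinstance(x, (list, tuple)):
                return [pyify(v) for v in x]
            if isinstance(x, np.generic):
                return x.item()
            return x

        d = pyify(asdict(self))
        d["_prior_class"] = "BayesB" if self.prior == "BayesB" else "BRR"
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        d.pop("_prior_class", None)
        mcmc = MCMCSettings(**d.get("mcmc", {}))
        eps = d.get("error_priors")
        error_priors = [ErrorPrior(**e) for e in eps] if eps else None
        tps = d.get("effect_priors")
        effect_priors = None
        if tps:
            prior_cls = BayesBPrior if d.get("prior") == "BayesB" else BRRPrior
            effect_priors = {k: prior_cls(**v) for k, v in tps.items()}
        return cls(
            mode=d.get("mode", "interaction"),
            prior=d.get("prior", "BRR"),
            error_priors=error_priors,
            effect_priors=effect_priors,
            mcmc=mcmc,
        )

    @classmethod
    def from_yaml(cls, path) -> "ModelConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class DesignLayout:
    """Per-group view of the marker matrix plus the block structure.

    Samples are sorted by group so each group occupies a contiguous row slice
    ``group_starts[k-1]:group_starts[k]``; ``order`` maps sorted positions back
    to the original sample order.  ``terms`` lists the effect blocks as
    ``(name, group)`` pairs with ``group=None`` for the main (across-group)
    block; every block spans all p markers.
    """

    X: np.ndarray                 # (n, p) standardized, sorted by group
    order: np.ndarray             # original index of each sorted row
    group_starts: np.ndarray      # (q+1,) offsets into sorted rows
    labels_sorted: np.ndarray     # (n,) group of each sorted row
    terms: list                   # [(name, group|None), ...]
    mode: str
    q: int
    markers: list

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def n_k(self) -> np.ndarray:
        return np.diff(self.group_starts)

    def term_names(self) -> list:
        return [t[0] for t in self.terms]

    def group_rows(self, k: int) -> slice:
        """Sorted-row slice of group ``k`` (1-based)."""
        return slice(self.group_starts[k - 1], self.group_starts[k])


def build_design(
    geno_std: GenotypeMatrix, groups: GroupAssignment, mode: str
) -> DesignLayout:
    """Assemble the data-equation layout for the requested analysis mode.

    The marker effect seen by a sample in group k is ``b0_j + b_kj`` in
    interaction mode, ``b0_j`` in across mode and ``b_kj`` in stratified mode;
    extra groups simply add one deviation block each.
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")
    if not geno_std.standardized:
        raise ValueError("build_design expects standardized genotypes")
    if geno_std.n != groups.n:
        raise ValueError("genotypes and group assignment are not aligned")
    if (groups.sizes < 1).any():
        raise ValueError("every group needs at least one sample")
    order = np.argsort(groups.labels, kind="stable")
    labels_sorted = groups.labels[order]
    q = groups.q
    starts = np.zeros(q + 1, dtype=np.int64)
    starts[1:] = np.cumsum(np.bincount(labels_sorted, minlength=q + 1)[1:])
    if mode == "across":
        terms = [("main", None)]
    elif mode == "stratified":
        terms = [(f"group_{k}", k) for k in range(1, q + 1)]
    else:
        terms = [("main", None)] + [(f"group_{k}", k) for k in range(1, q + 1)]
    X = np.ascontiguousarray(geno_std.dosages[order])
    return DesignLayout(
        X=X, order=order, group_starts=starts, labels_sorted=labels_sorted,
        terms=terms, mode=mode, q=q, markers=list(geno_std.markers),
    )


def _sichi2_scale_for_mode(mode_value: float, df: float) -> float:
    # mode of scaled-inv-chi2(S, df) is S*df/(df+2); invert for S
    return mode_value * (df + 2.0) / df


def default_hyperparameters(
    y: GroupedPhenotypes,
    layout: DesignLayout,
    prior: str = "BRR",
    mcmc: MCMCSettings | None = None,
) -> ModelConfig:
    """Weakly-informative defaults from a variance budget.

    Half of the (within-group average) phenotypic variance is assigned a
    priori to the residual and half to the genomic terms, the genomic share
    split equally across the blocks.  Error priors use df=5 with the scale set
    so the prior mode of ``sigma2_k`` is half the within-group phenotypic
    variance.  BRR block-variance hyperpriors likewise place their prior mode
    at the block's equal share (per-marker scale).  BayesB uses marker df=5, a
    Beta(5, 5) inclusion prior (mean 0.5, weight of ten prior observations)
    and a Gamma hyperprior on the slab scale whose mode matches the budget.
    """
    if prior not in PRIORS:
        raise ValueError(f"unknown prior {prior!r}")
    q, p = layout.q, layout.p
    if p == 0:
        raise ValueError(
            "cannot derive effect hyperparameters for zero markers; "
            "supply effect_priors explicitly"
        )
    var_k = np.empty(q)
    for k in range(1, q + 1):
        vals = y.group_values(k)
        if len(vals) < 2:
            raise ValueError(f"need at least 2 phenotypes in group {k}")
        var_k[k - 1] = vals.var(ddof=1)
        if var_k[k - 1] <= 0:
            raise ValueError(f"constant phenotypes in group {k}")
    error_priors = [
        ErrorPrior(S=_sichi2_scale_for_mode(0.5 * v, 5.0), df=5.0) for v in var_k
    ]
    n_terms = len(layout.terms)
    var_pheno = float(var_k.mean())
    term_share = 0.5 * var_pheno / n_terms     # genomic variance per block
    per_marker = term_share / p                # on the per-marker scale
    effect_priors: dict[str, BRRPrior | BayesBPrior] = {}
    for name, _ in layout.terms:
        if prior == "BRR":
            effect_priors[name] = BRRPrior(
                S=_sichi2_scale_for_mode(per_marker, 5.0), df=5.0
            )
        else:
            df_m, pi0 = 5.0, 0.5
            # E[sigma2_j] = S*df/(df-2); want p * pi0 * E[sigma2_j] = term_share
            s_star = term_share * (df_m - 2.0) / (df_m * p * pi0)
            effect_priors[name] = BayesBPrior(
                scale_shape=1.1, scale_rate=0.1 / s_star, marker_df=df_m
            )
    cfg = ModelConfig(
        mode=layout.mode,
        prior=prior,
        error_priors=error_priors,
        effect_priors=effect_priors,
        mcmc=mcmc if mcmc is not None else MCMCSettings(),
    )
    cfg.validate()
    return cfg
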