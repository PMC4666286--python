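"""Synthetic multi-subpopulation genotype/phenotype generator with known truth.

The generator emulates a structured breeding population: two or more
subpopulations whose allele frequencies have drifted apart (a Balding-Nichols
style Beta model parameterized by a differentiation coefficient F), marker
effects that decompose into a shared main effect plus group-specific
deviations, and group-specific residual variances.  Markers are simulated
independently (no linkage disequilibrium), so the generator probes the
statistical machinery, not LD-driven phenomena.

Truth variances are expressed on the scale of standardized genotypes: effects
are drawn so that the *total* genomic variance contributed by a term equals
the requested value, i.e. per-marker effect variance ``var / (p * pi)`` on the
shared support.  The implied between-group correlation of total effects is
``var_main / sqrt((var_main + var_k)(var_main + var_k'))`` by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datatypes import GenotypeMatrix, GroupAssignment, GroupedPhenotypes

__all__ = [
    "SyntheticTruth",
    "simulate_genotypes",
    "simulate_effects",
    "simulate_phenotypes",
    "simulate_dataset",
    "genetic_values",
]

_FREQ_LO, _FREQ_HI = 0.01, 0.99


@dataclass
class SyntheticTruth:
    """Ground-truth parameters of a simulated data set."""

    p: int
    q: int
    b_main: np.ndarray                      # (p,) shared effects
    b_dev: np.ndarray                       # (q, p) group deviations
    var_main: float
    var_int: np.ndarray                     # (q,) requested deviation variances
    mu: np.ndarray                          # (q,) group intercepts
    sigma2: np.ndarray                      # (q,) residual variances
    group_sizes: np.ndarray | None = None
    group_freqs: np.ndarray | None = None   # (q, p) generating allele freqs
    ancestral_freq: np.ndarray | None = None

    def total_effects(self, k: int) -> np.ndarray:
        """Total marker effects ``b_main + b_dev`` for group ``k`` (1-based)."""
        return self.b_main + self.b_dev[k - 1]

    def implied_correlation(self, k: int, kp: int) -> float:
        """Correlation of effects implied by the variance decomposition."""
        vm = self.var_main
        den = np.sqrt((vm + self.var_int[k - 1]) * (vm + self.var_int[kp - 1]))
        return float(vm / den) if den > 0 else 0.0

    def realized_correlation(self, k: int, kp: int) -> float:
        """Empirical correlation of the drawn total-effect vectors."""
        a, b = self.total_effects(k), self.total_effects(kp)
        if a.std() == 0 or b.std() == 0:
            return float("nan")
        return float(np.corrcoef(a, b)[0, 1])


def simulate_genotypes(
    n_k,
    p: int,
    differentiation: float = 0.2,
    seed: int = 0,
    inbred: bool = False,
):
    """Simulate allele dosages for ``q = len(n_k)`` differentiated groups.

    Ancestral frequencies are Uniform(0.1, 0.9); each group's frequency is a
    Beta draw centered on the ancestral one with spread controlled by the
    differentiation coefficient ``F in [0, 1)`` (``F -> 0`` uses the ancestral
    frequency exactly).  Dosages are Binomial(2, freq) per sample, or
    Bernoulli(freq) in ``inbred`` mode.  Frequencies are clamped to
    [0.01, 0.99].

    Returns ``(GenotypeMatrix, GroupAssignment, group_freqs)`` where
    ``group_freqs`` is the ``(q, p)`` matrix of generating frequencies.
    """
    n_k = np.asarray(n_k, dtype=np.int64)
    q = len(n_k)
    if p <= 0:
        raise ValueError("p must be positive")
    if (n_k <= 0).any():
        raise ValueError("every group size must be positive")
    if not (0.0 <= differentiation < 1.0):
        raise ValueError("differentiation F must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    anc = rng.uniform(0.1, 0.9, size=p)
    F = differentiation
    if F < 1e-12:
        freqs = np.tile(anc, (q, 1))
    else:
        a = anc * (1.0 - F) / F
        b = (1.0 - anc) * (1.0 - F) / F
        freqs = rng.beta(a, b, size=(q, p))
    freqs = np.clip(freqs, _FREQ_LO, _FREQ_HI)
    ploidy = 1 if inbred else 2
    blocks = [
        rng.binomial(ploidy, freqs[k], size=(n_k[k], p)).astype(np.float64)
        for k in range(q)
    ]
    X = np.vstack(blocks)
    labels = np.repeat(np.arange(1, q + 1), n_k)
    n = int(n_k.sum())
    geno = GenotypeMatrix(
        samples=[f"s{i:05d}" for i in range(n)],
        markers=[f"m{j:05d}" for j in range(p)],
        dosages=X,
    )
    return geno, GroupAssignment(labels=labels, q=q), freqs


def simulate_effects(
    p: int,
    var_main: float,
    var_int,
    sparsity: float = 1.0,
    seed: int = 0,
    shared_support: bool = True,
    mu=None,
    sigma2=None,
) -> SyntheticTruth:
    """Draw main effects and group deviations with known variances.

    A ``sparsity`` fraction of markers carries non-null effects; on that
    support, main effects are N(0, var_main / m) with ``m = round(p * pi)``
    so the total main-effect genomic variance equals ``var_main``; deviations
    are drawn likewise from each group's ``var_int``.  By default all terms
    share one support (group deviations on the same loci as main effects); a
    disjoint-support mode draws an independent support per deviation term to
    probe model misspecification.
    """
    var_int = np.asarray(var_int, dtype=np.float64)
    q = len(var_int)
    if var_main < 0 or (var_int < 0).any():
        raise ValueError("variances must be non-negative")
    if not (0.0 < sparsity <= 1.0):
        raise ValueError("sparsity must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    m = max(1, int(round(p * sparsity)))

    def draw(var: float, support: np.ndarray) -> np.ndarray:
        b = np.zeros(p)
        if var > 0:
            b[support] = rng.normal(0.0, np.sqrt(var / m), size=m)
        return b

    support = rng.choice(p, size=m, replace=False)
    b_main = draw(var_main, support)
    b_dev = np.zeros((q, p))
    for k in range(q):
        sup_k = support if shared_support else rng.choice(p, size=m, replace=False)
        b_dev[k] = draw(var_int[k], sup_k)
    mu = np.zeros(q) if mu is None else np.asarray(mu, dtype=np.float64)
    sigma2 = np.ones(q) if sigma2 is None else np.asarray(sigma2, dtype=np.float64)
    if mu.shape != (q,) or sigma2.shape != (q,):
        raise ValueError("mu and sigma2 must have one entry per group")
    return SyntheticTruth(
        p=p, q=q, b_main=b_main, b_dev=b_dev,
        var_main=float(var_main), var_int=var_int,
        mu=mu, sigma2=sigma2,
    )


def genetic_values(
    geno_std: GenotypeMatrix, groups: GroupAssignment, truth: SyntheticTruth
) -> np.ndarray:
    """Per-sample genetic values ``x_i' (b_main + b_dev[group_i])``."""
    if geno_std.p != truth.p:
        raise ValueError("marker dimension mismatch between genotypes and truth")
    g = np.empty(geno_std.n)
    for k in range(1, truth.q + 1):
        rows = groups.labels == k
        g[rows] = geno_std.dosages[rows] @ truth.total_effects(k)
    return g


def simulate_phenotypes(
    geno_std: GenotypeMatrix,
    groups: GroupAssignment,
    truth: SyntheticTruth,
    seed: int = 0,
) -> GroupedPhenotypes:
    """Phenotypes ``y = mu_k + x'(b_main + b_dev_k) + N(0, sigma2_k)``.

    Genotypes should be standardized so the truth variances live on the same
    scale as the fitted genomic variances.
    """
    if geno_std.p != truth.p:
        raise ValueError("marker dimension mismatch between genotypes and truth")
    if groups.q != truth.q:
        raise ValueError("group count mismatch between labels and truth")
    rng = np.random.default_rng(seed)
    g = genetic_values(geno_std, groups, truth)
    sd = np.sqrt(truth.sigma2[groups.labels - 1])
    y = truth.mu[groups.labels - 1] + g + rng.normal(0.0, 1.0, size=geno_std.n) * sd
    return GroupedPhenotypes(values=y, group=groups.labels, q=groups.q,
                             samples=list(geno_std.samples))


def simulate_dataset(
    n_k,
    p: int,
    var_main: float,
    var_int,
    differentiation: float = 0.2,
    sparsity: float = 1.0,
    mu=None,
    sigma2=None,
    seed: int = 0,
    shared_support: bool = True,
    inbred: bool = False,
):
    """One-call generator: genotypes, labels, standardized genotypes,
    phenotypes and the truth object.

    Returns ``(geno, geno_std, groups, phenos, truth)``.  Seeds for the three
    stages are derived from ``seed`` so the stages stay independent.
    """
    from .preprocess import center_scale_genotypes

    ss = np.random.SeedSequence(seed)
    s_geno, s_eff, s_phen = [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(3)]
    geno, groups, freqs = simulate_genotypes(
        n_k, p, differentiation=differentiation, seed=s_geno, inbred=inbred
    )
    geno_std = center_scale_genotypes(geno)
    truth = simulate_effects(
        p, var_main, var_int, sparsity=sparsity, seed=s_eff,
        shared_support=shared_support, mu=mu, sigma2=sigma2,
    )
    truth.group_sizes = np.asarray(n_k, dtype=np.int64)
    truth.group_freqs = freqs
    if geno_std.p != p:
        # monomorphic markers were dropped; restrict the truth accordingly
        kept = [geno.markers.index(mk) for mk in geno_std.markers]
        truth.b_main = truth.b_main[kept]
        truth.b_dev = truth.b_dev[:, kept]
        truth.group_freqs = freqs[:, kept]
        truth.p = geno_std.p
    phenos = simulate_phenotypes(geno_std, groups, truth, seed=s_phen)
    return geno, geno_std, groups, phenos, truth
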