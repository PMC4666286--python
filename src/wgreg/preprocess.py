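"""Genotype standardization, genomic relationships, PCs, pruning, clustering.

The preprocessing pipeline mirrors standard practice in genomic prediction:
markers are centered and scaled *across the whole sample* (never within
group), the genomic relationship matrix is ``G = W W' / p``, population
structure is summarized by the leading eigenvectors of ``G``, and subpopulation
labels are obtained by clustering samples in PC space.  The clusterer here is
k-means on the leading PC scores; any externally derived labels can be supplied
instead (see :class:`wgreg.datatypes.GroupAssignment`), which is the
recommended route when reproducing an analysis whose clustering came from a
dedicated admixture model.
"""

from __future__ import annotations

import logging

import numpy as np
from sklearn.cluster import KMeans

from .datatypes import GenotypeMatrix, GRM, GroupAssignment

__all__ = [
    "center_scale_genotypes",
    "compute_grm",
    "pca_decompose",
    "prune_markers_by_correlation",
    "assign_clusters",
]

logger = logging.getLogger(__name__)


def center_scale_genotypes(geno: GenotypeMatrix) -> GenotypeMatrix:
    """Center each marker to zero mean and scale to unit sample variance.

    The sample variance uses the n-1 divisor, and both moments are computed
    over all samples jointly.  Monomorphic (zero-variance) markers cannot be
    scaled and are dropped with a logged warning.

    Raises
    ------
    ValueError
        If missing values are present (impute first, e.g. via
        ``read_genotypes(..., impute=True)``) or if every column is
        zero-variance.
    """
    X = geno.dosages
    if np.isnan(X).any():
        raise ValueError(
            "genotype matrix contains missing values; impute before "
            "standardization (e.g. marker-mean imputation at read time)"
        )
    if geno.n < 2:
        raise ValueError("standardization requires at least two samples")
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0.0
    if not keep.any():
        raise ValueError("all markers are monomorphic; nothing to standardize")
    dropped = [m for m, k in zip(geno.markers, keep) if not k]
    if dropped:
        logger.warning(
            "dropping %d zero-variance marker(s): %s", len(dropped), dropped
        )
    W = (X[:, keep] - mean[keep]) / sd[keep]
    return GenotypeMatrix(
        samples=geno.samples,
        markers=[m for m, k in zip(geno.markers, keep) if k],
        dosages=W,
        standardized=True,
    )


def compute_grm(geno_std: GenotypeMatrix) -> GRM:
    """Genomic relationship matrix ``G = p^{-1} W W'``.

    With the n-1 standardization convention every column of ``W`` has squared
    norm n-1, hence ``trace(G) = n-1`` and the mean diagonal is ``(n-1)/n``.
    """
    if not geno_std.standardized:
        raise ValueError("compute_grm expects standardized genotypes")
    if geno_std.p == 0:
        raise ValueError("cannot compute a GRM from zero markers")
    if geno_std.n == 1:
        logger.warning("GRM of a single sample is degenerate (1x1 zero-variance)")
    W = geno_std.dosages
    G = (W @ W.T) / geno_std.p
    G = (G + G.T) / 2.0  # enforce exact symmetry against float round-off
    return GRM(matrix=G, samples=list(geno_std.samples))


def pca_decompose(g: GRM, k: int):
    """Leading principal components of a GRM.

    Returns ``(scores, explained)`` where ``scores`` is ``n x k`` with
    ``scores @ scores.T`` reproducing ``G`` in the full-rank limit
    (columns are eigenvectors scaled by the square root of their eigenvalue),
    and ``explained[i] = lambda_i / sum(lambda)`` with eigenvalues sorted in
    descending order.  Small negative eigenvalues from round-off are clipped
    at zero.
    """
    if k > g.n:
        raise ValueError(f"k={k} exceeds the matrix dimension n={g.n}")
    if k < 1:
        raise ValueError("k must be >= 1")
    evals, evecs = np.linalg.eigh(g.matrix)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    if evals.min() < -1e-8 * max(evals.max(), 1.0):
        raise ValueError("matrix is not positive semi-definite")
    evals = np.clip(evals, 0.0, None)
    g.eigenvalues = evals
    total = evals.sum()
    if total <= 0:
        raise ValueError("degenerate spectrum: all eigenvalues are zero")
    scores = evecs[:, :k] * np.sqrt(evals[:k])
    explained = evals[:k] / total
    return scores, explained


def prune_markers_by_correlation(
    geno: GenotypeMatrix, threshold: float
) -> GenotypeMatrix:
    """Greedy left-to-right pruning of correlated markers.

    A marker is retained iff its absolute Pearson correlation with every
    already-retained marker is strictly below ``threshold``.  The greedy order
    is the input marker order, so the result is deterministic.  Zero-variance
    markers (undefined correlation) are dropped with a warning.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError("threshold must lie in (0, 1]")
    if geno.p < 1:
        raise ValueError("need at least one marker")
    X = geno.dosages
    sd = X.std(axis=0, ddof=1)
    mean = X.mean(axis=0)
    kept: list[int] = []
    Z_cols: list[np.ndarray] = []  # unit-norm centered columns of kept markers
    for j in range(geno.p):
        if sd[j] == 0.0:
            logger.warning("dropping zero-variance marker %r during pruning", geno.markers[j])
            continue
        z = (X[:, j] - mean[j])
        z = z / np.linalg.norm(z)
        if Z_cols:
            corr = np.abs(np.asarray(Z_cols) @ z)
            if (corr >= threshold).any() and threshold < 1.0:
                continue
            if threshold == 1.0 and np.any(corr > 1.0 - 1e-12):
                continue  # exact duplicates only
        kept.append(j)
        Z_cols.append(z)
    return geno.subset_markers(kept)


def assign_clusters(scores: np.ndarray, q: int, seed: int) -> GroupAssignment:
    """Cluster samples into ``q`` groups by k-means on PC scores.

    Deterministic for a fixed seed (multiple k-means restarts with a fixed
    random state).  Groups are relabeled so group 1 is the largest, ties broken
    by the lowest original k-means label.  Degenerate inputs (e.g. identical
    points) resolve deterministically through the seeded k-means itself.
    """
    scores = np.asarray(scores, dtype=np.float64)
    if scores.ndim == 1:
        scores = scores[:, None]
    n = scores.shape[0]
    if q < 2:
        raise ValueError("q must be >= 2")
    if q > n:
        raise ValueError(f"cannot form q={q} groups from n={n} samples")
    km = KMeans(n_clusters=q, n_init=10, random_state=seed)
    raw = km.fit_predict(scores)
    sizes = np.bincount(raw, minlength=q)
    # sort by (size desc, original label asc)
    order = sorted(range(q), key=lambda lab: (-sizes[lab], lab))
    relabel = {old: new + 1 for new, old in enumerate(order)}
    labels = np.array([relabel[r] for r in raw], dtype=np.int64)
    return GroupAssignment(labels=labels, q=q)
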