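"""Core in-memory containers shared across the package.

Genotypes are allele dosages (0/1/2, or 0/1 for inbred lines) held as a plain
``numpy`` matrix with sample and marker identifiers; group membership is a
vector of integer labels in ``{1..q}``.  Phenotypes carry their group label so
group-specific likelihood terms can be evaluated without re-joining tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GenotypeMatrix",
    "GRM",
    "GroupAssignment",
    "GroupedPhenotypes",
]


def _check_unique(ids, what: str) -> None:
    seen = set()
    for x in ids:
        if x in seen:
            raise ValueError(f"duplicate {what} identifier: {x!r}")
        seen.add(x)


@dataclass
class GenotypeMatrix:
    """n x p allele-dosage matrix with sample and marker identifiers.

    Parameters
    ----------
    samples
        Ordered sample identifiers (length n, unique).
    markers
        Ordered marker identifiers (length p, unique).
    dosages
        ``(n, p)`` float matrix of allele counts, or standardized values when
        ``standardized`` is true.
    standardized
        Whether columns have been centered to zero mean and scaled to unit
        sample variance (n-1 divisor) across the whole sample.
    """

    samples: list
    markers: list
    dosages: np.ndarray
    standardized: bool = False

    def __post_init__(self) -> None:
        self.samples = list(self.samples)
        self.markers = list(self.markers)
        self.dosages = np.asarray(self.dosages, dtype=np.float64)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D matrix")
        if self.dosages.shape != (len(self.samples), len(self.markers)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.samples)} samples x {len(self.markers)} markers"
            )
        _check_unique(self.samples, "sample")
        _check_unique(self.markers, "marker")

    @property
    def n(self) -> int:
        return len(self.samples)

    @property
    def p(self) -> int:
        return len(self.markers)

    def subset_markers(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            samples=self.samples,
            markers=[self.markers[i] for i in index],
            dosages=self.dosages[:, index],
            standardized=self.standardized,
        )

    def reorder_samples(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            samples=[self.samples[i] for i in index],
            markers=self.markers,
            dosages=self.dosages[index, :],
            standardized=self.standardized,
        )


@dataclass
class GRM:
    """Genomic relationship matrix ``G = W W' / p`` from standardized genotypes.

    Symmetric positive semi-definite by construction; ``eigenvalues`` is filled
    lazily by :func:`wgreg.preprocess.pca_decompose`.
    """

    matrix: np.ndarray
    samples: list = field(default_factory=list)
    eigenvalues: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != self.matrix.shape[1]:
            raise ValueError("GRM must be a square matrix")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-10):
            raise ValueError("GRM must be symmetric within 1e-10")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


@dataclass
class GroupAssignment:
    """Per-sample cluster label among ``q`` groups (labels in ``{1..q}``)."""

    labels: np.ndarray
    q: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.labels.ndim != 1:
            raise ValueError("labels must be a 1-D vector")
        if self.q < 1:
            raise ValueError("q must be >= 1")
        if self.labels.min(initial=1) < 1 or self.labels.max(initial=1) > self.q:
            raise ValueError(f"labels must lie in 1..{self.q}")
        if len(np.unique(self.labels)) != self.q:
            raise ValueError("every group must receive at least one sample")

    @property
    def n(self) -> int:
        return self.labels.shape[0]

    @property
    def sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.q + 1)[1:]


@dataclass
class GroupedPhenotypes:
    """Trait values paired with a group label per sample.

    ``values[i]`` is the phenotype of sample ``i`` whose group is
    ``group[i] in {1..q}``.  Missing values never enter the likelihood: they
    must be dropped before construction.
    """

    values: np.ndarray
    group: np.ndarray
    q: int
    samples: list | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.group = np.asarray(self.group, dtype=np.int64)
        if self.values.shape != self.group.shape:
            raise ValueError("values and group must align")
        if np.isnan(self.values).any():
            raise ValueError("missing trait values must be dropped first")
        if self.group.min(initial=1) < 1 or self.group.max(initial=1) > self.q:
            raise ValueError(f"group labels must lie in 1..{self.q}")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def n_k(self) -> np.ndarray:
        return np.bincount(self.group, minlength=self.q + 1)[1:]

    def group_values(self, k: int) -> np.ndarray:
        return self.values[self.group == k]
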