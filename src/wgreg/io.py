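"""Delimited-text readers/writers and the run manifest.

File conventions (all plain tab-separated text, gzip allowed by extension):

* genotypes — first column sample id, header row of marker ids, numeric
  dosages;
* phenotypes — first column sample id, one column per trait, optional
  ``group`` column;
* labels — two columns ``sample``, ``group``;
* posterior/decomposition outputs — tidy tables as produced by the
  corresponding ``to_frame`` methods.

Every pipeline run emits a :class:`RunManifest` recording input paths with
content hashes, the resolved model configuration, the seed and the package
version, so outputs can be traced back to their exact inputs.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .datatypes import GenotypeMatrix, GroupAssignment, GroupedPhenotypes

__all__ = [
    "read_genotypes",
    "write_genotypes",
    "read_phenotypes",
    "write_phenotypes",
    "read_labels",
    "write_labels",
    "RunManifest",
    "file_sha256",
]

logger = logging.getLogger(__name__)


def read_genotypes(path, impute: bool = False, sep: str = "\t") -> GenotypeMatrix:
    """Read a sample-by-marker dosage matrix from delimited text.

    Missing cells are an error unless ``impute`` is set, in which case they
    are replaced by the marker mean (count logged).
    """
    opener = _maybe_gz(path) if str(path).endswith(".gz") else open(path)
    with opener as fh:
        header = fh.readline().rstrip("\n").split(sep)
    markers = header[1:]
    dup = _first_duplicate(markers)
    if dup is not None:
        raise ValueError(f"duplicate marker id {dup!r} in {path}")
    df = pd.read_csv(path, sep=sep, index_col=0)
    dup = _first_duplicate(df.index)
    if dup is not None:
        raise ValueError(f"duplicate sample id {dup!r} in {path}")
    try:
        dosages = df.to_numpy(dtype=np.float64)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric dosage in {path}: {exc}") from exc
    n_missing = int(np.isnan(dosages).sum())
    if n_missing:
        if not impute:
            raise ValueError(
                f"{n_missing} missing dosage(s) in {path}; re-read with "
                "impute=True for marker-mean imputation"
            )
        col_mean = np.nanmean(dosages, axis=0)
        idx = np.nonzero(np.isnan(dosages))
        dosages[idx] = col_mean[idx[1]]
        logger.warning("imputed %d missing dosage(s) with marker means", n_missing)
    return GenotypeMatrix(
        samples=[str(s) for s in df.index],
        markers=[str(m) for m in markers],
        dosages=dosages,
    )


def _maybe_gz(path):
    import gzip

    return gzip.open(path, "rt")


def _first_duplicate(ids):
    seen = set()
    for x in ids:
        if x in seen:
            return x
        seen.add(x)
    return None


def write_genotypes(geno: GenotypeMatrix, path, sep: str = "\t") -> None:
    df = pd.DataFrame(geno.dosages, index=geno.samples, columns=geno.markers)
    df.index.name = "sample"
    df.to_csv(path, sep=sep)


def write_phenotypes(
    samples, values: np.ndarray, path, trait: str = "trait", group=None, sep: str = "\t"
) -> None:
    df = pd.DataFrame({"sample": samples, trait: values})
    if group is not None:
        df["group"] = np.asarray(group)
    df.to_csv(path, sep=sep, index=False)


def read_phenotypes(
    path,
    trait: str,
    geno: GenotypeMatrix,
    groups: GroupAssignment | None = None,
    sep: str = "\t",
) -> GroupedPhenotypes:
    """Read one trait, aligned to the genotype sample order.

    Group labels come from a ``group`` column if present, else from
    ``groups``.  Samples missing the trait are dropped with a logged count;
    the result carries only samples present in both tables.
    """
    df = pd.read_csv(path, sep=sep)
    sample_col = df.columns[0]
    if trait not in df.columns:
        avail = [c for c in df.columns if c not in (sample_col, "group")]
        raise ValueError(f"trait {trait!r} not found; available traits: {avail}")
    df = df.set_index(sample_col)
    df.index = df.index.astype(str)
    geno_order = [s for s in geno.samples if s in df.index]
    if not geno_order:
        raise ValueError("no overlap between phenotype and genotype sample ids")
    df = df.loc[geno_order]
    missing = df[trait].isna()
    if missing.any():
        logger.warning("dropping %d sample(s) with missing %r", int(missing.sum()), trait)
        df = df[~missing]
    values = df[trait].to_numpy(dtype=np.float64)
    if "group" in df.columns:
        labels = df["group"].to_numpy(dtype=np.int64)
    elif groups is not None:
        pos = {s: i for i, s in enumerate(geno.samples)}
        labels = groups.labels[[pos[s] for s in df.index]]
    else:
        labels = np.ones(len(df), dtype=np.int64)
    q = int(labels.max())
    return GroupedPhenotypes(
        values=values, group=labels, q=q, samples=list(df.index)
    )


def write_labels(samples, groups: GroupAssignment, path, sep: str = "\t") -> None:
    pd.DataFrame({"sample": samples, "group": groups.labels}).to_csv(
        path, sep=sep, index=False
    )


def read_labels(path, geno: GenotypeMatrix | None = None, sep: str = "\t") -> GroupAssignment:
    df = pd.read_csv(path, sep=sep)
    df = df.set_index(df.columns[0])
    df.index = df.index.astype(str)
    if geno is not None:
        missing = [s for s in geno.samples if s not in df.index]
        if missing:
            raise ValueError(f"labels file lacks {len(missing)} sample(s), e.g. {missing[0]!r}")
        df = df.loc[geno.samples]
    labels = df.iloc[:, 0].to_numpy(dtype=np.int64)
    return GroupAssignment(labels=labels, q=int(labels.max()))


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Provenance record written next to every run's outputs."""

    inputs: dict = field(default_factory=dict)    # path -> sha256
    outputs: list = field(default_factory=list)
    seed: int | None = None
    config: dict | None = None
    version: str = ""

    def add_input(self, path) -> None:
        self.inputs[str(path)] = file_sha256(path)

    def write(self, path) -> None:
        from . import __version__

        self.version = self.version or __version__
        with open(path, "w") as fh:
            yaml.safe_dump(
                {
                    "inputs": self.inputs,
                    "outputs": [str(o) for o in self.outputs],
                    "seed": self.seed,
                    "config": self.config,
                    "version": self.version,
                },
                fh,
                sort_keys=False,
            )

    @classmethod
    def read(cls, path) -> "RunManifest":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls(
            inputs=d.get("inputs", {}),
            outputs=d.get("outputs", []),
            seed=d.get("seed"),
            config=d.get("config"),
            version=d.get("version", ""),
        )

    def verify_inputs(self) -> bool:
        """Recompute input hashes; True iff all match."""
        return all(file_sha256(p) == h for p, h in self.inputs.items())
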