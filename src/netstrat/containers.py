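"""Core data containers shared across the pipeline stages.

Expression data travel as genes x samples matrices on either a TPM or a
log2 scale; every correlation-based stage requires log2.  Networks are
symmetric weighted adjacencies over a module's genes with entries in
[0, 1] and a structurally zero diagonal.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd


class ConfigurationError(ValueError):
    """Raised when stage parameters are structurally invalid."""


class DataError(ValueError):
    """Raised when input data violate a stage precondition."""


@dataclass
class ExpressionMatrix:
    """Genes x samples abundance matrix with an explicit scale flag.

    Parameters
    ----------
    values : DataFrame
        Rows are genes, columns are samples. Must be free of missing
        values; gene and sample identifiers must be unique.
    scale : {"tpm", "log2"}
        Correlation-based operations require ``"log2"``.
    """

    values: pd.DataFrame
    scale: str = "log2"

    def __post_init__(self) -> None:
        if self.scale not in ("tpm", "log2"):
            raise ConfigurationError(f"unknown scale {self.scale!r}")
        if self.values.isna().any().any():
            raise DataError("expression matrix contains missing values")
        if self.values.index.has_duplicates:
            raise DataError("duplicate gene ids")
        if self.values.columns.has_duplicates:
            raise DataError("duplicate sample ids")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        missing = [g for g in genes if g not in self.values.index]
        if missing:
            raise DataError(f"genes absent from matrix: {missing[:10]}")
        return ExpressionMatrix(self.values.loc[list(genes)], scale=self.scale)

    def require_log2(self) -> None:
        if self.scale != "log2":
            raise DataError("operation requires log2-scale expression")


@dataclass
class WeightedNetwork:
    """Symmetric weighted adjacency in [0, 1] with zero diagonal."""

    adjacency: np.ndarray
    gene_ids: pd.Index
    power: float = 1.0
    flavor: str = "signed_hybrid"

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency, dtype=float)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise DataError("adjacency must be square")
        if a.shape[0] != len(self.gene_ids):
            raise DataError("gene ids do not match adjacency shape")
        if not np.allclose(a, a.T, atol=1e-10, equal_nan=True):
            raise DataError("adjacency must be symmetric")
        with np.errstate(invalid="ignore"):
            finite = a[np.isfinite(a)]
            if finite.size and (finite.min() < -1e-12 or finite.max() > 1 + 1e-12):
                raise DataError("adjacency entries must lie in [0, 1]")
        np.fill_diagonal(a, 0.0)
        self.adjacency = a

    @property
    def n_genes(self) -> int:
        return self.adjacency.shape[0]


@dataclass
class ModuleAssignment:
    """Gene -> module labels; 0 means unassigned (grey) genes.

    Module ids are contiguous positive integers ordered by decreasing
    module size.
    """

    labels: pd.Series  # gene id -> int
    dendrogram_order: np.ndarray | None = None

    @property
    def module_ids(self) -> list[int]:
        ids = sorted(int(m) for m in self.labels.unique() if m > 0)
        return ids

    @property
    def module_sizes(self) -> dict[int, int]:
        counts = self.labels[self.labels > 0].value_counts()
        return {int(m): int(counts[m]) for m in self.module_ids}

    def genes_of(self, module_id: int) -> list[str]:
        return list(self.labels.index[self.labels == module_id])


@dataclass
class EigengeneModel:
    """Reference statistics that make module PC scores portable.

    Stores, per module, the gene means / standard deviations used for
    standardization and the first two principal axes of the
    standardized reference submatrix.  PC1 is oriented so that it
    correlates non-negatively with the module's mean standardized
    expression, which removes the sign ambiguity of the decomposition.
    """

    module_id: int
    gene_ids: list[str]
    means: np.ndarray
    sds: np.ndarray
    eigenvectors: np.ndarray  # shape (2, n_genes), rows unit norm
    explained_variance: np.ndarray  # fractions for PC1, PC2
    orientation_sign: int = 1

    def to_dict(self) -> dict:
        return {
            "module_id": int(self.module_id),
            "gene_ids": list(self.gene_ids),
            "means": self.means.tolist(),
            "sds": self.sds.tolist(),
            "eigenvectors": self.eigenvectors.tolist(),
            "explained_variance": self.explained_variance.tolist(),
            "orientation_sign": int(self.orientation_sign),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "EigengeneModel":
        return cls(
            module_id=int(d["module_id"]),
            gene_ids=list(d["gene_ids"]),
            means=np.asarray(d["means"], dtype=float),
            sds=np.asarray(d["sds"], dtype=float),
            eigenvectors=np.asarray(d["eigenvectors"], dtype=float),
            explained_variance=np.asarray(d["explained_variance"], dtype=float),
            orientation_sign=int(d.get("orientation_sign", 1)),
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "EigengeneModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class GeneSet:
    """Named gene set with provenance sufficient to regenerate it."""

    name: str
    genes: list[str]
    provenance: str = "external"  # kme_threshold | kme_top_n | external
    parameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.genes:
            raise DataError(f"gene set {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise DataError(f"gene set {self.name!r} has duplicate genes")


@dataclass
class ClinicalTable:
    """Paired-biopsy clinical metadata.

    One row per sample; each patient contributes at most one Bx1
    (pre-treatment) and one Bx2 (on-treatment) biopsy.  ``responder``
    is True for best response SD or PR and False for PD.
    """

    table: pd.DataFrame

    REQUIRED = ("sample_id", "patient_id", "biopsy", "tissue", "best_response", "responder")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise DataError(f"clinical table missing columns: {missing}")
        if self.table.duplicated(["patient_id", "biopsy"]).any():
            raise DataError("duplicate (patient, biopsy) rows")
        bad = ~self.table["biopsy"].isin(["Bx1", "Bx2"])
        if bad.any():
            raise DataError("biopsy must be Bx1 or Bx2")
        expect = self.table["best_response"] != "PD"
        if not (self.table["responder"] == expect).all():
            raise DataError("responder flag inconsistent with best_response")

    def samples(self, biopsy: str | None = None) -> pd.DataFrame:
        t = self.table
        if biopsy is not None:
            t = t[t["biopsy"] == biopsy]
        return t.reset_index(drop=True)

    def responder_map(self) -> pd.Series:
        return self.table.set_index("sample_id")["responder"]


@dataclass
class CentroidModel:
    """Reference centroid profiles for nearest-centroid subtype calling."""

    profiles: pd.DataFrame  # genes x subtypes
    good_prognosis: str = "BLIA"
    poor_prognosis: str = "BLIS"

    def __post_init__(self) -> None:
        if self.profiles.shape[1] < 2:
            raise ConfigurationError("at least 2 centroids are required")

    @property
    def gene_ids(self) -> pd.Index:
        return self.profiles.index

    @property
    def subtypes(self) -> list[str]:
        return list(self.profiles.columns)


def as_expression(values: pd.DataFrame, scale: str = "log2") -> ExpressionMatrix:
    """Convenience wrapper validating a DataFrame into an ExpressionMatrix."""
    return ExpressionMatrix(values=values, scale=scale)
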