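"""Patient-specific network decomposition and wiring statistics.

Each co-expression module is decomposed into per-sample weighted
subnetworks by linear interpolation against the reference cohort
(LIONESS-style): with e(S) an edge function over sample set S and N
the reference size, a query sample q gets edge weights

    w(q) = (N + 1) * e(reference + q) - N * e(reference).

The signed weights are converted to a standard adjacency by zeroing
negative edges and scaling the remainder into [0, 1], after which
fundamental weighted-network concepts are computed: per-gene
connectivity, maximum adjacency ratio (MAR) and clustering
coefficient, and whole-network density, centralization and
heterogeneity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import DataError, ExpressionMatrix, WeightedNetwork
from .coexpression import bicor_matrix

__all__ = [
    "lioness_edge_weights",
    "to_adjacency",
    "gene_features",
    "whole_network_features",
    "PatientNetwork",
    "patient_networks_for_cohort",
]


def _pearson_matrix(values: np.ndarray) -> np.ndarray:
    x = values - values.mean(axis=1, keepdims=True)
    norm = np.sqrt((x**2).sum(axis=1, keepdims=True))
    with np.errstate(divide="ignore", invalid="ignore"):
        xn = x / norm
    xn[norm.ravel() == 0] = np.nan
    r = xn @ xn.T
    return np.clip(r, -1.0, 1.0, out=r)


_EDGE_FUNCTIONS = {"bicor": bicor_matrix, "pearson": _pearson_matrix}


def lioness_edge_weights(
    sample: pd.Series,
    reference: ExpressionMatrix,
    edge_function="bicor",
) -> pd.DataFrame:
    """Single-sample signed edge weights by linear interpolation.

    ``edge_function`` is "bicor" (default, consistent with the
    reference network), "pearson", or any callable mapping a genes x
    samples array to a symmetric edge matrix.  Edges touching a gene
    that is constant in the pooled sample set are undefined (NaN).
    """
    if callable(edge_function):
        f = edge_function
    else:
        try:
            f = _EDGE_FUNCTIONS[edge_function]
        except KeyError:
            raise DataError(f"unknown edge function {edge_function!r}") from None
    x = sample.reindex(reference.gene_ids)
    if x.isna().any():
        raise DataError("sample does not cover the reference gene order")
    ref = reference.values.to_numpy()
    n = ref.shape[1]
    if n < 3:
        raise DataError("reference must hold at least 3 samples")
    pooled = np.column_stack([ref, x.to_numpy(dtype=float)])
    e_all = np.asarray(f(pooled), dtype=float)
    e_ref = np.asarray(f(ref), dtype=float)
    w = (n + 1) * e_all - n * e_ref
    w = (w + w.T) / 2.0
    np.fill_diagonal(w, 0.0)
    return pd.DataFrame(w, index=reference.gene_ids, columns=reference.gene_ids)


def to_adjacency(
    signed: pd.DataFrame, scaling: str = "max_positive"
) -> WeightedNetwork:
    """Convert signed edge weights to a [0, 1] adjacency.

    Negative edges are removed (set to 0); the remaining positive
    weights are divided by the maximum positive weight
    (``scaling="max_positive"``, the default) or clipped at 1
    (``scaling="clip"``).  An all-nonpositive input yields the zero
    network with a warning.
    """
    w = signed.to_numpy(dtype=float).copy()
    if not np.allclose(w, w.T, atol=1e-9, equal_nan=True):
        raise DataError("signed edge matrix must be symmetric")
    np.fill_diagonal(w, 0.0)
    w = np.where(np.isnan(w), np.nan, np.maximum(w, 0.0))
    finite_max = np.nanmax(w) if np.isfinite(w).any() else 0.0
    if finite_max <= 0:
        warnings.warn("no positive edges; returning the zero network")
        a = np.zeros_like(w)
    elif scaling == "max_positive":
        a = w / finite_max
    elif scaling == "clip":
        a = np.minimum(w, 1.0)
    else:
        raise DataError(f"unknown scaling {scaling!r}")
    a = np.where(np.isnan(a), 0.0, a)
    return WeightedNetwork(adjacency=a, gene_ids=signed.index)


def gene_features(net: WeightedNetwork) -> pd.DataFrame:
    """Per-gene connectivity, MAR and clustering coefficient.

    k_i = sum_j a_ij; MAR_i = sum_j a_ij^2 / sum_j a_ij (NaN for an
    isolated gene); C_i = sum_{j != l} a_ij a_jl a_li / (k_i^2 -
    sum_j a_ij^2) (NaN when the denominator vanishes).  Undefined
    values propagate as NaN flags, never as zeros.
    """
    a = net.adjacency
    if a.shape[0] < 3:
        raise DataError("gene features need at least 3 genes")
    k = a.sum(axis=1)
    sq = (a**2).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        mar = np.where(k > 0, sq / k, np.nan)
        triangles = np.einsum("ij,jl,li->i", a, a, a)
        denom = k**2 - sq
        clustering = np.where(denom > 0, triangles / denom, np.nan)
    return pd.DataFrame(
        {"connectivity": k, "mar": mar, "clustering": clustering}, index=net.gene_ids
    )


def whole_network_features(net: WeightedNetwork) -> dict:
    """Density, centralization and heterogeneity of a weighted network.

    density = sum_i k_i / (n (n-1)); centralization = n/(n-2) *
    (max_i k_i/(n-1) - density); heterogeneity = population SD of k
    over its mean (NaN for an empty network).
    """
    a = net.adjacency
    n = a.shape[0]
    if n < 3:
        raise DataError("whole-network features need at least 3 genes")
    k = a.sum(axis=1)
    density = k.sum() / (n * (n - 1))
    centralization = n / (n - 2) * (k.max() / (n - 1) - density)
    mean_k = k.mean()
    heterogeneity = float(np.std(k) / mean_k) if mean_k > 0 else float("nan")
    return {
        "density": float(density),
        "centralization": float(centralization),
        "heterogeneity": heterogeneity,
    }


@dataclass
class PatientNetwork:
    """One sample's module subnetwork with conversion provenance."""

    sample_id: str
    module_id: int
    signed_weights: pd.DataFrame
    adjacency: WeightedNetwork
    reference_size: int
    scaling: str = "max_positive"


def patient_networks_for_cohort(
    cohort: ExpressionMatrix,
    reference: ExpressionMatrix,
    module_genes: dict[int, list[str]],
    edge_function="bicor",
    scaling: str = "max_positive",
) -> list[PatientNetwork]:
    """Decompose every cohort sample into per-module patient networks.

    Produces len(samples) x len(modules) networks (e.g. 26 samples x 3
    modules = 78 subnetworks for a paired 13-patient cohort).
    """
    nets = []
    for module_id, genes in module_genes.items():
        ref_sub = reference.subset_genes(genes)
        for sample_id in cohort.sample_ids:
            sample = cohort.values.loc[genes, sample_id]
            sample.name = sample_id
            signed = lioness_edge_weights(sample, ref_sub, edge_function=edge_function)
            adj = to_adjacency(signed, scaling=scaling)
            nets.append(
                PatientNetwork(
                    sample_id=str(sample_id),
                    module_id=module_id,
                    signed_weights=signed,
                    adjacency=adj,
                    reference_size=ref_sub.n_samples,
                    scaling=scaling,
                )
            )
    return nets


def feature_tables(networks: list[PatientNetwork]) -> dict[int, dict[str, pd.DataFrame]]:
    """Per-module tables of gene-level and whole-network features.

    Returns {module_id: {"connectivity"|"mar"|"clustering": samples x
    genes DataFrame, "whole": samples x 3 DataFrame}}.
    """
    out: dict[int, dict[str, pd.DataFrame]] = {}
    by_module: dict[int, list[PatientNetwork]] = {}
    for net in networks:
        by_module.setdefault(net.module_id, []).append(net)
    for module_id, nets in by_module.items():
        gene_rows = {f: [] for f in ("connectivity", "mar", "clustering")}
        whole_rows = []
        index = []
        for net in nets:
            gf = gene_features(net.adjacency)
            for f in gene_rows:
                gene_rows[f].append(gf[f])
            whole_rows.append(whole_network_features(net.adjacency))
            index.append(net.sample_id)
        out[module_id] = {
            f: pd.DataFrame(rows, index=index) for f, rows in gene_rows.items()
        }
        out[module_id]["whole"] = pd.DataFrame(whole_rows, index=index)
    return out
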