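"""Immune-repertoire clonotype diversity metrics.

Per (sample, chain/isotype class) the pipeline computes Shannon
entropy (nats), Evenness (entropy normalized by the log of the
clonotype count), D50 (minimal number of top clonotypes covering half
the reads, plus its fraction of the clonotype count), the Gini
coefficient of the clone-size distribution and the Gini–Simpson index
1 - sum(p^2).  Because diversity is confounded by sequencing depth,
metrics can be recomputed on reads downsampled without replacement to
a fixed depth (median over repeats), with per-biopsy default depths of
8500 (Bx1) and 400 (Bx2); samples below the depth are excluded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import ConfigurationError, DataError

__all__ = [
    "diversity_metrics",
    "downsampled_metrics",
    "class_abundance",
    "cohort_diversity",
    "DEFAULT_DEPTHS",
]

DEFAULT_DEPTHS = {"Bx1": 8500, "Bx2": 400}

CLONOTYPE_COLUMNS = ("sample_id", "clonotype_id", "chain", "isotype", "reads")


def _validate(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in CLONOTYPE_COLUMNS if c not in table.columns]
    if missing:
        raise DataError(f"clonotype table missing columns: {missing}")
    if (table["reads"] < 1).any():
        raise DataError("read counts must be >= 1")
    return table


def _filter_class(table: pd.DataFrame, chain=None, isotype=None) -> pd.DataFrame:
    t = table
    if chain is not None:
        t = t[t["chain"] == chain]
    if isotype is not None:
        t = t[t["isotype"] == isotype]
    return t


def _metrics_from_counts(counts: np.ndarray) -> dict:
    counts = np.asarray(counts, dtype=float)
    counts = counts[counts > 0]
    n = len(counts)
    total = counts.sum()
    p = counts / total
    entropy = float(-(p * np.log(p)).sum())
    evenness = float(entropy / np.log(n)) if n > 1 else float("nan")
    order = np.sort(counts)[::-1]
    cum = np.cumsum(order) / total
    d50 = int(np.searchsorted(cum, 0.5 - 1e-12) + 1)
    gini_simpson = float(1.0 - (p**2).sum())
    asc = np.sort(counts)
    i = np.arange(1, n + 1)
    gini = float(((2 * i - n - 1) * asc).sum() / (n * total)) if n > 0 else float("nan")
    return {
        "shannon_entropy": entropy,
        "evenness": evenness,
        "d50_count": d50,
        "d50_fraction": d50 / n,
        "gini": gini,
        "gini_simpson": gini_simpson,
        "n_clonotypes": n,
        "total_reads": int(total),
    }


def diversity_metrics(
    table: pd.DataFrame, chain: str | None = None, isotype: str | None = None
) -> dict:
    """Diversity panel of one sample's clonotype table (optionally filtered).

    Raises :class:`DataError` when the class filter leaves no
    clonotypes — callers running group tests should exclude such
    samples rather than imputing zeros.
    """
    t = _filter_class(_validate(table), chain, isotype)
    if t.empty:
        raise DataError("no clonotypes after class filtering")
    out = _metrics_from_counts(t["reads"].to_numpy())
    out["downsampled"] = False
    out["depth"] = None
    return out


def downsampled_metrics(
    table: pd.DataFrame,
    depth: int,
    n_reps: int = 5,
    seed: int = 0,
    chain: str | None = None,
    isotype: str | None = None,
) -> dict:
    """Median diversity metrics over reads downsampled to ``depth``.

    Each repeat draws ``depth`` reads without replacement from the
    read multiset (multivariate hypergeometric); the per-metric median
    across repeats is reported with the downsampling provenance.
    Samples whose total reads fall below the depth are refused.
    """
    if depth <= 0:
        raise ConfigurationError("depth must be positive")
    t = _filter_class(_validate(table), chain, isotype)
    if t.empty:
        raise DataError("no clonotypes after class filtering")
    counts = t["reads"].to_numpy(dtype=np.int64)
    total = int(counts.sum())
    if total < depth:
        raise DataError(f"total reads {total} below downsampling depth {depth}")
    rng = np.random.default_rng(seed)
    reps = []
    for _ in range(n_reps):
        drawn = rng.multivariate_hypergeometric(counts, depth)
        reps.append(_metrics_from_counts(drawn))
    keys = ("shannon_entropy", "evenness", "d50_count", "d50_fraction", "gini", "gini_simpson", "n_clonotypes")
    out = {k: float(np.median([r[k] for r in reps])) for k in keys}
    out["d50_count"] = out["d50_count"]
    out["n_clonotypes"] = out["n_clonotypes"]
    out["total_reads"] = depth
    out["downsampled"] = True
    out["depth"] = depth
    return out


def class_abundance(table: pd.DataFrame, by: str = "chain") -> pd.DataFrame:
    """Total reads per (sample, chain or isotype class).

    Classes absent from a sample are simply absent from the output
    (not zero-filled); an empty table yields an empty result.
    """
    if table.empty:
        return pd.DataFrame(columns=["sample_id", by, "reads"])
    t = _validate(table)
    out = t.groupby(["sample_id", by], as_index=False)["reads"].sum()
    return out


def cohort_diversity(
    tables: pd.DataFrame,
    clinical=None,
    depths: dict[str, int] | None = None,
    n_reps: int = 5,
    seed: int = 0,
    chain: str | None = "IGH",
    isotype: str | None = None,
) -> pd.DataFrame:
    """Per-sample diversity panel for a cohort, optionally downsampled.

    ``tables`` is a long-format clonotype table over many samples.
    With ``depths`` (biopsy -> depth; defaults per the shipped Bx1/Bx2
    configuration when ``clinical`` is given) metrics are downsampling
    medians; samples whose class total falls below the depth are
    excluded with a warning, mirroring the abundance-threshold rule.
    """
    rows = []
    excluded = 0
    biopsy_of = {}
    if clinical is not None:
        biopsy_of = clinical.table.set_index("sample_id")["biopsy"].to_dict()
        if depths is None:
            depths = dict(DEFAULT_DEPTHS)
    for sid, t in tables.groupby("sample_id"):
        try:
            if depths is not None:
                depth = depths.get(biopsy_of.get(sid, "Bx1"))
                rec = downsampled_metrics(
                    t, depth=depth, n_reps=n_reps, seed=seed, chain=chain, isotype=isotype
                )
            else:
                rec = diversity_metrics(t, chain=chain, isotype=isotype)
        except DataError:
            excluded += 1
            continue
        rec["sample_id"] = sid
        rows.append(rec)
    if excluded:
        warnings.warn(f"excluded {excluded} sample(s) below depth or without clonotypes")
    return pd.DataFrame(rows).set_index("sample_id") if rows else pd.DataFrame()
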