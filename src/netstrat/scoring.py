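"""Gene-set derivation and single-sample signature scoring.

Modules are distilled into portable gene sets by kME (module
membership) — either all genes above a kME threshold or the top-n by
kME — and samples are scored by rank-based single-sample enrichment
(ssGSEA-style cumulative walks, or GSVA with a Gaussian kernel CDF),
by plain mean score with a median split, or assessed by hypergeometric
over-representation against a gene-set collection.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import hypergeom, norm, rankdata
from statsmodels.stats.multitest import multipletests

from .containers import DataError, ExpressionMatrix, GeneSet

__all__ = [
    "derive_geneset_by_kme",
    "ssgsea_score",
    "gsva_score",
    "mean_z_score",
    "overrepresentation_test",
]


def derive_geneset_by_kme(
    kme_table: pd.Series,
    module_genes,
    name: str,
    threshold: float | None = None,
    top_n: int | None = None,
) -> GeneSet:
    """Distill a module into a gene set by kME.

    Exactly one of ``threshold`` (keep genes with kME > threshold) or
    ``top_n`` (keep the n highest-kME genes) must be given.  Output
    order is by descending kME then gene id; genes with undefined
    (NaN) kME are excluded.
    """
    if (threshold is None) == (top_n is None):
        raise DataError("specify exactly one of threshold or top_n")
    k = kme_table.reindex(list(module_genes))
    if k.isna().all():
        raise DataError("kME undefined for all module genes")
    k = k.dropna()
    order = sorted(k.index, key=lambda g: (-k[g], g))
    if threshold is not None:
        genes = [g for g in order if k[g] > threshold]
        if not genes:
            raise DataError(
                f"no genes with kME > {threshold}; observed maximum {k.max():.4f}"
            )
        prov = "kme_threshold"
        params = {"threshold": threshold}
    else:
        if top_n < 1:
            raise DataError("top_n must be >= 1")
        genes = order[: int(top_n)]
        prov = "kme_top_n"
        params = {"top_n": int(top_n)}
    return GeneSet(name=name, genes=genes, provenance=prov, parameters=params)


def _walk_scores(
    ranks: np.ndarray, in_set: np.ndarray, exponent: float, mx_diff: bool
) -> float:
    """Weighted Kolmogorov–Smirnov-like random walk over one sample.

    ``ranks`` are the per-gene rank statistics (larger = more
    expressed), ``in_set`` the set-membership mask.  Genes are walked
    in decreasing rank order; the in-set cumulative mass is weighted by
    rank**exponent, the out-of-set mass is uniform.  Returns the sum of
    the walk differences when ``mx_diff`` is False (ssGSEA-style
    integrated statistic) or max deviation + min deviation when True
    (GSVA-style signed difference).
    """
    order = np.argsort(-ranks, kind="stable")
    r = ranks[order]
    s = in_set[order]
    w = np.abs(r) ** exponent
    w_in = np.where(s, w, 0.0)
    denom_in = w_in.sum()
    if denom_in == 0:
        raise DataError("gene set has zero total rank weight")
    n_out = (~s).sum()
    if n_out == 0:
        raise DataError("gene set equals the whole universe; walk undefined")
    p_in = np.cumsum(w_in) / denom_in
    p_out = np.cumsum(np.where(s, 0.0, 1.0)) / n_out
    diff = p_in - p_out
    if mx_diff:
        return float(diff.max() + diff.min())
    return float(diff.sum())


def ssgsea_score(
    expr: ExpressionMatrix,
    gene_set: GeneSet,
    universe=None,
    exponent: float = 0.25,
) -> pd.Series:
    """Single-sample enrichment score of one gene set per sample.

    Per sample, genes in the universe are ranked by expression
    (average ranks for ties; the most expressed gene gets the largest
    rank) and the score is the integrated difference between the
    weighted in-set cumulative rank mass (weights rank**exponent) and
    the uniform out-of-set cumulative mass.  No cross-sample
    renormalization is applied, so scores are comparable only within a
    fixed universe and exponent.
    """
    if universe is None:
        universe = list(expr.gene_ids)
    universe = list(universe)
    missing = [g for g in universe if g not in set(expr.gene_ids)]
    if missing:
        raise DataError(f"universe genes absent from expression: {missing[:10]}")
    offenders = [g for g in gene_set.genes if g not in set(universe)]
    if offenders:
        raise DataError(f"gene set members outside the universe: {offenders[:10]}")
    sub = expr.values.loc[universe]
    in_set = np.array([g in set(gene_set.genes) for g in universe])
    out = {}
    x = sub.to_numpy()
    for j, sample in enumerate(sub.columns):
        ranks = rankdata(x[:, j], method="average")
        out[sample] = _walk_scores(ranks, in_set, exponent, mx_diff=False)
    return pd.Series(out, name=gene_set.name)


def gsva_score(
    expr: ExpressionMatrix,
    gene_sets: list[GeneSet],
    kcdf: str = "gaussian",
    mx_diff: bool = True,
    tau: float = 1.0,
) -> pd.DataFrame:
    """GSVA-style enrichment of several gene sets across samples.

    Per gene, a Gaussian-kernel cumulative density is estimated across
    samples (bandwidth sd/4); the resulting gene-level statistics are
    converted per sample into symmetric rank statistics |rank - N/2|
    and a Kolmogorov–Smirnov-like random walk is run per set.  With
    ``mx_diff`` the score is the signed sum of the maximum and minimum
    walk deviations.  Requires at least 3 samples because the kernel
    CDF is estimated across samples.
    """
    if kcdf != "gaussian":
        raise DataError(f"unsupported kernel {kcdf!r}")
    if expr.n_samples < 3:
        raise DataError("GSVA requires at least 3 samples")
    x = expr.values.to_numpy()
    n_genes, n_samples = x.shape
    sd = x.std(axis=1, ddof=0)  # population SD: invariant under sample duplication
    bw = np.where(sd > 0, sd / 4.0, 1.0)
    # kernel CDF per gene: z_ij = mean_k Phi((x_ij - x_ik) / h_i)
    z = np.empty_like(x)
    for i in range(n_genes):
        z[i] = norm.cdf((x[i][:, None] - x[i][None, :]) / bw[i]).mean(axis=1)
    # per-sample symmetric rank statistic
    genes = list(expr.gene_ids)
    gene_pos = {g: i for i, g in enumerate(genes)}
    masks = []
    for gs in gene_sets:
        if len(gs.genes) < 2:
            warnings.warn(f"gene set {gs.name!r} has fewer than 2 genes")
        missing = [g for g in gs.genes if g not in gene_pos]
        if missing:
            raise DataError(f"set {gs.name!r} genes absent: {missing[:10]}")
        mask = np.zeros(n_genes, dtype=bool)
        mask[[gene_pos[g] for g in gs.genes]] = True
        masks.append(mask)
    out = np.empty((n_samples, len(gene_sets)))
    for j in range(n_samples):
        ranks = rankdata(z[:, j], method="average")
        sym = np.abs(ranks - n_genes / 2.0)
        order_stat = ranks  # decreasing z determines the walk order
        for si, mask in enumerate(masks):
            # walk in decreasing-z order, weighted by the symmetric statistic
            order = np.argsort(-order_stat, kind="stable")
            s = mask[order]
            w = sym[order] ** tau
            denom = w[s].sum()
            if denom == 0:
                out[j, si] = np.nan
                continue
            p_in = np.cumsum(np.where(s, w, 0.0)) / denom
            n_out = (~s).sum()
            p_out = np.cumsum(np.where(s, 0.0, 1.0)) / n_out
            diff = p_in - p_out
            out[j, si] = diff.max() + diff.min() if mx_diff else diff.sum()
    return pd.DataFrame(out, index=expr.sample_ids, columns=[g.name for g in gene_sets])


def mean_z_score(
    expr: ExpressionMatrix,
    gene_set: GeneSet,
    standardize: bool = False,
) -> tuple[pd.Series, pd.Series]:
    """Mean expression over a gene set plus median-split labels.

    With ``standardize`` each gene is centered and scaled across
    samples before averaging (use this for single-hub-gene scoring).
    The binary label is "high" for scores strictly above the cohort
    median; ties at the median go to "low".  A degenerate (constant)
    score vector yields all "low" with a warning.
    """
    missing = [g for g in gene_set.genes if g not in set(expr.gene_ids)]
    if missing:
        raise DataError(f"gene set members absent: {missing[:10]}")
    sub = expr.values.loc[gene_set.genes]
    if standardize:
        mean = sub.mean(axis=1)
        sd = sub.std(axis=1, ddof=1).replace(0, 1.0)
        sub = sub.sub(mean, axis=0).div(sd, axis=0)
    scores = sub.mean(axis=0)
    med = scores.median()
    if scores.nunique() == 1:
        warnings.warn("constant score vector; median split is degenerate (all low)")
    labels = pd.Series(np.where(scores > med, "high", "low"), index=scores.index)
    scores.name = gene_set.name
    labels.name = f"{gene_set.name}_label"
    return scores, labels


def overrepresentation_test(
    module_genes,
    collection: list[GeneSet],
    universe,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric over-representation of a module in each gene set.

    Upper-tail hypergeometric p per set, Benjamini–Yekutieli adjusted
    across the collection; ``significant`` flags FDR < threshold.
    """
    universe = set(universe)
    module = set(module_genes)
    if not module <= universe:
        raise DataError("module genes must be contained in the universe")
    n_univ = len(universe)
    n_mod = len(module)
    rows = []
    for gs in collection:
        genes = set(gs.genes) & universe
        overlap = len(module & genes)
        # P(X >= overlap), X ~ Hypergeom(N=n_univ, K=len(genes), n=n_mod)
        p = float(hypergeom.sf(overlap - 1, n_univ, len(genes), n_mod))
        rows.append(
            {"set": gs.name, "overlap": overlap, "k": n_mod, "K": len(genes), "p": p}
        )
    table = pd.DataFrame(rows)
    if len(table):
        table["fdr_by"] = multipletests(table["p"], method="fdr_by")[1]
        table["significant"] = table["fdr_by"] < fdr_threshold
    return table
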