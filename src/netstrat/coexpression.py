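"""Reference co-expression network construction and module discovery.

The reference network is a signed-hybrid weighted network: biweight
midcorrelations (bicor) between gene expression profiles are truncated
at zero and raised to a soft-threshold power (default 5).  Modules are
found by average-linkage hierarchical clustering of the topological
overlap dissimilarity followed by a simplified dynamic hybrid tree
cut: a static cut at ``cut_height``, recursive branch splitting driven
by merge-height gaps (aggressiveness set by ``deep_split``), dissolution
of clusters below the minimum size, and an optional PAM-like
reassignment of unlabeled genes to the nearest module by average
dissimilarity.

Two quality gates mirror standard practice: a topological-significance
gate comparing density-based statistics of each module against random
gene sets of the same size (median Z >= 2 to pass), and a stability
assessment repeating the full detection on subsampled cohorts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, leaves_list
from scipy.spatial.distance import squareform

from .containers import (
    ConfigurationError,
    DataError,
    EigengeneModel,
    ExpressionMatrix,
    ModuleAssignment,
    WeightedNetwork,
)

__all__ = [
    "select_variable_genes",
    "bicor",
    "bicor_matrix",
    "adjacency",
    "topological_overlap",
    "detect_modules",
    "module_eigengene",
    "kme",
    "topological_significance",
    "module_stability",
]


# ---------------------------------------------------------------------------
# variable-gene selection
# ---------------------------------------------------------------------------

def select_variable_genes(expr: ExpressionMatrix, n: int) -> ExpressionMatrix:
    """Keep the ``n`` genes with the highest per-gene variance.

    Ties at the cutoff are broken by higher mean, then lexicographic
    gene id, so the selection is deterministic.  Sample order is
    preserved.
    """
    expr.require_log2()
    if n > expr.n_genes:
        raise ConfigurationError("requested more genes than available")
    var = expr.values.var(axis=1, ddof=1)
    mean = expr.values.mean(axis=1)
    order = pd.DataFrame({"var": var, "mean": mean, "gene": expr.gene_ids})
    order = order.sort_values(
        ["var", "mean", "gene"], ascending=[False, False, True], kind="mergesort"
    )
    keep = order.index[:n]
    # keep original gene order? Ranked order is conventional for reporting,
    # but downstream identity checks are simplest in matrix order.
    keep = [g for g in expr.gene_ids if g in set(keep)]
    return ExpressionMatrix(expr.values.loc[keep], scale=expr.scale)


# ---------------------------------------------------------------------------
# biweight midcorrelation
# ---------------------------------------------------------------------------

def _bicor_transform(rows: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-row biweight transform; returns (weighted deviations, mad0 mask).

    Rows whose median absolute deviation is zero fall back to plain
    centering (Pearson) per the standard individual-fallback rule.
    """
    med = np.median(rows, axis=1, keepdims=True)
    dev = rows - med
    mad = np.median(np.abs(dev), axis=1, keepdims=True)
    mad0 = (mad == 0).ravel()
    with np.errstate(divide="ignore", invalid="ignore"):
        u = dev / (9.0 * mad)
    w = (1.0 - u**2) ** 2
    w[np.abs(u) >= 1] = 0.0
    x = dev * w
    if mad0.any():
        x[mad0] = rows[mad0] - rows[mad0].mean(axis=1, keepdims=True)
    return x, mad0


def _normalize_rows(x: np.ndarray) -> np.ndarray:
    norm = np.sqrt((x**2).sum(axis=1, keepdims=True))
    with np.errstate(divide="ignore", invalid="ignore"):
        out = x / norm
    out[norm.ravel() == 0] = np.nan  # constant rows: correlation undefined
    return out


def bicor_matrix(values: np.ndarray) -> np.ndarray:
    """Biweight midcorrelation between all row pairs of ``values``.

    Uses the standard 9-MAD outlier weighting.  Rows with zero MAD use
    Pearson centering; constant rows yield NaN (undefined correlation,
    deliberately distinct from 0).
    """
    values = np.asarray(values, dtype=float)
    if values.shape[1] < 3:
        raise DataError("bicor requires at least 3 observations")
    x, _ = _bicor_transform(values)
    xn = _normalize_rows(x)
    r = xn @ xn.T
    return np.clip(r, -1.0, 1.0, out=r)


def bicor(x, y) -> float:
    """Biweight midcorrelation of two equal-length vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DataError("bicor expects two equal-length 1-D vectors")
    r = bicor_matrix(np.vstack([x, y]))
    return float(r[0, 1])


# ---------------------------------------------------------------------------
# adjacency and topological overlap
# ---------------------------------------------------------------------------

def adjacency(
    expr: ExpressionMatrix, power: float = 5.0, flavor: str = "signed_hybrid"
) -> WeightedNetwork:
    """Signed-hybrid soft-threshold adjacency: a_ij = max(bicor, 0)^power."""
    if power <= 0:
        raise ConfigurationError("power must be positive")
    if flavor != "signed_hybrid":
        raise ConfigurationError(f"unsupported network flavor {flavor!r}")
    expr.require_log2()
    if expr.n_samples < 3:
        raise DataError("adjacency requires at least 3 samples")
    r = bicor_matrix(expr.values.to_numpy())
    a = np.where(np.isnan(r), 0.0, np.maximum(r, 0.0)) ** power
    np.fill_diagonal(a, 0.0)
    return WeightedNetwork(adjacency=a, gene_ids=expr.gene_ids, power=power, flavor=flavor)


def topological_overlap(net: WeightedNetwork) -> np.ndarray:
    """Topological-overlap dissimilarity 1 - TOM with zero diagonal.

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij),
    combining direct adjacency with shared-neighbour connectivity.
    """
    a = net.adjacency
    k = a.sum(axis=1)
    shared = a @ a
    kmin = np.minimum.outer(k, k)
    denom = kmin + 1.0 - a
    tom = (shared + a) / denom
    np.fill_diagonal(tom, 1.0)
    d = 1.0 - tom
    np.fill_diagonal(d, 0.0)
    return np.clip(d, 0.0, 1.0)


# ---------------------------------------------------------------------------
# module detection (simplified dynamic hybrid cut)
# ---------------------------------------------------------------------------

def _gap_threshold(heights: np.ndarray, cut_height: float, deep_split: int) -> float:
    """Minimum merge-height gap that justifies splitting a branch.

    ``deep_split`` in 0..4 maps to a relative gap of (1 - (0.64 +
    0.08*ds)) * 3/4 of the usable dendrogram height range, the same
    interpolation scale the dynamic hybrid heuristic uses for its core
    scatter / gap parameters.  Larger deep_split -> smaller required
    gap -> more aggressive splitting.
    """
    if heights.size == 0:
        return 0.0
    h5 = float(np.percentile(heights, 5))
    span = max(cut_height - h5, 1e-12)
    rel = (1.0 - (0.64 + 0.08 * deep_split)) * 0.75
    return rel * span


def detect_modules(
    dissim: np.ndarray,
    gene_ids,
    min_size: int = 30,
    deep_split: int = 2,
    cut_height: float = 0.995,
    pam_stage: bool = True,
) -> ModuleAssignment:
    """Cluster a dissimilarity matrix into modules.

    Average-linkage hierarchical clustering followed by a simplified
    dynamic hybrid cut: the tree is first cut statically at
    ``cut_height``; each static branch is then recursively split at
    internal merges whose height gap over their children exceeds a
    deep_split-dependent threshold (large gaps indicate loosely glued
    sub-branches); clusters below ``min_size`` are dissolved to label
    0; and, when ``pam_stage`` is set, unlabeled genes are reassigned
    to the nearest module by average dissimilarity provided they fit
    no worse than that module's most peripheral member.

    Labels are contiguous positive integers ordered by decreasing
    module size (ties by first gene position); 0 means unassigned.
    """
    d = np.asarray(dissim, dtype=float)
    gene_ids = pd.Index(gene_ids)
    n = d.shape[0]
    if d.shape != (n, n):
        raise DataError("dissimilarity must be square")
    if len(gene_ids) != n:
        raise DataError("gene ids do not match dissimilarity shape")
    if not (0 <= deep_split <= 4):
        raise ConfigurationError("deep_split must be in 0..4")
    if n < min_size:
        warnings.warn("fewer genes than the minimum module size; all unassigned")
        return ModuleAssignment(labels=pd.Series(0, index=gene_ids))

    dsym = (d + d.T) / 2.0
    np.fill_diagonal(dsym, 0.0)
    Z = average(squareform(dsym, checks=False))
    order = leaves_list(Z)
    heights = Z[:, 2]
    gap_min = _gap_threshold(heights, cut_height, deep_split)

    # Iterative traversal over the merge tree. Nodes 0..n-1 are leaves,
    # node n+i is the cluster formed at merge i.
    n_merges = Z.shape[0]
    left = Z[:, 0].astype(int)
    right = Z[:, 1].astype(int)

    def node_height(node: int) -> float:
        return 0.0 if node < n else float(heights[node - n])

    def node_leaves(node: int) -> list[int]:
        out, stack = [], [node]
        while stack:
            v = stack.pop()
            if v < n:
                out.append(v)
            else:
                stack.extend((left[v - n], right[v - n]))
        return out

    clusters: list[list[int]] = []
    stack = [n + n_merges - 1] if n_merges else [0]
    while stack:
        node = stack.pop()
        if node < n:
            clusters.append([node])
            continue
        i = node - n
        h = node_height(node)
        child_h = max(node_height(left[i]), node_height(right[i]))
        if h > cut_height or (h - child_h) >= gap_min:
            stack.extend((left[i], right[i]))
        else:
            clusters.append(node_leaves(node))

    labels = np.zeros(n, dtype=int)
    kept = [c for c in clusters if len(c) >= min_size]
    kept.sort(key=lambda c: (-len(c), min(c)))
    for lab, members in enumerate(kept, start=1):
        labels[members] = lab

    if pam_stage and kept:
        labels = _pam_reassign(dsym, labels)

    labels = _relabel_by_size(labels)
    return ModuleAssignment(
        labels=pd.Series(labels, index=gene_ids), dendrogram_order=order
    )


def _pam_reassign(d: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Assign unlabeled genes to the nearest module if they fit.

    A gene joins its closest module (smallest average dissimilarity to
    members) only when that distance does not exceed the module's own
    radius, defined as the largest member-to-rest average
    dissimilarity.  This keeps genuinely unstructured genes out.
    """
    labels = labels.copy()
    mods = [m for m in np.unique(labels) if m > 0]
    if not mods:
        return labels
    radii = {}
    mean_to_mod = {}
    for m in mods:
        idx = np.where(labels == m)[0]
        sub = d[np.ix_(idx, idx)]
        size = len(idx)
        if size < 2:
            radii[m] = 0.0
        else:
            member_avg = sub.sum(axis=1) / (size - 1)
            radii[m] = float(member_avg.max())
        mean_to_mod[m] = d[:, idx].mean(axis=1)
    unassigned = np.where(labels == 0)[0]
    for g in unassigned:
        dists = [(mean_to_mod[m][g], m) for m in mods]
        best_d, best_m = min(dists)
        if best_d <= radii[best_m]:
            labels[g] = best_m
    return labels


def _relabel_by_size(labels: np.ndarray) -> np.ndarray:
    mods = [m for m in np.unique(labels) if m > 0]
    sizes = {m: (labels == m).sum() for m in mods}
    firsts = {m: int(np.argmax(labels == m)) for m in mods}
    order = sorted(mods, key=lambda m: (-sizes[m], firsts[m]))
    out = np.zeros_like(labels)
    for new, old in enumerate(order, start=1):
        out[labels == old] = new
    return out


# ---------------------------------------------------------------------------
# eigengenes and kME
# ---------------------------------------------------------------------------

def _standardize(values: pd.DataFrame) -> tuple[pd.DataFrame, pd.Index]:
    """Center/scale each gene by its own mean and SD; drop constant genes."""
    mean = values.mean(axis=1)
    sd = values.std(axis=1, ddof=1)
    constant = sd == 0
    if constant.any():
        warnings.warn(f"dropping {int(constant.sum())} constant gene(s) before PCA")
        values = values.loc[~constant]
        mean = mean[~constant]
        sd = sd[~constant]
    z = values.sub(mean, axis=0).div(sd, axis=0)
    return z, values.index


def module_eigengene(
    expr: ExpressionMatrix, genes, module_id: int = 0
) -> tuple[EigengeneModel, pd.DataFrame]:
    """First two principal axes of a module's standardized expression.

    Genes are centered and scaled by their own mean/SD; the
    standardized submatrix is decomposed by SVD.  PC1 (the module
    eigengene) is oriented to correlate non-negatively with the
    module's mean standardized expression; PC2's sign is fixed by
    making its largest-magnitude gene loading positive.

    Returns the fitted :class:`EigengeneModel` and a samples x
    ["PC1", "PC2"] score table.
    """
    genes = list(genes)
    if len(genes) < 2:
        raise DataError("module eigengene requires at least 2 genes")
    sub = expr.subset_genes(genes)
    if sub.n_samples < 3:
        raise DataError("module eigengene requires at least 3 samples")
    mean = sub.values.mean(axis=1)
    sd = sub.values.std(axis=1, ddof=1)
    z, kept = _standardize(sub.values)
    if len(kept) < 2:
        raise DataError("fewer than 2 non-constant genes in module")
    m = z.to_numpy().T  # samples x genes
    u, s, vt = np.linalg.svd(m, full_matrices=False)
    scores = u[:, :2] * s[:2]
    vecs = vt[:2].copy()
    total = (s**2).sum()
    explained = (s[:2] ** 2) / total if total > 0 else np.zeros(2)

    mean_profile = z.to_numpy().mean(axis=0)  # per sample
    orient = np.corrcoef(scores[:, 0], mean_profile)[0, 1] if np.std(mean_profile) > 0 else 1.0
    sign1 = -1 if orient < 0 else 1
    scores[:, 0] *= sign1
    vecs[0] *= sign1
    if vecs.shape[0] > 1:
        j = int(np.argmax(np.abs(vecs[1])))
        if vecs[1, j] < 0:
            vecs[1] *= -1
            scores[:, 1] *= -1

    model = EigengeneModel(
        module_id=module_id,
        gene_ids=list(kept),
        means=mean[kept].to_numpy(),
        sds=sd[kept].to_numpy(),
        eigenvectors=vecs,
        explained_variance=np.asarray(explained),
        orientation_sign=sign1,
    )
    score_df = pd.DataFrame(scores, index=sub.sample_ids, columns=["PC1", "PC2"])
    return model, score_df


def kme(expr: ExpressionMatrix, eigengene_scores: pd.Series) -> pd.Series:
    """Per-gene Pearson correlation with a module eigengene score.

    Constant genes get NaN (undefined membership) and should be
    excluded from rankings.
    """
    e = eigengene_scores.reindex(expr.sample_ids)
    if e.isna().any():
        raise DataError("eigengene scores missing for some samples")
    x = expr.values.to_numpy()
    y = e.to_numpy(dtype=float)
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    denom = np.sqrt((xc**2).sum(axis=1) * (yc**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (xc @ yc) / denom
    return pd.Series(r, index=expr.gene_ids, name="kME")


# ---------------------------------------------------------------------------
# quality gates
# ---------------------------------------------------------------------------

def _density_stats(a: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Density-based statistics of a subnetwork: density and mean adjacency.

    For a fully weighted network with zero diagonal these coincide by
    definition (both are the mean off-diagonal adjacency); both are
    reported so the gate's median-Z semantics stay explicit.
    """
    sub = a[np.ix_(idx, idx)]
    m = len(idx)
    if m < 2:
        return np.array([0.0, 0.0])
    dens = sub.sum() / (m * (m - 1))
    return np.array([dens, dens])


def topological_significance(
    net: WeightedNetwork,
    assignment: ModuleAssignment,
    n_random: int = 100,
    seed: int = 0,
    z_threshold: float = 2.0,
) -> pd.DataFrame:
    """Gate modules on density-based Z-scores against random gene sets.

    For every module, its density-based statistics are compared with
    ``n_random`` equally sized gene sets drawn without replacement
    from the analysis universe; Z = (observed - mean) / sd per
    statistic, and a module passes when the median Z across statistics
    is at least ``z_threshold``.
    """
    rng = np.random.default_rng(seed)
    a = net.adjacency
    gene_pos = {g: i for i, g in enumerate(net.gene_ids)}
    n = len(net.gene_ids)
    records = []
    for m in assignment.module_ids:
        genes = assignment.genes_of(m)
        idx = np.array([gene_pos[g] for g in genes])
        obs = _density_stats(a, idx)
        null = np.empty((n_random, obs.size))
        for b in range(n_random):
            ridx = rng.choice(n, size=len(idx), replace=False)
            null[b] = _density_stats(a, ridx)
        mu = null.mean(axis=0)
        sd = null.std(axis=0, ddof=1)
        z = np.empty_like(obs)
        for j in range(obs.size):
            if sd[j] <= 1e-10 * max(abs(mu[j]), 1e-30):
                # degenerate null (identical draws up to float noise)
                if np.isclose(obs[j], mu[j]):
                    z[j] = 0.0  # observed equals the degenerate null exactly
                elif obs[j] > mu[j]:
                    warnings.warn("degenerate null (sd=0); reporting +inf Z")
                    z[j] = np.inf
                else:
                    z[j] = -np.inf
            else:
                z[j] = (obs[j] - mu[j]) / sd[j]
        med = float(np.median(z))
        records.append(
            {
                "module": m,
                "z_density": z[0],
                "z_mean_adjacency": z[1],
                "median_z": med,
                "passed": bool(med >= z_threshold),
            }
        )
    return pd.DataFrame(records).set_index("module")


def _best_jaccard(ref_genes: set, found: ModuleAssignment) -> float:
    best = 0.0
    for m in found.module_ids:
        other = set(found.genes_of(m))
        inter = len(ref_genes & other)
        union = len(ref_genes | other)
        if union:
            best = max(best, inter / union)
    return best


def module_stability(
    expr: ExpressionMatrix,
    reference: ModuleAssignment,
    power: float = 5.0,
    min_size: int = 30,
    deep_split: int = 2,
    cut_height: float = 0.995,
    pam_stage: bool = True,
    n_iter: int = 50,
    frac: float = 0.632,
    seed: int = 0,
) -> pd.Series:
    """Subsampling stability of reference modules.

    Repeats sample subsampling (fraction ``frac`` without replacement)
    plus full module detection ``n_iter`` times; a reference module's
    stability is the mean over iterations of its best Jaccard overlap
    with any module found in that iteration.  Iterations that find no
    modules contribute overlap 0.
    """
    if not 0 < frac <= 1:
        raise ConfigurationError("frac must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    n = expr.n_samples
    k = max(int(round(frac * n)), 3)
    ref_sets = {m: set(reference.genes_of(m)) for m in reference.module_ids}
    sums = {m: 0.0 for m in ref_sets}
    for _ in range(n_iter):
        cols = expr.sample_ids[np.sort(rng.choice(n, size=k, replace=False))]
        sub = ExpressionMatrix(expr.values[cols], scale=expr.scale)
        net = adjacency(sub, power=power)
        dissim = topological_overlap(net)
        found = detect_modules(
            dissim,
            expr.gene_ids,
            min_size=min_size,
            deep_split=deep_split,
            cut_height=cut_height,
            pam_stage=pam_stage,
        )
        for m, genes in ref_sets.items():
            sums[m] += _best_jaccard(genes, found)
    return pd.Series({m: sums[m] / n_iter for m in ref_sets}, name="stability")
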