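"""Cross-cohort harmonization and module-score projection.

A clinical cohort measured on a different platform or batch is made
comparable with the reference by reference-moment matching: each gene
in the target is location/scale transformed so its batch mean and SD
equal the reference batch's, leaving reference values untouched.
Module scores for the new cohort are then "predicted" by standardizing
with the *reference* gene means and SDs and projecting onto the stored
reference principal axes — no refitting on the target cohort.
"""

from __future__ import annotations

import json
import warnings

import numpy as np
import pandas as pd

from .containers import DataError, EigengeneModel, ExpressionMatrix
from .coexpression import module_eigengene

__all__ = ["reference_batch_correct", "fit_projection", "project_scores", "ProjectionModel"]

# The projection model *is* the eigengene model: reference means, SDs,
# eigenvectors and gene order are exactly what portability requires.
ProjectionModel = EigengeneModel


def reference_batch_correct(
    target: ExpressionMatrix, reference: ExpressionMatrix
) -> ExpressionMatrix:
    """Match target per-gene batch moments to the reference batch.

    For each shared gene the target values are shifted and rescaled so
    their cohort mean and SD equal the reference cohort's.  Genes with
    zero target SD are only re-centered; genes absent from the
    reference are dropped with a warning.
    """
    target.require_log2()
    reference.require_log2()
    shared = [g for g in target.gene_ids if g in set(reference.gene_ids)]
    dropped = target.n_genes - len(shared)
    if dropped:
        warnings.warn(f"dropping {dropped} target gene(s) absent from the reference")
    if not shared:
        raise DataError("no shared genes between target and reference")
    t = target.values.loc[shared]
    r = reference.values.loc[shared]
    t_mean = t.mean(axis=1)
    t_sd = t.std(axis=1, ddof=1)
    r_mean = r.mean(axis=1)
    r_sd = r.std(axis=1, ddof=1)
    scale = pd.Series(np.where(t_sd > 0, r_sd / t_sd.replace(0, 1.0), 1.0), index=t.index)
    corrected = t.sub(t_mean, axis=0).mul(scale, axis=0).add(r_mean, axis=0)
    return ExpressionMatrix(corrected, scale="log2")


def fit_projection(
    reference: ExpressionMatrix, genes, module_id: int = 0
) -> ProjectionModel:
    """Fit reference means, SDs and oriented eigenvectors for a module.

    Zero-variance reference genes are excluded from the basis at fit
    time (a projection onto a partially degenerate basis would change
    scale silently).
    """
    model, _ = module_eigengene(reference, genes, module_id=module_id)
    return model


def project_scores(model: ProjectionModel, cohort: ExpressionMatrix) -> pd.DataFrame:
    """Project a cohort onto stored reference principal axes.

    The cohort is standardized per gene by the *reference* means and
    SDs and multiplied into the stored eigenvectors.  All model genes
    must be present; a projection on a partial basis is refused.
    """
    missing = [g for g in model.gene_ids if g not in cohort.values.index]
    if missing:
        raise DataError(f"cohort is missing {len(missing)} model gene(s): {missing[:10]}")
    sub = cohort.values.loc[list(model.gene_ids)].to_numpy()
    z = (sub - model.means[:, None]) / model.sds[:, None]
    scores = z.T @ model.eigenvectors.T  # samples x 2
    return pd.DataFrame(scores, index=cohort.sample_ids, columns=["PC1", "PC2"])


def save_projection(model: ProjectionModel, path) -> None:
    model.to_json(path)


def load_projection(path) -> ProjectionModel:
    return ProjectionModel.from_json(path)
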