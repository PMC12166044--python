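"""Synthetic cohorts with planted co-expression structure.

The generators emulate the study design the pipeline targets: a large
pre-treatment reference cohort (basal-like breast tumours) carrying a
handful of correlated gene modules, a small paired-biopsy clinical
cohort whose binary treatment response is driven by one module's latent
activity through a threshold, B-cell-receptor clonotype tables whose
total abundance tracks that module, and subtype centroid profiles.

The underlying model is linear-Gaussian: each module m has a latent
per-sample factor f_m ~ N(0, 1), and a member gene g observes

    x_gs = baseline_g + loading_g * f_ms + eps,   eps ~ N(0, noise_sd^2)

on the log2 scale, while background genes are baseline plus independent
noise.  This is the minimal structure under which module eigengenes and
kME are well defined and recoverable, so every downstream stage can be
tested against known ground truth.

All generators are pure functions of their arguments including the
integer seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import (
    CentroidModel,
    ClinicalTable,
    ConfigurationError,
    ExpressionMatrix,
)

BACKGROUND = 0  # module label for unstructured genes

# Study-scale defaults: reference of 150 basal-like samples over the
# 2000 most variable genes, with five planted modules whose sizes match
# the module sizes reported for the reference network build.
DEFAULT_N_SAMPLES = 150
DEFAULT_N_GENES = 2000
DEFAULT_MODULE_SIZES = (469, 323, 190, 48, 42)
DEFAULT_LOADING_RANGE = (0.4, 1.2)
DEFAULT_NOISE_SD = 0.5


@dataclass
class SyntheticTruth:
    """Ground truth of a synthetic reference cohort.

    ``loadings`` maps every gene to its module id (0 = background, with
    loading exactly 0) and loading weight; ``latent_factors`` holds the
    per-sample module factors.  Response labels downstream are a
    deterministic function of ``response_module``'s factor and
    ``response_threshold`` plus recorded label-noise draws.
    """

    latent_factors: pd.DataFrame  # samples x modules ("M1"...)
    loadings: pd.DataFrame  # index gene, columns: module (int), loading, baseline
    response_module: int
    response_threshold: float
    noise_sd: float
    seed: int
    loading_range: tuple[float, float] = DEFAULT_LOADING_RANGE

    @property
    def module_ids(self) -> list[int]:
        mods = sorted(int(m) for m in self.loadings["module"].unique() if m != BACKGROUND)
        return mods

    def genes_of(self, module_id: int) -> list[str]:
        return list(self.loadings.index[self.loadings["module"] == module_id])

    def module_sizes(self) -> dict[int, int]:
        return {m: len(self.genes_of(m)) for m in self.module_ids}

    def to_json(self, path) -> None:
        d = {
            "latent_factors": self.latent_factors.to_dict(orient="split"),
            "loadings": self.loadings.to_dict(orient="split"),
            "response_module": self.response_module,
            "response_threshold": self.response_threshold,
            "noise_sd": self.noise_sd,
            "seed": self.seed,
            "loading_range": list(self.loading_range),
        }
        with open(path, "w") as fh:
            json.dump(d, fh)


def _module_factor_names(n_modules: int) -> list[str]:
    return [f"M{i}" for i in range(1, n_modules + 1)]


def generate_reference_cohort(
    n_samples: int = DEFAULT_N_SAMPLES,
    n_genes: int = DEFAULT_N_GENES,
    module_sizes: tuple[int, ...] = DEFAULT_MODULE_SIZES,
    loading_range: tuple[float, float] = DEFAULT_LOADING_RANGE,
    noise_sd: float = DEFAULT_NOISE_SD,
    seed: int = 0,
    response_module: int = 3,
    response_threshold: float = 0.0,
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Generate a reference cohort with planted correlated modules.

    Module genes follow ``loading * factor + noise`` on the log2 scale
    around a gene-specific baseline; background genes are independent
    noise around their baseline.  Baselines mimic log2-TPM abundances.
    """
    if n_samples < 3:
        raise ConfigurationError("need at least 3 samples")
    if noise_sd <= 0:
        raise ConfigurationError("noise_sd must be positive")
    if sum(module_sizes) > n_genes:
        raise ConfigurationError("module sizes exceed the gene count")
    lo, hi = loading_range
    if not (0 < lo <= hi):
        raise ConfigurationError("loading range must be positive and ordered")

    rng = np.random.default_rng(seed)
    n_modules = len(module_sizes)
    sample_ids = [f"REF{idx:03d}" for idx in range(1, n_samples + 1)]
    gene_ids = [f"G{idx:04d}" for idx in range(1, n_genes + 1)]

    factors = rng.standard_normal((n_samples, n_modules))
    labels = np.zeros(n_genes, dtype=int)
    loadings = np.zeros(n_genes)
    pos = 0
    for m, size in enumerate(module_sizes, start=1):
        labels[pos : pos + size] = m
        loadings[pos : pos + size] = rng.uniform(lo, hi, size)
        pos += size
    baselines = rng.normal(7.0, 2.0, n_genes)

    values = baselines[:, None] + rng.normal(0.0, noise_sd, (n_genes, n_samples))
    member = labels > 0
    values[member] += loadings[member, None] * factors[:, labels[member] - 1].T

    expr = ExpressionMatrix(
        pd.DataFrame(values, index=gene_ids, columns=sample_ids), scale="log2"
    )
    truth = SyntheticTruth(
        latent_factors=pd.DataFrame(
            factors, index=sample_ids, columns=_module_factor_names(n_modules)
        ),
        loadings=pd.DataFrame(
            {"module": labels, "loading": loadings, "baseline": baselines}, index=gene_ids
        ),
        response_module=response_module,
        response_threshold=response_threshold,
        noise_sd=noise_sd,
        seed=seed,
        loading_range=(lo, hi),
    )
    return expr, truth


_TISSUES = ("Breast", "LymphNode", "Liver", "Skin")


def generate_clinical_cohort(
    truth: SyntheticTruth,
    n_patients: int = 13,
    effect: float = 2.0,
    label_noise: float = 0.0,
    seed: int = 0,
    responder_fraction: float = 8 / 13,
    within_patient_corr: float = 0.8,
    bx2_shift: dict[int, float] | None = None,
    batch_shift_sd: float = 0.3,
    batch_scale_sd: float = 0.1,
) -> tuple[ExpressionMatrix, ExpressionMatrix, ClinicalTable]:
    """Generate a paired-biopsy clinical cohort from reference truth.

    Responders receive response-module factors above the planted
    threshold and non-responders below it, separated by ``effect``:
    with ``label_noise = 0`` the factor orders the classes perfectly.
    Bx2 factors share the patient's Bx1 factor at correlation
    ``within_patient_corr`` plus an additive treatment shift on
    selected modules (``bx2_shift``; default shifts the response
    module by +1).  A mild per-gene batch shift/scale distinguishes the
    cohort from the reference so harmonization has real work to do.
    """
    if effect == 0:
        raise ConfigurationError("effect must be nonzero")
    if not 0 <= label_noise < 0.5:
        raise ConfigurationError("label_noise must lie in [0, 0.5)")
    if n_patients < 4:
        raise ConfigurationError(
            "need at least 4 patients to populate both classes with minimum leaf size 3"
        )
    rng = np.random.default_rng(seed)
    n_modules = truth.latent_factors.shape[1]
    r_idx = truth.response_module - 1
    thr = truth.response_threshold
    if bx2_shift is None:
        bx2_shift = {truth.response_module: 1.0}

    n_resp = int(round(responder_fraction * n_patients))
    n_resp = min(max(n_resp, 2), n_patients - 2)
    responder = np.zeros(n_patients, dtype=bool)
    responder[:n_resp] = True
    responder = responder[rng.permutation(n_patients)]

    # Bx1 factors: response module separated by +-effect around threshold
    bx1 = rng.standard_normal((n_patients, n_modules))
    offsets = effect * rng.uniform(0.1, 1.0, n_patients)
    bx1[:, r_idx] = np.where(responder, thr + offsets, thr - offsets)

    # label noise: recorded flips applied to the stated response
    flips = rng.random(n_patients) < label_noise
    observed_responder = responder ^ flips

    rho = within_patient_corr
    fresh = rng.standard_normal((n_patients, n_modules))
    bx2 = rho * bx1 + np.sqrt(max(1 - rho**2, 0.0)) * fresh
    for mod, delta in bx2_shift.items():
        bx2[:, mod - 1] += delta

    gene_ids = truth.loadings.index
    shift = rng.normal(0.0, batch_shift_sd, len(gene_ids))
    scale = np.exp(rng.normal(0.0, batch_scale_sd, len(gene_ids)))

    def _expr(factors: np.ndarray, tag: str) -> ExpressionMatrix:
        lab = truth.loadings["module"].to_numpy()
        load = truth.loadings["loading"].to_numpy()
        base = truth.loadings["baseline"].to_numpy()
        values = base[:, None] + rng.normal(0.0, truth.noise_sd, (len(gene_ids), n_patients))
        member = lab > 0
        values[member] += load[member, None] * factors[:, lab[member] - 1].T
        values = values * scale[:, None] + shift[:, None]
        cols = [f"P{p:02d}_{tag}" for p in range(1, n_patients + 1)]
        return ExpressionMatrix(
            pd.DataFrame(values, index=gene_ids, columns=cols), scale="log2"
        )

    expr_bx1 = _expr(bx1, "Bx1")
    expr_bx2 = _expr(bx2, "Bx2")

    tissues = rng.choice(_TISSUES, n_patients, p=(0.35, 0.4, 0.15, 0.1))
    best = np.where(
        observed_responder, np.where(rng.random(n_patients) < 0.5, "SD", "PR"), "PD"
    )
    rows = []
    for p in range(n_patients):
        pid = f"P{p + 1:02d}"
        for tag in ("Bx1", "Bx2"):
            rows.append(
                {
                    "sample_id": f"{pid}_{tag}",
                    "patient_id": pid,
                    "biopsy": tag,
                    "tissue": tissues[p],
                    "best_response": best[p],
                    "responder": bool(observed_responder[p]),
                }
            )
    clinical = ClinicalTable(pd.DataFrame(rows))

    # record clinical factors on the truth object for assertions
    factors = np.vstack([bx1, bx2])
    index = [f"P{p:02d}_Bx1" for p in range(1, n_patients + 1)] + [
        f"P{p:02d}_Bx2" for p in range(1, n_patients + 1)
    ]
    clinical_factors = pd.DataFrame(
        factors, index=index, columns=truth.latent_factors.columns
    )
    truth.clinical_factors = clinical_factors  # type: ignore[attr-defined]
    return expr_bx1, expr_bx2, clinical


_CHAINS = ("IGH", "IGK", "IGL")
_ISOTYPES = ("IGHM", "IGHG1", "IGHG3", "IGHA1")


def generate_clonotype_tables(
    clinical: ClinicalTable,
    truth: SyntheticTruth,
    mean_reads: int = 5000,
    clone_alpha: float = 2.0,
    abundance_slope: float = 0.8,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate per-sample clonotype tables with power-law clone sizes.

    Per-sample total reads scale log-linearly with the response
    module's latent factor so that responders (high factor) carry
    higher immunoglobulin abundance.  Clone sizes are drawn from a
    discrete power law with exponent ``clone_alpha`` truncated at the
    read budget.

    Returns a single long-format DataFrame with columns
    (sample_id, clonotype_id, chain, isotype, reads).
    """
    if mean_reads < 1:
        raise ConfigurationError("mean_reads must be >= 1")
    if clone_alpha <= 0:
        raise ConfigurationError("clone_alpha must be positive")
    rng = np.random.default_rng(seed)
    factors = getattr(truth, "clinical_factors", None)
    col = f"M{truth.response_module}"
    rows = []
    for _, rec in clinical.table.iterrows():
        sid = rec["sample_id"]
        f = float(factors.loc[sid, col]) if factors is not None else 0.0
        total = max(int(round(mean_reads * np.exp(abundance_slope * f))), 10)
        # discrete power law truncated at the remaining budget
        sizes = []
        remaining = total
        kmax = total
        ks = np.arange(1, kmax + 1)
        probs = ks ** (-clone_alpha)
        probs = probs / probs.sum()
        while remaining > 0:
            k = int(rng.choice(ks, p=probs))
            k = min(k, remaining)
            sizes.append(k)
            remaining -= k
        chains = rng.choice(_CHAINS, len(sizes), p=(0.6, 0.25, 0.15))
        for i, (k, chain) in enumerate(zip(sizes, chains), start=1):
            iso = rng.choice(_ISOTYPES) if chain == "IGH" else ""
            rows.append(
                {
                    "sample_id": sid,
                    "clonotype_id": f"{sid}_c{i:05d}",
                    "chain": chain,
                    "isotype": iso,
                    "reads": k,
                }
            )
    return pd.DataFrame(rows)


_SUBTYPES = ("BLIA", "BLIS", "LAR", "MES")


def generate_centroids(
    truth: SyntheticTruth,
    n_subtype_genes: int = 77,
    n_subtypes: int = 4,
    separation: float = 2.0,
    seed: int = 0,
) -> CentroidModel:
    """Generate nearest-centroid subtype profiles over a gene subset.

    Each subtype profile is the gene baseline plus an independent
    Gaussian offset of scale ``separation``; samples generated from a
    centroid (profile plus small noise) correlate most with it.
    """
    if n_subtypes < 2:
        raise ConfigurationError("at least 2 subtypes required")
    if n_subtype_genes > len(truth.loadings):
        raise ConfigurationError("n_subtype_genes exceeds the gene universe")
    rng = np.random.default_rng(seed)
    genes = list(
        rng.choice(truth.loadings.index.to_numpy(), n_subtype_genes, replace=False)
    )
    base = truth.loadings.loc[genes, "baseline"].to_numpy()
    names = list(_SUBTYPES[:n_subtypes]) + [
        f"S{i}" for i in range(5, n_subtypes + 1)
    ]
    names = names[:n_subtypes]
    profiles = pd.DataFrame(
        base[:, None] + rng.normal(0.0, separation, (n_subtype_genes, n_subtypes)),
        index=genes,
        columns=names,
    )
    return CentroidModel(profiles=profiles)


def sample_from_centroid(
    centroids: CentroidModel,
    subtype: str,
    noise_sd: float = 0.3,
    seed: int = 0,
) -> pd.Series:
    """Draw one expression profile near a centroid (testing helper)."""
    rng = np.random.default_rng(seed)
    mu = centroids.profiles[subtype]
    return mu + rng.normal(0.0, noise_sd, len(mu))
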