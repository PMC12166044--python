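"""End-to-end orchestration of the network-stratification pipeline.

Two stages mirror the reference/clinical cohort split of the study
design: :func:`run_reference_build` fits everything that depends only
on the reference cohort (modules, eigengene models, kME, quality
gates), and :func:`run_cohort_analysis` consumes those artifacts to
score, classify and decompose a clinical cohort.  :func:`run_demo`
exercises both on synthetic cohorts with planted structure.

All artifacts are plain text (TSV/JSON) and every report number is
recomputable from them; a run is reproducible from its config and
seed alone.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from . import io as nio
from .classify import (
    INDETERMINATE,
    call_subtype,
    calls_to_frame,
    classification_metrics,
    fit_threshold_classifier,
    format_metric,
    rescue_indeterminate,
)
from .coexpression import (
    adjacency,
    detect_modules,
    kme,
    module_eigengene,
    module_stability,
    select_variable_genes,
    topological_overlap,
    topological_significance,
)
from .containers import CentroidModel, ClinicalTable, ExpressionMatrix, GeneSet
from .differential import moderated_t, paired_delta, sector_assign
from .harmonize import project_scores, reference_batch_correct
from .patient_networks import feature_tables, patient_networks_for_cohort
from .repertoire import class_abundance, cohort_diversity
from .scoring import derive_geneset_by_kme, mean_z_score, ssgsea_score
from .synthetic import (
    generate_centroids,
    generate_clinical_cohort,
    generate_clonotype_tables,
    generate_reference_cohort,
)


@dataclass
class RunConfig:
    """Resolved parameters of a pipeline run.

    Defaults follow the reference analysis settings: signed-hybrid
    bicor network at power 5, dynamic-cut parameters (deepSplit 2,
    cut height 0.995, minimum module size 30, PAM stage on), a
    median-Z >= 2 topological-significance gate against 100 random
    gene sets, kME signature threshold 0.9 and top-3 set, a 0.1
    indeterminate margin for centroid calls, and ctree-style
    single-split classification with minimum leaf 3 at alpha 0.05.
    """

    n_variable_genes: int = 2000
    power: float = 5.0
    min_module_size: int = 30
    deep_split: int = 2
    cut_height: float = 0.995
    pam_stage: bool = True
    n_random_sets: int = 100
    z_threshold: float = 2.0
    stability_iterations: int = 0  # 0 disables the (expensive) stability gate
    stability_fraction: float = 0.632
    kme_threshold: float = 0.9
    kme_top_n: int = 3
    ssgsea_exponent: float = 0.25
    margin_threshold: float = 0.1
    min_leaf: int = 3
    alpha: float = 0.05
    n_perm: int = 10000
    n_patient_network_modules: int = 3
    response_module: int | None = None  # None: pick by Bx1 association p
    seed: int = 0

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass
class ReferenceArtifacts:
    """Everything :func:`run_cohort_analysis` needs from the reference."""

    expression: ExpressionMatrix  # variable-gene universe
    assignment: "pd.Series"
    significance: pd.DataFrame
    eigengene_models: dict[int, object]
    eigengene_scores: dict[int, pd.DataFrame]
    kme_tables: dict[int, pd.Series]
    stability: pd.Series | None
    config: RunConfig


def run_reference_build(
    reference: ExpressionMatrix, config: RunConfig, outdir: str | Path | None = None
) -> ReferenceArtifacts:
    """Build the reference network and its module summaries.

    Selects the most variable genes, forms the signed-hybrid network,
    detects modules on topological-overlap dissimilarity, applies the
    topological-significance gate, and fits eigengene models plus kME
    for every detected module.  Artifacts are written under
    ``outdir`` when given.
    """
    n_var = min(config.n_variable_genes, reference.n_genes)
    universe = select_variable_genes(reference, n_var)
    net = adjacency(universe, power=config.power)
    dissim = topological_overlap(net)
    assignment = detect_modules(
        dissim,
        universe.gene_ids,
        min_size=config.min_module_size,
        deep_split=config.deep_split,
        cut_height=config.cut_height,
        pam_stage=config.pam_stage,
    )
    significance = topological_significance(
        net,
        assignment,
        n_random=config.n_random_sets,
        seed=config.seed,
        z_threshold=config.z_threshold,
    )
    models, scores, kmes = {}, {}, {}
    for m in assignment.module_ids:
        model, sc = module_eigengene(universe, assignment.genes_of(m), module_id=m)
        models[m] = model
        scores[m] = sc
        kmes[m] = kme(universe, sc["PC1"])
    stability = None
    if config.stability_iterations > 0:
        stability = module_stability(
            universe,
            assignment,
            power=config.power,
            min_size=config.min_module_size,
            deep_split=config.deep_split,
            cut_height=config.cut_height,
            pam_stage=config.pam_stage,
            n_iter=config.stability_iterations,
            frac=config.stability_fraction,
            seed=config.seed,
        )
    artifacts = ReferenceArtifacts(
        expression=universe,
        assignment=assignment,
        significance=significance,
        eigengene_models=models,
        eigengene_scores=scores,
        kme_tables=kmes,
        stability=stability,
        config=config,
    )
    if outdir is not None:
        _write_reference(artifacts, Path(outdir))
    return artifacts


def _write_reference(art: ReferenceArtifacts, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    art.config.to_json(outdir / "config.json")
    art.assignment.labels.rename("module_id").to_csv(outdir / "modules.tsv", sep="\t")
    art.significance.to_csv(outdir / "significance.tsv", sep="\t")
    nio.write_expression_tsv(art.expression, outdir / "reference_universe.tsv")
    rows = []
    for m, sc in art.eigengene_scores.items():
        d = sc.copy()
        d.insert(0, "module", m)
        rows.append(d)
    pd.concat(rows).to_csv(outdir / "eigengene_scores.tsv", sep="\t")
    kme_df = pd.DataFrame({f"M{m}": k for m, k in art.kme_tables.items()})
    kme_df.to_csv(outdir / "kme.tsv", sep="\t")
    for m, model in art.eigengene_models.items():
        model.to_json(outdir / f"projection_M{m}.json")
    if art.stability is not None:
        art.stability.to_csv(outdir / "stability.tsv", sep="\t")


def _pick_response_module(
    projected: dict[int, pd.DataFrame],
    clinical: ClinicalTable,
    config: RunConfig,
) -> tuple[int, dict[int, float]]:
    """Choose the module whose Bx1 eigengene best separates response."""
    responder = clinical.responder_map()
    bx1 = clinical.samples("Bx1")["sample_id"]
    pvals = {}
    for m, sc in projected.items():
        scores = sc.loc[bx1, "PC1"]
        clf = fit_threshold_classifier(
            scores,
            responder.reindex(bx1),
            feature=f"M{m}_eigengene",
            min_leaf=config.min_leaf,
            alpha=config.alpha,
            n_perm=config.n_perm,
            seed=config.seed,
        )
        pvals[m] = clf.p_value
    best = min(pvals, key=lambda m: (pvals[m], m))
    return best, pvals


def run_cohort_analysis(
    artifacts: ReferenceArtifacts,
    expr_bx1: ExpressionMatrix,
    expr_bx2: ExpressionMatrix,
    clinical: ClinicalTable,
    centroids: CentroidModel | None = None,
    clonotypes: pd.DataFrame | None = None,
    external_sets: list[GeneSet] | None = None,
    outdir: str | Path | None = None,
) -> dict:
    """Score, classify and network-decompose a paired clinical cohort.

    Returns a report dict with per-classifier training metrics on the
    pre-treatment biopsy, subtype no-call rates before and after
    rescue, patient-network layout and differential/sector and
    repertoire summaries.
    """
    config = artifacts.config
    reference = artifacts.expression
    responder = clinical.responder_map()

    # 1. harmonize both biopsies against the reference batch
    cohort = ExpressionMatrix(
        pd.concat([expr_bx1.values, expr_bx2.values], axis=1), scale="log2"
    )
    harmonized = reference_batch_correct(cohort, reference)

    # 2. project onto reference module axes
    projected = {
        m: project_scores(model, harmonized)
        for m, model in artifacts.eigengene_models.items()
    }

    if config.response_module is not None:
        response_module = config.response_module
        assoc_p = {}
    else:
        response_module, assoc_p = _pick_response_module(projected, clinical, config)

    # 3. kME-derived signatures of the response module
    kme_table = artifacts.kme_tables[response_module]
    module_genes = list(artifacts.assignment.labels.index[
        artifacts.assignment.labels == response_module
    ])
    set_thr = derive_geneset_by_kme(
        kme_table, module_genes, name=f"M{response_module}_kme{config.kme_threshold}",
        threshold=config.kme_threshold,
    )
    set_top = derive_geneset_by_kme(
        kme_table, module_genes, name=f"M{response_module}_top{config.kme_top_n}",
        top_n=config.kme_top_n,
    )
    hub_gene = set_top.genes[0]
    hub_set = GeneSet(name=f"hub_{hub_gene}", genes=[hub_gene], provenance="kme_top_n",
                      parameters={"top_n": 1})

    universe = list(reference.gene_ids)
    bx1_ids = clinical.samples("Bx1")["sample_id"]
    labels_bx1 = responder.reindex(bx1_ids)

    def _fit(scores: pd.Series, name: str):
        clf = fit_threshold_classifier(
            scores.loc[bx1_ids],
            labels_bx1,
            feature=name,
            min_leaf=config.min_leaf,
            alpha=config.alpha,
            n_perm=config.n_perm,
            seed=config.seed,
        )
        pred_all = clf.predict(scores)
        metrics = classification_metrics(pred_all.loc[bx1_ids], labels_bx1)
        return clf, pred_all, metrics

    score_tables: dict[str, pd.Series] = {}
    score_tables["eigengene"] = projected[response_module]["PC1"]
    score_tables["kme_signature"] = ssgsea_score(
        harmonized, set_thr, universe=universe, exponent=config.ssgsea_exponent
    )
    score_tables["top_genes"] = ssgsea_score(
        harmonized, set_top, universe=universe, exponent=config.ssgsea_exponent
    )
    hub_scores, _ = mean_z_score(harmonized, hub_set, standardize=True)
    score_tables["hub_gene"] = hub_scores
    if external_sets:
        ext = external_sets[0]
        ext_scores, _ = mean_z_score(harmonized, ext, standardize=False)
        score_tables["external_signature"] = ext_scores

    classifiers, predictions, classifier_report = {}, {}, {}
    for name, scores in score_tables.items():
        clf, pred, metrics = _fit(scores, name)
        classifiers[name] = clf
        predictions[name] = pred
        classifier_report[name] = {
            "feature": clf.feature,
            "cutoff": clf.cutoff,
            "direction": clf.direction,
            "p_value": clf.p_value,
            "degenerate": clf.degenerate,
            "accuracy": metrics["accuracy"],
            "mcc": metrics["mcc"],
            "f1": metrics["f1"],
        }

    # 4. centroid subtype calls with rescue by the kME-signature classifier
    subtype_report = {}
    calls_frame = None
    if centroids is not None:
        calls = []
        for sid in harmonized.sample_ids:
            shared = [g for g in centroids.gene_ids if g in harmonized.values.index]
            sample = harmonized.values.loc[shared, sid]
            sample.name = sid
            sub_model = CentroidModel(
                profiles=centroids.profiles.loc[shared],
                good_prognosis=centroids.good_prognosis,
                poor_prognosis=centroids.poor_prognosis,
            )
            calls.append(
                call_subtype(sample, sub_model, margin_threshold=config.margin_threshold)
            )
        n_ind = sum(c.call == INDETERMINATE for c in calls)
        rescued = rescue_indeterminate(
            calls,
            predictions["kme_signature"],
            good_subtype=centroids.good_prognosis,
            poor_subtype=centroids.poor_prognosis,
        )
        n_ind_after = sum(c.call == INDETERMINATE for c in rescued)
        calls_frame = calls_to_frame(rescued)
        rescued_resp = pd.Series(
            [c.call != centroids.poor_prognosis for c in rescued],
            index=[c.sample_id for c in rescued],
        )
        sub_metrics = classification_metrics(
            rescued_resp.loc[bx1_ids], labels_bx1
        )
        subtype_report = {
            "no_call_rate_before": n_ind / len(calls),
            "no_call_rate_after": n_ind_after / len(calls),
            "n_rescued": n_ind - n_ind_after,
            "accuracy": sub_metrics["accuracy"],
            "mcc": sub_metrics["mcc"],
            "f1": sub_metrics["f1"],
        }
        classifier_report["rescued_subtype"] = {
            "feature": "subtype_call_with_rescue",
            "accuracy": sub_metrics["accuracy"],
            "mcc": sub_metrics["mcc"],
            "f1": sub_metrics["f1"],
        }

    # 5. patient-specific networks for the leading modules
    sig_modules = [
        m for m in artifacts.assignment.module_ids
        if artifacts.significance.loc[m, "passed"]
    ]
    focus = sorted(sig_modules)[: config.n_patient_network_modules]
    module_gene_map = {
        m: artifacts.assignment.labels.index[artifacts.assignment.labels == m].tolist()
        for m in focus
    }
    networks = patient_networks_for_cohort(harmonized, reference, module_gene_map)
    features = feature_tables(networks)

    # 6. differential expression / connectivity and sector assignment
    differential_report = {}
    sector_frames = {}
    focus_genes = [g for m in focus for g in module_gene_map[m]]
    bx2_ids = clinical.samples("Bx2")["sample_id"]
    expr_mat = harmonized.values
    for biopsy, ids in (("Bx1", bx1_ids), ("Bx2", bx2_ids)):
        de = moderated_t(
            expr_mat.loc[focus_genes, ids],
            groups=responder.reindex(ids),
            feature_type="expression",
        )
        differential_report[f"{biopsy}_n_significant_expression"] = int(
            (de["fdr"] < 0.05).sum()
        )
        if biopsy == "Bx1":
            t_expr_bx1 = de["t"]
    # connectivity contrast on Bx1 per focus module, then sectors
    t_net_parts = []
    for m in focus:
        conn = features[m]["connectivity"].T  # genes x samples
        dn = moderated_t(
            conn[bx1_ids], groups=responder.reindex(bx1_ids), feature_type="connectivity"
        )
        t_net_parts.append(dn["t"])
    t_net_bx1 = pd.concat(t_net_parts)
    common = [g for g in focus_genes if g in t_net_bx1.index and g in t_expr_bx1.index]
    sectors = sector_assign(t_expr_bx1.loc[common], t_net_bx1.loc[common])
    sector_frames["Bx1"] = sectors
    differential_report["sector_counts_bx1"] = {
        str(k): int(v) for k, v in sectors["sector"].value_counts().sort_index().items()
    }

    # paired Bx2 - Bx1 deltas of the focus-gene expression
    delta = paired_delta(expr_mat.loc[focus_genes], clinical)
    differential_report["paired_delta_mean_abs"] = float(delta.abs().mean().mean())

    # 7. repertoire diversity
    repertoire_report = {}
    if clonotypes is not None:
        abundance = class_abundance(clonotypes, by="chain")
        pc1 = projected[response_module]["PC1"]
        chain_corr = {}
        for chain, grp in abundance.groupby("chain"):
            joined = grp.set_index("sample_id")["reads"].reindex(pc1.index).dropna()
            if len(joined) >= 3:
                rho = spearmanr(joined, pc1.loc[joined.index]).statistic
                chain_corr[chain] = float(rho)
        panel = cohort_diversity(clonotypes, clinical=None, depths=None, chain="IGH")
        repertoire_report = {
            "abundance_eigengene_spearman": chain_corr,
            "n_samples_with_igh": int(len(panel)),
            "mean_evenness_igh": float(panel["evenness"].mean()) if len(panel) else None,
        }

    report = {
        "response_module": int(response_module),
        "module_association_p": {str(m): p for m, p in assoc_p.items()},
        "classifiers": classifier_report,
        "subtype_calls": subtype_report,
        "patient_networks": {
            "n_networks": len(networks),
            "n_samples": int(harmonized.n_samples),
            "modules": [int(m) for m in focus],
        },
        "differential": differential_report,
        "repertoire": repertoire_report,
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=1, sort_keys=True)
        with open(outdir / "report.txt", "w") as fh:
            fh.write(render_report(report))
        pd.DataFrame(score_tables).to_csv(outdir / "scores.tsv", sep="\t")
        if calls_frame is not None:
            calls_frame.to_csv(outdir / "subtype_calls.tsv", sep="\t", index=False)
        sector_frames["Bx1"].to_csv(outdir / "sectors_bx1.tsv", sep="\t")
        delta.to_csv(outdir / "paired_delta.tsv", sep="\t")
    return report


def render_report(report: dict) -> str:
    """Human-readable summary of a cohort-analysis report."""
    lines = ["Network stratification report", "=" * 30, ""]
    lines.append(f"Response module: M{report['response_module']}")
    lines.append("")
    lines.append("Classifier training performance (Bx1):")
    for name, rec in report["classifiers"].items():
        acc = format_metric(rec["accuracy"], pct=True)
        mcc = format_metric(rec["mcc"])
        f1 = format_metric(rec["f1"])
        lines.append(f"  {name:20s} accuracy {acc:>7s}  MCC {mcc:>6s}  F1 {f1:>6s}")
    if report.get("subtype_calls"):
        sc = report["subtype_calls"]
        lines.append("")
        lines.append(
            "Subtype no-call rate: "
            f"{100 * sc['no_call_rate_before']:.1f}% before rescue, "
            f"{100 * sc['no_call_rate_after']:.1f}% after"
        )
    pn = report["patient_networks"]
    lines.append("")
    lines.append(
        f"Patient networks: {pn['n_networks']} "
        f"({pn['n_samples']} samples x {len(pn['modules'])} modules)"
    )
    return "\n".join(lines) + "\n"


def run_demo(seed: int = 7, outdir: str | Path | None = None,
             config: RunConfig | None = None) -> dict:
    """Reference build plus cohort analysis on synthetic cohorts.

    Generates the default synthetic reference (150 samples, 2000
    genes, five planted modules), a 13-patient paired-biopsy clinical
    cohort driven by the planted response module, synthetic centroids
    and clonotype tables, and runs both pipeline stages.
    """
    if config is None:
        config = RunConfig(seed=seed)
    reference, truth = generate_reference_cohort(seed=seed)
    expr_bx1, expr_bx2, clinical = generate_clinical_cohort(truth, seed=seed + 1)
    centroids = generate_centroids(truth, seed=seed + 2)
    clonotypes = generate_clonotype_tables(clinical, truth, seed=seed + 3)
    rng = np.random.default_rng(seed + 4)
    resp_genes = truth.genes_of(truth.response_module)
    ext = GeneSet(
        name="synthetic_external_signature",
        genes=sorted(rng.choice(resp_genes, size=min(10, len(resp_genes)), replace=False)),
        provenance="external",
    )
    ref_dir = Path(outdir) / "reference" if outdir is not None else None
    artifacts = run_reference_build(reference, config, outdir=ref_dir)
    cohort_dir = Path(outdir) / "cohort" if outdir is not None else None
    report = run_cohort_analysis(
        artifacts,
        expr_bx1,
        expr_bx2,
        clinical,
        centroids=centroids,
        clonotypes=clonotypes,
        external_sets=[ext],
        outdir=cohort_dir,
    )
    report["demo"] = {
        "seed": seed,
        "planted_modules": truth.module_sizes(),
        "planted_response_module": truth.response_module,
    }
    if outdir is not None:
        with open(Path(outdir) / "demo_report.json", "w") as fh:
            json.dump(report, fh, indent=1, sort_keys=True)
    return report
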