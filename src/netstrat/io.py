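"""Plain-text readers and writers for the pipeline's artifact formats.

Expression matrices travel as TSV with genes as rows and a header row
of sample ids; gene sets as GMT (name, description, genes...); module
assignments, scores, kME tables, clonotype tables and centroid
profiles as TSV.
"""

from __future__ import annotations

import pandas as pd

from .containers import CentroidModel, ClinicalTable, DataError, ExpressionMatrix, GeneSet


def read_expression_tsv(path, scale: str = "log2") -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.empty:
        raise DataError(f"expression file {path} is empty")
    return ExpressionMatrix(df, scale=scale)


def write_expression_tsv(expr: ExpressionMatrix, path) -> None:
    expr.values.to_csv(path, sep="\t")


def read_clinical_tsv(path) -> ClinicalTable:
    df = pd.read_csv(path, sep="\t")
    if "responder" in df.columns:
        df["responder"] = df["responder"].astype(bool)
    else:
        df["responder"] = df["best_response"] != "PD"
    return ClinicalTable(df)


def write_clinical_tsv(clinical: ClinicalTable, path) -> None:
    clinical.table.to_csv(path, sep="\t", index=False)


def read_gmt(path) -> list[GeneSet]:
    sets = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            name, _desc, *genes = parts
            genes = [g for g in genes if g]
            sets.append(GeneSet(name=name, genes=genes, provenance="external"))
    if not sets:
        raise DataError(f"no gene sets found in {path}")
    return sets


def write_gmt(sets: list[GeneSet], path) -> None:
    with open(path, "w") as fh:
        for gs in sets:
            desc = gs.provenance
            fh.write("\t".join([gs.name, desc, *gs.genes]) + "\n")


def read_clonotype_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    needed = {"sample_id", "clonotype_id", "chain", "isotype", "reads"}
    missing = needed - set(df.columns)
    if missing:
        raise DataError(f"clonotype table missing columns: {sorted(missing)}")
    return df


def write_clonotype_tsv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_centroids_tsv(path, good_prognosis="BLIA", poor_prognosis="BLIS") -> CentroidModel:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return CentroidModel(profiles=df, good_prognosis=good_prognosis, poor_prognosis=poor_prognosis)


def write_centroids_tsv(model: CentroidModel, path) -> None:
    model.profiles.to_csv(path, sep="\t")
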