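"""Tab-delimited file interfaces for every pipeline stage."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .simulate import SyntheticStudy


def write_expression(expression: pd.DataFrame, path) -> None:
    expression.to_csv(path, sep="\t", index_label="gene")


def read_expression(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene")


def write_sample_meta(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t", index=False)


def read_sample_meta(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_truth(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t", index=False)


def read_truth(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_pod_table(path) -> pd.DataFrame:
    """POD table TSV: chemical, pod_type, value, units, strain_sex."""
    df = pd.read_csv(path, sep="\t")
    required = {"chemical", "pod_type", "value", "units"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"POD table missing columns: {sorted(missing)}")
    return df


def read_apical_endpoints(path) -> pd.DataFrame:
    """Long-format apical endpoint TSV.

    Columns: chemical, endpoint, kind, dose, n, then mean+sd (continuous) or
    affected (dichotomous).
    """
    df = pd.read_csv(path, sep="\t")
    required = {"chemical", "endpoint", "kind", "dose", "n"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"apical endpoint table missing columns: {sorted(missing)}")
    return df


def write_study(study: SyntheticStudy, outdir) -> dict[str, Path]:
    """Write a synthetic study's artifacts (expression, meta, GMTs, truth)."""
    from .pathways import write_gmt

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": outdir / "expression.tsv",
        "sample_meta": outdir / "sample_meta.tsv",
        "pathways": outdir / "pathways.gmt",
        "regulators": outdir / "regulators.gmt",
        "truth": outdir / "truth.tsv",
    }
    write_expression(study.expression, paths["expression"])
    write_sample_meta(study.sample_meta, paths["sample_meta"])
    write_gmt(study.pathways, paths["pathways"])
    write_gmt(study.regulators, paths["regulators"])
    write_truth(study.truth, paths["truth"])
    return paths
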