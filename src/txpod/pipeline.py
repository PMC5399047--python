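"""End-to-end orchestration: screen -> gene BMDs -> pathways -> approaches ->
bootstrap -> concordance, with file-level interfaces and a JSON run summary.

Every numeric constant of the workflow lives in :class:`RunConfig`; stage
logic takes its thresholds from the config rather than hard-coding them.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import approaches as approaches_mod
from . import bootstrap as bootstrap_mod
from . import concordance as concordance_mod
from . import genebmd, io, pathways, screen
from .simulate import SimConfig, SyntheticStudy, simulate_study


@dataclass
class RunConfig:
    """All tunable settings of the pipeline, with the workflow's defaults."""

    fdr_threshold: float = 0.05
    fc_threshold: float = 1.5
    anova_threshold: float = 0.05
    n_permutations: int = 1000
    bmr: float = 1.349
    confidence_level: float = 0.95
    max_iter: int = 250
    hill_flag_fraction: float = 1.0 / 3.0
    fallback_factor: float = 0.5
    min_genes_per_pathway: int = 4
    enrichment_alpha: float = 0.05
    top_n: int = 20
    dichotomous_bmr: float = 0.10
    apical_continuous_bmr: float = 1.0
    bootstrap_B: int = 2000
    compute_bmdl: bool = False
    enrich_gate_approach3: bool = False
    seed: int = 0

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class StudyResult:
    screen: pd.DataFrame
    gene_table_cons: pd.DataFrame
    gene_table_lib: pd.DataFrame
    pathway_table_cons: pd.DataFrame
    pathway_table_lib: pd.DataFrame
    pods: list
    approaches: pd.DataFrame
    bootstraps: dict
    filter_counts: dict = field(default_factory=dict)


def analyze_study(
    expression: pd.DataFrame,
    doses,
    pathway_sets: dict[str, set],
    regulator_sets: dict[str, set] | None = None,
    *,
    config: RunConfig | None = None,
    run_bootstrap: bool = True,
) -> StudyResult:
    """Run the full transcriptomic POD analysis on one study."""
    cfg = config or RunConfig()
    doses = np.asarray(doses, float)
    max_dose = float(doses.max())

    scr = screen.screen_genes(
        expression,
        doses,
        n_permutations=cfg.n_permutations,
        seed=cfg.seed,
        fdr_threshold=cfg.fdr_threshold,
        fc_threshold=cfg.fc_threshold,
        anova_threshold=cfg.anova_threshold,
    )
    cons = screen.filter_genes(scr, "conservative")
    lib = screen.filter_genes(scr, "liberal")

    union = sorted(cons | lib)
    fitted = genebmd.fit_gene_table(
        expression,
        doses,
        genes=union,
        bmr=cfg.bmr,
        compute_bmdl=cfg.compute_bmdl,
        max_iter=cfg.max_iter,
        seed=cfg.seed,
    )
    table_cons, counts_cons = genebmd.postfilter_gene_table(
        fitted[fitted["gene"].isin(cons)], max_dose
    )
    table_lib, counts_lib = genebmd.postfilter_gene_table(
        fitted[fitted["gene"].isin(lib)], max_dose
    )

    universe = set(expression.index)
    db = pathways.PathwayDB.from_sets(pathway_sets, universe, regulator_sets)
    overlap = len(set().union(*pathway_sets.values()) & universe) if pathway_sets else 0
    total_members = len(set().union(*pathway_sets.values())) if pathway_sets else 0
    if total_members and overlap / total_members < 0.10:
        raise ValueError(
            "gene universes inconsistent: <10% of pathway members occur in the "
            "expression matrix"
        )

    pw_cons = pathways.pathway_bmds(table_cons, db, min_genes=cfg.min_genes_per_pathway)
    pw_lib = pathways.pathway_bmds(table_lib, db, min_genes=cfg.min_genes_per_pathway)

    enrich_deg = pathways.enrichment_table(cons, db)
    # BMD-restricted enrichment: same Fisher test as conventional pathway
    # analysis, but the selected set is the genes that survived BMD modeling
    bmd_genes = set(table_lib["gene"])
    enrich_bmd = pathways.enrichment_table(bmd_genes, db) if db.pathways else None

    regs = None
    if regulator_sets:
        try:
            regs = pathways.regulator_significance(cons, db)
        except ValueError:
            regs = None

    inp = approaches_mod.ApproachInput(
        gene_table_cons=table_cons,
        gene_table_lib=table_lib,
        pathway_table_cons=pw_cons,
        pathway_table_lib=pw_lib,
        enrich_deg=enrich_deg,
        enrich_bmd=enrich_bmd,
        screen=scr,
        regulators=regs,
        db=db,
    )
    pods = approaches_mod.run_all(
        inp, top_n=cfg.top_n, enrich_gate_approach3=cfg.enrich_gate_approach3
    )
    boots = (
        bootstrap_mod.bootstrap_all(pods, B=cfg.bootstrap_B, seed=cfg.seed)
        if run_bootstrap
        else {}
    )
    frame = approaches_mod.approaches_frame(pods)
    if boots:
        frame["bootstrap_mean"] = [
            boots[a].mean if boots.get(a) else np.nan for a in frame["approach"]
        ]
        frame["bootstrap_cv"] = [
            boots[a].cv if boots.get(a) else np.nan for a in frame["approach"]
        ]
    return StudyResult(
        screen=scr,
        gene_table_cons=table_cons,
        gene_table_lib=table_lib,
        pathway_table_cons=pw_cons,
        pathway_table_lib=pw_lib,
        pods=pods,
        approaches=frame,
        bootstraps=boots,
        filter_counts={"conservative": counts_cons, "liberal": counts_lib},
    )


def pod_for_approach(result: StudyResult, approach: int) -> float:
    """Reported POD: the bootstrap mean when available, else the point estimate."""
    b = result.bootstraps.get(approach)
    if b is not None:
        return b.mean
    row = result.approaches.set_index("approach").loc[approach]
    return float(row["bmd_t"])


def evaluate_concordance(
    per_chemical: dict[str, StudyResult],
    pod_table: pd.DataFrame,
) -> pd.DataFrame:
    """Three-criterion verdicts for every approach x POD type.

    ``pod_table`` columns: chemical, pod_type, value, units, strain_sex
    (ppm entries are converted to mg/kg-day).  Chemicals missing either a
    POD or an available approach estimate are excluded pairwise.
    """
    verdicts = []
    pod_table = pod_table.copy()
    pod_table["value_mkd"] = [
        concordance_mod.harmonize_pod(
            row["value"], row["units"], row.get("strain_sex")
        )
        for _, row in pod_table.iterrows()
    ]
    for pod_type, sub in pod_table.groupby("pod_type"):
        pods_by_chem = sub.set_index("chemical")["value_mkd"]
        for k in approaches_mod.APPROACH_IDS:
            xs, ys = [], []
            for chem, res in per_chemical.items():
                if chem not in pods_by_chem.index:
                    continue
                row = res.approaches.set_index("approach").loc[k]
                if row["status"] == "unavailable" or not np.isfinite(row["bmd_t"]):
                    continue
                xs.append(pod_for_approach(res, k))
                ys.append(float(pods_by_chem[chem]))
            if len(xs) < 3:
                continue
            verdicts.append(
                concordance_mod.assess_three_criteria(k, pod_type, xs, ys)
            )
    return concordance_mod.verdicts_frame(verdicts)


def run_pipeline(
    expression_path,
    meta_path,
    gmt_path,
    outdir,
    *,
    regulators_path=None,
    pod_table_path=None,
    config: RunConfig | None = None,
) -> dict:
    """File-level entry point; writes stage TSVs plus a JSON run summary."""
    cfg = config or RunConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    expression = io.read_expression(expression_path)
    meta = io.read_sample_meta(meta_path)
    doses = meta.set_index("sample").loc[expression.columns, "dose"].to_numpy()
    pathway_sets = pathways.load_gmt(gmt_path)
    regulator_sets = pathways.load_gmt(regulators_path) if regulators_path else None

    result = analyze_study(
        expression, doses, pathway_sets, regulator_sets, config=cfg
    )

    io.write_table(result.screen, outdir / "screen.tsv")
    io.write_table(result.gene_table_cons, outdir / "gene_bmds_conservative.tsv")
    io.write_table(result.gene_table_lib, outdir / "gene_bmds_liberal.tsv")
    io.write_table(
        result.pathway_table_cons.drop(columns=["genes"]),
        outdir / "pathway_bmds_conservative.tsv",
    )
    io.write_table(
        result.pathway_table_lib.drop(columns=["genes"]),
        outdir / "pathway_bmds_liberal.tsv",
    )
    io.write_table(result.approaches, outdir / "approaches.tsv")
    if result.bootstraps:
        rows = [b.as_dict() for b in result.bootstraps.values() if b is not None]
        io.write_table(pd.DataFrame(rows), outdir / "bootstrap.tsv")

    summary = {
        "config": asdict(cfg),
        "config_hash": cfg.config_hash(),
        "n_genes": int(len(expression)),
        "n_samples": int(expression.shape[1]),
        "n_pass_conservative": int(result.screen["pass_conservative"].sum()),
        "n_pass_liberal": int(result.screen["pass_liberal"].sum()),
        "n_gene_bmds_conservative": int(len(result.gene_table_cons)),
        "n_gene_bmds_liberal": int(len(result.gene_table_lib)),
        "filter_counts": result.filter_counts,
        "approaches": result.approaches.replace({np.nan: None}).to_dict("records"),
    }
    with open(outdir / "run_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    return summary


def simulate_and_write(config: SimConfig, outdir) -> SyntheticStudy:
    study = simulate_study(config)
    io.write_study(study, outdir)
    return study


def run_concordance_suite(
    seed: int = 0,
    *,
    n_chemicals: int = 6,
    n_genes: int = 240,
    n_permutations: int = 300,
    run_bootstrap: bool = False,
    bootstrap_B: int = 500,
) -> dict:
    """Full synthetic concordance study: simulate, analyze, assess.

    Generates ``n_chemicals`` studies whose transcriptional signal sits at
    each chemical's apical BMD, runs the complete per-study analysis, and
    evaluates every approach against the known apical BMDs with the
    three-criterion scheme.  Returns the verdicts plus per-study results.
    """
    from .simulate import simulate_concordance_suite

    suite = simulate_concordance_suite(n_chemicals, seed=seed, n_genes=n_genes)
    per_chemical: dict[str, StudyResult] = {}
    pod_rows = []
    for i, entry in enumerate(suite):
        study = entry["study"]
        cfg = RunConfig(
            seed=seed + i,
            n_permutations=n_permutations,
            bootstrap_B=bootstrap_B,
        )
        per_chemical[entry["chemical"]] = analyze_study(
            study.expression,
            study.doses,
            study.pathways,
            study.regulators,
            config=cfg,
            run_bootstrap=run_bootstrap,
        )
        pod_rows.append(
            {
                "chemical": entry["chemical"],
                "pod_type": "bmd_a",
                "value": entry["apical_bmd"],
                "units": "mkd",
                "strain_sex": None,
            }
        )
    pod_table = pd.DataFrame(pod_rows)
    verdicts = evaluate_concordance(per_chemical, pod_table)
    return {
        "verdicts": verdicts,
        "per_chemical": per_chemical,
        "pod_table": pod_table,
    }
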