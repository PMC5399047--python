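"""The 11 rules for deriving a transcriptomic point of departure.

Each approach selects a group of genes or pathways from the screened and
BMD-modeled study and summarizes their benchmark doses:

1.  20 enriched pathways with the lowest pathway BMDs (conservative filter)
2.  20 most significantly enriched pathways (conservative)
3.  20 pathways with the lowest BMDs, no enrichment gate (liberal filter)
4.  20 genes with the largest fold changes (conservative)
5.  genes with BMDs inside the interquartile band (conservative)
6.  20 enriched pathways with the most shared genes (conservative)
7.  20 genes contributing to the most enriched pathways (conservative)
8.  genes targeted by the 20 most significant upstream regulators (conservative)
9.  the significantly enriched pathway with the lowest BMD (liberal,
    enrichment restricted to BMD-passing genes)
10. mean of all pathway BMDs (liberal)
11. median of all pathway BMDs (liberal)

Pathway-set approaches report the unweighted mean of the selected pathways'
BMDs (each pathway BMD already a mean over genes); gene-set approaches the
mean over the selected genes' BMDs.  Selections of fewer than the nominal 20
entities are flagged partial; an empty selection makes the approach
unavailable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pathways import PathwayDB, gene_membership_counts, shared_gene_counts

APPROACH_IDS = tuple(range(1, 12))
CONSERVATIVE_APPROACHES = frozenset({1, 2, 4, 5, 6, 7, 8})
LIBERAL_APPROACHES = frozenset({3, 9, 10, 11})
TOP_N = 20
ENRICHMENT_ALPHA = 0.05


@dataclass
class ApproachInput:
    """Everything the 11 rules consume, under both filter regimes."""

    gene_table_cons: pd.DataFrame  # post-filtered gene BMD table, FDR+FC filter
    gene_table_lib: pd.DataFrame  # post-filtered gene BMD table, ANOVA filter
    pathway_table_cons: pd.DataFrame  # pathway_bmds() output on the cons table
    pathway_table_lib: pd.DataFrame
    enrich_deg: pd.DataFrame | None = None  # DEG-based Fisher enrichment (cons)
    enrich_bmd: pd.DataFrame | None = None  # BMD-gene Fisher enrichment (lib)
    screen: pd.DataFrame | None = None  # screen table with max_fc
    regulators: pd.DataFrame | None = None  # regulator_significance() output
    db: PathwayDB | None = None


@dataclass
class ApproachPOD:
    approach: int
    status: str  # 'available' | 'partial' | 'unavailable'
    kind: str = "pathway"  # 'pathway' | 'gene'
    statistic: str = "mean"  # 'mean' | 'median'
    entities: list = field(default_factory=list)
    bmd_t: float | None = None
    bmdl_t: float | None = None
    reason: str = ""
    # resampling units for the bootstrap: pathway -> member gene BMDs, or a
    # flat gene BMD vector for gene-set approaches
    gene_bmds: dict | np.ndarray | None = None
    gene_bmdls: dict | np.ndarray | None = None


def _unavailable(k: int, reason: str, kind: str = "pathway") -> ApproachPOD:
    return ApproachPOD(approach=k, status="unavailable", kind=kind, reason=reason)


def _pathway_pod(k: int, rows: pd.DataFrame, statistic: str = "mean") -> ApproachPOD:
    bmds = rows["bmd"].to_numpy(float)
    agg = np.mean if statistic == "mean" else np.median
    bmdls = rows["bmdl"].to_numpy(float)
    bmdl_t = float(agg(bmdls)) if np.all(np.isfinite(bmdls)) else None
    pod = ApproachPOD(
        approach=k,
        status="available" if len(rows) >= min(TOP_N, 1) else "unavailable",
        kind="pathway",
        statistic=statistic,
        entities=list(rows["pathway"]),
        bmd_t=float(agg(bmds)),
        bmdl_t=bmdl_t,
        gene_bmds={r.pathway: np.asarray(r.gene_bmd_vec, float) for r in rows.itertuples()},
        gene_bmdls={
            r.pathway: np.asarray(r.gene_bmdl_vec, float) for r in rows.itertuples()
        },
    )
    return pod


def _gene_pod(k: int, sub: pd.DataFrame, nominal: int | None) -> ApproachPOD:
    bmds = sub["bmd"].to_numpy(float)
    bmdls = sub["bmdl"].to_numpy(float)
    status = "available"
    if nominal is not None and len(sub) < nominal:
        status = "partial"
    return ApproachPOD(
        approach=k,
        status=status,
        kind="gene",
        entities=list(sub["gene"]),
        bmd_t=float(np.mean(bmds)),
        bmdl_t=float(np.nanmean(bmdls)) if np.isfinite(bmdls).any() else None,
        gene_bmds=bmds,
        gene_bmdls=bmdls,
    )


def _scored_pathways(
    pathway_table: pd.DataFrame, gene_table: pd.DataFrame
) -> pd.DataFrame:
    """Pathways with assigned BMDs, augmented with member-gene BMD vectors."""
    rows = pathway_table[pathway_table["bmd"].notna()].copy()
    bmd_by_gene = gene_table.set_index("gene")["bmd"]
    bmdl_by_gene = gene_table.set_index("gene")["bmdl"]
    rows["gene_bmd_vec"] = rows["genes"].map(
        lambda gs: [float(bmd_by_gene[g]) for g in gs]
    )
    rows["gene_bmdl_vec"] = rows["genes"].map(
        lambda gs: [float(bmdl_by_gene[g]) for g in gs]
    )
    return rows


def _enriched_names(enrich: pd.DataFrame | None, alpha: float = ENRICHMENT_ALPHA):
    if enrich is None or enrich.empty:
        return set()
    return set(enrich.loc[enrich["p"] <= alpha, "pathway"])


def _top(rows: pd.DataFrame, key: str, n: int, ascending=True) -> pd.DataFrame:
    return rows.sort_values([key, "pathway"], ascending=[ascending, True]).head(n)


def run_approach(k: int, inp: ApproachInput, *, top_n: int = TOP_N,
                 enrich_gate_approach3: bool = False) -> ApproachPOD:
    """Apply rule ``k`` (1..11); never raises on missing inputs, reports status."""
    if k not in APPROACH_IDS:
        raise ValueError(f"unknown approach: {k}")

    if k in (1, 2, 6):
        scored = _scored_pathways(inp.pathway_table_cons, inp.gene_table_cons)
        enriched = _enriched_names(inp.enrich_deg)
        rows = scored[scored["pathway"].isin(enriched)]
        if rows.empty:
            return _unavailable(k, "no significantly enriched pathways with BMDs")
        if k == 1:
            sel = _top(rows, "bmd", top_n)
        elif k == 2:
            pmap = inp.enrich_deg.set_index("pathway")["p"]
            rows = rows.assign(enrich_p=rows["pathway"].map(pmap))
            sel = rows.sort_values(["enrich_p", "pathway"]).head(top_n)
        else:  # 6
            sets = {r.pathway: set(r.genes) for r in rows.itertuples()}
            if len(sets) < 2:
                counts = pd.Series({next(iter(sets)): 0}) if sets else pd.Series(dtype=int)
            else:
                counts = shared_gene_counts(sets)
            rows = rows.assign(shared=rows["pathway"].map(counts))
            sel = rows.sort_values(["shared", "pathway"], ascending=[False, True]).head(top_n)
        pod = _pathway_pod(k, sel)
        if len(sel) < top_n:
            pod.status = "partial"
        return pod

    if k == 3:
        scored = _scored_pathways(inp.pathway_table_lib, inp.gene_table_lib)
        if enrich_gate_approach3:
            scored = scored[scored["pathway"].isin(_enriched_names(inp.enrich_bmd))]
        if scored.empty:
            return _unavailable(k, "no pathways with BMDs")
        sel = _top(scored, "bmd", top_n)
        pod = _pathway_pod(k, sel)
        if len(sel) < top_n:
            pod.status = "partial"
        return pod

    if k == 4:
        gt = inp.gene_table_cons
        if inp.screen is None:
            return _unavailable(k, "no screen table with fold changes", kind="gene")
        fc = inp.screen.set_index("gene")["max_fc"]
        sub = gt[gt["gene"].isin(fc.index)].copy()
        if sub.empty:
            return _unavailable(k, "no scored genes", kind="gene")
        sub["max_fc"] = sub["gene"].map(fc)
        sub = sub.sort_values(["max_fc", "gene"], ascending=[False, True]).head(top_n)
        return _gene_pod(k, sub, top_n)

    if k == 5:
        gt = inp.gene_table_cons
        if gt.empty:
            return _unavailable(k, "no scored genes", kind="gene")
        q1, q3 = np.percentile(gt["bmd"].to_numpy(float), [25, 75])
        sub = gt[(gt["bmd"] >= q1) & (gt["bmd"] <= q3)]
        if sub.empty:
            return _unavailable(k, "empty interquartile band", kind="gene")
        return _gene_pod(k, sub, None)

    if k == 7:
        gt = inp.gene_table_cons
        enriched = _enriched_names(inp.enrich_deg)
        if inp.db is None or not enriched:
            return _unavailable(k, "no enriched pathways", kind="gene")
        sets = {p: inp.db.pathways[p] for p in enriched if p in inp.db.pathways}
        counts = gene_membership_counts(gt["gene"], sets)
        sub = gt.assign(n_pw=gt["gene"].map(counts))
        sub = sub[sub["n_pw"] > 0]
        if sub.empty:
            return _unavailable(k, "no genes in enriched pathways", kind="gene")
        # ties broken by smaller gene BMD, then id, for determinism
        sub = sub.sort_values(["n_pw", "bmd", "gene"],
                              ascending=[False, True, True]).head(top_n)
        return _gene_pod(k, sub, top_n)

    if k == 8:
        if inp.regulators is None or inp.regulators.empty or inp.db is None:
            return _unavailable(k, "no regulator annotations", kind="gene")
        top_regs = inp.regulators.sort_values(["p", "regulator"]).head(top_n)
        targets = set()
        for name in top_regs["regulator"]:
            targets |= inp.db.regulators.get(name, set())
        sub = inp.gene_table_cons[inp.gene_table_cons["gene"].isin(targets)]
        if sub.empty:
            return _unavailable(k, "no scored target genes", kind="gene")
        return _gene_pod(k, sub, None)

    if k == 9:
        scored = _scored_pathways(inp.pathway_table_lib, inp.gene_table_lib)
        enriched = _enriched_names(inp.enrich_bmd)
        rows = scored[scored["pathway"].isin(enriched)]
        if rows.empty:
            return _unavailable(k, "no significantly enriched pathways with BMDs")
        sel = _top(rows, "bmd", 1)
        return _pathway_pod(k, sel)

    # 10, 11: all pathways with BMDs under the liberal filter
    scored = _scored_pathways(inp.pathway_table_lib, inp.gene_table_lib)
    if scored.empty:
        return _unavailable(k, "no pathways with BMDs")
    statistic = "median" if k == 11 else "mean"
    return _pathway_pod(k, scored, statistic=statistic)


def run_all(inp: ApproachInput, **kwargs) -> list[ApproachPOD]:
    """All 11 approaches in order, each with an availability status."""
    return [run_approach(k, inp, **kwargs) for k in APPROACH_IDS]


def approaches_frame(pods: list[ApproachPOD]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "approach": [p.approach for p in pods],
            "status": [p.status for p in pods],
            "kind": [p.kind for p in pods],
            "n_entities": [len(p.entities) for p in pods],
            "bmd_t": [np.nan if p.bmd_t is None else p.bmd_t for p in pods],
            "bmdl_t": [np.nan if p.bmdl_t is None else p.bmdl_t for p in pods],
            "reason": [p.reason for p in pods],
        }
    )
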