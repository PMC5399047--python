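"""Gene-set (pathway) layer: GMT-backed membership, Fisher enrichment,
pathway BMDs, shared-gene and membership-count statistics, and a
target-overlap surrogate for upstream-regulator analysis.

A pathway is assigned a BMD only when at least four of its member genes carry
BMDs; the pathway BMD is the mean of those member-gene BMDs (likewise for
BMDLs).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

MIN_GENES_PER_PATHWAY = 4


@dataclass
class PathwayDB:
    """Pathway and regulator gene sets restricted to an analysis universe."""

    pathways: dict[str, set]
    universe: set
    regulators: dict[str, set] = field(default_factory=dict)
    n_outside_universe: int = 0

    @classmethod
    def from_sets(cls, pathways, universe, regulators=None) -> "PathwayDB":
        universe = set(universe)
        cleaned, outside = {}, 0
        for name, members in pathways.items():
            members = set(members)
            inside = members & universe
            outside += len(members - universe)
            if inside:
                cleaned[name] = inside
        regs = {}
        if regulators:
            for name, members in regulators.items():
                inside = set(members) & universe
                outside += len(set(members) - universe)
                if inside:
                    regs[name] = inside
        if outside:
            logger.info("ignored %d gene-set members outside the universe", outside)
        return cls(pathways=cleaned, universe=universe, regulators=regs,
                   n_outside_universe=outside)


def load_gmt(path) -> dict[str, set]:
    """Parse a GMT file (set name, description, tab-separated members)."""
    sets: dict[str, set] = {}
    errors = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not any(line.strip() for line in lines):
        raise ValueError(f"empty GMT file: {path}")
    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            errors.append(lineno)
            continue
        name = fields[0]
        sets[name] = set(f for f in fields[2:] if f)
    if errors:
        raise ValueError(f"malformed GMT lines (need >=3 fields): {errors}")
    return sets


def write_gmt(sets: dict[str, set], path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name in sorted(sets):
            members = "\t".join(sorted(sets[name]))
            fh.write(f"{name}\t{description}\t{members}\n")


def fisher_enrichment(selected, pathway, universe) -> float:
    """Right-tailed Fisher exact p for pathway over-representation.

    P(X >= overlap) under the hypergeometric null for the 2x2 table
    (in/out pathway) x (selected/not), all restricted to the universe.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    selected = set(selected) & universe
    pathway = set(pathway) & universe
    overlap = len(selected & pathway)
    N, K, n = len(universe), len(pathway), len(selected)
    return float(stats.hypergeom.sf(overlap - 1, N, K, n))


def enrichment_table(selected, db: PathwayDB, *, sets=None) -> pd.DataFrame:
    """Fisher enrichment p for every pathway (or the supplied ``sets``)."""
    sets = db.pathways if sets is None else sets
    rows = [
        {
            "pathway": name,
            "n_members": len(members),
            "n_selected": len(set(selected) & members),
            "p": fisher_enrichment(selected, members, db.universe),
        }
        for name, members in sets.items()
    ]
    return pd.DataFrame(rows).sort_values(["p", "pathway"]).reset_index(drop=True)


def pathway_bmds(
    gene_table: pd.DataFrame,
    db: PathwayDB,
    min_genes: int = MIN_GENES_PER_PATHWAY,
) -> pd.DataFrame:
    """Pathway BMD_t/BMDL_t as the mean of member-gene BMDs (>= min_genes)."""
    bmd_by_gene = gene_table.set_index("gene")["bmd"]
    bmdl_by_gene = gene_table.set_index("gene")["bmdl"] if "bmdl" in gene_table else None
    rows = []
    for name in sorted(db.pathways):
        members = db.pathways[name]
        scored = sorted(m for m in members if m in bmd_by_gene.index
                        and np.isfinite(bmd_by_gene[m]))
        row = {
            "pathway": name,
            "n_members": len(members),
            "n_with_bmd": len(scored),
            "bmd": np.nan,
            "bmdl": np.nan,
            "genes": scored,
        }
        if len(scored) >= min_genes:
            row["bmd"] = float(bmd_by_gene[scored].mean())
            if bmdl_by_gene is not None:
                vals = bmdl_by_gene[scored].dropna()
                row["bmdl"] = float(vals.mean()) if len(vals) else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def shared_gene_counts(enriched: dict[str, set]) -> pd.Series:
    """Per-pathway count of member genes shared with other enriched pathways."""
    if len(enriched) < 2:
        raise ValueError("need at least two enriched pathways")
    counts = {}
    for name, members in enriched.items():
        others = set().union(*(m for n, m in enriched.items() if n != name))
        counts[name] = len(members & others)
    return pd.Series(counts, name="shared_genes")


def gene_membership_counts(genes, enriched: dict[str, set]) -> pd.Series:
    """Per-gene number of enriched pathways containing it."""
    counts = {g: sum(1 for members in enriched.values() if g in members) for g in genes}
    return pd.Series(counts, name="n_pathways")


def regulator_significance(deg_set, db: PathwayDB) -> pd.DataFrame:
    """Fisher-overlap surrogate for upstream-regulator significance.

    Returns one row per regulator ranked by right-tailed Fisher p of the
    overlap between its target set and the differentially expressed genes.
    Raises when no regulator sets are loaded (the caller reports the
    corresponding approach as unavailable).
    """
    if not db.regulators:
        raise ValueError("no regulator annotations loaded")
    rows = [
        {
            "regulator": name,
            "n_targets": len(targets),
            "n_overlap": len(set(deg_set) & targets),
            "p": fisher_enrichment(deg_set, targets, db.universe),
        }
        for name, targets in db.regulators.items()
    ]
    return pd.DataFrame(rows).sort_values(["p", "regulator"]).reset_index(drop=True)
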