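"""Per-gene benchmark-dose workflow.

For each screened gene the five continuous models (linear, quadratic, cubic,
power, Hill) are fit and a best model is chosen by a three-step cascade:

1. nested chi-square (alpha 0.05) to pick among linear/polynomial models;
2. lowest AIC among {chosen polynomial, Hill, Power}, ties to fewer
   parameters;
3. goodness-of-fit p > 0.1 for the selected model.

A Hill fit whose half-max parameter k falls below one third of the lowest
positive dose is flagged as unsupported at low dose; the next-best unflagged
model with GOF p > 0.05 replaces it, and when none qualifies the gene's BMD
is set to half the lowest BMD among the study's unflagged Hill fits.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import curvefit
from .curvefit import FitResult

GENE_MODEL_SUITE = ("linear", "poly2", "poly3", "power", "hill")

EXCLUDE_NONE = "none"
EXCLUDE_BMD_HIGH = "bmd_above_max_dose"
EXCLUDE_GOF = "gof_below_0.1"
EXCLUDE_PROMISCUOUS = "promiscuous_probe"
EXCLUDE_NO_MODEL = "no_viable_model"


@dataclass
class GeneBMDRecord:
    gene: str
    family: str | None = None
    bmd: float | None = None
    bmdl: float | None = None
    gof_p: float | None = None
    aic: float | None = None
    hill_k: float | None = None
    hill_flagged: bool = False
    fallback_halved: bool = False
    needs_fallback: bool = False
    excluded_reason: str = EXCLUDE_NONE


def fit_gene_models(doses, responses, *, max_iter: int = 250, seed: int = 0):
    """All five continuous fits for one gene, keyed by family."""
    fits = {}
    for fam in GENE_MODEL_SUITE:
        try:
            fits[fam] = curvefit.fit(doses, responses, fam, max_iter=max_iter, seed=seed)
        except ValueError:
            continue
    return fits


def select_model(fits: dict[str, FitResult]) -> FitResult | None:
    """Steps 1-2 of the cascade: nested LR among polynomials, then AIC."""
    try:
        poly_choice = curvefit.nested_lr_select(fits["linear"], fits["poly2"], fits["poly3"])
    except KeyError:
        poly_choice = fits.get("linear")
    candidates = [f for f in (poly_choice, fits.get("hill"), fits.get("power"))
                  if f is not None and f.converged]
    if not candidates:
        return None
    return min(candidates, key=lambda f: (f.aic, f.n_params))


def fit_gene(
    gene: str,
    doses,
    responses,
    *,
    bmr: float = 1.349,
    compute_bmdl: bool = True,
    max_iter: int = 250,
    seed: int = 0,
    hill_flag_fraction: float = 1.0 / 3.0,
) -> tuple[GeneBMDRecord, dict[str, FitResult]]:
    """Run the full selection cascade for one gene.

    Returns the record plus the candidate fits (needed by the dataset-level
    Hill-flag fallback).  Never raises on an unfittable gene.
    """
    doses_arr = np.asarray(doses, float)
    lowest_pos = float(doses_arr[doses_arr > 0].min())
    try:
        fits = fit_gene_models(doses, responses, max_iter=max_iter, seed=seed)
    except Exception:
        return GeneBMDRecord(gene=gene, excluded_reason=EXCLUDE_NO_MODEL), {}
    chosen = select_model(fits)
    if chosen is None:
        return GeneBMDRecord(gene=gene, excluded_reason=EXCLUDE_NO_MODEL), fits

    record = GeneBMDRecord(gene=gene, family=chosen.family, aic=chosen.aic)
    record.gof_p = curvefit.goodness_of_fit(chosen)
    if chosen.family == "hill":
        record.hill_k = chosen.spec["k"]

    if chosen.family == "hill" and chosen.spec["k"] < hill_flag_fraction * lowest_pos:
        record = apply_hill_flag(record, fits, lowest_pos,
                                 hill_flag_fraction=hill_flag_fraction)
        if record.needs_fallback or record.excluded_reason != EXCLUDE_NONE:
            return record, fits
        chosen = fits[record.family]
    else:
        # never-flagged records face the stricter GOF p > 0.1 gate
        if record.gof_p is not None and not np.isnan(record.gof_p) and record.gof_p <= 0.1:
            record.excluded_reason = EXCLUDE_GOF
            return record, fits

    bmd = curvefit.bmd_from_fit(chosen, bmr)
    if bmd is None:
        record.excluded_reason = EXCLUDE_NO_MODEL
        return record, fits
    record.bmd = float(bmd)
    if compute_bmdl:
        bmdl = curvefit.bmdl_profile(chosen, bmr)
        record.bmdl = None if bmdl is None else float(bmdl)
    return record, fits


def apply_hill_flag(
    record: GeneBMDRecord,
    fits: dict[str, FitResult],
    lowest_positive_dose: float,
    *,
    hill_flag_fraction: float = 1.0 / 3.0,
    alt_gof_threshold: float = 0.05,
) -> GeneBMDRecord:
    """Handle a flagged Hill selection (k below a third of the lowest dose).

    Substitutes the next-best (by AIC) unflagged model with GOF p > 0.05; if
    none qualifies the record is marked ``needs_fallback`` for the
    dataset-level halving rule.
    """
    record = replace(record, hill_flagged=True)
    alternatives = sorted(
        (
            f
            for fam, f in fits.items()
            if fam != "hill" and f.converged
        ),
        key=lambda f: (f.aic, f.n_params),
    )
    for alt in alternatives:
        gof = curvefit.goodness_of_fit(alt)
        if gof is not None and not np.isnan(gof) and gof > alt_gof_threshold:
            record.family = alt.family
            record.aic = alt.aic
            record.gof_p = gof
            record.hill_k = None
            return record
    record.needs_fallback = True
    return record


def resolve_fallbacks(records: list[GeneBMDRecord], *, factor: float = 0.5) -> None:
    """Dataset-level 0.5x fallback for flagged Hill genes with no alternative.

    The lowest BMD among unflagged Hill selections in the study is halved and
    assigned (BMDL scaled by the same factor).  Genes needing the fallback
    when no unflagged Hill BMD exists become ``no_viable_model``.
    """
    donor_bmds = [
        (r.bmd, r.bmdl)
        for r in records
        if r.family == "hill" and not r.hill_flagged and r.bmd is not None
    ]
    donor = min(donor_bmds, key=lambda t: t[0]) if donor_bmds else None
    for r in records:
        if not r.needs_fallback:
            continue
        if donor is None:
            r.excluded_reason = EXCLUDE_NO_MODEL
            r.needs_fallback = False
            continue
        r.family = "hill"
        r.bmd = donor[0] * factor
        r.bmdl = None if donor[1] is None else donor[1] * factor
        r.fallback_halved = True
        r.needs_fallback = False


def fit_gene_table(
    expression: pd.DataFrame,
    doses,
    genes=None,
    *,
    bmr: float = 1.349,
    compute_bmdl: bool = True,
    max_iter: int = 250,
    seed: int = 0,
) -> pd.DataFrame:
    """Fit the model suite for every gene in ``genes`` (default: all rows)."""
    if genes is None:
        genes = list(expression.index)
    records = []
    for i, g in enumerate(genes):
        rec, _ = fit_gene(
            g,
            doses,
            expression.loc[g].to_numpy(),
            bmr=bmr,
            compute_bmdl=compute_bmdl,
            max_iter=max_iter,
            seed=seed + i,
        )
        records.append(rec)
    resolve_fallbacks(records)
    return records_to_frame(records)


def records_to_frame(records: list[GeneBMDRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene": [r.gene for r in records],
            "family": [r.family for r in records],
            "bmd": [np.nan if r.bmd is None else r.bmd for r in records],
            "bmdl": [np.nan if r.bmdl is None else r.bmdl for r in records],
            "gof_p": [np.nan if r.gof_p is None else r.gof_p for r in records],
            "hill_flagged": [r.hill_flagged for r in records],
            "fallback_halved": [r.fallback_halved for r in records],
            "excluded_reason": [r.excluded_reason for r in records],
        }
    )


def postfilter_gene_table(
    table: pd.DataFrame,
    max_dose: float,
    probe_annotation: dict[str, list[str]] | None = None,
    *,
    collapse: str = "mean",
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Remove promiscuous probes, BMDs above the top dose, and poor fits.

    The GOF p < 0.1 removal applies to never-flagged records only (flagged
    records already passed their own p > 0.05 gate).  Surviving probes are
    collapsed to unique genes by ``collapse`` ('mean' or 'lowest') over BMD
    and BMDL.  Returns the collapsed table and per-reason removal counts.
    """
    df = table.copy()
    counts = {EXCLUDE_PROMISCUOUS: 0, EXCLUDE_BMD_HIGH: 0, EXCLUDE_GOF: 0,
              EXCLUDE_NO_MODEL: 0}

    pre_excluded = df["excluded_reason"] != EXCLUDE_NONE
    for reason in counts:
        counts[reason] += int((df.loc[pre_excluded, "excluded_reason"] == reason).sum())
    df = df[~pre_excluded].copy()

    no_bmd = df["bmd"].isna()
    counts[EXCLUDE_NO_MODEL] += int(no_bmd.sum())
    df = df[~no_bmd]

    if probe_annotation is not None:
        promiscuous = df["gene"].map(
            lambda p: len(probe_annotation.get(p, [p])) > 1
        )
        counts[EXCLUDE_PROMISCUOUS] += int(promiscuous.sum())
        df = df[~promiscuous].copy()
        df["gene"] = df["gene"].map(lambda p: probe_annotation.get(p, [p])[0])

    too_high = df["bmd"] > max_dose
    counts[EXCLUDE_BMD_HIGH] += int(too_high.sum())
    df = df[~too_high]

    bad_gof = (~df["hill_flagged"]) & df["gof_p"].notna() & (df["gof_p"] < 0.1)
    counts[EXCLUDE_GOF] += int(bad_gof.sum())
    df = df[~bad_gof]

    if collapse == "mean":
        agg = df.groupby("gene", as_index=False).agg(
            bmd=("bmd", "mean"), bmdl=("bmdl", "mean"), gof_p=("gof_p", "mean"),
            family=("family", "first"),
        )
    elif collapse == "lowest":
        agg = df.sort_values("bmd").groupby("gene", as_index=False).first()
    else:
        raise ValueError(f"unknown collapse statistic: {collapse!r}")
    return agg.reset_index(drop=True), counts
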