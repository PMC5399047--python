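"""Apical (whole-animal) endpoint benchmark-dose workflow.

Organ-weight-style endpoints arrive as per-group mean/SD/n summaries and are
fit as continuous data (Exponential 4, Exponential 5, Hill, Power,
Polynomial, Linear); histopathology incidence arrives as affected/n counts
and is fit as dichotomous data (Gamma, Dichotomous-Hill, Logistic,
LogLogistic, Probit, LogProbit, Weibull, Multistage).

A fit is *viable* when it converged, its goodness-of-fit p >= 0.1, a BMDL is
computable, its BMD does not exceed the highest dose, and BMD/BMDL < 20.
Among viable fits the recommendation is the lowest-AIC model when the BMDL
range is within 3-fold, otherwise the lowest BMDL.  When no model is viable
the highest dose group is dropped and the suite re-run; once only three dose
groups (including control) remain the endpoint is reported as having failed
BMD modeling.  A BMD above the current highest dose is never recommended.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import curvefit
from .curvefit import FitResult

CONTINUOUS_SUITE = ("exp4", "exp5", "hill", "power", "poly2", "linear")
DICHOTOMOUS_SUITE = (
    "gamma",
    "dhill",
    "logistic",
    "loglogistic",
    "probit",
    "logprobit",
    "weibull",
    "multistage",
)

DEFAULT_CONTINUOUS_BMR = 1.0  # SD units for apical organ weights
DEFAULT_DICHOTOMOUS_BMR = 0.10  # extra risk


@dataclass
class ApicalEndpoint:
    chemical: str
    endpoint: str
    kind: str  # 'continuous' | 'dichotomous'
    doses: np.ndarray
    # continuous summaries
    means: np.ndarray | None = None
    sds: np.ndarray | None = None
    n: np.ndarray | None = None
    # dichotomous incidence
    affected: np.ndarray | None = None
    dose_units: str = "mkd"

    def __post_init__(self) -> None:
        self.doses = np.asarray(self.doses, float)
        if len(self.doses) < 3:
            raise ValueError("need at least 3 dose groups including control")
        for attr in ("means", "sds", "n", "affected"):
            v = getattr(self, attr)
            if v is not None:
                setattr(self, attr, np.asarray(v, float))

    def truncated(self, n_groups: int) -> "ApicalEndpoint":
        sl = slice(0, n_groups)
        return ApicalEndpoint(
            chemical=self.chemical,
            endpoint=self.endpoint,
            kind=self.kind,
            doses=self.doses[sl],
            means=None if self.means is None else self.means[sl],
            sds=None if self.sds is None else self.sds[sl],
            n=None if self.n is None else self.n[sl],
            affected=None if self.affected is None else self.affected[sl],
            dose_units=self.dose_units,
        )


@dataclass
class ApicalBmdResult:
    chemical: str
    endpoint: str
    status: str  # 'viable' | 'failed'
    family: str | None = None
    bmd: float | None = None
    bmdl: float | None = None
    doses_dropped: int = 0
    notes: list = field(default_factory=list)


def _pseudo_responses(endpoint: ApicalEndpoint, points_per_group: int = 2):
    """Expand mean/SD/n summaries into exact sufficient-statistic pseudo-data.

    For a Gaussian constant-variance likelihood the fit depends on the data
    only through group means and the pooled within-group sum of squares, so a
    two-point expansion per group (mean +/- sd*sqrt((n-1)/n)) reweighted by n
    reproduces the summary-statistic likelihood up to a constant.
    """
    doses, ys = [], []
    for d, m, s, n in zip(endpoint.doses, endpoint.means, endpoint.sds, endpoint.n):
        n = int(n)
        # n replicate slots: alternate +/- offsets summing to the right SS
        offs = np.zeros(n)
        if n > 1 and s > 0:
            half = s * np.sqrt((n - 1) / n)
            offs[: n // 2] = half
            offs[n // 2 : 2 * (n // 2)] = -half
            # odd n: rescale so sum of squares matches (n-1) s^2
            ss_target = (n - 1) * s * s
            ss = float(np.sum(offs**2))
            if ss > 0:
                offs *= np.sqrt(ss_target / ss)
        doses.extend([d] * n)
        ys.extend(m + offs)
    return np.asarray(doses), np.asarray(ys)


def fit_endpoint(
    endpoint: ApicalEndpoint, *, max_iter: int = 250, seed: int = 0
) -> dict[str, FitResult]:
    """Fit every model of the suite appropriate to the endpoint's data type."""
    fits: dict[str, FitResult] = {}
    if endpoint.kind == "continuous":
        x, y = _pseudo_responses(endpoint)
        for fam in CONTINUOUS_SUITE:
            try:
                fits[fam] = curvefit.fit(x, y, fam, max_iter=max_iter, seed=seed)
            except Exception:
                continue
    elif endpoint.kind == "dichotomous":
        for fam in DICHOTOMOUS_SUITE:
            try:
                fits[fam] = curvefit.fit_dichotomous(
                    endpoint.doses, endpoint.affected, endpoint.n, fam,
                    max_iter=max_iter, seed=seed,
                )
            except Exception:
                continue
    else:
        raise ValueError(f"unknown endpoint kind: {endpoint.kind!r}")
    return fits


def _classify(fit: FitResult, bmr: float, max_dose: float):
    """Return (viable, bmd, bmdl, note)."""
    if not fit.converged:
        return False, None, None, "non-convergence"
    n_groups = len(np.unique(fit.doses))
    k_mean = fit.n_params if fit.is_dichotomous else fit.n_params - 1
    if n_groups - k_mean < 1:
        # no residual degrees of freedom: fit adequacy cannot be assessed
        return False, None, None, "gof not testable"
    gof = curvefit.goodness_of_fit(fit)
    if gof is None or np.isnan(gof) or gof < 0.1:
        return False, None, None, "gof<0.1"
    bmd = curvefit.bmd_from_fit(fit, bmr)
    if bmd is None:
        return False, None, None, "no BMD crossing"
    if bmd > max_dose:
        return False, None, None, "BMD above highest dose"
    bmdl = curvefit.bmdl_profile(fit, bmr)
    if bmdl is None or bmdl <= 0:
        return False, None, None, "BMDL not computable"
    if bmd / bmdl >= 20:
        return False, None, None, "BMD/BMDL >= 20"
    return True, bmd, bmdl, "viable"


def recommend(
    endpoint: ApicalEndpoint,
    *,
    bmr: float | None = None,
    max_iter: int = 250,
    seed: int = 0,
) -> ApicalBmdResult:
    """BMDS-style recommendation with the highest-dose-drop retry ladder."""
    if bmr is None:
        bmr = DEFAULT_CONTINUOUS_BMR if endpoint.kind == "continuous" else DEFAULT_DICHOTOMOUS_BMR
    notes = []
    n_groups = len(endpoint.doses)
    dropped = 0
    current = endpoint
    while n_groups - dropped >= 3:
        fits = fit_endpoint(current, max_iter=max_iter, seed=seed)
        viable = []
        for fam, f in fits.items():
            ok, bmd, bmdl, note = _classify(f, bmr, float(current.doses.max()))
            notes.append(f"{fam}@drop{dropped}: {note}")
            if ok:
                viable.append((fam, f, bmd, bmdl))
        if viable:
            bmdls = [v[3] for v in viable]
            if max(bmdls) / min(bmdls) <= 3.0:
                fam, f, bmd, bmdl = min(viable, key=lambda v: (v[1].aic, v[1].n_params))
            else:
                fam, f, bmd, bmdl = min(viable, key=lambda v: v[3])
            return ApicalBmdResult(
                chemical=endpoint.chemical,
                endpoint=endpoint.endpoint,
                status="viable",
                family=fam,
                bmd=float(bmd),
                bmdl=float(bmdl),
                doses_dropped=dropped,
                notes=notes,
            )
        dropped += 1
        if n_groups - dropped < 3:
            break
        current = endpoint.truncated(n_groups - dropped)
    return ApicalBmdResult(
        chemical=endpoint.chemical,
        endpoint=endpoint.endpoint,
        status="failed",
        doses_dropped=min(dropped, n_groups - 3),
        notes=notes,
    )


def lowest_bmd_summary(results: list[ApicalBmdResult]) -> pd.DataFrame:
    """Per-chemical lowest viable BMD_a (the apical POD candidate)."""
    rows = []
    for chem in sorted({r.chemical for r in results}):
        ok = [r for r in results if r.chemical == chem and r.status == "viable"]
        if ok:
            best = min(ok, key=lambda r: r.bmd)
            rows.append(
                {
                    "chemical": chem,
                    "endpoint": best.endpoint,
                    "bmd_a": best.bmd,
                    "bmdl_a": best.bmdl,
                    "status": "viable",
                }
            )
        else:
            rows.append(
                {"chemical": chem, "endpoint": None, "bmd_a": np.nan, "bmdl_a": np.nan,
                 "status": "failed"}
            )
    return pd.DataFrame(rows)
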