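"""Bootstrap distributions for each approach's summary statistic.

Gene BMDs are resampled with replacement — within each selected pathway for
pathway-set approaches, within the selected gene set for gene-set approaches
— the pathway means are recomputed, and the approach statistic (mean across
pathways or genes; median for the median-of-pathways approach) is taken per
replicate.  The selected entity sets are held fixed across replicates.  The
bootstrap mean is the reported POD; the coefficient of variation (SD/mean)
summarizes dispersion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .approaches import ApproachPOD

PERCENTILES = (2.5, 10.0, 25.0, 50.0, 75.0, 90.0, 97.5)
DEFAULT_B = 2000


@dataclass
class BootstrapSummary:
    approach: int
    B: int
    mean: float
    sd: float
    cv: float
    percentiles: dict[float, float]
    seed: int
    point_estimate: float

    def as_dict(self) -> dict:
        d = {
            "approach": self.approach,
            "B": self.B,
            "mean": self.mean,
            "sd": self.sd,
            "cv": self.cv,
            "seed": self.seed,
            "point_estimate": self.point_estimate,
        }
        for q, v in self.percentiles.items():
            d[f"p{q:g}"] = v
        return d


def _replicate_statistic(pod: ApproachPOD, rng: np.random.Generator) -> float:
    if pod.kind == "gene":
        vals = np.asarray(pod.gene_bmds, float)
        draw = vals[rng.integers(len(vals), size=len(vals))]
        return float(np.mean(draw))
    pw_means = []
    for vals in pod.gene_bmds.values():
        vals = np.asarray(vals, float)
        draw = vals[rng.integers(len(vals), size=len(vals))]
        pw_means.append(np.mean(draw))
    agg = np.median if pod.statistic == "median" else np.mean
    return float(agg(pw_means))


def bootstrap_approach(
    pod: ApproachPOD, B: int = DEFAULT_B, seed: int = 0
) -> BootstrapSummary:
    """Bootstrap one approach's statistic; deterministic given ``seed``.

    Raises ValueError for an unavailable approach (status propagated by the
    caller).
    """
    if pod.status == "unavailable" or pod.bmd_t is None:
        raise ValueError(f"approach {pod.approach} unavailable: {pod.reason}")
    rng = np.random.default_rng(seed)
    stats_ = np.empty(B)
    for b in range(B):
        stats_[b] = _replicate_statistic(pod, rng)
    mean = float(stats_.mean())
    sd = float(stats_.std(ddof=1)) if B > 1 else 0.0
    return BootstrapSummary(
        approach=pod.approach,
        B=B,
        mean=mean,
        sd=sd,
        cv=sd / mean if mean != 0 else 0.0,
        percentiles={q: float(np.percentile(stats_, q)) for q in PERCENTILES},
        seed=seed,
        point_estimate=pod.bmd_t,
    )


def bootstrap_all(
    pods: list[ApproachPOD], B: int = DEFAULT_B, seed: int = 0
) -> dict[int, BootstrapSummary | None]:
    """Counter-based per-approach seeding so runs parallelize reproducibly."""
    out: dict[int, BootstrapSummary | None] = {}
    for pod in pods:
        sub_seed = (seed * 1000 + pod.approach) % (2**31 - 1)
        try:
            out[pod.approach] = bootstrap_approach(pod, B=B, seed=sub_seed)
        except ValueError:
            out[pod.approach] = None
    return out
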