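"""Synthetic dose-response study generator with known ground truth.

Emulates the structure of a subchronic rodent toxicogenomics study: a log2
expression matrix over six dose groups (control plus five treated) with six
replicate animals per group, gene-set (pathway) and regulator->target
annotations, and matched continuous and dichotomous apical endpoints.  Every
responsive gene carries a recorded true benchmark dose so each downstream
stage can be tested against a known answer.

Noise is i.i.d. Gaussian on the log2 scale (constant variance, matching the
SD-based benchmark-response definition); true BMDs are sampled log-uniformly
over a configured interval and the direction of response is random per gene.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .curvefit import ModelSpec, mean_function

DEFAULT_DOSES = (0.0, 2.5, 5.0, 10.0, 25.0, 75.0)  # mg/kg-day design

GENERATING_FAMILIES = ("hill", "linear", "power")


@dataclass
class SimConfig:
    """Parameters of one synthetic study.

    Defaults mirror the study design the package emulates: six dose groups
    (control at 0 then 2.5-75 mg/kg-day), six replicate animals per group,
    log2-scale expression with residual SD ``sigma``.
    """

    doses: tuple = DEFAULT_DOSES
    n_reps: int = 6
    n_genes: int = 2000
    frac_responsive: float = 0.15
    response_model: str = "mixed"  # hill | linear | power | mixed
    bmd_range: tuple = (1.0, 50.0)
    sigma: float = 0.2
    effect_size: float = 1.0  # asymptotic |log2 shift| scale for responsive genes
    max_amplitude: float = 4.0  # saturation cap on |mu(d) - mu(0)|, log2 units
    n_pathways: int = 50
    pathway_size: int = 20
    enrichment_frac: float = 0.6
    n_regulators: int = 10
    regulator_size: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        d = np.asarray(self.doses, float)
        if d[0] != 0:
            raise ValueError("first dose must be the control (0)")
        if np.any(np.diff(d) <= 0):
            raise ValueError("doses must be strictly increasing")
        if self.n_reps < 2:
            raise ValueError("n_reps must be >= 2")
        if not 0 <= self.frac_responsive <= 1:
            raise ValueError("frac_responsive must be in [0, 1]")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.response_model not in GENERATING_FAMILIES + ("mixed",):
            raise ValueError(f"unknown response_model: {self.response_model!r}")


@dataclass
class SyntheticStudy:
    expression: pd.DataFrame  # genes x samples, log2 scale
    sample_meta: pd.DataFrame  # sample, dose
    pathways: dict[str, set]
    regulators: dict[str, set]
    truth: pd.DataFrame  # gene, family, true_bmd (NaN for null genes)
    apical_continuous: pd.DataFrame | None = None
    apical_dichotomous: pd.DataFrame | None = None
    config: SimConfig | None = None

    @property
    def doses(self) -> np.ndarray:
        return self.sample_meta["dose"].to_numpy()


def simulate_gene(
    spec: ModelSpec, doses, n_reps: int, sigma: float, rng,
    max_amplitude: float | None = None,
) -> np.ndarray:
    """Draw an (n_doses, n_reps) replicate matrix as mu(d) + N(0, sigma).

    ``max_amplitude`` saturates the mean shift from control at the given
    number of log2 units (transcripts do not rise without bound); the clip
    acts far above the benchmark-response crossing, so the true BMD of the
    generating curve is unaffected.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    doses = np.asarray(doses, float)
    mu = mean_function(spec)(doses)
    if max_amplitude is not None:
        mu0 = float(mean_function(spec)(0.0))
        mu = mu0 + np.clip(mu - mu0, -max_amplitude, max_amplitude)
    out = np.repeat(mu[:, None], n_reps, axis=1)
    if sigma > 0:
        out = out + rng.normal(0.0, sigma, size=(len(doses), n_reps))
    return out


def true_bmd(spec: ModelSpec, sigma: float, bmr: float = 1.349):
    """Dose at which |mu(d) - mu(0)| = bmr * sigma; None when no crossing.

    Closed form for linear, power and Hill generating curves.
    """
    delta = bmr * sigma
    p = spec.params
    if spec.family == "linear":
        if abs(p[1]) < 1e-300:
            return None
        return delta / abs(p[1])
    if spec.family == "power":
        if abs(p[1]) < 1e-300:
            return None
        return (delta / abs(p[1])) ** (1.0 / p[2])
    if spec.family == "hill":
        if abs(p[1]) < 1e-300:
            return None
        a = delta / abs(p[1])
        if a >= 1.0:
            return None
        return p[2] * (a / (1.0 - a)) ** (1.0 / p[3])
    raise ValueError(f"no closed-form true BMD for family {spec.family!r}")


def _spec_for_target_bmd(family: str, target: float, sigma: float, bmr: float,
                         effect: float, sign: float, rng) -> ModelSpec:
    """Construct generating parameters whose true BMD equals ``target``."""
    baseline = rng.uniform(4.0, 12.0)
    delta = bmr * sigma
    if family == "linear":
        slope = sign * delta / target
        return ModelSpec("linear", [baseline, slope])
    if family == "power":
        expo = rng.uniform(1.0, 2.5)
        beta = sign * delta / target**expo
        return ModelSpec("power", [baseline, beta, expo])
    if family == "hill":
        n = rng.uniform(1.0, 4.0)
        v = sign * max(effect, delta * 1.5)
        a = delta / abs(v)
        k = target * ((1.0 - a) / a) ** (1.0 / n)
        return ModelSpec("hill", [baseline, v, k, n])
    raise ValueError(family)


def simulate_study(config: SimConfig) -> SyntheticStudy:
    """Generate a full synthetic study; deterministic given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    doses = np.asarray(config.doses, float)
    n_dose = len(doses)
    n_resp = int(round(config.n_genes * config.frac_responsive))
    if config.pathway_size > config.n_genes:
        raise ValueError("pathway_size exceeds gene count")

    genes = [f"g{i:05d}" for i in range(config.n_genes)]
    responsive = np.zeros(config.n_genes, dtype=bool)
    responsive[:n_resp] = True

    lo, hi = config.bmd_range
    expr = np.empty((config.n_genes, n_dose * config.n_reps))
    fam_col, bmd_col = [], []
    for i in range(config.n_genes):
        if responsive[i]:
            family = (
                config.response_model
                if config.response_model != "mixed"
                else GENERATING_FAMILIES[rng.integers(len(GENERATING_FAMILIES))]
            )
            target = math.exp(rng.uniform(math.log(lo), math.log(hi)))
            sign = 1.0 if rng.random() < 0.5 else -1.0
            spec = _spec_for_target_bmd(
                family, target, config.sigma, 1.349, config.effect_size, sign, rng
            )
            tb = true_bmd(spec, config.sigma)
            fam_col.append(family)
            bmd_col.append(tb)
        else:
            spec = ModelSpec("linear", [rng.uniform(4.0, 12.0), 0.0])
            fam_col.append("null")
            bmd_col.append(np.nan)
        expr[i] = simulate_gene(
            spec, doses, config.n_reps, config.sigma, rng,
            max_amplitude=config.max_amplitude,
        ).ravel()

    samples = [f"s_d{j}_r{r}" for j in range(n_dose) for r in range(config.n_reps)]
    sample_dose = np.repeat(doses, config.n_reps)
    expression = pd.DataFrame(expr, index=pd.Index(genes, name="gene"), columns=samples)
    sample_meta = pd.DataFrame({"sample": samples, "dose": sample_dose})
    truth = pd.DataFrame({"gene": genes, "family": fam_col, "true_bmd": bmd_col})

    pathways = _build_pathways(
        genes, responsive, config.n_pathways, config.pathway_size, config.enrichment_frac, rng
    )
    regulators = _build_regulators(
        genes, responsive, config.n_regulators, config.regulator_size, rng
    )

    return SyntheticStudy(
        expression=expression,
        sample_meta=sample_meta,
        pathways=pathways,
        regulators=regulators,
        truth=truth,
        config=config,
    )


def _build_pathways(genes, responsive, n_pathways, pathway_size, enrichment_frac, rng):
    """Half the pathways are 'enriched' (drawn mostly from responsive genes)."""
    genes = np.asarray(genes)
    resp_idx = np.flatnonzero(responsive)
    null_idx = np.flatnonzero(~responsive)
    pathways: dict[str, set] = {}
    n_enriched = n_pathways // 2 if len(resp_idx) else 0
    for p in range(n_pathways):
        if p < n_enriched and len(resp_idx):
            n_r = min(int(round(pathway_size * enrichment_frac)), len(resp_idx))
            n_o = pathway_size - n_r
            members = list(rng.choice(resp_idx, size=n_r, replace=False))
            if n_o and len(null_idx):
                members += list(rng.choice(null_idx, size=min(n_o, len(null_idx)), replace=False))
        else:
            pool = null_idx if len(null_idx) >= pathway_size else np.arange(len(genes))
            members = list(rng.choice(pool, size=pathway_size, replace=False))
        pathways[f"PW{p:03d}"] = set(genes[members])
    return pathways


def _build_regulators(genes, responsive, n_regulators, regulator_size, rng):
    genes = np.asarray(genes)
    resp_idx = np.flatnonzero(responsive)
    size = min(regulator_size, len(genes))
    regulators: dict[str, set] = {}
    for r in range(n_regulators):
        if len(resp_idx) and r < n_regulators // 2:
            n_r = min(size // 2, len(resp_idx))
            members = list(rng.choice(resp_idx, size=n_r, replace=False))
            rest = min(size - n_r, len(genes))
            members += list(rng.choice(len(genes), size=rest, replace=False))
        else:
            members = list(rng.choice(len(genes), size=size, replace=False))
        regulators[f"REG{r:02d}"] = set(genes[members])
    return regulators


def simulate_apical(
    kind: str,
    doses,
    n_per_group: int,
    rng,
    *,
    effect: float = 1.0,
    baseline: float = 10.0,
    sigma: float = 1.0,
    bmd: float | None = None,
    bmr: float = 1.349,
    background: float = 0.05,
    extra_risk: float = 0.10,
) -> pd.DataFrame:
    """Simulate one apical endpoint table with its generating (true) BMD.

    continuous: group mean/SD/n summaries of a Hill-shaped organ-weight-like
    response; the true BMD is the ``bmr``-SD crossing of the generating curve.
    dichotomous: binomial draws from a logistic dose-incidence curve anchored
    so that the extra risk at ``bmd`` equals ``extra_risk``.
    """
    doses = np.asarray(doses, float)
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    if kind == "continuous":
        if effect == 0.0:
            mu = np.full(len(doses), baseline)
            tb = None
        else:
            target = bmd if bmd is not None else float(np.median(doses[doses > 0]))
            spec = _spec_for_target_bmd(
                "hill", target, sigma, bmr, effect * sigma * 4, 1.0, rng
            )
            spec.params[0] = baseline
            mu = mean_function(spec)(doses)
            tb = true_bmd(spec, sigma, bmr)
        rows = []
        for d, m in zip(doses, mu):
            draws = rng.normal(m, sigma, size=n_per_group)
            rows.append({"dose": d, "n": n_per_group, "mean": draws.mean(), "sd": draws.std(ddof=1)})
        out = pd.DataFrame(rows)
        out.attrs["true_bmd"] = tb
        out.attrs["kind"] = "continuous"
        return out
    if kind == "dichotomous":
        if not 0 <= background < 1:
            raise ValueError("background rate must be in [0, 1)")
        target = bmd if bmd is not None else float(np.median(doses[doses > 0]))
        # logistic in log-dose anchored so extra risk at `target` = extra_risk
        slope = 3.0
        logit_r = (
            math.inf if extra_risk >= 1 else math.log(extra_risk / (1 - extra_risk))
        )

        def prob(d):
            d = np.asarray(d, float)
            with np.errstate(divide="ignore", invalid="ignore"):
                z = np.where(
                    d > 0,
                    logit_r + slope * (np.log(np.maximum(d, 1e-300)) - math.log(target)),
                    -np.inf,
                )
            return background + (1 - background) / (1.0 + np.exp(-z))

        p = prob(doses)
        affected = rng.binomial(n_per_group, np.clip(p, 0, 1))
        out = pd.DataFrame({"dose": doses, "n": n_per_group, "affected": affected})
        out.attrs["true_bmd"] = float(target)
        out.attrs["kind"] = "dichotomous"
        out.attrs["extra_risk"] = extra_risk
        return out
    raise ValueError(f"unknown apical kind: {kind!r}")


def simulate_concordance_suite(
    n_chemicals: int = 6,
    *,
    seed: int = 0,
    n_genes: int = 240,
    frac_responsive: float = 0.25,
    n_reps: int = 6,
    sigma: float = 0.2,
    bmd_spread: float = 0.25,
    chemical_scatter: float = 0.2,
) -> list[dict]:
    """A multi-chemical suite whose transcriptional signal sits at the apical BMD.

    Each chemical gets an apical BMD spread over ~2 orders of magnitude, a
    dose grid scaled around it, and responsive genes whose true BMDs are
    lognormally scattered (GSD ``exp(bmd_spread)``) around a transcriptional
    center that itself scatters around the apical BMD with log-SD
    ``chemical_scatter`` — the chemical-to-chemical variation real studies
    show between transcriptomic and apical potency.
    """
    rng = np.random.default_rng(seed)
    apical_bmds = np.geomspace(2.0, 300.0, n_chemicals) * np.exp(
        rng.normal(0, 0.1, n_chemicals)
    )
    suite = []
    for i, ab in enumerate(apical_bmds):
        doses = tuple(ab * np.array([0.0, 0.2, 0.5, 1.0, 2.5, 6.0]))
        center = ab * math.exp(rng.normal(0.0, chemical_scatter))
        lo = center * math.exp(-bmd_spread)
        hi = center * math.exp(bmd_spread)
        cfg = SimConfig(
            doses=doses,
            n_reps=n_reps,
            n_genes=n_genes,
            frac_responsive=frac_responsive,
            bmd_range=(lo, hi),
            sigma=sigma,
            n_pathways=16,
            pathway_size=12,
            enrichment_frac=0.85,
            n_regulators=8,
            regulator_size=18,
            seed=int(rng.integers(2**31 - 1)),
        )
        study = simulate_study(cfg)
        suite.append({"chemical": f"chem{i + 1}", "study": study, "apical_bmd": float(ab)})
    return suite
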