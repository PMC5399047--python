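"""Pre-filtering of genes for treatment response ahead of BMD modeling.

Two regimes are provided, mirroring common microarray practice:

* conservative — a shrinkage-variance ANOVA (Fs statistic with James-Stein
  shrinkage of log residual variances), permutation p values by residual
  shuffling, Benjamini-Hochberg FDR adjustment, and a least-squares-means
  fold-change cutoff (FDR p <= 0.05 and max linear |FC| >= 1.5);
* liberal — an unadjusted one-way ANOVA p <= 0.05 in at least one dose group.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

FDR_THRESHOLD = 0.05
FC_THRESHOLD = 1.5
ANOVA_THRESHOLD = 0.05


def _group_layout(groups):
    groups = np.asarray(groups)
    levels, inverse = np.unique(groups, return_inverse=True)
    counts = np.bincount(inverse)
    return levels, inverse, counts


def one_way_anova(matrix, groups):
    """Vectorized one-way ANOVA across the rows of ``matrix``.

    Returns (F, p) arrays.  Rows that are exactly constant get F=0, p=1.
    """
    X = np.atleast_2d(np.asarray(matrix, float))
    levels, inverse, counts = _group_layout(groups)
    k = len(levels)
    n = X.shape[1]
    if k < 2:
        raise ValueError("need at least two groups")
    if n - k < 1:
        raise ValueError("need at least one residual degree of freedom")
    if np.any(counts < 2) and n - k < 2:
        raise ValueError("single replicate per group leaves no residual variance")

    group_sums = np.zeros((X.shape[0], k))
    np.add.at(group_sums.T, inverse, X.T)
    group_means = group_sums / counts
    grand_mean = X.mean(axis=1, keepdims=True)
    ss_between = np.sum(counts * (group_means - grand_mean) ** 2, axis=1)
    ss_total = np.sum((X - grand_mean) ** 2, axis=1)
    ss_within = np.maximum(ss_total - ss_between, 0.0)
    df_b, df_w = k - 1, n - k
    ms_b = ss_between / df_b
    ms_w = ss_within / df_w
    with np.errstate(divide="ignore", invalid="ignore"):
        F = np.where(ms_w > 0, ms_b / ms_w, np.where(ms_b > 0, np.inf, 0.0))
    p = np.where(
        np.isfinite(F), stats.f.sf(np.where(np.isfinite(F), F, 0.0), df_b, df_w), 0.0
    )
    p = np.where(F == 0.0, 1.0, p)
    return F, p


def _residual_ms(X, inverse, counts):
    k = len(counts)
    group_sums = np.zeros((X.shape[0], k))
    np.add.at(group_sums.T, inverse, X.T)
    group_means = group_sums / counts
    fitted = group_means[:, inverse]
    resid = X - fitted
    return resid, np.sum(resid**2, axis=1) / (X.shape[1] - k), group_means


def _shrunken_variance(ms_w, df_w):
    """James-Stein positive-part shrinkage of log residual variances.

    Log variances are shrunk toward their mean; the shrinkage weight uses the
    known sampling variance of log s^2 for a chi-square variance estimate,
    trigamma(df/2).
    """
    g = len(ms_w)
    z = np.log(np.maximum(ms_w, 1e-300))
    zbar = z.mean()
    s2_z0 = float(special.polygamma(1, df_w / 2.0))
    ss = np.sum((z - zbar) ** 2)
    if ss <= 0:
        shrink = 1.0
    else:
        shrink = min(1.0, max(0.0, (g - 3) * s2_z0 / ss)) if g > 3 else 0.0
    z_tilde = zbar + (1.0 - shrink) * (z - zbar)
    return np.exp(z_tilde)


def fs_statistic(matrix, groups, n_permutations: int = 1000, rng=None):
    """Shrinkage-variance ANOVA statistic with permutation p values.

    Fs = between-group mean square / shrunken residual variance.  p values
    come from residual shuffling: within-gene residuals are permuted across
    samples (one sample permutation per replicate, applied to all genes),
    the group structure reimposed, and Fs recomputed;
    p = (1 + #{Fs* >= Fs}) / (1 + B).
    """
    X = np.atleast_2d(np.asarray(matrix, float))
    if n_permutations < 100:
        raise ValueError("need at least 100 permutations")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    levels, inverse, counts = _group_layout(groups)
    k = len(levels)
    n = X.shape[1]
    df_w = n - k

    if X.shape[0] < 2:
        warnings.warn("fewer than 2 genes: falling back to the ordinary F statistic")
        F, p = one_way_anova(X, groups)
        return F, p

    def _fs(mat):
        resid, ms_w, group_means = _residual_ms(mat, inverse, counts)
        grand = mat.mean(axis=1, keepdims=True)
        ss_b = np.sum(counts * (group_means - grand) ** 2, axis=1)
        ms_b = ss_b / (k - 1)
        return ms_b / _shrunken_variance(ms_w, df_w), resid, group_means

    fs_obs, resid, group_means = _fs(X)
    # residuals carry only (n-k)/n of the error variance; restandardize so the
    # permuted data mimic null data on the correct scale (the shrunken
    # denominator does not cancel a per-gene scale deficit the way plain F does)
    resid_std = (resid * np.sqrt((n - 1) / (n - k))).ravel()
    exceed = np.zeros(X.shape[0])
    for _ in range(n_permutations):
        # global residual shuffling: null data are drawn from the pooled
        # residual matrix, then the group structure is reimposed.  Per-gene
        # shuffling cannot reproduce the chi-square spread of the
        # between-group mean square once the denominator is shrunken, so it
        # is anti-conservative; pooling across genes restores calibration.
        perm = rng.permutation(resid_std.size)
        fs_p, _, _ = _fs(resid_std[perm].reshape(X.shape))
        exceed += fs_p >= fs_obs
    p = (1.0 + exceed) / (1.0 + n_permutations)
    return fs_obs, p


def bh_adjust(pvalues):
    """Benjamini-Hochberg step-up adjusted p values (capped at 1)."""
    p = np.asarray(pvalues, float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def ls_mean_fold_changes(matrix, groups, control=None):
    """Per-dose log2 fold changes versus control via least-squares means.

    For a one-factor design the LS mean is the unweighted group mean of log2
    values, so log2FC(dose) = mean(dose) - mean(control).  Returns a
    (genes x non-control-groups) DataFrame of log2 fold changes.
    """
    X = np.atleast_2d(np.asarray(matrix, float))
    levels, inverse, counts = _group_layout(groups)
    control = levels[0] if control is None else control
    if control not in levels:
        raise ValueError(f"control group {control!r} not present")
    group_sums = np.zeros((X.shape[0], len(levels)))
    np.add.at(group_sums.T, inverse, X.T)
    means = group_sums / counts
    ctrl_idx = int(np.where(levels == control)[0][0])
    keep = [i for i in range(len(levels)) if i != ctrl_idx]
    log2fc = means[:, keep] - means[:, [ctrl_idx]]
    return pd.DataFrame(log2fc, columns=[levels[i] for i in keep])


def screen_genes(
    expression: pd.DataFrame,
    doses,
    *,
    n_permutations: int = 1000,
    seed: int = 0,
    fdr_threshold: float = FDR_THRESHOLD,
    fc_threshold: float = FC_THRESHOLD,
    anova_threshold: float = ANOVA_THRESHOLD,
) -> pd.DataFrame:
    """Full screen table: F, Fs, permutation p, FDR p, fold changes, flags."""
    X = expression.to_numpy()
    doses = np.asarray(doses, float)
    F, p_anova = one_way_anova(X, doses)
    fs, p_perm = fs_statistic(X, doses, n_permutations=n_permutations,
                              rng=np.random.default_rng(seed))
    fdr_p = bh_adjust(p_perm)
    log2fc = ls_mean_fold_changes(X, doses)
    max_abs_l2fc = np.abs(log2fc.to_numpy()).max(axis=1)
    max_fc = 2.0 ** np.minimum(max_abs_l2fc, 50.0)  # linear FC, overflow-safe
    out = pd.DataFrame(
        {
            "gene": expression.index,
            "F": F,
            "p_anova": p_anova,
            "Fs": fs,
            "p_perm": p_perm,
            "fdr_p": fdr_p,
            "max_abs_log2fc": max_abs_l2fc,
            "max_fc": max_fc,
        }
    )
    out["pass_conservative"] = (out["fdr_p"] <= fdr_threshold) & (out["max_fc"] >= fc_threshold)
    out["pass_liberal"] = out["p_anova"] <= anova_threshold
    return out


def filter_genes(screen: pd.DataFrame, mode: str) -> set:
    """Retained gene ids under 'conservative' (FDR+FC) or 'liberal' (ANOVA p)."""
    if mode == "conservative":
        mask = screen["pass_conservative"]
    elif mode == "liberal":
        mask = screen["pass_liberal"]
    else:
        raise ValueError(f"unknown filter mode: {mode!r}")
    return set(screen.loc[mask, "gene"])
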