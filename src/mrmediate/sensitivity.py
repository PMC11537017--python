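"""Heterogeneity, pleiotropy and influence diagnostics for an MR analysis.

Implements Cochran's Q, funnel-plot coordinates, leave-one-out re-estimation
and a simulation-based residual-sum-and-outlier (MR-PRESSO style) test with
global, per-SNP outlier, and distortion components.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import EstimationError, InputError
from .estimators import MRResult, ivw, wald_ratios
from .gwas_io import HarmonizedSet

logger = logging.getLogger(__name__)


@dataclass
class QResult:
    """Cochran's heterogeneity statistic over Wald ratios."""

    q: float
    df: int
    pvalue: float


@dataclass
class LooResult:
    """Leave-one-out IVW re-estimates.

    ``rows`` has one row per left-out SNP (beta/se/p of the IVW estimate on
    the remaining instruments, plus flags for sign changes and crossings of
    the 0.05 significance boundary relative to the full estimate).
    """

    rows: pd.DataFrame
    full_beta: float
    full_se: float
    full_pvalue: float


@dataclass
class PressoResult:
    """Residual-sum-and-outlier test output."""

    global_rss_obs: float
    global_pvalue: float
    outliers: list[tuple[str, float]]
    distortion_pvalue: float | None
    beta_raw: MRResult
    beta_corrected: MRResult
    per_snp_pvalues: dict[str, float] = field(default_factory=dict)


def cochran_q(h: HarmonizedSet, beta: float) -> QResult:
    """Cochran's Q at a given causal estimate.

    ``Q = sum_j w_j (r_j - beta)^2`` over Wald ratios with inverse-variance
    weights; df = J - 1; p from the upper tail of chi-square(df).
    """
    ratios = wald_ratios(h)
    j = len(ratios)
    if j < 2:
        raise InputError(f"cochran_q requires >= 2 instruments, got {j}")
    r = ratios["ratio"].to_numpy()
    w = 1.0 / ratios["ratio_se"].to_numpy() ** 2
    q = float(np.sum(w * (r - beta) ** 2))
    df = j - 1
    return QResult(q=q, df=df, pvalue=float(sps.chi2.sf(q, df)))


def funnel_data(h: HarmonizedSet) -> pd.DataFrame:
    """Per-SNP funnel-plot coordinates: Wald ratio vs precision (1/ratio SE)."""
    ratios = wald_ratios(h)
    if ratios.empty:
        raise InputError("funnel_data requires >= 1 usable instrument")
    return pd.DataFrame(
        {
            "variant_id": ratios["variant_id"],
            "ratio": ratios["ratio"],
            "precision": 1.0 / ratios["ratio_se"],
        }
    )


def leave_one_out(
    h: HarmonizedSet, model: str = "multiplicative_random", significance: float = 0.05
) -> LooResult:
    """Re-run IVW leaving each SNP out in turn.

    Flags SNPs whose omission flips the sign of the estimate or moves its
    p-value across the ``significance`` boundary.
    """
    if len(h) < 3:
        raise InputError(f"leave_one_out requires >= 3 instruments, got {len(h)}")
    full = ivw(h, model=model)
    rows = []
    for vid in h.df["variant_id"]:
        sub = ivw(h.drop_variant(vid), model=model)
        rows.append(
            {
                "left_out": vid,
                "beta": sub.beta,
                "se": sub.se,
                "pvalue": sub.pvalue,
                "sign_change": np.sign(sub.beta) != np.sign(full.beta),
                "significance_crossing": (sub.pvalue < significance)
                != (full.pvalue < significance),
            }
        )
    return LooResult(
        rows=pd.DataFrame(rows),
        full_beta=full.beta,
        full_se=full.se,
        full_pvalue=full.pvalue,
    )


def _loo_betas(ratio: np.ndarray, weight: np.ndarray) -> np.ndarray:
    """IVW point estimates leaving each instrument out, via sum updates."""
    sw = weight.sum()
    swr = (weight * ratio).sum()
    return (swr - weight * ratio) / (sw - weight)


def mr_presso(
    h: HarmonizedSet,
    n_sim: int = 1000,
    seed: int = 20240916,
    outlier_sig: float = 0.05,
    model: str = "multiplicative_random",
) -> PressoResult:
    """Simulation-based pleiotropy residual-sum and outlier test.

    Global test: the observed weighted residual sum uses leave-one-out IVW
    expected values, ``RSS = sum_j w_j (Gamma_j - beta_{-j} gamma_j)^2`` with
    ``w_j = 1/se_Gamma_j^2``; its null distribution is simulated by drawing
    ``Gamma*_j ~ Normal(beta_{-j} gamma_j, se_Gamma_j)`` ``n_sim`` times and
    recomputing the statistic (including the leave-one-out expectations) on
    each draw. The Monte-Carlo p adds one to numerator and denominator so it
    can never be exactly zero.

    Outlier test: each SNP's own weighted squared residual is compared with
    its simulated distribution; p-values are Bonferroni-adjusted across the J
    SNPs and SNPs with adjusted p < ``outlier_sig`` are flagged.

    Distortion test: when outliers exist, the change in the IVW estimate
    after removing them is compared with the distribution of changes from
    removing equally many randomly chosen non-outlier SNPs.
    """
    df = h.df
    j = len(df)
    if j < 4:
        raise InputError(f"mr_presso requires >= 4 instruments, got {j}")
    rng = np.random.default_rng(seed)

    gamma = df["beta_exp"].to_numpy(float)
    Gamma = df["beta_out"].to_numpy(float)
    se_G = df["se_out"].to_numpy(float)
    if np.any(gamma == 0):
        raise InputError("mr_presso requires nonzero exposure betas")

    ratio = Gamma / gamma
    w_ratio = gamma**2 / se_G**2
    w_out = 1.0 / se_G**2

    beta_loo = _loo_betas(ratio, w_ratio)
    res_obs = w_out * (Gamma - beta_loo * gamma) ** 2
    rss_obs = float(res_obs.sum())

    # Simulated null: expected outcome betas under each SNP's leave-one-out fit.
    sims = rng.normal(
        loc=beta_loo[None, :] * gamma[None, :],
        scale=se_G[None, :],
        size=(n_sim, j),
    )
    ratio_sim = sims / gamma[None, :]
    sw = w_ratio.sum()
    swr_sim = ratio_sim @ w_ratio
    beta_loo_sim = (swr_sim[:, None] - w_ratio[None, :] * ratio_sim) / (
        sw - w_ratio[None, :]
    )
    res_sim = w_out[None, :] * (sims - beta_loo_sim * gamma[None, :]) ** 2
    rss_sim = res_sim.sum(axis=1)

    global_p = float((1 + np.sum(rss_sim >= rss_obs)) / (1 + n_sim))

    p_per = (1 + (res_sim >= res_obs[None, :]).sum(axis=0)) / (1 + n_sim)
    p_adj = np.minimum(p_per * j, 1.0)
    ids = df["variant_id"].tolist()
    outlier_mask = p_adj < outlier_sig
    outliers = [(vid, float(p)) for vid, p, m in zip(ids, p_adj, outlier_mask) if m]

    beta_raw = ivw(h, model=model)
    if outlier_mask.all():
        raise EstimationError("mr_presso: every instrument flagged as an outlier")
    if outliers:
        corrected = ivw(h.subset(~outlier_mask), model=model)
        n_out = int(outlier_mask.sum())
        inlier_idx = np.flatnonzero(~outlier_mask)
        d_obs = beta_raw.beta - corrected.beta
        d_sim = np.empty(n_sim)
        for s in range(n_sim):
            drop = rng.choice(inlier_idx, size=n_out, replace=False)
            keep = np.ones(j, dtype=bool)
            keep[drop] = False
            b = float(np.sum(w_ratio[keep] * ratio[keep]) / np.sum(w_ratio[keep]))
            d_sim[s] = beta_raw.beta - b
        distortion_p = float((1 + np.sum(np.abs(d_sim) >= abs(d_obs))) / (1 + n_sim))
    else:
        corrected = beta_raw
        distortion_p = None

    return PressoResult(
        global_rss_obs=rss_obs,
        global_pvalue=global_p,
        outliers=outliers,
        distortion_pvalue=distortion_p,
        beta_raw=beta_raw,
        beta_corrected=corrected,
        per_snp_pvalues={vid: float(p) for vid, p in zip(ids, p_adj)},
    )


def egger_intercept_test(h: HarmonizedSet) -> tuple[float, float, float]:
    """Convenience view of the MR-Egger intercept pleiotropy test.

    Returns (intercept, se, pvalue) from the Egger regression.
    """
    from .estimators import egger

    res = egger(h)
    return (
        res.extras["egger_intercept"],
        res.extras["egger_intercept_se"],
        res.extras["egger_intercept_pvalue"],
    )
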