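"""Causal-effect estimators for two-sample MR, plus statistical power.

All estimators consume a :class:`~mrmediate.gwas_io.HarmonizedSet` and return
an :class:`MRResult` whose ``beta`` is the causal log-odds (or per-SD) effect
of one exposure unit; odds-ratio views are ``exp`` transforms with normal
95% intervals on the log scale.

The per-SNP building block is the Wald ratio Gamma_j / gamma_j with
first-order standard error se(Gamma_j) / |gamma_j|; IVW, the weighted median
and the heterogeneity statistics all operate on these ratios. MR-Egger
regresses outcome betas on exposure betas directly.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps

from .errors import EstimationError, InputError
from .gwas_io import HarmonizedSet

logger = logging.getLogger(__name__)

Z95 = sps.norm.ppf(0.975)


@dataclass
class MRResult:
    """One estimator's causal estimate.

    ``extras`` carries method-specific quantities (Egger intercept and its
    test, bootstrap settings, optimizer diagnostics).
    """

    method: str
    beta: float
    se: float
    pvalue: float
    n_snps: int
    extras: dict = field(default_factory=dict)

    @property
    def or_point(self) -> float:
        return math.exp(self.beta)

    @property
    def or_low(self) -> float:
        return math.exp(self.beta - Z95 * self.se)

    @property
    def or_high(self) -> float:
        return math.exp(self.beta + Z95 * self.se)

    @property
    def ci_low(self) -> float:
        return self.beta - Z95 * self.se

    @property
    def ci_high(self) -> float:
        return self.beta + Z95 * self.se

    def as_row(self) -> dict:
        row = {
            "method": self.method,
            "beta": self.beta,
            "se": self.se,
            "pvalue": self.pvalue,
            "or": self.or_point,
            "or_low": self.or_low,
            "or_high": self.or_high,
            "n_snps": self.n_snps,
        }
        row["extras"] = ";".join(f"{k}={v}" for k, v in self.extras.items())
        return row


def wald_ratios(h: HarmonizedSet) -> pd.DataFrame:
    """Per-SNP Wald ratios and first-order delta standard errors.

    Rows with a zero exposure beta are excluded with a logged reason (the
    ratio is undefined there).
    """
    df = h.df
    nonzero = df["beta_exp"].to_numpy(float) != 0.0
    n_excluded = int((~nonzero).sum())
    if n_excluded:
        logger.info("wald_ratios: excluded %d rows with zero exposure beta", n_excluded)
    sub = df.loc[nonzero]
    gamma = sub["beta_exp"].to_numpy(float)
    return pd.DataFrame(
        {
            "variant_id": sub["variant_id"].to_numpy(),
            "ratio": sub["beta_out"].to_numpy(float) / gamma,
            "ratio_se": sub["se_out"].to_numpy(float) / np.abs(gamma),
        }
    )


def _two_sided_normal_p(z: float) -> float:
    return float(2.0 * sps.norm.sf(abs(z)))


def ivw(h: HarmonizedSet, model: str = "multiplicative_random") -> MRResult:
    """Inverse-variance-weighted estimate over Wald ratios.

    ``fixed``: se = (sum of weights)^-1/2. ``multiplicative_random``
    (default, matching common two-sample MR practice): the fixed-effect se is
    scaled by sqrt(max(Q/(J-1), 1)) with Q Cochran's heterogeneity statistic
    at the estimate; with a single SNP the result reduces to that SNP's Wald
    ratio and no scaling is applied.
    """
    if model not in ("fixed", "multiplicative_random"):
        raise InputError(f"unknown IVW model {model!r}")
    ratios = wald_ratios(h)
    if ratios.empty:
        raise InputError("ivw: no usable instruments")
    r = ratios["ratio"].to_numpy()
    w = 1.0 / ratios["ratio_se"].to_numpy() ** 2
    beta = float(np.sum(w * r) / np.sum(w))
    se = float(1.0 / math.sqrt(np.sum(w)))
    j = len(r)
    extras = {"model": model}
    if model == "multiplicative_random" and j > 1:
        q = float(np.sum(w * (r - beta) ** 2))
        scale = math.sqrt(max(q / (j - 1), 1.0))
        se *= scale
        extras["overdispersion"] = scale
    method = "ivw_fixed" if model == "fixed" else "ivw_mre"
    if j == 1:
        method = "wald"
    return MRResult(
        method=method,
        beta=beta,
        se=se,
        pvalue=_two_sided_normal_p(beta / se),
        n_snps=j,
        extras=extras,
    )


def egger(h: HarmonizedSet) -> MRResult:
    """MR-Egger regression: weighted regression of outcome on exposure betas
    with a free intercept.

    Rows are oriented so every exposure beta is non-negative (the convention
    that makes the intercept interpretable as average directional
    pleiotropy). Weights are 1/se_out^2; coefficient standard errors use the
    regression residual variance inflated to at least 1 (multiplicative
    random-effects model); p-values use the t distribution with J - 2 degrees
    of freedom. The intercept estimate, its SE and p-value are reported in
    ``extras`` as the pleiotropy test.
    """
    df = h.df
    if len(df) < 3:
        raise InputError(f"egger requires >= 3 instruments, got {len(df)}")
    gamma = df["beta_exp"].to_numpy(float).copy()
    Gamma = df["beta_out"].to_numpy(float).copy()
    flip = gamma < 0
    gamma[flip] *= -1
    Gamma[flip] *= -1
    w = 1.0 / df["se_out"].to_numpy(float) ** 2

    X = np.column_stack([np.ones_like(gamma), gamma])
    XtW = X.T * w
    xtwx = XtW @ X
    try:
        cov_unscaled = np.linalg.inv(xtwx)
    except np.linalg.LinAlgError as exc:
        raise EstimationError("egger design matrix is singular") from exc
    coef = cov_unscaled @ (XtW @ Gamma)
    resid = Gamma - X @ coef
    j = len(gamma)
    sigma2 = float(np.sum(w * resid**2) / (j - 2))
    sigma2 = max(sigma2, 1.0)
    cov = cov_unscaled * sigma2
    se_int, se_slope = math.sqrt(cov[0, 0]), math.sqrt(cov[1, 1])
    tdist = sps.t(df=j - 2)
    p_slope = float(2 * tdist.sf(abs(coef[1] / se_slope)))
    p_int = float(2 * tdist.sf(abs(coef[0] / se_int)))
    return MRResult(
        method="egger",
        beta=float(coef[1]),
        se=se_slope,
        pvalue=p_slope,
        n_snps=j,
        extras={
            "egger_intercept": float(coef[0]),
            "egger_intercept_se": se_int,
            "egger_intercept_pvalue": p_int,
            "residual_sd": math.sqrt(sigma2),
        },
    )


def _weighted_median_estimate(ratio: np.ndarray, weight: np.ndarray) -> float:
    """Interpolated weighted median of ``ratio`` under ``weight``."""
    order = np.argsort(ratio, kind="mergesort")
    r = ratio[order]
    wn = weight[order] / weight.sum()
    s = np.cumsum(wn) - wn / 2.0
    if s[0] >= 0.5:
        return float(r[0])
    if s[-1] <= 0.5:
        return float(r[-1])
    k = int(np.searchsorted(s, 0.5))
    return float(r[k - 1] + (r[k] - r[k - 1]) * (0.5 - s[k - 1]) / (s[k] - s[k - 1]))


def weighted_median(
    h: HarmonizedSet, n_boot: int = 1000, seed: int = 20240916
) -> MRResult:
    """Weighted-median estimator with parametric-bootstrap standard error.

    Consistent when instruments carrying at least half the total weight are
    valid. The estimate interpolates the inverse-variance-weighted empirical
    quantile function of the Wald ratios at 0.5; the SE is the standard
    deviation of the estimate over ``n_boot`` parametric resamples of the
    per-SNP betas from normal distributions with their reported SEs.
    """
    df = h.df
    if len(df) < 3:
        raise InputError(f"weighted_median requires >= 3 instruments, got {len(df)}")
    gamma = df["beta_exp"].to_numpy(float)
    Gamma = df["beta_out"].to_numpy(float)
    se_g = df["se_exp"].to_numpy(float)
    se_G = df["se_out"].to_numpy(float)
    if np.any(gamma == 0):
        keep = gamma != 0
        gamma, Gamma, se_g, se_G = gamma[keep], Gamma[keep], se_g[keep], se_G[keep]
        if keep.sum() < 3:
            raise InputError("weighted_median: < 3 instruments with nonzero exposure beta")

    ratio = Gamma / gamma
    weight = gamma**2 / se_G**2  # 1 / ratio_se^2
    beta = _weighted_median_estimate(ratio, weight)

    rng = np.random.default_rng(seed)
    j = len(ratio)
    boot = np.empty(n_boot)
    for b in range(n_boot):
        g_b = rng.normal(gamma, se_g)
        G_b = rng.normal(Gamma, se_G)
        nz = g_b != 0
        if nz.sum() < 2:  # pragma: no cover - vanishing probability
            boot[b] = beta
            continue
        boot[b] = _weighted_median_estimate(
            G_b[nz] / g_b[nz], g_b[nz] ** 2 / se_G[nz] ** 2
        )
    se = float(boot.std(ddof=1))
    if se == 0.0:
        se = float(np.finfo(float).tiny ** 0.5)
    return MRResult(
        method="weighted_median",
        beta=beta,
        se=se,
        pvalue=_two_sided_normal_p(beta / se),
        n_snps=j,
        extras={"n_boot": n_boot, "seed": seed},
    )


_HUBER_C = 1.345


def _rho(t: np.ndarray, loss: str) -> np.ndarray:
    if loss == "l2":
        return t**2
    a = np.abs(t)
    return np.where(a <= _HUBER_C, t**2, 2 * _HUBER_C * a - _HUBER_C**2)


def raps(h: HarmonizedSet, loss: str = "l2", bracket: float = 10.0) -> MRResult:
    """Profile-score estimator robust to measurement error in exposure betas.

    Maximizes the profile log-likelihood -1/2 sum_j rho(t_j(beta)) with
    standardized residuals t_j(beta) = (Gamma_j - beta gamma_j) /
    sqrt(se_Gamma_j^2 + beta^2 se_gamma_j^2) and rho the squared (``l2``) or
    Huber (tuning constant 1.345) loss. This is the simple profile-score
    variant without an overdispersion parameter. The SE comes from the
    numerically differentiated observed information.
    """
    if loss not in ("l2", "huber"):
        raise InputError(f"unknown raps loss {loss!r}")
    df = h.df
    if len(df) < 3:
        raise InputError(f"raps requires >= 3 instruments, got {len(df)}")
    gamma = df["beta_exp"].to_numpy(float)
    Gamma = df["beta_out"].to_numpy(float)
    var_g = df["se_exp"].to_numpy(float) ** 2
    var_G = df["se_out"].to_numpy(float) ** 2

    def negloglik(beta: float) -> float:
        t = (Gamma - beta * gamma) / np.sqrt(var_G + beta**2 * var_g)
        return 0.5 * float(np.sum(_rho(t, loss)))

    res = optimize.minimize_scalar(
        negloglik, bounds=(-bracket, bracket), method="bounded",
        options={"xatol": 1e-10},
    )
    beta = float(res.x)
    if bracket - abs(beta) < 1e-3:
        raise EstimationError(
            f"raps estimate {beta:.3f} at the bracket boundary (+-{bracket}); "
            "widen the bracket"
        )
    # Observed information by central second difference.
    step = 1e-4 * max(1.0, abs(beta))
    info = (negloglik(beta + step) - 2 * negloglik(beta) + negloglik(beta - step)) / step**2
    if info <= 0:
        raise EstimationError("raps: non-positive observed information")
    se = float(1.0 / math.sqrt(info))
    return MRResult(
        method="raps",
        beta=beta,
        se=se,
        pvalue=_two_sided_normal_p(beta / se),
        n_snps=len(gamma),
        extras={"loss": loss, "objective": float(res.fun)},
    )


def mr_power(
    n_outcome: int,
    case_fraction: float,
    r2_xz: float,
    beta: float,
    alpha: float = 0.05,
) -> float:
    """Statistical power of an MR test for a binary outcome.

    Non-centrality approach of the mRnd calculator:
    ``NCP = n r2 beta^2 cf (1 - cf)`` and
    ``power = Phi(-z + sqrt(NCP)) + Phi(-z - sqrt(NCP))`` with
    ``z = z_{1-alpha/2}``. ``beta`` is the true causal log-odds effect per SD
    of exposure; ``r2_xz`` the variance in exposure explained by the
    instruments.
    """
    if not 0 < case_fraction < 1:
        raise InputError(f"case_fraction must be in (0,1), got {case_fraction}")
    if not 0 < r2_xz < 1:
        raise InputError(f"r2_xz must be in (0,1), got {r2_xz}")
    if not 0 < alpha < 1:
        raise InputError(f"alpha must be in (0,1), got {alpha}")
    if n_outcome <= 0:
        raise InputError(f"n_outcome must be positive, got {n_outcome}")
    ncp = n_outcome * r2_xz * beta**2 * case_fraction * (1.0 - case_fraction)
    z = sps.norm.ppf(1.0 - alpha / 2.0)
    root = math.sqrt(ncp)
    return float(sps.norm.cdf(-z + root) + sps.norm.cdf(-z - root))


def results_to_tsv(results: list[MRResult], path, exposure: str = "", outcome: str = "") -> None:
    """Serialize a list of MRResults to TSV, one row per method."""
    rows = []
    for r in results:
        row = {"exposure": exposure, "outcome": outcome}
        row.update(r.as_row())
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
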