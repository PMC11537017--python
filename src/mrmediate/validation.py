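"""Calibration and recovery experiments for the full analysis pipeline.

Each function runs a self-contained Monte-Carlo experiment against the
synthetic generator and returns the measured operating characteristic:
type-I error of the IVW test under the null, the null distribution of
Cochran's Q, coverage of the delta-method mediated-proportion interval,
recovery of a known mediated proportion by the full pipeline, the
IVW-versus-Egger bias ordering under directional pleiotropy, and detection
of an injected pleiotropic outlier.

These experiments are what the package's statistical guarantees rest on;
they are exercised by the test suite and by the acceptance script.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .estimators import ivw
from .gwas_io import HarmonizedSet, harmonize
from .mediation import EffectEstimate, mediate
from .sensitivity import cochran_q, mr_presso
from .instruments import filter_weak_instruments, select_by_pvalue
from .synthetic import SimulationConfig, _quick_mr, recovery_suite, simulate_triplet

#: Null system: no causal effects anywhere, independent SNPs.
NULL_CONFIG = SimulationConfig(beta_total=0.0, beta_xm=0.0, beta_my=0.0)

#: Strong-instrument recovery conditions: the default true effects (mediated
#: proportion ~0.148) estimated from three well-powered studies.
STRONG_RECOVERY_CONFIG = SimulationConfig(
    n_exposure=20_000, n_mediator=20_000, n_outcome=20_000
)

#: Directional-pleiotropy conditions: exposure SNPs carry a mean direct
#: outcome effect of 0.01 in the exposure-increasing orientation, the
#: setting where IVW is biased and the Egger intercept absorbs the offset.
DIRECTIONAL_CONFIG = replace(
    STRONG_RECOVERY_CONFIG, pleiotropy="directional", pleiotropy_magnitude=0.01
)


def ivw_type1_error(n_reps: int = 500, seed: int = 0, alpha: float = 0.05) -> float:
    """Empirical size of the fixed-effect IVW z-test under the global null.

    Instruments are selected on the exposure side only (p-value screen and
    weak-instrument filter); no outcome-dependent filtering is applied, so
    the z-statistic's nominal null distribution is the reference. The
    multiplicative random-effects flavor and the Steiger filter both only
    add conservatism on top of this.
    """
    rejections = usable = 0
    for rep in range(n_reps):
        cfg = replace(NULL_CONFIG, seed=seed + rep)
        exp_s, _, out_s, _, _ = simulate_triplet(cfg)
        res = _quick_mr(
            exp_s, out_s, None, 1e-5, 10.0, "fixed", ("ivw",), steiger=False
        )
        if res is None:
            continue
        usable += 1
        rejections += res["ivw"].pvalue < alpha
    if usable == 0:
        return float("nan")
    return rejections / usable


def cochran_q_null_sample(
    n_reps: int = 1000, j: int = 10, seed: int = 0
) -> np.ndarray:
    """Draws of Cochran's Q at the fixed-effect IVW estimate under
    homogeneity with exactly known exposure effects (Q is then chi-square
    with J - 1 degrees of freedom)."""
    rng = np.random.default_rng(seed)
    qs = np.empty(n_reps)
    for r in range(n_reps):
        gamma = rng.uniform(0.05, 0.3, j)
        se_g = np.full(j, 1e-12)
        se_G = rng.uniform(0.01, 0.05, j)
        Gamma = 0.2 * gamma + rng.normal(0, se_G)
        df = pd.DataFrame(
            {
                "variant_id": [f"rs{i}" for i in range(j)],
                "chromosome": "1",
                "position": np.arange(1, j + 1),
                "beta_exp": gamma,
                "se_exp": se_g,
                "beta_out": Gamma,
                "se_out": se_G,
                "eaf": 0.3,
                "n_exp": 10_000,
                "n_out": 10_000,
            }
        )
        h = HarmonizedSet("x", "y", df)
        qs[r] = cochran_q(h, ivw(h, "fixed").beta).q
    return qs


def mediation_ci_coverage(n_reps: int = 2000, seed: int = 0) -> float:
    """Coverage of the default delta-method proportion interval on synthetic
    effect triples drawn around the generator's default true effects, with
    estimation noise typical of well-powered constituent MR fits."""
    rng = np.random.default_rng(seed)
    cfg = SimulationConfig()
    b1, se1 = cfg.beta_xm, 0.010
    b2, se2 = cfg.beta_my, 0.015
    tot, se_t = cfg.beta_total, 0.004
    truth = b1 * b2 / tot
    covered = 0
    for _ in range(n_reps):
        res = mediate(
            EffectEstimate(rng.normal(tot, se_t), se_t),
            EffectEstimate(rng.normal(b1, se1), se1),
            EffectEstimate(rng.normal(b2, se2), se2),
        )
        lo, hi = res.proportion_ci
        covered += lo <= truth <= hi
    return covered / n_reps


def proportion_recovery(n_reps: int = 500, seed: int = 0) -> pd.DataFrame:
    """Full-pipeline recovery of the true mediated proportion (~0.148) under
    strong instruments; returns the recovery_suite summary table."""
    cfg = replace(STRONG_RECOVERY_CONFIG, seed=seed)
    return recovery_suite(cfg, n_reps=n_reps)


def directional_pleiotropy_bias(n_reps: int = 100, seed: int = 0) -> dict:
    """Mean absolute bias of IVW and Egger under directional pleiotropy."""
    cfg = replace(DIRECTIONAL_CONFIG, seed=seed)
    tab = recovery_suite(cfg, n_reps=n_reps, methods=("ivw", "egger"))
    out = {}
    for m in ("ivw", "egger"):
        row = tab[tab["method"] == m]
        out[m] = float(abs(row["mean_bias"].iloc[0])) if len(row) else float("nan")
    return out


def injected_outlier_harmonized(seed: int = 0, displacement_se: float = 10.0):
    """A clean harmonized instance with one outcome beta displaced by
    ``displacement_se`` standard errors; returns (harmonized, outlier_id)."""
    cfg = SimulationConfig(
        n_snps=40, n_snps_mediator=0, n_snps_outcome=0,
        n_exposure=20_000, n_outcome=20_000, seed=seed,
    )
    exp_s, _, out_s, _, _ = simulate_triplet(cfg)
    sel = select_by_pvalue(exp_s, 1e-5)
    iv = filter_weak_instruments(sel)
    sel = iv.subset(sel)
    h = harmonize(sel, out_s)
    idx = len(h) // 2
    h.df.loc[idx, "beta_out"] += displacement_se * h.df.loc[idx, "se_out"]
    return h, h.df.loc[idx, "variant_id"]


def presso_detects_injected_outlier(seed: int = 0, n_sim: int = 1000) -> dict:
    """Run the residual-sum outlier test on the injected-outlier instance."""
    h, outlier_id = injected_outlier_harmonized(seed)
    res = mr_presso(h, n_sim=n_sim, seed=seed + 1)
    flagged = [v for v, _ in res.outliers]
    return {
        "outlier_id": outlier_id,
        "detected": outlier_id in flagged,
        "global_pvalue": res.global_pvalue,
        "n_flagged": len(flagged),
    }
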