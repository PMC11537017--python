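"""Workflow orchestration: forward/reverse MR, sensitivity battery, mediation.

`run_mr` chains instrument selection, harmonization, the estimator suite and
the diagnostics into a single report; `run_bidirectional` runs both causal
directions and flags forward-only relationships; `run_mediation_workflow`
performs two-step mediation with each constituent MR report attached.

Reports embed the effective configuration and all seeds so a run can be
reproduced byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import estimators as est
from . import sensitivity as sens
from .errors import InputError, MRMediateError
from .gwas_io import HarmonizedSet, SummaryStats, harmonize
from .instruments import (
    LDMatrix,
    filter_weak_instruments,
    ld_clump,
    select_by_pvalue,
    steiger_filter,
)
from .mediation import EffectEstimate, MediationResult, mediate

logger = logging.getLogger(__name__)

EXIT_OK = 0
EXIT_CRASH = 1
EXIT_NOT_COMPUTABLE = 2


@dataclass(frozen=True)
class AnalysisConfig:
    """Thresholds and seeds for a full MR workflow run."""

    iv_pvalue: float = 1e-5
    clump_window_kb: float = 10_000.0
    clump_r2: float = 0.001
    min_f: float = 10.0
    ivw_model: str = "multiplicative_random"
    n_boot: int = 1000
    presso_n_sim: int = 1000
    seed: int = 20240916
    multiple_testing: str = "none"  # none | bh_fdr
    significance: float = 0.05
    steiger: bool = True
    r2_method: str = "t_stat"
    power_case_fraction: float = 0.1
    power_beta: float | None = None  # None -> use the IVW estimate

    def __post_init__(self) -> None:
        if not 0 < self.iv_pvalue <= 1:
            raise InputError("iv_pvalue must be in (0, 1]")
        if not 0 <= self.clump_r2 <= 1:
            raise InputError("clump_r2 must be in [0, 1]")
        if self.clump_window_kb < 0 or self.min_f < 0:
            raise InputError("clump_window_kb and min_f must be non-negative")
        if not 0 < self.significance < 1:
            raise InputError("significance must be in (0, 1)")
        if self.multiple_testing not in ("none", "bh_fdr"):
            raise InputError("multiple_testing must be 'none' or 'bh_fdr'")
        if self.ivw_model not in ("fixed", "multiplicative_random"):
            raise InputError("ivw_model must be 'fixed' or 'multiplicative_random'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise InputError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class MRReport:
    """One direction's full MR report: estimator rows plus diagnostics."""

    exposure_label: str
    outcome_label: str
    rows: pd.DataFrame  # one row per method (or a not-computable marker row)
    diagnostics: dict
    dropped: list[tuple[str, str]]
    config: dict
    computable: bool
    harmonized: HarmonizedSet | None = None

    def to_tsv(self, path: str | Path) -> None:
        out = self.rows.copy()
        out.insert(0, "exposure", self.exposure_label)
        out.insert(1, "outcome", self.outcome_label)
        out["config"] = ";".join(f"{k}={v}" for k, v in sorted(self.config.items()))
        out.to_csv(path, sep="\t", index=False)

    def result(self, method: str) -> est.MRResult | None:
        for r in self.diagnostics.get("results", []):
            if r.method == method or (
                method == "ivw" and r.method in ("ivw_fixed", "ivw_mre", "wald")
            ):
                return r
        return None


def _not_computable_report(
    config: AnalysisConfig,
    exposure_label: str,
    outcome_label: str,
    reason: str,
    dropped: list[tuple[str, str]],
    n_instruments: int,
) -> MRReport:
    rows = pd.DataFrame(
        [
            {
                "method": "not_computable",
                "beta": np.nan,
                "se": np.nan,
                "pvalue": np.nan,
                "or": np.nan,
                "or_low": np.nan,
                "or_high": np.nan,
                "n_snps": n_instruments,
                "extras": f"reason={reason}",
            }
        ]
    )
    logger.warning("%s -> %s not computable: %s", exposure_label, outcome_label, reason)
    return MRReport(
        exposure_label=exposure_label,
        outcome_label=outcome_label,
        rows=rows,
        diagnostics={"reason": reason, "results": []},
        dropped=dropped,
        config=config.as_dict(),
        computable=False,
    )


def run_mr(
    config: AnalysisConfig,
    exposure: SummaryStats,
    outcome: SummaryStats,
    ld: LDMatrix | None = None,
) -> MRReport:
    """Run the full single-direction MR workflow.

    Steps: p-value selection, LD clumping (when an LD matrix is given),
    weak-instrument filtering, harmonization, optional Steiger filtering,
    the estimator suite (IVW, MR-Egger, weighted median, profile-score), and
    the sensitivity battery (Cochran's Q, Egger intercept, leave-one-out,
    residual-sum outlier test, funnel coordinates) plus a power estimate.

    With fewer than three surviving instruments a report is still returned,
    marked not-computable, rather than raising.
    """
    audit: list[tuple[str, str]] = []

    sel = select_by_pvalue(exposure, config.iv_pvalue)
    if len(sel) == 0:
        return _not_computable_report(
            config, exposure.trait_label, outcome.trait_label,
            "no_variants_pass_pvalue", audit, 0,
        )
    if ld is not None:
        sel = ld_clump(sel, ld, config.clump_window_kb, config.clump_r2)
    iv = filter_weak_instruments(sel, min_f=config.min_f, method=config.r2_method)
    audit.extend(iv.audit)
    if not iv.selected:
        return _not_computable_report(
            config, exposure.trait_label, outcome.trait_label,
            "all_instruments_weak", audit, 0,
        )
    sel = iv.subset(sel)

    try:
        h = harmonize(sel, outcome)
    except InputError as exc:
        return _not_computable_report(
            config, exposure.trait_label, outcome.trait_label,
            f"harmonization_failed:{exc}", audit, 0,
        )
    audit.extend(h.dropped)
    if config.steiger and len(h) > 0:
        h = steiger_filter(h, method=config.r2_method)
        audit = list(dict.fromkeys(audit + h.dropped))

    if len(h) < 3:
        return _not_computable_report(
            config, exposure.trait_label, outcome.trait_label,
            "fewer_than_3_instruments", audit, len(h),
        )

    results: list[est.MRResult] = [est.ivw(h, model=config.ivw_model)]
    for fn in (
        lambda: est.egger(h),
        lambda: est.weighted_median(h, n_boot=config.n_boot, seed=config.seed),
        lambda: est.raps(h),
    ):
        try:
            results.append(fn())
        except MRMediateError as exc:
            logger.warning("estimator failed: %s", exc)

    ivw_res = results[0]
    diagnostics: dict = {"results": results, "n_instruments": len(h), "seed": config.seed}
    try:
        diagnostics["cochran_q"] = sens.cochran_q(h, ivw_res.beta)
    except MRMediateError as exc:
        logger.warning("cochran_q failed: %s", exc)
    try:
        diagnostics["egger_intercept"] = sens.egger_intercept_test(h)
    except MRMediateError as exc:
        logger.warning("egger intercept failed: %s", exc)
    try:
        diagnostics["leave_one_out"] = sens.leave_one_out(
            h, model=config.ivw_model, significance=config.significance
        )
    except MRMediateError as exc:
        logger.warning("leave_one_out failed: %s", exc)
    try:
        diagnostics["mr_presso"] = sens.mr_presso(
            h, n_sim=config.presso_n_sim, seed=config.seed, model=config.ivw_model
        )
    except MRMediateError as exc:
        logger.warning("mr_presso failed: %s", exc)
    diagnostics["funnel"] = sens.funnel_data(h)

    # Power: variance explained in the exposure by the retained instruments.
    r2_xz = min(sum(iv.per_snp_r2.get(v, 0.0) for v in h.df["variant_id"]), 0.999)
    beta_for_power = config.power_beta if config.power_beta is not None else ivw_res.beta
    n_out = int(h.df["n_out"].median())
    if outcome.trait_type == "binary" and r2_xz > 0 and beta_for_power != 0:
        diagnostics["power"] = est.mr_power(
            n_out, config.power_case_fraction, r2_xz, beta_for_power,
            alpha=config.significance,
        )
    diagnostics["r2_xz"] = r2_xz
    diagnostics["f_statistic"] = iv.f_stat

    rows = pd.DataFrame([r.as_row() for r in results])
    return MRReport(
        exposure_label=exposure.trait_label,
        outcome_label=outcome.trait_label,
        rows=rows,
        diagnostics=diagnostics,
        dropped=audit,
        config=config.as_dict(),
        computable=True,
        harmonized=h,
    )


def run_bidirectional(
    config: AnalysisConfig,
    trait_a: SummaryStats,
    trait_b: SummaryStats,
    ld_a: LDMatrix | None = None,
    ld_b: LDMatrix | None = None,
) -> dict:
    """Run MR in both directions with direction-specific instrument selection.

    Returns ``{"forward": MRReport, "reverse": MRReport, "forward_only": bool}``
    where ``forward_only`` is set when the forward IVW p-value is below the
    significance threshold while the reverse one is not (or the reverse
    analysis is not computable).
    """
    forward = run_mr(config, trait_a, trait_b, ld_a)
    reverse = run_mr(config, trait_b, trait_a, ld_b)

    def _ivw_p(report: MRReport) -> float | None:
        r = report.result("ivw")
        return None if r is None else r.pvalue

    p_f, p_r = _ivw_p(forward), _ivw_p(reverse)
    forward_only = (
        p_f is not None
        and p_f < config.significance
        and (p_r is None or p_r >= config.significance)
    )
    return {"forward": forward, "reverse": reverse, "forward_only": forward_only}


@dataclass
class MediationWorkflowResult:
    """Two-step mediation output with the three constituent MR reports."""

    mediation: MediationResult | None
    total_report: MRReport
    step1_report: MRReport
    step2_report: MRReport
    computable: bool
    reason: str = ""


def run_mediation_workflow(
    config: AnalysisConfig,
    exposure: SummaryStats,
    mediator: SummaryStats,
    outcome: SummaryStats,
    ld: LDMatrix | None = None,
) -> MediationWorkflowResult:
    """Two-step MR mediation.

    Step 1 estimates exposure -> mediator with the exposure's instruments;
    step 2 estimates mediator -> outcome with instruments selected from the
    mediator's own GWAS (standard univariable two-step MR); the total effect
    is exposure -> outcome. The decomposition uses the IVW estimate of each
    constituent. If any constituent is not computable the mediation is
    marked not-computable with the first failing step as reason.
    """
    total_rep = run_mr(config, exposure, outcome, ld)
    step1_rep = run_mr(config, exposure, mediator, ld)
    step2_rep = run_mr(config, mediator, outcome, ld)

    for name, rep in (
        ("total", total_rep),
        ("step1", step1_rep),
        ("step2", step2_rep),
    ):
        if not rep.computable:
            return MediationWorkflowResult(
                mediation=None,
                total_report=total_rep,
                step1_report=step1_rep,
                step2_report=step2_rep,
                computable=False,
                reason=f"{name}_not_computable",
            )

    t = total_rep.result("ivw")
    b1 = step1_rep.result("ivw")
    b2 = step2_rep.result("ivw")
    med = mediate(
        EffectEstimate(t.beta, t.se, "total"),
        EffectEstimate(b1.beta, b1.se, "step1"),
        EffectEstimate(b2.beta, b2.se, "step2"),
    )
    return MediationWorkflowResult(
        mediation=med,
        total_report=total_rep,
        step1_report=step1_rep,
        step2_report=step2_rep,
        computable=True,
    )


def bh_fdr(pvalues: "pd.Series | np.ndarray") -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values (monotone step-up)."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    order = np.argsort(p)
    ranked = p[order] * m / (np.arange(m) + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def screen_positive(
    report: MRReport, significance: float = 0.05
) -> bool:
    """The screen's positive-result rule: IVW p below the threshold with
    direction-consistent point estimates across IVW, Egger and the weighted
    median (estimators that failed to run are not counted against
    consistency)."""
    ivw_res = report.result("ivw")
    if ivw_res is None or not np.isfinite(ivw_res.pvalue):
        return False
    if ivw_res.pvalue >= significance:
        return False
    signs = {np.sign(r.beta) for r in report.diagnostics.get("results", []) if r.beta != 0}
    return len(signs) <= 1
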