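"""Synthetic two-sample GWAS summary statistics with a known causal structure.

The generator emulates three non-overlapping GWAS — an exposure (e.g. a gut
microbial taxon abundance), a quantitative mediator (a blood metabolite) and
a binary outcome on the log-odds scale (a disease) — linked by the causal
diagram

    exposure --(beta_xm)--> mediator --(beta_my)--> outcome
    exposure --(beta_direct)------------------------^

with ``beta_direct = beta_total - beta_xm * beta_my``. Statistics are drawn
directly at the summary level: each study's estimated beta is the true
marginal per-allele effect plus independent normal noise with
``SE = 1 / sqrt(2 n maf (1 - maf))``, the standard large-sample SE for a
standardized trait. For the binary outcome the same form is used with ``n``
interpreted as an effective sample size (logistic asymptotics).

The SNP panel has three disjoint instrument classes: SNPs affecting the
exposure (and, downstream, mediator and outcome), SNPs affecting the
mediator directly (the instruments a two-step mediation analysis needs for
step 2), and SNPs affecting the outcome directly (giving a reverse analysis
its own instruments while remaining null for reverse causation). Horizontal
pleiotropy, when enabled, gives exposure SNPs extra direct outcome effects:
``balanced`` draws them with mean zero, ``directional`` with a positive mean
in the exposure-increasing-allele orientation (the configuration under which
IVW is biased but the Egger intercept can absorb the bias).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InputError
from .gwas_io import CANONICAL_COLUMNS, SummaryStats, harmonize
from .instruments import LDMatrix, filter_weak_instruments, select_by_pvalue, steiger_filter
from .mediation import EffectEstimate, mediate

logger = logging.getLogger(__name__)

#: Non-palindromic allele pairs; drawn uniformly so harmonization of the
#: generated files is loss-free. Palindromic behaviour is tested separately.
_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"), ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic exposure–mediator–outcome system.

    Defaults mirror the motivating study conditions: exposure and mediator
    GWAS of several thousand European-ancestry samples, a large
    case-control outcome GWAS (n_outcome is the effective sample size), and
    true effects equal to the central published worked example — total
    log-OR ln(1.149), exposure->mediator ln(1.112), mediator->outcome
    ln(1.214), i.e. a true mediated proportion of ~0.148.
    """

    n_snps: int = 100  # SNPs with direct exposure effects
    n_snps_mediator: int = 100  # SNPs with direct mediator effects
    n_snps_outcome: int = 50  # SNPs with direct outcome effects
    n_exposure: int = 7_700
    n_mediator: int = 8_300
    n_outcome: int = 14_500
    beta_total: float = 0.13889  # ln(1.149)
    beta_xm: float = 0.10619  # ln(1.112)
    beta_my: float = 0.19392  # ln(1.214)
    gamma_sd: float = 0.08  # SD of true SNP-exposure effects
    pleiotropy: str = "none"  # none | balanced | directional
    pleiotropy_magnitude: float = 0.0
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_blocks: int = 0  # 0 -> all SNPs independent
    ld_r2: float = 0.0  # within-block r2
    seed: int = 20240916

    def validate(self) -> None:
        if min(self.n_exposure, self.n_mediator, self.n_outcome) < 100:
            raise InputError("sample sizes must be >= 100")
        if self.n_snps < 4:
            raise InputError("n_snps must be >= 4")
        if self.n_snps_mediator < 0 or self.n_snps_outcome < 0:
            raise InputError("SNP counts must be non-negative")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise InputError(f"maf_range must lie within (0, 0.5], got {self.maf_range}")
        if self.pleiotropy not in ("none", "balanced", "directional"):
            raise InputError(f"unknown pleiotropy kind {self.pleiotropy!r}")
        if self.pleiotropy != "none" and self.pleiotropy_magnitude < 0:
            raise InputError("pleiotropy_magnitude must be >= 0")
        if self.ld_blocks < 0 or not 0 <= self.ld_r2 <= 1:
            raise InputError("invalid LD configuration")

    @property
    def beta_indirect(self) -> float:
        return self.beta_xm * self.beta_my

    @property
    def beta_direct(self) -> float:
        return self.beta_total - self.beta_indirect

    @property
    def true_proportion(self) -> float:
        if self.beta_total == 0:
            return float("nan")
        return self.beta_indirect / self.beta_total


@dataclass
class TruthSet:
    """Ground truth for one simulated triplet."""

    true_gamma: np.ndarray  # per-SNP true exposure effects (0 off-class)
    true_pleiotropy: np.ndarray  # per-SNP direct outcome effects of exposure SNPs
    true_mediator_effects: np.ndarray
    true_outcome_effects: np.ndarray
    beta_total: float
    beta_direct: float
    beta_indirect: float
    true_proportion: float
    variant_ids: list[str] = field(default_factory=list)

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "variant_id": self.variant_ids,
                "true_gamma": self.true_gamma,
                "true_pleiotropy": self.true_pleiotropy,
                "true_mediator_effect": self.true_mediator_effects,
                "true_outcome_effect": self.true_outcome_effects,
            }
        ).to_csv(path, sep="\t", index=False)


def _study_frame(
    ids: list[str],
    chrom: np.ndarray,
    pos: np.ndarray,
    ea: np.ndarray,
    oa: np.ndarray,
    maf: np.ndarray,
    true_beta: np.ndarray,
    n: int,
    rng: np.random.Generator,
) -> pd.DataFrame:
    se = 1.0 / np.sqrt(2.0 * n * maf * (1.0 - maf))
    beta_hat = true_beta + rng.normal(0.0, se)
    pval = 2.0 * sps.norm.sf(np.abs(beta_hat / se))
    # A p-value of exactly 0 would violate the record invariant.
    pval = np.clip(pval, np.finfo(float).tiny, 1.0)
    return pd.DataFrame(
        {
            "variant_id": ids,
            "chromosome": chrom.astype(str),
            "position": pos,
            "effect_allele": ea,
            "other_allele": oa,
            "eaf": maf,
            "beta": beta_hat,
            "se": se,
            "pvalue": pval,
            "n": n,
        },
        columns=CANONICAL_COLUMNS,
    )


def simulate_triplet(
    config: SimulationConfig,
) -> tuple[SummaryStats, SummaryStats, SummaryStats, TruthSet, LDMatrix]:
    """Simulate exposure, mediator and outcome summary statistics.

    Returns the three studies, the ground truth and the LD matrix. Fully
    deterministic given ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    n_total = config.n_snps + config.n_snps_mediator + config.n_snps_outcome
    ids = [f"rs{i + 1:06d}" for i in range(n_total)]
    maf = rng.uniform(*config.maf_range, size=n_total)
    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=n_total)
    ea = np.array([_ALLELE_PAIRS[i][0] for i in pair_idx])
    oa = np.array([_ALLELE_PAIRS[i][1] for i in pair_idx])

    # Positions/chromosomes: LD blocks sit together (1 kb spacing); distinct
    # blocks and unblocked SNPs are spaced far beyond any clumping window.
    chrom = np.empty(n_total, dtype=object)
    pos = np.empty(n_total, dtype=int)
    if config.ld_blocks > 0:
        block_of = np.arange(n_total) % config.ld_blocks
        within = np.arange(n_total) // config.ld_blocks
        for i in range(n_total):
            chrom[i] = str(block_of[i] % 22 + 1)
            pos[i] = 1 + (block_of[i] // 22) * 50_000_000 + within[i] * 1_000
        r2 = np.eye(n_total)
        for b in range(config.ld_blocks):
            members = np.flatnonzero(block_of == b)
            for x in members:
                for y in members:
                    if x != y:
                        r2[x, y] = config.ld_r2
        ld = LDMatrix(ids, r2)
    else:
        chrom[:] = [str(i % 22 + 1) for i in range(n_total)]
        pos[:] = [1 + (i // 22) * 50_000_000 for i in range(n_total)]
        ld = LDMatrix.identity(ids)

    is_exp = np.zeros(n_total, dtype=bool)
    is_exp[: config.n_snps] = True
    is_med = np.zeros(n_total, dtype=bool)
    is_med[config.n_snps : config.n_snps + config.n_snps_mediator] = True
    is_out = ~(is_exp | is_med)

    gamma = np.zeros(n_total)
    gamma[is_exp] = rng.normal(0.0, config.gamma_sd, size=config.n_snps) if config.gamma_sd > 0 else 0.0
    delta = np.zeros(n_total)  # direct SNP-mediator effects
    delta[is_med] = rng.normal(0.0, config.gamma_sd, size=config.n_snps_mediator) if config.gamma_sd > 0 else 0.0
    eta = np.zeros(n_total)  # direct SNP-outcome effects (outcome's own loci)
    eta[is_out] = rng.normal(0.0, config.gamma_sd, size=int(is_out.sum())) if config.gamma_sd > 0 else 0.0

    pleio = np.zeros(n_total)
    mag = config.pleiotropy_magnitude
    if config.pleiotropy == "balanced" and mag > 0:
        pleio[is_exp] = rng.normal(0.0, mag, size=config.n_snps)
    elif config.pleiotropy == "directional" and mag > 0:
        # Directional in the exposure-increasing-allele orientation.
        oriented = rng.normal(mag, mag / 2.0, size=config.n_snps)
        pleio[is_exp] = np.sign(gamma[is_exp]) * oriented

    beta_direct = config.beta_direct
    true_exp = gamma
    true_med = gamma * config.beta_xm + delta
    true_out = (
        gamma * beta_direct
        + (gamma * config.beta_xm) * config.beta_my
        + pleio
        + delta * config.beta_my
        + eta
    )

    exp_stats = SummaryStats(
        "synthetic_exposure",
        "quantitative",
        _study_frame(ids, chrom, pos, ea, oa, maf, true_exp, config.n_exposure, rng),
    )
    med_stats = SummaryStats(
        "synthetic_mediator",
        "quantitative",
        _study_frame(ids, chrom, pos, ea, oa, maf, true_med, config.n_mediator, rng),
    )
    out_stats = SummaryStats(
        "synthetic_outcome",
        "binary",
        _study_frame(ids, chrom, pos, ea, oa, maf, true_out, config.n_outcome, rng),
    )

    truth = TruthSet(
        true_gamma=gamma,
        true_pleiotropy=pleio,
        true_mediator_effects=true_med,
        true_outcome_effects=true_out,
        beta_total=config.beta_total,
        beta_direct=beta_direct,
        beta_indirect=config.beta_indirect,
        true_proportion=config.true_proportion,
        variant_ids=ids,
    )
    return exp_stats, med_stats, out_stats, truth, ld


def _quick_mr(
    exposure: SummaryStats,
    outcome: SummaryStats,
    ld: LDMatrix | None,
    iv_pvalue: float,
    min_f: float,
    model: str,
    methods: tuple[str, ...],
    clump: bool = False,
    steiger: bool = True,
):
    """Selection -> harmonization -> estimation, returning {method: MRResult}.

    The light-weight path used by :func:`recovery_suite`; the full pipeline
    with diagnostics lives in :mod:`mrmediate.pipeline`.
    """
    from . import estimators
    from .instruments import ld_clump

    sel = select_by_pvalue(exposure, iv_pvalue)
    if len(sel) == 0:
        return None
    if clump and ld is not None:
        sel = ld_clump(sel, ld)
    iv = filter_weak_instruments(sel, min_f=min_f)
    if not iv.selected:
        return None
    sel = iv.subset(sel)
    h = harmonize(sel, outcome)
    if steiger and len(h) > 0:
        h = steiger_filter(h)
    if len(h) == 0:
        return None
    out = {}
    for m in methods:
        try:
            if m == "ivw":
                out[m] = estimators.ivw(h, model=model)
            elif m == "egger":
                out[m] = estimators.egger(h)
            elif m == "weighted_median":
                out[m] = estimators.weighted_median(h, n_boot=200, seed=0)
            elif m == "raps":
                out[m] = estimators.raps(h)
        except Exception as exc:  # too few instruments etc.
            logger.debug("quick_mr %s failed: %s", m, exc)
    return out or None


def recovery_suite(
    config: SimulationConfig,
    n_reps: int = 100,
    methods: tuple[str, ...] = ("ivw", "egger", "weighted_median"),
    iv_pvalue: float = 1e-5,
    min_f: float = 10.0,
    ivw_model: str = "multiplicative_random",
) -> pd.DataFrame:
    """Monte-Carlo recovery of the total effect and the mediated proportion.

    Repeatedly simulates a triplet, runs the full analysis path (p-value
    selection, weak-instrument filtering, harmonization, Steiger filtering,
    estimation, two-step mediation) and summarizes, per estimator, the mean
    bias and empirical SD of the total-effect estimate and the coverage of
    its normal 95% interval; a final ``mediation_proportion`` row summarizes
    the estimated mediated proportion against the configured truth, with
    coverage of the delta-method interval.
    """
    if n_reps < 1:
        raise InputError("n_reps must be >= 1")
    est_rows: dict[str, list] = {m: [] for m in methods}
    cover: dict[str, list] = {m: [] for m in methods}
    prop_rows: list[float] = []
    prop_cover: list[bool] = []

    for rep in range(n_reps):
        cfg = replace(config, seed=config.seed + rep)
        exp_s, med_s, out_s, truth, ld = simulate_triplet(cfg)

        total_res = _quick_mr(
            exp_s, out_s, ld, iv_pvalue, min_f, ivw_model, methods
        )
        if total_res is None:
            continue
        for m, r in total_res.items():
            est_rows[m].append(r.beta)
            cover[m].append(r.ci_low <= truth.beta_total <= r.ci_high)

        b1_res = _quick_mr(exp_s, med_s, ld, iv_pvalue, min_f, ivw_model, ("ivw",))
        b2_res = _quick_mr(med_s, out_s, ld, iv_pvalue, min_f, ivw_model, ("ivw",))
        if b1_res is None or b2_res is None or "ivw" not in total_res:
            continue
        total_e = total_res["ivw"]
        med = mediate(
            EffectEstimate(total_e.beta, total_e.se, "total"),
            EffectEstimate(b1_res["ivw"].beta, b1_res["ivw"].se, "step1"),
            EffectEstimate(b2_res["ivw"].beta, b2_res["ivw"].se, "step2"),
        )
        prop_rows.append(med.proportion)
        lo, hi = med.proportion_ci
        prop_cover.append(lo <= truth.true_proportion <= hi)

    rows = []
    for m in methods:
        vals = np.asarray(est_rows[m])
        if len(vals) == 0:
            continue
        rows.append(
            {
                "method": m,
                "n_reps": len(vals),
                "mean_estimate": float(vals.mean()),
                "mean_bias": float(vals.mean() - config.beta_total),
                "empirical_sd": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
                "ci_coverage": float(np.mean(cover[m])),
            }
        )
    if prop_rows:
        props = np.asarray(prop_rows)
        rows.append(
            {
                "method": "mediation_proportion",
                "n_reps": len(props),
                "mean_estimate": float(props.mean()),
                "mean_bias": float(props.mean() - config.true_proportion),
                "empirical_sd": float(props.std(ddof=1)) if len(props) > 1 else 0.0,
                "ci_coverage": float(np.mean(prop_cover)),
            }
        )
    return pd.DataFrame(rows)


def write_fixtures(config: SimulationConfig, out_dir: str | Path) -> dict[str, Path]:
    """Materialize the standard synthetic fixtures as TSV files."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    exp_s, med_s, out_s, truth, ld = simulate_triplet(config)
    from .gwas_io import write_summary_stats

    paths = {
        "exposure": out_dir / "exposure.tsv",
        "mediator": out_dir / "mediator.tsv",
        "outcome": out_dir / "outcome.tsv",
        "ld": out_dir / "ld_matrix.tsv",
        "truth": out_dir / "truth.tsv",
    }
    write_summary_stats(exp_s, paths["exposure"])
    write_summary_stats(med_s, paths["mediator"])
    write_summary_stats(out_s, paths["outcome"])
    ld.to_tsv(paths["ld"])
    truth.to_tsv(paths["truth"])
    return paths
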