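"""Two-step MR mediation: effect decomposition with delta-method intervals.

The total effect of an exposure on an outcome (log-OR scale) is decomposed
into an indirect effect through a mediator — the product of the
exposure-to-mediator effect (b1) and the mediator-to-outcome effect (b2) —
and a direct effect, total minus indirect. The proportion mediated is
indirect / total; its 95% interval comes from first-order (delta-method)
variance propagation. All arithmetic is on the natural-log scale; odds
ratios are exp views and percentages are 100 x proportion.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InputError

logger = logging.getLogger(__name__)

Z95 = 1.959963984540054  # Phi^-1(0.975)


@dataclass(frozen=True)
class EffectEstimate:
    """A log-scale effect with its standard error."""

    beta: float
    se: float
    source_label: str = ""

    def __post_init__(self) -> None:
        if not self.se > 0:
            raise InputError(f"EffectEstimate se must be > 0, got {self.se}")

    @classmethod
    def from_odds_ratio(
        cls,
        or_point: float,
        or_low: float | None = None,
        or_high: float | None = None,
        se: float | None = None,
        source_label: str = "",
    ) -> "EffectEstimate":
        """Build from an odds ratio, deriving the SE from a 95% CI if given.

        When neither a CI nor an SE is supplied the SE is set to a tiny
        placeholder so the point estimate can still flow through the
        decomposition (interval outputs are then meaningless and flagged).
        """
        beta = math.log(or_point)
        if se is None:
            if or_low is not None and or_high is not None:
                se = (math.log(or_high) - math.log(or_low)) / (2 * Z95)
            else:
                se = 1e-12
        return cls(beta=beta, se=se, source_label=source_label)

    @property
    def odds_ratio(self) -> float:
        return math.exp(self.beta)


@dataclass
class MediationResult:
    """Decomposition of a total effect through one mediator.

    Invariants: ``direct.beta + indirect.beta == total.beta`` exactly and
    ``proportion == indirect.beta / total.beta`` exactly (floating point
    aside, both are computed that way, not re-derived).
    """

    total: EffectEstimate
    step1: EffectEstimate
    step2: EffectEstimate
    indirect: EffectEstimate
    direct: EffectEstimate
    proportion: float
    proportion_ci: tuple[float, float]
    consistent_direction: bool
    ci_method: str

    @property
    def proportion_pct(self) -> float:
        return 100.0 * self.proportion


def indirect_effect(b1: EffectEstimate, b2: EffectEstimate) -> EffectEstimate:
    """Product-method indirect effect with first-order delta SE.

    ``beta = b1.beta * b2.beta``;
    ``se = sqrt(b2.beta^2 b1.se^2 + b1.beta^2 b2.se^2)`` assuming
    independence of the two estimates (non-overlapping samples).
    """
    beta = b1.beta * b2.beta
    se = math.sqrt(b2.beta**2 * b1.se**2 + b1.beta**2 * b2.se**2)
    if se == 0.0:
        se = 1e-12
    return EffectEstimate(beta=beta, se=se, source_label="indirect")


def mediate(
    total: EffectEstimate,
    b1: EffectEstimate,
    b2: EffectEstimate,
    ci_method: str = "delta_indirect_over_fixed_total",
) -> MediationResult:
    """Decompose a total effect into direct and indirect parts.

    ``delta_indirect_over_fixed_total`` (default): the proportion CI scales
    the indirect effect's normal interval by the total effect treated as
    fixed: ``(indirect +- 1.96 se_indirect) / total``.
    ``delta_full_ratio`` additionally propagates the total effect's SE
    through the ratio (independence assumed):
    ``var(p) = var(ind)/total^2 + ind^2 var(total)/total^4``.

    ``consistent_direction`` is True when the indirect and total effects
    share a sign — the qualitative requirement for interpreting the ratio as
    a mediated proportion.
    """
    if total.beta == 0:
        raise InputError("mediate: total effect is zero; proportion undefined")
    if ci_method not in ("delta_indirect_over_fixed_total", "delta_full_ratio"):
        raise InputError(f"unknown ci_method {ci_method!r}")

    ind = indirect_effect(b1, b2)
    direct_beta = total.beta - ind.beta
    direct_se = math.sqrt(total.se**2 + ind.se**2)
    direct = EffectEstimate(beta=direct_beta, se=max(direct_se, 1e-12), source_label="direct")
    proportion = ind.beta / total.beta

    if ci_method == "delta_indirect_over_fixed_total":
        lo = (ind.beta - Z95 * ind.se) / total.beta
        hi = (ind.beta + Z95 * ind.se) / total.beta
    else:
        var_p = ind.se**2 / total.beta**2 + ind.beta**2 * total.se**2 / total.beta**4
        half = Z95 * math.sqrt(var_p)
        lo, hi = proportion - half, proportion + half
    if lo > hi:
        lo, hi = hi, lo

    if proportion < 0 or proportion > 1:
        warnings.warn(
            f"mediated proportion {proportion:.3f} outside [0, 1]; "
            "reported as-is (direction inconsistency or estimation noise)",
            stacklevel=2,
        )

    return MediationResult(
        total=total,
        step1=b1,
        step2=b2,
        indirect=ind,
        direct=direct,
        proportion=proportion,
        proportion_ci=(lo, hi),
        consistent_direction=bool(np.sign(ind.beta) == np.sign(total.beta)),
        ci_method=ci_method,
    )


def mediation_screen(
    triples: list[tuple[str, EffectEstimate, EffectEstimate, EffectEstimate]],
    ci_method: str = "delta_indirect_over_fixed_total",
) -> pd.DataFrame:
    """Batch mediation over labelled (total, b1, b2) triples.

    Output is sorted by descending absolute mediated proportion. Rows whose
    indirect and total effects disagree in sign are flagged via
    ``consistent_direction`` but kept.
    """
    labels = [t[0] for t in triples]
    if len(set(labels)) != len(labels):
        raise InputError("mediation_screen: duplicate labels")
    rows = []
    for label, total, b1, b2 in triples:
        res = mediate(total, b1, b2, ci_method=ci_method)
        rows.append(
            {
                "label": label,
                "total_beta": res.total.beta,
                "indirect_beta": res.indirect.beta,
                "direct_beta": res.direct.beta,
                "indirect_se": res.indirect.se,
                "proportion": res.proportion,
                "proportion_pct": res.proportion_pct,
                "proportion_ci_low": res.proportion_ci[0],
                "proportion_ci_high": res.proportion_ci[1],
                "consistent_direction": res.consistent_direction,
            }
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "label",
            "total_beta",
            "indirect_beta",
            "direct_beta",
            "indirect_se",
            "proportion",
            "proportion_pct",
            "proportion_ci_low",
            "proportion_ci_high",
            "consistent_direction",
        ],
    )
    if not out.empty:
        out = (
            out.reindex(out["proportion"].abs().sort_values(ascending=False).index)
            .reset_index(drop=True)
        )
    return out


def load_worked_example_triples() -> list[tuple[str, EffectEstimate, EffectEstimate, EffectEstimate]]:
    """Load the packaged worked example: published IVW odds-ratio triples for
    the gut-microbiota -> blood-metabolite -> chronic-gastritis pathways.

    Each row carries the total (taxon -> gastritis), step-1 (taxon ->
    metabolite) and step-2 (metabolite -> gastritis) odds ratios per SD of
    exposure.
    """
    with resources.files("mrmediate.data").joinpath(
        "gastritis_mediation_or_triples.csv"
    ).open() as fh:
        df = pd.read_csv(fh)
    triples = []
    for row in df.itertuples(index=False):
        triples.append(
            (
                row.label,
                EffectEstimate.from_odds_ratio(row.or_total, source_label="total"),
                EffectEstimate.from_odds_ratio(row.or_step1, source_label="step1"),
                EffectEstimate.from_odds_ratio(row.or_step2, source_label="step2"),
            )
        )
    return triples


def read_triples_csv(path: str | Path) -> list[tuple[str, EffectEstimate, EffectEstimate, EffectEstimate]]:
    """Read labelled OR or beta/se triples from a CSV.

    Accepts either columns ``label, or_total, or_step1, or_step2`` (optionally
    with ``*_low``/``*_high`` CI columns) or
    ``label, beta_total, se_total, beta_step1, se_step1, beta_step2, se_step2``.
    """
    df = pd.read_csv(path)
    triples = []
    if {"or_total", "or_step1", "or_step2"}.issubset(df.columns):
        for row in df.itertuples(index=False):
            d = row._asdict()
            triples.append(
                (
                    d["label"],
                    EffectEstimate.from_odds_ratio(
                        d["or_total"], d.get("or_total_low"), d.get("or_total_high")
                    ),
                    EffectEstimate.from_odds_ratio(
                        d["or_step1"], d.get("or_step1_low"), d.get("or_step1_high")
                    ),
                    EffectEstimate.from_odds_ratio(
                        d["or_step2"], d.get("or_step2_low"), d.get("or_step2_high")
                    ),
                )
            )
    elif {"beta_total", "se_total"}.issubset(df.columns):
        for row in df.itertuples(index=False):
            d = row._asdict()
            triples.append(
                (
                    d["label"],
                    EffectEstimate(d["beta_total"], d["se_total"]),
                    EffectEstimate(d["beta_step1"], d["se_step1"]),
                    EffectEstimate(d["beta_step2"], d["se_step2"]),
                )
            )
    else:
        raise InputError(
            f"{path}: expected OR columns (or_total/or_step1/or_step2) or "
            "beta/se columns (beta_total/se_total/...)"
        )
    return triples
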