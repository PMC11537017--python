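"""Instrument selection for two-sample MR.

Covers the standard pipeline: genome-wide screening at a p-value threshold,
greedy LD clumping against a user-supplied r-squared matrix, per-SNP and
overall instrument-strength (F-statistic) filtering, and Steiger
directionality filtering of harmonized instruments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InputError
from .gwas_io import HarmonizedSet, SummaryStats, VariantRecord

logger = logging.getLogger(__name__)


@dataclass
class LDMatrix:
    """Pairwise squared-correlation (r2) matrix over a set of variants.

    Symmetric with a unit diagonal; values in [0, 1]. Variants absent from
    the matrix are treated as independent by consumers.
    """

    variant_ids: list[str]
    r2: np.ndarray

    def __post_init__(self) -> None:
        self.r2 = np.asarray(self.r2, dtype=float)
        self._index = {v: i for i, v in enumerate(self.variant_ids)}

    def validate(self) -> None:
        if self.r2.shape != (len(self.variant_ids), len(self.variant_ids)):
            raise InputError("LD matrix shape does not match variant id list")
        if not np.allclose(self.r2, self.r2.T, atol=1e-8):
            raise InputError("LD matrix is not symmetric")
        if not np.allclose(np.diag(self.r2), 1.0, atol=1e-8):
            raise InputError("LD matrix diagonal is not 1")
        if self.r2.min() < -1e-12 or self.r2.max() > 1 + 1e-12:
            raise InputError("LD matrix values outside [0, 1]")

    def pair_r2(self, a: str, b: str) -> float:
        """r2 between two variants; absent pairs are independent (0)."""
        ia, ib = self._index.get(a), self._index.get(b)
        if ia is None or ib is None:
            return 0.0
        return float(self.r2[ia, ib])

    @classmethod
    def identity(cls, variant_ids: Sequence[str]) -> "LDMatrix":
        return cls(list(variant_ids), np.eye(len(variant_ids)))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "LDMatrix":
        """Read a square matrix with variant ids as header row and first column."""
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.columns.astype(str)), df.to_numpy(dtype=float))

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.r2, index=self.variant_ids, columns=self.variant_ids).to_csv(
            path, sep="\t"
        )


@dataclass
class InstrumentSet:
    """Outcome of instrument-strength filtering.

    ``f_stat`` is the overall F over the retained set computed from the summed
    per-SNP variance explained; ``audit`` lists excluded variants with
    reasons.
    """

    selected: list[str]
    per_snp_r2: dict[str, float]
    f_stat: float
    k: int
    n: int
    audit: list[tuple[str, str]] = field(default_factory=list)

    def subset(self, stats: SummaryStats) -> SummaryStats:
        """Restrict a SummaryStats to the selected instruments, order preserved."""
        return stats.subset(stats.df["variant_id"].isin(self.selected).to_numpy())


def select_by_pvalue(stats: SummaryStats, threshold: float = 1e-5) -> SummaryStats:
    """Keep records with p-value strictly below ``threshold``, order preserved."""
    if not 0 < threshold <= 1:
        raise InputError(f"p-value threshold must be in (0, 1], got {threshold}")
    mask = (stats.df["pvalue"] < threshold).to_numpy()
    if not mask.any():
        logger.warning(
            "%s: no variants pass p < %g", stats.trait_label, threshold
        )
    return stats.subset(mask)


def ld_clump(
    stats: SummaryStats,
    ld: LDMatrix,
    window_kb: float = 10_000,
    r2_threshold: float = 0.001,
) -> SummaryStats:
    """Greedy LD clumping.

    Variants are visited in order of ascending p-value (ties broken by
    lexicographic ``variant_id``); each index variant removes every remaining
    variant on the same chromosome within ``window_kb`` kilobases whose r2
    with it exceeds ``r2_threshold``. Variants absent from the LD matrix are
    treated as independent.
    """
    ld.validate()
    df = stats.df
    order = df.assign(rowidx=np.arange(len(df))).sort_values(
        ["pvalue", "variant_id"], kind="mergesort"
    )
    absent = [v for v in df["variant_id"] if v not in ld._index]
    if absent:
        logger.info("ld_clump: %d variants absent from LD matrix, treated independent", len(absent))

    window_bp = window_kb * 1000.0
    remaining = list(order.itertuples(index=False))
    kept_rows: list[int] = []
    while remaining:
        index_snp = remaining.pop(0)
        kept_rows.append(index_snp.rowidx)
        survivors = []
        for cand in remaining:
            if (
                cand.chromosome == index_snp.chromosome
                and abs(cand.position - index_snp.position) <= window_bp
                and ld.pair_r2(cand.variant_id, index_snp.variant_id) > r2_threshold
            ):
                continue
            survivors.append(cand)
        remaining = survivors

    keep_mask = np.zeros(len(df), dtype=bool)
    keep_mask[kept_rows] = True
    return stats.subset(keep_mask)


def variance_explained(
    record: VariantRecord, method: str = "t_stat"
) -> float:
    """Proportion of trait variance explained by one SNP, clamped to [0, 1).

    ``eaf_beta``: ``2 * beta^2 * eaf * (1 - eaf)`` (SD-scale trait assumed);
    falls back to ``t_stat`` with a logged note when eaf is missing.
    ``t_stat``: ``t^2 / (t^2 + n - 2)`` with ``t = beta / se``.
    """
    if method not in ("eaf_beta", "t_stat"):
        raise InputError(f"unknown variance_explained method {method!r}")
    eaf = record.eaf
    if method == "eaf_beta":
        if eaf is None or (isinstance(eaf, float) and np.isnan(eaf)):
            logger.info(
                "variance_explained: %s has no eaf, falling back to t_stat",
                record.variant_id,
            )
            method = "t_stat"
        else:
            r2 = 2.0 * record.beta**2 * eaf * (1.0 - eaf)
            return float(min(max(r2, 0.0), np.nextafter(1.0, 0.0)))
    if record.n <= 2:
        raise InputError("t_stat variance_explained requires n > 2")
    t2 = (record.beta / record.se) ** 2
    r2 = t2 / (t2 + record.n - 2)
    return float(min(max(r2, 0.0), np.nextafter(1.0, 0.0)))


def _r2_arrays(
    beta: np.ndarray,
    se: np.ndarray,
    eaf: np.ndarray,
    n: np.ndarray,
    method: str,
) -> np.ndarray:
    """Vectorized per-SNP variance explained with the eaf_beta -> t_stat fallback."""
    t2 = (beta / se) ** 2
    r2_t = t2 / (t2 + np.maximum(n - 2, 1))
    if method == "t_stat":
        r2 = r2_t
    elif method == "eaf_beta":
        r2_eaf = 2.0 * beta**2 * eaf * (1.0 - eaf)
        r2 = np.where(np.isnan(eaf), r2_t, r2_eaf)
    else:
        raise InputError(f"unknown variance_explained method {method!r}")
    return np.clip(r2, 0.0, np.nextafter(1.0, 0.0))


def f_statistic(r2_total: float, n: int, k: int) -> float:
    """Instrument-strength F: ``R2 (N - K - 1) / ((1 - R2) K)``."""
    if not 0 <= r2_total < 1:
        raise InputError(f"r2_total must be in [0, 1), got {r2_total}")
    if k < 1:
        raise InputError(f"k must be >= 1, got {k}")
    if n <= k + 1:
        raise InputError(f"need n > k + 1 (n={n}, k={k})")
    return float(r2_total * (n - k - 1) / ((1.0 - r2_total) * k))


def filter_weak_instruments(
    stats: SummaryStats,
    n: int | None = None,
    min_f: float = 10.0,
    method: str = "t_stat",
) -> InstrumentSet:
    """Exclude weak instruments by per-SNP F-statistic.

    Each SNP's single-instrument F (k = 1) is computed from its variance
    explained; SNPs with F < ``min_f`` are excluded with reason
    ``weak_instrument``. The overall F over the retained set uses the summed
    per-SNP R2 with K equal to the number retained.

    ``n`` overrides the per-record sample sizes when given.
    """
    if len(stats) == 0:
        raise InputError("filter_weak_instruments requires non-empty stats")
    df = stats.df
    n_arr = (
        np.full(len(df), float(n)) if n is not None else df["n"].to_numpy(dtype=float)
    )
    r2 = _r2_arrays(
        df["beta"].to_numpy(float),
        df["se"].to_numpy(float),
        df["eaf"].to_numpy(float),
        n_arr,
        method,
    )
    with np.errstate(divide="ignore"):
        f_per = r2 * (n_arr - 2) / (1.0 - r2)
    keep = f_per >= min_f

    ids = df["variant_id"].tolist()
    selected = [v for v, k_ in zip(ids, keep) if k_]
    audit = [(v, "weak_instrument") for v, k_ in zip(ids, keep) if not k_]
    if not selected:
        logger.warning("%s: all instruments weak at F < %g", stats.trait_label, min_f)
        return InstrumentSet([], {}, 0.0, 0, int(np.median(n_arr)), audit)

    r2_total = float(min(r2[keep].sum(), np.nextafter(1.0, 0.0)))
    n_eff = int(np.median(n_arr[keep]))
    k = len(selected)
    overall_f = f_statistic(r2_total, n_eff, k) if n_eff > k + 1 else 0.0
    return InstrumentSet(
        selected=selected,
        per_snp_r2={v: float(r) for v, r in zip(ids, r2) if v in set(selected)},
        f_stat=overall_f,
        k=k,
        n=n_eff,
        audit=audit,
    )


def steiger_filter(h: HarmonizedSet, method: str = "t_stat") -> HarmonizedSet:
    """Keep instruments explaining more variance in the exposure than the outcome.

    Rows with exposure R2 strictly greater than outcome R2 are retained; the
    rest are recorded in ``dropped`` with reason ``steiger_fail``. A
    ``steiger_z`` column is attached: the z-statistic of the difference of
    Fisher-transformed |r| values, scaled by the harmonic mean of the two
    sample sizes.
    """
    if len(h) == 0:
        raise InputError("steiger_filter requires a non-empty HarmonizedSet")
    df = h.df
    eaf = df["eaf"].to_numpy(float)
    r2_exp = _r2_arrays(
        df["beta_exp"].to_numpy(float),
        df["se_exp"].to_numpy(float),
        eaf,
        df["n_exp"].to_numpy(float),
        method,
    )
    r2_out = _r2_arrays(
        df["beta_out"].to_numpy(float),
        df["se_out"].to_numpy(float),
        eaf,
        df["n_out"].to_numpy(float),
        method,
    )
    n_h = sps.hmean(df[["n_exp", "n_out"]].to_numpy(float), axis=1)
    denom = np.sqrt(2.0 / np.maximum(n_h - 3.0, 1.0))
    z = (np.arctanh(np.sqrt(r2_exp)) - np.arctanh(np.sqrt(r2_out))) / denom

    keep = r2_exp > r2_out
    out_df = df.loc[keep].reset_index(drop=True).copy()
    out_df["steiger_z"] = z[keep]
    dropped = list(h.dropped) + [
        (v, "steiger_fail") for v in df.loc[~keep, "variant_id"]
    ]
    return HarmonizedSet(h.exposure_label, h.outcome_label, out_df, dropped)


def resolve_proxies(
    instrument_ids: Sequence[str],
    available_ids: Sequence[str],
    proxy_table: Mapping[str, str] | None = None,
) -> tuple[list[str], dict[str, str]]:
    """Substitute user-supplied LD proxies for instruments missing downstream.

    Returns the resolved id list (order preserved, missing-without-proxy ids
    omitted) and the substitutions applied. No remote LD panel is consulted;
    ``proxy_table`` maps missing ids to candidate proxies.
    """
    available = set(available_ids)
    proxy_table = dict(proxy_table or {})
    resolved: list[str] = []
    used: dict[str, str] = {}
    for vid in instrument_ids:
        if vid in available:
            resolved.append(vid)
        elif vid in proxy_table and proxy_table[vid] in available:
            resolved.append(proxy_table[vid])
            used[vid] = proxy_table[vid]
        else:
            logger.info("resolve_proxies: %s absent and no usable proxy", vid)
    return resolved, used


def read_proxy_table(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV (missing_id, proxy_id) into a mapping."""
    df = pd.read_csv(path, sep="\t", header=0)
    if df.shape[1] < 2:
        raise InputError(f"{path}: proxy table needs two columns")
    return dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))
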