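"""GWAS summary-statistic data model, delimited-text I/O, and harmonization.

The central containers are :class:`SummaryStats` (one trait's per-variant
association records) and :class:`HarmonizedSet` (exposure and outcome records
aligned to a common effect allele, the input to every MR estimator).

Effect sizes for binary traits are stored on the natural-log-odds scale
throughout; odds ratios are derived views (``exp(beta)``). Quantitative-trait
effects are in SD units. Positions are 1-based and are used only for
LD-clumping windows, never in estimator arithmetic.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError

logger = logging.getLogger(__name__)

VALID_ALLELES = frozenset("ACGT")

#: Canonical column order used in memory and by the TSV writer.
CANONICAL_COLUMNS = [
    "variant_id",
    "chromosome",
    "position",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pvalue",
    "n",
]

#: Built-in column dialects. Keys are semantic names, values are header names.
DIALECTS: dict[str, dict[str, str]] = {
    "canonical": {c: c for c in CANONICAL_COLUMNS},
    # GWAS-Catalog-style harmonized headers.
    "gwas_catalog": {
        "variant_id": "variant_id",
        "chromosome": "chromosome",
        "position": "base_pair_location",
        "effect_allele": "effect_allele",
        "other_allele": "other_allele",
        "eaf": "effect_allele_frequency",
        "beta": "beta",
        "se": "standard_error",
        "pvalue": "p_value",
        "n": "n",
    },
    # Generic exposure/outcome style (TwoSampleMR-like headers).
    "exposure_outcome": {
        "variant_id": "SNP",
        "chromosome": "chr",
        "position": "pos",
        "effect_allele": "effect_allele",
        "other_allele": "other_allele",
        "eaf": "eaf",
        "beta": "beta",
        "se": "se",
        "pvalue": "pval",
        "n": "samplesize",
    },
}


@dataclass(frozen=True)
class VariantRecord:
    """A single per-variant association record.

    ``beta`` is the per-allele effect of ``effect_allele``: log-odds for a
    binary trait, SD units for a quantitative one.
    """

    variant_id: str
    chromosome: str
    position: int
    effect_allele: str
    other_allele: str
    eaf: float | None
    beta: float
    se: float
    pvalue: float
    n: int

    def validate(self) -> list[str]:
        """Return a list of invariant violations (empty when valid)."""
        problems = []
        if self.effect_allele == self.other_allele:
            problems.append("identical_alleles")
        if self.effect_allele not in VALID_ALLELES or self.other_allele not in VALID_ALLELES:
            problems.append("invalid_allele")
        if not (self.se > 0 and math.isfinite(self.se)):
            problems.append("nonpositive_se")
        if not (0 < self.pvalue <= 1):
            problems.append("pvalue_out_of_range")
        if self.eaf is not None and not (np.isnan(self.eaf) or 0 <= self.eaf <= 1):
            problems.append("eaf_out_of_range")
        if not math.isfinite(self.beta):
            problems.append("nonfinite_beta")
        if not self.n > 0:
            problems.append("nonpositive_n")
        return problems

    @property
    def is_palindromic(self) -> bool:
        return {self.effect_allele, self.other_allele} in ({"A", "T"}, {"C", "G"})


@dataclass
class SummaryStats:
    """GWAS summary statistics for one trait.

    Backed by a :class:`pandas.DataFrame` with the canonical columns; rows are
    unique by ``variant_id``. Construct via :func:`read_summary_stats`,
    :meth:`from_records`, or directly from a canonical frame.
    """

    trait_label: str
    trait_type: str  # "binary" or "quantitative"
    df: pd.DataFrame

    def __post_init__(self) -> None:
        if self.trait_type not in ("binary", "quantitative"):
            raise ConfigurationError(
                f"trait_type must be 'binary' or 'quantitative', got {self.trait_type!r}"
            )
        missing = [c for c in CANONICAL_COLUMNS if c not in self.df.columns]
        if missing:
            raise ConfigurationError(f"summary-stat frame missing columns: {missing}")
        if self.df["variant_id"].duplicated().any():
            dupes = self.df.loc[self.df["variant_id"].duplicated(), "variant_id"]
            raise InputError(f"duplicate variant_id values: {sorted(set(dupes))[:5]} ...")

    @classmethod
    def from_records(
        cls, trait_label: str, trait_type: str, records: Iterable[VariantRecord]
    ) -> "SummaryStats":
        rows = [
            {
                "variant_id": r.variant_id,
                "chromosome": str(r.chromosome),
                "position": int(r.position),
                "effect_allele": r.effect_allele,
                "other_allele": r.other_allele,
                "eaf": np.nan if r.eaf is None else float(r.eaf),
                "beta": float(r.beta),
                "se": float(r.se),
                "pvalue": float(r.pvalue),
                "n": int(r.n),
            }
            for r in records
        ]
        df = pd.DataFrame(rows, columns=CANONICAL_COLUMNS)
        return cls(trait_label, trait_type, df)

    def records(self) -> list[VariantRecord]:
        out = []
        for row in self.df.itertuples(index=False):
            out.append(
                VariantRecord(
                    variant_id=row.variant_id,
                    chromosome=str(row.chromosome),
                    position=int(row.position),
                    effect_allele=row.effect_allele,
                    other_allele=row.other_allele,
                    eaf=None if pd.isna(row.eaf) else float(row.eaf),
                    beta=float(row.beta),
                    se=float(row.se),
                    pvalue=float(row.pvalue),
                    n=int(row.n),
                )
            )
        return out

    def __len__(self) -> int:
        return len(self.df)

    def subset(self, mask) -> "SummaryStats":
        """Row-subset preserving order; mask is boolean or an index list."""
        return SummaryStats(self.trait_label, self.trait_type, self.df.loc[mask].reset_index(drop=True))


@dataclass
class HarmonizedSet:
    """Exposure/outcome records aligned to the exposure's effect allele.

    ``df`` has one row per usable instrument with columns
    ``variant_id, chromosome, position, beta_exp, se_exp, beta_out, se_out,
    eaf, n_exp, n_out`` (gamma = ``beta_exp``, Gamma = ``beta_out`` in the
    usual two-sample MR notation). ``dropped`` records the variants from the
    intersection that could not be aligned, with a reason each.
    """

    exposure_label: str
    outcome_label: str
    df: pd.DataFrame
    dropped: list[tuple[str, str]] = field(default_factory=list)

    HARMONIZED_COLUMNS = [
        "variant_id",
        "chromosome",
        "position",
        "beta_exp",
        "se_exp",
        "beta_out",
        "se_out",
        "eaf",
        "n_exp",
        "n_out",
    ]

    def __len__(self) -> int:
        return len(self.df)

    @property
    def n_snps(self) -> int:
        return len(self.df)

    def subset(self, mask) -> "HarmonizedSet":
        return HarmonizedSet(
            self.exposure_label,
            self.outcome_label,
            self.df.loc[mask].reset_index(drop=True),
            list(self.dropped),
        )

    def drop_variant(self, variant_id: str) -> "HarmonizedSet":
        return self.subset(self.df["variant_id"] != variant_id)

    def to_tsv(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", index=False)


def _sniff_sep(path: Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def read_summary_stats(
    path: str | Path,
    dialect: str | Mapping[str, str] = "canonical",
    trait_label: str | None = None,
    trait_type: str = "quantitative",
) -> SummaryStats:
    """Read delimited-text summary statistics.

    Parameters
    ----------
    path
        Delimited text file with a header row (TSV by default; comma accepted).
    dialect
        Name of a built-in dialect (``canonical``, ``gwas_catalog``,
        ``exposure_outcome``) or a mapping from semantic column names
        (:data:`CANONICAL_COLUMNS`) to the file's header names. ``eaf`` and
        ``n`` may be omitted from the mapping; ``eaf`` is then missing and
        ``n`` must be supplied some other way by the caller downstream.
    trait_label, trait_type
        Label and kind ("binary" or "quantitative") of the trait.

    Rows violating a record invariant (non-positive SE, p-value outside
    (0, 1], identical or non-ACGT alleles, duplicate id ...) are dropped with
    a logged reason and count.
    """
    path = Path(path)
    if isinstance(dialect, str):
        try:
            colmap = DIALECTS[dialect]
        except KeyError:
            raise ConfigurationError(
                f"unknown dialect {dialect!r}; built-ins: {sorted(DIALECTS)}"
            ) from None
    else:
        colmap = dict(dialect)

    raw = pd.read_csv(path, sep=_sniff_sep(path), float_precision="round_trip")
    required = [c for c in CANONICAL_COLUMNS if c not in ("eaf",)]
    missing = [c for c in required if colmap.get(c, c) not in raw.columns]
    if missing:
        raise ConfigurationError(
            f"{path}: required columns missing for dialect: "
            f"{[colmap.get(c, c) for c in missing]}"
        )

    df = pd.DataFrame(index=raw.index)
    for sem in CANONICAL_COLUMNS:
        src = colmap.get(sem, sem)
        if src in raw.columns:
            df[sem] = raw[src]
        elif sem == "eaf":
            df[sem] = np.nan
        else:  # pragma: no cover - guarded above
            raise ConfigurationError(f"missing column {src}")

    df["variant_id"] = df["variant_id"].astype(str)
    df["chromosome"] = df["chromosome"].astype(str)
    df["effect_allele"] = df["effect_allele"].astype(str).str.upper()
    df["other_allele"] = df["other_allele"].astype(str).str.upper()
    for col in ("eaf", "beta", "se", "pvalue"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df["position"] = pd.to_numeric(df["position"], errors="coerce")
    df["n"] = pd.to_numeric(df["n"], errors="coerce")

    drop_reasons: dict[str, int] = {}

    def _mark(mask: pd.Series, reason: str) -> pd.Series:
        k = int(mask.sum())
        if k:
            drop_reasons[reason] = drop_reasons.get(reason, 0) + k
        return mask

    bad = _mark(~(df["se"] > 0) | ~np.isfinite(df["se"]), "nonpositive_se")
    bad |= _mark(~((df["pvalue"] > 0) & (df["pvalue"] <= 1)), "pvalue_out_of_range")
    bad |= _mark(~np.isfinite(df["beta"]), "nonfinite_beta")
    bad |= _mark(df["effect_allele"] == df["other_allele"], "identical_alleles")
    bad |= _mark(
        ~df["effect_allele"].isin(list(VALID_ALLELES))
        | ~df["other_allele"].isin(list(VALID_ALLELES)),
        "invalid_allele",
    )
    bad |= _mark(df["eaf"].notna() & ~df["eaf"].between(0, 1), "eaf_out_of_range")
    bad |= _mark(~(df["n"] > 0) | df["n"].isna(), "nonpositive_n")
    bad |= _mark(df["position"].isna() | (df["position"] < 1), "invalid_position")
    bad |= _mark(df["variant_id"].duplicated(), "duplicate_variant_id")

    n_dropped = int(bad.sum())
    if n_dropped:
        logger.warning(
            "%s: dropped %d/%d rows failing validation (%s)",
            path.name,
            n_dropped,
            len(df),
            ", ".join(f"{r}={k}" for r, k in sorted(drop_reasons.items())),
        )
    df = df.loc[~bad].reset_index(drop=True)
    if df.empty:
        raise InputError(f"{path}: no usable rows after validation")
    df["position"] = df["position"].astype(int)
    df["n"] = df["n"].astype(int)

    label = trait_label if trait_label is not None else path.stem
    stats = SummaryStats(label, trait_type, df[CANONICAL_COLUMNS])
    return stats


def write_summary_stats(stats: SummaryStats, path: str | Path) -> None:
    """Write a :class:`SummaryStats` to the canonical TSV dialect."""
    stats.df[CANONICAL_COLUMNS].to_csv(
        path, sep="\t", index=False, na_rep="NA", float_format="%.17g"
    )


def _is_palindromic(a1: pd.Series, a2: pd.Series) -> pd.Series:
    return ((a1 == "A") & (a2 == "T")) | ((a1 == "T") & (a2 == "A")) | (
        (a1 == "C") & (a2 == "G")
    ) | ((a1 == "G") & (a2 == "C"))


def harmonize(
    exposure: SummaryStats,
    outcome: SummaryStats,
    palindrome_eaf_window: float = 0.08,
) -> HarmonizedSet:
    """Align exposure and outcome records to the exposure's effect allele.

    The variant intersection is partitioned into kept rows and dropped
    variants. Pairs sharing the same effect/other alleles are kept as-is;
    pairs with swapped alleles are flipped (outcome beta negated, outcome eaf
    complemented). Strand-ambiguous palindromic pairs (A/T or C/G) are kept
    only when both effect-allele frequencies are available, both lie outside
    ``[0.5 - w, 0.5 + w]``, and the frequency-implied orientation agrees with
    the allele-implied one; otherwise they are dropped with reason
    ``palindromic_ambiguous``. Non-matching allele sets are dropped with
    reason ``allele_mismatch``.
    """
    if len(exposure) == 0 or len(outcome) == 0:
        raise InputError("harmonize requires non-empty exposure and outcome")

    w = float(palindrome_eaf_window)
    m = exposure.df.merge(
        outcome.df, on="variant_id", suffixes=("_exp", "_out"), how="inner"
    )
    if m.empty:
        raise InputError(
            f"no shared variants between exposure {exposure.trait_label!r} "
            f"and outcome {outcome.trait_label!r}"
        )

    ea_e, oa_e = m["effect_allele_exp"], m["other_allele_exp"]
    ea_o, oa_o = m["effect_allele_out"], m["other_allele_out"]

    same = (ea_e == ea_o) & (oa_e == oa_o)
    swapped = (ea_e == oa_o) & (oa_e == ea_o)
    pal = _is_palindromic(ea_e, oa_e)

    eaf_e, eaf_o = m["eaf_exp"], m["eaf_out"]
    eaf_informative = (
        eaf_e.notna()
        & eaf_o.notna()
        & ((eaf_e - 0.5).abs() > w)
        & ((eaf_o - 0.5).abs() > w)
    )
    # Orientation implied by frequency: same side of 0.5 -> same orientation.
    freq_same = (eaf_e < 0.5) == (eaf_o < 0.5)

    keep_plain = ~pal & same
    flip_plain = ~pal & swapped
    keep_pal = pal & same & eaf_informative & freq_same
    flip_pal = pal & swapped & eaf_informative & ~freq_same

    keep = keep_plain | keep_pal
    flip = flip_plain | flip_pal
    mismatch = ~(same | swapped)

    out = pd.DataFrame(
        {
            "variant_id": m["variant_id"],
            "chromosome": m["chromosome_exp"].astype(str),
            "position": m["position_exp"].astype(int),
            "beta_exp": m["beta_exp"].astype(float),
            "se_exp": m["se_exp"].astype(float),
            "beta_out": np.where(flip, -m["beta_out"], m["beta_out"]).astype(float),
            "se_out": m["se_out"].astype(float),
            "eaf": m["eaf_exp"].astype(float),
            "n_exp": m["n_exp"].astype(int),
            "n_out": m["n_out"].astype(int),
        }
    )

    kept_mask = (keep | flip).to_numpy()
    dropped: list[tuple[str, str]] = []
    for vid, is_mismatch in zip(m.loc[~kept_mask, "variant_id"], mismatch[~kept_mask]):
        dropped.append((vid, "allele_mismatch" if is_mismatch else "palindromic_ambiguous"))
    if dropped:
        logger.info(
            "harmonize(%s -> %s): dropped %d of %d shared variants",
            exposure.trait_label,
            outcome.trait_label,
            len(dropped),
            len(m),
        )

    return HarmonizedSet(
        exposure_label=exposure.trait_label,
        outcome_label=outcome.trait_label,
        df=out.loc[kept_mask].reset_index(drop=True),
        dropped=dropped,
    )
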