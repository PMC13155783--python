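"""Reading, validating and writing GWAS summary statistics.

The canonical on-disk dialect is a tab-separated UTF-8 file with a header
row and the columns::

    snp_id  chrom  pos  effect_allele  other_allele  eaf  beta  se  pval  n

Positions are 1-based, alleles are upper-cased single bases, missing
effect-allele frequency is written as ``NA``, and the decimal separator is
always a point. Alternate column names in source files are mapped through a
``dialect`` dictionary at read time. Rows violating hard invariants
(non-positive SE, out-of-range p-value or frequency, malformed alleles) are
dropped and itemised in a rejection report rather than aborting the read.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CANONICAL_COLUMNS",
    "MANDATORY_COLUMNS",
    "VariantAssociation",
    "SummaryDataset",
    "SummaryFormatError",
    "EmptyDatasetError",
    "read_summary",
    "write_summary",
]

CANONICAL_COLUMNS = [
    "snp_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pval",
    "n",
]

MANDATORY_COLUMNS = ["snp_id", "effect_allele", "other_allele", "beta", "se", "pval"]

_BASES = frozenset("ACGT")


class SummaryFormatError(ValueError):
    """A summary-statistics file is structurally unusable (e.g. missing column)."""


class EmptyDatasetError(ValueError):
    """No valid variant rows remain after validation."""


@dataclass(frozen=True)
class VariantAssociation:
    """One SNP's summary association with one trait.

    ``beta`` is in SD units for continuous traits and log-odds for binary
    ones; ``eaf`` (effect-allele frequency) may be ``None`` when the source
    GWAS did not report it.
    """

    snp_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pval: float
    chrom: str = ""
    pos: int = 0
    eaf: float | None = None
    n: int = 0

    def __post_init__(self) -> None:
        for reason in _row_problems(
            self.effect_allele, self.other_allele, self.eaf, self.se, self.pval
        ):
            raise ValueError(f"{self.snp_id}: {reason}")


def _row_problems(ea, oa, eaf, se, pval) -> list[str]:
    """Hard-invariant violations for one row; empty list means valid."""
    problems = []
    if not (isinstance(ea, str) and ea in _BASES):
        problems.append("invalid effect allele")
    if not (isinstance(oa, str) and oa in _BASES):
        problems.append("invalid other allele")
    if isinstance(ea, str) and isinstance(oa, str) and ea == oa:
        problems.append("identical alleles")
    if not np.isfinite(se) or se <= 0:
        problems.append("nonpositive se")
    if not np.isfinite(pval) or not (0.0 < pval <= 1.0):
        problems.append("pval out of (0,1]")
    if eaf is not None and not np.isnan(eaf) and not (0.0 <= eaf <= 1.0):
        problems.append("eaf out of [0,1]")
    return problems


@dataclass
class SummaryDataset:
    """GWAS summary statistics for one trait.

    ``records`` is a DataFrame with the canonical columns, unique by
    ``snp_id``. ``scale`` distinguishes continuous (SD-unit) betas from
    binary-trait log-odds.
    """

    trait_id: str
    records: pd.DataFrame
    trait_role: str = "exposure"  # exposure | mediator | outcome
    scale: str = "continuous_sd"  # continuous_sd | log_odds

    def __post_init__(self) -> None:
        if self.trait_role not in ("exposure", "mediator", "outcome"):
            raise ValueError(f"unknown trait_role {self.trait_role!r}")
        if self.scale not in ("continuous_sd", "log_odds"):
            raise ValueError(f"unknown scale {self.scale!r}")
        df = pd.DataFrame(self.records)
        missing = [c for c in CANONICAL_COLUMNS if c not in df.columns]
        if missing:
            raise SummaryFormatError(f"missing columns: {', '.join(missing)}")
        if len(df) == 0:
            raise EmptyDatasetError(f"{self.trait_id}: no variant records")
        if df["snp_id"].duplicated().any():
            dups = df.loc[df["snp_id"].duplicated(), "snp_id"].tolist()
            raise ValueError(f"duplicate snp_id: {dups[:5]}")
        self.records = df[CANONICAL_COLUMNS].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def snp_ids(self) -> list[str]:
        return self.records["snp_id"].tolist()

    def subset(self, snp_ids: Iterable[str]) -> "SummaryDataset":
        """Restrict to the given SNPs, preserving this dataset's row order."""
        keep = self.records[self.records["snp_id"].isin(set(snp_ids))]
        return SummaryDataset(self.trait_id, keep, self.trait_role, self.scale)

    def to_associations(self) -> list[VariantAssociation]:
        out = []
        for row in self.records.itertuples(index=False):
            eaf = None if pd.isna(row.eaf) else float(row.eaf)
            out.append(
                VariantAssociation(
                    snp_id=str(row.snp_id),
                    chrom=str(row.chrom),
                    pos=int(row.pos),
                    effect_allele=str(row.effect_allele),
                    other_allele=str(row.other_allele),
                    eaf=eaf,
                    beta=float(row.beta),
                    se=float(row.se),
                    pval=float(row.pval),
                    n=int(row.n),
                )
            )
        return out


def _validate_frame(df: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a raw frame into (valid rows, rejection report)."""
    rejections: list[tuple[str, str]] = []
    keep_mask = np.ones(len(df), dtype=bool)
    for i, row in enumerate(df.itertuples(index=False)):
        eaf = None if pd.isna(row.eaf) else float(row.eaf)
        problems = _row_problems(row.effect_allele, row.other_allele, eaf, row.se, row.pval)
        if problems:
            keep_mask[i] = False
            rejections.append((str(row.snp_id), "; ".join(problems)))
    valid = df[keep_mask].reset_index(drop=True)
    report = pd.DataFrame(rejections, columns=["snp_id", "reason"])
    return valid, report


def _warn_inconsistent_pvals(df: pd.DataFrame, trait_id: str) -> None:
    # |beta/se| should reproduce pval under a two-sided normal test; a
    # factor-of-2 mismatch usually means mixed-up columns upstream.
    z = np.abs(df["beta"].to_numpy() / df["se"].to_numpy())
    implied = 2.0 * stats.norm.sf(z)
    reported = df["pval"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(implied > 0, reported / implied, np.inf)
    bad = (ratio > 2.0) | (ratio < 0.5)
    # very small p-values lose precision in text files; only flag moderate ones
    bad &= reported > 1e-30
    if bad.any():
        ids = df.loc[bad, "snp_id"].head(5).tolist()
        warnings.warn(
            f"{trait_id}: {int(bad.sum())} rows have p-values inconsistent with "
            f"|beta/se| beyond a factor of 2 (e.g. {ids})",
            stacklevel=3,
        )


def read_summary(
    path,
    dialect: Mapping[str, str] | None = None,
    trait_id: str | None = None,
    trait_role: str = "exposure",
    scale: str = "continuous_sd",
    return_rejections: bool = False,
):
    """Read a delimited summary-statistics file into a :class:`SummaryDataset`.

    Parameters
    ----------
    path
        Tab-separated file with a header row.
    dialect
        Mapping from canonical column name to the name used in the file,
        e.g. ``{"snp_id": "SNP", "pval": "P"}``. Unmapped canonical names
        are looked up verbatim.
    return_rejections
        If true, also return the rejection report DataFrame
        (columns ``snp_id``, ``reason``) for rows dropped by validation.
    """
    dialect = dict(dialect or {})
    raw = pd.read_csv(path, sep="\t", dtype={0: str}, na_values=["NA"])
    rename = {}
    for canon in CANONICAL_COLUMNS:
        src = dialect.get(canon, canon)
        if src in raw.columns:
            rename[src] = canon
    raw = raw.rename(columns=rename)
    missing = [c for c in MANDATORY_COLUMNS if c not in raw.columns]
    if missing:
        raise SummaryFormatError(
            f"{path}: missing mandatory column(s): {', '.join(missing)}"
        )
    for col, default in (("chrom", ""), ("pos", 0), ("eaf", np.nan), ("n", 0)):
        if col not in raw.columns:
            raw[col] = default
    raw["snp_id"] = raw["snp_id"].astype(str)
    raw["chrom"] = raw["chrom"].fillna("").astype(str)
    raw["pos"] = raw["pos"].fillna(0).astype(np.int64)
    raw["n"] = raw["n"].fillna(0).astype(np.int64)
    for col in ("eaf", "beta", "se", "pval"):
        raw[col] = pd.to_numeric(raw[col], errors="coerce")
    raw["effect_allele"] = raw["effect_allele"].astype(str).str.upper()
    raw["other_allele"] = raw["other_allele"].astype(str).str.upper()

    valid, rejections = _validate_frame(raw[CANONICAL_COLUMNS])
    if len(valid) == 0:
        raise EmptyDatasetError(f"{path}: zero valid rows after validation")
    _warn_inconsistent_pvals(valid, trait_id or str(path))
    ds = SummaryDataset(
        trait_id=trait_id or str(path),
        records=valid,
        trait_role=trait_role,
        scale=scale,
    )
    if return_rejections:
        return ds, rejections
    return ds


def write_summary(ds: SummaryDataset, path) -> None:
    """Write a dataset in the canonical tab-separated dialect.

    ``read_summary(write_summary(ds))`` round-trips record-for-record.
    """
    if len(ds) == 0:  # SummaryDataset forbids this, but guard direct misuse
        raise EmptyDatasetError(f"{ds.trait_id}: refusing to write empty dataset")
    out = ds.records.copy()
    # %.17g guarantees exact float64 round-trips through text
    out.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.17g")


def write_rejections(report: pd.DataFrame, path) -> None:
    """Write a rejection report (snp_id, reason) as TSV."""
    report.to_csv(path, sep="\t", index=False)
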