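"""Instrument selection, strength filtering and allele harmonization.

Instruments are genome-wide-significant-ish SNPs for the exposure
(default threshold p < 1e-5, relaxed from 5e-8 to keep enough variants for
molecular phenotypes), pruned for linkage disequilibrium by greedy clumping
(default window 10,000 kb, r^2 < 0.001) and strength-checked with the
instrument F-statistic

    F = [R^2 (N - 1 - K)] / [K (1 - R^2)]

where R^2 is the exposure variance explained by the K kept SNPs and N the
exposure GWAS sample size. Sets with F <= 10 are flagged weak and excluded
downstream.

Harmonization aligns outcome effect sizes to the exposure's effect allele:
swapped allele labels flip the outcome beta's sign, palindromic (A/T, C/G)
SNPs are kept only when both allele frequencies fall outside the ambiguity
band and on the same side of 0.5, and irreconcilable allele pairs are
dropped. Every exclusion is reported with its reason.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from mrmediate.summary_io import SummaryDataset

__all__ = [
    "InstrumentSet",
    "HarmonizedSet",
    "select_instruments",
    "f_statistic",
    "filter_weak",
    "harmonize",
    "NoInstrumentsError",
]

logger = logging.getLogger(__name__)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class NoInstrumentsError(ValueError):
    """No SNP passes the instrument significance threshold."""


@dataclass
class InstrumentSet:
    """A clumped set of instruments for one exposure.

    ``r2_total`` is the proportion of exposure variance jointly explained
    (sum of per-SNP ``2 p (1-p) beta^2``, or the frequency-free
    ``beta^2 / (beta^2 + n se^2)`` fallback); ``f_stat`` the instrument
    F-statistic; ``weak`` marks sets failing the strength filter.
    """

    exposure_id: str
    snps: list[str]
    r2_total: float
    n_gwas: int
    f_stat: float = field(init=False)
    weak: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.r2_total < 1.0:
            raise ValueError("r2_total must be in [0, 1)")
        self.f_stat = f_statistic(self.r2_total, self.n_gwas, self.k)

    @property
    def k(self) -> int:
        return len(self.snps)


@dataclass
class HarmonizedSet:
    """Exposure/outcome betas aligned to a common effect allele.

    ``table`` columns: snp_id, effect_allele, other_allele, beta_exp,
    se_exp, eaf_exp, beta_out, se_out, eaf_out (outcome values re-signed /
    re-oriented to the exposure's effect allele). ``dropped`` lists
    (snp_id, reason) for every excluded instrument.
    """

    exposure_id: str
    outcome_id: str
    table: pd.DataFrame
    dropped: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        dropped_ids = {s for s, _ in self.dropped}
        overlap = dropped_ids & set(self.table["snp_id"])
        if overlap:
            raise ValueError(f"SNPs both aligned and dropped: {sorted(overlap)[:5]}")
        if len(self.table) and not (
            (self.table["se_exp"] > 0).all() and (self.table["se_out"] > 0).all()
        ):
            raise ValueError("harmonized SEs must be positive")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def beta_exp(self) -> np.ndarray:
        return self.table["beta_exp"].to_numpy(dtype=float)

    @property
    def se_exp(self) -> np.ndarray:
        return self.table["se_exp"].to_numpy(dtype=float)

    @property
    def beta_out(self) -> np.ndarray:
        return self.table["beta_out"].to_numpy(dtype=float)

    @property
    def se_out(self) -> np.ndarray:
        return self.table["se_out"].to_numpy(dtype=float)

    @property
    def snp_ids(self) -> list[str]:
        return self.table["snp_id"].tolist()

    def drop_snps(self, snp_ids, reason: str = "outlier") -> "HarmonizedSet":
        """Return a copy without the given SNPs (e.g. MR-PRESSO outliers)."""
        snp_ids = set(snp_ids)
        keep = self.table[~self.table["snp_id"].isin(snp_ids)].reset_index(drop=True)
        return HarmonizedSet(
            self.exposure_id,
            self.outcome_id,
            keep,
            self.dropped + [(s, reason) for s in sorted(snp_ids)],
        )


def f_statistic(r2_total: float, n_gwas: int, k: int) -> float:
    """Instrument-strength F-statistic, F = [R^2 (N-1-K)] / [K (1-R^2)]."""
    if not 0.0 <= r2_total < 1.0:
        raise ValueError(f"r2_total must be in [0, 1), got {r2_total}")
    if k < 1:
        raise ValueError("k must be >= 1")
    if n_gwas <= k + 1:
        raise ValueError(f"n_gwas must exceed k+1 (got n={n_gwas}, k={k})")
    return (r2_total * (n_gwas - 1 - k)) / (k * (1.0 - r2_total))


def _variance_explained(rows: pd.DataFrame) -> float:
    """Per-SNP exposure variance explained, summed over kept instruments.

    Uses 2 p (1-p) beta^2 where the effect-allele frequency is known and
    the frequency-free approximation beta^2 / (beta^2 + n se^2) otherwise.
    """
    eaf = rows["eaf"].to_numpy(dtype=float)
    beta = rows["beta"].to_numpy(dtype=float)
    se = rows["se"].to_numpy(dtype=float)
    n = rows["n"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        by_freq = 2.0 * eaf * (1.0 - eaf) * beta**2
        fallback = beta**2 / (beta**2 + n * se**2)
    have_freq = ~np.isnan(eaf)
    have_n = n > 0
    per_snp = np.where(have_freq, by_freq, np.where(have_n, fallback, 0.0))
    return float(np.minimum(per_snp, 1.0).sum())


def greedy_clump(
    frame: pd.DataFrame,
    ld: pd.DataFrame | None,
    kb_window: float,
    r2_threshold: float,
) -> list[str]:
    """Greedy p-value-ordered LD clumping; returns kept snp_ids.

    Sort ascending by p (ties: chrom, pos, snp_id); keep the best SNP and
    discard every remaining SNP with r^2 >= ``r2_threshold`` to a kept SNP
    within ``kb_window`` kb on the same chromosome; repeat. SNPs absent
    from the LD matrix are treated as unlinked.
    """
    order = frame.sort_values(
        ["pval", "chrom", "pos", "snp_id"], kind="mergesort"
    ).reset_index(drop=True)
    window_bp = kb_window * 1000.0
    kept: list[int] = []
    missing_warned = False
    for i in range(len(order)):
        row = order.iloc[i]
        pruned = False
        for ki in kept:
            kept_row = order.iloc[ki]
            if kept_row["chrom"] != row["chrom"]:
                continue
            if abs(int(kept_row["pos"]) - int(row["pos"])) > window_bp:
                continue
            r2 = 0.0
            if ld is not None:
                try:
                    r2 = float(ld.at[row["snp_id"], kept_row["snp_id"]])
                except KeyError:
                    if not missing_warned:
                        logger.warning(
                            "SNPs missing from LD matrix treated as unlinked "
                            "(first: %s)", row["snp_id"],
                        )
                        missing_warned = True
            if r2 >= r2_threshold:
                pruned = True
                break
        if not pruned:
            kept.append(i)
    return order.iloc[kept]["snp_id"].tolist()


def select_instruments(
    exposure: SummaryDataset,
    p_threshold: float = 1e-5,
    ld: pd.DataFrame | None = None,
    kb_window: float = 10_000,
    r2_threshold: float = 0.001,
) -> InstrumentSet:
    """Select and clump instruments for an exposure.

    Raises :class:`NoInstrumentsError` when nothing passes ``p_threshold``;
    callers screening many exposures should catch it and skip the trait.
    """
    if not 0.0 < p_threshold < 1.0:
        raise ValueError("p_threshold must be in (0,1)")
    candidates = exposure.records[exposure.records["pval"] < p_threshold]
    if len(candidates) == 0:
        raise NoInstrumentsError(
            f"{exposure.trait_id}: no SNP passes p < {p_threshold:g}"
        )
    kept = greedy_clump(candidates, ld, kb_window, r2_threshold)
    rows = exposure.records.set_index("snp_id").loc[kept].reset_index()
    r2_total = min(_variance_explained(rows), 1.0 - 1e-12)
    n_gwas = int(rows["n"].max())
    if n_gwas <= len(kept) + 1:
        # degenerate tiny-n corner: F undefined, flag as weak via r2=0
        n_gwas = len(kept) + 2
        r2_total = 0.0
    return InstrumentSet(
        exposure_id=exposure.trait_id,
        snps=kept,
        r2_total=r2_total,
        n_gwas=n_gwas,
    )


def filter_weak(inst: InstrumentSet, f_min: float = 10.0) -> InstrumentSet:
    """Flag instrument sets with F <= ``f_min`` as weak (strict F > f_min passes)."""
    if inst.f_stat > f_min:
        return inst
    flagged = InstrumentSet(
        exposure_id=inst.exposure_id,
        snps=list(inst.snps),
        r2_total=inst.r2_total,
        n_gwas=inst.n_gwas,
    )
    flagged.weak = True
    warnings.warn(
        f"{inst.exposure_id}: instrument F = {inst.f_stat:.2f} <= {f_min:g}; "
        "set flagged weak and excluded from estimation",
        stacklevel=2,
    )
    return flagged


def _is_palindromic(ea: str, oa: str) -> bool:
    return _COMPLEMENT.get(ea) == oa


def harmonize(
    inst,
    exposure: SummaryDataset,
    outcome: SummaryDataset,
    palindromic_eaf_band: tuple[float, float] = (0.42, 0.58),
) -> HarmonizedSet:
    """Align outcome associations to the exposure's effect alleles.

    ``inst`` is an :class:`InstrumentSet` or a plain list of snp_ids.

    Rules, applied per instrument SNP:

    * absent from the outcome GWAS -> dropped ``"missing in outcome"``;
    * same allele pair -> kept as-is; swapped pair -> outcome beta sign
      flipped and outcome EAF complemented;
    * palindromic SNPs (allele pair is its own reverse complement) are kept
      only when both EAFs lie outside ``palindromic_eaf_band`` and on the
      same side of 0.5, else dropped ``"palindromic-ambiguous"``;
    * any other allele combination -> dropped ``"allele mismatch"``.
    """
    lo, hi = palindromic_eaf_band
    if isinstance(inst, InstrumentSet):
        snps, exposure_id = inst.snps, inst.exposure_id
    else:
        snps, exposure_id = list(inst), exposure.trait_id
    exp_rows = exposure.records.set_index("snp_id")
    out_rows = outcome.records.set_index("snp_id")
    aligned = []
    dropped: list[tuple[str, str]] = []
    for snp in snps:
        if snp not in exp_rows.index:
            dropped.append((snp, "missing in exposure"))
            continue
        e = exp_rows.loc[snp]
        if snp not in out_rows.index:
            dropped.append((snp, "missing in outcome"))
            continue
        o = out_rows.loc[snp]
        e_ea, e_oa = e["effect_allele"], e["other_allele"]
        o_ea, o_oa = o["effect_allele"], o["other_allele"]
        if (o_ea, o_oa) == (e_ea, e_oa):
            beta_out, eaf_out = float(o["beta"]), float(o["eaf"])
        elif (o_ea, o_oa) == (e_oa, e_ea):
            beta_out = -float(o["beta"])
            eaf_out = 1.0 - float(o["eaf"]) if not pd.isna(o["eaf"]) else np.nan
        else:
            dropped.append((snp, "allele mismatch"))
            continue
        if _is_palindromic(e_ea, e_oa):
            eaf_exp = float(e["eaf"]) if not pd.isna(e["eaf"]) else np.nan
            ambiguous = (
                np.isnan(eaf_exp)
                or np.isnan(eaf_out)
                or (lo < eaf_exp < hi)
                or (lo < eaf_out < hi)
                or (eaf_exp - 0.5) * (eaf_out - 0.5) <= 0
            )
            if ambiguous:
                dropped.append((snp, "palindromic-ambiguous"))
                continue
        aligned.append(
            {
                "snp_id": snp,
                "effect_allele": e_ea,
                "other_allele": e_oa,
                "beta_exp": float(e["beta"]),
                "se_exp": float(e["se"]),
                "eaf_exp": float(e["eaf"]) if not pd.isna(e["eaf"]) else np.nan,
                "beta_out": beta_out,
                "se_out": float(o["se"]),
                "eaf_out": eaf_out,
            }
        )
    table = pd.DataFrame(
        aligned,
        columns=[
            "snp_id", "effect_allele", "other_allele", "beta_exp", "se_exp",
            "eaf_exp", "beta_out", "se_out", "eaf_out",
        ],
    )
    return HarmonizedSet(
        exposure_id=exposure_id,
        outcome_id=outcome.trait_id,
        table=table,
        dropped=dropped,
    )


def harmonization_report(h: HarmonizedSet) -> pd.DataFrame:
    """Dropped-SNP report as a DataFrame (snp_id, reason)."""
    return pd.DataFrame(h.dropped, columns=["snp_id", "reason"])
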