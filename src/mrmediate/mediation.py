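"""Two-step mediation MR: decomposition, masking rule, reverse check, screening.

The total causal effect *c* of an exposure on the outcome is split into an
indirect path through a mediator and a direct remainder::

    ab = a * b          (a: exposure->mediator, b: mediator->outcome)
    c' = c - a * b      (direct effect)
    proportion mediated = ab / c

with the product-of-coefficients SE by the first-order delta method,
``se(ab) = sqrt(a^2 se_b^2 + b^2 se_a^2)``. A candidate whose mediated
effect opposes the total effect in sign is a *masking* (suppression)
effect and is excluded from mediation-proportion reporting.

``screen`` runs the multi-stage funnel over many candidate exposures and
mediators: (1) exposures causally associated with the outcome at IVW
p < 0.05; (2) drop exposures failing the heterogeneity/pleiotropy
sensitivity gates; (3) keep mediators with both exposure->mediator and
mediator->outcome IVW p < 0.05; (4) decompose and classify. ``reverse_mr``
re-runs the forward chain with roles swapped to rule out reverse
causation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from mrmediate.estimators import EstimationError, MREstimate, ivw
from mrmediate.instruments import (
    HarmonizedSet,
    NoInstrumentsError,
    filter_weak,
    harmonize,
    select_instruments,
)
from mrmediate.sensitivity import SensitivityReport, sensitivity_report
from mrmediate.summary_io import SummaryDataset

__all__ = [
    "MRConfig",
    "MediationResult",
    "ScreenReport",
    "decompose",
    "classify_mediator",
    "forward_mr",
    "reverse_mr",
    "screen",
    "mediation_table",
]


@dataclass(frozen=True)
class MRConfig:
    """Pipeline thresholds and Monte-Carlo settings.

    Defaults mirror the screening design: instrument p < 1e-5, clumping
    window 10,000 kb at r^2 < 0.001, instrument F > 10, significance gate
    p < 0.05, no multiple-testing correction (set ``fdr=True`` to apply
    Benjamini-Hochberg at stage 1 instead).
    """

    p_threshold: float = 1e-5
    kb_window: float = 10_000
    r2_threshold: float = 0.001
    f_min: float = 10.0
    palindromic_eaf_band: tuple[float, float] = (0.42, 0.58)
    alpha: float = 0.05
    ivw_model: str = "multiplicative_random"
    n_sim: int = 1000
    n_boot: int = 1000
    seed: int = 0
    fdr: bool = False
    run_sensitivity: bool = True


@dataclass
class MediationResult:
    """Decomposition of one exposure-mediator-outcome triple.

    ``ab`` may have been rounded (see :func:`decompose`); ``c_prime`` and
    ``proportion`` are always derived from the ``ab`` stored here, so the
    identity ``c_prime = c_total - ab`` holds to machine precision.
    ``proportion`` is ``nan`` when the total effect is zero.
    """

    exposure_id: str
    mediator_id: str
    outcome_id: str
    c_total: float
    a_effect: float
    b_effect: float
    ab: float
    c_prime: float = field(init=False)
    proportion: float = field(init=False)
    ab_se: float | None = None
    classification: str = field(init=False)
    reverse_total: float | None = None

    def __post_init__(self) -> None:
        self.c_prime = self.c_total - self.ab
        if self.c_total == 0.0:
            self.proportion = float("nan")
            warnings.warn(
                f"{self.exposure_id}->{self.outcome_id}: zero total effect, "
                "proportion mediated undefined",
                stacklevel=3,
            )
        else:
            self.proportion = self.ab / self.c_total
        self.classification = (
            "masking"
            if self.ab != 0.0 and np.sign(self.ab) != np.sign(self.c_total)
            else "mediation"
        )


def decompose(
    c_total: float,
    a_effect: float,
    b_effect: float,
    a_se: float | None = None,
    b_se: float | None = None,
    rounding: int | None = None,
    exposure_id: str = "exposure",
    mediator_id: str = "mediator",
    outcome_id: str = "outcome",
) -> MediationResult:
    """Product-of-coefficients mediation decomposition.

    ``rounding`` optionally rounds ``ab`` to that many decimals *before*
    deriving the direct effect and the proportion mediated, reproducing
    published tables computed from rounded intermediates; leave ``None``
    for full precision. The delta-method SE of ``ab`` is computed when
    both coefficient SEs are given.
    """
    ab = a_effect * b_effect
    if rounding is not None:
        ab = round(ab, rounding)
    ab_se = None
    if a_se is not None and b_se is not None:
        if a_se <= 0 or b_se <= 0:
            raise ValueError("coefficient SEs must be positive")
        ab_se = float(np.sqrt(a_effect**2 * b_se**2 + b_effect**2 * a_se**2))
    return MediationResult(
        exposure_id=exposure_id,
        mediator_id=mediator_id,
        outcome_id=outcome_id,
        c_total=c_total,
        a_effect=a_effect,
        b_effect=b_effect,
        ab=ab,
        ab_se=ab_se,
    )


def classify_mediator(res: MediationResult) -> str:
    """``"masking"`` iff the mediated effect opposes the total effect in sign.

    Masking (suppression) candidates are excluded from mediation-proportion
    reporting; a zero ``ab`` is degenerate mediation.
    """
    return res.classification


def forward_mr(
    exposure: SummaryDataset,
    outcome: SummaryDataset,
    config: MRConfig = MRConfig(),
    ld: pd.DataFrame | None = None,
) -> tuple[MREstimate, HarmonizedSet]:
    """Instrument selection -> strength filter -> harmonization -> IVW.

    The single-path building block used by both the forward screen and the
    reverse-causation check. Raises :class:`NoInstrumentsError` when the
    exposure has no instruments and :class:`EstimationError` when fewer
    than two harmonized SNPs remain or the instrument set is weak.
    """
    inst = select_instruments(
        exposure,
        p_threshold=config.p_threshold,
        ld=ld,
        kb_window=config.kb_window,
        r2_threshold=config.r2_threshold,
    )
    inst = filter_weak(inst, f_min=config.f_min)
    if inst.weak:
        raise EstimationError(
            f"{exposure.trait_id}: weak instruments (F = {inst.f_stat:.2f})"
        )
    h = harmonize(inst, exposure, outcome, config.palindromic_eaf_band)
    return ivw(h, model=config.ivw_model), h


def reverse_mr(
    outcome: SummaryDataset,
    exposure: SummaryDataset,
    config: MRConfig = MRConfig(),
    ld: pd.DataFrame | None = None,
) -> MREstimate:
    """Reverse-causation check: the forward chain with roles swapped.

    Instruments are selected from the *outcome* GWAS and the original
    exposure becomes the outcome. A reverse IVW p >= 0.05 supports
    retaining the forward pair; a significant reverse effect signals
    reverse causation. Raises :class:`NoInstrumentsError` when the outcome
    trait has no instruments (the check is then not evaluable).
    """
    est, _ = forward_mr(outcome, exposure, config=config, ld=ld)
    return est


@dataclass
class ScreenReport:
    """Per-stage survivors of the screening funnel plus final results."""

    stage1_exposures: list[str]
    stage2_exposures: list[str]
    stage3_pairs: list[tuple[str, str]]
    results: list[MediationResult]
    exposure_estimates: dict[str, MREstimate]
    sensitivity: dict[str, SensitivityReport]
    skipped: list[tuple[str, str]]

    def counts(self) -> dict[str, int]:
        return {
            "stage1_significant_exposures": len(self.stage1_exposures),
            "stage2_sensitivity_clean": len(self.stage2_exposures),
            "stage3_mediator_pairs": len(self.stage3_pairs),
            "stage4_mediation_results": len(
                [r for r in self.results if r.classification == "mediation"]
            ),
        }


def _bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    n = len(pvals)
    order = np.argsort(pvals)
    ranked = pvals[order] * n / (np.arange(n) + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def screen(
    exposures: list[SummaryDataset],
    mediators: list[SummaryDataset],
    outcome: SummaryDataset,
    config: MRConfig = MRConfig(),
    ld: pd.DataFrame | None = None,
) -> ScreenReport:
    """Multi-stage exposure/mediator screening funnel.

    Stage 1 keeps exposures whose IVW effect on the outcome is significant
    at ``config.alpha`` (BH-adjusted when ``config.fdr``). Stage 2 drops
    exposures failing the heterogeneity/pleiotropy verdict. Stage 3, per
    surviving exposure, keeps mediators with significant exposure->mediator
    *and* mediator->outcome IVW effects. Stage 4 decomposes each surviving
    triple and classifies mediation vs masking. Exposures or mediators
    without usable instruments are skipped and recorded, never fatal.
    """
    skipped: list[tuple[str, str]] = []
    exposure_estimates: dict[str, MREstimate] = {}
    harmonized: dict[str, HarmonizedSet] = {}

    for exp in exposures:
        try:
            est, h = forward_mr(exp, outcome, config=config, ld=ld)
        except (NoInstrumentsError, EstimationError) as exc:
            skipped.append((exp.trait_id, str(exc)))
            continue
        exposure_estimates[exp.trait_id] = est
        harmonized[exp.trait_id] = h

    ids = list(exposure_estimates)
    pvals = np.array([exposure_estimates[i].pval for i in ids])
    if config.fdr and len(pvals):
        pvals = _bh_adjust(pvals)
    stage1 = [i for i, p in zip(ids, pvals) if p < config.alpha]

    sensitivity: dict[str, SensitivityReport] = {}
    stage2 = []
    for trait in stage1:
        if not config.run_sensitivity:
            stage2.append(trait)
            continue
        h = harmonized[trait]
        if len(h) < 3:
            stage2.append(trait)  # too few SNPs to gate on diagnostics
            continue
        rep = sensitivity_report(h, n_sim=config.n_sim, seed=config.seed)
        sensitivity[trait] = rep
        if rep.passes:
            stage2.append(trait)

    exposures_by_id = {e.trait_id: e for e in exposures}
    stage3: list[tuple[str, str]] = []
    results: list[MediationResult] = []
    for trait in stage2:
        exp = exposures_by_id[trait]
        c_est = exposure_estimates[trait]
        for med in mediators:
            try:
                a_est, _ = forward_mr(exp, med, config=config, ld=ld)
                b_est, _ = forward_mr(med, outcome, config=config, ld=ld)
            except (NoInstrumentsError, EstimationError) as exc:
                skipped.append((f"{trait}->{med.trait_id}", str(exc)))
                continue
            if a_est.pval < config.alpha and b_est.pval < config.alpha:
                stage3.append((trait, med.trait_id))
                res = decompose(
                    c_total=c_est.beta,
                    a_effect=a_est.beta,
                    b_effect=b_est.beta,
                    a_se=a_est.se,
                    b_se=b_est.se,
                    exposure_id=trait,
                    mediator_id=med.trait_id,
                    outcome_id=outcome.trait_id,
                )
                results.append(res)

    return ScreenReport(
        stage1_exposures=stage1,
        stage2_exposures=stage2,
        stage3_pairs=stage3,
        results=results,
        exposure_estimates=exposure_estimates,
        sensitivity=sensitivity,
        skipped=skipped,
    )


def mediation_table(results: list[MediationResult]) -> pd.DataFrame:
    """Tabulate decompositions with the standard column layout.

    Columns: exposure, mediator, outcome, c, a, b, ab, proportion, c_prime,
    classification. Masking candidates are listed but their proportion is
    not meaningful as a mediated share.
    """
    rows = [
        {
            "exposure": r.exposure_id,
            "mediator": r.mediator_id,
            "outcome": r.outcome_id,
            "c": r.c_total,
            "a": r.a_effect,
            "b": r.b_effect,
            "ab": r.ab,
            "proportion": r.proportion,
            "c_prime": r.c_prime,
            "classification": r.classification,
        }
        for r in results
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "exposure", "mediator", "outcome", "c", "a", "b", "ab",
            "proportion", "c_prime", "classification",
        ],
    )
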