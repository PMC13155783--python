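"""Causal-effect estimators for two-sample summary-data MR.

All five estimators operate on a :class:`~mrmediate.instruments.HarmonizedSet`
and share the per-SNP Wald ratio ``beta_out / beta_exp`` as their primitive:

* **IVW** — weighted least squares of outcome on exposure betas through the
  origin, weights ``se_out^-2``; algebraically the ``se^-2``-weighted mean
  of Wald ratios. The default multiplicative random-effects variant
  inflates the SE by ``sqrt(max(1, Q/(k-1)))``.
* **MR-Egger** — the same regression with a free intercept after orienting
  all SNPs to non-negative exposure betas; the intercept and its p-value
  are the directional-pleiotropy test.
* **Weighted median** — inverse-variance-weighted median of the ratio
  estimates; consistent when valid instruments carry >50% of the weight.
* **Simple / weighted mode** — argmax of a normal-kernel density over the
  ratios (uniform or ``se^-2`` weights); consistent when the largest group
  of instruments sharing one ratio is valid.

Median and mode SEs come from a seeded parametric bootstrap. For a binary
outcome the estimates are log odds ratios per exposure SD; ``or_value`` and
``or_ci`` exponentiate them. p-values are two-sided normal throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterator

import numpy as np
from scipy import stats

from mrmediate.instruments import HarmonizedSet

__all__ = [
    "MREstimate",
    "EstimationError",
    "wald_ratios",
    "ivw",
    "egger",
    "weighted_median",
    "mode_estimators",
    "estimate_all",
    "METHODS",
]

METHODS = ("ivw", "egger", "weighted_median", "simple_mode", "weighted_mode")

_Z95 = stats.norm.ppf(0.975)


class EstimationError(ValueError):
    """An estimator cannot run (too few usable instruments)."""


@dataclass(frozen=True)
class MREstimate:
    """One method's causal estimate with Wald CI and OR-scale reporting."""

    method: str
    beta: float
    se: float
    n_snps: int
    ci_low: float = None  # type: ignore[assignment]
    ci_high: float = None  # type: ignore[assignment]
    pval: float = None  # type: ignore[assignment]
    egger_intercept: float | None = None
    egger_intercept_se: float | None = None
    egger_intercept_pval: float | None = None

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}")
        if not self.se > 0:
            raise ValueError("se must be positive")
        if self.ci_low is None:
            object.__setattr__(self, "ci_low", self.beta - _Z95 * self.se)
        if self.ci_high is None:
            object.__setattr__(self, "ci_high", self.beta + _Z95 * self.se)
        if self.pval is None:
            p = 2.0 * stats.norm.sf(abs(self.beta) / self.se)
            object.__setattr__(self, "pval", max(p, np.finfo(float).tiny))
        if not self.ci_low <= self.beta <= self.ci_high:
            raise ValueError("CI must bracket the point estimate")

    @property
    def or_value(self) -> float:
        return float(np.exp(self.beta))

    @property
    def or_ci(self) -> tuple[float, float]:
        return float(np.exp(self.ci_low)), float(np.exp(self.ci_high))


def wald_ratios(h: HarmonizedSet) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Per-SNP ratio estimates ``beta_out/beta_exp`` and first-order SEs.

    SNPs with a zero exposure beta are dropped with a warning. Returns
    (ratios, ses, snp_ids) for the usable SNPs.
    """
    x, y = h.beta_exp, h.beta_out
    usable = x != 0.0
    if not usable.all():
        skipped = [s for s, u in zip(h.snp_ids, usable) if not u]
        warnings.warn(
            f"dropping {len(skipped)} SNP(s) with zero exposure beta: "
            f"{skipped[:5]}",
            stacklevel=2,
        )
    if not usable.any():
        raise EstimationError("no usable SNP for Wald ratios")
    ratios = y[usable] / x[usable]
    ses = h.se_out[usable] / np.abs(x[usable])
    ids = [s for s, u in zip(h.snp_ids, usable) if u]
    return ratios, ses, ids


def _ivw_fit(x, y, w) -> tuple[float, float, float]:
    """Origin WLS: returns (beta, fixed-effect se, Cochran Q)."""
    sxx = float(np.sum(w * x * x))
    beta = float(np.sum(w * x * y)) / sxx
    se_fixed = 1.0 / np.sqrt(sxx)
    q = float(np.sum(w * (y - beta * x) ** 2))
    return beta, se_fixed, q


def ivw(h: HarmonizedSet, model: str = "multiplicative_random") -> MREstimate:
    """Inverse-variance-weighted estimate (the primary method).

    ``model='fixed'`` uses the fixed-effect SE; the default
    ``'multiplicative_random'`` inflates it by ``sqrt(max(1, Q/(k-1)))`` to
    absorb over-dispersion of the ratio estimates.
    """
    if model not in ("fixed", "multiplicative_random"):
        raise ValueError(f"unknown IVW model {model!r}")
    if len(h) < 2:
        raise EstimationError(f"IVW needs >= 2 SNPs, got {len(h)}")
    x, y = h.beta_exp, h.beta_out
    w = h.se_out**-2.0
    beta, se, q = _ivw_fit(x, y, w)
    k = len(h)
    if model == "multiplicative_random" and k > 1:
        se *= np.sqrt(max(1.0, q / (k - 1)))
    return MREstimate(method="ivw", beta=beta, se=se, n_snps=k)


def egger(h: HarmonizedSet) -> MREstimate:
    """MR-Egger regression: slope = causal estimate, intercept = pleiotropy test.

    SNPs are oriented so every exposure beta is non-negative before the
    weighted (``se_out^-2``) regression with free intercept; SEs use the
    multiplicative over-dispersion factor ``sqrt(max(1, RSS/(k-2)))``.
    """
    if len(h) < 3:
        raise EstimationError(f"MR-Egger needs >= 3 SNPs, got {len(h)}")
    sign = np.where(h.beta_exp < 0, -1.0, 1.0)
    x = sign * h.beta_exp
    y = sign * h.beta_out
    w = h.se_out**-2.0
    sw = w.sum()
    xbar = float(np.sum(w * x) / sw)
    ybar = float(np.sum(w * y) / sw)
    sxx = float(np.sum(w * (x - xbar) ** 2))
    if sxx <= 0:
        raise EstimationError("MR-Egger: no spread in exposure betas")
    slope = float(np.sum(w * (x - xbar) * (y - ybar)) / sxx)
    intercept = ybar - slope * xbar
    k = len(h)
    rss = float(np.sum(w * (y - intercept - slope * x) ** 2))
    scale = max(1.0, rss / (k - 2)) if k > 2 else 1.0
    se_slope = float(np.sqrt(scale / sxx))
    se_int = float(np.sqrt(scale * (1.0 / sw + xbar**2 / sxx)))
    p_int = max(2.0 * stats.norm.sf(abs(intercept) / se_int), np.finfo(float).tiny)
    return MREstimate(
        method="egger",
        beta=slope,
        se=se_slope,
        n_snps=k,
        egger_intercept=intercept,
        egger_intercept_se=se_int,
        egger_intercept_pval=p_int,
    )


def _weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(ratios, kind="mergesort")
    r = ratios[order]
    w = weights[order]
    # cumulative weight at each ratio's centre, normalised to [0,1]
    q = (np.cumsum(w) - 0.5 * w) / np.sum(w)
    return float(np.interp(0.5, q, r))


def _bootstrap_betas(
    h: HarmonizedSet, n_boot: int, seed: int
) -> Iterator[tuple[np.ndarray, np.ndarray]]:
    rng = np.random.default_rng(seed)
    x, y = h.beta_exp, h.beta_out
    sx, sy = h.se_exp, h.se_out
    for _ in range(n_boot):
        yield x + rng.normal(0.0, sx), y + rng.normal(0.0, sy)


def weighted_median(h: HarmonizedSet, n_boot: int = 1000, seed: int = 0) -> MREstimate:
    """Weighted-median estimator with parametric-bootstrap SE.

    Ratio estimates are ordered and the estimate interpolated at cumulative
    normalised weight 0.5 (weights ``se^-2`` of the ratio). With equal
    weights and odd k this is the sample median of the ratios.
    """
    if len(h) < 3:
        raise EstimationError(f"weighted median needs >= 3 SNPs, got {len(h)}")
    ratios, ses, _ = wald_ratios(h)
    weights = ses**-2.0
    point = _weighted_median_point(ratios, weights)
    boots = np.empty(n_boot)
    for i, (bx, by) in enumerate(_bootstrap_betas(h, n_boot, seed)):
        ok = bx != 0.0
        br = by[ok] / bx[ok]
        bw = (h.se_out[ok] / np.abs(bx[ok])) ** -2.0
        boots[i] = _weighted_median_point(br, bw)
    se = float(np.std(boots, ddof=1))
    if se == 0.0:  # degenerate all-identical fixture
        se = np.finfo(float).tiny**0.5
    return MREstimate(method="weighted_median", beta=point, se=se, n_snps=len(h))


def _mode_bandwidth(ratios: np.ndarray, bandwidth_factor: float) -> float:
    """Modified Silverman rule: 0.9 min(sd, mad/0.6745) k^(-1/5), scaled.

    Falls back from a zero MAD to the SD (and vice versa) so clustered
    fixtures with exact ties keep a positive bandwidth.
    """
    sd = float(np.std(ratios, ddof=1)) if len(ratios) > 1 else 0.0
    mad = float(stats.median_abs_deviation(ratios, scale="normal"))
    candidates = [s for s in (sd, mad) if s > 0]
    if not candidates:
        return 0.0  # all ratios identical; caller short-circuits
    return 0.9 * min(candidates) * len(ratios) ** (-1.0 / 5.0) * bandwidth_factor


def _mode_point(
    ratios: np.ndarray, weights: np.ndarray, bandwidth_factor: float, grid_n: int = 512
) -> float:
    h_bw = _mode_bandwidth(ratios, bandwidth_factor)
    if h_bw == 0.0:
        return float(ratios[0])
    lo = ratios.min() - 3 * h_bw
    hi = ratios.max() + 3 * h_bw
    grid = np.linspace(lo, hi, grid_n)
    z = (grid[:, None] - ratios[None, :]) / h_bw
    dens = (np.exp(-0.5 * z**2) * weights[None, :]).sum(axis=1)
    return float(grid[int(np.argmax(dens))])


def mode_estimators(
    h: HarmonizedSet,
    weighted: bool = False,
    bandwidth_factor: float = 1.0,
    n_boot: int = 1000,
    seed: int = 0,
) -> MREstimate:
    """Simple (uniform-weight) or weighted (``se^-2``) mode estimator.

    The estimate is the argmax of a normal-kernel smoothed density of the
    Wald ratios on a dense grid; bandwidth is a modified Silverman rule
    scaled by ``bandwidth_factor``. SE by parametric bootstrap.
    """
    if len(h) < 3:
        raise EstimationError(f"mode estimator needs >= 3 SNPs, got {len(h)}")
    ratios, ses, _ = wald_ratios(h)
    weights = ses**-2.0 if weighted else np.ones_like(ratios)
    weights = weights / weights.sum()
    point = _mode_point(ratios, weights, bandwidth_factor)
    boots = np.empty(n_boot)
    for i, (bx, by) in enumerate(_bootstrap_betas(h, n_boot, seed)):
        ok = bx != 0.0
        br = by[ok] / bx[ok]
        if weighted:
            bw = (h.se_out[ok] / np.abs(bx[ok])) ** -2.0
        else:
            bw = np.ones_like(br)
        bw = bw / bw.sum()
        boots[i] = _mode_point(br, bw, bandwidth_factor, grid_n=256)
    se = float(np.std(boots, ddof=1))
    if se == 0.0:
        se = np.finfo(float).tiny**0.5
    method = "weighted_mode" if weighted else "simple_mode"
    return MREstimate(method=method, beta=point, se=se, n_snps=len(h))


def estimate_all(
    h: HarmonizedSet,
    ivw_model: str = "multiplicative_random",
    bandwidth_factor: float = 1.0,
    n_boot: int = 1000,
    seed: int = 0,
) -> dict[str, MREstimate]:
    """Run all five estimators, skipping (with a warning) any whose
    instrument-count minimum is not met. Deterministic given ``seed``."""
    results: dict[str, MREstimate] = {}
    runners = {
        "ivw": lambda: ivw(h, model=ivw_model),
        "egger": lambda: egger(h),
        "weighted_median": lambda: weighted_median(h, n_boot=n_boot, seed=seed),
        "simple_mode": lambda: mode_estimators(
            h, weighted=False, bandwidth_factor=bandwidth_factor,
            n_boot=n_boot, seed=seed + 1,
        ),
        "weighted_mode": lambda: mode_estimators(
            h, weighted=True, bandwidth_factor=bandwidth_factor,
            n_boot=n_boot, seed=seed + 2,
        ),
    }
    for name, run in runners.items():
        try:
            results[name] = run()
        except EstimationError as exc:
            warnings.warn(f"{name} skipped: {exc}", stacklevel=2)
    if not results:
        raise EstimationError("all five estimators skipped")
    return results
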