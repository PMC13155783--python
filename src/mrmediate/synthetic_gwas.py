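"""Synthetic two-sample GWAS summary statistics with known causal structure.

The generator emulates the three-cohort design of a two-step mediation MR
study: an exposure GWAS (continuous trait, e.g. an immune-cell phenotype),
a mediator GWAS (continuous trait, e.g. a plasma metabolite level) and a
binary-outcome GWAS on the log-odds scale (e.g. myocardial infarction),
each from a separate cohort. Per SNP *j* with instrument effect
``gamma_j`` on the exposure, mediator-specific effect ``kappa_j`` and
direct (horizontally pleiotropic) outcome effect ``alpha_j``, the expected
marginal associations are::

    E[beta_exp_j] = gamma_j
    E[beta_med_j] = a * gamma_j + kappa_j
    E[beta_out_j] = (c_dir + a * b) * gamma_j + b * kappa_j + alpha_j

where ``a`` is the exposure->mediator effect, ``b`` the mediator->outcome
effect (log-odds per mediator SD) and ``c_dir`` the direct
exposure->outcome effect. Observed betas add independent normal noise with
the standard summary-statistic SE ``1/sqrt(2 p (1-p) n)`` (effective n for
the binary outcome is deflated by ``phi (1-phi)`` with case fraction
``phi``). Only summary statistics are generated — no individual-level
genotypes — because that is all two-sample MR consumes.

Default cohort sizes follow the real studies the generator stands in for:
3,757 (Sardinian immune phenotypes), 8,299 (CLSA metabolites) and 406,565
with 28,546 cases (FinnGen myocardial infarction).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from mrmediate.summary_io import SummaryDataset

__all__ = [
    "TruthParams",
    "ScenarioOutput",
    "make_truth",
    "simulate_scenario",
    "inject_ld_blocks",
    "FINNGEN_N_TOTAL",
    "FINNGEN_N_CASES",
]

# FinnGen I9_MI_STRICT cohort composition (cases / total)
FINNGEN_N_CASES = 28_546
FINNGEN_N_TOTAL = 406_565

N_EXPOSURE_DEFAULT = 3_757  # Sardinian immune-phenotype cohort
N_MEDIATOR_DEFAULT = 8_299  # CLSA metabolite cohort

_PALINDROMIC_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]
_NONPAL_PAIRS = [
    (a, b)
    for a in "ACGT"
    for b in "ACGT"
    if a != b and (a, b) not in _PALINDROMIC_PAIRS
]


@dataclass(frozen=True)
class TruthParams:
    """Ground-truth parameters of one synthetic scenario.

    ``gamma``, ``alpha`` and ``kappa`` are per-SNP vectors of length
    ``m_snps``: instrument effects on the exposure, direct pleiotropic
    effects on the outcome, and mediator effects not routed through the
    exposure, respectively.
    """

    m_snps: int
    gamma: np.ndarray
    alpha: np.ndarray
    kappa: np.ndarray
    a_true: float
    b_true: float
    c_direct_true: float
    n_exp: int = N_EXPOSURE_DEFAULT
    n_med: int = N_MEDIATOR_DEFAULT
    n_out: int = FINNGEN_N_TOTAL
    maf: tuple[float, float] = (0.05, 0.5)
    pleiotropy_mode: str = "none"  # none | balanced | directional
    seed: int = 0
    case_fraction: float = FINNGEN_N_CASES / FINNGEN_N_TOTAL
    palindromic_fraction: float = 0.10

    def __post_init__(self) -> None:
        if self.m_snps < 3:
            raise ValueError("m_snps must be >= 3")
        for name in ("gamma", "alpha", "kappa"):
            vec = np.asarray(getattr(self, name), dtype=float)
            if vec.shape != (self.m_snps,):
                raise ValueError(f"{name} must have length m_snps={self.m_snps}")
            object.__setattr__(self, name, vec)
        if min(self.n_exp, self.n_med, self.n_out) <= 0:
            raise ValueError("sample sizes must be positive")
        lo, hi = self.maf
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf bounds must lie within (0, 0.5]")
        if self.pleiotropy_mode not in ("none", "balanced", "directional"):
            raise ValueError(f"unknown pleiotropy_mode {self.pleiotropy_mode!r}")
        if not (0.0 < self.case_fraction < 1.0):
            raise ValueError("case_fraction must be in (0,1)")

    @property
    def total_effect(self) -> float:
        """True total exposure->outcome effect c = c_dir + a*b."""
        return self.c_direct_true + self.a_true * self.b_true

    @property
    def mediated_effect(self) -> float:
        return self.a_true * self.b_true


@dataclass
class ScenarioOutput:
    """Three generated summary datasets plus the truth that produced them."""

    exposure_ds: SummaryDataset
    mediator_ds: SummaryDataset
    outcome_ds: SummaryDataset
    truth: TruthParams
    ld: pd.DataFrame | None = None  # pairwise r^2 over snp_id, None = unlinked

    def __post_init__(self) -> None:
        ids = self.exposure_ds.snp_ids
        if self.mediator_ds.snp_ids != ids or self.outcome_ds.snp_ids != ids:
            raise ValueError("the three datasets must share one snp_id universe")
        if self.ld is not None:
            mat = self.ld.to_numpy()
            if not np.allclose(mat, mat.T) or not np.allclose(np.diag(mat), 1.0):
                raise ValueError("ld must be symmetric with unit diagonal")


def make_truth(
    m_snps: int = 100,
    seed: int = 0,
    a_true: float = 0.0,
    b_true: float = 0.0,
    c_direct_true: float = 0.0,
    m_mediator_snps: int = 0,
    m_outcome_snps: int = 0,
    gamma_range: tuple[float, float] = (0.10, 0.50),
    kappa_range: tuple[float, float] = (0.10, 0.50),
    pleiotropy_mode: str = "none",
    pleiotropy_sd: float = 0.02,
    pleiotropy_mean: float = 0.02,
    gamma_signs: str = "random",
    **kwargs,
) -> TruthParams:
    """Build a :class:`TruthParams` with randomly drawn per-SNP effects.

    The first ``m_snps - m_mediator_snps - m_outcome_snps`` SNPs are
    exposure instruments (``gamma`` drawn uniformly from ``gamma_range``
    with random sign, ``kappa = 0``); the next ``m_mediator_snps`` are
    mediator-specific instruments (``kappa`` nonzero, ``gamma = 0``) so
    the mediator->outcome leg has valid instruments of its own; the last
    ``m_outcome_snps`` are outcome-specific loci (``alpha`` nonzero only)
    emulating the outcome trait's own genetic architecture, which gives
    reverse-MR analyses genuine instruments. Default effect magnitudes give
    per-SNP instrument F-statistics well above the weak-instrument cutoff
    at the default cohort sizes, with enough spread in instrument strength
    (high I2_GX) for the MR-Egger slope not to suffer appreciable
    regression dilution.

    ``pleiotropy_mode='balanced'`` draws ``alpha ~ N(0, pleiotropy_sd)``
    on the exposure-instrument SNPs; ``'directional'`` shifts the mean to
    ``pleiotropy_mean``.
    """
    if m_mediator_snps < 0 or m_outcome_snps < 0:
        raise ValueError("SNP role counts must be non-negative")
    if m_mediator_snps + m_outcome_snps >= m_snps:
        raise ValueError("mediator+outcome SNPs must leave >= 1 exposure SNP")
    rng = np.random.default_rng(seed)
    m_exp = m_snps - m_mediator_snps - m_outcome_snps
    gamma = np.zeros(m_snps)
    kappa = np.zeros(m_snps)
    if gamma_signs == "random":
        signs = rng.choice([-1.0, 1.0], size=m_exp)
    elif gamma_signs == "positive":
        # oriented instruments: needed to exhibit directional-pleiotropy bias
        signs = np.ones(m_exp)
    else:
        raise ValueError(f"unknown gamma_signs {gamma_signs!r}")
    gamma[:m_exp] = rng.uniform(*gamma_range, size=m_exp) * signs
    med_hi = m_exp + m_mediator_snps
    kappa[m_exp:med_hi] = rng.uniform(
        *kappa_range, size=m_mediator_snps
    ) * rng.choice([-1.0, 1.0], size=m_mediator_snps)
    alpha = np.zeros(m_snps)
    if pleiotropy_mode == "balanced":
        alpha[:m_exp] = rng.normal(0.0, pleiotropy_sd, size=m_exp)
    elif pleiotropy_mode == "directional":
        alpha[:m_exp] = rng.normal(pleiotropy_mean, pleiotropy_sd, size=m_exp)
    elif pleiotropy_mode != "none":
        raise ValueError(f"unknown pleiotropy_mode {pleiotropy_mode!r}")
    # outcome-specific loci: the outcome trait's own genetic architecture
    alpha[med_hi:] = rng.uniform(*kappa_range, size=m_outcome_snps) * rng.choice(
        [-1.0, 1.0], size=m_outcome_snps
    )
    return TruthParams(
        m_snps=m_snps,
        gamma=gamma,
        alpha=alpha,
        kappa=kappa,
        a_true=a_true,
        b_true=b_true,
        c_direct_true=c_direct_true,
        pleiotropy_mode=pleiotropy_mode,
        seed=seed,
        **kwargs,
    )


def _summary_se(freq: np.ndarray, n: float) -> np.ndarray:
    return 1.0 / np.sqrt(2.0 * freq * (1.0 - freq) * n)


def _two_sided_p(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    p = 2.0 * stats.norm.sf(np.abs(beta) / se)
    return np.clip(p, np.finfo(float).tiny, 1.0)


def _make_dataset(
    trait_id: str,
    trait_role: str,
    scale: str,
    snp_ids: Sequence[str],
    chrom: np.ndarray,
    pos: np.ndarray,
    ea: Sequence[str],
    oa: Sequence[str],
    eaf: np.ndarray,
    beta: np.ndarray,
    se: np.ndarray,
    n: int,
) -> SummaryDataset:
    df = pd.DataFrame(
        {
            "snp_id": list(snp_ids),
            "chrom": chrom,
            "pos": pos,
            "effect_allele": list(ea),
            "other_allele": list(oa),
            "eaf": eaf,
            "beta": beta,
            "se": se,
            "pval": _two_sided_p(beta, se),
            "n": n,
        }
    )
    return SummaryDataset(trait_id, df, trait_role=trait_role, scale=scale)


def simulate_scenario(truth: TruthParams) -> ScenarioOutput:
    """Generate exposure, mediator and outcome summary datasets from truth.

    Deterministic given ``truth.seed``: the same truth yields bitwise
    identical datasets. SNPs are mutually unlinked (``ld=None``); use
    :func:`inject_ld_blocks` to add block-structured LD afterwards.
    """
    rng = np.random.default_rng(truth.seed)
    m = truth.m_snps
    snp_ids = [f"rs{j + 1}" for j in range(m)]

    # spread SNPs across chromosomes, well separated within each
    chrom = np.array([str(j % 22 + 1) for j in range(m)])
    pos = np.array([1_000_000 + 2_000_000 * (j // 22) for j in range(m)], dtype=np.int64)

    maf = rng.uniform(truth.maf[0], truth.maf[1], size=m)
    # effect allele is randomly the minor or the major one
    freq = np.where(rng.random(m) < 0.5, maf, 1.0 - maf)

    n_pal = int(round(truth.palindromic_fraction * m))
    pal_idx = rng.choice(m, size=n_pal, replace=False)
    is_pal = np.zeros(m, dtype=bool)
    is_pal[pal_idx] = True
    ea, oa = [], []
    for j in range(m):
        pairs = _PALINDROMIC_PAIRS if is_pal[j] else _NONPAL_PAIRS
        a1, a2 = pairs[rng.integers(len(pairs))]
        ea.append(a1)
        oa.append(a2)

    expected_exp = truth.gamma
    expected_med = truth.a_true * truth.gamma + truth.kappa
    expected_out = (
        truth.total_effect * truth.gamma
        + truth.b_true * truth.kappa
        + truth.alpha
    )

    phi = truth.case_fraction
    se_exp = _summary_se(freq, truth.n_exp)
    se_med = _summary_se(freq, truth.n_med)
    se_out = _summary_se(freq, truth.n_out * phi * (1.0 - phi))

    beta_exp = expected_exp + rng.normal(0.0, se_exp)
    beta_med = expected_med + rng.normal(0.0, se_med)
    beta_out = expected_out + rng.normal(0.0, se_out)

    def study_eaf(n: int) -> np.ndarray:
        noise = rng.normal(0.0, np.sqrt(freq * (1.0 - freq) / (2.0 * n)))
        return np.clip(freq + noise, 1e-3, 1.0 - 1e-3)

    exposure = _make_dataset(
        "exposure", "exposure", "continuous_sd", snp_ids, chrom, pos, ea, oa,
        study_eaf(truth.n_exp), beta_exp, se_exp, truth.n_exp,
    )
    mediator = _make_dataset(
        "mediator", "mediator", "continuous_sd", snp_ids, chrom, pos, ea, oa,
        study_eaf(truth.n_med), beta_med, se_med, truth.n_med,
    )
    outcome = _make_dataset(
        "outcome", "outcome", "log_odds", snp_ids, chrom, pos, ea, oa,
        study_eaf(truth.n_out), beta_out, se_out, truth.n_out,
    )
    return ScenarioOutput(exposure, mediator, outcome, truth, ld=None)


def inject_ld_blocks(
    out: ScenarioOutput, block_size: int, r2_within: float
) -> ScenarioOutput:
    """Re-simulate a scenario with consecutive SNPs grouped into LD blocks.

    Within a block all SNPs tag the same causal signal (shared expected
    betas, taken from the block's first SNP) and their sampling noise is
    correlated with correlation ``sqrt(r2_within)``; between blocks r^2 is
    zero. Block members are placed 1 kb apart on one chromosome; blocks are
    separated far beyond any clumping window. Returns a new scenario with
    the pairwise r^2 matrix attached.
    """
    if block_size < 1:
        raise ValueError("block_size must be >= 1")
    truth = out.truth
    m = truth.m_snps
    if block_size > m:
        raise ValueError(f"block_size {block_size} exceeds m_snps {m}")

    block_of = np.arange(m) // block_size
    n_blocks = int(block_of.max()) + 1
    # shared causal signal within each block
    lead = np.array([np.flatnonzero(block_of == b)[0] for b in block_of])
    truth_ld = replace(
        truth,
        gamma=truth.gamma[lead],
        alpha=truth.alpha[lead],
        kappa=truth.kappa[lead],
    )

    rng = np.random.default_rng(np.random.SeedSequence([truth.seed, 7]))
    snp_ids = [f"rs{j + 1}" for j in range(m)]
    chrom = np.array([str(b % 22 + 1) for b in block_of])
    pos = np.array(
        [1_000_000 + 50_000_000 * (b // 22) + 1_000 * (j % block_size)
         for j, b in enumerate(block_of)],
        dtype=np.int64,
    )

    # shared allele frequency within a block (tagging SNPs of one signal)
    base = rng.uniform(truth.maf[0], truth.maf[1], size=n_blocks)
    flip = rng.random(n_blocks) < 0.5
    freq = np.where(flip[block_of], 1.0 - base[block_of], base[block_of])

    n_pal = int(round(truth.palindromic_fraction * m))
    pal_idx = rng.choice(m, size=n_pal, replace=False)
    is_pal = np.zeros(m, dtype=bool)
    is_pal[pal_idx] = True
    ea, oa = [], []
    for j in range(m):
        pairs = _PALINDROMIC_PAIRS if is_pal[j] else _NONPAL_PAIRS
        a1, a2 = pairs[rng.integers(len(pairs))]
        ea.append(a1)
        oa.append(a2)

    rho = float(np.sqrt(r2_within))

    def correlated_noise(se: np.ndarray) -> np.ndarray:
        shared = rng.standard_normal(n_blocks)[block_of]
        own = rng.standard_normal(m)
        return se * (rho * shared + np.sqrt(1.0 - rho**2) * own)

    expected_exp = truth_ld.gamma
    expected_med = truth.a_true * truth_ld.gamma + truth_ld.kappa
    expected_out = (
        truth.total_effect * truth_ld.gamma
        + truth.b_true * truth_ld.kappa
        + truth_ld.alpha
    )
    phi = truth.case_fraction
    se_exp = _summary_se(freq, truth.n_exp)
    se_med = _summary_se(freq, truth.n_med)
    se_out = _summary_se(freq, truth.n_out * phi * (1.0 - phi))

    beta_exp = expected_exp + correlated_noise(se_exp)
    beta_med = expected_med + correlated_noise(se_med)
    beta_out = expected_out + correlated_noise(se_out)

    def study_eaf(n: int) -> np.ndarray:
        noise = rng.normal(0.0, np.sqrt(freq * (1.0 - freq) / (2.0 * n)))
        return np.clip(freq + noise, 1e-3, 1.0 - 1e-3)

    exposure = _make_dataset(
        "exposure", "exposure", "continuous_sd", snp_ids, chrom, pos, ea, oa,
        study_eaf(truth.n_exp), beta_exp, se_exp, truth.n_exp,
    )
    mediator = _make_dataset(
        "mediator", "mediator", "continuous_sd", snp_ids, chrom, pos, ea, oa,
        study_eaf(truth.n_med), beta_med, se_med, truth.n_med,
    )
    outcome = _make_dataset(
        "outcome", "outcome", "log_odds", snp_ids, chrom, pos, ea, oa,
        study_eaf(truth.n_out), beta_out, se_out, truth.n_out,
    )

    same_block = block_of[:, None] == block_of[None, :]
    r2 = np.where(same_block, r2_within, 0.0)
    np.fill_diagonal(r2, 1.0)
    ld = pd.DataFrame(r2, index=snp_ids, columns=snp_ids)
    return ScenarioOutput(exposure, mediator, outcome, truth_ld, ld=ld)


def harmonized_pair(sc: ScenarioOutput, x: str = "exposure", y: str = "outcome"):
    """Directly pair two of a scenario's datasets as a HarmonizedSet.

    Generated datasets share snp_id order and allele orientation by
    construction, so no allele logic is needed; this is the fast path for
    calibration studies that bypass instrument selection (avoiding
    winner's-curse conditioning on the significance threshold).
    """
    from mrmediate.instruments import HarmonizedSet

    frames = {
        "exposure": sc.exposure_ds,
        "mediator": sc.mediator_ds,
        "outcome": sc.outcome_ds,
    }
    a, b = frames[x].records, frames[y].records
    table = pd.DataFrame(
        {
            "snp_id": a["snp_id"],
            "effect_allele": a["effect_allele"],
            "other_allele": a["other_allele"],
            "beta_exp": a["beta"].to_numpy(),
            "se_exp": a["se"].to_numpy(),
            "eaf_exp": a["eaf"].to_numpy(),
            "beta_out": b["beta"].to_numpy(),
            "se_out": b["se"].to_numpy(),
            "eaf_out": b["eaf"].to_numpy(),
        }
    )
    return HarmonizedSet(frames[x].trait_id, frames[y].trait_id, table)


def write_truth_sidecar(truth: TruthParams, path) -> None:
    """Serialize scenario truth as a simple key-value sidecar file."""
    scalars = {
        "m_snps": truth.m_snps,
        "a_true": truth.a_true,
        "b_true": truth.b_true,
        "c_direct_true": truth.c_direct_true,
        "n_exp": truth.n_exp,
        "n_med": truth.n_med,
        "n_out": truth.n_out,
        "maf_low": truth.maf[0],
        "maf_high": truth.maf[1],
        "pleiotropy_mode": truth.pleiotropy_mode,
        "seed": truth.seed,
        "case_fraction": truth.case_fraction,
        "palindromic_fraction": truth.palindromic_fraction,
    }
    with open(path, "w", encoding="utf-8") as fh:
        for key, val in scalars.items():
            fh.write(f"{key}\t{val}\n")
        for name in ("gamma", "alpha", "kappa"):
            vec = getattr(truth, name)
            fh.write(f"{name}\t{','.join(f'{v:.17g}' for v in vec)}\n")
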