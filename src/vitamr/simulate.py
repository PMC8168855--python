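"""Synthetic GWAS summary statistics with known ground truth.

The generator emulates the structure a two-sample Mendelian randomization
analysis of a standardized continuous exposure (log 25-hydroxy-vitamin-D)
on binary outcomes assumes: J unlinked instruments whose per-variant effects
``gamma_j`` jointly explain a target fraction of exposure variance,
case-control outcome effects ``Gamma_j = causal_beta * gamma_j + alpha_j``
on the log odds-ratio scale, and sampling noise scaled by allele frequency
and sample size through the standard first-order GWAS approximations

    se(gamma_hat_j) = 1 / sqrt(2 p_j (1 - p_j) * n_exposure)
    se(Gamma_hat_j) = 1 / sqrt(2 p_j (1 - p_j) * N * phi * (1 - phi))

with ``phi`` the case fraction.  ``alpha_j`` is a direct (horizontally
pleiotropic) path from variant to outcome: zero, balanced (mean-zero) or
directional (nonzero mean) — the signal an Egger intercept detects.

Per-variant exposure effects are oriented to the exposure-raising allele
(``gamma_j > 0``), the usual reporting convention for MR instruments.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .io import VariantAssociation
from .util import split_rng

_PALINDROMIC_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]
_STANDARD_PAIRS = [
    ("A", "G"), ("G", "A"), ("A", "C"), ("C", "A"),
    ("T", "G"), ("G", "T"), ("T", "C"), ("C", "T"),
]

#: Sample sizes of the study conditions emulated by default: a 443,734-person
#: European 25OHD GWAS for the exposure, and a 14,134-case / 1,284,876-control
#: COVID-19 susceptibility meta-analysis for the outcome.
DEFAULT_EXPOSURE_N = 443_734
DEFAULT_OUTCOME_N_CASES = 14_134
DEFAULT_OUTCOME_N_CONTROLS = 1_284_876


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic two-sample MR dataset."""

    n_variants: int = 80
    maf_range: tuple[float, float] = (0.05, 0.45)
    exposure_n: int = DEFAULT_EXPOSURE_N
    outcome_n_cases: int = DEFAULT_OUTCOME_N_CASES
    outcome_n_controls: int = DEFAULT_OUTCOME_N_CONTROLS
    causal_beta: float = 0.0
    target_r2: float = 0.04
    pleiotropy_mode: str = "none"  # none | balanced | directional
    pleiotropy_sd: float = 0.0
    pleiotropy_mean: float = 0.0
    palindromic_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_variants < 1:
            raise ValueError("n_variants must be >= 1")
        low, high = self.maf_range
        if not (0.0 < low < high < 0.5):
            raise ValueError(f"maf_range must satisfy 0 < low < high < 0.5, got {self.maf_range}")
        if not (0.0 < self.target_r2 < 1.0):
            raise ValueError(
                f"target_r2 must be in (0, 1) for a standardized exposure, got {self.target_r2}"
            )
        for name in ("exposure_n", "outcome_n_cases", "outcome_n_controls"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.pleiotropy_mode not in ("none", "balanced", "directional"):
            raise ValueError(f"unknown pleiotropy_mode {self.pleiotropy_mode!r}")
        if self.pleiotropy_mode == "balanced" and self.pleiotropy_mean != 0.0:
            raise ValueError("balanced pleiotropy requires pleiotropy_mean == 0")
        if self.pleiotropy_sd < 0:
            raise ValueError("pleiotropy_sd must be >= 0")
        if not (0.0 <= self.palindromic_fraction <= 1.0):
            raise ValueError("palindromic_fraction must be in [0, 1]")

    @property
    def outcome_n(self) -> int:
        return self.outcome_n_cases + self.outcome_n_controls

    @property
    def case_fraction(self) -> float:
        return self.outcome_n_cases / self.outcome_n


@dataclass
class TrueInstrumentSet:
    """Ground truth behind a simulated dataset (the recovery-test ledger)."""

    variant_ids: list[str]
    chrom: list[str]
    pos: np.ndarray
    effect_allele: list[str]
    other_allele: list[str]
    maf: np.ndarray          # frequency of the effect (exposure-raising) allele's minor form
    eaf: np.ndarray          # frequency of the effect allele itself
    gamma: np.ndarray        # true exposure effect, SD units, > 0
    alpha: np.ndarray        # true direct (pleiotropic) outcome effect, log-OR units

    @property
    def n(self) -> int:
        return len(self.variant_ids)

    def variance_explained(self) -> float:
        p = self.eaf
        return float(np.sum(2.0 * p * (1.0 - p) * self.gamma**2))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "variant_id": self.variant_ids,
                "chrom": self.chrom,
                "pos": self.pos,
                "effect_allele": self.effect_allele,
                "other_allele": self.other_allele,
                "maf": self.maf,
                "eaf": self.eaf,
                "gamma": self.gamma,
                "alpha": self.alpha,
            }
        )

    def write(self, path: Union[str, Path]) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def simulate_truth(config: SimulationConfig) -> TrueInstrumentSet:
    """Draw a ground-truth instrument set satisfying the variance budget.

    Allele frequencies are uniform on ``maf_range``; raw effect magnitudes are
    uniform on (0.5, 1.5) — a ~3-fold spread of instrument strengths — then
    rescaled so that ``sum_j 2 p_j (1-p_j) gamma_j^2`` equals ``target_r2``
    exactly.  A configurable fraction of variants receive palindromic (A/T or
    C/G) allele pairs.  Deterministic given ``config.seed``.
    """
    rng = split_rng(config.seed, "truth")
    j = config.n_variants
    maf = rng.uniform(config.maf_range[0], config.maf_range[1], size=j)
    # effect allele may be the minor or the major allele
    eaf = np.where(rng.random(j) < 0.5, maf, 1.0 - maf)

    raw = rng.uniform(0.5, 1.5, size=j)
    budget = np.sum(2.0 * eaf * (1.0 - eaf) * raw**2)
    gamma = raw * np.sqrt(config.target_r2 / budget)

    if config.pleiotropy_mode == "none":
        alpha = np.zeros(j)
    else:
        mean = config.pleiotropy_mean if config.pleiotropy_mode == "directional" else 0.0
        alpha = rng.normal(mean, config.pleiotropy_sd, size=j)

    n_pal = int(round(config.palindromic_fraction * j))
    pal_idx = set(rng.choice(j, size=n_pal, replace=False).tolist()) if n_pal else set()
    effect_allele, other_allele = [], []
    for k in range(j):
        pool = _PALINDROMIC_PAIRS if k in pal_idx else _STANDARD_PAIRS
        ea, oa = pool[rng.integers(len(pool))]
        effect_allele.append(ea)
        other_allele.append(oa)

    return TrueInstrumentSet(
        variant_ids=[f"rs{100000 + k}" for k in range(j)],
        chrom=[str((k % 22) + 1) for k in range(j)],
        pos=np.asarray([1_000_000 + 1_000_000 * k for k in range(j)]),
        effect_allele=effect_allele,
        other_allele=other_allele,
        maf=maf,
        eaf=eaf,
        gamma=gamma,
        alpha=alpha,
    )


def exposure_se(eaf: np.ndarray, n: int) -> np.ndarray:
    """First-order SE of a per-allele effect on a standardized continuous trait."""
    return 1.0 / np.sqrt(2.0 * eaf * (1.0 - eaf) * n)


def outcome_se(eaf: np.ndarray, n: int, case_fraction: float) -> np.ndarray:
    """First-order SE of a per-allele log-OR from a case-control GWAS."""
    return 1.0 / np.sqrt(2.0 * eaf * (1.0 - eaf) * n * case_fraction * (1.0 - case_fraction))


def _pvals(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    p = 2.0 * stats.norm.sf(np.abs(beta) / se)
    return np.clip(p, 1e-300, 1.0)


def simulate_summary_stats(
    truth: TrueInstrumentSet,
    config: SimulationConfig,
    stream: str = "",
) -> tuple[list[VariantAssociation], list[VariantAssociation]]:
    """Draw noisy exposure and outcome summary-statistic tables around ``truth``.

    ``stream`` labels an extra RNG stream so several outcome tables can be
    drawn from one truth (one per clinical outcome) without correlated noise.
    Returned tables pass :mod:`vitamr.io` validation as-is.
    """
    rng_x = split_rng(config.seed, "exposure", stream)
    rng_y = split_rng(config.seed, "outcome", stream)
    se_x = exposure_se(truth.eaf, config.exposure_n)
    se_y = outcome_se(truth.eaf, config.outcome_n, config.case_fraction)
    beta_x = rng_x.normal(truth.gamma, se_x)
    beta_y = rng_y.normal(config.causal_beta * truth.gamma + truth.alpha, se_y)
    p_x = _pvals(beta_x, se_x)
    p_y = _pvals(beta_y, se_y)

    exposure, outcome = [], []
    for k in range(truth.n):
        common = dict(
            variant_id=truth.variant_ids[k],
            chrom=truth.chrom[k],
            pos=int(truth.pos[k]),
            effect_allele=truth.effect_allele[k],
            other_allele=truth.other_allele[k],
            eaf=float(truth.eaf[k]),
        )
        exposure.append(
            VariantAssociation(
                beta=float(beta_x[k]), se=float(se_x[k]), pval=float(p_x[k]),
                n=config.exposure_n, **common,
            )
        )
        outcome.append(
            VariantAssociation(
                beta=float(beta_y[k]), se=float(se_y[k]), pval=float(p_y[k]),
                n=config.outcome_n, n_cases=config.outcome_n_cases,
                n_controls=config.outcome_n_controls, **common,
            )
        )
    return exposure, outcome


_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def corrupt_allele_coding(
    records: Sequence[VariantAssociation],
    swap_frac: float,
    strandflip_frac: float,
    seed: int,
) -> tuple[list[VariantAssociation], list[tuple[str, str]]]:
    """Corrupt a table's allele coding to exercise harmonization.

    A *swap* exchanges effect/other alleles, negates beta and reflects eaf —
    the same association reported against the opposite allele.  A *strand
    flip* complements both alleles with beta and eaf unchanged — the same
    association reported off the opposite strand.  Each row receives at most
    one edit; the returned ledger lists ``(variant_id, action)`` for every
    edited row.
    """
    if not (0.0 <= swap_frac <= 1.0 and 0.0 <= strandflip_frac <= 1.0):
        raise ValueError("fractions must be in [0, 1]")
    if swap_frac + strandflip_frac > 1.0:
        raise ValueError("swap_frac + strandflip_frac must be <= 1")
    rng = split_rng(seed, "corrupt")
    u = rng.random(len(records))
    out: list[VariantAssociation] = []
    ledger: list[tuple[str, str]] = []
    for rec, ui in zip(records, u):
        if ui < swap_frac:
            out.append(
                replace(
                    rec,
                    effect_allele=rec.other_allele,
                    other_allele=rec.effect_allele,
                    beta=-rec.beta,
                    eaf=None if rec.eaf is None else 1.0 - rec.eaf,
                )
            )
            ledger.append((rec.variant_id, "swap"))
        elif ui < swap_frac + strandflip_frac:
            out.append(
                replace(
                    rec,
                    effect_allele=_COMPLEMENT[rec.effect_allele],
                    other_allele=_COMPLEMENT[rec.other_allele],
                )
            )
            ledger.append((rec.variant_id, "strand_flip"))
        else:
            out.append(rec)
    return out, ledger
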