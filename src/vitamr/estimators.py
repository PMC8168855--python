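"""Mendelian randomization estimators and diagnostics.

Per-variant causal estimates are Wald ratios ``theta_j = Gamma_hat_j /
gamma_hat_j`` with first-order delta-method standard errors
``se_j = se(Gamma_hat_j) / |gamma_hat_j|`` (a second-order correction adding
the exposure-side noise term is available behind a flag).  On top of the
ratios sit:

* **IVW** — the inverse-variance-weighted mean of the ratios, algebraically
  identical to the slope of a zero-intercept weighted regression of outcome
  on exposure effects with weights ``1/se(Gamma_hat)^2``.  The fixed-effect
  SE is ``1/sqrt(sum w_j)``; the multiplicative random-effects variant
  inflates it by ``max(1, sqrt(Q/(J-1)))``.
* **Cochran's Q** — weighted squared deviations from the pooled fit; an
  upper-tail chi-square test for instrument heterogeneity (a pleiotropy
  signal).
* **MR-Egger** — weighted regression with a free intercept after orienting
  all exposure effects positive; the intercept estimates directional
  horizontal pleiotropy (valid under the InSIDE assumption), the slope is
  the pleiotropy-adjusted causal effect.  A parametric-bootstrap variant
  guards against MR-Egger's finite-sample instability.
* **Weighted median** — consistent when at least half the weight comes from
  valid instruments; a penalized variant downweights outlying ratios by
  their heterogeneity contribution.
* **Mode-based estimators** — the peak of a kernel-smoothed density of the
  ratios (simple: equal weights; weighted: inverse-variance weights);
  consistent when the largest group of instruments sharing a ratio is valid.

All point estimators report two-sided normal p-values and ``beta ±
1.96 se`` confidence intervals (normal approximations); odds-ratio columns
exponentiate the log-OR quantities.  Bootstrap randomness is split per
method from a single seed, so adding one method never perturbs another.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .harmonize import HarmonizedPair
from .util import split_rng

Z95 = 1.959963984540054  # norm.ppf(0.975)

METHODS = (
    "wald",
    "ivw_fe",
    "ivw_mre",
    "egger_slope",
    "egger_bootstrap",
    "weighted_median",
    "penalized_weighted_median",
    "simple_mode",
    "weighted_mode",
)

MODE_GRID_POINTS = 4096
PENALTY_CONSTANT = 20.0
DEFAULT_N_BOOT = 1000


@dataclass(frozen=True)
class MREstimate:
    """A causal-effect estimate on the log-OR-per-SD scale, with OR counterparts."""

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    n_snps: int
    or_: float = float("nan")
    or_ci_low: float = float("nan")
    or_ci_high: float = float("nan")

    def __post_init__(self) -> None:
        def _exp(x: float) -> float:
            try:
                return math.exp(x)
            except OverflowError:
                return math.inf
        if math.isnan(self.or_):
            object.__setattr__(self, "or_", _exp(self.beta))
        if math.isnan(self.or_ci_low):
            object.__setattr__(self, "or_ci_low", _exp(self.ci_low))
        if math.isnan(self.or_ci_high):
            object.__setattr__(self, "or_ci_high", _exp(self.ci_high))


@dataclass(frozen=True)
class HeterogeneityResult:
    """Cochran's Q with its degrees of freedom and upper-tail chi-square p."""

    Q: float
    df: int
    pval: float


@dataclass(frozen=True)
class EggerIntercept:
    """The MR-Egger intercept: average directional pleiotropy per variant."""

    alpha: float
    se: float
    ci_low: float
    ci_high: float
    pval: float


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _unpack(pairs: Sequence[HarmonizedPair]) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    if not pairs:
        raise ValueError("no harmonized pairs supplied")
    bx = np.array([p.beta_exposure for p in pairs], dtype=float)
    sx = np.array([p.se_exposure for p in pairs], dtype=float)
    by = np.array([p.beta_outcome for p in pairs], dtype=float)
    sy = np.array([p.se_outcome for p in pairs], dtype=float)
    if np.any(bx == 0):
        raise ValueError("zero exposure beta: Wald ratio undefined")
    return bx, sx, by, sy


def _ratios(bx: np.ndarray, by: np.ndarray, sy: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    theta = by / bx
    se = np.abs(sy / bx)
    return theta, se


def _norm_p(beta: float, se: float) -> float:
    if se == 0:
        return 1.0 if beta == 0 else 0.0
    return float(2.0 * stats.norm.sf(abs(beta) / se))


def _estimate(method: str, beta: float, se: float, n: int,
              ci: Optional[tuple[float, float]] = None,
              pval: Optional[float] = None) -> MREstimate:
    if ci is None:
        ci = (beta - Z95 * se, beta + Z95 * se)
    if pval is None:
        pval = _norm_p(beta, se)
    return MREstimate(method=method, beta=float(beta), se=float(se),
                      ci_low=float(ci[0]), ci_high=float(ci[1]),
                      pval=float(pval), n_snps=n)


# ---------------------------------------------------------------------------
# Wald ratio and IVW
# ---------------------------------------------------------------------------


def wald_ratio(pair: HarmonizedPair, second_order: bool = False) -> MREstimate:
    """Per-variant causal estimate: outcome effect over exposure effect."""
    if pair.beta_exposure == 0:
        raise ValueError(f"{pair.variant_id}: zero exposure beta")
    beta = pair.beta_outcome / pair.beta_exposure
    se = abs(pair.se_outcome / pair.beta_exposure)
    if second_order:
        se = math.sqrt(
            pair.se_outcome**2 / pair.beta_exposure**2
            + pair.beta_outcome**2 * pair.se_exposure**2 / pair.beta_exposure**4
        )
    return _estimate("wald", beta, se, 1)


def ivw(pairs: Sequence[HarmonizedPair], variant: str = "multiplicative_random") -> MREstimate:
    """Inverse-variance-weighted meta-analysis of the Wald ratios.

    ``variant='fixed'`` reports the fixed-effect SE; the default
    multiplicative random-effects model inflates it by
    ``max(1, sqrt(Q/(J-1)))`` so that observed heterogeneity widens the
    interval but can never shrink it.  A single pair degrades gracefully to
    the Wald ratio.
    """
    if variant not in ("fixed", "multiplicative_random"):
        raise ValueError(f"unknown IVW variant {variant!r}")
    bx, sx, by, sy = _unpack(pairs)
    theta, se_r = _ratios(bx, by, sy)
    w = 1.0 / se_r**2
    beta = float(np.sum(w * theta) / np.sum(w))
    se = float(1.0 / math.sqrt(np.sum(w)))
    j = len(pairs)
    method = "ivw_fe" if variant == "fixed" else "ivw_mre"
    if variant == "multiplicative_random" and j > 1:
        q = float(np.sum(w * (theta - beta) ** 2))
        se *= max(1.0, math.sqrt(q / (j - 1)))
    return _estimate(method, beta, se, j)


def cochran_q(pairs: Sequence[HarmonizedPair], model: str = "ivw") -> HeterogeneityResult:
    """Heterogeneity of the per-variant estimates around the pooled fit.

    ``model='ivw'`` measures deviations of the Wald ratios from the
    fixed-effect IVW estimate (df = J - 1); ``model='egger'`` measures
    weighted residuals around the Egger regression line (df = J - 2).
    """
    j = len(pairs)
    if model == "ivw":
        if j < 2:
            raise ValueError("cochran_q(ivw) needs >= 2 pairs")
        bx, sx, by, sy = _unpack(pairs)
        theta, se_r = _ratios(bx, by, sy)
        w = 1.0 / se_r**2
        fit = np.sum(w * theta) / np.sum(w)
        q = float(np.sum(w * (theta - fit) ** 2))
        df = j - 1
    elif model == "egger":
        if j < 3:
            raise ValueError("cochran_q(egger) needs >= 3 pairs")
        bx, sx, by, sy = _unpack(pairs)
        sign = np.where(bx < 0, -1.0, 1.0)
        bxo, byo = np.abs(bx), by * sign
        w = 1.0 / sy**2
        a, b = _wls_line(bxo, byo, w)
        q = float(np.sum(w * (byo - a - b * bxo) ** 2))
        df = j - 2
    else:
        raise ValueError(f"unknown heterogeneity model {model!r}")
    return HeterogeneityResult(Q=q, df=df, pval=float(stats.chi2.sf(q, df)))


# ---------------------------------------------------------------------------
# MR-Egger
# ---------------------------------------------------------------------------


def _wls_line(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    """Weighted least-squares intercept and slope via the normal equations."""
    sw = np.sum(w)
    mx = np.sum(w * x) / sw
    my = np.sum(w * y) / sw
    sxx = np.sum(w * (x - mx) ** 2)
    if sxx <= 1e-12 * np.sum(w * x**2):  # no spread up to rounding
        raise ValueError("no spread in exposure effects: Egger slope unidentified")
    slope = float(np.sum(w * (x - mx) * (y - my)) / sxx)
    return float(my - slope * mx), slope


def egger(pairs: Sequence[HarmonizedPair]) -> tuple[MREstimate, EggerIntercept]:
    """MR-Egger regression: pleiotropy-adjusted slope plus intercept test.

    Exposure effects are oriented positive (outcome signs flipped in tandem)
    before fitting, weights are ``1/se(Gamma_hat)^2``, and both coefficient
    SEs are multiplicatively inflated by ``max(1, sqrt(Q_egger/(J-2)))``.
    """
    if len(pairs) < 3:
        raise ValueError("egger needs >= 3 pairs")
    bx, sx, by, sy = _unpack(pairs)
    sign = np.where(bx < 0, -1.0, 1.0)
    x, y = np.abs(bx), by * sign
    w = 1.0 / sy**2
    a, b = _wls_line(x, y, w)
    j = len(pairs)
    q = float(np.sum(w * (y - a - b * x) ** 2))
    scale = max(1.0, math.sqrt(q / (j - 2)))
    sw = np.sum(w)
    mx = np.sum(w * x) / sw
    sxx = float(np.sum(w * (x - mx) ** 2))
    se_b = scale / math.sqrt(sxx)
    se_a = scale * math.sqrt(1.0 / sw + mx**2 / sxx)
    slope = _estimate("egger_slope", b, se_b, j)
    intercept = EggerIntercept(
        alpha=a, se=se_a,
        ci_low=a - Z95 * se_a, ci_high=a + Z95 * se_a,
        pval=_norm_p(a, se_a),
    )
    return slope, intercept


def egger_bootstrap(
    pairs: Sequence[HarmonizedPair], n_boot: int = DEFAULT_N_BOOT, seed: int = 0
) -> MREstimate:
    """Parametric-bootstrap MR-Egger slope.

    Resamples both effect vectors from their reported sampling distributions,
    refits the Egger regression per resample (including re-orientation), and
    reports the median slope with the bootstrap SD as SE and the 2.5/97.5
    percentile interval.  Deterministic given ``seed``.
    """
    if len(pairs) < 3:
        raise ValueError("egger_bootstrap needs >= 3 pairs")
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    bx, sx, by, sy = _unpack(pairs)
    rng = split_rng(seed, "egger_bootstrap")
    bxs = rng.normal(bx, sx, size=(n_boot, bx.size))
    bys = rng.normal(by, sy, size=(n_boot, by.size))
    sign = np.where(bxs < 0, -1.0, 1.0)
    x = np.abs(bxs)
    y = bys * sign
    w = 1.0 / sy**2  # weights fixed across resamples
    sw = np.sum(w)
    mx = (x * w).sum(axis=1) / sw
    my = (y * w).sum(axis=1) / sw
    dx = x - mx[:, None]
    sxx = (w * dx**2).sum(axis=1)
    slopes = (w * dx * (y - my[:, None])).sum(axis=1) / sxx
    point = float(np.median(slopes))
    se = float(np.std(slopes, ddof=1))
    ci = (float(np.percentile(slopes, 2.5)), float(np.percentile(slopes, 97.5)))
    return _estimate("egger_bootstrap", point, se, len(pairs), ci=ci)


# ---------------------------------------------------------------------------
# Weighted median
# ---------------------------------------------------------------------------


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    """Interpolated weighted median: cumulative weight midpoints bracket 0.5."""
    order = np.argsort(values, kind="stable")
    v = values[order]
    wn = weights[order] / np.sum(weights)
    s = np.cumsum(wn) - 0.5 * wn
    if 0.5 <= s[0]:
        return float(v[0])
    if 0.5 >= s[-1]:
        return float(v[-1])
    k = int(np.searchsorted(s, 0.5, side="right")) - 1
    if s[k + 1] == s[k]:
        return float(v[k])
    return float(v[k] + (v[k + 1] - v[k]) * (0.5 - s[k]) / (s[k + 1] - s[k]))


def _wm_point(theta: np.ndarray, w: np.ndarray, penalized: bool) -> float:
    beta = _weighted_median(theta, w)
    if not penalized:
        return beta
    q_contrib = w * (theta - beta) ** 2
    penalty = np.minimum(1.0, PENALTY_CONSTANT * stats.chi2.sf(q_contrib, 1))
    return _weighted_median(theta, w * penalty)


def weighted_median(
    pairs: Sequence[HarmonizedPair],
    penalized: bool = False,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = 0,
) -> MREstimate:
    """Weighted-median estimator of the causal effect.

    Inverse-variance weights on the Wald ratios; the penalized variant
    multiplies each weight by ``min(1, 20 q_j)`` where ``q_j`` is the
    upper-tail chi-square(1) probability of the variant's heterogeneity
    contribution around the unpenalized estimate, damping outliers.  The SE
    comes from a parametric bootstrap (``n_boot = 0`` returns the point
    estimate alone, with NaN SE).
    """
    if len(pairs) < 3:
        raise ValueError("weighted_median needs >= 3 pairs")
    bx, sx, by, sy = _unpack(pairs)
    theta, se_r = _ratios(bx, by, sy)
    w = 1.0 / se_r**2
    beta = _wm_point(theta, w, penalized)
    method = "penalized_weighted_median" if penalized else "weighted_median"
    if n_boot == 0:
        nan = float("nan")
        return MREstimate(method=method, beta=beta, se=nan, ci_low=nan, ci_high=nan,
                          pval=nan, n_snps=len(pairs), or_=math.exp(beta))
    rng = split_rng(seed, method)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        bxs = rng.normal(bx, sx)
        bys = rng.normal(by, sy)
        ths = bys / bxs
        ws = (bxs / sy) ** 2
        boots[b] = _wm_point(ths, ws, penalized)
    se = float(np.std(boots, ddof=1))
    return _estimate(method, beta, se, len(pairs))


# ---------------------------------------------------------------------------
# Mode-based estimators
# ---------------------------------------------------------------------------


def _weighted_mad(values: np.ndarray, weights: np.ndarray) -> float:
    med = _weighted_median(values, weights)
    return 1.4826 * _weighted_median(np.abs(values - med), weights)


def _mode_point(theta: np.ndarray, w: np.ndarray, phi: float) -> float:
    """Argmax of the normal-kernel smoothed, weighted density of the ratios.

    Bandwidth: ``phi * 0.9 * wMAD * J^(-1/5)`` with wMAD the weighted median
    absolute deviation (scaled to the normal).  Grid: 4096 points spanning
    the ratios +- 3 bandwidths; density ties break to the lower grid point.
    """
    wn = w / np.sum(w)
    h = phi * 0.9 * _weighted_mad(theta, w) * theta.size ** (-1.0 / 5.0)
    if h == 0:  # degenerate: (weighted majority of) ratios coincide
        return _weighted_median(theta, w)
    grid = np.linspace(theta.min() - 3 * h, theta.max() + 3 * h, MODE_GRID_POINTS)
    dens = np.exp(-0.5 * ((grid[:, None] - theta[None, :]) / h) ** 2) @ wn
    return float(grid[int(np.argmax(dens))])


def mode_estimate(
    pairs: Sequence[HarmonizedPair],
    weighted: bool = False,
    phi: float = 1.0,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = 0,
) -> MREstimate:
    """Mode-based estimate: the peak of the smoothed density of Wald ratios.

    ``weighted=False`` gives every ratio equal mass (simple mode);
    ``weighted=True`` uses inverse-variance weights.  ``phi`` scales the
    kernel bandwidth.  SE via parametric bootstrap (``n_boot = 0`` for the
    point estimate alone).
    """
    if len(pairs) < 3:
        raise ValueError("mode_estimate needs >= 3 pairs")
    if phi <= 0:
        raise ValueError("phi must be > 0")
    bx, sx, by, sy = _unpack(pairs)
    theta, se_r = _ratios(bx, by, sy)
    w = 1.0 / se_r**2 if weighted else np.ones_like(theta)
    beta = _mode_point(theta, w, phi)
    method = "weighted_mode" if weighted else "simple_mode"
    if n_boot == 0:
        nan = float("nan")
        return MREstimate(method=method, beta=beta, se=nan, ci_low=nan, ci_high=nan,
                          pval=nan, n_snps=len(pairs), or_=math.exp(beta))
    rng = split_rng(seed, method)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        bxs = rng.normal(bx, sx)
        bys = rng.normal(by, sy)
        ths = bys / bxs
        ws = (bxs / sy) ** 2 if weighted else np.ones_like(ths)
        boots[b] = _mode_point(ths, ws, phi)
    se = float(np.std(boots, ddof=1))
    return _estimate(method, beta, se, len(pairs))


# ---------------------------------------------------------------------------
# Reporting scale
# ---------------------------------------------------------------------------


def to_odds_scale(estimate: MREstimate) -> MREstimate:
    """Return the estimate with OR columns freshly exponentiated from log scale."""
    return replace(
        estimate,
        or_=math.exp(estimate.beta),
        or_ci_low=math.exp(estimate.ci_low),
        or_ci_high=math.exp(estimate.ci_high),
    )
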