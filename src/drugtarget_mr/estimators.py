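"""Two-sample MR estimators and diagnostics.

All estimators consume instrument-aligned (beta_x, se_x, beta_y, se_y)
summary statistics and use first-order Wald-ratio weights.  The primary
estimator is inverse-variance weighting (IVW) under multiplicative random
effects: the fixed-effect standard error is inflated by
sqrt(Q/(k-1)) when Cochran's Q exceeds its degrees of freedom, never
deflated.  P-values are two-sided normal, and 95% intervals use 1.96
throughout, matching standard summary-data MR practice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import EstimationError, InsufficientInstrumentsError
from .sumstats import HarmonizedSet

Z95 = 1.96


@dataclass(frozen=True)
class MrEstimate:
    """One estimator's causal-effect estimate.

    ``beta`` is on the outcome scale per unit of instrumented exposure
    (log odds for binary outcomes); odds-ratio fields are populated only
    when the outcome is binary.
    """

    method: str
    beta: float
    se: float
    pval: float
    k: int
    q: float | None = None
    q_pval: float | None = None
    egger_intercept: float | None = None
    intercept_pval: float | None = None
    outcome_binary: bool = False
    n_outliers: int | None = None

    @property
    def ci_low(self) -> float:
        return self.beta - Z95 * self.se

    @property
    def ci_high(self) -> float:
        return self.beta + Z95 * self.se

    @property
    def odds_ratio(self) -> float | None:
        return float(np.exp(self.beta)) if self.outcome_binary else None

    @property
    def or_low(self) -> float | None:
        return float(np.exp(self.ci_low)) if self.outcome_binary else None

    @property
    def or_high(self) -> float | None:
        return float(np.exp(self.ci_high)) if self.outcome_binary else None

    def as_dict(self) -> dict:
        d = {
            "method": self.method,
            "beta": self.beta,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "pval": self.pval,
            "k": self.k,
            "q": self.q,
            "q_pval": self.q_pval,
            "egger_intercept": self.egger_intercept,
            "intercept_pval": self.intercept_pval,
        }
        if self.outcome_binary:
            d.update(odds_ratio=self.odds_ratio, or_low=self.or_low, or_high=self.or_high)
        if self.n_outliers is not None:
            d["n_outliers"] = self.n_outliers
        return d


def _norm_p(z: float) -> float:
    return float(2 * stats.norm.sf(abs(z)))


def cochran_q_pval(q: float, df: int) -> float:
    """Upper-tail chi-square p for a heterogeneity statistic."""
    return float(stats.chi2.sf(q, df)) if df >= 1 else float("nan")


def wald_ratio(bx: float, sx: float, by: float, sy: float, outcome_binary: bool = False) -> MrEstimate:
    """Single-instrument causal estimate by/bx with first-order se sy/|bx|."""
    if bx == 0:
        raise EstimationError("wald_ratio: exposure beta is zero (degenerate instrument)")
    beta = by / bx
    se = sy / abs(bx)
    return MrEstimate("wald", float(beta), float(se), _norm_p(beta / se), 1, outcome_binary=outcome_binary)


def _ivw_core(bx, by, sy):
    """Weighted regression of by on bx through the origin; returns (beta, se_fixed, Q)."""
    w = bx**2 / sy**2
    beta = float(np.sum(bx * by / sy**2) / np.sum(bx**2 / sy**2))
    se_fixed = float(1.0 / np.sqrt(np.sum(w)))
    q = float(np.sum(w * (by / bx - beta) ** 2))
    return beta, se_fixed, q


def ivw(
    h: HarmonizedSet,
    mode: str = "multiplicative_random",
    outcome_binary: bool = False,
    min_k: int = 2,
) -> MrEstimate:
    """Inverse-variance-weighted estimate pooling per-SNP Wald ratios.

    ``mode`` chooses fixed-effect or multiplicative-random-effect standard
    errors (the latter inflates by sqrt(Q/(k-1)), floored at 1).
    """
    if mode not in ("fixed", "multiplicative_random"):
        raise EstimationError(f"unknown IVW mode {mode!r}")
    bx, by, sy = h.beta_x, h.beta_y, h.se_y
    k = h.k
    if k < min_k:
        raise InsufficientInstrumentsError(f"IVW needs >= {min_k} instruments, got {k}")
    if np.any(bx == 0):
        raise EstimationError("IVW: zero exposure beta (degenerate instrument)")
    beta, se_fixed, q = _ivw_core(bx, by, sy)
    df = k - 1
    q_pval = cochran_q_pval(q, df)
    se = se_fixed
    if mode == "multiplicative_random" and df >= 1:
        se = se_fixed * max(1.0, float(np.sqrt(q / df)))
    tag = "ivw_fe" if mode == "fixed" else "ivw_mre"
    return MrEstimate(tag, beta, se, _norm_p(beta / se), k, q=q, q_pval=q_pval, outcome_binary=outcome_binary)


def mr_egger(h: HarmonizedSet, outcome_binary: bool = False) -> MrEstimate:
    """Egger regression: weighted fit of by on bx *with* an intercept.

    Pairs are oriented so every exposure beta is non-negative; a nonzero
    intercept estimates the average directional pleiotropic effect.
    Standard errors carry a multiplicative overdispersion factor floored
    at 1 (residual Q on k-2 degrees of freedom).
    """
    if h.k < 3:
        raise InsufficientInstrumentsError(f"MR-Egger needs >= 3 instruments, got {h.k}")
    sign = np.where(h.beta_x < 0, -1.0, 1.0)
    bx = h.beta_x * sign
    by = h.beta_y * sign
    w = 1.0 / h.se_y**2

    x = np.column_stack([np.ones_like(bx), bx])
    xtwx = x.T @ (w[:, None] * x)
    xtwy = x.T @ (w * by)
    coef = np.linalg.solve(xtwx, xtwy)
    resid = by - x @ coef
    q = float(np.sum(w * resid**2))
    df = h.k - 2
    phi = max(1.0, q / df) if df >= 1 else 1.0
    cov = np.linalg.inv(xtwx) * phi
    inter, slope = float(coef[0]), float(coef[1])
    se_inter, se_slope = float(np.sqrt(cov[0, 0])), float(np.sqrt(cov[1, 1]))
    return MrEstimate(
        "egger",
        slope,
        se_slope,
        _norm_p(slope / se_slope),
        h.k,
        q=q,
        q_pval=cochran_q_pval(q, df),
        egger_intercept=inter,
        intercept_pval=_norm_p(inter / se_inter),
        outcome_binary=outcome_binary,
    )


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(values, kind="stable")
    v = values[order]
    w = weights[order] / weights.sum()
    s = np.cumsum(w) - 0.5 * w  # standardized cumulative weights
    return float(np.interp(0.5, s, v))


def weighted_median(
    h: HarmonizedSet,
    n_boot: int = 1000,
    seed: int | None = None,
    outcome_binary: bool = False,
) -> MrEstimate:
    """Weighted-median estimator: the 50% point of the weighted empirical
    distribution of per-SNP ratio estimates.

    Consistent when instruments carrying a majority of the weight are
    valid.  The standard error comes from a seeded parametric bootstrap
    (``n_boot`` resamples of beta_x, beta_y around their observed values).
    """
    if h.k < 3:
        raise InsufficientInstrumentsError(f"weighted median needs >= 3 instruments, got {h.k}")
    if seed is None:
        raise EstimationError("weighted_median requires an explicit seed")
    bx, sx, by, sy = h.beta_x, h.se_x, h.beta_y, h.se_y
    if np.any(bx == 0):
        raise EstimationError("weighted median: zero exposure beta")
    ratios = by / bx
    weights = bx**2 / sy**2
    beta = _weighted_median(ratios, weights)

    rng = np.random.default_rng(seed)
    bx_star = rng.normal(bx, sx, size=(n_boot, h.k))
    by_star = rng.normal(by, sy, size=(n_boot, h.k))
    boots = np.empty(n_boot)
    for i in range(n_boot):
        bxs = np.where(bx_star[i] == 0, np.finfo(float).tiny, bx_star[i])
        boots[i] = _weighted_median(by_star[i] / bxs, bxs**2 / sy**2)
    se = float(boots.std(ddof=1))
    pval = _norm_p(beta / se) if se > 0 else 0.0
    return MrEstimate("weighted_median", beta, se, pval, h.k, outcome_binary=outcome_binary)


def run_mr_suite(
    h: HarmonizedSet,
    outcome_binary: bool,
    seed: int,
    methods: tuple = ("ivw", "weighted_median", "egger", "presso"),
    ivw_mode: str = "multiplicative_random",
    n_boot: int = 1000,
    n_sim: int = 1000,
) -> list[MrEstimate]:
    """The full estimator suite: IVW (primary), weighted median, MR-Egger,
    and the outlier-corrected IVW from MR-PRESSO."""
    from .presso import presso  # deferred: presso depends on this module

    out: list[MrEstimate] = []
    for m in methods:
        if m == "ivw":
            out.append(ivw(h, mode=ivw_mode, outcome_binary=outcome_binary))
        elif m == "weighted_median":
            out.append(weighted_median(h, n_boot=n_boot, seed=seed, outcome_binary=outcome_binary))
        elif m == "egger":
            out.append(mr_egger(h, outcome_binary=outcome_binary))
        elif m == "presso":
            out.append(presso(h, n_sim=n_sim, seed=seed, outcome_binary=outcome_binary).corrected_estimate)
        else:
            raise EstimationError(f"unknown method {m!r}")
    return out
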