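"""Inverse-variance meta-analysis of MR estimates across replicate datasets.

Fixed-effect pooling weights each study by 1/se^2; the DerSimonian-Laird
random-effects variant adds a method-of-moments between-study variance
tau^2 (truncated at zero) to every weight.  Confidence intervals are
beta +/- 1.96*se on the linear scale, exponentiated to odds ratios when
the inputs are log odds.  Literature-style inputs quoted as 95% CIs are
converted to standard errors as (upper - lower)/(2*1.96).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DataError
from .estimators import Z95, _norm_p, cochran_q_pval


@dataclass(frozen=True)
class MetaResult:
    beta: float
    se: float
    pval: float
    q: float
    q_pval: float
    tau2: float
    mode: str
    inputs: tuple  # (beta, se, label) triples

    @property
    def ci_low(self) -> float:
        return self.beta - Z95 * self.se

    @property
    def ci_high(self) -> float:
        return self.beta + Z95 * self.se

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.beta))

    @property
    def or_low(self) -> float:
        return float(np.exp(self.ci_low))

    @property
    def or_high(self) -> float:
        return float(np.exp(self.ci_high))

    def as_dict(self) -> dict:
        return {
            "mode": self.mode,
            "beta": self.beta,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "odds_ratio": self.odds_ratio,
            "or_low": self.or_low,
            "or_high": self.or_high,
            "pval": self.pval,
            "q": self.q,
            "q_pval": self.q_pval,
            "tau2": self.tau2,
            "inputs": [list(t) for t in self.inputs],
        }


def ci_to_se(ci_low: float, ci_high: float) -> float:
    """Standard error implied by a printed 95% interval: (hi - lo)/(2*1.96)."""
    if ci_high <= ci_low:
        raise DataError("ci_to_se: upper bound must exceed lower bound")
    return (ci_high - ci_low) / (2 * Z95)


def _check(estimates):
    est = [(float(b), float(s)) for b, s in estimates]
    if len(est) < 2:
        raise DataError("meta-analysis needs at least two estimates")
    if any(s <= 0 for _, s in est):
        raise DataError("meta-analysis: all ses must be > 0")
    return np.array([b for b, _ in est]), np.array([s for _, s in est])


def meta_fixed(estimates, labels=None) -> MetaResult:
    """Fixed-effect inverse-variance pooling of (beta, se) pairs."""
    betas, ses = _check(estimates)
    w = 1.0 / ses**2
    beta = float(np.sum(w * betas) / np.sum(w))
    se = float(1.0 / np.sqrt(np.sum(w)))
    q = float(np.sum(w * (betas - beta) ** 2))
    labels = labels or [f"study{i+1}" for i in range(len(betas))]
    return MetaResult(
        beta, se, _norm_p(beta / se), q, cochran_q_pval(q, len(betas) - 1), 0.0, "fixed",
        tuple((float(b), float(s), l) for b, s, l in zip(betas, ses, labels)),
    )


def meta_dl_random(estimates, labels=None) -> MetaResult:
    """DerSimonian-Laird random-effects pooling; reduces to fixed effect
    when the heterogeneity Q does not exceed its degrees of freedom."""
    betas, ses = _check(estimates)
    w = 1.0 / ses**2
    fixed_beta = float(np.sum(w * betas) / np.sum(w))
    q = float(np.sum(w * (betas - fixed_beta) ** 2))
    df = len(betas) - 1
    denom = np.sum(w) - np.sum(w**2) / np.sum(w)
    tau2 = float(max(0.0, (q - df) / denom)) if denom > 0 else 0.0
    w_star = 1.0 / (ses**2 + tau2)
    beta = float(np.sum(w_star * betas) / np.sum(w_star))
    se = float(1.0 / np.sqrt(np.sum(w_star)))
    labels = labels or [f"study{i+1}" for i in range(len(betas))]
    return MetaResult(
        beta, se, _norm_p(beta / se), q, cochran_q_pval(q, df), tau2, "dl_random",
        tuple((float(b), float(s), l) for b, s, l in zip(betas, ses, labels)),
    )
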