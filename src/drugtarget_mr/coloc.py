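"""Approximate-Bayes-factor colocalization.

Given per-variant association summaries for two traits over one genomic
region, compares five hypotheses about the region's causal configuration:

* H0 — no association with either trait,
* H1 / H2 — association with one trait only,
* H3 — both traits associated through *distinct* causal variants,
* H4 — both traits share a *single* causal variant.

Per-variant evidence is the Wakefield approximate Bayes factor computed
from (beta, se) with a normal prior on the true effect; hypothesis
posteriors follow from prior-weighted sums over single-causal-variant
configurations, normalized in log space.  A region is declared colocalized
when the posterior of H4 exceeds a threshold (0.70 by default, the
decision rule used for drug-target instrument validation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .errors import DataError


@dataclass(frozen=True)
class ColocResult:
    """Posterior probabilities PP.H0..PP.H4 for one region."""

    pp: dict
    n_variants: int
    priors: tuple
    h4_threshold: float

    @property
    def colocalized(self) -> bool:
        return self.pp["PP.H4"] > self.h4_threshold

    def as_dict(self) -> dict:
        out = dict(self.pp)
        out.update(
            n_variants=self.n_variants,
            priors={"p1": self.priors[0], "p2": self.priors[1], "p12": self.priors[2]},
            h4_threshold=self.h4_threshold,
            colocalized=self.colocalized,
        )
        return out


def wakefield_labf(beta, se, prior_sd: float) -> np.ndarray:
    """Log approximate Bayes factor for association at one variant.

    With V = se^2, W = prior_sd^2 and z = beta/se:
    lABF = 0.5 * [ln(V/(V+W)) + z^2 * W/(V+W)].
    """
    beta = np.asarray(beta, float)
    se = np.asarray(se, float)
    if np.any(se <= 0):
        raise DataError("wakefield_labf: se must be > 0")
    if prior_sd <= 0:
        raise DataError("wakefield_labf: prior_sd must be > 0")
    v = se**2
    w = prior_sd**2
    z2 = (beta / se) ** 2
    r = w / (v + w)
    return 0.5 * (np.log(1 - r) + z2 * r)


def _log_or_neginf(x: float) -> float:
    return np.log(x) if x > 0 else -np.inf


def coloc_abf(
    beta1,
    se1,
    beta2,
    se2,
    p1: float = 1e-4,
    p2: float = 1e-4,
    p12: float = 1e-5,
    prior_sd1: float = 0.15,
    prior_sd2: float = 0.15,
    h4_threshold: float = 0.70,
) -> ColocResult:
    """Colocalize two traits over a shared, identically ordered variant set.

    ``p1``/``p2`` are the per-variant prior probabilities of association
    with trait 1/2 only and ``p12`` the prior of shared causality; the
    defaults are the canonical single-variant colocalization priors.
    """
    beta1, se1 = np.asarray(beta1, float), np.asarray(se1, float)
    beta2, se2 = np.asarray(beta2, float), np.asarray(se2, float)
    if not (len(beta1) == len(se1) == len(beta2) == len(se2)):
        raise DataError("coloc_abf: variant lists differ in length")
    if len(beta1) < 1:
        raise DataError("coloc_abf: need at least one variant")

    l1 = wakefield_labf(beta1, se1, prior_sd1)
    l2 = wakefield_labf(beta2, se2, prior_sd2)

    s1 = logsumexp(l1)            # log sum_i ABF1_i
    s2 = logsumexp(l2)            # log sum_j ABF2_j
    s12 = logsumexp(l1 + l2)      # log sum_i ABF1_i * ABF2_i (same variant)
    # H3 sums over distinct-variant pairs: total cross product minus the
    # same-variant diagonal, done stably in log space
    cross = s1 + s2
    if len(beta1) == 1 or s12 >= cross:
        s3 = -np.inf  # single variant: no distinct-pair configuration
    else:
        s3 = cross + np.log1p(-np.exp(s12 - cross))

    lh = np.array(
        [
            0.0,
            _log_or_neginf(p1) + s1,
            _log_or_neginf(p2) + s2,
            _log_or_neginf(p1) + _log_or_neginf(p2) + s3,
            _log_or_neginf(p12) + s12,
        ]
    )
    post = np.exp(lh - logsumexp(lh))
    pp = {f"PP.H{i}": float(post[i]) for i in range(5)}
    return ColocResult(pp, len(beta1), (p1, p2, p12), h4_threshold)
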