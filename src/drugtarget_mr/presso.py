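"""MR-PRESSO: pleiotropy residual sum of squares and outlier test.

Detects instruments whose outcome associations deviate from the causal
model implied by the remaining instruments.  Three parts:

* **global test** — the observed weighted residual sum of squares (each
  instrument's residual taken against the leave-one-out IVW fit) is
  compared with its distribution under ``n_sim`` parametric simulations of
  a pleiotropy-free model;
* **outlier test** — each instrument's observed squared residual is
  compared with its own simulated distribution, Bonferroni-corrected over
  the instrument count; flagged instruments are removed in a single pass;
* **distortion test** — the shift between the raw and outlier-corrected
  estimates is compared with shifts from removing random subsets of the
  same size.

P-values use the add-one estimator (1 + exceedances)/(n_sim + 1), so they
are never exactly zero, and the whole result is a pure function of the
inputs and the seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import EstimationError, InsufficientInstrumentsError
from .estimators import MrEstimate, ivw
from .sumstats import HarmonizedSet


@dataclass(frozen=True)
class PressoResult:
    rss_obs: float
    global_pval: float
    per_snp_pvals: np.ndarray
    outlier_ids: list[str]
    beta_raw: float
    beta_corrected: float
    distortion_pval: float | None
    n_sim: int
    seed: int
    corrected_estimate: MrEstimate

    def as_dict(self) -> dict:
        return {
            "rss_obs": self.rss_obs,
            "global_pval": self.global_pval,
            "per_snp_pvals": [float(p) for p in self.per_snp_pvals],
            "outlier_ids": list(self.outlier_ids),
            "beta_raw": self.beta_raw,
            "beta_corrected": self.beta_corrected,
            "distortion_pval": self.distortion_pval,
            "n_sim": self.n_sim,
            "seed": self.seed,
        }


def _loo_betas(bx: np.ndarray, by: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leave-one-out IVW slopes, vectorized over the left-out index.

    Supports batched inputs of shape (..., k); weights broadcast.
    """
    s1 = np.sum(bx * by * w, axis=-1, keepdims=True)
    s2 = np.sum(bx**2 * w, axis=-1, keepdims=True)
    return (s1 - bx * by * w) / (s2 - bx**2 * w)


def presso(
    h: HarmonizedSet,
    n_sim: int = 1000,
    outlier_alpha: float = 0.05,
    seed: int | None = None,
    outcome_binary: bool = False,
) -> PressoResult:
    """Run the global, outlier and distortion tests on a harmonized set."""
    if h.k < 4:
        raise InsufficientInstrumentsError(f"MR-PRESSO needs >= 4 instruments, got {h.k}")
    if seed is None:
        raise EstimationError("presso requires an explicit seed")
    bx, sx, by, sy = h.beta_x, h.se_x, h.beta_y, h.se_y
    k = h.k
    w = 1.0 / sy**2

    beta_loo = _loo_betas(bx, by, w)
    resid = by - beta_loo * bx
    obs_sq = w * resid**2
    rss_obs = float(obs_sq.sum())

    # parametric null: redraw both sides around the no-pleiotropy fit
    rng = np.random.default_rng(seed)
    expected_y = beta_loo * bx
    bx_star = rng.normal(bx, sx, size=(n_sim, k))
    by_star = rng.normal(expected_y, sy, size=(n_sim, k))
    loo_star = _loo_betas(bx_star, by_star, w)
    sq_star = w * (by_star - loo_star * bx_star) ** 2
    rss_star = sq_star.sum(axis=1)

    global_pval = float((1 + np.sum(rss_star >= rss_obs)) / (n_sim + 1))
    per_snp_pvals = (1 + np.sum(sq_star >= obs_sq, axis=0)) / (n_sim + 1)
    flagged = per_snp_pvals < outlier_alpha / k
    outlier_ids = [vid for vid, f in zip(h.variant_ids, flagged) if f]

    raw = ivw(h, mode="multiplicative_random", outcome_binary=outcome_binary)
    n_out = int(flagged.sum())
    if n_out == k or k - n_out < 2:
        raise EstimationError("MR-PRESSO flagged (almost) all instruments as outliers")

    if n_out == 0:
        corrected = MrEstimate(
            "ivw_presso", raw.beta, raw.se, raw.pval, raw.k,
            q=raw.q, q_pval=raw.q_pval, outcome_binary=outcome_binary, n_outliers=0,
        )
        return PressoResult(
            rss_obs, global_pval, per_snp_pvals, [], raw.beta, raw.beta,
            None, n_sim, seed, corrected,
        )

    keep_df = h.df[~flagged].reset_index(drop=True)
    h_clean = HarmonizedSet(h.exposure_label, h.outcome_label, keep_df)
    corr = ivw(h_clean, mode="multiplicative_random", outcome_binary=outcome_binary)
    corrected = MrEstimate(
        "ivw_presso", corr.beta, corr.se, corr.pval, corr.k,
        q=corr.q, q_pval=corr.q_pval, outcome_binary=outcome_binary, n_outliers=n_out,
    )

    # distortion null: random same-size removals
    d_obs = raw.beta - corr.beta
    n_draws = 1000
    d_null = np.empty(n_draws)
    idx = np.arange(k)
    for b in range(n_draws):
        drop = rng.choice(idx, size=n_out, replace=False)
        mask = np.ones(k, bool)
        mask[drop] = False
        beta_b = float(np.sum(bx[mask] * by[mask] * w[mask]) / np.sum(bx[mask] ** 2 * w[mask]))
        d_null[b] = raw.beta - beta_b
    distortion_pval = float((1 + np.sum(np.abs(d_null) >= abs(d_obs))) / (n_draws + 1))

    return PressoResult(
        rss_obs, global_pval, per_snp_pvals, outlier_ids, raw.beta, corr.beta,
        distortion_pval, n_sim, seed, corrected,
    )
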