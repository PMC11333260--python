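"""Multivariable MR and two-step mediation decomposition.

The mediation model is the product-of-coefficients decomposition on the
summary-statistic scale: with

* ``beta1`` — effect of the (drug-target) exposure on the mediator,
* ``beta2`` — univariable effect of the mediator on the outcome,
* ``beta2_adj`` — mediator effect on the outcome *conditional on* the
  exposure, from multivariable MR (MVMR),
* ``beta3`` — total exposure effect on the outcome,

the indirect effect is ``beta1 * beta2_adj`` (or ``beta1 * beta2`` for the
unadjusted variant) and the proportion mediated is the indirect effect
divided by ``beta3``.  Proportions are reported signed and unclamped;
values outside [0, 1] indicate inconsistent mediation and raise a warning
rather than an error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from .errors import CollinearityError, EstimationError, InsufficientInstrumentsError
from .estimators import _norm_p, cochran_q_pval, ivw
from .instruments import InstrumentSet
from .sumstats import GwasTable, harmonize_pair


@dataclass(frozen=True)
class MvmrEstimate:
    """Conditional (direct) effects of m exposures from multivariable IVW."""

    betas: np.ndarray
    ses: np.ndarray
    pvals: np.ndarray
    k: int
    m: int
    q: float
    q_pval: float
    exposure_labels: tuple

    def as_dict(self) -> dict:
        return {
            "exposures": list(self.exposure_labels),
            "betas": [float(b) for b in self.betas],
            "ses": [float(s) for s in self.ses],
            "pvals": [float(p) for p in self.pvals],
            "k": self.k,
            "q": self.q,
            "q_pval": self.q_pval,
        }


@dataclass(frozen=True)
class MediationResult:
    """Two-step mediation decomposition with both UVMR and MVMR variants."""

    beta1: float
    beta2: float
    beta2_adj: float
    beta3: float
    estimates: dict  # per-leg MrEstimate / MvmrEstimate objects

    @property
    def indirect_uvmr(self) -> float:
        return self.beta1 * self.beta2

    @property
    def indirect_mvmr(self) -> float:
        return self.beta1 * self.beta2_adj

    @property
    def proportion_uvmr(self) -> float:
        return proportion_mediated(self.beta1, self.beta2, self.beta3)

    @property
    def proportion_mvmr(self) -> float:
        return proportion_mediated(self.beta1, self.beta2_adj, self.beta3)

    def as_dict(self) -> dict:
        return {
            "beta1": self.beta1,
            "beta2": self.beta2,
            "beta2_adj": self.beta2_adj,
            "beta3": self.beta3,
            "indirect_uvmr": self.indirect_uvmr,
            "indirect_mvmr": self.indirect_mvmr,
            "proportion_uvmr": self.proportion_uvmr,
            "proportion_mvmr": self.proportion_mvmr,
        }


def mvmr_ivw(
    exposure_betas: np.ndarray,
    outcome_beta: np.ndarray,
    outcome_se: np.ndarray,
    exposure_labels: tuple | None = None,
    min_condition: float = 1e8,
) -> MvmrEstimate:
    """Multivariable IVW: weighted regression of outcome betas on the
    exposure-beta matrix, no intercept, weights 1/se_y^2.

    Standard errors carry a multiplicative overdispersion factor
    max(1, Q/(k - m)) on the coefficient covariance.
    """
    x = np.atleast_2d(np.asarray(exposure_betas, float))
    y = np.asarray(outcome_beta, float)
    sy = np.asarray(outcome_se, float)
    k, m = x.shape
    if m < 1 or k <= m:
        raise InsufficientInstrumentsError(f"MVMR needs k > m (got k={k}, m={m})")
    # pass min_condition=inf to relax the collinearity guard (testing only)
    if np.isfinite(min_condition) and (
        np.linalg.matrix_rank(x) < m or np.linalg.cond(x.T @ x) > min_condition
    ):
        norms = np.linalg.norm(x, axis=0)
        bad = [i for i, nrm in enumerate(norms) if nrm == 0]
        labels = exposure_labels or tuple(f"x{i}" for i in range(m))
        named = [labels[i] for i in bad] if bad else list(labels)
        raise CollinearityError(f"exposure-beta matrix rank deficient (columns: {named})")

    w = 1.0 / sy**2
    fit = sm.WLS(y, x, weights=w).fit()
    resid = y - x @ fit.params
    q = float(np.sum(w * resid**2))
    df = k - m
    phi = max(1.0, q / df)
    cov = np.linalg.pinv(x.T @ (w[:, None] * x)) * phi
    ses = np.sqrt(np.diag(cov))
    betas = np.asarray(fit.params, float)
    pvals = np.array([_norm_p(b / s) for b, s in zip(betas, ses)])
    labels = exposure_labels or tuple(f"x{i}" for i in range(m))
    return MvmrEstimate(betas, ses, pvals, k, m, q, cochran_q_pval(q, df), tuple(labels))


def proportion_mediated(beta1: float, beta2_path: float, beta3: float) -> float:
    """Indirect effect beta1*beta2_path as a signed fraction of the total
    effect beta3; not clamped to [0, 1]."""
    if beta3 == 0:
        raise EstimationError("proportion_mediated undefined: total effect beta3 is zero")
    prop = beta1 * beta2_path / beta3
    if not 0 <= prop <= 1:
        warnings.warn(
            f"proportion mediated {prop:.3g} outside [0, 1]: inconsistent-sign mediation",
            stacklevel=2,
        )
    return float(prop)


def proportion_mediated_se(beta1, se1, beta2_path, se2, beta3, se3) -> float:
    """Optional first-order delta-method se for the proportion (treats the
    three estimates as independent across GWAS samples).  An extension
    beyond the core decomposition; off by default in reports."""
    p = beta1 * beta2_path / beta3
    rel_var = (se1 / beta1) ** 2 + (se2 / beta2_path) ** 2 + (se3 / beta3) ** 2
    return float(abs(p) * np.sqrt(rel_var))


def _harmonized_mvmr_design(
    exposure_gwas: GwasTable,
    mediator_gwas: GwasTable,
    outcome_gwas: GwasTable,
    variant_ids: list,
):
    """Align exposure/mediator/outcome betas to the exposure effect allele
    over a shared instrument union; returns (X, y, sy, ids)."""
    h_m = harmonize_pair(exposure_gwas, mediator_gwas, variant_ids)
    h_y = harmonize_pair(exposure_gwas, outcome_gwas, variant_ids)
    common = [v for v in h_m.variant_ids if v in set(h_y.variant_ids)]
    if len(common) <= 2:
        raise InsufficientInstrumentsError(
            f"MVMR union has only {len(common)} instruments after harmonization"
        )
    dm = h_m.df.set_index("variant_id").loc[common]
    dy = h_y.df.set_index("variant_id").loc[common]
    x = np.column_stack([dy["beta_x"].to_numpy(float), dm["beta_y"].to_numpy(float)])
    return x, dy["beta_y"].to_numpy(float), dy["se_y"].to_numpy(float), common


def two_step_mediation(
    exposure_instruments: InstrumentSet,
    mediator_gwas: GwasTable,
    mediator_instruments: InstrumentSet,
    outcome_gwas: GwasTable,
    seed: int,
    exposure_gwas: GwasTable | None = None,
    ivw_mode: str = "multiplicative_random",
) -> MediationResult:
    """Two-step MR mediation through one mediator.

    Legs: beta1 = IVW(exposure -> mediator) on the exposure instruments;
    beta2 = IVW(mediator -> outcome) on the mediator instruments;
    beta3 = IVW(exposure -> outcome); beta2_adj = the mediator's conditional
    effect from MVMR.  When ``exposure_gwas`` is supplied the MVMR design
    uses the union of exposure and mediator instruments (exposure betas for
    mediator instruments looked up in the full exposure GWAS); otherwise it
    falls back to the exposure instruments alone.
    """
    if exposure_instruments.k < 1 or mediator_instruments.k < 1:
        raise InsufficientInstrumentsError("empty instrument set")
    exp_table = exposure_instruments.to_gwas_table()
    outcome_binary = outcome_gwas.trait_type == "binary"

    h1 = harmonize_pair(exp_table, mediator_gwas, exposure_instruments.variant_ids)
    est1 = ivw(h1, mode=ivw_mode)

    med_table = mediator_instruments.to_gwas_table()
    h2 = harmonize_pair(med_table, outcome_gwas, mediator_instruments.variant_ids)
    est2 = ivw(h2, mode=ivw_mode, outcome_binary=outcome_binary)

    h3 = harmonize_pair(exp_table, outcome_gwas, exposure_instruments.variant_ids)
    est3 = ivw(h3, mode=ivw_mode, outcome_binary=outcome_binary)

    if exposure_gwas is not None:
        union = list(dict.fromkeys(exposure_instruments.variant_ids + mediator_instruments.variant_ids))
        x, y, sy, ids = _harmonized_mvmr_design(exposure_gwas, mediator_gwas, outcome_gwas, union)
        if exposure_instruments.inverted:
            x[:, 0] = -x[:, 0]  # keep the exposure column on the inhibition scale
    else:
        x, y, sy, ids = _harmonized_mvmr_design(exp_table, mediator_gwas, outcome_gwas, exposure_instruments.variant_ids)
    labels = (exposure_instruments.exposure_label, mediator_gwas.trait_label)
    mv = mvmr_ivw(x, y, sy, exposure_labels=labels)

    return MediationResult(
        beta1=est1.beta,
        beta2=est2.beta,
        beta2_adj=float(mv.betas[1]),
        beta3=est3.beta,
        estimates={"beta1": est1, "beta2": est2, "beta3": est3, "mvmr": mv, "mvmr_instruments": ids},
    )
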