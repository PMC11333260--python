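"""Synthetic GWAS summary statistics with known ground truth.

Every generator is a pure function of its parameters and an explicit seed,
producing the same delimited-table containers the real pipeline consumes,
so each stage can be validated against injected truth without external
downloads.

Three scenario families:

* :func:`simulate_region` — a single LD region (AR(1) correlation) with
  one causal variant per trait, shared or distinct, for colocalization;
* :func:`simulate_mediation_gwas` — four trait GWASs over independent
  instrument SNPs following the mediation DAG
  exposure -> mediator -> outcome plus a direct exposure -> outcome path,
  with configurable horizontal pleiotropy, and an independent replicate of
  the mediator GWAS for meta-analysis;
* :func:`simulate_outcome_panel` — many outcome GWASs over one instrument
  set, a chosen number carrying a true effect, for screen calibration.

Default GWAS sample sizes mirror the study's data sources: 344,182 for the
biomarker-scale exposure (a UK-Biobank-sized HbA1c GWAS), 8,299 for the
metabolite mediator (a CLSA-sized panel), 140,254 for the case-control
outcome (a PRACTICAL-sized prostate-cancer GWAS) and 218,792 for screening
outcomes (a FinnGen-sized registry cohort).  Summary statistics are drawn
directly at summary level — marginal betas are LD-propagated true joint
effects plus multivariate-normal sampling noise with covariance LD/n — and
per-variant standard errors scale as 1/sqrt(n) on the standardized scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError
from .instruments import InstrumentSet
from .sumstats import GwasTable


@dataclass(frozen=True)
class SimulationTruth:
    """Ground-truth parameters of the mediation DAG.

    ``theta_total = theta_direct + theta_xm * theta_my`` by construction.
    ``pleiotropy_mode`` controls direct instrument -> outcome effects:
    ``none``, ``balanced`` (zero-mean) or ``directional`` (mean
    ``pleiotropy_mean``); ``pleiotropy_frac`` is the fraction of exposure
    instruments that are pleiotropic (1.0 = all).
    """

    theta_xm: float = 0.4
    theta_my: float = 0.25
    theta_direct: float = -0.9
    shared_causal: bool = True
    pleiotropy_mode: str = "none"
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.02
    pleiotropy_frac: float = 1.0
    n_exposure: int = 344_182
    n_mediator: int = 8_299
    n_mediator_replicate: int = 8_299
    n_outcome: int = 140_254
    ld_rho: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.pleiotropy_mode not in ("none", "balanced", "directional"):
            raise ConfigError(f"unknown pleiotropy_mode {self.pleiotropy_mode!r}")
        if not 0 <= self.ld_rho < 1:
            raise ConfigError("ld_rho must be in [0, 1)")

    @property
    def theta_total(self) -> float:
        return self.theta_direct + self.theta_xm * self.theta_my

    @property
    def proportion_mediated(self) -> float:
        return self.theta_xm * self.theta_my / self.theta_total

    def as_dict(self) -> dict:
        d = {f: getattr(self, f) for f in self.__dataclass_fields__}
        d["theta_total"] = self.theta_total
        d["proportion_mediated"] = self.proportion_mediated
        return d


def _pvals(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    p = 2 * stats.norm.sf(np.abs(beta / se))
    return np.clip(p, 1e-300, 1.0)


def _table(label, trait_type, ids, chrom, pos, beta, se, eaf, n) -> GwasTable:
    beta = np.asarray(beta, float)
    se = np.asarray(se, float)
    df = pd.DataFrame(
        {
            "variant_id": ids,
            "chrom": [str(chrom)] * len(ids) if np.isscalar(chrom) else [str(c) for c in chrom],
            "pos": np.asarray(pos, np.int64),
            "effect_allele": "A",
            "other_allele": "G",
            "eaf": eaf,
            "beta": beta,
            "se": se,
            "pval": _pvals(beta, se),
            "n": n,
        }
    )
    return GwasTable(label, trait_type, df)


def ar1_corr(m: int, rho: float) -> np.ndarray:
    """AR(1) correlation matrix r_ij = rho^|i-j|."""
    idx = np.arange(m)
    return rho ** np.abs(idx[:, None] - idx[None, :])


def simulate_region(
    m_variants: int,
    ld_rho: float,
    n1: int,
    n2: int,
    shared_causal: bool,
    effect_size: float,
    seed: int,
    chrom: str = "16",
    causal_gap: int = 10,
) -> tuple[GwasTable, GwasTable, dict]:
    """One LD region observed in two GWASs, each with one causal variant.

    The causal index is shared iff ``shared_causal``; otherwise the second
    trait's causal variant sits ``causal_gap`` positions away.
    ``effect_size`` is the standardized joint effect, so the expected
    causal-variant z-score is effect_size * sqrt(n).
    """
    if m_variants < 2:
        raise ConfigError("simulate_region needs m_variants >= 2")
    if not 0 <= ld_rho < 1:
        raise ConfigError("ld_rho must be in [0, 1)")
    rng = np.random.default_rng(seed)
    r = ar1_corr(m_variants, ld_rho)
    chol = np.linalg.cholesky(r + 1e-12 * np.eye(m_variants))

    c1 = m_variants // 3
    c2 = c1 if shared_causal else min(m_variants - 1, c1 + max(causal_gap, 1))
    b1 = np.zeros(m_variants)
    b1[c1] = effect_size
    b2 = np.zeros(m_variants)
    b2[c2] = effect_size

    tables = []
    for b, n, tag in ((b1, n1, "trait1"), (b2, n2, "trait2")):
        se = np.full(m_variants, 1.0 / np.sqrt(n))
        noise = chol @ rng.standard_normal(m_variants) / np.sqrt(n)
        beta_hat = r @ b + noise
        ids = [f"rs{tag_i}" for tag_i in range(1, m_variants + 1)]
        pos = 100_000 + 1_000 * np.arange(m_variants)
        tables.append(_table(tag, "quantitative", ids, chrom, pos, beta_hat, se, 0.3, n))
    truth = {
        "causal_index_trait1": int(c1),
        "causal_index_trait2": int(c2),
        "shared_causal": bool(shared_causal),
        "effect_size": float(effect_size),
        "ld_rho": float(ld_rho),
        "seed": int(seed),
    }
    return tables[0], tables[1], truth


@dataclass
class MediationDatasets:
    """Bundle returned by :func:`simulate_mediation_gwas`."""

    exposure: GwasTable
    mediator: GwasTable
    mediator_replicate: GwasTable
    outcome: GwasTable
    truth: SimulationTruth
    exposure_snp_ids: list[str] = field(default_factory=list)
    mediator_snp_ids: list[str] = field(default_factory=list)
    true_exposure_betas: np.ndarray | None = None

    def exposure_instruments(self) -> InstrumentSet:
        return InstrumentSet.from_gwas(self.exposure, self.exposure_snp_ids)

    def mediator_instruments(self) -> InstrumentSet:
        return InstrumentSet.from_gwas(self.mediator, self.mediator_snp_ids)


def simulate_mediation_gwas(
    truth: SimulationTruth,
    k_exposure_snps: int = 10,
    k_mediator_snps: int = 10,
    instrument_strength: float = 0.012,
    mediator_snp_strength: float = 0.10,
    seed: int | None = None,
) -> MediationDatasets:
    """Generate the four-GWAS mediation test bed.

    Exposure instruments carry standardized effects of magnitude around
    ``instrument_strength`` (random sign); mediator-specific instruments
    around ``mediator_snp_strength`` (the mediator GWAS is much smaller, so
    its detectable effects are larger).  The outcome table is on the
    log-odds scale (``trait_type='binary'``).  Horizontal pleiotropy adds
    direct instrument -> outcome effects per ``truth.pleiotropy_mode``.
    """
    if k_exposure_snps < 4:
        raise ConfigError("k_exposure_snps must be >= 4 (MR-PRESSO minimum)")
    if instrument_strength <= 0:
        raise ConfigError("instrument_strength must be > 0")
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    ke, km = k_exposure_snps, k_mediator_snps

    b_x = instrument_strength * rng.uniform(0.7, 1.5, ke) * rng.choice([-1.0, 1.0], ke)
    b_m_own = mediator_snp_strength * rng.uniform(0.7, 1.5, km) * rng.choice([-1.0, 1.0], km)

    # horizontal pleiotropy: direct instrument -> outcome effects
    alpha = np.zeros(ke)
    if truth.pleiotropy_mode != "none":
        n_pleio = int(round(truth.pleiotropy_frac * ke))
        which = rng.choice(ke, size=n_pleio, replace=False)
        mean = truth.pleiotropy_mean if truth.pleiotropy_mode == "directional" else 0.0
        alpha[which] = rng.normal(mean, truth.pleiotropy_sd, n_pleio)

    exp_ids = [f"rs_exp{i+1}" for i in range(ke)]
    med_ids = [f"rs_med{i+1}" for i in range(km)]
    ids = exp_ids + med_ids
    chroms = ["16"] * ke + ["4"] * km
    pos = np.concatenate([31_480_000 + 5_000 * np.arange(ke), 68_600_000 + 5_000 * np.arange(km)])

    # pleiotropic effects are expressed relative to the exposure-increasing
    # allele (sign(b_x)): "directional" means directional after orienting
    # instruments by their exposure effect, the convention the Egger
    # intercept tests
    true_exp = np.concatenate([b_x, np.zeros(km)])
    true_med = np.concatenate([truth.theta_xm * b_x, b_m_own])
    true_out = np.concatenate(
        [truth.theta_total * b_x + alpha * np.sign(b_x), truth.theta_my * b_m_own]
    )

    def observe(true_beta, n, label, trait_type):
        se = np.full(len(true_beta), 1.0 / np.sqrt(n))
        beta_hat = true_beta + rng.normal(0.0, se)
        return _table(label, trait_type, ids, chroms, pos, beta_hat, se, 0.3, n)

    exposure = observe(true_exp, truth.n_exposure, "exposure", "quantitative")
    mediator = observe(true_med, truth.n_mediator, "mediator", "quantitative")
    mediator_rep = observe(true_med, truth.n_mediator_replicate, "mediator_replicate", "quantitative")
    outcome = observe(true_out, truth.n_outcome, "outcome", "binary")

    return MediationDatasets(
        exposure, mediator, mediator_rep, outcome, truth,
        exposure_snp_ids=exp_ids, mediator_snp_ids=med_ids, true_exposure_betas=b_x,
    )


def simulate_outcome_panel(
    instruments: InstrumentSet,
    n_outcomes: int,
    n_true: int,
    true_effect: float,
    seed: int,
    n_gwas: int = 218_792,
) -> tuple[list[GwasTable], list[bool]]:
    """A panel of outcome GWASs over the instrument variants.

    The first ``n_true`` outcomes (after seeded shuffling) carry the causal
    effect ``true_effect`` of the instrumented exposure; the rest are null.
    Returns the tables and a parallel list of truth labels.
    """
    if not 0 <= n_true <= n_outcomes:
        raise ConfigError("need 0 <= n_true <= n_outcomes")
    rng = np.random.default_rng(seed)
    is_true = np.array([True] * n_true + [False] * (n_outcomes - n_true))
    rng.shuffle(is_true)
    bx = instruments.betas
    k = instruments.k
    pos = instruments.positions if instruments.positions is not None else 1_000 * np.arange(1, k + 1)
    chroms = instruments.chroms if instruments.chroms is not None else ["1"] * k

    tables = []
    for i, flag in enumerate(is_true):
        effect = true_effect if flag else 0.0
        se = np.full(k, 1.0 / np.sqrt(n_gwas))
        beta_y = effect * bx + rng.normal(0.0, se)
        tables.append(
            _table(f"outcome_{i+1:04d}", "binary", instruments.variant_ids, chroms, pos, beta_y, se, 0.3, n_gwas)
        )
    return tables, [bool(f) for f in is_true]


def simulate_genotypes(
    n_individuals: int,
    m_variants: int,
    ld_rho: float = 0.0,
    maf: float = 0.3,
    seed: int = 0,
) -> np.ndarray:
    """Dosage matrix (0/1/2) from two latent-Gaussian haplotypes per person
    with AR(1) between-variant correlation; for LD-matrix testing."""
    rng = np.random.default_rng(seed)
    r = ar1_corr(m_variants, ld_rho)
    chol = np.linalg.cholesky(r + 1e-12 * np.eye(m_variants))
    thresh = stats.norm.ppf(maf)
    dosage = np.zeros((n_individuals, m_variants))
    for _ in range(2):
        z = rng.standard_normal((n_individuals, m_variants)) @ chol.T
        dosage += (z < thresh).astype(float)
    return dosage
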