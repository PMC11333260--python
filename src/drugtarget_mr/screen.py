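"""Batch-MR screening across many outcomes and lookup-style PheWAS.

Two phenome-wide operations share the Bonferroni machinery:

* :func:`screen_outcomes` runs the MR suite of one instrument set against
  a panel of outcome GWASs (the MR-PheWAS design) and flags outcomes whose
  primary IVW p-value beats alpha divided by the number of outcomes
  *attempted* — outcomes that fail harmonization still count toward the
  correction, so the family-wise guarantee is not weakened by failures;
* :func:`phewas_lookup` filters a long-format (snp, trait, p) association
  table at alpha divided by the number of SNP x trait pairs queried.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .errors import ConfigError, DataError, EstimationError
from .estimators import run_mr_suite
from .instruments import InstrumentSet
from .sumstats import GwasTable, harmonize_pair


def bonferroni_alpha(alpha: float, n_tests: int) -> float:
    """Family-wise corrected per-test significance level alpha/n_tests."""
    if not 0 < alpha < 1:
        raise ConfigError(f"alpha must be in (0,1), got {alpha}")
    if n_tests < 1:
        raise ConfigError(f"n_tests must be >= 1, got {n_tests}")
    return alpha / n_tests


@dataclass(frozen=True)
class ScreenResult:
    """One tidy row per outcome attempted, plus the multiplicity context."""

    table: pd.DataFrame
    n_tests: int
    alpha: float

    @property
    def adjusted_alpha(self) -> float:
        return bonferroni_alpha(self.alpha, self.n_tests)

    @property
    def significant(self) -> pd.DataFrame:
        return self.table[self.table["significant"]]


def screen_outcomes(
    instruments: InstrumentSet,
    outcomes: list[GwasTable],
    alpha: float = 0.05,
    seed: int = 0,
    methods: tuple = ("ivw", "weighted_median", "egger"),
    n_boot: int = 200,
) -> ScreenResult:
    """Run MR of one exposure against every outcome in a panel.

    Significance is judged on the primary IVW p-value at the strict
    Bonferroni level alpha/n_outcomes.  Rows are returned in sorted
    outcome-label order so the result is independent of input ordering.
    """
    if not outcomes:
        raise DataError("screen_outcomes: empty outcome panel")
    n_tests = len(outcomes)
    adj = bonferroni_alpha(alpha, n_tests)
    exp_table = instruments.to_gwas_table()

    rows = []
    n_failed = 0
    for out_gwas in sorted(outcomes, key=lambda t: t.trait_label):
        row = {"outcome_label": out_gwas.trait_label, "status": "ok", "failure_code": ""}
        try:
            h = harmonize_pair(exp_table, out_gwas, instruments.variant_ids)
            ests = run_mr_suite(
                h,
                outcome_binary=out_gwas.trait_type == "binary",
                seed=seed,
                methods=methods,
                n_boot=n_boot,
            )
            by_method = {e.method: e for e in ests}
            primary = by_method.get("ivw_mre") or by_method.get("ivw_fe") or ests[0]
            row.update(
                k=primary.k,
                beta=primary.beta,
                se=primary.se,
                ci_low=primary.ci_low,
                ci_high=primary.ci_high,
                pval=primary.pval,
                q=primary.q,
                q_pval=primary.q_pval,
                significant=primary.pval < adj,
            )
            for tag in ("weighted_median", "egger"):
                if tag in by_method:
                    row[f"{tag}_beta"] = by_method[tag].beta
                    row[f"{tag}_pval"] = by_method[tag].pval
            if "egger" in by_method:
                row["egger_intercept"] = by_method["egger"].egger_intercept
                row["intercept_pval"] = by_method["egger"].intercept_pval
        except (DataError, EstimationError) as exc:
            n_failed += 1
            row.update(status="failed", failure_code=type(exc).__name__, significant=False)
        rows.append(row)
    if n_failed == n_tests:
        raise DataError("screen_outcomes: every outcome failed harmonization")
    table = pd.DataFrame(rows).reset_index(drop=True)
    return ScreenResult(table, n_tests, alpha)


def phewas_lookup(associations: pd.DataFrame, alpha: float = 0.05, n_tests: int | None = None) -> ScreenResult:
    """Bonferroni filter over a long-format (snp, trait, pval) lookup table.

    ``n_tests`` defaults to the number of rows (SNP x trait pairs queried);
    pass it explicitly when the table was pre-filtered.
    """
    for col in ("snp", "trait", "pval"):
        if col not in associations.columns:
            raise ConfigError(f"phewas_lookup table missing column {col!r}")
    n = n_tests if n_tests is not None else len(associations)
    adj = bonferroni_alpha(alpha, n)
    table = associations.copy().reset_index(drop=True)
    table["significant"] = table["pval"] < adj
    return ScreenResult(table, n, alpha)
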