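"""GWAS summary statistics: containers, I/O, allele harmonization, LD.

A :class:`GwasTable` holds one trait's per-variant association statistics
(beta, se, p, allele frequency) with validated invariants.  Two tables are
combined into a :class:`HarmonizedSet` whose exposure/outcome effects are
expressed relative to a single effect allele per variant — the input every
two-sample MR estimator consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError

COLUMNS = [
    "variant_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pval",
    "n",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass(frozen=True)
class FilterRecord:
    """One structured exclusion/filter event (assertable in tests)."""

    step: str
    variant_id: str
    action: str
    reason: str


def _complement(allele: str) -> str:
    return "".join(_COMPLEMENT.get(b, "N") for b in reversed(allele)) if len(allele) > 1 else _COMPLEMENT.get(allele, "N")


def is_palindromic(a1: str, a2: str) -> bool:
    """A/T and C/G variant pairs read the same on both strands."""
    return {a1, a2} in ({"A", "T"}, {"C", "G"})


@dataclass
class GwasTable:
    """Per-variant summary statistics for a single trait.

    ``df`` has the canonical columns of :data:`COLUMNS`; ``trait_type`` is
    ``"binary"`` when betas are log odds ratios, else ``"quantitative"``.
    """

    trait_label: str
    trait_type: str
    df: pd.DataFrame
    log: list[FilterRecord] = field(default_factory=list)

    def __post_init__(self):
        if self.trait_type not in ("quantitative", "binary"):
            raise ConfigError(f"unknown trait_type {self.trait_type!r}")
        missing = [c for c in COLUMNS if c not in self.df.columns]
        if missing:
            raise ConfigError(f"GwasTable missing columns: {missing}")
        if self.df["variant_id"].duplicated().any():
            raise DataError(f"duplicate variant_id in table {self.trait_label!r}")

    @property
    def variant_ids(self) -> list[str]:
        return list(self.df["variant_id"])

    def __len__(self) -> int:
        return len(self.df)

    def subset(self, variant_ids) -> "GwasTable":
        keep = self.df[self.df["variant_id"].isin(set(variant_ids))].reset_index(drop=True)
        return GwasTable(self.trait_label, self.trait_type, keep)

    def lookup(self, variant_id: str) -> pd.Series:
        rows = self.df[self.df["variant_id"] == variant_id]
        if rows.empty:
            raise DataError(f"variant {variant_id} absent from {self.trait_label!r}")
        return rows.iloc[0]


def validate_records(df: pd.DataFrame, trait_label: str) -> tuple[pd.DataFrame, list[FilterRecord]]:
    """Drop rows violating record invariants; return (clean df, filter log).

    Invariants: se > 0, pval in (0, 1], alleles differ and are ACGT strings,
    eaf missing or in [0, 1].  Duplicated variant_id keeps the lowest-p row
    (ties broken by original file order).
    """
    log: list[FilterRecord] = []
    df = df.copy()
    df["effect_allele"] = df["effect_allele"].astype(str).str.upper()
    df["other_allele"] = df["other_allele"].astype(str).str.upper()
    for col in ("pos", "eaf", "beta", "se", "pval", "n"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df["chrom"] = df["chrom"].astype(str)

    allele_ok = (
        df["effect_allele"].str.fullmatch(r"[ACGT]+")
        & df["other_allele"].str.fullmatch(r"[ACGT]+")
        & (df["effect_allele"] != df["other_allele"])
    )
    checks = {
        "se_nonpositive": df["se"].notna() & (df["se"] > 0),
        "pval_out_of_range": df["pval"].notna() & (df["pval"] > 0) & (df["pval"] <= 1),
        "beta_missing": df["beta"].notna(),
        "pos_missing": df["pos"].notna(),
        "bad_alleles": allele_ok,
        "eaf_out_of_range": df["eaf"].isna() | ((df["eaf"] >= 0) & (df["eaf"] <= 1)),
    }
    bad = pd.Series(False, index=df.index)
    for reason, ok in checks.items():
        newly_bad = ~ok & ~bad
        for vid in df.loc[newly_bad, "variant_id"]:
            log.append(FilterRecord("validate", str(vid), "dropped", reason))
        bad |= ~ok
    df = df[~bad]

    if df["variant_id"].duplicated().any():
        # stable sort: lowest p wins, file order breaks ties
        order = df.assign(_ord=np.arange(len(df))).sort_values(["pval", "_ord"], kind="stable")
        dup_mask = order.duplicated("variant_id", keep="first")
        for vid in order.loc[dup_mask, "variant_id"]:
            log.append(FilterRecord("validate", str(vid), "dropped", "duplicate_variant_id"))
        order = order[~dup_mask].sort_values("_ord")
        df = order.drop(columns="_ord")

    df = df.reset_index(drop=True)
    df["pos"] = df["pos"].astype(np.int64)
    if df.empty:
        raise DataError(f"no valid rows remain for trait {trait_label!r}")
    return df[COLUMNS], log


def read_sumstats(path, column_map: dict, trait_label: str, trait_type: str = "quantitative") -> GwasTable:
    """Read a delimited summary-statistics table.

    ``column_map`` maps canonical field names (:data:`COLUMNS`) to the
    physical column names in the file; ``eaf`` and ``n`` may be omitted.
    The delimiter is sniffed from the header (tab wins over comma).
    """
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ","
    raw = pd.read_csv(path, sep=sep, dtype={column_map.get("chrom", "chrom"): str})

    mandatory = [c for c in COLUMNS if c not in ("eaf", "n")]
    missing = [c for c in mandatory if column_map.get(c, c) not in raw.columns]
    if missing:
        raise ConfigError(f"{path}: column_map does not resolve {missing} in header {list(raw.columns)}")

    df = pd.DataFrame()
    for canon in COLUMNS:
        phys = column_map.get(canon, canon)
        df[canon] = raw[phys] if phys in raw.columns else np.nan
    df["variant_id"] = df["variant_id"].astype(str)
    clean, log = validate_records(df, trait_label)
    return GwasTable(trait_label, trait_type, clean, log)


def write_sumstats(table: GwasTable, path, sep: str = "\t") -> None:
    table.df.to_csv(path, sep=sep, index=False)


@dataclass
class HarmonizedSet:
    """Instrument-aligned exposure/outcome effects on a shared effect allele.

    Columns: variant_id, effect_allele, other_allele, beta_x, se_x,
    beta_y, se_y (exposure betas beta_x with standard errors se_x, outcome
    betas beta_y with se_y).
    """

    exposure_label: str
    outcome_label: str
    df: pd.DataFrame
    log: list[FilterRecord] = field(default_factory=list)

    def __post_init__(self):
        if len(self.df) < 1:
            raise DataError("HarmonizedSet requires at least one instrument")
        if (self.df[["se_x", "se_y"]] <= 0).any().any():
            raise DataError("non-positive standard error in HarmonizedSet")

    @property
    def k(self) -> int:
        return len(self.df)

    @property
    def beta_x(self) -> np.ndarray:
        return self.df["beta_x"].to_numpy(float)

    @property
    def se_x(self) -> np.ndarray:
        return self.df["se_x"].to_numpy(float)

    @property
    def beta_y(self) -> np.ndarray:
        return self.df["beta_y"].to_numpy(float)

    @property
    def se_y(self) -> np.ndarray:
        return self.df["se_y"].to_numpy(float)

    @property
    def variant_ids(self) -> list[str]:
        return list(self.df["variant_id"])

    def write(self, path, sep: str = "\t") -> None:
        cols = ["variant_id", "beta_x", "se_x", "beta_y", "se_y", "effect_allele", "other_allele"]
        self.df[cols].to_csv(path, sep=sep, index=False)


def _align_one(exp_row, out_row, eaf_window: float):
    """Return (beta_y, se_y, action) or (None, None, reason) for one variant."""
    ea, oa = exp_row["effect_allele"], exp_row["other_allele"]
    oea, ooa = out_row["effect_allele"], out_row["other_allele"]
    beta_y, se_y = float(out_row["beta"]), float(out_row["se"])

    if is_palindromic(ea, oa):
        # strand cannot be read from the alleles; use allele frequency,
        # excluding when either frequency is missing or near 0.5
        eaf_x, eaf_y = exp_row["eaf"], out_row["eaf"]
        if pd.isna(eaf_x) or pd.isna(eaf_y):
            return None, None, "palindromic_missing_eaf"
        if abs(eaf_x - 0.5) < eaf_window or abs(eaf_y - 0.5) < eaf_window:
            return None, None, "palindromic_ambiguous_eaf"
        if {oea, ooa} != {ea, oa} and {_complement(oea), _complement(ooa)} != {ea, oa}:
            return None, None, "allele_mismatch"
        # orient by frequency: effect alleles agree iff their frequencies
        # fall on the same side of 0.5
        if (eaf_x - 0.5) * (eaf_y - 0.5) > 0:
            return beta_y, se_y, "kept_palindromic_inferred"
        return -beta_y, se_y, "flipped_palindromic_inferred"

    if (oea, ooa) == (ea, oa):
        return beta_y, se_y, "kept"
    if (oea, ooa) == (oa, ea):
        return -beta_y, se_y, "flipped"
    cea, coa = _complement(oea), _complement(ooa)
    if (cea, coa) == (ea, oa):
        return beta_y, se_y, "kept_strand"
    if (cea, coa) == (oa, ea):
        return -beta_y, se_y, "flipped_strand"
    return None, None, "allele_mismatch"


def harmonize_pair(
    exposure: GwasTable,
    outcome: GwasTable,
    variant_ids,
    palindrome_eaf_window: float = 0.08,
) -> HarmonizedSet:
    """Align outcome effects to the exposure's effect allele per variant.

    Identical alleles pass through; swapped alleles negate the outcome beta
    (and reflect eaf); strand flips are complemented first; palindromic
    variants with allele frequency within ``palindrome_eaf_window`` of 0.5
    in either dataset are excluded as strand-ambiguous.
    """
    variant_ids = list(variant_ids)
    if not variant_ids:
        raise DataError("harmonize_pair: empty variant_ids")
    exp_idx = exposure.df.set_index("variant_id")
    out_idx = outcome.df.set_index("variant_id")
    missing_exp = [v for v in variant_ids if v not in exp_idx.index]
    if missing_exp:
        raise DataError(f"variants absent from exposure table: {missing_exp[:5]}")

    rows, log = [], []
    for vid in variant_ids:
        exp_row = exp_idx.loc[vid]
        if vid not in out_idx.index:
            log.append(FilterRecord("harmonize", vid, "excluded", "missing_in_outcome"))
            continue
        beta_y, se_y, action = _align_one(exp_row, out_idx.loc[vid], palindrome_eaf_window)
        if beta_y is None:
            log.append(FilterRecord("harmonize", vid, "excluded", action))
            continue
        log.append(FilterRecord("harmonize", vid, "kept", action))
        rows.append(
            {
                "variant_id": vid,
                "effect_allele": exp_row["effect_allele"],
                "other_allele": exp_row["other_allele"],
                "beta_x": float(exp_row["beta"]),
                "se_x": float(exp_row["se"]),
                "beta_y": beta_y,
                "se_y": se_y,
            }
        )
    if not rows:
        reasons = sorted({r.reason for r in log})
        raise DataError(f"no variants survived harmonization (reasons: {reasons})")
    return HarmonizedSet(exposure.trait_label, outcome.trait_label, pd.DataFrame(rows), log)


def ld_matrix(genotypes: np.ndarray, variant_ids=None) -> pd.DataFrame:
    """Pearson correlation (r, not r^2) between dosage columns.

    ``genotypes`` is n_individuals x m_variants; a constant column is a
    data error (correlation undefined).
    """
    g = np.asarray(genotypes, float)
    if g.ndim != 2:
        raise DataError("genotype matrix must be 2-D (individuals x variants)")
    ids = list(variant_ids) if variant_ids is not None else [f"v{i}" for i in range(g.shape[1])]
    sd = g.std(axis=0)
    if np.any(sd == 0):
        names = [ids[i] for i in np.flatnonzero(sd == 0)]
        raise DataError(f"constant genotype column(s): {names}")
    r = np.corrcoef(g, rowvar=False)
    r = np.atleast_2d(r)
    return pd.DataFrame(r, index=ids, columns=ids)
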