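"""Drug-target instrument construction.

Proxies for pharmacological target inhibition are built from variants in a
cis-window around the target gene that are associated with the gene's
expression and with a downstream biomarker, pruned for linkage
disequilibrium, and sign-inverted so a positive instrumented exposure means
*inhibition* (the drug's direction of action).

Three clumping profiles mirror the study settings: a lenient profile for
the drug-target region (r^2 < 0.8 within 1,000 kb), a relaxed metabolite
profile (p < 1e-5, r^2 < 0.1, 500 kb) and a strict metabolite profile
(p < 5e-8, r^2 < 0.001, 10 Mb).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigError, SelectionError, StateError
from .sumstats import GwasTable

#: named (assoc_p, r2_threshold, window_bp) clumping profiles
PROFILES = {
    "sglt2": {"assoc_p": 1e-4, "r2_threshold": 0.8, "window_bp": 1_000_000},
    "metabolite_relaxed": {"assoc_p": 1e-5, "r2_threshold": 0.1, "window_bp": 500_000},
    "metabolite_strict": {"assoc_p": 5e-8, "r2_threshold": 0.001, "window_bp": 10_000_000},
}


@dataclass
class InstrumentSet:
    """An ordered set of instrumental variants with per-SNP effects.

    ``inverted`` records whether betas have been sign-flipped to represent
    target inhibition rather than raw biomarker-increasing effects.
    ``f_stats`` are per-SNP (beta/se)^2 instrument-strength statistics.
    """

    exposure_label: str
    variant_ids: list[str]
    betas: np.ndarray
    ses: np.ndarray
    pvals: np.ndarray | None = None
    effect_alleles: list[str] | None = None
    other_alleles: list[str] | None = None
    eafs: np.ndarray | None = None
    chroms: list[str] | None = None
    positions: np.ndarray | None = None
    inverted: bool = False
    selection_log: list[tuple] = field(default_factory=list)

    def __post_init__(self):
        self.betas = np.asarray(self.betas, float)
        self.ses = np.asarray(self.ses, float)
        if len(self.variant_ids) != len(self.betas) or len(self.betas) != len(self.ses):
            raise ConfigError("InstrumentSet field lengths differ")
        if len(set(self.variant_ids)) != len(self.variant_ids):
            raise ConfigError("duplicate variant ids in InstrumentSet")
        if np.any(self.ses <= 0):
            raise ConfigError("non-positive se in InstrumentSet")

    @property
    def k(self) -> int:
        return len(self.variant_ids)

    @property
    def f_stats(self) -> np.ndarray:
        return (self.betas / self.ses) ** 2

    @classmethod
    def from_gwas(cls, table: GwasTable, variant_ids, label: str | None = None) -> "InstrumentSet":
        sub = table.df.set_index("variant_id").loc[list(variant_ids)]
        return cls(
            exposure_label=label or table.trait_label,
            variant_ids=list(variant_ids),
            betas=sub["beta"].to_numpy(float),
            ses=sub["se"].to_numpy(float),
            pvals=sub["pval"].to_numpy(float),
            effect_alleles=list(sub["effect_allele"]),
            other_alleles=list(sub["other_allele"]),
            eafs=sub["eaf"].to_numpy(float),
            chroms=list(sub["chrom"]),
            positions=sub["pos"].to_numpy(np.int64),
        )

    def to_gwas_table(self, trait_type: str = "quantitative") -> GwasTable:
        """Re-materialize as a GwasTable (for harmonizing against outcomes)."""
        if self.effect_alleles is None or self.positions is None:
            raise ConfigError("InstrumentSet lacks allele/position metadata")
        df = pd.DataFrame(
            {
                "variant_id": self.variant_ids,
                "chrom": self.chroms,
                "pos": self.positions,
                "effect_allele": self.effect_alleles,
                "other_allele": self.other_alleles,
                "eaf": self.eafs if self.eafs is not None else np.nan,
                "beta": self.betas,
                "se": self.ses,
                "pval": self.pvals if self.pvals is not None else np.nan,
                "n": np.nan,
            }
        )
        return GwasTable(self.exposure_label, trait_type, df)

    def to_frame(self) -> pd.DataFrame:
        weak = self.f_stats < 10
        return pd.DataFrame(
            {
                "variant_id": self.variant_ids,
                "beta": self.betas,
                "se": self.ses,
                "pval": self.pvals if self.pvals is not None else np.nan,
                "f_stat": self.f_stats,
                "weak": weak,
                "inverted": self.inverted,
            }
        )


def select_target_variants(
    expression: GwasTable,
    biomarker: GwasTable,
    gene_region: tuple,
    cis_window_bp: int = 100_000,
    assoc_p: float = 1e-4,
    expression_p: float = 1e-4,
) -> list[str]:
    """Candidate drug-target variants: cis to the gene, eQTL for it, and
    associated with the weighting biomarker at ``assoc_p``.

    Returns variant ids ordered by biomarker p ascending (position, then id,
    break ties deterministically).
    """
    chrom, start, end = gene_region
    if start > end:
        raise ConfigError(f"gene_region start {start} > end {end}")
    if len(expression) == 0 or len(biomarker) == 0:
        raise SelectionError("empty input table")

    expr = expression.df
    in_region = expr[
        (expr["chrom"].astype(str) == str(chrom))
        & (expr["pos"] >= start - cis_window_bp)
        & (expr["pos"] <= end + cis_window_bp)
    ]
    expr_hits = in_region[in_region["pval"] < expression_p]
    bio = biomarker.df.set_index("variant_id")
    shared = [v for v in expr_hits["variant_id"] if v in bio.index]
    strong = [v for v in shared if bio.loc[v, "pval"] < assoc_p]
    counts = {
        "cis_region": len(in_region),
        "expression_associated": len(expr_hits),
        "in_biomarker": len(shared),
        "biomarker_associated": len(strong),
    }
    if not strong:
        raise SelectionError(f"no variants survived selection: {counts}", counts)
    meta = bio.loc[strong]
    order = sorted(strong, key=lambda v: (meta.loc[v, "pval"], meta.loc[v, "pos"], v))
    return order


def clump(
    variants: pd.DataFrame,
    ld: pd.DataFrame,
    r2_threshold: float,
    window_bp: int,
) -> list[str]:
    """Greedy LD clumping.

    ``variants`` needs columns variant_id, pval, pos (and optionally chrom);
    ``ld`` is a correlation DataFrame covering every candidate.  Variants are
    visited by ascending p (position then id on ties); one is retained iff
    its r^2 with every previously retained variant closer than ``window_bp``
    on the same chromosome is below ``r2_threshold``.
    """
    df = variants.copy()
    for col in ("variant_id", "pval", "pos"):
        if col not in df.columns:
            raise ConfigError(f"clump input missing column {col!r}")
    missing = [v for v in df["variant_id"] if v not in ld.index]
    if missing:
        raise ConfigError(f"variants absent from LD matrix: {missing[:5]}")
    if "chrom" not in df.columns:
        df["chrom"] = "1"

    df = df.sort_values(["pval", "pos", "variant_id"], kind="stable")
    kept: list[str] = []
    for _, row in df.iterrows():
        vid = row["variant_id"]
        ok = True
        for prev in kept:
            prow = df[df["variant_id"] == prev].iloc[0]
            if prow["chrom"] != row["chrom"]:
                continue
            if abs(int(prow["pos"]) - int(row["pos"])) > window_bp:
                continue
            if float(ld.loc[vid, prev]) ** 2 >= r2_threshold:
                ok = False
                break
        if ok:
            kept.append(vid)
    return kept


def invert_effects(instruments: InstrumentSet) -> InstrumentSet:
    """Negate betas so the instrumented exposure represents target inhibition.

    Standard errors and F statistics are unchanged; a second inversion is a
    state error (use a fresh set instead).
    """
    if instruments.inverted:
        raise StateError("instrument set already inverted")
    out = replace(instruments, betas=-instruments.betas, inverted=True)
    out.selection_log = list(instruments.selection_log) + [
        ("invert", vid, "negated", "represent_inhibition") for vid in instruments.variant_ids
    ]
    return out


def f_statistics(betas, ses, weak_threshold: float = 10.0):
    """Per-SNP instrument strength F = (beta/se)^2 and weak-instrument flags."""
    betas = np.asarray(betas, float)
    ses = np.asarray(ses, float)
    if np.any(ses <= 0):
        raise ConfigError("f_statistics: all ses must be > 0")
    f = (betas / ses) ** 2
    return f, f < weak_threshold


def check_residual_ld(instrument_ids, ld: pd.DataFrame, r2_warn: float = 0.1) -> list[tuple]:
    """Warn when retained instruments remain correlated (estimators assume
    independence); returns the offending pairs."""
    pairs = []
    ids = [v for v in instrument_ids if v in ld.index]
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            if float(ld.loc[a, b]) ** 2 > r2_warn:
                pairs.append((a, b, float(ld.loc[a, b]) ** 2))
    if pairs:
        warnings.warn(
            f"{len(pairs)} instrument pair(s) with r^2 > {r2_warn}; "
            "estimates assume independent instruments",
            stacklevel=2,
        )
    return pairs


def build_target_instruments(
    expression: GwasTable,
    biomarker: GwasTable,
    gene_region: tuple,
    ld: pd.DataFrame,
    profile: str = "sglt2",
    cis_window_bp: int = 100_000,
    expression_p: float = 1e-4,
    invert: bool = True,
) -> InstrumentSet:
    """Full drug-target proxy construction: select, clump, extract, invert."""
    if profile not in PROFILES:
        raise ConfigError(f"unknown profile {profile!r}; choose from {sorted(PROFILES)}")
    prof = PROFILES[profile]
    candidates = select_target_variants(
        expression, biomarker, gene_region, cis_window_bp, prof["assoc_p"], expression_p
    )
    bio = biomarker.df.set_index("variant_id")
    cand_df = pd.DataFrame(
        {
            "variant_id": candidates,
            "pval": [bio.loc[v, "pval"] for v in candidates],
            "pos": [bio.loc[v, "pos"] for v in candidates],
            "chrom": [bio.loc[v, "chrom"] for v in candidates],
        }
    )
    kept = clump(cand_df, ld, prof["r2_threshold"], prof["window_bp"])
    check_residual_ld(kept, ld)
    inst = InstrumentSet.from_gwas(biomarker, kept, label=f"{biomarker.trait_label}")
    inst.selection_log = [("select", v, "candidate", "passed_filters") for v in candidates] + [
        ("clump", v, "retained" if v in kept else "pruned", profile) for v in candidates
    ]
    return invert_effects(inst) if invert else inst


def select_metabolite_instruments(
    metabolite: GwasTable,
    ld: pd.DataFrame,
    profile: str = "metabolite_relaxed",
) -> InstrumentSet:
    """Genome-wide instrument selection for a metabolite at a named profile."""
    if profile not in PROFILES:
        raise ConfigError(f"unknown profile {profile!r}")
    prof = PROFILES[profile]
    df = metabolite.df
    hits = df[df["pval"] < prof["assoc_p"]]
    if hits.empty:
        raise SelectionError(
            f"no variants at p < {prof['assoc_p']} for {metabolite.trait_label!r}",
            {"assoc": 0},
        )
    kept = clump(hits[["variant_id", "pval", "pos", "chrom"]], ld, prof["r2_threshold"], prof["window_bp"])
    return InstrumentSet.from_gwas(metabolite, kept)
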