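"""Config-driven end-to-end orchestration.

``run_pipeline`` executes the study design in order — instrument
construction with colocalization, positive-control MR, outcome MR with the
full estimator suite, a mediator (metabolome) screen, two-step/MVMR
mediation, meta-analysis of replicate mediator datasets, and a batch-MR
phenome screen — with fail-fast validation and a machine-readable run
report.  All thresholds and seeds are materialized into the report so the
report alone documents the run; rerunning the same config is bit-identical.

Two input modes: ``simulate`` (a bundled synthetic scenario with known
truth; the default) and ``files`` (delimited summary-statistics tables
named in the config).
"""

from __future__ import annotations

import copy
import json
import os
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import coloc as coloc_mod
from .errors import ConfigError
from .estimators import ivw, run_mr_suite
from .instruments import PROFILES, InstrumentSet, clump, invert_effects, select_target_variants
from .mediation import two_step_mediation
from .meta import meta_dl_random, meta_fixed
from .screen import bonferroni_alpha, phewas_lookup, screen_outcomes
from .simulate import SimulationTruth, ar1_corr, simulate_mediation_gwas, simulate_outcome_panel, simulate_region
from .sumstats import GwasTable, read_sumstats

DEFAULT_CONFIG: dict[str, Any] = {
    "mode": "simulate",
    "seed": 1,
    "alpha": 0.05,
    "profiles": copy.deepcopy(PROFILES),
    "estimators": {"ivw_mode": "multiplicative_random", "n_boot": 1000, "n_sim": 1000},
    "coloc": {
        "p1": 1e-4,
        "p2": 1e-4,
        "p12": 1e-5,
        "prior_sd1": 0.15,
        "prior_sd2": 0.15,
        "h4_threshold": 0.70,
    },
    "simulate": {
        "region": {
            "m_variants": 50,
            "ld_rho": 0.5,
            "n_expression": 31_684,
            "n_biomarker": 344_182,
            "effect_size": 0.08,
            "shared_causal": True,
        },
        "truth": {},  # overrides for SimulationTruth fields
        "k_exposure_snps": 10,
        "k_mediator_snps": 10,
        "instrument_strength": 0.012,
        "positive_control_effect": -1.0,
        "n_screen_outcomes": 20,
        "n_true_outcomes": 1,
        "screen_effect": -0.5,
    },
    "files": {},
}


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ConfigError(f"config {path} must be a mapping")
    return cfg


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, val in override.items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], val)
        else:
            out[key] = copy.deepcopy(val)
    return out


def validate_config(config: dict) -> dict:
    """Materialize defaults and fail fast on structural problems."""
    cfg = _merge(DEFAULT_CONFIG, config or {})
    if cfg["mode"] not in ("simulate", "files"):
        raise ConfigError(f"mode must be 'simulate' or 'files', got {cfg['mode']!r}")
    if not isinstance(cfg["seed"], int):
        raise ConfigError("seed must be an integer (and is mandatory)")
    if cfg["mode"] == "files":
        files = cfg["files"]
        if "exposure" not in files or "outcomes" not in files:
            raise ConfigError("files mode needs 'exposure' and 'outcomes' entries")
        paths = [files["exposure"]["path"]]
        paths += [o["path"] for o in files["outcomes"]]
        for opt in ("mediator", "mediator_replicates", "phewas_table"):
            entry = files.get(opt)
            if entry is None:
                continue
            if isinstance(entry, list):
                paths += [e["path"] for e in entry]
            elif isinstance(entry, dict):
                paths.append(entry["path"])
            else:
                paths.append(entry)
        missing = [p for p in paths if not os.path.exists(p)]
        if missing:
            raise ConfigError(f"missing input file(s): {missing}")
    return cfg


def _estimates_block(estimates) -> list[dict]:
    return [e.as_dict() for e in estimates]


def _mr_stage(cfg, h, outcome_binary, seed):
    est = cfg["estimators"]
    suite = run_mr_suite(
        h,
        outcome_binary=outcome_binary,
        seed=seed,
        ivw_mode=est["ivw_mode"],
        n_boot=est["n_boot"],
        n_sim=est["n_sim"],
    )
    return _estimates_block(suite)


def _simulate_stages(cfg: dict) -> dict:
    seed = cfg["seed"]
    sim = cfg["simulate"]
    stages: dict[str, Any] = {}

    # --- stage 1: instrument construction on a simulated cis region -------
    reg = sim["region"]
    expr, bio, reg_truth = simulate_region(
        reg["m_variants"], reg["ld_rho"], reg["n_expression"], reg["n_biomarker"],
        reg["shared_causal"], reg["effect_size"], seed,
    )
    region_span = (expr.df["chrom"].iloc[0], int(expr.df["pos"].min()), int(expr.df["pos"].max()))
    candidates = select_target_variants(
        expr, bio, region_span,
        cis_window_bp=0,
        assoc_p=cfg["profiles"]["sglt2"]["assoc_p"],
    )
    cl = coloc_mod.coloc_abf(
        expr.df["beta"], expr.df["se"], bio.df["beta"], bio.df["se"], **cfg["coloc"]
    )
    ld = pd.DataFrame(ar1_corr(reg["m_variants"], reg["ld_rho"]),
                      index=expr.variant_ids, columns=expr.variant_ids)
    bio_idx = bio.df.set_index("variant_id")
    cand_df = pd.DataFrame(
        {
            "variant_id": candidates,
            "pval": [bio_idx.loc[v, "pval"] for v in candidates],
            "pos": [bio_idx.loc[v, "pos"] for v in candidates],
            "chrom": [bio_idx.loc[v, "chrom"] for v in candidates],
        }
    )
    prof = cfg["profiles"]["sglt2"]
    kept = clump(cand_df, ld, prof["r2_threshold"], prof["window_bp"])
    region_instruments = invert_effects(InstrumentSet.from_gwas(bio, kept))
    stages["instruments"] = {
        "region_truth": reg_truth,
        "counts": {
            "region_variants": len(expr),
            "biomarker_associated": len(candidates),
            "after_clumping": len(kept),
        },
        "colocalization": cl.as_dict(),
        "profile": prof,
        "instruments": region_instruments.to_frame().to_dict(orient="list"),
    }

    # --- mediation test bed shared by the remaining stages ----------------
    truth = SimulationTruth(seed=seed, **sim["truth"])
    data = simulate_mediation_gwas(
        truth, sim["k_exposure_snps"], sim["k_mediator_snps"],
        instrument_strength=sim["instrument_strength"], seed=seed,
    )
    exp_inst = data.exposure_instruments()

    # --- stage 2: positive-control MR -------------------------------------
    pc_tables, _ = simulate_outcome_panel(
        exp_inst, 1, 1, sim["positive_control_effect"], seed + 1
    )
    pc = pc_tables[0]
    from .sumstats import harmonize_pair

    h_pc = harmonize_pair(exp_inst.to_gwas_table(), pc, exp_inst.variant_ids)
    stages["positive_control"] = {
        "true_effect": sim["positive_control_effect"],
        "estimates": _mr_stage(cfg, h_pc, True, seed),
    }

    # --- stage 3: outcome MR ----------------------------------------------
    h_out = harmonize_pair(exp_inst.to_gwas_table(), data.outcome, exp_inst.variant_ids)
    stages["outcome_mr"] = {
        "truth": truth.as_dict(),
        "k": h_out.k,
        "estimates": _mr_stage(cfg, h_out, True, seed),
    }

    # --- stage 4: mediator screen (metabolome-style) ----------------------
    med_inst = data.mediator_instruments()
    h_med_out = harmonize_pair(med_inst.to_gwas_table(), data.outcome, med_inst.variant_ids)
    med_ivw = ivw(h_med_out, mode=cfg["estimators"]["ivw_mode"], outcome_binary=True)
    n_metabolites = 1400  # correction matches the metabolome-wide family size
    stages["metabolite_screen"] = {
        "n_tests": n_metabolites,
        "adjusted_alpha": bonferroni_alpha(cfg["alpha"], n_metabolites),
        "mediator_on_outcome": med_ivw.as_dict(),
        "significant": med_ivw.pval < bonferroni_alpha(cfg["alpha"], n_metabolites),
    }

    # --- stage 5: mediation ------------------------------------------------
    med_res = two_step_mediation(
        exp_inst, data.mediator, med_inst, data.outcome, seed, exposure_gwas=data.exposure
    )
    stages["mediation"] = {
        "result": med_res.as_dict(),
        "true_proportion": truth.proportion_mediated,
    }

    # --- stage 6: meta-analysis over replicate mediator datasets ----------
    h1 = harmonize_pair(exp_inst.to_gwas_table(), data.mediator, exp_inst.variant_ids)
    h1r = harmonize_pair(exp_inst.to_gwas_table(), data.mediator_replicate, exp_inst.variant_ids)
    e1 = ivw(h1, mode=cfg["estimators"]["ivw_mode"])
    e2 = ivw(h1r, mode=cfg["estimators"]["ivw_mode"])
    pooled_f = meta_fixed([(e1.beta, e1.se), (e2.beta, e2.se)], labels=["mediator", "mediator_replicate"])
    pooled_r = meta_dl_random([(e1.beta, e1.se), (e2.beta, e2.se)])
    stages["meta"] = {"fixed": pooled_f.as_dict(), "dl_random": pooled_r.as_dict()}

    # --- stage 7: phenome-wide batch MR ------------------------------------
    panel, labels = simulate_outcome_panel(
        exp_inst, sim["n_screen_outcomes"], sim["n_true_outcomes"], sim["screen_effect"], seed + 2
    )
    sc = screen_outcomes(exp_inst, panel, alpha=cfg["alpha"], seed=seed, methods=("ivw", "egger"))
    stages["phewas"] = {
        "n_tests": sc.n_tests,
        "adjusted_alpha": sc.adjusted_alpha,
        "n_significant": int(sc.table["significant"].sum()),
        "true_labels": {t.trait_label: l for t, l in zip(panel, labels)},
        "table": sc.table.where(pd.notna(sc.table), None).to_dict(orient="list"),
    }
    return stages


def _read(entry: dict, trait_type_default="quantitative") -> GwasTable:
    return read_sumstats(
        entry["path"],
        entry.get("column_map", {}),
        entry.get("label", os.path.basename(str(entry["path"]))),
        entry.get("trait_type", trait_type_default),
    )


def _files_stages(cfg: dict) -> dict:
    from .sumstats import harmonize_pair

    seed = cfg["seed"]
    files = cfg["files"]
    stages: dict[str, Any] = {}

    exposure = _read(files["exposure"])
    inst_ids = files.get("instrument_ids") or exposure.variant_ids
    inst = InstrumentSet.from_gwas(exposure, inst_ids)
    if files.get("invert_exposure", False):
        inst = invert_effects(inst)
    stages["instruments"] = {"k": inst.k, "instruments": inst.to_frame().to_dict(orient="list")}

    outcome_tables = [_read(o, "binary") for o in files["outcomes"]]
    stages["outcome_mr"] = {}
    for table in outcome_tables:
        h = harmonize_pair(inst.to_gwas_table(), table, inst.variant_ids)
        stages["outcome_mr"][table.trait_label] = {
            "k": h.k,
            "estimates": _mr_stage(cfg, h, table.trait_type == "binary", seed),
        }

    med_entry = files.get("mediator")
    if med_entry:
        mediator = _read(med_entry)
        med_inst_ids = files.get("mediator_instrument_ids") or mediator.variant_ids
        med_inst = InstrumentSet.from_gwas(mediator, med_inst_ids)
        res = two_step_mediation(inst, mediator, med_inst, outcome_tables[0], seed, exposure_gwas=exposure)
        stages["mediation"] = {"result": res.as_dict()}

        reps = files.get("mediator_replicates") or []
        if reps:
            ests = []
            for entry in [med_entry] + list(reps):
                t = _read(entry)
                h = harmonize_pair(inst.to_gwas_table(), t, inst.variant_ids)
                e = ivw(h, mode=cfg["estimators"]["ivw_mode"])
                ests.append((e.beta, e.se))
            stages["meta"] = {"fixed": meta_fixed(ests).as_dict()}

    phe = files.get("phewas_table")
    if phe:
        path = phe["path"] if isinstance(phe, dict) else phe
        tab = pd.read_csv(path, sep=None, engine="python")
        res = phewas_lookup(tab, alpha=cfg["alpha"])
        stages["phewas"] = {
            "n_tests": res.n_tests,
            "adjusted_alpha": res.adjusted_alpha,
            "n_significant": int(res.table["significant"].sum()),
        }
    return stages


def run_pipeline(config: dict | None = None, out_dir: str | None = None) -> dict:
    """Validate, execute every stage in order, and return the run report."""
    cfg = validate_config(config or {})
    stages = _simulate_stages(cfg) if cfg["mode"] == "simulate" else _files_stages(cfg)
    report = {"config": cfg, "seed": cfg["seed"], "stages": stages}
    if out_dir:
        os.makedirs(out_dir, exist_ok=True)
        with open(os.path.join(out_dir, "run_report.json"), "w") as fh:
            fh.write(report_json(report))
    return report


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.bool_):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, float) and (np.isnan(obj) or np.isinf(obj)):
        return None
    return obj


def report_json(report: dict) -> str:
    """Canonical serialization: sorted keys, no timestamps, bit-stable."""
    return json.dumps(_jsonable(report), sort_keys=True, indent=2) + "\n"
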