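"""End-to-end orchestration: simulate/ingest -> similarity -> dataset -> engines -> report.

A single config (YAML/JSON/dict) names the stages to run and their
parameters; each run writes its outputs plus a manifest recording the
config hash, input checksums, seeds, scaling constants and the output
inventory.  Deterministic stages are skipped on re-run when their config
hash is unchanged and their outputs still exist (a cache hit, noted in the
manifest); stochastic stages reproduce exactly from the recorded seeds.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import chemsim, dataset_builder, hazards_aalen, hazards_cox, survival_forest, synthetic_data
from .dataset_builder import FIXED_EFFECT_COLUMNS

__all__ = ["run_pipeline", "risk_report", "load_config"]

log = logging.getLogger("resistsurv")

_KNOWN_STAGES = ("simulate", "chemsim", "build_dataset", "fit_cox", "fit_aalen", "fit_forest", "report")


def load_config(path_or_dict) -> dict:
    if isinstance(path_or_dict, Mapping):
        cfg = dict(path_or_dict)
    else:
        text = Path(path_or_dict).read_text()
        cfg = yaml.safe_load(text)
    unknown = [s for s in cfg.get("stages", []) if s not in _KNOWN_STAGES]
    if unknown:
        raise ValueError(f"unknown stage/engine name(s) in config: {unknown}; known: {list(_KNOWN_STAGES)}")
    if "out_dir" not in cfg:
        raise ValueError("config is missing required field 'out_dir'")
    for f in cfg.get("inputs", {}).values():
        if not Path(f).exists():
            raise FileNotFoundError(f"missing input file: {f}")
    return cfg


def _hash(obj) -> str:
    return hashlib.md5(json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()


def _file_checksum(path: Path) -> str:
    return hashlib.md5(path.read_bytes()).hexdigest()


def risk_report(
    cox_fit: hazards_cox.HazardFit,
    forest_risk: np.ndarray,
    design: pd.DataFrame,
) -> pd.DataFrame:
    """Ranked not-yet-resistant pest x insecticide pairs.

    Restricted to censored records (resistance not yet documented); ranks
    under the Cox linear predictor and the forest mortality are combined by
    their mean (consensus rank), smaller = higher predicted risk.
    """
    design = design.reset_index(drop=True)
    forest_risk = np.asarray(forest_risk, float)
    mask = design["event"].to_numpy() == 0
    sub = design[mask].copy()
    pred = hazards_cox.predict_relative_risk(cox_fit, sub).sort_index()
    sub["cox_rank"] = (-pred["linear_predictor"]).rank(method="first").astype(int)
    sub["forest_rank"] = pd.Series(-forest_risk[mask], index=sub.index).rank(method="first").astype(int)
    sub["consensus_rank"] = (sub["cox_rank"] + sub["forest_rank"]) / 2.0
    cols = [c for c in ("pest_id", "insecticide_id", "moa_class") if c in sub.columns]
    out = sub[cols + ["cox_rank", "forest_rank", "consensus_rank"]]
    return out.sort_values(["consensus_rank", "cox_rank"]).reset_index(drop=True)


def run_pipeline(config) -> dict:
    """Execute the configured stages in dependency order; returns the manifest."""
    cfg = load_config(config)
    out_dir = Path(cfg["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    stages = cfg.get("stages", ["simulate", "fit_cox", "fit_aalen", "fit_forest", "report"])

    manifest_path = out_dir / "manifest.json"
    previous = json.loads(manifest_path.read_text()) if manifest_path.exists() else {}
    manifest: dict = {
        "config_hash": _hash(cfg),
        "seed": seed,
        "inputs": {k: _file_checksum(Path(v)) for k, v in cfg.get("inputs", {}).items()},
        "stages": {},
        "outputs": [],
    }

    def _emit(name: str, df: pd.DataFrame) -> Path:
        p = out_dir / name
        df.to_csv(p, index=False)
        manifest["outputs"].append(name)
        return p

    def _cached(stage: str, stage_cfg) -> bool:
        prev = previous.get("stages", {}).get(stage)
        if not prev or prev.get("hash") != _hash([stage_cfg, seed]):
            return False
        ok = all((out_dir / f).exists() for f in prev.get("outputs", []))
        if ok:
            manifest["stages"][stage] = {**prev, "cache_hit": True}
            manifest["outputs"].extend(prev.get("outputs", []))
            log.info("stage %s: cache hit, skipped", stage)
        return ok

    design = records = None
    cox_fit = None
    forest_fit = None

    if "simulate" in stages:
        scfg = cfg.get("simulate", {})
        if not _cached("simulate", scfg):
            sim_cfg = synthetic_data.SimConfig(**scfg)
            records, design, truth = synthetic_data.simulate_interactions(sim_cfg, seed)
            outs = []
            outs.append(_emit("records.csv", records).name)
            outs.append(_emit("design.csv", design).name)
            truth_df = pd.DataFrame({"linear_predictor": truth.linear_predictor})
            outs.append(_emit("truth.csv", truth_df).name)
            manifest["stages"]["simulate"] = {
                "hash": _hash([scfg, seed]),
                "outputs": outs,
                "scaling_constants": truth.constants.as_dict(),
            }
        else:
            records = pd.read_csv(out_dir / "records.csv")
            design = pd.read_csv(out_dir / "design.csv")

    if "chemsim" in stages:
        ccfg = cfg.get("chemsim", {})
        if not _cached("chemsim", ccfg):
            compounds = pd.read_csv(cfg["inputs"]["compounds"])
            diet = pd.read_csv(cfg["inputs"]["diet"])
            fp_cfg = chemsim.FingerprintConfig(
                n_bits=int(ccfg.get("fp_bits", 1024)), max_path=int(ccfg.get("fp_depth", 7))
            )
            sim_table, exclusions = chemsim.build_similarity_table(compounds, diet, fp_cfg)
            outs = [_emit("similarity.csv", sim_table).name, _emit("chem_exclusions.csv", exclusions).name]
            manifest["stages"]["chemsim"] = {"hash": _hash([ccfg, seed]), "outputs": outs}

    if "build_dataset" in stages:
        bcfg = cfg.get("build_dataset", {})
        if not _cached("build_dataset", bcfg):
            hosts = pd.read_csv(cfg["inputs"]["hosts"])
            regs = pd.read_csv(cfg["inputs"]["registrations"])
            reports = pd.read_csv(cfg["inputs"]["resistance"])
            ledgers = {}
            for iid, grp in regs.groupby("insecticide_id"):
                generic = grp.loc[grp["crop_genus"].isna(), "year"]
                crop = grp.dropna(subset=["crop_genus"])
                ledgers[iid] = dataset_builder.RegistrationLedger(
                    iid,
                    int(generic.min()) if len(generic) else None,
                    dict(zip(crop["crop_genus"], crop["year"].astype(int))),
                )
            recs, excl = dataset_builder.assemble_records(
                hosts, ledgers, reports,
                mode=bcfg.get("mode", "all_in"),
                censor_year=int(bcfg.get("censor_year", dataset_builder.CENSOR_YEAR)),
            )
            outs = [_emit("records.csv", recs).name, _emit("record_exclusions.csv", excl).name]
            manifest["stages"]["build_dataset"] = {
                "hash": _hash([bcfg, seed]),
                "outputs": outs,
                "summary": dataset_builder.dataset_summary(recs, excl),
            }
            records = recs

    if design is None and (out_dir / "design.csv").exists():
        design = pd.read_csv(out_dir / "design.csv")
    if design is None and any(s in stages for s in ("fit_cox", "fit_aalen", "fit_forest", "report")):
        raise FileNotFoundError("no design available: run 'simulate' or provide design.csv")

    if "fit_cox" in stages:
        kcfg = cfg.get("cox", {})
        spec = hazards_cox.CoxSpec(
            random_effects=tuple(kcfg.get("random_effects", ("moa_class", "family", "pest_id"))),
            ties=kcfg.get("ties", "efron"),
        )
        cox_fit = hazards_cox.fit_cox(design, spec)
        _emit("cox_coefficients.csv", hazards_cox.forest_table(cox_fit))
        _emit(
            "cox_variances.csv",
            pd.DataFrame(
                [{"term": k, "variance": v} for k, v in cox_fit.variances.items()],
                columns=["term", "variance"],
            ),
        )
        manifest["stages"]["fit_cox"] = {
            "hash": _hash([kcfg, seed]),
            "outputs": ["cox_coefficients.csv", "cox_variances.csv"],
            "loglik": cox_fit.loglik,
            "aic": cox_fit.aic,
            "converged": cox_fit.converged,
        }

    if "fit_aalen" in stages:
        acfg = cfg.get("aalen", {})
        afit = hazards_aalen.fit_aalen(
            design,
            covariates=list(acfg.get("covariates", FIXED_EFFECT_COLUMNS)),
            liability_group=acfg.get("liability", "moa_class"),
        )
        _emit("aalen_curves.csv", hazards_aalen.curve_table(afit))
        _emit("aalen_tests.csv", hazards_aalen.aalen_tests(afit))
        manifest["stages"]["fit_aalen"] = {
            "hash": _hash([acfg, seed]),
            "outputs": ["aalen_curves.csv", "aalen_tests.csv"],
            "n_skipped": afit.n_skipped,
            "truncated_at": afit.truncated_at,
        }

    if "fit_forest" in stages:
        fcfg = cfg.get("forest", {})
        fspec = survival_forest.ForestSpec(
            n_trees=int(fcfg.get("n_trees", 500)),
            mtry=fcfg.get("mtry"),
            min_node_size=int(fcfg.get("min_node_size", 15)),
            seed=int(fcfg.get("seed", seed)),
        )
        forest_fit = survival_forest.fit_forest(
            design, fspec, predictors=FIXED_EFFECT_COLUMNS + ["moa_class", "family"]
        )
        imp = survival_forest.permutation_importance(forest_fit, seed=seed)
        _emit("forest_importance.csv", imp)
        _emit(
            "forest_risk.csv",
            pd.DataFrame({"risk": forest_fit.risk}),
        )
        (out_dir / "forest_oob.json").write_text(
            json.dumps({"oob_error": forest_fit.oob_error, "n_trees": fspec.n_trees, "seed": fspec.seed})
        )
        manifest["outputs"].append("forest_oob.json")
        manifest["stages"]["fit_forest"] = {
            "hash": _hash([fcfg, seed]),
            "outputs": ["forest_importance.csv", "forest_risk.csv", "forest_oob.json"],
            "oob_error": forest_fit.oob_error,
        }

    if "report" in stages:
        if cox_fit is None or forest_fit is None:
            raise ValueError("report stage needs fit_cox and fit_forest in the same run")
        rep = risk_report(cox_fit, forest_fit.risk, design)
        _emit("risk_report.csv", rep)
        manifest["stages"]["report"] = {
            "hash": _hash([None, seed]),
            "outputs": ["risk_report.csv"],
            "n_rows": len(rep),
        }

    manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
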