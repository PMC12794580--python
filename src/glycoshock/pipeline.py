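"""End-to-end orchestration: simulate -> scan -> quantify -> stats -> classify.

A run is described by a :class:`RunConfig` (loadable from YAML/JSON), executes
its enabled stages in dependency order, writes plain TSV/CSV/JSON outputs into
one directory, and finishes with a reproducibility manifest recording the
config hash, seed, package version and a content hash of every output file.
Reruns with an identical config and seed reproduce all numeric outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, Optional

import pandas as pd
import yaml

from . import __version__
from .classify import ModelSpec, evaluate_survivorship
from .errors import GlycoshockError, SpecValidationError
from .glycans import feature_table
from .psm import lewis_level, protein_lewis_distribution, protein_lewis_level
from .spectra import DiagnosticIonConfig, diagnostic_fraction, read_mgf
from .stats import mann_whitney_u, roc_auc
from .synthetic import (
    CohortSpec,
    EffectSpec,
    GlycoPSMSetSpec,
    SpectrumSetSpec,
    default_catalog,
    generate_cohort,
    generate_glycome_profiles,
    generate_glycopsm_table,
    generate_spectra,
)

__all__ = ["RunConfig", "PipelineStageError", "run_pipeline"]

log = logging.getLogger("glycoshock.pipeline")
if not log.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("[%(name)s] %(levelname)s %(message)s"))
    log.addHandler(_h)
    log.setLevel(logging.INFO)


class PipelineStageError(GlycoshockError):
    """A stage failed; carries the stage name and underlying cause."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage '{stage}' failed: {cause}")


_DEFAULT_STAGES = {"simulate": True, "scan": True, "quantify": True,
                   "stats": True, "classify": True}


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run."""

    out_dir: str = "glycoshock_run"
    seed: Optional[int] = None
    stages: Dict[str, bool] = field(default_factory=lambda: dict(_DEFAULT_STAGES))
    cohort: Dict = field(default_factory=dict)
    effect: Dict = field(default_factory=dict)
    spectra: Dict = field(default_factory=dict)
    psm: Dict = field(default_factory=dict)
    scan: Dict = field(default_factory=dict)
    model: Dict = field(default_factory=dict)
    stats: Dict = field(default_factory=dict)
    inputs: Dict = field(default_factory=dict)

    def __post_init__(self):
        unknown = set(self.stages) - set(_DEFAULT_STAGES)
        if unknown:
            raise SpecValidationError("stages", f"unknown stage(s) {sorted(unknown)}")
        stages = dict(_DEFAULT_STAGES)
        stages.update(self.stages)
        self.stages = stages
        stochastic = self.stages.get("simulate") or self.stages.get("classify")
        if stochastic and self.seed is None:
            raise SpecValidationError(
                "seed", "a seed is required when a stochastic stage is enabled"
            )
        if not self.stages.get("simulate"):
            for key in ("cohort", "profiles"):
                p = self.inputs.get(key)
                if not p or not Path(p).exists():
                    raise SpecValidationError(
                        "inputs", f"'{key}' path required (and existing) without simulate"
                    )

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise SpecValidationError("config", "top level must be a mapping")
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise SpecValidationError("config", f"unknown key(s) {sorted(unknown)}")
        return cls(**data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _tuplify(d: Dict) -> Dict:
    return {k: tuple(v) if isinstance(v, list) else v for k, v in d.items()}


def run_pipeline(config: RunConfig) -> Dict[str, object]:
    """Execute the enabled stages; return output paths and headline metrics."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: Dict[str, object] = {"out_dir": str(out)}
    outputs: Dict[str, Path] = {}
    catalog = default_catalog()

    cohort = profiles = psm_table = None
    mgf_path = None

    if config.stages["simulate"]:
        stage = "simulate"
        log.info("stage %s: generating cohort, profiles, spectra, glycoPSMs", stage)
        try:
            cspec = CohortSpec(seed=config.seed, **_tuplify(config.cohort))
            cohort = generate_cohort(cspec)
            espec = EffectSpec(**config.effect)
            profiles, _ = generate_glycome_profiles(
                cohort, catalog, espec, seed=config.seed + 1
            )
            sspec = SpectrumSetSpec(seed=config.seed + 2, **_tuplify(config.spectra))
            mgf_path = out / "spectra.mgf"
            generate_spectra(sspec, mgf_path)
            pspec = GlycoPSMSetSpec(seed=config.seed + 3, **config.psm)
            psm_table, _ = generate_glycopsm_table(cohort, pspec, out / "glycopsms.tsv")
            cohort.to_csv(out / "cohort.csv", index=False)
            profiles.to_csv(out / "profiles.csv", float_format="%.6f")
            catalog.to_csv(out / "catalog.csv")
            outputs.update(
                cohort=out / "cohort.csv", profiles=out / "profiles.csv",
                catalog=out / "catalog.csv", glycopsms=out / "glycopsms.tsv",
                spectra=mgf_path,
            )
        except Exception as e:  # noqa: BLE001 - rewrapped with stage context
            raise PipelineStageError(stage, e) from e
    else:
        stage = "load"
        log.info("stage %s: reading provided inputs", stage)
        try:
            cohort = pd.read_csv(config.inputs["cohort"])
            profiles = pd.read_csv(config.inputs["profiles"], index_col="sample_id")
            profiles.columns = [str(c) for c in profiles.columns]
            if config.inputs.get("psms"):
                from .psm import read_glycopsm_table

                psm_table = read_glycopsm_table(
                    config.inputs["psms"], config.inputs.get("psm_dialect", "canonical")
                )
            if config.inputs.get("mgf"):
                mgf_path = Path(config.inputs["mgf"])
            if config.inputs.get("catalog"):
                from .glycans import Catalog

                catalog = Catalog.from_csv(config.inputs["catalog"])
        except Exception as e:  # noqa: BLE001
            raise PipelineStageError(stage, e) from e

    features = feature_table(profiles, catalog)
    features.to_csv(out / "features.tsv", sep="\t", float_format="%.6f")
    outputs["features"] = out / "features.tsv"

    if config.stages["scan"] and mgf_path is not None:
        stage = "scan"
        log.info("stage %s: diagnostic-ion scanning of %s", stage, mgf_path)
        try:
            records = read_mgf(mgf_path)
            scan_cfg = _scan_config(config.scan)
            frac = diagnostic_fraction(records, scan_cfg)
            report = pd.DataFrame(
                [
                    {
                        "target": t,
                        "n_spectra": len(records),
                        "n_hits": round(f * len(records)),
                        "fraction": f,
                    }
                    for t, f in frac.items()
                ]
            )
            report.to_csv(out / "scan_report.tsv", sep="\t", index=False)
            outputs["scan_report"] = out / "scan_report.tsv"
            results["diagnostic_fractions"] = frac
        except Exception as e:  # noqa: BLE001
            raise PipelineStageError(stage, e) from e

    if config.stages["quantify"] and psm_table is not None:
        stage = "quantify"
        log.info("stage %s: Lewis glycoform spectral counting", stage)
        try:
            levels = lewis_level(psm_table).rename("lewis_level").to_frame()
            levels["AGP1_lewis_level"] = protein_lewis_level(psm_table, "AGP1")
            levels.to_csv(out / "lex_levels.tsv", sep="\t", float_format="%.6f")
            shares = protein_lewis_distribution(psm_table)
            shares.to_csv(out / "lex_protein_shares.tsv", sep="\t", float_format="%.6f")
            outputs["lex_levels"] = out / "lex_levels.tsv"
            outputs["lex_protein_shares"] = out / "lex_protein_shares.tsv"
            results["agp1_lewis_share"] = float(shares.get("AGP1", 0.0))
        except Exception as e:  # noqa: BLE001
            raise PipelineStageError(stage, e) from e

    if config.stages["stats"]:
        stage = "stats"
        log.info("stage %s: day-1 group statistics", stage)
        try:
            results["stats"] = _day_statistics(
                config, cohort, profiles, features, out, outputs
            )
        except Exception as e:  # noqa: BLE001
            raise PipelineStageError(stage, e) from e

    if config.stages["classify"]:
        stage = "classify"
        log.info("stage %s: survivorship random forest", stage)
        try:
            mspec = ModelSpec(seed=config.seed + 4, **config.model)
            ev = evaluate_survivorship(profiles, cohort, mspec)
            ev["predictions"].to_csv(out / "predictions.tsv", sep="\t")
            cc, metrics = ev["confusion"], ev["metrics"]
            metrics_payload = {
                "tp": cc.tp, "tn": cc.tn, "fp": cc.fp, "fn": cc.fn,
                **metrics.as_dict(),
                "top_features": ev["importances"][:5],
            }
            (out / "metrics.json").write_text(json.dumps(metrics_payload, indent=2))
            outputs["predictions"] = out / "predictions.tsv"
            outputs["metrics"] = out / "metrics.json"
            results["classifier"] = metrics_payload
        except Exception as e:  # noqa: BLE001
            raise PipelineStageError(stage, e) from e

    config_dict = asdict(config)
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": config_dict,
        "config_sha256": hashlib.sha256(
            json.dumps(config_dict, sort_keys=True).encode()
        ).hexdigest(),
        "outputs": {name: {"path": str(p), "sha256": _sha256(p)}
                    for name, p in outputs.items()},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    results["manifest"] = manifest
    log.info("run complete: %d output files in %s", len(outputs), out)
    return results


def _scan_config(scan: Dict) -> DiagnosticIonConfig:
    mode = scan.get("mode", "manual")
    if mode == "glycounter":
        cfg = DiagnosticIonConfig.glycounter_hcd()
    else:
        cfg = DiagnosticIonConfig.manual_hcd()
    overrides = {k: v for k, v in scan.items() if k != "mode"}
    if overrides:
        base = asdict(cfg)
        base.update(_tuplify(overrides))
        cfg = DiagnosticIonConfig(**base)
    return cfg


def _day_statistics(config, cohort, profiles, features, out: Path, outputs) -> Dict:
    opts = dict(config.stats)
    feature = opts.get("feature", "pct_lewis_fuc")
    day = int(opts.get("day", 1))
    tail = opts.get("tail", "one")
    glycans = opts.get("glycans", ["22a", "23a"])
    day_rows = cohort[cohort["icu_day"] == day]
    values = (features if feature in features.columns else profiles)[feature]
    day_values = values.loc[day_rows["sample_id"]]
    is_pos = (day_rows["outcome"] == "nonsurvivor").to_numpy()
    x = day_values.to_numpy()[is_pos]      # nonsurvivors
    y = day_values.to_numpy()[~is_pos]     # survivors
    alternative = "greater" if tail == "one" else "two_sided"
    rows = []
    res = mann_whitney_u(x, y, alternative=alternative)
    roc = roc_auc(day_values.to_numpy(), is_pos.astype(int))
    rows.append({"quantity": feature, "day": day, "U": res.statistic,
                 "p_value": res.p_value, "alternative": alternative, "auc": roc.auc})
    for gid in glycans:
        if gid not in profiles.columns:
            continue
        gv = profiles[gid].loc[day_rows["sample_id"]].to_numpy()
        gres = mann_whitney_u(gv[is_pos], gv[~is_pos], alternative=alternative)
        groc = roc_auc(gv, is_pos.astype(int))
        rows.append({"quantity": f"glycan_{gid}", "day": day, "U": gres.statistic,
                     "p_value": gres.p_value, "alternative": alternative,
                     "auc": groc.auc})
    table = pd.DataFrame(rows)
    table.to_csv(out / "stats.tsv", sep="\t", index=False, float_format="%.6g")
    outputs["stats"] = out / "stats.tsv"
    return {r["quantity"]: {"p_value": r["p_value"], "auc": r["auc"]} for r in rows}
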