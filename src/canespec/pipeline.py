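"""End-to-end orchestration: simulate (or load) grid samples, compute
indices, run GRA selection, fit CNC regressions, classify irrigation
levels, and write a reproducible run report.

Every artifact in the report carries the configuration hash and the
global seed, and a rerun with the identical configuration reproduces
identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import classification, features, regression, selection, synthetic

log = logging.getLogger("canespec.pipeline")

#: CNC feature sets mirroring the modeling experiment grid: bands
#: alone, selected pigment indices singly/combined, bands + indices.
DEFAULT_CNC_FEATURE_SETS = {
    "FR": ["FR"],
    "SRPI_NPCI_NGBDI": ["SRPI", "NPCI", "NGBDI"],
    "FR_SRPI_NPCI_NGBDI": ["FR", "SRPI", "NPCI", "NGBDI"],
}


@dataclass(frozen=True)
class PipelineConfig:
    seed: int = 0
    design: synthetic.TreatmentDesign = field(default_factory=synthetic.TreatmentDesign.default)
    generator: synthetic.GeneratorConfig | None = None  # seeded from `seed` if None
    gra: selection.GraConfig = field(default_factory=selection.GraConfig)
    rules: selection.SelectionRules = field(default_factory=selection.SelectionRules.strict)
    cnc_feature_sets: dict = field(default_factory=lambda: dict(DEFAULT_CNC_FEATURE_SETS))
    split: regression.SplitSpec | None = None
    kfold: int = 3
    classifier_features: tuple = classification.DEFAULT_FEATURES
    run_cnc: bool = True
    run_classification: bool = True
    input_table: str | None = None  # CSV path; skips simulation when set

    def resolved_generator(self) -> synthetic.GeneratorConfig:
        return self.generator or synthetic.GeneratorConfig(seed=self.seed)

    def resolved_split(self) -> regression.SplitSpec:
        return self.split or regression.SplitSpec(seed=self.seed)

    def content_hash(self) -> str:
        blob = repr(self).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def run_pipeline(config: PipelineConfig, out_dir: str | Path | None = None) -> dict:
    """Execute all enabled stages in dependency order.

    Returns the run report: samples table, GRA ranking, selected
    features, CNC fit reports, pooled confusion matrices, and
    provenance (config hash, seed, stage timings).  When `out_dir` is
    given, CSV/JSON artifacts are written there.
    """
    t0 = time.time()
    provenance = {"config_hash": config.content_hash(), "seed": config.seed, "stages": {}}

    def _stage(name):
        log.info("stage %s start", name)
        return time.time()

    def _done(name, t):
        provenance["stages"][name] = round(time.time() - t, 3)
        log.info("stage %s done in %.2fs", name, provenance["stages"][name])

    t = _stage("simulate" if config.input_table is None else "load")
    if config.input_table is None:
        samples = synthetic.generate_dataset(config.design, config.resolved_generator())
        table = synthetic.samples_to_frame(samples)
    else:
        table = pd.read_csv(config.input_table)
    _done("simulate", t)

    t = _stage("features")
    table = features.build_feature_table(table)
    _done("features", t)

    t = _stage("select")
    feat_cols = features.feature_columns(table)
    gra, corr, selected = selection.rank_and_select(
        table, feat_cols, "cnc", config.gra, config.rules
    )
    _done("select", t)

    report: dict = {
        "provenance": provenance,
        "table": table,
        "gra": gra,
        "correlation": corr,
        "selected_features": selected,
    }

    if config.run_cnc:
        t = _stage("fit-cnc")
        specs = [
            regression.RegressorSpec.pls(seed=config.seed),
            regression.RegressorSpec.bpnn(seed=config.seed),
            regression.RegressorSpec.elm(seed=config.seed),
        ]
        report["cnc_reports"] = regression.run_cnc_experiment(
            table, config.cnc_feature_sets, specs, config.resolved_split()
        )
        _done("fit-cnc", t)

    if config.run_classification:
        t = _stage("classify-irrigation")
        report["irrigation_correlations"] = classification.irrigation_feature_correlations(table)
        report["confusion"] = {
            spec.algorithm: classification.cross_validated_confusion(
                spec, table, list(config.classifier_features), k=config.kfold, seed=config.seed
            )
            for spec in (
                classification.ClassifierSpec.svm(seed=config.seed),
                classification.ClassifierSpec.bpnn(seed=config.seed),
            )
        }
        _done("classify-irrigation", t)

    provenance["elapsed"] = round(time.time() - t0, 3)
    if out_dir is not None:
        _write_report(report, Path(out_dir))
    return report


def _write_report(report: dict, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    report["table"].to_csv(out / "feature_table.csv", index=False)
    report["correlation"].to_csv(out / "feature_correlations.csv")
    gra = report["gra"]
    pd.DataFrame({"GRD": gra.grd, "rank": gra.rank}).to_csv(out / "gra.csv")
    summary = {
        "provenance": report["provenance"],
        "selected_features": report["selected_features"],
    }
    if "cnc_reports" in report:
        regression.reports_to_frame(report["cnc_reports"]).to_csv(
            out / "cnc_reports.csv", index=False
        )
        summary["cnc_reports"] = [r.__dict__ for r in report["cnc_reports"]]
    if "confusion" in report:
        summary["confusion"] = {k: cm.metrics() for k, cm in report["confusion"].items()}
        for k, cm in report["confusion"].items():
            pd.DataFrame(cm.counts, index=cm.labels, columns=cm.labels).to_csv(
                out / f"confusion_{k.lower()}.csv"
            )
    if "irrigation_correlations" in report:
        report["irrigation_correlations"].to_csv(out / "irrigation_correlations.csv")
    (out / "run_report.json").write_text(json.dumps(summary, indent=2, default=str))


def load_config(path: str | Path) -> PipelineConfig:
    """Build a PipelineConfig from a YAML file (flat keys; nested
    generator/rules/gra blocks optional)."""
    d = yaml.safe_load(Path(path).read_text()) or {}
    kwargs: dict = {}
    if "seed" in d:
        kwargs["seed"] = int(d["seed"])
    if "generator" in d:
        kwargs["generator"] = synthetic.GeneratorConfig(**d["generator"])
    if "gra" in d:
        kwargs["gra"] = selection.GraConfig(**d["gra"])
    if "rules" in d:
        r = d["rules"]
        kwargs["rules"] = (
            selection.PRESETS[r]() if isinstance(r, str) else selection.SelectionRules(**r)
        )
    if "split" in d:
        kwargs["split"] = regression.SplitSpec(**d["split"])
    for key in ("kfold", "run_cnc", "run_classification", "input_table", "cnc_feature_sets"):
        if key in d:
            kwargs[key] = d[key]
    if "classifier_features" in d:
        kwargs["classifier_features"] = tuple(d["classifier_features"])
    return PipelineConfig(**kwargs)
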