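"""End-to-end orchestration: configuration, artifact management, ablations.

``run_pipeline`` executes split -> exploration -> feature selection -> rule
extraction -> rule selection -> signature search -> (optional) validation
evaluation, and writes every artifact (JSON/CSV/GraphML/DOT, figures when
plotting is enabled) plus a manifest that records the config, seeds and
package versions needed to reproduce any artifact.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__, explore
from . import rules as R
from .classifiers import FAST_ROSTER, FULL_ROSTER, ClassifierRoster
from .crossval import CVSpec
from .model import BlastocystSignatureModel, MiningParams, SignatureResults
from .schema import CohortTable, load_cohort, stratified_split, zscore
from .signature import EvaluationReport
from .simulate import (
    SimulationConfig,
    default_planted_rules,
    diagnostics_report,
    generate_cohort,
    write_ground_truth,
)

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """Everything one pipeline run needs.

    Exactly one of ``train_path`` / ``simulation`` must be given.  The
    ``fast`` profile (reduced CV repeats, light roster) keeps desk-scale
    runtimes; the ``full`` profile uses 10-fold x 100 CV and all seven
    classifiers.
    """

    train_path: str | None = None
    validation_path: str | None = None
    simulation: SimulationConfig | None = None
    train_frac: float = 0.7
    profile: str = "fast"  # "fast" | "full"
    roster_members: tuple[str, ...] | None = None
    n_folds: int = 10
    n_repeats: int | None = None  # profile default when None
    mining: MiningParams = field(default_factory=MiningParams)
    feature_min_k: int = 3
    signature_max_k: int | None = 25
    mode: str = "selected_features"
    output_dir: str = "artifacts"
    plotting: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.train_path is None) == (self.simulation is None):
            raise ConfigError("exactly one of train_path / simulation is required")
        if self.profile not in ("fast", "full"):
            raise ConfigError("profile must be 'fast' or 'full'")
        if not 0 < self.train_frac < 1:
            raise ConfigError("train_frac must be in (0, 1)")
        for name, lo, hi in (
            ("min_support_frac", 0.0, 1.0),
            ("mcc_min", -1.0, 1.0),
            ("redundancy_threshold", 0.0, 1.0),
            ("edge_threshold", 0.0, 1.0),
        ):
            v = getattr(self.mining, name)
            if not lo <= v <= hi:
                raise ConfigError(f"mining.{name} = {v} outside [{lo}, {hi}]")

    # ------------------------------------------------------- components

    def cv_spec(self) -> CVSpec:
        repeats = self.n_repeats
        if repeats is None:
            repeats = 100 if self.profile == "full" else 10
        return CVSpec(n_folds=self.n_folds, n_repeats=repeats, seed=self.seed)

    def roster(self) -> ClassifierRoster:
        members = self.roster_members
        if members is None:
            members = FULL_ROSTER if self.profile == "full" else FAST_ROSTER
        return ClassifierRoster(tuple(members), seed=self.seed)

    def to_dict(self) -> dict:
        d = asdict(self)
        if self.simulation is not None:
            sim = asdict(self.simulation)
            sim["planted_rules"] = [
                {"rule": r.to_dict(), "weight": w}
                for r, w in self.simulation.planted_rules
            ]
            d["simulation"] = sim
        return d

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        """Load from YAML or JSON."""
        text = Path(path).read_text()
        raw = yaml.safe_load(text)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        if raw.get("simulation") is not None:
            sim = dict(raw["simulation"])
            planted = sim.pop("planted_rules", None)
            if planted == "default":
                sim["planted_rules"] = default_planted_rules()
            elif planted:
                sim["planted_rules"] = tuple(
                    (R.Rule.from_dict(p["rule"]), float(p["weight"])) for p in planted
                )
            raw["simulation"] = SimulationConfig(**sim)
        if raw.get("mining") is not None:
            raw["mining"] = MiningParams(**raw["mining"])
        if raw.get("roster_members") is not None:
            raw["roster_members"] = tuple(raw["roster_members"])
        return cls(**raw)


def _json_dump(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)
        fh.write("\n")


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the full pipeline; returns the artifact directory.

    Artifacts: cohort CSVs, correlation matrix, feature tests, feature
    selection result, rules, rule graph (GraphML + DOT), signature.json,
    AUC curves, evaluation report, run manifest.
    """
    t0 = time.time()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}

    def tick(stage: str, start: float) -> None:
        timings[stage] = round(time.time() - start, 3)

    # ---- data -------------------------------------------------------
    t = time.time()
    truth = None
    if config.simulation is not None:
        cohort, truth = generate_cohort(config.simulation)
        cohort.to_csv(out / "cohort.csv")
        write_ground_truth(truth, out / "ground_truth.json")
        _json_dump(diagnostics_report(cohort, truth), out / "simulation_diagnostics.json")
        train, validation = stratified_split(cohort, config.train_frac, config.seed)
    else:
        cohort = load_cohort(config.train_path)
        if config.validation_path:
            train = cohort
            validation = load_cohort(config.validation_path)
        else:
            train, validation = stratified_split(cohort, config.train_frac, config.seed)
    train.to_csv(out / "train.csv")
    validation.to_csv(out / "validation.csv")
    tick("data", t)

    # ---- exploration ------------------------------------------------
    t = time.time()
    ztrain = zscore(train)
    corr = explore.pearson_matrix(ztrain)
    corr.to_csv(out / "correlation_matrix.csv")
    tests = explore.kruskal_tests(train)
    explore.tests_to_frame(tests).to_csv(out / "feature_tests.csv", index=False)
    explore.group_quantiles(train).to_csv(out / "group_quantiles.csv", index=False)
    if config.plotting:
        scores, _ = explore.pca_embed(ztrain)
        explore.plot_pca(scores, train.labels, out / "pca.svg")
        explore.plot_correlation_heatmap(corr, out / "correlation_heatmap.svg")
    tick("explore", t)

    # ---- modelling --------------------------------------------------
    t = time.time()
    model = BlastocystSignatureModel(
        train,
        validation,
        roster=config.roster(),
        cv_spec=config.cv_spec(),
        mining=config.mining,
        feature_min_k=config.feature_min_k,
        signature_max_k=config.signature_max_k,
        seed=config.seed,
    )
    results = model.fit(mode=config.mode)
    tick("model", t)

    # ---- artifacts --------------------------------------------------
    t = time.time()
    if results.feature_selection is not None:
        _json_dump(results.feature_selection.to_dict(), out / "feature_selection.json")
        results.feature_selection.curve.to_csv(
            out / "feature_auc_curve.csv", index=False
        )
    _json_dump(R.rules_to_json(results.candidate_rules), out / "rules_candidates.json")
    _json_dump(R.rules_to_json(results.selected_rules), out / "rules_selected.json")
    R.write_graphml(results.rule_graph, out / "rule_graph.graphml")
    R.write_dot(results.rule_graph, out / "rule_graph.dot")
    _json_dump(results.signature.to_dict(), out / "signature.json")
    results.cv_report.curve.to_csv(out / "auc_curve.csv", index=False)
    evaluation = {"cv": results.cv_report.to_dict()}
    if results.validation_report is not None:
        evaluation["validation"] = results.validation_report.to_dict()
        results.validation_report.per_classifier.to_csv(
            out / "validation_report.csv", index=False
        )
    _json_dump(evaluation, out / "evaluation.json")
    (out / "summary.txt").write_text(results.summary() + "\n")
    tick("artifacts", t)

    manifest = {
        "package_version": __version__,
        "config": config.to_dict(),
        "seed": config.seed,
        "n_train": len(train),
        "n_validation": len(validation),
        "timings_s": timings,
        "total_s": round(time.time() - t0, 3),
    }
    _json_dump(manifest, out / "manifest.json")
    logger.info("pipeline done in %.1fs -> %s", time.time() - t0, out)
    return out


def ablation_run(
    train: CohortTable,
    validation: CohortTable,
    mode: str,
    roster: ClassifierRoster | None = None,
    cv_spec: CVSpec | None = None,
    mining: MiningParams | None = None,
    seed: int = 0,
) -> tuple[SignatureResults, EvaluationReport | None]:
    """Run extraction -> selection -> search -> evaluation under a feature
    pool ablation: ``all_variables`` skips feature selection, ``embryo_only``
    restricts to the 14 embryo-related variables, ``selected_features`` is
    the main pipeline."""
    model = BlastocystSignatureModel(
        train, validation, roster=roster, cv_spec=cv_spec, mining=mining, seed=seed
    )
    results = model.fit(mode=mode)
    return results, results.validation_report
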