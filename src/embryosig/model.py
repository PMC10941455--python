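"""Model/results interface to the four-stage rule-signature pipeline.

:class:`BlastocystSignatureModel` is constructed from a training cohort
(and optionally an independent validation cohort); ``fit()`` runs feature
selection, rule extraction, rule selection and the signature search, and
returns a :class:`SignatureResults` carrying the selected feature set, the
candidate and surviving rules, the rule-correlation graph, the frozen
signature with its cross-validated AUC curve, the held-out evaluation, and
a ``summary()`` table.

The estimand is interpretable by design: a short ordered list of
feature-threshold rules whose binary firing indicators, fed to a standard
classifier, discriminate embryos that reach the expanded blastocyst stage
on day 5 from those that do not.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import rules as R
from .classifiers import ClassifierRoster
from .crossval import CVSpec
from .feature_selection import FeatureSelectionResult, select_feature_set
from .schema import CohortTable, derive_features
from .signature import (
    EvaluationReport,
    Signature,
    evaluate_on_cohort,
    search_signature,
)

logger = logging.getLogger(__name__)

MODES = ("selected_features", "all_variables", "embryo_only")


@dataclass
class MiningParams:
    """Rule extraction and selection thresholds."""

    n_trees: int = 50
    max_depth: int = 3
    min_support_frac: float = 0.05
    mcc_min: float = 0.0
    redundancy_threshold: float = 0.8
    edge_threshold: float = 0.8
    positive_only: bool = False


class BlastocystSignatureModel:
    """Rule-signature model of timely blastocyst development.

    Parameters
    ----------
    train:
        Labelled training cohort (canonical 30-feature schema).
    validation:
        Optional independent cohort for frozen-signature evaluation.
    roster:
        Classifier roster searched over at every evaluation step; reported
        AUC/accuracy are maxima over the roster.
    cv_spec:
        Repeated stratified CV specification (default 10-fold x 100).
    mining:
        Rule extraction/selection thresholds.
    seed:
        Master seed for every stochastic component.
    """

    def __init__(
        self,
        train: CohortTable,
        validation: CohortTable | None = None,
        roster: ClassifierRoster | None = None,
        cv_spec: CVSpec | None = None,
        mining: MiningParams | None = None,
        feature_min_k: int = 3,
        signature_max_k: int | None = 25,
        seed: int = 0,
    ):
        self.train = derive_features(train)
        self.validation = derive_features(validation) if validation is not None else None
        self.roster = roster or ClassifierRoster(seed=seed)
        self.cv_spec = cv_spec or CVSpec(seed=seed)
        self.mining = mining or MiningParams()
        self.feature_min_k = feature_min_k
        self.signature_max_k = signature_max_k
        self.seed = seed

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, validation: pd.DataFrame | None = None,
                       **kwargs) -> "BlastocystSignatureModel":
        val = CohortTable(validation) if validation is not None else None
        return cls(CohortTable(df), val, **kwargs)

    @classmethod
    def from_csv(cls, path, validation_path=None, strict: bool = True,
                 **kwargs) -> "BlastocystSignatureModel":
        from .schema import load_cohort

        val = load_cohort(validation_path, strict) if validation_path else None
        return cls(load_cohort(path, strict), val, **kwargs)

    # ------------------------------------------------------------------

    def fit(self, mode: str = "selected_features") -> "SignatureResults":
        """Run the four stages and return the fitted results.

        ``mode`` controls the feature pool: ``selected_features`` (stage-1
        selection), ``all_variables`` (skip selection), or ``embryo_only``
        (restrict to the 14 embryo-related variables, skip selection).
        """
        if mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        train = self.train
        y = train.labels

        fs_result: FeatureSelectionResult | None = None
        if mode == "selected_features":
            fs_result = select_feature_set(
                train, y, roster=self.roster, spec=self.cv_spec,
                min_k=self.feature_min_k, seed=self.seed,
            )
            feature_set = fs_result.selected
        elif mode == "all_variables":
            feature_set = list(train.feature_names)
        else:
            feature_set = train.category_features("embryo")
        logger.info("mode=%s: %d features in play", mode, len(feature_set))

        m = self.mining
        candidates = R.extract_rules(
            train, y, feature_set,
            n_trees=m.n_trees, max_depth=m.max_depth,
            min_support_frac=m.min_support_frac, seed=self.seed,
        )
        selected, graph = R.select_rules(
            candidates, train, y,
            mcc_min=m.mcc_min,
            redundancy_threshold=m.redundancy_threshold,
            edge_threshold=m.edge_threshold,
            positive_only=m.positive_only,
        )
        if not selected:
            raise RuntimeError("all candidate rules were pruned; nothing to search")
        signature, cv_report = search_signature(
            selected, train, y, roster=self.roster, spec=self.cv_spec,
            max_k=self.signature_max_k,
        )
        validation_report = None
        if self.validation is not None:
            validation_report = evaluate_on_cohort(
                signature, train, self.validation, roster=self.roster
            )
        return SignatureResults(
            model=self,
            mode=mode,
            feature_selection=fs_result,
            feature_set=list(feature_set),
            candidate_rules=candidates,
            selected_rules=selected,
            rule_graph=graph,
            signature=signature,
            cv_report=cv_report,
            validation_report=validation_report,
        )


@dataclass
class SignatureResults:
    """Fitted results of :class:`BlastocystSignatureModel`."""

    model: BlastocystSignatureModel
    mode: str
    feature_selection: FeatureSelectionResult | None
    feature_set: list[str]
    candidate_rules: list[R.Rule]
    selected_rules: list[R.Rule]
    rule_graph: object
    signature: Signature
    cv_report: EvaluationReport
    validation_report: EvaluationReport | None = None

    # convenience accessors -------------------------------------------

    @property
    def n_candidate_rules(self) -> int:
        return len(self.candidate_rules)

    @property
    def n_selected_rules(self) -> int:
        return len(self.selected_rules)

    @property
    def n_isolated_rules(self) -> int:
        return len(R.isolated_rules(self.rule_graph))

    @property
    def cv_max_auc(self) -> float:
        return float(self.cv_report.curve["auc_mean"].max())

    def summary(self) -> str:
        """Human-readable fitting summary."""
        sig = self.signature
        lines = [
            "Blastocyst rule-signature model",
            "=" * 46,
            f"mode:                 {self.mode}",
            f"training embryos:     {len(self.model.train)}"
            f"  (prevalence {self.model.train.prevalence():.3f})",
            f"feature pool:         {len(self.feature_set)}",
            f"candidate rules:      {self.n_candidate_rules}",
            f"selected rules:       {self.n_selected_rules}"
            f"  (isolated in graph: {self.n_isolated_rules})",
            f"signature size k:     {sig.chosen_k}",
            f"winning classifier:   {sig.classifier}",
            f"CV max AUC:           {self.cv_max_auc:.3f}",
            f"composition:          {sig.composition}",
            "-" * 46,
            "signature rules (MCC-ordered):",
        ]
        for r in sig.rules:
            lines.append(f"  [{r.mcc:+.3f}] {r}")
        if self.validation_report is not None:
            vr = self.validation_report
            lines += [
                "-" * 46,
                f"validation embryos:   {len(self.model.validation)}",
                f"validation max AUC:   {vr.max_auc:.3f}",
                f"validation max acc:   {vr.max_accuracy:.3f}",
            ]
        return "\n".join(lines)
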