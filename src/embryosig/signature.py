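"""Stage 4: rule-combination search and frozen-signature evaluation.

Selected rules are encoded as binary features (one column per rule, 1 if
the rule fires on the embryo).  Rules are ordered by training MCC and the
k-prefix encodings are scored by repeated stratified CV with every roster
classifier; the signature is the prefix achieving the maximal
max-over-roster mean AUC (smallest k on ties).  The frozen signature is then
evaluated on an independent cohort: each roster member is fitted on the
training encoding and scored on the validation encoding — the rules
themselves are never refitted.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import rules as R
from .classifiers import ClassifierRoster
from .crossval import CVSpec, auc_score, make_pipeline, predict_scores, repeated_cv_auc
from .schema import CohortTable

logger = logging.getLogger(__name__)


@dataclass
class Signature:
    """The frozen, ordered rule set plus the classifier achieving max AUC."""

    rules: list[R.Rule]
    chosen_k: int
    classifier: str
    composition: dict[str, int]  # distinct features per category
    train_fingerprint: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "chosen_k": int(self.chosen_k),
            "classifier": self.classifier,
            "composition": {k: int(v) for k, v in self.composition.items()},
            "rules": [r.to_dict() for r in self.rules],
            "train_fingerprint": self.train_fingerprint,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Signature":
        return cls(
            rules=[R.Rule.from_dict(r) for r in d["rules"]],
            chosen_k=d["chosen_k"],
            classifier=d["classifier"],
            composition=d["composition"],
            train_fingerprint=d.get("train_fingerprint", {}),
        )


@dataclass
class EvaluationReport:
    per_classifier: pd.DataFrame  # columns: classifier, auc, accuracy
    curve: pd.DataFrame | None = None  # columns: k, auc_mean, auc_sd, classifier

    @property
    def max_auc(self) -> float:
        return float(self.per_classifier["auc"].max())

    @property
    def max_accuracy(self) -> float:
        return float(self.per_classifier["accuracy"].max())

    def to_dict(self) -> dict:
        out = {
            "per_classifier": self.per_classifier.to_dict(orient="records"),
            "max_auc": self.max_auc,
            "max_accuracy": self.max_accuracy,
        }
        if self.curve is not None:
            out["auc_curve"] = self.curve.to_dict(orient="records")
        return out


def encode_rules(rules: list[R.Rule], table: CohortTable) -> np.ndarray:
    """Binary n x r encoding: entry (i, j) = 1 iff rule j fires on embryo i."""
    if not rules:
        raise ValueError("empty rule list")
    return np.column_stack(
        [R.fire_vector(r, table).astype(float) for r in rules]
    )


def order_rules(rules: list[R.Rule]) -> list[R.Rule]:
    """MCC descending; ties by fewer conditions then canonical order."""
    return sorted(rules, key=lambda r: (-r.mcc, len(r.conditions), r.key()))


def search_signature(
    selected_rules: list[R.Rule],
    train: CohortTable,
    labels: np.ndarray | None = None,
    roster: ClassifierRoster | None = None,
    spec: CVSpec | None = None,
    max_k: int | None = 25,
) -> tuple[Signature, EvaluationReport]:
    """Prefix search over MCC-ordered rules for the max-CV-AUC combination.

    The chosen k is the smallest prefix whose max-over-roster mean AUC is
    within one standard error of the curve maximum (parsimony under CV
    noise).  ``max_k`` caps the sweep (the curve flattens well before
    large rule counts; None sweeps every prefix).
    """
    if not selected_rules:
        raise ValueError("signature search needs at least one selected rule")
    y = train.labels if labels is None else np.asarray(labels, dtype=float)
    roster = roster or ClassifierRoster()
    spec = spec or CVSpec()

    ordered = order_rules(selected_rules)
    X = encode_rules(ordered, train)
    k_max = len(ordered) if max_k is None else min(max_k, len(ordered))
    rows = []
    for k in range(1, k_max + 1):
        for name, factory in roster.factories().items():
            mean_auc, sd_auc = repeated_cv_auc(X[:, :k], y, factory, spec, scale=False)
            rows.append(
                {"k": k, "classifier": name, "auc_mean": mean_auc, "auc_sd": sd_auc}
            )
    curve_full = pd.DataFrame(rows)
    # per-k max over the roster
    best_per_k = (
        curve_full.sort_values(["k", "auc_mean"], ascending=[True, False])
        .groupby("k", as_index=False)
        .first()
    )
    # parsimony: smallest k within one standard error of the curve maximum
    # (strict argmax drifts upward on CV noise from uninformative rules)
    i_best = int(best_per_k["auc_mean"].idxmax())
    n_evals = spec.n_folds * spec.n_repeats
    se = float(best_per_k.loc[i_best, "auc_sd"]) / np.sqrt(max(n_evals, 1))
    threshold = float(best_per_k.loc[i_best, "auc_mean"]) - se
    chosen_row = best_per_k[best_per_k["auc_mean"] >= threshold].iloc[0]
    chosen_k = int(chosen_row["k"])
    winner = str(chosen_row["classifier"])

    sig_rules = ordered[:chosen_k]
    signature = Signature(
        rules=sig_rules,
        chosen_k=chosen_k,
        classifier=winner,
        composition=R.category_composition(sig_rules),
        train_fingerprint={
            "n": len(train),
            "prevalence": float(np.nanmean(y)),
            "n_candidate_rules": len(selected_rules),
        },
    )
    report = EvaluationReport(
        per_classifier=best_per_k.rename(columns={"auc_mean": "auc"})[
            ["classifier", "k", "auc", "auc_sd"]
        ].assign(accuracy=np.nan),
        curve=best_per_k[["k", "auc_mean", "auc_sd", "classifier"]],
    )
    logger.info("signature: k=%d rules, %s, CV AUC %.3f",
                chosen_k, winner, best_per_k.loc[i_best, "auc_mean"])
    return signature, report


def evaluate_on_cohort(
    signature: Signature,
    train: CohortTable,
    validation: CohortTable,
    train_labels: np.ndarray | None = None,
    validation_labels: np.ndarray | None = None,
    roster: ClassifierRoster | None = None,
) -> EvaluationReport:
    """Frozen-signature evaluation on an independent cohort.

    Roster members are fitted on the training encoding and scored on the
    validation encoding; per-member AUC and accuracy (0.5 threshold on the
    predicted positive-class probability) are reported together with the
    maxima over the roster.  Validation labels are only read to score the
    predictions, never to fit.
    """
    if len(validation) == 0:
        raise ValueError("empty validation cohort")
    roster = roster or ClassifierRoster()
    y_train = train.labels if train_labels is None else np.asarray(train_labels, float)
    y_val = (
        validation.labels
        if validation_labels is None
        else np.asarray(validation_labels, float)
    )
    missing = sorted(
        set().union(*(r.features for r in signature.rules))
        - set(validation.feature_names)
    )
    if missing:
        logger.warning(
            "validation cohort lacks feature(s) %s referenced by the signature; "
            "rules conditioned on them will never fire", missing,
        )
    Xtr = encode_rules(signature.rules, train)
    Xva = encode_rules(signature.rules, validation)

    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for name, factory in roster.factories().items():
            model = make_pipeline(factory(), scale=False)
            model.fit(Xtr, y_train)
            scores = predict_scores(model, Xva)
            pred = model.predict(Xva)
            rows.append(
                {
                    "classifier": name,
                    "auc": auc_score(y_val, scores),
                    "accuracy": float(np.mean(pred == y_val)),
                }
            )
    return EvaluationReport(per_classifier=pd.DataFrame(rows))
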