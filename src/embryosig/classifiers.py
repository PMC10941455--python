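"""The classifier roster used by feature selection and signature evaluation.

Seven algorithms spanning the four classical families — geometric (support
vector machine, k-nearest neighbours), probabilistic (logistic regression,
naive Bayes), rule/tree-based (random forest) and ensemble methods (gradient
boosting, AdaBoost) — with library-default hyperparameters and a fixed seed.
Reported AUC/accuracy maxima are taken over the roster, so the roster is a
search space, not a single model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from sklearn.ensemble import (
    AdaBoostClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.linear_model import LogisticRegression
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

FULL_ROSTER: tuple[str, ...] = (
    "svm",
    "knn",
    "logistic_regression",
    "naive_bayes",
    "random_forest",
    "gradient_boosting",
    "adaboost",
)

#: light subset for desk-scale runs: the two probabilistic members, whose
#: fits are orders of magnitude cheaper than the ensembles at equal AUC on
#: binary rule encodings
FAST_ROSTER: tuple[str, ...] = ("logistic_regression", "naive_bayes")

_FAMILY = {
    "svm": "geometric",
    "knn": "geometric",
    "logistic_regression": "probabilistic",
    "naive_bayes": "probabilistic",
    "random_forest": "rule_based",
    "gradient_boosting": "ensemble",
    "adaboost": "ensemble",
}


def _factories(seed: int, hyperparams: dict[str, dict] | None = None):
    hp = hyperparams or {}

    def params(name: str, **defaults):
        defaults.update(hp.get(name, {}))
        return defaults

    return {
        "svm": lambda: SVC(probability=True, **params("svm", random_state=seed)),
        "knn": lambda: KNeighborsClassifier(**params("knn")),
        "logistic_regression": lambda: LogisticRegression(
            **params("logistic_regression", max_iter=1000)
        ),
        "naive_bayes": lambda: GaussianNB(**params("naive_bayes")),
        "random_forest": lambda: RandomForestClassifier(
            **params("random_forest", random_state=seed)
        ),
        "gradient_boosting": lambda: GradientBoostingClassifier(
            **params("gradient_boosting", random_state=seed)
        ),
        "adaboost": lambda: AdaBoostClassifier(
            **params("adaboost", random_state=seed)
        ),
    }


@dataclass
class ClassifierRoster:
    """Named, seeded classifier factories.

    ``members`` must be a nonempty subset of the seven supported names;
    ``hyperparams`` overrides per-member constructor arguments.
    """

    members: tuple[str, ...] = FULL_ROSTER
    seed: int = 0
    hyperparams: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.members = tuple(self.members)
        if not self.members:
            raise ValueError("roster must be nonempty")
        unknown = [m for m in self.members if m not in FULL_ROSTER]
        if unknown:
            raise ValueError(f"unknown roster members: {unknown}")

    def factories(self) -> dict[str, object]:
        all_f = _factories(self.seed, self.hyperparams)
        return {m: all_f[m] for m in self.members}

    def family(self, member: str) -> str:
        return _FAMILY[member]

    def reseeded(self, seed: int) -> "ClassifierRoster":
        return ClassifierRoster(self.members, seed, dict(self.hyperparams))
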