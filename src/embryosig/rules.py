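"""Rule extraction and selection (pipeline stages 2-3).

Candidate rules are root-to-leaf paths of a seeded bagged ensemble of shallow
CART trees fitted on the selected features.  Each rule is a conjunction of
``feature <= threshold`` / ``feature > threshold`` conditions predicting BL
or nBL.  Rules are scored on the training cohort by the Matthews correlation
coefficient (MCC) — a correlation-style quality index that is robust to the
class imbalance of the cohort — then pruned: rules with MCC at or below a
floor are unpredictive, and of any two rules that both fire on essentially
the same embryos (pairwise phi above a redundancy threshold) *and* share a
feature, only the higher-MCC one is kept.  The survivors form the
rule-correlation graph: nodes weighted by MCC, edges where the pairwise
association exceeds the edge threshold (default 0.8).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, asdict

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeClassifier

from .schema import CohortTable, CATEGORY_MAP, LABEL_POSITIVE, LABEL_NEGATIVE

logger = logging.getLogger(__name__)

OP_LE = "<="
OP_GT = ">"


@dataclass(frozen=True)
class Condition:
    feature: str
    op: str  # "<=" or ">"
    threshold: float

    def __str__(self) -> str:
        return f"{self.feature} {self.op} {self.threshold:g}"


@dataclass
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def mcc(counts: ConfusionCounts) -> float:
    """Matthews correlation coefficient of a 2x2 confusion table.

    (tp*tn - fp*fn) / sqrt((tp+fp)(tp+fn)(tn+fp)(tn+fn)); defined as 0
    when any marginal is zero (the usual convention for a degenerate
    table).  Equals the phi coefficient — the Pearson correlation of the
    binary prediction and label vectors.
    """
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)


@dataclass
class Rule:
    """A conjunction of threshold conditions predicting one class.

    Conditions are simplified so each feature carries at most one lower
    (``>``) and one upper (``<=``) bound with a nonempty interval.
    ``support``, ``confusion`` and ``mcc`` refer to the training cohort the
    rule was extracted from.
    """

    conditions: tuple[Condition, ...]
    predicted_class: str  # BL or nBL
    support: int = 0
    confusion: ConfusionCounts | None = None
    mcc: float = float("nan")

    def __post_init__(self) -> None:
        if not self.conditions:
            raise ValueError("a rule needs at least one condition")
        self.conditions = simplify_conditions(self.conditions)

    @property
    def features(self) -> frozenset[str]:
        return frozenset(c.feature for c in self.conditions)

    def key(self) -> tuple:
        """Canonical identity: sorted conditions plus predicted class."""
        conds = tuple(sorted((c.feature, c.op, c.threshold) for c in self.conditions))
        return (conds, self.predicted_class)

    def __str__(self) -> str:
        body = " AND ".join(str(c) for c in self.conditions)
        return f"IF {body} THEN {self.predicted_class}"

    def to_dict(self) -> dict:
        return {
            "conditions": [asdict(c) for c in self.conditions],
            "predicted_class": self.predicted_class,
            "support": self.support,
            "confusion": asdict(self.confusion) if self.confusion else None,
            "mcc": None if math.isnan(self.mcc) else self.mcc,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Rule":
        conf = ConfusionCounts(**d["confusion"]) if d.get("confusion") else None
        return cls(
            conditions=tuple(Condition(**c) for c in d["conditions"]),
            predicted_class=d["predicted_class"],
            support=d.get("support", 0),
            confusion=conf,
            mcc=d.get("mcc") if d.get("mcc") is not None else float("nan"),
        )


def simplify_conditions(conditions) -> tuple[Condition, ...]:
    """Tightest-interval simplification: per feature keep min upper and max
    lower bound; an empty interval is a contradiction."""
    upper: dict[str, float] = {}
    lower: dict[str, float] = {}
    order: list[str] = []
    for c in conditions:
        if c.feature not in order:
            order.append(c.feature)
        if c.op == OP_LE:
            upper[c.feature] = min(upper.get(c.feature, math.inf), c.threshold)
        elif c.op == OP_GT:
            lower[c.feature] = max(lower.get(c.feature, -math.inf), c.threshold)
        else:
            raise ValueError(f"unknown operator {c.op!r}")
    out: list[Condition] = []
    for f in order:
        lo, hi = lower.get(f), upper.get(f)
        if lo is not None and hi is not None and lo >= hi:
            raise ValueError(f"empty interval for {f}: > {lo} and <= {hi}")
        if lo is not None:
            out.append(Condition(f, OP_GT, float(lo)))
        if hi is not None:
            out.append(Condition(f, OP_LE, float(hi)))
    return tuple(out)


def rule_fire(rule: Rule, record) -> bool:
    """True iff every condition holds; a condition on a missing value never
    fires (conservative missing-data policy)."""
    for c in rule.conditions:
        v = record.get(c.feature, None) if hasattr(record, "get") else getattr(record, c.feature)
        if v is None or (isinstance(v, float) and math.isnan(v)):
            return False
        if c.op == OP_LE and not v <= c.threshold:
            return False
        if c.op == OP_GT and not v > c.threshold:
            return False
    return True


def fire_vector(rule: Rule, table: CohortTable) -> np.ndarray:
    """Vectorized firing indicator (bool per embryo)."""
    X = table.features(sorted(rule.features))
    fires = np.ones(len(table), dtype=bool)
    for c in rule.conditions:
        col = X[c.feature].to_numpy()
        with np.errstate(invalid="ignore"):
            ok = col <= c.threshold if c.op == OP_LE else col > c.threshold
        fires &= np.where(np.isnan(col), False, ok)
    return fires


def confusion(rule: Rule, table: CohortTable, labels: np.ndarray | None = None) -> ConfusionCounts:
    """Confusion counts treating fire = predicted class."""
    if len(table) == 0:
        raise ValueError("empty table")
    y = table.labels if labels is None else np.asarray(labels, dtype=float)
    fires = fire_vector(rule, table)
    positive = y == (1.0 if rule.predicted_class == LABEL_POSITIVE else 0.0)
    return ConfusionCounts(
        tp=int(np.sum(fires & positive)),
        fp=int(np.sum(fires & ~positive)),
        tn=int(np.sum(~fires & ~positive)),
        fn=int(np.sum(~fires & positive)),
    )


def score_rule(rule: Rule, table: CohortTable, labels: np.ndarray | None = None) -> Rule:
    """Return the rule with support/confusion/MCC filled in on ``table``."""
    conf = confusion(rule, table, labels)
    rule.support = conf.tp + conf.fp
    rule.confusion = conf
    rule.mcc = mcc(conf)
    return rule


def rule_association(rule_a: Rule, rule_b: Rule, table: CohortTable) -> float:
    """Phi coefficient (MCC) between the two binary firing vectors."""
    a = fire_vector(rule_a, table)
    b = fire_vector(rule_b, table)
    return binary_phi(a, b)


def binary_phi(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    table = ConfusionCounts(
        tp=int(np.sum(a & b)),
        fp=int(np.sum(a & ~b)),
        fn=int(np.sum(~a & b)),
        tn=int(np.sum(~a & ~b)),
    )
    return mcc(table)


# ------------------------------------------------------------- extraction


def _paths_from_tree(tree: DecisionTreeClassifier, feature_names: list[str]) -> list[Rule]:
    t = tree.tree_
    classes = tree.classes_
    rules: list[Rule] = []

    def walk(node: int, conds: list[Condition]) -> None:
        if t.children_left[node] == -1:  # leaf
            counts = t.value[node][0]
            cls = classes[int(np.argmax(counts))]
            if conds:
                try:
                    rules.append(Rule(tuple(conds), predicted_class=str(cls)))
                except ValueError:
                    pass  # contradictory path after simplification
            return
        f = feature_names[t.feature[node]]
        thr = float(t.threshold[node])
        if not math.isfinite(thr):
            # missingness-only split (CART's NaN handling): no finite
            # threshold exists, so the branch adds no condition
            walk(t.children_left[node], conds)
            walk(t.children_right[node], conds)
            return
        walk(t.children_left[node], conds + [Condition(f, OP_LE, thr)])
        walk(t.children_right[node], conds + [Condition(f, OP_GT, thr)])

    walk(0, [])
    return rules


def extract_rules(
    train: CohortTable,
    labels: np.ndarray | None = None,
    feature_set: list[str] | None = None,
    n_trees: int = 50,
    max_depth: int = 3,
    min_support_frac: float = 0.05,
    bootstrap: bool = True,
    seed: int = 0,
) -> list[Rule]:
    """Enumerate candidate rules from a bagged ensemble of shallow trees.

    Every root-to-leaf path of every tree becomes one rule predicting the
    leaf-majority class.  Rules are simplified to tightest intervals,
    deduplicated, filtered by minimum support (default 5% of the training
    cohort) and returned with confusion counts and MCC computed on the full
    training cohort.  Trees are fitted on the raw feature values (NaN
    allowed: CART routes missing values during fitting, while rule firing
    on a missing value is always false).
    """
    y = train.labels if labels is None else np.asarray(labels, dtype=float)
    if len(np.unique(y[~np.isnan(y)])) < 2:
        raise ValueError("rule extraction needs both classes in the training data")
    feats = list(feature_set) if feature_set else list(train.feature_names)
    X = train.features(feats).to_numpy()
    y_str = np.where(y == 1.0, LABEL_POSITIVE, LABEL_NEGATIVE)

    rng = np.random.default_rng(seed)
    n = len(train)
    seen: dict[tuple, Rule] = {}
    for t in range(n_trees):
        idx = rng.integers(0, n, size=n) if bootstrap else np.arange(n)
        tree = DecisionTreeClassifier(
            max_depth=max_depth,
            random_state=int(rng.integers(0, 2**31 - 1)),
        )
        tree.fit(X[idx], y_str[idx])
        for rule in _paths_from_tree(tree, feats):
            k = rule.key()
            if k not in seen:
                seen[k] = rule

    min_support = max(1, int(math.ceil(min_support_frac * n)))
    out: list[Rule] = []
    for rule in seen.values():
        score_rule(rule, train, y)
        if rule.support >= min_support:
            out.append(rule)
    # canonical deterministic order
    out.sort(key=lambda r: r.key())
    logger.info("extracted %d candidate rules (%d paths before support filter)",
                len(out), len(seen))
    return out


# -------------------------------------------------------------- selection


def _rule_sort_key(r: Rule) -> tuple:
    return (-r.mcc, len(r.conditions), r.key())


def build_rule_graph(
    rules: list[Rule], table: CohortTable, edge_threshold: float = 0.8
) -> nx.Graph:
    """Rule-correlation graph: nodes = rules (weight = MCC), undirected
    edges where the firing-vector phi exceeds ``edge_threshold``."""
    g = nx.Graph(edge_threshold=edge_threshold)
    vecs = [fire_vector(r, table) for r in rules]
    for i, r in enumerate(rules):
        g.add_node(
            i,
            rule=str(r),
            mcc=float(r.mcc),
            support=int(r.support),
            predicted_class=r.predicted_class,
        )
    for i in range(len(rules)):
        for j in range(i + 1, len(rules)):
            assoc = binary_phi(vecs[i], vecs[j])
            if assoc > edge_threshold:
                g.add_edge(i, j, weight=float(assoc))
    return g


def isolated_rules(graph: nx.Graph) -> list[int]:
    return [n for n in graph.nodes if graph.degree(n) == 0]


def select_rules(
    rules: list[Rule],
    train: CohortTable,
    labels: np.ndarray | None = None,
    mcc_min: float = 0.0,
    redundancy_threshold: float = 0.8,
    edge_threshold: float = 0.8,
    positive_only: bool = False,
) -> tuple[list[Rule], nx.Graph]:
    """Prune unpredictive and redundant rules, then build the rule graph.

    A rule is unpredictive if its training MCC <= ``mcc_min``.  Two rules
    are redundant when their firing vectors have phi > the redundancy
    threshold *and* they share at least one feature; the lower-MCC rule is
    dropped (ties: fewer conditions, then canonical order).  The returned
    graph covers the survivors with edges above ``edge_threshold``;
    isolated vertices are rules with no strong dependency on any other.
    Deterministic and invariant to the input rule order.
    """
    if not rules:
        raise ValueError("empty candidate rule list")
    y = train.labels if labels is None else np.asarray(labels, dtype=float)
    pool = [r for r in rules if r.mcc > mcc_min]
    if positive_only:
        pool = [r for r in pool if r.predicted_class == LABEL_POSITIVE]
    pool.sort(key=_rule_sort_key)

    kept: list[Rule] = []
    kept_vecs: list[np.ndarray] = []
    for r in pool:
        v = fire_vector(r, train)
        redundant = any(
            (r.features & k.features) and binary_phi(v, kv) > redundancy_threshold
            for k, kv in zip(kept, kept_vecs)
        )
        if not redundant:
            kept.append(r)
            kept_vecs.append(v)
    if not kept:
        logger.warning("all rules pruned; empty selection")
    graph = build_rule_graph(kept, train, edge_threshold)
    return kept, graph


# ------------------------------------------------------------------ export


def rules_to_json(rules: list[Rule]) -> list[dict]:
    return [r.to_dict() for r in rules]


def category_composition(rules: list[Rule]) -> dict[str, int]:
    """Distinct features used across the rules, counted per category."""
    feats = sorted(set().union(*(r.features for r in rules))) if rules else []
    comp = {"woman": 0, "cos": 0, "embryo": 0}
    for f in feats:
        comp[CATEGORY_MAP[f]] += 1
    return comp


def write_graphml(graph: nx.Graph, path) -> None:
    nx.write_graphml(graph, path)


def write_dot(graph: nx.Graph, path) -> None:
    """Minimal DOT export (node label = rule, width ~ MCC)."""
    lines = ["graph rules {"]
    for n, data in graph.nodes(data=True):
        label = data.get("rule", str(n)).replace('"', "'")
        lines.append(f'  {n} [label="{label}", mcc="{data.get("mcc", 0):.3f}"];')
    for a, b, data in graph.edges(data=True):
        lines.append(f'  {a} -- {b} [weight="{data.get("weight", 0):.3f}"];')
    lines.append("}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
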