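"""Seeded synthetic embryo-cohort generator with plantable rule signatures.

The generator emulates the statistical structure the analysis pipeline
assumes, without attempting to reproduce any real patient's data:

* patient -> embryo nesting: woman- and COS-related variables are drawn per
  patient and repeated across that patient's embryos;
* a woman <-> COS correlation block: stimulation outcome variables are noisy
  functions of a patient-level ovarian-responsiveness latent, with strength
  ``woman_cos_coupling``;
* an embryo-block correlation: all cytokinesis timings of an embryo share a
  developmental-pace latent (strength ``embryo_block_coupling``) and are
  built as a first event time plus strictly positive lognormal increments,
  so the event ordering tPNa <= tPNf <= t2 <= t3 <= t4 <= t8 holds by
  construction;
* conventional-IVF missingness: embryos of conventionally inseminated
  cycles have tPNa and tPNf_tPNa blanked;
* labels: Bernoulli draws from a logistic model in the planted rules'
  firing indicators, with the intercept calibrated so the expected
  prevalence matches the configured one, then flipped with probability
  ``label_noise``.

Everything is reproducible from the config seed.  The ground truth (firing
indicators and the Bayes-optimal score of every embryo) is returned
alongside the cohort so downstream recovery can be measured exactly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from . import rules as R
from .crossval import auc_score
from .schema import (
    CONVENTIONAL,
    FEATURE_NAMES,
    ICSI,
    INTERVAL_DEFS,
    LABEL_NEGATIVE,
    LABEL_POSITIVE,
    CohortTable,
    validate,
)

logger = logging.getLogger(__name__)

#: timing increments (hours): event, mean of the lognormal increment, sigma
_TIMING_PLAN = (
    ("tPNa", 6.5, 0.15),       # absolute first event
    ("tPNf", 17.0, 0.18),      # tPNf - tPNa
    ("t2", 2.6, 0.30),         # t2 - tPNf
    ("t3", 10.5, 0.22),        # t3 - t2
    ("t4", 1.8, 0.45),         # t4 - t3
    ("t8", 17.0, 0.28),        # t8 - t4
)


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    Defaults mirror the cohort the framework was developed on: 80 cycles,
    575 embryos, 36.5% reaching the expanded blastocyst stage, roughly a
    third of cycles inseminated by conventional IVF.
    """

    n_patients: int = 80
    n_embryos: int | None = 575  # fixed total; None = free Poisson total
    embryos_per_patient_mean: float = 7.2
    prevalence: float = 0.365
    planted_rules: tuple[tuple[R.Rule, float], ...] = ()  # (rule, log-odds weight)
    woman_cos_coupling: float = 0.6
    embryo_block_coupling: float = 0.6
    conventional_fraction: float = 0.34  # per cycle, as in the study cohort
    label_noise: float = 0.0
    nested: bool = True  # patient-level features repeat across embryos
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("prevalence", "woman_cos_coupling", "embryo_block_coupling",
                     "conventional_fraction", "label_noise"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} = {v} outside [0, 1]")
        if self.n_patients < 1:
            raise ValueError("n_patients >= 1 required")
        for rule, _ in self.planted_rules:
            unknown = rule.features - set(FEATURE_NAMES)
            if unknown:
                raise ValueError(f"planted rule uses unknown features: {sorted(unknown)}")


@dataclass
class GroundTruth:
    planted_rules: tuple[tuple[R.Rule, float], ...]
    fires: np.ndarray          # (n_embryos, n_rules) bool
    bayes_score: np.ndarray    # P(BL | rules) per embryo, before label noise
    realized_prevalence: float

    @property
    def planted_features(self) -> set[str]:
        return set().union(*(r.features for r, _ in self.planted_rules)) \
            if self.planted_rules else set()

    def bayes_auc(self, labels: np.ndarray) -> float:
        """AUC of the Bayes-optimal score against the realized labels."""
        return auc_score(np.asarray(labels, dtype=float), self.bayes_score)


def default_planted_rules() -> tuple[tuple[R.Rule, float], ...]:
    """Three planted rules on a day-2 morphology score, a cytokinesis
    timing and a stimulation-response feature — one per Fig-2-style
    correlation block, with weights giving a moderately strong signal."""
    c = R.Condition
    return (
        (R.Rule((c("imcs", R.OP_GT, 6.5),), LABEL_POSITIVE), 5.0),
        (R.Rule((c("t4", R.OP_LE, 39.0),), LABEL_POSITIVE), 4.5),
        (R.Rule((c("osi", R.OP_GT, 5.2),), LABEL_POSITIVE), 4.0),
    )


def _patient_sizes(cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    sizes = np.maximum(1, rng.poisson(cfg.embryos_per_patient_mean, cfg.n_patients))
    if cfg.n_embryos is not None:
        while sizes.sum() > cfg.n_embryos:
            i = rng.integers(cfg.n_patients)
            if sizes[i] > 1:
                sizes[i] -= 1
        while sizes.sum() < cfg.n_embryos:
            sizes[rng.integers(cfg.n_patients)] += 1
    return sizes


def _truncnorm(rng, mean, sd, lo, hi, size):
    x = rng.normal(mean, sd, size)
    return np.clip(x, lo, hi)


def _generate_patients(cfg: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = cfg.n_patients
    c = cfg.woman_cos_coupling
    u = rng.normal(size=n)                       # ovarian reserve/responsiveness
    eta = rng.normal(size=n)                     # COS-specific component
    w = c * u + np.sqrt(1.0 - c**2) * eta        # COS driver

    e = lambda: rng.normal(size=n)
    df = pd.DataFrame(
        {
            "age": np.clip(35.3 + 3.5 * (-0.45 * u + 0.89 * e()), 25, 42).round(1),
            "bmi": _truncnorm(rng, 24.2, 4.8, 18, 34, n).round(1),
            "day3_fsh": np.clip(7.0 - 1.0 * u + 1.2 * e(), 2.0, 12.0).round(2),
            "amh": np.clip(3.2 * np.exp(0.30 * u + 0.25 * e()), 0.4, 12.0).round(2),
            "afc": np.clip(np.round(13 + 2.5 * u + 1.5 * e()), 3, 28),
            "infertility_years": np.clip(rng.gamma(2.0, 1.5, n), 0.5, 12.0).round(1),
        }
    )
    # derived values (OSI, rates) are stored exactly so the schema's
    # derivation cross-check holds bit-for-bit
    total_fsh = np.clip(2250 - 450 * w + 250 * e(), 1000, 4500).round(0)
    n_cocs = np.maximum(1, np.round(11 + 3.5 * w + 1.5 * e())).astype(int)
    df["total_fsh"] = total_fsh
    df["peak_e2"] = np.clip(170 * n_cocs + 250 * e(), 400, 6500).round(0)
    df["osi"] = n_cocs * 1000.0 / total_fsh
    df["n_cocs"] = n_cocs
    df["n_mature"] = rng.binomial(n_cocs, 0.80)
    df["n_fertilized"] = rng.binomial(df["n_mature"], 0.75)
    df["n_cleaved"] = rng.binomial(df["n_fertilized"], 0.95)
    with np.errstate(divide="ignore", invalid="ignore"):
        df["maturation_rate"] = df["n_mature"] / df["n_cocs"]
        df["fertilization_rate"] = df["n_fertilized"] / df["n_mature"]
        df["cleavage_rate"] = df["n_cleaved"] / df["n_fertilized"]
    for col, den in (("fertilization_rate", "n_mature"), ("cleavage_rate", "n_fertilized")):
        df.loc[df[den] == 0, col] = np.nan
    df["insemination"] = np.where(
        rng.random(n) < cfg.conventional_fraction, CONVENTIONAL, ICSI
    )
    return df


def _generate_embryos(
    cfg: SimulationConfig, rng: np.random.Generator, n_embryos: int
) -> pd.DataFrame:
    b = cfg.embryo_block_coupling
    pace = rng.normal(size=n_embryos)  # shared developmental-pace latent
    times = {}
    prev = np.zeros(n_embryos)
    for event, mean, sigma in _TIMING_PLAN:
        z = b * pace + np.sqrt(1.0 - b**2) * rng.normal(size=n_embryos)
        increment = mean * np.exp(sigma * z - 0.5 * sigma**2)
        prev = prev + increment
        times[event] = prev
    df = pd.DataFrame({k: v.round(2) for k, v in times.items()})
    # day-2 morphology: slower pace -> lower score, half-point scale in [0, 10]
    imcs = 6.5 - 1.1 * pace + 1.0 * rng.normal(size=n_embryos)
    df["imcs"] = np.clip(np.round(imcs * 2) / 2, 0.0, 10.0)
    return df


def generate_cohort(config: SimulationConfig) -> tuple[CohortTable, GroundTruth]:
    """Draw one cohort and its ground truth from the configured conditions."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    sizes = _patient_sizes(cfg, rng)
    n = int(sizes.sum())

    patients = _generate_patients(cfg, rng)
    if cfg.nested:
        pat_rows = patients.loc[np.repeat(np.arange(cfg.n_patients), sizes)].reset_index(
            drop=True
        )
    else:  # ablation mode: break nesting by re-drawing patient rows per embryo
        unnested = SimulationConfig(
            n_patients=n,
            n_embryos=None,
            prevalence=cfg.prevalence,
            woman_cos_coupling=cfg.woman_cos_coupling,
            conventional_fraction=cfg.conventional_fraction,
            seed=cfg.seed,
        )
        pat_rows = _generate_patients(unnested, rng).reset_index(drop=True)

    embryos = _generate_embryos(cfg, rng, n)
    df = pd.concat([pat_rows.reset_index(drop=True), embryos], axis=1)
    df["patient_id"] = (
        np.repeat([f"P{i:03d}" for i in range(cfg.n_patients)], sizes)
        if cfg.nested
        else [f"P{i:03d}" for i in range(n)]
    )
    df["embryo_id"] = [f"E{i:04d}" for i in range(n)]

    for interval, (late, early) in INTERVAL_DEFS.items():
        df[interval] = (df[late] - df[early]).round(2)

    # conventional-IVF embryos lack the pronuclear-appearance annotation
    conventional = df["insemination"] == CONVENTIONAL
    df.loc[conventional, ["tPNa", "tPNf_tPNa"]] = np.nan

    df["label"] = "unknown"
    table = CohortTable(df[list(("embryo_id", "patient_id", "label") + FEATURE_NAMES)])

    # ---- labels from planted rules -----------------------------------
    planted = cfg.planted_rules
    if planted:
        fires = np.column_stack([R.fire_vector(rule, table) for rule, _ in planted])
        weights = np.array([w for _, w in planted], dtype=float)
    else:
        fires = np.zeros((n, 0), dtype=bool)
        weights = np.zeros(0)

    if np.any(np.isinf(weights)):
        # noiseless limit: the label is exactly the infinite-weight indicator
        p = fires[:, np.isinf(weights)].any(axis=1).astype(float)
    else:
        linear = fires @ weights
        # calibrate the pre-noise rate so that the expected prevalence
        # AFTER the label flips equals the configured one
        target = cfg.prevalence
        if 0.0 < cfg.label_noise < 0.5:
            target = (cfg.prevalence - cfg.label_noise) / (1.0 - 2.0 * cfg.label_noise)
            target = float(np.clip(target, 1e-6, 1.0 - 1e-6))

        def mean_prev(b0: float) -> float:
            return float(np.mean(expit(b0 + linear))) - target

        if target in (0.0, 1.0):
            p = np.full(n, target)
        else:
            b0 = brentq(mean_prev, -40.0, 40.0)
            p = expit(b0 + linear)

    y = (rng.random(n) < p).astype(int)
    flips = rng.random(n) < cfg.label_noise
    y = np.where(flips, 1 - y, y)
    table.df["label"] = np.where(y == 1, LABEL_POSITIVE, LABEL_NEGATIVE)

    truth = GroundTruth(
        planted_rules=tuple(planted),
        fires=fires,
        bayes_score=p,
        realized_prevalence=float(np.mean(y)),
    )
    validate(table, strict=True)  # construction guarantee, cheap insurance
    return table, truth


def woman_cos_mean_abs_r(table: CohortTable) -> float:
    """Mean |Pearson r| between the woman- and COS-related blocks."""
    X = table.features()
    woman = table.category_features("woman")
    cos = table.category_features("cos")
    corr = X[woman + cos].corr()
    block = corr.loc[woman, cos].to_numpy()
    return float(np.nanmean(np.abs(block)))


def ordering_violations(table: CohortTable) -> int:
    """Count embryos whose annotated event times are out of order."""
    X = table.features(["tPNa", "tPNf", "t2", "t3", "t4", "t8"])
    bad = 0
    arr = X.to_numpy()
    for row in arr:
        present = row[~np.isnan(row)]
        if np.any(np.diff(present) < -1e-9):
            bad += 1
    return bad


def diagnostics_report(table: CohortTable, truth: GroundTruth) -> dict:
    """Summary of the realized cohort against its configured conditions."""
    y = table.labels
    report = {
        "n_embryos": len(table),
        "n_patients": table.n_patients,
        "realized_prevalence": float(np.nanmean(y)),
        "woman_cos_mean_abs_r": woman_cos_mean_abs_r(table),
        "ordering_violations": ordering_violations(table),
        "feature_moments": {
            c: {"mean": float(m), "sd": float(s)}
            for c, m, s in zip(
                table.feature_names,
                table.features().mean(),
                table.features().std(ddof=1),
            )
        },
    }
    if truth.planted_rules:
        report["planted_rule_mcc"] = [
            R.mcc(R.confusion(rule, table)) for rule, _ in truth.planted_rules
        ]
        report["bayes_auc"] = truth.bayes_auc(y)
    return report


def write_ground_truth(truth: GroundTruth, path) -> None:
    payload = {
        "planted_rules": [
            {"rule": rule.to_dict(), "weight": w} for rule, w in truth.planted_rules
        ],
        "realized_prevalence": truth.realized_prevalence,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
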