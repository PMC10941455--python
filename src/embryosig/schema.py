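"""Canonical cohort schema: the 30-variable embryo table, I/O and preprocessing.

One row per embryo. The 30 features fall into three categories:

* woman-related (6): maternal clinical characteristics,
* COS-related (10): controlled-ovarian-stimulation characteristics and
  outcomes, constant across a patient's embryos,
* embryo-related (14): insemination technique, day-2 morphology score (IMCS)
  and the time-lapse morphokinetic annotations (hours post-insemination).

Embryos inseminated by conventional IVF lack the pronuclear-appearance time
``tPNa`` (and hence the ``tPNf_tPNa`` interval) because normal fertilization
is only checked after cumulus-cell removal; this missingness pattern is part
of the schema and is validated, not imputed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

WOMAN_FEATURES: tuple[str, ...] = (
    "age",
    "bmi",
    "day3_fsh",
    "amh",
    "afc",
    "infertility_years",
)

COS_FEATURES: tuple[str, ...] = (
    "total_fsh",
    "peak_e2",
    "osi",
    "n_cocs",
    "n_mature",
    "maturation_rate",
    "n_fertilized",
    "fertilization_rate",
    "n_cleaved",
    "cleavage_rate",
)

EMBRYO_FEATURES: tuple[str, ...] = (
    "insemination",
    "imcs",
    "tPNa",
    "tPNf",
    "t2",
    "t3",
    "t4",
    "t8",
    "tPNf_tPNa",
    "t2_tPNf",
    "t3_t2",
    "t4_t3",
    "t4_t2",
    "t8_t4",
)

FEATURE_NAMES: tuple[str, ...] = WOMAN_FEATURES + COS_FEATURES + EMBRYO_FEATURES

CATEGORY_MAP: dict[str, str] = {
    **{f: "woman" for f in WOMAN_FEATURES},
    **{f: "cos" for f in COS_FEATURES},
    **{f: "embryo" for f in EMBRYO_FEATURES},
}

META_COLUMNS: tuple[str, ...] = ("embryo_id", "patient_id", "label")

#: ordered cytokinesis / pronuclear event times (hours post-insemination)
TIME_FEATURES: tuple[str, ...] = ("tPNa", "tPNf", "t2", "t3", "t4", "t8")

#: interval name -> (later event, earlier event)
INTERVAL_DEFS: dict[str, tuple[str, str]] = {
    "tPNf_tPNa": ("tPNf", "tPNa"),
    "t2_tPNf": ("t2", "tPNf"),
    "t3_t2": ("t3", "t2"),
    "t4_t3": ("t4", "t3"),
    "t4_t2": ("t4", "t2"),
    "t8_t4": ("t8", "t4"),
}

RATE_FEATURES: tuple[str, ...] = (
    "maturation_rate",
    "fertilization_rate",
    "cleavage_rate",
)

CONVENTIONAL = "conventional_IVF"
ICSI = "ICSI"
LABEL_POSITIVE = "BL"  # reached expanded blastocyst on day 5
LABEL_NEGATIVE = "nBL"

_INTERVAL_TOL = 1e-6


class SchemaError(ValueError):
    """The table does not have the canonical columns."""


class ValidationError(ValueError):
    """One or more rows violate a schema invariant (strict mode)."""


@dataclass
class CohortTable:
    """A validated embryo cohort.

    Wraps a :class:`pandas.DataFrame` with the meta columns
    (``embryo_id``, ``patient_id``, ``label``) and the 30 canonical
    features.  ``insemination`` is stored as the strings
    ``conventional_IVF`` / ``ICSI``; :meth:`features` exposes the numeric
    view used by every modelling stage (ICSI encoded as 1).
    """

    df: pd.DataFrame
    feature_names: tuple[str, ...] = FEATURE_NAMES
    category_map: dict[str, str] = field(default_factory=lambda: dict(CATEGORY_MAP))

    def __post_init__(self) -> None:
        missing = [c for c in META_COLUMNS + self.feature_names if c not in self.df.columns]
        if missing:
            raise SchemaError(f"missing mandatory columns: {missing}")
        self.df = self.df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def n_patients(self) -> int:
        return self.df["patient_id"].nunique()

    @property
    def labels(self) -> np.ndarray:
        """Binary outcome vector: 1 for BL, 0 for nBL, NaN for unknown."""
        return (
            self.df["label"]
            .map({LABEL_POSITIVE: 1.0, LABEL_NEGATIVE: 0.0})
            .to_numpy(dtype=float)
        )

    def features(self, names: list[str] | tuple[str, ...] | None = None) -> pd.DataFrame:
        """Numeric feature matrix (insemination mapped conventional=0, ICSI=1)."""
        names = list(names) if names is not None else list(self.feature_names)
        out = self.df[names].copy()
        if "insemination" in out.columns and out["insemination"].dtype == object:
            out["insemination"] = out["insemination"].map({CONVENTIONAL: 0.0, ICSI: 1.0})
        return out.astype(float)

    def category_features(self, category: str) -> list[str]:
        return [f for f in self.feature_names if self.category_map[f] == category]

    def subset(self, index: np.ndarray) -> "CohortTable":
        return CohortTable(self.df.iloc[np.asarray(index)].reset_index(drop=True))

    def prevalence(self) -> float:
        y = self.labels
        y = y[~np.isnan(y)]
        return float(np.mean(y)) if y.size else math.nan

    # ------------------------------------------------------------------ I/O

    def to_csv(self, path) -> None:
        """Write the canonical CSV (missing values as empty fields)."""
        self.df.to_csv(path, index=False)

    def to_json(self, path) -> None:
        self.df.to_json(path, orient="records", indent=1)

    def copy(self) -> "CohortTable":
        return CohortTable(self.df.copy())


def _row_violations(row: pd.Series) -> list[str]:
    """All invariant violations for one record (empty if valid)."""
    problems: list[str] = []
    insem = row["insemination"]
    if insem not in (CONVENTIONAL, ICSI):
        problems.append(f"unknown insemination technique {insem!r}")

    times = [(t, row[t]) for t in TIME_FEATURES if pd.notna(row[t])]
    for name, v in times:
        if v <= 0:
            problems.append(f"{name} = {v} is not > 0")
    for (a, va), (b, vb) in zip(times, times[1:]):
        if va > vb + _INTERVAL_TOL:
            problems.append(f"time ordering violated: {a}={va} > {b}={vb}")

    for interval, (late, early) in INTERVAL_DEFS.items():
        if pd.notna(row[interval]) and pd.notna(row[late]) and pd.notna(row[early]):
            expect = row[late] - row[early]
            if abs(row[interval] - expect) > _INTERVAL_TOL:
                problems.append(
                    f"{interval} = {row[interval]} != {late} - {early} = {expect:g}"
                )

    for rate in RATE_FEATURES:
        if pd.notna(row[rate]) and not (0.0 <= row[rate] <= 1.0):
            problems.append(f"{rate} = {row[rate]} outside [0, 1]")

    # tPNa / tPNf_tPNa missing if and only if conventional IVF
    tpna_missing = pd.isna(row["tPNa"]) and pd.isna(row["tPNf_tPNa"])
    if insem == CONVENTIONAL and not tpna_missing:
        problems.append("conventional-IVF embryo has annotated tPNa/tPNf_tPNa")
    if insem == ICSI and (pd.isna(row["tPNa"]) or pd.isna(row["tPNf_tPNa"])):
        problems.append("ICSI embryo missing tPNa/tPNf_tPNa")

    for lo, hi in (("n_mature", "n_cocs"), ("n_fertilized", "n_mature"),
                   ("n_cleaved", "n_fertilized")):
        if pd.notna(row[lo]) and pd.notna(row[hi]) and row[lo] > row[hi]:
            problems.append(f"{lo} = {row[lo]} > {hi} = {row[hi]}")
    return problems


def validate(table: CohortTable, strict: bool = True) -> CohortTable:
    """Check every record against the schema invariants.

    strict: raise :class:`ValidationError` naming the offending embryos.
    lenient: drop invalid rows with a logged warning.
    """
    bad: dict[str, list[str]] = {}
    for _, row in table.df.iterrows():
        problems = _row_violations(row)
        if problems:
            bad[str(row["embryo_id"])] = problems
    if not bad:
        return table
    if strict:
        detail = "; ".join(f"{eid}: {', '.join(p)}" for eid, p in bad.items())
        raise ValidationError(f"{len(bad)} invalid record(s): {detail}")
    keep = ~table.df["embryo_id"].astype(str).isin(bad)
    for eid, problems in bad.items():
        logger.warning("dropping embryo %s: %s", eid, "; ".join(problems))
    return CohortTable(table.df[keep].reset_index(drop=True))


def load_cohort(path, strict: bool = True) -> CohortTable:
    """Read the canonical cohort CSV and validate it.

    The header must contain all canonical columns (order-free); missing
    values are empty fields.
    """
    df = pd.read_csv(path)
    missing = [c for c in META_COLUMNS + FEATURE_NAMES if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory columns {missing}")
    numeric = [f for f in FEATURE_NAMES if f != "insemination"]
    df[numeric] = df[numeric].apply(pd.to_numeric)
    return validate(CohortTable(df), strict=strict)


def derive_features(table: CohortTable, rate_denominator: str = "mature") -> CohortTable:
    """Fill the derived variables and cross-check any already present.

    Derivations: OSI = n_cocs*1000/total_fsh; maturation_rate =
    n_mature/n_cocs; fertilization_rate = n_fertilized/n_mature (or
    /n_cocs when ``rate_denominator='cocs'``); cleavage_rate =
    n_cleaved/n_fertilized; each timing interval as the difference of its
    endpoints.  Zero denominators leave the value missing with a warning.
    A pre-existing value that disagrees with the derivation beyond 1e-6 is
    reported (warning) and left as-is.

    Idempotent: applying it twice changes nothing.
    """
    if rate_denominator not in ("mature", "cocs"):
        raise ValueError("rate_denominator must be 'mature' or 'cocs'")
    df = table.df.copy()

    def ratio(num, den, scale=1.0):
        num = df[num]
        den = df[den]
        with np.errstate(divide="ignore", invalid="ignore"):
            out = num * scale / den
        zero = den == 0
        if zero.any():
            logger.warning("zero denominator in %d row(s); value left missing",
                           int(zero.sum()))
        return out.where(~zero)

    fert_den = "n_mature" if rate_denominator == "mature" else "n_cocs"
    derived = {
        "osi": ratio("n_cocs", "total_fsh", 1000.0),
        "maturation_rate": ratio("n_mature", "n_cocs"),
        "fertilization_rate": ratio("n_fertilized", fert_den),
        "cleavage_rate": ratio("n_cleaved", "n_fertilized"),
    }
    for interval, (late, early) in INTERVAL_DEFS.items():
        derived[interval] = df[late] - df[early]

    for col, values in derived.items():
        present = df[col].notna() & values.notna()
        clash = present & ((df[col] - values).abs() > _INTERVAL_TOL)
        if clash.any():
            logger.warning(
                "%s: %d recorded value(s) disagree with derivation beyond 1e-6",
                col, int(clash.sum()),
            )
        df[col] = df[col].where(df[col].notna(), values)
    return CohortTable(df)


def zscore(table: CohortTable) -> CohortTable:
    """Per-feature z-score normalization, (x - mean) / sd.

    Sample standard deviation (n-1 denominator).  Missing values are
    ignored when computing moments and propagate as missing.  A constant
    feature has no spread and maps to all zeros with a warning.
    """
    df = table.df.copy()
    feats = table.features()
    for col in table.feature_names:
        x = feats[col]
        mu = x.mean()
        sd = x.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            logger.warning("feature %s is constant; z-scores set to 0", col)
            df[col] = (x - x).astype(float)  # 0 where present, NaN where missing
        else:
            df[col] = (x - mu) / sd
    # normalized view keeps insemination numeric; mark it so validation is skipped
    out = CohortTable.__new__(CohortTable)
    out.df = df.reset_index(drop=True)
    out.feature_names = table.feature_names
    out.category_map = dict(table.category_map)
    return out


def _round_half_up(x: float) -> int:
    # small epsilon guards against binary representation error
    # (e.g. 0.7 * 365 evaluating just below 255.5)
    return int(math.floor(x + 0.5 + 1e-9))


def stratified_split(
    table: CohortTable, train_frac: float, seed: int
) -> tuple[CohortTable, CohortTable]:
    """Stratified random train/test split of the cohort.

    Per class, round-half-up of ``train_frac * class count`` embryos go to
    the training side; membership within a class is uniform at random from
    ``seed``.  On 210 BL / 365 nBL at 70% this yields 147 + 256 = 403
    training and 172 test embryos.
    """
    if not 0.0 < train_frac < 1.0:
        raise ValueError("train_frac must be in (0, 1)")
    y = table.df["label"].to_numpy()
    classes = [c for c in (LABEL_POSITIVE, LABEL_NEGATIVE) if (y == c).any()]
    if len(classes) < 2:
        raise ValueError("stratified split needs both outcome classes present")
    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    for cls in classes:
        idx = np.flatnonzero(y == cls)
        if idx.size < 2:
            raise ValueError(f"class {cls} has fewer than 2 members")
        n_train = _round_half_up(train_frac * idx.size)
        chosen = rng.choice(idx, size=n_train, replace=False)
        train_idx.extend(chosen.tolist())
    mask = np.zeros(len(table), dtype=bool)
    mask[train_idx] = True
    return table.subset(np.flatnonzero(mask)), table.subset(np.flatnonzero(~mask))
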