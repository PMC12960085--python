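"""Participant cohort tables.

A cohort is one row per participant carrying the six predictors of the
oxygen-cost-of-ventilation model — peak expired ventilation (V̇E, L·min⁻¹,
STPD), age (years), weight (kg), height (cm), V̇O2 peak (L·min⁻¹) and
maximal heart rate (beats·min⁻¹) — plus, for derivation cohorts, the
measured oxygen cost of ventilation (V̇O2VENT, L·min⁻¹) obtained from
ventilation-mimicking trials.

Two reference tables ship with the package: the 42-participant derivation
cohort (:func:`derivation_cohort`) used to fit and validate the model, and
the 14-cyclist application summary (:func:`application_table`) with measured
V̇O2max, predicted V̇O2VENT and its percentage of V̇O2max.
"""

from __future__ import annotations

import dataclasses
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd

from .exceptions import (
    CohortValidationError,
    DomainError,
    InsufficientDataError,
    ParseError,
    SchemaError,
)

__all__ = [
    "ParticipantRecord",
    "CohortTable",
    "PREDICTOR_COLUMNS",
    "TABLE1_PREDICTOR_RANGES",
    "load_cohort",
    "write_cohort",
    "select_peak_trials",
    "summarize",
    "percent_of_max",
    "derivation_cohort",
    "application_table",
]

#: canonical predictor column names, in model order
PREDICTOR_COLUMNS = ("ve_peak", "age", "weight", "height", "vo2peak", "hr_max")

NUMERIC_COLUMNS = PREDICTOR_COLUMNS + ("vo2vent_measured",)

#: observed predictor ranges of the packaged derivation cohort; used as the
#: default extrapolation guard when evaluating fitted relationships.
TABLE1_PREDICTOR_RANGES = {
    "ve_peak": (57.71, 189.87),
    "age": (20.0, 44.0),
    "weight": (38.1, 94.6),
    "height": (152.0, 195.7),
    "vo2peak": (1.82, 6.5328),
    "hr_max": (158.0, 197.0),
}

# accepted header aliases (lower-cased, stripped) -> canonical name
_DEFAULT_ALIASES = {
    "participant": "subject_id",
    "subject": "subject_id",
    "id": "subject_id",
    "ventilation": "ve_peak",
    "ve": "ve_peak",
    "age (years)": "age",
    "weight (kg)": "weight",
    "height (cm)": "height",
    "vo2 peak": "vo2peak",
    "vo2max": "vo2peak",
    "maxhr": "hr_max",
    "maxhr (bpm)": "hr_max",
    "hrmax": "hr_max",
    "vo2vent": "vo2vent_measured",
}

# (low, high) inclusive physiological bounds per column
_BOUNDS = {
    "ve_peak": (np.nextafter(0.0, 1.0), np.inf),
    "age": (10.0, 100.0),
    "weight": (30.0, 200.0),
    "height": (120.0, 230.0),
    "vo2peak": (np.nextafter(0.0, 1.0), np.inf),
    "hr_max": (60.0, 230.0),
}


@dataclasses.dataclass(frozen=True)
class ParticipantRecord:
    """One subject's predictors plus the optional measured V̇O2VENT."""

    subject_id: str
    ve_peak: float
    age: float
    weight: float
    height: float
    vo2peak: float
    hr_max: float
    vo2vent_measured: float | None = None
    sex: str = "unknown"

    def __post_init__(self) -> None:
        msgs = _row_violations(dataclasses.asdict(self))
        if msgs:
            raise CohortValidationError(msgs)

    def predictors(self) -> np.ndarray:
        """Predictor values in canonical model order."""
        return np.array([getattr(self, c) for c in PREDICTOR_COLUMNS], dtype=float)


def _row_violations(row: Mapping, label: str | None = None) -> list[str]:
    where = f"row {label}: " if label is not None else ""
    msgs = []
    for col, (lo, hi) in _BOUNDS.items():
        v = row.get(col)
        if v is None or not np.isfinite(v) or not (lo <= v <= hi):
            msgs.append(f"{where}{col}={v!r} outside [{lo:g}, {hi:g}]")
    v = row.get("vo2vent_measured")
    if v is not None and not (isinstance(v, float) and np.isnan(v)):
        vo2peak = row.get("vo2peak", np.nan)
        if not (0.0 < v < vo2peak):
            msgs.append(
                f"{where}vo2vent_measured={v!r} not in (0, vo2peak={vo2peak!r})"
            )
    return msgs


@dataclasses.dataclass
class CohortTable:
    """Ordered participant table plus the gas-volume condition of its V̇E column.

    The underlying :class:`pandas.DataFrame` always carries the canonical
    columns ``subject_id``, the six predictors, ``vo2vent_measured`` (possibly
    all-NaN) and ``sex``. Model fitting requires ``volume_condition == "STPD"``.
    """

    df: pd.DataFrame
    volume_condition: str = "STPD"

    def __len__(self) -> int:
        return len(self.df)

    def __post_init__(self) -> None:
        if self.volume_condition not in ("STPD", "BTPS"):
            raise SchemaError(f"unknown volume_condition {self.volume_condition!r}")

    @property
    def records(self) -> list[ParticipantRecord]:
        out = []
        for _, r in self.df.iterrows():
            v = r.get("vo2vent_measured")
            out.append(
                ParticipantRecord(
                    subject_id=str(r["subject_id"]),
                    ve_peak=float(r["ve_peak"]),
                    age=float(r["age"]),
                    weight=float(r["weight"]),
                    height=float(r["height"]),
                    vo2peak=float(r["vo2peak"]),
                    hr_max=float(r["hr_max"]),
                    vo2vent_measured=None if pd.isna(v) else float(v),
                    sex=str(r.get("sex", "unknown")),
                )
            )
        return out

    def predictors(self) -> np.ndarray:
        """(n, 6) predictor matrix in canonical order."""
        return self.df.loc[:, list(PREDICTOR_COLUMNS)].to_numpy(dtype=float)

    def measured(self) -> np.ndarray:
        return self.df["vo2vent_measured"].to_numpy(dtype=float)

    def require_stpd(self) -> None:
        if self.volume_condition != "STPD":
            from .exceptions import UnitsError

            raise UnitsError(
                "cohort V̇E is tagged BTPS; convert with gas_volume.btps_to_stpd first"
            )


def _canonicalize_columns(df: pd.DataFrame, schema: Mapping[str, str] | None) -> pd.DataFrame:
    rename: dict[str, str] = {}
    mapping = dict(schema) if schema else {}
    for col in df.columns:
        if col in mapping:
            rename[col] = mapping[col]
        else:
            key = str(col).strip().lower()
            rename[col] = _DEFAULT_ALIASES.get(key, key)
    return df.rename(columns=rename)


def load_cohort(
    path,
    schema: Mapping[str, str] | None = None,
    *,
    volume_condition: str = "STPD",
) -> CohortTable:
    """Read a delimited cohort file (comma default, tab accepted) and validate it.

    Parameters
    ----------
    path
        Delimited-text file; the header row is mapped onto the canonical
        column names through `schema` (original header -> canonical name)
        or, failing that, a small built-in alias table.
    schema
        Optional explicit column map for files whose headers do not match
        the defaults.
    volume_condition
        ``"STPD"`` (default) or ``"BTPS"`` tag for the V̇E column.

    Raises
    ------
    SchemaError
        Missing required column or unreadable/empty file.
    ParseError
        A mapped cell does not parse as a number (row and column named).
    CohortValidationError
        Rows violating the physiological invariants, with row-indexed messages.
    """
    import csv

    try:
        raw = pd.read_csv(path, sep=None, engine="python", dtype=str, skipinitialspace=True)
    except (pd.errors.EmptyDataError, pd.errors.ParserError, csv.Error) as exc:
        raise SchemaError(f"cannot read cohort file {path}: {exc}") from exc
    df = _canonicalize_columns(raw, schema)

    required = ("subject_id",) + PREDICTOR_COLUMNS
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"missing column(s) {missing} in {path}")

    numeric_present = [c for c in NUMERIC_COLUMNS if c in df.columns]
    for col in numeric_present:
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = parsed.isna() & df[col].notna() & (df[col].str.strip() != "")
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise ParseError(
                f"non-numeric value {df[col].iloc[i]!r} in column {col!r}, row {i}"
            )
        df[col] = parsed
    if "vo2vent_measured" not in df.columns:
        df["vo2vent_measured"] = np.nan
    if "sex" not in df.columns:
        df["sex"] = "unknown"

    msgs: list[str] = []
    for i, (_, row) in enumerate(df.iterrows()):
        d = {c: (None if pd.isna(row[c]) else float(row[c])) for c in NUMERIC_COLUMNS}
        msgs.extend(_row_violations(d, label=str(i)))
    if msgs:
        raise CohortValidationError(msgs)

    keep = ["subject_id"] + list(NUMERIC_COLUMNS) + ["sex"]
    df = df.loc[:, keep].reset_index(drop=True)
    df["subject_id"] = df["subject_id"].astype(str)
    return CohortTable(df=df, volume_condition=volume_condition)


def write_cohort(cohort: CohortTable, path, *, sep: str = ",") -> None:
    """Write a cohort back to delimited text; numeric fields keep full precision."""
    cohort.df.to_csv(path, sep=sep, index=False)


def select_peak_trials(raw: CohortTable) -> CohortTable:
    """Reduce to one row per subject: the trial with the highest measured V̇O2VENT.

    Ties on V̇O2VENT are broken by the higher peak V̇E, then by first
    occurrence. Already-unique input is returned unchanged (idempotent).
    """
    df = raw.df.copy()
    order = np.arange(len(df))
    df["_order"] = order
    key = df["vo2vent_measured"].fillna(-np.inf)
    df["_key"] = key
    df = df.sort_values(
        ["_key", "ve_peak", "_order"], ascending=[False, False, True], kind="stable"
    )
    df = df.drop_duplicates("subject_id", keep="first")
    df = df.sort_values("_order").drop(columns=["_order", "_key"]).reset_index(drop=True)
    return CohortTable(df=df, volume_condition=raw.volume_condition)


def summarize(cohort: CohortTable) -> pd.DataFrame:
    """Per-column mean and sample (n−1) standard deviation.

    Returns a two-row frame indexed ``["mean", "sd"]`` over the numeric
    columns present; raises :class:`InsufficientDataError` for n < 2.
    """
    if len(cohort) < 2:
        raise InsufficientDataError("summarize needs at least 2 records")
    num = cohort.df.loc[:, [c for c in NUMERIC_COLUMNS if c in cohort.df.columns]]
    return pd.DataFrame({"mean": num.mean(), "sd": num.std(ddof=1)}).T


def percent_of_max(part, whole):
    """100 · part / whole, e.g. V̇O2VENT as a percentage of V̇O2max.

    Accepts scalars or arrays; requires ``whole > 0`` and ``part >= 0``.
    """
    part = np.asarray(part, dtype=float)
    whole = np.asarray(whole, dtype=float)
    if np.any(whole <= 0):
        raise DomainError("percent_of_max requires whole > 0")
    if np.any(part < 0):
        raise DomainError("percent_of_max requires part >= 0")
    out = 100.0 * part / whole
    return float(out) if out.ndim == 0 else out


def _data_path(name: str):
    return resources.files("ventcost.data").joinpath(name)


def derivation_cohort() -> CohortTable:
    """The packaged 42-participant derivation cohort (one peak V̇O2VENT per subject)."""
    with resources.as_file(_data_path("table1_derivation.csv")) as p:
        return load_cohort(p)


def application_table() -> pd.DataFrame:
    """The packaged 14-cyclist application summary.

    Columns: ``subject_id``, ``sex``, ``vo2max`` (L·min⁻¹), ``vo2vent``
    (predicted oxygen cost of ventilation at V̇O2max, L·min⁻¹) and
    ``percent_of_vo2max``.
    """
    with resources.as_file(_data_path("table2_application.csv")) as p:
        return pd.read_csv(p)
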