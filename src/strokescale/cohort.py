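"""Patient records, derived outcome variables, and cohort table I/O.

The unit of analysis is an acute ischemic-stroke admission observed on day 1
and day 3 after onset, with a 90-day Barthel Index (BI) follow-up.  A cohort
is an ordered collection of :class:`PatientRecord` sharing one symptom panel:
a fixed, ordered list of binary clinician-recorded symptoms & signs (anxiety,
irritability, tinnitus, circumrotating, ...) assessed on both days.

Three derived variables drive everything downstream:

* the dichotomous 90-day outcome — *good* recovery iff BI >= 90;
* the early NIHSS change, ``nihss_day3 - nihss_day1`` (negative = improvement);
* the ternary symptom change status between day 1 and day 3 —
  ``appear`` (absent -> present), ``disappear`` (present -> absent),
  ``keep`` (state unchanged, whether present-present or absent-absent).

Cohorts are stored as plain UTF-8 CSV with one header row; see
:func:`read_cohort` for the column contract.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import CohortLoadError, CohortValidationError

__all__ = [
    "Outcome",
    "ChangeStatus",
    "PatientRecord",
    "CohortTable",
    "HISTORY_FLAGS",
    "derive_outcome",
    "derive_delta_nihss",
    "derive_change_status",
    "read_cohort",
    "write_cohort",
]

#: Medical-history flags carried by every record, in file-column order.
HISTORY_FLAGS: tuple[str, ...] = ("hypertension", "stroke", "chd", "dm", "af")

#: BI threshold defining good 90-day recovery (near full functional independence).
GOOD_RECOVERY_BI: int = 90

#: Maximum onset-to-admission delay admitted by the inclusion criteria, hours.
MAX_ONSET_HOURS: float = 24.0


class Outcome(str, enum.Enum):
    """Dichotomous 90-day recovery outcome."""

    GOOD = "good"
    POOR = "poor"


class ChangeStatus(str, enum.Enum):
    """Ternary day-1 -> day-3 change of a binary symptom."""

    APPEAR = "appear"
    KEEP = "keep"
    DISAPPEAR = "disappear"


def derive_outcome(bi_day90: int) -> Outcome:
    """Dichotomize the day-90 Barthel Index: good recovery iff BI >= 90.

    Parameters
    ----------
    bi_day90:
        Barthel Index on day 90, integer in [0, 100].

    Raises
    ------
    CohortValidationError
        If the BI is outside [0, 100].
    """
    if not 0 <= bi_day90 <= 100:
        raise CohortValidationError(f"bi_day90 must be in [0, 100], got {bi_day90}")
    return Outcome.GOOD if bi_day90 >= GOOD_RECOVERY_BI else Outcome.POOR


def derive_delta_nihss(nihss_day1: int, nihss_day3: int) -> int:
    """Early NIHSS change, day 3 minus day 1 (negative values = improvement)."""
    for name, v in (("nihss_day1", nihss_day1), ("nihss_day3", nihss_day3)):
        if not 0 <= v <= 42:
            raise CohortValidationError(f"{name} must be in [0, 42], got {v}")
    return nihss_day3 - nihss_day1


def derive_change_status(present_day1: bool, present_day3: bool) -> ChangeStatus:
    """Ternary change coding of a symptom between day 1 and day 3.

    ``(True, False) -> disappear``, ``(False, True) -> appear``; both
    unchanged states — present on both days or absent on both days — map to
    ``keep``.  Whether an absent-absent ``keep`` earns the keep points on the
    two change items of the scale is a scoring-policy question, not a coding
    one; see :func:`strokescale.scale.score_patient`.
    """
    if present_day1 and not present_day3:
        return ChangeStatus.DISAPPEAR
    if not present_day1 and present_day3:
        return ChangeStatus.APPEAR
    return ChangeStatus.KEEP


@dataclass(frozen=True)
class PatientRecord:
    """One admitted patient with day-1/day-3 observations and 90-day BI.

    Attributes
    ----------
    id:
        Opaque unique identifier.
    age:
        Age in years, positive.
    sex:
        ``"male"`` or ``"female"``.
    history:
        Medical-history flags keyed by :data:`HISTORY_FLAGS`.
    onset_to_admission:
        Hours from symptom onset to hospital arrival, in [0, 24] per the
        inclusion criteria.
    nihss_day1, nihss_day3:
        NIHSS total scores, integers in [0, 42].
    symptoms_day1, symptoms_day3:
        Presence/absence of each panel symptom; both maps share one key set.
    bi_day90:
        Barthel Index on day 90, integer in [0, 100].
    """

    id: str
    age: float
    sex: str
    history: Mapping[str, bool]
    onset_to_admission: float
    nihss_day1: int
    nihss_day3: int
    symptoms_day1: Mapping[str, bool]
    symptoms_day3: Mapping[str, bool]
    bi_day90: int

    def __post_init__(self) -> None:
        if not self.id:
            raise CohortValidationError("record id must be a nonempty string")
        if not self.age > 0:
            raise CohortValidationError(f"age must be positive, got {self.age}")
        if self.sex not in ("male", "female"):
            raise CohortValidationError(f"sex must be 'male' or 'female', got {self.sex!r}")
        missing = set(HISTORY_FLAGS) - set(self.history)
        if missing:
            raise CohortValidationError(f"history missing flags: {sorted(missing)}")
        if not 0 <= self.onset_to_admission <= MAX_ONSET_HOURS:
            raise CohortValidationError(
                f"onset_to_admission must be in [0, {MAX_ONSET_HOURS}] hours, "
                f"got {self.onset_to_admission}"
            )
        for name in ("nihss_day1", "nihss_day3"):
            v = getattr(self, name)
            if not (isinstance(v, (int,)) and 0 <= v <= 42):
                raise CohortValidationError(f"{name} must be an integer in [0, 42], got {v!r}")
        if not (isinstance(self.bi_day90, int) and 0 <= self.bi_day90 <= 100):
            raise CohortValidationError(
                f"bi_day90 must be an integer in [0, 100], got {self.bi_day90!r}"
            )
        if set(self.symptoms_day1) != set(self.symptoms_day3):
            raise CohortValidationError(
                f"record {self.id}: symptoms_day1 and symptoms_day3 key sets differ"
            )

    # -- derived views ----------------------------------------------------

    @property
    def outcome(self) -> Outcome:
        return derive_outcome(self.bi_day90)

    @property
    def delta_nihss(self) -> int:
        return derive_delta_nihss(self.nihss_day1, self.nihss_day3)

    def change_status(self, symptom: str) -> ChangeStatus:
        """Day-1 -> day-3 change status of one panel symptom."""
        try:
            d1 = self.symptoms_day1[symptom]
            d3 = self.symptoms_day3[symptom]
        except KeyError as exc:
            raise CohortValidationError(
                f"record {self.id}: symptom {symptom!r} not in panel"
            ) from exc
        return derive_change_status(d1, d3)


@dataclass(frozen=True)
class CohortTable:
    """An ordered cohort of validated records over a fixed symptom panel."""

    records: tuple[PatientRecord, ...]
    panel: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))
        object.__setattr__(self, "panel", tuple(self.panel))
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise CohortValidationError(f"duplicate record ids: {dupes}")
        panel_set = set(self.panel)
        if len(panel_set) != len(self.panel):
            raise CohortValidationError("panel contains duplicate symptom names")
        for r in self.records:
            if set(r.symptoms_day1) != panel_set:
                raise CohortValidationError(
                    f"record {r.id}: symptom map does not cover the panel exactly"
                )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def outcomes(self) -> list[Outcome]:
        return [r.outcome for r in self.records]


# -- file I/O ------------------------------------------------------------

_FIXED_COLUMNS = [
    "id", "age", "sex",
    "hx_hypertension", "hx_stroke", "hx_chd", "hx_dm", "hx_af",
    "onset_hours", "nihss_d1", "nihss_d3", "bi_d90",
]


def _panel_columns(panel: Sequence[str]) -> list[str]:
    cols: list[str] = []
    for name in panel:
        cols.append(f"sym_{name}_d1")
        cols.append(f"sym_{name}_d3")
    return cols


def _parse_bool(value, row: int, column: str) -> bool:
    if value in (0, 1):
        return bool(value)
    if isinstance(value, str) and value.strip() in ("0", "1"):
        return value.strip() == "1"
    raise CohortLoadError(f"row {row}, column {column!r}: expected 0/1, got {value!r}")


def read_cohort(path, panel: Sequence[str] | None = None) -> CohortTable:
    """Read a cohort CSV into a validated :class:`CohortTable`.

    The file must carry one header row with the fixed columns
    ``id, age, sex, hx_hypertension, hx_stroke, hx_chd, hx_dm, hx_af,
    onset_hours, nihss_d1, nihss_d3, bi_d90`` followed by a
    ``sym_<name>_d1`` / ``sym_<name>_d3`` 0/1 pair per panel symptom.
    Row order is preserved.

    Parameters
    ----------
    path:
        CSV file path.
    panel:
        Expected symptom panel.  If ``None``, the panel is inferred from the
        ``sym_*_d1`` columns in file order.

    Raises
    ------
    CohortLoadError
        Missing column, unparseable cell, or duplicate id — the message
        names the offending row/column.
    """
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise CohortLoadError(f"could not read {path}: {exc}") from exc

    missing = [c for c in _FIXED_COLUMNS if c not in df.columns]
    if missing:
        raise CohortLoadError(f"missing required column(s): {missing}")

    if panel is None:
        panel = [c[len("sym_"):-len("_d1")] for c in df.columns
                 if c.startswith("sym_") and c.endswith("_d1")]
    panel = list(panel)
    missing_sym = [c for c in _panel_columns(panel) if c not in df.columns]
    if missing_sym:
        raise CohortLoadError(f"missing symptom column(s): {missing_sym}")

    def cell(row_idx: int, col: str, caster, kind: str):
        raw = df.at[row_idx, col]
        try:
            return caster(raw)
        except (TypeError, ValueError) as exc:
            raise CohortLoadError(
                f"row {row_idx}, column {col!r}: expected {kind}, got {raw!r}"
            ) from exc

    records: list[PatientRecord] = []
    for i in range(len(df)):
        try:
            rec = PatientRecord(
                id=str(df.at[i, "id"]),
                age=cell(i, "age", float, "number"),
                sex=str(df.at[i, "sex"]),
                history={
                    flag: _parse_bool(df.at[i, f"hx_{flag}"], i, f"hx_{flag}")
                    for flag in HISTORY_FLAGS
                },
                onset_to_admission=cell(i, "onset_hours", float, "number"),
                nihss_day1=cell(i, "nihss_d1", int, "integer"),
                nihss_day3=cell(i, "nihss_d3", int, "integer"),
                symptoms_day1={
                    s: _parse_bool(df.at[i, f"sym_{s}_d1"], i, f"sym_{s}_d1") for s in panel
                },
                symptoms_day3={
                    s: _parse_bool(df.at[i, f"sym_{s}_d3"], i, f"sym_{s}_d3") for s in panel
                },
                bi_day90=cell(i, "bi_d90", int, "integer"),
            )
        except CohortValidationError as exc:
            raise CohortLoadError(f"row {i}: {exc}") from exc
        records.append(rec)

    try:
        return CohortTable(records=tuple(records), panel=tuple(panel))
    except CohortValidationError as exc:
        raise CohortLoadError(str(exc)) from exc


def cohort_to_frame(cohort: CohortTable) -> pd.DataFrame:
    """Flatten a cohort into the canonical wide DataFrame layout."""
    rows = []
    for r in cohort.records:
        row: dict[str, object] = {
            "id": r.id,
            "age": r.age,
            "sex": r.sex,
            **{f"hx_{flag}": int(r.history[flag]) for flag in HISTORY_FLAGS},
            "onset_hours": r.onset_to_admission,
            "nihss_d1": r.nihss_day1,
            "nihss_d3": r.nihss_day3,
            "bi_d90": r.bi_day90,
        }
        for s in cohort.panel:
            row[f"sym_{s}_d1"] = int(r.symptoms_day1[s])
            row[f"sym_{s}_d3"] = int(r.symptoms_day3[s])
        rows.append(row)
    columns = _FIXED_COLUMNS + _panel_columns(cohort.panel)
    return pd.DataFrame(rows, columns=columns)


def write_cohort(cohort: CohortTable, path) -> None:
    """Write a cohort as CSV; ``read_cohort`` of the result is the identity."""
    cohort_to_frame(cohort).to_csv(path, index=False)
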