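"""The 8-item prognostic scale: item definitions, scoring, classification.

The published instrument assigns half-point-granular points to eight items —
age degree, history of diabetes, day-1 anxiety, day-1 NIHSS degree, day-1
irritability, early NIHSS change, and the day-1 -> day-3 change of
circumrotating and of tinnitus — sums them into a total in [0, 16.5], and
predicts poor 90-day recovery when the total is strictly greater than the
cutoff (9.5 by default).

Each :class:`ScaleItem` couples a *feature* (what to read off the patient
record), a *rule* (how to categorize that feature) and a *points* vector
(what each category scores).  Three rule kinds cover the instrument:

``thresholds``
    Continuous value binned into half-open intervals ``(-inf, t1], (t1, t2],
    ..., (tk, inf)`` so printed "<=" boundaries are honoured.
``flag``
    Boolean feature; category 0 = absent, 1 = present.
``change``
    Ternary symptom change; categories 0/1/2 = disappear/keep/appear.

The one genuinely underdetermined scoring question is how a symptom absent on
*both* days scores on the two change items: the literal reading scores it as
"keep" (the default), the alternative scores it 0.  Both policies are
available via ``absent_pair_policy``.
"""

from __future__ import annotations

import itertools
import json
from bisect import bisect_left
from dataclasses import dataclass, field
from importlib import resources
from typing import Literal, Sequence

from .cohort import ChangeStatus, CohortTable, Outcome, PatientRecord
from .errors import ScaleError, ScoringError

__all__ = [
    "ScaleItem",
    "ScaleDefinition",
    "ScoreResult",
    "default_scale",
    "score_patient",
    "classify",
    "save_scale",
    "load_scale",
    "enumerate_totals",
    "category_codes",
]

AbsentPairPolicy = Literal["keep", "zero"]

#: Feature kinds an item may read from a record.
_FEATURE_KINDS = ("age", "nihss_day1", "delta_nihss", "history", "symptom_day1", "change")

#: Ordinal coding of change categories (also used by the outcome model).
CHANGE_ORDER: tuple[ChangeStatus, ...] = (
    ChangeStatus.DISAPPEAR,
    ChangeStatus.KEEP,
    ChangeStatus.APPEAR,
)


def _is_half_point(x: float) -> bool:
    return abs(x * 2 - round(x * 2)) < 1e-9


@dataclass(frozen=True)
class ScaleItem:
    """One scored item of the scale.

    ``points[k]`` is the score of category ``k``; the item weight satisfies
    ``max(points) == weight * (len(points) - 1)``, the weight-times-level
    scheme of the published table.
    """

    name: str
    weight: float
    feature: str           # one of _FEATURE_KINDS
    key: str | None = None  # history flag or symptom name, where applicable
    thresholds: tuple[float, ...] = ()
    points: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "thresholds", tuple(self.thresholds))
        object.__setattr__(self, "points", tuple(float(p) for p in self.points))
        if self.feature not in _FEATURE_KINDS:
            raise ScaleError(f"item {self.name!r}: unknown feature {self.feature!r}")
        if not self.points:
            raise ScaleError(f"item {self.name!r}: empty points list")
        if self.weight < 0 or any(p < 0 for p in self.points):
            raise ScaleError(f"item {self.name!r}: weight and points must be nonnegative")
        if not all(_is_half_point(p) for p in self.points):
            raise ScaleError(f"item {self.name!r}: points must be multiples of 0.5")
        n_cat = self._n_categories()
        if len(self.points) != n_cat:
            raise ScaleError(
                f"item {self.name!r}: {len(self.points)} points for {n_cat} categories"
            )
        expected_max = self.weight * (n_cat - 1)
        if abs(max(self.points) - expected_max) > 1e-9:
            raise ScaleError(
                f"item {self.name!r}: max points {max(self.points)} != "
                f"weight x top level {expected_max}"
            )
        if list(self.thresholds) != sorted(set(self.thresholds)):
            raise ScaleError(f"item {self.name!r}: thresholds must be strictly increasing")
        if self.feature in ("history", "symptom_day1", "change") and not self.key:
            raise ScaleError(f"item {self.name!r}: feature {self.feature!r} needs a key")

    def _n_categories(self) -> int:
        if self.feature in ("age", "nihss_day1", "delta_nihss"):
            return len(self.thresholds) + 1
        if self.feature in ("history", "symptom_day1"):
            return 2
        return 3  # change: disappear / keep / appear

    def categorize(self, record: PatientRecord) -> int:
        """Category index of ``record`` under this item's rule."""
        try:
            if self.feature == "age":
                return bisect_left(self.thresholds, record.age)
            if self.feature == "nihss_day1":
                return bisect_left(self.thresholds, record.nihss_day1)
            if self.feature == "delta_nihss":
                return bisect_left(self.thresholds, record.delta_nihss)
            if self.feature == "history":
                return int(record.history[self.key])
            if self.feature == "symptom_day1":
                return int(record.symptoms_day1[self.key])
            # change
            return CHANGE_ORDER.index(record.change_status(self.key))
        except KeyError as exc:
            raise ScoringError(
                f"item {self.name!r}: record {record.id} lacks feature "
                f"{self.feature}:{self.key}"
            ) from exc


@dataclass(frozen=True)
class ScaleDefinition:
    """An ordered set of scale items plus the decision cutoff."""

    items: tuple[ScaleItem, ...]
    cutoff: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "items", tuple(self.items))
        if len({it.name for it in self.items}) != len(self.items):
            raise ScaleError("duplicate item names in scale")
        if not self.items:
            raise ScaleError("scale must have at least one item")
        if not 0 < self.cutoff < self.max_total:
            raise ScaleError(
                f"cutoff {self.cutoff} must lie strictly inside (0, {self.max_total})"
            )

    @property
    def max_total(self) -> float:
        return sum(max(it.points) for it in self.items)


@dataclass(frozen=True)
class ScoreResult:
    """Per-item points, their sum, and the cutoff classification."""

    per_item: dict[str, float]
    total: float
    label: Outcome


def default_scale() -> ScaleDefinition:
    """The published 8-item scale (max total 16.5, cutoff 9.5).

    Point maps: age <=56.44 -> 0, >56.44 -> 1; diabetes history no/yes ->
    0/1; day-1 anxiety no/yes -> 0/1; day-1 NIHSS <=2 -> 0, 3-6 -> 1,
    >=7 -> 2; day-1 irritability no/yes -> 0/1.5; NIHSS change <=-1 -> 0,
    >-1 -> 1; circumrotating change disappear/keep/appear -> 0/2/4; tinnitus
    change disappear/keep/appear -> 0/2.5/5.
    """
    items = (
        ScaleItem("age_degree", 1.0, "age", thresholds=(56.44,), points=(0, 1)),
        ScaleItem("history_dm", 1.0, "history", key="dm", points=(0, 1)),
        ScaleItem("anxiety_day1", 1.0, "symptom_day1", key="anxiety", points=(0, 1)),
        ScaleItem("nihss_degree_day1", 1.0, "nihss_day1", thresholds=(2, 6), points=(0, 1, 2)),
        ScaleItem("irritability_day1", 1.5, "symptom_day1", key="irritability",
                  points=(0, 1.5)),
        ScaleItem("delta_nihss_degree", 1.0, "delta_nihss", thresholds=(-1,), points=(0, 1)),
        ScaleItem("circumrotating_change", 2.0, "change", key="circumrotating",
                  points=(0, 2, 4)),
        ScaleItem("tinnitus_change", 2.5, "change", key="tinnitus", points=(0, 2.5, 5)),
    )
    return ScaleDefinition(items=items, cutoff=9.5)


def classify(total: float, cutoff: float) -> Outcome:
    """Predict poor recovery iff the total is *strictly* greater than the cutoff."""
    return Outcome.POOR if total > cutoff else Outcome.GOOD


def score_patient(
    scale: ScaleDefinition,
    record: PatientRecord,
    absent_pair_policy: AbsentPairPolicy = "keep",
) -> ScoreResult:
    """Apply the scale to one record.

    With ``absent_pair_policy="keep"`` (the literal reading of the published
    point maps) a symptom absent on both days falls in the "keep" category of
    its change item and earns the keep points; with ``"zero"`` it scores 0.
    """
    per_item: dict[str, float] = {}
    for item in scale.items:
        if (
            item.feature == "change"
            and absent_pair_policy == "zero"
            and not record.symptoms_day1.get(item.key, False)
            and not record.symptoms_day3.get(item.key, False)
        ):
            per_item[item.name] = 0.0
            continue
        per_item[item.name] = item.points[item.categorize(record)]
    total = sum(per_item.values())
    return ScoreResult(per_item=per_item, total=total, label=classify(total, scale.cutoff))


def enumerate_totals(scale: ScaleDefinition) -> list[float]:
    """Total score of every item-category combination (brute force).

    The length is the product of the per-item category counts; for the
    default scale that is 2*2*2*3*2*2*3*3 = 864 combinations.
    """
    return [sum(combo) for combo in itertools.product(*(it.points for it in scale.items))]


def category_codes(
    scale: ScaleDefinition,
    record: PatientRecord,
    absent_pair_policy: AbsentPairPolicy = "keep",
) -> dict[str, int]:
    """Category index of each item for one record (the model's ordinal coding).

    Change items use disappear/keep/appear = 0/1/2; under the ``"zero"``
    policy an absent-on-both-days symptom codes 0.
    """
    codes: dict[str, int] = {}
    for item in scale.items:
        if (
            item.feature == "change"
            and absent_pair_policy == "zero"
            and not record.symptoms_day1.get(item.key, False)
            and not record.symptoms_day3.get(item.key, False)
        ):
            codes[item.name] = 0
            continue
        codes[item.name] = item.categorize(record)
    return codes


# -- persistence ---------------------------------------------------------

def _item_to_dict(item: ScaleItem) -> dict:
    d: dict = {
        "name": item.name,
        "weight": item.weight,
        "feature": item.feature,
        "points": list(item.points),
    }
    if item.key is not None:
        d["key"] = item.key
    if item.thresholds:
        d["thresholds"] = list(item.thresholds)
    return d


def save_scale(scale: ScaleDefinition, path) -> None:
    """Serialize a scale definition to JSON."""
    payload = {
        "items": [_item_to_dict(it) for it in scale.items],
        "cutoff": scale.cutoff,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")


def _scale_from_payload(payload: dict, strict: bool) -> ScaleDefinition:
    try:
        items = tuple(
            ScaleItem(
                name=d["name"],
                weight=float(d["weight"]),
                feature=d["feature"],
                key=d.get("key"),
                thresholds=tuple(d.get("thresholds", ())),
                points=tuple(d["points"]),
            )
            for d in payload["items"]
        )
        cutoff = float(payload["cutoff"])
    except (KeyError, TypeError, ValueError) as exc:
        raise ScaleError(f"malformed scale definition: {exc}") from exc
    if strict and len(items) != 8:
        raise ScaleError(f"strict mode expects the 8-item scale, got {len(items)} items")
    return ScaleDefinition(items=items, cutoff=cutoff)


def load_scale(path, strict: bool = True) -> ScaleDefinition:
    """Load a JSON scale definition; ``strict`` enforces the 8-item structure."""
    with open(path, encoding="utf-8") as fh:
        try:
            payload = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ScaleError(f"malformed scale definition file {path}: {exc}") from exc
    return _scale_from_payload(payload, strict=strict)


def packaged_default_scale() -> ScaleDefinition:
    """The shipped ``data/default_scale.json``, parsed strictly."""
    text = resources.files("strokescale").joinpath("data/default_scale.json").read_text()
    return _scale_from_payload(json.loads(text), strict=True)
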