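"""Declarative point-score engine plus ISS/NISS from AIS item lists.

One schema expresses the trauma-bay scores compared in this package:

* **categorical-bin items** — a numeric parameter mapped through ordered,
  disjoint bins (with explicit bound closure) to points; this covers GAP's
  GCS/age/SBP items and all six mREMS items;
* **any-of indicator groups** — a list of dichotomous predicates awarding a
  fixed number of points if any one holds; this covers the four AdHOC
  aspects (and generalizes their any-parameter-positive rule).

Definitions are loaded from YAML; ``adhoc``, ``gap`` and ``mrems`` ship with
the package.  The GAP and mREMS point tables are transcribed from their
original publications (Kondo et al. 2011; Miller et al. 2017 — mREMS swaps
systolic blood pressure for the mean arterial pressure of the original
REMS); this package validates them against their published score ranges
(GAP 3-24, mREMS 0-26).

Missing data are handled per the definition's ``missing_policy``:
``zero_points`` awards 0 for an unobserved item and clears the completeness
flag; ``propagate_indeterminate`` makes the whole total NaN instead.
"""

from __future__ import annotations

import itertools
import math
from importlib import resources
from pathlib import Path
from typing import Annotated, Iterable, Literal, Optional, Union

import yaml
from pydantic import BaseModel, Field, model_validator

from .records import (
    _CATEGORY_FIELDS,
    AisItem,
    PatientRecord,
)

BUNDLED_DEFINITIONS = ("adhoc", "gap", "mrems")


class ScoreDefinitionError(ValueError):
    """Invalid score definition or record value outside a declared domain."""


# ---------------------------------------------------------------------------
# schema


class PredicateSpec(BaseModel):
    parameter: str
    op: Literal["<", ">", "<=", ">=", "is_true", "in"]
    value: object = None
    requires: Optional[str] = None


class BinSpec(BaseModel):
    lower: float
    upper: float
    points: float
    lower_closed: bool = True
    upper_closed: bool = False

    @model_validator(mode="after")
    def _ordered(self) -> "BinSpec":
        if self.lower > self.upper:
            raise ValueError(f"bin bounds out of order: [{self.lower}, {self.upper}]")
        if self.lower == self.upper and not (self.lower_closed and self.upper_closed):
            raise ValueError("a degenerate single-value bin must be closed on both sides")
        return self

    def contains(self, v: float) -> bool:
        lo = v >= self.lower if self.lower_closed else v > self.lower
        hi = v <= self.upper if self.upper_closed else v < self.upper
        return lo and hi


class BinsItemSpec(BaseModel):
    kind: Literal["bins"] = "bins"
    parameter: str
    bins: list[BinSpec] = Field(min_length=1)

    @model_validator(mode="after")
    def _contiguous(self) -> "BinsItemSpec":
        """Bins must be ordered, disjoint and contiguous over the domain they
        declare (the span from the first bin's lower to the last bin's upper
        bound)."""
        ordered = sorted(self.bins, key=lambda b: (b.lower, b.upper))
        for a, b in itertools.pairwise(ordered):
            if a.upper != b.lower:
                raise ValueError(
                    f"{self.parameter}: gap or overlap between bins ending at "
                    f"{a.upper} and starting at {b.lower}")
            if a.upper_closed == b.lower_closed:
                raise ValueError(
                    f"{self.parameter}: boundary {a.upper} is "
                    f"{'claimed by both bins' if a.upper_closed else 'covered by neither bin'}")
        self.bins = ordered
        return self


class AnyOfItemSpec(BaseModel):
    kind: Literal["any_of"] = "any_of"
    name: str
    points: float = 1.0
    predicates: list[PredicateSpec] = Field(min_length=1)


ItemSpec = Annotated[Union[BinsItemSpec, AnyOfItemSpec], Field(discriminator="kind")]


class ScoreDefinition(BaseModel):
    """A declarative point score: named, ordered items, missing-data policy."""

    name: str
    missing_policy: Literal["zero_points", "propagate_indeterminate"] = "zero_points"
    items: list[ItemSpec] = Field(default_factory=list)


def load_definition(source: str | Path) -> ScoreDefinition:
    """Load a score definition from a bundled name or a YAML/JSON file path."""
    if isinstance(source, str) and source in BUNDLED_DEFINITIONS:
        text = resources.files("adhocscore.definitions").joinpath(f"{source}.yaml").read_text()
    else:
        text = Path(source).read_text()
    return ScoreDefinition.model_validate(yaml.safe_load(text))


# ---------------------------------------------------------------------------
# evaluation


def _lookup(record: PatientRecord, parameter: str) -> object:
    """Parameter value from a canonical field or, failing that, the extras
    passthrough (numeric strings coerced)."""
    if parameter in PatientRecord.__dataclass_fields__:
        return getattr(record, parameter)
    raw = record.extras.get(parameter)
    if raw is None:
        return None
    try:
        return float(raw)
    except ValueError:
        return raw


def _holds(op: str, v: object, threshold: object) -> bool:
    if op == "<":
        return v < threshold  # type: ignore[operator]
    if op == ">":
        return v > threshold  # type: ignore[operator]
    if op == "<=":
        return v <= threshold  # type: ignore[operator]
    if op == ">=":
        return v >= threshold  # type: ignore[operator]
    if op == "is_true":
        return v is True
    if op == "in":
        return v in threshold  # type: ignore[operator]
    raise ScoreDefinitionError(f"unknown comparator {op!r}")


def _evaluate_any_of(record: PatientRecord, item: AnyOfItemSpec) -> Optional[bool]:
    """True = triggered, False = observed negative, None = indeterminate."""
    observed = False
    for pred in item.predicates:
        if pred.requires is not None and _lookup(record, pred.requires) is not True:
            continue
        v = _lookup(record, pred.parameter)
        if v is None:
            continue
        observed = True
        if _holds(pred.op, v, pred.value):
            return True
    return False if observed else None


def apply_score_definition(
    record: PatientRecord, definition: ScoreDefinition
) -> tuple[float, bool]:
    """Score one record: (total points, completeness flag).

    ``complete`` is False when any item lacked an observed applicable
    parameter; under ``propagate_indeterminate`` the total is then NaN.
    """
    total = 0.0
    complete = True
    for item in definition.items:
        if isinstance(item, BinsItemSpec):
            v = _lookup(record, item.parameter)
            if v is None:
                complete = False
                continue
            if not isinstance(v, (int, float)):
                raise ScoreDefinitionError(
                    f"{definition.name}/{item.parameter}: non-numeric value {v!r}")
            for b in item.bins:
                if b.contains(float(v)):
                    total += b.points
                    break
            else:
                raise ScoreDefinitionError(
                    f"{definition.name}/{item.parameter}: value {v} outside the "
                    f"declared domain "
                    f"[{item.bins[0].lower}, {item.bins[-1].upper}]")
        else:
            state = _evaluate_any_of(record, item)
            if state is None:
                complete = False
            elif state:
                total += item.points
    if not complete and definition.missing_policy == "propagate_indeterminate":
        return math.nan, False
    return total, complete


# ---------------------------------------------------------------------------
# attainable range


def _non_trigger_value(pred: PredicateSpec) -> object:
    """A value that is observed but does not satisfy the predicate."""
    t = pred.value
    if pred.op == "<":
        return t
    if pred.op == ">":
        return t
    if pred.op == "<=":
        return t + 1  # type: ignore[operator]
    if pred.op == ">=":
        return t - 1  # type: ignore[operator]
    if pred.op == "is_true":
        return False
    if pred.op == "in":
        domain = _CATEGORY_FIELDS.get(pred.parameter)
        if domain is None:
            raise ScoreDefinitionError(
                f"no category domain known for {pred.parameter!r}")
        for cat in domain:
            if cat not in t:  # type: ignore[operator]
                return cat
        raise ScoreDefinitionError(f"{pred.parameter!r}: predicate covers its whole domain")
    raise ScoreDefinitionError(pred.op)


def _trigger_value(pred: PredicateSpec) -> object:
    t = pred.value
    if pred.op == "<":
        return t - 1  # type: ignore[operator]
    if pred.op == ">":
        return t + 1  # type: ignore[operator]
    if pred.op in ("<=", ">="):
        return t
    if pred.op == "is_true":
        return True
    if pred.op == "in":
        return t[0]  # type: ignore[index]
    raise ScoreDefinitionError(pred.op)


def _bin_representative(b: BinSpec) -> float:
    if math.isinf(b.lower) and math.isinf(b.upper):
        return 0.0
    if math.isinf(b.lower):
        return b.upper if b.upper_closed else b.upper - 1.0
    if math.isinf(b.upper):
        return b.lower if b.lower_closed else b.lower + 1.0
    if b.lower_closed:
        return b.lower
    if b.upper_closed:
        return b.upper
    return (b.lower + b.upper) / 2.0


def _item_states(item: ItemSpec) -> list[tuple[float, dict[str, object]]]:
    """(points, field assignments) for one representative per bin / per
    predicate state — the enumeration basis of the brute-force range mode."""
    if isinstance(item, BinsItemSpec):
        return [(b.points, {item.parameter: _bin_representative(b)}) for b in item.bins]
    states: list[tuple[float, dict[str, object]]] = []
    negative: dict[str, object] = {}
    for pred in item.predicates:
        negative[pred.parameter] = _non_trigger_value(pred)
        if pred.requires is not None:
            negative.setdefault(pred.requires, True)
    states.append((0.0, negative))
    for pred in item.predicates:
        assignment = dict(negative)
        assignment[pred.parameter] = _trigger_value(pred)
        if pred.requires is not None:
            assignment[pred.requires] = True
        states.append((item.points, assignment))
    return states


def _assign(record: PatientRecord, assignment: dict[str, object]) -> None:
    for name, value in assignment.items():
        if name in PatientRecord.__dataclass_fields__:
            setattr(record, name, value)
        else:
            record.extras[name] = str(value)


def score_range(
    definition: ScoreDefinition, method: str = "analytic"
) -> tuple[float, float]:
    """Exact (min, max) attainable total for fully observed inputs.

    Items are additive and independent, so the analytic mode sums per-item
    extremes.  The brute-force mode instead builds one synthetic record per
    combination of per-item representative values and pushes each through
    :func:`apply_score_definition`; it exists as an independent oracle for
    the analytic mode and for the bundled definition files.
    """
    if not definition.items:
        return 0.0, 0.0
    if method == "analytic":
        lo = hi = 0.0
        for item in definition.items:
            pts = [p for p, _ in _item_states(item)]
            lo += min(pts)
            hi += max(pts)
        return lo, hi
    if method == "brute":
        per_item = [_item_states(item) for item in definition.items]
        totals = []
        for combo in itertools.product(*per_item):
            rec = PatientRecord()
            for _, assignment in combo:
                _assign(rec, assignment)
            pts, complete = apply_score_definition(rec, definition)
            if not complete:
                raise ScoreDefinitionError(
                    f"{definition.name}: brute-force enumeration produced an "
                    "incomplete record; representative values are inconsistent")
            totals.append(pts)
        return min(totals), max(totals)
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# ISS / NISS


def _checked_severities(items: Iterable[AisItem]) -> list[AisItem]:
    # AisItem validates region/severity on construction; tuples are coerced
    return [it if isinstance(it, AisItem) else AisItem(*it) for it in items]


def iss(items: Iterable[AisItem], ais6_to_max: bool = True) -> int:
    """Injury Severity Score from AIS items.

    Sum of squared highest severities in the three most severely injured
    distinct body regions; empty list scores 0.  Under the standard
    convention (default) any unsurvivable AIS-6 injury sets the score to the
    maximum of 75.
    """
    items = _checked_severities(items)
    if not items:
        return 0
    if ais6_to_max and any(it.severity == 6 for it in items):
        return 75
    per_region: dict[str, int] = {}
    for it in items:
        per_region[it.body_region] = max(per_region.get(it.body_region, 0), it.severity)
    top3 = sorted(per_region.values(), reverse=True)[:3]
    return min(75, sum(s * s for s in top3))


def niss(items: Iterable[AisItem], ais6_to_max: bool = True) -> int:
    """New Injury Severity Score: the three highest AIS severities regardless
    of body region, squared and summed (same AIS-6 and cap conventions as
    :func:`iss`)."""
    items = _checked_severities(items)
    if not items:
        return 0
    if ais6_to_max and any(it.severity == 6 for it in items):
        return 75
    top3 = sorted((it.severity for it in items), reverse=True)[:3]
    return min(75, sum(s * s for s in top3))


__all__ = [
    "ScoreDefinition",
    "ScoreDefinitionError",
    "PredicateSpec",
    "BinSpec",
    "BinsItemSpec",
    "AnyOfItemSpec",
    "BUNDLED_DEFINITIONS",
    "load_definition",
    "apply_score_definition",
    "score_range",
    "iss",
    "niss",
    "AisItem",
]
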