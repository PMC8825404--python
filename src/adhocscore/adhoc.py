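"""The AdHOC trauma-bay score (Age, Head injury, Oxygenation, Circulation).

AdHOC is a 0-4 point score computable within ~30 minutes of trauma-bay
admission.  Each of four prognostic *aspects* groups a handful of clinical
parameters behind one dichotomous threshold apiece; the aspect scores one
point as soon as **any** of its parameters crosses its threshold.  Because
of this any-parameter-positive rule the score tolerates missing findings: a
missing GCS is irrelevant once a pupil abnormality already made the head
aspect positive.  Only an aspect with *no* observed parameter at all is
indeterminate; it contributes 0 to the total and clears the ``complete``
flag so downstream consumers can see that severity may be underestimated.

Aspects and thresholds:

==============  =====================================================
Age             age > 65 years
Head            GCS < 12; ECS motor non-specific/none; ECS pupil size
                not normal; ECS pupil reactivity not normal
Oxygenation     hemothorax present; base excess <= -6 mmol/L;
                Horowitz ratio (PaO2/FiO2) <= 200 in intubated patients
Circulation     SBP <= 90 mmHg; pRBC transfusion; INR > 1.4;
                Hb < 7 (configured unit, default g/dL)
==============  =====================================================

Boundary semantics follow the printed comparators literally: age 66 triggers
but 65 does not; GCS 11 triggers but 12 does not; base excess -6 and a
Horowitz ratio of exactly 200 trigger; INR 1.4 and Hb 7 do not.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .records import PatientRecord

RISK_CLASSES = ("stable", "borderline", "unstable")
ASPECT_NAMES = ("age", "head", "oxygenation", "circulation")


@dataclass(frozen=True)
class Predicate:
    """One dichotomized clinical parameter.

    ``op`` is one of ``<``, ``>``, ``<=``, ``>=``, ``is_true`` or ``in``
    (category membership).  ``requires`` names a boolean field that must be
    True for the predicate to be applicable at all (the Horowitz ratio is
    only scored in intubated patients).
    """

    parameter: str
    op: str
    value: object = None
    requires: Optional[str] = None

    def applicable(self, record: PatientRecord) -> bool:
        if self.requires is None:
            return True
        return getattr(record, self.requires) is True

    def observed(self, record: PatientRecord) -> bool:
        return getattr(record, self.parameter) is not None

    def satisfied(self, record: PatientRecord) -> bool:
        v = getattr(record, self.parameter)
        if v is None:
            return False
        if self.op == "<":
            return v < self.value  # type: ignore[operator]
        if self.op == ">":
            return v > self.value  # type: ignore[operator]
        if self.op == "<=":
            return v <= self.value  # type: ignore[operator]
        if self.op == ">=":
            return v >= self.value  # type: ignore[operator]
        if self.op == "is_true":
            return v is True
        if self.op == "in":
            return v in self.value  # type: ignore[operator]
        raise ValueError(f"unknown comparator {self.op!r}")


@dataclass(frozen=True)
class AspectDefinition:
    name: str
    predicates: tuple[Predicate, ...]

    def __post_init__(self) -> None:
        known = {f.name for f in PatientRecord.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        for p in self.predicates:
            if p.parameter not in PatientRecord.__dataclass_fields__:
                raise ValueError(f"aspect {self.name!r}: unknown parameter {p.parameter!r}")
            if p.requires is not None and p.requires not in known:
                raise ValueError(f"aspect {self.name!r}: unknown applicability field {p.requires!r}")


@dataclass(frozen=True)
class AdhocConfig:
    """Tunables that registry conventions can vary.

    Hemoglobin unit and threshold travel together: the default is the severe
    anemia cutoff 7 g/dL; a registry storing Hb in g/L would configure
    ``hb_unit="g/L", hb_threshold=70``.
    """

    hb_unit: str = "g/dL"
    hb_threshold: float = 7.0


def aspect_definitions(config: AdhocConfig = AdhocConfig()) -> tuple[AspectDefinition, ...]:
    """The four bundled AdHOC aspects."""
    return (
        AspectDefinition("age", (Predicate("age", ">", 65),)),
        AspectDefinition("head", (
            Predicate("gcs", "<", 12),
            Predicate("ecs_motor", "in", ("non_specific", "none")),
            Predicate("ecs_pupil_size", "in", ("not_normal",)),
            Predicate("ecs_pupil_reactivity", "in", ("not_normal",)),
        )),
        AspectDefinition("oxygenation", (
            Predicate("hemothorax", "is_true"),
            Predicate("base_excess", "<=", -6.0),
            Predicate("pao2_fio2", "<=", 200.0, requires="intubated"),
        )),
        AspectDefinition("circulation", (
            Predicate("sbp", "<=", 90.0),
            Predicate("prbc_transfused", "is_true"),
            Predicate("inr", ">", 1.4),
            Predicate("hb", "<", config.hb_threshold),
        )),
    )


@dataclass(frozen=True)
class AspectResult:
    name: str
    status: str                     # "positive" | "negative" | "indeterminate"
    triggered: tuple[str, ...]      # parameters that crossed their threshold
    observed_count: int
    applicable_count: int


@dataclass(frozen=True)
class AdhocResult:
    score: int
    aspects: tuple[AspectResult, ...]
    risk_class: str
    complete: bool

    def aspect(self, name: str) -> AspectResult:
        for a in self.aspects:
            if a.name == name:
                return a
        raise KeyError(name)


def evaluate_aspect(record: PatientRecord, aspect: AspectDefinition) -> AspectResult:
    """Evaluate one prognostic aspect under the any-parameter-positive rule.

    positive      — some applicable, observed parameter crossed its threshold
    negative      — at least one applicable parameter observed, none crossed
    indeterminate — no applicable parameter observed at all

    An inapplicable predicate (Horowitz ratio without intubation) counts as
    neither observed nor triggerable.
    """
    triggered: list[str] = []
    observed = 0
    applicable = 0
    for pred in aspect.predicates:
        if not pred.applicable(record):
            continue
        applicable += 1
        if pred.observed(record):
            observed += 1
            if pred.satisfied(record):
                triggered.append(pred.parameter)
    if triggered:
        status = "positive"
    elif observed > 0:
        status = "negative"
    else:
        status = "indeterminate"
    return AspectResult(aspect.name, status, tuple(triggered), observed, applicable)


def risk_class(score: int) -> str:
    """Map a total score to the clinical risk class.

    0-1 stable, 2 borderline (intermediate risk, may improve or deteriorate
    rapidly under resuscitation), 3-4 unstable.
    """
    if not (isinstance(score, int) and 0 <= score <= 4):
        raise ValueError(f"score must be an integer in 0..4, got {score!r}")
    if score <= 1:
        return "stable"
    if score == 2:
        return "borderline"
    return "unstable"


def adhoc_score(record: PatientRecord, config: AdhocConfig = AdhocConfig()) -> AdhocResult:
    """Compute the AdHOC score: one point per positive aspect.

    Indeterminate aspects contribute 0 points but clear ``complete``; with
    missing findings the result can only underestimate, never overestimate,
    trauma severity.
    """
    aspects = tuple(evaluate_aspect(record, a) for a in aspect_definitions(config))
    score = sum(1 for a in aspects if a.status == "positive")
    complete = all(a.status != "indeterminate" for a in aspects)
    return AdhocResult(score, aspects, risk_class(score), complete)


# ---------------------------------------------------------------------------
# Eppendorf-Cologne Scale


@dataclass(frozen=True)
class EcsMapping:
    """Category -> points maps for the three ECS subscales.

    The ECS grades head injury by pupil reactivity, pupil size and motor
    response; the total is the sum of the three subscores, maximum 8, and a
    fully normal exam scores 0.  The bundled default point values are a
    synthetic assignment satisfying those structural constraints on the
    dichotomized categories used here (the registry stores findings already
    collapsed to normal / not-normal); a site using the original multi-level
    scale should supply its own mapping.
    """

    motor: dict[str, int] = field(default_factory=lambda: {"normal": 0, "non_specific": 2, "none": 3})
    pupil_size: dict[str, int] = field(default_factory=lambda: {"normal": 0, "not_normal": 2})
    pupil_reactivity: dict[str, int] = field(default_factory=lambda: {"normal": 0, "not_normal": 3})

    def __post_init__(self) -> None:
        for name, sub in (("motor", self.motor), ("pupil_size", self.pupil_size),
                          ("pupil_reactivity", self.pupil_reactivity)):
            if sub.get("normal") != 0:
                raise ValueError(f"ECS subscale {name}: 'normal' must map to 0")
            if min(sub.values()) < 0:
                raise ValueError(f"ECS subscale {name}: points must be >= 0")
        if max(self.motor.values()) + max(self.pupil_size.values()) + max(self.pupil_reactivity.values()) != 8:
            raise ValueError("ECS subscale maxima must sum to 8")


def ecs_total(
    motor: str,
    pupil_size: str,
    pupil_reactivity: str,
    mapping: EcsMapping = EcsMapping(),
) -> int:
    """Total Eppendorf-Cologne Scale: sum of the three subscores, in [0, 8]."""
    try:
        return (
            mapping.motor[motor]
            + mapping.pupil_size[pupil_size]
            + mapping.pupil_reactivity[pupil_reactivity]
        )
    except KeyError as exc:
        raise ValueError(f"unknown ECS category {exc.args[0]!r}") from None


__all__ = [
    "Predicate",
    "AspectDefinition",
    "AspectResult",
    "AdhocResult",
    "AdhocConfig",
    "EcsMapping",
    "ASPECT_NAMES",
    "RISK_CLASSES",
    "aspect_definitions",
    "evaluate_aspect",
    "adhoc_score",
    "risk_class",
    "ecs_total",
]
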