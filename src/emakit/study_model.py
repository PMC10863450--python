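"""Declarative study definitions for mobile EMA/EMI interventions.

A *study* is the unit participants enroll in (via a short study code). It
holds one or more *interventions* — concrete packages of digital content —
each of which is an ordered list of *modules* (chapters). A module carries
*items* (questions or informative components), the timing rules that open
and close it per participant, and the push-notification specs attached to
it. Calculated variables (named expressions over item variables, see
:mod:`emakit.calc_expr`) hang off the intervention.

All clock quantities are integer minutes from a study-local epoch;
timestamps are timezone-naive. The finest timing granularity the engine
needs is the 15-minute notification lead, so minute resolution is exact.

Serialization is one canonical JSON schema (``schema_version: 1``); YAML is
accepted as an alternate surface syntax of the same schema. Unknown fields
are hard errors so that no-code study designers get loud feedback.
"""

from __future__ import annotations

import json
import os
from enum import Enum
from pathlib import Path
from typing import Annotated, Literal, Optional, Union

import yaml
from pydantic import (
    BaseModel,
    ConfigDict,
    Field,
    NonNegativeInt,
    PositiveInt,
    ValidationError,
)

SCHEMA_VERSION = 1

Minutes = int
AnswerValue = Union[float, int, str]


class StudyLoadError(ValueError):
    """Raised when a study document cannot be parsed into the schema.

    ``errors`` holds ``(path, message)`` pairs pointing at the offending
    fields, e.g. ``("interventions.0.modules.1.items.0.item_type", ...)``.
    """

    def __init__(self, message: str, errors: list[tuple[str, str]] | None = None):
        super().__init__(message)
        self.errors = errors or []


class _StrictModel(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ItemType(str, Enum):
    open_text = "open_text"
    closed = "closed"
    multiple_choice = "multiple_choice"
    drag_and_drop = "drag_and_drop"
    slider = "slider"
    number_input = "number_input"
    text_field = "text_field"
    dropdown = "dropdown"
    image_input = "image_input"
    microphone_input = "microphone_input"
    info_content = "info_content"


#: Item types whose answers are numeric and hence legal targets of the
#: numeric aggregation functions. Coded-choice types count as numeric
#: because each option carries a numeric code.
NUMERIC_ITEM_TYPES = frozenset(
    {
        ItemType.slider,
        ItemType.number_input,
        ItemType.closed,
        ItemType.multiple_choice,
        ItemType.dropdown,
        ItemType.drag_and_drop,
    }
)

#: Item types that take no answer and do not block module completion.
NON_ANSWERABLE_TYPES = frozenset({ItemType.info_content})


class Option(_StrictModel):
    label: str
    code: float


class Item(_StrictModel):
    id: str
    item_type: ItemType
    prompt: str = ""
    variable: Optional[str] = None
    options: Optional[list[Option]] = None
    media_ref: Optional[str] = None

    @property
    def answerable(self) -> bool:
        return self.item_type not in NON_ANSWERABLE_TYPES

    @property
    def numeric(self) -> bool:
        return self.item_type in NUMERIC_ITEM_TYPES


class Comparator(str, Enum):
    eq = "eq"
    ne = "ne"
    lt = "lt"
    le = "le"
    gt = "gt"
    ge = "ge"


#: Comparators legal on text answers; ordering comparators need numbers.
TEXT_COMPARATORS = frozenset({Comparator.eq, Comparator.ne})


# --- opening rules (tagged union) -------------------------------------------

class RelativeToInterventionStart(_StrictModel):
    """Open a fixed number of minutes after the participant enrolled."""

    rule: Literal["relative_to_intervention_start"] = "relative_to_intervention_start"
    offset_minutes: NonNegativeInt


class RelativeToModuleCompletion(_StrictModel):
    """Open a fixed number of minutes after another module was completed."""

    rule: Literal["relative_to_module_completion"] = "relative_to_module_completion"
    ref_module_id: str
    offset_minutes: NonNegativeInt


class OnModuleNotFinished(_StrictModel):
    """Open if the referenced module is still unfinished when checked.

    The check fires ``check_offset_minutes`` after the referenced module
    opened; if that module never opens, the rule never fires.
    """

    rule: Literal["on_module_not_finished"] = "on_module_not_finished"
    ref_module_id: str
    check_offset_minutes: NonNegativeInt


class OpeningAnswerCondition(_StrictModel):
    """Open when an answer to the referenced item satisfies the condition."""

    rule: Literal["answer_condition"] = "answer_condition"
    ref_item_id: str
    comparator: Comparator
    value: AnswerValue


class FixedDateTime(_StrictModel):
    """Open at a fixed study-local time (clamped to enrollment)."""

    rule: Literal["fixed_datetime"] = "fixed_datetime"
    at: NonNegativeInt


OpeningRule = Annotated[
    Union[
        RelativeToInterventionStart,
        RelativeToModuleCompletion,
        OnModuleNotFinished,
        OpeningAnswerCondition,
        FixedDateTime,
    ],
    Field(discriminator="rule"),
]


# --- closing rules (tagged union) -------------------------------------------

class ClosingAnswerCondition(_StrictModel):
    rule: Literal["answer_condition"] = "answer_condition"
    ref_item_id: str
    comparator: Comparator
    value: AnswerValue


class FixedDate(_StrictModel):
    rule: Literal["fixed_date"] = "fixed_date"
    at: NonNegativeInt


class RelativeToModuleStart(_StrictModel):
    rule: Literal["relative_to_module_start"] = "relative_to_module_start"
    offset_minutes: PositiveInt


ClosingRule = Annotated[
    Union[ClosingAnswerCondition, FixedDate, RelativeToModuleStart],
    Field(discriminator="rule"),
]

#: Closing-rule variants compatible with a closing notification: only these
#: yield a close time known ahead of the close, so a 15-minute lead exists.
CLOSING_NOTIF_COMPATIBLE = ("fixed_date", "relative_to_module_start")


# --- notifications -----------------------------------------------------------

class IntervalAfterOpen(_StrictModel):
    """Dispatch a fixed or uniformly random interval after the module opens.

    Either ``offset_minutes`` (deterministic) or ``window`` = (lo, hi)
    inclusive integer-minute bounds for a seeded uniform draw.
    """

    trigger: Literal["interval_after_open"] = "interval_after_open"
    offset_minutes: Optional[NonNegativeInt] = None
    window: Optional[tuple[NonNegativeInt, NonNegativeInt]] = None

    def model_post_init(self, __context) -> None:
        if (self.offset_minutes is None) == (self.window is None):
            raise ValueError(
                "interval_after_open takes exactly one of offset_minutes/window"
            )
        if self.window is not None and self.window[0] > self.window[1]:
            raise ValueError("window lower bound exceeds upper bound")


class FixedDispatch(_StrictModel):
    trigger: Literal["fixed_datetime"] = "fixed_datetime"
    at: NonNegativeInt


NotificationTrigger = Annotated[
    Union[IntervalAfterOpen, FixedDispatch], Field(discriminator="trigger")
]


class NotificationKind(str, Enum):
    opening = "opening"
    reminder = "reminder"
    closing = "closing"


#: A reminder is sent only after the module has been available this long;
#: a closing notification is sent exactly this long before the close.
MIN_REMINDER_OFFSET = 15
CLOSING_LEAD_MINUTES = 15


class NotificationSpec(_StrictModel):
    kind: NotificationKind
    text: str = ""
    # opening notifications need an explicit trigger; reminders default to
    # the minimum offset after open; closing dispatch is derived from the
    # close time and carries no trigger.
    trigger: Optional[NotificationTrigger] = None
    reminder_offset_minutes: Optional[int] = None


class CalcVariable(_StrictModel):
    name: str
    expression: str


class InterventionModule(_StrictModel):
    id: str
    title: str = ""
    items: list[Item] = Field(default_factory=list)
    opening_rules: list[OpeningRule] = Field(default_factory=list)
    closing_rules: list[ClosingRule] = Field(default_factory=list)
    notifications: list[NotificationSpec] = Field(default_factory=list)

    def answerable_items(self) -> list[Item]:
        return [it for it in self.items if it.answerable]


class AssignmentPolicy(str, Enum):
    auto_assign = "auto_assign"
    waitlist = "waitlist"


class Intervention(_StrictModel):
    id: str
    name: str = ""
    assignment_policy: AssignmentPolicy = AssignmentPolicy.auto_assign
    modules: list[InterventionModule] = Field(default_factory=list)
    calc_variables: list[CalcVariable] = Field(default_factory=list)

    def calc_variable_names(self) -> set[str]:
        return {cv.name for cv in self.calc_variables}


class StudyDefinition(_StrictModel):
    schema_version: Literal[1] = SCHEMA_VERSION
    study_code: str
    title: str = ""
    interventions: list[Intervention] = Field(default_factory=list)

    def intervention(self, intervention_id: str) -> Intervention:
        for iv in self.interventions:
            if iv.id == intervention_id:
                return iv
        raise KeyError(intervention_id)


# --- structural validation ---------------------------------------------------

class Violation(_StrictModel):
    """One structural problem; violations are data, never exceptions."""

    code: str
    path: str
    message: str


def _check_module(path: str, iv: Intervention, mod: InterventionModule,
                  module_ids: set[str], item_ids: set[str]) -> list[Violation]:
    out: list[Violation] = []
    for k, it in enumerate(mod.items):
        ipath = f"{path}.items.{k}"
        if it.item_type in NON_ANSWERABLE_TYPES and it.variable is not None:
            out.append(Violation(
                code="INFO_VARIABLE", path=ipath,
                message=f"info_content item {it.id!r} takes no answers and "
                        "cannot bind a variable"))
    for k, rule in enumerate(mod.opening_rules):
        rpath = f"{path}.opening_rules.{k}"
        ref_mod = getattr(rule, "ref_module_id", None)
        if ref_mod is not None and ref_mod not in module_ids:
            out.append(Violation(
                code="DANGLING_REF", path=rpath,
                message=f"opening rule references unknown module {ref_mod!r}"))
        out.extend(_check_answer_rule(rule, rpath, item_ids))
    for k, rule in enumerate(mod.closing_rules):
        rpath = f"{path}.closing_rules.{k}"
        out.extend(_check_answer_rule(rule, rpath, item_ids))

    kinds = [n.kind for n in mod.notifications]
    for kind in (NotificationKind.opening, NotificationKind.closing):
        if kinds.count(kind) > 1:
            out.append(Violation(
                code="NOTIF_CARDINALITY", path=f"{path}.notifications",
                message=f"only one {kind.value} notification can be created "
                        f"per module (found {kinds.count(kind)})"))
    for k, spec in enumerate(mod.notifications):
        npath = f"{path}.notifications.{k}"
        if spec.kind is NotificationKind.closing:
            compatible = any(r.rule in CLOSING_NOTIF_COMPATIBLE
                             for r in mod.closing_rules)
            if not compatible:
                out.append(Violation(
                    code="CLOSING_NOTIF_INCOMPATIBLE", path=npath,
                    message="a closing notification requires a fixed-date or "
                            "relative-after-start closing rule"))
        if spec.kind is NotificationKind.reminder:
            off = spec.reminder_offset_minutes
            if off is not None and off < MIN_REMINDER_OFFSET:
                out.append(Violation(
                    code="REMINDER_OFFSET", path=npath,
                    message=f"reminder offset {off} is below the "
                            f"{MIN_REMINDER_OFFSET}-minute minimum"))
        if spec.kind is NotificationKind.opening and spec.trigger is None:
            out.append(Violation(
                code="OPENING_TRIGGER_MISSING", path=npath,
                message="opening notification needs an interval or "
                        "fixed-date trigger"))
    return out


def _check_answer_rule(rule, rpath: str, item_ids: set[str]) -> list[Violation]:
    out: list[Violation] = []
    ref_item = getattr(rule, "ref_item_id", None)
    if ref_item is None:
        return out
    if ref_item not in item_ids:
        out.append(Violation(
            code="DANGLING_REF", path=rpath,
            message=f"rule references unknown item {ref_item!r}"))
    if isinstance(rule.value, str) and rule.comparator not in TEXT_COMPARATORS:
        out.append(Violation(
            code="COMPARATOR_TEXT", path=rpath,
            message=f"comparator {rule.comparator.value!r} needs a numeric "
                    "value; text answers support only eq/ne"))
    return out


def validate_study(study: StudyDefinition) -> list[Violation]:
    """Check every cross-reference and cardinality invariant of a study.

    Returns an empty list iff the study is structurally sound; a sound study
    never raises dangling-reference errors downstream in the scheduler or
    the expression evaluator. Violations are stable-ordered by path.
    """
    from . import calc_expr  # local import: calc_expr has no model deps

    out: list[Violation] = []
    if not study.study_code or not study.study_code.isalnum():
        out.append(Violation(
            code="STUDY_CODE", path="study_code",
            message="study_code must be a non-empty alphanumeric token"))
    if not study.interventions:
        out.append(Violation(
            code="NO_INTERVENTIONS", path="interventions",
            message="a study needs at least one intervention"))
    seen_iv: set[str] = set()
    for i, iv in enumerate(study.interventions):
        base = f"interventions.{i}"
        if iv.id in seen_iv:
            out.append(Violation(
                code="DUP_ID", path=base,
                message=f"duplicate intervention id {iv.id!r}"))
        seen_iv.add(iv.id)

        module_ids = {m.id for m in iv.modules}
        item_ids = {it.id for m in iv.modules for it in m.items}
        variables: dict[str, str] = {}
        numeric_vars: set[str] = set()

        seen_mod: set[str] = set()
        for j, mod in enumerate(iv.modules):
            mpath = f"{base}.modules.{j}"
            if mod.id in seen_mod:
                out.append(Violation(
                    code="DUP_ID", path=mpath,
                    message=f"duplicate module id {mod.id!r}"))
            seen_mod.add(mod.id)
            for k, it in enumerate(mod.items):
                if it.variable is not None:
                    if it.variable in variables:
                        out.append(Violation(
                            code="DUP_VARIABLE", path=f"{mpath}.items.{k}",
                            message=f"variable {it.variable!r} already bound "
                                    f"by item {variables[it.variable]!r}"))
                    else:
                        variables[it.variable] = it.id
                        if it.numeric:
                            numeric_vars.add(it.variable)
            out.extend(_check_module(mpath, iv, mod, module_ids, item_ids))

        for k, cv in enumerate(iv.calc_variables):
            cpath = f"{base}.calc_variables.{k}"
            try:
                ast = calc_expr.parse(cv.expression)
            except calc_expr.ExprSyntaxError as exc:
                out.append(Violation(
                    code="EXPR_SYNTAX", path=cpath,
                    message=f"expression does not parse: {exc}"))
                continue
            for var, aggregated in calc_expr.referenced_variables(ast):
                if var not in variables and var not in iv.calc_variable_names():
                    out.append(Violation(
                        code="EXPR_UNKNOWN_VAR", path=cpath,
                        message=f"expression references unknown variable {var!r}"))
                elif aggregated and var in variables and var not in numeric_vars:
                    out.append(Violation(
                        code="EXPR_NON_NUMERIC", path=cpath,
                        message=f"numeric aggregation over non-numeric "
                                f"variable {var!r}"))

    out.sort(key=lambda v: (v.path, v.code))
    return out


# --- serialization -----------------------------------------------------------

def loads_study(text: str) -> StudyDefinition:
    """Parse a study document from JSON or YAML text.

    Tries JSON first (the canonical surface), then YAML; schema errors
    carry the dotted field path.
    """
    try:
        raw = json.loads(text)
    except json.JSONDecodeError:
        try:
            raw = yaml.safe_load(text)
        except yaml.error.YAMLError as exc:
            raise StudyLoadError(f"document is not well-formed JSON/YAML: {exc}")
    if not isinstance(raw, dict):
        raise StudyLoadError("study document must be a mapping at top level")
    try:
        return StudyDefinition.model_validate(raw)
    except ValidationError as exc:
        errors = [(".".join(str(p) for p in e["loc"]), e["msg"])
                  for e in exc.errors()]
        detail = "; ".join(f"{path}: {msg}" for path, msg in errors)
        raise StudyLoadError(f"study document invalid: {detail}", errors)


def load_study(path: Union[str, os.PathLike]) -> StudyDefinition:
    """Load a ``.study.json`` / ``.study.yaml`` file into a typed tree."""
    return loads_study(Path(path).read_text(encoding="utf-8"))


def save_study(study: StudyDefinition, fmt: str = "json") -> str:
    """Serialize a study canonically; ``loads_study(save_study(s)) == s``.

    Key order follows the schema's field order, ``None`` fields are omitted,
    so serialization is byte-stable for equal trees.
    """
    data = study.model_dump(mode="json", exclude_none=True)
    if fmt == "json":
        return json.dumps(data, indent=2, ensure_ascii=False) + "\n"
    if fmt == "yaml":
        return yaml.safe_dump(data, sort_keys=False, allow_unicode=True)
    raise ValueError(f"unknown format {fmt!r}")


def example_study_path(name: str = "self_reflection") -> Path:
    """Path of a packaged example study definition."""
    return Path(__file__).parent / "examples" / f"{name}.study.json"
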