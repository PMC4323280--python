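"""Declarative schemas and scoring for standardized questionnaire instruments.

The validation battery around the KINDEX interview consists of fixed-form
instruments (PSS-14, ESI, HSCL-25, SCL-90-R somatization, PDS, CFV) plus the
PSS-4 embedded in the KINDEX itself.  Every one of them is scored the same
way: optionally reverse-code a declared subset of items, then sum items
within each declared subscale and across the whole instrument.  This module
expresses that contract as data (:class:`InstrumentSchema`) so that item
sets, response bounds and reverse-coded items are configuration, not code.

Missing data are handled by complete-case analysis: a subscale with any
missing item gets a missing sum, and the instrument total is missing
whenever any subscale is.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

__all__ = [
    "InstrumentSchema",
    "ResponseSet",
    "InstrumentScore",
    "ValidationIssue",
    "ValidationReport",
    "SchemaError",
    "ResponseValidationError",
    "reverse_code",
    "score_instrument",
    "score_range",
    "subscale_ranges",
    "score_table",
    "validate_responses",
    "load_schema",
    "default_schemas",
    "BUILTIN_SCHEMA_IDS",
]


class SchemaError(ValueError):
    """An instrument schema is internally inconsistent or an item is unknown."""


class ResponseValidationError(ValueError):
    """A response value violates the schema bounds."""


@dataclass(frozen=True)
class InstrumentSchema:
    """Declarative description of a sum-scored questionnaire.

    Parameters
    ----------
    instrument_id
        Short name token, e.g. ``"pss14"``.
    items
        Ordered item identifiers.
    response_min, response_max
        Inclusive per-item response bounds (e.g. 0-4 for the PSS,
        1-4 for the HSCL-25).
    reverse_coded
        Items whose value ``v`` is reflected to ``min + max - v`` before
        summation (the "positive" items of the PSS).
    subscales
        Named partition of the items; instruments without subscales use a
        single subscale covering all items.
    missing_policy
        Only ``"complete_case"`` is supported: any missing item voids its
        subscale sum and the total.
    """

    instrument_id: str
    items: tuple[str, ...]
    response_min: int
    response_max: int
    reverse_coded: frozenset[str] = frozenset()
    subscales: Mapping[str, tuple[str, ...]] = field(default_factory=dict)
    missing_policy: str = "complete_case"

    def __post_init__(self) -> None:
        if len(set(self.items)) != len(self.items):
            raise SchemaError(f"{self.instrument_id}: duplicate item ids")
        if self.response_min >= self.response_max:
            raise SchemaError(
                f"{self.instrument_id}: response_min must be < response_max"
            )
        if self.missing_policy != "complete_case":
            raise SchemaError(
                f"{self.instrument_id}: unsupported missing policy "
                f"{self.missing_policy!r}"
            )
        item_set = set(self.items)
        if not set(self.reverse_coded) <= item_set:
            unknown = sorted(set(self.reverse_coded) - item_set)
            raise SchemaError(f"{self.instrument_id}: reverse-coded items not "
                              f"in item list: {unknown}")
        if not self.subscales:
            object.__setattr__(self, "subscales", {"total": self.items})
        covered: list[str] = []
        for name, sub in self.subscales.items():
            covered.extend(sub)
            if not set(sub) <= item_set:
                raise SchemaError(
                    f"{self.instrument_id}: subscale {name!r} references "
                    f"unknown items"
                )
        if sorted(covered) != sorted(self.items):
            raise SchemaError(
                f"{self.instrument_id}: subscales must partition the items"
            )

    # -- convenience -------------------------------------------------------

    @property
    def n_items(self) -> int:
        return len(self.items)

    def reflect(self, value: int) -> int:
        """Reflect a value across the response scale (min + max - v)."""
        return self.response_min + self.response_max - value

    @classmethod
    def from_dict(cls, doc: Mapping) -> "InstrumentSchema":
        return cls(
            instrument_id=doc["instrument_id"],
            items=tuple(doc["items"]),
            response_min=int(doc["response_min"]),
            response_max=int(doc["response_max"]),
            reverse_coded=frozenset(doc.get("reverse_coded", ())),
            subscales={k: tuple(v) for k, v in doc.get("subscales", {}).items()},
            missing_policy=doc.get("missing_policy", "complete_case"),
        )

    def to_dict(self) -> dict:
        return {
            "instrument_id": self.instrument_id,
            "items": list(self.items),
            "response_min": self.response_min,
            "response_max": self.response_max,
            "reverse_coded": sorted(self.reverse_coded),
            "subscales": {k: list(v) for k, v in self.subscales.items()},
            "missing_policy": self.missing_policy,
        }


@dataclass(frozen=True)
class ResponseSet:
    """One respondent's raw answers to one instrument.

    ``values`` maps item id to an integer response or ``None`` for missing.
    """

    respondent_id: str
    instrument_id: str
    values: Mapping[str, Optional[int]]


@dataclass(frozen=True)
class InstrumentScore:
    respondent_id: str
    instrument_id: str
    subscale_sums: Mapping[str, Optional[int]]
    total: Optional[int]
    complete: bool


@dataclass(frozen=True)
class ValidationIssue:
    kind: str  # "out_of_range" | "unknown_item"
    respondent_id: str
    item: str
    value: object


@dataclass(frozen=True)
class ValidationReport:
    instrument_id: str
    issues: tuple[ValidationIssue, ...]
    missing_counts: Mapping[str, int]

    @property
    def ok(self) -> bool:
        return not self.issues


def _check_values(schema: InstrumentSchema, responses: ResponseSet) -> None:
    for item, value in responses.values.items():
        if item not in set(schema.items):
            raise SchemaError(
                f"unknown item {item!r} for instrument "
                f"{schema.instrument_id} (respondent {responses.respondent_id})"
            )
        if value is None:
            continue
        if not (schema.response_min <= value <= schema.response_max):
            raise ResponseValidationError(
                f"value {value} out of range "
                f"[{schema.response_min}, {schema.response_max}] on item "
                f"{item!r} for respondent {responses.respondent_id}"
            )


def reverse_code(schema: InstrumentSchema, responses: ResponseSet) -> ResponseSet:
    """Reflect the reverse-coded items of ``responses`` across the scale.

    A value ``v`` on a reverse-coded item becomes ``min + max - v``; other
    items and missing values are untouched.  Applying the operation twice is
    the identity.
    """
    _check_values(schema, responses)
    out = {
        item: (
            schema.reflect(v)
            if item in schema.reverse_coded and v is not None
            else v
        )
        for item, v in responses.values.items()
    }
    return ResponseSet(responses.respondent_id, responses.instrument_id, out)


def score_instrument(
    schema: InstrumentSchema, responses: ResponseSet
) -> InstrumentScore:
    """Score one respondent: reverse-code, then sum per subscale and overall.

    Under complete-case analysis a subscale with any missing item yields a
    missing sum; the total is missing unless every subscale is complete.
    """
    recoded = reverse_code(schema, responses)
    sums: dict[str, Optional[int]] = {}
    for name, sub_items in schema.subscales.items():
        vals = [recoded.values.get(item) for item in sub_items]
        sums[name] = None if any(v is None for v in vals) else int(sum(vals))
    complete = all(v is not None for v in sums.values())
    total = int(sum(sums.values())) if complete else None  # type: ignore[arg-type]
    return InstrumentScore(
        respondent_id=responses.respondent_id,
        instrument_id=schema.instrument_id,
        subscale_sums=sums,
        total=total,
        complete=complete,
    )


def score_range(schema: InstrumentSchema) -> tuple[int, int]:
    """Attainable (min, max) of the instrument total.

    Reflection maps the response interval onto itself, so reverse coding
    does not change the attainable bounds: the minimum total is
    ``n_items * response_min`` and the maximum ``n_items * response_max``.
    """
    return (
        schema.n_items * schema.response_min,
        schema.n_items * schema.response_max,
    )


def subscale_ranges(schema: InstrumentSchema) -> dict[str, tuple[int, int]]:
    """Attainable (min, max) per subscale sum (same reflection argument as
    :func:`score_range`)."""
    return {
        name: (len(items) * schema.response_min,
               len(items) * schema.response_max)
        for name, items in schema.subscales.items()
    }


def validate_responses(
    schema: InstrumentSchema, responses: Iterable[ResponseSet]
) -> ValidationReport:
    """Report (without mutating) out-of-range values, unknown items and
    per-item missingness over a table of response sets."""
    issues: list[ValidationIssue] = []
    missing: dict[str, int] = {item: 0 for item in schema.items}
    item_set = set(schema.items)
    for rs in responses:
        for item, value in rs.values.items():
            if item not in item_set:
                issues.append(
                    ValidationIssue("unknown_item", rs.respondent_id, item, value)
                )
                continue
            if value is None:
                missing[item] += 1
            elif not (schema.response_min <= value <= schema.response_max):
                issues.append(
                    ValidationIssue("out_of_range", rs.respondent_id, item, value)
                )
        for item in item_set - set(rs.values):
            missing[item] += 1
    return ValidationReport(schema.instrument_id, tuple(issues), missing)


def score_table(schema: InstrumentSchema, wide: pd.DataFrame) -> pd.DataFrame:
    """Vectorized scoring of a wide response table.

    ``wide`` has one row per respondent indexed by respondent id and one
    column per item id (missing entries as NaN).  Returns a frame with one
    column per subscale, a ``total`` column and a boolean ``complete``
    column.  Values follow the same complete-case rules as
    :func:`score_instrument`.
    """
    missing_cols = [c for c in schema.items if c not in wide.columns]
    if missing_cols:
        raise SchemaError(
            f"{schema.instrument_id}: response table lacks item columns "
            f"{missing_cols}"
        )
    data = wide[list(schema.items)].astype("float64").copy()
    in_bounds = data.isna() | (
        (data >= schema.response_min) & (data <= schema.response_max)
    )
    if not in_bounds.all().all():
        bad = (~in_bounds).stack()
        r, item = bad[bad].index[0]
        raise ResponseValidationError(
            f"value {wide.loc[r, item]} out of range on item {item!r} "
            f"for respondent {r}"
        )
    for item in schema.reverse_coded:
        data[item] = schema.response_min + schema.response_max - data[item]
    out = pd.DataFrame(index=wide.index)
    for name, sub_items in schema.subscales.items():
        out[name] = data[list(sub_items)].sum(axis=1, min_count=len(sub_items))
    out["total"] = out[list(schema.subscales)].sum(
        axis=1, min_count=len(schema.subscales)
    )
    out["complete"] = out["total"].notna()
    return out


# ---------------------------------------------------------------------------
# Built-in schemas (shipped as versioned JSON documents)
# ---------------------------------------------------------------------------

BUILTIN_SCHEMA_IDS = (
    "pss14",
    "pss4",
    "esi",
    "hscl25",
    "scl90r_somatization",
    "pds_events",
    "pds_symptoms",
    "cfv",
)


def load_schema(instrument_id: str) -> InstrumentSchema:
    """Load a built-in schema shipped with the package."""
    try:
        text = (
            resources.files("kindex")
            .joinpath("schemas", f"{instrument_id}.json")
            .read_text(encoding="utf-8")
        )
    except FileNotFoundError as exc:
        raise SchemaError(f"no built-in schema {instrument_id!r}") from exc
    return InstrumentSchema.from_dict(json.loads(text))


def default_schemas() -> dict[str, InstrumentSchema]:
    """All built-in instrument schemas keyed by instrument id."""
    return {sid: load_schema(sid) for sid in BUILTIN_SCHEMA_IDS}
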