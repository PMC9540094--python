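"""Formal contexts and information bucketing.

A formal context is a triple ``K = (G, M, I)``: a set of objects ``G``, a set
of attributes ``M``, and an incidence relation ``I`` saying which object has
which attribute.  Raw tabular records become a context through *bucketing*:
each categorical feature contributes one binary attribute per admissible
value, and each numeric feature is cut into named half-open intervals
(lower bound inclusive, upper bound exclusive) that partition its range.

The module also reads and writes the two standard on-disk forms of a
context: the cross-table CSV (objects as rows, attributes as columns,
``X`` marks) and the Burmeister ``.cxt`` format.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

__all__ = [
    "BucketingError",
    "UncoveredValueError",
    "UnknownCategoryError",
    "ContextParseError",
    "NumericRule",
    "CategoricalRule",
    "BucketingSchema",
    "FormalContext",
    "Instance",
    "bucketize_numeric",
    "build_context",
    "read_context",
    "write_context",
    "read_schema",
    "write_schema",
    "vectorize_text",
]


class BucketingError(ValueError):
    """A record value cannot be mapped to an attribute."""


class UncoveredValueError(BucketingError):
    """A numeric value falls outside every interval of its feature's rule."""


class UnknownCategoryError(BucketingError):
    """A categorical value is not among the rule's admissible values."""


class ContextParseError(ValueError):
    """A context file is malformed; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


@dataclass(frozen=True)
class NumericRule:
    """Ordered half-open intervals ``[lower, upper)`` naming a numeric feature.

    The last interval's upper bound may be ``math.inf``.  Intervals must be
    disjoint and ascending so every covered value maps to exactly one
    attribute.
    """

    intervals: tuple[tuple[str, float, float], ...]

    def __post_init__(self):
        if not self.intervals:
            raise ValueError("numeric rule needs at least one interval")
        prev_hi = -math.inf
        for name, lo, hi in self.intervals:
            if not lo < hi:
                raise ValueError(f"interval {name!r} is empty: [{lo}, {hi})")
            if lo < prev_hi:
                raise ValueError(f"interval {name!r} overlaps its predecessor")
            prev_hi = hi

    @property
    def attributes(self) -> tuple[str, ...]:
        return tuple(name for name, _, _ in self.intervals)


@dataclass(frozen=True)
class CategoricalRule:
    """Admissible values of a categorical feature, one attribute per value.

    ``attributes`` defaults to the values themselves; pass explicit names
    (e.g. ``"smoker=yes"``) when raw values would collide across features.
    """

    values: tuple[str, ...]
    attributes: tuple[str, ...] | None = None

    def __post_init__(self):
        if len(set(self.values)) != len(self.values):
            raise ValueError("categorical values must be unique")
        if self.attributes is not None and len(self.attributes) != len(self.values):
            raise ValueError("attributes must parallel values")

    @property
    def attribute_names(self) -> tuple[str, ...]:
        return self.attributes if self.attributes is not None else self.values

    def attribute_for(self, value: str) -> str:
        try:
            return self.attribute_names[self.values.index(str(value))]
        except ValueError:
            raise UnknownCategoryError(
                f"value {value!r} not admissible (expected one of {list(self.values)})"
            ) from None


@dataclass(frozen=True)
class BucketingSchema:
    """Per-feature bucketing rules mapping raw records to attribute sets."""

    rules: Mapping[str, NumericRule | CategoricalRule]

    def __post_init__(self):
        seen: set[str] = set()
        for feature, rule in self.rules.items():
            names = (
                rule.attributes
                if isinstance(rule, NumericRule)
                else rule.attribute_names
            )
            for name in names:
                if name in seen:
                    raise ValueError(
                        f"attribute {name!r} (feature {feature!r}) duplicated across schema"
                    )
                seen.add(name)

    @property
    def features(self) -> tuple[str, ...]:
        return tuple(self.rules)

    @property
    def attributes(self) -> tuple[str, ...]:
        """Full attribute list M, in schema order."""
        out: list[str] = []
        for rule in self.rules.values():
            out.extend(
                rule.attributes
                if isinstance(rule, NumericRule)
                else rule.attribute_names
            )
        return tuple(out)

    def bucketize_record(self, record: Mapping[str, object]) -> frozenset[str]:
        attrs: set[str] = set()
        for feature, rule in self.rules.items():
            if feature not in record or record[feature] is None or (
                isinstance(record[feature], float) and math.isnan(record[feature])
            ):
                raise BucketingError(f"record is missing feature {feature!r}")
            value = record[feature]
            if isinstance(rule, NumericRule):
                try:
                    attrs.add(bucketize_numeric(float(value), rule))
                except UncoveredValueError as exc:
                    raise UncoveredValueError(
                        f"feature {feature!r}: {exc}"
                    ) from None
            else:
                try:
                    attrs.add(rule.attribute_for(value))
                except UnknownCategoryError as exc:
                    raise UnknownCategoryError(f"feature {feature!r}: {exc}") from None
        return frozenset(attrs)


def bucketize_numeric(value: float, rule: NumericRule) -> str:
    """Map ``value`` to the unique interval attribute containing it.

    Bounds are lower-inclusive / upper-exclusive, so with
    ``Adult = [0, 60)`` an age of 59 is ``Adult`` and 60 is not.
    """
    for name, lo, hi in rule.intervals:
        if lo <= value < hi:
            return name
    raise UncoveredValueError(f"value {value} outside all intervals")


@dataclass(frozen=True)
class Instance:
    """A new object to score: an identifier and its attribute set.

    The attribute set may mention attributes absent from the training
    context's M; they count toward the instance's size but can never be
    shared with a concept.
    """

    id: str
    attributes: frozenset[str]

    def __post_init__(self):
        object.__setattr__(self, "attributes", frozenset(self.attributes))


@dataclass(frozen=True)
class FormalContext:
    """An object/attribute incidence table ``K = (G, M, I)``.

    ``objects`` and ``attributes`` are ordered; ``incidence`` maps each
    object id to the (frozen) set of attributes it holds.  Attributes held
    by no object are legal and retained — this keeps M stable between a
    training context and later instances bucketized by the same schema.
    """

    objects: tuple[str, ...]
    attributes: tuple[str, ...]
    incidence: Mapping[str, frozenset[str]] = field(compare=True)

    def __post_init__(self):
        if len(set(self.objects)) != len(self.objects):
            raise ValueError("object identifiers must be unique")
        if len(set(self.attributes)) != len(self.attributes):
            raise ValueError("attribute names must be unique")
        attr_set = set(self.attributes)
        inc = {}
        for g in self.objects:
            row = frozenset(self.incidence.get(g, frozenset()))
            extra = row - attr_set
            if extra:
                raise ValueError(f"object {g!r} holds unknown attributes {sorted(extra)}")
            inc[g] = row
        unknown = set(self.incidence) - set(self.objects)
        if unknown:
            raise ValueError(f"incidence mentions unknown objects {sorted(unknown)}")
        object.__setattr__(self, "incidence", inc)

    def __eq__(self, other) -> bool:
        if not isinstance(other, FormalContext):
            return NotImplemented
        return (
            self.objects == other.objects
            and self.attributes == other.attributes
            and all(self.incidence[g] == other.incidence[g] for g in self.objects)
        )

    def __hash__(self):
        return hash((self.objects, self.attributes))

    def intent_of(self, obj: str) -> frozenset[str]:
        """Attr(g): the full attribute set of one object."""
        try:
            return self.incidence[obj]
        except KeyError:
            raise KeyError(f"unknown object {obj!r}") from None

    def has(self, obj: str, attr: str) -> bool:
        return attr in self.incidence[obj]

    def to_frame(self):
        """The cross table as a boolean pandas DataFrame (objects × attributes)."""
        import pandas as pd

        return pd.DataFrame(
            [[a in self.incidence[g] for a in self.attributes] for g in self.objects],
            index=list(self.objects),
            columns=list(self.attributes),
        )


def build_context(
    records: Sequence[Mapping[str, object]],
    schema: BucketingSchema,
    ids: Sequence[str] | None = None,
) -> FormalContext:
    """Bucketize raw ``records`` into a formal context.

    One object per record, in order; M is the full schema attribute list,
    including attributes no record supports.  ``records`` may also be a
    pandas DataFrame, in which case its index supplies the object ids.
    """
    if hasattr(records, "iterrows"):  # pandas DataFrame
        df = records
        ids = [str(i) for i in df.index] if ids is None else list(ids)
        records = [row.to_dict() for _, row in df.iterrows()]
    if ids is None:
        ids = [f"obj{i + 1}" for i in range(len(records))]
    if len(ids) != len(records):
        raise ValueError("ids must parallel records")
    incidence = {
        str(g): schema.bucketize_record(rec) for g, rec in zip(ids, records)
    }
    return FormalContext(tuple(str(g) for g in ids), schema.attributes, incidence)


# ---------------------------------------------------------------------------
# On-disk formats


def _read_csv_context(path: Path) -> FormalContext:
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ContextParseError("empty cross-table file", line=1) from None
        attributes = tuple(h.strip() for h in header[1:])
        objects: list[str] = []
        incidence: dict[str, frozenset[str]] = {}
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) != len(header):
                raise ContextParseError(
                    f"expected {len(header)} cells, found {len(row)}", line=lineno
                )
            obj = row[0].strip()
            marks = set()
            for attr, cell in zip(attributes, row[1:]):
                cell = cell.strip().lower()
                if cell == "x":
                    marks.add(attr)
                elif cell not in ("", "."):
                    raise ContextParseError(
                        f"cell for {obj!r}/{attr!r} must be 'X' or empty, got {cell!r}",
                        line=lineno,
                    )
            objects.append(obj)
            incidence[obj] = frozenset(marks)
    return FormalContext(tuple(objects), attributes, incidence)


def _write_csv_context(context: FormalContext, path: Path) -> None:
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["object", *context.attributes])
        for g in context.objects:
            row = ["X" if a in context.incidence[g] else "" for a in context.attributes]
            writer.writerow([g, *row])


def _read_cxt_context(path: Path) -> FormalContext:
    lines = path.read_text().splitlines()

    def get(i: int) -> str:
        if i >= len(lines):
            raise ContextParseError("unexpected end of file", line=len(lines))
        return lines[i]

    if get(0).strip() != "B":
        raise ContextParseError("Burmeister file must start with 'B'", line=1)
    i = 1
    if i < len(lines) and lines[i].strip() == "":  # optional name line slot
        i += 1
    try:
        n_obj = int(get(i).strip())
        n_attr = int(get(i + 1).strip())
    except ValueError:
        raise ContextParseError("expected object/attribute counts", line=i + 1) from None
    if n_obj < 0 or n_attr < 0:
        raise ContextParseError("negative dimensions", line=i + 1)
    i += 2
    if i < len(lines) and lines[i].strip() == "":
        i += 1
    objects = tuple(get(i + j) for j in range(n_obj))
    i += n_obj
    attributes = tuple(get(i + j) for j in range(n_attr))
    i += n_attr
    incidence: dict[str, frozenset[str]] = {}
    for j, g in enumerate(objects):
        row = get(i + j)
        if len(row) != n_attr:
            raise ContextParseError(
                f"incidence row for {g!r} has {len(row)} cells, expected {n_attr}",
                line=i + j + 1,
            )
        marks = set()
        for attr, cell in zip(attributes, row):
            if cell in ("X", "x"):
                marks.add(attr)
            elif cell != ".":
                raise ContextParseError(
                    f"incidence cell must be 'X' or '.', got {cell!r}", line=i + j + 1
                )
        incidence[g] = frozenset(marks)
    tail = [ln for ln in lines[i + n_obj :] if ln.strip()]
    if tail:
        raise ContextParseError("trailing content after incidence rows", line=i + n_obj + 1)
    return FormalContext(objects, attributes, incidence)


def _write_cxt_context(context: FormalContext, path: Path) -> None:
    lines = ["B", "", str(len(context.objects)), str(len(context.attributes)), ""]
    lines.extend(context.objects)
    lines.extend(context.attributes)
    for g in context.objects:
        lines.append(
            "".join("X" if a in context.incidence[g] else "." for a in context.attributes)
        )
    path.write_text("\n".join(lines) + "\n")


_DIALECTS = {
    "csv": (_read_csv_context, _write_csv_context),
    "cxt": (_read_cxt_context, _write_cxt_context),
}


def _infer_dialect(path: Path, dialect: str | None) -> str:
    if dialect is None:
        dialect = path.suffix.lstrip(".").lower()
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown context dialect {dialect!r} (use 'csv' or 'cxt')")
    return dialect


def read_context(path: str | Path, dialect: str | None = None) -> FormalContext:
    """Read a context from a cross-table CSV or a Burmeister CXT file."""
    path = Path(path)
    return _DIALECTS[_infer_dialect(path, dialect)][0](path)


def write_context(
    context: FormalContext, path: str | Path, dialect: str | None = None
) -> None:
    """Write a context; ``read_context(write_context(K)) == K`` exactly."""
    path = Path(path)
    _DIALECTS[_infer_dialect(path, dialect)][1](context, path)


# ---------------------------------------------------------------------------
# Schema config files


def _rule_to_config(rule: NumericRule | CategoricalRule) -> dict:
    if isinstance(rule, NumericRule):
        return {
            "type": "numeric",
            "bins": [
                {"name": name, "lo": lo, "hi": ("inf" if math.isinf(hi) else hi)}
                for name, lo, hi in rule.intervals
            ],
        }
    cfg: dict = {"type": "categorical", "values": list(rule.values)}
    if rule.attributes is not None:
        cfg["attributes"] = list(rule.attributes)
    return cfg


def _rule_from_config(feature: str, cfg: Mapping) -> NumericRule | CategoricalRule:
    kind = cfg.get("type")
    if kind == "numeric":
        intervals = tuple(
            (
                b["name"],
                float(b["lo"]),
                math.inf if str(b["hi"]).lower() in ("inf", ".inf") else float(b["hi"]),
            )
            for b in cfg["bins"]
        )
        return NumericRule(intervals)
    if kind == "categorical":
        attrs = cfg.get("attributes")
        return CategoricalRule(
            tuple(str(v) for v in cfg["values"]),
            tuple(attrs) if attrs is not None else None,
        )
    raise ValueError(f"feature {feature!r}: unknown rule type {kind!r}")


def read_schema(path: str | Path) -> BucketingSchema:
    """Load a bucketing schema from a YAML (or JSON) config file."""
    path = Path(path)
    raw = yaml.safe_load(path.read_text())
    if not isinstance(raw, Mapping):
        raise ValueError("schema config must map feature names to rules")
    return BucketingSchema({f: _rule_from_config(f, cfg) for f, cfg in raw.items()})


def write_schema(schema: BucketingSchema, path: str | Path) -> None:
    path = Path(path)
    cfg = {f: _rule_to_config(r) for f, r in schema.rules.items()}
    if path.suffix == ".json":
        path.write_text(json.dumps(cfg, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(cfg, sort_keys=False))


def vectorize_text(documents: Iterable[str], **options):  # pragma: no cover
    """Extension hook: binarize tf-idf text vectors into context attributes.

    Deliberately unimplemented — how term weights should be thresholded into
    binary attributes is an open modelling question for textual data.
    """
    raise NotImplementedError(
        "text vectorization into a formal context is an extension point"
    )
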