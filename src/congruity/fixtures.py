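"""The worked BMI example: ten people, three features, two new arrivals.

This tiny clinical-flavoured dataset exercises every stage of the
pipeline: age is cut at 60 into Adult/Elderly, gender is one-hot, and BMI
is cut at the WHO thresholds 18.5 / 25 / 30 into Underweight / Normal /
Overweight / Obese.  The resulting context has 10 objects and 8
attributes; its lattice has 22 concepts.

Two new people are then scored: one whose profile exactly matches a
training profile seen once (a high score driven by the exact-match case)
and one whose attribute combination was never seen together (a middling
score averaged over four partially matching concepts).

The first new person's raw record is ambiguous in the source tables; two
readings reproduce the same published score, so both are exposed
(:data:`PERSON11` and :data:`PERSON11_ALT`).
"""

from __future__ import annotations

import math
from typing import NamedTuple

import pandas as pd

from .formal_context import (
    BucketingSchema,
    CategoricalRule,
    FormalContext,
    Instance,
    NumericRule,
    build_context,
)

__all__ = [
    "BmiExample",
    "bmi_schema",
    "bmi_records",
    "bmi_example_fixture",
    "PERSON11",
    "PERSON11_ALT",
    "PERSON12",
]

_RAW = [
    ("Person1", 25, "Male", 23.0),
    ("Person2", 59, "Female", 20.5),
    ("Person3", 68, "Female", 24.0),
    ("Person4", 18, "Male", 25.0),
    ("Person5", 44, "Male", 27.0),
    ("Person6", 81, "Male", 17.5),
    ("Person7", 33, "Female", 31.0),
    ("Person8", 49, "Male", 19.5),
    ("Person9", 77, "Female", 30.0),
    ("Person10", 90, "Female", 18.0),
]

PERSON11 = Instance("Person11", frozenset({"Elderly", "Male", "Underweight"}))
#: Alternative reading of the ambiguous Person11 record; scores identically.
PERSON11_ALT = Instance("Person11", frozenset({"Elderly", "Female", "Normal"}))
PERSON12 = Instance("Person12", frozenset({"Adult", "Female", "Overweight"}))


def bmi_schema() -> BucketingSchema:
    """Age/Gender/BMI bucketing rules of the worked example."""
    return BucketingSchema(
        {
            "Age": NumericRule(
                (("Adult", 0.0, 60.0), ("Elderly", 60.0, math.inf))
            ),
            "Gender": CategoricalRule(("Male", "Female")),
            "BMI": NumericRule(
                (
                    ("Underweight", 0.0, 18.5),
                    ("Normal", 18.5, 25.0),
                    ("Overweight", 25.0, 30.0),
                    ("Obese", 30.0, math.inf),
                )
            ),
        }
    )


def bmi_records() -> pd.DataFrame:
    """The ten raw training records, indexed by person id."""
    return pd.DataFrame(
        [(age, gender, bmi) for _, age, gender, bmi in _RAW],
        index=[pid for pid, *_ in _RAW],
        columns=["Age", "Gender", "BMI"],
    )


class BmiExample(NamedTuple):
    records: pd.DataFrame
    schema: BucketingSchema
    context: FormalContext
    instances: tuple[Instance, Instance]


def bmi_example_fixture() -> BmiExample:
    """Records, schema, derived 10×8 context, and the two test instances."""
    records = bmi_records()
    schema = bmi_schema()
    context = build_context(records, schema)
    return BmiExample(records, schema, context, (PERSON11, PERSON12))
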