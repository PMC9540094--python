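"""Synthetic train/test generator with controllable representativeness.

The generator emulates the situation the congruity score is built for:
a tabular training set whose attribute profiles cover part of the feature
space, and a test set in which some instances repeat training profiles
while others are novel combinations.  Simulated classifier predictions
flip the true label with probability proportional to a profile's novelty
(Hamming distance to the nearest training profile), so score and accuracy
are positively coupled *by construction* — the generator creates the
condition the evaluation workflow is supposed to detect, which is exactly
what makes it a usable end-to-end test bed.

Defaults model a small clinical-style table: 500 training and 500 test
records over 6 binary features, with 30% novel test profiles and a strong
novelty-accuracy penalty.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, NamedTuple

import numpy as np
import pandas as pd

from .formal_context import (
    BucketingSchema,
    CategoricalRule,
    Instance,
    NumericRule,
)

__all__ = ["SyntheticConfig", "SyntheticData", "generate_synthetic"]


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs of the generator.

    feature_kinds
        One ``("categorical", v)`` or ``("numeric", b)`` entry per feature
        (v admissible values / b equal-width bins).  After bucketing both
        kinds are equivalent; numeric features exist to exercise interval
        rules end to end.
    train_pool_fraction
        Fraction of the full profile space from which training profiles
        are drawn; the remainder is reachable only by novel test items.
    novelty_rate
        Probability that a test instance is a perturbed (1–2 feature
        flips) rather than repeated training profile.
    noise_slope
        Misclassification probability per unit of normalized Hamming
        distance to the nearest training profile; 0 means a perfect
        simulated classifier.
    """

    n_train: int = 500
    n_test: int = 500
    feature_kinds: tuple[tuple[str, int], ...] = (("categorical", 2),) * 6
    train_pool_fraction: float = 0.6
    novelty_rate: float = 0.3
    noise_slope: float = 0.9
    seed: int = 0

    def __post_init__(self):
        if self.n_train <= 0 or self.n_test <= 0:
            raise ValueError("counts must be positive")
        for rate in (self.train_pool_fraction, self.novelty_rate, self.noise_slope):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        for kind, card in self.feature_kinds:
            if kind not in ("categorical", "numeric") or card < 2:
                raise ValueError(f"bad feature kind {(kind, card)!r}")

    @property
    def n_features(self) -> int:
        return len(self.feature_kinds)

    @property
    def profile_space(self) -> int:
        return int(np.prod([card for _, card in self.feature_kinds]))


class SyntheticData(NamedTuple):
    train_records: pd.DataFrame
    test_records: pd.DataFrame
    labels: Mapping[str, tuple[int, int]]  # test id -> (y_true, y_pred)
    schema: BucketingSchema

    def test_instances(self) -> list[Instance]:
        """Test records bucketized with the training schema."""
        return [
            Instance(str(idx), self.schema.bucketize_record(row.to_dict()))
            for idx, row in self.test_records.iterrows()
        ]


def _make_schema(config: SyntheticConfig) -> BucketingSchema:
    rules = {}
    for i, (kind, card) in enumerate(config.feature_kinds):
        feat = f"f{i + 1}"
        if kind == "categorical":
            values = tuple(f"v{j}" for j in range(card))
            rules[feat] = CategoricalRule(
                values, tuple(f"{feat}={v}" for v in values)
            )
        else:
            rules[feat] = NumericRule(
                tuple(
                    (f"{feat}:[{j},{j + 1})", float(j), float(j + 1))
                    for j in range(card)
                )
            )
    return BucketingSchema(rules)


def _profile_to_record(profile, config, rng) -> dict:
    rec = {}
    for i, ((kind, _), idx) in enumerate(zip(config.feature_kinds, profile)):
        feat = f"f{i + 1}"
        if kind == "categorical":
            rec[feat] = f"v{idx}"
        else:
            rec[feat] = idx + float(rng.uniform(0.0, 1.0))  # any point in the bin
    return rec


def generate_synthetic(config: SyntheticConfig = SyntheticConfig()) -> SyntheticData:
    """Draw train/test records, true labels and simulated predictions.

    Reproducible: the same config (including seed) yields identical
    frames and labels.  Raises when the profile space is too small to hold
    both a training pool and, if ``novelty_rate > 0``, unseen profiles.
    """
    rng = np.random.default_rng(config.seed)
    cards = [card for _, card in config.feature_kinds]
    space = list(itertools.product(*[range(c) for c in cards]))
    n_pool = max(1, round(config.train_pool_fraction * len(space)))
    if config.novelty_rate > 0 and n_pool >= len(space):
        raise ValueError(
            "attribute space admits no unseen profiles: shrink "
            "train_pool_fraction, add features, or set novelty_rate=0"
        )

    pool_idx = rng.choice(len(space), size=n_pool, replace=False)
    pool = [space[i] for i in sorted(pool_idx)]
    weights = rng.dirichlet(np.ones(n_pool))

    train_profiles = [pool[i] for i in rng.choice(n_pool, size=config.n_train, p=weights)]
    seen = set(train_profiles)

    # true label: a simple threshold rule on the summed value indices,
    # learnable in principle but irrelevant to the simulated classifier
    half = sum(c - 1 for c in cards) / 2

    def true_label(profile) -> int:
        return int(sum(profile) >= half)

    def nearest_distance(profile) -> int:
        if profile in seen:
            return 0
        return min(
            sum(a != b for a, b in zip(profile, q)) for q in seen
        )

    test_profiles = []
    for _ in range(config.n_test):
        # resample from the empirical training distribution, so a
        # non-novel test profile is guaranteed to have been seen
        base = train_profiles[int(rng.integers(config.n_train))]
        if rng.random() < config.novelty_rate:
            mutated = list(base)
            n_flips = int(rng.integers(1, 3))  # 1 or 2 feature flips
            for fi in rng.choice(config.n_features, size=n_flips, replace=False):
                current = mutated[fi]
                choices = [v for v in range(cards[fi]) if v != current]
                mutated[fi] = int(rng.choice(choices))
            test_profiles.append(tuple(mutated))
        else:
            test_profiles.append(base)

    labels: dict[str, tuple[int, int]] = {}
    for j, profile in enumerate(test_profiles):
        y = true_label(profile)
        d = nearest_distance(profile)
        flip_p = config.noise_slope * d / config.n_features
        y_hat = 1 - y if rng.random() < flip_p else y
        labels[f"t{j + 1}"] = (y, y_hat)

    schema = _make_schema(config)
    feat_names = [f"f{i + 1}" for i in range(config.n_features)]
    train_records = pd.DataFrame(
        [_profile_to_record(p, config, rng) for p in train_profiles],
        index=[f"g{j + 1}" for j in range(config.n_train)],
        columns=feat_names,
    )
    test_records = pd.DataFrame(
        [_profile_to_record(p, config, rng) for p in test_profiles],
        index=[f"t{j + 1}" for j in range(config.n_test)],
        columns=feat_names,
    )
    return SyntheticData(train_records, test_records, labels, schema)
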