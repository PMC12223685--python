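"""Test/train split construction for the learning-curve simulation.

Design: per outcome, a 30% simple-random held-out test set; nested
training sets at increasing budgets (each budget's set contains every
smaller budget's set) with the positive:negative ratio of the remaining
pool preserved by exact stratified sampling; and an oversampling arm that
adds positive cases (negatives held fixed) to a base training set until a
target positive fraction is reached.

All sampling shuffles lexicographically sorted record ids with a seeded
NumPy generator, so plans are platform-independent and exactly replayable
from their JSON serialization.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Mapping, Sequence

import numpy as np

from .synthetic import NarrativeRecord

__all__ = [
    "SplitPlan",
    "OversamplePlan",
    "restrict_cohort",
    "make_test_split",
    "make_nested_train_splits",
    "plan_oversample_addition",
    "composition_after_addition",
    "make_oversampled_splits",
]

DEFAULT_BUDGETS = (100, 200, 500, 1000, 1500, 2000)
DEFAULT_OVERSAMPLE_FRACTIONS = (0.10, 0.20, 0.30, 0.40, 0.50)


def _round_half_up(x: float) -> int:
    return math.floor(x + 0.5)


@dataclass
class SplitPlan:
    """Held-out test ids plus nested training-id sets per budget."""

    outcome: str
    test_ids: frozenset[str]
    train_budgets: tuple[int, ...]
    train_ids_by_budget: dict[int, frozenset[str]]
    seed: int

    def validate(self) -> None:
        prev: frozenset[str] = frozenset()
        for b in self.train_budgets:
            ids = self.train_ids_by_budget[b]
            if len(ids) != b:
                raise ValueError(f"budget {b}: got {len(ids)} ids")
            if ids & self.test_ids:
                raise ValueError(f"budget {b}: train ids overlap test set")
            if not prev <= ids:
                raise ValueError(f"budget {b}: train sets not nested")
            prev = ids

    def to_json(self, path) -> None:
        doc = {
            "outcome": self.outcome,
            "seed": self.seed,
            "test_ids": sorted(self.test_ids),
            "train_budgets": list(self.train_budgets),
            "train_ids_by_budget": {
                str(b): sorted(ids) for b, ids in self.train_ids_by_budget.items()
            },
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(doc, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SplitPlan":
        with open(path, encoding="utf-8") as fh:
            doc = json.load(fh)
        return cls(
            outcome=doc["outcome"],
            test_ids=frozenset(doc["test_ids"]),
            train_budgets=tuple(doc["train_budgets"]),
            train_ids_by_budget={
                int(b): frozenset(ids) for b, ids in doc["train_ids_by_budget"].items()
            },
            seed=doc["seed"],
        )


@dataclass
class OversamplePlan:
    """Positive ids added to a base training set, per target positive fraction."""

    outcome: str
    base_budget: int
    target_fractions: tuple[float, ...]
    added_pos_ids_by_fraction: dict[float, frozenset[str]]
    seed: int
    base_ids: frozenset[str] = field(default_factory=frozenset)

    def to_json(self, path) -> None:
        doc = {
            "outcome": self.outcome,
            "seed": self.seed,
            "base_budget": self.base_budget,
            "base_ids": sorted(self.base_ids),
            "target_fractions": list(self.target_fractions),
            "added_pos_ids_by_fraction": {
                repr(f): sorted(ids) for f, ids in self.added_pos_ids_by_fraction.items()
            },
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(doc, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "OversamplePlan":
        with open(path, encoding="utf-8") as fh:
            doc = json.load(fh)
        return cls(
            outcome=doc["outcome"],
            base_budget=doc["base_budget"],
            target_fractions=tuple(doc["target_fractions"]),
            added_pos_ids_by_fraction={
                float(f): frozenset(ids)
                for f, ids in doc["added_pos_ids_by_fraction"].items()
            },
            seed=doc["seed"],
            base_ids=frozenset(doc["base_ids"]),
        )


def restrict_cohort(records: Sequence[NarrativeRecord]) -> list[NarrativeRecord]:
    """Keep firearm homicides only (the analytic sample), order preserved."""
    return [
        r for r in records if r.weapon_type == "firearm" and r.manner == "homicide"
    ]


def _shuffled_ids(ids: Sequence[str], rng: np.random.Generator) -> list[str]:
    arr = np.array(sorted(ids))
    rng.shuffle(arr)
    return [str(x) for x in arr]


def make_test_split(
    records: Sequence[NarrativeRecord],
    outcome: str,
    test_fraction: float,
    seed: int,
) -> frozenset[str]:
    """Simple random held-out test set of round(test_fraction * n) records."""
    if not records:
        raise ValueError("cohort is empty")
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must be in (0,1)")
    n = len(records)
    n_test = _round_half_up(test_fraction * n)
    if n_test == 0 or n_test == n:
        raise ValueError("cohort too small for a non-empty test set and pool")
    rng = np.random.default_rng(seed)
    shuffled = _shuffled_ids([r.record_id for r in records], rng)
    return frozenset(shuffled[:n_test])


def make_nested_train_splits(
    pool: Sequence[NarrativeRecord],
    outcome: str,
    budgets: Sequence[int],
    seed: int,
) -> dict[int, frozenset[str]]:
    """Nested, class-stratified training sets at each budget.

    The positive count at budget ``b`` is round-half-up of ``b`` times the
    pool's positive fraction (clamped to the available positives); each
    budget's set extends the previous one, so adding training data never
    swaps out earlier cases.
    """
    budgets = list(budgets)
    if any(b2 <= b1 for b1, b2 in zip(budgets, budgets[1:])):
        raise ValueError("budgets must be strictly increasing")
    if budgets[-1] > len(pool):
        raise ValueError(f"largest budget {budgets[-1]} exceeds pool size {len(pool)}")
    pos_ids = [r.record_id for r in pool if r.outcomes[outcome] == 1]
    neg_ids = [r.record_id for r in pool if r.outcomes[outcome] == 0]
    pool_frac = len(pos_ids) / len(pool)
    rng = np.random.default_rng(seed)
    pos_shuffled = _shuffled_ids(pos_ids, rng)
    neg_shuffled = _shuffled_ids(neg_ids, rng)

    out: dict[int, frozenset[str]] = {}
    prev_pos = 0
    for b in budgets:
        n_pos = min(max(_round_half_up(b * pool_frac), prev_pos), len(pos_ids))
        n_neg = b - n_pos
        if n_neg > len(neg_ids):
            raise ValueError(
                f"budget {b}: needs {n_neg} negatives, pool has {len(neg_ids)}"
            )
        out[b] = frozenset(pos_shuffled[:n_pos] + neg_shuffled[:n_neg])
        prev_pos = n_pos
    return out


def plan_oversample_addition(n_pos: int, n_neg: int, target_fraction: float) -> int:
    """Minimal number of positives to add so the positive fraction reaches target.

    Returns the smallest non-negative integer ``a`` with
    ``(n_pos + a) / (n_pos + n_neg + a) >= target_fraction``.  The target is
    interpreted as the decimal written by the caller (0.2 means exactly
    1/5), so boundary compositions that already sit on the target need no
    additions.
    """
    if n_pos < 0 or n_neg < 0:
        raise ValueError("counts must be non-negative")
    if not 0.0 < target_fraction < 1.0:
        raise ValueError("target_fraction must be in (0,1)")
    f = Fraction(target_fraction).limit_denominator(1_000_000)
    need = (f * (n_pos + n_neg) - n_pos) / (1 - f)
    return max(0, math.ceil(need))


def composition_after_addition(n_pos: int, n_neg: int, n_add: int) -> tuple[int, int, float]:
    """(total positives, total records, achieved positive fraction) after
    adding ``n_add`` positives to an ``n_pos``/``n_neg`` training base."""
    total_pos = n_pos + n_add
    total = n_pos + n_neg + n_add
    return total_pos, total, total_pos / total


def make_oversampled_splits(
    records: Sequence[NarrativeRecord],
    outcome: str,
    base_ids: frozenset[str],
    test_ids: frozenset[str],
    target_fractions: Sequence[float],
    seed: int,
) -> OversamplePlan:
    """Plan positive-case additions for each target fraction.

    Added ids are positive-class records outside both the base training set
    and the test set, drawn without replacement; additions are nested across
    increasing fractions (a larger target reuses the smaller target's
    additions).  Fractions already met by the base composition get an empty
    addition set.
    """
    fractions = list(target_fractions)
    if any(f2 <= f1 for f1, f2 in zip(fractions, fractions[1:])):
        raise ValueError("target_fractions must be strictly increasing")
    by_id = {r.record_id: r for r in records}
    n_pos = sum(1 for i in base_ids if by_id[i].outcomes[outcome] == 1)
    n_neg = len(base_ids) - n_pos
    pool = [
        r.record_id
        for r in records
        if r.outcomes[outcome] == 1
        and r.record_id not in base_ids
        and r.record_id not in test_ids
    ]
    rng = np.random.default_rng(seed)
    pool_shuffled = _shuffled_ids(pool, rng)

    added: dict[float, frozenset[str]] = {}
    for f in fractions:
        n_add = plan_oversample_addition(n_pos, n_neg, f)
        if n_add > len(pool_shuffled):
            raise ValueError(
                f"fraction {f}: needs {n_add} extra positives, pool has "
                f"{len(pool_shuffled)}"
            )
        added[f] = frozenset(pool_shuffled[:n_add])
    return OversamplePlan(
        outcome=outcome,
        base_budget=len(base_ids),
        target_fractions=tuple(fractions),
        added_pos_ids_by_fraction=added,
        seed=seed,
        base_ids=frozenset(base_ids),
    )
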