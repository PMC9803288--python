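"""Number-sequence randomizer construction and validation.

The randomizing device behind the unrelated question: the respondent
memorizes one number from a first sequence, is later shown a second
sequence, and answers whether the memorized number reappears.  Because
exactly a designed fraction of first-sequence numbers is planted in the
second sequence, the "Yes" probability of the unrelated question is known
by construction — and since the sequences are never shown together, the
respondent cannot work out which crosswise response would be
incriminating, which is what forecloses informed self-protection.

Construction rules for the first sequence: random two-digit numbers,
excluding single digits, repdigit "master" numbers (11, 22, ..., 99) and
multiples of ten (10, 20, ..., 90) as too memorable or too likely to be
picked non-uniformly.  This leaves a pool of exactly 72 numbers.  The
second sequence may contain any number from 1 to 99 in its filler slots.
Supported designs: sequence lengths 5, 10 or 15 with reappearance
probability 1/5 or 4/5 (overlaps 1/2/3 or 4/8/12), plus degenerate
control items with probability 0 (no overlap) or 1 (the first sequence
reshuffled), whose expected response is known exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np

__all__ = [
    "SequencePair",
    "ValidationReport",
    "DeploymentItem",
    "eligible_pool",
    "generate_pair",
    "validate_pair",
    "design_survey",
]

LENGTHS = (5, 10, 15)
TARGET_PS = (Fraction(0), Fraction(1, 5), Fraction(4, 5), Fraction(1))


@dataclass(frozen=True)
class SequencePair:
    """One randomizer item: the memorization sequence and the lookup
    sequence, with the implied unrelated-question "Yes" probability."""

    first_seq: tuple[int, ...]
    second_seq: tuple[int, ...]

    @property
    def length(self) -> int:
        return len(self.first_seq)

    @property
    def overlap(self) -> int:
        return len(set(self.first_seq) & set(self.second_seq))

    @property
    def implied_p(self) -> Fraction:
        return Fraction(self.overlap, self.length)


@dataclass(frozen=True)
class ValidationReport:
    implied_p: Fraction
    violations: tuple[str, ...]

    @property
    def ok(self) -> bool:
        return not self.violations


@dataclass(frozen=True)
class DeploymentItem:
    """One row of a deployment sheet: the randomizer pair a given
    sub-sample sees for a given question."""

    question: str
    subsample: int
    pair: SequencePair


def eligible_pool() -> frozenset[int]:
    """The 72 admissible first-sequence numbers: two-digit numbers minus
    the nine repdigits and the nine multiples of ten."""
    masters = {11 * k for k in range(1, 10)}
    tens = {10 * k for k in range(1, 10)}
    return frozenset(set(range(10, 100)) - masters - tens)


def generate_pair(
    L: int,
    target_p: Fraction | float,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> SequencePair:
    """Generate a randomizer pair with exact reappearance probability.

    Exactly ``L * target_p`` first-sequence numbers are planted in the
    second sequence; the remaining slots are filled from 1..99 excluding
    all first-sequence numbers (fillers are exempt from the memorability
    exclusions).  For ``target_p = 1`` the second sequence is the first in
    a different order.  Same seed, same sequences.
    """
    target_p = Fraction(target_p).limit_denominator(100)
    if L not in LENGTHS:
        raise ValueError(f"sequence length must be one of {LENGTHS}, got {L}")
    if target_p not in TARGET_PS:
        raise ValueError(f"target probability must be one of {TARGET_PS}, got {target_p}")
    overlap = target_p * L
    if overlap.denominator != 1:  # cannot happen for the supported grid
        raise ValueError(f"L * target_p must be an integer, got {overlap}")
    overlap = int(overlap)

    if rng is None:
        rng = np.random.default_rng(seed)
    pool = sorted(eligible_pool())
    first = tuple(int(v) for v in rng.choice(pool, size=L, replace=False))

    planted = [int(v) for v in rng.choice(first, size=overlap, replace=False)]
    fillers_pool = sorted(set(range(1, 100)) - set(first))
    fillers = [int(v) for v in rng.choice(fillers_pool, size=L - overlap, replace=False)]
    second = np.array(planted + fillers)
    rng.shuffle(second)
    if overlap == L and L > 1:
        while tuple(second) == first:  # control items must reshuffle visibly
            rng.shuffle(second)
    return SequencePair(first_seq=first, second_seq=tuple(int(v) for v in second))


def validate_pair(pair: SequencePair) -> ValidationReport:
    """Recompute the implied probability and report every rule violation."""
    violations: list[str] = []
    pool = eligible_pool()
    if len(set(pair.first_seq)) != len(pair.first_seq):
        violations.append("first sequence contains duplicates")
    if len(set(pair.second_seq)) != len(pair.second_seq):
        violations.append("second sequence contains duplicates")
    if len(pair.second_seq) != len(pair.first_seq):
        violations.append("sequences differ in length")
    if pair.length not in LENGTHS:
        violations.append(f"length {pair.length} not in {LENGTHS}")
    for v in pair.first_seq:
        if v not in pool:
            violations.append(f"first-sequence number {v} violates the exclusion rules")
    for v in pair.second_seq:
        if not 1 <= v <= 99:
            violations.append(f"second-sequence number {v} outside 1..99")
    if pair.implied_p not in TARGET_PS:
        violations.append(f"implied probability {pair.implied_p} not a supported design value")
    return ValidationReport(implied_p=pair.implied_p, violations=tuple(violations))


def design_survey(
    questions,
    L: int,
    seed: int | None = None,
    control_p: Fraction | float | int | None = None,
) -> list[DeploymentItem]:
    """Generate per-question, per-sub-sample randomizer pairs.

    The 1/5 and 4/5 probabilities alternate between consecutive questions
    within each sub-sample, and the two sub-samples are complementary for
    every question: question 1 pairs sub-sample 1 with 1/5 and sub-sample
    2 with 4/5, question 2 the reverse, and so on.  ``control_p`` (0 or 1)
    appends a control item with known expected response, identical in both
    sub-samples.
    """
    questions = list(questions)
    if not questions:
        raise ValueError("at least one question is required")
    rng = np.random.default_rng(seed)
    items: list[DeploymentItem] = []
    low, high = Fraction(1, 5), Fraction(4, 5)
    for idx, q in enumerate(questions):
        p_arm1 = low if idx % 2 == 0 else high
        for s in (1, 2):
            p = p_arm1 if s == 1 else 1 - p_arm1
            items.append(DeploymentItem(str(q), s, generate_pair(L, p, rng=rng)))
    if control_p is not None:
        cp = Fraction(control_p)
        if cp not in (Fraction(0), Fraction(1)):
            raise ValueError("control items use probability 0 or 1")
        for s in (1, 2):
            items.append(DeploymentItem("control", s, generate_pair(L, cp, rng=rng)))
    return items
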