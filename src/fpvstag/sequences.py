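"""Stimulus sequence construction for frequency-tagged oddball designs.

An FPVS trial is an ordered stream of stimulus tokens presented at the base
rate. Experimental trials alternate two categories (XYXYXY...), so one
category recurs at half the base rate (the oddball frequency); baseline
trials draw every token from a single category (xxxxxx). Each item is
presented a fixed number of times, pseudo-randomized so the same item never
occurs twice in a row.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["StimulusCategory", "TrialSequence", "generate_sequence"]

@dataclass(frozen=True)
class StimulusCategory:
    """A labelled set of stimulus item identifiers."""

    label: str
    items: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.items) < 2:
            raise ValueError(f"category {self.label!r} needs >= 2 items")
        if len(set(self.items)) != len(self.items):
            raise ValueError(f"duplicate items in category {self.label!r}")

    def __len__(self) -> int:
        return len(self.items)


@dataclass(frozen=True)
class TrialSequence:
    """A realized stimulus stream with its category labelling."""

    tokens: tuple[str, ...]
    category_of: dict[str, str] = field(compare=False)
    mode: str = "uniform"
    seed: int = 0

    def __len__(self) -> int:
        return len(self.tokens)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(self.category_of[t] for t in self.tokens)


def _shuffled_no_adjacent(items: tuple[str, ...], reps: int,
                          rng: np.random.Generator) -> list[str]:
    """Random order of ``items * reps`` with no two equal neighbours.

    Greedy construction: draw each token with probability proportional to
    its remaining count (excluding the previous token), except that an
    item holding more than half the remaining slots must be placed
    immediately — which guarantees success whenever an arrangement exists.
    """
    counts = {item: reps for item in items}
    total = len(items) * reps
    seq: list[str] = []
    prev: str | None = None
    for pos in range(total):
        remaining = total - pos
        forced = [it for it, c in counts.items() if 2 * c > remaining]
        if forced:
            choice = forced[0]
            if choice == prev:
                raise ValueError(
                    "cannot satisfy the no-adjacent-repetition constraint "
                    f"for {len(items)} items x {reps} repetitions")
        else:
            avail = [it for it, c in counts.items() if c > 0 and it != prev]
            if not avail:
                raise ValueError(
                    "cannot satisfy the no-adjacent-repetition constraint "
                    f"for {len(items)} items x {reps} repetitions")
            weights = np.array([counts[it] for it in avail], dtype=float)
            choice = avail[rng.choice(len(avail), p=weights / weights.sum())]
        counts[choice] -= 1
        seq.append(choice)
        prev = choice
    return seq


def generate_sequence(cat_a: StimulusCategory,
                      cat_b: StimulusCategory | None = None,
                      reps: int = 5,
                      mode: str = "alternating",
                      seed: int = 0) -> TrialSequence:
    """Build one pseudo-randomized trial sequence.

    Parameters
    ----------
    cat_a, cat_b
        Stimulus categories. ``cat_b`` is required in alternating mode and
        must have the same number of items as ``cat_a`` (strict alternation
        with equal repetition counts is otherwise impossible).
    reps
        Number of presentations of every item (the study design presents
        each of 32 items exactly 5 times, giving 160-token sequences).
    mode
        ``"alternating"`` (ABAB...; oddball design) or ``"uniform"``
        (single-category baseline).
    seed
        Seeds the pseudo-randomization; identical inputs reproduce the
        identical sequence.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if mode not in ("alternating", "uniform"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)

    if mode == "alternating":
        if cat_b is None:
            raise ValueError("alternating mode requires two categories")
        if len(cat_a) != len(cat_b):
            raise ValueError(
                "alternating mode requires equal category sizes "
                f"({len(cat_a)} vs {len(cat_b)})"
            )
        overlap = set(cat_a.items) & set(cat_b.items)
        if overlap:
            raise ValueError(f"item ids shared between categories: {sorted(overlap)}")
        stream_a = _shuffled_no_adjacent(cat_a.items, reps, rng)
        stream_b = _shuffled_no_adjacent(cat_b.items, reps, rng)
        tokens: list[str] = []
        for a, b in zip(stream_a, stream_b):
            tokens.extend((a, b))
        category_of = {i: cat_a.label for i in cat_a.items}
        category_of.update({i: cat_b.label for i in cat_b.items})
    else:
        tokens = _shuffled_no_adjacent(cat_a.items, reps, rng)
        category_of = {i: cat_a.label for i in cat_a.items}

    return TrialSequence(tokens=tuple(tokens), category_of=category_of,
                         mode=mode, seed=seed)
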