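"""Compact letter displays via the insert-and-absorb algorithm.

Groups that are not significantly different share at least one letter;
groups with no letter in common differ significantly.  The construction
starts from a single class holding every group and, for each significant
pair, splits every class still containing both members, then absorbs any
class that became a subset of another.  Any insertion order yields a valid
display; a fixed order (pairs by group position) makes the output
deterministic.

Letter names are presentation only — two displays that assign different
letters to the same classes encode the same result.  The canonical,
comparison-safe form is the partition returned by
:func:`letters_to_partition`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

__all__ = ["LetterDisplay", "insert_absorb", "letters_to_partition"]


def _letter(i: int) -> str:
    """a, b, ..., z, aa, ab, ... for pathologically many classes."""
    out = ""
    i += 1
    while i > 0:
        i, rem = divmod(i - 1, 26)
        out = chr(ord("a") + rem) + out
    return out


@dataclass(frozen=True)
class LetterDisplay:
    """Letters per group plus the induced partition into letter-classes."""

    labels: tuple[str, ...]
    letters: tuple[str, ...]
    partition: frozenset  # frozenset of frozensets of labels

    def __str__(self):
        return ", ".join(f"{lab}: {let}" for lab, let in zip(self.labels, self.letters))


def insert_absorb(labels: Sequence[str], relation,
                  ranks: Optional[Sequence[float]] = None) -> LetterDisplay:
    """Build a letter display from a pairwise significance relation.

    ``relation`` is a symmetric boolean matrix with a false diagonal;
    ``relation[i][j]`` True means groups i and j differ significantly.
    ``ranks``, when given, orders the letter names: classes are lettered by
    their best-ranked member (ascending rank), so passing the descending-
    mean rank of each group attaches 'a' to the class containing the
    largest mean.  Without ranks, input position is used.
    """
    labels = tuple(str(x) for x in labels)
    k = len(labels)
    rel = np.asarray(relation, dtype=bool)
    if rel.shape != (k, k):
        raise ValueError("relation shape does not match labels")
    if not np.array_equal(rel, rel.T):
        raise ValueError("relation must be symmetric")
    if rel.diagonal().any():
        raise ValueError("relation diagonal must be false")
    if ranks is None:
        rank = list(range(k))
    else:
        if len(ranks) != k:
            raise ValueError("ranks length must match labels")
        rank = list(ranks)

    classes: list[set[int]] = [set(range(k))]
    for i in range(k):
        for j in range(i + 1, k):
            if not rel[i, j]:
                continue
            new_classes: list[set[int]] = []
            for cls in classes:
                if i in cls and j in cls:
                    new_classes.append(cls - {i})
                    new_classes.append(cls - {j})
                else:
                    new_classes.append(cls)
            # absorb: deduplicate, then drop any class strictly contained
            # in another
            unique = []
            for cls in new_classes:
                if cls not in unique:
                    unique.append(cls)
            classes = [c for c in unique if not any(c < o for o in unique)]
    # letter classes in order of their best-ranked member
    classes.sort(key=lambda cls: min(rank[m] for m in cls))
    letters_per_group: list[list[str]] = [[] for _ in range(k)]
    for ci, cls in enumerate(classes):
        for m in cls:
            letters_per_group[m].append(_letter(ci))
    letter_strings = tuple("".join(sorted(ls)) for ls in letters_per_group)
    partition = frozenset(frozenset(labels[m] for m in cls) for cls in classes)
    return LetterDisplay(labels=labels, letters=letter_strings, partition=partition)


def letters_to_partition(display: LetterDisplay) -> frozenset:
    """Canonical partition of a display: letter-classes as sets of labels.

    Independent of which letter names the classes, so two displays with
    swapped letters compare equal.
    """
    by_letter: dict[str, set[str]] = {}
    for lab, letters in zip(display.labels, display.letters):
        for ch in _split_letters(letters):
            by_letter.setdefault(ch, set()).add(lab)
    return frozenset(frozenset(v) for v in by_letter.values())


def _split_letters(s: str) -> list[str]:
    # single chars unless multi-letter names are in play (>26 classes);
    # multi-letter names never occur alongside single letters ambiguously
    # for k <= 26, which is the practical range for published tables
    return list(s)
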