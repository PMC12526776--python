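"""Train/validation/test splits under two protocols, with leakage audit.

The subject-wise (leave-n-subject-out) protocol partitions *subjects*, so
held-out sets contain only runners never seen in training.  The
subject-dependent protocol shuffles segment indices directly, so one
runner's cycles can land in every set — the optimistic regime most
wearable studies report.  ``audit_split`` quantifies exactly that
difference.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

PROTOCOLS = ("subject_wise", "subject_dependent")
DEFAULT_FRACTIONS = (0.70, 0.15, 0.15)
_SET_NAMES = ("train", "val", "test")


@dataclass(frozen=True)
class SplitSpec:
    """Index sets for one split plus the protocol that produced them."""

    protocol: str
    train: np.ndarray
    val: np.ndarray
    test: np.ndarray
    fractions: tuple[float, float, float]
    seed: int

    def __post_init__(self) -> None:
        if self.protocol not in PROTOCOLS:
            raise ValueError(f"unknown protocol {self.protocol!r}")
        for name in _SET_NAMES:
            object.__setattr__(
                self, name, np.asarray(getattr(self, name), dtype=np.int64)
            )
        sets = [set(self.train), set(self.val), set(self.test)]
        total = sum(len(s) for s in sets)
        union = set().union(*sets)
        if total != len(union):
            raise ValueError("index sets must be pairwise disjoint")

    @property
    def n_segments(self) -> int:
        return len(self.train) + len(self.val) + len(self.test)

    def sets(self) -> dict[str, np.ndarray]:
        return {name: getattr(self, name) for name in _SET_NAMES}


def _check_fractions(fractions: Sequence[float]) -> tuple[float, float, float]:
    if len(fractions) != 3:
        raise ValueError("fractions must be (train, val, test)")
    if any(f <= 0 for f in fractions):
        raise ValueError("all fractions must be > 0")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    return tuple(float(f) for f in fractions)


def largest_remainder_counts(n: int, fractions: Sequence[float]) -> list[int]:
    """Integer set sizes summing to n, by largest-remainder rounding."""
    exact = [n * f for f in fractions]
    base = [int(np.floor(e)) for e in exact]
    remainder = n - sum(base)
    # Distribute leftovers to the largest fractional parts; ties go to the
    # earlier set (train before val before test).
    order = sorted(range(len(exact)), key=lambda i: (-(exact[i] - base[i]), i))
    for i in order[:remainder]:
        base[i] += 1
    return base


def split_subject_wise(
    subjects_per_segment: Sequence,
    fractions: Sequence[float] = DEFAULT_FRACTIONS,
    seed: int = 0,
) -> SplitSpec:
    """Partition subjects, then let every segment follow its subject.

    No subject ever appears in more than one set.  Requires at least
    three distinct subjects (one per set).
    """
    fractions = _check_fractions(fractions)
    subjects = np.asarray(subjects_per_segment)
    unique = np.unique(subjects)
    if len(unique) < 3:
        raise ValueError(
            f"subject-wise split needs >= 3 distinct subjects, got {len(unique)}"
        )
    rng = np.random.default_rng(seed)
    shuffled = rng.permutation(unique)
    counts = largest_remainder_counts(len(unique), fractions)
    if any(c == 0 for c in counts):
        raise ValueError("fractions leave an empty subject set")
    edges = np.cumsum(counts)
    groups = np.split(shuffled, edges[:-1])
    index_sets = []
    for group in groups:
        mask = np.isin(subjects, group)
        index_sets.append(np.flatnonzero(mask).astype(np.int64))
    return SplitSpec(
        protocol="subject_wise",
        train=index_sets[0],
        val=index_sets[1],
        test=index_sets[2],
        fractions=fractions,
        seed=seed,
    )


def split_subject_dependent(
    n_segments: int,
    fractions: Sequence[float] = DEFAULT_FRACTIONS,
    seed: int = 0,
    stratify_by_surface: bool = False,
    surface_labels: Sequence[int] | None = None,
) -> SplitSpec:
    """Shuffle all segment indices, then cut at the fraction boundaries.

    With stratification on, shuffling and cutting happen within each
    surface class, keeping the class balance of every set near the
    global balance.
    """
    fractions = _check_fractions(fractions)
    if n_segments < 3:
        raise ValueError("need at least 3 segments")
    rng = np.random.default_rng(seed)
    if stratify_by_surface:
        if surface_labels is None:
            raise ValueError("stratified split needs surface_labels")
        surface_labels = np.asarray(surface_labels)
        if len(surface_labels) != n_segments:
            raise ValueError("surface_labels must have length n_segments")
        parts: list[list[np.ndarray]] = [[], [], []]
        for label in np.unique(surface_labels):
            idx = rng.permutation(np.flatnonzero(surface_labels == label))
            counts = largest_remainder_counts(len(idx), fractions)
            edges = np.cumsum(counts)
            for part, chunk in zip(parts, np.split(idx, edges[:-1])):
                part.append(chunk)
        sets = [np.sort(np.concatenate(p)).astype(np.int64) for p in parts]
    else:
        idx = rng.permutation(n_segments)
        counts = largest_remainder_counts(n_segments, fractions)
        edges = np.cumsum(counts)
        sets = [s.astype(np.int64) for s in np.split(idx, edges[:-1])]
    if any(len(s) == 0 for s in sets):
        raise ValueError("fractions leave an empty set")
    return SplitSpec(
        protocol="subject_dependent",
        train=sets[0],
        val=sets[1],
        test=sets[2],
        fractions=fractions,
        seed=seed,
    )


@dataclass(frozen=True)
class SplitAudit:
    """Leakage report for one split."""

    sizes: dict
    surface_balance: dict
    shared_train_test_subjects: int
    shared_subject_ids: tuple


def audit_split(
    split: SplitSpec,
    subjects_per_segment: Sequence,
    surface_labels: Sequence[int] | None = None,
) -> SplitAudit:
    """Sizes, per-set class balance, and train/test subject overlap.

    The overlap count must be zero for a subject-wise split (asserted
    here), and is typically positive for a subject-dependent one — the
    leakage that inflates its accuracy.
    """
    subjects = np.asarray(subjects_per_segment)
    covered = np.concatenate([split.train, split.val, split.test])
    if len(subjects) != len(covered):
        raise ValueError("split does not cover subjects_per_segment")
    sizes = {name: len(idx) for name, idx in split.sets().items()}
    balance = {}
    if surface_labels is not None:
        surface_labels = np.asarray(surface_labels)
        for name, idx in split.sets().items():
            balance[name] = (
                float(np.mean(surface_labels[idx])) if len(idx) else float("nan")
            )
    shared = np.intersect1d(
        np.unique(subjects[split.train]), np.unique(subjects[split.test])
    )
    if split.protocol == "subject_wise" and len(shared):
        raise AssertionError(
            f"subject-wise split leaks subjects between train and test: "
            f"{shared.tolist()}"
        )
    return SplitAudit(
        sizes=sizes,
        surface_balance=balance,
        shared_train_test_subjects=int(len(shared)),
        shared_subject_ids=tuple(shared.tolist()),
    )
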