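"""Transition taxonomy between two conditions: the 16 patterns A-P.

Comparing a locus between two conditions (typically control vs salinity
stress) yields an ordered pair of methylation states, one of 16 possibilities.
The field labels them A-P and groups them into three change classes:

* A-D — monomorphic: the state is identical in both conditions;
* E-J — demethylation: methylation rank decreases;
* K-P — methylation: methylation rank increases.

Also provides the chi-square independence test used to ask whether the
distribution of methylation levels depends on the treatment condition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .states import MethylationState, MsapDataset, lanes_from_state

__all__ = [
    "TransitionPattern",
    "TransitionSummary",
    "ContingencyTable",
    "PATTERN_ORDER",
    "CHANGE_CLASSES",
    "INCONSISTENT",
    "classify_transition",
    "compare_conditions",
    "summarize_pattern_counts",
    "consensus_transition",
    "chi_square_independence",
]

PATTERN_ORDER = tuple("ABCDEFGHIJKLMNOP")
CHANGE_CLASSES = ("no_change", "demethylation", "methylation")

# Lane encodings (HpaII, MspI) before -> after for each label.  A-D are the
# identity transitions, E-J the rank-decreasing ones, K-P the rank-increasing
# ones, in the conventional listing order.
_PATTERN_LANES: dict[str, tuple[tuple[int, int], tuple[int, int]]] = {
    "A": ((1, 0), (1, 0)),
    "B": ((0, 1), (0, 1)),
    "C": ((1, 1), (1, 1)),
    "D": ((0, 0), (0, 0)),
    "E": ((1, 0), (1, 1)),
    "F": ((0, 1), (1, 1)),
    "G": ((0, 0), (1, 1)),
    "H": ((0, 1), (1, 0)),
    "I": ((0, 0), (1, 0)),
    "J": ((0, 0), (0, 1)),
    "K": ((1, 1), (1, 0)),
    "L": ((1, 1), (0, 1)),
    "M": ((1, 1), (0, 0)),
    "N": ((1, 0), (0, 1)),
    "O": ((1, 0), (0, 0)),
    "P": ((0, 1), (0, 0)),
}


@dataclass(frozen=True)
class TransitionPattern:
    """One of the 16 labels A-P for an ordered (before, after) state pair."""

    label: str
    before: MethylationState
    after: MethylationState

    @property
    def before_lanes(self) -> tuple[int, int]:
        return lanes_from_state(self.before)

    @property
    def after_lanes(self) -> tuple[int, int]:
        return lanes_from_state(self.after)

    @property
    def change_class(self) -> str:
        if self.after.rank == self.before.rank:
            return "no_change"
        return "demethylation" if self.after.rank < self.before.rank else "methylation"


def _build_pattern_index() -> dict[tuple[MethylationState, MethylationState], TransitionPattern]:
    from .states import state_from_lanes

    index = {}
    for label, (before_lanes, after_lanes) in _PATTERN_LANES.items():
        before = state_from_lanes(*before_lanes)
        after = state_from_lanes(*after_lanes)
        index[(before, after)] = TransitionPattern(label, before, after)
    assert len(index) == 16
    return index


_PAIR_TO_PATTERN = _build_pattern_index()
PATTERNS: dict[str, TransitionPattern] = {
    p.label: p for p in sorted(_PAIR_TO_PATTERN.values(), key=lambda p: p.label)
}

# sentinel for loci whose per-timepoint patterns disagree under pooling
INCONSISTENT = "inconsistent"


def classify_transition(
    before: MethylationState, after: MethylationState
) -> TransitionPattern:
    """Map an ordered state pair to its pattern A-P (total on the 16 pairs)."""
    return _PAIR_TO_PATTERN[(MethylationState(before), MethylationState(after))]


@dataclass(frozen=True)
class TransitionSummary:
    """Per-pattern counts with change-class totals and percentages."""

    pattern_counts: dict[str, int]
    n_total: int
    n_inconsistent: int = 0

    def __post_init__(self) -> None:
        if set(self.pattern_counts) != set(PATTERN_ORDER):
            raise ValueError("pattern_counts must cover exactly the labels A..P")
        if any(c < 0 for c in self.pattern_counts.values()):
            raise ValueError("counts must be non-negative")
        if sum(self.pattern_counts.values()) + self.n_inconsistent != self.n_total:
            raise ValueError("pattern counts (plus inconsistent) must sum to n_total")

    @property
    def class_counts(self) -> dict[str, int]:
        out = {c: 0 for c in CHANGE_CLASSES}
        for label, count in self.pattern_counts.items():
            out[PATTERNS[label].change_class] += count
        return out

    @property
    def class_percentages(self) -> dict[str, float]:
        return {
            c: 100.0 * n / self.n_total for c, n in self.class_counts.items()
        }

    @property
    def changed_fraction_pct(self) -> float:
        """Percentage of loci whose methylation state changed (demeth + meth)."""
        cc = self.class_counts
        return 100.0 * (cc["demethylation"] + cc["methylation"]) / self.n_total


def summarize_pattern_counts(
    pattern_counts: Mapping[str, int], total: int
) -> TransitionSummary:
    """Build a summary from per-pattern counts (e.g. a published table)."""
    counts = {label: int(pattern_counts.get(label, 0)) for label in PATTERN_ORDER}
    if sum(counts.values()) != total:
        raise ValueError(
            f"pattern counts sum to {sum(counts.values())}, expected total {total}"
        )
    return TransitionSummary(pattern_counts=counts, n_total=total)


def compare_conditions(
    dataset: MsapDataset, before_sample: str, after_sample: str
) -> TransitionSummary:
    """Classify every locus's transition between two samples and aggregate."""
    before = dataset.states(before_sample)
    after = dataset.states(after_sample)
    mask = dataset.locus_mask()
    counts = {label: 0 for label in PATTERN_ORDER}
    for b, a in zip(before[mask], after[mask]):
        pattern = classify_transition(MethylationState(b), MethylationState(a))
        counts[pattern.label] += 1
    return TransitionSummary(pattern_counts=counts, n_total=int(mask.sum()))


def consensus_transition(
    patterns: Sequence[TransitionPattern],
) -> TransitionPattern | str:
    """Pool per-timepoint patterns by unanimity.

    Returns the shared pattern when all timepoints agree, otherwise the
    :data:`INCONSISTENT` marker.  Loci marked inconsistent feed the "others"
    class in the recovery accounting.
    """
    if not patterns:
        raise ValueError("cannot pool an empty list of patterns")
    first = patterns[0]
    if all(p.label == first.label for p in patterns[1:]):
        return first
    return INCONSISTENT


@dataclass(frozen=True)
class ContingencyTable:
    """Labelled non-negative integer contingency table, at least 2x2."""

    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape[0] < 2 or counts.shape[1] < 2:
            raise ValueError("contingency table must be at least 2x2")
        if counts.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("labels must match the count matrix shape")
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")
        if (counts.sum(axis=1) == 0).any() or (counts.sum(axis=0) == 0).any():
            raise ValueError("contingency table has an all-zero row or column")
        object.__setattr__(self, "counts", counts.astype(np.int64))


def chi_square_independence(
    table: ContingencyTable,
) -> tuple[float, int, float]:
    """Pearson chi-square test of independence, no continuity correction.

    Returns ``(statistic, degrees_of_freedom, p_value)`` with the p-value from
    the upper tail of the asymptotic chi-square distribution.  Warns when any
    expected cell count falls below 5 (the asymptotic approximation degrades).
    """
    counts = table.counts
    expected = stats.contingency.expected_freq(counts)
    if (expected == 0).any():
        raise ValueError("expected cell count of zero; test undefined")
    if (expected < 5).any():
        warnings.warn(
            "expected cell count below 5; chi-square approximation may be poor",
            stacklevel=2,
        )
    statistic, p_value, dof, _ = stats.chi2_contingency(counts, correction=False)
    return float(statistic), int(dof), float(p_value)
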