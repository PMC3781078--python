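"""Recovery-class taxonomy for (control, stress, recovery) state triples.

After stress relief, each locus's trajectory across the three conditions is
assigned one of nine classes:

* a / b / c — loci demethylated by salinity that, after recovery, returned to
  the control state (a), stayed at the stress state (b), or took some other
  state (c);
* d / e / f — the mirror image for loci methylated by salinity;
* g / h — loci unchanged by salinity whose state changed (g) or did not
  change (h) after recovery;
* i — "others": loci whose per-timepoint classifications disagree when
  several stress/recovery timepoints are pooled.  On any single triple the
  classes a-h are exhaustive, so i can only arise at aggregation level.

The stress-vs-control branch is exactly the change class of the two-condition
transition taxonomy, so the two taxonomies always agree on direction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .states import MethylationState, MsapDataset

__all__ = [
    "RecoveryClass",
    "RecoverySummary",
    "RECOVERY_CLASS_ORDER",
    "classify_recovery",
    "summarize_recovery",
    "triples_for_genotype",
]

RECOVERY_CLASS_ORDER = tuple("abcdefghi")

CLASS_DEFINITIONS = {
    "a": "demethylated by salinity, remethylated after recovery",
    "b": "demethylated by salinity, remaining hypomethylated after recovery",
    "c": "demethylated by salinity, re-methylated in a different pattern after recovery",
    "d": "methylated by salinity, demethylated after recovery",
    "e": "methylated by salinity, remaining methylated after recovery",
    "f": "methylated by salinity, demethylated in a different pattern after recovery",
    "g": "unchanged under salinity, changed after recovery",
    "h": "unchanged under salinity, unchanged after recovery",
    "i": "others (per-timepoint classifications disagree under pooling)",
}


@dataclass(frozen=True)
class RecoveryClass:
    label: str

    def __post_init__(self) -> None:
        if self.label not in RECOVERY_CLASS_ORDER:
            raise ValueError(f"unknown recovery class {self.label!r}")

    @property
    def definition(self) -> str:
        return CLASS_DEFINITIONS[self.label]


def classify_recovery(
    control: MethylationState,
    stress: MethylationState,
    recovery: MethylationState,
) -> RecoveryClass:
    """Assign a (control, stress, recovery) triple to one of classes a-h.

    The branch is decided by comparing stress to control on methylation rank;
    within a branch, "returned to control" and "stayed at stress" are exact
    state equality, and the residual class (c or f) catches any other state.
    """
    control = MethylationState(control)
    stress = MethylationState(stress)
    recovery = MethylationState(recovery)
    if stress.rank < control.rank:  # demethylated by salinity
        if recovery == control:
            return RecoveryClass("a")
        if recovery == stress:
            return RecoveryClass("b")
        return RecoveryClass("c")
    if stress.rank > control.rank:  # methylated by salinity
        if recovery == control:
            return RecoveryClass("d")
        if recovery == stress:
            return RecoveryClass("e")
        return RecoveryClass("f")
    # unchanged by salinity
    return RecoveryClass("h" if recovery == control else "g")


@dataclass(frozen=True)
class RecoverySummary:
    """Counts per class a-i with branch totals and within-branch percentages."""

    class_counts: dict[str, int]
    n_total: int

    def __post_init__(self) -> None:
        if set(self.class_counts) != set(RECOVERY_CLASS_ORDER):
            raise ValueError("class_counts must cover exactly the labels a..i")
        if any(c < 0 for c in self.class_counts.values()):
            raise ValueError("counts must be non-negative")
        if sum(self.class_counts.values()) != self.n_total:
            raise ValueError("class counts must sum to n_total")

    @property
    def demethylation_branch_total(self) -> int:
        return sum(self.class_counts[c] for c in "abc")

    @property
    def methylation_branch_total(self) -> int:
        return sum(self.class_counts[c] for c in "def")

    def within_branch_pct(self, label: str) -> float:
        """Percentage of a class within its own branch (a of a+b+c, etc.)."""
        if label in "abc":
            branch = self.demethylation_branch_total
        elif label in "def":
            branch = self.methylation_branch_total
        elif label in "gh":
            branch = self.class_counts["g"] + self.class_counts["h"]
        else:
            raise ValueError(f"class {label!r} has no within-branch percentage")
        if branch == 0:
            raise ZeroDivisionError(f"branch of class {label!r} is empty")
        return 100.0 * self.class_counts[label] / branch

    @classmethod
    def from_counts(cls, **counts: int) -> "RecoverySummary":
        full = {label: int(counts.get(label, 0)) for label in RECOVERY_CLASS_ORDER}
        return cls(class_counts=full, n_total=sum(full.values()))


def triples_for_genotype(
    dataset: MsapDataset, genotype: str
) -> list[tuple[str, str, str]]:
    """Pair a genotype's samples into (control, stress, recovery) triples.

    Stress and recovery samples are sorted by timepoint and paired
    element-wise (k-th stress with k-th recovery); each pair is matched with
    the control sample at the same sorted index, falling back to the last
    control when there are fewer stress/recovery timepoints than controls.
    """
    by_cond = {
        cond: sorted(
            dataset.select_samples(genotype=genotype, condition=cond),
            key=lambda s: s.timepoint_das,
        )
        for cond in ("control", "stress", "recovery")
    }
    for cond, samples in by_cond.items():
        if not samples:
            raise ValueError(f"genotype {genotype!r} has no {cond} sample")
    n = min(len(by_cond["stress"]), len(by_cond["recovery"]))
    controls = by_cond["control"]
    return [
        (
            controls[min(k, len(controls) - 1)].sample_id,
            by_cond["stress"][k].sample_id,
            by_cond["recovery"][k].sample_id,
        )
        for k in range(n)
    ]


def summarize_recovery(
    dataset: MsapDataset,
    genotype: str | None = None,
    triples: Sequence[tuple[str, str, str]] | None = None,
) -> RecoverySummary:
    """Classify every locus over one or more condition triples and aggregate.

    ``triples`` is a list of (control_id, stress_id, recovery_id) sample
    triples; when omitted it is derived from ``genotype`` via
    :func:`triples_for_genotype`.  With several triples, a locus whose
    per-triple classes disagree is assigned to class i (unanimity pooling).
    """
    if triples is None:
        if genotype is None:
            raise ValueError("provide either a genotype or explicit triples")
        triples = triples_for_genotype(dataset, genotype)
    if not triples:
        raise ValueError("at least one (control, stress, recovery) triple required")

    mask = dataset.locus_mask()
    per_triple = []
    for control_id, stress_id, recovery_id in triples:
        c = dataset.states(control_id)[mask]
        s = dataset.states(stress_id)[mask]
        r = dataset.states(recovery_id)[mask]
        per_triple.append(
            [
                classify_recovery(
                    MethylationState(ci), MethylationState(si), MethylationState(ri)
                ).label
                for ci, si, ri in zip(c, s, r)
            ]
        )

    counts = {label: 0 for label in RECOVERY_CLASS_ORDER}
    for locus_classes in zip(*per_triple):
        first = locus_classes[0]
        if all(c == first for c in locus_classes[1:]):
            counts[first] += 1
        else:
            counts["i"] += 1
    return RecoverySummary(class_counts=counts, n_total=int(mask.sum()))
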