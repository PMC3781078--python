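"""Per-locus methylation-state decoding from paired isoschizomer lanes.

MSAP profiles a locus with two parallel digests of the same DNA: EcoRI+HpaII
and EcoRI+MspI.  HpaII and MspI both cut CCGG but are blocked by different
cytosine-methylation configurations, so the (HpaII, MspI) band presence/absence
pair at a locus decodes into one of four epigenotypes:

=====  ======  =====  ==============================================
state  HpaII   MspI   interpretation
=====  ======  =====  ==============================================
I      1       1      unmethylated
II     1       0      hemi-methylated (one strand only)
III    0       1      full CG (internal cytosine) methylation
IV     0       0      full methylation at both cytosines
=====  ======  =====  ==============================================

States carry an integer methylation rank (I=0 < II=1 < III=2 < IV=3) that the
transition and recovery taxonomies compare to decide whether a change is a
demethylation (rank decreases) or a methylation (rank increases).
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "MethylationState",
    "SampleMeta",
    "MsapDataset",
    "MethylationSummary",
    "state_from_lanes",
    "lanes_from_state",
    "summarize_sample",
    "average_summaries",
]


class MethylationState(enum.IntEnum):
    """One of the four MSAP epigenotypes, ordered by methylation level."""

    I = 0
    II = 1
    III = 2
    IV = 3

    @property
    def rank(self) -> int:
        return int(self)

    @property
    def interpretation(self) -> str:
        return _INTERPRETATION[self]

    @property
    def lanes(self) -> tuple[int, int]:
        """(hpaii_present, mspi_present) encoding of this state."""
        return _STATE_TO_LANES[self]


_INTERPRETATION = {
    MethylationState.I: "unmethylated",
    MethylationState.II: "hemi-methylated",
    MethylationState.III: "full CG (internal cytosine) methylation",
    MethylationState.IV: "full methylation at both cytosines",
}

# Fixed bijection between lane pairs and states; not configurable.
_STATE_TO_LANES = {
    MethylationState.I: (1, 1),
    MethylationState.II: (1, 0),
    MethylationState.III: (0, 1),
    MethylationState.IV: (0, 0),
}
_LANES_TO_STATE = {v: k for k, v in _STATE_TO_LANES.items()}

CONDITIONS = ("control", "stress", "recovery")


def _check_binary(value: object, name: str) -> int:
    if isinstance(value, bool):
        return int(value)
    if isinstance(value, (int, np.integer)) and value in (0, 1):
        return int(value)
    raise ValueError(f"{name} must be 0 or 1, got {value!r}")


def state_from_lanes(hpaii_present: int, mspi_present: int) -> MethylationState:
    """Decode a (HpaII, MspI) band-presence pair into a methylation state.

    Parameters
    ----------
    hpaii_present, mspi_present
        Binary flags: band present (1) or absent (0) in the EcoRI/HpaII and
        EcoRI/MspI lanes respectively.
    """
    h = _check_binary(hpaii_present, "hpaii_present")
    m = _check_binary(mspi_present, "mspi_present")
    return _LANES_TO_STATE[(h, m)]


def lanes_from_state(state: MethylationState) -> tuple[int, int]:
    """Inverse of :func:`state_from_lanes`; round-trips exactly."""
    return _STATE_TO_LANES[MethylationState(state)]


@dataclass(frozen=True)
class SampleMeta:
    """Metadata for one biological sample (one pair of enzyme lanes)."""

    sample_id: str
    genotype: str
    condition: str
    timepoint_das: int
    replicate: int | None = None

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(
                f"condition must be one of {CONDITIONS}, got {self.condition!r}"
            )
        if self.timepoint_das <= 0:
            raise ValueError("timepoint_das must be a positive integer")


@dataclass
class MsapDataset:
    """Locus x sample binary band matrix with two enzyme lanes per sample.

    ``presence`` has shape (n_loci, n_samples, 2); the last axis is
    (HpaII, MspI).  All values are strictly 0/1 — missing lanes are rejected,
    matching a scoring protocol that keeps only clear, reproducible bands.
    """

    locus_ids: list[str]
    samples: list[SampleMeta]
    presence: np.ndarray
    exclude_all_type_iv: bool = False

    def __post_init__(self) -> None:
        self.presence = np.asarray(self.presence)
        if len(self.locus_ids) == 0:
            raise ValueError("dataset must contain at least one locus")
        if len(set(self.locus_ids)) != len(self.locus_ids):
            raise ValueError("locus_ids must be unique")
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("sample_id must be unique within a dataset")
        expected = (len(self.locus_ids), len(self.samples), 2)
        if self.presence.shape != expected:
            raise ValueError(
                f"presence must have shape {expected}, got {self.presence.shape}"
            )
        if not np.isin(self.presence, (0, 1)).all():
            raise ValueError("presence values must be strictly 0 or 1")
        self.presence = self.presence.astype(np.uint8)

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)

    def sample_index(self, sample_id: str) -> int:
        for i, s in enumerate(self.samples):
            if s.sample_id == sample_id:
                return i
        raise KeyError(f"unknown sample_id: {sample_id!r}")

    def sample_meta(self, sample_id: str) -> SampleMeta:
        return self.samples[self.sample_index(sample_id)]

    def states(self, sample_id: str) -> np.ndarray:
        """Per-locus methylation states for one sample (ints 0..3, rank order)."""
        lanes = self.presence[:, self.sample_index(sample_id), :]
        # rank = 3 - 2*hpaii - mspi reproduces the I..IV bijection
        return (3 - 2 * lanes[:, 0].astype(int) - lanes[:, 1].astype(int)).astype(
            np.int8
        )

    def locus_mask(self) -> np.ndarray:
        """Boolean mask of loci retained under ``exclude_all_type_iv``."""
        if not self.exclude_all_type_iv:
            return np.ones(self.n_loci, dtype=bool)
        all_iv = (self.presence == 0).all(axis=(1, 2))
        return ~all_iv

    def select_samples(
        self,
        genotype: str | None = None,
        condition: str | None = None,
        timepoint_das: int | None = None,
    ) -> list[SampleMeta]:
        out = []
        for s in self.samples:
            if genotype is not None and s.genotype != genotype:
                continue
            if condition is not None and s.condition != condition:
                continue
            if timepoint_das is not None and s.timepoint_das != timepoint_das:
                continue
            out.append(s)
        return out


@dataclass(frozen=True)
class MethylationSummary:
    """Per-sample band-type counts and the derived percentage statistics.

    ``msap_pct`` is the total methylation level: the percentage of scored loci
    whose state is II, III, or IV.  ``fully_pct`` covers III+IV and
    ``hemi_pct`` covers II, so ``msap_pct = fully_pct + hemi_pct`` up to
    floating-point error.  All arithmetic is on unrounded floats; round only
    at report time.
    """

    sample_id: str
    n_type: dict[str, int]
    n_total: int
    n_methylated: int = field(init=False)
    n_fully: int = field(init=False)
    n_hemi: int = field(init=False)
    msap_pct: float = field(init=False)
    fully_pct: float = field(init=False)
    hemi_pct: float = field(init=False)

    def __post_init__(self) -> None:
        counts = self.n_type
        if set(counts) != {"I", "II", "III", "IV"}:
            raise ValueError("n_type must have exactly the keys I, II, III, IV")
        if any(c < 0 for c in counts.values()):
            raise ValueError("counts must be non-negative")
        if sum(counts.values()) != self.n_total:
            raise ValueError("type counts must sum to n_total")
        if self.n_total == 0:
            raise ValueError("empty locus set")
        object.__setattr__(self, "n_hemi", counts["II"])
        object.__setattr__(self, "n_fully", counts["III"] + counts["IV"])
        object.__setattr__(self, "n_methylated", self.n_hemi + self.n_fully)
        object.__setattr__(self, "msap_pct", 100.0 * self.n_methylated / self.n_total)
        object.__setattr__(self, "fully_pct", 100.0 * self.n_fully / self.n_total)
        object.__setattr__(self, "hemi_pct", 100.0 * self.n_hemi / self.n_total)

    @classmethod
    def from_counts(
        cls, n_i: int, n_ii: int, n_iii: int, n_iv: int, sample_id: str = ""
    ) -> "MethylationSummary":
        """Build a summary directly from the four band-type counts."""
        return cls(
            sample_id=sample_id,
            n_type={"I": n_i, "II": n_ii, "III": n_iii, "IV": n_iv},
            n_total=n_i + n_ii + n_iii + n_iv,
        )


def summarize_sample(dataset: MsapDataset, sample_id: str) -> MethylationSummary:
    """Tally band types I-IV for one sample and derive the percentage rows."""
    mask = dataset.locus_mask()
    if not mask.any():
        raise ValueError("empty locus set after type-IV exclusion")
    states = dataset.states(sample_id)[mask]
    counts = {
        name: int((states == st.rank).sum())
        for name, st in zip(("I", "II", "III", "IV"), MethylationState)
    }
    return MethylationSummary(
        sample_id=sample_id, n_type=counts, n_total=int(mask.sum())
    )


@dataclass(frozen=True)
class AveragedSummary:
    """Arithmetic means of the percentage rows over a group of samples."""

    n_samples: int
    msap_pct: float
    fully_pct: float
    hemi_pct: float


def average_summaries(summaries: Sequence[MethylationSummary]) -> AveragedSummary:
    """Average msap/fully/hemi percentages over samples, on unrounded values."""
    summaries = list(summaries)
    if not summaries:
        raise ValueError("cannot average an empty list of summaries")
    totals = {s.n_total for s in summaries}
    if len(totals) > 1:
        warnings.warn(
            f"averaging summaries with differing locus totals: {sorted(totals)}",
            stacklevel=2,
        )
    return AveragedSummary(
        n_samples=len(summaries),
        msap_pct=float(np.mean([s.msap_pct for s in summaries])),
        fully_pct=float(np.mean([s.fully_pct for s in summaries])),
        hemi_pct=float(np.mean([s.hemi_pct for s in summaries])),
    )
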