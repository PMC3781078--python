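"""Bisulfite cytosine-context methylation calling on the top strand.

Sodium bisulfite converts unmethylated cytosine to uracil (read as T after
PCR) while 5-methylcytosine resists conversion.  Comparing a bisulfite-treated
clone sequence against the untreated reference therefore calls methylation at
every reference C: a retained C is methylated, a C-to-T conversion is
unmethylated, and any other base is ambiguous (sequencing error or SNP).

Plant methylation is tracked in three sequence contexts — CG, CHG, CHH
(H = A, T or C) — served by distinct maintenance pathways, so calls are
tallied per context.  The per-context methylation level is

    %mC = 100 * (methylated cytosines) / (total cytosines of that context)

with ambiguous calls and undetermined contexts excluded from both numerator
and denominator.  Only the top strand is analysed; clone sequences must be
pre-aligned to the reference and gap-free.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Sequence

__all__ = [
    "CytosineContext",
    "CallStatus",
    "CytosineCall",
    "BisulfiteSummary",
    "classify_context",
    "call_cytosines",
    "summarize_contexts",
    "locate_ccgg_sites",
]

_VALID_BASES = frozenset("ACGTN")
_H = frozenset("ATC")  # H = A, T or C


class CytosineContext(str, enum.Enum):
    CG = "CG"
    CHG = "CHG"
    CHH = "CHH"
    UNDETERMINED = "UNDETERMINED"


class CallStatus(str, enum.Enum):
    METHYLATED = "methylated"
    UNMETHYLATED = "unmethylated"
    AMBIGUOUS = "ambiguous"


@dataclass(frozen=True)
class CytosineCall:
    """Methylation call at one reference-C position (0-based, top strand)."""

    position: int
    context: CytosineContext
    status: CallStatus


def _validate_sequence(seq: str, name: str) -> str:
    seq = seq.upper()
    if not seq:
        raise ValueError(f"{name} must be non-empty")
    bad = set(seq) - _VALID_BASES
    if bad:
        raise ValueError(f"{name} contains invalid bases: {sorted(bad)}")
    return seq


def classify_context(ref: str, position: int) -> CytosineContext:
    """Classify the context of the reference C at ``position``.

    CG if the next base is G; CHG if the next base is H and the one after is
    G; CHH if both following bases are H.  Positions too close to the 3' end
    for the required lookahead, or with an N in the window, are UNDETERMINED.
    """
    ref = _validate_sequence(ref, "reference")
    if not 0 <= position < len(ref):
        raise ValueError(f"position {position} out of range for length {len(ref)}")
    if ref[position] != "C":
        raise ValueError(f"reference base at position {position} is {ref[position]}, not C")
    if position + 1 >= len(ref):
        return CytosineContext.UNDETERMINED
    nxt = ref[position + 1]
    if nxt == "G":
        return CytosineContext.CG
    if nxt not in _H:  # N in the lookahead window
        return CytosineContext.UNDETERMINED
    if position + 2 >= len(ref):
        return CytosineContext.UNDETERMINED
    nxt2 = ref[position + 2]
    if nxt2 == "G":
        return CytosineContext.CHG
    if nxt2 in _H:
        return CytosineContext.CHH
    return CytosineContext.UNDETERMINED


def call_cytosines(ref: str, bis: str) -> list[CytosineCall]:
    """Call methylation at every reference C against one bisulfite clone.

    ``bis`` must be the same length as ``ref`` (pre-aligned, gap-free, same
    strand).  C in the clone means methylated, T means unmethylated, anything
    else is ambiguous.  Non-C reference positions produce no call.
    """
    ref = _validate_sequence(ref, "reference")
    bis = _validate_sequence(bis, "bisulfite sequence")
    if len(bis) != len(ref):
        raise ValueError(
            f"bisulfite sequence length {len(bis)} != reference length {len(ref)}"
        )
    calls = []
    for i, base in enumerate(ref):
        if base != "C":
            continue
        b = bis[i]
        if b == "C":
            status = CallStatus.METHYLATED
        elif b == "T":
            status = CallStatus.UNMETHYLATED
        else:
            status = CallStatus.AMBIGUOUS
        calls.append(CytosineCall(position=i, context=classify_context(ref, i), status=status))
    return calls


@dataclass(frozen=True)
class BisulfiteSummary:
    """Per-context methylation percentages pooled over clones.

    ``pct_methylated[context]`` is absent (not 0) when a context has no
    informative calls.  ``n_excluded`` counts ambiguous-status and
    undetermined-context calls dropped from the percentages.
    """

    n_methylated: dict[str, int]
    n_total: dict[str, int]
    n_excluded: int

    @property
    def pct_methylated(self) -> dict[str, float]:
        return {
            ctx: 100.0 * self.n_methylated[ctx] / self.n_total[ctx]
            for ctx in self.n_total
            if self.n_total[ctx] > 0
        }

    @property
    def overall_pct(self) -> float | None:
        total = sum(self.n_total.values())
        if total == 0:
            return None
        return 100.0 * sum(self.n_methylated.values()) / total


def summarize_contexts(calls_per_clone: Sequence[Iterable[CytosineCall]]) -> BisulfiteSummary:
    """Pool per-clone calls and compute %mC per context by the count formula."""
    clones = [list(c) for c in calls_per_clone]
    if not clones or all(not c for c in clones):
        raise ValueError("no cytosine calls to summarize")
    contexts = ("CG", "CHG", "CHH")
    n_meth = {ctx: 0 for ctx in contexts}
    n_total = {ctx: 0 for ctx in contexts}
    n_excluded = 0
    for clone in clones:
        for call in clone:
            if (
                call.context is CytosineContext.UNDETERMINED
                or call.status is CallStatus.AMBIGUOUS
            ):
                n_excluded += 1
                continue
            ctx = call.context.value
            n_total[ctx] += 1
            if call.status is CallStatus.METHYLATED:
                n_meth[ctx] += 1
    return BisulfiteSummary(n_methylated=n_meth, n_total=n_total, n_excluded=n_excluded)


def locate_ccgg_sites(ref: str) -> list[int]:
    """0-based start positions of every exact CCGG occurrence (overlaps allowed).

    CCGG is the HpaII/MspI recognition site, enabling cross-checks between
    MSAP band states and bisulfite calls at restriction-site cytosines.
    """
    ref = _validate_sequence(ref, "reference")
    positions = []
    start = 0
    while True:
        i = ref.find("CCGG", start)
        if i == -1:
            return positions
        positions.append(i)
        start = i + 1
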