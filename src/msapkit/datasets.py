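"""Reference count tables from the rapeseed salt-stress MSAP study.

Two cultivars — salt-tolerant Exagone (772 scored loci) and salt-sensitive
Toccata (783 loci) — were profiled under control (water), salinity-stress
(100 mmol/L NaCl) and post-stress recovery conditions at several timepoints
(days after sowing, DAS).  These are the published summary counts, embedded
as inputs for re-analysis: per-sample band-type counts (I-IV), per-pattern
transition counts (A-P, control vs stress), and recovery-class counts (a-i).
"""

from __future__ import annotations

from .patterns import PATTERN_ORDER, TransitionSummary, summarize_pattern_counts
from .recovery import RecoverySummary
from .states import MethylationSummary

__all__ = [
    "BAND_TYPE_COUNTS",
    "TRANSITION_COUNTS",
    "RECOVERY_COUNTS",
    "band_type_summaries",
    "transition_summary",
    "recovery_summary",
]

# (genotype, condition, timepoint DAS) -> (I, II, III, IV) band-type counts
BAND_TYPE_COUNTS: dict[tuple[str, str, int], tuple[int, int, int, int]] = {
    ("Exagone", "control", 4): (404, 12, 144, 212),
    ("Exagone", "control", 7): (418, 11, 142, 201),
    ("Exagone", "control", 14): (414, 7, 148, 203),
    ("Exagone", "control", 15): (410, 8, 148, 206),
    ("Exagone", "control", 17): (416, 9, 145, 202),
    ("Exagone", "stress", 7): (474, 20, 138, 140),
    ("Exagone", "stress", 14): (479, 19, 134, 140),
    ("Exagone", "recovery", 15): (389, 22, 124, 237),
    ("Exagone", "recovery", 17): (388, 24, 128, 232),
    ("Toccata", "control", 4): (442, 23, 149, 169),
    ("Toccata", "control", 7): (462, 20, 141, 160),
    ("Toccata", "control", 14): (472, 18, 139, 154),
    ("Toccata", "control", 15): (470, 17, 140, 156),
    ("Toccata", "control", 17): (463, 19, 143, 158),
    ("Toccata", "stress", 7): (409, 37, 153, 184),
    ("Toccata", "stress", 14): (395, 44, 168, 176),
    ("Toccata", "recovery", 15): (390, 25, 127, 241),
    ("Toccata", "recovery", 17): (389, 29, 130, 235),
}

# genotype -> per-pattern A..P counts, control vs salinity stress
TRANSITION_COUNTS: dict[str, dict[str, int]] = {
    "Exagone": dict(
        zip(PATTERN_ORDER, (4, 133, 366, 117, 1, 6, 97, 0, 15, 2, 2, 1, 23, 0, 2, 3))
    ),
    "Toccata": dict(
        zip(PATTERN_ORDER, (10, 136, 386, 142, 0, 0, 6, 0, 22, 4, 10, 5, 56, 0, 6, 0))
    ),
}

# genotype -> recovery-class a..i counts
RECOVERY_COUNTS: dict[str, dict[str, int]] = {
    "Exagone": dict(
        a=87, b=32, c=2, d=4, e=21, f=6, g=105, h=493, i=22
    ),
    "Toccata": dict(
        a=27, b=5, c=0, d=28, e=22, f=27, g=81, h=575, i=18
    ),
}


def band_type_summaries(
    genotype: str, condition: str | None = None
) -> list[MethylationSummary]:
    """Per-sample methylation summaries recomputed from the published counts."""
    out = []
    for (g, cond, das), (i, ii, iii, iv) in BAND_TYPE_COUNTS.items():
        if g != genotype:
            continue
        if condition is not None and cond != condition:
            continue
        out.append(
            MethylationSummary.from_counts(
                i, ii, iii, iv, sample_id=f"{g}_{cond}_{das}"
            )
        )
    if not out:
        raise KeyError(f"no published counts for {genotype!r}/{condition!r}")
    return out


def transition_summary(genotype: str) -> TransitionSummary:
    """Control-vs-stress transition summary recomputed from published counts."""
    counts = TRANSITION_COUNTS[genotype]
    return summarize_pattern_counts(counts, total=sum(counts.values()))


def recovery_summary(genotype: str) -> RecoverySummary:
    """Recovery-class summary recomputed from the published class counts."""
    return RecoverySummary.from_counts(**RECOVERY_COUNTS[genotype])
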