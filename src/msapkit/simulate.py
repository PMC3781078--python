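"""Seeded simulators for MSAP band matrices and bisulfite clone sets.

The study design these emulate: two rapeseed genotypes scored at ~770-780
CCGG loci, with control, salinity-stress and post-stress recovery conditions
sampled at a handful of timepoints (days after sowing).  The MSAP simulator
draws per-locus methylation states either independently per condition
(marginal mode) or as a control -> stress -> recovery Markov chain (kernel
mode), then derives the two enzyme-lane flags from each state.  The bisulfite
simulator draws a reference sequence at a given GC content, assigns each
reference cytosine a true methylation state by its context, and emits clones
with imperfect conversion: an unmethylated C reads T with probability equal
to the conversion efficiency, else C.

Everything is driven by ``numpy.random.default_rng(seed)``: identical configs
and seeds give byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .states import CONDITIONS, MethylationState, MsapDataset, SampleMeta

__all__ = [
    "MsapSimConfig",
    "BisulfiteSimConfig",
    "simulate_msap",
    "simulate_bisulfite",
]

# state -> (hpaii, mspi) lane pair, indexed by rank
_LANES_BY_RANK = np.array([[1, 1], [1, 0], [0, 1], [0, 0]], dtype=np.uint8)

# Study-layout defaults: controls at every sampled timepoint, stress from
# 7 DAS, recovery timepoints after stress relief at 14 DAS.
DEFAULT_TIMEPOINTS = {
    "control": (4, 7, 14, 15, 17),
    "stress": (7, 14),
    "recovery": (15, 17),
}


def _check_probs(p, name: str) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.shape != (4,):
        raise ValueError(f"{name} must be a probability 4-vector over states I-IV")
    if (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"{name} must be non-negative and sum to 1")
    return p


@dataclass
class MsapSimConfig:
    """Configuration for the MSAP band-matrix simulator.

    ``state_probs`` maps each condition to a probability 4-vector over states
    I-IV.  When ``transition_kernel`` (control->stress) is given, stress
    states are drawn by chaining through the kernel instead of marginally;
    ``recovery_kernel`` (stress->recovery) likewise.  Kernel mode assigns one
    state chain per locus, shared across a condition's timepoints; marginal
    mode redraws independently per sample, so replicate timepoints can
    disagree (exercising unanimity pooling).
    """

    n_loci: int = 772
    genotypes: tuple[str, ...] = ("Exagone",)
    state_probs: dict[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: {
            "control": (0.535, 0.016, 0.187, 0.262),
            "stress": (0.617, 0.025, 0.176, 0.182),
            "recovery": (0.503, 0.030, 0.163, 0.304),
        }
    )
    transition_kernel: np.ndarray | None = None
    recovery_kernel: np.ndarray | None = None
    timepoints: dict[str, tuple[int, ...]] = field(
        default_factory=lambda: dict(DEFAULT_TIMEPOINTS)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_loci <= 0:
            raise ValueError("n_loci must be positive")
        if not self.genotypes:
            raise ValueError("at least one genotype required")
        for cond in self.timepoints:
            if cond not in CONDITIONS:
                raise ValueError(f"unknown condition {cond!r}")
        for cond, p in self.state_probs.items():
            _check_probs(p, f"state_probs[{cond}]")
        for name in ("transition_kernel", "recovery_kernel"):
            k = getattr(self, name)
            if k is not None:
                k = np.asarray(k, dtype=float)
                if k.shape != (4, 4) or (k < 0).any() or np.abs(k.sum(axis=1) - 1).max() > 1e-9:
                    raise ValueError(f"{name} must be a 4x4 row-stochastic matrix")
                setattr(self, name, k)
        if (self.transition_kernel is None) != (self.recovery_kernel is None) and (
            "recovery" in self.timepoints and self.recovery_kernel is None
            and self.transition_kernel is not None
        ):
            raise ValueError(
                "kernel mode needs both transition_kernel and recovery_kernel "
                "when recovery timepoints are simulated"
            )


def simulate_msap(config: MsapSimConfig) -> MsapDataset:
    """Draw a seeded synthetic MSAP dataset under the configured state laws."""
    rng = np.random.default_rng(config.seed)
    samples: list[SampleMeta] = []
    columns: list[np.ndarray] = []

    kernel_mode = config.transition_kernel is not None
    for genotype in config.genotypes:
        if kernel_mode:
            chain = _draw_chain(config, rng)
        for cond in ("control", "stress", "recovery"):
            for das in config.timepoints.get(cond, ()):
                if kernel_mode:
                    states = chain[cond]
                else:
                    p = _check_probs(
                        config.state_probs[cond], f"state_probs[{cond}]"
                    )
                    states = rng.choice(4, size=config.n_loci, p=p)
                samples.append(
                    SampleMeta(
                        sample_id=f"{genotype}_{cond}_{das}",
                        genotype=genotype,
                        condition=cond,
                        timepoint_das=das,
                    )
                )
                columns.append(_LANES_BY_RANK[states])

    presence = np.stack(columns, axis=1)
    locus_ids = [f"L{i:05d}" for i in range(config.n_loci)]
    return MsapDataset(locus_ids=locus_ids, samples=samples, presence=presence)


def _draw_chain(config: MsapSimConfig, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """One control->stress->recovery state chain per locus (kernel mode)."""
    p0 = _check_probs(config.state_probs["control"], "state_probs[control]")
    control = rng.choice(4, size=config.n_loci, p=p0)
    out = {"control": control}
    stress = np.array(
        [rng.choice(4, p=config.transition_kernel[s]) for s in control]
    )
    out["stress"] = stress
    if config.recovery_kernel is not None:
        out["recovery"] = np.array(
            [rng.choice(4, p=config.recovery_kernel[s]) for s in stress]
        )
    return out


@dataclass
class BisulfiteSimConfig:
    """Configuration for the bisulfite clone-set simulator.

    True methylation is assigned once at the reference level (all clones share
    the true states, differing only through conversion noise), which keeps the
    conversion efficiency identifiable from the unmethylated-site floor.
    """

    ref_length: int = 5000
    gc_content: float = 0.4
    p_meth: dict[str, float] = field(
        default_factory=lambda: {"CG": 0.8, "CHG": 0.3, "CHH": 0.05}
    )
    conversion_efficiency: float = 0.99
    n_clones: int = 15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ref_length <= 0 or self.n_clones <= 0:
            raise ValueError("ref_length and n_clones must be positive")
        if not 0 < self.gc_content < 1:
            raise ValueError("gc_content must be in (0, 1)")
        if not 0 < self.conversion_efficiency <= 1:
            raise ValueError("conversion_efficiency must be in (0, 1]")
        for ctx, p in self.p_meth.items():
            if not 0 <= p <= 1:
                raise ValueError(f"p_meth[{ctx}] must be in [0, 1]")


def simulate_bisulfite(
    config: BisulfiteSimConfig,
) -> tuple[str, list[str], list[dict]]:
    """Draw a reference, per-C truth, and bisulfite clone sequences.

    Returns ``(reference, clones, truth)`` where ``truth`` has one record per
    reference C: ``{"position", "context", "methylated"}``.  Cytosines with an
    UNDETERMINED context are never truly methylated (they are excluded from
    summaries anyway).
    """
    from .bisulfite import CytosineContext, classify_context

    rng = np.random.default_rng(config.seed)
    gc = config.gc_content
    ref = "".join(
        rng.choice(
            np.array(list("ACGT")),
            size=config.ref_length,
            p=[(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2],
        )
    )

    truth: list[dict] = []
    for i, base in enumerate(ref):
        if base != "C":
            continue
        ctx = classify_context(ref, i)
        p = config.p_meth.get(ctx.value, 0.0)
        if ctx is CytosineContext.UNDETERMINED:
            p = 0.0
        truth.append(
            {
                "position": i,
                "context": ctx.value,
                "methylated": bool(rng.random() < p),
            }
        )

    clones = []
    meth_by_pos = {t["position"]: t["methylated"] for t in truth}
    for _ in range(config.n_clones):
        seq = list(ref)
        for pos, methylated in meth_by_pos.items():
            if methylated:
                continue  # 5mC resists conversion, reads C
            if rng.random() < config.conversion_efficiency:
                seq[pos] = "T"
        clones.append("".join(seq))
    return ref, clones, truth
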