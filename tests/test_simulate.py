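"""Seeded simulators: determinism, parameter recovery, pipeline closure."""

import numpy as np
import pytest

from msapkit import (
    BisulfiteSimConfig,
    MsapSimConfig,
    average_summaries,
    compare_conditions,
    simulate_bisulfite,
    simulate_msap,
    summarize_recovery,
    summarize_sample,
)

EXAGONE_CONTROL_PROBS = (0.535, 0.016, 0.187, 0.262)


def small_config(**kwargs):
    defaults = dict(
        n_loci=200,
        genotypes=("G1",),
        timepoints={"control": (4,), "stress": (7, 14), "recovery": (15,)},
        seed=5,
    )
    defaults.update(kwargs)
    return MsapSimConfig(**defaults)


def test_msap_determinism_byte_identical():
    ds1 = simulate_msap(small_config())
    ds2 = simulate_msap(small_config())
    assert np.array_equal(ds1.presence, ds2.presence)
    assert [s.sample_id for s in ds1.samples] == [s.sample_id for s in ds2.samples]
    ds3 = simulate_msap(small_config(seed=6))
    assert not np.array_equal(ds1.presence, ds3.presence)


def test_degenerate_all_unmethylated():
    config = small_config(
        state_probs={
            "control": (1.0, 0.0, 0.0, 0.0),
            "stress": (1.0, 0.0, 0.0, 0.0),
            "recovery": (1.0, 0.0, 0.0, 0.0),
        }
    )
    ds = simulate_msap(config)
    assert (ds.presence == 1).all()
    assert summarize_sample(ds, ds.samples[0].sample_id).msap_pct == 0.0


def test_msap_percentage_recovered_at_study_scale():
    # empirical control state frequencies imply MSAP% = 100*(1-0.535) = 46.5;
    # mean over 20 seeds should sit within 3 SE of the binomial expectation
    probs = {
        "control": EXAGONE_CONTROL_PROBS,
        "stress": EXAGONE_CONTROL_PROBS,
        "recovery": EXAGONE_CONTROL_PROBS,
    }
    n_loci, n_seeds = 772, 20
    values = []
    for seed in range(n_seeds):
        config = MsapSimConfig(
            n_loci=n_loci,
            genotypes=("G1",),
            state_probs=probs,
            timepoints={"control": (4,), "stress": (7,), "recovery": (15,)},
            seed=seed,
        )
        ds = simulate_msap(config)
        values.append(summarize_sample(ds, "G1_control_4").msap_pct)
    p = 1 - EXAGONE_CONTROL_PROBS[0]
    se_mean = 100 * (p * (1 - p) / n_loci) ** 0.5 / n_seeds**0.5
    assert np.mean(values) == pytest.approx(100 * p, abs=3 * se_mean)


def test_state_frequency_law_of_large_numbers():
    config = small_config(n_loci=20000, seed=11)
    ds = simulate_msap(config)
    states = ds.states("G1_control_4")
    freqs = np.bincount(states, minlength=4) / len(states)
    for observed, expected in zip(freqs, config.state_probs["control"]):
        se = (expected * (1 - expected) / 20000) ** 0.5 if expected > 0 else 0
        assert observed == pytest.approx(expected, abs=max(3 * se, 1e-12))


def test_kernel_mode_chains_conditions():
    # identity kernels freeze the chain: every condition repeats control
    eye = np.eye(4)
    config = small_config(transition_kernel=eye, recovery_kernel=eye)
    ds = simulate_msap(config)
    control = ds.states("G1_control_4")
    for sid in ("G1_stress_7", "G1_stress_14", "G1_recovery_15"):
        assert np.array_equal(ds.states(sid), control)


def test_kernel_mode_demethylating_kernel_shifts_ranks_down():
    # kernel sending every state to I: stress must be all-unmethylated
    to_i = np.zeros((4, 4))
    to_i[:, 0] = 1.0
    config = small_config(transition_kernel=to_i, recovery_kernel=np.eye(4))
    ds = simulate_msap(config)
    assert (ds.states("G1_stress_7") == 0).all()


def test_invalid_configs_rejected():
    with pytest.raises(ValueError, match="sum to 1"):
        small_config(
            state_probs={
                "control": (0.5, 0.5, 0.5, 0.0),
                "stress": (1, 0, 0, 0),
                "recovery": (1, 0, 0, 0),
            }
        )
    with pytest.raises(ValueError, match="row-stochastic"):
        small_config(transition_kernel=np.ones((4, 4)), recovery_kernel=np.eye(4))
    with pytest.raises(ValueError):
        MsapSimConfig(n_loci=0)
    with pytest.raises(ValueError):
        BisulfiteSimConfig(gc_content=0.0)
    with pytest.raises(ValueError):
        BisulfiteSimConfig(conversion_efficiency=0.0)
    with pytest.raises(ValueError):
        BisulfiteSimConfig(p_meth={"CG": 1.5})


def test_simulated_dataset_flows_through_whole_pipeline():
    ds = simulate_msap(small_config())
    summaries = [summarize_sample(ds, s.sample_id) for s in ds.samples]
    avg = average_summaries(summaries)
    assert 0 <= avg.msap_pct <= 100
    t = compare_conditions(ds, "G1_control_4", "G1_stress_7")
    assert sum(t.class_counts.values()) == ds.n_loci
    r = summarize_recovery(ds, genotype="G1")
    assert r.n_total == ds.n_loci


def test_bisulfite_determinism_and_degenerate_rates():
    config = BisulfiteSimConfig(ref_length=500, n_clones=3, seed=3)
    out1 = simulate_bisulfite(config)
    out2 = simulate_bisulfite(BisulfiteSimConfig(ref_length=500, n_clones=3, seed=3))
    assert out1 == out2

    all_meth = BisulfiteSimConfig(
        ref_length=400,
        p_meth={"CG": 1.0, "CHG": 1.0, "CHH": 1.0},
        conversion_efficiency=1.0,
        n_clones=2,
        seed=1,
    )
    ref, clones, truth = simulate_bisulfite(all_meth)
    determined = [t for t in truth if t["context"] != "UNDETERMINED"]
    assert all(t["methylated"] for t in determined)
    for clone in clones:
        for t in determined:
            assert clone[t["position"]] == "C"

    none_meth = BisulfiteSimConfig(
        ref_length=400,
        p_meth={"CG": 0.0, "CHG": 0.0, "CHH": 0.0},
        conversion_efficiency=1.0,
        n_clones=2,
        seed=1,
    )
    ref, clones, truth = simulate_bisulfite(none_meth)
    for clone in clones:
        for t in truth:
            assert clone[t["position"]] == "T"


def test_bisulfite_gc_content_controls_composition():
    config = BisulfiteSimConfig(ref_length=20000, gc_content=0.6, seed=2, n_clones=1)
    ref, _, _ = simulate_bisulfite(config)
    gc = sum(ref.count(b) for b in "GC") / len(ref)
    assert gc == pytest.approx(0.6, abs=0.02)
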