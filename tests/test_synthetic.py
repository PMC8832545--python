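"""Generator ground-truth rules: spike placement, PSC statistics, drug
compositionality, Poisson trains, morphology validity, transcript panels."""

import numpy as np
import pytest

from pvcircuit import synthetic as syn
from pvcircuit.swc import SWCError


# ---------------------------------------------------------------- step sweeps


@pytest.mark.parametrize("phenotype", syn.PHENOTYPES)
def test_spike_placement_follows_phenotype_rule(phenotype, step_protocol):
    cell = syn.CellSpec(phenotype=phenotype, noise_sd=0.0)
    ts = syn.simulate_step_sweeps(cell, step_protocol, seed=1)
    dur = step_protocol.step_duration
    onset = step_protocol.baseline_duration
    for si, amp in enumerate(step_protocol.step_amplitudes):
        times = ts.annotations.query("sweep == @si").time_ms.to_numpy() - onset
        if amp < cell.rheobase_pa:
            assert times.size == 0
            continue
        frac = times / dur
        if phenotype == "SS":
            assert times.size == 1
        elif phenotype == "TF":
            assert frac[-1] >= 0.90  # last spike within the final 10%
            assert frac[-1] - frac[0] >= 0.90
            assert times.size >= 4
        elif phenotype == "IB":
            assert times.size >= 2 and frac[-1] <= 0.20
        elif phenotype == "RA":
            assert times.size >= 3 and frac[-1] <= 0.20
        elif phenotype == "DF":
            assert frac[0] >= 0.40


def test_df_first_spike_latency_rule_seed1(step_protocol):
    ts = syn.simulate_step_sweeps(
        syn.CellSpec(phenotype="DF", noise_sd=0.0), step_protocol, seed=1
    )
    first = ts.annotations.query("sweep == 2").time_ms.min()
    assert first - step_protocol.baseline_duration >= 0.4 * step_protocol.step_duration


def test_step_sweeps_reject_nonfinite_spec():
    with pytest.raises(ValueError):
        syn.CellSpec(rmp=float("nan"))
    with pytest.raises(ValueError):
        syn.StepProtocol(step_amplitudes=(40.0, 20.0))


def test_same_seed_reproduces_identical_traces(step_protocol):
    cell = syn.CellSpec()
    a = syn.simulate_step_sweeps(cell, step_protocol, seed=11)
    b = syn.simulate_step_sweeps(cell, step_protocol, seed=11)
    assert np.array_equal(a.data, b.data)
    assert a.annotations.equals(b.annotations)


# ------------------------------------------------------------ photostim trials


def test_no_connections_no_chr2_gives_noise_only(photostim_protocol):
    ts = syn.simulate_photostim_trials(
        syn.CellSpec(), [], photostim_protocol, seed=0, noise_sd=3.0
    )
    assert len(ts.annotations) == 0
    assert np.abs(ts.data.mean()) < 1.0  # zero-mean noise


def test_bicuculline_scales_mixed_connection_amplitude():
    """GABA/glycine 0.25/0.75 mix in bicuculline: mean ground-truth
    amplitude is 0.75 x the control mean (within 5% over 1000 trials)."""
    conn = syn.ConnectionSpec(
        kind="monosynaptic",
        transmitter_mix={"GABA_A": 0.25, "glycine": 0.75, "AMPA": 0.0},
        amplitude_mean=300.0,
    )
    proto = syn.PhotostimProtocol(n_trials=1000)
    ts = syn.simulate_photostim_trials(
        syn.CellSpec(), [conn], proto, syn.DrugCondition(bicuculline=True),
        seed=2, noise_sd=0.0,
    )
    assert ts.annotations.amplitude_pa.mean() == pytest.approx(0.75 * 300, rel=0.05)


def test_drug_scaling_is_compositional(photostim_protocol):
    """Bicuculline then strychnine on a pure GABA/glycine mix abolishes the
    response entirely (residual fraction 0)."""
    conn = syn.ConnectionSpec(
        kind="monosynaptic",
        transmitter_mix={"GABA_A": 0.4, "glycine": 0.6, "AMPA": 0.0},
    )
    both = syn.DrugCondition(bicuculline=True, strychnine=True)
    ts = syn.simulate_photostim_trials(
        syn.CellSpec(), [conn], photostim_protocol, both, seed=3, noise_sd=0.0
    )
    assert ts.annotations.amplitude_pa.sum() == 0.0
    assert np.allclose(ts.data, 0.0)


def test_ttx_4ap_spares_only_terminal_release(photostim_protocol):
    glut = {"GABA_A": 0.0, "glycine": 0.0, "AMPA": 1.0}
    pad = syn.ConnectionSpec(
        kind="polysynaptic", transmitter_mix=glut, pad_driven=True,
        latency_mean=15.0, latency_sd=4.0,
    )
    relayed = syn.ConnectionSpec(
        kind="polysynaptic", transmitter_mix=glut, latency_mean=15.0, latency_sd=4.0
    )
    mono = syn.ConnectionSpec(kind="monosynaptic", transmitter_mix=glut)
    ttx = syn.DrugCondition(ttx=True)
    ttx4ap = syn.DrugCondition(ttx=True, four_ap=True)
    n = photostim_protocol.n_trials

    def events(conn, drug):
        ts = syn.simulate_photostim_trials(
            syn.CellSpec(), [conn], photostim_protocol, drug, seed=4
        )
        return len(ts.annotations)

    assert events(mono, ttx) == 0  # TTX silences everything
    assert events(mono, ttx4ap) == n  # 4-AP reinstates direct release
    assert events(pad, ttx4ap) == n  # PAD-driven events survive
    assert events(relayed, ttx4ap) == 0  # spike-relayed events do not


def test_photocurrent_only_with_chr2(photostim_protocol):
    with pytest.raises(ValueError):
        syn.CellSpec(has_chr2=False, photocurrent_amp=100.0)
    chr2 = syn.CellSpec(has_chr2=True, photocurrent_amp=200.0)
    ts = syn.simulate_photostim_trials(chr2, [], photostim_protocol, seed=5, noise_sd=0.0)
    i0 = int((photostim_protocol.pulse_onset + 1.0) * photostim_protocol.sampling_rate)
    assert ts.data[0, i0] < -150.0  # large inward photocurrent during pulse


# ---------------------------------------------------------------- mEPSC trains


def test_mepsc_event_counts_scale_with_capsaicin_factor():
    factor = 10.33 / 4.28
    ts = syn.simulate_mepsc_train(4.28, 15.4, 60.0, factor, seed=6)
    ann = ts.annotations
    nb = (ann.epoch == "baseline").sum()
    np_ = (ann.epoch == "capsaicin").sum()
    # Poisson sampling error: ~4 SDs of the ratio
    assert np_ / nb == pytest.approx(factor, rel=0.25)
    # amplitudes are drawn identically in the two epochs
    assert ann[ann.epoch == "baseline"].amplitude_pa.mean() == pytest.approx(
        ann[ann.epoch == "capsaicin"].amplitude_pa.mean(), rel=0.15
    )


def test_mepsc_validation_errors():
    with pytest.raises(ValueError):
        syn.simulate_mepsc_train(1.0, 15.0, 0.0, 1.0, seed=0)
    with pytest.raises(ValueError):
        syn.simulate_mepsc_train(1.0, 15.0, 10.0, -0.5, seed=0)
    with pytest.raises(ValueError):
        syn.simulate_mepsc_train(0.0, 15.0, 10.0, 1.0, seed=0)


# ----------------------------------------------------------------- morphology


def test_straight_dendrite_spec_gives_exact_line():
    spec = syn.MorphoClassSpec(
        name="line", soma_volume_um3=523.6, total_length_um=100.0,
        rc_length_um=100.0, rc_spread_um=100.0, dv_spread_um=0.0,
        n_primary_dendrites=1, branch_prob=0.0, tortuosity_wiggle=0.0,
        dispersion_cv=0.0,
    )
    m = syn.generate_morphology(spec, seed=1)
    assert m.edge_lengths().sum() == pytest.approx(100.0, abs=1e-6)
    rc = m.axis_coord("RC")
    assert rc.max() - rc.min() == pytest.approx(100.0, abs=1e-6)
    # no lateral excursion at all
    assert np.allclose(m.axis_coord("DV"), 0.0)
    assert np.allclose(m.axis_coord("ML"), 0.0)


def test_generated_trees_pass_swc_validation_over_1000_seeds():
    spec = syn.epvin_morphology_spec()
    for s in range(1000):
        m = syn.generate_morphology(spec, seed=s)  # validates on build
        assert np.all(m.radius > 0)
        assert np.sum(m.parent == -1) == 1


def test_unreachable_morphology_targets_raise():
    spec = syn.MorphoClassSpec(
        name="bad", soma_volume_um3=500.0, total_length_um=50.0,
        rc_length_um=50.0, rc_spread_um=400.0, dv_spread_um=0.0,
        n_primary_dendrites=2, dispersion_cv=0.0,
    )
    with pytest.raises(RuntimeError):
        syn.generate_morphology(spec, seed=0)


def test_morphology_generation_is_seed_deterministic():
    spec = syn.ipvin_morphology_spec()
    a = syn.generate_morphology(spec, seed=42)
    b = syn.generate_morphology(spec, seed=42)
    assert np.array_equal(a.xyz, b.xyz)


# ---------------------------------------------------------------- transcripts


def test_all_negative_panel_counts_stay_below_threshold():
    zero = {g: syn.GeneModel(expr_prob=0.0, neg_lambda=0.0) for g in
            ("PValb", "Slc17a6", "GAD1", "CCK")}
    panel = syn.TranscriptPanelSpec(
        classes={"silent": zero}, class_mixture={"silent": 1.0}
    )
    table = syn.generate_transcript_table(panel, [50], seed=0)
    assert (table[list(panel.genes)] <= 4).all().all()


def test_transcript_mixture_and_long_format():
    panel = syn.default_transcript_panel(excitatory_fraction=0.5)
    table = syn.generate_transcript_table(panel, [250, 250], seed=1)
    frac = (table.true_class == "excitatory").mean()
    assert 0.44 <= frac <= 0.56  # well inside the binomial CI at n=500
    long = syn.transcripts_to_long(table, panel.genes)
    assert set(long.columns) == {"cell_id", "animal", "gene", "count"}
    assert len(long) == 4 * len(table)


def test_transcript_panel_mixture_must_sum_to_one():
    with pytest.raises(ValueError):
        syn.TranscriptPanelSpec(
            classes={"a": {}, "b": {}}, class_mixture={"a": 0.6, "b": 0.6}
        )


def test_swc_error_type_is_value_error():
    assert issubclass(SWCError, ValueError)
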