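"""oPSC detection, trial statistics, connection classification, pharmacology,
TTX/4-AP confirmation, capsaicin assay, spike modulation, incidence tables."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pvcircuit import opto
from pvcircuit import synthetic as syn
from pvcircuit.traces import Sweep


def _mono(latency_total=4.34, sd=0.54, rel=1.0, amp=260.0, cv=0.2):
    return syn.ConnectionSpec(
        kind="monosynaptic",
        latency_mean=latency_total - syn.RECRUITMENT_DELAY_MS,
        latency_sd=sd, reliability=rel, amplitude_mean=amp, amplitude_cv=cv,
    )


def _poly(latency_total=16.9, sd=4.3, rel=0.7, amp=140.0):
    return syn.ConnectionSpec(
        kind="polysynaptic",
        latency_mean=latency_total - syn.RECRUITMENT_DELAY_MS,
        latency_sd=sd, reliability=rel, amplitude_mean=amp,
    )


def _run(conn, proto, drug=None, seed=0, noise=3.0, cell=None):
    cell = cell or syn.CellSpec()
    ts = syn.simulate_photostim_trials(
        cell, [conn] if conn else [], proto, drug, seed=seed, noise_sd=noise
    )
    events = opto.trial_events(ts)
    stats = opto.trial_statistics(events, ts.average())
    return ts, events, stats


# ----------------------------------------------------------------- detection


def test_noise_only_trials_detect_nothing(photostim_protocol):
    _, events, stats = _run(None, photostim_protocol, seed=1)
    assert all(e is None for e in events)
    assert stats.reliability == 0.0
    assert np.isnan(stats.mean_latency)
    assert opto.classify_connection(stats).label == "none"


def test_mono_event_onset_recovered_within_half_ms(photostim_protocol):
    conn = _mono(sd=0.0, cv=0.0)
    ts, events, _ = _run(conn, photostim_protocol, seed=2)
    truth = ts.annotations.latency_ms.to_numpy()
    est = np.array([e.onset_latency for e in events])
    assert np.max(np.abs(est - truth)) < 0.5


def test_event_below_amplitude_floor_is_none(photostim_protocol):
    conn = _mono(amp=5.0, cv=0.0)  # below the 10 pA default floor
    _, events, _ = _run(conn, photostim_protocol, seed=3, noise=0.0)
    assert all(e is None for e in events)


def test_zero_photocurrent_baseline_arithmetic():
    sw = Sweep(samples=np.full(200, -200.0), sampling_rate=20.0, units="pA")
    z = opto.zero_photocurrent_baseline(sw, 5.0)
    assert np.allclose(z.samples, 0.0)
    with pytest.raises(ValueError):
        opto.zero_photocurrent_baseline(sw, 1000.0)


def test_psc_amplitude_recovered_on_photocurrent():
    """A 150 pA PSC riding on a 200 pA photocurrent plateau is recovered
    within 5 pA after re-zeroing at the synaptic onset."""
    chr2 = syn.CellSpec(has_chr2=True, photocurrent_amp=200.0)
    conn = _mono(latency_total=4.3, sd=0.0, amp=150.0, cv=0.0)
    proto = syn.PhotostimProtocol(n_trials=10)
    ts = syn.simulate_photostim_trials(chr2, [conn], proto, seed=4, noise_sd=0.0)
    avg = ts.average()
    onset = proto.pulse_onset + 4.3
    z = opto.zero_photocurrent_baseline(avg, onset)
    i0 = avg.index_at(onset)
    win = int(20 * avg.sampling_rate)
    assert -(z.samples[i0 : i0 + win].min()) == pytest.approx(150.0, abs=5.0)


# ----------------------------------------------------------- trial statistics


def test_trial_statistics_worked_example():
    ev = [
        opto.PSCEvent(trial_index=k, onset_latency=4.0, amplitude=100.0)
        for k in range(4)
    ] + [None] * 6
    stats = opto.trial_statistics(ev)
    assert stats.mean_latency == 4.0
    assert stats.jitter == 0.0
    assert stats.reliability == 0.4


def test_jitter_estimator_consistent_at_1000_trials():
    conn = _mono()
    proto = syn.PhotostimProtocol(n_trials=1000)
    _, events, stats = _run(conn, proto, seed=5)
    assert stats.jitter == pytest.approx(0.54, rel=0.10)
    assert stats.mean_latency == pytest.approx(4.34, rel=0.05)


def test_average_amplitude_flattens_with_jitter():
    """Averaged-trace amplitude matches the per-trial mean for tight jitter
    and falls below it as onset dispersion grows."""
    proto = syn.PhotostimProtocol(n_trials=20)

    def amp_pair(sd, seed):
        conn = _mono(sd=sd, amp=200.0, cv=0.0)
        ts, events, stats = _run(conn, proto, seed=seed, noise=0.5)
        per_trial = np.mean([e.amplitude for e in events if e])
        return stats.amplitude, per_trial

    avg_tight, trial_tight = amp_pair(0.1, 6)
    assert avg_tight == pytest.approx(trial_tight, rel=0.05)
    avg_wide, trial_wide = amp_pair(3.0, 6)
    assert avg_wide < 0.9 * trial_wide


# ----------------------------------------------------- connection classifier


@pytest.mark.parametrize(
    "mean_lat,jitter,rel,expected",
    [
        (4.3, 0.5, 1.0, "monosynaptic"),
        (17.0, 4.3, 0.9, "polysynaptic"),
        (4.3, 0.5, 0.1, "none"),
        (6.9, 0.9, 0.8, "monosynaptic"),  # just inside every criterion
        (7.1, 0.5, 1.0, "polysynaptic"),  # outside the 7.0 ms window
        (4.3, 1.1, 1.0, "polysynaptic"),  # jitter criterion fails
    ],
)
def test_connection_classification_rules(mean_lat, jitter, rel, expected):
    stats = opto.TrialStats(
        mean_latency=mean_lat, jitter=jitter, reliability=rel,
        amplitude=100.0, n_trials=10,
    )
    call = opto.classify_connection(stats)
    assert call.label == expected
    assert set(call.criteria_trace) == {
        "detected", "latency_window", "jitter", "reliability",
    }


def test_classifier_accuracy_on_simulated_regimes(photostim_protocol):
    """>= 95% over connections drawn from the mono (4.3 / 0.5 ms) and poly
    (17 / 4.3 ms) latency-jitter regimes, plus unconnected cells."""
    kinds = ["monosynaptic", "polysynaptic", "none"]
    correct = 0
    n = 90
    for k in range(n):
        kind = kinds[k % 3]
        conn = {
            "monosynaptic": _mono(),
            "polysynaptic": _poly(),
            "none": syn.ConnectionSpec(kind="none"),
        }[kind]
        _, _, stats = _run(conn, photostim_protocol, seed=7000 + k)
        assert opto.trial_statistics is not None
        call = opto.classify_connection(stats)
        correct += call.label == kind
    assert correct / n >= 0.95


# -------------------------------------------------------------- pharmacology


def test_opsc_index_endpoints():
    assert opto.opsc_index(100.0, 100.0).index == 1.0
    assert opto.opsc_index(0.0, 250.0).index == 0.0
    with pytest.raises(ValueError):
        opto.opsc_index(10.0, 0.0)


@given(
    a=st.floats(0.0, 1e4),
    b=st.floats(1e-3, 1e4),
    c=st.floats(1e-3, 1e4),
)
def test_opsc_index_scale_invariance(a, b, c):
    assert opto.opsc_index(c * a, c * b).index == pytest.approx(
        opto.opsc_index(a, b).index, rel=1e-9
    )


def test_sequential_pharmacology_fractions():
    prof = opto.pharmacology_profile(
        [opto.DrugIndex("bicuculline", 0.75), opto.DrugIndex("strychnine", 0.0)]
    )
    assert prof.component_fractions["GABA_A"] == pytest.approx(0.25)
    assert prof.component_fractions["glycine"] == pytest.approx(0.75)
    assert prof.dominance == "glycine-dominant"
    assert sum(prof.component_fractions.values()) == pytest.approx(1.0)
    assert prof.residual == pytest.approx(0.0)


def test_glutamatergic_profile():
    prof = opto.pharmacology_profile(
        [
            opto.DrugIndex("cnqx", 0.12),
            opto.DrugIndex("bicuculline", 1.0),
            opto.DrugIndex("strychnine", 0.99),
        ]
    )
    assert prof.dominance == "glutamatergic"
    assert prof.component_fractions["AMPA"] == pytest.approx(0.88)


def test_disinhibition_is_flagged_not_clamped():
    prof = opto.pharmacology_profile([opto.DrugIndex("strychnine", 1.26)])
    assert prof.unmasked == ["strychnine"]
    assert prof.component_fractions["glycine"] == 0.0


def test_strychnine_index_matches_glycine_fraction_over_population():
    """Glycine-dominant 0.25/0.75 mix: the population-mean strychnine index
    equals the surviving GABA fraction (~0.25) over 200 simulated cells."""
    proto = syn.PhotostimProtocol(n_trials=10)
    mix = {"GABA_A": 0.25, "glycine": 0.75, "AMPA": 0.0}
    idx = []
    for k in range(200):
        conn = syn.ConnectionSpec(
            kind="monosynaptic", transmitter_mix=mix, amplitude_mean=300.0
        )
        pre = syn.simulate_photostim_trials(
            syn.CellSpec(), [conn], proto, seed=9000 + k
        )
        drug = syn.simulate_photostim_trials(
            syn.CellSpec(), [conn], proto,
            syn.DrugCondition(strychnine=True), seed=9000 + k,
        )
        a_pre = opto.trial_statistics(opto.trial_events(pre), pre.average()).amplitude
        a_drug = opto.trial_statistics(
            opto.trial_events(drug), drug.average()
        ).amplitude
        idx.append(opto.opsc_index(a_drug, a_pre, "strychnine").index)
    assert np.mean(idx) == pytest.approx(0.25, abs=0.03)


def test_ttx_4ap_worked_examples():
    assert (
        opto.ttx_4ap_classify(298.0, 10.0, 306.0)
        == "confirmed_monosynaptic_or_terminal"
    )
    assert opto.ttx_4ap_classify(300.0, 10.0, 20.0) == "spike_dependent"
    with pytest.raises(ValueError):
        opto.ttx_4ap_classify(0.0, 10.0, 20.0)


def test_pad_driven_connection_confirmed_by_ttx_4ap_pipeline():
    proto = syn.PhotostimProtocol(n_trials=10)
    pad = syn.ConnectionSpec(
        kind="polysynaptic",
        transmitter_mix={"GABA_A": 0.0, "glycine": 0.0, "AMPA": 1.0},
        latency_mean=14.0, latency_sd=3.0, amplitude_mean=200.0, pad_driven=True,
    )

    def amp(drug, seed=11):
        ts = syn.simulate_photostim_trials(syn.CellSpec(), [pad], proto, drug, seed=seed)
        return opto.trial_statistics(opto.trial_events(ts), ts.average()).amplitude

    a0 = amp(None)
    a1 = amp(syn.DrugCondition(ttx=True))
    a2 = amp(syn.DrugCondition(ttx=True, four_ap=True))
    assert opto.ttx_4ap_classify(a0, a1, a2) == "confirmed_monosynaptic_or_terminal"


# ------------------------------------------------------------------ capsaicin


def test_capsaicin_rule_worked_example_and_boundary():
    assert opto.capsaicin_responder([4.0, 4.2, 4.4], 10.3) is True
    base = [4.0, 4.2, 4.4]
    mu, sd = np.mean(base), np.std(base, ddof=1)
    assert opto.capsaicin_responder(base, mu + 3 * sd) is False  # strict
    assert opto.capsaicin_responder([4.0, 4.0, 4.0], 4.0) is False
    assert opto.capsaicin_responder([4.0, 4.0, 4.0], 4.1) is True
    with pytest.raises(ValueError):
        opto.capsaicin_responder([4.0, 4.2], 10.0)


def test_capsaicin_assay_detects_responders_and_nonresponders():
    ts = syn.simulate_mepsc_train(4.28, 15.4, 60.0, 10.33 / 4.28, seed=12)
    base, post, responder = opto.capsaicin_assay(ts)
    assert responder
    assert post / np.mean(base) == pytest.approx(10.33 / 4.28, rel=0.25)
    flat = syn.simulate_mepsc_train(4.28, 15.4, 60.0, 1.0, seed=12)
    _, _, responder = opto.capsaicin_assay(flat)
    assert not responder


# ----------------------------------------------------------- spike modulation


def test_spike_modulation_metric_deltas():
    pre = {"rheobase": 89.0, "latency": 24.0, "n_spikes": 2.1}
    test = {"rheobase": 130.0, "latency": 39.5, "n_spikes": 1.3}
    post = {"rheobase": 87.0, "latency": 22.6, "n_spikes": 1.9}
    mod = opto.spike_modulation(pre, test, post)
    assert mod.deltas_vs_pre["rheobase"] == pytest.approx(41.0)
    assert mod.deltas_vs_pre["latency"] == pytest.approx(15.5)
    assert mod.reversible  # post within 15% of pre on every metric


def test_spike_modulation_identical_series_gives_zero_deltas(
    quiet_cell, step_protocol
):
    ts = syn.simulate_step_sweeps(quiet_cell, step_protocol, seed=13)
    sweeps = ts.sweeps()
    mod = opto.spike_modulation(sweeps, sweeps, sweeps)
    assert all(v == 0.0 for v in mod.deltas_vs_pre.values())
    assert mod.reversible
    with pytest.raises(ValueError):
        opto.spike_modulation(sweeps, None, sweeps)


def test_photostim_raises_rheobase_in_simulated_inhibition(step_protocol):
    """An inhibited test series (higher generator rheobase) yields a positive
    rheobase delta and reverses."""
    pre = syn.simulate_step_sweeps(
        syn.CellSpec(rheobase_pa=60.0), step_protocol, seed=14
    ).sweeps()
    test = syn.simulate_step_sweeps(
        syn.CellSpec(rheobase_pa=100.0), step_protocol, seed=15
    ).sweeps()
    post = syn.simulate_step_sweeps(
        syn.CellSpec(rheobase_pa=60.0), step_protocol, seed=16
    ).sweeps()
    mod = opto.spike_modulation(pre, test, post)
    assert mod.deltas_vs_pre["rheobase"] == pytest.approx(40.0)
    assert mod.reversible


# ------------------------------------------------------------ incidence table


def test_incidence_percentages_match_printed_counts():
    rows = (
        [{"group": "UN:LIIi-III", "label": "monosynaptic"}] * 146
        + [{"group": "UN:LIIi-III", "label": "none"}] * 39
        + [{"group": "RA", "label": "monosynaptic"}] * 18
        + [{"group": "RA", "label": "none"}] * 9
    )
    table = opto.incidence_table(pd.DataFrame(rows))
    assert table.percent("UN:LIIi-III", "monosynaptic") == 79
    assert table.percent("RA", "monosynaptic") == 67


def test_incidence_empty_group_is_undefined():
    from pvcircuit.reporting import ContingencyTable

    counts = pd.DataFrame({"monosynaptic": [2, 0]}, index=["a", "b"])
    table = ContingencyTable(counts=counts)
    assert table.percent("a", "monosynaptic") == 100
    assert np.isnan(table.percent("b", "monosynaptic"))
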