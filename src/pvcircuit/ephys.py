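"""Intrinsic excitability analysis of current-clamp step recordings.

Covers derivative-threshold spike detection (dV/dt > 15 V/s), passive
membrane properties from the response to a small hyperpolarising voltage
step, rheobase, AP latency, discharge-pattern classification (tonic firing,
initial bursting, delayed firing, single spiking, rapidly adapting), and
recording quality control.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .traces import Sweep

__all__ = [
    "SpikeEvent",
    "PassiveProperties",
    "DischargeCall",
    "QCResult",
    "detect_spikes",
    "measure_passive",
    "find_rheobase",
    "ap_latency",
    "classify_discharge",
    "qc_recording",
]

DISCHARGE_LABELS = ("TF", "IB", "DF", "SS", "RA")


@dataclass
class SpikeEvent:
    threshold_time: float  # ms
    threshold_voltage: float  # mV
    peak_time: float  # ms
    peak_voltage: float  # mV

    def __post_init__(self) -> None:
        if self.peak_time < self.threshold_time:
            raise ValueError("peak must not precede threshold")


@dataclass
class PassiveProperties:
    r_series: float  # MΩ
    r_input: float  # MΩ
    c_mem: float  # pF
    rmp: float = float("nan")  # mV

    def __post_init__(self) -> None:
        if self.r_series <= 0 or self.r_input <= 0:
            raise ValueError("resistances must be positive")


@dataclass
class DischargeCall:
    label: str
    evidence: dict = field(default_factory=dict)
    low_confidence: bool = False


@dataclass
class QCResult:
    passed: bool
    reasons: list = field(default_factory=list)


# --------------------------------------------------------------------------
# spike detection
# --------------------------------------------------------------------------


def _smoothed_dvdt(v: np.ndarray, rate_khz: float) -> np.ndarray:
    """Central-difference dV/dt (V/s) on a 3-point smoothed trace."""
    kernel = np.array([0.25, 0.5, 0.25])
    vs = np.convolve(v, kernel, mode="same")
    vs[0], vs[-1] = v[0], v[-1]
    dvdt = np.gradient(vs) * rate_khz  # mV/ms == V/s
    return dvdt


def detect_spikes(
    sweep: Sweep,
    dvdt_threshold: float = 15.0,
    peak_margin_mv: float = 20.0,
) -> list[SpikeEvent]:
    """Derivative-threshold spike detection.

    One event is returned per contiguous excursion of the smoothed dV/dt
    above ``dvdt_threshold`` whose subsequent voltage peak exceeds the
    threshold-crossing voltage by at least ``peak_margin_mv`` (a guard
    against spurious slow deflections).
    """
    if sweep.sampling_rate < 5.0:
        warnings.warn(
            "sampling rate below 5 kHz: dV/dt estimate unreliable",
            stacklevel=2,
        )
    v = sweep.samples
    dvdt = _smoothed_dvdt(v, sweep.sampling_rate)
    above = dvdt > dvdt_threshold
    if not above.any():
        return []
    # contiguous suprathreshold runs
    edges = np.diff(above.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1
    if above[0]:
        starts = np.r_[0, starts]
    if above[-1]:
        ends = np.r_[ends, above.size]
    t = sweep.time_ms()
    events: list[SpikeEvent] = []
    n = v.size
    for s, e in zip(starts, ends):
        thr_v = v[s]
        # peak search: from crossing until dV/dt has been negative (repolarised)
        stop = e
        while stop < n - 1 and dvdt[stop] > -dvdt_threshold:
            stop += 1
            if t[stop] - t[s] > 10.0:  # spikes are brief
                break
        seg = slice(s, max(stop, s + 1) + 1)
        pk = int(np.argmax(v[seg])) + s
        if v[pk] < thr_v + peak_margin_mv:
            continue
        events.append(
            SpikeEvent(
                threshold_time=float(t[s]),
                threshold_voltage=float(thr_v),
                peak_time=float(t[pk]),
                peak_voltage=float(v[pk]),
            )
        )
    return events


# --------------------------------------------------------------------------
# passive properties
# --------------------------------------------------------------------------


def measure_passive(vc_response: Sweep, step_mv: float = -5.0) -> PassiveProperties:
    """Series/input resistance and capacitance from a small voltage step.

    The response is modelled as a series resistance feeding a parallel
    RC: the instantaneous (peak) current gives Rs = V/I_peak, the steady
    state gives the total resistance Rs + Rin, and the transient decay
    time constant tau = Cm * (Rs || Rin) gives the capacitance. In the
    noise-free limit this inverts the closed-form generator exactly.
    """
    if step_mv == 0:
        raise ValueError("zero-amplitude step")
    i = vc_response.samples
    rate = vc_response.sampling_rate
    onset_idx = vc_response.index_at(vc_response.stim_onset)
    dur = vc_response.stim_duration or 10.0
    end_idx = vc_response.index_at(vc_response.stim_onset + dur)
    baseline = float(np.mean(i[:onset_idx])) if onset_idx > 0 else 0.0
    step_seg = i[onset_idx:end_idx] - baseline
    if step_seg.size < 4:
        raise ValueError("step window too short")
    # peak transient: largest deviation in the step's polarity
    sign = -1.0 if step_mv < 0 else 1.0
    i_peak = float(step_seg[np.argmax(sign * step_seg)])
    # steady state: mean of the last 20% of the step
    tail = step_seg[int(0.8 * step_seg.size):]
    i_ss = float(np.mean(tail))
    if abs(i_peak) <= abs(i_ss) or i_peak == 0 or i_ss == 0:
        raise ValueError("no detectable capacitive transient")
    r_series = step_mv / i_peak * 1000.0  # mV / pA -> MΩ (×1000)
    r_total = step_mv / i_ss * 1000.0
    r_input = r_total - r_series
    if r_series <= 0 or r_input <= 0:
        raise ValueError("inconsistent step response")
    # transient decay: log-linear fit of (I - Iss) over the early step
    trans = sign * (step_seg - i_ss)
    t_ms = np.arange(step_seg.size) / rate
    amp0 = trans[0]
    if amp0 <= 0:
        raise ValueError("no detectable capacitive transient")
    # fit over the leading run where the transient is still well resolved
    below = np.flatnonzero(trans <= 1e-3 * amp0)
    stop = int(below[0]) if below.size else trans.size
    if stop < 3:
        raise ValueError("capacitive transient too fast to fit")
    k = np.arange(stop)
    slope = np.polyfit(t_ms[k], np.log(trans[k]), 1)[0]
    if slope >= 0:
        raise ValueError("non-decaying transient")
    tau = -1.0 / slope  # ms
    r_par = r_series * r_input / (r_series + r_input)
    c_mem = tau / r_par * 1000.0  # ms / MΩ -> nF; ×1000 -> pF
    return PassiveProperties(r_series=r_series, r_input=r_input, c_mem=c_mem)


# --------------------------------------------------------------------------
# rheobase / latency
# --------------------------------------------------------------------------


def find_rheobase(sweeps: list[Sweep], **detect_kw) -> float | None:
    """Amplitude of the first sweep (sorted by amplitude) with >=1 spike."""
    if not sweeps:
        raise ValueError("empty sweep list")
    for sw in sorted(sweeps, key=lambda s: s.stim_amplitude):
        if detect_spikes(sw, **detect_kw):
            return float(sw.stim_amplitude)
    return None


def ap_latency(sweep: Sweep, onset: float | None = None, **detect_kw) -> float | None:
    """Latency (ms) from stimulus onset to the first spike's AP threshold."""
    if onset is None:
        onset = sweep.stim_onset
    events = detect_spikes(sweep, **detect_kw)
    events = [e for e in events if e.threshold_time >= onset]
    if not events:
        return None
    return events[0].threshold_time - onset


# --------------------------------------------------------------------------
# discharge classification
# --------------------------------------------------------------------------


def _sweep_evidence(sweep: Sweep, events: list[SpikeEvent]) -> dict:
    onset = sweep.stim_onset
    dur = sweep.stim_duration
    times = np.array([e.threshold_time - onset for e in events])
    frac = times / dur if dur > 0 else times * 0
    n_onset = int(np.sum(frac <= 0.20))
    # depolarising-hump metric: spike-masked mean V of the first 50 ms of the
    # step minus the spike-masked steady-state V (last 20% of the step)
    t = sweep.time_ms()
    mask = np.ones(t.size, dtype=bool)
    for e in events:
        mask &= ~((t >= e.threshold_time - 1.0) & (t <= e.threshold_time + 4.0))
    early = mask & (t >= onset) & (t < onset + min(50.0, 0.2 * dur))
    late = mask & (t >= onset + 0.8 * dur) & (t < onset + dur)
    hump = float("nan")
    if early.any() and late.any():
        hump = float(np.mean(sweep.samples[early]) - np.mean(sweep.samples[late]))
    return {
        "n_spikes": len(events),
        "first_frac": float(frac[0]) if times.size else float("nan"),
        "last_frac": float(frac[-1]) if times.size else float("nan"),
        "onset_burst_count": n_onset,
        "hump_mv": hump,
    }


def _label_from_evidence(ev: dict, all_single: bool) -> str | None:
    n = ev["n_spikes"]
    if n == 0:
        return None
    confined = ev["last_frac"] <= 0.20
    if all_single:
        return "SS"
    if confined and ev["onset_burst_count"] >= 3 and ev["hump_mv"] >= 3.0:
        return "RA"
    if confined and n >= 2:
        return "IB"
    if ev["first_frac"] > 0.40 and ev["onset_burst_count"] == 0:
        return "DF"
    if ev["last_frac"] >= 0.80 and n >= 4:
        return "TF"
    # fallbacks for patterns at rule margins, in the same priority order
    if confined:
        return "IB" if n >= 2 else "SS"
    if ev["first_frac"] > 0.40:
        return "DF"
    return "TF"


def classify_discharge(step_responses: list[Sweep], **detect_kw) -> DischargeCall:
    """Classify the discharge pattern from a current-step series.

    The label is assigned from the first suprathreshold sweep and confirmed
    on the next; on disagreement the highest-amplitude sweep decides and
    the call is flagged low-confidence.
    """
    ordered = sorted(step_responses, key=lambda s: s.stim_amplitude)
    detected = [(sw, detect_spikes(sw, **detect_kw)) for sw in ordered]
    supra = [(sw, ev) for sw, ev in detected if ev]
    if not supra:
        raise ValueError("no suprathreshold sweep: cannot classify discharge")
    all_single = all(len(ev) == 1 for _, ev in supra)
    calls = []
    for sw, ev in supra:
        e = _sweep_evidence(sw, ev)
        calls.append((_label_from_evidence(e, all_single), e))
    first_label, first_ev = calls[0]
    if len(calls) == 1 or calls[1][0] == first_label:
        return DischargeCall(label=first_label, evidence=first_ev)
    # contradictory sweeps: defer to the highest-amplitude one
    return DischargeCall(
        label=calls[-1][0], evidence=calls[-1][1], low_confidence=True
    )


# --------------------------------------------------------------------------
# quality control
# --------------------------------------------------------------------------


def qc_recording(
    props_start: PassiveProperties,
    props_end: PassiveProperties,
    rmp_max_mv: float = -50.0,
    rs_max_mohm: float = 30.0,
    max_drift: float = 0.30,
) -> QCResult:
    """Inclusion criteria: RMP strictly more negative than -50 mV, series
    resistance < 30 MΩ, and no monitored value drifting more than 30%
    (relative to the start value)."""
    reasons = []
    if not np.isnan(props_start.rmp) and props_start.rmp >= rmp_max_mv:
        reasons.append(f"RMP {props_start.rmp:.1f} mV not more negative than {rmp_max_mv:.0f} mV")
    if props_start.r_series >= rs_max_mohm or props_end.r_series >= rs_max_mohm:
        reasons.append(f"Rs >= {rs_max_mohm:.0f} MOhm")
    monitored = {
        "Rs": (props_start.r_series, props_end.r_series),
        "Rin": (props_start.r_input, props_end.r_input),
        "Cm": (props_start.c_mem, props_end.c_mem),
    }
    if not np.isnan(props_start.rmp) and not np.isnan(props_end.rmp):
        monitored["RMP"] = (props_start.rmp, props_end.rmp)
    for name, (a, b) in monitored.items():
        if a != 0 and abs(b - a) / abs(a) > max_drift:
            reasons.append(f"{name} drift > {max_drift:.0%}")
    return QCResult(passed=not reasons, reasons=reasons)
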