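"""Synthetic-data generators for every input class the pipeline consumes.

Each generator attaches ground truth (spike times, PSC event tables, true
class labels) so downstream detection and classification stages can be
tested for recovery without any recorded data.

All stochastic operations take an explicit integer seed and draw from a
single ``numpy.random.default_rng`` stream per call, so identical seeds
give bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd

from .swc import Morphology
from .traces import Sweep, TraceSet

__all__ = [
    "StepProtocol",
    "PhotostimProtocol",
    "ConnectionSpec",
    "CellSpec",
    "DrugCondition",
    "MorphoClassSpec",
    "GeneModel",
    "TranscriptPanelSpec",
    "simulate_step_sweeps",
    "simulate_photostim_trials",
    "simulate_mepsc_train",
    "synth_rc_response",
    "generate_morphology",
    "generate_transcript_table",
    "transcripts_to_long",
    "ipvin_morphology_spec",
    "epvin_morphology_spec",
    "default_transcript_panel",
]

PHENOTYPES = ("TF", "IB", "DF", "SS", "RA")
TRANSMITTERS = ("GABA_A", "glycine", "AMPA")

# fixed photostimulation recruitment delay (ms): time for the ChR2-expressing
# presynaptic cell to reach spike threshold, treated as a constant offset
RECRUITMENT_DELAY_MS = 1.3

# default PSC kernel kinetics (ms), matching miniature-EPSC measurements
PSC_RISE_MS = 1.2
PSC_DECAY_MS = 4.5


def _require_finite(obj) -> None:
    for f in fields(obj):
        v = getattr(obj, f.name)
        if isinstance(v, (int, float)) and not math.isfinite(v):
            raise ValueError(f"{type(obj).__name__}.{f.name} is not finite")


# --------------------------------------------------------------------------
# protocol / spec types
# --------------------------------------------------------------------------


@dataclass
class StepProtocol:
    """Depolarising current-step protocol (current clamp)."""

    baseline_duration: float = 100.0  # ms
    step_duration: float = 1000.0  # ms (50, 500, or 1000 typical)
    step_amplitudes: tuple = (20.0, 40.0, 60.0, 80.0, 100.0)  # pA, 20 pA steps
    inter_step_interval: float = 100.0  # ms of tail after the step
    sampling_rate: float = 10.0  # kHz

    def __post_init__(self) -> None:
        _require_finite(self)
        if self.step_duration <= 0:
            raise ValueError("step_duration must be positive")
        amps = np.asarray(self.step_amplitudes, dtype=float)
        if amps.size == 0 or np.any(np.diff(amps) <= 0):
            raise ValueError("step_amplitudes must be strictly increasing")
        if not (10.0 <= self.sampling_rate <= 20.0):
            raise ValueError("sampling_rate must lie in [10, 20] kHz")


@dataclass
class PhotostimProtocol:
    """Brief light-pulse protocol for ChR2 photostimulation trials."""

    pulse_onset: float = 10.0  # ms
    pulse_duration: float = 1.0  # ms
    n_trials: int = 10
    train_frequency: float | None = None  # Hz, optional pulse train
    n_pulses: int = 1
    post_window: float = 150.0  # ms recorded after the (last) pulse
    sampling_rate: float = 20.0  # kHz

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if self.pulse_duration <= 0:
            raise ValueError("pulse_duration must be positive")
        if self.train_frequency is not None and self.train_frequency <= 0:
            raise ValueError("train_frequency must be positive")

    def pulse_times(self) -> np.ndarray:
        if self.train_frequency is None or self.n_pulses <= 1:
            return np.array([self.pulse_onset])
        period = 1000.0 / self.train_frequency
        return self.pulse_onset + period * np.arange(self.n_pulses)


@dataclass
class ConnectionSpec:
    """One synaptic connection onto the recorded cell.

    ``latency_mean``/``latency_sd`` describe the synaptic latency measured
    from the end of the fixed recruitment delay; the total latency from the
    light pulse is ``RECRUITMENT_DELAY_MS + latency``.
    """

    kind: str  # monosynaptic | polysynaptic | none
    transmitter_mix: dict = field(
        default_factory=lambda: {"GABA_A": 0.0, "glycine": 0.0, "AMPA": 1.0}
    )
    latency_mean: float = 3.0  # ms
    latency_sd: float = 0.5  # ms
    reliability: float = 1.0
    amplitude_mean: float = 100.0  # pA
    amplitude_cv: float = 0.2
    pad_driven: bool = False  # afferent-terminal event; survives TTX + 4-AP

    def __post_init__(self) -> None:
        _require_finite(self)
        if self.kind not in ("monosynaptic", "polysynaptic", "none"):
            raise ValueError(f"unknown connection kind {self.kind!r}")
        fr = np.array([self.transmitter_mix.get(t, 0.0) for t in TRANSMITTERS])
        if np.any(fr < 0) or not np.isclose(fr.sum(), 1.0):
            raise ValueError("transmitter fractions must be >=0 and sum to 1")
        if not 0.0 <= self.reliability <= 1.0:
            raise ValueError("reliability must lie in [0, 1]")
        if self.latency_sd < 0:
            raise ValueError("latency_sd must be >= 0")


@dataclass
class CellSpec:
    """Intrinsic properties and discharge phenotype of a simulated cell."""

    phenotype: str = "TF"
    rmp: float = -60.0  # mV
    r_input: float = 400.0  # MΩ
    r_series: float = 15.0  # MΩ
    c_mem: float = 25.0  # pF
    has_chr2: bool = False
    photocurrent_amp: float = 0.0  # pA (inward magnitude)
    noise_sd: float = 0.3  # mV (CC) or pA (VC)
    rheobase_pa: float = 60.0
    spike_threshold_mv: float = -45.0
    spike_peak_mv: float = 25.0

    def __post_init__(self) -> None:
        _require_finite(self)
        if self.phenotype not in PHENOTYPES:
            raise ValueError(f"unknown phenotype {self.phenotype!r}")
        if self.rmp >= 0:
            raise ValueError("rmp must be negative (mV)")
        if self.r_series <= 0:
            raise ValueError("r_series must be positive")
        if self.photocurrent_amp < 0:
            raise ValueError("photocurrent_amp must be >= 0")
        if not self.has_chr2 and self.photocurrent_amp != 0:
            raise ValueError("photocurrent_amp must be 0 without ChR2")


@dataclass
class DrugCondition:
    """Bath pharmacology flags; residual_fraction is the amplitude fraction
    a blocked component retains (0 = complete block)."""

    bicuculline: bool = False
    strychnine: bool = False
    cnqx: bool = False
    ttx: bool = False
    four_ap: bool = False
    residual_fraction: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.residual_fraction <= 1.0:
            raise ValueError("residual_fraction must lie in [0, 1]")

    def transmitter_scale(self, transmitter: str) -> float:
        blocked = {
            "GABA_A": self.bicuculline,
            "glycine": self.strychnine,
            "AMPA": self.cnqx,
        }[transmitter]
        return self.residual_fraction if blocked else 1.0


# --------------------------------------------------------------------------
# current-clamp step sweeps with phenotype-specific spike placement
# --------------------------------------------------------------------------


def _spike_times(phenotype, step_dur, rng) -> np.ndarray:
    """Phenomenological spike placement (ms from step onset)."""
    d = step_dur
    if phenotype == "SS":
        return np.array([0.02 * d + rng.uniform(0, 0.02 * d)])
    if phenotype == "IB":
        # >=2 spikes confined to the first 20% of the step
        t0 = 0.02 * d + rng.uniform(0, 0.01 * d)
        return np.array([t0, t0 + max(3.0, 0.05 * d)])
    if phenotype == "RA":
        # onset burst of >=3 spikes, confined to the first 20%
        t0 = 0.015 * d + rng.uniform(0, 0.01 * d)
        gap = max(3.0, 0.035 * d)
        return t0 + gap * np.arange(4)
    if phenotype == "DF":
        first = rng.uniform(0.45, 0.60) * d
        times = [first]
        t = first
        while t + max(8.0, 0.08 * d) < 0.92 * d:
            t += max(8.0, 0.08 * d)
            times.append(t)
        return np.asarray(times)
    # TF: regular discharge spanning >=90% of the step, last spike in the
    # final 10%, at least 4 spikes
    n = max(4, int(round(d / 40.0)))
    base = np.linspace(0.02 * d, 0.96 * d, n)
    jitter = rng.uniform(-0.005 * d, 0.005 * d, size=n)
    t = np.sort(base + jitter)
    t[-1] = min(max(t[-1], 0.93 * d), 0.97 * d)
    return t


def _render_spike(v, t, spike_t, thr, peak, plateau, rise=0.5, decay=1.2):
    """Overwrite samples with a fast spike waveform starting at threshold
    time ``spike_t``; the rising phase crosses dV/dt = 15 V/s at onset."""
    in_rise = (t >= spike_t) & (t < spike_t + rise)
    v[in_rise] = thr + (peak - thr) * (t[in_rise] - spike_t) / rise
    in_fall = (t >= spike_t + rise) & (t < spike_t + rise + 4 * decay)
    v[in_fall] = plateau + (peak - plateau) * np.exp(
        -(t[in_fall] - spike_t - rise) / decay
    )


def simulate_step_sweeps(
    cell: CellSpec, proto: StepProtocol, seed: int
) -> TraceSet:
    """Voltage sweeps for a current-step series with ground-truth spikes.

    Suprathreshold sweeps (amplitude >= cell.rheobase_pa) carry spikes
    placed by the phenotype rule; annotations record the threshold-crossing
    time of every spike.
    """
    rng = np.random.default_rng(seed)
    rate = proto.sampling_rate
    total_ms = (
        proto.baseline_duration + proto.step_duration + proto.inter_step_interval
    )
    n = int(round(total_ms * rate))
    t = np.arange(n) / rate
    onset = proto.baseline_duration
    tau_m = cell.r_input * cell.c_mem / 1000.0  # ms

    sweeps = []
    meta_rows = []
    ann_rows = []
    for si, amp in enumerate(proto.step_amplitudes):
        dv = min(amp * cell.r_input / 1000.0, cell.spike_threshold_mv - cell.rmp)
        in_step = (t >= onset) & (t < onset + proto.step_duration)
        v = np.full(n, cell.rmp)
        v[in_step] += dv * (1 - np.exp(-(t[in_step] - onset) / tau_m))
        after = t >= onset + proto.step_duration
        v_end = dv * (1 - np.exp(-proto.step_duration / tau_m))
        v[after] = cell.rmp + v_end * np.exp(
            -(t[after] - onset - proto.step_duration) / tau_m
        )

        supra = amp >= cell.rheobase_pa
        if supra and cell.phenotype == "RA":
            # rapid depolarising hump at step onset: bi-exponential so the
            # rising phase stays well below the spike dV/dt criterion
            hump = (t >= onset) & (t < onset + proto.step_duration)
            th = t[hump] - onset
            v[hump] += 20.0 * (np.exp(-th / 25.0) - np.exp(-th / 3.0))
        if supra:
            plateau = cell.rmp + dv
            for st in _spike_times(cell.phenotype, proto.step_duration, rng):
                abs_t = onset + st
                _render_spike(
                    v,
                    t,
                    abs_t,
                    cell.spike_threshold_mv,
                    cell.spike_peak_mv,
                    plateau,
                )
                ann_rows.append(
                    {
                        "sweep": float(si),
                        "time_ms": abs_t,
                        "stim_amplitude_pa": float(amp),
                        "kind": "spike",
                    }
                )
        if cell.noise_sd > 0:
            v = v + rng.normal(0, cell.noise_sd, size=n)
        sweeps.append(v)
        meta_rows.append(
            {
                "stim_onset_ms": onset,
                "stim_amplitude_pa": float(amp),
                "stim_duration_ms": proto.step_duration,
            }
        )

    ann = pd.DataFrame(
        ann_rows, columns=["sweep", "time_ms", "stim_amplitude_pa", "kind"]
    )
    supra_amps = [a for a in proto.step_amplitudes if a >= cell.rheobase_pa]
    return TraceSet(
        data=np.vstack(sweeps),
        sampling_rate=rate,
        units="mV",
        sweep_meta=pd.DataFrame(meta_rows),
        annotations=ann,
        meta={
            "phenotype": cell.phenotype,
            "rheobase_pa": float(supra_amps[0]) if supra_amps else float("nan"),
            "kind": "step_cc",
        },
    )


# --------------------------------------------------------------------------
# photostimulation trials (voltage clamp)
# --------------------------------------------------------------------------


def _psc_kernel(t, rise=PSC_RISE_MS, decay=PSC_DECAY_MS):
    """Unit-peak bi-exponential synaptic-current kernel (t in ms, t>=0)."""
    tpk = rise * decay / (decay - rise) * math.log(decay / rise)
    norm = math.exp(-tpk / decay) - math.exp(-tpk / rise)
    k = np.exp(-t / decay) - np.exp(-t / rise)
    k[t < 0] = 0.0
    return k / norm


def _lognormal_mean_cv(rng, mean, cv):
    if mean <= 0:
        return 0.0
    if cv <= 0:
        return mean
    sigma2 = math.log(1 + cv**2)
    mu = math.log(mean) - sigma2 / 2
    return float(rng.lognormal(mu, math.sqrt(sigma2)))


def _event_allowed(conn: ConnectionSpec, drug: DrugCondition) -> bool:
    if conn.kind == "none":
        return False
    if drug.ttx:
        if not drug.four_ap:
            return False  # all spike-dependent transmission silenced
        # 4-AP in TTX reinstates direct terminal release: monosynaptic
        # inputs and PAD-driven (afferent-terminal) polysynaptic events
        return conn.kind == "monosynaptic" or conn.pad_driven
    return True


def simulate_photostim_trials(
    cell: CellSpec,
    connections,
    proto: PhotostimProtocol,
    drug: DrugCondition | None = None,
    seed: int = 0,
    noise_sd: float = 3.0,
) -> TraceSet:
    """Voltage-clamp photostimulation trials with ground-truth PSC events.

    Each trial holds the cell's photocurrent (if it expresses ChR2) plus,
    per connection and per pulse, a Bernoulli(reliability) PSC whose onset
    is pulse + recruitment delay + truncated-normal synaptic latency and
    whose amplitude is log-normal around the drug-scaled mean. PSCs are
    rendered as inward (negative) bi-exponential currents.
    """
    drug = drug or DrugCondition()
    rng = np.random.default_rng(seed)
    rate = proto.sampling_rate
    pulses = proto.pulse_times()
    total_ms = pulses[-1] + proto.post_window
    n = int(round(total_ms * rate))
    t = np.arange(n) / rate

    photo = np.zeros(n)
    if cell.has_chr2 and cell.photocurrent_amp > 0:
        for p in pulses:
            during = (t >= p) & (t < p + proto.pulse_duration)
            photo[during] -= cell.photocurrent_amp * (
                1 - np.exp(-(t[during] - p) / 0.3)
            )
            off = p + proto.pulse_duration
            lvl = cell.photocurrent_amp * (1 - math.exp(-proto.pulse_duration / 0.3))
            # slow ChR2 deactivation: a near-plateau under the synaptic
            # response window, as required for baseline re-zeroing
            post = t >= off
            photo[post] = np.minimum(
                photo[post], -lvl * np.exp(-(t[post] - off) / 150.0)
            )

    data = np.zeros((proto.n_trials, n))
    ann_rows = []
    for trial in range(proto.n_trials):
        i = photo.copy()
        for ci, conn in enumerate(connections):
            scale = sum(
                conn.transmitter_mix.get(tr, 0.0) * drug.transmitter_scale(tr)
                for tr in TRANSMITTERS
            )
            for p in pulses:
                responds = rng.random() < conn.reliability
                lat = rng.normal(conn.latency_mean, conn.latency_sd)
                amp = _lognormal_mean_cv(
                    rng, conn.amplitude_mean * scale, conn.amplitude_cv
                )
                if not responds or not _event_allowed(conn, drug):
                    continue
                lat = max(lat, 0.0)
                onset = p + RECRUITMENT_DELAY_MS + lat
                if amp > 0:
                    i -= amp * _psc_kernel(t - onset)
                ann_rows.append(
                    {
                        "trial": float(trial),
                        "connection": float(ci),
                        "onset_ms": onset,
                        "latency_ms": onset - p,
                        "amplitude_pa": amp,
                        "kind": conn.kind,
                    }
                )
        if noise_sd > 0:
            i = i + rng.normal(0, noise_sd, size=n)
        data[trial] = i

    ann = pd.DataFrame(
        ann_rows,
        columns=[
            "trial",
            "connection",
            "onset_ms",
            "latency_ms",
            "amplitude_pa",
            "kind",
        ],
    )
    meta_rows = pd.DataFrame(
        {
            "stim_onset_ms": np.full(proto.n_trials, pulses[0]),
            "stim_amplitude_pa": np.zeros(proto.n_trials),
            "stim_duration_ms": np.full(proto.n_trials, proto.pulse_duration),
        }
    )
    return TraceSet(
        data=data,
        sampling_rate=rate,
        units="pA",
        sweep_meta=meta_rows,
        annotations=ann,
        meta={"kind": "photostim_vc", "pulse_onset_ms": float(pulses[0])},
    )


# --------------------------------------------------------------------------
# miniature EPSC trains
# --------------------------------------------------------------------------


def simulate_mepsc_train(
    rate: float,
    amplitude_mean: float,
    duration: float,
    capsaicin_factor: float,
    seed: int,
    sampling_rate: float = 10.0,
    amplitude_cv: float = 0.3,
    noise_sd: float = 3.0,
) -> TraceSet:
    """Poisson mEPSC train: baseline epoch at ``rate`` (Hz) for ``duration``
    seconds, then a second epoch at ``rate * capsaicin_factor``. Amplitudes
    are drawn identically in both epochs."""
    if rate <= 0:
        raise ValueError("rate must be positive")
    if duration <= 0:
        raise ValueError("duration must be positive")
    if capsaicin_factor < 0:
        raise ValueError("capsaicin_factor must be >= 0")
    rng = np.random.default_rng(seed)
    dur_ms = duration * 1000.0
    total_ms = 2 * dur_ms
    n = int(round(total_ms * sampling_rate))
    t = np.arange(n) / sampling_rate

    def _draw(rate_hz, t0):
        count = rng.poisson(rate_hz * duration)
        times = np.sort(rng.uniform(t0, t0 + dur_ms, size=count))
        amps = np.array(
            [_lognormal_mean_cv(rng, amplitude_mean, amplitude_cv) for _ in times]
        )
        return times, amps

    tb, ab = _draw(rate, 0.0)
    tp, ap_ = _draw(rate * capsaicin_factor, dur_ms)
    i = np.zeros(n)
    for times, amps in ((tb, ab), (tp, ap_)):
        for et, ea in zip(times, amps):
            j0 = int(et * sampling_rate)
            j1 = min(n, j0 + int(40 * sampling_rate))
            i[j0:j1] -= ea * _psc_kernel(t[j0:j1] - et)
    if noise_sd > 0:
        i = i + rng.normal(0, noise_sd, size=n)

    ann = pd.DataFrame(
        {
            "time_ms": np.concatenate([tb, tp]),
            "amplitude_pa": np.concatenate([ab, ap_]),
            "epoch": ["baseline"] * tb.size + ["capsaicin"] * tp.size,
        }
    )
    return TraceSet(
        data=i[None, :],
        sampling_rate=sampling_rate,
        units="pA",
        annotations=ann,
        meta={
            "kind": "mepsc_vc",
            "epoch_duration_ms": dur_ms,
            "rate_hz": float(rate),
            "capsaicin_factor": float(capsaicin_factor),
        },
    )


# --------------------------------------------------------------------------
# closed-form passive (RC) voltage-clamp response
# --------------------------------------------------------------------------


def synth_rc_response(
    r_series: float,
    r_input: float,
    c_mem: float,
    step_mv: float = -5.0,
    step_onset: float = 5.0,
    step_duration: float = 10.0,
    sampling_rate: float = 20.0,
    total_ms: float = 25.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> Sweep:
    """Exact current response of the series-Rs / parallel-(Rin, Cm) circuit
    to a small voltage step (mV -> pA), used as an independent oracle for
    passive-property estimation."""
    if step_mv == 0:
        raise ValueError("step amplitude must be non-zero")
    n = int(round(total_ms * sampling_rate))
    t = np.arange(n) / sampling_rate
    i_peak = step_mv / r_series * 1000.0  # pA
    i_ss = step_mv / (r_series + r_input) * 1000.0
    tau = c_mem * (r_series * r_input / (r_series + r_input)) / 1000.0  # ms

    def f(ts):
        out = np.zeros_like(ts)
        pos = ts >= 0
        out[pos] = i_ss + (i_peak - i_ss) * np.exp(-ts[pos] / tau)
        return out

    i = f(t - step_onset) - f(t - step_onset - step_duration)
    if noise_sd > 0:
        i = i + np.random.default_rng(seed).normal(0, noise_sd, size=n)
    return Sweep(
        samples=i,
        sampling_rate=sampling_rate,
        units="pA",
        stim_onset=step_onset,
        stim_amplitude=step_mv,
        stim_duration=step_duration,
    )


# --------------------------------------------------------------------------
# morphology generator
# --------------------------------------------------------------------------


@dataclass
class MorphoClassSpec:
    """Population targets for one morphological class.

    Scalar targets are sampled per cell from a log-normal with the given
    mean and coefficient of variation ``dispersion_cv``; the grown tree
    then hits its sampled total length and spreads (near-)exactly.
    """

    name: str = "class"
    soma_volume_um3: float = 500.0
    total_length_um: float = 1000.0
    rc_length_um: float = 750.0
    rc_spread_um: float = 300.0
    dv_spread_um: float = 120.0
    n_primary_dendrites: int = 5
    branch_prob: float = 0.02  # per growth step
    tortuosity_wiggle: float = 0.3  # per-step ML sign-flip probability
    dispersion_cv: float = 0.25
    step_um: float = 5.0

    def __post_init__(self) -> None:
        for f in (
            self.soma_volume_um3,
            self.total_length_um,
            self.rc_length_um,
            self.rc_spread_um,
        ):
            if f <= 0:
                raise ValueError("all means must be positive")
        if self.dv_spread_um < 0:
            raise ValueError("dv_spread_um must be >= 0")
        if not 0.0 <= self.branch_prob <= 1.0:
            raise ValueError("branch_prob must lie in [0, 1]")


def ipvin_morphology_spec() -> MorphoClassSpec:
    """Inhibitory-PVIN class: large somata, long rostrocaudally elongated
    arbors (population means match the reported group statistics)."""
    return MorphoClassSpec(
        name="iPVIN",
        soma_volume_um3=841.8,
        total_length_um=2054.0,
        rc_length_um=1603.0,
        rc_spread_um=433.4,
        dv_spread_um=150.0,
        n_primary_dendrites=5,
        branch_prob=0.025,
    )


def epvin_morphology_spec() -> MorphoClassSpec:
    """Excitatory-PVIN class: smaller somata and more compact arbors."""
    return MorphoClassSpec(
        name="ePVIN",
        soma_volume_um3=444.3,
        total_length_um=943.0,
        rc_length_um=696.0,
        rc_spread_um=236.2,
        dv_spread_um=110.0,
        n_primary_dendrites=4,
        branch_prob=0.02,
    )


def _sample_mean_cv(rng, mean, cv):
    if cv <= 0:
        return float(mean)
    return _lognormal_mean_cv(rng, mean, cv)


class _Walker:
    """Grows one dendritic subtree as a bounded zigzag walk.

    Every full step has a fixed |ΔRC| = c * step so the summed RC length is
    (almost) exact; on reaching an RC or DV bound the step lands exactly on
    the bound and the walk direction reflects, which keeps the coordinate
    extents equal to the sampled spreads.
    """

    def __init__(self, builder, c, d, rc_bound, dv_bound, wiggle, rng):
        self.b = builder
        self.c = c
        self.d = d
        self.rc_bound = rc_bound
        self.dv_bound = dv_bound
        self.wiggle = wiggle
        self.rng = rng

    def grow(self, parent_id, pos, rc_sign, dv_sign, budget, branch_prob, depth=0):
        rc_dir, dv_dir = 1.0, 1.0  # outward along the stem's side
        ml_sign = 1.0 if self.rng.random() < 0.5 else -1.0
        step = self.b.step
        while budget > 1e-9:
            ln = min(step, budget)
            # RC displacement (signed position within [0, rc_bound])
            p = abs(pos[0])
            drc = self.c * ln
            if rc_dir > 0 and p + drc > self.rc_bound:
                drc = self.rc_bound - p
                rc_dir = -1.0
            elif rc_dir < 0 and p - drc < 0:
                drc = p
                rc_dir = 1.0
                drc = -drc
            elif rc_dir < 0:
                drc = -drc
            # DV displacement
            q = abs(pos[1])
            ddv = self.d * ln
            if self.dv_bound <= 0:
                ddv = 0.0
            elif dv_dir > 0 and q + ddv > self.dv_bound:
                ddv = self.dv_bound - q
                dv_dir = -1.0
            elif dv_dir < 0 and q - ddv < 0:
                ddv = q
                dv_dir = 1.0
                ddv = -ddv
            elif dv_dir < 0:
                ddv = -ddv
            ml = math.sqrt(max(ln**2 - drc**2 - ddv**2, 0.0))
            if self.wiggle > 0 and self.rng.random() < self.wiggle:
                ml_sign = -ml_sign
            new = pos + np.array([rc_sign * drc, dv_sign * ddv, ml_sign * ml])
            parent_id = self.b.add_node(new, parent_id)
            pos = new
            budget -= ln
            if (
                branch_prob > 0
                and budget > 4 * step
                and self.rng.random() < branch_prob
            ):
                child_budget = 0.4 * budget
                budget -= child_budget
                self.grow(
                    parent_id,
                    pos,
                    rc_sign,
                    dv_sign,
                    child_budget,
                    branch_prob,
                    depth + 1,
                )


class _TreeBuilder:
    def __init__(self, soma_radius, step):
        self.step = step
        self.ids = [1]
        self.types = [1]
        self.xyz = [np.zeros(3)]
        self.radius = [soma_radius]
        self.parent = [-1]

    def add_node(self, pos, parent_id, radius=0.5, node_type=3):
        nid = self.ids[-1] + 1
        self.ids.append(nid)
        self.types.append(node_type)
        self.xyz.append(np.asarray(pos, dtype=float))
        self.radius.append(radius)
        self.parent.append(parent_id)
        return nid

    def build(self) -> Morphology:
        return Morphology(
            ids=np.array(self.ids),
            types=np.array(self.types),
            xyz=np.vstack(self.xyz),
            radius=np.array(self.radius),
            parent=np.array(self.parent),
        )


def generate_morphology(
    spec: MorphoClassSpec, seed: int, max_attempts: int = 10
) -> Morphology:
    """Grow one SWC-conformant cell from a class spec.

    The soma is a single sphere node; ``n_primary_dendrites`` stems grow as
    RC-biased bounded walks so that total length, RC-projected length, and
    RC/DV spreads match the per-cell sampled targets. Raises RuntimeError
    if the sampled targets are geometrically unreachable after bounded
    retries.
    """
    rng = np.random.default_rng(seed)
    last_err = None
    for _ in range(max_attempts):
        L = _sample_mean_cv(rng, spec.total_length_um, spec.dispersion_cv)
        # the RC fraction is sampled as a ratio (tied to this cell's L) so
        # the realized RC length averages to the population target without
        # rejecting draws where an independent Lrc would exceed L
        ratio_mean = spec.rc_length_um / spec.total_length_um
        ratio = _sample_mean_cv(rng, ratio_mean, spec.dispersion_cv / 2.0)
        ratio_cap = 0.95 if spec.dv_spread_um > 0 else 1.0
        Lrc = min(ratio, ratio_cap) * L
        Src = _sample_mean_cv(rng, spec.rc_spread_um, spec.dispersion_cv)
        Sdv = (
            _sample_mean_cv(rng, spec.dv_spread_um, spec.dispersion_cv)
            if spec.dv_spread_um > 0
            else 0.0
        )
        Vsoma = _sample_mean_cv(rng, spec.soma_volume_um3, spec.dispersion_cv)
        c = min(max(Lrc / L, 0.05), 1.0)
        n_stems = max(1, int(spec.n_primary_dendrites))
        rc_bound = Src if n_stems == 1 else Src / 2.0
        # the principal stems are unbranched so their path depth, and hence
        # the coordinate extents, are guaranteed by their length budget
        need = rc_bound / c + 1e-9
        n_principal = 1 if n_stems == 1 else 2
        if n_principal * need > 0.98 * L and n_stems > 1:
            last_err = "RC spread unreachable with total length"
            continue
        if n_stems == 1:
            if need > L + 1e-9:
                last_err = "RC spread unreachable with total length"
                continue
            budgets = [L]
        else:
            even = L / n_stems
            b0 = max(need, even)
            rest = L - 2 * b0
            others = max(n_stems - 2, 0)
            if others and rest <= 0:
                others, rest = 0, 0.0
            budgets = [b0, b0] + ([rest / others] * others if others else [])
        rem = math.sqrt(max(1 - c * c, 0.0))
        if Sdv > 0 and rem > 0:
            dv_bound = Sdv if n_stems == 1 else Sdv / 2.0
            d_req = dv_bound / (0.9 * max(budgets[0], 1e-9))
            if d_req > 0.9 * rem:
                last_err = "DV spread unreachable with direction budget"
                continue
            d = min(max(d_req, 0.3 * rem), 0.9 * rem)
        else:
            dv_bound, d = 0.0, 0.0

        soma_r = (3.0 * Vsoma / (4.0 * math.pi)) ** (1.0 / 3.0)
        b = _TreeBuilder(soma_r, spec.step_um)
        walker = _Walker(
            b, c, d, rc_bound, dv_bound, spec.tortuosity_wiggle, rng
        )
        for k, budget in enumerate(budgets):
            rc_sign = 1.0 if k % 2 == 0 else -1.0
            if k == 0:
                dv_sign = 1.0
            elif k == 1:
                dv_sign = -1.0
            else:
                dv_sign = 1.0 if rng.random() < 0.5 else -1.0
            bp = 0.0 if k < n_principal else spec.branch_prob
            walker.grow(1, np.zeros(3), rc_sign, dv_sign, budget, bp)
        m = b.build()
        rc = m.axis_coord("RC")
        dv = m.axis_coord("DV")
        rc_ext = rc.max() - rc.min()
        dv_ext = dv.max() - dv.min()
        if rc_ext < 0.9 * Src or (Sdv > 0 and dv_ext < 0.85 * Sdv):
            last_err = "spread target missed"
            continue
        return m
    raise RuntimeError(
        f"could not generate morphology for {spec.name}: {last_err}"
    )


# --------------------------------------------------------------------------
# transcript-count tables
# --------------------------------------------------------------------------


@dataclass
class GeneModel:
    """Per-gene expression model within one cell class."""

    expr_prob: float  # probability the gene is expressed in this class
    pos_mean: float = 20.0  # mean extra transcripts above the floor of 5
    pos_shape: float = 4.0  # gamma shape of the Poisson rate (overdispersion)
    neg_lambda: float = 0.3  # Poisson background in non-expressing cells

    def sample(self, rng) -> int:
        if rng.random() < self.expr_prob:
            lam = rng.gamma(self.pos_shape, self.pos_mean / self.pos_shape)
            return 5 + int(rng.poisson(lam))
        return int(rng.poisson(self.neg_lambda)) if self.neg_lambda > 0 else 0


@dataclass
class TranscriptPanelSpec:
    """Gene panel with per-class expression models and class mixture."""

    genes: tuple = ("PValb", "Slc17a6", "GAD1", "CCK")
    classes: dict = field(default_factory=dict)  # class -> {gene: GeneModel}
    class_mixture: dict = field(default_factory=dict)  # class -> proportion

    def __post_init__(self) -> None:
        if self.classes:
            props = np.array(
                [self.class_mixture.get(c, 0.0) for c in self.classes]
            )
            if np.any(props < 0) or not np.isclose(props.sum(), 1.0):
                raise ValueError("class proportions must sum to 1")


def default_transcript_panel(
    excitatory_fraction: float = 0.527, cck_in_excitatory: float = 0.745
) -> TranscriptPanelSpec:
    """Panel emulating the in situ experiment: PV cells split into an
    excitatory (Slc17a6+) and an inhibitory (GAD1+) class, with CCK
    co-expressed in most excitatory cells."""
    exc = {
        "PValb": GeneModel(1.0),
        "Slc17a6": GeneModel(1.0),
        "GAD1": GeneModel(0.0),
        "CCK": GeneModel(cck_in_excitatory),
    }
    inh = {
        "PValb": GeneModel(1.0),
        "Slc17a6": GeneModel(0.0),
        "GAD1": GeneModel(1.0),
        "CCK": GeneModel(0.05),
    }
    return TranscriptPanelSpec(
        classes={"excitatory": exc, "inhibitory": inh},
        class_mixture={
            "excitatory": excitatory_fraction,
            "inhibitory": 1.0 - excitatory_fraction,
        },
    )


def generate_transcript_table(
    panel: TranscriptPanelSpec, n_cells_per_animal, seed: int
) -> pd.DataFrame:
    """Per-cell integer transcript counts with hidden true class labels.

    Returns a wide DataFrame: ``cell_id``, ``animal``, ``true_class``, and
    one count column per gene.
    """
    rng = np.random.default_rng(seed)
    class_names = list(panel.classes)
    props = np.array([panel.class_mixture[c] for c in class_names])
    rows = []
    cell_n = 0
    for ai, n_cells in enumerate(n_cells_per_animal):
        for _ in range(int(n_cells)):
            cls = class_names[rng.choice(len(class_names), p=props)]
            counts = {
                g: panel.classes[cls][g].sample(rng) for g in panel.genes
            }
            rows.append(
                {
                    "cell_id": f"cell_{cell_n:05d}",
                    "animal": f"animal_{ai + 1}",
                    "true_class": cls,
                    **counts,
                }
            )
            cell_n += 1
    return pd.DataFrame(rows)


def transcripts_to_long(table: pd.DataFrame, genes) -> pd.DataFrame:
    """Wide table -> long TSV layout (`cell_id animal gene count`)."""
    long = table.melt(
        id_vars=["cell_id", "animal"],
        value_vars=list(genes),
        var_name="gene",
        value_name="count",
    )
    return long.sort_values(["cell_id", "gene"]).reset_index(drop=True)
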