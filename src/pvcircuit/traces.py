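"""Sweep and TraceSet containers with an HDF5 on-disk layout.

A :class:`TraceSet` holds a stack of uniformly sampled sweeps (all the same
length and sampling rate), per-sweep stimulus metadata, free-form scalar
metadata, and an optional ground-truth event table (annotations) used by the
synthetic generators and by recovery tests.

HDF5 layout::

    /sweeps                          float64, shape (n_sweeps, n_samples)
    /meta                            group; scalar attrs (sampling_rate_khz,
                                     units, plus any user metadata)
    /sweep_meta/<column>             float64, shape (n_sweeps,)
    /annotations/<column>            one dataset per column (float64 or utf-8)

The CSV export is intentionally lossy (no annotations, no metadata); the HDF5
round trip is bit-exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

__all__ = ["Sweep", "TraceSet"]

_SWEEP_META_COLS = ("stim_onset_ms", "stim_amplitude_pa", "stim_duration_ms")


@dataclass
class Sweep:
    """A single uniformly sampled recording sweep (mV or pA)."""

    samples: np.ndarray
    sampling_rate: float  # kHz
    units: str = "mV"
    stim_onset: float = 0.0  # ms
    stim_amplitude: float = 0.0  # pA
    stim_duration: float = 0.0  # ms

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.stim_duration > 0:
            end = self.stim_onset + self.stim_duration
            if self.stim_onset < 0 or end > self.duration_ms + 1e-9:
                raise ValueError("stimulus window falls outside the sweep")

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def dt_ms(self) -> float:
        return 1.0 / self.sampling_rate

    @property
    def duration_ms(self) -> float:
        return self.n_samples / self.sampling_rate

    def time_ms(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate

    def index_at(self, t_ms: float) -> int:
        """Sample index of time ``t_ms`` (rounded to the grid)."""
        return int(round(t_ms * self.sampling_rate))


@dataclass
class TraceSet:
    """A stack of sweeps with shared sampling rate and units."""

    data: np.ndarray  # (n_sweeps, n_samples)
    sampling_rate: float  # kHz
    units: str = "mV"
    sweep_meta: pd.DataFrame | None = None
    annotations: pd.DataFrame | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=np.float64))
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        n = self.data.shape[0]
        if self.sweep_meta is None:
            self.sweep_meta = pd.DataFrame(
                {c: np.zeros(n) for c in _SWEEP_META_COLS}
            )
        if len(self.sweep_meta) != n:
            raise ValueError("sweep_meta length does not match sweep count")

    @property
    def n_sweeps(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def time_ms(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate

    def sweep(self, i: int) -> Sweep:
        row = self.sweep_meta.iloc[i]
        return Sweep(
            samples=self.data[i],
            sampling_rate=self.sampling_rate,
            units=self.units,
            stim_onset=float(row.get("stim_onset_ms", 0.0)),
            stim_amplitude=float(row.get("stim_amplitude_pa", 0.0)),
            stim_duration=float(row.get("stim_duration_ms", 0.0)),
        )

    def sweeps(self) -> list[Sweep]:
        return [self.sweep(i) for i in range(self.n_sweeps)]

    def average(self) -> Sweep:
        """Sweep-wise mean trace (the "10-trial average")."""
        row = self.sweep_meta.iloc[0]
        return Sweep(
            samples=self.data.mean(axis=0),
            sampling_rate=self.sampling_rate,
            units=self.units,
            stim_onset=float(row.get("stim_onset_ms", 0.0)),
            stim_amplitude=float(row.get("stim_amplitude_pa", 0.0)),
            stim_duration=float(row.get("stim_duration_ms", 0.0)),
        )

    # ------------------------------------------------------------------ I/O

    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("sweeps", data=self.data)
            meta = f.create_group("meta")
            meta.attrs["sampling_rate_khz"] = float(self.sampling_rate)
            meta.attrs["units"] = self.units
            for k, v in self.meta.items():
                meta.attrs[k] = v
            sm = f.create_group("sweep_meta")
            for col in self.sweep_meta.columns:
                sm.create_dataset(
                    col, data=np.asarray(self.sweep_meta[col], dtype=np.float64)
                )
            if self.annotations is not None:
                ann = f.create_group("annotations")
                ann.attrs["columns"] = list(self.annotations.columns)
                for col in self.annotations.columns:
                    vals = self.annotations[col].to_numpy()
                    if vals.dtype.kind in "OU":
                        ann.create_dataset(
                            col,
                            data=np.array(
                                [str(v).encode() for v in vals], dtype="S64"
                            ),
                        )
                    else:
                        ann.create_dataset(
                            col, data=np.asarray(vals, dtype=np.float64)
                        )

    @classmethod
    def from_hdf5(cls, path) -> "TraceSet":
        with h5py.File(path, "r") as f:
            data = f["sweeps"][()]
            meta_grp = f["meta"]
            rate = float(meta_grp.attrs["sampling_rate_khz"])
            units = str(meta_grp.attrs["units"])
            meta = {
                k: (v.item() if hasattr(v, "item") else v)
                for k, v in meta_grp.attrs.items()
                if k not in ("sampling_rate_khz", "units")
            }
            meta = {
                k: (v.decode() if isinstance(v, bytes) else v)
                for k, v in meta.items()
            }
            sweep_meta = pd.DataFrame(
                {col: f["sweep_meta"][col][()] for col in f["sweep_meta"]}
            )
            annotations = None
            if "annotations" in f:
                cols = list(f["annotations"].attrs["columns"])
                out = {}
                for col in cols:
                    vals = f["annotations"][col][()]
                    if vals.dtype.kind == "S":
                        vals = np.array([v.decode() for v in vals], dtype=object)
                    out[col] = vals
                annotations = pd.DataFrame(out)
        return cls(
            data=data,
            sampling_rate=rate,
            units=units,
            sweep_meta=sweep_meta,
            annotations=annotations,
            meta=meta,
        )

    def to_csv(self, path) -> None:
        """Lossy CSV export: time column plus one column per sweep."""
        df = pd.DataFrame(
            self.data.T,
            columns=[f"sweep_{i:03d}" for i in range(self.n_sweeps)],
        )
        df.insert(0, "time_ms", self.time_ms())
        df.to_csv(path, index=False)
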