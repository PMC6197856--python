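"""Epoched sensor data container with HDF5 round-trip."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

__all__ = ["EpochedData"]


@dataclass
class EpochedData:
    """Trials × channels × samples sensor data.

    The time axis is in seconds with 0 at the alignment event (one of
    ``rdk``, ``cue``, ``response``).  ``trials`` is a per-trial condition
    table (congruence, coherence level, correctness, rejection mask, ...).
    """

    data: np.ndarray  # (n_trials, n_channels, n_samples)
    sfreq: float
    times: np.ndarray  # (n_samples,), seconds, 0 at alignment event
    event: str = "rdk"
    trials: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, float)
        self.times = np.asarray(self.times, float)
        if self.data.ndim != 3:
            raise ValueError("data must be (trials, channels, samples)")
        if len(self.times) != self.data.shape[2]:
            raise ValueError("time axis length must equal sample count")
        if len(self.trials) == 0:
            self.trials = pd.DataFrame(index=range(self.data.shape[0]))
        if len(self.trials) != self.data.shape[0]:
            raise ValueError("trial table rows must equal trial count")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def time_mask(self, tmin: float, tmax: float) -> np.ndarray:
        return (self.times >= tmin) & (self.times <= tmax)

    def save(self, path: str | Path) -> None:
        with h5py.File(path, "w") as f:
            d = f.create_dataset("data", data=self.data)
            d.attrs["dims"] = ["trial", "channel", "sample"]
            f.create_dataset("times", data=self.times)
            f.attrs["sfreq"] = self.sfreq
            f.attrs["event"] = self.event
            g = f.create_group("trials")
            for col in self.trials.columns:
                vals = self.trials[col].to_numpy()
                if vals.dtype == object:
                    vals = vals.astype("S")
                g.create_dataset(str(col), data=vals)

    @classmethod
    def load(cls, path: str | Path) -> "EpochedData":
        with h5py.File(path, "r") as f:
            cols = {}
            for k in f["trials"]:
                v = f["trials"][k][()]
                if v.dtype.kind == "S":
                    v = v.astype(str)
                cols[k] = v
            return cls(
                data=f["data"][()],
                sfreq=float(f.attrs["sfreq"]),
                times=f["times"][()],
                event=str(f.attrs["event"]),
                trials=pd.DataFrame(cols),
            )
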