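"""Core containers and text-based I/O.

The whole package works on uniformly sampled multichannel series
(channels x samples) and on per-sample integer state labelings.  Both are
thin dataclasses over numpy arrays; every analysis function accepts and
returns these so that intermediate products (envelopes, CSD signals,
simulated amplitudes) share one representation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


@dataclass
class MultichannelSeries:
    """Uniformly sampled channels x samples matrix.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal values; float.
    sample_rate : float
        Sampling rate in Hz.
    channel_names : list of str, optional
        One name per channel; generated as ``ch01..chNN`` when omitted.
    t0 : float
        Time of the first retained sample in seconds.  Edge trimming during
        envelope analysis advances ``t0`` so levels stay mutually alignable.
    """

    data: np.ndarray
    sample_rate: float
    channel_names: list[str] = field(default_factory=list)
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if not self.channel_names:
            self.channel_names = [f"ch{i + 1:02d}" for i in range(self.n_channels)]
        if len(self.channel_names) != self.n_channels:
            raise ValueError("channel_names length must match data rows")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sample_rate

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.sample_rate

    def copy_with(self, data: np.ndarray, t0: float | None = None) -> "MultichannelSeries":
        return MultichannelSeries(
            data=np.asarray(data, dtype=float),
            sample_rate=self.sample_rate,
            channel_names=list(self.channel_names),
            t0=self.t0 if t0 is None else t0,
        )

    def save(self, path: str | Path) -> None:
        """Write as delimited matrix plus a JSON metadata sidecar."""
        path = Path(path)
        np.savetxt(path, self.data.T, delimiter="\t")
        meta = {
            "sample_rate": self.sample_rate,
            "channel_names": self.channel_names,
            "t0": self.t0,
        }
        path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "MultichannelSeries":
        path = Path(path)
        meta_path = path.with_suffix(path.suffix + ".meta.json")
        if not meta_path.exists():
            raise FileNotFoundError(f"missing metadata sidecar: {meta_path}")
        meta = json.loads(meta_path.read_text())
        data = np.loadtxt(path, delimiter="\t").T
        if data.ndim == 1:
            data = data[np.newaxis, :]
        return cls(
            data=data,
            sample_rate=float(meta["sample_rate"]),
            channel_names=list(meta["channel_names"]),
            t0=float(meta.get("t0", 0.0)),
        )


@dataclass
class StateLabeling:
    """Per-sample state labels L(t) in {1..K}.

    ``centroids`` (K x channels) is populated when the labeling comes from
    clustering; overlap-based labelings leave it empty.
    """

    labels: np.ndarray
    K: int
    centroids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 1:
            raise ValueError("labels must be 1-D")
        if self.K < 1:
            raise ValueError("K must be >= 1")
        present = np.unique(self.labels)
        if present.min() < 1 or present.max() > self.K:
            raise ValueError("labels must lie in {1..K}")

    @property
    def n_samples(self) -> int:
        return self.labels.size

    def state_mask(self, k: int) -> np.ndarray:
        return self.labels == k

    def counts(self) -> np.ndarray:
        """Occupancy of each state 1..K (may contain zeros)."""
        return np.bincount(self.labels, minlength=self.K + 1)[1:]

    def save(self, path: str | Path) -> None:
        np.savetxt(Path(path), self.labels, fmt="%d")

    @classmethod
    def load(cls, path: str | Path, K: int | None = None) -> "StateLabeling":
        labels = np.loadtxt(Path(path), dtype=int)
        return cls(labels=np.atleast_1d(labels), K=int(K or labels.max()))


def wrap_phase(theta: np.ndarray | float) -> np.ndarray:
    """Wrap angles to the interval (-pi, pi]."""
    wrapped = np.mod(-np.asarray(theta) + np.pi, 2.0 * np.pi)
    return np.pi - wrapped
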