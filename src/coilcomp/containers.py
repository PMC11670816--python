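"""In-memory containers shared across the toolkit.

``Montage`` holds electrode labels and unit-sphere positions; ``Epochs``
holds a channels x samples x trials tensor of epoched EEG in microvolts,
with a time axis in milliseconds relative to the TMS pulse, rejection
masks, and an append-only provenance log.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class Montage:
    """Electrode labels and 3-D positions on the unit sphere."""

    labels: tuple[str, ...]
    positions: np.ndarray  # (n_channels, 3), each row unit norm

    def __post_init__(self):
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 3:
            raise ValueError("positions must be (n_channels, 3)")
        if len(self.labels) != pos.shape[0]:
            raise ValueError("labels/positions length mismatch")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate electrode labels")
        norms = np.linalg.norm(pos, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("positions must lie on the unit sphere")
        object.__setattr__(self, "positions", pos)

    def __len__(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def subset(self, labels) -> "Montage":
        idx = [self.index(l) for l in labels]
        return Montage(tuple(labels), self.positions[idx])

    def cosine_angles(self, other: "Montage | None" = None) -> np.ndarray:
        """Pairwise cosines of great-circle angles between electrodes."""
        other = other if other is not None else self
        c = self.positions @ other.positions.T
        return np.clip(c, -1.0, 1.0)

    def to_table(self) -> str:
        """4-column whitespace table: label x y z."""
        lines = [
            f"{lab}\t{p[0]:.6f}\t{p[1]:.6f}\t{p[2]:.6f}"
            for lab, p in zip(self.labels, self.positions)
        ]
        return "\n".join(lines) + "\n"

    @classmethod
    def from_table(cls, text: str) -> "Montage":
        labels, rows = [], []
        for line in text.strip().splitlines():
            parts = line.split()
            if not parts or parts[0].startswith("#"):
                continue
            labels.append(parts[0])
            rows.append([float(v) for v in parts[1:4]])
        pos = np.asarray(rows)
        pos = pos / np.linalg.norm(pos, axis=1, keepdims=True)
        return cls(tuple(labels), pos)


@dataclass
class Epochs:
    """Epoched multichannel EEG: data is (channels, samples, trials), microvolts."""

    data: np.ndarray
    srate: float  # Hz
    times: np.ndarray  # ms relative to the pulse, strictly increasing
    ch_names: tuple[str, ...]
    montage: Montage | None = None
    bad_trials: np.ndarray = field(default=None)  # bool mask over trials
    bad_channels: np.ndarray = field(default=None)  # bool mask over channels
    provenance: list = field(default_factory=list)
    info: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be (channels, samples, trials)")
        if self.data.shape[0] != len(self.ch_names):
            raise ValueError("channel count mismatch")
        if self.data.shape[1] != self.times.size:
            raise ValueError("sample count mismatch with time axis")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.bad_trials is None:
            self.bad_trials = np.zeros(self.data.shape[2], dtype=bool)
        if self.bad_channels is None:
            self.bad_channels = np.zeros(self.data.shape[0], dtype=bool)
        if self.montage is not None and tuple(self.montage.labels) != tuple(self.ch_names):
            raise ValueError("montage labels do not match channel names")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def n_trials(self) -> int:
        return self.data.shape[2]

    def copy(self) -> "Epochs":
        return Epochs(
            data=self.data.copy(),
            srate=self.srate,
            times=self.times.copy(),
            ch_names=tuple(self.ch_names),
            montage=self.montage,
            bad_trials=self.bad_trials.copy(),
            bad_channels=self.bad_channels.copy(),
            provenance=list(self.provenance),
            info=dict(self.info),
        )

    def log(self, operation: str, **params) -> None:
        """Append a provenance entry; entries are never mutated afterwards."""
        self.provenance.append({"operation": operation, **params})

    def time_index(self, t_ms: float) -> int:
        """Index of the sample closest to ``t_ms``."""
        return int(np.argmin(np.abs(self.times - t_ms)))

    def time_mask(self, lo_ms: float, hi_ms: float) -> np.ndarray:
        """Boolean sample mask for the closed interval [lo_ms, hi_ms]."""
        return (self.times >= lo_ms) & (self.times <= hi_ms)

    def good_data(self) -> np.ndarray:
        """Data restricted to retained channels and trials."""
        return self.data[~self.bad_channels][:, :, ~self.bad_trials]

    def average(self) -> np.ndarray:
        """Trial-average ERP (channels x samples) over retained trials only."""
        keep = ~self.bad_trials
        if not keep.any():
            raise ValueError("no retained trials to average")
        return self.data[:, :, keep].mean(axis=2)

    def good_channel_names(self) -> list[str]:
        return [c for c, bad in zip(self.ch_names, self.bad_channels) if not bad]
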