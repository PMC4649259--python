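"""In-memory container for a multichannel EEG recording.

Amplitudes are kept in microvolts throughout; annotations are (label, sample
index) pairs, matching the manual piece-arrival markers of the museum
protocol.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np


@dataclass
class Recording:
    """channels x samples EEG matrix with labels, rate and annotations.

    Parameters
    ----------
    data
        Array of shape (n_channels, n_samples), microvolts.
    ch_names
        Unique channel labels (extended 10-20 names for scalp channels).
    fs
        Sampling rate in Hz.
    annotations
        Event markers as (label, sample index) pairs, sorted by sample.
    """

    data: np.ndarray
    ch_names: list[str]
    fs: float
    annotations: list[tuple[str, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.ch_names = list(self.ch_names)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if len(self.ch_names) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.ch_names)} labels for {self.data.shape[0]} channels"
            )
        if len(set(self.ch_names)) != len(self.ch_names):
            raise ValueError("channel labels must be unique")
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")
        self.annotations = sorted(
            [(str(lbl), int(s)) for lbl, s in self.annotations], key=lambda a: a[1]
        )
        for lbl, s in self.annotations:
            if not 0 <= s < self.n_samples:
                raise ValueError(f"annotation {lbl!r} at sample {s} out of bounds")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Length in seconds."""
        return self.n_samples / self.fs

    def copy(self) -> "Recording":
        return replace(
            self, data=self.data.copy(), ch_names=list(self.ch_names),
            annotations=list(self.annotations),
        )

    def index_of(self, label: str) -> int:
        try:
            return self.ch_names.index(label)
        except ValueError:
            raise KeyError(f"no channel {label!r}") from None

    def pick(self, labels) -> "Recording":
        """Sub-recording restricted to ``labels``, preserving their montage order."""
        idx = [self.index_of(lbl) for lbl in labels]
        return Recording(self.data[idx].copy(), [self.ch_names[i] for i in idx],
                         self.fs, list(self.annotations))

    def drop(self, labels) -> "Recording":
        keep = [ch for ch in self.ch_names if ch not in set(labels)]
        return self.pick(keep)

    def crop(self, start_sample: int, stop_sample: int) -> "Recording":
        """Samples [start, stop); annotations re-indexed, out-of-window ones dropped."""
        if not 0 <= start_sample < stop_sample <= self.n_samples:
            raise ValueError("invalid crop window")
        ann = [(lbl, s - start_sample) for lbl, s in self.annotations
               if start_sample <= s < stop_sample]
        return Recording(self.data[:, start_sample:stop_sample].copy(),
                         list(self.ch_names), self.fs, ann)
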