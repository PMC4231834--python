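"""Shared containers and montage constants.

The analyses in this package operate on a fixed 12-electrode scalp montage
(frontal, central, parietal, occipital rows in left/mid/right columns) plus
two mastoid reference channels, the layout used for nap polysomnography with
word stimulation.  Signals are held in plain numpy arrays in microvolts;
event tables are pandas DataFrames.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: Scalp electrodes, ordered row-wise: frontal, central, parietal, occipital.
SCALP_CHANNELS: tuple[str, ...] = (
    "F3", "Fz", "F4",
    "C3", "Cz", "C4",
    "P3", "Pz", "P4",
    "O1", "Oz", "O2",
)

#: Mastoid reference channels (left, right).
MASTOID_CHANNELS: tuple[str, ...] = ("M1", "M2")

#: Default full channel set of a recording.
ALL_CHANNELS: tuple[str, ...] = SCALP_CHANNELS + MASTOID_CHANNELS

#: Columns of an event log (one row per scheduled word presentation).
EVENT_COLUMNS = (
    "onset_s", "word_id", "repetition_index", "volume_dBA",
    "excluded", "exclusion_reason",
)


def channel_grid_position(name: str) -> tuple[int, int]:
    """(row, column) of a scalp electrode on the 4x3 montage grid."""
    if name not in SCALP_CHANNELS:
        raise KeyError(f"not a scalp channel: {name!r}")
    i = SCALP_CHANNELS.index(name)
    return divmod(i, 3)


def channel_adjacency(channels: tuple[str, ...] = SCALP_CHANNELS) -> np.ndarray:
    """Boolean adjacency matrix of the montage.

    Electrodes are neighbours when they sit next to each other in the same
    row or the same column of the 4x3 grid (rook moves, no diagonals).
    Channels outside the standard scalp set have no neighbours.
    """
    n = len(channels)
    adj = np.zeros((n, n), dtype=bool)
    pos = {}
    for i, ch in enumerate(channels):
        try:
            pos[i] = channel_grid_position(ch)
        except KeyError:
            continue
    for i, (ri, ci) in pos.items():
        for j, (rj, cj) in pos.items():
            if i != j and abs(ri - rj) + abs(ci - cj) == 1:
                adj[i, j] = True
    return adj


@dataclass
class EEGRecording:
    """A multichannel EEG recording in microvolts.

    Attributes
    ----------
    data : ndarray, shape (n_channels, n_samples)
    sfreq : float
        Sampling rate in Hz.
    ch_names : tuple of str
    artifacts : list of (start_s, end_s)
        Intervals marked as rejected (arousals, movement); sorted,
        non-overlapping.
    participant : int or None
    """

    data: np.ndarray
    sfreq: float
    ch_names: tuple[str, ...]
    artifacts: list[tuple[float, float]] = field(default_factory=list)
    participant: int | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.data.shape[0] != len(self.ch_names):
            raise ValueError(
                f"{self.data.shape[0]} rows but {len(self.ch_names)} channel names"
            )
        self.ch_names = tuple(self.ch_names)

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.sfreq

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sfreq

    def get_channel(self, name: str) -> np.ndarray:
        try:
            return self.data[self.ch_names.index(name)]
        except ValueError:
            raise KeyError(f"channel {name!r} not in recording") from None

    def copy(self) -> "EEGRecording":
        return replace(self, data=self.data.copy(),
                       artifacts=list(self.artifacts))


def make_event_log(onsets_s, word_ids, repetition_index, volume_dBA) -> pd.DataFrame:
    """Assemble an event log DataFrame with the standard columns."""
    df = pd.DataFrame({
        "onset_s": np.asarray(onsets_s, dtype=float),
        "word_id": np.asarray(word_ids, dtype=int),
        "repetition_index": np.asarray(repetition_index, dtype=int),
        "volume_dBA": np.asarray(volume_dBA, dtype=float),
    })
    df["excluded"] = False
    df["exclusion_reason"] = ""
    return df


@dataclass
class EpochSet:
    """Epochs cut around word onsets.

    data has shape (n_epochs, n_channels, n_samples); ``times_ms`` is the
    shared epoch time axis in milliseconds relative to word onset, covering
    the half-open window [tmin, tmax).
    """

    data: np.ndarray
    times_ms: np.ndarray
    ch_names: tuple[str, ...]
    events: pd.DataFrame
    sfreq: float
    participant: int | None = None
    n_dropped: int = 0

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]
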