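"""Readers and writers for recordings, events, epochs and grids.

Recordings and array-valued results are stored in HDF5 (h5py); event
logs, behavioural tables and reports use tab-separated text.  Externally
supplied recordings can be read from EDF (via MNE) together with a
BIDS-like ``events.tsv``.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .core import EEGRecording, EpochSet, make_event_log
from .ersp import TimeFreqGrid


def save_recording_h5(rec: EEGRecording, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=rec.data, compression="gzip")
        f.attrs["sfreq"] = rec.sfreq
        f.attrs["ch_names"] = list(rec.ch_names)
        if rec.participant is not None:
            f.attrs["participant"] = rec.participant
        f.create_dataset("artifacts",
                         data=np.array(rec.artifacts, dtype=float)
                         if rec.artifacts else np.empty((0, 2)))


def load_recording_h5(path: str | Path) -> EEGRecording:
    with h5py.File(path, "r") as f:
        return EEGRecording(
            data=f["data"][()],
            sfreq=float(f.attrs["sfreq"]),
            ch_names=tuple(str(c) for c in f.attrs["ch_names"]),
            artifacts=[tuple(map(float, row)) for row in f["artifacts"][()]],
            participant=(int(f.attrs["participant"])
                         if "participant" in f.attrs else None),
        )


def save_events_tsv(events: pd.DataFrame, path: str | Path) -> None:
    events.to_csv(path, sep="\t", index=False)


def load_events_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "excluded" not in df.columns:
        df["excluded"] = False
        df["exclusion_reason"] = ""
    return df


def save_epochs_h5(ep: EpochSet, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=ep.data, compression="gzip")
        f.create_dataset("times_ms", data=ep.times_ms)
        f.attrs["sfreq"] = ep.sfreq
        f.attrs["ch_names"] = list(ep.ch_names)
        f.attrs["n_dropped"] = ep.n_dropped
        if ep.participant is not None:
            f.attrs["participant"] = ep.participant
        grp = f.create_group("events")
        for col in ep.events.columns:
            vals = ep.events[col].to_numpy()
            if vals.dtype == object:
                vals = vals.astype("S")
            grp.create_dataset(col, data=vals)


def save_grid_h5(grid: TimeFreqGrid, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=grid.values, compression="gzip")
        f.create_dataset("freqs", data=grid.freqs)
        f.create_dataset("times_ms", data=grid.times_ms)
        f.attrs["ch_names"] = list(grid.ch_names)


def load_grid_h5(path: str | Path) -> TimeFreqGrid:
    with h5py.File(path, "r") as f:
        return TimeFreqGrid(
            values=f["values"][()], freqs=f["freqs"][()],
            times_ms=f["times_ms"][()],
            ch_names=tuple(str(c) for c in f.attrs["ch_names"]))


def save_config_yaml(config: dict, path: str | Path) -> None:
    with open(path, "w") as f:
        yaml.safe_dump(config, f, sort_keys=False)


def load_config_yaml(path: str | Path) -> dict:
    with open(path) as f:
        return yaml.safe_load(f) or {}


def read_edf(path: str | Path,
             events_tsv: str | Path | None = None
             ) -> tuple[EEGRecording, pd.DataFrame | None]:
    """Read an externally recorded EDF file (and optionally a BIDS-like
    events.tsv with columns onset, word_id/trial_type, ...).

    Data are converted to microvolts.  Requires MNE.
    """
    try:
        import mne
    except ImportError as err:  # pragma: no cover
        raise ImportError("reading EDF requires the 'mne' package") from err
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    rec = EEGRecording(data=raw.get_data() * 1e6,
                       sfreq=float(raw.info["sfreq"]),
                       ch_names=tuple(raw.ch_names))
    events = None
    if events_tsv is not None:
        df = pd.read_csv(events_tsv, sep="\t")
        onset = df["onset"] if "onset" in df.columns else df["onset_s"]
        word = (df["word_id"] if "word_id" in df.columns
                else pd.factorize(df.get("trial_type", onset))[0])
        rep = df.get("repetition_index", pd.Series(np.zeros(len(df), int)))
        vol = df.get("volume_dBA", pd.Series(np.full(len(df), np.nan)))
        events = make_event_log(onset, word, rep, vol)
    return rec, events
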