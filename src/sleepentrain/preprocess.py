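"""Re-referencing, trial exclusion, epoching and baseline correction.

The event-related analyses run on unfiltered EEG: epochs from 1 s before
to 3 s after word onset are cut from the mastoid-re-referenced signal and
baseline-corrected by subtracting the mean of the 1 s pre-stimulus window
(long enough to be unbiased by the phase of the dominant ~1 Hz rhythm of
deep NREM sleep).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import MASTOID_CHANNELS, EEGRecording, EpochSet

#: Exclusion window: a word is rejected if its onset falls within this many
#: seconds before the start of a rejected segment (or inside one).
PRE_ARTIFACT_WINDOW_S = 3.0


def rereference_pooled_mastoids(
    rec: EEGRecording,
    mastoids: tuple[str, str] = MASTOID_CHANNELS,
) -> EEGRecording:
    """Subtract the mean of the two mastoid channels from every scalp
    channel, sample-wise, and drop the mastoids from the output."""
    for m in mastoids:
        if m not in rec.ch_names:
            raise ValueError(f"mastoid channel {m!r} missing from recording")
    m_idx = [rec.ch_names.index(m) for m in mastoids]
    keep = [i for i in range(len(rec.ch_names)) if i not in m_idx]
    ref = rec.data[m_idx].mean(axis=0)
    return EEGRecording(
        data=rec.data[keep] - ref,
        sfreq=rec.sfreq,
        ch_names=tuple(rec.ch_names[i] for i in keep),
        artifacts=list(rec.artifacts),
        participant=rec.participant,
    )


def apply_exclusion_rules(
    events: pd.DataFrame,
    artifacts: list[tuple[float, float]],
    pre_window_s: float = PRE_ARTIFACT_WINDOW_S,
) -> pd.DataFrame:
    """Flag events contaminated by rejected EEG segments.

    An event is excluded when its onset lies within ``pre_window_s`` seconds
    before the start of a rejected interval or inside one (the word's
    evoked response would overlap the rejected data).  If any presentation
    of a repeated word is excluded, every presentation of that word is
    excluded as well, so behavioural and EEG analyses see the same words.
    Re-applying the rules never un-excludes an event.
    """
    for s, e in artifacts:
        if e < s or s < 0:
            raise ValueError(f"invalid artifact interval ({s}, {e})")
    out = events.copy()
    onsets = out["onset_s"].to_numpy()
    hit = np.zeros(len(out), dtype=bool)
    for s, e in artifacts:
        hit |= (onsets >= s - pre_window_s) & (onsets <= e)
    reason = np.where(hit, "artifact", "")
    bad_words = set(out.loc[hit, "word_id"])
    cascade = out["word_id"].isin(bad_words).to_numpy() & ~hit
    reason = np.where(cascade, "repetition_of_excluded_word", reason)
    newly = hit | cascade
    prev = out["excluded"].to_numpy(dtype=bool)
    out["excluded"] = prev | newly
    out["exclusion_reason"] = np.where(
        prev, out["exclusion_reason"], reason)
    return out


def epoch(
    rec: EEGRecording,
    events: pd.DataFrame,
    tmin: float = -1.0,
    tmax: float = 3.0,
) -> EpochSet:
    """Cut one epoch per non-excluded event over the half-open window
    [tmin, tmax) seconds around onset.

    Events whose window would exceed the recording bounds are dropped and
    counted in ``n_dropped``.  Zero usable events yields an empty EpochSet.
    """
    n_win = int(round((tmax - tmin) * rec.sfreq))
    usable = events[~events["excluded"].astype(bool)]
    segs, kept_rows = [], []
    n_dropped = 0
    for _, ev in usable.iterrows():
        i0 = int(round((ev["onset_s"] + tmin) * rec.sfreq))
        if i0 < 0 or i0 + n_win > rec.n_samples:
            n_dropped += 1
            continue
        segs.append(rec.data[:, i0:i0 + n_win])
        kept_rows.append(ev)
    times_ms = (np.arange(n_win) / rec.sfreq + tmin) * 1000.0
    if segs:
        data = np.stack(segs)
        meta = pd.DataFrame(kept_rows).reset_index(drop=True)
    else:
        data = np.empty((0, len(rec.ch_names), n_win))
        meta = usable.iloc[0:0].reset_index(drop=True)
    return EpochSet(data=data, times_ms=times_ms, ch_names=rec.ch_names,
                    events=meta, sfreq=rec.sfreq,
                    participant=rec.participant, n_dropped=n_dropped)


def baseline_correct(ep: EpochSet) -> EpochSet:
    """Subtract, per epoch and channel, the mean voltage over the 1 s
    pre-stimulus window (all samples with t < 0)."""
    pre = ep.times_ms < 0
    if not pre.any():
        raise ValueError("epochs do not include a pre-stimulus window")
    data = ep.data - ep.data[:, :, pre].mean(axis=2, keepdims=True)
    return EpochSet(data=data, times_ms=ep.times_ms, ch_names=ep.ch_names,
                    events=ep.events, sfreq=ep.sfreq,
                    participant=ep.participant, n_dropped=ep.n_dropped)


def average_erp(ep: EpochSet) -> np.ndarray:
    """Arithmetic mean across epochs -> (n_channels, n_samples)."""
    if ep.n_epochs == 0:
        raise ValueError("cannot average an empty epoch set")
    return ep.data.mean(axis=0)


def exclusion_report(events: pd.DataFrame) -> pd.DataFrame:
    """TSV-ready table of excluded events (event index, word, reason)."""
    bad = events[events["excluded"].astype(bool)]
    return pd.DataFrame({
        "event": bad.index,
        "word_id": bad["word_id"].to_numpy(),
        "onset_s": bad["onset_s"].to_numpy(),
        "reason": bad["exclusion_reason"].to_numpy(),
    })
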