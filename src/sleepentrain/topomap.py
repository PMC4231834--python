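"""Slow-oscillation-triggered topographies and their contrast.

Spontaneous slow-oscillation topographies come from averaging the raw
EEG of all detected slow oscillations aligned at the down-to-up
transition (the negative-to-positive zero crossing between the two
peaks) and reading the per-electrode amplitude at the down-state peak
(196 ms before the transition) and up-state peak (176 ms after it).
Entrained (word-evoked) topographies are the per-participant ERP values
at the group cluster peak times.  Before contrasting, every topography
is z-scored across electrodes within participant, which removes overall
amplitude and leaves only the spatial pattern; the contrast is the
Topography x Event interaction of a two-way repeated-measures ANOVA
(no sphericity correction is applied; see the methods note).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import EEGRecording
from .so_detect import SlowOscillation

#: Default lags (ms) of the down- and up-state peaks relative to the
#: down-to-up transition of the averaged slow oscillation.
DOWN_PEAK_LAG_MS = -196.0
UP_PEAK_LAG_MS = 176.0


@dataclass
class TriggeredAverage:
    """SO-triggered average waveform, aligned at the down-to-up
    transition (lag 0)."""

    data: np.ndarray          # (n_channels, n_lags)
    lags_ms: np.ndarray
    ch_names: tuple[str, ...]
    n_oscillations: int


def so_triggered_average(rec: EEGRecording, sos: list[SlowOscillation],
                         window_s: tuple[float, float] = (-0.5, 0.5)
                         ) -> TriggeredAverage:
    """Average the raw multichannel EEG across slow oscillations, centred
    on each oscillation's down-to-up transition."""
    lo, hi = window_s
    if hi <= lo or hi < 0.4 or lo > -0.4:
        raise ValueError("window must cover at least [-0.4, 0.4] s")
    n_pre = int(round(-lo * rec.sfreq))
    n_post = int(round(hi * rec.sfreq))
    segs = []
    for so in sos:
        if so.transition_time is None:
            continue
        i = int(round(so.transition_time * rec.sfreq))
        if i - n_pre < 0 or i + n_post > rec.n_samples:
            continue
        segs.append(rec.data[:, i - n_pre:i + n_post])
    if not segs:
        raise ValueError("no usable slow oscillations for averaging")
    avg = np.mean(segs, axis=0)
    lags_ms = (np.arange(-n_pre, n_post) / rec.sfreq) * 1000.0
    return TriggeredAverage(data=avg, lags_ms=lags_ms,
                            ch_names=rec.ch_names,
                            n_oscillations=len(segs))


def extract_peak_topography(avg: TriggeredAverage,
                            lag_ms: float) -> np.ndarray:
    """Per-electrode amplitude of the triggered average at ``lag_ms``."""
    if lag_ms < avg.lags_ms[0] or lag_ms > avg.lags_ms[-1]:
        raise ValueError(f"lag {lag_ms} ms outside the averaged window")
    i = int(np.argmin(np.abs(avg.lags_ms - lag_ms)))
    return avg.data[:, i].copy()


def normalize_topography(topo: np.ndarray) -> np.ndarray:
    """z-score across electrodes (population SD): mean 0, SD 1.

    Affine-invariant: a*x + b (a > 0) normalizes identically to x.
    """
    x = np.asarray(topo, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 electrodes")
    s = x.std()
    if s == 0:
        raise ValueError("zero spread across electrodes")
    return (x - x.mean()) / s


def topography_table(topos: dict[tuple[int, str], np.ndarray],
                     ch_names: tuple[str, ...]) -> pd.DataFrame:
    """Long-format table (participant, event, electrode, value) from a
    dict keyed by (participant, event label)."""
    rows = []
    for (p, ev), vals in topos.items():
        for ch, v in zip(ch_names, vals):
            rows.append((p, ev, ch, float(v)))
    return pd.DataFrame(rows, columns=["participant", "event", "electrode",
                                       "value"])


def topography_anova(table: pd.DataFrame) -> dict:
    """Two-way repeated-measures ANOVA (Topography x Event) on normalized
    topographies of two events; returns the interaction test.

    table: long format with columns participant, event (2 levels),
    electrode, value; every participant must contribute both events at
    all electrodes.  Partial eta squared is
    SS_interaction / (SS_interaction + SS_error).
    """
    import pingouin as pg

    events = sorted(table["event"].unique())
    electrodes = sorted(table["electrode"].unique())
    counts = table.groupby(["participant", "event", "electrode"]).size()
    n_sub = table["participant"].nunique()
    if len(events) != 2:
        raise ValueError("exactly two event levels are required")
    if (counts != 1).any() or len(counts) != n_sub * 2 * len(electrodes):
        raise ValueError("missing or duplicated cells in the design")
    res = pg.rm_anova(data=table, dv="value",
                      within=["electrode", "event"], subject="participant",
                      detailed=True)
    inter = res[res["Source"] == "electrode * event"].iloc[0]
    ss_inter = float(inter["SS"])
    f = float(inter["F"])
    df1, df2 = int(inter["ddof1"]), int(inter["ddof2"])
    total_ss = float(((table["value"] - table["value"].mean()) ** 2).sum())
    if (not np.isfinite(f)) or abs(ss_inter) <= 1e-12 * max(total_ss, 1.0):
        # identical event topographies: no interaction variance at all
        return {"F": 0.0, "df1": df1, "df2": df2, "p": 1.0,
                "eta_p_squared": 0.0}
    # F = MS_inter / MS_err  =>  SS_err = df2 * SS_inter / (df1 * F)
    ss_err = df2 * ss_inter / (df1 * f) if f > 0 else np.inf
    eta_p = ss_inter / (ss_inter + ss_err) if np.isfinite(ss_err) else 0.0
    return {"F": f, "df1": df1, "df2": df2,
            "p": float(inter["p_unc"]), "eta_p_squared": float(eta_p)}
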