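"""Discrete slow-oscillation detection and up-state timing statistics.

Detection follows the classic scalp-EEG slow-oscillation algorithm:
low-pass at 30 Hz, down-sample to 250 Hz, band-pass 0.15-2 Hz (all
zero-phase so detected peak times remain comparable with ERP latencies),
then take every interval between two consecutive positive-to-negative
zero crossings as a candidate cycle.  A candidate is accepted when

1. its duration lies between 0.9 and 2 s,
2. its negative peak is more negative than 2/3 of the mean negative-peak
   amplitude, and
3. its peak-to-peak amplitude exceeds 2/3 of the mean peak-to-peak
   amplitude,

with both means taken over the duration-passing candidates of the same
recording.  Both criteria are relative, so the accepted set is invariant
to rescaling the trace.

Up-state peaks (positive peaks of accepted cycles) are then counted in
0.2 s bins from 1 s before to 3 s after each word onset; counts and mean
peak amplitudes are z-scored per participant before group averaging.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .core import EEGRecording

TARGET_SFREQ = 250.0
DURATION_BOUNDS = (0.9, 2.0)
BIN_WIDTH_S = 0.2
BIN_WINDOW_S = (-1.0, 3.0)
N_BINS = 20


@dataclass
class SlowOscillation:
    """One candidate or accepted slow-oscillation cycle.

    Times are in seconds from the start of the trace; amplitudes in the
    units of the filtered trace (microvolts).  ``transition_time`` is the
    negative-to-positive zero crossing between the down- and up-state
    peaks (None when the peaks are not in down-then-up order).
    """

    start: float
    end: float
    neg_peak_time: float
    neg_peak_amp: float
    pos_peak_time: float
    pos_peak_amp: float
    transition_time: float | None = None

    @property
    def duration(self) -> float:
        return self.end - self.start

    @property
    def ptp(self) -> float:
        return self.pos_peak_amp - self.neg_peak_amp


@dataclass
class BinSeries:
    """Up-state occurrence per peristimulus time bin.

    ``edges`` has length 21 (20 left-closed bins of 0.2 s covering
    [-1, 3) s around word onset); ``counts`` are total peak counts over
    events; ``mean_amp`` is the mean positive-peak amplitude of the
    contributing peaks, NaN for empty bins.
    """

    edges: np.ndarray
    counts: np.ndarray
    mean_amp: np.ndarray
    n_events: int


def so_filter_chain(trace: np.ndarray, sfreq: float
                    ) -> tuple[np.ndarray, float]:
    """Low-pass 30 Hz, resample to 250 Hz, band-pass 0.15-2 Hz.

    All filters are applied forward-backward (zero phase); the passband
    gain at 1 Hz is within 5% of unity.  Returns (filtered, 250.0).
    """
    if sfreq < TARGET_SFREQ:
        raise ValueError(f"sampling rate {sfreq} Hz is below 250 Hz")
    x = np.asarray(trace, dtype=float)
    sos_lp = signal.butter(4, 30.0, btype="low", fs=sfreq, output="sos")
    x = signal.sosfiltfilt(sos_lp, x)
    if sfreq != TARGET_SFREQ:
        q = sfreq / TARGET_SFREQ
        if abs(q - round(q)) < 1e-9:
            x = x[:: int(round(q))]
        else:
            from fractions import Fraction
            frac = Fraction(int(round(TARGET_SFREQ * 1000)),
                            int(round(sfreq * 1000)))
            x = signal.resample_poly(x, frac.numerator, frac.denominator)
    sos_bp = signal.butter(3, (0.15, 2.0), btype="band", fs=TARGET_SFREQ,
                           output="sos")
    x = signal.sosfiltfilt(sos_bp, x)
    return x, TARGET_SFREQ


def find_candidates(filtered: np.ndarray, sfreq: float = TARGET_SFREQ
                    ) -> list[SlowOscillation]:
    """Candidate cycles between consecutive positive-to-negative zero
    crossings, each with its local minimum and maximum."""
    x = np.asarray(filtered, dtype=float)
    pos = x > 0
    down = np.flatnonzero(pos[:-1] & ~pos[1:])  # x[i] > 0 >= x[i+1]
    if down.size < 2:
        return []
    # sub-sample crossing times by linear interpolation
    xi, xi1 = x[down], x[down + 1]
    frac = np.where(xi != xi1, xi / (xi - xi1), 0.0)
    cross_t = (down + frac) / sfreq
    out: list[SlowOscillation] = []
    for k in range(down.size - 1):
        a, b = down[k] + 1, down[k + 1] + 1
        seg = x[a:b]
        if seg.size == 0:
            continue
        i_min = int(np.argmin(seg))
        i_max = int(np.argmax(seg))
        neg_t, pos_t = (a + i_min) / sfreq, (a + i_max) / sfreq
        trans = None
        if i_min < i_max:
            mid = seg[i_min:i_max + 1]
            ups = np.flatnonzero((mid[:-1] <= 0) & (mid[1:] > 0))
            if ups.size:
                j = a + i_min + ups[-1]
                f = x[j] / (x[j] - x[j + 1]) if x[j] != x[j + 1] else 0.0
                trans = (j + f) / sfreq
        out.append(SlowOscillation(
            start=float(cross_t[k]), end=float(cross_t[k + 1]),
            neg_peak_time=float(neg_t), neg_peak_amp=float(seg[i_min]),
            pos_peak_time=float(pos_t), pos_peak_amp=float(seg[i_max]),
            transition_time=None if trans is None else float(trans)))
    return out


def apply_criteria(candidates: list[SlowOscillation],
                   duration_bounds: tuple[float, float] = DURATION_BOUNDS,
                   ) -> list[SlowOscillation]:
    """Accepted slow oscillations.

    The 2/3 amplitude thresholds are computed once over the
    duration-passing candidate pool of the recording.
    """
    lo, hi = duration_bounds
    pool = [c for c in candidates if lo <= c.duration <= hi]
    if not pool:
        return []
    mean_neg = float(np.mean([c.neg_peak_amp for c in pool]))
    mean_ptp = float(np.mean([c.ptp for c in pool]))
    thr_neg = (2.0 / 3.0) * mean_neg      # a negative number
    thr_ptp = (2.0 / 3.0) * mean_ptp
    return [c for c in pool
            if c.neg_peak_amp < thr_neg and c.ptp > thr_ptp]


def detect_slow_oscillations(rec: EEGRecording, channel: str = "Fz"
                             ) -> list[SlowOscillation]:
    """Full detection chain on one channel (Fz by default)."""
    filt, fs = so_filter_chain(rec.get_channel(channel), rec.sfreq)
    return apply_criteria(find_candidates(filt, fs))


def _peak_times_amps(sos: list[SlowOscillation]
                     ) -> tuple[np.ndarray, np.ndarray]:
    t = np.array([s.pos_peak_time for s in sos])
    a = np.array([s.pos_peak_amp for s in sos])
    return t, a


def bin_up_states(sos: list[SlowOscillation], events: pd.DataFrame,
                  window: tuple[float, float] = BIN_WINDOW_S,
                  bin_width: float = BIN_WIDTH_S) -> BinSeries:
    """Count up-state peaks in peristimulus time bins.

    Bins are left-closed, right-open: a peak exactly on an edge counts in
    the bin to its right.  Counts aggregate over all non-excluded events;
    ``mean_amp`` averages the positive-peak amplitudes per bin (NaN where
    the count is zero).
    """
    lo, hi = window
    n_bins = int(round((hi - lo) / bin_width))
    edges = lo + bin_width * np.arange(n_bins + 1)
    counts = np.zeros(n_bins, dtype=int)
    amp_sum = np.zeros(n_bins)
    usable = events[~events["excluded"].astype(bool)]
    t, a = _peak_times_amps(sos)
    for onset in usable["onset_s"].to_numpy():
        rel = t - onset
        sel = (rel >= lo) & (rel < hi)
        # small epsilon keeps edge peaks in the right (left-closed) bin
        # despite float rounding of the bin arithmetic
        idx = np.floor((rel[sel] - lo) / bin_width + 1e-9).astype(int)
        idx = np.minimum(idx, n_bins - 1)
        np.add.at(counts, idx, 1)
        np.add.at(amp_sum, idx, a[sel])
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_amp = np.where(counts > 0, amp_sum / np.maximum(counts, 1),
                            np.nan)
    return BinSeries(edges=edges, counts=counts, mean_amp=mean_amp,
                     n_events=len(usable))


def z_normalize(values: np.ndarray) -> np.ndarray:
    """z-score across bins (population SD).

    A zero-variance input maps to all zeros rather than dividing by zero;
    NaNs (empty-bin amplitudes) are ignored in the moments and preserved.
    """
    x = np.asarray(values, dtype=float)
    m = np.nanmean(x)
    s = np.nanstd(x)          # population SD (ddof=0)
    if s == 0 or np.isnan(s):
        return np.where(np.isnan(x), np.nan, 0.0)
    return (x - m) / s


def up_state_rate(sos: list[SlowOscillation], events: pd.DataFrame,
                  window_ms: tuple[float, float]) -> float:
    """Up-state peaks per second within a peristimulus window.

    rate = (peaks falling in [w0, w1) across events) /
           (window length in s * number of events)
    """
    usable = events[~events["excluded"].astype(bool)]
    if len(usable) == 0:
        raise ValueError("no usable events")
    w0, w1 = window_ms[0] / 1000.0, window_ms[1] / 1000.0
    if w1 <= w0:
        raise ValueError("empty window")
    t, _ = _peak_times_amps(sos)
    n = 0
    for onset in usable["onset_s"].to_numpy():
        rel = t - onset
        n += int(((rel >= w0) & (rel < w1)).sum())
    return n / ((w1 - w0) * len(usable))


def so_table(sos: list[SlowOscillation]) -> pd.DataFrame:
    """TSV-ready table of detected slow oscillations."""
    return pd.DataFrame([{
        "start_s": s.start, "end_s": s.end, "duration_s": s.duration,
        "neg_peak_time_s": s.neg_peak_time, "neg_peak_amp_uV": s.neg_peak_amp,
        "pos_peak_time_s": s.pos_peak_time, "pos_peak_amp_uV": s.pos_peak_amp,
        "transition_time_s": s.transition_time,
    } for s in sos])
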