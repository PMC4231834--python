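"""Event-related spectral perturbation on a fixed wavelet grid.

Each epoch is decomposed with Gaussian-windowed complex sinusoids
(Morlet-style kernels) whose length grows from 3 cycles at 4 Hz linearly
with frequency to 20.0625 cycles at 53.5 Hz.  Power is evaluated on a
fixed grid of 100 linearly spaced frequencies (4-53.5 Hz) by 200 time
points (-582 to 2582 ms), chosen so that every kernel fits inside the
[-1000, 3000) ms epoch.

Normalization is two-stage and scale-free: raw power at each
time-frequency point is divided by the epoch-wide mean power of its
frequency (single-epoch division over the 200 output times), then the
mean relative power of the pre-stimulus window (-582 to 0 ms) of the
same frequency is subtracted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy import stats

F_MIN, F_MAX, N_FREQS = 4.0, 53.5, 100
T_MIN_MS, T_MAX_MS, N_TIMES = -582.0, 2582.0, 200
CYCLES_MIN, CYCLES_MAX = 3.0, 20.0625

#: Fixed output axes of every grid.
GRID_FREQS = np.linspace(F_MIN, F_MAX, N_FREQS)
GRID_TIMES_MS = np.linspace(T_MIN_MS, T_MAX_MS, N_TIMES)

#: Band definitions (Hz) used for the spectral-power contrasts.  The alpha
#: band is deliberately 4-12 Hz (overlapping theta), mirroring the
#: convention of the analysis this package reproduces; gamma is the
#: half-open interval (24, 50].
BANDS = {
    "theta": (4.0, 8.0),
    "alpha": (4.0, 12.0),
    "sigma": (11.0, 16.0),
    "beta": (12.0, 24.0),
    "gamma": (24.0, 50.0),
}


@dataclass
class TimeFreqGrid:
    """Power on the fixed 100 x 200 grid, per channel.

    values has shape (n_freqs, n_times, n_channels).
    """

    values: np.ndarray
    freqs: np.ndarray
    times_ms: np.ndarray
    ch_names: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.values.shape[:2] != (len(self.freqs), len(self.times_ms)):
            raise ValueError("grid shape does not match axes")


def wavelet_cycles(f: float | np.ndarray) -> float | np.ndarray:
    """Kernel length in cycles at frequency ``f``: linear from 3 cycles at
    4 Hz to 20.0625 cycles at 53.5 Hz."""
    f = np.asarray(f, dtype=float)
    if np.any(f < F_MIN) or np.any(f > F_MAX):
        raise ValueError(f"frequency outside [{F_MIN}, {F_MAX}] Hz")
    c = CYCLES_MIN + (f - F_MIN) * (CYCLES_MAX - CYCLES_MIN) / (F_MAX - F_MIN)
    return float(c) if c.ndim == 0 else c


def _kernel(f: float, sfreq: float) -> np.ndarray:
    """Complex Morlet-style kernel: window length c(f)/f seconds, Gaussian
    taper with sigma = length/6 (so the taper reaches ~3 sigma at the
    window edge), unit L2 norm."""
    length = wavelet_cycles(f) / f
    n = int(round(length * sfreq))
    n += (n + 1) % 2  # odd length, symmetric support
    t = (np.arange(n) - n // 2) / sfreq
    sigma = length / 6.0
    k = np.exp(2j * np.pi * f * t) * np.exp(-0.5 * (t / sigma) ** 2)
    return k / np.linalg.norm(k)


def tf_decompose(epoch: np.ndarray, sfreq: float,
                 epoch_tmin_ms: float = -1000.0,
                 ch_names: tuple[str, ...] | None = None) -> TimeFreqGrid:
    """Raw-power time-frequency decomposition of one epoch.

    epoch: (n_channels, n_samples) covering at least the span needed for
    every kernel centred on the 200 output times.
    """
    epoch = np.atleast_2d(np.asarray(epoch, dtype=float))
    n_ch, n_samp = epoch.shape
    if ch_names is None:
        ch_names = tuple(f"ch{i}" for i in range(n_ch))
    # sample index of each output time
    out_idx = np.round(
        (GRID_TIMES_MS - epoch_tmin_ms) / 1000.0 * sfreq).astype(int)
    half_max = (_kernel(F_MIN, sfreq).size - 1) // 2
    if out_idx[0] - half_max < 0 or out_idx[-1] + half_max >= n_samp:
        raise ValueError(
            "epoch too short for the longest wavelet kernel at the "
            "requested output times")
    power = np.empty((N_FREQS, N_TIMES, n_ch))
    for i, f in enumerate(GRID_FREQS):
        k = _kernel(f, sfreq)
        conv = sps.fftconvolve(epoch, k[None, :], mode="same", axes=1)
        power[i] = np.abs(conv[:, out_idx]).T ** 2
    return TimeFreqGrid(values=power, freqs=GRID_FREQS.copy(),
                        times_ms=GRID_TIMES_MS.copy(),
                        ch_names=tuple(ch_names))


def normalize_power(raw: TimeFreqGrid) -> TimeFreqGrid:
    """Two-stage normalization: divide by the per-frequency epoch-wide mean
    power, then subtract the per-frequency mean relative power of the
    pre-stimulus window (t < 0 ms).

    The output is invariant to scaling the epoch by any positive constant.
    An all-zero frequency row normalizes to zero (logged).
    """
    v = raw.values
    if np.any(v < 0):
        raise ValueError("raw power must be non-negative")
    mean_f = v.mean(axis=1, keepdims=True)           # (f, 1, ch)
    zero_rows = mean_f == 0
    if np.any(zero_rows):
        warnings.warn("all-zero frequency rows normalized to zero",
                      stacklevel=2)
    rel = np.divide(v, mean_f, out=np.zeros_like(v), where=~zero_rows)
    pre = raw.times_ms < 0
    base = rel[:, pre].mean(axis=1, keepdims=True)
    out = np.where(zero_rows, 0.0, rel - base)
    return TimeFreqGrid(values=out, freqs=raw.freqs, times_ms=raw.times_ms,
                        ch_names=raw.ch_names)


def average_ersp(grids: list[TimeFreqGrid]) -> TimeFreqGrid:
    """Element-wise mean of per-epoch grids."""
    if not grids:
        raise ValueError("cannot average zero grids")
    v = np.mean([g.values for g in grids], axis=0)
    g0 = grids[0]
    return TimeFreqGrid(values=v, freqs=g0.freqs, times_ms=g0.times_ms,
                        ch_names=g0.ch_names)


def ersp_for_epochs(data: np.ndarray, sfreq: float,
                    epoch_tmin_ms: float = -1000.0,
                    ch_names: tuple[str, ...] | None = None) -> TimeFreqGrid:
    """Per-participant ERSP: decompose and normalize each epoch, then
    average the baseline-corrected grids.

    data: (n_epochs, n_channels, n_samples).
    """
    grids = [normalize_power(tf_decompose(ep, sfreq, epoch_tmin_ms, ch_names))
             for ep in data]
    return average_ersp(grids)


def band_power_contrast(participant_grids: list[TimeFreqGrid],
                        band: tuple[float, float],
                        half_open_low: bool = False,
                        ) -> tuple[np.ndarray, dict]:
    """Post- minus pre-stimulus mean relative power in a frequency band.

    For each participant the statistic is the mean normalized power over
    band x [0, 2582] ms minus the mean over band x [-582, 0) ms, averaged
    over channels; the group test is a one-sample t across participants
    (df = n - 1).  ``half_open_low`` treats the band as (lo, hi] rather
    than [lo, hi] (used for gamma, ">24-50 Hz").
    """
    lo, hi = band
    if hi <= lo:
        raise ValueError("empty band")
    g0 = participant_grids[0]
    fmask = ((g0.freqs > lo) if half_open_low else (g0.freqs >= lo))
    fmask &= g0.freqs <= hi
    if not fmask.any():
        raise ValueError(f"band ({lo}, {hi}) Hz contains no grid frequency")
    pre = g0.times_ms < 0
    post = g0.times_ms >= 0
    stats_per = np.array([
        g.values[fmask][:, post].mean() - g.values[fmask][:, pre].mean()
        for g in participant_grids])
    n = len(stats_per)
    if n >= 2 and stats_per.std(ddof=1) > 0:
        t, p = stats.ttest_1samp(stats_per, 0.0)
        t, p = float(t), float(p)
    else:
        t, p = 0.0 if np.allclose(stats_per, 0) else np.inf, np.nan
    return stats_per, {"t": t, "df": n - 1, "p": p,
                       "mean": float(stats_per.mean())}
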