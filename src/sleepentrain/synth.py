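"""Synthetic nap-EEG cohorts with word stimulation and priming behaviour.

The generator emulates the statistical structure of an afternoon-nap study
in which spoken nouns are played rhythmically (one word every 4 s) during
NREM sleep while 12-channel scalp EEG plus two mastoids is recorded at
500 Hz.  Each simulated participant produces

* a continuous EEG recording containing 1/f background activity,
  spontaneous slow oscillations (~0.75 Hz, fronto-central maximum),
  and a stereotyped word-evoked response: a down-state around 500 ms
  followed by two up-states around 1000 and 2400 ms with a
  centro-parietal maximum, accompanied by slow- and fast-spindle bursts;
* an event log of word presentations (56 nouns, half played once and half
  six times, 196 scheduled presentations at the defaults);
* behavioural tables for a post-nap word-identification (semantic priming)
  task and a two-alternative forced-choice (perceptual priming) task.

A single cohort-level coupling parameter links each participant's evoked
up-state amplitude to the expected priming scores, which is the ground
truth that the downstream brain-behaviour correlation analysis recovers.

Evoked components are modelled as fixed-latency half-sine lobes rather
than phase resets of the ongoing rhythm: the downstream analyses consume
only event-locked averages and discrete slow-oscillation peaks, for which
the two models are equivalent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    ALL_CHANNELS,
    MASTOID_CHANNELS,
    SCALP_CHANNELS,
    EEGRecording,
    make_event_log,
)


class ConfigurationError(ValueError):
    """Raised when a cohort configuration violates its invariants."""


# Spatial weight maps (relative amplitude per scalp electrode).  Spontaneous
# slow oscillations have the canonical fronto-central maximum at Fz; evoked
# up-states peak centro-parietally (P4 heaviest); the evoked down-state is
# centred around C4.
_SPONT_SO_WEIGHTS = {
    "F3": 0.85, "Fz": 1.00, "F4": 0.85,
    "C3": 0.70, "Cz": 0.80, "C4": 0.70,
    "P3": 0.50, "Pz": 0.55, "P4": 0.50,
    "O1": 0.35, "Oz": 0.40, "O2": 0.35,
}
_UP_WEIGHTS = {
    "F3": 0.60, "Fz": 0.65, "F4": 0.70,
    "C3": 0.70, "Cz": 0.80, "C4": 0.85,
    "P3": 0.80, "Pz": 0.90, "P4": 1.00,
    "O1": 0.50, "Oz": 0.55, "O2": 0.60,
}
_DOWN_WEIGHTS = {
    "F3": 0.80, "Fz": 0.90, "F4": 0.85,
    "C3": 0.85, "Cz": 0.95, "C4": 1.00,
    "P3": 0.60, "Pz": 0.70, "P4": 0.75,
    "O1": 0.40, "Oz": 0.45, "O2": 0.40,
}

# Fixed sub-stream keys so that independent parts of the generator draw
# from independent seeded streams derived from one global seed.
_KEY_SCHEDULE = 104729
_KEY_AMPLITUDE = 7919
_KEY_SIGNAL = 27644437
_KEY_BEHAVIOR = 15485863
_KEY_ARTIFACT = 49979687


@dataclass
class CohortConfig:
    """Parameters of a synthetic cohort.

    Amplitudes are in microvolts, latencies in milliseconds relative to
    word onset, rates in Hz.
    """

    n_participants: int = 16
    sfreq: float = 500.0
    channels: tuple[str, ...] = ALL_CHANNELS
    n_words: int = 56            # half played once, half ``n_repeats`` times
    n_repeats: int = 6
    isi: float = 4.0             # seconds between word onsets
    so_freq: float = 0.75        # spontaneous slow-oscillation frequency
    so_duration_jitter: float = 0.08   # fractional SD of cycle duration
    spont_so_rate: float = 0.55        # spontaneous SO events per second
    spont_so_ptp_mean: float = 150.0   # peak-to-peak amplitude at Fz
    spont_so_ptp_sd: float = 45.0
    evoked_down_latency: float = 500.0
    evoked_up1_latency: float = 1000.0
    evoked_up2_latency: float = 2400.0
    evoked_down_width: float = 350.0   # half-sine lobe widths (ms)
    evoked_up1_width: float = 700.0
    evoked_up2_width: float = 650.0
    evoked_amp_mean: float = 62.0      # across-participant mean up-state lobe
    evoked_amp_sd: float = 18.0        # across-participant SD
    evoked_amp_within_sd: float = 0.35  # fractional trial-to-trial SD
    entrain_prob: float = 0.32  # probability a trial entrains (produces the
                                # full evoked slow-oscillation sequence)
    evoked_down_gain: float = 0.5      # down lobe relative to up lobes
    # weak intermediate down-state between the two up-states (the trough of
    # the entrained ~0.7 Hz sequence); 0 disables it
    evoked_down2_latency: float = 1750.0
    evoked_down2_gain: float = 0.45
    evoked_down2_width: float = 400.0
    slow_spindle_freq: float = 11.0    # Hz, coupled to the down-state
    fast_spindle_freq: float = 15.0    # Hz, coupled to up-state 1
    spindle_duration: float = 0.8      # s, within the 0.5-3 s spindle range
    spindle_amp: float = 5.0
    noise_exponent: float = 1.0        # 1/f^a slope of the background
    noise_sd: float = 20.0             # background SD per scalp channel
    coupling_beta: float = 1.5         # dB(A) of semantic priming per SD of
                                       # evoked amplitude; perceptual priming
                                       # uses the same slope scaled to ms
    perceptual_scale: float = 150.0    # ms of perceptual priming per dB
    noise_sd_behavior: float = 0.5     # participant-level score noise (dB)
    n_afc_trials: int = 28
    start_volume_dBA: float = 38.7     # identification staircase start
    volume_step_dBA: float = 2.5
    mean_identification_volume: float = 54.0
    presentation_volume_dBA: float = 53.2
    lead_in: float = 20.0              # s of recording before the first word
    tail: float = 5.0                  # s after the last word
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_words % 2 != 0:
            raise ConfigurationError("n_words must be even")
        if self.n_words < 2:
            raise ConfigurationError("n_words must be at least 2")
        if self.isi <= 3.0:
            raise ConfigurationError(
                "isi must exceed the 3 s post-onset epoch tail")
        lat = (self.evoked_down_latency, self.evoked_up1_latency,
               self.evoked_up2_latency)
        if not (lat[0] < lat[1] < lat[2]):
            raise ConfigurationError(
                "evoked latencies must be strictly increasing")
        if self.sfreq <= 2 * self.fast_spindle_freq:
            raise ConfigurationError(
                "sfreq must exceed twice the fast spindle frequency")
        if self.spont_so_rate * (1.0 / self.so_freq) >= 1.0:
            raise ConfigurationError(
                "spont_so_rate too high for the configured cycle duration")
        for name in ("evoked_amp_sd", "noise_sd", "noise_sd_behavior",
                     "spont_so_rate"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        self.channels = tuple(self.channels)

    @property
    def n_presentations(self) -> int:
        return self.n_words // 2 * (1 + self.n_repeats)

    @property
    def recording_duration(self) -> float:
        return self.lead_in + self.n_presentations * self.isi + self.tail


@dataclass
class BehaviorTable:
    """Post-nap behavioural data of one participant.

    identification: one row per word of the identification task
        (columns word, condition in {synonym, new}, repetition_condition,
        volume_dBA, identified).  Volumes are continuous dB(A) values on
        the staircase scale, never below the starting volume.
    afc: one row per 2AFC trial (trial, repetition_condition, rt_ms,
        correct).
    """

    participant: int
    identification: pd.DataFrame
    afc: pd.DataFrame


@dataclass
class ParticipantData:
    """One simulated participant: recording, events, behaviour, plus the
    ground-truth evoked up-state amplitude used by the coupling model."""

    recording: EEGRecording
    events: pd.DataFrame
    behavior: BehaviorTable
    evoked_amp: float


def _rng(cfg: CohortConfig, key: int, *extra: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, key, *extra])


def participant_evoked_amplitude(cfg: CohortConfig, participant: int) -> float:
    """Ground-truth evoked up-state lobe amplitude of one participant."""
    r = _rng(cfg, _KEY_AMPLITUDE, participant)
    return float(max(1.0, r.normal(cfg.evoked_amp_mean, cfg.evoked_amp_sd)))


def presentation_schedule(cfg: CohortConfig) -> pd.DataFrame:
    """Word presentation schedule shared by all participants.

    Half of the words appear once, half ``n_repeats`` times; presentations
    are intermixed with no immediate repetition of the same word, spaced
    exactly ``isi`` seconds apart starting after ``lead_in`` seconds.
    """
    r = _rng(cfg, _KEY_SCHEDULE)
    n_once = cfg.n_words // 2
    tokens = list(range(n_once)) + [
        w for w in range(n_once, cfg.n_words) for _ in range(cfg.n_repeats)
    ]
    tokens = np.array(tokens)
    for _ in range(1000):
        r.shuffle(tokens)
        bad = np.flatnonzero(tokens[1:] == tokens[:-1])
        if bad.size == 0:
            break
        # swap each offending token with a random other position
        for i in bad + 1:
            j = int(r.integers(len(tokens)))
            tokens[i], tokens[j] = tokens[j], tokens[i]
    else:  # pragma: no cover - astronomically unlikely at the defaults
        raise RuntimeError("could not build a repetition-free schedule")
    reps = np.zeros(len(tokens), dtype=int)
    seen: dict[int, int] = {}
    for i, w in enumerate(tokens):
        reps[i] = seen.get(int(w), 0)
        seen[int(w)] = reps[i] + 1
    onsets = cfg.lead_in + cfg.isi * np.arange(len(tokens))
    return pd.DataFrame({"onset_s": onsets, "word_id": tokens,
                         "repetition_index": reps})


def one_over_f_noise(n_samples: int, sfreq: float, exponent: float,
                     sd: float, rng: np.random.Generator,
                     n_channels: int = 1) -> np.ndarray:
    """Gaussian noise with a 1/f^exponent power spectrum, unit variance
    scaled to ``sd``, shape (n_channels, n_samples)."""
    white = rng.standard_normal((n_channels, n_samples))
    if sd == 0:
        return np.zeros((n_channels, n_samples))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / sfreq)
    shaping = np.ones_like(freqs)
    nz = freqs > 0
    shaping[nz] = freqs[nz] ** (-exponent / 2.0)
    shaping[0] = 0.0  # no DC
    out = np.fft.irfft(spec * shaping, n=n_samples, axis=1)
    out *= sd / out.std(axis=1, keepdims=True)
    return out


def _half_sine(n: int) -> np.ndarray:
    return np.sin(np.pi * (np.arange(n) + 0.5) / n)


def _add_lobe(sig: np.ndarray, sfreq: float, center_s: float, width_s: float,
              amp: float, weights: np.ndarray) -> None:
    """Add a half-sine lobe (peak ``amp``) spatially scaled by ``weights``."""
    n = max(2, int(round(width_s * sfreq)))
    i0 = int(round((center_s - width_s / 2.0) * sfreq))
    lobe = amp * _half_sine(n)
    a, b = max(i0, 0), min(i0 + n, sig.shape[1])
    if a >= b:
        return
    sig[:, a:b] += weights[:, None] * lobe[a - i0: b - i0]


def _add_spindle(sig: np.ndarray, sfreq: float, center_s: float,
                 duration_s: float, freq: float, amp: float,
                 weights: np.ndarray, phase: float) -> None:
    n = max(2, int(round(duration_s * sfreq)))
    i0 = int(round((center_s - duration_s / 2.0) * sfreq))
    t = np.arange(n) / sfreq
    burst = amp * np.hanning(n) * np.sin(2 * np.pi * freq * t + phase)
    a, b = max(i0, 0), min(i0 + n, sig.shape[1])
    if a >= b:
        return
    sig[:, a:b] += weights[:, None] * burst[a - i0: b - i0]


def _spontaneous_so_times(cfg: CohortConfig, duration: float,
                          rng: np.random.Generator) -> np.ndarray:
    """Start times of spontaneous SO cycles (renewal process: one cycle
    plus an exponential gap, targeting ``spont_so_rate`` events/s)."""
    if cfg.spont_so_rate <= 0:
        return np.empty(0)
    cycle = 1.0 / cfg.so_freq
    extra_mean = 1.0 / cfg.spont_so_rate - cycle
    times = []
    t = rng.uniform(0, cycle + extra_mean)
    while t < duration - cycle:
        times.append(t)
        t += cycle + rng.exponential(extra_mean) if extra_mean > 0 else cycle
    return np.asarray(times)


def generate_recording(cfg: CohortConfig, participant: int
                       ) -> tuple[EEGRecording, pd.DataFrame]:
    """Generate one participant's recording and event log.

    Deterministic for fixed (config seed, participant index): the same call
    returns bit-identical data.
    """
    if not isinstance(cfg, CohortConfig):
        raise ConfigurationError("cfg must be a CohortConfig")
    sched = presentation_schedule(cfg)
    sfreq = cfg.sfreq
    n_samples = int(round(cfg.recording_duration * sfreq))
    ch = cfg.channels
    scalp_idx = [i for i, c in enumerate(ch) if c in SCALP_CHANNELS]
    scalp_names = [ch[i] for i in scalp_idx]

    r = _rng(cfg, _KEY_SIGNAL, participant)
    data = np.zeros((len(ch), n_samples))

    # background 1/f activity; mastoids carry attenuated background only
    if cfg.noise_sd > 0:
        bg = one_over_f_noise(n_samples, sfreq, cfg.noise_exponent,
                              cfg.noise_sd, r, n_channels=len(ch))
        for i, c in enumerate(ch):
            data[i] += bg[i] * (0.4 if c in MASTOID_CHANNELS else 1.0)
    else:
        r.standard_normal((len(ch), 2))  # keep stream alignment

    scalp = data[scalp_idx]
    w_spont = np.array([_SPONT_SO_WEIGHTS[c] for c in scalp_names])
    w_up = np.array([_UP_WEIGHTS[c] for c in scalp_names])
    w_down = np.array([_DOWN_WEIGHTS[c] for c in scalp_names])

    # spontaneous slow oscillations: one negative then one positive half-wave
    for t0 in _spontaneous_so_times(cfg, cfg.recording_duration, r):
        dur = (1.0 / cfg.so_freq) * max(
            0.5, r.normal(1.0, cfg.so_duration_jitter))
        ptp = max(10.0, r.normal(cfg.spont_so_ptp_mean, cfg.spont_so_ptp_sd))
        half = dur / 2.0
        _add_lobe(scalp, sfreq, t0 + half / 2.0, half, -ptp / 2.0, w_spont)
        _add_lobe(scalp, sfreq, t0 + 1.5 * half, half, ptp / 2.0, w_spont)

    # word-evoked responses
    amp_p = participant_evoked_amplitude(cfg, participant)
    volume = float(np.clip(r.normal(cfg.presentation_volume_dBA - 0.7, 1.0),
                           47.2, 53.2))
    onsets = sched["onset_s"].to_numpy()
    for onset in onsets:
        entrained = r.random() < cfg.entrain_prob
        gain = max(0.0, r.normal(1.0, cfg.evoked_amp_within_sd))
        if not entrained:
            continue
        a = amp_p * gain
        _add_lobe(scalp, sfreq, onset + cfg.evoked_down_latency / 1000.0,
                  cfg.evoked_down_width / 1000.0, -a * cfg.evoked_down_gain,
                  w_down)
        _add_lobe(scalp, sfreq, onset + cfg.evoked_up1_latency / 1000.0,
                  cfg.evoked_up1_width / 1000.0, a, w_up)
        _add_lobe(scalp, sfreq, onset + cfg.evoked_up2_latency / 1000.0,
                  cfg.evoked_up2_width / 1000.0, a, w_up)
        if cfg.evoked_down2_gain > 0:
            _add_lobe(scalp, sfreq,
                      onset + cfg.evoked_down2_latency / 1000.0,
                      cfg.evoked_down2_width / 1000.0,
                      -a * cfg.evoked_down2_gain, w_down)
        if cfg.spindle_amp > 0:
            _add_spindle(scalp, sfreq,
                         onset + cfg.evoked_down_latency / 1000.0,
                         cfg.spindle_duration, cfg.slow_spindle_freq,
                         cfg.spindle_amp * gain, w_spont,
                         r.uniform(0, 2 * np.pi))
            _add_spindle(scalp, sfreq,
                         onset + cfg.evoked_up1_latency / 1000.0,
                         cfg.spindle_duration, cfg.fast_spindle_freq,
                         cfg.spindle_amp * gain, w_up,
                         r.uniform(0, 2 * np.pi))

    data[scalp_idx] = scalp
    rec = EEGRecording(data=data, sfreq=sfreq, ch_names=ch,
                       participant=participant)
    events = make_event_log(sched["onset_s"], sched["word_id"],
                            sched["repetition_index"],
                            np.full(len(sched), volume))
    return rec, events


def generate_behavior(cfg: CohortConfig, participant: int,
                      evoked_amp: float | None = None) -> BehaviorTable:
    """Behavioural tables whose per-participant means encode the coupling.

    The expected semantic priming score (dB) is
    ``coupling_beta * z`` where ``z`` standardises the participant's evoked
    amplitude by the configured across-participant mean and SD; the expected
    perceptual priming score is the same quantity scaled to milliseconds by
    ``perceptual_scale``.  ``noise_sd_behavior`` sets both the
    participant-level score noise and (scaled) the word/trial-level noise,
    so a noise-free configuration encodes the coupling exactly.
    """
    if evoked_amp is None:
        evoked_amp = participant_evoked_amplitude(cfg, participant)
    r = _rng(cfg, _KEY_BEHAVIOR, participant)
    sd_amp = cfg.evoked_amp_sd if cfg.evoked_amp_sd > 0 else 1.0
    z = (evoked_amp - cfg.evoked_amp_mean) / sd_amp
    sem_score = cfg.coupling_beta * z + r.normal(0, cfg.noise_sd_behavior)
    perc_score = cfg.perceptual_scale * (
        cfg.coupling_beta * z + r.normal(0, cfg.noise_sd_behavior))

    word_sd = 4.0 * cfg.noise_sd_behavior        # dB per identified word
    rt_sd = 400.0 * cfg.noise_sd_behavior        # ms per 2AFC trial

    n_half = cfg.n_words // 2
    n_syn = n_half // 2 if n_half >= 2 else 1
    mu_new = cfg.mean_identification_volume
    rows = []
    wid = 0
    for cond, rep_cond, n, mu in (
        ("synonym", "once", n_syn, mu_new - sem_score),
        ("synonym", "sixfold", n_half - n_syn, mu_new - sem_score),
        ("new", "control", n_half, mu_new),
    ):
        vols = mu + r.normal(0, word_sd, n)
        vols = np.maximum(vols, cfg.start_volume_dBA)
        for v in vols:
            rows.append((wid, cond, rep_cond, float(v), True))
            wid += 1
    ident = pd.DataFrame(rows, columns=[
        "word", "condition", "repetition_condition", "volume_dBA",
        "identified"])

    n_trials = cfg.n_afc_trials
    correct = r.random(n_trials) < 0.5   # forced guessing: chance accuracy
    rts = np.where(correct,
                   r.normal(2750.0, rt_sd if rt_sd > 0 else 0, n_trials),
                   r.normal(2750.0 + perc_score,
                            rt_sd if rt_sd > 0 else 0, n_trials))
    rts = np.maximum(rts, 300.0)
    afc = pd.DataFrame({
        "trial": np.arange(n_trials),
        "repetition_condition": np.where(
            np.arange(n_trials) % 2 == 0, "once", "sixfold"),
        "rt_ms": rts,
        "correct": correct,
    })
    return BehaviorTable(participant=participant, identification=ident,
                         afc=afc)


def generate_cohort(cfg: CohortConfig) -> list[ParticipantData]:
    """Generate the full cohort (recordings, events, behaviour)."""
    if cfg.n_participants < 2:
        raise ConfigurationError("n_participants must be at least 2")
    out = []
    for p in range(cfg.n_participants):
        rec, events = generate_recording(cfg, p)
        amp = participant_evoked_amplitude(cfg, p)
        beh = generate_behavior(cfg, p, amp)
        out.append(ParticipantData(recording=rec, events=events,
                                   behavior=beh, evoked_amp=amp))
    return out


def inject_artifacts(rec: EEGRecording, rate_per_min: float,
                     seed: int) -> EEGRecording:
    """Mark Poisson-distributed artifact intervals and overwrite the signal
    inside them with high-amplitude noise.

    Interval count over the recording is Poisson with mean
    ``rate_per_min * duration_min``; interval lengths are uniform on 1-3 s.
    ``rate_per_min = 0`` returns a copy with no intervals.
    """
    if rate_per_min < 0:
        raise ValueError("artifact rate must be non-negative")
    out = rec.copy()
    if rate_per_min == 0:
        return out
    r = np.random.default_rng([seed, _KEY_ARTIFACT])
    duration = rec.duration
    n = r.poisson(rate_per_min * duration / 60.0)
    starts = np.sort(r.uniform(0, duration, n))
    lengths = r.uniform(1.0, 3.0, n)
    intervals: list[tuple[float, float]] = []
    for s, ln in zip(starts, lengths):
        e = min(s + ln, duration)
        if intervals and s <= intervals[-1][1]:
            intervals[-1] = (intervals[-1][0], max(intervals[-1][1], e))
        else:
            intervals.append((float(s), float(e)))
    for s, e in intervals:
        i0, i1 = int(s * rec.sfreq), int(e * rec.sfreq)
        out.data[:, i0:i1] = r.normal(0, 300.0, (rec.data.shape[0], i1 - i0))
    out.artifacts = sorted(set(out.artifacts) | set(intervals))
    return out
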