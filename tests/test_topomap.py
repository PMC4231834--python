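"""SO-triggered averages, topography normalization, rm-ANOVA contrast."""

import numpy as np
import pandas as pd
import pytest

from sleepentrain.core import EEGRecording, SCALP_CHANNELS
from sleepentrain.so_detect import SlowOscillation, detect_slow_oscillations
from sleepentrain.synth import CohortConfig, generate_recording
from sleepentrain.preprocess import rereference_pooled_mastoids
from sleepentrain.topomap import (
    DOWN_PEAK_LAG_MS,
    UP_PEAK_LAG_MS,
    extract_peak_topography,
    normalize_topography,
    so_triggered_average,
    topography_anova,
    topography_table,
)

FS = 250.0


def _so_recording(n_cycles=12, amp=1.0, weights=(1.0, 0.5)):
    """Repeated identical SO cycles (neg then pos half-wave) on two
    channels with fixed spatial weights, plus the matching SO list."""
    f = 0.8
    n_cycle = int(FS / f)
    cycle = -amp * np.sin(2 * np.pi * f * np.arange(n_cycle) / FS)
    gap = np.zeros(n_cycle)
    trace = np.concatenate([np.concatenate([cycle, gap])
                            for _ in range(n_cycles)])
    data = np.vstack([w * trace for w in weights])
    rec = EEGRecording(data, FS, ("Fz", "Pz"))
    sos = []
    for k in range(n_cycles):
        t0 = k * 2 * n_cycle / FS
        sos.append(SlowOscillation(
            start=t0, end=t0 + 1.25,
            neg_peak_time=t0 + 0.3125, neg_peak_amp=-amp,
            pos_peak_time=t0 + 0.9375, pos_peak_amp=amp,
            transition_time=t0 + 0.625))
    return rec, sos


class TestTriggeredAverage:
    def test_identical_cycles_average_to_one_cycle(self):
        rec, sos = _so_recording()
        avg = so_triggered_average(rec, sos, window_s=(-0.5, 0.5))
        i = np.argmin(np.abs(avg.lags_ms - (-312.5)))
        assert avg.data[0, i] == pytest.approx(-1.0, abs=0.01)
        j = np.argmin(np.abs(avg.lags_ms - 312.5))
        assert avg.data[0, j] == pytest.approx(1.0, abs=0.01)

    def test_average_crosses_zero_at_lag_zero(self):
        rec, sos = _so_recording()
        avg = so_triggered_average(rec, sos)
        i0 = np.argmin(np.abs(avg.lags_ms))
        assert abs(avg.data[0, i0]) < 0.05

    def test_no_oscillations_rejected(self):
        rec, _ = _so_recording()
        with pytest.raises(ValueError):
            so_triggered_average(rec, [])

    def test_spontaneous_up_state_topography_peaks_at_fz(self):
        cfg = CohortConfig(n_words=6, n_repeats=4, seed=21, entrain_prob=0.0,
                           spindle_amp=0.0, noise_sd=5.0)
        rec, _ = generate_recording(cfg, 0)
        reref = rereference_pooled_mastoids(rec)
        sos = detect_slow_oscillations(reref)
        avg = so_triggered_average(reref, sos)
        up = extract_peak_topography(avg, UP_PEAK_LAG_MS)
        down = extract_peak_topography(avg, DOWN_PEAK_LAG_MS)
        topo = dict(zip(reref.ch_names, up))
        assert max(topo, key=topo.get) == "Fz"
        assert np.mean(down) < 0 < np.mean(up)


class TestPeakTopography:
    def test_constant_map_constant_topography(self):
        rec, sos = _so_recording(weights=(1.0, 1.0))
        avg = so_triggered_average(rec, sos)
        t = extract_peak_topography(avg, UP_PEAK_LAG_MS)
        assert t[0] == pytest.approx(t[1])

    def test_spatial_weights_recovered_up_to_scale(self):
        rec, sos = _so_recording(weights=(1.0, 0.5))
        avg = so_triggered_average(rec, sos)
        t = extract_peak_topography(avg, UP_PEAK_LAG_MS)
        assert t[1] / t[0] == pytest.approx(0.5, abs=1e-6)

    def test_lag_outside_window_rejected(self):
        rec, sos = _so_recording()
        avg = so_triggered_average(rec, sos)
        with pytest.raises(ValueError):
            extract_peak_topography(avg, 900.0)


class TestNormalize:
    def test_mean_zero_sd_one(self, rng):
        z = normalize_topography(rng.normal(size=12))
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std() == pytest.approx(1.0, abs=1e-12)

    def test_affine_invariance(self, rng):
        x = rng.normal(size=12)
        assert np.allclose(normalize_topography(x),
                           normalize_topography(5.0 * x + 2.0))

    def test_three_electrode_hand_oracle(self):
        z = normalize_topography(np.array([1.0, 2.0, 3.0]))
        assert np.allclose(z, [-1.224745, 0.0, 1.224745], atol=1e-5)

    def test_zero_spread_rejected(self):
        with pytest.raises(ValueError):
            normalize_topography(np.ones(12))


def _rm_anova_oracle(y):
    """Textbook two-way repeated-measures decomposition for the
    interaction term; y has shape (subjects, a_levels, b_levels)."""
    n, a, b = y.shape
    gm = y.mean()
    ss_a_b = 0.0
    cell = y.mean(axis=0)
    ma, mb = y.mean(axis=(0, 2)), y.mean(axis=(0, 1))
    ss_inter = n * np.sum((cell - ma[:, None] - mb[None, :] + gm) ** 2)
    # interaction error: SS of (subject x a x b) residual
    ms = y.mean(axis=2)          # subject x a
    mbs = y.mean(axis=1)         # subject x b
    msub = y.mean(axis=(1, 2))   # subject
    resid = (y - cell[None] - ms[:, :, None] - mbs[:, None, :]
             + ma[None, :, None] + mb[None, None, :] + msub[:, None, None]
             - gm)
    ss_err = np.sum(resid ** 2)
    df1 = (a - 1) * (b - 1)
    df2 = (n - 1) * df1
    f = (ss_inter / df1) / (ss_err / df2)
    eta_p = ss_inter / (ss_inter + ss_err)
    return f, df1, df2, eta_p


def _table(y, participants=None):
    n, a, b = y.shape
    rows = []
    for s in range(n):
        for i in range(a):
            for j in range(b):
                rows.append((s, f"e{i}", f"ev{j}", y[s, i, j]))
    return pd.DataFrame(rows, columns=["participant", "electrode",
                                       "event", "value"])


class TestAnova:
    def test_matches_hand_sums_of_squares_oracle(self, rng):
        y = rng.normal(size=(3, 2, 2))
        res = topography_anova(_table(y))
        f, df1, df2, eta = _rm_anova_oracle(y)
        assert res["F"] == pytest.approx(f)
        assert (res["df1"], res["df2"]) == (df1, df2)
        assert res["eta_p_squared"] == pytest.approx(eta)

    def test_identical_topographies_give_zero_f(self, rng):
        base = rng.normal(size=(4, 3))
        y = np.stack([np.stack([base[s], base[s]], axis=1)
                      for s in range(4)])
        res = topography_anova(_table(y))
        assert res["F"] == 0.0
        assert res["eta_p_squared"] == 0.0

    def test_event_label_swap_leaves_interaction_unchanged(self, rng):
        y = rng.normal(size=(5, 4, 2))
        res1 = topography_anova(_table(y))
        res2 = topography_anova(_table(y[:, :, ::-1]))
        assert res1["F"] == pytest.approx(res2["F"])
        assert res1["eta_p_squared"] == pytest.approx(res2["eta_p_squared"])

    def test_missing_cell_rejected(self, rng):
        tab = _table(rng.normal(size=(3, 2, 2))).iloc[:-1]
        with pytest.raises(ValueError):
            topography_anova(tab)

    def test_distinct_spatial_patterns_detected_at_n16(self, rng):
        # Fz-weighted spontaneous vs P4-weighted entrained up-states
        w_spont = np.linspace(1.0, 0.3, 12)
        w_entr = np.linspace(0.3, 1.0, 12)
        rows = []
        for s in range(16):
            for w, ev in ((w_spont, "spont"), (w_entr, "entrained")):
                vals = w * rng.normal(1.0, 0.2) + rng.normal(0, 0.15, 12)
                z = normalize_topography(vals)
                for ch, v in zip(SCALP_CHANNELS, z):
                    rows.append((s, ch, ev, v))
        tab = pd.DataFrame(rows, columns=["participant", "electrode",
                                          "event", "value"])
        res = topography_anova(tab)
        assert res["p"] < 0.01
        assert 0.0 <= res["eta_p_squared"] <= 1.0


class TestTable:
    def test_long_format_round_trip(self):
        topos = {(0, "up"): np.array([1.0, 2.0]),
                 (1, "up"): np.array([3.0, 4.0])}
        tab = topography_table(topos, ("Fz", "Pz"))
        assert len(tab) == 4
        assert set(tab.columns) == {"participant", "event", "electrode",
                                    "value"}
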