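"""End-to-end orchestration: simulate -> preprocess -> detect -> ERP/ERSP
-> cluster statistics -> response magnitudes -> behaviour -> correlations.

The pipeline mirrors the analysis of a word-stimulation nap study on a
synthetic cohort and writes a reproducible output directory: cluster
report tables, peristimulus up-state bin series, topography tables and
ANOVA results, priming scores and the brain-behaviour correlation table,
plus a manifest with the configuration snapshot, seed, and output
hashes.  Re-running with an identical configuration and seed reproduces
identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, ValidationError

from . import behavior as beh
from . import cluster_stats as cs
from . import ersp as ersp_mod
from . import preprocess as pp
from . import so_detect as so
from . import topomap as topo
from .core import channel_adjacency
from .io import load_config_yaml, save_config_yaml
from .synth import (
    CohortConfig,
    ConfigurationError,
    generate_behavior,
    generate_recording,
    inject_artifacts,
    participant_evoked_amplitude,
)

log = logging.getLogger("sleepentrain")


class ErspSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    enabled: bool = True
    channels: list[str] = ["Fz"]
    max_epochs: int = 30
    cluster_test: bool = True


class AnalysisSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    artifact_rate_per_min: float = 0.3
    n_permutations: int = 1000
    alpha: float = 0.05
    so_channel: str = "Fz"
    ersp: ErspSettings = ErspSettings()


class OutputSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    save_recordings: bool = False
    plots: bool = False


class PipelineConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    cohort: dict = {}
    analysis: AnalysisSettings = AnalysisSettings()
    output: OutputSettings = OutputSettings()

    def cohort_config(self, seed: int | None = None) -> CohortConfig:
        kw = dict(self.cohort)
        if seed is not None:
            kw["seed"] = seed
        valid = {f.name for f in dataclasses.fields(CohortConfig)}
        unknown = set(kw) - valid
        if unknown:
            raise ConfigurationError(
                f"unknown cohort parameter(s): {sorted(unknown)}")
        return CohortConfig(**kw)


def validate_config(path: str | Path) -> tuple[PipelineConfig | None,
                                               list[str]]:
    """Schema-check a YAML config; returns (config, errors).

    Unknown keys are rejected; defaults are filled in and echoed in the
    returned config.
    """
    try:
        raw = load_config_yaml(path)
    except Exception as err:
        return None, [f"cannot read config: {err}"]
    errors: list[str] = []
    try:
        cfg = PipelineConfig(**(raw or {}))
    except (ValidationError, TypeError) as err:
        if isinstance(err, ValidationError):
            for e in err.errors():
                loc = ".".join(str(x) for x in e["loc"])
                errors.append(f"{loc}: {e['msg']}")
        else:
            errors.append(str(err))
        return None, errors
    try:
        cfg.cohort_config()
    except (ConfigurationError, TypeError) as err:
        errors.append(f"cohort: {err}")
        return None, errors
    return cfg, []


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _classify_erp_clusters(summaries: list[dict], cfg: CohortConfig
                           ) -> dict[str, int]:
    """Map significant ERP clusters to down-state / up-state 1 / 2 by sign
    and peak-time proximity to the configured latencies."""
    targets = {
        "down_state": (-1, cfg.evoked_down_latency),
        "up_state_1": (1, cfg.evoked_up1_latency),
        "up_state_2": (1, cfg.evoked_up2_latency),
    }
    out: dict[str, int] = {}
    for label, (sign, lat) in targets.items():
        best, best_d = None, np.inf
        for i, s in enumerate(summaries):
            if not s["significant"]:
                continue
            if (s["sign"] == "positive") != (sign > 0):
                continue
            d = abs(s["peak_time_ms"] - lat)
            if d < best_d and d < 700.0 and i not in out.values():
                best, best_d = i, d
        if best is not None:
            out[label] = best
    return out


def run_pipeline(config: PipelineConfig, out_dir: str | Path,
                 seed: int | None = None) -> dict:
    """Run the full analysis; returns the manifest dict.

    ``seed`` overrides the cohort seed from the config.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    warnings_log: list[str] = []
    cfg = config.cohort_config(seed)
    ana = config.analysis
    adjacency = None  # set after re-referencing, from actual channel order

    log.info("stage simulate+preprocess: %d participants", cfg.n_participants)
    erps: list[np.ndarray] = []       # (n_times, n_ch) per participant
    erp_times = erp_chs = None
    all_sos: list[list[so.SlowOscillation]] = []
    all_events: list[pd.DataFrame] = []
    bin_counts_z, bin_amps_z = [], []
    spont_topos: list[dict[str, np.ndarray]] = []
    scores_rows = []
    volumes = []
    ersp_grids: list[ersp_mod.TimeFreqGrid] = []

    for p in range(cfg.n_participants):
        rec, events = generate_recording(cfg, p)
        if ana.artifact_rate_per_min > 0:
            rec = inject_artifacts(rec, ana.artifact_rate_per_min,
                                   seed=cfg.seed * 1009 + p)
        events = pp.apply_exclusion_rules(events, rec.artifacts)
        n_excl = int(events["excluded"].sum())
        if n_excl:
            warnings_log.append(
                f"participant {p}: {n_excl} events excluded")
        reref = pp.rereference_pooled_mastoids(rec)
        ep = pp.baseline_correct(pp.epoch(reref, events))
        if ep.n_epochs == 0:
            warnings_log.append(f"participant {p}: no usable epochs")
            continue
        erp = pp.average_erp(ep)                   # (n_ch, n_t)
        erps.append(erp.T)
        erp_times, erp_chs = ep.times_ms, ep.ch_names

        sos = so.detect_slow_oscillations(reref, ana.so_channel)
        all_sos.append(sos)
        all_events.append(events)
        bins = so.bin_up_states(sos, events)
        bin_counts_z.append(so.z_normalize(bins.counts.astype(float)))
        bin_amps_z.append(so.z_normalize(bins.mean_amp))

        try:
            avg = topo.so_triggered_average(reref, sos)
            spont_topos.append({
                "spontaneous_down": topo.extract_peak_topography(
                    avg, topo.DOWN_PEAK_LAG_MS),
                "spontaneous_up": topo.extract_peak_topography(
                    avg, topo.UP_PEAK_LAG_MS),
            })
        except ValueError as err:
            spont_topos.append({})
            warnings_log.append(f"participant {p}: {err}")

        amp = participant_evoked_amplitude(cfg, p)
        b = generate_behavior(cfg, p, amp)
        s = beh.scores_from_table(b)
        scores_rows.append({
            "participant": p, "semantic_dB": s.semantic_dB,
            "perceptual_ms": s.perceptual_ms,
            "accuracy_pct": s.accuracy_pct,
            "true_evoked_amp": amp,
        })
        volumes.append(float(events["volume_dBA"].iloc[0]))

        if ana.ersp.enabled:
            ch_idx = [ep.ch_names.index(c) for c in ana.ersp.channels]
            sub = ep.data[: ana.ersp.max_epochs][:, ch_idx]
            ersp_grids.append(ersp_mod.ersp_for_epochs(
                sub, ep.sfreq, float(ep.times_ms[0]),
                tuple(ana.ersp.channels)))

    n = len(erps)
    if n < 2:
        raise RuntimeError("fewer than 2 participants with usable data")
    scores = pd.DataFrame(scores_rows)

    # --- group ERP cluster statistics -------------------------------------
    log.info("stage cluster_stats: %d permutations", ana.n_permutations)
    group = np.stack(erps)                       # (n, n_t, n_ch)
    adjacency = channel_adjacency(erp_chs)
    rng = np.random.default_rng(cfg.seed + 20211)
    clusters, null = cs.run_cluster_test(
        group, n_perm=ana.n_permutations, alpha=ana.alpha,
        ch_adjacency=adjacency, rng=rng)
    t_map = cs.pointwise_t(group)
    summaries = [cs.summarize_cluster(c, erp_times, erp_chs, t_map)
                 for c in clusters]
    pd.DataFrame(summaries).to_csv(out / "erp_clusters.tsv", sep="\t",
                                   index=False)
    labels = _classify_erp_clusters(summaries, cfg)
    if len(labels) < 3:
        warnings_log.append(
            f"only {sorted(labels)} ERP responses identified")

    # --- per-participant response magnitudes ------------------------------
    magnitudes: dict[str, np.ndarray] = {}
    for label, ci in labels.items():
        magnitudes[label] = np.array([
            cs.cluster_mean_amplitude(erps[i], clusters[ci])
            for i in range(n)])
        scores[f"magnitude_{label}_uV"] = magnitudes[label]
    scores.to_csv(out / "priming_scores.tsv", sep="\t", index=False)

    # --- up-state rates in the identified response windows ----------------
    rate_rows = []
    rates: dict[str, np.ndarray] = {}
    for label, ci in labels.items():
        s = summaries[ci]
        win = (s["start_ms"], s["end_ms"])
        rates[label] = np.array([
            so.up_state_rate(all_sos[i], all_events[i], win)
            for i in range(n)])
        rate_rows.append({
            "response": label, "window_start_ms": win[0],
            "window_end_ms": win[1],
            "mean_rate_per_s": float(rates[label].mean()),
            "sem_rate_per_s": float(rates[label].std(ddof=1) / np.sqrt(n)),
        })
    rate_tests = {}
    if "down_state" in rates:
        for label in ("up_state_1", "up_state_2"):
            if label in rates:
                res = beh.one_sample_t(rates[label] - rates["down_state"])
                rate_tests[f"{label}_vs_down"] = dataclasses.asdict(res)
    pd.DataFrame(rate_rows).to_csv(out / "up_state_rates.tsv", sep="\t",
                                   index=False)

    # --- peristimulus bin series (group mean of z-scores) -----------------
    edges = so.BIN_WINDOW_S[0] + so.BIN_WIDTH_S * np.arange(so.N_BINS + 1)
    bin_df = pd.DataFrame({
        "bin_start_s": edges[:-1], "bin_end_s": edges[1:],
        "z_count_mean": np.nanmean(np.stack(bin_counts_z), axis=0),
        "z_amp_mean": np.nanmean(np.stack(bin_amps_z), axis=0),
    })
    bin_df.to_csv(out / "up_state_bins.tsv", sep="\t", index=False)

    # --- topographies: spontaneous vs entrained ---------------------------
    anova_results: dict[str, dict] = {}
    topo_rows: dict[tuple[int, str], np.ndarray] = {}
    ev_pairs = {"up_state_1": "spontaneous_up",
                "up_state_2": "spontaneous_up",
                "down_state": "spontaneous_down"}
    for label, ci in labels.items():
        s = summaries[ci]
        ti = int(np.argmin(np.abs(erp_times - s["peak_time_ms"])))
        for i in range(n):
            topo_rows[(i, label)] = topo.normalize_topography(erps[i][ti])
    for i, d in enumerate(spont_topos):
        for ev, vals in d.items():
            try:
                topo_rows[(i, ev)] = topo.normalize_topography(vals)
            except ValueError:
                warnings_log.append(
                    f"participant {i}: degenerate {ev} topography")
    topo_table = topo.topography_table(topo_rows, erp_chs)
    topo_table.to_csv(out / "topographies.tsv", sep="\t", index=False)
    for label, spont in ev_pairs.items():
        if label not in labels:
            continue
        sub = topo_table[topo_table["event"].isin([label, spont])]
        complete = (sub.groupby("participant")["event"].nunique() == 2)
        keep = complete[complete].index
        sub = sub[sub["participant"].isin(keep)]
        if sub["participant"].nunique() >= 3:
            try:
                anova_results[f"{label}_vs_{spont}"] = \
                    topo.topography_anova(sub)
            except ValueError as err:
                warnings_log.append(f"topography ANOVA {label}: {err}")
        else:
            warnings_log.append(
                f"too few participants for topography ANOVA of {label}")

    # --- ERSP: band contrasts and time-frequency clusters -----------------
    band_rows = []
    ersp_summaries: list[dict] = []
    if ana.ersp.enabled and ersp_grids:
        for name, band in ersp_mod.BANDS.items():
            _, res = ersp_mod.band_power_contrast(
                ersp_grids, band, half_open_low=(name == "gamma"))
            band_rows.append({"band": name, "low_hz": band[0],
                              "high_hz": band[1], **res})
        pd.DataFrame(band_rows).to_csv(out / "band_power_contrasts.tsv",
                                       sep="\t", index=False)
        if ana.ersp.cluster_test:
            g = np.stack([gr.values for gr in ersp_grids])
            sub_adj = channel_adjacency(tuple(ana.ersp.channels))
            eclusters, _ = cs.run_cluster_test(
                g, n_perm=ana.n_permutations, alpha=ana.alpha,
                ch_adjacency=sub_adj,
                rng=np.random.default_rng(cfg.seed + 40213))
            et = cs.pointwise_t(g)
            ersp_summaries = [
                cs.summarize_cluster(c, ersp_grids[0].times_ms,
                                     tuple(ana.ersp.channels), et,
                                     freqs=ersp_grids[0].freqs)
                for c in eclusters]
            pd.DataFrame(ersp_summaries).to_csv(
                out / "ersp_clusters.tsv", sep="\t", index=False)

    # --- behaviour: group tests and brain-behaviour correlations ----------
    stats_report: dict = {"n_participants": n}
    for col, key in (("semantic_dB", "semantic_priming"),
                     ("perceptual_ms", "perceptual_priming")):
        vals = scores[col].dropna().to_numpy()
        if vals.size >= 2:
            stats_report[key] = dataclasses.asdict(beh.one_sample_t(vals))
    acc = scores["accuracy_pct"].to_numpy()
    stats_report["accuracy_vs_chance"] = dataclasses.asdict(
        beh.one_sample_t(acc - 50.0))
    stats_report["accuracy_mean_pct"] = float(acc.mean())
    try:
        sp = beh.spearman_correlation(
            scores["semantic_dB"], scores["perceptual_ms"])
        stats_report["semantic_vs_perceptual"] = dataclasses.asdict(sp)
    except ValueError as err:
        warnings_log.append(f"semantic-perceptual correlation: {err}")
    if "up_state_1" in labels and "up_state_2" in labels:
        stats_report["entrained_frequency_hz"] = beh.entrained_frequency(
            [summaries[labels["up_state_1"]]["peak_time_ms"],
             summaries[labels["up_state_2"]]["peak_time_ms"]], ndigits=2)
    stats_report["up_state_rate_tests"] = rate_tests
    stats_report["topography_anovas"] = anova_results

    if magnitudes:
        try:
            corr = beh.brain_behavior_correlations(
                magnitudes, scores,
                covariates={"presentation_volume": np.array(volumes)})
            corr.to_csv(out / "brain_behavior_correlations.tsv", sep="\t",
                        index=False)
        except ValueError as err:
            warnings_log.append(f"brain-behavior correlations: {err}")

    with open(out / "stats_report.json", "w") as f:
        json.dump(stats_report, f, indent=2, default=float)

    if config.output.plots:
        _write_plots(out, bin_df, erps, erp_times, erp_chs)

    # --- manifest ---------------------------------------------------------
    from . import __version__
    import scipy
    manifest = {
        "config": json.loads(config.model_dump_json()),
        "cohort_config": dataclasses.asdict(cfg),
        "seed": cfg.seed,
        "versions": {"sleepentrain": __version__,
                     "numpy": np.__version__, "scipy": scipy.__version__,
                     "pandas": pd.__version__},
        "outputs": {},
        "warnings": warnings_log,
    }
    for f_ in sorted(out.iterdir()):
        if f_.name != "manifest.json" and f_.is_file():
            manifest["outputs"][f_.name] = _sha256(f_)
    save_config_yaml(json.loads(config.model_dump_json()),
                     out / "config_used.yaml")
    manifest["outputs"]["config_used.yaml"] = _sha256(
        out / "config_used.yaml")
    with open(out / "manifest.json", "w") as f:
        json.dump(manifest, f, indent=2, default=float)
    log.info("pipeline finished: %s", out)
    return manifest


def _write_plots(out: Path, bin_df: pd.DataFrame, erps, erp_times,
                 erp_chs) -> None:  # pragma: no cover - optional output
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(2, 1, figsize=(7, 6), sharex=True)
    centers = (bin_df["bin_start_s"] + bin_df["bin_end_s"]) / 2
    axes[0].bar(centers, bin_df["z_count_mean"], width=0.18)
    axes[0].set_ylabel("z(count)")
    axes[1].bar(centers, bin_df["z_amp_mean"], width=0.18)
    axes[1].set_ylabel("z(peak amplitude)")
    axes[1].set_xlabel("time from word onset (s)")
    fig.savefig(out / "up_state_bins.png", dpi=120)
    plt.close(fig)

    fz = erp_chs.index("Fz")
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.plot(erp_times, np.mean([e[:, fz] for e in erps], axis=0))
    ax.axvline(0, color="k", lw=0.5)
    ax.set_xlabel("time from word onset (ms)")
    ax.set_ylabel("amplitude (uV)")
    fig.savefig(out / "erp_fz.png", dpi=120)
    plt.close(fig)
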