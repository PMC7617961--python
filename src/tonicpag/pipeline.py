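"""End-to-end orchestration: simulate -> analyse -> report.

The pipeline runs the stages of the escape-activity analysis on a synthetic
session (or on data loaded through the per-module readers), with every
numeric default mirroring the analysis constants (activity z threshold 1.96,
transient prominence 0.3 Z, 660 ms slope window, 500 ms baseline window,
6 s / 7.5 s escape deadlines, +/-0.2 Z ternary thresholds, 1.5 / 2 cm/s
speed thresholds, 1000 bootstrap/permutation replicates, 50 ms charge
window, 2 min drug baseline). A JSON manifest echoes the full configuration
and library versions so a run is reproducible from its output directory.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import behavior, calcium, clustering, escape_response, locomotion, spiketrain, synaptic, synth

__all__ = ["PipelineConfig", "run", "load_config"]

STAGES = (
    "simulate",
    "invitro",
    "calcium",
    "locomotion",
    "behavior",
    "response",
    "cluster",
    "report",
)


@dataclass
class PipelineConfig:
    """Run configuration; unknown keys in a config file are rejected."""

    seed: int = 0
    stages: tuple[str, ...] = STAGES
    out_dir: str = "tonicpag_run"
    # synthetic-session conditions
    n_ramp: int = 12
    n_dip: int = 8
    n_unmod: int = 14
    n_trials: int = 8
    n_fail_trials: int = 3
    session_noise_sd: float = 0.5
    frame_rate: float = 15.0
    # in vitro conditions
    spike_rate_hz: float = 4.7
    spike_duration_s: float = 240.0
    ipsc_rate_hz: float = 6.5
    ipsc_duration_s: float = 60.0
    # analysis constants (mirroring the published analysis)
    active_z_threshold: float = 1.96
    transient_prominence: float = 0.3
    slope_window_s: float = 0.66
    baseline_window_s: float = 0.5
    escape_deadline_s: float = 6.0
    imaging_escape_deadline_s: float = 7.5
    ternary_lo: float = -0.2
    ternary_hi: float = 0.2
    speed_threshold_cmps: float = 1.5
    movement_event_threshold_cmps: float = 2.0
    n_bootstrap: int = 1000
    n_permutations: int = 1000
    charge_window_ms: float = 50.0
    drug_baseline_min: float = 2.0
    lowpass_cutoff_hz: float = 2.0
    make_plots: bool = False

    def validate_stages(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")


def load_config(path: str | Path | None = None, **overrides: Any) -> PipelineConfig:
    """Config from YAML with CLI-style overrides; unknown keys raise."""
    data: dict[str, Any] = {}
    if path is not None:
        data = yaml.safe_load(Path(path).read_text()) or {}
    data.update({k: v for k, v in overrides.items() if v is not None})
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "stages" in data:
        data["stages"] = tuple(data["stages"])
    cfg = PipelineConfig(**data)
    cfg.validate_stages()
    return cfg


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g")


def run(config: PipelineConfig, out_dir: str | Path | None = None) -> dict[str, Any]:
    """Execute the configured stages; returns the result summary dict.

    Each stage writes its own tables into the run directory and never
    mutates another stage's outputs; outputs are deterministic for a fixed
    seed.
    """
    config.validate_stages()
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict[str, Any] = {}
    rng_seed = int(config.seed)

    session = None
    if "simulate" in config.stages:
        spec = synth.SessionSpec(
            n_ramp=config.n_ramp,
            n_dip=config.n_dip,
            n_unmod=config.n_unmod,
            n_trials=config.n_trials,
            n_fail_trials=config.n_fail_trials,
            noise_sd=config.session_noise_sd,
            frame_rate=config.frame_rate,
            seed=rng_seed,
        )
        session = synth.gen_session(spec)
        synth.write_session_manifest(spec, out / "session_spec.yaml")
        results["simulate"] = {
            "n_neurons": session.n_neurons,
            "n_trials": len(session.trials),
            "duration_s": session.duration,
        }

    if "invitro" in config.stages:
        train = synth.gen_spike_train(
            synth.SpikeTrainSpec(
                mode="gamma",
                rate=config.spike_rate_hz,
                duration=config.spike_duration_s,
                gamma_shape=20.0,
                seed=rng_seed + 1,
            )
        )
        st = spiketrain.isi_stats(train)
        rec, truth = synth.gen_ipsc_trace(
            synth.IpscTraceSpec(
                event_rate=config.ipsc_rate_hz,
                duration=config.ipsc_duration_s,
                seed=rng_seed + 2,
            )
        )
        events = synaptic.detect_events(rec, charge_window_ms=config.charge_window_ms)
        summary = synaptic.summarize(events, rec)
        df = pd.DataFrame(
            [
                {
                    "firing_rate_hz": st.mean_rate,
                    "cv": st.cv,
                    "cv2": st.cv2,
                    "ipsc_frequency_hz": summary.frequency,
                    "ipsc_amplitude_pa": summary.mean_peak_amplitude,
                    "peak_conductance_ns": summary.peak_conductance,
                    "unitary_charge_pc": summary.unitary_charge,
                    "average_charge_rate_pc_per_s": summary.average_charge_rate,
                    "n_true_events": len(truth),
                    "n_detected_events": len(events),
                }
            ]
        )
        _write_csv(df, out / "invitro_summary.csv")
        results["invitro"] = df.iloc[0].to_dict()

    active_mask = None
    if "calcium" in config.stages:
        if session is None:
            raise RuntimeError("calcium stage requires the simulate stage")
        rows = []
        active_mask = np.zeros(session.n_neurons, dtype=bool)
        for i in range(session.n_neurons):
            z = session.traces[i]
            active_mask[i] = calcium.is_active(z, config.active_z_threshold)
            _, rate = calcium.detect_transients(
                z,
                session.frame_rate,
                prominence=config.transient_prominence,
            )
            rows.append(
                {
                    "neuron_id": f"n{i:03d}",
                    "motif": session.motifs[i],
                    "active": bool(active_mask[i]),
                    "transient_rate_hz": rate,
                }
            )
        df = pd.DataFrame(rows)
        _write_csv(df, out / "calcium_summary.csv")
        results["calcium"] = {
            "n_active": int(active_mask.sum()),
            "mean_transient_rate_hz": float(df["transient_rate_hz"].mean()),
        }

    if "locomotion" in config.stages:
        if session is None:
            raise RuntimeError("locomotion stage requires the simulate stage")
        baseline = (0.0, session.spec.baseline_duration)
        bins = locomotion.segment_states(
            session.speed,
            session.in_shelter,
            frame_rate=session.frame_rate,
            dff=session.traces.T,
            baseline_window=baseline,
            threshold=config.speed_threshold_cmps,
        )
        lmi_results = {}
        for i in range(session.n_neurons):
            try:
                lmi_results[f"n{i:03d}"] = locomotion.bootstrap_lmi(
                    bins,
                    neuron=i,
                    n_reps=config.n_bootstrap,
                    seed=rng_seed + 100 + i,
                )
            except spiketrain.InsufficientDataError:
                continue
        locomotion.write_lmi_csv(lmi_results, out / "lmi.csv")
        n_sig = sum(r.significant for r in lmi_results.values())
        results["locomotion"] = {
            "n_bins": len(bins.table),
            "n_neurons_tested": len(lmi_results),
            "n_significant": int(n_sig),
        }

    trial_rows = None
    if "behavior" in config.stages:
        if session is None:
            raise RuntimeError("behavior stage requires the simulate stage")
        geometry = behavior.ArenaGeometry(
            arena_length=session.spec.arena_length,
            shelter_entrance=session.spec.shelter_position,
            far_end=session.spec.arena_length,
        )
        rows = []
        for k, tr in enumerate(session.trials):
            trial = behavior.EscapeTrial(
                stimulus_onset=tr.stimulus_onset,
                stimulus_end=tr.stimulus_end,
                events=dict(tr.events),
                speed=session.speed,
                position=session.position,
                frame_rate=session.frame_rate,
                animal_id="sim",
            )
            outcome = behavior.classify_escape(
                trial,
                deadline=config.escape_deadline_s,
                imaging_deadline=config.imaging_escape_deadline_s,
                imaging=True,
            )
            row = {
                "trial_id": k,
                "animal_id": "sim",
                "outcome": outcome,
                "ground_truth": tr.outcome,
            }
            if outcome == "escape":
                row["peak_speed_cmps"] = behavior.peak_escape_speed(trial)
                stop_pos = session.position[
                    int(round(tr.events["escape_stop"] * session.frame_rate))
                ]
                row["termination_distance"] = behavior.termination_distance(
                    stop_pos, geometry
                )
                row["path_length_cm"] = behavior.escape_path_length(trial)
            rows.append(row)
        trial_rows = pd.DataFrame(rows)
        _write_csv(trial_rows, out / "trials.csv")
        prob = behavior.escape_probability(trial_rows)
        _write_csv(prob, out / "escape_probability.csv")
        results["behavior"] = {
            "escape_probability": float(prob["escape_probability"].iloc[0]),
            "outcome_agreement": float(
                (trial_rows["outcome"] == trial_rows["ground_truth"]).mean()
            ),
        }

    warped_means = None
    template = None
    window_means = None
    if "response" in config.stages:
        if session is None:
            raise RuntimeError("response stage requires the simulate stage")
        escape_events = [
            tr.events for tr in session.trials if tr.outcome == "escape"
        ]
        template = escape_response.build_template(
            [
                {k: v - tr.stimulus_onset for k, v in tr.events.items()}
                for tr in session.trials
                if tr.outcome == "escape"
            ]
        )
        fs = session.frame_rate
        active_rows = []
        means = []
        win_means = []
        kept_idx = []
        for i in range(session.n_neurons):
            trials_for_test = []
            trials_for_mean = []
            for tr in session.trials:
                z = escape_response.baseline_subtract(
                    session.traces[i],
                    fs,
                    tr.stimulus_onset,
                    window_s=config.baseline_window_s,
                )
                trials_for_test.append((z, tr.events))
                trials_for_mean.append((z, tr.events, tr.outcome))
            test = escape_response.escape_active_test(
                trials_for_test, fs, window_s=config.slope_window_s
            )
            active_rows.append(
                {
                    "neuron_id": f"n{i:03d}",
                    "motif": session.motifs[i],
                    "escape_active": test.escape_active,
                }
            )
            resp = escape_response.mean_response(trials_for_mean, fs, template)
            if resp.mean_escape is not None:
                means.append(resp.mean_escape)
                win_means.append(resp.window_mean_escape)
                kept_idx.append(i)
        warped_means = np.asarray(means)
        window_means = np.asarray(win_means)
        df = pd.DataFrame(active_rows)
        _write_csv(df, out / "escape_active.csv")
        escape_response.write_warped_h5(warped_means, template, out / "warped_means.h5")
        results["response"] = {
            "n_escape_active": int(df["escape_active"].sum()),
            "kept_neurons": kept_idx,
        }

    if "cluster" in config.stages:
        if warped_means is None or template is None:
            raise RuntimeError("cluster stage requires the response stage")
        filt = np.vstack(
            [
                calcium.lowpass_fft(m, template.grid_rate, config.lowpass_cutoff_hz)
                for m in warped_means
            ]
        )
        tern = clustering.ternarize(filt, config.ternary_lo, config.ternary_hi)
        scores, evr = clustering.embed_pca(tern)
        cres = clustering.cluster_k(scores, window_means=window_means, seed=rng_seed)
        kept = results.get("response", {}).get("kept_neurons", list(range(len(filt))))
        ids = [f"n{i:03d}" for i in kept]
        clustering.write_labels_csv(cres.labels, ids, out / "cluster_labels.csv")
        _write_csv(
            pd.DataFrame(
                {
                    "k": list(cres.silhouette_by_k),
                    "silhouette": list(cres.silhouette_by_k.values()),
                    "inertia": list(cres.inertia_by_k.values()),
                }
            ),
            out / "silhouette.csv",
        )
        stop_t = template.anchor_time("escape_stop")
        timings = [
            clustering.extremum_timing(filt[j], template.grid, cres.labels[j], stop_t)
            for j in range(len(filt))
        ]
        _write_csv(
            pd.DataFrame(
                {"neuron_id": ids, "cluster": cres.labels, "extremum_time_s": timings}
            ),
            out / "extremum_timing.csv",
        )
        overlap = None
        if len(np.unique(cres.labels)) == 2:
            counts = np.bincount(cres.labels)[1:]
            if counts.min() >= 3:
                cents = session.centroids[kept]
                overlap = clustering.spatial_overlap(
                    cents,
                    cres.labels,
                    n_permutations=config.n_permutations,
                    seed=rng_seed,
                )
                _write_csv(
                    pd.DataFrame(
                        [
                            {
                                "jaccard": overlap.jaccard,
                                "permutation_p": overlap.permutation_p,
                                "n_permutations": overlap.n_permutations,
                            }
                        ]
                    ),
                    out / "spatial_overlap.csv",
                )
        results["cluster"] = {
            "chosen_k": cres.chosen_k,
            "silhouette": cres.silhouette_by_k.get(cres.chosen_k),
            "explained_variance": [float(v) for v in evr],
            "labels": [int(v) for v in cres.labels],
            "jaccard": None if overlap is None else overlap.jaccard,
        }

    if "report" in config.stages:
        manifest = {
            "config": asdict(config) | {"stages": list(config.stages)},
            "versions": {
                "python": sys.version.split()[0],
                "numpy": np.__version__,
                "pandas": pd.__version__,
            },
            "results": _jsonable(results),
        }
        blob = json.dumps(manifest["config"], sort_keys=True).encode()
        manifest["config_hash"] = hashlib.sha256(blob).hexdigest()[:16]
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        if config.make_plots and warped_means is not None:
            _plot_overview(out, warped_means, template)
    return results


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def _plot_overview(out: Path, warped_means: np.ndarray, template) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for m in warped_means:
        ax.plot(template.grid, m, lw=0.5, alpha=0.5)
    for name, t in zip(template.event_names, template.template_times):
        ax.axvline(t, color="k", lw=0.5, ls=":")
    ax.set_xlabel("template time (s)")
    ax.set_ylabel("z-score")
    fig.tight_layout()
    fig.savefig(out / "warped_means.png", dpi=120)
    plt.close(fig)
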