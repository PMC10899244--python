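"""Config-driven end-to-end pipeline.

Runs filter -> detect -> snippets -> PCA -> k-means -> cluster quality ->
phase locking -> behavioral statistics over a recording (loaded from disk
or produced by the built-in simulator), writes every intermediate table
as TSV plus a JSON summary, and is bit-reproducible for a fixed config
and seed.  The single config seed fans out to per-stage child seeds via
``numpy.random.SeedSequence([seed, stage_index])`` so stages can be rerun
in isolation.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import behavior, detect, dsp, phase, quality, synth
from .core import (
    EventTable,
    Recording,
    SpikeTrain,
    read_events,
    read_recording,
    write_events,
    write_recording,
    write_spike_table,
)

log = logging.getLogger("thetasort")

_STAGE_SEEDS = {"simulate": 0, "sort": 1, "track": 2}


class ConfigError(ValueError):
    """Invalid or incomplete pipeline configuration."""


def stage_seed(seed: int, stage: str) -> int:
    """Derive a per-stage child seed from the pipeline seed (documented fan-out)."""
    return int(
        np.random.SeedSequence([seed, _STAGE_SEEDS[stage]]).generate_state(1)[0]
        % (2**31)
    )


def _unit_specs(cfg: dict) -> dict[str, synth.UnitSpec]:
    units = {}
    for uid, u in cfg.items():
        units[uid] = synth.UnitSpec(
            channel_id=u["channel_id"],
            base_rate=float(u.get("base_rate", 5.0)),
            amplitude=float(u.get("amplitude", 100.0)),
            trough_width_ms=float(u.get("trough_width_ms", 0.3)),
            repol_width_ms=float(u.get("repol_width_ms", 0.6)),
            preferred_phase=float(u.get("preferred_phase", 0.0)),
            kappa=float(u.get("kappa", 0.0)),
            state_gain={k: float(v) for k, v in u.get("state_gain", {}).items()},
            refractory=float(u.get("refractory", 0.002)),
        )
    return units


def _events_from_config(config: dict) -> EventTable | None:
    if "events" in config:
        return read_events(config["events"])
    if "events_inline" in config:
        return EventTable(pd.DataFrame(
            config["events_inline"], columns=["label", "t_start", "t_end"]
        ))
    return None


def _load_inputs(
    config: dict, seed: int
) -> tuple[Recording, EventTable | None, synth.GroundTruth | None]:
    events = _events_from_config(config)
    if "recording" in config:
        return read_recording(config["recording"]), events, None
    if "simulate" not in config:
        raise ConfigError("config needs either 'recording' or a 'simulate' block")
    sim = config["simulate"]
    lfp_cfg = sim.get("lfp", {})
    lfp = synth.LfpSpec(
        theta_freq=float(lfp_cfg.get("theta_freq", 6.0)),
        theta_amp=float(lfp_cfg.get("theta_amp", 150.0)),
        delays={k: float(v) for k, v in lfp_cfg.get("delays", {}).items()},
        pink_rms=float(lfp_cfg.get("pink_rms", 20.0)),
        mains_amp=float(lfp_cfg.get("mains_amp", 0.0)),
    )
    rec, gt = synth.simulate_recording(
        channel_ids=list(sim["channels"]),
        units=_unit_specs(sim.get("units", {})),
        lfp=lfp,
        events=events,
        duration=float(sim.get("duration", 10.0)),
        noise_rms=float(sim.get("noise_rms", 15.0)),
        rate=float(sim.get("rate", 24414.0)),
        seed=stage_seed(seed, "simulate"),
        regions=sim.get("regions"),
    )
    return rec, events, gt


def run_pipeline(config: dict, seed: int, out_dir: str | Path) -> dict[str, Any]:
    """Execute the full analysis chain and write a report bundle.

    Returns the summary dict (also written as ``summary.json``).  Any
    stage error is logged with the stage name and re-raised; tables
    produced before the failure remain on disk.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    t_start = time.time()
    summary: dict[str, Any] = {"seed": seed, "channels": {}}

    stage = "load"
    try:
        rec, events, gt = _load_inputs(config, seed)
        log.info("stage=%s channels=%d samples=%d rate=%g", stage,
                 rec.n_channels, rec.n_samples, rec.rate)

        stage = "filter"
        band_name = config.get("spike_band", "spike")
        band = dsp.NAMED_BANDS[band_name] if isinstance(band_name, str) else dsp.BandSpec(
            float(band_name["low"]), float(band_name["high"])
        )
        if config.get("notch60", False):
            rec = dsp.notch60(rec)
        spike_rec = dsp.bandpass(rec, band)
        theta_rec = dsp.bandpass(rec, dsp.THETA_BAND)

        stage = "detect"
        params = detect.DetectionParams(**config.get("detection", {}))
        sort_seed = stage_seed(seed, "sort")
        d = int(config.get("d", 8))
        k_map = config.get("k", {})
        min_spikes = int(config.get("min_spikes", 25))
        trains: list[SpikeTrain] = []
        labels_per_channel: list[np.ndarray] = []
        qual_rows, phase_rows, epoch_frames = [], [], []
        for ch in rec.channel_ids:
            trace = spike_rec.channel(ch)
            train = detect.detect_spikes(trace, rec.rate, params, channel_id=ch)
            snippets, n_dropped = detect.extract_snippets(
                trace, train.spike_times, rec.rate, params
            )
            train = SpikeTrain(ch, snippets.spike_times)
            log.info("stage=detect channel=%s spikes=%d dropped=%d",
                     ch, len(train), n_dropped)
            k = int(k_map.get(ch, 1))
            ch_summary: dict[str, Any] = {"n_spikes": len(train), "k": k}
            if len(train) > max(d, k):
                feats = detect.pca_features(snippets, d=d)
                labels = detect.kmeans_cluster(feats, k, seed=sort_seed)
                if k > 1:
                    for cq in quality.quality_report(feats, labels, df=d):
                        qual_rows.append(
                            (ch, cq.cluster_id, cq.n_c, cq.L, cq.l_ratio,
                             np.nan if cq.isolation_distance is None
                             else cq.isolation_distance, cq.df)
                        )
                theta_phase = dsp.instantaneous_phase(theta_rec.channel(ch))
                unit_spike_times = {}
                for cid in np.unique(labels):
                    uid = f"{ch}/c{cid}"
                    times = train.spike_times[labels == cid]
                    unit_spike_times[uid] = times
                    res = phase.phase_locking(
                        uid, times, theta_phase, rec.rate, min_spikes=min_spikes
                    )
                    phase_rows.append(
                        (uid, res.n_spikes, res.circular_mean,
                         res.resultant_length, res.rayleigh_z, res.rayleigh_p,
                         res.included)
                    )
                if events is not None and len(events):
                    epoch_frames.append(behavior.epoch_stats(unit_spike_times, events))
                amps, _ = detect.peak_to_peak(snippets, groups=labels)
                ch_summary["mean_amplitude_uV"] = float(amps.mean())
                ch_summary["units"] = {
                    f"c{cid}": int((labels == cid).sum()) for cid in np.unique(labels)
                }
            else:
                labels = np.ones(len(train), dtype=int)
            trains.append(train)
            labels_per_channel.append(labels)
            summary["channels"][ch] = ch_summary

        stage = "write"
        write_spike_table(trains, labels_per_channel, out_dir / "spikes.tsv")
        pd.DataFrame(
            qual_rows,
            columns=["channel", "cluster", "N_c", "L", "L_ratio",
                     "isolation_distance", "df"],
        ).to_csv(out_dir / "quality.tsv", sep="\t", index=False, float_format="%.6g")
        pd.DataFrame(
            phase_rows,
            columns=["unit", "n", "mean_deg", "R", "z", "p", "included"],
        ).to_csv(out_dir / "phase.tsv", sep="\t", index=False, float_format="%.6g")
        if epoch_frames:
            pd.concat(epoch_frames, ignore_index=True).to_csv(
                out_dir / "epochs.tsv", sep="\t", index=False, float_format="%.6g"
            )
        n_sortable = sum(
            1 for ch in summary["channels"].values() if ch["n_spikes"] > 0
        )
        summary["yield_percent"] = behavior.recording_yield(n_sortable, rec.n_channels)
        summary["n_spikes_total"] = int(sum(len(t) for t in trains))
        if gt is not None:
            summary["ground_truth_units"] = {
                uid: int(len(times)) for uid, times in gt.spike_times.items()
            }
        text = json.dumps(summary, indent=1, sort_keys=True)
        (out_dir / "summary.json").write_text(text)
        log.info("stage=done wall=%.2fs", time.time() - t_start)
        return summary
    except Exception:
        log.exception("pipeline failed at stage=%s", stage)
        raise


def make_fixtures(seed: int, out_dir: str | Path) -> dict[str, Any]:
    """Small deterministic test dataset: 2 channels, 10 s, two phase-locked units.

    Writes recording, events and a ground-truth JSON under ``out_dir``
    and returns the generating configuration.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    events = EventTable(pd.DataFrame(
        [("running", 0.0, 5.0), ("standstill", 5.0, 10.0)],
        columns=["label", "t_start", "t_end"],
    ))
    units = {
        "u1": synth.UnitSpec("ch1", base_rate=8.0, amplitude=120.0,
                             preferred_phase=330.0, kappa=4.0,
                             state_gain={"running": 2.0}),
        "u2": synth.UnitSpec("ch1", base_rate=6.0, amplitude=60.0,
                             trough_width_ms=0.5, repol_width_ms=0.9,
                             preferred_phase=45.0, kappa=4.0),
    }
    lfp = synth.LfpSpec(theta_freq=6.0, theta_amp=150.0,
                        delays={"ch2": 0.015}, pink_rms=10.0)
    rec, gt = synth.simulate_recording(
        ["ch1", "ch2"], units, lfp, events, duration=10.0,
        noise_rms=15.0, rate=24414.0, seed=seed,
    )
    write_recording(rec, out_dir / "fixture")
    write_events(events, out_dir / "fixture_events.tsv")
    gt_json = {
        "spike_times": {u: list(map(float, t)) for u, t in gt.spike_times.items()},
        "unit_channels": gt.unit_channels,
        "noise_rms": gt.noise_rms,
    }
    (out_dir / "fixture_truth.json").write_text(json.dumps(gt_json, indent=1))
    return {
        "recording": str(out_dir / "fixture.bin"),
        "events": str(out_dir / "fixture_events.tsv"),
        "k": {"ch1": 2},
    }
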