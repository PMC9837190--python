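"""Plain-text export of synthetic datasets.

Writes the tabular interchange files a decoding analysis would consume:
spikes.csv, units.csv, frames.csv, labels.csv, cuts.csv, scenes.csv,
clips.csv and embeddings.json, plus a run-manifest JSON recording the
seeds and configuration used.
"""
from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .labeling import FrameLabelTable
from .synthetic import (CharacterTimeline, CropClusterSet, MemorySession,
                        SpikeDataset)

__all__ = ["write_dataset", "write_embeddings", "write_rates",
           "write_windows_manifest", "write_cut_confusion", "read_spikes"]


def _jsonable(obj):
    if dataclasses.is_dataclass(obj):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    return obj


def write_dataset(out_dir: str | Path, timeline: CharacterTimeline,
                  spikes: SpikeDataset,
                  labels: FrameLabelTable | None = None,
                  session: MemorySession | None = None,
                  seeds: dict | None = None) -> Path:
    """Write a synthetic session as plain CSV tables plus a manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spikes.events.to_csv(out / "spikes.csv", index=False)
    spikes.units.to_csv(out / "units.csv", index=False)
    pd.DataFrame({"frame_idx": np.arange(len(timeline.frame_times)),
                  "time_s": timeline.frame_times}).to_csv(
        out / "frames.csv", index=False)
    if labels is not None:
        labels.to_frame().to_csv(out / "labels.csv", index=False)
    pd.DataFrame(timeline.cuts, columns=["start_s", "end_s"]).to_csv(
        out / "cuts.csv", index=False)
    timeline.scene_table().to_csv(out / "scenes.csv", index=False)
    if session is not None:
        session.clips.to_csv(out / "clips.csv", index=False)
    manifest = {
        "seeds": seeds or {},
        "timeline_config": _jsonable(timeline.config),
        "n_units": spikes.n_units,
        "n_spikes": spikes.total_spikes(),
        "duration_s": timeline.duration_s,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out


def write_embeddings(out_path: str | Path, crops: CropClusterSet) -> Path:
    out = Path(out_path)
    out.parent.mkdir(parents=True, exist_ok=True)
    payload = {
        "dim": crops.dim,
        "noise_sd": crops.noise_sd,
        "clusters": [{
            "cluster_id": c.cluster_id,
            "embeddings": c.embeddings.tolist(),
            "has_face": c.has_face.astype(bool).tolist(),
            "frame_span": list(c.frame_span),
            "identity": c.identity,
        } for c in crops.clusters],
    }
    out.write_text(json.dumps(payload))
    return out


def write_rates(out_dir: str | Path, rates) -> Path:
    """Write a RateMatrix as rates.csv (units x samples) with a JSON
    sidecar holding the sample rate, time origin, unit order and the
    excluded-sample mask."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    np.savetxt(out / "rates.csv", rates.rates, delimiter=",", fmt="%.6g")
    sidecar = {
        "sample_rate_hz": rates.sample_rate_hz,
        "t0": rates.t0,
        "unit_ids": [int(u) for u in rates.unit_ids],
        "excluded": np.flatnonzero(rates.excluded).tolist(),
    }
    (out / "rates_meta.json").write_text(json.dumps(sidecar))
    return out


def write_windows_manifest(out_path: str | Path, samples,
                           fold_plan=None) -> Path:
    """Sample count, dropped-frame count and the fold plan of a
    WindowSampleSet, as JSON."""
    out = Path(out_path)
    out.parent.mkdir(parents=True, exist_ok=True)
    payload = {"n_samples": int(samples.n_samples),
               "n_dropped": int(samples.n_dropped),
               "window_steps": int(samples.x.shape[1]),
               "unit_ids": [int(u) for u in samples.unit_ids]}
    if fold_plan is not None:
        payload["seed"] = fold_plan.seed
        payload["folds"] = [{k: v.tolist() for k, v in f.items()}
                            for f in fold_plan.folds]
    out.write_text(json.dumps(payload))
    return out


def write_cut_confusion(out_path: str | Path, confusion: dict) -> Path:
    """Per-character normalized cut-level confusion matrices as CSV."""
    rows = []
    for char, mat in confusion.items():
        rows.append({"character": char,
                     "tp_rate": mat[0, 0], "fn_rate": mat[0, 1],
                     "fp_rate": mat[1, 0], "tn_rate": mat[1, 1]})
    out = Path(out_path)
    out.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(out, index=False)
    return out


def read_spikes(data_dir: str | Path) -> SpikeDataset:
    """Load a dataset written by :func:`write_dataset`."""
    data_dir = Path(data_dir)
    events = pd.read_csv(data_dir / "spikes.csv")
    units = pd.read_csv(data_dir / "units.csv")
    manifest = json.loads((data_dir / "manifest.json").read_text())
    return SpikeDataset(events=events, units=units,
                        duration_s=manifest["duration_s"])
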