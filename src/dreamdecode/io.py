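"""Array-container I/O and the run manifest.

Session bundles (runs + report table), sample sets and decoder banks are
stored in HDF5 via h5py; tables travel as CSV; the manifest is JSON with a
SHA-256 checksum per emitted file so a downstream stage re-run from disk
can verify its inputs.
"""

from __future__ import annotations

import hashlib
import json
from io import StringIO
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .decoding import DecoderBank, UnitDecoder
from .preprocess import SampleSet
from .simulate import Event, RunTimeSeries

__all__ = [
    "save_session_bundle",
    "load_session_bundle",
    "save_sampleset",
    "load_sampleset",
    "save_decoder_bank",
    "load_decoder_bank",
    "write_manifest",
]

_STR = h5py.string_dtype(encoding="utf-8")


def _write_roi_masks(grp: h5py.Group, masks: dict[str, np.ndarray]) -> None:
    mg = grp.create_group("roi_masks")
    for roi, idx in masks.items():
        mg.create_dataset(roi, data=np.asarray(idx, dtype=np.int64))


def _read_roi_masks(grp: h5py.Group) -> dict[str, np.ndarray]:
    return {roi: np.asarray(ds) for roi, ds in grp["roi_masks"].items()}


def save_session_bundle(
    path: str | Path, runs: list[RunTimeSeries], reports: pd.DataFrame | None = None
) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        rg = f.create_group("runs")
        for run in runs:
            g = rg.create_group(run.run_id)
            g.create_dataset("data", data=run.data)
            g.create_dataset("nuisance", data=run.nuisance)
            g.attrs["tr_seconds"] = run.tr_seconds
            ev = g.create_group("events")
            for i, e in enumerate(run.events):
                eg = ev.create_group(f"ev{i:04d}")
                eg.attrs["onset"] = e.onset
                eg.attrs["duration"] = e.duration
                eg.attrs["kind"] = e.kind
                eg.attrs["labels"] = ";".join(e.labels)
                eg.attrs["exemplar"] = -1 if e.exemplar is None else e.exemplar
            _write_roi_masks(g, run.roi_masks)
            if run.spike_log:
                g.create_dataset("spike_log", data=np.asarray(run.spike_log, np.int64))
        if reports is not None:
            f.attrs["reports_json"] = reports.to_json(orient="records")


def load_session_bundle(
    path: str | Path,
) -> tuple[list[RunTimeSeries], pd.DataFrame | None]:
    runs = []
    with h5py.File(path, "r") as f:
        for run_id in sorted(f["runs"]):
            g = f["runs"][run_id]
            events = []
            for key in sorted(g["events"]):
                eg = g["events"][key]
                ex = int(eg.attrs["exemplar"])
                events.append(
                    Event(
                        onset=int(eg.attrs["onset"]),
                        duration=int(eg.attrs["duration"]),
                        labels=tuple(str(eg.attrs["labels"]).split(";")),
                        kind=str(eg.attrs["kind"]),
                        exemplar=None if ex < 0 else ex,
                    )
                )
            spikes = (
                [tuple(map(int, row)) for row in np.asarray(g["spike_log"])]
                if "spike_log" in g
                else []
            )
            runs.append(
                RunTimeSeries(
                    data=np.asarray(g["data"]),
                    nuisance=np.asarray(g["nuisance"]),
                    events=events,
                    roi_masks=_read_roi_masks(g),
                    tr_seconds=float(g.attrs["tr_seconds"]),
                    run_id=run_id,
                    spike_log=spikes,
                )
            )
        reports = None
        if "reports_json" in f.attrs:
            reports = pd.read_json(StringIO(str(f.attrs["reports_json"])), orient="records")
    return runs, reports


def save_sampleset(path: str | Path, ss: SampleSet) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        f.create_dataset("X", data=ss.X)
        f.create_dataset(
            "labels", data=np.array([";".join(ls) for ls in ss.labels], dtype=_STR)
        )
        f.attrs["mode"] = ss.mode
        f.attrs["meta_json"] = ss.sample_meta.to_json(orient="records")
        _write_roi_masks(f, ss.roi_masks)


def load_sampleset(path: str | Path) -> SampleSet:
    with h5py.File(path, "r") as f:
        return SampleSet(
            X=np.asarray(f["X"]),
            labels=[tuple(s.split(";")) for s in np.asarray(f["labels"]).astype(str)],
            sample_meta=pd.read_json(StringIO(str(f.attrs["meta_json"])), orient="records"),
            roi_masks=_read_roi_masks(f),
            mode=str(f.attrs["mode"]),
        )


def save_decoder_bank(path: str | Path, bank: DecoderBank) -> None:
    """Weights stored as sparse (unit, voxel, weight) triplets plus per-unit
    normalisation constants and JSON metadata."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    triplets, norms = [], {}
    for unit_id, dec in bank.decoders.items():
        for vox, w in zip(dec.selected_voxels, dec.weights):
            if w != 0.0:
                triplets.append((unit_id, int(vox), float(w)))
        norms[unit_id] = {
            "selected_voxels": [int(v) for v in dec.selected_voxels],
            "voxel_mean": dec.train_voxel_mean.tolist(),
            "voxel_sd": dec.train_voxel_sd.tolist(),
            "target_mean": dec.train_target_mean,
            "target_sd": dec.train_target_sd,
            "bias": dec.bias,
            "converged": dec.converged,
            "n_iterations": dec.n_iterations,
        }
    with h5py.File(path, "w") as f:
        f.create_dataset(
            "weight_unit", data=np.array([t[0] for t in triplets], dtype=_STR)
        )
        f.create_dataset("weight_voxel", data=np.array([t[1] for t in triplets], np.int64))
        f.create_dataset("weight_value", data=np.array([t[2] for t in triplets]))
        f.attrs["meta_json"] = json.dumps(
            {
                "layer_id": bank.layer_id,
                "roi": bank.roi,
                "unit_ids": bank.unit_ids,
                "skipped_units": bank.skipped_units,
                "n_voxels": bank.n_voxels,
                "norms": norms,
            }
        )


def load_decoder_bank(path: str | Path) -> DecoderBank:
    with h5py.File(path, "r") as f:
        meta = json.loads(f.attrs["meta_json"])
        w_unit = np.asarray(f["weight_unit"]).astype(str)
        w_vox = np.asarray(f["weight_voxel"])
        w_val = np.asarray(f["weight_value"])
    decoders = {}
    for unit_id, nm in meta["norms"].items():
        sel = np.asarray(nm["selected_voxels"], np.int64)
        weights = np.zeros(len(sel))
        mask = w_unit == unit_id
        pos = {int(v): i for i, v in enumerate(sel)}
        for vox, val in zip(w_vox[mask], w_val[mask]):
            weights[pos[int(vox)]] = val
        decoders[unit_id] = UnitDecoder(
            unit_id=unit_id,
            roi=meta["roi"],
            selected_voxels=sel,
            weights=weights,
            bias=float(nm["bias"]),
            train_voxel_mean=np.asarray(nm["voxel_mean"]),
            train_voxel_sd=np.asarray(nm["voxel_sd"]),
            train_target_mean=float(nm["target_mean"]),
            train_target_sd=float(nm["target_sd"]),
            converged=bool(nm["converged"]),
            n_iterations=int(nm["n_iterations"]),
        )
    return DecoderBank(
        layer_id=int(meta["layer_id"]),
        roi=meta["roi"],
        unit_ids=list(meta["unit_ids"]),
        decoders=decoders,
        skipped_units=list(meta["skipped_units"]),
        n_voxels=int(meta["n_voxels"]),
    )


def write_manifest(outdir: str | Path, extra: dict | None = None) -> Path:
    """Record every file under ``outdir`` with its SHA-256 checksum."""
    outdir = Path(outdir)
    entries = {}
    for p in sorted(outdir.rglob("*")):
        if p.is_file() and p.name != "manifest.json":
            entries[str(p.relative_to(outdir))] = hashlib.sha256(
                p.read_bytes()
            ).hexdigest()
    manifest = {"files": entries}
    if extra:
        manifest.update(extra)
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path
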