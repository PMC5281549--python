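"""Synthetic encoding-model generator.

Produces the three ingredients the decoding analyses need, with the
statistical structure the pipeline assumes:

* **layered feature tables** — per layer, a prototype vector per object
  category plus exemplar scatter scaled so that the expected
  exemplar-to-prototype correlation equals that layer's *invariance*
  target (rising with depth, like the category invariance of a deep
  network's layers);
* **a linear encoding model** — each ROI's voxels respond to a mixture of
  layers, with the mixture peaked at progressively higher layers along the
  visual hierarchy (V1 -> low layers, LOC/FFA/PPA -> high layers);
* **run-structured sessions** — perception (3-volume stimulus blocks),
  imagery (5-volume blocks), and sleep runs in which the multi-category
  dream content signal occupies only the final seconds before each
  awakening, on top of a stable BOLD baseline, linear drift,
  motion-correlated nuisance, occasional logged spikes and Gaussian noise.

Everything is deterministic under ``SimConfig.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import VC, SimConfig

__all__ = [
    "Event",
    "FeatureTable",
    "EncodingModel",
    "RunTimeSeries",
    "make_feature_tables",
    "make_encoding_model",
    "simulate_perception_session",
    "simulate_imagery_session",
    "simulate_dream_session",
]


@dataclass
class Event:
    """One labelled epoch inside a run (volume units)."""

    onset: int
    duration: int
    labels: tuple[str, ...]
    kind: str  # stimulus | imagery | awakening
    exemplar: int | None = None  # row index into the layer FeatureTable


@dataclass
class FeatureTable:
    """Exemplar-level feature values for one layer (exemplars x units)."""

    layer_id: int
    unit_ids: np.ndarray
    values: np.ndarray
    exemplar_category: np.ndarray

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature values must be finite")
        if len(self.exemplar_category) != self.values.shape[0]:
            raise ValueError("one category label per exemplar row required")

    @property
    def n_units(self) -> int:
        return self.values.shape[1]

    def rows_for_category(self, category: str) -> np.ndarray:
        return np.flatnonzero(self.exemplar_category == category)


@dataclass
class EncodingModel:
    """Linear feature-to-voxel map with an ROI-to-layer affinity gradient."""

    rois: tuple[str, ...]
    layer_affinity: dict[str, np.ndarray]  # roi -> (n_layers,), rows sum to 1
    weights: dict[tuple[str, int], np.ndarray]  # (roi, layer) -> units x voxels
    signal_sd: dict[str, np.ndarray]  # roi -> per-voxel signal SD (training set)
    n_voxels: dict[str, int]

    def __post_init__(self) -> None:
        for roi, aff in self.layer_affinity.items():
            if not np.isclose(aff.sum(), 1.0, atol=1e-12):
                raise ValueError(f"layer affinity for {roi} must sum to 1")
        for key, w in self.weights.items():
            if not np.all(np.isfinite(w)):
                raise ValueError(f"non-finite encoding weights for {key}")

    def response(self, features_by_layer: dict[int, np.ndarray], roi: str) -> np.ndarray:
        """Noiseless voxel response of one ROI to per-layer feature rows.

        ``features_by_layer[L]`` is (n, units); the result is (n, voxels),
        the affinity-weighted sum of per-layer linear projections.
        """
        aff = self.layer_affinity[roi]
        out = np.zeros((next(iter(features_by_layer.values())).shape[0], self.n_voxels[roi]))
        for layer_id, feats in features_by_layer.items():
            a = aff[layer_id]
            if a > 0:
                out += a * (feats @ self.weights[(roi, layer_id)])
        return out


@dataclass
class RunTimeSeries:
    """One run of voxel amplitudes with nuisance regressors and events."""

    data: np.ndarray  # volumes x voxels (all ROIs concatenated)
    nuisance: np.ndarray  # volumes x 7 (linear trend + 6 motion series)
    events: list[Event]
    roi_masks: dict[str, np.ndarray]
    tr_seconds: float
    run_id: str = "run"
    spike_log: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        T = self.data.shape[0]
        for ev in self.events:
            if ev.onset < 0 or ev.onset + max(ev.duration, 0) > T:
                raise ValueError(f"event window outside run: {ev}")
        atomic = [r for r in self.roi_masks if r != VC]
        all_idx = np.concatenate([self.roi_masks[r] for r in atomic]) if atomic else np.array([])
        if len(all_idx) != len(set(all_idx.tolist())):
            raise ValueError("atomic ROI masks must be disjoint")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[0]


# ---------------------------------------------------------------------------
# feature tables


def _scatter_sd(invariance: float) -> float:
    """Scatter SD giving expected exemplar<->prototype correlation = invariance.

    With unit-variance prototypes z and exemplar x = z + sigma*eps, the
    correlation across units is 1/sqrt(1+sigma^2); solving gives
    sigma = sqrt(1-rho^2)/rho. rho = 0 degenerates to pure scatter.
    """
    if invariance >= 1:
        raise ValueError("invariance must be < 1 (zero scatter is degenerate)")
    if invariance < 0:
        raise ValueError("invariance must be >= 0")
    if invariance == 0:
        return np.inf
    return float(np.sqrt(1.0 - invariance**2) / invariance)


def make_feature_tables(config: SimConfig) -> list[FeatureTable]:
    """Generate one exemplar-level feature table per layer.

    Per layer, each category gets an i.i.d. standard-normal prototype over
    the layer's units; exemplars are prototype + isotropic Gaussian scatter
    whose scale realises the layer's invariance target. Categories are
    partitioned into training / test / dream-base / extra-candidate sets by
    name (see :class:`SimConfig`).
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    cats = config.all_categories()
    n_cat, n_ex, U = len(cats), config.exemplars_per_category, config.units_per_layer
    tables = []
    for layer in range(config.n_layers):
        sigma = _scatter_sd(config.invariance_profile[layer])
        protos = rng.standard_normal((n_cat, U))
        eps = rng.standard_normal((n_cat * n_ex, U))
        if np.isinf(sigma):
            values = eps
        else:
            values = np.repeat(protos, n_ex, axis=0) + sigma * eps
        tables.append(
            FeatureTable(
                layer_id=layer,
                unit_ids=np.array([f"L{layer}u{j:05d}" for j in range(U)]),
                values=values,
                exemplar_category=np.repeat(np.array(cats), n_ex),
            )
        )
    return tables


def category_prototypes(config: SimConfig, layer: int) -> tuple[np.ndarray, list[str]]:
    """Ground-truth prototypes of one layer (categories x units), for tests.

    Re-draws with the same generator stream as :func:`make_feature_tables`.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    cats = config.all_categories()
    n_cat, n_ex, U = len(cats), config.exemplars_per_category, config.units_per_layer
    protos = None
    for lyr in range(layer + 1):
        protos = rng.standard_normal((n_cat, U))
        rng.standard_normal((n_cat * n_ex, U))
    return protos, cats


# ---------------------------------------------------------------------------
# encoding model


def _affinity_matrix(n_rois: int, n_layers: int, tau: float = 0.6) -> np.ndarray:
    """Rows: per-ROI distribution over layers, peak position increasing with
    ROI rank so the first ROI prefers the lowest layer and the last the
    highest (the hierarchy homology the decoding analysis probes)."""
    rows = []
    for i in range(n_rois):
        pref = i * (n_layers - 1) / max(n_rois - 1, 1)
        w = np.exp(-0.5 * ((np.arange(n_layers) - pref) / tau) ** 2)
        rows.append(w / w.sum())
    return np.array(rows)


def make_encoding_model(config: SimConfig, tables: list[FeatureTable]) -> EncodingModel:
    if not config.rois:
        raise ValueError("ROI list is empty")
    if len(tables) != config.n_layers:
        raise ValueError("need one feature table per layer")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    aff = _affinity_matrix(len(config.rois), config.n_layers)
    layer_affinity = {roi: aff[i] for i, roi in enumerate(config.rois)}
    weights = {}
    for roi in config.rois:
        V = config.n_voxels_per_roi[roi]
        for t in tables:
            # 1/sqrt(U) scaling keeps per-layer projections O(1) per voxel
            weights[(roi, t.layer_id)] = rng.standard_normal((t.n_units, V)) / np.sqrt(
                t.n_units
            )
    model = EncodingModel(
        rois=tuple(config.rois),
        layer_affinity=layer_affinity,
        weights=weights,
        signal_sd={},
        n_voxels={roi: config.n_voxels_per_roi[roi] for roi in config.rois},
    )
    # empirical per-voxel signal scale over the training exemplars; used to
    # set session noise so that snr = signal SD / noise SD
    train_rows = np.flatnonzero(
        np.isin(tables[0].exemplar_category, config.train_categories())
    )
    feats = {t.layer_id: t.values[train_rows] for t in tables}
    for roi in config.rois:
        resp = model.response(feats, roi)
        sd = resp.std(axis=0)
        model.signal_sd[roi] = np.maximum(sd, 1e-12)
    return model


# ---------------------------------------------------------------------------
# session scaffolding


def _roi_masks(config: SimConfig) -> dict[str, np.ndarray]:
    masks, start = {}, 0
    for roi in config.rois:
        V = config.n_voxels_per_roi[roi]
        masks[roi] = np.arange(start, start + V)
        start += V
    masks[VC] = np.arange(0, start)
    return masks


def _stimulus_response(
    model: EncodingModel, config: SimConfig, tables: list[FeatureTable], rows: np.ndarray
) -> np.ndarray:
    """Concatenated all-ROI response to the given exemplar rows (n x voxels)."""
    feats = {t.layer_id: t.values[rows] for t in tables}
    return np.concatenate([model.response(feats, roi) for roi in config.rois], axis=1)


def _prototype_response(
    model: EncodingModel, config: SimConfig, protos_by_layer: dict[int, np.ndarray]
) -> np.ndarray:
    return np.concatenate(
        [model.response(protos_by_layer, roi) for roi in config.rois], axis=1
    )


def _noise_sd_vector(model: EncodingModel, config: SimConfig, snr: float) -> np.ndarray:
    sd = np.concatenate([model.signal_sd[roi] for roi in config.rois])
    if np.isinf(snr):
        return np.zeros_like(sd)
    return sd / snr


def _assemble_run(
    signal: np.ndarray,
    events: list[Event],
    config: SimConfig,
    model: EncodingModel,
    snr: float,
    rng: np.random.Generator,
    run_id: str,
    baseline: float,
    drift: bool = True,
    spikes: bool = True,
) -> RunTimeSeries:
    """Add baseline, drift, motion-coupled nuisance, spikes and noise to a
    noiseless signal matrix (T x voxels) and wrap it as a run."""
    T, V = signal.shape
    sig_sd = np.concatenate([model.signal_sd[roi] for roi in config.rois])
    t = np.arange(T, dtype=float)
    motion = np.cumsum(rng.normal(0.0, 0.02, size=(T, 6)), axis=0)
    nuisance = np.column_stack([t, motion])

    data = signal + baseline
    if drift:
        slope = rng.normal(0.0, config.drift_fraction, size=V) * sig_sd / max(T - 1, 1)
        data = data + np.outer(t, slope)
    coupling = rng.normal(0.0, config.motion_coupling_fraction, size=(6, V)) * sig_sd
    data = data + motion @ coupling
    noise_sd = _noise_sd_vector(model, config, snr)
    if noise_sd.any():
        data = data + rng.normal(0.0, 1.0, size=(T, V)) * noise_sd

    spike_log: list[tuple[int, int]] = []
    if spikes and config.spike_rate > 0:
        pre_sd = np.maximum(data.std(axis=0), 1e-12)
        n_spk = rng.binomial(T * V, config.spike_rate)
        for _ in range(n_spk):
            vol = int(rng.integers(T))
            vox = int(rng.integers(V))
            sign = 1.0 if rng.random() < 0.5 else -1.0
            data[vol, vox] += sign * config.spike_amplitude_sd * pre_sd[vox]
            spike_log.append((vol, vox))

    return RunTimeSeries(
        data=data,
        nuisance=nuisance,
        events=events,
        roi_masks=_roi_masks(config),
        tr_seconds=config.tr_seconds,
        run_id=run_id,
        spike_log=spike_log,
    )


_REST_EDGE = 4  # rest volumes at each end of a block run


def _block_run_signal(
    responses: np.ndarray, block_volumes: int, gap_volumes: int, shift: int, T: int
) -> tuple[np.ndarray, list[int]]:
    """Place per-block responses into a run; returns (signal, onsets)."""
    n_blocks, V = responses.shape
    signal = np.zeros((T, V))
    onsets = []
    vol = _REST_EDGE
    for b in range(n_blocks):
        onsets.append(vol)
        lo = vol + shift
        signal[lo : lo + block_volumes] += responses[b]
        vol += block_volumes + gap_volumes
    return signal, onsets


def simulate_perception_session(
    config: SimConfig,
    tables: list[FeatureTable],
    model: EncodingModel,
    session: str = "train",
) -> list[RunTimeSeries]:
    """Perception runs: 3-volume (9 s) stimulus blocks.

    ``session='train'`` presents every training exemplar exactly once
    (150 categories x 8 exemplars = 1200 stimulus events at defaults);
    ``session='test'`` presents one fixed exemplar ("the test image") of
    each test category ``test_repetitions`` times.
    """
    if session not in ("train", "test"):
        raise ValueError("session must be 'train' or 'test'")
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, 3 if session == "train" else 4])
    )
    cats0 = tables[0].exemplar_category
    if session == "train":
        rows = np.flatnonzero(np.isin(cats0, config.train_categories()))
        rows = rng.permutation(rows)
    else:
        first_rows = [
            int(tables[0].rows_for_category(c)[0]) for c in config.test_categories()
        ]
        rows = np.array(first_rows * config.test_repetitions)
        rows = rng.permutation(rows)
    if rows.size == 0:
        raise ValueError("no exemplars available for requested session")

    block_vol = int(round(9.0 / config.tr_seconds))
    shift = config.hemodynamic_shift_volumes
    per_run = config.blocks_per_run
    runs = []
    for r0 in range(0, len(rows), per_run):
        chunk = rows[r0 : r0 + per_run]
        T = 2 * _REST_EDGE + len(chunk) * block_vol + shift
        resp = _stimulus_response(model, config, tables, chunk)
        signal, onsets = _block_run_signal(resp, block_vol, 0, shift, T)
        events = [
            Event(
                onset=o,
                duration=block_vol,
                labels=(str(cats0[row]),),
                kind="stimulus",
                exemplar=int(row),
            )
            for o, row in zip(onsets, chunk)
        ]
        runs.append(
            _assemble_run(
                signal,
                events,
                config,
                model,
                config.snr_perception,
                rng,
                run_id=f"{session}_run{r0 // per_run:03d}",
                baseline=config.baseline_amplitude,
            )
        )
    return runs


def simulate_imagery_session(
    config: SimConfig, tables: list[FeatureTable], model: EncodingModel
) -> list[RunTimeSeries]:
    """Imagery runs: 5-volume (15 s) imagery blocks separated by cue /
    evaluation / rest volumes that carry no category signal. Imagined
    content is the category prototype (subjects imagine the category, not a
    particular exemplar); each test category recurs ``imagery_repetitions``
    times.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 5]))
    test_cats = config.test_categories()
    order = np.array(test_cats * config.imagery_repetitions)
    order = rng.permutation(order)

    # per-category prototype proxy: mean of that category's exemplars
    cat_rows = {c: tables[0].rows_for_category(c) for c in test_cats}
    proto_by_layer = {
        t.layer_id: np.stack([t.values[cat_rows[c]].mean(axis=0) for c in test_cats])
        for t in tables
    }
    cat_index = {c: i for i, c in enumerate(test_cats)}
    responses_all = _prototype_response(model, config, proto_by_layer)

    block_vol = int(round(15.0 / config.tr_seconds))
    cue, evaluation, rest = 1, 1, 1  # one volume each at tr=3
    shift = config.hemodynamic_shift_volumes
    per_run = config.imagery_blocks_per_run
    stride = cue + block_vol + evaluation + rest
    runs = []
    for r0 in range(0, len(order), per_run):
        chunk = order[r0 : r0 + per_run]
        T = 2 * _REST_EDGE + len(chunk) * stride + shift
        signal = np.zeros((T, model_total_voxels(model)))
        events = []
        vol = _REST_EDGE
        for c in chunk:
            onset = vol + cue  # imagery period starts after the cue volume
            lo = onset + shift
            signal[lo : lo + block_vol] += responses_all[cat_index[c]]
            events.append(
                Event(onset=onset, duration=block_vol, labels=(str(c),), kind="imagery")
            )
            vol += stride
        runs.append(
            _assemble_run(
                signal,
                events,
                config,
                model,
                config.snr_imagery,
                rng,
                run_id=f"imagery_run{r0 // per_run:03d}",
                baseline=config.baseline_amplitude,
            )
        )
    return runs


def model_total_voxels(model: EncodingModel) -> int:
    return sum(model.n_voxels[r] for r in model.rois)


# ---------------------------------------------------------------------------
# dream session

#: fixed sleep-run layout (volumes at tr=3): the awakening falls at volume 38,
#: leaving the 60-90 s pre-awakening baseline window (volumes 18-28) and a
#: wide margin for sliding-window analyses on both sides.
DREAM_PRE_VOLUMES = 38
DREAM_POST_VOLUMES = 10


def _draw_report_sets(config: SimConfig, rng: np.random.Generator) -> list[tuple[str, ...]]:
    """Label sets of 1-3 base categories per awakening, then deterministic
    top-up so every base category reaches ``base_category_min_reports``."""
    base = config.base_categories()
    lo, hi = config.report_set_size_range
    sets: list[set[str]] = []
    for _ in range(config.n_awakenings):
        k = int(rng.integers(lo, hi + 1))
        sets.append(set(rng.choice(base, size=k, replace=False).tolist()))
    counts = {c: sum(c in s for s in sets) for c in base}
    need = config.base_category_min_reports
    for c in base:
        i = 0
        while counts[c] < need:
            if i >= len(sets):
                raise RuntimeError("cannot satisfy base-category minimum reports")
            if c not in sets[i] and len(sets[i]) < hi:
                sets[i].add(c)
                counts[c] += 1
            i += 1
    return [tuple(sorted(s)) for s in sets]


def simulate_dream_session(
    config: SimConfig, tables: list[FeatureTable], model: EncodingModel
) -> tuple[list[RunTimeSeries], pd.DataFrame]:
    """Sleep runs, one awakening per run, plus the report table.

    Each awakening is labelled by 1-3 base categories. The dream-content
    signal — the encoding response to the *mean of the labelled categories'
    prototype features* — occupies only the final ``dream_content_window_s``
    before the awakening; the preceding minutes carry baseline, drift,
    nuisance and noise only. The report table records awakening id, run,
    awakening volume and the label set (semicolon separated).
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 6]))
    label_sets = _draw_report_sets(config, rng)

    base = config.base_categories()
    cat_rows = {c: tables[0].rows_for_category(c) for c in base}
    proto_by_layer = {
        t.layer_id: np.stack([t.values[cat_rows[c]].mean(axis=0) for c in base])
        for t in tables
    }
    base_index = {c: i for i, c in enumerate(base)}
    proto_resp = _prototype_response(model, config, proto_by_layer)  # base x voxels

    content_vol = int(round(config.dream_content_window_s / config.tr_seconds))
    A = DREAM_PRE_VOLUMES
    T = DREAM_PRE_VOLUMES + DREAM_POST_VOLUMES
    if A - int(round(90.0 / config.tr_seconds)) < 0:
        raise ValueError("run too short to host the 60-90 s baseline window")

    runs, records = [], []
    for i, labels in enumerate(label_sets):
        mix = np.mean([proto_resp[base_index[c]] for c in labels], axis=0)
        signal = np.zeros((T, proto_resp.shape[1]))
        signal[A - content_vol : A] = mix
        events = [Event(onset=A, duration=0, labels=labels, kind="awakening")]
        run = _assemble_run(
            signal,
            events,
            config,
            model,
            config.snr_dream,
            rng,
            run_id=f"dream_run{i:03d}",
            baseline=config.baseline_amplitude,
        )
        runs.append(run)
        records.append(
            {
                "awakening_id": i,
                "run": run.run_id,
                "volume": A,
                "labels": ";".join(labels),
                "sleep_stage_eligible": True,
            }
        )
    return runs, pd.DataFrame.from_records(records)
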