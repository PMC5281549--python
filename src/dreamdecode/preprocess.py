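"""Run-level preprocessing and sample construction.

Fixed pipeline order per dataset style:

* perception / imagery: nuisance regression (constant + linear trend +
  6 motion series) -> despiking -> 1-volume hemodynamic shift -> block
  averaging (3 volumes for 9-s stimulus blocks, 5 for 15-s imagery blocks),
  optionally followed by per-category averaging of test blocks;
* dream: nuisance regression (trend + motion, no constant) -> despiking ->
  normalisation against the 60-90 s pre-awakening baseline -> 3-volume
  (9 s) windows ending at the awakening (shiftable for time-course
  analysis), optionally followed by per-category averaging across
  awakenings that report the same category.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .simulate import RunTimeSeries

logger = logging.getLogger(__name__)

__all__ = [
    "SampleSet",
    "regress_out_nuisance",
    "despike",
    "normalize_dream_baseline",
    "make_dream_samples",
    "average_dream_samples_by_category",
    "make_block_samples",
    "preprocess_block_runs",
    "preprocess_dream_runs",
]


@dataclass
class SampleSet:
    """Preprocessed samples (samples x voxels) with labels and provenance.

    ``mode='single'``: exactly one category label per sample.
    ``mode='multi'``: one or more labels per sample (dream reports).
    """

    X: np.ndarray
    labels: list[tuple[str, ...]]
    sample_meta: pd.DataFrame
    roi_masks: dict[str, np.ndarray]
    mode: str

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.X)):
            raise ValueError("sample matrix contains non-finite values")
        if len(self.labels) != self.X.shape[0]:
            raise ValueError("one label set per sample required")
        for ls in self.labels:
            if self.mode == "single" and len(ls) != 1:
                raise ValueError("single-category mode requires exactly one label")
            if len(ls) < 1:
                raise ValueError("every sample needs at least one label")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    def roi_view(self, roi: str) -> np.ndarray:
        return self.X[:, self.roi_masks[roi]]


# ---------------------------------------------------------------------------
# run-level steps


def regress_out_nuisance(run: RunTimeSeries, include_constant: bool = True) -> RunTimeSeries:
    """Replace each voxel series by its OLS residual against the nuisance
    design (linear trend + 6 motion series, plus a constant when requested).

    Residuals are orthogonal to every regressor by construction. A
    rank-deficient design is rejected with the offending columns named.
    """
    cols = ["trend"] + [f"motion{j}" for j in range(1, run.nuisance.shape[1])]
    X = run.nuisance
    if include_constant:
        X = np.column_stack([np.ones(run.n_volumes), X])
        cols = ["constant"] + cols
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify columns that add no rank
        bad = []
        kept = np.zeros((X.shape[0], 0))
        for j in range(X.shape[1]):
            trial = np.column_stack([kept, X[:, j]])
            if np.linalg.matrix_rank(trial) == kept.shape[1]:
                bad.append(cols[j])
            else:
                kept = trial
        raise ValueError(f"rank-deficient nuisance design; collinear columns: {bad}")
    beta, *_ = np.linalg.lstsq(X, run.data, rcond=None)
    resid = run.data - X @ beta
    return replace(run, data=resid)


def despike(run: RunTimeSeries, k_sd: float = 3.0) -> RunTimeSeries:
    """Clip each voxel's series to mean +/- ``k_sd`` SD (statistics computed
    once per run, before clipping). Zero-variance voxels pass through."""
    if run.n_volumes < 2:
        raise ValueError("despiking needs at least 2 volumes")
    mean = run.data.mean(axis=0)
    sd = run.data.std(axis=0)
    lo = mean - k_sd * sd
    hi = mean + k_sd * sd
    clipped = np.clip(run.data, lo, hi)
    keep = sd == 0
    if keep.any():
        clipped[:, keep] = run.data[:, keep]
    return replace(run, data=clipped)


def normalize_dream_baseline(
    run: RunTimeSeries,
    awakening_volume: int,
    baseline_window_s: tuple[float, float] = (60.0, 90.0),
    mode: str = "subtract",
) -> RunTimeSeries:
    """Express a sleep run's amplitudes relative to the mean over the
    pre-awakening baseline window (default 60-90 s before the awakening).

    ``mode='subtract'`` (default) subtracts the per-voxel baseline mean;
    ``mode='divide'`` computes percent change relative to it.
    """
    if mode not in ("subtract", "divide"):
        raise ValueError("mode must be 'subtract' or 'divide'")
    tr = run.tr_seconds
    near_s, far_s = baseline_window_s
    lo = awakening_volume - int(round(far_s / tr))
    hi = awakening_volume - int(round(near_s / tr))
    if lo < 0 or hi <= lo:
        raise ValueError(
            f"baseline window [{far_s},{near_s}] s before volume "
            f"{awakening_volume} does not fit in the run"
        )
    base = run.data[lo:hi].mean(axis=0)
    if mode == "subtract":
        data = run.data - base
    else:
        safe = np.where(base == 0, 1.0, base)
        data = 100.0 * (run.data - base) / safe
    return replace(run, data=data)


# ---------------------------------------------------------------------------
# sample construction


def _window_volumes(
    awakening_volume: int, offset_s: float, window_s: float, tr: float
) -> tuple[int, int]:
    """Volume range [lo, hi) of the window of ``window_s`` ending at
    (awakening + offset_s); offset 0 gives the volumes immediately before
    the awakening."""
    n = int(round(window_s / tr))
    shift = int(round(offset_s / tr))
    hi = awakening_volume + shift
    return hi - n, hi


def make_dream_samples(
    runs: list[RunTimeSeries],
    reports: pd.DataFrame,
    window_center_offset_s: float = 0.0,
    window_s: float = 9.0,
) -> SampleSet:
    """One multi-category sample per eligible awakening: the mean over the
    3-volume (9 s) window ending at awakening + offset; labels are the full
    report set. Windows falling outside their run are dropped and logged.
    """
    by_id = {r.run_id: r for r in runs}
    rows, labels, meta = [], [], []
    eligible = reports
    if "sleep_stage_eligible" in reports.columns:
        eligible = reports[reports["sleep_stage_eligible"].astype(bool)]
    for rec in eligible.itertuples(index=False):
        run = by_id[rec.run]
        lo, hi = _window_volumes(
            int(rec.volume), window_center_offset_s, window_s, run.tr_seconds
        )
        if lo < 0 or hi > run.n_volumes or hi <= lo:
            logger.warning(
                "awakening %s: window [%d,%d) outside run %s; dropped",
                rec.awakening_id,
                lo,
                hi,
                rec.run,
            )
            continue
        rows.append(run.data[lo:hi].mean(axis=0))
        labels.append(tuple(str(rec.labels).split(";")))
        meta.append(
            {
                "run": rec.run,
                "awakening_id": rec.awakening_id,
                "window_offset_s": window_center_offset_s,
            }
        )
    if not rows:
        raise ValueError("no dream samples could be constructed")
    return SampleSet(
        X=np.stack(rows),
        labels=labels,
        sample_meta=pd.DataFrame(meta),
        roi_masks=runs[0].roi_masks,
        mode="multi",
    )


def average_dream_samples_by_category(samples: SampleSet) -> SampleSet:
    """Single-category samples: for each category that appears in any
    report set, the mean over all awakening samples containing it (other
    co-reported categories are disregarded). One output row per category.
    """
    if samples.mode != "multi":
        raise ValueError("expected multi-category dream samples")
    cats = sorted({c for ls in samples.labels for c in ls})
    rows, labels, meta = [], [], []
    for c in cats:
        idx = [i for i, ls in enumerate(samples.labels) if c in ls]
        if not idx:  # pragma: no cover - cats built from labels
            logger.warning("category %s has no occurrences; excluded", c)
            continue
        rows.append(samples.X[idx].mean(axis=0))
        labels.append((c,))
        meta.append({"category": c, "n_awakenings": len(idx)})
    return SampleSet(
        X=np.stack(rows),
        labels=labels,
        sample_meta=pd.DataFrame(meta),
        roi_masks=samples.roi_masks,
        mode="single",
    )


def make_block_samples(
    runs: list[RunTimeSeries],
    kind: str,
    shift_volumes: int = 1,
    average_by_category: bool = False,
) -> SampleSet:
    """One sample per stimulus/imagery block: the mean over the block's
    volumes after shifting by ``shift_volumes`` (hemodynamic delay). With
    ``average_by_category`` the blocks of the same category are further
    averaged (test-session and imagery evaluation style)."""
    if kind not in ("perception", "imagery"):
        raise ValueError("kind must be 'perception' or 'imagery'")
    want = "stimulus" if kind == "perception" else "imagery"
    rows, labels, meta = [], [], []
    for run in runs:
        for ev in run.events:
            if ev.kind != want:
                continue
            lo = ev.onset + shift_volumes
            hi = lo + ev.duration
            if hi > run.n_volumes or lo < 0:
                logger.warning(
                    "block at volume %d in %s extends past run end after shift; dropped",
                    ev.onset,
                    run.run_id,
                )
                continue
            rows.append(run.data[lo:hi].mean(axis=0))
            labels.append(ev.labels)
            meta.append(
                {"run": run.run_id, "onset": ev.onset, "exemplar": ev.exemplar}
            )
    if not rows:
        raise ValueError("no blocks found")
    ss = SampleSet(
        X=np.stack(rows),
        labels=labels,
        sample_meta=pd.DataFrame(meta),
        roi_masks=runs[0].roi_masks,
        mode="single",
    )
    if average_by_category:
        cats = sorted({ls[0] for ls in ss.labels})
        X = np.stack(
            [
                ss.X[[i for i, ls in enumerate(ss.labels) if ls[0] == c]].mean(axis=0)
                for c in cats
            ]
        )
        ss = SampleSet(
            X=X,
            labels=[(c,) for c in cats],
            sample_meta=pd.DataFrame({"category": cats}),
            roi_masks=ss.roi_masks,
            mode="single",
        )
    return ss


# ---------------------------------------------------------------------------
# composed per-dataset pipelines (the fixed order)


def preprocess_block_runs(
    runs: list[RunTimeSeries],
    kind: str,
    shift_volumes: int = 1,
    average_by_category: bool = False,
    k_sd: float = 3.0,
) -> SampleSet:
    """Nuisance regression (with constant) -> despike -> block samples."""
    cleaned = [despike(regress_out_nuisance(r, include_constant=True), k_sd) for r in runs]
    return make_block_samples(cleaned, kind, shift_volumes, average_by_category)


def preprocess_dream_runs(
    runs: list[RunTimeSeries],
    reports: pd.DataFrame,
    window_center_offset_s: float = 0.0,
    window_s: float = 9.0,
    baseline_mode: str = "subtract",
    k_sd: float = 3.0,
) -> SampleSet:
    """Nuisance regression (no constant) -> despike -> per-awakening
    baseline normalisation -> windowed multi-category samples."""
    by_run = {rec.run: int(rec.volume) for rec in reports.itertuples(index=False)}
    cleaned = []
    kept_reports = []
    for r in runs:
        step = despike(regress_out_nuisance(r, include_constant=False), k_sd)
        try:
            step = normalize_dream_baseline(step, by_run[r.run_id], mode=baseline_mode)
        except ValueError:
            logger.warning("run %s: baseline window missing; awakening skipped", r.run_id)
            continue
        cleaned.append(step)
        kept_reports.append(r.run_id)
    reports = reports[reports["run"].isin(kept_reports)]
    return make_dream_samples(cleaned, reports, window_center_offset_s, window_s)
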