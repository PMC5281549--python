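"""End-to-end orchestration of the synthetic dream-decoding experiment.

``run_experiment`` composes the whole chain — simulate sessions, preprocess
into samples, build category features, train a decoder bank per
layer x ROI, decode the dream / perception / imagery test sets, score and
pool per-unit accuracies, run zero-shot pairwise identification, and trace
the awakening-locked time course — and writes tidy CSV results plus a
checksummed manifest. Stages are also exposed individually so a downstream
stage can be re-run from on-disk artifacts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import VC, PipelineConfig
from .decoding import DecoderBank, predict_features, train_decoder_bank
from .evaluation import pool_and_test, reference_matrix, time_course, unitwise_correlation
from .features import CategoryFeatureSet, build_single_category_features, subsample_units
from .identification import identify_all
from .preprocess import (
    SampleSet,
    average_dream_samples_by_category,
    preprocess_block_runs,
    preprocess_dream_runs,
)
from .simulate import (
    EncodingModel,
    FeatureTable,
    RunTimeSeries,
    make_encoding_model,
    make_feature_tables,
    simulate_dream_session,
    simulate_imagery_session,
    simulate_perception_session,
)

logger = logging.getLogger(__name__)

__all__ = ["ExperimentData", "ExperimentResults", "simulate_stage", "run_experiment"]


@dataclass
class ExperimentData:
    """All simulated and preprocessed inputs of one experiment."""

    tables: list[FeatureTable]
    model: EncodingModel
    train_runs: list[RunTimeSeries]
    test_runs: list[RunTimeSeries]
    dream_runs: list[RunTimeSeries]
    reports: pd.DataFrame
    imagery_runs: list[RunTimeSeries]
    train_samples: SampleSet = None
    test_samples: SampleSet = None
    dream_multi: SampleSet = None
    dream_single: SampleSet = None
    imagery_samples: SampleSet = None
    cfs_by_layer: dict[int, CategoryFeatureSet] = field(default_factory=dict)


@dataclass
class ExperimentResults:
    unit_accuracies: pd.DataFrame
    cell_summaries: pd.DataFrame
    identification: pd.DataFrame
    identification_summary: pd.DataFrame
    timecourse: pd.DataFrame | None
    banks: dict[tuple[int, str], DecoderBank]


def simulate_stage(config: PipelineConfig) -> ExperimentData:
    sim = config.sim
    tables = [
        subsample_units(t, min(sim.units_per_layer, t.n_units), seed=sim.seed + t.layer_id)
        for t in make_feature_tables(sim)
    ]
    model = make_encoding_model(sim, tables)
    train_runs = simulate_perception_session(sim, tables, model, "train")
    test_runs = simulate_perception_session(sim, tables, model, "test")
    dream_runs, reports = simulate_dream_session(sim, tables, model)
    imagery_runs = (
        simulate_imagery_session(sim, tables, model) if config.include_imagery else []
    )
    return ExperimentData(
        tables=tables,
        model=model,
        train_runs=train_runs,
        test_runs=test_runs,
        dream_runs=dream_runs,
        reports=reports,
        imagery_runs=imagery_runs,
    )


def preprocess_stage(config: PipelineConfig, data: ExperimentData) -> ExperimentData:
    shift = config.sim.hemodynamic_shift_volumes
    data.train_samples = preprocess_block_runs(data.train_runs, "perception", shift)
    data.test_samples = preprocess_block_runs(
        data.test_runs, "perception", shift, average_by_category=True
    )
    data.dream_multi = preprocess_dream_runs(
        data.dream_runs, data.reports, baseline_mode=config.baseline_mode
    )
    data.dream_single = average_dream_samples_by_category(data.dream_multi)
    if data.imagery_runs:
        data.imagery_samples = preprocess_block_runs(
            data.imagery_runs, "imagery", shift, average_by_category=True
        )
    return data


def feature_stage(config: PipelineConfig, data: ExperimentData) -> ExperimentData:
    data.cfs_by_layer = {
        t.layer_id: build_single_category_features(t) for t in data.tables
    }
    return data


def train_stage(
    config: PipelineConfig,
    data: ExperimentData,
    layers: list[int] | None = None,
    rois: list[str] | None = None,
) -> dict[tuple[int, str], DecoderBank]:
    """One decoder bank per (layer, ROI) cell, including the union ROI."""
    if layers is None:
        layers = [t.layer_id for t in data.tables]
    if rois is None:
        rois = list(config.sim.rois) + [VC]
    banks = {}
    for layer_id in layers:
        table = data.tables[layer_id]
        for roi in rois:
            banks[(layer_id, roi)] = train_decoder_bank(
                data.train_samples,
                table,
                roi,
                config.screening_cap(roi),
                config.ard,
                use_abs=config.screen_by_abs,
            )
    return banks


def _dataset_samples(data: ExperimentData) -> dict[str, tuple[SampleSet, str]]:
    out = {"perception": (data.test_samples, "single"), "dream": (data.dream_single, "single")}
    out["dream_single_trial"] = (data.dream_multi, "multi")
    if data.imagery_samples is not None:
        out["imagery"] = (data.imagery_samples, "single")
    return out


def evaluate_stage(
    config: PipelineConfig,
    data: ExperimentData,
    banks: dict[tuple[int, str], DecoderBank],
    subject_id: str = "sim",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-unit accuracies and pooled cell summaries for every dataset."""
    accs = []
    for dataset, (samples, _) in _dataset_samples(data).items():
        for (layer_id, roi), bank in banks.items():
            cfs = data.cfs_by_layer[layer_id]
            decoded = predict_features(bank, samples)
            ref = reference_matrix(samples, cfs)
            acc = unitwise_correlation(
                decoded, ref, bank.unit_ids, layer_id, roi, subject_id
            )
            acc.insert(0, "dataset", dataset)
            accs.append(acc)
    unit_acc = pd.concat(accs, ignore_index=True)
    summaries = []
    for dataset, grp in unit_acc.groupby("dataset", sort=True):
        cells = pool_and_test(grp, ("layer", "roi"))
        cells.insert(0, "dataset", dataset)
        summaries.append(cells)
    return unit_acc, pd.concat(summaries, ignore_index=True)


def identification_stage(
    config: PipelineConfig,
    data: ExperimentData,
    banks: dict[tuple[int, str], DecoderBank],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise identification per dataset x layer x ROI against the
    candidate pool (training categories excluded; zero-shot)."""
    pool_cats = config.sim.candidate_categories()
    tables_rows, summary_rows = [], []
    datasets = {
        "dream": data.dream_single,
        "perception": data.test_samples,
    }
    if data.imagery_samples is not None:
        datasets["imagery"] = data.imagery_samples
    for dataset, samples in datasets.items():
        truths = [ls[0] for ls in samples.labels]
        for (layer_id, roi), bank in banks.items():
            cfs = data.cfs_by_layer[layer_id]
            candidates = cfs.subset(pool_cats)
            decoded = predict_features(bank, samples)
            keep = ~np.any(np.isnan(decoded), axis=1)
            if not keep.all():
                decoded = np.nan_to_num(decoded)  # skipped-unit columns
            table, summary = identify_all(
                decoded, truths, candidates, dataset=dataset, layer_id=layer_id, roi=roi
            )
            tables_rows.append(table)
            summary_rows.append(summary)
    return (
        pd.concat(tables_rows, ignore_index=True),
        pd.DataFrame(summary_rows),
    )


def run_experiment(
    config: PipelineConfig, outdir: str | Path | None = None
) -> ExperimentResults:
    """Execute the full synthetic experiment; optionally write results.

    With ``outdir`` set, writes ``unit_accuracies.csv``,
    ``cell_summaries.csv``, ``identification.csv``,
    ``identification_summary.csv``, ``timecourse.csv`` and a checksummed
    ``manifest.json``. Two runs under the same config are byte-identical.
    """
    from .config import config_to_yaml
    from .io import write_manifest

    stage = "simulate"
    try:
        data = simulate_stage(config)
        stage = "preprocess"
        data = preprocess_stage(config, data)
        stage = "features"
        data = feature_stage(config, data)
        stage = "train"
        banks = train_stage(config, data)
        stage = "evaluate"
        unit_acc, cells = evaluate_stage(config, data, banks)
        stage = "identify"
        ident, ident_summary = identification_stage(config, data, banks)
        stage = "timecourse"
        tc = None
        if config.include_timecourse:
            roi = config.timecourse_roi
            tc_banks = {
                layer_id: bank for (layer_id, r), bank in banks.items() if r == roi
            }
            if not tc_banks:
                raise ValueError(f"no decoder banks trained for ROI {roi!r}")
            tc = time_course(
                data.dream_runs,
                data.reports,
                tc_banks,
                data.cfs_by_layer,
                config.timecourse_offsets_s,
                window_s=config.sim.dream_content_window_s,
                baseline_mode=config.baseline_mode,
            )
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    results = ExperimentResults(
        unit_accuracies=unit_acc,
        cell_summaries=cells,
        identification=ident,
        identification_summary=ident_summary,
        timecourse=tc,
        banks=banks,
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "config.yaml").write_text(config_to_yaml(config))
        unit_acc.to_csv(outdir / "unit_accuracies.csv", index=False)
        cells.to_csv(outdir / "cell_summaries.csv", index=False)
        ident.to_csv(outdir / "identification.csv", index=False)
        ident_summary.to_csv(outdir / "identification_summary.csv", index=False)
        if tc is not None:
            tc.to_csv(outdir / "timecourse.csv", index=False)
        write_manifest(outdir, extra={"seed": config.sim.seed})
    return results
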