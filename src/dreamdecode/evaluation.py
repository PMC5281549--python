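"""Decoding-accuracy evaluation.

Accuracy is measured *per feature unit*: the Pearson correlation between
the series of decoded values and the series of reference (category or
multi-category) feature values across test samples. A per-sample
vector-wise correlation would be inflated by the baseline amplitude
pattern across units, since the unit decoders are trained independently —
hence the per-unit series convention.

Unit-level correlations are pooled across units (and subjects) per
layer x ROI cell, Fisher-Z transformed (z = atanh r) and tested against
zero with a one-sided one-sample t-test; cell summaries report the plain
mean of r with a 95% CI across units.

The awakening-locked time course re-windows the dream runs on an offset
grid, decodes each window, and traces mean accuracy per offset in both the
averaged-trial (single-category) and single-trial (multi-category) modes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .decoding import DecoderBank, predict_features
from .features import CategoryFeatureSet, build_multi_category_feature
from .preprocess import (
    SampleSet,
    average_dream_samples_by_category,
    make_dream_samples,
)
from .simulate import RunTimeSeries

logger = logging.getLogger(__name__)

__all__ = [
    "unitwise_correlation",
    "pool_and_test",
    "reference_matrix",
    "time_course",
    "ATANH_CLAMP",
]

#: clamp applied to |r| before atanh so that z stays finite
ATANH_CLAMP = 1e-7


def unitwise_correlation(
    decoded: np.ndarray,
    reference: np.ndarray,
    unit_ids: list[str],
    layer_id: int,
    roi: str,
    subject_id: str = "sim",
) -> pd.DataFrame:
    """Per-unit Pearson r down the sample series.

    ``decoded`` and ``reference`` are (samples x units) in matching order.
    Units with zero variance in either series (or NaN decoded columns from
    skipped units) are dropped and logged. Requires >= 3 samples.
    """
    if decoded.shape != reference.shape:
        raise ValueError("decoded and reference shapes differ")
    n = decoded.shape[0]
    if n < 3:
        raise ValueError("need at least 3 samples for a correlation series")
    finite = ~np.any(np.isnan(decoded), axis=0)
    d = np.where(finite, decoded, 0.0)
    d = d - d.mean(axis=0)
    f = reference - reference.mean(axis=0)
    sd_d = np.sqrt((d**2).mean(axis=0))
    sd_f = np.sqrt((f**2).mean(axis=0))
    ok = finite & (sd_d > 0) & (sd_f > 0)
    n_bad = int((~ok).sum())
    if n_bad:
        logger.info("dropping %d zero-variance/undecoded units", n_bad)
    r = np.full(decoded.shape[1], np.nan)
    r[ok] = (d[:, ok] * f[:, ok]).mean(axis=0) / (sd_d[ok] * sd_f[ok])
    r = np.clip(r, -1.0, 1.0)
    return pd.DataFrame(
        {
            "unit_id": np.asarray(unit_ids)[ok],
            "layer": layer_id,
            "roi": roi,
            "subject": subject_id,
            "r": r[ok],
            "n_samples": n,
        }
    )


def pool_and_test(
    accuracies: pd.DataFrame, group_cols: tuple[str, ...] = ("layer", "roi")
) -> pd.DataFrame:
    """Cell summaries: mean r, 95% CI across pooled units, and a one-sided
    one-sample t-test of Fisher-Z transformed r > 0.

    Units from multiple subjects are pooled by concatenation before the
    test. |r| values of exactly 1 are clamped to 1 - 1e-7 (logged) so that
    atanh stays finite; a zero-variance cell is flagged and reported with
    p -> 0 (mean z > 0) or p = 1.
    """
    rows = []
    for key, grp in accuracies.groupby(list(group_cols), sort=True):
        r = grp["r"].to_numpy(float)
        if len(r) < 2:
            raise ValueError(f"cell {key}: need >= 2 units to pool")
        n_clamped = int((np.abs(r) >= 1.0 - ATANH_CLAMP).sum())
        if n_clamped:
            logger.info("cell %s: clamped %d |r|~1 values before atanh", key, n_clamped)
        z = np.arctanh(np.clip(r, -1 + ATANH_CLAMP, 1 - ATANH_CLAMP))
        degenerate = np.isclose(z.std(ddof=1), 0.0)
        if degenerate:
            t = np.inf if z.mean() > 0 else (-np.inf if z.mean() < 0 else 0.0)
            p = 0.0 if z.mean() > 0 else 1.0
        else:
            t, p = stats.ttest_1samp(z, 0.0, alternative="greater")
        mean_r = float(r.mean())
        half = 1.96 * r.std(ddof=1) / np.sqrt(len(r))
        rows.append(
            dict(
                zip(group_cols, key if isinstance(key, tuple) else (key,)),
                mean_r=mean_r,
                ci_lo=mean_r - half,
                ci_hi=mean_r + half,
                t=float(t),
                p_one_sided=float(min(max(p, 0.0), 1.0)) if p > 0 else 0.0,
                n_units_pooled=len(r),
                degenerate_variance=bool(degenerate),
            )
        )
    return pd.DataFrame(rows)


def reference_matrix(
    samples: SampleSet, cfs: CategoryFeatureSet
) -> np.ndarray:
    """Reference feature rows aligned with a sample set: the single-category
    vector for single-label samples, the multi-category mean otherwise."""
    return np.stack([build_multi_category_feature(cfs, ls) for ls in samples.labels])


def time_course(
    runs: list[RunTimeSeries],
    reports: pd.DataFrame,
    banks: dict[int, DecoderBank],
    cfs_by_layer: dict[int, CategoryFeatureSet],
    offsets_s: tuple[float, ...],
    window_s: float = 9.0,
    baseline_mode: str = "subtract",
    subject_id: str = "sim",
) -> pd.DataFrame:
    """Awakening-locked sliding-window accuracy (no hemodynamic correction).

    For each offset the dream windows are rebuilt ending at
    awakening + offset, decoded with each layer's bank, and scored in both
    modes: ``averaged`` (per-category averaged samples vs single-category
    features) and ``single`` (per-awakening samples vs multi-category
    features). Offsets where more than half the awakenings lose their
    window are marked missing (NaN mean r).
    """
    from .preprocess import despike, normalize_dream_baseline, regress_out_nuisance

    by_run = {rec.run: int(rec.volume) for rec in reports.itertuples(index=False)}
    cleaned = []
    for r in runs:
        step = despike(regress_out_nuisance(r, include_constant=False))
        step = normalize_dream_baseline(step, by_run[r.run_id], mode=baseline_mode)
        cleaned.append(step)

    n_awake = len(reports)
    rows = []
    for off in offsets_s:
        try:
            multi = make_dream_samples(cleaned, reports, off, window_s)
        except ValueError:
            multi = None
        if multi is None or multi.n_samples < 0.5 * n_awake:
            for layer_id in banks:
                for mode in ("averaged", "single"):
                    rows.append(
                        {"offset_s": off, "mode": mode, "layer": layer_id,
                         "mean_r": np.nan, "n_units": 0, "missing": True}
                    )
            continue
        single = average_dream_samples_by_category(multi)
        for layer_id, bank in banks.items():
            cfs = cfs_by_layer[layer_id]
            for mode, ss in (("averaged", single), ("single", multi)):
                decoded = predict_features(bank, ss)
                ref = reference_matrix(ss, cfs)
                acc = unitwise_correlation(
                    decoded, ref, bank.unit_ids, layer_id, bank.roi, subject_id
                )
                rows.append(
                    {
                        "offset_s": off,
                        "mode": mode,
                        "layer": layer_id,
                        "mean_r": float(acc["r"].mean()) if len(acc) else np.nan,
                        "n_units": len(acc),
                        "missing": False,
                    }
                )
    return pd.DataFrame(rows)
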