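"""Experiment configuration objects.

Two levels: :class:`SimConfig` parameterises the synthetic encoding-model
generator (layer count, category partition, ROI geometry, SNRs, session
layout), and :class:`PipelineConfig` wraps it together with preprocessing,
decoding, evaluation and identification settings for a full experiment.

All randomness downstream flows from ``SimConfig.seed`` through a
``numpy.random.SeedSequence`` split per stage, so one integer pins the
whole experiment.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import yaml

DEFAULT_ROIS = ("V1", "V2", "V3", "V4", "LOC", "FFA", "PPA")
#: name of the derived union ROI (all atomic ROIs combined)
VC = "VC"


def _default_invariance(n_layers: int) -> tuple[float, ...]:
    # within-category exemplar/prototype correlation rising with depth,
    # emulating increasing invariance along a feature hierarchy
    return tuple(np.round(np.linspace(0.2, 0.9, n_layers), 6))


@dataclass
class SimConfig:
    """Parameters of the synthetic experiment generator.

    Counts mirror the source study's design: 150 training categories with
    8 exemplars each (1200 training stimuli), 50 held-out test categories,
    a large candidate pool for zero-shot identification, 1000 feature units
    per layer, and sleep sessions with >= ``n_awakenings`` awakenings whose
    base categories each recur in at least ``base_category_min_reports``
    reports.
    """

    n_layers: int = 8
    units_per_layer: int = 1000
    n_train_categories: int = 150
    exemplars_per_category: int = 8
    n_test_categories: int = 50
    n_base_categories: int = 20
    n_candidate_categories: int = 1000
    rois: tuple[str, ...] = DEFAULT_ROIS
    n_voxels_per_roi: dict[str, int] = field(default_factory=dict)
    invariance_profile: tuple[float, ...] = ()
    snr_perception: float = 0.5
    snr_imagery: float = 0.25
    snr_dream: float = 0.12
    tr_seconds: float = 3.0
    hemodynamic_shift_volumes: int = 1
    dream_content_window_s: float = 9.0
    n_awakenings: int = 200
    base_category_min_reports: int = 10
    report_set_size_range: tuple[int, int] = (1, 3)
    test_repetitions: int = 35
    imagery_repetitions: int = 10
    blocks_per_run: int = 50
    imagery_blocks_per_run: int = 25
    # nuisance/noise shape parameters (fractions of per-voxel signal SD)
    baseline_amplitude: float = 100.0
    drift_fraction: float = 0.3
    motion_coupling_fraction: float = 0.3
    spike_rate: float = 1e-4
    spike_amplitude_sd: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.invariance_profile:
            self.invariance_profile = _default_invariance(self.n_layers)
        if not self.n_voxels_per_roi:
            self.n_voxels_per_roi = {roi: 500 for roi in self.rois}
        self.rois = tuple(self.rois)
        self.invariance_profile = tuple(float(v) for v in self.invariance_profile)
        self.report_set_size_range = tuple(self.report_set_size_range)
        self.validate()

    def validate(self) -> None:
        counts = {
            "n_layers": self.n_layers,
            "units_per_layer": self.units_per_layer,
            "n_train_categories": self.n_train_categories,
            "exemplars_per_category": self.exemplars_per_category,
            "n_test_categories": self.n_test_categories,
            "n_base_categories": self.n_base_categories,
            "n_candidate_categories": self.n_candidate_categories,
            "n_awakenings": self.n_awakenings,
            "base_category_min_reports": self.base_category_min_reports,
            "hemodynamic_shift_volumes": self.hemodynamic_shift_volumes + 1,
        }
        for name, v in counts.items():
            if v <= 0:
                raise ValueError(f"{name} must be positive, got {v}")
        for name in ("snr_perception", "snr_imagery", "snr_dream", "tr_seconds"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not self.rois:
            raise ValueError("ROI list is empty")
        if len(self.invariance_profile) != self.n_layers:
            raise ValueError(
                f"invariance_profile has {len(self.invariance_profile)} entries "
                f"for {self.n_layers} layers"
            )
        prof = np.asarray(self.invariance_profile)
        if np.any(prof < 0) or np.any(prof >= 1):
            raise ValueError("invariance values must lie in [0, 1)")
        if np.any(np.diff(prof) < 0):
            raise ValueError("invariance_profile must be non-decreasing across layers")
        if self.n_test_categories + self.n_base_categories > self.n_candidate_categories:
            raise ValueError("candidate pool must contain the test and base categories")
        if set(self.n_voxels_per_roi) != set(self.rois):
            raise ValueError("n_voxels_per_roi keys must match rois")
        lo, hi = self.report_set_size_range
        if not (1 <= lo <= hi):
            raise ValueError("report_set_size_range must satisfy 1 <= lo <= hi")
        if hi > self.n_base_categories:
            raise ValueError("report sets cannot exceed the number of base categories")
        need = self.n_base_categories * self.base_category_min_reports
        if self.n_awakenings * hi < need:
            raise ValueError(
                f"{self.n_awakenings} awakenings with <= {hi} labels cannot give "
                f"{self.n_base_categories} base categories >= "
                f"{self.base_category_min_reports} reports each"
            )

    # -- category partition -------------------------------------------------
    def train_categories(self) -> list[str]:
        return [f"trn{i:04d}" for i in range(self.n_train_categories)]

    def candidate_categories(self) -> list[str]:
        """Candidate pool for zero-shot identification (disjoint from training)."""
        return [f"cnd{i:05d}" for i in range(self.n_candidate_categories)]

    def test_categories(self) -> list[str]:
        return self.candidate_categories()[: self.n_test_categories]

    def base_categories(self) -> list[str]:
        """Dream-report base categories; drawn from the candidate pool but
        disjoint from the test categories."""
        lo = self.n_test_categories
        return self.candidate_categories()[lo : lo + self.n_base_categories]

    def all_categories(self) -> list[str]:
        return self.train_categories() + self.candidate_categories()

    def total_voxels(self) -> int:
        return sum(self.n_voxels_per_roi[r] for r in self.rois)


@dataclass
class ArdSettings:
    """Hyperparameters of the evidence-maximisation ARD regression."""

    max_iterations: int = 500
    tol: float = 1e-6
    alpha_init: float = 1.0
    noise_precision_init: float | None = None  # None -> 1/var(y)
    prune_threshold: float = 1e10

    def __post_init__(self) -> None:
        if self.max_iterations <= 0 or self.tol <= 0 or self.alpha_init <= 0:
            raise ValueError("ArdSettings values must be positive")
        if self.noise_precision_init is not None and self.noise_precision_init <= 0:
            raise ValueError("noise_precision_init must be positive")
        if self.prune_threshold <= 0:
            raise ValueError("prune_threshold must be positive")


@dataclass
class PipelineConfig:
    """Full experiment configuration: simulator + analysis settings."""

    sim: SimConfig = field(default_factory=SimConfig)
    ard: ArdSettings = field(default_factory=ArdSettings)
    baseline_mode: str = "subtract"  # or "divide"
    screening_cap_atomic: int = 500
    screening_cap_vc: int = 1000
    screen_by_abs: bool = True
    alpha_levels: tuple[float, ...] = (0.01, 0.05)
    timecourse_offsets_s: tuple[float, ...] = tuple(float(o) for o in range(-36, 21, 3))
    include_imagery: bool = True
    include_timecourse: bool = True
    timecourse_roi: str = VC

    def __post_init__(self) -> None:
        if self.baseline_mode not in ("subtract", "divide"):
            raise ValueError("baseline_mode must be 'subtract' or 'divide'")
        if self.screening_cap_atomic <= 0 or self.screening_cap_vc <= 0:
            raise ValueError("screening caps must be positive")
        self.alpha_levels = tuple(self.alpha_levels)
        self.timecourse_offsets_s = tuple(self.timecourse_offsets_s)

    def screening_cap(self, roi: str) -> int:
        return self.screening_cap_vc if roi == VC else self.screening_cap_atomic


_KNOWN = {
    "sim": SimConfig,
    "ard": ArdSettings,
}


def _to_plain(obj):
    if dataclasses.is_dataclass(obj):
        return {k: _to_plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, Mapping):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, tuple):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def config_to_yaml(cfg: PipelineConfig) -> str:
    return yaml.safe_dump(_to_plain(cfg), sort_keys=True)


def _build(cls, data: Mapping):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    kwargs = {}
    for k, v in data.items():
        if k in _KNOWN and isinstance(v, Mapping):
            v = _build(_KNOWN[k], v)
        elif isinstance(v, list):
            v = tuple(tuple(x) if isinstance(x, list) else x for x in v)
        kwargs[k] = v
    return cls(**kwargs)


def config_from_yaml(text: str) -> PipelineConfig:
    data = yaml.safe_load(text) or {}
    return _build(PipelineConfig, data)
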