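"""Ready-made experiment configurations.

``desk_config`` is the package's standard reduced-scale synthetic
experiment: 4 ROIs x 4 feature layers with a designed low-to-high
ROI-to-layer affinity gradient, 100 units per layer and 300 voxels per
ROI. It keeps every structural property of the full design (separate
training / test / dream-base category partitions, multi-label sleep
reports, all three session styles) at sizes that train in minutes on one
CPU; the full-scale defaults of :class:`SimConfig` remain available for
larger runs.
"""

from __future__ import annotations

from .config import ArdSettings, PipelineConfig, SimConfig

__all__ = ["desk_config"]


def desk_config(seed: int = 0, **sim_overrides) -> PipelineConfig:
    sim_kwargs = dict(
        n_layers=4,
        units_per_layer=100,
        n_train_categories=50,
        exemplars_per_category=8,
        n_test_categories=25,
        n_base_categories=16,
        n_candidate_categories=200,
        rois=("V1", "V2", "V4", "FFA"),
        n_voxels_per_roi={"V1": 300, "V2": 300, "V4": 300, "FFA": 300},
        invariance_profile=(0.3, 0.5, 0.7, 0.85),
        n_awakenings=200,
        base_category_min_reports=10,
        test_repetitions=10,
        imagery_repetitions=5,
        seed=seed,
    )
    sim_kwargs.update(sim_overrides)
    return PipelineConfig(
        sim=SimConfig(**sim_kwargs),
        ard=ArdSettings(),
        screening_cap_atomic=100,
        screening_cap_vc=200,
        timecourse_offsets_s=tuple(float(o) for o in range(-18, 13, 3)),
    )
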