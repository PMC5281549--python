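import numpy as np
import pytest

from dreamdecode.config import PipelineConfig, SimConfig


def tiny_sim(**overrides) -> SimConfig:
    """Small but fully-featured simulator config for fast tests."""
    kwargs = dict(
        n_layers=2,
        units_per_layer=20,
        n_train_categories=12,
        exemplars_per_category=4,
        n_test_categories=6,
        n_base_categories=4,
        n_candidate_categories=30,
        rois=("V1", "FFA"),
        n_voxels_per_roi={"V1": 30, "FFA": 30},
        invariance_profile=(0.3, 0.8),
        n_awakenings=40,
        base_category_min_reports=4,
        test_repetitions=3,
        imagery_repetitions=2,
        seed=11,
    )
    kwargs.update(overrides)
    return SimConfig(**kwargs)


def clean_sim(**overrides) -> SimConfig:
    """Noise-free variant: no noise, drift, motion coupling, spikes or
    baseline offset, so samples equal encoding responses exactly."""
    kwargs = dict(
        snr_perception=np.inf,
        snr_imagery=np.inf,
        snr_dream=np.inf,
        drift_fraction=0.0,
        motion_coupling_fraction=0.0,
        spike_rate=0.0,
        baseline_amplitude=0.0,
    )
    kwargs.update(overrides)
    return tiny_sim(**kwargs)


@pytest.fixture(scope="session")
def tiny_experiment():
    """Simulated + preprocessed tiny experiment shared across tests."""
    import dreamdecode.pipeline as pl

    cfg = PipelineConfig(
        sim=tiny_sim(),
        screening_cap_atomic=20,
        screening_cap_vc=40,
        include_imagery=True,
    )
    data = pl.simulate_stage(cfg)
    data = pl.preprocess_stage(cfg, data)
    data = pl.feature_stage(cfg, data)
    return cfg, data
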