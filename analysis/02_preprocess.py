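"""Stage 2: preprocess runs into labelled sample matrices.

Perception/imagery runs: nuisance regression (with constant) -> despiking
-> hemodynamically shifted block averages. Sleep runs: nuisance regression
(no constant) -> despiking -> 60-90 s pre-awakening baseline normalisation
-> 3-volume windows ending at each awakening, plus the per-category
averages used by the single-category analysis.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
import common  # noqa: E402

from dreamdecode.io import load_session_bundle, save_sampleset  # noqa: E402
from dreamdecode.preprocess import (  # noqa: E402
    average_dream_samples_by_category,
    preprocess_block_runs,
    preprocess_dream_runs,
)


def main() -> None:
    common.ensure_dirs()
    cfg = common.config()
    shift = cfg.sim.hemodynamic_shift_volumes

    train_runs, _ = load_session_bundle(common.ARTIFACTS / "training.h5")
    test_runs, _ = load_session_bundle(common.ARTIFACTS / "perception_test.h5")
    imagery_runs, _ = load_session_bundle(common.ARTIFACTS / "imagery.h5")
    dream_runs, reports = load_session_bundle(common.ARTIFACTS / "dream.h5")

    train = preprocess_block_runs(train_runs, "perception", shift)
    test = preprocess_block_runs(test_runs, "perception", shift, average_by_category=True)
    imagery = preprocess_block_runs(imagery_runs, "imagery", shift, average_by_category=True)
    dream_multi = preprocess_dream_runs(dream_runs, reports, baseline_mode=cfg.baseline_mode)
    dream_single = average_dream_samples_by_category(dream_multi)

    for name, ss in (
        ("train", train),
        ("perception_test", test),
        ("imagery", imagery),
        ("dream_multi", dream_multi),
        ("dream_single", dream_single),
    ):
        save_sampleset(common.ARTIFACTS / f"samples_{name}.h5", ss)
        common.say(f"{name}: {ss.n_samples} samples x {ss.X.shape[1]} voxels ({ss.mode})")


if __name__ == "__main__":
    main()
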