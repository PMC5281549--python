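"""Stage 1: simulate the synthetic experiment's sessions.

Generates the layered feature tables, the ROI-to-layer encoding model, and
the perception (training + test), imagery and sleep sessions, then writes
the session bundles and the awakening report table.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
import common  # noqa: E402

import dreamdecode.pipeline as pl  # noqa: E402
from dreamdecode.io import save_session_bundle  # noqa: E402


def main() -> None:
    common.ensure_dirs()
    cfg = common.config()
    data = pl.simulate_stage(cfg)

    save_session_bundle(common.ARTIFACTS / "training.h5", data.train_runs)
    save_session_bundle(common.ARTIFACTS / "perception_test.h5", data.test_runs)
    save_session_bundle(common.ARTIFACTS / "imagery.h5", data.imagery_runs)
    save_session_bundle(common.ARTIFACTS / "dream.h5", data.dream_runs, data.reports)
    data.reports.to_csv(common.RESULTS / "dream_reports.csv", index=False)

    n_stim = sum(len(r.events) for r in data.train_runs)
    common.say(
        f"simulated {n_stim} training stimuli across {len(data.train_runs)} runs, "
        f"{len(data.test_runs)} test runs, {len(data.imagery_runs)} imagery runs, "
        f"{len(data.dream_runs)} sleep runs / {len(data.reports)} awakenings"
    )
    counts = (
        data.reports["labels"].str.split(";").explode().value_counts()
    )
    common.say(
        f"base categories: {len(counts)}, report counts "
        f"{counts.min()}..{counts.max()} (all >= "
        f"{cfg.sim.base_category_min_reports})"
    )


if __name__ == "__main__":
    main()
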