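"""Stage 6: awakening-locked time course of dream feature decoding.

Slides the 9-s decoding window around each awakening and traces mean
per-unit accuracy per offset from the union-ROI decoders, in both the
averaged-trial and single-trial modes. The peak is expected in the final
window before awakening, where the simulated dream content lives.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
import common  # noqa: E402

from dreamdecode.config import VC  # noqa: E402
from dreamdecode.evaluation import time_course  # noqa: E402
from dreamdecode.features import build_single_category_features  # noqa: E402
from dreamdecode.io import load_decoder_bank, load_session_bundle  # noqa: E402
from dreamdecode.simulate import make_feature_tables  # noqa: E402


def main() -> None:
    common.ensure_dirs()
    cfg = common.config()
    tables = make_feature_tables(cfg.sim)
    cfs = {t.layer_id: build_single_category_features(t) for t in tables}
    dream_runs, reports = load_session_bundle(common.ARTIFACTS / "dream.h5")
    banks = {
        layer: load_decoder_bank(common.ARTIFACTS / f"bank_L{layer}_{VC}.h5")
        for layer in range(cfg.sim.n_layers)
    }

    tc = time_course(
        dream_runs,
        reports,
        banks,
        cfs,
        cfg.timecourse_offsets_s,
        window_s=cfg.sim.dream_content_window_s,
        baseline_mode=cfg.baseline_mode,
    )
    tc.to_csv(common.RESULTS / "timecourse.csv", index=False)

    for mode in ("averaged", "single"):
        prof = (
            tc[tc["mode"] == mode].groupby("offset_s")["mean_r"].mean().dropna()
        )
        common.say(
            f"{mode}-trial accuracy peaks at offset {prof.idxmax():+.0f} s "
            f"(r = {prof.max():.3f}); window [-9, 0] s holds the content"
        )


if __name__ == "__main__":
    main()
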