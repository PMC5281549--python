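"""Stage 3: train one sparse (ARD) decoder per feature unit.

For every layer x ROI cell (including the union ROI VC), screens voxels by
training-set correlation and fits the per-unit evidence-maximisation ARD
regressors on the 400 training samples. Banks are written to the artifact
store; this is the expensive stage (a few minutes on one CPU).
"""

import sys
import time
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
import common  # noqa: E402

import numpy as np  # noqa: E402

from dreamdecode.config import VC  # noqa: E402
from dreamdecode.decoding import train_decoder_bank  # noqa: E402
from dreamdecode.io import load_sampleset, save_decoder_bank  # noqa: E402
from dreamdecode.simulate import make_feature_tables  # noqa: E402


def main() -> None:
    common.ensure_dirs()
    cfg = common.config()
    tables = make_feature_tables(cfg.sim)
    train = load_sampleset(common.ARTIFACTS / "samples_train.h5")

    for table in tables:
        for roi in list(cfg.sim.rois) + [VC]:
            t0 = time.time()
            bank = train_decoder_bank(
                train, table, roi, cfg.screening_cap(roi), cfg.ard,
                use_abs=cfg.screen_by_abs,
            )
            save_decoder_bank(
                common.ARTIFACTS / f"bank_L{table.layer_id}_{roi}.h5", bank
            )
            n_active = np.median(
                [d.n_active for d in bank.decoders.values()]
            )
            common.say(
                f"layer {table.layer_id} x {roi}: {len(bank)} units trained "
                f"({len(bank.skipped_units)} skipped), median {n_active:.0f} "
                f"surviving voxels, {time.time() - t0:.1f}s"
            )


if __name__ == "__main__":
    main()
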