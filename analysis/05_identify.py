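"""Stage 5: zero-shot pairwise identification of decoded categories.

Matches each dataset's decoded feature vectors against the candidate
category pool by correlation; accuracy is the fraction of true-vs-false
pairs won (chance 0.5). Writes per-category and summary tables and prints
the per-dataset accuracies from the union-ROI (VC) decoders.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
import common  # noqa: E402

import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402

from dreamdecode.config import VC  # noqa: E402
from dreamdecode.decoding import predict_features  # noqa: E402
from dreamdecode.features import build_single_category_features  # noqa: E402
from dreamdecode.identification import identify_all  # noqa: E402
from dreamdecode.io import load_decoder_bank, load_sampleset  # noqa: E402
from dreamdecode.simulate import make_feature_tables  # noqa: E402


def main() -> None:
    common.ensure_dirs()
    cfg = common.config()
    tables = make_feature_tables(cfg.sim)
    pool_cats = cfg.sim.candidate_categories()
    datasets = {
        "dream": load_sampleset(common.ARTIFACTS / "samples_dream_single.h5"),
        "perception": load_sampleset(common.ARTIFACTS / "samples_perception_test.h5"),
        "imagery": load_sampleset(common.ARTIFACTS / "samples_imagery.h5"),
    }

    per_cat, summaries = [], []
    for table in tables:
        candidates = build_single_category_features(table).subset(pool_cats)
        for roi in list(cfg.sim.rois) + [VC]:
            bank = load_decoder_bank(
                common.ARTIFACTS / f"bank_L{table.layer_id}_{roi}.h5"
            )
            for dataset, ss in datasets.items():
                decoded = np.nan_to_num(predict_features(bank, ss))
                tbl, summary = identify_all(
                    decoded,
                    [ls[0] for ls in ss.labels],
                    candidates,
                    dataset=dataset,
                    layer_id=table.layer_id,
                    roi=roi,
                )
                per_cat.append(tbl)
                summaries.append(summary)
    per_cat = pd.concat(per_cat, ignore_index=True)
    summaries = pd.DataFrame(summaries)
    per_cat.to_csv(common.RESULTS / "identification.csv", index=False)
    summaries.to_csv(common.RESULTS / "identification_summary.csv", index=False)

    vc = summaries[summaries.roi == VC].pivot(
        index="layer", columns="dataset", values="mean_accuracy"
    )
    common.say("pairwise identification accuracy from VC (chance = 0.5):")
    common.say(vc.round(3).to_string())


if __name__ == "__main__":
    main()
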