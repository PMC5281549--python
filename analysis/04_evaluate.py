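"""Stage 4: decode the test sets and score per-unit accuracy.

Applies every trained bank to the perception, imagery and dream samples,
correlates decoded unit series with (multi-)category feature values, and
pools units per layer x ROI cell with Fisher-Z one-sided t-tests. Writes
the tidy unit- and cell-level tables and prints the layer x ROI mean-r
matrix, whose diagonal structure is the designed brain-to-feature-layer
homology.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
import common  # noqa: E402

import pandas as pd  # noqa: E402

from dreamdecode.config import VC  # noqa: E402
from dreamdecode.decoding import predict_features  # noqa: E402
from dreamdecode.evaluation import (  # noqa: E402
    pool_and_test,
    reference_matrix,
    unitwise_correlation,
)
from dreamdecode.features import build_single_category_features  # noqa: E402
from dreamdecode.io import load_decoder_bank, load_sampleset  # noqa: E402
from dreamdecode.simulate import make_feature_tables  # noqa: E402


def main() -> None:
    common.ensure_dirs()
    cfg = common.config()
    tables = make_feature_tables(cfg.sim)
    cfs = {t.layer_id: build_single_category_features(t) for t in tables}
    datasets = {
        "perception": load_sampleset(common.ARTIFACTS / "samples_perception_test.h5"),
        "imagery": load_sampleset(common.ARTIFACTS / "samples_imagery.h5"),
        "dream": load_sampleset(common.ARTIFACTS / "samples_dream_single.h5"),
        "dream_single_trial": load_sampleset(common.ARTIFACTS / "samples_dream_multi.h5"),
    }

    accs = []
    for layer in range(cfg.sim.n_layers):
        for roi in list(cfg.sim.rois) + [VC]:
            bank = load_decoder_bank(common.ARTIFACTS / f"bank_L{layer}_{roi}.h5")
            for dataset, ss in datasets.items():
                acc = unitwise_correlation(
                    predict_features(bank, ss),
                    reference_matrix(ss, cfs[layer]),
                    bank.unit_ids,
                    layer,
                    roi,
                )
                acc.insert(0, "dataset", dataset)
                accs.append(acc)
    unit_acc = pd.concat(accs, ignore_index=True)
    cells = []
    for dataset, grp in unit_acc.groupby("dataset", sort=True):
        c = pool_and_test(grp, ("layer", "roi"))
        c.insert(0, "dataset", dataset)
        cells.append(c)
    cells = pd.concat(cells, ignore_index=True)

    # the unit-level table is large and regenerable; it stays with the
    # artifacts, while the pooled summaries go to results/
    unit_acc.to_csv(common.ARTIFACTS / "unit_accuracies.csv", index=False)
    cells.to_csv(common.RESULTS / "cell_summaries.csv", index=False)

    for dataset in datasets:
        m = cells[cells.dataset == dataset].pivot(
            index="layer", columns="roi", values="mean_r"
        )
        common.say(f"\n{dataset}: mean per-unit r by layer x ROI")
        common.say(m.round(3).to_string())
        atoms = [r for r in m.columns if r != VC]
        common.say(f"best ROI per layer: {m[atoms].idxmax(axis=1).tolist()}")


if __name__ == "__main__":
    main()
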