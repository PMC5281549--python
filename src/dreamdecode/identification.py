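"""Zero-shot pairwise category identification.

A decoded feature vector is matched against candidate category feature
vectors by Pearson correlation over the unit dimension: for each false
candidate, the identification is correct iff the true category's vector
correlates more strongly with the decoded vector than the false one does.
Accuracy is the fraction of false candidates beaten; chance is 0.5. The
true category is excluded from the false pool and exact ties count as
incorrect (conservative, deterministic).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .features import CategoryFeatureSet

__all__ = ["IdentificationResult", "pairwise_identify", "identify_all"]


@dataclass
class IdentificationResult:
    test_category: str
    n_pairs: int
    n_correct: int
    accuracy: float
    dataset: str = ""
    layer_id: int = -1
    roi: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.n_correct <= self.n_pairs):
            raise ValueError("n_correct out of range")


def _corr_to_candidates(decoded: np.ndarray, values: np.ndarray) -> np.ndarray:
    """Pearson r of one decoded vector with each candidate row."""
    d = decoded - decoded.mean()
    dsd = d.std()
    if dsd == 0:
        raise ValueError("constant decoded vector: correlations undefined")
    V = values - values.mean(axis=1, keepdims=True)
    vsd = V.std(axis=1)
    vsd = np.where(vsd == 0, np.nan, vsd)
    return (V @ d) / (len(d) * vsd * dsd)


def pairwise_identify(
    decoded: np.ndarray,
    true_cat: str,
    candidates: CategoryFeatureSet,
    true_features: CategoryFeatureSet | None = None,
    dataset: str = "",
    layer_id: int = -1,
    roi: str = "",
) -> IdentificationResult:
    """Score one decoded vector against every false candidate.

    ``true_features`` lets the true category's vector come from a separate
    feature store than the candidate pool (the dream categories' features
    are built from a different image source); by default the candidate set
    itself supplies it.
    """
    decoded = np.asarray(decoded, float)
    if decoded.ndim != 1 or decoded.shape[0] != len(candidates.unit_ids):
        raise ValueError("decoded vector does not match the candidate unit set")
    store = true_features if true_features is not None else candidates
    true_vec = store.row(true_cat)
    r_true = float(_corr_to_candidates(decoded, true_vec[None, :])[0])
    r_false = _corr_to_candidates(decoded, candidates.values)
    mask = np.array([c != true_cat for c in candidates.category_ids])
    r_false = r_false[mask]
    ok = np.isfinite(r_false)
    n_pairs = int(ok.sum())
    n_correct = int((r_true > r_false[ok]).sum())  # ties incorrect
    return IdentificationResult(
        test_category=true_cat,
        n_pairs=n_pairs,
        n_correct=n_correct,
        accuracy=n_correct / n_pairs if n_pairs else np.nan,
        dataset=dataset,
        layer_id=layer_id,
        roi=roi,
    )


def identify_all(
    decoded: np.ndarray,
    truths: list[str],
    candidates: CategoryFeatureSet,
    true_features: CategoryFeatureSet | None = None,
    dataset: str = "",
    layer_id: int = -1,
    roi: str = "",
) -> tuple[pd.DataFrame, dict]:
    """Identification for every test category plus a pooled summary.

    ``decoded`` is (test categories x units), one averaged-trial vector per
    category. The summary carries the mean accuracy across categories and a
    one-sided t-test of per-category accuracies against chance (0.5).
    Constant decoded vectors are reported missing, never imputed.
    """
    if decoded.shape[0] != len(truths):
        raise ValueError("one decoded vector per test category required")
    rows = []
    for i, cat in enumerate(truths):
        try:
            res = pairwise_identify(
                decoded[i], cat, candidates, true_features, dataset, layer_id, roi
            )
            rows.append(vars(res))
        except ValueError:
            rows.append(
                dict(
                    test_category=cat, n_pairs=0, n_correct=0, accuracy=np.nan,
                    dataset=dataset, layer_id=layer_id, roi=roi,
                )
            )
    table = pd.DataFrame(rows)
    acc = table["accuracy"].dropna().to_numpy(float)
    if len(acc) >= 2 and acc.std(ddof=1) > 0:
        t, p = stats.ttest_1samp(acc, 0.5, alternative="greater")
    elif len(acc) >= 1:
        m = acc.mean()
        t = np.inf if m > 0.5 else (-np.inf if m < 0.5 else 0.0)
        p = 0.0 if m > 0.5 else 1.0
    else:
        t, p = np.nan, np.nan
    summary = {
        "dataset": dataset,
        "layer": layer_id,
        "roi": roi,
        "mean_accuracy": float(acc.mean()) if len(acc) else np.nan,
        "t_vs_chance": float(t),
        "p_one_sided": float(p),
        "n_categories": int(len(acc)),
        "n_missing": int(table["accuracy"].isna().sum()),
    }
    return table, summary
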