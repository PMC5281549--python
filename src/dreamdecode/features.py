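"""Category feature vectors and unit subsampling.

A *single-category feature vector* is the arithmetic mean of the feature
vectors of the exemplars belonging to a category, computed per layer on the
raw feature values. A *multi-category feature vector* (used for multi-label
dream reports) is the unweighted mean of the named single-category vectors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .simulate import FeatureTable

__all__ = [
    "CategoryFeatureSet",
    "subsample_units",
    "build_single_category_features",
    "build_multi_category_feature",
    "feature_table_from_extractor",
]


@dataclass
class CategoryFeatureSet:
    """Per-layer category prototype vectors (categories x units)."""

    layer_id: int
    unit_ids: np.ndarray
    values: np.ndarray
    category_ids: list[str]
    n_exemplars: dict[str, int]

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.category_ids), len(self.unit_ids)):
            raise ValueError("values must be categories x units")
        self._index = {c: i for i, c in enumerate(self.category_ids)}

    def row(self, category: str) -> np.ndarray:
        try:
            return self.values[self._index[category]]
        except KeyError:
            raise KeyError(f"unknown category: {category!r}") from None

    def subset(self, categories: list[str]) -> "CategoryFeatureSet":
        rows = np.stack([self.row(c) for c in categories])
        return CategoryFeatureSet(
            layer_id=self.layer_id,
            unit_ids=self.unit_ids,
            values=rows,
            category_ids=list(categories),
            n_exemplars={c: self.n_exemplars[c] for c in categories},
        )


def subsample_units(table: FeatureTable, n: int = 1000, seed: int = 0) -> FeatureTable:
    """Uniform random unit subset without replacement, deterministic under
    ``seed``. A table with exactly ``n`` units passes through unchanged
    (the fully connected top-layer case)."""
    total = table.n_units
    if n > total:
        raise ValueError(f"requested {n} units but table has {total}")
    if n == total:
        return table
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(total, size=n, replace=False))
    return FeatureTable(
        layer_id=table.layer_id,
        unit_ids=table.unit_ids[idx],
        values=table.values[:, idx],
        exemplar_category=table.exemplar_category,
    )


def build_single_category_features(table: FeatureTable) -> CategoryFeatureSet:
    """Average exemplar rows within each category (singletons allowed)."""
    cats = list(dict.fromkeys(table.exemplar_category.tolist()))
    rows, n_ex = [], {}
    for c in cats:
        idx = table.rows_for_category(c)
        rows.append(table.values[idx].mean(axis=0))
        n_ex[c] = len(idx)
    return CategoryFeatureSet(
        layer_id=table.layer_id,
        unit_ids=table.unit_ids,
        values=np.stack(rows),
        category_ids=cats,
        n_exemplars=n_ex,
    )


def build_multi_category_feature(
    cfs: CategoryFeatureSet, labels: tuple[str, ...] | list[str]
) -> np.ndarray:
    """Unweighted mean of the named single-category rows (order-invariant)."""
    if not labels:
        raise ValueError("label set is empty")
    return np.mean([cfs.row(c) for c in labels], axis=0)


def feature_table_from_extractor(
    layer_id: int,
    exemplars: list[tuple[str, str]],
    extractor,
    unit_ids=None,
) -> FeatureTable:
    """Adapter hook: build a :class:`FeatureTable` from an external feature
    source, e.g. a real network's activations.

    ``exemplars`` is a list of ``(exemplar_ref, category)`` pairs (the ref
    is typically an image path); ``extractor`` maps a ref to a 1-D feature
    vector. All vectors must share one length.
    """
    if not exemplars:
        raise ValueError("no exemplars given")
    rows = [np.asarray(extractor(ref), float).ravel() for ref, _ in exemplars]
    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        raise ValueError(f"extractor returned mixed vector lengths: {sorted(lengths)}")
    values = np.stack(rows)
    if unit_ids is None:
        unit_ids = np.array([f"L{layer_id}u{j:05d}" for j in range(values.shape[1])])
    return FeatureTable(
        layer_id=layer_id,
        unit_ids=np.asarray(unit_ids),
        values=values,
        exemplar_category=np.array([c for _, c in exemplars]),
    )
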