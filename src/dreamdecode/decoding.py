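"""Per-unit sparse linear feature decoders.

One decoder per feature unit: correlation-based voxel pre-screening (the
``k`` voxels most correlated with the unit's training values, by |r| by
default), followed by sparse Bayesian linear regression with an automatic
relevance determination (ARD) prior, fitted by evidence maximisation with
MacKay-style fixed-point updates:

    gamma_j = 1 - alpha_j * Sigma_jj
    alpha_j <- gamma_j / mu_j**2
    beta    <- (n - sum_j gamma_j) / ||y - X mu||**2

where mu, Sigma are the posterior mean/covariance of the weights given the
per-weight precisions alpha and noise precision beta. Weights whose
precision exceeds ``prune_threshold`` are pruned to exactly zero, which
performs the voxel selection. Both predictors and targets are standardised
with training statistics (the prior is scale-sensitive); predictions are
mapped back to the original target scale, so the decoder is affine in the
input pattern.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import ArdSettings
from .preprocess import SampleSet
from .simulate import FeatureTable

logger = logging.getLogger(__name__)

__all__ = [
    "UnitDecoder",
    "DecoderBank",
    "select_voxels",
    "fit_ard",
    "train_decoder_bank",
    "predict_features",
]


@dataclass
class UnitDecoder:
    """Trained regression model for one feature unit."""

    unit_id: str
    roi: str
    selected_voxels: np.ndarray  # column indices into the ROI voxel set
    weights: np.ndarray  # standardised-space weights, one per selected voxel
    bias: float  # standardised-space intercept (0 after centring)
    train_voxel_mean: np.ndarray
    train_voxel_sd: np.ndarray
    train_target_mean: float
    train_target_sd: float
    converged: bool
    n_iterations: int
    failed: bool = False

    def predict(self, X_roi: np.ndarray) -> np.ndarray:
        """Affine prediction on the original target scale from ROI columns."""
        Z = (X_roi[:, self.selected_voxels] - self.train_voxel_mean) / self.train_voxel_sd
        yhat_std = Z @ self.weights + self.bias
        return yhat_std * self.train_target_sd + self.train_target_mean

    @property
    def n_active(self) -> int:
        return int(np.count_nonzero(self.weights))


@dataclass
class DecoderBank:
    """All unit decoders of one layer x ROI cell."""

    layer_id: int
    roi: str
    unit_ids: list[str]
    decoders: dict[str, UnitDecoder]
    skipped_units: list[str] = field(default_factory=list)
    n_voxels: int = 0

    def __len__(self) -> int:
        return len(self.decoders)


def select_voxels(
    X: np.ndarray, y: np.ndarray, k: int, use_abs: bool = True
) -> np.ndarray:
    """Indices of the ``k`` voxels most correlated with the target.

    Ranking uses |r| by default (an anticorrelated voxel is equally
    informative for a linear decoder); set ``use_abs=False`` for signed
    ranking. Zero-variance voxels are excluded before ranking; ties break
    by ascending voxel index; if fewer than ``k`` voxels remain, all are
    returned. Output indices are sorted ascending.
    """
    if X.shape[0] < 3:
        raise ValueError("need at least 3 samples for screening")
    if k < 1:
        raise ValueError("k must be >= 1")
    ysd = y.std()
    if ysd == 0:
        raise ValueError("constant target: unit cannot be screened")
    Xc = X - X.mean(axis=0)
    xsd = X.std(axis=0)
    valid = xsd > 0
    r = np.zeros(X.shape[1])
    yc = y - y.mean()
    denom = X.shape[0] * xsd[valid] * ysd
    r[valid] = (Xc[:, valid].T @ yc) / denom
    score = np.abs(r) if use_abs else r
    score[~valid] = -np.inf
    n_valid = int(valid.sum())
    k_eff = min(k, n_valid)
    # stable ranking: sort by (-score, index)
    order = np.lexsort((np.arange(X.shape[1]), -score))
    return np.sort(order[:k_eff])


def fit_ard(
    X_sel: np.ndarray, y: np.ndarray, settings: ArdSettings | None = None
) -> tuple[np.ndarray, dict]:
    """Evidence-maximisation ARD on standardised inputs.

    ``X_sel`` (samples x voxels) and ``y`` must already be standardised
    per-column with training statistics. Returns the full-length weight
    vector (pruned entries exactly zero) and a diagnostics dict with keys
    ``converged``, ``n_iterations``, ``alpha``, ``beta``.
    """
    if settings is None:
        settings = ArdSettings()
    n, p = X_sel.shape
    if n < 2:
        raise ValueError("need at least 2 samples")
    if not (np.all(np.isfinite(X_sel)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite input to ARD fit")

    var_y = float(np.var(y))
    if settings.noise_precision_init is not None:
        beta = settings.noise_precision_init
    elif n > p + 1:
        # initialise the noise level from the OLS residual: starting from
        # 1/var(y) treats all signal variance as noise, over-shrinks the
        # first posterior and prunes dense-truth predictors prematurely
        resid = y - X_sel @ np.linalg.lstsq(X_sel, y, rcond=None)[0]
        beta = (n - p) / max(float(resid @ resid), 1e-12)
    else:
        beta = 1.0 / max(var_y, 1e-12)
    active = np.arange(p)
    alpha = np.full(p, settings.alpha_init)
    mu_full = np.zeros(p)
    converged = False
    it = 0
    BETA_MAX = 1e12

    Xa = X_sel
    gram = Xa.T @ Xa
    Xty = Xa.T @ y
    yty = float(y @ y)

    for it in range(1, settings.max_iterations + 1):
        a = alpha[active]
        G = gram[np.ix_(active, active)]
        A = beta * G + np.diag(a)
        try:
            L = np.linalg.cholesky(A)
            Sigma = np.linalg.inv(L.T) @ np.linalg.inv(L)
        except np.linalg.LinAlgError:
            try:
                Sigma = np.linalg.pinv(A)
            except np.linalg.LinAlgError as exc:  # pragma: no cover
                raise RuntimeError("posterior covariance solve failed") from exc
        mu = beta * Sigma @ Xty[active]
        gamma = 1.0 - a * np.diag(Sigma)
        gamma = np.clip(gamma, 1e-12, None)

        new_alpha = gamma / np.maximum(mu**2, 1e-300)
        rss = yty - 2.0 * mu @ Xty[active] + mu @ (G @ mu)
        rss = max(rss, 0.0)
        denom = max(n - gamma.sum(), 1e-12)
        beta = min(denom / max(rss, denom / BETA_MAX), BETA_MAX)

        alpha[active] = np.minimum(new_alpha, 10 * settings.prune_threshold)
        keep = alpha[active] <= settings.prune_threshold
        prev = mu_full.copy()
        mu_full = np.zeros(p)
        mu_full[active] = np.where(keep, mu, 0.0)
        active = active[keep]

        delta = np.linalg.norm(mu_full - prev)
        scale = max(np.linalg.norm(prev), 1e-12)
        if delta / scale < settings.tol:
            converged = True
            break
        if active.size == 0:
            converged = True
            break

    return mu_full, {
        "converged": converged,
        "n_iterations": it,
        "alpha": alpha,
        "beta": beta,
    }


def _fit_unit(
    X_roi: np.ndarray,
    y: np.ndarray,
    unit_id: str,
    roi: str,
    k: int,
    settings: ArdSettings,
    use_abs: bool,
) -> UnitDecoder:
    sel = select_voxels(X_roi, y, k, use_abs=use_abs)
    Xs = X_roi[:, sel]
    xm = Xs.mean(axis=0)
    xs = Xs.std(axis=0)
    xs = np.where(xs == 0, 1.0, xs)
    ym = float(y.mean())
    ys = float(y.std())
    Z = (Xs - xm) / xs
    w, info = fit_ard(Z, (y - ym) / ys, settings)
    return UnitDecoder(
        unit_id=unit_id,
        roi=roi,
        selected_voxels=sel,
        weights=w,
        bias=0.0,
        train_voxel_mean=xm,
        train_voxel_sd=xs,
        train_target_mean=ym,
        train_target_sd=ys,
        converged=bool(info["converged"]),
        n_iterations=int(info["n_iterations"]),
    )


def train_decoder_bank(
    samples: SampleSet,
    features: FeatureTable,
    roi: str,
    k: int,
    settings: ArdSettings | None = None,
    use_abs: bool = True,
) -> DecoderBank:
    """Train one decoder per feature unit on the training samples.

    Each sample must correspond to one feature-table exemplar row
    (``sample_meta['exemplar']``); targets for unit ``j`` are that unit's
    values at those rows. Units whose target is constant or whose fit fails
    numerically are skipped and logged. Units are independent, so training
    order does not matter.
    """
    if settings is None:
        settings = ArdSettings()
    if "exemplar" not in samples.sample_meta.columns:
        raise ValueError("samples lack exemplar provenance; cannot align features")
    rows = samples.sample_meta["exemplar"].to_numpy()
    if np.any(pd.isna(rows)):
        raise ValueError("some samples have no exemplar row")
    rows = rows.astype(int)
    if rows.max() >= features.values.shape[0]:
        raise ValueError("exemplar row index outside the feature table")
    for i, ls in enumerate(samples.labels):
        if str(features.exemplar_category[rows[i]]) != ls[0]:
            raise ValueError(
                f"sample {i} label {ls[0]} does not match feature row category "
                f"{features.exemplar_category[rows[i]]}"
            )
    X_roi = samples.roi_view(roi)
    Y = features.values[rows]

    decoders: dict[str, UnitDecoder] = {}
    skipped: list[str] = []
    for j, unit_id in enumerate(features.unit_ids):
        y = Y[:, j]
        try:
            decoders[str(unit_id)] = _fit_unit(
                X_roi, y, str(unit_id), roi, k, settings, use_abs
            )
        except (ValueError, RuntimeError) as exc:
            logger.warning("unit %s skipped: %s", unit_id, exc)
            skipped.append(str(unit_id))
    return DecoderBank(
        layer_id=features.layer_id,
        roi=roi,
        unit_ids=[str(u) for u in features.unit_ids],
        decoders=decoders,
        skipped_units=skipped,
        n_voxels=X_roi.shape[1],
    )


def predict_features(bank: DecoderBank, samples: SampleSet) -> np.ndarray:
    """Decoded feature values (samples x units) on the original feature
    scale; skipped units yield NaN columns (excluded downstream)."""
    X_roi = samples.roi_view(bank.roi)
    if X_roi.shape[1] != bank.n_voxels:
        raise ValueError(
            f"ROI voxel dimension mismatch: bank has {bank.n_voxels}, "
            f"samples have {X_roi.shape[1]}"
        )
    out = np.full((samples.n_samples, len(bank.unit_ids)), np.nan)
    for j, unit_id in enumerate(bank.unit_ids):
        dec = bank.decoders.get(unit_id)
        if dec is not None and not dec.failed:
            out[:, j] = dec.predict(X_roi)
    return out
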