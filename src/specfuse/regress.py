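"""Latent-variable calibration: PLS1 via NIPALS and principal component
regression, with grouped cross-validation and the RMSEC/RMSECV/RMSEP/R^2
metric set.

Both fitters take a column-centered predictor matrix and centered response
(the centering vector and response mean live in the returned model, so
prediction on raw spectra replays the full preprocessing chain).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    AlignmentError,
    InvalidInputError,
    RankDeficiencyError,
    UndefinedMetricError,
)
from .preprocess import (
    FusedData,
    PreprocessPipeline,
    PreprocessSpec,
    fuse_blocks,
)
from .synthetic import SpectralBlock

__all__ = [
    "CalibrationModel",
    "FitMetrics",
    "fit_pls",
    "fit_pcr",
    "predict",
    "cross_validate",
    "rmse",
    "r_squared",
    "compute_metrics",
]

_RANK_TOL = 1e-10


@dataclass
class CalibrationModel:
    """A fitted latent-variable calibration.

    ``regression_vector`` maps a centered fused spectrum to the centered
    concentration; ``weights`` is None for PCR. When the preprocessing state
    (spec, masks, centering vector, provenance) is attached, :func:`predict`
    accepts raw spectral blocks.
    """

    method: str  # "PLS" | "PCR"
    n_components: int
    x_loadings: np.ndarray
    x_scores: np.ndarray
    regression_vector: np.ndarray
    weights: np.ndarray | None = None
    y_loadings: np.ndarray | None = None
    x_mean: np.ndarray | None = None
    y_mean: float = 0.0
    preprocess: PreprocessSpec | None = None
    masks: Mapping[str, tuple[float, float] | None] | None = None
    provenance: pd.DataFrame | None = None


@dataclass(frozen=True)
class FitMetrics:
    """Calibration / cross-validation / prediction error summary (mg/mL)."""

    rmsec: float
    rmsecv: float
    rmsep: float
    r2_pred: float

    def __post_init__(self) -> None:
        for name in ("rmsec", "rmsecv", "rmsep"):
            v = getattr(self, name)
            if np.isfinite(v) and v < 0:
                raise InvalidInputError(f"{name} must be >= 0")
        if np.isfinite(self.r2_pred) and self.r2_pred > 1:
            raise InvalidInputError("r2_pred cannot exceed 1")


def _check_centered_inputs(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] != y.size:
        raise InvalidInputError("X must be 2-D with one row per y value")
    return X, y


def fit_pls(X: np.ndarray, y: np.ndarray, n_lv: int) -> CalibrationModel:
    """PLS1 by NIPALS with deflation of X (and y) per component.

    Weight vectors are unit norm and successive score vectors orthogonal.
    For a univariate response each component is closed-form (the NIPALS
    iteration converges in one step). If X deflates to (numerically) zero
    before ``n_lv`` components, the requested dimension exceeds the rank and
    a :class:`RankDeficiencyError` is raised; if instead the residual
    response becomes orthogonal to the deflated X, the remaining components
    carry zero weight and iteration stops early with a zero contribution.
    """
    X, y = _check_centered_inputs(X, y)
    if n_lv < 1:
        raise InvalidInputError("n_lv must be >= 1")
    x_scale = np.linalg.norm(X)
    y_scale = np.linalg.norm(y)

    Xk = X.copy()
    yk = y.copy()
    W, P, T, q = [], [], [], []
    for _ in range(n_lv):
        if np.linalg.norm(Xk) <= _RANK_TOL * max(x_scale, 1.0):
            raise RankDeficiencyError(
                f"n_lv={n_lv} exceeds the rank of X ({len(W)} components fitted)"
            )
        g = Xk.T @ yk
        if np.linalg.norm(g) <= _RANK_TOL * max(x_scale * y_scale, 1.0):
            break  # residual response orthogonal to X: nothing left to model
        w = g / np.linalg.norm(g)
        t = Xk @ w
        tt = float(t @ t)
        p = (Xk.T @ t) / tt
        qk = float(yk @ t) / tt
        Xk -= np.outer(t, p)
        yk = yk - qk * t
        W.append(w)
        P.append(p)
        T.append(t)
        q.append(qk)

    p_feat = X.shape[1]
    if not W:  # y orthogonal to every column of X
        return CalibrationModel(
            method="PLS",
            n_components=n_lv,
            x_loadings=np.zeros((p_feat, 0)),
            x_scores=np.zeros((X.shape[0], 0)),
            regression_vector=np.zeros(p_feat),
            weights=np.zeros((p_feat, 0)),
            y_loadings=np.zeros(0),
        )
    Wm = np.column_stack(W)
    Pm = np.column_stack(P)
    Tm = np.column_stack(T)
    qv = np.asarray(q)
    # Standard closed form: b = W (P' W)^-1 q.
    beta = Wm @ np.linalg.solve(Pm.T @ Wm, qv)
    return CalibrationModel(
        method="PLS",
        n_components=n_lv,
        x_loadings=Pm,
        x_scores=Tm,
        regression_vector=beta,
        weights=Wm,
        y_loadings=qv,
    )


def pls_regression_vectors(X: np.ndarray, y: np.ndarray, n_lv: int) -> np.ndarray:
    """Regression vectors for every component count 1..n_lv (columns).

    One NIPALS pass; used by cross-validation to score all component counts
    without refitting.
    """
    model = fit_pls(X, y, n_lv)
    Wm, Pm, qv = model.weights, model.x_loadings, model.y_loadings
    k_eff = Wm.shape[1]
    p = X.shape[1]
    out = np.zeros((p, n_lv))
    for k in range(1, k_eff + 1):
        out[:, k - 1] = Wm[:, :k] @ np.linalg.solve(
            Pm[:, :k].T @ Wm[:, :k], qv[:k]
        )
    for k in range(k_eff + 1, n_lv + 1):  # early stop: vector frozen
        out[:, k - 1] = out[:, k_eff - 1] if k_eff else 0.0
    return out


def fit_pcr(X: np.ndarray, y: np.ndarray, n_pc: int) -> CalibrationModel:
    """Principal component regression via SVD of the centered X.

    The response is regressed on the first ``n_pc`` score vectors (which are
    orthogonal, so the regression is a per-component projection).
    """
    X, y = _check_centered_inputs(X, y)
    if n_pc < 1:
        raise InvalidInputError("n_pc must be >= 1")
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    rank = int(np.sum(s > _RANK_TOL * (s[0] if s.size else 0.0)))
    if n_pc > rank:
        raise RankDeficiencyError(f"n_pc={n_pc} exceeds rank(X)={rank}")
    T = U[:, :n_pc] * s[:n_pc]
    coefs = (T.T @ y) / s[:n_pc] ** 2
    beta = Vt[:n_pc].T @ coefs
    return CalibrationModel(
        method="PCR",
        n_components=n_pc,
        x_loadings=Vt[:n_pc].T,
        x_scores=T,
        regression_vector=beta,
        y_loadings=coefs,
    )


def predict(
    model: CalibrationModel,
    data: FusedData | Sequence[SpectralBlock] | np.ndarray,
) -> np.ndarray:
    """Predict concentrations (mg/mL) for new data.

    Raw blocks are pushed through the stored preprocessing state (derivative,
    SNV, fusion mask, centering vector); a :class:`FusedData` is assumed
    already derivatized/SNV-normalized but not centered; a bare matrix
    likewise. The feature axis must match the training provenance.
    """
    if isinstance(data, np.ndarray):
        X = np.atleast_2d(np.asarray(data, dtype=float))
    elif isinstance(data, FusedData):
        X = data.X
    else:  # raw spectral blocks
        if model.preprocess is None or model.masks is None:
            raise InvalidInputError(
                "model carries no preprocessing state; pass a matrix instead"
            )
        pp = PreprocessPipeline(model.preprocess)
        blocks = [
            b if b.is_preprocessed else pp.transform_block(b) for b in data
        ]
        fused = fuse_blocks(blocks, model.masks)
        if model.provenance is not None and not np.allclose(
            fused.provenance["value"].to_numpy(),
            model.provenance["value"].to_numpy(),
        ):
            raise AlignmentError("fused axis does not match training provenance")
        X = fused.X
    if X.shape[1] != model.regression_vector.size:
        raise AlignmentError(
            f"feature count {X.shape[1]} does not match model "
            f"({model.regression_vector.size})"
        )
    if model.x_mean is not None:
        X = X - model.x_mean
    return X @ model.regression_vector + model.y_mean


def rmse(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_true.size != y_pred.size:
        raise InvalidInputError("length mismatch")
    if y_true.size < 1:
        raise InvalidInputError("empty input")
    return float(np.sqrt(np.mean((y_pred - y_true) ** 2)))


def r_squared(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_true.size != y_pred.size or y_true.size < 2:
        raise InvalidInputError("need >= 2 paired values")
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    if ss_tot == 0.0:
        raise UndefinedMetricError("R^2 undefined: zero variance in y_true")
    return 1.0 - float(np.sum((y_pred - y_true) ** 2)) / ss_tot


def compute_metrics(
    y_true: np.ndarray, y_pred: np.ndarray, context: str = "prediction"
) -> dict[str, float]:
    """RMSE (always) and R^2 (prediction context) for one y/ŷ pair."""
    if context not in ("calibration", "cv", "prediction"):
        raise InvalidInputError(f"unknown context {context!r}")
    out = {"rmse": rmse(y_true, y_pred)}
    if context == "prediction":
        out["r2"] = r_squared(y_true, y_pred)
    return out


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray,
    method: str = "PLS",
    n_components: int = 10,
    n_splits: int = 10,
) -> np.ndarray:
    """Grouped venetian-blind cross-validation RMSECV per component count.

    Groups (sample ids) are taken in order of first appearance; fold ``j``
    holds out groups ``j, j+n_splits, j+2*n_splits, ...`` so replicate
    spectra of one sample never straddle a fold boundary. Returns an array
    of RMSECV values for 1..n_components.
    """
    X, y = _check_centered_inputs(X, y)
    groups = np.asarray(groups)
    uniq = list(dict.fromkeys(groups.tolist()))
    n_splits = min(n_splits, len(uniq))
    if n_splits < 2:
        raise InvalidInputError("need at least 2 cross-validation folds")

    sq_err = np.zeros(n_components)
    n_total = 0
    for j in range(n_splits):
        held = set(uniq[j::n_splits])
        test = np.asarray([g in held for g in groups])
        train = ~test
        if not test.any():
            continue
        y_train = y[train]
        if np.ptp(y_train) == 0:
            warnings.warn(
                f"degenerate fold {j}: constant response in training part"
            )
        x_mean = X[train].mean(axis=0)
        y_mean = y_train.mean()
        Xt = X[train] - x_mean
        Xv = X[test] - x_mean
        yt = y_train - y_mean
        if method == "PLS":
            betas = pls_regression_vectors(Xt, yt, n_components)
            preds = Xv @ betas + y_mean  # (n_test, n_components)
        elif method == "PCR":
            U, s, Vt = np.linalg.svd(Xt, full_matrices=False)
            rank = int(np.sum(s > _RANK_TOL * s[0]))
            kmax = min(n_components, rank)
            coefs = (U[:, :kmax].T @ yt)  # = s_k * proj coefficients
            betas = np.zeros((X.shape[1], n_components))
            for k in range(1, n_components + 1):
                kk = min(k, kmax)
                betas[:, k - 1] = Vt[:kk].T @ (coefs[:kk] / s[:kk])
            preds = Xv @ betas + y_mean
        else:
            raise InvalidInputError(f"unknown method {method!r}")
        sq_err += np.sum((preds - y[test, None]) ** 2, axis=0)
        n_total += int(test.sum())
    return np.sqrt(sq_err / n_total)
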