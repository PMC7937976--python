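"""Trait prediction from spectra: index-based linear models and PLSR.

Partial least squares regression is fitted with the classical orthogonal-
scores (NIPALS) algorithm on mean-centered data.  The number of latent
components is chosen by exhaustive leave-one-out cross-validation, taking the
count that minimizes the RMSE of the predicted residual sum of squares
(PRESS).  Per-band variable importance in the projection (VIP) summarizes how
much each wavelength contributes to the retained components; the squared VIP
scores average to exactly 1, so VIP > 1 flags above-average importance, and a
single-threshold backward elimination on VIP provides wavelength selection.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PLSRModel",
    "ModelEvaluation",
    "IndexModel",
    "split_train_test",
    "fit_index_model",
    "fit_plsr",
    "select_components",
    "loocv_rmse",
    "vip_scores",
    "vip_feature_selection",
    "evaluate",
]


# --------------------------------------------------------------------------
# Data splitting
# --------------------------------------------------------------------------

def split_train_test(
    table: pd.DataFrame,
    train_fraction: float = 0.8,
    seed: int = 0,
    stratify_column: str = "treatment",
):
    """Stratified random train/test split with an exact global train size.

    The train set holds ``floor(train_fraction * n)`` rows, allocated across
    strata by largest remainder so that e.g. 178 rows split 142/36 and
    111 rows split 88/23.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie in (0, 1)")
    n = len(table)
    if n < 5:
        raise ValueError("need at least 5 rows to split")
    n_train = int(np.floor(train_fraction * n))
    rng = np.random.default_rng(seed)
    if stratify_column in table.columns:
        groups = [np.asarray(idx) for _, idx in table.groupby(stratify_column).groups.items()]
    else:
        groups = [np.asarray(table.index)]
    quotas = np.array([train_fraction * g.size for g in groups])
    base = np.floor(quotas).astype(int)
    short = n_train - base.sum()
    order = np.argsort(-(quotas - base))
    for i in range(short):
        base[order[i % len(groups)]] += 1
    train_idx = []
    for g, k in zip(groups, base):
        perm = rng.permutation(g)
        train_idx.extend(perm[:k])
    train_mask = table.index.isin(train_idx)
    return table[train_mask].copy(), table[~train_mask].copy()


# --------------------------------------------------------------------------
# Index-based linear models
# --------------------------------------------------------------------------

@dataclass
class IndexModel:
    """Ordinary least squares trait = slope * index + intercept."""

    slope: float
    intercept: float
    r_squared: float
    p_value: float
    stderr: float
    n: int

    def predict(self, index_values: np.ndarray) -> np.ndarray:
        return self.slope * np.asarray(index_values, float) + self.intercept


def fit_index_model(index_values: np.ndarray, trait_values: np.ndarray) -> IndexModel:
    x = np.asarray(index_values, dtype=float)
    y = np.asarray(trait_values, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("need at least 3 complete (index, trait) pairs")
    if np.ptp(x) == 0:
        raise ValueError("index is constant; cannot fit")
    res = stats.linregress(x, y)
    return IndexModel(
        float(res.slope), float(res.intercept), float(res.rvalue**2),
        float(res.pvalue), float(res.stderr), int(x.size),
    )


# --------------------------------------------------------------------------
# PLSR (classical orthogonal scores / NIPALS)
# --------------------------------------------------------------------------

@dataclass
class PLSRModel:
    """Fitted PLSR model with per-component-count coefficient paths.

    ``coefficients`` are for the retained ``n_components``; ``coef_path[k]``
    gives the coefficient vector using the first k+1 components, so cheaper
    models can be read off the same fit.  Predictions:
    y = (X - x_mean) @ coefficients + y_mean.
    """

    n_components: int
    x_weights: np.ndarray     # W  (bands x A)
    x_loadings: np.ndarray    # P  (bands x A)
    x_scores: np.ndarray      # T  (n x A)
    y_loadings: np.ndarray    # q  (A,)
    coefficients: np.ndarray  # (bands,)
    coef_path: np.ndarray     # (A, bands)
    x_mean: np.ndarray
    y_mean: float
    wavelengths: np.ndarray | None = None
    vip: np.ndarray | None = None
    cv_rmse: np.ndarray | None = None

    def predict(self, X: np.ndarray, n_components: int | None = None) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if n_components is None:
            beta = self.coefficients
        else:
            beta = self.coef_path[n_components - 1]
        return (X - self.x_mean) @ beta + self.y_mean

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "n_components": self.n_components,
                "coefficients": self.coefficients.tolist(),
                "x_mean": self.x_mean.tolist(),
                "y_mean": self.y_mean,
                "vip": None if self.vip is None else self.vip.tolist(),
                "wavelengths": None
                if self.wavelengths is None
                else np.asarray(self.wavelengths).tolist(),
            },
            indent=2,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload


def fit_plsr(
    X: np.ndarray, y: np.ndarray, n_components: int,
    wavelengths: np.ndarray | None = None,
) -> PLSRModel:
    """NIPALS orthogonal-scores PLSR on mean-centered X and y.

    For a single trait the inner NIPALS loop collapses to one pass per
    component: w_a = X'y (normalized), t_a = X w_a, deflate X by t_a p_a'.
    Coefficients accumulate as B_A = W (P'W)^-1 q over the first A components.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if y.size != n:
        raise ValueError("X and y disagree on the number of observations")
    if np.ptp(y) == 0:
        raise ValueError("zero-variance response")
    if not 1 <= n_components <= min(n - 1, p):
        raise ValueError(
            f"n_components must lie in [1, min(n-1, bands)] = "
            f"[1, {min(n - 1, p)}]"
        )
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    E = X - x_mean
    f = y - y_mean
    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    T = np.zeros((n, n_components))
    q = np.zeros(n_components)
    for a in range(n_components):
        w = E.T @ f
        norm = np.linalg.norm(w)
        if norm < 1e-14:  # response fully deflated; stop early
            W = W[:, :a]; P = P[:, :a]; T = T[:, :a]; q = q[:a]
            n_components = a
            break
        w /= norm
        t = E @ w
        tt = float(t @ t)
        if tt < 1e-14:
            W = W[:, :a]; P = P[:, :a]; T = T[:, :a]; q = q[:a]
            n_components = a
            break
        p_a = E.T @ t / tt
        q_a = float(f @ t / tt)
        E = E - np.outer(t, p_a)
        f = f - q_a * t
        W[:, a], P[:, a], T[:, a], q[a] = w, p_a, t, q_a
    if n_components == 0:
        raise ValueError("response is orthogonal to all predictors")
    # coefficient path: B_k uses components 1..k
    coef_path = np.zeros((n_components, p))
    PtW = P.T @ W  # upper triangular with unit-free diagonal
    for k in range(1, n_components + 1):
        R = W[:, :k] @ np.linalg.inv(PtW[:k, :k])
        coef_path[k - 1] = R @ q[:k]
    model = PLSRModel(
        n_components=n_components,
        x_weights=W, x_loadings=P, x_scores=T, y_loadings=q,
        coefficients=coef_path[-1], coef_path=coef_path,
        x_mean=x_mean, y_mean=y_mean,
        wavelengths=None if wavelengths is None else np.asarray(wavelengths, float),
    )
    model.vip = vip_scores(model)
    return model


def vip_scores(model: PLSRModel) -> np.ndarray:
    """Variable importance in the projection over the retained components.

    VIP_j = sqrt( p * sum_a SS_a * (w_ja / ||w_a||)^2 / sum_a SS_a ) with
    SS_a = q_a^2 t_a't_a the response variance explained by component a.
    The mean of the squared scores is exactly 1.
    """
    W, T, q = model.x_weights, model.x_scores, model.y_loadings
    p = W.shape[0]
    ss = q**2 * np.einsum("na,na->a", T, T)
    total = float(ss.sum())
    if total <= 0:
        raise ValueError("model explains no response variance")
    wnorm2 = (W / np.linalg.norm(W, axis=0, keepdims=True)) ** 2
    return np.sqrt(p * (wnorm2 @ ss) / total)


def loocv_rmse(X: np.ndarray, y: np.ndarray, max_components: int) -> np.ndarray:
    """Exhaustive leave-one-out RMSE for 1..max_components PLSR components.

    n refits; each left-out fit's coefficient path yields predictions for all
    candidate counts at once.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if n < 3:
        raise ValueError("too few observations for LOOCV")
    max_components = min(max_components, n - 2, X.shape[1])
    errs = np.full((n, max_components), np.nan)
    for i in range(n):
        keep = np.ones(n, dtype=bool)
        keep[i] = False
        m = fit_plsr(X[keep], y[keep], max_components)
        for k in range(1, m.n_components + 1):
            errs[i, k - 1] = m.predict(X[i : i + 1], n_components=k)[0] - y[i]
        # if the fit stopped early, reuse its deepest model for larger counts
        for k in range(m.n_components + 1, max_components + 1):
            errs[i, k - 1] = errs[i, m.n_components - 1]
    return np.sqrt(np.nanmean(errs**2, axis=0))


def select_components(X: np.ndarray, y: np.ndarray, max_components: int) -> int:
    """Component count minimizing the LOOCV (PRESS) RMSE; ties take the smallest."""
    if max_components < 1:
        raise ValueError("max_components must be >= 1")
    rmse = loocv_rmse(X, y, max_components)
    return int(np.argmin(rmse)) + 1


@dataclass
class VIPSelection:
    """Backward-elimination outcome: surviving bands and the refitted model."""

    selected: np.ndarray          # indices into the original band axis
    model: PLSRModel
    cv_rmse: float
    history: list[dict] = field(default_factory=list)


def vip_feature_selection(
    X: np.ndarray,
    y: np.ndarray,
    threshold: float = 1.0,
    max_components: int = 10,
    wavelengths: np.ndarray | None = None,
) -> VIPSelection:
    """Iterative VIP-threshold backward elimination with a CV stopping rule.

    Each round fits a PRESS-selected PLSR on the surviving bands, then drops
    every band with VIP < threshold.  Iteration ends when the LOOCV RMSE stops
    improving, no band is dropped, or fewer than two bands would remain; the
    best-RMSE round is returned.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[1] < 2:
        raise ValueError("need at least 2 candidate bands")
    wl = None if wavelengths is None else np.asarray(wavelengths, float)
    active = np.arange(X.shape[1])
    best: VIPSelection | None = None
    history: list[dict] = []
    while True:
        Xa = X[:, active]
        k = select_components(Xa, y, min(max_components, Xa.shape[1]))
        model = fit_plsr(Xa, y, k, None if wl is None else wl[active])
        rmse = float(loocv_rmse(Xa, y, k)[k - 1])
        history.append(
            {"n_bands": int(active.size), "n_components": k, "cv_rmse": rmse}
        )
        if best is None or rmse < best.cv_rmse:
            best = VIPSelection(active.copy(), model, rmse, history)
        elif rmse > best.cv_rmse:
            break
        keep = model.vip >= threshold
        if keep.all() or keep.sum() < 2:
            break
        active = active[keep]
    best.history = history
    return best


# --------------------------------------------------------------------------
# Evaluation
# --------------------------------------------------------------------------

@dataclass
class ModelEvaluation:
    rmse: float
    r_squared: float
    split: str
    n: int


def evaluate(observed: np.ndarray, predicted: np.ndarray,
             split_kind: str = "test") -> ModelEvaluation:
    """RMSE and R² (squared Pearson correlation of observed vs predicted).

    Constant predictions leave the correlation undefined; R² is reported as 0
    by convention.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.size != pred.size or obs.size < 2:
        raise ValueError("need >= 2 matching observation/prediction pairs")
    rmse = float(np.sqrt(np.mean((obs - pred) ** 2)))
    if np.ptp(pred) == 0 or np.ptp(obs) == 0:
        r2 = 0.0
    else:
        r2 = float(np.corrcoef(obs, pred)[0, 1] ** 2)
    return ModelEvaluation(rmse, r2, split_kind, int(obs.size))
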