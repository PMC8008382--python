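"""NIPALS partial least squares for under-determined field matrices.

A CoMFA field matrix has far more columns (lattice points × fields) than
rows (molecules), so ordinary least squares is unusable.  PLS extracts a
small number of latent components that maximize covariance with the
response; with as many components as the centered matrix has rank, PLS
coincides with OLS.

Conventions: X and y are mean-centered before extraction; no per-column
autoscaling is applied here (block scaling, when wanted, lives in the
descriptor-matrix assembly and is passed in as ``x_scale``).  Single-y
NIPALS is deterministic: each weight vector is X'y of the deflated data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["PlsModel", "fit_pls", "predict", "r_squared", "sd_error",
           "save_model", "load_model"]

CONVERGENCE_TOL = 1e-12
MAX_INNER_ITER = 500
SCORE_VARIANCE_FLOOR = 1e-12  # relative to the first component


@dataclass
class PlsModel:
    """A fitted PLS regression in centered/scaled coordinates.

    The prediction identity is
        y_hat = y_mean + ((x - x_mean) / x_scale) · coefficients
    where the division is element-wise over columns.
    """

    n_components: int
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: float
    coefficients: np.ndarray
    weights: np.ndarray      # columns: w_a
    loadings: np.ndarray     # columns: p_a
    y_loadings: np.ndarray   # q_a
    scores: np.ndarray       # training scores, columns t_a
    r2: float
    sdec: float
    column_provenance: list[tuple[str, int]] = field(default_factory=list)


def fit_pls(
    X: np.ndarray,
    y: np.ndarray,
    n_components: int,
    x_scale: np.ndarray | None = None,
    column_provenance: list[tuple[str, int]] | None = None,
) -> PlsModel:
    """Fit a single-response NIPALS PLS model.

    Components whose score variance collapses below 1e-12 of the first
    component's end extraction early (the data carry no further signal).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if len(y) != n:
        raise ValueError("X row count and y length differ")
    if n < 3:
        raise ValueError("need at least 3 training rows")
    if np.ptp(y) == 0:
        raise ValueError("response is constant; nothing to model")
    max_comp = min(n - 1, p)
    if not (1 <= n_components <= max_comp):
        raise ValueError(
            f"n_components must be in [1, {max_comp}], got {n_components}"
        )

    if x_scale is None:
        x_scale = np.ones(p)
    x_scale = np.asarray(x_scale, dtype=float)
    Xs = X / x_scale
    x_mean = Xs.mean(axis=0)
    y_mean = float(y.mean())
    E = Xs - x_mean
    f = y - y_mean

    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    T = np.zeros((n, n_components))
    q = np.zeros(n_components)
    first_tt = None
    a_used = 0
    for a in range(n_components):
        if np.linalg.norm(E.T @ f) == 0:
            break  # no covariance left to extract
        # classic NIPALS u -> w -> t -> c -> u loop; with a single response
        # u stays proportional to the deflated y, so one pass converges
        u = f
        t_old = None
        for _ in range(MAX_INNER_ITER):
            w = E.T @ u
            w = w / np.linalg.norm(w)
            t = E @ w
            c = float(f @ t) / max(float(t @ t), 1e-300)
            u = f * c
            if t_old is not None and np.linalg.norm(t - t_old) <= (
                CONVERGENCE_TOL * max(np.linalg.norm(t), 1e-300)
            ):
                break
            t_old = t
        tt = float(t @ t)
        if first_tt is None:
            first_tt = tt
        if tt <= SCORE_VARIANCE_FLOOR * first_tt or tt == 0:
            break
        p_a = E.T @ t / tt
        q_a = float(f @ t / tt)
        E = E - np.outer(t, p_a)
        f = f - q_a * t
        W[:, a], P[:, a], T[:, a], q[a] = w, p_a, t, q_a
        a_used = a + 1

    if a_used == 0:
        raise ValueError("no PLS component could be extracted")
    W, P, T, q = W[:, :a_used], P[:, :a_used], T[:, :a_used], q[:a_used]

    # B maps centered/scaled X to centered y: B = W (P'W)^-1 q
    coefficients = W @ np.linalg.solve(P.T @ W, q)

    fitted = y_mean + (Xs - x_mean) @ coefficients
    return PlsModel(
        n_components=a_used,
        x_mean=x_mean,
        x_scale=x_scale,
        y_mean=y_mean,
        coefficients=coefficients,
        weights=W,
        loadings=P,
        y_loadings=q,
        scores=T,
        r2=r_squared(y, fitted),
        sdec=sd_error(y, fitted),
        column_provenance=list(column_provenance or []),
    )


def predict(model: PlsModel, X_new: np.ndarray) -> np.ndarray:
    """Predicted responses for new rows on the model's column layout."""
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != len(model.x_mean):
        raise ValueError(
            f"column mismatch: model has {len(model.x_mean)}, "
            f"X_new has {X_new.shape[1]}"
        )
    return model.y_mean + (X_new / model.x_scale - model.x_mean) @ model.coefficients


def r_squared(y: np.ndarray, y_hat: np.ndarray) -> float:
    """r² = 1 - SS_res/SS_tot over observed/predicted pairs."""
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if len(y) < 2:
        raise ValueError("need at least 2 observations")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("observed values are constant")
    return 1.0 - float(np.sum((y - y_hat) ** 2)) / ss_tot


def sd_error(y: np.ndarray, y_hat: np.ndarray, kind: str = "SDEC") -> float:
    """Root mean squared error, sqrt(sum((y - y_hat)²)/n).

    SDEC when y_hat are fitted values, SDEP when they are out-of-sample
    predictions; the formula is identical, the provenance differs.
    """
    if kind not in ("SDEC", "SDEP"):
        raise ValueError("kind must be SDEC or SDEP")
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if len(y) == 0:
        raise ValueError("need at least 1 observation")
    return float(np.sqrt(np.mean((y - y_hat) ** 2)))


# ---------------------------------------------------------------------------
# Serialization (npz container; round-trips bit-exactly)

def save_model(model: PlsModel, path: str | Path) -> None:
    prov_types = np.array([t for t, _ in model.column_provenance])
    prov_idx = np.array([i for _, i in model.column_provenance], dtype=int)
    np.savez(
        path,
        n_components=model.n_components,
        x_mean=model.x_mean,
        x_scale=model.x_scale,
        y_mean=model.y_mean,
        coefficients=model.coefficients,
        weights=model.weights,
        loadings=model.loadings,
        y_loadings=model.y_loadings,
        scores=model.scores,
        r2=model.r2,
        sdec=model.sdec,
        prov_types=prov_types,
        prov_idx=prov_idx,
    )


def load_model(path: str | Path) -> PlsModel:
    with np.load(path, allow_pickle=False) as z:
        provenance = [
            (str(t), int(i)) for t, i in zip(z["prov_types"], z["prov_idx"])
        ]
        return PlsModel(
            n_components=int(z["n_components"]),
            x_mean=z["x_mean"],
            x_scale=z["x_scale"],
            y_mean=float(z["y_mean"]),
            coefficients=z["coefficients"],
            weights=z["weights"],
            loadings=z["loadings"],
            y_loadings=z["y_loadings"],
            scores=z["scores"],
            r2=float(z["r2"]),
            sdec=float(z["sdec"]),
            column_provenance=provenance,
        )
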