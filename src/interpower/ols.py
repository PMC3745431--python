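"""Least-squares fitting of the interaction model and the t-test on its product term."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .generate import ReplicateDataset

__all__ = ["InteractionFit", "RankDeficientDesignError", "fit_interaction_model", "batch_interaction_pvalues"]

_COLUMN_NAMES = ("intercept", "x1", "x2", "x1x2")


class RankDeficientDesignError(ValueError):
    """The design matrix has a (numerically) collinear or constant column."""

    def __init__(self, column: str):
        self.column = column
        super().__init__(f"design matrix is rank deficient (degenerate column: {column})")


@dataclass(frozen=True)
class InteractionFit:
    """OLS estimates and the significance test of the interaction coefficient."""

    beta_hat: np.ndarray  # (intercept, x1, x2, x1x2)
    se_interaction: float
    t_interaction: float
    p_interaction: float
    df_resid: int


def fit_interaction_model(data: ReplicateDataset) -> InteractionFit:
    """Fit y ~ 1 + x1 + x2 + x1*x2 by least squares via a QR decomposition.

    The p-value is two-sided from the central t distribution with n - 4
    degrees of freedom, using the unbiased residual variance estimate.
    """
    n = data.n
    if n < 5:
        raise ValueError(f"need n >= 5 for a residual degree of freedom, got {n}")
    X = data.design_matrix()
    Q, R = np.linalg.qr(X)
    diag = np.abs(np.diag(R))
    tol = np.finfo(float).eps * n * max(diag.max(), 1.0)
    if np.any(diag < tol):
        bad = int(np.argmin(diag))
        raise RankDeficientDesignError(_COLUMN_NAMES[bad])
    beta = np.linalg.solve(R, Q.T @ data.y)
    resid = data.y - X @ beta
    df = n - 4
    s2 = float(resid @ resid) / df
    # (X'X)^{-1} = R^{-1} R^{-T}; only the interaction entry is needed.
    Rinv = np.linalg.solve(R, np.eye(4))
    var_b3 = s2 * float(Rinv[3] @ Rinv[3])
    se = np.sqrt(var_b3)
    t = float(beta[3] / se) if se > 0 else np.inf * np.sign(beta[3])
    p = float(2.0 * stats.t.sf(abs(t), df))
    return InteractionFit(
        beta_hat=beta, se_interaction=float(se), t_interaction=t, p_interaction=p, df_resid=df
    )


def batch_interaction_pvalues(
    x1: np.ndarray, x2: np.ndarray, y: np.ndarray
) -> np.ndarray:
    """Two-sided interaction p-values for a stack of replicates.

    Parameters are arrays of shape (n_replicates, n); each row is one
    replicate.  Solves the 4-column normal equations per replicate with
    batched linear algebra (the design is standardized and 4-dimensional,
    so this is numerically equivalent to the QR path to near machine
    precision; a unit test enforces agreement).  Rows whose design is
    degenerate must be screened out by the caller beforehand.
    """
    n_rep, n = y.shape
    X = np.empty((n_rep, n, 4))
    X[:, :, 0] = 1.0
    X[:, :, 1] = x1
    X[:, :, 2] = x2
    X[:, :, 3] = x1 * x2
    xtx = np.einsum("rni,rnj->rij", X, X, optimize=True)
    xty = np.einsum("rni,rn->ri", X, y, optimize=True)
    beta = np.linalg.solve(xtx, xty[:, :, None])[:, :, 0]
    resid = y - np.einsum("rni,ri->rn", X, beta, optimize=True)
    df = n - 4
    s2 = np.einsum("rn,rn->r", resid, resid) / df
    inv33 = np.linalg.inv(xtx)[:, 3, 3]
    se = np.sqrt(s2 * inv33)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta[:, 3] / se
    return 2.0 * stats.t.sf(np.abs(t), df)
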