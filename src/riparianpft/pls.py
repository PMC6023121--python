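"""Partial least squares regression with cross-validated component selection.

A from-scratch NIPALS implementation (PLS2, reducing to PLS1 for a single
response) with the chemometric model-assessment toolkit used in gradient
analyses of community data:

* R2(Y)     in-sample fraction of response variance explained;
* Q2        cross-validated fraction of response variance *predicted*,
            computed from leave-one-out PRESS with centering/scaling refit
            inside every fold (no leakage);
* the component-entry rule: per-component Q2_a = 1 - PRESS_a / RESS_{a-1}
  must exceed a significance threshold (default 0.097) for component a to
  enter; among admissible counts the one maximising cumulative Q2 is kept;
* VIP       variable importance in the projection,
            VIP_j = sqrt(p * sum_a SSY_a w_aj^2 / sum_a SSY_a),
            normalised so that mean(VIP^2) = 1;
* standardized coefficients B = W (P'W)^{-1} C' on the unit-variance scale
  of both predictors and responses.

Matrices are plain numpy arrays or pandas DataFrames; column names, when
present, are carried through to VIP and coefficient vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ScalingRecord",
    "PLSModel",
    "Q2Result",
    "ComponentSelection",
    "center_scale",
    "fit_pls",
    "predict",
    "q2_crossval",
    "components_from_q2",
    "select_components",
    "vip",
    "standardized_coefficients",
]

#: Default per-component Q2 significance cut (P < 0.05 entry rule).
Q2_SIGNIFICANCE = 0.097

_ORTHO_TOL = 1e-8


class ConvergenceError(RuntimeError):
    """NIPALS inner iteration failed to converge for some component."""


@dataclass(frozen=True)
class ScalingRecord:
    """Column means and SDs used to autoscale a matrix; allows exact inverse."""

    mean: np.ndarray
    std: np.ndarray
    ddof: int
    names: list[str] | None = None

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean) / self.std

    def inverse(self, Z: np.ndarray) -> np.ndarray:
        return np.asarray(Z, dtype=float) * self.std + self.mean


def _as_matrix(X, kind: str) -> tuple[np.ndarray, list[str] | None]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), [str(c) for c in X.columns]
    if isinstance(X, pd.Series):
        return X.to_numpy(dtype=float).reshape(-1, 1), [str(X.name or kind)]
    arr = np.asarray(X, dtype=float)
    if arr.ndim == 1:
        arr = arr.reshape(-1, 1)
    if arr.ndim != 2:
        raise ValueError(f"{kind} must be a 2-D matrix")
    return arr, None


def center_scale(X, ddof: int = 1) -> tuple[np.ndarray, ScalingRecord]:
    """Center each column to mean 0 and scale to unit variance.

    Parameters
    ----------
    X : array-like or DataFrame, shape (n, p)
    ddof : int
        Delta degrees of freedom for the SD: 1 (default) uses the sample SD,
        0 the population SD. The convention is recorded in the returned
        :class:`ScalingRecord`.

    Raises
    ------
    ValueError
        If any column is constant (SD of zero), naming the offending
        variable(s).
    """
    arr, names = _as_matrix(X, "X")
    if np.isnan(arr).any():
        raise ValueError("matrix contains missing values")
    mean = arr.mean(axis=0)
    std = arr.std(axis=0, ddof=ddof)
    bad = np.flatnonzero(std <= 0)
    if bad.size:
        labels = [names[j] if names else f"column {j}" for j in bad]
        raise ValueError(f"constant column(s), cannot scale: {', '.join(labels)}")
    rec = ScalingRecord(mean=mean, std=std, ddof=ddof, names=names)
    return rec.transform(arr), rec


@dataclass
class PLSModel:
    """Fitted PLS regression model (NIPALS, X-deflation only)."""

    n: int
    p: int
    m: int
    A: int
    x_scaling: ScalingRecord
    y_scaling: ScalingRecord
    W: np.ndarray  # (p, A) X-weights, unit norm
    T: np.ndarray  # (n, A) X-scores, mutually orthogonal
    P: np.ndarray  # (p, A) X-loadings
    C: np.ndarray  # (m, A) Y-weights
    R: np.ndarray  # (p, A) W (P'W)^{-1}: maps scaled X to scores
    B: np.ndarray  # (p, m) standardized coefficients
    ssy_comp: np.ndarray  # (A,) Y sum of squares captured per component
    ssy_total: float
    r2y_comp: np.ndarray = field(init=False)
    r2y_cum: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.r2y_comp = self.ssy_comp / self.ssy_total
        self.r2y_cum = np.cumsum(self.r2y_comp)

    @property
    def x_names(self) -> list[str] | None:
        return self.x_scaling.names

    @property
    def y_names(self) -> list[str] | None:
        return self.y_scaling.names


def _check_invariants(W: np.ndarray, T: np.ndarray) -> None:
    # typed invariants: unit weights, orthogonal scores
    norms = np.linalg.norm(W, axis=0)
    if not np.allclose(norms, 1.0, atol=1e-8):
        raise AssertionError("PLS weight vectors are not unit-norm")
    G = T.T @ T
    scale = np.sqrt(np.outer(np.diag(G), np.diag(G)))
    off = np.abs(G - np.diag(np.diag(G)))
    mask = scale > 0
    if np.any(off[mask] > _ORTHO_TOL * np.maximum(scale[mask], 1.0)):
        raise AssertionError("PLS score vectors are not orthogonal")


def fit_pls(X, Y, A: int, *, ddof: int = 1, max_iter: int = 2000, tol: float = 1e-10) -> PLSModel:
    """Fit a PLS regression with ``A`` latent components by NIPALS.

    Predictors and responses are autoscaled internally (mean 0, unit
    variance; ``ddof`` selects the SD convention). X is deflated after each
    component; Y is not (standard PLS2, identical to PLS1 when m = 1).

    Raises
    ------
    ValueError
        If A exceeds min(n - 1, p) or the inputs contain missing values.
    ConvergenceError
        If the inner NIPALS iteration fails for some component.
    """
    X0, x_rec = center_scale(X, ddof=ddof)
    Y0, y_rec = center_scale(Y, ddof=ddof)
    n, p = X0.shape
    m = Y0.shape[1]
    if Y0.shape[0] != n:
        raise ValueError("X and Y must have the same number of rows")
    if not 1 <= A <= min(n - 1, p):
        raise ValueError(f"number of components must be in [1, min(n-1, p)] = [1, {min(n - 1, p)}]")

    Xa = X0.copy()
    W = np.empty((p, A))
    T = np.empty((n, A))
    P = np.empty((p, A))
    C = np.empty((m, A))

    for a in range(A):
        u = Y0[:, np.argmax(Y0.var(axis=0))].copy()
        w_old = None
        drift = np.inf
        for _ in range(max_iter):
            w = Xa.T @ u
            nw = np.linalg.norm(w)
            if nw == 0:
                raise ValueError(f"X exhausted before component {a + 1}; reduce A")
            w /= nw
            t = Xa @ w
            tt = t @ t
            if tt == 0:
                raise ValueError(f"degenerate score at component {a + 1}")
            c = Y0.T @ t / tt
            if m == 1:
                break  # PLS1: single pass is exact
            u = Y0 @ c / (c @ c)
            # w is unit norm, so the sign-invariant drift is already relative
            if w_old is not None:
                drift = min(np.linalg.norm(w - w_old), np.linalg.norm(w + w_old))
                if drift <= tol:
                    break
            w_old = w
        else:
            # near-ties between latent directions converge slowly; any unit w
            # in the degenerate subspace keeps the scores orthogonal (the
            # deflation guarantees it), so accept a numerically stationary
            # weight and reject only a genuinely drifting one
            if drift > 1e-3:
                raise ConvergenceError(f"NIPALS did not converge for component {a + 1}")
        p_load = Xa.T @ t / tt
        Xa = Xa - np.outer(t, p_load)
        W[:, a], T[:, a], P[:, a], C[:, a] = w, t, p_load, c

    R = W @ np.linalg.inv(P.T @ W)
    B = R @ C.T
    # Y SS captured per component: scores are orthogonal, so contributions add
    ssy_comp = np.einsum("ia,ia->a", T, T) * np.einsum("ja,ja->a", C, C)
    ssy_total = float(np.sum(Y0**2))
    _check_invariants(W, T)
    return PLSModel(
        n=n, p=p, m=m, A=A, x_scaling=x_rec, y_scaling=y_rec,
        W=W, T=T, P=P, C=C, R=R, B=B,
        ssy_comp=ssy_comp, ssy_total=ssy_total,
    )


def predict(model: PLSModel, X, ncomp: int | None = None) -> np.ndarray:
    """Predict responses (on the raw Y scale) for new predictor rows.

    ``ncomp`` truncates the model to its first components; default uses all.
    """
    a = model.A if ncomp is None else ncomp
    if not 0 <= a <= model.A:
        raise ValueError("ncomp out of range")
    arr, _ = _as_matrix(X, "X")
    Z = model.x_scaling.transform(arr)
    if a == 0:
        Yhat0 = np.zeros((arr.shape[0], model.m))
    else:
        Yhat0 = (Z @ model.R[:, :a]) @ model.C[:, :a].T
    return model.y_scaling.inverse(Yhat0)


@dataclass(frozen=True)
class Q2Result:
    """Leave-one-out PRESS and the derived Q2 statistics, on the raw Y scale."""

    press: np.ndarray     # (A,) PRESS with 1..A components
    ress: np.ndarray      # (A+1,) residual SS of the full model with 0..A components
    q2_comp: np.ndarray   # (A,) per-component Q2_a = 1 - PRESS_a / RESS_{a-1}
    q2_cum: np.ndarray    # (A,) cumulative Q2 = 1 - PRESS_a / RESS_0


def q2_crossval(X, Y, A: int, *, ddof: int = 1) -> Q2Result:
    """Leave-one-out cross-validation of a PLS model with 1..A components.

    Every fold refits the full model, including the centering/scaling of both
    X and Y, on the retained rows; PRESS accumulates squared prediction error
    for the withheld row on the raw response scale.
    """
    Xa, _ = _as_matrix(X, "X")
    Ya, _ = _as_matrix(Y, "Y")
    n = Xa.shape[0]
    if n < 5:
        raise ValueError("leave-one-out Q2 needs at least 5 samples")
    if not 1 <= A <= min(n - 2, Xa.shape[1]):
        raise ValueError(f"A must be in [1, min(n-2, p)] = [1, {min(n - 2, Xa.shape[1])}]")

    press = np.zeros(A)
    for i in range(n):
        keep = np.arange(n) != i
        try:
            sub = fit_pls(Xa[keep], Ya[keep], A, ddof=ddof)
        except ValueError as exc:
            raise ValueError(f"leave-one-out refit failed excluding row {i}: {exc}") from exc
        zi = sub.x_scaling.transform(Xa[i:i + 1])
        t_row = zi @ sub.R  # (1, A)
        yhat0 = np.zeros((1, sub.m))
        for a in range(A):
            yhat0 = yhat0 + t_row[:, a:a + 1] @ sub.C[:, a:a + 1].T
            err = Ya[i] - sub.y_scaling.inverse(yhat0)[0]
            press[a] += float(err @ err)

    full = fit_pls(Xa, Ya, A, ddof=ddof)
    ress = np.empty(A + 1)
    ress[0] = float(np.sum((Ya - Ya.mean(axis=0)) ** 2))
    for a in range(1, A + 1):
        resid = Ya - predict(full, Xa, ncomp=a)
        ress[a] = float(np.sum(resid**2))

    q2_comp = 1.0 - press / ress[:-1]
    q2_cum = 1.0 - press / ress[0]
    return Q2Result(press=press, ress=ress, q2_comp=q2_comp, q2_cum=q2_cum)


def components_from_q2(q2_comp, q2_cum=None, threshold: float = Q2_SIGNIFICANCE) -> int:
    """Number of significant latent components N from a per-component Q2 sequence.

    Components enter while their per-component Q2 exceeds ``threshold``; among
    the admissible counts the one with maximal cumulative Q2 is returned
    (maximum-Q2 rule). Returns 0 when no component is significant.
    """
    q2_comp = np.asarray(q2_comp, dtype=float)
    admissible = 0
    for q in q2_comp:
        if q > threshold:
            admissible += 1
        else:
            break
    if admissible == 0:
        return 0
    if q2_cum is None:
        return admissible
    q2_cum = np.asarray(q2_cum, dtype=float)
    return int(np.argmax(q2_cum[:admissible]) + 1)


@dataclass(frozen=True)
class ComponentSelection:
    """Outcome of the Q2-based component-entry rule."""

    a_star: int
    q2: Q2Result
    threshold: float

    @property
    def significant(self) -> bool:
        return self.a_star >= 1

    @property
    def q2_cum_star(self) -> float:
        """Cumulative Q2 at the selected component count (0 for no model)."""
        return float(self.q2.q2_cum[self.a_star - 1]) if self.a_star else 0.0


def select_components(X, Y, *, threshold: float = Q2_SIGNIFICANCE,
                      a_max: int | None = None, ddof: int = 1) -> ComponentSelection:
    """Select the number of latent components by the Q2 entry / max-Q2 rule.

    ``a_max`` caps the sequence searched (default min(n - 2, p, 5)). An
    ``a_star`` of 0 flags a non-significant model.
    """
    Xa, _ = _as_matrix(X, "X")
    # cap at the effective rank of centered X so exactly low-rank inputs
    # (e.g. noiseless planted structure) never request an exhausted component
    rank = int(np.linalg.matrix_rank(Xa - Xa.mean(axis=0)))
    cap = min(Xa.shape[0] - 2, Xa.shape[1], rank, 5)
    if a_max is not None:
        cap = min(cap, a_max)
    res = q2_crossval(X, Y, cap, ddof=ddof)
    a_star = components_from_q2(res.q2_comp, res.q2_cum, threshold=threshold)
    return ComponentSelection(a_star=a_star, q2=res, threshold=threshold)


def vip(model: PLSModel, ncomp: int | None = None) -> np.ndarray:
    """Variable importance in the projection for every predictor.

    VIP_j = sqrt( p * sum_a SSY_a w_aj^2 / sum_a SSY_a ) over the first
    ``ncomp`` components (default: all retained). mean(VIP^2) = 1 because the
    weight vectors are unit norm.
    """
    a = model.A if ncomp is None else ncomp
    if a < 1:
        raise ValueError("VIP requires at least one fitted component")
    ssy = model.ssy_comp[:a]
    w2 = model.W[:, :a] ** 2
    return np.sqrt(model.p * (w2 @ ssy) / ssy.sum())


def standardized_coefficients(model: PLSModel) -> np.ndarray:
    """Regression coefficients on the autoscaled (unit-variance) X and Y scales.

    Shape (p, m); equals the Pearson correlation for a single predictor,
    single response, one-component model.
    """
    return model.B.copy()
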