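"""NIPALS partial least squares, single- and multi-response.

The bilinear model is Y = X B + E with X = T P' + E_X and Y regressed on the
orthogonal X-scores T; W holds the X-weights, P the X-loadings, Q the
Y-loadings (regression of the deflated Y on each score), U the Y-scores and
``c_inner`` the inner-relation coefficients linking U to T.  Both blocks are
centered internally and the centering statistics are stored, so prediction on
new (identically pre-treated) data is ``(Xnew - x_mean) B + y_mean``.

Numerical conventions (the standard ones, stated for reproducibility):
per-component iteration starts from the deflated-Y column of largest
variance, converges when the relative change of the weight vector drops below
1e-10 (cap 500 iterations), and each weight vector is flipped so that its
largest-magnitude entry is positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PLSModel", "fit", "predict", "explained_variance", "b_matrix"]

_TOL = 1e-10
_MAX_ITER = 500


@dataclass
class PLSModel:
    W: np.ndarray  # p x A X-weights (unit norm)
    P: np.ndarray  # p x A X-loadings
    Q: np.ndarray  # m x A Y-loadings
    T: np.ndarray  # n x A X-scores
    U: np.ndarray  # n x A Y-scores
    c_inner: np.ndarray  # A inner-relation coefficients (u't / t't)
    B: np.ndarray  # p x m regression coefficients
    x_mean: np.ndarray  # p
    y_mean: np.ndarray  # m
    explained_x_var: np.ndarray  # A fractions of centered-X variance
    explained_y_var: np.ndarray  # A fractions of centered-Y variance
    n_components: int
    y_was_1d: bool = False

    @property
    def n_features(self) -> int:
        return self.W.shape[0]


def b_matrix(W: np.ndarray, P: np.ndarray, Q: np.ndarray, a: int) -> np.ndarray:
    """Direct regression coefficients from the first ``a`` components:
    B_a = W_a (P_a' W_a)^-1 Q_a'."""
    Wa, Pa, Qa = W[:, :a], P[:, :a], Q[:, :a]
    return Wa @ np.linalg.solve(Pa.T @ Wa, Qa.T)


def fit(X: np.ndarray, Y: np.ndarray, n_components: int) -> PLSModel:
    """Fit NIPALS PLS with deflation of both blocks.

    X is n x p, Y is n x m (or length-n for a single response); both are
    centered internally.  Raises if ``n_components`` exceeds min(n-1, p), if a
    response column has zero variance, or if X runs out of rank during
    deflation.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    y_was_1d = Y.ndim == 1
    if y_was_1d:
        Y = Y[:, None]
    n, p = X.shape
    if Y.shape[0] != n:
        raise ValueError("X and Y row counts differ")
    m = Y.shape[1]
    if n < 2:
        raise ValueError("need at least 2 samples")
    A = int(n_components)
    if A < 1 or A > min(n - 1, p):
        raise ValueError(f"n_components must lie in [1, min(n-1, p)] = [1, {min(n - 1, p)}]")
    if np.any(Y.std(axis=0) == 0):
        raise ValueError("a response column has zero variance")

    x_mean = X.mean(axis=0)
    y_mean = Y.mean(axis=0)
    Xa = X - x_mean
    Ya = Y - y_mean
    ssx_total = float(np.sum(Xa**2))
    ssy_total = float(np.sum(Ya**2))

    W = np.empty((p, A))
    P = np.empty((p, A))
    Q = np.empty((m, A))
    T = np.empty((n, A))
    U = np.empty((n, A))
    c = np.empty(A)
    evx = np.empty(A)
    evy = np.empty(A)

    for a in range(A):
        u = Ya[:, int(np.argmax(Ya.var(axis=0)))].copy()
        if np.allclose(u, 0):
            raise ValueError(f"Y fully deflated before component {a + 1}: reduce n_components")
        w = np.zeros(p)
        for _ in range(_MAX_ITER):
            w_new = Xa.T @ u / (u @ u)
            norm = np.linalg.norm(w_new)
            if norm < 1e-14:
                raise ValueError(f"X rank exhausted at component {a + 1}")
            w_new /= norm
            t = Xa @ w_new
            tt = t @ t
            if tt < 1e-14:
                raise ValueError(f"X rank exhausted at component {a + 1}")
            q = Ya.T @ t / tt
            u_new = Ya @ q / (q @ q)
            if np.linalg.norm(w_new - w) < _TOL * max(1.0, np.linalg.norm(w_new)):
                w = w_new
                u = u_new
                break
            w = w_new
            u = u_new
        # sign convention: largest-magnitude weight entry positive
        if w[int(np.argmax(np.abs(w)))] < 0:
            w = -w
        t = Xa @ w
        tt = t @ t
        pvec = Xa.T @ t / tt
        q = Ya.T @ t / tt
        c[a] = u @ t / tt
        W[:, a], P[:, a], Q[:, a], T[:, a], U[:, a] = w, pvec, q, t, u
        evx[a] = tt * (pvec @ pvec) / ssx_total if ssx_total > 0 else 0.0
        evy[a] = tt * (q @ q) / ssy_total if ssy_total > 0 else 0.0
        Xa = Xa - np.outer(t, pvec)
        Ya = Ya - np.outer(t, q)

    B = b_matrix(W, P, Q, A)
    return PLSModel(
        W=W, P=P, Q=Q, T=T, U=U, c_inner=c, B=B,
        x_mean=x_mean, y_mean=y_mean,
        explained_x_var=evx, explained_y_var=evy,
        n_components=A, y_was_1d=y_was_1d,
    )


def predict(
    model: PLSModel, Xnew: np.ndarray, n_components: int | None = None
) -> np.ndarray:
    """Predict responses for new samples: (Xnew - x_mean) B_a + y_mean.

    ``n_components`` truncates the model to its first ``a`` components, which
    lets one cross-validate a whole component grid from a single fit.
    """
    Xnew = np.atleast_2d(np.asarray(Xnew, dtype=float))
    if Xnew.shape[1] != model.n_features:
        raise ValueError(
            f"Xnew has {Xnew.shape[1]} columns, model expects {model.n_features}"
        )
    if n_components is None or n_components == model.n_components:
        B = model.B
    else:
        a = int(n_components)
        if not 1 <= a <= model.n_components:
            raise ValueError("n_components out of fitted range")
        B = b_matrix(model.W, model.P, model.Q, a)
    Yhat = (Xnew - model.x_mean) @ B + model.y_mean
    return Yhat[:, 0] if model.y_was_1d else Yhat


def explained_variance(model: PLSModel) -> tuple[np.ndarray, np.ndarray]:
    """Per-component fractions of centered-X and centered-Y variance."""
    return model.explained_x_var.copy(), model.explained_y_var.copy()
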