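"""Spectral pre-treatments: SNV, Savitzky-Golay first derivative, mean centering.

Pre-treatments compose in the printed order of the model labels
("SNV + MC", "D1 + SNV + MC").  SNV and D1 act row-wise and need no fitting;
mean centering (MC) learns per-wavenumber column means from the training
block only and subtracts them from both blocks, so no test-set statistic ever
enters a fitted model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter

__all__ = ["snv", "d1", "PretreatmentChain", "fit_apply_chain"]

_STEPS = ("SNV", "D1", "MC")

D1_WINDOW = 9
D1_POLYORDER = 2


def snv(X: np.ndarray) -> np.ndarray:
    """Standard normal variate: per spectrum, subtract mean and divide by the
    n-1 standard deviation.  Removes additive offsets and multiplicative
    scatter; output rows have mean 0 and unit sd."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] < 2:
        raise ValueError("SNV needs spectra with at least 2 points")
    sd = X.std(axis=1, ddof=1, keepdims=True)
    if np.any(sd == 0):
        raise ValueError("SNV undefined for a constant spectrum (zero variance)")
    return (X - X.mean(axis=1, keepdims=True)) / sd


def d1(X: np.ndarray, axis: np.ndarray) -> np.ndarray:
    """First derivative with respect to wavenumber (Savitzky-Golay, quadratic
    polynomial, 9-point window, scaled by the grid step).  Edge points come
    from the filter's one-sided polynomial fits, so the length is preserved.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    axis = np.asarray(axis, dtype=float)
    if X.shape[1] != axis.size:
        raise ValueError("spectrum length does not match the wavenumber axis")
    if X.shape[1] < D1_WINDOW:
        raise ValueError(f"spectrum shorter than the {D1_WINDOW}-point window")
    step = axis[1] - axis[0]
    out = savgol_filter(
        X, window_length=D1_WINDOW, polyorder=D1_POLYORDER, deriv=1,
        delta=abs(step), axis=-1, mode="interp",
    )
    # columns ordered by decreasing wavenumber: index derivative flips sign
    return -out if step < 0 else out


@dataclass
class PretreatmentChain:
    """Ordered pre-treatment chain over {SNV, D1, MC}.

    MC may appear at most once and only last.  ``fit`` learns the MC column
    means from a training block; ``transform`` then applies the chain to any
    block with the stored means.
    """

    steps: tuple[str, ...] = ()
    mc_column_means: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.steps = tuple(self.steps)
        for s in self.steps:
            if s not in _STEPS:
                raise ValueError(f"unknown pre-treatment step {s!r}")
        if self.steps.count("MC") > 1:
            raise ValueError("MC may appear at most once")
        if "MC" in self.steps and self.steps[-1] != "MC":
            raise ValueError("MC must be the last step of the chain")

    # -- helpers -----------------------------------------------------------
    def _rowwise(self, X: np.ndarray, axis: np.ndarray | None) -> np.ndarray:
        out = np.atleast_2d(np.asarray(X, dtype=float))
        for s in self.steps:
            if s == "SNV":
                out = snv(out)
            elif s == "D1":
                if axis is None:
                    raise ValueError("D1 requires the wavenumber axis")
                out = d1(out, axis)
        return out

    # -- API ---------------------------------------------------------------
    def fit(self, train: np.ndarray, axis: np.ndarray | None = None) -> "PretreatmentChain":
        out = self._rowwise(train, axis)
        if "MC" in self.steps:
            self.mc_column_means = out.mean(axis=0)
        return self

    def transform(self, X: np.ndarray, axis: np.ndarray | None = None) -> np.ndarray:
        out = self._rowwise(X, axis)
        if "MC" in self.steps:
            if self.mc_column_means is None:
                raise ValueError("MC not fitted: call fit on a training block first")
            out = out - self.mc_column_means
        return out

    def fit_transform(self, train: np.ndarray, axis: np.ndarray | None = None) -> np.ndarray:
        return self.fit(train, axis).transform(train, axis)


def fit_apply_chain(
    train: np.ndarray,
    test: np.ndarray,
    steps: tuple[str, ...],
    axis: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, PretreatmentChain]:
    """Fit the chain on ``train``, apply it to both blocks.

    The MC means come from the training block only; the test block is
    centered with those stored means.
    """
    chain = PretreatmentChain(steps)
    train2 = chain.fit_transform(train, axis)
    test2 = chain.transform(test, axis)
    return train2, test2, chain
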