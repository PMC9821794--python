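"""Duplex splitting, cross-validated model selection and figures of merit.

The duplex algorithm (Snee) deterministically partitions a stratum into
representative calibration and validation subsets: the two mutually farthest
samples seed the training set, the two farthest remaining samples seed the
test set, and the remaining samples are handed out alternately, each time
picking the candidate with the largest minimum distance to the receiving set.
The test set is capped at ceil(test_fraction * n); everything left goes to
training.  Ties break toward the lowest row index, which also makes the split
invariant to row permutation up to relabeling.

Model selection runs a stratified k-fold cross-validation over a grid of
latent-variable counts and pre-treatment chains; the per-fold pre-treatment
(MC means) and PLS centering are always re-fitted on the in-fold training
part, so held-out samples never leak into any fitted statistic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from . import pls, plsda
from .preprocess import fit_apply_chain

__all__ = [
    "SplitResult",
    "duplex_split",
    "stratified_duplex",
    "stratified_folds",
    "cross_validate",
    "choose_model",
    "regression_metrics",
]


@dataclass(frozen=True)
class SplitResult:
    train_idx: np.ndarray
    test_idx: np.ndarray


def duplex_split(X: np.ndarray, test_fraction: float = 0.3) -> SplitResult:
    """Snee's duplex split of one stratum on Euclidean distances between the
    rows of ``X`` (pass pre-treated spectra to control the metric)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = X.shape[0]
    if n < 4:
        raise ValueError("duplex needs a stratum of at least 4 samples")
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must lie in (0, 1)")
    n_test = int(np.ceil(test_fraction * n))

    diff = X[:, None, :] - X[None, :, :]
    D = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))

    def farthest_pair(pool: np.ndarray) -> tuple[int, int]:
        # argmax of the row-major flattened block: ties fall on the lowest indices
        sub = D[np.ix_(pool, pool)]
        np.fill_diagonal(sub, -1.0)
        i, j = np.unravel_index(int(np.argmax(sub)), sub.shape)
        return int(pool[min(i, j)]), int(pool[max(i, j)])

    remaining = list(range(n))
    train = list(farthest_pair(np.array(remaining)))
    for i in train:
        remaining.remove(i)
    test = list(farthest_pair(np.array(remaining)))
    for i in test:
        remaining.remove(i)

    receiver = "train"
    while remaining:
        target = train if receiver == "train" else test
        if receiver == "test" and len(test) >= n_test:
            target = train
        # candidate with maximal minimum distance to the receiving set
        rem = np.array(remaining)  # kept sorted: argmax ties -> lowest index
        dmin = D[np.ix_(rem, np.array(target))].min(axis=1)
        pick = int(rem[int(np.argmax(dmin))])
        target.append(pick)
        remaining.remove(pick)
        receiver = "test" if receiver == "train" else "train"

    if len(test) > n_test:  # seeding may overshoot tiny strata
        train += test[n_test:]
        test = test[:n_test]
    return SplitResult(
        train_idx=np.array(sorted(train)), test_idx=np.array(sorted(test))
    )


def stratified_duplex(
    X: np.ndarray,
    strata: Sequence,
    test_fraction: float = 0.3,
    distance_transform=None,
) -> SplitResult:
    """Duplex split applied separately to each stratum (class or level).

    ``distance_transform`` maps the stratum block to the representation used
    for the distances (e.g. SNV) without affecting the returned indices.
    """
    strata = np.asarray(strata, dtype=object)
    train, test = [], []
    for s in pd.unique(strata):
        idx = np.flatnonzero(strata == s)
        block = X[idx]
        if distance_transform is not None:
            block = distance_transform(block)
        sub = duplex_split(block, test_fraction)
        train.extend(idx[sub.train_idx])
        test.extend(idx[sub.test_idx])
    return SplitResult(train_idx=np.array(sorted(train)), test_idx=np.array(sorted(test)))


def stratified_folds(strata: Sequence, k: int, seed: int) -> np.ndarray:
    """Random stratified fold assignment (0..k-1) with near-equal fold sizes."""
    strata = np.asarray(strata, dtype=object)
    rng = np.random.default_rng(seed)
    folds = np.empty(strata.size, dtype=int)
    offset = 0
    for s in pd.unique(strata):
        idx = np.flatnonzero(strata == s)
        perm = rng.permutation(idx.size)
        folds[idx[perm]] = (np.arange(idx.size) + offset) % k
        offset += idx.size  # stagger strata so fold sizes balance globally
    return folds


def cross_validate(
    X: np.ndarray,
    y,
    axis: np.ndarray,
    chains: Sequence[tuple[str, ...]],
    lv_grid: Sequence[int],
    mode: str,
    k: int = 5,
    seed: int = 0,
    strata: Sequence | None = None,
    class_order: Sequence | None = None,
    priors: str = "equal",
) -> pd.DataFrame:
    """k-fold CV metric for every (chain, LV count) candidate.

    mode="regression": y is the numeric response, metric RMSECV (pooled over
    all held-out predictions).  mode="classification": y holds class labels,
    the metric is the mean correct-classification rate (fraction, 0-1) of the
    pooled fold-wise probabilistic attributions.
    """
    X = np.asarray(X, dtype=float)
    if mode not in ("regression", "classification"):
        raise ValueError("mode must be 'regression' or 'classification'")
    n = X.shape[0]
    y = np.asarray(y)
    if strata is None:
        strata = y if mode == "classification" else y
    folds = stratified_folds(strata, k, seed)

    if mode == "classification":
        if class_order is None:
            class_order = list(pd.unique(np.asarray(y, dtype=object)))
        Yfull = plsda.encode_dummy(y, class_order)
    else:
        Yfull = np.asarray(y, dtype=float)

    lv_grid = sorted(set(int(a) for a in lv_grid))
    # per chain/A accumulators; candidates whose class rule cannot be fitted
    # in some fold (no density crossing / degenerate variance) are dropped
    cv_pred = {tuple(c): {a: np.full(n, np.nan) for a in lv_grid} for c in chains}
    cv_sets = {tuple(c): {a: [None] * n for a in lv_grid} for c in chains}
    dead: set[tuple[tuple[str, ...], int]] = set()

    for f in range(k):
        tr = np.flatnonzero(folds != f)
        te = np.flatnonzero(folds == f)
        if mode == "classification":
            present = set(np.asarray(y, dtype=object)[tr])
            missing = [c for c in class_order if c not in present]
            if missing:
                raise ValueError(f"fold {f}: class(es) {missing} missing from training part")
        for chain in chains:
            chain = tuple(chain)
            Xtr, Xte, _ = fit_apply_chain(X[tr], X[te], chain, axis)
            a_cap = min(tr.size - 1, Xtr.shape[1])
            grid_f = [a for a in lv_grid if a <= a_cap]
            if not grid_f:
                raise ValueError("LV grid exceeds the rank bound in a CV fold")
            # degenerate folds (duplicate rows) can exhaust the X rank below
            # the sample-count bound: back off to the largest fittable A
            while True:
                try:
                    model = pls.fit(Xtr, Yfull[tr], max(grid_f))
                    break
                except ValueError as exc:
                    if "rank exhausted" not in str(exc) or len(grid_f) == 1:
                        raise
                    grid_f = grid_f[:-1]
            for a in grid_f:
                if mode == "regression":
                    cv_pred[chain][a][te] = pls.predict(model, Xte, a)
                else:
                    if (chain, a) in dead:
                        continue
                    yhat_cal = pls.predict(model, Xtr, a)
                    try:
                        rules = plsda.fit_rules(
                            yhat_cal, np.asarray(y, dtype=object)[tr], class_order, priors
                        )
                    except ValueError:
                        dead.add((chain, a))
                        continue
                    sets, _ = plsda.attribute(rules, pls.predict(model, Xte, a), class_order)
                    for i, s in zip(te, sets):
                        cv_sets[chain][a][i] = s

    rows = []
    for chain in chains:
        chain = tuple(chain)
        for a in lv_grid:
            if mode == "regression":
                pred = cv_pred[chain][a]
                if np.isnan(pred).any():
                    continue  # A above some fold's rank bound
                metric = float(np.sqrt(np.mean((np.asarray(y, float) - pred) ** 2)))
                rows.append({"chain": chain, "n_lv": a, "rmsecv": metric})
            else:
                sets = cv_sets[chain][a]
                if (chain, a) in dead or any(s is None for s in sets):
                    continue
                m = plsda.classification_metrics(sets, y, class_order)
                rows.append({"chain": chain, "n_lv": a, "mean_ccr_cv": m["mean_ccr"]})
    return pd.DataFrame(rows)


def choose_model(cv_results: pd.DataFrame, mode: str) -> tuple[tuple[str, ...], int]:
    """Pick (chain, LV count) from a CV table: classification maximizes the
    mean CCR, regression minimizes RMSECV; ties break toward fewer LVs, then
    toward the shorter chain."""
    if cv_results.empty:
        raise ValueError("empty CV results")
    df = cv_results.copy()
    if mode == "classification":
        df["_score"] = -df["mean_ccr_cv"]
    elif mode == "regression":
        df["_score"] = df["rmsecv"]
    else:
        raise ValueError("mode must be 'regression' or 'classification'")
    df["_steps"] = df["chain"].map(len)
    best = df.sort_values(["_score", "n_lv", "_steps"], kind="stable").iloc[0]
    return tuple(best["chain"]), int(best["n_lv"])


def regression_metrics(y_true, y_hat, y_train_mean: float) -> dict:
    """RMSEP and Q^2 = 1 - PRESS / total sum of squares about the training mean."""
    y_true = np.asarray(y_true, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y_true.size != y_hat.size or y_true.size < 2:
        raise ValueError("need aligned vectors with n >= 2")
    press = float(np.sum((y_true - y_hat) ** 2))
    tss = float(np.sum((y_true - y_train_mean) ** 2))
    if tss == 0:
        raise ValueError("zero total sum of squares about the training mean")
    return {
        "rmsep": float(np.sqrt(press / y_true.size)),
        "q2": 1.0 - press / tss,
    }
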