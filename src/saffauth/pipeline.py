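"""End-to-end experiments over a spectra matrix and its sample metadata.

Three experiment families mirror the study design:

* ``run_model_i`` — freshness PLS-DA on the pure materials only (fresh 2020,
  pure expired 2016, pure expired 2018), to verify that aging is visible.
* ``run_model_ii`` — compliance screening: three-class PLS-DA on everything
  (compliant plus both adulterated classes at 10-100 %), with the
  probabilistic Gaussian-crossing attribution rule; reported in terms of
  sensitivity / specificity of the compliant class.
* ``run_regression`` — per-vintage PLS regression of the adulteration level
  (% w/w); the pure expired samples (100 %) are excluded and the duplex split
  is stratified by level.

Every experiment duplex-splits 70/30 per stratum (distances on SNV-treated
spectra), selects the pre-treatment chain and latent-variable count by
stratified 5-fold cross-validation on the training set only, refits on the
full training set and evaluates on the untouched test set.  Reports are
reproducible bit-for-bit from (data, settings.seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import pls, plsda, select
from .preprocess import PretreatmentChain, snv
from .synth import Dataset, validate_axis
from .vip import VIPResult, vip_scores

__all__ = [
    "ExperimentSettings",
    "ExperimentReport",
    "run_model_i",
    "run_model_ii",
    "run_regression",
    "read_spectra",
]

MODEL_I_CLASSES = ("Fresh2020", "Aged2016", "Aged2018")
MODEL_II_CLASSES = ("Compliant", "Adulterated2016", "Adulterated2018")
REGRESSION_LEVELS = (0.0, 0.10, 0.25, 0.40)  # the 100% level is excluded


@dataclass(frozen=True)
class ExperimentSettings:
    test_fraction: float = 0.3
    cv_folds: int = 5
    lv_grid: tuple[int, ...] = tuple(range(1, 21))
    chain_candidates: tuple[tuple[str, ...], ...] = (("SNV", "MC"), ("D1", "SNV", "MC"))
    priors: str = "equal"
    seed: int = 0


@dataclass
class ExperimentReport:
    experiment: str
    class_order: tuple | None
    chain_steps: tuple[str, ...]
    n_lv: int
    cv_table: pd.DataFrame
    split: select.SplitResult  # indices into the experiment subset
    subset_index: np.ndarray  # rows of the full dataset used by the experiment
    metrics: dict
    predictions: pd.DataFrame
    model: pls.PLSModel
    chain: PretreatmentChain
    rules: dict | None = None
    vip: VIPResult | None = None
    explained_x_var: np.ndarray | None = None
    explained_y_var: np.ndarray | None = None
    settings: ExperimentSettings = field(default_factory=ExperimentSettings)


def _cap_grid(grid: Sequence[int], n_train: int, p: int, k: int) -> list[int]:
    # every CV fold must respect A <= min(n_fold_train - 1, p)
    cap = min(n_train - int(np.ceil(n_train / k)) - 1, p)
    out = [a for a in grid if a <= cap]
    if not out:
        raise ValueError("LV grid entirely above the rank bound")
    return out


def _run_classification(
    experiment: str,
    X: np.ndarray,
    labels: np.ndarray,
    axis: np.ndarray,
    settings: ExperimentSettings,
    class_order: tuple,
    split: select.SplitResult | None,
    subset_index: np.ndarray,
    meta: pd.DataFrame,
) -> ExperimentReport:
    for cls in class_order:
        if cls not in set(labels):
            raise ValueError(f"{experiment}: class {cls!r} missing from the data")
    if split is None:
        split = select.stratified_duplex(
            X, labels, settings.test_fraction, distance_transform=snv
        )
    tr, te = split.train_idx, split.test_idx
    grid = _cap_grid(settings.lv_grid, tr.size, X.shape[1], settings.cv_folds)
    cv = select.cross_validate(
        X[tr], labels[tr], axis, settings.chain_candidates, grid,
        mode="classification", k=settings.cv_folds, seed=settings.seed,
        class_order=class_order, priors=settings.priors,
    )
    chain_steps, n_lv = select.choose_model(cv, "classification")

    chain = PretreatmentChain(chain_steps)
    Xtr = chain.fit_transform(X[tr], axis)
    Xte = chain.transform(X[te], axis)
    Ytr = plsda.encode_dummy(labels[tr], class_order)
    model = pls.fit(Xtr, Ytr, n_lv)
    yhat_cal = pls.predict(model, Xtr)
    rules = plsda.fit_rules(yhat_cal, labels[tr], class_order, settings.priors)
    sets, post = plsda.attribute(rules, pls.predict(model, Xte), class_order)
    metrics = plsda.classification_metrics(sets, labels[te], class_order)

    cal_sets, _ = plsda.attribute(rules, yhat_cal, class_order)
    metrics["calibration"] = plsda.classification_metrics(cal_sets, labels[tr], class_order)

    pred = pd.DataFrame(
        {
            "sample_id": meta["sample_id"].to_numpy()[te],
            "true_label": labels[te],
            "attributed": ["+".join(sorted(s)) if s else "" for s in sets],
        }
    )
    for j, cls in enumerate(class_order):
        pred[f"posterior_{cls}"] = post[:, j]

    return ExperimentReport(
        experiment=experiment,
        class_order=class_order,
        chain_steps=chain_steps,
        n_lv=n_lv,
        cv_table=cv,
        split=split,
        subset_index=subset_index,
        metrics=metrics,
        predictions=pred,
        model=model,
        chain=chain,
        rules=rules,
        vip=vip_scores(model),
        explained_x_var=model.explained_x_var,
        explained_y_var=model.explained_y_var,
        settings=settings,
    )


def run_model_i(
    dataset: Dataset,
    settings: ExperimentSettings = ExperimentSettings(),
    split: select.SplitResult | None = None,
) -> ExperimentReport:
    """Freshness model on pure materials: fresh 2020 vs pure expired 2016/2018."""
    meta = dataset.meta
    pure = (meta["alpha"] == 0.0) | (meta["alpha"] == 1.0)
    idx = np.flatnonzero(pure.to_numpy())
    sub = meta.iloc[idx]
    labels = np.where(
        sub["alpha"].to_numpy() == 0.0,
        "Fresh2020",
        np.where(sub["vintage"].to_numpy() == 2016, "Aged2016", "Aged2018"),
    ).astype(object)
    return _run_classification(
        "model_i", dataset.X[idx], labels, dataset.axis, settings,
        MODEL_I_CLASSES, split, idx, sub.reset_index(drop=True),
    )


def run_model_ii(
    dataset: Dataset,
    settings: ExperimentSettings = ExperimentSettings(),
    split: select.SplitResult | None = None,
) -> ExperimentReport:
    """Compliance screening on all samples (mixtures and pure expired included)."""
    meta = dataset.meta
    idx = np.arange(len(meta))
    labels = meta["label"].to_numpy(dtype=object)
    return _run_classification(
        "model_ii", dataset.X, labels, dataset.axis, settings,
        MODEL_II_CLASSES, split, idx, meta,
    )


REGRESSION_CHAINS = (("D1", "SNV", "MC"), ("SNV", "MC"))


def run_regression(
    dataset: Dataset,
    vintage: int,
    settings: ExperimentSettings | None = None,
    split: select.SplitResult | None = None,
) -> ExperimentReport:
    """Adulteration-level PLS regression for one vintage, response in % w/w.

    Uses the compliant samples (0 %) and the vintage's mixtures at 10/25/40 %;
    pure expired stigmas (100 %) are excluded.  Duplex stratifies by level.
    """
    if vintage not in (2016, 2018):
        raise ValueError("vintage must be 2016 or 2018")
    if settings is None:
        settings = ExperimentSettings(chain_candidates=REGRESSION_CHAINS)
    meta = dataset.meta
    keep = (meta["label"] == "Compliant") | (
        (meta["vintage"] == vintage) & meta["alpha"].isin(REGRESSION_LEVELS)
    )
    keep &= meta["alpha"] < 1.0
    idx = np.flatnonzero(keep.to_numpy())
    sub = meta.iloc[idx]
    levels = sub["alpha"].to_numpy()
    present = sorted(set(np.round(levels, 6)))
    if present != sorted(REGRESSION_LEVELS):
        raise ValueError(
            f"regression needs levels {sorted(REGRESSION_LEVELS)}, found {present}"
        )
    y = levels * 100.0
    X = dataset.X[idx]
    axis = dataset.axis

    if split is None:
        split = select.stratified_duplex(
            X, levels, settings.test_fraction, distance_transform=snv
        )
    tr, te = split.train_idx, split.test_idx
    grid = _cap_grid(settings.lv_grid, tr.size, X.shape[1], settings.cv_folds)
    cv = select.cross_validate(
        X[tr], y[tr], axis, settings.chain_candidates, grid,
        mode="regression", k=settings.cv_folds, seed=settings.seed, strata=levels[tr],
    )
    chain_steps, n_lv = select.choose_model(cv, "regression")

    chain = PretreatmentChain(chain_steps)
    Xtr = chain.fit_transform(X[tr], axis)
    Xte = chain.transform(X[te], axis)
    model = pls.fit(Xtr, y[tr], n_lv)
    yhat = pls.predict(model, Xte)
    metrics = select.regression_metrics(y[te], yhat, float(y[tr].mean()))
    chosen = cv[(cv["chain"].map(tuple) == chain_steps) & (cv["n_lv"] == n_lv)]
    metrics["rmsecv"] = float(chosen["rmsecv"].iloc[0])

    pred = pd.DataFrame(
        {
            "sample_id": sub["sample_id"].to_numpy()[te],
            "measured_pct": y[te],
            "predicted_pct": yhat,
        }
    )
    return ExperimentReport(
        experiment=f"regression_{vintage}",
        class_order=None,
        chain_steps=chain_steps,
        n_lv=n_lv,
        cv_table=cv,
        split=split,
        subset_index=idx,
        metrics=metrics,
        predictions=pred,
        model=model,
        chain=chain,
        vip=vip_scores(model),
        explained_x_var=model.explained_x_var,
        explained_y_var=model.explained_y_var,
        settings=settings,
    )


def read_spectra(spectra_csv, metadata_csv) -> Dataset:
    """Read a spectra CSV (sample_id + wavenumber columns) and its metadata
    CSV, realigning metadata rows to the spectra by sample_id."""
    sp = pd.read_csv(spectra_csv)
    if sp.columns[0] != "sample_id":
        raise ValueError("first spectra column must be 'sample_id'")
    ids = sp["sample_id"].astype(str)
    if ids.duplicated().any():
        raise ValueError("duplicate sample_id in spectra file")
    try:
        axis = np.array([float(c) for c in sp.columns[1:]])
    except ValueError as exc:
        raise ValueError("non-numeric wavenumber column header") from exc
    axis = validate_axis(axis)
    try:
        X = sp.iloc[:, 1:].to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError("non-numeric absorbance cell in spectra file") from exc

    meta = pd.read_csv(metadata_csv)
    required = {"sample_id", "label", "alpha", "vintage", "batch"}
    if not required.issubset(meta.columns):
        raise ValueError(f"metadata must have columns {sorted(required)}")
    meta = meta.copy()
    meta["sample_id"] = meta["sample_id"].astype(str)
    if meta["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_id in metadata file")
    missing = set(ids) - set(meta["sample_id"])
    if missing:
        raise ValueError(f"sample_id(s) missing from metadata: {sorted(missing)[:5]}")
    meta = meta.set_index("sample_id").loc[ids].reset_index()
    return Dataset(X=X, meta=meta, axis=axis)
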