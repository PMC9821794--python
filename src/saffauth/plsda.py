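"""PLS-DA: dummy coding and the probabilistic Gaussian-crossing class rule.

Class membership is dummy-coded (class g of G -> a row with a single 1 in
column g) and the coded matrix regressed on the spectra by PLS.  Because
predicted responses are continuous, assignment uses a per-class probabilistic
rule: for every class, a Gaussian is fitted to the calibration responses of
the in-class samples and another to those of all remaining samples; the
decision threshold is the response where the two densities cross (the 50 %
point of the normalized probability), and the posterior of a new response is
f_in / (f_in + f_out).  A sample is attributed to every class whose posterior
exceeds 50 % — unless its response exceeds the largest calibration response
of that class, where the posterior would be an extrapolation and the class is
refused.  The rule therefore admits non-attributions and ambiguous
(multi-class) attributions.

Densities are unweighted by default (equal priors), mirroring two normalized
probability curves crossing at 50 %; ``priors="frequency"`` weights them by
the calibration class proportions instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.special import expit

__all__ = [
    "ClassRule",
    "encode_dummy",
    "fit_rules",
    "posterior",
    "attribute",
    "classification_metrics",
]


def encode_dummy(labels: Sequence, class_order: Sequence) -> np.ndarray:
    """Binary n x G membership matrix, one column per class in ``class_order``."""
    class_order = list(class_order)
    index = {c: j for j, c in enumerate(class_order)}
    Y = np.zeros((len(labels), len(class_order)))
    for i, lab in enumerate(labels):
        if lab not in index:
            raise ValueError(f"label {lab!r} not in class_order {class_order}")
        Y[i, index[lab]] = 1.0
    return Y


@dataclass(frozen=True)
class ClassRule:
    """In-class / out-of-class Gaussian pair for one response column."""

    class_label: object
    mu_in: float
    sd_in: float
    mu_out: float
    sd_out: float
    threshold: float  # response at the 50% posterior crossing
    y_cal_max: float  # largest calibration response of the class
    log_prior_in: float = 0.0
    log_prior_out: float = 0.0


def _crossing(mu_in, sd_in, mu_out, sd_out, log_prior_ratio) -> float:
    """Response where the two (possibly prior-weighted) densities are equal,
    taking the root between the two means — the decision boundary."""
    a2 = 0.5 * (1.0 / sd_out**2 - 1.0 / sd_in**2)
    a1 = mu_in / sd_in**2 - mu_out / sd_out**2
    a0 = (
        0.5 * (mu_out**2 / sd_out**2 - mu_in**2 / sd_in**2)
        + np.log(sd_out / sd_in)
        + log_prior_ratio
    )
    if abs(a2) < 1e-14:
        return float(-a0 / a1)
    roots = np.roots([a2, a1, a0])
    roots = roots[np.abs(roots.imag) < 1e-9].real
    inside = roots[(roots > mu_out) & (roots < mu_in)]
    if inside.size == 0:
        raise ValueError("no density crossing between the class means")
    return float(inside[0])


def fit_rules(
    y_cal_hat: np.ndarray,
    labels: Sequence,
    class_order: Sequence,
    priors: str = "equal",
) -> dict:
    """Fit the Gaussian pair of every class from calibration responses.

    ``y_cal_hat`` is the n x G matrix of fitted PLS-DA responses on the
    calibration set.  For class g, the in-group is column g restricted to the
    true class-g samples and the out-group pools all other samples.
    """
    y_cal_hat = np.asarray(y_cal_hat, dtype=float)
    labels = np.asarray(labels, dtype=object)
    if priors not in ("equal", "frequency"):
        raise ValueError("priors must be 'equal' or 'frequency'")
    rules = {}
    for j, cls in enumerate(class_order):
        in_mask = labels == cls
        y_in = y_cal_hat[in_mask, j]
        y_out = y_cal_hat[~in_mask, j]
        if y_in.size < 2 or y_out.size < 2:
            raise ValueError(f"need >= 2 samples on each side of class {cls!r}")
        mu_in, sd_in = float(y_in.mean()), float(y_in.std(ddof=1))
        mu_out, sd_out = float(y_out.mean()), float(y_out.std(ddof=1))
        if sd_in <= 0 or sd_out <= 0:
            raise ValueError(f"degenerate response variance for class {cls!r}")
        if mu_in <= mu_out:
            raise ValueError(
                f"class {cls!r}: in-class mean response does not exceed the "
                "out-of-class mean; the dummy coding did not separate"
            )
        if priors == "frequency":
            lp_in = float(np.log(in_mask.mean()))
            lp_out = float(np.log(1.0 - in_mask.mean()))
        else:
            lp_in = lp_out = 0.0
        thr = _crossing(mu_in, sd_in, mu_out, sd_out, lp_in - lp_out)
        rules[cls] = ClassRule(
            class_label=cls, mu_in=mu_in, sd_in=sd_in, mu_out=mu_out,
            sd_out=sd_out, threshold=thr,
            y_cal_max=float(y_cal_hat[:, j].max()),
            log_prior_in=lp_in, log_prior_out=lp_out,
        )
    return rules


def posterior(rule: ClassRule, y_hat) -> np.ndarray | float:
    """Posterior probability f_in / (f_in + f_out) of the class at response(s)
    ``y_hat``; computed as a numerically stable sigmoid of the log-density
    difference."""
    y = np.asarray(y_hat, dtype=float)
    g = (
        rule.log_prior_in - rule.log_prior_out
        + np.log(rule.sd_out / rule.sd_in)
        - (y - rule.mu_in) ** 2 / (2 * rule.sd_in**2)
        + (y - rule.mu_out) ** 2 / (2 * rule.sd_out**2)
    )
    post = expit(g)
    return float(post) if np.isscalar(y_hat) else post


def attribute(
    rules: Mapping, y_hat_new: np.ndarray, class_order: Sequence
) -> tuple[list[frozenset], np.ndarray]:
    """Attribute each sample to every class with posterior > 0.5 whose response
    does not exceed the class's calibration maximum.  Returns the per-sample
    attribution sets (possibly empty or multi-class) and the posterior matrix.
    """
    Y = np.atleast_2d(np.asarray(y_hat_new, dtype=float))
    post = np.column_stack(
        [posterior(rules[c], Y[:, j]) for j, c in enumerate(class_order)]
    )
    sets = []
    for i in range(Y.shape[0]):
        accepted = {
            c
            for j, c in enumerate(class_order)
            if post[i, j] > 0.5 and Y[i, j] <= rules[c].y_cal_max
        }
        sets.append(frozenset(accepted))
    return sets, post


def classification_metrics(
    attributions: Sequence[frozenset], true_labels: Sequence, class_order: Sequence
) -> dict:
    """Per-class sensitivity / specificity / CCR and the unweighted mean CCR.

    sensitivity(G): fraction of true-G samples whose set contains G;
    specificity(G): fraction of non-G samples whose set excludes G;
    CCR(G): fraction of true-G samples attributed uniquely and correctly to G.
    """
    true_labels = np.asarray(true_labels, dtype=object)
    for cls in class_order:
        if not np.any(true_labels == cls):
            raise ValueError(f"class {cls!r} absent from the true labels")
    per_class = {}
    for cls in class_order:
        in_mask = true_labels == cls
        sens = np.mean([cls in s for s, m in zip(attributions, in_mask) if m])
        spec = np.mean([cls not in s for s, m in zip(attributions, in_mask) if not m])
        ccr = np.mean([s == frozenset({cls}) for s, m in zip(attributions, in_mask) if m])
        per_class[cls] = {
            "sensitivity": float(sens),
            "specificity": float(spec),
            "ccr": float(ccr),
        }
    mean_ccr = float(np.mean([v["ccr"] for v in per_class.values()]))
    return {"per_class": per_class, "mean_ccr": mean_ccr}
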