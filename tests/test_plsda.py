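"""PLS-DA tests: dummy coding, the Gaussian-crossing rule, attribution,
classification figures of merit."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from saffauth.plsda import (
    ClassRule,
    attribute,
    classification_metrics,
    encode_dummy,
    fit_rules,
    posterior,
)


class TestDummyCoding:
    def test_printed_coding(self):
        Y = encode_dummy(["a", "c", "b"], ["a", "b", "c"])
        np.testing.assert_array_equal(Y, [[1, 0, 0], [0, 0, 1], [0, 1, 0]])

    def test_column_sums_count_classes(self):
        labels = ["x"] * 5 + ["y"] * 3
        Y = encode_dummy(labels, ["x", "y"])
        assert Y.sum(axis=0).tolist() == [5, 3]
        assert np.all(Y.sum(axis=1) == 1)

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="label"):
            encode_dummy(["a", "z"], ["a", "b"])


def two_class_responses(mu_in, sd_in, mu_out, sd_out, n=40, seed=0):
    """Calibration responses for one focus class 'G' vs rest 'H'."""
    rng = np.random.default_rng(seed)
    y_in = mu_in + sd_in * standardize(rng.normal(size=n))
    y_out = mu_out + sd_out * standardize(rng.normal(size=n))
    yhat = np.concatenate([y_in, y_out])[:, None]
    yhat = np.hstack([yhat, 1.0 - yhat])
    labels = np.array(["G"] * n + ["H"] * n, dtype=object)
    return yhat, labels


def standardize(x):
    return (x - x.mean()) / x.std(ddof=1)


class TestRuleFitting:
    def test_symmetric_gaussians_cross_at_midpoint(self):
        yhat, labels = two_class_responses(1.0, 0.1, 0.0, 0.1)
        rule = fit_rules(yhat, labels, ["G", "H"])["G"]
        assert rule.threshold == pytest.approx(0.5, abs=1e-10)
        assert posterior(rule, 0.5) == pytest.approx(0.5, abs=1e-10)

    def test_unequal_sds_root_lies_between_means(self):
        yhat, labels = two_class_responses(1.0, 0.3, 0.0, 0.1)
        rule = fit_rules(yhat, labels, ["G", "H"])["G"]
        assert 0.0 < rule.threshold < 1.0
        # the two (unweighted) densities really are equal at the threshold
        f = lambda y, mu, sd: np.exp(-((y - mu) ** 2) / (2 * sd**2)) / sd
        assert f(rule.threshold, rule.mu_in, rule.sd_in) == pytest.approx(
            f(rule.threshold, rule.mu_out, rule.sd_out), rel=1e-8
        )

    def test_posterior_at_threshold_is_half(self):
        yhat, labels = two_class_responses(1.0, 0.25, -0.2, 0.12, seed=5)
        rule = fit_rules(yhat, labels, ["G", "H"])["G"]
        assert posterior(rule, rule.threshold) == pytest.approx(0.5, abs=1e-9)

    def test_degenerate_variance_rejected(self):
        yhat = np.array([[1.0, 0], [1.0, 0], [0.0, 1], [0.1, 1]])
        labels = np.array(["G", "G", "H", "H"], dtype=object)
        with pytest.raises(ValueError, match="variance"):
            fit_rules(yhat, labels, ["G", "H"])

    def test_inverted_means_rejected(self):
        yhat, labels = two_class_responses(0.0, 0.1, 1.0, 0.1)
        with pytest.raises(ValueError, match="mean"):
            fit_rules(yhat, labels, ["G", "H"])

    def test_frequency_priors_shift_threshold_toward_minority(self):
        yhat, labels = two_class_responses(1.0, 0.15, 0.0, 0.15, n=40)
        # drop most of the in-class side: frequency prior penalizes it
        keep = np.r_[np.arange(8), np.arange(40, 80)]
        eq = fit_rules(yhat[keep], labels[keep], ["G", "H"], priors="equal")["G"]
        fr = fit_rules(yhat[keep], labels[keep], ["G", "H"], priors="frequency")["G"]
        assert fr.threshold > eq.threshold

    def test_max_calibration_response_recorded(self):
        yhat, labels = two_class_responses(1.0, 0.1, 0.0, 0.1)
        rule = fit_rules(yhat, labels, ["G", "H"])["G"]
        assert rule.y_cal_max == yhat[:, 0].max()


class TestPosterior:
    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(
        sd_in=st.floats(0.05, 0.5),
        sd_out=st.floats(0.05, 0.5),
        gap=st.floats(0.2, 2.0),
    )
    def test_monotone_between_the_means(self, sd_in, sd_out, gap):
        rule = ClassRule("G", gap, sd_in, 0.0, sd_out, gap / 2, gap + 1.0)
        grid = np.linspace(0.0, gap, 201)
        post = posterior(rule, grid)
        # non-decreasing everywhere (the sigmoid may saturate in floats),
        # rising overall from the out-group mean to the in-group mean
        assert np.all(np.diff(post) >= 0)
        assert post[0] < 0.5 < post[-1]

    def test_vanishes_far_below_the_out_group(self):
        rule = ClassRule("G", 1.0, 0.1, 0.0, 0.1, 0.5, 2.0)
        assert posterior(rule, -5.0) < 1e-6


class TestAttribution:
    def make_rules(self):
        return {
            "G": ClassRule("G", 1.0, 0.1, 0.0, 0.1, 0.5, 1.2),
            "H": ClassRule("H", 1.0, 0.1, 0.0, 0.1, 0.5, 1.2),
        }

    def test_clear_sample_gets_single_class(self):
        sets, post = attribute(self.make_rules(), np.array([[1.0, 0.0]]), ["G", "H"])
        assert sets[0] == frozenset({"G"})
        assert post[0, 0] > 0.99

    def test_extrapolation_above_calibration_max_is_refused(self):
        # response beyond anything seen in calibration: high density but no
        # trustworthy posterior, the class must refuse the sample
        sets, post = attribute(self.make_rules(), np.array([[1.5, 0.0]]), ["G", "H"])
        assert post[0, 0] > 0.99
        assert sets[0] == frozenset()

    def test_all_posteriors_low_gives_empty_set(self):
        sets, _ = attribute(self.make_rules(), np.array([[0.45, 0.45]]), ["G", "H"])
        assert sets[0] == frozenset()

    def test_ambiguous_sample_gets_both_classes(self):
        sets, _ = attribute(self.make_rules(), np.array([[0.9, 0.9]]), ["G", "H"])
        assert sets[0] == frozenset({"G", "H"})


class TestMetrics:
    def test_all_correct_unique_attributions(self):
        labels = ["a", "a", "b", "b"]
        sets = [frozenset({l}) for l in labels]
        m = classification_metrics(sets, labels, ["a", "b"])
        assert m["mean_ccr"] == 1.0
        for v in m["per_class"].values():
            assert v == {"sensitivity": 1.0, "specificity": 1.0, "ccr": 1.0}

    def test_one_false_acceptance_among_twenty(self):
        labels = ["G"] * 4 + ["H"] * 20
        sets = [frozenset({"G"})] * 4 + [frozenset({"G"})] + [frozenset({"H"})] * 19
        m = classification_metrics(sets, labels, ["G", "H"])
        assert m["per_class"]["G"]["specificity"] == pytest.approx(0.95)

    def test_non_attribution_lowers_sensitivity_not_specificity(self):
        # hand-counted 6-sample truth table
        labels = ["G", "G", "G", "H", "H", "H"]
        sets = [frozenset({"G"}), frozenset(), frozenset({"G"}),
                frozenset({"H"}), frozenset({"H"}), frozenset({"H"})]
        m = classification_metrics(sets, labels, ["G", "H"])
        assert m["per_class"]["G"]["sensitivity"] == pytest.approx(2 / 3)
        assert m["per_class"]["G"]["ccr"] == pytest.approx(2 / 3)
        assert m["per_class"]["G"]["specificity"] == 1.0
        assert m["mean_ccr"] == pytest.approx((2 / 3 + 1.0) / 2)

    def test_ambiguous_attribution_counts_for_sensitivity_not_ccr(self):
        labels = ["G", "H"]
        sets = [frozenset({"G", "H"}), frozenset({"H"})]
        m = classification_metrics(sets, labels, ["G", "H"])
        assert m["per_class"]["G"]["sensitivity"] == 1.0
        assert m["per_class"]["G"]["ccr"] == 0.0

    def test_absent_class_rejected(self):
        with pytest.raises(ValueError, match="absent"):
            classification_metrics([frozenset({"a"})], ["a"], ["a", "b"])
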