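"""Generator tests: axis, profiles, mixtures, design counts, artifacts."""

from dataclasses import replace

import numpy as np
import pytest

import saffauth as sa
from saffauth.synth import (
    Band,
    GeneratorConfig,
    default_axis,
    default_config,
    generate_dataset,
    mixture_profile,
    pure_profile,
)

AXIS = default_axis()


def no_artifact(config):
    return replace(
        config,
        noise_sd=0.0,
        scatter_sd=0.0,
        batch_jitter_sd=0.0,
        baseline_offset_range=(0.0, 0.0),
        baseline_slope_range=(0.0, 0.0),
    )


class TestAxis:
    def test_instrument_grid(self):
        assert AXIS.size == 876
        assert AXIS[0] == 4000.0 and AXIS[-1] == 500.0
        assert np.all(np.diff(AXIS) == -4.0)

    def test_invalid_axes_rejected(self):
        from saffauth.synth import validate_axis

        with pytest.raises(ValueError):
            validate_axis(np.array([500.0, 1000.0, 1500.0]))  # increasing
        with pytest.raises(ValueError):
            validate_axis(np.array([4000.0, 3990.0, 3985.0]))  # uneven


class TestProfiles:
    def test_zero_bands_gives_zero_spectrum(self):
        cfg = GeneratorConfig(bands=(), design=())
        assert np.all(pure_profile("fresh", AXIS, cfg) == 0.0)

    def test_single_band_peak_equals_amplitude(self):
        band = Band(2000.0, 10.0, 0.7, {"fresh": 1.0})
        cfg = GeneratorConfig(bands=(band,), design=())
        prof = pure_profile("fresh", AXIS, cfg)
        assert prof[AXIS == 2000.0][0] == pytest.approx(0.7)

    def test_unknown_condition_rejected(self):
        with pytest.raises(ValueError, match="condition"):
            pure_profile("aged1999", AXIS, default_config())

    def test_aging_changes_point_the_right_way(self):
        """Sugar/glycosidic band weaker and carbonyl shoulder stronger in the
        expired material, the hydrolysis signature of saffron aging."""
        cfg = default_config()
        fresh = pure_profile("fresh", AXIS, cfg)
        aged = pure_profile("aged2016", AXIS, cfg)
        at = lambda wn: np.argmin(np.abs(AXIS - wn))
        assert fresh[at(1051)] > aged[at(1051)]
        assert aged[at(1730)] > fresh[at(1730)]

    def test_noise_free_profiles_nonnegative(self):
        cfg = default_config()
        for cond in ("fresh", "aged2016", "aged2018"):
            assert np.all(pure_profile(cond, AXIS, cfg) >= 0.0)


class TestMixture:
    @pytest.mark.parametrize("vintage", [2016, 2018])
    def test_endpoints_and_linearity(self, vintage):
        cfg = default_config()
        fresh = pure_profile("fresh", AXIS, cfg)
        aged = pure_profile(f"aged{vintage}", AXIS, cfg)
        np.testing.assert_allclose(mixture_profile(0.0, vintage, AXIS, cfg), fresh)
        np.testing.assert_allclose(mixture_profile(1.0, vintage, AXIS, cfg), aged)
        np.testing.assert_allclose(
            mixture_profile(0.5, vintage, AXIS, cfg), 0.5 * (fresh + aged)
        )

    def test_alpha_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            mixture_profile(1.2, 2016, AXIS, default_config())
        with pytest.raises(ValueError):
            mixture_profile(-0.1, 2016, AXIS, default_config())


class TestGenerateDataset:
    def test_default_design_counts(self, default_dataset):
        """The study design: 334 samples, 112 compliant, 112 adulterated with
        the 2016 vintage (20 pure + 30/30/32 mixtures), 110 with 2018."""
        meta = default_dataset.meta
        assert default_dataset.X.shape == (334, 876)
        assert meta["label"].value_counts().to_dict() == {
            "Compliant": 112,
            "Adulterated2016": 112,
            "Adulterated2018": 110,
        }
        counts = meta.groupby(["label", "alpha"]).size().to_dict()
        assert counts[("Adulterated2016", 1.0)] == 20
        assert counts[("Adulterated2016", 0.40)] == 30
        assert counts[("Adulterated2016", 0.25)] == 30
        assert counts[("Adulterated2016", 0.10)] == 32
        assert counts[("Adulterated2018", 1.0)] == 20
        assert counts[("Adulterated2018", 0.40)] == 30
        assert counts[("Adulterated2018", 0.25)] == 30
        assert counts[("Adulterated2018", 0.10)] == 30
        # five compliant batches of ~22 analyses
        comp = meta[meta["label"] == "Compliant"]
        assert sorted(comp.groupby("batch").size()) == [22, 22, 22, 23, 23]

    def test_seeded_determinism(self, small_config):
        a = generate_dataset(small_config)
        b = generate_dataset(small_config)
        assert np.array_equal(a.X, b.X)
        assert a.meta.equals(b.meta)
        c = generate_dataset(small_config.with_seed(8))
        assert not np.array_equal(a.X, c.X)

    def test_artifacts_disabled_reproduce_profiles_exactly(self, small_config):
        cfg = no_artifact(small_config)
        ds = generate_dataset(cfg)
        for i, row in ds.meta.iterrows():
            if row["alpha"] == 0.0:
                expect = pure_profile("fresh", ds.axis, cfg)
            else:
                expect = mixture_profile(row["alpha"], row["vintage"], ds.axis, cfg)
            np.testing.assert_allclose(ds.X[i], expect, atol=1e-12)

    def test_alpha_recoverable_by_least_squares(self, small_config):
        """Without artifacts every mixture is a convex combination of the two
        endpoints, so projecting onto the aged-minus-fresh direction returns
        the exact mass fraction."""
        cfg = no_artifact(small_config)
        ds = generate_dataset(cfg)
        fresh = pure_profile("fresh", ds.axis, cfg)
        for vintage in (2016, 2018):
            aged = pure_profile(f"aged{vintage}", ds.axis, cfg)
            d = aged - fresh
            sel = ds.meta["vintage"] == vintage
            alphas = (ds.X[sel.to_numpy()] - fresh) @ d / (d @ d)
            np.testing.assert_allclose(
                alphas, ds.meta.loc[sel, "alpha"].to_numpy(), atol=1e-10
            )

    def test_class_mean_converges_to_profile(self):
        """The artifact model is unbiased apart from the known mean baseline
        offset: averaging many fresh replicates recovers profile + E[offset]."""
        from saffauth.synth import DesignGroup, default_bands

        cfg = GeneratorConfig(
            bands=default_bands(),
            design=(DesignGroup("Compliant", 0.0, 2020, (200,)),),
            batch_jitter_sd=0.0,
            seed=3,
        )
        ds = generate_dataset(cfg)
        expect = pure_profile("fresh", ds.axis, cfg) + 0.025  # mean U(0, 0.05)
        se = ds.X.std(axis=0, ddof=1) / np.sqrt(ds.X.shape[0])
        frac_within = np.mean(np.abs(ds.X.mean(axis=0) - expect) < 3 * se)
        assert frac_within > 0.99
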