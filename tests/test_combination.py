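"""Combination index, interaction bands, isobolograms, CI bootstrap."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from enzymix import (
    MixtureTruth,
    ci_bootstrap,
    classify_interaction,
    combination_index,
    fit_median_effect,
    generate_mixture_series,
    isobologram_points,
)
from enzymix.combination import combination_report, ratio_fractions
from enzymix.errors import BootstrapError, InputError

RATIOS = ((1, 4), (4, 1), (3, 2), (2, 3), (1, 1))


def pipeline_ci(truth, x=0.5, **gen_kwargs):
    s1, s2, mixes = generate_mixture_series(truth, **gen_kwargs)
    f1, f2 = fit_median_effect(s1), fit_median_effect(s2)
    return [combination_index(f1, f2, mix, x) for mix in mixes]


class TestCombinationIndex:
    def test_sham_combination_is_unity_at_every_ratio_and_level(self):
        truth = MixtureTruth(dm1=0.22, dm2=0.22, m1=1.0, m2=1.0, psi=1.0,
                             ratios=RATIOS)
        for x in (0.3, 0.5, 0.7):
            for res in pipeline_ci(truth, x=x):
                assert res.ci == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize("psi", [0.25, 0.5, 1.0, 1.5, 2.5])
    def test_noise_free_interaction_index_recovery(self, psi):
        truth = MixtureTruth(dm1=0.10, dm2=0.69, m1=1.0, m2=1.0, psi=psi,
                             ratios=RATIOS)
        for x in (0.3, 0.5, 0.7):
            for res in pipeline_ci(truth, x=x):
                assert res.ci == pytest.approx(psi, abs=1e-6)

    def test_strong_synergy_truth_recovered(self):
        (res,) = pipeline_ci(MixtureTruth(dm1=0.10, dm2=0.69, psi=0.24,
                                          ratios=((1, 1),)))
        assert res.ci == pytest.approx(0.24, abs=1e-6)
        assert res.label == "strong synergism"

    def test_antagonism_truth_recovered(self):
        (res,) = pipeline_ci(MixtureTruth(dm1=0.10, dm2=0.69, psi=2.15,
                                          ratios=((1, 1),)))
        assert res.ci == pytest.approx(2.15, abs=1e-6)
        assert res.label == "antagonism"

    def test_eq1_identity_dri(self):
        for psi in (0.3, 1.0, 2.0):
            for res in pipeline_ci(MixtureTruth(dm1=0.1, dm2=0.7, psi=psi,
                                                ratios=RATIOS)):
                assert res.ci == pytest.approx(1 / res.dri1 + 1 / res.dri2,
                                               abs=1e-12)

    def test_symmetry_under_agent_swap(self):
        truth_fwd = MixtureTruth(dm1=0.10, dm2=0.69, psi=0.5, ratios=((3, 2),))
        truth_rev = MixtureTruth(dm1=0.69, dm2=0.10, psi=0.5, ratios=((2, 3),))
        (fwd,) = pipeline_ci(truth_fwd)
        (rev,) = pipeline_ci(truth_rev)
        assert fwd.ci == pytest.approx(rev.ci, rel=1e-9)

    def test_monotone_in_interaction_index(self):
        cis = [pipeline_ci(MixtureTruth(dm1=0.1, dm2=0.7, psi=p,
                                        ratios=((1, 1),)))[0].ci
               for p in (0.25, 0.5, 1.0, 1.5, 2.5)]
        assert np.all(np.diff(cis) > 0)

    @pytest.mark.parametrize("x", [0.0, 1.0, 2.0])
    def test_effect_level_must_be_fraction(self, x):
        truth = MixtureTruth(dm1=0.1, dm2=0.7, ratios=((1, 1),))
        s1, s2, (mix,) = generate_mixture_series(truth)
        with pytest.raises(InputError):
            combination_index(fit_median_effect(s1), fit_median_effect(s2), mix, x)


class TestInteractionBands:
    # all nine printed (CI, label) pairs from the study's three assays
    @pytest.mark.parametrize("ci,label", [
        (0.98, "nearly additive"),
        (0.24, "strong synergism"),
        (0.46, "synergism"),
        (0.53, "synergism"),
        (0.48, "synergism"),
        (2.15, "antagonism"),
        (0.63, "synergism"),
        (0.69, "synergism"),
        (2.21, "antagonism"),
    ])
    def test_published_pairs(self, ci, label):
        assert classify_interaction(ci) == label

    @pytest.mark.parametrize("ci,label", [
        (0.05, "very strong synergism"), (0.75, "moderate synergism"),
        (0.87, "slight synergism"), (1.0, "nearly additive"),
        (1.15, "slight antagonism"), (1.3, "moderate antagonism"),
        (5.0, "strong antagonism"), (20.0, "very strong antagonism"),
    ])
    def test_remaining_bands(self, ci, label):
        assert classify_interaction(ci) == label

    @pytest.mark.parametrize("bad", [0.0, -1.0, float("nan"), float("inf")])
    def test_invalid_ci(self, bad):
        with pytest.raises(InputError):
            classify_interaction(bad)

    @given(st.floats(0.01, 50.0))
    @settings(max_examples=100, deadline=None)
    def test_bands_are_monotone(self, ci):
        order = ["very strong synergism", "strong synergism", "synergism",
                 "moderate synergism", "slight synergism", "nearly additive",
                 "slight antagonism", "moderate antagonism", "antagonism",
                 "strong antagonism", "very strong antagonism"]
        a = order.index(classify_interaction(ci))
        b = order.index(classify_interaction(min(ci * 1.2, 50.0)))
        assert b >= a


class TestIsobologram:
    def test_additive_points_on_unit_antidiagonal(self):
        results = pipeline_ci(MixtureTruth(dm1=0.1, dm2=0.7, psi=1.0, ratios=RATIOS))
        pts = isobologram_points(results)
        np.testing.assert_allclose(pts["u"] + pts["v"], 1.0, atol=1e-6)

    def test_sham_ratio_coordinates(self):
        truth = MixtureTruth(dm1=0.22, dm2=0.22, psi=1.0, ratios=((1, 4), (4, 1)))
        r14, r41 = pipeline_ci(truth)
        assert r14.isobole_point == pytest.approx((0.2, 0.8), abs=1e-6)
        assert r41.isobole_point == pytest.approx((0.8, 0.2), abs=1e-6)

    def test_synergy_points_on_half_antidiagonal(self):
        results = pipeline_ci(MixtureTruth(dm1=0.1, dm2=0.7, psi=0.5, ratios=RATIOS))
        pts = isobologram_points(results)
        np.testing.assert_allclose(pts["u"] + pts["v"], 0.5, atol=1e-6)

    def test_below_antidiagonal_iff_synergistic(self):
        for psi in (0.4, 1.6):
            pts = isobologram_points(pipeline_ci(
                MixtureTruth(dm1=0.1, dm2=0.7, psi=psi, ratios=RATIOS)))
            below = (pts["u"] + pts["v"] < 1.0).all()
            assert below == (psi < 1.0)

    def test_empty_results_rejected(self):
        with pytest.raises(InputError):
            isobologram_points([])


class TestRatioFractions:
    def test_equal_stocks(self):
        assert ratio_fractions((3, 2)) == pytest.approx((0.6, 0.4))

    def test_unequal_stocks(self):
        assert ratio_fractions((1, 1), stocks_mM=(2.0, 1.0)) == pytest.approx((2 / 3, 1 / 3))

    @pytest.mark.parametrize("ratio", [(0, 1), (-1, 2)])
    def test_invalid_ratio(self, ratio):
        with pytest.raises(InputError):
            ratio_fractions(ratio)


class TestCiBootstrap:
    def test_noise_free_sd_zero(self):
        truth = MixtureTruth(dm1=0.1, dm2=0.7, psi=1.0, ratios=((1, 1),))
        s1, s2, (mix,) = generate_mixture_series(truth, replicates=3)
        assert ci_bootstrap(s1, s2, mix, n_boot=100, seed=0) == pytest.approx(0.0, abs=1e-12)

    def test_same_seed_identical_sd(self):
        truth = MixtureTruth(dm1=0.1, dm2=0.7, psi=1.0, noise_cv=0.05, seed=3,
                             ratios=((1, 1),))
        s1, s2, (mix,) = generate_mixture_series(truth, replicates=3)
        a = ci_bootstrap(s1, s2, mix, n_boot=200, seed=11)
        b = ci_bootstrap(s1, s2, mix, n_boot=200, seed=11)
        assert a == b > 0

    def test_single_replicate_unavailable(self):
        truth = MixtureTruth(dm1=0.1, dm2=0.7, ratios=((1, 1),))
        s1, s2, (mix,) = generate_mixture_series(truth, replicates=1)
        with pytest.raises(BootstrapError):
            ci_bootstrap(s1, s2, mix, n_boot=100, seed=0)

    def test_small_b_warns(self):
        truth = MixtureTruth(dm1=0.1, dm2=0.7, noise_cv=0.02, seed=1, ratios=((1, 1),))
        s1, s2, (mix,) = generate_mixture_series(truth, replicates=3)
        with pytest.warns(UserWarning, match="small"):
            ci_bootstrap(s1, s2, mix, n_boot=40, seed=0)

    def test_sd_tracks_monte_carlo_truth(self):
        """Median bootstrap SD within 30% of the across-simulation SD of CI."""
        def one_ci(seed):
            truth = MixtureTruth(dm1=0.1, dm2=0.7, psi=1.0, noise_cv=0.05,
                                 seed=seed, ratios=((1, 1),))
            s1, s2, (mix,) = generate_mixture_series(truth, replicates=3)
            res = combination_index(fit_median_effect(s1), fit_median_effect(s2), mix)
            return res.ci, (s1, s2, mix)
        cis, boot_sds = [], []
        for seed in range(200):
            ci, data = one_ci(seed)
            cis.append(ci)
            if seed < 30:
                boot_sds.append(ci_bootstrap(*data, n_boot=300, seed=0))
        mc_sd = np.std(cis, ddof=1)
        assert abs(np.median(boot_sds) - mc_sd) / mc_sd < 0.30


class TestCombinationReport:
    def test_per_ratio_rows_plus_mean_summary(self):
        results = pipeline_ci(MixtureTruth(dm1=0.1, dm2=0.7, psi=0.5, ratios=RATIOS))
        df = combination_report(results)
        assert len(df) == len(RATIOS) + 1
        mean_row = df[df["ratio"] == "mean"].iloc[0]
        assert mean_row["ci"] == pytest.approx(0.5, abs=1e-6)
        assert mean_row["label"] == "synergism"
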