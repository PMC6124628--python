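"""Tests of the model-averaging core against naive direct implementations."""

import itertools

import numpy as np
import pytest
from scipy.stats import chi2, norm

from hpmr import (
    SummarizedData,
    build_mixture,
    enumerate_subsets,
    hpma_estimate,
    ivw,
    loglik,
    make_fixture,
    mode_and_ci,
    ratio_estimates,
    subset_ivw,
    subset_log_weight,
)
from hpmr.hpma import CausalResult
from hpmr.io import ValidationError
from conftest import random_summarized


def naive_subset_quantities(data, psi_scale="sd"):
    """Direct per-subset loops: subset IVW, over-dispersion, raw weights.

    Deliberately naive - explicit sums and plain products on the natural
    scale - to serve as an independent oracle for the vectorized log-space
    implementation.
    """
    r = ratio_estimates(data)
    out = []
    for size in range(2, data.J + 1):
        for combo in itertools.combinations(range(data.J), size):
            num = sum(r.theta[j] / r.se_theta[j] ** 2 for j in combo)
            den = sum(1.0 / r.se_theta[j] ** 2 for j in combo)
            theta_k = num / den
            q = sum(
                (data.beta_y[j] - theta_k * data.beta_x[j]) ** 2 / data.se_y[j] ** 2
                for j in combo
            )
            ratio = q / (len(combo) - 1)
            psi = max(1.0, np.sqrt(ratio) if psi_scale == "sd" else ratio)
            se_re = psi / np.sqrt(den)
            w = 1.0
            for j in combo:
                w *= (1.0 / r.se_theta[j]) * np.exp(
                    -((r.theta[j] - theta_k) ** 2) / (2.0 * r.se_theta[j] ** 2)
                )
            out.append((combo, theta_k, psi, se_re, w))
    return out


class TestEnumerateSubsets:
    @pytest.mark.parametrize("J,count", [(2, 1), (3, 4), (5, 26), (10, 1013)])
    def test_model_count_is_2J_minus_J_minus_1(self, J, count):
        masks = enumerate_subsets(J)
        assert masks.shape == (count, J)
        assert masks.sum(axis=1).min() >= 2
        # each subset exactly once
        assert len({tuple(row) for row in masks}) == count

    def test_three_variant_subsets_explicit(self):
        masks = enumerate_subsets(3)
        got = {tuple(np.flatnonzero(m)) for m in masks}
        assert got == {(0, 1), (0, 2), (1, 2), (0, 1, 2)}

    def test_cap_raises_with_guidance(self):
        with pytest.raises(ValidationError, match="cap"):
            enumerate_subsets(25)


class TestSubsetIVW:
    def test_zero_heterogeneity_subset(self):
        bx = np.array([0.4, 0.5, 0.6])
        d = SummarizedData(("a", "b", "c"), bx, 0.3 * bx, np.full(3, 0.05))
        theta_k, psi, se_re = subset_ivw(d, np.array([True, True, True]))
        assert theta_k == pytest.approx(0.3)
        assert psi == pytest.approx(1.0)
        w = (bx / 0.05) ** 2
        assert se_re == pytest.approx(1.0 / np.sqrt(w.sum()))

    def test_full_mask_matches_random_effects_ivw(self, valid_fixture):
        theta_k, psi, se_re = subset_ivw(
            valid_fixture, np.ones(valid_fixture.J, bool)
        )
        res = ivw(valid_fixture, model="random")
        assert theta_k == pytest.approx(res.estimate, rel=1e-12)
        assert psi == pytest.approx(res.psi, rel=1e-12)
        assert se_re == pytest.approx(res.se, rel=1e-12)

    def test_three_variant_hand_summation(self):
        d = SummarizedData(
            ("a", "b", "c"),
            beta_x=np.array([0.5, 0.4, 0.25]),
            beta_y=np.array([0.15, 0.2, 0.05]),
            se_y=np.array([0.04, 0.05, 0.03]),
        )
        mask = np.array([True, True, True])
        (combo, theta_k, psi, se_re, _), = [
            t for t in naive_subset_quantities(d) if t[0] == (0, 1, 2)
        ]
        got = subset_ivw(d, mask)
        assert got[0] == pytest.approx(theta_k, rel=1e-12)
        assert got[1] == pytest.approx(psi, rel=1e-12)
        assert got[2] == pytest.approx(se_re, rel=1e-12)


class TestSubsetLogWeight:
    def test_homogeneous_subset_weight_is_product_of_inverse_ses(self):
        bx = np.array([0.4, 0.5])
        d = SummarizedData(("a", "b"), bx, 0.3 * bx, np.full(2, 0.05))
        r = ratio_estimates(d)
        mask = np.array([True, True])
        theta_k, _, _ = subset_ivw(d, mask)
        lw = subset_log_weight(d, mask, theta_k)
        assert lw == pytest.approx(-np.sum(np.log(r.se_theta)), rel=1e-12)

    def test_far_outlier_strictly_decreases_weight_term(self):
        d = SummarizedData(
            ("a", "b", "c"),
            beta_x=np.array([0.5, 0.5, 0.5]),
            beta_y=np.array([0.15, 0.15, 0.45]),
            se_y=np.full(3, 0.02),
        )
        pair = np.array([True, True, False])
        full = np.array([True, True, True])
        lw_pair = subset_log_weight(d, pair, subset_ivw(d, pair)[0])
        lw_full = subset_log_weight(d, full, subset_ivw(d, full)[0])
        # the third inverse-se factor alone would add -log(se); heterogeneity
        # penalty overwhelms it
        assert lw_full < lw_pair

    def test_exp_log_weight_matches_direct_product(self):
        rng = np.random.default_rng(11)
        d = random_summarized(rng, 4)
        naive = naive_subset_quantities(d)
        for combo, theta_k, _, _, w in naive:
            mask = np.zeros(4, bool)
            mask[list(combo)] = True
            assert np.exp(subset_log_weight(d, mask, theta_k)) == pytest.approx(
                w, rel=1e-12
            )


class TestBuildMixture:
    def test_two_variants_single_component_weight_one(self):
        d = SummarizedData(("a", "b"), [0.5, 0.3], [0.3, 0.05], [0.05, 0.04])
        mix = build_mixture(d)
        assert mix.n_components == 1
        assert np.exp(mix.log_weights_norm[0]) == pytest.approx(1.0)

    def test_weights_sum_to_one(self, valid_fixture):
        mix = build_mixture(valid_fixture)
        assert np.exp(mix.log_weights_norm).sum() == pytest.approx(1.0, abs=1e-12)

    def test_homogeneous_data_full_subset_heaviest(self):
        bx = np.linspace(0.3, 0.7, 5)
        d = SummarizedData(tuple("abcde"), bx, 0.2 * bx, 0.05 * bx)
        mix = build_mixture(d)  # equal se_theta, identical ratio estimates
        heaviest = int(np.argmax(mix.log_weights_norm))
        assert mix.masks[heaviest].all()

    def test_prior_reweighting_ratio_identity(self):
        d = make_fixture(10, 0.1, seed=6)
        mix_half = build_mixture(d, prior_p=0.5)
        mix_08 = build_mixture(d, prior_p=0.8)
        K = mix_half.masks.sum(axis=1)
        # log w(p=0.8) - log w(p=0.5) = K log(0.8/0.5) + (J-K) log(0.2/0.5) + const
        delta = mix_08.log_weights_norm - mix_half.log_weights_norm
        expect = K * np.log(0.8 / 0.5) + (10 - K) * np.log(0.2 / 0.5)
        np.testing.assert_allclose(delta - delta[0], expect - expect[0], atol=1e-9)

    def test_default_prior_equals_equal_prior_weights(self, valid_fixture):
        mix = build_mixture(valid_fixture, prior_p=0.5)
        # recompute without any prior factor
        naive = naive_subset_quantities(valid_fixture)
        w = np.array([t[4] for t in naive])
        np.testing.assert_allclose(
            np.exp(mix.log_weights_norm), w / w.sum(), rtol=1e-9
        )


class TestLoglik:
    def _single_component(self, mean=0.4, se=0.1):
        d = SummarizedData(
            ("a", "b"), [0.5, 0.5], [mean * 0.5, mean * 0.5], [se * 0.5, se * 0.5]
        )
        return build_mixture(d)

    def test_single_component_gaussian_identity(self):
        mix = self._single_component(0.4, 0.1)
        mode_ll = loglik(mix, float(mix.means[0]))
        for theta in (0.1, 0.3, 0.55):
            diff = loglik(mix, theta) - mode_ll
            assert diff == pytest.approx(
                -((theta - mix.means[0]) ** 2) / (2 * mix.sds[0] ** 2), rel=1e-9
            )

    def test_dominant_separated_component_value(self):
        # two components far apart; at the heavy component's mean the loglik
        # is log w' + log N(0) = log w' - log se - log sqrt(2 pi)
        d = SummarizedData(
            ("a", "b", "c"),
            beta_x=np.array([0.5, 0.5, 0.5]),
            beta_y=np.array([0.10, 0.101, 2.0]),
            se_y=np.full(3, 0.005),
        )
        mix = build_mixture(d)
        k = int(np.argmax(mix.log_weights_norm))
        expect = (
            mix.log_weights_norm[k]
            - np.log(mix.sds[k])
            - 0.5 * np.log(2 * np.pi)
        )
        assert loglik(mix, float(mix.means[k])) == pytest.approx(expect, rel=1e-6)

    def test_symmetric_mixture_symmetric_loglik(self):
        d = SummarizedData(
            ("a", "b", "c", "d"),
            beta_x=np.full(4, 0.5),
            beta_y=np.array([-0.15, -0.15, 0.15, 0.15]),
            se_y=np.full(4, 0.01),
        )
        mix = build_mixture(d)
        for dx in (0.05, 0.12, 0.3):
            assert loglik(mix, dx) == pytest.approx(loglik(mix, -dx), rel=1e-9)

    def test_finite_far_from_all_components(self, valid_fixture):
        mix = build_mixture(valid_fixture)
        assert np.isfinite(loglik(mix, 0.999))
        assert np.isfinite(loglik(mix, -0.999))

    def test_oracle_loglik_small_J(self):
        rng = np.random.default_rng(21)
        d = random_summarized(rng, 5)
        mix = build_mixture(d)
        naive = naive_subset_quantities(d)
        w = np.array([t[4] for t in naive])
        wn = w / w.sum()
        for theta in (-0.3, 0.0, 0.2):
            direct = np.log(
                sum(
                    wn_k / se * np.exp(-((theta - m) ** 2) / (2 * se**2))
                    for wn_k, (_, m, _, se, _) in zip(wn, naive)
                )
                / np.sqrt(2 * np.pi)
            )
            assert loglik(mix, theta) == pytest.approx(direct, rel=1e-9)


class TestModeAndCI:
    def test_chi2_threshold_value(self):
        assert chi2.ppf(0.95, df=1) == pytest.approx(3.841, abs=5e-4)

    def test_single_component_ci_matches_gaussian_interval(self):
        d = SummarizedData(
            ("a", "b"), [0.5, 0.5], [0.2, 0.2], [0.05, 0.05]
        )
        mix = build_mixture(d)
        res = mode_and_ci(mix)
        se = float(mix.sds[0])
        assert res.estimate == pytest.approx(0.4, abs=0.001)
        lo, hi = res.confidence_set[0]
        z = np.sqrt(chi2.ppf(0.95, 1))
        assert lo == pytest.approx(0.4 - z * se, abs=0.002)
        assert hi == pytest.approx(0.4 + z * se, abs=0.002)
        assert not res.multimodal

    def test_two_separated_components_give_disjoint_intervals(self):
        d = SummarizedData(
            ("a", "b", "c", "d"),
            beta_x=np.full(4, 0.5),
            beta_y=np.array([-0.15, -0.15, 0.15, 0.15]),
            se_y=np.full(4, 0.01),
        )
        res = mode_and_ci(build_mixture(d))
        assert res.multimodal
        assert len(res.confidence_set) == 2
        (lo1, hi1), (lo2, hi2) = res.confidence_set
        assert hi1 < 0 < lo2
        assert lo1 < -0.3 < hi1 and lo2 < 0.3 < hi2

    def test_confidence_set_matches_dense_direct_evaluation(self, valid_fixture):
        mix = build_mixture(valid_fixture)
        res = mode_and_ci(mix)
        grid = np.linspace(-1, 1, 2001)
        ll = np.array([loglik(mix, float(t)) for t in grid[::20]])
        thresh = chi2.ppf(0.95, 1)
        llmax = loglik(mix, res.estimate)
        for t, l in zip(grid[::20], ll):
            inside_rule = 2 * (llmax - l) <= thresh
            inside_set = any(lo <= t <= hi for lo, hi in res.confidence_set)
            assert inside_rule == inside_set

    def test_estimate_inside_confidence_set(self, valid_fixture):
        res = mode_and_ci(build_mixture(valid_fixture))
        assert any(lo <= res.estimate <= hi for lo, hi in res.confidence_set)

    def test_boundary_mode_warns(self, caplog):
        d = SummarizedData(("a", "b"), [0.5, 0.5], [0.9, 0.9], [0.05, 0.05])
        with caplog.at_level("WARNING", logger="hpmr.hpma"):
            mode_and_ci(build_mixture(d), grid_lo=-1, grid_hi=1)  # mode ~1.8
        assert any("boundary" in rec.message for rec in caplog.records)


class TestHpmaEstimate:
    def test_two_variant_reduction_to_ivw(self):
        d = SummarizedData(("a", "b"), [0.5, 0.4], [0.15, 0.13], [0.04, 0.05])
        res, table = hpma_estimate(d)
        r = ivw(d, model="random")
        assert res.estimate == pytest.approx(r.estimate, abs=0.001)
        lo, hi = res.confidence_set[0]
        z = np.sqrt(chi2.ppf(0.95, 1))
        assert lo == pytest.approx(r.estimate - z * r.se, abs=0.002)
        assert hi == pytest.approx(r.estimate + z * r.se, abs=0.002)
        assert len(table) == 1

    def test_weight_concentrates_on_homogeneous_plurality(self):
        # 4 precise variants at theta=0.2 vs 2 at theta=0.8
        bx = np.full(6, 0.5)
        theta = np.r_[np.full(4, 0.2), np.full(2, 0.8)]
        d = SummarizedData(
            tuple(f"v{i}" for i in range(6)), bx, theta * bx, np.full(6, 0.005)
        )
        res, table = hpma_estimate(d)
        assert res.estimate == pytest.approx(0.2, abs=0.002)
        top = table.iloc[0]
        assert top["subset"] == "111100"
        assert top["weight"] > 0.5

    def test_weight_table_columns_and_normalization(self, valid_fixture):
        _, table = hpma_estimate(valid_fixture)
        assert list(table.columns) == ["subset", "K", "theta_ivw", "psi", "se_re", "weight"]
        assert table["weight"].sum() == pytest.approx(1.0, abs=1e-9)
        assert len(table) == 2**10 - 10 - 1

    def test_shrinking_se_concentrates_winning_weight(self):
        bx = np.full(6, 0.5)
        theta = np.r_[np.full(4, 0.2), np.full(2, 0.8)]
        prev = 0.0
        for c in (1.0, 10.0, 100.0):
            d = SummarizedData(
                tuple(f"v{i}" for i in range(6)), bx, theta * bx,
                np.full(6, 0.02) / c,
            )
            _, table = hpma_estimate(d)
            w = float(table.loc[table["subset"] == "111100", "weight"].iloc[0])
            assert w >= prev
            prev = w
        assert prev > 0.99


class TestNormalizationInvariance:
    def test_mode_ci_invariant_to_constant_log_weight_shift(self, valid_fixture):
        import dataclasses

        mix = build_mixture(valid_fixture)
        shifted = dataclasses.replace(
            mix, log_weights_norm=mix.log_weights_norm + 7.5
        )
        a = mode_and_ci(mix)
        b = mode_and_ci(shifted)
        assert a.estimate == b.estimate
        assert a.confidence_set == b.confidence_set
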