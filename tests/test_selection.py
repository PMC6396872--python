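import numpy as np
import pytest

from menisq import (
    BiParams,
    aicc,
    biexp_percentage,
    eval_bi,
    f_test,
    fit_bi,
    fit_mono,
    fit_volume,
    select_fit_pair,
    select_voxels,
    synthesize_echo_series,
)
from menisq.selection import slice_summary

from .conftest import uniform_phantom


class TestAicc:
    def test_penalty_arithmetic_n12(self):
        # 2k + 2k(k+1)/(n-k-1) on top of n*log(sse/n)
        assert aicc(12.0, 12, 3) == pytest.approx(9.0, abs=1e-12)
        assert aicc(12.0, 12, 5) == pytest.approx(20.0, abs=1e-12)

    def test_direct_evaluation(self):
        # 20 + 12*ln(1/12), evaluated independently
        assert aicc(1.0, 12, 5) == pytest.approx(-9.818879797456, abs=1e-9)

    def test_perfect_fit_sentinel(self):
        assert aicc(0.0, 12, 3) == float("-inf")

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            aicc(1.0, 4, 3)  # n - k - 1 < 1
        with pytest.raises(ValueError):
            aicc(-1.0, 12, 3)

    def test_ranking_invariant_under_signal_rescaling(self):
        # multiplying the signal by c multiplies both SSEs by c^2;
        # the AICc difference must not move
        for c2 in (0.01, 1.0, 25.0):
            d = aicc(c2 * 5.0, 12, 5) - aicc(c2 * 9.0, 12, 3)
            d0 = aicc(5.0, 12, 5) - aicc(9.0, 12, 3)
            assert d == pytest.approx(d0, abs=1e-10)


class TestFTest:
    def test_no_improvement_gives_f0_p1(self):
        f, p = f_test(3.0, 3.0, 12)
        assert f == 0.0 and p == 1.0

    def test_halved_sse_closed_form(self):
        # F = (1)*(7/2) = 3.5; for 2 numerator df the survival function is
        # (1 + 2F/7)^(-7/2) = 2^(-3.5)
        f, p = f_test(2.0, 1.0, 12)
        assert f == pytest.approx(3.5, abs=1e-12)
        assert p == pytest.approx(2.0 ** (-3.5), abs=1e-9)

    def test_perfect_bi_fit_limit(self):
        f, p = f_test(1.0, 0.0, 12)
        assert np.isinf(f) and p == 0.0

    def test_worse_bi_fit_clamped_to_zero(self):
        f, p = f_test(1.0, 2.0, 12)
        assert f == 0.0 and p == 1.0

    def test_too_few_echoes_rejected(self):
        with pytest.raises(ValueError):
            f_test(2.0, 1.0, 6)


class TestSelectFitPair:
    def test_mono_and_bi_must_share_data(self, schedule12, schedule9):
        y12 = eval_bi(BiParams(50, 50, 1.5, 15.0, 0.0), schedule12.array)
        y9 = eval_bi(BiParams(50, 50, 1.5, 15.0, 0.0), schedule9.array)
        m = fit_mono(y12, schedule12)
        b = fit_bi(y9, schedule9)
        with pytest.raises(ValueError):
            select_fit_pair(m, b)

    def test_invalid_alpha_rejected(self, schedule12):
        y = eval_bi(BiParams(50, 50, 1.5, 15.0, 0.0), schedule12.array)
        m, b = fit_mono(y, schedule12), fit_bi(y, schedule12)
        with pytest.raises(ValueError):
            select_fit_pair(m, b, alpha=0.0)

    def test_separated_bi_truth_preferred_by_both(self, schedule12):
        y = eval_bi(BiParams(50, 50, 1.5, 15.0, 0.0), schedule12.array)
        m = fit_mono(y, schedule12)
        b = fit_bi(y, schedule12, mono=m)
        sel = select_fit_pair(m, b)
        assert sel.prefer_bi_aicc and sel.prefer_bi_ftest

    def test_noise_free_mono_truth_not_flagged(self, schedule12):
        y = 100.0 * np.exp(-schedule12.array / 10.0)
        m = fit_mono(y, schedule12)
        b = fit_bi(y, schedule12, mono=m)
        sel = select_fit_pair(m, b)
        assert not sel.prefer_bi_aicc and not sel.prefer_bi_ftest
        assert sel.f_stat == 0.0 and sel.p_value == 1.0


class TestSelectVoxels:
    def test_noise_free_mono_phantom_zero_percent(self, schedule12):
        spec = uniform_phantom(shape=(4, 4, 2), noise_model="none")
        series, truth = synthesize_echo_series(spec, schedule12)
        mono, bi = fit_volume(series, schedule12, truth.label_map > 0, model="both")
        sel = select_voxels(mono, bi)
        assert biexp_percentage(sel.prefer_bi_ftest, sel.valid) == 0.0
        assert biexp_percentage(sel.prefer_bi_aicc, sel.valid) == 0.0

    def test_noise_free_separated_bi_phantom_100_percent(self, schedule12):
        spec = uniform_phantom(
            shape=(4, 4, 2),
            decay_kind="bi",
            params=BiParams(50.0, 50.0, 1.5, 15.0, 0.0),
            noise_model="none",
        )
        series, truth = synthesize_echo_series(spec, schedule12)
        mono, bi = fit_volume(series, schedule12, truth.label_map > 0, model="both")
        sel = select_voxels(mono, bi)
        assert biexp_percentage(sel.prefer_bi_aicc, sel.valid) == 100.0
        assert biexp_percentage(sel.prefer_bi_ftest, sel.valid) == 100.0
        # both criteria agree everywhere in the saturated regime
        agree = sel.prefer_bi_aicc[sel.valid] == sel.prefer_bi_ftest[sel.valid]
        assert agree.mean() >= 0.90

    def test_equal_amplitudes_give_fs_50(self, schedule12):
        spec = uniform_phantom(
            shape=(3, 3, 1),
            decay_kind="bi",
            params=BiParams(50.0, 50.0, 1.5, 15.0, 0.0),
            noise_model="none",
        )
        series, truth = synthesize_echo_series(spec, schedule12)
        mono, bi = fit_volume(series, schedule12, truth.label_map > 0, model="both")
        sel = select_voxels(mono, bi)
        np.testing.assert_allclose(sel.fs_percent[sel.valid], 50.0, atol=1e-3)
        np.testing.assert_allclose(
            sel.fs_percent[sel.valid] + sel.fl_percent[sel.valid], 100.0, atol=1e-9
        )

    def test_zero_amplitude_fraction_is_sentinel(self):
        # B1 + B2 = 0 (pure-offset voxel) -> fraction undefined
        from menisq.fitting import BI_MAP_NAMES, MONO_MAP_NAMES, ParameterMaps

        shape = (1, 1, 1)
        mask = np.ones(shape, bool)
        conv = np.ones(shape, bool)
        mono_maps = {k: np.full(shape, 1.0) for k in MONO_MAP_NAMES}
        bi_maps = {k: np.full(shape, 1.0) for k in BI_MAP_NAMES}
        bi_maps["b1"][:] = 0.0
        bi_maps["b2"][:] = 0.0
        mono = ParameterMaps("mono", mono_maps, mask, conv, 12)
        bi = ParameterMaps("bi", bi_maps, mask, conv, 12)
        sel = select_voxels(mono, bi)
        assert np.isnan(sel.fs_percent[sel.valid]).all()

    def test_slice_summary_layout(self, schedule12):
        spec = uniform_phantom(shape=(4, 4, 3), seed=2)
        series, truth = synthesize_echo_series(spec, schedule12)
        mono, bi = fit_volume(series, schedule12, truth.label_map > 0, model="both")
        sel = select_voxels(mono, bi)
        table = slice_summary(sel, slice_axis=2)
        assert list(table.columns) == ["slice", "n_voxels", "pct_bi_aicc", "pct_bi_ftest"]
        assert len(table) == 3
        assert (table["n_voxels"] <= 16).all()


class TestBiexpPercentage:
    def test_all_and_none_flagged(self):
        valid = np.ones((3, 3), bool)
        assert biexp_percentage(np.ones((3, 3), bool), valid) == 100.0
        assert biexp_percentage(np.zeros((3, 3), bool), valid) == 0.0

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            biexp_percentage(np.ones((2, 2), bool), np.zeros((2, 2), bool))


class TestErrorRatesAndPower:
    def test_type_i_error_bounded_at_alpha(self, mono_truth_ftest_sim):
        """F-test false-positive rate on mono-truth voxels stays near alpha."""
        p = mono_truth_ftest_sim["p_values"]
        conv = mono_truth_ftest_sim["converged"]
        rate = np.mean(p[conv] < 0.05)
        n = conv.sum()
        mc_se = np.sqrt(0.05 * 0.95 / n)
        assert rate <= 0.05 + 3 * mc_se

    def test_power_monotone_in_snr_and_separation(self, schedule12):
        """Bi-detection rate rises with SNR and with component separation."""
        te = schedule12.array
        rng = np.random.default_rng(31)
        n_rep = 80
        rates = {}
        for snr in (10.0, 60.0, 400.0):
            for sep in (2.0, 4.0, 8.0):
                truth = BiParams(50.0, 50.0, 1.5, 1.5 * sep, 0.0)
                clean = eval_bi(truth, te)
                sd = clean[0] / snr
                hits = 0
                n_ok = 0
                for _ in range(n_rep):
                    y = clean + rng.normal(0, sd, te.size)
                    m = fit_mono(y, schedule12)
                    b = fit_bi(y, schedule12, mono=m)
                    if m.converged and b.converged:
                        n_ok += 1
                        hits += select_fit_pair(m, b).prefer_bi_ftest
                rates[(snr, sep)] = hits / max(n_ok, 1)
        slack = 0.08  # Monte-Carlo tolerance at 80 replicates per cell
        for sep in (2.0, 4.0, 8.0):
            assert rates[(60.0, sep)] >= rates[(10.0, sep)] - slack
            assert rates[(400.0, sep)] >= rates[(60.0, sep)] - slack
        for snr in (10.0, 60.0, 400.0):
            assert rates[(snr, 4.0)] >= rates[(snr, 2.0)] - slack
            assert rates[(snr, 8.0)] >= rates[(snr, 4.0)] - slack
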