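import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lvpet.agreement import (
    PairedSeries,
    bland_altman,
    icc_absolute,
    pearson_r,
    relative_bias,
    wilcoxon_signed_rank,
)

from oracles import wilcoxon_exact_enumeration


class TestBlandAltman:
    def test_identical_series_have_zero_bias_and_rpc(self):
        p = PairedSeries([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        res = bland_altman(p)
        assert res.bias == 0.0 and res.rpc == 0.0

    def test_alternating_differences_match_sample_sd_formula(self):
        p = PairedSeries([1.0, -1.0, 1.0, -1.0], [0.0, 0.0, 0.0, 0.0])
        res = bland_altman(p)
        assert res.bias == 0.0
        assert res.rpc == pytest.approx(1.96 * np.sqrt(4.0 / 3.0))  # 2.263...

    def test_constant_offset_gives_bias_without_spread(self):
        b = np.array([10.0, 20.0, 30.0])
        res = bland_altman(PairedSeries(b + 5.0, b))
        assert res.bias == pytest.approx(5.0)
        assert res.rpc == 0.0
        assert (res.loa_low, res.loa_high) == (5.0, 5.0)

    @settings(derandomize=True, max_examples=50)
    @given(
        st.lists(
            st.tuples(
                st.floats(-1e3, 1e3, allow_nan=False),
                st.floats(-1e3, 1e3, allow_nan=False),
            ),
            min_size=2,
            max_size=30,
        )
    )
    def test_swapping_series_negates_bias_keeps_rpc(self, pairs):
        a = np.array([p[0] for p in pairs])
        b = np.array([p[1] for p in pairs])
        r1, r2 = bland_altman(PairedSeries(a, b)), bland_altman(PairedSeries(b, a))
        assert r1.bias == pytest.approx(-r2.bias, abs=1e-9)
        assert r1.rpc == pytest.approx(r2.rpc, abs=1e-9)


class TestRelativeBias:
    def test_five_percent_inflation(self):
        b = np.array([100.0, 150.0, 80.0])
        mean, sd = relative_bias(PairedSeries(1.05 * b, b))
        assert mean == pytest.approx(5.0)
        assert sd == pytest.approx(0.0, abs=1e-10)

    def test_two_subject_hand_computation(self):
        mean, sd = relative_bias(PairedSeries([110.0, 100.0], [100.0, 100.0]))
        assert mean == pytest.approx(5.0)
        assert sd == pytest.approx(np.sqrt(50.0))  # 7.071...

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            relative_bias(PairedSeries([1.0, 2.0], [0.0, 2.0]))


class TestICC:
    def test_perfect_agreement_with_spread_gives_one(self):
        a = np.array([10.0, 20.0, 30.0, 40.0])
        res = icc_absolute(PairedSeries(a, a.copy()))
        assert res.icc == pytest.approx(1.0)

    def test_matches_two_way_anova_reference_value(self):
        """Frozen reference computed independently with pingouin's ICC(A,1)."""
        a = [10.0, 12.0, 15.0, 20.0, 25.0, 18.0]
        b = [11.0, 11.5, 16.0, 19.0, 26.5, 17.0]
        res = icc_absolute(PairedSeries(a, b))
        assert res.icc == pytest.approx(0.9826249666, abs=1e-6)
        assert res.ci_low == pytest.approx(0.886636, abs=1e-4)
        assert res.ci_high == pytest.approx(0.997537, abs=1e-4)

    def test_cross_check_against_pingouin(self):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(4)
        a = rng.normal(100, 20, 12)
        b = a + rng.normal(3, 8, 12)
        res = icc_absolute(PairedSeries(a, b))
        df = pd.DataFrame(
            {
                "subject": np.tile(np.arange(12), 2),
                "rater": np.repeat(["a", "b"], 12),
                "score": np.concatenate([a, b]),
            }
        )
        table = pg.intraclass_corr(df, targets="subject", raters="rater", ratings="score")
        expected = float(table.loc[table.Type.isin(["ICC2", "ICC(A,1)"]), "ICC"].iloc[0])
        assert res.icc == pytest.approx(expected, abs=1e-9)

    def test_unpaired_shuffle_gives_near_zero(self):
        rng = np.random.default_rng(8)
        a = rng.normal(0, 1, 200)
        b = rng.permutation(a)
        res = icc_absolute(PairedSeries(a, b))
        assert abs(res.icc) <= 0.1

    def test_icc_never_exceeds_one(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            a = rng.normal(0, 1, 10)
            b = a + rng.normal(0, 0.1, 10)
            assert icc_absolute(PairedSeries(a, b)).icc <= 1.0

    def test_constant_data_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            icc_absolute(PairedSeries([3.0, 3.0, 3.0], [3.0, 3.0, 3.0]))


class TestPearson:
    def test_affine_relation_gives_unit_correlation(self):
        a = np.array([1.0, 2.0, 5.0, 9.0])
        assert pearson_r(PairedSeries(2 * a + 1, a)) == pytest.approx(1.0)
        assert pearson_r(PairedSeries(-a, a)) == pytest.approx(-1.0)

    def test_independent_noise_is_weakly_correlated(self):
        rng = np.random.default_rng(12)
        r = pearson_r(PairedSeries(rng.normal(0, 1, 1000), rng.normal(0, 1, 1000)))
        assert abs(r) < 0.1

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            pearson_r(PairedSeries([1.0, 1.0, 1.0], [1.0, 2.0, 3.0]))


class TestWilcoxon:
    def test_all_positive_n6_matches_exact_tail(self):
        p = PairedSeries([1.0, 2.0, 3.0, 4.0, 5.0, 6.0], np.zeros(6))
        stat, pval = wilcoxon_signed_rank(p)
        assert stat == 0.0
        assert pval == pytest.approx(2 / 64)  # one-sided exact 1/64, two-sided

    def test_symmetric_differences_are_insignificant(self):
        d = np.array([1.0, -1.1, 2.0, -2.1, 3.0, -3.1])
        stat, pval = wilcoxon_signed_rank(PairedSeries(d, np.zeros(6)))
        assert pval > 0.8

    @pytest.mark.parametrize("trial", range(10))
    def test_matches_exhaustive_sign_enumeration_n8(self, trial):
        rng = np.random.default_rng(40 + trial)
        d = rng.normal(0.4, 1.0, 8)
        assert len(np.unique(np.abs(d))) == 8  # continuous draws: no ties
        _, pval = wilcoxon_signed_rank(PairedSeries(d, np.zeros(8)))
        assert pval == pytest.approx(wilcoxon_exact_enumeration(d), abs=1e-12)

    def test_all_zero_differences_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            wilcoxon_signed_rank(PairedSeries([1.0, 2.0], [1.0, 2.0]))

    def test_fewer_than_five_nonzero_differences_rejected(self):
        with pytest.raises(ValueError, match="at least 5"):
            wilcoxon_signed_rank(PairedSeries([1.0, 2.0, 3.0, 1.0], [0.0, 0.0, 0.0, 1.0]))


class TestPairedSeries:
    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            PairedSeries([1.0, 2.0], [1.0])

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            PairedSeries([1.0, np.inf], [1.0, 2.0])
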