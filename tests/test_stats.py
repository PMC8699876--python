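import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plaqueprop.datasets import (
    RECONSTRUCTION_UNCERTAINTY,
    ess_summary_reference,
    smartffr_reference,
)
from plaqueprop.errors import StatsError
from plaqueprop.stats import (
    PairedComparison,
    bland_altman,
    bland_altman_from_stats,
    max_relative_error,
    paired_stats,
    pearson_r,
    propagate_uncertainty,
    relative_error_summary,
)


@pytest.fixture(scope="module")
def smartffr_table():
    return smartffr_reference()


class TestPairedStats:
    def test_reference_mean_differences(self, smartffr_table):
        over = PairedComparison(
            smartffr_table["original"].to_numpy(), smartffr_table["overestimated"].to_numpy()
        )
        under = PairedComparison(
            smartffr_table["original"].to_numpy(), smartffr_table["underestimated"].to_numpy()
        )
        assert paired_stats(over)[0] == pytest.approx(-0.004, abs=5e-4)
        assert paired_stats(under)[0] == pytest.approx(0.009, abs=5e-4)
        # population sd reproduces the published spread to printed precision
        assert paired_stats(over)[1] == pytest.approx(0.006, abs=5e-4)
        assert paired_stats(under)[1] == pytest.approx(0.008, abs=5e-4)

    def test_identical_vectors(self):
        comp = PairedComparison(np.ones(5), np.ones(5))
        assert paired_stats(comp) == (0.0, 0.0)

    def test_sign_convention_flip(self, smartffr_table):
        comp = PairedComparison(
            smartffr_table["original"].to_numpy(),
            smartffr_table["overestimated"].to_numpy(),
            flip_sign=True,
        )
        assert paired_stats(comp)[0] == pytest.approx(0.004, abs=5e-4)

    def test_length_mismatch_rejected(self):
        with pytest.raises(StatsError):
            PairedComparison(np.ones(3), np.ones(4))


class TestBlandAltman:
    def test_constant_differences_zero_width(self):
        comp = PairedComparison(np.arange(5.0) + 2.0, np.arange(5.0))
        res = bland_altman(comp)
        assert res.loa_low == res.loa_high == res.mean_diff == 2.0

    def test_published_shear_limits(self):
        res = bland_altman_from_stats(-0.149, 0.2430)
        assert res.loa_low == pytest.approx(-0.6262, abs=2e-3)
        assert res.loa_high == pytest.approx(0.3263, abs=2e-3)

    def test_limits_bracket_95pct_of_normal_differences(self):
        rng = np.random.default_rng(42)
        orig = rng.normal(10.0, 1.0, 100_000)
        pert = orig + rng.normal(0.2, 0.5, 100_000)
        res = bland_altman(PairedComparison(orig, pert))
        d = orig - pert
        inside = np.mean((d >= res.loa_low) & (d <= res.loa_high))
        assert inside == pytest.approx(0.95, abs=0.005)

    def test_ci_width_formula(self):
        res = bland_altman_from_stats(0.0, 1.0, n=100)
        half = 1.96 * np.sqrt(3.0 / 100.0)
        assert res.ci_low_upper - res.loa_low == pytest.approx(half, rel=1e-12)

    def test_limits_recompute_from_mean_and_sd(self):
        rng = np.random.default_rng(0)
        comp = PairedComparison(rng.normal(size=50), rng.normal(size=50))
        res = bland_altman(comp)
        mean, sd = paired_stats(comp)
        assert res.loa_low == mean - 1.96 * sd
        assert res.loa_high == mean + 1.96 * sd


class TestPearson:
    def test_perfect_correlations(self):
        x = np.arange(10.0)
        assert pearson_r(x, x)[0] == pytest.approx(1.0)
        assert pearson_r(x, -x)[0] == pytest.approx(-1.0)

    def test_reference_smartffr_correlations(self, smartffr_table):
        for col in ("overestimated", "underestimated"):
            r, p = pearson_r(smartffr_table["original"], smartffr_table[col])
            assert r >= 0.99
            assert p < 0.001

    def test_zero_variance_rejected(self):
        with pytest.raises(StatsError):
            pearson_r(np.ones(5), np.arange(5.0))


class TestRelativeError:
    def test_published_shear_rows(self):
        ess = ess_summary_reference()
        orig = tuple(ess.loc["original", ["min", "max", "mean"]])
        over = relative_error_summary(orig, tuple(ess.loc["overestimated", ["min", "max", "mean"]]))
        under = relative_error_summary(orig, tuple(ess.loc["underestimated", ["min", "max", "mean"]]))
        assert over.re_mean == pytest.approx(-6.72, abs=0.05)
        assert over.re_min == pytest.approx(-14.2, abs=0.05)
        assert under.re_min == pytest.approx(9.19, abs=0.05)

    def test_no_perturbation_no_error(self):
        re = relative_error_summary((1.0, 2.0, 1.5), (1.0, 2.0, 1.5))
        assert re.as_tuple() == (0.0, 0.0, 0.0)

    def test_uniform_scaling(self):
        re = relative_error_summary((1.0, 2.0, 1.5), (1.02, 2.04, 1.53))
        assert np.allclose(re.as_tuple(), 2.0)

    def test_max_relative_error_locates_worst_case(self, smartffr_table):
        value, idx = max_relative_error(
            smartffr_table["original"], smartffr_table["underestimated"]
        )
        assert value == pytest.approx(3.797, abs=5e-3)
        assert smartffr_table.index[idx] == "Case 13"

    def test_zero_original_rejected(self):
        with pytest.raises(StatsError):
            relative_error_summary((0.0, 1.0, 1.0), (1.0, 1.0, 1.0))


class TestUncertaintyChain:
    def test_published_shear_uncertainties(self):
        assert propagate_uncertainty(1.7576, RECONSTRUCTION_UNCERTAINTY) == pytest.approx(
            1.7599, abs=1e-4
        )
        assert propagate_uncertainty(1.9902, RECONSTRUCTION_UNCERTAINTY) == pytest.approx(
            1.9922, abs=1e-4
        )

    def test_zero_previous_level(self):
        assert propagate_uncertainty(1.5, 0.0) == 1.5

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(sd=st.floats(0.0, 1e6), u_prev=st.floats(0.0, 1e6))
    def test_commutative_and_dominating(self, sd, u_prev):
        u = propagate_uncertainty(sd, u_prev)
        assert u == propagate_uncertainty(u_prev, sd)
        assert u >= max(sd, u_prev)

    def test_negative_inputs_rejected(self):
        with pytest.raises(StatsError):
            propagate_uncertainty(-0.1, 0.0)
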