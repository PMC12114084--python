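"""Causal estimators: Wald, IVW, MR-Egger, weighted median, OR reporting."""

import math

import numpy as np
import pytest
import statsmodels.api as sm

from tests._helpers import make_instruments
from tsmr.estimators import (
    egger,
    ivw,
    to_or_scale,
    wald_ratio,
    weighted_median,
    weighted_median_point,
    _weighted_median_rows,
)
from tsmr.exceptions import DomainError, InsufficientInstrumentsError, ZeroInstrumentError
from tsmr.instruments import HarmonizedInstrument


def _inst(bx, by, sy, sx=0.01, snp_id="rs1"):
    return HarmonizedInstrument(
        snp_id=snp_id, beta_exp=bx, se_exp=sx, beta_out=by, se_out=sy, n_exp=10_000
    )


class TestWaldRatio:
    def test_direct_division(self):
        est = wald_ratio(_inst(0.1, 0.05, 0.01))
        assert est.beta == pytest.approx(0.5)
        assert est.se == pytest.approx(0.1)

    def test_zero_outcome_effect_gives_or_one(self):
        est = wald_ratio(_inst(0.1, 0.0, 0.01))
        assert est.beta == 0.0 and est.or_ == 1.0

    def test_ratio_invariant_to_joint_negation(self):
        a = wald_ratio(_inst(0.1, 0.05, 0.01))
        b = wald_ratio(_inst(-0.1, -0.05, 0.01))
        assert (a.beta, a.se, a.pvalue) == (b.beta, b.se, b.pvalue)

    def test_zero_exposure_effect_is_an_error(self):
        with pytest.raises(DomainError):
            wald_ratio(_inst(0.0, 0.05, 0.01))


class TestIVW:
    def test_single_instrument_reduces_to_wald(self):
        inst = _inst(0.2, 0.08, 0.02)
        w = wald_ratio(inst)
        est = ivw([inst])
        assert est.beta == pytest.approx(w.beta) and est.se == pytest.approx(w.se)

    def test_duplicated_instrument_halves_fixed_variance(self):
        inst = _inst(0.2, 0.08, 0.02)
        one = ivw([inst], effects_model="fixed")
        two = ivw([inst, inst], effects_model="fixed")
        assert two.beta == pytest.approx(one.beta)
        assert two.se == pytest.approx(one.se / math.sqrt(2))

    def test_empty_set_raises(self):
        with pytest.raises(ZeroInstrumentError):
            ivw([])

    def test_equals_origin_constrained_wls_oracle(self):
        """Precision-weighted ratio mean == WLS through the origin (statsmodels)."""
        for seed in range(5):
            instruments = make_instruments(seed, 8)
            bx = np.array([i.beta_exp for i in instruments])
            by = np.array([i.beta_out for i in instruments])
            sy = np.array([i.se_out for i in instruments])
            fit = sm.WLS(by, bx[:, None], weights=1 / sy**2).fit()
            est = ivw(instruments, effects_model="fixed")
            assert est.beta == pytest.approx(fit.params[0], abs=1e-10)

    def test_random_effects_never_shrink_the_se(self, instrument_factory):
        instruments = instrument_factory(7, 10, noise=3.0)
        fixed = ivw(instruments, effects_model="fixed")
        random = ivw(instruments, effects_model="multiplicative_random")
        assert random.beta == fixed.beta
        assert random.se >= fixed.se


class TestEgger:
    def test_noiseless_line_recovered_exactly(self):
        instruments = [
            _inst(bx, 0.02 + 0.5 * bx, 0.01, snp_id=f"rs{k}")
            for k, bx in enumerate([0.1, 0.2, 0.3, 0.4])
        ]
        est, rec = egger(instruments)
        assert est.beta == pytest.approx(0.5, abs=1e-12)
        assert rec.estimate == pytest.approx(0.02, abs=1e-12)

    def test_collinear_through_origin_matches_ivw(self):
        instruments = [
            _inst(bx, 0.4 * bx, 0.01, snp_id=f"rs{k}") for k, bx in enumerate([0.1, 0.25, 0.4])
        ]
        est, rec = egger(instruments)
        assert rec.estimate == pytest.approx(0.0, abs=1e-12)
        assert est.beta == pytest.approx(ivw(instruments).beta, abs=1e-12)

    def test_matches_free_intercept_wls_oracle(self):
        """Slope, intercept and (rescaled) SEs equal a statsmodels WLS fit."""
        for seed in range(5):
            instruments = make_instruments(seed, 10, intercept=0.01)
            bx = np.array([i.beta_exp for i in instruments])
            by = np.array([i.beta_out for i in instruments])
            sy = np.array([i.se_out for i in instruments])
            sign = np.where(bx < 0, -1, 1)
            x, y = bx * sign, by * sign
            fit = sm.WLS(y, sm.add_constant(x), weights=1 / sy**2).fit()
            est, rec = egger(instruments)
            assert est.beta == pytest.approx(fit.params[1], abs=1e-10)
            assert rec.estimate == pytest.approx(fit.params[0], abs=1e-10)
            # statsmodels bse carry the sigma factor; ours floor it at 1
            sigma = math.sqrt(fit.mse_resid)
            assert est.se == pytest.approx(fit.bse[1] / sigma * max(1, sigma), rel=1e-10)
            assert rec.se == pytest.approx(fit.bse[0] / sigma * max(1, sigma), rel=1e-10)

    def test_requires_three_instruments(self):
        with pytest.raises(InsufficientInstrumentsError):
            egger([_inst(0.1, 0.05, 0.01), _inst(0.2, 0.1, 0.01)])


class TestWeightedMedian:
    def test_symmetric_ratios_give_central_value(self):
        instruments = [
            _inst(0.1, 0.1 * r, 0.01, snp_id=f"rs{k}") for k, r in enumerate([0.4, 0.5, 0.6])
        ]
        assert weighted_median(instruments, n_boot=100, seed=1).beta == pytest.approx(0.5)

    def test_identical_ratios_return_that_value_with_tiny_se(self):
        instruments = [
            _inst(bx, 0.3 * bx, 1e-12, sx=1e-12, snp_id=f"rs{k}")
            for k, bx in enumerate([0.1, 0.2, 0.3])
        ]
        # zero-noise instruments: every bootstrap replicate nearly identical
        est = weighted_median(instruments, n_boot=100, seed=1)
        assert est.beta == pytest.approx(0.3, abs=1e-9)
        assert est.se < 1e-6

    def test_matches_brute_force_percentile_interpolation(self):
        instruments = make_instruments(11, 11)
        theta = np.array([i.beta_out / i.beta_exp for i in instruments])
        w = np.array([i.beta_exp**2 / i.se_out**2 for i in instruments])
        # independent re-computation, scalar loop instead of array ops
        order = sorted(range(len(theta)), key=lambda k: theta[k])
        total = sum(w)
        cum, s_vals, t_vals = 0.0, [], []
        for k in order:
            s_vals.append((cum + w[k] / 2) / total)
            t_vals.append(theta[k])
            cum += w[k]
        expected = None
        for i in range(1, len(s_vals)):
            if s_vals[i] >= 0.5:
                lo_s, hi_s = s_vals[i - 1], s_vals[i]
                frac = (0.5 - lo_s) / (hi_s - lo_s)
                expected = t_vals[i - 1] + frac * (t_vals[i] - t_vals[i - 1])
                break
        est = weighted_median(instruments, n_boot=100, seed=2)
        assert est.beta == pytest.approx(expected, rel=1e-12)

    def test_vectorized_bootstrap_rows_match_scalar_path(self):
        rng = np.random.default_rng(5)
        theta = rng.normal(size=(50, 9))
        w = rng.uniform(0.1, 2.0, size=(50, 9))
        rows = _weighted_median_rows(theta, w)
        for i in range(50):
            assert rows[i] == pytest.approx(weighted_median_point(theta[i], w[i]), rel=1e-12)

    def test_seed_is_mandatory_and_reproducible(self):
        instruments = make_instruments(3, 5)
        with pytest.raises(DomainError):
            weighted_median(instruments, n_boot=50)
        a = weighted_median(instruments, n_boot=200, seed=9)
        b = weighted_median(instruments, n_boot=200, seed=9)
        assert (a.beta, a.se, a.pvalue) == (b.beta, b.se, b.pvalue)


class TestEquivariance:
    @pytest.mark.parametrize("seed", [0, 1])
    def test_negating_outcomes_negates_estimates_and_inverts_or(self, seed):
        instruments = make_instruments(seed, 8)
        flipped = [
            HarmonizedInstrument(
                snp_id=i.snp_id, beta_exp=i.beta_exp, se_exp=i.se_exp,
                beta_out=-i.beta_out, se_out=i.se_out, n_exp=i.n_exp,
            )
            for i in instruments
        ]
        for method in (
            lambda ins: ivw(ins),
            lambda ins: egger(ins)[0],
            lambda ins: weighted_median(ins, n_boot=200, seed=4),
        ):
            a, b = method(instruments), method(flipped)
            assert b.beta == pytest.approx(-a.beta, rel=1e-9, abs=1e-12)
            assert b.or_ == pytest.approx(1 / a.or_, rel=1e-9)

    def test_scaling_exposures_divides_estimates(self):
        instruments = make_instruments(2, 8)
        c = 2.5
        scaled = [
            HarmonizedInstrument(
                snp_id=i.snp_id, beta_exp=c * i.beta_exp, se_exp=c * i.se_exp,
                beta_out=i.beta_out, se_out=i.se_out, n_exp=i.n_exp,
            )
            for i in instruments
        ]
        assert ivw(scaled).beta == pytest.approx(ivw(instruments).beta / c)
        assert egger(scaled)[0].beta == pytest.approx(egger(instruments)[0].beta / c)


class TestORScale:
    def test_null_beta_gives_unit_or(self):
        or_, lo, hi = to_or_scale(0.0, 0.2)
        assert or_ == 1.0
        assert lo == pytest.approx(math.exp(-1.96 * 0.2))
        assert hi == pytest.approx(math.exp(1.96 * 0.2))

    def test_log_or_round_trips_through_reporting(self):
        or_, lo, hi = to_or_scale(math.log(1.541), 0.16777)
        assert or_ == pytest.approx(1.541, rel=1e-12)
        assert lo == pytest.approx(or_ * math.exp(-1.96 * 0.16777), rel=1e-12)
        assert hi == pytest.approx(or_ * math.exp(1.96 * 0.16777), rel=1e-12)

    def test_se_must_be_positive(self):
        with pytest.raises(DomainError):
            to_or_scale(0.1, 0.0)
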