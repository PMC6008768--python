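import numpy as np
import pytest
from scipy.special import stdtr

from petpbpk.core_data import PhysiologyConstants, ValidationError, plasma_volume
from petpbpk.derived_pk import (
    cl_hepatic,
    cl_renal,
    compare_groups,
    d_tissue,
    derive_all,
)
from petpbpk.pbpk_model import RateConstantSet, ScanGeometry

from conftest import random_rate_constants

V_P = 0.6552  # plasma volume at 20 g, default physiology


def steady_state_amounts(k: RateConstantSet, infusion_rate: float) -> np.ndarray:
    """Independent oracle: steady state of the non-absorbing subsystem
    (B, H1, H2, R1, R2, T1, T2) under a constant infusion, with G and U as
    pure sinks.  Solves the linear balance directly."""
    # order: B H1 H2 R1 R2 T1 T2
    m = np.zeros((7, 7))
    B, H1, H2, R1, R2, T1, T2 = range(7)
    m[B, B] = -(k.k_bh1 + k.k_br1 + k.k_bg + k.k_bt)
    m[B, H1] = k.k_h1b
    m[B, R1] = k.k_r1b
    m[B, T1] = k.k_tb1
    m[B, T2] = k.k_tb2
    m[H1, B] = k.k_bh1
    m[H1, H1] = -(k.k_h1b + k.k_h1h2)
    m[H2, H1] = k.k_h1h2
    m[H2, H2] = -k.k_h2g
    m[R1, B] = k.k_br1
    m[R1, R2] = k.k_r2r1
    m[R1, R1] = -(k.k_r1b + k.k_r1r2 + k.k_r1u)
    m[R2, R1] = k.k_r1r2
    m[R2, R2] = -k.k_r2r1
    m[T1, B] = k.f_bt1 * k.k_bt
    m[T1, T1] = -k.k_tb1
    m[T2, B] = (1.0 - k.f_bt1) * k.k_bt
    m[T2, T2] = -k.k_tb2
    u = np.zeros(7)
    u[B] = infusion_rate
    return np.linalg.solve(m, -u)


class TestHepaticClearance:
    def test_irreversible_limit(self):
        k = RateConstantSet(k_bh1=0.2, k_h1h2=1e6, k_h1b=1.0)
        assert cl_hepatic(k, V_P) == pytest.approx(0.2 * V_P * 1000.0, rel=1e-5)

    def test_symmetric_split(self):
        k = RateConstantSet(k_bh1=0.2, k_h1h2=0.05, k_h1b=0.05)
        assert cl_hepatic(k, V_P) == pytest.approx(0.5 * 0.2 * V_P * 1000.0)

    def test_zero_uptake(self):
        assert cl_hepatic(RateConstantSet(), V_P) == 0.0

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValidationError):
            cl_hepatic(RateConstantSet(k_bh1=0.1), V_P)

    def test_steady_state_oracle(self):
        # flux into G over C_plasma at steady state, with reabsorption and
        # the transintestinal route switched off
        rng = np.random.default_rng(0)
        for _ in range(20):
            k = random_rate_constants(rng).replace(k_gh1=0.0, k_bg=0.0)
            ss = steady_state_amounts(k, infusion_rate=100.0)
            flux_to_g = k.k_h2g * ss[2]
            c_plasma = ss[0] / V_P
            assert cl_hepatic(k, V_P) == pytest.approx(flux_to_g / c_plasma * 1000.0, rel=5e-3)

    def test_bounded_by_uptake_and_monotone(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            k = random_rate_constants(rng)
            assert cl_hepatic(k, V_P) <= k.k_bh1 * V_P * 1000.0 + 1e-9
            up = k.replace(k_h1h2=k.k_h1h2 * 2)
            down = k.replace(k_h1b=k.k_h1b * 2)
            assert cl_hepatic(up, V_P) >= cl_hepatic(k, V_P)
            assert cl_hepatic(down, V_P) <= cl_hepatic(k, V_P)


class TestRenalClearance:
    def test_single_compartment_collapse(self):
        k = RateConstantSet(k_br1=0.1, k_r1b=0.3, k_r1u=0.2, k_r1r2=0.0, k_r2r1=0.0)
        expected = 0.1 * 0.2 / (0.3 + 0.2) * V_P * 1000.0
        assert cl_renal(k, V_P) == pytest.approx(expected)

    def test_uptake_limited(self):
        k = RateConstantSet(k_br1=0.1, k_r1b=1e-9, k_r1u=10.0)
        assert cl_renal(k, V_P) == pytest.approx(0.1 * V_P * 1000.0, rel=1e-6)

    def test_irreversible_trap_rejected(self):
        with pytest.raises(ValidationError):
            cl_renal(RateConstantSet(k_br1=0.1, k_r1b=0.1, k_r1r2=0.1, k_r2r1=0.0, k_r1u=0.1), V_P)

    def test_steady_state_oracle_collapsed_deep_compartment(self):
        # with the deep kidney exchange off, the formula equals the true
        # steady-state flux/concentration ratio
        rng = np.random.default_rng(2)
        for _ in range(20):
            k = random_rate_constants(rng).replace(k_r1r2=0.0)  # R2 stays empty
            ss = steady_state_amounts(k, infusion_rate=100.0)
            flux_to_u = k.k_r1u * ss[3]
            c_plasma = ss[0] / V_P
            assert cl_renal(k, V_P) == pytest.approx(flux_to_u / c_plasma * 1000.0, rel=5e-3)

    def test_formula_bounds_steady_state_from_below(self):
        # applying the mass-ratio correction to the urine rate alone makes
        # the published formula a lower bound of the exact steady-state
        # clearance k_br1*k_r1u/(k_r1b + k_r1u)*V_p for a reversible deep
        # compartment, tight as k_r1r2 -> 0
        rng = np.random.default_rng(12)
        for _ in range(20):
            k = random_rate_constants(rng)
            ss = steady_state_amounts(k, infusion_rate=100.0)
            exact = k.k_r1u * ss[3] / (ss[0] / V_P) * 1000.0
            assert cl_renal(k, V_P) <= exact * (1 + 1e-9)

    def test_monotonicity(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            k = random_rate_constants(rng)
            base = cl_renal(k, V_P)
            assert cl_renal(k.replace(k_r1u=k.k_r1u * 2), V_P) >= base
            assert cl_renal(k.replace(k_r2r1=k.k_r2r1 * 2), V_P) >= base
            assert cl_renal(k.replace(k_r1b=k.k_r1b * 2), V_P) <= base
            assert cl_renal(k.replace(k_r1r2=k.k_r1r2 * 2), V_P) <= base


class TestTissueDistribution:
    def test_single_route(self):
        k = RateConstantSet(k_bt=0.2, k_tb1=0.1, f_bt1=1.0, v_tissue=10.0)
        assert d_tissue(k, V_P) == pytest.approx(2.0 * V_P / 10.0)

    def test_symmetric_efflux_independent_of_split(self):
        for f in (0.0, 0.3, 1.0):
            k = RateConstantSet(k_bt=0.2, k_tb1=0.1, k_tb2=0.1, f_bt1=f, v_tissue=10.0)
            assert d_tissue(k, V_P) == pytest.approx(2.0 * V_P / 10.0)

    def test_zero_efflux_with_influx_rejected(self):
        with pytest.raises(ValidationError):
            d_tissue(RateConstantSet(k_bt=0.2, k_tb1=0.0, f_bt1=1.0), V_P)

    def test_equilibrium_oracle(self):
        # closed conservative system (no elimination): after a bolus the
        # tissue/plasma concentration ratio converges to d_tissue
        from petpbpk.pbpk_model import simulate

        geom = ScanGeometry(
            body_weight=20.0,
            dose_a0=7.1,
            infusion_duration=10.0 / 60.0,
            frame_grid=((1.0, 3000.0),),
        )
        rng = np.random.default_rng(4)
        for _ in range(5):
            k = random_rate_constants(rng).replace(
                k_h1h2=0.0, k_h2g=0.0, k_gh1=0.0, k_bg=0.0, k_r1u=0.0
            )
            traj = simulate(k, geom)
            b = traj.compartment("B")[-1]
            tissue = traj.compartment("T1")[-1] + traj.compartment("T2")[-1]
            ratio = (tissue / k.v_tissue) / (b / V_P)
            assert d_tissue(k, V_P) == pytest.approx(ratio, rel=5e-3)


class TestDeriveAll:
    GEOM = ScanGeometry(
        body_weight=19.0, dose_a0=7.1, infusion_duration=10.0 / 60.0, frame_grid=((1.0, 61.0),)
    )

    def _k_with_clearances(self, cl_h_target, cl_r_target, bw):
        from petpbpk.synthetic_data import _hepatic_backflux, _renal_urine_rate

        v_p = plasma_volume(bw)
        return RateConstantSet(
            k_bh1=0.2,
            k_h1h2=0.05,
            k_h1b=_hepatic_backflux(0.2, 0.05, cl_h_target, v_p),
            k_h2g=0.05,
            k_br1=0.1,
            k_r1b=0.3,
            k_r1r2=0.05,
            k_r2r1=0.05,
            k_r1u=_renal_urine_rate(0.1, 0.3, 1.0, cl_r_target, v_p),
            k_bt=0.2,
            k_tb1=0.3,
            k_tb2=0.3,
            v_tissue=14.0,
        )

    def test_extraction_ratio_printed_value(self):
        k = self._k_with_clearances(35.2, 11.9, 19.0)
        derived = derive_all(k, self.GEOM)
        assert derived.e_h == pytest.approx(0.0352)
        assert round(derived.e_h, 3) == 0.035

    def test_gfr_fraction_printed_value(self):
        k = self._k_with_clearances(35.2, 11.9, 19.0)
        derived = derive_all(k, self.GEOM)
        assert round(derived.cl_r_over_gfr, 3) == 0.074

    def test_no_transintestinal_contribution_by_default(self):
        k = self._k_with_clearances(35.2, 11.9, 19.0)
        derived = derive_all(k, self.GEOM)
        assert derived.cl_ti == 0.0
        assert derived.cl_total == pytest.approx(derived.cl_h + derived.cl_r)

    def test_transintestinal_included_when_kbg_positive(self):
        k = self._k_with_clearances(35.2, 11.9, 19.0).replace(k_bg=0.02)
        derived = derive_all(k, self.GEOM)
        v_p = plasma_volume(19.0)
        assert derived.cl_ti == pytest.approx(0.02 * v_p * 1000.0)
        assert derived.cl_total == pytest.approx(derived.cl_h + derived.cl_r + derived.cl_ti)

    def test_extraction_ratio_bounded_when_uptake_bounded(self):
        rng = np.random.default_rng(5)
        phys = PhysiologyConstants()
        v_p = plasma_volume(20.0, phys)
        for _ in range(20):
            k = random_rate_constants(rng)
            if k.k_bh1 * v_p <= phys.q_p_hepatic:
                geom = ScanGeometry(20.0, 7.1, 10 / 60, ((1.0, 61.0),))
                assert 0.0 <= derive_all(k, geom, phys).e_h <= 1.0


class TestCompareGroups:
    def test_identical_groups(self):
        result = compare_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert result.t_statistic == pytest.approx(0.0)
        assert result.p_value == pytest.approx(1.0)
        assert not result.significant

    def test_large_shift_significant(self):
        result = compare_groups([1.0, 2.0, 3.0], [101.0, 102.0, 103.0])
        assert result.p_value < 1e-6
        assert result.significant

    def test_hand_computed_pooled_t(self):
        a, b = [1.0, 2.0, 3.0, 4.0], [2.0, 3.0, 4.0, 5.0]
        # hand oracle: pooled var = 5/3, se = sqrt(5/3 * 1/2), t = -1/se
        se = np.sqrt(5.0 / 3.0 * 0.5)
        t_expected = -1.0 / se
        df = 6
        p_expected = 2.0 * stdtr(df, t_expected)  # two-sided, t < 0
        result = compare_groups(a, b)
        assert result.t_statistic == pytest.approx(t_expected, rel=1e-12)
        assert result.p_value == pytest.approx(p_expected, rel=1e-12)

    def test_degenerate_zero_variance(self):
        equal = compare_groups([2.0, 2.0], [2.0, 2.0])
        assert equal.p_value == 1.0 and equal.degenerate
        unequal = compare_groups([2.0, 2.0], [3.0, 3.0])
        assert unequal.p_value == 0.0 and unequal.degenerate and unequal.significant

    def test_too_small_group_rejected(self):
        with pytest.raises(ValidationError):
            compare_groups([1.0], [1.0, 2.0])
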