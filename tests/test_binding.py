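"""Equilibrium binding: exact fraction bound, competition, K_D fitting."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from adpa_circuit.binding import (
    BindingSystem,
    MixtureBinding,
    TitrationCurve,
    anisotropy,
    competitive_bound,
    emsa_profile,
    fit_kd,
    fraction_bound,
)
from adpa_circuit.synthetic import DEFAULT_FP_GRID, NoiseModel, gen_fp_titration


def scan_equilibrium(mix: MixtureBinding, resolution=1e-6):
    """Brute-force oracle: exhaustive scan over free probe, then refine."""
    def imbalance(d):
        bA = mix.A_total * d / (mix.Kd_A + d)
        bAs = mix.As_total * d / (mix.Kd_As + d)
        return np.abs(d + bA + bAs - mix.D_total)

    d = np.linspace(0.0, mix.D_total, 2001)
    for _ in range(3):  # refinement rounds reach < 1e-6 * D resolution
        i = int(imbalance(d).argmin())
        lo = d[max(i - 1, 0)]
        hi = d[min(i + 1, len(d) - 1)]
        d = np.linspace(lo, hi, 2001)
    d_free = float(d[int(imbalance(d).argmin())])
    return (mix.A_total * d_free / (mix.Kd_A + d_free) / mix.D_total,
            mix.As_total * d_free / (mix.Kd_As + d_free) / mix.D_total,
            d_free)


class TestFractionBound:
    def test_huge_kd_unbinds(self):
        assert fraction_bound(BindingSystem(1.0, 1.0, 1e12)) < 1e-9

    def test_excess_tf_saturates(self):
        assert fraction_bound(BindingSystem(1e6, 1.0, 1.0)) > 0.999998

    def test_symmetric_unit_case(self):
        # closed form: bound probe = (3 - sqrt(5))/2 when T = D = Kd = 1
        f = fraction_bound(BindingSystem(1.0, 1.0, 1.0))
        assert f == pytest.approx((3.0 - math.sqrt(5.0)) / 2.0, rel=1e-12)

    def test_numerically_stable_in_weak_binding_limit(self):
        # naive quadratic branch cancels catastrophically here
        f = fraction_bound(BindingSystem(1e-3, 1e-3, 1e9))
        assert f == pytest.approx(1e-12, rel=1e-6)

    @given(t=st.floats(0.01, 1e5), d=st.floats(0.01, 1e3),
           kd=st.floats(0.01, 1e5))
    @settings(max_examples=80, deadline=None)
    def test_monotone_in_tf_and_kd(self, t, d, kd):
        f = fraction_bound(BindingSystem(t, d, kd))
        assert 0.0 <= f <= 1.0
        assert fraction_bound(BindingSystem(t * 1.5, d, kd)) > f
        assert fraction_bound(BindingSystem(t, d, kd * 1.5)) < f

    def test_invalid_kd_rejected(self):
        with pytest.raises(ValueError):
            BindingSystem(1.0, 1.0, 0.0)


class TestCompetitiveBound:
    def test_degenerate_mixture_reduces_to_single_species(self):
        mix = MixtureBinding(A_total=10.0, As_total=0.0, D_total=5.0,
                             Kd_A=20.0, alpha_K=20.0)
        f_A, f_As, _ = competitive_bound(mix)
        single = fraction_bound(BindingSystem(10.0, 5.0, 20.0))
        assert f_As == 0.0
        assert f_A == pytest.approx(single, abs=1e-9)

    def test_identical_species_pool_together(self):
        mix = MixtureBinding(A_total=6.0, As_total=4.0, D_total=5.0,
                             Kd_A=20.0, alpha_K=1.0)
        f_A, f_As, _ = competitive_bound(mix)
        pooled = fraction_bound(BindingSystem(10.0, 5.0, 20.0))
        assert f_A + f_As == pytest.approx(pooled, abs=1e-9)

    def test_matches_exhaustive_scan(self):
        mix = MixtureBinding(A_total=1.0, As_total=1.0, D_total=1.0,
                             Kd_A=1.0, alpha_K=10.0)
        f_A, f_As, d_free = competitive_bound(mix)
        o_A, o_As, o_d = scan_equilibrium(mix)
        assert f_A == pytest.approx(o_A, rel=1e-4)
        assert f_As == pytest.approx(o_As, rel=1e-4)
        assert d_free == pytest.approx(o_d, rel=1e-4)

    @given(a=st.floats(0.1, 500.0), as_=st.floats(0.1, 500.0),
           d=st.floats(1.0, 50.0), kd=st.floats(0.5, 200.0),
           alpha=st.floats(1.0, 50.0))
    @settings(max_examples=40, deadline=None)
    def test_mass_balance_and_oracle_agreement(self, a, as_, d, kd, alpha):
        mix = MixtureBinding(a, as_, d, kd, alpha)
        f_A, f_As, d_free = competitive_bound(mix)
        # probe conservation to 1e-9 relative
        assert d_free + (f_A + f_As) * d == pytest.approx(d, rel=1e-9)
        o_A, o_As, _ = scan_equilibrium(mix)
        assert f_A == pytest.approx(o_A, rel=1e-4, abs=1e-12)
        assert f_As == pytest.approx(o_As, rel=1e-4, abs=1e-12)


class TestAnisotropy:
    def test_linear_endpoints_and_midpoint(self):
        curve = TitrationCurve(points=((1.0, 0.1),), r_free=0.05,
                               r_bound=0.25, probe_conc=1.0)
        assert anisotropy(0.0, curve) == 0.05
        assert anisotropy(1.0, curve) == 0.25
        assert anisotropy(0.5, curve) == pytest.approx(0.15)

    def test_degenerate_curve_rejected(self):
        curve = TitrationCurve(points=((1.0, 0.1),), r_free=0.1,
                               r_bound=0.1, probe_conc=1.0)
        with pytest.raises(ValueError):
            anisotropy(0.5, curve)


class TestFitKd:
    def test_noise_free_round_trip(self):
        curve = gen_fp_titration(50.0, 0.05, 0.25, noise=NoiseModel(scale=0.0))
        fit = fit_kd(curve)
        assert fit.Kd_hat == pytest.approx(50.0, rel=1e-3)

    def test_mixture_inflates_apparent_kd(self):
        """A 50/50 apo/persulfidated mixture fits to a larger apparent K_D."""
        rs = []
        for c in DEFAULT_FP_GRID:
            f_A, f_As, _ = competitive_bound(
                MixtureBinding(c / 2, c / 2, 1.0, 50.0, 20.0))
            rs.append(0.05 + 0.2 * (f_A + f_As))
        curve = TitrationCurve(points=tuple(zip(DEFAULT_FP_GRID, rs)),
                               r_free=0.05, r_bound=0.25, probe_conc=1.0)
        assert fit_kd(curve).Kd_hat > 50.0

    def test_apparent_kd_monotone_in_modified_fraction(self):
        kds = []
        for phi in (0.0, 0.3, 0.6, 0.9):
            rs = []
            for c in DEFAULT_FP_GRID:
                f_A, f_As, _ = competitive_bound(
                    MixtureBinding((1 - phi) * c, phi * c, 1.0, 50.0, 20.0))
                rs.append(0.05 + 0.2 * (f_A + f_As))
            curve = TitrationCurve(points=tuple(zip(DEFAULT_FP_GRID, rs)),
                                   r_free=0.05, r_bound=0.25, probe_conc=1.0)
            kds.append(fit_kd(curve).Kd_hat)
        assert all(k2 > k1 for k1, k2 in zip(kds, kds[1:]))

    def test_flat_curve_unidentifiable(self):
        pts = tuple((c, 0.05) for c in DEFAULT_FP_GRID)
        curve = TitrationCurve(points=pts, r_free=0.05, r_bound=0.25,
                               probe_conc=1.0)
        with pytest.raises(ValueError):
            fit_kd(curve, noise_floor=0.005)

    def test_too_few_points_rejected(self):
        curve = TitrationCurve(points=((1.0, 0.05), (10.0, 0.1),
                                       (100.0, 0.2)),
                               r_free=0.05, r_bound=0.25, probe_conc=1.0)
        with pytest.raises(ValueError):
            fit_kd(curve)


class TestEmsaProfile:
    def test_unmodified_lanes_reproduce_fraction_bound(self):
        grid = [0.0, 10.0, 50.0, 200.0, 500.0]
        fracs = emsa_profile(grid, D=20.0, Kd_A=50.0, phi_mod=0.0,
                             alpha_K=20.0)
        for tf, f in zip(grid[1:], fracs[1:]):
            assert f == pytest.approx(
                fraction_bound(BindingSystem(tf, 20.0, 50.0)), abs=1e-9)
        assert fracs[0] == 0.0

    def test_fully_modified_binds_less(self):
        grid = [10.0, 50.0, 200.0, 500.0]
        apo = emsa_profile(grid, 20.0, 50.0, 0.0, 20.0)
        mod = emsa_profile(grid, 20.0, 50.0, 1.0, 20.0)
        assert np.all(mod < apo)

    def test_bound_fraction_decreasing_in_modified_fraction(self):
        """Lane-wise bound fraction drops monotonically as more of the TF
        pool is persulfidated (the gel-shift dose response)."""
        grid = np.linspace(25.0, 500.0, 6)
        profiles = [emsa_profile(grid, 20.0, 50.0, phi, 20.0)
                    for phi in (0.0, 0.5, 0.9)]
        assert np.all(profiles[0] > profiles[1])
        assert np.all(profiles[1] > profiles[2])

    def test_monotone_in_tf(self):
        grid = np.linspace(0.0, 500.0, 11)
        fracs = emsa_profile(grid, 20.0, 50.0, 0.5, 20.0)
        assert np.all(np.diff(fracs) >= 0)

    def test_invalid_phi_rejected(self):
        with pytest.raises(ValueError):
            emsa_profile([10.0], 20.0, 50.0, 1.5, 20.0)
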