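"""Rate laws: Eyring, Bell, hydrolysis heuristic, dimerization, surrogate."""

import math

import numpy as np
import pytest
from scipy import integrate, optimize, stats

import molkmc as mk
from molkmc.errors import EmptyEnsembleError, RecipeError
from molkmc.rate_models import (
    BarrierTable,
    Constants,
    DEFAULT_HAT_TABLE,
    hat_barrier_from_distance,
)
from molkmc.units import KB, KCALMOL_TO_PN_ANGSTROM, PLANCK

C300 = Constants()


class TestEyring:
    def test_zero_barrier_is_attempt_frequency(self):
        assert mk.eyring_rate(0.0, C300) == pytest.approx(
            KB * 300 / PLANCK, rel=1e-12
        )
        assert mk.eyring_rate(0.0, C300) == pytest.approx(6.25e12, rel=1e-2)

    def test_large_barrier_limit(self):
        assert mk.eyring_rate(500.0, C300) < 1e-300

    def test_strictly_decreasing(self):
        barriers = np.linspace(0, 40, 30)
        rates = mk.eyring_rate(barriers, C300)
        assert np.all(np.diff(rates) < 0)

    def test_negative_barrier_rejected(self):
        with pytest.raises(ValueError):
            mk.eyring_rate(-1.0, C300)

    def test_median_barrier_fold_change(self):
        """A 4.5 kcal/mol barrier advantage at 300 K is >= 1800-fold."""
        ratio = mk.eyring_rate(28.7, C300) / mk.eyring_rate(33.2, C300)
        assert ratio >= 1800.0
        assert ratio == pytest.approx(math.exp(4.5 / (KB * 300)), rel=1e-9)


class TestEnsembleAverage:
    def test_single_frame_equals_eyring(self):
        assert mk.ensemble_average_rate([17.0], C300) == pytest.approx(
            mk.eyring_rate(17.0, C300)
        )

    def test_identical_barriers(self):
        assert mk.ensemble_average_rate([12.0] * 3, C300) == pytest.approx(
            mk.eyring_rate(12.0, C300)
        )

    def test_low_barrier_frame_dominates(self):
        avg = mk.ensemble_average_rate([10.0, 20.0], C300)
        assert avg == pytest.approx(0.5 * mk.eyring_rate(10.0, C300), rel=1e-6)
        assert avg > mk.eyring_rate(15.0, C300)

    def test_jensen_inequality(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            barriers = rng.uniform(5, 35, size=rng.integers(2, 50))
            assert mk.ensemble_average_rate(barriers, C300) >= mk.eyring_rate(
                float(np.mean(barriers)), C300
            )

    def test_empty_rejected(self):
        with pytest.raises(EmptyEnsembleError):
            mk.ensemble_average_rate([], C300)


class TestBell:
    def test_zero_force_returns_k0(self):
        p = mk.BellParams(k0=1e-12, delta_x=0.5)
        assert mk.bell_rate(0.0, p, C300) == pytest.approx(1e-12)

    def test_log_rate_affine_in_force(self):
        p = mk.BellParams(k0=3e-10, delta_x=0.3)
        k0, k1, k2 = (mk.bell_rate(f, p, C300) for f in (0.0, 700.0, 1400.0))
        assert k2 / k1 == pytest.approx(k1 / k0, rel=1e-9)

    def test_direct_evaluation(self):
        p = mk.BellParams(k0=1e-12, delta_x=0.5)
        kT_pn_a = KB * 300 * KCALMOL_TO_PN_ANGSTROM
        assert mk.bell_rate(1000.0, p, C300) == pytest.approx(
            1e-12 * math.exp(500.0 / kT_pn_a), rel=1e-12
        )

    def test_strictly_increasing(self):
        p = mk.BellParams(k0=1e-12, delta_x=0.5)
        forces = np.linspace(0, 4000, 50)
        assert np.all(np.diff(mk.bell_rate(forces, p, C300)) > 0)


class TestHydrolysis:
    P = mk.HydrolysisParams()

    def test_reference_point(self):
        assert mk.hydrolysis_rate(
            self.P.F_ref, self.P.pH_ref, self.P.sasa_ref, self.P, C300
        ) == pytest.approx(self.P.k_ref)

    def test_zero_sasa_zero_rate(self):
        assert mk.hydrolysis_rate(500.0, 7.0, 0.0, self.P, C300) == 0.0

    def test_ph_decade_factor(self):
        k7 = mk.hydrolysis_rate(0.0, 7.0, 50.0, self.P, C300)
        k9 = mk.hydrolysis_rate(0.0, 9.0, 50.0, self.P, C300)
        assert k9 / k7 == pytest.approx(100.0)

    def test_force_response_bounded(self):
        sup = self.P.k_ref * math.exp(self.P.alpha * self.P.F_sat)
        forces = np.linspace(0, 1e6, 200)
        rates = mk.hydrolysis_rate(forces, self.P.pH_ref, self.P.sasa_ref, self.P, C300)
        assert np.all(rates <= sup * (1 + 1e-9))

    def test_crossover_force_exists(self):
        """Hydrolysis wins at 1 nN, but unbounded Bell homolysis overtakes
        it at some higher force (found numerically)."""
        bell = mk.BellParams()

        kT_pn_a = KB * 300 * KCALMOL_TO_PN_ANGSTROM

        def gap(f):
            log_bell = math.log(bell.k0) + f * bell.delta_x / kT_pn_a
            return log_bell - math.log(mk.hydrolysis_rate(f, 7.0, 50.0, self.P, C300))

        assert gap(1000.0) < 0  # hydrolysis dominates at 1 nN
        assert mk.bell_rate(1000.0, bell, C300) < mk.hydrolysis_rate(
            1000.0, 7.0, 50.0, self.P, C300
        )
        f_cross = optimize.brentq(gap, 1000.0, 1e5)
        assert f_cross > 1000.0
        assert gap(f_cross * 1.5) > 0  # homolysis dominates beyond


class TestDimerization:
    P = mk.DimerParams(A=1e12, d0=0.5, theta_max=60.0, rate_threshold=1e8)

    def test_far_distance_and_perpendicular_are_zero(self):
        assert mk.dimerization_rate(500.0, 0.0, self.P) == pytest.approx(0.0, abs=1e-250)
        assert mk.dimerization_rate(1.0, 90.0, self.P) == 0.0

    def test_angle_window(self):
        assert mk.dimerization_rate(1.0, 59.0, self.P) > 0
        assert mk.dimerization_rate(1.0, 61.0, self.P) == 0.0

    def test_constructed_yield_is_exact(self):
        inside = np.full(300, 2.0), np.zeros(300)  # rate ~ 1.8e10 > 1e8
        outside = np.full(700, 50.0), np.full(700, 170.0)
        ge = mk.GeometryEnsemble(
            distances=np.concatenate([inside[0], outside[0]]),
            dihedrals=np.concatenate([inside[1], outside[1]]),
        )
        assert mk.quantum_yield(ge, self.P) == pytest.approx(0.300)

    def test_yield_monotone_in_threshold(self):
        ge = mk.synth_dimer_geometry_ensemble(3.5, 0.6, 0.0, 40.0, n=20_000, seed=5)
        thresholds = [1e2, 1e4, 1e6, 1e8]
        yields = [
            mk.quantum_yield(
                ge, mk.DimerParams(A=1e12, d0=0.5, theta_max=60.0, rate_threshold=th)
            )
            for th in thresholds
        ]
        assert all(a >= b for a, b in zip(yields, yields[1:]))

    def test_sampled_yield_matches_analytic_window_probability(self):
        """Monte Carlo quantum yield versus direct numerical integration of
        the generating distributions (truncated-normal distance, wrapped-
        normal dihedral)."""
        p = self.P
        d_mean, d_sd, th_mean, th_sd, n = 5.5, 0.5, 0.0, 35.0, 100_000
        ge = mk.synth_dimer_geometry_ensemble(d_mean, d_sd, th_mean, th_sd, n, seed=11)
        phi = mk.quantum_yield(ge, p)

        a = (0.0 - d_mean) / d_sd
        dmax = lambda th: p.d0 * (
            math.log(p.A / p.rate_threshold) + math.log(math.cos(math.radians(th)))
        )

        def wrapped_pdf(th):
            return sum(
                stats.norm.pdf(th + 360.0 * k, loc=th_mean, scale=th_sd)
                for k in range(-3, 4)
            )

        def integrand(th):
            top = dmax(th)
            if top <= 0:
                return 0.0
            return wrapped_pdf(th) * stats.truncnorm.cdf(
                top, a, np.inf, loc=d_mean, scale=d_sd
            )

        p_true, _ = integrate.quad(integrand, -p.theta_max, p.theta_max, limit=200)
        se = math.sqrt(p_true * (1 - p_true) / n)
        assert abs(phi - p_true) <= 3 * se

    def test_empty_rejected(self):
        with pytest.raises(Exception):
            mk.quantum_yield(
                mk.GeometryEnsemble(distances=np.empty(0), dihedrals=np.empty(0)),
                self.P,
            )


class TestSurrogateBarrier:
    def test_pure_function_of_geometry(self, octyl_radical):
        t, f = octyl_radical
        h = [a.index for a in t.atoms if a.element == "H"][5]
        b1 = mk.surrogate_hat_barrier(t, h, 0, f)
        b2 = mk.surrogate_hat_barrier(t, h, 0, f.copy())
        assert b1 == b2

    def test_covalent_distance_gives_bare_table_value(self):
        assert hat_barrier_from_distance("1-5", 1.1, DEFAULT_HAT_TABLE) == (
            DEFAULT_HAT_TABLE.entries["1-5"]
        )
        assert hat_barrier_from_distance("1-5", 0.8, DEFAULT_HAT_TABLE) == (
            DEFAULT_HAT_TABLE.entries["1-5"]
        )

    def test_distance_penalty_slope(self):
        b = hat_barrier_from_distance("1-4", 2.1, DEFAULT_HAT_TABLE)
        assert b == pytest.approx(
            DEFAULT_HAT_TABLE.entries["1-4"] + DEFAULT_HAT_TABLE.slope * 1.0
        )

    def test_ring_strain_ordering(self):
        """1-2 and 1-3 shifts carry the highest barriers, 1-5 the lowest."""
        e = DEFAULT_HAT_TABLE.entries
        assert e["1-2"] > e["1-3"] > e["1-4"] > e["1-5"]
        assert e["1-6"] > e["1-5"]
        assert min(e["1-2"], e["1-3"]) > max(e["1-4"], e["1-5"], e["1-6"])

    def test_missing_label_falls_back_to_default(self):
        table = BarrierTable(entries={"default": 30.0}, slope=0.0)
        assert hat_barrier_from_distance("1-9", 1.0, table) == 30.0
        with pytest.raises(Exception):
            BarrierTable(entries={}, slope=0.0).lookup("1-5")

    def test_invalid_candidates_rejected(self, octyl_radical):
        t, f = octyl_radical
        with pytest.raises(RecipeError):
            mk.surrogate_hat_barrier(t, 1, 0, f)  # not a hydrogen


def test_all_rates_finite_nonnegative():
    rng = np.random.default_rng(3)
    for _ in range(100):
        k = mk.eyring_rate(float(rng.uniform(0, 60)), C300)
        assert np.isfinite(k) and k >= 0
        k = mk.bell_rate(float(rng.uniform(0, 5000)), mk.BellParams(), C300)
        assert np.isfinite(k) and k >= 0
        k = mk.hydrolysis_rate(
            float(rng.uniform(0, 5000)), float(rng.uniform(2, 12)),
            float(rng.uniform(0, 200)), mk.HydrolysisParams(), C300,
        )
        assert np.isfinite(k) and k >= 0
        k = mk.dimerization_rate(
            float(rng.uniform(0, 20)), float(rng.uniform(-180, 180)), mk.DimerParams()
        )
        assert np.isfinite(k) and k >= 0
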