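"""COSMO-SAC correctness via thermodynamic identities and small oracles."""

from types import SimpleNamespace

import numpy as np
import pytest

from sfelip import synthetic_data as sd
from sfelip.cosmo_idac import (
    DEFAULT_PARAMETERS,
    CosmoParameters,
    MixtureState,
    average_segments,
    celsius_to_kelvin,
    exchange_energy,
    flows_to_mole_fractions,
    idac_curve,
    ln_activity_coefficient,
    solve_segment_gammas,
)
from sfelip.io_core import ValidationError, default_sigma_grid

T50 = celsius_to_kelvin(50.0)


class TestAverageSegments:
    def test_single_segment_at_zero_lands_in_central_bin(self):
        prof = average_segments([(np.zeros(3), 5.0, 0.0)])
        assert prof.p[25] == pytest.approx(5.0)
        assert prof.p.sum() == pytest.approx(5.0)

    def test_distant_equal_segments_give_symmetric_profile(self):
        segs = [
            (np.array([0.0, 0, 0]), 4.0, 0.01),
            (np.array([100.0, 0, 0]), 4.0, -0.01),
        ]
        prof = average_segments(segs)
        assert np.allclose(prof.p, prof.p[::-1], atol=1e-12)

    def test_mirror_equivariance(self):
        rng = np.random.default_rng(0)
        segs = [
            (rng.normal(size=3), float(rng.uniform(1, 3)), float(rng.uniform(-0.015, 0.015)))
            for _ in range(12)
        ]
        mirrored = [(p, a, -s) for p, a, s in segs]
        prof = average_segments(segs)
        prof_m = average_segments(mirrored)
        assert np.allclose(prof.p, prof_m.p[::-1], atol=1e-9)

    def test_empty_rejected(self):
        with pytest.raises(ValidationError, match="empty"):
            average_segments([])


class TestExchangeEnergy:
    def test_opposite_signs_below_hb_cutoff_is_zero(self):
        assert exchange_energy(0.005, -0.005) == pytest.approx(0.0)

    def test_symmetry(self):
        assert exchange_energy(0.013, -0.021) == exchange_energy(-0.021, 0.013)

    def test_reference_value_straight_line_rederivation(self):
        # independent re-evaluation of misfit + hydrogen-bond terms
        p = DEFAULT_PARAMETERS
        sm, sn = 0.01, -0.02
        misfit = 0.5 * p.alpha_prime * (sm + sn) ** 2
        hb = p.c_hb * max(0.0, max(sm, sn) - p.sigma_hb) * min(0.0, min(sm, sn) + p.sigma_hb)
        assert exchange_energy(sm, sn) == pytest.approx(misfit + hb, rel=1e-12)
        assert hb < 0  # attractive donor/acceptor pair


class TestSegmentSolver:
    def test_ideal_limit_zero_exchange_energy(self):
        params = CosmoParameters(alpha_prime=0.0, c_hb=0.0)
        p = np.random.default_rng(1).random(51)
        p /= p.sum()
        g = solve_segment_gammas(p, T50, params=params)
        assert np.allclose(g.ln_gamma, 0.0, atol=1e-12)

    def test_two_bin_fixed_point_matches_grid_search(self):
        grid = np.array([-0.005, 0.005])
        p = np.array([0.4, 0.6])
        g = solve_segment_gammas(p, T50, grid=grid, tol=1e-12)
        # brute-force oracle: progressively refined 2-D grid search on (G1, G2)
        dW = exchange_energy(grid[:, None], grid[None, :])
        psi = np.exp(-dW / (1.987204259e-3 * T50))

        def residual(G):
            return np.max(np.abs(G * (psi @ (p * G)) - 1.0))

        lo, hi = np.full(2, 0.01), np.full(2, 5.0)
        best = None
        for _ in range(12):
            g1 = np.linspace(lo[0], hi[0], 21)
            g2 = np.linspace(lo[1], hi[1], 21)
            vals = [(residual(np.array([a, b])), a, b) for a in g1 for b in g2]
            _, a, b = min(vals)
            span = (hi - lo) / 10
            lo, hi = np.array([a, b]) - span, np.array([a, b]) + span
            best = np.array([a, b])
        assert np.exp(g.ln_gamma) == pytest.approx(best, abs=1e-8)

    def test_convergence_monotone_in_damping_on_mild_toy(self):
        # the undamped substitution alternates around the fixed point, so on
        # this toy the iteration count falls monotonically as damping rises
        # towards the optimal 0.5 mixing
        grid = np.array([-0.005, 0.005])
        p = np.array([0.5, 0.5])
        iters = [
            solve_segment_gammas(p, T50, grid=grid, tol=1e-10, damping=d).iterations
            for d in (0.2, 0.35, 0.5)
        ]
        assert iters[0] >= iters[1] >= iters[2]


class TestActivityCoefficient:
    def test_pure_component_identity(self, solvent_profiles, lipid_profiles):
        for prof in list(solvent_profiles) + list(lipid_profiles.values())[:3]:
            state = MixtureState([prof], [1.0], T50)
            assert abs(ln_activity_coefficient(0, state)) < 1e-10

    def test_identical_components_ideal_at_any_composition(self, solvent_profiles):
        co2, _ = solvent_profiles
        twin = co2.renamed("twin")
        for x in (0.1, 0.5, 0.9):
            state = MixtureState([co2, twin], [x, 1 - x], T50)
            assert abs(ln_activity_coefficient(0, state)) < 1e-10
            assert abs(ln_activity_coefficient(1, state)) < 1e-10

    def test_component_relabeling_invariance(self, solvent_profiles):
        co2, eth = solvent_profiles
        a = ln_activity_coefficient(0, MixtureState([co2, eth], [0.3, 0.7], T50))
        b = ln_activity_coefficient(1, MixtureState([eth, co2], [0.7, 0.3], T50))
        assert a == pytest.approx(b, abs=1e-12)

    def test_binary_gibbs_duhem_trapezoid(self, solvent_profiles):
        co2, eth = solvent_profiles
        xs = np.linspace(0.02, 0.98, 49)
        ln1 = np.array(
            [ln_activity_coefficient(0, MixtureState([co2, eth], [x, 1 - x], T50)) for x in xs]
        )
        ln2 = np.array(
            [ln_activity_coefficient(1, MixtureState([co2, eth], [x, 1 - x], T50)) for x in xs]
        )
        mid = (xs[1:] + xs[:-1]) / 2
        residual = float(np.abs((mid * np.diff(ln1) + (1 - mid) * np.diff(ln2)).sum()))
        assert residual < 1e-3


class TestIdacCurve:
    def test_lipid_identical_to_ethanol_limit(self, solvent_profiles):
        co2, eth = solvent_profiles
        lipid = eth.renamed("pseudo-lipid")
        val = idac_curve(lipid, (co2, eth), T50, [1.0 - 1e-9])[0]
        assert abs(val) < 1e-3

    def test_already_at_infinite_dilution(self, solvent_profiles, lipid_profiles):
        co2, eth = solvent_profiles
        lipid = next(iter(lipid_profiles.values()))
        a = idac_curve(lipid, (co2, eth), T50, [0.1], x_lipid=1e-5)[0]
        b = idac_curve(lipid, (co2, eth), T50, [0.1], x_lipid=5e-6)[0]
        assert abs(a - b) < 1e-4

    def test_grid_outside_unit_interval_rejected(self, solvent_profiles, lipid_profiles):
        co2, eth = solvent_profiles
        lipid = next(iter(lipid_profiles.values()))
        with pytest.raises(ValidationError):
            idac_curve(lipid, (co2, eth), T50, [0.5, 1.0])

    def test_regression_pinned_snapshot(self, solvent_profiles):
        """Frozen curve for one polar synthetic lipid: guards the full
        solver + combinatorial stack against silent numerical drift."""
        co2, eth = solvent_profiles
        config = sd.GeneratorConfig(seed=1, n_lipids=5)
        records, _ = sd.generate_lipid_library(config)
        profiles = sd.generate_sigma_profiles(records, config)
        gpl = next(r for r in records if r.lipid_class == "glycerophospholipids")
        xs = np.arange(0.0, 0.91, 0.1)
        curve = idac_curve(profiles[gpl.lipid_id], (co2, eth), celsius_to_kelvin(50), xs)
        expected = [
            0.692774, -0.702336, -1.005348, -1.093354, -1.085019,
            -1.026656, -0.94265, -0.848181, -0.753692, -0.666708,
        ]
        assert curve == pytest.approx(expected, abs=1e-5)


class TestFlowsToMoleFractions:
    def test_arithmetic_oracle(self):
        cond = SimpleNamespace(co2_flow=5.0, ethanol_flow=0.6)
        n_eth = 0.6 * 0.789 / 46.07
        n_co2 = 5.0 * 0.90 / 44.01
        x_co2, x_eth = flows_to_mole_fractions(cond)
        assert x_eth == pytest.approx(n_eth / (n_eth + n_co2), rel=1e-12)
        assert x_eth == pytest.approx(0.091, abs=5e-4)
        assert x_co2 + x_eth == pytest.approx(1.0)

    def test_zero_ethanol_flow(self):
        cond = SimpleNamespace(co2_flow=5.0, ethanol_flow=0.0)
        assert flows_to_mole_fractions(cond)[1] == 0.0

    def test_scale_invariance(self):
        a = flows_to_mole_fractions(SimpleNamespace(co2_flow=5.0, ethanol_flow=0.9))
        b = flows_to_mole_fractions(SimpleNamespace(co2_flow=10.0, ethanol_flow=1.8))
        assert a == pytest.approx(b, rel=1e-12)

    def test_nonpositive_co2_flow_rejected(self):
        with pytest.raises(ValidationError):
            flows_to_mole_fractions(SimpleNamespace(co2_flow=0.0, ethanol_flow=0.6))
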