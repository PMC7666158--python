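"""Response-surface metrics on constructed and simulated surfaces."""

import numpy as np
import pytest

from phosphoswitch import (
    FluxGrid,
    ModelParameters,
    ReactionNetwork,
    ResponseSurface,
    detect_local_minimum,
    equal_sensitivity_line,
    find_inflection,
    run_affinity_scenarios,
    run_flux_scan,
)
from phosphoswitch.scan import FlatResponseError
from phosphoswitch.species import ConfigurationError


def synthetic_surface(f, n=21):
    """Surface on pp axes spanning 1e-3..1 µM (log), response = f(ppj, ppp)."""
    axis = np.logspace(-3, 0, n)
    ppp, ppj = np.meshgrid(axis, axis, indexing="ij")
    grid = FluxGrid(np.logspace(-6, -2, n), np.logspace(-6, -2, n))
    return ResponseSurface(grid, ppj, ppp, f(ppj, ppp))


class TestInflection:
    def test_hill_midpoint_recovered(self):
        """Hill response with midpoint at 10% of the axis maximum → ~10%."""
        x50 = 0.1  # axis max is 1 µM
        surf = synthetic_surface(lambda j, p: 1.0 / (1.0 + (x50 / j) ** 2))
        got = find_inflection(surf, path="jnk_axis")
        # within one coarse grid step (axis step ~x1.41)
        assert 10.0 / 1.45 < got < 10.0 * 1.45

    def test_flat_response_raises(self):
        surf = synthetic_surface(lambda j, p: np.full_like(j, 0.4))
        with pytest.raises(FlatResponseError):
            find_inflection(surf, path="diagonal")

    def test_requires_enough_samples(self):
        surf = synthetic_surface(lambda j, p: j, n=8)
        with pytest.raises(ConfigurationError):
            find_inflection(surf, path="jnk_axis")

    def test_unknown_path_rejected(self):
        surf = synthetic_surface(lambda j, p: j)
        with pytest.raises(ConfigurationError):
            find_inflection(surf, path="antidiagonal")


class TestEqualSensitivity:
    def test_separable_surface_analytic_locus(self):
        """f = a·log(ppj) + b·log(ppp)²: locus is log(ppp) = a/(2b)."""
        a, b = -2.0, 0.5
        surf = synthetic_surface(
            lambda j, p: a * np.log(j) + b * np.log(p) ** 2
        )
        line = equal_sensitivity_line(surf)
        expected_ppp = np.exp(a / (2 * b))  # e^-2 ≈ 0.135 µM, inside the axis
        assert len(line) > 5
        assert np.allclose(line[:, 1], expected_ppp, rtol=0.15)

    def test_one_signed_field_warns_and_returns_empty(self):
        surf = synthetic_surface(lambda j, p: np.log(j))  # only JNK-sensitive
        with pytest.warns(UserWarning):
            line = equal_sensitivity_line(surf)
        assert line.shape == (0, 2)

    def test_symmetric_kinases_give_diagonal(self):
        """Identical binding/catalysis/activation rates for both MAPKs with
        the S90 pathway off: the contour is the main diagonal."""
        # With S90 never phosphorylated, pp-p38 binds via the bipartite
        # channel and np-p38 via the DRS channel; giving both JNK's rates
        # makes the two kinases exactly interchangeable.
        params = ModelParameters().updated(
            k2=0.0, dp4=0.0,                       # S90 pathway off
            kon2=1.0, koff2=5.0,                   # pp-p38 binds like JNK
            kon3=1.0, koff3=5.0,                   # np-p38 binds like JNK
            k3=0.1, k4=0.1,                        # p38 catalyzes like JNK
            k_eq6=1e-6, k_eq7=1e-6, dp1=4.5e-3, dp2=4.5e-3,
        )
        net = ReactionNetwork.build(params)
        surf = run_flux_scan(net, params, FluxGrid.default(15))
        assert np.allclose(surf.pp_atf2, surf.pp_atf2.T, atol=1e-6)
        line = equal_sensitivity_line(surf)
        assert len(line) > 0
        # on the diagonal pp-JNK = pp-p38 (symmetry)
        assert np.allclose(np.log(line[:, 0]), np.log(line[:, 1]), atol=0.35)


class TestLocalMinima:
    def test_constructed_row(self):
        assert detect_local_minimum(np.array([0.1, 0.05, 0.3])) == [1]

    def test_monotone_row_has_none(self):
        assert detect_local_minimum(np.linspace(0, 1, 9)) == []

    def test_noise_floor_suppresses_shallow_dips(self):
        row = np.array([0.1, 0.0999, 0.3])
        assert detect_local_minimum(row, noise_floor=1e-3) == []
        assert detect_local_minimum(row, noise_floor=1e-5) == [1]


class TestScenariosAndScan:
    @pytest.fixture(scope="class")
    @staticmethod
    def small_grid():
        return FluxGrid.default(6)

    def test_identity_scenario_reproduces_baseline(self, small_grid):
        params = ModelParameters().with_variant("WT")
        out = run_affinity_scenarios(params, ("identity",), small_grid)
        assert np.array_equal(out["baseline"].pp_atf2, out["identity"].pp_atf2)
        assert np.array_equal(out["baseline"].pp_jnk, out["identity"].pp_jnk)

    def test_unknown_scenario_rejected(self, small_grid):
        with pytest.raises(ConfigurationError):
            run_affinity_scenarios(ModelParameters(), ("kon5_x100",), small_grid)

    def test_stimulation_to_activity_mapping_is_monotone(self, small_grid):
        params = ModelParameters().with_variant("WT")
        net = ReactionNetwork.build(params)
        surf = run_flux_scan(net, params, small_grid)
        assert np.all(np.diff(surf.pp_jnk, axis=1) > 0)
        assert np.all(np.diff(surf.pp_p38, axis=0) > 0)

    def test_minimum_corner_equals_baseline(self, small_grid):
        """Both rates at the basal 1e-6: the pre-equilibrated state persists."""
        params = ModelParameters().with_variant("WT")
        net = ReactionNetwork.build(params)
        surf = run_flux_scan(net, params, small_grid)
        from phosphoswitch.simulate import Trajectory, pre_equilibrate

        steady = pre_equilibrate(net, params)
        base = Trajectory(np.array([0.0]), steady[None, :], net, params)
        assert surf.pp_atf2[0, 0] == pytest.approx(
            base.observables["pp_atf2_fraction"][0], abs=1e-6
        )

    def test_grid_must_increase(self):
        with pytest.raises(ConfigurationError):
            FluxGrid(np.array([1e-3, 1e-4]), np.array([1e-6, 1e-5]))

    def test_axis_inflection_stable_under_density_doubling(self):
        """p38-axis inflection moves by less than one coarse-grid step."""
        params = ModelParameters().with_variant("WT")
        net = ReactionNetwork.build(params)

        def axis_inflection(n):
            grid = FluxGrid(np.logspace(-6, -2, n), np.logspace(-6, -2, 1))
            surf = run_flux_scan(net, params, grid)
            return find_inflection(surf, path="p38_axis")

        coarse = axis_inflection(15)
        fine = axis_inflection(29)
        step = 10 ** (4.0 / 14)  # coarse-grid multiplicative step
        assert coarse / step < fine < coarse * step
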