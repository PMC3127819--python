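"""Nullclines, equilibrium finding, stability, bifurcation and basins."""

import numpy as np
import pytest

from tetswitch.equilibria import (
    RHS_TOL,
    basin_of_attraction,
    bifurcation_scan,
    classify_stability,
    find_equilibria,
    nullclines,
    relative_rhs_norm,
)
from tetswitch.model import pfl_rhs


class TestNullclines:
    def test_linear_nullcline_through_origin(self, p):
        nc = nullclines(0.0, p, np.linspace(0.0, 10.0, 11))
        assert nc["mrna_dx2"].iloc[0] == 0.0
        slopes = np.diff(nc["mrna_dx2"]) / np.diff(nc["tta"])
        assert np.allclose(slopes, p.d2 / p.kp)

    def test_basal_intercept_of_mrna_nullcline(self, p):
        nc = nullclines(0.0, p, np.array([0.0, 1.0]))
        assert nc["mrna_dx1"].iloc[0] == pytest.approx(p.v1 * p.alpha0 / p.d1, rel=1e-12)

    def test_intersections_agree_with_equilibria(self, p):
        # brute-force sign-change scan of the curve difference as the oracle
        grid = np.linspace(0.0, 30.0, 30001)
        nc = nullclines(0.0, p, grid)
        diff = (nc["mrna_dx1"] - nc["mrna_dx2"]).to_numpy()
        crossings = grid[:-1][np.sign(diff[:-1]) != np.sign(diff[1:])]
        roots = sorted(e.x2 for e in find_equilibria(0.0, p).points)
        assert len(crossings) == len(roots) == 3
        assert np.allclose(crossings, roots, atol=grid[1] - grid[0])

    def test_empty_grid_rejected(self, p):
        with pytest.raises(ValueError):
            nullclines(0.0, p, np.array([]))


class TestFindEquilibria:
    def test_bistable_at_zero_dox(self, p):
        es = find_equilibria(0.0, p)
        assert len(es) == 3
        assert es.n_stable == 2 and es.n_unstable == 1
        for e in es.points:
            assert relative_rhs_norm(e.state, 0.0, p) < RHS_TOL

    def test_unstable_point_sits_between_the_stable_pair(self, p):
        labels = [e.stability for e in sorted(find_equilibria(0.0, p).points,
                                              key=lambda e: e.x2)]
        assert labels == ["stable", "unstable", "stable"]

    def test_monostable_at_saturating_dox(self, p):
        es = find_equilibria(1000.0, p)
        assert len(es) == 1 and es.n_stable == 1
        assert es.points[0].x2 < 1e-2  # the OFF state

    def test_origin_only_without_production(self, p):
        es = find_equilibria(0.0, p.replace(v1=1e-30))
        assert len(es) == 1
        assert np.allclose(es.points[0].state, 0.0, atol=1e-20)


class TestClassifyStability:
    def test_middle_equilibrium_is_unstable(self, p):
        mid = sorted(find_equilibria(0.0, p).points, key=lambda e: e.x2)[1]
        label, eig = classify_stability(mid.state, 0.0, p)
        assert label == "unstable"
        assert np.max(eig.real) > 0.0

    def test_nopfl_eigenvalues_independent_of_dox(self, p):
        x = np.array([1.0, 1.0, 1.0])  # any state: linear system
        # build an equilibrium state so the residual check passes
        from tetswitch.simulate import steady_state

        for dox in (0.0, 50.0):
            ss = steady_state("NOPFL", dox, p)
            x = np.array([ss.x1, ss.x3, ss.x4])
            _, eig = classify_stability(x, dox, p, network="NOPFL")
            assert np.allclose(np.sort(eig.real),
                               np.sort([-p.d1, -(p.Kf + p.d3), -p.d3]))

    def test_non_equilibrium_rejected(self, p):
        with pytest.raises(ValueError, match="not an equilibrium"):
            classify_stability(np.array([5.0, 5.0, 5.0, 5.0]), 0.0, p)


class TestBifurcationScan:
    def test_default_scan_rows(self, p):
        table = bifurcation_scan([0.1, 1.0, 10.0, 100.0], p)
        first, last = table.iloc[0], table.iloc[-1]
        assert first["n_equilibria"] == 3 and first["n_stable"] == 2
        assert last["n_equilibria"] == 1 and last["n_stable"] == 1

    def test_single_transition_along_dense_scan(self, p):
        table = bifurcation_scan(np.geomspace(0.01, 1000.0, 25), p)
        counts = table["n_equilibria"].to_numpy()
        assert counts[0] == 3 and counts[-1] == 1
        assert np.all(np.diff(counts) <= 0)  # monotone 3 -> 1

    def test_empty_scan_rejected(self, p):
        with pytest.raises(ValueError):
            bifurcation_scan([], p)


class TestBasins:
    def test_monostable_lattice_has_single_label(self, p):
        lattice, fractions = basin_of_attraction(
            1000.0, p, tta_grid=np.linspace(0.0, 20.0, 5),
            mrna_grid=np.linspace(0.0, 8.0, 5),
        )
        assert set(lattice["label"]) == {"OFF"}
        assert fractions["OFF"] == 1.0

    def test_off_basin_much_smaller_than_on_basin_without_dox(self, p):
        lattice, fractions = basin_of_attraction(
            0.0, p, tta_grid=np.linspace(0.0, 25.0, 11),
            mrna_grid=np.linspace(0.0, 10.0, 11),
        )
        assert fractions.get("undetermined", 0.0) == 0.0
        assert fractions["OFF"] < 0.5 * fractions["ON"]

    def test_off_basin_grows_with_dox(self, p):
        fracs = []
        for dox in (0.0, 10.0):
            _, fractions = basin_of_attraction(
                dox, p, tta_grid=np.linspace(0.0, 25.0, 9),
                mrna_grid=np.linspace(0.0, 10.0, 9),
            )
            fracs.append(fractions.get("OFF", 0.0))
        assert fracs[1] >= fracs[0]

    def test_stable_equilibria_map_to_themselves(self, p):
        es = find_equilibria(0.0, p)
        for e in es.stable():
            lattice, _ = basin_of_attraction(
                0.0, p, tta_grid=[e.state[1]], mrna_grid=[e.state[0]],
            )
            expected = "OFF" if e.x2 < 1.0 else "ON"
            assert lattice["label"].iloc[0] == expected
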