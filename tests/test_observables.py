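"""Current extraction, steady detection, half-time, mass balance."""

import numpy as np
import pytest

from ampersim.fem import FieldState, SolverConfig, build_system, run_transient, solve_steady
from ampersim.model import DimensionalParams, build_problem
from ampersim.observables import (
    CurrentTrace,
    dimensional_current,
    dimensionless_current_from_density,
    electrode_current,
    electrode_current_direct,
    half_time,
    mass_balance_report,
    steady_state_current,
)

from conftest import slab_mesh, slab_params


@pytest.fixture(scope="module")
def slab_system():
    m = slab_mesh(h=0.5)
    return build_system(build_problem(slab_params(0.0), m), m), m


class TestElectrodeCurrent:
    def test_linear_profile_closed_form(self, slab_system):
        """P = c z gives i = c * ∫ r dr = c/2."""
        sys_, m = slab_system
        c = 3.7
        st = FieldState(0.0, c * m.points[:, 1], np.zeros(sys_.n_s))
        assert electrode_current(sys_, st) == pytest.approx(c / 2, rel=1e-12)
        assert electrode_current_direct(sys_, st) == pytest.approx(c / 2, rel=1e-10)

    def test_zero_field_zero_current(self, slab_system):
        sys_, m = slab_system
        st = FieldState(0.0, np.zeros(sys_.n_nodes), np.zeros(sys_.n_s))
        assert electrode_current(sys_, st) == 0.0

    def test_consistent_and_direct_agree_on_solution(self):
        m = slab_mesh(h=0.25, h_min=0.05, growth=1.3)
        st, sys_ = solve_steady(build_problem(slab_params(100.0), m), m)
        ic = electrode_current(sys_, st)
        idir = electrode_current_direct(sys_, st)
        assert idir == pytest.approx(ic, rel=5e-3)


class TestDimensionalCurrent:
    P = DimensionalParams(
        D1_star=3e-6, D2_star=3e-6, D3_star=6e-6,
        a1_star=1e-3, a2_star=1e-4, a3_star=1e-4,
        b1_star=2e-3, b2_star=4e-3, b3_star=9e-3, b4_star=1.4e-2, b5_star=1.6e-2,
        S0_star=1e-4, Vmax=1e-2, Km=1e-4, ne=2,
    )

    def test_zero_maps_to_zero(self):
        assert dimensional_current(0.0, self.P) == 0.0

    def test_linear_in_ne(self):
        import dataclasses

        p2 = dataclasses.replace(self.P, ne=4)
        assert dimensional_current(1.0, p2) == pytest.approx(
            2 * dimensional_current(1.0, self.P)
        )

    def test_roundtrip(self):
        i = 0.0123
        i_star = dimensional_current(i, self.P)
        assert dimensionless_current_from_density(i_star, self.P) == pytest.approx(
            i, rel=1e-15
        )


class TestSteadyDetection:
    def test_constant_trace(self):
        t = np.linspace(0, 3, 61)
        tr = steady_state_current(CurrentTrace(t, np.full_like(t, 2.5)),
                                  window=1.0, t_min=0.0)
        assert tr.converged and tr.I == pytest.approx(2.5)

    def test_exponential_saturation(self):
        t = np.linspace(0, 30, 3001)
        tr = steady_state_current(CurrentTrace(t, 1 - np.exp(-t)),
                                  eps_ss=1e-4, window=1.0, t_min=0.0)
        assert tr.converged
        assert tr.I == pytest.approx(1.0, abs=1e-3)
        # detection happens once t > -ln(eps): not much earlier
        assert tr.times[-1] > 8.0

    def test_unconverged_trace_flagged(self):
        t = np.linspace(0, 5, 101)
        tr = steady_state_current(CurrentTrace(t, t), window=1.0, t_min=0.0)
        assert not tr.converged and tr.I is None

    def test_tightening_epsilon_changes_I_little(self):
        m = slab_mesh(h=0.5, h_min=0.1, growth=1.3)
        prob = build_problem(slab_params(10.0), m)
        out = []
        for eps in (1e-4, 1e-5):
            cfg = SolverConfig(dt=0.02, dt_max=0.4, dt_growth=1.1, t_max=400,
                               eps_ss=eps)
            tr, _, _ = run_transient(prob, m, cfg)
            out.append(tr.I)
        assert abs(out[1] - out[0]) / out[1] < 1e-3


class TestHalfTime:
    def test_exponential_inversion(self):
        t = np.linspace(0, 30, 30001)
        tr = CurrentTrace(t, 1 - np.exp(-t), I=1.0, converged=True)
        assert half_time(tr) == pytest.approx(np.log(2), abs=1e-3)

    def test_piecewise_linear(self):
        t = np.linspace(0, 10, 1001)
        tr = CurrentTrace(t, np.minimum(t / 2, 1.0), I=1.0, converged=True)
        assert half_time(tr) == pytest.approx(1.0, abs=1e-9)

    def test_sampling_resolution_bound(self):
        for dt in (0.01, 0.005):
            t = np.arange(0, 20, dt)
            tr = CurrentTrace(t, 1 - np.exp(-t), I=1.0, converged=True)
            assert abs(half_time(tr) - np.log(2)) < dt

    def test_zero_current_undefined(self):
        t = np.linspace(0, 10, 11)
        tr = CurrentTrace(t, np.zeros_like(t), I=0.0, converged=True)
        assert half_time(tr) is None


class TestMassBalance:
    def test_no_reaction_ledger_zero(self):
        m = slab_mesh(h=0.5)
        st, sys_ = solve_steady(build_problem(slab_params(0.0), m), m)
        rep = mass_balance_report(sys_, st)
        assert rep["reaction_total"] == pytest.approx(0.0, abs=1e-12)
        assert rep["product_efflux_electrode"] == pytest.approx(0.0, abs=1e-10)

    def test_steady_closure_small(self):
        m = slab_mesh(h=0.5, h_min=0.05, growth=1.3)
        st, sys_ = solve_steady(build_problem(slab_params(100.0), m), m)
        rep = mass_balance_report(sys_, st)
        assert rep["closure_substrate"] < 1e-2
        assert rep["closure_product"] < 1e-2

    def test_refinement_shrinks_closure(self):
        errs = []
        for h, hmin in ((1.0, 0.2), (0.5, 0.1), (0.25, 0.05)):
            m = slab_mesh(h=h, h_min=hmin, growth=1.3)
            st, sys_ = solve_steady(build_problem(slab_params(100.0), m), m)
            rep = mass_balance_report(sys_, st)
            errs.append(max(rep["closure_substrate"], rep["closure_product"]))
        assert errs[2] < errs[0]

    def test_trace_csv_roundtrip(self, tmp_path):
        t = np.linspace(0, 1, 11)
        tr = CurrentTrace(t, t**2)
        path = tmp_path / "trace.csv"
        tr.to_csv(path)
        data = np.loadtxt(path, delimiter=",", skiprows=1)
        np.testing.assert_allclose(data[:, 1], t**2, atol=1e-9)
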