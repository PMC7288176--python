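"""Biosensor response quantities: current, steady state, half-time, mass balance.

The dimensionless electrode current is the r-weighted product flux through
the electrode disc,

.. math:: i(t) = \\int_0^1 \\left.\\partial_z P\\right|_{z=0} \\, r\\, dr ,

evaluated by the consistent (residual-based) boundary-flux method: summing
the interior weak residual over the electrode Dirichlet nodes yields the
discrete flux that is exactly conserved by the Galerkin scheme and
superconverges relative to pointwise gradients.  A direct-gradient
estimator is also provided as an independent cross-check and for the
mass-balance ledger.

The steady-state current ``I`` is the long-time limit of ``i(t)``;
operationally it is declared once the current changes by less than a
relative tolerance over a trailing time window.  The half-time response
``T_0.5`` is the first time the current reaches half of ``I``.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CurrentTrace",
    "SteadyDetector",
    "electrode_current",
    "electrode_current_direct",
    "boundary_flux_direct",
    "dimensional_current",
    "dimensionless_current_from_density",
    "steady_state_current",
    "half_time",
    "mass_balance_report",
]


@dataclass
class CurrentTrace:
    """Sampled transient current with derived steady-state quantities."""

    times: np.ndarray
    i_values: np.ndarray
    I: float | None = None
    T_half: float | None = None
    converged: bool = False

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.i_values = np.asarray(self.i_values, dtype=float)
        if self.times.shape != self.i_values.shape:
            raise ValueError("times and i_values must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["t", "i"])
            for t, i in zip(self.times, self.i_values):
                w.writerow([f"{t:.10g}", f"{i:.10g}"])

    def summary(self) -> dict:
        return {
            "I": self.I,
            "T_half": self.T_half,
            "converged": bool(self.converged),
            "t_end": float(self.times[-1]),
            "n_samples": int(len(self.times)),
        }


class SteadyDetector:
    """Online steady-state rule: ``|i(t) - i(t - window)| < eps * max(i, floor)``.

    Not armed before ``t_min`` so that the initial dead time (current still
    at zero while the product front crosses the membrane) is not mistaken
    for steady state.
    """

    def __init__(
        self,
        eps_ss: float = 1e-4,
        window: float = 1.0,
        t_min: float = 5.0,
        floor: float = 1e-12,
    ):
        self.eps_ss = eps_ss
        self.window = window
        self.t_min = t_min
        self.floor = floor
        self._t: list[float] = []
        self._i: list[float] = []
        self.converged = False

    def update(self, t: float, i: float) -> bool:
        self._t.append(t)
        self._i.append(i)
        if t < max(self.t_min, self.window):
            return False
        i_back = float(np.interp(t - self.window, self._t, self._i))
        scale = max(abs(i), self.floor)
        if abs(i - i_back) <= self.eps_ss * scale:
            self.converged = True
        return self.converged


def electrode_current(system, state, state_prev=None, dt=None, theta=1.0) -> float:
    """Consistent-flux current at the electrode.

    Sums the interior weak residual of the product equation over the
    electrode nodes; for a steady state pass ``state_prev=None``.
    """
    sys_ = system
    F, _ = sys_.mm_source(state.S, with_jac=False)
    FP = sys_.source_to_P(F)
    R = theta * (sys_.K_P @ state.P - FP)
    if state_prev is not None:
        if dt is None:
            raise ValueError("dt required for a transient current evaluation")
        R = R + sys_.M_P @ ((state.P - state_prev.P) / dt)
        if theta < 1.0:
            F_o, _ = sys_.mm_source(state_prev.S, with_jac=False)
            R = R + (1 - theta) * (sys_.K_P @ state_prev.P - sys_.source_to_P(F_o))
    return float(-np.sum(R[sys_.electrode_nodes]))


# --- direct-gradient boundary flux -----------------------------------------

_EDGE_PARAM = {
    0: lambda t: np.stack([t, np.zeros_like(t)], axis=1),
    1: lambda t: np.stack([1 - t, t], axis=1),
    2: lambda t: np.stack([np.zeros_like(t), 1 - t], axis=1),
}
_GL3_T = 0.5 + 0.5 * np.array([-np.sqrt(3 / 5), 0.0, np.sqrt(3 / 5)])
_GL3_W = 0.5 * np.array([5 / 9, 8 / 9, 5 / 9])


def _facet_parents(mesh, tag):
    """Match each tagged facet to (element, local edge)."""
    tris = mesh.tris
    edge_map = {}
    locals_ = [(0, 1), (1, 2), (2, 0)]
    for m in range(tris.shape[0]):
        for le, (a, b) in enumerate(locals_):
            key = tuple(sorted((int(tris[m, a]), int(tris[m, b]))))
            edge_map.setdefault(key, []).append((m, le))
    out = []
    for f in mesh.facets[tag]:
        key = tuple(sorted((int(f[0]), int(f[1]))))
        m, le = edge_map[key][0]
        out.append((m, le, f))
    return out


def boundary_flux_direct(system, field_name: str, u: np.ndarray, tag: str) -> float:
    """``∫ D ∂u/∂n r ds`` over a tagged boundary by direct gradient
    evaluation (outward normal).  Independent of the consistent estimator.
    """
    from .fem import _shape_p2

    mesh = system.mesh
    problem = system.problem
    diff = problem.diffusivity_P if field_name == "P" else problem.diffusivity_S
    if field_name == "S":
        u_full = np.zeros(system.n_nodes)
        u_full[system.s_nodes] = u
    else:
        u_full = u
    total = 0.0
    for m, le, f in _facet_parents(mesh, tag):
        if int(mesh.region[m]) not in diff:
            continue
        D = diff[int(mesh.region[m])]
        xy = mesh.points[mesh.tris[m]]  # (6, 2)
        ue = u_full[mesh.tris[m]]
        ref = _EDGE_PARAM[le](_GL3_T)  # (3, 2)
        N, dN = _shape_p2(ref)
        A = np.einsum("qni,nj->qij", dN, xy)  # d x_j / d xi_i
        det = A[:, 0, 0] * A[:, 1, 1] - A[:, 0, 1] * A[:, 1, 0]
        invA = np.empty_like(A)
        invA[:, 0, 0] = A[:, 1, 1]
        invA[:, 0, 1] = -A[:, 0, 1]
        invA[:, 1, 0] = -A[:, 1, 0]
        invA[:, 1, 1] = A[:, 0, 0]
        invA /= det[:, None, None]
        grad = np.einsum("qni,qji,n->qj", dN, invA, ue)  # (3, 2) physical
        # edge geometry from its three nodes (quadratic curve)
        ge = mesh.points[f]  # (end, end, mid)
        tq = _GL3_T
        # x(t) = end0*(1-t)(1-2t)... use P2 1-D shape functions
        sh = np.stack([(1 - tq) * (1 - 2 * tq), tq * (2 * tq - 1), 4 * tq * (1 - tq)], axis=1)
        dsh = np.stack([4 * tq - 3, 4 * tq - 1, 4 - 8 * tq], axis=1)
        x = sh @ ge  # (3, 2)
        dx = dsh @ ge  # tangent
        jac = np.linalg.norm(dx, axis=1)
        # outward normal: rotate tangent; orient away from the element interior
        nvec = np.stack([dx[:, 1], -dx[:, 0]], axis=1) / jac[:, None]
        centroid = xy[:3].mean(axis=0)
        if np.dot(nvec[1], x[1] - centroid) < 0:
            nvec = -nvec
        dn = np.einsum("qj,qj->q", grad, nvec)
        total += float(np.sum(_GL3_W * D * dn * x[:, 0] * jac))
    return total


def electrode_current_direct(system, state) -> float:
    """Direct-gradient current (inward product flux at the electrode)."""
    return -boundary_flux_direct(system, "P", state.P, "electrode")


def dimensional_current(i: float, p) -> float:
    """Dimensional current density from the dimensionless current.

    ``i* = 2 ne F D1* Km / a1* · i`` (Faraday/Fick scaling of the electrode
    flux integral, including the factor-2 prefactor of the dimensional
    current-density formula).
    """
    return 2.0 * p.ne * p.F * p.D1_star * p.Km / p.a1_star * i


def dimensionless_current_from_density(i_star: float, p) -> float:
    """Inverse of :func:`dimensional_current`."""
    return i_star * p.a1_star / (2.0 * p.ne * p.F * p.D1_star * p.Km)


def steady_state_current(
    trace: CurrentTrace,
    eps_ss: float = 1e-4,
    window: float = 1.0,
    t_min: float = 5.0,
) -> CurrentTrace:
    """Scan a finished trace with the steady-state rule; fills ``I``,
    ``T_half`` and ``converged`` on (a copy of) the trace."""
    det = SteadyDetector(eps_ss, window, t_min)
    out = CurrentTrace(trace.times.copy(), trace.i_values.copy())
    for k, (t, i) in enumerate(zip(trace.times, trace.i_values)):
        if det.update(float(t), float(i)):
            out.times = trace.times[: k + 1].copy()
            out.i_values = trace.i_values[: k + 1].copy()
            out.converged = True
            out.I = float(i)
            out.T_half = half_time(out)
            return out
    out.converged = False
    return out


def half_time(trace: CurrentTrace) -> float | None:
    """First time the current reaches half its steady value (interpolated)."""
    if not trace.converged or trace.I is None:
        return None
    if trace.I <= 0:
        return None
    target = 0.5 * trace.I
    i, t = trace.i_values, trace.times
    above = np.nonzero(i >= target)[0]
    if above.size == 0:
        return None
    k = int(above[0])
    if k == 0:
        return float(t[0])
    # linear interpolation in the bracketing interval
    f = (target - i[k - 1]) / (i[k] - i[k - 1])
    return float(t[k - 1] + f * (t[k] - t[k - 1]))


def mass_balance_report(system, state, state_prev=None, dt=None) -> dict:
    """Flux/reaction ledger at a (near-)steady state.

    All integrals use the r-weighted measure (no 2π factor, consistent
    with the current normalization).  Fluxes are direct-gradient boundary
    integrals, so the closure errors measure genuine discretization error
    and shrink under mesh refinement.
    """
    sys_ = system
    F, _ = sys_.mm_source(state.S, with_jac=False)
    reaction = float(F.sum())  # ∫ sigma2 S/(1+S) r dΩ over the enzyme region
    # boundary_flux_direct returns the OUTWARD ∫ D ∂u/∂n r ds
    influx_S = boundary_flux_direct(sys_, "S", state.S, "bulk_top")
    efflux_P_elec = -boundary_flux_direct(sys_, "P", state.P, "electrode")
    efflux_P_top = -boundary_flux_direct(sys_, "P", state.P, "bulk_top")
    out = {
        "substrate_influx_top": influx_S,
        "reaction_total": reaction,
        "product_efflux_electrode": efflux_P_elec,
        "product_efflux_top": efflux_P_top,
        "consistent_current": electrode_current(sys_, state, state_prev, dt),
    }
    if reaction > 0:
        out["closure_substrate"] = abs(influx_S - reaction) / reaction
        out["closure_product"] = abs((efflux_P_elec + efflux_P_top) - reaction) / reaction
    else:
        out["closure_substrate"] = abs(influx_S)
        out["closure_product"] = abs(efflux_P_elec + efflux_P_top)
    return out
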