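"""Independent 1-D reference solvers (correctness oracles).

In the fully open limit (hole as wide as the cell) the unit-cell problem
loses its radial dependence and reduces to a three-layer 1-D slab:
selective membrane (product only, diffusivity 1), enzyme layer
(both species, ``D2``, Michaelis–Menten sink/source), and outer diffusion
layer (``D3``).  Two solvers live here:

* :func:`solve_1d_transient` — a finite-volume / central-difference
  discretization on a graded 1-D grid, implicit in time with a Newton
  solve per step.  Completely independent of the 2-D finite-element path
  (different discretization, different code), which is what makes it an
  oracle.
* :func:`analytic_linear_steady` — the closed-form steady current in the
  first-order kinetic regime ``S << 1`` (source -> sigma2 * S): hyperbolic
  profile in the enzyme layer, linear profiles in the passive layers,
  flux-matched at the interfaces.

Current convention: the 2-D current carries the factor ``∫ r dr = 1/2``
over the unit disc, so the 1-D current is reported as
``(1/2) ∂P/∂z|_{z=0}`` for direct comparability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .fem import NonConvergenceError, SolverConfig
from .meshing import graded_segment
from .observables import CurrentTrace, SteadyDetector, half_time

__all__ = ["Slab1DParams", "solve_1d_transient", "analytic_linear_steady"]


@dataclass(frozen=True)
class Slab1DParams:
    """Three-layer slab: thicknesses, diffusivities, kinetics, grid controls."""

    L_sel: float  # selective membrane thickness (product only), D = 1
    L_enz: float  # enzyme layer thickness, D = D2
    L_dif: float  # outer diffusion layer thickness, D = D3
    D2: float
    D3: float
    sigma2: float
    S0: float
    h: float = 0.2  # largest grid interval
    h_min: float | None = None  # smallest (at the enzyme/diffusion interface)
    growth: float = 1.3

    def __post_init__(self) -> None:
        if min(self.L_sel, self.L_enz, self.L_dif) <= 0:
            raise ValueError("layer thicknesses must be positive")
        if min(self.D2, self.D3, self.S0) <= 0 or self.sigma2 < 0:
            raise ValueError("D2, D3, S0 must be positive; sigma2 >= 0")

    def grid(self) -> tuple[np.ndarray, np.ndarray]:
        """Graded node positions and per-interval diffusivities (for S/P)."""
        z1 = self.L_sel
        z2 = z1 + self.L_enz
        z3 = z2 + self.L_dif
        h_min = self.h_min
        if h_min is None:
            if self.sigma2 > 0:
                bl = math.sqrt(self.D2 * (1.0 + self.S0) / self.sigma2)
                h_min = min(self.h, max(bl / 4, 1e-5))
            else:
                h_min = self.h
        z = np.unique(
            np.concatenate(
                [
                    graded_segment(0.0, z1, self.h, self.h / 2, self.h, self.growth),
                    graded_segment(z1, z2, self.h / 2, h_min, self.h, self.growth),
                    graded_segment(z2, z3, h_min, self.h, self.h, self.growth),
                ]
            )
        )
        for plane in (z1, z2, z3):
            z[np.argmin(np.abs(z - plane))] = plane
        z = np.unique(z)
        zm = 0.5 * (z[:-1] + z[1:])
        D = np.where(zm < z1, 1.0, np.where(zm < z2, self.D2, self.D3))
        return z, D


def _stiffness(z: np.ndarray, D: np.ndarray):
    """1-D diffusion stiffness and control volumes on a graded grid."""
    n = len(z)
    h = np.diff(z)
    w = D / h  # interface conductances (D constant per interval)
    main = np.zeros(n)
    main[:-1] += w
    main[1:] += w
    K = sp.diags([main, -w, -w], [0, -1, 1], format="csr")
    vol = np.zeros(n)
    vol[:-1] += h / 2
    vol[1:] += h / 2
    return K, vol


def _operators(p: Slab1DParams):
    """Stiffness/mass/volume data on the graded grid (finite volume)."""
    z, D = p.grid()
    n = len(z)
    K, vol = _stiffness(z, D)
    z1, z2 = p.L_sel, p.L_sel + p.L_enz
    # enzyme fraction of each control volume (reaction weight)
    enz = np.zeros(n)
    for k in range(n - 1):
        lo, hi = z[k], z[k + 1]
        ov = max(0.0, min(hi, z2) - max(lo, z1))
        if ov > 0:
            mid = 0.5 * (lo + hi)
            # split the interval's overlap between its two half-cells
            lo_half = max(0.0, min(mid, z2) - max(lo, z1))
            enz[k] += lo_half
            enz[k + 1] += ov - lo_half
    i_enz_top = int(np.argmin(np.abs(z - z1)))  # selective-membrane top
    return z, K, vol, enz, i_enz_top


def solve_1d_transient(
    p: Slab1DParams, config: SolverConfig | None = None
) -> CurrentTrace:
    """Transient three-layer solve; returns the current trace with
    steady-state current and half-time filled in when detected.

    ``P`` lives on all nodes (Dirichlet 0 at both ends); ``S`` lives on
    nodes above the selective membrane (natural zero flux at its top face,
    Dirichlet ``S0`` at the bulk).  Backward Euler (or θ scheme) with a
    Newton solve per step, mirroring the 2-D driver's step-ramp policy.
    """
    cfg = config or SolverConfig(dt=0.01, dt_max=0.25, dt_growth=1.05)
    z, K, vol, enz, i0 = _operators(p)
    n = len(z)
    s_idx = np.arange(i0, n)  # substrate dofs (nodes in enzyme+diffusion)
    ns = len(s_idx)
    # substrate operator on its own subgrid (zero flux at the closed face)
    zm_s = 0.5 * (z[i0:-1] + z[i0 + 1 :])
    D_s = np.where(zm_s < p.L_sel + p.L_enz, p.D2, p.D3)
    K_S, vol_S = _stiffness(z[i0:], D_s)
    enz_S = enz[s_idx]

    free_P = np.arange(1, n - 1)
    free_S = np.arange(0, ns - 1)  # last node is the bulk Dirichlet
    M_P = sp.diags(vol)
    M_S = sp.diags(vol_S)

    K_P_ff = K[free_P][:, free_P].tocsc()
    M_P_ff = M_P.tocsr()[free_P][:, free_P].tocsc()
    K_S_ff = K_S[free_S][:, free_S].tocsc()
    K_S_fd = K_S[free_S][:, [ns - 1]]
    M_S_ff = M_S.tocsr()[free_S][:, free_S].tocsc()

    S = np.zeros(ns)
    S[-1] = p.S0
    P = np.zeros(n)
    theta = cfg.theta
    if theta != 1.0:
        raise NotImplementedError("1-D oracle implements backward Euler only")

    def source(Svec):
        s = np.maximum(Svec, 0.0)
        g = p.sigma2 * s / (1.0 + s)
        gp = np.where(Svec > 0.0, p.sigma2 / (1.0 + s) ** 2, 0.0)
        return enz_S * g, enz_S * gp

    times = [0.0]
    cur = [0.0]
    det = SteadyDetector(cfg.eps_ss, cfg.ss_window, cfg.t_min_steady)
    t = 0.0
    dt = cfg.dt
    lu_P = None
    lu_P_dt = None
    while t < cfg.t_max - 1e-12:
        dt_eff = min(dt, cfg.t_max - t)
        S_old, P_old = S.copy(), P.copy()
        # Newton on the substrate block
        Sn = S.copy()
        ok = False
        for it in range(cfg.newton_max_iter):
            F, Fp = source(Sn)
            R = (
                vol_S * (Sn - S_old) / dt_eff
                + K_S @ Sn
                + F
            )[free_S]
            rss = float(R @ R)
            if rss <= cfg.newton_tol and it >= 1:
                ok = True
                break
            A = M_S_ff / dt_eff + K_S_ff + sp.diags(Fp[free_S])
            Sn[free_S] += spla.spsolve(A.tocsc(), -R)
        if not ok:
            raise NonConvergenceError("1-D Newton failed; reduce dt", t + dt_eff)
        S = Sn
        # linear product solve
        F, _ = source(S)
        FP = np.zeros(n)
        FP[s_idx] = F
        if lu_P is None or lu_P_dt != dt_eff:
            lu_P = spla.splu((M_P_ff / dt_eff + K_P_ff).tocsc())
            lu_P_dt = dt_eff
        rhs = (vol * P_old / dt_eff + FP)[free_P]
        P = np.zeros(n)
        P[free_P] = lu_P.solve(rhs)
        t += dt_eff
        # consistent flux at the electrode node, with the 1/2 disc factor
        Rel = (vol * (P - P_old) / dt_eff + K @ P - FP)[0]
        i_t = 0.5 * float(-Rel)
        times.append(t)
        cur.append(i_t)
        if det.update(t, i_t):
            break
        dt = min(dt * cfg.dt_growth, cfg.dt_max)

    trace = CurrentTrace(np.array(times), np.array(cur), converged=det.converged)
    if det.converged:
        trace.I = cur[-1]
        trace.T_half = half_time(trace)
    return trace


def _sech(x: float) -> float:
    return 0.0 if x > 700 else 1.0 / math.cosh(x)


def analytic_linear_steady(p: Slab1DParams) -> float:
    """Closed-form steady current for first-order kinetics (``S << 1``).

    Solves ``D2 S'' = sigma2 S`` in the enzyme layer (zero flux at its
    bottom face, the selective membrane passes no substrate) matched to a
    linear profile in the diffusion layer with ``S = S0`` at the bulk;
    then integrates the product problem with the resulting source.
    Evaluated in overflow-safe tanh/sech form.  Returns the current with
    the ``1/2`` disc factor, comparable to :func:`solve_1d_transient`.
    """
    if p.sigma2 == 0:
        return 0.0
    b1, he, hd = p.L_sel, p.L_enz, p.L_dif
    kappa = math.sqrt(p.sigma2 / p.D2)
    x = kappa * he
    th = math.tanh(x)
    # substrate at the enzyme/diffusion interface
    S_be = p.S0 / (1.0 + (p.D2 / p.D3) * kappa * hd * th)
    Q = p.D2 * kappa * S_be * th  # total reaction per unit area
    A = S_be * (1.0 - _sech(x))  # sigma2 C (cosh-1)/(kappa^2 D2)
    F0 = (A + Q * hd / p.D3) / (b1 + he / p.D2 + hd / p.D3)
    return 0.5 * F0
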