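"""Axisymmetric Galerkin finite-element solver for the coupled system.

Discretization notes
--------------------
* Quadratic (6-node) triangles; isoparametric on curved hole-wall elements.
* The axisymmetric weak form carries the cylindrical measure ``r dr dz``
  (volume-weighted, self-adjoint form of the axisymmetric Laplacian); the
  symmetry axis then needs no special treatment.
* 7-point (degree-5) Gauss rule: exact for the r-weighted quadratic mass
  and stiffness integrands on straight elements.
* Implicit θ time stepping (backward Euler default, Crank–Nicolson at
  θ=0.5) with a Newton–Raphson solve per step; convergence criterion is
  the residual sum of squares over free dofs, default ``1e-7``.
* The substrate equation is independent of the product, so the Newton
  update solves the substrate block first and then the (linear) product
  block exactly — this is Newton on the block-triangular full system.
* The Michaelis–Menten source clamps its argument at zero (tolerating
  infinitesimal undershoot); overshoot beyond ``eps_over`` raises.
* Assembly order is deterministic: runs are bit-reproducible.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .meshing import Mesh
from .model import ProblemSpec

__all__ = [
    "FieldState",
    "SolverConfig",
    "DiscreteSystem",
    "NonConvergenceError",
    "OvershootError",
    "build_system",
    "assemble",
    "newton_solve",
    "run_transient",
    "solve_steady",
    "reference_p2",
]


class NonConvergenceError(RuntimeError):
    def __init__(self, msg: str, t: float | None = None):
        super().__init__(msg + (f" (at t={t:g})" if t is not None else ""))
        self.t = t


class OvershootError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# reference element
# ---------------------------------------------------------------------------

_QUADS = {
    2: (  # 3-point, degree 2 (the minimal rule)
        np.array([[1 / 6, 1 / 6], [2 / 3, 1 / 6], [1 / 6, 2 / 3]]),
        np.full(3, 1 / 6),
    ),
    4: (  # 6-point, degree 4
        np.array(
            [
                [0.44594849091597, 0.44594849091597],
                [0.44594849091597, 0.10810301816807],
                [0.10810301816807, 0.44594849091597],
                [0.09157621350977, 0.09157621350977],
                [0.09157621350977, 0.81684757298046],
                [0.81684757298046, 0.09157621350977],
            ]
        ),
        np.array([0.111690794839, 0.111690794839, 0.111690794839,
                  0.054975871827, 0.054975871827, 0.054975871827]) / 1.0,
    ),
    5: (  # 7-point, degree 5
        np.array(
            [
                [1 / 3, 1 / 3],
                [0.05971587178977, 0.47014206410511],
                [0.47014206410511, 0.05971587178977],
                [0.47014206410511, 0.47014206410511],
                [0.79742698535309, 0.10128650732346],
                [0.10128650732346, 0.79742698535309],
                [0.10128650732346, 0.10128650732346],
            ]
        ),
        np.array([0.1125, 0.06619707639425, 0.06619707639425, 0.06619707639425,
                  0.06296959027241, 0.06296959027241, 0.06296959027241]),
    ),
}


def _shape_p2(xi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """P2 shape functions and reference gradients at points (Q, 2)."""
    x, y = xi[:, 0], xi[:, 1]
    l1 = 1.0 - x - y
    N = np.stack(
        [
            l1 * (2 * l1 - 1),
            x * (2 * x - 1),
            y * (2 * y - 1),
            4 * l1 * x,
            4 * x * y,
            4 * y * l1,
        ],
        axis=1,
    )
    dN = np.empty((xi.shape[0], 6, 2))
    dN[:, 0, 0] = 1 - 4 * l1
    dN[:, 0, 1] = 1 - 4 * l1
    dN[:, 1, 0] = 4 * x - 1
    dN[:, 1, 1] = 0.0
    dN[:, 2, 0] = 0.0
    dN[:, 2, 1] = 4 * y - 1
    dN[:, 3, 0] = 4 * (l1 - x)
    dN[:, 3, 1] = -4 * x
    dN[:, 4, 0] = 4 * y
    dN[:, 4, 1] = 4 * x
    dN[:, 5, 0] = -4 * y
    dN[:, 5, 1] = 4 * (l1 - y)
    return N, dN


@functools.lru_cache(maxsize=8)
def reference_p2(order: int = 5):
    """Quadrature points/weights and P2 shape data: (qp, qw, N, dN)."""
    qp, qw = _QUADS[order]
    N, dN = _shape_p2(qp)
    return qp, qw.copy(), N, dN


# ---------------------------------------------------------------------------
# state and configuration
# ---------------------------------------------------------------------------


@dataclass
class FieldState:
    """Nodal fields at one time: P over all nodes, S over substrate nodes."""

    t: float
    P: np.ndarray
    S: np.ndarray

    def copy(self) -> "FieldState":
        return FieldState(self.t, self.P.copy(), self.S.copy())


@dataclass
class SolverConfig:
    """Transient solver controls (all times dimensionless).

    ``dt`` is the initial step (0.01, the classical choice for half-time
    evaluation); it may grow geometrically by ``dt_growth`` per step up to
    ``dt_max`` once the start-up transient is past.  Steady state is
    declared when the current changes by less than ``eps_ss`` (relative)
    over a trailing ``ss_window``, not before ``t_min_steady``.
    """

    dt: float = 0.01
    dt_max: float | None = None
    dt_growth: float = 1.0
    t_max: float = 400.0
    newton_tol: float = 1e-7
    newton_max_iter: int = 25
    theta: float = 1.0  # 1 = backward Euler, 0.5 = Crank-Nicolson
    quad_order: int = 5
    eps_ss: float = 1e-4
    ss_window: float = 1.0
    t_min_steady: float = 5.0
    eps_over: float = 2e-2

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.newton_tol <= 0:
            raise ValueError("dt and newton_tol must be positive")
        if self.dt_max is None:
            self.dt_max = self.dt


# ---------------------------------------------------------------------------
# discrete system
# ---------------------------------------------------------------------------


class DiscreteSystem:
    """Precomputed matrices and dof maps for one (problem, mesh) pair."""

    def __init__(self, problem: ProblemSpec, mesh: Mesh, quad_order: int = 5):
        self.problem = problem
        self.mesh = mesh
        self.quad_order = quad_order
        qp, qw, N, dN = reference_p2(quad_order)
        self._N = N
        pts, tris, region = mesh.points, mesh.tris, mesh.region
        n_nodes = pts.shape[0]

        coords = pts[tris]  # (M, 6, 2)
        A = np.einsum("qni,mnj->mqij", dN, coords)  # A[i,j] = d x_j / d xi_i
        detJ = A[..., 0, 0] * A[..., 1, 1] - A[..., 0, 1] * A[..., 1, 0]
        if np.any(detJ <= 0):
            bad = int(np.argwhere(np.any(detJ <= 0, axis=1))[0, 0])
            raise ValueError(f"non-positive Jacobian in element {bad}")
        invA = np.empty_like(A)
        invA[..., 0, 0] = A[..., 1, 1]
        invA[..., 0, 1] = -A[..., 0, 1]
        invA[..., 1, 0] = -A[..., 1, 0]
        invA[..., 1, 1] = A[..., 0, 0]
        invA /= detJ[..., None, None]
        # physical gradients: dN/dx_j = sum_i dN/dxi_i * invA[j, i]
        dNdx = np.einsum("qni,mqji->mqnj", dN, invA)
        r_q = np.einsum("qn,mn->mq", N, coords[..., 0])
        wdet = qw[None, :] * detJ * r_q  # r-weighted measure

        D_P = np.array([problem.diffusivity_P[int(t)] for t in region])
        K_P_e = np.einsum("mq,mqid,mqjd->mij", wdet * D_P[:, None], dNdx, dNdx)
        M_e = np.einsum("mq,qi,qj->mij", wdet, N, N)

        rows = np.repeat(tris, 6, axis=1).ravel()
        cols = np.tile(tris, (1, 6)).ravel()
        self.K_P = sp.coo_matrix(
            (K_P_e.ravel(), (rows, cols)), shape=(n_nodes, n_nodes)
        ).tocsr()
        self.M_P = sp.coo_matrix(
            (M_e.ravel(), (rows, cols)), shape=(n_nodes, n_nodes)
        ).tocsr()

        # --- substrate dofs -------------------------------------------------
        s_mask_el = np.isin(region, list(problem.diffusivity_S.keys()))
        s_nodes = np.unique(tris[s_mask_el])
        s_of_node = -np.ones(n_nodes, dtype=np.int64)
        s_of_node[s_nodes] = np.arange(len(s_nodes))
        self.s_nodes = s_nodes
        self.s_of_node = s_of_node
        ns = len(s_nodes)
        self.n_nodes, self.n_s = n_nodes, ns

        tris_s = s_of_node[tris[s_mask_el]]
        D_S = np.array(
            [problem.diffusivity_S[int(t)] for t in region[s_mask_el]]
        )
        K_S_e = np.einsum(
            "mq,mqid,mqjd->mij",
            wdet[s_mask_el] * D_S[:, None],
            dNdx[s_mask_el],
            dNdx[s_mask_el],
        )
        M_S_e = M_e[s_mask_el]
        rows_s = np.repeat(tris_s, 6, axis=1).ravel()
        cols_s = np.tile(tris_s, (1, 6)).ravel()
        self.K_S = sp.coo_matrix((K_S_e.ravel(), (rows_s, cols_s)), shape=(ns, ns)).tocsr()
        self.M_S = sp.coo_matrix((M_S_e.ravel(), (rows_s, cols_s)), shape=(ns, ns)).tocsr()

        # --- Michaelis-Menten source data (enzyme region) -------------------
        src_mask = region == problem.source_region
        self.src_tris = tris[src_mask]
        self.src_s = s_of_node[self.src_tris]
        self.src_w = wdet[src_mask]  # (Me, Q)
        if np.any(self.src_s < 0):
            raise ValueError("source region contains nodes without substrate dof")

        # --- Dirichlet sets -------------------------------------------------
        dir_p_nodes, dir_p_vals = [], []
        for tag, val in problem.dirichlet_P.items():
            nn = mesh.nodes_of(tag)
            if nn.size == 0 and tag in ("electrode", "bulk_top"):
                raise ValueError(f"mesh lacks required facet tag {tag!r}")
            dir_p_nodes.append(nn)
            dir_p_vals.append(np.full(nn.size, val))
        self.dir_P = np.concatenate(dir_p_nodes)
        self.dir_P_vals = np.concatenate(dir_p_vals)
        dir_s_nodes, dir_s_vals = [], []
        for tag, val in problem.dirichlet_S.items():
            nn = s_of_node[mesh.nodes_of(tag)]
            if np.any(nn < 0):
                raise ValueError(f"S Dirichlet tag {tag!r} touches non-S nodes")
            dir_s_nodes.append(nn)
            dir_s_vals.append(np.full(nn.size, val))
        self.dir_S = np.concatenate(dir_s_nodes)
        self.dir_S_vals = np.concatenate(dir_s_vals)

        self.free_P = np.setdiff1d(np.arange(n_nodes), self.dir_P)
        self.free_S = np.setdiff1d(np.arange(ns), self.dir_S)

        self.electrode_nodes = mesh.nodes_of("electrode")
        self.bulk_top_nodes = mesh.nodes_of("bulk_top")

        # reduced constant blocks
        self.K_P_ff = self.K_P[self.free_P][:, self.free_P].tocsc()
        self.M_P_ff = self.M_P[self.free_P][:, self.free_P].tocsc()
        self.K_S_ff = self.K_S[self.free_S][:, self.free_S].tocsc()
        self.M_S_ff = self.M_S[self.free_S][:, self.free_S].tocsc()
        # columns hitting Dirichlet dofs (for rhs lifting)
        self.K_S_fd = self.K_S[self.free_S][:, self.dir_S]
        self.M_S_fd = self.M_S[self.free_S][:, self.dir_S]
        self.K_P_fd = self.K_P[self.free_P][:, self.dir_P]
        self.M_P_fd = self.M_P[self.free_P][:, self.dir_P]

        # precomputed reduction map for the source Jacobian scatter
        pos_of_free = -np.ones(ns, dtype=np.int64)
        pos_of_free[self.free_S] = np.arange(len(self.free_S))
        rr = pos_of_free[np.repeat(self.src_s, 6, axis=1).ravel()]
        cc = pos_of_free[np.tile(self.src_s, (1, 6)).ravel()]
        keep = (rr >= 0) & (cc >= 0)
        self._src_keep = keep
        self._src_rr = rr[keep]
        self._src_cc = cc[keep]
        self._pos_of_free = pos_of_free

        self._lu_cache: dict[tuple[str, float, float], spla.SuperLU] = {}

    # -- source terms --------------------------------------------------------
    def mm_source(self, S: np.ndarray, with_jac: bool = True):
        """Nodal Michaelis–Menten load vector (on S dofs) and its Jacobian.

        The concentration is clamped at zero inside the source only.
        Returns ``(F, J)`` with ``F`` a length-``n_s`` vector (positive for
        consumption) and ``J`` its derivative as a CSR on free S dofs.
        """
        sigma2 = self.problem.sigma2
        N = self._N
        s_el = S[self.src_s]  # (Me, 6)
        s_raw = np.einsum("qn,mn->mq", N, s_el)
        s_q = np.maximum(s_raw, 0.0)
        g = sigma2 * s_q / (1.0 + s_q)
        F_el = np.einsum("mq,qn->mn", self.src_w * g, N)
        F = np.zeros(self.n_s)
        np.add.at(F, self.src_s.ravel(), F_el.ravel())
        if not with_jac:
            return F, None
        # exact (semismooth) derivative of the clamped source
        gp = np.where(s_raw > 0.0, sigma2 / (1.0 + s_q) ** 2, 0.0)
        E = np.einsum("mq,qi,qj->mij", self.src_w * gp, N, N)
        nf = len(self.free_S)
        J = sp.coo_matrix(
            (E.ravel()[self._src_keep], (self._src_rr, self._src_cc)),
            shape=(nf, nf),
        ).tocsr()
        return F, J

    def source_to_P(self, F_s: np.ndarray) -> np.ndarray:
        """Map the S-indexed source vector onto P dofs (all nodes)."""
        out = np.zeros(self.n_nodes)
        out[self.s_nodes] = F_s
        return out

    def lu(self, which: str, dt: float, theta: float) -> spla.SuperLU:
        key = (which, dt, theta)
        lu = self._lu_cache.get(key)
        if lu is None:
            if which == "P":
                A = self.M_P_ff / dt + theta * self.K_P_ff
            else:
                A = self.M_S_ff / dt + theta * self.K_S_ff
            lu = spla.splu(A.tocsc())
            if len(self._lu_cache) > 6:
                self._lu_cache.clear()
            self._lu_cache[key] = lu
        return lu

    # -- initial condition ---------------------------------------------------
    def initial_state(self) -> FieldState:
        """Zero fields; bulk-top substrate Dirichlet applied from t=0."""
        P = np.zeros(self.n_nodes)
        S = np.zeros(self.n_s)
        S[self.dir_S] = self.dir_S_vals
        P[self.dir_P] = self.dir_P_vals
        return FieldState(0.0, P, S)

    # -- residuals -----------------------------------------------------------
    def residual_S(self, S, S_old, dt, theta, F=None, F_old=None):
        """Free-dof residual of the substrate step (theta scheme)."""
        if F is None:
            F, _ = self.mm_source(S, with_jac=False)
        if theta < 1.0 and F_old is None:
            F_old, _ = self.mm_source(S_old, with_jac=False)
        R = self.M_S @ ((S - S_old) / dt) + theta * (self.K_S @ S + F)
        if theta < 1.0:
            R += (1 - theta) * (self.K_S @ S_old + F_old)
        return R[self.free_S]

    def residual_P(self, P, P_old, S, S_old, dt, theta):
        F, _ = self.mm_source(S, with_jac=False)
        FP = self.source_to_P(F)
        R = self.M_P @ ((P - P_old) / dt) + theta * (self.K_P @ P - FP)
        if theta < 1.0:
            F_o, _ = self.mm_source(S_old, with_jac=False)
            R += (1 - theta) * (self.K_P @ P_old - self.source_to_P(F_o))
        return R[self.free_P]

    def check_bounds(self, state: FieldState, eps_over: float) -> None:
        S0 = self.problem.S0
        if not (np.all(np.isfinite(state.S)) and np.all(np.isfinite(state.P))):
            raise NonConvergenceError("non-finite field values", state.t)
        if state.S.min() < -eps_over * S0 or state.S.max() > S0 * (1 + eps_over):
            raise OvershootError(
                f"substrate out of [0, S0] beyond eps_over at t={state.t:g}: "
                f"min={state.S.min():.3e}, max={state.S.max():.3e}"
            )
        pmax = max(state.P.max(), S0)
        if state.P.min() < -eps_over * pmax:
            raise OvershootError(
                f"product undershoot beyond eps_over at t={state.t:g}: "
                f"min={state.P.min():.3e}"
            )


def build_system(problem: ProblemSpec, mesh: Mesh, quad_order: int = 5) -> DiscreteSystem:
    return DiscreteSystem(problem, mesh, quad_order)


# ---------------------------------------------------------------------------
# assembly of the monolithic residual/Jacobian (used by verification tests)
# ---------------------------------------------------------------------------


def assemble(
    system: DiscreteSystem,
    state: FieldState,
    state_old: FieldState,
    dt: float,
    theta: float = 1.0,
):
    """Full residual vector and consistent Jacobian of one implicit step.

    Dof ordering: free substrate dofs then free product dofs.  The Jacobian
    is block lower-triangular: the substrate equation does not involve the
    product.
    """
    sys_ = system
    F, J_mm = sys_.mm_source(state.S)
    R_S = sys_.residual_S(state.S, state_old.S, dt, theta, F=F)
    R_P = sys_.residual_P(state.P, state_old.P, state.S, state_old.S, dt, theta)
    A_SS = sys_.M_S_ff / dt + theta * sys_.K_S_ff + theta * J_mm
    A_PP = sys_.M_P_ff / dt + theta * sys_.K_P_ff
    # dR_P/dS = -theta * dF/dS mapped into P rows; build via dense-free scatter
    nfs, nfp = len(sys_.free_S), len(sys_.free_P)
    # P-row indices of source entries: P dof = global node of S dof
    pos_free_P = -np.ones(sys_.n_nodes, dtype=np.int64)
    pos_free_P[sys_.free_P] = np.arange(nfp)
    rows_nodes = sys_.s_nodes[sys_.free_S[sys_._src_rr]]
    rp = pos_free_P[rows_nodes]
    keep = rp >= 0
    sigma2 = sys_.problem.sigma2
    N = sys_._N
    s_raw = np.einsum("qn,mn->mq", N, state.S[sys_.src_s])
    s_q = np.maximum(s_raw, 0.0)
    gp = np.where(s_raw > 0.0, sigma2 / (1.0 + s_q) ** 2, 0.0)
    E = np.einsum("mq,qi,qj->mij", sys_.src_w * gp, N, N).ravel()[sys_._src_keep]
    A_PS = sp.coo_matrix(
        (-theta * E[keep], (rp[keep], sys_._src_cc[keep])), shape=(nfp, nfs)
    ).tocsr()
    J = sp.bmat([[A_SS, None], [A_PS, A_PP]], format="csr")
    return np.concatenate([R_S, R_P]), J


# ---------------------------------------------------------------------------
# Newton step
# ---------------------------------------------------------------------------


def newton_solve(
    system: DiscreteSystem,
    state: FieldState,
    dt: float,
    config: SolverConfig | None = None,
):
    """Advance one implicit step; returns (new_state, info).

    ``info`` holds the Newton iteration count and the residual-sum-of-
    squares history (substrate block; the product block is linear and its
    residual after the direct solve is at round-off).
    """
    cfg = config or SolverConfig(dt=dt)
    theta = cfg.theta
    sys_ = system
    S_old, P_old = state.S, state.P
    S = state.S.copy()
    S[sys_.dir_S] = sys_.dir_S_vals

    # rhs pieces independent of the iterate
    b_S = sys_.M_S @ (S_old / dt)
    if theta < 1.0:
        F_old, _ = sys_.mm_source(S_old, with_jac=False)
        b_S = b_S - (1 - theta) * (sys_.K_S @ S_old + F_old)

    hist = []
    it = 0
    converged = False
    while it < cfg.newton_max_iter:
        F, J_mm = sys_.mm_source(S)
        R_full = sys_.M_S @ (S / dt) + theta * (sys_.K_S @ S + F) - b_S
        R = R_full[sys_.free_S]
        rss = float(R @ R)
        hist.append(rss)
        # always take at least one update so the criterion is checked on a
        # solved iterate (the absolute tolerance is met trivially at small S0)
        if rss <= cfg.newton_tol and it >= 1:
            converged = True
            break
        A = sys_.M_S_ff / dt + theta * sys_.K_S_ff + theta * J_mm
        delta = spla.spsolve(A.tocsc(), -R)
        S[sys_.free_S] += delta
        it += 1
    if not converged:
        raise NonConvergenceError(
            f"Newton stalled after {it} iterations (rss={hist[-1]:.2e}); "
            "reduce dt",
            state.t + dt,
        )

    # linear product solve (exact Newton step for the triangular block)
    F, _ = sys_.mm_source(S, with_jac=False)
    FP = sys_.source_to_P(F)
    rhs = (sys_.M_P @ (P_old / dt) + theta * FP)[sys_.free_P]
    if theta < 1.0:
        F_o, _ = sys_.mm_source(S_old, with_jac=False)
        rhs += (
            -(1 - theta) * (sys_.K_P @ P_old - sys_.source_to_P(F_o))
        )[sys_.free_P]
    P = np.zeros_like(P_old)
    P[sys_.dir_P] = sys_.dir_P_vals
    lu = sys_.lu("P", dt, theta)
    P[sys_.free_P] = lu.solve(rhs)

    new = FieldState(state.t + dt, P, S)
    info = {"iterations": it, "residual_history": hist, "final_rss": hist[-1]}
    return new, info


# ---------------------------------------------------------------------------
# transient driver
# ---------------------------------------------------------------------------


def run_transient(
    problem: ProblemSpec,
    mesh: Mesh,
    config: SolverConfig | None = None,
    snapshot_times: list[float] | None = None,
    system: DiscreteSystem | None = None,
):
    """Integrate from the rest initial condition until steady state.

    Returns ``(trace, snapshots, diagnostics)`` where ``trace`` is a
    :class:`~ampersim.observables.CurrentTrace` with the steady current and
    half-time filled in when detected, ``snapshots`` maps requested times
    to :class:`FieldState`, and ``diagnostics`` reports Newton statistics
    and the final state.
    """
    from .observables import CurrentTrace, SteadyDetector, electrode_current, half_time

    cfg = config or SolverConfig()
    sys_ = system or build_system(problem, mesh, cfg.quad_order)
    state = sys_.initial_state()
    detector = SteadyDetector(cfg.eps_ss, cfg.ss_window, cfg.t_min_steady)

    times = [0.0]
    currents = [0.0]
    snapshots: dict[float, FieldState] = {}
    wanted = sorted(snapshot_times or [])
    max_rss = 0.0
    newton_iters: list[int] = []
    dt = cfg.dt
    retries = 0
    while state.t < cfg.t_max - 1e-12:
        dt_eff = min(dt, cfg.t_max - state.t)
        try:
            new, info = newton_solve(sys_, state, dt_eff, cfg)
        except NonConvergenceError:
            if retries >= 4:
                raise
            retries += 1
            dt = max(dt / 4, cfg.dt / 100)
            continue
        retries = 0
        sys_.check_bounds(new, cfg.eps_over)
        max_rss = max(max_rss, info["final_rss"])
        newton_iters.append(info["iterations"])
        i_t = electrode_current(sys_, new, state_prev=state, dt=dt_eff, theta=cfg.theta)
        state = new
        times.append(state.t)
        currents.append(i_t)
        while wanted and state.t >= wanted[0] - 1e-12:
            snapshots[wanted.pop(0)] = state.copy()
        if detector.update(state.t, i_t):
            break
        dt = min(dt * cfg.dt_growth, cfg.dt_max)

    trace = CurrentTrace(
        times=np.array(times),
        i_values=np.array(currents),
        converged=detector.converged,
    )
    if detector.converged:
        trace.I = currents[-1]
        trace.T_half = half_time(trace)
    diagnostics = {
        "max_newton_rss": max_rss,
        "newton_iterations": newton_iters,
        "n_steps": len(times) - 1,
        "final_state": state,
        "system": sys_,
    }
    return trace, snapshots, diagnostics


# ---------------------------------------------------------------------------
# direct steady solve (used for spatial-convergence studies)
# ---------------------------------------------------------------------------


def solve_steady(
    problem: ProblemSpec,
    mesh: Mesh,
    *,
    tol: float = 1e-10,
    max_iter: int = 60,
    system: DiscreteSystem | None = None,
) -> tuple[FieldState, DiscreteSystem]:
    """Damped Newton on the steady equations (no time derivative).

    Starts from a uniform substrate profile at ``S0``; suitable for
    moderate Damköhler numbers where the steady problem is mildly
    nonlinear.  For strongly stiff cases use :func:`run_transient`.
    """
    sys_ = system or build_system(problem, mesh)
    # initial guess: the linear-kinetics steady state (source linearized at
    # S=0), which already carries the reaction boundary layer
    S = np.zeros(sys_.n_s)
    S[sys_.dir_S] = sys_.dir_S_vals
    _, J0 = sys_.mm_source(np.zeros(sys_.n_s))
    rhs0 = -(sys_.K_S_fd @ sys_.dir_S_vals)
    S[sys_.free_S] = spla.spsolve((sys_.K_S_ff + J0).tocsc(), rhs0)
    S = np.clip(S, 0.0, problem.S0)
    S[sys_.dir_S] = sys_.dir_S_vals

    def rss_of(Svec):
        F, _ = sys_.mm_source(Svec, with_jac=False)
        R = (sys_.K_S @ Svec + F)[sys_.free_S]
        return float(R @ R), R

    rss, R = rss_of(S)
    for _ in range(max_iter):
        if rss <= tol:
            break
        _, J_mm = sys_.mm_source(S)
        A = sys_.K_S_ff + J_mm
        delta = spla.spsolve(A.tocsc(), -R)
        lam = 1.0
        for _ls in range(12):
            trial = S.copy()
            trial[sys_.free_S] += lam * delta
            trial[sys_.dir_S] = sys_.dir_S_vals
            rss_t, R_t = rss_of(trial)
            if rss_t < rss or rss_t <= tol:
                S, rss, R = trial, rss_t, R_t
                break
            lam /= 2
        else:
            raise NonConvergenceError("steady Newton line search failed")
    else:
        raise NonConvergenceError(f"steady Newton did not reach tol (rss={rss:.2e})")

    F, _ = sys_.mm_source(S, with_jac=False)
    rhs = sys_.source_to_P(F)[sys_.free_P]
    P = np.zeros(sys_.n_nodes)
    P[sys_.dir_P] = sys_.dir_P_vals
    P[sys_.free_P] = spla.spsolve(sys_.K_P_ff.tocsc(), rhs)
    return FieldState(np.inf, P, S), sys_
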