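"""Boundary-fitted quadratic-triangle meshes of the unit cell.

The mesher builds a block-structured grid in mapped coordinates and emits
6-node (quadratic) triangles:

* an *inner* block covering ``0 <= r <= A(z)`` for all ``0 <= z <= b5``,
  where ``A(z)`` is the hole radius inside the membrane and its continuation
  (constant) into the full-width slabs above and below,
* *outer* blocks covering ``A(z) <= r <= 1`` for ``z <= b2`` and
  ``z >= b4`` (inside the membrane that annulus is the impermeable carrier
  and is not meshed).

Wall nodes — including edge midnodes — are placed exactly on ``r = a(z)``;
because every wall profile is at most quadratic in ``z``, the isoparametric
quadratic edges reproduce the curved wall exactly (up to round-off).

Axial grid lines always contain ``b1, b2, b3, b4`` so no element crosses a
region interface, and are geometrically graded toward the enzyme interface
``z = b3`` (where the reaction boundary layer sits at large Damköhler
number) and toward the carrier corner planes ``b2``/``b4``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import (
    GeometrySpec,
    Shape,
    build_unit_cell,
    hole_radius_profile,
)

__all__ = ["Mesh", "MeshingError", "generate_mesh", "graded_segment"]

_TOL = 1e-10

#: boundary / interface facet tags
BOUNDARY_TAGS = (
    "electrode",
    "axis",
    "outer",
    "bulk_top",
    "hole_wall",
    "carrier_bottom",
    "carrier_top",
    "gamma1",
    "gamma3",
)


class MeshingError(RuntimeError):
    pass


@dataclass
class Mesh:
    """Axisymmetric (r, z) mesh of quadratic triangles.

    ``tris`` follows the Gmsh/VTK quadratic-triangle ordering: corners
    ``(0, 1, 2)`` then edge midnodes ``(01, 12, 20)``.  ``facets`` maps a
    tag to an ``(k, 3)`` array of quadratic edges ``(end, end, mid)``;
    ``gamma1`` and ``gamma3`` are interior interfaces, the rest are domain
    boundary.
    """

    points: np.ndarray  # (N, 2)
    tris: np.ndarray  # (M, 6)
    region: np.ndarray  # (M,) in {1, 2, 3}
    facets: dict[str, np.ndarray]
    spec: GeometrySpec | None = None
    h: float | None = None
    meta: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return self.points.shape[0]

    @property
    def n_elements(self) -> int:
        return self.tris.shape[0]

    def nodes_of(self, tag: str) -> np.ndarray:
        """Sorted unique node ids of a facet group."""
        f = self.facets.get(tag)
        if f is None or f.size == 0:
            return np.empty(0, dtype=np.int64)
        return np.unique(f)

    def element_areas(self) -> np.ndarray:
        """Plane areas by quadrature of the isoparametric map (degree 4)."""
        from .fem import reference_p2  # local import to avoid cycle

        qp, qw, N, dN = reference_p2(order=4)
        coords = self.points[self.tris]  # (M, 6, 2)
        J = np.einsum("qni,mnj->mqij", dN, coords)
        detJ = J[..., 0, 0] * J[..., 1, 1] - J[..., 0, 1] * J[..., 1, 0]
        return detJ @ qw

    def validate(self, check_area: bool = True) -> None:
        """Check the mesh invariants; raise MeshingError on violation."""
        pts, tris = self.points, self.tris
        s = self.spec
        if s is not None:
            lo = np.array([0.0, 0.0])
            hi = np.array([1.0, s.b5])
            if np.any(pts < lo - 1e-9) or np.any(pts > hi + 1e-9):
                raise MeshingError("nodes outside the unit cell box")
        from .fem import reference_p2

        qp, qw, N, dN = reference_p2(order=4)
        coords = pts[tris]
        J = np.einsum("qni,mnj->mqij", dN, coords)
        detJ = J[..., 0, 0] * J[..., 1, 1] - J[..., 0, 1] * J[..., 1, 0]
        if np.any(detJ <= 0):
            bad = int(np.argwhere(np.any(detJ <= 0, axis=1))[0, 0])
            raise MeshingError(f"non-positive Jacobian in element {bad}")
        if s is not None:
            # no element may cross a region interface plane
            zc = pts[tris[:, :3], 1]
            for plane in (s.b1, s.b3):
                lo_side = np.all(zc <= plane + 1e-9, axis=1)
                hi_side = np.all(zc >= plane - 1e-9, axis=1)
                if not np.all(lo_side | hi_side):
                    raise MeshingError(f"element crosses interface z={plane}")
        # conforming edges: interior edges shared by exactly 2 elements,
        # boundary edges by exactly 1
        edges = np.concatenate(
            [tris[:, [0, 1]], tris[:, [1, 2]], tris[:, [2, 0]]], axis=0
        )
        edges = np.sort(edges, axis=1)
        _, counts = np.unique(edges, axis=0, return_counts=True)
        if np.any(counts > 2):
            raise MeshingError("non-conforming edge shared by >2 elements")
        # each boundary facet carries exactly one tag
        seen: dict[tuple, str] = {}
        for tag, f in self.facets.items():
            for e in np.sort(f[:, :2], axis=1) if f.size else []:
                key = (int(e[0]), int(e[1]))
                if key in seen and seen[key] != tag:
                    raise MeshingError(
                        f"facet {key} tagged both {seen[key]} and {tag}"
                    )
                seen[key] = tag
        if check_area and s is not None:
            cell = build_unit_cell(s)
            rel = abs(self.element_areas().sum() - cell.total_area()) / cell.total_area()
            if rel > 1e-3:
                raise MeshingError(f"mesh area off by {rel:.2e} relative")


def graded_segment(
    z0: float,
    z1: float,
    h0: float,
    h1: float,
    hmax: float,
    growth: float = 1.4,
) -> np.ndarray:
    """Node positions on [z0, z1], sizes growing geometrically from ``h0``
    at the start and ``h1`` at the end up to ``hmax``, then rescaled so the
    endpoints are hit exactly."""
    L = z1 - z0
    if L <= _TOL:
        return np.array([z0, z1]) if L > 0 else np.array([z0])
    h0 = min(h0, L)
    h1 = min(h1, L)
    sizes_l, sizes_r = [h0], [h1]
    while sum(sizes_l) + sum(sizes_r) < L:
        if sizes_l[-1] <= sizes_r[-1]:
            sizes_l.append(min(sizes_l[-1] * growth, hmax))
        else:
            sizes_r.append(min(sizes_r[-1] * growth, hmax))
    sizes = np.array(sizes_l + sizes_r[::-1])
    sizes *= L / sizes.sum()  # rescale to fit exactly; ratios preserved
    xs = np.concatenate([[0.0], np.cumsum(sizes)])
    xs[-1] = L
    return z0 + xs


def _z_lines(spec: GeometrySpec, h: float, h_min: float, growth: float) -> np.ndarray:
    """Axial grid lines including b1..b5, graded toward b2, b3, b4."""
    s = spec
    hc = min(h, 0.5 * (s.b2 - s.b1))  # moderate size near interfaces
    parts = [
        graded_segment(0.0, s.b1, h, min(h, hc), h, growth),
        graded_segment(s.b1, s.b2, hc, max(h_min, hc / 4) if s.b3 <= s.b2 + _TOL else hc / 2, h, growth),
    ]
    if s.b3 > s.b2 + _TOL:
        parts.append(graded_segment(s.b2, s.b3, min(hc / 2, h), h_min, h, growth))
    if s.b4 > s.b3 + _TOL:
        parts.append(graded_segment(s.b3, s.b4, h_min, min(hc / 2, h), h, growth))
    parts.append(graded_segment(s.b4, s.b5, hc / 2, h, h, growth))
    z = np.unique(np.concatenate(parts))
    # snap interface planes exactly
    for plane in (s.b1, s.b2, s.b3, s.b4, s.b5):
        z[np.argmin(np.abs(z - plane))] = plane
    return np.unique(z)


def generate_mesh(
    spec: GeometrySpec,
    h: float = 0.5,
    *,
    h_min: float | None = None,
    growth: float = 1.4,
    n_r_inner: int = 5,
    n_r_outer: int = 6,
    z_lines: np.ndarray | None = None,
) -> Mesh:
    """Generate a tagged quadratic-triangle mesh of the unit cell.

    Parameters
    ----------
    h:
        Target axial element size away from interfaces.
    h_min:
        Smallest axial size, used at the enzyme interface ``z = b3``
        (default ``h / 10``); pick ``~ sqrt(D2 (1 + S0) / sigma2) / 2`` to
        resolve the reaction boundary layer.
    growth:
        Geometric grading ratio of the axial grid.
    n_r_inner, n_r_outer:
        Radial element counts across the hole and across the outer annulus.
    z_lines:
        Explicit axial grid lines (must contain b1..b5); overrides the
        graded construction — used e.g. for nested refinement studies.
    """
    if h <= 0:
        raise MeshingError("h must be positive")
    h_min = h / 10 if h_min is None else h_min
    cell = build_unit_cell(spec)
    full = cell.full_width
    if not full and spec.a3 >= 1.0 - _TOL:
        raise MeshingError(
            "a3=1 with a2<1 gives a zero-thickness carrier plane; not meshable"
        )
    a_floor = spec.a2
    if not full and a_floor < 4 * h_min / 50:
        pass  # slender throats are fine for the mapped grid
    if spec.a2 <= 0:
        raise MeshingError("degenerate throat: increase a2 or reduce h")

    if z_lines is not None:
        zl = np.unique(np.asarray(z_lines, dtype=float))
        for plane in (spec.b1, spec.b2, spec.b3, spec.b4):
            if not np.any(np.abs(zl - plane) < 1e-12):
                raise MeshingError(f"z_lines must contain the interface z={plane}")
    else:
        zl = _z_lines(spec, h, h_min, growth)
    nzc = len(zl) - 1
    # fine (quadratic) axial lines
    zf = np.empty(2 * nzc + 1)
    zf[0::2] = zl
    zf[1::2] = 0.5 * (zl[:-1] + zl[1:])
    nzf = len(zf)

    def A_of(z: np.ndarray) -> np.ndarray:
        if full:
            return np.ones_like(z)
        zz = np.clip(z, spec.b2, spec.b4)
        return np.asarray(hole_radius_profile(spec.shape, zz, spec))

    Af = A_of(zf)

    ns, nt = n_r_inner, n_r_outer
    s_fine = np.linspace(0.0, 1.0, 2 * ns + 1)
    if full:
        nt = 0
        t_fine = np.empty(0)
    else:
        # outer radial fractions graded toward the carrier corner (t=0)
        t_coarse = 1.0 - np.cos(np.linspace(0, np.pi / 2, nt + 1))  # clustered at 0
        tf = np.empty(2 * nt + 1)
        tf[0::2] = t_coarse
        tf[1::2] = 0.5 * (t_coarse[:-1] + t_coarse[1:])
        t_fine = tf[1:]  # t=0 shared with the inner wall line

    in_slab = (zf <= spec.b2 + _TOL) | (zf >= spec.b4 - _TOL)

    n_in = 2 * ns + 1
    n_out = len(t_fine)
    ids = -np.ones((nzf, n_in + n_out), dtype=np.int64)
    pts: list[tuple[float, float]] = []
    for k in range(nzf):
        z = zf[k]
        A = Af[k]
        for j in range(n_in):
            ids[k, j] = len(pts)
            pts.append((s_fine[j] * A, z))
        if not full and in_slab[k]:
            for m in range(n_out):
                ids[k, n_in + m] = len(pts)
                pts.append((A + t_fine[m] * (1.0 - A), z))
    points = np.array(pts)

    tris: list[list[int]] = []
    region: list[int] = []

    def region_of(zmid: float, inner: bool) -> int:
        if zmid < spec.b1:
            return 1
        if inner:
            return 2 if zmid < spec.b3 else 3
        return 2 if zmid < spec.b2 else 3

    def add_quad(p):
        """p: 3x3 fine-node patch, p[ii][jj], ii axial, jj radial."""
        c00, c01, c11, c10 = p[0][0], p[0][2], p[2][2], p[2][0]
        tris.append([c00, c01, c11, p[0][1], p[1][2], p[1][1]])
        tris.append([c00, c11, c10, p[1][1], p[2][1], p[1][0]])

    for k in range(nzc):
        kf = 2 * k
        zmid = 0.5 * (zl[k] + zl[k + 1])
        inner_reg = region_of(zmid, True)
        for j in range(ns):
            jf = 2 * j
            patch = [[ids[kf + ii, jf + jj] for jj in range(3)] for ii in range(3)]
            add_quad(patch)
            region += [inner_reg, inner_reg]
        if not full and (zmid < spec.b2 or zmid > spec.b4):
            outer_reg = region_of(zmid, False)
            cols = [n_in - 1] + [n_in + m for m in range(n_out)]
            for j in range(nt):
                jj0 = 2 * j
                patch = [
                    [ids[kf + ii, cols[jj0 + jj]] for jj in range(3)]
                    for ii in range(3)
                ]
                add_quad(patch)
                region += [outer_reg, outer_reg]

    tris_a = np.array(tris, dtype=np.int64)
    region_a = np.array(region, dtype=np.int8)

    # ----- facets -----------------------------------------------------------
    def row_edges(k: int, cols: list[int]) -> np.ndarray:
        out = []
        for a, mid, b in zip(cols[:-2:2], cols[1:-1:2], cols[2::2]):
            out.append([ids[k, a], ids[k, b], ids[k, mid]])
        return np.array(out, dtype=np.int64) if out else np.empty((0, 3), np.int64)

    def col_edges(col: int, k_sel) -> np.ndarray:
        out = []
        for k in k_sel:
            kf = 2 * k
            out.append([ids[kf, col], ids[kf + 2, col], ids[kf + 1, col]])
        return np.array(out, dtype=np.int64) if out else np.empty((0, 3), np.int64)

    all_in = list(range(n_in))
    all_out = [n_in - 1] + [n_in + m for m in range(n_out)]
    full_row = all_in + ([] if full else all_out[1:])
    k_of_plane = {p: int(np.argmin(np.abs(zl - p))) for p in (spec.b1, spec.b2, spec.b3, spec.b4)}

    facets: dict[str, np.ndarray] = {}
    facets["electrode"] = row_edges(0, full_row)
    facets["bulk_top"] = row_edges(nzf - 1, full_row)
    facets["axis"] = col_edges(0, range(nzc))
    if full:
        facets["outer"] = col_edges(n_in - 1, range(nzc))
        facets["hole_wall"] = np.empty((0, 3), np.int64)
        facets["carrier_bottom"] = np.empty((0, 3), np.int64)
        facets["carrier_top"] = np.empty((0, 3), np.int64)
    else:
        k2, k4 = k_of_plane[spec.b2], k_of_plane[spec.b4]
        outer_rows = [k for k in range(nzc) if k < k2 or k >= k4]
        facets["outer"] = col_edges(n_in + n_out - 1, outer_rows)
        facets["hole_wall"] = col_edges(n_in - 1, range(k2, k4))
        facets["carrier_bottom"] = row_edges(2 * k2, all_out)
        facets["carrier_top"] = row_edges(2 * k4, all_out)
    k1 = k_of_plane[spec.b1]
    facets["gamma1"] = row_edges(2 * k1, full_row)
    k3 = k_of_plane[spec.b3]
    facets["gamma3"] = row_edges(2 * k3, all_in)

    mesh = Mesh(
        points=points,
        tris=tris_a,
        region=region_a,
        facets=facets,
        spec=spec,
        h=h,
        meta={
            "h_min": h_min,
            "growth": growth,
            "n_r_inner": ns,
            "n_r_outer": nt,
            "n_z": nzc,
            "degenerate": cell.degenerate,
        },
    )
    return mesh
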