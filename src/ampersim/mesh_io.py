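"""Mesh and field exchange in neutral text formats.

* Gmsh ``.msh`` v2.2 ASCII: 6-node triangles (element type 9) carry the
  region as their physical tag; 3-node boundary lines (type 8) carry the
  facet tag.  Tags round-trip through :func:`write_msh` / :func:`read_msh`.
* Legacy VTK ASCII unstructured grids (quadratic triangles, cell type 22)
  for field snapshots: point data ``S`` and ``P``, cell data ``region``.
"""

from __future__ import annotations

import numpy as np

from .meshing import BOUNDARY_TAGS, Mesh

__all__ = ["write_msh", "read_msh", "write_vtk", "TAG_IDS"]

#: numeric physical ids for facet tags (regions use their own 1..3)
TAG_IDS = {name: 100 + k for k, name in enumerate(BOUNDARY_TAGS)}
_ID_TAGS = {v: k for k, v in TAG_IDS.items()}


def write_msh(mesh: Mesh, path) -> None:
    with open(path, "w") as fh:
        fh.write("$MeshFormat\n2.2 0 8\n$EndMeshFormat\n")
        fh.write("$Nodes\n%d\n" % mesh.n_nodes)
        for k, (r, z) in enumerate(mesh.points, start=1):
            fh.write(f"{k} {r:.16g} {z:.16g} 0\n")
        fh.write("$EndNodes\n$Elements\n")
        n_lines = sum(f.shape[0] for f in mesh.facets.values())
        fh.write("%d\n" % (mesh.n_elements + n_lines))
        eid = 1
        for tag in BOUNDARY_TAGS:
            f = mesh.facets.get(tag)
            if f is None:
                continue
            pid = TAG_IDS[tag]
            for edge in f:
                a, b, m = (int(x) + 1 for x in edge)
                fh.write(f"{eid} 8 2 {pid} {pid} {a} {b} {m}\n")
                eid += 1
        for tri, reg in zip(mesh.tris, mesh.region):
            nodes = " ".join(str(int(x) + 1) for x in tri)
            fh.write(f"{eid} 9 2 {int(reg)} {int(reg)} {nodes}\n")
            eid += 1
        fh.write("$EndElements\n")


def read_msh(path) -> Mesh:
    with open(path) as fh:
        lines = fh.read().splitlines()
    it = iter(lines)

    def seek(token):
        for line in it:
            if line.strip() == token:
                return
        raise ValueError(f"section {token} not found")

    seek("$Nodes")
    n_nodes = int(next(it))
    pts = np.empty((n_nodes, 2))
    for _ in range(n_nodes):
        parts = next(it).split()
        pts[int(parts[0]) - 1] = (float(parts[1]), float(parts[2]))
    seek("$Elements")
    n_el = int(next(it))
    tris, regions = [], []
    facets: dict[str, list] = {t: [] for t in BOUNDARY_TAGS}
    for _ in range(n_el):
        parts = next(it).split()
        etype = int(parts[1])
        ntags = int(parts[2])
        phys = int(parts[3]) if ntags else 0
        conn = [int(x) - 1 for x in parts[3 + ntags :]]
        if etype == 9:
            tris.append(conn)
            regions.append(phys)
        elif etype == 8:
            tag = _ID_TAGS.get(phys)
            if tag is not None:
                facets[tag].append(conn)
    return Mesh(
        points=pts,
        tris=np.array(tris, dtype=np.int64),
        region=np.array(regions, dtype=np.int8),
        facets={
            t: (np.array(v, dtype=np.int64) if v else np.empty((0, 3), np.int64))
            for t, v in facets.items()
        },
    )


def write_vtk(mesh: Mesh, path, point_data: dict | None = None) -> None:
    """Legacy ASCII VTK snapshot (quadratic triangles, cell type 22)."""
    point_data = point_data or {}
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nbiosensor unit cell\nASCII\n")
        fh.write("DATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {mesh.n_nodes} double\n")
        for r, z in mesh.points:
            fh.write(f"{r:.10g} {z:.10g} 0\n")
        m = mesh.n_elements
        fh.write(f"CELLS {m} {7 * m}\n")
        for tri in mesh.tris:
            fh.write("6 " + " ".join(str(int(x)) for x in tri) + "\n")
        fh.write(f"CELL_TYPES {m}\n")
        fh.write("\n".join(["22"] * m) + "\n")
        if point_data:
            fh.write(f"POINT_DATA {mesh.n_nodes}\n")
            for name, vals in point_data.items():
                fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                fh.write("\n".join(f"{v:.10g}" for v in vals) + "\n")
        fh.write(f"CELL_DATA {m}\nSCALARS region int 1\nLOOKUP_TABLE default\n")
        fh.write("\n".join(str(int(r)) for r in mesh.region) + "\n")
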