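"""Axisymmetric cross-section meshes.

Meshes live in the (r, z) half-plane, r >= 0, with z along the optical axis.
Elements are 4-node (bilinear) or 8-node (serendipity) quadrilaterals.
Structured blocks are generated by mapping a unit square (u, v) through a
user-supplied coordinate function, which covers every geometry in this
package (rectangular flap cross-sections, spherical shell segments and the
polar "fan" filling the fluid cavity).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = ["AxiMesh", "build_mapped_block", "merge_meshes"]

# local edge -> node indices within the element connectivity
EDGES_Q4 = [(0, 1), (1, 2), (2, 3), (3, 0)]
EDGES_Q8 = [(0, 1, 4), (1, 2, 5), (2, 3, 6), (3, 0, 7)]


class MeshError(ValueError):
    """Raised for degenerate or inconsistent mesh geometry."""


@dataclass
class AxiMesh:
    """Unstructured axisymmetric mesh.

    Attributes
    ----------
    nodes : (N, 2) float array of (r, z) coordinates in metres.
    elements : (E, 4) or (E, 8) int array (homogeneous order per mesh).
    region : length-E array of region labels (str), e.g. ``cornea-anterior``,
        ``fluid``.
    edge_sets : named collections of (element, local_edge) pairs used for
        boundary conditions, loads and coupling surfaces.
    node_sets : named node-index arrays (probe points, constraint rings).
    fsi_edges : (element, local_edge) pairs of *solid* element edges wetted
        by the fluid, used to build the fluid-structure coupling operator.
    """

    nodes: np.ndarray
    elements: np.ndarray
    region: np.ndarray
    edge_sets: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    node_sets: dict[str, np.ndarray] = field(default_factory=dict)
    fsi_edges: list[tuple[int, int]] = field(default_factory=list)

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_elements(self) -> int:
        return self.elements.shape[0]

    @property
    def order(self) -> int:
        return self.elements.shape[1]

    def edge_nodes(self, elem: int, local_edge: int) -> np.ndarray:
        table = EDGES_Q4 if self.order == 4 else EDGES_Q8
        return self.elements[elem][list(table[local_edge])]

    def element_centroids(self) -> np.ndarray:
        return self.nodes[self.elements[:, :4]].mean(axis=1)

    def elements_in(self, *regions: str) -> np.ndarray:
        mask = np.isin(self.region, regions)
        return np.flatnonzero(mask)

    def validate(self) -> None:
        """Check basic invariants: r >= 0 and positive Jacobians at all
        quadrature points (degenerate/collapsed edges are allowed as long as
        the interior mapping stays orientation-preserving)."""
        from .elements import jacobians_at_gauss

        if self.nodes[:, 0].min() < -1e-12:
            raise MeshError("negative radial coordinate in mesh")
        for e in range(self.n_elements):
            J = jacobians_at_gauss(self.nodes[self.elements[e]])
            if J.min() <= 0.0:
                raise MeshError(
                    f"element {e} ({self.region[e]}) has non-positive Jacobian "
                    f"(min {J.min():.3e}) at a quadrature point"
                )
        if len(self.region) != self.n_elements:
            raise MeshError("region tags do not partition the element set")


def _lattice(order: int, nu: int, nv: int) -> tuple[np.ndarray, np.ndarray]:
    """Sample-point parameter grid for a structured block.

    Returns (u_params, v_params): for 8-node elements the lattice is twice as
    fine (midside nodes) with element-centre points later discarded.
    """
    step = 1 if order == 4 else 2
    uu = np.linspace(0.0, 1.0, step * nu + 1)
    vv = np.linspace(0.0, 1.0, step * nv + 1)
    return uu, vv


def build_mapped_block(
    xfun: Callable[[np.ndarray, np.ndarray], np.ndarray],
    nu: int,
    nv: int,
    order: int = 4,
    region: str | Sequence[str] = "solid",
    collapse_v0: bool = False,
) -> AxiMesh:
    """Structured quad block on the unit square mapped through ``xfun``.

    ``xfun(u, v)`` takes broadcastable parameter arrays in [0, 1] and returns
    (..., 2) physical coordinates.  ``region`` may be a single label or a
    length-``nu*nv`` sequence (element index = iu * nv + iv... column-major in
    u).  With ``collapse_v0`` every v=0 lattice point maps to a single node
    (polar fan centre).

    Edge sets created: ``u0``, ``u1`` (columns at u=0/1), ``v0``, ``v1``.
    """
    if nu < 1 or nv < 1:
        raise MeshError("block must have at least one element per direction")
    uu, vv = _lattice(order, nu, nv)
    U, V = np.meshgrid(uu, vv, indexing="ij")
    coords = np.asarray(xfun(U, V), dtype=float)  # (nuu, nvv, 2)
    nuu, nvv = U.shape

    step = 1 if order == 4 else 2
    nid = -np.ones((nuu, nvv), dtype=int)
    counter = 0
    nodes: list[tuple[float, float]] = []
    center_id = -1
    for i in range(nuu):
        for j in range(nvv):
            if order == 8 and i % 2 == 1 and j % 2 == 1:
                continue  # serendipity: no element-centre node
            if collapse_v0 and j == 0:
                if center_id < 0:
                    center_id = counter
                    nodes.append(tuple(coords[i, j]))
                    counter += 1
                nid[i, j] = center_id
                continue
            nid[i, j] = counter
            nodes.append(tuple(coords[i, j]))
            counter += 1

    elems = []
    for iu in range(nu):
        for iv in range(nv):
            i0, j0 = step * iu, step * iv
            if order == 4:
                conn = [nid[i0, j0], nid[i0 + 1, j0], nid[i0 + 1, j0 + 1], nid[i0, j0 + 1]]
            else:
                conn = [
                    nid[i0, j0], nid[i0 + 2, j0], nid[i0 + 2, j0 + 2], nid[i0, j0 + 2],
                    nid[i0 + 1, j0], nid[i0 + 2, j0 + 1], nid[i0 + 1, j0 + 2], nid[i0, j0 + 1],
                ]
            elems.append(conn)
    elements = np.asarray(elems, dtype=int)

    if isinstance(region, str):
        regions = np.array([region] * (nu * nv), dtype=object)
    else:
        regions = np.asarray(list(region), dtype=object)
        if regions.size != nu * nv:
            raise MeshError("per-element region sequence has wrong length")

    # element (iu, iv) -> flat index iu * nv + iv
    def eidx(iu: int, iv: int) -> int:
        return iu * nv + iv

    edge_sets: dict[str, list[tuple[int, int]]] = {
        "v0": [(eidx(iu, 0), 0) for iu in range(nu)],
        "v1": [(eidx(iu, nv - 1), 2) for iu in range(nu)],
        "u0": [(eidx(0, iv), 3) for iv in range(nv)],
        "u1": [(eidx(nu - 1, iv), 1) for iv in range(nv)],
    }
    return AxiMesh(
        nodes=np.asarray(nodes, dtype=float),
        elements=elements,
        region=regions,
        edge_sets=edge_sets,
    )


def merge_meshes(a: AxiMesh, b: AxiMesh, tol: float = 1e-12) -> AxiMesh:
    """Concatenate two meshes, fusing nodes that coincide within ``tol``.

    Edge sets and node sets are carried over; name clashes are resolved by
    prefixing the second mesh's names with ``b:``.
    """
    key = {}
    for idx, (r, z) in enumerate(a.nodes):
        key[(round(r / tol), round(z / tol))] = idx
    remap = np.empty(b.n_nodes, dtype=int)
    new_nodes = list(map(tuple, a.nodes))
    for idx, (r, z) in enumerate(b.nodes):
        k = (round(r / tol), round(z / tol))
        if k in key:
            remap[idx] = key[k]
        else:
            key[k] = len(new_nodes)
            remap[idx] = len(new_nodes)
            new_nodes.append((r, z))

    if a.order != b.order:
        raise MeshError("cannot merge meshes of different element order")
    elements = np.vstack([a.elements, remap[b.elements]])
    region = np.concatenate([a.region, b.region])
    off = a.n_elements
    edge_sets = {k: list(v) for k, v in a.edge_sets.items()}
    for k, v in b.edge_sets.items():
        name = k if k not in edge_sets else f"b:{k}"
        edge_sets[name] = [(e + off, le) for e, le in v]
    node_sets = {k: v.copy() for k, v in a.node_sets.items()}
    for k, v in b.node_sets.items():
        name = k if k not in node_sets else f"b:{k}"
        node_sets[name] = remap[v]
    fsi = list(a.fsi_edges) + [(e + off, le) for e, le in b.fsi_edges]
    return AxiMesh(
        nodes=np.asarray(new_nodes, dtype=float),
        elements=elements,
        region=region,
        edge_sets=edge_sets,
        node_sets=node_sets,
        fsi_edges=fsi,
    )
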