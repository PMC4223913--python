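"""Assembly and solution of the damped structural-acoustic harmonic system.

The steady-state response at an imposed circular frequency Omega = 2*pi*f
solves

    (-Omega^2 [M] + i Omega [C] + [K(Omega)]) {u1 + i u2} = {F1 + i F2}

where the stiffness is complex and frequency dependent through the Prony
viscoelastic modulus.  With an acoustic fluid the coupled (unsymmetric)
block system in displacement u and pressure p is

    [ K_s(Omega) + K_g - Omega^2 M_s      -R          ] [u]   [F]
    [ -rho_f Omega^2 R^T            K_f - Omega^2 M_f ] [p] = [0]

with R the wetted-surface coupling operator.  Every frequency point is
solved with a direct complex sparse factorisation; meshes are small enough
that robustness beats iterative speed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from . import elements as el
from .materials import FluidSpec, MaterialSpec, complex_modulus
from .mesh import AxiMesh

__all__ = [
    "DofMap",
    "PrestressState",
    "HarmonicSystem",
    "HarmonicSolution",
    "SolverError",
    "assemble_solid",
    "assemble_fluid",
    "assemble_coupling",
    "assemble_geometric_stiffness",
    "pressure_load",
    "static_solve",
    "stress_field",
    "acoustic_eigenfrequencies",
]

SOLID_REGIONS_EXCLUDED = ("fluid",)


class SolverError(RuntimeError):
    pass


@dataclass
class DofMap:
    """Global dof numbering: solid (u_r, u_z) pairs first, then pressures."""

    solid_nodes: np.ndarray
    fluid_nodes: np.ndarray
    s_of_node: np.ndarray  # node -> solid slot (-1 if none)
    p_of_node: np.ndarray  # node -> fluid slot (-1 if none)

    @classmethod
    def build(cls, mesh: AxiMesh) -> "DofMap":
        solid_mask = ~np.isin(mesh.region, SOLID_REGIONS_EXCLUDED)
        sn = np.unique(mesh.elements[solid_mask])
        fn = np.unique(mesh.elements[~solid_mask]) if (~solid_mask).any() else np.array([], int)
        s_of = -np.ones(mesh.n_nodes, dtype=int)
        s_of[sn] = np.arange(sn.size)
        p_of = -np.ones(mesh.n_nodes, dtype=int)
        p_of[fn] = np.arange(fn.size)
        return cls(sn, fn, s_of, p_of)

    @property
    def n_solid(self) -> int:
        return 2 * self.solid_nodes.size

    @property
    def n_fluid(self) -> int:
        return self.fluid_nodes.size

    @property
    def n_total(self) -> int:
        return self.n_solid + self.n_fluid

    def sdofs(self, nodes: np.ndarray) -> np.ndarray:
        """Interleaved (r, z) dof indices for the given nodes."""
        s = self.s_of_node[nodes]
        if (s < 0).any():
            raise ValueError("node without solid dofs")
        return np.column_stack([2 * s, 2 * s + 1]).ravel()

    def pdofs(self, nodes: np.ndarray) -> np.ndarray:
        p = self.p_of_node[nodes]
        if (p < 0).any():
            raise ValueError("node without pressure dof")
        return self.n_solid + p


@dataclass
class PrestressState:
    """Per-element Gauss-point stresses (Pa) feeding the geometric stiffness.

    ``stresses`` maps element index -> (n_gauss, 4) array in
    [s_rr, s_zz, s_tt, s_rz] order.  An empty state (or all zeros)
    reproduces the unstressed stiffness exactly.
    """

    stresses: dict[int, np.ndarray] = field(default_factory=dict)

    @classmethod
    def uniform(cls, mesh: AxiMesh, elems: Sequence[int], sigma: np.ndarray) -> "PrestressState":
        sigma = np.asarray(sigma, dtype=float)
        ngp = 4 if mesh.order == 4 else 9
        return cls({int(e): np.tile(sigma, (ngp, 1)) for e in elems})

    def is_zero(self, tol: float = 0.0) -> bool:
        return all(np.abs(s).max() <= tol for s in self.stresses.values()) if self.stresses else True


class _Accumulator:
    def __init__(self):
        self.rows, self.cols, self.vals = [], [], []

    def add(self, dofs_r, dofs_c, mat):
        self.rows.append(np.repeat(dofs_r, len(dofs_c)))
        self.cols.append(np.tile(dofs_c, len(dofs_r)))
        self.vals.append(np.asarray(mat, dtype=float).ravel())

    def tocsr(self, nr, nc):
        if not self.rows:
            return sp.csr_matrix((nr, nc))
        return sp.csr_matrix(
            (np.concatenate(self.vals), (np.concatenate(self.rows), np.concatenate(self.cols))),
            shape=(nr, nc),
        )


def _solid_elements(mesh: AxiMesh) -> np.ndarray:
    return np.flatnonzero(~np.isin(mesh.region, SOLID_REGIONS_EXCLUDED))


def assemble_solid(
    mesh: AxiMesh,
    materials: dict[str, MaterialSpec],
    dof: DofMap | None = None,
    e_scale: np.ndarray | None = None,
):
    """Assemble solid mass and per-region stiffness blocks.

    Returns (M, K_blocks, dof) where ``K_blocks`` is a list of
    (csr_matrix, scale_fn) pairs: the frequency-domain stiffness is
    ``sum(block * scale_fn(f))`` with ``scale_fn(f) = E*(f) / E`` for the
    block's material.  ``e_scale`` optionally multiplies each element's
    modulus (local weakening); it folds into the assembled block, so the
    complex frequency factor is unaffected.
    """
    dof = dof or DofMap.build(mesh)
    n = dof.n_solid
    accM = _Accumulator()
    accK: dict[str, _Accumulator] = {}
    for e in _solid_elements(mesh):
        reg = mesh.region[e]
        mat = materials[reg]
        if mat is None:
            raise ValueError(f"no material for solid region {reg!r}")
        scale = 1.0 if e_scale is None else float(e_scale[e])
        xy = mesh.nodes[mesh.elements[e]]
        lam, mu = mat.lame(mat.E * scale)
        try:
            Ke, Me = el.solid_matrices(xy, lam, mu, mat.rho)
        except ValueError as exc:
            raise ValueError(f"degenerate geometry in element {e} ({reg}): {exc}") from exc
        dofs = dof.sdofs(mesh.elements[e])
        accM.add(dofs, dofs, Me)
        accK.setdefault(reg, _Accumulator()).add(dofs, dofs, Ke)

    M = accM.tocsr(n, n)

    def make_scale(mat: MaterialSpec) -> Callable[[float], complex]:
        def scale_fn(f: float, _mat=mat) -> complex:
            return complex_modulus(_mat, f) / _mat.E

        return scale_fn

    K_blocks = [(acc.tocsr(n, n), make_scale(materials[reg])) for reg, acc in accK.items()]
    return M, K_blocks, dof


def assemble_geometric_stiffness(
    mesh: AxiMesh, prestress: PrestressState | None, dof: DofMap
) -> sp.csr_matrix:
    n = dof.n_solid
    if prestress is None or not prestress.stresses:
        return sp.csr_matrix((n, n))
    acc = _Accumulator()
    for e, sgp in prestress.stresses.items():
        xy = mesh.nodes[mesh.elements[e]]
        Kg = el.geometric_stiffness(xy, sgp)
        dofs = dof.sdofs(mesh.elements[e])
        acc.add(dofs, dofs, Kg)
    return acc.tocsr(n, n)


def assemble_fluid(mesh: AxiMesh, fluid: FluidSpec, dof: DofMap):
    """Acoustic (Helmholtz) matrices over the pressure dofs.

    Scaled so that rigid-cavity eigenfrequencies equal their analytic
    values: K_f p = Omega^2 M_f p with M_f carrying the 1/c^2 factor.
    """
    if dof.n_fluid == 0:
        raise ValueError("mesh has no fluid region")
    nf = dof.n_fluid
    accK, accM = _Accumulator(), _Accumulator()
    for e in np.flatnonzero(np.isin(mesh.region, SOLID_REGIONS_EXCLUDED)):
        xy = mesh.nodes[mesh.elements[e]]
        Ke, Me = el.fluid_matrices(xy, fluid.c)
        pd = dof.pdofs(mesh.elements[e]) - dof.n_solid
        accK.add(pd, pd, Ke)
        accM.add(pd, pd, Me)
    return accK.tocsr(nf, nf), accM.tocsr(nf, nf)


def _edge_geometry(mesh: AxiMesh, e: int, le: int):
    conn = mesh.elements[e]
    enodes = mesh.edge_nodes(e, le)
    elem_xy = mesh.nodes[conn]
    edge_xy = mesh.nodes[enodes]
    sign = el.edge_normal_sign(elem_xy, edge_xy)
    return enodes, edge_xy, sign


def assemble_coupling(
    mesh: AxiMesh,
    dof: DofMap,
    fsi_edges: Sequence[tuple[int, int]] | None = None,
) -> sp.csr_matrix:
    """Fluid-structure coupling operator R (n_solid x n_fluid).

    R[u_a, p_b] = int_Gamma N_a n N_b r ds with n pointing from the fluid
    into the solid (so the force on the solid from a pressure field p is
    +R p and the fluid equation receives -rho_f Omega^2 R^T u).
    """
    edges = mesh.fsi_edges if fsi_edges is None else fsi_edges
    rows, cols, vals = [], [], []
    for e, le in edges:
        enodes, edge_xy, sign = _edge_geometry(mesh, e, le)
        n_f_sign = -sign  # fluid->solid normal is minus the solid outward normal
        sd = dof.sdofs(enodes)  # interleaved (r, z)
        pd = dof.pdofs(enodes) - dof.n_solid
        nn = len(enodes)
        Re = np.zeros((2 * nn, nn))
        for N, r, normal, w in el.edge_quadrature(edge_xy):
            nvec = n_f_sign * normal
            Re[0::2] += w * r * nvec[0] * np.outer(N, N)
            Re[1::2] += w * r * nvec[1] * np.outer(N, N)
        rows.append(np.repeat(sd, nn))
        cols.append(np.tile(pd, 2 * nn))
        vals.append(Re.ravel())
    if not rows:
        return sp.csr_matrix((dof.n_solid, dof.n_fluid))
    return sp.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(dof.n_solid, dof.n_fluid),
    )


def pressure_load(
    mesh: AxiMesh,
    dof: DofMap,
    edges: Sequence[tuple[int, int]],
    p: float,
) -> np.ndarray:
    """Consistent nodal forces of a pressure ``p`` acting *against* the
    outward normal of the solid along the given edges (an external or
    internal fluid pushing on the surface).  Returns a length-n_total vector.
    """
    f = np.zeros(dof.n_total)
    for e, le in edges:
        enodes, edge_xy, sign = _edge_geometry(mesh, e, le)
        sd = dof.sdofs(enodes)
        fe = np.zeros(2 * len(enodes))
        for N, r, normal, w in el.edge_quadrature(edge_xy):
            t = -p * sign * normal  # traction on the solid
            fe[0::2] += w * r * t[0] * N
            fe[1::2] += w * r * t[1] * N
        f[sd] += fe
    return f


@dataclass
class HarmonicSystem:
    """Assembled frequency-domain operators plus constraints and load."""

    dof: DofMap
    M: sp.csr_matrix
    K_blocks: list  # [(csr, scale_fn)]
    Kg: sp.csr_matrix | None = None
    C: sp.csr_matrix | None = None
    R: sp.csr_matrix | None = None
    Kf: sp.csr_matrix | None = None
    Mf: sp.csr_matrix | None = None
    rho_f: float = 0.0
    fixed: np.ndarray | None = None  # bool over n_total
    load: np.ndarray | None = None  # complex over n_total
    # inertial (base-motion) load component, multiplied by Omega^2 at solve
    # time: for a rigid base acceleration the consistent force is
    # Omega^2 [M u_base; rho_f R^T u_base]
    load_omega2: np.ndarray | None = None

    def __post_init__(self):
        n = self.dof.n_total
        if self.fixed is None:
            self.fixed = np.zeros(n, dtype=bool)
        if self.load is None:
            self.load = np.zeros(n, dtype=complex)
        if self.Kf is None and self.dof.n_fluid:
            # in-vacuo analysis on a mesh that has a fluid region: the
            # pressure dofs carry no equations, deactivate them
            self.fixed = self.fixed.copy()
            self.fixed[self.dof.n_solid:] = True

    @property
    def free(self) -> np.ndarray:
        return np.flatnonzero(~self.fixed)

    def stiffness(self, f: float) -> sp.csr_matrix:
        K = None
        for block, scale_fn in self.K_blocks:
            term = block * scale_fn(f)
            K = term if K is None else K + term
        if self.Kg is not None and self.Kg.nnz:
            K = K + self.Kg.astype(complex)
        return K

    def operator(self, f: float) -> sp.csr_matrix:
        """Full (unreduced) system matrix at imposed frequency f in Hz."""
        omega = 2.0 * np.pi * f
        A_ss = self.stiffness(f) - (omega**2) * self.M
        if self.C is not None and self.C.nnz:
            A_ss = A_ss + (1j * omega) * self.C
        if self.Kf is not None:
            A_sf = -self.R
            A_fs = -(self.rho_f * omega**2) * self.R.T
            A_ff = self.Kf - (omega**2) * self.Mf
            A = sp.bmat([[A_ss, A_sf], [A_fs, A_ff]], format="csr").astype(complex)
        else:
            A = A_ss.tocsr().astype(complex)
        return A

    # -- cached fast path: union sparsity over the free dofs, updated in-place

    def _parts(self):
        """(matrix, coefficient_fn) pairs over the full dof set."""
        ns, n = self.dof.n_solid, self.dof.n_total
        two_pi = 2.0 * np.pi

        def expand(mat, ro, co):
            c = mat.tocoo()
            return sp.csr_matrix((c.data, (c.row + ro, c.col + co)), shape=(n, n))

        parts = [(expand(blk, 0, 0), (lambda f, s=sf: s(f))) for blk, sf in self.K_blocks]
        parts.append((expand(self.M, 0, 0), lambda f: -((two_pi * f) ** 2)))
        if self.Kg is not None and self.Kg.nnz:
            parts.append((expand(self.Kg, 0, 0), lambda f: 1.0))
        if self.C is not None and self.C.nnz:
            parts.append((expand(self.C, 0, 0), lambda f: 1j * two_pi * f))
        if self.Kf is not None:
            parts.append((expand(self.R, 0, ns), lambda f: -1.0))
            parts.append(
                (expand(self.R.T.tocsr(), ns, 0), lambda f: -self.rho_f * (two_pi * f) ** 2)
            )
            parts.append((expand(self.Kf, ns, ns), lambda f: 1.0))
            parts.append((expand(self.Mf, ns, ns), lambda f: -((two_pi * f) ** 2)))
        return parts

    def _compile(self):
        free = self.free
        parts = []
        for mat, coeff in self._parts():
            red = mat[free][:, free].tocsr()
            red.sort_indices()
            parts.append((red, coeff))
        union = None
        for red, _ in parts:
            pat = sp.csr_matrix(
                (np.ones_like(red.data), red.indices.copy(), red.indptr.copy()), shape=red.shape
            )
            union = pat if union is None else union + pat
        union = union.tocsr()
        union.sort_indices()
        maps = []
        for red, coeff in parts:
            pos = np.empty(red.nnz, dtype=np.int64)
            for i in range(red.shape[0]):
                a0, a1 = union.indptr[i], union.indptr[i + 1]
                p0, p1 = red.indptr[i], red.indptr[i + 1]
                if p0 < p1:
                    pos[p0:p1] = a0 + np.searchsorted(
                        union.indices[a0:a1], red.indices[p0:p1]
                    )
            maps.append((pos, red.data.copy(), coeff))
        self._cache = (union.indptr, union.indices, union.nnz, union.shape, maps)

    def operator_reduced(self, f: float) -> sp.csc_matrix:
        """System matrix restricted to free dofs (cached-pattern fast path)."""
        if not hasattr(self, "_cache"):
            self._compile()
        indptr, indices, nnz, shape, maps = self._cache
        data = np.zeros(nnz, dtype=complex)
        for pos, vals, coeff in maps:
            data[pos] += coeff(f) * vals
        return sp.csc_matrix(sp.csr_matrix((data, indices, indptr), shape=shape))


@dataclass
class HarmonicSolution:
    f: float
    u: np.ndarray  # complex, length n_total (zeros at constrained dofs)
    dof: DofMap
    residual: float

    @property
    def omega(self) -> float:
        return 2.0 * np.pi * self.f

    def u_z(self, node: int) -> complex:
        return self.u[2 * self.dof.s_of_node[node] + 1]

    def u_r(self, node: int) -> complex:
        return self.u[2 * self.dof.s_of_node[node]]

    def pressure(self, node: int) -> complex:
        return self.u[self.dof.n_solid + self.dof.p_of_node[node]]

    def amplitude(self, node: int) -> float:
        return abs(self.u_z(node))

    def phase(self, node: int) -> float:
        return float(np.angle(self.u_z(node)))


def solve_harmonic(system: HarmonicSystem, f: float) -> HarmonicSolution:
    """Direct sparse solve of the assembled system at one frequency."""
    A_red = system.operator_reduced(f)
    free = system.free
    b = system.load[free].astype(complex)
    if system.load_omega2 is not None:
        b = b + (2.0 * np.pi * f) ** 2 * system.load_omega2[free]
    try:
        # the block system has a symmetric pattern; SuperLU's symmetric mode
        # with minimum-degree on A + A^T cuts fill by ~3x on these meshes
        lu = spla.splu(
            A_red,
            permc_spec="MMD_AT_PLUS_A",
            options=dict(SymmetricMode=True, DiagPivotThresh=0.01),
        )
        x = lu.solve(b)
        bn = np.linalg.norm(b)
        if bn > 0 and (
            not np.all(np.isfinite(x))
            or np.linalg.norm(A_red @ x - b) / bn > 1e-8
        ):
            raise RuntimeError("weak-pivot factorisation inaccurate")
    except RuntimeError:
        try:
            lu = spla.splu(A_red)
            x = lu.solve(b)
        except RuntimeError as exc:
            raise SolverError(
                f"factorisation failed at f = {f:.6g} Hz ({exc}); the undamped "
                "system is singular exactly at an eigenfrequency -- add damping "
                "(Prony or Rayleigh) or offset the frequency"
            ) from exc
    if not np.all(np.isfinite(x)):
        raise SolverError(
            f"non-finite response at f = {f:.6g} Hz; solve exactly at an undamped "
            "resonance -- add damping or offset the frequency"
        )
    bn = np.linalg.norm(b)
    residual = float(np.linalg.norm(A_red @ x - b) / bn) if bn > 0 else 0.0
    u = np.zeros(system.dof.n_total, dtype=complex)
    u[free] = x
    return HarmonicSolution(f=f, u=u, dof=system.dof, residual=residual)


def static_solve(system: HarmonicSystem, load: np.ndarray | None = None) -> np.ndarray:
    """Static (f = 0, relaxed-modulus) displacement solve on the solid block.

    Used to compute the IOP prestress state.  Returns a real vector over all
    dofs (pressure entries zero).
    """
    ns = system.dof.n_solid
    K = None
    for block, scale_fn in system.K_blocks:
        term = block * float(np.real(scale_fn(0.0)))
        K = term if K is None else K + term
    b = np.real(system.load if load is None else load)[:ns]
    fixed_s = system.fixed[:ns]
    free = np.flatnonzero(~fixed_s)
    x = spla.spsolve(K[free][:, free].tocsc(), b[free])
    u = np.zeros(system.dof.n_total)
    u[np.flatnonzero(~fixed_s)] = x
    return u


def stress_field(
    mesh: AxiMesh,
    materials: dict[str, MaterialSpec],
    dof: DofMap,
    u: np.ndarray,
    e_scale: np.ndarray | None = None,
) -> PrestressState:
    """Gauss-point stresses of a static displacement field (relaxed moduli)."""
    out: dict[int, np.ndarray] = {}
    for e in _solid_elements(mesh):
        mat = materials[mesh.region[e]]
        scale = (1.0 if e_scale is None else float(e_scale[e])) * mat.relaxed_fraction
        lam, mu = mat.lame(mat.E * scale)
        xy = mesh.nodes[mesh.elements[e]]
        u_e = np.real(u[dof.sdofs(mesh.elements[e])])
        out[int(e)] = el.solid_stress_at_gauss(xy, lam, mu, u_e)
    return PrestressState(out)


def initial_stress_forces(
    mesh: AxiMesh, prestress: PrestressState, dof: DofMap
) -> np.ndarray:
    """Internal nodal forces of an initial stress field, f = int B^T s dV.

    A stress state is self-equilibrated iff this vector vanishes on the
    free dofs; relaxing a homogeneous initial stress amounts to solving
    K u = -f and adding the resulting stress increment.
    """
    f = np.zeros(dof.n_total)
    for e, sgp in prestress.stresses.items():
        xy = mesh.nodes[mesh.elements[e]]
        order = xy.shape[0]
        Bbars, wJr, _, _ = el._b_matrices(order, xy)
        fe = np.zeros(2 * order)
        for B, w, s in zip(Bbars, wJr, np.atleast_2d(sgp)):
            fe += w * (B.T @ s)
        f[dof.sdofs(mesh.elements[e])] += fe
    return f


def acoustic_eigenfrequencies(
    mesh: AxiMesh,
    fluid: FluidSpec,
    n_modes: int = 5,
    fixed_pressure_nodes: np.ndarray | None = None,
) -> np.ndarray:
    """Eigenfrequencies (Hz) of the rigid-walled (optionally pressure-release)
    acoustic cavity.  Small meshes only: dense generalised eigensolve."""
    import scipy.linalg as sla

    dof = DofMap.build(mesh)
    Kf, Mf = assemble_fluid(mesh, fluid, dof)
    keep = np.ones(dof.n_fluid, dtype=bool)
    if fixed_pressure_nodes is not None:
        keep[dof.p_of_node[fixed_pressure_nodes]] = False
    K = Kf.toarray()[np.ix_(keep, keep)]
    M = Mf.toarray()[np.ix_(keep, keep)]
    w2 = sla.eigh(K, M, eigvals_only=True)
    w2 = np.sort(w2[w2 > 1e-8 * w2.max()])  # drop the constant-pressure mode
    return np.sqrt(w2[:n_modes]) / (2.0 * np.pi)
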