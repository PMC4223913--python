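"""Axisymmetric isoparametric quadrilateral elements (circumferential order n = 0).

Solid elements carry (u_r, u_z) displacement per node with the strain vector
[eps_rr, eps_zz, eps_theta, gamma_rz]; near-incompressibility is handled by
mean-dilatation B-bar (the volumetric strain operator is replaced by its
element average), which keeps the formulation locking-free at nu = 0.499.
Fluid elements carry one acoustic pressure per node and discretise the
Helmholtz operator.  All integrals include the axisymmetric weight r; the
common factor 2*pi is dropped consistently from every operator and load.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "shape_functions",
    "gauss_points",
    "solid_matrices",
    "geometric_stiffness",
    "fluid_matrices",
    "edge_quadrature",
    "edge_normal_sign",
    "jacobians_at_gauss",
    "solid_stress_at_gauss",
]

_SQ3 = 1.0 / np.sqrt(3.0)
_SQ35 = np.sqrt(0.6)
_GAUSS_1D_2 = (np.array([-_SQ3, _SQ3]), np.array([1.0, 1.0]))
_GAUSS_1D_3 = (np.array([-_SQ35, 0.0, _SQ35]), np.array([5.0, 8.0, 5.0]) / 9.0)

# corner coordinates in the reference square, counter-clockwise
_XI_C = np.array([-1.0, 1.0, 1.0, -1.0])
_ETA_C = np.array([-1.0, -1.0, 1.0, 1.0])


def shape_functions(order: int, xi: float, eta: float) -> tuple[np.ndarray, np.ndarray]:
    """Shape functions N and reference-gradients dN (shape (n, 2)) at (xi, eta)."""
    if order == 4:
        N = 0.25 * (1 + xi * _XI_C) * (1 + eta * _ETA_C)
        dN = np.empty((4, 2))
        dN[:, 0] = 0.25 * _XI_C * (1 + eta * _ETA_C)
        dN[:, 1] = 0.25 * _ETA_C * (1 + xi * _XI_C)
        return N, dN
    if order == 8:
        N = np.empty(8)
        dN = np.empty((8, 2))
        # corners
        for a in range(4):
            xa, ea = _XI_C[a], _ETA_C[a]
            N[a] = 0.25 * (1 + xi * xa) * (1 + eta * ea) * (xi * xa + eta * ea - 1)
            dN[a, 0] = 0.25 * xa * (1 + eta * ea) * (2 * xi * xa + eta * ea)
            dN[a, 1] = 0.25 * ea * (1 + xi * xa) * (xi * xa + 2 * eta * ea)
        # midsides: 4 (eta=-1), 5 (xi=+1), 6 (eta=+1), 7 (xi=-1)
        N[4] = 0.5 * (1 - xi**2) * (1 - eta)
        dN[4] = [-xi * (1 - eta), -0.5 * (1 - xi**2)]
        N[5] = 0.5 * (1 + xi) * (1 - eta**2)
        dN[5] = [0.5 * (1 - eta**2), -eta * (1 + xi)]
        N[6] = 0.5 * (1 - xi**2) * (1 + eta)
        dN[6] = [-xi * (1 + eta), 0.5 * (1 - xi**2)]
        N[7] = 0.5 * (1 - xi) * (1 - eta**2)
        dN[7] = [-0.5 * (1 - eta**2), -eta * (1 - xi)]
        return N, dN
    raise ValueError(f"unsupported element order {order}")


def gauss_points(order: int) -> tuple[np.ndarray, np.ndarray]:
    """(points (g, 2), weights (g,)) — 2x2 for 4-node, 3x3 for 8-node."""
    pts1, w1 = _GAUSS_1D_2 if order == 4 else _GAUSS_1D_3
    P = np.array([(x, e) for x in pts1 for e in pts1])
    W = np.array([wx * we for wx in w1 for we in w1])
    return P, W


def _geometry_at(order, xy, xi, eta):
    N, dN = shape_functions(order, xi, eta)
    J = xy.T @ dN  # (2, 2): d(r,z)/d(xi,eta)
    detJ = J[0, 0] * J[1, 1] - J[0, 1] * J[1, 0]
    r = N @ xy[:, 0]
    return N, dN, J, detJ, r


def jacobians_at_gauss(xy: np.ndarray) -> np.ndarray:
    order = xy.shape[0]
    P, _ = gauss_points(order)
    return np.array([_geometry_at(order, xy, xi, eta)[3] for xi, eta in P])


def _b_matrices(order, xy):
    """Per-Gauss-point B matrices, B-bar corrected, plus integration weights.

    Returns (Bbar list, wJr array, N list, r array).
    """
    P, W = gauss_points(order)
    n = order
    Bs, Ns, wJr, rs = [], [], np.empty(len(P)), np.empty(len(P))
    for g, (xi, eta) in enumerate(P):
        N, dN, J, detJ, r = _geometry_at(order, xy, xi, eta)
        if detJ <= 0:
            raise ValueError("non-positive Jacobian in element")
        invJ = np.linalg.inv(J)
        grad = dN @ invJ  # (n, 2): dN/dr, dN/dz
        B = np.zeros((4, 2 * n))
        B[0, 0::2] = grad[:, 0]
        B[1, 1::2] = grad[:, 1]
        B[2, 0::2] = N / r
        B[3, 0::2] = grad[:, 1]
        B[3, 1::2] = grad[:, 0]
        Bs.append(B)
        Ns.append(N)
        wJr[g] = W[g] * detJ * r
        rs[g] = r
    # mean dilatation: replace volumetric row by its volume average
    vol = wJr.sum()
    bv_bar = sum(w * (B[0] + B[1] + B[2]) for B, w in zip(Bs, wJr)) / vol
    Bbars = []
    for B in Bs:
        bv = B[0] + B[1] + B[2]
        corr = (bv_bar - bv) / 3.0
        Bb = B.copy()
        Bb[0] += corr
        Bb[1] += corr
        Bb[2] += corr
        Bbars.append(Bb)
    return Bbars, wJr, Ns, rs


def _dmat(lam, mu):
    D = np.array(
        [
            [lam + 2 * mu, lam, lam, 0.0],
            [lam, lam + 2 * mu, lam, 0.0],
            [lam, lam, lam + 2 * mu, 0.0],
            [0.0, 0.0, 0.0, mu],
        ],
        dtype=complex if isinstance(lam, complex) else float,
    )
    return D


def solid_matrices(xy: np.ndarray, lam: float, mu: float, rho: float):
    """Element stiffness (at unit-scale modulus) and consistent mass.

    Returns (K (2n, 2n), M (2n, 2n)).
    """
    order = xy.shape[0]
    Bbars, wJr, Ns, _ = _b_matrices(order, xy)
    D = _dmat(lam, mu)
    n2 = 2 * order
    K = np.zeros((n2, n2))
    M = np.zeros((n2, n2))
    for B, w, N in zip(Bbars, wJr, Ns):
        K += w * (B.T @ D @ B)
        NN = np.outer(N, N)
        M[0::2, 0::2] += rho * w * NN
        M[1::2, 1::2] += rho * w * NN
    return K, M


def solid_stress_at_gauss(xy: np.ndarray, lam: float, mu: float, u_e: np.ndarray) -> np.ndarray:
    """Stress [s_rr, s_zz, s_tt, s_rz] at each Gauss point from element dofs."""
    order = xy.shape[0]
    Bbars, _, _, _ = _b_matrices(order, xy)
    D = _dmat(lam, mu)
    return np.array([D @ (B @ u_e) for B in Bbars])


def geometric_stiffness(xy: np.ndarray, stress_gp: np.ndarray) -> np.ndarray:
    """Initial-stress (stress-stiffening) matrix for axisymmetric n = 0 motion.

    ``stress_gp`` is (n_gauss, 4) in [s_rr, s_zz, s_tt, s_rz] order; a (4,)
    array is broadcast to all Gauss points (uniform prestress).
    """
    order = xy.shape[0]
    P, W = gauss_points(order)
    stress_gp = np.asarray(stress_gp, dtype=float)
    if stress_gp.ndim == 1:
        stress_gp = np.tile(stress_gp, (len(P), 1))
    n2 = 2 * order
    Kg = np.zeros((n2, n2))
    for g, (xi, eta) in enumerate(P):
        N, dN, J, detJ, r = _geometry_at(order, xy, xi, eta)
        invJ = np.linalg.inv(J)
        grad = dN @ invJ
        srr, szz, stt, srz = stress_gp[g]
        S = np.array([[srr, srz], [srz, szz]])
        G = grad @ S @ grad.T  # (n, n)
        w = W[g] * detJ * r
        Kg[0::2, 0::2] += w * (G + stt * np.outer(N, N) / r**2)
        Kg[1::2, 1::2] += w * G
    return Kg


def fluid_matrices(xy: np.ndarray, c: float):
    """Acoustic element matrices: K_f = int grad N . grad N r dA and
    M_f = (1/c^2) int N N r dA, so that (K_f - Omega^2 M_f) p = coupling."""
    order = xy.shape[0]
    P, W = gauss_points(order)
    K = np.zeros((order, order))
    M = np.zeros((order, order))
    for g, (xi, eta) in enumerate(P):
        N, dN, J, detJ, r = _geometry_at(order, xy, xi, eta)
        if detJ <= 0:
            raise ValueError("non-positive Jacobian in fluid element")
        grad = dN @ np.linalg.inv(J)
        w = W[g] * detJ * r
        K += w * (grad @ grad.T)
        M += (w / c**2) * np.outer(N, N)
    return K, M


def edge_quadrature(edge_xy: np.ndarray):
    """1D quadrature data along an element edge.

    ``edge_xy``: (2, 2) for linear edges (end, end) or (3, 2) for quadratic
    edges ordered (end, end, midside).  Yields tuples
    (N (n,), r, normal (2,), w * |dX/ds|) where ``normal`` is the tangent
    rotated by -90 deg (t_z, -t_r), unit length; orientation is fixed by the
    caller via :func:`edge_normal_sign`.
    """
    nn = edge_xy.shape[0]
    pts, wts = _GAUSS_1D_3
    out = []
    for s, w in zip(pts, wts):
        if nn == 2:
            N = np.array([0.5 * (1 - s), 0.5 * (1 + s)])
            dN = np.array([-0.5, 0.5])
        else:
            N = np.array([0.5 * s * (s - 1), 0.5 * s * (s + 1), 1 - s**2])
            dN = np.array([s - 0.5, s + 0.5, -2 * s])
        t = dN @ edge_xy  # (2,)
        L = np.hypot(t[0], t[1])
        normal = np.array([t[1], -t[0]]) / L
        r = N @ edge_xy[:, 0]
        out.append((N, r, normal, w * L))
    return out


def edge_normal_sign(elem_xy: np.ndarray, edge_xy: np.ndarray) -> float:
    """+1 if the (t_z, -t_r) edge normal points out of the element, else -1."""
    centroid = elem_xy[:4].mean(axis=0)
    mid = edge_xy.mean(axis=0)
    # normal at edge midpoint
    for N, r, normal, w in edge_quadrature(edge_xy)[1:2]:
        pass
    return 1.0 if float(np.dot(normal, mid - centroid)) >= 0.0 else -1.0
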