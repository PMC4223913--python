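"""Analytic oracles for the axisymmetric solid/acoustic/FSI core.

Every expected value here comes from an independent closed form: the 1-dof
oscillator transfer function, the Lame thick-walled-cylinder solution, the
clamped prestressed membrane frequency, rigid-cavity acoustic modes, and
the transcendental piston-on-fluid-column resonance condition.
"""

import numpy as np
import pytest
import scipy.optimize
import scipy.sparse as sp

import ocuvib as ov
from ocuvib import elements as el
from ocuvib import fem
from ocuvib.materials import FluidSpec, MaterialSpec
from ocuvib.mesh import build_mapped_block


def _single_dof_system(m, k, prony=(), load=1.0):
    """One structural node; the radial dof is fixed, leaving one axial dof."""
    dof = fem.DofMap(
        solid_nodes=np.array([0]),
        fluid_nodes=np.array([], dtype=int),
        s_of_node=np.array([0]),
        p_of_node=np.array([-1]),
    )
    mat = MaterialSpec(1.0, 0.3, 1.0, prony)
    from ocuvib.materials import complex_modulus

    K = sp.csr_matrix(np.diag([1.0, k]))
    M = sp.csr_matrix(np.diag([0.0, m]))
    return fem.HarmonicSystem(
        dof=dof,
        M=M,
        K_blocks=[(K, lambda f: complex_modulus(mat, f))],
        fixed=np.array([True, False]),
        load=np.array([0.0, load], dtype=complex),
    )


class TestSingleDof:
    def test_undamped_response_matches_closed_form_and_flips_sign(self):
        m, k = 2.0, 8.0e4  # omega_n = 200 rad/s
        system = _single_dof_system(m, k)
        for f in (10.0, 25.0, 50.0):
            om = 2 * np.pi * f
            sol = fem.solve_harmonic(system, f)
            u = sol.u[1]
            assert u.real == pytest.approx(1.0 / (k - m * om**2), rel=1e-12)
            assert abs(u.imag) < 1e-12 * abs(u.real)
        below = fem.solve_harmonic(system, 25.0).u[1].real
        above = fem.solve_harmonic(system, 50.0).u[1].real  # past 31.8 Hz resonance
        assert below > 0 > above

    def test_prony_damping_keeps_resonance_finite_with_phase_lag(self):
        m, k, T = 1.0, (2 * np.pi * 159.15) ** 2, 1e-3
        system = _single_dof_system(m, k, prony=((0.1, T),))
        f_res = 1.0 / (2 * np.pi * T)  # Omega*T = 1
        sol = fem.solve_harmonic(system, f_res)
        u = sol.u[1]
        assert np.isfinite(abs(u))
        lag = -np.angle(u)
        assert 0.0 < lag < np.pi

    def test_exactly_singular_undamped_solve_raises_solver_error(self):
        m, k = 1.0, (2 * np.pi * 100.0) ** 2
        system = _single_dof_system(m, k)
        with pytest.raises(fem.SolverError):
            fem.solve_harmonic(system, 100.0)


class TestSolidElementOracles:
    def test_patch_uniform_radial_stretch_energy(self):
        """Constant-strain patch: u_r = c*r, u_z = 0 on a square element away
        from the axis stores exactly the analytic strain-energy density."""
        r0, h, c = 5e-3, 1e-3, 1e-3
        xy = np.array([[r0, 0], [r0 + h, 0], [r0 + h, h], [r0, h]])
        E, nu = 1e4, 0.3
        lam = E * nu / ((1 + nu) * (1 - 2 * nu))
        mu = E / (2 * (1 + nu))
        K, _ = el.solid_matrices(xy, lam, mu, 1000.0)
        u = np.zeros(8)
        u[0::2] = c * xy[:, 0]
        # eps = [c, 0, c, 0]; W = 0.5 * eps : sigma, volume integral carries r
        eps = np.array([c, 0.0, c, 0.0])
        D = np.array(
            [
                [lam + 2 * mu, lam, lam, 0],
                [lam, lam + 2 * mu, lam, 0],
                [lam, lam, lam + 2 * mu, 0],
                [0, 0, 0, mu],
            ]
        )
        w_density = 0.5 * eps @ D @ eps
        volume = h * ((r0 + h) ** 2 - r0**2) / 2.0  # int r dr dz (2*pi dropped)
        assert 0.5 * u @ K @ u == pytest.approx(w_density * volume, rel=1e-12)

    def test_pressurised_cylinder_matches_lame_solution(self):
        """Thick-walled cylinder under internal pressure: radial displacement
        at the bore equals the plane-strain Lame closed form."""
        a, b, L, p = 4e-3, 8e-3, 2e-3, 1e3
        E, nu = 2e4, 0.3

        def xfun(u, v):
            return np.stack([a + (b - a) * u, L * v], axis=-1)

        mesh = build_mapped_block(xfun, 24, 4, order=8, region="wall")
        dof = fem.DofMap.build(mesh)
        mat = MaterialSpec(E, nu, 1000.0)
        M, K_blocks, _ = fem.assemble_solid(mesh, {"wall": mat}, dof)
        fixed = np.zeros(dof.n_total, dtype=bool)
        for name in ("v0", "v1"):  # plane strain: u_z = 0 on both faces
            nodes = np.unique(
                np.concatenate([mesh.edge_nodes(e, le) for e, le in mesh.edge_sets[name]])
            )
            fixed[2 * dof.s_of_node[nodes] + 1] = True
        load = fem.pressure_load(mesh, dof, mesh.edge_sets["u0"], p)
        system = fem.HarmonicSystem(dof=dof, M=M, K_blocks=K_blocks, fixed=fixed,
                                    load=load.astype(complex))
        u = fem.static_solve(system)
        bore = np.unique(
            np.concatenate([mesh.edge_nodes(e, le) for e, le in mesh.edge_sets["u0"]])
        )
        u_r = np.mean(u[2 * dof.s_of_node[bore]])
        # Lame, plane strain
        c2 = p * a**2 / (b**2 - a**2)
        u_exact = (1 + nu) / E * (c2 * ((1 - 2 * nu) * a + b**2 / a))
        assert u_r == pytest.approx(u_exact, rel=2e-3)

    def test_reciprocity_of_the_undamped_solid(self):
        """Response at dof j to a unit load at k equals the response at k to
        a unit load at j (symmetric real operator)."""
        cfg = ov.FlapConfig(prony=())
        model = ov.build_flap(cfg)
        system = model.system()
        free = system.free
        rng = np.random.default_rng(3)
        pairs = rng.choice(free.size, size=(3, 2), replace=False)
        f = 80.0
        for j, k in pairs:
            for a, b in ((j, k), (k, j)):
                load = np.zeros(system.dof.n_total, dtype=complex)
                load[free[a]] = 1.0
                system.load = load
                if (a, b) == (j, k):
                    u_jk = fem.solve_harmonic(system, f).u[free[b]]
                else:
                    u_kj = fem.solve_harmonic(system, f).u[free[b]]
            assert abs(u_jk - u_kj) <= 1e-10 * max(abs(u_jk), abs(u_kj))

    def test_uniform_tension_raises_flap_fundamental(self):
        f0 = _first_flap_peak(ov.FlapConfig(prestress_kpa=0.0))
        f1 = _first_flap_peak(ov.FlapConfig(prestress_kpa=0.67))
        assert f1 > f0

    def test_near_incompressible_formulation_does_not_lock(self):
        """At nu = 0.499 the (unstressed) bending frequency should only
        exceed the nu = 0.49 one by the analytic stiffness ratio, not blow
        up as a locking element would."""
        fa = _first_flap_peak(ov.FlapConfig(prestress_kpa=0.0, nu=0.499))
        fb = _first_flap_peak(ov.FlapConfig(prestress_kpa=0.0, nu=0.49))
        ratio_exact = np.sqrt((1 - 0.49**2) / (1 - 0.499**2))
        assert fa / fb == pytest.approx(ratio_exact, rel=0.05)

    def test_flap_frequency_converges_under_refinement(self):
        f1 = _first_flap_peak(ov.FlapConfig(refine=1))
        f2 = _first_flap_peak(ov.FlapConfig(refine=2))
        assert abs(f2 - f1) / f1 < 0.01

    def test_prestressed_membrane_matches_analytic_frequency(self):
        """Tension-dominated clamped disc: first resonance within 2% of
        (2.405 / 2 pi a) sqrt(sigma0 / rho) at sufficient refinement."""
        a, rho, sigma0 = 2e-3, 1160.0, 10.0  # kPa
        cfg = ov.FlapConfig(
            E_kpa=0.5, prestress_kpa=sigma0, nu=0.3, prony=((0.02, 1e-3),),
            refine=3,
        )
        f_exact = 2.405 / (2 * np.pi * a) * np.sqrt(sigma0 * 1e3 / rho)
        model = ov.build_flap(cfg)
        peaks = ov.resonance_frequencies(model, 0.7 * f_exact, 1.3 * f_exact, 4.0, 1.0)
        assert peaks, "no membrane resonance detected"
        assert peaks[0].frequency == pytest.approx(f_exact, rel=0.02)


def _first_flap_peak(cfg):
    model = ov.build_flap(cfg)
    peaks = ov.resonance_frequencies(model, 30.0, 750.0, 5.0, 1.0)
    assert peaks
    return peaks[0].frequency


class TestAcousticAndCoupling:
    def test_rigid_cylinder_first_axial_mode(self):
        L, R = 0.02, 0.01
        fluid = FluidSpec()

        def xfun(u, v):
            return np.stack([R * u, L * v], axis=-1)

        mesh = build_mapped_block(xfun, 6, 12, order=8, region="fluid")
        freqs = fem.acoustic_eigenfrequencies(mesh, fluid, n_modes=2)
        assert freqs[0] == pytest.approx(fluid.c / (2 * L), rel=0.02)

    def test_zero_radius_cavity_rejected(self):
        def xfun(u, v):
            return np.stack([0.0 * u, 0.02 * v], axis=-1)

        mesh = build_mapped_block(xfun, 2, 4, order=4, region="fluid")
        with pytest.raises(Exception):
            fem.assemble_fluid(mesh, FluidSpec(), fem.DofMap.build(mesh))

    def test_piston_on_open_fluid_column_matches_transcendental_oracle(self):
        """Rigid piston (m, k) over a pressure-release column: the coupled
        resonance solves k - w^2 m = rho c w A tan(wL/c); the added mass
        lowers the in-vacuo resonance."""
        R, L = 0.01, 0.05
        rho, c = 1000.0, 1480.0
        A_s = R**2 / 2.0  # surface integral of r ds (2*pi dropped throughout)
        m = rho * A_s * L  # piston as heavy as the column
        f_target = 300.0
        k = (2 * np.pi * f_target) ** 2 * (m + rho * A_s * L)

        def xfun(u, v):
            return np.stack([R * u, L * v], axis=-1)

        mesh = build_mapped_block(xfun, 6, 30, order=8, region="fluid")
        n_nodes = mesh.n_nodes
        dof = fem.DofMap(
            solid_nodes=np.array([n_nodes]),  # virtual piston node
            fluid_nodes=np.arange(n_nodes),
            s_of_node=np.concatenate([-np.ones(n_nodes, int), [0]]),
            p_of_node=np.concatenate([np.arange(n_nodes), [-1]]),
        )
        Kf, Mf = _fluid_matrices_with_custom_dof(mesh, FluidSpec(rho=rho, c=c), dof)
        # coupling: piston axial dof <- pressure shape integral over the top edge
        cvec = np.zeros(n_nodes)
        for e, le in mesh.edge_sets["v1"]:
            enodes = mesh.edge_nodes(e, le)
            edge_xy = mesh.nodes[enodes]
            for N, r, normal, w in el.edge_quadrature(edge_xy):
                cvec[enodes] += w * r * N  # n_f = +z at the top surface
        Rmat = sp.lil_matrix((2, n_nodes))
        Rmat[1, :] = cvec
        Rmat = Rmat.tocsr()
        fixed = np.zeros(2 + n_nodes, dtype=bool)
        fixed[0] = True  # piston slides axially only
        bottom = np.unique(
            np.concatenate([mesh.edge_nodes(e, le) for e, le in mesh.edge_sets["v0"]])
        )
        fixed[2 + dof.p_of_node[bottom]] = True  # pressure release
        load = np.zeros(2 + n_nodes, dtype=complex)
        load[1] = 1.0
        system = fem.HarmonicSystem(
            dof=dof,
            M=sp.csr_matrix(np.diag([0.0, m])),
            K_blocks=[(sp.csr_matrix(np.diag([1.0, k])), lambda f: 1.0 + 0.002j)],
            R=Rmat,
            Kf=Kf,
            Mf=Mf,
            rho_f=rho,
            fixed=fixed,
            load=load,
        )

        def character(omega):
            return k - omega**2 * m - rho * c * omega * A_s * np.tan(omega * L / c)

        w_exact = scipy.optimize.brentq(character, 2 * np.pi * 100, 2 * np.pi * 420)
        f_exact = w_exact / (2 * np.pi)
        grid = np.arange(0.8 * f_exact, 1.2 * f_exact, 1.0)
        amps = []
        for f in grid:
            sol = fem.solve_harmonic(system, float(f))
            amps.append(abs(sol.u[1]))
        f_num = grid[int(np.argmax(amps))]
        assert f_num == pytest.approx(f_exact, rel=0.02)
        f_vacuum = np.sqrt(k / m) / (2 * np.pi)
        assert f_num < f_vacuum  # added mass lowers the structural resonance


def _fluid_matrices_with_custom_dof(mesh, fluid, dof):
    nf = dof.n_fluid
    rows, cols, kv, mv = [], [], [], []
    for e in range(mesh.n_elements):
        xy = mesh.nodes[mesh.elements[e]]
        Ke, Me = el.fluid_matrices(xy, fluid.c)
        pd = dof.p_of_node[mesh.elements[e]]
        rows.append(np.repeat(pd, pd.size))
        cols.append(np.tile(pd, pd.size))
        kv.append(Ke.ravel())
        mv.append(Me.ravel())
    ij = (np.concatenate(rows), np.concatenate(cols))
    Kf = sp.csr_matrix((np.concatenate(kv), ij), shape=(nf, nf))
    Mf = sp.csr_matrix((np.concatenate(mv), ij), shape=(nf, nf))
    return Kf, Mf
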