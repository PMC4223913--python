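"""Flap and whole-globe eye models: geometry, boundary conditions, loads.

Two axisymmetric geometries are provided:

* a circular corneal **flap** (rectangular r-z cross-section) clamped at its
  rim and pre-tensioned by the mounting stress of the flap holder;
* a **whole eye globe** (cornea + limbus + sclera shell around an acoustic
  fluid representing the aqueous and vitreous humours), pre-stressed by the
  intraocular pressure, held by a scleral constraint ring at the back, and
  driven by a uniform harmonic sound pressure on the anterior cornea.

Configuration values use the clinical units of the source tables (mm, um,
kPa); everything is converted to strict SI when the mesh is built.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from . import fem
from .materials import ConfigurationError, FluidSpec, MaterialSpec
from .mesh import AxiMesh, build_mapped_block, merge_meshes

__all__ = [
    "FlapConfig",
    "GlobeConfig",
    "WeakZone",
    "EyeModel",
    "build_flap",
    "build_globe",
    "apply_weak_zone",
]

MM = 1e-3
UM = 1e-6
KPA = 1e3

DEFAULT_PRONY = ((0.1, 1e-3),)


@dataclass(frozen=True)
class FlapConfig:
    """Circular corneal flap clamped in a holder."""

    diameter_mm: float = 4.0
    thickness_um: float = 120.0
    E_kpa: float = 14.58
    prestress_kpa: float = 0.67
    density: float = 1160.0
    nu: float = 0.499
    prony: tuple[tuple[float, float], ...] = DEFAULT_PRONY
    n_radial: int = 27
    n_thickness: int = 2
    refine: int = 1
    drive_pressure_pa: float = 1.0

    def __post_init__(self):
        if self.diameter_mm <= 0 or self.thickness_um <= 0:
            raise ConfigurationError("flap diameter and thickness must be positive")
        if self.refine < 1:
            raise ConfigurationError("refine must be >= 1")

    def material(self) -> MaterialSpec:
        return MaterialSpec(self.E_kpa * KPA, self.nu, self.density, self.prony)


@dataclass(frozen=True)
class GlobeConfig:
    """Whole eye globe held at the posterior sclera."""

    central_thickness_um: float = 865.0
    anterior_curvature_mm: float = 6.8
    posterior_curvature_mm: float = 5.57
    corneal_diameter_mm: float = 10.40
    sclera_diameter_mm: float = 19.0
    sclera_thickness_mm: float = 1.0
    limbus_width_mm: float = 1.0
    E_anterior_kpa: float = 24.8
    E_posterior_kpa: float = 19.8
    # The printed parameter table lists a scleral stiffness of 79.2 kPa, but
    # the same study's scleral-elasticity variation calls 744 kPa "normal"
    # (74.4 low, rigid high) and every reported sensitivity (strong corneal-E
    # dependence, minor scleral deformation) is consistent only with the
    # stiff sclera; the table value appears to have lost a digit.  The
    # default is therefore 744; set 79.2 explicitly to reproduce the table.
    limbus_E_kpa: float = 37.2
    sclera_E_kpa: float = 744.0
    density: float = 1160.0
    nu: float = 0.499
    prony: tuple[tuple[float, float], ...] = DEFAULT_PRONY
    iop_kpa: float = 2.2
    # "equilibrated" (default): a homogeneous initial stress of magnitude
    # IOP is applied to all ocular tissues and relaxed to self-equilibrium
    # by a static solve; the small residual field feeds the geometric
    # stiffness.  A raw homogeneous stress is not an equilibrium state, and
    # carrying it unrelaxed ("uniform") tensions the cornea like a drum,
    # which contradicts the near-independence of the natural frequencies
    # from IOP.  "static": stress from a static solve under internal IOP
    # pressure (corneal membrane stress ~IOP*R/2t, several times larger).
    # "none": no prestress.
    prestress_mode: str = "equilibrated"
    # "base": the sound field shakes the mounted globe as a whole, so every
    # node is driven at the imposed frequency (consistent inertial load on
    # tissue and humour).  "pressure": uniform harmonic pressure on the
    # anterior cornea only.  Both are spatially smooth and symmetric; the
    # base drive also couples to modes whose anterior-surface pressure
    # coupling is weak.
    drive_mode: str = "base"
    fluid_density: float = 1000.0
    fluid_sonic_velocity: float = 1480.0
    fluid_viscosity: float = 8.94e-4
    fsi_range_mm: float = 2.8
    holder_arc_mm: float = 5.0
    holder_width_mm: float = 1.0
    n_cornea: int = 40
    n_limbus: int = 6
    n_sclera: int = 91
    n_thickness: int = 2
    n_fluid_rings: int = 9
    drive_pressure_pa: float = 1.0

    def __post_init__(self):
        if not self.posterior_curvature_mm < self.anterior_curvature_mm:
            raise ConfigurationError("posterior curvature radius must be < anterior")
        if not self.corneal_diameter_mm < self.sclera_diameter_mm:
            raise ConfigurationError("corneal diameter must be < sclera diameter")
        if self.iop_kpa < 0:
            raise ConfigurationError("IOP must be non-negative")
        if self.corneal_diameter_mm / 2.0 >= self.anterior_curvature_mm:
            raise ConfigurationError("corneal cap does not meet the limbus (diameter too large)")

    def materials(self) -> dict[str, MaterialSpec]:
        return {
            "cornea-anterior": MaterialSpec(self.E_anterior_kpa * KPA, self.nu, self.density, self.prony),
            "cornea-posterior": MaterialSpec(self.E_posterior_kpa * KPA, self.nu, self.density, self.prony),
            "limbus": MaterialSpec(self.limbus_E_kpa * KPA, self.nu, self.density, self.prony),
            "sclera": MaterialSpec(self.sclera_E_kpa * KPA, self.nu, self.density, self.prony),
        }

    def fluid(self) -> FluidSpec:
        return FluidSpec(
            rho=self.fluid_density,
            c=self.fluid_sonic_velocity,
            mu=self.fluid_viscosity,
            fsi_range=self.fsi_range_mm * MM,
        )


@dataclass(frozen=True)
class WeakZone:
    """Angular zone of reduced corneal elasticity (keratoconus idealisation).

    Angles are measured from the scleral equator (0 deg) to the corneal apex
    (90 deg) about the scleral sphere centre.
    """

    theta1_deg: float
    theta2_deg: float
    reduced_E_kpa: float

    def __post_init__(self):
        if not 0.0 <= self.theta1_deg < self.theta2_deg <= 90.0:
            raise ConfigurationError("weak zone must satisfy 0 <= theta1 < theta2 <= 90")
        if self.reduced_E_kpa <= 0:
            raise ConfigurationError("reduced modulus must be positive")


@dataclass
class EyeModel:
    """A meshed, constrained and loaded model ready for harmonic solves."""

    kind: str
    config: object
    mesh: AxiMesh
    materials: dict[str, MaterialSpec]
    fluid: FluidSpec | None
    e_scale: np.ndarray
    fixed: np.ndarray
    load: np.ndarray
    prestress: fem.PrestressState | None
    probe_node: int
    arc_nodes: np.ndarray
    dof: fem.DofMap
    static_displacement: np.ndarray | None = None
    _system: fem.HarmonicSystem | None = field(default=None, repr=False)
    _preassembled: tuple | None = field(default=None, repr=False)

    def system(self) -> fem.HarmonicSystem:
        if self._system is None:
            if self._preassembled is not None:
                M, K_blocks = self._preassembled
            else:
                M, K_blocks, _ = fem.assemble_solid(
                    self.mesh, self.materials, self.dof, self.e_scale
                )
            Kg = fem.assemble_geometric_stiffness(self.mesh, self.prestress, self.dof)
            kwargs = {}
            if self.fluid is not None and self.dof.n_fluid:
                Kf, Mf, R = _fluid_operators_cached(self.mesh, self.fluid, self.dof)
                kwargs = dict(Kf=Kf, Mf=Mf, R=R, rho_f=self.fluid.rho)
            load = self.load
            load_omega2 = None
            if getattr(self.config, "drive_mode", "pressure") == "base":
                # rigid base motion along z with unit amplitude: consistent
                # inertial forcing of both tissue and humour
                ub = np.zeros(self.dof.n_solid)
                ub[1::2] = 1.0
                parts = [M @ ub]
                if "R" in kwargs:
                    parts.append(kwargs["rho_f"] * (kwargs["R"].T @ ub))
                else:
                    parts.append(np.zeros(self.dof.n_fluid))
                load_omega2 = np.concatenate(parts).astype(complex)
                load = np.zeros_like(self.load)
            self._system = fem.HarmonicSystem(
                dof=self.dof, M=M, K_blocks=K_blocks, Kg=Kg,
                fixed=self.fixed, load=load, load_omega2=load_omega2, **kwargs,
            )
        return self._system

    def solve(self, f: float) -> fem.HarmonicSolution:
        return fem.solve_harmonic(self.system(), f)

    def without_fluid(self) -> "EyeModel":
        """In-vacuo copy (fluid removed; same solid, constraints, load)."""
        clone = dataclasses.replace(self, fluid=None, _system=None)
        return clone

    def solid_elements_of(self, *regions: str) -> np.ndarray:
        return self.mesh.elements_in(*regions)


# acoustic operators depend only on the mesh geometry and fluid properties,
# not on tissue moduli, so they are shared across the rebuilds an elasticity
# fit performs; keyed by the node/element arrays and the fluid spec
_FLUID_CACHE: dict = {}


def _fluid_operators_cached(mesh: AxiMesh, fluid: FluidSpec, dof: fem.DofMap):
    import hashlib

    h = hashlib.sha1()
    h.update(mesh.nodes.tobytes())
    h.update(mesh.elements.tobytes())
    key = (h.hexdigest(), fluid)
    if key not in _FLUID_CACHE:
        if len(_FLUID_CACHE) > 8:
            _FLUID_CACHE.clear()
        Kf, Mf = fem.assemble_fluid(mesh, fluid, dof)
        R = fem.assemble_coupling(mesh, dof)
        _FLUID_CACHE[key] = (Kf, Mf, R)
    return _FLUID_CACHE[key]


# ----------------------------------------------------------------- flap ----


def build_flap(cfg: FlapConfig) -> EyeModel:
    """Rectangular r-z cross-section of the circular flap, clamped at the rim,
    uniform in-plane mounting prestress, unit pressure drive on one face."""
    a = cfg.diameter_mm * MM / 2.0
    h = cfg.thickness_um * UM
    nr = cfg.n_radial * cfg.refine
    nz = cfg.n_thickness * cfg.refine

    def xfun(u, v):
        return np.stack([a * u, h * v], axis=-1)

    mesh = build_mapped_block(xfun, nr, nz, order=4, region="cornea")
    dof = fem.DofMap.build(mesh)

    fixed = np.zeros(dof.n_total, dtype=bool)
    rim = np.unique(np.concatenate([mesh.edge_nodes(e, le) for e, le in mesh.edge_sets["u1"]]))
    fixed[dof.sdofs(rim)] = True
    axis = np.flatnonzero(np.abs(mesh.nodes[:, 0]) < 1e-12)
    fixed[2 * dof.s_of_node[axis]] = True  # u_r = 0 on the symmetry axis

    load = fem.pressure_load(mesh, dof, mesh.edge_sets["v1"], cfg.drive_pressure_pa).astype(complex)

    sigma0 = cfg.prestress_kpa * KPA
    if sigma0 != 0.0:
        prestress = fem.PrestressState.uniform(
            mesh, range(mesh.n_elements), np.array([sigma0, 0.0, sigma0, 0.0])
        )
    else:
        prestress = fem.PrestressState({})

    top = np.unique(np.concatenate([mesh.edge_nodes(e, le) for e, le in mesh.edge_sets["v1"]]))
    top = top[np.argsort(mesh.nodes[top, 0])]
    probe = int(top[0])

    return EyeModel(
        kind="flap", config=cfg, mesh=mesh, materials={"cornea": cfg.material()},
        fluid=None, e_scale=np.ones(mesh.n_elements), fixed=fixed, load=load,
        prestress=prestress, probe_node=probe, arc_nodes=top, dof=dof,
    )


# ---------------------------------------------------------------- globe ----


def _globe_curves(cfg: GlobeConfig):
    """Sample the anterior and posterior tissue surfaces at every lattice
    station of the half-globe shell, from the corneal apex (station 0) to
    the scleral equator."""
    Rs = cfg.sclera_diameter_mm * MM / 2.0
    ts = cfg.sclera_thickness_mm * MM
    Ra = cfg.anterior_curvature_mm * MM
    Rp = cfg.posterior_curvature_mm * MM
    tc = cfg.central_thickness_um * UM
    r_lim = cfg.corneal_diameter_mm * MM / 2.0
    wl = cfg.limbus_width_mm * MM

    z_int = np.sqrt(Rs**2 - r_lim**2)  # corneal edge on the scleral sphere
    z_ca = z_int - np.sqrt(Ra**2 - r_lim**2)  # anterior corneal sphere centre
    delta = Ra - tc - Rp  # posterior centre offset above the anterior centre
    if Rp**2 <= delta**2:
        raise ConfigurationError("posterior corneal sphere never meets the anterior cap")

    alpha_c = float(np.arccos(np.clip(-z_int / Rs, -1, 1)))  # polar angle of the limbus end
    dalpha = wl / Rs
    alpha_l0 = alpha_c - dalpha
    if alpha_l0 <= 0:
        raise ConfigurationError("limbus wider than the available scleral arc")
    phi_edge = float(np.arcsin(r_lim / Ra))

    def scl(alpha):
        return np.stack([Rs * np.sin(alpha), -Rs * np.cos(alpha)], axis=-1)

    def scl_in(alpha):
        return np.stack([(Rs - ts) * np.sin(alpha), -(Rs - ts) * np.cos(alpha)], axis=-1)

    def cor_a(phi):
        return np.stack([Ra * np.sin(phi), z_ca + Ra * np.cos(phi)], axis=-1)

    def cor_p(phi):
        a = delta * np.cos(phi) + np.sqrt(Rp**2 - (delta * np.sin(phi)) ** 2)
        return np.stack([a * np.sin(phi), z_ca + a * np.cos(phi)], axis=-1)

    if alpha_l0 <= np.pi / 2:
        raise ConfigurationError("limbus reaches below the scleral equator")

    n_s, n_l, n_c = cfg.n_sclera, cfg.n_limbus, cfg.n_cornea
    alpha_s = np.linspace(np.pi / 2, alpha_l0, 2 * n_s + 1)  # equator -> limbus
    s_l = np.linspace(0.0, 1.0, 2 * n_l + 1)
    alpha_l = alpha_l0 + s_l * dalpha
    phi_c = np.linspace(phi_edge, 0.0, 2 * n_c + 1)

    A = np.vstack([scl(alpha_s), scl(alpha_l[1:]), cor_a(phi_c[1:])])
    P_edge = cor_p(np.array([phi_edge]))[0]
    P_lim = (1 - s_l)[:, None] * scl_in(alpha_l) + s_l[:, None] * P_edge[None, :]
    P = np.vstack([scl_in(alpha_s), P_lim[1:], cor_p(phi_c[1:])])
    # clip round-off at the apex / equator stations
    A[np.abs(A[:, 0]) < 1e-15, 0] = 0.0
    P[np.abs(P[:, 0]) < 1e-15, 0] = 0.0
    A[np.abs(A[:, 1]) < 1e-15, 1] = 0.0
    P[np.abs(P[:, 1]) < 1e-15, 1] = 0.0
    # order stations apex -> equator so the (u, v) block mapping is
    # positively oriented (v runs posterior -> anterior through the shell)
    A, P = A[::-1].copy(), P[::-1].copy()

    regions_per_column = ["cornea"] * n_c + ["limbus"] * n_l + ["sclera"] * n_s
    geo = {
        "Rs": Rs, "Ra": Ra, "z_ca": z_ca, "alpha_c": alpha_c,
        "alpha_l0": alpha_l0, "phi_edge": phi_edge,
    }
    return A, P, regions_per_column, geo


def build_globe(cfg: GlobeConfig, e_scale: np.ndarray | None = None) -> EyeModel:
    """Half-globe eye model (scleral equator to corneal apex).

    8-node shell of cornea / limbus / sclera around an acoustic fluid fan
    filling the anterior half of the humour cavity.  The equatorial
    cross-section of the sclera is fixed (the mounted posterior half is not
    modelled) and the fluid is pressure-released on the cut plane, which
    stands in for the compliance of the unmodelled posterior humour.  A
    1 mm holder ring on the outer sclera at a lateral distance of 5 mm from
    the apex (immediately behind the limbus, where the holder cup grips the
    globe) is constrained.  IOP prestress follows ``cfg.prestress_mode``;
    the harmonic drive is a uniform sound pressure on the anterior cornea.
    """
    A, P, col_regions, geo = _globe_curves(cfg)
    n_cols = len(col_regions)
    nv = cfg.n_thickness

    def shell_fun(u, v):
        i = np.rint(u * (len(A) - 1)).astype(int)
        return (1 - v)[..., None] * P[i] + v[..., None] * A[i]

    regions = []
    for iu in range(n_cols):
        for iv in range(nv):
            base = col_regions[iu]
            if base == "cornea":
                regions.append("cornea-posterior" if iv < nv / 2 else "cornea-anterior")
            else:
                regions.append(base)
    shell = build_mapped_block(shell_fun, n_cols, nv, order=8, region=regions)
    shell.fsi_edges = list(shell.edge_sets["v0"])  # wetted interior surface

    def fluid_fun(u, v):
        i = np.rint(u * (len(P) - 1)).astype(int)
        return v[..., None] * P[i]

    fan = build_mapped_block(
        fluid_fun, n_cols, cfg.n_fluid_rings, order=8, region="fluid", collapse_v0=True
    )
    mesh = merge_meshes(shell, fan)
    dof = fem.DofMap.build(mesh)

    # filter FSI edges by the coupling range (all wetted edges touch tissue,
    # so the range only matters if configured to something unphysically small)
    if cfg.fsi_range_mm * MM <= 0:
        mesh.fsi_edges = []

    fixed = np.zeros(dof.n_total, dtype=bool)
    Rs = geo["Rs"]
    radii = np.linalg.norm(mesh.nodes, axis=1)
    on_outer_sclera = np.abs(radii - Rs) < 1e-9
    half_w = cfg.holder_width_mm * MM / 2.0
    holder = np.flatnonzero(
        on_outer_sclera
        & (np.abs(mesh.nodes[:, 0] - cfg.holder_arc_mm * MM) <= half_w)
    )
    if holder.size == 0:
        raise ConfigurationError("holder ring selects no nodes")
    fixed[dof.sdofs(holder)] = True
    # equatorial cut: the scleral cross-section at z = 0 is clamped
    cut = dof.solid_nodes[np.abs(mesh.nodes[dof.solid_nodes, 1]) < 1e-12]
    fixed[dof.sdofs(cut)] = True
    # pressure release on the cut plane of the fluid
    open_fluid = dof.fluid_nodes[np.abs(mesh.nodes[dof.fluid_nodes, 1]) < 1e-12]
    fixed[dof.n_solid + dof.p_of_node[open_fluid]] = True
    axis_nodes = dof.solid_nodes[np.abs(mesh.nodes[dof.solid_nodes, 0]) < 1e-12]
    fixed[2 * dof.s_of_node[axis_nodes]] = True

    drive_edges = [(e, le) for e, le in mesh.edge_sets["v1"]
                   if str(mesh.region[e]).startswith("cornea")]
    load = fem.pressure_load(mesh, dof, drive_edges, cfg.drive_pressure_pa).astype(complex)

    materials = cfg.materials()
    if e_scale is None:
        e_scale = np.ones(mesh.n_elements)
    if cfg.drive_mode not in ("base", "pressure"):
        raise ConfigurationError(f"unknown drive_mode {cfg.drive_mode!r}")

    # IOP prestress
    iop = cfg.iop_kpa * KPA
    static_u = None
    preassembled = None
    solid_elems = np.flatnonzero(mesh.region != "fluid")
    if iop <= 0 or cfg.prestress_mode == "none":
        prestress = fem.PrestressState({})
    elif cfg.prestress_mode in ("uniform", "equilibrated"):
        # homogeneously distributed initial stress equivalent to the IOP in
        # all ocular tissues (isotropic tension of magnitude IOP)
        prestress = fem.PrestressState.uniform(
            mesh, solid_elems, np.array([iop, iop, iop, 0.0])
        )
        if cfg.prestress_mode == "equilibrated":
            # a homogeneous stress is not self-equilibrated; relax it by a
            # static solve and keep the residual stress field
            M, K_blocks, _ = fem.assemble_solid(mesh, materials, dof, e_scale)
            preassembled = (M, K_blocks)
            sys0 = fem.HarmonicSystem(dof=dof, M=M, K_blocks=K_blocks, fixed=fixed)
            f_int = fem.initial_stress_forces(mesh, prestress, dof)
            static_u = fem.static_solve(sys0, -f_int.astype(complex))
            relax = fem.stress_field(mesh, materials, dof, static_u, e_scale)
            prestress = fem.PrestressState(
                {e: prestress.stresses[e] + relax.stresses[e] for e in relax.stresses}
            )
    elif cfg.prestress_mode == "static":
        M, K_blocks, _ = fem.assemble_solid(mesh, materials, dof, e_scale)
        preassembled = (M, K_blocks)
        sys0 = fem.HarmonicSystem(dof=dof, M=M, K_blocks=K_blocks, fixed=fixed)
        f_iop = fem.pressure_load(mesh, dof, mesh.fsi_edges, iop)
        static_u = fem.static_solve(sys0, f_iop.astype(complex))
        prestress = fem.stress_field(mesh, materials, dof, static_u, e_scale)
    else:
        raise ConfigurationError(f"unknown prestress_mode {cfg.prestress_mode!r}")

    # probe and anterior corneal arc (ordered from the apex outwards)
    z_ca, Ra = geo["z_ca"], geo["Ra"]
    on_ant_cornea = np.abs(np.linalg.norm(mesh.nodes - np.array([0.0, z_ca]), axis=1) - Ra) < 1e-9
    on_ant_cornea &= mesh.nodes[:, 1] > -geo["Rs"] * np.cos(geo["alpha_c"]) + 1e-12
    arc_nodes = np.flatnonzero(on_ant_cornea & (dof.s_of_node >= 0))
    arc_nodes = arc_nodes[np.argsort(mesh.nodes[arc_nodes, 0])]
    probe = int(arc_nodes[0])

    model = EyeModel(
        kind="globe", config=cfg, mesh=mesh, materials=materials,
        fluid=cfg.fluid(), e_scale=e_scale, fixed=fixed, load=load,
        prestress=prestress, probe_node=probe, arc_nodes=arc_nodes, dof=dof,
        static_displacement=static_u, _preassembled=preassembled,
    )
    return model


def corneal_centroid_angles(model: EyeModel) -> tuple[np.ndarray, np.ndarray]:
    """(element indices, angles in degrees) of corneal elements; 0 deg at the
    scleral equator, 90 deg at the apex, about the scleral sphere centre."""
    elems = model.mesh.elements_in("cornea-anterior", "cornea-posterior")
    cent = model.mesh.element_centroids()[elems]
    theta = np.degrees(np.arctan2(cent[:, 1], cent[:, 0]))
    return elems, theta


def apply_weak_zone(model: EyeModel, zone: WeakZone) -> EyeModel:
    """Return a rebuilt globe model with corneal elements whose centroid angle
    lies inside the zone set to the reduced modulus (all else untouched)."""
    if model.kind != "globe":
        raise ConfigurationError("weak zones apply to globe models")
    cfg: GlobeConfig = model.config
    elems, theta = corneal_centroid_angles(model)
    sel = elems[(theta >= zone.theta1_deg) & (theta <= zone.theta2_deg)]
    if sel.size == 0:
        raise ConfigurationError(
            f"weak zone ({zone.theta1_deg}, {zone.theta2_deg}) deg misses the cornea"
        )
    e_scale = model.e_scale.copy()
    for e in sel:
        nominal = (
            cfg.E_posterior_kpa
            if model.mesh.region[e] == "cornea-posterior"
            else cfg.E_anterior_kpa
        )
        e_scale[e] = zone.reduced_E_kpa / nominal
    return build_globe(cfg, e_scale=e_scale)
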