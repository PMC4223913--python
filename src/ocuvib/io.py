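"""Interchange I/O: Gmsh mesh export, solution-field CSV, YAML configs.

Config files mirror the model parameter tables: a ``kind: flap`` or
``kind: globe`` key selects the model and the remaining keys map onto the
corresponding config dataclass fields (clinical units: mm, um, kPa).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import yaml

from .materials import ConfigurationError
from .mesh import AxiMesh
from .models import FlapConfig, GlobeConfig

__all__ = ["export_gmsh", "solution_to_csv", "load_config", "save_config"]

_REGION_IDS = {
    "cornea": 1,
    "cornea-anterior": 1,
    "cornea-posterior": 2,
    "limbus": 3,
    "sclera": 4,
    "fluid": 5,
}
# Gmsh MSH 2.2 element types: 3 = 4-node quad, 16 = 8-node quad
_GMSH_TYPE = {4: 3, 8: 16}


def export_gmsh(mesh: AxiMesh, path) -> None:
    """Write the mesh in Gmsh ASCII 2.2 format (x = r, y = z, z = 0), with
    region labels as physical tags, for inspection in standard viewers."""
    lines = ["$MeshFormat", "2.2 0 8", "$EndMeshFormat"]
    lines.append("$Nodes")
    lines.append(str(mesh.n_nodes))
    for i, (r, z) in enumerate(mesh.nodes, start=1):
        lines.append(f"{i} {r:.12g} {z:.12g} 0")
    lines.append("$EndNodes")
    lines.append("$Elements")
    lines.append(str(mesh.n_elements))
    etype = _GMSH_TYPE[mesh.order]
    for e in range(mesh.n_elements):
        tag = _REGION_IDS.get(str(mesh.region[e]), 99)
        conn = " ".join(str(n + 1) for n in mesh.elements[e])
        lines.append(f"{e + 1} {etype} 2 {tag} {tag} {conn}")
    lines.append("$EndElements")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def solution_to_csv(mesh: AxiMesh, dof, u: np.ndarray, path) -> None:
    """Displacement field as CSV: node id, r, z, Re/Im of u_r and u_z."""
    rows = []
    for node in dof.solid_nodes:
        s = dof.s_of_node[node]
        ur, uz = u[2 * s], u[2 * s + 1]
        r, z = mesh.nodes[node]
        rows.append(
            {
                "node": int(node), "r_m": r, "z_m": z,
                "re_u_r": np.real(ur), "im_u_r": np.imag(ur),
                "re_u_z": np.real(uz), "im_u_z": np.imag(uz),
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def load_config(path):
    """YAML -> FlapConfig or GlobeConfig (``kind`` key or field inference)."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    kind = data.pop("kind", None)
    if kind is None:
        kind = "globe" if "anterior_curvature_mm" in data or "iop_kpa" in data else "flap"
    cls = {"flap": FlapConfig, "globe": GlobeConfig}.get(kind)
    if cls is None:
        raise ConfigurationError(f"unknown model kind {kind!r}")
    if "prony" in data:
        data["prony"] = tuple(tuple(term) for term in data["prony"])
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ConfigurationError(f"unknown config keys for {kind}: {sorted(unknown)}")
    return cls(**data)


def save_config(cfg, path) -> None:
    data = dataclasses.asdict(cfg)
    data["kind"] = "flap" if isinstance(cfg, FlapConfig) else "globe"
    data["prony"] = [list(t) for t in cfg.prony]
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
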