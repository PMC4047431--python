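"""Parametric axisymmetric iris geometry and meshing.

The iris cross-section is idealized as an annular plate of configurable
thickness between the pupil margin (inner radius) and the iris root (outer
radius), optionally bowed out of plane and tapered to a sharp tip at the
pupil margin.  Coordinates are (r, y): r is the radial distance from the
optical axis and y the axial coordinate, positive pointing posteriorly, so
a pressure differential applied to the anterior surface drives positive
displacements.  Units are mm throughout.

The crystalline lens is represented by an analytical rigid spherical cap
posterior to the iris; its axial position at load level ``dp`` is the
reference position plus the prescribed (pressure-linear) translation.

The mesh is a structured quad grid (4-node axisymmetric quadrilaterals)
with optional 3-node triangles forming the tapered tip fan.  Refining with
``density`` multiplies both grid directions, quadrupling the quad count
while leaving the boundary geometry unchanged.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

__all__ = ["GeometryConfig", "LensSurface", "AxisymMesh",
           "build_reference_geometry", "GeometryError"]


class GeometryError(ValueError):
    """Raised for degenerate or inconsistent geometry configuration."""


@dataclass(frozen=True)
class GeometryConfig:
    """Geometry and discretization of the idealized iris model (mm).

    Defaults are configurable stand-ins for a rabbit eye: 12-mm iris
    diameter at the root, 4-mm pupil, 0.4-mm thickness, a ~6-mm-radius
    anterior lens surface with a small axial clearance at the pupil margin.
    """

    root_radius: float = 6.0
    pupil_radius: float = 2.0
    thickness: float = 0.4
    bow: float = 0.0            # anterior bow amplitude of the midsurface
    taper_tip: bool = False     # collapse the pupil margin to a sharp tip
    lens_radius: float = 6.0
    lens_gap: float = 0.1       # clearance iris posterior -> lens at pupil margin
    n_radial: int = 20
    n_thickness: int = 3
    density: int = 1

    def __post_init__(self):
        if not (0 < self.pupil_radius < self.root_radius):
            raise GeometryError("require 0 < pupil_radius < root_radius")
        if self.thickness <= 0:
            raise GeometryError("thickness must be > 0")
        if self.density < 1 or self.n_radial < 2 or self.n_thickness < 1:
            raise GeometryError("mesh density/counts must be >= 1")
        if self.lens_radius <= self.pupil_radius:
            raise GeometryError("lens radius must exceed pupil radius")

    @classmethod
    def from_dict(cls, d: dict) -> "GeometryConfig":
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "GeometryConfig":
        path = Path(path)
        text = path.read_text()
        d = yaml.safe_load(text) if path.suffix in (".yml", ".yaml") else json.loads(text)
        return cls.from_dict(d)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class LensSurface:
    """Rigid spherical cap: center (0, center_y), radius (mm).

    The anterior lens surface seen by the iris is the -y side of the
    sphere; a point penetrates when it enters the sphere.
    """

    center_y: float
    radius: float

    def gap(self, points: np.ndarray, translation: float = 0.0) -> np.ndarray:
        """Signed distance of points (n, 2) to the translated sphere
        (positive outside, negative = penetration)."""
        c = np.array([0.0, self.center_y + translation])
        return np.linalg.norm(points - c, axis=1) - self.radius

    def normal(self, points: np.ndarray, translation: float = 0.0) -> np.ndarray:
        """Outward unit normal (from sphere center to point), (n, 2)."""
        c = np.array([0.0, self.center_y + translation])
        d = points - c
        return d / np.linalg.norm(d, axis=1, keepdims=True)


@dataclass
class AxisymMesh:
    """Axisymmetric node/element description with tagged boundary sets.

    nodes: (n, 2) reference coordinates (r, y); quads: (nq, 4) positively
    oriented connectivity; tris: (nt, 3); node_sets maps the named sets
    root_edge / anterior_surface / posterior_surface / pupil_margin /
    surface_all to node index arrays; anterior_edges lists the ordered
    pressure-loaded edge segments; lens_surface is the rigid lens cap.
    """

    nodes: np.ndarray
    quads: np.ndarray
    tris: np.ndarray
    node_sets: dict[str, np.ndarray]
    anterior_edges: np.ndarray
    lens_surface: LensSurface | None = None
    config: GeometryConfig | None = None

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def validate(self) -> None:
        if np.any(self.nodes[:, 0] < -1e-12):
            raise GeometryError("negative radius in mesh")
        for name, idx in self.node_sets.items():
            if len(idx) and (idx.min() < 0 or idx.max() >= self.n_nodes):
                raise GeometryError(f"node set {name} references missing nodes")
        if np.intersect1d(self.node_sets["anterior_surface"],
                          self.node_sets["posterior_surface"]).size:
            raise GeometryError("anterior and posterior surfaces overlap")
        if np.any(self._areas_quads() <= 0) or np.any(self._areas_tris() <= 0):
            raise GeometryError("non-positively-oriented element")

    def _areas_quads(self) -> np.ndarray:
        if not len(self.quads):
            return np.zeros(0)
        p = self.nodes[self.quads]          # (nq, 4, 2)
        a = 0.0
        for k in range(4):
            q = p[:, k], p[:, (k + 1) % 4]
            a = a + q[0][:, 0] * q[1][:, 1] - q[1][:, 0] * q[0][:, 1]
        return 0.5 * a

    def _areas_tris(self) -> np.ndarray:
        if not len(self.tris):
            return np.zeros(0)
        p = self.nodes[self.tris]
        v1, v2 = p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]
        return 0.5 * (v1[:, 0] * v2[:, 1] - v1[:, 1] * v2[:, 0])

    # ---------------- I/O ----------------

    def to_json(self) -> str:
        obj = {
            "nodes": self.nodes.tolist(),
            "quads": self.quads.tolist(),
            "tris": self.tris.tolist(),
            "node_sets": {k: v.tolist() for k, v in self.node_sets.items()},
            "anterior_edges": self.anterior_edges.tolist(),
        }
        if self.lens_surface is not None:
            obj["lens_surface"] = {"center_y": self.lens_surface.center_y,
                                   "radius": self.lens_surface.radius}
        if self.config is not None:
            obj["config"] = self.config.to_dict()
        return json.dumps(obj)

    @classmethod
    def from_json(cls, text: str) -> "AxisymMesh":
        obj = json.loads(text)
        lens = obj.get("lens_surface")
        cfg = obj.get("config")
        m = cls(
            nodes=np.asarray(obj["nodes"], dtype=float),
            quads=np.asarray(obj["quads"], dtype=int).reshape(-1, 4),
            tris=np.asarray(obj["tris"], dtype=int).reshape(-1, 3),
            node_sets={k: np.asarray(v, dtype=int)
                       for k, v in obj["node_sets"].items()},
            anterior_edges=np.asarray(obj["anterior_edges"], dtype=int).reshape(-1, 2),
            lens_surface=LensSurface(**lens) if lens else None,
            config=GeometryConfig.from_dict(cfg) if cfg else None,
        )
        m.validate()
        return m

    def export_inp(self, params=None) -> str:
        """Minimal Abaqus INP dialect (CAX4RH/CAX3, optional Ogden card)
        so the model can be cross-checked in a commercial solver."""
        lines = ["*NODE"]
        for i, (r, y) in enumerate(self.nodes, start=1):
            lines.append(f"{i}, {r:.9g}, {y:.9g}")
        if len(self.quads):
            lines.append("*ELEMENT, TYPE=CAX4RH, ELSET=IRIS_Q")
            for e, c in enumerate(self.quads, start=1):
                lines.append(f"{e}, " + ", ".join(str(n + 1) for n in c))
        if len(self.tris):
            lines.append("*ELEMENT, TYPE=CAX3, ELSET=IRIS_T")
            for e, c in enumerate(self.tris, start=1 + len(self.quads)):
                lines.append(f"{e}, " + ", ".join(str(n + 1) for n in c))
        if params is not None:
            lines.append(f"*HYPERELASTIC, OGDEN, N={params.order}")
            row = []
            for mu, al, D in zip(params.mu, params.alpha, params.D):
                row += [mu, al, D]
            lines.append(", ".join(f"{v:.9g}" for v in row))
        return "\n".join(lines) + "\n"

    def export_vtk(self, displacements: np.ndarray | None = None) -> str:
        """Legacy ASCII VTK (unstructured grid) of the reference mesh,
        optionally carrying a nodal displacement vector field."""
        out = ["# vtk DataFile Version 3.0", "irisid axisymmetric mesh",
               "ASCII", "DATASET UNSTRUCTURED_GRID",
               f"POINTS {self.n_nodes} float"]
        for r, y in self.nodes:
            out.append(f"{r:.9g} {y:.9g} 0.0")
        ncell = len(self.quads) + len(self.tris)
        size = 5 * len(self.quads) + 4 * len(self.tris)
        out.append(f"CELLS {ncell} {size}")
        for c in self.quads:
            out.append("4 " + " ".join(map(str, c)))
        for c in self.tris:
            out.append("3 " + " ".join(map(str, c)))
        out.append(f"CELL_TYPES {ncell}")
        out += ["9"] * len(self.quads) + ["5"] * len(self.tris)
        if displacements is not None:
            out.append(f"POINT_DATA {self.n_nodes}")
            out.append("VECTORS displacement float")
            for ur, uy in displacements:
                out.append(f"{ur:.9g} {uy:.9g} 0.0")
        return "\n".join(out) + "\n"


def build_reference_geometry(config: GeometryConfig | dict | None = None) -> AxisymMesh:
    """Mesh the idealized iris annulus per the geometry config.

    Structured quad grid over radius x thickness; if ``taper_tip`` the
    innermost column collapses to a single tip node and becomes a triangle
    fan (the only place 3-node elements appear).
    """
    if config is None:
        config = GeometryConfig()
    elif isinstance(config, dict):
        config = GeometryConfig.from_dict(config)

    nr = config.n_radial * config.density
    nt = config.n_thickness * config.density
    rp, rr, t = config.pupil_radius, config.root_radius, config.thickness

    r = np.linspace(rp, rr, nr + 1)
    xi = (r - rp) / (rr - rp)
    # quadratic anterior bow of the midsurface, clamped flat at the root
    y_mid = -config.bow * (1.0 - xi) ** 2
    eta = np.linspace(-0.5, 0.5, nt + 1)

    grid = np.empty((nr + 1, nt + 1), dtype=int)
    nodes = []
    for i in range(nr + 1):
        for j in range(nt + 1):
            grid[i, j] = len(nodes)
            nodes.append((r[i], y_mid[i] + eta[j] * t))
    nodes = np.asarray(nodes)

    quads, tris = [], []
    i0 = 0
    tip = None
    if config.taper_tip:
        # collapse column 0 to a midsurface tip node
        tip = len(nodes)
        nodes = np.vstack([nodes, [rp, y_mid[0]]])
        for j in range(nt):
            # fan oriented so the (r, y) area is positive
            tris.append((tip, grid[1, j], grid[1, j + 1]))
        i0 = 1
    for i in range(i0, nr):
        for j in range(nt):
            quads.append((grid[i, j], grid[i + 1, j],
                          grid[i + 1, j + 1], grid[i, j + 1]))

    used = np.unique(np.concatenate(
        [np.asarray(quads, dtype=int).ravel(),
         np.asarray(tris, dtype=int).ravel() if tris else np.zeros(0, dtype=int)]))
    # with a collapsed tip, column-0 grid nodes are orphaned; re-index
    remap = -np.ones(len(nodes), dtype=int)
    remap[used] = np.arange(len(used))
    nodes = nodes[used]
    quads = remap[np.asarray(quads, dtype=int).reshape(-1, 4)]
    tris = (remap[np.asarray(tris, dtype=int).reshape(-1, 3)]
            if tris else np.zeros((0, 3), dtype=int))

    def live(ids):
        ids = np.asarray(ids, dtype=int)
        return np.sort(remap[ids[remap[ids] >= 0]])

    root = live(grid[nr, :])
    if config.taper_tip:
        anterior = live(grid[1:, 0])
        posterior = live(grid[1:, nt])
        margin = np.array([remap[tip]])
        ant_chain = np.concatenate([margin, live_ordered(remap, grid[1:, 0])])
    else:
        anterior = live(grid[:, 0])
        posterior = live(grid[:, nt])
        margin = live(grid[0, :])
        ant_chain = live_ordered(remap, grid[:, 0])
    edges = np.column_stack([ant_chain[:-1], ant_chain[1:]])

    surface_all = np.unique(np.concatenate([anterior, posterior, margin]))
    sets = {"root_edge": root, "anterior_surface": anterior,
            "posterior_surface": posterior, "pupil_margin": margin,
            "surface_all": surface_all}

    lens_y = (t / 2.0 + config.lens_gap
              + np.sqrt(config.lens_radius**2 - rp**2))
    mesh = AxisymMesh(nodes=nodes, quads=quads, tris=tris, node_sets=sets,
                      anterior_edges=edges,
                      lens_surface=LensSurface(center_y=lens_y,
                                               radius=config.lens_radius),
                      config=config)
    mesh.validate()
    return mesh


def live_ordered(remap: np.ndarray, ids: np.ndarray) -> np.ndarray:
    """Remap a node-id chain preserving order (helper for edge chains)."""
    ids = np.asarray(ids, dtype=int)
    out = remap[ids]
    return out[out >= 0]
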