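"""Labeled epicardial surface meshes and activation-time maps.

The geometric substrate for all activation analysis is a triangulated
biventricular epicardial surface in which every triangle carries a chamber
label (LV or RV).  Electrical data live on top of it as one activation time
per vertex, measured in milliseconds from QRS onset (earliest ventricular
activation).  A triangle's activation time is defined as the arithmetic mean
of its three vertex times, which gives every surface element a well-defined
area weight in the cumulative activation curves computed downstream.

Two on-disk dialects are supported, both plain text:

* a CSV pair — ``vertices.csv`` with columns ``id,x,y,z`` and
  ``triangles.csv`` with columns ``id,v1,v2,v3,label``;
* ASCII PLY with a per-face integer ``chamber`` property (0 = LV, 1 = RV).

Units are fixed: millimetres for coordinates, milliseconds for times.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

logger = logging.getLogger(__name__)

LV = "LV"
RV = "RV"
CHAMBERS = (LV, RV)

#: integer codes used in the PLY dialect
_PLY_LABEL_CODE = {LV: 0, RV: 1}
_PLY_CODE_LABEL = {v: k for k, v in _PLY_LABEL_CODE.items()}


class MeshFormatError(ValueError):
    """A mesh file is syntactically malformed or lacks chamber labels."""


class MeshValidationError(ValueError):
    """Mesh contents violate a structural invariant."""


class MapValidationError(ValueError):
    """Activation-map contents violate an invariant."""


class PacingSetting(str, Enum):
    """The five pacing configurations mapped in the study protocol.

    ``INTRINSIC`` is the native (atrial-only paced) rhythm; ``RVP`` and
    ``LVP`` pace a single ventricle; ``BIVP`` paces both simultaneously and
    ``BIVP_LV30`` paces both with the LV stimulated 30 ms before the RV.
    """

    INTRINSIC = "INTRINSIC"
    RVP = "RVP"
    LVP = "LVP"
    BIVP = "BIVP"
    BIVP_LV30 = "BIVP_LV30"

    @property
    def lv_offset_ms(self) -> float:
        """How much earlier the LV site fires than the RV site (ms)."""
        return 30.0 if self is PacingSetting.BIVP_LV30 else 0.0


PACED_SETTINGS = (
    PacingSetting.RVP,
    PacingSetting.LVP,
    PacingSetting.BIVP,
    PacingSetting.BIVP_LV30,
)


@dataclass(frozen=True, eq=False)
class TriSurfaceMesh:
    """A labeled biventricular epicardial triangle mesh.

    Parameters
    ----------
    vertices : (n_vertices, 3) float array
        Vertex coordinates in mm.
    triangles : (n_triangles, 3) int array
        Vertex-index triples.
    chamber_label : (n_triangles,) array of ``"LV"`` / ``"RV"``
        Per-triangle chamber tag.

    The constructor validates all structural invariants: index bounds,
    strictly positive triangle areas, presence of both chamber labels, and
    connectedness of the vertex-edge graph (the wavefront simulator requires
    a single connected component).
    """

    vertices: np.ndarray
    triangles: np.ndarray
    chamber_label: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "vertices", np.asarray(self.vertices, dtype=float))
        object.__setattr__(self, "triangles", np.asarray(self.triangles, dtype=np.int64))
        object.__setattr__(self, "chamber_label", np.asarray(self.chamber_label, dtype=object))
        self._validate()

    # -- invariants ------------------------------------------------------
    def _validate(self) -> None:
        v, t, lab = self.vertices, self.triangles, self.chamber_label
        if v.ndim != 2 or v.shape[1] != 3:
            raise MeshValidationError(f"vertices must be (n, 3), got {v.shape}")
        if t.ndim != 2 or t.shape[1] != 3:
            raise MeshValidationError(f"triangles must be (m, 3), got {t.shape}")
        if lab.shape != (t.shape[0],):
            raise MeshFormatError(
                f"chamber_label must have one entry per triangle "
                f"({t.shape[0]}), got {lab.shape}"
            )
        if t.size and (t.min() < 0 or t.max() >= len(v)):
            bad = t[(t < 0) | (t >= len(v))][0]
            raise MeshValidationError(
                f"triangle references vertex index {bad} outside [0, {len(v)})"
            )
        unknown = set(lab) - set(CHAMBERS)
        if unknown:
            raise MeshFormatError(f"unknown chamber labels: {sorted(map(str, unknown))}")
        for ch in CHAMBERS:
            if not np.any(lab == ch):
                raise MeshValidationError(f"no triangle labeled {ch}")
        areas = triangle_areas(self, _validate=False)
        if np.any(areas <= 0):
            idx = int(np.flatnonzero(areas <= 0)[0])
            raise MeshValidationError(f"triangle {idx} is degenerate (zero area)")
        n_comp, membership = connected_components(self.vertex_adjacency(), directed=False)
        if n_comp != 1:
            sizes = np.bincount(membership)
            raise MeshValidationError(
                f"mesh edge-graph has {n_comp} connected components "
                f"(sizes {sizes.tolist()}); the smallest starts at vertex "
                f"{int(np.flatnonzero(membership == np.argmin(sizes))[0])}"
            )

    # -- derived geometry ------------------------------------------------
    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)

    def edges(self) -> np.ndarray:
        """Unique undirected edges as an (n_edges, 2) sorted-index array."""
        e = np.concatenate(
            [self.triangles[:, [0, 1]], self.triangles[:, [1, 2]], self.triangles[:, [2, 0]]]
        )
        e = np.sort(e, axis=1)
        return np.unique(e, axis=0)

    def vertex_adjacency(self):
        """Sparse symmetric vertex adjacency matrix (unweighted)."""
        e = self.edges()
        n = self.n_vertices
        data = np.ones(len(e))
        m = coo_matrix((data, (e[:, 0], e[:, 1])), shape=(n, n))
        return (m + m.T).tocsr()

    def triangle_mask(self, scope: str) -> np.ndarray:
        """Boolean mask of triangles belonging to ``scope`` ∈ {LV, RV, BIV}."""
        if scope == "BIV":
            return np.ones(self.n_triangles, dtype=bool)
        if scope not in CHAMBERS:
            raise ValueError(f"scope must be LV, RV or BIV, got {scope!r}")
        return self.chamber_label == scope


def triangle_areas(mesh: TriSurfaceMesh, *, _validate: bool = True) -> np.ndarray:
    """Per-triangle areas in mm², half the magnitude of the edge cross product.

    Raises :class:`MeshValidationError` if any triangle is degenerate.
    """
    v = mesh.vertices
    t = mesh.triangles
    a = v[t[:, 1]] - v[t[:, 0]]
    b = v[t[:, 2]] - v[t[:, 0]]
    areas = 0.5 * np.linalg.norm(np.cross(a, b), axis=1)
    if _validate and np.any(areas <= 0):
        idx = int(np.flatnonzero(areas <= 0)[0])
        raise MeshValidationError(f"triangle {idx} is degenerate (zero area)")
    return areas


@dataclass(frozen=True, eq=False)
class ActivationMap:
    """Per-vertex activation times for one patient × pacing setting.

    Times are in ms from QRS onset: every map is referenced so its earliest
    vertex activates at t = 0.  Construct with ``strict=False`` (default) to
    auto-shift a map whose minimum is nonzero; ``strict=True`` raises instead.
    """

    mesh: TriSurfaceMesh
    vertex_time: np.ndarray
    setting: PacingSetting = PacingSetting.INTRINSIC
    strict: bool = field(default=False, compare=False, repr=False)

    def __post_init__(self) -> None:
        times = np.asarray(self.vertex_time, dtype=float)
        if times.shape != (self.mesh.n_vertices,):
            raise MapValidationError(
                f"expected {self.mesh.n_vertices} vertex times, got {times.shape}"
            )
        if not np.all(np.isfinite(times)):
            raise MapValidationError("activation times must be finite")
        if np.any(times < 0):
            raise MapValidationError("activation times must be non-negative")
        tmin = times.min()
        if tmin != 0.0:
            if self.strict:
                raise MapValidationError(
                    f"earliest activation is {tmin} ms, not 0 (strict mode)"
                )
            logger.warning("re-referencing activation map: shifting by -%g ms", tmin)
            times = times - tmin
        object.__setattr__(self, "vertex_time", times)
        object.__setattr__(self, "setting", PacingSetting(self.setting))

    def triangle_times(self) -> np.ndarray:
        """Activation time per triangle: mean of its three vertex times."""
        return self.vertex_time[self.mesh.triangles].mean(axis=1)


# ---------------------------------------------------------------------------
# mesh I/O
# ---------------------------------------------------------------------------

def write_mesh(mesh: TriSurfaceMesh, path: str | Path, fmt: str = "csv-pair") -> None:
    """Write a labeled mesh as a CSV pair or ASCII PLY.

    For ``csv-pair``, ``path`` is a directory that will contain
    ``vertices.csv`` and ``triangles.csv``.  For ``ply``, ``path`` is the
    PLY file.  Coordinates are written with 17 significant digits so that an
    ASCII round-trip is bit-exact.
    """
    path = Path(path)
    if fmt == "csv-pair":
        path.mkdir(parents=True, exist_ok=True)
        vdf = pd.DataFrame(mesh.vertices, columns=["x", "y", "z"])
        vdf.insert(0, "id", np.arange(mesh.n_vertices))
        vdf.to_csv(path / "vertices.csv", index=False, float_format="%.17g")
        tdf = pd.DataFrame(mesh.triangles, columns=["v1", "v2", "v3"])
        tdf.insert(0, "id", np.arange(mesh.n_triangles))
        tdf["label"] = mesh.chamber_label
        tdf.to_csv(path / "triangles.csv", index=False)
    elif fmt == "ply":
        with open(path, "w") as fh:
            fh.write("ply\nformat ascii 1.0\ncomment crtsync labeled epicardial mesh\n")
            fh.write(f"element vertex {mesh.n_vertices}\n")
            fh.write("property double x\nproperty double y\nproperty double z\n")
            fh.write(f"element face {mesh.n_triangles}\n")
            fh.write("property list uchar int vertex_indices\n")
            fh.write("property int chamber\n")
            fh.write("end_header\n")
            for x, y, z in mesh.vertices:
                fh.write(f"{x:.17g} {y:.17g} {z:.17g}\n")
            for (a, b, c), lab in zip(mesh.triangles, mesh.chamber_label):
                fh.write(f"3 {a} {b} {c} {_PLY_LABEL_CODE[lab]}\n")
    else:
        raise ValueError(f"unknown mesh format {fmt!r} (use 'csv-pair' or 'ply')")


def load_mesh(path: str | Path, fmt: str | None = None) -> TriSurfaceMesh:
    """Load and validate a labeled mesh from a CSV pair or ASCII PLY.

    ``fmt`` is inferred from the path when omitted: a directory means
    ``csv-pair``, a ``.ply`` suffix means ``ply``.
    """
    path = Path(path)
    if fmt is None:
        fmt = "csv-pair" if path.is_dir() else "ply"
    if fmt == "csv-pair":
        vfile, tfile = path / "vertices.csv", path / "triangles.csv"
        if not vfile.exists() or not tfile.exists():
            raise MeshFormatError(f"CSV pair not found under {path}")
        vdf = pd.read_csv(vfile, float_precision="round_trip")
        tdf = pd.read_csv(tfile)
        for col in ("x", "y", "z"):
            if col not in vdf.columns:
                raise MeshFormatError(f"vertices.csv lacks column {col!r}")
        if "label" not in tdf.columns:
            raise MeshFormatError("triangles.csv lacks the 'label' column")
        vdf = vdf.sort_values("id") if "id" in vdf.columns else vdf
        tdf = tdf.sort_values("id") if "id" in tdf.columns else tdf
        return TriSurfaceMesh(
            vertices=vdf[["x", "y", "z"]].to_numpy(float),
            triangles=tdf[["v1", "v2", "v3"]].to_numpy(np.int64),
            chamber_label=tdf["label"].to_numpy(object),
        )
    if fmt == "ply":
        return _read_labeled_ply(path)
    raise ValueError(f"unknown mesh format {fmt!r} (use 'csv-pair' or 'ply')")


def _read_labeled_ply(path: Path) -> TriSurfaceMesh:
    # Minimal ASCII PLY reader for this package's dialect: per-face integer
    # chamber property.  General-purpose mesh libraries drop custom face
    # scalars on round-trip, so the dialect is parsed directly.
    with open(path) as fh:
        line = fh.readline().strip()
        if line != "ply":
            raise MeshFormatError(f"{path} is not a PLY file")
        n_vert = n_face = None
        elements: list[tuple[str, int]] = []
        face_props: list[str] = []
        current = None
        while True:
            line = fh.readline()
            if not line:
                raise MeshFormatError("unexpected EOF in PLY header")
            parts = line.split()
            if not parts or parts[0] == "comment":
                continue
            if parts[0] == "format":
                if parts[1] != "ascii":
                    raise MeshFormatError("only ASCII PLY is supported")
            elif parts[0] == "element":
                current = parts[1]
                elements.append((parts[1], int(parts[2])))
                if parts[1] == "vertex":
                    n_vert = int(parts[2])
                elif parts[1] == "face":
                    n_face = int(parts[2])
            elif parts[0] == "property" and current == "face":
                face_props.append(parts[-1])
            elif parts[0] == "end_header":
                break
        if n_vert is None or n_face is None:
            raise MeshFormatError("PLY lacks vertex or face element")
        if "chamber" not in face_props:
            raise MeshFormatError("PLY face element lacks the 'chamber' label property")
        verts = np.empty((n_vert, 3))
        for i in range(n_vert):
            verts[i] = [float(tok) for tok in fh.readline().split()[:3]]
        tris = np.empty((n_face, 3), dtype=np.int64)
        labels = np.empty(n_face, dtype=object)
        for i in range(n_face):
            toks = fh.readline().split()
            if int(toks[0]) != 3:
                raise MeshFormatError(f"face {i} is not a triangle")
            tris[i] = [int(t) for t in toks[1:4]]
            code = int(toks[4])
            if code not in _PLY_CODE_LABEL:
                raise MeshFormatError(f"face {i} has unknown chamber code {code}")
            labels[i] = _PLY_CODE_LABEL[code]
    return TriSurfaceMesh(vertices=verts, triangles=tris, chamber_label=labels)


# ---------------------------------------------------------------------------
# activation-map I/O
# ---------------------------------------------------------------------------

def write_activation_map(amap: ActivationMap, path: str | Path) -> None:
    """Write an activation map as CSV with header ``vertex_id,time_ms``."""
    df = pd.DataFrame(
        {"vertex_id": np.arange(len(amap.vertex_time)), "time_ms": amap.vertex_time}
    )
    df.to_csv(path, index=False, float_format="%.17g")


def load_activation_map(
    path: str | Path,
    mesh: TriSurfaceMesh,
    setting: PacingSetting = PacingSetting.INTRINSIC,
    strict: bool = False,
) -> ActivationMap:
    """Load an activation map CSV and bind it to ``mesh``.

    Raises :class:`MapValidationError` when the row count does not match the
    mesh vertex count or any time is negative.  In the default (auto-shift)
    mode a map whose minimum time is nonzero is re-referenced to 0 with a
    logged warning; ``strict=True`` raises instead.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    if not {"vertex_id", "time_ms"} <= set(df.columns):
        raise MapValidationError("activation map CSV needs columns vertex_id,time_ms")
    if len(df) != mesh.n_vertices:
        raise MapValidationError(
            f"map has {len(df)} rows but mesh has {mesh.n_vertices} vertices"
        )
    df = df.sort_values("vertex_id")
    return ActivationMap(
        mesh=mesh,
        vertex_time=df["time_ms"].to_numpy(float),
        setting=setting,
        strict=strict,
    )
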