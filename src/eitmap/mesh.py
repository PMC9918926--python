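"""Triangular FEM meshes of a 2D torso cross-section with boundary electrodes.

The domain is a simply connected region (by default a superellipse shaped
like an adult pelvis cross-section) triangulated with piecewise-linear
elements.  Electrodes are contiguous runs of boundary edges placed on the
*front* (lower) arc of the boundary, matching a wearable sensor strip worn
on one side of the abdomen.

Units are meters throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely
from scipy.spatial import Delaunay
from shapely.geometry import Polygon

from ._errors import ConfigurationError, MeshParseError, ResolutionError, ValidationError

__all__ = [
    "SuperellipseOutline",
    "TorsoMesh",
    "build_torso_mesh",
    "default_torso_outline",
    "save_mesh",
    "load_mesh",
]


class SuperellipseOutline:
    """Superellipse |x/a|^p + |y/b|^p = 1 centered at the origin.

    Parameters
    ----------
    a, b : float
        Half-axes in meters (left-right, front-back).
    p : float
        Exponent; p=2 is an ellipse, larger p is boxier (torso-like).
    """

    def __init__(self, a: float, b: float, p: float = 2.5):
        if a <= 0 or b <= 0 or p < 1:
            raise ConfigurationError("superellipse requires a, b > 0 and p >= 1")
        self.a, self.b, self.p = float(a), float(b), float(p)

    def boundary_polygon(self, edge_length: float) -> np.ndarray:
        """Sample the outline CCW at arc spacing close to ``edge_length``."""
        # Oversample, measure arc length, then resample uniformly.
        t = np.linspace(0.0, 2 * np.pi, 4096, endpoint=False)
        pts = self._point(t)
        seg = np.linalg.norm(np.diff(np.vstack([pts, pts[:1]]), axis=0), axis=1)
        s = np.concatenate([[0.0], np.cumsum(seg)])
        perim = s[-1]
        k = max(8, int(round(perim / edge_length)))
        target = np.linspace(0.0, perim, k, endpoint=False)
        t_ext = np.concatenate([t, [2 * np.pi]])
        tt = np.interp(target, s, t_ext)
        return self._point(tt)

    def _point(self, t: np.ndarray) -> np.ndarray:
        ct, st = np.cos(t), np.sin(t)
        x = self.a * np.sign(ct) * np.abs(ct) ** (2.0 / self.p)
        y = self.b * np.sign(st) * np.abs(st) ** (2.0 / self.p)
        return np.column_stack([x, y])

    @property
    def diameter(self) -> float:
        return 2.0 * max(self.a, self.b)


def default_torso_outline() -> SuperellipseOutline:
    """Default pelvis-level torso cross-section: 0.15 m x 0.10 m superellipse."""
    return SuperellipseOutline(0.15, 0.10, 2.5)


@dataclass
class TorsoMesh:
    """Conforming triangulation of the torso cross-section.

    Attributes
    ----------
    nodes : (V, 2) float array
        Node coordinates in meters.
    elements : (E, 3) int array
        CCW node-index triples (0-based).
    boundary_edges : (B, 2) int array
        Boundary edges ordered along the CCW boundary walk.
    electrodes : list of list of int
        Per electrode, the indices into ``boundary_edges`` it occupies;
        each run is contiguous along the walk and runs are disjoint.
    """

    nodes: np.ndarray
    elements: np.ndarray
    boundary_edges: np.ndarray
    electrodes: list = field(default_factory=list)

    def __post_init__(self):
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.elements = np.asarray(self.elements, dtype=np.int64)
        self.boundary_edges = np.asarray(self.boundary_edges, dtype=np.int64).reshape(-1, 2)

    # -- derived geometry ---------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    @property
    def element_areas(self) -> np.ndarray:
        p = self.nodes[self.elements]
        return 0.5 * np.abs(_cross2(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]))

    @property
    def element_centroids(self) -> np.ndarray:
        return self.nodes[self.elements].mean(axis=1)

    def electrode_edge_nodes(self, k: int) -> np.ndarray:
        """Node pairs of electrode k's boundary edges."""
        return self.boundary_edges[np.asarray(self.electrodes[k], dtype=int)]

    def edge_lengths(self, edges: np.ndarray) -> np.ndarray:
        d = self.nodes[edges[:, 1]] - self.nodes[edges[:, 0]]
        return np.linalg.norm(d, axis=1)

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        """Check structural invariants; raise ValidationError on violation."""
        if self.elements.min(initial=0) < 0 or self.elements.max(initial=-1) >= self.n_nodes:
            raise ValidationError("element references a node index out of range")
        p = self.nodes[self.elements]
        signed = 0.5 * _cross2(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
        if np.any(signed <= 0):
            raise ValidationError("element with non-positive signed area (orientation)")
        # Edge census / Euler characteristic of an open planar disk: V - E + F = 1.
        edges = _all_edges(self.elements)
        n_edges = len(np.unique(edges, axis=0))
        if self.n_nodes - n_edges + self.n_elements != 1:
            raise ValidationError("mesh is not a triangulated disk (Euler census failed)")
        boundary = _boundary_edge_set(self.elements)
        declared = {tuple(sorted(e)) for e in self.boundary_edges}
        if declared != boundary:
            raise ValidationError("declared boundary edges do not match the edge census")
        seen = set()
        for k, idxs in enumerate(self.electrodes):
            for i in idxs:
                if not 0 <= i < len(self.boundary_edges):
                    raise ValidationError(f"electrode {k} references a missing boundary edge")
                if i in seen:
                    raise ValidationError(f"electrode {k} overlaps another electrode")
                seen.add(i)

    def min_angle_deg(self) -> float:
        p = self.nodes[self.elements]
        angles = []
        for i in range(3):
            u = p[:, (i + 1) % 3] - p[:, i]
            v = p[:, (i + 2) % 3] - p[:, i]
            c = (u * v).sum(1) / (np.linalg.norm(u, axis=1) * np.linalg.norm(v, axis=1))
            angles.append(np.degrees(np.arccos(np.clip(c, -1, 1))))
        return float(np.min(angles))


def _cross2(u, v):
    return u[..., 0] * v[..., 1] - u[..., 1] * v[..., 0]


def _all_edges(elements: np.ndarray) -> np.ndarray:
    e = np.concatenate([elements[:, [0, 1]], elements[:, [1, 2]], elements[:, [2, 0]]])
    return np.sort(e, axis=1)


def _boundary_edge_set(elements: np.ndarray) -> set:
    edges, counts = np.unique(_all_edges(elements), axis=0, return_counts=True)
    return {tuple(e) for e in edges[counts == 1]}


# ---------------------------------------------------------------------------
# Mesh construction


def build_torso_mesh(
    outline=None,
    electrode_count: int = 8,
    electrode_arc_fraction: float = 0.5,
    target_edge_length: float = 0.02,
    min_angle_deg: float = 20.0,
    front_fraction: float = 0.5,
    smoothing_iterations: int = 4,
) -> TorsoMesh:
    """Triangulate the torso outline and attach boundary electrodes.

    Parameters
    ----------
    outline : SuperellipseOutline or (k, 2) array, optional
        Domain boundary; a closed CCW polygon or a parametric superellipse.
        Defaults to the 0.15 m x 0.10 m torso cross-section.
    electrode_count : int
        Number of electrodes placed on the front (lowest-y) boundary arc.
    electrode_arc_fraction : float
        Fraction of the front arc covered by electrodes in total.
    target_edge_length : float
        Requested mesh edge length in meters; controls element count.
    min_angle_deg : float
        Reject the mesh if any triangle angle falls below this bound.
    front_fraction : float
        Fraction of the boundary perimeter counted as the front arc,
        centered (by arc length) at the lowest boundary point.

    Notes
    -----
    Interior nodes start on a hexagonal lattice and are relaxed by a few
    Laplacian smoothing passes; triangulation is Delaunay.  This gives
    near-equilateral elements away from the boundary.
    """
    if outline is None:
        outline = default_torso_outline()
    if electrode_count < 2:
        raise ConfigurationError("need at least 2 electrodes")
    if not 0 < electrode_arc_fraction < 1:
        raise ConfigurationError("electrode_arc_fraction must lie in (0, 1)")
    h = float(target_edge_length)
    if h <= 0:
        raise ConfigurationError("target_edge_length must be positive")
    if isinstance(outline, SuperellipseOutline):
        if h >= outline.diameter:
            raise ConfigurationError("target_edge_length exceeds the outline diameter")
        boundary = outline.boundary_polygon(h)
    else:
        boundary = _resample_polygon(np.asarray(outline, dtype=float), h)
    if _polygon_area(boundary) < 0:
        boundary = boundary[::-1]

    poly = Polygon(boundary)
    interior = _hex_lattice(boundary, h)
    if len(interior):
        shrunk = poly.buffer(-0.55 * h)
        keep = shapely.contains_xy(shrunk, interior[:, 0], interior[:, 1])
        interior = interior[keep]

    pts = np.vstack([boundary, interior]) if len(interior) else boundary.copy()
    n_fixed = len(boundary)
    for _ in range(smoothing_iterations if len(interior) else 0):
        tri = _delaunay_inside(pts, poly)
        pts = _smooth_interior(pts, tri, n_fixed)
    elements = _delaunay_inside(pts, poly)
    if len(elements) < 1:
        raise ResolutionError("triangulation produced no elements at this edge length")

    elements = _orient_ccw(pts, elements)
    mesh = TorsoMesh(pts, elements, _ordered_boundary(pts, elements))
    mesh.electrodes = _place_electrodes(
        mesh, electrode_count, electrode_arc_fraction, front_fraction
    )
    mesh.validate()
    q = mesh.min_angle_deg()
    if q < min_angle_deg:
        raise ResolutionError(
            f"mesh quality too low: min angle {q:.1f} deg < {min_angle_deg} deg; "
            "adjust target_edge_length"
        )
    return mesh


def _resample_polygon(verts: np.ndarray, h: float) -> np.ndarray:
    if np.allclose(verts[0], verts[-1]):
        verts = verts[:-1]
    out = []
    k = len(verts)
    for i in range(k):
        a, b = verts[i], verts[(i + 1) % k]
        n = max(1, int(round(np.linalg.norm(b - a) / h)))
        for j in range(n):
            out.append(a + (b - a) * (j / n))
    return np.asarray(out)


def _polygon_area(verts: np.ndarray) -> float:
    x, y = verts[:, 0], verts[:, 1]
    return 0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def _hex_lattice(boundary: np.ndarray, h: float) -> np.ndarray:
    xmin, ymin = boundary.min(axis=0)
    xmax, ymax = boundary.max(axis=0)
    dy = h * np.sqrt(3) / 2
    rows = np.arange(ymin + 0.5 * dy, ymax, dy)
    pts = []
    for r, y in enumerate(rows):
        x0 = xmin + (0.25 if r % 2 else 0.75) * h
        xs = np.arange(x0, xmax, h)
        pts.append(np.column_stack([xs, np.full_like(xs, y)]))
    return np.vstack(pts) if pts else np.empty((0, 2))


def _delaunay_inside(pts: np.ndarray, poly: Polygon) -> np.ndarray:
    tri = Delaunay(pts)
    cells = tri.simplices
    cent = pts[cells].mean(axis=1)
    keep = shapely.contains_xy(poly, cent[:, 0], cent[:, 1])
    # Guard against sliver cells along a curved boundary.
    p = pts[cells]
    area = 0.5 * np.abs(_cross2(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]))
    keep &= area > 1e-12 * poly.area
    return cells[keep]


def _smooth_interior(pts: np.ndarray, elements: np.ndarray, n_fixed: int) -> np.ndarray:
    new = pts.copy()
    acc = np.zeros_like(pts)
    cnt = np.zeros(len(pts))
    for i in range(3):
        a = elements[:, i]
        b = elements[:, (i + 1) % 3]
        np.add.at(acc, a, pts[b])
        np.add.at(acc, b, pts[a])
        np.add.at(cnt, a, 1)
        np.add.at(cnt, b, 1)
    movable = np.arange(len(pts)) >= n_fixed
    ok = movable & (cnt > 0)
    new[ok] = acc[ok] / cnt[ok, None]
    return new


def _orient_ccw(pts: np.ndarray, elements: np.ndarray) -> np.ndarray:
    p = pts[elements]
    signed = _cross2(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
    flip = signed < 0
    out = elements.copy()
    out[flip] = out[flip][:, [0, 2, 1]]
    return out


def _ordered_boundary(pts: np.ndarray, elements: np.ndarray) -> np.ndarray:
    bset = _boundary_edge_set(elements)
    succ = {}
    # Orient boundary edges CCW: a boundary edge of a CCW triangle appears
    # in element order (i -> j); collect directed versions.
    for tri in elements:
        for i in range(3):
            a, b = int(tri[i]), int(tri[(i + 1) % 3])
            if tuple(sorted((a, b))) in bset:
                succ[a] = b
    start = min(succ)
    walk = [start]
    nxt = succ[start]
    while nxt != start:
        walk.append(nxt)
        nxt = succ[nxt]
    return np.array([[walk[i], walk[(i + 1) % len(walk)]] for i in range(len(walk))])


def _place_electrodes(mesh: TorsoMesh, count: int, arc_fraction: float, front_fraction: float):
    edges = mesh.boundary_edges
    lengths = mesh.edge_lengths(edges)
    centers = 0.5 * (mesh.nodes[edges[:, 0]] + mesh.nodes[edges[:, 1]])
    s_end = np.cumsum(lengths)
    s_mid = s_end - 0.5 * lengths
    perim = s_end[-1]
    # Front arc: centered by arc length at the lowest boundary node.
    walk_nodes = edges[:, 0]
    ys = mesh.nodes[walk_nodes, 1]
    low = int(np.argmin(ys))
    s_low = s_end[low] - lengths[low] if low > 0 else 0.0
    front_len = front_fraction * perim
    front_start = s_low - front_len / 2

    pitch = front_len / count
    width = arc_fraction * pitch
    groups = []
    used = set()
    for k in range(count):
        c = front_start + (k + 0.5) * pitch
        lo, hi = c - width / 2, c + width / 2
        rel = (s_mid - front_start) % perim + front_start  # unwrap around the seam
        inside = (rel >= lo) & (rel <= hi)
        idxs = sorted(np.nonzero(inside)[0].tolist(), key=lambda i: (rel[i]))
        if not idxs:
            idxs = [int(np.argmin(np.abs(((s_mid - c + perim / 2) % perim) - perim / 2)))]
        if used & set(idxs):
            raise ConfigurationError(
                "electrodes overlap: reduce electrode_arc_fraction or electrode_count"
            )
        used |= set(idxs)
        groups.append(idxs)
    _ = centers  # centers retained for debugging/plots
    return groups


# ---------------------------------------------------------------------------
# Serialization

_MAGIC = "eitmap-mesh 1"


def save_mesh(mesh: TorsoMesh, path, dialect: str = "native") -> None:
    """Write a mesh to disk.

    ``native`` is a single sectioned text file; ``triangle`` writes the
    Triangle-style ``.node``/``.ele`` pair (1-based) plus a ``.electrode``
    sidecar carrying boundary-edge node pairs per electrode.
    """
    if dialect == "native":
        _save_native(mesh, path)
    elif dialect == "triangle":
        _save_triangle(mesh, path)
    else:
        raise ConfigurationError(f"unknown mesh dialect {dialect!r}")


def load_mesh(path, dialect: str = "native") -> TorsoMesh:
    if dialect == "native":
        mesh = _load_native(path)
    elif dialect == "triangle":
        mesh = _load_triangle(path)
    else:
        raise ConfigurationError(f"unknown mesh dialect {dialect!r}")
    mesh.validate()
    return mesh


def _save_native(mesh: TorsoMesh, path) -> None:
    with open(path, "w") as f:
        f.write(_MAGIC + "\n")
        f.write(f"nodes {mesh.n_nodes}\n")
        for x, y in mesh.nodes:
            f.write(f"{float(x)!r} {float(y)!r}\n")
        f.write(f"elements {mesh.n_elements}\n")
        for i, j, k in mesh.elements:
            f.write(f"{i} {j} {k}\n")
        f.write(f"boundary_edges {len(mesh.boundary_edges)}\n")
        for i, j in mesh.boundary_edges:
            f.write(f"{i} {j}\n")
        f.write(f"electrodes {len(mesh.electrodes)}\n")
        for idxs in mesh.electrodes:
            f.write(" ".join(str(int(i)) for i in idxs) + "\n")


def _load_native(path) -> TorsoMesh:
    with open(path) as f:
        lines = f.read().splitlines()
    ln = 0

    def expect(prefix):
        nonlocal ln
        if ln >= len(lines):
            raise MeshParseError(path, ln + 1, f"unexpected end of file, wanted {prefix!r}")
        parts = lines[ln].split()
        if not parts or parts[0] != prefix:
            raise MeshParseError(path, ln + 1, f"expected section {prefix!r}")
        ln += 1
        return int(parts[1]) if len(parts) > 1 else 0

    if lines[ln].strip() != _MAGIC:
        raise MeshParseError(path, 1, "not an eitmap mesh file")
    ln += 1
    n = expect("nodes")
    try:
        nodes = np.array(
            [[float(v) for v in lines[ln + i].split()] for i in range(n)], dtype=float
        ).reshape(n, 2)
    except (ValueError, IndexError) as exc:
        raise MeshParseError(path, ln + 1, f"bad node record: {exc}") from exc
    ln += n
    e = expect("elements")
    try:
        elements = np.array(
            [[int(v) for v in lines[ln + i].split()] for i in range(e)], dtype=np.int64
        ).reshape(e, 3)
    except (ValueError, IndexError) as exc:
        raise MeshParseError(path, ln + 1, f"bad element record: {exc}") from exc
    ln += e
    b = expect("boundary_edges")
    bedges = np.array(
        [[int(v) for v in lines[ln + i].split()] for i in range(b)], dtype=np.int64
    ).reshape(b, 2)
    ln += b
    g = expect("electrodes")
    electrodes = []
    for i in range(g):
        electrodes.append([int(v) for v in lines[ln + i].split()])
    return TorsoMesh(nodes, elements, bedges, electrodes)


def _save_triangle(mesh: TorsoMesh, path) -> None:
    base = str(path)
    with open(base + ".node", "w") as f:
        f.write(f"{mesh.n_nodes} 2 0 0\n")
        for i, (x, y) in enumerate(mesh.nodes, start=1):
            f.write(f"{i} {float(x)!r} {float(y)!r}\n")
    with open(base + ".ele", "w") as f:
        f.write(f"{mesh.n_elements} 3 0\n")
        for n, (i, j, k) in enumerate(mesh.elements, start=1):
            f.write(f"{n} {i + 1} {j + 1} {k + 1}\n")
    with open(base + ".electrode", "w") as f:
        f.write(f"{len(mesh.electrodes)}\n")
        for idxs in mesh.electrodes:
            pairs = mesh.boundary_edges[np.asarray(idxs, dtype=int)]
            f.write(" ".join(f"{a + 1},{b + 1}" for a, b in pairs) + "\n")


def _load_triangle(path) -> TorsoMesh:
    base = str(path)
    with open(base + ".node") as f:
        header = f.readline().split()
        n = int(header[0])
        nodes = np.empty((n, 2))
        for ln, line in enumerate(f):
            parts = line.split()
            if not parts or parts[0].startswith("#"):
                continue
            idx = int(parts[0]) - 1
            if not 0 <= idx < n:
                raise MeshParseError(base + ".node", ln + 2, "node index out of range")
            nodes[idx] = [float(parts[1]), float(parts[2])]
    with open(base + ".ele") as f:
        header = f.readline().split()
        e = int(header[0])
        elements = np.empty((e, 3), dtype=np.int64)
        for ln, line in enumerate(f):
            parts = line.split()
            if not parts or parts[0].startswith("#"):
                continue
            idx = int(parts[0]) - 1
            tri = [int(v) - 1 for v in parts[1:4]]
            if min(tri) < 0 or max(tri) >= n:
                raise ValidationError(
                    f"{base}.ele line {ln + 2}: element references a missing node"
                )
            elements[idx] = tri
    bedges = _ordered_boundary(nodes, elements)
    key = {tuple(sorted(e_)): i for i, e_ in enumerate(map(tuple, bedges))}
    electrodes = []
    with open(base + ".electrode") as f:
        g = int(f.readline())
        for _ in range(g):
            idxs = []
            for pair in f.readline().split():
                a, b = (int(v) - 1 for v in pair.split(","))
                idxs.append(key[tuple(sorted((a, b)))])
            electrodes.append(idxs)
    return TorsoMesh(nodes, elements, bedges, electrodes)
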