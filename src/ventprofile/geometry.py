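"""Thorax geometry: contours, electrode belts, 2.5D meshes and pixel grids.

Coordinate convention used throughout the package (viewed from cranial):

* ``+y`` points posterior (dorsal), so the anterior midline is the ``-y``
  direction from the thorax centroid;
* ``+x`` points to the animal's left, so image column 0 (minimum ``x``)
  is the animal's right side;
* image row 0 is the most anterior row (minimum ``y``), row 31 the most
  posterior one.  Anteroposterior ventilation profiles are therefore plain
  row-wise aggregates.

Contours are simple closed polygons given counter-clockwise.  Reconstruction
geometries are area-normalized (enclosed thorax area ``pi``) so that lengths
are expressed in units of the thorax effective radius.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import shapely
from scipy.spatial import Delaunay
from shapely.geometry import LineString, Point, Polygon

__all__ = [
    "Contour",
    "ThoraxGeometry",
    "ElectrodeLayout",
    "Mesh",
    "PixelGrid",
    "InvalidGeometryError",
    "MeshingError",
    "normalize_contour",
    "symmetric_difference",
    "place_electrodes",
    "build_mesh",
    "rasterize",
]

GeometryKind = Literal["circular", "averaged", "individual"]

REGION_CODES = {"background": 0, "lung": 1, "heart": 2}
REGION_NAMES = {v: k for k, v in REGION_CODES.items()}


class InvalidGeometryError(ValueError):
    """A contour or geometry violates its invariants."""


class MeshingError(RuntimeError):
    """Mesh generation failed (degenerate or conflicting contours)."""


@dataclass(frozen=True)
class Contour:
    """Simple closed polygon (implicitly closed, counter-clockwise)."""

    vertices: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 8:
            raise InvalidGeometryError(
                f"contour {self.label!r} needs >= 8 two-dimensional vertices"
            )
        area = _shoelace(v)
        if area < 0:  # re-orient to counter-clockwise
            v = v[::-1]
            area = -area
        if area <= 0:
            raise InvalidGeometryError(f"contour {self.label!r} has non-positive area")
        poly = Polygon(v)
        if not poly.is_valid:
            raise InvalidGeometryError(f"contour {self.label!r} is self-intersecting")
        object.__setattr__(self, "vertices", v)

    @property
    def polygon(self) -> Polygon:
        return Polygon(self.vertices)

    @property
    def area(self) -> float:
        return _shoelace(self.vertices)

    @property
    def centroid(self) -> np.ndarray:
        c = self.polygon.centroid
        return np.array([c.x, c.y])

    @property
    def perimeter(self) -> float:
        closed = np.vstack([self.vertices, self.vertices[:1]])
        return float(np.sum(np.linalg.norm(np.diff(closed, axis=0), axis=1)))

    def contains_points(self, xy: np.ndarray) -> np.ndarray:
        xy = np.asarray(xy, dtype=float)
        return shapely.contains_xy(self.polygon, xy[:, 0], xy[:, 1])


def _shoelace(v: np.ndarray) -> float:
    x, y = v[:, 0], v[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


@dataclass(frozen=True)
class ThoraxGeometry:
    """Thorax contour with optional lung and heart contours (the anatomical prior)."""

    thorax: Contour
    lungs: tuple[Contour, ...] = ()
    heart: Contour | None = None
    kind: GeometryKind = "circular"

    def __post_init__(self) -> None:
        if len(self.lungs) > 2:
            raise InvalidGeometryError("at most two lung contours are supported")
        organs = list(self.lungs) + ([self.heart] if self.heart is not None else [])
        tp = self.thorax.polygon
        for organ in organs:
            if not tp.contains(organ.polygon):
                raise InvalidGeometryError(
                    f"organ {organ.label!r} is not strictly inside the thorax"
                )
        for i, a in enumerate(organs):
            for b in organs[i + 1 :]:
                if a.polygon.intersects(b.polygon):
                    raise InvalidGeometryError(
                        f"organ contours {a.label!r} and {b.label!r} overlap"
                    )

    @property
    def has_organs(self) -> bool:
        return bool(self.lungs) or self.heart is not None

    @property
    def effective_radius(self) -> float:
        return float(np.sqrt(self.thorax.area / np.pi))

    def normalized(self) -> "ThoraxGeometry":
        """Center the thorax at the origin and scale its area to ``pi``.

        Lung/heart contours undergo the same similarity transform so the
        geometry stays consistent.
        """
        c = self.thorax.centroid
        s = np.sqrt(np.pi / self.thorax.area)

        def tf(contour: Contour) -> Contour:
            return Contour((contour.vertices - c) * s, label=contour.label)

        return ThoraxGeometry(
            thorax=tf(self.thorax),
            lungs=tuple(tf(l) for l in self.lungs),
            heart=tf(self.heart) if self.heart is not None else None,
            kind=self.kind,
        )


def normalize_contour(c: Contour) -> Contour:
    """Translate the centroid to the origin and scale the enclosed area to ``pi``."""
    area = c.area
    if area <= 0:
        raise InvalidGeometryError("cannot normalize a degenerate contour")
    scale = np.sqrt(np.pi / area)
    return Contour((c.vertices - c.centroid) * scale, label=c.label)


def symmetric_difference(
    a: Contour,
    b: Contour,
    method: Literal["polygon", "raster"] = "polygon",
    raster_resolution: int = 4096,
) -> float:
    """Shape-mismatch metric: non-overlapping area of the two area-normalized,
    centroid-aligned contours, as a percentage of ``pi``.

    Exact polygon clipping by default; a fine rasterization fallback is
    available for cross-checking.  The result is symmetric, translation
    invariant and invariant to uniform scaling of either input.
    """
    pa = normalize_contour(a).polygon
    pb = normalize_contour(b).polygon
    if method == "polygon":
        diff = pa.symmetric_difference(pb).area
    elif method == "raster":
        diff = _raster_symmetric_difference(pa, pb, raster_resolution)
    else:
        raise ValueError(f"unknown method {method!r}")
    return 100.0 * diff / np.pi


def _raster_symmetric_difference(pa: Polygon, pb: Polygon, n: int) -> float:
    xmin = min(pa.bounds[0], pb.bounds[0])
    ymin = min(pa.bounds[1], pb.bounds[1])
    xmax = max(pa.bounds[2], pb.bounds[2])
    ymax = max(pa.bounds[3], pb.bounds[3])
    dx = (xmax - xmin) / n
    dy = (ymax - ymin) / n
    xs = xmin + (np.arange(n) + 0.5) * dx
    ys = ymin + (np.arange(n) + 0.5) * dy
    # row-chunked to bound memory at 4096^2
    count = 0
    chunk = 256
    for i0 in range(0, n, chunk):
        yy, xx = np.meshgrid(ys[i0 : i0 + chunk], xs, indexing="ij")
        ina = shapely.contains_xy(pa, xx.ravel(), yy.ravel())
        inb = shapely.contains_xy(pb, xx.ravel(), yy.ravel())
        count += int(np.sum(ina ^ inb))
    return count * dx * dy


@dataclass(frozen=True)
class ElectrodeLayout:
    """Electrode belt: equally arc-spaced positions on the thorax contour.

    Electrode 0 sits at the anterior midline; numbering proceeds clockwise
    when viewed from cranial (i.e. from the anterior midline toward the
    animal's left with ``+x`` left / ``+y`` posterior).
    """

    positions: np.ndarray  # (n, 2)
    arc_centers: np.ndarray  # (n,) arc-length parameter of each electrode center
    width: float  # arc length covered by one electrode
    perimeter: float
    clockwise: bool = True

    @property
    def n_electrodes(self) -> int:
        return len(self.positions)


def place_electrodes(
    c: Contour,
    n: int = 32,
    width_fraction: float = 0.5,
    clockwise: bool = True,
) -> ElectrodeLayout:
    """Place ``n`` electrodes equally spaced by arc length along ``c``.

    ``width_fraction`` is the fraction of the inter-electrode pitch covered
    by the electrode patch (belt electrodes do not touch).
    """
    if n < 4:
        raise ValueError("at least 4 electrodes are required")
    ring = LineString(np.vstack([c.vertices, c.vertices[:1]]))
    L = ring.length
    centroid = c.centroid
    # anterior midline: ray from the centroid in -y
    ray = LineString([centroid, centroid + np.array([0.0, -10.0 * (L + 1.0)])])
    hit = ring.intersection(ray)
    if hit.is_empty:  # pragma: no cover - centroid inside a simple polygon
        raise InvalidGeometryError("anterior ray does not meet the contour")
    if hit.geom_type != "Point":
        pts = [g for g in getattr(hit, "geoms", [hit]) if g.geom_type == "Point"]
        hit = min(pts, key=lambda p: p.distance(Point(centroid)))
    s0 = ring.project(hit)
    step = L / n
    direction = -1.0 if clockwise else 1.0
    arcs = np.mod(s0 + direction * step * np.arange(n), L)
    pos = np.array([[p.x, p.y] for p in (ring.interpolate(s) for s in arcs)])
    return ElectrodeLayout(
        positions=pos,
        arc_centers=arcs,
        width=width_fraction * step,
        perimeter=L,
        clockwise=clockwise,
    )


@dataclass
class Mesh:
    """2.5D tetrahedral mesh extruded symmetrically about the electrode plane.

    The in-plane triangulation is stored alongside the tetrahedra: every
    tetrahedron belongs to one vertical column above a 2D triangle, which
    is what ties element space to the 32x32 image plane.
    """

    nodes: np.ndarray  # (N, 3)
    elements: np.ndarray  # (M, 4) int
    element_region: np.ndarray  # (M,) int codes, see REGION_CODES
    electrode_patches: list[np.ndarray]  # per electrode: (F, 3) boundary faces
    plane_height: float  # total extrusion height
    points2d: np.ndarray  # (n2d, 2) in-plane triangulation points
    triangles2d: np.ndarray  # (ntri, 3) kept in-plane triangles
    element_column: np.ndarray  # (M,) index into triangles2d
    column_region: np.ndarray  # (ntri,) region code per column
    kept_tri_index: np.ndarray  # full-Delaunay simplex -> column index or -1

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    @property
    def element_centroids(self) -> np.ndarray:
        return self.nodes[self.elements].mean(axis=1)

    @property
    def element_volumes(self) -> np.ndarray:
        x = self.nodes[self.elements]
        d = x[:, 1:] - x[:, :1]
        return np.abs(np.linalg.det(d)) / 6.0

    @property
    def column_areas(self) -> np.ndarray:
        p = self.points2d[self.triangles2d]
        return 0.5 * np.abs(
            (p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1])
            - (p[:, 2, 0] - p[:, 0, 0]) * (p[:, 1, 1] - p[:, 0, 1])
        )

    def region_name(self, code: int) -> str:
        return REGION_NAMES[code]

    def fingerprint(self) -> str:
        h = hashlib.sha256()
        h.update(np.ascontiguousarray(self.nodes).tobytes())
        h.update(np.ascontiguousarray(self.elements).tobytes())
        h.update(np.ascontiguousarray(self.element_region).tobytes())
        return h.hexdigest()[:16]


# relative z levels of the extrusion (fractions of the total height); the
# middle slab carries the electrode patches (patch height 0.1 * height)
_Z_LEVELS = np.array([-0.5, -0.05, 0.05, 0.5])


def _resample_closed(vertices: np.ndarray, spacing: float) -> np.ndarray:
    ring = LineString(np.vstack([vertices, vertices[:1]]))
    n = max(8, int(np.ceil(ring.length / spacing)))
    s = np.linspace(0.0, ring.length, n, endpoint=False)
    return np.array([[p.x, p.y] for p in (ring.interpolate(si) for si in s)])


def _thorax_boundary_nodes(
    c: Contour, layout: ElectrodeLayout, h: float
) -> tuple[np.ndarray, np.ndarray]:
    """Boundary nodes with electrode patch edges as exact break points.

    Returns the node coordinates and their arc-length parameters.  Each
    electrode span receives at least two edges so every patch has faces.
    """
    ring = LineString(np.vstack([c.vertices, c.vertices[:1]]))
    L = ring.length
    breaks: list[float] = []
    spans = []
    for s_c in layout.arc_centers:
        a = (s_c - layout.width / 2.0) % L
        b = (s_c + layout.width / 2.0) % L
        spans.append((a, b))
    spans.sort()
    h_el = min(h, layout.width / 2.0)
    for a, b in spans:
        span_len = (b - a) % L
        n_sub = max(2, int(np.ceil(span_len / h_el)))
        breaks.extend(((a + span_len * k / n_sub) % L) for k in range(n_sub + 1))
    # fill gaps between consecutive electrode spans
    for (a0, b0), (a1, _) in zip(spans, spans[1:] + spans[:1]):
        gap = (a1 - b0) % L
        n_sub = max(1, int(np.ceil(gap / h)))
        breaks.extend(((b0 + gap * k / n_sub) % L) for k in range(1, n_sub))
    s = np.unique(np.mod(np.asarray(breaks), L))
    # drop near-duplicates from the modular arithmetic
    keep = np.ones(len(s), dtype=bool)
    keep[1:] = np.diff(s) > 1e-9 * L
    s = s[keep]
    xy = np.array([[p.x, p.y] for p in (ring.interpolate(si) for si in s)])
    return xy, s


def _interior_points(g: ThoraxGeometry, h: float, boundary_sets: list[np.ndarray]) -> np.ndarray:
    xmin, ymin, xmax, ymax = g.thorax.polygon.bounds
    dy = h * np.sqrt(3.0) / 2.0
    ys = np.arange(ymin + h / 3.0, ymax, dy)
    pts = []
    for i, y in enumerate(ys):
        x0 = xmin + h / 3.0 + (h / 2.0 if i % 2 else 0.0)
        xs = np.arange(x0, xmax, h)
        pts.append(np.column_stack([xs, np.full(len(xs), y)]))
    if not pts:
        return np.empty((0, 2))
    p = np.vstack(pts)
    inside = g.thorax.contains_points(p)
    p = p[inside]
    # keep clear of all contour polylines to avoid slivers
    lines = [LineString(np.vstack([b, b[:1]])) for b in boundary_sets]
    pts_geom = shapely.points(p[:, 0], p[:, 1])
    ok = np.ones(len(p), dtype=bool)
    for line in lines:
        ok &= shapely.distance(pts_geom, line) > 0.45 * h
    return p[ok]


def build_mesh(
    g: ThoraxGeometry,
    layout: ElectrodeLayout,
    target_elements: int = 20000,
    extrusion_height: float | None = None,
) -> Mesh:
    """Build the 2.5D FEM: conforming in-plane triangulation extruded into
    tetrahedra, with electrode patches centered on the mid-plane.

    The triangulation is a Delaunay triangulation of contour-sampled
    boundary nodes plus a hexagonal interior lattice; it is deterministic
    for identical inputs.  Each prism is split into 8 tetrahedra around its
    centroid, so the element count is ``24 * n_triangles`` with the default
    3-slab extrusion.
    """
    if target_elements < 1000:
        raise ValueError("target_elements must be >= 1000")
    A = g.thorax.area
    tets_per_column = 8 * (len(_Z_LEVELS) - 1)
    h = float(np.sqrt(4.0 * A / (np.sqrt(3.0) * target_elements / tets_per_column)))
    mesh = _build_mesh_at(g, layout, h, extrusion_height)
    # corrective passes while the achieved count drifts off target (the
    # electrode-resolving boundary nodes impose a count floor, so the
    # density-count relation is not a pure power law)
    for _ in range(4):
        achieved = mesh.n_elements
        if abs(achieved - target_elements) <= 0.2 * target_elements:
            break
        h *= float(np.sqrt(achieved / target_elements))
        mesh = _build_mesh_at(g, layout, h, extrusion_height)
    if abs(mesh.n_elements - target_elements) > 0.3 * target_elements:
        raise MeshingError(
            f"achieved {mesh.n_elements} elements for target {target_elements}"
        )
    return mesh


def _build_mesh_at(
    g: ThoraxGeometry,
    layout: ElectrodeLayout,
    h: float,
    extrusion_height: float | None,
) -> Mesh:
    R_eff = g.effective_radius
    H = extrusion_height if extrusion_height is not None else R_eff

    thorax_xy, thorax_arcs = _thorax_boundary_nodes(g.thorax, layout, h)
    organ_sets = [o.vertices for o in g.lungs]
    if g.heart is not None:
        organ_sets.append(g.heart.vertices)
    organ_xy = [_resample_closed(v, h) for v in organ_sets]
    all_boundaries = [g.thorax.vertices] + organ_sets
    interior = _interior_points(g, h, all_boundaries)

    points = np.vstack([thorax_xy] + organ_xy + [interior]) if organ_xy else np.vstack(
        [thorax_xy, interior]
    )
    n_thorax = len(thorax_xy)
    if len(points) < 8:
        raise MeshingError("too few mesh points; contours may be degenerate")

    try:
        tri = Delaunay(points)
    except Exception as exc:  # pragma: no cover
        raise MeshingError(f"Delaunay triangulation failed: {exc}") from exc

    cent = points[tri.simplices].mean(axis=1)
    inside = shapely.contains_xy(g.thorax.polygon, cent[:, 0], cent[:, 1])
    # guard against degenerate slivers
    p = points[tri.simplices]
    areas2 = np.abs(
        (p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1])
        - (p[:, 2, 0] - p[:, 0, 0]) * (p[:, 1, 1] - p[:, 0, 1])
    )
    keep = inside & (areas2 > 1e-12 * h * h)
    triangles = tri.simplices[keep]
    if len(triangles) == 0:
        raise MeshingError("no triangles inside the thorax contour")
    kept_tri_index = np.full(len(tri.simplices), -1, dtype=int)
    kept_tri_index[np.flatnonzero(keep)] = np.arange(len(triangles))

    cent = cent[keep]
    column_region = np.zeros(len(triangles), dtype=int)
    for lung in g.lungs:
        column_region[lung.contains_points(cent)] = REGION_CODES["lung"]
    if g.heart is not None:
        column_region[g.heart.contains_points(cent)] = REGION_CODES["heart"]

    nodes, elements, element_column = _extrude(points, triangles, H)
    # label each tetrahedron by its own mid-plane centroid projection
    ecent = nodes[elements].mean(axis=1)
    element_region = np.zeros(len(elements), dtype=int)
    for lung in g.lungs:
        element_region[lung.contains_points(ecent[:, :2])] = REGION_CODES["lung"]
    if g.heart is not None:
        element_region[g.heart.contains_points(ecent[:, :2])] = REGION_CODES["heart"]

    patches = _electrode_patches(
        g, layout, points, triangles, n_thorax, thorax_arcs, nodes, elements, H
    )
    mesh = Mesh(
        nodes=nodes,
        elements=elements,
        element_region=element_region,
        electrode_patches=patches,
        plane_height=H,
        points2d=points,
        triangles2d=triangles,
        element_column=element_column,
        column_region=column_region,
        kept_tri_index=kept_tri_index,
    )
    for i, patch in enumerate(patches):
        if len(patch) == 0:
            raise MeshingError(f"electrode {i} has an empty boundary patch")
    return mesh


def _extrude(
    points: np.ndarray, triangles: np.ndarray, H: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Extrude triangles through the z levels; split each prism into 8 tets
    around its centroid (quad faces split by the smallest-global-index rule,
    so adjacent prisms tile conformingly)."""
    n2d = len(points)
    zs = _Z_LEVELS * H
    nlev = len(zs)
    nodes_levels = [
        np.column_stack([points, np.full(n2d, z)]) for z in zs
    ]
    nodes = np.vstack(nodes_levels)
    ntri = len(triangles)
    nlayer = nlev - 1
    # prism centroid nodes
    tri_cent = points[triangles].mean(axis=1)
    centers = []
    for li in range(nlayer):
        zc = 0.5 * (zs[li] + zs[li + 1])
        centers.append(np.column_stack([tri_cent, np.full(ntri, zc)]))
    center_base = len(nodes)
    nodes = np.vstack([nodes] + centers)

    tets = []
    cols = []
    for li in range(nlayer):
        lo = li * n2d
        hi = (li + 1) * n2d
        a, b, c = triangles[:, 0], triangles[:, 1], triangles[:, 2]
        A0, B0, C0 = a + lo, b + lo, c + lo
        A1, B1, C1 = a + hi, b + hi, c + hi
        P = center_base + li * ntri + np.arange(ntri)
        # caps
        tets.append(np.column_stack([A0, B0, C0, P]))
        tets.append(np.column_stack([A1, B1, C1, P]))
        # quad faces (v0,v1) x (z_lo, z_hi), diagonal through min global index
        for (u0, v0, u1, v1) in ((A0, B0, A1, B1), (B0, C0, B1, C1), (C0, A0, C1, A1)):
            # quad corners: u0, v0 (bottom), u1, v1 (top); diagonal u0-v1 or v0-u1
            use_uv = np.minimum(u0, v1) < np.minimum(v0, u1)
            # diagonal u0-v1: triangles (u0, v0, v1), (u0, v1, u1)
            t1 = np.column_stack([u0, v0, v1, P])
            t2 = np.column_stack([u0, v1, u1, P])
            # diagonal v0-u1: triangles (u0, v0, u1), (v0, v1, u1)
            t3 = np.column_stack([u0, v0, u1, P])
            t4 = np.column_stack([v0, v1, u1, P])
            tets.append(np.where(use_uv[:, None], t1, t3))
            tets.append(np.where(use_uv[:, None], t2, t4))
        cols.extend([np.arange(ntri)] * 8)
    elements = np.vstack(tets)
    element_column = np.concatenate(cols)
    # fix orientation so volumes are positive
    x = nodes[elements]
    det = np.linalg.det(x[:, 1:] - x[:, :1])
    flip = det < 0
    elements[flip, 2], elements[flip, 3] = (
        elements[flip, 3].copy(),
        elements[flip, 2].copy(),
    )
    return nodes, elements, element_column


def _electrode_patches(
    g: ThoraxGeometry,
    layout: ElectrodeLayout,
    points: np.ndarray,
    triangles: np.ndarray,
    n_thorax: int,
    thorax_arcs: np.ndarray,
    nodes: np.ndarray,
    elements: np.ndarray,
    H: float,
) -> list[np.ndarray]:
    """Collect boundary faces of the middle slab under each electrode span."""
    n2d = len(points)
    # boundary edges of the kept triangulation between thorax-boundary nodes
    edges = np.vstack(
        [triangles[:, [0, 1]], triangles[:, [1, 2]], triangles[:, [2, 0]]]
    )
    edges_sorted = np.sort(edges, axis=1)
    uniq, counts = np.unique(edges_sorted, axis=0, return_counts=True)
    boundary = uniq[(counts == 1)]
    boundary = boundary[(boundary < n_thorax).all(axis=1)]

    L = layout.perimeter
    arc = {i: thorax_arcs[i] for i in range(n_thorax)}

    # middle slab: level index 1 -> 2 (z in [-0.05H, 0.05H])
    lo = 1 * n2d
    hi = 2 * n2d
    # face triangles on the boundary quad of the middle layer follow the same
    # min-index diagonal rule used in _extrude
    patches: list[list[np.ndarray]] = [[] for _ in range(layout.n_electrodes)]
    for u, v in boundary:
        su, sv = arc[int(u)], arc[int(v)]
        # midpoint arc coordinate, careful across the wrap
        d = (sv - su) % L
        if d > L / 2.0:
            su, sv = sv, su
            d = (sv - su) % L
        smid = (su + d / 2.0) % L
        for k in range(layout.n_electrodes):
            off = (smid - layout.arc_centers[k]) % L
            if off > L / 2.0:
                off -= L
            if abs(off) <= layout.width / 2.0 + 1e-12:
                u0, v0 = int(u) + lo, int(v) + lo
                u1, v1 = int(u) + hi, int(v) + hi
                if min(u0, v1) < min(v0, u1):
                    patches[k].append(np.array([[u0, v0, v1], [u0, v1, u1]]))
                else:
                    patches[k].append(np.array([[u0, v0, u1], [v0, v1, u1]]))
                break
    return [
        np.vstack(p) if p else np.empty((0, 3), dtype=int) for p in patches
    ]


@dataclass(frozen=True)
class PixelGrid:
    """32x32 image grid over the tight bounding box of the thorax contour."""

    bounds: tuple[float, float, float, float]  # xmin, ymin, xmax, ymax
    body_mask: np.ndarray
    lung_mask: np.ndarray
    heart_mask: np.ndarray
    shape: tuple[int, int] = (32, 32)

    @property
    def pixel_size(self) -> tuple[float, float]:
        xmin, ymin, xmax, ymax = self.bounds
        return ((xmax - xmin) / self.shape[1], (ymax - ymin) / self.shape[0])

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(X, Y) arrays of pixel-center coordinates, row 0 anterior."""
        xmin, ymin, xmax, ymax = self.bounds
        dx, dy = self.pixel_size
        xs = xmin + (np.arange(self.shape[1]) + 0.5) * dx
        ys = ymin + (np.arange(self.shape[0]) + 0.5) * dy
        return np.meshgrid(xs, ys)

    def subpixel_centers(self, factor: int = 4) -> tuple[np.ndarray, np.ndarray]:
        xmin, ymin, xmax, ymax = self.bounds
        n = self.shape[0] * factor
        dx = (xmax - xmin) / n
        dy = (ymax - ymin) / n
        xs = xmin + (np.arange(n) + 0.5) * dx
        ys = ymin + (np.arange(n) + 0.5) * dy
        return np.meshgrid(xs, ys)


def rasterize(g: ThoraxGeometry, shape: tuple[int, int] = (32, 32)) -> PixelGrid:
    """Rasterize the geometry onto the image grid.

    A pixel belongs to a region iff its center lies inside the region's
    contour; the grid covers the thorax contour's tight axis-aligned
    bounding box and row index increases anterior to posterior.
    """
    xmin, ymin, xmax, ymax = g.thorax.polygon.bounds
    bounds = (float(xmin), float(ymin), float(xmax), float(ymax))
    nr, nc = shape
    dx = (xmax - xmin) / nc
    dy = (ymax - ymin) / nr
    xs = xmin + (np.arange(nc) + 0.5) * dx
    ys = ymin + (np.arange(nr) + 0.5) * dy
    X, Y = np.meshgrid(xs, ys)
    pts = np.column_stack([X.ravel(), Y.ravel()])
    body = g.thorax.contains_points(pts).reshape(shape)
    lung = np.zeros(shape, dtype=bool)
    for l in g.lungs:
        lung |= l.contains_points(pts).reshape(shape)
    heart = np.zeros(shape, dtype=bool)
    if g.heart is not None:
        heart = g.heart.contains_points(pts).reshape(shape)
    return PixelGrid(
        bounds=bounds,
        body_mask=body,
        lung_mask=lung & body,
        heart_mask=heart & body,
        shape=shape,
    )
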