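"""Plaque domain geometry: segmentation of the simulation region and sprout seeding.

The simulation region is a uniform ``nx x ny`` grid (default 200 x 200 cells
covering 4 mm x 4 mm, i.e. 20 um cells) segmented into histological regions:
vessel lumen, necrotic core (NC), the two shoulders (SA), fibrous cap (FC), a
media band, and exterior tissue.  Segmentation follows the classical wedge
construction on a plaque cross-section: the two plaque tips are joined to the
lumen center, the bisector of the resulting angle is extended to the outer
plaque boundary (point ``b``), and the lines tip--b split the plaque body into
the central necrotic core and the two flanking shoulders.  The narrow band
around the lumen is the fibrous cap.

Twelve vasa-vasorum sprout seeds are placed on the media band at 30-degree
angular steps about the lumen center.

Grid convention (repo-wide): 0-based cell indices, cell-centered coordinates,
arrays indexed ``[y, x]``, coordinates as ``(x, y)`` floats in cell units.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np
import shapely
from scipy.optimize import brentq
from shapely.geometry import LineString, Point, Polygon


class GeometryError(ValueError):
    """Raised for degenerate or inconsistent segmentation inputs."""


class Region(IntEnum):
    """Categorical region labels of the plaque cross-section."""

    OUTSIDE = 0
    LUMEN = 1
    NC = 2      # necrotic core
    SA = 3      # shoulder areas (both sides share one label)
    FC = 4      # fibrous cap
    MEDIA = 5   # media/adventitia band hosting the vasa vasorum


N_SPROUTS = 12
SPROUT_STEP_DEG = 30.0


@dataclass
class SegmentationInput:
    """Labeled-boundary description of a plaque cross-section.

    This is the exchange format between an (external or synthetic) plaque
    segmentation and :func:`segment_domain`.  All coordinates are in cell
    units on the simulation grid.
    """

    nx: int
    ny: int
    extent_cm: float
    plaque_boundary: np.ndarray   # (N, 2) outer plaque/artery boundary polygon
    lumen_boundary: np.ndarray    # (M, 2) lumen boundary polygon
    lumen_center: np.ndarray      # (2,)
    tips: np.ndarray              # (2, 2) the two plaque tip points
    fc_thickness: float = 3.0     # fibrous-cap band thickness, cells
    media_width: float = 3.0      # media band width outside the plaque, cells

    @property
    def h_cm(self) -> float:
        """Grid spacing in cm."""
        return self.extent_cm / self.nx


@dataclass
class PlaqueDomain:
    """Segmented simulation domain.

    ``region_label`` partitions the grid: every cell carries exactly one
    :class:`Region` code.  ``shoulder_centers`` are the centroids of the two
    shoulder regions and seed the initial growth-factor field.
    """

    nx: int
    ny: int
    extent_cm: float
    region_label: np.ndarray          # (ny, nx) int8 of Region codes
    lumen_center: np.ndarray          # (2,) float, cell units
    shoulder_centers: np.ndarray      # (2, 2) float, cell units
    sprout_seeds: np.ndarray = field(default=None)  # (12, 2) int cell coords

    @property
    def h_cm(self) -> float:
        return self.extent_cm / self.nx

    @property
    def cell_area_mm2(self) -> float:
        return (10.0 * self.h_cm) ** 2

    def region_mask(self, region: Region) -> np.ndarray:
        return self.region_label == int(region)

    @property
    def plaque_mask(self) -> np.ndarray:
        """Cells belonging to the plaque body (NC, SA or FC)."""
        lab = self.region_label
        return (lab == Region.NC) | (lab == Region.SA) | (lab == Region.FC)


def make_synthetic_fixture(
    seed: int,
    stenosis_fraction: float,
    *,
    nx: int = 200,
    ny: int = 200,
    extent_cm: float = 0.4,
    fc_thickness: float = 3.0,
    media_width: float = 3.0,
    jitter: float = 0.0,
) -> SegmentationInput:
    """Build a synthetic crescent-plaque segmentation input.

    Stands in for a histology-derived segmentation: an off-center circular
    lumen inside a circular artery cross-section leaves a crescent-shaped
    plaque whose two tips (where the plaque pinches out) are well defined.
    ``stenosis_fraction`` is the areal degree of stenosis (plaque area over
    artery cross-section area); the patient case emulated here is an 80%
    stenosis.  Deterministic for a given seed; ``jitter`` optionally perturbs
    the artery radius and cap gap (in cells) for ensemble geometry variation.
    """
    if not 0.0 < stenosis_fraction < 1.0:
        raise GeometryError(
            f"stenosis_fraction must be in (0, 1), got {stenosis_fraction}"
        )
    rng = np.random.default_rng(seed)
    jit = lambda: rng.uniform(-jitter, jitter) if jitter > 0 else 0.0

    cx = (nx - 1) / 2.0
    cy = (ny - 1) / 2.0
    artery_center = np.array([cx, cy])
    r_artery = 0.40 * nx + jit()
    r_lumen = r_artery * float(np.sqrt(1.0 - stenosis_fraction))
    gap = max(fc_thickness + 2.0, 6.0) + jit()          # residual wall at the cap
    d = r_artery - r_lumen - gap                         # lumen offset (+y)
    if d <= 0:
        raise GeometryError("stenosis too mild for a crescent plaque geometry")
    lumen_center = artery_center + np.array([0.0, d])

    # Plaque thickness along the ray at elevation u_y (unit direction from the
    # lumen center): tau(u_y) = rho_out(u_y) - r_lumen, monotone in u_y.
    def thickness(u_y: float) -> float:
        rho_out = -d * u_y + np.sqrt(r_artery**2 - d**2 * (1.0 - u_y**2))
        return rho_out - r_lumen

    tau_tip = fc_thickness + 8.0  # plaque thickness at which the tips are defined
    if thickness(-1.0) <= tau_tip:
        raise GeometryError("plaque too thin to define tips")
    uy_tip = brentq(lambda u: thickness(u) - tau_tip, -1.0, 1.0)
    ux_tip = float(np.sqrt(1.0 - uy_tip**2))
    rho_tip = r_lumen + tau_tip / 2.0
    tips = np.array(
        [
            lumen_center + rho_tip * np.array([+ux_tip, uy_tip]),
            lumen_center + rho_tip * np.array([-ux_tip, uy_tip]),
        ]
    )

    theta = np.linspace(0.0, 2.0 * np.pi, 721)[:-1]
    circle = np.stack([np.cos(theta), np.sin(theta)], axis=1)
    return SegmentationInput(
        nx=nx,
        ny=ny,
        extent_cm=extent_cm,
        plaque_boundary=artery_center + r_artery * circle,
        lumen_boundary=lumen_center + r_lumen * circle,
        lumen_center=lumen_center,
        tips=tips,
        fc_thickness=fc_thickness,
        media_width=media_width,
    )


def _bisector_direction(u1: np.ndarray, u2: np.ndarray, seg: SegmentationInput) -> np.ndarray:
    """Unit bisector of the tip rays, oriented into the plaque body."""
    s = u1 + u2
    if np.linalg.norm(s) < 1e-12:
        # Tips diametrically opposite: pick the direction away from the
        # plaque-boundary centroid -> lumen-center axis.
        s = seg.lumen_center - seg.plaque_boundary.mean(axis=0)
        if np.linalg.norm(s) < 1e-12:
            raise GeometryError("cannot orient bisector: degenerate tip rays")
        s = -s
    cand = s / np.linalg.norm(s)
    # Of the two opposite candidates, the plaque-side bisector travels farther
    # from the lumen center before leaving the plaque boundary.
    poly = Polygon(seg.plaque_boundary)
    span = 4.0 * max(seg.nx, seg.ny)
    best, best_len = None, -1.0
    for direction in (cand, -cand):
        ray = LineString([seg.lumen_center, seg.lumen_center + span * direction])
        hit = ray.intersection(poly.exterior)
        if hit.is_empty:
            continue
        dist = max(
            Point(seg.lumen_center).distance(g) for g in _as_points(hit)
        )
        if dist > best_len:
            best, best_len = direction, dist
    if best is None:
        raise GeometryError("bisector does not intersect the plaque boundary")
    return best


def _as_points(geom) -> list:
    if geom.geom_type == "Point":
        return [geom]
    if hasattr(geom, "geoms"):
        pts = []
        for g in geom.geoms:
            pts.extend(_as_points(g))
        return pts
    # LineString overlap edge case: use its vertices
    return [Point(c) for c in geom.coords]


def segment_domain(seg: SegmentationInput) -> PlaqueDomain:
    """Segment the grid into plaque regions from a labeled-boundary input.

    Implements the wedge construction: the angle at the lumen center between
    the two tip rays is bisected; the bisector meets the outer plaque boundary
    at ``b``; the (extended) lines tip--b separate the necrotic core from the
    two shoulders.  Cells within ``fc_thickness`` of the lumen form the
    fibrous cap, and a ``media_width`` band outside the plaque boundary is the
    media.  Raises :class:`GeometryError` on degenerate inputs.
    """
    t1, t2 = np.asarray(seg.tips, dtype=float)
    lc = np.asarray(seg.lumen_center, dtype=float)
    if np.linalg.norm(t1 - t2) < 1e-9:
        raise GeometryError("the two plaque tips coincide")
    for name, t in (("tip 1", t1), ("tip 2", t2)):
        if np.linalg.norm(t - lc) < 1e-9:
            raise GeometryError(f"{name} coincides with the lumen center")

    u1 = (t1 - lc) / np.linalg.norm(t1 - lc)
    u2 = (t2 - lc) / np.linalg.norm(t2 - lc)
    bis = _bisector_direction(u1, u2, seg)

    plaque_poly = Polygon(seg.plaque_boundary)
    lumen_poly = Polygon(seg.lumen_boundary)
    if not plaque_poly.is_valid or not lumen_poly.is_valid:
        raise GeometryError("boundary polygon is self-intersecting")

    span = 4.0 * max(seg.nx, seg.ny)
    ray = LineString([lc, lc + span * bis])
    hit = ray.intersection(plaque_poly.exterior)
    if hit.is_empty:
        raise GeometryError("bisector does not intersect the plaque boundary")
    b = max(_as_points(hit), key=lambda p: Point(lc).distance(p))
    b = np.array([b.x, b.y])

    xs, ys = np.meshgrid(np.arange(seg.nx, dtype=float), np.arange(seg.ny, dtype=float))
    pts = shapely.points(xs.ravel(), ys.ravel())
    in_plaque_body = shapely.contains_xy(plaque_poly, xs.ravel(), ys.ravel()).reshape(ys.shape)
    in_lumen = shapely.contains_xy(lumen_poly, xs.ravel(), ys.ravel()).reshape(ys.shape)
    lumen_ring = LineString(seg.lumen_boundary)
    plaque_ring = LineString(seg.plaque_boundary)
    d_lumen = shapely.distance(pts, lumen_ring).reshape(ys.shape)
    d_outer = shapely.distance(pts, plaque_ring).reshape(ys.shape)

    label = np.full((seg.ny, seg.nx), int(Region.OUTSIDE), dtype=np.int8)
    label[in_lumen] = Region.LUMEN

    wall = in_plaque_body & ~in_lumen
    fc = wall & (d_lumen < seg.fc_thickness)
    label[fc] = Region.FC

    # Side tests against the two tip--b lines; the necrotic core lies on the
    # same side as a reference point partway down the bisector.
    def side(p0, p1, x, y):
        return (p1[0] - p0[0]) * (y - p0[1]) - (p1[1] - p0[1]) * (x - p0[0])

    ref = lc + 0.7 * np.dot(b - lc, bis) * bis
    s1 = side(t1, b, xs, ys) * np.sign(side(t1, b, ref[0], ref[1]))
    s2 = side(t2, b, xs, ys) * np.sign(side(t2, b, ref[0], ref[1]))
    core_side = (s1 >= 0) & (s2 >= 0)
    body = wall & ~fc
    label[body & core_side] = Region.NC
    label[body & ~core_side] = Region.SA

    media = ~in_plaque_body & (d_outer <= seg.media_width)
    label[media] = Region.MEDIA

    # Shoulder centroids, one on each side of the bisector axis.
    sa = label == Region.SA
    axis_side = np.sign(bis[0] * (ys - lc[1]) - bis[1] * (xs - lc[0]))
    centers = []
    for sgn in (+1.0, -1.0):
        m = sa & (axis_side == sgn)
        if not m.any():
            raise GeometryError("a shoulder region is empty")
        centers.append([xs[m].mean(), ys[m].mean()])
    shoulder_centers = np.array(centers)

    dom = PlaqueDomain(
        nx=seg.nx,
        ny=seg.ny,
        extent_cm=seg.extent_cm,
        region_label=label,
        lumen_center=lc.copy(),
        shoulder_centers=shoulder_centers,
    )
    dom.sprout_seeds = place_sprouts(dom)
    return dom


def place_sprouts(domain: PlaqueDomain, snap_tolerance: float = 5.0) -> np.ndarray:
    """Place the 12 vasa-vasorum sprout seeds on the media band.

    Rays are cast from the lumen center at angles ``k * 30`` degrees; each
    seed is the first media cell met along its ray (i.e. the ray-media
    intersection snapped to the grid).  Raises :class:`GeometryError` if any
    ray misses the media within ``snap_tolerance`` cells or if seeds collide.
    """
    label = domain.region_label
    if not (label == Region.MEDIA).any():
        raise GeometryError("domain has no media band")
    lc = domain.lumen_center
    rmax = float(np.hypot(domain.nx, domain.ny))
    ts = np.arange(1.0, rmax, 0.25)
    seeds = []
    for k in range(N_SPROUTS):
        ang = np.deg2rad(k * SPROUT_STEP_DEG)
        u = np.array([np.cos(ang), np.sin(ang)])
        px = np.rint(lc[0] + ts * u[0]).astype(int)
        py = np.rint(lc[1] + ts * u[1]).astype(int)
        ok = (px >= 0) & (px < domain.nx) & (py >= 0) & (py < domain.ny)
        px, py = px[ok], py[ok]
        on_media = label[py, px] == Region.MEDIA
        if not on_media.any():
            raise GeometryError(f"sprout ray at {k * 30} deg does not meet the media")
        i = int(np.argmax(on_media))  # first media cell along the ray
        # The snapped seed must lie close to the exact ray.
        t_hit = ts[ok][i]
        exact = lc + t_hit * u
        if np.hypot(px[i] - exact[0], py[i] - exact[1]) > snap_tolerance:
            raise GeometryError(f"no media cell within tolerance of the {k * 30} deg ray")
        seeds.append((px[i], py[i]))
    if len(set(seeds)) != N_SPROUTS:
        raise GeometryError("sprout seeds collide; media band too coarse")
    return np.array(seeds, dtype=int)
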