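"""Per-bleb morphometry from annotated outlines.

A subretinal bleb is recorded as a closed planar polygon (its base outline,
in arbitrary retinal-plane units), the retinotomy (injection-site) point,
and the y-coordinate of the visual-streak (VS) centerline.  All quantities
derive from these three pieces of data:

* vertical extents ``p_prox`` / ``p_dist`` — how far the bleb margin
  reaches toward / away from the VS along the superior–inferior axis,
  measured from the retinotomy (the temporal–nasal component is ignored);
* the vertical propagation anisotropy ``a_v = p_prox / p_dist``;
* an area-based cross-validation of the same split (polygon clipped by the
  horizontal line through the retinotomy);
* an ellipse approximation of the base from exact polygon second moments,
  giving eccentricity ``a/b`` and — when the bleb is sufficiently eccentric
  (``a/b > 1.1``) — the unsigned long-axis tilt in degrees from horizontal.

The canonical frame is +y = superior, +x = nasal→temporal.  Raw annotation
frames that use −y = superior are normalized by :func:`canonicalize`.
"""

from __future__ import annotations

import csv
import json
import math
import warnings as _warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from shapely.geometry import Point as _ShapelyPoint
from shapely.geometry import Polygon as _ShapelyPolygon
from shapely.ops import split as _shapely_split
from shapely.geometry import LineString as _LineString

__all__ = [
    "BlebMorphError",
    "ValidationError",
    "FitError",
    "ConfigurationError",
    "PlanarPoint",
    "BlebOutline",
    "EyeRecord",
    "EllipseFit",
    "BlebMetrics",
    "AnnotationWarning",
    "ECCENTRICITY_GATE",
    "BALANCED_LOW",
    "BALANCED_HIGH",
    "AREA_CONSERVATION_RTOL",
    "canonicalize",
    "polygon_area",
    "polygon_centroid",
    "fit_ellipse",
    "vertical_extents",
    "vertical_anisotropy",
    "classify_propagation",
    "area_split",
    "area_anisotropy",
    "long_axis_tilt",
    "compute_bleb_metrics",
    "validate_eye_record",
    "read_outline",
    "write_outline",
]


# --- errors and tunables ---------------------------------------------------

class BlebMorphError(Exception):
    """Base class for all package errors."""


class ValidationError(BlebMorphError):
    """Input fails a structural invariant (bad polygon, bad value)."""


class FitError(BlebMorphError):
    """Geometric fit impossible (degenerate polygon, clipping failure)."""


class ConfigurationError(BlebMorphError):
    """Missing or inconsistent configuration (e.g. undeclared frame)."""


class AnnotationWarning(UserWarning):
    """Suspect but usable annotation (retinotomy off-bleb, label mismatch)."""


#: eccentricity a/b above which a long-axis tilt is recorded (strict >)
ECCENTRICITY_GATE = 1.1
#: closed interval of a_v classified as balanced (isotropic propagation)
BALANCED_LOW = 0.9
BALANCED_HIGH = 1.1
#: relative tolerance for area_prox + area_dist == total area
AREA_CONSERVATION_RTOL = 1e-9


# --- domain types ----------------------------------------------------------

@dataclass(frozen=True)
class PlanarPoint:
    """A retinal-plane point in arbitrary units (+x temporal–nasal, +y superior)."""

    x: float
    y: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValidationError(f"non-finite coordinates ({self.x}, {self.y})")

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y], dtype=float)


class BlebOutline:
    """Closed simple polygon of the bleb base.

    Vertices are an ordered ``(n, 2)`` array, implicitly closed (the last
    vertex connects back to the first).  The polygon must be simple
    (non-self-intersecting), enclose strictly positive area, and contain no
    two identical consecutive vertices.
    """

    __slots__ = ("vertices",)

    def __init__(self, vertices: Sequence[Sequence[float]] | np.ndarray):
        arr = np.asarray(vertices, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise ValidationError(f"outline must be (n, 2), got shape {arr.shape}")
        # drop an explicit closing vertex if present
        if arr.shape[0] >= 2 and np.array_equal(arr[0], arr[-1]):
            arr = arr[:-1]
        if arr.shape[0] < 3:
            raise ValidationError("outline needs at least 3 distinct vertices")
        if not np.all(np.isfinite(arr)):
            raise ValidationError("outline contains non-finite coordinates")
        nxt = np.roll(arr, -1, axis=0)
        if np.any(np.all(arr == nxt, axis=1)):
            raise ValidationError("outline has identical consecutive vertices")
        poly = _ShapelyPolygon(arr)
        if not poly.is_valid:
            raise ValidationError("outline polygon is self-intersecting or invalid")
        if poly.area <= 0.0:
            raise ValidationError("outline encloses no area")
        self.vertices = arr
        self.vertices.setflags(write=False)

    def __len__(self) -> int:
        return self.vertices.shape[0]

    def __eq__(self, other: object) -> bool:
        return isinstance(other, BlebOutline) and np.array_equal(
            self.vertices, other.vertices
        )

    def __repr__(self) -> str:
        return f"BlebOutline({len(self)} vertices)"

    def to_shapely(self) -> _ShapelyPolygon:
        return _ShapelyPolygon(self.vertices)


@dataclass
class EyeRecord:
    """One annotated eye: outline + retinotomy + VS reference + metadata."""

    eye_id: str
    animal_id: str
    laterality: str          # left | right
    injection_site: str      # superior | inferior (relative to the VS)
    injectate: str           # aav | pbs | other
    outline: BlebOutline
    retinotomy: PlanarPoint
    vs_reference_y: float

    def __post_init__(self) -> None:
        if self.laterality not in ("left", "right"):
            raise ValidationError(f"bad laterality {self.laterality!r}")
        if self.injection_site not in ("superior", "inferior"):
            raise ValidationError(f"bad injection_site {self.injection_site!r}")
        if self.injectate not in ("aav", "pbs", "other"):
            raise ValidationError(f"bad injectate {self.injectate!r}")
        if not math.isfinite(self.vs_reference_y):
            raise ValidationError("vs_reference_y must be finite")
        if self.vs_reference_y == self.retinotomy.y:
            raise ValidationError(
                f"eye {self.eye_id}: retinotomy lies on the VS centerline"
            )


@dataclass(frozen=True)
class EllipseFit:
    """Area-matched moment ellipse of a bleb base.

    ``orientation`` is the signed angle of the long axis in degrees,
    measured from the +x (temporal–nasal) axis, in (−90, 90].
    """

    center: PlanarPoint
    a: float
    b: float
    orientation: float

    def __post_init__(self) -> None:
        if not (self.a >= self.b > 0):
            raise ValidationError(f"require a >= b > 0, got a={self.a}, b={self.b}")
        if not (-90.0 < self.orientation <= 90.0):
            raise ValidationError(f"orientation {self.orientation} outside (-90, 90]")

    @property
    def eccentricity(self) -> float:
        """Axis ratio a/b >= 1 (the eccentricity measure used for gating)."""
        return self.a / self.b


@dataclass
class BlebMetrics:
    """All per-bleb derived quantities.

    ``a_v`` / ``area_anisotropy`` are ``None`` when the distal extent / area
    is zero (ratio undefined); ``tilt`` is ``None`` unless eccentricity
    exceeds the gate.  ``warnings`` collects annotation-quality flags.
    """

    p_prox: float
    p_dist: float
    a_v: float | None
    area_prox: float
    area_dist: float
    area_anisotropy: float | None
    eccentricity: float
    tilt: float | None
    propagation_class: str
    warnings: list[str] = field(default_factory=list)


# --- canonical frame -------------------------------------------------------

def canonicalize(
    outline: BlebOutline,
    retinotomy: PlanarPoint,
    vs_reference_y: float,
    superior_direction: str,
) -> tuple[BlebOutline, PlanarPoint, float]:
    """Normalize an annotation to the canonical +y = superior frame.

    ``superior_direction`` declares the raw frame: ``"+y"`` (already
    canonical, returned unchanged) or ``"-y"`` (image-style frame with y
    growing inferiorly; all y-coordinates are negated).
    """
    if superior_direction == "+y":
        return outline, retinotomy, float(vs_reference_y)
    if superior_direction == "-y":
        flipped = outline.vertices.copy()
        flipped[:, 1] *= -1.0
        # reverse to preserve counter-clockwise winding after reflection
        return (
            BlebOutline(flipped[::-1]),
            PlanarPoint(retinotomy.x, -retinotomy.y),
            -float(vs_reference_y),
        )
    raise ConfigurationError(
        f"superior_direction must be '+y' or '-y', got {superior_direction!r}"
    )


# --- polygon integrals -----------------------------------------------------

def _shoelace_terms(verts: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    x, y = verts[:, 0], verts[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    return x, y, (x * yn - xn * y)


def polygon_area(outline: BlebOutline) -> float:
    """Shoelace area of the closed outline, orientation-independent."""
    _, _, cross = _shoelace_terms(outline.vertices)
    return abs(0.5 * float(np.sum(cross)))


def polygon_centroid(outline: BlebOutline) -> PlanarPoint:
    """Region centroid of the enclosed polygon (not the vertex mean)."""
    verts = outline.vertices
    x, y, cross = _shoelace_terms(verts)
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    a_signed = 0.5 * float(np.sum(cross))
    cx = float(np.sum((x + xn) * cross)) / (6.0 * a_signed)
    cy = float(np.sum((y + yn) * cross)) / (6.0 * a_signed)
    return PlanarPoint(cx, cy)


def _second_central_moments(verts: np.ndarray) -> tuple[float, float, float, float]:
    """Exact region integrals via Green's theorem.

    Returns ``(area, mu20, mu02, mu11)`` where ``mu20 = ∫(x-cx)² dA`` etc.
    Works for either winding (signs cancel on normalization).
    """
    x, y, cross = _shoelace_terms(verts)
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    a_signed = 0.5 * float(np.sum(cross))
    cx = float(np.sum((x + xn) * cross)) / (6.0 * a_signed)
    cy = float(np.sum((y + yn) * cross)) / (6.0 * a_signed)
    ix2 = float(np.sum((x * x + x * xn + xn * xn) * cross)) / 12.0
    iy2 = float(np.sum((y * y + y * yn + yn * yn) * cross)) / 12.0
    ixy = float(np.sum((x * yn + 2.0 * x * y + 2.0 * xn * yn + xn * y) * cross)) / 24.0
    mu20 = ix2 - a_signed * cx * cx
    mu02 = iy2 - a_signed * cy * cy
    mu11 = ixy - a_signed * cx * cy
    if a_signed < 0:
        a_signed, mu20, mu02, mu11 = -a_signed, -mu20, -mu02, -mu11
    return a_signed, mu20, mu02, mu11


def fit_ellipse(outline: BlebOutline) -> EllipseFit:
    """Approximate the bleb base by its area-matched moment ellipse.

    The center is the polygon centroid; axis directions and the axis ratio
    come from the eigen-decomposition of the region's second central moment
    tensor (computed exactly from the polygon via Green's-theorem
    integrals); the axes are then scaled jointly so the ellipse area equals
    the polygon area.  For a polygon densely sampling a true ellipse this
    recovers that ellipse.
    """
    area, mu20, mu02, mu11 = _second_central_moments(outline.vertices)
    if area <= 0:
        raise FitError("degenerate polygon: zero area")
    # normalized covariance of the region
    cxx, cyy, cxy = mu20 / area, mu02 / area, mu11 / area
    tr, det = cxx + cyy, cxx * cyy - cxy * cxy
    disc = max(0.0, 0.25 * tr * tr - det)
    lam1 = 0.5 * tr + math.sqrt(disc)
    lam2 = 0.5 * tr - math.sqrt(disc)
    if lam2 <= 0 or not math.isfinite(lam1):
        raise FitError("degenerate (collinear) polygon: singular moment tensor")
    # for a solid ellipse the covariance eigenvalues are a²/4 and b²/4
    a0, b0 = 2.0 * math.sqrt(lam1), 2.0 * math.sqrt(lam2)
    scale = math.sqrt(area / (math.pi * a0 * b0))
    theta = 0.5 * math.degrees(math.atan2(2.0 * cxy, cxx - cyy))
    if theta <= -90.0:
        theta += 180.0
    elif theta > 90.0:
        theta -= 180.0
    centroid = polygon_centroid(outline)
    return EllipseFit(center=centroid, a=a0 * scale, b=b0 * scale, orientation=theta)


# --- vertical propagation --------------------------------------------------

def _proximal_sign(retinotomy: PlanarPoint, vs_reference_y: float) -> float:
    s = math.copysign(1.0, vs_reference_y - retinotomy.y)
    if vs_reference_y == retinotomy.y:
        raise ValidationError("retinotomy lies on the VS centerline")
    return s


def vertical_extents(
    outline: BlebOutline,
    retinotomy: PlanarPoint,
    vs_reference_y: float,
) -> tuple[float, float]:
    """Vertical extents (p_prox, p_dist) of the bleb from the retinotomy.

    Proximal means toward the VS centerline.  Each extent is the maximal
    vertical distance from the retinotomy to the bleb margin on that side
    (x-coordinates are disregarded), clamped at zero when the whole outline
    lies on the other side.  A retinotomy outside the outline is suspect
    annotation: an :class:`AnnotationWarning` is emitted and computation
    proceeds.
    """
    s = _proximal_sign(retinotomy, vs_reference_y)
    poly = outline.to_shapely()
    if not poly.buffer(1e-9 * max(1.0, math.sqrt(poly.area))).contains(
        _ShapelyPoint(retinotomy.x, retinotomy.y)
    ):
        _warnings.warn(
            "retinotomy lies outside the bleb outline (annotation suspect)",
            AnnotationWarning,
            stacklevel=2,
        )
    dy = outline.vertices[:, 1] - retinotomy.y
    p_prox = max(0.0, float(np.max(s * dy)))
    p_dist = max(0.0, float(np.max(-s * dy)))
    return p_prox, p_dist


def vertical_anisotropy(p_prox: float, p_dist: float) -> float | None:
    """A_V = p_prox / p_dist; ``None`` (undefined) when p_dist is zero."""
    if p_prox < 0 or p_dist < 0:
        raise ValidationError("vertical extents must be non-negative")
    if p_dist == 0.0:
        return None
    return p_prox / p_dist


def classify_propagation(a_v: float | None) -> str:
    """Classify a bleb by its vertical anisotropy.

    ``away`` if a_v < 0.9, ``balanced`` on the closed interval [0.9, 1.1],
    ``toward`` if a_v > 1.1; an undefined a_v passes through as
    ``"undefined"``.
    """
    if a_v is None:
        return "undefined"
    if a_v < 0:
        raise ValidationError(f"a_v must be non-negative, got {a_v}")
    if a_v < BALANCED_LOW:
        return "away"
    if a_v > BALANCED_HIGH:
        return "toward"
    return "balanced"


# --- area cross-validation -------------------------------------------------

def area_split(
    outline: BlebOutline,
    retinotomy: PlanarPoint,
    vs_reference_y: float,
) -> tuple[float, float]:
    """Split the bleb area by the horizontal line through the retinotomy.

    Returns ``(area_prox, area_dist)``: the area on the VS side of the line
    and the remainder.  Their sum equals the polygon area to within
    ``AREA_CONSERVATION_RTOL``.
    """
    s = _proximal_sign(retinotomy, vs_reference_y)
    poly = outline.to_shapely()
    total = poly.area
    ys = outline.vertices[:, 1]
    y0 = retinotomy.y
    if np.all(s * (ys - y0) >= 0):
        return total, 0.0
    if np.all(s * (ys - y0) <= 0):
        return 0.0, total
    xs = outline.vertices[:, 0]
    pad = (xs.max() - xs.min()) + 1.0
    cut = _LineString([(xs.min() - pad, y0), (xs.max() + pad, y0)])
    try:
        pieces = _shapely_split(poly, cut)
    except Exception as exc:  # pragma: no cover - shapely internal failure
        raise FitError(f"clipping failed on degenerate geometry: {exc}") from exc
    area_prox = sum(
        g.area for g in pieces.geoms if s * (g.representative_point().y - y0) > 0
    )
    area_dist = total - area_prox
    if not math.isclose(area_prox + area_dist, total, rel_tol=AREA_CONSERVATION_RTOL):
        raise FitError("area split does not conserve total polygon area")
    return float(area_prox), float(area_dist)


def area_anisotropy(area_prox: float, area_dist: float) -> float | None:
    """Area-based anisotropy area_prox/area_dist; ``None`` when distal area is zero."""
    if area_prox < 0 or area_dist < 0:
        raise ValidationError("areas must be non-negative")
    if area_dist == 0.0:
        return None
    return area_prox / area_dist


# --- tilt ------------------------------------------------------------------

def long_axis_tilt(fit: EllipseFit) -> float | None:
    """Unsigned long-axis tilt in degrees [0, 90], gated on eccentricity.

    Returns ``None`` when a/b <= 1.1 (near-circular blebs have no
    meaningful long axis).  0° is the temporal–nasal (horizontal) axis,
    90° the superior–inferior (vertical) axis.
    """
    if fit.eccentricity <= ECCENTRICITY_GATE:
        return None
    return abs(fit.orientation)


# --- composition -----------------------------------------------------------

def validate_eye_record(record: EyeRecord) -> list[str]:
    """Cross-check the injection-site label against the geometry.

    In the canonical frame a superior injection site means the retinotomy
    sits above the VS centerline (vs_reference_y < retinotomy.y).  A
    mismatch is reported as a warning string, not an error: proximal is
    always computed geometrically from vs_reference_y.
    """
    msgs: list[str] = []
    geometric_site = (
        "superior" if record.vs_reference_y < record.retinotomy.y else "inferior"
    )
    if geometric_site != record.injection_site:
        msgs.append(
            f"eye {record.eye_id}: injection_site label {record.injection_site!r} "
            f"inconsistent with geometry (retinotomy is {geometric_site} of the VS)"
        )
    return msgs


def compute_bleb_metrics(record: EyeRecord) -> BlebMetrics:
    """Compute all per-bleb metrics for a canonical eye record."""
    try:
        warns = validate_eye_record(record)
        with _warnings.catch_warnings(record=True) as caught:
            _warnings.simplefilter("always", AnnotationWarning)
            p_prox, p_dist = vertical_extents(
                record.outline, record.retinotomy, record.vs_reference_y
            )
            a_prox, a_dist = area_split(
                record.outline, record.retinotomy, record.vs_reference_y
            )
        warns.extend(
            f"eye {record.eye_id}: {w.message}"
            for w in caught
            if issubclass(w.category, AnnotationWarning)
        )
        a_v = vertical_anisotropy(p_prox, p_dist)
        if a_v is None:
            warns.append(f"eye {record.eye_id}: a_v undefined (p_dist = 0)")
        fit = fit_ellipse(record.outline)
        return BlebMetrics(
            p_prox=p_prox,
            p_dist=p_dist,
            a_v=a_v,
            area_prox=a_prox,
            area_dist=a_dist,
            area_anisotropy=area_anisotropy(a_prox, a_dist),
            eccentricity=fit.eccentricity,
            tilt=long_axis_tilt(fit),
            propagation_class=classify_propagation(a_v),
            warnings=warns,
        )
    except BlebMorphError as exc:
        raise type(exc)(f"eye {record.eye_id}: {exc}") from exc


# --- outline I/O -----------------------------------------------------------

def read_outline(path: str | Path) -> BlebOutline:
    """Read an outline from CSV (``x,y`` header) or GeoJSON Polygon.

    GeoJSON polygons use the first (exterior) ring only; holes are
    rejected.  The format is inferred from the file suffix.
    """
    path = Path(path)
    if path.suffix.lower() == ".csv":
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None or [
                f.strip() for f in reader.fieldnames[:2]
            ] != ["x", "y"]:
                raise ValidationError(f"{path}: outline CSV must have header 'x,y'")
            verts = [(float(row["x"]), float(row["y"])) for row in reader]
        return BlebOutline(verts)
    if path.suffix.lower() in (".geojson", ".json"):
        obj = json.loads(path.read_text())
        if obj.get("type") == "Feature":
            obj = obj["geometry"]
        if obj.get("type") != "Polygon":
            raise ValidationError(f"{path}: GeoJSON geometry must be a Polygon")
        rings = obj["coordinates"]
        if len(rings) > 1:
            raise ValidationError(f"{path}: polygons with holes are not supported")
        return BlebOutline(rings[0])
    raise ValidationError(f"{path}: unknown outline format {path.suffix!r}")


def write_outline(outline: BlebOutline, path: str | Path) -> Path:
    """Write an outline as GeoJSON Polygon or CSV, by file suffix.

    Coordinates are written with 12 significant digits so CSV round-trips
    are exact at that precision.
    """
    path = Path(path)
    if path.suffix.lower() == ".csv":
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["x", "y"])
            for vx, vy in outline.vertices:
                writer.writerow([f"{vx:.12g}", f"{vy:.12g}"])
        return path
    ring = [[float(f"{vx:.12g}"), float(f"{vy:.12g}")] for vx, vy in outline.vertices]
    ring.append(ring[0])
    obj = {"type": "Polygon", "coordinates": [ring]}
    path.write_text(json.dumps(obj))
    return path
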