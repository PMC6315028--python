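"""Scene-object inventories: LabelMe parsing, rasterization, geometry, filters.

A scene inventory couples an image's dimensions with its manually outlined
object polygons. All derived geometry is expressed as proportions of image
width/height so downstream metrics are resolution-independent; pixels use
the top-left origin, x rightward, y downward, 0-based, half-open convention.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from lxml import etree

logger = logging.getLogger(__name__)

__all__ = [
    "SceneImage",
    "SceneObject",
    "SceneInventory",
    "parse_labelme",
    "to_labelme_xml",
    "rasterize_polygon",
    "object_geometry",
    "filter_objects",
    "object_count_map",
    "resample_nearest",
]

#: canonical long side in pixels for study stimuli
CANONICAL_LONG_SIDE = 512
#: minimum equivalent diameter (px) for an outline to count as an object
MIN_OBJECT_DIAMETER = 50

# names treated as scene surfaces rather than objects
SPACE_DEFINING_NAMES = frozenset(
    {"wall", "ceiling", "floor", "sky", "ground", "road surface"}
)


@dataclass
class SceneImage:
    image_id: str
    category: str
    width: int
    height: int
    role: str = "high"  # high | low | medium_foil
    memorability_hr: float | None = None
    memorability_fa: float | None = None

    def __post_init__(self):
        if self.width < 1 or self.height < 1:
            raise ValueError("image dimensions must be >= 1")
        for v in (self.memorability_hr, self.memorability_fa):
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValueError("memorability values must lie in [0, 1]")

    def validate_canonical(self, long_side: int = CANONICAL_LONG_SIDE) -> None:
        if max(self.width, self.height) != long_side:
            raise ValueError(
                f"{self.image_id}: longest side {max(self.width, self.height)} "
                f"!= canonical {long_side}"
            )


@dataclass
class SceneObject:
    """A named polygon outline plus geometry derived from its raster mask."""

    object_id: str
    name: str
    polygon: np.ndarray  # (k, 2) float vertices in pixel coordinates
    space_defining: bool = False
    # derived (filled by object_geometry)
    mask: np.ndarray | None = field(default=None, repr=False)
    centroid: tuple[float, float] | None = None  # image-proportion units
    bbox: tuple[float, float, float, float] | None = None  # half-open px box
    bounding_ellipse: tuple[float, float, float, float] | None = None  # cx,cy,w,h prop
    equivalent_diameter: float | None = None  # px

    def __post_init__(self):
        self.polygon = np.asarray(self.polygon, dtype=float)
        if self.polygon.ndim != 2 or self.polygon.shape[1] != 2 or len(self.polygon) < 3:
            raise ValueError(
                f"object {self.name!r}: polygon must have >= 3 (x, y) vertices"
            )


@dataclass
class SceneInventory:
    image: SceneImage
    objects: list[SceneObject]
    filtered_object_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        ids = [o.object_id for o in self.objects]
        if len(set(ids)) != len(ids):
            raise ValueError("object_ids must be unique within an inventory")

    def object_by_id(self, object_id: str) -> SceneObject:
        for o in self.objects:
            if o.object_id == object_id:
                return o
        raise KeyError(object_id)

    @property
    def filtered_objects(self) -> list[SceneObject]:
        keep = set(self.filtered_object_ids)
        return [o for o in self.objects if o.object_id in keep]


# ---------------------------------------------------------------------------
# LabelMe parsing


def parse_labelme(
    xml_source,
    image_dims: tuple[int, int],
    image_id: str | None = None,
    category: str = "",
    compute_geometry: bool = True,
    **image_kwargs,
) -> SceneInventory:
    """Parse a LabelMe annotation document into a SceneInventory.

    ``xml_source`` may be a path, bytes, or an XML string. One SceneObject is
    created per non-deleted ``<object>`` in document order; vertices falling
    outside the image are clipped to its bounds (with a warning). Objects
    whose name matches a space-defining surface are flagged as such.
    """
    width, height = image_dims
    try:
        if isinstance(xml_source, (str, bytes)) and (
            isinstance(xml_source, bytes) or xml_source.lstrip().startswith("<")
        ):
            data = xml_source.encode() if isinstance(xml_source, str) else xml_source
            root = etree.fromstring(data)
        else:
            root = etree.parse(str(xml_source)).getroot()
    except etree.XMLSyntaxError as exc:
        raise ValueError(f"malformed LabelMe XML: {exc}") from exc

    if image_id is None:
        fn = root.findtext("filename")
        image_id = fn.strip() if fn else "unknown"

    objects: list[SceneObject] = []
    for i, obj_el in enumerate(root.iterfind("object")):
        deleted = (obj_el.findtext("deleted") or "0").strip()
        if deleted not in {"", "0"}:
            continue
        name = (obj_el.findtext("name") or "").strip()
        poly_el = obj_el.find("polygon")
        if poly_el is None:
            raise ValueError(f"object {name!r}: missing <polygon> element")
        pts = []
        for pt in poly_el.iterfind("pt"):
            x = float(pt.findtext("x"))
            y = float(pt.findtext("y"))
            pts.append((x, y))
        if len(pts) < 3:
            raise ValueError(f"object {name!r}: polygon has fewer than 3 points")
        verts = np.array(pts, dtype=float)
        clipped = np.column_stack(
            [np.clip(verts[:, 0], 0, width), np.clip(verts[:, 1], 0, height)]
        )
        if not np.array_equal(clipped, verts):
            logger.warning(
                "object %r: vertices outside %dx%d image clipped", name, width, height
            )
        objects.append(
            SceneObject(
                object_id=f"{image_id}:obj{i}",
                name=name,
                polygon=clipped,
                space_defining=name.casefold() in SPACE_DEFINING_NAMES,
            )
        )

    image = SceneImage(image_id=image_id, category=category, width=width,
                       height=height, **image_kwargs)
    inv = SceneInventory(image=image, objects=objects)
    if compute_geometry:
        for o in inv.objects:
            object_geometry(o, (width, height))
        inv.filtered_object_ids = filter_objects(inv)
    return inv


def to_labelme_xml(inventory: SceneInventory) -> str:
    """Serialize an inventory back to LabelMe XML (round-trip safe)."""
    root = etree.Element("annotation")
    etree.SubElement(root, "filename").text = inventory.image.image_id
    for obj in inventory.objects:
        el = etree.SubElement(root, "object")
        etree.SubElement(el, "name").text = obj.name
        etree.SubElement(el, "deleted").text = "0"
        poly = etree.SubElement(el, "polygon")
        for x, y in obj.polygon:
            pt = etree.SubElement(poly, "pt")
            etree.SubElement(pt, "x").text = repr(float(x))
            etree.SubElement(pt, "y").text = repr(float(y))
    return etree.tostring(root, pretty_print=True, encoding="unicode")


# ---------------------------------------------------------------------------
# Rasterization and geometry


def rasterize_polygon(polygon, width: int, height: int) -> np.ndarray:
    """Rasterize a polygon to a boolean (height, width) mask.

    A pixel is inside iff its center (x + 0.5, y + 0.5) is inside the
    polygon under the even-odd (ray casting) rule.
    """
    if width < 1 or height < 1:
        raise ValueError("dimensions must be positive")
    verts = np.asarray(polygon, dtype=float)
    if verts.ndim != 2 or len(verts) < 3:
        raise ValueError("polygon must have >= 3 vertices")

    # restrict work to the polygon's bounding box
    x0 = max(int(math.floor(verts[:, 0].min())), 0)
    x1 = min(int(math.ceil(verts[:, 0].max())), width)
    y0 = max(int(math.floor(verts[:, 1].min())), 0)
    y1 = min(int(math.ceil(verts[:, 1].max())), height)
    mask = np.zeros((height, width), dtype=bool)
    if x1 <= x0 or y1 <= y0:
        raise ValueError("degenerate polygon: empty mask after rasterization")

    px = np.arange(x0, x1) + 0.5
    py = np.arange(y0, y1) + 0.5
    gx = px[np.newaxis, :]
    gy = py[:, np.newaxis]
    inside = np.zeros((y1 - y0, x1 - x0), dtype=bool)
    n = len(verts)
    for i in range(n):
        xa, ya = verts[i]
        xb, yb = verts[(i + 1) % n]
        if ya == yb:
            continue
        crosses = (ya > gy) != (yb > gy)
        with np.errstate(invalid="ignore"):
            x_at = (xb - xa) * (gy - ya) / (yb - ya) + xa
        inside ^= crosses & (gx < x_at)
    if not inside.any():
        raise ValueError("degenerate polygon: empty mask after rasterization")
    mask[y0:y1, x0:x1] = inside
    return mask


def object_geometry(obj: SceneObject, image_dims: tuple[int, int]) -> SceneObject:
    """Fill the derived geometry of ``obj`` from its rasterized mask.

    centroid: mean of mask pixel centers, in image-proportion units.
    bbox: tight half-open pixel box around the mask.
    bounding_ellipse: axis-aligned ellipse inscribed in the bbox
    (center = bbox center, full axes = bbox extents), proportion units —
    the "true ellipse" drawn-object ellipses are compared against.
    equivalent_diameter: diameter of the circle with the mask's area.
    """
    width, height = image_dims
    if obj.mask is None:
        obj.mask = rasterize_polygon(obj.polygon, width, height)
    mask = obj.mask
    if not mask.any():
        raise ValueError(f"object {obj.name!r}: empty mask")
    ys, xs = np.nonzero(mask)
    cx = float((xs + 0.5).mean()) / width
    cy = float((ys + 0.5).mean()) / height
    x0, x1 = int(xs.min()), int(xs.max()) + 1
    y0, y1 = int(ys.min()), int(ys.max()) + 1
    obj.centroid = (cx, cy)
    obj.bbox = (float(x0), float(y0), float(x1), float(y1))
    obj.bounding_ellipse = (
        (x0 + x1) / 2.0 / width,
        (y0 + y1) / 2.0 / height,
        (x1 - x0) / width,
        (y1 - y0) / height,
    )
    obj.equivalent_diameter = 2.0 * math.sqrt(mask.sum() / math.pi)
    return obj


def filter_objects(
    inventory: SceneInventory,
    min_diameter_px: float = MIN_OBJECT_DIAMETER,
    exclude_space_defining: bool = True,
) -> list[str]:
    """Object ids passing the inclusion rules, in inventory order.

    Keeps objects whose mask equivalent diameter is >= ``min_diameter_px``
    (boundary inclusive) and, by default, drops space-defining surfaces
    (wall, ceiling, ...).
    """
    kept = []
    for obj in inventory.objects:
        if obj.equivalent_diameter is None:
            raise ValueError(f"object {obj.name!r}: geometry not computed")
        if exclude_space_defining and obj.space_defining:
            continue
        if obj.equivalent_diameter >= min_diameter_px:
            kept.append(obj.object_id)
    if not kept:
        logger.info("inventory %s: no objects pass filters", inventory.image.image_id)
    return kept


# ---------------------------------------------------------------------------
# Count maps


def resample_nearest(values: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Nearest-neighbor resample of a 2-D array to (height, width) ``shape``."""
    h, w = values.shape
    th, tw = shape
    rows = np.minimum((np.arange(th) + 0.5) * h / th, h - 1).astype(int)
    cols = np.minimum((np.arange(tw) + 0.5) * w / tw, w - 1).astype(int)
    return values[np.ix_(rows, cols)]


def minmax_scale(values: np.ndarray) -> np.ndarray:
    """Min-max scale to [0, 1]; a (numerically) constant array maps to all
    zeros (logged) rather than amplifying floating-point dust."""
    lo, hi = float(np.min(values)), float(np.max(values))
    if hi - lo <= 1e-9 * max(abs(hi), abs(lo), 1.0):
        logger.info("degenerate min-max scaling: constant map -> zeros")
        return np.zeros_like(values, dtype=float)
    return (values - lo) / (hi - lo)


def object_count_map(
    inventories, shape: tuple[int, int] | None = None, resample: bool = True
) -> np.ndarray:
    """Per-pixel count of filtered-object masks over images, min-max scaled.

    All inventories must share ``shape`` (height, width); if not and
    ``resample`` is true, masks are nearest-neighbor resampled.
    """
    inventories = list(inventories)
    if not inventories:
        raise ValueError("no inventories")
    if shape is None:
        shape = (inventories[0].image.height, inventories[0].image.width)
    counts = np.zeros(shape, dtype=float)
    for inv in inventories:
        native = (inv.image.height, inv.image.width)
        for obj in inv.filtered_objects:
            m = obj.mask
            if native != shape:
                if not resample:
                    raise ValueError(
                        f"inventory {inv.image.image_id}: resolution {native} != {shape}"
                    )
                m = resample_nearest(m.astype(float), shape) > 0.5
            counts += m
    return minmax_scale(counts)
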