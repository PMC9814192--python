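"""Calibrated 2-D cell segmentations: label-mask tracing, GeoJSON
interchange, and geometric validation.

Conventions
-----------
Coordinates are pixel units in the y-down image frame (origin top-left,
``x = column``, ``y = row``); every reported metric is converted to nm or
µm through ``pixel_size_nm``.  Exterior rings are stored counter-clockwise
(positive shoelace area), interior holes clockwise.  Organelle components
smaller than 4 pixels are discarded as segmentation specks.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import shapely
import shapely.affinity
from shapely.geometry import LinearRing, Polygon, mapping, shape
from shapely.geometry.polygon import orient
from skimage import measure

from .errors import FormatError, GeometryError, MissingRegionError

log = logging.getLogger(__name__)

ORGANELLE_CLASSES = ("cytoplasm", "nucleus", "er", "mito")
MIN_COMPONENT_PX = 4


@dataclass(frozen=True)
class ClassMap:
    """Maps integer label values of a mask to segmentation classes.

    At most one label may map to ``cytoplasm`` and one to ``nucleus``;
    several labels may map to ``er`` or ``mito``.
    """

    labels: dict[int, str]

    def __post_init__(self) -> None:
        for value, cls in self.labels.items():
            if cls not in ORGANELLE_CLASSES:
                raise FormatError(f"unknown class {cls!r} for label {value}")
        for unique_cls in ("cytoplasm", "nucleus"):
            n = sum(1 for c in self.labels.values() if c == unique_cls)
            if n > 1:
                raise FormatError(f"more than one {unique_cls} label in class map")

    def values_for(self, cls: str) -> list[int]:
        return sorted(v for v, c in self.labels.items() if c == cls)


@dataclass
class CellGeometry:
    """One neuronal soma: cytoplasm ring (with optional nucleus hole),
    plasma membrane, and lists of ER and mitochondrion polygons.

    All polygons are in pixel coordinates; ``pixel_size_nm`` calibrates
    them.  ``flags`` holds per-polygon annotations such as
    ``edge_truncated`` keyed by ``(class, index)``.
    """

    cell_id: str
    group: str
    pixel_size_nm: float
    cytoplasm: Polygon
    er: list[Polygon] = field(default_factory=list)
    mito: list[Polygon] = field(default_factory=list)
    flags: dict[tuple[str, int], set[str]] = field(default_factory=dict)

    @property
    def plasma_membrane(self) -> LinearRing:
        """The cell's outer boundary (identical to the cytoplasm exterior)."""
        return LinearRing(self.cytoplasm.exterior.coords)

    @property
    def nucleus(self) -> LinearRing | None:
        rings = list(self.cytoplasm.interiors)
        return LinearRing(rings[0].coords) if rings else None

    def scaled_to_nm(self, geom):
        """Return ``geom`` scaled from pixel to nm coordinates."""
        s = self.pixel_size_nm
        return shapely.affinity.scale(geom, xfact=s, yfact=s, origin=(0, 0))

    def cytoplasm_area_nm2(self) -> float:
        return self.cytoplasm.area * self.pixel_size_nm**2


class Violation(NamedTuple):
    """One named invariant failure found by :func:`validate_geometry`."""

    kind: str
    cls: str
    index: int
    detail: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.kind}({self.cls}[{self.index}]): {self.detail}"


def _orient_polygon(poly: Polygon) -> Polygon:
    """Exterior CCW (positive shoelace), holes CW."""
    return orient(poly, sign=1.0)


def _trace_component(mask: np.ndarray) -> np.ndarray | None:
    """Sub-pixel boundary of a binary component via marching squares at the
    0.5 iso-level.  Returns an (n, 2) array of (x, y) vertices or None if no
    closed contour is found."""
    padded = np.pad(mask.astype(float), 1)
    contours = measure.find_contours(padded, 0.5)
    if not contours:
        return None
    # longest contour is the exterior; subtract the pad offset, swap to (x, y)
    ext = max(contours, key=len)
    return ext[:, ::-1] - 1.0


def load_mask(
    label_image: np.ndarray,
    class_map: ClassMap,
    pixel_size_nm: float,
    cell_id: str,
    group: str = "",
) -> CellGeometry:
    """Convert an integer label mask into a :class:`CellGeometry`.

    Each 8-connected component of each organelle class becomes one polygon
    traced at the 0.5 iso-level.  Components touching the image frame are
    clipped there and flagged ``edge_truncated``.

    Raises
    ------
    FormatError
        If the mask contains a label value absent from ``class_map``.
    MissingRegionError
        If no cytoplasm-labelled pixels are present.
    GeometryError
        If a traced polygon self-intersects, naming the component.
    """
    if pixel_size_nm <= 0:
        raise FormatError("pixel_size_nm must be positive")
    label_image = np.asarray(label_image)
    present = set(np.unique(label_image).tolist()) - {0}
    unknown = present - set(class_map.labels)
    if unknown:
        raise FormatError(f"mask contains unknown label values {sorted(unknown)}")

    def class_mask(cls: str) -> np.ndarray:
        values = class_map.values_for(cls)
        return np.isin(label_image, values) if values else np.zeros_like(label_image, bool)

    cyto_mask = class_mask("cytoplasm")
    nuc_mask = class_mask("nucleus")
    if not cyto_mask.any():
        raise MissingRegionError("no cytoplasm-labelled pixels in mask")

    # The cytoplasm outer ring encloses everything including the nucleus.
    outer = _trace_component(cyto_mask | nuc_mask | class_mask("er") | class_mask("mito"))
    holes: list[np.ndarray] = []
    if nuc_mask.any():
        nuc_ring = _trace_component(nuc_mask)
        if nuc_ring is not None:
            holes.append(nuc_ring[::-1])  # holes clockwise
    cytoplasm = _orient_polygon(Polygon(outer, holes))
    if not cytoplasm.is_valid:
        raise GeometryError("traced cytoplasm polygon is invalid")

    flags: dict[tuple[str, int], set[str]] = {}
    organelles: dict[str, list[Polygon]] = {"er": [], "mito": []}
    h, w = label_image.shape
    for cls in ("er", "mito"):
        mask = class_mask(cls)
        labelled = measure.label(mask, connectivity=2)  # 8-connectivity
        for comp_id in range(1, labelled.max() + 1):
            comp = labelled == comp_id
            n_px = int(comp.sum())
            if n_px < MIN_COMPONENT_PX:
                log.warning(
                    "%s: discarding %s component of %d px (< %d)",
                    cell_id, cls, n_px, MIN_COMPONENT_PX,
                )
                continue
            ring = _trace_component(comp)
            if ring is None:
                continue
            poly = Polygon(ring)
            if not poly.is_valid:
                raise GeometryError(
                    f"{cell_id}: traced {cls} component {comp_id} self-intersects"
                )
            idx = len(organelles[cls])
            organelles[cls].append(_orient_polygon(poly))
            rows, cols = np.nonzero(comp)
            if rows.min() == 0 or cols.min() == 0 or rows.max() == h - 1 or cols.max() == w - 1:
                flags.setdefault((cls, idx), set()).add("edge_truncated")

    return CellGeometry(
        cell_id=cell_id,
        group=group,
        pixel_size_nm=float(pixel_size_nm),
        cytoplasm=cytoplasm,
        er=organelles["er"],
        mito=organelles["mito"],
        flags=flags,
    )


def validate_geometry(cell: CellGeometry) -> list[Violation]:
    """Check every :class:`CellGeometry` invariant; empty list iff valid.

    Checks: positive calibration; each polygon simple, closed, with positive
    area; organelle interiors pairwise disjoint (within and across classes);
    every organelle inside the cytoplasm ring and outside the nucleus hole.
    """
    out: list[Violation] = []
    if cell.pixel_size_nm <= 0:
        out.append(Violation("calibration", "cell", 0, "pixel_size_nm <= 0"))

    def check_poly(poly: Polygon, cls: str, idx: int) -> bool:
        if not poly.is_valid:
            out.append(Violation("invalid-polygon", cls, idx, shapely.is_valid_reason(poly)))
            return False
        if poly.area <= 0:
            out.append(Violation("zero-area", cls, idx, "polygon area <= 0"))
            return False
        return True

    ok_cyto = check_poly(cell.cytoplasm, "cytoplasm", 0)
    tagged = [("er", i, p) for i, p in enumerate(cell.er)]
    tagged += [("mito", i, p) for i, p in enumerate(cell.mito)]
    ok = [check_poly(p, cls, i) for cls, i, p in tagged]

    # bbox prefilter keeps the pairwise interior-overlap check near-linear
    good = [t for t, o in zip(tagged, ok) if o]
    if good:
        tree = shapely.STRtree([p for _, _, p in good])
        for ia, ib in tree.query([p for _, _, p in good], predicate="intersects").T:
            if ia >= ib:
                continue
            cls_a, i_a, p_a = good[ia]
            cls_b, i_b, p_b = good[ib]
            if p_a.relate_pattern(p_b, "T********"):  # interiors intersect
                out.append(
                    Violation(
                        "overlap", cls_a, i_a, f"overlap({cls_a}[{i_a}],{cls_b}[{i_b}])"
                    )
                )
    if ok_cyto:
        for (cls, i, p), good in zip(tagged, ok):
            if good and not cell.cytoplasm.covers(p):
                out.append(
                    Violation("outside-cytoplasm", cls, i,
                              "polygon not inside cytoplasm ring / outside nucleus")
                )
    return out


def read_mask_tiff(
    tiff_path,
    class_map_path,
    pixel_size_nm: float,
    cell_id: str,
    group: str = "",
) -> CellGeometry:
    """Load a single-channel integer label TIFF with its class-map config.

    The config (TOML or YAML) maps class names to label values, e.g.::

        [labels]
        cytoplasm = 1
        nucleus = 2
        er = 3
        mito = 4
    """
    import tifffile

    label_image = tifffile.imread(tiff_path)
    if label_image.ndim != 2:
        raise FormatError(f"{tiff_path}: expected a single-channel 2-D label mask")
    path = str(class_map_path)
    if path.endswith((".yaml", ".yml")):
        import yaml

        with open(path) as fh:
            doc = yaml.safe_load(fh)
    else:
        import tomllib

        with open(path, "rb") as fh:
            doc = tomllib.load(fh)
    labels = doc.get("labels")
    if not isinstance(labels, dict):
        raise FormatError(f"{class_map_path}: missing [labels] table")
    class_map = ClassMap({int(v): str(k) for k, v in labels.items()})
    return load_mask(label_image.astype(np.int64), class_map, pixel_size_nm,
                     cell_id, group)


# ---------------------------------------------------------------------------
# GeoJSON interchange
# ---------------------------------------------------------------------------

def write_geometry(cell: CellGeometry, path) -> None:
    """Serialize a cell as a GeoJSON FeatureCollection.

    One Feature per polygon with ``properties.class``; ``metadata`` carries
    ``cell_id``, ``group`` and ``pixel_size_nm``; per-polygon flags are kept
    in ``properties.flags``.
    """
    features = []

    def feature(poly: Polygon, cls: str, idx: int) -> dict:
        props = {"class": cls, "index": idx}
        fl = cell.flags.get((cls, idx))
        if fl:
            props["flags"] = sorted(fl)
        return {"type": "Feature", "properties": props, "geometry": mapping(poly)}

    features.append(feature(cell.cytoplasm, "cytoplasm", 0))
    for i, p in enumerate(cell.er):
        features.append(feature(p, "er", i))
    for i, p in enumerate(cell.mito):
        features.append(feature(p, "mito", i))
    doc = {
        "type": "FeatureCollection",
        "metadata": {
            "cell_id": cell.cell_id,
            "group": cell.group,
            "pixel_size_nm": cell.pixel_size_nm,
        },
        "features": features,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def read_geometry(path) -> CellGeometry:
    """Read a GeoJSON FeatureCollection written by :func:`write_geometry`.

    Raises :class:`FormatError` on missing calibration/metadata and
    :class:`GeometryError` listing invariant failures.
    """
    with open(path) as fh:
        doc = json.load(fh)
    meta = doc.get("metadata") or {}
    if "pixel_size_nm" not in meta:
        raise FormatError(f"{path}: missing pixel_size_nm calibration in metadata")
    cytoplasm = None
    er: list[Polygon] = []
    mito: list[Polygon] = []
    flags: dict[tuple[str, int], set[str]] = {}
    for feat in doc.get("features", []):
        cls = feat.get("properties", {}).get("class")
        geom = shape(feat["geometry"])
        if cls == "cytoplasm":
            cytoplasm = geom
        elif cls == "er":
            er.append(geom)
        elif cls == "mito":
            mito.append(geom)
        elif cls == "nucleus":
            # tolerated as a standalone feature: folded into the cytoplasm hole
            if cytoplasm is not None:
                cytoplasm = Polygon(
                    cytoplasm.exterior.coords,
                    [geom.exterior.coords[::-1]],
                )
        else:
            raise FormatError(f"{path}: unknown feature class {cls!r}")
        fl = feat.get("properties", {}).get("flags")
        if fl and cls in ("er", "mito"):
            idx = len(er) - 1 if cls == "er" else len(mito) - 1
            flags[(cls, idx)] = set(fl)
    if cytoplasm is None:
        raise MissingRegionError(f"{path}: no cytoplasm feature")
    cell = CellGeometry(
        cell_id=str(meta.get("cell_id", "")),
        group=str(meta.get("group", "")),
        pixel_size_nm=float(meta["pixel_size_nm"]),
        cytoplasm=cytoplasm,
        er=er,
        mito=mito,
        flags=flags,
    )
    violations = validate_geometry(cell)
    if violations:
        raise GeometryError(
            f"{path}: invalid geometry: " + "; ".join(str(v) for v in violations)
        )
    return cell


def rasterize(poly: Polygon, shape_hw: tuple[int, int]) -> np.ndarray:
    """Rasterize a pixel-space polygon back onto a grid (pixel centres
    covered by the polygon).  Used by round-trip consistency checks."""
    h, w = shape_hw
    yy, xx = np.mgrid[0:h, 0:w]
    pts = shapely.points(np.column_stack([xx.ravel(), yy.ravel()]))
    inside = shapely.covers(poly, pts)
    return inside.reshape(h, w)
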