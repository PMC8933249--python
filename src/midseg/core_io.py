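"""Core data model, NIfTI I/O and geometry primitives.

Conventions used throughout the package
---------------------------------------
* Volumes are scalar 3D arrays in axis order ``(x, y, slice)``.
* Voxel indices are 0-based; pixel centers sit at integer coordinates, so a
  pixel ``(i, j)`` occupies the square ``[i-1/2, i+1/2] x [j-1/2, j+1/2]``.
* Contours are closed subpixel polygons per slice, vertices as ``(x, y)``.
* Rasterization counts pixel centers inside **or on** the polygon;
  ``mask_to_contour`` returns the exact pixel-boundary polygon (vertices at
  half-integer coordinates), so ``contour area == pixel count`` and the
  contour<->mask round trip is lossless.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

import nibabel as nib
import numpy as np
import shapely
from scipy import ndimage
from shapely.geometry import Polygon

from .errors import DimensionError, FormatError, GeometryError

STRUCTURE_LABELS = ("NM", "SN", "RN", "STN", "VTA", "BG")
HEMISPHERES = ("L", "R")


# ---------------------------------------------------------------------------
# Volume container
# ---------------------------------------------------------------------------

@dataclass
class Volume3D:
    """Scalar 3D image with voxel spacing, world affine and acquisition meta.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
    spacing : (dx, dy, dz) in mm, strictly positive
    affine : 4x4 voxel->world mapping; defaults to ``diag(spacing, 1)``
    meta : free-form acquisition metadata (TE in ms, units, ...)
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    affine: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise DimensionError(f"expected 3D data, got {self.data.ndim}D")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive numbers, got {self.spacing}")
        if self.affine is None:
            self.affine = np.diag(list(self.spacing) + [1.0])
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume(self) -> float:
        """Voxel volume in mm^3."""
        return float(np.prod(self.spacing))

    def copy(self, data: np.ndarray | None = None) -> "Volume3D":
        return Volume3D(
            data=self.data.copy() if data is None else np.asarray(data),
            spacing=self.spacing,
            affine=self.affine.copy(),
            meta=dict(self.meta),
        )


def read_volume(path: str | Path) -> Volume3D:
    """Read a NIfTI-1/2 volume.

    Raises :class:`FormatError` for unreadable files and
    :class:`DimensionError` for non-3D images.
    """
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises a zoo of errors for bad headers
        raise FormatError(f"cannot read NIfTI file {path}: {exc}") from exc
    if img.ndim != 3:
        raise DimensionError(f"{path}: expected a 3D volume, got {img.ndim}D")
    data = np.asanyarray(img.dataobj)
    zooms = img.header.get_zooms()[:3]
    return Volume3D(data=data, spacing=tuple(float(z) for z in zooms), affine=img.affine)


def write_volume(vol: Volume3D, path: str | Path) -> None:
    img = nib.Nifti1Image(vol.data, vol.affine)
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# Contours and structure sets
# ---------------------------------------------------------------------------

@dataclass
class Contour:
    """Ordered closed subpixel polygon on one slice."""

    slice_index: int
    vertices: np.ndarray  # (n, 2) float, (x, y)
    closed: bool = True

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 2)
        if len(self.vertices) < 3:
            raise GeometryError("a contour needs at least 3 vertices")
        # drop an explicitly repeated closing vertex
        if np.allclose(self.vertices[0], self.vertices[-1]) and len(self.vertices) > 3:
            self.vertices = self.vertices[:-1]
        self.slice_index = int(self.slice_index)

    def polygon(self) -> Polygon:
        return Polygon(self.vertices)

    @property
    def area(self) -> float:
        """Shoelace area (always positive)."""
        x, y = self.vertices[:, 0], self.vertices[:, 1]
        return float(abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))) / 2.0)

    @property
    def perimeter(self) -> float:
        d = np.diff(np.vstack([self.vertices, self.vertices[:1]]), axis=0)
        return float(np.hypot(d[:, 0], d[:, 1]).sum())

    def translated(self, dx: float, dy: float, dz: int = 0) -> "Contour":
        return Contour(self.slice_index + dz, self.vertices + [dx, dy])


class StructureSet:
    """Contours grouped by anatomical label and hemisphere.

    Keys are ``(label, hemisphere)`` with label in NM/SN/RN/STN/VTA/BG and
    hemisphere "L"/"R".
    """

    def __init__(self, structures: Mapping[tuple[str, str], list[Contour]] | None = None):
        self.structures: dict[tuple[str, str], list[Contour]] = {}
        if structures:
            for key, contours in structures.items():
                for c in contours:
                    self.add(key[0], key[1], c)

    def add(self, label: str, hemisphere: str, contour: Contour) -> None:
        if label not in STRUCTURE_LABELS:
            raise ValueError(f"unknown structure label {label!r}")
        if hemisphere not in HEMISPHERES:
            raise ValueError(f"unknown hemisphere {hemisphere!r}")
        self.structures.setdefault((label, hemisphere), []).append(contour)

    def get(self, label: str, hemisphere: str) -> list[Contour]:
        return sorted(self.structures.get((label, hemisphere), []),
                      key=lambda c: c.slice_index)

    def keys(self):
        return self.structures.keys()

    def __iter__(self) -> Iterator[tuple[tuple[str, str], list[Contour]]]:
        return iter(self.structures.items())

    def __len__(self) -> int:
        return sum(len(v) for v in self.structures.values())

    def slice_range(self, label: str, hemisphere: str) -> tuple[int, int]:
        contours = self.get(label, hemisphere)
        if not contours:
            raise KeyError((label, hemisphere))
        idx = [c.slice_index for c in contours]
        return min(idx), max(idx)

    def mask(self, label: str, hemisphere: str, grid_shape: tuple[int, int, int]) -> np.ndarray:
        """Rasterize one structure into a 3D boolean mask."""
        out = np.zeros(grid_shape, dtype=bool)
        for c in self.get(label, hemisphere):
            if 0 <= c.slice_index < grid_shape[2]:
                out[:, :, c.slice_index] |= contour_to_mask(c, grid_shape[:2])
        return out

    def combined_mask(self, label: str, grid_shape: tuple[int, int, int]) -> np.ndarray:
        out = np.zeros(grid_shape, dtype=bool)
        for hemi in HEMISPHERES:
            if (label, hemi) in self.structures:
                out |= self.mask(label, hemi, grid_shape)
        return out

    def validate(self, grid_shape: tuple[int, int] | None = None) -> None:
        """Check per-structure slice monotonicity and the BG/NM exclusion rule."""
        for (label, hemi), contours in self.structures.items():
            idx = [c.slice_index for c in sorted(contours, key=lambda c: c.slice_index)]
            if len(idx) != len(set(idx)):
                raise GeometryError(f"{label}/{hemi}: duplicate slice indices {idx}")
        if grid_shape is not None:
            for hemi in HEMISPHERES:
                nm = {c.slice_index: c for c in self.get("NM", hemi)}
                for bg in self.get("BG", hemi):
                    if bg.slice_index in nm:
                        m_bg = contour_to_mask(bg, grid_shape)
                        m_nm = contour_to_mask(nm[bg.slice_index], grid_shape)
                        if (m_bg & m_nm).any():
                            raise GeometryError(
                                f"BG overlaps NM on slice {bg.slice_index} ({hemi})")

    # -- JSON serialization -------------------------------------------------

    def to_json(self, path: str | Path | None = None) -> str:
        records = []
        for (label, hemi), contours in sorted(self.structures.items()):
            for c in sorted(contours, key=lambda c: c.slice_index):
                records.append({
                    "label": label,
                    "hemisphere": hemi,
                    "slice": c.slice_index,
                    "vertices": np.round(c.vertices, 4).tolist(),
                })
        text = json.dumps(records, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "StructureSet":
        if isinstance(source, Path) or (isinstance(source, str) and "\n" not in source
                                        and source.strip().endswith(".json")):
            source = Path(source).read_text()
        out = cls()
        for rec in json.loads(source):
            out.add(rec["label"], rec["hemisphere"],
                    Contour(rec["slice"], np.asarray(rec["vertices"])))
        return out


@dataclass
class LabelMask:
    """Integer label volume with a legend mapping label names to values."""

    volume: Volume3D
    legend: dict[str, int]

    def mask(self, label: str) -> np.ndarray:
        return self.volume.data == self.legend[label]


def rasterize_structures(sset: StructureSet, like: Volume3D) -> LabelMask:
    """Rasterize a StructureSet into a label volume on the grid of ``like``.

    Later labels overwrite earlier ones on overlap; hemisphere information is
    collapsed (both hemispheres share one label value).
    """
    data = np.zeros(like.shape, dtype=np.int16)
    legend: dict[str, int] = {}
    next_val = 1
    for label in STRUCTURE_LABELS:
        m = sset.combined_mask(label, like.shape)
        if m.any():
            legend[label] = next_val
            data[m] = next_val
            next_val += 1
    return LabelMask(Volume3D(data, like.spacing, like.affine.copy()), legend)


# ---------------------------------------------------------------------------
# Contour <-> mask
# ---------------------------------------------------------------------------

def contour_to_mask(contour: Contour, grid_shape: tuple[int, int]) -> np.ndarray:
    """Rasterize a closed contour: pixels whose centers are inside or on it.

    Raises :class:`GeometryError` for self-intersecting polygons.
    """
    poly = contour.polygon()
    if not poly.is_valid:
        raise GeometryError("self-intersecting or otherwise invalid polygon")
    nx, ny = grid_shape
    mask = np.zeros((nx, ny), dtype=bool)
    x0 = max(0, int(np.floor(poly.bounds[0])))
    y0 = max(0, int(np.floor(poly.bounds[1])))
    x1 = min(nx - 1, int(np.ceil(poly.bounds[2])))
    y1 = min(ny - 1, int(np.ceil(poly.bounds[3])))
    if x1 < x0 or y1 < y0:
        return mask
    xs, ys = np.meshgrid(np.arange(x0, x1 + 1), np.arange(y0, y1 + 1), indexing="ij")
    hit = shapely.intersects_xy(poly, xs.ravel(), ys.ravel())
    mask[x0:x1 + 1, y0:y1 + 1] = hit.reshape(xs.shape)
    return mask


def mask_to_contour(mask: np.ndarray, slice_index: int = 0,
                    min_area: int = 1) -> list[Contour]:
    """Trace the exact pixel-boundary polygons of a binary mask.

    Each connected region yields one contour whose vertices lie on pixel
    corners (half-integer coordinates); the polygon area equals the pixel
    count exactly. Interior holes are ignored (outer boundary only).
    Contours are returned largest-first.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return []
    # merge vertical runs into rectangles before the union (much cheaper
    # than one box per pixel, same exact outline)
    x0s, y0s, y1s = [], [], []
    for x in np.flatnonzero(mask.any(axis=1)):
        col = mask[x]
        d = np.diff(col.astype(np.int8))
        starts = np.flatnonzero(d == 1) + 1
        ends = np.flatnonzero(d == -1) + 1
        if col[0]:
            starts = np.concatenate([[0], starts])
        if col[-1]:
            ends = np.concatenate([ends, [len(col)]])
        for s, e in zip(starts, ends):
            x0s.append(x)
            y0s.append(s)
            y1s.append(e - 1)
    x0s = np.asarray(x0s, dtype=float)
    boxes = shapely.box(x0s - 0.5, np.asarray(y0s, float) - 0.5,
                        x0s + 0.5, np.asarray(y1s, float) + 0.5)
    merged = shapely.unary_union(boxes, grid_size=0.5)
    if merged.geom_type == "Polygon":
        polys = [merged]
    else:
        polys = list(merged.geoms)
    polys = [p for p in polys if p.area >= min_area - 0.5]
    polys.sort(key=lambda p: p.area, reverse=True)
    out = []
    for p in polys:
        verts = np.asarray(p.exterior.coords)[:-1]
        out.append(Contour(slice_index, verts))
    return out


# ---------------------------------------------------------------------------
# Interpolation primitives
# ---------------------------------------------------------------------------

def zoom_points(points: np.ndarray, factor: float) -> np.ndarray:
    """Map voxel coordinates to the grid produced by :func:`zoom_inplane`."""
    return np.asarray(points, dtype=float) * factor + (factor - 1.0) / 2.0


def unzoom_points(points: np.ndarray, factor: float) -> np.ndarray:
    return (np.asarray(points, dtype=float) - (factor - 1.0) / 2.0) / factor


def zoom_inplane(vol: Volume3D, factor: float, order: int = 3) -> Volume3D:
    """In-plane zoom by ``factor`` (cubic spline), preserving physical extent.

    The output grid follows the pixel-edge convention: input pixel ``i`` maps
    to output coordinate ``factor*i + (factor-1)/2`` (see :func:`zoom_points`).
    """
    if factor < 1:
        raise ValueError(f"zoom factor must be >= 1, got {factor}")
    if factor == 1:
        return vol.copy()
    out = ndimage.zoom(vol.data.astype(float), (factor, factor, 1.0), order=order,
                       mode="nearest", grid_mode=True)
    dx, dy, dz = vol.spacing
    new_spacing = (dx / factor, dy / factor, dz)
    affine = vol.affine.copy()
    affine[:3, 0] /= factor
    affine[:3, 1] /= factor
    v = Volume3D(out, new_spacing, affine, dict(vol.meta))
    return v


def interp_slices(vol: Volume3D, target_dz: float) -> Volume3D:
    """Linearly interpolate along the slice axis to ``target_dz`` spacing.

    ``target_dz`` must divide the source slice thickness (e.g. 2 mm -> 0.167 mm
    is a factor of 12, turning 16 slices into 192). Physical extent is
    preserved: new slice centers tile the same slab.
    """
    dz = vol.spacing[2]
    m = dz / target_dz
    m_int = int(round(m))
    if m_int < 1 or abs(m - m_int) > 1e-3 * m_int:
        raise ValueError(f"target_dz {target_dz} must divide slice thickness {dz}")
    if m_int == 1:
        return vol.copy()
    nz = vol.shape[2]
    # new slice j center at input index coordinate (j + 0.5)/m - 0.5
    zc = (np.arange(nz * m_int) + 0.5) / m_int - 0.5
    data = vol.data.astype(float)
    out = np.empty(vol.shape[:2] + (nz * m_int,), dtype=float)
    lo = np.clip(np.floor(zc).astype(int), 0, nz - 1)
    hi = np.clip(lo + 1, 0, nz - 1)
    w = np.clip(zc - lo, 0.0, 1.0)
    for j in range(len(zc)):
        out[:, :, j] = (1 - w[j]) * data[:, :, lo[j]] + w[j] * data[:, :, hi[j]]
    spacing = (vol.spacing[0], vol.spacing[1], dz / m_int)
    affine = vol.affine.copy()
    affine[:3, 2] /= m_int
    return Volume3D(out, spacing, affine, dict(vol.meta))


def fine_slice_of(coarse_slice: int, factor: int = 12) -> int:
    """Representative interpolated-slice index of a thick slice center."""
    return coarse_slice * factor + factor // 2


def coarse_slice_of(fine_slice: int, factor: int = 12) -> int:
    """Thick-slice index containing an interpolated slice."""
    return int(fine_slice) // factor
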