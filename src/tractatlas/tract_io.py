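"""Streamline, mask and transform data model with standard-format I/O.

All geometry lives in world RAS millimeters.  Tractograms read from disk are
converted into that frame on load (TRK voxel/voxmm coordinates go through the
header affine via nibabel); polydata files are assumed to already store world
coordinates, as is conventional for tractography polydata.

Supported formats
-----------------
- VTK legacy polydata, ASCII (``.vtk``)
- VTK XML polydata, ASCII-encoded (``.vtp``)
- TrackVis (``.trk``), via :mod:`nibabel.streamlines`
- NIfTI-1 masks (``.nii`` / ``.nii.gz``), via :mod:`nibabel`
- JSON transform files (affine and b-spline displacement grids)

Per-fiber integer cluster labels are stored in polydata output as a cell-data
array named ``ClusterId`` so a parcellation travels in one standard file.
"""

from __future__ import annotations

import json
import logging
import warnings
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import nibabel as nib
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Fiber",
    "Tractogram",
    "VolumeMask",
    "LinearTransform",
    "GridTransform",
    "read_tractogram",
    "write_tractogram",
    "read_mask",
    "write_mask",
    "read_transform",
    "write_transform",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class Fiber:
    """An ordered 3-D polyline (one streamline) in world RAS mm."""

    points: np.ndarray

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise ValueError("fiber points must be an (n, 3) array")
        if pts.shape[0] < 2:
            raise ValueError("a fiber needs at least 2 points")
        if not np.all(np.isfinite(pts)):
            raise ValueError("fiber coordinates must be finite")
        self.points = pts

    def __len__(self) -> int:
        return self.points.shape[0]


@dataclass
class Tractogram:
    """A subject's fiber set, tagged with the frame it lives in."""

    subject_id: str
    fibers: list[Fiber] = field(default_factory=list)
    frame: str = "subject"  # {"subject", "atlas"}

    def __post_init__(self) -> None:
        if self.frame not in ("subject", "atlas"):
            raise ValueError(f"unknown frame {self.frame!r}")

    def __len__(self) -> int:
        return len(self.fibers)

    def point_arrays(self) -> list[np.ndarray]:
        return [f.points for f in self.fibers]


@dataclass
class VolumeMask:
    """Binary 3-D volume plus its voxel-index -> world RAS mm affine."""

    data: np.ndarray
    voxel_to_world: np.ndarray

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.ndim != 3:
            raise ValueError("mask data must be 3-D")
        self.data = (data > 0).astype(np.uint8)
        aff = np.asarray(self.voxel_to_world, dtype=float)
        if aff.shape != (4, 4):
            raise ValueError("voxel_to_world must be 4x4")
        if abs(np.linalg.det(aff[:3, :3])) < 1e-12:
            raise ValueError("voxel_to_world must be invertible")
        self.voxel_to_world = aff

    @property
    def voxel_sizes(self) -> np.ndarray:
        return np.linalg.norm(self.voxel_to_world[:3, :3], axis=0)


@dataclass
class LinearTransform:
    """Homogeneous 4x4 affine acting on world coordinates (mm)."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (4, 4):
            raise ValueError("affine matrix must be 4x4")
        if not np.allclose(m[3], [0, 0, 0, 1]):
            raise ValueError("last row of an affine must be (0,0,0,1)")
        if np.linalg.det(m[:3, :3]) <= 0:
            raise ValueError("affine must be orientation-preserving (det > 0)")
        self.matrix = m

    @classmethod
    def identity(cls) -> "LinearTransform":
        return cls(np.eye(4))

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.matrix[:3, :3].T + self.matrix[:3, 3]

    def inverse(self) -> "LinearTransform":
        return LinearTransform(np.linalg.inv(self.matrix))

    def compose(self, other: "LinearTransform") -> "LinearTransform":
        """Return the transform applying ``other`` first, then ``self``."""
        return LinearTransform(self.matrix @ other.matrix)


@dataclass
class GridTransform:
    """Cubic b-spline free-form displacement field over a world-space box.

    ``control_displacements`` holds the b-spline *coefficients* (mm) on a
    ``grid_shape`` lattice spanning ``domain_bounds``
    (xmin, xmax, ymin, ymax, zmin, zmax).
    """

    control_displacements: np.ndarray
    domain_bounds: np.ndarray

    def __post_init__(self) -> None:
        disp = np.asarray(self.control_displacements, dtype=float)
        if disp.ndim != 4 or disp.shape[3] != 3:
            raise ValueError("control_displacements must be (gx, gy, gz, 3)")
        if min(disp.shape[:3]) < 4:
            raise ValueError("b-spline grid needs >= 4 control points per axis")
        if not np.all(np.isfinite(disp)):
            raise ValueError("control displacements must be finite")
        bounds = np.asarray(self.domain_bounds, dtype=float).reshape(6)
        if np.any(bounds[1::2] <= bounds[::2]):
            raise ValueError("domain bounds must have positive extent per axis")
        self.control_displacements = disp
        self.domain_bounds = bounds

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.control_displacements.shape[:3]

    def displacement(self, points: np.ndarray) -> np.ndarray:
        """Evaluate the displacement field (mm) at world points."""
        from scipy.ndimage import map_coordinates

        pts = np.asarray(points, dtype=float)
        lo = self.domain_bounds[::2]
        hi = self.domain_bounds[1::2]
        shape = np.asarray(self.grid_shape, dtype=float)
        # map world -> fractional control-grid coordinates
        u = (pts - lo) / (hi - lo) * (shape - 1)
        coords = u.T
        out = np.empty_like(pts)
        for c in range(3):
            # prefilter=False: grid values are spline coefficients (FFD)
            out[:, c] = map_coordinates(
                self.control_displacements[..., c], coords,
                order=3, mode="nearest", prefilter=False)
        return out

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) + self.displacement(points)


Transform = Union[LinearTransform, GridTransform]


# ---------------------------------------------------------------------------
# Tractogram I/O
# ---------------------------------------------------------------------------

def _sniff_format(path: Path, fmt: str) -> str:
    if fmt != "auto":
        return fmt
    suffix = path.suffix.lower()
    table = {".vtk": "vtk", ".vtp": "vtp", ".trk": "trk"}
    if suffix not in table:
        raise ValueError(f"cannot infer tractogram format from {path.name!r}")
    return table[suffix]


def read_tractogram(path, format: str = "auto",
                    subject_id: Optional[str] = None) -> Tractogram:
    """Read a tractogram; coordinates come back in world RAS mm.

    Parameters
    ----------
    path : path-like
        Input file (``.vtk``, ``.vtp`` or ``.trk``).
    format : {"auto", "vtk", "vtp", "trk"}
        Explicit format, or sniff from the extension.
    subject_id : str, optional
        Subject tag; defaults to the file stem.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _sniff_format(path, format)
    sid = subject_id if subject_id is not None else path.stem
    if fmt == "vtk":
        arrays, _ = _read_vtk_legacy(path)
    elif fmt == "vtp":
        arrays, _ = _read_vtp(path)
    elif fmt == "trk":
        arrays = _read_trk(path)
    else:
        raise ValueError(f"unsupported format {fmt!r}")
    if not arrays:
        warnings.warn(f"{path.name}: no streamlines found", stacklevel=2)
    return Tractogram(subject_id=sid, fibers=[Fiber(a) for a in arrays])


def read_tractogram_labels(path, format: str = "auto") -> Optional[np.ndarray]:
    """Read the per-fiber ``ClusterId`` array from a polydata file, if any."""
    path = Path(path)
    fmt = _sniff_format(path, format)
    if fmt == "vtk":
        _, labels = _read_vtk_legacy(path)
    elif fmt == "vtp":
        _, labels = _read_vtp(path)
    else:
        return None
    return labels


def write_tractogram(tractogram: Tractogram, path, format: str = "auto",
                     labels: Optional[Sequence[int]] = None) -> None:
    """Write a tractogram; polydata output can carry per-fiber labels."""
    path = Path(path)
    fmt = _sniff_format(path, format)
    if labels is not None:
        labels = np.asarray(labels, dtype=np.int64)
        if labels.shape != (len(tractogram),):
            raise ValueError("labels length must equal the fiber count")
    arrays = tractogram.point_arrays()
    if fmt == "vtk":
        _write_vtk_legacy(arrays, path, labels)
    elif fmt == "vtp":
        _write_vtp(arrays, path, labels)
    elif fmt == "trk":
        if labels is not None:
            warnings.warn("TRK output does not store ClusterId labels",
                          stacklevel=2)
        _write_trk(arrays, path)
    else:
        raise ValueError(f"unsupported format {fmt!r}")


# -- VTK legacy ASCII polydata ----------------------------------------------

def _write_vtk_legacy(arrays, path: Path, labels) -> None:
    n_pts = sum(a.shape[0] for a in arrays)
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write("tractatlas streamlines\nASCII\nDATASET POLYDATA\n")
        fh.write(f"POINTS {n_pts} float\n")
        for a in arrays:
            for p in a:
                fh.write(f"{p[0]:.6f} {p[1]:.6f} {p[2]:.6f}\n")
        n_lines = len(arrays)
        size = sum(a.shape[0] + 1 for a in arrays)
        fh.write(f"LINES {n_lines} {size}\n")
        offset = 0
        for a in arrays:
            ids = " ".join(str(offset + i) for i in range(a.shape[0]))
            fh.write(f"{a.shape[0]} {ids}\n")
            offset += a.shape[0]
        if labels is not None:
            fh.write(f"CELL_DATA {n_lines}\n")
            fh.write("SCALARS ClusterId int 1\nLOOKUP_TABLE default\n")
            fh.write("\n".join(str(int(v)) for v in labels))
            fh.write("\n")


def _read_vtk_legacy(path: Path):
    tokens: list[str] = []
    with open(path, "r", errors="replace") as fh:
        header = fh.readline()
        if not header.startswith("# vtk DataFile"):
            raise ValueError(f"{path.name}: not a VTK legacy file")
        fh.readline()  # title
        mode = fh.readline().strip().upper()
        if mode != "ASCII":
            raise ValueError(f"{path.name}: only ASCII VTK legacy is supported")
        dataset = fh.readline().split()
        if len(dataset) < 2 or dataset[1].upper() != "POLYDATA":
            raise ValueError(f"{path.name}: expected DATASET POLYDATA")
        tokens = fh.read().split()

    pos = 0

    def expect(keyword: str) -> bool:
        return pos < len(tokens) and tokens[pos].upper() == keyword

    points = None
    lines: list[np.ndarray] = []
    labels = None
    while pos < len(tokens):
        kw = tokens[pos].upper()
        if kw == "POINTS":
            n = int(tokens[pos + 1])
            vals = np.array(tokens[pos + 3:pos + 3 + 3 * n], dtype=float)
            points = vals.reshape(n, 3)
            pos += 3 + 3 * n
        elif kw == "LINES":
            n_lines = int(tokens[pos + 1])
            size = int(tokens[pos + 2])
            pos += 3
            flat = tokens[pos:pos + size]
            pos += size
            i = 0
            for _ in range(n_lines):
                cnt = int(flat[i])
                ids = np.array(flat[i + 1:i + 1 + cnt], dtype=int)
                lines.append(ids)
                i += 1 + cnt
        elif kw == "CELL_DATA":
            pos += 2
        elif kw == "SCALARS":
            name = tokens[pos + 1]
            ncomp = int(tokens[pos + 3]) if tokens[pos + 3].isdigit() else 1
            pos += 4 if tokens[pos + 3].isdigit() else 3
            if tokens[pos].upper() == "LOOKUP_TABLE":
                pos += 2
            count = len(lines) * ncomp
            vals = np.array(tokens[pos:pos + count], dtype=float)
            pos += count
            if name == "ClusterId":
                labels = vals.astype(np.int64)
        else:
            pos += 1
    if points is None:
        raise ValueError(f"{path.name}: no POINTS section")
    arrays = [points[ids] for ids in lines]
    return arrays, labels


# -- VTK XML polydata (.vtp, ascii encoding) --------------------------------

def _write_vtp(arrays, path: Path, labels) -> None:
    n_pts = sum(a.shape[0] for a in arrays)
    root = ET.Element("VTKFile", type="PolyData", version="0.1",
                      byte_order="LittleEndian")
    poly = ET.SubElement(root, "PolyData")
    piece = ET.SubElement(poly, "Piece", NumberOfPoints=str(n_pts),
                          NumberOfVerts="0", NumberOfLines=str(len(arrays)),
                          NumberOfStrips="0", NumberOfPolys="0")
    pts_el = ET.SubElement(piece, "Points")
    da = ET.SubElement(pts_el, "DataArray", type="Float32",
                       NumberOfComponents="3", format="ascii")
    da.text = " ".join(f"{v:.6f}" for a in arrays for p in a for v in p)
    lines_el = ET.SubElement(piece, "Lines")
    conn = ET.SubElement(lines_el, "DataArray", type="Int64",
                         Name="connectivity", format="ascii")
    conn.text = " ".join(str(i) for i in range(n_pts))
    offs = ET.SubElement(lines_el, "DataArray", type="Int64",
                         Name="offsets", format="ascii")
    offsets = np.cumsum([a.shape[0] for a in arrays])
    offs.text = " ".join(str(int(o)) for o in offsets)
    if labels is not None:
        cd = ET.SubElement(piece, "CellData")
        la = ET.SubElement(cd, "DataArray", type="Int64", Name="ClusterId",
                           format="ascii")
        la.text = " ".join(str(int(v)) for v in labels)
    ET.ElementTree(root).write(path, xml_declaration=True, encoding="utf-8")


def _read_vtp(path: Path):
    try:
        tree = ET.parse(path)
    except ET.ParseError as exc:
        raise ValueError(f"{path.name}: not a parsable VTP file: {exc}") from exc
    piece = tree.getroot().find("./PolyData/Piece")
    if piece is None:
        raise ValueError(f"{path.name}: no PolyData Piece element")

    def data_array(el) -> np.ndarray:
        if el.get("format", "ascii") != "ascii":
            raise ValueError(f"{path.name}: only ascii-format VTP is supported")
        return np.array((el.text or "").split(), dtype=float)

    pts_el = piece.find("./Points/DataArray")
    points = data_array(pts_el).reshape(-1, 3) if pts_el is not None \
        else np.empty((0, 3))
    conn = np.array([], dtype=int)
    offsets = np.array([], dtype=int)
    for el in piece.findall("./Lines/DataArray"):
        if el.get("Name") == "connectivity":
            conn = data_array(el).astype(int)
        elif el.get("Name") == "offsets":
            offsets = data_array(el).astype(int)
    arrays = []
    start = 0
    for end in offsets:
        arrays.append(points[conn[start:end]])
        start = end
    labels = None
    for el in piece.findall("./CellData/DataArray"):
        if el.get("Name") == "ClusterId":
            labels = data_array(el).astype(np.int64)
    return arrays, labels


# -- TrackVis ----------------------------------------------------------------

def _read_trk(path: Path) -> list[np.ndarray]:
    trk = nib.streamlines.load(str(path))  # -> RAS mm
    return [np.asarray(s, dtype=float) for s in trk.streamlines]


def _write_trk(arrays, path: Path) -> None:
    from nibabel.streamlines import Tractogram as NibTractogram

    t = NibTractogram(arrays, affine_to_rasmm=np.eye(4))
    nib.streamlines.save(t, str(path))


# ---------------------------------------------------------------------------
# Mask I/O
# ---------------------------------------------------------------------------

def read_mask(path) -> VolumeMask:
    """Load a NIfTI volume as a binarized mask (value > 0 -> foreground)."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(
            f"expected a 3-D volume, got shape {data.shape}; "
            "select a single volume from the 4-D series first")
    return VolumeMask(data=data, voxel_to_world=img.affine)


def write_mask(mask: VolumeMask, path) -> None:
    img = nib.Nifti1Image(mask.data.astype(np.uint8), mask.voxel_to_world)
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# Transform I/O (JSON)
# ---------------------------------------------------------------------------

def write_transform(transform: Transform, path) -> None:
    if isinstance(transform, LinearTransform):
        doc = {"type": "affine", "matrix": transform.matrix.ravel().tolist()}
    elif isinstance(transform, GridTransform):
        doc = {
            "type": "bspline",
            "grid_shape": list(transform.grid_shape),
            "bounds": transform.domain_bounds.tolist(),
            "displacements": transform.control_displacements.ravel().tolist(),
        }
    else:
        raise TypeError(f"cannot serialize transform of type {type(transform)}")
    with open(path, "w") as fh:
        json.dump(doc, fh)


def read_transform(path) -> Transform:
    with open(path) as fh:
        doc = json.load(fh)
    kind = doc.get("type")
    if kind == "affine":
        if "matrix" not in doc:
            raise ValueError("affine transform file missing field 'matrix'")
        return LinearTransform(np.asarray(doc["matrix"], float).reshape(4, 4))
    if kind == "bspline":
        for key in ("grid_shape", "bounds", "displacements"):
            if key not in doc:
                raise ValueError(f"bspline transform file missing field {key!r}")
        shape = tuple(doc["grid_shape"])
        disp = np.asarray(doc["displacements"], float).reshape(*shape, 3)
        return GridTransform(disp, np.asarray(doc["bounds"], float))
    raise ValueError(f"unknown transform type {kind!r}; missing field 'type'"
                     if kind is None else f"unknown transform type {kind!r}")
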