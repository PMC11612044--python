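"""Segmentation, fiducial and report I/O with explicit geometry handling.

Everything in this package works in a single world frame: **LPS millimetres**
(the DICOM patient frame: +x left, +y posterior, +z superior).  Images read
through SimpleITK are already expressed in LPS; fiducial files declared in RAS
are converted on read by negating the first two coordinates.

The voxel-centre convention is::

    world(i, j, k) = origin + direction @ (spacing * (i, j, k))

with 0-based indices, matching the usual NIfTI/NRRD affine semantics.  Arrays
are stored index-ordered ``(i, j, k)`` so that ``array.shape == grid.dims``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np
import pandas as pd
import SimpleITK as sitk

from .errors import (
    DegenerateInputError,
    FormatError,
    RenoterraError,
    ValidationError,
)

if TYPE_CHECKING:  # pragma: no cover - import cycle guard, types only
    from .planning import PlanResult
    from .territory import TerritoryMap, TerritoryTable

MASK_SUFFIXES = (".nii", ".nii.gz", ".nrrd", ".nhdr")

ROLE_OSTIUM = "ostium"
ROLE_ENDPOINT = "endpoint"
_ROLES = (ROLE_OSTIUM, ROLE_ENDPOINT)


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ImageGrid:
    """Lattice geometry mapping voxel indices to world millimetres.

    Parameters
    ----------
    dims
        Voxel counts per axis, all >= 1.
    spacing
        Millimetres per voxel step along each axis, all > 0.
    origin
        World coordinates (LPS mm) of the centre of voxel ``(0, 0, 0)``.
    direction
        3x3 orthonormal matrix of axis cosines (columns are the world
        directions of the index axes).
    """

    dims: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    direction: tuple[float, ...] = (1.0, 0.0, 0.0, 0.0, 1.0, 0.0, 0.0, 0.0, 1.0)

    def __post_init__(self) -> None:
        dims = tuple(int(d) for d in self.dims)
        spacing = tuple(float(s) for s in self.spacing)
        origin = tuple(float(o) for o in self.origin)
        direction = tuple(float(d) for d in np.asarray(self.direction).ravel())
        if len(dims) != 3 or any(d < 1 for d in dims):
            raise ValidationError(f"dims must be three integers >= 1, got {dims}")
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValidationError(f"spacing must be three positive reals, got {spacing}")
        if len(origin) != 3:
            raise ValidationError(f"origin must be a real triple, got {origin}")
        if len(direction) != 9:
            raise ValidationError("direction must be a 3x3 matrix")
        d = np.array(direction).reshape(3, 3)
        if np.max(np.abs(d.T @ d - np.eye(3))) >= 1e-6:
            raise ValidationError("direction matrix is not orthonormal")
        object.__setattr__(self, "dims", dims)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", origin)
        object.__setattr__(self, "direction", direction)

    @property
    def direction_matrix(self) -> np.ndarray:
        return np.array(self.direction, dtype=float).reshape(3, 3)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def world(self, indices: np.ndarray) -> np.ndarray:
        """World coordinates (mm) of voxel centres for an ``(N, 3)`` index array."""
        idx = np.atleast_2d(np.asarray(indices, dtype=float))
        local = idx * np.asarray(self.spacing)
        return np.asarray(self.origin) + local @ self.direction_matrix.T

    def index_of(self, points: np.ndarray) -> np.ndarray:
        """Continuous voxel indices of world points (inverse of :meth:`world`)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        local = (pts - np.asarray(self.origin)) @ self.direction_matrix
        return local / np.asarray(self.spacing)

    def isclose(self, other: "ImageGrid", tol: float = 1e-6) -> bool:
        return (
            self.dims == other.dims
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
            and np.allclose(self.direction, other.direction, atol=tol)
        )


@dataclass
class ParenchymaMask:
    """Binary occupancy of renal parenchyma on an :class:`ImageGrid`.

    The mask is expected to already exclude cysts, caliceal systems, proximal
    vessels and fat; this package treats it as ground truth geometry.
    """

    grid: ImageGrid
    occupancy: np.ndarray

    def __post_init__(self) -> None:
        occ = np.asarray(self.occupancy, dtype=bool)
        if occ.shape != self.grid.dims:
            raise ValidationError(
                f"occupancy shape {occ.shape} does not match grid dims {self.grid.dims}"
            )
        if not occ.any():
            raise DegenerateInputError("mask has no foreground voxels")
        self.occupancy = occ

    @property
    def foreground_count(self) -> int:
        return int(self.occupancy.sum())

    @property
    def volume_cm3(self) -> float:
        return self.foreground_count * self.grid.voxel_volume_mm3 / 1000.0


# ---------------------------------------------------------------------------
# fiducials
# ---------------------------------------------------------------------------


@dataclass
class Fiducial:
    """A named landmark in world (LPS mm) coordinates.

    ``role`` is ``"ostium"`` (artery origin on the aorta/iliacs) or
    ``"endpoint"`` (most distal visible intraparenchymal ending).  Endpoints
    must carry the label of their parent artery.
    """

    id: int
    name: str
    role: str
    artery: str
    position: np.ndarray

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float).reshape(3)
        if not np.all(np.isfinite(pos)):
            raise ValidationError(f"fiducial {self.name!r} has non-finite position")
        if self.role not in _ROLES:
            raise ValidationError(f"fiducial {self.name!r}: unknown role {self.role!r}")
        if self.role == ROLE_ENDPOINT and not self.artery:
            raise ValidationError(f"endpoint {self.name!r} has no artery label")
        self.position = pos


@dataclass
class FiducialSet:
    """Ordered landmark collection, normalised to the LPS frame."""

    fiducials: list[Fiducial]
    frame: str = "LPS"

    def __post_init__(self) -> None:
        for i, f in enumerate(self.fiducials):
            if f.id != i:
                raise ValidationError(
                    f"fiducial ids must equal list position: {f.name!r} has id {f.id} at index {i}"
                )
        for role in _ROLES:
            names = [f.name for f in self.fiducials if f.role == role]
            if len(names) != len(set(names)):
                dupes = sorted({n for n in names if names.count(n) > 1})
                raise ValidationError(f"duplicate {role} names: {dupes}")

    @property
    def endpoints(self) -> list[Fiducial]:
        return [f for f in self.fiducials if f.role == ROLE_ENDPOINT]

    @property
    def ostia(self) -> list[Fiducial]:
        return [f for f in self.fiducials if f.role == ROLE_OSTIUM]

    def endpoint_names(self) -> list[str]:
        return [f.name for f in self.endpoints]


def _parse_control_point(i: int, cp: dict) -> Fiducial:
    label = cp.get("label", cp.get("name"))
    if label is None:
        raise FormatError(f"control point {i} has no label")
    position = cp.get("position")
    if position is None or len(position) != 3:
        raise FormatError(f"control point {label!r} has no 3-component position")
    role = cp.get("role")
    artery = cp.get("artery")
    if role is None:
        # role/artery encoded in the name: "<role>:<artery>:<tag>"
        parts = str(label).split(":")
        if len(parts) >= 2 and parts[0] in _ROLES:
            role = parts[0]
            artery = artery if artery is not None else parts[1]
        else:
            raise FormatError(
                f"control point {label!r}: role not declared and name is not "
                "'<role>:<artery>:<tag>'"
            )
    return Fiducial(id=i, name=str(label), role=role, artery=artery or "", position=position)


def read_fiducials(path: str | Path) -> FiducialSet:
    """Read a Slicer-markups-style JSON point list, normalising to LPS.

    The accepted schema is either a bare object with keys ``coordinateSystem``
    and ``controlPoints`` or a full Slicer markups file whose first entry under
    ``markups`` carries them.  Each control point needs ``label`` and
    ``position``; role and parent artery come from explicit ``role``/``artery``
    keys or from a label of the form ``"<role>:<artery>:<tag>"``.
    """
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise FormatError(f"cannot read fiducial file {path}: {exc}") from exc
    if isinstance(doc, dict) and "markups" in doc:
        if not doc["markups"]:
            raise FormatError(f"{path}: empty markups list")
        doc = doc["markups"][0]
    if not isinstance(doc, dict):
        raise FormatError(f"{path}: expected a JSON object")
    frame = doc.get("coordinateSystem")
    if frame is None:
        raise FormatError(f"{path}: missing coordinateSystem declaration")
    frame = str(frame).upper()
    if frame not in ("LPS", "RAS"):
        raise FormatError(f"{path}: unsupported coordinate system {frame!r}")
    points = doc.get("controlPoints")
    if points is None:
        raise FormatError(f"{path}: missing controlPoints")
    fiducials = [_parse_control_point(i, cp) for i, cp in enumerate(points)]
    if frame == "RAS":
        for f in fiducials:
            f.position = f.position * np.array([-1.0, -1.0, 1.0])
    return FiducialSet(fiducials=fiducials, frame="LPS")


def write_fiducials(fset: FiducialSet, path: str | Path) -> None:
    """Write a fiducial set as an LPS JSON point list (readable by this package
    and, with its explicit ``coordinateSystem``, by Slicer-compatible tools)."""
    doc = {
        "coordinateSystem": "LPS",
        "controlPoints": [
            {
                "label": f.name,
                "role": f.role,
                "artery": f.artery,
                "position": [float(x) for x in f.position],
            }
            for f in fset.fiducials
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1))


# ---------------------------------------------------------------------------
# volumes
# ---------------------------------------------------------------------------


def _grid_from_sitk(img: sitk.Image) -> ImageGrid:
    return ImageGrid(
        dims=tuple(img.GetSize()),
        spacing=tuple(img.GetSpacing()),
        origin=tuple(img.GetOrigin()),
        direction=tuple(img.GetDirection()),
    )


def _sitk_from_grid(array: np.ndarray, grid: ImageGrid) -> sitk.Image:
    img = sitk.GetImageFromArray(np.ascontiguousarray(array.transpose(2, 1, 0)))
    img.SetSpacing(grid.spacing)
    img.SetOrigin(grid.origin)
    img.SetDirection(grid.direction)
    return img


def _check_suffix(path: Path) -> None:
    name = path.name.lower()
    if not any(name.endswith(s) for s in MASK_SUFFIXES):
        raise FormatError(
            f"{path}: unsupported image format (expected one of {MASK_SUFFIXES})"
        )


def _read_image(path: str | Path) -> tuple[np.ndarray, ImageGrid]:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    _check_suffix(path)
    try:
        img = sitk.ReadImage(str(path))
    except RuntimeError as exc:
        raise FormatError(f"cannot read image {path}: {exc}") from exc
    arr = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    return arr, _grid_from_sitk(img)


def read_mask(path: str | Path, label: int | None = None) -> ParenchymaMask:
    """Read a binary/multi-label segmentation as a parenchyma mask.

    With ``label`` given, foreground is ``value == label``; otherwise any
    nonzero voxel is foreground (the common case for binary masks).
    """
    arr, grid = _read_image(path)
    occupancy = (arr == label) if label is not None else (arr != 0)
    if not occupancy.any():
        raise DegenerateInputError(
            f"{path}: no foreground voxels"
            + (f" with label {label}" if label is not None else "")
        )
    return ParenchymaMask(grid=grid, occupancy=occupancy)


def write_mask(mask: ParenchymaMask, path: str | Path) -> None:
    path = Path(path)
    _check_suffix(path)
    try:
        sitk.WriteImage(_sitk_from_grid(mask.occupancy.astype(np.uint8), mask.grid), str(path))
    except RuntimeError as exc:
        raise RenoterraError(f"cannot write {path}: {exc}") from exc


def write_labelmap(
    tmap: "TerritoryMap",
    path: str | Path,
    endpoints: FiducialSet | None = None,
) -> None:
    """Write a territory map as an integer labelmap with a JSON sidecar.

    Voxel value 0 is background; value ``k`` marks the territory of the
    endpoint with id ``k - 1`` (the offset is recorded in the sidecar, which
    also lists endpoint names/arteries when a fiducial set is supplied).
    """
    path = Path(path)
    _check_suffix(path)
    if not (tmap.labels > 0).any():
        raise DegenerateInputError("refusing to write a background-only territory map")
    try:
        sitk.WriteImage(_sitk_from_grid(tmap.labels.astype(np.int32), tmap.grid), str(path))
    except RuntimeError as exc:
        raise RenoterraError(f"cannot write {path}: {exc}") from exc
    sidecar = {
        "label_offset": "voxel value k marks endpoint id k-1; 0 is background",
        "labels": {},
    }
    present = sorted(int(v) for v in np.unique(tmap.labels) if v > 0)
    for v in present:
        entry: dict = {"endpoint_id": v - 1}
        if endpoints is not None:
            for f in endpoints.endpoints:
                if f.id == v - 1:
                    entry.update(name=f.name, artery=f.artery)
        sidecar["labels"][str(v)] = entry
    Path(str(path) + ".labels.json").write_text(json.dumps(sidecar, indent=1))


def read_labelmap(path: str | Path) -> "TerritoryMap":
    from .territory import TerritoryMap

    arr, grid = _read_image(path)
    return TerritoryMap(grid=grid, labels=arr.astype(np.int32))


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

ENDPOINT_COLUMNS = ["endpoint_id", "name", "artery", "volume_cm3", "fraction"]
ARTERY_COLUMNS = ["artery", "volume_cm3", "fraction"]


def _table_csv(df: pd.DataFrame, columns: list[str]) -> str:
    out = df.reindex(columns=columns).copy()
    if "volume_cm3" in out:
        out["volume_cm3"] = out["volume_cm3"].map(lambda v: f"{v:.1f}")
    if "fraction" in out:
        out["fraction"] = out["fraction"].map(lambda v: f"{v:.3f}")
    return out.to_csv(index=False)


def write_report(obj, path: str | Path, format: str = "csv") -> None:
    """Write a :class:`~renoterra.territory.TerritoryTable` or
    :class:`~renoterra.planning.PlanResult` report.

    CSV prints volumes with 1 decimal (cm3) and fractions with 3 decimals;
    JSON retains full float precision.  Column order is fixed so reruns are
    byte-identical.
    """
    from .planning import PlanResult
    from .territory import TerritoryTable

    path = Path(path)
    if format not in ("csv", "json"):
        raise ValidationError(f"unknown report format {format!r} (expected csv or json)")
    if isinstance(obj, TerritoryTable):
        if format == "csv":
            path.write_text(_table_csv(obj.endpoints, ENDPOINT_COLUMNS))
        else:
            path.write_text(json.dumps(obj.to_dict(), indent=1))
    elif isinstance(obj, PlanResult):
        if format == "csv":
            df = pd.DataFrame([obj.to_dict()])
            for c in ("kvls_cm3", "kvls_pct", "pkvl_cm3", "pkvl_pct"):
                df[c] = df[c].map(lambda v: "" if v is None else f"{v:.1f}")
            df["lost_endpoint_names"] = ";".join(obj.lost_endpoint_names)
            path.write_text(df.to_csv(index=False))
        else:
            path.write_text(json.dumps(obj.to_dict(), indent=1))
    else:
        raise ValidationError(f"cannot report object of type {type(obj).__name__}")


def write_artery_report(table: "TerritoryTable", path: str | Path) -> None:
    """CSV of per-artery volumes (artery, volume_cm3, fraction)."""
    if table.arteries is None:
        raise ValidationError("table has no artery rows; run aggregate_by_artery first")
    Path(path).write_text(_table_csv(table.arteries, ARTERY_COLUMNS))
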