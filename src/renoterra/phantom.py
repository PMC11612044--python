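"""Synthetic horseshoe-kidney phantoms with by-construction ground truth.

The phantom emulates the geometry this pipeline actually depends on — a fused
kidney mask on an anisotropic grid with marked arterial endpoints — not the
anatomy: two lateral ellipsoids joined by a cylindrical isthmus bridging the
midline (the fusion in front of the aorta), optional spherical "cyst" holes,
ostia placed on a simulated aortic axis anterior to the mask, and endpoints
sampled uniformly inside the parenchyma.  Ground-truth territories come from
the exhaustive brute-force assignment, so every downstream stage (partition,
volumetry, planning) can be checked against planted values exactly.

All randomness flows through one ``numpy.random.default_rng(seed)``: identical
spec + seed reproduces bit-identical bundles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import GenerationError, ValidationError
from .image_io import (
    ROLE_ENDPOINT,
    ROLE_OSTIUM,
    Fiducial,
    FiducialSet,
    ImageGrid,
    ParenchymaMask,
)
from .territory import TerritoryMap, TerritoryTable, aggregate_by_artery, brute_force_assign, territory_volumes

_MIN_DIM = 16
_MIN_ENDPOINT_SEP_MM = 1.0


@dataclass
class PhantomSpec:
    """Phantom generation parameters.

    Defaults mirror a plausible clinical CTA setting: sub-millimetre in-plane
    spacing with 1-mm slices, four renal arteries (the cohort mean artery
    count), roughly five to six visible endings per artery, and ~15% of the
    parenchyma in the isthmus (the scale of the resected central bridge).
    """

    dims: tuple[int, int, int] = (64, 64, 48)
    spacing: tuple[float, float, float] = (0.9, 0.9, 1.0)
    n_arteries: int = 4
    endpoints_per_artery: tuple[int, int] = (4, 7)
    isthmus_fraction: float = 0.15
    seed: int = 0
    cyst_count: int = 0
    surface_endpoint_fraction: float = 0.0

    def __post_init__(self) -> None:
        if any(d < _MIN_DIM for d in self.dims):
            raise GenerationError(f"dims must be >= {_MIN_DIM} on every axis, got {self.dims}")
        if any(s <= 0 for s in self.spacing):
            raise ValidationError(f"spacing must be positive, got {self.spacing}")
        if self.n_arteries < 1:
            raise ValidationError("need at least one artery")
        lo, hi = self.endpoints_per_artery
        if lo < 1 or hi < lo:
            raise ValidationError(f"bad endpoints_per_artery range {self.endpoints_per_artery}")
        if not 0.0 <= self.isthmus_fraction <= 1.0:
            raise ValidationError("isthmus_fraction must be in [0, 1]")
        if not 0.0 <= self.surface_endpoint_fraction <= 1.0:
            raise ValidationError("surface_endpoint_fraction must be in [0, 1]")
        if self.cyst_count < 0:
            raise ValidationError("cyst_count must be >= 0")


@dataclass
class PhantomBundle:
    """A phantom and its ground truth: mask, fiducials, territory map/table."""

    spec: PhantomSpec
    mask: ParenchymaMask
    fiducials: FiducialSet
    truth_map: TerritoryMap
    truth_table: TerritoryTable
    lost_truth: list[str] = field(default_factory=list)
    midline_x_mm: float = 0.0


def _world_axes(grid: ImageGrid) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    # identity-direction grids only (phantom grids are axis-aligned)
    sp = np.asarray(grid.spacing)
    org = np.asarray(grid.origin)
    return tuple(org[a] + sp[a] * np.arange(grid.dims[a]) for a in range(3))


def _horseshoe_mask(spec: PhantomSpec) -> tuple[np.ndarray, ImageGrid, float]:
    """Binary horseshoe: two ellipsoids + midline cylinder sized by bisection
    so the bridge holds ~isthmus_fraction of the total volume."""
    grid = ImageGrid(dims=spec.dims, spacing=spec.spacing)
    wx, wy, wz = _world_axes(grid)
    X, Y, Z = [spec.dims[a] * spec.spacing[a] for a in range(3)]
    gx, gy, gz = np.meshgrid(wx, wy, wz, indexing="ij")

    centers = [(0.28 * X, 0.50 * Y, 0.55 * Z), (0.72 * X, 0.50 * Y, 0.55 * Z)]
    axes = (0.16 * X, 0.24 * Y, 0.36 * Z)
    ell = np.zeros(spec.dims, dtype=bool)
    for cx, cy, cz in centers:
        ell |= (
            ((gx - cx) / axes[0]) ** 2 + ((gy - cy) / axes[1]) ** 2 + ((gz - cz) / axes[2]) ** 2
        ) <= 1.0

    midline = 0.5 * X
    if spec.isthmus_fraction == 0.0:
        return ell, grid, midline

    y0, z0 = 0.50 * Y, 0.38 * Z
    in_span = (gx >= centers[0][0]) & (gx <= centers[1][0])
    r2 = (gy - y0) ** 2 + (gz - z0) ** 2

    def frac(r: float) -> float:
        cyl = in_span & (r2 <= r * r)
        total = ell | cyl
        return (cyl & ~ell).sum() / total.sum()

    r_hi = 0.5 * min(Y, Z)
    if frac(r_hi) + 1e-9 < spec.isthmus_fraction:
        raise GenerationError(
            f"isthmus_fraction {spec.isthmus_fraction} not achievable on this grid "
            f"(max ~{frac(r_hi):.2f})"
        )
    lo, hi = 0.0, r_hi
    for _ in range(48):
        mid = 0.5 * (lo + hi)
        if frac(mid) < spec.isthmus_fraction:
            lo = mid
        else:
            hi = mid
    cyl = in_span & (r2 <= hi * hi)
    return ell | cyl, grid, midline


def _punch_cysts(occ: np.ndarray, grid: ImageGrid, n: int, rng: np.random.Generator) -> np.ndarray:
    wx, wy, wz = _world_axes(grid)
    gx, gy, gz = np.meshgrid(wx, wy, wz, indexing="ij")
    mean_sp = float(np.mean(grid.spacing))
    for _ in range(n):
        fg = np.argwhere(occ)
        c = grid.world(fg[rng.integers(len(fg))])[0]
        r = rng.uniform(1.5, 3.5) * mean_sp
        hole = ((gx - c[0]) ** 2 + (gy - c[1]) ** 2 + (gz - c[2]) ** 2) <= r * r
        if (occ & ~hole).any():
            occ = occ & ~hole
    return occ


def _boundary_background(occ: np.ndarray) -> np.ndarray:
    """Background voxels 6-adjacent to foreground (just outside the surface)."""
    from scipy import ndimage

    dilated = ndimage.binary_dilation(occ)
    return np.argwhere(dilated & ~occ)


def _sample_endpoints(
    mask: ParenchymaMask, n_inside: int, n_surface: int, rng: np.random.Generator
) -> np.ndarray:
    grid = mask.grid
    dims = np.asarray(grid.dims)
    lo = grid.world([0, 0, 0])[0] - np.asarray(grid.spacing) / 2
    hi = grid.world(dims - 1)[0] + np.asarray(grid.spacing) / 2
    accepted: list[np.ndarray] = []
    attempts = 0
    while len(accepted) < n_inside:
        attempts += 1
        if attempts > 20000:
            raise GenerationError("could not place endpoints inside the mask")
        p = rng.uniform(lo, hi)
        idx = np.rint(grid.index_of(p)[0]).astype(int)
        if np.any(idx < 0) or np.any(idx >= dims) or not mask.occupancy[tuple(idx)]:
            continue
        if accepted and np.min(np.linalg.norm(np.array(accepted) - p, axis=1)) < _MIN_ENDPOINT_SEP_MM:
            continue
        accepted.append(p)
    if n_surface:
        shell = _boundary_background(mask.occupancy)
        picks = rng.choice(len(shell), size=n_surface, replace=False)
        for idx in shell[picks]:
            accepted.append(grid.world(idx)[0])
    return np.array(accepted)


def generate_phantom(spec: PhantomSpec) -> PhantomBundle:
    """Generate a seeded phantom bundle with exact ground-truth territories."""
    rng = np.random.default_rng(spec.seed)
    occ, grid, midline = _horseshoe_mask(spec)
    if spec.cyst_count:
        occ = _punch_cysts(occ, grid, spec.cyst_count, rng)
    mask = ParenchymaMask(grid=grid, occupancy=occ)

    X, Y, Z = [spec.dims[a] * spec.spacing[a] for a in range(3)]
    # ostia on a simulated aortic axis, anterior to (outside) the mask
    z_ost = np.linspace(0.30 * Z, 0.80 * Z, spec.n_arteries)
    z_ost = z_ost + rng.uniform(-0.02 * Z, 0.02 * Z, size=spec.n_arteries)
    ostia_pos = np.column_stack(
        [np.full(spec.n_arteries, 0.5 * X), np.full(spec.n_arteries, -10.0), z_ost]
    )
    artery_names = [f"A{i + 1}" for i in range(spec.n_arteries)]

    lo_e, hi_e = spec.endpoints_per_artery
    n_total = int(rng.integers(lo_e, hi_e + 1, size=spec.n_arteries).sum())
    n_surface = int(round(spec.surface_endpoint_fraction * n_total))
    positions = _sample_endpoints(mask, n_total - n_surface, n_surface, rng)
    # each ending belongs to the artery whose ostium is nearest
    d = np.linalg.norm(positions[:, None, :] - ostia_pos[None, :, :], axis=2)
    artery_of = np.argmin(d, axis=1)

    fiducials = [
        Fiducial(
            id=i,
            name=f"{ROLE_OSTIUM}:{artery_names[i]}:o{i + 1}",
            role=ROLE_OSTIUM,
            artery=artery_names[i],
            position=ostia_pos[i],
        )
        for i in range(spec.n_arteries)
    ]
    for j, p in enumerate(positions):
        art = artery_names[artery_of[j]]
        fiducials.append(
            Fiducial(
                id=spec.n_arteries + j,
                name=f"{ROLE_ENDPOINT}:{art}:e{j + 1}",
                role=ROLE_ENDPOINT,
                artery=art,
                position=p,
            )
        )
    fset = FiducialSet(fiducials=fiducials)

    with warnings.catch_warnings():
        if n_surface:  # surface endings legitimately sit outside the mask
            warnings.simplefilter("ignore")
        truth_map = brute_force_assign(mask, fset)
    truth_table = aggregate_by_artery(territory_volumes(truth_map, fset), fset)
    return PhantomBundle(
        spec=spec,
        mask=mask,
        fiducials=fset,
        truth_map=truth_map,
        truth_table=truth_table,
        midline_x_mm=midline,
    )


def _drop_endpoints(fset: FiducialSet, lost: set[str]) -> FiducialSet:
    kept = [f for f in fset.fiducials if not (f.role == ROLE_ENDPOINT and f.name in lost)]
    return FiducialSet(
        fiducials=[
            Fiducial(id=i, name=f.name, role=f.role, artery=f.artery, position=f.position.copy())
            for i, f in enumerate(kept)
        ]
    )


def simulate_postop(
    bundle: PhantomBundle, resected_fraction: float, seed: int = 0
) -> tuple[ParenchymaMask, FiducialSet]:
    """Simulate isthmus division: remove a midline-centred slab of parenchyma.

    Foreground voxels are removed in order of distance from the midline plane
    until ``resected_fraction`` of the volume is gone, emulating a central
    resection that grows outward from the isthmus.  Endpoints whose entire
    territory is removed are dropped from the returned postoperative fiducial
    set and recorded in ``bundle.lost_truth``.  The pair's KVLS equals the
    removed volume exactly.  The resection is deterministic given the bundle;
    ``seed`` is accepted for interface symmetry with the generator.
    """
    if not 0.0 <= resected_fraction <= 1.0:
        raise ValidationError("resected_fraction must be in [0, 1]")
    occ = bundle.mask.occupancy
    fg = np.argwhere(occ)
    total = len(fg)
    k = int(round(resected_fraction * total))
    if k >= total:
        warnings.warn("resected_fraction would empty the mask; capping below total", stacklevel=2)
        k = total - 1

    worlds = bundle.mask.grid.world(fg)
    axis = bundle.mask.grid.direction_matrix @ np.array([1.0, 0.0, 0.0])
    dist = np.abs(worlds @ axis - bundle.midline_x_mm)
    order = np.argsort(dist, kind="stable")
    removed = fg[order[:k]]

    post_occ = occ.copy()
    post_occ[removed[:, 0], removed[:, 1], removed[:, 2]] = False
    post_mask = ParenchymaMask(grid=bundle.mask.grid, occupancy=post_occ)

    labels = bundle.truth_map.labels
    total_counts = np.bincount(labels.ravel())
    removed_counts = np.bincount(
        labels[removed[:, 0], removed[:, 1], removed[:, 2]], minlength=len(total_counts)
    )
    lost: list[str] = []
    for f in bundle.fiducials.endpoints:
        lab = f.id + 1
        if lab < len(total_counts) and total_counts[lab] > 0 and removed_counts[lab] == total_counts[lab]:
            lost.append(f.name)
    bundle.lost_truth = lost
    return post_mask, _drop_endpoints(bundle.fiducials, set(lost))


def resect_territories(
    bundle: PhantomBundle, names: list[str]
) -> tuple[ParenchymaMask, FiducialSet]:
    """Remove whole named territories (positive control: PKVL = KVLS exactly)."""
    known = {f.name for f in bundle.fiducials.endpoints}
    unknown = [n for n in names if n not in known]
    if unknown:
        raise ValidationError(f"unknown endpoints: {unknown}")
    ids = {f.id + 1 for f in bundle.fiducials.endpoints if f.name in names}
    drop = np.isin(bundle.truth_map.labels, list(ids))
    post_occ = bundle.mask.occupancy & ~drop
    post_mask = ParenchymaMask(grid=bundle.mask.grid, occupancy=post_occ)
    bundle.lost_truth = [f.name for f in bundle.fiducials.endpoints if f.name in names]
    return post_mask, _drop_endpoints(bundle.fiducials, set(names))
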