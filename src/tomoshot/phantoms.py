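"""Macromolecule-like 3D density maps: geometric phantoms, atomic-structure
rasterization, random poses and ground-truth masks.

Geometric phantoms stand in for PDB-derived density maps in tests and
desk-scale experiments: each is a compact, connected shape with a distinct
canonical-pose footprint, so that an 8+ class library gives well-separated
classification targets. Atomic models (PDB/mmCIF via gemmi) can be rasterized
to density maps with a Gaussian kernel when real structures are available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "DensityMap",
    "StructureModel",
    "Pose",
    "make_phantom",
    "rasterize_structure",
    "random_pose",
    "apply_pose",
    "make_ground_truth_mask",
    "phantom_library",
    "load_structure",
]


@dataclass
class DensityMap:
    """Nonnegative cubic 3D density with physical voxel size in Angstrom."""

    grid: np.ndarray
    voxel_size: float = 10.0
    name: str = ""

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=np.float32)
        if self.grid.ndim != 3 or len(set(self.grid.shape)) != 1:
            raise ValueError(f"grid must be cubic 3D, got shape {self.grid.shape}")
        if not np.isfinite(self.grid).all():
            raise ValueError("grid contains non-finite values")
        if (self.grid < 0).any():
            raise ValueError("density must be nonnegative")


@dataclass
class StructureModel:
    """Point-atom model: coordinates in Angstrom plus per-atom weights."""

    coords: np.ndarray  # (n_atoms, 3)
    weights: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3 or len(self.coords) == 0:
            raise ValueError("coords must be a non-empty (n, 3) array")
        if not np.isfinite(self.coords).all():
            raise ValueError("coordinates must be finite")
        if self.weights is None:
            self.weights = np.ones(len(self.coords))
        self.weights = np.asarray(self.weights, dtype=np.float64)


@dataclass
class Pose:
    """Rigid pose: proper rotation plus translation in voxels."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, dtype=np.float64)
        self.translation = np.asarray(self.translation, dtype=np.float64)
        r = self.rotation
        if not np.allclose(r.T @ r, np.eye(3), atol=1e-6):
            raise ValueError("rotation is not orthonormal")
        if abs(np.linalg.det(r) - 1.0) > 1e-6:
            raise ValueError("rotation must be proper (det = +1)")

    @staticmethod
    def identity() -> "Pose":
        return Pose(np.eye(3), np.zeros(3))


def _centered_coords(grid_size: int):
    # integer center voxel: keeps shape membership aligned with the rotation
    # center used by apply_pose
    ax = np.arange(grid_size) - grid_size // 2
    return np.meshgrid(ax, ax, ax, indexing="ij")


def _check_extent(extent: float, grid_size: int, kind: str) -> None:
    # shape must fit with a 2-voxel margin on each side
    if extent > grid_size / 2.0 - 2.0:
        raise ValueError(
            f"{kind} with half-extent {extent:.1f} does not fit a {grid_size}^3 "
            f"grid with a 2-voxel margin"
        )


def make_phantom(shape_spec: dict, grid_size: int) -> DensityMap:
    """Build a binary-valued geometric phantom from a parametric spec.

    shape_spec: {"kind": sphere|shell|dumbbell|torus|lshape|plate|rod|helix,
    ...size parameters in voxels}. Deterministic; density 1 inside, 0 outside.
    """
    if grid_size < 8:
        raise ValueError("grid_size must be >= 8")
    kind = shape_spec.get("kind")
    x, y, z = _centered_coords(grid_size)
    r2 = x**2 + y**2 + z**2

    if kind == "sphere":
        radius = float(shape_spec["radius"])
        if radius <= 0:
            inside = np.zeros((grid_size,) * 3, dtype=bool)
        else:
            _check_extent(radius, grid_size, "sphere")
            inside = r2 <= radius**2
    elif kind == "shell":
        outer, inner = float(shape_spec["outer"]), float(shape_spec["inner"])
        _check_extent(outer, grid_size, "shell")
        inside = (r2 <= outer**2) & (r2 >= inner**2)
    elif kind == "dumbbell":
        radius = float(shape_spec["radius"])
        sep = float(shape_spec["separation"])
        _check_extent(sep + radius, grid_size, "dumbbell")
        lobe1 = (x - sep) ** 2 + y**2 + z**2 <= radius**2
        lobe2 = (x + sep) ** 2 + y**2 + z**2 <= radius**2
        neck = (np.abs(x) <= sep) & (y**2 + z**2 <= (radius / 2.5) ** 2)
        inside = lobe1 | lobe2 | neck
    elif kind == "torus":
        major, minor = float(shape_spec["major"]), float(shape_spec["minor"])
        _check_extent(major + minor, grid_size, "torus")
        inside = (np.sqrt(x**2 + y**2) - major) ** 2 + z**2 <= minor**2
    elif kind == "lshape":
        arm, thick = float(shape_spec["arm"]), float(shape_spec["thickness"])
        _check_extent(arm / 2.0, grid_size, "lshape")
        h = thick / 2.0
        bar1 = (np.abs(x + arm / 4) <= arm / 2) & (np.abs(y) <= h) & (np.abs(z) <= h)
        bar2 = (np.abs(y + arm / 4) <= arm / 2) & (np.abs(x - arm / 4 + h) <= h) & (
            np.abs(z) <= h
        )
        inside = bar1 | bar2
    elif kind == "plate":
        width, thick = float(shape_spec["width"]), float(shape_spec["thickness"])
        _check_extent(width / np.sqrt(2), grid_size, "plate")
        inside = (x**2 + y**2 <= (width / 2) ** 2) & (np.abs(z) <= thick / 2)
    elif kind == "rod":
        length, radius = float(shape_spec["length"]), float(shape_spec["radius"])
        _check_extent(length / 2.0, grid_size, "rod")
        inside = (np.abs(x) <= length / 2) & (y**2 + z**2 <= radius**2)
    elif kind == "helix":
        radius = float(shape_spec["radius"])
        pitch = float(shape_spec["pitch"])
        turns = float(shape_spec["turns"])
        tube = float(shape_spec["tube"])
        height = pitch * turns
        _check_extent(max(radius + tube, height / 2 + tube), grid_size, "helix")
        t = np.linspace(-turns * np.pi, turns * np.pi, int(80 * turns))
        cx = radius * np.cos(t)
        cy = radius * np.sin(t)
        cz = t / (2 * np.pi) * pitch
        inside = np.zeros((grid_size,) * 3, dtype=bool)
        for px, py, pz in zip(cx, cy, cz):
            inside |= (x - px) ** 2 + (y - py) ** 2 + (z - pz) ** 2 <= tube**2
    else:
        raise ValueError(f"unknown phantom kind: {kind!r}")

    name = shape_spec.get("name", kind or "phantom")
    return DensityMap(inside.astype(np.float32), name=str(name))


def rasterize_structure(
    model: StructureModel, voxel_size: float, grid_size: int, resolution: float
) -> DensityMap:
    """Sum of isotropic Gaussians at (centered) atom positions.

    sigma = resolution / (pi * sqrt(2)) in Angstrom, a standard conversion
    between nominal map resolution and Gaussian width.
    """
    sigma_vox = resolution / (np.pi * np.sqrt(2.0)) / voxel_size
    center = np.mean(model.coords, axis=0)
    pos = (model.coords - center) / voxel_size + grid_size // 2
    bad = np.where(
        (pos < 0).any(axis=1) | (pos > grid_size - 1).any(axis=1)
    )[0]
    if len(bad):
        raise ValueError(
            f"{len(bad)} atoms fall outside the {grid_size}^3 grid after "
            f"centering (first offenders: {bad[:5].tolist()})"
        )
    grid = np.zeros((grid_size,) * 3, dtype=np.float64)
    # splat each atom onto a truncated local neighborhood (4 sigma)
    reach = max(int(np.ceil(4 * sigma_vox)), 1)
    offsets = np.arange(-reach, reach + 1)
    for p, w in zip(pos, model.weights):
        i0 = np.round(p).astype(int)
        ii = [np.clip(i0[d] + offsets, 0, grid_size - 1) for d in range(3)]
        dd = [(np.arange(i0[d] - reach, i0[d] + reach + 1) - p[d]) for d in range(3)]
        g = [np.exp(-(d * d) / (2 * sigma_vox**2)) for d in dd]
        kernel = w * g[0][:, None, None] * g[1][None, :, None] * g[2][None, None, :]
        np.add.at(grid, np.ix_(ii[0], ii[1], ii[2]), kernel)
    return DensityMap(grid.astype(np.float32), voxel_size=voxel_size)


def random_pose(rng: np.random.Generator, max_translation: float = 0.0) -> Pose:
    """Uniform SO(3) rotation (normalized-quaternion method) plus a uniform
    translation within a cube of half-width `max_translation` voxels."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, xq, yq, zq = q
    rot = np.array(
        [
            [1 - 2 * (yq**2 + zq**2), 2 * (xq * yq - zq * w), 2 * (xq * zq + yq * w)],
            [2 * (xq * yq + zq * w), 1 - 2 * (xq**2 + zq**2), 2 * (yq * zq - xq * w)],
            [2 * (xq * zq - yq * w), 2 * (yq * zq + xq * w), 1 - 2 * (xq**2 + yq**2)],
        ]
    )
    trans = rng.uniform(-max_translation, max_translation, size=3)
    return Pose(rot, trans)


def apply_pose(grid: np.ndarray, pose: Pose) -> np.ndarray:
    """Resample `grid` under a rigid pose: rotation about the grid center then
    translation, trilinear interpolation, zero outside."""
    center = np.array(grid.shape) // 2
    matrix = pose.rotation.T
    offset = center - matrix @ (center + pose.translation)
    return ndimage.affine_transform(
        grid, matrix, offset=offset, order=1, mode="constant", cval=0.0
    ).astype(np.float32)


def make_ground_truth_mask(dmap: DensityMap, threshold_frac: float = 0.0) -> np.ndarray:
    """Binary mask of voxels with density > threshold_frac * max(density)."""
    if not 0.0 <= threshold_frac < 1.0:
        raise ValueError("threshold_frac must be in [0, 1)")
    peak = float(dmap.grid.max())
    if peak == 0.0:
        warnings.warn("all-zero density map: ground-truth mask is empty")
        return np.zeros_like(dmap.grid, dtype=bool)
    return dmap.grid > threshold_frac * peak


_LIBRARY_SPECS = [
    {"kind": "sphere", "radius": 6, "name": "sphere"},
    {"kind": "shell", "outer": 8, "inner": 5.5, "name": "shell"},
    {"kind": "dumbbell", "radius": 4, "separation": 6, "name": "dumbbell"},
    {"kind": "torus", "major": 7, "minor": 2.5, "name": "torus"},
    {"kind": "lshape", "arm": 14, "thickness": 5, "name": "lshape"},
    {"kind": "plate", "width": 18, "thickness": 4, "name": "plate"},
    {"kind": "rod", "length": 22, "radius": 3, "name": "rod"},
    {"kind": "helix", "radius": 6, "pitch": 9, "turns": 2, "tube": 2.2, "name": "helix"},
]


def phantom_library(grid_size: int = 32, voxel_size: float = 10.0) -> list[DensityMap]:
    """Eight geometric phantom classes with well-separated canonical shapes."""
    maps = []
    for spec in _LIBRARY_SPECS:
        m = make_phantom(spec, grid_size)
        m.voxel_size = voxel_size
        maps.append(m)
    return maps


def load_structure(path: str) -> StructureModel:
    """Read atom coordinates (and atomic-number weights) from PDB/mmCIF."""
    import gemmi

    st = gemmi.read_structure(str(path))
    coords, weights = [], []
    for model in st:
        for chain in model:
            for residue in chain:
                for atom in residue:
                    coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
                    weights.append(atom.element.atomic_number or 1)
        break  # first model only
    if not coords:
        raise ValueError(f"no atoms found in {path}")
    return StructureModel(np.array(coords), np.array(weights, dtype=float))
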