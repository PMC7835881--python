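"""Realistic subtomogram simulation: pack structures into a volume, project a
single-axis tilt series (missing wedge), apply CTF/MTF, add Gaussian noise at
a target SNR, reconstruct by weighted back-projection and extract 32^3
subtomograms with ground-truth masks.

Geometry: volume axes are (H, W, D); the tilt axis is H (axis 0), the beam
runs along D at zero tilt, and each projection image has shape (H, n_det)
with the detector coordinate along W. Projection is implemented as an
explicit sparse linear operator (linear splatting of each voxel onto the
detector), so unfiltered back-projection is its exact matrix transpose.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

from .phantoms import DensityMap, Pose, apply_pose, random_pose

__all__ = [
    "TiltSeries",
    "OpticsParams",
    "SimulationConfig",
    "SubtomogramRecord",
    "TomoDataset",
    "pack_volume",
    "project_tilt_series",
    "backproject",
    "apply_ctf_mtf",
    "add_noise_to_snr",
    "reconstruct_wbp",
    "extract_subtomograms",
    "build_dataset",
    "electron_wavelength",
]


@dataclass
class TiltSeries:
    images: np.ndarray  # (n_angles, H, n_det)
    angles: np.ndarray  # degrees, strictly increasing

    def __post_init__(self):
        self.images = np.asarray(self.images, dtype=np.float64)
        self.angles = np.asarray(self.angles, dtype=np.float64)
        if len(self.images) != len(self.angles):
            raise ValueError("one image per tilt angle required")
        if len(self.angles) > 1:
            if not (np.diff(self.angles) > 0).all():
                raise ValueError("tilt angles must be strictly increasing")
            if self.angles[-1] - self.angles[0] >= 180.0:
                raise ValueError("tilt span must be < 180 degrees")


@dataclass
class OpticsParams:
    """Microscope model: CTF phase parameters plus a Gaussian MTF envelope."""

    voltage: float = 300.0           # kV
    defocus: float = -5.0            # um (negative = underfocus convention)
    spherical_aberration: float = 2.0  # mm
    amplitude_contrast: float = 0.07
    mtf_cutoff: float = 0.4          # fraction of Nyquist
    enabled: bool = True

    def __post_init__(self):
        if self.voltage <= 0:
            raise ValueError("voltage must be positive")
        if not 0.0 <= self.amplitude_contrast <= 1.0:
            raise ValueError("amplitude_contrast must be in [0, 1]")


@dataclass
class SimulationConfig:
    tilt_min: float = -60.0
    tilt_max: float = 60.0
    tilt_step: float = 2.0
    snr: float = np.inf
    tomogram_shape: tuple[int, int, int] = (150, 150, 100)
    n_particles: int = 100
    subtomo_size: int = 32
    voxel_size: float = 10.0         # Angstrom
    n_test_classes: int = 2
    test_classes: tuple[str, ...] | None = None  # explicit hold-out classes
    seed: int = 0
    optics: OpticsParams = field(default_factory=OpticsParams)
    mask_threshold_frac: float = 0.0

    def __post_init__(self):
        if self.tilt_min >= self.tilt_max:
            raise ValueError("tilt_min must be < tilt_max")
        if self.tilt_step <= 0:
            raise ValueError("tilt_step must be positive")
        if self.subtomo_size > min(self.tomogram_shape):
            raise ValueError("subtomo_size exceeds the tomogram")
        if not self.snr > 0:
            raise ValueError("snr must be positive (np.inf for noiseless)")

    @property
    def angles(self) -> np.ndarray:
        return np.arange(self.tilt_min, self.tilt_max + 1e-9, self.tilt_step)


@dataclass
class SubtomogramRecord:
    volume: np.ndarray       # (s, s, s) float
    class_label: str
    gt_mask: np.ndarray      # (s, s, s) bool
    pose: Pose
    snr: float
    split: str = ""

    def __post_init__(self):
        if not np.isfinite(self.volume).all():
            raise ValueError("subtomogram volume contains non-finite values")
        if self.volume.shape != self.gt_mask.shape:
            raise ValueError("mask shape must match volume shape")


@dataclass
class TomoDataset:
    records: list[SubtomogramRecord]
    class_names: list[str]
    train_classes: list[str]
    test_classes: list[str]
    snr: float
    seed: int

    def subset(self, split: str) -> list[SubtomogramRecord]:
        return [r for r in self.records if r.split == split]

    def by_class(self, split: str) -> dict[str, list[SubtomogramRecord]]:
        out: dict[str, list[SubtomogramRecord]] = {}
        for r in self.subset(split):
            out.setdefault(r.class_label, []).append(r)
        return out


# --------------------------------------------------------------------------
# projection operator


def _support_radius(grid: np.ndarray) -> float:
    idx = np.argwhere(grid > 0)
    if len(idx) == 0:
        return 0.0
    center = (np.array(grid.shape) - 1) / 2.0
    return float(np.sqrt(((idx - center) ** 2).sum(axis=1).max()))


_PROJ_CACHE: dict[tuple, sparse.csr_matrix] = {}


def _projection_matrix(w: int, d: int, angle_deg: float) -> sparse.csr_matrix:
    """(W*D, n_det) splatting matrix for one tilt angle; n_det = W."""
    key = (w, d, round(float(angle_deg), 6))
    m = _PROJ_CACHE.get(key)
    if m is not None:
        return m
    theta = np.deg2rad(angle_deg)
    cw, cd = w // 2, d // 2  # integer rotation center, matching apply_pose
    wi, di = np.meshgrid(np.arange(w), np.arange(d), indexing="ij")
    u = (wi - cw) * np.cos(theta) + (di - cd) * np.sin(theta) + cw
    u0 = np.floor(u).astype(int)
    frac = u - u0
    rows = np.arange(w * d)
    r = np.concatenate([rows, rows])
    c = np.concatenate([u0.ravel(), u0.ravel() + 1])
    v = np.concatenate([(1 - frac).ravel(), frac.ravel()])
    ok = (c >= 0) & (c < w)
    m = sparse.csr_matrix((v[ok], (r[ok], c[ok])), shape=(w * d, w))
    if len(_PROJ_CACHE) > 512:
        _PROJ_CACHE.clear()
    _PROJ_CACHE[key] = m
    return m


def project_tilt_series(volume: np.ndarray, angles) -> TiltSeries:
    """Line-integral projections of `volume` for each tilt angle (degrees)."""
    angles = np.atleast_1d(np.asarray(angles, dtype=np.float64))
    if (np.abs(angles) >= 90.0).any():
        raise ValueError("tilt angles must lie within (-90, 90) degrees")
    h, w, d = volume.shape
    v2d = volume.reshape(h, w * d)
    images = np.stack([v2d @ _projection_matrix(w, d, a) for a in angles])
    return TiltSeries(images, angles)


def backproject(ts: TiltSeries, shape: tuple[int, int, int]) -> np.ndarray:
    """Unfiltered back-projection: the exact adjoint of project_tilt_series."""
    h, w, d = shape
    vol = np.zeros((h, w * d))
    for img, a in zip(ts.images, ts.angles):
        vol += img @ _projection_matrix(w, d, a).T
    return vol.reshape(h, w, d)


def _ramp_filter(images: np.ndarray) -> np.ndarray:
    n_det = images.shape[-1]
    npad = max(64, int(2 ** np.ceil(np.log2(2 * n_det))))
    freqs = np.fft.fftfreq(npad)
    ramp = np.abs(freqs)
    spec = np.fft.fft(images, n=npad, axis=-1) * ramp
    return np.real(np.fft.ifft(spec, axis=-1))[..., :n_det]


def reconstruct_wbp(ts: TiltSeries, shape: tuple[int, int, int]) -> np.ndarray:
    """Weighted (ramp-filtered) back-projection reconstruction."""
    if len(ts.images) == 0:
        raise ValueError("empty tilt series")
    if len(ts.images) == 1:
        warnings.warn("single-projection reconstruction is severely ill-posed")
    filtered = _ramp_filter(ts.images)
    vol = backproject(TiltSeries(filtered, ts.angles), shape)
    return vol * np.pi / (2.0 * len(ts.angles))


# --------------------------------------------------------------------------
# optics and noise


def electron_wavelength(voltage_kv: float) -> float:
    """Relativistic electron wavelength in Angstrom."""
    v = voltage_kv * 1e3
    return 12.2639 / np.sqrt(v + 0.97845e-6 * v**2)


def ctf_mtf_transfer(shape: tuple[int, int], pixel_size: float,
                     optics: OpticsParams) -> np.ndarray:
    """2D transfer function CTF(f) * MTF(f) on the FFT grid of `shape`.

    CTF(f) = -(sqrt(1 - A^2) sin(gamma) + A cos(gamma)), with phase
    gamma(f) = pi*lambda*defocus*f^2 - (pi/2)*Cs*lambda^3*f^4.
    MTF is a Gaussian envelope exp(-0.5 (f/fc)^2), fc = cutoff * Nyquist.
    """
    lam = electron_wavelength(optics.voltage)
    defocus_a = optics.defocus * 1e4      # um -> A
    cs_a = optics.spherical_aberration * 1e7  # mm -> A
    fy = np.fft.fftfreq(shape[0], d=pixel_size)
    fx = np.fft.fftfreq(shape[1], d=pixel_size)
    f2 = fy[:, None] ** 2 + fx[None, :] ** 2
    gamma = np.pi * lam * defocus_a * f2 - 0.5 * np.pi * cs_a * lam**3 * f2**2
    a = optics.amplitude_contrast
    ctf = -(np.sqrt(1 - a**2) * np.sin(gamma) + a * np.cos(gamma))
    f_nyq = 0.5 / pixel_size
    fc = optics.mtf_cutoff * f_nyq
    mtf = np.exp(-0.5 * f2 / fc**2)
    return ctf * mtf


def apply_ctf_mtf(ts: TiltSeries, optics: OpticsParams,
                  pixel_size: float = 10.0) -> TiltSeries:
    """Frequency-domain application of the optical transfer function."""
    if not optics.enabled:
        return TiltSeries(ts.images.copy(), ts.angles.copy())
    transfer = ctf_mtf_transfer(ts.images.shape[1:], pixel_size, optics)
    spec = np.fft.fft2(ts.images, axes=(1, 2)) * transfer
    return TiltSeries(np.real(np.fft.ifft2(spec, axes=(1, 2))), ts.angles.copy())


def add_noise_to_snr(ts: TiltSeries, snr: float,
                     rng: np.random.Generator) -> TiltSeries:
    """Additive zero-mean Gaussian noise; SNR = var(signal)/var(noise) over
    the whole projection stack. snr = inf returns the input unchanged."""
    if not snr > 0:
        raise ValueError("snr must be positive")
    if np.isinf(snr):
        return TiltSeries(ts.images.copy(), ts.angles.copy())
    sig_var = float(ts.images.var())
    noise = rng.normal(0.0, np.sqrt(sig_var / snr), size=ts.images.shape)
    return TiltSeries(ts.images + noise, ts.angles.copy())


# --------------------------------------------------------------------------
# packing, extraction, full pipeline


def pack_volume(
    maps: list[DensityMap],
    n_particles: int,
    shape: tuple[int, int, int],
    rng: np.random.Generator,
    margin: float | None = None,
    max_retries: int = 1000,
) -> tuple[np.ndarray, list[tuple[str, Pose, np.ndarray]]]:
    """Place randomly posed copies of the class maps into an empty volume.

    Classes are drawn balanced (round-robin). Bounding-sphere rejection
    sampling prevents overlap. Returns the packed density and a placement
    list of (class_name, pose, integer center position).
    """
    volume = np.zeros(shape, dtype=np.float64)
    placements: list[tuple[str, Pose, np.ndarray]] = []
    if n_particles == 0:
        return volume, placements
    radii = [_support_radius(m.grid) for m in maps]
    centers: list[np.ndarray] = []
    placed_radii: list[float] = []
    for i in range(n_particles):
        ci = i % len(maps)
        dmap, rad = maps[ci], radii[ci]
        g = dmap.grid.shape[0]
        half = g // 2
        mrg = rad if margin is None else max(margin, rad)
        # the full (posed) map grid must fit, not just its bounding sphere
        lo = max(int(np.ceil(mrg)), half)
        hi = np.minimum(np.array(shape) - 1 - int(np.ceil(mrg)),
                        np.array(shape) - (g - half))
        if (hi < lo).any():
            raise ValueError(f"map {dmap.name!r} does not fit in volume {shape}")
        ok = False
        for _ in range(max_retries):
            pos = np.array([rng.integers(lo, int(h) + 1) for h in hi])
            if all(
                np.linalg.norm(pos - c) > rad + r
                for c, r in zip(centers, placed_radii)
            ):
                ok = True
                break
        if not ok:
            warnings.warn(
                f"packing stopped after {len(placements)} of {n_particles} "
                f"particles (no room left)"
            )
            break
        pose = random_pose(rng, max_translation=0.5)
        posed = apply_pose(dmap.grid, pose)
        g = dmap.grid.shape[0]
        corner = pos - g // 2
        sl = tuple(slice(c, c + g) for c in corner)
        volume[sl] += posed
        placements.append((dmap.name, pose, pos))
        centers.append(pos.astype(float))
        placed_radii.append(rad)
    return volume, placements


def extract_subtomograms(
    tomogram: np.ndarray,
    placements: list[tuple[str, Pose, np.ndarray]],
    subtomo_size: int,
    gt_maps: dict[str, DensityMap],
    snr: float = np.inf,
    mask_threshold_frac: float = 0.0,
) -> list[SubtomogramRecord]:
    """Crop one cube per in-bounds placement; the ground-truth mask is the
    identically posed source map, thresholded. Out-of-bounds placements are
    skipped (count logged as a warning)."""
    if subtomo_size % 2:
        raise ValueError("subtomo_size must be even")
    s = subtomo_size
    records: list[SubtomogramRecord] = []
    skipped = 0
    for name, pose, pos in placements:
        start = pos - s // 2
        end = start + s
        if (start < 0).any() or (end > np.array(tomogram.shape)).any():
            skipped += 1
            continue
        sl = tuple(slice(a, b) for a, b in zip(start, end))
        vol = np.asarray(tomogram[sl], dtype=np.float32)
        src = gt_maps[name]
        posed = apply_pose(src.grid, pose)
        g = posed.shape[0]
        canvas = np.zeros((s, s, s), dtype=np.float32)
        off = (s - g) // 2
        canvas[off:off + g, off:off + g, off:off + g] = posed
        peak = canvas.max()
        mask = canvas > mask_threshold_frac * peak if peak > 0 else canvas > 0
        records.append(SubtomogramRecord(vol, name, mask, pose, snr))
    if skipped:
        warnings.warn(f"skipped {skipped} out-of-bounds placements")
    return records


def build_dataset(config: SimulationConfig,
                  class_maps: list[DensityMap]) -> TomoDataset:
    """Run the full simulation pipeline and split classes into train/test.

    pack -> project tilt series -> CTF/MTF -> noise at SNR -> WBP
    reconstruction -> subtomogram extraction. The class-level split is
    disjoint: test classes are never seen in training.
    """
    if len(class_maps) < 2:
        raise ValueError("need at least 2 classes")
    n_held_out = (len(config.test_classes) if config.test_classes is not None
                  else config.n_test_classes)
    if n_held_out >= len(class_maps):
        raise ValueError(
            f"cannot hold out {n_held_out} of {len(class_maps)} classes"
        )
    ss = np.random.SeedSequence(config.seed)
    rng_pack, rng_noise, rng_split = [np.random.default_rng(s) for s in ss.spawn(3)]

    volume, placements = pack_volume(
        class_maps, config.n_particles, config.tomogram_shape, rng_pack,
        margin=config.subtomo_size / 2,
    )
    ts = project_tilt_series(volume, config.angles)
    ts = apply_ctf_mtf(ts, config.optics, pixel_size=config.voxel_size)
    ts = add_noise_to_snr(ts, config.snr, rng_noise)
    recon = reconstruct_wbp(ts, config.tomogram_shape)

    gt_maps = {m.name: m for m in class_maps}
    records = extract_subtomograms(
        recon, placements, config.subtomo_size, gt_maps, snr=config.snr,
        mask_threshold_frac=config.mask_threshold_frac,
    )

    names = [m.name for m in class_maps]
    if config.test_classes is not None:
        test_classes = list(config.test_classes)
        unknown = set(test_classes) - set(names)
        if unknown:
            raise ValueError(f"unknown test classes: {sorted(unknown)}")
    else:
        order = rng_split.permutation(len(names))
        test_classes = [names[i] for i in order[: config.n_test_classes]]
    train_classes = [n for n in names if n not in test_classes]
    for r in records:
        r.split = "test" if r.class_label in test_classes else "train"
    return TomoDataset(records, names, train_classes, test_classes,
                       config.snr, config.seed)
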