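"""Synthetic dual-layer spectral CT phantom with a hollow-artery calcium insert.

This module emulates an anthropomorphic thorax phantom carrying a hollow
artificial coronary artery in a water bath.  The artery lumen (5 mm diameter)
is filled with a blood-equivalent water/glucose mixture (40 HU), optionally
spiked with iodinated contrast, and carries five concentric ring calcifications
of calcium hydroxyapatite (CaHA) at increasing density.  Each scan produces a
:class:`SpectralVolume`: a conventional 120 kVp HU image plus the two
dual-layer base images (photoelectric effect and Compton scatter) on one voxel
grid.

The geometry is rasterized analytically with sub-voxel supersampling (partial
volume by area/volume averaging), repositioned per repetition by a seeded rigid
jitter, degraded by per-channel Gaussian noise, and finally resampled along z
into overlapping reconstruction slabs (slice thickness / increment).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "CalcificationSpec",
    "PhantomSpec",
    "ScanProtocol",
    "SpectralVolume",
    "MaterialPoint",
    "SpectralCoefficients",
    "DEFAULT_COEFFICIENTS",
    "CAHA_CALIBRATION",
    "LUMEN_CALIBRATION",
    "material_to_hu",
    "lumen_material",
    "ring_volume",
    "build_phantom",
    "resample_slices",
    "default_phantom_spec",
    "phantom_manifest",
]


# Printed HU calibration of the insert: CaHA density (mg/cc) -> conventional HU
# (70 keV monoenergetic, used interchangeably with 120 kVp conventional HU),
# anchored at water = 0 HU.
CAHA_CALIBRATION: tuple[tuple[float, float], ...] = (
    (0.0, 0.0),
    (75.0, 96.0),
    (100.0, 129.0),
    (200.0, 259.0),
    (400.0, 521.0),
    (800.0, 1044.0),
)

# Lumen mixture calibration: clinical contrast dose fraction -> conventional HU
# of the blood/iodine mixture (blood-equivalent baseline 40 HU at 0%).
LUMEN_CALIBRATION: tuple[tuple[float, float], ...] = (
    (0.0, 40.0),
    (0.5, 185.0),
    (1.0, 390.0),
    (1.5, 590.0),
)

# Protocol reference point for the first-order noise scaling
# sigma ~ sqrt(mAs_ref / mAs) * sqrt(3.0 mm / thickness).
MAS_REFERENCE = 202.0
THICKNESS_REFERENCE_MM = 3.0


@dataclass(frozen=True)
class SpectralCoefficients:
    """Per-material directions of the synthetic base images.

    Each coefficient is the base-image response per conventional HU of that
    material above the water baseline.  The vendor's base-image scaling is
    proprietary; these defaults are calibrated, not physical.  They are chosen
    so that the shipped decision boundary (slope 3.69, intercept -3361)
    separates pure CaHA (any density >= ~37 HU) from the contrast-filled lumen
    at every contrast dose from 0% to 150%:

    * CaHA is Compton-heavy here, so ``3.69 * compton - pe`` clears the
      intercept already at low densities;
    * iodine is photoelectric-heavy, keeping the lumen above the boundary.
    """

    caha_pe: float = 2.0
    caha_compton: float = 25.0
    iodine_pe: float = 3.38
    iodine_compton: float = 2.0
    blood_pe: float = 0.0
    blood_compton: float = 1.5


DEFAULT_COEFFICIENTS = SpectralCoefficients()


@dataclass(frozen=True)
class MaterialPoint:
    """Channel values of one material (or mixture) above the water baseline."""

    caha_density: float
    iodine_fraction: float
    hu_conventional: float
    hu_pe: float
    hu_compton: float

    @property
    def triple(self) -> tuple[float, float, float]:
        return (self.hu_conventional, self.hu_pe, self.hu_compton)


def _piecewise_linear(x: float, points: tuple[tuple[float, float], ...]) -> float:
    """Monotone piecewise-linear interpolation with end-slope extrapolation."""
    xs = np.array([p[0] for p in points])
    ys = np.array([p[1] for p in points])
    if x <= xs[0]:
        slope = (ys[1] - ys[0]) / (xs[1] - xs[0])
        return float(ys[0] + (x - xs[0]) * slope)
    if x >= xs[-1]:
        slope = (ys[-1] - ys[-2]) / (xs[-1] - xs[-2])
        return float(ys[-1] + (x - xs[-1]) * slope)
    return float(np.interp(x, xs, ys))


def material_to_hu(
    caha_density: float,
    iodine_fraction: float = 0.0,
    coefficients: SpectralCoefficients = DEFAULT_COEFFICIENTS,
    lumen_base_hu: float = 40.0,
) -> MaterialPoint:
    """Channel values of a pure material voxel.

    ``caha_density`` (mg CaHA/cc) and ``iodine_fraction`` (fraction of the
    clinical contrast dose) may not both be nonzero: mixtures are formed by
    the rasterizer as volume-weighted sums over the water baseline.  A lumen
    query (``iodine_fraction > 0``) returns the blood/iodine *mixture*
    including the 40 HU blood baseline, matching the printed lumen HU.
    ``material_to_hu(0, 0)`` is water (0 HU everywhere); the contrast-free
    blood-filled lumen is :func:`lumen_material` at fraction 0.
    """
    if caha_density < 0:
        raise ValueError(f"caha_density must be >= 0, got {caha_density}")
    if iodine_fraction < 0:
        raise ValueError(f"iodine_fraction must be >= 0, got {iodine_fraction}")
    if caha_density > 0 and iodine_fraction > 0:
        raise ValueError("at most one of caha_density / iodine_fraction may be nonzero")
    if caha_density > 0:
        conv = _piecewise_linear(caha_density, CAHA_CALIBRATION)
        return MaterialPoint(
            caha_density,
            0.0,
            conv,
            coefficients.caha_pe * conv,
            coefficients.caha_compton * conv,
        )
    if iodine_fraction > 0:
        point = lumen_material(iodine_fraction, coefficients, lumen_base_hu)
        return point
    return MaterialPoint(0.0, 0.0, 0.0, 0.0, 0.0)


def lumen_material(
    contrast_fraction: float,
    coefficients: SpectralCoefficients = DEFAULT_COEFFICIENTS,
    lumen_base_hu: float = 40.0,
) -> MaterialPoint:
    """Blood/iodine lumen mixture at a clinical contrast dose fraction.

    The conventional HU follows the printed lumen calibration (40 HU blood at
    0%, ~185/390/590 HU at 50/100/150%); the base images are the sum of the
    blood baseline and the iodine enhancement along their respective
    directions.
    """
    if contrast_fraction < 0:
        raise ValueError(f"contrast_fraction must be >= 0, got {contrast_fraction}")
    conv = _piecewise_linear(contrast_fraction, LUMEN_CALIBRATION)
    # Rescale the table's 40 HU baseline if a different blood HU is requested.
    conv = conv + (lumen_base_hu - 40.0)
    enhancement = conv - lumen_base_hu
    pe = coefficients.blood_pe * lumen_base_hu + coefficients.iodine_pe * enhancement
    compton = (
        coefficients.blood_compton * lumen_base_hu
        + coefficients.iodine_compton * enhancement
    )
    return MaterialPoint(0.0, contrast_fraction, conv, pe, compton)


def ring_volume(inner_diameter: float, outer_diameter: float, length: float) -> float:
    """Analytic volume (mm^3) of an annular ring calcification."""
    if not 0 <= inner_diameter <= outer_diameter:
        raise ValueError(
            f"need 0 <= inner_diameter <= outer_diameter, got {inner_diameter}, {outer_diameter}"
        )
    if length <= 0:
        raise ValueError(f"length must be > 0, got {length}")
    return math.pi * ((outer_diameter / 2) ** 2 - (inner_diameter / 2) ** 2) * length


@dataclass(frozen=True)
class CalcificationSpec:
    """One concentric ring calcification inside the hollow artery."""

    density: float  # mg CaHA / cc
    inner_diameter: float = 5.0  # mm
    outer_diameter: float = 11.0  # mm
    length: float = 5.0  # mm
    center_z: float = 0.0  # mm along the artery axis
    name: str = ""

    def __post_init__(self) -> None:
        if self.density <= 0:
            raise ValueError(f"density must be > 0, got {self.density}")
        if not 0 <= self.inner_diameter < self.outer_diameter:
            raise ValueError("need 0 <= inner_diameter < outer_diameter")
        if self.length <= 0:
            raise ValueError("length must be > 0")
        if not self.name:
            object.__setattr__(self, "name", f"{self.density:g}mgcc")

    @property
    def z_extent(self) -> tuple[float, float]:
        return (self.center_z - self.length / 2, self.center_z + self.length / 2)

    @property
    def analytic_volume(self) -> float:
        return ring_volume(self.inner_diameter, self.outer_diameter, self.length)


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and filling of the hollow-artery calcium insert."""

    calcifications: tuple[CalcificationSpec, ...]
    lumen_contrast_fraction: float = 0.0
    lumen_base_hu: float = 40.0
    background_hu: float = 0.0
    artery_length_mm: float = 80.0
    lumen_radius_mm: float = 2.5
    artery_axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    reposition_rotation_deg: float = 2.0
    reposition_translation_mm: float = 2.0
    coefficients: SpectralCoefficients = field(default=DEFAULT_COEFFICIENTS)

    def __post_init__(self) -> None:
        if self.lumen_contrast_fraction < 0:
            raise ValueError("lumen_contrast_fraction must be >= 0")
        if self.reposition_rotation_deg < 0 or self.reposition_translation_mm < 0:
            raise ValueError("reposition magnitudes must be >= 0")
        axis = np.asarray(self.artery_axis, dtype=float)
        norm = np.linalg.norm(axis)
        if not norm > 0:
            raise ValueError("artery_axis must be a nonzero vector")
        object.__setattr__(self, "artery_axis", tuple(axis / norm))
        object.__setattr__(self, "calcifications", tuple(self.calcifications))
        half = self.artery_length_mm / 2
        extents = sorted(c.z_extent for c in self.calcifications)
        for (lo, hi) in extents:
            if lo < -half or hi > half:
                raise ValueError(
                    f"calcification [{lo}, {hi}] mm extends outside the "
                    f"artery segment [+-{half}] mm"
                )
        for (_, hi), (lo, _) in zip(extents, extents[1:]):
            if lo < hi:
                raise ValueError("calcification z-extents overlap")

    def calcium_free_center(self) -> float | None:
        """Center of the widest calcium-free lumen stretch (>= 6 mm), if any."""
        half = self.artery_length_mm / 2
        edges = [-half]
        for lo, hi in sorted(c.z_extent for c in self.calcifications):
            edges.extend([lo, hi])
        edges.append(half)
        best: tuple[float, float] | None = None
        for lo, hi in zip(edges[::2], edges[1::2]):
            if best is None or (hi - lo) > (best[1] - best[0]):
                best = (lo, hi)
        if best is None or best[1] - best[0] < 6.0:
            return None
        return (best[0] + best[1]) / 2


@dataclass(frozen=True)
class ScanProtocol:
    """Acquisition / reconstruction parameters of one synthetic scan.

    Defaults follow the contrast-enhanced coronary protocol: 220 mm field of
    view on a 512 matrix (0.4297 mm pixels), 202 mAs, reconstructed at
    3.0/1.5 mm.  Noise sigmas are per-channel Gaussian standard deviations at
    the (202 mAs, 3.0 mm) reference, applied on the native z grid and scaled
    by sqrt(mAs_ref/mAs) * sqrt(3.0/thickness).
    """

    fov_mm: float = 220.0
    matrix: int = 512
    slice_thickness_mm: float = 3.0
    slice_increment_mm: float = 1.5
    native_spacing_mm: float = 0.335
    supersample: int = 3
    noise_sigma_conv: float = 20.0
    noise_sigma_pe: float = 40.0
    noise_sigma_compton: float = 60.0
    mas: float = 202.0
    seed: int = 0
    z_margin_mm: float = 5.0

    def __post_init__(self) -> None:
        if self.matrix <= 0:
            raise ValueError("matrix must be > 0")
        if not 0 < self.slice_increment_mm <= self.slice_thickness_mm:
            raise ValueError("need 0 < slice_increment_mm <= slice_thickness_mm")
        if self.native_spacing_mm <= 0 or self.native_spacing_mm > self.slice_thickness_mm:
            raise ValueError("native z sampling must be finer than the slice thickness")
        if self.supersample < 1:
            raise ValueError("supersample must be >= 1")
        if min(self.noise_sigma_conv, self.noise_sigma_pe, self.noise_sigma_compton) < 0:
            raise ValueError("noise sigmas must be >= 0")
        if self.mas <= 0:
            raise ValueError("mas must be > 0")

    @property
    def pixel_mm(self) -> float:
        return self.fov_mm / self.matrix

    @property
    def noise_scale(self) -> float:
        return math.sqrt(MAS_REFERENCE / self.mas) * math.sqrt(
            THICKNESS_REFERENCE_MM / self.slice_thickness_mm
        )

    def noiseless(self) -> "ScanProtocol":
        return replace(
            self, noise_sigma_conv=0.0, noise_sigma_pe=0.0, noise_sigma_compton=0.0
        )


@dataclass
class SpectralVolume:
    """Co-registered conventional / photoelectric / Compton volumes.

    Arrays are indexed ``[x, y, z]``; ``spacing`` and ``origin`` are in mm,
    with world coordinates at voxel centers.
    """

    conventional: np.ndarray
    pe_base: np.ndarray
    compton_base: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.conventional = np.asarray(self.conventional, dtype=float)
        self.pe_base = np.asarray(self.pe_base, dtype=float)
        self.compton_base = np.asarray(self.compton_base, dtype=float)
        if not (
            self.conventional.shape == self.pe_base.shape == self.compton_base.shape
        ):
            raise ValueError("the three channels must share one shape")
        if self.conventional.ndim != 3:
            raise ValueError("channels must be 3D arrays")
        if min(self.spacing) <= 0:
            raise ValueError("spacing components must be > 0")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.conventional.shape

    @property
    def z_centers(self) -> np.ndarray:
        return self.origin[2] + np.arange(self.shape[2]) * self.spacing[2]

    @property
    def voxel_volume(self) -> float:
        return self.spacing[0] * self.spacing[1] * self.spacing[2]


def default_phantom_spec(
    contrast_fraction: float = 0.0,
    densities: tuple[float, ...] = (75.0, 100.0, 200.0, 400.0, 800.0),
    spacing_mm: float = 13.0,
    **kwargs,
) -> PhantomSpec:
    """The five-ring insert: densities ascending along z, 13 mm apart."""
    n = len(densities)
    centers = (np.arange(n) - (n - 1) / 2) * spacing_mm
    calcs = tuple(
        CalcificationSpec(density=d, center_z=float(c))
        for d, c in zip(densities, centers)
    )
    return PhantomSpec(
        calcifications=calcs, lumen_contrast_fraction=contrast_fraction, **kwargs
    )


def phantom_manifest(spec: PhantomSpec) -> list[dict]:
    """Per-calcification ground truth plus a calcium-free control region."""
    entries = [
        {
            "name": c.name,
            "density": c.density,
            "center_z": c.center_z,
            "analytic_volume_mm3": c.analytic_volume,
        }
        for c in spec.calcifications
    ]
    free = spec.calcium_free_center()
    if free is not None:
        entries.append(
            {
                "name": "calcium_free",
                "density": 0.0,
                "center_z": free,
                "analytic_volume_mm3": 0.0,
            }
        )
    return entries


def _jitter_transform(
    spec: PhantomSpec, seed: int, repetition: int
) -> tuple[np.ndarray, np.ndarray, np.random.Generator]:
    """Seeded rigid repositioning of the insert for one repetition.

    Rotation: uniform angle within +-reposition_rotation_deg about a random
    transverse axis; translation: uniform within +-reposition_translation_mm
    per component.  The returned generator continues the same stream (used for
    noise), so repetitions are independent and seeds reproducible.
    """
    rng = np.random.default_rng([int(seed) % (2**31), int(repetition)])
    angle = math.radians(rng.uniform(-spec.reposition_rotation_deg, spec.reposition_rotation_deg))
    azimuth = rng.uniform(0.0, 2 * math.pi)
    rotvec = angle * np.array([math.cos(azimuth), math.sin(azimuth), 0.0])
    jitter = Rotation.from_rotvec(rotvec)
    axis = np.asarray(spec.artery_axis)
    if np.allclose(axis, [0.0, 0.0, 1.0]):
        base = Rotation.identity()
    else:
        base, _ = Rotation.align_vectors(axis[None, :], np.array([[0.0, 0.0, 1.0]]))
    matrix = (jitter * base).as_matrix()
    translation = rng.uniform(
        -spec.reposition_translation_mm, spec.reposition_translation_mm, size=3
    )
    return matrix, translation, rng


def _rasterize(
    spec: PhantomSpec,
    protocol: ScanProtocol,
    matrix: np.ndarray,
    translation: np.ndarray,
) -> SpectralVolume:
    """Anti-aliased rasterization of the insert on the native grid."""
    n = protocol.matrix
    px = protocol.pixel_mm
    dz = protocol.native_spacing_mm
    half_z = spec.artery_length_mm / 2 + protocol.z_margin_mm
    nz = max(1, int(math.ceil(2 * half_z / dz)))
    x = (np.arange(n) - (n - 1) / 2) * px
    y = (np.arange(n) - (n - 1) / 2) * px
    z = (np.arange(nz) - (nz - 1) / 2) * dz

    lumen = lumen_material(
        spec.lumen_contrast_fraction, spec.coefficients, spec.lumen_base_hu
    )
    rings = [
        (c, material_to_hu(c.density, 0.0, spec.coefficients)) for c in spec.calcifications
    ]

    ss = protocol.supersample
    offsets = (np.arange(ss) + 0.5) / ss - 0.5
    channels = [np.zeros((n, n, nz)) for _ in range(3)]
    r_lumen2 = spec.lumen_radius_mm**2
    half_art = spec.artery_length_mm / 2
    minv = matrix  # world -> artery frame uses matrix transpose

    chunk = max(1, int(2_000_000 / (n * n)))
    for z0 in range(0, nz, chunk):
        zc = z[z0 : z0 + chunk]
        acc = [np.zeros((n, n, zc.size)) for _ in range(3)]
        for ox in offsets * px:
            for oy in offsets * px:
                for oz in offsets * dz:
                    X = (x + ox - translation[0])[:, None, None]
                    Y = (y + oy - translation[1])[None, :, None]
                    Z = (zc + oz - translation[2])[None, None, :]
                    u = minv[0, 0] * X + minv[1, 0] * Y + minv[2, 0] * Z
                    v = minv[0, 1] * X + minv[1, 1] * Y + minv[2, 1] * Z
                    zeta = minv[0, 2] * X + minv[1, 2] * Y + minv[2, 2] * Z
                    rho2 = u * u + v * v
                    in_artery = np.abs(zeta) <= half_art
                    lum = (rho2 < r_lumen2) & in_artery
                    for ch, val in enumerate(lumen.triple):
                        if val:
                            acc[ch] += np.where(lum, val, 0.0)
                    for calc, mat in rings:
                        lo, hi = calc.z_extent
                        rin2 = (calc.inner_diameter / 2) ** 2
                        rout2 = (calc.outer_diameter / 2) ** 2
                        mask = (
                            (rho2 >= rin2)
                            & (rho2 < rout2)
                            & (zeta >= lo)
                            & (zeta <= hi)
                        )
                        for ch, val in enumerate(mat.triple):
                            if val:
                                acc[ch] += np.where(mask, val, 0.0)
        for ch in range(3):
            channels[ch][:, :, z0 : z0 + chunk] = acc[ch] / ss**3

    if spec.background_hu:
        # Homogeneous water bath offset (blood-like spectral direction).
        channels[0] += spec.background_hu
        channels[1] += spec.coefficients.blood_pe * spec.background_hu
        channels[2] += spec.coefficients.blood_compton * spec.background_hu

    return SpectralVolume(
        conventional=channels[0],
        pe_base=channels[1],
        compton_base=channels[2],
        spacing=(px, px, dz),
        origin=(float(x[0]), float(y[0]), float(z[0])),
    )


def build_phantom(
    spec: PhantomSpec, protocol: ScanProtocol, repetition: int = 0
) -> SpectralVolume:
    """Simulate one spectral scan of the phantom.

    Steps: seeded rigid repositioning jitter for this repetition, supersampled
    rasterization (partial volume), independent per-channel Gaussian noise on
    the native grid, then z resampling into overlapping reconstruction slabs.
    Identical ``(seed, repetition)`` pairs are bit-reproducible.
    """
    if repetition < 0:
        raise ValueError("repetition must be >= 0")
    matrix, translation, rng = _jitter_transform(spec, protocol.seed, repetition)
    volume = _rasterize(spec, protocol, matrix, translation)

    scale = protocol.noise_scale
    sigmas = (
        protocol.noise_sigma_conv,
        protocol.noise_sigma_pe,
        protocol.noise_sigma_compton,
    )
    for arr, sigma in zip(
        (volume.conventional, volume.pe_base, volume.compton_base), sigmas
    ):
        if sigma > 0:
            arr += rng.normal(0.0, sigma * scale, size=arr.shape)

    if (
        protocol.slice_thickness_mm == protocol.native_spacing_mm
        and protocol.slice_increment_mm == protocol.native_spacing_mm
    ):
        return volume
    return resample_slices(
        volume, protocol.slice_thickness_mm, protocol.slice_increment_mm
    )


def resample_slices(
    volume: SpectralVolume, thickness: float, increment: float
) -> SpectralVolume:
    """Resample z into overlapping slabs of ``thickness`` spaced by ``increment``.

    Each output slice is the mean of the native slices whose centers fall in a
    slab of the given thickness centered on the output position; all three
    channels are treated identically.  Only the overlapping-slab convention
    (``increment <= thickness``) is supported.
    """
    if increment > thickness:
        raise ValueError("increment must be <= thickness (overlapping slabs only)")
    if increment <= 0:
        raise ValueError("increment must be > 0")
    dz = volume.spacing[2]
    if dz > thickness + 1e-9:
        raise ValueError("native z sampling must be finer than the target thickness")
    z = volume.z_centers
    c0 = z[0] + (thickness - dz) / 2
    centers = []
    c = c0
    while c + thickness / 2 <= z[-1] + dz / 2 + 1e-9:
        centers.append(c)
        c += increment
    if not centers:
        centers = [z[0] + (z[-1] - z[0]) / 2]
    centers = np.asarray(centers)

    lo = np.searchsorted(z, centers - thickness / 2 - 1e-9, side="left")
    hi = np.searchsorted(z, centers + thickness / 2 - 1e-9, side="right")
    hi = np.maximum(hi, lo + 1)

    def slab(arr: np.ndarray) -> np.ndarray:
        cum = np.concatenate(
            [np.zeros(arr.shape[:2] + (1,)), np.cumsum(arr, axis=2)], axis=2
        )
        out = np.empty(arr.shape[:2] + (centers.size,))
        for j, (a, b) in enumerate(zip(lo, hi)):
            out[:, :, j] = (cum[:, :, b] - cum[:, :, a]) / (b - a)
        return out

    return SpectralVolume(
        conventional=slab(volume.conventional),
        pe_base=slab(volume.pe_base),
        compton_base=slab(volume.compton_base),
        spacing=(volume.spacing[0], volume.spacing[1], float(increment)),
        origin=(volume.origin[0], volume.origin[1], float(centers[0])),
    )
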