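"""Independent reference implementations used as test oracles.

Everything here is deliberately written without the package's scoring or
rasterization code paths: the Agatston reference is an exhaustive per-pixel
flood fill with union-find grouping, and the slab model predicts voxelized
ring scores from grid parameters and closed-form geometry alone.
"""

from __future__ import annotations

import math

import numpy as np


# ---------------------------------------------------------------------------
# Exhaustive per-pixel Agatston reference (no scipy.ndimage)


def _flood_components(mask2d: np.ndarray) -> list[list[tuple[int, int]]]:
    """8-connected components by explicit stack-based flood fill."""
    visited = np.zeros_like(mask2d, dtype=bool)
    comps = []
    nx, ny = mask2d.shape
    for i in range(nx):
        for j in range(ny):
            if not mask2d[i, j] or visited[i, j]:
                continue
            stack = [(i, j)]
            visited[i, j] = True
            comp = []
            while stack:
                a, b = stack.pop()
                comp.append((a, b))
                for da in (-1, 0, 1):
                    for db in (-1, 0, 1):
                        na, nb = a + da, b + db
                        if (
                            0 <= na < nx
                            and 0 <= nb < ny
                            and mask2d[na, nb]
                            and not visited[na, nb]
                        ):
                            visited[na, nb] = True
                            stack.append((na, nb))
            comps.append(comp)
    return comps


def _weight(max_hu: float) -> int:
    if max_hu >= 400:
        return 4
    if max_hu >= 300:
        return 3
    if max_hu >= 200:
        return 2
    return 1


def reference_agatston(
    image: np.ndarray,
    spacing: tuple[float, float, float],
    hu_threshold: float = 130.0,
    min_area_mm2: float = 0.5,
) -> list[float]:
    """Sorted per-3D-lesion raw Agatston scores by exhaustive evaluation."""
    image = np.asarray(image, dtype=float)
    pixel_area = spacing[0] * spacing[1]
    kept: list[tuple[int, list[tuple[int, int]], float]] = []  # (slice, pixels, score)
    for k in range(image.shape[2]):
        for comp in _flood_components(image[:, :, k] >= hu_threshold):
            area = len(comp) * pixel_area
            if area < min_area_mm2 - 1e-9:
                continue
            max_hu = max(image[a, b, k] for a, b in comp)
            kept.append((k, comp, area * _weight(max_hu)))

    # union-find over kept 2D components: same 3D lesion when any pixel pair
    # is within one step in-plane (Chebyshev) and one slice apart (or same).
    parent = list(range(len(kept)))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i in range(len(kept)):
        for j in range(i + 1, len(kept)):
            ki, pi, _ = kept[i]
            kj, pj, _ = kept[j]
            if abs(ki - kj) > 1:
                continue
            touch = any(
                abs(a1 - a2) <= 1 and abs(b1 - b2) <= 1
                for a1, b1 in pi
                for a2, b2 in pj
            )
            if touch:
                ra, rb = find(i), find(j)
                if ra != rb:
                    parent[rb] = ra

    scores: dict[int, float] = {}
    for idx, (_, _, score) in enumerate(kept):
        root = find(idx)
        scores[root] = scores.get(root, 0.0) + score
    return sorted(scores.values())


# ---------------------------------------------------------------------------
# Closed-form slab model for the voxelized noiseless ring phantom


def pixel_edge_offset(f_min: float, pixel_mm: float) -> float:
    """Signed distance from a pixel center to a half-plane edge at which the
    covered fraction equals ``f_min``, averaged over edge orientations."""
    thetas = np.linspace(0.0, math.pi / 4, 64)
    out = []
    for th in thetas:
        c, s = math.cos(th), math.sin(th)
        f = min(f_min, 1.0 - f_min)
        a = pixel_mm
        corner_f = ((a / 2) * (c + s) - (a / 2) * (c - s)) ** 2 / (2 * a * a * s * c) if s > 1e-9 else 0.0
        if s > 1e-9 and f < corner_f:
            d = (a / 2) * (c + s) - math.sqrt(2 * f * a * a * s * c)
        else:
            d = (0.5 - f) * a * c
        out.append(d if f_min <= 0.5 else -d)
    return float(np.mean(out))


def _native_grid(spec, protocol) -> np.ndarray:
    dz = protocol.native_spacing_mm
    half_z = spec.artery_length_mm / 2 + protocol.z_margin_mm
    nz = max(1, int(math.ceil(2 * half_z / dz)))
    return (np.arange(nz) - (nz - 1) / 2) * dz


def _slab_centers(z: np.ndarray, thickness: float, increment: float, dz: float) -> list[float]:
    centers = []
    c = z[0] + (thickness - dz) / 2
    while c + thickness / 2 <= z[-1] + dz / 2 + 1e-9:
        centers.append(c)
        c += increment
    return centers


def _slab_coverages(spec, protocol, calc) -> list[float]:
    """Fraction of each reconstructed slab covered by the calcification."""
    z = _native_grid(spec, protocol)
    dz = protocol.native_spacing_mm
    t, inc = protocol.slice_thickness_mm, protocol.slice_increment_mm
    lo, hi = calc.z_extent
    coverages = []
    for c in _slab_centers(z, t, inc, dz):
        zin = z[(z >= c - t / 2 - 1e-9) & (z < c + t / 2 - 1e-9)]
        window = (zin[0] - dz / 2, zin[-1] + dz / 2)
        overlap = max(0.0, min(window[1], hi) - max(window[0], lo))
        coverages.append(overlap / (zin.size * dz))
    return coverages


def _ring_area(calc, f_min: float, pixel_mm: float) -> float:
    d = pixel_edge_offset(f_min, pixel_mm)
    r_out = calc.outer_diameter / 2 + d
    r_in = calc.inner_diameter / 2 - d
    return math.pi * max(r_out**2 - r_in**2, 0.0)


def slab_model_equivalent_score(spec, protocol, calc, hu: float, hu_threshold: float = 130.0) -> float:
    """Predicted 3 mm-equivalent Agatston of one uniform ring, closed form.

    Per reconstructed slab: mean HU = coverage x ring HU; slabs below the
    scoring threshold drop out; kept slabs contribute the thresholded ring
    area (linear pixel-edge model) times the Agatston weight of their mean
    HU; the per-slice sum is rescaled by increment / 3.
    """
    raw = 0.0
    for w in _slab_coverages(spec, protocol, calc):
        mean_hu = w * hu
        if mean_hu < hu_threshold:
            continue
        raw += _ring_area(calc, hu_threshold / mean_hu, protocol.pixel_mm) * _weight(mean_hu)
    return raw * protocol.slice_increment_mm / 3.0


def slab_model_volume(spec, protocol, calc, hu: float, hu_threshold: float = 130.0) -> float:
    """Predicted volume score (mm^3) of one uniform ring, closed form."""
    total = 0.0
    for w in _slab_coverages(spec, protocol, calc):
        mean_hu = w * hu
        if mean_hu < hu_threshold:
            continue
        total += _ring_area(calc, hu_threshold / mean_hu, protocol.pixel_mm)
    return total * protocol.slice_increment_mm
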