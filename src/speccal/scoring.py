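"""Agatston and volume scoring of calcium on conventional-HU volumes.

The reference-standard quantification: per slice, 8-connected components of
voxels at or above 130 HU with an in-plane area of at least 0.5 mm^2 are
lesions; each contributes (area in mm^2) x (weight 1-4 from the component's
maximum HU: 130-199 -> 1, 200-299 -> 2, 300-399 -> 3, >= 400 -> 4).  2D
components are grouped into 3D lesions by 26-connectivity across slices.
Because overlapping reconstructions visit the same anatomy more than once per
3 mm, a "3 mm-equivalent" Agatston score rescales the per-slice sum by
(slice increment / 3.0).  The volume score counts voxels of accepted lesions,
with the slice increment as z-extent so overlapping slabs are not double
counted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "ScoringConfig",
    "Lesion2D",
    "ScoreEntry",
    "ScoreReport",
    "agatston_weight",
    "find_lesions",
    "agatston_score",
    "equivalent_score_3mm",
    "volume_score",
    "score_volume",
    "ideal_agatston_score",
]


@dataclass(frozen=True)
class ScoringConfig:
    """Thresholds and slice geometry of the scoring protocol."""

    hu_threshold: float = 130.0
    min_area_mm2: float = 0.5
    weight_bins: tuple[float, ...] = (130.0, 200.0, 300.0, 400.0)
    slice_thickness_mm: float = 3.0
    slice_increment_mm: float = 1.5

    def __post_init__(self) -> None:
        if self.hu_threshold <= 0:
            raise ValueError("hu_threshold must be > 0")
        if self.min_area_mm2 <= 0:
            raise ValueError("min_area_mm2 must be > 0")
        if any(later <= earlier for later, earlier in zip(self.weight_bins[1:], self.weight_bins)):
            raise ValueError("weight_bins must be strictly increasing")
        if self.slice_increment_mm <= 0:
            raise ValueError("slice_increment_mm must be > 0")


@dataclass(frozen=True)
class Lesion2D:
    """One in-plane connected component of an accepted lesion."""

    slice_index: int
    pixel_count: int
    area_mm2: float
    max_hu: float
    weight: int
    label3d: int


@dataclass
class ScoreEntry:
    """Scores of one calcification (or unassigned lesion group)."""

    name: str
    agatston_raw: float
    agatston_3mm: float
    volume_mm3: float
    n_lesions: int = 0
    center_z: float | None = None


@dataclass
class ScoreReport:
    """Per-calcification scores plus provenance."""

    entries: list[ScoreEntry]
    config: ScoringConfig
    source: str = ""

    @property
    def total_agatston_raw(self) -> float:
        return sum(e.agatston_raw for e in self.entries)

    @property
    def total_agatston_3mm(self) -> float:
        return sum(e.agatston_3mm for e in self.entries)

    @property
    def total_volume_mm3(self) -> float:
        return sum(e.volume_mm3 for e in self.entries)

    def by_name(self) -> dict[str, ScoreEntry]:
        return {e.name: e for e in self.entries}

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "name": e.name,
                    "agatston_raw": round(e.agatston_raw, 1),
                    "agatston_3mm": round(e.agatston_3mm, 1),
                    "volume_mm3": round(e.volume_mm3, 1),
                    "n_lesions": e.n_lesions,
                }
                for e in self.entries
            ]
        )


def agatston_weight(max_hu: float, bins: tuple[float, ...] = (130.0, 200.0, 300.0, 400.0)) -> int:
    """Agatston density weight from a lesion's maximum HU (bin edges inclusive)."""
    if max_hu < bins[0]:
        raise ValueError(f"max_hu {max_hu} below the scoring threshold {bins[0]}")
    weight = 1
    for i, edge in enumerate(bins[1:], start=2):
        if max_hu >= edge:
            weight = i
    return weight


_STRUCT_2D = np.ones((3, 3), dtype=bool)
_STRUCT_3D = np.ones((3, 3, 3), dtype=bool)


def find_lesions(
    image: np.ndarray,
    spacing: tuple[float, float, float],
    config: ScoringConfig = ScoringConfig(),
) -> list[Lesion2D]:
    """Accepted 2D lesion components, grouped into 3D lesions.

    ``image`` is a conventional-HU array indexed [x, y, z]; ``spacing`` is the
    (x, y, z) voxel spacing in mm (z = slice increment).  Components smaller
    than ``min_area_mm2`` (strictly) are discarded as noise specks before the
    3D grouping.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 3:
        raise ValueError("image must be a 3D array")
    if spacing is None or len(spacing) != 3 or min(spacing) <= 0:
        raise ValueError("voxel spacing metadata is required")
    pixel_area = spacing[0] * spacing[1]
    above = image >= config.hu_threshold

    kept = np.zeros_like(above)
    per_slice: list[tuple[int, np.ndarray, list[int]]] = []
    for k in range(image.shape[2]):
        labels, n = ndimage.label(above[:, :, k], structure=_STRUCT_2D)
        if n == 0:
            continue
        counts = np.bincount(labels.ravel())
        ids = [
            lid
            for lid in range(1, n + 1)
            if counts[lid] * pixel_area >= config.min_area_mm2 - 1e-9
        ]
        if not ids:
            continue
        kept[:, :, k] = np.isin(labels, ids)
        per_slice.append((k, labels, ids))

    labels3d, _ = ndimage.label(kept, structure=_STRUCT_3D)
    lesions: list[Lesion2D] = []
    for k, labels, ids in per_slice:
        max_hu = ndimage.maximum(image[:, :, k], labels=labels, index=ids)
        counts = np.bincount(labels.ravel())
        lab3 = ndimage.maximum(labels3d[:, :, k], labels=labels, index=ids)
        for lid, mhu, l3 in zip(ids, np.atleast_1d(max_hu), np.atleast_1d(lab3)):
            lesions.append(
                Lesion2D(
                    slice_index=k,
                    pixel_count=int(counts[lid]),
                    area_mm2=counts[lid] * pixel_area,
                    max_hu=float(mhu),
                    weight=agatston_weight(float(mhu), config.weight_bins),
                    label3d=int(l3),
                )
            )
    return lesions


def agatston_score(
    image: np.ndarray,
    spacing: tuple[float, float, float],
    config: ScoringConfig = ScoringConfig(),
) -> dict[int, float]:
    """Raw Agatston score per 3D lesion (sum of area x weight over slices)."""
    lesions = find_lesions(image, spacing, config)
    scores: dict[int, float] = {}
    for les in lesions:
        scores[les.label3d] = scores.get(les.label3d, 0.0) + les.area_mm2 * les.weight
    return scores


def equivalent_score_3mm(raw_score: float, config: ScoringConfig) -> float:
    """Rescale a per-slice-summed score to the standard 3 mm protocol.

    Overlapping reconstructions sample each 3 mm of anatomy
    (3 / increment) times; multiplying by (increment / 3) removes the
    multiple counting.  At increment 3.0 this is the identity.
    """
    return raw_score * config.slice_increment_mm / 3.0


def volume_score(
    image: np.ndarray,
    spacing: tuple[float, float, float],
    config: ScoringConfig = ScoringConfig(),
) -> dict[int, float]:
    """Volume (mm^3) per 3D lesion: accepted voxels x (x * y * increment)."""
    lesions = find_lesions(image, spacing, config)
    voxel = spacing[0] * spacing[1] * config.slice_increment_mm
    volumes: dict[int, float] = {}
    for les in lesions:
        volumes[les.label3d] = volumes.get(les.label3d, 0.0) + les.pixel_count * voxel
    return volumes


def score_volume(
    image: np.ndarray,
    spacing: tuple[float, float, float],
    config: ScoringConfig = ScoringConfig(),
    manifest: list[dict] | None = None,
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0),
    assign_tolerance_mm: float = 6.5,
    source: str = "",
) -> ScoreReport:
    """Full scoring pass: lesions, Agatston (raw and 3 mm-equivalent), volume.

    With a phantom ``manifest`` (entries with ``name`` and ``center_z``), 3D
    lesions are assigned to the nearest listed region by z centroid (within
    ``assign_tolerance_mm``; farther lesions land in an ``unassigned`` entry),
    and every listed region gets an entry even when its scores are zero.
    """
    lesions = find_lesions(image, spacing, config)
    voxel = spacing[0] * spacing[1] * config.slice_increment_mm

    by3d: dict[int, dict[str, float]] = {}
    for les in lesions:
        agg = by3d.setdefault(
            les.label3d, {"raw": 0.0, "vol": 0.0, "zsum": 0.0, "px": 0.0}
        )
        agg["raw"] += les.area_mm2 * les.weight
        agg["vol"] += les.pixel_count * voxel
        z = origin[2] + les.slice_index * spacing[2]
        agg["zsum"] += z * les.pixel_count
        agg["px"] += les.pixel_count

    if manifest:
        entries = {
            m["name"]: ScoreEntry(
                name=m["name"],
                agatston_raw=0.0,
                agatston_3mm=0.0,
                volume_mm3=0.0,
                center_z=m.get("center_z"),
            )
            for m in manifest
        }
        unassigned = ScoreEntry("unassigned", 0.0, 0.0, 0.0)
        for agg in by3d.values():
            zc = agg["zsum"] / agg["px"]
            best_name, best_d = None, None
            for m in manifest:
                d = abs(zc - m["center_z"])
                if best_d is None or d < best_d:
                    best_name, best_d = m["name"], d
            target = (
                entries[best_name]
                if best_d is not None and best_d <= assign_tolerance_mm
                else unassigned
            )
            target.agatston_raw += agg["raw"]
            target.volume_mm3 += agg["vol"]
            target.n_lesions += 1
        out = list(entries.values())
        if unassigned.n_lesions:
            out.append(unassigned)
    else:
        out = [
            ScoreEntry(
                name=f"lesion_{label}",
                agatston_raw=agg["raw"],
                agatston_3mm=0.0,
                volume_mm3=agg["vol"],
                n_lesions=1,
                center_z=agg["zsum"] / agg["px"],
            )
            for label, agg in sorted(by3d.items())
        ]
    for entry in out:
        entry.agatston_3mm = equivalent_score_3mm(entry.agatston_raw, config)
    return ScoreReport(entries=out, config=config, source=source)


def ideal_agatston_score(
    hu: float,
    area_mm2: float,
    length_mm: float,
    slice_thickness_mm: float = 3.0,
    config: ScoringConfig = ScoringConfig(),
) -> float:
    """Analytic ideal score of a uniform lesion, free of partial volume.

    The lesion contributes its full in-plane area at its nominal HU on each of
    the contiguous standard slices needed to cover it
    (``ceil(length / thickness)``).  Lesions below the HU threshold score 0.
    For the annular ring inserts (area 75.4 mm^2, length 5 mm) at their
    calibrated HU this yields 0, 0, 302, 603 and 603 points (nearest integer)
    for 75-800 mg CaHA/cc.
    """
    if hu < config.hu_threshold:
        return 0.0
    slices = math.ceil(length_mm / slice_thickness_mm)
    return area_mm2 * agatston_weight(hu, config.weight_bins) * slices
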