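"""NIfTI and JSON round-tripping of volumes, manifests and boundaries.

One spectral scan is stored as three NIfTI-1 files sharing one grid
(``<name>_conv.nii.gz``, ``<name>_pe.nii.gz``, ``<name>_compton.nii.gz``)
whose affine carries the voxel spacing and origin, plus a JSON manifest with
the phantom spec, protocol, seed, repetition and per-calcification ground
truth.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .phantom import PhantomSpec, ScanProtocol, SpectralVolume, phantom_manifest
from .spectral import DecisionBoundary

__all__ = [
    "save_spectral_volume",
    "load_spectral_volume",
    "write_manifest",
    "read_manifest",
    "save_boundary",
    "load_boundary",
]

_CHANNELS = ("conv", "pe", "compton")


def _affine(volume: SpectralVolume) -> np.ndarray:
    affine = np.eye(4)
    affine[0, 0], affine[1, 1], affine[2, 2] = volume.spacing
    affine[:3, 3] = volume.origin
    return affine


def save_spectral_volume(volume: SpectralVolume, directory, name: str = "scan") -> list[Path]:
    """Write the three channels as NIfTI files; returns the written paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    affine = _affine(volume)
    paths = []
    arrays = (volume.conventional, volume.pe_base, volume.compton_base)
    for channel, array in zip(_CHANNELS, arrays):
        path = directory / f"{name}_{channel}.nii.gz"
        nib.save(nib.Nifti1Image(np.asarray(array, dtype=np.float32), affine), path)
        paths.append(path)
    return paths


def load_spectral_volume(directory, name: str = "scan") -> SpectralVolume:
    """Load the three channels written by :func:`save_spectral_volume`."""
    directory = Path(directory)
    arrays = []
    affine = None
    for channel in _CHANNELS:
        img = nib.load(directory / f"{name}_{channel}.nii.gz")
        arrays.append(np.asarray(img.dataobj, dtype=float))
        affine = img.affine
    spacing = tuple(float(affine[i, i]) for i in range(3))
    origin = tuple(float(affine[i, 3]) for i in range(3))
    return SpectralVolume(*arrays, spacing=spacing, origin=origin)


def write_manifest(
    path,
    spec: PhantomSpec,
    protocol: ScanProtocol,
    repetition: int = 0,
    extra: dict | None = None,
) -> None:
    payload = {
        "spec": dataclasses.asdict(spec),
        "protocol": dataclasses.asdict(protocol),
        "seed": protocol.seed,
        "repetition": repetition,
        "calcifications": phantom_manifest(spec),
    }
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2))


def read_manifest(path) -> dict:
    return json.loads(Path(path).read_text())


def save_boundary(path, boundary: DecisionBoundary) -> None:
    Path(path).write_text(
        json.dumps({"slope": boundary.slope, "intercept": boundary.intercept}, indent=2)
    )


def load_boundary(path) -> DecisionBoundary:
    payload = json.loads(Path(path).read_text())
    return DecisionBoundary(float(payload["slope"]), float(payload["intercept"]))
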