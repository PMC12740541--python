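"""Shared fixtures: small noiseless phantom scans at the clinical pixel size.

All generated volumes use a 27.5 mm field of view on a 64 matrix — the exact
clinical 0.4297 mm pixel (220 mm / 512) with the water bath cropped to the
artery neighbourhood — and are cached per session since generation dominates
test run time.
"""

import pytest

from speccal import (
    ScanProtocol,
    ScoringConfig,
    build_phantom,
    default_phantom_spec,
    phantom_manifest,
)

TEST_FOV_MM = 27.5
TEST_MATRIX = 64


def make_protocol(thickness: float = 3.0, increment: float = 1.5, **kwargs) -> ScanProtocol:
    """Noiseless small-FOV scan protocol used throughout the suite."""
    kwargs.setdefault("fov_mm", TEST_FOV_MM)
    kwargs.setdefault("matrix", TEST_MATRIX)
    kwargs.setdefault("noise_sigma_conv", 0.0)
    kwargs.setdefault("noise_sigma_pe", 0.0)
    kwargs.setdefault("noise_sigma_compton", 0.0)
    return ScanProtocol(
        slice_thickness_mm=thickness, slice_increment_mm=increment, **kwargs
    )


THICK_CONFIG = ScoringConfig(slice_thickness_mm=3.0, slice_increment_mm=1.5)
THIN_CONFIG = ScoringConfig(slice_thickness_mm=0.67, slice_increment_mm=0.335)


@pytest.fixture(scope="session")
def spec_tnc():
    """Five-ring insert, contrast-free lumen, no repositioning jitter."""
    return default_phantom_spec(
        0.0, reposition_rotation_deg=0.0, reposition_translation_mm=0.0
    )


@pytest.fixture(scope="session")
def spec_ccta():
    """Five-ring insert at 100% clinical contrast dose, no jitter."""
    return default_phantom_spec(
        1.0, reposition_rotation_deg=0.0, reposition_translation_mm=0.0
    )


@pytest.fixture(scope="session")
def tnc_thick(spec_tnc):
    return build_phantom(spec_tnc, make_protocol(3.0, 1.5), repetition=0)


@pytest.fixture(scope="session")
def ccta_thick(spec_ccta):
    return build_phantom(spec_ccta, make_protocol(3.0, 1.5), repetition=0)


@pytest.fixture(scope="session")
def ccta_thin(spec_ccta):
    return build_phantom(spec_ccta, make_protocol(0.67, 0.335), repetition=0)


@pytest.fixture(scope="session")
def tnc_thin(spec_tnc):
    return build_phantom(spec_tnc, make_protocol(0.67, 0.335), repetition=0)


@pytest.fixture(scope="session")
def manifest_tnc(spec_tnc):
    return phantom_manifest(spec_tnc)


@pytest.fixture(scope="session")
def manifest_ccta(spec_ccta):
    return phantom_manifest(spec_ccta)
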