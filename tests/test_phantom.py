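"""Phantom generator: calibration, geometry, partial volume, noise, jitter."""

import math

import numpy as np
import pytest
from conftest import make_protocol

from speccal import (
    CalcificationSpec,
    PhantomSpec,
    SpectralVolume,
    build_phantom,
    default_phantom_spec,
    lumen_material,
    material_to_hu,
    resample_slices,
    ring_volume,
)


class TestMaterialCalibration:
    @pytest.mark.parametrize(
        "density, expected_hu",
        [(75, 96), (100, 129), (200, 259), (400, 521), (800, 1044)],
    )
    def test_caha_calibration_points(self, density, expected_hu):
        assert material_to_hu(density).hu_conventional == pytest.approx(expected_hu)

    @pytest.mark.parametrize(
        "fraction, expected_hu", [(0.5, 185), (1.0, 390), (1.5, 590)]
    )
    def test_lumen_calibration_points(self, fraction, expected_hu):
        assert material_to_hu(0, fraction).hu_conventional == pytest.approx(expected_hu)

    def test_water_is_zero(self):
        point = material_to_hu(0, 0)
        assert point.triple == (0.0, 0.0, 0.0)

    def test_contrast_free_lumen_is_blood(self):
        assert lumen_material(0.0).hu_conventional == pytest.approx(40.0)

    def test_interpolation_is_monotone(self):
        densities = np.linspace(0, 900, 200)
        hus = [material_to_hu(d).hu_conventional for d in densities]
        assert np.all(np.diff(hus) > 0)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            material_to_hu(-1)
        with pytest.raises(ValueError):
            material_to_hu(0, -0.5)

    def test_mixture_call_rejected(self):
        with pytest.raises(ValueError):
            material_to_hu(200, 1.0)


class TestRingVolume:
    def test_insert_geometry(self):
        assert round(ring_volume(5, 11, 5)) == 377

    def test_solid_cylinder(self):
        assert ring_volume(0, 2, 1) == pytest.approx(math.pi)

    def test_degenerate_annulus(self):
        assert ring_volume(4, 4 + 1e-12, 5) == pytest.approx(0.0, abs=1e-9)

    def test_inverted_diameters_rejected(self):
        with pytest.raises(ValueError):
            ring_volume(11, 5, 5)


class TestSpecValidation:
    def test_overlapping_calcifications_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            PhantomSpec(
                calcifications=(
                    CalcificationSpec(200, center_z=0.0),
                    CalcificationSpec(400, center_z=3.0),
                )
            )

    def test_calcification_outside_artery_rejected(self):
        with pytest.raises(ValueError, match="artery"):
            PhantomSpec(
                calcifications=(CalcificationSpec(200, center_z=50.0),),
                artery_length_mm=40.0,
            )

    def test_spectral_channels_must_align(self):
        with pytest.raises(ValueError):
            SpectralVolume(
                conventional=np.zeros((4, 4, 2)),
                pe_base=np.zeros((4, 4, 3)),
                compton_base=np.zeros((4, 4, 2)),
                spacing=(1, 1, 1),
            )


class TestBuildPhantom:
    def test_interior_voxels_hit_calibration(self, spec_tnc, spec_ccta):
        """Noiseless voxels fully inside one material carry its exact HU."""
        protocol = make_protocol(0.335, 0.335)  # native grid, no slab averaging
        for spec, lumen_hu in ((spec_tnc, 40.0), (spec_ccta, 390.0)):
            vol = build_phantom(spec, protocol, repetition=0)
            x = vol.origin[0] + np.arange(vol.shape[0]) * vol.spacing[0]
            rho = np.hypot(x[:, None], x[None, :])
            z = vol.z_centers
            lumen_core = (rho < 1.5)[:, :, None] & (np.abs(z) < 30)[None, None, :]
            assert vol.conventional[lumen_core] == pytest.approx(lumen_hu)
            for calc in spec.calcifications:
                core = ((rho > 3.2) & (rho < 4.8))[:, :, None] & (
                    np.abs(z - calc.center_z) < 1.5
                )[None, None, :]
                expected = material_to_hu(calc.density).hu_conventional
                assert vol.conventional[core] == pytest.approx(expected)

    def test_seeded_determinism(self, spec_tnc):
        protocol = make_protocol(3.0, 1.5, noise_sigma_conv=15.0, seed=42)
        a = build_phantom(spec_tnc, protocol, repetition=1)
        b = build_phantom(spec_tnc, protocol, repetition=1)
        assert np.array_equal(a.conventional, b.conventional)
        assert np.array_equal(a.pe_base, b.pe_base)
        assert np.array_equal(a.compton_base, b.compton_base)

    def test_repetitions_are_independent(self, spec_tnc):
        protocol = make_protocol(3.0, 1.5, noise_sigma_conv=15.0, seed=42)
        a = build_phantom(spec_tnc, protocol, repetition=0)
        b = build_phantom(spec_tnc, protocol, repetition=1)
        assert not np.array_equal(a.conventional, b.conventional)

    def test_supersampling_convergence(self):
        """Doubling the supersampling factor moves the rasterized ring's
        partial-volume mass integral by well under 1%."""
        spec = PhantomSpec(
            calcifications=(CalcificationSpec(400.0),),
            artery_length_mm=30.0,
            reposition_rotation_deg=0.0,
            reposition_translation_mm=0.0,
        )
        masses = {}
        for ss in (2, 4):
            protocol = make_protocol(
                0.335, 0.335, supersample=ss, z_margin_mm=3.0
            )
            vol = build_phantom(spec, protocol, repetition=0)
            x = vol.origin[0] + np.arange(vol.shape[0]) * vol.spacing[0]
            rho = np.hypot(x[:, None], x[None, :])
            region = ((rho > 2.0) & (rho < 6.0))[:, :, None] & (
                np.abs(vol.z_centers) < 3.2
            )[None, None, :]
            masses[ss] = vol.conventional[region].sum() / 521.0 * vol.voxel_volume
        assert abs(masses[4] - masses[2]) / masses[2] < 0.01

    def test_jitter_preserves_calcium_volume(self):
        """Rigid repositioning (~2 deg, ~2 mm) leaves the voxelized
        above-threshold ring volume unchanged to within 5%."""
        from conftest import THIN_CONFIG

        from speccal import phantom_manifest, score_volume

        spec = default_phantom_spec(0.0)  # default jitter magnitudes
        volumes = []
        for rep in range(3):
            vol = build_phantom(spec, make_protocol(0.67, 0.335, seed=11), rep)
            report = score_volume(
                vol.conventional,
                vol.spacing,
                THIN_CONFIG,
                manifest=phantom_manifest(spec),
                origin=vol.origin,
            )
            volumes.append(report.by_name()["400mgcc"].volume_mm3)
        assert (max(volumes) - min(volumes)) / np.mean(volumes) < 0.05


class TestResampleSlices:
    @staticmethod
    def _volume_from_z(values, dz=1.0):
        arr = np.broadcast_to(
            np.asarray(values, dtype=float), (4, 4, len(values))
        ).copy()
        return SpectralVolume(arr, arr.copy(), arr.copy(), spacing=(1, 1, dz))

    def test_constant_volume_preserved(self):
        vol = self._volume_from_z([7.0] * 12)
        out = resample_slices(vol, thickness=3.0, increment=1.5)
        assert out.conventional == pytest.approx(7.0)

    def test_identity_when_thickness_equals_native(self):
        vol = self._volume_from_z(np.arange(10.0))
        out = resample_slices(vol, thickness=1.0, increment=1.0)
        assert np.allclose(out.conventional, vol.conventional)
        assert out.spacing == vol.spacing

    def test_slab_partial_volume_closed_form(self):
        """A 5-sample lesion slab-averaged at 3/1.5 (native 1 mm): boundary
        slabs carry the closed-form overlap fraction, the interior slab the
        full value."""
        values = np.zeros(11)
        values[3:8] = 300.0  # native centers 3..7 hold the lesion
        vol = self._volume_from_z(values)
        out = resample_slices(vol, thickness=3.0, increment=1.5)
        # slab centers at native index 1, 2.5, 4, 5.5, 7, 8.5; each averages
        # 3 native samples -> expected means 0, 100 (1 of 3... see below)
        profile = out.conventional[0, 0, :]
        centers = out.z_centers
        for c, value in zip(centers, profile):
            members = [k for k in range(11) if c - 1.5 - 1e-9 <= k < c + 1.5 - 1e-9]
            expected = np.mean(values[members])
            assert value == pytest.approx(expected)
        assert profile.max() == pytest.approx(300.0)

    def test_overlapping_convention_only(self):
        vol = self._volume_from_z(np.arange(10.0))
        with pytest.raises(ValueError):
            resample_slices(vol, thickness=2.0, increment=3.0)

    def test_native_coarser_than_target_rejected(self):
        vol = self._volume_from_z(np.arange(10.0), dz=4.0)
        with pytest.raises(ValueError):
            resample_slices(vol, thickness=3.0, increment=1.5)
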