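"""I/O round trips, preprocessing geometry and Z-axis phase alignment."""

import numpy as np
import pytest

from hfsnet import imaging_io as io


@pytest.fixture
def rng():
    return np.random.default_rng(0)


class TestNifti:
    def test_intensity_roundtrip_identity(self, rng, tmp_path):
        arr = rng.normal(size=(5, 16, 16))
        path = tmp_path / "v.nii.gz"
        io.save_nifti(arr, (2.5, 1.4, 1.4), path, z_origin=12.0)
        vol = io.load_volume(path)
        assert np.array_equal(vol.data, arr)
        np.testing.assert_allclose(vol.spacing_mm, (2.5, 1.4, 1.4), atol=1e-5)
        np.testing.assert_allclose(vol.z_coords,
                                   12.0 + np.arange(5) * 2.5, atol=1e-4)

    def test_label_roundtrip_exact(self, rng, tmp_path):
        lab = rng.integers(0, 5, size=(4, 8, 8)).astype(np.int16)
        io.save_nifti(lab, (2.0, 1.0, 1.0), tmp_path / "l.nii.gz")
        assert np.array_equal(io.load_volume(tmp_path / "l.nii.gz").data, lab)

    def test_512_input_loads_unchanged(self, rng, tmp_path):
        arr = rng.normal(size=(2, 512, 512))
        io.save_nifti(arr, (5.0, 0.7, 0.7), tmp_path / "big.nii.gz")
        vol = io.load_volume(tmp_path / "big.nii.gz")
        assert vol.data.shape == (2, 512, 512)  # resizing is a separate step


class TestDicom:
    @staticmethod
    def _write_series(path, zs, rng):
        import pydicom
        from pydicom.dataset import FileDataset, FileMetaDataset

        path.mkdir()
        for i, z in enumerate(zs):
            meta = FileMetaDataset()
            meta.MediaStorageSOPClassUID = pydicom.uid.CTImageStorage
            meta.MediaStorageSOPInstanceUID = pydicom.uid.generate_uid()
            meta.TransferSyntaxUID = pydicom.uid.ExplicitVRLittleEndian
            ds = FileDataset(str(path / f"s{i:03d}.dcm"), {},
                             file_meta=meta, preamble=b"\0" * 128)
            ds.PatientID = "phantom"
            ds.Rows = ds.Columns = 8
            ds.PixelSpacing = [0.7, 0.7]
            ds.ImagePositionPatient = [0.0, 0.0, float(z)]
            ds.BitsAllocated = 16
            ds.BitsStored = 16
            ds.HighBit = 15
            ds.PixelRepresentation = 0
            ds.SamplesPerPixel = 1
            ds.PhotometricInterpretation = "MONOCHROME2"
            ds.RescaleSlope = 1.0
            ds.RescaleIntercept = -1024.0
            ds.PixelData = rng.integers(
                0, 2000, size=(8, 8)).astype(np.uint16).tobytes()
            ds.save_as(str(path / f"s{i:03d}.dcm"), enforce_file_format=True)

    def test_series_loads_sorted_with_rescale(self, rng, tmp_path):
        self._write_series(tmp_path / "series", [6.0, 2.0, 4.0], rng)
        vol = io.load_volume(tmp_path / "series")
        assert vol.data.shape == (3, 8, 8)
        np.testing.assert_allclose(vol.z_coords, [2.0, 4.0, 6.0])
        assert vol.data.min() >= -1024  # intercept applied
        assert vol.spacing_mm == (2.0, 0.7, 0.7)

    def test_missing_slice_raises_naming_gap(self, rng, tmp_path):
        self._write_series(tmp_path / "gappy", [0.0, 2.0, 6.0, 8.0], rng)
        with pytest.raises(ValueError, match="gap"):
            io.load_volume(tmp_path / "gappy")


class TestPreprocess:
    def test_512_at_07mm_becomes_256_at_14mm(self, rng):
        vol = io.SinglePhaseVolume(rng.normal(size=(3, 512, 512)),
                                   (2.5, 0.7, 0.7))
        out = io.preprocess(vol)
        assert out.data.shape == (3, 256, 256)
        assert out.spacing_mm == (2.5, 1.4, 1.4)
        assert 0.0 <= out.data.min() and out.data.max() <= 1.0

    def test_already_standard_grid_unchanged_geometry(self, rng):
        data = rng.normal(size=(2, 256, 256))
        vol = io.SinglePhaseVolume(data, (2.5, 1.4, 1.4))
        out = io.preprocess(vol, normalize=False)
        assert out.data.shape == (2, 256, 256)
        np.testing.assert_allclose(out.data, data)

    def test_resample_preserves_physical_extent(self, rng):
        vol = io.SinglePhaseVolume(rng.normal(size=(2, 300, 300)),
                                   (2.5, 0.9, 0.9))
        out = io.resample_inplane(vol)
        before = 300 * 0.9
        after = out.data.shape[1] * 1.4
        assert abs(before - after) <= 1.4  # within one voxel

    def test_anisotropic_inplane_spacing_rejected(self, rng):
        vol = io.SinglePhaseVolume(rng.normal(size=(2, 64, 64)),
                                   (2.5, 0.7, 0.9))
        with pytest.raises(ValueError, match="anisotropic"):
            io.preprocess(vol)

    def test_label_resampling_stays_integer(self):
        lab = np.zeros((2, 64, 64))
        lab[:, 20:40, 20:40] = 3
        vol = io.SinglePhaseVolume(lab, (2.5, 0.7, 0.7))
        out = io.preprocess(vol, target_size=32, is_label=True)
        assert out.data.dtype == np.int32
        assert set(np.unique(out.data)) <= {0, 3}


class TestAlignPhases:
    @staticmethod
    def _vol(rng, zs):
        return io.SinglePhaseVolume(rng.normal(size=(len(zs), 8, 8)),
                                    (2.0, 1.4, 1.4), np.asarray(zs))

    def test_identical_geometry_is_noop(self, rng):
        zs = np.arange(5) * 2.0
        nc, art, pv = (self._vol(rng, zs) for _ in range(3))
        dv = io.align_phases(nc, art, pv)
        assert dv.shape == (5, 8, 8)
        assert np.array_equal(dv.portal_venous, pv.data)
        assert np.array_equal(dv.non_contrast, nc.data)

    def test_one_slice_shift_drops_ends(self, rng):
        zs = np.arange(5) * 2.0
        nc = self._vol(rng, zs)
        art = self._vol(rng, zs)
        pv = self._vol(rng, zs + 2.0)
        dv = io.align_phases(nc, art, pv)
        # common range [2, 8]: pv loses its top slice, nc/art their bottom
        assert dv.shape[0] == 4
        assert np.array_equal(dv.portal_venous, pv.data[:4])
        assert np.array_equal(dv.non_contrast, nc.data[1:])
        np.testing.assert_allclose(dv.z_coords, [2.0, 4.0, 6.0, 8.0])

    def test_alignment_is_idempotent(self, rng):
        zs = np.arange(6) * 2.0
        dv = io.align_phases(self._vol(rng, zs), self._vol(rng, zs + 2.0),
                             self._vol(rng, zs + 0.6))
        again = io.align_phases(
            io.SinglePhaseVolume(dv.non_contrast, dv.spacing_mm, dv.z_coords),
            io.SinglePhaseVolume(dv.arterial, dv.spacing_mm, dv.z_coords),
            io.SinglePhaseVolume(dv.portal_venous, dv.spacing_mm,
                                 dv.z_coords))
        assert again.shape == dv.shape
        for a, b in zip(again.phases, dv.phases):
            assert np.array_equal(a, b)

    def test_disjoint_z_ranges_raise(self, rng):
        zs = np.arange(4) * 2.0
        with pytest.raises(io.AlignmentError):
            io.align_phases(self._vol(rng, zs), self._vol(rng, zs),
                            self._vol(rng, zs + 100.0))


class TestStackDynamic:
    @pytest.fixture
    def dyn(self, rng):
        zs = np.arange(4) * 2.0
        return io.align_phases(
            *(io.SinglePhaseVolume(rng.normal(size=(4, 8, 8)),
                                   (2.0, 1.4, 1.4), zs) for _ in range(3)))

    def test_three_channel_stack(self, dyn):
        img = io.stack_dynamic(dyn, 0)
        assert img.shape == (3, 8, 8)
        assert np.array_equal(img[0], dyn.non_contrast[0])
        assert np.array_equal(img[1], dyn.arterial[0])
        assert np.array_equal(img[2], dyn.portal_venous[0])

    def test_single_phase_request(self, dyn):
        img = io.stack_dynamic(dyn, 2, phases=("portal_venous",))
        assert img.shape == (1, 8, 8)
        assert np.array_equal(img[0], dyn.portal_venous[2])

    def test_out_of_range_slice(self, dyn):
        with pytest.raises(IndexError):
            io.stack_dynamic(dyn, 99)


def test_case_roundtrip(tmp_path):
    from hfsnet import phantom
    spec = phantom.PhantomSpec(grid_shape=(8, 32, 32),
                               liver_semiaxes_mm=(8, 18, 19),
                               n_tumors=1, tumor_diameters_cm=(1.5,), seed=1)
    case = phantom.generate_case(spec)
    io.write_case(tmp_path / "c", case.volume,
                  io.LabelVolume(case.liver_mask.astype(np.int32), "liver",
                                 spec.spacing_mm),
                  case.tumor_labels)
    vol, liver, tumor = io.read_case(tmp_path / "c")
    for a, b in zip(vol.phases, case.volume.phases):
        np.testing.assert_allclose(a, b, atol=1e-12)
    assert np.array_equal(tumor.labels, case.tumor_labels.labels)
    assert np.array_equal(liver.labels > 0, case.liver_mask)
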