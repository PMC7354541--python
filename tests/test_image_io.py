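import numpy as np
import pytest

from eqctta import (
    CTSlice,
    DataError,
    GeometryError,
    InputError,
    ROIMask,
    check_registration,
    copy_roi,
    read_clinical_table,
    read_mask,
    read_slice,
    write_mask,
    write_slice,
)
from eqctta.image_io import masks_disjoint


class TestCTSliceValidation:
    def test_rejects_nonpositive_spacing(self):
        with pytest.raises(GeometryError):
            CTSlice(np.zeros((4, 4)), (0.0, 0.7), "pre")

    def test_rejects_out_of_range_hu(self):
        pix = np.zeros((4, 4))
        pix[0, 0] = 5000.0
        with pytest.raises(DataError):
            CTSlice(pix, (1.0, 1.0), "pre")

    def test_rejects_nonfinite_pixels(self):
        pix = np.zeros((4, 4))
        pix[1, 1] = np.nan
        with pytest.raises(DataError):
            CTSlice(pix, (1.0, 1.0), "pre")

    def test_rejects_unknown_phase(self):
        with pytest.raises(InputError):
            CTSlice(np.zeros((4, 4)), (1.0, 1.0), "portal")


class TestRoundTrip:
    def test_slice_pixels_bitwise_and_spacing(self, rng, tmp_path):
        pix = rng.uniform(-500, 500, (64, 64))
        slc = CTSlice(pix, (0.7, 0.7), "eq", "p9")
        path = write_slice(slc, tmp_path / "s.nii.gz")
        back = read_slice(path, "eq", patient_id="p9")
        np.testing.assert_array_equal(back.pixels, slc.pixels)
        # NIfTI-1 stores pixdim as float32; agreement is within the
        # registration tolerance and the two lattices count as matched
        assert back.spacing_mm == pytest.approx(slc.spacing_mm, abs=1e-6)
        assert check_registration(back, slc)

    def test_mask_bits_bitwise(self, rng, tmp_path, flat_slice):
        m = rng.random((64, 64)) > 0.6
        m[0, 0] = True  # ensure non-empty
        mask = ROIMask.from_slice(m, "segment7", flat_slice)
        path = write_mask(mask, tmp_path / "m.nii.gz")
        back = read_mask(path, "segment7", flat_slice)
        np.testing.assert_array_equal(back.mask, mask.mask)

    def test_spacing_override_and_missing_spacing(self, tmp_path):
        slc = CTSlice(np.zeros((8, 8)), (1.0, 1.0), "pre")
        path = write_slice(slc, tmp_path / "s.nii")
        back = read_slice(path, "pre", spacing_override=(2.0, 3.0))
        assert back.spacing_mm == (2.0, 3.0)

    def test_mask_with_other_values_rejected(self, tmp_path, flat_slice):
        import nibabel as nib

        data = np.zeros((64, 64), dtype=np.uint8)
        data[1, 1] = 2
        nib.save(nib.Nifti1Image(data, np.eye(4)), tmp_path / "bad.nii")
        with pytest.raises(DataError):
            read_mask(tmp_path / "bad.nii", "aorta", flat_slice)


class TestRegistration:
    def test_reflexive(self, flat_slice):
        assert check_registration(flat_slice, flat_slice)

    def test_shape_mismatch(self, flat_slice):
        other = CTSlice(np.zeros((64, 65)), (0.7, 0.7), "eq")
        assert not check_registration(flat_slice, other)

    def test_spacing_beyond_tolerance(self, flat_slice):
        other = CTSlice(np.zeros((64, 64)), (0.7 + 1e-3, 0.7), "eq")
        assert not check_registration(flat_slice, other)

    def test_spacing_within_tolerance(self, flat_slice):
        other = CTSlice(np.zeros((64, 64)), (0.7 + 1e-8, 0.7), "eq")
        assert check_registration(flat_slice, other)


class TestCopyRoi:
    def test_copy_preserves_bits_and_count(self, flat_slice, central_mask):
        target = CTSlice(np.full((64, 64), 60.0), (0.7, 0.7), "eq")
        copied = copy_roi(central_mask, target)
        np.testing.assert_array_equal(copied.mask, central_mask.mask)
        assert copied.n_pixels == central_mask.n_pixels

    def test_copy_to_mismatched_lattice_fails(self, central_mask):
        target = CTSlice(np.zeros((32, 32)), (0.7, 0.7), "eq")
        with pytest.raises(GeometryError):
            copy_roi(central_mask, target)

    def test_area_cm2(self, flat_slice):
        m = np.zeros((64, 64), dtype=bool)
        m[:10, :10] = True  # 100 px at 0.49 mm^2
        mask = ROIMask.from_slice(m, "segment7", flat_slice)
        assert mask.area_cm2() == pytest.approx(100 * 0.49 / 100)


class TestMaskInvariants:
    def test_empty_mask_rejected(self, flat_slice):
        with pytest.raises(GeometryError):
            ROIMask.from_slice(np.zeros((64, 64), dtype=bool), "aorta", flat_slice)

    def test_shape_mismatch_rejected(self, flat_slice):
        with pytest.raises(GeometryError):
            ROIMask(np.ones((32, 32), dtype=bool), "aorta", (64, 64), (0.7, 0.7))

    def test_disjointness_predicate(self, flat_slice):
        a = np.zeros((64, 64), dtype=bool)
        a[:10] = True
        b = np.zeros((64, 64), dtype=bool)
        b[20:30] = True
        liver = ROIMask.from_slice(a, "whole_liver", flat_slice)
        aorta = ROIMask.from_slice(b, "aorta", flat_slice)
        assert masks_disjoint(liver, aorta)
        b[5] = True
        aorta2 = ROIMask.from_slice(b, "aorta", flat_slice)
        assert not masks_disjoint(liver, aorta2)


class TestClinicalTable:
    def test_reads_valid_table(self, tmp_path):
        p = tmp_path / "c.csv"
        p.write_text(
            "patient_id,haematocrit,cpa_percent,elf,ishak\n"
            "p1,0.41,5.0,9.7,3\np2,0.44,,10.2,\n"
        )
        df = read_clinical_table(p)
        assert list(df["patient_id"]) == ["p1", "p2"]
        assert np.isnan(df["cpa_percent"].iloc[1])

    @pytest.mark.parametrize(
        "body",
        [
            "patient_id,haematocrit,cpa_percent,elf\np1,0.4,5,9",  # missing column
            "patient_id,haematocrit,cpa_percent,elf,ishak\np1,0.4,5,9,3\np1,0.4,5,9,3",
            "patient_id,haematocrit,cpa_percent,elf,ishak\np1,0.4,5,9,9",  # ishak > 6
            "patient_id,haematocrit,cpa_percent,elf,ishak\np1,0.4,-2,9,3",  # cpa < 0
        ],
    )
    def test_rejects_malformed(self, tmp_path, body):
        p = tmp_path / "c.csv"
        p.write_text(body + "\n")
        with pytest.raises(InputError):
            read_clinical_table(p)
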