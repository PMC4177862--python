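"""Unbiased template construction and Jacobian area measurement."""

import numpy as np
import pytest
from scipy import ndimage

from ccmorph.errors import RegistrationError
from ccmorph.io import REGION_NAMES, MidsagittalMask, SubjectRecord
from ccmorph.registration import DeformationField
from ccmorph.template import (
    build_template,
    measure_cohort,
    region_areas,
    resample_to_common_grid,
)
from conftest import small_cohort_spec


def _dice(a, b):
    return 2.0 * (a & b).sum() / (a.sum() + b.sum())


class TestBuildTemplate:
    def test_identical_cohort_is_a_fixed_point(self, arch_mask):
        masks = [
            MidsagittalMask(arch_mask.pixels, arch_mask.spacing, f"s{i}")
            for i in range(3)
        ]
        res = build_template(masks)
        grids, _, _ = resample_to_common_grid(masks)
        assert _dice(res.template > 0.5, grids[0] > 0.5) > 0.99
        assert all(
            np.abs(f.displacements).max() < 0.1 for f in res.fields.values()
        )

    def test_translated_pair_template_sits_at_midpoint(self, arch_mask):
        a = np.zeros((60, 140), dtype=bool)
        a[10:45, 10:110] = arch_mask.pixels
        b = np.zeros((60, 140), dtype=bool)
        b[10:45, 14:114] = arch_mask.pixels
        masks = [
            MidsagittalMask(a, (1.0, 1.0), "a"),
            MidsagittalMask(b, (1.0, 1.0), "b"),
        ]
        res = build_template(masks)
        grids, _, _ = resample_to_common_grid(masks)
        mids = np.add(
            ndimage.center_of_mass(grids[0]), ndimage.center_of_mass(grids[1])
        ) / 2.0
        cen = ndimage.center_of_mass(res.template > 0.5)
        assert np.hypot(*(np.array(cen) - mids)) < 0.75

        # spatial unbiasedness: the average of the final subject fields is
        # close to zero over the template foreground
        bias = np.linalg.norm(res.mean_field_px, axis=0)
        assert bias[res.template > 0.5].mean() < 0.2

    def test_cohort_order_does_not_change_template(self, cohort_spec):
        from ccmorph.synthetic import sample_mask_cohort

        masks, _ = sample_mask_cohort(cohort_spec)
        res1 = build_template(masks)
        res2 = build_template(masks[::-1])
        assert _dice(res1.template > 0.5, res2.template > 0.5) > 0.98

    def test_single_mask_rejected(self, arch_mask):
        with pytest.raises(RegistrationError):
            build_template([arch_mask])

    def test_mixed_spacing_rejected(self, arch_mask):
        other = MidsagittalMask(arch_mask.pixels, (0.5, 0.5), "other")
        with pytest.raises(RegistrationError, match="spacing"):
            build_template([arch_mask, other])


def _identity_field(shape, spacing=(1.0, 1.0)):
    return DeformationField(np.zeros((2,) + shape), spacing)


def _record(scale=1.0):
    return SubjectRecord("s1", "CB", "M", 30.0, linear_scale=scale)


class TestRegionAreas:
    @pytest.fixture(scope="class")
    def template_labels(self):
        from ccmorph.synthetic import CCShapeParams, make_cc_shape

        mask = make_cc_shape(
            CCShapeParams(100.0, 35.27, (330.0, 95.0, 100.0, 70.0, 240.0))
        )
        from ccmorph.shape import bounding_rectangle
        from ccmorph.subdivision import subdivide

        return subdivide(mask, bounding_rectangle(mask), "-col"), mask

    def test_identity_field_recovers_pixel_counts(self, template_labels):
        labels, mask = template_labels
        f = _identity_field(mask.pixels.shape)
        out = region_areas(labels, f, _record())
        for k, name in enumerate(REGION_NAMES, start=1):
            expected = float((labels.labels == k).sum())
            assert out[name]["stereotaxic_area_mm2"] == pytest.approx(expected)
            assert out[name]["native_area_mm2"] == pytest.approx(expected)

    def test_affine_scaling_multiplies_areas_exactly(self, template_labels):
        labels, mask = template_labels
        shape = mask.pixels.shape
        grid = np.mgrid[0 : shape[0], 0 : shape[1]].astype(float)
        disp = 0.1 * grid  # u = (s-1) x with s = 1.1
        f = DeformationField(disp, (1.0, 1.0))
        out = region_areas(labels, f, _record())
        for k, name in enumerate(REGION_NAMES, start=1):
            expected = 1.21 * float((labels.labels == k).sum())
            assert out[name]["stereotaxic_area_mm2"] == pytest.approx(
                expected, rel=1e-9
            )

    def test_linear_scale_quarters_native_only(self, template_labels):
        labels, mask = template_labels
        f = _identity_field(mask.pixels.shape)
        out1 = region_areas(labels, f, _record(scale=1.0))
        out2 = region_areas(labels, f, _record(scale=2.0))
        for name in REGION_NAMES:
            assert (
                out2[name]["stereotaxic_area_mm2"]
                == out1[name]["stereotaxic_area_mm2"]
            )
            assert out2[name]["native_area_mm2"] == pytest.approx(
                out1[name]["native_area_mm2"] / 4.0
            )

    def test_grid_mismatch_rejected(self, template_labels):
        labels, _ = template_labels
        with pytest.raises(RegistrationError, match="grid"):
            region_areas(labels, _identity_field((5, 5)), _record())


class TestMeasureCohort:
    @pytest.fixture(scope="class")
    def measured(self):
        spec = small_cohort_spec(n=3, seed=7)
        from ccmorph.synthetic import sample_mask_cohort

        masks, records = sample_mask_cohort(spec)
        table, result, labels = measure_cohort(
            masks, records, anterior_direction="-col"
        )
        return masks, table, result, labels

    def test_table_shape_and_metadata(self, measured):
        masks, table, _, _ = measured
        assert len(table) == 6 * 5
        assert set(table["region"]) == set(REGION_NAMES)
        assert table["bending_deg"].between(90, 140).all()

    def test_additivity_of_jacobian_integration(self, measured):
        """Sum of the five regional integrals equals the whole-CC integral
        (integration is additive over the label partition)."""
        masks, table, result, labels = measured
        from ccmorph.registration import jacobian_map

        for mask in masks:
            f = result.fields[mask.subject_id]
            detj = jacobian_map(f)
            whole = detj[labels.labels > 0].sum()
            regional = table[table.subject_id == mask.subject_id][
                "stereotaxic_area_mm2"
            ].sum()
            assert regional == pytest.approx(whole, rel=1e-9)

    def test_whole_cc_area_agrees_with_pixel_count(self, measured):
        """Two-estimator agreement: Jacobian-integrated whole-CC area is
        within 5% of each subject's own pixel-count area."""
        masks, table, _, _ = measured
        for mask in masks:
            integrated = table[table.subject_id == mask.subject_id][
                "stereotaxic_area_mm2"
            ].sum()
            assert integrated == pytest.approx(mask.area_mm2, rel=0.05)

    def test_template_labels_partition_template(self, measured):
        _, _, result, labels = measured
        fg = result.template > 0.5
        assert np.array_equal(labels.labels > 0, fg)
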