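import numpy as np
import pytest
from dataclasses import replace
from scipy import ndimage

from petrr.phantom import (
    PhantomParameterError,
    PhantomSpec,
    TissueIntensity,
    assign_dp_intensities,
    build_label_volume,
    generate_phantom,
    make_dataset,
    render_pseudo_mri,
)
from petrr.volumes import TISSUE_CLASSES


def zero_variance_spec(**kw) -> PhantomSpec:
    ti = {k: TissueIntensity(v.mean_negative, v.mean_positive, 0.0)
          for k, v in PhantomSpec().tissue_intensity.items()}
    return PhantomSpec(tissue_intensity=ti, **kw)


class TestLabelGeometry:
    def test_all_tissue_classes_present_on_default_grid(self, default_phantom):
        present = {default_phantom.labels.dictionary[lab]
                   for lab in np.unique(default_phantom.labels.labels) if lab}
        assert present == set(TISSUE_CLASSES) - {"background"}

    def test_deterministic_given_spec(self):
        spec = PhantomSpec(seed=42)
        a = build_label_volume(spec)
        b = build_label_volume(spec)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_zero_ventricle_scale_removes_csf(self):
        labels = build_label_volume(PhantomSpec(seed=1, ventricle_scale=0.0))
        assert labels.mask("ventricle_csf").sum() == 0

    def test_brain_fraction_bounds(self, default_phantom):
        frac = default_phantom.labels.brain_mask().mean()
        assert 0.1 < frac < 0.9

    def test_cortical_ribbon_is_an_outer_shell_on_white_matter(self, default_phantom):
        labels = default_phantom.labels
        cortex = labels.mask("cortical_gm")
        wm = labels.mask("white_matter")
        # the ribbon touches white matter ...
        assert (ndimage.binary_dilation(cortex) & wm).any()
        # ... and has no voxels in the deep interior
        cerebrum = cortex | wm | labels.mask("ventricle_csf", "subcortical_gm")
        deep = ndimage.binary_erosion(cerebrum, iterations=4)
        assert not (cortex & deep).any()

    def test_infeasible_thickness_rejected(self):
        with pytest.raises(PhantomParameterError):
            PhantomSpec(cortical_thickness_mm=80.0)


class TestDpIntensities:
    def test_zero_variance_gives_exact_region_means(self):
        spec = zero_variance_spec(seed=5, amyloid_burden=1.0)
        labels = build_label_volume(spec)
        dp = assign_dp_intensities(labels, spec)
        for cls, ti in spec.tissue_intensity.items():
            mask = labels.mask(cls)
            if mask.any():
                np.testing.assert_allclose(dp.data[mask], ti.mean_positive)

    def test_burden_moves_cortex_not_white_matter(self):
        neg = zero_variance_spec(seed=5, amyloid_burden=0.0)
        pos = zero_variance_spec(seed=5, amyloid_burden=1.0)
        labels = build_label_volume(neg)
        dp0 = assign_dp_intensities(labels, neg)
        dp1 = assign_dp_intensities(labels, pos)
        cortex = labels.mask("cortical_gm")
        wm = labels.mask("white_matter")
        assert dp1.data[cortex].mean() > dp0.data[cortex].mean() + 1.0
        np.testing.assert_allclose(dp1.data[wm].mean(), dp0.data[wm].mean())

    def test_sample_mean_matches_configured_mean(self, default_phantom):
        # Monte-Carlo: cortical sample mean within 4 SE of the configured mean
        spec = PhantomSpec(seed=7, amyloid_burden=1.0)
        labels, dp = default_phantom.labels, default_phantom.dp
        cortex = labels.mask("cortical_gm")
        n = cortex.sum()
        assert n > 5000  # large-region Monte-Carlo check
        ti = spec.tissue_intensity["cortical_gm"]
        se = ti.sd(1.0) / np.sqrt(n)
        # clipping at 0 never triggers here (mean 2.2, sd 0.11)
        assert abs(dp.data[cortex].mean() - ti.mean(1.0)) < 4 * se

    def test_missing_tissue_distribution_raises(self):
        spec = PhantomSpec(seed=2)
        labels = build_label_volume(spec)
        broken = replace(spec, tissue_intensity={"cortical_gm": TissueIntensity(1, 2)})
        with pytest.raises(PhantomParameterError):
            assign_dp_intensities(labels, broken)

    def test_background_is_zero_and_nonnegative(self, default_phantom):
        labels, dp = default_phantom.labels, default_phantom.dp
        assert dp.data[labels.labels == 0].max() == 0.0
        assert dp.data.min() >= 0.0


class TestPseudoMri:
    def test_noise_free_bias_free_is_piecewise_constant(self):
        spec = PhantomSpec(seed=3, mri_noise_sd=0.0, mri_bias_amplitude=0.0)
        labels = build_label_volume(spec)
        mri = render_pseudo_mri(labels, spec)
        for lab, cls in labels.dictionary.items():
            mask = labels.labels == lab
            if mask.any():
                np.testing.assert_allclose(mri.data[mask], spec.mri_means[cls])

    def test_normalized_to_unit_interval(self):
        for seed in (0, 1, 2):
            spec = PhantomSpec(seed=seed)
            mri = render_pseudo_mri(build_label_volume(spec), spec)
            assert mri.data.min() >= 0.0 and mri.data.max() <= 1.0

    def test_wm_gm_contrast_to_noise_exceeds_one(self, default_phantom):
        labels, mri = default_phantom.labels, default_phantom.mri
        wm = mri.data[labels.mask("white_matter")]
        gm = mri.data[labels.mask("cortical_gm")]
        cnr = abs(wm.mean() - gm.mean()) / np.sqrt(0.5 * (wm.var() + gm.var()))
        assert cnr > 1.0


class TestDataset:
    def test_bitwise_reproducible(self):
        a = make_dataset(3, seed=99)
        b = make_dataset(3, seed=99)
        for s, t in zip(a, b):
            np.testing.assert_array_equal(s.dp.data, t.dp.data)
            np.testing.assert_array_equal(s.mri.data, t.mri.data)
            np.testing.assert_array_equal(s.labels.labels, t.labels.labels)

    def test_single_sample_valid(self):
        (s,) = make_dataset(1, seed=0)
        assert s.dp.data.min() >= 0
        assert s.labels.shape == s.dp.shape == s.mri.shape

    def test_uniform_burden_mean(self):
        # burden ~ U(0,1): empirical mean within 4 SE of 0.5
        samples = make_dataset(100, seed=5)
        burdens = np.array([s.burden for s in samples])
        se = np.sqrt(1.0 / 12.0 / 100)
        assert abs(burdens.mean() - 0.5) < 4 * se

    def test_burden_spans_a_wide_range(self):
        burdens = [s.burden for s in make_dataset(30, seed=8)]
        assert min(burdens) < 0.2 and max(burdens) > 0.8

    def test_invalid_n(self):
        with pytest.raises(PhantomParameterError):
            make_dataset(0)


def test_label_dp_support_conservation(default_phantom):
    """Brain voxel count in the labels equals the DP's brain support."""
    labels, dp = default_phantom.labels, default_phantom.dp
    brain = labels.brain_mask()
    assert (dp.data[brain] > 0).all()
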