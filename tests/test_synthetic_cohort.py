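"""Synthetic cohort generator: phantom rendering, field sampling, output layout."""

import dataclasses
import hashlib

import numpy as np
import pytest
from scipy.stats import ks_2samp

import deformark as dm
from deformark.synthetic_cohort import CONTROL, DISEASE

from conftest import small_cohort, small_phantom


def _blob_spec(centers, amplitudes, sigmas, size=64):
    landmarks = ((32.0, 32.0), (20.0, 20.0), (20.0, 44.0), (44.0, 20.0),
                 (44.0, 44.0), (32.0, 16.0), (32.0, 48.0))
    return dm.PhantomSpec(size, size, tuple(centers), tuple(amplitudes), tuple(sigmas), landmarks)


class TestMakeReference:
    def test_single_center_blob_peaks_at_center(self):
        spec = _blob_spec([(32.0, 32.0)], [1.0], [8.0])
        img = dm.make_reference(spec).pixels
        assert np.unravel_index(np.argmax(img), img.shape) == (32, 32)
        assert img.max() == pytest.approx(1.0)

    def test_zero_blobs_gives_uniform_zero(self):
        spec = _blob_spec([], [], [])
        assert np.all(dm.make_reference(spec).pixels == 0.0)

    def test_mirrored_blobs_give_mirror_symmetric_image(self):
        # two identical blobs mirrored about the vertical midline
        spec = _blob_spec([(30.0, 20.0), (30.0, 43.0)], [0.8, 0.8], [5.0, 5.0])
        img = dm.make_reference(spec).pixels
        assert np.allclose(img, img[:, ::-1], atol=1e-12)

    def test_texture_is_deterministic_and_in_range(self):
        spec = dataclasses.replace(_blob_spec([(32.0, 32.0)], [1.0], [8.0]),
                                   texture_amplitude=0.2)
        a = dm.make_reference(spec).pixels
        b = dm.make_reference(spec).pixels
        assert np.array_equal(a, b)
        assert a.min() == pytest.approx(0.0) and a.max() == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(image_height=32),  # too small
            dict(landmark_positions=((32.0, 32.0),) * 6),  # wrong landmark count
            dict(blob_sigmas=(0.0,)),  # nonpositive sigma
            dict(landmark_positions=((0.0, 32.0),) + ((32.0, 32.0),) * 6),  # on border
        ],
    )
    def test_invalid_specs_rejected(self, kwargs):
        base = dict(
            image_height=64, image_width=64,
            blob_centers=((32.0, 32.0),), blob_amplitudes=(1.0,), blob_sigmas=(8.0,),
            landmark_positions=((32.0, 32.0), (20.0, 20.0), (20.0, 44.0), (44.0, 20.0),
                                (44.0, 44.0), (32.0, 16.0), (32.0, 48.0)),
        )
        base.update(kwargs)
        with pytest.raises(ValueError):
            dm.PhantomSpec(**base)


class TestSampleSubjectField:
    def test_effect_peak_equals_amplitude_times_direction(self):
        cohort = small_cohort(background_field_amplitude=0.0)
        rng = np.random.default_rng(0)
        field = dm.sample_subject_field(cohort, DISEASE, rng, (64, 64))
        r, c = map(int, cohort.effects[0].locus_center)
        assert field.d[r, c] == pytest.approx((0.0, 3.0), abs=1e-12)

    def test_all_amplitudes_zero_gives_zero_field(self):
        effect = dataclasses.replace(small_cohort().effects[0],
                                     control_amplitude=0.0, disease_amplitude=0.0)
        cohort = small_cohort(background_field_amplitude=0.0, effects=(effect,))
        rng = np.random.default_rng(0)
        for label in (CONTROL, DISEASE):
            assert np.all(dm.sample_subject_field(cohort, label, rng, (64, 64)).d == 0.0)

    def test_background_rms_is_rescaled_to_amplitude(self):
        cohort = small_cohort(background_field_amplitude=2.0, effects=())
        rng = np.random.default_rng(42)
        rms = []
        for _ in range(200):
            d = dm.sample_subject_field(cohort, CONTROL, rng, (64, 64)).d
            rms.append(np.sqrt(np.mean(d[..., 0] ** 2 + d[..., 1] ** 2)))
        assert np.mean(rms) == pytest.approx(2.0, rel=0.05)

    def test_field_is_background_plus_effect_terms(self):
        """Ground-truth conservation: the sampled field decomposes exactly."""
        cohort = small_cohort(background_field_amplitude=1.5)
        bg_only = small_cohort(background_field_amplitude=1.5, effects=())
        full = dm.sample_subject_field(cohort, DISEASE, np.random.default_rng(7), (64, 64)).d
        background = dm.sample_subject_field(bg_only, DISEASE, np.random.default_rng(7), (64, 64)).d
        eff = cohort.effects[0]
        rr, cc = np.meshgrid(np.arange(64.0), np.arange(64.0), indexing="ij")
        env = np.exp(-((rr - eff.locus_center[0]) ** 2 + (cc - eff.locus_center[1]) ** 2)
                     / (2 * eff.locus_sigma ** 2))
        expected = background + eff.disease_amplitude * env[..., None] * np.array(
            eff.disease_direction)
        assert np.allclose(full, expected, atol=1e-10)

    def test_equal_class_effects_make_magnitude_label_independent(self):
        """Null cohort: per-pixel magnitude distribution carries no label signal."""
        effect = dataclasses.replace(small_cohort().effects[0],
                                     control_amplitude=2.0, disease_amplitude=2.0,
                                     control_direction=(0.0, 1.0))
        cohort = small_cohort(effects=(effect,), background_field_amplitude=1.0)
        rng = np.random.default_rng(314)
        r, c = map(int, effect.locus_center)
        mags = {label: [] for label in (CONTROL, DISEASE)}
        for label in (CONTROL, DISEASE):
            for _ in range(250):
                d = dm.sample_subject_field(cohort, label, rng, (64, 64)).d
                mags[label].append(np.hypot(*d[r, c]))
        assert ks_2samp(mags[CONTROL], mags[DISEASE]).pvalue > 0.01

    def test_bad_label_rejected(self):
        with pytest.raises(ValueError, match="label"):
            dm.sample_subject_field(small_cohort(), "sick", np.random.default_rng(0), (64, 64))


class TestRenderCohort:
    def test_no_deformation_no_noise_reproduces_reference(self):
        effect = dataclasses.replace(small_cohort().effects[0],
                                     control_amplitude=0.0, disease_amplitude=0.0)
        cohort = small_cohort(
            n_control=2, n_disease=2, effects=(effect,),
            background_field_amplitude=0.0, intensity_noise_sd=0.0,
        )
        bundle = dm.render_cohort(small_phantom(), cohort)
        for sid in bundle.subject_ids:
            assert np.allclose(bundle.images[sid].pixels, bundle.reference.pixels, atol=1e-12)

    def test_labels_bookkeeping(self):
        cohort = small_cohort(n_control=3, n_disease=4)
        bundle = dm.render_cohort(small_phantom(), cohort)
        assert len(bundle.subject_ids) == 7
        labels = list(bundle.labels.values())
        assert labels.count(CONTROL) == 3 and labels.count(DISEASE) == 4

    def test_rerun_with_same_seed_is_byte_identical(self, tmp_path):
        cohort = small_cohort(n_control=2, n_disease=2)
        sums = []
        for sub in ("a", "b"):
            out = tmp_path / sub
            dm.render_cohort(small_phantom(), cohort, out_dir=out)
            digest = {}
            for p in sorted(out.rglob("*")):
                if p.is_file():
                    digest[p.relative_to(out)] = hashlib.sha256(p.read_bytes()).hexdigest()
            sums.append(digest)
        assert sums[0] == sums[1]

    def test_landmarks_transported_by_true_field(self):
        # place an effect exactly at a landmark; its displacement must move the landmark
        phantom = small_phantom()
        effect = dm.EffectSpec(
            locus_center=phantom.landmark_positions[2], locus_sigma=3.0,
            control_direction=(0.0, -1.0), disease_direction=(0.0, 1.0),
            control_amplitude=0.0, disease_amplitude=2.0,
        )
        cohort = small_cohort(n_control=2, n_disease=2, effects=(effect,),
                              background_field_amplitude=0.0, intensity_noise_sd=0.0,
                              include_reference_subject=False)
        bundle = dm.render_cohort(phantom, cohort)
        disease_sid = [s for s in bundle.subject_ids if bundle.labels[s] == DISEASE][0]
        moved = bundle.landmarks[disease_sid][2]
        expected = np.asarray(phantom.landmark_positions[2]) + (0.0, 2.0)
        assert np.allclose(moved, expected, atol=1e-9)

    def test_output_layout(self, small_cohort_dir):
        assert (small_cohort_dir / "labels.csv").exists()
        assert (small_cohort_dir / "landmarks.csv").exists()
        assert (small_cohort_dir / "truth" / "effects.json").exists()
        images = list((small_cohort_dir / "images").glob("s*.nii.gz"))
        fields = list((small_cohort_dir / "truth" / "fields").glob("s*.nii.gz"))
        assert len(images) == 16 and len(fields) == 16

    def test_undeformed_reference_subject_present_by_default(self, small_bundle):
        first = small_bundle.subject_ids[0]
        assert small_bundle.labels[first] == CONTROL
        assert np.all(small_bundle.true_fields[first].d == 0.0)


class TestCohortSpecValidation:
    @pytest.mark.parametrize(
        "kwargs", [dict(n_control=1), dict(background_field_amplitude=-1.0),
                   dict(background_field_sigma=0.0), dict(intensity_noise_sd=-0.1)]
    )
    def test_invalid_cohorts_rejected(self, kwargs):
        with pytest.raises(ValueError):
            small_cohort(**kwargs)

    def test_direction_must_be_unit_norm(self):
        with pytest.raises(ValueError, match="unit norm"):
            dm.EffectSpec(
                locus_center=(10.0, 10.0), locus_sigma=2.0,
                control_direction=(1.0, 1.0), disease_direction=(0.0, 1.0),
                control_amplitude=1.0, disease_amplitude=1.0,
            )
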