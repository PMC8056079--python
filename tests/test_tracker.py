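"""Registration tracker: warping algebra, losses, penalties, curriculum,
and desk-scale recovery properties."""

import datetime as dt

import numpy as np
import pytest

from pam.grids import AffineTransform, DisplacementField, ScanPair, VolumeGrid
from pam.tracker import (CurriculumSchedule, TrackerConfig, TrackerModel,
                         UndefinedCorrelationWarning, affine_forward,
                         apply_affine, correlation_loss, correspondences,
                         curriculum_smooth, deformable_forward, recover_affine,
                         regularization_penalties, train_tracker, warp)

RNG = np.random.default_rng(11)


def vol(arr):
    return VolumeGrid(arr, spacing_mm=(2.0, 2.0, 2.0),
                      intensity_units="normalized")


def random_vol(shape=(12, 12, 12), seed=0):
    return vol(np.random.default_rng(seed).random(shape))


def make_pair(prior, subsequent):
    return ScanPair(patient_id="1", prior=prior, subsequent=subsequent,
                    prior_date=dt.date(2020, 1, 1),
                    subsequent_date=dt.date(2020, 2, 1),
                    days_from_treatment_start=31, days_between_scans=31,
                    region="abdomen")


class TestWarping:
    def test_zero_field_is_bitwise_identity(self):
        v = random_vol(seed=1)
        field = DisplacementField(np.zeros((3,) + v.shape))
        out = warp(v, field)
        np.testing.assert_array_equal(out.intensities, v.intensities)

    def test_constant_field_equals_affine_translation(self):
        v = random_vol(seed=2)
        field = DisplacementField(np.broadcast_to(
            np.array([0.0, 0.0, 3.0])[:, None, None, None],
            (3,) + v.shape).copy())
        by_field = warp(v, field)
        by_affine = apply_affine(v, AffineTransform(np.eye(3), [0, 0, 3]))
        np.testing.assert_allclose(by_field.intensities,
                                   by_affine.intensities, atol=1e-12)

    def test_integer_translation_matches_array_shift(self):
        v = random_vol(seed=3)
        out = apply_affine(v, AffineTransform(np.eye(3), [0, 0, 3]))
        np.testing.assert_allclose(out.intensities[..., :-3],
                                   v.intensities[..., 3:], atol=1e-12)
        assert np.all(out.intensities[..., -3:] == 0)

    def test_identity_affine_reproduces_input_exactly(self):
        v = random_vol(seed=4)
        out = apply_affine(v, AffineTransform.identity())
        np.testing.assert_array_equal(out.intensities, v.intensities)

    def test_affine_composition_consistency(self):
        v = vol(np.random.default_rng(5).random((16, 16, 16)))
        t1 = AffineTransform(np.eye(3) * 1.05, [1.0, 0.0, 0.0])
        t2 = AffineTransform(np.eye(3), [0.0, 2.0, -1.0])
        seq = apply_affine(apply_affine(v, t1), t2)
        composed = apply_affine(v, t1.compose(t2))
        # compare away from the zero-padded boundary
        core = (slice(3, -3),) * 3
        np.testing.assert_allclose(seq.intensities[core],
                                   composed.intensities[core], atol=5e-2)

    def test_random_smooth_field_stays_in_range(self):
        from pam.phantom import FieldSpec, smooth_random_field

        v = random_vol(seed=6)
        f = smooth_random_field(v.shape, FieldSpec(amplitude=2.0,
                                                   smoothness=3.0, seed=6))
        out = warp(v, DisplacementField(f))
        assert np.isfinite(out.intensities).all()
        assert out.intensities.min() >= 0.0
        assert out.intensities.max() <= 1.0

    def test_shape_mismatch_rejected(self):
        v = random_vol(seed=7)
        with pytest.raises(ValueError):
            warp(v, DisplacementField(np.zeros((3, 4, 4, 4))))


class TestCorrelationLoss:
    def test_self_correlation_zero(self):
        x = RNG.random((10, 10, 10))
        assert correlation_loss(x, x) == pytest.approx(0.0, abs=1e-9)

    def test_negated_image_gives_two(self):
        x = RNG.random((10, 10, 10))
        assert correlation_loss(x, 1.0 - x) == pytest.approx(2.0, abs=1e-9)

    def test_independent_noise_near_one(self):
        a = np.random.default_rng(1).random((32, 32, 32))
        b = np.random.default_rng(2).random((32, 32, 32))
        assert abs(correlation_loss(a, b) - 1.0) < 0.05

    def test_symmetry_and_intensity_invariance(self):
        a = RNG.random((8, 8, 8))
        b = RNG.random((8, 8, 8))
        assert correlation_loss(a, b) == pytest.approx(
            correlation_loss(b, a), abs=1e-12)
        assert correlation_loss(3.0 * a + 2.0, b) == pytest.approx(
            correlation_loss(a, b), abs=1e-9)

    def test_both_constant_warns_loss_one(self):
        x = np.ones((4, 4, 4))
        with pytest.warns(UndefinedCorrelationWarning):
            assert correlation_loss(x, 2 * x) == 1.0

    def test_range(self):
        for s in range(5):
            a = np.random.default_rng(s).random((6, 6, 6))
            b = np.random.default_rng(s + 50).random((6, 6, 6))
            assert 0.0 <= correlation_loss(a, b) <= 2.0


class TestPenalties:
    def test_zero_at_identity_and_constant_field(self):
        field = DisplacementField(np.full((3, 8, 8, 8), 1.7))
        assert regularization_penalties(AffineTransform.identity(),
                                        field) == pytest.approx(0.0)

    def test_unit_translation_weighs_one_tenth(self):
        field = DisplacementField(np.zeros((3, 8, 8, 8)))
        total = regularization_penalties(
            AffineTransform(np.eye(3), [1.0, 0.0, 0.0]), field)
        assert total == pytest.approx(0.1)

    def test_nonnegative_on_random_inputs(self):
        for s in range(5):
            rng = np.random.default_rng(s)
            t = AffineTransform(np.eye(3) + rng.normal(0, 0.1, (3, 3)),
                                rng.normal(0, 1, 3))
            f = DisplacementField(rng.normal(0, 1, (3, 6, 6, 6)))
            assert regularization_penalties(t, f) >= 0.0


class TestCurriculum:
    @pytest.mark.parametrize("epoch,kernel", [
        (0, 9), (99, 9), (100, 6), (149, 6), (150, 3), (160, 3),
        (174, 3), (175, 1), (200, 1),
    ])
    def test_kernel_schedule(self, epoch, kernel):
        assert CurriculumSchedule().kernel_at(epoch) == kernel

    def test_identity_after_last_boundary(self):
        v = random_vol(seed=8)
        out = curriculum_smooth(v, epoch=200)
        np.testing.assert_array_equal(out.intensities, v.intensities)

    def test_smoothing_reduces_variance(self):
        v = random_vol(seed=9)
        out = curriculum_smooth(v, epoch=0)
        assert out.intensities.var() < v.intensities.var()

    def test_scaled_schedule(self):
        sch = CurriculumSchedule().scaled(total_epochs=20)
        assert sch.boundaries == (10, 15, 18)


class TestModelStructure:
    def test_untrained_model_is_identity_map(self):
        model = TrackerModel(config=TrackerConfig(seed=0))
        v = random_vol((32, 32, 32), seed=10)
        pair = make_pair(v, v)
        out = model.track(pair)
        assert np.allclose(out.affine.linear, np.eye(3))
        assert np.allclose(out.affine.translation, 0.0)
        assert np.all(out.field.vectors == 0.0)
        assert out.latent_maps.shape[0] == 96

    def test_encoder_halves_resolution_four_times(self):
        model = TrackerModel(config=TrackerConfig(seed=0))
        v = random_vol((32, 32, 32), seed=11)
        out = model.track(make_pair(v, v))
        # four stride-2 blocks: 32 -> 16 -> 8 -> 4 -> 2 per axis
        assert out.latent_maps.shape == (96, 2, 2, 2)
        assert out.field.vectors.shape == (3, 32, 32, 32)
        # the same arithmetic at full scale: 192 -> 96 -> 48 -> 24 -> 12
        scales = [192 // 2 ** (i + 1) for i in range(4)]
        assert scales == [96, 48, 24, 12]

    def test_shape_mismatch_errors(self):
        model = TrackerModel(config=TrackerConfig(seed=0))
        a, b = random_vol((12, 12, 12)), random_vol((12, 12, 8))
        pair = make_pair(a, b)
        with pytest.raises(ValueError):
            affine_forward(pair, model)
        with pytest.raises(ValueError):
            deformable_forward(a, b, model)

    def test_deformable_forward_exposes_96_latents(self):
        model = TrackerModel(config=TrackerConfig(seed=1))
        a, b = random_vol((16, 16, 16), 1), random_vol((16, 16, 16), 2)
        field, latent = deformable_forward(a, b, model)
        assert latent.shape[0] == 96
        assert field.spatial_shape == (16, 16, 16)

    def test_save_load_round_trip(self, tmp_path):
        model = TrackerModel(region="chest", config=TrackerConfig(seed=3))
        for p in model.parameters():
            p.data = p.data + np.random.default_rng(0).normal(
                0, 0.01, p.data.shape)
        path = tmp_path / "tracker.npz"
        model.save(path)
        back = TrackerModel.load(path)
        assert back.region == "chest"
        v = random_vol((16, 16, 16), seed=12)
        pair = make_pair(v, random_vol((16, 16, 16), seed=13))
        np.testing.assert_array_equal(model.track(pair).latent_maps,
                                      back.track(pair).latent_maps)

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            train_tracker([], TrackerConfig())


class TestDeskScaleRecovery:
    """Properties of desk-trained registration (session fixtures)."""

    def test_affine_oracle_recovers_planted_translation(self):
        from pam.phantom import PhantomSpec, make_warped_pair

        spec = PhantomSpec(shape=(32, 32, 32), seed=3,
                           lesions=[((20, 16, 16), 3.0, 0.0)],
                           organ_blobs=[((22, 12, 16), 5.0, 0.6)])
        pair, _ = make_warped_pair(
            spec, affine=AffineTransform(np.eye(3), [0, 0, 4]))
        t = recover_affine(pair.prior, pair.subsequent, steps=300)
        assert np.linalg.norm(t.translation - [0, 0, 4]) < 1.0

    def test_trained_tracker_beats_two_voxel_tre(self, trained_tracker,
                                                 registration_fixtures):
        pairs, truths = registration_fixtures
        errs = []
        for pair, truth in zip(pairs, truths):
            out = trained_tracker.track(pair)
            for lm in truth["landmarks"].values():
                p = np.asarray(lm["fixed_point"])
                q_true = np.asarray(lm["moving_point"])
                q_pred = correspondences(out.affine, out.field, p)[0]
                errs.append(np.linalg.norm(q_pred - q_true))
        baseline = np.mean([np.linalg.norm(np.asarray(lm["moving_point"])
                                           - np.asarray(lm["fixed_point"]))
                            for t in truths
                            for lm in t["landmarks"].values()])
        assert baseline > 2.0  # registration is actually needed
        assert np.mean(errs) < 2.0

    def test_registration_strictly_increases_cc(self, trained_tracker,
                                                registration_fixtures):
        pairs, _ = registration_fixtures
        for pair in pairs:
            out = trained_tracker.track(pair)
            cc_before = 1.0 - correlation_loss(pair.prior, pair.subsequent)
            cc_after = 1.0 - correlation_loss(out.warped_moving,
                                              pair.subsequent)
            assert cc_after > cc_before

    def test_loss_decreases_in_moving_average(self, trained_tracker):
        h = np.asarray(trained_tracker.loss_history)
        ma = np.convolve(h, np.ones(50) / 50, mode="valid")
        assert ma[-1] < ma[0]
        # no 50-step window mean rises above the running minimum by
        # more than curriculum switching noise
        running_min = np.minimum.accumulate(ma)
        assert np.all(ma <= running_min + 0.05)

    def test_holdout_subjects_monitored(self, registration_fixtures):
        pairs, _ = registration_fixtures
        import copy

        tagged = []
        for i, p in enumerate(pairs):
            q = copy.copy(p)
            q.patient_id = "10" if i == 0 else str(i)
            tagged.append(q)
        model = train_tracker(tagged, TrackerConfig(steps=4, batch_size=2,
                                                    seed=0, val_every=2))
        assert len(model.val_history) == 2
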