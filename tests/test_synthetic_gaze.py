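"""Stimulus construction, oculomotor response models, deformation, cohorts."""

import dataclasses
import io

import numpy as np
import pytest

from oculoscreen import (
    AffineMap,
    CohortConfig,
    Condition,
    DeformationParams,
    ResponderProfile,
    Test,
    apply_deformation,
    generate_cohort,
    make_stimulus,
    simulate_response,
)
from oculoscreen.synthetic_gaze import _H_BOX


QUIET = dict(noise_sd=0.0, drift_sd=0.0, wander_sd=0.0, blink_rate_per_min=0.0)


class TestStimuli:
    def test_dot_shape_and_piecewise_constant(self):
        stim = make_stimulus(Test.DOT, duration_s=10.0, rate_hz=120.0)
        assert stim.t.shape == (1200,)
        jumps = np.any(np.diff(stim.positions, axis=0) != 0, axis=1)
        assert jumps.sum() >= 5  # discrete target jumps only
        dx = np.abs(np.diff(stim.positions[np.concatenate([[True], jumps])], axis=0))
        assert (dx[:, 0] > 0).any() and (dx[:, 1] > 0).any()

    def test_okn_phase_displacement_matches_kinematics(self):
        v, T = 300.0, 10.0
        stim = make_stimulus(Test.OKN, duration_s=T, rate_hz=120.0, okn_speed=v)
        half = len(stim.t) // 2
        seg1 = stim.positions[half - 1, 0] - stim.positions[0, 0]
        seg2 = stim.positions[-1, 0] - stim.positions[half, 0]
        assert seg1 == pytest.approx(-v * (T / 2), rel=0.01)
        assert seg2 == pytest.approx(v * (T / 2), rel=0.01)

    def test_h_path_reaches_all_four_extremes(self):
        stim = make_stimulus(Test.H)
        x, y = stim.positions[:, 0], stim.positions[:, 1]
        step = 3900.0 / len(stim.t)  # path length per sample at default speed
        assert x.min() == _H_BOX["xmin"] and x.max() == _H_BOX["xmax"]
        assert y.min() == pytest.approx(_H_BOX["ytop"], abs=2 * step)
        assert y.max() == pytest.approx(_H_BOX["ybot"], abs=2 * step)

    def test_unknown_test_errors(self):
        with pytest.raises(ValueError):
            make_stimulus("SPIRAL")


class TestSimulateResponse:
    def test_noiseless_normal_fixates_targets_after_latency(self):
        stim = make_stimulus(Test.DOT, duration_s=9.0)
        profile = dataclasses.replace(
            ResponderProfile(condition=Condition.NORMAL,
                             saccade_gain=(1.0, 1.0), saccade_latency_ms=150.0),
            **QUIET)
        rec = simulate_response(stim, profile, seed=0)
        dwell = stim.meta["dwell_s"]
        rate = stim.rate_hz
        for k in range(1, 9):  # check steady state at the end of each dwell
            idx = int(k * dwell * rate) - 2
            target = stim.positions[idx]
            np.testing.assert_allclose(rec.left[idx], target, atol=1e-6)
            np.testing.assert_allclose(rec.right[idx], target, atol=1e-6)

    def test_same_profile_and_seed_reproduces_recording(self):
        stim = make_stimulus(Test.OKN)
        profile = ResponderProfile.sample(Condition.NYSTAGMUS,
                                          np.random.default_rng(3))
        a = simulate_response(stim, profile, seed=17)
        b = simulate_response(stim, profile, seed=17)
        np.testing.assert_array_equal(a.left, b.left)
        np.testing.assert_array_equal(a.left_valid, b.left_valid)

    def test_okn_response_is_sawtooth(self):
        stim = make_stimulus(Test.OKN)
        profile = dataclasses.replace(
            ResponderProfile(condition=Condition.NORMAL), **QUIET)
        rec = simulate_response(stim, profile, seed=0)
        x = rec.left[:, 0]
        dx = np.diff(x)
        # many small slow-phase steps in one direction, few large resets opposite
        n_resets = np.sum(np.abs(dx) > 50)
        assert 5 <= n_resets <= 60
        slow = dx[np.abs(dx) < 50]
        assert np.abs(slow).max() < 10  # slow phase tracks bar speed per sample

    def test_blinks_mark_both_eyes_invalid(self):
        stim = make_stimulus(Test.DOT)
        profile = dataclasses.replace(
            ResponderProfile(condition=Condition.NORMAL),
            blink_rate_per_min=60.0)
        rec = simulate_response(stim, profile, seed=5)
        assert (~rec.left_valid).sum() > 0
        np.testing.assert_array_equal(rec.left_valid, rec.right_valid)
        assert np.isnan(rec.left[~rec.left_valid]).all()

    def test_dysconjugate_widens_disparity(self):
        stim = make_stimulus(Test.DOT)
        rng = np.random.default_rng(2)
        normal = simulate_response(stim, ResponderProfile.sample("NORMAL", rng), 1)
        dys = simulate_response(
            stim, ResponderProfile.sample("DYSCONJUGATE", rng), 1)
        spread = lambda r: np.nanstd(r.left - r.right)
        assert spread(dys) > 2 * spread(normal)


class TestDeformation:
    def test_identity_leaves_recording_unchanged(self, small_cohort):
        rec = small_cohort.participants[0].recordings[Test.DOT]
        out = apply_deformation(rec, DeformationParams.identity())
        v = rec.left_valid
        np.testing.assert_allclose(out.left[v], rec.left[v], atol=1e-12)

    def test_pure_translation_shifts_each_eye(self, small_cohort):
        rec = small_cohort.participants[0].recordings[Test.H]
        d = DeformationParams(left=AffineMap(tx=10.0, ty=-5.0),
                              right=AffineMap(tx=-4.0, ty=8.0))
        out = apply_deformation(rec, d)
        v = rec.left_valid
        np.testing.assert_allclose(out.left[v], rec.left[v] + [10.0, -5.0],
                                   atol=1e-12)
        np.testing.assert_allclose(out.right[v], rec.right[v] + [-4.0, 8.0],
                                   atol=1e-12)
        np.testing.assert_array_equal(out.left_valid, rec.left_valid)

    def test_singular_map_rejected(self, small_cohort):
        rec = small_cohort.participants[0].recordings[Test.DOT]
        with pytest.raises(ValueError, match="invertible|singular|positive"):
            apply_deformation(
                rec, DeformationParams(left=AffineMap(sx=0.0), right=AffineMap()))


class TestGenerateCohort:
    def test_cohort_composition(self, small_cohort):
        assert len(small_cohort) == 12
        labels = [p.label for p in small_cohort.participants]
        assert sum(labels) == 6
        for p in small_cohort.participants:
            assert set(p.recordings) == {Test.DOT, Test.H, Test.OKN}
            assert (p.condition is Condition.NORMAL) == (p.label == 0)

    def test_all_negative_cohort(self):
        cohort = generate_cohort(0, 5, seed=1)
        assert all(p.label == 0 for p in cohort.participants)

    def test_same_seed_regenerates_identical_manifest(self):
        a = generate_cohort(3, 2, seed=23).manifest()
        b = generate_cohort(3, 2, seed=23).manifest()
        buf_a, buf_b = io.StringIO(), io.StringIO()
        a.to_csv(buf_a, index=False)
        b.to_csv(buf_b, index=False)
        assert buf_a.getvalue() == buf_b.getvalue()

    def test_same_seed_regenerates_identical_recordings(self):
        a = generate_cohort(2, 1, seed=31)
        b = generate_cohort(2, 1, seed=31)
        for pa, pb in zip(a.participants, b.participants):
            np.testing.assert_array_equal(pa.recordings[Test.H].left,
                                          pb.recordings[Test.H].left)

    def test_blink_dropout_rate_matches_configuration(self):
        """Invalid-sample fraction across a cohort tracks the configured
        blink rate times the mean blink duration."""
        cohort = generate_cohort(0, 20, CohortConfig(apply_deformations=False),
                                 seed=3)
        fracs = []
        rates = []
        for p in cohort.participants:
            rec = p.recordings[Test.DOT]
            fracs.append((~rec.left_valid).mean())
            rates.append(p.profile.blink_rate_per_min)
        expected = np.mean(rates) / 60.0 * 0.15  # mean blink ~150 ms
        assert np.mean(fracs) == pytest.approx(expected, rel=0.35)

    def test_save_writes_csvs_and_manifest(self, tmp_path):
        cohort = generate_cohort(1, 1, seed=2)
        cohort.save(tmp_path)
        assert (tmp_path / "manifest.csv").exists()
        assert len(list(tmp_path.glob("p*.csv"))) == 6
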