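"""RP candidate screening and transducer positioning tests.

The candidate screen is checked against an independent brute-force oracle
that applies the screening rules literally with different primitives
(component labelling + KD-tree instead of flood fill + distance transform).
"""

import numpy as np
import pytest

from tfusplan.positioning import (
    ControlPose,
    NoReachablePlacementError,
    TargetSpec,
    candidate_matrix,
    control_group_placement,
    extract_beam_plane,
    model_center,
    position_transducer,
)
from tfusplan.properties import MediumMaps
from tfusplan.pulse import PulseSequence
from tfusplan.solver import TransducerSpec
from tfusplan.volumes import PhantomSpec, SkullMask, binarize_skull, generate_phantom

from _oracles import rp_candidates_bruteforce


class TestModelCenter:
    def test_centered_shell(self, shell_mask, shell_phantom_spec):
        mc = model_center(shell_mask)
        np.testing.assert_allclose(mc, shell_phantom_spec.center, atol=0.5)

    def test_translation_equivariance(self):
        base = PhantomSpec(outer_radius=15.0, thickness=4.0, center=(24.0,) * 3,
                           target_point=(24.0,) * 3, domain_extent=(64.0,) * 3)
        shifted = PhantomSpec(outer_radius=15.0, thickness=4.0,
                              center=(34.0, 24.0, 24.0),
                              target_point=(34.0, 24.0, 24.0),
                              domain_extent=(64.0,) * 3)
        mc0 = model_center(binarize_skull(generate_phantom(base)))
        mc1 = model_center(binarize_skull(generate_phantom(shifted)))
        np.testing.assert_allclose(mc1 - mc0, [10.0, 0.0, 0.0], atol=1e-9)

    def test_two_disjoint_shells_use_combined_extent(self):
        data = np.zeros((40, 20, 20), bool)
        data[4:8, 8:12, 8:12] = True
        data[30:36, 8:12, 8:12] = True
        mc = model_center(SkullMask(data, (1.0,) * 3))
        # x extent 4..35 -> midpoint 19.5
        np.testing.assert_allclose(mc, [19.5, 9.5, 9.5])

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            model_center(SkullMask(np.zeros((4, 4, 4), bool), (1.0,) * 3))


class TestCandidateMatrix:
    def test_matches_bruteforce_oracle_exactly(self, offset_target_phantom):
        spec, hu, mask = offset_target_phantom
        target = TargetSpec(spec.target_point)
        tr = TransducerSpec()
        cm = candidate_matrix(mask, target, roc=30.0, transducer=tr)
        oracle = rp_candidates_bruteforce(
            mask.data, mask.spacing, mask.origin, spec.target_point,
            roc=30.0, clearance=tr.cap_depth,
        )
        assert cm.n_candidates == oracle.shape[0]
        np.testing.assert_allclose(cm.candidates, oracle)

    def test_no_candidate_on_or_inside_skull(self, shell_mask, shell_target):
        cm = candidate_matrix(shell_mask, shell_target, roc=30.0,
                              transducer=TransducerSpec())
        import scipy.ndimage as ndi
        filled = ndi.binary_fill_holes(shell_mask.data)
        vox = np.round(np.array([
            shell_mask.world_to_voxel(c) for c in cm.candidates
        ])).astype(int)
        assert not filled[vox[:, 0], vox[:, 1], vox[:, 2]].any()

    def test_unreachable_target_raises(self):
        # shell with inner radius > ROC: skull nowhere within reach
        spec = PhantomSpec(outer_radius=45.0, thickness=5.0, center=(56.0,) * 3,
                           target_point=(56.0,) * 3, domain_extent=(112.0,) * 3)
        mask = binarize_skull(generate_phantom(spec))
        with pytest.raises(NoReachablePlacementError):
            candidate_matrix(mask, TargetSpec(spec.target_point), roc=30.0,
                             transducer=TransducerSpec())

    def test_clearance_screening_is_monotone(self, shell_mask, shell_target):
        counts = [
            candidate_matrix(shell_mask, shell_target, roc=30.0,
                             clearance=c).n_candidates
            for c in (0.0, 2.0, 3.5)
        ]
        assert counts[0] >= counts[1] >= counts[2]

    def test_smaller_ball_never_adds_candidates(self, shell_mask, shell_target):
        big = candidate_matrix(shell_mask, shell_target, roc=30.0, clearance=2.7)
        small = candidate_matrix(shell_mask, shell_target, roc=29.0, clearance=2.7)
        big_set = set(map(tuple, np.round(big.candidates, 6)))
        small_set = set(map(tuple, np.round(small.candidates, 6)))
        assert small_set <= big_set

    def test_exclusion_counts_reported(self, shell_mask, shell_target):
        cm = candidate_matrix(shell_mask, shell_target, roc=30.0, clearance=2.7)
        assert set(cm.excluded) == {
            "inside_skull", "below_average_radius", "contact_clearance"}
        assert all(v >= 0 for v in cm.excluded.values())
        assert cm.n_candidates > 0


class TestControlGroup:
    def test_zero_degree_pose_on_coronal_axis(self):
        target = TargetSpec((40.0, 40.0, 40.0))
        poses = control_group_placement(target, roc=30.0, angles=(0.0,),
                                        planes=("transverse",))
        np.testing.assert_allclose(poses[0].center, [40.0, 70.0, 40.0])

    def test_transverse_30_degrees(self):
        target = TargetSpec((0.0, 0.0, 0.0))
        poses = control_group_placement(target, roc=30.0, angles=(30.0,),
                                        planes=("transverse",))
        np.testing.assert_allclose(
            poses[0].center, [15.0, 30.0 * np.cos(np.pi / 6), 0.0], atol=1e-9)

    def test_pose_count_dedupes_shared_baseline(self):
        target = TargetSpec((0.0, 0.0, 0.0))
        poses = control_group_placement(target, roc=30.0)
        assert len(poses) == 2 * 4 - 1  # 0 degrees appears once

    def test_oblique_angles_flag_shear_caveat(self):
        target = TargetSpec((0.0, 0.0, 0.0))
        poses = control_group_placement(target, roc=30.0)
        flags = {(p.plane, p.angle): p.shear_wave_caveat for p in poses}
        assert flags[("transverse", 60.0)] is True
        assert flags[("transverse", 45.0)] is False


class TestBeamPlane:
    def test_slice_preserves_apex_target_geometry(self, shell_medium):
        apex = np.array([40.0, 70.0, 40.0])
        target = np.array([40.0, 40.0, 40.0])
        med2d, apex2d, tgt2d = extract_beam_plane(
            shell_medium, apex, target, roc=30.0, aperture=25.0, spacing=0.5)
        assert med2d.sound_speed.ndim == 2
        assert np.linalg.norm(tgt2d - apex2d) == pytest.approx(30.0)
        # target sits in the water cavity; the path crosses the shell
        ti = tuple(np.round(tgt2d / 0.5).astype(int))
        assert med2d.sound_speed[ti] == pytest.approx(1482.0)
        n_line = 80
        s = np.linspace(0, 1, n_line)
        line = apex2d[None, :] + s[:, None] * (tgt2d - apex2d)[None, :]
        idx = np.round(line / 0.5).astype(int)
        assert (med2d.sound_speed[idx[:, 0], idx[:, 1]] > 1482.0).any()


@pytest.fixture(scope="module")
def small_positioning(shell_medium, shell_mask, shell_target):
    """Positioning run on a sparse candidate subsample (fast settings)."""
    cm = candidate_matrix(shell_mask, shell_target, roc=30.0,
                          transducer=TransducerSpec())
    res = position_transducer(
        cm, shell_target, TransducerSpec(), shell_medium,
        PulseSequence(), mode="2d", subsample=4000, seed=1,
        settle_periods=26, measure_periods=6, spacing=1.0,
    )
    return cm, res


class TestPositioning:
    def test_chosen_center_attains_max_amplitude(self, small_positioning):
        _, res = small_positioning
        assert res.chosen_amplitude == pytest.approx(
            np.nanmax(res.candidate_amplitudes))

    def test_positioning_is_deterministic(self, shell_medium, shell_mask,
                                          shell_target):
        cm = candidate_matrix(shell_mask, shell_target, roc=30.0,
                              transducer=TransducerSpec())
        runs = [
            position_transducer(
                cm, shell_target, TransducerSpec(), shell_medium,
                PulseSequence(), mode="2d", subsample=200,
                max_candidates=3, seed=7,
                settle_periods=26, measure_periods=6, spacing=1.0,
            )
            for _ in range(2)
        ]
        np.testing.assert_array_equal(runs[0].chosen_center,
                                      runs[1].chosen_center)
        np.testing.assert_array_equal(runs[0].candidate_amplitudes,
                                      runs[1].candidate_amplitudes)

    def test_single_candidate_is_chosen(self, shell_medium, shell_target,
                                        shell_mask):
        cm = candidate_matrix(shell_mask, shell_target, roc=30.0,
                              transducer=TransducerSpec())
        res = position_transducer(
            cm, shell_target, TransducerSpec(), shell_medium,
            PulseSequence(), mode="2d", subsample=cm.n_candidates + 1,
            settle_periods=26, measure_periods=6, spacing=1.0,
        )
        assert res.candidate_amplitudes.size == 1
        np.testing.assert_array_equal(res.chosen_center, cm.candidates[0])
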