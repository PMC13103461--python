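"""Phantom generator, probe streams, placement errors, end-to-end truth recovery."""

import numpy as np
import pytest

from emnav.acquisition import AcquisitionConfig, acquire_landmark
from emnav.errors import SpecError
from emnav.geometry import RigidTransform, relative_pose, rotation_about_point
from emnav.navigation import pointwise_distance, tracked_cloud
from emnav.registration import compute_fre, compute_tre, horn_register
from emnav.simulator import (
    PhantomSpec,
    generate_phantom,
    simulate_placement,
    simulate_probe_stream,
)

NOISELESS = dict(fle_sigma_mm=0.0, orientation_sigma_deg=0.0)


@pytest.fixture(scope="module")
def clean_case():
    return generate_phantom(PhantomSpec(seed=7, **NOISELESS))


def _case_equal(a, b) -> bool:
    if not np.array_equal(a.graft.cloud, b.graft.cloud):
        return False
    if not np.array_equal(a.mandible.cloud, b.mandible.cloud):
        return False
    for obj in ("residual_mandible", "graft"):
        if not a.truth_registration[obj].isclose(b.truth_registration[obj], atol=0):
            return False
    for sensor in a.streams:
        for sa, sb in zip(a.streams[sensor], b.streams[sensor]):
            if sa.timestamp != sb.timestamp or not sa.pose.isclose(sb.pose, atol=0):
                return False
    return True


class TestGeneratePhantom:
    def test_same_seed_is_byte_identical(self):
        spec = PhantomSpec(seed=42)
        assert _case_equal(generate_phantom(spec), generate_phantom(spec))

    def test_different_seed_differs(self):
        a = generate_phantom(PhantomSpec(seed=1))
        b = generate_phantom(PhantomSpec(seed=2))
        assert not _case_equal(a, b)

    def test_structure(self, clean_case):
        case = clean_case
        assert len(case.mandible.cloud) == case.spec.mandible_cloud_size
        assert len(case.graft.cloud) == case.spec.graft_cloud_size
        for name in ("CON", "ANG", "JUN"):
            assert name in case.graft.landmarks.names
        segments = {case.segment_assignment[n] for n in case.segment_assignment}
        assert segments == set(range(1, case.spec.n_segments + 1))

    def test_four_segments_present_when_requested(self):
        case = generate_phantom(PhantomSpec(seed=3, n_segments=4))
        segs = {v for v in case.segment_assignment.values()}
        assert segs == {1, 2, 3, 4}

    def test_infeasible_specs_rejected(self):
        with pytest.raises(SpecError):
            PhantomSpec(n_segments=5)
        with pytest.raises(SpecError):
            PhantomSpec(n_fiducials_graft=3)
        with pytest.raises(SpecError):
            PhantomSpec(fle_sigma_mm=-1.0)

    def test_zero_noise_registration_recovers_truth(self, clean_case):
        """End-to-end noiseless identity: FRE = 0, TRE = 0 at machine precision."""
        case = clean_case
        for obj, obj_id in ((case.mandible, "residual_mandible"), (case.graft, "graft")):
            truth = case.truth_registration[obj_id]
            fixed = obj.landmarks.transformed(truth)
            est = horn_register(obj.landmarks, fixed)
            assert compute_fre(est, obj.landmarks, fixed) < 1e-9
            for target in obj.landmarks.points:
                assert compute_tre(est, target, truth=truth) < 1e-9

    def test_zero_noise_full_chain_through_streams(self, clean_case):
        """Acquire from streams, register, navigate: distance map is all zero."""
        case = clean_case
        ref0 = case.streams["reference"][0]
        graft0 = case.streams["graft"][0]
        rel0 = relative_pose(graft0, ref0)
        # acquire every graft fiducial through the probe-stream machinery
        fid_names = [n for n in case.graft.landmarks.names if n.startswith("G_F")]
        acquired = []
        for name in fid_names:
            stream = simulate_probe_stream(case, name, tremble_sigma_mm=0.0)
            acquired.append(acquire_landmark(stream).mean_point)
        from emnav.registration import LandmarkSet

        fixed = LandmarkSet(tuple(fid_names), np.array(acquired), rel0.target_frame)
        est = horn_register(case.graft.landmarks.subset(fid_names), fixed)
        assert compute_fre(est, case.graft.landmarks.subset(fid_names), fixed) < 1e-9
        # navigate: sensor has not moved, so tracked cloud sits on the plan
        current = tracked_cloud(case.graft, est.relabel(target_frame=rel0.target_frame), rel0, rel0)
        truth_cloud = case.truth_registration["graft"].apply(case.graft.cloud)
        dmap = pointwise_distance(current, truth_cloud)
        assert dmap.distances_mm.max() < 1e-9


class TestProbeStream:
    def test_no_tremble_no_slip_is_constant(self, clean_case):
        stream = simulate_probe_stream(clean_case, "CON", tremble_sigma_mm=0.0)
        assert np.allclose(stream, stream[0])
        assert np.allclose(stream[0], clean_case.true_landmark_in_reference("CON"))

    def test_one_slip_yields_exactly_one_restart(self, clean_case):
        stream = simulate_probe_stream(
            clean_case, "CON", tremble_sigma_mm=0.0, slip_events=[(30, 1.0)]
        )
        res = acquire_landmark(stream, AcquisitionConfig())
        assert res.restarts == 1

    def test_subthreshold_slip_does_not_restart(self, clean_case):
        stream = simulate_probe_stream(
            clean_case, "CON", tremble_sigma_mm=0.0, slip_events=[(30, 0.4)]
        )
        res = acquire_landmark(stream, AcquisitionConfig())
        assert res.restarts == 0

    def test_tremble_mean_close_to_truth(self, clean_case):
        """In >= 9/10 seeded repetitions the mean is within 4 sigma/sqrt(60)."""
        sigma = 0.1
        truth = clean_case.true_landmark_in_reference("ANG")
        bound = 4 * sigma / np.sqrt(60)
        hits = 0
        for rep in range(10):
            stream = simulate_probe_stream(
                clean_case, "ANG", tremble_sigma_mm=sigma, seed=1000 + rep
            )
            res = acquire_landmark(stream)
            if np.all(np.abs(res.mean_point - truth) < bound):
                hits += 1
        assert hits >= 9


class TestPlacement:
    def test_identity_error_gives_zero_deviation(self, clean_case):
        placed = simulate_placement(clean_case, RigidTransform.identity("plan"))
        for name in ("CON", "ANG", "JUN"):
            assert placed.placement_deviation(name) == pytest.approx(0.0, abs=1e-12)

    def test_pure_translation_moves_all_landmarks_equally(self, clean_case):
        from emnav.geometry import Rotation

        err = RigidTransform(Rotation.identity(), [0.0, 0.0, 2.0], "plan", "plan")
        placed = simulate_placement(clean_case, err)
        for name in ("CON", "ANG", "JUN"):
            assert placed.placement_deviation(name) == pytest.approx(2.0, abs=1e-9)

    def test_rotation_about_junction_lever_arm_ordering(self, clean_case):
        """A small rotation about JUN displaces CON most and JUN not at all.

        This is the leverage effect: small shifts at the fixation site swing
        the free-standing condyle through the largest arc.
        """
        jun = clean_case.graft.landmarks["JUN"]
        err = rotation_about_point([0.0, 0.0, 1.0], np.deg2rad(2.0), jun, "plan")
        placed = simulate_placement(clean_case, err)
        dev = {n: placed.placement_deviation(n) for n in ("CON", "ANG", "JUN")}
        assert dev["JUN"] == pytest.approx(0.0, abs=1e-9)
        assert dev["CON"] > dev["ANG"] > dev["JUN"]
        # closed form: displacement = 2 r sin(theta/2), r = distance from axis
        for name in ("CON", "ANG"):
            p = clean_case.graft.landmarks[name] - jun
            r = np.linalg.norm(p[:2])  # axis is z through JUN
            assert dev[name] == pytest.approx(2 * r * np.sin(np.deg2rad(1.0)), abs=1e-9)

    def test_lever_arm_holds_across_random_axes(self, clean_case, rng):
        """CON deviation exceeds JUN deviation in 100 % of rotation-only trials."""
        jun = clean_case.graft.landmarks["JUN"]
        for _ in range(100):
            axis = rng.normal(size=3)
            err = rotation_about_point(axis, np.deg2rad(rng.uniform(0.5, 5.0)), jun, "plan")
            placed = simulate_placement(clean_case, err)
            assert placed.placement_deviation("CON") > placed.placement_deviation("JUN")

    def test_out_of_range_errors_rejected(self, clean_case):
        from emnav.geometry import Rotation

        with pytest.raises(SpecError):
            simulate_placement(
                clean_case,
                RigidTransform(Rotation.identity(), [25.0, 0, 0], "plan", "plan"),
            )
        with pytest.raises(SpecError):
            simulate_placement(
                clean_case,
                RigidTransform(
                    Rotation.from_axis_angle([1, 0, 0], np.deg2rad(20)), np.zeros(3), "plan", "plan"
                ),
            )

    def test_streams_reflect_placement(self, clean_case):
        """After placement the graft sensor stream encodes the final pose."""
        from emnav.geometry import Rotation

        err = RigidTransform(Rotation.identity(), [1.0, 2.0, 2.0], "plan", "plan")
        placed = simulate_placement(clean_case, err)
        rel = relative_pose(placed.streams["graft"][0], placed.streams["reference"][0])
        expected = placed.truth_final_pose.compose(placed.sensor_mounts["graft"])
        assert rel.isclose(expected, atol=1e-9)


class TestParameterRecovery:
    def test_registration_error_shrinks_with_fle(self):
        """Mean TRE at CON decreases monotonically over sigma in {1.0, 0.5, 0.1, 0.01}."""
        case = generate_phantom(PhantomSpec(seed=11, fle_sigma_mm=0.0, orientation_sigma_deg=0.0))
        fid_names = [n for n in case.graft.landmarks.names if n.startswith("G_F")]
        plan_fids = case.graft.landmarks.subset(fid_names)
        truth = case.truth_registration["graft"]
        target = case.graft.landmarks["CON"]
        rng = np.random.default_rng(2024)
        from emnav.registration import horn_register_arrays

        fixed_exact = truth.apply(plan_fids.points)
        mean_tre = []
        for sigma in (1.0, 0.5, 0.1, 0.01):
            noisy = fixed_exact + rng.normal(scale=sigma, size=(200,) + fixed_exact.shape)
            R, t = horn_register_arrays(plan_fids.points, noisy)
            est_target = np.einsum("bij,j->bi", R, target) + t
            tre = np.linalg.norm(est_target - truth.apply(target), axis=1)
            mean_tre.append(tre.mean())
        assert all(a > b for a, b in zip(mean_tre, mean_tre[1:]))
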