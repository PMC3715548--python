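"""Superposition, RMSD series, radius clustering, essential dynamics."""

from __future__ import annotations

import numpy as np
import pytest

from enmswitch import (
    ContractError,
    DumbbellSpec,
    Trajectory,
    TwoStateTrajSpec,
    essential_correlations,
    essential_modes,
    kabsch_superpose,
    make_chain,
    make_dumbbell,
    make_two_state_trajectory,
    msf_from_trajectory,
    radius_cluster,
    rmsd_series,
)

from conftest import rand_index, structure_from_coords


def rotation_z(theta: float) -> np.ndarray:
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])


@pytest.fixture(scope="module")
def two_state():
    a, _ = make_dumbbell(DumbbellSpec(15, 3, 0, seed=0))
    b, _ = make_dumbbell(DumbbellSpec(15, 3, 0, seed=1))
    b = a.with_coordinates(b.coordinates)  # same topology, distinct conformer
    return make_two_state_trajectory(a, b, TwoStateTrajSpec(25, 0.3, "blocks", 0))


class TestKabsch:
    def test_rigid_motion_gives_zero_rmsd(self):
        chain = make_chain(30, seed=0)
        moved = chain.with_coordinates(
            chain.coordinates @ rotation_z(np.pi / 2).T + [10.0, -3.0, 7.0]
        )
        _, rmsd = kabsch_superpose(moved, chain)
        assert rmsd == pytest.approx(0.0, abs=1e-8)

    def test_self_superposition_is_exact_and_symmetric(self):
        chain = make_chain(20, seed=1)
        other = chain.with_coordinates(chain.coordinates + np.random.default_rng(0).normal(0, 1, (20, 3)))
        _, r0 = kabsch_superpose(chain, chain)
        assert r0 == 0.0
        _, rab = kabsch_superpose(chain, other)
        _, rba = kabsch_superpose(other, chain)
        assert rab == pytest.approx(rba, abs=1e-10)

    def test_single_residue_displacement_closed_form(self):
        # moving one of N residues by d gives RMSD = d/sqrt(N); refitting
        # recovers slightly less (ratio 0.994 measured at build time)
        chain = make_chain(100, seed=0)
        moved = chain.coordinates.copy()
        moved[40] += [0.0, 0.0, 4.0]
        _, rmsd = kabsch_superpose(chain.with_coordinates(moved), chain)
        expected = 4.0 / np.sqrt(100)
        assert rmsd <= expected + 1e-12
        assert rmsd == pytest.approx(expected, rel=0.02)

    def test_reflection_related_pair_keeps_positive_rmsd(self):
        chain = make_chain(30, seed=2)
        mirrored = chain.with_coordinates(chain.coordinates * [1.0, 1.0, -1.0])
        _, rmsd = kabsch_superpose(mirrored, chain)
        assert rmsd > 0.5

    def test_topology_mismatch_rejected(self):
        a = structure_from_coords([[0, 0, 0], [3.8, 0, 0]])
        b = structure_from_coords([[0, 0, 0], [3.8, 0, 0]], start=10)
        with pytest.raises(ContractError):
            kabsch_superpose(a, b)


class TestRMSDSeries:
    def test_constant_trajectory_is_all_zeros(self):
        chain = make_chain(20, seed=3)
        traj = Trajectory([chain] * 5)
        np.testing.assert_allclose(rmsd_series(traj), 0.0, atol=1e-8)

    def test_two_state_series_is_bimodal(self, two_state):
        series = rmsd_series(two_state.trajectory)
        labels = two_state.labels
        low = series[labels == 0][1:]  # first frame is the reference
        high = series[labels == 1]
        assert low.max() < 1.0
        assert high.min() > 3.0

    def test_length_matches_post_discard_frame_count(self):
        chain = make_chain(20, seed=3)
        traj = Trajectory([chain] * 10, equilibration_frames=4)
        assert rmsd_series(traj).size == 6


class TestRadiusCluster:
    def test_identical_frames_collapse_to_one_cluster(self):
        chain = make_chain(20, seed=4)
        result = radius_cluster(Trajectory([chain] * 8), radius=2.0)
        assert result.n_clusters == 1
        assert result.populations.tolist() == [8]

    def test_two_state_recovery_with_wide_margin(self, two_state):
        result = radius_cluster(two_state.trajectory, radius=3.5)
        assert result.n_clusters == 2
        assert rand_index(result.assignments, two_state.labels) == 1.0
        assert two_state.margin >= 10

    def test_radius_beyond_diameter_gives_one_cluster(self, two_state):
        series = rmsd_series(two_state.trajectory)
        result = radius_cluster(two_state.trajectory, radius=series.max() * 2 + 5)
        assert result.n_clusters == 1

    def test_partition_is_frame_order_invariant(self, two_state):
        traj = two_state.trajectory
        result = radius_cluster(traj, radius=3.5)
        order = np.random.default_rng(5).permutation(len(traj.frames))
        shuffled = Trajectory([traj.frames[i] for i in order])
        result2 = radius_cluster(shuffled, radius=3.5)
        assert rand_index(result2.assignments, two_state.labels[order]) == 1.0
        assert result.populations.sum() == result2.populations.sum() == len(order)

    def test_best_members_belong_to_their_clusters(self, two_state):
        result = radius_cluster(two_state.trajectory, radius=3.5)
        for k, frame in enumerate(result.best_members):
            assert result.assignments[frame] == k


def internal_direction(coords: np.ndarray, seed: int) -> np.ndarray:
    """A random unit 3N-direction orthogonal to all rigid-body motions.

    Superposition removes net translations and infinitesimal rotations;
    a planted mode must live in their orthogonal complement to survive.
    """
    n = coords.shape[0]
    center = coords - coords.mean(axis=0)
    rigid = []
    for axis in np.eye(3):
        rigid.append(np.tile(axis, n))  # translation
        rigid.append(np.cross(np.broadcast_to(axis, (n, 3)), center).ravel())
    direction = np.random.default_rng(seed).normal(size=3 * n)
    basis, _ = np.linalg.qr(np.array(rigid).T)
    direction -= basis @ (basis.T @ direction)
    return direction / np.linalg.norm(direction)


class TestEssentialModes:
    def test_rank_one_trajectory_recovers_planted_direction(self):
        chain = make_chain(20, seed=6)
        direction = internal_direction(chain.coordinates, seed=0).reshape(20, 3)
        frames = [
            chain.with_coordinates(chain.coordinates + amp * direction)
            for amp in 0.5 * np.sin(np.linspace(0, 6 * np.pi, 40))
        ]
        ess = essential_modes(Trajectory(frames), n_modes=1)
        assert ess.eigenvalues[0] > 1e-6
        # numerical rank 1: nothing else survives the rank cut
        assert ess.eigenvalues.size == 1
        cosine = abs(ess.eigenvectors[:, 0] @ direction.ravel())
        assert cosine > 0.999

    def test_white_noise_spectrum_is_flat(self):
        base = make_chain(30, seed=7)
        rng = np.random.default_rng(2)
        frames = [
            base.with_coordinates(base.coordinates + rng.normal(0, 0.4, (30, 3)))
            for _ in range(3000)
        ]
        ess = essential_modes(Trajectory(frames), n_modes=10)
        top = ess.eigenvalues[:10]
        assert top.max() / top.min() < 3.0

    def test_variance_conservation_trace_identity(self, two_state):
        ess = essential_modes(two_state.trajectory, n_modes=10)
        msf = msf_from_trajectory(two_state.trajectory)
        assert ess.eigenvalues.sum() == pytest.approx(msf.values.sum(), rel=1e-8)

    def test_requesting_too_many_modes_warns_and_truncates(self):
        chain = make_chain(10, seed=8)
        direction = internal_direction(chain.coordinates, seed=1).reshape(10, 3)
        frames = [
            chain.with_coordinates(chain.coordinates + eps * direction)
            for eps in (0.0, 0.3, 0.6)
        ]
        with pytest.warns(UserWarning, match="rank"):
            ess = essential_modes(Trajectory(frames), n_modes=10)
        assert ess.truncated
        assert ess.n_modes_kept <= 2


def planted_modes(structure, eigenvector: np.ndarray, variance: float = 1.0):
    """EssentialModes with one planted unit eigenvector (for map unit tests)."""
    from enmswitch import EssentialModes

    v = eigenvector.ravel() / np.linalg.norm(eigenvector)
    return EssentialModes(
        mean_structure=structure.coordinates.copy(),
        eigenvalues=np.array([variance]),
        eigenvectors=v[:, None],
        n_modes_kept=1,
        residues=list(structure.residues),
    )


class TestEssentialCorrelations:
    def test_uniform_translation_mode_correlates_everything(self):
        # a single mode translating every residue identically: every
        # residue pair fluctuates in lockstep, so the whole map is +1
        chain = make_chain(15, seed=9)
        ess = planted_modes(chain, np.tile([0.0, 0.0, 1.0], 15))
        cmap = essential_correlations(ess, 1)
        np.testing.assert_allclose(cmap.normalized, 1.0, atol=1e-12)

    def test_opposed_rigid_blocks_anticorrelate(self):
        a = make_chain(10, seed=10)
        b = make_chain(10, seed=11)
        s = structure_from_coords(
            np.vstack([a.coordinates, b.coordinates + [60.0, 0, 0]])
        )
        mode = np.concatenate([np.tile([1.0, 0, 0], 10), np.tile([-1.0, 0, 0], 10)])
        cmap = essential_correlations(planted_modes(s, mode), 1)
        inter = cmap.normalized[:10, 10:]
        np.testing.assert_allclose(inter, -1.0, atol=1e-12)

    def test_all_modes_equal_direct_covariance_correlations(self, two_state):
        traj = two_state.trajectory
        ess = essential_modes(traj, n_modes=10)
        cmap = essential_correlations(ess, ess.eigenvalues.size)
        # independent oracle: correlation of residue fluctuation dot
        # products from the covariance computed directly
        from enmswitch.trajectory import _superposed_coords

        coords = _superposed_coords(traj)
        dev = coords - coords.mean(axis=0)
        raw = np.einsum("tia,tja->ij", dev, dev) / coords.shape[0]
        d = np.sqrt(np.diag(raw))
        expected = raw / np.outer(d, d)
        np.testing.assert_allclose(cmap.normalized, expected, atol=1e-8)

    def test_diagonal_is_one(self, two_state):
        ess = essential_modes(two_state.trajectory, n_modes=5)
        cmap = essential_correlations(ess, 5)
        np.testing.assert_array_equal(np.diag(cmap.normalized), 1.0)


class TestTrajectoryMSF:
    def test_constant_trajectory_has_zero_msf(self):
        chain = make_chain(20, seed=12)
        msf = msf_from_trajectory(Trajectory([chain] * 4))
        np.testing.assert_allclose(msf.values, 0.0, atol=1e-10)

    def test_iid_noise_msf_matches_expectation(self):
        # 3 sigma^2 per residue, deflated ~2% by removing the 6 rigid-body
        # degrees of freedom in superposition (ratio 0.963 at build time)
        base = make_chain(60, seed=0)
        rng = np.random.default_rng(1)
        sigma = 0.5
        frames = [
            base.with_coordinates(base.coordinates + rng.normal(0, sigma, (60, 3)))
            for _ in range(3000)
        ]
        msf = msf_from_trajectory(Trajectory(frames))
        assert msf.values.mean() == pytest.approx(3 * sigma**2, rel=0.05)

    def test_msf_sum_equals_covariance_trace(self, two_state):
        msf = msf_from_trajectory(two_state.trajectory)
        ess = essential_modes(two_state.trajectory, n_modes=3)
        assert msf.values.sum() == pytest.approx(ess.eigenvalues.sum(), rel=1e-8)
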