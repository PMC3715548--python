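"""Generators: determinism, geometric ground truth, connectivity claims."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import cdist, pdist, squareform

from enmswitch import (
    ContractError,
    DumbbellSpec,
    TwoStateTrajSpec,
    build_kirchhoff,
    cross_correlations,
    decompose,
    extreme_patch,
    kabsch_superpose,
    make_chain,
    make_dimer,
    make_dumbbell,
    make_switch_dimer,
    make_two_state_trajectory,
    perturb_ensemble,
    slowest_modes,
)


def n_components(coords, cutoff=10.0) -> int:
    adj = squareform(pdist(coords) <= cutoff).astype(int)
    return connected_components(adj, directed=False)[0]


class TestMakeChain:
    def test_consecutive_spacing_is_exact(self):
        chain = make_chain(40, spacing=3.8, seed=0)
        steps = np.linalg.norm(np.diff(chain.coordinates, axis=0), axis=1)
        np.testing.assert_allclose(steps, 3.8, atol=1e-9)

    def test_chain_is_self_avoiding_and_connected(self):
        chain = make_chain(50, seed=1)
        d = squareform(pdist(chain.coordinates))
        np.fill_diagonal(d, np.inf)
        off_bond = d.copy()
        for i in range(49):
            off_bond[i, i + 1] = off_bond[i + 1, i] = np.inf
        assert off_bond.min() >= 3.4
        assert n_components(chain.coordinates) == 1

    def test_deterministic_under_seed(self):
        a = make_chain(30, seed=7)
        b = make_chain(30, seed=7)
        np.testing.assert_array_equal(a.coordinates, b.coordinates)

    def test_rejects_trivial_length(self):
        with pytest.raises(ContractError):
            make_chain(1)


class TestMakeDumbbell:
    def test_ground_truth_hinge_and_connectivity(self):
        structure, hinge = make_dumbbell(DumbbellSpec(25, 3, 0, seed=0))
        assert hinge == [25, 26, 27]
        assert structure.n_residues == 53
        assert n_components(structure.coordinates) == 1

    def test_isolated_domains_touch_only_through_linker(self):
        structure, hinge = make_dumbbell(DumbbellSpec(25, 3, 0, seed=3))
        coords = structure.coordinates
        cross = cdist(coords[:25], coords[25 + 3 :])
        assert cross.min() > 10.0

    def test_inter_domain_contacts_strengthen_cross_correlations(self):
        mr_means = {}
        for contacts in (0, 40):
            structure, _ = make_dumbbell(DumbbellSpec(25, 3, contacts, seed=5))
            modes = decompose(build_kirchhoff(structure, 10.0))
            cmap = cross_correlations(modes, slowest_modes(modes))
            mr_means[contacts] = cmap.normalized[:25, 28:].mean()
        assert mr_means[40] > mr_means[0]

    def test_requested_contacts_are_formed(self):
        spec = DumbbellSpec(25, 3, 20, seed=6)
        structure, _ = make_dumbbell(spec)
        coords = structure.coordinates
        cross = cdist(coords[:25], coords[28:])
        assert (cross <= 10.0).sum() >= 20
        assert cross.min() >= 3.6 - 1e-9


class TestMakeDimer:
    @pytest.fixture(scope="class")
    def monomer(self):
        structure, hinge = make_dumbbell(DumbbellSpec(25, 3, 0, seed=1))
        return structure, hinge

    def test_designed_interface_pairs_within_cutoff(self, monomer):
        structure, hinge = monomer
        dimer = make_dimer(structure, hinge)
        n = structure.n_residues
        a, b = dimer.coordinates[:n], dimer.coordinates[n:]
        mate = cdist(a[hinge], b[hinge])
        assert mate.min(axis=1).max() <= 10.0

    def test_c2_symmetry_makes_map_block_symmetric(self, monomer):
        structure, hinge = monomer
        dimer = make_dimer(structure, hinge)
        modes = decompose(build_kirchhoff(dimer, 10.0))
        cmap = cross_correlations(modes, slowest_modes(modes))
        n = structure.n_residues
        aa, bb = cmap.normalized[:n, :n], cmap.normalized[n:, n:]
        ab, ba = cmap.normalized[:n, n:], cmap.normalized[n:, :n]
        np.testing.assert_allclose(aa, bb, atol=1e-8)
        np.testing.assert_allclose(ab, ba.T, atol=1e-8)

    def test_zero_interface_gives_disconnected_dimer(self, monomer):
        structure, _ = monomer
        dimer = make_dimer(structure, [])
        modes = decompose(build_kirchhoff(dimer, 10.0))
        assert modes.n_zero == 2

    def test_surface_patch_interface_stays_in_contact(self, monomer):
        structure, _ = monomer
        patch = extreme_patch(structure, [-1.0, 0, 0], 4)
        dimer = make_dimer(structure, patch)
        n = structure.n_residues
        mate = cdist(dimer.coordinates[:n][patch], dimer.coordinates[n:][patch])
        assert mate.min(axis=1).max() <= 10.0


class TestSwitchDimer:
    def test_on_state_contact_architecture(self):
        sd = make_switch_dimer("on", seed=0)
        n = sd.structure.n_residues // 2
        a, b = sd.structure.coordinates[:n], sd.structure.coordinates[n:]
        hinge = sd.hinge_indices
        assert cdist(a[hinge], b[hinge]).min() <= 10.0  # hinge meets hinge
        camp = list(range(25))
        dna = list(range(28, 53))
        assert (cdist(a[camp], b[camp]) <= 10.0).sum() >= 15  # fused core
        assert cdist(a[dna], b[dna]).min() > 10.0  # free DNA domains

    def test_off_state_contact_architecture(self):
        sd = make_switch_dimer("off", seed=0)
        n = sd.structure.n_residues // 2
        a, b = sd.structure.coordinates[:n], sd.structure.coordinates[n:]
        assert cdist(a[sd.hinge_indices], b[sd.hinge_indices]).min() > 10.0
        assert cdist(a, b).min() <= 10.0  # but the chains do touch

    def test_deterministic_and_distinct_under_seed(self):
        a = make_switch_dimer("on", seed=3).structure.coordinates
        b = make_switch_dimer("on", seed=3).structure.coordinates
        c = make_switch_dimer("on", seed=4).structure.coordinates
        np.testing.assert_array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_unknown_state_rejected(self):
        with pytest.raises(ContractError):
            make_switch_dimer("maybe")  # type: ignore[arg-type]


class TestPerturbEnsemble:
    def test_zero_sigma_gives_identical_members(self):
        base, _ = make_dumbbell(DumbbellSpec(10, 2, 0, seed=0))
        ens = perturb_ensemble(base, 0.0, 5, seed=1)
        for m in ens:
            np.testing.assert_array_equal(m.coordinates, base.coordinates)

    def test_mean_structure_near_original(self):
        base, _ = make_dumbbell(DumbbellSpec(10, 2, 0, seed=0))
        sigma, n = 0.5, 200
        ens = perturb_ensemble(base, sigma, n, seed=2)
        mean = np.mean([m.coordinates for m in ens], axis=0)
        # CLT: per-coordinate deviation within 4 sigma / sqrt(n)
        assert np.abs(mean - base.coordinates).max() < 4 * sigma / np.sqrt(n)

    def test_seed_reproducibility_bit_exact(self):
        base, _ = make_dumbbell(DumbbellSpec(10, 2, 0, seed=0))
        a = perturb_ensemble(base, 0.3, 3, seed=9)
        b = perturb_ensemble(base, 0.3, 3, seed=9)
        for ma, mb in zip(a, b):
            np.testing.assert_array_equal(ma.coordinates, mb.coordinates)


class TestTwoStateTrajectory:
    @pytest.fixture(scope="class")
    def conformers(self):
        a, _ = make_dumbbell(DumbbellSpec(15, 3, 0, seed=0))
        b, _ = make_dumbbell(DumbbellSpec(15, 3, 0, seed=1))
        return a, a.with_coordinates(b.coordinates)

    def test_zero_noise_frames_equal_their_conformers(self, conformers):
        a, b = conformers
        result = make_two_state_trajectory(a, b, TwoStateTrajSpec(5, 0.0, "blocks", 0))
        for frame, label in zip(result.trajectory.frames, result.labels):
            np.testing.assert_array_equal(
                frame.coordinates, (a if label == 0 else b).coordinates
            )
        assert result.margin == np.inf

    def test_frame_count_and_margin_recorded(self, conformers):
        a, b = conformers
        result = make_two_state_trajectory(a, b, TwoStateTrajSpec(8, 0.4, "blocks", 1))
        assert len(result.trajectory.frames) == 16
        _, sep = kabsch_superpose(a, b)
        assert result.margin == pytest.approx(sep / 0.4)

    def test_shuffled_mixing_keeps_label_bookkeeping(self, conformers):
        a, b = conformers
        result = make_two_state_trajectory(a, b, TwoStateTrajSpec(6, 0.1, "shuffled", 2))
        assert sorted(result.labels.tolist()) == [0] * 6 + [1] * 6
        for frame, label in zip(result.trajectory.frames, result.labels):
            ref = (a if label == 0 else b).coordinates
            assert np.abs(frame.coordinates - ref).max() < 1.0
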