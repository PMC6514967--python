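"""Extraction, superposition, unfitted RMSD and population-ranked clustering."""

import numpy as np
import pytest

from metabind import (ClusterResult, DegenerateBackboneError,
                      EmptySelectionError, ExtractionParams, cluster_frames,
                      extract_frames, ligand_rmsd, pocket_atom_indices,
                      report_clusters, superpose_backbone,
                      sample_planted_ensemble)

from conftest import five_mode_spec, make_frames


class TestExtraction:
    def test_all_frames_at_minimum(self):
        frames = make_frames([0.5] * 10)
        selected, fraction = extract_frames(frames, 0.5)
        assert len(selected) == 10
        assert fraction == 100.0

    def test_hand_enumerated_window(self):
        cvs = np.round(np.arange(0.1, 1.01, 0.1), 10)
        frames = make_frames(cvs)
        selected, fraction = extract_frames(frames, 0.5,
                                            ExtractionParams(0.3))
        assert np.allclose(np.sort(selected.cv),
                           [0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8])
        assert fraction == pytest.approx(70.0)

    def test_matches_brute_force_filter(self):
        rng = np.random.default_rng(30)
        cvs = rng.uniform(0.0, 3.0, size=10_000)
        frames = make_frames(cvs)
        minimum, delta = 1.2, 0.3
        selected, fraction = extract_frames(frames, minimum,
                                            ExtractionParams(delta))
        brute = [i for i, c in enumerate(cvs) if abs(c - minimum) <= delta]
        assert np.array_equal(np.flatnonzero(np.isin(
            np.arange(len(cvs)), brute)), brute)
        assert len(selected) == len(brute)
        assert np.array_equal(selected.cv, cvs[brute])
        assert fraction == pytest.approx(100.0 * len(brute) / 10_000)

    def test_idempotent(self):
        rng = np.random.default_rng(31)
        frames = make_frames(rng.uniform(0, 3, 500))
        once, _ = extract_frames(frames, 1.0, ExtractionParams(0.3))
        twice, frac = extract_frames(once, 1.0, ExtractionParams(0.3))
        assert len(twice) == len(once)
        assert frac == 100.0

    def test_empty_selection_advises(self):
        frames = make_frames([0.1, 0.2])
        with pytest.raises(EmptySelectionError, match="larger delta_cv"):
            extract_frames(frames, 2.5, ExtractionParams(0.3))


def _toy_frames(coords_list, backbone, ligand):
    coords = np.array(coords_list)
    n = len(coords)
    return make_frames_from_coords(coords, backbone, ligand)


def make_frames_from_coords(coords, backbone, ligand):
    from metabind import FrameSet
    n = len(coords)
    return FrameSet(coords, np.zeros(n), np.arange(n, dtype=float),
                    np.zeros(n, dtype=int),
                    backbone_indices=np.asarray(backbone),
                    ligand_indices=np.asarray(ligand))


class TestSuperposition:
    backbone = [0, 1, 2, 3]
    ligand = [4]

    def _reference(self):
        ref = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0],
                        [0.3, 0.2, 0.9], [0.5, 0.5, 0.5]])
        return ref

    def test_identity_for_identical_frame(self):
        ref = self._reference()
        frames = make_frames_from_coords(ref[None], self.backbone, self.ligand)
        fitted = superpose_backbone(frames, ref)
        assert np.allclose(fitted.coordinates[0], ref, atol=1e-12)

    def test_undoes_rigid_motion(self):
        ref = self._reference()
        theta = np.pi / 2
        rot = np.array([[np.cos(theta), -np.sin(theta), 0],
                        [np.sin(theta), np.cos(theta), 0], [0, 0, 1]])
        moved = ref @ rot.T + np.array([1.0, -2.0, 0.5])
        frames = make_frames_from_coords(moved[None], self.backbone,
                                         self.ligand)
        fitted = superpose_backbone(frames, ref)
        rmsd_bb = np.sqrt(np.mean(np.sum(
            (fitted.coordinates[0][self.backbone] - ref[self.backbone]) ** 2,
            axis=1)))
        assert rmsd_bb <= 1e-9
        # the ligand is co-transformed, so it returns to its reference spot
        assert np.allclose(fitted.coordinates[0][self.ligand],
                           ref[self.ligand], atol=1e-9)

    def test_recovers_constructed_rotation(self):
        rng = np.random.default_rng(40)
        ref = rng.normal(size=(5, 3))
        from scipy.spatial.transform import Rotation
        true_rot = Rotation.from_euler("zyx", [0.4, -0.2, 1.1])
        moved = true_rot.apply(ref) + np.array([0.2, 0.3, -0.1])
        frames = make_frames_from_coords(moved[None], [0, 1, 2, 3], [4])
        fitted = superpose_backbone(frames, ref)
        assert np.allclose(fitted.coordinates[0], ref, atol=1e-9)

    def test_collinear_backbone_rejected(self):
        line = np.array([[0.0, 0.0, float(i)] for i in range(4)]
                        + [[0.5, 0.5, 0.5]])
        frames = make_frames_from_coords(line[None], [0, 1, 2, 3], [4])
        with pytest.raises(DegenerateBackboneError):
            superpose_backbone(frames, line)


class TestLigandRMSD:
    def test_identity(self):
        a = np.random.default_rng(41).normal(size=(6, 3))
        assert ligand_rmsd(a, a, [0, 1, 2]) == 0.0

    def test_hand_arithmetic(self):
        a = np.zeros((2, 3))
        b = np.zeros((2, 3))
        b[:, 0] = 0.1  # both atoms displaced by 0.1 nm
        assert ligand_rmsd(a, b, [0, 1]) == pytest.approx(1.0)

    def test_metric_properties(self):
        rng = np.random.default_rng(42)
        a, b, c = rng.normal(size=(3, 5, 3))
        sel = [0, 2, 4]
        assert ligand_rmsd(a, b, sel) == pytest.approx(
            ligand_rmsd(b, a, sel))
        assert ligand_rmsd(a, b, sel) >= 0
        assert ligand_rmsd(a, b, sel) <= (ligand_rmsd(a, c, sel)
                                          + ligand_rmsd(c, b, sel) + 1e-12)

    def test_selection_mismatch(self):
        with pytest.raises((ValueError, IndexError)):
            ligand_rmsd(np.zeros((3, 3)), np.zeros((2, 3)), [0, 2])


def _average_linkage_reference(dm, k):
    """Exhaustive O(n^3) average-linkage agglomeration."""
    n = len(dm)
    clusters = [[i] for i in range(n)]
    while len(clusters) > k:
        best = (np.inf, None)
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = np.mean([dm[a, b] for a in clusters[i]
                             for b in clusters[j]])
                if d < best[0] - 1e-15:
                    best = (d, (i, j))
        i, j = best[1]
        clusters[i] = clusters[i] + clusters[j]
        del clusters[j]
    labels = np.empty(n, dtype=int)
    for ci, members in enumerate(clusters):
        labels[members] = ci
    return labels


def _partition(labels):
    groups = {}
    for i, c in enumerate(labels):
        groups.setdefault(c, []).append(i)
    return sorted(tuple(v) for v in groups.values())


class TestClustering:
    def test_two_modes_zero_noise_exact_partition(self, binding_system):
        from metabind import PlantedEnsembleSpec
        decoy = np.array(binding_system.metadata["decoy_pose"])
        spec = PlantedEnsembleSpec(
            modes=[(binding_system.reference_pose, 0.6, 0.0),
                   (decoy, 0.4, 0.0)],
            n_frames=50, backbone_jitter_sd=0.0, seed=50)
        frames = sample_planted_ensemble(binding_system, spec)
        result = cluster_frames(frames, n_clusters=2)
        assert result.n_clusters == 2
        expected = np.where(frames.true_mode == 0, 1, 2)
        assert np.array_equal(result.labels, expected)
        counts = np.bincount(frames.true_mode)
        assert result.populations[0] == pytest.approx(100.0 * counts[0] / 50)

    def test_planted_five_modes_populations(self, binding_system,
                                            planted_frames):
        fitted = superpose_backbone(planted_frames,
                                    binding_system.coordinates)
        result = cluster_frames(fitted, n_clusters=5)
        n = len(planted_frames)
        true_pct = 100.0 * np.bincount(planted_frames.true_mode,
                                       minlength=5) / n
        got = np.sort(result.populations)[::-1]
        want = np.sort(true_pct)[::-1]
        assert np.all(np.abs(got - want) <= 2.0)
        # top representative close to the planted dominant pose
        rep = fitted.coordinates[result.representative_indices[0]]
        assert ligand_rmsd(rep, _full_reference(binding_system),
                           fitted.ligand_indices) <= 0.5

    def test_matches_exhaustive_average_linkage(self, binding_system):
        spec = five_mode_spec(binding_system, n_frames=50, seed=51)
        frames = sample_planted_ensemble(binding_system, spec)
        result = cluster_frames(frames, n_clusters=5)
        lig = frames.coordinates[:, frames.ligand_indices, :]
        n = len(frames)
        dm = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                dm[i, j] = dm[j, i] = ligand_rmsd(
                    frames.coordinates[i], frames.coordinates[j],
                    frames.ligand_indices)
        ref_labels = _average_linkage_reference(dm, 5)
        assert _partition(result.labels) == _partition(ref_labels)

    def test_order_invariance_up_to_relabeling(self, binding_system):
        spec = five_mode_spec(binding_system, n_frames=60, seed=52)
        frames = sample_planted_ensemble(binding_system, spec)
        perm = np.random.default_rng(0).permutation(len(frames))
        a = cluster_frames(frames, 5)
        b = cluster_frames(frames.subset(perm), 5)
        part_a = _partition(a.labels)
        # map the permuted labels back to original frame ids
        groups_b = {}
        for pos, lab in enumerate(b.labels):
            groups_b.setdefault(lab, []).append(int(perm[pos]))
        part_b = sorted(tuple(sorted(v)) for v in groups_b.values())
        assert part_a == part_b

    def test_representative_minimizes_rmsd_sum(self, binding_system):
        spec = five_mode_spec(binding_system, n_frames=40, seed=53)
        frames = sample_planted_ensemble(binding_system, spec)
        result = cluster_frames(frames, 3)
        lig = frames.coordinates[:, frames.ligand_indices, :]
        for c in range(1, result.n_clusters + 1):
            members = result.members(c)
            rep = result.representative_indices[c - 1]
            assert rep in members
            sums = []
            for i in members:
                s = sum(ligand_rmsd(frames.coordinates[i],
                                    frames.coordinates[j],
                                    frames.ligand_indices) for j in members)
                sums.append(s)
            best = members[int(np.argmin(sums))]
            assert rep == best

    def test_too_few_frames_raises(self, binding_system):
        spec = five_mode_spec(binding_system, n_frames=5, seed=54)
        frames = sample_planted_ensemble(binding_system, spec)
        with pytest.raises(ValueError, match="clusters"):
            cluster_frames(frames.subset([0, 1]), 5)

    def test_fewer_distinct_conformations_truncates(self, binding_system):
        from metabind import PlantedEnsembleSpec
        spec = PlantedEnsembleSpec(
            modes=[(binding_system.reference_pose, 1.0, 0.0)],
            n_frames=10, backbone_jitter_sd=0.0, seed=55)
        frames = sample_planted_ensemble(binding_system, spec)
        result = cluster_frames(frames, 5)
        assert result.truncated
        assert result.n_clusters == 1
        assert result.populations[0] == pytest.approx(100.0)


def _full_reference(system):
    ref = system.coordinates.copy()
    ref[system.ligand_indices] = system.reference_pose
    return ref


class TestReport:
    def test_columns_without_reference(self, binding_system, planted_frames):
        fitted = superpose_backbone(planted_frames,
                                    binding_system.coordinates)
        result = cluster_frames(fitted, 5)
        table = report_clusters(result, fitted)
        assert "ligand_rmsd_A" not in table.columns
        assert table["population_pct"].sum() == pytest.approx(100.0, abs=1e-6)

    def test_top_cluster_has_lowest_rmsd(self, binding_system,
                                         planted_frames):
        fitted = superpose_backbone(planted_frames,
                                    binding_system.coordinates)
        result = cluster_frames(fitted, 5)
        table = report_clusters(result, fitted, _full_reference(binding_system))
        assert table["ligand_rmsd_A"].iloc[0] == table["ligand_rmsd_A"].min()
        assert np.all(np.diff(table["population_pct"]) <= 1e-12)

    def test_pocket_selection_from_reference(self, binding_system):
        ref = _full_reference(binding_system)
        pocket = pocket_atom_indices(ref, binding_system.backbone_indices,
                                     binding_system.ligand_indices,
                                     cutoff_nm=0.5)
        assert len(pocket) >= 2
        assert set(pocket).issubset(set(binding_system.backbone_indices))
        lig = ref[binding_system.ligand_indices]
        for idx in pocket:
            d = np.linalg.norm(lig - ref[idx], axis=1).min()
            assert d <= 0.5
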