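"""PWES construction, clustering, and position-shuffle significance."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crisprscan.simulate import StructureSimSpec, simulate_structure
from crisprscan.spatial_hotspots import (
    StructureModel,
    cluster_pwes,
    cluster_significance,
    compute_pwes,
    gaussian_kernel,
    load_structure_centroids,
    pairwise_scores,
    spatial_scan,
    summed_abs_pwes,
)


def _grid_structure(residues, spacing=5.0):
    """Residues laid out on a line with the given spacing."""
    return StructureModel({r: np.array([i * spacing, 0.0, 0.0]) for i, r in enumerate(residues)})


class TestPairwiseScores:
    def test_hand_computation_three_scores(self):
        # scores {0,1,2}: pair sums {1,2,3}; x_bar=2; population SD over sums
        pw, x_bar, s_x = pairwise_scores(np.array([0.0, 1.0, 2.0]))
        assert x_bar == pytest.approx(2.0)
        assert s_x == pytest.approx(np.sqrt(2.0 / 3.0))
        assert pw[0, 1] == pytest.approx(np.tanh((1.0 - 2.0) / s_x))
        assert pw[0, 2] == pytest.approx(0.0)  # pair at the mean sum

    def test_symmetry_bounds_and_zero_diagonal(self):
        rng = np.random.default_rng(2)
        pw, _, _ = pairwise_scores(rng.normal(size=15))
        assert np.allclose(pw, pw.T)
        assert np.all(np.abs(pw) < 1.0)
        assert np.allclose(np.diag(pw), 0.0)

    def test_constant_scores_degenerate_to_zero(self):
        with pytest.warns(UserWarning, match="pw set to 0"):
            pw, _, s_x = pairwise_scores(np.full(5, 3.3))
        assert s_x == 0.0 and np.allclose(pw, 0.0)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        scores=st.lists(
            st.floats(-5, 5, allow_nan=False), min_size=3, max_size=10
        ),
        shift=st.floats(-10, 10, allow_nan=False),
    )
    def test_shift_invariance(self, scores, shift):
        """Adding a constant to all scores leaves pw unchanged."""
        x = np.array(scores)
        if np.std(x[:, None] + x[None, :]) == 0:
            return
        pw1, _, _ = pairwise_scores(x)
        pw2, _, _ = pairwise_scores(x + shift)
        assert np.allclose(pw1, pw2, atol=1e-10)


class TestPWES:
    def test_kernel_closed_forms(self):
        t = 16.0
        assert gaussian_kernel(np.array(0.0), t) == pytest.approx(1.0)
        assert gaussian_kernel(np.array(t * np.sqrt(2.0)), t) == pytest.approx(
            np.exp(-1.0)
        )
        assert gaussian_kernel(np.array(200.0), t) < 1e-30

    def test_same_residue_pair_keeps_pw(self):
        model = _grid_structure([1, 2], spacing=0.0)  # both residues coincide
        scores = {"a": 0.0, "b": 1.0, "c": 2.0}
        model = StructureModel(
            {1: np.zeros(3), 2: np.zeros(3), 3: np.array([200.0, 0, 0])}
        )
        pwes = compute_pwes(scores, {"a": 1, "b": 2, "c": 3}, model)
        i, j = pwes.sgrna_ids.index("a"), pwes.sgrna_ids.index("b")
        assert pwes.matrix[i, j] == pytest.approx(pwes.pw[i, j])

    def test_kernel_limit_t_to_infinity(self):
        rng = np.random.default_rng(3)
        model = _grid_structure(range(1, 7), spacing=20.0)
        scores = {f"s{i}": float(v) for i, v in enumerate(rng.normal(size=6), 1)}
        residues = {f"s{i}": i for i in range(1, 7)}
        pwes = compute_pwes(scores, residues, model, t=1e9)
        np.testing.assert_allclose(pwes.matrix, pwes.pw, atol=1e-12)

    def test_vectorized_matches_double_loop_oracle(self):
        rng = np.random.default_rng(4)
        model = StructureModel(
            {i: rng.normal(0, 20, size=3) for i in range(1, 7)}
        )
        x = rng.normal(size=6)
        scores = {f"s{i}": float(x[i - 1]) for i in range(1, 7)}
        residues = {f"s{i}": i for i in range(1, 7)}
        t = 16.0
        pwes = compute_pwes(scores, residues, model, t=t)
        # explicit double loops
        sums = [x[i] + x[j] for i in range(6) for j in range(i + 1, 6)]
        x_bar = np.mean(sums)
        s_x = np.std(sums)
        for i in range(6):
            for j in range(6):
                if i == j:
                    assert pwes.matrix[i, j] == 0.0
                    continue
                d = np.linalg.norm(model.centroids[i + 1] - model.centroids[j + 1])
                expect = np.tanh((x[i] + x[j] - x_bar) / s_x) * np.exp(
                    -(d**2) / (2 * t * t)
                )
                assert pwes.matrix[i, j] == pytest.approx(expect, abs=1e-12)

    def test_unresolved_sgrnas_dropped(self):
        model = _grid_structure([1, 2, 3])
        scores = {"a": 1.0, "b": 2.0, "c": 0.5, "d": -1.0}
        pwes = compute_pwes(scores, {"a": 1, "b": 2, "c": 99, "d": 3}, model)
        assert pwes.dropped == ["c"] and pwes.sgrna_ids == ["a", "b", "d"]


class TestStructureIO:
    def test_centroid_is_mean_of_atoms(self, tmp_path):
        pdb = (
            "ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N\n"
            "ATOM      2  CA  ALA A   1       2.000   0.000   0.000  1.00  0.00           C\n"
            "END\n"
        )
        path = tmp_path / "two_atoms.pdb"
        path.write_text(pdb)
        model = load_structure_centroids(path, "A")
        np.testing.assert_allclose(model.centroids[1], [1.0, 0.0, 0.0], atol=1e-6)

    def test_roundtrip_through_synthetic_writer(self, tmp_path):
        spec = StructureSimSpec(n_residues=50, planted_residues=(5, 25, 45))
        text, centers = simulate_structure(spec, seed=9)
        path = tmp_path / "synthetic.pdb"
        path.write_text(text)
        model = load_structure_centroids(path, "A")
        assert set(model.centroids) == set(centers)
        for r, c in centers.items():
            assert np.linalg.norm(model.centroids[r] - c) < 1e-3

    def test_missing_chain_errors(self, tmp_path):
        path = tmp_path / "x.pdb"
        path.write_text(simulate_structure(StructureSimSpec(n_residues=5), seed=0)[0])
        with pytest.raises(ValueError, match="chain"):
            load_structure_centroids(path, "B")


class TestClustering:
    def _block_pwes(self, seed=0):
        """Two spatially separated, score-enriched blocks."""
        rng = np.random.default_rng(seed)
        model = StructureModel(
            {
                **{i: np.array([0.0, 0, 0]) + rng.normal(0, 2, 3) for i in range(1, 6)},
                **{i: np.array([300.0, 0, 0]) + rng.normal(0, 2, 3) for i in range(6, 11)},
            }
        )
        scores = {f"s{i}": (3.0 if i < 6 else -2.0) + rng.normal(0, 0.1) for i in range(1, 11)}
        residues = {f"s{i}": i for i in range(1, 11)}
        return compute_pwes(scores, residues, model)

    def test_two_block_recovery(self):
        pwes = self._block_pwes()
        clusters = cluster_pwes(pwes, 2)
        members = {frozenset(c.members) for c in clusters}
        assert members == {
            frozenset(f"s{i}" for i in range(1, 6)),
            frozenset(f"s{i}" for i in range(6, 11)),
        }
        # cluster 1 has the higher mean score
        assert clusters[0].mean_score > clusters[1].mean_score

    def test_singletons_when_k_equals_n(self):
        pwes = self._block_pwes()
        clusters = cluster_pwes(pwes, 10)
        assert all(len(c.members) == 1 for c in clusters)
        means = [c.mean_score for c in clusters]
        assert means == sorted(means, reverse=True)

    def test_input_order_invariance(self):
        pwes = self._block_pwes()
        # same geometry as _block_pwes (same rng stream for the centroids)
        rng = np.random.default_rng(0)
        model = StructureModel(
            {
                **{i: np.array([0.0, 0, 0]) + rng.normal(0, 2, 3) for i in range(1, 6)},
                **{i: np.array([300.0, 0, 0]) + rng.normal(0, 2, 3) for i in range(6, 11)},
            }
        )
        ids = [f"s{i}" for i in range(10, 0, -1)]  # reversed input order
        scores = {s: float(pwes.scores[pwes.sgrna_ids.index(s)]) for s in ids}
        residues = {s: int(s[1:]) for s in ids}
        pw2 = compute_pwes(scores, residues, model)
        a = {frozenset(c.members) for c in cluster_pwes(pwes, 2)}
        b = {frozenset(c.members) for c in cluster_pwes(pw2, 2)}
        assert a == b

    def test_n_clusters_bounds(self):
        pwes = self._block_pwes()
        with pytest.raises(ValueError):
            cluster_pwes(pwes, 0)
        with pytest.raises(ValueError):
            cluster_pwes(pwes, 11)


class TestSignificance:
    def test_singleton_cluster_p_one(self):
        pwes = TestClustering()._block_pwes()
        clusters = cluster_pwes(pwes, 10)
        assert all(c.summed_pwes == 0.0 for c in clusters)
        assert cluster_significance(clusters[0], pwes, n_perm=50, seed=0) == 1.0

    def test_tight_enriched_cluster_significant(self):
        rng = np.random.default_rng(12)
        n = 30
        centroids = {i: rng.uniform(0, 150, size=3) for i in range(1, n + 1)}
        tight = list(range(1, 7))
        center = np.array([75.0, 75.0, 75.0])
        for k, r in enumerate(tight):
            centroids[r] = center + rng.normal(0, 2.0, size=3)
        model = StructureModel(centroids)
        scores = {f"s{i}": (3.0 if i in tight else rng.normal()) for i in range(1, n + 1)}
        residues = {f"s{i}": i for i in range(1, n + 1)}
        pwes = compute_pwes(scores, residues, model)
        from crisprscan.spatial_hotspots import SpatialCluster

        members = [f"s{i}" for i in tight]
        idx = np.array([pwes.sgrna_ids.index(m) for m in members])
        target = SpatialCluster(
            cluster_id=1,
            members=members,
            mean_score=3.0,
            summed_pwes=summed_abs_pwes(pwes.matrix, idx),
        )
        p = cluster_significance(target, pwes, n_perm=2000, seed=1)
        assert p < 0.01

    def test_summed_abs_pwes_oracle(self):
        pwes = TestClustering()._block_pwes()
        idx = np.array([0, 2, 4])
        manual = sum(
            abs(pwes.matrix[i, j]) for a, i in enumerate(idx) for j in idx[a + 1 :]
        )
        assert summed_abs_pwes(pwes.matrix, idx) == pytest.approx(manual, abs=1e-12)


def test_spatial_scan_end_to_end(tmp_path):
    spec = StructureSimSpec(n_residues=120, planted_residues=(10, 60, 110))
    text, _ = simulate_structure(spec, seed=5)
    path = tmp_path / "s.pdb"
    path.write_text(text)
    model = load_structure_centroids(path, "A")
    rng = np.random.default_rng(6)
    ids = [f"s{i}" for i in range(1, 121, 4)]
    residues = {s: int(s[1:]) for s in ids}
    scores = {s: float(rng.normal()) for s in ids}
    for planted in (10, 60, 110):
        if f"s{planted}" not in scores:
            ids.append(f"s{planted}")
            residues[f"s{planted}"] = planted
    for planted in (10, 60, 110):
        scores[f"s{planted}"] = 3.0
    pwes, clusters = spatial_scan(scores, residues, model, n_clusters=6, n_perm=500, seed=7)
    assert all(c.p_value is not None for c in clusters)
    assert {m for c in clusters for m in c.members} == set(pwes.sgrna_ids)
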