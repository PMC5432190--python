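import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

from phyc import (
    ClassicalMDS,
    binarize_multifurcations,
    build_reference,
    cluster_diversity_summary,
    cmds_embed,
    diversity_curve,
    parse_newick,
    register_set,
)


class TestCmdsEmbed:
    def test_two_points_closed_form(self):
        S = np.array([[0.0, 3.0], [3.0, 0.0]])
        emb = cmds_embed(S, dim=1)
        np.testing.assert_allclose(np.sort(emb.coordinates[:, 0]), [-1.5, 1.5], atol=1e-12)

    def test_planar_configuration_reconstructed(self, rng):
        pts = rng.random((12, 2)) * 5
        S = squareform(pdist(pts))
        emb = cmds_embed(S, dim=2)
        np.testing.assert_allclose(
            squareform(pdist(emb.coordinates)), S, atol=1e-8
        )

    def test_duplicate_rows_coincide(self):
        S = np.array(
            [[0.0, 0.0, 1.0], [0.0, 0.0, 1.0], [1.0, 1.0, 0.0]]
        )
        emb = cmds_embed(S, dim=1)
        np.testing.assert_allclose(emb.coordinates[0], emb.coordinates[1], atol=1e-10)

    def test_registered_cohort_distances_reconstructed(self, random_trees):
        # registered trees are genuinely Euclidean, so a full-rank embedding
        # must reproduce every pairwise distance
        Z = register_set(random_trees).Z
        S = squareform(pdist(Z))
        emb = cmds_embed(S, dim=Z.shape[0] - 1)
        np.testing.assert_allclose(
            squareform(pdist(emb.coordinates)), S, atol=1e-8
        )

    def test_centered_and_sorted(self, rng):
        S = squareform(pdist(rng.random((8, 3))))
        emb = cmds_embed(S, dim=2)
        np.testing.assert_allclose(emb.coordinates.mean(axis=0), 0, atol=1e-10)
        assert (np.diff(emb.eigenvalues) <= 1e-10).all()
        assert 0 < emb.goodness <= 1

    def test_pad_warning_when_rank_deficient(self):
        # three collinear points have a rank-1 configuration
        S = np.abs(np.subtract.outer([0.0, 1.0, 2.0], [0.0, 1.0, 2.0]))
        with pytest.warns(UserWarning, match="padding"):
            cmds_embed(S, dim=2)

    @pytest.mark.parametrize("bad", ["asym", "diag", "dim"])
    def test_input_validation(self, bad, rng):
        S = squareform(pdist(rng.random((5, 2))))
        if bad == "asym":
            S[0, 1] += 1
        elif bad == "diag":
            S[2, 2] = 1.0
        with pytest.raises(ValueError):
            cmds_embed(S, dim=10 if bad == "dim" else 2)

    def test_estimator_api(self, rng):
        S = squareform(pdist(rng.random((9, 3))))
        model = ClassicalMDS(n_components=2)
        coords = model.fit_transform(S)
        assert coords.shape == (9, 2)
        np.testing.assert_array_equal(coords, model.embedding_)


class TestDiversityCurve:
    def test_trunk_fraction_jump(self):
        tree = parse_newick("((a:3,b:4)f:3);")  # trunk 30% of 10 SSNVs
        Z = register_set([tree])
        curve = diversity_curve(Z.Z[0], reference=Z.reference)
        assert curve.y_at(0.3) == 2
        assert curve.y_at(0.29) == 1
        assert curve.trunk_fraction == pytest.approx(0.3)

    def test_worked_vector_example(self):
        ref = build_reference(2)
        curve = diversity_curve(np.array([0.5, 0, 1 / 3, 1 / 6, 0, 0]), reference=ref)
        assert [(round(x, 6), y) for x, y in curve.breakpoints] == [
            (0.5, 2),
            (round(2 / 3, 6), 3),
            (round(5 / 6, 6), 4),
        ]

    def test_full_accumulation_counts_all_subclones(self, random_trees):
        for tree in random_trees:
            total = tree.total_length
            normalized = type(tree)(
                root_id=tree.root_id,
                parent_of=dict(tree.parent_of),
                edge_length_of={k: v / total for k, v in tree.edge_length_of.items()},
                label=tree.label,
            )
            curve = diversity_curve(normalized)
            assert curve.y_at(1.0) == 1 + len(tree.parent_of)

    def test_non_decreasing_and_increment_sum(self, random_trees):
        tree = random_trees[0]
        total = tree.total_length
        normalized = type(tree)(
            root_id=tree.root_id,
            parent_of=dict(tree.parent_of),
            edge_length_of={k: v / total for k, v in tree.edge_length_of.items()},
        )
        curve = diversity_curve(normalized)
        ys = [y for _, y in curve.breakpoints]
        assert all(b > a for a, b in zip(ys, ys[1:]))
        assert ys[-1] - 1 == len(tree.parent_of)

    def test_unnormalized_input_warns(self):
        with pytest.warns(UserWarning, match="normaliz"):
            curve = diversity_curve(parse_newick("((a:3,b:4)f:3);"))
        assert curve.trunk_fraction == pytest.approx(0.3)

    def test_spine_nodes_not_counted_as_clones(self):
        tree = parse_newick("((a:1,b:1,c:1,d:1)f:6);")  # trunk 0.6, star below
        bt = binarize_multifurcations(tree)
        scaled = type(bt)(
            root_id=bt.root_id,
            parent_of=dict(bt.parent_of),
            edge_length_of={k: v / 10 for k, v in bt.edge_length_of.items()},
            spine_of=dict(bt.spine_of),
        )
        curve = diversity_curve(scaled)
        # 5 original non-root nodes, not 7 (two spine artifacts excluded)
        assert curve.y_at(1.0) == 6
        assert curve.y_at(0.6) == 2

    def test_tie_merging_single_step(self):
        ref = build_reference(2)
        curve = diversity_curve(np.array([0.5, 0, 0.25, 0.25, 0, 0]), reference=ref)
        assert curve.breakpoints == [(0.5, 2), (0.75, 4)]


class TestClusterDiversitySummary:
    def _curve(self, trunk):
        tree = parse_newick(f"((a:{(1 - trunk) / 2:g},b:{(1 - trunk) / 2:g})f:{trunk:g});")
        return diversity_curve(tree)

    def test_uniform_cluster_first_expansion(self):
        curves = [self._curve(0.6) for _ in range(3)]
        summary = cluster_diversity_summary(curves, [1, 1, 1])
        assert summary.median_first_expansion[1] == pytest.approx(0.6)

    def test_median_across_clusters(self):
        curves = [self._curve(x) for x in (0.6, 0.1, 0.2)]
        summary = cluster_diversity_summary(curves, [1, 2, 2])
        assert summary.median_first_expansion[1] == pytest.approx(0.6)
        assert summary.median_first_expansion[2] == pytest.approx(0.15)

    def test_no_empty_cluster_emitted(self):
        curves = [self._curve(0.5), self._curve(0.4)]
        summary = cluster_diversity_summary(curves, [3, 3])
        assert set(summary.curves_by_cluster) == {3}

    def test_label_mismatch_error(self):
        with pytest.raises(ValueError):
            cluster_diversity_summary([self._curve(0.5)], [1, 2])

    def test_frame_output(self):
        curves = [self._curve(x) for x in (0.6, 0.2)]
        frame = cluster_diversity_summary(curves, [1, 2]).to_frame()
        assert list(frame.columns) == ["label", "cluster", "trunk_fraction", "n_clones_total"]
        assert len(frame) == 2
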