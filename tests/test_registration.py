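import numpy as np
import pytest
from sklearn.base import clone

from phyc import (
    TreeRegistration,
    binarize_multifurcations,
    build_reference,
    canonical_child_order,
    normalize_lengths,
    parse_newick,
    register,
    register_set,
)

from conftest import make_random_tree


class TestReferenceTree:
    @pytest.mark.parametrize("depth, m", [(1, 2), (2, 6), (3, 14), (4, 30), (5, 62), (6, 126)])
    def test_edge_count_formula(self, depth, m):
        assert build_reference(depth).n_edges == m == 2 * (2**depth - 1)

    def test_invalid_depth(self):
        with pytest.raises(ValueError):
            build_reference(0)

    def test_level_order_indexing(self):
        ref = build_reference(3)
        assert ref.parent_edge(1) is None and ref.parent_edge(2) is None
        assert ref.child_edges(1) == (3, 4)
        assert ref.parent_edge(4) == 1 and ref.parent_edge(6) == 2
        assert ref.child_edges(3) == (7, 8)
        assert ref.child_edges(7) is None  # deepest level
        assert ref.child_edges(14) is None
        assert ref.path_to_root(13) == [13, 6, 2]


class TestCanonicalChildOrder:
    def test_deeper_subtree_first(self):
        t = parse_newick("((a:5,(y:1,(x:1)z:1)b:1)f:1);")
        bt = binarize_multifurcations(t)
        assert canonical_child_order(bt, "f")[0] == "b"  # depth 3 beats depth 1

    def test_edge_length_breaks_depth_ties(self):
        t = parse_newick("((a:2,b:5)f:1);")
        assert canonical_child_order(t, "f") == ["b", "a"]

    def test_identical_subtrees_keep_input_order(self):
        t = parse_newick("((a:1,b:1)f:1);")
        assert canonical_child_order(t, "f") == ["a", "b"]


class TestRegister:
    def test_trunk_only(self):
        bt = binarize_multifurcations(parse_newick("(f:3);"))
        rt = register(bt, build_reference(1))
        assert rt.z.tolist() == [3.0, 0.0]
        assert rt.mapped == frozenset({1})

    def test_worked_example_prenormalization(self):
        # root -> f(3) -> {a(1), b(2)}: b maps first (longer edge)
        bt = binarize_multifurcations(parse_newick("((a:1,b:2)f:3);"))
        rt = register(bt, build_reference(2))
        assert rt.z.tolist() == [3.0, 0.0, 2.0, 1.0, 0.0, 0.0]

    def test_identical_topologies_same_mapped_set(self):
        a = binarize_multifurcations(parse_newick("((a:1,b:2)f:3);"))
        b = binarize_multifurcations(parse_newick("((p:10,q:20)g:30);"))
        ref = build_reference(2)
        assert register(a, ref).mapped == register(b, ref).mapped

    def test_too_deep_tree_rejected(self):
        bt = binarize_multifurcations(parse_newick("((a:1,b:2)f:3);"))
        with pytest.raises(ValueError, match="rebuild the reference"):
            register(bt, build_reference(1))


class TestNormalize:
    def test_worked_example(self):
        bt = binarize_multifurcations(parse_newick("((a:1,b:2)f:3);"))
        rt = normalize_lengths(register(bt, build_reference(2)))
        np.testing.assert_allclose(rt.z, [0.5, 0, 1 / 3, 1 / 6, 0, 0])

    def test_idempotent(self):
        bt = binarize_multifurcations(parse_newick("((a:1,b:2)f:3);"))
        once = normalize_lengths(register(bt, build_reference(2)))
        twice = normalize_lengths(once)
        np.testing.assert_array_equal(once.z, twice.z)

    def test_single_edge_becomes_one(self):
        bt = binarize_multifurcations(parse_newick("(f:7);"))
        rt = normalize_lengths(register(bt, build_reference(1)))
        assert rt.z.tolist() == [1.0, 0.0]


class TestRegisterSet:
    def test_single_tree_row_sums_one(self):
        tsm = register_set([parse_newick("((a:1,b:2)f:3);")])
        assert tsm.Z.shape[0] == 1
        assert tsm.Z.sum() == pytest.approx(1.0)

    def test_shared_depth_across_cohort(self):
        tsm = register_set([parse_newick("(f:1);"), parse_newick("((a:1,b:1)f:1);")])
        assert tsm.reference.depth == 2
        assert tsm.Z.shape == (2, 6)

    def test_union_depth_when_cohorts_combined(self):
        shallow = [parse_newick("(f:1);")]
        deep = [parse_newick("(((c:1)a:1,b:1)f:1);")]
        alone = register_set(shallow)
        joint = register_set(shallow + deep)
        assert alone.reference.depth == 1
        assert joint.reference.depth == 3
        assert joint.Z.shape[1] == 14

    def test_row_sums_and_nonnegativity(self, random_trees):
        tsm = register_set(random_trees)
        np.testing.assert_allclose(tsm.Z.sum(axis=1), 1.0, atol=1e-12)
        assert (tsm.Z >= 0).all()

    def test_sibling_permutation_invariance(self):
        a = register_set([parse_newick("((a:1,b:2)f:3);")]).Z
        b = register_set([parse_newick("((b:2,a:1)f:3);")]).Z
        np.testing.assert_array_equal(a, b)

    def test_scale_invariance(self, rng):
        for _ in range(20):
            t = make_random_tree(rng)
            c = float(rng.uniform(0.1, 50))
            scaled = type(t)(
                root_id=t.root_id,
                parent_of=dict(t.parent_of),
                edge_length_of={k: v * c for k, v in t.edge_length_of.items()},
                label=t.label,
            )
            np.testing.assert_allclose(
                register_set([t]).Z, register_set([scaled]).Z, atol=1e-12
            )

    def test_mapped_set_connected_rooted(self, random_trees):
        tsm = register_set(random_trees)
        for mapped in tsm.mapped_sets:
            assert 1 in mapped
            for k in mapped:
                parent = tsm.reference.parent_edge(k)
                assert parent is None or parent in mapped

    def test_failure_names_offending_tree(self):
        good = parse_newick("((a:1,b:1)f:1);", label="ok")
        bad = parse_newick("(((x:1)c:1)f:1);", label="bad_tree")  # depth 3
        with pytest.raises(ValueError, match="bad_tree"):
            register_set([good, bad], depth=2)

    def test_empty_cohort_error(self):
        with pytest.raises(ValueError):
            register_set([])


class TestTreeRegistrationEstimator:
    def test_fit_transform_matches_register_set(self, random_trees):
        est = TreeRegistration()
        Z = est.fit_transform(random_trees)
        np.testing.assert_array_equal(Z, register_set(random_trees).Z)
        assert est.n_features_out_ == Z.shape[1] == 2 * (2**est.d_max_ - 1)

    def test_sklearn_clone_and_params(self):
        est = TreeRegistration(depth=4, normalize=False)
        cloned = clone(est)
        assert cloned.get_params() == {"depth": 4, "normalize": False}

    def test_feature_names(self, random_trees):
        est = TreeRegistration().fit(random_trees)
        names = est.get_feature_names_out()
        assert names[0] == "e1" and len(names) == est.n_features_out_

    def test_transform_before_fit_raises(self, random_trees):
        with pytest.raises(RuntimeError):
            TreeRegistration().transform(random_trees)

    def test_explicit_depth_smaller_than_cohort_rejected(self):
        deep = [parse_newick("(((c:1)a:1,b:1)f:1);")]
        with pytest.raises(ValueError):
            TreeRegistration(depth=2).fit(deep)
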