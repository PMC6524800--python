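"""Core distances, matrix normalization, and Fitch-Margoliash fitting."""

import io

import numpy as np
import pytest
from skbio.tree import TreeNode

from corecluster import (
    build_distance_matrix,
    build_hierarchy,
    fitch_margoliash_tree,
    pair_core_distance,
    write_newick,
)
from corecluster.distance_tree import DistanceMatrix, read_newick, wls_objective

from conftest import make_trace_model, perturbed_copy


def _core_of(models):
    return build_hierarchy(models).payload


def rigid_copy(model, seed, model_id):
    from scipy.spatial.transform import Rotation

    from corecluster.structure_io import ResidueRecord, StructureModel

    rng = np.random.default_rng(seed)
    r = Rotation.from_rotvec(rng.uniform(-2, 2, 3)).as_matrix()
    t = rng.uniform(-20, 20, 3)
    xyz = model.ca_coords @ r.T + t
    return StructureModel(
        model_id,
        [
            ResidueRecord("A", rec.res_seq, rec.icode, rec.aa, tuple(xyz[i]))
            for i, rec in enumerate(model.residues)
        ],
    )


class TestPairCoreDistance:
    def test_identical_members_zero(self):
        a = make_trace_model(40, seed=1, model_id="a")
        b = perturbed_copy(a, 0.0, seed=0, model_id="b")
        c = perturbed_copy(a, 0.3, seed=1, model_id="c")
        core = _core_of([a, b, c])
        assert pair_core_distance(core, "a", "b") == pytest.approx(0.0, abs=1e-9)
        assert pair_core_distance(core, "a", "a") == 0.0

    def test_rigid_motion_removed(self):
        a = make_trace_model(40, seed=2, model_id="a")
        b = rigid_copy(a, seed=5, model_id="b")
        c = perturbed_copy(a, 0.3, seed=2, model_id="c")
        core = _core_of([a, b, c])
        assert pair_core_distance(core, "a", "b") == pytest.approx(0.0, abs=1e-7)

    def test_matches_hand_computation(self):
        """Spreadsheet-style oracle over the core columns of one pair."""
        from corecluster.distance_tree import _property_dissimilarity
        from corecluster.pairwise_align import as_view, kabsch_superpose

        a = make_trace_model(30, seed=3, model_id="a")
        b = perturbed_copy(a, 0.5, seed=3, model_id="b")
        c = perturbed_copy(a, 0.5, seed=4, model_id="c")
        core = _core_of([a, b, c])
        ia, ib = core.col_index["a"], core.col_index["b"]
        xa, xb = a.ca_coords[ia], b.ca_coords[ib]
        sup = kabsch_superpose(xa, xb)
        dev = np.mean(np.linalg.norm(xa - sup.apply(xb), axis=1))
        prop = _property_dissimilarity(as_view(a), as_view(b), ia, ib, sup.rotation)
        expected = 2.0 * dev + 0.5 * prop
        got = pair_core_distance(core, "a", "b", weights=(2.0, 0.5))
        assert got == pytest.approx(expected, abs=1e-12)

    def test_symmetric_and_nonnegative(self):
        a = make_trace_model(35, seed=4, model_id="a")
        b = perturbed_copy(a, 0.4, seed=5, model_id="b")
        c = perturbed_copy(a, 0.6, seed=6, model_id="c")
        core = _core_of([a, b, c])
        for x in "abc":
            for y in "abc":
                dxy = pair_core_distance(core, x, y)
                assert dxy >= 0
                assert dxy == pytest.approx(pair_core_distance(core, y, x), abs=1e-9)

    def test_unknown_member_is_an_error(self):
        a = make_trace_model(30, seed=5, model_id="a")
        b = perturbed_copy(a, 0.2, seed=7, model_id="b")
        core = build_hierarchy([a, b]).payload
        with pytest.raises(KeyError):
            pair_core_distance(core, "a", "zz")


class TestBuildDistanceMatrix:
    def test_identical_members_flagged_unnormalized(self):
        a = make_trace_model(30, seed=6, model_id="a")
        b = perturbed_copy(a, 0.0, seed=0, model_id="b")
        c = perturbed_copy(a, 0.0, seed=0, model_id="c")
        core = _core_of([a, b, c])
        with pytest.warns(UserWarning, match="un-normalized"):
            dm = build_distance_matrix(core)
        assert not dm.normalized
        assert np.all(dm.data == 0)

    def test_max_entry_is_one(self, small_clan):
        models, _ = small_clan
        dm = build_distance_matrix(_core_of(models))
        assert dm.data.max() == pytest.approx(1.0)
        assert np.allclose(dm.data, dm.data.T)
        assert np.all(np.diag(dm.data) == 0)

    def test_two_family_separation(self):
        from corecluster import SyntheticSpec, generate_clan

        for seed in range(1, 6):
            models, truth = generate_clan(
                SyntheticSpec(seed=seed, n_families=2, members_per_family=3,
                              core_length=40, n_decorations=1)
            )
            dm = build_distance_matrix(_core_of(models))
            fam = truth.family_label
            within = [
                dm[(x, y)]
                for x in dm.labels
                for y in dm.labels
                if x < y and fam[x] == fam[y]
            ]
            between = [
                dm[(x, y)]
                for x in dm.labels
                for y in dm.labels
                if x < y and fam[x] != fam[y]
            ]
            assert max(within) < min(between)

    def test_normalization_idempotent(self, small_clan):
        models, _ = small_clan
        dm = build_distance_matrix(_core_of(models))
        renorm = dm.data / dm.data.max()
        assert np.allclose(renorm, dm.data)


def random_additive_tree(n, rng):
    """A random unrooted binary tree with branch lengths in [0.1, 1]."""
    nodes = [TreeNode(name=f"T{i}") for i in range(n)]
    for nd in nodes:
        nd.length = rng.uniform(0.1, 1.0)
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        parent = TreeNode(children=[nodes[i], nodes[j]])
        parent.length = rng.uniform(0.1, 1.0)
        nodes = [nd for k, nd in enumerate(nodes) if k not in (i, j)] + [parent]
    root = TreeNode(children=nodes)
    labels = sorted(t.name for t in root.tips())
    arr = np.zeros((len(labels), len(labels)))
    tips = {t.name: t for t in root.tips()}
    for i, x in enumerate(labels):
        for j, y in enumerate(labels):
            if i < j:
                arr[i, j] = arr[j, i] = tips[x].distance(tips[y])
    return labels, arr, root


def _bipartitions(tree):
    leaves = frozenset(t.name for t in tree.tips())
    out = set()
    for node in tree.postorder(include_self=False):
        if node.children:
            below = frozenset(t.name for t in node.tips())
            if 1 < len(below) < len(leaves) - 1:
                out.add(min(below, leaves - below, key=sorted))
    return out


class TestFitchMargoliash:
    def test_three_taxon_closed_form(self):
        m = DistanceMatrix(list("ABC"), np.array(
            [[0, 2, 2], [2, 0, 2], [2, 2, 0]], float), normalized=False)
        tree = fitch_margoliash_tree(m)
        lengths = {t.name: t.length for t in tree.tips()}
        # a = (d_AB + d_AC - d_BC) / 2 = 1 for every taxon
        for lab in "ABC":
            assert lengths[lab] == pytest.approx(1.0, abs=1e-9)

    def test_four_taxon_additive_exact(self):
        # distances generated from ((A:1,B:2):1,(C:3,D:1))
        labels = list("ABCD")
        arr = np.array(
            [[0, 3, 5, 3], [3, 0, 6, 4], [5, 6, 0, 4], [3, 4, 4, 0]], float
        )
        m = DistanceMatrix(labels, arr, normalized=False)
        tree = fitch_margoliash_tree(m)
        assert wls_objective(tree, m) < 1e-10
        assert _bipartitions(tree) == {frozenset("AB")}
        tips = {t.name: t for t in tree.tips()}
        for x in labels:
            for y in labels:
                if x < y:
                    assert tips[x].distance(tips[y]) == pytest.approx(
                        m[(x, y)], abs=1e-6
                    )

    def test_random_additive_matrices_recovered(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            n = int(rng.integers(4, 7))
            labels, arr, true_tree = random_additive_tree(n, rng)
            m = DistanceMatrix(labels, arr, normalized=False)
            tree = fitch_margoliash_tree(m)
            assert wls_objective(tree, m) < 1e-10
            assert _bipartitions(tree) == _bipartitions(true_tree)
            tips = {t.name: t for t in tree.tips()}
            for i, x in enumerate(labels):
                for j, y in enumerate(labels):
                    if i < j:
                        assert abs(tips[x].distance(tips[y]) - arr[i, j]) < 1e-6

    def test_branch_lengths_nonnegative_on_noisy_matrix(self):
        rng = np.random.default_rng(8)
        labels, arr, _ = random_additive_tree(6, rng)
        noisy = arr + rng.uniform(0, 0.2, arr.shape)
        noisy = (noisy + noisy.T) / 2
        np.fill_diagonal(noisy, 0.0)
        m = DistanceMatrix(labels, noisy, normalized=False)
        tree = fitch_margoliash_tree(m)
        assert all(
            (nd.length or 0.0) >= 0.0 for nd in tree.preorder(include_self=False)
        )

    def test_invalid_matrix_is_an_error(self):
        with pytest.raises(ValueError):
            DistanceMatrix(list("AB"), np.array([[0, 1], [2, 0]], float))
        with pytest.raises(ValueError):
            fitch_margoliash_tree(
                DistanceMatrix(list("AB"), np.array([[0, 1], [1, 0]], float))
            )


class TestNewick:
    def test_two_leaf_form(self, tmp_path):
        tree = TreeNode.read(io.StringIO("(A:1.0,B:1.0);"))
        path = tmp_path / "t.nwk"
        write_newick(tree, path)
        text = path.read_text().strip()
        assert text.startswith("(") and text.endswith(";")
        assert "A:1.0" in text and "B:1.0" in text

    def test_round_trip_topology_and_lengths(self, tmp_path):
        rng = np.random.default_rng(9)
        labels, arr, _ = random_additive_tree(5, rng)
        tree = fitch_margoliash_tree(
            DistanceMatrix(labels, arr, normalized=False)
        )
        path = tmp_path / "t.nwk"
        write_newick(tree, path)
        back = read_newick(path)
        assert _bipartitions(back) == _bipartitions(tree)
        t0 = {t.name: t for t in tree.tips()}
        t1 = {t.name: t for t in back.tips()}
        for x in labels:
            for y in labels:
                if x < y:
                    assert t1[x].distance(t1[y]) == pytest.approx(
                        t0[x].distance(t0[y]), abs=1e-9
                    )

    def test_support_label_round_trips(self, tmp_path):
        tree = TreeNode.read(io.StringIO("((A:1,B:1)0.85:0.5,C:1,D:1);"))
        path = tmp_path / "s.nwk"
        write_newick(tree, path)
        back = read_newick(path)
        internal = [
            n for n in back.postorder(include_self=False) if n.children
        ]
        assert any(n.name == "0.85" for n in internal)
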