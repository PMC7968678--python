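from itertools import combinations

import numpy as np
import pytest
from skbio import DistanceMatrix

from neighborgo.conservation import (
    QuantileBins,
    build_distance_matrix,
    build_score_table,
    build_tree,
    discretize,
    fit_quantile_bins,
    genome_distance,
    phylo_score,
    supporting_genomes,
)
from neighborgo.genome_io import Gene, GenomeCollection, SimilarityHit, ValidationError
from neighborgo.homology import cluster_proteins
from neighborgo.neighborhood import call_neighborhoods

from _oracles import steiner_length_by_paths


class TestGenomeDistance:
    def test_identical_sets_zero(self):
        assert genome_distance({"a", "b"}, {"a", "b"}) == 0.0

    def test_disjoint_sets_one(self):
        assert genome_distance({"a"}, {"b"}) == 1.0

    def test_formula(self):
        assert genome_distance({"1", "2"}, {"2", "3"}) == pytest.approx(2 / 3)

    def test_both_empty_rejected(self):
        with pytest.raises(ValidationError):
            genome_distance(set(), set())


def tiny_collection(n_genomes, families_per_genome):
    """One gene per family per genome; families_per_genome maps genome index
    to a list of family indices."""
    genes = []
    for gi in range(n_genomes):
        pos = 0
        for fam in families_per_genome[gi]:
            pid = f"G{gi}|F{fam}"
            genes.append(Gene(pid, pid, f"G{gi}", "c1", pos, pos + 500, "+"))
            pos += 2000
    return GenomeCollection.from_genes(genes)


def family_hits(collection):
    """Link all proteins sharing a family suffix with tiny e-values."""
    by_family = {}
    for pid in collection.protein_ids:
        by_family.setdefault(pid.split("|")[1], []).append(pid)
    hits = []
    for members in by_family.values():
        for a, b in zip(members, members[1:]):
            hits.append(SimilarityHit(a, b, 90.0, 1e-150, 1000.0))
    return hits


class TestDistanceMatrix:
    def test_pair_count_small(self):
        coll = tiny_collection(2, {0: [0, 1], 1: [1, 2]})
        clustering = cluster_proteins(family_hits(coll), coll.protein_ids, 1e-10)
        dm = build_distance_matrix(coll, clustering)
        assert len(dm.condensed_form()) == 1

    def test_duplicate_genomes_zero_distance(self):
        coll = tiny_collection(3, {0: [0, 1], 1: [0, 1], 2: [2, 3]})
        clustering = cluster_proteins(family_hits(coll), coll.protein_ids, 1e-10)
        dm = build_distance_matrix(coll, clustering)
        assert dm["G0", "G1"] == 0.0
        assert dm["G0", "G2"] == 1.0

    def test_metric_properties_on_random_genomes(self):
        rng = np.random.default_rng(8)
        fams = {
            gi: sorted(rng.choice(20, size=int(rng.integers(3, 12)),
                                  replace=False))
            for gi in range(6)
        }
        coll = tiny_collection(6, fams)
        clustering = cluster_proteins(family_hits(coll), coll.protein_ids, 1e-10)
        dm = build_distance_matrix(coll, clustering)
        mat = dm.data
        assert np.allclose(mat, mat.T)
        assert np.allclose(np.diag(mat), 0.0)
        for i, j, k in combinations(range(6), 3):
            assert mat[i, k] <= mat[i, j] + mat[j, k] + 1e-12


class TestBuildTree:
    def test_additive_matrix_reproduced_exactly(self):
        # ultrametric 4-leaf matrix: NJ recovers additive distances
        ids = ["a", "b", "c", "d"]
        mat = np.array(
            [
                [0.0, 0.2, 0.6, 0.6],
                [0.2, 0.0, 0.6, 0.6],
                [0.6, 0.6, 0.0, 0.4],
                [0.6, 0.6, 0.4, 0.0],
            ]
        )
        tree = build_tree(DistanceMatrix(mat, ids=ids))
        tt = tree.tree.tip_tip_distances(ids)
        assert np.allclose(tt.data, mat, atol=1e-12)

    def test_two_genomes_single_edge(self):
        tree = build_tree(DistanceMatrix([[0.0, 0.3], [0.3, 0.0]], ids=["a", "b"]))
        assert tree.total_length == pytest.approx(0.3)
        assert tree.phylogenetic_diversity({"a", "b"}) == pytest.approx(0.3)

    def test_star_matrix_total_length_matches_independent_nj(self):
        """All-equal distances: compare against a dendropy NJ tree."""
        dendropy = pytest.importorskip("dendropy")
        n, d = 5, 0.8
        ids = [f"t{i}" for i in range(n)]
        mat = np.full((n, n), d)
        np.fill_diagonal(mat, 0.0)
        ours = build_tree(DistanceMatrix(mat, ids=ids))
        csv = "," + ",".join(ids) + "\n" + "\n".join(
            ids[i] + "," + ",".join(str(mat[i, j]) for j in range(n))
            for i in range(n)
        )
        pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
            src=__import__("io").StringIO(csv)
        )
        ref = pdm.nj_tree()
        ref_total = sum(
            e.length or 0.0 for e in ref.edges() if e.length is not None
        )
        assert ours.total_length == pytest.approx(ref_total, rel=1e-9)
        # closed form: star tree, every pendant branch d/2
        assert ours.total_length == pytest.approx(n * d / 2)

    def test_negative_lengths_clamped(self):
        # strongly non-additive matrix can induce negative NJ estimates
        ids = ["a", "b", "c", "d"]
        mat = np.array(
            [
                [0.0, 0.1, 0.9, 0.9],
                [0.1, 0.0, 0.05, 0.9],
                [0.9, 0.05, 0.0, 0.1],
                [0.9, 0.9, 0.1, 0.0],
            ]
        )
        tree = build_tree(DistanceMatrix(mat, ids=ids))
        for node in tree.tree.traverse(include_self=False):
            assert (node.length or 0.0) >= 0.0


def random_tree(rng, n_leaves):
    points = rng.random((n_leaves, 5))
    mat = np.sqrt(((points[:, None] - points[None]) ** 2).sum(-1))
    ids = [f"L{i}" for i in range(n_leaves)]
    return build_tree(DistanceMatrix(mat, ids=ids))


class TestPhylogeneticDiversity:
    def test_singleton_and_empty_are_zero(self):
        tree = random_tree(np.random.default_rng(0), 6)
        assert tree.phylogenetic_diversity([]) == 0.0
        assert tree.phylogenetic_diversity(["L0"]) == 0.0

    def test_all_leaves_equals_total_length(self):
        tree = random_tree(np.random.default_rng(1), 8)
        assert tree.phylogenetic_diversity(tree.leaf_names) == pytest.approx(
            tree.total_length
        )

    def test_two_leaves_equals_path_length(self):
        tree = random_tree(np.random.default_rng(2), 7)
        tt = tree.tree.tip_tip_distances(["L0", "L3"])
        assert tree.phylogenetic_diversity({"L0", "L3"}) == pytest.approx(
            tt["L0", "L3"]
        )

    def test_steiner_brute_force_equivalence(self):
        """Split-based PD ≡ union of pairwise paths on random trees."""
        rng = np.random.default_rng(9)
        for _ in range(60):
            n = int(rng.integers(3, 13))
            tree = random_tree(rng, n)
            size = int(rng.integers(2, n + 1))
            subset = set(
                rng.choice(tree.leaf_names, size=size, replace=False)
            )
            expected = steiner_length_by_paths(tree.tree, subset)
            assert tree.phylogenetic_diversity(subset) == pytest.approx(expected)

    def test_monotone_in_supporting_set(self):
        rng = np.random.default_rng(10)
        for _ in range(30):
            tree = random_tree(rng, 10)
            size = int(rng.integers(1, 9))
            subset = set(rng.choice(tree.leaf_names, size=size, replace=False))
            extra = rng.choice(sorted(set(tree.leaf_names) - subset))
            a = tree.phylogenetic_diversity(subset)
            b = tree.phylogenetic_diversity(subset | {extra})
            assert b >= a - 1e-12
            assert b <= tree.total_length + 1e-12


@pytest.fixture(scope="module")
def scenario():
    # families 0 and 1 adjacent in G0 and G1; in G2 only family 0 is
    # present (next to an unrelated family).  Families 5/6 differentiate
    # G0 from G1 so their tree path length is positive.
    genes = []
    for gi, fams in {0: [0, 1, 5], 1: [0, 1, 6], 2: [0, 9]}.items():
        pos = 0
        for fam in fams:
            pid = f"G{gi}|F{fam}"
            genes.append(Gene(pid, pid, f"G{gi}", "c1", pos, pos + 500, "+"))
            pos += 600  # gap 100 -> same neighborhood
    coll = GenomeCollection.from_genes(genes)
    clustering = cluster_proteins(family_hits(coll), coll.protein_ids, 1e-10)
    nbhd = call_neighborhoods(coll)
    tree = build_tree(build_distance_matrix(coll, clustering))
    return coll, clustering, nbhd, tree


class TestPhyloScore:

    def test_supported_pair_scores_path_length(self, scenario):
        coll, clustering, nbhd, tree = scenario
        fam_a = clustering.cluster_of("G0|F0")
        fam_b = clustering.cluster_of("G0|F1")
        support = supporting_genomes(fam_a, fam_b, nbhd, clustering)
        assert support == {"G0", "G1"}
        score = phylo_score(fam_a, fam_b, nbhd, tree, clustering)
        assert score == pytest.approx(tree.phylogenetic_diversity({"G0", "G1"}))

    def test_single_genome_support_scores_zero(self, scenario):
        coll, clustering, nbhd, tree = scenario
        fam_a = clustering.cluster_of("G2|F0")
        fam_c = clustering.cluster_of("G2|F9")
        assert supporting_genomes(fam_a, fam_c, nbhd, clustering) == {"G2"}
        assert phylo_score(fam_a, fam_c, nbhd, tree, clustering) == 0.0

    def test_unknown_cluster_raises(self, scenario):
        _coll, clustering, nbhd, tree = scenario
        with pytest.raises(LookupError):
            phylo_score("nope", "nada", nbhd, tree, clustering)

    def test_score_table_matches_pointwise_scores(self, scenario):
        _coll, clustering, nbhd, tree = scenario
        table = build_score_table(nbhd, clustering, tree)
        for (focal, nb), raw in table.scores.items():
            assert raw == pytest.approx(
                phylo_score(focal, nb, nbhd, tree, clustering)
            )
            assert (raw == 0.0) == (len(table.supporting[(focal, nb)]) <= 1)


class TestQuantileBins:
    def test_tertiles_of_one_to_nine(self):
        bins = fit_quantile_bins([0.0, 0.0] + list(range(1, 10)))
        # linear-interpolation tertiles of {1..9}
        q1, q2 = np.quantile(np.arange(1.0, 10.0), [1 / 3, 2 / 3])
        assert bins.q1 == pytest.approx(q1)
        assert bins.q2 == pytest.approx(q2)
        assert bins.discretize(4.0) == 2

    def test_zero_always_bin_zero(self):
        bins = fit_quantile_bins(list(range(1, 10)))
        assert bins.discretize(0.0) == 0

    def test_above_training_max_is_bin_three(self):
        bins = fit_quantile_bins(list(range(1, 10)))
        assert bins.discretize(1000.0) == 3

    def test_bin_edges_inclusive_on_the_left_bins(self):
        bins = QuantileBins(q1=1.0, q2=2.0)
        assert [bins.discretize(v) for v in (0.5, 1.0, 1.5, 2.0, 2.5)] == [
            1, 1, 2, 2, 3,
        ]

    def test_degenerate_fallback_warns(self):
        with pytest.warns(UserWarning, match="degenerate"):
            bins = fit_quantile_bins([0.0, 5.0, 5.0])
        assert bins.q1 == bins.q2 == 5.0

    def test_discretize_module_function(self):
        bins = QuantileBins(q1=1.0, q2=2.0)
        assert discretize(1.5, bins) == 2


class TestQuantileBinProperties:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(
        st.lists(st.floats(min_value=0.01, max_value=1e3), min_size=3,
                 max_size=50),
        st.floats(min_value=0.0, max_value=2e3),
        st.floats(min_value=0.0, max_value=2e3),
    )
    @settings(deadline=None, max_examples=60, derandomize=True)
    def test_discretize_monotone_and_bounded(self, scores, raw_a, raw_b):
        import warnings as _warnings

        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            bins = fit_quantile_bins(scores)
        lo, hi = sorted((raw_a, raw_b))
        assert 0 <= bins.discretize(lo) <= bins.discretize(hi) <= 3

    @given(
        st.sets(st.integers(min_value=0, max_value=30), min_size=1),
        st.sets(st.integers(min_value=0, max_value=30), min_size=1),
    )
    @settings(deadline=None, max_examples=100, derandomize=True)
    def test_jaccard_distance_symmetric_and_bounded(self, a, b):
        sa = {str(x) for x in a}
        sb = {str(x) for x in b}
        d = genome_distance(sa, sb)
        assert 0.0 <= d <= 1.0
        assert d == genome_distance(sb, sa)
        assert (d == 0.0) == (sa == sb)
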