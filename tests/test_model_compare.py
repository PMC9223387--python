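"""Reaction-content dissimilarities, linkage, CCC, and clade support."""

import numpy as np
import pandas as pd
import pytest

from finflux.model_compare import (
    DISSIMILARITY_MEASURES,
    LINKAGE_METHODS,
    agglomerate,
    build_reaction_matrix,
    clade_support,
    cophenetic_correlation,
    dendrogram_to_newick,
    reaction_dissimilarity,
)
from finflux.model_core import ModelValidationError


@pytest.fixture()
def binary_matrix():
    return pd.DataFrame(
        [[1, 1, 0, 1, 0], [1, 1, 0, 1, 1], [0, 1, 1, 0, 0], [0, 1, 1, 0, 1]],
        index=["A", "B", "C", "D"],
        columns=[f"r{i}" for i in range(5)],
    )


class TestDissimilarity:
    def test_registry_has_sixteen_measures(self):
        assert len(DISSIMILARITY_MEASURES) == 16

    @pytest.mark.parametrize("measure", DISSIMILARITY_MEASURES)
    def test_symmetry_and_zero_diagonal(self, binary_matrix, measure):
        d = reaction_dissimilarity(binary_matrix, measure)
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0.0)

    @pytest.mark.parametrize(
        "measure", [m for m in DISSIMILARITY_MEASURES if m != "russellrao"]
    )
    def test_identical_rows_distance_zero(self, measure):
        # russellrao is excluded: by definition d(x, x) = (n - c11)/n != 0,
        # so it does not satisfy identity of indiscernibles
        mat = pd.DataFrame([[1, 0, 1, 1], [1, 0, 1, 1], [0, 1, 0, 1]],
                           index=list("XYZ"))
        d = reaction_dissimilarity(mat, measure)
        assert d.loc["X", "Y"] == pytest.approx(0.0, abs=1e-12)

    def test_jaccard_hand_count(self):
        # rows {1,1,0} vs {1,0,1}: intersection 1, union 3
        mat = pd.DataFrame([[1, 1, 0], [1, 0, 1]], index=["a", "b"])
        d = reaction_dissimilarity(mat, "jaccard")
        assert d.loc["a", "b"] == pytest.approx(2.0 / 3.0)

    def test_jaccard_disjoint_rows(self):
        mat = pd.DataFrame([[1, 1, 0, 0], [0, 0, 1, 1]], index=["a", "b"])
        assert reaction_dissimilarity(mat, "jaccard").loc["a", "b"] == 1.0

    def test_kulczynski1_hand_count(self):
        # a=1 shared, b+c=2 mismatches -> distance 2
        mat = pd.DataFrame([[1, 1, 0], [1, 0, 1]], index=["a", "b"])
        d = reaction_dissimilarity(mat, "kulczynski1")
        assert d.loc["a", "b"] == pytest.approx(2.0)

    def test_unknown_measure_lists_registry(self, binary_matrix):
        with pytest.raises(ModelValidationError, match="jaccard"):
            reaction_dissimilarity(binary_matrix, "notametric")


class TestAgglomerate:
    def test_unique_nearest_pair_merges_first_all_methods(self):
        d = pd.DataFrame(
            [[0.0, 0.1, 5.0], [0.1, 0.0, 4.0], [5.0, 4.0, 0.0]],
            index=list("ABC"), columns=list("ABC"),
        )
        for method in LINKAGE_METHODS:
            Z = agglomerate(d, method)
            assert sorted(Z[0, :2].astype(int)) == [0, 1]

    def test_average_linkage_hand_worked(self):
        # AB merge at 1; CD at 2; cross at mean(5, 6, 6.5, 5.5) = 5.75
        d = pd.DataFrame(
            [[0, 1, 5, 6], [1, 0, 6.5, 5.5], [5, 6.5, 0, 2], [6, 5.5, 2, 0]],
            index=list("ABCD"), columns=list("ABCD"), dtype=float,
        )
        Z = agglomerate(d, "average")
        assert Z[0, 2] == pytest.approx(1.0)
        assert Z[1, 2] == pytest.approx(2.0)
        assert Z[2, 2] == pytest.approx(5.75)

    def test_ultrametric_fixpoint(self):
        # cophenetic distances of an ultrametric input reproduce the input
        from scipy.cluster.hierarchy import cophenet
        from scipy.spatial.distance import squareform

        d = pd.DataFrame(
            [[0, 1, 4, 4], [1, 0, 4, 4], [4, 4, 0, 2], [4, 4, 2, 0]],
            index=list("ABCD"), columns=list("ABCD"), dtype=float,
        )
        Z = agglomerate(d, "single")
        assert np.allclose(cophenet(Z), squareform(d.values))

    def test_unknown_method(self):
        d = pd.DataFrame(np.zeros((2, 2)), index=["a", "b"], columns=["a", "b"])
        with pytest.raises(ModelValidationError):
            agglomerate(d, "median-ish")


class TestCopheneticCorrelation:
    def test_ultrametric_gives_one(self):
        d = pd.DataFrame(
            [[0, 1, 4, 4], [1, 0, 4, 4], [4, 4, 0, 2], [4, 4, 2, 0]],
            index=list("ABCD"), columns=list("ABCD"), dtype=float,
        )
        res = cophenetic_correlation(d, agglomerate(d, "average"))
        assert res.ccc == pytest.approx(1.0, abs=1e-12)

    def test_four_leaf_hand_oracle(self):
        # input x and hand-derived cophenetic t for average linkage:
        # AB merge at 1, CD at 2, cross at 5.75; the expected CCC is the
        # Pearson correlation of the two frozen vectors, computed here with
        # the explicit sum formula (independent of the implementation path)
        d = pd.DataFrame(
            [[0, 1, 5, 6], [1, 0, 6.5, 5.5], [5, 6.5, 0, 2], [6, 5.5, 2, 0]],
            index=list("ABCD"), columns=list("ABCD"), dtype=float,
        )
        x = np.array([1.0, 5.0, 6.0, 6.5, 5.5, 2.0])
        t = np.array([1.0, 5.75, 5.75, 5.75, 5.75, 2.0])
        xc, tc = x - x.mean(), t - t.mean()
        expected = (xc * tc).sum() / np.sqrt((xc**2).sum() * (tc**2).sum())
        res = cophenetic_correlation(d, agglomerate(d, "average"))
        assert res.ccc == pytest.approx(expected, abs=1e-12)
        assert res.cophenetic_distances.loc["A", "C"] == pytest.approx(5.75)

    def test_affine_invariance(self):
        rng = np.random.default_rng(9)
        pts = rng.normal(size=(6, 4))
        from scipy.spatial.distance import pdist, squareform

        d = pd.DataFrame(squareform(pdist(pts)), index=list("ABCDEF"),
                         columns=list("ABCDEF"))
        Z = agglomerate(d, "complete")
        base = cophenetic_correlation(d, Z).ccc
        scaled = cophenetic_correlation(3.0 * d + 0.0 * d, Z).ccc
        assert scaled == pytest.approx(base, abs=1e-12)

    def test_degenerate_variance_raises(self):
        d = pd.DataFrame(
            1.0 - np.eye(4), index=list("ABCD"), columns=list("ABCD")
        )
        with pytest.raises(ModelValidationError, match="degenerate"):
            cophenetic_correlation(d, agglomerate(d, "average"))


class TestCladeSupport:
    @pytest.fixture()
    def planted(self):
        # two planted identical pairs plus one outlier
        rng = np.random.default_rng(13)
        a = rng.integers(0, 2, 40)
        b = rng.integers(0, 2, 40)
        c = rng.integers(0, 2, 40)
        return pd.DataFrame(
            [a, a, b, b, c],
            index=["a1", "a2", "b1", "b2", "out"],
            columns=[f"r{i}" for i in range(40)],
        )

    def test_planted_pairs_full_support(self, planted):
        for pair in ({"a1", "a2"}, {"b1", "b2"}):
            frac, hits, total = clade_support(planted, pair)
            assert total == 80
            assert frac == 1.0

    def test_all_models_and_singletons_trivially_clades(self, planted):
        assert clade_support(planted, set(planted.index))[0] == 1.0
        assert clade_support(planted, {"out"})[0] == 1.0

    def test_order_invariance(self, planted):
        frac1 = clade_support(planted, {"a1", "a2"})[0]
        frac2 = clade_support(planted.iloc[::-1], {"a1", "a2"})[0]
        assert frac1 == frac2

    def test_unknown_group_member(self, planted):
        with pytest.raises(ModelValidationError):
            clade_support(planted, {"a1", "nope"})


class TestReactionMatrix:
    def test_toy_models_share_namespace(self, toy_model, aerobe_model):
        mat = build_reaction_matrix({"full": toy_model, "aerobe": aerobe_model})
        # intracellular reactions only, no boundary reactions
        assert not any(rid.startswith("EX_") for rid in mat.columns)
        # LDH separates the two variants
        assert "LDH" in mat.columns
        assert mat.loc["full", "LDH"] == 1
        assert mat.loc["aerobe", "LDH"] == 0
        # no all-zero columns by construction (union of contents)
        assert (mat.sum(axis=0) > 0).all()

    def test_newick_roundtrip_labels(self, binary_matrix):
        d = reaction_dissimilarity(binary_matrix, "jaccard")
        tree = agglomerate(d, "average")
        nwk = dendrogram_to_newick(tree, list(binary_matrix.index))
        assert nwk.endswith(";")
        for name in binary_matrix.index:
            assert name in nwk
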