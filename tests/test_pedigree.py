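"""Divergence-chain inference, clustering and PCA baselines."""

import numpy as np
import pandas as pd
import pytest

from clonehet import genotypes as gt
from clonehet.intersections import (
    ElevatedSet,
    combination_counts,
    condition_on_focal,
    detect_elevated,
    prune_uninformative,
)
from clonehet.pedigree import (
    bootstrap_cluster,
    encode_numeric,
    infer_divergence_chain,
    pca_scores,
    select_representatives,
)

from conftest import matrix_from_classes

R, H, A = gt.REF, gt.HET, gt.ALT


def _elev(samples, count, degree=None):
    s = tuple(sorted(samples))
    return ElevatedSet(s, degree or len(s), count, 10.0, 3.5, 0.0, 0.0, 10, True)


class TestDivergenceChain:
    def test_nested_sets_make_full_chain(self):
        sets = [_elev("ABCDEFGHIJKLMNOP", 40), _elev("ABCDEFGH", 30), _elev("AB", 20)]
        chain = infer_divergence_chain(sets, "A")
        assert [e.samples for e in chain.sets] == [s.samples for s in sets]
        assert chain.residuals == []
        groups = chain.divergence_groups()
        assert groups[-1] == ("A", "B")

    def test_non_nested_tie_keeps_lexicographic_first(self):
        sets = [_elev("ABC", 10), _elev("ABD", 10)]
        chain = infer_divergence_chain(sets, "A")
        assert [e.samples for e in chain.sets] == [("A", "B", "C")]
        assert [e.samples for e in chain.residuals] == [("A", "B", "D")]

    def test_no_focal_set_gives_diagnostic(self):
        chain = infer_divergence_chain([_elev("BC", 5)], "A")
        assert chain.sets == [] and chain.diagnostic is not None
        assert [e.samples for e in chain.residuals] == [("B", "C")]

    def test_higher_count_wins_at_equal_degree(self):
        sets = [_elev("ABCD", 10), _elev("ABC", 3), _elev("ABE", 9, degree=3)]
        chain = infer_divergence_chain(sets, "A")
        # ABE has the higher count at degree 3 and nests in ABCD? it does not:
        # E is outside ABCD, so ABE goes to residuals and ABC extends the chain
        assert [e.samples for e in chain.sets] == [("A", "B", "C", "D"), ("A", "B", "C")]
        assert [e.samples for e in chain.residuals] == [("A", "B", "E")]


class TestEncodeNumeric:
    def test_mapping(self):
        m = matrix_from_classes([[R, H, A], [H, H, H]], "XYZ")
        num = encode_numeric(m)
        assert num.shape == (3, 2)  # samples x loci
        np.testing.assert_allclose(num.loc["X"], [0.0, 0.5])
        np.testing.assert_allclose(num.loc["Z"], [1.0, 0.5])

    def test_other_raises_unless_dropped(self):
        m = matrix_from_classes([[gt.OTHER, H, R], [R, H, A]], "XYZ")
        with pytest.raises(ValueError, match="OTHER"):
            encode_numeric(m)
        assert encode_numeric(m, drop_other=True).shape == (3, 1)


class TestBootstrapCluster:
    def test_two_clades_high_support(self):
        rng = np.random.default_rng(0)
        rows = [[H, H, H, H, R, R, R, R]] * 30 + [[R, R, R, R, H, H, H, H]] * 30
        # sprinkle sample-private noise so resamples vary
        noise = []
        for j in range(8):
            for _ in range(3):
                row = [R] * 8
                row[j] = H
                noise.append(row)
        m = matrix_from_classes(rows + noise, "ABCDEFGH")
        dend = bootstrap_cluster(encode_numeric(m), nboot=200, seed=1)
        assert dend.support[frozenset("ABCD")] >= 0.95
        assert dend.support[frozenset("EFGH")] >= 0.95

    def test_nboot_zero_no_support(self):
        m = matrix_from_classes([[H, R, R], [R, H, R], [R, R, H]], "ABC")
        dend = bootstrap_cluster(encode_numeric(m), nboot=0)
        assert dend.support is None and len(dend.clades()) == 2

    def test_forced_topology(self):
        """Pairwise distances 1,1,10-ish force the close pair to merge first."""
        num = pd.DataFrame(
            [[0.0] * 8, [0.5] + [0.0] * 7, [1.0] * 8],
            index=["P", "Q", "Z"],
        )
        dend = bootstrap_cluster(num, nboot=0)
        assert dend.clades()[0] == frozenset({"P", "Q"})

    def test_constant_matrix_errors(self):
        m = matrix_from_classes([[H, H, H]] * 4, "ABC")
        with pytest.raises(ValueError, match="no variation"):
            bootstrap_cluster(encode_numeric(m), nboot=0)


class TestPCA:
    def test_duplicated_samples_identical_scores(self):
        rng = np.random.default_rng(2)
        codes = rng.integers(0, 3, size=(40, 3)).astype(np.int8)
        codes = np.hstack([codes, codes[:, :1]])  # sample D duplicates A
        from clonehet.matrix import GenotypeMatrix

        m = GenotypeMatrix(codes, [("s1", i + 1) for i in range(40)], list("ABCD"))
        scores, var = pca_scores(encode_numeric(m))
        np.testing.assert_allclose(scores.loc["A"], scores.loc["D"], atol=1e-9)
        assert var.sum() == pytest.approx(100.0)

    def test_two_cluster_separation_and_sign_stability(self):
        rows = [[H, H, H, H, R, R, R, R]] * 20 + [[R, R, R, R, H, H, H, H]] * 20
        m = matrix_from_classes(rows, "ABCDEFGH")
        scores1, _ = pca_scores(encode_numeric(m))
        scores2, _ = pca_scores(encode_numeric(m))
        pd.testing.assert_frame_equal(scores1, scores2)
        left = scores1.loc[list("ABCD"), "PC1"]
        right = scores1.loc[list("EFGH"), "PC1"]
        assert (left.max() < right.min()) or (right.max() < left.min())

    def test_rank_zero_errors(self):
        m = matrix_from_classes([[H, H, H], [H, H, H]], "ABC")
        with pytest.raises(ValueError, match="rank-0"):
            pca_scores(encode_numeric(m))


class TestRepresentatives:
    def test_median_selection_and_ties(self):
        scores = pd.DataFrame(
            {
                "PC1": [0.0, 1.0, 10.0, 5.0],
                "PC2": [0.0, 0.0, 0.0, 5.0],
                "PC3": [0.0, 0.0, 0.0, 5.0],
            },
            index=["a1", "a2", "a3", "b1"],
        )
        region_of = {"a1": "A", "a2": "A", "a3": "A", "b1": "B"}
        reps = select_representatives(scores, region_of)
        assert reps == {"A": "a2", "B": "b1"}  # a2 sits at the median (1,0,0)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(4)
        scores = pd.DataFrame(
            rng.normal(size=(6, 3)), columns=["PC1", "PC2", "PC3"],
            index=[f"s{i}" for i in range(6)],
        )
        region_of = {f"s{i}": "R1" if i < 3 else "R2" for i in range(6)}
        reps = select_representatives(scores, region_of)
        perm = scores.iloc[::-1]
        assert select_representatives(perm, region_of) == reps

    def test_unlabelled_sample_errors(self):
        scores = pd.DataFrame(
            [[0.0, 0.0, 0.0]], columns=["PC1", "PC2", "PC3"], index=["x"]
        )
        with pytest.raises(KeyError, match="region"):
            select_representatives(scores, {})


def test_chain_recovers_where_clustering_misplaces_focal():
    """High focal-private mutation load distorts distance-based clustering
    but not the intersection chain.

    Regime: caterpillar truth order A,(B,(C,(D,(E,F)))) with 20 shared
    loci per clade branch and 300 loci private to the focal sample F.
    On the focal-conditioned matrix, F's private load dominates every
    distance to F, so Ward merges D with E before E can join its true
    sister F; the chain prunes the singletons and recovers the order.
    """
    samples = "ABCDEF"
    clades = ["BCDEF", "CDEF", "DEF", "EF"]
    rows = []
    for clade in clades:
        rows += [[H if s in clade else R for s in samples]] * 20
    rows += [[R, R, R, R, R, H]] * 300  # focal-private load
    m = matrix_from_classes(rows, samples)

    pruned, _ = prune_uninformative(m)
    focal = condition_on_focal(pruned, "F")
    flagged = detect_elevated(combination_counts(focal, H), min_degree=2)
    chain = infer_divergence_chain(flagged, "F")
    assert [e.samples for e in chain.sets] == [
        ("B", "C", "D", "E", "F"),
        ("C", "D", "E", "F"),
        ("D", "E", "F"),
        ("E", "F"),
    ]

    dend = bootstrap_cluster(encode_numeric(condition_on_focal(m, "F")), nboot=0)
    assert dend.smallest_clade_containing("F") != frozenset({"E", "F"})
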