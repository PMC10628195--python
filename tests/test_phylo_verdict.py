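import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import nnls

from heterotrace.core_io import InputError, revcomp
from heterotrace.phylo_verdict import (
    AlignedHaplotypeMatrix,
    SaturationError,
    SupportTree,
    bootstrap_support,
    jc_distance,
    nj_tree,
    supported_grouping,
    test_monophyly as check_monophyly,
    w_origin_verdict,
)
from heterotrace.trace_origin import TraceResult


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def canon_split(side, taxa):
    """Bipartition as a frozenset of both sides (orientation-free)."""
    side = frozenset(side)
    return frozenset([side, frozenset(taxa) - side])


def all_topologies(taxa):
    """Every unrooted binary topology as a frozenset of canonical
    bipartitions; supports 4 or 5 taxa."""
    taxa = sorted(taxa)
    if len(taxa) == 4:
        a = taxa[0]
        return [
            frozenset([canon_split([a, other], taxa)]) for other in taxa[1:]
        ]
    tops = []
    for cherry1 in itertools.combinations(taxa, 2):
        rest = [t for t in taxa if t not in cherry1]
        for cherry2 in itertools.combinations(rest, 2):
            top = frozenset(
                [canon_split(cherry1, taxa), canon_split(cherry2, taxa)]
            )
            if top not in tops:
                tops.append(top)
    return tops


def ls_fit(topology, taxa, dmat):
    """Least-squares branch lengths for a topology; returns (rss, lengths)."""
    taxa = sorted(taxa)
    pairs = list(itertools.combinations(taxa, 2))
    # pick one side of each canonical bipartition for path incidence
    internal = [sorted(bp, key=lambda x: sorted(x))[0] for bp in topology]
    edges = [frozenset([t]) for t in taxa] + internal
    A = np.zeros((len(pairs), len(edges)))
    d = np.zeros(len(pairs))
    for r, (i, j) in enumerate(pairs):
        d[r] = dmat.loc[i, j]
        for c, side in enumerate(edges):
            if (i in side) != (j in side):
                A[r, c] = 1.0
    x, rnorm = nnls(A, d)
    return rnorm**2, x


def exhaustive_ls_topology(dmat):
    """Exhaustive least-squares topology search (the NJ oracle)."""
    taxa = sorted(dmat.index)
    best, best_rss = None, math.inf
    for top in all_topologies(taxa):
        rss, _ = ls_fit(top, taxa, dmat)
        if rss < best_rss - 1e-12:
            best, best_rss = top, rss
    return best, best_rss


def random_additive_matrix(taxa, rng):
    top = all_topologies(taxa)[rng.integers(0, len(all_topologies(taxa)))]
    taxa_s = sorted(taxa)
    internal = [sorted(bp, key=lambda x: sorted(x))[0] for bp in top]
    edges = [frozenset([t]) for t in taxa_s] + internal
    lengths = rng.uniform(0.05, 1.0, len(edges))
    d = pd.DataFrame(0.0, index=taxa_s, columns=taxa_s)
    for i, j in itertools.combinations(taxa_s, 2):
        total = sum(
            l for side, l in zip(edges, lengths) if (i in side) != (j in side)
        )
        d.loc[i, j] = d.loc[j, i] = total
    return d, top


def nj_canonical_topology(tree):
    taxa = tree.taxa
    return frozenset(canon_split(side, taxa) for side in tree.bipartitions())


# ---------------------------------------------------------------------------
# JC distances
# ---------------------------------------------------------------------------


class TestJcDistance:
    def test_identical_rows_zero(self):
        m = AlignedHaplotypeMatrix(["a", "b"], ["ACGTACGT", "ACGTACGT"])
        assert jc_distance(m).loc["a", "b"] == 0.0

    def test_closed_form_inverted(self):
        # choose p so that 1 - 4p/3 = exp(-4*0.03/3): then d = 0.03 exactly
        p = 0.75 * (1.0 - math.exp(-4.0 * 0.03 / 3.0))
        n = 200_000
        k = round(p * n)
        a = "A" * n
        b = "C" * k + "A" * (n - k)
        d = jc_distance(AlignedHaplotypeMatrix(["a", "b"], [a, b])).loc["a", "b"]
        assert d == pytest.approx(0.03, abs=1e-5)

    def test_formula_oracle_random_pairs(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            n = int(rng.integers(100, 2_000))
            k = int(rng.integers(0, int(0.7 * n)))
            a = "A" * n
            b = "G" * k + "A" * (n - k)
            d = jc_distance(AlignedHaplotypeMatrix(["a", "b"], [a, b])).loc[
                "a", "b"
            ]
            p = k / n
            expected = -0.75 * math.log(1 - 4 * p / 3)
            assert d == pytest.approx(expected, abs=1e-12)

    def test_saturation_error(self):
        a = "A" * 100
        b = "C" * 80 + "A" * 20  # p = 0.8 >= 0.75
        with pytest.raises(SaturationError):
            jc_distance(AlignedHaplotypeMatrix(["a", "b"], [a, b]))

    def test_gap_columns_ignored(self):
        m = AlignedHaplotypeMatrix(["a", "b"], ["ACGTNNNN", "ACGTCCCC"])
        assert jc_distance(m).loc["a", "b"] == 0.0

    def test_unequal_rows_rejected(self):
        with pytest.raises(InputError):
            AlignedHaplotypeMatrix(["a", "b"], ["ACGT", "ACG"])


# ---------------------------------------------------------------------------
# NJ
# ---------------------------------------------------------------------------


class TestNjTree:
    def test_three_taxa_closed_form(self):
        d = pd.DataFrame(
            [[0, 3, 4], [3, 0, 5], [4, 5, 0]],
            index=list("abc"),
            columns=list("abc"),
            dtype=float,
        )
        tree = nj_tree(d)
        assert tree.path_length("a", "b") == pytest.approx(3.0, abs=1e-9)
        assert tree.path_length("a", "c") == pytest.approx(4.0, abs=1e-9)
        assert tree.path_length("b", "c") == pytest.approx(5.0, abs=1e-9)

    def test_four_taxa_additive_recovery(self):
        rng = np.random.default_rng(2)
        d, top = random_additive_matrix(list("abcd"), rng)
        tree = nj_tree(d)
        assert nj_canonical_topology(tree) == top
        for i, j in itertools.combinations(list("abcd"), 2):
            assert tree.path_length(i, j) == pytest.approx(d.loc[i, j], abs=1e-9)

    def test_matches_exhaustive_ls_search(self):
        """NJ equals the exhaustive least-squares topology search on random
        additive 4- and 5-taxon matrices."""
        rng = np.random.default_rng(3)
        for taxa in (list("abcd"), list("abcde")):
            for _ in range(10):
                d, true_top = random_additive_matrix(taxa, rng)
                tree = nj_tree(d)
                oracle_top, rss = exhaustive_ls_topology(d)
                assert rss < 1e-12
                assert oracle_top == true_top
                assert nj_canonical_topology(tree) == oracle_top

    def test_asymmetric_rejected(self):
        d = pd.DataFrame(
            [[0, 1, 2], [3, 0, 1], [2, 1, 0]],
            index=list("abc"),
            columns=list("abc"),
            dtype=float,
        )
        with pytest.raises(InputError):
            nj_tree(d)

    def test_equal_distances_deterministic(self):
        d = pd.DataFrame(1.0, index=list("abcd"), columns=list("abcd"))
        np.fill_diagonal(d.values, 0.0)
        t1 = nj_tree(d).to_newick()
        t2 = nj_tree(d).to_newick()
        assert t1 == t2  # tie broken by taxon-name order, stable


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------


def structured_matrix(n_cols=400, seed=4):
    """Four taxa, divergence far above noise: (a,b) vs (c,d)."""
    rng = np.random.default_rng(seed)
    base = rng.integers(0, 4, n_cols)
    other = base.copy()
    idx = rng.choice(n_cols, n_cols // 3, replace=False)
    other[idx] = (other[idx] + 2) % 4
    dec = np.array(list("ACGT"))
    def noisy(arr, rate):
        out = arr.copy()
        hit = rng.random(n_cols) < rate
        out[hit] = (out[hit] + 1) % 4
        return "".join(dec[out])
    return AlignedHaplotypeMatrix(
        ["a", "b", "c", "d"],
        [noisy(base, 0.02), noisy(base, 0.02), noisy(other, 0.02), noisy(other, 0.02)],
    )


class TestBootstrap:
    def test_saturated_signal_full_support(self):
        tree = bootstrap_support(structured_matrix(), B=100, seed=0)
        assert set(tree.supports.values()) == {100.0}

    def test_b_zero_supports_unset(self):
        tree = bootstrap_support(structured_matrix(), B=0)
        assert tree.supports == {}
        assert tree.bipartitions()

    def test_fixed_seed_deterministic(self):
        t1 = bootstrap_support(structured_matrix(), B=50, seed=9)
        t2 = bootstrap_support(structured_matrix(), B=50, seed=9)
        assert t1.supports == t2.supports
        assert t1.to_newick() == t2.to_newick()


class TestNewickRoundTrip:
    def test_supports_survive(self):
        tree = bootstrap_support(structured_matrix(), B=50, seed=1)
        back = SupportTree.from_newick(tree.to_newick())
        assert back.bipartitions().keys() == tree.bipartitions().keys()
        assert back.supports == {
            k: float(int(round(v))) for k, v in tree.supports.items()
        }


# ---------------------------------------------------------------------------
# monophyly and verdict
# ---------------------------------------------------------------------------


class TestMonophyly:
    def test_four_taxon_complement_clade(self):
        tree = SupportTree.from_newick("((Y:1,Z:1):1,(W:1,X:1):1);")
        flag, support = check_monophyly(tree, {"Y", "Z", "W"}, "X")
        assert flag and support == 100.0

    def test_five_taxon_true_clade(self):
        tree = SupportTree.from_newick(
            "((X:1,OUT:1)95:1,(Z:1,W:1)80:1,Y:1);"
        )
        flag, support = check_monophyly(tree, {"Y", "Z", "W"}, "OUT")
        assert flag and support == 95.0  # the {X,OUT} edge is the same split

    def test_five_taxon_false(self):
        tree = SupportTree.from_newick(
            "((X:1,W:1)95:1,(Z:1,Y:1)80:1,OUT:1);"
        )
        flag, support = check_monophyly(tree, {"Y", "Z", "W"}, "OUT")
        assert not flag

    def test_missing_taxon_error(self):
        tree = SupportTree.from_newick("((Y:1,Z:1):1,(W:1,X:1):1);")
        with pytest.raises(InputError):
            check_monophyly(tree, {"Y", "Q"}, "X")

    def test_simulated_monophyly(self, sim_wy):
        from heterotrace.core_io import HaplotypeSequence
        from heterotrace.trace_origin import harvest_window_alignment

        haps = sim_wy.haplotypes
        rows, used = harvest_window_alignment(
            sim_wy.reference,
            [t["pos"] for t in sim_wy.truth.tracer_loci],
            haps,
        )
        matrix = AlignedHaplotypeMatrix(list(rows), [rows[n] for n in rows])
        tree = bootstrap_support(matrix, B=100, seed=5)
        flag, support = check_monophyly(tree, {"Y", "Z", "W"}, "OUT")
        assert flag and support >= 70


def _trace(n_y, n_x, n_neither=0, n_unplaced=0):
    return TraceResult(
        "W", [], n_y_match=n_y, n_x_match=n_x,
        n_neither=n_neither, n_unplaced=n_unplaced,
    )


GOOD_TREE = SupportTree.from_newick("((X:1,OUT:1)100:1,(Z:1,W:1)90:1,Y:1);")
MIRROR_TREE = SupportTree.from_newick("((Y:1,OUT:1)100:1,(Z:1,Y2:0):0,(W:1,X:1)90:1);")


class TestVerdict:
    def test_lopsided_counts_give_w_from_y(self):
        # 28 of 30 Y-identical, 0 X-identical, plus a supporting tree
        report = w_origin_verdict(_trace(28, 0, n_neither=2), GOOD_TREE)
        assert report["verdict"] == "W_from_Y"
        assert report["binomial_p"] < 1e-6

    def test_symmetric_counts_undetermined(self):
        report = w_origin_verdict(_trace(10, 10), GOOD_TREE)
        assert report["verdict"] == "undetermined"
        assert report["reason"] == "symmetric allele evidence"

    def test_zero_placed_undetermined(self):
        report = w_origin_verdict(_trace(0, 0, n_unplaced=30), GOOD_TREE)
        assert report["verdict"] == "undetermined"

    def test_counts_without_tree_support_undetermined(self):
        bad_tree = SupportTree.from_newick(
            "((Y:1,OUT:1)100:1,(Z:1,X:1)90:1,W:1);"
        )
        report = w_origin_verdict(_trace(28, 0), bad_tree)
        assert report["verdict"] == "undetermined"

    def test_antisymmetry_label_swap(self):
        """Swapping the X and Y roles flips the verdict."""
        tree = SupportTree.from_newick("((X:1,OUT:1)100:1,(Z:1,W:1)90:1,Y:1);")
        fwd = w_origin_verdict(_trace(25, 1), tree)
        swapped_tree = SupportTree.from_newick(
            "((Y:1,OUT:1)100:1,(Z:1,W:1)90:1,X:1);"
        )
        rev = w_origin_verdict(_trace(1, 25), swapped_tree)
        assert fwd["verdict"] == "W_from_Y"
        assert rev["verdict"] == "W_from_X"

    def test_insignificant_binomial_undetermined(self):
        report = w_origin_verdict(_trace(3, 1), GOOD_TREE)
        assert report["verdict"] == "undetermined"


class TestSupportedGrouping:
    def test_found_with_support(self):
        ok, sup = supported_grouping(GOOD_TREE, {"Y", "W"}, {"X"})
        assert ok and sup == 100.0  # the {Y,Z,W} side also qualifies

    def test_absent(self):
        ok, _ = supported_grouping(GOOD_TREE, {"X", "W"}, {"Y"})
        assert not ok


class TestPerDuplicateTrees:
    def test_single_origin_signal(self, sim_wy):
        """Each planted duplicate's tree groups the Y copy with the Z copy to
        the exclusion of the intact-gene homologs."""
        gene = sim_wy.query_gene.seq
        z = sim_wy.truth.sequences["Z"]
        for d in sim_wy.truth.duplicates:
            y_frag = sim_wy.reference.seq[d.start : d.end]
            z_frag = z[d.start : d.end]
            if d.strand == "-":
                y_frag, z_frag = revcomp(y_frag), revcomp(z_frag)
            intact = gene[d.query_start : d.query_end]
            matrix = AlignedHaplotypeMatrix(
                ["Ycopy", "Zcopy", "intact", "intact2"],
                [y_frag, z_frag, intact, intact],
            )
            tree = nj_tree(jc_distance(matrix))
            flag, _ = check_monophyly(tree, {"Ycopy", "Zcopy"}, "intact")
            assert flag
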