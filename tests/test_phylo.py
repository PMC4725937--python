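"""Site classification, Fitch parsimony length, CI/RI, and marker
concatenation — all scored against exhaustive oracles on small instances."""

import dendropy
import numpy as np
import pytest

from sagqc.phylo import (
    CharacterMatrix,
    classify_sites,
    concatenate_markers,
    consistency_retention,
    fitch_length,
)
from sagqc.simulate import simulate_matrix
from tests.conftest import brute_force_fitch, random_tree


def _matrix(cols, taxa=None):
    """Build a matrix from a list of column strings."""
    n_taxa = len(cols[0])
    taxa = taxa or tuple(f"t{i+1}" for i in range(n_taxa))
    rows = tuple("".join(col[i] for col in cols) for i in range(n_taxa))
    return CharacterMatrix(tuple(taxa), rows)


def _tree(newick, taxa):
    tns = dendropy.TaxonNamespace(list(taxa))
    return dendropy.Tree.get(
        data=newick, schema="newick", taxon_namespace=tns,
        preserve_underscores=True,
    )


class TestClassifySites:
    @pytest.mark.parametrize(
        "col,expected",
        [
            ("AAAA", "constant"),
            ("AAAT", "variable_uninformative"),
            ("AATT", "parsimony_informative"),
            ("ACGT", "variable_uninformative"),
            ("AAT?", "variable_uninformative"),
            ("AATT-A", "parsimony_informative"),
        ],
    )
    def test_single_columns(self, col, expected):
        classes, _ = classify_sites(_matrix([col]))
        assert classes == [expected]

    def test_all_missing_column_counts_constant(self):
        classes, counts = classify_sites(_matrix(["????"]))
        assert classes == ["constant"] and counts["variable"] == 0

    def test_variable_count_bounds_informative(self):
        taxa, rows, _ = simulate_matrix(2, 8, 120, 0.5)
        _, counts = classify_sites(CharacterMatrix(tuple(taxa), tuple(rows)))
        assert counts["parsimony_informative"] <= counts["variable"]
        assert counts["constant"] + counts["variable"] == 120

    def test_invariant_under_taxon_and_column_permutation(self):
        taxa, rows, _ = simulate_matrix(6, 5, 40, 0.7)
        m = CharacterMatrix(tuple(taxa), tuple(rows))
        _, c1 = classify_sites(m)
        rng = np.random.default_rng(0)
        row_perm = rng.permutation(5)
        col_perm = rng.permutation(40)
        m2 = CharacterMatrix(
            tuple(taxa[i] for i in row_perm),
            tuple("".join(rows[i][j] for j in col_perm) for i in row_perm),
        )
        _, c2 = classify_sites(m2)
        assert c1 == c2


class TestFitchLength:
    def test_constant_matrix_zero_length(self):
        m = _matrix(["AAAA", "CCCC"])
        total, _ = fitch_length(_tree("((t1,t2),(t3,t4));", m.taxa), m)
        assert total == 0

    def test_two_taxa_hamming(self):
        m = CharacterMatrix(("a", "b"), ("ACGTAC", "ACCTAA"))
        total, _ = fitch_length(_tree("(a,b);", ("a", "b")), m)
        assert total == 2

    def test_missing_excluded_from_two_taxon_distance(self):
        m = CharacterMatrix(("a", "b"), ("AC?T", "AG-T"))
        total, _ = fitch_length(_tree("(a,b);", ("a", "b")), m)
        assert total == 1

    def test_aatt_topology_dependence(self):
        m = CharacterMatrix(("A1", "A2", "T1", "T2"), ("A", "A", "T", "T"))
        congruent = _tree("((A1,A2),(T1,T2));", m.taxa)
        conflicting = _tree("((A1,T1),(A2,T2));", m.taxa)
        assert fitch_length(congruent, m)[0] == 1
        assert fitch_length(conflicting, m)[0] == 2

    def test_leaf_absent_from_matrix_named(self):
        m = _matrix(["AATT"])
        tree = _tree("((t1,t2),(t3,zz));", ("t1", "t2", "t3", "zz"))
        with pytest.raises(ValueError, match="zz"):
            fitch_length(tree, m)

    def test_rooting_invariance(self):
        taxa, rows, _ = simulate_matrix(21, 6, 25, 0.8)
        m = CharacterMatrix(tuple(taxa), tuple(rows))
        tree = random_tree(list(taxa), seed=2)
        ref, _ = fitch_length(tree, m)
        for i in range(2, 6):
            t2 = tree.clone(depth=1)
            edges = [e for e in t2.preorder_edge_iter()
                     if e.head_node.parent_node is not None]
            t2.reroot_at_edge(edges[i], update_bipartitions=False)
            assert fitch_length(t2, m)[0] == ref

    def test_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(13)
        for trial in range(25):
            n = int(rng.integers(4, 7))
            taxa, rows, _ = simulate_matrix(
                int(rng.integers(1 << 30)), n, 6, 0.9
            )
            m = CharacterMatrix(tuple(taxa), tuple(rows))
            tree = random_tree(list(taxa), seed=trial)
            _, per_site = fitch_length(tree, m)
            for j in range(m.n_sites):
                col = {t: rows[i][j] for i, t in enumerate(taxa)}
                assert per_site[j] == brute_force_fitch(tree, col)


class TestConsistencyRetention:
    def test_congruent_matrix_ci_one(self):
        m = CharacterMatrix(("A1", "A2", "T1", "T2"), ("AAG", "AAG", "TCG", "TCG"))
        tree = _tree("((A1,A2),(T1,T2));", m.taxa)
        ci, ri = consistency_retention(tree, m)
        assert ci == 1.0 and ri == 1.0

    def test_single_informative_site_on_its_tree(self):
        m = CharacterMatrix(("A1", "A2", "T1", "T2"), ("A", "A", "T", "T"))
        tree = _tree("((A1,A2),(T1,T2));", m.taxa)
        ci, ri = consistency_retention(tree, m)
        assert ci == 1.0 and ri == 1.0  # m=1, s=1, g=2

    def test_homoplastic_site_lowers_indices(self):
        m = CharacterMatrix(("A1", "T1", "A2", "T2"), ("A", "T", "A", "T"))
        tree = _tree("((A1,T1),(A2,T2));", m.taxa)
        ci, ri = consistency_retention(tree, m)
        assert ci == pytest.approx(0.5)  # m=1, s=2
        assert ri == pytest.approx(0.0)  # g=2: (2-2)/(2-1)

    def test_zero_changes_ci_undefined(self):
        m = _matrix(["AAAA"])
        tree = _tree("((t1,t2),(t3,t4));", m.taxa)
        ci, ri = consistency_retention(tree, m)
        assert ci is None and ri is None

    def test_indices_in_unit_interval_and_match_oracle(self):
        rng = np.random.default_rng(29)
        for trial in range(10):
            taxa, rows, _ = simulate_matrix(
                int(rng.integers(1 << 30)), 6, 20, 0.8
            )
            m = CharacterMatrix(tuple(taxa), tuple(rows))
            tree = random_tree(list(taxa), seed=100 + trial)
            ci, ri = consistency_retention(tree, m)
            assert 0 < ci <= 1 and 0 <= ri <= 1
            # rebuild both indices from the exhaustive per-site oracle
            sum_m = sum_s = rm = rg = rs = 0
            for j in range(m.n_sites):
                col = {t: rows[i][j] for i, t in enumerate(taxa)}
                obs = [c for c in col.values()]
                counts = {s: obs.count(s) for s in set(obs)}
                mm = len(counts) - 1
                gg = len(obs) - max(counts.values())
                ss = brute_force_fitch(tree, col)
                sum_m += mm
                sum_s += ss
                if gg > mm:
                    rm, rg, rs = rm + mm, rg + gg, rs + ss
            assert ci == pytest.approx(sum_m / sum_s)
            assert ri == pytest.approx((rg - rs) / (rg - rm))


class TestConcatenateMarkers:
    def _aln(self, mapping):
        taxa = tuple(mapping)
        return CharacterMatrix(taxa, tuple(mapping[t] for t in taxa))

    def test_partitions_and_width(self):
        a = self._aln({"x": "AAAAA", "y": "CCCCC"})
        b = self._aln({"x": "GGGGGGG", "y": "TTTTTTT"})
        matrix, parts = concatenate_markers([("m1", a), ("m2", b)], ["x", "y"])
        assert matrix.n_sites == 12
        assert parts.to_dict("records") == [
            {"marker": "m1", "start": 1, "end": 5},
            {"marker": "m2", "start": 6, "end": 12},
        ]

    def test_absent_taxon_padded_missing(self):
        a = self._aln({"x": "AAAAA", "y": "CCCCC"})
        b = self._aln({"x": "GGGGGGG", "z": "TTTTTTT"})
        matrix, _ = concatenate_markers([("m1", a), ("m2", b)], ["x", "y"])
        row_y = dict(zip(matrix.taxa, matrix.rows))["y"]
        assert row_y == "CCCCC" + "?" * 7

    def test_duplicate_marker_names_rejected(self):
        a = self._aln({"x": "A", "y": "C"})
        with pytest.raises(ValueError, match="duplicate"):
            concatenate_markers([("m1", a), ("m1", a)], ["x", "y"])

    def test_order_permutation_preserves_site_class_counts(self):
        a = self._aln({"x": "AATT", "y": "AATA", "z": "TATT", "w": "AAAT"})
        b = self._aln({"x": "GGG", "y": "GCG", "z": "CCG", "w": "GCC"})
        m1, _ = concatenate_markers([("a", a), ("b", b)], ["x", "y", "z", "w"])
        m2, _ = concatenate_markers([("b", b), ("a", a)], ["x", "y", "z", "w"])
        _, c1 = classify_sites(m1)
        _, c2 = classify_sites(m2)
        assert c1 == c2
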