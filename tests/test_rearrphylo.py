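"""Orientation encoding, BioNJ, consensus and column machinery."""

import numpy as np
import pytest

from lepcompgen import rearrphylo as rp
from lepcompgen import synthio
from lepcompgen.io import parse_newick
from lepcompgen.rearrphylo import FamilyPair, OrthologFamily

from conftest import additive_matrix, random_tree_with_lengths

SPECIES = ["sp1", "sp2", "sp3"]


def _family(fid, placements):
    """placements: species -> list of (scaffold, strand) tuples."""
    fam = OrthologFamily(fid)
    for sp, locs in placements.items():
        fam.members[sp] = [
            (f"{fid}.{sp}.{i}", scf, 100 * i, strand)
            for i, (scf, strand) in enumerate(locs)
        ]
    return fam


class TestFilterFamilies:
    def test_five_copies_removed_four_kept(self):
        f5 = _family("f5", {sp: [("s1", "+")] * (5 if sp == "sp1" else 1) for sp in SPECIES})
        f4 = _family("f4", {sp: [("s1", "+")] * 4 for sp in SPECIES})
        out = rp.filter_families({"f5": f5, "f4": f4}, SPECIES)
        assert set(out) == {"f4"}

    def test_absent_in_one_species_removed(self):
        f = _family("f1", {"sp1": [("s1", "+")], "sp2": [("s1", "+")]})
        assert rp.filter_families({"f1": f}, SPECIES) == {}


class TestOrientationState:
    @pytest.mark.parametrize(
        "sa,sb,state",
        [("+", "+", "A"), ("-", "-", "B"), ("+", "-", "C"), ("-", "+", "D")],
    )
    def test_state_letters(self, sa, sb, state):
        a = ("ga", "s1", 100, sa)
        b = ("gb", "s1", 500, sb)
        assert rp.orientation_state(a, b) == state

    def test_different_scaffolds_undetermined(self):
        assert rp.orientation_state(("ga", "s1", 0, "+"), ("gb", "s2", 0, "+")) is None

    def test_same_gene_rejected(self):
        g = ("ga", "s1", 0, "+")
        with pytest.raises(ValueError):
            rp.orientation_state(g, g)


class TestResolvablePairs:
    def test_co_scaffolded_single_copy_pair(self):
        fams = {
            "fa": _family("fa", {sp: [("s1", "+")] for sp in SPECIES}),
            "fb": _family("fb", {sp: [("s1", "-")] for sp in SPECIES}),
        }
        (pair,) = rp.resolvable_pairs(fams, SPECIES)
        assert (pair.fam_a, pair.fam_b) == ("fa", "fb")
        assert pair.states == {sp: "C" for sp in SPECIES}

    def test_split_across_scaffolds_excluded(self):
        fams = {
            "fa": _family("fa", {sp: [("s1", "+")] for sp in SPECIES}),
            "fb": _family(
                "fb",
                {"sp1": [("s2", "+")], "sp2": [("s1", "+")], "sp3": [("s1", "+")]},
            ),
        }
        assert rp.resolvable_pairs(fams, SPECIES) == []

    def test_multicopy_with_discordant_strands_excluded(self):
        fams = {
            "fa": _family("fa", {sp: [("s1", "+")] for sp in SPECIES}),
            "fb": _family(
                "fb",
                {
                    "sp1": [("s1", "+"), ("s1", "-")],  # copies disagree
                    "sp2": [("s1", "+")],
                    "sp3": [("s1", "+")],
                },
            ),
        }
        assert rp.resolvable_pairs(fams, SPECIES) == []

    def test_multicopy_concordant_resolves(self):
        fams = {
            "fa": _family("fa", {sp: [("s1", "+")] for sp in SPECIES}),
            "fb": _family(
                "fb",
                {
                    "sp1": [("s1", "-"), ("s1", "-")],
                    "sp2": [("s1", "-")],
                    "sp3": [("s1", "-")],
                },
            ),
        }
        (pair,) = rp.resolvable_pairs(fams, SPECIES)
        assert pair.states["sp1"] == "C"


class TestSelectDisjointPairs:
    def _pair(self, a, b):
        return FamilyPair(a, b, {sp: "A" for sp in SPECIES})

    def test_greedy_chain(self):
        pairs = [self._pair("f1", "f2"), self._pair("f2", "f3"), self._pair("f3", "f4")]
        chosen = rp.select_disjoint_pairs(pairs)
        assert [(p.fam_a, p.fam_b) for p in chosen] == [("f1", "f2"), ("f3", "f4")]

    def test_disjoint_input_all_kept(self):
        pairs = [self._pair("f1", "f2"), self._pair("f3", "f4")]
        assert len(rp.select_disjoint_pairs(pairs)) == 2

    def test_families_all_distinct(self):
        rng = np.random.default_rng(0)
        fams = [f"f{i:02d}" for i in range(20)]
        pairs = []
        for _ in range(40):
            a, b = sorted(rng.choice(fams, size=2, replace=False))
            pairs.append(self._pair(a, b))
        chosen = rp.select_disjoint_pairs(pairs)
        used = [f for p in chosen for f in (p.fam_a, p.fam_b)]
        assert len(used) == len(set(used))


class TestHamming:
    def _matrix(self, strings):
        sp = list(strings)
        pairs = [(f"fa{i}", f"fb{i}") for i in range(len(next(iter(strings.values()))))]
        return rp.OrientationMatrix(sp, pairs, strings)

    def test_identical_and_single_difference(self):
        m = self._matrix({"x": "AABB", "y": "ABBB", "z": "AABB"})
        d, labels = rp.hamming_distances(m)
        i, j, k = labels.index("x"), labels.index("y"), labels.index("z")
        assert d[i, j] == 1 and d[i, k] == 0

    def test_metric_properties_on_random_matrices(self):
        rng = np.random.default_rng(5)
        n, L = 7, 200
        strings = {
            f"s{i}": "".join(rng.choice(list("ABCD"), size=L)) for i in range(n)
        }
        d, _ = rp.hamming_distances(self._matrix(strings))
        assert np.allclose(d, d.T)
        assert np.all(np.diag(d) == 0)
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    assert d[i, j] <= d[i, k] + d[k, j]


class TestBioNJ:
    def test_three_taxon_closed_form(self):
        d = np.array([[0, 5, 9], [5, 0, 10], [9, 10, 0]], dtype=float)
        tree = rp.bionj(d, ["A", "B", "C"])
        lengths = {
            l.taxon.label: l.edge.length for l in tree.leaf_node_iter()
        }
        assert lengths["A"] == pytest.approx((5 + 9 - 10) / 2)
        assert lengths["B"] == pytest.approx((5 + 10 - 9) / 2)
        assert lengths["C"] == pytest.approx((9 + 10 - 5) / 2)

    def test_additive_matrix_exact_recovery(self):
        rng = np.random.default_rng(7)
        for n_taxa in (5, 6, 8):
            t = random_tree_with_lengths(rng, n_taxa)
            d, labels = additive_matrix(t)
            bt = rp.bionj(d, labels)
            assert rp.rf_distance(bt, t) == 0
            db, lb = additive_matrix(bt)
            order = [lb.index(x) for x in labels]
            assert np.allclose(db[np.ix_(order, order)], d, atol=1e-9)

    def test_agrees_with_dendropy_nj_on_additive_input(self):
        """Independent oracle: classical NJ recovers the same (true) topology."""
        import dendropy

        rng = np.random.default_rng(9)
        t = random_tree_with_lengths(rng, 6)
        d, labels = additive_matrix(t)
        bt = rp.bionj(d, labels)
        csv = "," + ",".join(labels) + "\n"
        for i, a in enumerate(labels):
            csv += a + "," + ",".join(str(x) for x in d[i]) + "\n"
        pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
            src=__import__("io").StringIO(csv)
        )
        njt = pdm.nj_tree()
        njt_parsed = parse_newick(njt.as_string(schema="newick"))
        assert rp.rf_distance(bt, njt_parsed) == 0

    def test_permutation_invariance(self):
        rng = np.random.default_rng(11)
        t = random_tree_with_lengths(rng, 6)
        d, labels = additive_matrix(t)
        perm = rng.permutation(len(labels))
        dp = d[np.ix_(perm, perm)]
        lp = [labels[i] for i in perm]
        assert rp.rf_distance(rp.bionj(d, labels), rp.bionj(dp, lp)) == 0

    def test_asymmetric_matrix_rejected(self):
        d = np.array([[0, 1, 2], [1, 0, 3], [9, 3, 0]], dtype=float)
        with pytest.raises(ValueError):
            rp.bionj(d, ["A", "B", "C"])


class TestCharacterMatrix:
    def test_header_and_round_trip(self, tmp_path):
        strings = {"Species_A": "ABCD" * 10, "B": "DCBA" * 10, "C": "AAAA" * 10}
        m = rp.OrientationMatrix(
            list(strings), [(f"a{i}", f"b{i}") for i in range(40)], strings
        )
        p = tmp_path / "m.phy"
        rp.export_character_matrix(m, p)
        first = p.read_text().splitlines()[0]
        assert first == "3 40"
        back = rp.read_character_matrix(p)
        assert back == strings  # long names preserved (relaxed dialect)


class TestConsistentColumns:
    def test_identical_msas_keep_all(self):
        msa = {"a": "AC-GT", "b": "ACTGT"}
        assert rp.consistent_columns(msa, dict(msa)) == [0, 1, 2, 3, 4]

    def test_shifted_block_dropped(self):
        # second aligner shifts sequence b by one in the last block
        msa1 = {"a": "ACGTAC", "b": "ACGTAC"}
        msa2 = {"a": "ACGTAC-", "b": "ACG-TAC"}
        kept = rp.consistent_columns(msa1, msa2)
        assert kept == [0, 1, 2]

    def test_gap_only_column_kept_vacuously(self):
        msa1 = {"a": "A-C", "b": "-TC"}
        msa2 = {"a": "AC--", "b": "--TC"}
        kept = rp.consistent_columns(msa1, msa2)
        assert 0 in kept and 1 in kept and 2 not in kept

    def test_pairwise_mode(self):
        msa = {"a": "AC", "b": "AC"}
        pairs = {
            frozenset({("a", 0), ("b", 0)}),
        }
        assert rp.consistent_columns(msa, pairs) == [0]


class TestSampleColumnGroups:
    def test_paper_scale_group_sizes(self):
        groups = rp.sample_column_groups(570_686, n_groups=100, n_reps=1, seed=0)
        sizes = sorted(len(g) for g in groups)
        assert max(sizes) == 5707
        assert sizes.count(5707) == 86 and sizes.count(5706) == 14

    def test_singletons(self):
        groups = rp.sample_column_groups(10, n_groups=10, n_reps=1, seed=0)
        assert all(len(g) == 1 for g in groups)

    def test_partition_per_repetition(self):
        groups = rp.sample_column_groups(103, n_groups=7, n_reps=3, seed=1)
        assert len(groups) == 21
        for rep in range(3):
            rep_groups = groups[rep * 7 : (rep + 1) * 7]
            allidx = np.concatenate(rep_groups)
            assert len(allidx) == 103 and len(np.unique(allidx)) == 103


class TestConsensus:
    def test_identical_trees(self):
        trees = [parse_newick("((A,B),(C,D),E);") for _ in range(4)]
        cons = rp.majority_consensus(trees)
        assert rp.rf_distance(cons, trees[0]) == 0

    def test_two_of_three_split_retained_with_support(self):
        t1 = parse_newick("((A,B),C,(D,E));")
        t2 = parse_newick("((A,B),D,(C,E));")
        t3 = parse_newick("((A,C),B,(D,E));")
        cons = rp.majority_consensus([t1, t2, t3])
        splits = rp.tree_splits(cons)
        assert frozenset({"A", "B"}) in splits or frozenset({"C", "D", "E"}) in splits
        supports = [
            n.label for n in cons.preorder_node_iter() if n.label is not None
        ]
        assert any(s and abs(float(s) - 2 / 3) < 1e-3 for s in supports)

    def test_exactly_half_excluded(self):
        t1 = parse_newick("((A,B),(C,D),E);")
        t2 = parse_newick("((A,C),(B,D),E);")
        cons = rp.majority_consensus([t1, t2])
        assert rp.tree_splits(cons) == set()  # star tree

    def test_different_leaf_sets_rejected(self):
        with pytest.raises(ValueError):
            rp.majority_consensus(
                [parse_newick("(A,B,C);"), parse_newick("(A,B,D);")]
            )


class TestRfAndTopology:
    def test_identical_trees_zero(self, butterfly_tree):
        assert rp.rf_distance(butterfly_tree, parse_newick(rp.TRADITIONAL_NEWICK)) == 0

    def test_four_taxon_alternative_resolutions(self):
        t1 = parse_newick("((A,B),(C,D));")
        t2 = parse_newick("((A,C),(B,D));")
        assert rp.rf_distance(t1, t2) == 2
        assert rp.rf_distance(t2, t1) == 2

    def test_topology_report_three_way(self):
        assert rp.topology_report(parse_newick(rp.TRADITIONAL_NEWICK)) == "traditional"
        assert rp.topology_report(parse_newick(rp.ALTERNATE_NEWICK)) == "alternate"
        pgl_lac = parse_newick("(((((Mci,Hme),Dpl),(Pgl,Lac))),Bmo,Pxy);")
        assert rp.topology_report(pgl_lac) == "other"


class TestEncodingInvariance:
    def _truth_families(self, seed=0):
        tree = parse_newick(rp.TRADITIONAL_NEWICK)
        truth = synthio.simulate_gene_orders(
            tree, n_families=200, n_scaffolds=4, seed=seed
        )
        return truth, rp.families_from_tables(truth.tables)

    def test_coordinate_offset_and_renaming_change_no_state(self):
        truth, fams = self._truth_families()
        species = sorted(truth.tables)
        base = rp.orientation_matrix(
            rp.select_disjoint_pairs(rp.resolvable_pairs(fams, species)), species
        )
        shifted = {}
        for fid, fam in fams.items():
            nf = OrthologFamily(fid)
            for sp, members in fam.members.items():
                nf.members[sp] = [
                    (g, "scaffold_" + scf, start + 10_000, strand)
                    for g, scf, start, strand in members
                ]
            shifted[fid] = nf
        moved = rp.orientation_matrix(
            rp.select_disjoint_pairs(rp.resolvable_pairs(shifted, species)), species
        )
        assert moved.strings == base.strings

    def test_inverting_one_gene_flips_pair_state(self):
        strands_of = {"A": "++", "B": "--", "C": "+-", "D": "-+"}
        flip_first = {"A": "D", "B": "C", "C": "B", "D": "A"}
        flip_second = {"A": "C", "B": "D", "C": "A", "D": "B"}
        for s_in, (sa, sb) in strands_of.items():
            fa = "-" if sa == "+" else "+"
            fb = "-" if sb == "+" else "+"
            a, b = ("ga", "s1", 0), ("gb", "s1", 100)
            assert rp.orientation_state(a + (fa,), b + (sb,)) == flip_first[s_in]
            assert rp.orientation_state(a + (sa,), b + (fb,)) == flip_second[s_in]


class TestEndToEndRecovery:
    def test_pipeline_recovers_true_topology_small(self, butterfly_tree):
        """3-seed smoke version of the 50-seed recovery experiment."""
        hits = 0
        for seed in range(3):
            truth = synthio.simulate_gene_orders(butterfly_tree, seed=seed)
            fams = rp.families_from_tables(truth.tables)
            tree, matrix = rp.rearrangement_tree(fams, sorted(truth.tables))
            assert len(matrix.pairs) >= 300
            hits += rp.rf_distance(tree, butterfly_tree) == 0
        assert hits == 3
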