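"""Newick handling, grafting, bladj calibration, polytomy resolution and
cophenetic distances."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sympatree import (
    AgeTable,
    CalibrationConflictError,
    NewickParseError,
    TaxonPath,
    TreeError,
    calibrate_bladj,
    cophenetic,
    graft_taxa,
    parse_newick,
    resolve_polytomies,
    write_newick,
)
from sympatree.trees import Tree

from conftest import brute_force_path_distance, random_calibrated_tree


# ---------------------------------------------------------------------------
# Newick parse / write
# ---------------------------------------------------------------------------


class TestNewick:
    def test_four_tip_structure(self):
        tree = parse_newick("((A:1,B:1):2,(C:1,D:1):2);")
        assert sorted(tree.tip_names()) == ["A", "B", "C", "D"]
        assert len(tree.root.children) == 2
        assert tree.n_tips() == 4

    def test_single_tip_under_root(self):
        tree = parse_newick("(A);")
        assert tree.tip_names() == ["A"]

    @pytest.mark.parametrize(
        "bad", ["((A,B)", "", "(A,B);x", "(A,B)", "(A,,B);", "A:x;"]
    )
    def test_malformed_raises_with_offset(self, bad):
        with pytest.raises(NewickParseError) as err:
            parse_newick(bad)
        assert err.value.offset >= 0

    def test_duplicate_tip_names_rejected(self):
        with pytest.raises(TreeError, match="duplicate"):
            parse_newick("(A,A);")

    def test_round_trip_preserves_names_and_lengths(self):
        text = "((A:1,B:1)ab:2,(C:1.5,D:0.5)cd:2)r;"
        assert write_newick(parse_newick(text)) == text

    def test_tree_without_lengths_has_no_colons(self):
        assert ":" not in write_newick(parse_newick("((A,B),(C,D));"))

    def test_interior_names_emitted_after_paren(self):
        out = write_newick(parse_newick("((A,B)inner)root;"))
        assert ")inner" in out and ")root" in out

    def test_quoted_labels_round_trip(self):
        text = "('sp one':1,'it''s':2);"
        tree = parse_newick(text)
        assert set(tree.tip_names()) == {"sp one", "it's"}
        assert write_newick(tree) == text


def _random_newick(rng, depth=0):
    if depth > 3 or rng.random() < 0.3:
        return f"t{rng.integers(1_000_000)}:{rng.integers(1, 50)}"
    k = rng.integers(2, 4)
    inner = ",".join(_random_newick(rng, depth + 1) for _ in range(k))
    name = f"n{rng.integers(1_000_000)}" if rng.random() < 0.5 else ""
    return f"({inner}){name}:{rng.integers(1, 50)}"


@given(st.integers(0, 10_000))
@settings(max_examples=60, deadline=None)
def test_write_parse_identity_on_random_trees(seed):
    rng = np.random.default_rng(seed)
    text = "(" + _random_newick(rng) + "," + _random_newick(rng) + ");"
    try:
        tree = parse_newick(text)
    except TreeError:
        return  # rare duplicate random labels
    assert write_newick(parse_newick(write_newick(tree))) == write_newick(tree)


def test_parse_agrees_with_dendropy_on_cophenetic():
    dendropy = pytest.importorskip("dendropy")
    rng = np.random.default_rng(7)
    tree = random_calibrated_tree(rng, 16)
    text = write_newick(tree)
    dtree = dendropy.Tree.get(data=text, schema="newick")
    pdm = dtree.phylogenetic_distance_matrix()
    D = cophenetic(tree)
    taxa = {t.label: t for t in dtree.taxon_namespace}
    for i, a in enumerate(D.labels):
        for b in D.labels[i + 1:]:
            assert pdm.distance(taxa[a], taxa[b]) == pytest.approx(D.get(a, b))


# ---------------------------------------------------------------------------
# Grafting
# ---------------------------------------------------------------------------


BACKBONE = "(((Ocotea,Persea)Lauraceae,(Myrcia)Myrtaceae)core)root;"


class TestGraft:
    def test_graft_into_existing_genus(self):
        result = graft_taxa(
            parse_newick(BACKBONE),
            [TaxonPath("Lauraceae", "Ocotea", "Ocotea_sp1")],
        )
        tree = result.tree
        assert tree.tip_names() == ["Ocotea_sp1"]
        assert tree.find("Ocotea") is not None
        assert not result.skipped

    def test_new_genus_created_under_family(self):
        result = graft_taxa(
            parse_newick(BACKBONE),
            [TaxonPath("Lauraceae", "Nectandra", "Nectandra_sp1")],
        )
        genus = result.tree.find("Nectandra")
        assert genus is not None
        assert genus.parent.name == "Lauraceae"
        assert [t.name for t in genus.children] == ["Nectandra_sp1"]

    def test_congeners_form_cherry_and_backbone_pruned(self):
        result = graft_taxa(
            parse_newick(BACKBONE),
            [
                TaxonPath("Lauraceae", "Nectandra", "N_a"),
                TaxonPath("Lauraceae", "Nectandra", "N_b"),
            ],
        )
        genus = result.tree.find("Nectandra")
        assert sorted(t.name for t in genus.children) == ["N_a", "N_b"]
        # pre-existing backbone tips not in the list are gone
        assert sorted(result.tree.tip_names()) == ["N_a", "N_b"]

    def test_case_insensitive_matching(self):
        result = graft_taxa(
            parse_newick(BACKBONE),
            [TaxonPath("LAURACEAE", "ocotea", "Ocotea odorifera")],
        )
        assert result.tree.tip_names() == ["Ocotea_odorifera"]

    def test_unknown_family_skipped_not_fatal(self):
        result = graft_taxa(
            parse_newick(BACKBONE),
            [
                TaxonPath("Lauraceae", "Ocotea", "O_x"),
                TaxonPath("Unknownaceae", "Mystery", "M_y"),
            ],
        )
        assert result.tree.tip_names() == ["O_x"]
        assert [t.family for t in result.skipped] == ["Unknownaceae"]

    def test_empty_taxon_list_is_error(self):
        with pytest.raises(TreeError):
            graft_taxa(parse_newick(BACKBONE), [])


# ---------------------------------------------------------------------------
# bladj
# ---------------------------------------------------------------------------


class TestBladj:
    def test_chain_even_spacing(self):
        tree = parse_newick("(((T)u2)u1)root;")
        cal = calibrate_bladj(tree, AgeTable({"root": 10.0}))
        ages = {n.name: n.age for n in cal.preorder()}
        assert ages["u1"] == pytest.approx(20 / 3)
        assert ages["u2"] == pytest.approx(10 / 3)
        assert ages["T"] == 0.0

    def test_fully_dated_tree_unchanged(self):
        tree = parse_newick("((A,B)x,(C,D)y)r;")
        cal = calibrate_bladj(tree, AgeTable({"r": 10.0, "x": 4.0, "y": 7.0}))
        ages = {n.name: n.age for n in cal.interior()}
        assert ages == {"r": 10.0, "x": 4.0, "y": 7.0}

    def test_descendant_older_than_ancestor_is_conflict(self):
        tree = parse_newick("((A,B)old)root;")
        with pytest.raises(CalibrationConflictError) as err:
            calibrate_bladj(tree, AgeTable({"root": 10.0, "old": 12.0}))
        assert "old" in str(err.value) and "root" in str(err.value)

    def test_root_age_argument_used_when_root_undated(self):
        tree = parse_newick("((A,B)x);")
        cal = calibrate_bladj(tree, AgeTable({"x": 5.0}), root_age=20.0)
        assert cal.root.age == 20.0

    def test_missing_root_age_is_error(self):
        with pytest.raises(TreeError):
            calibrate_bladj(parse_newick("((A,B)x);"), AgeTable({"x": 5.0}))

    def test_age_table_name_absent_from_tree_is_error(self):
        with pytest.raises(TreeError, match="ghost"):
            calibrate_bladj(parse_newick("(A,B)r;"),
                            AgeTable({"r": 5.0, "ghost": 1.0}))

    @pytest.mark.parametrize("seed", range(25))
    def test_random_chains_match_closed_formula(self, seed):
        # a > b with k undated nodes between them: i-th gets a - i(a-b)/(k+1)
        rng = np.random.default_rng(seed)
        k = int(rng.integers(1, 7))
        a = float(rng.uniform(20, 100))
        b = float(rng.uniform(0.5, a - 10))
        # chain A -> u1 -> ... -> uk -> B(cherry), with only A and B dated
        from sympatree.trees import Node, Tree

        top = Node("A")
        cur = top
        for i in range(1, k + 1):
            cur = cur.add_child(Node(f"u{i}"))
        bnode = cur.add_child(Node("B"))
        bnode.add_child(Node("TIP1"))
        bnode.add_child(Node("TIP2"))
        tree = Tree(top)
        cal = calibrate_bladj(tree, AgeTable({"A": a, "B": b}))
        ages = {n.name: n.age for n in cal.preorder()}
        for i in range(1, k + 1):
            assert ages[f"u{i}"] == pytest.approx(a - i * (a - b) / (k + 1))

    @pytest.mark.parametrize("seed", range(10))
    def test_random_trees_all_branch_lengths_nonneg_and_dated_exact(self, seed):
        rng = np.random.default_rng(100 + seed)
        tree = random_calibrated_tree(rng, 24, max_children=4)
        # keep a random subset of interior dates; bladj must restore a valid tree
        dated = {}
        for node in tree.interior():
            if node.parent is None or rng.random() < 0.4:
                dated[node.name] = node.age
        bare = parse_newick(write_newick(tree))
        cal = calibrate_bladj(bare, AgeTable(dated))
        for node in cal.preorder():
            if node.parent is not None:
                assert node.length >= 0
            if node.name in dated:
                assert node.age == dated[node.name]  # bit-exact


# ---------------------------------------------------------------------------
# Polytomy resolution
# ---------------------------------------------------------------------------


class TestResolve:
    def test_binary_tree_topologically_unchanged(self, four_tip_tree):
        out = resolve_polytomies(four_tip_tree, seed=1)
        assert write_newick(out) == write_newick(four_tip_tree)

    def test_trichotomy_choices_uniform(self):
        from scipy.stats import chisquare

        tree = parse_newick("(A,B,C)r;")
        cal = calibrate_bladj(tree, AgeTable({"r": 9.0}))
        counts = {"AB": 0, "AC": 0, "BC": 0}
        n = 10_000
        for seed in range(n):
            out = resolve_polytomies(cal, seed=seed)
            for node in out.interior():
                kids = sorted(c.name for c in node.children if c.is_tip)
                if len(kids) == 2 and node.parent is not None:
                    counts["".join(kids)] += 1
        assert sum(counts.values()) == n
        stat, p = chisquare(list(counts.values()))
        assert p > 1e-4  # uniform over the three rooted resolutions

    def test_four_child_polytomy_counts_and_ages(self):
        tree = parse_newick("(A,B,C,D)r;")
        cal = calibrate_bladj(tree, AgeTable({"r": 8.0}))
        out = resolve_polytomies(cal, seed=5)
        assert out.is_binary()
        assert len(out.interior()) == out.n_tips() - 1 == 3
        for node in out.interior():
            if node.parent is not None:
                assert 0 < node.age < node.parent.age

    def test_same_seed_same_output_different_seed_differs(self):
        tree = parse_newick("(A,B,C,D,E,F)r;")
        cal = calibrate_bladj(tree, AgeTable({"r": 8.0}))
        a = write_newick(resolve_polytomies(cal, seed=11))
        b = write_newick(resolve_polytomies(cal, seed=11))
        assert a == b
        outs = {write_newick(resolve_polytomies(cal, seed=s)) for s in range(20)}
        assert len(outs) > 1

    def test_distances_outside_polytomy_unchanged(self):
        # ((A,B,C)p,(D,E)q)r: only pairs inside the p-polytomy may change
        tree = parse_newick("((A,B,C)p,(D,E)q)r;")
        cal = calibrate_bladj(tree, AgeTable({"r": 10.0, "p": 4.0, "q": 6.0}))
        D0 = cophenetic(cal)
        out = resolve_polytomies(cal, seed=3)
        D1 = cophenetic(out)
        poly = {"A", "B", "C"}
        for i, a in enumerate(D0.labels):
            for b in D0.labels[i + 1:]:
                if not ({a, b} <= poly):
                    assert D1.get(a, b) == pytest.approx(D0.get(a, b))


# ---------------------------------------------------------------------------
# Cophenetic distances
# ---------------------------------------------------------------------------


class TestCophenetic:
    def test_four_tip_values(self, four_tip_D):
        D = four_tip_D
        assert D.get("A", "B") == 2.0
        assert D.get("C", "D") == 2.0
        for a, b in (("A", "C"), ("A", "D"), ("B", "C"), ("B", "D")):
            assert D.get(a, b) == 6.0

    def test_zero_diagonal_and_symmetry(self, four_tip_D):
        assert np.all(np.diag(four_tip_D.values) == 0)
        assert np.array_equal(four_tip_D.values, four_tip_D.values.T)

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_brute_force_path_sums(self, seed):
        rng = np.random.default_rng(seed)
        tree = random_calibrated_tree(rng, int(rng.integers(4, 33)), max_children=4)
        D = cophenetic(tree)
        for i, a in enumerate(D.labels):
            for b in D.labels[i + 1:]:
                assert D.get(a, b) == pytest.approx(
                    brute_force_path_distance(tree, a, b)
                )

    def test_ultrametric_three_point_condition(self):
        rng = np.random.default_rng(99)
        tree = random_calibrated_tree(rng, 12, max_children=3)
        D = cophenetic(tree)
        n = len(D)
        import itertools

        for i, j, k in itertools.combinations(range(n), 3):
            d = sorted([D.values[i, j], D.values[i, k], D.values[j, k]])
            assert d[2] == pytest.approx(d[1])
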