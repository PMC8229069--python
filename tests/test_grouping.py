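"""Profile distances, group partitioning, UPGMA trees, and Newick output."""

import itertools
import random

import dendropy
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from satprofile.grouping import (
    partition_profiles,
    profile_distance,
    profile_distance_matrix,
    state_distance,
    to_newick,
    upgma,
)
from satprofile.profiling import ProfileMatrix

from conftest import CON2_GROUP1

CODES = "ACGTRYSWKMBDHVN"


@pytest.mark.parametrize(
    "s1,s2,expected",
    [("A", "A", 0.0), ("A", "G", 1.0), ("A", "R", 0.5), ("R", "R", 0.0), ("R", "Y", 1.0)],
)
def test_state_distance_examples(s1, s2, expected):
    assert state_distance(s1, s2) == pytest.approx(expected)


def test_profile_distance_identity_and_shared_columns():
    assert profile_distance(("A", "R", "C"), ("A", "R", "C")) == 0.0
    # missing column excluded from the average
    assert profile_distance(("A", "-", "C"), ("G", "A", "C")) == pytest.approx(0.5)
    with pytest.raises(ValueError, match="p1.*p2|no shared"):
        profile_distance(("-", "N"), ("A", "-"), ids=("p1", "p2"))


def test_con2_group_profiles_vs_reference(con2_run):
    """Group 1 differs from the reference at exactly 1 of 8 columns; group 4 at 6."""
    _, _, _, matrix = con2_run
    ref = matrix.reference_profile()
    g1 = matrix.profile("D. parvula")
    g4 = matrix.profile("D. danthonioides")
    assert sum(a != b for a, b in zip(g1, ref)) == 1
    assert sum(a != b for a, b in zip(g4, ref)) == 6
    assert profile_distance(g1, ref) > 0.0


@settings(deadline=None, derandomize=True, max_examples=60)
@given(
    p=st.lists(st.sampled_from(CODES[:14]), min_size=1, max_size=10),
    q=st.data(),
)
def test_profile_distance_metric_axioms(p, q):
    """Identity of indiscernibles, symmetry, and the triangle inequality on
    random profile triples without missing states."""
    n = len(p)
    r = [q.draw(st.sampled_from(CODES[:14])) for _ in range(n)]
    s = [q.draw(st.sampled_from(CODES[:14])) for _ in range(n)]
    d_pr = profile_distance(p, r)
    assert d_pr == pytest.approx(profile_distance(r, p))
    assert profile_distance(p, p) == 0.0
    if tuple(p) != tuple(r):
        assert d_pr > 0.0
    assert d_pr <= profile_distance(p, s) + profile_distance(s, r) + 1e-12


def _matrix_from_profiles(profiles: dict[str, tuple[str, ...]], n_cols: int) -> ProfileMatrix:
    lines = ["# family: X", "# reference: ref", "accession\t" + "\t".join(str(p) for p in range(n_cols))]
    lines.append("ref\t" + "\t".join("A" * n_cols))
    for sid, prof in profiles.items():
        lines.append(sid + "\t" + "\t".join(prof))
    return ProfileMatrix.from_tsv("\n".join(lines) + "\n")


def test_partition_all_identical_single_group():
    m = _matrix_from_profiles({f"s{i}": ("G", "C") for i in range(5)}, 2)
    part = partition_profiles(m)
    assert part.sizes == [5]


def test_partition_all_distinct():
    profs = {"s0": ("A", "A"), "s1": ("G", "A"), "s2": ("R", "A"), "s3": ("A", "C")}
    part = partition_profiles(_matrix_from_profiles(profs, 2))
    assert part.sizes == [1, 1, 1, 1]


def test_con2_partition_groups_and_membership(con2_run):
    _, _, _, matrix = con2_run
    part = partition_profiles(matrix)
    assert part.sizes == [4, 6, 2, 1]
    assert part.groups[0].members == CON2_GROUP1
    assert set(part.groups[1].members) == {
        "D. sukatschewii",
        "D. cespitosa PI-562652",
        "D. cespitosa PI-577069",
        "D. cespitosa PI-371724",
        "D. elongata",
        "D. flexuosa",
    }
    assert set(part.groups[2].members) == {"H. pubescens", "K. macrantha"}
    assert part.groups[3].members == ["D. danthonioides"]


def test_partition_invariant_under_sample_reordering(con2_run):
    """Permuting input order changes group ordering only, never membership."""
    _, _, _, matrix = con2_run
    part = partition_profiles(matrix)
    canonical = {frozenset(g.members) for g in part.groups}
    rng = random.Random(123)
    for _ in range(5):
        order = list(matrix.sample_ids)
        rng.shuffle(order)
        shuffled = ProfileMatrix(
            family=matrix.family,
            reference_id=matrix.reference_id,
            columns=matrix.columns,
            sample_ids=order,
        )
        assert {frozenset(g.members) for g in partition_profiles(shuffled).groups} == canonical


def test_upgma_two_leaves():
    tree = upgma(np.array([[0.0, 0.2], [0.2, 0.0]]), ["A", "B"])
    assert tree.root.height == pytest.approx(0.1)
    assert to_newick(tree) == "(A:0.1,B:0.1);"


def test_upgma_three_leaves_hand_executed():
    """d(A,B)=0.2, d(A,C)=d(B,C)=0.8 -> ((A,B),C) with root height 0.4."""
    D = np.array([[0.0, 0.2, 0.8], [0.2, 0.0, 0.8], [0.8, 0.8, 0.0]])
    tree = upgma(D, ["A", "B", "C"])
    assert tree.root.height == pytest.approx(0.4)
    ab = [ch for ch in tree.root.children if len(ch.leaf_labels()) == 2][0]
    assert sorted(ab.leaf_labels()) == ["A", "B"]
    assert ab.height == pytest.approx(0.1)
    assert tree.is_monophyletic({"A", "B"})
    assert not tree.is_monophyletic({"A", "C"})


def test_upgma_rejects_negative_distances():
    with pytest.raises(ValueError, match="negative"):
        upgma(np.array([[0.0, -0.1], [-0.1, 0.0]]), ["A", "B"])


def _random_distance_matrix(rng, n):
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = rng.uniform(0.05, 1.0)
    return D


def test_upgma_heights_monotone_rootward():
    """Cluster heights never decrease along any root-ward path."""
    rng = random.Random(99)
    for _ in range(20):
        n = rng.randint(2, 8)
        tree = upgma(_random_distance_matrix(rng, n), [f"L{i}" for i in range(n)])

        def walk(node):
            for ch in node.children:
                assert ch.height <= node.height + 1e-12
                walk(ch)

        walk(tree.root)


def test_upgma_matches_scipy_average_linkage():
    """On tie-free random matrices the root height agrees with scipy's
    average-linkage cophenetic height (independent oracle)."""
    from scipy.cluster.hierarchy import average
    from scipy.spatial.distance import squareform

    rng = random.Random(7)
    for _ in range(10):
        n = rng.randint(3, 7)
        D = _random_distance_matrix(rng, n)
        tree = upgma(D, [f"L{i}" for i in range(n)])
        Z = average(squareform(D))
        assert tree.root.height == pytest.approx(Z[-1, 2] / 2.0)


def test_newick_round_trip_via_dendropy():
    rng = random.Random(42)
    for _ in range(10):
        n = rng.randint(2, 8)
        labels = [f"leaf {i}" for i in range(n)]  # spaces force quoting
        tree = upgma(_random_distance_matrix(rng, n), labels)
        newick = to_newick(tree)
        parsed = dendropy.Tree.get(data=newick, schema="newick")
        assert sorted(t.label for t in parsed.taxon_namespace) == sorted(labels)
        # ultrametric root-to-leaf distances reproduce the UPGMA heights
        parsed.calc_node_ages(ultrametricity_precision=1e-6)
        for leaf in parsed.leaf_node_iter():
            assert leaf.distance_from_root() == pytest.approx(tree.root.height, abs=1e-9)


def test_newick_single_leaf_degenerate():
    tree = upgma(np.zeros((1, 1)), ["A"])
    assert to_newick(tree) == "A:0.0;"


def test_con2_tree_antarctica_parvula_clade(con2_run):
    """The three D. antarctica accessions and D. parvula form one clade."""
    _, _, _, matrix = con2_run
    labels, D = profile_distance_matrix(matrix)
    tree = upgma(D, labels)
    assert tree.is_monophyletic(CON2_GROUP1)


def test_upgma_deterministic_tiebreak():
    """All-equal distances: merges proceed by lexicographically smallest label."""
    D = np.full((3, 3), 0.6)
    np.fill_diagonal(D, 0.0)
    tree = upgma(D, ["C", "A", "B"])
    first = [ch for ch in tree.root.children if len(ch.leaf_labels()) == 2][0]
    assert sorted(first.leaf_labels()) == ["A", "B"]
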