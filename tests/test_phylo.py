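"""Alignment, similarity matrices, neighbor joining, bootstrap and clades."""

import numpy as np
import pytest

from cd28fam.errors import PhyloError
from cd28fam.phylo import (
    DistanceMatrix,
    align_global,
    bootstrap_support,
    clade_membership,
    nj_tree,
    poisson_distance_matrix,
    progressive_msa,
    similarity_matrix,
)

from helpers import (
    oracle_alignment_score,
    oracle_clade_membership,
    random_additive_matrix,
)


def test_self_alignment_is_identity_100():
    r = align_global("MKLLVV", "MKLLVV")
    assert r.percent_identity == 100.0
    assert r.aligned_a == r.aligned_b == "MKLLVV"


def test_ppp_pap_identity_two_thirds():
    r = align_global("PPP", "PAP")
    assert r.percent_identity == pytest.approx(66.67, abs=0.01)
    assert r.score == oracle_alignment_score("PPP", "PAP")


def test_alignment_restores_inputs_when_degapped():
    r = align_global("ACDEFGHIK", "ACDFGIK")
    assert r.aligned_a.replace("-", "") == "ACDEFGHIK"
    assert r.aligned_b.replace("-", "") == "ACDFGIK"
    assert len(r.aligned_a) == len(r.aligned_b)


def test_alignment_score_matches_exhaustive_enumeration():
    rng = np.random.default_rng(7)
    aa = list("ACDEFGHIKLMNPQRSTVWY")
    for _ in range(25):
        a = "".join(rng.choice(aa, size=int(rng.integers(1, 6))))
        b = "".join(rng.choice(aa, size=int(rng.integers(1, 6))))
        assert align_global(a, b).score == pytest.approx(
            oracle_alignment_score(a, b)
        ), (a, b)


def test_alignment_rejects_empty_input():
    with pytest.raises(PhyloError):
        align_global("", "PPP")


def test_exemplars_same_family_different_seeds_similar_not_identical(exemplar):
    # different seeds share only the planted motif architecture, so identity
    # sits well above the ~14% scaffold-only baseline but below 100
    a, _ = exemplar("CD28", seed=1)
    b, _ = exemplar("CD28", seed=2)
    pid = align_global(a.sequence, b.sequence).percent_identity
    assert 20.0 < pid < 100.0


def test_similarity_matrix_symmetric_unit_diagonal(exemplar):
    records = [exemplar(f, seed=i)[0] for i, f in enumerate(("CD28", "CTLA4", "CD28H"))]
    df = similarity_matrix(records)
    m = df.to_numpy()
    assert np.allclose(m, m.T)
    assert np.allclose(np.diag(m), 100.0)
    assert (m[~np.eye(3, dtype=bool)] < 100.0).all()


def test_similarity_matrix_permutation_equivariant(exemplar):
    records = [exemplar(f, seed=i)[0] for i, f in enumerate(("CD28", "CTLA4", "CD28H"))]
    df = similarity_matrix(records)
    df_perm = similarity_matrix(records[::-1])
    reordered = df_perm.loc[df.index, df.columns]
    assert np.allclose(df.to_numpy(), reordered.to_numpy())


def test_nj_three_taxa_closed_form():
    labels = ("a", "b", "c")
    d = np.array([[0, 3, 5], [3, 0, 6], [5, 6, 0]], float)
    tree = nj_tree(DistanceMatrix(labels, d))
    lengths = {t.name: t.length for t in tree.tips()}
    # three-point formulas: la = (dab + dac - dbc) / 2, etc.
    assert lengths["a"] == pytest.approx(1.0)
    assert lengths["b"] == pytest.approx(2.0)
    assert lengths["c"] == pytest.approx(4.0)


def test_nj_recovers_four_leaf_additive_tree():
    # tree ((a:2,b:3):1,(c:4,d:5)) -> additive distances
    labels = ("a", "b", "c", "d")
    d = np.array(
        [[0, 5, 7, 8], [5, 0, 8, 9], [7, 8, 0, 9], [8, 9, 9, 0]], float
    )
    tree = nj_tree(DistanceMatrix(labels, d))
    # topology: a+b against c+d
    sides = [frozenset(t.name for t in n.tips()) for n in tree.non_tips()]
    assert frozenset("ab") in sides or frozenset("cd") in sides
    tt = tree.tip_tip_distances()
    ids = list(tt.ids)
    for i, x in enumerate(labels):
        for j, y in enumerate(labels):
            assert tt[ids.index(x), ids.index(y)] == pytest.approx(d[i, j], abs=1e-9)


def test_nj_reproduces_random_additive_path_lengths():
    for rep in range(10):
        labels, m, _ = random_additive_matrix(8, seed=rep)
        tree = nj_tree(DistanceMatrix(labels, m))
        tt = tree.tip_tip_distances()
        ids = list(tt.ids)
        for i, x in enumerate(labels):
            for j, y in enumerate(labels):
                assert abs(tt[ids.index(x), ids.index(y)] - m[i, j]) < 1e-9


def test_nj_rejects_bad_input():
    with pytest.raises(PhyloError):
        DistanceMatrix(("a", "b"), np.array([[0, 1], [2, 0]], float))  # asymmetric
    with pytest.raises(PhyloError):
        nj_tree(DistanceMatrix(("a", "b"), np.zeros((2, 2))))  # too few taxa


def test_poisson_distance_cap_on_saturated_pairs():
    with pytest.warns(UserWarning):
        dm = poisson_distance_matrix(("a", "b"), ("AAAA", "CCCC"))
    assert dm.values[0, 1] == 10.0


def test_bootstrap_single_replicate_supports_are_zero_or_hundred():
    rows = [
        ("a", "MKLLVVAAAE"),
        ("b", "MKLLVVAAAD"),
        ("c", "MKILVVSATE"),
        ("d", "WWHHHPPGGE"),
        ("e", "WWHHHPPGGD"),
    ]
    st = bootstrap_support(rows, n_reps=1, seed=3)
    assert set(st.support.values()) <= {0.0, 100.0}


def test_bootstrap_reproducible_and_taxon_order_invariant():
    rows = [
        ("a", "MKLLVVAAAE"),
        ("b", "MKLLVVAAAD"),
        ("c", "MKILVVSATE"),
        ("d", "WWHHHPPGGE"),
    ]
    s1 = bootstrap_support(rows, n_reps=25, seed=11)
    s2 = bootstrap_support(rows, n_reps=25, seed=11)
    s3 = bootstrap_support(rows[::-1], n_reps=25, seed=11)
    assert s1.support == s2.support == s3.support
    assert s1.newick == s2.newick


def test_bootstrap_strong_split_gets_high_support(catalog):
    # two clearly separated 4-taxon clusters: four mutated descendants of one
    # CD28 scaffold against four of an unrelated CD28X scaffold (within-group
    # divergence 0.10 per copy, between-group scaffolds independent)
    from cd28fam.simulate import SimProteinConfig, simulate_family_protein

    rows = []
    for i in range(4):
        r, _ = simulate_family_protein(
            SimProteinConfig(family="CD28", seed=1, divergence=0.10, mutation_seed=300 + i),
            profiles=catalog,
        )
        rows.append((f"cd28.{i}", r.sequence))
    for i in range(4):
        r, _ = simulate_family_protein(
            SimProteinConfig(family="CD28X", seed=2, divergence=0.10, mutation_seed=400 + i),
            profiles=catalog,
        )
        rows.append((f"cd28x.{i}", r.sequence))
    msa = progressive_msa(rows)
    st = bootstrap_support(msa, n_reps=100, seed=5)
    left = frozenset(label for label, _ in rows[:4])
    right = frozenset(label for label, _ in rows[4:])
    key = [k for k in st.support if k in (left, right)]
    assert key, "between-cluster bipartition absent from NJ tree"
    assert st.support[key[0]] >= 95.0


def test_progressive_msa_rows_degap_to_inputs(exemplar):
    records = [exemplar(f, seed=i)[0] for i, f in enumerate(("CD28", "CTLA4", "ICOS", "CD28H"))]
    rows = progressive_msa(records)
    assert len({len(s) for _, s in rows}) == 1
    for record, (label, row) in zip(records, rows):
        assert label == record.id
        assert row.replace("-", "") == record.sequence


def test_clade_membership_inside_and_outside():
    nwk = "((a:1,b:1):1,(c:1,(d:1,e:1):1):1,f:1);"
    assert clade_membership(nwk, "e", ["c", "d"])
    assert not clade_membership(nwk, "a", ["c", "d"])


def test_clade_membership_star_tree_false():
    assert not clade_membership("(a:1,b:1,c:1,d:1);", "a", ["b", "c"])


def test_clade_membership_missing_label_raises():
    with pytest.raises(PhyloError):
        clade_membership("(a:1,b:1,(c:1,d:1):1);", "z", ["a"])


def test_clade_membership_matches_bipartition_oracle():
    rng = np.random.default_rng(13)
    for rep in range(12):
        _, _, newick = random_additive_matrix(8, seed=900 + rep)
        taxa = [f"t{i}" for i in range(8)]
        for _ in range(6):
            candidate = str(rng.choice(taxa))
            n_refs = int(rng.integers(1, 4))
            refs = [t for t in rng.choice(taxa, size=n_refs, replace=False) if t != candidate]
            if not refs:
                continue
            got = clade_membership(newick, candidate, refs)
            want = oracle_clade_membership(newick, candidate, refs)
            assert got == want, (newick, candidate, refs)
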