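"""Repeat masking, motif typing, p-distances, NJ and bootstrap."""

import numpy as np
import pytest

from rlecfam import (
    DistanceMatrix,
    FAMILY_MOTIFS,
    NucSequence,
    assign_types,
    bootstrap_support,
    decompose,
    extract_motif,
    mask_repeats,
    n_types,
    nj_tree,
    p_distance,
    p_distance_matrix,
    translate,
)
from rlecfam.classify import DistanceError, MaskError

from conftest import ls_topology_search, random_additive_matrix


# --- masking ---------------------------------------------------------------


def test_mask_removes_repeat_block(family20_clean):
    """A 297-aa protein with a 93-aa (279 nt) repeat block masks to 204 aa."""
    m9 = next(m for m in family20_clean.members if m.copy_number == 9)
    assert sum(m9.unit_lengths) in (270, 273, 276, 279, 282, 285, 288, 291, 297)
    prot = translate(m9.cds, (0, len(m9.cds)))
    arr = decompose(NucSequence(m9.id, m9.cds))
    masked = mask_repeats(prot, arr)
    assert len(masked) == len(prot) - sum(m9.unit_lengths) // 3
    assert mask_repeats(prot, None) == prot


def test_mask_out_of_frame_region_errors(family20_clean):
    from rlecfam.repeats import RepeatArray, RepeatUnit

    m = family20_clean.members[0]
    arr = decompose(NucSequence(m.id, m.cds))
    shifted = RepeatArray(
        m.id, arr.units, arr.flank5 + "A", arr.flank3, arr.consensus
    )
    prot = translate(m.cds, (0, len(m.cds)))
    with pytest.raises(MaskError):
        mask_repeats(prot, shifted)
    # snapping tolerates a 1-nt boundary ambiguity
    assert len(mask_repeats(prot, shifted, snap=True)) == \
        len(prot) - arr.region_length // 3


# --- motif extraction ------------------------------------------------------


def test_extract_motif_planted_types(family20_clean):
    fam = family20_clean
    anchor = fam.anchor
    for m in fam.members:
        prot = translate(m.cds, (0, len(m.cds)))
        arr = decompose(NucSequence(m.id, m.cds))
        a = extract_motif(mask_repeats(prot, arr, snap=True), anchor, m.id)
        assert a is not None and a.motif == m.motif


def test_extract_motif_missing_anchor():
    assert extract_motif("M" * 100, ("WWWWWWWW", 8), "x") is None


def test_assign_types_counts(family20):
    motifs = [m.motif for m in family20.members]
    assigns = [
        __import__("rlecfam").MotifAssignment(m.id, m.motif, 1, m.motif)
        for m in family20.members
    ]
    table = assign_types(assigns)
    assert n_types(table) == len(set(motifs))
    assert sum(len(v) for v in table.values()) == len(family20.members)
    # order invariance
    table2 = assign_types(list(reversed(assigns)))
    assert table == table2


def test_assign_types_single_motif():
    from rlecfam import MotifAssignment

    assigns = [MotifAssignment(f"r{i}", "YRSKDD", 1, "YRSKDD") for i in range(4)]
    assert n_types(assign_types(assigns)) == 1


# --- distances -------------------------------------------------------------


def test_p_distance_rules(rng):
    assert p_distance("ACDEF", "ACDEF") == 0.0
    assert p_distance("AAAA", "AAAT") == 0.25
    assert p_distance("A-XA", "AAAA") == 0.0  # gap/X columns excluded
    with pytest.raises(DistanceError):
        p_distance("XX", "AA")
    aas = "ACDEFGHIKLMNPQRSTVWY"
    a = "".join(aas[i] for i in rng.integers(0, 20, size=100))
    b = "".join(aas[i] for i in rng.integers(0, 20, size=100))
    expected = sum(x != y for x, y in zip(a, b)) / 100
    assert p_distance(a, b) == pytest.approx(expected)
    m = p_distance_matrix(["a", "b"], [a, b])
    assert m.d[0, 1] == pytest.approx(expected)


# --- neighbour joining ------------------------------------------------------


def test_nj_three_taxa_closed_form():
    d = np.array([[0, 2, 3], [2, 0, 4], [3, 4, 0]], float)
    t = nj_tree(DistanceMatrix(["a", "b", "c"], d))
    center = 3
    assert t.adj[center][0] == pytest.approx(0.5)
    assert t.adj[center][1] == pytest.approx(1.5)
    assert t.adj[center][2] == pytest.approx(2.5)


def test_nj_recovers_four_taxon_tree():
    # additive distances from ((a:1,b:2):0.5,(c:3,d:1))
    d = np.array(
        [[0, 3, 4.5, 2.5], [3, 0, 5.5, 3.5], [4.5, 5.5, 0, 4],
         [2.5, 3.5, 4, 0]], float
    )
    t = nj_tree(DistanceMatrix(list("abcd"), d))
    assert t.bipartitions() == {frozenset({"c", "d"})}
    lengths = sorted(
        round(bl, 9) for u in t.adj for v, bl in t.adj[u].items() if u < v
    )
    assert lengths == [0.5, 1.0, 1.0, 2.0, 3.0]


def test_nj_matches_exhaustive_ls_search_five_taxa(rng):
    for _ in range(5):
        D, ids, true_bips = random_additive_matrix(rng, 5)
        t = nj_tree(DistanceMatrix(ids, D))
        assert t.bipartitions() == true_bips
        assert ls_topology_search(D, ids) == true_bips


def test_nj_rejects_bad_matrix():
    with pytest.raises(DistanceError):
        DistanceMatrix(["a", "b"], np.array([[0, 1], [2, 0]], float))


# --- bootstrap --------------------------------------------------------------


def test_bootstrap_identical_clades_full_support():
    ids = ["a1", "a2", "b1", "b2"]
    aln = ["AAAAAAAA", "AAAAAAAA", "TTTTTTTT", "TTTTTTTT"]
    t = bootstrap_support(ids, aln, n_reps=100, seed=0)
    assert t.support == {frozenset({"b1", "b2"}): 100.0}


def test_bootstrap_zero_reps_and_determinism(rng):
    ids = [f"s{i}" for i in range(6)]
    aas = "ACDEFGHIKL"
    aln = [
        "".join(aas[j] for j in rng.integers(0, 10, size=40)) for _ in ids
    ]
    t0 = bootstrap_support(ids, aln, n_reps=0, seed=1)
    assert t0.support == {}
    t1 = bootstrap_support(ids, aln, n_reps=50, seed=7)
    t2 = bootstrap_support(ids, aln, n_reps=50, seed=7)
    assert t1.support == t2.support
    assert all(0 <= v <= 100 for v in t1.support.values())


def test_newick_round_trip_with_dendropy(family20):
    """Our newick output parses in dendropy with the same leaf set."""
    dendropy = pytest.importorskip("dendropy")
    ids = [m.id for m in family20.members[:8]]
    aln = []
    rng = np.random.default_rng(3)
    aas = "ACDEFGHIKL"
    for _ in ids:
        aln.append("".join(aas[j] for j in rng.integers(0, 10, size=60)))
    t = bootstrap_support(ids, aln, n_reps=20, seed=2)
    dt = dendropy.Tree.get(data=t.newick(), schema="newick")
    assert {leaf.taxon.label for leaf in dt.leaf_node_iter()} == set(ids)


def test_type_monophyly_with_divergent_types():
    """With between-type divergence >> within-type, each type is a clade."""
    from rlecfam import FamilyConfig, generate_family
    from rlecfam import classify as cl

    fam = generate_family(
        FamilyConfig(
            n_members=12,
            motif_list=FAMILY_MOTIFS[:4],
            seed=21,
            n_slippage_pairs=0,
            n_splice_variants=0,
            substitution_rate=0.002,
            type_divergence_rate=0.5,
        )
    )
    from rlecfam import decompose_family

    arrays = decompose_family([NucSequence(m.id, m.cds) for m in fam.members])
    masked = {}
    for m, arr in zip(fam.members, arrays):
        prot = translate(m.cds, (0, len(m.cds)))
        masked[m.id] = cl.mask_repeats(prot, arr, snap=True)
    ids = [m.id for m in fam.members]
    tree = nj_tree(p_distance_matrix(ids, [masked[i] for i in ids]))
    bips = tree.bipartitions()
    for motif in {m.motif for m in fam.members}:
        clade = frozenset(m.id for m in fam.members if m.motif == motif)
        if 2 <= len(clade) <= len(ids) - 2:
            side = clade if fam.members[0].id not in clade else \
                frozenset(ids) - clade
            assert side in bips, f"type {motif} not monophyletic"
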