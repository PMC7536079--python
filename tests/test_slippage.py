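"""Slipped-strand-mispairing inference and five-class classification."""

import numpy as np
import pytest

from rlecfam import (
    classify_slippage,
    infer_excision,
    plant_slippage_pair,
    scan_family,
    unit_match,
)
from rlecfam.repeats import RepeatArray, RepeatUnit
from rlecfam.simulate import PlantingError

from conftest import oracle_excision_matchings


def _arr(sid, unit_seqs):
    return RepeatArray(
        sid, [RepeatUnit(u, 1.0) for u in unit_seqs], "", "", unit_seqs[0]
    )


def _units(rng, lens, diversify=True):
    u30 = "".join("ACGT"[i] for i in rng.integers(0, 4, size=30))
    u33 = u30[:15] + "CAG" + u30[15:]
    units = [u33 if L == 33 else u30 for L in lens]
    if diversify:
        out = []
        for i, u in enumerate(units):
            s = list(u)
            s[3 * i] = "ACGT"[("ACGT".index(s[3 * i]) + 1) % 4]
            s[3 * i + 1] = "ACGT"[("ACGT".index(s[3 * i + 1]) + 1) % 4]
            out.append("".join(s))
        units = out
    return units


def test_unit_match_thresholds():
    u = "A" * 30
    assert unit_match(u, u)
    assert not unit_match(u, "A" * 33)  # length mismatch
    v = "C" + "A" * 28 + "C"  # 28/30 = 0.933
    assert unit_match(u, v)
    assert not unit_match(u, v, min_identity=0.95)


def test_infer_excision_contiguous_block(rng):
    longer_units = _units(rng, [30] * 9)
    keep = [0, 6, 7, 8]  # delete units 2-6 (1-based)
    shorter_units = [longer_units[i] for i in keep]
    ev = infer_excision(_arr("L", longer_units), _arr("S", shorter_units))
    assert ev is not None
    assert ev.conserved_prefix == 1 and ev.conserved_suffix == 3
    assert [p for p, _ in ev.excised] == [2, 3, 4, 5, 6]
    assert ev.excised_block_contiguous
    # oracle: exactly one valid order-preserving matching
    matchings = oracle_excision_matchings(longer_units, shorter_units)
    assert matchings == [(0, 6, 7, 8)]


def test_infer_excision_degenerate_inputs(rng):
    units = _units(rng, [30] * 4)
    assert infer_excision(_arr("L", units), _arr("S", units)) is None
    foreign = _units(np.random.default_rng(99), [30] * 3)
    assert infer_excision(_arr("L", units), _arr("S", foreign)) is None


def test_excision_soundness_on_random_deletions(rng):
    """Applying the inferred excision to the longer array reproduces the
    shorter array's pattern, for every contiguous internal deletion."""
    for trial in range(10):
        n = int(rng.integers(4, 10))
        lens = [int(rng.choice([30, 33])) for _ in range(n)]
        longer_units = _units(rng, lens)
        a = int(rng.integers(1, n - 1))
        b = int(rng.integers(a + 1, n))
        shorter_units = longer_units[:a] + longer_units[b:]
        ev = infer_excision(_arr("L", longer_units), _arr("S", shorter_units))
        assert ev is not None
        kept = [
            u for i, u in enumerate(longer_units, 1)
            if i not in {p for p, _ in ev.excised}
        ]
        assert [len(u) for u in kept] == [len(u) for u in shorter_units]
        assert ev.excised_block_contiguous


@pytest.mark.parametrize(
    "lens,excise,expected_class",
    [
        # first + last three conserved, 30-nt excisions
        ([33, 30, 30, 30, 30, 30], [2], 1),
        # first two + last conserved, 33-nt excisions
        ([30, 30, 33, 33, 30], [3, 4], 2),
        # first + last conserved, five 30-nt units missing
        ([33, 30, 30, 30, 30, 30, 30, 30], [3, 4, 5, 6, 7], 3),
        # first + last two conserved, 30-nt excisions
        ([33, 30, 30, 30, 30, 30], [3, 4], 4),
        # all-33 array
        ([33, 33, 33, 33, 33], [3, 4], 5),
    ],
)
def test_classification_decision_table(rng, lens, excise, expected_class):
    longer_units = _units(rng, lens)
    shorter_units = [
        u for i, u in enumerate(longer_units, 1) if i not in excise
    ]
    L, S = _arr("L", longer_units), _arr("S", shorter_units)
    ev = infer_excision(L, S)
    assert ev is not None
    assert classify_slippage(ev, L, S) == expected_class


def test_mixed_length_excision_unclassified(rng):
    longer_units = _units(rng, [30, 30, 33, 30, 30, 30])
    shorter_units = [longer_units[i] for i in (0, 1, 4, 5)]  # drop 33+30
    L, S = _arr("L", longer_units), _arr("S", shorter_units)
    ev = infer_excision(L, S)
    assert ev is not None
    assert classify_slippage(ev, L, S) is None


def test_plant_recipes_and_feasibility(rng):
    u30 = "".join("ACGT"[i] for i in rng.integers(0, 4, size=30))
    u33 = u30[:15] + "CTG" + u30[15:]
    # class 3 on the 8-unit founder array -> shorter has 3 units
    founder = [u33] + [u30] * 7
    longer, shorter, truth = plant_slippage_pair(founder, 3, rng)
    assert len(shorter) == 3 and truth["class"] == 3
    assert truth["conserved_suffix"] == 1
    # class 1 on a 6-unit array conserves >= 3 trailing units
    longer, shorter, truth = plant_slippage_pair([u33] + [u30] * 5, 1, rng)
    assert truth["conserved_prefix"] >= 1 and truth["conserved_suffix"] >= 3
    # class 5 demands an all-33 array
    with pytest.raises(PlantingError):
        plant_slippage_pair([u33, u30, u33], 5, rng)


def test_scan_family_planted_pairs(family20):
    """Each planted exemplar pair is recovered with its true class."""
    from rlecfam import NucSequence, decompose_family

    fam = family20
    arrays = decompose_family([NucSequence(m.id, m.cds) for m in fam.members])
    tt = {}
    for m in fam.members:
        tt.setdefault(m.motif, []).append(m.id)
    events = scan_family(arrays, tt)
    found = {
        (e.longer_id, e.shorter_id): e.slip_class for e in events
    }
    for pair in fam.truth["slippage_pairs"]:
        assert found.get((pair["longer"], pair["shorter"])) == pair["class"]
    # cross-type scanning is a superset
    all_events = scan_family(arrays, tt, within_type_only=False)
    assert len(all_events) >= len(events)


def test_scan_family_identical_arrays_no_events(rng):
    units = _units(rng, [30, 30, 30])
    arrays = [_arr("a", units), _arr("b", units)]
    assert scan_family(arrays, {"X": ["a", "b"]}) == []
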