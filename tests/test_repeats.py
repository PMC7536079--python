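"""Period detection, consensus and repeat-unit segmentation."""

import numpy as np
import pytest

from rlecfam import (
    NucSequence,
    build_consensus,
    decompose,
    decompose_family,
    detect_period,
    family_consensus,
    segment_units,
)
from rlecfam.simulate import UNIT_INSERT_POS

from conftest import oracle_autocorr_score, oracle_best_tiling


def _rand_dna(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


def test_detect_period_exact_tandem(rng):
    u = _rand_dna(rng, 30)
    ranked = detect_period(u * 5)
    assert ranked[0][0] == 30 and ranked[0][1] == 1.0


def test_detect_period_random_sequence_matches_oracle(rng):
    s = _rand_dna(rng, 300)
    ranked = dict(detect_period(s))
    for p in range(24, 40):
        assert ranked[p] == pytest.approx(oracle_autocorr_score(s, p))
    assert max(ranked.values()) < 0.8


def test_detect_period_mixed_unit_array(rng):
    u30 = _rand_dna(rng, 30)
    u33 = u30[:UNIT_INSERT_POS] + "GGG" + u30[UNIT_INSERT_POS:]
    lens = [33, 30, 30, 30, 30, 30, 33, 30, 33]
    seq = "".join(u33 if L == 33 else u30 for L in lens)
    ranked = detect_period(seq)
    assert ranked[0][0] == 30 and ranked[0][1] > 0.8
    assert ranked[0][1] == pytest.approx(oracle_autocorr_score(seq, 30))


def test_consensus_majority_and_ties(rng):
    u = _rand_dna(rng, 30)
    assert build_consensus(u * 4, 30) == u
    # one substitution in one copy: majority recovers the unit
    mutated = list(u * 4)
    mutated[35] = "A" if u[5] != "A" else "C"
    assert build_consensus("".join(mutated), 30) == u
    # two-copy tie column -> alphabetically first base
    a, b = "A" + u[1:], "G" + u[1:]
    assert build_consensus(a + b, 30)[0] == "A"


def test_segment_exact_33mers_in_flanks(rng):
    u = _rand_dna(rng, 33)
    f5, f3 = _rand_dna(rng, 40), _rand_dna(rng, 45)
    seq = f5 + u * 4 + f3
    arr = segment_units(seq, u, source_id="x")
    oracle = oracle_best_tiling(seq, u)
    assert oracle is not None
    _, n_units, start, lens = oracle
    assert [u_.length for u_ in arr.units] == lens
    assert len(arr.flank5) == start
    assert arr.copy_number == n_units == 4
    assert arr.reconstruct() == seq


def test_segment_no_resemblance(rng):
    seq = _rand_dna(rng, 200)
    cons = _rand_dna(rng, 30)
    # astronomically unlikely to contain a 30-mer at 80% identity by chance
    arr = segment_units(seq, cons, source_id="x")
    if arr.flagged:
        assert arr.units == [] and arr.flank5 == seq
    else:  # pragma: no cover - seed-dependent escape hatch
        pytest.fail("random sequence should not segment")


@pytest.mark.parametrize("n_instances", [30])
def test_segmentation_matches_bruteforce_oracle(rng, n_instances):
    """DP tiling equals exhaustive search on small mixed arrays."""
    for _ in range(n_instances):
        u30 = _rand_dna(rng, 30)
        u33 = u30[:UNIT_INSERT_POS] + _rand_dna(rng, 3) + u30[UNIT_INSERT_POS:]
        k = int(rng.integers(2, 6))
        lens = [int(rng.choice([30, 33])) for _ in range(k)]
        units = [u33 if L == 33 else u30 for L in lens]
        # sprinkle noise
        region = list("".join(units))
        for _ in range(int(rng.integers(0, 4))):
            p = int(rng.integers(0, len(region)))
            region[p] = "ACGT"[int(rng.integers(0, 4))]
        seq = _rand_dna(rng, int(rng.integers(10, 40))) + "".join(region) \
            + _rand_dna(rng, int(rng.integers(10, 40)))
        seq = seq[:250]
        arr = segment_units(seq, u30, source_id="x")
        oracle = oracle_best_tiling(seq, u30)
        assert oracle is not None
        _, n_units, start, olens = oracle
        assert arr.unit_lengths == olens
        assert len(arr.flank5) == start
        assert arr.reconstruct() == seq


def test_decompose_printed_unit_arrays(family20_clean):
    """The 9-unit (279 nt) and founder 8-unit arrays decompose exactly."""
    from rlecfam import FamilyConfig, generate_family

    fam = generate_family(
        FamilyConfig(
            n_members=2,
            seed=5,
            substitution_rate=0.0,
            member_specs=[
                {"id": "yrskdd9", "motif": "YRSKDD",
                 "unit_lengths": [33, 30, 30, 30, 30, 30, 33, 30, 33]},
                {"id": "cndsgd8", "motif": "CNDSGD",
                 "unit_lengths": [33, 30, 30, 30, 30, 30, 30, 30]},
            ],
        )
    )
    m9, m8 = fam.members
    a9 = decompose(NucSequence(m9.id, m9.cds))
    assert a9.unit_lengths == [33, 30, 30, 30, 30, 30, 33, 30, 33]
    assert a9.region_length == 279
    assert a9.reconstruct() == m9.cds
    a8 = decompose(NucSequence(m8.id, m8.cds))
    assert a8.copy_number == 8
    assert a8.region_length == 243


def test_single_copy_needs_family_consensus():
    """A 1-copy array has no tandem self-similarity; the family-level
    consensus (from multi-copy members) still segments it."""
    from rlecfam import FamilyConfig, generate_family

    fam = generate_family(
        FamilyConfig(
            n_members=3,
            seed=9,
            substitution_rate=0.0,
            member_specs=[
                {"id": "one30", "unit_lengths": [30]},
                {"id": "one33", "unit_lengths": [33]},
                {"id": "many", "unit_lengths": [30] * 6},
            ],
        )
    )
    cds = [NucSequence(m.id, m.cds) for m in fam.members]
    # alone, the single-copy member is undetectable
    assert decompose(cds[0]).flagged
    cons = family_consensus(cds)
    assert cons is not None
    for m, c in zip(fam.members[:2], cds[:2]):
        arr = decompose(c, consensus=cons)
        assert arr.copy_number == 1
        assert arr.unit_lengths == m.unit_lengths


def test_decompose_no_signal(rng):
    arr = decompose(_rand_dna(rng, 400))
    assert arr.flagged and arr.units == []


def test_reconstruction_and_frame_invariants(family20):
    """flank5 + units + flank3 == CDS and unit lengths are codon multiples."""
    cds = [NucSequence(m.id, m.cds) for m in family20.members]
    for m, arr in zip(family20.members, decompose_family(cds)):
        assert arr.reconstruct() == m.cds
        assert all(u.length % 3 == 0 for u in arr.units)
        assert arr.unit_lengths == m.unit_lengths
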