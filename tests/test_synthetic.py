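"""Generator determinism, planted-structure arithmetic, truth comparison."""

import numpy as np
import pytest

from rlecfam import (
    FamilyConfig,
    NucSequence,
    decompose_family,
    find_orf,
    find_polya_signal,
    generate_family,
    plant_splice_variant,
    truth_compare,
    validate_splice_sites,
)
from rlecfam.simulate import ComparisonError, ConfigError


def test_determinism_byte_identical(tmp_path):
    c = dict(n_members=10, seed=123)
    f1 = generate_family(FamilyConfig(**c))
    f2 = generate_family(FamilyConfig(**c))
    p1 = f1.write(tmp_path / "a")
    p2 = f2.write(tmp_path / "b")
    for k in p1:
        assert p1[k].read_bytes() == p2[k].read_bytes(), k
    f3 = generate_family(FamilyConfig(n_members=10, seed=124))
    assert f3.members[0].cds != f1.members[0].cds


def test_config_validation():
    with pytest.raises(ConfigError):
        FamilyConfig(substitution_rate=1.5)
    with pytest.raises(ConfigError):
        FamilyConfig(copy_number_range=(0, 9))
    with pytest.raises(ConfigError):
        FamilyConfig(backbone_exon_lengths=(160, 267, 159))
    with pytest.raises(ConfigError):  # repeat region exceeding exon 2
        generate_family(FamilyConfig(
            backbone_exon_lengths=(160, 100, 159, 106, 108, 58)
        ))


def test_member_structure(family20):
    """Every member carries the planted architecture: UTR lengths, in-frame
    repeat region, polyA signal, canonical GT..AG introns."""
    cfg = family20.config
    for m in family20.members[:8]:
        t = m.transcript
        span = find_orf(t)
        assert span == (cfg.utr5_len, cfg.utr5_len + len(m.cds))
        assert len(m.cds) % 3 == 0
        assert find_polya_signal(t) == len(t) - 26
        assert all(d and a for d, a in validate_splice_sites(m.model))
        assert m.model.spliced() == t.seq
        assert all(L % 3 == 0 for L in m.unit_lengths)
        # the truth's unit sequences concatenate back into the CDS
        region = "".join(m.units)
        assert region in m.cds


def test_seventy_six_members_fifteen_types():
    fam = generate_family(FamilyConfig(n_members=76, seed=2))
    assert len(fam.members) == 76
    assert len({m.motif for m in fam.members}) == 15
    assert len(fam.truth["members"]) == 76


def test_splice_variant_length_arithmetic(family20_clean):
    model = family20_clean.members[0].model
    rng = np.random.default_rng(0)
    full = len(model.spliced())
    t, _ = plant_splice_variant(
        model, "alt_acceptor", {"exon": 5, "acceptor_offset": 11}, rng
    )
    assert len(t) == full - 11
    t, _ = plant_splice_variant(
        model, "alt_donor_acceptor",
        {"exons": (5, 6), "donor_offset": 79, "acceptor_offset": 58}, rng,
    )
    assert len(t) == full - 137
    t, _ = plant_splice_variant(model, "exon_skipping", {"exon": 3}, rng)
    assert len(t) == full - 159  # backbone exon-3 coding length
    with pytest.raises(ConfigError):  # offset >= exon length
        plant_splice_variant(
            model, "alt_acceptor", {"exon": 5, "acceptor_offset": 500}, rng
        )


def test_truth_compare_identity_and_errors(family20_clean):
    fam = family20_clean
    truth = fam.truth
    arrays = {
        a.source_id: a
        for a in decompose_family(
            [NucSequence(m.id, m.cds) for m in fam.members]
        )
    }
    motifs = {m.id: m.motif for m in fam.members}
    rep = truth_compare(truth, {"arrays": arrays, "motifs": motifs})
    assert rep["copy_number"] == 1.0
    assert rep["pattern"] == 1.0
    assert rep["type"] == 1.0
    with pytest.raises(ComparisonError):
        truth_compare(truth, {"arrays": {}})


def test_copy_number_recovery_under_mutation():
    """>= 95% copy-number recovery at 2% per-base substitution (n=200)."""
    fam = generate_family(
        FamilyConfig(n_members=200, seed=7, substitution_rate=0.02)
    )
    arrays = decompose_family(
        [NucSequence(m.id, m.cds) for m in fam.members]
    )
    rep = truth_compare(
        fam.truth, {"arrays": {a.source_id: a for a in arrays}}
    )
    assert rep["copy_number"] >= 0.95


def test_slip_class_recovery_under_mutation(rng):
    """>= 90% slippage-class recovery at 2% per-base substitution."""
    from rlecfam import classify_slippage, infer_excision
    from rlecfam.repeats import RepeatArray, RepeatUnit
    from rlecfam.simulate import plant_slippage_pair

    def mutate(u, rate):
        s = list(u)
        for i in range(len(s)):
            if rng.random() < rate:
                s[i] = "ACGT"[int(rng.integers(0, 4))]
        return "".join(s)

    def arr(sid, units):
        return RepeatArray(
            sid, [RepeatUnit(u, 1.0) for u in units], "", "", units[0]
        )

    recipes = {1: [33] + [30] * 5, 2: [30, 30, 33, 33, 30],
               3: [33] + [30] * 7, 4: [33] + [30] * 5, 5: [33] * 5}
    ok = total = 0
    for trial in range(20):
        u30 = "".join("ACGT"[i] for i in rng.integers(0, 4, size=30))
        u33 = u30[:15] + "GAC" + u30[15:]
        for cls, lens in recipes.items():
            base = [u33 if L == 33 else u30 for L in lens]
            longer, shorter, truth = plant_slippage_pair(base, cls, rng)
            longer = [mutate(u, 0.02) for u in longer]
            shorter = [mutate(u, 0.02) for u in shorter]
            ev = infer_excision(arr("L", longer), arr("S", shorter))
            got = (
                classify_slippage(ev, arr("L", longer), arr("S", shorter))
                if ev
                else None
            )
            ok += got == cls
            total += 1
    assert total == 100
    assert ok / total >= 0.90


def test_hostile_mode_lifts_protection():
    fam = generate_family(
        FamilyConfig(n_members=30, seed=4, substitution_rate=0.05,
                     hostile=True, n_slippage_pairs=0, n_splice_variants=0)
    )
    # at 5% unprotected mutation some motifs should be corrupted
    anchor = fam.anchor
    from rlecfam import classify as cl
    from rlecfam import translate

    hits = 0
    for m in fam.members:
        prot = translate(m.cds, (0, len(m.cds)))
        a = cl.extract_motif(prot, anchor, m.id)
        hits += a is not None and a.motif == m.motif
    assert hits < len(fam.members)
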