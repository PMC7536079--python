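"""Synthetic gene-family generator with complete ground truth.

Emulates the statistical structure of a hypervariable C-type lectin family:
duplicated six-exon genes whose second exon carries an in-frame tandem
repeat of 30/33-nt units at copy numbers 1-9, fifteen diagnostic
six-amino-acid motif types in the exon-5-encoded block, flank-conserved
slippage contractions in five classes, and three alternative-splicing modes.
Every planted feature is recorded in a ground-truth structure so the full
analysis pipeline can be validated end to end.

Member layout (coding coordinates; the 5'/3' UTRs sit inside exons 1 and 6
of the genomic representation, so the configured exon lengths are *coding*
lengths):

    exon1 | exon2 = 11 + repeat region + flank3 | exon3 | exon4 | exon5
    | exon6 (ends in the TAG stop codon)

The repeat region starts on a codon boundary, so repeat-encoded residues are
codon-resolvable and maskable; exon 2's total length varies with the
member's copy number while all other exons are fixed, as observed in the
family.  33-nt units are the 30-nt consensus with one extra codon inserted
at a fixed in-unit position, keeping mixed-length arrays alignable.  The
6-aa motif sits at a fixed exon-5 offset behind an 8-aa conserved context
(the classifier's default anchor); an exonic AG (exon-5 offsets 9-10), an
exonic GT (offsets 29-30) and the TAG stop codon provide canonical-context
shifted splice sites for the three splicing modes of the default plan.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .classify import FAMILY_MOTIFS
from .seqio import (
    CODON_TABLE,
    GeneModel,
    NucSequence,
    STOP_CODONS,
    find_orf,
    write_fasta,
    write_gff3,
)
from .splicing import SpliceEvent, apply_events

log = logging.getLogger("rlecfam")

BASES = "ACGT"
NON_STOP_CODONS = tuple(sorted(c for c in CODON_TABLE if c not in STOP_CODONS))
#: preferred codon per amino acid (alphabetically first), for motif writing
AA_TO_CODON: dict[str, str] = {}
for _c in NON_STOP_CODONS:
    AA_TO_CODON.setdefault(CODON_TABLE[_c], _c)

EXON2_FLANK5 = 11  # chosen so exon1 + 11 is a codon boundary (160 + 11 = 171)
UNIT_INSERT_POS = 15  # where the extra codon of a 33-nt unit sits
E5_AG = (9, 11)  # exonic AG: acceptor context for the +11 acceptor shift
E5_GT = (29, 31)  # exonic GT: donor context for the -79 donor shift
#: stops in all three reading frames, placed at the start of the 3'UTR so no
#: spurious ORF can outrun the real one
UTR3_STOP_WALL = "TTAATTAATTAA"


class ConfigError(ValueError):
    pass


class PlantingError(ValueError):
    """A slippage/splice recipe is infeasible on the given input."""


@dataclass
class FamilyConfig:
    """Generator parameters; defaults are the family's observed structure."""

    n_members: int = 76
    motif_list: Sequence[str] = FAMILY_MOTIFS
    copy_number_range: tuple[int, int] = (1, 9)
    unit_lengths: tuple[int, ...] = (30, 33)
    backbone_exon_lengths: tuple[int, ...] = (160, 267, 159, 106, 108, 58)
    backbone_intron_lengths: tuple[int, ...] = (201, 910, 420, 563, 532)
    utr5_len: int = 47
    utr3_len: int = 467
    substitution_rate: float = 0.005
    type_divergence_rate: float = 0.15
    p33: float = 0.25
    n_slippage_pairs: int = 1  # pairs planted per slippage class
    n_splice_variants: int = 1  # copies of each default splice-plan entry
    seed: int = 0
    canonical_context: bool = True
    hostile: bool = False  # lift mutation protections (robustness testing)
    member_specs: Optional[Sequence[dict]] = None

    def __post_init__(self) -> None:
        if not (0 <= self.substitution_rate <= 1):
            raise ConfigError("substitution_rate must be in [0, 1]")
        if not (0 <= self.type_divergence_rate <= 1):
            raise ConfigError("type_divergence_rate must be in [0, 1]")
        lo, hi = self.copy_number_range
        if not (1 <= lo <= hi <= 20):
            raise ConfigError("copy_number_range must lie within [1, 20]")
        if len(self.backbone_exon_lengths) != 6:
            raise ConfigError("backbone requires exactly 6 exons")
        if len(self.backbone_intron_lengths) != 5:
            raise ConfigError("backbone requires exactly 5 introns")
        if set(self.unit_lengths) - {30, 33}:
            raise ConfigError("this generator models 30/33-nt units only")
        if (self.backbone_exon_lengths[0] + EXON2_FLANK5) % 3 != 0:
            raise ConfigError(
                "exon-1 coding length + 11 must be a codon multiple so the "
                "repeat region starts on a codon boundary"
            )


class _Arch:
    """Per-config coordinate arithmetic for the gene architecture."""

    def __init__(self, config: FamilyConfig, founder_region_len: int):
        exl = config.backbone_exon_lengths
        self.exl = exl
        self.region_start = exl[0] + EXON2_FLANK5
        self.flank3 = exl[1] - EXON2_FLANK5 - founder_region_len
        if self.flank3 < 1:
            raise ConfigError(
                f"founder repeat region ({founder_region_len} nt) exceeds "
                f"exon 2 ({exl[1]} nt)"
            )
        self.founder_region_len = founder_region_len
        self.const_coding = (
            exl[0] + EXON2_FLANK5 + self.flank3 + exl[2] + exl[3] + exl[4] + exl[5]
        )
        # anchor context: first codon boundary at or after exon-5 offset 31
        e5 = self.e5_start(founder_region_len)
        off = 31
        while (e5 + off) % 3 != 0:
            off += 1
        self.anchor_off = off  # 8-aa context at [off, off+24)
        self.motif_off = off + 24  # 6-aa motif at [off+24, off+42)
        if self.motif_off + 18 > exl[4]:
            raise ConfigError("exon 5 too short for the anchor + motif block")

    def e5_start(self, region_len: int) -> int:
        return self.region_start + region_len + self.flank3 + self.exl[2] \
            + self.exl[3]

    def cds_len(self, region_len: int) -> int:
        return self.const_coding + region_len

    def protected(self, region_len: int) -> set[int]:
        e5 = self.e5_start(region_len)
        n = self.cds_len(region_len)
        prot = {0, 1, 2, n - 3, n - 2, n - 1}
        for a, b in (
            E5_AG,
            E5_GT,
            (self.anchor_off, self.anchor_off + 24),
            (self.motif_off, self.motif_off + 18),
        ):
            prot.update(range(e5 + a, e5 + b))
        return prot


@dataclass
class Member:
    id: str
    motif: str
    unit_lengths: list[int]
    units: list[str]
    cds: str
    transcript: NucSequence
    model: GeneModel

    @property
    def copy_number(self) -> int:
        return len(self.units)


@dataclass
class Variant:
    id: str
    base_id: str
    transcript: NucSequence
    mode: str
    exon: object
    donor_offset: int
    acceptor_offset: int


@dataclass
class Family:
    config: FamilyConfig
    members: list[Member]
    variants: list[Variant]
    truth: dict
    consensus_unit: str
    anchor: tuple[str, int]

    def transcripts(self) -> list[NucSequence]:
        return [m.transcript for m in self.members] + [
            v.transcript for v in self.variants
        ]

    def gene_models(self) -> list[GeneModel]:
        return [m.model for m in self.members]

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "transcripts": outdir / "transcripts.fasta",
            "genomic": outdir / "genomic.fasta",
            "gff3": outdir / "models.gff3",
            "truth": outdir / "truth.json",
        }
        write_fasta(self.transcripts(), paths["transcripts"])
        write_fasta([m.model.genomic for m in self.members], paths["genomic"])
        write_gff3(self.gene_models(), paths["gff3"])
        paths["truth"].write_text(json.dumps(self.truth, indent=1))
        return paths


# ---------------------------------------------------------------------------
# low-level deterministic sequence builders
# ---------------------------------------------------------------------------


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=n))


def _dna_avoiding(rng: np.random.Generator, n: int, forbidden: Sequence[str]) -> str:
    s = list(_random_dna(rng, n))
    changed = True
    while changed:
        changed = False
        text = "".join(s)
        for sub in forbidden:
            i = text.find(sub)
            if i >= 0:
                mid = i + len(sub) // 2
                s[mid] = BASES[(BASES.index(s[mid]) + 1) % 4]
                changed = True
                break
    return "".join(s)


def _random_codons(rng: np.random.Generator, n: int) -> str:
    idx = rng.integers(0, len(NON_STOP_CODONS), size=n)
    return "".join(NON_STOP_CODONS[i] for i in idx)


def _fix_stops(cds: list[str], protected: set[int]) -> None:
    """Replace internal in-frame stop codons, avoiding protected positions."""
    for c in range(1, len(cds) // 3 - 1):
        codon = "".join(cds[3 * c : 3 * c + 3])
        if codon in STOP_CODONS:
            for off in (0, 1, 2):
                pos = 3 * c + off
                if pos not in protected:
                    cds[pos] = "C"
                    break
            else:  # pragma: no cover - all three positions protected
                raise PlantingError("stop codon inside fully protected region")


def _diversify(unit: str, index: int) -> str:
    """Two private substitutions per unit copy, at positions (3i, 3i+1).

    Distinct units then differ pairwise at >= 4 positions (< 90% identity),
    so order-preserving matching can identify each copy unambiguously, while
    each copy stays > 93% identical to the consensus.
    """
    s = list(unit)
    for pos in (3 * index, 3 * index + 1):
        s[pos] = BASES[(BASES.index(s[pos]) + 1) % 4]
    return "".join(s)


# ---------------------------------------------------------------------------
# slippage and splice planting
# ---------------------------------------------------------------------------


def plant_slippage_pair(
    founder_units: Sequence[str],
    slip_class: int,
    rng: np.random.Generator,
) -> tuple[list[str], list[str], dict]:
    """Build a (longer, shorter) unit-array pair realizing a slippage class.

    The longer array is the input array with per-copy diversifying
    substitutions; the shorter excises units according to the class recipe,
    conserving the class's flank signature (e.g. class 3 excises exactly five
    30-nt units while conserving the first and last unit).  Returns
    ``(longer_units, shorter_units, truth)`` with 1-based excised positions.
    Raises :class:`PlantingError` when the recipe is infeasible.
    """
    n = len(founder_units)
    lens = [len(u) for u in founder_units]
    if slip_class == 5:
        if set(lens) != {33}:
            raise PlantingError("class 5 requires an all-33 array")
        avail = list(range(2, n))  # keep first and last
        if not avail:
            raise PlantingError("array too short for class 5")
        k = int(rng.integers(1, len(avail) + 1))
        excised = sorted(rng.choice(avail, size=k, replace=False).tolist())
    elif slip_class == 1:
        avail = [p for p in range(2, n - 2) if lens[p - 1] == 30]
        if not avail:
            raise PlantingError(
                "class 1 needs interior 30-nt units with three conserved "
                "trailing units"
            )
        k = int(rng.integers(1, len(avail) + 1))
        excised = sorted(rng.choice(avail, size=k, replace=False).tolist())
    elif slip_class == 2:
        avail = [p for p in range(3, n) if lens[p - 1] == 33]
        if not avail or set(lens) == {33}:
            raise PlantingError(
                "class 2 needs interior 33-nt units in a mixed-length array"
            )
        k = int(rng.integers(1, len(avail) + 1))
        excised = sorted(rng.choice(avail, size=k, replace=False).tolist())
    elif slip_class == 4:
        # suffix exactly 2: position n-2 must be excised (and be 30 nt)
        if n < 5 or lens[n - 3] != 30:
            raise PlantingError("class 4 needs a 30-nt unit at position n-2")
        extra = [p for p in range(2, n - 2) if lens[p - 1] == 30]
        k = int(rng.integers(0, len(extra) + 1))
        excised = sorted(
            rng.choice(extra, size=k, replace=False).tolist() + [n - 2]
        )
    elif slip_class == 3:
        # five 30-nt excisions with suffix exactly 1: position n-1 excised
        cand = [p for p in range(2, n) if lens[p - 1] == 30]
        if (n - 1) not in cand or len(cand) < 5:
            raise PlantingError(
                "class 3 needs five excisable 30-nt units including "
                "position n-1"
            )
        others = [p for p in cand if p != n - 1]
        excised = sorted(
            rng.choice(others, size=4, replace=False).tolist() + [n - 1]
        )
    else:
        raise PlantingError(f"unknown slippage class {slip_class}")

    longer = [_diversify(u, i) for i, u in enumerate(founder_units)]
    keep = [p for p in range(1, n + 1) if p not in excised]
    shorter = [longer[p - 1] for p in keep]
    prefix = 0
    while prefix < len(keep) and keep[prefix] == prefix + 1:
        prefix += 1
    suffix = 0
    while suffix < len(keep) and keep[-1 - suffix] == n - suffix:
        suffix += 1
    truth = {
        "class": slip_class,
        "excised": [[p, lens[p - 1]] for p in excised],
        "conserved_prefix": prefix,
        "conserved_suffix": suffix,
    }
    return longer, shorter, truth


#: the family's observed splicing events (assumes the default backbone)
DEFAULT_SPLICE_PLAN: tuple[tuple[str, dict], ...] = (
    ("alt_acceptor", {"exon": 5, "acceptor_offset": 11}),
    ("alt_donor_acceptor", {"exons": (5, 6), "donor_offset": 79,
                            "acceptor_offset": 58}),
    ("exon_skipping", {"exon": 5}),
    ("exon_skipping", {"exon": 3}),
)


def plant_splice_variant(
    model: GeneModel,
    mode: str,
    params: dict,
    rng: Optional[np.random.Generator] = None,
) -> tuple[str, SpliceEvent]:
    """Emit the transcript implied by one alternative-splicing event.

    Offsets must be smaller than the target exon's length.  The genomic
    context for the default plan's shifted sites (exonic AG/GT) is part of
    the family backbone, so those transcripts carry canonical-context
    shifted junctions.
    """
    if mode == "alt_acceptor":
        e, off = params["exon"], params["acceptor_offset"]
        a, b = model.exons[e - 1]
        if off >= b - a:
            raise ConfigError(f"acceptor offset {off} >= exon {e} length")
        ev = SpliceEvent("alt_acceptor", e, off)
    elif mode == "alt_donor_acceptor":
        ei, ej = params["exons"]
        d, acc = params["donor_offset"], params["acceptor_offset"]
        if d >= model.exons[ei - 1][1] - model.exons[ei - 1][0]:
            raise ConfigError(f"donor offset {d} >= exon {ei} length")
        if acc >= model.exons[ej - 1][1] - model.exons[ej - 1][0]:
            raise ConfigError(f"acceptor offset {acc} >= exon {ej} length")
        ev = SpliceEvent("alt_donor_acceptor", (ei, ej), acc, d)
    elif mode == "exon_skipping":
        ev = SpliceEvent("exon_skipping", params["exon"])
    else:
        raise ConfigError(f"unknown splicing mode {mode!r}")
    return apply_events(model, [ev]), ev


# ---------------------------------------------------------------------------
# family generation
# ---------------------------------------------------------------------------


def generate_family(config: FamilyConfig) -> Family:
    """Generate a family with ground truth; byte-deterministic under seed."""
    rng = np.random.default_rng(config.seed)
    exl = config.backbone_exon_lengths

    # --- founder building blocks ------------------------------------------
    u30 = _random_codons(rng, 10)
    insert_codon = _random_codons(rng, 1)
    u33 = u30[:UNIT_INSERT_POS] + insert_codon + u30[UNIT_INSERT_POS:]
    founder_lens = [33] + [30] * 7
    founder_units = [u33 if L == 33 else u30 for L in founder_lens]
    arch = _Arch(config, sum(founder_lens))

    cds = list(
        "ATG" + _random_codons(rng, arch.cds_len(sum(founder_lens)) // 3 - 2)
        + "TAG"
    )
    cds[arch.region_start : arch.region_start + sum(founder_lens)] = list(
        "".join(founder_units)
    )
    e5 = arch.e5_start(sum(founder_lens))
    if config.canonical_context:
        cds[e5 + E5_AG[0]] = "A"
        cds[e5 + E5_AG[0] + 1] = "G"
        cds[e5 + E5_GT[0]] = "G"
        cds[e5 + E5_GT[0] + 1] = "T"
    protected = arch.protected(sum(founder_lens))
    _fix_stops(cds, protected)
    founder_cds = "".join(cds)

    aa_anchor = (e5 + arch.anchor_off) // 3
    anchor_context = "".join(
        CODON_TABLE[founder_cds[3 * (aa_anchor + k) : 3 * (aa_anchor + k) + 3]]
        for k in range(8)
    )
    anchor = (anchor_context, 8)

    utr5 = _dna_avoiding(rng, config.utr5_len, ["ATG"])
    utr3_mid = _dna_avoiding(
        rng, config.utr3_len - len(UTR3_STOP_WALL) - 26, ["AATAAA"]
    )
    utr3_tail = _dna_avoiding(rng, 20, ["AATAAA"])
    utr3 = _plant_single_polya(
        UTR3_STOP_WALL + utr3_mid + "AATAAA" + utr3_tail, config.utr3_len
    )
    introns = [
        "GT" + _dna_avoiding(rng, L - 4, []) + "AG"
        for L in config.backbone_intron_lengths
    ]

    # --- per-type coding templates -----------------------------------------
    motifs = list(config.motif_list)
    free_e5 = [
        e5 + o
        for o in range(exl[4])
        if not any(
            a <= o < b
            for a, b in (
                E5_AG,
                E5_GT,
                (arch.anchor_off, arch.anchor_off + 24),
                (arch.motif_off, arch.motif_off + 18),
            )
        )
    ]
    type_templates: dict[str, str] = {}
    for motif in motifs:
        t = list(founder_cds)
        hits = rng.random(len(free_e5)) < config.type_divergence_rate
        for pos, hit in zip(free_e5, hits):
            if hit:
                t[pos] = BASES[
                    (BASES.index(t[pos]) + 1 + int(rng.integers(0, 3))) % 4
                ]
        mstart = e5 + arch.motif_off
        t[mstart : mstart + 18] = list("".join(AA_TO_CODON[aa] for aa in motif))
        _fix_stops(t, protected)
        type_templates[motif] = "".join(t)

    # --- member plan --------------------------------------------------------
    plan: list[dict] = []
    truth_pairs: list[dict] = []
    if config.member_specs is not None:
        for i, spec in enumerate(config.member_specs):
            plan.append(
                {
                    "id": spec.get("id", f"m{i + 1:03d}"),
                    "motif": spec.get("motif", motifs[i % len(motifs)]),
                    "unit_lengths": list(spec["unit_lengths"]),
                    "units": None,
                }
            )
    else:
        # slippage exemplar pairs first (types follow the observed per-class
        # type lists), then free members round-robin over the motif list
        class_arrays = {
            1: [33] + [30] * 5,
            2: [30, 30, 33, 33, 30],
            3: list(founder_lens),
            4: [33] + [30] * 5,
            5: [33] * 5,
        }
        class_types = {1: "YRSKDD", 2: "FHFKGD", 3: "CNDSGD",
                       4: "YTYKED", 5: "FHYKGD"}
        idx = 1
        for _rep in range(config.n_slippage_pairs):
            for cls in (1, 2, 3, 4, 5):
                lens = class_arrays[cls]
                base_units = [u33 if L == 33 else u30 for L in lens]
                longer, shorter, ev = plant_slippage_pair(base_units, cls, rng)
                motif = (
                    class_types[cls]
                    if class_types[cls] in motifs
                    else motifs[(cls - 1) % len(motifs)]
                )
                lid, sid = f"m{idx:03d}", f"m{idx + 1:03d}"
                idx += 2
                plan.append({"id": lid, "motif": motif, "units": longer,
                             "unit_lengths": [len(u) for u in longer]})
                plan.append({"id": sid, "motif": motif, "units": shorter,
                             "unit_lengths": [len(u) for u in shorter]})
                truth_pairs.append({"longer": lid, "shorter": sid, **ev})
        lo, hi = config.copy_number_range
        while len(plan) < config.n_members:
            cn = int(rng.integers(lo, hi + 1))
            lens = [33 if rng.random() < config.p33 else 30 for _ in range(cn)]
            plan.append({
                "id": f"m{idx:03d}",
                "motif": motifs[len(plan) % len(motifs)],
                "unit_lengths": lens,
                "units": None,
            })
            idx += 1
        plan = plan[: config.n_members]
        kept_ids = {e["id"] for e in plan}
        truth_pairs = [
            p for p in truth_pairs
            if p["longer"] in kept_ids and p["shorter"] in kept_ids
        ]

    # --- assemble members ----------------------------------------------------
    members: list[Member] = []
    for entry in plan:
        units = entry["units"] or [
            u33 if L == 33 else u30 for L in entry["unit_lengths"]
        ]
        region = "".join(units)
        template = type_templates[entry["motif"]]
        base_cds = (
            template[: arch.region_start]
            + region
            + template[arch.region_start + arch.founder_region_len :]
        )
        prot = set() if config.hostile else arch.protected(len(region))
        for _attempt in range(5):
            trial = list(base_cds)
            if config.substitution_rate > 0:
                hits = np.nonzero(
                    rng.random(len(trial)) < config.substitution_rate
                )[0]
                for pos in hits:
                    if int(pos) in prot:
                        continue
                    trial[pos] = BASES[
                        (BASES.index(trial[pos]) + 1 + int(rng.integers(0, 3)))
                        % 4
                    ]
            _fix_stops(trial, prot)
            cds_str = "".join(trial)
            transcript = utr5 + cds_str + utr3
            if config.hostile or find_orf(transcript) == (
                config.utr5_len,
                config.utr5_len + len(cds_str),
            ):
                # hostile mode deliberately allows a corrupted ORF
                break
        else:  # pragma: no cover - astronomically unlikely
            raise PlantingError(f"{entry['id']}: could not realize intended ORF")
        # record the exact (possibly mutated) unit sequences as the truth
        pos = arch.region_start
        real_units = []
        for L in entry["unit_lengths"]:
            real_units.append(cds_str[pos : pos + L])
            pos += L
        model = _build_gene_model(
            entry["id"], utr5, cds_str, utr3, len(region), arch, introns
        )
        members.append(
            Member(
                entry["id"], entry["motif"], list(entry["unit_lengths"]),
                real_units, cds_str, NucSequence(entry["id"], transcript),
                model,
            )
        )

    # --- splice variants ------------------------------------------------------
    variants: list[Variant] = []
    variant_base: dict[str, Optional[Member]] = {"YHYQEH": None, "FHYKGD": None}
    for m in members:
        if m.motif in variant_base and variant_base[m.motif] is None:
            variant_base[m.motif] = m
    if config.n_splice_variants > 0 and config.member_specs is None:
        for _rep in range(config.n_splice_variants):
            for mode, params in DEFAULT_SPLICE_PLAN:
                base = (
                    variant_base.get("FHYKGD")
                    if params.get("exon") == 3
                    else variant_base.get("YHYQEH")
                ) or members[0]
                t, ev = plant_splice_variant(base.model, mode, params, rng)
                vid = f"{base.id}_v{len(variants) + 1}_{mode}"
                variants.append(
                    Variant(
                        vid, base.id, NucSequence(vid, t), mode, ev.exon,
                        ev.donor_offset, ev.acceptor_offset,
                    )
                )

    truth = {
        "anchor": list(anchor),
        "consensus_unit": u30,
        "unit_33": u33,
        "members": {
            m.id: {
                "motif": m.motif,
                "type": m.motif,
                "copy_number": m.copy_number,
                "unit_lengths": m.unit_lengths,
                "units": m.units,
                "utr5_len": config.utr5_len,
                "orf_len": len(m.cds),
                "utr3_len": config.utr3_len,
                "exons": [list(e) for e in m.model.exons],
            }
            for m in members
        },
        "slippage_pairs": truth_pairs,
        "splice_variants": [
            {
                "id": v.id,
                "base": v.base_id,
                "mode": v.mode,
                "exon": list(v.exon) if isinstance(v.exon, tuple) else v.exon,
                "donor_offset": v.donor_offset,
                "acceptor_offset": v.acceptor_offset,
            }
            for v in variants
        ],
    }
    return Family(config, members, variants, truth, u30, anchor)


def _plant_single_polya(utr3: str, want_len: int) -> str:
    """Ensure exactly one AATAAA, sited 26 nt from the 3' end."""
    assert len(utr3) == want_len, (len(utr3), want_len)
    planted = want_len - 26
    i = utr3.find("AATAAA")
    while i >= 0:
        if i != planted:
            utr3 = utr3[: i + 3] + "C" + utr3[i + 4 :]
            i = utr3.find("AATAAA")
        else:
            i = utr3.find("AATAAA", i + 1)
    return utr3


def _build_gene_model(
    mid: str,
    utr5: str,
    cds: str,
    utr3: str,
    region_len: int,
    arch: _Arch,
    introns: Sequence[str],
) -> GeneModel:
    exl = arch.exl
    coding_lens = [
        exl[0],
        EXON2_FLANK5 + region_len + arch.flank3,
        exl[2],
        exl[3],
        exl[4],
        exl[5],
    ]
    pieces = []
    p = 0
    for L in coding_lens:
        pieces.append(cds[p : p + L])
        p += L
    exon_seqs = [utr5 + pieces[0]] + pieces[1:5] + [pieces[5] + utr3]
    parts: list[str] = []
    exons = []
    pos = 0
    for i, ex in enumerate(exon_seqs):
        exons.append((pos, pos + len(ex)))
        parts.append(ex)
        pos += len(ex)
        if i < 5:
            parts.append(introns[i])
            pos += len(introns[i])
    genomic = NucSequence(f"{mid}_g", "".join(parts))
    return GeneModel(mid, genomic, exons)


# ---------------------------------------------------------------------------
# truth comparison
# ---------------------------------------------------------------------------


class ComparisonError(ValueError):
    pass


def truth_compare(truth: dict, results: dict) -> dict[str, float]:
    """Per-stage recovery fractions of pipeline results against ground truth.

    ``results`` holds ``arrays`` (id -> RepeatArray), ``motifs`` (id -> motif
    or None), ``slippage_events`` (list of SlippageEvent) and ``splice``
    (variant id -> list of SpliceEvent).  Stages absent from ``results`` are
    skipped.  Fractions are exact-match recoveries; ``copy_number_within_1``
    is the tolerance variant for the copy-number stage.
    """
    out: dict[str, float] = {}
    tm = truth["members"]
    if "arrays" in results:
        arrays = results["arrays"]
        missing = set(tm) - set(arrays)
        if missing:
            raise ComparisonError(
                f"results lack arrays for {sorted(missing)[:3]}"
            )
        cn_ok = pat_ok = within1 = 0
        for mid, info in tm.items():
            a = arrays[mid]
            cn_ok += a.copy_number == info["copy_number"]
            within1 += abs(a.copy_number - info["copy_number"]) <= 1
            pat_ok += a.unit_lengths == info["unit_lengths"]
        out["copy_number"] = cn_ok / len(tm)
        out["copy_number_within_1"] = within1 / len(tm)
        out["pattern"] = pat_ok / len(tm)
    if "motifs" in results:
        motifs = results["motifs"]
        ok = sum(motifs.get(mid) == info["motif"] for mid, info in tm.items())
        out["type"] = ok / len(tm)
    if "slippage_events" in results and truth.get("slippage_pairs"):
        evs = {
            (e.longer_id, e.shorter_id): e for e in results["slippage_events"]
        }
        ok = 0
        for pair in truth["slippage_pairs"]:
            e = evs.get((pair["longer"], pair["shorter"]))
            ok += e is not None and e.slip_class == pair["class"]
        out["slip_class"] = ok / len(truth["slippage_pairs"])
    if "splice" in results and truth.get("splice_variants"):
        ok = 0
        for v in truth["splice_variants"]:
            evs_v = results["splice"].get(v["id"], [])
            want_exon = (
                tuple(v["exon"]) if isinstance(v["exon"], list) else v["exon"]
            )
            ok += any(
                e.mode == v["mode"]
                and (tuple(e.exon) if isinstance(e.exon, tuple) else e.exon)
                == want_exon
                and e.donor_offset == v["donor_offset"]
                and e.acceptor_offset == v["acceptor_offset"]
                for e in evs_v
            )
        out["splice"] = ok / len(truth["splice_variants"])
    return out
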