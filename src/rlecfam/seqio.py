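"""Domain types, FASTA/GFF3 I/O and basic cDNA annotation.

Conventions used throughout the package:

* all internal coordinates are 0-based, half-open; GFF3 I/O converts to and
  from the standard's 1-based inclusive intervals;
* sequences are plus-strand, upper-case DNA over ``{A, C, G, T, N}``;
* exon numbers reported to users are 1-based (exon 1 .. exon 6), as
  biologists count them.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger("rlecfam")

DNA_ALPHABET = frozenset("ACGTN")

#: Standard genetic code (NCBI table 1) as DNA codon -> 1-letter amino acid.
_std = CodonTable.unambiguous_dna_by_id[1]
CODON_TABLE: dict[str, str] = dict(_std.forward_table)
STOP_CODONS = frozenset(_std.stop_codons)


class SequenceError(ValueError):
    """Malformed sequence, header or alphabet."""


class CoordinateError(ValueError):
    """Interval outside sequence bounds or inconsistent exon chain."""


class FrameError(ValueError):
    """Reading-frame violation (length, internal stop)."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NucSequence:
    """A linear DNA sequence restricted to the {A,C,G,T,N} alphabet."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        s = self.seq.upper()
        object.__setattr__(self, "seq", s)
        if len(s) < 1:
            raise SequenceError(f"{self.id}: empty sequence")
        bad = set(s) - DNA_ALPHABET
        if bad:
            raise SequenceError(
                f"{self.id}: illegal characters {sorted(bad)} (alphabet is A/C/G/T/N)"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class TranscriptRecord:
    """A cDNA with its UTR/ORF decomposition and derived annotations.

    Invariant: ``utr5_len + orf_len + utr3_len == len(cdna)``; the ORF length
    is divisible by 3 and the protein excludes the stop codon.
    """

    id: str
    cdna: NucSequence
    orf_span: tuple[int, int]
    protein: str
    polya_signal_pos: Optional[int] = None
    motif: Optional[str] = None
    repeat_array: Optional[object] = None  # RepeatArray, set by the decomposer

    @property
    def utr5_len(self) -> int:
        return self.orf_span[0]

    @property
    def orf_len(self) -> int:
        return self.orf_span[1] - self.orf_span[0]

    @property
    def utr3_len(self) -> int:
        return len(self.cdna) - self.orf_span[1]

    def __post_init__(self) -> None:
        a, b = self.orf_span
        if not (0 <= a <= b <= len(self.cdna)):
            raise CoordinateError(f"{self.id}: ORF span {self.orf_span} out of bounds")
        if (b - a) % 3 != 0:
            raise FrameError(f"{self.id}: ORF length {b - a} not divisible by 3")
        if self.protein and len(self.protein) != (b - a) // 3 - 1:
            raise FrameError(
                f"{self.id}: protein length {len(self.protein)} != orf/3 - 1"
            )


@dataclass
class GeneModel:
    """An exon/intron chain on a plus-strand genomic sequence.

    ``exons`` are 0-based half-open intervals, non-overlapping and strictly
    increasing; introns are the gaps between consecutive exons and must leave
    room for the GT..AG dinucleotides.
    """

    id: str
    genomic: NucSequence
    exons: list[tuple[int, int]]

    def __post_init__(self) -> None:
        n = len(self.genomic)
        prev_end = -1
        for i, (a, b) in enumerate(self.exons):
            if not (0 <= a < b <= n):
                raise CoordinateError(
                    f"{self.id}: exon {i + 1} [{a},{b}) outside sequence of length {n}"
                )
            if a <= prev_end:
                raise CoordinateError(
                    f"{self.id}: exon {i + 1} overlaps or is out of order"
                )
            if prev_end >= 0 and a - prev_end < 4:
                raise CoordinateError(
                    f"{self.id}: intron before exon {i + 1} shorter than 4 nt"
                )
            prev_end = b

    @property
    def introns(self) -> list[tuple[int, int]]:
        return [
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        ]

    def exon_seq(self, i: int) -> str:
        a, b = self.exons[i]
        return self.genomic.seq[a:b]

    def spliced(self) -> str:
        """The canonical splice product (concatenation of all exons)."""
        return "".join(self.exon_seq(i) for i in range(len(self.exons)))


@dataclass
class DomainAnnotation:
    """Protein-level feature annotation (1-based inclusive aa intervals)."""

    protein_id: str
    protein_length: int
    features: list[tuple[str, int, int]] = field(default_factory=list)

    def add(self, label: str, start: int, end: int) -> None:
        if not (1 <= start <= end <= self.protein_length):
            raise CoordinateError(
                f"{self.protein_id}: feature {label} [{start},{end}] outside protein"
            )
        if label in ("EPN", "QPD") and end - start != 2:
            raise CoordinateError(f"{self.protein_id}: Ca-site motif must span 3 aa")
        self.features.append((label, start, end))


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> list[NucSequence]:
    """Read a FASTA file into validated :class:`NucSequence` records.

    Raises :class:`SequenceError` naming the record when a sequence contains
    characters outside ``{A,C,G,T,N}``.  An empty file yields an empty list
    with a logged warning.
    """
    path = Path(path)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        try:
            records.append(NucSequence(rec.id, str(rec.seq)))
        except SequenceError as exc:
            raise SequenceError(f"{path.name}: {exc}") from exc
    if not records:
        log.warning("FASTA file %s contained no records", path)
    return records


def write_fasta(records: Iterable[NucSequence], path: str | Path) -> None:
    """Write records as upper-case, 60-column-wrapped FASTA."""
    seqrecs = [
        SeqRecord(Seq(r.seq), id=r.id, description="") for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=60)
        writer.write_file(seqrecs)


# ---------------------------------------------------------------------------
# GFF3 (gene + exon features only; 1-based inclusive on disk)
# ---------------------------------------------------------------------------


def read_gff3(path: str | Path, genomic: Sequence[NucSequence]) -> list[GeneModel]:
    """Read gene models (gene + exon features) from a GFF3 file.

    ``genomic`` supplies the sequences referenced by the GFF3 seqid column.
    Coordinates are converted from 1-based inclusive to internal 0-based
    half-open; exons are validated against the sequence bounds.
    """
    by_id = {s.id: s for s in genomic}
    genes: dict[str, tuple[str, list[tuple[int, int]]]] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise SequenceError(f"{path}:{lineno}: expected 9 GFF3 columns")
            seqid, _src, ftype, start, end, _score, strand, _phase, attrs = cols
            if ftype not in ("gene", "exon"):
                continue
            attr = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            if ftype == "gene":
                gid = attr.get("ID", seqid)
                if gid not in genes:
                    genes[gid] = (seqid, [])
                    order.append(gid)
                continue
            gid = attr.get("Parent") or attr.get("ID", seqid)
            if gid not in genes:
                genes[gid] = (seqid, [])
                order.append(gid)
            s1, e1 = int(start), int(end)
            if strand == "-":
                raise CoordinateError(
                    f"{path}:{lineno}: minus-strand models must be "
                    "reverse-complemented before import"
                )
            seq = by_id.get(genes[gid][0])
            if seq is None:
                raise CoordinateError(
                    f"{path}:{lineno}: unknown seqid {genes[gid][0]!r}"
                )
            if not (1 <= s1 <= e1 <= len(seq)):
                raise CoordinateError(
                    f"{path}:{lineno}: exon {s1}..{e1} outside {seq.id} "
                    f"(length {len(seq)})"
                )
            genes[gid][1].append((s1 - 1, e1))  # 1-based incl -> 0-based half-open
    models = []
    for gid in order:
        seqid, exons = genes[gid]
        models.append(GeneModel(gid, by_id[seqid], sorted(exons)))
    return models


def write_gff3(models: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            span = (m.exons[0][0] + 1, m.exons[-1][1])
            fh.write(
                f"{m.genomic.id}\trlecfam\tgene\t{span[0]}\t{span[1]}"
                f"\t.\t+\t.\tID={m.id}\n"
            )
            for i, (a, b) in enumerate(m.exons, 1):
                fh.write(
                    f"{m.genomic.id}\trlecfam\texon\t{a + 1}\t{b}\t.\t+\t."
                    f"\tID={m.id}.exon{i};Parent={m.id}\n"
                )


# ---------------------------------------------------------------------------
# ORF finding, translation, simple motif scans
# ---------------------------------------------------------------------------


def find_orf(cdna: NucSequence | str) -> Optional[tuple[int, int]]:
    """Longest ATG-initiated ORF terminated by an in-frame stop.

    Returns the 0-based half-open span *including* the stop codon, or ``None``
    when no complete ORF exists.  Ties in length are broken by the 5'-most
    start.
    """
    seq = cdna.seq if isinstance(cdna, NucSequence) else cdna.upper()
    best: Optional[tuple[int, int]] = None
    n = len(seq)
    # earliest stop per frame beyond a position, scanned lazily per start
    for start in range(n - 5):
        if seq[start : start + 3] != "ATG":
            continue
        for p in range(start + 3, n - 2, 3):
            if seq[p : p + 3] in STOP_CODONS:
                length = p + 3 - start
                if best is None or length > best[1] - best[0]:
                    best = (start, p + 3)
                break
    return best


def translate(cdna: NucSequence | str, orf_span: tuple[int, int]) -> str:
    """Translate an ORF span with the standard code, stop codon excluded.

    Codons containing ``N`` translate to ``X``.  An internal stop before the
    end of the span raises :class:`FrameError`.
    """
    seq = cdna.seq if isinstance(cdna, NucSequence) else cdna.upper()
    a, b = orf_span
    if (b - a) % 3 != 0:
        raise FrameError(f"span length {b - a} not divisible by 3")
    aa = []
    for p in range(a, b - 3, 3):
        codon = seq[p : p + 3]
        if codon in STOP_CODONS:
            raise FrameError(f"internal stop codon {codon} at position {p}")
        aa.append("X" if "N" in codon else CODON_TABLE[codon])
    return "".join(aa)


def find_polya_signal(cdna: NucSequence | str, window: int = 50) -> Optional[int]:
    """0-based position of the 3'-most AATAAA within the last ``window`` nt."""
    seq = cdna.seq if isinstance(cdna, NucSequence) else cdna.upper()
    lo = max(0, len(seq) - window)
    pos = seq.rfind("AATAAA", lo)
    return pos if pos >= 0 else None


def scan_ca_site_motif(protein: str) -> list[tuple[str, int]]:
    """All EPN/QPD Ca2+-site-2 motif occurrences, 1-based start positions.

    EPN and QPD are the CRD tripeptides conferring mannose- vs galactose-type
    sugar specificity in C-type lectins.
    """
    hits = []
    for i in range(len(protein) - 2):
        tri = protein[i : i + 3]
        if tri in ("EPN", "QPD"):
            hits.append((tri, i + 1))
    return hits


def annotate_transcript(nuc: NucSequence) -> TranscriptRecord:
    """Build a :class:`TranscriptRecord` by ORF finding + translation.

    A transcript with no complete ORF gets a zero-length ORF span at 0 and an
    empty protein (flagged via a warning rather than an exception).
    """
    span = find_orf(nuc)
    if span is None:
        warnings.warn(f"{nuc.id}: no ATG-initiated ORF found")
        return TranscriptRecord(nuc.id, nuc, (0, 0), "")
    prot = translate(nuc, span)
    return TranscriptRecord(
        nuc.id, nuc, span, prot, polya_signal_pos=find_polya_signal(nuc)
    )
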