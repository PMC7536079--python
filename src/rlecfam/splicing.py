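"""Alternative-splicing classification against a gene model.

Observed transcripts are mapped exon-by-exon onto a six-exon gene model
(exact matching — the transcripts compared here are Sanger-grade, effectively
mismatch-free) and deviations from the canonical splice product are
classified into three modes:

* ``alt_acceptor`` — a 3' splice site shifted into the exon, truncating its
  5' end by ``acceptor_offset`` nt;
* ``alt_donor_acceptor`` — a shifted 5' site on exon *i* combined with a
  shifted 3' site on exon *i+1*, reported as ONE event with
  ``(donor_offset, acceptor_offset)``;
* ``exon_skipping`` — an exon entirely absent from the transcript.

Exon numbers in events and chains are 1-based.  Canonical and shifted splice
junctions are validated against the GT..AG rule on the genomic sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

from .seqio import GeneModel, NucSequence

MODES = ("alt_acceptor", "alt_donor_acceptor", "exon_skipping")


class MappingError(ValueError):
    """Transcript cannot be expressed as in-order exon substrings."""


class UnsupportedSpliceError(ValueError):
    """A splicing pattern outside the three supported modes."""


@dataclass
class ExonChain:
    """Per-exon usage of a transcript: (exon number, 5' and 3' truncations).

    ``entries`` hold ``(exon_no, start_offset, end_offset)`` where the used
    portion of exon *k* (length L) is ``exon[start_offset : L - end_offset]``;
    the used portion is always non-empty.  ``skipped`` is the set of exon
    numbers absent from the transcript.
    """

    entries: list[tuple[int, int, int]]
    skipped: set[int] = field(default_factory=set)

    def __post_init__(self) -> None:
        prev = 0
        for e, s, t in self.entries:
            if e <= prev:
                raise MappingError("exon numbers must be strictly increasing")
            if s < 0 or t < 0:
                raise MappingError("negative truncation offset")
            prev = e

    @property
    def skipped_exons(self) -> set[int]:
        return set(self.skipped)


@dataclass
class SpliceEvent:
    mode: str
    exon: Union[int, tuple[int, int]]
    acceptor_offset: int = 0
    donor_offset: int = 0

    def __post_init__(self) -> None:
        if self.mode == "alt_acceptor":
            assert self.acceptor_offset > 0 and self.donor_offset == 0
        elif self.mode == "alt_donor_acceptor":
            assert self.acceptor_offset > 0 and self.donor_offset > 0
            assert isinstance(self.exon, tuple)
        elif self.mode == "exon_skipping":
            assert self.acceptor_offset == 0 and self.donor_offset == 0
        elif self.mode not in ("alt_donor",):  # alt_donor only via split flag
            raise UnsupportedSpliceError(f"unknown mode {self.mode!r}")


def canonical_chain(model: GeneModel) -> ExonChain:
    return ExonChain([(i + 1, 0, 0) for i in range(len(model.exons))])


def map_transcript(
    model: GeneModel,
    transcript: NucSequence | str,
    min_use: int = 8,
) -> ExonChain:
    """Map a transcript onto the model's exons by exact in-order matching.

    Depth-first search over per-exon choices (use a contiguous portion, or
    skip the exon), preferring canonical usage: full exon first, then the
    longest usable portion.  ``min_use`` is the minimum used portion of any
    exon, which suppresses spurious few-nucleotide matches.  Raises
    :class:`MappingError` with the first failing transcript position when no
    complete mapping exists (e.g. intron retention).
    """
    T = transcript.seq if isinstance(transcript, NucSequence) else transcript
    exons = [model.exon_seq(i) for i in range(len(model.exons))]
    n = len(exons)
    fail_pos = 0
    dead: set[tuple[int, int]] = set()

    def common_prefix(p: int, ex: str, s: int) -> int:
        k = 0
        while p + k < len(T) and s + k < len(ex) and T[p + k] == ex[s + k]:
            k += 1
        return k

    def dfs(p: int, e: int) -> Optional[list[tuple[int, int, int]]]:
        nonlocal fail_pos
        if p == len(T):
            return []
        if e == n or (p, e) in dead:
            fail_pos = max(fail_pos, p)
            return None
        ex = exons[e]
        L = len(ex)
        for s in range(0, L - min_use + 1):
            k = common_prefix(p, ex, s)
            if k < min_use:
                continue
            # prefer the longest used portion (canonical), then shorter
            for used in range(min(k, L - s), min_use - 1, -1):
                rest = dfs(p + used, e + 1)
                if rest is not None:
                    return [(e + 1, s, L - s - used)] + rest
        rest = dfs(p, e + 1)  # skip this exon
        if rest is not None:
            return [(-(e + 1), 0, 0)] + rest
        dead.add((p, e))
        return None

    result = dfs(0, 0)
    if result is None:
        raise MappingError(
            f"{model.id}: transcript unmappable (first failing position "
            f"{fail_pos})"
        )
    entries = [(e, s, t) for e, s, t in result if e > 0]
    used = {e for e, _, _ in entries}
    skipped = set(range(1, n + 1)) - used
    return ExonChain(entries, skipped)


def classify_events(
    ref_chain: ExonChain,
    obs_chain: ExonChain,
    split_combined: bool = False,
) -> list[SpliceEvent]:
    """Compare an observed exon chain against the canonical chain.

    A 5' truncation of an exon is ``alt_acceptor``; a 3' truncation of exon
    *i* together with a 5' truncation of exon *i+1* is one
    ``alt_donor_acceptor`` event (two events, ``alt_donor`` + ``alt_acceptor``,
    with ``split_combined=True``); a fully absent exon is ``exon_skipping``.
    A lone 3' truncation matches none of the supported modes and raises
    :class:`UnsupportedSpliceError`.  Events are reported 5'->3'.
    """
    ref_exons = {e for e, _, _ in ref_chain.entries} | ref_chain.skipped
    obs_exons = {e for e, _, _ in obs_chain.entries} | obs_chain.skipped
    if ref_exons != obs_exons:
        raise MappingError("chains refer to different exon sets")
    if any(s or t for _, s, t in ref_chain.entries):
        raise MappingError("reference chain must be canonical (no truncations)")

    events: list[SpliceEvent] = []
    entries = obs_chain.entries
    used_ref = {e for e, _, _ in ref_chain.entries}
    for e in sorted(obs_chain.skipped & used_ref):
        events.append(SpliceEvent("exon_skipping", e))

    pending_donor: Optional[tuple[int, int]] = None  # (exon_no, donor_offset)
    for e, s, t in entries:
        if pending_donor is not None:
            de, doff = pending_donor
            if s > 0 and e == de + 1:
                if split_combined:
                    events.append(SpliceEvent("alt_donor", de, 0, doff))
                    events.append(SpliceEvent("alt_acceptor", e, s))
                else:
                    events.append(
                        SpliceEvent("alt_donor_acceptor", (de, e), s, doff)
                    )
                pending_donor = None
                s = 0  # consumed
            else:
                raise UnsupportedSpliceError(
                    f"lone donor-side truncation on exon {de}"
                )
        if s > 0:
            events.append(SpliceEvent("alt_acceptor", e, s))
        if t > 0:
            pending_donor = (e, t)
    if pending_donor is not None:
        raise UnsupportedSpliceError(
            f"lone donor-side truncation on exon {pending_donor[0]}"
        )
    events.sort(key=lambda ev: ev.exon if isinstance(ev.exon, int) else ev.exon[0])
    return events


def validate_splice_sites(model: GeneModel) -> list[tuple[bool, bool]]:
    """(donor GT ok, acceptor AG ok) for each intron, 5'->3'."""
    g = model.genomic.seq
    out = []
    for a, b in model.introns:
        out.append((g[a : a + 2] == "GT", g[b - 2 : b] == "AG"))
    return out


def shifted_site_validation(
    model: GeneModel, event: SpliceEvent
) -> tuple[bool, bool]:
    """GT/AG check at the effective (shifted) junctions of an event.

    For ``alt_acceptor`` the donor side is the canonical upstream donor; for
    ``alt_donor_acceptor`` both effective junctions are shifted into their
    exons.  ``exon_skipping`` has no shifted site and is a precondition error.
    """
    g = model.genomic.seq
    if event.mode == "alt_acceptor":
        e = event.exon
        assert isinstance(e, int)
        acc_pos = model.exons[e - 1][0] + event.acceptor_offset
        acceptor_ok = g[acc_pos - 2 : acc_pos] == "AG"
        if e >= 2:
            a, _b = model.introns[e - 2]
            donor_ok = g[a : a + 2] == "GT"
        else:
            donor_ok = True
        return donor_ok, acceptor_ok
    if event.mode == "alt_donor_acceptor":
        ei, ej = event.exon  # type: ignore[misc]
        don_pos = model.exons[ei - 1][1] - event.donor_offset
        donor_ok = g[don_pos : don_pos + 2] == "GT"
        acc_pos = model.exons[ej - 1][0] + event.acceptor_offset
        acceptor_ok = g[acc_pos - 2 : acc_pos] == "AG"
        return donor_ok, acceptor_ok
    raise ValueError(f"event mode {event.mode!r} has no shifted splice sites")


def apply_events(model: GeneModel, events: Sequence[SpliceEvent]) -> str:
    """Emit the mature transcript implied by a list of splice events."""
    n = len(model.exons)
    trunc5 = {i: 0 for i in range(1, n + 1)}
    trunc3 = {i: 0 for i in range(1, n + 1)}
    skipped: set[int] = set()
    for ev in events:
        if ev.mode == "exon_skipping":
            skipped.add(ev.exon)  # type: ignore[arg-type]
        elif ev.mode == "alt_acceptor":
            trunc5[ev.exon] = ev.acceptor_offset  # type: ignore[index]
        elif ev.mode == "alt_donor_acceptor":
            ei, ej = ev.exon  # type: ignore[misc]
            trunc3[ei] = ev.donor_offset
            trunc5[ej] = ev.acceptor_offset
        elif ev.mode == "alt_donor":
            trunc3[ev.exon] = ev.donor_offset  # type: ignore[index]
        else:
            raise UnsupportedSpliceError(ev.mode)
    parts = []
    for i in range(1, n + 1):
        if i in skipped:
            continue
        ex = model.exon_seq(i - 1)
        used = ex[trunc5[i] : len(ex) - trunc3[i]]
        if not used:
            raise ValueError(f"exon {i} fully truncated")
        parts.append(used)
    return "".join(parts)


def splice_report_tsv(
    rows: Iterable[tuple[str, SpliceEvent, Optional[tuple[bool, bool]]]],
    path: str | Path,
) -> None:
    """TSV of events: (transcript_id, event, optional shifted GT/AG flags)."""
    with open(path, "w") as fh:
        fh.write(
            "transcript_id\tmode\texon\tdonor_offset\tacceptor_offset"
            "\tshifted_donor_gt\tshifted_acceptor_ag\n"
        )
        for tid, ev, flags in rows:
            exon = (
                f"{ev.exon[0]}-{ev.exon[1]}"
                if isinstance(ev.exon, tuple)
                else str(ev.exon)
            )
            d = "" if flags is None else str(int(flags[0]))
            a = "" if flags is None else str(int(flags[1]))
            fh.write(
                f"{tid}\t{ev.mode}\t{exon}\t{ev.donor_offset}\t"
                f"{ev.acceptor_offset}\t{d}\t{a}\n"
            )
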