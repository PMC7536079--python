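"""Slipped-strand-mispairing inference on repeat-array pairs.

Variable copy numbers in this family are explained by replication slippage:
a shorter array is derived from a longer one by excision of whole units,
with the flanking units conserved.  Given two arrays of the same type, this
module infers the unit-level correspondence (order-preserving, deletions
only in the longer array) and classifies the event into five empirical
classes distinguished by which flanking units are conserved and whether the
excised units are 30 or 33 nt:

1. first unit and last three units conserved; >=1 x 30-nt units excised
2. first two units and last unit conserved; 33-nt units excised
3. first and last unit conserved; 30-nt units excised
4. first unit and last two units conserved; 30-nt units excised
5. all units (both arrays) are 33 nt; 33-nt units excised

Classes overlap, so they are evaluated in the order 5, 1, 2, 4, 3 (most to
least specific); flank thresholds are "at least" and configurable.  The data
cannot distinguish a contraction of the longer array from an expansion of
the shorter one, so events are reported as contractions with the direction
flagged.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .repeats import RepeatArray

log = logging.getLogger("rlecfam")

#: (class, min_prefix, min_suffix, excised unit length, all-33 required)
DEFAULT_CLASS_RULES: tuple[tuple[int, int, int, int, bool], ...] = (
    (5, 0, 0, 33, True),
    (1, 1, 3, 30, False),
    (2, 2, 1, 33, False),
    (4, 1, 2, 30, False),
    (3, 1, 1, 30, False),
)


@dataclass
class SlippageEvent:
    longer_id: str
    shorter_id: str
    conserved_prefix: int
    conserved_suffix: int
    excised: list[tuple[int, int]]  # (1-based unit position in longer, length)
    excised_block_contiguous: bool
    slip_class: Optional[int] = None
    direction: str = "contraction"  # the expansion hypothesis is the same event

    @property
    def n_excised(self) -> int:
        return len(self.excised)


def unit_match(u: str, v: str, min_identity: float = 0.9) -> bool:
    """True iff equal length and ungapped identity >= ``min_identity``."""
    if len(u) != len(v):
        return False
    same = sum(a == b for a, b in zip(u, v))
    return same / len(u) >= min_identity


def infer_excision(
    longer: RepeatArray,
    shorter: RepeatArray,
    min_identity: float = 0.9,
) -> Optional[SlippageEvent]:
    """Infer the unit excision relating a longer array to a shorter one.

    Searches all order-preserving matchings of the shorter array's units into
    the longer array's (deletions only in the longer array).  Every shorter
    unit must find a match; otherwise ``None``.  Among valid matchings a
    single contiguous excised block is preferred, then the 5'-most block.
    """
    nl, ns = longer.copy_number, shorter.copy_number
    if nl <= ns:
        log.warning(
            "%s vs %s: longer array must have more units (%d vs %d)",
            longer.source_id, shorter.source_id, nl, ns,
        )
        return None
    lu = [u.seq for u in longer.units]
    su = [u.seq for u in shorter.units]
    # positions of longer units each shorter unit can match
    compat = [
        [i for i, x in enumerate(lu) if unit_match(x, v, min_identity)]
        for v in su
    ]
    if any(not c for c in compat):
        return None
    best: Optional[tuple] = None
    for keep in itertools.combinations(range(nl), ns):
        if not all(keep[k] in compat[k] for k in range(ns)):
            continue
        excised = tuple(sorted(set(range(nl)) - set(keep)))
        contiguous = excised[-1] - excised[0] + 1 == len(excised)
        key = (not contiguous, excised)  # contiguous first, then 5'-most
        if best is None or key < best[0]:
            best = (key, keep, excised, contiguous)
    if best is None:
        return None
    _, keep, excised, contiguous = best
    prefix = 0
    while prefix < len(keep) and keep[prefix] == prefix:
        prefix += 1
    suffix = 0
    while suffix < len(keep) and keep[-1 - suffix] == nl - 1 - suffix:
        suffix += 1
    return SlippageEvent(
        longer.source_id,
        shorter.source_id,
        prefix,
        suffix,
        [(i + 1, len(lu[i])) for i in excised],
        contiguous,
    )


def classify_slippage(
    event: SlippageEvent,
    longer: RepeatArray,
    shorter: RepeatArray,
    rules: Sequence[tuple[int, int, int, int, bool]] = DEFAULT_CLASS_RULES,
) -> Optional[int]:
    """Assign a slippage class (1-5) from the event's flank/length signature.

    Returns ``None`` (unclassified) when no class admits the event, e.g. when
    the excised set mixes 30- and 33-nt units.
    """
    exc_lens = {L for _, L in event.excised}
    all33 = all(u.length == 33 for u in longer.units) and all(
        u.length == 33 for u in shorter.units
    )
    for cls, min_pre, min_suf, exc_len, need_all33 in rules:
        if need_all33 and not all33:
            continue
        if exc_lens != {exc_len}:
            continue
        if event.conserved_prefix >= min_pre and event.conserved_suffix >= min_suf:
            return cls
    return None


def scan_family(
    arrays: Sequence[RepeatArray],
    type_table: Optional[dict[str, list[str]]] = None,
    within_type_only: bool = True,
    min_identity: float = 0.9,
    rules: Sequence[tuple[int, int, int, int, bool]] = DEFAULT_CLASS_RULES,
) -> list[SlippageEvent]:
    """Evaluate all ordered (longer, shorter) pairs and report classified events.

    With ``within_type_only`` (the default) only pairs within the same
    motif-defined type are compared, which requires ``type_table``.  Events
    are sorted by class, then by the id pair.
    """
    by_id = {a.source_id: a for a in arrays if a.copy_number > 0}
    if within_type_only:
        if type_table is None:
            raise ValueError("within-type scan requires a type table")
        groups = [
            [by_id[r] for r in members if r in by_id]
            for motif, members in type_table.items()
            if motif
        ]
    else:
        groups = [list(by_id.values())]
    events = []
    for group in groups:
        for longer, shorter in itertools.permutations(group, 2):
            if longer.copy_number <= shorter.copy_number:
                continue
            ev = infer_excision(longer, shorter, min_identity)
            if ev is None:
                continue
            ev.slip_class = classify_slippage(ev, longer, shorter, rules)
            if ev.slip_class is not None:
                events.append(ev)
    events.sort(key=lambda e: (e.slip_class, e.longer_id, e.shorter_id))
    return events


def events_to_tsv(events: Iterable[SlippageEvent], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "longer_id\tshorter_id\tclass\tconserved_prefix\tconserved_suffix"
            "\texcised\tcontiguous\tdirection\n"
        )
        for e in events:
            exc = ",".join(f"{p}:{L}" for p, L in e.excised)
            cls = "" if e.slip_class is None else str(e.slip_class)
            fh.write(
                f"{e.longer_id}\t{e.shorter_id}\t{cls}\t{e.conserved_prefix}\t"
                f"{e.conserved_suffix}\t{exc}\t{int(e.excised_block_contiguous)}"
                f"\t{e.direction}\n"
            )
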