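"""Repeat-unit arrangement catalogues.

An arrangement pattern is the ordered list of unit lengths of an array,
written 5'->3' as a dash-joined string (e.g. ``33-30-30-33``).  Orientation
is biological: patterns are never reversed or rotated.  Pattern identity is
by unit length only by default; an optional sequence-level mode refines the
catalogue by requiring >=95% per-unit nucleotide identity.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .repeats import RepeatArray


@dataclass
class ArrangementPattern:
    pattern_string: str
    copy_number: int
    member_ids: list[str]

    def __post_init__(self) -> None:
        if self.copy_number != len(parse_pattern(self.pattern_string)):
            raise ValueError(
                f"copy number {self.copy_number} inconsistent with "
                f"{self.pattern_string!r}"
            )


def canonical_pattern(array: RepeatArray) -> str:
    """Dash-joined 5'->3' unit lengths, e.g. ``33-30-30-30-30-30-33-30-33``."""
    if array.copy_number == 0:
        raise ValueError(f"{array.source_id}: empty repeat array has no pattern")
    return "-".join(str(u.length) for u in array.units)


def parse_pattern(pattern: str) -> list[int]:
    """Parse a pattern string back to unit lengths (accepts '-' and en-dash)."""
    return [int(tok) for tok in pattern.replace("–", "-").split("-")]


def catalog(
    arrays: Iterable[RepeatArray],
    by_sequence: bool = False,
    min_unit_identity: float = 0.95,
) -> list[ArrangementPattern]:
    """Unique arrangement patterns with their member lists.

    With ``by_sequence=True`` two arrays share a pattern only if, in addition
    to matching unit lengths, every pair of corresponding units is
    >= ``min_unit_identity`` identical; a representative-linkage grouping is
    used (each array joins the first matching group).

    The result is sorted by copy number then pattern string, and is invariant
    under input order (member lists sorted).
    """
    groups: list[tuple[str, RepeatArray, list[str]]] = []
    for a in sorted(arrays, key=lambda x: x.source_id):
        if a.copy_number == 0:
            continue
        pat = canonical_pattern(a)
        placed = False
        for gpat, rep, members in groups:
            if gpat != pat:
                continue
            if by_sequence and not _units_similar(rep, a, min_unit_identity):
                continue
            members.append(a.source_id)
            placed = True
            break
        if not placed:
            groups.append((pat, a, [a.source_id]))
    out = [
        ArrangementPattern(pat, len(parse_pattern(pat)), sorted(members))
        for pat, _rep, members in groups
    ]
    out.sort(key=lambda p: (p.copy_number, p.pattern_string))
    return out


def _units_similar(a: RepeatArray, b: RepeatArray, min_identity: float) -> bool:
    for u, v in zip(a.units, b.units):
        same = sum(x == y for x, y in zip(u.seq, v.seq))
        if same / u.length < min_identity:
            return False
    return True


def per_copy_number_counts(patterns: Sequence[ArrangementPattern]) -> dict[int, int]:
    """Number of unique patterns at each copy number."""
    counts: dict[int, int] = {}
    for p in patterns:
        counts[p.copy_number] = counts.get(p.copy_number, 0) + 1
    return dict(sorted(counts.items()))


def per_type_patterns(
    arrays: Iterable[RepeatArray],
    type_table: dict[str, list[str]],
) -> dict[str, list[ArrangementPattern]]:
    """Catalogue restricted to each motif-defined type."""
    by_id = {a.source_id: a for a in arrays}
    out = {}
    for motif in sorted(type_table):
        members = [by_id[r] for r in type_table[motif] if r in by_id]
        out[motif] = catalog(members)
    return out


def catalog_to_tsv(patterns: Sequence[ArrangementPattern], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("pattern\tcopy_number\tn_members\tmember_ids\n")
        for p in patterns:
            fh.write(
                f"{p.pattern_string}\t{p.copy_number}\t{len(p.member_ids)}\t"
                f"{','.join(p.member_ids)}\n"
            )


def per_type_to_tsv(
    nested: dict[str, list[ArrangementPattern]], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("type\tpattern\tcopy_number\tn_members\tmember_ids\n")
        for motif in sorted(nested):
            for p in nested[motif]:
                fh.write(
                    f"{motif}\t{p.pattern_string}\t{p.copy_number}\t"
                    f"{len(p.member_ids)}\t{','.join(p.member_ids)}\n"
                )
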