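"""In-frame tandem-repeat decomposition of coding sequences.

The family analysed here carries a variable-number tandem repeat inside the
coding region: arrays of 30- or 33-nt units (10 or 11 codons) at copy numbers
1-9.  This module detects the repeat period, builds a consensus unit, and
segments a CDS into an ordered unit array with exact 5'/3' flanks, such that

    flank5 + unit_1 + ... + unit_k + flank3 == CDS   (byte-exact)

Unit lengths are restricted to codon multiples (default {30, 33}), which
preserves the reading frame by construction — frameshifting indels are not
modelled because they are vanishingly rare in this family.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

from .seqio import NucSequence

log = logging.getLogger("rlecfam")

DEFAULT_UNIT_LENGTHS = (30, 33)


@dataclass(frozen=True)
class RepeatUnit:
    seq: str
    identity_to_consensus: float

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass
class RepeatArray:
    """An ordered in-frame repeat-unit array with its flanking sequence."""

    source_id: str
    units: list[RepeatUnit]
    flank5: str
    flank3: str
    consensus: str
    phase_offset: int = 0  # rotation of the consensus used for tiling
    flagged: bool = False  # True when no unit passed the identity threshold

    @property
    def copy_number(self) -> int:
        return len(self.units)

    @property
    def region(self) -> str:
        return "".join(u.seq for u in self.units)

    @property
    def region_length(self) -> int:
        return sum(u.length for u in self.units)

    @property
    def unit_lengths(self) -> list[int]:
        return [u.length for u in self.units]

    def reconstruct(self) -> str:
        return self.flank5 + self.region + self.flank3


# ---------------------------------------------------------------------------
# period detection
# ---------------------------------------------------------------------------


def detect_period(
    seq: str | NucSequence,
    min_period: int = 24,
    max_period: int = 39,
) -> list[tuple[int, float]]:
    """Rank candidate tandem periods by windowed self-match score.

    For each period ``p`` the score is the best, over all window offsets
    ``o`` with ``o + 2p <= len(seq)``, of the fraction of positions
    ``i in [o, o+p)`` with ``seq[i] == seq[i+p]`` — i.e. the identity of the
    best pair of adjacent period-``p`` windows.  Windowing (rather than a
    whole-sequence autocorrelation) keeps the score near 1 when the repeat
    region is embedded in long non-repetitive flanks.

    Returns ``(period, score)`` pairs sorted by descending score, ties broken
    by the smaller period; empty when the sequence is shorter than
    ``2 * min_period``.
    """
    s = seq.seq if isinstance(seq, NucSequence) else seq.upper()
    n = len(s)
    if n < 2 * min_period:
        return []
    arr = np.frombuffer(s.encode(), dtype=np.uint8)
    out = []
    for p in range(min_period, min(max_period, n // 2) + 1):
        eq = (arr[:-p] == arr[p:]).astype(np.int32)
        c = np.concatenate(([0], np.cumsum(eq)))
        # window sums of length p over positions [o, o+p), o + 2p <= n
        n_off = n - 2 * p + 1
        sums = c[p : p + n_off] - c[:n_off]
        out.append((p, float(sums.max()) / p))
    out.sort(key=lambda t: (-t[1], t[0]))
    return out


def best_window_offset(seq: str, period: int) -> int:
    """Offset of the best-matching adjacent window pair for a given period."""
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    n = len(arr)
    eq = (arr[:-period] == arr[period:]).astype(np.int32)
    c = np.concatenate(([0], np.cumsum(eq)))
    n_off = n - 2 * period + 1
    sums = c[period : period + n_off] - c[:n_off]
    return int(np.argmax(sums))


# ---------------------------------------------------------------------------
# consensus construction
# ---------------------------------------------------------------------------


def _majority_column(chars: Sequence[str]) -> str:
    # ties -> alphabetically first base
    counts: dict[str, int] = {}
    for ch in chars:
        counts[ch] = counts.get(ch, 0) + 1
    return max(sorted(counts), key=lambda b: counts[b])


def build_consensus(seq: str | NucSequence, period: int) -> str:
    """Per-column majority consensus over period-phased windows.

    Windows are taken from offset 0 in steps of ``period`` (partial trailing
    window discarded); column ties resolve to the alphabetically first base.
    """
    s = seq.seq if isinstance(seq, NucSequence) else seq.upper()
    k = len(s) // period
    if k < 1:
        raise ValueError("sequence shorter than one period")
    windows = [s[i * period : (i + 1) * period] for i in range(k)]
    return "".join(
        _majority_column([w[j] for w in windows]) for j in range(period)
    )


def _ident(a: str, b: str) -> float:
    return sum(x == y for x, y in zip(a, b)) / len(a)


def localized_consensus(seq: str, period: int, anchor: int) -> str:
    """Consensus restricted to the repeat region around an anchor window.

    Starting from the window pair at ``anchor`` found by period detection,
    adjacent windows are accreted left and right while they stay >= 60%
    identical to the anchor window, then a column-majority consensus is taken
    over the accreted windows only.  This keeps non-repetitive flank sequence
    out of the consensus, which matters at low copy numbers.
    """
    n = len(seq)
    anchor_w = seq[anchor : anchor + period]
    windows = [anchor_w, seq[anchor + period : anchor + 2 * period]]
    o = anchor - period
    while o >= 0 and _ident(seq[o : o + period], anchor_w) >= 0.6:
        windows.insert(0, seq[o : o + period])
        o -= period
    o = anchor + 2 * period
    while o + period <= n and _ident(seq[o : o + period], anchor_w) >= 0.6:
        windows.append(seq[o : o + period])
        o += period
    return "".join(
        _majority_column([w[j] for w in windows]) for j in range(period)
    )


# ---------------------------------------------------------------------------
# segmentation (dynamic programming over codon-granular unit tilings)
# ---------------------------------------------------------------------------


def _match_counts(seq_arr: np.ndarray, cons: str, length: int) -> np.ndarray:
    """Best per-start match counts of windows of ``length`` vs the consensus.

    ``length`` may equal the consensus length m, m+3 (one extra codon in the
    unit; the best 3-nt deletion from the window is found), or m-3 (one codon
    missing; the best 3-nt skip in the consensus is found).  Indels are
    allowed at any position — frame preservation is guaranteed by the unit
    lengths alone, not by pinning indels to codon boundaries.
    """
    m = len(cons)
    c = np.frombuffer(cons.encode(), dtype=np.uint8)
    n = len(seq_arr)
    if n < length:
        return np.zeros(0, dtype=np.int32)
    W = np.lib.stride_tricks.sliding_window_view(seq_arr, length)
    if length == m:
        return (W == c).sum(axis=1).astype(np.int32)
    if length == m + 3:
        # delete window[j:j+3]; matched = pref(A, j) + suff(B, j)
        A = (W[:, :m] == c).astype(np.int32)
        B = (W[:, 3:] == c).astype(np.int32)
        cumA = np.concatenate([np.zeros((len(W), 1), np.int32), np.cumsum(A, 1)], 1)
        sufB = np.concatenate(
            [np.cumsum(B[:, ::-1], 1)[:, ::-1], np.zeros((len(W), 1), np.int32)], 1
        )
        return (cumA[:, : m + 1] + sufB[:, : m + 1]).max(axis=1)
    if length == m - 3:
        # skip consensus[j:j+3]
        A = (W == c[: m - 3]).astype(np.int32)
        B = (W == c[3:]).astype(np.int32)
        cumA = np.concatenate([np.zeros((len(W), 1), np.int32), np.cumsum(A, 1)], 1)
        sufB = np.concatenate(
            [np.cumsum(B[:, ::-1], 1)[:, ::-1], np.zeros((len(W), 1), np.int32)], 1
        )
        return (cumA[:, : m - 2] + sufB[:, : m - 2]).max(axis=1)
    raise ValueError(f"unit length {length} incompatible with consensus {m}")


def segment_units(
    cds: str | NucSequence,
    consensus: str,
    min_identity: float = 0.8,
    allowed_unit_lengths: Sequence[int] = DEFAULT_UNIT_LENGTHS,
    source_id: str = "",
    phase_offset: int = 0,
) -> RepeatArray:
    """Tile a maximal contiguous region of a CDS into repeat units.

    Dynamic programming over all contiguous tilings whose units (i) have a
    length in ``allowed_unit_lengths`` within one codon of the consensus
    length and (ii) align to the consensus at >= ``min_identity``.  The
    tiling maximizes total matched bases; ties prefer fewer units, then the
    5'-most region.  Untiled prefix/suffix become the flanks.  When no unit
    passes the threshold the whole CDS is returned as flank with
    ``flagged=True``.
    """
    s = cds.seq if isinstance(cds, NucSequence) else cds.upper()
    sid = source_id or (cds.id if isinstance(cds, NucSequence) else "")
    m = len(consensus)
    lengths = sorted(
        L for L in set(allowed_unit_lengths) if L in (m - 3, m, m + 3) and L > 0
    )
    if not lengths:
        raise ValueError(
            f"no allowed unit length within one codon of consensus length {m}"
        )
    n = len(s)
    arr = np.frombuffer(s.encode(), dtype=np.uint8)
    # score = 2*matches - 3 gap penalty for length-mismatched units: without
    # the penalty a unit could absorb flank bases into a free deletion and
    # tie an exact tiling, stealing the 5'-most tie-break
    cand: dict[int, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for L in lengths:
        mc = _match_counts(arr, consensus, L)
        ok = mc >= min_identity * min(L, m)
        cand[L] = (2 * mc - (3 if L != m else 0), ok, mc)

    NEG = (-1, 0, 0)
    # dp[e]: best (matches, -units, -start) over tilings of a contiguous run
    # ending exactly at position e (5'-most start preferred on ties)
    dp: list[tuple[int, int, int]] = [NEG] * (n + 1)
    back: list[Optional[int]] = [None] * (n + 1)  # unit length ending at e
    best = NEG
    best_end = -1
    for e in range(min(lengths), n + 1):
        for L in lengths:
            a = e - L
            if a < 0:
                continue
            sc_arr, ok, _mc = cand[L]
            if a >= len(sc_arr) or not ok[a]:
                continue
            sc = int(sc_arr[a])
            # extend an existing run or start a new one at a
            if dp[a][0] >= 0:
                t = (dp[a][0] + sc, dp[a][1] - 1, dp[a][2])
            else:
                t = (sc, -1, -a)
            if t > dp[e]:
                dp[e] = t
                back[e] = L
        if dp[e] > best:
            best = dp[e]
            best_end = e

    if best_end < 0:
        log.debug("%s: no repeat unit passed identity threshold", sid)
        return RepeatArray(sid, [], s, "", consensus, phase_offset, flagged=True)

    # traceback
    lengths_rev: list[int] = []
    e = best_end
    start = -best[2]
    while e > start:
        L = back[e]
        assert L is not None
        lengths_rev.append(L)
        e -= L
    units = []
    pos = start
    for L in reversed(lengths_rev):
        u = s[pos : pos + L]
        mc = cand[L][2]
        units.append(RepeatUnit(u, int(mc[pos]) / min(L, m)))
        pos += L
    return RepeatArray(
        sid, units, s[:start], s[best_end:], consensus, phase_offset
    )


def _array_key(a: RepeatArray) -> tuple:
    m = len(a.consensus)
    score = sum(
        2 * u.identity_to_consensus * min(u.length, m)
        - (3 if u.length != m else 0)
        for u in a.units
    )
    return (round(score, 6), -a.copy_number, -len(a.flank5))


def decompose(
    cds: str | NucSequence,
    consensus: Optional[str] = None,
    min_identity: float = 0.8,
    allowed_unit_lengths: Sequence[int] = DEFAULT_UNIT_LENGTHS,
    detect_threshold: float = 0.8,
    min_period: int = 24,
    max_period: int = 39,
) -> RepeatArray:
    """Full decomposition: period detection, consensus, phased segmentation.

    When ``consensus`` is given (e.g. a family-level consensus), detection is
    skipped — this is required for single-copy arrays, which carry no tandem
    self-similarity of their own.  Otherwise the top-scoring period above
    ``detect_threshold`` is used and a region-localized consensus is built.
    All rotations of the consensus are tried and the segmentation with most
    matched bases kept (ties: fewer units, then 5'-most, then the smallest
    rotation), because the phase recovered from self-similarity is an
    arbitrary rotation of the biological unit boundary.
    """
    s = cds.seq if isinstance(cds, NucSequence) else cds.upper()
    sid = cds.id if isinstance(cds, NucSequence) else ""
    if consensus is None:
        ranked = detect_period(s, min_period, max_period)
        if not ranked or ranked[0][1] < detect_threshold:
            return RepeatArray(sid, [], s, "", "", flagged=True)
        period = ranked[0][0]
        anchor = best_window_offset(s, period)
        consensus = localized_consensus(s, period, anchor)
        rotations = range(len(consensus))
    else:
        rotations = range(len(consensus))
    best: Optional[RepeatArray] = None
    for r in rotations:
        c_r = consensus[r:] + consensus[:r]
        arr = segment_units(
            s, c_r, min_identity, allowed_unit_lengths, sid, phase_offset=r
        )
        if arr.flagged:
            continue
        if best is None or _array_key(arr) > _array_key(best):
            best = arr
    if best is None:
        return RepeatArray(sid, [], s, "", consensus, flagged=True)
    return best


def family_consensus(
    seqs: Iterable[str | NucSequence],
    detect_threshold: float = 0.8,
    min_period: int = 24,
    max_period: int = 39,
) -> Optional[str]:
    """Derive one consensus unit for a whole family.

    The member with the strongest period signal contributes the consensus;
    members with no detectable tandem structure (e.g. single-copy arrays)
    are segmented against it downstream.
    """
    best_score, best = -1.0, None
    for rec in seqs:
        s = rec.seq if isinstance(rec, NucSequence) else rec.upper()
        ranked = detect_period(s, min_period, max_period)
        if ranked and ranked[0][1] > best_score:
            best_score = ranked[0][1]
            best = (s, ranked[0][0])
    if best is None or best_score < detect_threshold:
        return None
    s, period = best
    anchor = best_window_offset(s, period)
    return localized_consensus(s, period, anchor)


def decompose_family(
    seqs: Sequence[NucSequence],
    min_identity: float = 0.8,
    allowed_unit_lengths: Sequence[int] = DEFAULT_UNIT_LENGTHS,
    detect_threshold: float = 0.8,
) -> list[RepeatArray]:
    """Decompose every member with one shared, phase-fixed consensus.

    The member with the strongest period signal contributes the consensus
    and fixes its rotation (via a full rotation search on that member only);
    every member is then segmented against that single rotated consensus.
    A per-member rotation search would let different members settle on
    different phases, making their units incomparable across the family —
    which would corrupt pattern cataloguing and slippage inference.
    """
    cons = family_consensus(seqs, detect_threshold)
    if cons is None:
        log.warning("no tandem period detected in any family member")
        return [
            RepeatArray(r.id, [], r.seq, "", "", flagged=True) for r in seqs
        ]
    # fix the rotation on the best-signal member
    best_score, ref = -1.0, None
    for r in seqs:
        ranked = detect_period(r.seq)
        if ranked and ranked[0][1] > best_score:
            best_score, ref = ranked[0][1], r
    ref_arr = decompose(ref, cons, min_identity, allowed_unit_lengths)
    c_star = ref_arr.consensus if not ref_arr.flagged else cons
    phase = ref_arr.phase_offset if not ref_arr.flagged else 0
    return [
        segment_units(
            r, c_star, min_identity, allowed_unit_lengths,
            source_id=r.id, phase_offset=phase,
        )
        for r in seqs
    ]


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------


def arrays_to_tsv(arrays: Iterable[RepeatArray], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "id\tcopy_number\tunit_lengths\tregion_length\t"
            "flank5_length\tflank3_length\tflagged\n"
        )
        for a in arrays:
            pat = "-".join(str(L) for L in a.unit_lengths)
            fh.write(
                f"{a.source_id}\t{a.copy_number}\t{pat}\t{a.region_length}\t"
                f"{len(a.flank5)}\t{len(a.flank3)}\t{int(a.flagged)}\n"
            )


def arrays_to_json(arrays: Iterable[RepeatArray], path: str | Path) -> None:
    payload = [
        {
            "id": a.source_id,
            "copy_number": a.copy_number,
            "units": [
                {"seq": u.seq, "length": u.length,
                 "identity_to_consensus": round(u.identity_to_consensus, 4)}
                for u in a.units
            ],
            "flank5": a.flank5,
            "flank3": a.flank3,
            "consensus": a.consensus,
            "phase_offset": a.phase_offset,
            "flagged": a.flagged,
        }
        for a in arrays
    ]
    Path(path).write_text(json.dumps(payload, indent=1))
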