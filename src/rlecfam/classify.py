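"""Motif-based family typing and neighbour-joining phylogenetics.

Each family member carries a diagnostic six-amino-acid motif in the block
encoded by exon 5; the motif defines the member's type.  Trees are built
with the classic Saitou-Nei neighbour-joining agglomeration on p-distances
over repeat-masked protein alignments (the repeat-encoded residues are
removed before comparison so that copy-number variation does not swamp the
phylogenetic signal), with bootstrap support from column resampling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

from .repeats import RepeatArray

log = logging.getLogger("rlecfam")

#: The fifteen diagnostic motifs observed in the family.
FAMILY_MOTIFS = (
    "CNDSGD", "FHFKGG", "FHFKGD", "FHYKGD", "FQSKDG",
    "YHSKDD", "YHYQEH", "YKKKED", "YKKRED", "YNYFDD",
    "YRSKDD", "YTYKED", "YTYKKD", "YVVSDD", "YYYKED",
)

AA20 = frozenset("ACDEFGHIKLMNPQRSTVWY")


class MaskError(ValueError):
    """Repeat region not codon-resolvable within the ORF."""


class DistanceError(ValueError):
    """Undefined or invalid distance computation."""


# ---------------------------------------------------------------------------
# repeat masking and motif extraction
# ---------------------------------------------------------------------------


def mask_repeats(
    protein: str,
    repeat_array: Optional[RepeatArray],
    snap: bool = False,
) -> str:
    """Remove the repeat-encoded residues from a protein.

    The repeat region must start and end on codon boundaries of the ORF
    (flank5 length and region length divisible by 3) and map inside the
    protein; otherwise :class:`MaskError` is raised.  With ``snap=True`` a
    region whose length is a codon multiple but whose start sits 1 nt off a
    codon boundary is snapped to the nearest boundary first — decomposition
    boundaries are ambiguous by a rotation when unit copies are identical and
    a flank base happens to extend the array, so the pipeline masks with
    snapping.  Records without repeat units are returned unchanged.
    """
    if repeat_array is None or repeat_array.copy_number == 0:
        return protein
    f5 = len(repeat_array.flank5)
    rl = repeat_array.region_length
    if f5 % 3 != 0 and snap and rl % 3 == 0:
        f5 = 3 * round(f5 / 3)
    if f5 % 3 != 0 or rl % 3 != 0:
        raise MaskError(
            f"{repeat_array.source_id}: repeat region out of frame "
            f"(flank5={f5} nt, region={rl} nt)"
        )
    aa_start, aa_len = f5 // 3, rl // 3
    if aa_start + aa_len > len(protein):
        raise MaskError(
            f"{repeat_array.source_id}: repeat region maps outside the protein"
        )
    return protein[:aa_start] + protein[aa_start + aa_len :]


@dataclass(frozen=True)
class MotifAssignment:
    record_id: str
    motif: str
    anchor_pos: int  # 1-based aa position of the motif in the masked protein
    type_label: str

    def __post_init__(self) -> None:
        if len(self.motif) != 6 or not set(self.motif) <= AA20:
            raise ValueError(f"{self.record_id}: invalid motif {self.motif!r}")


def extract_motif(
    masked_protein: str,
    anchor: tuple[str, int],
    record_id: str = "",
) -> Optional[MotifAssignment]:
    """Extract the diagnostic 6-aa motif at a conserved-context anchor.

    ``anchor`` is ``(context_kmer, offset)``: the motif is the 6 residues at
    ``offset`` from the start of the context k-mer, which is located by exact
    search first, then by a single-mismatch search.  Returns ``None``
    (unassigned) when the anchor cannot be located or the motif would be
    truncated or contain non-standard residues.
    """
    context, offset = anchor
    pos = masked_protein.find(context)
    if pos < 0:
        k = len(context)
        for i in range(len(masked_protein) - k + 1):
            if sum(a != b for a, b in zip(masked_protein[i : i + k], context)) <= 1:
                pos = i
                break
    if pos < 0:
        return None
    start = pos + offset
    motif = masked_protein[start : start + 6]
    if len(motif) != 6 or not set(motif) <= AA20:
        return None
    return MotifAssignment(record_id, motif, start + 1, motif)


def assign_types(
    assignments: Iterable[Optional[MotifAssignment]],
) -> dict[str, list[str]]:
    """Group members by motif; one type per distinct motif.

    Unassigned members (``None``) are collected under the key ``""``.
    The grouping is invariant under input order (keys sorted).
    """
    groups: dict[str, list[str]] = {}
    for a in assignments:
        key = "" if a is None else a.motif
        rid = "?" if a is None else a.record_id
        groups.setdefault(key, []).append(rid)
    return {k: sorted(groups[k]) for k in sorted(groups)}


def n_types(type_table: dict[str, list[str]]) -> int:
    return sum(1 for k in type_table if k)


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------


def p_distance(aligned_a: str, aligned_b: str) -> float:
    """Proportion of differing sites; gap ('-') and 'X' columns excluded."""
    if len(aligned_a) != len(aligned_b):
        raise DistanceError("aligned sequences differ in length")
    valid = diff = 0
    for x, y in zip(aligned_a, aligned_b):
        if x in "-X" or y in "-X":
            continue
        valid += 1
        diff += x != y
    if valid == 0:
        raise DistanceError("no valid columns shared by the pair")
    return diff / valid


@dataclass
class DistanceMatrix:
    ids: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise DistanceError("matrix shape does not match id count")
        if not np.all(np.isfinite(self.d)):
            raise DistanceError("non-finite distances")
        if not np.allclose(self.d, self.d.T):
            raise DistanceError("matrix is not symmetric")
        if not np.allclose(np.diag(self.d), 0):
            raise DistanceError("non-zero diagonal")


def p_distance_matrix(ids: Sequence[str], seqs: Sequence[str]) -> DistanceMatrix:
    n = len(ids)
    L = len(seqs[0])
    A = np.frombuffer("".join(seqs).encode(), dtype=np.uint8).reshape(n, L)
    invalid = (A == ord("-")) | (A == ord("X"))
    d = np.zeros((n, n))
    for i in range(n):
        ok = ~(invalid[i] | invalid)
        nv = ok.sum(axis=1)
        if np.any(nv == 0):
            raise DistanceError("a pair shares no valid columns")
        d[i] = ((A[i] != A) & ok).sum(axis=1) / nv
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2
    return DistanceMatrix(list(ids), d)


# ---------------------------------------------------------------------------
# neighbour joining
# ---------------------------------------------------------------------------


@dataclass
class Phylogeny:
    """An unrooted tree: leaves 0..n-1 named by ``ids``, internal nodes above.

    ``adj`` maps node -> {neighbor: branch length}.  ``support`` maps the
    canonical bipartition of an internal edge (the leaf-name side not
    containing ``ids[0]``) to a bootstrap percentage in [0, 100].
    """

    ids: list[str]
    adj: dict[int, dict[int, float]]
    support: dict[frozenset, float] = field(default_factory=dict)

    def _side_leaves(self, u: int, v: int) -> frozenset:
        # leaves reachable from v without crossing edge (u, v)
        seen, stack, leaves = {u, v}, [v], []
        while stack:
            x = stack.pop()
            if x < len(self.ids):
                leaves.append(self.ids[x])
            for y in self.adj[x]:
                if y not in seen:
                    seen.add(y)
                    stack.append(y)
        return frozenset(leaves)

    def bipartitions(self) -> set[frozenset]:
        """Canonical non-trivial bipartitions, one per internal edge."""
        out = set()
        for u in self.adj:
            for v in self.adj[u]:
                if u < v and u >= len(self.ids) and v >= len(self.ids):
                    side = self._side_leaves(u, v)
                    if self.ids[0] in side:
                        side = frozenset(self.ids) - side
                    if 2 <= len(side) <= len(self.ids) - 2:
                        out.add(side)
        return out

    def newick(self, with_support: bool = True) -> str:
        root = max(self.adj)  # an internal node (or a leaf for n=2)

        def fmt(u: int, parent: Optional[int]) -> str:
            kids = [v for v in self.adj[u] if v != parent]
            if not kids:
                name = self.ids[u] if u < len(self.ids) else ""
                bl = f":{self.adj[parent][u]:.6f}" if parent is not None else ""
                return f"{name}{bl}"
            inner = ",".join(fmt(v, u) for v in sorted(kids))
            label = ""
            if with_support and parent is not None:
                side = self._side_leaves(parent, u)
                if self.ids[0] in side:
                    side = frozenset(self.ids) - side
                if side in self.support:
                    label = f"{self.support[side]:g}"
            bl = f":{self.adj[parent][u]:.6f}" if parent is not None else ""
            return f"({inner}){label}{bl}"

        return fmt(root, None) + ";"


def nj_tree(matrix: DistanceMatrix) -> Phylogeny:
    """Saitou-Nei neighbour joining with deterministic tie-breaking.

    At each step the pair minimizing Q(i,j) = (n-2) d(i,j) - R_i - R_j is
    joined; ties resolve to the lexicographically lowest active index pair.
    Negative branch lengths are clamped to zero with a logged warning.
    """
    n0 = len(matrix.ids)
    if n0 < 2:
        raise DistanceError("need at least 2 taxa")
    ids = list(matrix.ids)
    adj: dict[int, dict[int, float]] = {i: {} for i in range(n0)}
    next_node = n0

    def clamp(x: float) -> float:
        if x < 0:
            log.warning("negative NJ branch length %.4g clamped to 0", x)
            return 0.0
        return x

    def connect(u: int, v: int, bl: float) -> None:
        adj[u][v] = bl
        adj[v][u] = bl

    if n0 == 2:
        connect(0, 1, clamp(float(matrix.d[0, 1])))
        return Phylogeny(ids, adj)

    active = list(range(n0))
    D = matrix.d.copy()
    # D indexed by position in `active`
    while len(active) > 3:
        m = len(active)
        R = D.sum(axis=1)
        Q = (m - 2) * D - R[:, None] - R[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        # lowest (i, j) pair among ties, i < j by active-node index
        ties = np.argwhere(np.isclose(Q, qmin, rtol=0, atol=1e-12))
        pairs = sorted(
            (active[min(a, b)], active[max(a, b)], min(a, b), max(a, b))
            for a, b in ties
        )
        _, _, i, j = pairs[0]
        dij = D[i, j]
        li = 0.5 * dij + (R[i] - R[j]) / (2 * (m - 2))
        lj = dij - li
        u = next_node
        next_node += 1
        adj[u] = {}
        connect(u, active[i], clamp(li))
        connect(u, active[j], clamp(lj))
        # distances from u to remaining nodes
        keep = [k for k in range(m) if k not in (i, j)]
        du = 0.5 * (D[i, keep] + D[j, keep] - dij)
        Dn = np.empty((m - 1, m - 1))
        Dn[: m - 2, : m - 2] = D[np.ix_(keep, keep)]
        Dn[: m - 2, m - 2] = du
        Dn[m - 2, : m - 2] = du
        Dn[m - 2, m - 2] = 0.0
        D = Dn
        active = [active[k] for k in keep] + [u]

    # final three nodes join at a central vertex (closed form)
    a, b, c = active
    dab, dac, dbc = D[0, 1], D[0, 2], D[1, 2]
    u = next_node
    adj[u] = {}
    connect(u, a, clamp(0.5 * (dab + dac - dbc)))
    connect(u, b, clamp(0.5 * (dab + dbc - dac)))
    connect(u, c, clamp(0.5 * (dac + dbc - dab)))
    return Phylogeny(ids, adj)


def bootstrap_support(
    ids: Sequence[str],
    alignment: Sequence[str],
    n_reps: int = 1000,
    seed: int = 0,
) -> Phylogeny:
    """NJ tree with bootstrap support from column resampling.

    Columns are resampled with replacement ``n_reps`` times; each replicate
    alignment yields an NJ tree and every internal-edge bipartition of the
    main tree is scored by its replicate frequency x 100.  Deterministic
    under ``seed``.  With ``n_reps=0`` the tree is returned without support.
    """
    L = len(alignment[0])
    if L < 2 and n_reps > 0:
        raise DistanceError("need at least 2 alignment columns to bootstrap")
    tree = nj_tree(p_distance_matrix(ids, alignment))
    if n_reps == 0 or len(ids) < 4:
        return tree
    main_bips = tree.bipartitions()
    counts = {bp: 0 for bp in main_bips}
    rng = np.random.default_rng(seed)
    arr = np.frombuffer("".join(alignment).encode(), dtype=np.uint8)
    arr = arr.reshape(len(ids), L)
    for _ in range(n_reps):
        cols = rng.integers(0, L, size=L)
        rep = ["".join(map(chr, row)) for row in arr[:, cols]]
        try:
            rep_tree = nj_tree(p_distance_matrix(list(ids), rep))
        except DistanceError:
            continue
        rep_bips = rep_tree.bipartitions()
        for bp in main_bips:
            if bp in rep_bips:
                counts[bp] += 1
    tree.support = {bp: 100.0 * c / n_reps for bp, c in counts.items()}
    return tree


# ---------------------------------------------------------------------------
# alignment helper (experimental) and reports
# ---------------------------------------------------------------------------


def align_proteins(seqs: Sequence[str]) -> list[str]:
    """Reference-projection alignment for unequal-length inputs (experimental).

    Families simulated by this package share a no-indel backbone, so masked
    proteins are already aligned and pass through unchanged.  For real data
    each sequence is globally aligned against the longest member and
    projected onto its coordinates (insertions relative to the reference are
    dropped); this is a pragmatic fallback, not a substitute for a dedicated
    MSA tool.
    """
    if len(set(map(len, seqs))) == 1:
        return list(seqs)
    log.warning(
        "unequal masked-protein lengths; using experimental "
        "reference-projection alignment"
    )
    center = max(seqs, key=len)
    aligned = []
    for s in seqs:
        rc, rs = _nw_pair(center, s)
        aligned.append("".join(b for a, b in zip(rc, rs) if a != "-"))
    return aligned


def _nw_pair(a: str, b: str) -> tuple[str, str]:
    """Needleman-Wunsch (match +1, mismatch -1, gap -2)."""
    n, m = len(a), len(b)
    score = np.zeros((n + 1, m + 1))
    score[:, 0] = -2 * np.arange(n + 1)
    score[0, :] = -2 * np.arange(m + 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = 1 if a[i - 1] == b[j - 1] else -1
            score[i, j] = max(
                score[i - 1, j - 1] + s, score[i - 1, j] - 2, score[i, j - 1] - 2
            )
    ra, rb = [], []
    i, j = n, m
    while i > 0 or j > 0:
        if i > 0 and j > 0 and score[i, j] == score[i - 1, j - 1] + (
            1 if a[i - 1] == b[j - 1] else -1
        ):
            ra.append(a[i - 1]); rb.append(b[j - 1]); i -= 1; j -= 1
        elif i > 0 and score[i, j] == score[i - 1, j] - 2:
            ra.append(a[i - 1]); rb.append("-"); i -= 1
        else:
            ra.append("-"); rb.append(b[j - 1]); j -= 1
    return "".join(reversed(ra)), "".join(reversed(rb))


def types_to_tsv(
    type_table: dict[str, list[str]],
    path: str | Path,
    copy_numbers: Optional[dict[str, int]] = None,
) -> None:
    with open(path, "w") as fh:
        fh.write("id\tmotif\ttype\tcopy_number\n")
        for motif in sorted(type_table):
            label = motif or "unassigned"
            for rid in sorted(type_table[motif]):
                cn = "" if not copy_numbers else copy_numbers.get(rid, "")
                fh.write(f"{rid}\t{motif}\t{label}\t{cn}\n")
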