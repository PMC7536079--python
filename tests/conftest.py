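import numpy as np
import pytest

from rlecfam import FamilyConfig, generate_family


@pytest.fixture(scope="session")
def family20():
    """A small default-noise family shared by read-only tests."""
    return generate_family(FamilyConfig(n_members=20, seed=11))


@pytest.fixture(scope="session")
def family20_clean():
    """A zero-noise family: every truth object must be exactly recoverable."""
    return generate_family(
        FamilyConfig(n_members=20, seed=11, substitution_rate=0.0)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


# ---------------------------------------------------------------------------
# independent oracles (plain-loop implementations, no shared code paths)
# ---------------------------------------------------------------------------


def oracle_autocorr_score(seq: str, period: int) -> float:
    """Best adjacent-window identity for a period, by direct double loop."""
    n = len(seq)
    best = 0.0
    for o in range(0, n - 2 * period + 1):
        same = sum(
            seq[o + i] == seq[o + period + i] for i in range(period)
        )
        best = max(best, same / period)
    return best


def _oracle_unit_score(window: str, cons: str):
    """(score, identity) of one window vs the consensus, plain loops.

    Equal length: hamming.  One codon longer: best 3-nt deletion from the
    window.  One codon shorter: best 3-nt skip in the consensus.  Score is
    2*matches - 3 for length-mismatched units (gap penalty).
    """
    m, L = len(cons), len(window)
    if L == m:
        matches = sum(a == b for a, b in zip(window, cons))
        return 2 * matches, matches / m
    if L == m + 3:
        best = 0
        for j in range(L - 2):
            cand = window[:j] + window[j + 3 :]
            best = max(best, sum(a == b for a, b in zip(cand, cons)))
        return 2 * best - 3, best / m
    if L == m - 3:
        best = 0
        for j in range(m - 2):
            cand = cons[:j] + cons[j + 3 :]
            best = max(best, sum(a == b for a, b in zip(window, cand)))
        return 2 * best - 3, best / L
    raise ValueError(L)


def oracle_best_tiling(seq: str, cons: str, min_identity=0.8,
                       allowed=(30, 33)):
    """Exhaustive search over all contiguous codon-granular unit tilings.

    Returns (score, n_units, start, lengths) of the optimum under the same
    objective as the decomposer: max score, then fewer units, then 5'-most.
    None when no tiling exists.
    """
    m = len(cons)
    lengths = sorted(L for L in allowed if L in (m - 3, m, m + 3))
    n = len(seq)
    best = None

    def extend(start, pos, lens, score):
        nonlocal best
        if lens:
            key = (score, -len(lens), -start)
            if best is None or key > best[0]:
                best = (key, (score, len(lens), start, list(lens)))
        for L in lengths:
            if pos + L > n:
                continue
            sc, ident = _oracle_unit_score(seq[pos : pos + L], cons)
            if ident < min_identity:
                continue
            lens.append(L)
            extend(start, pos + L, lens, score + sc)
            lens.pop()

    for start in range(n):
        extend(start, start, [], 0)
    return None if best is None else best[1]


def oracle_excision_matchings(longer, shorter, min_identity=0.9):
    """All order-preserving matchings of shorter units into longer units,
    found by plain recursion (every shorter unit must match)."""

    def match(u, v):
        if len(u) != len(v):
            return False
        return sum(a == b for a, b in zip(u, v)) / len(u) >= min_identity

    out = []

    def rec(si, lo, chosen):
        if si == len(shorter):
            out.append(tuple(chosen))
            return
        for j in range(lo, len(longer) - (len(shorter) - si) + 1):
            if match(longer[j], shorter[si]):
                chosen.append(j)
                rec(si + 1, j + 1, chosen)
                chosen.pop()

    rec(0, 0, [])
    return out


# --- least-squares topology search for NJ ---------------------------------


def enumerate_topologies(n):
    """All unrooted leaf-labelled binary topologies on n leaves, as edge
    lists over nodes (leaves 0..n-1, internal nodes n..)."""
    assert n >= 3
    base = [(0, n), (1, n), (2, n)]
    trees = [(base, n + 1)]
    for leaf in range(3, n):
        nxt = []
        for edges, next_node in trees:
            for k in range(len(edges)):
                u, v = edges[k]
                w = next_node
                new_edges = (
                    edges[:k] + edges[k + 1 :] + [(u, w), (v, w), (leaf, w)]
                )
                nxt.append((new_edges, next_node + 1))
        trees = nxt
    return [e for e, _ in trees]


def topology_bipartitions(edges, n, ids):
    adj = {}
    for u, v in edges:
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)
    bips = set()
    for u, v in edges:
        if u < n or v < n:
            continue
        seen, stack, leaves = {u, v}, [v], []
        while stack:
            x = stack.pop()
            if x < n:
                leaves.append(ids[x])
            for y in adj[x]:
                if y not in seen:
                    seen.add(y)
                    stack.append(y)
        side = frozenset(leaves)
        if ids[0] in side:
            side = frozenset(ids) - side
        if 2 <= len(side) <= n - 2:
            bips.add(side)
    return bips


def ls_topology_search(D, ids):
    """Bipartitions of the least-squares-best topology for a distance
    matrix, over every topology (exhaustive)."""
    n = len(ids)
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    best = None
    for edges in enumerate_topologies(n):
        adj = {}
        for ei, (u, v) in enumerate(edges):
            adj.setdefault(u, []).append((v, ei))
            adj.setdefault(v, []).append((u, ei))

        def path_edges(a, b):
            # DFS path from a to b
            stack = [(a, None, [])]
            seen = {a}
            while stack:
                x, _, path = stack.pop()
                if x == b:
                    return path
                for y, ei in adj[x]:
                    if y not in seen:
                        seen.add(y)
                        stack.append((y, x, path + [ei]))
            raise RuntimeError

        X = np.zeros((len(pairs), len(edges)))
        y = np.zeros(len(pairs))
        for r, (i, j) in enumerate(pairs):
            for ei in path_edges(i, j):
                X[r, ei] = 1.0
            y[r] = D[i, j]
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        sse = float(((X @ beta - y) ** 2).sum())
        if best is None or sse < best[0] - 1e-12:
            best = (sse, edges)
    return topology_bipartitions(best[1], n, ids)


def random_additive_matrix(rng, n):
    """A distance matrix that is exactly additive on a random binary tree;
    returns (D, bipartitions of the generating topology)."""
    topos = enumerate_topologies(n)
    edges = topos[rng.integers(0, len(topos))]
    lengths = {e: float(rng.uniform(0.15, 1.0)) for e in edges}
    adj = {}
    for u, v in edges:
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)

    def dist(a, b):
        stack = [(a, None, 0.0)]
        while stack:
            x, parent, d = stack.pop()
            if x == b:
                return d
            for y in adj[x]:
                if y != parent:
                    e = (x, y) if (x, y) in lengths else (y, x)
                    stack.append((y, x, d + lengths[e]))
        raise RuntimeError

    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = dist(i, j)
    ids = [f"t{i}" for i in range(n)]
    return D, ids, topology_bipartitions(edges, n, ids)
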