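"""Independent oracles used by the test suite.

Each oracle recomputes a quantity by a route deliberately different from
the package implementation: explicit per-column loops for p-distances,
graph shortest paths for patristic distances, exhaustive enumeration of
global alignments, the two-pass textbook formula for Pearson, and a
truth-table enumerator for concordance classes.
"""

from __future__ import annotations

import itertools
import math

import networkx as nx
import numpy as np

from otuaudit.io_formats import Lineage, PhyloTree


# ---------------------------------------------------------------------------
# MSD brute-force column counter
# ---------------------------------------------------------------------------

def msd_bruteforce(row_a: str, row_b: str) -> tuple[int, int]:
    """Count (countable, disagreeing) columns one character at a time."""
    counted = disagree = 0
    for i in range(len(row_a)):
        x, y = row_a[i], row_b[i]
        if "N" in (x, y):
            continue
        if x == "-" or y == "-":
            continue
        counted += 1
        if x != y:
            disagree += 1
    return counted, disagree


# ---------------------------------------------------------------------------
# Patristic distance via graph shortest path
# ---------------------------------------------------------------------------

def tree_graph(tree: PhyloTree) -> tuple[nx.Graph, dict[str, int]]:
    g = nx.Graph()
    leaf_ids: dict[str, int] = {}
    for node in tree.tree.preorder_node_iter():
        if node.is_leaf():
            leaf_ids[node.taxon.label] = id(node)
        for child in node.child_nodes():
            g.add_edge(id(node), id(child), weight=child.edge.length)
    return g, leaf_ids


def patristic_shortest_path(tree: PhyloTree, a: str, b: str) -> float:
    g, leaves = tree_graph(tree)
    return nx.dijkstra_path_length(g, leaves[a], leaves[b])


def patristic_all_pairs(tree: PhyloTree) -> dict[tuple[str, str], float]:
    g, leaves = tree_graph(tree)
    out = {}
    labels = sorted(leaves)
    lengths = dict(nx.all_pairs_dijkstra_path_length(g))
    for a, b in itertools.combinations(labels, 2):
        out[(a, b)] = lengths[leaves[a]][leaves[b]]
    return out


# ---------------------------------------------------------------------------
# Exhaustive global-alignment enumeration
# ---------------------------------------------------------------------------

def nw_enumerate_max(sa: str, sb: str, match: float, mismatch: float,
                     gap: float) -> float:
    """Max score over every global alignment, by exhaustive recursion."""
    def rec(i: int, j: int) -> float:
        if i == len(sa) and j == len(sb):
            return 0.0
        best = -math.inf
        if i < len(sa) and j < len(sb):
            s = match if sa[i] == sb[j] else mismatch
            best = max(best, s + rec(i + 1, j + 1))
        if i < len(sa):
            best = max(best, gap + rec(i + 1, j))
        if j < len(sb):
            best = max(best, gap + rec(i, j + 1))
        return best

    return rec(0, 0)


def _paths(m: int, n: int):
    """All monotone paths (diag/up/left) from (0,0) to (m,n)."""
    stack = [(0, 0, [])]
    while stack:
        i, j, cols = stack.pop()
        if i == m and j == n:
            yield cols
            continue
        if i < m and j < n:
            stack.append((i + 1, j + 1, cols + [(i, j)]))
        if i < m:
            stack.append((i + 1, j, cols))  # gap column, b side
        if j < n:
            stack.append((i, j + 1, cols))  # gap column, a side


def nw_enumerate_all_pairs(m: int, n: int, alphabet: str, match: float,
                           mismatch: float, gap: float) -> np.ndarray:
    """Best enumeration score for every pair of length-m x length-n sequences.

    Returns a (|alphabet|^m, |alphabet|^n) matrix indexed by the sequences
    in itertools.product order.
    """
    k = len(alphabet)
    A = np.array(list(itertools.product(range(k), repeat=m)))  # (k^m, m)
    B = np.array(list(itertools.product(range(k), repeat=n)))
    eq = {
        (i, j): (A[:, i, None] == B[None, :, j])
        for i in range(m) for j in range(n)
    }
    best = np.full((k ** m, k ** n), -np.inf)
    for cols in _paths(m, n):
        n_gap = (m - len(cols)) + (n - len(cols))
        score = np.full(best.shape, gap * n_gap + mismatch * len(cols))
        for i, j in cols:
            score += (match - mismatch) * eq[(i, j)]
        np.maximum(best, score, out=best)
    return best


# ---------------------------------------------------------------------------
# Pearson, two-pass textbook formula
# ---------------------------------------------------------------------------

def pearson_two_pass(xs, ys) -> float:
    n = len(xs)
    mx = sum(xs) / n
    my = sum(ys) / n
    sxy = sum((x - mx) * (y - my) for x, y in zip(xs, ys))
    sxx = sum((x - mx) ** 2 for x in xs)
    syy = sum((y - my) ** 2 for y in ys)
    return sxy / math.sqrt(sxx * syy)


# ---------------------------------------------------------------------------
# Concordance truth-table enumerator
# ---------------------------------------------------------------------------

def enumerate_lineage_pairs():
    """Yield (rep, member, expected_class_name) over all valid rank patterns.

    For representative depth da and member depth db (0..7 each), every
    equal/different pattern on the shared assigned prefix is generated.
    The expected class follows from the construction: any differing shared
    rank -> conflicting; else shallower member -> under, deeper -> over,
    equal depths -> concordant.
    """
    for da in range(8):
        for db in range(8):
            shared = min(da, db)
            for pattern in itertools.product((True, False), repeat=shared):
                rep_names = [f"R{i}" for i in range(da)]
                mem_names = [
                    (f"R{i}" if (i >= shared or pattern[i]) else f"R{i}x")
                    for i in range(db)
                ]
                if any(not p for p in pattern):
                    expected = "conflicting"
                elif db < da:
                    expected = "under"
                elif db > da:
                    expected = "over"
                else:
                    expected = "concordant"
                yield (Lineage.from_names(*rep_names),
                       Lineage.from_names(*mem_names),
                       expected)
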