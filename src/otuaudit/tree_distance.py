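"""BLD: patristic (branch-length) distance between leaves of a tree.

The BLD between two sequences is the sum of branch lengths along the
unique path joining their leaves on the estimated tree, in expected
substitutions per site. It is independent of root placement, so trees are
treated as unrooted regardless of how the Newick file is rooted.
"""

from __future__ import annotations

import logging
from collections import deque
from typing import Iterable, Mapping

import dendropy

from .errors import InputError, UnknownIdError
from .io_formats import OTUCluster, PhyloTree
from .records import DistanceRecord

logger = logging.getLogger(__name__)


def _adjacency(tree: dendropy.Tree) -> dict[int, list[tuple[int, float]]]:
    """Undirected adjacency over node ids with edge lengths (root edge ignored)."""
    adj: dict[int, list[tuple[int, float]]] = {}
    for node in tree.preorder_node_iter():
        adj.setdefault(id(node), [])
        for child in node.child_nodes():
            length = child.edge.length
            adj.setdefault(id(child), [])
            adj[id(node)].append((id(child), length))
            adj[id(child)].append((id(node), length))
    return adj


def _leaf_nodes(tree: dendropy.Tree) -> dict[str, dendropy.Node]:
    return {lf.taxon.label: lf for lf in tree.leaf_node_iter()}


def _distances_from(tree: dendropy.Tree, source: dendropy.Node) -> dict[int, float]:
    """Path length from ``source`` to every node — one traversal of the tree."""
    adj = _adjacency(tree)
    dist = {id(source): 0.0}
    queue = deque([id(source)])
    while queue:
        u = queue.popleft()
        for v, w in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + w
                queue.append(v)
    return dist


def bld(tree: PhyloTree, leaf_a: str, leaf_b: str) -> float:
    """Patristic distance between two leaves."""
    leaves = _leaf_nodes(tree.tree)
    for label in (leaf_a, leaf_b):
        if label not in leaves:
            raise UnknownIdError(f"leaf {label!r} not present in tree")
    if leaf_a == leaf_b:
        return 0.0
    dist = _distances_from(tree.tree, leaves[leaf_a])
    return dist[id(leaves[leaf_b])]


def bld_rep_vs_all(tree: PhyloTree, cluster: OTUCluster,
                   ignore_extra_leaves: bool = True) -> list[DistanceRecord]:
    """BLD from the representative to every member, in one traversal.

    Leaves of the tree that belong to neither the representative nor the
    member set (e.g., reference taxa retained in the OTU alignment) are
    ignored with a logged count.
    """
    leaves = _leaf_nodes(tree.tree)
    rep = cluster.representative_id
    if rep not in leaves:
        raise UnknownIdError(f"representative {rep!r} of OTU {cluster.otu_id!r} not in tree")
    missing = sorted(m for m in cluster.member_ids if m not in leaves)
    if missing:
        raise UnknownIdError(
            f"OTU {cluster.otu_id!r}: member(s) {', '.join(missing)} not in tree"
        )
    wanted = set(cluster.member_ids) | {rep}
    extra = len(leaves) - len(wanted & set(leaves))
    if extra:
        if not ignore_extra_leaves:
            raise InputError(f"OTU {cluster.otu_id!r}: tree has {extra} leaves outside the OTU")
        logger.info("OTU %s: ignoring %d tree leaves outside the OTU", cluster.otu_id, extra)
    dist = _distances_from(tree.tree, leaves[rep])
    return [
        DistanceRecord(cluster.otu_id, member, bld=dist[id(leaves[member])])
        for member in sorted(cluster.member_ids)
    ]


def merge_records(msd_records: Iterable[DistanceRecord],
                  bld_records: Iterable[DistanceRecord],
                  psd_records: Iterable[DistanceRecord] = ()) -> list[DistanceRecord]:
    """Outer join of per-member records on (otu_id, member_id).

    Members present in only one input carry the other metric as absent;
    conflicting duplicate keys within one input are an error.
    """
    merged: dict[tuple[str, str], dict[str, float | None]] = {}

    def _fold(records: Iterable[DistanceRecord], metric: str) -> None:
        for rec in records:
            key = (rec.otu_id, rec.member_id)
            value = getattr(rec, metric)
            slot = merged.setdefault(key, {"msd": None, "bld": None, "psd": None})
            if slot[metric] is not None and slot[metric] != value:
                raise InputError(
                    f"conflicting {metric} values for ({key[0]}, {key[1]}): "
                    f"{slot[metric]} vs {value}"
                )
            slot[metric] = value

    _fold(msd_records, "msd")
    _fold(bld_records, "bld")
    _fold(psd_records, "psd")

    out = [
        DistanceRecord(otu, member, msd=v["msd"], bld=v["bld"], psd=v["psd"])
        for (otu, member), v in sorted(merged.items())
    ]
    partial = sum(1 for r in out if r.msd is None or r.bld is None)
    if partial:
        logger.info("merge_records: %d record(s) carry only one metric", partial)
    return out


def patristic_matrix(tree: PhyloTree, labels: list[str] | None = None
                     ) -> tuple[list[str], "list[list[float]]"]:
    """All-pairs patristic distances (convenience for diagnostics/tests)."""
    leaves = _leaf_nodes(tree.tree)
    if labels is None:
        labels = sorted(leaves)
    rows = []
    for a in labels:
        if a not in leaves:
            raise UnknownIdError(f"leaf {a!r} not present in tree")
        dist = _distances_from(tree.tree, leaves[a])
        rows.append([dist[id(leaves[b])] for b in labels])
    return labels, rows
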