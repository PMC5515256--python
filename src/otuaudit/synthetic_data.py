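"""Synthetic OTU datasets with known ground truth.

Each simulated OTU is built from a Yule (pure-birth) tree topology with
i.i.d. exponential branch lengths, rescaled per tree so the mean path
length from the designated representative leaf to every other leaf equals
``target_depth`` (in expected substitutions per site). Sequences are
evolved down the tree under Jukes–Cantor or GTR+Gamma; with the default
indel rate of 0 the true alignment is simply the site matrix, so the
pipeline's MSD is measured against an error-free MSA. A deletion-only
indel model is available to exercise gap handling.

Lineages come from a small synthetic seven-rank taxonomy. A fraction
``p_discordant`` of members (Bernoulli per member) receives a perturbed
lineage — half switched to a sibling genus (a CONFLICTING annotation),
half truncated by one rank (UNDER) — and the constructed class of every
member is recorded as ground truth.

All randomness flows from one master seed through per-OTU derived seeds,
so a dataset is reproducible as a whole and per OTU.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import dendropy
import numpy as np
from scipy import stats
from scipy.linalg import expm

from .concordance import ConcordanceClass
from .errors import InputError
from .io_formats import Lineage, MultipleAlignment, OTUCluster, PhyloTree, Sequence

_BASES = "ACGT"


# ---------------------------------------------------------------------------
# Substitution models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class JC:
    """Jukes–Cantor: equal base frequencies, one substitution rate.

    Expected p-distance at true distance d is (3/4)(1 - exp(-4d/3)).
    """

    base_freqs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)

    def site_rates(self, rng: np.random.Generator, n_sites: int) -> np.ndarray:
        return np.zeros(n_sites, dtype=np.intp)  # single rate category

    def transition_matrices(self, t: float) -> np.ndarray:
        e = math.exp(-4.0 * t / 3.0)
        same = 0.25 + 0.75 * e
        diff = 0.25 - 0.25 * e
        P = np.full((4, 4), diff)
        np.fill_diagonal(P, same)
        return P[None, :, :]


@dataclass(frozen=True)
class GTRGamma:
    """General time-reversible model with discrete-Gamma rate variation.

    ``rates`` are the six exchangeabilities (AC, AG, AT, CG, CT, GT); the
    rate matrix is normalized to one expected substitution per site per
    unit branch length. Site rates use ``n_categories`` equal-probability
    Gamma(alpha, 1/alpha) categories (category means via quantile
    midpoints, renormalized to mean one).
    """

    rates: tuple[float, float, float, float, float, float] = (1, 2, 1, 1, 2, 1)
    base_freqs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    alpha: float = 1.0
    n_categories: int = 4

    def __post_init__(self) -> None:
        if abs(sum(self.base_freqs) - 1.0) > 1e-9:
            raise InputError("base frequencies must sum to 1")
        if any(r <= 0 for r in self.rates) or self.alpha <= 0:
            raise InputError("exchangeabilities and alpha must be positive")

    def _q(self) -> np.ndarray:
        ac, ag, at, cg, ct, gt = self.rates
        pi = np.asarray(self.base_freqs)
        R = np.array([
            [0, ac, ag, at],
            [ac, 0, cg, ct],
            [ag, cg, 0, gt],
            [at, ct, gt, 0],
        ], dtype=float)
        Q = R * pi[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        mu = -(pi * np.diag(Q)).sum()
        return Q / mu

    def _category_rates(self) -> np.ndarray:
        k = self.n_categories
        quantiles = (2 * np.arange(k) + 1) / (2 * k)
        r = stats.gamma.ppf(quantiles, a=self.alpha, scale=1.0 / self.alpha)
        return r / r.mean()

    def site_rates(self, rng: np.random.Generator, n_sites: int) -> np.ndarray:
        return rng.integers(0, self.n_categories, size=n_sites)

    def transition_matrices(self, t: float) -> np.ndarray:
        Q = self._q()
        return np.stack([expm(Q * t * r) for r in self._category_rates()])


SubstModel = JC | GTRGamma


def make_model(name: str, **kwargs) -> SubstModel:
    name = name.lower()
    if name == "jc":
        return JC()
    if name in ("gtr", "gtrgamma", "gtr+gamma"):
        return GTRGamma(**kwargs)
    raise InputError(f"unknown substitution model {name!r}")


# ---------------------------------------------------------------------------
# Closed forms
# ---------------------------------------------------------------------------

def expected_p_distance(d: float) -> float:
    """Expected Jukes–Cantor p-distance at true distance ``d``.

    p = (3/4)(1 - exp(-4d/3)); the inverse of the JC correction.
    Monotone increasing with asymptote 3/4.
    """
    if d < 0:
        raise InputError(f"distance must be >= 0, got {d}")
    return 0.75 * (1.0 - math.exp(-4.0 * d / 3.0))


# ---------------------------------------------------------------------------
# Tree simulation
# ---------------------------------------------------------------------------

class _Node:
    __slots__ = ("children", "lengths", "label", "parent", "plen")

    def __init__(self, label: str | None = None):
        self.children: list[_Node] = []
        self.lengths: list[float] = []
        self.label = label
        self.parent: _Node | None = None
        self.plen = 0.0


def _yule_topology(n_leaves: int, labels: list[str], rng: np.random.Generator) -> _Node:
    root = _Node()
    first = _Node()
    second = _Node()
    root.children = [first, second]
    leaves = [first, second]
    while len(leaves) < n_leaves:
        idx = int(rng.integers(0, len(leaves)))
        node = leaves[idx]
        a, b = _Node(), _Node()
        node.children = [a, b]
        leaves[idx] = a
        leaves.append(b)
    for leaf, label in zip(leaves, labels):
        leaf.label = label
    return root


def _assign_lengths(root: _Node, rng: np.random.Generator) -> None:
    stack = [root]
    while stack:
        node = stack.pop()
        node.lengths = [float(x) for x in rng.exponential(1.0, size=len(node.children))]
        for child, ln in zip(node.children, node.lengths):
            child.parent = node
            child.plen = ln
            stack.append(child)


def _leaf_list(root: _Node) -> list[_Node]:
    out, stack = [], [root]
    while stack:
        node = stack.pop()
        if node.children:
            stack.extend(reversed(node.children))
        else:
            out.append(node)
    return out


def _leaf_distances(ref: _Node, leaves: list[_Node]) -> dict[str, float]:
    """Path length from ``ref`` to every other leaf via root depths + LCA."""
    def ancestors(node: _Node) -> dict[int, float]:
        depth: dict[int, float] = {}
        d = 0.0
        cur: _Node | None = node
        while cur is not None:
            depth[id(cur)] = d
            d += cur.plen
            cur = cur.parent
        return depth

    ref_depth = ancestors(ref)
    out: dict[str, float] = {}
    for leaf in leaves:
        if leaf is ref:
            continue
        d = 0.0
        cur: _Node | None = leaf
        while id(cur) not in ref_depth:
            d += cur.plen
            cur = cur.parent
        out[leaf.label] = d + ref_depth[id(cur)]
    return out


def _scale(root: _Node, factor: float) -> None:
    stack = [root]
    while stack:
        node = stack.pop()
        node.lengths = [l * factor for l in node.lengths]
        for child, ln in zip(node.children, node.lengths):
            child.plen = ln
            stack.append(child)


def _to_newick(node: _Node) -> str:
    if not node.children:
        return node.label
    inner = ",".join(
        f"{_to_newick(c)}:{ln:.17g}" for c, ln in zip(node.children, node.lengths)
    )
    return f"({inner})"


def sample_tree(n_leaves: int, target_depth: float, seed: int,
                labels: list[str] | None = None,
                reference_leaf: int = 0,
                tree_model: Literal["yule"] = "yule",
                ) -> tuple[PhyloTree, dict[str, float]]:
    """Sample a Yule tree rescaled to a given mean reference-to-leaf depth.

    The tree is rescaled exactly, per tree, so the mean path length from
    the leaf at index ``reference_leaf`` to every other leaf equals
    ``target_depth``. Returns the tree plus the map of true path lengths
    from the reference leaf to every other leaf.
    """
    if n_leaves < 2:
        raise InputError("need at least 2 leaves")
    if target_depth <= 0:
        raise InputError("target_depth must be > 0")
    if tree_model != "yule":
        raise InputError(f"unknown tree model {tree_model!r}")
    if labels is None:
        labels = [f"s{i:04d}" for i in range(n_leaves)]
    if len(labels) != n_leaves:
        raise InputError("label count must equal n_leaves")
    rng = np.random.default_rng(seed)
    root = _yule_topology(n_leaves, labels, rng)
    _assign_lengths(root, rng)
    leaves = _leaf_list(root)
    ref_label = labels[reference_leaf]
    ref = next(l for l in leaves if l.label == ref_label)
    dists = _leaf_distances(ref, leaves)
    mean = sum(dists.values()) / len(dists)
    _scale(root, target_depth / mean)
    dists = _leaf_distances(ref, leaves)

    newick = _to_newick(root) + ";"
    tree = dendropy.Tree.get(data=newick, schema="newick",
                             suppress_internal_node_taxa=True,
                             preserve_underscores=True)
    return PhyloTree(tree), dists


# ---------------------------------------------------------------------------
# Sequence evolution
# ---------------------------------------------------------------------------

def _sample_transitions(states: np.ndarray, P: np.ndarray, cats: np.ndarray,
                        rng: np.random.Generator) -> np.ndarray:
    """Draw child states per site from transition matrices P[cat, parent, :]."""
    cum = P.cumsum(axis=2)  # (k, 4, 4)
    u = rng.random(states.shape[0])
    rows = cum[cats, states]  # (L, 4)
    return (u[:, None] > rows).sum(axis=1).astype(states.dtype)


def evolve_sequences(tree: PhyloTree, seq_length: int,
                     subst_model: SubstModel = JC(),
                     indel_rate: float = 0.0,
                     seed: int = 0) -> MultipleAlignment:
    """Evolve sequences down ``tree`` and return the true alignment.

    The root sequence is drawn from the model's base frequencies; each
    branch applies the model's transition probabilities at its length.
    With ``indel_rate`` > 0, each site on a branch is deleted with
    probability 1 - exp(-indel_rate * length); deletions are inherited by
    all descendants and appear as gap characters in the true alignment.
    """
    if seq_length < 1:
        raise InputError("seq_length must be >= 1")
    if indel_rate < 0:
        raise InputError("indel_rate must be >= 0")
    rng = np.random.default_rng(seed)
    freqs = np.asarray(subst_model.base_freqs)
    cats = subst_model.site_rates(rng, seq_length)
    root_states = rng.choice(4, size=seq_length, p=freqs)

    rows: dict[str, str] = {}

    def descend(node, states: np.ndarray, alive: np.ndarray) -> None:
        for child in node.child_nodes():
            t = child.edge.length or 0.0
            if t > 0:
                P = subst_model.transition_matrices(t)
                child_states = _sample_transitions(states, P, cats, rng)
            else:
                child_states = states.copy()
            child_alive = alive
            if indel_rate > 0 and t > 0:
                p_del = 1.0 - math.exp(-indel_rate * t)
                child_alive = alive & (rng.random(seq_length) >= p_del)
            if child.is_leaf():
                chars = np.array(list(_BASES))[child_states]
                chars[~child_alive] = "-"
                rows[child.taxon.label] = "".join(chars)
            else:
                descend(child, child_states, child_alive)

    alive0 = np.ones(seq_length, dtype=bool)
    descend(tree.tree.seed_node, root_states, alive0)
    ordered = [Sequence(lbl, rows[lbl]) for lbl in tree.leaf_labels]
    return MultipleAlignment(ordered)


# ---------------------------------------------------------------------------
# Dataset generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    Defaults emulate size-filtered 16S OTUs: clusters of 100+1 sequences,
    amplicon-scale alignment length, mean representative-to-member depth
    0.05 substitutions/site (straddling the 0.03 audit threshold), and a
    10% member discordance rate.
    """

    n_otus: int = 20
    members_per_otu: int = 100
    seq_length: int = 5000
    target_depth: float = 0.05
    subst_model: SubstModel = field(default_factory=JC)
    p_discordant: float = 0.1
    indel_rate: float = 0.0
    seed: int = 42
    otu_id_offset: int = 0

    def __post_init__(self) -> None:
        if min(self.n_otus, self.members_per_otu, self.seq_length) < 1:
            raise InputError("n_otus, members_per_otu, seq_length must be >= 1")
        if self.target_depth <= 0:
            raise InputError("target_depth must be > 0")
        if not (0.0 <= self.p_discordant <= 1.0):
            raise InputError("p_discordant must lie in [0, 1]")
        if self.indel_rate < 0:
            raise InputError("indel_rate must be >= 0")


@dataclass(frozen=True)
class SimulatedOTU:
    """One synthetic OTU with full ground truth."""

    cluster: OTUCluster
    true_tree: PhyloTree
    alignment: MultipleAlignment
    true_rep_distances: dict[str, float]
    lineages: dict[str, Lineage]
    truth_classes: dict[str, ConcordanceClass]


def _base_lineage(otu_index: int) -> Lineage:
    """Synthetic genus-depth lineage; OTUs cycle over five phyla."""
    p = otu_index % 5
    return Lineage.from_names(
        "Bacteria", f"Phylum_{p}", f"Class_{p}", f"Order_{p}",
        f"Family_{otu_index % 20}", f"Genus_{otu_index}",
    )


def _perturb(base: Lineage, kind: ConcordanceClass) -> Lineage:
    names = [n for n in base.ranks if n is not None]
    if kind is ConcordanceClass.CONFLICTING:
        return Lineage.from_names(*names[:-1], names[-1] + "_sibling")
    if kind is ConcordanceClass.UNDER:
        return Lineage.from_names(*names[:-1])
    raise InputError(f"cannot perturb to class {kind}")


def make_dataset(config: SimulationConfig) -> list[SimulatedOTU]:
    """Generate a dataset of simulated OTUs under ``config``."""
    master = np.random.default_rng(config.seed)
    otu_seeds = master.integers(0, 2 ** 31, size=config.n_otus)
    out: list[SimulatedOTU] = []
    for i in range(config.n_otus):
        idx = config.otu_id_offset + i
        otu_id = f"otu{idx:04d}"
        rng = np.random.default_rng(otu_seeds[i])
        n_leaves = config.members_per_otu + 1
        labels = [f"{otu_id}_s{j:04d}" for j in range(n_leaves)]
        rep_index = int(rng.integers(0, n_leaves))
        tree_seed = int(rng.integers(0, 2 ** 31))
        evo_seed = int(rng.integers(0, 2 ** 31))
        tree, true_dists = sample_tree(
            n_leaves, config.target_depth, tree_seed,
            labels=labels, reference_leaf=rep_index,
        )
        alignment = evolve_sequences(
            tree, config.seq_length, config.subst_model,
            indel_rate=config.indel_rate, seed=evo_seed,
        )
        rep_id = labels[rep_index]
        members = [l for l in labels if l != rep_id]
        cluster = OTUCluster(otu_id, rep_id, frozenset(members))

        base = _base_lineage(idx)
        lineages: dict[str, Lineage] = {rep_id: base}
        truth: dict[str, ConcordanceClass] = {}
        discord_toggle = 0
        for member in members:
            if config.p_discordant > 0 and rng.random() < config.p_discordant:
                kind = (ConcordanceClass.CONFLICTING if discord_toggle % 2 == 0
                        else ConcordanceClass.UNDER)
                discord_toggle += 1
                lineages[member] = _perturb(base, kind)
                truth[member] = kind
            else:
                lineages[member] = base
                truth[member] = ConcordanceClass.CONCORDANT
        out.append(SimulatedOTU(cluster, tree, alignment, true_dists, lineages, truth))
    return out
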