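"""Readers and writers for every external format the audit pipeline touches.

Formats supported:

* FASTA (gapped or ungapped) via Biopython, with residue normalization:
  uppercase, ``U`` mapped to ``T``, IUPAC ambiguity codes other than ``N``
  mapped to ``N`` with a logged warning.
* Newick trees with branch lengths via dendropy, validated so that every
  non-root edge carries a non-negative length and leaf labels are unique.
* OTU membership maps in the QIIME classic dialect (one tab-separated line
  per OTU: otu_id followed by member sequence ids).
* Representative assignments (two-column TSV: otu_id, representative_id).
* Taxonomy tables with Greengenes rank-prefixed lineage strings
  (``k__Bacteria; p__Firmicutes; ...``).
* Plain TSV report files with a ``#`` comment header.

All identifiers are compared case-sensitively.
"""

from __future__ import annotations

import logging
import os
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence as TSequence

import dendropy
import pandas as pd
from Bio import SeqIO

from .errors import FormatError, InputError, UnknownIdError

logger = logging.getLogger(__name__)

ALPHABET = frozenset("ACGTN-")

#: IUPAC nucleotide ambiguity codes collapsed to N at read time.
_AMBIGUITY = frozenset("RYSWKMBDHV")

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")
RANK_PREFIXES = ("k__", "p__", "c__", "o__", "f__", "g__", "s__")
UNASSIGNED = None


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Sequence:
    """A DNA sequence with a unique identifier.

    Residues are uppercase over ``{A, C, G, T, N, -}``; ``U`` has been
    mapped to ``T`` and other ambiguity codes to ``N`` at read time.
    """

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("sequence identifier must be a non-empty token")
        bad = set(self.residues) - ALPHABET
        if bad:
            pos = next(i for i, c in enumerate(self.residues) if c in bad)
            raise FormatError(
                f"sequence {self.id!r}: character {self.residues[pos]!r} at "
                f"position {pos} outside alphabet ACGTN-"
            )

    def ungapped(self) -> "Sequence":
        return Sequence(self.id, self.residues.replace("-", ""), self.description)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class MultipleAlignment:
    """Equal-length gapped sequences keyed by identifier."""

    sequences: list[Sequence]

    def __post_init__(self) -> None:
        if not self.sequences:
            raise FormatError("alignment must contain at least one sequence")
        width = len(self.sequences[0].residues)
        if width < 1:
            raise FormatError("alignment width must be >= 1")
        for seq in self.sequences:
            if len(seq.residues) != width:
                raise FormatError(
                    f"ragged alignment: sequence {seq.id!r} has length "
                    f"{len(seq.residues)}, expected {width}"
                )
        ids = [s.id for s in self.sequences]
        if len(set(ids)) != len(ids):
            dup = next(i for i in ids if ids.count(i) > 1)
            raise FormatError(f"duplicate sequence identifier {dup!r} in alignment")
        self._index = {s.id: s for s in self.sequences}

    @property
    def width(self) -> int:
        return len(self.sequences[0].residues)

    def __len__(self) -> int:
        return len(self.sequences)

    def __contains__(self, seq_id: str) -> bool:
        return seq_id in self._index

    def row(self, seq_id: str) -> str:
        try:
            return self._index[seq_id].residues
        except KeyError:
            raise UnknownIdError(f"sequence {seq_id!r} not present in alignment") from None

    def ids(self) -> list[str]:
        return [s.id for s in self.sequences]


@dataclass
class PhyloTree:
    """A leaf-labelled tree with branch lengths in expected substitutions/site.

    Wraps a :class:`dendropy.Tree`; the tree is treated as unrooted for all
    distance purposes (patristic distance is root-invariant).
    """

    tree: dendropy.Tree

    def __post_init__(self) -> None:
        leaves = [lf.taxon.label if lf.taxon else None for lf in self.tree.leaf_node_iter()]
        if any(lbl is None for lbl in leaves):
            raise FormatError("tree contains an unlabelled leaf")
        if len(leaves) < 2:
            raise FormatError("tree must have at least 2 leaves")
        if len(set(leaves)) != len(leaves):
            dup = next(l for l in leaves if leaves.count(l) > 1)
            raise FormatError(f"duplicate leaf label {dup!r} in tree")
        root = self.tree.seed_node
        for node in self.tree.preorder_node_iter():
            if node is root:
                continue
            if node.edge.length is None:
                label = node.taxon.label if node.taxon else "<internal>"
                raise FormatError(f"missing branch length on edge above {label}")
            if node.edge.length < 0:
                label = node.taxon.label if node.taxon else "<internal>"
                raise InputError(f"negative branch length on edge above {label}")

    @property
    def leaf_labels(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    def newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()


@dataclass(frozen=True)
class OTUCluster:
    """An OTU: identifier, designated representative, and remaining members."""

    otu_id: str
    representative_id: str
    member_ids: frozenset[str]

    def __post_init__(self) -> None:
        if self.representative_id in self.member_ids:
            raise FormatError(
                f"OTU {self.otu_id!r}: representative {self.representative_id!r} "
                "must not appear in member set"
            )
        if len(self.member_ids) < 1:
            raise FormatError(f"OTU {self.otu_id!r} needs at least one non-representative member")

    @property
    def size(self) -> int:
        """Total sequence count, representative included."""
        return len(self.member_ids) + 1

    def all_ids(self) -> list[str]:
        return [self.representative_id, *sorted(self.member_ids)]


@dataclass(frozen=True)
class Lineage:
    """Ordered taxonomic assignments, kingdom through species.

    ``None`` marks an unassigned rank; assigned ranks always form a prefix
    (no assigned rank below an unassigned one).
    """

    ranks: tuple[str | None, ...]

    def __post_init__(self) -> None:
        if len(self.ranks) != 7:
            raise FormatError(f"lineage must have 7 ranks, got {len(self.ranks)}")
        seen_unassigned = False
        for name, rank in zip(self.ranks, RANKS):
            if name is None:
                seen_unassigned = True
            else:
                if seen_unassigned:
                    raise FormatError(
                        f"assigned rank {rank} ({name!r}) follows an unassigned rank"
                    )
                if not name:
                    raise FormatError(f"empty name at rank {rank}")

    @property
    def depth(self) -> int:
        """Number of assigned ranks (0..7)."""
        return sum(1 for r in self.ranks if r is not None)

    def at(self, rank: str) -> str | None:
        return self.ranks[RANKS.index(rank)]

    def format(self) -> str:
        """Greengenes-style rank-prefixed string, all seven ranks present."""
        return "; ".join(
            f"{p}{n if n is not None else ''}" for p, n in zip(RANK_PREFIXES, self.ranks)
        )

    @classmethod
    def from_names(cls, *names: str) -> "Lineage":
        """Build a lineage from the assigned prefix only."""
        ranks = tuple(names) + (None,) * (7 - len(names))
        return cls(ranks)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def _normalize_residues(raw: str, seq_id: str) -> str:
    out = []
    warned = False
    for i, ch in enumerate(raw.upper()):
        if ch == "U":
            ch = "T"
        elif ch in _AMBIGUITY:
            if not warned:
                logger.warning(
                    "sequence %s: ambiguity code %r at position %d normalized to N",
                    seq_id, ch, i,
                )
                warned = True
            ch = "N"
        elif ch == ".":
            ch = "-"  # RDP/greengenes alignments use '.' for terminal gaps
        elif ch not in ALPHABET:
            raise FormatError(
                f"sequence {seq_id!r}: character {ch!r} at position {i} "
                "outside alphabet ACGTN- after normalization"
            )
        out.append(ch)
    return "".join(out)


def read_fasta(path: str | Path, aligned: bool = False):
    """Read a FASTA file.

    Parameters
    ----------
    path : str or Path
    aligned : bool
        If True, validate equal lengths and return a
        :class:`MultipleAlignment`; otherwise return a list of
        :class:`Sequence`.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"FASTA file not found: {path}")
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq_id = rec.id  # first whitespace-delimited token of the header
        if seq_id in seen:
            raise FormatError(f"{path}: duplicate sequence identifier {seq_id!r}")
        seen.add(seq_id)
        residues = _normalize_residues(str(rec.seq), seq_id)
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        records.append(Sequence(seq_id, residues, desc))
    if not records:
        raise FormatError(f"{path}: empty FASTA file")
    if aligned:
        try:
            return MultipleAlignment(records)
        except FormatError as exc:
            raise FormatError(f"{path}: {exc}") from None
    return records


def write_fasta(sequences: Iterable[Sequence] | MultipleAlignment, path: str | Path,
                width: int = 80) -> None:
    seqs = sequences.sequences if isinstance(sequences, MultipleAlignment) else list(sequences)
    with _atomic_open(path) as fh:
        for seq in seqs:
            header = f">{seq.id}" + (f" {seq.description}" if seq.description else "")
            fh.write(header + "\n")
            for i in range(0, len(seq.residues), width):
                fh.write(seq.residues[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------

def read_newick(path: str | Path) -> PhyloTree:
    """Read a single Newick tree with branch lengths."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"Newick file not found: {path}")
    try:
        tree = dendropy.Tree.get(
            path=str(path), schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises assorted parse errors
        raise FormatError(f"{path}: not valid Newick: {exc}") from None
    try:
        return PhyloTree(tree)
    except (FormatError, InputError) as exc:
        raise type(exc)(f"{path}: {exc}") from None


def write_newick(tree: PhyloTree, path: str | Path) -> None:
    with _atomic_open(path) as fh:
        fh.write(tree.newick() + "\n")


# ---------------------------------------------------------------------------
# OTU maps and representative assignments
# ---------------------------------------------------------------------------

def read_rep_assignments(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV mapping otu_id -> representative_id."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"representative-assignment file not found: {path}")
    reps: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2 or not all(parts):
                raise FormatError(f"{path}:{lineno}: expected 'otu_id<TAB>representative_id'")
            otu_id, rep = parts
            if otu_id in reps:
                raise FormatError(f"{path}:{lineno}: duplicate OTU id {otu_id!r}")
            reps[otu_id] = rep
    return reps


def read_otu_map(path: str | Path,
                 representatives: Mapping[str, str] | None = None) -> list[OTUCluster]:
    """Read a QIIME-classic OTU map.

    Each line is ``otu_id<TAB>member_id[<TAB>member_id...]``. If
    ``representatives`` is given it assigns the representative per OTU
    (the representative may or may not be listed among the line's ids);
    otherwise the first listed member is the representative
    ("first-member convention").
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"OTU map not found: {path}")
    clusters: list[OTUCluster] = []
    seen_otus: set[str] = set()
    seen_members: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2 or not all(parts):
                raise FormatError(f"{path}:{lineno}: expected 'otu_id<TAB>member ids...'")
            otu_id, *ids = parts
            if otu_id in seen_otus:
                raise FormatError(f"{path}:{lineno}: duplicate OTU id {otu_id!r}")
            seen_otus.add(otu_id)
            if len(set(ids)) != len(ids):
                dup = next(i for i in ids if ids.count(i) > 1)
                raise FormatError(f"{path}:{lineno}: sequence {dup!r} listed twice in OTU {otu_id!r}")
            for sid in ids:
                if sid in seen_members:
                    raise FormatError(
                        f"{path}:{lineno}: sequence {sid!r} appears in both OTU "
                        f"{seen_members[sid]!r} and OTU {otu_id!r}"
                    )
                seen_members[sid] = otu_id
            if representatives is not None:
                if otu_id not in representatives:
                    raise FormatError(f"{path}:{lineno}: no representative assigned for OTU {otu_id!r}")
                rep = representatives[otu_id]
                members = [i for i in ids if i != rep]
            else:
                rep, members = ids[0], ids[1:]
            if not members:
                raise FormatError(
                    f"{path}:{lineno}: OTU {otu_id!r} has no members besides the representative"
                )
            clusters.append(OTUCluster(otu_id, rep, frozenset(members)))
    if not clusters:
        raise FormatError(f"{path}: empty OTU map")
    return clusters


def write_otu_map(clusters: Iterable[OTUCluster], path: str | Path) -> None:
    """Write QIIME-classic OTU map, representative listed first on each line."""
    with _atomic_open(path) as fh:
        for c in clusters:
            fh.write("\t".join([c.otu_id, c.representative_id, *sorted(c.member_ids)]) + "\n")


def write_rep_assignments(clusters: Iterable[OTUCluster], path: str | Path) -> None:
    with _atomic_open(path) as fh:
        for c in clusters:
            fh.write(f"{c.otu_id}\t{c.representative_id}\n")


# ---------------------------------------------------------------------------
# Taxonomy
# ---------------------------------------------------------------------------

def parse_lineage(text: str, context: str = "") -> Lineage:
    """Parse a Greengenes rank-prefixed lineage string into a Lineage."""
    fields = [f.strip() for f in text.split(";")]
    if fields and fields[-1] == "":
        fields = fields[:-1]
    names: list[str | None] = [None] * 7
    last_idx = -1
    for f in fields:
        prefix = f[:3]
        if prefix not in RANK_PREFIXES:
            raise FormatError(f"{context}unknown rank prefix in field {f!r}")
        idx = RANK_PREFIXES.index(prefix)
        if idx <= last_idx:
            raise FormatError(f"{context}rank prefix {prefix!r} out of order")
        last_idx = idx
        name = f[3:].strip()
        names[idx] = name if name else None
    try:
        return Lineage(tuple(names))
    except FormatError as exc:
        raise FormatError(f"{context}{exc}") from None


def read_taxonomy(path: str | Path) -> dict[str, Lineage]:
    """Read a taxonomy table: sequence_id TAB rank-prefixed lineage string."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"taxonomy file not found: {path}")
    out: dict[str, Lineage] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"{path}:{lineno}: expected 'sequence_id<TAB>lineage'")
            seq_id, lineage_str = parts[0], parts[1]
            if seq_id in out:
                raise FormatError(f"{path}:{lineno}: duplicate sequence id {seq_id!r}")
            out[seq_id] = parse_lineage(lineage_str, context=f"{path}:{lineno}: ")
    if not out:
        raise FormatError(f"{path}: empty taxonomy file")
    return out


def write_taxonomy(taxonomy: Mapping[str, Lineage], path: str | Path) -> None:
    with _atomic_open(path) as fh:
        for seq_id in taxonomy:
            fh.write(f"{seq_id}\t{taxonomy[seq_id].format()}\n")


# ---------------------------------------------------------------------------
# Report TSVs
# ---------------------------------------------------------------------------

def write_records_tsv(records: TSequence, path: str | Path,
                      header_comments: TSequence[str] = ()) -> None:
    """Serialize a collection of dataclass records to TSV.

    Numeric fields are written with 6 decimal places; absent values as
    empty fields. An optional ``#`` comment header carries provenance.
    """
    rows = [vars(r) if not isinstance(r, dict) else r for r in records]
    if rows:
        columns = list(rows[0].keys())
    else:
        columns = []
    with _atomic_open(path) as fh:
        for comment in header_comments:
            fh.write(f"# {comment}\n")
        df = pd.DataFrame(rows, columns=columns) if columns else pd.DataFrame()
        df.to_csv(fh, sep="\t", index=False, float_format="%.6f", na_rep="")


def read_tsv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise InputError(f"TSV file not found: {path}")
    return pd.read_csv(path, sep="\t", comment="#")


# ---------------------------------------------------------------------------
# Atomic write helper
# ---------------------------------------------------------------------------

class _atomic_open:
    """Write to a temp file in the target directory, rename on success."""

    def __init__(self, path: str | Path):
        self.path = Path(path)

    def __enter__(self):
        self.path.parent.mkdir(parents=True, exist_ok=True)
        fd, self._tmp = tempfile.mkstemp(dir=self.path.parent, suffix=".tmp")
        self._fh = os.fdopen(fd, "w")
        return self._fh

    def __exit__(self, exc_type, exc, tb):
        self._fh.close()
        if exc_type is None:
            os.replace(self._tmp, self.path)
        else:
            os.unlink(self._tmp)
        return False
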