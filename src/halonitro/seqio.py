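"""Readers and writers for every format the pipeline touches.

FASTA (protein / nucleotide / aligned nucleotide), the taxonomy and
gene-order TSV tables, and Newick trees with MEGA-style integer supports
as internal node labels.  All readers validate and reject malformed
input; none silently repairs.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import dendropy
import pandas as pd
from Bio import SeqIO

from .errors import FormatError, ParseError
from .tree import Tree, TreeNode

PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY") | {"X"}
NUCLEOTIDE_ALPHABET = set("ACGT") | {"N"}
ALIGNED_NUCLEOTIDE_ALPHABET = NUCLEOTIDE_ALPHABET | {"-"}

_ALPHABETS = {
    "protein": PROTEIN_ALPHABET,
    "nucleotide": NUCLEOTIDE_ALPHABET,
    "aligned_nucleotide": ALIGNED_NUCLEOTIDE_ALPHABET,
}


@dataclass(frozen=True)
class SequenceRecord:
    """A single FASTA record; ``residues`` is an upper-case string."""

    id: str
    residues: str
    description: str = ""

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class GeneOrder:
    """Ordered gene positions along the replicons of one species.

    Positions are 0-based ordinal indices within each replicon (not
    physical coordinates) -- adjacency checks only need ordering.
    """

    species: str
    entries: list[tuple[str, int, str]] = field(default_factory=list)
    # each entry: (replicon, position, gene_id)

    def position_of(self, gene_id: str) -> Optional[tuple[str, int]]:
        for replicon, pos, gid in self.entries:
            if gid == gene_id:
                return replicon, pos
        return None

    def validate(self) -> None:
        by_replicon: dict[str, list[int]] = {}
        for replicon, pos, _ in self.entries:
            by_replicon.setdefault(replicon, []).append(pos)
        for replicon, positions in by_replicon.items():
            if sorted(positions) != list(range(len(positions))):
                raise FormatError(
                    f"gene positions on {self.species}/{replicon} are not "
                    f"consecutive 0-based indices"
                )


def read_fasta(path: str | Path, alphabet: str = "protein") -> list[SequenceRecord]:
    """Read a FASTA file into a list of validated records.

    Raises :class:`ParseError` on duplicate ids or characters outside the
    declared alphabet (named by record and position).  An empty file
    yields an empty list with a warning.
    """
    allowed = _ALPHABETS[alphabet]
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise ParseError(f"{path}: record with empty id")
        if rec.id in seen:
            raise ParseError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        residues = str(rec.seq).upper()
        if not residues:
            raise ParseError(f"{path}: record {rec.id!r} has no residues")
        for i, ch in enumerate(residues):
            if ch not in allowed:
                raise ParseError(
                    f"{path}: illegal character {ch!r} at position {i + 1} "
                    f"of record {rec.id!r} (alphabet {alphabet})"
                )
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id):].strip()
        records.append(SequenceRecord(id=rec.id, residues=residues, description=desc))
    if not records:
        warnings.warn(f"{path}: no FASTA records found", stacklevel=2)
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, wrap: int = 60) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.residues), wrap):
                fh.write(rec.residues[i : i + wrap] + "\n")


# ---------------------------------------------------------------------------
# taxonomy table


def read_taxonomy(path: str | Path) -> dict[str, tuple[str, bool]]:
    """Read the species -> (family, genome_available) table.

    Expects a TSV with columns ``species``, ``family``,
    ``genome_available`` (true/false or 1/0).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"species", "family", "genome_available"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing taxonomy columns {sorted(missing)}")
    if df["species"].duplicated().any():
        dups = df.loc[df["species"].duplicated(), "species"].tolist()
        raise FormatError(f"{path}: repeated species {dups}")
    out: dict[str, tuple[str, bool]] = {}
    for _, row in df.iterrows():
        ga = str(row["genome_available"]).strip().lower()
        if ga in {"true", "1", "yes"}:
            avail = True
        elif ga in {"false", "0", "no"}:
            avail = False
        else:
            raise FormatError(
                f"{path}: unparseable genome_available {row['genome_available']!r} "
                f"for species {row['species']!r}"
            )
        out[str(row["species"])] = (str(row["family"]), avail)
    return out


def write_taxonomy(taxonomy: dict[str, tuple[str, bool]], path: str | Path) -> None:
    rows = [
        {"species": sp, "family": fam, "genome_available": str(avail).lower()}
        for sp, (fam, avail) in taxonomy.items()
    ]
    pd.DataFrame(rows, columns=["species", "family", "genome_available"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# gene-order table


def read_gene_orders(path: str | Path) -> dict[str, GeneOrder]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"species", "replicon", "position", "gene_id"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing gene-order columns {sorted(missing)}")
    orders: dict[str, GeneOrder] = {}
    for _, row in df.iterrows():
        sp = str(row["species"])
        order = orders.setdefault(sp, GeneOrder(species=sp))
        order.entries.append(
            (str(row["replicon"]), int(row["position"]), str(row["gene_id"]))
        )
    for order in orders.values():
        order.validate()
    return orders


def write_gene_orders(
    orders: Iterable[GeneOrder], path: str | Path, marker_truth: Optional[dict] = None
) -> None:
    """Write gene orders as TSV; ``marker_truth`` optionally maps
    gene_id -> enzyme name for ground-truth annotation."""
    rows = []
    for order in orders:
        for replicon, pos, gid in order.entries:
            rows.append(
                {
                    "species": order.species,
                    "replicon": replicon,
                    "position": pos,
                    "gene_id": gid,
                    "marker_truth": (marker_truth or {}).get(gid, ""),
                }
            )
    pd.DataFrame(
        rows, columns=["species", "replicon", "position", "gene_id", "marker_truth"]
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Newick

_SUPPORT_RE = re.compile(r"^\d+$")


def write_newick(tree: Tree) -> str:
    """Serialise a tree: supports as internal node labels (MEGA style),
    branch lengths to 6 decimals."""

    def fmt(node: TreeNode) -> str:
        if node.is_leaf:
            s = node.label or ""
        else:
            inner = ",".join(fmt(c) for c in node.children)
            label = "" if node.support is None else str(node.support)
            s = f"({inner}){label}"
        if node.length is not None:
            s += f":{node.length:.6f}"
        return s

    return fmt(tree.root) + ";"


def read_newick(text: str) -> Tree:
    """Parse a Newick string; integer internal labels become supports."""
    if text.count("(") != text.count(")"):
        raise ParseError("unbalanced parentheses in Newick string")
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises various subclasses
        raise ParseError(f"invalid Newick: {exc}") from exc

    def convert(dnode) -> TreeNode:
        if dnode.is_leaf():
            label = dnode.taxon.label if dnode.taxon else dnode.label
            node = TreeNode(label=label)
        else:
            node = TreeNode()
            raw = dnode.label
            if raw is not None and _SUPPORT_RE.match(str(raw)):
                node.support = int(raw)
            elif raw:
                node.label = str(raw)
            for child in dnode.child_nodes():
                node.add_child(convert(child))
        node.length = dnode.edge.length
        return node

    return Tree(convert(dtree.seed_node))


def write_newick_file(tree: Tree, path: str | Path) -> None:
    Path(path).write_text(write_newick(tree) + "\n")


def read_newick_file(path: str | Path) -> Tree:
    return read_newick(Path(path).read_text())
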