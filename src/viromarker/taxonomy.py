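"""Rank-labelled taxonomy tree with lineage extraction at the working ranks.

The classifier and the marker calibration both reason about taxa at four
ranks only (genus, subfamily, family, order); everything else in the tree is
treated as pass-through. Two input dialects are supported: the NCBI
``nodes.dmp``/``names.dmp`` pair and a simplified four-column lineage TSV
(``taxid  name  rank  parent_taxid``), which is the canonical fixture format.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

#: Ranks the calibration/voting machinery operates on, finest first.
WORKING_RANKS: tuple[str, ...] = ("genus", "subfamily", "family", "order")

#: Rank strings kept verbatim; anything else is normalised to "no-rank".
RANK_VOCABULARY: frozenset[str] = frozenset(
    {
        "superkingdom",
        "realm",
        "kingdom",
        "phylum",
        "class",
        "order",
        "suborder",
        "family",
        "subfamily",
        "genus",
        "subgenus",
        "species",
        "no-rank",
    }
)


class TaxonomyError(Exception):
    """Structural problem in a taxonomy source (cycle, missing parent...)."""


class UnknownTaxonError(KeyError):
    """Lookup of a taxon id absent from the tree."""


@dataclass(frozen=True)
class TaxonNode:
    taxid: str
    name: str
    rank: str
    parent: str  # equals taxid at the root


@dataclass(frozen=True)
class Lineage:
    """The four working-rank slots plus the full root-ward chain.

    Each slot holds the taxon id of the unique ancestor-or-self at that rank,
    or ``None`` when the lineage has no node of that rank.
    """

    genus: str | None = None
    subfamily: str | None = None
    family: str | None = None
    order: str | None = None
    chain: tuple[str, ...] = ()  # self first, root last

    def at(self, rank: str) -> str | None:
        if rank not in WORKING_RANKS:
            raise ValueError(f"not a working rank: {rank!r}")
        return getattr(self, rank)


class TaxonomyTree:
    """Validated parent-pointer tree over taxon ids.

    Invariants enforced at construction: exactly one root, no cycles, every
    non-root parent resolvable.
    """

    def __init__(self, nodes: Mapping[str, TaxonNode]):
        self.nodes: dict[str, TaxonNode] = dict(nodes)
        self._children: dict[str, list[str]] = {}
        self.root = self._validate()
        for node in self.nodes.values():
            if node.taxid != node.parent:
                self._children.setdefault(node.parent, []).append(node.taxid)

    # -- construction / validation -------------------------------------------------

    def _validate(self) -> str:
        roots = [t for t, n in self.nodes.items() if n.parent == t]
        if len(roots) != 1:
            raise TaxonomyError(
                f"expected exactly one root, found {len(roots)}: {sorted(roots)[:5]}"
            )
        root = roots[0]
        state: dict[str, int] = {}  # 0 = on current path, 1 = verified
        for start in self.nodes:
            path: list[str] = []
            cur = start
            while True:
                if cur in state:
                    if state[cur] == 0:
                        raise TaxonomyError(f"cycle detected involving taxon {cur!r}")
                    break
                node = self.nodes.get(cur)
                if node is None:
                    raise TaxonomyError(f"parent {cur!r} not present in the table")
                state[cur] = 0
                path.append(cur)
                if node.parent == cur:
                    break
                cur = node.parent
            for t in path:
                state[t] = 1
        return root

    # -- queries -------------------------------------------------------------------

    def __contains__(self, taxid: str) -> bool:
        return taxid in self.nodes

    def __len__(self) -> int:
        return len(self.nodes)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, TaxonomyTree) and self.nodes == other.nodes

    def node(self, taxid: str) -> TaxonNode:
        try:
            return self.nodes[taxid]
        except KeyError:
            raise UnknownTaxonError(taxid) from None

    def name(self, taxid: str) -> str:
        return self.node(taxid).name

    def rank(self, taxid: str) -> str:
        return self.node(taxid).rank

    def walk_to_root(self, taxid: str) -> Iterator[TaxonNode]:
        """Yield nodes from ``taxid`` (inclusive) up to and including the root."""
        node = self.node(taxid)
        while True:
            yield node
            if node.parent == node.taxid:
                return
            node = self.nodes[node.parent]

    def lineage_of(self, taxid: str) -> Lineage:
        slots: dict[str, str | None] = {r: None for r in WORKING_RANKS}
        chain = []
        for node in self.walk_to_root(taxid):
            chain.append(node.taxid)
            if node.rank in slots and slots[node.rank] is None:
                slots[node.rank] = node.taxid
        return Lineage(chain=tuple(chain), **slots)

    def ancestor_at(self, taxid: str, rank: str) -> str | None:
        """Ancestor-or-self of ``taxid`` at a working rank, or None."""
        return self.lineage_of(taxid).at(rank)

    def descendants(self, taxid: str) -> set[str]:
        """All strict descendants of ``taxid``."""
        self.node(taxid)  # raise on unknown ids
        out: set[str] = set()
        stack = list(self._children.get(taxid, ()))
        while stack:
            t = stack.pop()
            out.add(t)
            stack.extend(self._children.get(t, ()))
        return out

    def children(self, taxid: str) -> list[str]:
        self.node(taxid)
        return list(self._children.get(taxid, ()))


# -- loading ------------------------------------------------------------------------


def _normalise_rank(rank: str) -> str:
    rank = rank.strip().replace(" ", "-")
    if rank in RANK_VOCABULARY:
        return rank
    warnings.warn(f"unknown rank {rank!r}; keeping node with rank 'no-rank'")
    return "no-rank"


def _load_lineage_tsv(path: Path) -> dict[str, TaxonNode]:
    nodes: dict[str, TaxonNode] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["taxid", "name", "rank", "parent_taxid"]
        if [c.strip().lower() for c in header[:4]] != expected:
            raise TaxonomyError(
                f"{path}: expected header {expected}, got {header[:4]}"
            )
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise TaxonomyError(f"{path}:{lineno}: expected 4 columns")
            taxid, name, rank, parent = (f.strip() for f in fields[:4])
            if not parent:
                parent = taxid
            nodes[taxid] = TaxonNode(taxid, name, _normalise_rank(rank), parent)
    return nodes


def _split_dmp(line: str) -> list[str]:
    return [f.strip() for f in line.rstrip("\t|\n").split("\t|\t")]


def _load_ncbi_dmp(source: Path) -> dict[str, TaxonNode]:
    if source.is_dir():
        nodes_path = source / "nodes.dmp"
        names_path = source / "names.dmp"
    else:
        nodes_path = source
        names_path = source.with_name("names.dmp")
    names: dict[str, str] = {}
    if names_path.exists():
        with open(names_path) as fh:
            for line in fh:
                fields = _split_dmp(line)
                if len(fields) >= 4 and fields[3] == "scientific name":
                    names[fields[0]] = fields[1]
    nodes: dict[str, TaxonNode] = {}
    with open(nodes_path) as fh:
        for line in fh:
            fields = _split_dmp(line)
            if len(fields) < 3:
                raise TaxonomyError(f"{nodes_path}: bad dmp row: {line!r}")
            taxid, parent, rank = fields[0], fields[1], fields[2]
            nodes[taxid] = TaxonNode(
                taxid, names.get(taxid, taxid), _normalise_rank(rank), parent
            )
    return nodes


def load_taxonomy(source: str | Path, dialect: str = "lineage-tsv") -> TaxonomyTree:
    """Load a taxonomy from a lineage TSV or an NCBI dmp node table.

    ``dialect`` is ``"lineage-tsv"`` or ``"ncbi-dmp"``; for the latter,
    ``source`` may be the ``nodes.dmp`` file or the directory containing
    ``nodes.dmp`` and (optionally) ``names.dmp``.
    """
    source = Path(source)
    if not source.exists():
        raise FileNotFoundError(source)
    if dialect == "lineage-tsv":
        nodes = _load_lineage_tsv(source)
    elif dialect == "ncbi-dmp":
        nodes = _load_ncbi_dmp(source)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return TaxonomyTree(nodes)


def write_lineage_tsv(tree: TaxonomyTree, path: str | Path) -> None:
    """Serialize a tree to the normalized lineage TSV dialect."""
    with open(path, "w") as fh:
        fh.write("taxid\tname\trank\tparent_taxid\n")
        for taxid in sorted(tree.nodes):
            n = tree.nodes[taxid]
            fh.write(f"{n.taxid}\t{n.name}\t{n.rank}\t{n.parent}\n")
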