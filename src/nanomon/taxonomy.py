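"""A minimal taxonomy tree with the seven canonical ranks and LCA queries."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

__all__ = ["RANKS", "TaxonNode", "Taxonomy"]

#: Canonical rank order, broadest first.
RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")
_RANK_DEPTH = {rank: i for i, rank in enumerate(RANKS)}


@dataclass(frozen=True)
class TaxonNode:
    taxid: int
    parent: int
    rank: str
    name: str


class Taxonomy:
    """Rooted tree of :class:`TaxonNode`; the root has ``parent == taxid``.

    Parent links must be acyclic and each child's rank strictly below its
    parent's in the canonical order (intermediate ranks may be skipped).
    """

    def __init__(self, nodes: Iterable[TaxonNode]):
        self._nodes: dict[int, TaxonNode] = {}
        for node in nodes:
            if node.rank not in _RANK_DEPTH:
                raise ValueError(f"unknown rank {node.rank!r} for taxid {node.taxid}")
            if node.taxid in self._nodes:
                raise ValueError(f"duplicate taxid {node.taxid}")
            self._nodes[node.taxid] = node
        roots = [n for n in self._nodes.values() if n.parent == n.taxid]
        if len(roots) != 1:
            raise ValueError(f"expected exactly one root, found {len(roots)}")
        self.root = roots[0]
        for node in self._nodes.values():
            if node.parent not in self._nodes:
                raise ValueError(f"taxid {node.taxid} has unknown parent {node.parent}")
            if node.taxid != node.parent:
                parent = self._nodes[node.parent]
                if _RANK_DEPTH[node.rank] <= _RANK_DEPTH[parent.rank]:
                    raise ValueError(
                        f"rank of {node.taxid} ({node.rank}) not below its "
                        f"parent's ({parent.rank})"
                    )
        # acyclicity: every lineage must reach the root
        for taxid in self._nodes:
            self.lineage(taxid)

    def __contains__(self, taxid: int) -> bool:
        return taxid in self._nodes

    def __len__(self) -> int:
        return len(self._nodes)

    def node(self, taxid: int) -> TaxonNode:
        try:
            return self._nodes[taxid]
        except KeyError:
            raise KeyError(f"unknown taxid {taxid}") from None

    def name(self, taxid: int) -> str:
        return self.node(taxid).name

    def nodes(self) -> list[TaxonNode]:
        return list(self._nodes.values())

    def lineage(self, taxid: int) -> list[int]:
        """Path root -> ... -> taxid (inclusive)."""
        path = [taxid]
        seen = {taxid}
        node = self.node(taxid)
        while node.parent != node.taxid:
            node = self.node(node.parent)
            if node.taxid in seen:
                raise ValueError(f"cycle in parent links at taxid {node.taxid}")
            seen.add(node.taxid)
            path.append(node.taxid)
        path.reverse()
        return path

    def ancestor_at_rank(self, taxid: int, rank: str) -> int | None:
        """The lineage node at ``rank``, or None if the lineage skips it."""
        if rank not in _RANK_DEPTH:
            raise ValueError(f"unknown rank {rank!r}")
        for ancestor in self.lineage(taxid):
            if self.node(ancestor).rank == rank:
                return ancestor
        return None

    def lca(self, taxids: Iterable[int]) -> int:
        """Lowest common ancestor: deepest node ancestral to every input."""
        taxids = list(taxids)
        if not taxids:
            raise ValueError("lca of an empty set is undefined")
        common = self.lineage(taxids[0])
        for taxid in taxids[1:]:
            lineage = self.lineage(taxid)
            shared = min(len(common), len(lineage))
            i = 0
            while i < shared and common[i] == lineage[i]:
                i += 1
            common = common[:i]
        return common[-1]

    # --- TSV interface (taxid, parent, rank, name) ---

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Taxonomy":
        nodes = []
        with open(path, "rt", encoding="utf-8") as handle:
            for line in handle:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                taxid, parent, rank, name = line.split("\t")
                nodes.append(TaxonNode(int(taxid), int(parent), rank, name))
        return cls(nodes)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "wt", encoding="utf-8") as out:
            for node in sorted(self._nodes.values(), key=lambda n: n.taxid):
                out.write(f"{node.taxid}\t{node.parent}\t{node.rank}\t{node.name}\n")
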