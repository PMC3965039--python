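"""Rank-labeled taxonomic hierarchy with lineage and LCA queries.

The on-disk format is the classifier-training convention: one node per
line, five ``*``-separated fields ``taxid*name*parentid*depth*rank``.
The root's parent is itself.  Rank paths need not be uniform — trees
with uncommon or missing intermediate ranks are valid.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable


class TaxonomyError(ValueError):
    pass


@dataclass(frozen=True)
class TaxonNode:
    taxid: int
    name: str
    parent: int
    depth: int
    rank: str


class TaxonomyTree:
    """Rooted tree of :class:`TaxonNode` indexed by taxid and by name path."""

    def __init__(self, nodes: Iterable[TaxonNode]):
        self.nodes: dict[int, TaxonNode] = {}
        self.children: dict[int, list[int]] = {}
        root = None
        for node in nodes:
            if node.taxid in self.nodes:
                raise TaxonomyError(f"duplicate taxid {node.taxid}")
            self.nodes[node.taxid] = node
            if node.parent == node.taxid:
                if root is not None:
                    raise TaxonomyError("multiple roots")
                root = node.taxid
        if root is None:
            raise TaxonomyError("no root node (parent == taxid)")
        self.root = root
        for node in self.nodes.values():
            if node.parent not in self.nodes:
                raise TaxonomyError(
                    f"node {node.taxid} has unknown parent {node.parent}")
            if node.taxid != root:
                self.children.setdefault(node.parent, []).append(node.taxid)
                parent = self.nodes[node.parent]
                if node.depth != parent.depth + 1:
                    raise TaxonomyError(
                        f"node {node.taxid}: depth {node.depth} != parent depth "
                        f"{parent.depth} + 1")
        self._check_reachability()

    def _check_reachability(self) -> None:
        seen = {self.root}
        stack = [self.root]
        while stack:
            for c in self.children.get(stack.pop(), []):
                seen.add(c)
                stack.append(c)
        if len(seen) != len(self.nodes):
            orphans = sorted(set(self.nodes) - seen)
            raise TaxonomyError(f"nodes unreachable from root: {orphans}")

    def __len__(self) -> int:
        return len(self.nodes)

    def lineage(self, taxid: int) -> list[TaxonNode]:
        """Nodes from root down to ``taxid`` inclusive."""
        if taxid not in self.nodes:
            raise TaxonomyError(f"unknown taxid {taxid}")
        path = []
        cur = taxid
        while True:
            node = self.nodes[cur]
            path.append(node)
            if cur == self.root:
                break
            cur = node.parent
        return path[::-1]

    def lca(self, taxids: Iterable[int]) -> TaxonNode:
        """Deepest node ancestral to (or equal to) every input node."""
        taxids = list(taxids)
        if not taxids:
            raise TaxonomyError("lca of an empty taxid set")
        cur = taxids[0]
        if cur not in self.nodes:
            raise TaxonomyError(f"unknown taxid {cur}")
        for other in taxids[1:]:
            if other not in self.nodes:
                raise TaxonomyError(f"unknown taxid {other}")
            a, b = self.nodes[cur], self.nodes[other]
            while a.depth > b.depth:
                a = self.nodes[a.parent]
            while b.depth > a.depth:
                b = self.nodes[b.parent]
            while a.taxid != b.taxid:
                a, b = self.nodes[a.parent], self.nodes[b.parent]
            cur = a.taxid
        return self.nodes[cur]

    def resolve_path(self, names: list[str]) -> TaxonNode:
        """Node at the end of a root-first name path (e.g. a training lineage)."""
        node = self.nodes[self.root]
        if names and names[0] == node.name:
            names = names[1:]
        for name in names:
            for cid in self.children.get(node.taxid, []):
                if self.nodes[cid].name == name:
                    node = self.nodes[cid]
                    break
            else:
                raise TaxonomyError(
                    f"lineage name {name!r} not found under {node.name!r}")
        return node

    def serialize(self) -> str:
        lines = []
        for taxid in sorted(self.nodes):
            n = self.nodes[taxid]
            lines.append(f"{n.taxid}*{n.name}*{n.parent}*{n.depth}*{n.rank}")
        return "\n".join(lines) + "\n"


def parse_taxonomy(text: str | Iterable[str]) -> TaxonomyTree:
    """Parse ``taxid*name*parentid*depth*rank`` lines into a tree."""
    if isinstance(text, str):
        text = text.splitlines()
    nodes = []
    for i, line in enumerate(text):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("*")
        if len(fields) != 5:
            raise TaxonomyError(f"line {i + 1}: expected 5 '*'-separated fields")
        taxid, name, parent, depth, rank = fields
        nodes.append(TaxonNode(int(taxid), name, int(parent), int(depth), rank))
    return TaxonomyTree(nodes)


def tree_from_lineages(lineages: Iterable[tuple[list[str], list[str]]],
                       root_name: str = "Root") -> TaxonomyTree:
    """Build a tree from (name path, rank path) pairs, names root-first
    (the root itself is implicit and need not be listed)."""
    nodes = [TaxonNode(0, root_name, 0, 0, "rootrank")]
    index: dict[tuple[str, ...], int] = {(): 0}
    next_id = 1
    for names, ranks in lineages:
        if names and names[0] == root_name:
            names, ranks = names[1:], ranks[1:]
        if len(names) != len(ranks):
            raise TaxonomyError("lineage name/rank lengths differ")
        for d in range(1, len(names) + 1):
            key = tuple(names[:d])
            if key not in index:
                parent = index[key[:-1]]
                nodes.append(TaxonNode(next_id, names[d - 1], parent, d, ranks[d - 1]))
                index[key] = next_id
                next_id += 1
    return TaxonomyTree(nodes)
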