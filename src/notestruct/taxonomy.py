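"""Rooted heading taxonomy: two category subtrees under an artificial root.

Care-classification standards organize subject headings into a nursing
*diagnosis* taxonomy and a nursing *intervention* taxonomy, each a hierarchy
of depth at most three.  Joining the two category roots under one artificial
root yields a single tree of maximum depth four, on which heading-to-heading
distance is the length of the unique connecting path.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

__all__ = ["HeadingTaxonomy", "tree_distance"]

ROOT = "<root>"


@dataclass
class HeadingTaxonomy:
    """A rooted tree over heading identifiers.

    ``parent`` maps every non-root node to its parent; ``category`` maps
    nodes to their top-level category label (e.g. ``"diagnosis"`` or
    ``"intervention"``).  The root has no parent and no category.
    """

    parent: dict[str, str]
    category: dict[str, str] = field(default_factory=dict)
    root: str = ROOT

    def __post_init__(self) -> None:
        if self.root in self.parent:
            raise ValueError("root must not have a parent")
        for node, par in self.parent.items():
            if par != self.root and par not in self.parent:
                raise ValueError(f"parent {par!r} of {node!r} is not a node")
        # acyclicity + reachability: every node must walk up to the root
        for node in self.parent:
            seen = {node}
            cur = node
            while cur != self.root:
                cur = self.parent[cur]
                if cur in seen:
                    raise ValueError(f"cycle through {node!r}")
                seen.add(cur)

    @property
    def nodes(self) -> set[str]:
        return set(self.parent) | {self.root}

    def depth(self, node: str) -> int:
        """Edges from the root; depth(root) = 0."""
        if node not in self.nodes:
            raise KeyError(node)
        d = 0
        while node != self.root:
            node = self.parent[node]
            d += 1
        return d

    def children(self, node: str) -> list[str]:
        return sorted(c for c, p in self.parent.items() if p == node)

    def leaves(self) -> list[str]:
        internal = set(self.parent.values())
        return sorted(n for n in self.parent if n not in internal)

    def _ancestors(self, node: str) -> list[str]:
        path = [node]
        while node != self.root:
            node = self.parent[node]
            path.append(node)
        return path

    # -- persistence: JSON edge list -----------------------------------

    def to_json(self, path: str | Path) -> None:
        nodes = [{"id": self.root, "parent": None, "category": None}]
        for n in sorted(self.parent):
            nodes.append({"id": n, "parent": self.parent[n], "category": self.category.get(n)})
        Path(path).write_text(json.dumps({"nodes": nodes}, indent=1, ensure_ascii=False))

    @classmethod
    def from_json(cls, path: str | Path) -> "HeadingTaxonomy":
        data = json.loads(Path(path).read_text())
        parent, category, root = {}, {}, None
        for n in data["nodes"]:
            if n["parent"] is None:
                root = n["id"]
            else:
                parent[n["id"]] = n["parent"]
                if n.get("category"):
                    category[n["id"]] = n["category"]
        if root is None:
            raise ValueError("taxonomy JSON has no root node")
        return cls(parent=parent, category=category, root=root)


def tree_distance(tax: HeadingTaxonomy, a: str, b: str) -> int:
    """Length (edge count) of the unique path between two nodes.

    Computed from the two root paths: d(a, b) = depth(a) + depth(b)
    - 2 depth(lca).  Symmetric, zero iff ``a == b``.
    """
    if a not in tax.nodes or b not in tax.nodes:
        missing = a if a not in tax.nodes else b
        raise KeyError(f"unknown heading {missing!r}")
    if a == b:
        return 0
    up_a = tax._ancestors(a)
    up_b = set(tax._ancestors(b))
    for i, anc in enumerate(up_a):
        if anc in up_b:
            lca = anc
            break
    da = i  # edges from a to lca
    db = tax._ancestors(b).index(lca)
    return da + db
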