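"""A small rooted-tree structure with Newick I/O.

Branch support values are carried as internal-node labels on write
(the PhyML convention), so ``(a:1,(b:1,c:1)0.93:0.5);`` round-trips with
the support 0.93 attached to the internal branch above ``(b,c)``.
"""

from __future__ import annotations

import itertools
from typing import Iterator, Optional


class TreeError(ValueError):
    pass


class Node:
    __slots__ = ("name", "length", "support", "children", "parent")

    def __init__(self, name: str = "", length: float = 0.0,
                 support: Optional[float] = None):
        self.name = name
        self.length = length
        self.support = support
        self.children: list[Node] = []
        self.parent: Optional[Node] = None

    def add(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def walk(self) -> Iterator["Node"]:
        """Preorder traversal."""
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator["Node"]:
        out = list(self.walk())
        return reversed(out)

    def leaves(self) -> list["Node"]:
        return [n for n in self.walk() if n.is_leaf]

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    def __repr__(self):
        return f"<Node {self.name or '(internal)'} len={self.length:g}>"


class Tree:
    """Rooted tree; used unrooted by treating the root as an anchor node."""

    def __init__(self, root: Node):
        self.root = root
        names = self.root.leaf_names()
        if len(set(names)) != len(names):
            raise TreeError("duplicate tip labels")

    # -- queries ---------------------------------------------------------
    def leaves(self):
        return self.root.leaves()

    def leaf_names(self):
        return self.root.leaf_names()

    def find(self, name: str) -> Node:
        for n in self.root.walk():
            if n.name == name:
                return n
        raise KeyError(name)

    def internal_edges(self) -> list[Node]:
        """Nodes whose parent edge is internal (neither tip nor root edge)."""
        return [n for n in self.root.walk()
                if n.parent is not None and not n.is_leaf]

    def copy(self) -> "Tree":
        def clone(n: Node) -> Node:
            c = Node(n.name, n.length, n.support)
            for ch in n.children:
                c.add(clone(ch))
            return c
        return Tree(clone(self.root))

    def tip_distances(self) -> dict:
        """All-pairs tip-to-tip path lengths."""
        dists = {}
        # distance from every node down to its tips
        down: dict[Node, dict[str, float]] = {}
        for node in self.root.postorder():
            if node.is_leaf:
                down[node] = {node.name: 0.0}
            else:
                d = {}
                for ch in node.children:
                    for tip, x in down[ch].items():
                        d[tip] = x + ch.length
                down[node] = d
        for node in self.root.walk():
            if node.is_leaf:
                continue
            for c1, c2 in itertools.combinations(node.children, 2):
                for t1, x1 in down[c1].items():
                    for t2, x2 in down[c2].items():
                        key = (t1, t2) if t1 < t2 else (t2, t1)
                        dists[key] = x1 + c1.length + x2 + c2.length
        return dists

    def bipartitions(self) -> set:
        """Non-trivial splits as frozensets of the smaller-or-lexicographic
        side, suitable for Robinson–Foulds comparison."""
        all_tips = frozenset(self.leaf_names())
        splits = set()
        for node in self.root.walk():
            if node.parent is None or node.is_leaf:
                continue
            side = frozenset(node.leaf_names())
            other = all_tips - side
            if len(side) < 2 or len(other) < 2:
                continue
            splits.add(min(side, other, key=lambda s: (len(s), sorted(s))))
        return splits

    def robinson_foulds(self, other: "Tree") -> int:
        if set(self.leaf_names()) != set(other.leaf_names()):
            raise TreeError("trees have different tip sets")
        a, b = self.bipartitions(), other.bipartitions()
        return len(a ^ b)

    # -- newick ----------------------------------------------------------
    def to_newick(self, support_as_label: bool = True) -> str:
        def fmt(n: Node) -> str:
            if n.is_leaf:
                return f"{n.name}:{n.length:.10g}"
            inner = ",".join(fmt(c) for c in n.children)
            label = n.name
            if support_as_label and n.support is not None:
                label = f"{n.support:.4g}"
            if n.parent is None:
                return f"({inner}){label}"
            return f"({inner}){label}:{n.length:.10g}"
        return fmt(self.root) + ";"

    def write(self, path, **kw):
        with open(path, "w") as fh:
            fh.write(self.to_newick(**kw) + "\n")

    @classmethod
    def from_newick(cls, text: str) -> "Tree":
        return cls(_parse_newick(text))

    @classmethod
    def read(cls, path) -> "Tree":
        with open(path) as fh:
            return cls.from_newick(fh.read())

    def __repr__(self):
        return f"<Tree with {len(self.leaves())} tips>"


def _parse_newick(text: str) -> Node:
    text = text.strip()
    if not text.endswith(";"):
        raise TreeError("newick string must end with ';'")
    s = text[:-1]
    pos = 0

    def parse_node() -> Node:
        nonlocal pos
        node = Node()
        if pos < len(s) and s[pos] == "(":
            pos += 1
            node.add(parse_node())
            while pos < len(s) and s[pos] == ",":
                pos += 1
                node.add(parse_node())
            if pos >= len(s) or s[pos] != ")":
                raise TreeError("unbalanced parentheses in newick")
            pos += 1
        # label
        start = pos
        while pos < len(s) and s[pos] not in ":,()[];":
            pos += 1
        label = s[start:pos].strip()
        if label:
            if node.is_leaf:
                node.name = label
            else:
                try:
                    node.support = float(label)
                except ValueError:
                    node.name = label
        if pos < len(s) and s[pos] == ":":
            pos += 1
            start = pos
            while pos < len(s) and s[pos] not in ",()[];":
                pos += 1
            node.length = float(s[start:pos])
        return node

    root = parse_node()
    if pos != len(s):
        raise TreeError(f"trailing characters in newick at offset {pos}")
    return root
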