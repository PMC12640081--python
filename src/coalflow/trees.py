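"""Rooted trees with branch lengths, and Newick round-tripping.

Branch lengths are always expected substitutions per site.  Gene trees
additionally carry node ages (``Node.age``), with tips at age 0, so a branch
length equals the age difference between a node and its parent.
"""

from __future__ import annotations

from typing import Iterator, Optional


class NewickError(ValueError):
    """Malformed Newick input; ``offset`` is the 0-based character position."""

    def __init__(self, message: str, offset: int):
        super().__init__(f"{message} (at character {offset})")
        self.offset = offset


class Node:
    __slots__ = ("name", "length", "children", "parent", "age")

    def __init__(self, name: str = "", length: Optional[float] = None):
        self.name = name
        self.length = length  # branch length to parent; None at an unrooted root
        self.children: list[Node] = []
        self.parent: Optional[Node] = None
        self.age: Optional[float] = None

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_tip(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Node({self.name!r}, len={self.length}, age={self.age})"


class Tree:
    """A rooted tree.  Tip labels must be unique."""

    def __init__(self, root: Node):
        self.root = root
        labels = [t.name for t in self.tips()]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate tip labels")

    def tips(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_tip]

    def tip_labels(self) -> list[str]:
        return [t.name for t in self.tips()]

    def postorder(self) -> Iterator[Node]:
        stack = [(self.root, False)]
        while stack:
            node, done = stack.pop()
            if done:
                yield node
            else:
                stack.append((node, True))
                for c in reversed(node.children):
                    stack.append((c, False))

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            for c in reversed(node.children):
                stack.append(c)

    def find(self, name: str) -> Node:
        for n in self.postorder():
            if n.name == name:
                return n
        raise KeyError(f"no node named {name!r}")

    def n_tips(self) -> int:
        return len(self.tips())

    def copy(self) -> "Tree":
        def _copy(n: Node) -> Node:
            m = Node(n.name, n.length)
            m.age = n.age
            for c in n.children:
                m.add_child(_copy(c))
            return m

        return Tree(_copy(self.root))

    def set_ages_from_lengths(self) -> None:
        """Derive node ages assuming the tree is ultrametric with tips at 0."""
        depth = {self.root: 0.0}
        maxd = 0.0
        for n in self.preorder():
            if n is not self.root:
                depth[n] = depth[n.parent] + (n.length or 0.0)
                maxd = max(maxd, depth[n])
        for n in self.postorder():
            n.age = maxd - depth[n]
        for t in self.tips():
            t.age = 0.0

    def set_lengths_from_ages(self) -> None:
        for n in self.preorder():
            if n.parent is not None:
                n.length = n.parent.age - n.age

    def newick(self, precision: int = 6) -> str:
        return write_newick(self, precision)


def parse_newick(text: str) -> Tree:
    """Parse a single Newick statement into a :class:`Tree`.

    Topology, labels and branch lengths are preserved; child order is kept as
    written.  Raises :class:`NewickError` naming the character offset of the
    first problem.
    """
    s = text.strip()
    if not s:
        raise NewickError("empty input", 0)
    # offset of stripped string within original text
    base = text.index(s[0])
    pos = 0
    n = len(s)

    def error(msg: str, at: int):
        raise NewickError(msg, base + at)

    def parse_label(start: int) -> tuple[str, int]:
        i = start
        if i < n and s[i] in "'\"":
            quote = s[i]
            j = s.find(quote, i + 1)
            if j < 0:
                error("unterminated quoted label", i)
            return s[i + 1 : j], j + 1
        while i < n and s[i] not in "(),:;[]":
            i += 1
        return s[start:i].strip(), i

    def parse_length(start: int) -> tuple[Optional[float], int]:
        if start < n and s[start] == ":":
            i = start + 1
            j = i
            while j < n and (s[j] in "+-.eE" or s[j].isdigit()):
                j += 1
            try:
                val = float(s[i:j])
            except ValueError:
                error("invalid branch length", i)
            return val, j
        return None, start

    def parse_clade(start: int) -> tuple[Node, int]:
        i = start
        node = Node()
        if i < n and s[i] == "(":
            i += 1
            while True:
                child, i = parse_clade(i)
                node.add_child(child)
                if i >= n:
                    error("missing ')'", i)
                if s[i] == ",":
                    i += 1
                    continue
                if s[i] == ")":
                    i += 1
                    break
                error("expected ',' or ')'", i)
        name, i = parse_label(i)
        node.name = name
        node.length, i = parse_length(i)
        return node, i

    root, pos = parse_clade(0)
    if pos >= n or s[pos] != ";":
        error("missing ';'", pos)
    if s[pos + 1 :].strip():
        error("trailing characters after ';'", pos + 1)
    if root.is_tip and not root.name:
        error("empty tree", 0)
    return Tree(root)


def write_newick(tree: Tree, precision: int = 6) -> str:
    """Serialize deterministically; child order preserved, lengths fixed-point."""

    def fmt(x: float) -> str:
        if precision <= 0:
            return str(int(round(x)))
        return f"{x:.{precision}f}"

    def rec(node: Node) -> str:
        if node.is_tip:
            body = node.name
        else:
            body = "(" + ",".join(rec(c) for c in node.children) + ")" + node.name
        if node.length is not None:
            body += ":" + fmt(node.length)
        return body

    return rec(tree.root) + ";"
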