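"""Rooted phylogenies with branch tags, and tag-aware Newick I/O.

Trees are rooted, carry branch lengths in expected substitutions per site,
and attach string tag sets to edges (identified by their child node). The
Newick dialect accepted here extends the standard with PAML-style ``#1``
foreground marks and an explicit ``[&tags=A,B]`` annotation; both attach to
the edge above the node they follow. ``#1`` maps to the ``FOREGROUND`` tag.

Internal nodes are numbered by a deterministic post-order traversal of the
parsed tree; all downstream outputs refer to these ids.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

FOREGROUND = "FOREGROUND"

#: the seven foreground configurations scanned in the study design
FOREGROUND_CONFIGS: dict[str, tuple[str, ...]] = {
    "CF": ("CF",),
    "FM": ("FM",),
    "CLICK": ("CLICK",),
    "TW": ("TW",),
    "CF+FM": ("CF", "FM"),
    "CF+FM+CLICK": ("CF", "FM", "CLICK"),
    "CF+FM+CLICK+TW": ("CF", "FM", "CLICK", "TW"),
}


class NewickParseError(ValueError):
    """Malformed Newick input; the message names the offending token."""


@dataclass
class Node:
    label: str | None = None
    length: float | None = None
    tags: set[str] = field(default_factory=set)
    children: list["Node"] = field(default_factory=list)
    parent: "Node | None" = None
    node_id: int = -1  # post-order index, assigned by PhyloTree

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def postorder(self) -> Iterator["Node"]:
        for child in self.children:
            yield from child.postorder()
        yield self


class PhyloTree:
    """A rooted tree with named leaves, branch lengths and edge tag sets."""

    def __init__(self, root: Node):
        self.root = root
        self._index()

    def _index(self) -> None:
        self.nodes: list[Node] = list(self.root.postorder())
        for i, node in enumerate(self.nodes):
            node.node_id = i
            for child in node.children:
                child.parent = node
        self.root.parent = None
        self.leaves: list[Node] = [n for n in self.nodes if n.is_leaf]
        self.leaf_labels: list[str] = [n.label for n in self.leaves]
        self._by_label = {n.label: n for n in self.nodes if n.label is not None}

    # -- lookups ---------------------------------------------------------

    def node(self, key: int | str) -> Node:
        """Find a node by post-order id or by label."""
        if isinstance(key, int):
            return self.nodes[key]
        try:
            return self._by_label[key]
        except KeyError:
            raise KeyError(f"no node labelled {key!r} in tree") from None

    def mrca(self, labels: Sequence[str]) -> Node:
        paths = []
        for lab in labels:
            node, path = self.node(lab), []
            while node is not None:
                path.append(node)
                node = node.parent
            paths.append(path[::-1])
        common = None
        for ancestors in zip(*paths):
            if all(a is ancestors[0] for a in ancestors):
                common = ancestors[0]
            else:
                break
        return common

    def is_ancestor(self, anc: Node, desc: Node) -> bool:
        node = desc
        while node is not None:
            if node is anc:
                return True
            node = node.parent
        return False

    # -- editing ---------------------------------------------------------

    def copy(self) -> "PhyloTree":
        def clone(n: Node) -> Node:
            return Node(label=n.label, length=n.length, tags=set(n.tags),
                        children=[clone(c) for c in n.children])
        return PhyloTree(clone(self.root))

    def scaled(self, factor: float) -> "PhyloTree":
        out = self.copy()
        for n in out.nodes:
            if n.length is not None:
                n.length *= factor
        return out

    @property
    def height(self) -> float:
        """Maximum root-to-leaf path length."""
        def depth(n: Node, acc: float) -> float:
            acc += n.length or 0.0
            if n.is_leaf:
                return acc
            return max(depth(c, acc) for c in n.children)
        return max(depth(c, 0.0) for c in self.root.children)

    def subtree_retaining(self, taxa: Sequence[str]) -> "PhyloTree":
        """Prune to the given leaf set, suppressing unifurcations.

        Branch lengths along suppressed paths are summed; tags on suppressed
        edges are unioned onto the surviving edge.
        """
        keep = set(taxa)
        missing = keep - set(self.leaf_labels)
        if missing:
            raise KeyError(f"taxa not in tree: {sorted(missing)}")

        def prune(n: Node) -> Node | None:
            if n.is_leaf:
                if n.label in keep:
                    return Node(label=n.label, length=n.length, tags=set(n.tags))
                return None
            kids = [k for k in (prune(c) for c in n.children) if k is not None]
            if not kids:
                return None
            if len(kids) == 1:
                child = kids[0]
                if n.length is not None:
                    child.length = (child.length or 0.0) + n.length
                child.tags |= n.tags
                return child
            return Node(label=n.label, length=n.length, tags=set(n.tags), children=kids)

        root = prune(self.root)
        if root is None or root.is_leaf:
            raise ValueError("pruned tree has fewer than 2 leaves")
        root.length = None
        return PhyloTree(root)

    # -- serialization ---------------------------------------------------

    def newick(self, tags: bool = True, paml: bool = False) -> str:
        return write_newick(self, tags=tags, paml=paml)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"PhyloTree({len(self.leaves)} leaves)"


# -- Newick parsing ------------------------------------------------------

_TOKEN_RE = re.compile(
    r"\s*(\(|\)|,|;|:|\[&tags=[^\]]*\]|#[A-Za-z0-9_]+|[^\s(),:;#\[\]]+)"
)


def _tokenize(text: str) -> list[str]:
    tokens, pos = [], 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            rest = text[pos:].strip()
            if not rest:
                break
            raise NewickParseError(f"unparseable input at {rest[:20]!r}")
        tokens.append(m.group(1))
        pos = m.end()
    return tokens


def parse_newick(text: str) -> PhyloTree:
    """Parse a rooted Newick string, accepting ``#1`` and ``[&tags=...]``.

    Raises :class:`NewickParseError` naming the offending token for
    malformed parentheses, duplicate leaf labels or negative branch lengths.
    """
    tokens = _tokenize(text)
    if not tokens:
        raise NewickParseError("empty Newick string")
    pos = 0

    def peek() -> str | None:
        return tokens[pos] if pos < len(tokens) else None

    def take() -> str:
        nonlocal pos
        if pos >= len(tokens):
            raise NewickParseError("unexpected end of input (missing ';'?)")
        tok = tokens[pos]
        pos += 1
        return tok

    def parse_tags(node: Node) -> None:
        # tags may appear before and/or after the branch length
        while True:
            tok = peek()
            if tok is None:
                return
            if tok.startswith("[&tags="):
                take()
                body = tok[len("[&tags="):-1]
                node.tags.update(t for t in body.split(",") if t)
            elif tok.startswith("#"):
                take()
                mark = tok[1:]
                node.tags.add(FOREGROUND if mark.isdigit() else mark)
            else:
                return

    def parse_clade() -> Node:
        node = Node()
        tok = peek()
        if tok == "(":
            take()
            node.children.append(parse_clade())
            while peek() == ",":
                take()
                node.children.append(parse_clade())
            closing = take()
            if closing != ")":
                raise NewickParseError(f"expected ')' but found {closing!r}")
            if peek() is not None and _is_label(peek()):
                node.label = take()
        else:
            if tok is None or not _is_label(tok):
                raise NewickParseError(f"expected a taxon label, found {tok!r}")
            node.label = take()
        parse_tags(node)
        if peek() == ":":
            take()
            tok = take()
            try:
                length = float(tok)
            except ValueError:
                raise NewickParseError(f"bad branch length token {tok!r}") from None
            if length < 0:
                raise NewickParseError(f"negative branch length {tok!r}")
            node.length = length
        parse_tags(node)
        return node

    root = parse_clade()
    tok = peek()
    if tok != ";":
        raise NewickParseError(f"expected ';' at end, found {tok!r}")
    pos += 1
    if pos < len(tokens):
        raise NewickParseError(f"trailing content after ';': {tokens[pos]!r}")

    tree = PhyloTree(root)
    seen: set[str] = set()
    for leaf in tree.leaves:
        if leaf.label is None:
            raise NewickParseError("leaf without a label")
        if leaf.label in seen:
            raise NewickParseError(f"duplicate leaf label {leaf.label!r}")
        seen.add(leaf.label)
    return tree


def _is_label(tok: str) -> bool:
    return tok not in "(),:;" and not tok.startswith("#") and not tok.startswith("[&tags=")


def _fmt_length(x: float) -> str:
    s = f"{x:.10g}"
    return s


def write_newick(tree: PhyloTree, tags: bool = True, paml: bool = False) -> str:
    """Serialize a tree. ``paml=True`` writes FOREGROUND edges as `` #1``
    and drops all other tags; otherwise tags go into ``[&tags=...]``."""

    def fmt(node: Node) -> str:
        if node.is_leaf:
            s = node.label or ""
        else:
            s = "(" + ",".join(fmt(c) for c in node.children) + ")"
            if node.label:
                s += node.label
        if tags and node.tags and not paml:
            s += "[&tags=" + ",".join(sorted(node.tags)) + "]"
        if node.length is not None:
            s += f":{_fmt_length(node.length)}"
        if paml and FOREGROUND in node.tags:
            s += " #1"
        return s

    return fmt(tree.root) + ";"


# -- foreground marking --------------------------------------------------

def mark_foreground(
    tree: PhyloTree,
    config_name: str,
    lineages: Mapping[str, Sequence[str]] | None = None,
) -> PhyloTree:
    """Return a copy of the tree with FOREGROUND tags set for one of the
    seven study configurations (terminal branches of the member lineages).

    ``lineages`` maps lineage names (CF, FM, CLICK, TW, ...) to taxon
    labels; defaults to the 19-taxon study design.
    """
    if config_name not in FOREGROUND_CONFIGS:
        raise ValueError(
            f"unknown foreground configuration {config_name!r}; "
            f"expected one of {sorted(FOREGROUND_CONFIGS)}"
        )
    if lineages is None:
        from echoconv.study import STUDY_LINEAGES
        lineages = STUDY_LINEAGES

    out = tree.copy()
    for node in out.nodes:
        node.tags.discard(FOREGROUND)
    present = set(out.leaf_labels)
    for lineage in FOREGROUND_CONFIGS[config_name]:
        taxa = lineages.get(lineage)
        if taxa is None:
            raise ValueError(f"lineage {lineage!r} not defined in lineage map")
        missing = [t for t in taxa if t not in present]
        if missing:
            raise ValueError(
                f"tree lacks taxa for lineage {lineage!r}: missing {missing}"
            )
        for taxon in taxa:
            out.node(taxon).tags.add(FOREGROUND)
    return out


def foreground_edges(tree: PhyloTree) -> list[Node]:
    """Nodes whose parent edge carries the FOREGROUND tag."""
    return [n for n in tree.nodes if FOREGROUND in n.tags and n.parent is not None]
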