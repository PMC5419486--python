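"""Unrooted genealogies: Newick I/O, bipartitions, pruning, and monophyly collapsing.

A :class:`Genealogy` is stored rooted (parent/child pointers) but is always
*interpreted* unrooted: topology identity is the set of nontrivial
bipartitions, so the storage root never affects any downstream computation.
Branch lengths are optional and unit-agnostic (simulated trees carry lengths
in units of 4N generations).
"""

from __future__ import annotations

import gzip
import itertools
from collections import deque
from collections.abc import Iterable, Iterator, Mapping, Sequence
from dataclasses import dataclass

import numpy as np

__all__ = [
    "Genealogy",
    "CollapsedGenealogy",
    "Bipartition",
    "TaxonMap",
    "GenealogyError",
    "NewickParseError",
    "parse_newick",
    "write_newick",
    "bipartitions",
    "prune_to_samples",
    "collapse_monophyletic",
    "collapse_zero_branches",
    "patristic_distance",
    "patristic_distance_matrix",
    "topological_distance_matrix",
    "reroot",
    "read_groups",
    "iter_newick_file",
]


class GenealogyError(ValueError):
    """Invalid tree structure or invariant violation."""


class NewickParseError(GenealogyError):
    """Malformed Newick text; carries the character offset of the problem."""

    def __init__(self, message: str, offset: int):
        super().__init__(f"{message} (at character {offset})")
        self.offset = offset


class Node:
    """One vertex of a rooted tree representation."""

    __slots__ = ("parent", "children", "label", "length")

    def __init__(self, label: str | None = None, length: float | None = None):
        self.parent: Node | None = None
        self.children: list[Node] = []
        self.label = label
        self.length = length

    def add(self, child: "Node") -> None:
        child.parent = self
        self.children.append(child)

    @property
    def is_tip(self) -> bool:
        return not self.children


class Genealogy:
    """A tree over uniquely labeled sample tips, interpreted unrooted."""

    def __init__(self, root: Node, validate: bool = True):
        self.root = root
        self._tips: dict[str, Node] = {}
        for node in self.postorder():
            if node.is_tip:
                if not node.label:
                    raise GenealogyError("tip with empty label")
                if node.label in self._tips:
                    raise GenealogyError(f"duplicate tip label {node.label!r}")
                self._tips[node.label] = node
        if validate:
            for node in self.postorder():
                if node.length is not None and node.length < 0:
                    raise GenealogyError(
                        f"negative branch length {node.length} above "
                        f"{node.label or 'internal node'}"
                    )

    # -- traversal ---------------------------------------------------------

    def postorder(self) -> Iterator[Node]:
        stack: list[tuple[Node, bool]] = [(self.root, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded or node.is_tip:
                yield node
            else:
                stack.append((node, True))
                for child in reversed(node.children):
                    stack.append((child, False))

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    @property
    def tip_labels(self) -> tuple[str, ...]:
        """Tip labels in left-to-right (postorder) order."""
        return tuple(n.label for n in self.postorder() if n.is_tip)

    @property
    def n_tips(self) -> int:
        return len(self._tips)

    def tip(self, label: str) -> Node:
        try:
            return self._tips[label]
        except KeyError:
            raise GenealogyError(f"unknown tip label {label!r}") from None

    @property
    def has_branch_lengths(self) -> bool:
        """True iff every edge (i.e. every non-root node) carries a length."""
        return all(
            n.length is not None for n in self.postorder() if n is not self.root
        )

    @property
    def is_bifurcating(self) -> bool:
        """True iff every internal vertex of the unrooted tree has degree 3.

        A degree-2 storage root is suppressed in the unrooted interpretation
        and so does not count against bifurcation.
        """
        for node in self.postorder():
            if node.is_tip:
                continue
            degree = len(node.children) + (0 if node.parent is None else 1)
            if node.parent is None and len(node.children) == 2:
                continue  # suppressed root
            if degree != 3:
                return False
        return True

    def copy(self) -> "Genealogy":
        return Genealogy(_clone(self.root), validate=False)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<Genealogy with {self.n_tips} tips>"


def _clone(node: Node) -> Node:
    new = Node(node.label, node.length)
    for child in node.children:
        new.add(_clone(child))
    return new


class CollapsedGenealogy(Genealogy):
    """A genealogy whose maximal same-taxon clades are single weighted tips.

    ``multiplicity[label]`` counts how many original samples the tip stands
    for, and ``tip_taxon[label]`` records its taxon. Branch lengths on a
    collapsed tree are representative only (the first merged tip's); the tree
    exists for topology counting, where lengths are irrelevant.
    """

    def __init__(
        self,
        root: Node,
        multiplicity: Mapping[str, int],
        tip_taxon: Mapping[str, str],
    ):
        super().__init__(root, validate=False)
        self.multiplicity = dict(multiplicity)
        self.tip_taxon = dict(tip_taxon)


# ---------------------------------------------------------------------------
# Taxon mapping


class TaxonMap:
    """Ordered taxa plus a sample → taxon assignment.

    The taxon order is significant: it fixes the enumeration order of taxon
    topologies and hence the stable ``topo1..topoK`` identifiers.
    """

    def __init__(
        self,
        assignment: Mapping[str, str],
        taxa: Sequence[str] | None = None,
    ):
        self.assignment = dict(assignment)
        if taxa is None:
            seen: dict[str, None] = {}
            for t in self.assignment.values():
                seen.setdefault(t)
            taxa = list(seen)
        self.taxa: tuple[str, ...] = tuple(taxa)
        extra = set(self.assignment.values()) - set(self.taxa)
        if extra:
            raise GenealogyError(f"samples assigned to unlisted taxa: {sorted(extra)}")
        self._samples: dict[str, list[str]] = {t: [] for t in self.taxa}
        for sample, taxon in self.assignment.items():
            self._samples[taxon].append(sample)
        if len(self.taxa) < 3:
            raise GenealogyError("at least 3 taxa are required")
        empties = [t for t in self.taxa if not self._samples[t]]
        if empties:
            raise GenealogyError(f"taxa with no samples: {empties}")

    @property
    def n(self) -> int:
        return len(self.taxa)

    @property
    def sizes(self) -> dict[str, int]:
        """s_j: the number of samples in each taxon."""
        return {t: len(self._samples[t]) for t in self.taxa}

    def samples(self, taxon: str) -> tuple[str, ...]:
        return tuple(self._samples[taxon])

    @property
    def n_combinations(self) -> int:
        """N = prod_j s_j, the number of one-sample-per-taxon transversals."""
        out = 1
        for t in self.taxa:
            out *= len(self._samples[t])
        return out

    def taxon_of(self, sample: str) -> str:
        try:
            return self.assignment[sample]
        except KeyError:
            raise GenealogyError(f"sample {sample!r} not assigned to a taxon") from None

    def restrict(self, samples: Iterable[str]) -> "TaxonMap":
        """A map covering only ``samples`` (taxon order preserved)."""
        keep = set(samples)
        sub = {s: t for s, t in self.assignment.items() if s in keep}
        return TaxonMap(sub, taxa=self.taxa)

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, TaxonMap)
            and self.taxa == other.taxa
            and self.assignment == other.assignment
        )

    def __repr__(self) -> str:  # pragma: no cover
        sizes = ",".join(f"{t}:{s}" for t, s in self.sizes.items())
        return f"<TaxonMap {sizes}>"


def read_groups(path, taxa: Sequence[str] | None = None) -> TaxonMap:
    """Read a two-column tab-separated ``sample<TAB>taxon`` file.

    Lines starting with ``#`` are ignored. ``taxa`` optionally fixes the
    taxon order (default: order of first appearance).
    """
    assignment: dict[str, str] = {}
    with _open_text(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise GenealogyError(
                    f"{path}:{lineno}: expected 'sample<TAB>taxon', got {line!r}"
                )
            sample, taxon = parts
            if sample in assignment:
                raise GenealogyError(f"{path}:{lineno}: duplicate sample {sample!r}")
            assignment[sample] = taxon
    return TaxonMap(assignment, taxa=taxa)


def _open_text(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


# ---------------------------------------------------------------------------
# Newick I/O


def parse_newick(text: str) -> Genealogy:
    """Parse one Newick tree.

    Internal node labels and bracketed comments are accepted and discarded;
    quoted tip labels are unquoted. Errors name the character offset.
    """
    pos = 0
    n = len(text)

    def skip_ws() -> None:
        nonlocal pos
        while pos < n:
            c = text[pos]
            if c.isspace():
                pos += 1
            elif c == "[":  # comment
                end = text.find("]", pos)
                if end < 0:
                    raise NewickParseError("unterminated comment", pos)
                pos = end + 1
            else:
                break

    def read_label() -> str:
        nonlocal pos
        skip_ws()
        if pos < n and text[pos] == "'":
            end = text.find("'", pos + 1)
            if end < 0:
                raise NewickParseError("unterminated quoted label", pos)
            label = text[pos + 1 : end]
            pos = end + 1
            return label
        start = pos
        while pos < n and text[pos] not in "(),:;[":
            pos += 1
        return text[start:pos].strip()

    def read_length() -> float | None:
        nonlocal pos
        skip_ws()
        if pos < n and text[pos] == ":":
            pos += 1
            skip_ws()
            start = pos
            while pos < n and (text[pos] in "+-.eE" or text[pos].isdigit()):
                pos += 1
            try:
                return float(text[start:pos])
            except ValueError:
                raise NewickParseError("invalid branch length", start) from None
        return None

    def read_clade() -> Node:
        nonlocal pos
        skip_ws()
        node = Node()
        if pos < n and text[pos] == "(":
            pos += 1
            while True:
                node.add(read_clade())
                skip_ws()
                if pos >= n:
                    raise NewickParseError("unbalanced parentheses", pos)
                if text[pos] == ",":
                    pos += 1
                    continue
                if text[pos] == ")":
                    pos += 1
                    break
                raise NewickParseError(
                    f"unexpected character {text[pos]!r}", pos
                )
            label = read_label()  # internal label: discarded
            if not node.children:
                raise NewickParseError("empty clade", pos)
        else:
            label = read_label()
            if not label:
                raise NewickParseError("expected a tip label", pos)
            node.label = label
        node.length = read_length()
        return node

    root = read_clade()
    skip_ws()
    if pos < n and text[pos] == ";":
        pos += 1
    skip_ws()
    if pos != n:
        raise NewickParseError("trailing characters after tree", pos)
    while not root.is_tip and len(root.children) == 1:
        root = root.children[0]
        root.parent = None
        root.length = None
    if root.is_tip:
        raise NewickParseError("tree has a single tip", 0)
    return Genealogy(root)


def write_newick(tree: Genealogy, lengths: bool = True) -> str:
    """Serialize to Newick with unquoted labels; ``;``-terminated."""

    def fmt(node: Node) -> str:
        if node.is_tip:
            body = node.label
        else:
            body = "(" + ",".join(fmt(c) for c in node.children) + ")"
        if lengths and node.length is not None:
            body += f":{node.length:.10g}"
        return body

    return fmt(tree.root) + ";"


def iter_newick_file(path) -> Iterator[Genealogy | None]:
    """Yield one tree per line; blank or ``NA`` lines yield ``None``."""
    with _open_text(path) as handle:
        for line in handle:
            line = line.strip()
            if not line or line.upper() in {"NA", "NAN", "NONE"}:
                yield None
            else:
                yield parse_newick(line)


# ---------------------------------------------------------------------------
# Bipartitions


@dataclass(frozen=True)
class Bipartition:
    """One nontrivial split of an unrooted tree, canonically represented.

    ``block`` is the smaller side (ties broken by lexicographically smallest
    sorted tuple), ``universe`` the full label set.
    """

    block: frozenset
    universe: frozenset

    @staticmethod
    def make(block: Iterable, universe: Iterable) -> "Bipartition":
        universe = frozenset(universe)
        block = frozenset(block)
        other = universe - block
        if len(other) < len(block) or (
            len(other) == len(block) and sorted(other) < sorted(block)
        ):
            block = other
        if not block or block == universe:
            raise GenealogyError("trivial bipartition")
        return Bipartition(block, universe)

    @property
    def sides(self) -> tuple[frozenset, frozenset]:
        return self.block, self.universe - self.block


def bipartitions(
    tree: Genealogy, labels: Iterable[str] | None = None
) -> frozenset[Bipartition]:
    """Nontrivial splits of the unrooted tree, restricted to ``labels``.

    For a bifurcating tree on k labels this is exactly k-3 splits.
    """
    universe = frozenset(labels) if labels is not None else frozenset(tree._tips)
    unknown = universe - set(tree._tips)
    if unknown:
        raise GenealogyError(f"labels not in tree: {sorted(unknown)}")
    if len(universe) < 4:
        raise GenealogyError("bipartitions need at least 4 labels")
    below: dict[int, frozenset] = {}
    out: set[Bipartition] = set()
    for node in tree.postorder():
        if node.is_tip:
            sub = frozenset({node.label}) & universe
        else:
            sub = frozenset().union(*(below[id(c)] for c in node.children))
        below[id(node)] = sub
        if node.parent is not None and 2 <= len(sub) <= len(universe) - 2:
            out.add(Bipartition.make(sub, universe))
    return frozenset(out)


# ---------------------------------------------------------------------------
# Pruning


def prune_to_samples(tree: Genealogy, samples: Iterable[str]) -> Genealogy:
    """The subtree spanning ``samples``, with unary nodes suppressed.

    Branch lengths along suppressed paths are summed, so patristic distances
    among the retained tips are preserved exactly.
    """
    keep = set(samples)
    unknown = keep - set(tree._tips)
    if unknown:
        raise GenealogyError(f"unknown sample labels: {sorted(unknown)}")
    if len(keep) < 3:
        raise GenealogyError("pruning requires at least 3 samples")

    def build(node: Node) -> Node | None:
        if node.is_tip:
            if node.label in keep:
                return Node(node.label, node.length)
            return None
        kept = [c2 for c in node.children if (c2 := build(c)) is not None]
        if not kept:
            return None
        if len(kept) == 1:
            child = kept[0]
            if child.length is not None and node.length is not None:
                child.length += node.length
            elif node.length is not None:
                child.length = node.length
            return child
        new = Node(None, node.length)
        for c in kept:
            new.add(c)
        return new

    root = build(tree.root)
    assert root is not None
    root.length = None  # no edge above the storage root
    return Genealogy(root, validate=False)


def collapse_zero_branches(tree: Genealogy, tol: float = 0.0) -> Genealogy:
    """Contract internal branches of length <= ``tol`` into polytomies."""

    def build(node: Node, parent: Node | None) -> Node:
        new = Node(node.label, node.length)
        for child in node.children:
            built = build(child, new)
            if (
                not built.is_tip
                and built.length is not None
                and built.length <= tol
            ):
                for gc in built.children:
                    new.add(gc)
            else:
                new.add(built)
        return new

    return Genealogy(build(tree.root, None), validate=False)


# ---------------------------------------------------------------------------
# Unrooted adjacency helpers


def _adjacency(tree: Genealogy) -> dict[Node, list[tuple[Node, float | None]]]:
    """Undirected adjacency with a degree-2 storage root suppressed."""
    adj: dict[Node, list[tuple[Node, float | None]]] = {}

    def connect(u: Node, v: Node, length: float | None) -> None:
        adj.setdefault(u, []).append((v, length))
        adj.setdefault(v, []).append((u, length))

    for node in tree.postorder():
        if node.parent is not None:
            connect(node.parent, node, node.length)
    root = tree.root
    if len(root.children) == 2 and root in adj:
        (a, la), (b, lb) = adj.pop(root)
        adj[a] = [(x, l) for x, l in adj[a] if x is not root]
        adj[b] = [(x, l) for x, l in adj[b] if x is not root]
        if la is None and lb is None:
            merged = None
        else:
            merged = (la or 0.0) + (lb or 0.0)
        connect(a, b, merged)
    return adj


def _rebuild_rooted(
    adj: Mapping[Node, Sequence[tuple[Node, float | None]]], start: Node
) -> Node:
    """Re-root an adjacency structure at ``start`` into fresh Nodes."""

    def build(node: Node, parent: Node | None, length: float | None) -> Node:
        new = Node(node.label, length)
        for nbr, l in adj[node]:
            if nbr is not parent:
                new.add(build(nbr, node, l))
        return new

    return build(start, None, None)


def reroot(tree: Genealogy, outgroup: str) -> Genealogy:
    """Re-root on the edge above tip ``outgroup`` (topology-preserving)."""
    tip = tree.tip(outgroup)
    adj = _adjacency(tree)
    (nbr, length) = adj[tip][0]
    root = Node()
    new_tip = Node(tip.label, length)
    root.add(new_tip)

    def build(node: Node, parent: Node) -> Node:
        new = Node(node.label)
        for other, l in adj[node]:
            if other is not parent:
                child = build(other, node)
                child.length = l
                new.add(child)
        return new

    sub = build(nbr, tip)
    sub.length = 0.0 if length is not None else None
    root.add(sub)
    return Genealogy(root, validate=False)


# ---------------------------------------------------------------------------
# Monophyly collapsing


def collapse_monophyletic(tree: Genealogy, taxa: TaxonMap) -> CollapsedGenealogy:
    """Collapse maximal same-taxon clades (unrooted sense) to weighted tips.

    Weighting over the collapsed tree, multiplying each transversal by the
    product of chosen tip multiplicities, is exactly equivalent to weighting
    over the original tree (the counting shortcut this transform exists for).
    """
    for label in tree._tips:
        if label not in taxa.assignment:
            raise GenealogyError(f"tip {label!r} has no taxon assignment")

    adj = _adjacency(tree)
    mult: dict[Node, int] = {}
    taxon_of: dict[Node, str] = {}
    for label, tip in tree._tips.items():
        mult[tip] = 1
        taxon_of[tip] = taxa.taxon_of(label)

    def neighbors(v: Node):
        return adj[v]

    changed = True
    while changed:
        changed = False
        for v in list(adj):
            if v not in adj or v.is_tip:
                continue
            # group leaf neighbors of v by taxon
            groups: dict[str, list[tuple[Node, float | None]]] = {}
            for nbr, l in neighbors(v):
                if nbr.is_tip:
                    groups.setdefault(taxon_of[nbr], []).append((nbr, l))
            for taxon, leaves in groups.items():
                if len(leaves) < 2:
                    continue
                keeper, keep_len = leaves[0]
                for other, _ in leaves[1:]:
                    mult[keeper] += mult[other]
                    adj[v] = [(x, l) for x, l in adj[v] if x is not other]
                    del adj[other]
                    del mult[other]
                    del taxon_of[other]
                changed = True
            if len(adj[v]) == 2:
                (a, la), (b, lb) = adj[v]
                if la is None and lb is None:
                    merged = None
                else:
                    merged = (la or 0.0) + (lb or 0.0)
                adj[a] = [
                    (x if x is not v else b, l if x is not v else merged)
                    for x, l in adj[a]
                ]
                adj[b] = [
                    (x if x is not v else a, l if x is not v else merged)
                    for x, l in adj[b]
                ]
                del adj[v]

    internal = [v for v in adj if not v.is_tip]
    if internal:
        root = _rebuild_rooted(adj, internal[0])
    elif len(adj) == 2:  # two tips left: trivial join
        (a, b) = list(adj)
        root = Node()
        na = Node(a.label, adj[a][0][1])
        nb = Node(b.label, 0.0 if adj[a][0][1] is not None else None)
        root.add(na)
        root.add(nb)
    else:
        raise GenealogyError("tree collapsed to fewer than 2 tips")

    multiplicity = {v.label: m for v, m in mult.items()}
    tip_taxon = {v.label: t for v, t in taxon_of.items()}
    collapsed = CollapsedGenealogy(root, multiplicity, tip_taxon)

    # invariant: per-taxon multiplicities sum to the source sample counts
    totals: dict[str, int] = {}
    for label, m in collapsed.multiplicity.items():
        totals[collapsed.tip_taxon[label]] = (
            totals.get(collapsed.tip_taxon[label], 0) + m
        )
    source: dict[str, int] = {}
    for label in tree._tips:
        t = taxa.taxon_of(label)
        source[t] = source.get(t, 0) + 1
    assert totals == source, "collapse lost samples"
    return collapsed


# ---------------------------------------------------------------------------
# Distances


def patristic_distance(tree: Genealogy, tip1: str, tip2: str) -> float:
    """Sum of branch lengths on the unique path between two tips."""
    a, b = tree.tip(tip1), tree.tip(tip2)
    if tip1 == tip2:
        return 0.0
    anc_a: dict[int, tuple[Node, float]] = {}
    total = 0.0
    node: Node | None = a
    while node is not None:
        anc_a[id(node)] = (node, total)
        if node.parent is not None:
            if node.length is None:
                raise GenealogyError("branch lengths required for distances")
            total += node.length
        node = node.parent
    total = 0.0
    node = b
    while node is not None:
        if id(node) in anc_a:
            return total + anc_a[id(node)][1]
        if node.parent is not None:
            if node.length is None:
                raise GenealogyError("branch lengths required for distances")
            total += node.length
        node = node.parent
    raise GenealogyError("tips are not connected")  # pragma: no cover


def _distance_matrix(
    tree: Genealogy, labels: Sequence[str] | None, unit: bool
) -> tuple[tuple[str, ...], np.ndarray]:
    labels = tuple(labels) if labels is not None else tree.tip_labels
    index = {tree.tip(l): i for i, l in enumerate(labels)}
    adj = _adjacency(tree)
    k = len(labels)
    d = np.zeros((k, k), dtype=float if not unit else np.int64)
    for start, i in index.items():
        seen = {start}
        queue = deque([(start, 0.0 if not unit else 0)])
        while queue:
            node, dist = queue.popleft()
            if node in index and node is not start:
                d[i, index[node]] = dist
            for nbr, l in adj[node]:
                if nbr in seen:
                    continue
                seen.add(nbr)
                if unit:
                    queue.append((nbr, dist + 1))
                else:
                    if l is None:
                        raise GenealogyError(
                            "branch lengths required for distances"
                        )
                    queue.append((nbr, dist + l))
    return labels, d


def patristic_distance_matrix(
    tree: Genealogy, labels: Sequence[str] | None = None
) -> tuple[tuple[str, ...], np.ndarray]:
    """All-pairs path-length matrix (branch-length weighted)."""
    return _distance_matrix(tree, labels, unit=False)


def topological_distance_matrix(
    tree: Genealogy, labels: Sequence[str] | None = None
) -> tuple[tuple[str, ...], np.ndarray]:
    """All-pairs path lengths counted in edges (integers).

    Zero-length branches still count as edges, so they resolve topology,
    matching the default treatment elsewhere in the package.
    """
    return _distance_matrix(tree, labels, unit=True)
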