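"""Taxon-topology enumeration and topology weighting of genealogies.

The weighting of a taxon topology tau for a genealogy is

    w_tau = K / N,

where N = prod_j s_j is the number of one-sample-per-taxon transversals
(s_j samples in taxon j) and K counts the transversals whose induced subtree
matches tau. Exact weighting iterates all N transversals (after collapsing
monophyletic same-taxon clades, which leaves the counts unchanged but can
shrink the iteration enormously); approximate weighting samples transversals
with replacement, so each count is binomial and carries a Wilson confidence
interval.
"""

from __future__ import annotations

import itertools
import warnings
from collections.abc import Iterable, Iterator, Sequence
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .treecore import (
    Bipartition,
    CollapsedGenealogy,
    Genealogy,
    GenealogyError,
    Node,
    TaxonMap,
    bipartitions,
    collapse_monophyletic,
    patristic_distance_matrix,
    topological_distance_matrix,
    write_newick,
)

__all__ = [
    "TaxonTopology",
    "WeightRecord",
    "WeightTrack",
    "Interval",
    "enumerate_taxon_topologies",
    "n_taxon_topologies",
    "count_sample_combinations",
    "match_topology",
    "weight_exact",
    "weight_fixed_sample",
    "weight_threshold",
    "binomial_ci",
    "topology_branch_distances",
    "weight_tree_stream",
    "write_weights",
    "read_weights",
    "write_topologies",
    "ExactWeightingError",
    "TopologyCountError",
]

#: Enumerating beyond this many taxa is refused unless explicitly overridden:
#: the catalog grows as (2n-5)!! (n=9 already gives 135,135 topologies).
MAX_ENUMERATED_TAXA = 8

#: Default ceiling on N for exact weighting; past this, sample instead.
MAX_EXACT_COMBINATIONS = 10_000_000


class TopologyCountError(GenealogyError):
    """Too many taxa for exhaustive topology enumeration."""


class ExactWeightingError(GenealogyError):
    """Too many sample combinations for exact weighting; sample instead."""


# ---------------------------------------------------------------------------
# Topology catalog


@dataclass(frozen=True)
class TaxonTopology:
    """One canonical unrooted bifurcating topology over the taxon labels."""

    id: str
    taxa: tuple[str, ...]
    splits: frozenset[Bipartition]
    newick: str


def n_taxon_topologies(n: int) -> int:
    """(2n-5)!! — the number of unrooted bifurcating topologies on n tips."""
    if n < 3:
        raise GenealogyError("need at least 3 taxa")
    out = 1
    for k in range(2 * n - 5, 1, -2):
        out *= k
    return out


def enumerate_taxon_topologies(
    taxa: Sequence[str],
    max_taxa: int = MAX_ENUMERATED_TAXA,
    allow_large: bool = False,
) -> list[TaxonTopology]:
    """All unrooted bifurcating topologies over ``taxa``, in a stable order.

    Trees are generated by adding taxa one at a time onto every existing
    edge, edges visited in preorder — the order is therefore fixed by the
    taxon order alone, so the ``topo1..topoK`` ids are reproducible.
    """
    taxa = tuple(taxa)
    n = len(taxa)
    if n < 3:
        raise GenealogyError("need at least 3 taxa")
    if len(set(taxa)) != n:
        raise GenealogyError("duplicate taxon names")
    if n > max_taxa and not allow_large:
        raise TopologyCountError(
            f"{n} taxa give {n_taxon_topologies(n)} topologies "
            f"((2n-5)!!); pass allow_large=True to enumerate anyway"
        )

    def base() -> Node:
        root = Node()
        for t in taxa[:3]:
            root.add(Node(t))
        return root

    def clone(node: Node) -> Node:
        new = Node(node.label)
        for c in node.children:
            new.add(clone(c))
        return new

    def edges_preorder(root: Node) -> list[Node]:
        out: list[Node] = []
        stack = list(reversed(root.children))
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(reversed(node.children))
        return out

    trees = [base()]
    for taxon in taxa[3:]:
        nxt: list[Node] = []
        for tree in trees:
            for k in range(len(edges_preorder(tree))):
                new_tree = clone(tree)
                target = edges_preorder(new_tree)[k]
                parent = target.parent
                mid = Node()
                parent.children[parent.children.index(target)] = mid
                mid.parent = parent
                mid.add(target)
                mid.add(Node(taxon))
                nxt.append(new_tree)
        trees = nxt

    catalog: list[TaxonTopology] = []
    for i, root in enumerate(trees, 1):
        g = Genealogy(root, validate=False)
        splits = bipartitions(g) if n >= 4 else frozenset()
        catalog.append(
            TaxonTopology(
                id=f"topo{i}",
                taxa=taxa,
                splits=splits,
                newick=write_newick(g, lengths=False),
            )
        )
    assert len(catalog) == n_taxon_topologies(n)
    assert len({t.splits for t in catalog}) == len(catalog)
    return catalog


def count_sample_combinations(taxa: TaxonMap) -> int:
    """N of the weighting definition: the product of taxon sample counts."""
    return taxa.n_combinations


def match_topology(
    subtree: Genealogy,
    taxa: TaxonMap,
    catalog: Sequence[TaxonTopology],
) -> TaxonTopology | None:
    """Identify a one-tip-per-taxon subtree in the catalog.

    Returns ``None`` for an unresolved subtree (a polytomy among >= 4 taxa).
    """
    tips = subtree.tip_labels
    tip_taxa = [taxa.taxon_of(t) for t in tips]
    if sorted(tip_taxa) != sorted(taxa.taxa):
        raise GenealogyError(
            "subtree tips must contain exactly one sample per taxon"
        )
    n = len(tip_taxa)
    if n == 3:
        return catalog[0]
    relabel = {t: taxa.taxon_of(t) for t in tips}
    splits = set()
    for bp in bipartitions(subtree):
        splits.add(
            Bipartition.make({relabel[x] for x in bp.block}, set(taxa.taxa))
        )
    if len(splits) < n - 3:
        return None
    for topo in catalog:
        if topo.splits == frozenset(splits):
            return topo
    raise GenealogyError("subtree matches no catalog topology")  # pragma: no cover


# ---------------------------------------------------------------------------
# Weight records


@dataclass
class WeightRecord:
    """Per-genealogy topology counts and normalized weights."""

    topologies: tuple[str, ...]
    counts: tuple[int, ...]
    unresolved: int
    evaluated: int
    n_combinations: int
    method: str
    seed: int | None = None
    level: float | None = None
    ci: tuple[tuple[float, float], ...] | None = None
    stop_reason: str | None = None

    def __post_init__(self) -> None:
        if sum(self.counts) + self.unresolved != self.evaluated:
            raise GenealogyError("counts + unresolved must equal evaluated")
        if self.evaluated > self.n_combinations and self.method == "exact":
            raise GenealogyError("evaluated exceeds N in exact mode")

    @property
    def weights(self) -> tuple[float, ...]:
        """w_i = K_i / evaluated (sums to 1 when nothing is unresolved)."""
        return tuple(k / self.evaluated for k in self.counts)

    def weight_of(self, topo_id: str) -> float:
        return self.weights[self.topologies.index(topo_id)]


@dataclass(frozen=True)
class Interval:
    """1-based inclusive genomic interval of a window (or simulated block)."""

    chrom: str
    start: int
    end: int

    @property
    def span(self) -> int:
        return self.end - self.start + 1


@dataclass
class WeightTrack:
    """An ordered sequence of weight records, optionally genome-anchored."""

    topologies: tuple[str, ...]
    rows: list[tuple[Interval | None, WeightRecord | None]] = field(
        default_factory=list
    )

    def append(self, interval: Interval | None, record: WeightRecord | None):
        if record is not None and record.topologies != self.topologies:
            raise GenealogyError("record topology ids do not match the track")
        self.rows.append((interval, record))

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def records(self) -> list[WeightRecord | None]:
        return [r for _, r in self.rows]


# ---------------------------------------------------------------------------
# Fast transversal classification
#
# Internally a transversal's topology is identified in one of two ways:
#
# * generic: the restricted nontrivial splits of the subtree, read off
#   precomputed per-tip root-path edge lists (each chosen tip ORs its taxon
#   bit into every edge on its root path; surviving signatures with 2..n-2
#   bits are the subtree's splits);
# * n <= 5 fast path: integer tip-to-tip path lengths (edge counts) and the
#   four-point condition — a taxon pair is a cherry-side split iff it wins
#   every quartet containing it, and for 4 or 5 taxa the cherry-pair set
#   determines the topology (for n >= 6 it does not, hence the generic path).
#
# The public `match_topology` is a separate, bipartition-based route; tests
# hold all routes in agreement.


class _Classifier:
    def __init__(
        self,
        tree: Genealogy,
        taxa: TaxonMap,
        catalog: Sequence[TaxonTopology],
    ):
        self.taxa = taxa
        self.n = taxa.n
        self.catalog = list(catalog)
        labels = tree.tip_labels
        if isinstance(tree, CollapsedGenealogy):
            taxon_of = tree.tip_taxon
            mult = tree.multiplicity
        else:
            taxon_of = {l: taxa.taxon_of(l) for l in labels}
            mult = {l: 1 for l in labels}
        self.labels, self.dist = topological_distance_matrix(tree)
        index = {l: i for i, l in enumerate(self.labels)}
        # per-taxon tip indices + multiplicities, taxon order fixed by the map
        self.tip_idx: list[np.ndarray] = []
        self.tip_mult: list[np.ndarray] = []
        for t in taxa.taxa:
            idx = [index[l] for l in self.labels if taxon_of[l] == t]
            if not idx:
                raise GenealogyError(f"taxon {t!r} has no tips in the tree")
            self.tip_idx.append(np.asarray(idx, dtype=np.intp))
            self.tip_mult.append(
                np.asarray([mult[self.labels[i]] for i in idx], dtype=np.int64)
            )
        self._build_edge_paths(tree)
        self._build_lookup()

    def _build_edge_paths(self, tree: Genealogy) -> None:
        """Per tip: the edge ids on its path to the storage root."""
        edge_id: dict[int, int] = {}
        paths: dict[str, list[int]] = {}
        next_id = 0
        for node in tree.postorder():
            if node.parent is not None:
                edge_id[id(node)] = next_id
                next_id += 1
        for label in self.labels:
            node = tree.tip(label)
            path = []
            while node.parent is not None:
                path.append(edge_id[id(node)])
                node = node.parent
            paths[label] = path
        self.n_edges = next_id
        self.tip_paths = [paths[l] for l in self.labels]

    def _build_lookup(self) -> None:
        n = self.n
        taxon_index = {t: i for i, t in enumerate(self.taxa.taxa)}
        full = (1 << n) - 1
        # generic: frozenset of canonical split masks -> catalog index
        self.split_lookup: dict[frozenset, int] = {}
        # n<=5: frozenset of cherry pairs -> catalog index
        self.cherry_lookup: dict[frozenset, int] = {}
        for ci, topo in enumerate(self.catalog):
            masks = set()
            pairs = set()
            for bp in topo.splits:
                for side in bp.sides:
                    if len(side) == 2:
                        pairs.add(frozenset(taxon_index[t] for t in side))
                mask = 0
                for t in bp.block:
                    mask |= 1 << taxon_index[t]
                if mask & 1:
                    mask ^= full
                masks.add(mask)
            self.split_lookup[frozenset(masks)] = ci
            self.cherry_lookup[frozenset(pairs)] = ci
        if n == 3:
            self.split_lookup[frozenset()] = 0
            self.cherry_lookup[frozenset()] = 0
        assert len(self.split_lookup) == len(self.catalog)
        if n <= 5:
            assert len(self.cherry_lookup) == len(self.catalog)

    def _quartet(self, d, a, b, c, e) -> int:
        """0: ab|ce, 1: ac|be, 2: ae|bc, -1: unresolved."""
        s0 = d[a, b] + d[c, e]
        s1 = d[a, c] + d[b, e]
        s2 = d[a, e] + d[b, c]
        m = min(s0, s1, s2)
        if (s0 == m) + (s1 == m) + (s2 == m) > 1:
            return -1
        return 0 if s0 == m else (1 if s1 == m else 2)

    def _classify_cherries(self, chosen: Sequence[int]) -> int:
        n = self.n
        d = self.dist
        pairs = set()
        for i, j in itertools.combinations(range(n), 2):
            others = [x for x in range(n) if x != i and x != j]
            is_cherry = True
            for k, l in itertools.combinations(others, 2):
                if (
                    self._quartet(d, chosen[i], chosen[j], chosen[k], chosen[l])
                    != 0
                ):
                    is_cherry = False
                    break
            if is_cherry:
                pairs.add(frozenset((i, j)))
        return self.cherry_lookup.get(frozenset(pairs), -1)

    def _classify_splits(self, chosen: Sequence[int]) -> int:
        n = self.n
        full = (1 << n) - 1
        acc: dict[int, int] = {}
        for ti, tip in enumerate(chosen):
            bit = 1 << ti
            for e in self.tip_paths[tip]:
                acc[e] = acc.get(e, 0) | bit
        sigs = set()
        for mask in acc.values():
            pc = mask.bit_count()
            if 2 <= pc <= n - 2:
                sigs.add(mask ^ full if mask & 1 else mask)
        if len(sigs) != n - 3:
            return -1
        return self.split_lookup.get(frozenset(sigs), -1)

    def classify(self, chosen: Sequence[int]) -> int:
        """Catalog index for one transversal (one tip index per taxon);
        -1 if the induced subtree is unresolved."""
        if self.n == 3:
            return 0
        if self.n <= 5:
            return self._classify_cherries(chosen)
        return self._classify_splits(chosen)

    # -- vectorized four-taxon path ---------------------------------------

    def classify_quartets(
        self, a: np.ndarray, b: np.ndarray, c: np.ndarray, e: np.ndarray
    ) -> np.ndarray:
        """Vectorized quartet classification (n must be 4).

        Returns catalog indices, -1 for unresolved, for broadcastable index
        arrays of chosen tips per taxon.
        """
        d = self.dist
        s0 = d[a, b] + d[c, e]
        s1 = d[a, c] + d[b, e]
        s2 = d[a, e] + d[b, c]
        m = np.minimum(np.minimum(s0, s1), s2)
        e0, e1, e2 = s0 == m, s1 == m, s2 == m
        ties = e0.astype(np.int8) + e1 + e2 > 1
        i01 = self.cherry_lookup[
            frozenset({frozenset((0, 1)), frozenset((2, 3))})
        ]
        i02 = self.cherry_lookup[
            frozenset({frozenset((0, 2)), frozenset((1, 3))})
        ]
        i03 = self.cherry_lookup[
            frozenset({frozenset((0, 3)), frozenset((1, 2))})
        ]
        out = np.where(e0, i01, np.where(e1, i02, i03)).astype(np.int64)
        out = np.broadcast_to(out, ties.shape).copy()
        out[ties] = -1
        return out


def _prepare(
    tree: Genealogy,
    taxa: TaxonMap,
    catalog: Sequence[TaxonTopology] | None,
    collapse: bool,
) -> tuple[_Classifier, list[TaxonTopology]]:
    tips = set(tree.tip_labels)
    mapped = set(taxa.assignment)
    if tips != mapped:
        missing = sorted(tips - mapped)
        extra = sorted(mapped - tips)
        raise GenealogyError(
            f"tree tips and taxon map disagree (unassigned tips: {missing}; "
            f"absent samples: {extra})"
        )
    if catalog is None:
        catalog = enumerate_taxon_topologies(taxa.taxa)
    work: Genealogy = collapse_monophyletic(tree, taxa) if collapse else tree
    return _Classifier(work, taxa, catalog), list(catalog)


def weight_exact(
    tree: Genealogy,
    taxa: TaxonMap,
    catalog: Sequence[TaxonTopology] | None = None,
    max_combinations: int = MAX_EXACT_COMBINATIONS,
    collapse: bool = True,
) -> WeightRecord:
    """Exact topology weighting: every one of the N transversals is counted.

    The tree is first collapsed (`collapse_monophyletic`), each collapsed
    transversal contributing the product of its tip multiplicities, which is
    exactly equivalent to iterating all N uncollapsed transversals.
    """
    N = taxa.n_combinations
    if N > max_combinations:
        raise ExactWeightingError(
            f"N = {N} sample combinations exceeds the exact-mode ceiling "
            f"({max_combinations}); use weight_fixed_sample or "
            f"weight_threshold instead"
        )
    clf, catalog = _prepare(tree, taxa, catalog, collapse)
    counts = np.zeros(len(catalog), dtype=np.int64)
    unresolved = 0

    if clf.n == 4:
        i0, i1, i2, i3 = clf.tip_idx
        m0, m1, m2, m3 = clf.tip_mult
        b = i1[:, None, None]
        c = i2[None, :, None]
        e = i3[None, None, :]
        rest_mult = (
            m1[:, None, None] * m2[None, :, None] * m3[None, None, :]
        )
        # chunk over the first taxon to bound grid memory
        for a_idx, a_mult in zip(i0, m0):
            topo = clf.classify_quartets(np.int64(a_idx), b, c, e)
            mult = int(a_mult) * rest_mult
            for ci in range(len(catalog)):
                counts[ci] += int(mult[topo == ci].sum())
            unresolved += int(mult[topo == -1].sum())
    else:
        for combo in itertools.product(
            *(range(len(idx)) for idx in clf.tip_idx)
        ):
            chosen = [int(clf.tip_idx[t][i]) for t, i in enumerate(combo)]
            w = 1
            for t, i in enumerate(combo):
                w *= int(clf.tip_mult[t][i])
            ci = clf.classify(chosen)
            if ci < 0:
                unresolved += w
            else:
                counts[ci] += w

    assert int(counts.sum()) + unresolved == N
    return WeightRecord(
        topologies=tuple(t.id for t in catalog),
        counts=tuple(int(k) for k in counts),
        unresolved=unresolved,
        evaluated=N,
        n_combinations=N,
        method="exact",
    )


def _sample_batch(
    clf: _Classifier, rng: np.random.Generator, iterations: int
) -> tuple[np.ndarray, int]:
    """Counts per topology (+unresolved) from ``iterations`` uniform draws."""
    n = clf.n
    chosen_cols = []
    for t in range(n):
        p = clf.tip_mult[t] / clf.tip_mult[t].sum()
        chosen_cols.append(rng.choice(clf.tip_idx[t], size=iterations, p=p))
    counts = np.zeros(len(clf.catalog), dtype=np.int64)
    unresolved = 0
    if n == 4:
        topo = clf.classify_quartets(*chosen_cols)
        for ci in range(len(clf.catalog)):
            counts[ci] = int((topo == ci).sum())
        unresolved = int((topo == -1).sum())
    else:
        chosen = np.stack(chosen_cols, axis=1)
        for row in chosen:
            ci = clf.classify([int(x) for x in row])
            if ci < 0:
                unresolved += 1
            else:
                counts[ci] += 1
    return counts, unresolved


def weight_fixed_sample(
    tree: Genealogy,
    taxa: TaxonMap,
    iterations: int,
    level: float = 0.95,
    seed: int | None = None,
    catalog: Sequence[TaxonTopology] | None = None,
    collapse: bool = True,
) -> WeightRecord:
    """Approximate weighting from ``iterations`` transversals drawn uniformly
    with replacement; per-topology Wilson confidence intervals attached."""
    if iterations < 1:
        raise GenealogyError("iterations must be >= 1")
    clf, catalog = _prepare(tree, taxa, catalog, collapse)
    rng = np.random.default_rng(seed)
    counts, unresolved = _sample_batch(clf, rng, iterations)
    ci = tuple(binomial_ci(int(k), iterations, level) for k in counts)
    return WeightRecord(
        topologies=tuple(t.id for t in catalog),
        counts=tuple(int(k) for k in counts),
        unresolved=unresolved,
        evaluated=iterations,
        n_combinations=taxa.n_combinations,
        method="fixed",
        seed=seed,
        level=level,
        ci=ci,
    )


def weight_threshold(
    tree: Genealogy,
    taxa: TaxonMap,
    max_ci_width: float,
    batch: int = 100,
    max_iterations: int = 10_000,
    level: float = 0.95,
    seed: int | None = None,
    catalog: Sequence[TaxonTopology] | None = None,
    collapse: bool = True,
) -> WeightRecord:
    """Sample in batches until every topology's CI is narrow enough.

    Highly sorted trees stop early (their intervals collapse fast); star-like
    trees run to ``max_iterations``. The stopping rule that fired is recorded
    in ``stop_reason``.
    """
    if not 0 < max_ci_width < 1:
        raise GenealogyError("max_ci_width must be in (0, 1)")
    if batch < 1:
        raise GenealogyError("batch must be >= 1")
    clf, catalog = _prepare(tree, taxa, catalog, collapse)
    rng = np.random.default_rng(seed)
    counts = np.zeros(len(catalog), dtype=np.int64)
    unresolved = 0
    evaluated = 0
    stop_reason = "max_iterations"
    while evaluated < max_iterations:
        step = min(batch, max_iterations - evaluated)
        c, u = _sample_batch(clf, rng, step)
        counts += c
        unresolved += u
        evaluated += step
        ci = [binomial_ci(int(k), evaluated, level) for k in counts]
        if all(hi - lo <= max_ci_width for lo, hi in ci):
            stop_reason = "ci_width"
            break
    ci = tuple(binomial_ci(int(k), evaluated, level) for k in counts)
    return WeightRecord(
        topologies=tuple(t.id for t in catalog),
        counts=tuple(int(k) for k in counts),
        unresolved=unresolved,
        evaluated=evaluated,
        n_combinations=taxa.n_combinations,
        method="threshold",
        seed=seed,
        level=level,
        ci=ci,
        stop_reason=stop_reason,
    )


def binomial_ci(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion.

    Chosen over the Wald interval because it stays sane at k = 0 and k = n,
    which threshold-based sampling probes constantly.
    """
    if not 0 <= k <= n or n < 1:
        raise GenealogyError("need 0 <= k <= n and n >= 1")
    z = norm.ppf(0.5 + level / 2)
    p = k / n
    denom = 1 + z * z / n
    center = (p + z * z / (2 * n)) / denom
    half = z * np.sqrt(p * (1 - p) / n + z * z / (4 * n * n)) / denom
    lo = 0.0 if k == 0 else max(0.0, float(center - half))
    hi = 1.0 if k == n else min(1.0, float(center + half))
    return (min(lo, p), max(hi, p))


# ---------------------------------------------------------------------------
# Branch-length diagnostics


def topology_branch_distances(
    tree: Genealogy,
    taxa: TaxonMap,
    method: str = "exact",
    iterations: int = 1000,
    seed: int | None = None,
    catalog: Sequence[TaxonTopology] | None = None,
    max_combinations: int = MAX_EXACT_COMBINATIONS,
):
    """Mean patristic distance between each taxon pair, per matched topology.

    Subtrees that cluster two taxa through recent introgression are separated
    by shorter branches than those reflecting the deeper species branching,
    so these means help tell the two apart. Unresolved transversals are
    excluded; topologies never matched get NaN means.

    Returns a dict ``topo_id -> {(taxonA, taxonB): mean_distance}``.
    """
    if not tree.has_branch_lengths:
        raise GenealogyError("branch lengths required for branch distances")
    if method not in {"exact", "sampled"}:
        raise GenealogyError("method must be 'exact' or 'sampled'")
    clf, catalog = _prepare(tree, taxa, catalog, collapse=False)
    labels, pdist = patristic_distance_matrix(tree)
    assert labels == clf.labels  # same label ordering as classifier indices
    n = taxa.n
    pair_list = list(itertools.combinations(range(n), 2))
    sums = np.zeros((len(catalog), len(pair_list)))
    hits = np.zeros(len(catalog), dtype=np.int64)

    def visit(chosen: list[int]) -> None:
        ci = clf.classify(chosen)
        if ci < 0:
            return
        hits[ci] += 1
        for pi, (a, b) in enumerate(pair_list):
            sums[ci, pi] += pdist[chosen[a], chosen[b]]

    if method == "exact":
        if taxa.n_combinations > max_combinations:
            raise ExactWeightingError(
                "too many combinations for exact branch distances; "
                "use method='sampled'"
            )
        for combo in itertools.product(*clf.tip_idx):
            visit([int(x) for x in combo])
    else:
        rng = np.random.default_rng(seed)
        for _ in range(iterations):
            visit([int(rng.choice(idx)) for idx in clf.tip_idx])

    out: dict[str, dict[tuple[str, str], float]] = {}
    for ci, topo in enumerate(catalog):
        entry: dict[tuple[str, str], float] = {}
        for pi, (a, b) in enumerate(pair_list):
            key = (taxa.taxa[a], taxa.taxa[b])
            entry[key] = (
                sums[ci, pi] / hits[ci] if hits[ci] > 0 else float("nan")
            )
        out[topo.id] = entry
    return out


# ---------------------------------------------------------------------------
# Streams and serialization


def weight_tree_stream(
    trees: Iterable[Genealogy | tuple[Genealogy | None, Interval | None] | None],
    taxa: TaxonMap,
    method: str = "exact",
    catalog: Sequence[TaxonTopology] | None = None,
    allow_missing: bool = False,
    **params,
) -> WeightTrack:
    """Weight every tree of a stream; malformed or missing entries become
    all-missing rows (with a warning) rather than aborting the run."""
    if catalog is None:
        catalog = enumerate_taxon_topologies(taxa.taxa)
    funcs = {
        "exact": weight_exact,
        "complete": weight_exact,
        "fixed": weight_fixed_sample,
        "threshold": weight_threshold,
    }
    try:
        fn = funcs[method]
    except KeyError:
        raise GenealogyError(f"unknown weighting method {method!r}") from None
    track = WeightTrack(topologies=tuple(t.id for t in catalog))
    for i, item in enumerate(trees):
        if isinstance(item, tuple):
            tree, interval = item
        else:
            tree, interval = item, None
        if tree is None:
            track.append(interval, None)
            continue
        try:
            tm = taxa
            if allow_missing:
                present = set(tree.tip_labels) & set(taxa.assignment)
                tm = taxa.restrict(present)
                if set(tree.tip_labels) - present:
                    tree = _prune_safe(tree, present)
            record = fn(tree, tm, catalog=catalog, **params)
        except GenealogyError as exc:
            warnings.warn(f"tree {i}: {exc}; emitting missing row")
            record = None
        track.append(interval, record)
    return track


def _prune_safe(tree: Genealogy, keep: set) -> Genealogy:
    from .treecore import prune_to_samples

    return prune_to_samples(tree, keep)


def write_topologies(catalog: Sequence[TaxonTopology], path) -> None:
    """The catalog as Newick, one per line, in id order."""
    with open(path, "w") as handle:
        for topo in catalog:
            handle.write(topo.newick + "\n")


def write_weights(
    track: WeightTrack,
    path,
    catalog: Sequence[TaxonTopology] | None = None,
    counts: bool = False,
    header_lines: Sequence[str] = (),
) -> None:
    """Write the tab-separated weights dialect.

    Comment lines ``#topoI <newick>`` describe the catalog; data columns are
    chrom/start/end, one column per topology (normalized weights by default,
    raw counts with ``counts=True``), plus unresolved/N/evaluated and, when
    present, per-topology ``_lo``/``_hi`` CI columns.
    """
    has_ci = any(r is not None and r.ci is not None for r in track.records)
    with open(path, "w") as handle:
        for line in header_lines:
            handle.write(f"#{line}\n")
        if catalog is not None:
            for topo in catalog:
                handle.write(f"#{topo.id} {topo.newick}\n")
        cols = ["chrom", "start", "end", *track.topologies]
        cols += ["unresolved", "N", "evaluated"]
        if has_ci:
            for t in track.topologies:
                cols += [f"{t}_lo", f"{t}_hi"]
        handle.write("\t".join(cols) + "\n")
        for interval, rec in track.rows:
            loc = (
                [interval.chrom, str(interval.start), str(interval.end)]
                if interval is not None
                else [".", ".", "."]
            )
            if rec is None:
                row = loc + ["NA"] * (len(cols) - 3)
            else:
                vals = (
                    [str(k) for k in rec.counts]
                    if counts
                    else [f"{w:.6g}" for w in rec.weights]
                )
                row = loc + vals + [
                    str(rec.unresolved),
                    str(rec.n_combinations),
                    str(rec.evaluated),
                ]
                if has_ci:
                    if rec.ci is None:
                        row += ["NA"] * (2 * len(track.topologies))
                    else:
                        for lo, hi in rec.ci:
                            row += [f"{lo:.6g}", f"{hi:.6g}"]
            handle.write("\t".join(row) + "\n")


def read_weights(path):
    """Read the weights TSV back: (topology newicks by id, pandas frame)."""
    import pandas as pd

    topo_newicks: dict[str, str] = {}
    header: list[str] | None = None
    rows: list[list[str]] = []
    from .treecore import _open_text

    with _open_text(path) as handle:
        for line in handle:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:]
                parts = body.split(" ", 1)
                if (
                    len(parts) == 2
                    and parts[0].startswith("topo")
                    and parts[0][4:].isdigit()
                ):
                    topo_newicks[parts[0]] = parts[1]
                continue
            if header is None:
                header = line.split("\t")
            else:
                rows.append(line.split("\t"))
    if header is None:
        raise GenealogyError(f"{path}: no data header")
    frame = pd.DataFrame(rows, columns=header)
    for col in frame.columns:
        if col not in {"chrom"}:
            frame[col] = pd.to_numeric(frame[col], errors="coerce")
    return topo_newicks, frame


def track_from_frame(frame, topologies: Sequence[str]) -> WeightTrack:
    """Rebuild a WeightTrack (weights only) from a read_weights frame."""
    track = WeightTrack(topologies=tuple(topologies))
    for _, row in frame.iterrows():
        interval = None
        if isinstance(row.get("chrom"), str) and row["chrom"] != ".":
            interval = Interval(
                row["chrom"], int(row["start"]), int(row["end"])
            )
        if any(np.isnan(float(row[t])) for t in topologies):
            track.append(interval, None)
            continue
        evaluated = int(row["evaluated"]) if "evaluated" in row else 10**9
        counts = [int(round(float(row[t]) * evaluated)) for t in topologies]
        unresolved = evaluated - sum(counts)
        record = WeightRecord(
            topologies=tuple(topologies),
            counts=tuple(counts),
            unresolved=unresolved,
            evaluated=evaluated,
            n_combinations=int(row["N"]) if "N" in row else evaluated,
            method="loaded",
        )
        track.append(interval, record)
    return track
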