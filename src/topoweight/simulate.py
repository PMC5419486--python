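"""Neutral structured-coalescent simulation and infinite-sites mutation.

Time runs backward in units of 4N generations with constant deme sizes:
within a deme holding k lineages, coalescence occurs at total rate k(k-1)
(so a pair has mean coalescence time 0.5); a lineage in a migration-
receiving deme jumps (backward) into the source deme at per-lineage rate
4Nm; at a split time all lineages of the derived deme move into the
ancestral deme. Recombination is not simulated: chromosome-scale averages
are reproduced as means over independent loci, whose marginal genealogy
distribution is the same.

The mutation engine drops exactly ``n_snps`` biallelic infinite-sites
variants on a genealogy, each on a branch drawn with probability
proportional to its length, producing the same genotype-matrix shape the
window pipeline consumes for real data.
"""

from __future__ import annotations

from collections.abc import Iterator, Sequence
from dataclasses import dataclass

import numpy as np

from .treecore import Genealogy, GenealogyError, Node, TaxonMap
from .weighting import weight_exact
from .windows import GenotypeWindow, Site, is_taxon_informative

__all__ = [
    "SplitEvent",
    "MigrationRoute",
    "DemographyModel",
    "preset_models",
    "power_model",
    "simulate_genealogy",
    "simulate_replicates",
    "iter_replicates",
    "mutate_sequences",
    "run_power_analysis",
]

#: Backward-time per-lineage migration rate per unit of forward rate 4Nm,
#: with time measured in 4N generations. Isolated here because simulators
#: differ by factors of two in migration conventions; validated against the
#: analytic no-migration ILS limit and the neutral-scenario asymmetry.
MIGRATION_RATE_SCALE = 1.0

_BASES = np.array(["A", "C", "G", "T"])


@dataclass(frozen=True)
class SplitEvent:
    """Backward in time, deme ``derived`` merges into ``ancestral``."""

    time: float
    derived: str
    ancestral: str


@dataclass(frozen=True)
class MigrationRoute:
    """Forward-time migration ``source -> recipient`` at rate 4Nm.

    Backward in time, lineages in ``recipient`` move to ``source`` at
    per-lineage rate ``rate`` (x :data:`MIGRATION_RATE_SCALE`), while both
    demes exist.
    """

    recipient: str
    source: str
    rate: float


@dataclass(frozen=True)
class DemographyModel:
    """Constant-size demes related by a tree of split events."""

    name: str
    demes: tuple[str, ...]
    samples: tuple[int, ...]
    splits: tuple[SplitEvent, ...]
    migrations: tuple[MigrationRoute, ...] = ()

    def __post_init__(self) -> None:
        if len(self.demes) != len(self.samples):
            raise GenealogyError("one sample count per deme required")
        if any(s < 1 for s in self.samples):
            raise GenealogyError("every deme needs at least one sample")
        if any(ev.time <= 0 for ev in self.splits):
            raise GenealogyError("split times must be positive")
        derived = [ev.derived for ev in self.splits]
        if len(set(derived)) != len(derived):
            raise GenealogyError("each deme may merge at most once")
        if len(self.splits) != len(self.demes) - 1:
            raise GenealogyError("splits must join all demes into one root")
        if any(m.rate < 0 for m in self.migrations):
            raise GenealogyError("migration rates must be nonnegative")
        # every migration route must be between demes that coexist at time 0
        names = set(self.demes)
        for m in self.migrations:
            if m.recipient not in names or m.source not in names:
                raise GenealogyError(f"unknown deme in migration route {m}")

    @property
    def n_samples(self) -> int:
        return sum(self.samples)

    def sample_labels(self) -> list[str]:
        out = []
        for deme, k in zip(self.demes, self.samples):
            out.extend(f"{deme}_{i + 1}" for i in range(k))
        return out

    def taxon_map(self) -> TaxonMap:
        assignment = {}
        for deme, k in zip(self.demes, self.samples):
            for i in range(k):
                assignment[f"{deme}_{i + 1}"] = deme
        return TaxonMap(assignment, taxa=self.demes)

    def end_time(self, deme: str) -> float:
        """Split time at which ``deme`` stops existing (inf for the root)."""
        for ev in self.splits:
            if ev.derived == deme:
                return ev.time
        return float("inf")


# ---------------------------------------------------------------------------
# Preset demographies


def preset_models() -> dict[str, DemographyModel]:
    """The named study demographies.

    ``neutral4``: taxa A,B,C,D (10 samples each) splitting in the order
    {[(A,B),C],D} at 0.5/1.0/1.5 x 4N generations, with forward migration
    C->B at 4Nm = 0.1. ``neutral5``: {[(A,B),(C,D)],E} with six samples per
    taxon and the same split times and migration. ``power-...``: the
    power-analysis designs (no migration), four or five populations with
    4/5/6/10 sequences each, basal split t1 at 0.5 or 1.0, terminal splits
    at t2 = 0.1 (five-population intermediate split t1b = 0.2).
    """
    models: dict[str, DemographyModel] = {}
    models["neutral4"] = DemographyModel(
        name="neutral4",
        demes=("A", "B", "C", "D"),
        samples=(10, 10, 10, 10),
        splits=(
            SplitEvent(0.5, "B", "A"),
            SplitEvent(1.0, "C", "A"),
            SplitEvent(1.5, "D", "A"),
        ),
        migrations=(MigrationRoute(recipient="B", source="C", rate=0.1),),
    )
    models["neutral5"] = DemographyModel(
        name="neutral5",
        demes=("A", "B", "C", "D", "E"),
        samples=(6, 6, 6, 6, 6),
        splits=(
            SplitEvent(0.5, "B", "A"),
            SplitEvent(0.5, "D", "C"),
            SplitEvent(1.0, "C", "A"),
            SplitEvent(1.5, "E", "A"),
        ),
        migrations=(MigrationRoute(recipient="B", source="C", rate=0.1),),
    )
    for n_pops in (4, 5):
        for n_seqs in (4, 5, 6, 10):
            for t1 in (0.5, 1.0):
                m = power_model(n_pops, n_seqs, t1)
                models[m.name] = m
    return models


def power_model(
    n_pops: int,
    n_seqs: int,
    t1: float,
    t2: float = 0.1,
    t1b: float = 0.2,
) -> DemographyModel:
    """A power-analysis design: populations split [(1,2),(3,4)] (plus an
    outgroup population 5 in the five-population case), no migration."""
    if n_pops not in (4, 5):
        raise GenealogyError("power designs have 4 or 5 populations")
    name = f"power-{n_pops}pop-{n_seqs}seq-t1_{t1:g}"
    demes = tuple(f"P{i + 1}" for i in range(n_pops))
    splits = [
        SplitEvent(t2, "P2", "P1"),
        SplitEvent(t2, "P4", "P3"),
    ]
    if n_pops == 4:
        splits.append(SplitEvent(t1, "P3", "P1"))
    else:
        splits.append(SplitEvent(t1b, "P3", "P1"))
        splits.append(SplitEvent(t1, "P5", "P1"))
    return DemographyModel(
        name=name,
        demes=demes,
        samples=(n_seqs,) * n_pops,
        splits=tuple(splits),
    )


# ---------------------------------------------------------------------------
# Structured-coalescent event loop


def simulate_genealogy(
    model: DemographyModel, seed: int | np.random.Generator | None = None
) -> Genealogy:
    """One genealogy over all samples, branch lengths in 4N generations."""
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    pools: dict[str, list[Node]] = {}
    height: dict[int, float] = {}
    for deme, k in zip(model.demes, model.samples):
        pools[deme] = []
        for i in range(k):
            node = Node(f"{deme}_{i + 1}")
            pools[deme].append(node)
            height[id(node)] = 0.0
    pending = sorted(model.splits, key=lambda ev: ev.time)
    split_i = 0
    t = 0.0
    alive = set(model.demes)

    def route_active(route: MigrationRoute) -> bool:
        return route.recipient in alive and route.source in alive

    while True:
        n_lineages = sum(len(p) for p in pools.values())
        if n_lineages == 1 and split_i >= len(pending):
            break
        events: list[tuple[float, str, object]] = []
        for deme in model.demes:
            if deme in alive:
                k = len(pools[deme])
                if k >= 2:
                    events.append((k * (k - 1), "coal", deme))
        for route in model.migrations:
            if route_active(route) and route.rate > 0:
                k = len(pools[route.recipient])
                if k >= 1:
                    events.append(
                        (k * route.rate * MIGRATION_RATE_SCALE, "mig", route)
                    )
        total = sum(r for r, _, _ in events)
        next_split = pending[split_i].time if split_i < len(pending) else np.inf
        if total > 0:
            wait = rng.exponential(1.0 / total)
        else:
            wait = np.inf
        if t + wait >= next_split:
            ev = pending[split_i]
            split_i += 1
            t = ev.time
            pools[ev.ancestral].extend(pools[ev.derived])
            pools[ev.derived] = []
            alive.discard(ev.derived)
            continue
        t += wait
        pick = rng.random() * total
        acc = 0.0
        kind, payload = events[-1][1], events[-1][2]
        for rate, ekind, epayload in events:
            acc += rate
            if pick < acc:
                kind, payload = ekind, epayload
                break
        if kind == "coal":
            pool = pools[payload]  # type: ignore[index]
            i = int(rng.integers(len(pool)))
            j = int(rng.integers(len(pool) - 1))
            if j >= i:
                j += 1
            a, b = pool[i], pool[j]
            parent = Node()
            a.length = t - height[id(a)]
            b.length = t - height[id(b)]
            parent.add(a)
            parent.add(b)
            height[id(parent)] = t
            pools[payload] = [x for x in pool if x is not a and x is not b]
            pools[payload].append(parent)
        else:
            route = payload  # type: ignore[assignment]
            pool = pools[route.recipient]
            i = int(rng.integers(len(pool)))
            lineage = pool.pop(i)
            pools[route.source].append(lineage)

    root = next(p[0] for p in pools.values() if p)
    root.length = None
    return Genealogy(root, validate=False)


def iter_replicates(
    model: DemographyModel, n_loci: int, seed: int | None = None
) -> Iterator[Genealogy]:
    """Independent genealogies, reproducible given ``seed`` (streaming)."""
    if n_loci < 1:
        raise GenealogyError("n_loci must be >= 1")
    rng = np.random.default_rng(seed)
    for _ in range(n_loci):
        yield simulate_genealogy(model, rng)


def simulate_replicates(
    model: DemographyModel, n_loci: int, seed: int | None = None
) -> list[Genealogy]:
    return list(iter_replicates(model, n_loci, seed))


# ---------------------------------------------------------------------------
# Mutation engine


def mutate_sequences(
    tree: Genealogy,
    n_snps: int,
    seed: int | np.random.Generator | None = None,
    chrom: str = "sim",
    start_pos: int = 1,
) -> GenotypeWindow:
    """Exactly ``n_snps`` biallelic infinite-sites variants on a genealogy.

    Each variant falls on a branch with probability proportional to branch
    length; carriers of the derived allele are the tips below that branch.
    Positions are assigned consecutively from ``start_pos``.
    """
    if n_snps < 1:
        raise GenealogyError("n_snps must be >= 1")
    labels = tree.tip_labels
    index = {l: i for i, l in enumerate(labels)}
    edges: list[tuple[np.ndarray, float]] = []
    below: dict[int, list[str]] = {}
    for node in tree.postorder():
        if node.is_tip:
            below[id(node)] = [node.label]
        else:
            below[id(node)] = [
                l for c in node.children for l in below[id(c)]
            ]
        if node.parent is not None:
            if node.length is None:
                raise GenealogyError("branch lengths required for mutation")
            carriers = np.array([index[l] for l in below[id(node)]])
            edges.append((carriers, node.length))
    total = sum(l for _, l in edges)
    if total <= 0:
        raise GenealogyError("tree has zero total branch length")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    probs = np.array([l for _, l in edges]) / total
    chosen = rng.choice(len(edges), size=n_snps, p=probs)
    alleles = np.empty((len(labels), n_snps), dtype="U1")
    for j, e in enumerate(chosen):
        anc, der = _BASES[rng.choice(4, size=2, replace=False)]
        alleles[:, j] = anc
        alleles[edges[e][0], j] = der
    return GenotypeWindow(
        chrom=chrom,
        positions=np.arange(start_pos, start_pos + n_snps),
        haplotypes=labels,
        alleles=alleles,
    )


# ---------------------------------------------------------------------------
# Power analysis


def run_power_analysis(
    designs: Sequence[DemographyModel],
    snp_counts: Sequence[int],
    replicates: int,
    tis_mode: bool = False,
    seed: int | None = None,
):
    """Accuracy of sequence-inferred weightings versus the true weightings.

    For each replicate genealogy the true weightings are computed exactly;
    an infinite-sites alignment is generated and truncated to each SNP count
    (taxon-informative sites only under ``tis_mode``); a neighbor-joining
    tree built from p-distances yields inferred weightings; the two are
    compared with the scaled weighting distance. Returns a pandas frame with
    one row per (design, snp_count): mean/sd distance and accuracy
    = 1 - mean distance.
    """
    import pandas as pd

    from .evaluate import weighting_distance
    from .windows import nj_tree, p_distance_matrix

    if replicates < 1:
        raise GenealogyError("replicates must be >= 1")
    snp_counts = sorted(snp_counts)
    top = snp_counts[-1]
    rows = []
    rng = np.random.default_rng(seed)
    for model in designs:
        taxa = model.taxon_map()
        hap_taxa = [taxa.taxon_of(l) for l in model.sample_labels()]
        dists: dict[int, list[float]] = {k: [] for k in snp_counts}
        for _ in range(replicates):
            tree = simulate_genealogy(model, rng)
            true_rec = weight_exact(tree, taxa)
            window = _simulated_window(
                tree, top, rng, taxa, tis_mode=tis_mode
            )
            for k in snp_counts:
                sub = GenotypeWindow(
                    chrom=window.chrom,
                    positions=window.positions[:k],
                    haplotypes=window.haplotypes,
                    alleles=window.alleles[:, :k],
                )
                inferred = nj_tree(p_distance_matrix(sub))
                est = weight_exact(inferred, taxa)
                dists[k].append(
                    weighting_distance(true_rec.weights, est.weights)
                )
        for k in snp_counts:
            arr = np.asarray(dists[k])
            rows.append(
                {
                    "design": model.name,
                    "n_snps": k,
                    "replicates": replicates,
                    "tis_mode": tis_mode,
                    "mean_distance": arr.mean(),
                    "sd_distance": arr.std(ddof=1) if len(arr) > 1 else 0.0,
                    "accuracy": 1.0 - arr.mean(),
                }
            )
    return pd.DataFrame(rows)


def _simulated_window(
    tree: Genealogy,
    n_snps: int,
    rng: np.random.Generator,
    taxa: TaxonMap,
    tis_mode: bool,
) -> GenotypeWindow:
    """A window holding ``n_snps`` usable sites (TIS-filtered if asked)."""
    if not tis_mode:
        return mutate_sequences(tree, n_snps, rng)
    hap_taxa: list[str] | None = None
    kept_cols: list[np.ndarray] = []
    kept = 0
    while kept < n_snps:
        window = mutate_sequences(tree, 2 * n_snps, rng)
        if hap_taxa is None:
            hap_taxa = [taxa.taxon_of(l) for l in window.haplotypes]
        for j in range(window.n_snps):
            site = Site(window.chrom, int(window.positions[j]),
                        tuple(window.alleles[:, j]))
            if is_taxon_informative(site, hap_taxa):
                kept_cols.append(window.alleles[:, j])
                kept += 1
                if kept == n_snps:
                    break
        labels = window.haplotypes
    return GenotypeWindow(
        chrom="sim",
        positions=np.arange(1, n_snps + 1),
        haplotypes=labels,
        alleles=np.stack(kept_cols, axis=1),
    )
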