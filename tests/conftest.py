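"""Shared fixtures: random genealogies and a brute-force weighting oracle."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from topoweight.simulate import DemographyModel, SplitEvent, simulate_genealogy
from topoweight.treecore import Genealogy, TaxonMap, prune_to_samples
from topoweight.weighting import TaxonTopology, match_topology


def single_deme_model(n_tips: int) -> DemographyModel:
    """A panmictic stand-in: one deme, so trees are unstructured coalescents."""
    return DemographyModel(
        name="panmictic",
        demes=("X",),
        samples=(n_tips,),
        splits=(),
    )


def random_coalescent(n_tips: int, rng: np.random.Generator) -> Genealogy:
    """An unstructured random coalescent genealogy on ``n_tips`` tips."""
    return simulate_genealogy(single_deme_model(n_tips), rng)


def random_taxon_map(
    labels, n_taxa: int, rng: np.random.Generator, taxa_names=None
) -> TaxonMap:
    """Assign tips to taxa at random (every taxon nonempty)."""
    taxa_names = taxa_names or [f"T{i + 1}" for i in range(n_taxa)]
    labels = list(labels)
    while True:
        assignment = {l: taxa_names[int(rng.integers(n_taxa))] for l in labels}
        if len(set(assignment.values())) == n_taxa:
            return TaxonMap(assignment, taxa=taxa_names)


def brute_force_weights(
    tree: Genealogy,
    taxa: TaxonMap,
    catalog: list[TaxonTopology],
) -> tuple[list[int], int]:
    """Independent oracle: explicitly prune every one of the N transversals
    and match it by bipartition comparison. Returns (counts, unresolved)."""
    counts = [0] * len(catalog)
    unresolved = 0
    pools = [taxa.samples(t) for t in taxa.taxa]
    for combo in itertools.product(*pools):
        sub = prune_to_samples(tree, set(combo))
        topo = match_topology(sub, taxa, catalog)
        if topo is None:
            unresolved += 1
        else:
            counts[catalog.index(topo)] += 1
    return counts, unresolved


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)
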