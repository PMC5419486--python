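"""Per-window genealogies from SNP genotype matrices.

The protocol: cut each chromosome into nonoverlapping windows of a fixed
number of SNPs, reject windows where any haplotype is genotyped at too few
sites, build a p-distance matrix over haplotypes, and infer a neighbor-
joining tree per window. SNP bootstrap (resampling window columns with
replacement) gives per-topology confidence quantiles.
"""

from __future__ import annotations

import warnings
from collections.abc import Iterable, Iterator, Sequence
from dataclasses import dataclass

import numpy as np

from .treecore import Genealogy, GenealogyError, TaxonMap, parse_newick, _open_text
from .weighting import (
    Interval,
    TaxonTopology,
    WeightRecord,
    weight_exact,
    weight_fixed_sample,
    weight_threshold,
)

__all__ = [
    "Site",
    "GenotypeWindow",
    "DistanceMatrix",
    "GenoFormatError",
    "read_geno",
    "write_geno",
    "snp_windows",
    "is_taxon_informative",
    "p_distance_matrix",
    "nj_tree",
    "window_weights",
    "bootstrap_window_weights",
    "BootstrapSummary",
]

MISSING = "N"
_MISSING_CODES = {"N", "n", ".", "-"}


class GenoFormatError(GenealogyError):
    """Malformed genotype file; messages carry the line number."""


@dataclass(frozen=True)
class Site:
    """One SNP: chromosome, 1-based position, one call per haplotype."""

    chrom: str
    pos: int
    calls: tuple[str, ...]


@dataclass
class GenotypeWindow:
    """A block of consecutive SNPs for all haplotypes.

    ``alleles`` is a haplotypes x positions matrix of single bases, with
    ``"N"`` marking missing calls.
    """

    chrom: str
    positions: np.ndarray
    haplotypes: tuple[str, ...]
    alleles: np.ndarray
    rejected: bool = False

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.alleles = np.asarray(self.alleles, dtype="U1")
        if self.alleles.shape != (len(self.haplotypes), len(self.positions)):
            raise GenealogyError("allele matrix shape mismatch")
        if len(self.positions) > 1 and not np.all(np.diff(self.positions) > 0):
            raise GenealogyError("positions must be strictly increasing")

    @property
    def n_snps(self) -> int:
        return len(self.positions)

    @property
    def interval(self) -> Interval:
        return Interval(self.chrom, int(self.positions[0]), int(self.positions[-1]))

    def calls_per_haplotype(self) -> np.ndarray:
        return (self.alleles != MISSING).sum(axis=1)

    def resample_columns(self, rng: np.random.Generator) -> "GenotypeWindow":
        """Bootstrap replicate: columns drawn with replacement, same count."""
        idx = np.sort(rng.integers(0, self.n_snps, size=self.n_snps))
        return GenotypeWindow(
            chrom=self.chrom,
            positions=np.arange(1, self.n_snps + 1),
            haplotypes=self.haplotypes,
            alleles=self.alleles[:, idx],
            rejected=self.rejected,
        )


@dataclass
class DistanceMatrix:
    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        k = len(self.labels)
        if self.values.shape != (k, k):
            raise GenealogyError("distance matrix shape mismatch")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise GenealogyError("distance matrix is not symmetric")
        if np.any(np.abs(np.diag(self.values)) > 1e-12):
            raise GenealogyError("distance matrix diagonal must be zero")
        if np.any(self.values < 0):
            raise GenealogyError("distances must be nonnegative")


# ---------------------------------------------------------------------------
# Geno file I/O


def _parse_call(raw: str, phase_policy: str, rng, warned: list) -> tuple[str, ...]:
    if "|" in raw:
        a, b = raw.split("|", 1)
        return (_clean_base(a), _clean_base(b))
    if "/" in raw:
        a, b = raw.split("/", 1)
        if phase_policy == "random":
            pair = [_clean_base(a), _clean_base(b)]
            if rng.random() < 0.5:
                pair.reverse()
            return tuple(pair)
        if not warned:
            warnings.warn(
                "unphased heterozygote calls set to missing "
                "(phase_policy='missing')"
            )
            warned.append(True)
        return (MISSING, MISSING)
    return (_clean_base(raw),)


def _clean_base(raw: str) -> str:
    raw = raw.strip()
    if raw in _MISSING_CODES or not raw:
        return MISSING
    return raw.upper()


def read_geno(
    path, phase_policy: str = "missing", seed: int | None = None
) -> tuple[list[str], Iterator[Site]]:
    """Read a tab-separated genotype file.

    Header ``#CHROM POS sample...``; calls are single bases (haploid) or
    phased pairs ``X|Y`` (diploid sample X becomes haplotypes X_A and X_B).
    Unphased ``X/Y`` calls become missing under the default policy (phase
    errors mimic introgression, the costlier failure), or are randomly
    phased with ``phase_policy='random'``.

    Returns ``(haplotype_labels, site_iterator)``; the iterator raises
    :class:`GenoFormatError` with a line number on malformed rows.
    """
    if phase_policy not in {"missing", "random"}:
        raise GenealogyError("phase_policy must be 'missing' or 'random'")
    handle = _open_text(path)
    header = handle.readline()
    if not header.startswith("#"):
        raise GenoFormatError(f"{path}:1: missing '#CHROM POS ...' header")
    fields = header.lstrip("#").split()
    if len(fields) < 3 or fields[0].upper() != "CHROM" or fields[1].upper() != "POS":
        raise GenoFormatError(f"{path}:1: header must be '#CHROM POS sample...'")
    samples = fields[2:]
    # peek the first data row to fix the per-sample ploidy
    first_line = handle.readline()
    if not first_line.strip():
        handle.close()
        return [], iter(())
    first_parts = first_line.split()
    if len(first_parts) != len(samples) + 2:
        raise GenoFormatError(f"{path}:2: ragged row ({len(first_parts)} fields)")
    ploidy = [2 if ("|" in c or "/" in c) else 1 for c in first_parts[2:]]
    haplotypes: list[str] = []
    for s, p in zip(samples, ploidy):
        haplotypes.extend([s] if p == 1 else [f"{s}_A", f"{s}_B"])
    rng = np.random.default_rng(seed)
    warned: list = []

    def gen() -> Iterator[Site]:
        try:
            yield _make_site(first_line, 2)
            for lineno, line in enumerate(handle, 3):
                if not line.strip():
                    continue
                yield _make_site(line, lineno)
        finally:
            handle.close()

    def _make_site(line: str, lineno: int) -> Site:
        parts = line.split()
        if len(parts) != len(samples) + 2:
            raise GenoFormatError(
                f"{path}:{lineno}: ragged row ({len(parts)} fields, "
                f"expected {len(samples) + 2})"
            )
        chrom = parts[0]
        try:
            pos = int(parts[1])
        except ValueError:
            raise GenoFormatError(
                f"{path}:{lineno}: non-numeric POS {parts[1]!r}"
            ) from None
        calls: list[str] = []
        for raw, p in zip(parts[2:], ploidy):
            got = _parse_call(raw, phase_policy, rng, warned)
            if len(got) != p:
                raise GenoFormatError(
                    f"{path}:{lineno}: inconsistent ploidy for call {raw!r}"
                )
            calls.extend(got)
        return Site(chrom, pos, tuple(calls))

    def checked() -> Iterator[Site]:
        last_chrom: str | None = None
        last_pos = -1
        for site in gen():
            if site.chrom == last_chrom and site.pos <= last_pos:
                raise GenoFormatError(
                    f"{path}: unsorted positions on {site.chrom} "
                    f"({site.pos} after {last_pos})"
                )
            last_chrom, last_pos = site.chrom, site.pos
            yield site

    return haplotypes, checked()


def write_geno(path, haplotypes: Sequence[str], sites: Iterable[Site]) -> None:
    """Write haploid-coded geno TSV (one column per haplotype)."""
    with open(path, "w") as handle:
        handle.write("#CHROM\tPOS\t" + "\t".join(haplotypes) + "\n")
        for site in sites:
            handle.write(
                f"{site.chrom}\t{site.pos}\t" + "\t".join(site.calls) + "\n"
            )


def sites_of_window(window: GenotypeWindow) -> Iterator[Site]:
    for j, pos in enumerate(window.positions):
        yield Site(window.chrom, int(pos), tuple(window.alleles[:, j]))


# ---------------------------------------------------------------------------
# Windows


def snp_windows(
    sites: Iterable[Site],
    size: int,
    min_calls: int = 0,
    haplotypes: Sequence[str] | None = None,
) -> Iterator[GenotypeWindow]:
    """Cut a site stream into nonoverlapping fixed-SNP windows per chromosome.

    Trailing partial windows are dropped so rows stay comparable. Windows in
    which any haplotype has fewer than ``min_calls`` genotyped sites are
    emitted with ``rejected=True`` (their weights become missing downstream).
    """
    if size < 1:
        raise GenealogyError("window size must be >= 1")
    if not 0 <= min_calls <= size:
        raise GenealogyError("min_calls must be between 0 and size")
    buffer: list[Site] = []
    current: str | None = None
    for site in sites:
        if current is not None and site.chrom != current:
            buffer = []
        current = site.chrom
        buffer.append(site)
        if len(buffer) == size:
            yield _finish_window(buffer, min_calls, haplotypes)
            buffer = []


def _finish_window(
    buffer: list[Site], min_calls: int, haplotypes: Sequence[str] | None
) -> GenotypeWindow:
    n_hap = len(buffer[0].calls)
    labels = (
        tuple(haplotypes)
        if haplotypes is not None
        else tuple(f"hap{i + 1}" for i in range(n_hap))
    )
    alleles = np.array([s.calls for s in buffer], dtype="U1").T
    window = GenotypeWindow(
        chrom=buffer[0].chrom,
        positions=np.array([s.pos for s in buffer]),
        haplotypes=labels,
        alleles=alleles,
    )
    if min_calls > 0:
        window.rejected = bool((window.calls_per_haplotype() < min_calls).any())
    return window


def is_taxon_informative(
    site: Site,
    hap_taxa: Sequence[str],
    mode: str = "strict",
) -> bool:
    """Is a SNP informative about inter-taxon relationships?

    ``strict`` (default): at least two distinct alleles, each observed in at
    least two distinct taxa. ``lax``: at least two distinct alleles whose
    carriers jointly span at least two taxa. The strict reading discards
    fixed inter-taxon differences, which resolve no taxon *topology* beyond
    separating two taxa.
    """
    if mode not in {"strict", "lax"}:
        raise GenealogyError("mode must be 'strict' or 'lax'")
    taxa_by_allele: dict[str, set[str]] = {}
    for call, taxon in zip(site.calls, hap_taxa):
        if call != MISSING:
            taxa_by_allele.setdefault(call, set()).add(taxon)
    if len(taxa_by_allele) < 2:
        return False
    if mode == "lax":
        spanned = set().union(*taxa_by_allele.values())
        return len(spanned) >= 2
    widespread = [a for a, ts in taxa_by_allele.items() if len(ts) >= 2]
    return len(widespread) >= 2


# ---------------------------------------------------------------------------
# Distances and trees


def p_distance_matrix(window: GenotypeWindow) -> DistanceMatrix:
    """Pairwise mismatch proportions over sites called in both haplotypes."""
    if len(window.haplotypes) < 4:
        raise GenealogyError("need at least 4 haplotypes")
    alleles = window.alleles
    called = alleles != MISSING
    k = alleles.shape[0]
    d = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            both = called[i] & called[j]
            shared = int(both.sum())
            if shared == 0:
                raise GenealogyError(
                    f"haplotypes {window.haplotypes[i]!r} and "
                    f"{window.haplotypes[j]!r} share no called sites"
                )
            mism = int((alleles[i][both] != alleles[j][both]).sum())
            d[i, j] = d[j, i] = mism / shared
    return DistanceMatrix(labels=window.haplotypes, values=d)


def jukes_cantor(d: DistanceMatrix) -> DistanceMatrix:
    """JC69-corrected distances (monotone in p; optional, default off)."""
    p = np.minimum(d.values, 0.74999)
    vals = -0.75 * np.log1p(-4.0 * p / 3.0)
    np.fill_diagonal(vals, 0.0)
    return DistanceMatrix(labels=d.labels, values=vals)


def nj_tree(d: DistanceMatrix) -> Genealogy:
    """Neighbor-joining tree (classical Saitou-Nei, via scikit-bio).

    Negative branch-length estimates are clamped to zero; the result is an
    unrooted bifurcating tree over all labels.
    """
    if len(d.labels) < 4:
        raise GenealogyError("neighbor joining needs at least 4 labels")
    import skbio

    dm = skbio.DistanceMatrix(d.values, ids=list(d.labels))
    tree = skbio.tree.nj(dm, neg_as_zero=True)
    return parse_newick(str(tree).strip())


# ---------------------------------------------------------------------------
# Window weighting


_METHODS = {
    "exact": weight_exact,
    "complete": weight_exact,
    "fixed": weight_fixed_sample,
    "threshold": weight_threshold,
}


def window_weights(
    window: GenotypeWindow,
    taxa: TaxonMap,
    method: str = "exact",
    catalog: Sequence[TaxonTopology] | None = None,
    **params,
) -> tuple[Interval, WeightRecord | None]:
    """p-distances -> NJ tree -> topology weighting for one window.

    Rejected windows yield a missing record (interval retained).
    """
    interval = window.interval
    if window.rejected:
        return interval, None
    tree = nj_tree(p_distance_matrix(window))
    fn = _METHODS[method]
    return interval, fn(tree, taxa, catalog=catalog, **params)


@dataclass
class BootstrapSummary:
    """SNP-bootstrap quantiles of the per-topology weights of one window."""

    topologies: tuple[str, ...]
    replicates: int
    mean: np.ndarray
    q_low: np.ndarray
    q_high: np.ndarray
    weights: np.ndarray  # replicates x topologies
    levels: tuple[float, float]


def bootstrap_window_weights(
    window: GenotypeWindow,
    taxa: TaxonMap,
    replicates: int = 100,
    seed: int | None = None,
    levels: tuple[float, float] = (0.05, 0.95),
    method: str = "exact",
    catalog: Sequence[TaxonTopology] | None = None,
    **params,
) -> BootstrapSummary:
    """Resample SNP columns with replacement, rebuild the tree, reweight.

    Reports the empirical lower/upper quantiles (default 5% and 95%) of each
    topology's weight across replicates; reproducible given ``seed``.
    """
    if replicates < 2:
        raise GenealogyError("need at least 2 bootstrap replicates")
    rng = np.random.default_rng(seed)
    fn = _METHODS[method]
    rows = []
    topo_ids: tuple[str, ...] | None = None
    for _ in range(replicates):
        rep = window.resample_columns(rng)
        tree = nj_tree(p_distance_matrix(rep))
        rec = fn(tree, taxa, catalog=catalog, **params)
        topo_ids = rec.topologies
        rows.append(rec.weights)
    weights = np.asarray(rows)
    assert topo_ids is not None
    return BootstrapSummary(
        topologies=topo_ids,
        replicates=replicates,
        mean=weights.mean(axis=0),
        q_low=np.quantile(weights, levels[0], axis=0),
        q_high=np.quantile(weights, levels[1], axis=0),
        weights=weights,
        levels=levels,
    )
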