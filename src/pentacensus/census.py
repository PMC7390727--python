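"""Abundance statistics over classified chemoreceptors.

"Abundance" throughout is the receptor-level fraction: pentapeptide-carrying
chemoreceptors as a percentage of all chemoreceptors within a stratum (a
genome, taxon, LBD family, habitat category, or topology class).  The module
also provides the per-genome receptor-count summary, the histogram of
pentapeptide receptors per genome, and the pooled abundance-versus-count
curve with its Pearson correlation.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

from .io_tables import UNCLASSIFIED, ProteomeMeta

#: Ranks at which taxonomic censuses may be taken.
CENSUS_RANKS = ("superkingdom", "phylum", "class", "order", "family")


@dataclass(frozen=True)
class CensusRow:
    """Aggregated counts and abundance for one stratum."""

    group: str
    total_receptors: int
    pentapeptide_receptors: int
    abundance_percent: float

    def __post_init__(self) -> None:
        if self.total_receptors <= 0:
            raise ValueError(f"{self.group}: rows require a positive receptor total")
        if not 0 <= self.pentapeptide_receptors <= self.total_receptors:
            raise ValueError(f"{self.group}: pentapeptide count out of range")

    @classmethod
    def from_counts(cls, group: str, total: int, penta: int) -> "CensusRow":
        return cls(group, total, penta, 100.0 * penta / total)


@dataclass(frozen=True)
class GenomeCount:
    """Receptor totals for one proteome."""

    proteome_id: str
    total_receptors: int
    pentapeptide_receptors: int

    def __post_init__(self) -> None:
        if not 0 <= self.pentapeptide_receptors <= self.total_receptors:
            raise ValueError(f"{self.proteome_id}: pentapeptide count out of range")


@dataclass(frozen=True)
class AbundanceByCountPoint:
    """Pooled abundance among all genomes sharing one receptor count."""

    receptor_count: int
    pooled_abundance_percent: float
    n_genomes: int


def per_genome_counts(annotations: Iterable) -> list[GenomeCount]:
    """Total and pentapeptide receptor counts per proteome."""
    totals: Counter[str] = Counter()
    penta: Counter[str] = Counter()
    for a in annotations:
        totals[a.proteome_id] += 1
        if a.has_pentapeptide:
            penta[a.proteome_id] += 1
    return [
        GenomeCount(pid, totals[pid], penta.get(pid, 0)) for pid in totals
    ]


def genome_summary(counts: Sequence[GenomeCount]) -> tuple[float, float | None]:
    """Mean and sample (n-1) standard deviation of receptors per genome.

    With a single genome the standard deviation is undefined and returned as
    None; an empty input raises.
    """
    if not counts:
        raise ValueError("genome_summary requires at least one genome")
    totals = np.array([c.total_receptors for c in counts], dtype=float)
    mean = float(totals.mean())
    sd = float(totals.std(ddof=1)) if len(totals) > 1 else None
    return mean, sd


def pentapeptide_histogram(counts: Iterable[GenomeCount]) -> dict[int, int]:
    """Number of genomes with exactly k pentapeptide receptors, k >= 1."""
    hist: Counter[int] = Counter(
        c.pentapeptide_receptors for c in counts if c.pentapeptide_receptors >= 1
    )
    return dict(sorted(hist.items()))


def abundance_by_group(
    annotations: Iterable,
    group_fn: Callable,
    unclassified_label: str = UNCLASSIFIED,
) -> list[CensusRow]:
    """Aggregate abundance per group key.

    ``group_fn`` maps an annotation to zero, one, or several keys (a string or
    an iterable of strings).  A receptor contributes to every key it maps to;
    receptors mapping to no key are pooled into an explicit unclassified row.
    Rows are sorted by group name; strata with zero receptors never appear.
    """
    totals: Counter[str] = Counter()
    penta: Counter[str] = Counter()
    for a in annotations:
        keys = group_fn(a)
        if keys is None:
            keys = []
        elif isinstance(keys, str):
            keys = [keys]
        else:
            keys = list(keys)
        if not keys:
            keys = [unclassified_label]
        for k in keys:
            totals[k] += 1
            if a.has_pentapeptide:
                penta[k] += 1
    return [
        CensusRow.from_counts(k, totals[k], penta.get(k, 0))
        for k in sorted(totals)
    ]


def abundance_by_taxon(
    annotations: Sequence,
    metadata: Mapping[str, ProteomeMeta],
    rank: str,
) -> list[CensusRow]:
    """Abundance per lineage name at the given rank.

    Proteomes whose rank is unnamed pool into the unclassified row; receptors
    from proteomes absent from the metadata raise, listing the orphan IDs.
    """
    if rank not in CENSUS_RANKS:
        raise ValueError(f"unsupported census rank {rank!r}; choose from {CENSUS_RANKS}")
    orphans = sorted({a.proteome_id for a in annotations} - set(metadata))
    if orphans:
        raise KeyError(f"proteomes missing from metadata: {orphans}")
    return abundance_by_group(
        annotations, lambda a: metadata[a.proteome_id].rank(rank)
    )


def abundance_by_topology(annotations: Iterable) -> list[CensusRow]:
    """Abundance within the transmembrane and cytosolic receptor classes."""
    return abundance_by_group(annotations, lambda a: a.topology)


def abundance_by_lbd_family(annotations: Iterable) -> list[CensusRow]:
    """Abundance per LBD family; multi-family receptors count in each family."""
    return abundance_by_group(annotations, lambda a: a.lbd_families)


def abundance_by_habitat(
    annotations: Iterable,
    habitat: Mapping,
    include_unassigned: bool = False,
) -> list[CensusRow]:
    """Abundance per habitat category.

    Receptors from proteomes without a habitat assignment are excluded by
    default (habitat databases cover only a subset of strains); set
    ``include_unassigned`` to pool them into an unclassified row instead.
    """
    def group_fn(a):
        assignment = habitat.get(a.proteome_id)
        if assignment is None:
            return [UNCLASSIFIED] if include_unassigned else None
        return assignment.categories

    kept = [
        a for a in annotations
        if include_unassigned or a.proteome_id in habitat
    ]
    return abundance_by_group(kept, group_fn)


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation coefficient.

    Raises on unequal lengths, fewer than two points, or a constant input.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("pearson_r requires two equal-length vectors")
    if len(x) < 2:
        raise ValueError("pearson_r requires at least two points")
    dx = x - x.mean()
    dy = y - y.mean()
    sx = float(np.sqrt(np.dot(dx, dx)))
    sy = float(np.sqrt(np.dot(dy, dy)))
    if sx == 0.0 or sy == 0.0:
        raise ValueError("pearson_r is undefined for a constant input")
    return float(np.dot(dx, dy) / (sx * sy))


def abundance_vs_receptor_count(
    counts: Sequence[GenomeCount],
    min_genomes: int = 1,
    cap_percentile: float | None = 99.5,
) -> tuple[list[AbundanceByCountPoint], float | None]:
    """Pooled abundance as a function of receptors per genome, with Pearson r.

    For each distinct receptor count c carried by at least ``min_genomes``
    genomes, the pooled abundance is 100 x (sum of pentapeptide receptors) /
    (sum of receptors) over those genomes.  Counts above the
    ``cap_percentile`` percentile of genome counts are dropped (the extreme
    tail holds too few genomes to estimate an abundance).  The correlation is
    computed unweighted over the retained (count, abundance) points and is
    None when fewer than two points remain or either coordinate is constant.
    """
    by_count: dict[int, list[GenomeCount]] = {}
    for c in counts:
        by_count.setdefault(c.total_receptors, []).append(c)
    cap = np.inf
    if cap_percentile is not None and counts:
        cap = float(np.percentile([c.total_receptors for c in counts], cap_percentile))
    points = []
    for count in sorted(by_count):
        genomes = by_count[count]
        if count > cap or len(genomes) < min_genomes:
            continue
        total = sum(g.total_receptors for g in genomes)
        penta = sum(g.pentapeptide_receptors for g in genomes)
        points.append(
            AbundanceByCountPoint(count, 100.0 * penta / total, len(genomes))
        )
    r: float | None
    try:
        r = pearson_r(
            [p.receptor_count for p in points],
            [p.pooled_abundance_percent for p in points],
        )
    except ValueError:
        r = None
    return points, r
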