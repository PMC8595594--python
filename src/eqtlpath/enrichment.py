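"""eGene-level pathway enrichment for in-region eQTLs.

For each tissue the catalog's eQTLs falling inside the trait query regions
are collected and deduplicated to their target genes (eGenes) — several
eQTLs in linkage disequilibrium often point at the same gene, so the unit
of counting is the distinct eGene, not the eQTL record.  Each pathway is
then tested for over-representation of the hit eGenes with a one-sided
Fisher's exact test on a 2x2 table whose background universe is the set of
eGenes testable in that tissue (the catalog's eGene universe intersected
with the gene-set collection's universe), and p-values are adjusted by the
Benjamini-Hochberg step-up procedure across the pathways of each
(tissue, collection) pair.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
from scipy.stats import hypergeom

from .catalogs import EqtlCatalog, GeneSet, GeneSetCollection
from .regions import IntervalIndex, QueryRegionSet, build_interval_index

logger = logging.getLogger(__name__)

CountingUnit = Literal["egene", "eqtl"]
BhFamily = Literal["per_pair", "per_tissue", "global"]


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 table: in-region hits vs pathway membership over the gene universe.

    a: hit and in pathway; b: hit, not in pathway; c: in pathway, not hit;
    d: neither.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError(f"negative cell in {self}")

    @property
    def universe_size(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass
class EnrichmentResult:
    tissue: str
    pathway: str
    source: str
    table: ContingencyTable
    p_raw: float
    p_adj: float
    hit_genes: list[str]
    hit_eqtl_count: int


def select_in_region_egenes(
    cat: EqtlCatalog, idx: IntervalIndex
) -> tuple[frozenset[str], dict[str, int]]:
    """Distinct eGenes of catalog records inside any query interval.

    Returns the eGene set and the per-eGene count of in-region eQTL records;
    deduplication to genes is mandatory because LD places many eQTLs on one
    eGene.  Record positions are 1-based and converted here.
    """
    counts: dict[str, int] = {}
    for r in cat.records:
        if idx.contains(r.chrom, r.pos - 1):
            counts[r.egene] = counts.get(r.egene, 0) + 1
    return frozenset(counts), counts


def build_contingency(
    hits: frozenset[str] | set[str],
    pathway: GeneSet,
    universe: frozenset[str] | set[str],
) -> ContingencyTable:
    """Classify the universe into the 2x2 table for one pathway.

    Pathway members outside the universe are excluded from the margins;
    hits are intersected with the universe first.
    """
    if not universe:
        raise ValueError("empty gene universe")
    p_in_u = set(pathway.members) & set(universe)
    hits_in_u = set(hits) & set(universe)
    a = len(hits_in_u & p_in_u)
    b = len(hits_in_u - p_in_u)
    c = len(p_in_u - hits_in_u)
    d = len(universe) - a - b - c
    return ContingencyTable(a, b, c, d)


def fisher_one_sided_p(t: ContingencyTable) -> float:
    """One-sided (enrichment) Fisher exact p: P(A >= a) with fixed margins.

    Computed as the hypergeometric survival function; degenerate margins
    (no hits or an empty pathway) give p = 1.
    """
    n_hit = t.a + t.b
    n_path = t.a + t.c
    if n_hit == 0 or n_path == 0:
        logger.debug("degenerate margins (%d hits, %d pathway genes): p = 1",
                     n_hit, n_path)
        return 1.0
    return float(hypergeom.sf(t.a - 1, t.universe_size, n_path, n_hit))


def bh_adjust(pvals: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjustment, returned in input order.

    q_i = min_{j >= i} (p_(j) * m / j), capped at 1.
    """
    arr = np.asarray(pvals, dtype=float)
    if arr.size == 0:
        return []
    if np.any((arr < 0) | (arr > 1)) or np.any(np.isnan(arr)):
        raise ValueError("p-values must lie in [0, 1]")
    m = arr.size
    order = np.argsort(arr, kind="mergesort")
    ranks = np.arange(1, m + 1)
    scaled = arr[order] * m / ranks
    q_sorted = np.minimum(np.minimum.accumulate(scaled[::-1])[::-1], 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    # the j = rank(i) term equals p_i * m / rank >= p_i in real arithmetic;
    # clamp so float rounding can never push q below p
    q = np.maximum(q, arr)
    return [float(x) for x in q]


def _result_sort_key(r: EnrichmentResult) -> tuple:
    return (r.p_adj, r.pathway, r.tissue)


def _raw_results_for_pair(
    cat: EqtlCatalog,
    idx: IntervalIndex,
    coll: GeneSetCollection,
    counting_unit: CountingUnit = "egene",
) -> list[EnrichmentResult]:
    """Per-pathway tables and raw p-values for one (tissue, collection) pair."""
    hits, hit_counts = select_in_region_egenes(cat, idx)
    universe = cat.egene_universe & coll.universe
    results: list[EnrichmentResult] = []
    if counting_unit == "eqtl":
        # classify individual eQTL records instead of distinct eGenes
        in_region = {r: idx.contains(r.chrom, r.pos - 1) for r in cat.records}
    for gs in coll.sets:
        if not universe:
            table = ContingencyTable(0, 0, 0, 0)
            p_raw = 1.0
            hit_in_path: set[str] = set()
        elif counting_unit == "egene":
            table = build_contingency(hits, gs, universe)
            p_raw = fisher_one_sided_p(table)
            hit_in_path = (hits & gs.members) & universe
        else:
            a = b = c = d = 0
            for rec, inr in in_region.items():
                if rec.egene not in universe:
                    continue
                in_path = rec.egene in gs.members
                if inr and in_path:
                    a += 1
                elif inr:
                    b += 1
                elif in_path:
                    c += 1
                else:
                    d += 1
            table = ContingencyTable(a, b, c, d)
            p_raw = fisher_one_sided_p(table)
            hit_in_path = (hits & gs.members) & universe
        results.append(
            EnrichmentResult(
                tissue=cat.tissue,
                pathway=gs.name,
                source=gs.source,
                table=table,
                p_raw=p_raw,
                p_adj=p_raw,  # adjusted by the caller
                hit_genes=sorted(hit_in_path),
                hit_eqtl_count=sum(hit_counts[g] for g in hit_in_path),
            )
        )
    return results


def _apply_bh(results: list[EnrichmentResult]) -> None:
    if results:
        adj = bh_adjust([r.p_raw for r in results])
        for r, q in zip(results, adj):
            r.p_adj = q


def scan_tissue(
    cat: EqtlCatalog,
    idx: IntervalIndex,
    coll: GeneSetCollection,
    counting_unit: CountingUnit = "egene",
) -> list[EnrichmentResult]:
    """Test every pathway of one collection against one tissue's catalog.

    BH adjustment runs across the collection's pathways; results come back
    sorted by adjusted p ascending (ties by pathway name).
    """
    results = _raw_results_for_pair(cat, idx, coll, counting_unit)
    _apply_bh(results)
    results.sort(key=_result_sort_key)
    return results


def run_all(
    catalogs: Mapping[str, EqtlCatalog],
    regions: QueryRegionSet,
    collections: Sequence[GeneSetCollection],
    counting_unit: CountingUnit = "egene",
    bh_family: BhFamily = "per_pair",
) -> list[EnrichmentResult]:
    """Run the enrichment scan over every (tissue, collection) pair.

    ``bh_family`` chooses the multiple-testing family: within each
    (tissue, collection) pair (default, matching per-database per-tissue
    reporting), across all collections within a tissue, or globally.
    """
    if not catalogs or not collections:
        raise ValueError("need at least one catalog and one collection")
    idx = build_interval_index(regions)
    per_pair: dict[tuple[str, str], list[EnrichmentResult]] = {}
    for tissue in sorted(catalogs):
        for coll in collections:
            per_pair[(tissue, coll.name)] = _raw_results_for_pair(
                catalogs[tissue], idx, coll, counting_unit
            )
    if bh_family == "per_pair":
        families = list(per_pair.values())
    elif bh_family == "per_tissue":
        families = [
            [r for (t, _), rs in per_pair.items() if t == tissue for r in rs]
            for tissue in sorted(catalogs)
        ]
    elif bh_family == "global":
        families = [[r for rs in per_pair.values() for r in rs]]
    else:
        raise ValueError(f"unknown bh_family {bh_family!r}")
    for fam in families:
        _apply_bh(fam)
    out = [r for rs in per_pair.values() for r in rs]
    out.sort(key=_result_sort_key)
    return out
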