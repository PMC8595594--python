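"""Trait query regions: variant flanking, interval merging and fast lookup.

Trait-associated variants (e.g., a PheGenI export) are expanded into
genomic intervals by flanking each variant position by a fixed number of
base pairs on each side; overlapping or abutting intervals are merged so
the query region set for a trait is a sorted, disjoint list of intervals.

Coordinates are 0-based half-open internally.  Variant positions in input
files are 1-based and converted at the read boundary; BED export/import is
0-based half-open as the format prescribes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

DEFAULT_FLANK_BP = 50_000


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval [start, end) on one chromosome."""

    chrom: str
    start: int
    end: int
    label: str = ""

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start, got [{self.start}, {self.end})"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, pos_0based: int) -> bool:
        return self.start <= pos_0based < self.end


@dataclass(frozen=True)
class Variant:
    """A trait-associated variant at a 1-based position."""

    id: str
    chrom: str
    pos: int
    trait: str = ""

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"variant position must be >= 1, got {self.pos}")


@dataclass
class QueryRegionSet:
    """Sorted, disjoint flanked-and-merged intervals for one trait."""

    trait: str
    intervals: list[GenomicInterval] = field(default_factory=list)
    flank_bp: int = DEFAULT_FLANK_BP

    def __len__(self) -> int:
        return len(self.intervals)

    def total_bp(self) -> int:
        return sum(len(iv) for iv in self.intervals)


def flank_variant(
    v: Variant,
    flank_bp: int,
    chrom_sizes: dict[str, int] | None = None,
) -> GenomicInterval:
    """Expand a variant into the interval covering it plus ``flank_bp`` per side.

    The variant base itself is included, so the unclamped length is
    ``2 * flank_bp + 1``.  The left end is clamped at the chromosome start;
    the right end is clamped only when a chromosome-sizes table is given.
    """
    if flank_bp < 0:
        raise ValueError(f"flank_bp must be >= 0, got {flank_bp}")
    start = max(0, v.pos - 1 - flank_bp)
    end = v.pos + flank_bp
    if chrom_sizes is not None and v.chrom in chrom_sizes:
        end = min(end, chrom_sizes[v.chrom])
    return GenomicInterval(v.chrom, start, end, label=v.id)


def merge_intervals(ivals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Coalesce overlapping or abutting intervals per chromosome.

    Returns the minimal sorted list of disjoint intervals covering exactly
    the same bases as the input; labels of merged inputs are joined with
    commas in sorted-input order.
    """
    ordered = sorted(ivals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    merged: list[GenomicInterval] = []
    for iv in ordered:
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end:
            prev = merged[-1]
            label = f"{prev.label},{iv.label}" if prev.label and iv.label else (
                prev.label or iv.label
            )
            merged[-1] = GenomicInterval(
                prev.chrom, prev.start, max(prev.end, iv.end), label=label
            )
        else:
            merged.append(iv)
    return merged


def build_query_regions(
    variants: Sequence[Variant],
    flank_bp: int = DEFAULT_FLANK_BP,
    chrom_sizes: dict[str, int] | None = None,
) -> QueryRegionSet:
    """Flank every variant and merge the results into one region set.

    All variants are expected to belong to one trait; the trait label of the
    first variant is carried on the result.
    """
    if not variants:
        logger.warning("build_query_regions called with no variants")
        return QueryRegionSet(trait="", intervals=[], flank_bp=flank_bp)
    trait = variants[0].trait
    flanked = [flank_variant(v, flank_bp, chrom_sizes) for v in variants]
    return QueryRegionSet(
        trait=trait, intervals=merge_intervals(flanked), flank_bp=flank_bp
    )


class IntervalIndex:
    """Point/range membership queries over a region set.

    Backed by one interval tree per chromosome; answers are identical to a
    linear scan over the intervals.
    """

    def __init__(self, regions: QueryRegionSet):
        self.regions = regions
        self._trees: dict[str, IntervalTree] = {}
        for iv in regions.intervals:
            self._trees.setdefault(iv.chrom, IntervalTree()).addi(
                iv.start, iv.end, iv
            )

    def contains(self, chrom: str, pos_0based: int) -> bool:
        tree = self._trees.get(chrom)
        return bool(tree.overlaps_point(pos_0based)) if tree else False

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        tree = self._trees.get(chrom)
        return bool(tree.overlap(start, end)) if tree else False

    def find(self, chrom: str, pos_0based: int) -> GenomicInterval | None:
        """The containing query interval, or None."""
        tree = self._trees.get(chrom)
        if not tree:
            return None
        hits = tree.at(pos_0based)
        return next(iter(hits)).data if hits else None


def build_interval_index(regions: QueryRegionSet) -> IntervalIndex:
    return IntervalIndex(regions)


# ---------------------------------------------------------------------------
# I/O


def read_variant_table(path: str | Path, trait: str | None = None) -> list[Variant]:
    """Read a variant TSV with columns trait, snp_id, chrom, pos_1based.

    Extra columns are ignored.  Rows with missing chromosome or position are
    dropped with a logged count.  When ``trait`` is given only that trait's
    rows are kept.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"trait", "snp_id", "chrom", "pos_1based"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"variant table missing columns: {sorted(missing)}")
    if trait is not None:
        df = df[df["trait"] == trait]
    n_in = len(df)
    df = df.dropna(subset=["chrom", "pos_1based"])
    pos = pd.to_numeric(df["pos_1based"], errors="coerce")
    df = df[pos.notna()]
    pos = pos[pos.notna()].astype(int)
    if len(df) < n_in:
        logger.info("dropped %d variant rows with unusable coordinates", n_in - len(df))
    return [
        Variant(id=r.snp_id, chrom=r.chrom, pos=p, trait=r.trait)
        for r, p in zip(df.itertuples(), pos)
    ]


def write_bed(regions: QueryRegionSet, path: str | Path) -> None:
    """Write the region set as BED (chrom, start, end, name); 0-based half-open."""
    with open(path, "w") as fh:
        for iv in regions.intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.label or '.'}\n")


def read_bed(path: str | Path, trait: str = "", flank_bp: int = 0) -> QueryRegionSet:
    ivals = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.rstrip("\n").split("\t")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            label = parts[3] if len(parts) > 3 and parts[3] != "." else ""
            ivals.append(GenomicInterval(chrom, start, end, label=label))
    return QueryRegionSet(trait=trait, intervals=merge_intervals(ivals), flank_bp=flank_bp)


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Two-column TSV of chromosome name and length in bp."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if line.strip():
                name, length = line.split()[:2]
                sizes[name] = int(length)
    return sizes
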