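"""Readers and writers for eQTL catalogs, gene-set collections and ID maps.

The ingestion contract for eQTL data is a long-format per-record TSV
(variant_id, chrom, pos_1based, gene_id, tissue, pvalue) rather than any
upstream multi-tissue release format; a GTEx-scale catalog is reduced to
these per-tissue (variant, eGene, p) triples before analysis.  Gene sets
come in as MSigDB-dialect GMT files or as the two-file bundle layout
(name+link file, name+member file).  Gene-ID translation uses an offline
three-column table (ensembl_id, entrez_id, symbol) instead of live
annotation queries.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_EQTL_P_THRESHOLD = 1e-4

EQTL_COLUMNS = ["variant_id", "chrom", "pos_1based", "gene_id", "tissue", "pvalue"]


@dataclass(frozen=True)
class EqtlRecord:
    variant_id: str
    chrom: str
    pos: int  # 1-based
    egene: str
    pvalue: float
    tissue: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.pvalue <= 1.0:
            raise ValueError(f"pvalue out of [0,1]: {self.pvalue}")
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")


@dataclass
class EqtlCatalog:
    """All passing eQTL records of one tissue plus the derived eGene universe."""

    tissue: str
    records: list[EqtlRecord] = field(default_factory=list)
    p_threshold: float = DEFAULT_EQTL_P_THRESHOLD

    @property
    def egene_universe(self) -> frozenset[str]:
        return frozenset(r.egene for r in self.records)

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class GeneSet:
    name: str
    members: frozenset[str]
    source: str = ""
    url: str = ""

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.name!r} has no members")


@dataclass
class GeneSetCollection:
    name: str
    sets: list[GeneSet] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [s.name for s in self.sets]
        if len(names) != len(set(names)):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate set names in collection: {dup}")

    @property
    def universe(self) -> frozenset[str]:
        out: set[str] = set()
        for s in self.sets:
            out |= s.members
        return frozenset(out)

    def __len__(self) -> int:
        return len(self.sets)


class GeneIdMap:
    """Bidirectional lookup between Ensembl IDs, Entrez IDs and symbols.

    Rows whose ensembl_id maps to more than one entrez_id are ambiguous and
    dropped (with a logged count).  Ensembl version suffixes (".N") are
    stripped before every lookup.
    """

    NAMESPACES = ("ensembl", "entrez", "symbol")

    def __init__(self, rows: Iterable[tuple[str, str, str]]):
        df = pd.DataFrame(rows, columns=["ensembl", "entrez", "symbol"]).astype(str)
        df["ensembl"] = df["ensembl"].str.replace(r"\.\d+$", "", regex=True)
        counts = df.groupby("ensembl")["entrez"].nunique()
        ambiguous = set(counts[counts > 1].index)
        if ambiguous:
            logger.info("dropping %d ambiguous ensembl ids from gene map", len(ambiguous))
            df = df[~df["ensembl"].isin(ambiguous)]
        self._df = df.drop_duplicates()
        self._maps: dict[tuple[str, str], dict[str, str]] = {}
        for src in self.NAMESPACES:
            for dst in self.NAMESPACES:
                if src != dst:
                    self._maps[(src, dst)] = dict(zip(self._df[src], self._df[dst]))

    def __len__(self) -> int:
        return len(self._df)

    def lookup(self, gene_id: str, source: str, target: str) -> str | None:
        if target not in self.NAMESPACES:
            raise ValueError(f"unknown namespace {target!r}")
        if source not in self.NAMESPACES:
            raise ValueError(f"unknown namespace {source!r}")
        if source == "ensembl":
            gene_id = gene_id.split(".")[0]
        return self._maps[(source, target)].get(gene_id)


def read_gene_map(path: str | Path) -> GeneIdMap:
    """Read a gene-map TSV with columns ensembl_id, entrez_id, symbol."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"ensembl_id", "entrez_id", "symbol"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"gene map missing columns: {sorted(missing)}")
    return GeneIdMap(zip(df["ensembl_id"], df["entrez_id"], df["symbol"]))


def map_gene_ids(
    ids: Sequence[str], m: GeneIdMap, target: str, source: str = "ensembl"
) -> list[tuple[str, str | None]]:
    """Translate each ID; unmapped IDs are reported as (input, None), never dropped."""
    return [(g, m.lookup(g, source, target)) for g in ids]


# ---------------------------------------------------------------------------
# GMT and bundle formats


def read_gmt(path: str | Path, source: str = "", name: str | None = None) -> GeneSetCollection:
    """Read an MSigDB-dialect GMT file: name, description/URL, members...

    Duplicate member IDs within a line are deduplicated; a line with fewer
    than three fields or no members is a format error naming the line.
    """
    path = Path(path)
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path.name}:{lineno}: GMT line needs >= 3 tab-separated fields"
                )
            set_name, url = fields[0], fields[1]
            members = frozenset(m for m in fields[2:] if m)
            if not members:
                raise ValueError(f"{path.name}:{lineno}: gene set {set_name!r} is empty")
            sets.append(GeneSet(name=set_name, members=members, source=source, url=url))
    return GeneSetCollection(name=name or path.stem, sets=sets)


def write_gmt(coll: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in coll.sets:
            members = "\t".join(sorted(s.members))
            fh.write(f"{s.name}\t{s.url}\t{members}\n")


def write_geneset_bundle(coll: GeneSetCollection, outdir: str | Path) -> tuple[Path, Path]:
    """Write the two-file bundle: a names+links file and a names+members file.

    Each file has one tab-separated line per pathway; the pair round-trips
    through :func:`read_geneset_bundle`.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    links_path = outdir / f"{coll.name}.links.txt"
    members_path = outdir / f"{coll.name}.members.txt"
    with open(links_path, "w") as fh:
        for s in coll.sets:
            fh.write(f"{s.name}\t{s.url}\n")
    with open(members_path, "w") as fh:
        for s in coll.sets:
            fh.write(f"{s.name}\t" + "\t".join(sorted(s.members)) + "\n")
    return links_path, members_path


def read_geneset_bundle(
    links_path: str | Path, members_path: str | Path, source: str = "", name: str | None = None
) -> GeneSetCollection:
    urls: dict[str, str] = {}
    with open(links_path) as fh:
        for line in fh:
            if line.strip():
                parts = line.rstrip("\n").split("\t")
                urls[parts[0]] = parts[1] if len(parts) > 1 else ""
    sets: list[GeneSet] = []
    with open(members_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            set_name, members = parts[0], frozenset(m for m in parts[1:] if m)
            if not members:
                raise ValueError(f"bundle line {lineno}: gene set {set_name!r} is empty")
            sets.append(
                GeneSet(name=set_name, members=members, source=source,
                        url=urls.get(set_name, ""))
            )
    if name is None:
        name = Path(members_path).name.removesuffix(".members.txt")
    return GeneSetCollection(name=name, sets=sets)


# ---------------------------------------------------------------------------
# eQTL catalog ingestion


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def read_eqtl_table(
    path: str | Path,
    p_threshold: float = DEFAULT_EQTL_P_THRESHOLD,
    gene_map: GeneIdMap | None = None,
    target_namespace: str = "entrez",
) -> dict[str, EqtlCatalog]:
    """Read the canonical long-format eQTL TSV into per-tissue catalogs.

    Records with pvalue > ``p_threshold`` are excluded (the comparison is
    inclusive at the threshold).  Rows with unparseable p-values are dropped
    with a logged count.  Duplicate (variant, egene, tissue) rows collapse to
    the smallest p-value.  When a ``gene_map`` is given, Ensembl gene IDs are
    translated into ``target_namespace`` at load; unmapped genes are dropped
    with a logged count.
    """
    with _open_text(path) as fh:
        df = pd.read_csv(fh, sep="\t", dtype={"variant_id": str, "chrom": str,
                                              "gene_id": str, "tissue": str})
    missing = set(EQTL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"eQTL table missing columns: {sorted(missing)}")
    n_total = len(df)
    pvals = pd.to_numeric(df["pvalue"], errors="coerce")
    n_bad = int(pvals.isna().sum())
    if n_bad:
        logger.info("dropped %d eQTL rows with unparseable p-values", n_bad)
    df = df[pvals.notna()].assign(pvalue=pvals[pvals.notna()])
    df = df[df["pvalue"] <= p_threshold]
    logger.info(
        "eQTL filter p <= %g: retained %d of %d records", p_threshold, len(df), n_total
    )
    if gene_map is not None:
        mapped = [gene_map.lookup(g, "ensembl", target_namespace) for g in df["gene_id"]]
        keep = [m is not None for m in mapped]
        n_unmapped = len(keep) - sum(keep)
        if n_unmapped:
            logger.info("dropped %d eQTL rows with unmappable gene ids", n_unmapped)
        df = df[keep].assign(gene_id=[m for m in mapped if m is not None])
    # collapse duplicate (variant, gene, tissue) rows to the smallest p
    df = (
        df.sort_values("pvalue", kind="mergesort")
        .drop_duplicates(subset=["variant_id", "gene_id", "tissue"], keep="first")
        .sort_index()
    )
    catalogs: dict[str, EqtlCatalog] = {}
    for tissue, grp in df.groupby("tissue", sort=True):
        records = [
            EqtlRecord(
                variant_id=r.variant_id,
                chrom=r.chrom,
                pos=int(r.pos_1based),
                egene=r.gene_id,
                pvalue=float(r.pvalue),
                tissue=tissue,
            )
            for r in grp.itertuples()
        ]
        catalogs[tissue] = EqtlCatalog(tissue=tissue, records=records,
                                       p_threshold=p_threshold)
    return catalogs


def write_eqtl_table(catalogs: dict[str, EqtlCatalog] | Iterable[EqtlRecord],
                     path: str | Path) -> None:
    """Write records to the canonical long-format TSV."""
    if isinstance(catalogs, dict):
        records: Iterable[EqtlRecord] = (
            r for t in sorted(catalogs) for r in catalogs[t].records
        )
    else:
        records = catalogs
    with open(path, "w") as fh:
        fh.write("\t".join(EQTL_COLUMNS) + "\n")
        for r in records:
            fh.write(
                f"{r.variant_id}\t{r.chrom}\t{r.pos}\t{r.egene}\t{r.tissue}\t{r.pvalue:.6g}\n"
            )


# ---------------------------------------------------------------------------
# Cytobands


def read_cytobands(path: str | Path) -> pd.DataFrame:
    """Read a cytoband TSV (chrom, start, end, band); 0-based half-open."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "band": str})
    required = {"chrom", "start", "end", "band"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"cytoband table missing columns: {sorted(missing)}")
    return df


def cytoband_at(bands: pd.DataFrame, chrom: str, pos_0based: int) -> str | None:
    hit = bands[
        (bands["chrom"] == chrom)
        & (bands["start"] <= pos_0based)
        & (pos_0based < bands["end"])
    ]
    if hit.empty:
        return None
    row = hit.iloc[0]
    short = chrom.removeprefix("chr")
    return f"{short}{row['band']}"
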