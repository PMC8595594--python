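"""Result filtering, the tissue x pathway significance matrix, and reports.

The matrix holds -log10 of BH-adjusted p-values (rows = tissues, columns =
pathways); its TSV export is the contract, the rendered heatmap is
cosmetic.  The gene-hit report mirrors the published table layout:
pathway, hit genes, genomic locations (cytoband when a band table is
available, otherwise the containing query interval) and adjusted p.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .catalogs import EqtlCatalog, cytoband_at
from .enrichment import ContingencyTable, EnrichmentResult
from .regions import IntervalIndex

logger = logging.getLogger(__name__)

DEFAULT_RESULT_P_THRESHOLD = 1e-4
P_FLOOR = 1e-300  # avoids infinities in -log10

RESULT_COLUMNS = [
    "tissue", "source", "pathway", "a", "b", "c", "d",
    "p_raw", "p_adj", "hit_genes", "hit_eqtl_count",
]


def filter_results(
    results: Sequence[EnrichmentResult],
    threshold: float = DEFAULT_RESULT_P_THRESHOLD,
    on: str = "adjusted",
) -> list[EnrichmentResult]:
    """Keep results at or below the significance threshold, sorted by p_adj.

    The filter applies to the BH-adjusted p by default; ``on='raw'``
    switches it to the unadjusted Fisher p.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    if on not in ("adjusted", "raw"):
        raise ValueError(f"filter_on must be 'adjusted' or 'raw', got {on!r}")
    key = (lambda r: r.p_adj) if on == "adjusted" else (lambda r: r.p_raw)
    kept = [r for r in results if key(r) <= threshold]
    kept.sort(key=lambda r: (r.p_adj, r.pathway, r.tissue))
    return kept


@dataclass
class ResultMatrix:
    """Tissues x pathways grid of -log10(p_adj); untested cells are masked."""

    row_labels: list[str]
    col_labels: list[str]
    values: np.ndarray  # shape (n_tissues, n_pathways), NaN where masked
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("matrix shape inconsistent with labels")
        if self.mask is None:
            self.mask = np.isnan(self.values)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.row_labels,
                            columns=self.col_labels)


def _col_label(r: EnrichmentResult) -> str:
    return f"{r.source}:{r.pathway}" if r.source else r.pathway


def build_result_matrix(
    results: Sequence[EnrichmentResult],
    filter_columns: bool = False,
    threshold: float = DEFAULT_RESULT_P_THRESHOLD,
) -> ResultMatrix:
    """Arrange results into the significance matrix.

    With ``filter_columns`` only pathways whose best cell passes the
    threshold are kept as columns.  Cells never tested stay masked (NaN).
    """
    if not results:
        logger.warning("build_result_matrix called with no results")
        return ResultMatrix([], [], np.empty((0, 0)))
    tissues = sorted({r.tissue for r in results})
    cols = sorted({_col_label(r) for r in results})
    if filter_columns:
        best: dict[str, float] = {}
        for r in results:
            lbl = _col_label(r)
            best[lbl] = min(best.get(lbl, 1.0), r.p_adj)
        cols = [c for c in cols if best[c] <= threshold]
    values = np.full((len(tissues), len(cols)), np.nan)
    ti = {t: i for i, t in enumerate(tissues)}
    ci = {c: j for j, c in enumerate(cols)}
    for r in results:
        lbl = _col_label(r)
        if lbl in ci:
            values[ti[r.tissue], ci[lbl]] = -np.log10(max(r.p_adj, P_FLOOR))
    return ResultMatrix(tissues, cols, values)


@dataclass
class GeneHitRow:
    tissue: str
    pathway: str
    source: str
    hit_genes: str       # ";"-joined
    locations: str       # ";"-joined cytobands or intervals
    p_adj: float


def gene_hit_report(
    results: Sequence[EnrichmentResult],
    catalogs: Mapping[str, EqtlCatalog] | None = None,
    idx: IntervalIndex | None = None,
    bands: pd.DataFrame | None = None,
) -> list[GeneHitRow]:
    """One report row per result, mirroring the published table columns.

    Genes within a row are ordered by descending in-region eQTL count, then
    name.  A gene's location is the cytoband of its first in-region eQTL
    position when a band table is given; otherwise the containing query
    interval rendered as chrom:start-end; otherwise "NA".
    """
    rows: list[GeneHitRow] = []
    for r in results:
        genes = list(r.hit_genes)
        counts: dict[str, int] = {g: 0 for g in genes}
        first_pos: dict[str, tuple[str, int]] = {}
        if catalogs is not None and idx is not None and r.tissue in catalogs:
            for rec in catalogs[r.tissue].records:
                if rec.egene in counts and idx.contains(rec.chrom, rec.pos - 1):
                    counts[rec.egene] += 1
                    first_pos.setdefault(rec.egene, (rec.chrom, rec.pos - 1))
        genes.sort(key=lambda g: (-counts[g], g))
        locations: list[str] = []
        for g in genes:
            loc = "NA"
            if g in first_pos:
                chrom, pos = first_pos[g]
                if bands is not None:
                    band = cytoband_at(bands, chrom, pos)
                    if band is not None:
                        loc = band
                if loc == "NA" and idx is not None:
                    iv = idx.find(chrom, pos)
                    if iv is not None:
                        loc = f"{iv.chrom}:{iv.start}-{iv.end}"
            if loc == "NA":
                logger.info("no resolvable location for gene %s", g)
            locations.append(loc)
        rows.append(
            GeneHitRow(
                tissue=r.tissue,
                pathway=r.pathway,
                source=r.source,
                hit_genes=";".join(genes),
                locations=";".join(dict.fromkeys(locations)) if locations else "NA",
                p_adj=r.p_adj,
            )
        )
    return rows


# ---------------------------------------------------------------------------
# TSV / image export


def write_results_tsv(results: Sequence[EnrichmentResult], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(RESULT_COLUMNS) + "\n")
        for r in results:
            t = r.table
            fh.write(
                f"{r.tissue}\t{r.source}\t{r.pathway}\t{t.a}\t{t.b}\t{t.c}\t{t.d}\t"
                f"{r.p_raw!r}\t{r.p_adj!r}\t{';'.join(r.hit_genes)}\t{r.hit_eqtl_count}\n"
            )


def read_results_tsv(path: str | Path) -> list[EnrichmentResult]:
    df = pd.read_csv(path, sep="\t", dtype={"tissue": str, "source": str,
                                            "pathway": str},
                     keep_default_na=False, float_precision="round_trip")
    out = []
    for r in df.itertuples():
        out.append(
            EnrichmentResult(
                tissue=r.tissue,
                source=r.source,
                pathway=r.pathway,
                table=ContingencyTable(int(r.a), int(r.b), int(r.c), int(r.d)),
                p_raw=float(r.p_raw),
                p_adj=float(r.p_adj),
                hit_genes=[g for g in str(r.hit_genes).split(";") if g],
                hit_eqtl_count=int(r.hit_eqtl_count),
            )
        )
    return out


def write_gene_hit_tsv(rows: Sequence[GeneHitRow], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("tissue\tsource\tpathway\thit_genes\tlocations\tp_adj\n")
        for row in rows:
            fh.write(
                f"{row.tissue}\t{row.source}\t{row.pathway}\t{row.hit_genes}\t"
                f"{row.locations}\t{row.p_adj!r}\n"
            )


def export_heatmap(
    matrix: ResultMatrix,
    path: str | Path,
    image: bool = False,
    cap: float = 300.0,
) -> list[Path]:
    """Write the matrix TSV (rows = tissues, columns = pathways).

    Masked cells become empty fields.  With ``image`` a heatmap is rendered
    beside the TSV using a red (significant) to blue (not) diverging
    palette; the TSV is the contract, the image is cosmetic.
    """
    path = Path(path)
    if path.suffix in (".png", ".svg", ".pdf"):
        tsv_path = path.with_suffix(".tsv")
        img_path = path
    else:
        tsv_path = path
        img_path = path.with_suffix(".png")
    written = [tsv_path]
    with open(tsv_path, "w") as fh:
        fh.write("tissue\t" + "\t".join(matrix.col_labels) + "\n")
        for i, t in enumerate(matrix.row_labels):
            cells = [
                "" if matrix.mask[i, j] else repr(float(matrix.values[i, j]))
                for j in range(len(matrix.col_labels))
            ]
            fh.write(t + "\t" + "\t".join(cells) + "\n")
    if image and matrix.values.size:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        import seaborn as sns

        capped = np.minimum(matrix.values, cap)
        fig_w = max(4.0, 0.4 * len(matrix.col_labels) + 2)
        fig_h = max(3.0, 0.4 * len(matrix.row_labels) + 2)
        fig, ax = plt.subplots(figsize=(fig_w, fig_h))
        sns.heatmap(
            pd.DataFrame(capped, index=matrix.row_labels,
                         columns=matrix.col_labels),
            cmap="RdBu_r", center=None, ax=ax,
            cbar_kws={"label": "-log10 adjusted p"},
        )
        ax.set_xlabel("pathway")
        ax.set_ylabel("tissue")
        fig.tight_layout()
        fig.savefig(img_path, dpi=120)
        plt.close(fig)
        written.append(img_path)
    return written


def read_matrix_tsv(path: str | Path) -> ResultMatrix:
    rows: list[str] = []
    cols: list[str] = []
    data: list[list[float]] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        cols = header[1:]
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            rows.append(parts[0])
            data.append([float(x) if x else np.nan for x in parts[1:]])
    values = np.array(data, dtype=float) if data else np.empty((0, len(cols)))
    return ResultMatrix(rows, cols, values.reshape(len(rows), len(cols)))
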