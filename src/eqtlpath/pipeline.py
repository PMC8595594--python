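"""End-to-end orchestration: config, the enrich pipeline, run manifests.

A run is fully described by a :class:`RunConfig`; given the same config and
input files the pipeline writes byte-identical outputs, and the manifest it
leaves in the output directory (config hash, input checksums, package
version) is sufficient to re-run it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .catalogs import read_cytobands, read_eqtl_table, read_gene_map, read_gmt
from .enrichment import run_all
from .regions import (
    build_interval_index,
    build_query_regions,
    read_chrom_sizes,
    read_variant_table,
    write_bed,
)
from .reporting import (
    build_result_matrix,
    export_heatmap,
    filter_results,
    gene_hit_report,
    write_gene_hit_tsv,
    write_results_tsv,
)

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """A run configuration that fails validation."""


@dataclass
class RunConfig:
    """All inputs and thresholds of one enrichment run.

    Defaults follow the reference analysis settings: 50 kb flanks, an
    inclusive 1e-4 nominal p filter on eQTLs at load, a 1e-4 filter on
    BH-adjusted enrichment p-values for reporting, distinct-eGene counting
    and per-(tissue, collection) adjustment families.
    """

    variants: str = ""
    eqtl_table: str = ""
    gmt: list[str] = field(default_factory=list)
    gene_map: str = ""
    outdir: str = "eqtlpath_out"
    cytobands: str | None = None
    chrom_sizes: str | None = None
    trait: str | None = None
    flank_bp: int = 50_000
    eqtl_p_threshold: float = 1e-4
    result_p_threshold: float = 1e-4
    counting_unit: str = "egene"
    bh_family: str = "per_pair"
    filter_on: str = "adjusted"
    image: bool = False

    def validate(self, check_paths: bool = True) -> None:
        if not 0.0 < self.eqtl_p_threshold <= 1.0:
            raise ConfigError("eqtl_p_threshold must be in (0, 1]")
        if not 0.0 < self.result_p_threshold <= 1.0:
            raise ConfigError("result_p_threshold must be in (0, 1]")
        if self.flank_bp < 0:
            raise ConfigError("flank_bp must be >= 0")
        if self.counting_unit not in ("egene", "eqtl"):
            raise ConfigError(f"counting_unit must be egene|eqtl, got {self.counting_unit!r}")
        if self.bh_family not in ("per_pair", "per_tissue", "global"):
            raise ConfigError(f"bh_family must be per_pair|per_tissue|global, "
                              f"got {self.bh_family!r}")
        if self.filter_on not in ("adjusted", "raw"):
            raise ConfigError(f"filter_on must be adjusted|raw, got {self.filter_on!r}")
        if check_paths:
            for name in ("variants", "eqtl_table", "gene_map"):
                p = getattr(self, name)
                if not p:
                    raise ConfigError(f"missing required path: {name}")
                if not Path(p).exists():
                    raise ConfigError(f"{name} path does not exist: {p}")
            if not self.gmt:
                raise ConfigError("missing required path: gmt")
            for g in self.gmt:
                if not Path(g).exists():
                    raise ConfigError(f"gmt path does not exist: {g}")
            for name in ("cytobands", "chrom_sizes"):
                p = getattr(self, name)
                if p is not None and not Path(p).exists():
                    raise ConfigError(f"{name} path does not exist: {p}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if isinstance(data.get("gmt"), str):
            data["gmt"] = [data["gmt"]]
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_run_manifest(config: RunConfig, outdir: Path) -> Path:
    """Record the config hash, input checksums and version; no timestamps,
    so re-running leaves the manifest unchanged."""
    cfg_json = json.dumps(config.to_dict(), sort_keys=True)
    inputs = {}
    for name in ("variants", "eqtl_table", "gene_map", "cytobands", "chrom_sizes"):
        p = getattr(config, name)
        if p:
            inputs[name] = _sha256(p)
    for i, g in enumerate(config.gmt):
        inputs[f"gmt_{i}"] = _sha256(g)
    manifest = {
        "package": "eqtlpath",
        "version": __version__,
        "config": config.to_dict(),
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "input_sha256": inputs,
    }
    path = outdir / "run_manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path


def run_enrich(config: RunConfig) -> dict[str, Path]:
    """The full pipeline: regions -> catalogs -> enrichment -> reports.

    Writes results.tsv (all tests), significant.tsv (filtered), the
    matrix TSV (optionally a heatmap image), the gene-hit table, the merged
    query regions as BED, and the run manifest.  Returns the output paths.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    chrom_sizes = read_chrom_sizes(config.chrom_sizes) if config.chrom_sizes else None
    variants = read_variant_table(config.variants, trait=config.trait)
    logger.info("read %d variants", len(variants))
    regions = build_query_regions(variants, config.flank_bp, chrom_sizes)
    logger.info("built %d merged query intervals", len(regions))
    idx = build_interval_index(regions)

    gene_map = read_gene_map(config.gene_map)
    catalogs = read_eqtl_table(
        config.eqtl_table, p_threshold=config.eqtl_p_threshold, gene_map=gene_map
    )
    logger.info("loaded catalogs for %d tissues", len(catalogs))
    collections = [read_gmt(g, source=Path(g).stem.upper()) for g in config.gmt]
    bands = read_cytobands(config.cytobands) if config.cytobands else None

    results = run_all(
        catalogs, regions, collections,
        counting_unit=config.counting_unit,  # type: ignore[arg-type]
        bh_family=config.bh_family,  # type: ignore[arg-type]
    )
    significant = filter_results(
        results, threshold=config.result_p_threshold, on=config.filter_on
    )
    logger.info("%d of %d tests pass the %g result filter",
                len(significant), len(results), config.result_p_threshold)

    paths: dict[str, Path] = {}
    paths["regions"] = outdir / "query_regions.bed"
    write_bed(regions, paths["regions"])
    paths["results"] = outdir / "results.tsv"
    write_results_tsv(results, paths["results"])
    paths["significant"] = outdir / "significant.tsv"
    write_results_tsv(significant, paths["significant"])

    matrix = build_result_matrix(
        results, filter_columns=True, threshold=config.result_p_threshold
    )
    written = export_heatmap(matrix, outdir / "matrix.tsv", image=config.image)
    paths["matrix"] = written[0]
    if len(written) > 1:
        paths["heatmap"] = written[1]

    rows = gene_hit_report(significant, catalogs=catalogs, idx=idx, bands=bands)
    paths["gene_hits"] = outdir / "gene_hits.tsv"
    write_gene_hit_tsv(rows, paths["gene_hits"])

    paths["manifest"] = write_run_manifest(config, outdir)
    return paths
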