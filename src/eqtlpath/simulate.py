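"""Seeded synthetic inputs with controllable planted tissue-pathway signal.

The generator emulates the full input bundle of a desk-scale analysis: toy
chromosomes, a trait variant list, per-tissue eQTL catalogs whose nominal
p-values all pass the load filter, MSigDB-style pathway collections, and a
gene-ID map.  Each gene has a single anchor position; its eQTLs scatter
within a cis window of +/-100 kb around the anchor, except that every eQTL
is independently placed *inside* a trait query region with a controlled
probability — the background in-region rate for ordinary genes, and
``min(1, factor * rate)`` for members of a planted pathway in the planted
tissue.  The Bernoulli in-region indicator makes the expected enrichment
(the a-cell of the contingency table) available in closed form, which the
manifest records.

One :class:`numpy.random.Generator` per independent stream, spawned from
the scenario seed — no global random state.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .catalogs import (
    EqtlCatalog,
    EqtlRecord,
    GeneIdMap,
    GeneSet,
    GeneSetCollection,
    write_eqtl_table,
    write_gmt,
)
from .regions import (
    IntervalIndex,
    QueryRegionSet,
    Variant,
    build_interval_index,
    build_query_regions,
)

CIS_WINDOW_BP = 100_000


@dataclass(frozen=True)
class PlantedSignal:
    tissue: str
    pathway: str
    enrichment_factor: float = 8.0

    def __post_init__(self) -> None:
        if self.enrichment_factor < 1:
            raise ValueError("enrichment_factor must be >= 1")


@dataclass
class ScenarioConfig:
    """Knobs of one synthetic study; defaults are the reference conditions."""

    seed: int = 0
    n_chroms: int = 3
    chrom_length_bp: int = 10_000_000
    n_genes: int = 500
    n_pathways: int = 50
    pathway_size: int = 20
    n_tissues: int = 3
    eqtls_per_gene: int = 3
    n_query_variants: int = 20
    flank_bp: int = 50_000
    background_inregion_rate: float = 0.05
    planted: PlantedSignal | None = None
    trait: str = "synthetic_trait"
    eqtl_p_max: float = 1e-4
    eqtl_p_min: float = 1e-12

    def __post_init__(self) -> None:
        for name in ("n_chroms", "chrom_length_bp", "n_genes", "n_pathways",
                     "pathway_size", "n_tissues", "eqtls_per_gene",
                     "n_query_variants"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.flank_bp < 0:
            raise ValueError("flank_bp must be >= 0")
        if not 0.0 < self.background_inregion_rate < 1.0:
            raise ValueError("background_inregion_rate must be in (0, 1)")
        if self.pathway_size > self.n_genes:
            raise ValueError("pathway_size cannot exceed n_genes")

    @property
    def chroms(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chroms)]

    @property
    def tissues(self) -> list[str]:
        return [f"tissue{i + 1}" for i in range(self.n_tissues)]


@dataclass
class Scenario:
    """In-memory synthetic bundle: ready-to-analyse objects plus ground truth."""

    cfg: ScenarioConfig
    variants: list[Variant]
    regions: QueryRegionSet
    catalogs: dict[str, EqtlCatalog]   # gene IDs in the canonical (Entrez) namespace
    collection: GeneSetCollection
    gene_map: GeneIdMap
    manifest: dict[str, object] = field(default_factory=dict)


def _gene_ids(cfg: ScenarioConfig) -> tuple[list[str], list[str], list[str]]:
    ensembl = [f"ENSG{i:08d}" for i in range(1, cfg.n_genes + 1)]
    entrez = [str(100000 + i) for i in range(1, cfg.n_genes + 1)]
    symbol = [f"GENE{i}" for i in range(1, cfg.n_genes + 1)]
    return ensembl, entrez, symbol


def _sample_in_region(rng: np.random.Generator, regions: QueryRegionSet) -> tuple[str, int]:
    """A uniformly random base over the total region coverage; returns 1-based pos."""
    lengths = np.array([len(iv) for iv in regions.intervals])
    iv = regions.intervals[rng.choice(len(lengths), p=lengths / lengths.sum())]
    return iv.chrom, int(rng.integers(iv.start, iv.end)) + 1


def _sample_out_of_region(
    rng: np.random.Generator,
    chrom: str,
    anchor: int,
    chrom_len: int,
    idx: IntervalIndex,
) -> int:
    """A cis-window base outside every query region; returns 1-based pos.

    Rejection sampling over the window; if the window is (nearly) fully
    covered the draw falls back to a uniform base anywhere outside regions
    on the chromosome.
    """
    lo = max(0, anchor - CIS_WINDOW_BP)
    hi = min(chrom_len, anchor + CIS_WINDOW_BP)
    for _ in range(200):
        pos = int(rng.integers(lo, hi))
        if not idx.contains(chrom, pos):
            return pos + 1
    for _ in range(10_000):
        pos = int(rng.integers(0, chrom_len))
        if not idx.contains(chrom, pos):
            return pos + 1
    raise RuntimeError("query regions cover the entire chromosome")


def plant_enrichment(
    catalog: EqtlCatalog,
    regions: QueryRegionSet,
    members: frozenset[str] | set[str],
    factor: float,
    background_rate: float,
    rng: np.random.Generator,
    gene_anchor: dict[str, tuple[str, int]],
    chrom_length_bp: int,
) -> EqtlCatalog:
    """Re-place the eQTLs of pathway member genes at an elevated in-region rate.

    Each member-gene record is independently put inside a query region with
    probability ``min(1, factor * background_rate)`` and outside otherwise;
    records of non-member genes are untouched.  ``factor = 1`` reproduces
    the background placement distribution.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    idx = build_interval_index(regions)
    p_in = min(1.0, factor * background_rate)
    out: list[EqtlRecord] = []
    for r in catalog.records:
        if r.egene not in members:
            out.append(r)
            continue
        chrom, anchor = gene_anchor[r.egene]
        if rng.random() < p_in:
            new_chrom, pos = _sample_in_region(rng, regions)
        else:
            new_chrom = chrom
            pos = _sample_out_of_region(rng, chrom, anchor, chrom_length_bp, idx)
        out.append(EqtlRecord(r.variant_id, new_chrom, pos, r.egene, r.pvalue, r.tissue))
    return EqtlCatalog(tissue=catalog.tissue, records=out,
                       p_threshold=catalog.p_threshold)


def simulate_scenario(cfg: ScenarioConfig) -> Scenario:
    """Build the full in-memory bundle, deterministically from cfg.seed."""
    ss = np.random.SeedSequence(cfg.seed)
    rng_var, rng_gene, rng_path, rng_eqtl, rng_plant = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )
    chroms = cfg.chroms
    # trait variants and query regions
    variants = [
        Variant(
            id=f"rs{i + 1}",
            chrom=chroms[int(rng_var.integers(cfg.n_chroms))],
            pos=int(rng_var.integers(1, cfg.chrom_length_bp + 1)),
            trait=cfg.trait,
        )
        for i in range(cfg.n_query_variants)
    ]
    regions = build_query_regions(variants, cfg.flank_bp)
    idx = build_interval_index(regions)

    # genes: anchor point per gene, scattered over the toy genome
    ensembl, entrez, symbols = _gene_ids(cfg)
    gene_chrom = [chroms[int(rng_gene.integers(cfg.n_chroms))] for _ in entrez]
    gene_pos = [int(rng_gene.integers(0, cfg.chrom_length_bp)) for _ in entrez]
    gene_anchor = {g: (c, p) for g, c, p in zip(entrez, gene_chrom, gene_pos)}
    gene_map = GeneIdMap(zip(ensembl, entrez, symbols))

    # pathways over the Entrez namespace
    sets = []
    for i in range(cfg.n_pathways):
        members = rng_path.choice(cfg.n_genes, size=cfg.pathway_size, replace=False)
        sets.append(
            GeneSet(
                name=f"PW{i + 1:03d}",
                members=frozenset(entrez[j] for j in members),
                source="SYNTH",
                url=f"https://example.org/PW{i + 1:03d}",
            )
        )
    collection = GeneSetCollection(name="synthetic_pathways", sets=sets)

    # background eQTL catalogs: every gene gets k records per tissue
    log_lo, log_hi = np.log10(cfg.eqtl_p_min), np.log10(cfg.eqtl_p_max)
    catalogs: dict[str, EqtlCatalog] = {}
    for tissue in cfg.tissues:
        records: list[EqtlRecord] = []
        for g, (chrom, anchor) in zip(entrez, gene_anchor.values()):
            for j in range(cfg.eqtls_per_gene):
                if rng_eqtl.random() < cfg.background_inregion_rate:
                    rc, pos = _sample_in_region(rng_eqtl, regions)
                else:
                    rc = chrom
                    pos = _sample_out_of_region(
                        rng_eqtl, chrom, anchor, cfg.chrom_length_bp, idx
                    )
                pval = float(10 ** rng_eqtl.uniform(log_lo, log_hi))
                records.append(
                    EqtlRecord(
                        variant_id=f"snp_{tissue}_{g}_{j + 1}",
                        chrom=rc,
                        pos=pos,
                        egene=g,
                        pvalue=pval,
                        tissue=tissue,
                    )
                )
        catalogs[tissue] = EqtlCatalog(tissue=tissue, records=records,
                                       p_threshold=cfg.eqtl_p_max)

    manifest: dict[str, object] = {
        "seed": cfg.seed,
        "trait": cfg.trait,
        "n_intervals": len(regions),
        "planted_tissue": "",
        "planted_pathway": "",
        "enrichment_factor": "",
        "expected_a_planted": "",
    }
    for key, val in asdict(cfg).items():
        if key not in ("planted",):
            manifest[f"cfg_{key}"] = val

    if cfg.planted is not None:
        planted_set = next(
            s for s in collection.sets if s.name == cfg.planted.pathway
        )
        p_in = min(1.0, cfg.planted.enrichment_factor * cfg.background_inregion_rate)
        catalogs[cfg.planted.tissue] = plant_enrichment(
            catalogs[cfg.planted.tissue],
            regions,
            planted_set.members,
            cfg.planted.enrichment_factor,
            cfg.background_inregion_rate,
            rng_plant,
            gene_anchor,
            cfg.chrom_length_bp,
        )
        p_hit = 1.0 - (1.0 - p_in) ** cfg.eqtls_per_gene
        manifest.update(
            planted_tissue=cfg.planted.tissue,
            planted_pathway=cfg.planted.pathway,
            enrichment_factor=cfg.planted.enrichment_factor,
            planted_inregion_prob=p_in,
            planted_gene_hit_prob=p_hit,
            expected_a_planted=len(planted_set.members) * p_hit,
        )

    return Scenario(
        cfg=cfg,
        variants=variants,
        regions=regions,
        catalogs=catalogs,
        collection=collection,
        gene_map=gene_map,
        manifest=manifest,
    )


def generate_scenario(cfg: ScenarioConfig, outdir: str | Path) -> dict[str, Path]:
    """Write the file bundle: variants, eQTL table, GMT, gene map, manifest.

    The eQTL TSV carries versioned Ensembl IDs (the on-disk convention);
    the GMT carries Entrez IDs, so re-analysing the bundle exercises the
    gene-ID mapping path.  Same config and seed give byte-identical files.
    """
    scenario = simulate_scenario(cfg)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ensembl, entrez, symbols = _gene_ids(cfg)
    to_ensembl = {e: f"{g}.1" for g, e in zip(ensembl, entrez)}

    paths = {
        "variants": outdir / "variants.tsv",
        "eqtl": outdir / "eqtl.tsv",
        "gmt": outdir / "genesets.gmt",
        "gene_map": outdir / "gene_map.tsv",
        "manifest": outdir / "manifest.txt",
    }
    with open(paths["variants"], "w") as fh:
        fh.write("trait\tsnp_id\tchrom\tpos_1based\n")
        for v in scenario.variants:
            fh.write(f"{v.trait}\t{v.id}\t{v.chrom}\t{v.pos}\n")
    all_records = [
        EqtlRecord(r.variant_id, r.chrom, r.pos, to_ensembl[r.egene],
                   r.pvalue, r.tissue)
        for t in sorted(scenario.catalogs)
        for r in scenario.catalogs[t].records
    ]
    write_eqtl_table(all_records, paths["eqtl"])
    write_gmt(scenario.collection, paths["gmt"])
    with open(paths["gene_map"], "w") as fh:
        fh.write("ensembl_id\tentrez_id\tsymbol\n")
        for g, e, s in zip(ensembl, entrez, symbols):
            fh.write(f"{g}\t{e}\t{s}\n")
    with open(paths["manifest"], "w") as fh:
        for key in sorted(scenario.manifest):
            fh.write(f"{key}: {scenario.manifest[key]}\n")
    return paths


def null_calibration_suite(
    cfg: ScenarioConfig,
    n_reps: int,
    alphas: Sequence[float] = (0.05, 0.01, 1e-4),
) -> pd.DataFrame:
    """Empirical type-I table over repeated null (unplanted) scans.

    Runs the full pipeline ``n_reps`` times with seeds spawned from
    ``cfg.seed`` and reports, for each alpha, the fraction of
    (tissue, pathway) tests with raw Fisher p below alpha.  With a valid
    exact test this fraction should not exceed alpha (discreteness makes
    the test conservative).
    """
    from .enrichment import run_all

    if cfg.planted is not None:
        raise ValueError("null calibration requires an unplanted scenario")
    if n_reps == 0:
        return pd.DataFrame(columns=["alpha", "n_tests", "n_below", "fraction"])
    child_seeds = np.random.SeedSequence(cfg.seed).generate_state(n_reps) % (2**31)
    pvals: list[float] = []
    for seed in child_seeds:
        rep_cfg = ScenarioConfig(**{**asdict(cfg), "seed": int(seed), "planted": None})
        sc = simulate_scenario(rep_cfg)
        results = run_all(sc.catalogs, sc.regions, [sc.collection])
        pvals.extend(r.p_raw for r in results)
    arr = np.asarray(pvals)
    rows = [
        {
            "alpha": a,
            "n_tests": arr.size,
            "n_below": int((arr < a).sum()),
            "fraction": float((arr < a).mean()),
        }
        for a in alphas
    ]
    return pd.DataFrame(rows)
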