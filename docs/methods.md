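# Methods

## The model

`eqtlpath` asks which biological pathways are over-represented among the
genes whose expression is regulated from within trait-associated genomic
regions, tissue by tissue. The chain of reasoning is:

1. **Query regions.** A trait is represented by a list of associated
   variants (e.g., a PheGenI-style catalog export). Each variant is
   expanded into the interval covering the variant base plus `flank_bp`
   on each side (default 50,000 bp, so an unclamped interval spans
   `2·flank + 1 = 100,001` bp), and overlapping or abutting intervals are
   merged into a sorted, disjoint set. Regions are built within one trait;
   traits are never pooled.
2. **In-region eGenes.** For each tissue, the eQTL catalog (records
   retained at load when their nominal association p-value is ≤ the
   inclusive threshold, default 10⁻⁴) is scanned for records whose variant
   position falls inside any query interval. The records are deduplicated
   to their distinct target genes (eGenes): linkage disequilibrium places
   many eQTLs on the same gene, so the unit of counting is the eGene, not
   the eQTL record. (An eQTL-record counting mode exists behind
   `counting_unit="eqtl"` for comparison; it is not the default.)
3. **Enrichment test.** For each pathway *P* in a gene-set collection,
   the 2×2 table over the gene universe *U* is

   |            | in *P*        | not in *P*    |
   |------------|---------------|---------------|
   | hit        | a             | b             |
   | not hit    | c             | d             |

   with *U* = (eGenes testable in the tissue, i.e. the catalog's eGene
   universe) ∩ (the collection's union of members). Pathway members
   outside *U* are excluded from the margins. The p-value is the
   one-sided Fisher exact tail P(A ≥ a) under the hypergeometric null
   with fixed margins — enrichment only; depletion is not tested.
4. **Multiplicity.** Benjamini–Hochberg step-up adjustment
   (q₍ᵢ₎ = min₍ⱼ≥ᵢ₎ p₍ⱼ₎·m/j, capped at 1) is applied across the pathways
   of each (tissue, collection) pair by default, reproducing per-tissue
   per-database rankings. `bh_family` can widen the family to
   `per_tissue` or `global`.
5. **Reporting.** Results with adjusted p ≤ 10⁻⁴ (configurable; the
   filter can be switched to raw p) are reported, a tissues × pathways
   matrix of −log₁₀(adjusted p) is exported as TSV (optionally rendered
   as a red-high/blue-low heatmap), and a gene-hit table lists each
   surviving (tissue, pathway) with its hit genes and their genomic
   locations — cytoband labels when a band table is supplied (the band of
   the gene's first in-region eQTL position), otherwise the containing
   query interval.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `flank_bp` | 50,000 bp | flank per side when building query regions |
| `eqtl_p_threshold` | 10⁻⁴ | inclusive nominal-p filter on eQTL records at load |
| `result_p_threshold` | 10⁻⁴ | inclusive filter on BH-adjusted enrichment p |
| `counting_unit` | `egene` | distinct eGenes vs raw eQTL records in the 2×2 cells |
| `bh_family` | `per_pair` | multiple-testing family granularity |
| `filter_on` | `adjusted` | whether the result filter applies to adjusted or raw p |

## Design choices that were genuinely open

- **"Spans 100 kb" arithmetic.** A 50 kb flank per side plus the variant
  base is 100,001 bp; the interval must contain its defining variant, so
  the base is included and "100 kb" is treated as approximate.
- **Abutting intervals merge.** With half-open coordinates, `end_i ==
  start_j` means zero gap; merging avoids zero-length artifacts.
- **Universe definition.** The 2×2 margins are not uniquely determined by
  the verbal description of the test. We use (tissue eGene universe) ∩
  (collection universe): genes that can never be hit in a tissue must not
  inflate the d cell, and genes absent from every pathway carry no
  information for the margins. This is the main fidelity risk relative to
  other implementations of the same idea and is therefore isolated in
  `build_contingency`.
- **Degenerate margins.** No hits, or a pathway with no members in the
  universe, gives p = 1 (P(A ≥ 0) = 1) rather than an error.
- **Duplicate eQTL rows** (same variant, gene, tissue) collapse to the
  smallest p at load; a variant associated with several eGenes yields one
  record per eGene.
- **Gene namespace.** Entrez IDs are canonical inside the engine (gene
  sets are distributed with Entrez members); Ensembl IDs in eQTL tables
  are translated at the read boundary via an offline three-column map,
  version suffixes stripped, ambiguous and unmapped IDs dropped with
  logged counts.

## Numerical choices

- Fisher tail probabilities come from `scipy.stats.hypergeom.sf`; the
  test suite verifies them against exact integer-arithmetic enumeration
  for every table with universe ≤ 60 at 10⁻¹² tolerance.
- BH is implemented directly as the step-up formula (numpy suffix
  minimum). The adjusted value is additionally clamped to
  `max(q_i, p_i)` — a no-op in exact arithmetic, since the j = rank(i)
  term is p_i·m/rank ≥ p_i, but it prevents float rounding of `p·m/j`
  from pushing q one ulp below p. The suite cross-checks against
  `statsmodels.multipletests("fdr_bh")` at 10⁻¹² tolerance.
- Adjusted p-values are floored at 10⁻³⁰⁰ before −log₁₀ so matrix values
  stay finite; the heatmap color scale is linear in −log₁₀, capped at 300.
- Ties in adjusted p are broken by pathway name, then tissue name, making
  every output ordering deterministic; run manifests contain no
  timestamps, so repeated runs are byte-identical.
- Coordinates are 0-based half-open internally; 1-based positions
  (variants, eQTL records) are converted at the read boundary; BED I/O is
  0-based half-open.

## The synthetic-data generator

The generator emulates the full input bundle at desk scale. Reference
conditions: 3 chromosomes of 10 Mb, 500 genes, one collection of 50
pathways × 20 genes, 3 tissues, 3 eQTLs per gene per tissue, 20 query
variants flanked by 50 kb, background in-region rate 0.05, and an
optional planted (tissue, pathway) pair whose member-gene eQTLs are
placed in-region with probability min(1, factor × background rate),
factor 8 by default. Nominal eQTL p-values are drawn log-uniform on
[10⁻¹², 10⁻⁴] so every generated record passes the load filter (the
filter itself is tested separately with out-of-range spikes). Each gene
has a single anchor position; out-of-region eQTLs scatter within ±100 kb
of it to mimic cis-locality. One `numpy` generator per independent
stream, spawned from the scenario seed — no global random state.

Because the in-region indicator is an independent Bernoulli per record,
the expected a-cell for the planted pathway has the closed form
`pathway_size × (1 − (1 − p_in)^k)` with k eQTLs per gene; the bundle
manifest records it, and the tests compare simulated means against it.

What the generator does **not** emulate: realistic LD structure (records
are independent; real eQTL clusters are correlated), minor-allele
frequency and effect-size distributions, per-tissue sharing of eQTLs,
genome-scale catalog volumes, or non-uniform gene density. Passing the
planted-recovery and calibration suites therefore demonstrates the
engine's statistical correctness under independence, not performance on
real GTEx-scale data, where LD-induced dependence makes raw-count
interpretations more delicate.

Scaled problem sizes used by the shipped suites — 100 replicate scans for
planted-signal recovery, 200 scans (30,000 tests) for null calibration,
a full table sweep to universe 60 for the Fisher oracle — are the
package's choice of a desk-scale evidence budget; all complete in a few
minutes on one CPU.

## Known limitations

- No LD-aware or permutation null; the Fisher test treats genes as
  exchangeable, and LD between query regions and eQTL positions in real
  data can inflate hits for clustered gene families.
- No colocalization or conditional analysis: an in-region eQTL is counted
  whether or not it shares a causal signal with the trait association.
- Multi-tissue release formats are not parsed directly; catalogs enter
  through the documented long-format TSV.
- Right-end clamping of flanked intervals requires an optional
  chromosome-sizes table; without it, intervals may extend past the real
  chromosome end (harmless for membership queries).
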