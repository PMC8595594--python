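"""Build trait query regions: flank variants by 50 kb per side and merge.

Two variants 40 kb apart collapse into one interval once each is flanked
by 50 kb; a distant third variant stays separate.  The printed intervals
are 0-based half-open and each spans 2 * flank + 1 bp before merging.
"""

from eqtlpath import Variant, build_query_regions

variants = [
    Variant("rs1", "chr1", 1_000_000, trait="demo"),
    Variant("rs2", "chr1", 1_040_000, trait="demo"),
    Variant("rs3", "chr1", 2_000_000, trait="demo"),
]
regions = build_query_regions(variants, flank_bp=50_000)

print(f"{len(variants)} variants -> {len(regions)} merged query intervals")
for iv in regions.intervals:
    print(f"  {iv.chrom}:{iv.start}-{iv.end}  ({len(iv):,} bp; from {iv.label})")
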