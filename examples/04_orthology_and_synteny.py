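"""From homology hits to merged syntenic regions, step by step.

Uses simulator output in memory (no files) to show the intermediate
objects: the reciprocal-best-hit ortholog map, ranked anchors, collinear
blocks and their 10 Mb merges, and the regions syntenic to one focal
chromosome.
"""
from synmito import (
    SimConfig, anchors_from_orthologs, chain_anchors, focal_syntenic_regions,
    merge_blocks, reciprocal_best_hits, restrict_to_placed, simulate,
)

res = simulate(SimConfig(seed=7, n_inversions=4, n_translocations=1,
                         move_rate=0.0, paralog_rate=0.05))
omap = reciprocal_best_hits(res.hits_ab, res.hits_ba)
print(f"reciprocal best hits: {len(omap)} of {len(res.truth.ortholog_pairs)} "
      "true pairs")

omap = restrict_to_placed(omap, res.catalog_a, res.catalog_b)
anchors = anchors_from_orthologs(omap, res.catalog_a, res.catalog_b)
blocks = chain_anchors(anchors)  # >=5 collinear genes, gaps <=25
print(f"synteny blocks: {len(blocks)} "
      f"(largest {len(blocks[0])} anchors, {blocks[0].orientation})")

regions = merge_blocks(blocks)  # join blocks closer than 10 Mb on both genomes
focal = focal_syntenic_regions(regions, "chr1", res.catalog_a)
print(f"merged regions: {len(regions)}; focal chr1 is covered at "
      f"{focal.coverage:.0%} by {len(focal.regions)} region(s) on "
      f"{', '.join(focal.chroms_b)}")
# The focal regions name the genome-B segments descended from the same
# ancestral chromosome as genome A's chr1 - the 'ancestral X' proxy.
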