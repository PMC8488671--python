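"""Chain ortholog anchors into syntenic blocks, including an inversion.

Feeds the chainer a hand-built similarity table in which genes 5-9 of
the donor chromosome are reversed, and shows that two blocks with
opposite orientations come back.
"""

import pandas as pd

from introgmap import GeneAnnotation, best_hit_pairs, chain_collinear

n = 10
ann_r = [GeneAnnotation(f"r{i}", "recurrent", "chr1", 1 + 2000 * i,
                        1500 + 2000 * i) for i in range(n)]
# donor order: 0 1 2 3 4 then 9 8 7 6 5 (an inverted tail)
donor_order = [0, 1, 2, 3, 4, 9, 8, 7, 6, 5]
ann_d = [GeneAnnotation(f"d{j}", "donor", "chr1", 1 + 2000 * k, 1500 + 2000 * k)
         for k, j in enumerate(donor_order)]
similarity = pd.DataFrame([(f"r{i}", f"d{i}", 100.0) for i in range(n)],
                          columns=["gene_a", "gene_b", "score"])

anchors = best_hit_pairs(similarity, 0.0, ann_r, ann_d)
# a stiff gap penalty keeps chains contiguous at this toy scale, so the
# inversion boundary falls exactly between the two runs
blocks = chain_collinear(anchors, max_gap=5, gap_penalty=60.0, min_block_size=3)

for b in blocks:
    genes = " ".join(p.gene_recurrent for p in b.pairs)
    print(f"block {b.block_id}: orientation {b.orientation}, "
          f"score {b.chain_score:.0f}, pairs: {genes}")
# Orientation "+" marks conserved order, "-" an inverted run: the donor
# ranks decrease while the recurrent ranks increase across the block.
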