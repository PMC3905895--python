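"""Stratify enhancer activity: eRNA x H3K27ac subgroups and gene expression.

Each enhancer is linked to its nearest TSS within 100 kb; enhancers within
2 kb of an H3K27ac peak are H3K27ac+. Crossing eRNA status with H3K27ac
status gives four subgroups whose associated-gene FPKM distributions are
compared with two-sided rank-sum tests.
"""

from example_utils import build_small_dataset

from ernapredict import (assign_genes, classify_h3k27ac, compare_expression,
                         subgroup_enhancers)
from ernapredict.io_formats import GenomicInterval
from ernapredict.synthetic import generate_expression

data = build_small_dataset(n_enhancers=600, seed=23)
expr = generate_expression(data.cfg, data.truth)

links = assign_genes(data.regions, data.genes, max_dist=100_000)
n_linked = sum(l.gene_id is not None for l in links)
print(f"{n_linked}/{len(links)} enhancers linked to a gene within 100 kb")

# synthetic H3K27ac peaks: windows around enhancers with high realized signal
k27_threshold = data.signal.marks["H3K27ac"].median()
peaks = [GenomicInterval(r.interval.chrom, r.interval.start, r.interval.end)
         for r in data.regions
         if data.signal.marks.loc[r.id, "H3K27ac"] > k27_threshold]
k27 = classify_h3k27ac(data.regions, peaks, dist=2000)

sub = subgroup_enhancers(data.labels.labels, k27)
print("subgroup sizes:", sub.value_counts().to_dict())

comp = compare_expression(sub, links, expr,
                          pairs=[("eRNA+K27ac+", "eRNA-K27ac+"),
                                 ("eRNA+K27ac-", "eRNA-K27ac+")])
for row in comp.itertuples(index=False):
    print(f"{row.group_a} vs {row.group_b}: median FPKM "
          f"{row.median_a:.1f} vs {row.median_b:.1f}, p = {row.p_value:.2e}")
# eRNA+ groups associate with higher expression even at equal H3K27ac
# status: transcription is the sharper activity readout in this simulation.
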