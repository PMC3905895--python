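"""Simulate a small enhancer dataset and call eRNA+/- from GRO-seq.

Generates read-level tracks for 300 enhancers with a planted active state,
builds the intergenic catalog and log-density signal matrix, then partitions
each GRO-seq strand with an exact 1-D 2-means and combines the calls:
positive = high on both strands (bidirectional transcription), negative =
low on both, ambiguous otherwise.
"""

from ernapredict import (GeneratorConfig, TrackLibrary,
                         compute_signal_matrix, label_enhancers)
from ernapredict.catalog import apply_mappability_filter, define_intergenic_enhancers
from ernapredict.synthetic import (_mappability_track, generate_annotation,
                                   generate_reads)

cfg = GeneratorConfig(n_enhancers=300, n_genes=360, seed=11)
genes, sites, truth = generate_annotation(cfg)
tracks = generate_reads(cfg, truth, genes, sites)

regions, removed = define_intergenic_enhancers(
    sites, genes, [], cfg.tss_exclusion_bp, cfg.window_half_bp)
regions, dropped = apply_mappability_filter(
    regions, _mappability_track(cfg, genes, sites, truth))
print(f"catalog: {len(sites)} candidate sites -> {len(regions)} retained "
      f"({len(dropped)} low-mappability)")

lib, gro = TrackLibrary(), TrackLibrary()
for mark in cfg.marks:
    lib.add_dataframe(mark, tracks[mark])
gro.add_dataframe("groseq_plus", tracks["groseq_plus"])
gro.add_dataframe("groseq_minus", tracks["groseq_minus"])
signal = compute_signal_matrix(regions, lib, gro)

labels = label_enhancers(signal)
counts = labels.labels.value_counts().to_dict()
print(f"eRNA labels: {counts}")
print(f"sense-strand 2-means threshold: {labels.sense.threshold:.2f} "
      f"(cluster means {labels.sense.mean_low:.2f} / "
      f"{labels.sense.mean_high:.2f} log2 density)")

acc = sum((labels.labels.loc[e] == "positive") == truth.states[e]
          for e in labels.training_ids) / len(labels.training_ids)
print(f"agreement with planted states (unambiguous): {100 * acc:.1f}%")
# The wide gap between cluster means reflects the bimodal log GRO-seq
# histogram; near-perfect agreement shows the 4-sd planted separation.
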