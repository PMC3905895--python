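"""Shared builder for the example scripts: small in-memory dataset."""

from types import SimpleNamespace

from ernapredict import (GeneratorConfig, TrackLibrary,
                         compute_signal_matrix, label_enhancers)
from ernapredict.catalog import (apply_mappability_filter,
                                 define_intergenic_enhancers)
from ernapredict.synthetic import (_mappability_track, generate_annotation,
                                   generate_reads)


def build_small_dataset(n_enhancers: int = 300, seed: int = 0,
                        **overrides) -> SimpleNamespace:
    cfg = GeneratorConfig(n_enhancers=n_enhancers,
                          n_genes=int(n_enhancers * 1.2), seed=seed,
                          **overrides)
    genes, sites, truth = generate_annotation(cfg)
    tracks = generate_reads(cfg, truth, genes, sites)
    regions, _ = define_intergenic_enhancers(
        sites, genes, [], cfg.tss_exclusion_bp, cfg.window_half_bp)
    regions, _ = apply_mappability_filter(
        regions, _mappability_track(cfg, genes, sites, truth))
    lib, gro = TrackLibrary(), TrackLibrary()
    for mark in cfg.marks:
        lib.add_dataframe(mark, tracks[mark])
    gro.add_dataframe("groseq_plus", tracks["groseq_plus"])
    gro.add_dataframe("groseq_minus", tracks["groseq_minus"])
    signal = compute_signal_matrix(regions, lib, gro)
    labels = label_enhancers(signal)
    return SimpleNamespace(cfg=cfg, genes=genes, sites=sites, truth=truth,
                           regions=regions, signal=signal, labels=labels)
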