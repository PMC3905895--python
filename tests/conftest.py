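"""Shared fixtures: small in-memory synthetic datasets built once per session."""

from types import SimpleNamespace

import pytest

from ernapredict import (GeneratorConfig, TrackLibrary, compute_signal_matrix,
                         label_enhancers)
from ernapredict.catalog import apply_mappability_filter, define_intergenic_enhancers
from ernapredict.synthetic import (_mappability_track, generate_annotation,
                                   generate_reads)


def build_pipeline_inputs(cfg: GeneratorConfig) -> SimpleNamespace:
    """Generate a dataset in memory and push it through catalog + labeling.

    Returns genes, sites, truth, the retained enhancer regions, the signal
    matrix and the eRNA label set — everything downstream stages consume.
    """
    genes, sites, truth = generate_annotation(cfg)
    tracks_df = generate_reads(cfg, truth, genes, sites)
    regions, removed = define_intergenic_enhancers(
        sites, genes, [], cfg.tss_exclusion_bp, cfg.window_half_bp)
    mapp = _mappability_track(cfg, genes, sites, truth)
    kept, dropped_map = apply_mappability_filter(regions, mapp)
    lib, gro = TrackLibrary(), TrackLibrary()
    for m in cfg.marks:
        lib.add_dataframe(m, tracks_df[m])
    gro.add_dataframe("groseq_plus", tracks_df["groseq_plus"])
    gro.add_dataframe("groseq_minus", tracks_df["groseq_minus"])
    signal = compute_signal_matrix(kept, lib, gro)
    labels = label_enhancers(signal)
    return SimpleNamespace(cfg=cfg, genes=genes, sites=sites, truth=truth,
                           regions=kept, removed=removed,
                           dropped_mappability=dropped_map,
                           tracks=tracks_df, signal=signal, labels=labels)


@pytest.fixture(scope="session")
def small_data() -> SimpleNamespace:
    """300-enhancer dataset at default effect structure (seconds to build)."""
    return build_pipeline_inputs(GeneratorConfig(n_enhancers=300, n_genes=360,
                                                 seed=11))
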