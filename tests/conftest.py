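import numpy as np
import pytest

from codonlab import ribo_occupancy as ro
from codonlab import synthetic_data as sd


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale conditions for unit-level simulation tests."""
    return sd.SimulationConfig(seed=7, n_genes=40, rpf_library_size=40_000,
                               trnaseq_depth_per_family=2_000)


@pytest.fixture(scope="session")
def small_transcriptome(small_config):
    rng = small_config.rng()
    transcripts, truth = sd.generate_transcriptome(small_config, rng)
    mrna = sd.generate_mrna_levels(small_config, transcripts, rng)
    return transcripts, truth, mrna


# --- study-condition simulations shared by the acceptance suite -------------

ACCEPT_CONFIG = dict(n_genes=200, rpf_library_size=200_000)


def _occupancy_all_sites(tracks):
    out = {}
    for site in ro.SITE_OFFSETS:
        rel = ro.relative_codon_occupancy(tracks, site=site)
        rel["z"] = ro.zscore_by_family(rel["occupancy"])
        out[site] = rel
    return out


@pytest.fixture(scope="session")
def uniform_dwell_occupancy():
    """Uniform-dwell (null) simulation at the stated study scale."""
    cfg = sd.SimulationConfig(seed=11, **ACCEPT_CONFIG)
    rng = cfg.rng()
    transcripts, _ = sd.generate_transcriptome(cfg, rng)
    mrna = sd.generate_mrna_levels(cfg, transcripts, rng)
    alns, _ = sd.simulate_rpf_reads(transcripts, sd.dwell_preset("wt"), mrna, cfg, rng)
    tracks = ro.build_density_tracks(alns, transcripts)
    return ro.relative_codon_occupancy(tracks, site="A")


@pytest.fixture(scope="session")
def two_condition_occupancy():
    """wt vs knockdown-preset footprint libraries over one transcriptome."""
    cfg = sd.SimulationConfig(seed=13, **ACCEPT_CONFIG)
    rng = cfg.rng()
    transcripts, _ = sd.generate_transcriptome(cfg, rng)
    mrna = sd.generate_mrna_levels(cfg, transcripts, rng)
    out = {}
    for cond in ("wt", "siadat2"):
        alns, _ = sd.simulate_rpf_reads(
            transcripts, sd.dwell_preset(cond), mrna, cfg, rng
        )
        tracks = ro.build_density_tracks(alns, transcripts)
        out[cond] = _occupancy_all_sites(tracks)
    return out


@pytest.fixture(scope="session")
def coupled_proteome():
    """Transcriptome with a TE-coupled proteome and its analysis inputs."""
    from codonlab import codon_model as cm

    cfg = sd.SimulationConfig(seed=17, n_genes=400)
    rng = cfg.rng()
    transcripts, _ = sd.generate_transcriptome(cfg, rng)
    sim = sd.simulate_expression_and_proteome(
        transcripts, sd.dwell_preset("wt"), sd.dwell_preset("siadat2"), cfg, rng
    )
    counts = {}
    for tid, ann in transcripts.items():
        counts[tid] = cm.count_codons("".join(ann.cds_codons)).counts
    import pandas as pd

    profiles = pd.DataFrame(counts).T
    genome = cm.CodonUsageTable(profiles.sum(axis=0))
    optimal = cm.optimal_codons_from_usage(genome)
    cbi_values = profiles.apply(lambda row: cm.cbi(row, optimal), axis=1)
    nnc = profiles.apply(cm.adat_nnc_content, axis=1)
    return {
        "config": cfg,
        "transcripts": transcripts,
        "sim": sim,
        "profiles": profiles,
        "cbi": cbi_values,
        "nnc_content": nnc,
    }
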