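#!/usr/bin/env python
"""Per-gene ribosome density changes and their codon-usage dependence.

A global elongation slowdown loads more ribosomes per mRNA.  Footprint
sampling already distributes reads in proportion to each gene's dwell-time
composition, so within one library NNC-rich genes gain share under the
knockdown; the overall load increase (a physiological scale that library-
normalized counts cannot see) is applied as an explicit 2x ribosome-load
factor on the knockdown densities.  Genes are then classified by density
fold change (2 / 0.5 cutoffs) and the class fractions are summarized across
CBI bins and along a sliding window of ADAT-NNC codon content.
"""

import sys
from pathlib import Path

import pandas as pd

from codonlab import codon_model as cm
from codonlab import expression_te as et
from codonlab import ribo_occupancy as ro
from codonlab import synthetic_data as sd

OUT = Path(__file__).resolve().parents[1] / "results" / "05_ribosome_density"


def main(seed: int = 23) -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = sd.SimulationConfig(seed=seed, n_genes=300, rpf_library_size=150_000)
    rng = cfg.rng()
    transcripts, _ = sd.generate_transcriptome(cfg, rng)
    mrna = sd.generate_mrna_levels(cfg, transcripts, rng)
    mrna_rpkm = sd.simulate_mrna_rpkm(transcripts, mrna, cfg, rng)

    ribosome_load_factor = 2.0  # global ribosome loading increase under slowdown
    dens = {}
    for cond in ("wt", "siadat2"):
        alns, _ = sd.simulate_rpf_reads(
            transcripts, sd.dwell_preset(cond), mrna, cfg, rng
        )
        tracks = ro.build_density_tracks(alns, transcripts)
        dens[cond] = ro.density_table(tracks, cfg.rpf_library_size, mrna_rpkm)
    fc = ro.density_fold_change(
        dens["wt"]["density"], dens["siadat2"]["density"] * ribosome_load_factor
    )
    fc.to_csv(OUT / "density_fold_change.tsv", sep="\t")

    profiles = pd.DataFrame(
        {t: cm.count_codons("".join(a.cds_codons)).counts
         for t, a in transcripts.items()}
    ).T
    optimal = cm.optimal_codons_from_usage(cm.CodonUsageTable(profiles.sum(axis=0)))
    cbi_values = profiles.apply(lambda row: cm.cbi(row, optimal), axis=1)
    nnc = profiles.apply(cm.adat_nnc_content, axis=1)

    bins = et.cbi_bin_summary(fc["density_class"], cbi_values, n_bins=7)
    bins.to_csv(OUT / "cbi_bin_fractions.tsv", sep="\t", index=False)
    windows = et.sliding_window_fraction(fc["density_class"], nnc, window_size=100)
    windows.to_csv(OUT / "nnc_sliding_window.tsv", sep="\t", index=False)

    shares = fc["density_class"].value_counts(normalize=True)
    print("density classes:", {k: f"{v:.1%}" for k, v in shares.items()})
    up_ends = windows["frac_up"].iloc[[0, -1]].tolist()
    print(f"up-fraction along NNC ranking: {up_ends[0]:.2f} (low NNC) -> "
          f"{up_ends[1]:.2f} (high NNC)")
    print(f"tables in {OUT}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 23)
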