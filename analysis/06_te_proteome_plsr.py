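#!/usr/bin/env python
"""Proteome integration: TE fold changes, classification and codon PLSR.

Simulates the metabolically labeled two-condition proteome, aggregates
peptide ratios (geometric mean, SD(geo) filter), keeps replicate-concordant
proteins, computes TE fold changes (protein fold change / mRNA fold change),
and regresses log10 TE change on the 61-codon composition of the changed
genes by PLSR with LOO cross-validation.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from codonlab import codon_model as cm
from codonlab import expression_te as et
from codonlab import synthetic_data as sd
from codonlab.genetic_code import ADAT_NNC_CODONS, ADAT_NNT_CODONS

OUT = Path(__file__).resolve().parents[1] / "results" / "06_te_proteome_plsr"


def main(seed: int = 17) -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = sd.SimulationConfig(seed=seed, n_genes=400)
    rng = cfg.rng()
    transcripts, _ = sd.generate_transcriptome(cfg, rng)
    sim = sd.simulate_expression_and_proteome(
        transcripts, sd.dwell_preset("wt"), sd.dwell_preset("siadat2"), cfg, rng
    )

    fcs = []
    for i, rep in enumerate(sim["peptide_tables"]):
        agg = et.aggregate_peptide_table(rep)
        agg.to_csv(OUT / f"protein_ratios_rep{i + 1}.tsv", sep="\t")
        fcs.append(agg.loc[agg["pass_filter"], "geometric_mean"])
    concordant = et.concordance_filter(fcs[0], fcs[1])
    print(f"replicate concordance: {len(concordant)}/{cfg.n_genes} proteins "
          f"({len(concordant) / cfg.n_genes:.1%}) changed in the same trend")

    te_tab = et.te_table(concordant["fold_change"], sim["mrna_fc"])
    profiles = pd.DataFrame(
        {t: cm.count_codons("".join(a.cds_codons)).counts
         for t, a in transcripts.items()}
    ).T
    optimal = cm.optimal_codons_from_usage(cm.CodonUsageTable(profiles.sum(axis=0)))
    te_tab["cbi"] = profiles.apply(lambda row: cm.cbi(row, optimal), axis=1)
    te_tab["nnc_content"] = profiles.apply(cm.adat_nnc_content, axis=1)
    te_tab.to_csv(OUT / "te_table.tsv", sep="\t")

    by_class = te_tab.groupby("te_class")[["cbi", "nnc_content"]].mean().round(3)
    print("mean CBI / NNC content by TE class:")
    print(by_class.to_string())

    windows = et.sliding_window_fraction(
        te_tab["te_class"], te_tab["nnc_content"], window_size=200
    )
    windows.to_csv(OUT / "te_sliding_window.tsv", sep="\t", index=False)
    rho = stats.spearmanr(windows["mean_ranking_value"], windows["frac_down"]).statistic
    print(f"down-TE fraction vs NNC content along the ranking: spearman rho = {rho:.3f}")

    changed = te_tab[te_tab["te_class"].isin(["up", "down"])]
    model = et.plsr_fit(
        et.codon_composition_matrix(profiles.loc[changed.index]),
        np.log10(changed["te_fc"]),
        n_components=2,
    )
    model.correlation_loadings.to_csv(OUT / "plsr_correlation_loadings.tsv", sep="\t")
    model.collinear_pairs.to_csv(OUT / "plsr_collinear_pairs.tsv", sep="\t", index=False)
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cl = model.correlation_loadings
    fig, ax = plt.subplots(figsize=(5, 5))
    for radius in (1.0, np.sqrt(0.5)):  # 100% and 50% explained variance
        ax.add_patch(plt.Circle((0, 0), radius, fill=False, color="0.7"))
    for codon in cl.index:
        x_, y_ = cl.loc[codon, "component_1"], cl.loc[codon, "component_2"]
        if codon == "y":
            ax.scatter([x_], [y_], marker="^", color="purple", zorder=3,
                       label="TE fold change")
        else:
            color = ("red" if codon in ADAT_NNC_CODONS
                     else "blue" if codon in ADAT_NNT_CODONS else "0.6")
            ax.annotate(codon, (x_, y_), fontsize=5, color=color,
                        ha="center", va="center")
    ax.set_xlim(-1.1, 1.1)
    ax.set_ylim(-1.1, 1.1)
    ax.set_xlabel("component 1 correlation loading")
    ax.set_ylabel("component 2 correlation loading")
    ax.legend(loc="lower right", fontsize=7)
    fig.tight_layout()
    fig.savefig(OUT / "plsr_correlation_loadings.png", dpi=150)
    plt.close(fig)

    c1 = model.correlation_loadings["component_1"]
    y_sign = np.sign(c1["y"])
    nnc_opp = sum(np.sign(c1[c]) != y_sign for c in ADAT_NNC_CODONS if c in c1.index)
    nnt_with = sum(np.sign(c1[c]) == y_sign for c in ADAT_NNT_CODONS if c in c1.index)
    print(f"PLSR on {len(changed)} TE-changed genes: component 1/2 explain "
          f"{model.explained_y_variance[0]:.1%} / "
          f"{model.explained_y_variance[1] - model.explained_y_variance[0]:.1%} "
          "of TE-change variance")
    print(f"component 1 separates codon optimality: {nnc_opp}/8 NNC loadings "
          f"opposite the TE response, {nnt_with}/8 NNU loadings with it")
    print(f"tables in {OUT}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 17)
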