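#!/usr/bin/env python
"""Wobble-position (position 34) base composition from simulated tRNA-seq.

Simulates the wild-type condition (near-complete A-to-I editing, read as G)
and the knockdown condition (family-dependent residual editing), maps reads
back to the references and writes the per-family base-composition tables
that mirror stacked-bar editing figures.
"""

import sys
from pathlib import Path

from codonlab import synthetic_data as sd
from codonlab import trna_editing as te
from codonlab.pipeline import SIADAT2_EDITING, WT_EDITING

OUT = Path(__file__).resolve().parents[1] / "results" / "02_trna_editing"


def main(seed: int = 19) -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = sd.SimulationConfig(seed=seed, trnaseq_depth_per_family=10_000)
    rng = cfg.rng()
    refs = sd.make_trna_references(rng)
    for cond in ("wt", "siadat2"):
        rates = {
            r.trna_id: (WT_EDITING if cond == "wt"
                        else SIADAT2_EDITING[r.trna_id.split("-")[1]])
            for r in refs
        }
        reads, _ = sd.simulate_trnaseq_reads(refs, rates, cfg, rng)
        alns = te.map_trna_reads(reads, refs)
        table = te.editing_table(alns, refs)
        table.to_csv(OUT / f"editing_{cond}.tsv", sep="\t")
        mapped = len(alns) / len(reads)
        print(f"{cond}: mapped {mapped:.1%} of reads")
        for tid, row in table.iterrows():
            truth = rates[tid]
            print(f"  {tid}: G fraction {row['pG']:.3f}, "
                  f"editing {row['editing_fraction']:.3f} (true {truth:.2f})")
    print(f"tables in {OUT}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 19)
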