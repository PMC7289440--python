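#!/usr/bin/env python
"""Per-transcript occupancy profile with an upstream-ORF stall.

Builds one transcript carrying a uORF in its 5' leader, places footprints so
ribosomes stall on the uORF (the regulatory configuration of
starvation-responsive master regulators), and writes the library- and
mRNA-normalized per-codon profile across the whole transcript.
"""

import sys
from pathlib import Path

import numpy as np

from codonlab import ribo_occupancy as ro
from codonlab.ribo_occupancy import RPFAlignment, TranscriptAnnotation

OUT = Path(__file__).resolve().parents[1] / "results" / "07_transcript_profile"


def main(seed: int = 5) -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    utr5 = "".join(rng.choice(list("ACGT"), 30)) + "ATGCAACGGTAA" + "".join(
        rng.choice(list("ACGT"), 18)
    )
    orf = "ATG" + "".join(
        rng.choice(["GCC", "AAA", "GAA", "CTC", "GTT"], 60)
    ) + "TAA"
    ann = TranscriptAnnotation("uorf_transcript", utr5 + orf + "T" * 40, len(utr5) + 1)

    # uORF codon 2 (the CAA) sits at codon index -9 relative to the main ORF
    uorf_codon = -(len(utr5) - 30) // 3 + 1
    alignments = []
    for i in range(300):  # stalled on the uORF
        a_nt = ann.orf_start + 3 * (uorf_codon - 1)
        alignments.append(RPFAlignment(f"u{i}", ann.transcript_id, a_nt - 15, 30))
    for i in range(200):  # elongating through the main ORF
        codon = int(rng.integers(1, 60))
        a_nt = ann.orf_start + 3 * (codon - 1)
        alignments.append(RPFAlignment(f"m{i}", ann.transcript_id, a_nt - 15, 30))

    profile = ro.transcript_occupancy_profile(alignments, ann, 500_000, 2.0)
    profile.rename("normalized_count").rename_axis("codon_position").to_csv(
        OUT / "uorf_transcript_profile.tsv", sep="\t"
    )
    uorf_peak = profile[profile.index < 1].max()
    orf_mean = profile[profile.index >= 1].mean()
    print(f"uORF peak {uorf_peak:.1f} vs main-ORF mean {orf_mean:.2f} "
          f"({uorf_peak / orf_mean:.0f}x enrichment at codon {profile.idxmax()})")
    print(f"table in {OUT}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 5)
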