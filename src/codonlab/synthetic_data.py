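"""Ground-truthed synthetic inputs for every analysis stage.

The generators emulate the design of a tRNA-editing knockdown experiment:
a transcriptome with tunable ADAT-NNC codon content, ribosome footprints
whose A sites are drawn in proportion to mRNA level x codon dwell time,
uniform-coverage mRNA-seq, tRNA-seq reads with per-family wobble editing
probabilities, and a metabolically-labeled proteome whose protein output
couples mRNA level to codon-dependent elongation efficiency.

Every generator is deterministic under a fixed seed and returns a
``truth`` mapping sufficient to score recovery without re-simulation.
Dwell-time sampling is a steady-state approximation (footprint probability
proportional to dwell), not a traffic/queueing model; ribosome collisions
and initiation limitation are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genetic_code import (
    ADAT_FAMILIES,
    ADAT_NNC_CODONS,
    CODON_TO_AA,
    SENSE_CODONS,
    SYNONYMOUS_FAMILIES,
)
from .ribo_occupancy import RPFAlignment, TranscriptAnnotation
from .trna_editing import TRNAReference

_BACKGROUND_CODONS = [c for c in SENSE_CODONS if c not in ADAT_NNC_CODONS]


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic experiment.

    Defaults describe a desk-scale fungal-like transcriptome: 200 genes of
    ~300 codons, per-gene target ADAT-NNC content drawn from Beta(2, 5)
    (mean ~0.29), log-normal mRNA levels (sigma 1), a 2x10^5-read footprint
    library with 10% frame errors and 28-32 nt lengths, 10^4 tRNA-seq reads
    per family with 0.1% sequencing error, and a proteome coupled to
    elongation efficiency with kappa = 1 and 10% replicate noise.
    """

    seed: int = 0
    n_genes: int = 200
    mean_gene_length_codons: int = 300
    gene_length_sigma: float = 0.35
    min_gene_length_codons: int = 80
    nnc_content_beta: tuple[float, float] = (2.0, 5.0)
    utr_length: int = 100
    rpf_library_size: int = 200_000
    mrna_library_size: int = 1_000_000
    mrna_log_sigma: float = 1.0
    frame_error_rate: float = 0.1
    read_lengths: tuple[int, ...] = (28, 29, 30, 31, 32)
    trnaseq_depth_per_family: int = 10_000
    sequencing_error_rate: float = 1e-3
    te_coupling_kappa: float = 2.5
    replicate_log_sigma: float = 0.1
    peptides_per_protein: tuple[int, int] = (3, 8)
    peptide_log_sigma: float = 0.15

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


# ---------------------------------------------------------------------------
# dwell-time presets
# ---------------------------------------------------------------------------

def dwell_preset(name: str) -> pd.Series:
    """Per-codon dwell times for the 'wt' and 'siadat2' conditions.

    'wt': all codons dwell 1 (uniform elongation).  'siadat2': the eight
    ADAT NNC codons slow 2.0x and the NNU codons speed up 1.3x (their
    Watson-Crick tRNA no longer competes with the edited pool), on top of a
    global 1.5x slowdown.  These are simulation parameters chosen to emulate
    the expected sign pattern of an editing knockdown, not measured values.
    """
    dwell = pd.Series(1.0, index=list(SENSE_CODONS))
    if name == "wt":
        return dwell
    if name == "siadat2":
        for fam in ADAT_FAMILIES.values():
            dwell[fam["nnc"]] *= 2.0
            dwell[fam["nnt"]] /= 1.3
        return dwell * 1.5
    raise ValueError(f"unknown preset {name!r}")


# ---------------------------------------------------------------------------
# transcriptome
# ---------------------------------------------------------------------------

def generate_transcriptome(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[dict[str, TranscriptAnnotation], dict]:
    """Random ORFs with exact per-gene ADAT-NNC codon content.

    Each gene draws a target NNC content from the configured Beta
    distribution; exactly round(target x n_internal) internal codons are
    ADAT NNC codons (uniform over the eight), the rest are uniform over the
    other sense codons, so the realized content matches the target to within
    half a codon.  ORFs start with ATG, end with TAA, contain no internal
    stop, and carry random UTRs on both sides.
    """
    rng = config.rng() if rng is None else rng
    a, b = config.nnc_content_beta
    transcripts: dict[str, TranscriptAnnotation] = {}
    truth: dict = {"genes": {}}
    nnc_list = sorted(ADAT_NNC_CODONS)
    for i in range(config.n_genes):
        tid = f"gene{i:04d}"
        n = int(
            np.clip(
                rng.lognormal(np.log(config.mean_gene_length_codons), config.gene_length_sigma),
                config.min_gene_length_codons,
                None,
            )
        )
        target = float(rng.beta(a, b))
        n_internal = n - 1  # ATG start is fixed
        n_nnc = int(round(target * n_internal))
        codons = np.array(
            [nnc_list[k] for k in rng.integers(0, len(nnc_list), n_nnc)]
            + [_BACKGROUND_CODONS[k]
               for k in rng.integers(0, len(_BACKGROUND_CODONS), n_internal - n_nnc)],
            dtype=object,
        )
        rng.shuffle(codons)
        orf = "ATG" + "".join(codons) + "TAA"
        utr5 = "".join(rng.choice(list("ACGT"), config.utr_length))
        utr3 = "".join(rng.choice(list("ACGT"), config.utr_length))
        transcripts[tid] = TranscriptAnnotation(
            transcript_id=tid,
            sequence=utr5 + orf + utr3,
            orf_start=config.utr_length + 1,
        )
        truth["genes"][tid] = {
            "n_codons": n,
            "target_nnc_content": target,
            "realized_nnc_content": n_nnc / n,
        }
    return transcripts, truth


def generate_mrna_levels(
    config: SimulationConfig, transcripts: Mapping[str, TranscriptAnnotation],
    rng: np.random.Generator | None = None,
) -> pd.Series:
    """Log-normal relative mRNA abundances (mean 1 on the log scale)."""
    rng = config.rng() if rng is None else rng
    vals = rng.lognormal(0.0, config.mrna_log_sigma, len(transcripts))
    return pd.Series(vals, index=list(transcripts))


def simulate_mrna_rpkm(
    transcripts: Mapping[str, TranscriptAnnotation],
    mrna_levels: pd.Series,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> pd.Series:
    """Uniform-coverage mRNA-seq: multinomial reads per gene, reported as RPKM."""
    rng = config.rng() if rng is None else rng
    tids = list(transcripts)
    lengths = np.array([len(transcripts[t].sequence) for t in tids], dtype=float)
    weights = mrna_levels[tids].to_numpy() * lengths
    counts = rng.multinomial(config.mrna_library_size, weights / weights.sum())
    rpkm = counts / (lengths / 1e3) / (config.mrna_library_size / 1e6)
    return pd.Series(rpkm, index=tids)


# ---------------------------------------------------------------------------
# ribosome footprints
# ---------------------------------------------------------------------------

def simulate_rpf_reads(
    transcripts: Mapping[str, TranscriptAnnotation],
    dwell: pd.Series,
    mrna_levels: pd.Series,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[list[RPFAlignment], dict]:
    """Footprint alignments with A sites sampled ∝ mRNA level x codon dwell.

    A-site codons are drawn from each ORF's analysis window (codons 16 to
    n-15); the 5' end is placed 15 nt upstream of the A-site codon, read
    lengths are drawn from the configured set, and with probability
    ``frame_error_rate`` the 5' end is shifted +/-1 nt (an out-of-frame
    read).  Truth records each read's intended gene and A-site codon index.
    """
    rng = config.rng() if rng is None else rng
    dwell = dwell.reindex(SENSE_CODONS).astype(float)
    tids = list(transcripts)
    gene_windows: dict[str, np.ndarray] = {}
    gene_weights = np.zeros(len(tids))
    for gi, tid in enumerate(tids):
        ann = transcripts[tid]
        codons = ann.cds_codons
        n = len(codons)
        if n <= 30:
            continue
        idx = np.arange(15, n - 15)
        w = dwell[[codons[j] for j in idx]].to_numpy()
        gene_windows[tid] = np.stack([idx, w])
        gene_weights[gi] = mrna_levels[tid] * w.sum()
    probs = gene_weights / gene_weights.sum()
    per_gene = rng.multinomial(config.rpf_library_size, probs)
    alignments: list[RPFAlignment] = []
    truth_rows = []
    read_no = 0
    for gi, tid in enumerate(tids):
        if per_gene[gi] == 0 or tid not in gene_windows:
            continue
        ann = transcripts[tid]
        idx, w = gene_windows[tid]
        codon_choice = rng.choice(len(idx), size=per_gene[gi], p=w / w.sum())
        lengths = rng.choice(config.read_lengths, size=per_gene[gi])
        frame_err = rng.random(per_gene[gi]) < config.frame_error_rate
        shifts = rng.choice([-1, 1], size=per_gene[gi])
        for k in range(per_gene[gi]):
            j = int(idx[codon_choice[k]])
            five_prime = ann.orf_start + 3 * j - 15  # 1-based
            if frame_err[k]:
                five_prime += int(shifts[k])
            alignments.append(
                RPFAlignment(
                    read_id=f"rpf{read_no:07d}",
                    transcript_id=tid,
                    five_prime_pos=five_prime,
                    read_length=int(lengths[k]),
                )
            )
            truth_rows.append((tid, j + 1, bool(frame_err[k])))
            read_no += 1
    truth = {
        "reads": pd.DataFrame(
            truth_rows, columns=["transcript_id", "a_site_codon_index", "frame_error"]
        ),
        "dwell": dwell,
    }
    return alignments, truth


def rpf_read_sequence(aln: RPFAlignment, transcripts: Mapping[str, TranscriptAnnotation]) -> str:
    seq = transcripts[aln.transcript_id].sequence
    return seq[aln.five_prime_pos - 1: aln.five_prime_pos - 1 + aln.read_length]


# ---------------------------------------------------------------------------
# tRNA references and tRNA-seq
# ---------------------------------------------------------------------------

def make_trna_references(
    rng: np.random.Generator, length: int = 76, wobble_index: int = 33
) -> list[TRNAReference]:
    """Synthetic mature tRNA references for the eight ADAT families.

    Random backbones with the family's ANN anticodon (DNA alphabet) placed
    so its first base sits at ``wobble_index``; backbones are resampled if
    two references end up closer than 10 mismatches so unique mapping is
    well defined.
    """
    refs: list[TRNAReference] = []
    seqs: list[str] = []
    for name, fam in ADAT_FAMILIES.items():
        anticodon_dna = fam["anticodon"].replace("U", "T")
        while True:
            backbone = rng.choice(list("ACGT"), length)
            backbone[wobble_index:wobble_index + 3] = list(anticodon_dna)
            seq = "".join(backbone)
            if all(sum(a != b for a, b in zip(seq, s)) >= 10 for s in seqs):
                break
        seqs.append(seq)
        refs.append(
            TRNAReference(
                trna_id=f"tRNA-{name}-{fam['anticodon']}",
                amino_acid=fam["aa"],
                anticodon=fam["anticodon"],
                sequence=seq,
                wobble_index=wobble_index,
            )
        )
    return refs


def simulate_trnaseq_reads(
    refs: Sequence[TRNAReference],
    editing_rates: Mapping[str, float],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    read_length: int = 36,
) -> tuple[list[tuple[str, str]], dict]:
    """tRNA-seq reads covering the anticodon, with wobble A->G editing.

    Each read copies a window of its reference that covers the wobble
    position; with probability e(family) the wobble A is written as G
    (inosine reads as G), then uniform sequencing errors are applied.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    reads: list[tuple[str, str]] = []
    truth = {"editing_rates": dict(editing_rates), "n_edited": {}}
    bases = np.array(list("ACGT"))
    for ref in refs:
        e = float(editing_rates.get(ref.trna_id, 0.0))
        depth = config.trnaseq_depth_per_family
        lo = max(0, ref.wobble_index - (read_length - 3))
        hi = min(ref.wobble_index, len(ref.sequence) - read_length)
        starts = rng.integers(lo, hi + 1, size=depth)
        edited = rng.random(depth) < e
        n_err = 0
        for k in range(depth):
            s = int(starts[k])
            read = list(ref.sequence[s:s + read_length])
            w = ref.wobble_index - s
            if edited[k] and read[w] == "A":
                read[w] = "G"
            errs = rng.random(read_length) < config.sequencing_error_rate
            for pos in np.nonzero(errs)[0]:
                read[pos] = rng.choice(bases[bases != read[pos]])
                n_err += 1
            reads.append((f"{ref.trna_id}_read{k}", "".join(read)))
        truth["n_edited"][ref.trna_id] = int(edited.sum())
    return reads, truth


# ---------------------------------------------------------------------------
# proteome
# ---------------------------------------------------------------------------

def translation_efficiency(
    transcripts: Mapping[str, TranscriptAnnotation], dwell: pd.Series, kappa: float
) -> pd.Series:
    """TE_g = exp(-kappa x mean log dwell over the gene's codons).

    Genes rich in slow codons elongate less efficiently; kappa scales how
    strongly dwell-time composition couples to protein output.
    """
    dwell = dwell.reindex(SENSE_CODONS).astype(float)
    log_dwell = np.log(dwell)
    out = {}
    for tid, ann in transcripts.items():
        codons = pd.Series(ann.cds_codons)
        content = codons.value_counts(normalize=True)
        out[tid] = float(np.exp(-kappa * (content * log_dwell[content.index]).sum()))
    return pd.Series(out)


def simulate_expression_and_proteome(
    transcripts: Mapping[str, TranscriptAnnotation],
    dwell_a: pd.Series,
    dwell_b: pd.Series,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    n_replicates: int = 2,
) -> dict:
    """Two-condition proteome: mRNA fold changes, peptide ratio tables, truth.

    Protein output per condition is mRNA x TE(dwell) x log-normal noise; the
    reported ratios are condition-b over condition-a (the knockdown over
    wild type, i.e. 14N/15N).  Because the labeling experiment mixes the two
    protein extracts 1:1 before digestion, the observable ratios are
    relative: fold changes are centered by their geometric mean, so genes
    whose elongation slows less than average come out up-regulated even
    under a global slowdown.  Each replicate redraws the noise; each
    protein's peptide ratios scatter log-normally around its fold change.
    """
    rng = config.rng() if rng is None else rng
    tids = list(transcripts)
    te_a = translation_efficiency(transcripts, dwell_a, config.te_coupling_kappa)
    te_b = translation_efficiency(transcripts, dwell_b, config.te_coupling_kappa)
    mrna_fc = pd.Series(
        rng.lognormal(0.0, config.replicate_log_sigma, len(tids)), index=tids
    )
    true_te_fc = (te_b / te_a)[tids]
    true_te_fc = true_te_fc / np.exp(np.log(true_te_fc).mean())  # 1:1 mixing
    replicates = []
    lo, hi = config.peptides_per_protein
    for _ in range(n_replicates):
        noise = rng.lognormal(0.0, config.replicate_log_sigma, len(tids))
        protein_fc = mrna_fc.to_numpy() * true_te_fc.to_numpy() * noise
        rows = []
        for gi, tid in enumerate(tids):
            n_pep = int(rng.integers(lo, hi + 1))
            ratios = protein_fc[gi] * rng.lognormal(0.0, config.peptide_log_sigma, n_pep)
            rows += [
                {"protein_id": tid, "peptide_id": f"{tid}_pep{k}", "ratio": r}
                for k, r in enumerate(ratios)
            ]
        replicates.append(pd.DataFrame(rows))
    return {
        "mrna_fc": mrna_fc,
        "peptide_tables": replicates,
        "truth": {"te_fc": true_te_fc, "te_a": te_a, "te_b": te_b},
    }


# ---------------------------------------------------------------------------
# reporter construct trio (synthetic stand-in for the luciferase set)
# ---------------------------------------------------------------------------

def make_reporter_trio(
    rng: np.random.Generator,
    n_codons: int = 550,
    optimal_codons: Mapping[str, str] | None = None,
) -> tuple[str, str, str, dict]:
    """Synthetic WT / codon-optimized / NNC->NNU reporter coding sequences.

    Stands in for a reporter-optimization experiment: 'opt' replaces every
    non-optimal codon of the random 'wt' ORF with its family's optimal codon
    (here: the ADAT NNC codon where the family has one, else the
    lexicographically first synonymous codon); 'opt_c2t' then swaps every
    ADAT NNC codon back to its synonymous NNU codon.  The returned truth
    holds the exact change counts for recovery tests.
    """
    if optimal_codons is None:
        optimal_codons = {}
        nnc_by_aa = {ADAT_FAMILIES[f]["aa"]: ADAT_FAMILIES[f]["nnc"] for f in ADAT_FAMILIES}
        for aa, codons in SYNONYMOUS_FAMILIES.items():
            optimal_codons[aa] = nnc_by_aa.get(aa, codons[0])
    wt_codons = ["ATG"] + [
        _BACKGROUND_CODONS[k]
        for k in rng.integers(0, len(_BACKGROUND_CODONS), n_codons - 1)
    ]
    opt_codons = [optimal_codons[CODON_TO_AA[c]] for c in wt_codons]
    n_optimized = sum(a != b for a, b in zip(wt_codons, opt_codons))
    nnc_to_nnt = {ADAT_FAMILIES[f]["nnc"]: ADAT_FAMILIES[f]["nnt"] for f in ADAT_FAMILIES}
    c2t_codons = [nnc_to_nnt.get(c, c) for c in opt_codons]
    n_nnc_changed = sum(a != b for a, b in zip(opt_codons, c2t_codons))
    stop = "TAA"
    return (
        "".join(wt_codons) + stop,
        "".join(opt_codons) + stop,
        "".join(c2t_codons) + stop,
        {"n_optimized": n_optimized, "n_nnc_to_nnt": n_nnc_changed},
    )


# ---------------------------------------------------------------------------
# tRNA pool for wobble-correlation experiments
# ---------------------------------------------------------------------------

def make_trna_pool(rng: np.random.Generator) -> "TRNAPool":
    """A synthetic genome's tRNA gene complement.

    Follows the eukaryotic pattern: the eight ADAT boxes carry only their
    ANN anticodon (I34 editing is what makes the NNC codons readable there),
    while elsewhere NNC codons are read by GNN anticodons (which also reach
    the NNU codon through G:U wobble) and NNA/NNG codons by their
    Watson-Crick anticodons.  Switching I34 off therefore leaves the ADAT
    NNC codons poorly decoded while the rest of the genome is unaffected.
    """
    from .codon_model import TRNAPool, TRNAGene
    from .genetic_code import RNA_COMPLEMENT, dna_to_rna

    adat_aas = {fam["aa"] for fam in ADAT_FAMILIES.values()}
    adat_boxes = {fam["nnc"][:2] for fam in ADAT_FAMILIES.values()}
    entries: list[TRNAGene] = []
    # ADAT-family ANN anticodons are among the highest-copy tRNA genes in
    # eukaryotic genomes (each serves a whole 4-codon box of an abundant
    # amino acid), so they draw from a higher copy-number range
    for name, fam in ADAT_FAMILIES.items():
        entries.append(TRNAGene(fam["aa"], fam["anticodon"], int(rng.integers(12, 31))))
    for aa, codons in SYNONYMOUS_FAMILIES.items():
        for codon in codons:
            if aa in adat_aas and codon[:2] in adat_boxes:
                continue  # the ADAT box is served by the ANN anticodon only
            if codon.endswith("T") and (codon[:2] + "C") in codons:
                continue  # NNU read via G:U wobble by the NNC decoder's GNN anticodon
            anticodon = "".join(
                RNA_COMPLEMENT[b] for b in reversed(dna_to_rna(codon))
            )
            entries.append(TRNAGene(aa, anticodon, int(rng.integers(3, 12))))
    return TRNAPool(entries)


def usage_tracking_weights(
    weights: pd.Series,
    rng: np.random.Generator,
    total_codons: int = 200_000,
    noise_log_sigma: float = 0.25,
) -> "pd.Series":
    """Codon counts whose frequencies track a decoding-weight vector.

    Counts are multinomial with probabilities proportional to weight x
    log-normal noise; codons with zero weight get a small floor so every
    sense codon appears (as in a real genome).
    """
    w = weights.reindex(SENSE_CODONS).astype(float).to_numpy()
    w = np.maximum(w, w[w > 0].min() * 0.05)
    p = w * rng.lognormal(0.0, noise_log_sigma, len(w))
    counts = rng.multinomial(total_codons, p / p.sum())
    return pd.Series(counts, index=list(SENSE_CODONS))
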