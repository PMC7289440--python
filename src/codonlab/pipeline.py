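"""End-to-end orchestration of the synthetic two-condition experiment.

``run_pipeline`` simulates a wild-type and an editing-knockdown condition
from one :class:`~codonlab.synthetic_data.SimulationConfig`, runs every
analysis stage (editing quantification, codon occupancy, ribosome density,
TE integration, PLSR) and writes the stage tables plus a run manifest that
makes the run reproducible byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import codon_model, expression_te, ribo_occupancy, synthetic_data, trna_editing
from .genetic_code import ADAT_FAMILIES, SENSE_CODONS
from .ribo_occupancy import FilterLog

logger = logging.getLogger("codonlab")

#: editing rates used for the two simulated conditions: near-complete in the
#: wild type, collapsed to family-dependent residual levels after knockdown
WT_EDITING = 0.98
SIADAT2_EDITING = {
    "Ala": 0.02, "Ser": 0.02, "Thr": 0.02,           # near-abolished
    "Arg": 0.3, "Ile": 0.4, "Leu": 0.25, "Pro": 0.5, "Val": 0.15,
}


def _hash_file(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(
    config: synthetic_data.SimulationConfig,
    out_dir: str | Path,
) -> dict:
    """Simulate both conditions and run every analysis stage.

    Writes, under ``out_dir``: occupancy tables per site and condition,
    the per-codon delta table, density classes, editing profiles, the TE
    table, PLSR loadings, and ``manifest.json``.  Returns the in-memory
    results keyed by stage.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = config.rng()

    # --- transcriptome and expression -----------------------------------
    transcripts, tx_truth = synthetic_data.generate_transcriptome(config, rng)
    mrna_levels = synthetic_data.generate_mrna_levels(config, transcripts, rng)
    mrna_rpkm = synthetic_data.simulate_mrna_rpkm(transcripts, mrna_levels, config, rng)

    profiles = pd.DataFrame(
        {
            tid: codon_model.count_codons(
                ann.sequence[ann.orf_start - 1: ann.orf_start - 1 + 3 * (ann.n_codons + 1)]
            ).counts
            for tid, ann in transcripts.items()
        }
    ).T
    nnc_content = profiles.apply(codon_model.adat_nnc_content, axis=1)
    genome_usage = codon_model.CodonUsageTable(profiles.sum(axis=0), scope="synthetic genome")
    optimal = codon_model.optimal_codons_from_usage(genome_usage)
    cbi_values = profiles.apply(lambda row: codon_model.cbi(row, optimal), axis=1)

    # --- ribosome profiling, both conditions ----------------------------
    results: dict = {"transcripts": transcripts, "mrna_rpkm": mrna_rpkm,
                     "nnc_content": nnc_content, "cbi": cbi_values}
    occupancy = {}
    tracks_by_cond = {}
    for cond in ("wt", "siadat2"):
        dwell = synthetic_data.dwell_preset(cond)
        alignments, _ = synthetic_data.simulate_rpf_reads(
            transcripts, dwell, mrna_levels, config, rng
        )
        log = FilterLog()
        tracks = ribo_occupancy.build_density_tracks(alignments, transcripts, log)
        logger.info("condition %s read accounting: %s", cond, log.counts)
        tracks_by_cond[cond] = tracks
        site_tables = {}
        for site in ribo_occupancy.SITE_OFFSETS:
            rel = ribo_occupancy.relative_codon_occupancy(tracks, site=site)
            rel["z"] = ribo_occupancy.zscore_by_family(rel["occupancy"])
            rel["absolute"] = ribo_occupancy.absolute_codon_occupancy(
                tracks, mrna_rpkm, config.rpf_library_size, site=site
            )
            site_tables[site] = rel
            rel.to_csv(out / f"occupancy_{cond}_{site.replace('+', 'p')}.tsv", sep="\t")
        occupancy[cond] = site_tables
        (out / f"filter_log_{cond}.json").write_text(json.dumps(log.counts, indent=1))
    results["occupancy"] = occupancy

    delta = pd.DataFrame(
        {
            site: ribo_occupancy.delta_relative_occupancy(
                occupancy["wt"][site]["occupancy"], occupancy["siadat2"][site]["occupancy"]
            )
            for site in ribo_occupancy.SITE_OFFSETS
        }
    )
    delta.to_csv(out / "delta_relative_occupancy.tsv", sep="\t")
    results["delta"] = delta

    # --- ribosome density ------------------------------------------------
    dens = {
        cond: ribo_occupancy.density_table(tracks_by_cond[cond], config.rpf_library_size, mrna_rpkm)
        for cond in tracks_by_cond
    }
    dens_fc = ribo_occupancy.density_fold_change(dens["wt"]["density"], dens["siadat2"]["density"])
    dens_fc.to_csv(out / "density_fold_change.tsv", sep="\t")
    density_windows = expression_te.sliding_window_fraction(
        dens_fc["density_class"], nnc_content, window_size=min(100, max(2, config.n_genes // 2))
    )
    density_windows.to_csv(out / "density_sliding_window.tsv", sep="\t", index=False)
    results["density"] = dens_fc

    # --- tRNA editing -----------------------------------------------------
    refs = synthetic_data.make_trna_references(rng)
    editing_tables = {}
    for cond in ("wt", "siadat2"):
        rates = {
            r.trna_id: (WT_EDITING if cond == "wt"
                        else SIADAT2_EDITING[r.trna_id.split("-")[1]])
            for r in refs
        }
        reads, _ = synthetic_data.simulate_trnaseq_reads(refs, rates, config, rng)
        alns = trna_editing.map_trna_reads(reads, refs)
        table = trna_editing.editing_table(alns, refs)
        table.to_csv(out / f"editing_{cond}.tsv", sep="\t")
        editing_tables[cond] = table
    results["editing"] = editing_tables

    # --- proteome and TE --------------------------------------------------
    sim = synthetic_data.simulate_expression_and_proteome(
        transcripts, synthetic_data.dwell_preset("wt"),
        synthetic_data.dwell_preset("siadat2"), config, rng,
    )
    rep_fc = []
    for rep in sim["peptide_tables"]:
        agg = expression_te.aggregate_peptide_table(rep)
        rep_fc.append(agg.loc[agg["pass_filter"], "geometric_mean"])
    concordant = expression_te.concordance_filter(rep_fc[0], rep_fc[1])
    te = expression_te.te_table(concordant["fold_change"], sim["mrna_fc"])
    te["cbi"] = cbi_values
    te["nnc_content"] = nnc_content
    te.to_csv(out / "te_table.tsv", sep="\t")
    results["te"] = te

    te_windows = expression_te.sliding_window_fraction(
        te["te_class"], te["nnc_content"], window_size=min(200, max(2, config.n_genes // 2))
    )
    te_windows.to_csv(out / "te_sliding_window.tsv", sep="\t", index=False)

    changed = te[te["te_class"].isin(["up", "down"])]
    X = expression_te.codon_composition_matrix(profiles.loc[changed.index])
    plsr = expression_te.plsr_fit(X, np.log10(changed["te_fc"]), n_components=2)
    plsr.correlation_loadings.to_csv(out / "plsr_correlation_loadings.tsv", sep="\t")
    results["plsr"] = plsr

    # --- manifest ---------------------------------------------------------
    manifest = {
        "config": asdict(config),
        "seed": config.seed,
        "outputs": {
            p.name: _hash_file(p) for p in sorted(out.iterdir()) if p.name != "manifest.json"
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    results["manifest"] = manifest
    return results


# ---------------------------------------------------------------------------
# input validation
# ---------------------------------------------------------------------------

def validate_inputs(paths: Mapping[str, str | Path]) -> list[str]:
    """Well-formedness checks for user-supplied inputs.

    Accepted keys: 'orf_fasta', 'transcript_fasta' + 'orf_table', 'fastq',
    'trna_pool', 'peptides'.  Returns a list of human-readable issues; an
    empty list means everything validated.
    """
    from . import io as cio
    from .genetic_code import STOP_CODONS

    issues: list[str] = []
    if "orf_fasta" in paths:
        try:
            seqs = cio.read_fasta(paths["orf_fasta"])
        except Exception as exc:  # noqa: BLE001 - report, don't crash
            issues.append(f"orf_fasta: unreadable ({exc})")
            seqs = {}
        for name, seq in seqs.items():
            if len(seq) % 3:
                issues.append(f"orf_fasta: {name} length {len(seq)} not a multiple of 3")
                continue
            codons = [seq[i:i + 3] for i in range(0, len(seq), 3)]
            internal_stops = [i + 1 for i, c in enumerate(codons[:-1]) if c in STOP_CODONS]
            if internal_stops:
                issues.append(f"orf_fasta: {name} internal stop at codon {internal_stops[0]}")
    if "fastq" in paths:
        try:
            reads = cio.read_fastq(paths["fastq"])
            if not reads:
                issues.append("fastq: no records")
        except Exception as exc:  # noqa: BLE001
            issues.append(f"fastq: malformed ({exc})")
    if "transcript_fasta" in paths and "orf_table" in paths:
        try:
            anns = cio.read_annotations(paths["transcript_fasta"], paths["orf_table"])
            for tid, ann in anns.items():
                if not ann.cds_codons:
                    issues.append(f"annotations: {tid} has an empty ORF")
                elif ann.sequence[ann.orf_start - 1: ann.orf_start + 2] != "ATG":
                    issues.append(f"annotations: {tid} orf_start does not point at ATG")
        except Exception as exc:  # noqa: BLE001
            issues.append(f"annotations: {exc}")
    if "trna_pool" in paths:
        try:
            cio.read_trna_pool_tsv(paths["trna_pool"])
        except Exception as exc:  # noqa: BLE001
            issues.append(f"trna_pool: {exc}")
    if "peptides" in paths:
        try:
            cio.read_peptide_ratios(paths["peptides"])
        except Exception as exc:  # noqa: BLE001
            issues.append(f"peptides: {exc}")
    return issues
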