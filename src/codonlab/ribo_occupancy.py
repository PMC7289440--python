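"""Ribosome-profiling codon occupancy: A-site assignment, filtering, relative
and absolute per-codon occupancy, z-scores, ribosome density and transcript
profiles.

Conventions
-----------
* The ribosomal A site of a 28-32 nt footprint is nucleotides 16-18 counting
  the read's 5'-most base as position 1 (a fixed 15 nt offset for all
  lengths); E and P sites sit two and one codons upstream, A+1 one codon
  downstream.
* Out-of-frame reads are excluded, as are reads whose A site falls within the
  first or last 15 codons of the coding sequence (initiation/termination
  effects).
* Relative codon occupancy: reads at a codon divided by the ORF's mean
  per-codon read density, averaged over all instances of that codon
  genome-wide.  Within each synonymous family the values are z-scored
  ((x - mu)/delta, population standard deviation), which makes codon ranks
  comparable between libraries whose per-gene densities differ.
* Absolute codon occupancy: per-codon read counts normalized to library size
  and the gene's mRNA level (RPKM), summed over genes and divided by the
  codon's occurrence count in the analyzed windows.

All user-facing positions are 1-based; internal arrays are 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .genetic_code import CODON_FAMILY, SENSE_CODONS

#: codon-site offsets relative to the A site
SITE_OFFSETS: dict[str, int] = {"E": -2, "P": -1, "A": 0, "A+1": 1}

A_SITE_OFFSET_NT = 15       # 0-based: A-site codon starts at read nt 16
EDGE_EXCLUDE_CODONS = 15
MIN_READ_LEN, MAX_READ_LEN = 28, 32


@dataclass(frozen=True)
class RPFAlignment:
    read_id: str
    transcript_id: str
    five_prime_pos: int     # 1-based position of the read's 5' base on the transcript
    read_length: int
    unique: bool = True


@dataclass(frozen=True)
class TranscriptAnnotation:
    """A transcript with its ORF location.

    ``orf_start`` is the 1-based transcript position of the first base of the
    start codon; ``cds`` is the coding sequence including the stop codon.
    """

    transcript_id: str
    sequence: str
    orf_start: int

    @property
    def cds_codons(self) -> list[str]:
        """Sense codons from orf_start up to (excluding) the first in-frame stop."""
        from .genetic_code import STOP_CODONS

        seq = self.sequence[self.orf_start - 1:]
        out = []
        for i in range(0, len(seq) - len(seq) % 3, 3):
            codon = seq[i:i + 3]
            if codon in STOP_CODONS:
                break
            out.append(codon)
        return out

    @property
    def n_codons(self) -> int:
        return len(self.cds_codons)


@dataclass(frozen=True)
class SiteAssignment:
    transcript_id: str
    a_site_codon_index: int   # 1-based within the ORF
    in_frame: bool

    def site_codon_index(self, site: str) -> int:
        return self.a_site_codon_index + SITE_OFFSETS[site]


@dataclass
class GeneDensityTrack:
    """In-frame A-site read counts per codon of one ORF (stop excluded)."""

    transcript_id: str
    codons: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if len(self.counts) != len(self.codons):
            raise ValueError("counts/codons length mismatch")

    @property
    def window(self) -> slice:
        """Analysis window: everything but the first and last 15 codons."""
        return slice(EDGE_EXCLUDE_CODONS, len(self.codons) - EDGE_EXCLUDE_CODONS)

    @property
    def window_indices(self) -> np.ndarray:
        return np.arange(len(self.codons))[self.window]


@dataclass
class FilterLog:
    """Read accounting through each filter, in the order applied."""

    counts: dict[str, int] = field(default_factory=dict)

    def add(self, stage: str, n: int = 1) -> None:
        self.counts[stage] = self.counts.get(stage, 0) + n

    def as_series(self) -> pd.Series:
        return pd.Series(self.counts, dtype=int)


def assign_a_site(alignment: RPFAlignment, orf_start: int) -> SiteAssignment:
    """Locate the A-site codon of a footprint and check its reading frame."""
    a_nt = alignment.five_prime_pos + A_SITE_OFFSET_NT  # 1-based first base of A codon
    offset = a_nt - orf_start
    return SiteAssignment(
        transcript_id=alignment.transcript_id,
        a_site_codon_index=offset // 3 + 1,
        in_frame=(offset % 3 == 0),
    )


def frame_statistics(assignments: Iterable[SiteAssignment]) -> float:
    """Fraction of assignments whose A site is in the annotated frame."""
    flags = [a.in_frame for a in assignments]
    if not flags:
        raise ValueError("no assignments")
    return sum(flags) / len(flags)


def rpkm(read_count: float, feature_length_nt: int, library_size: int) -> float:
    """Reads per kilobase of feature per million mapped reads."""
    if feature_length_nt <= 0 or library_size <= 0:
        raise ValueError("feature length and library size must be positive")
    return read_count / (feature_length_nt / 1e3) / (library_size / 1e6)


def build_density_tracks(
    alignments: Iterable[RPFAlignment],
    annotations: Mapping[str, TranscriptAnnotation],
    log: FilterLog | None = None,
) -> dict[str, GeneDensityTrack]:
    """Accumulate in-frame A-site counts per codon for every annotated ORF.

    Applies, in order: uniqueness, the 28-32 nt length filter, frame check,
    and the requirement that the A site lands on a sense codon of the ORF.
    The edge-codon exclusion is positional (via each track's window), so the
    same tracks serve occupancy (windowed) and density (full ORF) summaries.
    """
    log = log if log is not None else FilterLog()
    tracks = {
        tid: GeneDensityTrack(tid, ann.cds_codons, np.zeros(ann.n_codons))
        for tid, ann in annotations.items()
    }
    for aln in alignments:
        log.add("input")
        if not aln.unique:
            log.add("dropped_multimapped")
            continue
        if not (MIN_READ_LEN <= aln.read_length <= MAX_READ_LEN):
            log.add("dropped_length")
            continue
        ann = annotations.get(aln.transcript_id)
        if ann is None:
            log.add("dropped_unknown_transcript")
            continue
        sa = assign_a_site(aln, ann.orf_start)
        if not sa.in_frame:
            log.add("dropped_out_of_frame")
            continue
        idx = sa.a_site_codon_index - 1
        if not 0 <= idx < ann.n_codons:
            log.add("dropped_outside_orf")
            continue
        tracks[aln.transcript_id].counts[idx] += 1
        log.add("retained")
    return tracks


def _eligible_tracks(
    tracks: Mapping[str, GeneDensityTrack], min_window_reads: int
) -> list[GeneDensityTrack]:
    out = []
    for t in tracks.values():
        if len(t.codons) <= 2 * EDGE_EXCLUDE_CODONS:
            continue
        w = t.counts[t.window]
        if w.sum() < min_window_reads or w.mean() == 0:
            continue
        out.append(t)
    return out


def relative_codon_occupancy(
    tracks: Mapping[str, GeneDensityTrack],
    site: str = "A",
    min_window_reads: int = 64,
    mode: str = "instance_mean",
) -> pd.DataFrame:
    """Genome-wide relative occupancy of each sense codon at one ribosomal site.

    For every instance of codon c at window position j of gene g, the
    instance value is counts[j - d] / mean_density(g), where d is the site's
    codon offset from the A site (reads whose site-of-interest is at j have
    their A site at j - d).  ``mode`` 'instance_mean' averages instance
    values; 'pooled' ratios summed counts over summed expected counts.

    Returns a frame indexed by codon with columns occupancy, n_instances and
    sem (standard error over instances; NaN in pooled mode).
    """
    d = SITE_OFFSETS[site]
    values: dict[str, list[float]] = {c: [] for c in SENSE_CODONS}
    num: dict[str, float] = {c: 0.0 for c in SENSE_CODONS}
    den: dict[str, float] = {c: 0.0 for c in SENSE_CODONS}
    for t in _eligible_tracks(tracks, min_window_reads):
        w = t.window_indices
        mean_g = t.counts[t.window].mean()
        lo, hi = w[0], w[-1]
        for j in w:
            if not lo <= j - d <= hi:
                continue
            c = t.codons[j]
            if c not in values:   # stop codon read-through positions
                continue
            x = t.counts[j - d]
            values[c].append(x / mean_g)
            num[c] += x
            den[c] += mean_g
    rows = []
    for c in SENSE_CODONS:
        n = len(values[c])
        if n == 0:
            rows.append({"codon": c, "occupancy": np.nan, "n_instances": 0, "sem": np.nan})
            continue
        if mode == "instance_mean":
            arr = np.asarray(values[c])
            occ = arr.mean()
            sem = arr.std(ddof=1) / np.sqrt(n) if n > 1 else np.nan
        elif mode == "pooled":
            occ = num[c] / den[c]
            sem = np.nan
        else:
            raise ValueError(f"unknown mode {mode!r}")
        rows.append({"codon": c, "occupancy": occ, "n_instances": n, "sem": sem})
    return pd.DataFrame(rows).set_index("codon")


def zscore_by_family(occupancy: pd.Series) -> pd.Series:
    """z-score each codon's occupancy within its synonymous family.

    z = (x - mu) / delta with mu and delta the mean and population standard
    deviation over the family's codons.  Single-codon or constant families
    are undefined (NaN).
    """
    z = pd.Series(np.nan, index=occupancy.index, dtype=float)
    seen: set[tuple[str, ...]] = set()
    for codon in occupancy.index:
        fam = CODON_FAMILY.get(codon)
        if fam is None or fam in seen:
            continue
        seen.add(fam)
        members = [c for c in fam if c in occupancy.index]
        x = occupancy[members].to_numpy(float)
        if len(x) < 2 or np.isnan(x).any():
            continue
        sd = x.std()  # population SD: the formula carries no Bessel correction
        if sd == 0:
            continue
        z[members] = (x - x.mean()) / sd
    return z


def absolute_codon_occupancy(
    tracks: Mapping[str, GeneDensityTrack],
    mrna_rpkm: Mapping[str, float],
    library_size: int,
    site: str = "A",
    min_window_reads: int = 0,
) -> pd.Series:
    """Library- and mRNA-normalized per-codon occupancy.

    For each gene, the site-attributed read count at every windowed codon
    instance is divided by library size and the gene's mRNA RPKM; the
    quotients are summed over genes and divided by the codon's total number
    of analyzed instances.  Genes with zero or missing RPKM are excluded.
    """
    d = SITE_OFFSETS[site]
    num = pd.Series(0.0, index=list(SENSE_CODONS))
    n_inst = pd.Series(0, index=list(SENSE_CODONS))
    for t in _eligible_tracks(tracks, min_window_reads):
        r = mrna_rpkm.get(t.transcript_id, 0.0)
        if not r or r <= 0:
            continue
        w = t.window_indices
        lo, hi = w[0], w[-1]
        for j in w:
            if not lo <= j - d <= hi:
                continue
            c = t.codons[j]
            if c not in num.index:
                continue
            num[c] += t.counts[j - d] / library_size / r
            n_inst[c] += 1
    out = pd.Series(np.nan, index=list(SENSE_CODONS))
    mask = n_inst > 0
    out[mask] = num[mask] / n_inst[mask]
    return out


def normalize_to_max(values: pd.Series) -> pd.Series:
    """Scale so the most occupied codon is 1 (lexicographic tie-break)."""
    finite = values.dropna()
    if finite.empty:
        raise ValueError("no finite values")
    top = min(finite.index[finite == finite.max()])
    return values / values[top]


def ribosome_density(rpf_rpkm: float, mrna_rpkm: float) -> float:
    """RPF RPKM over mRNA RPKM for one gene."""
    if mrna_rpkm <= 0:
        raise ValueError("ribosome density undefined for mrna_rpkm <= 0")
    return rpf_rpkm / mrna_rpkm


def classify_fold_change(fc: float, up: float = 2.0, down: float = 0.5) -> str:
    """'up' above the upper cutoff, 'down' below the lower, else 'unchanged'.

    Inequalities are strict: a fold change exactly at a cutoff is unchanged.
    """
    if np.isnan(fc):
        return "undefined"
    if fc > up:
        return "up"
    if fc < down:
        return "down"
    return "unchanged"


def density_table(
    tracks: Mapping[str, GeneDensityTrack],
    rpf_library_size: int,
    mrna_rpkm: Mapping[str, float],
) -> pd.DataFrame:
    """Per-gene in-frame RPF counts, RPF RPKM and ribosome density."""
    rows = []
    for tid, t in tracks.items():
        n_reads = float(t.counts.sum())
        rpf = rpkm(n_reads, 3 * len(t.codons), rpf_library_size)
        m = mrna_rpkm.get(tid, np.nan)
        rows.append(
            {
                "transcript_id": tid,
                "rpf_reads": n_reads,
                "rpf_rpkm": rpf,
                "mrna_rpkm": m,
                "density": rpf / m if m and m > 0 else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("transcript_id")


def density_fold_change(
    density_a: pd.Series,
    density_b: pd.Series,
    up: float = 2.0,
    down: float = 0.5,
) -> pd.DataFrame:
    """Per-gene density fold change b/a with up/down/unchanged classes."""
    genes = density_a.index.intersection(density_b.index)
    fc = density_b[genes] / density_a[genes]
    return pd.DataFrame(
        {"fold_change": fc, "density_class": [classify_fold_change(v, up, down) for v in fc]},
        index=genes,
    )


def transcript_occupancy_profile(
    alignments: Iterable[RPFAlignment],
    annotation: TranscriptAnnotation,
    library_size: int,
    mrna_rpkm_value: float,
) -> pd.Series:
    """Normalized per-codon A-site counts across the whole transcript.

    Codon positions are indexed relative to the annotated ORF start (codon 1
    is the start codon; 5'-UTR positions are <= 0), so upstream-ORF peaks are
    directly comparable to main-ORF signal.  Counts are divided by library
    size (per million) and the transcript's mRNA RPKM.
    """
    if mrna_rpkm_value <= 0:
        raise ValueError("mrna_rpkm must be positive")
    n_nt = len(annotation.sequence)
    first = -((annotation.orf_start - 1) // 3)
    last = (n_nt - annotation.orf_start) // 3 + 1
    index = range(first, last + 1)
    counts = pd.Series(0.0, index=list(index))
    for aln in alignments:
        if aln.transcript_id != annotation.transcript_id:
            continue
        sa = assign_a_site(aln, annotation.orf_start)
        if not sa.in_frame:
            continue
        idx = sa.a_site_codon_index
        if idx in counts.index:
            counts[idx] += 1
    return counts / (library_size / 1e6) / mrna_rpkm_value


def delta_relative_occupancy(occ_a: pd.Series, occ_b: pd.Series) -> pd.Series:
    """Per-codon difference of family z-scored occupancies, b minus a."""
    return zscore_by_family(occ_b) - zscore_by_family(occ_a)


def absolute_occupancy_fold_change(abs_a: pd.Series, abs_b: pd.Series) -> pd.Series:
    """Per-codon absolute-occupancy fold change b/a."""
    return abs_b / abs_a
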