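"""Codon counting, codon-bias metrics and wobble-aware tRNA decoding weights.

The central scientific object here is the relationship between a genome's
codon usage and its tRNA pool.  Because the wobble adenosine (position 34) of
eight tRNA families is deaminated to inosine (I34) by ADAT, those tRNAs read
not only their Watson-Crick NNU codon but also NNC and NNA codons.  The
decoding-weight machinery below makes that switch explicit: a ``WobbleRuleSet``
holds the allowed anticodon-34 : codon-3 pairings with efficiency weights, and
``include_i34`` controls whether ADAT-eligible A34 anticodons are treated as
I34.

Codons are DNA strings (T); anticodons are RNA strings (U), written 5'->3' so
the first anticodon base is position 34 and pairs with codon position 3.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .genetic_code import (
    ADAT_ANTICODONS,
    ADAT_FAMILIES,
    ADAT_NNC_CODONS,
    CODON_TO_AA,
    RNA_COMPLEMENT,
    SENSE_CODONS,
    STOP_CODONS,
    SYNONYMOUS_FAMILIES,
    rna_to_dna,
)


class InvalidSequenceError(ValueError):
    """Sequence contains characters outside ACGT or an internal stop codon."""


class FrameError(ValueError):
    """Sequence length is not a multiple of three."""


class UndefinedStatisticError(ValueError):
    """A statistic (correlation, CBI, ...) is undefined for this input."""


# ---------------------------------------------------------------------------
# codon usage
# ---------------------------------------------------------------------------

@dataclass
class CodonUsageTable:
    """Counts of the 61 sense codons for a gene or gene set.

    ``freq_per_thousand`` follows the convention of codon-usage databases:
    frequencies scaled so they sum to 1000 over the sense codons.
    """

    counts: pd.Series
    scope: str = ""

    def __post_init__(self) -> None:
        self.counts = self.counts.reindex(SENSE_CODONS, fill_value=0).astype(int)
        if (self.counts < 0).any():
            raise ValueError("codon counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def freq_per_thousand(self) -> pd.Series:
        total = self.total
        if total == 0:
            return pd.Series(np.nan, index=self.counts.index)
        return self.counts / total * 1000.0

    def __add__(self, other: "CodonUsageTable") -> "CodonUsageTable":
        return CodonUsageTable(self.counts + other.counts, scope=self.scope)


def count_codons(orf_sequence: str, scope: str = "") -> CodonUsageTable:
    """Tally the sense codons of an in-frame coding sequence.

    A terminal stop codon is dropped; an internal stop raises
    :class:`InvalidSequenceError`.  The empty string yields an all-zero table.
    """
    seq = orf_sequence.upper().replace("U", "T")
    if any(ch not in "ACGT" for ch in seq):
        raise InvalidSequenceError("sequence contains non-ACGT characters")
    if len(seq) % 3 != 0:
        raise FrameError(f"length {len(seq)} is not a multiple of 3")
    codons = [seq[i:i + 3] for i in range(0, len(seq), 3)]
    if codons and codons[-1] in STOP_CODONS:
        codons = codons[:-1]
    for i, c in enumerate(codons):
        if c in STOP_CODONS:
            raise InvalidSequenceError(f"internal stop codon {c} at codon {i + 1}")
    counts = pd.Series(codons, dtype=object).value_counts() if codons else pd.Series(dtype=int)
    return CodonUsageTable(counts.reindex(SENSE_CODONS, fill_value=0), scope=scope)


def orf_codons(orf_sequence: str) -> list[str]:
    """Split an ORF into codons, dropping a terminal stop (no validation)."""
    seq = orf_sequence.upper().replace("U", "T")
    codons = [seq[i:i + 3] for i in range(0, len(seq), 3)]
    if codons and codons[-1] in STOP_CODONS:
        codons = codons[:-1]
    return codons


# ---------------------------------------------------------------------------
# tRNA pool and wobble rules
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TRNAGene:
    amino_acid: str          # one-letter code
    anticodon: str           # RNA, 5'->3' (position 34 first)
    gene_copy_number: int

    def __post_init__(self) -> None:
        ac = self.anticodon.upper()
        if len(ac) != 3 or any(b not in "ACGU" for b in ac):
            raise ValueError(f"invalid RNA anticodon {self.anticodon!r}")
        object.__setattr__(self, "anticodon", ac)
        if self.gene_copy_number < 0:
            raise ValueError("gene copy number must be non-negative")


@dataclass
class TRNAPool:
    """Anticodon gene copy numbers, grouped by amino acid."""

    entries: list[TRNAGene]

    @classmethod
    def from_records(cls, records: Iterable[tuple[str, str, int]]) -> "TRNAPool":
        return cls([TRNAGene(aa, ac, n) for aa, ac, n in records])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TRNAPool":
        return cls.from_records(
            df[["amino_acid", "anticodon", "gene_copy_number"]].itertuples(index=False)
        )

    def copy_number(self, amino_acid: str, anticodon: str) -> int:
        return sum(
            e.gene_copy_number
            for e in self.entries
            if e.amino_acid == amino_acid and e.anticodon == anticodon.upper()
        )

    @property
    def total_copies(self) -> int:
        return sum(e.gene_copy_number for e in self.entries)

    def copy_number_fractions(self) -> pd.Series:
        """Gene copies of each (aa, anticodon) over total tRNA gene copies."""
        grouped: dict[tuple[str, str], int] = {}
        for e in self.entries:
            key = (e.amino_acid, e.anticodon)
            grouped[key] = grouped.get(key, 0) + e.gene_copy_number
        total = sum(grouped.values())
        if total == 0:
            raise ValueError("empty tRNA pool")
        idx = pd.MultiIndex.from_tuples(grouped.keys(), names=["amino_acid", "anticodon"])
        return pd.Series(list(grouped.values()), index=idx, dtype=float) / total


#: default pairing efficiencies (anticodon-34 base, codon-3 base) -> weight.
#: Watson-Crick contacts have weight 1; the wobble and inosine weights are
#: configurable conventions, not measured constants.
DEFAULT_PAIRING_WEIGHTS: dict[tuple[str, str], float] = {
    ("A", "T"): 1.0,
    ("C", "G"): 1.0,
    ("G", "C"): 1.0,
    ("U", "A"): 1.0,
    ("G", "T"): 0.41,   # G34 : U3 wobble
    ("U", "G"): 0.41,   # U34 : G3 wobble
    ("I", "C"): 0.28,
    ("I", "T"): 1.0,    # I34 : U3
    ("I", "A"): 0.9999,
}

WATSON_CRICK_PAIRS = (("A", "T"), ("C", "G"), ("G", "C"), ("U", "A"))


@dataclass(frozen=True)
class WobbleRuleSet:
    """Allowed anticodon-34 : codon-3 pairings with efficiency weights.

    ``include_i34`` switches the I34 interpretation of ADAT-eligible A34
    anticodons on or off; with it off, an A34 anticodon reads only the NNU
    codon (Watson-Crick A:U).
    """

    pairings: Mapping[tuple[str, str], float]
    include_i34: bool = True

    def __post_init__(self) -> None:
        for wc in WATSON_CRICK_PAIRS:
            if self.pairings.get(wc) != 1.0:
                raise ValueError(f"Watson-Crick pairing {wc} must be present with weight 1")
        for (ac34, c3), w in self.pairings.items():
            if ac34 == "I" and c3 == "G":
                raise ValueError("inosine does not pair with G")
            if not 0 < w <= 1:
                raise ValueError(f"pairing weight for {(ac34, c3)} outside (0, 1]")

    @classmethod
    def default(cls, include_i34: bool = True, include_gu_wobble: bool = True) -> "WobbleRuleSet":
        pairings = dict(DEFAULT_PAIRING_WEIGHTS)
        if not include_gu_wobble:
            pairings.pop(("G", "T"))
            pairings.pop(("U", "G"))
        return cls(pairings, include_i34=include_i34)

    @classmethod
    def binary(cls, include_i34: bool = True, include_gu_wobble: bool = True) -> "WobbleRuleSet":
        """Topology-only mode: every allowed pairing has weight 1."""
        base = cls.default(include_i34=include_i34, include_gu_wobble=include_gu_wobble)
        return cls({k: 1.0 for k in base.pairings}, include_i34=include_i34)


def _is_adat_eligible(amino_acid: str, anticodon: str) -> bool:
    if anticodon not in ADAT_ANTICODONS:
        return False
    return any(
        fam["anticodon"] == anticodon and fam["aa"] == amino_acid
        for fam in ADAT_FAMILIES.values()
    )


def decoding_weights(
    pool: TRNAPool,
    rules: WobbleRuleSet,
    editing: Mapping[str, float] | None = None,
) -> pd.Series:
    """Per-codon decoding weight: sum of pairing weight x gene copy number.

    Codon positions 1 and 2 must be Watson-Crick matched to anticodon
    positions 36 and 35; position 3 is scored by the rule set.  ``editing``
    optionally maps an ADAT anticodon (RNA) to its measured editing fraction
    e, splitting that anticodon's contribution into e x I34 + (1-e) x A34;
    with ``editing`` absent and ``include_i34`` true, e = 1 for all eligible
    anticodons.

    Returns a weight for every sense codon; codons with weight 0 are
    undecodable under the rule set (``weights[weights == 0]`` flags them) and
    are excluded from correlations downstream.
    """
    if not pool.entries:
        raise ValueError("empty tRNA pool")
    weights = pd.Series(0.0, index=list(SENSE_CODONS))
    for entry in pool.entries:
        if entry.gene_copy_number == 0:
            continue
        ac = entry.anticodon
        c1 = rna_to_dna(RNA_COMPLEMENT[ac[2]])
        c2 = rna_to_dna(RNA_COMPLEMENT[ac[1]])
        base34_fractions: dict[str, float] = {ac[0]: 1.0}
        if rules.include_i34 and _is_adat_eligible(entry.amino_acid, ac):
            e = 1.0 if editing is None else float(editing.get(ac, 1.0))
            base34_fractions = {"I": e, ac[0]: 1.0 - e}
        for base34, frac in base34_fractions.items():
            if frac <= 0:
                continue
            for codon3 in "ACGT":
                w = rules.pairings.get((base34, codon3))
                if w is None:
                    continue
                codon = c1 + c2 + codon3
                # near-cognate pairings that would change the amino acid are
                # not decoding events
                if CODON_TO_AA.get(codon) != entry.amino_acid:
                    continue
                weights[codon] += w * frac * entry.gene_copy_number
    return weights


def pool_usage_correlation(
    weights: pd.Series, usage: CodonUsageTable, undecodable: str = "drop"
) -> float:
    """Pearson correlation of per-codon decoding weight vs usage frequency.

    ``undecodable`` controls codons with zero weight under the rule set:
    'drop' restricts the correlation to decodable codons; 'zero' keeps them
    at weight 0, the convention of tRNA-copy-number-vs-usage scatter plots
    (a codon that loses its decoder when I34 is switched off then pulls the
    correlation down instead of leaving the plot).
    """
    if undecodable not in ("drop", "zero"):
        raise ValueError(f"unknown undecodable mode {undecodable!r}")
    freq = usage.freq_per_thousand
    w = weights.reindex(SENSE_CODONS).fillna(0)
    mask = (w > 0) if undecodable == "drop" else pd.Series(True, index=w.index)
    x = w[mask].to_numpy(float)
    y = freq[list(mask.index[mask])].to_numpy(float)
    if len(x) < 3:
        raise UndefinedStatisticError("need at least 3 decodable codons")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedStatisticError("zero variance on one axis")
    return float(stats.pearsonr(x, y).statistic)


# ---------------------------------------------------------------------------
# family-relative fractions (heat-map style summaries)
# ---------------------------------------------------------------------------

def _family_codon_box(family: str) -> list[str]:
    """Synonymous codons in the 4-codon box containing the ADAT anticodon."""
    fam = ADAT_FAMILIES[family]
    prefix = fam["nnc"][:2]
    return [prefix + b for b in "ACGT" if CODON_TO_AA.get(prefix + b) == fam["aa"]]


def family_relative_values(
    source: TRNAPool | CodonUsageTable,
    families: Mapping[str, Mapping[str, str]] = ADAT_FAMILIES,
) -> pd.DataFrame:
    """Within-family relative fractions for the eight ADAT families.

    For a tRNA pool, members are the anticodons of the family's amino acid
    whose Watson-Crick codon lies in the family's 4-codon box; for a codon
    usage table, members are the box's synonymous codons.  Rows sum to 1;
    a family with zero total yields NaN (undefined), not 0/0.
    """
    rows: dict[str, dict[str, float]] = {}
    for name, fam in families.items():
        box = _family_codon_box(name)
        if isinstance(source, TRNAPool):
            from .genetic_code import anticodon_to_codon
            members: dict[str, float] = {}
            for e in source.entries:
                if e.amino_acid != fam["aa"]:
                    continue
                if anticodon_to_codon(e.anticodon) in box:
                    members[e.anticodon] = members.get(e.anticodon, 0.0) + e.gene_copy_number
        else:
            members = {c: float(source.counts[c]) for c in box}
        total = sum(members.values())
        if total > 0:
            rows[name] = {m: v / total for m, v in members.items()}
        else:
            rows[name] = {m: np.nan for m in members}
    return pd.DataFrame.from_dict(rows, orient="index")


# ---------------------------------------------------------------------------
# codon-bias metrics
# ---------------------------------------------------------------------------

def optimal_codons_from_usage(usage: CodonUsageTable) -> frozenset[str]:
    """Most frequent synonymous codon per multi-codon amino acid.

    Ties break to the lexicographically smallest codon, which keeps the set
    deterministic across inputs.
    """
    optimal = set()
    for aa, codons in SYNONYMOUS_FAMILIES.items():
        if len(codons) < 2:
            continue
        counts = usage.counts[list(codons)]
        optimal.add(min(counts.index[counts == counts.max()]))
    return frozenset(optimal)


def cbi(counts: pd.Series | CodonUsageTable, optimal_codons: frozenset[str] | set[str]) -> float:
    """Codon bias index: (N_opt - N_ran) / (N_tot - N_ran).

    N_opt is the number of optimal codons used, N_ran the count expected if
    synonymous codons were chosen uniformly, and N_tot the total codons of
    amino acids with a synonymous choice.  1 means extreme bias toward the
    optimal set, 0 random usage; returns NaN for a gene with no synonymous
    choice (only Met/Trp).
    """
    if isinstance(counts, CodonUsageTable):
        counts = counts.counts
    counts = counts.reindex(SENSE_CODONS, fill_value=0)
    by_aa = {aa: sum(int(counts[c]) for c in codons) for aa, codons in SYNONYMOUS_FAMILIES.items()}
    n_opt = n_ran = 0.0
    n_tot = 0
    for aa, codons in SYNONYMOUS_FAMILIES.items():
        if len(codons) < 2 or by_aa[aa] == 0:
            continue
        n_optimal_members = sum(1 for c in codons if c in optimal_codons)
        if n_optimal_members != 1:
            raise ValueError(f"optimal set must contain exactly one codon for {aa}")
        n_tot += by_aa[aa]
        n_opt += sum(int(counts[c]) for c in codons if c in optimal_codons)
        n_ran += by_aa[aa] / len(codons)
    if n_tot == 0 or n_tot == n_ran:
        return float("nan")
    return (n_opt - n_ran) / (n_tot - n_ran)


def tai(
    counts: pd.Series | CodonUsageTable,
    weights: pd.Series,
    zero_weight_floor: float = 1e-4,
) -> float:
    """tRNA adaptation index: geometric mean of relative adaptiveness.

    Weights are rescaled so the best-decoded codon has adaptiveness 1;
    undecodable codons are floored at ``zero_weight_floor`` instead of
    collapsing the whole index to zero.
    """
    if isinstance(counts, CodonUsageTable):
        counts = counts.counts
    counts = counts.reindex(SENSE_CODONS, fill_value=0)
    total = int(counts.sum())
    if total == 0:
        raise ValueError("empty ORF")
    w = weights.reindex(SENSE_CODONS).fillna(0).to_numpy(float)
    if w.max() <= 0:
        raise ValueError("all decoding weights are zero")
    rel = np.maximum(w / w.max(), zero_weight_floor)
    n = counts.to_numpy(float)
    return float(np.exp(np.sum(n * np.log(rel)) / total))


def adat_nnc_content(counts: pd.Series | CodonUsageTable) -> float:
    """Fraction of a gene's codons that are ADAT-related NNC codons."""
    if isinstance(counts, CodonUsageTable):
        counts = counts.counts
    counts = counts.reindex(SENSE_CODONS, fill_value=0)
    total = int(counts.sum())
    if total == 0:
        raise ValueError("zero-length gene")
    return float(sum(int(counts[c]) for c in ADAT_NNC_CODONS) / total)


@dataclass
class OrfCodonProfile:
    orf_id: str
    codon_counts: pd.Series
    cbi: float
    tai: float
    adat_nnc_content: float


def profile_orf(
    orf_id: str,
    sequence: str,
    optimal_codons: frozenset[str] | set[str] | None = None,
    weights: pd.Series | None = None,
) -> OrfCodonProfile:
    usage = count_codons(sequence, scope=orf_id)
    return OrfCodonProfile(
        orf_id=orf_id,
        codon_counts=usage.counts,
        cbi=cbi(usage, optimal_codons) if optimal_codons is not None else float("nan"),
        tai=tai(usage, weights) if weights is not None else float("nan"),
        adat_nnc_content=adat_nnc_content(usage),
    )


# ---------------------------------------------------------------------------
# construct comparison (reporter codon accounting)
# ---------------------------------------------------------------------------

@dataclass
class CodonComparison:
    n_changed: int
    violations: list[tuple[int, str, str]] = field(default_factory=list)


def compare_orf_codons(orf_a: str, orf_b: str, mode: str = "all") -> CodonComparison:
    """Count codon positions that differ between two same-frame ORFs.

    mode='all' counts every differing position; mode='adat_nnc_to_nnt' counts
    positions where ``orf_a`` carries an ADAT-family NNC codon and ``orf_b``
    the synonymous NNU codon.  Positions whose difference is non-synonymous
    are reported as violations (1-based codon index) and not counted.
    """
    if mode not in ("all", "adat_nnc_to_nnt"):
        raise ValueError(f"unknown mode {mode!r}")
    a, b = orf_codons(orf_a), orf_codons(orf_b)
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)} codons")
    nnc_to_nnt = {ADAT_FAMILIES[f]["nnc"]: ADAT_FAMILIES[f]["nnt"] for f in ADAT_FAMILIES}
    n = 0
    violations = []
    for i, (ca, cb) in enumerate(zip(a, b), start=1):
        if ca == cb:
            continue
        if CODON_TO_AA.get(ca) != CODON_TO_AA.get(cb):
            violations.append((i, ca, cb))
            continue
        if mode == "all":
            n += 1
        elif nnc_to_nnt.get(ca) == cb:
            n += 1
    return CodonComparison(n_changed=n, violations=violations)
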