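"""Standard genetic code constants and the eight ADAT-related codon families.

Codons are stored in the DNA alphabet (T); anticodons in the RNA alphabet (U).
Conversion happens only at this boundary.
"""

from __future__ import annotations

from Bio.Data import CodonTable

_STANDARD = CodonTable.unambiguous_dna_by_id[1]

#: codon (DNA) -> one-letter amino acid, 61 sense codons
CODON_TO_AA: dict[str, str] = dict(_STANDARD.forward_table)

STOP_CODONS: frozenset[str] = frozenset(_STANDARD.stop_codons)

SENSE_CODONS: tuple[str, ...] = tuple(sorted(CODON_TO_AA))

#: amino acid -> tuple of synonymous codons (the "codon family")
SYNONYMOUS_FAMILIES: dict[str, tuple[str, ...]] = {}
for _codon, _aa in sorted(CODON_TO_AA.items()):
    SYNONYMOUS_FAMILIES.setdefault(_aa, ())
    SYNONYMOUS_FAMILIES[_aa] += (_codon,)

#: codon -> all codons of its synonymous family
CODON_FAMILY: dict[str, tuple[str, ...]] = {
    c: SYNONYMOUS_FAMILIES[aa] for c, aa in CODON_TO_AA.items()
}

# The eight eukaryotic tRNA families whose wobble adenosine (position 34) is
# deaminated to inosine by the ADAT2/ADAT3 heterodimer.  Each family is named
# by its amino acid; the ANN anticodon decodes the NNU codon by Watson-Crick
# pairing and, once edited to INN, additionally reads the NNC (and NNA) codons.
ADAT_FAMILIES: dict[str, dict[str, str]] = {
    "Ala": {"aa": "A", "nnc": "GCC", "nnt": "GCT", "anticodon": "AGC"},
    "Arg": {"aa": "R", "nnc": "CGC", "nnt": "CGT", "anticodon": "ACG"},
    "Ile": {"aa": "I", "nnc": "ATC", "nnt": "ATT", "anticodon": "AAU"},
    "Leu": {"aa": "L", "nnc": "CTC", "nnt": "CTT", "anticodon": "AAG"},
    "Pro": {"aa": "P", "nnc": "CCC", "nnt": "CCT", "anticodon": "AGG"},
    "Ser": {"aa": "S", "nnc": "TCC", "nnt": "TCT", "anticodon": "AGA"},
    "Thr": {"aa": "T", "nnc": "ACC", "nnt": "ACT", "anticodon": "AGU"},
    "Val": {"aa": "V", "nnc": "GTC", "nnt": "GTT", "anticodon": "AAC"},
}

ADAT_NNC_CODONS: frozenset[str] = frozenset(f["nnc"] for f in ADAT_FAMILIES.values())
ADAT_NNT_CODONS: frozenset[str] = frozenset(f["nnt"] for f in ADAT_FAMILIES.values())
ADAT_ANTICODONS: frozenset[str] = frozenset(f["anticodon"] for f in ADAT_FAMILIES.values())

RNA_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}


def dna_to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def rna_to_dna(seq: str) -> str:
    return seq.upper().replace("U", "T")


def anticodon_to_codon(anticodon_rna: str) -> str:
    """Watson-Crick codon (DNA) read by an anticodon (RNA, 5'->3').

    The anticodon pairs antiparallel: anticodon position 34 (its first base)
    reads codon position 3.
    """
    return rna_to_dna("".join(RNA_COMPLEMENT[b] for b in reversed(anticodon_rna.upper())))
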