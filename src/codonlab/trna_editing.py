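"""Quantify A-to-I editing at tRNA position 34 from tRNA-seq reads.

Inosine templates as G during reverse transcription, so the editing level of
an ADAT-substrate tRNA family is read out as the G fraction at the wobble
position among reads covering it.  The mapper is an exhaustive
substitution-only scan (reads are short and references few); a read is kept
only if it has a unique best hit with at most ``max_mismatch`` mismatches.
Mismatches at the annotated wobble position are exempt from that budget —
otherwise edited (A->G) reads would preferentially fail mapping and the
editing estimate would be biased downward.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

_BASE_ORDER = ("A", "C", "G", "U")


@dataclass(frozen=True)
class TRNAReference:
    """A mature tRNA sequence with its anticodon annotation.

    ``wobble_index`` is the 0-based offset of the first anticodon base
    (position 34 in conventional tRNA numbering) within ``sequence``; it is
    annotated per reference because mature tRNA lengths vary.  Sequences are
    stored in the DNA alphabet for alignment.
    """

    trna_id: str
    amino_acid: str
    anticodon: str  # RNA
    sequence: str   # DNA alphabet
    wobble_index: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", self.sequence.upper().replace("U", "T"))
        if not 0 <= self.wobble_index < len(self.sequence):
            raise ValueError("wobble_index outside reference sequence")


@dataclass(frozen=True)
class TRNAAlignment:
    read_id: str
    trna_id: str
    ref_offset: int      # 0-based offset of the read's first base on the reference
    n_mismatch: int      # mismatches outside the wobble position
    read_sequence: str


@dataclass
class EditingProfile:
    """Base composition at one reference position for one tRNA family."""

    trna_id: str
    depth: int
    proportions: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.depth > 0:
            total = sum(self.proportions.get(b, 0.0) for b in _BASE_ORDER)
            if abs(total - 1.0) > 1e-9:
                raise ValueError("proportions must sum to 1 when depth > 0")


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


def map_trna_reads(
    reads: Iterable[tuple[str, str]],
    refs: Sequence[TRNAReference],
    max_mismatch: int = 2,
) -> list[TRNAAlignment]:
    """Exhaustive Hamming-scan mapping of reads against tRNA references.

    ``reads`` is an iterable of (read_id, sequence).  For each read, every
    ungapped placement within every reference is scored by mismatch count,
    with the reference's wobble position excluded from the count.  The read
    is retained only if the minimum score is <= ``max_mismatch`` and is
    achieved in exactly one reference (equal-best hits in two references make
    the read ambiguous and it is dropped; equal-best placements within one
    reference take the smallest offset).
    """
    if not refs:
        raise ValueError("empty reference set")
    encoded = [(_encode(r.sequence), r) for r in refs]
    out: list[TRNAAlignment] = []
    # batch reads by length so each (reference, offset) pair is one vector op
    by_len: dict[int, list[tuple[str, str]]] = {}
    for read_id, seq in reads:
        s = seq.upper().replace("U", "T")
        by_len.setdefault(len(s), []).append((read_id, s))
    for L, batch in sorted(by_len.items()):
        Q = np.stack([_encode(s) for _, s in batch])          # n_reads x L
        n = len(batch)
        best = np.full(n, np.iinfo(np.int32).max, dtype=np.int32)
        best_ref = np.full(n, -1, dtype=np.int32)
        best_off = np.zeros(n, dtype=np.int32)
        ambiguous = np.zeros(n, dtype=bool)
        for ri, (ref_arr, ref) in enumerate(encoded):
            span = len(ref_arr) - L
            if span < 0:
                continue
            for off in range(span + 1):
                mm = (Q != ref_arr[off:off + L]).sum(axis=1).astype(np.int32)
                w = ref.wobble_index - off
                if 0 <= w < L:
                    mm -= (Q[:, w] != ref_arr[off + w]).astype(np.int32)
                better = mm < best
                tie = (mm == best) & (best_ref != ri)
                ambiguous[tie] = True
                ambiguous[better] = False
                best[better] = mm[better]
                best_ref[better] = ri
                best_off[better] = off
        for k, (read_id, s) in enumerate(batch):
            if ambiguous[k] or best_ref[k] < 0 or best[k] > max_mismatch:
                continue
            ref = encoded[best_ref[k]][1]
            out.append(TRNAAlignment(read_id, ref.trna_id, int(best_off[k]), int(best[k]), s))
    return out


def position_base_composition(
    alignments: Iterable[TRNAAlignment],
    ref: TRNAReference,
    position: int | None = None,
) -> EditingProfile:
    """Base composition over reads covering one reference position.

    ``position`` is 1-based on the reference; by default the annotated wobble
    position is used.  T in reads is reported as U.  Zero coverage yields
    depth 0 with empty (undefined) proportions.
    """
    pos0 = ref.wobble_index if position is None else position - 1
    counts = {b: 0 for b in _BASE_ORDER}
    for aln in alignments:
        if aln.trna_id != ref.trna_id:
            continue
        i = pos0 - aln.ref_offset
        if 0 <= i < len(aln.read_sequence):
            base = aln.read_sequence[i].replace("T", "U")
            if base in counts:
                counts[base] += 1
    depth = sum(counts.values())
    if depth == 0:
        return EditingProfile(trna_id=ref.trna_id, depth=0, proportions={})
    return EditingProfile(
        trna_id=ref.trna_id,
        depth=depth,
        proportions={b: counts[b] / depth for b in _BASE_ORDER},
    )


def editing_fraction(profile: EditingProfile, denominator: str = "AG") -> float:
    """Edited fraction from a wobble-position base profile.

    'AG' mode returns G/(A+G), treating C/U reads as sequencing-error floor;
    'all' returns G over all bases.  Returns NaN when undefined.
    """
    if profile.depth == 0:
        return float("nan")
    g = profile.proportions.get("G", 0.0)
    if denominator == "all":
        return g
    if denominator == "AG":
        a = profile.proportions.get("A", 0.0)
        if a + g == 0:
            return float("nan")
        return g / (a + g)
    raise ValueError(f"unknown denominator mode {denominator!r}")


def editing_table(
    alignments: Iterable[TRNAAlignment],
    refs: Sequence[TRNAReference],
    min_depth: int = 50,
) -> pd.DataFrame:
    """Per-family wobble base composition table (one row per reference).

    Columns: depth, pA, pC, pG, pU, editing_fraction; families under
    ``min_depth`` keep their counts but have editing_fraction set to NaN.
    """
    alignments = list(alignments)
    rows = []
    for ref in refs:
        prof = position_base_composition(alignments, ref)
        frac = editing_fraction(prof) if prof.depth >= min_depth else float("nan")
        rows.append(
            {
                "trna_id": ref.trna_id,
                "amino_acid": ref.amino_acid,
                "anticodon": ref.anticodon,
                "depth": prof.depth,
                **{f"p{b}": prof.proportions.get(b, float("nan")) for b in _BASE_ORDER},
                "editing_fraction": frac,
            }
        )
    return pd.DataFrame(rows).set_index("trna_id")
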