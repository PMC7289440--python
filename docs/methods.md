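# Methods

## The system being modeled

Eight eukaryotic tRNA families (Ala, Arg, Ile, Leu, Pro, Ser, Thr, Val)
carry an ANN anticodon whose wobble adenosine (position 34) is deaminated to
inosine by the ADAT2/ADAT3 heterodimer. Inosine pairs with codon
third-position C, U and A, so the edited INN anticodon is the decoder of the
heavily used NNC codons of these families; unedited A34 pairs only with U.
codonlab implements the analyses that characterize this system at four
levels: genome (codon usage vs tRNA pool), tRNA (editing level from
sequencing), ribosome (per-codon occupancy from footprints), and proteome
(translation-efficiency changes), plus the synthetic-data generators that
stand in for a wild-type vs *adat2*-knockdown experiment.

## Decoding weights and correlations

A `WobbleRuleSet` is a table of allowed (anticodon-34 base : codon-3 base)
pairings with efficiency weights in (0, 1]. Watson–Crick contacts always
have weight 1. The default non-WC weights are G34:U3 = U34:G3 = 0.41,
I:C = 0.28, I:U = 1.0, I:A = 0.9999; these are conventions (no measured
efficiencies exist for this system), so a topology-only "binary" mode (every
allowed pairing = 1) is provided and both modes are reported by the
analysis drivers. The decoding weight of a codon is
Σ over cognate anticodons of pairing-weight × gene copy number, with codon
positions 1–2 required to be WC-paired and near-cognate events that would
change the amino acid excluded. With `include_i34=True`, every
ADAT-eligible A34 anticodon is treated as fully edited; a measured
`EditingProfile` can instead interpolate each anticodon between its I34 and
A34 readings.

`pool_usage_correlation` is a plain Pearson correlation between per-codon
weight and usage frequency. Codons with zero weight under a rule set
("undecodable") can either be dropped (`undecodable="drop"`, the
contract default) or kept at weight zero (`"zero"`). The with/without-I34
contrast is computed in the "zero" mode: a codon that loses its decoder when
I34 is switched off must stay in the comparison at zero, exactly as it would
appear in a copy-number-vs-usage scatter plot — dropping it would silently
remove the very signal the contrast measures.

## Codon-bias metrics

* **CBI** = (N_opt − N_ran) / (N_tot − N_ran) over amino acids with a
  synonymous choice, where N_ran is the optimal-codon count expected under
  uniform synonymous usage. The optimal set is the most frequent synonymous
  codon per amino acid in a supplied genome usage table (ties broken
  lexicographically, so the set is deterministic). 1 = extreme bias,
  0 = random, negative = avoidance; genes with only Met/Trp are undefined
  (NaN).
* **tAI** is the geometric mean over an ORF's codons of relative
  adaptiveness (decoding weight / max weight). Codons with zero weight are
  floored at 1e-4 rather than collapsing the index to zero; the floor is a
  configurable numerical guard, not a biological claim.
* **ADAT-NNC content** is the count of the eight NNC codons over the gene's
  total codon count.

## tRNA-seq editing quantification

Reads are mapped by exhaustive ungapped scan against every reference at
every offset, keeping a read only when its best score (mismatch count) is
≤ 2 and is achieved in exactly one reference; equal-best placements within
one reference take the smallest offset, and ties across references drop the
read. Mismatches at the annotated wobble position are exempt from the
budget — without this exemption, edited (A→G) reads would preferentially
fail mapping and the editing estimate would be biased downward. The wobble
position is a per-reference annotation (`wobble_index`), because mature
tRNA lengths vary. Editing level is reported as G/(A+G) by default, with
C/U proportions retained as a sequencing-error floor; families below
`min_depth` (default 50) reads report composition but no editing fraction.
RT-stop artefacts, CCA trimming and other modifications are out of scope:
reads are assumed full-length over the anticodon.

## Ribosome profiling

The A site of a 28–32 nt footprint is nucleotides 16–18 with the 5′-most
base as position 1 — one fixed 15 nt offset for all lengths. Out-of-frame
reads are excluded, as are A sites outside the ORF and (positionally, via
each gene's analysis window) the first and last 15 codons. Genes need more
than 30 codons and ≥ 64 in-frame A-site reads in the window (configurable)
to enter occupancy statistics.

Relative occupancy of codon c at site S: for each windowed instance of c,
the A-site count of the read whose S site is that instance (at codon offset
−2/−1/0/+1 for E/P/A/A+1) divided by the gene's mean per-codon density;
the codon's value is the unweighted mean over instances genome-wide
(a pooled-ratio mode is also provided; the two differ only in gene
weighting). Family z-scores use the population SD (the defining formula has
no Bessel correction), computed within each synonymous family, so each
family has mean 0 and SD 1 by construction — this makes codon ranks
comparable between libraries but not absolute levels. For cross-condition
absolute comparisons, absolute occupancy divides each instance's count by
library size and the gene's mRNA RPKM, sums over genes and divides by the
codon's instance count; figure-style reports normalize to the most occupied
codon (lexicographic tie-break).

Ribosome density is RPF RPKM / mRNA RPKM per gene, classified between
conditions at fold 2 / 0.5 (strict inequalities). Transcript profiles keep
UTRs: per-codon A-site counts indexed relative to the ORF start (codon ≤ 0
is 5′ leader), normalized by library size and mRNA level, which makes
uORF-stall peaks directly comparable to main-ORF signal.

## Proteome and TE integration

Per-protein ¹⁴N/¹⁵N peptide ratios are aggregated as a geometric mean with
geometric SD; proteins with SD(geo) ≥ 1000 are discarded, and singleton
peptide sets take SD(geo) = 1 by convention. Replicates are combined only
when their fold changes lie on the same side of 1 (log-product > 0; a
replicate exactly at 1 drops the protein), averaging geometrically —
consistent with ratio-scale statistics; an arithmetic mode exists. TE fold
change is protein FC / mRNA FC, classified at 1.5 / 0.67 (strict); mRNA
classes use 2 / 0.5. CBI-group summaries use seven equal-width CBI
intervals (gene counts per group may be uneven; a quantile mode exists),
and sliding-window summaries move a 100- or 200-gene window one gene at a
time along the ADAT-NNC-content ranking.

PLSR regresses log10 TE fold change on the 61-codon composition
(per-gene counts over total; autoscaled columns) of TE-changed genes. The
latent-variable fit is scikit-learn's NIPALS `PLSRegression`;
explained-variance bookkeeping, correlation loadings (Pearson correlation
of each variable and of y with each component's scores, hence inside the
unit disk with the 50%-variance circle at √0.5), leave-one-out predictions
(refit on n−1 for every gene) and a collinearity report (|r| > 0.8 codon
pairs, which PLSR cannot disentangle) are computed here. Zero-variance
codon columns are dropped with a record.

## Synthetic study conditions

The generators define one fixed set of study conditions
(`SimulationConfig` defaults):

| parameter | default | rationale |
|---|---|---|
| genes | 200 | desk-scale stand-in for a fungal transcriptome |
| gene length | lognormal, median ≈ 300 codons, min 80 | typical fungal ORF lengths |
| target NNC content | Beta(2, 5) per gene | right-skewed spread around ≈ 0.29, the genomic scale of ADAT-NNC usage |
| mRNA levels | lognormal, σ = 1 | typical expression dynamic range |
| RPF library | 2 × 10⁵ reads, lengths 28–32, 10% frame errors | enough depth for per-codon statistics at this gene count |
| tRNA-seq | 10⁴ reads/family, 0.1% error | binomial SE ≈ 0.005 on editing levels |
| TE coupling κ | 2.5 | see below |
| replicate noise | lognormal σ = 0.1 | MS replicate scatter |

ORFs place exactly round(target × n) NNC codons (uniform over the eight)
among otherwise uniform non-NNC sense codons, so realized content equals
the target to within half a codon. Footprint A sites are drawn with
probability ∝ mRNA × dwell(codon) within the analysis window — a
steady-state approximation (read count proportional to dwell) without
ribosome traffic or collisions; the 5′ end sits 15 nt upstream, and frame
errors shift it ±1 nt. The knockdown dwell preset multiplies NNC dwell by
2.0, divides NNU dwell by 1.3 and applies a global 1.5× slowdown — these
are simulation parameters chosen to produce the expected direction of
change, not measured values.

Protein output is mRNA × TE × noise with
TE = exp(−κ · Σ_c content(c) · log dwell(c)). Because the labeling
experiment mixes the two extracts 1:1, only relative changes are
observable, so the generator centers fold changes by their geometric mean;
a uniform slowdown therefore leaves low-NNC genes relatively up-regulated,
as in the real design. κ = 2.5 makes knockdown TE fold changes span the
1.5/0.67 classification cutoffs proteome-wide, giving substantial up and
down classes as observed in real knockdown proteomes.

The tRNA gene pool generator gives ADAT ANN anticodons copy numbers of
12–30 versus 3–11 elsewhere, mirroring their high gene-copy rank in
eukaryotic genomes, and serves NNU codons outside ADAT boxes through G:U
wobble from the GNN decoder (no ANN), the common eukaryotic pattern.

**What passing tests show, and what they don't.** The generators share the
estimators' structural assumptions (fixed A-site offset, no ligation or
RNase bias, uniform sequencing error, no rRNA contamination, no RT stops).
Recovery on this synthetic data validates the estimators' correctness and
the pipeline's plumbing — not robustness to the biases of real libraries,
which must be assessed on real data.

## Numerical and degenerate-input conventions

Undefined statistics are NaN with the reason documented (zero-coverage
editing profiles, constant z-score families, Met/Trp-only CBI, zero-RPKM
genes); hard errors are reserved for malformed inputs (non-ACGT characters,
frame violations, internal stops, empty pools). Classification inequalities
are strict at every cutoff. Determinism: every generator is reproducible
from a seed, equal-score mapping ties are resolved by fixed rules, and the
pipeline manifest hashes every output so a re-run can be verified
byte-for-byte.

## Known limitations

* No per-read-length A-site offset calibration (a single 15 nt rule).
* The steady-state dwell model ignores ribosome queuing, initiation
  limitation and elongation-collision effects.
* The editing mapper is substitution-only (no indels) and assumes
  adaptor-trimmed, full-length-over-anticodon reads.
* CBI/tAI follow the definitions above; they are not bit-exact
  reimplementations of any particular legacy tool.
* The minimum-coverage gene filter (64 window reads) and the wobble
  pairing weights are conventions exposed in configuration.
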