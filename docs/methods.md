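# Methods

This note documents the models, numerical choices and known limits of the
`rlecfam` pipeline: in-frame tandem-repeat decomposition, motif/NJ family
typing, arrangement cataloguing, slippage inference and alternative-splicing
classification for a hypervariable C-type lectin gene family, plus the
synthetic generator that drives the test suite.

## The family architecture being modelled

All members share a six-exon/five-intron gene. The printed exon lengths
(160, 267, 159, 106, 108, 58 nt) are *coding* lengths: they sum to 858 nt,
exactly the ORF length of an eight-repeat member, so the 47-nt 5'UTR and
467-nt 3'UTR must sit inside exons 1 and 6 of the genomic representation.
The generator follows that reading. Exon 2 carries the repeat region; its
total length varies with copy number while exons 1, 3 and 6 are fixed, as
observed in the family. A nine-repeat member with array
33–30–30–30–30–30–33–30–33 therefore has a 279-nt region, an 894-nt ORF, a
297-aa protein and a 1408-nt cDNA — the package's canonical worked example.

## Repeat decomposition

**Period detection.** For each candidate period `p` (default 24–39 nt) the
score is the best adjacent-window identity
`max_o |{i ∈ [o, o+p): x_i = x_{i+p}}| / p` with `o + 2p ≤ n`. Windowing is
essential: a whole-sequence autocorrelation dilutes the signal with the
long non-repetitive flanks and fails at low copy numbers. Detection is
considered successful at score ≥ 0.8 (the same scale as the per-unit
identity threshold below).

**Consensus.** The public `build_consensus` is the textbook per-column
majority over period-phased windows (ties to the alphabetically first
base). Inside `decompose` a *localized* variant is used: windows are
accreted left and right of the best-matching window pair while they stay
≥ 60% identical to it, so flank sequence never votes. The consensus
recovered this way is an arbitrary rotation of the biological unit.

**Segmentation.** A dynamic program tiles one maximal contiguous region
with units of length `m−3`, `m` or `m+3` (intersected with the configured
unit lengths, default {30, 33}); each unit must align to the consensus at
identity ≥ 0.8, with the best single 3-nt indel found at any offset (frame
safety comes from the codon-multiple unit lengths, not from pinning indels
to codon boundaries — the first 33-nt unit of an array need not share the
ORF's codon phase). The objective is `2·matches − 3·[length ≠ m]`,
maximized; ties prefer fewer units, then the 5'-most region. The gap
penalty matters: without it a length-mismatched unit can "absorb" flank
bases into a free deletion and tie an exact tiling, and the 5'-most rule
would then pick the absorbed variant. The identity threshold 0.8 keeps the
divergent first/last units seen in real arrays while rejecting flank
sequence.

**Phase.** Because the detected consensus is rotated, `decompose` runs the
DP for every rotation and keeps the best tiling (ties: fewer units,
5'-most, smallest rotation). `decompose_family` fixes the rotation *once*,
on the member with the strongest period signal, and segments every member
against that single rotated consensus. A per-member rotation search is
wrong for family work: different members can settle on different phases,
and their units then become pairwise incomparable, corrupting the pattern
catalogue and slippage inference. The chosen phase offset is reported in
the output.

**Inherent boundary ambiguity.** When unit copies are identical and a flank
base coincidentally extends a rotated match, tilings shifted by ±1 nt score
identically; no algorithm can prefer one. Copy number, unit lengths,
arrangement patterns and the reconstruction invariant are unaffected; only
the exact flank/unit byte boundary can shift. `mask_repeats(snap=True)`
absorbs this by snapping a region start that is 1 nt off a codon boundary
to the nearest boundary before masking.

**Single-copy arrays.** A one-unit region has no tandem self-similarity and
is undetectable in isolation; it is segmented against the family consensus.
This is why `decompose_family` (shared consensus) rather than per-sequence
`decompose` is the supported entry point for family data.

## Typing and phylogeny

Repeat-encoded residues are removed (not replaced) before comparison, so
copy-number variation does not swamp the signal. The diagnostic 6-aa motif
is read at a configurable anchor — an 8-aa conserved context located by
exact then 1-mismatch search, plus an offset — rather than a fixed residue
index, because the motif's coordinate shifts with copy number. Members
whose anchor cannot be located are reported unassigned, never fatal.

Distances are p-distances (mismatches over valid columns; gap and X columns
excluded) on the masked alignment; synthetic families are pre-aligned by
construction (no-indel backbone), and unequal-length real input goes
through an explicitly experimental reference-projection alignment — a
dedicated MSA tool is the right answer for seriously gapped data.

NJ is the classic Saitou–Nei agglomeration: join the pair minimizing
`Q(i,j) = (n−2)d(i,j) − R_i − R_j`, branch lengths
`l_i = d/2 + (R_i−R_j)/(2(n−2))`, reduction
`d(u,k) = (d(i,k)+d(j,k)−d(i,j))/2`, closed-form three-point termination.
Ties resolve to the lowest index pair; negative branch lengths are clamped
to 0 with a logged warning. Bootstrap support is the replicate frequency of
each internal-edge bipartition under column resampling with replacement,
seeded. The test suite checks NJ against an exhaustive least-squares
topology search on additive matrices up to 7 taxa.

## Slippage classes

Events are inferred longer→shorter (contraction); expansion is the same
event with the direction flag, since sequence data cannot distinguish them.
The matcher enumerates all order-preserving matchings of the shorter
array's units into the longer's (every shorter unit must match at ≥ 90%
identity and equal length), preferring a single contiguous excised block,
then the 5'-most block. The five classes are evaluated in the order
5, 1, 2, 4, 3 — all-33 arrays first (most specific), the weakest 30-nt
condition last — with "at least" flank thresholds (prefix/suffix ≥ 1/3,
2/1, 1/1, 1/2 for classes 1–4), all configurable.

A practical caveat baked into the generator: if unit copies are byte
identical, every matching is optimal and flank signatures collapse to the
contiguous 5'-most choice, so class 3 (suffix exactly 1) can masquerade as
class 4. Real arrays are conserved but not identical; the generator gives
each unit copy two private substitutions (pairwise unit identity ≤ 87%,
identity to consensus ≥ 93%), which makes each copy individually
recognizable — both more realistic and necessary for unambiguous class
recovery.

## Splicing

Mapping is exact (the intended inputs are Sanger-grade, effectively
mismatch-free): a depth-first search assigns each exon a used contiguous
portion or skips it, preferring canonical full use, with a minimum used
portion of 8 nt to suppress chance few-nucleotide matches. A combined
donor+acceptor truncation across adjacent exons is one event (a config flag
splits it); a lone donor-side truncation matches none of the three observed
modes and raises a dedicated error; intron retention surfaces as a mapping
failure. Junction validation checks GT/AG directly on the genomic sequence,
for canonical introns and for the effective (shifted) junctions of
alternative events.

When an event's last truncated base equals the first retained base, parses
sliding by ±1 produce byte-identical transcripts; the classifier's answer
is then one member of the equivalence class (the tests assert exact
recovery whenever the junction is unambiguous, transcript-level equivalence
otherwise). The family's reported offsets (11; 79/58) are far from this
regime.

## Synthetic generator

Defaults are the family's documented structure: 76 members, 15 motifs,
copy numbers 1–9 (uniform — the range is documented, the distribution is
not), units 30/33 with P(33) = 0.25, backbone exon/intron lengths and UTR
lengths as above, within-type substitution rate 0.005 per base ("highly
conserved" within type), type-level divergence 0.15 per base confined to
the exon-5 block (where the family's between-type variance concentrates).
33-nt units are the 30-nt consensus plus one codon inserted at in-unit
position 15, keeping mixed arrays alignable. The 3'UTR starts with a
12-nt three-frame stop wall and the 5'UTR avoids ATG, so the annotated ORF
is provably the longest; a single AATAAA is planted 26 nt from the 3' end.
Exonic AG (exon-5 offsets 9–10), exonic GT (offsets 29–30) and the TAG stop
codon provide canonical context for the three default shifted splice sites.
Mutations never touch the start/stop codons, the anchor context, the motif,
or the planted splice contexts — those are the signals under test, and
within-type drift that destroyed the diagnostic motif would by definition
create a new type; a `hostile` flag lifts all protections for robustness
work. Slippage exemplar pairs (one per class) and splice variants (the four
observed events) are planted by default and recorded in the ground truth.

What the generator does *not* emulate: indels outside the repeat region,
intron sequence evolution, alignment uncertainty, chimeric/PCR artefacts,
expression levels, or any population-genetic process. Green tests therefore
demonstrate correctness of the inference machinery on families matching the
documented architecture, not robustness to arbitrary real-world mess.

## Problem sizes and determinism

The shipped suites use families of 10–200 members, brute-force oracles on
instances ≤ 250 nt and ≤ 7 taxa, and 20–100 bootstrap replicates (the
function default is 1000, the value used for the documented tree). All
randomness flows from explicit integer seeds (`numpy.random.default_rng`);
the pipeline derives per-stage child seeds from one master seed, and
identical configs reproduce reports byte for byte.
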