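# Methods

This note documents the models, parameter choices and numerical
conventions behind `acepamir`, and what the synthetic benchmarks do and
do not demonstrate.

## Homology scanning

Candidate mature-miRNA loci are found by exhaustive ungapped scanning:
for every reference mature sequence (18–26 nt, unambiguous RNA), every
subject window of exactly that length, on both strands, is compared by
Hamming distance. Windows containing IUPAC ambiguity codes are
skipped. Defaults follow the conventional homology-survey settings:
minimum match length 18 nt, at most 3 substitutions, no gaps. Because
the scan is exhaustive it strictly dominates any seeded heuristic
(BLAST-like) search at these query lengths, and no E-value model is
needed. Minus-strand hits are reported on forward-strand coordinates.

Redundant hits — intervals on the same subject overlapping by at least
half of the shorter interval — collapse to the hit with the fewest
mismatches (ties: longer match, then smallest reference id). Likely
protein-coding reads are removed by a six-frame ORF heuristic: a
subject is dropped if any frame on either strand contains an
uninterrupted AUG-initiated ORF of ≥ 80 codons (configurable). This is
a deliberately local stand-in for a protein-database search: it cannot
recognize coding sequence without a long intact ORF (e.g. a fragment
lacking its start codon), so it is the weakest filter in the chain and
its threshold is exposed in the config.

## Folding model

`fold_mfe` minimizes free energy over pseudoknot-free structures with a
Zuker-style dynamic program (hairpin/stack/bulge/interior/multiloop
decomposition; interior loops capped at 30 unpaired nt; the fill runs
under numba). The energy function is deliberately small and fully
pinned in `data/energy_params.json` (version 1.0):

- stacking free energies (37 °C, kcal/mol) for the six canonical pair
  types (Watson–Crick + G:U), classic Freier/Turner-style values;
- loop penalties logarithmic in size: hairpin `4.5 + 1.0786·ln(n/3)`
  (minimum loop 3 nt), bulge `3.8 + 1.0786·ln(n)`, interior
  `4.1 + 1.0786·ln(n/2)` where n is the total unpaired count
  (1.0786 = 1.75·RT at 310.15 K);
- affine multiloops: 4.6 per closing + 0.4 per branch + 0.1 per
  unpaired nt; no dangling ends, no coaxial stacking, no asymmetry
  penalty.

The empty structure scores 0, so reported MFEs are ≤ 0. Every
reported energy equals the independent loop-decomposition rescoring of
the returned structure (`score_structure`), which is also the scoring
basis of the exhaustive-enumeration oracle in the tests.

This model is not a substitute Turner 2004 parameterization and will
not reproduce MFOLD/RNAfold energies in absolute terms; downstream
statistics (AMFE, MFEI) only require a consistent, documented ΔG.
Where published MFE values must be reproduced exactly, externally
computed structures can be read from dot-bracket or CT files and the
bundled dataset carries the published energies, which the statistics
operate on directly.

Co-optimal structures are resolved by a fixed traceback preference:
leave a base unpaired before pairing it, then hairpin before stack
before interior loop (smallest first) before multiloop (smallest split
first). This favors fewer pairs among ties and makes results
platform-independent; it does not guarantee the globally
lexicographically-smallest co-optimal structure, only a deterministic
one.

## Precursor windows

Public EST/GSS surveys rarely state the rule that cut a precursor out
of each read; the window-grid search here is this package's explicit
stand-in. Around each hit, all combinations of upstream/downstream
extensions from {0, 20, …, 180} nt (configurable) are folded, windows
clipped at subject ends, lengths restricted to 60–400 nt in the
pipeline (the extractor itself accepts any bounds, so a zero-extension
call returns the bare matched interval). Candidates are ranked by
|MFEI| descending; the pipeline keeps the first candidate that passes
all hairpin criteria, and collapses loci whose windows overlap by ≥ 50 %
of the shorter window (a mature-arm hit and its star-arm mirror
describe the same hairpin).

## Hairpin criteria and statistics

Per-precursor statistics: mononucleotide percentages, (G+C)% and
(A+U)%, MFE, AMFE = MFE/LP·100 (kcal/mol per 100 nt), MFEI =
AMFE/(G+C)% (signed; the 0.85 cutoff applies to |MFEI|). Reports round
to 2 decimals; tests compare published columns at 0.01–0.015 tolerance
to absorb mixed rounding/truncation in the printed values.

Qualification flags: the mature may not pair with itself and ≥ 18 of
its bases must lie on one side of the loop; ≥ 50 % of mature bases
paired (denominator = mature length — the adjacent criteria all concern
the miRNA/miRNA\* duplex, so the mature-local reading is used rather
than a precursor-wide one); duplex bulges < 4 nt; ≤ 1 asymmetric bulge
(an internal loop with unequal unpaired counts on the two strands,
counted once per loop); 30–70 % A+U; MFE < 0; |MFEI| ≥ 0.85. The arm
call compares the mature midpoint with the midpoint of its partner
positions (5p if the mature precedes the loop); with a completely
unpaired mature the arm is assigned from the sequence midpoint and the
structural flags fail anyway.

## Target scoring

Sites are scored ungapped and antiparallel: miRNA position i (5′→3′)
faces site position n−i+1. Penalties: mismatch 1.0, G:U wobble 0.5,
gap 2.0, doubled at miRNA positions 2–13. This classical plant schema
exactly reproduces the verified reported alignment (ace-miR162 vs its
Dicer-like site: one wobble at position 3 → expectation 1.0). A
mismatch or gap at positions 9–10 (configurable to 9–11) classifies
inhibition as translational, otherwise cleavage. Per transcript, all
windows at or below the expectation cutoff (default 3.0) are reported
best-first, overlapping sites merged to the best one, capped at 10
targets per miRNA. Target-site accessibility energy (UPE) is carried
through as an optional annotation but never computed: it requires a
full accessibility model outside this package's scope. An optional
single-gap alignment mode was considered and left out: all verified
reference alignments are 1:1 ungapped.

## Phylogenetics

Distances are p-distances (proportion of mismatched or gapped columns,
both-gap columns ignored) over deterministic Gotoh global alignments
(match +1, mismatch −1, gap open −2, gap extend −1; fixed traceback
preference diagonal → gap-in-second → gap-in-first). Progressive MSA
is replaced by pairwise alignments for the distance matrix plus a
center-star alignment (center = minimum summed distance) for bootstrap
column resampling — sufficient for distance-based trees and free of
external aligner dependencies.

Neighbor joining follows Saitou–Nei with the standard Q-criterion and
two-point branch-length formulas; exact ties join the
lexicographically smallest label pair; negative branch estimates are
clamped to zero and flagged (the common display convention). Two taxa
return a single edge by convention. Bootstrap (default 1000
replicates, seeded) resamples alignment columns with replacement,
rebuilds NJ, and reports per-edge bipartition frequencies as integer
percentages on the reference tree.

## Synthetic data

`make_precursor` builds mature + loop + star hairpins, the star being
the reverse complement with optional pair-breaking substitutions and
inserted bulges; loops are drawn from {A, C} so they cannot extend the
stem. `make_est_collection` embeds such hairpins (default total read
length 300–1000 nt, loop 6–20 nt, 0–3 planned mature substitutions) in
random flanks of A/U-rich composition (28.5/28.5/21.5/21.5 % A/U/G/C,
~57 % A+U, matching the average reported precursor sequence space), and
adds coding decoys (ORFs of 100–160 codons) and unstructured decoys.
Flanks and unstructured decoys are regenerated until they contain no
spurious ≥ 80-codon ORF, so non-coding truth labels hold by
construction. All randomness flows from one integer seed per call;
output is byte-identical across runs.

What the synthetic benchmark shows: with clean (0-mismatch) embedded
hairpins and default thresholds, the full chain recovers 100 % of
planted precursors over 20 seeds (40 precursors; recovery = a passing
hairpin whose window covers ≥ half of the true precursor interval) with
zero unstructured-decoy false passes. What it does not show: the
generator produces ideal near-perfect inverted repeats without
sequencing error, chimerism or paralogous families, so these rates are
upper bounds; real EST/GSS collections will yield lower sensitivity and
the coding filter is weaker than a database search (above).

## Problem sizes in the test suite

Folding-oracle equivalence is checked exhaustively for all sequences of
length ≤ 5 and on 150 random sequences of lengths 6–12 (full
enumeration beyond ~12 nt grows too quickly to be informative per unit
cost); scanner-oracle equivalence on 30 random subjects of 80–500 nt
against 4 references; NJ consistency on 50 random 8-taxon additive
matrices; the end-to-end sweep uses 20 seeds × (2 true + 3 decoy)
records with a {0,10,20,30,40,60} nt extension grid. These sizes were
chosen as the smallest instances that still exercise every code path
(multiloops appear from ~10 nt; 8 taxa give non-trivial topologies).

## Known limitations

- The energy model is intentionally minimal; absolute ΔG values differ
  from full Turner-parameter engines.
- The ORF heuristic under-detects coding sequence relative to BLASTx.
- Rfam-style screening of other non-coding RNA classes is not
  implemented; an rRNA fragment with a stable fold could survive to the
  MFEI filter (which is the criterion designed to reject it).
- GO terms are tabulated from a user-supplied mapping; no annotation
  transfer is performed.
- Bootstrap supports are on the center-star alignment, not a full
  progressive MSA; for distant sequences the alignment, and hence the
  supports, are approximate.
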