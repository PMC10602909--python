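# Methods

This note documents the models, conventions and design choices behind
`pbscreen`, in the order the screen runs them.

## Pairwise alignment (seq_core)

All pairwise comparisons use Needleman–Wunsch global alignment with
affine gap costs in the EMBOSS-Needle style: a gap of length L costs
`gap_open + L·gap_extend` (defaults 10 and 0.5), terminal gaps are free
by default, and identity/similarity percentages are computed over the
full alignment length, gap columns included in the denominator. A column
counts as "similar" when its substitution score is strictly positive;
with BLOSUM62 every identical pair of standard amino acids scores
positive, so identity ≤ similarity always holds there. Protein scores
are BLOSUM62; DNA uses match +5 / mismatch −4 (the EDNAFULL core).
Ambiguity codes (X, N) are fixed at score 0 against everything — neutral,
so runs of ambiguity neither inflate nor deflate similarity. The
underlying dynamic program is executed by Biopython's `PairwiseAligner`;
its first reported alignment is deterministic, and alignment *scores*
(what every downstream quantity depends on) are checked in the test
suite against exhaustive enumeration of all global alignments on small
inputs. Matrices in NCBI text format can be loaded for non-default
scoring.

One consequence worth knowing: with free end gaps, appending a
self-matching residue to both sequences can lower the optimal score
(a formerly free terminal gap becomes internal); with charged end gaps
it cannot. The tests pin both behaviours.

## PBS derivation, classification and scanning (pbs_catalog)

A PBS is the reverse complement of the 3′-terminal 18 nt of the priming
tRNA; derivation enforces the 18-nt length. Classification assigns an
18-mer to the catalog type minimizing Hamming distance, with N counted
as a mismatch and ties reported as ambiguous rather than broken. The
first nine nucleotides are the type-discriminating half (the shipped
catalog's types differ by ≥ 3 there); a `distinctiveness_report` makes
those inter-type distances explicit.

The scanner reports every 18-mer window (both strands) within
`max_mismatch` (default 3 — the conserved first half tolerates little
drift, the 3′ half more) of any catalog entry. The confidence score is
`round(100·(18−m)/18)` plus a +10 bonus when the hit starts within 20 bp
downstream of an annotated 5′-LTR end — the position a proviral PBS
occupies. The bonus is what makes a strict `score > 100` filter
meaningful: it keeps exact or near-exact matches in the expected proviral
context and discards chance matches elsewhere. The original
provirus-annotation software's scoring formula is unpublished, so this
score is this package's own declared stand-in; the default threshold
(100) and bonus geometry are configurable. Windows with more than 6 Ns
are skipped. All coordinates are 0-based half-open, matching BED.

## C2H2 fingers and the recognition code (zinc_finger)

Fingers are matched left-to-right, non-overlapping, against
`C-x(2,4)-C-x(12)-H-x(3,5)-H` with lazy variable stretches (earliest
start, shortest stretch), which resolves tandem arrays deterministically.
The C→H spacer is fixed at 12 residues, which pins the fingerprint
offsets: with the first histidine at recognition-helix position 7, helix
positions −1, 2, 3, 6 are sequence offsets −7, −5, −4, −1 from that
histidine (spacer indices 5, 7, 8, 11). The Zif268 finger-1 oracle
(helix RSDELTR → fingerprint R,D,E,R) validates this convention; a
literal reading of "positions −1, 2, 3, 6 relative to the first
histidine" as offsets −1/+2/+3/+6 would contradict that canonical
fingerprint and is deliberately not used.

Fingerprint arrays are compared by a global dynamic program over whole
fingers (no re-ordering): an aligned finger pair contributes the number
of positionally identical fingerprint residues (0–4), gaps contribute 0,
and the total is normalized by `4·max(|a|,|b|)` so extra fingers dilute
similarity — a conservative denominator suited to a < 50% dissimilarity
screen. How the published < 50% figure was computed is not stated
anywhere we could follow, so this definition is declared, not inferred.

The recognition code maps fingerprints to DNA triplets. Shipped are
(i) a small canonical table (Zif268 fingers: RDER→GCG, RDHT→TGG),
(ii) a complete systematic code with exactly one fingerprint per triplet
(helix 6/3/−1 contact the 5′/middle/3′ base through a fixed base→residue
map, helix 2 held constant), and (iii) a TSV loader for user tables. The
systematic code is invertible, which is what lets the synthetic-data
generator plant a binder whose predicted motif equals a chosen PBS
window exactly. Predicted motifs are emitted 3 nt per finger in reverse
finger order (the C-terminal finger binds the 5′-most triplet), and
motif-vs-PBS comparison slides the shorter sequence along the longer on
both strands, scoring the match fraction over non-N motif positions;
all-N motifs are reported as fraction 0 with an `undefined` flag.

## LTR dating (ltr_dating)

Divergence is the p-distance over aligned columns where both rows are
non-gap and non-N (DNA matrix, end gaps free); gaps are excluded from
numerator and denominator, and pairs whose alignment is more than 20%
gap columns are flagged low-confidence. The default is the raw
p-distance because the clock calibration is a linear rule — 0.4%
divergence per Myr, so `age = 100·p/0.4` — and a Jukes–Cantor corrected
mode (`−(3/4)·ln(1−4p/3)`) is available behind a flag; at the ≤ 1%
divergences of recent insertions the two agree within 1% relative.
Whether the original analysis corrected for multiple hits or how it
handled gaps is unstated, so both choices are declared here.

Invasion profiles bin ages at 5 Myr (default) over [0, max]. The peak
window is the maximal contiguous run of bins containing the modal bin
with counts ≥ 50% of the modal count — a full-width-at-half-maximum
reading; no published rule exists for this window, so the definition is
the package's own.

## Gene ages and co-occurrence (kzfp_age)

A gene's age is the maximum divergence time from the reference species
over all species carrying an ortholog. Reliability is "low" when fewer
than half (configurable) of the known species *younger* than the oldest
ortholog also carry the gene — a patchy distribution in which one
distant hit sets the age. This patchiness rule is a declared proxy; the
original marking criteria are unpublished. Co-occurrence keeps genes
whose age lies within the invasion-peak window widened by ± 10 Myr
(declared default; whether the original screen used a tolerance is
unstated), sorted by distance from the window midpoint.

## Peak overlap (peak_overlap)

BED3–6 is parsed strictly (line-numbered errors), 0-based half-open.
Strong-peak filters are strictly greater-than, with 500 the default
(300 suits epitope-tag data with systematically weaker peak scores). A
peak overlaps a PBS interval when the intersection is ≥ 1 bp
(configurable); each peak counts once toward a KZFP's overlap count no
matter how many PBS intervals it spans (the ranking counts peaks), and a
per-PBS count is emitted as the complementary view. Counting uses an
interval tree and is verified against a quadratic all-pairs scan in the
tests. Strand is ignored; ChIP peaks are unstranded.

## The two-arm screen (screen_pipeline)

Arm membership is determined by data availability: a KZFP with a peak
set is screened by overlap (arm A), all others by the evolutionary and
predictive route (arm B); every input KZFP lands in exactly one arm. Arm
A candidates need ≥ 3 strong-peak/PBS overlaps (`arm_a_min_overlaps`) —
a threshold chosen from the decoy null at the default synthetic scale,
where a random strong peak hits a PBS locus with probability ≈ n_PBS ·
(width+18)/genome ≈ 1.7%, making 3 hits from ~7 peaks vanishingly
unlikely — on top of the ranking itself. Arm B candidates must both
co-occur with the invasion window and reach a 0.7 predicted-motif match
fraction (declared default; no published cut-off exists). Fingerprint
similarity to the declared reference binders is reported for every arm-B
KZFP with a < 50% dissimilarity flag, as a report rather than a filter,
since the published screen used it descriptively. An empty PBS set after
filtering produces an explicit no-targets report with empty candidate
lists rather than an error. Reports are byte-identical across runs with
identical inputs and seed, and raising any threshold can only shrink the
candidate sets.

## Synthetic data (synthetic_data)

The generators define the study conditions the tests and acceptance
script run under:

- **Genome**: 150 kb with 8 planted PBS-Pro proviruses (1-kb LTRs,
  1.5-kb internal, PBS immediately downstream of the 5′ LTR), ERV ages
  drawn Normal(30, 3) Myr truncated at 0 — one invasion episode at the
  Old World monkey epoch. Each LTR copy descends from a common ancestral
  sequence mutated per site with probability `age·0.004/2`, so the
  expected pairwise divergence is `age·0.4%` — the same linear clock the
  dating stage inverts. At larger ages coincident hits make the raw
  p-distance slightly concave (≈ 4% low at 30 Myr), which is real
  mutation-process behaviour, not a generator artefact; dating accuracy
  is therefore stated as mean absolute error rather than exactness.
  Planted PBS mismatches (default 0) avoid the conserved first 9 nt.
- **Panel**: 20 proteins, 1 binder whose fingerprints invert the
  systematic code against the PBS first 9 nt (3 fingers); decoys carry
  3–8 random code-table fingerprints, resampled until their predicted
  motif matches the PBS below 0.5 on either strand. All scaffolds and
  linkers avoid C and H, so the finger scanner finds exactly the
  constructed fingers.
- **Peaks**: the binder gets one 200–400 bp peak (score 600–1000) on
  85% of PBS loci; each decoy gets the same number of uniformly placed
  peaks with scores 100–1000.
- **Orthologs**: a 10-species ladder (6 → 300 Myr from the reference,
  including the 30-Myr rung); a gene has orthologs exactly in species
  within its age, with optional patchy dropouts (oldest always kept) to
  exercise the reliability flag. The binder's age is 30 Myr, matching
  the invasion peak; decoy ages are drawn from the ladder.

Everything is a pure function of (parameters, seed) with substreams
derived from (seed, counter); identical seeds give byte-identical
output. What the generator does **not** emulate: real repeat families
and nested/truncated proviruses, indels and rate heterogeneity in LTRs,
realistic ChIP peak-shape or background enrichment at repeats,
horizontal transfer or gene loss in ortholog tables. Passing tests
therefore demonstrate the pipeline's correctness and discrimination
under clean planted truth, not its performance on real genomes.

Three reference proteins (`standin_reference_proteins`) are synthetic
stand-ins reproducing the documented *architecture* of the PBS-Pro
binders — for the ZNF506 stand-in, a KRAB box at residues 1–75 and
exactly 8 C2H2 fingers spanning residues 201–419 of a 419-residue
protein; the ZNF253 stand-in shares a near-identical KRAB box with it —
not the real database sequences. Pairwise-similarity figures published
for the real proteins are consequently not reproduced by these
stand-ins, and the one acceptance test asserting them documents the
stand-in values and fails by design.

## Problem sizes and numerics

Default scales (150-kb genomes, 20-protein panels, 8 ERVs, 10–20 seed
sweeps) were chosen so that every planted signal is recoverable with
comfortable statistical margin while the whole suite remains quick on a
single CPU. Scores are floats; percentage comparisons in tests are made
at the precision stated per test; the scanner is vectorized over windows
with NumPy. Degenerate inputs have defined behaviour throughout: empty
scan targets give empty hit lists, all-N LTR pairs raise an
undefined-divergence error, empty finger arrays are rejected by the
similarity comparison, and an all-N motif reports fraction 0 with a
flag.
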