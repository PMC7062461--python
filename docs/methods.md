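# Methods

## The dif grammar and site classification

A *dif* site is modelled as a fixed-width, ungapped grammar: an 11-bp
XerC-binding arm, a 6-bp central spacer, and an 11-bp XerD-binding arm
(28 bp total). The canonical sequence shipped as the default,
`GGTGCGCATAA·TGTATA·TTATGTTAAAT`, is the *E. coli* chromosomal *dif* from
the literature; it is a configuration value, not a hard-coded constant, and
every operation accepts an override (`DifGrammar(canonical_seq=...)`).
Hamming comparisons treat `N` as mismatching everything, including another
`N` (conservative).

Classification of a 28-bp window:

- **bacterial_like** — total mismatches ≤ 1 (`bacterial_dif_max_mm`),
  encoding the observation that chromosomal sites upstream of insertions
  differ by at most one nucleotide from canonical;
- **phage_like** — XerC arm within 2 mismatches (`xerC_arm_max_mm`) while
  the spacer/XerD arm may diverge freely;
- **partial_C_missing / partial_D_missing / non_site** — engineered arm
  deletions (produced by `simulate.delete_dif_arm`) or windows with a
  broken XerC arm.

## Synthetic data: what it emulates and what it does not

The generator reproduces the *architecture* the analysis depends on, not
sequence realism. Host chromosomes are i.i.d. background at a configured GC
with exactly one planted *dif* (rejection-sampled so that no 17-mer of the
site occurs elsewhere on either strand). Phage genomes are circular,
uniform in length over 4047–4692 bp (the wider of the two published length
ranges), and carry six genes in the order VP4, VP5, VP3, VP1, VP2, VP8,
each a back-translation of a deterministic synthetic reference protein
(optionally substituted at `protein_mut`, default 0.02/aa). Gene proteins
are synthetic stand-ins generated once under a fixed internal seed — the
real reference proteins are external database records — so simulator and
search are self-consistent by construction.

The phage *dif* sits in the VP8→VP4 intergenic gap, so that the integrated
prophage reads VP4…VP8 between the boundary sites, and is built as the
canonical XerC arm plus a spacer/XerD region substituted at
`phage_dif_spacer_mut` (default 0.3/bp). Two construction guarantees make
the ground truth usable as an oracle:

1. every phage-type *dif* or planted motif carries 2–13 substitutions —
   never bacterial-like, never identical to the host site, and always
   ≥15 bp identical to canonical;
2. each intergenic gap ends with a stop codon pinned in the frame of the
   following gene, and gap draws are rejection-sampled until the ORF caller
   recovers all six genes exactly, so gene-coordinate ground truth is
   attainable rather than probabilistic.

MAG sets plant motifs in three contexts — a non-coding gap, the first
90 bp of VP4, or mid-gene (a negative control only the context filter can
remove; such motifs are drawn with a stop-free codon phase so they can sit
inside an intact gene) — plus decoys with exactly 10–14 bp identity to
canonical and ≤14 bp identity (both orientations) to every planted motif in
the same set. What passing tests therefore show is that the *operators*
implement their rules exactly; they do not show robustness to real-sequence
features the generator omits: codon usage, phylogenetic correlation among
phages, repeats in real chromosomes, or sequencing error.

One global seed drives an explicit `numpy` generator passed through every
sampling call; FASTA output is byte-identical across runs of a seed.

## Gene calling

A greedy longest-ORF caller stands in for an interpolated-Markov-model gene
finder: downstream consumers need coordinates and roles, not gene scores.
All start→stop ORFs (starts ATG/GTG/TTG; both strands; origin-wrapping on
circular records) are enumerated, then accepted by decreasing length (ties:
leftmost, then + strand) subject to two published constraints: minimum gene
length 110 bp and maximum overlap 50 bp. Length *includes* the stop codon —
the convention must be fixed for the 110-bp threshold to be testable.
Roles are assigned by local protein alignment (BLOSUM62, open −11 / extend
−1) against the reference set, accepting the best reference when the score
reaches 50 % of the smaller self-score; "N-terminus" is quantified as the
first 90 bp of a gene (`n_term_window`), comfortably containing a 28-bp
site behind a start codon.

## Prophage discovery and boundary detection

Capsid loci are found by six-frame translation and protein 5-mer–seeded
local alignment of the VP1 query against each frame, keeping
non-overlapping loci with raw score ≥ `capsid_score_min` (default 100,
calibrated as measured-null-maximum-plus-margin: over 100 random 50-kb
genomes the best local alignment score was 71, mean 55.1, sd 4.4, while a
true hit scores ~2700).

Boundary detection searches the 5-kb flanks of a capsid locus for maximal
exact repeats seeded by shared 17-mers in the same orientation, ranked by
(1) longer match, (2) smaller enclosed interval, (3) leftmost upstream
copy. Because the two boundary *dif* copies share only the 11-bp XerC arm
plus whatever of the spacer/XerD region happens to be conserved, an exact
17-mer frequently does not exist; PWM fallback pairs are therefore always
appended after the exact pairs: both flanks are scanned with the
canonical-*dif* PWM at a permissive floor (0 bits), and candidate pairs are
ranked by grammar plausibility — a bacterial-like copy on the chromosomal
side first, then fewest XerC-arm mismatches on the phage side, then summed
score. Candidate pairs are consumed in rank order and validated by
`call_prophage`; invalid pairs are rejected with a reason, so a decoy
repeat farther out cannot displace the true boundary.

The prophage region convention: the region begins at the first base
*after* the upstream (bacterial) *dif* and ends at the *last base* of the
downstream (phage) *dif*. Excision returns the region circularized (phage
*dif* once, bacterial *dif* zero times) and the restored host; lengths are
conserved exactly, and excision∘integration is the identity up to
rotation. Prophages on the minus strand are mined on the flipped contig
and mapped back (region strand "−").

## Integration model

`integrate` refuses — with a typed reason — unless the host state has both
XerC and XerD active and the phage presents an intact phage-like (or
bacterial-like) *dif*; on success the phage is linearized immediately after
its *dif* and inserted directly downstream of the host *dif*, co-oriented,
leaving the host site unchanged. The host must carry exactly one
bacterial-like site (error otherwise). Auto-detection of the phage *dif*
uses the canonical PWM with a calibrated floor so chance XerC-arm
look-alikes cannot masquerade as sites; deletion constructs pass an
explicit site descriptor instead. The observed failure of induced *xerD*
complementation is reproduced phenomenologically via a
`xerD_complementable=False` default in `HostState.from_genotype` — a
configurable flag mirroring the measurement, not a mechanistic claim.

## dif-motif scanning

*dif* sites are fixed-length and ungapped, so the motif model is an
ungapped PWM over the 28 grammar columns: per-column log2-odds of
`(count + pseudocount) / (n + 4·pseudocount)` against a background
(uniform by default), pseudocount 0.5. `N` scores as the worst base of its
column. Scanning covers every position on both strands (origin-wrapping on
circular records); scores are rounded to 6 decimals so ties resolve
identically regardless of floating-point summation order, and overlapping
same-strand hits collapse to the local maximum (ties: higher score, + 
strand, leftmost).

The primary threshold is calibrated analytically: the exact null score
distribution under i.i.d. background is computed by convolving per-column
score distributions on a 0.01-bit grid, and the smallest score whose tail
probability keeps the expected false hits per 5 kb (both strands) at or
below `null_fpr` (default 0.05) is used. Filtering applies the
coding-context rule first — hits inside genes are rejected outright, with
the single exception of the VP4 N-terminal window — then confirms hits at
or above the threshold, then rescues sub-threshold hits having ≥15 bp
positionally identical (`min_identity`, frame-locked by default; a shifted
variant is available via `shifted_identity=True`) to a confirmed motif.

The iterative search retrains the PWM each round on the seed motifs plus
*confirmed* hits only. Feeding the potential class back was measured to
bootstrap chance 15/28-identity windows into the model (they self-match at
28/28 the next round) and within three rounds accept hundreds of spurious
windows and most decoys; restricting feedback and identity references to
confirmed motifs keeps 100 % recall of planted motifs with zero decoy
survival on seeded MAG sets. The search stops when no new MAG gains a hit
or after `max_rounds`.

## Comparative assays

ANI is one end-to-end global alignment (edlib, unit costs) of
rotation-normalized genomes — the second genome, doubled, is searched for
the best infix placement of the first on either strand — with identity =
matches / aligned columns, terminal gaps excluded. Arguments are ordered
canonically before aligning, so symmetry is exact. This deliberately
differs from fragment-based ANI tools; for genomes under ~5 kb a single
exact alignment is both simpler and tighter. Clades are single-linkage
components of the graph `{ANI > 95}` with deterministic labels (A, B, … by
size, then lexicographic smallest member; singletons labelled as such).

Identity profiles average, per alignment column, the indicator of identity
over unordered pairs with no gap in either member (columns with no valid
pair are missing; optional centered moving average). In-silico PCR matches
primers exactly by default with a mandatory 3′-terminal match (mismatch
tolerance configurable), tries both primer assignments, supports
origin-crossing products on circular templates, and reports product sizes
inclusive of both primers — the convention in which gel sizes are quoted.

## Problem sizes in the validation suites

The round-trip suite runs 100 seeded integrations on 16-kb hosts (full
generator phage architecture); the *dif*-scan recovery suite runs 50 seeded
nine-MAG sets; the null false-positive check scans ~500 unplanted MAG
genomes; the ORF-caller oracle comparison covers 200 random sequences up to
1.5 kb and the scanner oracle both topologies. Host lengths in tests are
reduced from the 100-kb default because a prophage's 5-kb flanking context
— the only length-sensitive ingredient — is fully contained well below
that size.

## Known limitations

- The identity-rescue rule (≥15/28 bp) is intrinsically weak against random
  sequence: on null genomes chance windows enter the *potential* class at a
  measurable rate. The calibrated guarantee covers the confirmed class
  only; potential hits are reported for curation, as in the source
  procedure.
- ORF calling is purely structural (no coding-potential model); role
  assignment depends on the supplied references.
- The integration model is a logical predicate — it reproduces which
  conditions permit lysogeny, not the quantitative lysogeny percentages,
  which are wet-lab quantities.
- `find_flanking_repeats` reports minus-strand fallback pairs for
  completeness, but calls are made after flipping the contig; linear
  records truncate flanks at contig ends.
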