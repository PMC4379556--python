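# Methods

This note documents the models, parameter choices and numerical decisions
behind hml2kit, and what the synthetic-data experiments do and do not
establish about real data.

## Element catalogue

Every element (provirus, solo LTR, fragmentary LTR, host-gene decoy) is an
independent reference sequence.  Coordinates are 1-based inclusive
throughout; conversion to 0-based half-open happens only inside format
writers.  N bases are permitted and count as mismatches everywhere,
including against another N — a deliberately conservative rule that keeps
the alignment metric simple.

The canonical LTR frame is 968 bp: U3 at 1–792, R at 793–870, U5 at
871–968.  Position 793 (the U3–R border) is the canonical transcription
start; 826 is the alternative start used mid-R by the fragmentary upstream
LTR in the chimera scenario.  The promoter-motif catalogue holds eight
instances: a GA-rich motif (379, GGGAAGGG), three E boxes (465
TTGCAGTTGAGA, 485 AGGCATCTGTCT, 832 CTCCATATGCTG), two GC boxes (602 GGCGG,
759 CCCCC), the TATA box (790, AATAAATA) and the initiator (807, CTCAGA).

## Synthetic families

The generator's defaults define the study conditions used across the test
suite; they are not tuning knobs.

**Ancestor.**  9500 bp with identical 968-bp LTRs at both ends, a 250-b
leader, and intact ORFs for gag (2001 b / 666 aa), pro (780 b), pol
(2400 b) and env (1800 b), followed by a 333-b untranslated spacer.  Gene
lengths are free choices within the family's typical ~9.5-kb span; gag's
666 aa matches the full-length Gag of the most highly packaged natural
locus.  A splice acceptor AG is planted in the leader at 1016–1017 (exon
start 1018) and a GT donor at 1075–1076, giving the canonical 1074→1018
chimeric junction geometry at age 0.

**Evolution.**  Substitution-only (Jukes–Cantor-like: each position mutates
independently with probability d, replacement uniform over the three
alternatives).  No indels except the engineered 292-bp pol–env deletion
(type-1 members) and solo-LTR recombination (5' LTR U3+R fused to 3' LTR
U5).  Because the ancestor's two LTRs are identical and mutations are
i.i.d., intra-element LTR divergence grows as ~2d automatically.
Hypermutated members replace a fraction h = 0.3 of plus-strand G with A,
reproducing the long-branch signature of APOBEC3G editing without modeling
its dinucleotide context.  Ages are expressed directly as divergence
proportions; no molecular-clock calibration is attempted.

**The default 12-provirus family** spans divergences 0.002–0.08 ("just
integrated" through old-5B-like), includes one identical duplicate pair,
two type-1 members, one hypermutated member and two solo LTRs.  The default
expression plan has two dominant loci, a strongly expressed but
packaging-incompetent ancient locus, a cell-only locus, a silent duplicate
twin, and one locus per transcription mechanism.  LTR groups are assigned
from divergence (≤0.012 Hs, ≤0.04 5A, else 5B).

**Host contexts.**  Contexted elements become "locus" records
(2000-b flanks around the element) with a placement map, mirroring a
genome-style alignment in which flanking reads exist.  The
upstream-fragmentary-LTR scenario places a 1118-b recent LTR fragment
exactly 551 bp upstream with a GT donor after fragment position 1074; the
acceptor is the AG nearest the canonical leader position in the *realized*
element sequence (descendant mutation can shift it), and the realized
junction is recorded as that locus's truth.  Read-through transcripts are
generated on the plus strand of the locus regardless of the annotated
neighbor's strand — the classifier only sees coverage, and the antisense
case is exercised by its own scenario.

**What the generator does not emulate:** indel evolution, recombination
between distinct proviruses, GC/positional coverage bias, PCR duplicates,
or the unknown distortion of whole-transcriptome amplification in real
virion libraries (simulated as unbiased unstranded sampling).  Passing
tests therefore demonstrate correctness of the *analysis* under a clean
substitution-only model, not robustness to every artefact of real
libraries.

## Read simulation

Fragment counts per transcript are Multinomial(n, fraction × length): molar
fractions weighted by transcript length, so FPKM (which divides by length)
recovers molar fractions — the correspondence the recovery tests assert.
Insert sizes are normal, truncated by resampling to the library's range
(cell default: mean 180, range 98–522, stranded; virion: mean 200, range
100–568, unstranded; the insert SD of 60/65 b is a free choice consistent
with those ranges).  Reads are 250 b; mates shorter than the insert are
emitted at insert length (mates may fully overlap).  Strandedness follows
the dUTP convention: mate 2 carries transcript sense.  Errors are i.i.d.
substitutions (default 0.005/base) with the base quality dropped from Q37
to Q12 at error positions; no indel errors, since alignment is ungapped.

Uniform simulation for mappability draws ceil(depth·L/(2·read_len))
fragments with uniform starts; `paired=False` keeps the pair format but
sets insert = read length so both mates cover the same window, making
per-placement uniqueness equivalent to a single-end read.

Trimming is a fixed simple policy (exact-overlap adapter removal ≥10 b,
then a 4-base sliding window cut at mean Q < 25, pairs kept only if both
mates stay ≥100 b) rather than a re-implementation of any particular tool.

## Alignment

Ungapped, full-length, at most 2 mismatches per mate (the budget is
per-mate; a per-pair reading of the "2 mismatches" budget would also be
defensible, and per-mate is adopted).  Completeness comes from
the pigeonhole principle — a mate with ≤m mismatches is cut into m+1
segments, one of which must match exactly, and segment prefixes are looked
up in an exact 20-mer table — and is certified against an exhaustive
brute-force scan in the tests.  Concordance is FR orientation on the same
record with the implied insert inside configured bounds.  **Unique** means
the *only* concordant location within the budget, not the best one: a
perfect hit plus a 2-mismatch hit elsewhere is a multi-read.  Unique pairs
get MAPQ 50, multi-reads MAPQ 1, so unique-only filtering is exactly
MAPQ ≥ 50.  Ties are never broken; allocation is the quantifier's job.

Splice rescue attempts a single split per mate (segments ≥20 b, ≤1
mismatch each, plus strand of one record), preferring split offsets whose
intron dinucleotides are GT…AG.  With short inserts both mates can cross
the junction, in which case both are split-aligned and must agree on the
junction.  Only pairs that fail full-length alignment are ever split.

## Quantification

Counting collapses pairs into equivalence classes by their attributed
location multiset; conservation (Σc_i = counted pairs) holds exactly in
every mode.  EM rescue starts from the uniform allocation and iterates
proportional reallocation by c_i/L_i until the largest relative change is
below 1e-6 (cap 200 iterations); its fixed point matches a brute-force
maximum-likelihood grid search on two-component problems within 1%, and the
multinomial log-likelihood is non-decreasing across iterations.

L_i is the full element length with no effective-length correction: at
element ≈ 9.5 kb and insert ≈ 180 b the correction is ≤2% and uniform
across the family, a documented deviation from fragment-length-corrected
FPKM implementations.  N defaults to the mode's own counted total
(equivalent to running the estimator on the filtered alignment) but can be
overridden; mode comparisons and mappability pass the unfiltered total so
that FPKM is on a common scale — with a family-only reference, mode-specific
N would cancel uniform fragment loss out of FPKM entirely, which is not the
behaviour of a genome-wide N that filtering barely changes.  Relative
abundance is N-invariant either way, and its family denominator includes
proviruses only.

With placements (contexted loci), a pair is attributed to the element only
when its fragment overlaps the element span; flank-only mass goes to a
per-locus flank bucket that counts toward N but is never reported as an
element.

## Mappability

Every non-host element ≥ read length is simulated to equal depth
(default 20X, 250 b, error-free — isolating mappability from sequencing
error; an error-rate option exists), pooled, realigned and quantified with
and without the unique filter.  u = 1 − F_unq/F̄ with F̄ the mean
unfiltered FPKM (the equal-representation comparator); a per-element
variant u' = 1 − F_unq,i/F_unf,i is emitted for diagnostics.  The flag
threshold 0.15 is configurable.

A note on the two-paralog closed form: the probability that a 250-b window
contains *no* diagnostic site is (1−d)^250, but under a 2-mismatch budget a
window with one or two diagnostic sites still cross-aligns, so u under the
default budget is approximately P(Binom(250, d) ≤ 2) — an order of
magnitude larger at d = 0.02 (and close to the 0.15 flag boundary).  The
closed-form check is therefore run at an exact-match budget
(`per_mate_mm=0`), and because the count of substitution-free gaps longer
than 250 b is a small Poisson number at 10-kb scale, the comparison
conditions on the realized substitution pattern of a 400-kb paralog pair:
u must match the realized zero-diagnostic-window fraction within read-
sampling noise, and that fraction must sit within a broad factor of the
analytic expectation.

## Structural annotation

ORF discovery is a plus-strand three-frame scan; the longest ATG-initiated
ORF overlapping ≥50% of an annotated gene span is assigned to that gene,
full-length at ≥95% of the reference protein length (666/259/799/599 aa for
gag/pro/pol/env in the synthetic layout), truncated otherwise, absent if
nothing qualifies.  The 95% rule is an artifact decision — "full length" is
not defined numerically by convention.

Type classification anchors the first and last 30 b of a type-2 boundary
reference in the element (≤3 mismatches per anchor) and reads the deletion
length off the inter-anchor span difference; [250, 330] is type 1, [−10,
10] type 2, anything else (or unplaceable anchors — solo LTRs, heavily
hypermutated elements) unknown.  The reference window extends 350 b past
the boundary so the right anchor lands beyond a full 292-bp deletion.

Motif scanning searches each of the eight catalogued motifs within ±15 b of
its canonical position, keeping the best hit (fewest mismatches, then
closest): 0 mismatches canonical, 1–3 mutated, else missing.  Chance hits
are expected for the short degenerate motifs (a 5-mer under a 3-mismatch
cap almost always "hits" a random window); only the 12-b E boxes are
reliably absent from random sequence, and the tests assert exactly that.

ORF-abundance allocation credits an element's full cellular abundance to
every gene with an ORF (the maximum probability of that ORF being
expressed); the allocation is non-exclusive, per-gene totals may jointly
exceed 100%, splicing is not considered, and elements with no ORF at all
accumulate under "none".

## Mechanism classification

Coverage profiles accumulate fragment spans (leftmost mate start to
rightmost mate end) per locus record on plus/minus tracks; by default the
pipeline uses unique pairs only, because 1/k-weighted multi-read mass from
a dominant paralog otherwise bleeds into the profiles of closely related
silent loci and distorts strand fractions.  All thresholds are artifact
decisions replacing what is usually judged by eye on genome-browser
tracks, each a config key:
silent floor 0.1× mean depth; antisense when the minus-strand share exceeds
0.8 (stranded data only — unstranded samples cannot yield antisense calls
and the label space collapses); upstream-LTR chimera when ≥3 junction-read
weights link the upstream flank into the element; intronic passenger when
both flanks carry ≥0.5× the element's plus-strand depth; read-through when
the upstream flank alone does; otherwise LTR-driven.  The reported TSS is
where the cumulative 5' depth first exceeds 10% of the 75th-percentile
plateau — the running sum makes the estimate robust to Poisson noise on the
coverage ramp and lands within ~±15 b of a true start under the default
library (insert ≈ 180 b).  All ratio thresholds make calls invariant to
global depth scaling.  Mixed states (e.g. antisense plus elevated sense
coverage) receive a single label; the supporting metrics are emitted so
borderline calls can be audited.

## Phylogenetics

Input must be pre-aligned; the synthetic families' substitution-only
evolution makes equal-age features (5' LTRs) a natural gap-free alignment,
and engineered deletions are restored as gap columns for full-element
trees.  p-distance uses pairwise deletion (columns with '-' or N excluded
per pair).  Neighbor joining is standard Saitou–Nei with the Q criterion,
deterministic lexicographic tie-breaking, and negative branch lengths
clamped to zero by default; on additive matrices the input distances are
reproduced to machine precision, and topologies match scikit-bio's
implementation (used strictly as a test oracle).  Bootstrap resamples
alignment columns with replacement; support is the percentage of replicates
containing each internal bipartition, with splits canonicalized so a
bipartition is counted regardless of which side appears as a clade in the
replicate's trifurcation rooting.  1000 replicates by default; the
demonstration pipeline uses 200 to keep reruns quick.

## Packaging enrichment

r = a_virion/a_cell on relative abundances from comparable modes; raw
values whenever both samples detect the locus, a 0.01% floor (with
cell_only/virion_only flags) otherwise.  The similar band [0.5, 2.0] is an
artifact decision — sorting loci into increased/decreased/similar panels
has no conventional cutoff.  Fold text truncates to a whole number at ≥10
(25.32/0.38 = 66.6 → "66-fold decrease", matching the printed value) and
keeps one decimal below 10; the exact ratio is always emitted alongside.
No statistical test is attached: the design has no replicates.

## Pipeline and reproducibility

`run-all` executes family → reads → trim → align → quantify (all modes) →
mappability → annotate → mechanism → compare → phylo, with one sub-seed per
stage derived from the config seed, plain-text intermediates, and a
manifest declaring every output.  Reruns with the same config are
byte-identical (fixed float formatting, no timestamps).  The demonstration
configuration uses the 12-provirus family at 50 000 pairs per sample with
200 bootstrap replicates; the heavier statistical checks in the test suite
use 200 000 pairs for EM recovery and 10 000 per suite elsewhere — problem
sizes chosen so the full suite runs in a couple of minutes on a laptop
while keeping Monte-Carlo noise well inside the asserted tolerances.

## Known limitations

* Ungapped alignment: real indel polymorphism between donor and reference
  would unalign reads rather than soft-clip them.
* The EM rescue allocates at pair granularity with one abundance per
  element; no positional re-estimation within elements, no isoform
  deconvolution.
* Identical duplicate pairs are fundamentally unresolvable: EM splits their
  joint mass evenly, and only the pair total is meaningful.
* Packaging efficiency is a free per-element truth parameter, not a
  sequence-computed quantity; the hypothesis that a 5' leader packaging
  signal explains it is not modeled.
* The type classifier reports "unknown" for heavily hypermutated elements
  whose anchors exceed the mismatch cap — a real limitation of
  anchor-based boundary typing.
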