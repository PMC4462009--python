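# Methods

This note documents the models, parameter choices and numerical
conventions behind `srnaome`, and what the synthetic-data harness does
and does not establish about real data.

## Small RNA substrate

Reads arrive adapter-trimmed; collapsing keeps 16–36-nt sequences (the
insert range of the emulated protocol), drops and counts everything
else, and is order-independent.  Mapping is exact over both strands —
no mismatches, matching the alignment settings the analysis emulates —
implemented as a sorted 16-mer seed index with verification.  Tags with
zero hits are retained but flagged unmapped; no hit-count cutoff is
applied at mapping time (the <40-hit rule is a miRNA-candidacy filter).

RPM normalization is `count · 10⁶ / total mapped reads of the library`;
summed over the mapped tags of a library it is exactly 10⁶.

**Top-5 % presence rule.**  A tag is "present" in a library when its
raw count ranks within the top 5 % of the library's *distinct mapped
tags*, ties at the boundary included.  Distinct-tag ranking (rather
than read-mass ranking) is used because it is stable under sequencing
depth changes; the boundary-tie rule makes the predicate monotone in
counts.  Reported percentages round half away from zero to integers;
read-count averages truncate toward zero.  These two rounding rules are
the report layer's contract.

The contaminant screen is exact matching (either strand) of every tag
against the contaminant genome, count-weighted — deterministic and
stricter than a heuristic local-alignment screen; with ≤ 36-nt tags the
difference is marginal and the exact rule is reproducible.

## Folding

Candidacy criteria are stated in terms of paired/unpaired positions, so
the built-in folder computes a maximum base-pairing structure (pairs
AU/UA/GC/CG/GU/UG, minimum loop 3, no pseudoknots) rather than a
thermodynamic minimum.  Maximum matching is massively degenerate;
among maximal-pair structures the folder deterministically prefers the
most stacked pairs, which resolves degeneracy toward the long helices
real hairpins form.  The pair count is the primary objective and is
never traded for stacking (verified against exhaustive enumeration for
sequences ≤ 18 nt).  Traceback order is pair-the-ends, stacked
continuation, then bifurcation at the smallest split, which fixes one
canonical structure.  The folder is pluggable — an `RNAfold` wrapper
with the same signature is provided and used as an independent
cross-check in the tests — but the built-in folder is the tested
contract.

## miRNA discovery

Excision is duplex-guided, in two stages, because folding every 250-nt
window around every mapped tag is neither informative nor tractable:

1. an ungapped antiparallel partner screen (G:U counts as pairing)
   within ±250 nt of the hit, on both sides of the tag.  The screen is
   a necessary condition for the duplex criterion: an accepted duplex
   leaves ≤ 4 mature positions unpaired, and the ungapped screen adds
   at most the 2-nt overhang edge, so windows with ≤ 6 screen
   mismatches proceed to folding;
2. windows with 7–8 screen mismatches are not folded but are still
   *scored* (read concentration plus screen pairing fraction) and enter
   the background pool over which the novel-mature percentile rule is
   computed, so that the "top 5 % of candidate scores" cutoff tracks
   the full candidate population, as a genome-wide score threshold
   does, rather than the handful of accepted hairpins.

The excised window spans tag, partner and a 15-nt flank (≤ 250 nt).
Acceptance requires: mature length 18–25 nt; top-5 % expression in ≥ 1
library; the mature on a single arm (no mature-mature pairing in the
duplex region); a star arm derived from the structure with 2-nt 3′
overhangs; ≤ 4 unpaired mature positions in the duplex with no bulge
> 2 nt; a real loop (≥ 3 nt) between the arms; and ≥ 60 % of precursor
bases paired.  The duplex is extracted as the longest antiparallel
chain of mature/star pairs with bounded asymmetry — stray long-range
pairs that a maximum-pairing fold adds are treated as unpaired, not as
extra stems.  If the full window's fold fails structurally, the window
trimmed to the screened duplex span is folded once more; flanking
sequence can otherwise divert the maximum-matching optimum.

**Scoring.**  The probabilistic precursor score of the original
discovery tool is not reproducible from its description, so a
transparent surrogate is defined:

    score = log2((mature_reads + star_reads + 1) / (other_reads + 1))
            + 2 · paired_fraction_of_mature

where "other" counts reads over the precursor *plus a 30-nt flank on
both strands*.  The flank term is what separates genuine pre-miRNAs
(no small RNA production around them) from siRNA-producing loci whose
edge reads can pair into neighbouring sequence by chance; without it,
abundant phasiRNAs occasionally pass as miRNAs.  Only the *percentile*
of the score matters: novel matures must reach the 95th percentile of
all candidate scores (accepted + background pool), so behaviour does
not depend on the surrogate's absolute scale.  Known and isomiR
matures bypass the score filter, and all precursors of every retained
mature are recovered regardless of score.

Overlapping accepted candidates (both-arm excision produces a mature-
and a star-arm version of each hairpin) are deduplicated per precursor
cluster: highest score, then more mature-arm reads, then the 5′ arm.

## Annotation

* *known*: exact full-length catalog match (U≡T).
* Families: greedy clustering of matures plus catalog representatives
  at ≥ 84.2 % identity, where identity = matches / length of the
  shorter sequence under the best ungapped offset.  Seeding order is
  longest, then most abundant, then lexicographic; catalog entries
  seed first so known families anchor on the reference.  An
  unclassified mature in a catalog-anchored family is an *isomiR*;
  catalog-free clusters found *novel* families.
* Conservation: exact full-length occurrence (either strand) per
  species genome; species-specific = absent from all non-self genomes.
* Genomic context: decided by the feature containing the precursor
  midpoint with precedence 5′UTR > 3′UTR > exon > intron > intergenic
  (midpoint containment because boundary-straddling precursors have no
  canonical assignment); orientation is sense when precursor and host
  gene strands agree.
* Transcript support: an expressed transcript fully contains the
  precursor on the same strand.

## Target prediction

Expectation is the minimal penalty of a global alignment of the miRNA
(5′→3′) against the reversed site: mismatch 1.0, G:U 0.5, gap 2.0, all
doubled at miRNA positions 2–13; a gap takes the seed factor of the
miRNA position that follows it (clamped at the 3′ end).  This is the
canonical plant-target scheme; the exact table of the original web tool
is not published, so this scheme is this package's contract.  Cutoffs:
expectation < 3 (strict) for targets, ≤ 5 (inclusive) for trigger
search — the strict/inclusive boundary conventions are fixed and
config-exposed.  Transcript scanning uses a fit-alignment DP of the
reversed miRNA over the whole transcript as a pre-screen (with slack
for gap-attribution differences) and re-scores each candidate site with
the exact scorer, keeping one site per overlap run (lowest expectation,
then 5′-most).  The slice site is the transcript base paired with
miRNA position 10; if position 10 is unaligned the gap-free convention
(site end − 9) applies.

## Degradome

Tags map exactly, sense-only, to spliced transcripts and to precursor
windows padded by 10 nt.  Processing validation: boundary reads B are
signatures within ±1 nt of the mature or star 5′ end; under the null
they are binomial with p₀ = boundary positions / precursor length; the
precursor validates when the one-sided tail P(X ≥ B) ≤ 0.05 and B ≥ 5.
The ±1-nt window and 5-read floor operationalize "a significant
processing event at the duplex boundaries" — values are the package's
own, chosen to tolerate 1-nt imprecision while excluding single stray
reads.

Cleavage calls: category 0 = unique transcript maximum with > 1 read;
1 = tied maximum; 2 = above the median of nonzero positions; 3 = > 1
read at or below the median; 4 = single read.  The p-value counts
dinucleotide-preserving shuffles of the miRNA (Altschul–Erickson-style
random Eulerian walks, seeded) that achieve, anywhere on the
transcript, an alignment at least as good with a same-or-better
category at its own predicted slice site: p = (1 + successes) /
(1 + n_shuffles), retained at p ≤ 0.05.  One scorer (the expectation
aligner) serves both prediction and degradome calling — a deliberate
unification so the two stages cannot disagree about what "a site" is.

## phasiRNA detection

Register axis: plus-strand 21-nt reads at their 5′ coordinate,
minus-strand reads at 5′ − 2 — without the 2-nt Dicer-overhang shift,
the two strands of one phased duplex would never share a register.
Only exactly-21-nt tags participate.  Windows are nine cycles (189 nt)
starting at each occupied position:

    score = (k − 2) · ln(1 + 10 ΣP / (1 + ΣU)),   k ≥ 3 (else 0)

Windows ≥ 15 are merged per (chromosome, register) when their spans
overlap, trimmed to the first/last occupied in-register position, then
extended along contiguous occupied in-register positions — leading
cycles can fall outside flagged windows when a second interleaved
register (or the trigger's own antisense hits at its binding site)
contributes off-phase mass.  Locus filters, in order: one-sided
chi-square of in-phase vs out-of-phase abundance against (N/21,
20N/21), 1 d.f., significant only for enrichment at p < 0.01; ≥ 3
in-register positions whose tags pass the top-5 % rule in ≥ 1 library;
no base overlap with a transposable element.  Loci are reported per
register, so a dual-phase locus yields two records on one interval.

Triggers: every mature is aligned (expectation ≤ 5) against the locus
sequence ± 90 nt in both orientations; 90 nt covers a trigger site a
few cycles upstream of a conservatively trimmed locus.  An assignment
is in phase iff its cleavage coordinate (minus-strand coordinates
shifted by −2 onto the register axis) is congruent to the locus start
modulo 21, with zero tolerance.

## Synthetic data

The generator emulates the five-organ study design: five libraries
(flower, leaf, root, seedling, nodule) of 5·10⁵ reads, 20 % background
noise, and an 8.3 % bacterial contaminant in the nodule library only.
Planted elements are laid out as non-overlapping blocks with random
spacers on `chr1..chrN`; coordinates are exact, and infeasible packing
fails with the violated constraint named.

* **Hairpins**: star = reverse complement of the mature duplex region
  with 1–3 planted non-pairing positions (real plant duplexes are
  never mismatch-free; a mismatch also keeps the star from being an
  exact substring of the mature's target sites), 2-nt 3′ overhangs,
  loop 8–60 nt.  The construction is rejection-sampled until the
  package's folder reproduces the planted duplex, which is the
  generator's contract: a "planted hairpin" that does not fold as one
  is not a hairpin.  Precursor contexts cover intergenic, intronic
  (sense and antisense), exonic and 3′UTR placements.
* ***PHAS* loci**: a trigger binding site whose predicted slice
  coordinate is the first base of the phased register, then 21-nt
  phasiRNAs tiling downstream; minus-strand loci follow the register
  conventions above.  One locus carries two interleaved registers
  offset by 31 nt (≡ +10 mod 21), each with its own trigger; dual
  loci get a longer span (17 cycles at the default 10), matching the
  ~360-nt scale of real dual-phase loci, because each register's reads
  are off-phase mass for the other.
* **Abundances**: known matures are expressed in all libraries,
  isomiRs in about half, novels in one or two (two novels are
  organ-specific); the star is 5–20 % of its mature (duplex
  asymmetry); each locus is expressed in three libraries.
* **Noise**: background reads are genome substrings of 18–25 nt drawn
  from a per-library pool of 1 000 "degradation hotspots" with mildly
  heterogeneous weights, never overlapping a planted element (±40 nt)
  and never equal to a planted sequence, so truth labels stay
  unambiguous.  A finite pool — rather than fully unique random
  substrings — keeps the collapsed count distribution long-tailed the
  way real libraries are; with all-unique noise the top-5 % rank rule
  degenerates to "every tag qualifies" and stops being the filter it
  is on real data.  The contaminant library draws from an analogous
  pool of contaminant-genome substrings.
* **Degradome**: 20-nt tags; peaks of height 50 at every planted
  cleavage position and at both duplex boundaries of every precursor;
  optional uniform 1-read noise at all other reference positions.

**What passing recovery shows — and does not.**  At the default
conditions (2-Mb genome, 20 miRNAs, 5 loci, 20 % noise) the pipeline
recovers all planted elements with no false discoveries across seeds.
This demonstrates internal consistency of all conventions (strands,
registers, coordinates, thresholds) and correct filter behaviour at
realistic signal-to-noise.  It does not demonstrate performance on
real libraries, whose noise includes structured degradation of real
transcripts, sequencing error, isomiR clouds around every mature, and
repeat families — none of which the generator models.  The per-library
distinct-tag universe (~1 000 hotspots + planted tags) is a deliberate
desk-scale reduction of the ~10⁵–10⁶ distinct tags of a real library.

## Problem sizes

The test suite exercises a 300-kb bundle (8 miRNAs, 3 loci, 5 × 5·10⁴
reads) for module tests and the full 2-Mb default design for the
recovery harness; the acceptance script runs the 2-Mb design once.
These sizes were chosen so the complete suite runs in minutes on one
CPU while keeping every rate estimated from ≥ 20 planted truths.

## Known limitations

* The folder maximizes pairing, not free energy; hairpin calls on real
  genomes would differ from an MFE folder in edge cases (the folder is
  pluggable for that reason).
* Splice-aware precursor assembly is not attempted; a precursor
  spanning an exon junction is missed by design.
* Randomization-based structure significance (randfold-style) is not
  implemented; the score percentile and duplex criteria carry that
  burden.
* 24-nt phasiRNAs and phase-drift detection are out of scope.
* The expectation scheme fixes one penalty table; other published
  tables differ in gap and bulge handling.
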