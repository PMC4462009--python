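# srnaome

Inference of a plant small-RNAome from small RNA and degradome
sequencing: miRNA hairpin discovery and classification, degradome-based
validation of precursor processing and target cleavage,
complementarity-based target prediction, and detection of 21-nt phased
siRNA (*PHAS*) loci with trigger-miRNA assignment.

The package is written for analyses like the common-bean (*Phaseolus
vulgaris*) sRNAome: a handful of organ-specific small RNA libraries
(flower, leaf, root, seedling, nitrogen-fixing nodule), one degradome
library, a reference genome with gene/ncRNA/transposable-element
annotation, and a reference mature-miRNA catalog.  Because such studies
cannot be regression-tested against their raw sequencing data at desk
scale, the package ships a first-class synthetic-data generator that
plants miRNA precursors, *PHAS* loci, target sites and degradome peaks
into a toy genome and records the exact truth, so every stage is
testable end to end.

## The methods in brief

* **miRNA discovery.**  Collapsed tags (16–36 nt) are mapped exactly to
  both genome strands.  A tag with fewer than 40 genome hits nominates
  candidate windows of ≤ 250 nt around each hit; windows overlapping
  annotated ncRNAs are discarded.  A candidate is accepted when the
  mature is 18–25 nt, ranks in the top 5 % of the most expressed mapped
  tags of at least one library, and the folded window shows a
  mature/star duplex with ≤ 4 unpaired mature positions, no bulge
  > 2 nt, 2-nt 3′ overhangs and ≥ 60 % stem pairing.  Matures that are
  not exact catalog matches and do not cluster with a catalog family at
  ≥ 84.2 % identity are "novel" and additionally require a precursor
  score in the top 5 % of all candidate scores; all precursors of every
  retained mature are then recovered regardless of score.
* **Targets.**  Expectation = penalty-sum of the best miRNA:site
  alignment (mismatch 1, G:U 0.5, gap 2; doubled at miRNA positions
  2–13).  Targets require expectation < 3; phasiRNA-trigger search uses
  ≤ 5.  The predicted slice site is the transcript base opposite miRNA
  position 10.
* **Degradome.**  5′-end tags map sense-only to transcripts and
  precursor windows.  Precursor processing is validated by a one-sided
  binomial test of signature abundance within ±1 nt of the mature/star
  5′ boundaries (p ≤ 0.05, ≥ 5 reads).  Cleavage calls carry the
  standard categories 0–4 and a dinucleotide-shuffle p-value (retained
  at p ≤ 0.05).
* **phasiRNA loci.**  21-nt reads are pooled on a register axis
  (minus-strand 5′ ends shifted by −2 nt for the Dicer overhang); a
  nine-cycle window scores
  `(k−2)·ln(1 + 10·ΣP/(1+ΣU))`, and windows ≥ 15 are merged into loci
  that must pass a one-sided chi-square enrichment test (p < 0.01),
  have ≥ 3 top-5 % in-register positions, and not overlap a
  transposable element.  Trigger miRNAs are assigned at expectation ≤ 5
  with an exact in-phase test modulo 21.

## Worked example

Simulate a small bundle and run every stage:

```bash
srnaome simulate --outdir demo --seed 11 --genome-length 300000 \
    --n-mirnas 8 --n-phas-loci 2 --library-depth 50000
srnaome run --config demo/pipeline.yaml --outdir demo_run
```

which prints the run summary

```json
{
 "mature_class_counts": {"isomiR": 1, "known": 4, "novel": 3},
 "n_accepted_candidates": 23,
 "n_candidate_windows": 7656,
 "n_cleavage_calls": 8,
 "n_final_matures": 8,
 "n_phas_loci": 3,
 "n_phas_triggered_in_phase": 3,
 "n_precursor_calls": 8,
 "n_target_alignments": 8,
 "n_unique_tags": 5834
}
```

All 8 planted matures are recovered (4 exact catalog matches, 1 isomiR
of a catalog family, 3 novel), each with a degradome-supported
precursor; all 8 planted target sites are called from the degradome;
the 2 planted *PHAS* loci are reported as 3 register records (one locus
carries two interleaved registers, each with its own in-phase trigger).
`demo_run/` then holds the per-stage tables: `matures.tsv`,
`precursors.gff3`, `targets.tsv`, `cleavage.tsv`, `phas.tsv`, the
report tables and a `manifest.json` with output checksums (re-running
the same config reproduces them byte for byte).

Stage subcommands (`map`, `mirna`, `annotate`, `targets`, `degradome`,
`phas`, `report`) write the corresponding subset of outputs.

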