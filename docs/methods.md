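# Methods

This note records the models, conventions and design choices behind the
package, in the spirit of a software methods section. It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Coordinates, gene models and intron extraction

All coordinates are 1-based inclusive (GFF3 convention); an interval
`(start, end)` spans `end − start + 1` nt. Genomic intervals are stored in
ascending order on both strands; everything transcript-level (intron
ordinal, phase, sequence) is computed in transcript orientation, with
minus-strand sequences reverse-complemented.

One `GeneModel` is built per mRNA. Coding exons come from CDS features; no
minimum-exon filter is applied, so 1-nt first exons and 4-nt internal exons
are legal. 5' UTR introns are only those representable as gaps between exon
features lying wholly upstream of the first CDS base — no ab initio UTR
inference. A CDS length that is not a codon multiple on a non-pseudo gene
warns and flags the gene rather than dropping it; unresolved `Parent`
references and duplicate FASTA ids are hard errors. Pseudogenes are parsed
but excluded from all downstream statistics by default.

Intron ordinals are numbered per compartment (CDS introns 1..k in transcript
order, 5' UTR introns separately), so "first intron" statistics always mean
the first intron of the coding sequence. Phase is the cumulative upstream
coding length mod 3 and obeys the chain rule
`phase_k = (phase_{k−1} + exon_length) mod 3`, which the tests verify on
both strands.

A downstream-statistics filter defaults to a 30-nt minimum intron length —
a conservative floor below the shortest intron plausible in a compact
fungal genome — while the extractor itself imposes no minimum.

## Splice-signal detection

The donor is the first intron hexamer, the acceptor the last trimer
(flagged canonical when it matches (C|T)AG). The branch point is the
**rightmost** exact CTAAC whose match lies wholly within a 60-nt window
immediately upstream of the acceptor trimer; if absent, the rightmost
degenerate CT(A|G)AC (which covers the TGCTGAC-style divergent branch
points seen in poorly spliced genes); if that also fails the fields are
None. Rightmost tie-breaking reflects the branch-point–acceptor
juxtaposition characteristic of these genomes and is configurable to
leftmost, as is the window. S1 counts the nucleotides between donor and
branch point, S2 those between branch point and acceptor. No PWM-scan BP
detection is attempted: there is no principled scoring scheme to calibrate
it against, and the exact-then-degenerate search is transparent.

## PTC scanning and motif attribution

`scan_retained_stops` reads codons starting at intron position
`((3 − phase) mod 3) + 1` (= 1, 3, 2 for phases 0, 1, 2) and records every
wholly-intronic TAA/TAG/TGA. Codons straddling the exon–intron junction are
deliberately excluded here: the motif rule system is expressible purely
intron-internally, and junction-spanning stops are caught by
full-transcript translation in the consequence module instead.

Each stop is labelled with every motif interval it overlaps (donor
positions 1–6, detected branch-point interval, terminal trimer), else
OTHER. Because "fraction of stop codons" and "fraction of stop-containing
introns" attributable to motifs are different denominators, the summary
reports both.

`rule_table()` derives the nine (phase × length-class) cells analytically:
donor stops for phase 2 in every class; branch-point TAA at the canonical
S2 = 1 in frame when `(class − 1) mod 3 == first_inframe_start mod 3`;
acceptor TAG in frame when `(class + 1) mod 3 == first_inframe_start mod 3`.
`bp_stop_in_frame(phase, class, s2)` generalizes the branch-point rule to
arbitrary spacing, since real S2 distances vary around one.

## The stop-free null

Under the uniform-codon null a string of L codons is stop-free with
probability `(61/64)^L`. The boundary length — the largest L with
probability ≥ 0.05 — is computed by iteration and equals 62
(`(61/64)^62 ≈ 0.0509`, `(61/64)^63 ≈ 0.0485`). The threshold is the
proportion 0.05: that is the only reading consistent with a 62-codon
boundary. A codon-usage mode instead derives the per-codon stop probability
from independent per-position base frequencies of the analyzed genome's
CDSs (stop codons excluded), which matters for genomes far from 50% GC.

Observed-vs-expected stop content is compared per (length class, 20-nt
bin), restricted by default to introns shorter than 186 nt (62 codons),
where stop-free introns are still expected by chance and constraint is
therefore detectable.

## Consequence prediction

Variant mRNAs are modelled as the coding region (concatenated coding
exons) with events applied: retention splices the intron back in, exon
skipping removes an internal exon (skipping the first or last coding exon
is unsupported), alternative 5'/3' splice sites transfer `offset_nt`
nucleotides between intron and flanking exon (negative offsets trim the
exon), and an alternative TSS re-anchors the 5' end at a genomic
coordinate — dropping upstream pieces, carrying a clipped intron remainder
into the transcript (its donor is gone), and starting translation at the
first downstream AUG. Retention combined with alternative splice-site use
on the *same* intron is rejected; the same events on different introns
compose freely.

Translation uses the standard nuclear code and stops at the first in-frame
stop. Because these mRNAs end with the annotated terminator, a stop is
premature exactly when complete codons remain downstream of it; a shorter
but normally-terminated protein (e.g. after in-frame exon skipping) is not
a PTC. Transcripts with no in-frame stop are flagged, not errors.
`frame_preserving` compares variant and annotated mRNA lengths mod 3 and is
undefined for TSS-re-anchored variants.

## Resampling test

Subsets are drawn **without replacement**; ties (resampled mean exactly
equal to observed) count as exceedances; the add-one estimator
`p = (count + 1)/(reps + 1)` avoids zero p-values. The default is 10,000
repetitions because 100 repetitions bound p below by 1/101 ≈ 0.0099; the
historical 100-rep design remains available via `--reps`. Calibration
(p approximately uniform when the subset is itself a random draw) is
checked by a seeded Kolmogorov–Smirnov test.

## The synthetic-data generator

The generator emulates the statistical structure of an intron-poor,
GC-rich hemiascomycete genome. Defaults (all configurable, probability
vectors validated to sum to 1):

| parameter | default | meaning |
|---|---|---|
| `gc_content` | 0.49 | genome-wide GC of CDS, introns, intergenic |
| `intron_fraction_of_genes` | 0.15 | genes carrying ≥ 1 CDS intron |
| `introns_per_gene_probs` | (.885, .098, .012, .003, .002) | 1–5 introns among intron-bearing genes |
| `phase_probs` | (.402, .380, .218) | intron phase distribution |
| `length_class_probs` | (.294, .355, .351) | 3n / 3n+1 / 3n+2 |
| `short_length_weight` | 0.25 | mass of the uniform 41–60 nt peak |
| `long_length_mu`, `sigma` | 5.33, 0.85 | lognormal tail offset by 61 nt, capped at 3,478 |
| `five_ss_probs` | GTGAGT .70, GTAAGT .10, random GT-hexamer .20 | donor mixture |
| `s2_probs` | 0:.05, 1:.80, 2:.10, 3:.05 | branch-point–acceptor spacer |
| `three_ss_probs` | CAG .89, TAG .105, AAG .005 | acceptor mixture |
| `stopfree_target_fraction` | 0.081 | introns forced stop-free |
| `first_decile_bias` | 0.60 | introns placed in the first 10% of the CDS |
| `utr5_intron_rate` | 0.0056 | genes given a 5' UTR intron (2× longer on average) |
| `pseudo_fraction` | 0.021 | pseudogene rate |

The lognormal tail parameters were chosen once so the length mixture's mean
is ≈ 280 nt and median ≈ 204 nt; the underlying real distribution is known
only as a histogram, so the parametric form is a modelling choice.

Genes are random non-stop codon strings (ATG…stop) of lognormal length;
intron insertion points are drawn per the decile bias and shifted to the
sampled phase; intron sequences are donor + random interior + CTAAC +
spacer + acceptor. **Stop content is enforced in both directions**: introns
flagged stop-free (Bernoulli at the target fraction) have offending
stop-codon bases in the interior/spacer resampled codon-wise until clean,
and unflagged introns are redrawn until they contain a stop. The two-sided
enforcement is what makes the planted fraction recoverable — short random
introns are otherwise stop-free by chance about half the time, which would
swamp an 8% target. A stop that lies wholly within fixed motif positions
cannot be scrubbed; after bounded retries over motif combinations the
generator raises an error naming the conflicting cell, which is exactly
what happens for configurations like a forced TAG acceptor with a forced
stop-free intron in a cell where the terminal TAG is in frame.

What the generator does **not** emulate: real splice-site degeneracy beyond
the configured mixtures, branch-point-free introns, sequence composition
heterogeneity along chromosomes, overlapping genes, alternative transcripts
per locus, 3' UTR structure, and any expression-level signal. Passing
recovery tests therefore show the pipeline measures what was planted, not
that real genomes obey the planted distributions.

## Numerical and reporting conventions

Chi-square tests are Pearson goodness-of-fit against a uniform null over
categories (no other null is defined for these tables), df = k − 1, no
continuity correction, via `scipy.stats.chisquare`; an independent
hand-rolled Pearson sum agrees to 1e-9 in tests. Counts reconstructed from
printed percentages use nearest-integer rounding with ±1 residuals assigned
by largest remainder so they sum to the printed total. Reported statistics
round to 2 decimals and percentages to 1 decimal, half away from zero.
Degenerate inputs (empty tables, zero denominators, empty annotations) are
either errors with explicit messages or produce zero-count reports, as
documented per function.

Test problem sizes: recovery checks run on a ~6,700-gene genome
(≈ 1,100 planted introns, so 3 binomial SE is a few percentage points);
the scanner-vs-translation oracle uses 10,000 random (sequence, phase)
pairs; exhaustive enumerations back the stop-free closed form up to three
codons and the resampling test on a 5-element population.

## Known limitations

* Branch-point detection is motif-matching, not scoring; genuinely
  degenerate branch points beyond CT(A|G)AC are reported as absent.
* The consequence module models coding regions only; UTR-mediated effects
  on translation (uORFs, reinitiation) are out of scope, as is any model of
  NMD kinetics — the package predicts PTC status, not decay.
* `codon_usage` null mode assumes positional independence of base
  frequencies within codons.
* Multi-mRNA genes are handled by treating each mRNA as a gene model;
  overlapping loci are counted independently.
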