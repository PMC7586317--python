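# Methods

## Model and assumptions

`trnafrag` treats tRF identification as an exact-placement problem on
purpose-built references rather than a general alignment problem. The
underlying biological model:

* A tRNA gene is transcribed with a 5′ leader and 3′ trailer; RNase P cleaves
  the leader boundary (**mature start**) and RNase Z the trailer boundary
  (**editing point**). CCA is added post-transcriptionally exactly at the
  editing point.
* Fragment classes are therefore *positional*: a class is determined by where
  a fragment's ends fall relative to the two anchors, plus whether its
  terminal CCA is genome-templated or not.
* All matching is full-length and exact (0 mismatches, no indels, no
  clipping). This is deliberate: with 15–29 nt reads a single tolerated
  mismatch already destroys class separation between near-identical tRNA
  copies, and the CCA/non-CCA distinction relies on exactness. Reads
  containing N never match. The cost is sensitivity to sequencing error; an
  erroneous read simply falls out as unmatched rather than being misplaced.

Introns are retained in the extended reference (so 3′-fragments of
intron-containing genes map at an offset reflecting the unspliced precursor)
and spliced only in the deduplicated unique-mature set. Minus-strand genes
are stored sense-strand so anchors always read left-to-right. Coordinates
are 0-based half-open everywhere internally; BED is ingested as 0-based and
GFF3 as 1-based inclusive, converted on input.

## Parameters that matter

| parameter | default | meaning / rationale |
|---|---|---|
| leader `up` | 25 nt | genomic extension 5′ of the gene; leader fragments and 5′-anchor live here |
| trailer `down` | 80 nt | genomic extension 3′; covers tRF-1 and taRFs. Clamped (and recorded) at contig ends — mitochondrial genomes routinely truncate it |
| tolerance `w` | 2 nt | window around anchors absorbing ragged fragment ends without collapsing classes; configurable |
| length window | 15–29 nt | the library's size selection; `min_len=17` reproduces the exclusion of the smallest (15–16 nt) fragments |
| adapter `min_overlap` | 7 nt | minimal adapter prefix at the read end accepted as clipping evidence |
| snoRNA split | 120 nt | ≤ 120 nt box C/D, > 120 nt box H/ACA |
| multimapper policy | `first` / `random` | `first` (smallest (ref, start)) wherever only the aligned/unaligned partition matters; seeded uniform `random` for coverage maps |

Classification precedence on non-edited coordinates is LEADER, FIVE_PRIME,
TRF1, TARF, I_TRF (first match wins); 3′-CCA fragments are classified on the
edited reference (end = editing point + 3 ± w, sequence ends CCA); SPANNER
is assigned only by the realignment rule: a non-CCA placement whose read has
no placement on the CCA-edited set. TRF1 has no enforced 3′ boundary (no
poly-U terminator model — termination signals are not modelled), and taRF is
a positional proxy (start > editing point + w within the trailer).

A caveat of following the staged workflow literally: a read whose *genomic*
sequence happens to end in CCA right at the editing point matches the
non-edited set first and is classified positionally there; it is never
force-labelled THREE_PRIME_CCA.

## Normalization

Size factors are median-of-ratios: for features with all-positive counts,
NF_j = median_i( c_ij / g_i ) with g_i the geometric mean of feature i
across samples; zero-containing features are excluded, and an even number of
usable features takes the mean of the two central ratios. Maps and tables
are scaled by 1/NF. Two properties worth stating precisely, because they are
easy to get wrong: multiplying one library by a constant c rescales *every*
factor (the geometric means move), but the between-sample factor *ratios*
scale by exactly c; and re-normalizing an already-scaled table yields equal
factors for all samples (the geometric mean of the originals), not
necessarily 1 — median-of-ratios does not constrain the factors' own
geometric mean. Both are verified against a scalar brute-force oracle in the
tests. Ratios between genotypes report a zero denominator as NA with an
explicit flag, never as infinity. The heatmap transform is log2(value + 1),
which is monotone and so preserves within-sample ordering.

## Two heatmap reference modes

Counting against the extended CCA-edited reference represents all fragment
classes but multimaps across tRNA gene copies with identical bodies (a
logged warning, not silently resolved); counting against the unique-mature
CCA-edited set removes multimapping but cannot represent tRF-1 (the trailer
is not part of the mature sequence). Both modes are exposed.

## The annotation cascade

Reads are assigned to the first reference category they match, in a stated
order; the order is a genuine bias knob because one sequence can belong to
several categories. Two published orders ship as named profiles —
`methods` (tRNA, tRNA-CCA-edited, miRNA, TE, ncRNA, genes, intergenic) and
`figure` (miRNA, ncRNA, intergenic, genes, TE, snoRNA, tRF-non-CCA,
tRF-CCA) — default `methods`. The `methods` profile carries no snoRNA
category (its position in that ordering is not defined); the `figure`
profile includes it.

## Synthetic fixtures: what they do and do not show

The generator builds a toy genome (default 10 nuclear + 2 mitochondrial
tRNA genes, bodies 70–90 nt, strands alternating, 20% of nuclear genes with
a 40–44 nt intron opening at mature position 37), snoRNAs straddling the
120 nt threshold, auxiliary rRNA/miRNA/TE/ncRNA/genic/intergenic sets, and
100 reads per fragment class sampled at the class-defining coordinates with
a TruSeq-style 3′ adapter appended. Defaults were chosen once as a
desk-scale image of a real annotation (hundreds of genes, sixteen intronic
in the fly) that still exercises every structural case.

Truth must be unambiguous for exact-recovery assertions, so the generator
rejection-samples: every sequence unit's 15-mers are unique fixture-wide on
both strands; spacer edges avoid bases that would mimic the CCA insertion;
each gene is resampled until no 15–29 nt junction-crossing window occurs
anywhere in its edited sequence (otherwise a genomic trailer starting with
C makes the insertion locally invisible and a true spanner would match the
edited reference); and each sampled read is verified to place exactly at
its intended site and nowhere else.

Consequently, passing fixtures demonstrate the *logic* of the pipeline —
staging, classification geometry, conservation, determinism — under
noise-free, ambiguity-free conditions. They do not demonstrate robustness
to sequencing error, RT stops at modified nucleotides, ligation bias,
tRNA-lookalike genes, or reads genuinely shared between categories; real
libraries contain all of these, and the cascade-order bias is then material.

## Numerical choices

* Ties in `first` mode break lexicographically on (ref name, start); random
  placement draws from one seeded stream consumed in input order, so a run
  is byte-reproducible from its seed, and one seed governs a whole run.
* Metaprofiles use scale-regions semantics: a region of length L is
  stretched to B bins with edges floor(b·L/B); the bin statistic is the
  mean, and a bin narrower than one base reuses the base it falls on
  (only possible when B > L).
* Logos are right-aligned position-frequency matrices over the last 15 nt
  (the motif of interest, CCA, is 3′-anchored); shorter sequences contribute
  only their rightmost positions, U folds onto T, and unfilled columns are
  all-zero rather than renormalized.
* Coverage is emitted as run-length-encoded bedGraph and TSV — bit-exact and
  dependency-free — rather than BigWig.
* Adapter clipping is exact, leftmost-occurrence-wins, with a ≥ 7 nt adapter
  prefix at the read end accepted; unclipped reads are dropped by default
  because in a size-selected library a missing adapter implies an insert
  longer than the read. Qualities are parsed but ignored (exact matching
  makes quality trimming redundant).

## Known limitations

* No mismatch tolerance means no recovery of edited/modified or erroneous
  reads; abundance estimates are floors.
* tRNA halves (≥ 30 nt) are out of scope by library design (the 15–29 nt
  size selection cannot capture them reliably).
* taRF and TRF1 boundaries are positional proxies; no terminator model.
* The cascade's category resolution is order-dependent by construction; the
  order is reported with every summary rather than hidden.
* Fixture-scale problem sizes (a dozen genes, hundreds of reads, 10⁴-scale
  oracle batches) were chosen as the package's own desk-scale defaults; all
  operations scale linearly in reads × references for larger inputs.
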