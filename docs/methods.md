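# Methods

## Discrete transcriptome mappability

A position *i* of genome *G* is mappable at read length *k* and safety
margin ε iff the k-mer `G[i:i+k]` is not within Hamming distance ε of any
*other* k-mer occurrence in *G* or in the transcriptome *T*. The safety
margin is what distinguishes this from plain uniqueness: a mappable
position guarantees that no read carrying up to ε mismatches (base-call
errors or subject-genome SNPs) can be uniquely misaligned there. Hamming
distance is the right metric because short-read aligners score substitutions
against a fixed-length window; indels are out of scope.

Occurrences are compared by *location*, not by string: the forward and
reverse-complement readings of the same genomic start are one occurrence,
so a unique palindromic k-mer is not its own neighbour, while a
reverse-complement match elsewhere does disqualify a position (reads are
sequenced from both strands, so opposite-strand duplicates are genuinely
ambiguous). K-mers containing N are unmappable and excluded from being
anyone's neighbour.

The transcriptome enters through synthetic regions: for each distinct
annotated splice junction, the last k−1 transcript bases of the donor exon
concatenated with the first k−1 of the acceptor exon (reverse-complemented
extraction on the − strand). Every junction-crossing k-mer occurs in
exactly one such region. Regions are compared against the genome and
against each other, so two near-identical junctions (parent vs duplicated
pseudogene) disqualify each other's k-mers. Exons shorter than k−1
contribute what they have; the region is flagged truncated, never padded.

### Parameters

- `k = 50` (bases). Mappability must be computed at the actual read
  length; a longer k overstates distinctiveness and loses specificity.
  50 is the default because it matches the read length of the breast
  cancer RNA-seq compendium this method targets.
- `epsilon = 2` (mismatches). Matches the common aligner setting of two
  allowed mismatches; one or two errors/SNPs per read is the regime in
  which unique misalignment between gene and pseudogene actually occurs.
  Monotone: the mappable set at ε+1 is a subset of the set at ε.

### Algorithm and verification

The production path uses pigeonhole partitioning: each k-mer is split into
ε+1 contiguous segments; any two k-mers within Hamming distance ε must
agree exactly on at least one segment, so candidate neighbours are found by
exact segment grouping and then verified by vectorised Hamming comparison.
A brute-force all-pairs implementation with the identical contract (guarded
to ≤50 kb of input) serves as the independent oracle; the test suite checks
exact equality of the two on dozens of random genomes across
k ∈ {8, 15, 25, 50} and ε ∈ {0, 1, 2}, with and without synthetic regions.

### From k-mer starts to mappable bases

Mappability is attached to the k-mer start position. For per-gene counting,
a base is mappable iff covered by at least one mappable k-mer window, or
iff it falls within the genomic provenance of a junction k-mer that occurs
exactly once in genome plus transcriptome (the spliced clause). The
spliced clause is evaluated from junction k-mer uniqueness, independent of
any observed read. Counting is strand-agnostic over the consensus gene
model — the union of all annotated exonic positions across transcripts.

Coverage counting is deliberately laxer than start counting: a base
surrounded by ambiguous sequence on one side may still be covered by a
distinctive window from the other. The per-gene retained-read fraction is
governed by mappable *starts* while the RPKUM denominator uses covered
*bases*; the resulting mild, largely uniform attenuation does not disturb
rank comparisons, which is what the downstream analysis consumes.

## Read filtering and RPKUM

A read survives iff it is uniquely aligned (exactly one reported candidate
alignment) AND (1) unspliced with a mappable start, or (2) spliced across
an annotated junction whose crossing k-mer is unique. Reads spanning two or
more junctions are conservatively dropped (the synthetic-region model
covers single junctions; at k = 50 and exons ≥ k such reads do not arise).
Every input read lands in exactly one ledger bucket — retained, unaligned,
multi-aligned, unmappable, or non-genic — and the buckets sum to the input
count.

RPKUM = retained reads × 10⁹ / (mappable bases × total reads), where
"total reads" is all aligned reads in the sample before filtering, keeping
values comparable across genes within a sample. A gene with zero mappable
bases has *undefined* RPKUM (NaN), not zero; genes with <50 mappable bases
are flagged unquantifiable and never called transcribed. When a gene is
fully mappable, RPKUM equals classical RPKM identically.

Transcription calls: ≥50 mappable bases, and ≥50 reads plus ≥1 RPKUM in at
least one sample; recurrent if the per-sample thresholds hold in at least
`floor(0.10 × n_samples)` samples (floor, minimum 1). A retained read whose
start lies in two genes' consensus models is counted for both; annotation
overlap is rare and the alternative (arbitrary assignment) hides signal.

## ceRNA screen

- **Pseudo-3′ UTR.** Each annotated parent 3′ UTR is locally aligned
  (Smith–Waterman, match +2, mismatch −3, gap open 5, gap extend 2)
  against the pseudogene locus ±10 kb. Significance is an ungapped
  Karlin–Altschul E-value, `E = K·m·n·exp(−λS)` with λ solved from the
  scoring scheme under uniform base composition (λ ≈ 0.634 for +2/−3) and
  K = 0.1; the cutoff is 1e−6. Among passing alignments the longest
  subject span wins; ties break to smaller E-value, then leftmost start.
  A reader for BLAST tabular output (outfmt 6) is provided so an external
  aligner can be slotted in.
- **Target prediction.** Canonical seed-match classes only: 8mer,
  7mer-m8, 7mer-A1, and 6mer (a 6mer is only reported where it is not
  part of a longer site). Context scores and conservation are not used —
  downstream logic consumes only the binary "targets / does not target"
  call, and a shared miRNA is one with ≥1 site on both the pseudo-3′ UTR
  and a parent UTR. Only the top 100 miRNAs by mean expression are
  scanned (ties at the cutoff are all included); isomiRs are distinct
  entries. U/T are normalised before matching.
- **Correlation.** Pearson r on log2(x+1)-transformed expression,
  computed over co-present samples only (both members ≥ 1 expression
  unit); pairs with <20 co-present samples are excluded. Correlating
  co-present samples avoids zero-inflation artifacts from samples where a
  transcript is simply absent. One-sided p-values come from the
  correlation T-statistic, `t = r√(n−2)/√(1−r²)`, testing H0: ρ ≥ 0 for
  the anti-correlation direction.
- **Permutation null.** For the count of pairs correlated beyond a
  threshold (default 0.3), 5000 random re-pairings of the two sides are
  scored under the identical presence filter; empirical
  p = count/n_permutations (so 5 extreme permutations of 5000 give
  p = 0.001). The permutation is seeded and bit-reproducible.
- **Triples.** A pseudogene/parent/miRNA triple is reported iff the miRNA
  is shared, r(pseudo, gene) > 0.3 strictly, and the pseudogene–miRNA
  anti-correlation is BH-significant at q < 0.05. Significance is
  required on the pseudogene side; the gene-side q-value is reported but
  not gated on, since the screen's hypothesis is that the *pseudogene*
  responds to the miRNA it sponges.

## Synthetic data

The generator emulates exactly the features the pipeline is sensitive to:

- genomes with parent genes (2–5 exons, 150–400 bp, both strands) and
  processed (spliced-transcript insertions), duplicated (genomic copies)
  and unitary pseudogenes at a controlled per-base divergence rate
  (default 5%, a typical pseudogene age);
- subject-genome SNPs placed inside expressed transcripts, per-base read
  errors (default 0.5%), and uniform read starts — Poisson read counts at
  `RPKM × kb × library/10⁶`;
- an idealised exhaustive aligner that reports *every* candidate
  alignment within 2 mismatches on either strand, direct or spliced, so
  filter behaviour is tested against complete alignment evidence rather
  than a heuristic aligner's output;
- expression matrices with planted ceRNA structure: per sample, a latent
  miRNA level and a shared factor drive pseudogene and gene
  log-expression as `a·f − b·c + noise` (defaults a = b = 1,
  noise σ = 0.8, giving r(pseudo, gene) ≈ 0.75 and
  r(pseudo, miRNA) ≈ −0.6); values are emitted as `2^(5+latent) − 1` so
  the log2(x+1) transform recovers the latent scale exactly.

The robustness simulation draws 1000 genes of 1 kb with true RPKM uniform
on [1, 200] at a library size of 5×10⁶ reads, then declares m ∈ {50, 100,
500} random positions per gene to be its only mappable bases. The library
size is a design choice: the depth is unstated in the setting this
emulates, and 5×10⁶ matches the low-coverage, pseudogene-like read pool
(order 10⁷ pseudogene-mapped reads per sample) whose sampling noise
produces the characteristic correlation regime ρ ≈ 0.95/0.97/0.99; the
correlations rise toward 1 at greater depth and fall at lesser, so the
reported values should be read relative to this regime.

What the simulations do **not** model: fragmentation/GC bias, quality-score
error profiles, paired ends, indels, alternative isoform usage, and
annotation error. Passing tests therefore demonstrate the correctness of
the computation and its behaviour under the stated noise model, not
performance on any particular real library.

## Numerical choices and degenerate inputs

- Coordinates are 0-based half-open internally; GTF I/O converts to/from
  1-based closed. Parent links travel in a separate
  `pseudogene_id/parent_gene_id/pseudo_class` TSV since GTF has no field
  for them.
- Chromosomes shorter than k yield empty (all-unmappable) track vectors
  with a warning; the brute-force oracle refuses inputs over 50 kb.
- `compute_rpkum` errors on zero total reads; undefined (0-base) cells are
  NaN and excluded from calls.
- miRNA ranking ties are resolved by id for determinism; BH adjustment is
  order-invariant; all generators are reproducible bit-for-bit under a
  fixed seed.
- The mappability BED records k, ε and per-chromosome vector lengths in
  its header so the round trip is lossless.

## Known limitations

- Junction reads with an overhang of ≤ ε bases into the acceptor exon are
  often ambiguous with a mismatched direct alignment; the filter drops
  them (conservative by construction — specificity over sensitivity).
- Gene-level only: isoform abundance and EM-style multi-mapper rescue are
  deliberately out of scope; the method's premise is that rescued
  multi-mappers are exactly the reads one cannot trust at pseudogenes.
- The E-value calibration is the ungapped approximation applied to gapped
  alignments; it is used only as a pass/fail gate at 1e−6, far from the
  decision boundary for genuine homology.
- At desk scale the mappability computation is exact; genome-scale runs
  would need an external k-mer index, which this package does not ship.
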