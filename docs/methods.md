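# Methods

## Measurement model

A library molecule is a cap-enriched transcript 5' fragment whose
adenosines were chemically deaminated unless N6-methylated. For an A-TSN
with true m6Am fraction *s* and conversion efficiency *ε* (probability
that an unmethylated A is deaminated), the probability of reading A at
the start position is

```
E[non-conversion] = s + (1 − s)(1 − ε)
```

so with complete conversion (ε = 1) the non-conversion rate A/(A+G) is an
unbiased binomial estimator of *s*. The same algebra gives the expected
calibration line against standards of known stoichiometry: slope ε,
intercept 1 − ε. Observed C/T bases at an A-TSN are sequencing errors;
they count toward site depth but are excluded from the A/(A+G)
denominator. A non-conversion rate is *undefined* (not zero) when a site
shows no A or G at all.

Internal m6A behaves identically at non-start positions: the body of each
restored read is piled up at transcript-sense adenosine positions, and a
site is called when covered by ≥ 50 reads in both compared genotypes with
non-conversion ≥ 0.2 in either; a DRACH (D=A/G/T, R=A/G, H=A/C/T) context
flag is attached from the genome.

## Pipeline stages and parameter defaults

| parameter | default | role |
|---|---|---|
| UMI length | 11 (8 supported) | PCR-duplicate collapse key |
| spacer | `ATAT`, exact match | anchors the +1 nucleotide; any slippage corrupts the start coordinate, so no mismatches are tolerated |
| adapter error rate | 0.25 | semi-global 3' suffix match, longest trim on ties, iterated to a fixpoint so trimming is idempotent |
| quality cutoff / min length | Q20 / 32 nt | running-sum 3' trim; shorter reads rejected |
| seed length k | 16 | exact converted-space k-mer seeds at both ends and the middle of the query, so one substitution can never break all seeds |
| scoring | match 0, mismatch −6, ungapped | paired score = mate1 + mate2 |
| uniqueness | score > −10, best − second > 9 | rank-1 ties count as secondary and are rejected |
| 5' softclip | 0 required on read 1 | a clipped first base means the TSN was not observed |
| identification / quantification depth | 20 / 50 deduplicated reads | depths summed across replicates before the 20-read cut |
| TSS window / priority | 100 nt, snRNA > snoRNA > protein-coding > lncRNA > others | same-strand only; ties broken by distance then gene id |
| similarity call | qcov ≥ 50 %, identity ≥ 50 %, word 10, bit ≥ 50 | Smith–Waterman (+1/−2, gap −2.5), Karlin–Altschul bits with λ = 1.33, K = 0.621 |
| TATA window | −36..−19, motif TATAWAWR | the 8-mer must lie fully inside the window |

The alignment score scale is implementation-defined (the published
uniqueness thresholds are meaningful relative to a match-0 scale, so
match 0 / mismatch −6 is used and is configurable through
`AlignScoring`). Gapped alignment is not implemented: the simulator's
only error mode is substitution, and the uniqueness filtering — not indel
handling — is the behaviour under test. Spliced alignment is likewise out
of scope; simulated genes are intronless across the 5' window, so the
two-pass transcriptome-then-genome strategy of spliced aligners collapses
to a single genome pass. The internal aligner only emits full-length
candidates, so softclipped records cannot arise from it; the softclip
filter is enforced on the record level and exercised on constructed
inputs.

## TSS motif classification

Motifs are matched at fixed offsets around the start nucleotide (+1; no
position zero): SSCA+1GC = S(−3)S(−2)C(−1)A(+1)G(+2)C(+3),
BBCA+1BW = B(−3)B(−2)C(−1)A(+1)B(+2)W(+3), VA+1RR = V(−1)A(+1)R(+2)R(+3),
BA+1 = B(−1)A(+1). The four classes overlap; precedence is
SSCA+1GC > BBCA+1BW > VA+1RR > BA+1, i.e. more specific (longer) motifs
first, which is the natural resolution when a context satisfies several
definitions. Any N among the examined positions yields "none". The
classifier is verified exhaustively against an independent direct-IUPAC
oracle over all 4^8 length-8 contexts.

## m6Am gene index

The gene index is the fraction of a gene's TSN signal attributable to
m6Am starts. The default is **read-weighted** — Σ over A-TSNs of
depth·non-conversion divided by Σ depth over all TSNs — because the
quantity is used in a transcript-abundance sense (what fraction of the
gene's transcripts carry m6Am). An unweighted per-position variant is
available behind a flag (`weighted=False`). When site depth equals
A+G counts the read-weighted index coincides with pct_m6Am/100, which is
asserted in tests.

## The simulator: what it emulates, and what it does not

`simulate.make_reference` builds a random genome of 600-nt gene loci
(25 per chromosome). Per gene, the number of TSNs is drawn from a shifted
negative binomial with mean 9.5 and s.d. 9 (minimum 1), matching the
heavy-tailed start-site multiplicity seen in 5'-end data; TSNs cluster in
a 100-nt window. Each TSN initiates with A with probability
`a_fraction = 0.5`; A-TSN stoichiometries are Beta(9, 1) (mean 0.9 —
mRNA m6Am is a high-stoichiometry modification), isoform abundances are
Dirichlet(1) (or uniform with `equal_abundance=True`), and 10 % of
isoforms carry one internal m6A site at +10..+70 with methylation
U(0.2, 0.8). `knockout()` zeroes all A-TSN stoichiometries, emulating
loss of the cap-adjacent methyltransferase while leaving internal m6A
(written by a different enzyme) untouched.

`simulate_library` emits per-molecule chemistry: the TSN A of each read
is methylated with probability *s*; unmethylated A anywhere on the
fragment converts with probability `conversion_efficiency` (default 1.0
— the chemistry fully converts unprotected Am); uniform substitution
errors (default 0.001/base) are applied after conversion; read 1 is
UMI + ATAT + the transcript 5' end, read 2 the reverse complement of the
fragment tail. A background fraction (default 0.07, mirroring the ~93 %
on-target purity of cap enrichment measured on a capped standard) starts
at uniform-random genomic positions and exercises the TSS-distance
filter. Minus-strand genes are handled in transcript sense and
reverse-complemented at FASTQ emission. All randomness flows from one
seeded generator, so outputs are byte-identical per seed.

The barcoded standards are five transcripts with identical 5' ends and
distinct A-free 6-nt barcodes 42 nt downstream of the start, mixed at
0/25/50/75/100 % m6Am; the default 80-nt read length lets read 1 span the
barcode so the uniqueness filter can separate the otherwise identical 5'
ends.

Deliberately **not** simulated: indels, spliced 5' ends, PCR duplication
beyond UMI collisions, structure-dependent conversion resistance,
glyoxal-protection failure, adapter read-through (fragments are at least
one read long), and base-quality degradation (all qualities are Q40).
Passing tests therefore demonstrate correctness of the estimator,
filters, and thresholds under substitution noise and multi-isoform
mixtures — not robustness to indel-rich or spliced alignments.

## Numerical and design choices

- **Dedup retention** is deterministic: highest alignment score, then
  lexicographically smallest read id.
- **Stoichiometry bins** are quantile groups of equal size ±1 with ties
  broken by (chrom, pos), so binning is order-independent.
- **Paired t-tests** are two-sided with no multiple-testing correction
  (none is applied to these analyses in practice); degenerate cases
  (identical tables, < 2 shared sites) return NaN rather than a fake
  p-value.
- **Spike-in scaling** uses the simple published design: per-library
  scale factor proportional to the spike total, and a false-positive
  threshold equal to the maximum off-terminus read fraction across
  spikes. The exact dynamic-threshold rule used with real spike mixtures
  is not published; this maximum-off-fraction rule is a documented
  stand-in with the same monotonicity.
- **Problem sizes in the test suite** (e.g. 120 genes × 4 TSNs at 48,000
  reads for parameter recovery; 5,000 reads on a 10-kb genome for the
  aligner-vs-oracle check) were chosen as the smallest instances at which
  the binomial tolerances asserted are comfortably away from sampling
  noise.

## Known limitations

- The aligner is exact-seed + ungapped extension; highly repetitive or
  indel-containing reads are either rejected by the uniqueness gap rule
  or misscored, which is the intended conservative behaviour for
  stoichiometry estimation but unsuitable as a general-purpose mapper.
- The three-letter alphabet genuinely reduces mappability of paralogous
  5' ends (snRNA families, pseudogenes); the similarity classifier
  labels such contexts, it does not recover their alignments.
- TPM here normalizes 5'-end counts ("start-nucleotide per million"),
  not transcript length; it is not comparable to RNA-seq TPM.
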