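# crownkit

Transcription-start-nucleotide (TSN) mapping and **m6Am stoichiometry**
estimation from conversion-based, cap-enriched 5'-end sequencing, with a
full synthetic-library simulator so every stage can be exercised and
validated without any external data.

## The problem

m6Am (*N*6,2'-O-dimethyladenosine) sits on the first transcribed
nucleotide of capped RNAs that initiate with adenosine. Because most genes
use many transcription start sites, gene-level "m6Am vs Am" labels are
ill-posed: methylation must be measured *per 5' isoform*, at
single-nucleotide resolution. Chemical deamination (sodium nitrite on
glyoxal-protected RNA) converts unmethylated A to inosine — read as G —
while m6Am and internal m6A resist conversion and are still read as A.
Sequencing cap-enriched 5' ends of converted RNA therefore yields, at
every observed start position, a binomial readout of methylation: the
**non-conversion rate**

```
stoichiometry ≈ A / (A + G)
```

computed over deduplicated reads whose 5' end maps exactly to that
position. crownkit implements the complete computational path from raw
paired FASTQ to per-TSN stoichiometry and downstream promoter analyses,
for anyone building or benchmarking conversion-based 5'-end assays.

## What the pipeline does

1. **readprep** — validates the read-1 structure (8- or 11-nt UMI + exact
   `ATAT` spacer, which anchors the start nucleotide), trims 3' adapters
   (error rate ≤ 0.25) and low-quality tails (Q20), and drops reads
   shorter than 32 nt.
2. **align** — "three-letter" alignment: reads are A→G converted in
   silico and aligned to an A→G-converted forward genome and a
   T→C-converted reverse genome (seed-and-extend, exact k-mer seeds,
   ungapped extension, paired score = mate1 + mate2). An alignment is kept
   only if its score exceeds −10 and beats the runner-up by more than 9;
   read-1 alignments with 5' softclips are discarded. Original bases are
   then restored so methylation appears as A over G.
3. **tsn_quant** — UMI deduplication per (position, strand, UMI), 5'-end
   pileup, TSN identification at ≥ 20 reads (summed across replicates),
   stoichiometry quantification at ≥ 50 reads, TPM normalization.
4. **annotate** — gene assignment by nearest same-strand annotated TSS
   within 100 nt (priority snRNA > snoRNA > protein-coding > lncRNA >
   others) and snRNA/snoRNA-like classification of 5' contexts by local
   alignment (coverage ≥ 50 %, identity ≥ 50 %, 10-nt word, bit score
   ≥ 50).
5. **analysis** — per-gene composition (%m6Am / %Am / %non-A), the m6Am
   gene index, stoichiometry quantile bins and positional base
   frequencies, TSS-motif classes (SSCA+1GC, BBCA+1BW, VA+1RR, BA+1),
   TATAWAWR scanning in −36..−19, standards calibration, per-site
   condition deltas with a paired t-test, 5'-proximal internal m6A calls
   (≥ 50 reads in both conditions, non-conversion ≥ 0.2 in either, DRACH
   context flag), and spike-in scaling.
6. **simulate** — generates the references, barcoded standards (0 / 25 /
   50 / 75 / 100 % m6Am with identical 5' ends) and FASTQ libraries that
   drive all of the above, with per-read ground truth.

## Worked example

```python
from crownkit.simulate import make_reference, simulate_library
from crownkit.types import SimConfig
from crownkit.pipeline import RunConfig, run_pipeline
from crownkit.analysis import gene_composition, m6am_gene_index

ref = make_reference(n_genes=20, tsns_per_gene=3, seed=42, a_fraction=0.6)
reads, truth = simulate_library(ref, SimConfig(depth=20_000, seed=42))
res = run_pipeline(ref, reads, RunConfig(seed=42))
table = res["table"]

ident = table[table["identified"]]
print(f"identified TSNs: {len(ident)} of {len(table)} observed 5' ends")
g = ident[ident["gene_id"] == "G0001"]
s = gene_composition(g)
print(f"gene G0001: frac_A={s.frac_A:.3f} mean_methylation={s.mean_methylation:.3f}")
print(f"  composition: {s.pct_m6Am:.1f}% m6Am / {s.pct_Am:.1f}% Am / {s.pct_nonA:.1f}% non-A")
print(f"  m6Am gene index: {m6am_gene_index(g):.3f}")
```

prints

```
identified TSNs: 54 of 1415 observed 5' ends
gene G0001: frac_A=0.396 mean_methylation=0.840
  composition: 33.3% m6Am / 6.3% Am / 60.4% non-A
  m6Am gene index: 0.333
```

Reading this: of 1,415 distinct observed 5'-end positions (most are
low-depth background fragments), 54 pass the 20-read identification
threshold. For gene `G0001`, 39.6 % of its deduplicated start reads begin
with A, and 84.0 % of the A/(A+G) calls at those A-TSNs retained A — so
33.3 % of the gene's transcripts are m6Am-initiated, 6.3 % Am-initiated
and 60.4 % start with another nucleotide. The simulator's ground truth
for this gene (two A-isoforms at stoichiometry 0.78 and 0.86, one
G-isoform carrying 58 % of transcription) agrees within binomial noise.

The same pipeline is available from the shell:

```sh
crownkit simulate --genes 20 --depth 20000 --seed 42 -o sim/
crownkit prep -1 sim/reads_R1.fastq.gz -2 sim/reads_R2.fastq.gz -o prep/
crownkit align -1 prep/prepped_R1.fastq.gz -2 prep/prepped_R2.fastq.gz \
    --genome sim/genome.fa -o aln.sam
crownkit quant --sam aln.sam -o tsn.tsv
crownkit annotate --tsn-table tsn.tsv --annotation sim/annotation.gtf \
    --genome sim/genome.fa -o tsn_annotated.tsv
crownkit analyze composition --tsn-table tsn_annotated.tsv -o genes.tsv
```

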