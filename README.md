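# hlacall

Class I HLA typing from multiplexed amplicon sequencing reads.

`hlacall` infers the pair of 4-digit HLA alleles an individual carries at
each classical class I locus (HLA-A, -B, -C) from pooled amplicon reads
covering exons 2 and 3.  It is aimed at labs doing high-throughput
sequence-based typing: many samples are pooled per run, each tagged with a
short molecular barcode, and each read carries a locus/exon-specific PCR
primer.  The package demultiplexes the pool, assigns reads to loci, places
them on a reference alignment of known alleles, removes mislocalized reads,
and calls the most likely allele pair per locus.  A built-in read simulator
with a full truth table makes the whole stack testable without any external
sequence data.

## The model

For every unordered pair of dictionary alleles (i, j) at a locus, three
log-scores are combined:

- **P_genotype** — per-column diploid genotype concordance.  At each
  alignment column the likelihood of the observed bases is computed for all
  10 diploid genotypes under an independent-reads error model
  (P(b|{x,y}) = ½P(b|x) + ½P(b|y), with P(b|a) = 1−e for a match and e/3
  otherwise, e = 10^(−Q/10) from the base quality).  The normalized
  posterior of the genotype implied by (i, j) is multiplied across columns.
- **P_phase** — read-backed phase consistency.  For each pair of adjacent
  polymorphic columns within an exon, with n spanning reads of which k match
  one of the candidate pair's two expected two-site haplotypes, the score is
  Binomial(k; n, 1−P_err) with P_err = 1% by default, multiplied across
  site pairs.
- **P_frequency** — the population prior f_i · f_j from a
  (population, allele) frequency table, with a small floor for alleles
  missing from the table.

P_combined = P_genotype · P_phase · P_frequency is normalized so the
posteriors over all n(n+1)/2 pairs sum to 1.  The **matching set** is every
pair attaining the maximal P_genotype · P_phase — alleles identical over the
sequenced exons are genuinely indistinguishable from sequence and all their
compatible pairs are reported; the **best guess** is the member of the
matching set with the highest P_combined, i.e. the frequency prior breaks
the ambiguity.

Upstream of the caller: barcodes (6–9 bp) are matched exactly at the read
start; primers (18–21 bp, IUPAC degeneracy honored) with up to one mismatch;
reads with < 75% agreement with the closest allele over the polymorphic
columns they cover are removed as misalignments; calls with mean exon depth
below 20 reads are flagged `low_coverage`, and loci showing three or more
well-supported bases at multiple columns are flagged `possible_contamination`.

## Worked example

```python
import hlacall as h
from hlacall.pipeline import type_simulated

dictionary, freqs = h.make_toy_dictionary(seed=0)
dataset = h.simulate_reads(dictionary, freqs,
                           h.SimConfig(n_samples=4, mean_coverage=50, seed=1))
result = type_simulated(dataset)
print('parse rate: %.1f%%' % (100 * result.demux_report.parse_rate))
print(result.calls_frame()[['sample', 'locus', 'allele1', 'allele2',
                            'posterior', 'matching_set']].head(6).to_string(index=False))
conc = h.evaluate_concordance(result.calls, dataset.truth_pairs)
print('4-digit accuracy: %.1f%%' % (100 * conc.accuracy_4digit))
```

prints

```
parse rate: 92.1%
sample locus allele1 allele2  posterior    matching_set
  S001     A A*05:01 A*10:01        1.0 A*05:01/A*10:01
  S001     B B*01:02 B*01:02        1.0 B*01:02/B*01:02
  S001     C C*08:01 C*13:01        1.0 C*08:01/C*13:01
  S002     A A*05:01 A*05:01        1.0 A*05:01/A*05:01
  S002     B B*15:01 B*01:02        1.0 B*15:01/B*01:02
  S002     C C*04:01 C*09:01        1.0 C*04:01/C*09:01
4-digit accuracy: 100.0%
```

The parse rate is below 100% because 1% per-base sequencing error
occasionally corrupts the 8 bp barcode, which is matched strictly.  Each
call's posterior is over all 210 allele pairs at the locus; the matching set
lists every pair consistent with the observed genotypes and phase.

The same pipeline is available from the shell:

```bash
hlacall simulate --samples 95 --coverage 50 --seed 1 --outdir sim/
hlacall demux --fastq sim/reads.fastq --barcodes sim/barcodes.tsv \
              --primers sim/primers.tsv --outdir demux/
hlacall call --fastq sim/reads.fastq --dict sim/dictionary \
             --freqs sim/frequencies.tsv --barcodes sim/barcodes.tsv \
             --primers sim/primers.tsv --population sim_pop --out calls/run
```

Real data enters the same way: the allele dictionary is a directory of
per-locus, per-exon aligned FASTA files (IMGT/HLA-style, one record per
allele), frequencies a TSV of (population, allele, frequency, sample_size),
and reads either a pooled FASTQ or pre-aligned SAM/BAM against the
dictionary's exported references (`hlacall call --sam …`).

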