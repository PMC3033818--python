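# Methods

## Problem setting

Classical class I HLA genes (HLA-A, -B, -C) are the most polymorphic loci in
the human genome; clinically and immunologically the relevant resolution is
the 4-digit (protein-level) allele pair per locus.  Almost all of the
protein-coding variation that distinguishes 4-digit alleles lies in exons 2
and 3, so amplicon sequencing of those six exons (2 loci-exons × 3 loci),
pooled across many barcoded samples, carries enough information to type an
individual — provided reads can be demultiplexed, localized, and interpreted
against the dictionary of known alleles.

`hlacall` treats typing as model selection over all unordered pairs of
dictionary alleles at a locus.  Nothing is called de novo: the caller asks
which known pair best explains the reads.

## Scoring model

### Genotype concordance (P_genotype)

Reads are assumed independent given the genotype.  A base call `b` with
Phred quality Q has error probability e = 10^(−Q/10); conditional on the
true base `a`, P(b|a) = 1−e if b = a, else e/3 (symmetric error).  For a
diploid genotype {x, y} the read is drawn from either chromosome with equal
probability, so P(b|{x,y}) = ½P(b|x) + ½P(b|y).  Per alignment column the
log-likelihood of the pileup is computed for all 10 unordered genotypes and
normalized into genotype posteriors under a uniform genotype prior.

For a candidate allele pair, the pair's implied genotype posterior is summed
(in log space) over every column where both alleles carry a callable base.
Columns where all candidate pairs imply the same genotype contribute equally
to every pair and cancel under the final normalization, so iterating over
all columns rather than only pair-discriminating ones changes absolute
values but never the ranking.  Columns with no data contribute the uniform
log(1/10) for every pair, which likewise cancels.

Whether per-column likelihoods should be normalized into posteriors before
multiplication was a genuinely open choice; normalization was adopted.  It
affects only the absolute scale of P_genotype, not the argmax, and keeps the
per-column factors interpretable as probabilities.

### Phase consistency (P_phase)

Polymorphic columns are the alignment columns at which at least two
dictionary alleles carry distinct bases.  For each pair of *adjacent*
polymorphic columns — consecutive entries of the per-locus sorted list,
restricted to pairs inside one exon, since no read spans two amplicons —
the reads covering both columns with callable bases are tallied by their
observed two-site haplotype.

A candidate allele pair predicts (at most) two haplotypes at such a site
pair.  With n spanning reads of which k match either predicted haplotype,
the site pair contributes Binomial(k; n, 1−P_err) with P_err = 0.01 by
default.  Reads matching neither predicted haplotype count in n but not k:
they are evidence against the candidate.  When the two alleles agree at both
sites the single predicted haplotype is used with the same formula.  Site
pairs with n = 0 contribute probability 1.  Contributions multiply across
site pairs.

Two deliberate simplifications: the success probability is 1−P_err
regardless of haplotype composition (per-site errors are not compounded
into (1−P_err)², keeping a single interpretable error parameter), and k
counts matches to *both* predicted haplotypes rather than one chosen cis
configuration, which keeps the score symmetric in the pair.  A consequence
worth knowing: on simulated data with 1% per-base error the empirical k/n
for the true pair concentrates near (1−P_err)² ≈ 0.98, slightly below the
binomial's nominal 0.99, because a read must be error-free at both sites to
match; the mild mismatch penalizes all candidate pairs equally and does not
affect ranking.

### Population prior (P_frequency)

The prior for pair (i, j) is the plain product f_i · f_j of population
allele frequencies, exactly as the combination rule defines it; the
Hardy-Weinberg heterozygote factor of 2 is available behind an `hwe` flag
but off by default.  Alleles absent from the frequency table receive a
configurable floor (default 1e−5): frequencies act as priors, never as
exclusion.  With no population specified the prior is uniform over
dictionary alleles and cancels under normalization.  Frequency tables may
aggregate several literature sources per allele; sources are combined by
the sample-size-weighted mean Σf·n / Σn.

### Combination and reporting

P_combined = P_genotype · P_phase · P_frequency, computed in log space
throughout; posteriors are recovered with a max-subtracted logsumexp, so
underflow cannot occur even with hundreds of informative columns.
Posteriors over all n(n+1)/2 pairs sum to 1 per locus.

The *matching set* is every pair whose P_genotype · P_phase lies within a
relative 1e−9 of the maximum — pairs of alleles identical over the
sequenced exons are reported together, because no amount of exon-2/3
sequence can separate them.  The best guess is the member of the matching
set with maximal P_combined (restricting to the matching set guarantees the
best guess is itself evidence-maximal); remaining ties break by allele-name
order so runs are reproducible.  Evidence across the two exons of a locus
combines by summation of log-scores over the concatenated column space.

## Upstream processing

- **Demultiplexing**: barcodes (6–9 bp) are matched exactly at the read
  start.  Manifests in which one barcode is a prefix of another are rejected
  at load time.  An optional 1-mismatch mode exists but is off by default:
  strict matching trades a few percent of parse rate for near-zero
  cross-sample assignment.
- **Locus assignment**: the barcode-trimmed prefix is compared against all
  primers (18–21 bp) honoring IUPAC degenerate codes, tolerating one
  mismatch by default (a 1% error rate over 20 bases corrupts ~18% of
  primers at zero tolerance, ~1.6% at one).  Reads matching two loci equally
  well are left unassigned.  Reads beginning with a reverse primer are
  reverse-complemented downstream and reported on the '-' strand.
- **Alignment**: external SAM/BAM against the dictionary's exported
  per-exon references is ingested with soft clips removed; secondary,
  unmapped and indel-containing records are skipped and counted (the model
  is substitution-only).  The built-in gapless aligner (match +1, mismatch
  −1, accept at ≥ 0.75 of read length) is plumbing for tests and small runs,
  not a replacement for a production aligner.
- **Misalignment filter**: per read, over the polymorphic columns it covers
  with callable bases, the maximum over alleles of the agreement fraction is
  computed; reads below 0.75 are removed.  The denominator is *covered*
  polymorphic sites (not all sites at the locus), since a read can only be
  judged where it has data; reads covering fewer than two such sites cannot
  meaningfully fail a 75% test and are kept.  The filter is idempotent and
  monotone in the threshold.
- **Base quality floor**: bases with Q < 5 are treated as unknown everywhere
  (homology, likelihood, phasing) as a guard against low-quality tails.

## Quality-control flags

- `low_coverage`: any exon of the call with mean depth < 20 reads — the
  regime where false homozygotes from uneven chromosome sampling become
  likely.
- `possible_contamination`: at least 2 columns each showing ≥ 3 distinct
  bases carried by ≥ 10% of that column's reads.  A diploid explains at most
  two bases per column; a third well-supported base implies foreign
  template.  The flag never auto-corrects a call.

## Parameter defaults

| parameter | default | meaning |
|---|---|---|
| `p_err` | 0.01 | sequencing error rate in the phase binomial |
| `quality_floor` | 5 (Phred) | below this a base is treated as unknown |
| homology threshold | 0.75 | minimum SNP agreement with closest allele |
| `frequency_floor` | 1e−5 | prior frequency for alleles missing from the table |
| primer mismatch `m` | 1 | tolerated mismatches in primer matching |
| barcode mismatch | 0 | barcode matching is exact |
| low-coverage flag | 20 reads | mean exon depth threshold |
| matching-set tolerance | 1e−9 (relative) | ties on P_genotype·P_phase |

## The simulator

The generator emulates the data regime the method targets: 3 loci × 2 exons
of 270/276 alignment columns, 20 alleles per locus with a polymorphic-column
density of 0.08 (a quarter of polymorphic columns carry a second alternative
base, as class I alignments are not purely biallelic), 95 samples by
default, Poisson(50) reads per sample per exon, read lengths ~N(364, 124)
truncated to the amplicon, i.i.d. substitution errors at 1%, and uniform
base qualities at the Phred equivalent of the error rate (so the likelihood
model's assumptions are exactly satisfiable; a jittered-quality mode exists
for robustness tests).  Two failure modes are reproducible on demand:
allelic coverage imbalance r (haplotype shares r/(1+r) vs 1/(1+r)), whose
dominant downstream error is the false homozygote of the covered chromosome,
and cross-sample contamination, implemented as a single donor sample per
recipient so a contaminated locus shows up to four distinct haplotypes.

The constructed dictionary always contains one pair of alleles identical
over both exons (the ambiguity case only a frequency prior can resolve) and
one pair separated by a single diagnostic column.  The exon-identical twin
receives a small fixed frequency (1e−3) rather than a symmetric-Dirichlet
draw like the other alleles: real alleles indistinguishable over exons 2–3
are rare variants of a common allele, and a common twin would model a regime
that does not occur.  Truth pairs are drawn i.i.d. from the frequency
distribution, so the caller's prior matches the generating process.

What the simulator does **not** emulate — and therefore what passing tests
do not demonstrate about real data: homopolymer-driven indel errors
(pyrosequencing's characteristic failure; the whole stack is
substitution-only), gapped allele alignments (real IMGT alignments contain
indels; the dictionary accepts gap characters but simulated reads never
cover them), quality-score miscalibration, PCR artifacts such as chimeras
and allele-specific amplification bias beyond the simple imbalance ratio,
and the real ~10⁴-allele dictionary (20 alleles per locus keeps pair
enumeration at 210 rather than ~10⁷; the algorithm is quadratic in dictionary
size and a production run over a full IMGT release would need the
pair-restriction optimization noted in the code).

## Numerical and engineering choices

- All score arithmetic in log space; posterior recovery via logsumexp.
- Per-column genotype posteriors sum to 1 within 1e−12; locus posteriors
  within 1e−9 (tested up to 50 alleles, 1275 pairs).
- The brute-force oracle used in tests recomputes posteriors with plain
  (non-log) arithmetic and pure-Python loops, sharing no code with the
  implementation.
- Test and acceptance problem sizes (200 samples × 3 loci at 50× for
  parameter recovery; 100 samples at 30× for the imbalance study; 95
  samples for the acceptance run) were chosen to give stable statistics at
  interactive runtimes on a single core.
- Deterministic throughout: a single seeded generator drives the simulator;
  identical inputs and seed give byte-identical FASTQ, truth tables and
  call TSVs.

## Known limitations

- Substitution-only: alleles distinguished solely by indels in exons 2–3
  are indistinguishable to the caller as implemented.
- No novel-allele discovery; an individual carrying an allele absent from
  the dictionary will be assigned the nearest known pair.
- Class II loci, and 6/8-digit resolution (synonymous and intronic
  variation), are out of scope.
- The phase model considers adjacent polymorphic-site pairs only; longer-
  range consistency within a read is not separately rewarded.
- Contamination is flagged, never modeled or corrected.
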