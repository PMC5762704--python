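# Methods

This note documents the models implemented in `scires`, the choices made
where the design was genuinely open, and what the synthetic data does and
does not establish about behaviour on real sequencing data.

## Consensus genotype calling

Calling emulates a VarScan-style consensus pass (`mpileup2cns` with
default parameters) applied identically to DNA exome and mRNA-seq
pileups. The concrete test is ours: the published tool is invoked only as
"defaults", so we use a one-sided binomial tail against a fixed per-base
error rate — is the observed variant support explainable by sequencing
error alone? The decision chain at a site:

1. depth < `min_coverage` (8 reads) or reference base N → no call;
2. evaluate only the most frequent non-reference base (ties broken
   alphabetically); multi-allelic residue is ignored — haploid oocytes
   make true triallelic sites negligible;
3. hom-ref when allele frequency f < `min_var_freq` (0.20, the VarScan
   consensus default) or the binomial tail p > `p_threshold` (0.01);
4. heterozygous when f < `het_af_upper` (0.75), homozygous otherwise.
   f = 0.75 exactly is homozygous: the het rule is strictly "less than".

The strand filter requires alt support on both strands with at most
`strand_bias_max` (0.90) of it on the majority strand; the exact
threshold used by the original tool's strand filter is not documented,
so the knob is exposed. Base qualities are parsed and can gate bases
(`min_base_quality`, default 0 = off); the published analysis filtered
at the read/variant level only. Pileups are assumed built from uniquely
mapped reads upstream — the package never inspects alignments.

## Recombination classification

Liver tissue provides the diploid reference genotype. At each
liver-covered variant site the oocyte panel is pooled: *recombined* when
liver is het and ≥ 1 covered oocyte is het (a per-cell flag is also
kept), *non-recombined* when liver is het and every covered oocyte is
hom, *discordant* when an oocyte allele is absent from the liver
genotype or an oocyte is het where liver is hom, *uninformative*
otherwise. Sites with no liver coverage are never classified
(liver is the reference, silence is not discordance). Window summaries
use fixed windows (default 1 Mb, matching the published figures) with
`het_hom_ratio = (n_recombined + n_non_recombined) / max(n_hom, 1)`,
where `n_hom` counts concordant homozygous-variant sites. Sites covered
in some but not all oocytes count through whichever oocytes cover them,
with per-sample coverage recorded.

## RES detection

The filter chain runs, in order: per-cell mismatch discovery (both
depths ≥ 8, both calls hom, strand filter passed, bases differ), merge
to distinct sites, removal of sites with more than one (DNA, RNA) base
pair across cells, removal of liver-heterozygous sites, annotation.
Candidates at liver-*uncovered* sites are retained with a
`liver_uncovered` flag — only sites *found* heterozygous are discarded;
the flag makes the stricter variant a one-line filter. Each record's
`filter_trail` plus the stage audit reconstruct exact counts everywhere
(in = out + removed).

Because mRNA-seq is non-strand-specific, mismatch types are
Watson-relative until a unique annotated gene strand resolves them
(complementing both bases for Crick-strand genes). Region assignment
uses precedence start/stop codon > CDS > UTR > intron > intergenic, so
start/stop-codon edits are countable as their own class; the start and
stop codons are taken as the terminal codons of the CDS span. Exonic
positions of transcripts without a CDS get their own label
(`noncoding_exon`) rather than a misleading UTR/CDS call. Among
overlapping same-strand genes the longest overlapping transcript wins,
ties broken by lexicographic gene_id — deterministic and auditable.
Genes on both strands give a region but no resolved type
(`strand_ambiguous`).

Note on sensitivity: requiring a homozygous RNA call means only editing
levels ≥ 75% are callable; partially edited sites look heterozygous and
are excluded by design (they are indistinguishable from allele-specific
expression at a het site).

## Expression and coverage statistics

FPKM uses a union-exon gene model rather than isoform deconvolution: all
downstream use (thresholding, correlation) is isoform-agnostic.
Expressed-gene counting exposes the comparator explicitly because the
two published conventions differ: strictly greater (for thresholds 0 and
0.1) versus at-least (for threshold 1). Sample correlation is computed
on log10(FPKM+1) over the union gene set; the raw scale (a flag) is
dominated by a handful of very large genes. Metagene profiles bin each
transcript into 100 percentile bins (bin b spans
`floor(bL/100)..floor((b+1)L/100)-1`), with two per-bin quantities:
fraction of bases covered ≥ 1×, and fraction of the transcript's reads
whose 5′-most base starts in the bin. Transcripts shorter than 100 nt
are excluded (a bin would be sub-base); group means are unweighted;
transcripts without reads enter only the coverage mean. Reads are
assigned to genomic regions by their 5′-most aligned base with
precedence exonic > intronic > intergenic.

## The simulator

The generator produces the statistical structure the analysis assumes,
not realistic reads:

* **Meiosis.** One diploid individual, heterozygous at every SNP
  (density 10⁻³/bp). Each oocyte is an independent meiosis: per
  chromosome, each crossover (default 1) exchanges the distal segment
  between one chromatid of each homolog; the oocyte receives one
  homolog's chromatid pair at random and the PB1 the other. A SNP is
  therefore het in the oocyte — and in its PB1 — iff an odd number of
  crossovers lie proximal to it. Multi-crossover and chromatid-choice
  generalisations exist, but the stated invariants are guaranteed only
  in this default two-strand model.
* **Amplification.** Coverage arrives in alternating exponential runs:
  MDA-like samples cover ~70% of the genome in ~10-kb runs, DOP-PCR-like
  samples ~30% in ~1.5-kb runs (the default panel is 2 MDA + 4 DOP-PCR
  oocytes, mirroring the study design; liver is MDA-like at 90%), which
  makes inter-sample coverage overlap tunably low. The simulator does
  not fit any real overlap matrix — it only exposes the knobs. Depth is
  negative-binomial (mean 25 for DNA); reads draw alleles 50/50 at het
  sites, substitute uniformly among the other bases at error rate 10⁻³,
  and take strands Bernoulli(0.5). Allelic dropout beyond what run-level
  coverage loss produces is not modelled at the amplicon level.
* **Transcription.** 60 genes (3 × 400-bp exons, 600-bp introns, 85%
  coding with 120-bp UTRs), expression log-normal(μ=1, σ=1) for 90% of
  genes, reads Poisson around a coverage target of 30× for the median
  gene. 5′ read starts follow a truncated exponential rising toward the
  3′ end with a fixed 600-bp scale, so the percentile-space skew grows
  with transcript length — one parameter reproducing the qualitative
  3′-bias (few, but not zero, 5′ reads). Editing events (4 per expressed
  exonic kb, level 1.0 by default so recovery under the ≥ 0.75 rule is
  well defined) land on exonic sense-strand adenosines away from SNPs
  and are emitted strand-correctly in genomic coordinates. Background
  intronic (5.5%) and intergenic (18%) reads enter the read-interval
  ledger (for region fractions) but not the pileups. RNA is simulated
  non-strand-specific.
* **Materialisation.** Pileups are materialised over the union of SNP
  and exonic positions — the positions any downstream operation can
  consume — rather than every genomic base; a whole bundle (13 DNA
  samples + 6 RNA samples over a 2 × 400-kb genome, ~750k pileup
  columns, ~260 planted editing sites) is a pure function of the seed
  and generates in a few seconds, which keeps the full test suite and
  the acceptance script comfortably small while leaving every rate
  estimated from hundreds of events.

What passing tests on this simulator does **not** show: robustness to
alignment artefacts, indels, repeat mis-mapping, amplicon-level allelic
dropout, strand-specific library chemistry, or known-SNP contamination —
none of which the generator emulates. Recovery rates on synthetic data
are upper bounds on real-data behaviour.

## Numerical choices

* Binomial tails come from `scipy.stats.binom.sf` and are memoised on
  `(alt, depth, error)`; an alt count of 0 returns exactly 1.
* Ties for the alt allele break alphabetically; calling is fully
  deterministic.
* Empty denominators (correlation of a constant vector, agreement with
  no common sites, fractions over zero observations) return an absent
  value (None/NaN), never 0.
* Coordinates: pileup/GTF/VCF are 1-based closed; transcript
  coordinates and metagene cover intervals are 0-based half-open.
* The VCF subset adds an ST (status) INFO key beyond AF/DP/PV so a
  write/read cycle is lossless including no-call records.

## Known limitations

* No indel calling, somatic modes, or base-quality recalibration.
* Crossover breakpoints are not point-estimated; only window counts are
  reported.
* Isoform-level expression is out of scope; FPKM is union-exon.
* The strand filter and error-rate defaults stand in for undocumented
  internals of the original calling tool; both are configurable.
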