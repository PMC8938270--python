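# wgr — whole-genome reconstruction of preimplantation embryos

`wgr` infers the full inherited genome of an IVF embryo from two data
sources that are practical to collect: deep sequencing of the **parents**
and sparse, noisy SNP-array genotyping of a biopsy from each **embryo**.
Direct sequencing of a few-cell biopsy is costly and plagued by allele
dropout; but an embryo's genome is just a mosaic of its parents'
haplotypes, so knowing (i) the parents' phased genomes and (ii) which
parental haplotype the embryo inherited along each chromosome determines
every inherited variant — including rare pathogenic ones that imputation
misses. The package is written for statistical geneticists working on
preimplantation genetic testing (PGT) who need a transparent, testable
implementation of the whole chain: phasing, transmission inference, dense
genotype prediction, polygenic risk scoring, and monogenic + polygenic risk
integration, with a synthetic-cohort generator standing in for clinical
data.

## The method

**Parental support** proceeds in two steps.

1. *Phase each parent from the sibling embryos.* Two nearby heterozygous
   parental sites transmit alleles from the same physical chromosome unless
   a meiotic crossover separates them (probability given by the genetic
   map). Maximizing the likelihood of all embryos' array calls over the two
   relative phases of each adjacent pair of heterozygous sites — and
   chaining the decisions — yields a phased scaffold with per-site
   confidence. The scaffold anchors the orientation of an externally phased
   parental genome (reference-panel phasing of the parents' WGS).

2. *Decode each embryo's transmission with a hidden Markov model.* The
   hidden state at a site is the pair (m, p) of transmitted haplotypes of
   mother and father. Per-parent switch probability between sites at
   genetic distance d cM is the Haldane recombination fraction
   r(d) = (1 − e^(−2d/100))/2; the parents' meioses are independent.
   Emissions model the biopsy noise: allele dropout (het observed as a
   homozygote), random miscalls and no-calls. Viterbi decoding gives the
   segment structure and recombination breakpoints (reported as the full
   interval between flanking informative markers); forward–backward
   marginals give per-site confidence. Reading the transmitted haplotypes
   off the parents' phased genomes predicts the embryo's genotype at every
   parental variant site.

Downstream, a polygenic risk score is the weighted sum of effect-allele
dosages, PRS = Σᵢ wᵢdᵢ (unpredicted sites contribute their population
expectation 2·AFᵢ), centered by regressing out the first four ancestry
principal components in controls, standardized by the reference-population
SD, and converted to an odds ratio, OR = e^(β·PRS), with β the log OR per
SD. Monogenic carrier status (read off the reconstruction) combines with
the PRS in a carrier-stratified logistic model,
OR = exp(α·1{carrier} + β_stratum·PRS), with separate PRS slopes for
carriers and noncarriers. A simulator draws virtual embryos of a couple
(map-driven crossovers, or fully unlinked) to show the distribution of
scores the couple's embryos can realize.

## Worked example

`examples/reconstruct_family.py` simulates a couple and six day-5 embryo
biopsies (3,000 analysis sites, 1,500 on the array, two chromosomes),
phases the parents from the embryos, reconstructs every embryo and scores
it against its true genome:

```
mother: phased 557 heterozygous array sites
father: phased 540 heterozygous array sites

embryo      genome-wide  het sites  hom sites  segments
embryo_0         99.87%     99.82%     99.90%        11
embryo_1         99.93%    100.00%     99.90%         7
embryo_2         99.80%     99.72%     99.84%         7
embryo_3         99.73%     99.63%     99.79%        15
embryo_4         99.87%     99.81%     99.90%         7
embryo_5         99.90%     99.91%     99.90%         9
```

Accuracy is the percent of sites whose unordered diploid genotype matches
the truth, stratified by the truth genotype (heterozygous sites are the
hard ones — allele dropout pushes them toward homozygous calls). Each
embryo's segment count reflects its detected meiotic crossovers. The other
examples show risk integration across a carrier family
(`score_and_integrate_risk.py`) and the sibling PRS distribution against
the midparent mean (`sibling_prs_distribution.py`).

The same pipeline is scriptable from a shell:

```bash
wgr run demo_run --seed 7 --noise-preset day5
```

writes a run directory with every intermediate file (phased VCFs,
reconstruction VCFs, segment BEDs, score and evaluation JSON) plus a
manifest, and the stage subcommands (`wgr simulate|phase|reconstruct|
score|report|simulate-embryos|evaluate`) compose to the identical result.

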