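# Methods

This note documents the models implemented in `wgr`, the choices made where
the design was genuinely open, and what the synthetic validation does and
does not demonstrate.

## Genotype and noise model

Genotypes are biallelic SNV codes (0 hom-ref, 1 het, 2 hom-alt, −1
no-call); multiallelic and non-SNV records are rejected at load. A biopsy
observation of a true genotype g is drawn from competing branches:

| event | probability | effect |
|---|---|---|
| no-call | `missing_rate` m | call = `./.`, independent of g |
| allele dropout (g = 1 only) | `allele_dropout_rate` a | call = each homozygote with a/2 |
| miscall | `genotype_error_rate` e | uniform over the two wrong calls |
| correct | remainder | call = g |

so, conditional on a call being made, a heterozygous site is observed
homozygous with probability a/2 + (1−a)e/2 per homozygote. The simulator
samples from exactly this distribution and the HMM uses it as its emission
matrix, so the decoder is exactly matched to the generative process.
Homozygous dropout is observationally silent and is folded into e.

The presets are package calibration constants, not published values (the
assay's error rates are not public): day-5 (multi-cell trophectoderm)
a = 0.02, e = 0.005, m = 0.02; day-3 (single-cell blastomere) a = 0.10,
e = 0.01, m = 0.05. Day-3 is strictly noisier, matching the observed
day-3 < day-5 accuracy ordering. Users can supply any `NoiseProfile`.

## Transmission HMM

Hidden state at an informative site (heterozygous in ≥ 1 parent): the pair
(m, p) ∈ {1,2}² of transmitted parental haplotypes. Transitions factorize
per parent — meioses are independent — with per-parent switch probability
r(d) = (1 − e^(−2d/100))/2 (Haldane, interference-free; it matches the
simulator's Poisson crossover model). Inference is exact forward–backward
and Viterbi in log space; per-site posteriors are exposed for confidence,
the Viterbi path for segment structure. Both agree with exhaustive path
enumeration to 1e-9 in log-likelihood on instances up to 12 sites (tested
over 200 random parameter draws).

Segment boundaries for a parent are placed only between consecutive sites
heterozygous in that parent — a crossover is not localizable more finely —
and the breakpoint is reported as that full interval. Segments tile the
chromosome by cutting at the interval midpoint. No minimum segment length
is imposed; spurious single-site switches are suppressed only by the
transition prior. Aneuploid-flagged chromosomes (flags are consumed as
input, as from a clinical copy-number caller) are never decoded and carry
no predictions.

Dense prediction reads each site's alleles off the transmitted haplotypes.
Per-site confidence is the product of each parent's transmission posterior
at the nearest informative site (the minimum of the two flanking sites, so
positions inside a breakpoint interval inherit the lower flank rather than
being dropped), multiplied by the parental phase confidence where the
transmitting parent is heterozygous (floored at 0.5; such sites are
downgraded, never dropped).

## Parental-support phasing

For each parent, the relative phase of adjacent heterozygous array sites is
chosen to maximize the likelihood of all sibling embryos' calls under the
same transmission chain and emission model as the HMM (uniform start,
Haldane switch). The other parent is marginalized at two levels: its
transmitted haplotype per embryo, and — because all siblings share it — its
own unknown pair-phase, jointly across embryos with a uniform prior.
Marginalizing the other parent's alleles independently per site instead
misreads its linkage as the target parent's and measurably inflates the
switch error (~4.5% vs ≤ 2% under the day-5 preset with six embryos).

Decisions are chained along the chromosome from an arbitrary labeling
anchor at the first heterozygous site. Exact likelihood ties (sites
intrinsically unphasable from the embryo data, e.g. every sibling ambiguous
there; ~5–10% of sites at the densities we simulate) are assigned by the
deterministic coupling tie-break but reported at confidence 0.5 — no phase
claim — and the chain anchor stays at the last informative decision so a
tie cannot flip everything downstream. Confidence is the posterior
probability of the chosen relative phase under a uniform prior; its
calibration is tested (reported 0.9–0.95 ⇒ empirical correctness in
[0.85, 1]). With one embryo the problem is unidentifiable and the operation
refuses.

The scaffold then orients an externally phased parental genome per
chromosome by majority vote over shared sites (the external source —
reference-panel phasing in production, the generating truth in simulation —
is authoritative for relative phase; the scaffold for orientation).
Orientation is immaterial to downstream decoding (label symmetry is
tested); the practical signal is the sample-swap check: disagreement of
*relative* phase between adjacent shared sites above 40% raises a warning.
Whole-chromosome (rather than per-arm) voting is used because orientation
does not propagate across the decoder anyway and synthetic chromosomes
carry no centromere annotation. Rare heterozygous variants with direct
phase evidence (linked reads) are attached to the haplotype of their anchor
allele; an absent or unphased anchor leaves the variant flagged unphased.

## Site filters

High-confidence sites exclude Mendelian-inconsistent trio genotypes, any
missing trio genotype, optional upstream low-quality flags, and (at load)
multiallelic records. A variant is *rare* iff its population allele
frequency is strictly below 0.1% or it is absent from the frequency table.

## Polygenic scoring

Raw score: Σ wᵢdᵢ with dᵢ the effect-allele dosage. Effect-allele
orientation is normalized at model load (published scoring files mix
orientations); a model variant whose site lacks any genotype contributes
its population expectation wᵢ·2·AFᵢ, and with no frequency available
contributes 0 (counted). Ancestry PCs come from an SVD of
frequency-standardized reference-panel genotypes, (g − 2p)/√(2p(1−p));
projection mean-imputes missing panel sites and refuses below 80%
coverage. Centering subtracts the OLS prediction of the raw score from the
first four PCs, fit on controls. Standardization divides by the standard
deviation of the **centered** score in the reference population most
closely related (nearest PC1–4 centroid when no label is given); using the
centered rather than raw SD keeps the score's scale independent of the
ancestry axis removed by centering. OR = e^(β·PRS).

Model QC gates: AUC ≥ 0.6; odds ratios increasing across score deciles
(reference: pooled deciles 5–6); top-vs-bottom decile OR ≥ 2. "Increasing"
is enforced with a two-standard-error slack per adjacent pair (Woolf SE
with 0.5 continuity): strict weak increase over ten sampled decile
estimates would reject genuinely strong scores at realistic cohort sizes,
while a null score still fails the AUC and top/bottom gates. The per-SD OR
is estimated by logistic regression; perfect separation reports an infinite
OR rather than failing.

## Risk integration

Carrier status per condition is read off the reconstruction: carrier iff
≥ 1 pathogenic allele at a panel site; a panel site without a prediction
(e.g. aneuploid chromosome) yields *unknown*, never silently noncarrier,
and the combined OR is then reported for both branches. The combined model
is OR = exp(α·1{carrier} + β_stratum·PRS) with stratified slopes (per-SD
ORs 1.3 carrier / 1.6 noncarrier for the breast-cancer configuration); no
interaction beyond the stratified slopes is modeled. The carrier main
effect α is **not** published and must be supplied in the panel file; the
demo configurations use a placeholder that is explicitly synthetic. The
family report ranks embryos by combined OR, reports max/min OR per
condition (fold difference), and flags embryos below the population median
PRS (standardized score < 0) that still carry a pathogenic variant — the
inadvertent-transfer scenario. Absolute-risk conversion is out of scope
(baseline prevalences are not modeled); only odds ratios are reported.

## Virtual embryo cohorts

The linkage scheme draws one meiosis per parent (Poisson crossovers on the
centimorgan scale, no interference — the same model as the synthetic
cohort, rather than an external pedigree simulator, so the package is
self-contained) and combines the gametes; the unlinked scheme draws one
allele per parent per site independently. Default 500 replicates;
reproducible bit-exactly under a seed. Standardization of simulated scores
reuses the scoring engine's PC model and centering so distributions are on
the same scale as reconstructed embryos; both schemes have the midparent
mean as their expectation (tested at 10,000 replicates).

## Synthetic cohort: what it does and does not emulate

The generator draws parental haplotype alleles independently per site from
a population frequency spectrum (default uniform on 0.05–0.95), transmits
them through Poisson/Haldane meioses on a user-supplied or uniform genetic
map (default 1 cM/Mb, 100 Mb chromosomes), designates one embryo as the
"born child" whose truth genome is exact, and corrupts array-site calls
with the noise model above. It does **not** emulate: linkage
disequilibrium between parental variants (every site is independent given
its frequency), crossover interference, mosaicism or segmental aneuploidy,
sex chromosomes (autosomes only), array intensity/B-allele-frequency
channels, or genotyping error that correlates across sites or embryos.
Passing tests therefore demonstrate correctness of the inference machinery
under its own generative assumptions and honest degradation under noise —
not clinical accuracy on real biopsies, which depends on error structure
the generator does not model.

## Validation problem sizes

Tests run at desk scale by design: 2 chromosomes of 100 Mb, 200–5,000
sites, 2–8 embryos per family (50–60 embryos where a rate is estimated),
200 random HMM instances of ≤ 12 sites for enumeration checks, 10,000
meioses/replicates for distributional checks (3-SE bands; chi-square GOF at
α = 0.001), and n = 2,000–5,000 cohorts for the scoring engine. Seeds are
fixed throughout.

## Known limitations

* Phase errors at intrinsically unphasable sites are tie-broken, flagged by
  confidence 0.5, and downgrade reconstruction confidence; they are not
  recovered.
* The X chromosome is not modeled; aneuploidy is consumed as flags, never
  called.
* Breakpoint resolution is bounded by informative-marker spacing; crossover
  pairs falling within one inter-marker gap cancel and are unobservable in
  principle (the evaluator classifies them as such rather than scoring them
  against the decoder).
* The decile-monotonicity QC gate and the centered-SD standardization are
  operationalizations of procedures whose exact reference category and
  scale were left open; both are stated above and tested as implemented.
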