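# Methods

This note documents the models and procedures implemented in `ibexload`,
the assumptions behind them, the defaults and why they were chosen, and
what the synthetic-data tests do and do not demonstrate about real data.

## Variant filtering and classification

Sites enter the analysis from a jointly called multi-species VCF. The hard
filter mirrors common GATK practice for non-model genomes: a site fails
when QD < 2.0, FS > 40.0, SOR > 5.0, MQ < 20.0, |MQRankSum| > 3.0,
|ReadPosRankSum| > 3.0 or AN < 62. All comparisons are strict, so a value
exactly at a threshold passes. Rank-sum annotations are genuinely absent at
sites without heterozygous calls; such sites pass those two filters rather
than being discarded. The AN floor corresponds to a called-allele quorum in
the original study panel and does not generalize — it is a plain
configuration value (`FilterThresholds.an_min`), as are all other
thresholds. A site whose INFO field cannot be parsed is excluded and
counted separately rather than silently dropped.

Three further screens define the analysis set: a minimum genotyping rate of
90 % per site; a minimum distance of 3 bp to the nearest SNP on the same
chromosome (both members of a closer pair are removed — the goal is to
avoid mis-annotated multi-nucleotide polymorphisms, and either member could
be the artifact); and, for non-intergenic sites, expression support
(maximum FPKM over overlapping features strictly greater than 0.3) together
with a GERP score strictly greater than −2 (regions below that are treated
as alignment-poor rather than informative). Intergenic sites skip the
expression/conservation screen because their role is to standardize Rxy,
not to measure load; they still pass the quality filters.

Impact categories (high, moderate, low, modifier) are taken verbatim from
an snpEff-style annotator after case/whitespace normalization; any other
label is a hard error that names the label. GERP effect bins partition the
retained range at 2, 4 and 6 (neutral, moderate, large, extreme). phyloP
calls a site conserved above 1; phastCons only at its maximum value 1.

**Polarization.** ALT is the derived allele at a biallelic site iff its
frequency is exactly zero among all *called* outgroup genotypes, across
every outgroup species; missing outgroup calls do not enter the
denominator. Sites where ALT segregates in any outgroup, multiallelic
sites, and sites with no called outgroup genotype are UNKNOWN and excluded
from all derived-allele statistics. The exact-zero rule is deliberately
conservative: one derived outgroup allele may reflect incomplete lineage
sorting or genotyping error, and either way the ancestral state is no
longer trustworthy.

## Load statistics

*SFS.* Per category, the histogram of derived-allele counts over sites at
which every individual of the chosen sample is called; monomorphic sites
are excluded. For display, counts above 10 can be binned; a bin's value is
the number of sites in the interval divided by the number of allele-count
values the interval spans (so a uniform tail plots flat).

*Individual counts.* Sites with more than 10 % missing genotypes are
dropped; an individual's own missing calls simply do not contribute. The
derived-allele count is the dosage sum, the homozygote count the number of
dosage-2 sites.

*Rxy.* With `f_i^X` the derived-allele frequency at site `i` among called
genotypes of X, L_X∉Y = Σ f_i^X (1 − f_i^Y) and symmetrically L_Y∉X; Rxy is
the ratio L_X∉Y/L_Y∉X divided by the same ratio over the intergenic control
set. The frequency-sum form follows Do et al. (2015); the ratio-of-ratios
standardization cancels sample-size and substructure effects shared between
the category and control sites. The implementation guarantees
Rxy(X,Y)·Rxy(Y,X) = 1 on identical site sets (tested to machine precision)
and is calibrated at 1 on exchangeable populations (tested over 20
synthetic cohorts). Uncertainty is a delete-one-block jackknife with
chromosomes as blocks; each pseudovalue is the estimate with one block's
category *and* control sites removed. Sites monomorphic in a population are
retained and contribute zeros.

*Diversity.* π uses the unbiased per-site estimator 2p̂(1−p̂)·n/(n−1) over
called alleles, summed and divided by the sequence length supplied by the
caller (the method cannot know the callable genome size). Individual
heterozygosity is the heterozygous-call count per kb of callable genome.

*ROH.* A window scanner with PLINK-style semantics and the PLINK parameter
set (window 100 SNPs, ≤ 2 heterozygous and ≤ 5 missing calls per
homozygous window, runs reported at ≥ 100 SNPs, ≥ 500 kb, ≤ 10 kb/SNP
density, gaps ≤ 100 kb). The per-SNP qualification threshold — the fraction
of spanning windows that must be homozygous — defaults to 0.05, the
upstream tool's default, because the literal printed setting (".0") would
qualify every SNP; it is configurable. The scanner is verified against an
exhaustive O(n·w) oracle on 50 randomized fixtures. F_ROH merges intervals
per chromosome and counts only ROH of at least 2.5 Mb.

## The synthetic cohort model

Per site, a derived-allele frequency is drawn from a category- and
population-specific Beta distribution; individual genotypes are
Binomial(2, f) — Hardy–Weinberg within populations, sites independent.
Outgroup samples are written fixed homozygous-reference, so ALT is the true
derived allele everywhere and polarization can be scored against the truth
table. Missingness is uniform per genotype call. Default Beta parameters
give mean derived frequencies around 0.04 (high impact) to 0.2 (modifier),
echoing the downward shift of deleterious site frequency spectra.

What the generator does *not* emulate: linkage disequilibrium, shared
drift/phylogenetic covariance between populations, coverage-dependent
genotype error, call-rate structure by population or site class, and indels
(fixtures are SNP-only). Passing tests therefore demonstrate algorithmic
correctness on marginally independent sites, not robustness to the
correlation structure of real resequencing data.

## The forward simulator

Discrete generations, separate sexes, one panmictic deme per patch. Each
female produces Poisson(5) offspring, each with an independently drawn
random father (polygyny allowed, no selfing). Loci are unlinked: each
offspring allele is an independent Bernoulli(g/2) draw from its parent's
dosage g, with mutation folded into the transmission probability
(ancestral→derived at µ = 5·10⁻⁵, derived→ancestral at 5·10⁻⁷). Selection
is hard, at the offspring level: survival probability equals fitness, so a
patch can decline below its carrying capacity and go extinct. Survivors are
culled uniformly at random to K. A patch with no survivors or one surviving
sex is extinct and stays empty unless re-founded.

Fitness is multiplicative across loci, w = Π (1−h_i s_i)^{het} (1−s_i)^{hom}
(an additive mode exists as configuration). Selection coefficients are
i.i.d. Gamma(shape 0.3, scale 0.01/0.3); dominance follows
h = exp(−51·s)/2, which makes weak mutations nearly additive and strong
ones nearly recessive, with mean h ≈ 0.37 — recessivity of large-effect
mutations is what makes purging under inbreeding possible in the first
place. Every locus starts the burn-in at derived frequency 0.0014, the
expected mutation–selection-balance frequency for the mean effect size.
Genetic load is L = 1 − W_mean/W_max over the females of a patch, W being
the expected number of surviving offspring (fecundity × w; the fecundity
factor cancels). Note L measures *segregating* load: mutations fixed in a
patch reduce everyone's fitness equally and cancel in the ratio.

Founding of a new population is migration of offspring: a fresh offspring
pool is produced from the source patch and founders are sampled from it
without replacement, with the sex ratio forced to 1:1 (odd counts get the
extra female). A founding whose source has meanwhile gone extinct is
skipped with a warning and the destination counts as extinct in the tally —
extinction cascades are a recorded outcome, not an error.

Reproducibility: each replicate runs on an RNG substream seeded by
(master seed, replicate index), so single replicates can be re-run in
isolation and results do not depend on execution order.

### Scenarios and problem sizes

`scenarios/ibex_reintroduction.yaml` encodes the full reintroduction
demography: a 3000-generation burn-in at K = 1000 (deliberately short of
equilibrium so deleterious variation still segregates), the species
bottleneck (K = 500 for five generations, then 80 for two), recovery at
generation 3007, zoo foundings three generations later, and wild foundings
in simplified phases, with carrying capacities set to harmonic means of
census records. Zoo capacities are adjusted upwards from their historical
harmonic means (16 and 20) to keep the zoos viable; founder counts and
capacities not fixed by the historical record are marked `estimated` in the
file and are meant to be edited there, never in code.

The tests and examples run `scenarios/ibex_scaled.yaml` (capacities ÷ 10,
burn-in 300, 500 deleterious + 100 neutral loci) and purpose-built small
scenarios; these sizes keep a full suite run to a couple of minutes on one
CPU while preserving the qualitative regimes of interest. At the scaled
sizes several patches have K ≤ 10, so extinction — including of the source
deme during the scaled species bottleneck — is noticeably more frequent
than in the full parametrization; quantitative extinction rates are
properties of the full-scale scenario only.

For the purging property test, the genetic architecture is chosen for
statistical power while remaining survivable through a K = 10 bottleneck:
100 near-recessive loci with s ∈ [0.5, 0.6] and 300 mild loci
(s ∈ [0.001, 0.01]) starting at frequency 0.05, with 400 neutral loci as
the Rxy control. Denser strong-effect architectures drive the bottlenecked
population extinct through inbreeding depression before purging can be
measured.

## Numerical choices and degenerate inputs

- All random draws flow from `numpy.random.Generator` objects seeded
  explicitly; fixtures are byte-reproducible for a given seed.
- Frequencies are computed over called alleles only; sites with no called
  genotype yield NaN frequencies and are excluded from the statistic at
  hand rather than propagating.
- Rxy raises (rather than returning ±inf) when a denominator sum is zero,
  with the advice to enlarge the control set; a jackknife block whose
  removal empties the control set yields a NaN pseudovalue and a warning.
- Fitness is accumulated in log space; s = 1 homozygotes produce w = 0
  exactly.
- Unsorted positions are sorted internally with a warning (proximity
  filter, ROH scan); ties in culling and founder sampling are broken by
  the RNG, never by input order.

## Known limitations

- No linkage anywhere: the empirical statistics treat sites marginally and
  the simulator recombines freely. ROH-based inferences on simulated data
  are therefore not meaningful, and jackknife blocks on synthetic cohorts
  capture sampling noise only, not LD block structure.
- The simulator has no age structure, migration outside founding events,
  environmental stochasticity, or linked selection.
- The scenario files carry estimated founder counts and capacities where
  the historical record in this repository is incomplete; quantitative
  extinction rates and load trajectories of the full pedigree depend on
  those entries.
- The empirical pipeline consumes annotations (impact, conservation,
  FPKM) as given; it neither computes them nor models their errors.
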