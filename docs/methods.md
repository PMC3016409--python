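# Methods

## Problem and model

`hapmc` tests whether a haplotype over a set of tightly linked SNPs is
associated with a dichotomous trait, in study resources that may mix
unrelated case-control samples, nuclear families and large multi-generation
pedigrees.  Two obstacles make this non-trivial: phase must be inferred
from unphased genotypes (and the inference should use pedigree structure),
and association statistics computed on inferred maximum-likelihood (MLE)
haplotypes have no tractable reference distribution — treating MLE
haplotypes as observed data is known to invalidate tests.  The package
addresses the first with a pedigree-informed EM phaser and the second with
a gene-dropping Monte Carlo null that repeats the *entire* phasing process
on every null data set.

Assumptions throughout: autosomal biallelic SNPs in a zero-recombination
region, mutation- and genotyping-error-free data, Hardy-Weinberg
equilibrium for founder haplotype pairs.  Allele "2" is the minor allele;
haplotypes are bit strings with bit *i* set when locus *i* carries allele 2.

## Phasing

**Preprocessing.** Large pedigrees are split for tractability: a nuclear
family is kept when both parents and at least one offspring have at least a
fraction `threshold` (default 0.5) of markers typed; retained families are
reconnected through shared individuals; typed members outside any retained
family are phased as independents, untyped ones are dropped from phasing
only (never from the later gene drop).  Fragments containing a loop (e.g.
by inbreeding) are detached to independents with a warning.

Each individual's genotypes are loaded into six n-locus bit vectors
(homozygous / heterozygous / unphased per genotype; set / missing / value
per haplotype).  Deduction rules then run to a fixed point over all
parent-offspring trios: homozygous parent loci resolve offspring ambiguity
and vice versa, with single-bit inheritance (which parent a child haplotype
came from) and transmission (which parental haplotype was passed)
bookkeeping resolved by exclusion and conditional exclusion; a shared
haplotype that is identified on both sides is copied in both directions;
an individual's last unphased heterozygous locus is gauge-fixed when its
haplotype labels are still interchangeable.  Rules whose published
descriptions are too terse to implement unambiguously (propagation when
only one or neither of inheritance/transmission is known) are deliberately
omitted: every rule here only shrinks ambiguity that enumeration would
expand, so omitting a rule costs speed, never correctness.  Soundness — the
configuration set after preprocessing equals brute-force
expansion-and-filter of the raw genotypes — is enforced by a property test
over random pedigrees, as is exactness of the configuration *weights*
against the Elston-Stewart prior.

**Configuration enumeration.** All Mendelian-consistent haplotype
configurations of a substructure are built family-by-family, extending
offspring in ascending order of their option counts (genotype elimination
is integrated: inconsistent partial configurations are discarded
immediately), then joined through linking individuals.  Founders whose two
haplotypes are still interchangeable are stored as canonical sorted pairs;
an unequal founder pair carries the HWE multiplicity 2.  A hard cap
(default 5,000,000 partial configurations) aborts enumeration with advice
to raise the genotyping threshold.

**EM.** The likelihood of a substructure is the Elston-Stewart sum over
configurations of founder HWE pair probabilities times Mendelian
transmission probabilities (1/2 per transmitting parent).  The E-step
computes configuration posteriors under current frequencies; the M-step
divides expected founder haplotype counts by the number of founder and
independent chromosomes (descendant chromosomes are copies and do not enter
the denominator).  Initial frequencies are uniform over the haplotypes
appearing in at least one configuration; iteration stops when the largest
frequency change drops below `tol` (default 1e-6, `max_iter` 1000).  The
log-likelihood is asserted non-decreasing in tests.

**PL-EM.** Beyond one partition (default length 5, overlap 1) the marker
set is phased window by window; after each window's EM, haplotypes with
frequency below `cutoff` (default 1e-6) are pruned except for the `buffer`
(default 25) most frequent of them; adjacent windows are ligated by
matching overlap loci, configurations are re-enumerated restricted to the
surviving concatenations, and the EM re-runs from a fresh uniform start.
If ligation leaves an individual with no consistent pair, that individual's
own genotype-consistent haplotypes are reinstated and the step retried.
With `cutoff=0` and an unbounded buffer PL-EM reproduces the full EM to
1e-6 (tested).  Practical marker limit is roughly 20 loci.

**MLE pairs.** Each individual's pair is read off the maximum-posterior
canonical configuration of its substructure (ties break to the
lexicographically smallest encoding, so runs are reproducible); missing
positions are thereby imputed.  A pedigree-naive baseline (`naive=True`)
phases every typed individual as an unrelated singleton through the same
machinery.

## Association testing and Monte Carlo significance

Statistics on MLE data: Cochran-Armitage trend (diploid coding, scores
0/1/2 copies of the target haplotype), Pearson chi-square and odds ratio
(haploid chromosome-based or carrier-collapsed diploid 2x2; Haldane 0.5
correction when a cell is zero), and the TDT ((b-c)^2/(b+c) over
transmissions from informative parents — exactly one target haplotype — to
affected offspring, one count per parent-offspring pair).  Sub-haplotype
and single-SNP tests project the full-length MLE pairs (imputed positions
included) onto the chosen loci.

Controls are explicit (all unaffected phased individuals) or
pseudocontrols: for each affected case whose two parents are typed,
unaffected and phased, the two untransmitted parental haplotypes form one
pseudocontrol that replaces both parents' explicit contributions; anyone
else stays explicit.  Cases with unresolvable transmission (possible when
pedigree splitting separates case and parents) fall back to explicit
controls, logged.  Exactly one pseudocontrol is generated per eligible
case.

Significance is always empirical.  Null data sets are generated by gene
dropping: founders and independents draw haplotype pairs i.i.d. from the
frequencies estimated on the observed data, descendants inherit one
haplotype from each parent uniformly, over the *full* pedigree structure
(members excluded from phasing included); the observed missing-data mask is
imposed and phase erased.  Each null is re-phased with identical settings
— matching the complete phasing-plus-MLE process between observed and null
data is what makes the test valid — and the statistic recomputed.  The
empirical p-value uses the add-one convention
p = (1 + #{null >= observed}) / (1 + n_null), with ties counted toward the
null (conservative) and odds ratios compared on |log OR|.  All randomness
in a run descends from a single integer seed; identical seed and inputs
give identical results.

## Synthetic data generator

The generator reproduces the standard simulation designs.  Founder
haplotypes come from a frequency table; a hidden disease SNP (dSNP) allele
is attached to each founder haplotype with
P(risk allele | risk haplotype) = q + sqrt(r2)(1-q) and
P(risk allele | other) = q(1 - sqrt(r2)), which fixes the marginal dSNP
allele frequency at q (the risk-haplotype frequency) and the
haplotype-dSNP squared correlation at r2 (default 0.8).  Affection is
Bernoulli with multiplicative penetrance `sporadic * GRR^g` (sporadic rate
0.05, g = dSNP risk-allele count); GRR = 1 is the null model.  Designs:

* **CC** — independent singletons ascertained to 500 cases and 500 controls;
* **TRIO** — 500 case-parent trios (affected child; parents' phenotypes
  drawn unconditionally from the penetrance model);
* **ASP** — 250 families with two affected siblings and their parents;
* **LP1/LP2** — five-generation pedigrees from a fixed template
  (187 members), kept when at least 14 generation-3-to-5 members are
  affected; the top two generations are fully untyped with unknown
  phenotype; all cases are sampled plus family controls at 2x (LP1) or 1x
  (LP2) the case count, composed of 80% close relatives of a case (50%
  parents, 30% siblings) and 20% beyond first degree.  For null LP runs the
  phenotype clustering comes from a separate model (default GRR 1.5 at
  q 0.10) while genotypes are re-dropped independently.

Missingness is injected per typed individual and marker independently.
The hidden truth (ordered haplotypes and dSNP genotypes) is returned
separately for accuracy scoring; the dSNP never appears in the emitted
genotypes.

**Packaged pool.** The default pool is a synthetic table of 15 haplotypes
over 15 markers (frequencies 0.17 down to 0.015, summing to one) chosen so
that marker minor-allele frequencies stay in [0.08, 0.5] and pairwise
marker r² is low (max 0.35, mean 0.08), with risk haplotypes at exactly
0.17, 0.10, 0.07 and 0.04, and all 15 haplotypes distinct on the 5-locus
prefix, so analyses can be scaled down in marker count without changing q.
What this pool does *not* emulate: real tagging-SNP panels carry far more
haplotype diversity, so here nearly every genotype resolves to a unique
pair and phasing accuracy saturates near 1 for informed and naive phasing
alike.  Consequently the strict informed-vs-naive accuracy ordering is
demonstrated on a denser 40-haplotype/10-locus pool (fixed seed) with
genuine phase ambiguity; passing tests on the packaged pool show
correctness of the machinery, not the hardness of real data.

## Problem sizes used by tests and the acceptance script

Full-scale replication of the simulation study (1000 replicates x 1000
nulls per cell) is a multi-hour computation per cell; the shipped checks
run the identical pipeline at reduced replicate counts, chosen once:

* type-I error: TRIO design, 60 families, 5 markers, 100 replicates, 99
  gene-dropped nulls each, judged against the central 95% region of
  Binomial(100, 0.05);
* power cells (q = 0.17, 5 markers, full design sample sizes — 500+500 CC,
  500 trios, 250 ASP families): 10-30 replicates with 99 nulls, judged by
  Clopper-Pearson 95% interval overlap with the reported cell +-0.04;
* p-value uniformity: 200 replicates of a 30+30 case-control resource at 3
  markers, Kolmogorov-Smirnov at alpha 0.01;
* property suites: 200 random pedigrees against the brute-force
  configuration oracle, 100 random EM fixtures for likelihood monotonicity,
  PL-EM vs full EM at 7 and 9 loci, pseudocontrol conservation on 10,000
  simulated trios.

With 99 nulls the add-one p-value lies on the grid {1/100, ..., 1}, so the
0.05 rejection threshold is exact.  Statistical bands everywhere are
computed for the replicate count actually used.

One caveat of the marker-count scaling: at five loci the sparse packaged
pool phases almost perfectly, so mid-range power cells (e.g. the trend
test at GRR 1.5) estimate somewhat above values published for 15-locus
panels, where phase misclassification dilutes power; the high-power cells
are unaffected.  The checks therefore verify interval consistency, not
cell-exact replication.

## Known limitations

* Non-zero recombination, X-linked markers, genotype error and mutation are
  out of scope; inbreeding loops are handled by detaching the fragment, not
  by phasing through it.
* Odds-ratio point estimates from ascertained pedigree data with related
  explicit controls can be upwardly biased; the Monte Carlo p-value remains
  valid, the point estimate should be read with caution.
* The enumeration cap means extremely sparse large pedigrees may refuse to
  phase at low thresholds; raising the genotyping threshold is the intended
  remedy.
* LP template topology is a fixed parameterised stand-in for "large
  linkage-style pedigrees"; absolute power numbers for LP designs depend on
  that topology and are not comparable cell-by-cell to published values.
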