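# Methods

## The measurement problem

A long-lived plant is a natural lineage-tracing experiment: a mutation in an
apical meristem is inherited by every branch that later grows from it, so the
genotypes of sampled branch tips are related by the plant's own branching
history. `dendromut` treats the measured physical structure of an individual
plant — a rooted tree whose edges are metres of growth and whose leaves are
sampled branch tips, each sequenced as several independent biological
replicates — as a phylogeny, and estimates where on that tree somatic
mutations arose and at what rate per metre, per year and per generation.

## Site model

Each site is modelled independently over the 10 unordered diploid genotypes
{AA, AC, …, TT}.

**Root (germline) prior.** Given reference base r and heterozygosity θ, the
root genotype is hom-ref with probability 1 − 3θ/2; the three r/x
heterozygotes share mass θ and the three x/x homozygotes share mass θ/2
(pseudo-reference disagreements), in both cases with weight κ on the
transition alternate and 1 on each transversion. The default κ = 2 reflects
the transition/transversion ratio typical of eucalypts and is fixed rather
than fitted (fitting is available via `fit_params(..., fit_kappa=True)`).

**Mutation kernel.** Along an edge of length L metres each allele mutates
independently with probability μ = 1 − exp(−λL), moving to its transition
partner with probability μκ/(κ+2) and to each transversion with μ/(κ+2).
The genotype transition matrix is the product of the two allele kernels
collapsed onto unordered genotypes. Two consequences worth knowing:

* this is a single-jump kernel, not a continuous-time chain, so
  T(L₁)·T(L₂) ≠ T(L₁+L₂); likelihoods are invariant to re-rooting at an
  existing node but not to subdividing an edge;
* the chain is reversible with respect to the ordered-pair multiplicity
  distribution (heterozygotes carry mass 2/16, homozygotes 1/16), not the
  uniform distribution on the 10 genotypes.

**Read model.** A read drawn from genotype {a₁, a₂} shows base d with
probability ½p(d|a₁) + ½p(d|a₂), where p(d|a) = 1 − ε if d = a and ε/3
otherwise. Replicates of a leaf share the leaf genotype, so their read
counts enter a single product; all arithmetic is in log space with per-node
rescaling.

**Scores.** Felsenstein pruning gives the total site likelihood. The de novo
probability (DNP) is the posterior probability that not every node shares the
root genotype — i.e. that at least one somatic mutation occurred — computed
as 1 − (shared-genotype likelihood)/(total likelihood). Branch attribution
renormalises over the configurations {no mutation, exactly one mutated edge},
with genotype g above the edge and h ≠ g below it; the edge with the largest
posterior is the call's branch. Multiple mutations at one site are ignored as
negligibly rare. LLD is the per-read-scaled log10 site likelihood,
log₁₀ L / max(1, reads at the site); low values flag model misfit. MAP
genotypes per node come from a standard inside–outside pass, with ties broken
toward reference-containing genotypes via the prior.

**Parameter fitting.** (θ, ε, λ) are fitted by Nelder–Mead simplex on
logit/log-transformed parameters, maximising the summed site log-likelihood
over putatively neutral sites (in the motivating design, 3-fold degenerate
positions). On 5000 simulated sites the fit recovers θ and ε within a few
percent. Base qualities can conceptually override ε per site; the default is
the single fitted genome-wide ε.

## Filters

Two cascades mirror the two calling routes.

*Positive-control filters* act on independent per-replicate MAP genotypes:
all replicates of each tip agree; at least one tip differs; at most two
alleles (counting the reference); total depth ≤ 500; heterozygote excess
≤ 40 on the phred scale; outside the repeat mask. Heterozygote excess is the
one-sided Levene exact-test probability of at least the observed number of
heterozygous samples given the sample allele counts, phred-scaled; it flags
uniformly heterozygous sites miscalled as variable. It is computed across
all replicate samples (24 in the default design), as a joint caller would
see them. With 24 samples in concordant leaf-triples a divergent site can
reach at most 21/24 heterozygotes (phred ≈ 37), so the excess-het rule
mostly matters when annotations are supplied from a joint caller that saw
discordant replicates.

*De novo filters* act on phylogenetically scored candidates: the call must
sit on a haplotype block of ≥ 500 nt (skippable when no phasing information
exists, e.g. on pileup-only data); candidate pairs closer than 1000 nt are
both removed ("within 1000 nt" = strictly less than; exactly 1000 nt apart
survives — the boundary is pinned in the test suite); LLD ≥ −5; DNP
≥ 0.99999. The proximity rule is evaluated once on the incoming candidate
set, before the other rules, so filtering is order-independent; a
consequence is that end-to-end recovery is not monotone in the DNP cutoff
(removing a candidate can rescue its close neighbour), while candidate-stage
recovery is. Haplotype blocks are built by union–find over heterozygous
sites sharing a sequencing fragment; block span is the min–max member
position.

## Positive control

Genotype calls surviving the strict filters form a discrete-state alignment
(one genotype string per tip per site). All (2n−5)!! unrooted topologies on
the n = 8 tips — 10 395 — are enumerated by successive leaf insertion, and
each is scored by Fitch parsimony (bitmask set-intersection, vectorised over
sites). The topological path difference (PD) between each topology and the
unrooted physical tree — the Euclidean distance between pairwise tip
path-length vectors with every edge counted as 1 — yields an exact null
distribution; a maximum-parsimony tree whose PD falls in the lowest 5% of
that null is closer to the physical structure than chance. Ties in the null
count as ≤ (conservative). An equal-rates (Jukes–Cantor-style, generalised
to r states) likelihood scan with per-edge length optimisation and
nonparametric site bootstrap (default 100 replicates) provides the
ML companion analysis, and a through-origin least-squares regression of
per-edge mutation counts on metres quantifies the growth–mutation
correlation.

## Validation loops

**False negatives.** Spike sites are drawn uniformly without replacement and
assigned evenly to the tree's 14 edges; at each site the caller's own MAP
root genotype determines the edit: at homozygous sites Binomial(n_ref, 0.5)
reference reads flip to the κ-weighted mutant allele (an induced
heterozygote) in every replicate of every descendant tip; at heterozygous
sites every reference read flips. Edits never touch non-descendant samples
(asserted in the tests). Recovery requires, by default, a surviving call at
the spiked site with the correct branch (site-only matching is a flag), and
attempted spikes at uncovered sites stay in the denominator. The package
edits pileup counts (or, optionally, emitted FASTQ reads); it does not
re-run read mapping, which the original wet-lab design required.

**False discoveries.** Replicate labels are permuted on the binary
replicate-level tree (each tip expanded into its replicates) until the
permuted tree shares no splits with the original — maximal Robinson–Foulds
distance 2(n−3) = 42 for 24 tips — destroying all phylogenetic signal while
preserving every marginal property of the data. Calls at previously unseen
sites under such permutations are false positives by construction; the rate
per experiment divided by the real run's call count is the false-discovery
rate.

## Rate arithmetic

The corrected mutation count is (calls − expected false positives)/recovery.
Dividing by total sampled branch length gives mutations per diploid genome
per metre; dividing further by the callable diploid genome size gives the
per-base per-metre rate. The per-year range combines the shortest root-tip
path with the oldest plausible age and the longest path with the youngest;
the per-generation range multiplies the per-base per-metre rate by the
species' adult height range. The default callable diploid genome size is
1.21×10⁹ bases, chosen so that 3.33 mutations/genome/metre corresponds to
2.75×10⁻⁹ /base/metre; it is an explicit input, not a measurement made here.
Cross-species comparison divides a per-generation rate by the height
separating generations.

## Synthetic data

The generator emulates the study design at desk scale: a uniform random
reference; germline genotypes drawn from the calling prior (het at θ,
hom-alt at θ/2 — matching the model is what makes parameter recovery a
meaningful test); somatic mutations Poisson(2λ·metres·sites) per edge,
placed uniformly at distinct sites with κ-weighted alleles; per-replicate
depths Poisson(mean) and reads multinomial under the ½/½-allele error-ε
model; repeat intervals as alternating exponential blocks/gaps covering a
target fraction (default 40%, mean block 1 kb). The default physical tree
has 8 tips, 14 edges, 90.1 m total length, and root-to-tip paths spanning
exactly 8.4–20.3 m, with the clade {1,2,3} subtended by edge B→C; the exact
per-edge metre values are otherwise unconstrained by the motivating design
and were fixed once. Default intensity λ is set for ~100 expected somatic
mutations on the configured genome.

What the generator does *not* emulate: mapping artefacts, repeat sequence
content (repeats only mask positions), indels and structural variation,
GC-coverage bias, library duplicates. Passing tests therefore demonstrate
the correctness and internal calibration of the inference machinery, not
performance on real alignments, where power is further limited by exactly
the artefacts the strict filters target.

## Problem sizes and numerical choices

Simulated analyses run on megabase genomes at 10× per replicate (30× per
tip, 24 samples), the package's standard desk-scale configuration; spike-in
calibration plants 2 spikes per edge (28 total per megabase), matching the
study-scale spike density of ~1 per 36 kb so that the proximity filter
interacts with spikes as it would at full scale. Pruning runs in 200k-site
blocks with per-node rescaling; genotype scans prescreen sites lacking ≥2
identical non-reference reads in any replicate (a necessary condition for a
confident call) before computing branch posteriors. Nelder–Mead runs on
transformed parameters with xatol 1e-4; ML branch lengths are bounded in
[1e-6, 20] substitutions. Degenerate inputs (all-zero counts, invariant
alignments, zero-length genomes, empty call lists) raise informative errors
or return empty results as documented per function.

## Known limitations

* The caller consumes raw pileup counts; base qualities are summarised by
  the global ε rather than used per read.
* Phasing is a deliberately simple fragment-connectivity construction, not a
  full read-backed phaser with switch-error handling; on pileup-only data
  the block filter is skipped.
* Only biallelic SNVs are modelled; indels and multi-allelic somatic events
  are out of scope.
* Exhaustive topology enumeration is capped at 10 leaves; no heuristic tree
  search is provided.
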