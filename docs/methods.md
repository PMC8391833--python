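# Methods

This note documents the models, estimators and numerical choices behind
`unipargen`, and what the synthetic-data generators do and do not emulate.

## Scope and data model

The package analyses the two uniparental marker systems used in
small-population human genetic history: whole mitochondrial genomes
(maternal line) and Y-chromosome STR haplotypes (paternal line). Samples
carry a population, a country and a language family; every structure
statistic is computed over a partition of samples into populations,
optionally nested inside groups defined by either of the two latter
variables.

## mtDNA typing

Genomes are aligned to a 16,569-position reference in rCRS coordinates
(1-based). The packaged reference is a **synthetic stand-in** with the
rCRS length and coordinate conventions; it is not the human sequence, and
every function accepts a user-supplied reference FASTA for real data.

The alignment path comes from edlib's end-to-end alignment (unit costs);
because unit-cost optima may scatter an indel across coincidentally
matching bases, clusters of nearby variants that contain indels are
re-aligned on short padded windows with affine gap costs (match +1,
mismatch −1, gap open −2, extend −1). With a gap-open cost the optimal
local alignment concentrates each indel into one run, so contiguous
deleted positions become a single `start-endd` record and contiguous
inserted bases one `pos.1X` record. Inputs below 95% identity to the
reference are rejected. Applying the returned variants to the reference
reconstructs the input exactly; this invariant is tested against every
simulated genome.

Hotspot handling removes substitutions at 16182–16193 and 16519 and any
indel whose span touches 303–315 or 515–522 — the classical
length-variation hotspots that inflate apparent diversity.

Haplogroups are assigned by motif scoring rather than phylogeny walking:
each label in a motif panel has a set of diagnostic variants; a genome
scores the fraction present among its filtered variants, the best label
wins, ties go to the label with more diagnostic sites and then
lexicographically, and calls below `min_match_fraction` (default 0.8,
which tolerates one or two back-mutated motif sites in the panel sizes
shipped) are `unassigned`. The default panel covers the four pan-American
founder clades A2, B2, C1 and D1 at Phylotree-inspired positions, with
alternate states derived from the packaged synthetic reference (a
transition of the reference base at each site, two designated
transversion sites, the 8281–8289 deletion for B2 and the 249 deletion
for C1). Sub-lineage motifs are supported through user-supplied panels;
none are shipped, to avoid freezing tree content into code.

## Diversity

Haplotype diversity uses Nei's unbiased estimator
`H = n(1 − Σ p_i²)/(n − 1)` with Nei's variance formula for the standard
error. Sequence reports give the mean number of pairwise differences
(MPD) and per-site nucleotide diversity with **pairwise deletion**: a
site is dropped only for pairs in which either sequence has a gap or N,
and each pair keeps its own effective length — at these sample sizes,
complete-column deletion would discard real signal. STR reports add the
mean over loci of the unbiased allele-size variance. STR haplotype
identity means equality at every panel locus.

## Structure statistics

AMOVA partitions variance from a matrix of squared inter-individual
distances: for sequences the squared distance is the number of pairwise
differences (yielding Φ statistics), for STRs the summed squared
allele-size difference over loci (yielding Slatkin's R_ST). Components
come from the standard nested sums-of-squares decomposition with the
usual unequal-sample-size coefficients. Raw components may be negative;
Φ statistics are computed from components floored at zero (keeping Φ in
[0, 1]) while raw values stay available (`phi_st_raw`, `sigma_*`). The
pairwise φ_ST/R_ST matrices report the floored statistic, so two
populations with identical haplotype multisets score exactly 0 instead of
a negative sampling artifact.

Permutation tests use the conventional schemes — Φ_ST permutes samples
among populations, Φ_SC samples among populations within groups, Φ_CT
whole populations among groups — with the +1 correction,
`p = (#{permuted ≥ observed} + 1)/(P + 1)`, so p is never 0 and is
uniform on the achievable grid under the null (verified by a KS test in
the suite). A two-level design requires strictly more populations than
groups; groups containing a single population are flagged because Φ_SC
carries no information for them.

## Ordination

PCA is a column-centred (optionally standardized) SVD of the haplogroup
frequency table, with the sign convention that each component's
largest-magnitude loading is positive. Non-metric MDS runs SMACOF with an
isotonic (pool-adjacent-violators) disparity fit, best of 20 random
restarts; the reported stress is Kruskal's stress-1 recomputed from the
final configuration, with ties in the input dissimilarities handled by
the primary approach (tied dissimilarities may take any order). Negative
φ_ST entries are floored at zero before embedding (rank-based, so only
ties are affected); a flag disables this.

A caveat worth stating: a non-metric fit constrains only the rank order
of distances, so at small n materially different configurations can have
near-identical (near-zero) stress. Embeddings are therefore reproducible
in stress but only weakly identified in shape; the suite checks
label-order invariance at tolerances the method can actually honour
(stress to 1e−3, Procrustes disparity 0.05 at n = 10).

## Median-joining networks

The construction iterates two steps until stable: (1) build the
ε-relaxed minimum spanning network over the current sequence set — link
(u, v) is included iff d(u, v) ≤ bottleneck(u, v) + ε, where the
bottleneck is the largest edge on the minimax MST path, so at ε = 0 the
network is exactly the union of all MSTs; (2) for every triplet spanning
a link, compute the quasi-median (sitewise majority for variant
characters, with three-way ties resolved deterministically to the first
sequence's state; coordinatewise integer median for STR characters) and
insert the new vectors of minimal connection cost. Afterwards inferred
vectors with degree below three are removed, recomputing the network
after each removal. The ε = 0 network provably contains every MST of its
final node set; note that an inserted median can displace a *direct*
link between two observed haplotypes via a lower-bottleneck path, so MST
containment is a statement about the final node set, not the observed
subset alone.

Default mtDNA site weights instantiate the usual homoplasy-minimizing
rule concretely: transversions weight 3, transitions and indels 1, and
sites carried by three or more distinct haplotype classes (a recurrence
proxy) are down-weighted by one with a floor of 1. The weight table is
emitted with results and fully configurable; ε defaults to 0.

## Descent clusters and TMRCA

The screen pools all complete haplotypes, ranks distinct haplotypes by
frequency (ties broken lexicographically), and keeps as cores those with
count ≥ `min_count` — by default `ceil(0.01 · N)`, overridable to an
absolute count; singletons are never cores. Each chromosome then joins
the nearest core within `d_max` stepwise steps (default 2), ties going
to the higher-count core then rank order, so clusters are disjoint and
partition the pool together with the unassigned set.

Geography profiling reports, per cluster: the fraction of each
population's (and country's) sampled chromosomes that fall in the
cluster, and the per-country mean unbiased allele-size variance among
members (computed only for countries with ≥ 3 members). The country of
maximum variance is the inferred origin — an old presence accumulates
variance around the founder while a recent expansion elsewhere shows
high frequency but low variance. Exact variance ties are reported as
ties (all argmax countries); with small discrete counts the variance
takes values k/(L·n), so cross-country collisions are possible and the
tie report is deliberate.

Dating uses the ASD clock: ASD = mean over members of the mean squared
repeat difference from the core over loci; under the single-step
mutation model on a star genealogy E[ASD] = μT per locus, so
T = ASD/μ generations, times 30 y per generation by default. The default
μ is 0.022 per locus per generation, the rate conventionally used with
this estimator family for evolutionary dating; confidence intervals are
a 2.5/97.5 percentile bootstrap over members. Two caveats: the clock
dates divergence from the *core* (a founder proxy), so when most members
stem from a recent sub-expansion the estimate bounds the full cluster
TMRCA from below; and the bootstrap CI reflects sampling of members, not
the coalescent variance of the genealogy.

## Synthetic data

The generators produce every input format the pipeline reads, with known
truth, deterministically from a seed.

**mtDNA.** Genealogies come from msprime (single population or n-island
model, haploid); mutations are placed on branches as a Poisson process
with total rate θ/(2·Ne) per genome per generation, positioned uniformly
over the 16,569 sites with a 20:1 transition:transversion bias and full
finite-sites bookkeeping (recurrent hits and back-mutations modify the
current state). Sequences are emitted as reference + mutations, so the
typing module is exercised end-to-end. Under this parameterization the
neutral identity E[MPD] = θ holds and is verified at θ ∈ {2, 5}.

**Y-STR.** Haplotypes evolve by the symmetric single-step model: on each
branch each locus takes Poisson(μt) unit steps of random sign.
Genealogies are either msprime coalescents (optionally with exponential
growth; the default growth rate echoes the 0.0217 used for male
expansion clusters) or star trees of fixed depth. The simulator default
μ is 0.0022 per locus per generation — the realistic average germline
Y-STR rate. This deliberately differs from the 0.022 dating default
above: at μ = 0.022 a lineage of a few-century depth would accumulate
~6 mutations per 14-locus haplotype, no haplotype would ever recur, and
frequency-ranked core selection would be structurally impossible — no
real pooled database in which frequent cores exist can have mutated at
that rate. Analyses of simulated data therefore date with the
generating rate.

**Descent scenario.** Three country pools (100 background chromosomes
each, per-country coalescents with haploid size 5,000, which keeps
background haplotype sharing at the ~1% level seen in pooled empirical
databases) plus one implanted cluster: a founder in the source country
at the full TMRCA depth (571 y default), 6 members sampled at that
depth, and 12 members from a migrant lineage that expanded in the spread
country starting 60 y ago. The migrant carries the founder haplotype, so
the implanted cluster has a single modal core; placing mutations on the
migration path would let deep members re-create a second core at
frequency and split the cluster under the nearest-core rule. This
geometry is what makes the characteristic signature — frequency maximal
in the spread country, variance maximal at the source — reproducible; a
flat star across countries gives exchangeable variances and no
identifiable origin.

What the generators do **not** emulate: recombination (irrelevant for
these markers), selection, heteroplasmy, locus-specific STR rates,
mutation-rate heterogeneity along the mitochondrial genome, sequencing
error, and database ascertainment bias. Passing tests therefore show the
estimators are correct under their stated models at desk-scale sample
sizes, not that real comparative databases would reproduce any
particular published value.

## Problem sizes and determinism

The test and acceptance workloads use desk-scale sizes chosen to give
stable Monte-Carlo estimates: 200 random AMOVA instances (≤12 samples)
against a brute-force oracle at 1e−9; 200 structureless replicates × 199
permutations for null calibration; 500 star replicates (n = 18, L = 14)
for TMRCA calibration and CI coverage; 100 scenario replicates (318
chromosomes) for end-to-end cluster recovery; 500 coalescent replicates
per θ for the E[MPD] identity and 1000 star replicates for the SMM
variance identity. All randomness flows from explicit integer seeds
(numpy Generator streams; msprime seeded per simulation), so every
number in every report is reproducible from the recorded configuration.
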