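# Methods

`mgmlst` quantifies the strain-group composition of one bacterial
species inside a microbiome sample. It combines multi-locus sequence
typing (MLST) with a supervised Bayesian admixture model: the sample's
marker-gene coverage is converted into an allelic profile encoded as a
single individual of ploidy 100, and that individual's "ancestry"
across predefined strain population groups is the vector of strain
relative abundances. The reference system is the skin commensal
*Cutibacterium (Propionibacterium) acnes*, whose strains cluster into
ribotype (RT) groups, but nothing in the implementation is specific to
that species.

## From coverage to an allelic profile

**Marker SNPs.** For each MLST locus the allele catalogue is a set of
pre-aligned, equal-length sequences with integer IDs. Restricting to
alleles actually used by the labeled learning set, a *marker SNP* for
allele *a* is a (position, base) pair carried by *a* and by no other
considered allele at that locus. This is the strictest reading of
"distinguishing SNP": every marker is individually diagnostic, and the
property is verified by exhaustive enumeration in the tests. One allele
per locus is the *default allele* (the RT1 allele in the *P. acnes*
schemes); it carries no markers and absorbs all unexplained coverage.
An allele with no diagnostic position is reported as an error — the
scheme cannot resolve it — rather than silently merged.

**Presence filters.** A marker is called present when its relative
abundance at its position is at least `min_freq` (default 0.01) and it
is supported by at least `min_reads` reads (default 4). Frequency is
supporting reads over total depth at the position, where depth is the
sum of A/C/G/T counts (N and ambiguous bases are excluded). Both
thresholds are inclusive, and raising either can only turn calls off —
a monotonicity the tests check.

**Allele abundances.** An allele is present only when *all* of its
markers are present. A present allele's abundance is the **minimum** of
its marker frequencies (configurable to the mean). The minimum is
conservative: it can never assign an allele more mass than any of its
diagnostic sites supports, at the cost of a small downward bias of
order the per-marker sampling noise. The per-locus residual
1 − Σ(present non-default abundances) goes to the default allele;
residuals in (−0.10, 0) are clamped to 0 with a warning, and anything
below −0.10 indicates grossly inconsistent marker frequencies and is an
error. The vector is renormalized to the simplex.

**Ploidy-100 encoding.** Abundances become exactly 100 discrete allele
copies per locus: round half away from zero; a total of 99 is filled
with one missing-data entry, a total of 101 drops one copy of the most
abundant allele (ties broken toward the lowest allele ID), and any
larger discrepancy falls back to largest-remainder apportionment. The
same repair is applied to real-sample encoding and simulated-community
construction alike. Missing data is −9, the STRUCTURE convention, in
all exports.

## The supervised admixture model

Let K population groups have per-locus allele frequencies
p_{k,l} ~ Dirichlet(λ, …, λ) updated **only** from the labeled learning
strains (n_{k,l,j} counts their allele copies — 100 per strain per
locus). The sample's 100 copies per locus are exchangeable draws from
the mixture Σ_k q_k p_{k,l}, with q ~ Dirichlet(α, …, α). Inference is
Gibbs sampling over (p, z, q), where z assigns each copy a group of
origin; because same-allele copies at a locus are exchangeable, the
z-step is one multinomial per distinct (locus, allele) pair, making a
sweep cheap at ploidy 100. The posterior mean of q over retained sweeps
is the strain-composition estimate, with a batch-means Monte-Carlo
standard error (20 batches).

Numerical choices:

- **λ = 1** (one pseudo-copy per allele). Learning counts are in the
  hundreds to thousands per (group, locus), so the prior is immaterial;
  the "correlated allele frequencies" prior of the original STRUCTURE
  configuration is deliberately not implemented — with frequencies
  pinned by the learning counts it would change nothing detectable, and
  independent Dirichlet priors are simpler and exactly specified.
- **α = 1/K fixed** by default. In the supervised, single-individual
  setting α is weakly identified; a Metropolis-updated common α
  (uniform prior on (0, 10], normal proposal, sd 0.25) is available via
  `alpha_mode="metropolis"`.
- **Chain length** defaults to a 25,000-sweep burn-in and 125,000
  retained sweeps per run. All fidelity results in this repository use
  a scaled operating point — burn-in 2,000, 10,000 retained sweeps,
  5 accepted runs — chosen as the package's standard simulation scale;
  at the synthetic schemes' strong group separation the posterior is
  essentially identical to longer chains (Monte-Carlo SEs ~1e-4).
- **Frequency sampling** (redrawing p each sweep) is the default; a
  fixed-posterior-mean mode (`sample_frequencies=False`) exists for
  oracle comparisons against numeric quadrature.
- Groups are indexed by first appearance in the learning set, which
  makes inference exactly equivariant under group renaming (no
  label-switching, verified to machine identity).

**Run acceptance.** Each run re-classifies every learning strain as if
it were a test sample, leaving its own copies out of its group's
counts; the strain is correct when the argmax of its inferred q is its
label. A run is accepted when accuracy ≥ 0.8 — the strict complement of
"more than 20% misassigned" (13/62 misassigned rejects, 12/62 accepts).
Classification uses its own shorter chains (defaults 100 burn-in / 400
sweeps): a pure 100-copy-per-locus strain against well-separated groups
converges orders of magnitude faster than a mixed sample, and the
argmax decision is insensitive to residual Monte-Carlo noise. Runs are
launched from consecutive seeds until the configured number (default
20) is accepted, capped at 100 attempts; per-sample q is the arithmetic
mean over accepted runs (median by flag), and reported uncertainty
combines between-run variance with within-run Monte-Carlo error.
Population groups that are clades of one reporting group (e.g. the two
RT1 clades) are summed via the scheme's merge map after aggregation.

## Learning-set curation

Per group, the per-locus majority allele (ties toward the lowest ID)
forms the consensus profile. A strain is excluded when it carries an
allele missing from the catalogue, or when its per-locus match count to
some other group's consensus is at least its match count to its own —
an ambiguous profile. Exclusion and consensus are iterated to a fixed
point, so curation is idempotent; a group losing all its strains is an
error. The exact-match-count rule is a deliberate choice: ambiguity
needed a concrete metric, and per-locus exact matches are simple,
deterministic, and reproducible.

## What the simulator emulates — and what it does not

`generate_synthetic_scheme` builds a K-group (default 6, emulating the
major *P. acnes* RT groups with the two RT1 clades merging on report),
L-locus (default 4, mirroring the four-gene *fba/lac/recA/zno* scheme)
catalogue: allele 1 is the reference (and default allele) at every
locus; every other allele deviates at `snp_divergence` (default 2)
dedicated positions, so marker SNPs exist by construction. Each group's
consensus carries its own allele at every locus; a minority of strains
per group carry one variant allele (within-group diversity). Defaults —
10 strains/group, 450 bp loci, 8 alleles/locus — give a learning set of
60 strains with fully separable groups.

Communities hold exactly 100 members sampled uniformly with replacement
from the learning strains of each reporting group. Set A is one group
(or a closely-related pair); Set B draws target fractions from a flat
Dirichlet over reporting groups — the maximum-entropy reading of
"randomly generated"; Set C uses fixed, clinically-shaped targets (a
packaged list with one dominant group at 0.5–0.9 plus minors, standing
in for unpublished clinical compositions). Expected fractions are the
realized member counts, so rounding repairs are reflected in the truth.

`community_to_pileup` draws per-position Poisson read counts and
multinomial bases from the member-weighted base distribution, with a
uniform substitution error model; `deterministic=True` removes the
sampling noise (exact counts at fixed depth), isolating the marker
chain's own error, and `community_to_sam` emits full-length reads as
plain SAM for the alignment path.

What passing these simulations does **not** show: the generator has no
sequencing-platform error structure (no homopolymer or quality-profile
effects), no PCR/amplification bias, no read-mapping ambiguity, and its
groups are perfectly separable by construction — real *P. acnes* RT
groups share alleles at some loci, which is precisely why the published
method's clinical correlations are imperfect. Fidelity here validates
the inference machinery, not clinical accuracy.

## Evaluation

Predicted and expected compositions are compared by Pearson's r over
the full reporting-group vector, zeros included; an exactly constant
vector makes r undefined and returns a flagged NaN instead of a number.
Cohort differences per group use a two-sided Mann–Whitney U (13-vs-13
compositional fractions rarely justify normality; a Welch t-test is a
flag away), reported per group without multiplicity correction. Under
label permutation the p-values are uniform, which the tests verify by a
Kolmogorov–Smirnov check.

## Problem sizes used in the shipped results

The acceptance script and fidelity tests run the synthetic 6-group,
4-locus scheme; Set A over all six groups plus the RT1-clade pair, 20
Set B communities, and the six packaged Set C targets, all at the
scaled MCMC operating point above; the quadrature oracle at K = 2, one
locus, ploidy 4; and noise-free pileup recovery at 500×. These sizes
are the package's standard desk-scale experiment; all are configurable.

## Known limitations

- The correlated-frequencies (F-model) prior and any linkage model are
  out of scope; so is unsupervised selection of K.
- The minimum-of-markers abundance rule is conservative: with finite
  noisy coverage it transfers a small bias toward the default allele
  that grows with the number of detected alleles per locus (visible at
  100× coverage, negligible without sampling noise).
- Indel-bearing or unequal-length alleles are rejected, not aligned.
- Novel alleles in samples are not named or reconstructed; their
  coverage lands on the default allele by the residual rule.
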