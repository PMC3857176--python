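# Methods

This note documents the models and procedures implemented in `whalekin`,
the defaults that matter, and what the synthetic scenarios do and do not
establish about real data.

## Encounter database

An encounter is a discrete boat-based data-collection event with one group
of whales (animals in close proximity with coordinated behaviour). The CSV
schema is one row per (encounter, individual) membership; dates are ISO 8601
at day granularity, with an integer `sighting_no` ordering encounters within
a day. `group_size_estimate` is the field estimate of the whole group and
must be at least the number of identified members — in practice many group
members are never identified.

Derived classifications follow the field's conventions: a whale is
**resighted** once it is identified in any encounter after its first,
including later the same day; a group is **familiar** if it contains at
least one resighted whale. Age class (`adult_or_juvenile`, `calf_of_year`,
`yearling`) is an input flag describing the whale at identification, not an
inference — visually judging a calf as ≤ 50 % of the adult's length is a
field protocol, not a reproducible computation. Unknown sex is a
first-class value; sex-restricted analyses exclude it rather than error.

## Attendance

The analysis year is the **seasonal cycle**, 1 April to 31 March, offset so
that whales over-summering on the feeding ground fall inside one unit.
**Occurrence** counts distinct sighting days per cycle; **occupancy** is the
whole-day difference between last and first sighting dates (consecutive
days → 1), defined only when occurrence ≥ 2. Occupancy makes no attempt to
model gaps in search effort within the interval.

The **operational sex ratio** counts distinct (individual, day)
identification events of known-sex, non-calf whales, pooled across years
within month-based seasonal groupings (May–Jul, Aug, Sep, Oct, Nov, Dec,
Jan–Feb). March and April belong to no grouping and are excluded, with the
excluded event count carried in the table's metadata. Pooling counts per
grouping (rather than averaging daily ratios) was chosen because months are
pooled across years anyway and daily samples are tiny. One consequence of
the individual-level age-class flag: a whale first identified as a calf of
the year keeps that label, so its identification days are excluded from the
OSR in later years too — slightly conservative relative to excluding only
natal-year events.

Goodness-of-fit of a sex ratio against parity uses the 1-df chi-square
without continuity correction; the Yates correction is applied only in the
2×2 comparison of two sex ratios (resighted vs non-resighted samples),
mirroring standard usage. Group-size comparisons between familiar and
unfamiliar groups use unpaired equal-variance t-tests under four filters:
all groups; groups larger than 1; the single largest group per class
removed (the outlier rule); and both. Two identical constant samples are
reported as t = 0, p = 1 rather than NaN. Expected sex compositions of
dyads assume random pairing: (2p(1−p), p², (1−p)²) at female proportion
p = 1/(1 + males-per-female).

## Associations

Dyad counts are tallied per encounter; same-day repeat encounters each
count, which is appropriate when groups are small and data sparse but does
give multi-group days extra weight. The half-weight index denominator uses
X + 0.5(Ya + Yb); the Yab term of the classic index (both seen in the same
sampling unit but not together) cannot arise with the encounter as sampling
unit and is omitted.

Per-individual **mean HWI** averages over all other eligible whales,
including zero-valued dyads — with ~60–80 eligible whales this produces the
characteristically small means (order 0.01–0.06) and makes means comparable
across individuals. **Max HWI** is the largest dyadic value; the associate
count is the number of partners ever co-grouped (X ≥ 1).

All computation is at full precision; rounding to the nearest 0.1
(half away from zero, so 0.25 → 0.3) happens only at network export, where
edges also carry a `displayable` flag at the conventional ≥ 0.3 display
threshold. Histogram summaries bin max HWI at 0.1 and mean HWI at 0.01 —
mean HWI values are an order of magnitude smaller, and 0.1 bins would
collapse them into one bar.

Confidence intervals and preferred/avoided-companion permutation tests are
deliberately out of scope: they need on the order of 15 observations per
dyad, far beyond sparse feeding-ground data.

## Relatedness

### Likelihood

For a non-inbred dyad, the probability of an unordered genotype pair at one
locus given k = (k0, k1, k2) is k2·P2 + k1·P1 + k0·P0, with

* P0 — product of the two Hardy–Weinberg genotype probabilities;
* P2 — HW probability of the shared genotype when the two genotypes are
  identical, else 0;
* P1 — HW(g1) times the probability that one uniformly chosen allele of g1
  plus one random allele from the population reproduce g2.

This reproduces the standard seven-case table (e.g. AiAi/AiAj: P2 = 0,
P1 = pi²pj, P0 = 2pi³pj) and sums to 1 over all genotype pairs for any k —
a conservation property checked numerically in the tests. Multilocus
log-likelihoods sum over loci typed in both members (pairwise deletion),
with a `min_loci` guard of 6 of 10 for incomplete panels.

### Estimation and classification

The unconstrained MLE of k maximises the pair log-likelihood over the
2-simplex via a deterministic 0.05-step grid followed by Nelder–Mead
refinement (tolerance 1e−8) from the top three grid points; there are no
stochastic restarts, so results are exactly reproducible. Classification
compares the log-likelihood at the four fixed points U, HS, FS, PO; ties
break toward the less related hypothesis (U > HS > FS > PO), conservative
against false kin claims.

A known limitation: because the simplex constrains r̂ = k̂2 + k̂1/2 ≥ 0,
the estimator is upward-biased for truly unrelated dyads — about +0.06 at a
panel of 10 loci × 8 equifrequent alleles (the bias shrinks with more or
more polymorphic loci). Recovery of HS/FS/PO means is accurate to within
a few hundredths at the same panel.

### Parent–offspring screening and the PO-vs-FS test

A pair is PO-compatible if it shares at least one allele at every locus
typed in both, and — for putative maternity — the mtDNA haplotypes match
when both are known; the haplotype condition is dropped for putative
father–offspring pairs. The census scans all unordered pairs and reports
those both classified PO and PO-compatible.

PO and FS both have r = 0.5 and are hard to separate. The test treats PO as
the null: the statistic is Λ = lnL(PO) − lnL(FS) for the observed pair, the
alternative FS is simulated (per-locus IBD state drawn from (¼,½,¼), then
alleles from the population frequencies), and p is the fraction of
simulated pairs with Λ at or above the observed value. Simulating under the
alternative (rather than the null) was a deliberate choice where either
reading was defensible; with it, p is uniform for genuine full siblings, so
rejecting FS at α = 0.05 has a 5 % error rate for true FS pairs — verified
by calibration in the acceptance tests. The production default is 10⁶
simulated pairs; tests use 10⁴.

### Null alleles

Off by default. When enabled, a per-locus null frequency is estimated from
homozygote excess (Brookfield 1996 estimator 1, r = (He − Ho)/(1 + He)),
observed frequencies are rescaled by (1 − r), the null is appended as an
extra allele, and every observed homozygote is treated as an ambiguity
class over {true homozygote, visible-allele/null heterozygote}, summing the
pair likelihood over configurations. This is a documented approximation:
it ignores full null–null dropout (which presents as a missing locus) and
estimation error in r.

## Synthetic scenarios

The generator produces a pedigreed population and a sex- and
class-structured encounter history with complete ground truth. Defaults
(`scenario_wsa_default`) describe a small mid-latitude coastal feeding
aggregation sampled over 15 April–March cycles:

* ~300 adults, 53 % female; annual return probability 0.25 for females and
  0.15 for males (maternal-line site fidelity is the phenomenon of
  interest, so females are the more faithful sex, and ex-calves inherit
  the female return rate for two post-natal cycles);
* arrival windows: non-nursing females centred mid-October (sd 18 d),
  males centred September (sd 35 d), cows with calves late January
  (sd 20 d); residency exponential with mean 30 d;
* effort calendar of 50 boat-days per cycle distributed over months in
  proportion to a spring-heavy schedule (Oct 96 : Nov 79 : Feb 49 : … :
  May 7); daily detection probability 0.05, with rare (p = 0.03/day)
  feeding episodes boosting detection eightfold and merging whales into
  aggregations of up to 20;
* groups otherwise assembled to a mean size near 2, with a Poisson count
  of unidentified members added to the group-size estimate, occasional
  same-day repeat encounters of one whale, and cow–calf pairs travelling
  together throughout the calf's natal year;
* 10 microsatellite loci with 8 alleles each (Dirichlet frequencies),
  12 mtDNA haplotypes; 8 cows with 1–3 calves at 1–3-cycle intervals;
  each calf's father is drawn from a small male pool and is absent from
  the sampled panel with probability 0.5.

A default run yields roughly 150–250 identified whales across ~300
encounters with a female-dominated resighted pool and a female-biased
mid-spring OSR, matching the scale and structure the pipeline is designed
for. Everything is reproducible byte-for-byte from the scenario seed.

What the generator does *not* emulate: spatial movement and oceanographic
covariates, heterogeneous per-individual detectability, identification
error (false matches or splits), genotyping error and allelic dropout, and
inter-annual changes in effort quality. Passing tests on synthetic data
therefore demonstrate correctness of the computations and internal
consistency of the pipeline under a realistic sighting process — not
robustness to the observational pathologies of real photo-identification
archives.

## Numerical conventions

* Log-likelihoods of impossible configurations are −∞ (e.g. lnL(PO) for a
  pair sharing no alleles at some locus); classification handles them
  without special-casing.
* Chi-square tests with zero totals raise; OSR rows with no events carry
  NaN ratios rather than fabricating zeros.
* The test suite sizes simulations to run comfortably on one CPU: 500
  pairs per relationship for parameter recovery, 10⁴ FS simulations ×
  1000 replicates for test calibration, 200 randomized stores for oracle
  equivalence.
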