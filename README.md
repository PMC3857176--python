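# whalekin

Analysis pipeline for long-term photo-identification and biopsy studies of
humpback whales (*Megaptera novaeangliae*) on a coastal feeding ground:
attendance statistics over April–March seasonal cycles, half-weight
association networks among resighted whales, and maximum-likelihood pairwise
relatedness from microsatellite genotypes with parent–offspring inference.
A pedigree-aware synthetic scenario generator exercises every stage of the
pipeline with known ground truth, so nothing requires field data to run.

It is written for marine-mammal researchers who hold an encounter database
(one row per identified whale per group encounter) and a multilocus
microsatellite panel, and want the standard feeding-ground analyses in one
tested, scriptable toolkit.

## The statistics at the core

**Half-weight association index.** Associations are tallied at the level of
the encounter. For a dyad (*a*, *b*) with *X* joint encounters, *Y<sub>a</sub>*
encounters of *a* without *b*, and *Y<sub>b</sub>* of *b* without *a*:

```
HWI(a,b) = X / (X + 0.5 (Ya + Yb))     in [0, 1]
```

1 means the two whales were seen together in every encounter of either.
Only *eligible* whales enter the matrix: resighted individuals (identified
in ≥ 2 encounters, same-day resightings included) that were grouped at least
once with another resighted whale.

**Attendance.** Within a seasonal cycle (1 April – 31 March), *occurrence*
is the number of distinct days a whale was sighted and *occupancy* the days
between its first and last sighting (defined only when sighted on ≥ 2 days).
The *operational sex ratio* pools (individual, day) identification events of
known-sex, non-calf whales by month-based seasonal grouping and is expressed
as 1 F : *x* M, with a 1-df chi-square against parity.

**Relatedness.** A dyad's kinship is parameterised by IBD coefficients
k = (k0, k1, k2), the probabilities of sharing 0/1/2 alleles identical by
descent; relatedness is r = k2 + k1/2. Per-locus genotype-pair likelihoods
k2·P2 + k1·P1 + k0·P0 (the standard seven-case table for non-inbred pairs
under Hardy–Weinberg) are summed in log over loci typed in both whales and
maximised over the k simplex (deterministic 0.05 grid + Nelder–Mead).
Each pair is classified as the most likely of U (1,0,0), HS (½,½,0),
FS (¼,½,¼) or PO (0,1,0). Putative parent–offspring pairs must share ≥ 1
allele at every locus and (for maternity) the mtDNA haplotype; because PO
and FS both imply r ≥ 0.5, PO is tested against the FS alternative by
simulating genotype pairs under FS and locating the observed
Λ = lnL(PO) − lnL(FS) in that distribution.

## Worked example

Simulate a default-scale scenario (≈ 300-whale pool, 15 seasonal cycles,
10 microsatellite loci) and run the full report:

```
whalekin simulate --out sim --seed 7
whalekin report --encounters sim/encounters.csv --genotypes sim/genotypes.csv \
                --out report --seed 7
```

The run prints `simulated 424 encounter rows, 166 genotyped individuals`,
and `report/summary.txt` begins:

```
Group sizes (familiar vs unfamiliar):
            variant      class   n     mean       se  min  max  prop_singles
                all   familiar 259 2.084942 0.096179    1   16      0.386100
                all unfamiliar  49 1.632653 0.119145    1    4      0.571429
...
all: t = 1.990, df = 306, P = 0.04751

Mid-spring OSR: 1 F : 0.52 M (chi2 = 16.29, P = 5.437e-05)
Sightings vs associates: r = 0.296, n = 80, P = 0.007737
Parent-offspring census: 7 PO pairs among 166 genotyped whales
```

Reading this: *familiar* groups (containing at least one resighted whale)
average 2.08 whales against 1.63 for unfamiliar ones, and nearly half of
unfamiliar groups are singletons — resighted whales are the more sociable
component. Mid-spring identifications are strongly female-biased
(1 F : 0.52 M), reflecting the configured influx of non-nursing females in
October. Whales seen more often accumulate more associates (r = 0.296 over
the 80 eligible individuals). The PO census (`report/po_census.csv`) lists
each detected parent–offspring pair with its IBD coefficients, r̂,
per-hypothesis log-likelihoods and mtDNA match flag; these are drawn from
the generator's true pedigree.

The same analyses are available per command (`whalekin attendance`, `osr`,
`associations`, `kinship`) and as library functions
(`whalekin.association.association_matrix`,
`whalekin.kinship.classify_relationship`, ...).

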