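# Methods

## Data model

A haplotype is a map from the 27 Yfiler Plus locus columns to allele
calls. Allele states follow forensic typing convention: *normal* (one
integer repeat count), *microvariant* (one non-integer count, e.g. 17.2,
kept as an exact decimal and treated as its own allele state in
frequency tables), *null* (no product, e.g. a deletion spanning DYS448),
and *duplicated* (two or more alleles at a single-copy locus, e.g. the
DYS19 copy-number variant). Repeat counts are validated to [5, 60] at
parse time. Multi-copy systems (DYS385a/b, DYF387S1a/b) are unordered:
tables canonicalize each pair to ascending order on construction, so
column order in input files cannot affect haplotype identity.

Haplotype identity is exact equality of all 27 canonical call tokens.
This makes identity deterministic and means abnormal states discriminate:
a DYS448-null haplotype never matches a typed one.

DYS389II is stored as the raw nested count (the amplicon physically
contains the DYS389I stretch). The adjustment `DYS389II − DYS389I` is
applied only where analyses need independent repeat counts (distances,
networks), through a table-level flag that refuses a second subtraction.
Frequency tables and haplotype identity use the raw value, as forensic
reports do.

## Haplotype and locus statistics

All haplotype-level statistics are direct-count functionals of the
spectrum {count_i}: HMP = Σ(count_i/n)², HD = n(1 − HMP)/(n − 1),
DC = distinct/n, unique fraction = singletons/n. The identity
HD = n(1 − HMP)/(n − 1) is enforced by construction and property-tested
over random spectra. "Unique fraction" is defined as singletons/n
(individuals carrying a haplotype observed once), the reading consistent
with the conventional reporting of these tables.

Per-locus GD/RMP/PD/PIC use allele-state frequencies with one
observation per individual. Null calls are excluded from the denominator
unless `include_nulls=True` makes the null state a frequency class.
PE and TPI are diploid-oriented quantities without a standard haploid
definition and are not reported.

## AMOVA and R_ST

The two-level decomposition on squared repeat distances
δ_ij = Σ_l (a_il − a_jl)² follows the standard variance-component
layout: SSD_total = (1/N)Σ_{i<j}δ_ij over all samples,
SSD_within = Σ_p (1/n_p)Σ_{i<j∈p}δ_ij, σ²_w = SSD_within/(N−P),
σ²_a = (SSD_among/(P−1) − σ²_w)/n′ with n′ = (N − Σn_p²/N)/(P−1), and
Φ_ST = σ²_a/(σ²_a + σ²_w). Using squared repeat differences makes Φ_ST
the microsatellite R_ST. Raw (possibly negative) Φ_ST is preserved in
`AmovaResult`; the `DistanceMatrix` entries are clamped to [0, 1], the
form in which R_ST is conventionally reported. Significance comes from
permuting individuals across groups, p = (1 + #{Φ_perm ≥ Φ_obs})/(n_perm+1).

Distances operate on the 23 single-copy loci with DYS389II adjusted;
multi-copy loci are excluded, and records with null/duplicated calls at
any network locus are excluded with an accounting report. Microvariants
enter as numeric values (a 0.2-repeat difference contributes 0.04);
their handling in reference-database implementations is not published,
so this choice is documented rather than assumed universal.

MDS is classical/metric (Torgerson double centering +
eigendecomposition): deterministic, so results are reproducible and
testable, unlike stress-minimizing iterative variants. Negative
eigenvalues of the centered matrix (non-Euclidean distance input) are
truncated to zero. Kruskal stress-1,
sqrt(Σ(d_ij − D_ij)²/Σd_ij²), is computed on the raw R_ST scale.

## Median-joining networks

Locus weights are integers w_l = round(c/μ_l), with c fixed so the
median weight is 10 and values clamped to [1, 99]; μ_l comes from the
bundled consensus mutation-rate table (per father-son transmission,
overridable per locus). Rapidly mutating loci thus contribute less to
the topology, since recurrent mutation makes their differences weaker
evidence of descent. The network distance is Σ_l w_l·|a_l − b_l|
(absolute differences — the single-step convention for STR networks;
squared differences are reserved for R_ST).

The ε-relaxed minimum spanning network contains edge (i,j) iff
d_ij ≤ bottleneck(i,j) + ε, where the bottleneck is the minimax path
weight; ε = 0 (the default) gives exactly the union of all minimum
spanning trees, which the tests verify against exhaustive spanning-tree
enumeration on small instances.

Median joining iterates: build the MSN over current nodes; for every
triplet sharing MSN adjacency form the candidate median — per locus the
*median of the three repeat counts*. Because repeat counts are
numerically ordered this consensus always exists; it equals the majority
state whenever two of the three agree, and it is the L1 Steiner point of
the triplet, which is what lets small networks reach the Steiner-minimal
cost that exhaustive search finds (a purely categorical majority rule
stalls whenever a triplet disagrees three ways at a locus and provably
cannot reach those optima). The candidate whose insertion most reduces
the minimum-spanning-tree cost is added (incremental MST update over
MST ∪ star(v)); at the fixed point, median nodes whose removal leaves
the tree cost unchanged are pruned. Network cost is defined as total MST
weight throughout, which makes the exhaustive Steiner-enumeration oracle
well-defined. Quasi-median expansion is not implemented. Ties are broken
by lexicographic vector order, so output is platform-independent; a
`max_medians` cap (default 500) bounds worst-case growth.

Cluster annotation cuts long MST edges. With a known cluster count k,
the longest edges are cut until k clusters exist, accepting a cut only
when both sides retain at least `min_size` samples (default 5% of the
sample, at least 2). The guard exists because inferred median nodes
subdivide long inter-cluster bridges into shorter segments, after which
the longest single edge is occasionally a private outlier branch;
without the guard, single-linkage would split off that one lineage
instead of a cluster. Without k, every edge above a configurable length
quantile (default 0.9) is cut. Clusters are reported with label
composition, purity (sums to 1 per cluster), and per-locus modal allele
profiles, which expose the loci separating clusters.

## Simulator

Each tribe is a star genealogy: lineages descend independently from the
tribe founder over g generations; per locus per generation a mutation
occurs with probability μ_l and moves the repeat count ±1 with equal
probability (single-step symmetric SMM; multi-step mutations are rare
enough to be omitted at these depths). The repeat count after g
generations therefore has mean equal to the founder value and variance
μ_l·g — the closed form the tests check at n = 2000 within three
standard errors. A star genealogy rather than a coalescent is a
deliberate simplification: it produces the founder-effect cluster
structure the analyses target and keeps the generator analytically
tractable, but it has no internal branching, so simulated within-tribe
genealogy is shallower and more even than real patrilineal kinship.

Default study design: n = 464 samples in three tribes with proportions
103/464, 272/464, 89/464 and founder-lineage shares 0.67, 0.746 and
0.258; founder-star expansion depth 20 generations (~600 years at ~30
years/generation, the scale of named tribal ancestors); tribe founders
derived from a common ancestral haplotype by 60 generations of SMM.
Samples outside the founder lineage model unrelated background: they
are drawn independently around the panel's modal haplotype with a
per-locus jitter that widens for rapidly mutating loci. Under these
defaults the simulated sample sits in the published high-diversity
regime (HD ≈ 0.999, DC ≈ 0.95–0.98).

Artifacts are injected post hoc as independent Bernoulli events per
sample: DYS448 null at rate 0.14, DYS19 duplication (second allele ±1)
at rate 0.14, DYS458 microvariant (+0.2) at rate 0.0065 — rates matching
the observed frequencies of these events in large Yfiler Plus tribal
datasets. Artifact injection is lineage-independent, which understates
the real clustering of such variants within clans.

The deterministic 59-record fixture (`fixture_karakalpakstan`) is a
synthetic table whose haplotype spectrum is exactly 57 singletons plus
one doubleton (58 distinct of 59); its allele values are simulated and
stand in for a real small population sample only at the level of the
spectrum.

All randomness flows through `numpy.random.default_rng` seeded
explicitly; identical seeds reproduce identical tables across platforms.

## Numerical choices and limitations

- Distance/MST tie-breaks: edges compared as (weight, lower index,
  higher index); tolerance 1e−9 for float comparisons (microvariant
  differences of 0.2 scale to exact binary fractions, so equality is
  reliable at this tolerance).
- Reported table values are conventionally rounded to 4 decimals
  (percentages to 2); internal computation is full double precision.
- AMOVA requires N − P ≥ 1; degenerate configurations raise informative
  errors rather than producing NaN.
- Groups of size 1 get an undefined (NaN) HD in summary reports.
- The R_ST/MDS machinery supports any number of populations, but no
  external reference-population haplotypes are bundled; comparisons to
  published multi-population analyses require the user to supply those
  tables.
- Passing tests on simulated data shows the machinery is correct under
  the stated model; real Y-STR datasets add features the generator does
  not emulate (coalescent branching, clan-correlated artifacts,
  population admixture), so empirical conclusions still require real
  data.
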