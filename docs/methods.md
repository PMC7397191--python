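# Methods

## Data model

Y-STR alleles are repeat counts with an optional fractional part naming
an incomplete repeat (micro-variants .1/.2/.3). They are stored as
scaled integers in tenths of a repeat unit, so 37.2 is the integer 372
and equality is exact — uniqueness counts and haplotype identity never
depend on binary-float rounding. A null allele (amplification dropout)
is a sentinel distinct from every numeric value and forms its own
allele class in diversity estimates.

The 27-locus panel contains two multi-copy loci (DYS385a/b,
DYF387S1a/b) whose a/b assignment is not phase-resolved by capillary
electrophoresis; their calls are unordered multisets, serialised sorted
ascending. A call is a CNV variant iff it contains more alleles than
the locus's expected copy number; a bare single allele at a multi-copy
locus is a copy-number anomaly (possible deletion), flagged but not
classed as a CNV. DYS389II is stored after subtracting the embedded
DYS389I repeats, so the two loci contribute independent information to
distances and diversity; the subtraction is undefined (and recorded as
a null variant) when either raw call is null.

Before any distance-based analysis (AMOVA/RST, individual d-values,
networks over integer lattices), haplotypes carrying null, intermediate
or CNV calls are removed; the forensic diversity statistics keep them,
since a variant allele is still a perfectly good identity mark.

## Forensic estimators

For n haplotypes with multiplicities m_j (frequencies p_j = m_j/n):

- match probability MP = Σ p_j²,
- haplotype diversity HD = n(1 − MP)/(n − 1) (unbiased),
- discrimination capacity DC = N_d/n with N_d the number of distinct
  haplotypes.

HD is undefined for n < 2 and strata that small are reported as missing
rather than raising. Gene diversity per locus applies the same
estimator to allele frequencies obtained by direct counting over the
allele pool; at multi-copy loci every allele of the multiset enters the
pool, so n is the pool size, not the sample size. Reported values are
rounded half-up to five decimals (the precision of published tables);
full precision is retained internally. Haplogroup strata are closed
under descent because nested published sample counts
(N(K) ≥ N(O2) ≥ N(O2a2) ≥ …) are only consistent with cumulative
membership.

## Haplogroup tree and assignment

The 24-marker panel tags the major East Asian paternal clades. The tree
is a plain-text edge list (`child  parent  label`) validated on load
(single root, acyclic, all nodes labelled); it follows ISOGG/YCC
nomenclature. Because the panel carries no marker for the GHIJK level,
G-M201 attaches directly to the root — the closest honest parent given
the markers available.

Assignment takes the deepest marker whose entire root path is derived.
Missing states count as non-derived while walking (conservative: a gap
truncates the call) but are never reported as conflicts; derived
markers off the chosen path, which indicate genotyping error or
recurrent mutation, are. An all-ancestral profile gets the explicit
`unresolved` label. Samples derived at K-M9 but ancestral at all K
descendants are labelled `K`.

Marker-frequency contrasts between two populations use the 2×2
chi-square with Yates continuity correction (the default of the R
`chisq.test` routine used in this field), switchable to the uncorrected
statistic; markers with no derived allele in either population are
untestable and say so. The whole-distribution test is a label ×
population chi-square with categories below a minimum expected count
(default 1) pooled into `other`, since no standard pooling rule exists
for sparse haplogroup tables.

## Distances and AMOVA

The individual Y-STR distance is d(a,b) = (1/n) Σ_i (a_i − b_i)²/(2 m_i)
with m_i the locus mutation rate and n the number of allele slots
(multi-copy loci contribute each copy, paired sorted-order, which is
the minimum-cost pairing under squared differences). The printed form
of this formula is ambiguous about parenthesisation; the reading used
here is the only one in which every symbol it defines (n, i, m_i, a_i,
b_i) is meaningful. The Y-SNP distance is the proportion of discordant
markers — a normalised Hamming metric in [0, 1].

RST is estimated from a two-level AMOVA in distance form: with the
matrix of pairwise squared allele-size differences summed over loci,
SS_total = Σ_{i<j} d²_ij/N and SS_within = Σ_g Σ_{i<j∈g} d²_ij/n_g;
σ²_within = SS_within/(N − k); σ²_among =
(SS_among/(k − 1) − σ²_within)/n′ with the weighted average group size
n′ = (N − Σ n_g²/N)/(k − 1); RST = σ²_among/(σ²_among + σ²_within).
Multi-copy loci are excluded from RST by default (no canonical allele
ordering), switchable to sorted-slot coding. Negative variance
components are reported as-is — flooring happens only on the ordination
input path, and is flagged. A zero total variance is reported as
RST = 0 with a degeneracy flag.

Permutation significance shuffles individuals across groups with group
sizes fixed; p = (#{RST_perm ≥ RST_obs} + 1)/(n_perm + 1), never exactly
zero. Pairwise population RST matrices carry a Bonferroni threshold
α/C(k,2).

The test suite checks the AMOVA implementation against an independent
oracle that computes the same components through per-locus ANOVA sums
of squares with explicit loops — an algebraically different route that
agrees to 1e-9 on a thousand random instances.

## Ordination and clustering

Non-metric MDS starts from classical (Torgerson) scaling of the
double-centred squared-distance matrix — deterministic, so results are
independent of object order — and then alternates isotonic regression
of configuration distances on the dissimilarity order with Guttman
transform updates, minimising Kruskal stress-1
(√(Σ(d − d̂)²/Σd²), a fraction in [0, 1]). Both the stress of the
starting configuration ("initial stress") and the best stress reached
are reported, because published MDS summaries often quote the former.
Disparities are rescaled to the configuration's sum of squares each
iteration; convergence is a stress change below 1e-9 or 500 iterations.

Complete-linkage clustering is implemented directly (cluster distance =
maximum member distance, Lance-Williams update) so that ties can be
broken deterministically by the lexicographically smallest pair of
cluster leader labels; scipy's `linkage` is used as an independent
cross-check of merge heights in the tests. Dendrograms export to
Newick with parent-minus-child heights as branch lengths. Cluster
purity cuts the tree into k clusters, assigns each its majority
haplogroup and counts disagreeing leaves, split into misfits within
versus across major haplogroups; k is a parameter because no single cut
rule is canonical.

## Median-joining network

Haplotypes are vectors in tenths of a repeat over single-copy loci by
default (multi-copy loci lack a well-defined coordinatewise median;
sorted-slot coding is available as an option). Distance is weighted
Manhattan with integer locus weights w_i = round(99 · min_rate/m_i)
clamped to [1, 99] — anti-monotone with mutation rate and invariant to
rescaling all rates. The micro-variant step 37 → 37.2 is an exact
2-tenth move in this lattice.

Construction iterates: (1) build the ε-relaxed minimum spanning network
— an edge of length d is feasible iff its endpoints are disconnected by
edges strictly shorter than d − ε, which for ε = 0 is exactly the union
of all minimum spanning trees; (2) for every triple with at least two
feasible links, add the coordinatewise median as an inferred node iff
connecting the triple through it is strictly cheaper than the best
two-edge connection (for Manhattan distance the median achieves the
half-perimeter bound, so this triggers exactly when the triangle
inequality is strict); (3) repeat until no median is added; (4) prune
inferred nodes of degree < 3. Observed haplotypes are never deleted,
and with ε = 0 and no cost-reducing medians the output equals the
minimum spanning network, which the tests verify against exhaustive
spanning-tree enumeration. ε defaults to 0.

Variant annotation labels each node by a per-locus predicate (default:
fractional part .2), and reports connected components of the carrier
subgraph plus the carrier/non-carrier boundary edges.

## Simulator

The generator emulates the study's sampling design: two populations
(565 and 305 males by default) with distinct haplogroup frequency
vectors anchored on the published major-lineage frequencies
(southern-like: O1a 16.3 %, O1b 14.9 %, …; northern-like: O2a2b
23.3 %, O2a1 18.4 %, …; the remaining mass is spread over the minor
clades, a package choice since full vectors are not published).
Haplogroup counts are multinomial. Haplotypes evolve from founders
under a single-step symmetric stepwise mutation model: each locus copy
mutates ±1 repeat with probability m_i per generation; micro-variants,
nulls and CNVs never arise from the SMM but only from the injector, so
the truth log stays interpretable. Alleles are floored at one repeat.

Shared ancestry has three tiers: a panel-wide modal haplotype, per-
haplogroup founders diverged from it (default 300 generations), and
per-population haplogroup founders diverged from those (default 40
generations) — the knob that drives between-population RST. Within each
(population, haplogroup) cell a random-merge genealogy of configurable
depth (default 100 generations) with uniform coalescence times links
the samples; mutations are binomial per branch and logged, and the
truth object records the full genealogy, per-locus mutation exposure,
true haplogroups and every injected variant. SNP profiles are set
exactly consistent with the true haplogroup, so noise-free assignment
recovery must be 100 %.

Default per-locus mutation rates are literature-plausible per-generation
values spanning roughly 3.8×10⁻⁴ (DYS438) to 1.8×10⁻² (DYS518),
within the published range for these panels; they are package defaults,
not a reproduction of any specific pedigree estimate, and are fully
configurable.

What the simulator does **not** model: multi-step mutations, mutation
rate heterogeneity across alleles, admixture/migration, demographic
growth, genotyping error in SNP states, or locus-specific allele
ranges. Passing tests therefore demonstrate correctness of the
estimators and algorithms under a clean stepwise-mutation world, not
calibration against any real population's values.

### Fixture presets

- `tiny`: 10 samples, two populations, for fast structural tests.
- `table1-like`: the full 565 + 305 design with variant injection
  (null 0.0025/locus over the commonly affected loci, ".2"-at-DYS518
  with probability 0.644 conditional on QR, CNV 0.012/sample).
- `qr-network`: a QR-only sample in which the DYS518 ".2" arises once.
  The carrier clade is simulated as a separately diverged founder
  lineage (stem 60 generations, within-clade depth 20) rather than
  being grafted onto an arbitrary internal branch: a cheap-weight
  variant whose origin branch is short tends to leave each carrier
  metrically closer to an outside "twin" haplotype than to other
  carriers, fragmenting the carrier subgraph even without homoplasy.
  A long-stem recent clade is the regime in which a single origin
  actually produces a single connected carrier cluster, and it is the
  scenario the network analysis is meant to illustrate.

## Numerical and interface choices

- All randomness flows from explicit seeds (`numpy.random.default_rng`
  / `SeedSequence`); identical seeds give byte-identical datasets,
  truth logs and permutation p-values.
- Table I/O is UTF-8 TSV; "null" is an allele token, never a missing
  value; multi-allele cells use "-" on write and accept "/" on read.
  SNP states are A/D/N (ancestral/derived/missing).
- Reported quantities use half-up decimal rounding where published
  precision matters; comparisons in tests use full precision.
- Analysis drivers default to moderate problem sizes (e.g. 250 samples
  for the individual-level tree and embeddings) chosen to keep the
  narrative runs quick; all sizes are flags.

## Known limitations

- The note printing "O2-M112" in the source literature for one of the
  significant markers is treated as a typo for O2-M122 (the panel has
  no M112); the package flags rather than silently renames.
- RST on real data depends on which loci the original software included;
  `include_multicopy` exposes both conventions but no claim is made
  about matching any specific published RST matrix.
- NMDS can stop in a local stress minimum; with the deterministic
  classical start this is reproducible but not guaranteed global.
- The MJ median-addition rule is a faithful Steiner-reduction variant
  of the published algorithm, not a byte-compatible reimplementation of
  any particular software's heuristics (ε semantics documented above).
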