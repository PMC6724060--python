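# Methods

This note documents the models implemented in `demescape`, the defaults
they ship with, the numerical choices made where the design was open, and
what the synthetic study conditions do and do not establish about real
data.

## The scientific setting

`demescape` targets the demographic history of flightless alpine organisms
restricted to "sky islands": patches of high-elevation habitat separated by
unsuitable lowland. The motivating system is a mitochondrial (COI, 575 bp)
dataset of an alpine grasshopper sampled at 22 localities grouped into 7
geographic regions (327 sequences in total), whose range is assumed to have
been colonised from a single source deme after the last glacial retreat.
The inferential question is whether colonisation proceeded by gradual
stepping-stone dispersal (GDD) or whether rare long-distance dispersal
events (LDD) shaped the expansion, and, under the better model, what the
onset time, ancestral size, growth rate, migration rate, carrying capacity
and mutation rate were.

## Landscape model

The habitat is a raster of elevations; cells at or above a threshold
(default 1400 m, the species' observed lower limit) are suitable demes of
area 0.1 km². NODATA cells are permanently unsuitable. Demes are connected
by a von Neumann 4-neighbourhood (the classical stepping-stone topology; an
8-neighbourhood is available as an option). Coordinates are 0-based
(row, col) with row 0 at the top of the raster, matching ESRI ASCII
reading order. Geo-referencing is out of scope: localities address demes
by grid coordinates.

## Forward demography

Each generation applies, in order:

1. **Logistic growth** per deme: `n' = n + r·n·(1 − n/K)`, floored at 0.
   `K` is a single global per-deme carrying capacity; the model assumes no
   spatial or temporal variation in `r`, `m` or `K`.
2. **Migration.** A stochastically rounded `m·n` emigrants leave each deme
   (capped at the whole individuals present, so a deme cannot emit more
   individuals than it holds). Under GDD they are split by a symmetric
   multinomial among the suitable neighbours; demes without suitable
   neighbours retain their would-be migrants. Under LDD a
   Binomial(emigrants, `p_ldd`) share instead jumps: distance ~
   Gamma(shape, scale) in deme units, truncated to [2, 100] demes
   (a jump spans more than one deme and at most 10 km), direction uniform;
   the landing cell is the nearest grid cell to the displaced point.
   Landings outside the grid or on unsuitable cells are redrawn up to 10
   times and then cancelled (the migrant stays), which avoids artificial
   absorbing boundaries.

Densities are real-valued; integer rounding is stochastic and applied only
where whole individuals are needed (migrant emission), which avoids
systematic bias at small deme sizes. Migration conserves the total
population exactly (integer migrant counts); growth is the only operator
that changes it.

The gamma jump kernel defaults to shape 1.5 with scale chosen so the
untruncated mean is 10 demes (1 km). These are package defaults, not
estimates: the kernels published for other terrestrial arthropods do not
transfer directly, and both parameters are exposed in `SimParams`.

The expansion starts with the full ancestral population in a single origin
deme and runs for `t_onset` generations (generation time 1 year). The
simulator records, per generation, every deme size and every directed
migrant count — the conditioning object for the backward coalescent.

### Stationary-phase collapse

With onset times of 15,000–20,000 generations and desk-scale grids the
expansion saturates within a few hundred generations, after which the
demography fluctuates around a steady state (every deme near K, stationary
migration flows). Recording 20,000 explicit generations per simulation
would dominate memory and run time while carrying no additional
information, so reference-table construction uses an optional collapse:
once every deme is colonised (minimum density ≥ K/2) and the
metapopulation holds ≥ 97% of its total carrying capacity, explicit
recording stops, later generations are treated as exactly-at-K, and the
backward walker uses the stationary migration kernel below. The small
idealisation (ignoring O(√K) fluctuations around K and the ≤3% residual
deficit at the switch point) perturbs coalescence rates by at most a few
percent, far below the Monte-Carlo noise of the ABC pipeline.
`simulate_forward` defaults to the fully explicit trace; every
conditioning-correctness test runs against explicit traces.

## Backward coalescent

Deme sizes are interpreted directly as haploid gene-copy counts (mtDNA is
maternally inherited and non-recombining); a `gene_copy_scale` multiplier
is exposed for other markers. Lineages walk backward in three phases:

* **Stationary phase** (collapsed traces only): each lineage moves with
  probability `m` per generation under the mirror of the forward kernel —
  a uniform suitable neighbour, or with probability `p_ldd` a truncated
  gamma jump. On a translation-symmetric saturated lattice this mirror is
  the exact time reversal; near grid edges it is an approximation (edge
  demes receive slightly less immigration than the reversal assumes).
  Co-resident lineages coalesce with pairwise probability 1/K.
* **Explicit phase**: a lineage in deme *i* at generation *t* relocates to
  source deme *j* with probability `immigrants_{j→i}(t) / sizes_t(i)`,
  exactly as recorded; co-resident lineages then coalesce with pairwise
  probability `1/round(size)` of the deme they now occupy (the earlier
  generation's size, floored at one copy).
* **Ancestral phase**: lineages older than the onset coalesce panmictically
  in a constant population of `n_ancestral` copies, with geometric waiting
  times at pairwise rate `1/n_ancestral` (discrete generations, not a
  continuous approximation).

Simultaneous collisions are resolved by sequential random pairing within
the generation: pairs are examined in shuffled order and a merged lineage
keeps participating, so a deme of size 1 forces a complete merge in one
generation. Chained merges within one generation are separated by 1e-6 of
a generation so node times stay strictly ordered; the perturbation to
branch lengths is below 1e-3 generations.

Correctness anchors (tested): two lineages in a constant deme of N copies
have Geometric(1/N) coalescence times (mean N, checked against msprime);
total tree length matches the Kingman expectation `2N·H_{n−1}`; lineage
paths never traverse empty demes.

## Sequence model

A single genealogy serves the whole fragment (no recombination). The root
sequence is uniform random; each branch receives Poisson(µ·L·length)
substitutions, each hitting a uniform site and substituting a uniform
different base — a deliberately minimal single-parameter finite-sites
model with no transition/transversion bias, since the inference places
only a rate prior on the mutation process. Sequence length defaults to
575 sites.

## Summary statistics

Per-locality descriptives: haplotype count, haplotype diversity
`Hd = n/(n−1)·(1 − Σp²)`, nucleotide diversity π (mean pairwise difference
per site) and Watterson's `θ_W = S/(a₁·L)` per site — both π and θ_W
estimate 2Nµ for a haploid locus, and their Monte-Carlo means agree within
10% under neutral simulations.

The ABC summary vector over G groups is, in fixed order: the G
within-group mean pairwise differences, the overall mean and standard
deviation of pairwise differences, Hudson's FST for each unordered group
pair (lexicographic), and a global FST — 31 statistics for G = 7. This is
the only natural decomposition of "diversity per group and overall,
differentiation per pair and overall" that sums to 31; per-group standard
deviations would not. Dimension-reduction (PLS) components are
deliberately not used: the raw statistics keep their biological meaning.

FST is the Hudson/Slatkin pairwise-difference form `1 − H_w/H_b` (0 when
`H_b = 0`), with plug-in (frequency-weighted, n²-denominator)
heterozygosities inside the estimator. The plug-in form makes FST exactly
0 for two identical groups and invariant to duplicating every sequence, at
the price of an O(1/n) bias relative to AMOVA variance components — the
cross-check against an independently implemented Φ_ST tolerates 0.02 at
n ≈ 80. The diversity entries keep conventional unbiased n(n−1)/2
denominators. Sites with ambiguity codes are excluded pairwise.

## Haplotype network

Identical sequences collapse into haplotypes annotated with frequencies
and the set of groups carrying them. The network is a tie-keeping minimum
spanning network: Kruskal over Hamming distances where every edge of an
accepted weight class joining components distinct at the class start is
kept, so equally parsimonious connections survive as loops. Median
(inferred intermediate) haplotypes are not inserted; edges carry step
counts instead. This preserves the quantities the network is read for —
sharing across groups, mutational distances, connected components —
without reimplementing full TCS cladogram heuristics, and no claim of
topological identity with TCS output is made.

The connection limit is statistical parsimony at 95%: the largest step
count *j* whose probability of containing no superimposed substitution
still reaches the confidence level. Under a uniform finite-sites model
with a uniform prior on the true substitution count, that posterior
probability has the closed form `P_j = Π_{i=1..j}(1 − i/L)` (derived from
the occupancy likelihood `C(L,j)·S(k,j)·j!/L^k` summed over k with the
Stirling-number generating function; the brute-force posterior is the test
oracle). For L = 575 at 95% the limit is 7 steps — the same order as, but
not numerically identical to, published TCS limits for fragments of this
length.

## ABC inference

Summary statistics are standardized by their median absolute deviation
over the reference table (columns with zero MAD are dropped with a
warning); distances are Euclidean. Two rejection variants are provided:
retain the nearest `ceil(tolerance·n)` rows (ties at the boundary all
kept), or retain everything within an absolute ε — by construction the two
coincide when ε is the k-th order-statistic distance. The default study
tolerance is 0.1 (3,000 of 30,000).

Regression adjustment is the local-linear (Beaumont) correction with
Epanechnikov weights on distance, bandwidth equal to the largest retained
distance; adjusted draws are clipped back into their prior bounds when a
prior specification is supplied; a singular design falls back to the
unadjusted sample with a warning. Model probabilities come either from
model shares among the jointly retained rows (rejection) or a weighted
multinomial logistic regression evaluated at the observed vector. A
neural-network variant is deliberately not implemented.

Posterior marginals are summarised by weighted mean and median, a mode
from a Gaussian KDE with Silverman bandwidth (the value of a 512-point
grid argmax; a zero-variance sample short-circuits to the common value),
and a 90% HPDI as the shortest interval holding 90% of the weighted mass.

Power is measured with pseudo-observed datasets (PODS): held-out
simulations with known parameters, re-analysed as if observed. Model
choice reports the confusion matrix and mean correct-classification rate;
parameter estimation reports bias, RMSE (posterior median as point
estimate) and 90% HPDI coverage.

## Study conditions and desk scale

The priors are those of the study design: onset U[15000, 20000]
generations, ancestral size U[100, 1000], growth U[0.2, 0.9], migration
U[0.05, 0.30], and LDD fraction U[0.001, 0.05] (LDD model only). Two
priors are package choices, fixed once: the carrying-capacity prior
(U[100, 1000], on the scale of the ancestral-size prior and comfortably
covering carrying capacities reported for alpine grasshopper demes) and
the mutation-rate prior (log-uniform [1e-7, 1e-5] per site per year,
bracketing published insect mtDNA rate estimates).

A full-scale analysis of the real range (an elevation grid of ~46,000
demes, tens of thousands of simulations per model) requires external GIS
data and cluster time. The package's power analysis therefore runs at
desk scale: a fully suitable 30×30 grid, one sampled deme per group carrying
the group's total sample size (20, 56, 25, 15, 78, 69, 64; origin in the
group-6 deme), 2,000 reference simulations and 50 PODS per model,
classification by rejection at tolerance 0.1. These sizes were chosen so
the whole analysis completes on a single CPU while keeping the
Monte-Carlo error of a classification rate over 100 PODS near ±0.04.

## What the synthetic data do and do not show

The generator emulates the *structure* of the real dataset — sample sizes,
grouping, fragment length, single-origin expansion on a patchy landscape —
with synthetic geography (massifs in a west-east chain joined by narrow
corridors). It does not emulate the real mountain-range topography, real
inter-locality distances, transition/transversion bias, rate
heterogeneity across sites, or sequencing artefacts. Passing tests
therefore establish that the pipeline is self-consistent (parameters used
to simulate are recovered; models used to simulate are identified), not
that the original biological conclusions are correct; applying the
pipeline to the real alignment requires only the deposited sequences and a
locality table.

## Known limitations

* The stationary-phase mirror kernel is exact only away from grid edges;
  on small grids edge effects slightly distort backward migration near
  boundaries.
* FST uses plug-in heterozygosities (small-n bias) — a deliberate trade
  for exact degenerate-case behaviour; group sizes in the study design
  (15–78) keep the bias small relative to between-model signal.
* The LDD gamma kernel parameters are conventions, not estimates.
* Classification power at desk scale is not directly comparable to the
  full-scale landscape, and the difference is structural, not just noisy.
  At fixed parameters the two dispersal models separate cleanly (LDD
  flattens equilibrium FST; standardized effect sizes above 1 on the FST
  statistics). Marginalised over the study priors, however, a GDD draw
  with high `m·K` produces the same FST level as an LDD draw with low
  `m·K`, and on a 30×30 grid — whose inter-deme distances are smaller
  than the lineage diffusion scale over 15,000+ generations — the
  FST-versus-distance profile carries too little shape to break that
  confound. The desk-scale classification rate the acceptance script
  computes therefore sits well below what the full-scale landscape (with
  distances of hundreds of demes and corridor topology) can support; it
  measures the method's bookkeeping, not its full-scale power.
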