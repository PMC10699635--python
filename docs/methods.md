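# Methods

This note documents the models behind each module, the defaults and why
they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical decisions a maintainer would want recorded.

## Mutation model and synthetic genealogies

Y-STR haplotypes evolve under the strictly symmetric single-step stepwise
mutation model (SMM): on a branch of length t generations each locus
accumulates K ~ Poisson(μ·t) mutations, each moving the repeat count by
±1 with probability ½. The SMM is the standard model behind step-counting
networks and rho dating; the package supports no two-phase or
length-dependent variants. Repeat counts are floored at 1; at the rates
and timescales of interest the boundary is effectively never reached.

Two genealogy shapes are generated:

* **star** — n lineages split simultaneously from one founder
  `age_generations` ago. This is the reference shape for dating because
  the rho/σ treatment used here assumes a star-like expansion.
* **two_level_hierarchy** — populations nested in groups.
  `divergence_generations = (t_g, t_p)` are the *shared* drift times: every
  member of a group shares a branch of t_g generations, every member of a
  population an additional t_p, and each sample a private branch of
  `age_generations − t_g − t_p`. Setting both shared times to zero gives
  exchangeable i.i.d. samples; making t_g large relative to t_p pushes the
  AMOVA decomposition toward the among-group component. `group_sizes` is a
  list of per-group population-size lists (a flat list means one
  population per group).

SNPs are placed once on genealogy branches (infinite sites): the tree root
lands on the genealogy root and every child node on a branch descending
from its parent's branch, so derived(child) ⊆ derived(parent) by
construction. The placement records the branch per tree node and the
deepest planted clade per sample; classification tests use these as the
oracle. Note that rho dates the *coalescence of the carriers*, not the
age of the mutation itself: a marker whose carriers all belong to one
population coalesces at that population's founder even if the mutation
arose on a much older stem branch.

The discovery-stage generator plants variants in named failure classes
(known-catalog hit, repeat overlap, proximity pair, transition) plus clean
transversions, spaces distinct plants farther apart than the field of view
so classes cannot interact, and emits the expected survivor list as a
manifest. Proximity plants come in pairs (transversion + close transversion
or indel), so their fraction is rounded down to an even count.

What the generator does **not** emulate: coalescent randomness within
populations (genealogies are deterministic given the spec; only mutations
are random), STR allele-size constraints and multi-step mutations,
genotyping error, missing data beyond an optional uniform missing rate,
recurrent or back-mutation at SNPs, and sequence context around variants.
Passing tests therefore demonstrate the correctness of the estimators
under their own model assumptions, not robustness to real-data artefacts
such as homoplasy at fast STRs or null alleles.

## Candidate-SNP filter

Rules in order: (i) single-nucleotide substitution; (ii) not in the known
catalog; (iii) outside the repeat mask; (iv) no other input variant within
`window_nt/2` on either side; (v) transversion. Decisions:

* The 3000-nt "field of view" is a **total** width centred on the variant
  (±1500 nt each side), configurable.
* Proximity is judged against the **full** input list, including variants
  other rules reject — what a browser field of view would show.
* Catalog membership is by (chrom, pos); an allele-aware flag exists.
* Coordinates: VCF positions are 1-based, BED masks 0-based half-open.
* Duplicate positions with conflicting alleles warn and are evaluated
  independently (they reject each other under any active window).

Because survivors are isolated by construction, the filter is idempotent
on its own output, monotone in catalog/mask size, and invariant to input
order; all three are tested.

## Haplogroup classification

A node with several phyloequivalent markers is derived when ANY typed
marker is derived and NONE ancestral; an internal disagreement is a
conflict and the node does not promote the sample. The default missing
policy is strict (stop at the first missing node) because typing failures
should not push a sample down-tree; the permissive policy bridges missing
nodes when a deeper derived node exists. Samples ancestral at the root
classify as "not <root>", fully missing ones as "unknown".

The packaged Q-M3 subtree is data (YAML), not code. Its trunk follows the
consortium hierarchy (M242 → L56 → M346 → L54 → {M3, Z780, CTS11780} →
M848); the order of the CO15–CO27 sublineages descending from the
CO24/CO27 clade was reconstructed from their relative coalescence ages and
the two clusters a correspondence analysis of the defining SNPs separates.
That branch order is a reading of a published figure rather than of
machine-readable data, so the file carries comments marking it amendable,
and alternative trees are drop-in files.

Carrier percentages are 100·derived/genotyped rounded half-up to one
decimal (Decimal arithmetic, not binary-float rounding); a marker with
zero genotyped samples reports an undefined — not 0.0 — percentage.

## Median-joining network

Distances are weighted L1 on repeat counts over the non-excluded loci
(DYS385a/b never enter). Locus weights are integers ∝ 1/variance, scaled
so the most variable locus gets 1 and clamped to [1, 99], the convention
of the established network software; the exact constants of the published
weighting scheme this stands in for are not public, so the scheme is
pluggable (`uniform` included).

The ε-relaxed minimum spanning network keeps edge (u,v) iff
d(u,v) ≤ bottleneck(u,v) + ε, where the bottleneck is the minimax-path
distance (max edge on the MST path). This characterisation is independent
of MST tie-breaking — at ε = 0 it yields exactly the union of all MSTs —
so the network is canonical and deterministic without explicit tie rules.
Quasi-medians are coordinate-wise medians of triplets with at least two
network links, inserted when their connection cost is within ε of the
cheapest candidate; the node lattice is bounded by the observed allele
ranges, so the iteration terminates (a hard cap of 10× the observed
haplotype count guards pathological inputs). Median vectors of degree ≤ 2
are pruned: in an L1 geometry a Steiner point of degree ≤ 2 never shortens
the network. ε-monotonicity (larger ε never removes edges) is guaranteed —
and tested — at the spanning-network stage; after median insertion a new
Steiner node can legitimately displace an observed–observed edge, so the
property is not asserted for the final graph.

## Rho dating

rho is the mean *unweighted* step count to the ancestral haplotype — rho
counts mutations, so network weights never apply. The ancestral haplotype
is the per-locus mode with ties broken to the smallest allele (a fixed,
documented rule; any deterministic rule would do). σ = √(rho/n) is the
star-genealogy approximation; the full tree-based variance would need the
true genealogy per sublineage, which a sample of extant haplotypes does
not provide. TMRCA = rho·g/(L·μ) with defaults g = 25 years and L = 15
(the 17-locus panel minus DYS385a/b, matching the network exclusion).
Sublineage dating restricts the profiles to each SNP's derived carriers
and re-infers the modal ancestor within them; a single-carrier sublineage
yields rho = 0 flagged low-confidence rather than an error. Only the EMR
calibration carries a numeric default; OMR-style calibrations are named
but must be supplied, and reports label the rates used.

## AMOVA

With pairwise squared distances δ² (count of differing loci, or sum of
squared repeat differences for an R_ST-style analysis), the
sums-of-squared-deviations identities give SSD(total), SSD(among groups),
SSD(among populations within groups) and SSD(within populations); variance
components Va/Vb/Vc follow from the expected-mean-square coefficients for
unbalanced designs (n', n'', n''' computed from population and group
sizes). Percentages are 100·component/total and must sum to 100 exactly up
to rounding — an identity, tested over random datasets. Negative
components (possible by construction, e.g. when group labels cross
population structure) are reported unmodified. Permutation tests permute
the exchangeable units per level — samples among all populations for
Phi_ST, samples within groups for Phi_SC, whole populations among groups
for Phi_CT — with p = (1 + #{perm ≥ obs})/(B + 1) and default B = 9999
under an explicit seed. A single-group design collapses to a one-level
AMOVA; an all-identical dataset is flagged degenerate instead of dividing
by zero.

## MCA

Indicator-matrix correspondence analysis: categories are (marker, state)
pairs with missing as its own category; constant markers are excluded with
a warning, and a table with fewer than two variable markers returns a
degenerate zero-inertia result rather than an error. Axes come from the
SVD of the standardised residual matrix; eigenvalues are squared singular
values and their sum equals the total inertia (tested as an identity).
Reported inertia percentages are raw by default with the Benzécri
correction behind a flag, since conventions differ between software.
Supplementary categories are projected through the transition formula from
row standard coordinates and cannot influence the axes (tested by
permuting the supplementary label).

## Problem sizes and tolerances

Simulation-backed tests use sizes chosen to make Monte-Carlo error small
relative to the asserted tolerances: the SMM law checks use ≥15,000 draws
against the exact compound-Poisson pmf (χ² at α = 0.01); mean-rho and
age-recovery checks use 200 replicates of n = 500 (3–4 SE bands, or the
5–10% relative bands stated in the tests); permutation-uniformity uses
300–500 null datasets at B = 99 with a KS test at α = 0.01. Where a spec
of the expected value exists in closed form (frequency rounding, TMRCA
linearity, SSD identities) the tests assert exact or near-machine
tolerances. The exact compound-Poisson expectation is used in preference
to the small-λ approximation E|D| ≈ λ, which is measurably biased at the
sample sizes tested.

## Known limitations

* The rho σ is star-approximate; for strongly non-star genealogies both
  rho and σ are biased (homoplasy hides steps at large μT — the estimator
  is validated only for μT ≤ ~0.02 per locus).
* Median-joining is exact only in the sense of the heuristic it implements;
  it does not guarantee a minimal Steiner tree.
* The packaged tree's CO branch order is a curated reconstruction (see
  above), not an authority; classification results at those depths inherit
  its uncertainty.
* AMOVA assumes haploid, non-recombining data; no within-individual level
  exists.
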