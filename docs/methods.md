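# Methods

This note documents the models behind each stage, the defaults and why they
were chosen, what the synthetic-data generator does and does not emulate,
and the numerical and design decisions a maintainer should know about.

## Haplotype encoding

Samples are encoded as sets of reference-relative variant calls from a
pre-aligned FASTA (or a position+base haplotype table). Positions are
1-based on the reference's linearization of the circular genome; intervals
are closed. Gaps against a reference base become deletion calls; bases
opposite a reference gap become insertion calls keyed to the 5′ flanking
position with a running insertion index. Ambiguity codes are counted per
sample and never emitted as variants; the QC filter removes samples whose
count exceeds `max_ambiguous` (strictly greater; default 0, since panels
entering network construction should be effectively ambiguity-free, and the
appropriate threshold is data-dependent).

Indel calls inside reference homopolymer runs of ≥ 5 bases are dropped by
default (`min_homopolymer=5`, pass `None` to keep them): length polymorphism
in such tracts is hypervariable and conventionally down-weighted in network
and dating practice. The default HVS-I window is positions 16051–16400,
configurable; windows differ between surveys and the restriction operation
takes any closed interval.

## Haplogroup classification

A motif table is a single-rooted hierarchy of labels, each with the
diagnostic variants of its branch. A profile receives the deepest label
whose *cumulative* motif (union along the root path) it matches with at most
`tolerance` missing variants; ties prefer more matched variants, then the
lexicographically smallest label, so assignment is deterministic. Tolerance
counts only missing motif variants (back mutations at diagnostic sites);
extra private variants never penalize — the usual motif-matching convention.
Default tolerance 0. The repository ships only a synthetic demonstration
table; real motif tables are study-specific configuration.

## Reduced-median networks

The binary matrix has one column per distinct variant call, so a site with
several derived states contributes one column per state (binary splitting of
multistate characters rather than a quasi-median generalization — matching
the binary-file form this class of network programs consumes). Columns
present in every sample are uninformative offsets and removed (recorded as
`shared_variants`); identical rows collapse with multiplicity.

The node set is the median hull: the closure of the observed rows under
coordinatewise majority over all triples. For binary data the hull contains
every most-parsimonious tree, where tree links are Hamming geodesics
(multi-mutation edges) between hull nodes; the test suite checks this
exactly against brute-force parsimony (all unrooted topologies with Fitch
counting) and an exact Dreyfus–Wagner Steiner computation on instances up to
5 taxa × 5 characters. Nodes are linked at Hamming distance 1; hulls that
are disconnected at that resolution (e.g. two haplotypes two steps apart
generate no medians) are completed by inserting the intermediate states of
the greedy shortest path, flipping characters in ascending column order.
The hull computation is cubic per pass and intended for the haplotype-class
counts of control-region panels, not thousands of distinct sequences; a
`max_nodes` guard (default 20,000) aborts pathological inputs.

Reticulations are resolved mechanically by the relative frequency of the
characters in the cycle: the most frequent character is assumed recurrent
(fast sites are the likely homoplasies) and is retained on two branches; one
link of the least frequent character is deleted, choosing the
lexicographically smallest endpoint pair. Frequency ties treat the character
at the larger site position as recurrent. Every resolution — characters,
frequencies, deleted link, and a `weak` flag when the frequency ratio is
below the reduction parameter r (default 2, the conventional default of this
algorithm family) or tied — goes into the resolution report, which is the
audit surface for judgement calls a human analyst would otherwise make by
hand. Inferred medians left dangling are pruned; sampled haplotypes are
never removed.

Rooting designates an ancestral state vector (default: the reference, i.e.
all-ancestral). An unsampled root is attached by maximum parsimony; ties go
to the lexicographically smallest node and are flagged in the report.

## ρ dating

ρ and its Saillard variance are computed from branch mutation counts with
tip-fraction weights (formulas in the README); identical sampled haplotypes
count as separate tips, since real panels contain duplicates. The effective
sample size is implemented as n_eff = ρ/σ², which equals n on a star and 1
for a fully shared stem; ρ = 0 (hence σ² = 0) returns n by convention, and
the founder stage clamps n_eff into [1, n_f].

Clocks are years-per-mutation constants with an optional correction
transform mapping raw years to corrected years. The whole-mtDNA clock
(1 substitution / 3624 yr) is used with a purifying-selection correction in
the literature; the published correction curve is not reproduced here, so
the hook defaults to the identity and accepts a user-supplied
piecewise-linear table (CSV of raw/corrected knots, interpolated and
linearly extrapolated). Standard errors propagate through the correction's
finite-difference local slope. The HVS-I clock is 16,677 years per mutation;
the source literature prints both 16,667 and 16,677 in different sentences,
and the founder-analysis figure of 16,677 is adopted as the default rather
than silently harmonizing the two. The synonymous clock is 7884 years per
substitution. Diversity statistics are ρ against a designated root haplotype
with the star-model SE √(total mutations)/n, and π as the mean pairwise
symmetric difference (0 for n = 1).

## Founder analysis

Sink lineages walk rootward to the nearest node whose haplotype equals some
source sample's haplotype (haplotype identity, not mere ancestry) and which
satisfies the criterion: f0 requires nothing further, f1 at least one child
branch whose subtree contains source samples, f2 at least two. f1 is the
default: a founder type with no derived source variation is
indistinguishable from a recent back migration. Lineages that reach the root
without a qualifying node are assigned to a root founder and a warning is
raised; cluster sizes always sum to the sink sample count.

Cluster dating uses only sink-side variation: m_f is the total mutation
count on the founder-to-member paths, ρ_f = m_f/n_f, and σ_f is the Saillard
formula over those paths with sink-member weights.

The migration-time scan needs a distributional model. Under a linear clock,
a cluster of n_eff independent lineages with m_eff = ρ_f·n_eff effective
mutations has Poisson likelihood ∝ t^m_eff·e^(−λt), λ = n_eff/μ, for the
arrival time t — a gamma-shaped curve peaking exactly at the cluster's ρ
age, reducing to n independent draws on a star and to a single draw for a
fully correlated cluster. This density is evaluated in log space on the
uniform grid (default 200-year steps, 0–120 ka), normalized per founder, and
aggregated with raw lineage-count weights n_f/N — n_eff enters the precision
(shape and rate) of each cluster, not its vote in the aggregate. The scan
requires an identity-correction clock; corrected clocks would need the
likelihood expressed on the corrected scale, which is out of scope. An
alternative normal-approximation scan (mean ρ_f·μ, SD σ_f·μ) was considered
and left out: the gamma form handles the m_eff = 0 boundary (mass decaying
from t = 0) without ad hoc truncation.

## Synthetic data

The generator simulates a backward-in-time coalescent in continuous years
with no recombination (mtDNA). Demes have a coalescent timescale `ne_years`
(N_e × generation time): constant, exponential-growth (ne(t) = ne₀e^(−gt)
backward, waiting times by inverting the cumulative hazard), or `star`, the
infinite-growth limit in which lineages persist untouched until their
founder event. Sink samples are split evenly across founder events
(youngest first); each group coalesces within the sink until its event time
T_f, where survivors are merged into at most k founder lineages
(multifurcating pulse nodes at exactly T_f).

Founder events are coupled to source demographic episodes: the oldest event
is the onset of the source expansion — all remaining source lineages and the
incoming founder lineages coalesce there — and at younger events each
founder lineage attaches to a burst of `attach_burst` (default 4) coalescing
source lineages. This is the regime founder analysis presupposes: the
founder type must be represented among sampled source lineages. An uncoupled
constant-size source essentially never retains a 60-ka-old founder haplotype
among 50 modern samples (each source tip carries Poisson(T/μ) ≈ 3.6
mutations on that path, so exact matches are ~3% per tip and unsystematic),
and every founder walk would fall through to the root. The burst size of 4
makes a younger founder type visible in the source with probability
≈ 1 − (1 − e^(−T/μ))⁴ (≈ 0.9 at 10 ka) — a deme-history assumption, stated
here openly, that real datasets may violate; recovery results say nothing
about migrations whose founder types vanished from the source.

Mutations fall on each branch as Poisson(L/μ) and hit sites in proportion to
rate class (a configurable hotspot fraction with a rate multiplier;
`infinite_sites` instead gives every mutation a fresh site, producing
compatible, homoplasy-free data). Sites are binary: the reference base and
its transition partner; a repeat hit reverts to the ancestral state, so
truth Hamming distances remain computable and back mutations are visible as
toggling. The emitted FASTA, metadata, truth genealogy (Newick in years),
branch-mutation table and manifest are mutually consistent by construction,
and the test suite checks the round trip exactly.

What the generator does not emulate: selection, recombination, population
structure within demes, sequencing error beyond ambiguous-base injection,
heteroplasmy, and realistic site-specific rate spectra. Passing recovery
tests therefore demonstrate correctness of the estimators under the stated
coalescent model, not robustness to every property of real surveys.

## Validation problem sizes

Chosen to exercise each claim at the smallest scale that is still
conclusive: parsimony containment on exhaustive ≤ 5 × 5 instances (where
brute force over all 15 topologies is exact); dating oracles on 200 random
trees of ≤ 8 tips with 10,000-replicate Poisson resampling (Monte-Carlo
z-scores compared at 3 SE with the binomially expected number of exceedances
allowed, since 200 independent 3-SE tests fail by chance more often than
not); recovery on 100 replicates of the 60-ka single-pulse scenario and 20
seeds each for scan calibration and two-pulse separability. With 50 sink
lineages at 60 ka under the HVS-I clock the total mutation count is
Poisson(≈180), so any ρ-based point estimate has an irreducible ~7.5%
relative SD per replicate; calibration is therefore asserted on the median
relative error across seeds (observed ≈ 4–6%), while the mean ρ-age over
replicates is unbiased well within its standard error.

## Pipeline

Each stage writes plain CSV/FASTA/JSON artifacts plus a manifest with the
config digest and seed, so stages re-run independently and full runs are
byte-reproducible given the seed. The founder stage can run on the network
tree (default) or, for simulated data, directly on the truth genealogy's
mutation tree (`founder.tree: truth`), which is also how large recovery
experiments avoid median-network blowup on highly recurrent HVS-I data. Dual
sink definitions (e.g. an entire region versus one migration stream) fan out
into suffixed founder/scan outputs from a single run.

## Known limitations

- The median hull is exponential in the worst case; large panels of distinct
  recurrent haplotypes need the truth-tree route or external tree input.
- The frequency rule resolves every reticulation deterministically, which is
  reproducible but cannot recover resolutions that depend on information
  outside the data (the report exists so such calls can be audited).
- The purifying-selection correction is user-supplied; with the identity
  default, whole-mtDNA ages at recent timescales will be underestimates
  relative to corrected published ages.
- n_eff is a variance-ratio heuristic, not a likelihood quantity; the scan's
  gamma model inherits it.
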