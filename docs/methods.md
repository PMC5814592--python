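# Methods

`agmap` rebuilds, as a tested pipeline, the analysis chain used to map a
wild wheat relative (the *Agropyron* P genome, chromosomes 1P–7P) with a
wheat SNP array: genotype QC on an outcrossing F1 population, two-point
linkage mapping, assignment of linkage groups to wheat homoeologous
groups 1–7, and detection of alien addition/substitution chromosomes in
wheat-background derivative lines.  Because no array dataset of this
design is publicly deposited, the package ships a synthetic-data module
with known ground truth; every claim the test suite makes is a recovery
or calibration statement about that generator.

## The cross and its segregation patterns

The mapping population is a cross-pollinated (CP) F1: both parents are
heterozygous outbred individuals, so each marker segregates according to
which parent is heterozygous.  With biallelic array calls only three CP
configurations are informative:

| code    | father x mother | progeny classes | informative meiosis |
|---------|-----------------|-----------------|---------------------|
| `hkxhk` | AB x AB         | AA:AB:BB = 1:2:1| both                |
| `lmxll` | AB x AA         | AA:AB = 1:1     | paternal            |
| `nnxnp` | AA x AB         | AA:AB = 1:1     | maternal            |

`lmxll` markers feed the male map, `nnxnp` the female map, and `hkxhk`
markers segregate through both meioses and stitch the two parental maps
into the integrated map.

## Genotype QC

Markers are first classified into array performance categories from the
calls alone: PolyHighResolution (both homozygote classes observed and at
least two carriers of the minor allele), NoMinorHomozygote (two classes,
one homozygote absent), MonoHighResolution, CallRateBelowThreshold, and
Other.  OffTargetVariant requires intensity clusters and is honoured only
as a pass-through label.  The variant call-rate threshold defaults to
0.8 — the relaxed threshold appropriate when a wild relative hybridises
to a wheat array — rather than the array default of 0.97.

Mapping keeps PolyHighResolution/NoMinorHomozygote markers with an
informative pattern, a segregation-distortion chi-square p-value of at
least `data_tolerance` (default 1e-3; tested against 1:2:1 for `hkxhk`,
df = 2, and 1:1 on the segregating classes for the testcross patterns,
df = 1) and a progeny missing fraction of at most `missing_limit`
(default 0.2).  Neither numeric threshold is published for the original
workflow ("default parameters" of the mapping tool); both are exposed as
flags and the defaults are conventional values in the mapping community.
When a parent call is missing, the pattern is inferred only if the
progeny classes force a unique one; otherwise the marker is dropped with
reason "parent NoCall" rather than risking a silent phase error.

## Two-point engine

For each marker pair the recombination fraction r and LOD score are
estimated by maximum likelihood on the joint class counts of
pairwise-complete progeny:

* **testcross pairs** (same parent): progeny reduce to transmitted
  parental alleles; with the error model off the MLE is the closed form
  r̂ = min(R, N−R)/N over the better phase, with
  LOD = R·log10(2r̂) + (N−R)·log10(2(1−r̂));
* **intercross pairs** (`hkxhk` x `hkxhk`): the 3x3 genotype table is
  scored under all four parental phase combinations (cc/cr/rc/rr), with
  both meioses assumed to share one r;
* **mixed pairs** (testcross x `hkxhk`): only the testcross parent's
  meiosis links the pair; heterozygous offspring at the `hkxhk` marker
  are ambiguous in allele origin and contribute a constant factor.
  Opposite-parent testcross pairs share no meiosis and carry no
  two-point information (LOD 0, flagged).

Numerically, a 257-point grid scan over r in [0, 0.5] x phases brackets
the optimum and golden-section refinement localises r̂ far below 1e-6;
the grid guards against any multimodality across phases.  Dedicated
tests check the estimates against exhaustive 1e-4-grid maximisation of
independently enumerated likelihoods.

**Genotyping-error model.**  Each likelihood optionally assumes the
observed call equals the truth with probability 1−e and each other call
with probability e/2 (calls impossible under a testcross pattern are
screened out beforehand).  The pair estimators default to e = 0; the
mapper defaults to e = 0.01, matching the generator's error rate and the
error regime of array data.  Without this term the apparent
recombination between tightly linked markers is dominated by miscalls
and a map built from adjacent two-point distances inflates severely;
the established multipoint tools model call errors for the same reason.

## Grouping, ordering, positions

Markers join a linkage group by single-linkage transitive closure over
pairs with LOD > `lod_limit` (default 11; complete linkage available
behind a flag); groups with at most `min_group_size` (default 15)
markers are discarded, and retained groups are numbered by descending
size.  Pairs observed in fewer than 20 progeny are excluded from
grouping.  Markers with byte-identical informative call vectors are
binned into one locus (zero observed recombination).

Ordering and positioning are deliberately split, because the two tasks
fail differently under noise:

1. **Order** — spectral seriation (Fiedler vector of a similarity
   Laplacian built from the Kosambi distance matrix, distances floored
   at the resolution 1/(2N)) initialises a weighted one-dimensional
   metric MDS (SMACOF majorisation, weights = inverse approximate
   sampling variances of the distances).  The 1D embedding is used only
   through its rank order.  A direct 2-opt/ripple minimisation of the
   sum of adjacent distances — the textbook SARF criterion, still used
   here as the standalone `order_markers` helper for small problems —
   is not used inside the mapper: at ~1 cM marker spacing and n = 119
   the adjacent-distance noise is as large as the signal, and an
   optimiser that minimises the summed noisy distances both scrambles
   local order and underestimates length by construction.
2. **Positions** — given the order, the adjacent gap vector is fitted by
   composite maximum likelihood: every informative pair constrains the
   gaps it spans, with the pair's r expressed as the Haldane composition
   of the spanned gaps (crossovers accumulate without interference at
   the two-point level) and the same cell likelihoods as above.  The
   summed pairwise log-likelihood is maximised over the non-negative
   gaps with L-BFGS-B (analytic chain-rule gradients; per-pair dlogL/dr
   by central differences).  Reported positions are the cumulative
   Kosambi transforms of the fitted adjacent recombination fractions, so
   the output is a conventional Kosambi map.  Pooling across all pairs
   removes both the upward bias of summing noisy adjacent estimates and
   the downward bias of fitting a coordinate system to long-range
   Kosambi distances (which are not additive without interference).

`n_iterations` (default 40) caps the improvement rounds of the
refinement stage (10x that many SMACOF majorisation steps; convergence
is typically reached within ten).  Orientation is normalised so the
lexicographically smallest marker id lies in the first half.  All
tie-breaks are deterministic; for fixed input and configuration the
mapper is bit-reproducible.

The male map restricts each group to `lmxll`+`hkxhk` markers and the
female map to `nnxnp`+`hkxhk`; both reuse the pair estimates relevant to
their meioses.  For `hkxhk` pairs a single shared r is estimated for
both parents — a deliberate simplification (sex-specific recombination
would need separate male/female r in the intercross likelihood, which
two-point data at n = 119 constrain poorly).

## Homoeology and synteny

Each marker's alignment hits against the 21 wheat chromosomes (1A–7D)
are filtered at e-value 1e-5; the best hit per marker (and per
subgenome) is flagged.  A linkage group is assigned to the homoeologous
group (leading digit of the chromosome name, A/B/D pooled) receiving the
largest share of its markers' top hits; the ambiguity flag fires when
the runner-up share reaches `ambiguity_ratio` (default 0.5) of the
winner — the signature of a large interchromosomal rearrangement, as
with the 4P group whose markers split between groups 4 and 2.  The
assignment never silently overrides the argmax; external evidence can be
supplied as an explicit override table.

Collinearity blocks are maximal marker chains monotone in both cM rank
and bp rank, allowing at most `max_rank_gap` (default 3) skipped markers
in either coordinate, extracted greedily by an O(n^2) dynamic program
(longest chain, remove, repeat) and discarded below `min_block` = 5
markers.  This replaces a full anchor-scoring synteny engine, which
operates on whole-proteome pairs rather than marker hits; the chain
finder is verified against exhaustive enumeration on small instances.
Retained blocks on a non-assigned group are reported as rearrangements,
and singleton off-group hits as small-fragment noise.  For cross-genome
drawing, each mapped chromosome is linearly rescaled to 500 Mbp.

## Introgression caller

An added P chromosome pair cannot be genotyped directly; its probes
cross-hybridise with the three wheat homoeologs, raising heterozygous
calls there, while a substituted wheat chromosome raises missingness
among markers specific to it.  Per line the caller computes each
chromosome's heterozygosity ratio (AB/called, all markers), a
genome-specific missing rate, and 50 Mb / 1 Mb sliding-window
heterozygosity tracks (0-based half-open windows, last window clipped;
windows with fewer than 10 called markers flagged uninformative).

Calls are deterministic rather than visual: a chromosome is *hot* when
its ratio exceeds the line's median by `z` robust standard deviations
(default z = 5), where the spread is the MAD across the 21 chromosomes
scaled by 1.4826 and floored at the binomial sampling error of the
median rate — without that floor the MAD underestimates noise when most
chromosomes share one true rate, and rare sampling excursions become
false calls.  Hot chromosomes vote for their homoeologous group; groups
rank by (number of hot homoeologs, mean excess heterozygosity).  A
cytological chromosome count (e.g. from GISH), when supplied, fixes the
number of alien pairs called, mirroring how single and double additions
are disambiguated in practice; otherwise a group needs at least two hot
homoeologs.  A high-missingness chromosome is called substituted only
when homoeologous to a called addition; otherwise it is reported as
unexplained.  Labels follow the conventional forms ("6P/6D substitution
line", "2P addition and 1P/1A substitution line").

## Synthetic-data generator

The generator emulates the study design rather than any specific
dataset:

* **Cross** — 7 chromosomes with default lengths
  120.0/87.0/156.7/110.0/125.0/130.0/111.0 cM (total 839.7; the second
  and third values are the reported extremes of the emulated map, the
  rest sit around its 120 cM mean); 100 markers per chromosome at
  uniform positions with the 45/27/28 `hkxhk`/`lmxll`/`nnxnp` mix; 119
  progeny; crossovers per meiosis Poisson(length/100) with uniform
  positions (no interference — two-point statistics do not constrain
  interference, so the simplest process is used); genotyping error 1%
  (uniform among the two other calls); missingness 15%; optional
  transmission distortion as a per-marker skew of the heterozygous
  parent's transmitted allele (equivalent to viability selection at the
  marker level, simpler to bookkeep).
* **Hit tables** — each marker's top hit lands on a wheat chromosome of
  its true group (subgenome uniform) at a bp position proportional to
  its cM position; the default rearrangement sends the proximal 40% of
  4P to group 2; 2% of markers hit a uniformly random chromosome;
  secondary same-group hits and above-cutoff junk hits exercise the
  filter.
* **Lines** — a 21-chromosome wheat background (default 300 uniformly
  spaced markers per 600 Mb chromosome, 30% genome-specific), with
  per-marker Bernoulli heterozygosity 0.15 on homoeologs of added P
  chromosomes versus 0.01 baseline, and missingness 0.6 on substituted
  chromosomes versus 0.05 baseline.  The mechanism linking alien
  additions to elevated heterozygous calls is presumed probe
  cross-hybridisation; the Bernoulli model is a stand-in for it, not a
  claim about the biology.  The 35-line reference panel reproduces the
  published compositions of the complete wheat–*A. cristatum*
  addition/substitution series (26 single additions, 3 double additions,
  5 substitutions, 1 combined case).

The generator does not simulate array intensities, probe sequences,
tetraploid donors, interference, or linkage disequilibrium between the
introgression signal and the wheat background; passing tests therefore
demonstrate correct recovery under the stated stochastic model, not
performance on real array data, where probe behaviour is correlated
within families and error is not uniform.

All randomness flows from one integer seed through spawned
`SeedSequence` streams; every generator and the full pipeline are
byte-identical across reruns with a fixed seed.

## Problem sizes and verification

The shipped test and acceptance runs use: 7x100 markers x 119 progeny
for map recovery (exactly 7 groups required, grouping adjusted Rand
>= 0.99, per-group order Spearman |rho| >= 0.95, integrated length
within 20% of truth); 200 random instances per pair type against the
1e-4-grid oracles (agreement <= 1e-3); 2 000 unlinked null markers per
segregation family for distortion calibration (rejection within 3
binomial SE of alpha at 0.05 and 0.01); 100 hit-table seeds at a 0.65
true-group share for assignment (>= 99 fully correct) plus the 40% 4P
rearrangement flag; 500 chain instances of 4–13 markers against
exhaustive enumeration; and the 35-line panel across 10 seeds (set-exact
recovery of additions and substitutions, i.e. recall = precision = 1).
`scripts/acceptance.py` recomputes all of these from scratch for any
seed.

## Known limitations

* Two-point only: no multipoint HMM, no imputation of missing
  genotypes; order resolution within ~0.5 cM is limited by n = 119.
* Shared-r intercross likelihood: sex-specific recombination rates are
  averaged through `hkxhk` pairs.
* Integrated-map distances implicitly weight male and female meioses by
  their information content rather than by an explicit sex-averaged
  model.
* Arm-level events are visible in window tracks and bp positions but
  the calling unit is the whole chromosome / homoeologous group.
* The category classifier reproduces intensity-based categories only to
  the extent they are visible in calls; OffTargetVariant is input-only.
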