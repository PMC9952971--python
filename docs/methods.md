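# Methods

## Karyomorphometry

### Measurement model and pairing

Input is a table of per-plate arm lengths (µm) for every chromosome of
each photographed metaphase spread. Arm identity is unordered at
measurement time, so the reader orients each chromosome to
short ≤ long by default (`auto_orient`); a `strict` policy is available
when the orientation is trusted upstream.

Homologs are paired within each plate by minimizing the summed
dissimilarity

    d(i, j) = w_len · |CL_i − CL_j| / mean(CL) + w_ci · |CI_i − CI_j| / 50

over all perfect matchings (CL total length, CI centromeric index;
default weights 1 and 1, balancing the two criteria on comparable
scales — the normalizers put a typical length difference and a typical
CI difference on the same order). The optimum is found with the blossom
algorithm on exact integer weights: costs are quantized at 1e-12 and
combined with a positional penalty (base-4096 positional code over the
id-sorted chromosome list) whose total stays below one cost quantum, so
a single matching call returns the global optimum and, among co-optimal
matchings, the lexicographically smallest pairing by chromosome ids.
The quantum means costs differing by less than 1e-12 are treated as
tied; tests validate the matcher against exhaustive enumeration of all
(2n−1)!! matchings for plates up to 2n = 10.

### Aggregation and statistics

Within a plate, pairs are ranked by decreasing pair-mean length (ties
by pair ids); rank-k pairs are identified across plates as haploid
chromosome k. This is the simplest deterministic reading of averaging
"the" k-th chromosome over plates; it can swap adjacent ranks when
noise exceeds the length gap, which perturbs per-rank means slightly
but leaves complement-level statistics (CVs, M_CA, THCL) essentially
unchanged. An optional per-plate relative-length normalization
(divide by plate total, off by default) absorbs condensation
differences; it is not used for the reported absolute lengths.

Means and standard errors use the sample (n−1) standard deviation over
plates (SE = s/√n_plates, zero for a single plate); CV_CL and CV_CI
likewise use the n−1 denominator over the n haploid chromosomes. The
THCL standard error sums per-rank variances (independence
approximation). All statistics are kept at full precision internally;
the report writer rounds half-to-even to two decimals.

Levan classes use the arm ratio with boundaries inclusive on the less
symmetric class (1.7 → sm, 3.0 → st, 7.0 → t); r = 1 exactly is M,
merged into m for the karyotype formula (T into t likewise). The
Stebbins digit counts the proportion of averaged haploid chromosomes
with arm ratio ≥ 2 (1: none, 2: ≤ half, 3: more than half, 4: all);
the letter comes from R = L/S (A: R < 2, B: 2 ≤ R ≤ 4, C: R > 4).

### Packaged truth complements

Two fixed complements mirror the published comparative karyotypes of
the two *Bentinckia* species. Their arm lengths were solved offline
(least squares on the moment constraints, then frozen in
`synthetic_data.py`) so that the noiseless pipeline reproduces the
published 2n, THCL, karyotype formula, CV_CL, CV_CI, M_CA, S, L and R
to two decimals:

* condapanna-like: 15 metacentric pairs, 1.48–3.00 µm, THCL 34.04 µm
  (2n = 30, formula 15m, R 2.03);
* nicobarica-like: 9 m + 7 sm pairs, 0.91–2.30 µm, THCL 25.83 µm
  (2n = 32, formula 9m + 7sm, R 2.527 ≈ printed 2.52).

These are synthetic complements *consistent with* the published summary
statistics, not the authors' raw measurements (which are unpublished).
Two published values are intentionally not reproduced because they are
internally inconsistent with their own table: the 2n = 30 column prints
MCL 1.62 µm although THCL/n = 34.04/15 = 2.27 µm (we compute
MCL = THCL/n), and the printed Stebbins digits (4 for an
all-metacentric complement, 3 for 9m + 7sm) cannot arise from the
proportion-of-arm-ratio-≥2 rule, which caps them at 1 and 2
respectively; the stated rule is implemented as written.

### Synthetic measurement generator

Each plate draws one condensation factor ~ lognormal(0, σ_plate),
default σ_plate = 0.05 (metaphase condensation varies by a few percent
between spreads); each arm of each homolog copy is further multiplied
by an independent lognormal(0, σ) measurement error, default σ = 0.03
with 10 plates — the study conditions used throughout the tests. Noise
is multiplicative because lengths are positive and errors scale with
size. The generator does not emulate real-data features such as
overlapping or bent chromosomes, satellite loss, or systematic
operator bias, so passing recovery tests demonstrate statistical
behaviour under the stated noise model only.

Monte-Carlo behaviour under those conditions (computed by the test
suite and the acceptance script, 200 replicates): CV_CL, CV_CI and
M_CA are each recovered within ±15 % relative error in ≥ 90 % of
replicates, and each per-rank mean length falls within 3 SE of its
truth in ≥ 95 % of replicates.

## Idiogram

Chromosomes are drawn as schematic bars (not photographic karyograms),
rank-ordered, short arm up, centromeres aligned, Levan class lettered
beneath, with a 5 µm scale bar by default. All coordinates are emitted
with fixed two-decimal formatting and no timestamps, so identical
inputs give byte-identical SVG.

## Dispersal–vicariance reconstruction

Ranges are nonempty subsets of an ordered alphabet of ≤ 8 areas,
stored as bit sets. The cost model is the classic DIVA one: dispersal
(gain one area along a branch) and extinction (lose one area) cost 1
each; at a node, a single-area range duplicates into both daughters
free of charge, and a multi-area range splits by vicariance into any
ordered pair of nonempty disjoint subsets covering it, also free.
Branch lengths are ignored (parsimony); input trees must be strictly
binary, and multifurcations are rejected at parse time.

The reconstruction is a Sankoff-style dynamic program over all
nonempty subsets: for each node and candidate range X,

    cost(node, X) = min over splits (I_L, I_R) of X of
                    Σ_child min over C of [ |C \ I| + |I \ C| + cost(child, C) ]

with tip cost 0 for the observed range and ∞ otherwise. `max_areas`
optionally caps ancestral range sizes (observed tip ranges are always
allowed). The traceback marks every range occurring in at least one
globally optimal scenario, so co-optimal histories are retained, not
sampled. The DP is validated against exhaustive enumeration of all
internal-node assignments for small instances (≤ 5 tips, 3 areas).

### Consensus and S-DIVA support

The all-compatible consensus counts rooted clades (tip sets) across
the sample and adds them in decreasing frequency — ties broken by
lexicographic tip-set order — whenever compatible (nested or disjoint)
with the clades already accepted; remaining polytomies are resolved
deterministically by repeatedly joining the two children with the
smallest minimum tip labels. Clades rather than unrooted bipartitions
are used because the trees are rooted and the support stage matches
clades.

S-DIVA-style support runs the reconstruction on every sample tree; at
each reference-tree clade present in a sample tree, the tree's
co-optimal ranges share weight 1/|co-optimal set| (an even split — the
frequency semantics are not standardized, and the even split keeps
per-tree weight 1), and frequencies are normalized by the number of
sample trees containing the clade, so they sum to 1 at every supported
node. A clade absent from every sample tree is flagged "no support"
rather than zero-filled. For presentation, ranges below a threshold
(default 0.05) are lumped into `*`; the full map is retained
internally. The "Maximal S-DIVA value" statistic printed by RASP is
not reproduced: its definition is not public and it depends on the
original authors' 1332-tree sample.

### Range-evolution generator

The root starts from a configurable range (default the single area A);
along each branch, Poisson(d) dispersals each add one uniformly chosen
absent area and Poisson(e) extinctions each remove one uniformly
chosen present area, in randomized order, with extinctions skipped
when the range is a single area (a range never empties). Default
d = e = 0.05 events per branch. Yule trees are grown by uniform
bifurcation of a random tip lineage with labels assigned in seeded
random order. Under the default rates, the true simulated root range
is among the top-two supported root ranges in ≥ 70 % of replicates
(measured at 8 tips, 100 replicates).

## Problem sizes and numerical choices

The test suite and acceptance script run at desk scale, chosen as the
smallest sizes that exercise every code path meaningfully: plates of
2n ≤ 10 for exhaustive matching enumeration (945 matchings), trees of
≤ 5 tips and 3 areas for exhaustive reconstruction enumeration, 200
measurement-recovery replicates at the study conditions, and 100
range-recovery replicates at 8 tips. All generators and the
command-line interface are pure functions of (parameters, seed);
manifests carry no timestamps, so identical invocations are
byte-identical.

## Known limitations

* Cross-plate identification is by length rank only; karyotypes with
  many near-equal chromosomes blur rank identity under noise (the
  complement-level indices are robust to this, per-rank SEs less so).
* The Stebbins digit is computed on averaged haploid chromosomes, not
  per-plate values; with arm ratios near 2 the digit can differ from a
  per-plate majority rule.
* The DIVA vicariance rule allows any disjoint cover split; variants
  that restrict one daughter to a single area would give different
  co-optimal sets on wide ranges.
* S-DIVA frequencies depend on the even co-optimum weight split; other
  weightings (e.g. proportional to scenario counts) are not
  implemented.
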