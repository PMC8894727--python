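# Methods

## Model and procedure

The package scores each feature of a relational assemblage for its
contribution to ecological convergence or divergence. The relational
structure is a rooted dendrogram with nonnegative branch lengths — a
phylogeny for taxa, or a molecular characteristics dendrogram (MCD) for
organic-matter formulas — and all distances are tip-to-tip path lengths
(cophenetic distances). The community data are a sample × feature table in
one of three declared modes (counts, relative, presence).

For a feature *a* and a scope of *n* samples the observed statistic is

    bmntd_feat(a) = w_a · (1/n) Σ_j ntd(a, j)

with `ntd(a, j)` the distance from *a* to its nearest relative present in
sample *j*, and `w_a` an abundance weight. In pairwise scope the weight is
the feature's relative abundance in the focal sample and the average
degenerates to one partner term; in dataset/group scope the weight is the
feature's mean relative abundance over the scope samples where it occurs,
and the average runs over every scope sample (a sample containing *a*
itself contributes a conspecific distance of 0 when conspecifics are
allowed, mirroring the inclusion semantics of the standard nearest-taxon
implementations). The scope-aggregation choice only affects the reported
`bmntd_obs` column: any per-sample weighting multiplies observed and null
values identically and cancels in the z-score.

The null model shuffles the dendrogram's tip labels uniformly at random,
implemented as a joint row/column permutation of the cophenetic matrix
(exactly equivalent, and avoids re-traversing the tree per replicate).
Abundances are never shuffled. One shared permutation per replicate is
applied to all features, partners and groups, so values are comparable
within a replicate; with 999 replicates (the default) the z-score

    bnti_feat = (obs − mean(null)) / sd(null)

uses the sample standard deviation (ddof = 1); the exhaustive-enumeration
oracle in the test suite uses the same convention. On trees of at most 8
tips the null can instead enumerate every distinct permutation
(`exhaustive=True`), in which case no noise is added.

Classification: |z| < 1 insignificant; 1 ≤ |z| < 2 convergence (z < 0) or
divergence (z > 0); |z| ≥ 2 significant. Boundary values belong to the
higher-magnitude category; the conventional statement uses strict
inequalities on both sides and leaves equality undefined, so a tie-break
had to be fixed. Undefined z (zero null SD, or no defined comparison) is
reported as `Undefined`, never silently dropped; features missing from the
whole scope are reported `Absent`.

### Noise injection and the conspecific-everywhere quirk

Each sampled null replicate receives an additive noise term drawn uniformly
from [1e-20, 5e-20] per replicate per feature (the published range names no
distribution; uniform is the minimal reading). The noise is below
double-precision resolution relative to any nonzero distance, so it changes
nothing — except for features whose null values are exactly zero, i.e.
features present in every scope sample with conspecifics allowed. For
those, observed = 0 and null = ε, giving z ≈ −mean(ε)/sd(ε) = −√(27/4) ≈
−2.6 regardless of the data. This is a faithful consequence of the
published procedure, not a bug fix target: the package emits the value and
logs a warning identifying the affected features.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `n_null` | 999 | null replicates (tip shuffles) |
| `noise_low`, `noise_high` | 1e-20, 5e-20 | uniform noise bounds per replicate |
| `allow_conspecifics` | true | count a feature's own presence as distance 0 |
| `exhaustive` / `exhaustive_cap` | false / 8 | enumerate all permutations on tiny trees |
| scope `mode` | dataset | dataset, group, or pairwise with a focal sample |

Distances inherit the dendrogram's branch-length units. Cophenetic
distances are rooting-invariant, so no behaviour is pinned to rooting;
zero-length branches are allowed (polytomy-resolution artifacts), negative
ones rejected.

## Community-level companions

`community.py` provides the abundance-weighted community βMNTD
(½[Σ_a f_ai·ntd(a,j) + Σ_b f_bj·ntd(b,i)], cross-checked in the tests
against picante's `comdistnt` via Rscript), its z-score against the same
shared-shuffle null (without noise injection — identical-composition pairs
come out undefined and are logged), and Bray–Curtis/Jaccard dissimilarities
via scipy. The identity

    Σ_a pairwise bmntd_feat(a, i→j) + Σ_b pairwise bmntd_feat(b, j→i)
      = 2 · βMNTD(i, j)

holds exactly by construction and is asserted on random instances; it ties
the feature-level decomposition to the community metric. Ordination and
PERMANOVA are deliberately not reimplemented; the square labelled TSV
matrices are what those tools consume.

## Molecular formulas and the MCD

Derived properties follow the standard closed forms: DBE = 1 + (2C − H +
N + P)/2; AI_mod = (1 + C − O/2 − S − (N+P+H)/2)/(C − O/2 − N − S − P)
clamped to 0 for nonpositive numerator or denominator (the conventional
treatment; without it heteroatom-rich formulas give meaningless negative
aromaticities); NOSC = 4 − (4C + H − 3N − 2O + 5P − 2S)/C, equivalent to
per-atom oxidation-state assignment in a neutral molecule (the test-suite
oracle); Kendrick mass = mass·14/14.01565 with defect = round(KM) − KM (a
`floor` convention is available via `--kendrick-convention`). Isotopes and
charge are out of scope; masses are treated as neutral monoisotopic.

Van Krevelen compound classes are rectangular O/C–H/C regions read from an
editable TSV (first matching row wins, overlaps are warned about); the
packaged default is the widely used eight-class set (lipid … condensed
hydrocarbon). No numeric boundary is hard-coded in logic because published
boundary sets are versioned.

The MCD standardizes a configurable property set (default: the six element
counts, O/C, H/C, DBE, AI_mod, NOSC, Kendrick defect; constant or undefined
properties are dropped with a warning), takes Euclidean distances and UPGMA
(average linkage) agglomeration, and emits a dendrogram whose tip-to-tip
distances equal the merge heights (child branch length = (parent height −
child height)/2), hence ultrametric and byte-deterministic given input
order; the exact recipe of the original MCD lives in unpublished
configuration, so the property list and linkage are exposed rather than
guessed.

## Co-contribution networks

Pairwise-mode z-profiles over a common partner set are Pearson-correlated
feature-by-feature (features with missing entries are excluded — a missing
z is information, imputation is refused). A signed soft-threshold adjacency
a = ((1+r)/2)^power (default power 6; unsigned |r|^power optional), the
dissimilarity 1 − a, average-linkage clustering and a flat cut at
`cut_height` yield modules; modules smaller than `min_size` (default 3) are
dissolved, which removes doublets. This is a documented simplification of
full weighted-correlation network analysis: no topological overlap matrix
and no dynamic tree cut, because the reference analysis does not report its
parameters and a faithful reproduction is not claimable. Note the geometry
of the defaults: a cut at height c merges profiles correlated at
r ≥ 2(1−c)^(1/6) − 1, so the default 0.25 demands r ≈ 0.91 — the planted
two-block tests therefore cut at 0.35 (r ≈ 0.86), matched to blocks planted
at r ≈ 0.9. Module statistics: Shannon H over member taxa's mean relative
abundances renormalized within the module, exp(H), Pielou J = H/ln(richness)
(undefined for singletons, never zero), distinct taxonomic Orders, and
elemental-composition proportions over formula members.

## Synthetic data: what it emulates and what it does not

`synthetic.py` generates Yule trees (pure-birth via dendropy, exponential
branch lengths), neutral communities (per-feature Bernoulli occupancy
independent of the tree, log-normal abundances, empty samples redrawn and
logged), selection scenarios, and chemically plausible formula tables
(element ranges typical of high-resolution MS assignments, rejecting DBE <
0 and H > 2C + 2 + N; masses neutral monoisotopic).

Two selection regimes plant known truth:

* `clade_filter` boosts a monophyletic clade's per-sample occupancy toward
  1 (occ′ = occ + s(1−occ)); clade members then co-occur in nearly every
  sample and each member's nearest relative is consistently a close sibling
  — expected convergent. When a fraction rather than an explicit tip set is
  given, the generator picks the most phylogenetically *compact* clade of
  about that size: the scenario models a conserved niche, and a conserved
  niche clade is a compact one.
* `group_contrast` confines one clade to one half of the samples and a
  disjoint clade to the other half; members of each clade are far from
  everything present on the opposite side — expected divergent. Here the
  generator picks the most *isolated* clades (largest minimum cophenetic
  distance to any outside tip), i.e. distinct lineages.

At selection strength 0 both regimes reduce exactly to the neutral
generator. Selection acts on occupancy, not abundance, because the z-score
is abundance-invariant under this null — abundance-based selection would be
undetectable by design.

What passing these tests shows: the statistic is calibrated under
tree-independent assembly (pooled mean z ≈ 0, ≈5% of |z| > 2 at the 2σ
threshold) and detects occupancy-mediated selection on compact/isolated
clades with ≥80% power at strength 0.9. What it does not show: behaviour
under compositional (relative-abundance) selection, phylogenetic signal in
abundances, sequencing noise, or the sample sizes and effect structures of
real survey data.

## Problem sizes and numerical choices

The calibration harness uses 200-tip trees, 20 samples, occupancy 0.5, 999
nulls, pooled over 5 seeds; the power harness uses 120-tip trees, 30
samples, background occupancy 0.25, a ~10% target clade at strength 0.9,
999 nulls, 5 seeds per regime. These sizes were fixed by a design-stage
power analysis and are the package's standard demonstration conditions.
Null means/SDs are computed two-pass over stored replicate values, so a
constant nonzero null gives an exact SD of 0 (→ Undefined) rather than
catastrophic-cancellation garbage. Permutations and noise derive from a
single seeded generator; there is no global random state. Table/tree
feature sets are aligned explicitly (`harmonize`), with pruning opt-in and
logged; table orientation is declared, never guessed from shape.

## Known limitations

* Dataset/group `bmntd_obs` magnitudes depend on the scope-aggregation
  convention (the z does not); comparisons of raw `bmntd_obs` across tools
  should expect constant per-feature factors.
* The conspecific-everywhere z ≈ −2.6 is an artifact of the published
  noise-injection procedure and is reproduced, flagged, and documented, not
  corrected.
* Module detection is a simplified weighted-correlation pipeline; module
  counts are not comparable to full WGCNA results.
* FTICR spectral processing, formula assignment, 16S read processing, tree
  inference, ordination and PERMANOVA are out of scope; the package
  consumes and produces the standard text formats those tools use.
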