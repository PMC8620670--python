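# Methods

## The analysis

The package takes two inputs: a species checklist (CSV; one row per alien
species with family, genus, lifeform, TDWG level-1 origin region(s),
introduction pathway and invasion status) and a rooted phylogeny with
branch lengths (Newick) covering the checklist species. From these it
produces categorical tabulations, per-family stage-transition rates,
per-assemblage NTI values, a between-assemblage nearest-taxon distance
matrix and its PCoA.

### Status algebra

The status column records only the *highest* attained stage
(casual < naturalized < invasive). The five analysis assemblages are
derived: alien = all species, naturalized = status ∈ {naturalized,
invasive}, invasive = status invasive, casual = alien \ naturalized,
NNI = naturalized \ invasive. Storing one stage and deriving the nested
sets makes the invariants (invasive ⊆ naturalized ⊆ alien; the two
partition identities) true by construction; they are nevertheless
re-checked on every `AssemblageSet` construction and property-tested on
random checklists.

Tabulations count each species once per category, except origins: TDWG
regions are not exclusive for a species, so a species contributes one count
to *each* of its regions and origin proportions may sum to more than 1
(denominator = assemblage size throughout). Transition rates are plain
ratios; a rate whose denominator is zero is reported as undefined (`None`),
never as 0. Reports render percentages to one decimal; all CSV output keeps
full precision.

### Patristic distances, MNTD, comdistnt

All phylogenetic statistics are functions of the dense patristic matrix
(tip-to-tip path length, in the tree's branch-length units, typically Myr).
The matrix is built in one postorder pass with vectorized outer sums —
O(n²) time and memory, ~23 MB at 1700 tips — and is the module's contract;
polytomies need no special handling. Missing branch lengths are a hard
error (never silently zero). Checklist names are matched to tips exactly
after replacing spaces with underscores; unmatched species are dropped with
a logged count, and the pipeline aborts if more than 20% of any assemblage
would be dropped (configurable).

MNTD is the mean over assemblage members of the distance to the nearest
other member. `comdistnt` is its two-sample analogue: each taxon of either
set is matched to its nearest taxon in the *other* set and all |A|+|B|
values are averaged (abundance-unweighted). Because the stage assemblages
are nested, shared species contribute distance 0 and pull between-stage
values toward 0; this matches the default of the standard implementation of
this statistic, so conspecifics are **included** by default, the
`exclude_conspecifics` flag reroutes shared taxa to the other set minus
themselves, and the pipeline logs which mode was used.

### The NTI null model

NTI = −(MNTD_obs − mean(MNTD_null)) / sd(MNTD_null), where the null holds
species richness fixed: assemblages are uniform without-replacement draws
of the observed richness from the reference pool (all alien species).
Choices that the formula itself does not pin down:

- **Sd estimator:** sample standard deviation (n−1), the convention of
  standard SES implementations.
- **Draw count:** 1000 by default. When C(|pool|, richness) ≤ 10,000 the
  null is enumerated exhaustively instead (`mode="auto"`); Monte-Carlo NTI
  converges to the exhaustive value, which brute-force enumeration verifies
  on small trees to 1e-9.
- **Degenerate null:** when the assemblage *is* the pool, every
  richness-preserving draw reproduces the pool and the null sd is 0. NTI is
  then flagged undefined (NaN plus a diagnostic) — never ±inf or a silent
  0. A bootstrap-with-replacement null is available
  (`degenerate_pool_mode="bootstrap"`) and yields a finite value near 0,
  consistent with reading the full alien pool as "random by definition".
- **Sub-seeds:** each assemblage uses master seed + its stable index
  (alien 0 … invasive 4), so adding or removing one assemblage does not
  shift the others' draws. All outputs are bit-reproducible under a fixed
  seed.

Sign convention: positive NTI = observed MNTD *below* the null mean =
clustering; negative = overdispersion; zero = random. Calibration: the mean
NTI of uniformly drawn assemblages is 0 in expectation (the observed draw
and the null draws are exchangeable), and NTI is invariant under global
branch-length scaling since numerator and denominator scale together.

### PCoA

Classical scaling: Gower double-centering of −½d², symmetric
eigendecomposition, coordinates = eigenvectors × √λ for positive
eigenvalues (relative cutoff 1e-10). Nearest-taxon distances between
nested assemblages are generally non-Euclidean, so negative eigenvalues can
occur; they are dropped from the coordinates, excluded from the variance
denominator, and their summed magnitude is reported — no Cailliez/Lingoes
correction, matching the default of standard classical-scaling routines.
Axis signs are fixed by making each axis's largest-magnitude coordinate
positive, so output is fully deterministic. One subtlety: duplicating a
point adds a zero eigenvalue and coincident coordinates but *does* shift
the variance fractions, because the duplicate reweights the centroid of the
Gower centering — the tests assert the former, not fraction invariance.

## The synthetic generator

`synthetic_data` stands in for the real checklist and mega-tree:

- **Tree:** Yule (pure-birth) process conditioned on tip count, with a
  final exponential hold so terminal branches are positive; ultrametric by
  construction. Chosen as the simplest tree prior with known properties —
  adequacy is for testing statistics, not biological realism. Default
  birth rate 1.0 (time units are arbitrary; every statistic downstream is
  either scale-invariant or reported in branch-length units).
- **Stage membership:** nested sampling — alien from all tips, naturalized
  from alien, invasive from naturalized — mirroring the
  introduction–naturalization–invasion continuum. Each stage uses
  `sample_clustered`: the first member uniform, each later member with
  probability ρ the unchosen pool taxon nearest to the chosen set (ties by
  label order) and otherwise uniform. ρ=0 is exactly uniform sampling;
  defaults ρ(alien)=0, ρ(naturalized)=0.3, ρ(invasive)=0.8, so invasive
  species are strongly clade-biased and the qualitative NTI ranking
  (invasive most clustered) holds by construction. `sample_overdispersed`
  (greedy maximin, ties by label order) is the negative-NTI control.
- **Sizes:** 1686 alien / 1198 naturalized / 232 invasive by default — the
  scale of the national checklist the package targets, from which casual =
  488 and NNI = 966 follow.
- **Taxonomy:** families and genera are clades cut at 0.6 and 0.9 of tree
  height; on a ~1700-tip Yule tree this yields on the order of 10² families
  and several hundred genera, and makes family structure correlate with
  phylogeny as in real floras (the genus cut is deeper, so genera nest in
  families).
- **Composition:** lifeform, pathway and origins are i.i.d. categoricals
  per highest stage. Invasive lifeform defaults are the reported invasive
  marginals (annual 0.621, perennial 0.263); casual/NNI values are
  back-solved so the aggregate alien marginals land on ~33.6% annual /
  ~49.0% perennial at the default sizes. Pathways are set analogously:
  ~56.5% of aliens ornamental, ~16.7% introduced by other means
  (unintentional/natural/unknown), and invasives split roughly half
  economic (ornamental+forage+medicinal ≈ 55%) / half other means. Origins:
  a species draws a primary region and, with probability 0.2, a second one;
  the primary categoricals are calibrated (fixed-point solve, done once) so
  the per-region *inclusion* shares — what the tabulation counts — land on
  the reported values, America 57.8% and tropical Asia 3.9% among
  invasives. Only some of these marginals are reported for the real flora;
  the remainder are single fixed choices of plausible values, not fitted
  quantities.

What the generator does **not** emulate: real taxonomic imbalance beyond
clade cuts, biogeographic structure in origins, trait evolution,
correlations between pathway and phylogeny, or name-matching noise between
checklist and tree. Passing tests therefore demonstrate that the statistics
and pipeline are correct and calibrated on data with known structure — not
that any particular biological conclusion about a real flora is true.

## Problem sizes in tests and the acceptance script

Simulation-based checks use sizes chosen to make sampling error small while
keeping the default suite fast: null calibration on a 200-tip tree (200
assemblages of 30, 1000 draws each); sign recovery over 100 replicates
(k=20, 200 tips); brute-force agreement on 1000 random trees of ≤ 10 tips;
end-to-end ranking over 50 replicates at 250 tips (stage sizes 200/100/30,
200 draws); study-scale composition at the full 1686 tips averaged over 10
generator seeds. The acceptance script repeats these measurements from
scratch under a caller-supplied seed.

## Known limitations

- The dense patristic matrix is O(n²) memory; fine to ~10⁴ tips, not for
  megatrees of 10⁵+ tips.
- `comdistnt` between nested assemblages is dominated by shared species
  under the default mode; use `exclude_conspecifics` to measure distances
  among distinct members, and expect non-Euclidean PCoA input either way.
- The bootstrap resolution of the degenerate pool-vs-pool null is a
  pragmatic alternative, not a statement that its SES is the "right" value
  for the pool.
- Checklist validation enforces closed vocabularies for lifeform, pathway,
  region and status; genuinely new categories require extending the maps
  (lifeform synonyms are user-overridable at read time).
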