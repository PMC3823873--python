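# Methods

`barcodegap` re-creates, as a tested pipeline, the retrospective style of
DNA-barcoding evaluation: score specimen identification and species
discovery against a *historic* taxonomy (what a morphology-only
classification once recognised) and a *current* one (what integrated
taxonomy recognises today), and ask what each identification method would
have got right.  Because the interesting failure modes — lumped species
complexes, recent radiations, mitochondrial capture after hybridisation —
are properties of the data, the package ships a simulator that generates
alignments with exactly those properties and known truth, so every stage
can be validated end to end without any sequence download.

## Distances

Pairwise divergence is the Kimura 2-parameter (K2P) distance

    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)

with P and Q the proportions of transition (A↔G, C↔T) and transversion
differences over the comparable sites.  Sites with a gap or IUPAC
ambiguity in either sequence are deleted pairwise (the MEGA distance-table
convention), so `n_sites` varies by pair.  A pair for which either log
argument is non-positive is *saturated* and raises an error rather than
being clamped: a silently capped distance would distort every overlap
statistic downstream.  Distances are substitutions/site internally;
percentages appear only in reports.

## Barcoding-gap statistics

Distances are pooled into intraspecific and interspecific sets under a
chosen taxonomy scheme.  The *global* gap diagnostics follow the
total/90% overlap convention: the overlap interval runs from the smallest
interspecific to the largest intraspecific distance; the 90% variant
first discards the top 5% of intra and bottom 5% of inter values **by
count (ceiling)** — not by interpolated percentile — and the "% of
observations" is the share of *all* pooled distances (intra ∪ inter,
untrimmed) inside the closed interval.  With `upper <= lower` the overlap
is reported as width 0 and 0% observations.  The *local* gap table
compares each species' maximum intraspecific distance with its
nearest-neighbour distance (minimum over its specimens to any
heterospecific specimen); singletons have max-intra 0 and hence a local
gap by construction.

Two data-driven thresholds are provided.  The 10×-mean-intraspecific rule
is exactly that.  The barcode-gap partitioner is a simplified
re-derivation of the automatic-barcode-gap idea: for each prior maximum
intraspecific divergence `p` on a log grid (defaults 0.001–0.1, 20 steps,
gap-width multiplier X = 1.5), scan the sorted pairwise distances for the
first gap wider than `X·p` that extends above `p` *and* actually
disconnects the single-linkage graph cut at its midpoint; split, recurse
within groups, and report the group count.  Each prior's reported
threshold is the boundary implied by its final partition (midpoint
between the largest within-group and smallest between-group distance) —
under single linkage any cut in that interval reproduces the partition,
whereas the raw scan gap can sit spuriously low when a sparse
intraspecific tail isolates one extreme pair.  The consensus is the range
of these thresholds over the priors yielding the modal group count;
priors that find no qualifying gap are a failure state and do not vote.
Exact parity with the original ABGD server is not claimed; at priors far
below the true intraspecific depth the recursion over-splits, which is
the known behaviour of this family of methods.

The between-taxonomy comparison of intraspecific divergence is a one-way
fixed-effects ANOVA (delegated to `scipy.stats.f_oneway`) on species-level
*mean* intraspecific distances; singletons contribute no intra distances
and are excluded from those means.

## Trees

Neighbour joining follows the Saitou–Nei Q-criterion agglomeration.  Two
determinism rules: Q-ties are broken by the lexicographically smallest
pair of cluster representatives (the minimal leaf id in each cluster),
and negative branch lengths are clamped to zero with the deficit moved to
the sister edge — downstream identification consumes clades, not signed
lengths.  On additive matrices the output path lengths reproduce the
input exactly (this is tested to 1e-10, and cross-checked against
scikit-bio's independent implementation).  Bootstrap support resamples
alignment columns with replacement, rebuilds matrix and tree per
replicate, and scores each original internal bipartition by the
percentage of successful replicates containing it; replicates that
produce a saturated pair are skipped and counted.

## Identification methods

All methods evaluate leave-one-out: a query's own record never serves as
its reference.  Threshold comparisons are closed (d = t counts as
within).

* **Best match** — nearest reference(s); a tie spanning several species is
  ambiguous.
* **Best close match** — best match, but no_match when the nearest
  reference lies beyond the threshold.
* **All species barcodes** — every reference within the threshold must be
  conspecific; a mixed neighbourhood is ambiguous, a purely wrong one a
  misidentification, an empty one no_match.
* **Distance to exemplar** — nearest designated species exemplar; beyond
  the threshold the query is flagged as a candidate new species.  Exemplar
  specimens are not scored by default (their self-distance of zero is
  uninformative); pass `exemplar_queries="self_excluded"` to score them
  against the other exemplars instead.
* **NJ tree-based** — the published criteria table for this method was not
  available, so the rules here are a documented reconstruction and are
  frozen as follows.  The tree is midpoint-rooted.  For a query, let A be
  the maximal ancestor clade containing no exemplar, and S the set of
  exemplar species entering at A's parent.  S = {query's species} →
  success.  |S| ≥ 2 → ambiguous.  S a single other species → if A is
  *pure* (all its leaves share the query's label) the query-clade is
  sister to, not inside, foreign material: ambiguous, flagged
  `candidate_new`; if A is impure (the query nests among heterospecific
  specimens, the introgression signature) → misidentified.  The purity
  distinction is what lets the same rule flag an unsampled species as new
  while convicting a captured mitochondrion.

## Scoring against truth

Outcomes are produced under the evaluated scheme and then audited against
the truth scheme.  A flagged query (no_match, or ambiguous with the
`candidate_new` flag) is *correctly flagged (new)* when its truth species
has no reference in the evaluated dataset and is outside any recorded
complex; *correctly flagged (known complex)* when its truth species
belongs to the expansion of a lumped label (the complex map, derivable
from the paired label columns plus an explicit `part_of_complex` column
for members absent from the lumped scheme); *incorrectly flagged* when
its truth species had a reference after all.  Counts are primary;
percentages are always recomputed from counts and rounded only in
rendered reports.

Species discovery restricts the references to specimens already known at
the historic baseline and queries the later discoveries.  Grouped new
forms of existing species are correct; grouped new taxa are incorrectly
lumped; flagged new taxa are correct (as complex members when the
reference scheme records the complex); flagged new forms are incorrect.

## The simulator

The generator produces the study conditions, not a tuning surface.  The
substitution process is a continuous-time two-parameter model (transition
rate α, transversion rate β, κ = α/β = 4 by default, overall rate 1
substitution/site per unit branch length) — precisely the process the K2P
estimator assumes, so the estimator is unbiased on its own generator and
estimator/generator matching is itself a test.  Genealogies are star
approximations: each specimen evolves independently for `intra_depth/2`
from its population's ancestral sequence, so expected pairwise
intraspecific divergence equals `intra_depth`.  Real genealogical
structure (coalescent correlations), rate heterogeneity among sites and
indels are deliberately absent: only the distance *distributions* matter
to the methods under test, and passing on these conditions shows the
logic of every stage, not robustness to alignment error or heterotachy.
An optional codon screen (off by default) resamples any branch whose
child sequence would carry an internal stop under the vertebrate
mitochondrial code.

Three presets define the bundled conditions.  `gapped`: 20 species × 5
specimens, 2% intraspecific depth, 10% between species — a textbook
global gap.  `skink_current` is a 246-specimen world with 650-bp
sequences shaped like a recent island radiation under its current
taxonomy (26 species): a six-species radiation at ~1.2% interspecific
divergence; four historic "species" that turned out to be one (merged
into a single current species); three deep complexes (~16% internal
divergence) that the historic scheme lumped, one harbouring a newly
discovered third member; one hybridising pair (6% apart) with two
recipient specimens carrying captured donor mitochondria; eight
well-separated species of sizes 1–20 (including singletons) with
realistic intraspecific depths (0.4–2%); and two new taxa plus two new
forms discovered after the baseline.  `skink1977` is the same world
restricted to the 228 specimens labelled under the 23 historic labels.
Branch depths were chosen so the historic scheme shows near-complete
intra/inter overlap (the lumped complexes' internal divergence rivals the
between-group distances, most of which exceed the widest 10% threshold)
while the current scheme retains only partial overlap — the qualitative
signature the retrospective design depends on.  All preset values were
fixed at design time from these structural requirements.

## Numerical and reporting choices

Problem sizes throughout (246-specimen world, 100-specimen gapped
condition, 20-seed partitioner sweep, ≤100 bootstrap replicates in the
analysis drivers) were chosen as the smallest at which every structural
signal is unambiguous; `analysis/03_build_trees.py --reps` raises the
bootstrap effort when publication-grade supports are wanted.  Exact
distance ties (identical sequences) are preserved as ties, which is how
ambiguous best matches arise.  `scripts/acceptance.py` seeds every source
of randomness from its `--seed` argument and recomputes all reported
quantities at run time.

## Known limitations

The NJ identification criteria are a reconstruction (see above) and must
not be changed silently.  The gap partitioner is a re-derivation, not a
port.  Deep lumped complexes "succeed" under the NJ and nearest-match
methods when scored against the lumped scheme itself — the closest-match
fallacy; only the neighbourhood-purity method and the flagging categories
expose them, which is the central contrast the pipeline measures.  The
simulator's star genealogies understate within-species distance variance
relative to a coalescent, so absolute percentages on real data will
differ; the pipeline's claims are about orderings and contrasts, which
are stable across seeds.
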