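# Methods

## The two-lineage model of twinning

Post-zygotic early embryonic mutations (EEMs) accrue at a roughly constant
rate per cell division and are stably inherited, so each one marks the
clade of cells descending from the division in which it arose. In a
monozygotic twin pair, write L1 and L2 for the two earliest ancestral cells
whose descendants make up the twins' somatic tissues, and (a, b) for the
fraction of Twin 1's and Twin 2's soma derived from L1, with Twin 1
labelled so a ≥ b. Heterozygous EEMs carried by L1 then appear at VAFs
(a/2, b/2) in (Twin 1, Twin 2) VAF space — the anchor cluster, with summed
VAF (a + b)/2 ≥ 0.5 since L1 is the dominant lineage — and EEMs carried by
L2 at ((1−a)/2, (1−b)/2), the point reflection of the anchor through
(0.25, 0.25). Two identities follow and are exact: the midpoint of the two
clusters is (0.25, 0.25) for every (a, b), and 2·v(anchor) + 2·v(counter)
= 1 in each twin. Pre-zygotic de novo variants are heterozygous in every
somatic cell and sit at (0.5, 0.5).

The categories are regions of (a, b) space: para-identical (a = 1, b = 0),
sub-identical (a = 1, 0 < b < 1), full-identical (a ≈ b < 1). They do not
tile the space, so the classifier emits a fourth label, `discordant`, for
fits with a < 1 − ε and |a − b| > 2ε rather than forcing a label onto a
poor fit. The boundary tolerance ε (default 0.10) is a free parameter
reported with every call; no principled value exists because the boundaries
("a = 1", "a ≈ b") are idealizations.

## Estimation

EEM VAF pairs are clustered by agglomerative average linkage in 2-D VAF
space, cut at `link_radius` (default 0.05, comfortably above the VAF
standard error at 700x, ≈0.017). Average linkage is used deliberately:
single linkage chains the quasi-continuum of private and subclonal EEMs
into the anchor cluster and dissolves it. Single-EEM clusters count
(`min_cluster_size` = 1): at targeted depth a singleton is informative, and
real counter-anchors can consist of one mutation.

The anchor/counter-anchor pair is selected by searching all cluster pairs
for the best match to the identity anchor + counter = (0.5, 0.5), accepted
within `symmetry_tol` (default 0.10). Candidacy carries a noise margin of
`symmetry_tol`/2 on the sum rule because a para-identical anchor sits
exactly on the a + b = 1 boundary. When both clusters are present, (a, b)
is the size-weighted average of the anchor reading (2v₁, 2v₂) and the
counter reading (1 − 2u₁, 1 − 2u₂). Two fallbacks handle missing
witnesses:

* **Composite anchor.** If no single cluster passes the sum rule (the L1
  cell acquired no detectable mutation), two sub-threshold clusters whose
  centroid *sum* pairs symmetrically with a counter candidate stand in for
  the anchor — carrier fractions are additive over disjoint daughter
  lineages. The match threshold is halved because composites have more
  ways to fit by chance.
* **Unpaired evidence.** If an anchor exists but no counter pairs with it,
  the estimate uses the anchor alone; counter candidates that cannot pair
  are ambiguous deep sublineages and are excluded (see Limitations).
  Conversely, with no anchor at all, the strongest counter candidate
  (largest summed VAF ≥ 0.1 — lower sums are deep-sublineage scatter)
  carries the fit alone.

Genetic distance between co-twins counts EEM events detected in exactly
one twin. In the pipeline this uses a near-clonal threshold (targeted VAF
≥ 0.2, i.e. cell fraction ≥ 0.4): at the discovery threshold the count is
dominated by deep subclonal mutations whose apparent twin-uniqueness is an
artifact of finite progenitor sampling, and the biological ordering across
membrane types inverts. Founder timing divides the count of unique clonal
mutations by the per-division rate (default 1.2), rounding to the nearest
integer, or flooring for "at least" statements.

Variant classification follows the trio logic: parent-present → inherited;
parent-absent with VAF ≥ 0.3 in every sibling → de novo; parent-absent with
a detection (alt reads ≥ 3 and VAF ≥ 0.03) in ≥ 1 sibling → EEM; otherwise
unresolved. Classification runs on the 60x discovery counts and the
de-novo/EEM boundary is then re-evaluated on the 700x validation VAFs
(`refine_with_targeted`): at 60x, a variant clonal in both twins dips below
the 0.3 rule in one sample about once per thousand observations — frequent
enough, over ~100 clonal sites per family, to plant spurious anchors.

Cord-blood chimerism: an EEM clonal in exactly one twin's buccal tissue
(VAF ≥ 0.4) and absent in the co-twin's (≤ 0.02) marks that twin's
hematopoietic lineage. A blood sample whose cells are a fraction m from
the Twin-2 lineage shows Twin-2 markers at expected VAF m/2 and Twin-1
markers at (1 − m)/2; m is estimated by maximizing the binomial read-count
likelihood on a 10⁻³ grid with golden-section refinement, expected VAFs
clamped to [seq_error/3, 0.5], and a 95% profile-likelihood interval at a
log-likelihood drop of 1.92. Estimates are reported per cord-blood sample;
a pooled-likelihood mode is also provided since monochorionic bloods come
from one mixed pool.

Single-cell reconstruction uses the per-site observation model
P(missing) = λ, P(alt | alt) = (1−λ)(1−α), P(ref | alt) = (1−λ)α,
P(alt | ref) = (1−λ)·fp (defaults α = 0.23, λ = 0.46, fp = 0.01; fp is a
conservative guess — MDA false-positive rates are poorly constrained).
Clades are seeded with the bulk anchor/counter marker sets (re-validated
against the cells: a marker co-occurring with the opposite set beyond the
99th percentile of the false-positive binomial is dropped and re-placed by
recursion) or, without a bulk fit, with the two most prevalent mutually
exclusive variant groups. Each cell goes to the clade maximizing its summed
log observation likelihood; cells with a score gap under one log-unit are
labelled `ambiguous` rather than forced. The search recurses greedily
within clades — the analysis targets L1/L2 and their immediate
sublineages, not a full error-tolerant perfect phylogeny.

Multi-tissue refinement clusters EEMs on their VAF profile across ≥ 3
samples (correlation distance, average linkage, cut at 0.3 — nested
parent/child lineages separate at distance ≈ 0.4–0.5 while same-origin
EEMs stay below ≈ 0.2 even at 24x). Flat profiles get distance 0 to each
other and 1 to varying ones, since correlation is undefined there.
Clusters are nested by containment of their detection patterns and emitted
as a Newick tree. Triplet topology joins the pair sharing the most clonal
EEMs first; in each sub-identical pair the pure (a = 1) member is the
nested, later-founded individual, and contradictory nesting is flagged
`unresolvable` rather than guessed.

Cohort statistics are implemented from first principles: the exact 2×2
Fisher test enumerates the hypergeometric table range (two-sided by the
probability-mass rule by default; the doubled-one-tail convention is
switchable since printed two-sided values differ between conventions); the
r×c Monte Carlo Fisher test samples fixed-margin tables by random
relabelling — permuting the column-label vector reproduces the
multivariate hypergeometric null exactly — and uses the add-one estimator
(1 + hits)/(B + 1); the Kruskal–Wallis H statistic carries the standard
tie correction with a guard returning (H = 0, p = 1) when every
observation ties. Pairwise follow-ups are Bonferroni-adjusted.

## The simulator

The embryo grows as a complete binary division tree to `n_generations`
(default 12, ≈4,096 leaf cells); each daughter cell acquires
Poisson(1.2) new EEMs at birth, and the zygote carries 68 de novo
variants. Sites are drawn uniformly from a 3.0 Gb virtual genome (23
chromosomes), so independent zygotes collide with negligible probability.
Twinning partitions one generation: para-identical pairs take the two
daughters of a random ancestor one generation above the split (their
lineages segregate completely, and each founder carries its root-path
mutations privately); sub-identical pairs bud a single founder cell while
the co-twin keeps every other contemporaneous cell; full-identical pairs
partition the generation at random with a given Twin-1 share, or build
founder sets realizing requested (a, b) exactly. A triplet is two
consecutive sub-mode events. Tissues are founded by progenitor
bottlenecks sampled from the twin's leaf cells (defaults: 32 for buccal
and cord blood, 8 per placental patch — the real effective progenitor
numbers are unknown, and these are recorded in the truth file). Sequencing
draws Poisson depths (60x discovery, 700x validation, 30x parents) and
binomial alt counts with substitution error 10⁻³ split equally among the
three non-reference bases. Monochorionic cord bloods are exact linear
mixtures of the twins' hematopoietic pools with the major contributor
drawn uniformly from 56–83%; dichorionic bloods do not mix. Single-cell
readouts apply the dropout model above to true leaf genotypes.

The default cohort is 8 MCMA + 7 MCDA + 7 DCDA monozygotic pairs, one
DCTA triplet and 6 dizygotic controls, with clonal categories assigned
deterministically per membrane type (MCMA: 7 full + 1 sub; MCDA: 2 para +
4 sub + 1 full; DCDA: 1 para + 5 sub + 1 full) so that every simulated
cohort reproduces the 3/10/9 composition and its association with
amnionicity. Identical seeds give byte-identical outputs.

What the generator does not emulate: chromatin- or replication-timing-
dependent mutation placement, trinucleotide contexts, mapping or
alignment artifacts, copy-number changes, contamination, parental
mosaicism, and cell death/lineage extinction (every simulated lineage
survives). Passing recovery tests therefore demonstrates correctness of
the estimators under the stated generative model, not robustness to
artifacts real pipelines must handle upstream.

A separate direct generator (`simulate_pair_vafs`) emits EEM read counts
straight from the two-lineage geometry with exact control over (a, b) and
cluster sizes; parameter-recovery studies use it because the tree
simulator's per-node Poisson mutation counts cannot guarantee a fixed
anchor-cluster size.

## Numerical and design choices

* Missing VAF (depth 0) is distinct from VAF 0 everywhere.
* Mixing likelihoods clamp expected VAFs to an error floor of seq_error/3
  to avoid zero-probability degeneracy; the likelihood is unimodal in m
  (verified numerically), so grid + golden-section refinement is exact to
  grid resolution.
* Anchor-selection ties break toward larger clusters, then lower Twin-1
  VAF variance; all tie-breaks are deterministic, making fits invariant to
  input order.
* Allelic dropout applies to the variant allele only (a true het reads as
  hom-ref with probability α).
* Observation-model log-probabilities use a hard floor (~e⁻⁶⁹⁰) instead of
  −∞ so score gaps stay finite when fp = 0.
* The Monte Carlo Fisher null calibration in the acceptance suite uses
  margins (20, 20, 20) × (20, 20, 20): rich table support keeps the
  discrete p-value near-uniform.

## Problem sizes

The test and acceptance suites run the recovery studies at 200 replicates
(anchor-model grid, chimerism, single-cell assignment), cohort-level
checks at 3–10 seeded cohorts of the default 29 families, and the Monte
Carlo calibration at 2,000 null tables × B = 1,000; the full suite
completes in about a minute on one CPU.

## Known limitations

* **Para/sub identifiability.** A sub-identical pair whose first few path
  ancestors carry no detectable EEM presents exactly the geometry of a
  para-identical pair missing one founder's cluster; the fit reports para
  (the anchor-only reading) in roughly 7% of simulated sub pairs. Real
  data has the same blind spot — sharing cannot be seen without a mutation
  witnessing it.
* **Boundary discordance.** With 32-progenitor tissue bottlenecks the
  realized |a − b| of a full-identical pair fluctuates by ~0.1, so pairs
  near the 2ε boundary are genuinely discordant at tissue level; cohort
  category recovery against tissue-level truth is ~0.86, dominated by
  these two effects plus pairs whose L1 and L2 are both EEM-free (~9% of
  full pairs).
* **Chimerism clonality assumption.** Informative EEMs are assumed fully
  clonal in the source twin's hematopoietic pool; bottleneck-induced
  subclonality biases m̂ by up to a few percent in cohort simulations
  (controlled-generator recovery is within 0.05 in > 90% of runs).
* A fully clonal EEM present in both twins is indistinguishable from a de
  novo variant by VAF alone and is labelled de novo.
* Bulk fits resolve only L1/L2 and near-ancestral structure; downstream
  lineage decomposition needs the single-cell or multi-tissue modules.
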