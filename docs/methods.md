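# Methods

## Marker detection

Candidate proteins are compared to a reference panel (one or more
well-described sequences per enzyme family: NarG, NarH, NirK, NirS,
Nor/qNor, NosZ) by exact global alignment with affine gaps (Gotoh
three-state dynamic programme). Scoring defaults are match +1,
mismatch 0, gap open −10, gap extend −1 (a gap of length L costs
−10 − (L−1)); they are exposed as parameters, but the acceptance
decision consumes only percent identity, not score, so moderate changes
to the scoring do not move the decision boundary for substitution-only
homologs. End gaps are penalised (true global alignment); identity is
matches / alignment columns with terminal-gap overhang columns excluded
from the denominator, so a domain fragment aligned to a full-length
reference is judged on the region it covers rather than being diluted
by overhang. Alternative denominators (query length, subject length)
would make the statistic asymmetric; the overhang-excluding column
count keeps identity symmetric, which the test suite asserts.

A hit is accepted when identity ≥ 0.65, threshold inclusive, with the
comparison performed on the exact rational matches/columns (no
pre-rounding), so a sequence at exactly 65.0% is accepted. Per
(species, enzyme family) only the best hit is kept — highest identity,
ties broken toward the lexicographically lower protein id — and
sub-threshold best hits are retained with `accepted=False` for
reporting. Traceback ties in the aligner are broken by a fixed state
priority (substitution > gap-in-subject > gap-in-query), giving a
single canonical alignment; an independently coded plain-loop DP oracle
with the same documented convention reproduces both score and identity
in the tests, and the optimal score is additionally cross-checked
against Biopython's pairwise aligner.

Nitrate reductase is scored on the catalytic subunit NarG only, but a
genome counts as Nar-positive only if an accepted *narH* hit lies on
the same replicon within 2 ordinal gene positions of the *narG* gene
(either side). The window of 2 operationalises "adjacent, same operon"
while tolerating one intervening ORF (mis-called or inserted genes are
common in draft annotations); it is a parameter. A NarG hit whose gene
id cannot be located in the gene order raises an error rather than
silently verifying false. Nitrite-reductase class (NirK vs NirS) is the
family of the accepted hit; a single protein accepted against both
panels is an ambiguity error, while distinct proteins resolve to the
stronger match. The class affects reporting only, never the
completeness arithmetic.

## Phenotype classification

The chain order is fixed: Nar → Nir → Nor → Nos. A genome with ≥ 1
marker is a potential denitrifier (`strict=True` raises the bar to ≥ 2,
reflecting the caveat that single-enzyme genomes may not be
denitrifiers under canonical definitions; all cohort statistics use the
default). Completeness is non/partial/complete for 0 / 1–3 / 4 markers.
The theoretical end product is the product of the most downstream
enzyme present — nitrite, NO, N₂O or N₂ for Nar, Nir, Nor, Nos
respectively. This rule reproduces every explicitly enumerated
combination (NarG-NirK and NirK-only end in NO; Nar-Nir-Nor, Nar-Nor,
Nir-Nor and Nor-only end in N₂O; the full set ends in N₂) and extends
deterministically to the remaining subsets (e.g. {Nar, Nos} → N₂);
extrapolated combinations carry a `rule_derived` flag in the output.
`is_consecutive` reports whether the present markers occupy a
contiguous interval of the chain (empty set: true by convention). The
16-row truth table is asserted exhaustively against brute-force oracles.

## Phylogeny

Distances are p-distances with pairwise deletion: columns containing a
gap or N in either sequence of a pair are excluded; a pair with zero
comparable columns is an error naming the pair. p-distance is
assumption-free and sufficient for neighbour-joining topology at 16S
divergences; no substitution-model correction is applied, so branch
lengths underestimate deep divergences — acceptable because no rate or
date inference is built on them.

Neighbour joining follows Saitou–Nei: join the pair minimising
Q(i,j) = (n−2)·d(i,j) − Σd(i,·) − Σd(j,·), branch lengths from the
two-point formulas, distances to the new node by the reduction formula.
Ties in Q (within 1e−12) are broken by the lexicographically smallest
pair of cluster labels, each cluster labelled by its smallest member
leaf — this makes the output invariant to input order. Negative branch
lengths are clamped to zero without redistributing the deficit, so
total tree length is non-increasing under clamping and every length in
the output is interpretable as ≥ 0. On strictly additive matrices no
clamping triggers and the generating tree is recovered exactly
(verified to 1e−9 on random trees with n ≤ 8).

Bootstrap: columns are resampled with replacement (length preserved);
each replicate uses an independent child of the master seed
(`numpy.random.SeedSequence.spawn`), so replicate r is reproducible in
isolation. Supports are the percentage of replicates containing the
same leaf bipartition, rounded half-up, and are attached to the
original topology only — no consensus tree is constructed. Rooting on
an outgroup splits its pendant edge in half and re-hangs the tree;
bipartitions and their supports are preserved, which the tests check.

## Synthetic communities

The generator emulates a cohort of species with curated proteomes and
16S sequences. Conditions and defaults:

- **Class mix per family** — allocated by largest-remainder rounding so
  small families realise their fractions exactly. "Partial" species
  draw a uniformly random non-empty, non-full subset of the four
  markers (all 14 subsets possible). All planted nitrite reductases
  derive from the NirK panel, matching the observation that NirK is the
  only class found in haloarchaea.
- **identity_true = 0.85, identity_decoy = 0.30** by default (the
  threshold-stress scenario uses 0.70 vs 0.50): homologs are
  substitution-only mutants of panel members with an exact mutated-site
  count, so realised identity equals the target to within half a
  position; decoys are mutated panel copies rather than random strings,
  so the identity threshold — not mere relatedness — is what separates
  them. At least 5 decoys per proteome.
- **Gene order** — one replicon, random permutation, with the *narH*
  homolog inserted immediately after *narG* for Nar-positive species.
- **16S** — evolved along a random ultrametric bifurcating tree of
  root-to-tip depth `tree_depth` (default 0.10 substitutions/site) by a
  Jukes–Cantor-style uniform substitution process over 1200 sites
  (substitution probability 3/4(1 − e^{−4t/3}) per site per edge of
  length t). No indels are simulated, so the output is already an
  alignment.
- **Panel lengths** — NarG 400, NarH 250, NirK/NirS 300, Nor 350,
  NosZ 300 residues: domain-scale lengths that keep the thousands of
  pairwise alignments in a community scan cheap while leaving the
  identity statistic well-resolved (±0.25% per site at length 400).
- **No-genome species** — a `p_no_genome` fraction (rounded half-up) is
  flagged without proteomes; they appear in the 16S set and taxonomy
  but are excluded from every classification denominator.

Everything is driven by one seed through a single `numpy` generator, so
identical configurations give byte-identical output files.

What the generator does **not** emulate: realistic amino-acid
substitution matrices or site-rate heterogeneity, indels, paralogous
marker families at intermediate identity (e.g. other molybdopterin
oxidoreductases near NarG), operon rearrangements, or horizontal
transfer. Passing the recovery tests therefore demonstrates that the
decision rules are implemented correctly and separate planted signal
from decoys at the stated identities — not that a 65% threshold is
optimal for real proteomes.

## Cohort statistics and the packaged fixture

Percentages are 100·count/denominator with denominator = genome-available
species (never the full species list), rounded half-up to one decimal.
Emitter fractions are reported over both denominators (denitrifiers;
genomes); with zero denitrifiers the former is undefined (`None`), not
zero.

The packaged cohort fixture is a synthetic per-species reconstruction
of the published family-marginal table: 147 species in 10 families, 25
without genomes, and per-family non/partial/complete counts equal to
the published values. Because the published table is family-marginal,
the assignment of individual marker combinations within a family is
arbitrary; the global composition of the 71 partial profiles is chosen
to reproduce the published cohort-level emitter fractions (11 NO-enders
and 40 N₂O-enders among 86 denitrifiers; 34 Nos-bearing genomes),
weighted toward NirK-Nor-containing sets, reported as the most frequent
co-occurrence. Two cohort-level companion percentages printed in the
original survey (48.6% gas emitters and 16.5% Nos-bearers "of total
genomes") are arithmetically inconsistent with their own stated
components (the consistent values over 122 genomes are 41.8% and
27.9%); the package reproduces the component figures and does not
attempt to match the inconsistent ones.

## Problem sizes and limitations

The shipped analyses use communities of 8–60 species, panel sequences
of 250–400 residues, 1200-site 16S alignments, 100 bootstrap replicates
and 50 additive-tree recovery trials — sizes at which every stage is
exact and the full suite runs in well under a minute per stage.
Bootstrap replicate counts are a parameter (the CLI default for `tree`
is 1000). Known limitations: the aligner is O(nm) per pair with no
heuristic prefilter, so very large proteomes scan slowly; p-distance
saturates for deep divergences; the fixture encodes marginals, not real
species identities, so per-species conclusions cannot be drawn from it.
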