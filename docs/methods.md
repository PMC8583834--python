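# Methods

## The problem

Six low-copy nuclear markers and a combined plastid matrix for a clade of
slipper orchids tell incompatible stories: every marker resolves the two
outgroup subgenera (F — Brachypetalum, G — Parvisepalum) the same way, but the
five ingroup sections of the hybrid-origin subgenus (A — Coryopedilum, B —
Pardalopetalum, C — Cochlopetalum, D — Barbata, E — Paphiopedilum) shuffle
between trees, and some nuclear trees even deny that the subgenus is
monophyletic. The working model is ancestral homoploid hybridization: the
subgenus descends from a hybrid between two "proto" populations, and each
nuclear locus subsequently fixed one or the other parental copy in each
section. Loci fixed uniformly from one parent date the subgenus crown at the
radiation (~11 Ma); loci whose sections retain different parental copies
coalesce only at the proto split (~16.5 Ma) and support conflicting
topologies.

The package implements the complete desk-scale analysis around that model:
detecting which groups conflict per marker, concatenating the markers into a
*duplicated supermatrix* that separates the conflicting signal instead of
discarding it, re-inferring the species tree, and simulating the whole
process under a network coalescent so every stage can be verified against a
known truth.

## The duplicated supermatrix

For each marker a conflict report is computed against a reference topology
(the plastid tree, which agrees with morphology): the *conflicted groups* are
the smallest set of group codes whose removal from both trees makes all
remaining resolved splits pairwise compatible. The search is exhaustive over
group subsets in increasing size (<= 7 groups, <= 128 subsets); when several
subsets of the minimal size reconcile the trees, their union is taken
conservatively. Conflict is assessed on support-collapsed trees: internal
nodes with support strictly below 0.97 become polytomies first, so weakly
supported disagreement never triggers duplication.

A clean marker enters the supermatrix once. A conflicted marker is entered
twice: copy 1 excludes the conflicted sections, copy 2 excludes the remaining
ingroup sections, and the two outgroup subgenera stay in both copies. Excluded
blocks are coded `?`. Every observed character is therefore used, but no
taxon's data argues for two incompatible placements inside one partition.
Combined inference on the matrix is exact parsimony over all unrooted
topologies at group level (945 for 7 groups; Fitch counting vectorized over
sites), with neighbor-joining and MDC-on-gene-trees as alternatives.

## MDC

Deep-coalescence scoring follows the classic extra-lineage count: for each
cluster C of the species tree, the minimum number of gene-tree lineages
exiting C equals the number of maximal gene-tree clades whose tips all map
into C, and each lineage beyond the first is an extra lineage. Species-tree
search is exhaustive over rooted binary topologies (capped at 8 species;
7 species = 10,395 candidates), with polytomous gene trees scored as the best
of their binary resolutions. The search core works on integer leaf-set
bitmasks with the per-cluster counts vectorized across all resolutions of all
gene trees; the slow tree-based scorer is kept as the public single-pair API
and the two are cross-checked in the tests, along with an independent oracle
that enumerates every valid embedding.

## The simulator

`hybsim` draws gene trees under the multispecies coalescent on a fixed dated
history: root (G split) 24 Ma, simultaneous divergence of F and the two
parental proto populations at 16.5 Ma, hybrid origin of the ingroup ancestor
at 12 Ma, ingroup radiation at 11 (A-E crown), 9 (A,B,C), 8.5 (D,E), 8 (A,B)
Ma. The radiation ages sit at the young end of the allowed 8-11 Ma window so
that within-section-pair coalescence is mostly complete by the crown — the
regime a rapid island radiation implies.

Allele sorting is modeled as fixed haplotype classes: each section carries a
parental label (1 or 2) per locus, and below the hybridization age lineages
with different labels cannot coalesce; at 12 Ma each lineage is routed into
its parental population and the restriction ends. The three modes are
`single_parent` (one label per locus, probability gamma for parent 1),
`random_sorting` (independent label per section), and `congruent_sorting`
(the multi-flowered {A,B,C} and single-flowered {D,E} daughter lineages fix
opposite labels). In the zero-ILS limit (N_e = 0, deterministic instant
coalescence) this yields exactly: single-parent trees identical to the
species tree with ingroup tMRCA 11 Ma, and label-spanning loci with ingroup
tMRCA 16.5 Ma — the dating contrast that motivates the whole analysis.

Parameters with no measurable real-world counterpart are free, with defaults
chosen once as plausible for long-lived perennial herbs: haploid N_e = 1e5,
generation time 10 yr (so one coalescent unit = 1 Myr), gamma = 0.5, one
allele per species, JC69 sequences at 1.5e-3 substitutions/site/Myr under a
strict clock, 1 kb loci. Sequence evolution draws the root from equilibrium
frequencies and evolves states by the branch transition matrix
(`expm(Q * rate * t)`); HKY85 with adjustable kappa is available. All
randomness flows from one root seed through per-marker `SeedSequence`
streams; a study bundle is bit-reproducible from its manifest.

The coalescent engine is cross-checked against msprime on an equivalent
demography (single-parent routing reduces to a plain MSC on the species
tree), and three-lineage within-branch coalescence probabilities against the
closed form.

What the generator does *not* emulate: recombination within loci, sequencing
error, rate variation among sites or lineages, gene duplication/loss, more
than one reticulation, and unequal base composition. Passing tests therefore
show the method behaves correctly when incongruence really is generated by
one ancestral hybridization plus ILS — not that real matrices satisfy those
assumptions.

## Desk-scale inference in place of MCMC

Bayesian tree inference and dating are out of scope; the deterministic
analogues are: JC69 distances over mutually non-missing sites (saturated
pairs clamped to a ceiling of 5 subst/site), neighbor-joining via scikit-bio
with negative branch lengths clamped to zero, bootstrap proportions (100
column resamples) as the support analogue — an explicit substitution for
posterior probabilities, not an equivalence — and a strict-clock chronogram
obtained by averaging root-to-tip distances below each node on the fixed
topology and rescaling so the root sits at the calibration age (24 Ma).
Rooting places the root on the outgroup tip's edge at the clock-consistent
point (outgroup depth equal to the mean depth of the other side); a midpoint
split would be badly biased because the outgroup branch spans the full
root-to-tip depth. Markers are classified as one- or two-parent by comparing
the chronogram's ingroup tMRCA with a threshold midway between the
hybridization and proto-split ages (14.25 Ma by default).

Bayes-factor clock selection is exact arithmetic on supplied log marginal
likelihoods: H0 is auto-oriented to the lower value, 2lnBF = 2(lnML_alt −
lnML_H0), and evidence bands follow Kass-Raftery with left-closed boundaries
(<2 inconclusive, [2,6) positive — displayed "Weak" in tabulations, [6,10)
strong, >=10 very strong). Display rounding is two decimals with the trailing
zero trimmed (5.30 → "5.3", 1.00 → "1.0").

## Parsimony statistics

Site classification, Fitch tree length, and CI/RI use the conventional
definitions: `?` and `-` are fully ambiguous and excluded from state counts;
informativeness requires two states each in two or more taxa; per-site minima
m_i = states − 1 and maxima g_i = non-missing taxa − modal-state count;
CI = Σm/S, RI = (Σg − S)/(Σg − Σm) with g_i = m_i sites excluded from the RI
sums (their steps are forced, so the convention does not change the value).
Invariant matrices define CI = RI = 1. Exact most-parsimonious-tree search is
capped at 9 taxa.

## Numerical and degenerate-input choices

- Ultrametricity is checked at 1e-9 relative tolerance on exact trees and
  1e-6 where estimates are involved.
- Support values in (1, 100] are read as percentages and divided by 100 with
  a warning; nodes without support are never collapsed; support exactly at
  the threshold survives ("lower than" is strict).
- Zero-ILS coalescence merges lineages deterministically in
  population-priority order, so the ((P1,P2),F) attachment at the proto split
  and byte-identical reruns are guaranteed.
- NJ Q-matrix ties follow scikit-bio's deterministic order; chronogram
  monotonicity is enforced top-down (a child's age is capped by its
  parent's).
- When the union of tied minimal conflict subsets covers every ingroup
  section, the pipeline falls back to the canonically first minimal subset
  for the duplication scheme (the module-level builder treats that union as
  an error, which is correct for single-marker use).

## Problem sizes used by the shipped checks

The test suite and `scripts/acceptance.py` run entirely on synthetic or
bundled data: 200 random parsimony instances and 100 random MDC instances
against exhaustive oracles, six 10-kb loci for chronogram recovery, 1,000
loci per sorting class for the tMRCA contrast, and 100 end-to-end pipeline
replicates (about two minutes total) for the recovery-rate demonstration.

## Known limitations

- Conflict detection needs a resolved reference; with a bootstrap-supported
  reference tree at the 0.97 threshold, desk-scale data rarely resolve it,
  which is why the pipeline defaults to the fixed plastid reference topology.
- The exhaustive searches (MDC, parsimony) are for group-level problems;
  there is deliberately no heuristic mode.
- Classification of markers from 1-kb loci is noisy near the threshold; the
  pipeline reports per-marker tMRCAs so borderline calls are visible.
- The simulator's hybridization is instantaneous and homoploid; allopolyploid
  subgenome tracking is out of scope.
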