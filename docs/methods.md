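# Methods

## Dimorphism scoring

Each species carries one discrete score per sex per character; the
catalogue (`fixtures/table1_catalog.tsv`) holds 39 characters in seven
categories (M-I osteology 5, M-II morphometrics 4, M-III soft anatomy 7,
M-IV fins 6; C-I head 3, C-II body 3, C-III fin coloration 11).  A
character is dimorphic in a species iff both sex scores are present and
differ.  A score missing in either sex contributes zero and is logged:
museum material cannot always be sexed or scored, so published counts are
explicit minima, and we preserve that convention rather than imputing.

State labels are free strings, never integers, so no ordering can leak
into the mapping: every character is treated as unordered.  The catalogue's
state lists are editorial reconstructions of the range of conditions each
character can take (e.g. jaw length gets five anatomical landmarks:
short-of-orbit, to-orbit-margin, past-orbit, past-preopercle,
past-opercle); they constrain validation only, not the scoring logic.

Score matrices are long-format TSV (`species, sex, char_id, state`), one
row per cell; a NEXUS CHARACTERS writer (one composite taxon per
species × sex, states encoded as 0-based symbols, `?` for missing) provides
interoperability with standard phylogenetics tools.  Converting another
layout (e.g. a wide per-character table) means melting it to this long
format.

## Summaries and binning

Genus statistics are the arithmetic mean, *sample* standard deviation
(n−1 denominator; omitted for single-species genera), and min–max range of
the per-species counts.  The n−1 choice was verified against the published
genus table (e.g. totals 30, 29, 28, 31, 29, 28 give SD 1.169 → printed
1.2).  Published one-decimal values are compared at ±0.05 because the
source's own print rounding is inconsistent: some cells round half away
from zero (29.1667 → 29.2) while at least two truncate (8.75 → 8.7;
11.1667 → 11.1, which even exceeds ±0.05).  The comparison helper therefore
also accepts an exact one-decimal truncation.  Internal computations are
never rounded.

Ordinal map scores 0–4 use inclusive integer bins tied to each character
set's size — morphology: 0 / 1–4 / 5–8 / 9–11 / 12–17; coloration: 0 /
1–4 / 5–8 / 9–11 / 12–14; total: 0 / 1–6 / 7–13 / 14–19 / 20–31.  Score 0
is reserved for exactly zero; counts above the top edge are an error, not
clamped, because they would mean the count table and catalogue disagree.

## Composite phylogeny

The family tree is assembled, not inferred: a YAML backbone
(`fixtures/backbone.yaml`) nests named clades and genera, and species are
attached under their genus as a polytomy (membership derived from the
species name's first token, overridable).  The default backbone places the
*Neoclinus* + *Mccoskerichthys* lineage as sister to the Chaenopsinae;
within the subfamily *Coralliozetus* splits first, then a
(*Protemblemaria*, *Cirriemblemaria*, *Emblemariopsis*) clade — kept as a
trichotomy because its internal resolution is not fixed by the source
text — then *Acanthemblemaria* plus the reef-sand clade
((*Ekemblemaria*, *Hemiemblemaria*), Chaenopsis clade), the last holding
*Lucayablennius*, *Chaenopsis* and *Emblemaria* as a polytomy.
*Tanyemblemaria* has no scored species and is omitted.  Within-genus
topologies published elsewhere can be imposed by supplying a user Newick;
by default every genus is a polytomy except the "caldwelli species group"
clade inside *Emblemaria*.  That group is described as having four species
but only three identifiable, sampled members (*caldwelli*, *caycedoi*,
*hyltoni*); the config lists those three and the fourth slot is simply
unsampled — a phantom tip would corrupt the 66-tip analyses.

Assembly is deterministic (species sorted within genera), every genus is
monophyletic by construction, and reconciliation between the backbone and
the species list is strict unless `allow_partial` is set.  Branch lengths
are ignored throughout: parsimony is length-free.

## Unordered parsimony with hard and soft polytomies

Hard mode treats a polytomy as a true multifurcation and is computed with
a unit-cost Sankoff dynamic programme — for each node and state, the
minimum subtree cost; each child edge pays 1 iff its two ends differ.  On
multifurcating multistate inputs this is exactly Hartigan's generalisation
of Fitch parsimony.  Missing tips are assigned zero cost for every state
(the standard treatment), so they never force a change.

Soft mode scores a polytomy as the minimum over **all** binary refinements,
each polytomy refined independently per character.  At a polytomy the
programme minimises, over non-empty subsets *S* of the alphabet, the sum of
each child's cheapest state within *S* plus |*S*| − 1 if the parent state
is in *S* (else |*S*|): a refinement can group the children that agree, so
one change "opens" each distinct child state not shared with the parent.
With the ≤5-state alphabets used here this subset minimisation is exact
for any polytomy size; the test suite validates it against exhaustive
refinement enumeration (children kept intact — an earlier naive oracle
that re-inserted siblings inside refined clades is exactly the mistake the
enumeration must avoid).  Soft scores never exceed hard scores, the modes
coincide on binary trees, and soft scores cannot decrease when a tree is
made more resolved.

When several most-parsimonious reconstructions exist, the step count is
unique but placements are not.  Results report one MPR — ties broken by
preferring the parent's state (ACCTRAN-like) and then alphabet order — the
per-node sets of states optimal in at least one reconstruction (computed
by constrained re-runs of the programme), and, in hard mode, the number of
equally parsimonious assignments (missing-tip states included).  Soft-mode
transitions inside a polytomy are attached to virtual branches labelled
`node:group(state)`.  No output claims a unique history.

The jaw analysis maps three characters: male states, female states, and
the derived presence/absence of dimorphism (male ≠ female, missing if
either sex is unscored).  The dimorphism map alone under-counts evolution;
comparing the three attributes each divergence to one or both sexes.

## Jaw-state fixture

The survey's raw per-species scores live in its supplementary material,
which is not redistributable here.  `fixtures/jaw_states.tsv` is a
clearly-labelled best-effort reconstruction: the states pinned by the
running text (ancestral dimorphism with long-jawed males and short-jawed
females; male elongation in two *Neoclinus*; female elongation to
monomorphism in *N. stephensae*, *Protemblemaria* and *Acanthemblemaria*;
shared elongation in most *Chaenopsis*; shared reduction in
*Lucayablennius*; female reduction within *Emblemaria*; pedomorphic
short-jawed *Coralliozetus* females) are entered directly, and the
remaining species were fixed, consistently with each species' published
per-category dimorphism counts, so that the three soft-mode maps need 4 /
7 / 10 steps, the minima the survey reports.  Where the text allows the
single dimorphic morphometric character of a species to be either the jaw
or a cirrus (both *Ekemblemaria*, the caldwelli group), the fixture scores
the jaw monomorphic.  Conclusions that depend on individual unpinned
species states should not be drawn from this fixture.

## Simulation model

The generator emulates the *shape* of the survey's raw data, not its
rates.  On a random tree (binary, or polytomised by collapsing internal
edges with probability 0.3 up to degree 6), each character starts
monomorphic at the root; on each branch, with probability `p_shared`
(default 0.05) both sexes jump together to a common new state, and with
probability `p_sex` (default 0.05) one sex (fair coin) jumps alone.
Sex-limited jumps both create and destroy dimorphism, mirroring the
documented female-side changes.  The per-branch Bernoulli model was chosen
over a continuous-time Mk process for transparency: every change is one
recorded event, so "parsimony steps ≤ true events" is exact bookkeeping,
not an approximation.  Defaults (16 species, 39 characters in the
catalogue's category sizes, 3 states) match the survey's dimensions at a
size where exhaustive validation is cheap; test sweeps use 12–32 species
and one or two characters per category to keep hundreds of replicates
fast.  What passing simulations show is that the pipeline's bookkeeping
and bounds are correct under the model's assumptions — independent
characters, no rate heterogeneity, no correlated evolution, no missing
data — not that real chaenopsid characters evolved this way.

A frozen recovery baseline (equality of inferred steps and true event
counts in 756/800 character–sex maps at rate 0.02 on 32-tip trees,
generating seed 20260925) guards against silent regressions in either the
simulator or the reconstruction.

## Numerical and reporting choices

All randomness flows from a single integer seed through one numpy
generator per simulation; seeded runs are bit-reproducible.  The report
bundle (`run-paper`) contains no timestamps, only versions, configuration
and content digests, so identical inputs give byte-identical bundles.
Exit codes: 0 success, 2 validation failure, 3 tree/fixture
reconciliation failure.

## Known limitations

* Soft-mode refinement is per-polytomy and per-character, matching the
  "minimum steps within polytomies" convention; a single refinement
  consistent across characters could need more steps.
* Which polytomy semantics the original figures used is not stated; both
  modes are computed and reported side by side.
* The jaw fixture caveats above apply to every jaw-map number.
* Bright (non-melanophore) coloration, body size, and the morphometric
  characters excluded from the original survey are out of scope, as is
  phylogeny inference.
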