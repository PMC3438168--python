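# Methods

This note documents the models and procedures `florakey` implements, the
defaults it ships, the design choices made where the design was genuinely
open, and what the synthetic-data tests do and do not establish.

## Identification model

A flora is described twice: morphologically, as a taxa × categorical
characters matrix in which every character carries an organ tag
(`whole-plant`, `leaf`, `flower`, `fruit`, `other`) and an optional
seasonal flag; and molecularly, as a barcode library of aligned reference
sequences for a declared marker set (default `rbcL`, `matK`,
`trnH-psbA`), one flagged reference individual per species plus optional
extra individuals for intraspecific surveys.

Identification sessions combine three primitives:

1. **Multi-entry filtering.** A query is a set of `character → state`
   constraints applied simultaneously; a taxon survives if its scored
   state equals the required state on every constrained character.
   Taxa scored UNKNOWN on a constrained character are *retained*: a key
   must not lose the true taxon to an unscored cell. Consequence:
   extending a query can only shrink the result (monotonicity), which is
   property-tested.
2. **Dichotomous keys.** Built greedily: at each node, over all usable
   characters and observed states, the one-state-vs-rest binary split
   minimising the size imbalance of the two sides is chosen (ties broken
   by ascending char_id, then state label). Multistate characters are
   binarized at each node rather than fanned out polytomously — each step
   is a choice between two alternatives. Taxa scored UNKNOWN on the
   splitting character are routed down both branches. Both sides of an
   accepted split must be proper subsets, so recursion always terminates;
   when no usable character splits the set, the node becomes a leaf, and
   multi-taxon leaves are an honest statement of indistinguishability.
3. **Stepwise sessions.** Descending the key with a specimen profile
   yields SUCCESS at a singleton leaf, AMBIGUOUS at a multi-taxon leaf,
   or STALLED — with the residual taxon set and the blocking character —
   as soon as the node's character is absent from the profile. A
   character is unusable on a specimen iff its organ is in the specimen's
   unavailable set; that is exactly how out-of-season collections break
   identifications.

## Barcode analysis

**K2P distance.** For two aligned sequences, columns where either side
carries anything other than an unambiguous A/C/G/T (gaps, N, IUPAC
ambiguity codes) are deleted pairwise; over the surviving `L` columns,
with transition proportion `P` and transversion proportion `Q`,

    d = -1/2 * ln[(1 - 2P - Q) * sqrt(1 - 2Q)].

Pairwise deletion (rather than complete-column deletion) keeps per-pair
`L` maximal and matches standard practice in the distance tools this
package mirrors. When `1 − 2P − Q ≤ 0` or `1 − 2Q ≤ 0` the pair is
SATURATED; when `L = 0` it is NO_OVERLAP. Both are raised signals at the
single-pair level and flagged cells at the matrix level; means always
exclude flagged cells and expose the exclusion count, so no NaN ever
leaks into a reported average. Distances are reported ×100 (%) with
half-up rounding to one decimal, applied only at the report layer.

**MOTUs.** Taxa whose aligned reference sequences are *completely
identical* are non-identifiable with that marker and share a MOTU.
Identity is exact string equality after case normalisation; gap columns
and ambiguity codes compare verbatim (`N ≠ A`), because spacer indels are
treated as diagnostic. Looser matching is deliberately not the default.
Concatenating markers restricts to taxa carrying all components (which is
why combination columns report smaller N) and can only refine the
partition — MOTU counts never decrease when a marker is added.

**Sampling rule.** Exactly one reference individual per species enters
discrimination analyses; additional individuals feed only the
intraspecific summary (per species and marker: mean within-species K2P
and its standard error over all individual pairs).

**Efficiency.** The discriminatory efficiency of a marker over a
candidate group is `100 × MOTU / N` rounded half-up to one decimal. Note
this is *not* the fraction of singleton MOTUs: a k-taxon MOTU still
contributes one resolvable entity out of its k members. The formula is
pinned by tests against every checkable reported value, e.g.
(41, 38) → 92.7 and (101, 96) → 95.0.

## Integrated identification

Stage 1 (barcode filter): each query sequence is assigned to a MOTU by
exact identity with a reference sequence; failing that, to the nearest
reference by K2P if within a threshold (default 0.02 — the intraspecific
ceiling: within-species distances sit consistently below 2%, so anything
farther is unlikely to be conspecific). With several markers the
candidate set is the intersection of MOTU memberships; if markers
disagree outright the union is used with a warning (multi-marker query
semantics are not otherwise constrained by the source material, so the
conservative choice is configurable behaviour, not doctrine). No marker
matching at all yields NO_MATCH.

Stage 2 (residual key): a singleton candidate set is SUCCESS without
touching morphology; otherwise a dichotomous key is built over the
candidates using only characters whose organ is available on the
specimen, and the session proceeds stepwise. With no query sequences the
call degrades to morphology-only identification over the full key
(built over *all* characters, so the session stalls informatively at the
first unobservable character instead of quietly losing resolution).

Guarantee, restated precisely: whenever the set of barcode collisions
and the set of morphologically unavailable distinctions are disjoint —
every multi-taxon MOTU is separable by a character observable on the
specimen — the integrated identifier returns the true species for 100%
of queries. The acceptance suite constructs exactly this condition and
verifies the 100%.

## Synthetic flora: the stated world

The generator emulates a strongly heterogeneous local flora:

* **Skeleton**: 115 genera with 1–5 species each (~345 taxa) on a
  two-level tree — a genus radiation followed by a species radiation —
  rather than a full birth–death process; genus branches draw uniformly
  from 0.35–0.55 and species branches from 0.02–0.08 of each marker's
  scale, so intergeneric pairs (the dominant class) sit near the scale
  and congeners an order of magnitude closer.
* **Markers**: sequences evolve site-independently under the
  two-parameter (K80) model with transition/transversion rate ratio
  κ = 3, the generator matching the distance estimator used downstream.
  Defaults: rbcL-like 552 nt at scale 0.108, matK-like 840 nt at 0.279
  (both flora-wide reported means), trnH-psbA-like 450 nt at 0.35. No
  flora-wide mean is reported for the spacer — only that its divergences
  are the greatest — so its scale is set above matK's to preserve the
  ordering without claiming the exact value. The spacer additionally
  receives random gap blocks (3–12 columns, expected gapped fraction
  4%) applied post hoc so the alignment length stays fixed; real spacer
  alignment difficulty is out of scope.
* **Intraspecific variants**: for 50 surveyed species, 3 extra
  individuals per marker evolve from the reference at branch lengths
  uniform on [0, 2·mean] with marker means 0.0005 (rbcL-like, nearly
  invariant within species) and 0.004 (the others), keeping expected
  within-species K2P well under the 2% ceiling.
* **Planted identities**: directives pin the first two species of a
  genus to byte-identical sequences for chosen markers. After
  generation, any *unplanned* cross-taxon identity is re-drawn (up to 60
  rounds; exceeding the cap is an error, not a silent acceptance), so
  planted pairs are the only identities and expected MOTU counts are
  exactly `n_species − n_planted_pairs` — the oracle the MOTU tests use.
* **Characters**: 13 genus-level binary characters (growth form, latex,
  spines, phenology, leaf arrangement, fruit type, ...) are drawn per
  genus with weights chosen so the built-in scenario filters retain a
  realistic slice of the flora; the first k genera per scenario profile
  (default 2) are pinned to the scenario's states so each scenario is
  always instantiable. Species-level characters (petal colour, corolla
  shape, fruit surface, leaf shape, stamen number) encode the global
  species index in mixed radix — capacity 1440 taxa — so every species
  pair differs in at least one character unless a morphological-twin
  directive says otherwise. Flower characters occupy the least
  significant digits: congeners therefore tend to differ *only* in
  flower characters, which is what makes flowerless specimens stall and
  gives the barcode filter its work.
* **Determinism**: one PCG64 generator threaded through fixed-order
  loops; the same seed yields byte-identical on-disk bundles.

What a green synthetic test does **not** establish: real floras have
rate heterogeneity across sites and lineages, pseudogenes, alignment
ambiguity, partially scored matrices and amplification failure, none of
which the generator models (amplification success rates are wet-lab
outcomes and deliberately absent — synthetic libraries are complete
unless records are removed by hand). Scenario candidate-group sizes are
therefore structural analogues, not reproductions of any particular
flora's 37/105/41-taxon lists.

## Built-in scenarios

* **A** — herb or small shrub, green, spineless, terrestrial, leaves
  opposite, simple, not whorled (7 constraints); flowers unavailable.
* **B** — herb or small shrub, green, spineless, terrestrial, with
  leaves, not opposite, entire, not whorled (8 constraints); flowers
  unavailable.
* **C** — tree/shrub over 50 cm, not a woody climber, deciduous,
  terrestrial, dry fruit (5 constraints); leaves unavailable.

Scenario B's narrative mentions *simple* leaves while its enumerated
character list says *entire*; the list is followed. Constraint names map
to matrix characters through a configurable vocabulary, so the scenarios
can be re-targeted at any matrix that can express their states.

## Numerical choices

* All reported percentages round half-up to one decimal (`Decimal`,
  `ROUND_HALF_UP`); internal values keep full precision.
* Congeneric group reports emit the *mean* intragroup K2P by default and
  the maximum only on request, since the parenthesised group statistic
  in the source tables is not unambiguously one or the other; no claim
  is made to reproduce those exact cells.
* Distance cells for groups with fewer than two sequenced members are
  inapplicable (NaN-valued in the report, never averaged).
* FASTA headers follow `voucher|taxon|marker[|role]` with a configurable
  regex; when several records share (taxon, marker) without role flags,
  the lexicographically smallest voucher becomes the reference.
* Infraspecific entities (subspecies, varieties) are terminal taxa with
  their own taxon_id; no nomenclatural resolution is attempted.

## Known limitations

* The K80 generator has no gamma rate variation, codon structure or
  indel *process* (gaps are overlay blocks), so spacer realism is
  limited to "more divergent, with shared gap columns".
* The greedy balance-first key is deterministic and reproducible but not
  guaranteed minimal-depth; real key-building software may rank
  characters differently.
* Query sequences must be pre-aligned to the library's alignment length;
  alignment itself is out of scope.
* `efficiency` treats every MOTU as one resolvable entity; it is a
  library-level discrimination measure, not a per-specimen success
  probability.
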