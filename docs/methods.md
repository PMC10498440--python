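# Methods

## Model

`polyforge` treats polymerization as a library of functional-group
transformations. A *monomer class* is a substructure pattern (SMARTS) plus
occurrence bounds; a *reaction rule* is a reaction SMARTS mapping one or two
monomer classes to a repeating-unit template whose open valences are written
as wildcard atoms. The generator is purely combinatorial and deterministic:
no kinetics, no molar mass, no tacticity, no probabilistic sequence
statistics. Copolymers are restricted to strictly alternating binaries, and
the post-processing step keeps only linear chains (exactly two attachment
points), because a single SMILES repeating unit cannot faithfully describe
branching or cross-linking.

### Monomer classification

A molecule joins a class when every detection pattern of the class matches
between `min_occurrence` and `max_occurrence` times (symmetry-distinct atom
sets only) and no forbidden pattern matches. Defaults:

| kind | bounds | rationale |
|---|---|---|
| chain-growth groups (vinyl, cyclic olefin) | 1–4 | a single polymerizable site suffices; polyfunctional olefins remain usable site-by-site |
| chain ring-opening groups (epoxide, lactone, lactam, cyclic anhydride) | exactly 1 | a second ring would force branching under homopolymerization; diepoxides route to the step-growth diepoxide class instead |
| step-growth di/poly classes | 2–4 | bifunctionality is required for chain extension; above four groups gels are near-certain (bounds configurable via `--min-fg/--max-fg`) |
| bifunctional single-molecule classes (hydroxy acid, amino acid, plus the one-pattern phenol/sulfone/ketone motifs) | exactly 1 of each pattern | one of each group per molecule defines the self-condensing monomer |

Multi-class membership is expected: a thiol-free diol is a member of both
diol classes, a primary diamine of both amine classes. The thiol-free diol
class adds a forbidden thiol pattern; amide- and ester-adjacent O/N are
excluded by negative constraints inside the patterns themselves, with no
extra protecting-group logic.

Incompatibility screening happens at two points. A registry-level
`exclusion_patterns` list (empty by default, user-editable) can knock
molecules out of the whole run before counting. Independently, at
enumeration time, a monomer entering a two-slot step-growth rule is dropped
if it also carries the partner slot's reactive group (a diol bearing an
isocyanate would self-react under the urethane rule). Chain rules are not
screened this way: mutual reactivity between olefin slots is the desired
polymerization, not an incompatibility.

### Generation

For each rule, reactant tuples are the pool (one-slot rules), the cartesian
product of two pools (distinct-class two-slot rules), or unordered distinct
pairs (same-class two-slot rules). Self-pairs are off by default — an A+A
"copolymer" duplicates homopolymer chemistry — and can be enabled with
`allow_self_pairs` for parity experiments. The transform runs at every
matching site combination; chemically identical products from equivalent
sites of the same reactant set are collapsed, while regioisomers (head-head
vs head-tail dyads, the two opening directions of an unsymmetrical epoxide)
stay distinct, each with its own `site_index`. Products that fail valence
sanitization are skipped with a logged warning rather than aborting — on
exotic inputs, combinatorial transforms occasionally propose impossible
intermediates.

Two library-size counters are kept because both conventions are in use:
`provenance_distinct_count` distinguishes identical structures made from
different monomers (or different sites), `structure_distinct_count` does
not.

Each rule stores `leaving_group_heavy_atoms` (per linkage) and
`linkages_formed` (per application), derived from its own transform; the
invariant `heavy(product) = Σ heavy(reactants) − leaving × linkages` is
asserted in the tests and in the acceptance run over every generated record.
Chain, ring-opening and polyaddition rules conserve heavy atoms exactly;
the condensations lose one heavy atom (hydroxyl oxygen or acyl halide) per
linkage. The polycarbonate rule consumes carbon monoxide as a fixed
co-reactant baked into the rule — CO is the only phosgene equivalent in the
default registry — so atoms balance with zero loss.

### Identity and dedup

Structural identity is canonical-SMILES equality of the repeating unit *as
written*, wildcards included. Shifted-register equivalence (cutting the same
infinite chain one bond later) is deliberately not collapsed; a
chain-equivalence mode would need its own canonical rotation and is out of
scope. Wildcards are never hydrogen-capped: attachment topology is part of
the identity.

### Evaluation

Fingerprinting an end-capped oligomer biases bits toward the artificial
chain ends, so each two-point unit is closed into a macrocyclic `n_units`
oligomer (default 10): copies joined head-to-tail by single bonds between
the wildcard-adjacent atoms, wildcards removed, final bond closing the ring.
The joining bond is single regardless of attachment-atom hybridization;
units whose closure cannot sanitize (e.g. an aromatic attachment atom with
no free valence) are reported and skipped rather than failing the run. The
construction gives exactly `n_units × heavy(unit)` heavy atoms, which the
tests assert for the whole toy library.

Fingerprints are the toolkit's Morgan/circular bits at radius 3 folded to
2048 bits (the ECFP6 convention). Absolute Tanimoto values are
toolkit-dialect-dependent, so the package's guarantees are structural:
symmetry, self-similarity 1, exact agreement between the vectorized
similarity path and a nested-loop computation, and monotonicity of the CN
curve. Coverage uses `T ≥ γ` and novelty `T < γ`, so the two statistics
complement one event exactly; ties go to coverage, visible only at grid
endpoints.

## Synthetic data

`generate_toy_monomer_set` emits homologous series per class: 1-alkenes,
cycloalkenes, terminal alkyl epoxides, lactones/lactams of varying ring
size, ω-hydroxy and ω-amino acids, 2,6-dialkylphenols, bis(p-haloaryl)
sulfones and bis(p-fluoroaryl) ketones, alkylene-bridged bis-epoxides,
α,ω-diacids/diols/dithiols/diamines/diisocyanates, cyclic anhydrides, and
dianhydrides (pyromellitic dianhydride plus alkylene-bridged
bis(succinic anhydride)s). Dithiols stand in for the thiol-bearing diol
class so the two diol classes stay distinguishable; N,N′-dimethyl diamines
populate the general amine class without the primary one. Homologue indices
are drawn by a seeded RNG, so fixture sets are fully reproducible.

What the toy sets do **not** emulate about real monomer catalogues:
aromatic/heteroaromatic backbone diversity, stereochemistry, substituent
effects on reactivity, and the multi-class overlap structure of a curated
vendor list (each family is built to hit exactly one intended class). A
passing test therefore certifies the mechanics of classification,
enumeration, bookkeeping and evaluation — not the chemical coverage
obtainable from any particular real monomer list.

Problem sizes: the default test and acceptance runs use three homologues per
class (57 molecules), which already exercises every rule and produces all
seven polymer classes (~190 records); the oracle-equivalence checks run 20
random 10-monomer subsets against an independent brute-force enumeration.

## Numerical and design choices

* Everything is deterministic: record order is (rule id, monomer input
  order, site index); dedup output is lexicographic; the only RNG in the
  package is the fixture generator's, and it is seeded.
* The transforms are shipped verbatim from their printed source except for
  three transcription repairs (a stray aromatic-phosphorus token in the
  sulfone rule read as an italic "p-" leak, component dots line-wrapped into
  branches, and a vacuous `!$(OC=*)` amine constraint); each repair is
  flagged in the rules-file header.
* The polyoxazolidone transform emits four attachment points per unit
  (its template carries a pendant reacted epoxide/isocyanate pair), so its
  products are dropped by the linear filter; the counters expose this
  rather than hiding it.
* Tanimoto of two all-zero vectors is defined as 0.
* Class labels of structures generated by rules of different polymer
  classes collide rarely; dedup keeps the lexicographically first label and
  logs the collision.

## Known limitations

* No branched or cross-linked polymers; no representation beyond a single
  linear repeating unit.
* No ring-opening metathesis, phenol/melamine addition-condensation, or
  aryl-coupling rules; monomer selectivity is purely substructural, with no
  steric or electronic reactivity model.
* Shifted-register duplicate repeating units are counted as distinct.
* The reference polymer list shipped for evaluation is a small curated set
  of textbook repeating units, suitable for exercising the CN machinery,
  not a survey of synthesized polymer space.
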