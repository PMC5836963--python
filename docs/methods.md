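# Methods

## Fragmentation model

A fragmentation rule is a SMARTS pattern matching exactly two atoms
joined by one bond; the matched bond is the cleavage site. This
single-bond dialect is the smallest one that expresses the classic rule
collections and keeps user-supplied rule files trivial (one
`SMARTS<TAB>rule_id` per line). Regardless of what a pattern matches,
**only acyclic single-order bonds are cut**: matches on ring bonds or
multiple bonds are silently skipped, so rings — including macrocycles —
are always preserved in the fragments. A symmetric pattern such as
`[C]-[C]` matches each bond twice; cut bonds are deduplicated by
normalized atom-index pairs, with every matching rule id recorded.

Cutting all matched bonds partitions the heavy atoms into *base
fragments* — the nodes of the fragment-adjacency graph, whose edges are
the cut bonds. Exhaustive fragmentation enumerates every non-empty node
set inducing a connected subgraph with at most *k* nodes (*k* ≤ 0 means
no limit) and reassembles each into a fragment: bonds internal to the
member set, including cut bonds between member fragments, are restored
exactly as in the parent; every boundary cut becomes a cap — a dummy
atom when the cut-point flag *x* is on, an implicit hydrogen otherwise.
Fragment identity is the capped canonical SMILES.

### Enumeration

Connected subsets are generated by breadth-first expansion: start from
each single node and repeatedly add one boundary neighbour, keeping a
visited set of frozensets so each subset is emitted once. A naive
power-set-plus-connectivity brute force lives in `fixtures` purely as a
test oracle. A configurable guard (default 100,000 subsets per
molecule) aborts pathological cases with a per-record error; drug-sized
molecules typically yield a few dozen base fragments at most, and the
per-compound fragment counts we observe are well below the guard.
For a path of *p* base fragments the subset count is *p*(*p*+1)/2
(contiguous runs), which the synthetic chain fixtures verify against
the closed form.

## Rule sets

* **RECAP** — the 11 classic retrosynthetic bond types (amide, ester,
  amine, urea, ether, olefin, quaternary nitrogen, aromatic N–aliphatic
  C, lactam N–aliphatic C, biaryl, sulphonamide), written as two-atom
  SMARTS with the chemical environment folded into recursive atom
  queries. The amine rule accepts any neutral, non-terminal nitrogen
  whose partner carbon is not a carbonyl-like carbon; that makes
  anilide N–aryl bonds cleavable (so N-phenylbenzamide yields a
  three-fragment path), while the amide rule handles the acyl side.
  The olefin rule can never fire under the single-bond policy; it is
  retained for rule-file completeness.
* **BRICS** — the published link-environment bond definitions recast as
  two-atom patterns `[$(envA)]-!@[$(envB)]`; the environment SMARTS and
  the allowed pairs are taken from RDKit's BRICS data. Link-environment
  labels are not emitted: this tool needs cut positions, not BRICS
  recombination typing.
* **CCQ** — one rule: an acyclic C–C single bond where at least one of
  the carbons has a heteroatom neighbour.
* **extendedRECAP** — RECAP plus 16 rules covering thioethers,
  sulfones/sulfoxides, thioureas, thioesters, disulfides, phosphate and
  phosphonate bonds, phosphoramides, sulfonate esters, carbamates,
  benzylic C–C, C–C alpha to carbonyls, amidines, hydrazines and aryl
  thioethers. The original 16-rule extension is distributed only as
  part of an external C++ tool, not as published SMARTS; this set is an
  **extendedRECAP-style approximation** covering the same chemistry
  families. Absolute fragment counts under extendedRECAP therefore
  depend on this choice of SMARTS.

## Parameters

| Parameter | Meaning | Default | Notes |
|---|---|---|---|
| `k` | max base fragments per output fragment | 1 | ≤ 0 = unlimited; `-e` is an alias for `k=1` |
| `n_min` (`-n`) | minimum heavy atoms | 1 | standard runs use 5 |
| `m_max` (`-m`) | maximum heavy atoms | none | |
| `s_rel` (`-s`) | max size relative to parent | none | fragment passes iff heavy ≤ s·parent-heavy (real-valued, no rounding); 0.99 excludes the parent, keeps every proper substructure |
| `w_max` (`-w`) | maximum weight (Da) | none | computed on the capped structure |
| `x` | dummy-atom caps | off | `*` count equals the fragment's boundary cuts |

Atom counts for `n`/`m`/`s` are **heavy atoms only** — dummy caps and
hydrogens never count — so the size filters select identical fragment
sets with and without `x`. Molecular weight is computed on the capped
structure: dummy atoms contribute zero mass, hydrogen caps contribute
normally.

Stereochemistry is stripped at parse time; fragment identity is
constitution-level throughout (deduplication, frequencies, top-N).
Multi-component SMILES (salts, mixtures) are skipped with a diagnostic:
salt stripping is preprocessing, not fragmentation.

## Deduplication and library statistics

Fragments are deduplicated **within each compound** by capped canonical
SMILES before aggregation; a fragment's library frequency is the number
of compounds containing it. Under this convention, switching `x` on is
a pure refinement: hydrogen capping is a many-to-one projection of
dummy-capped forms, so per-compound and library-level unique counts can
only grow — an invariant the test suite asserts. Per-compound fragment
count distributions (five-number summaries) use linear interpolation
between order statistics and are computed over fragmented compounds
only; compounds with zero surviving fragments are excluded rather than
counted as zeros, and reported separately via `n_fragmented`.

## Rule-of-three properties

Properties are computed on the capped representation exactly as
emitted, which is the point of the cut-point flag: a hydrogen cap on N
or O counts as a donor, a dummy cap contributes nothing.

* donors: N/O with ≥ 1 explicit or implicit hydrogen;
* acceptors: N/O, excluding pyrrole-type aromatic NH and nitrogen
  singly bonded to a carbonyl/thiocarbonyl/sulfonyl group;
* rotatable non-terminal bonds: acyclic single bonds between two
  non-terminal heavy atoms; amide C–N bonds and bonds to dummies are
  excluded, and a dummy neighbour does not make an atom non-terminal;
* logP: the Wildman–Crippen atom-contribution estimate, used as the
  xlogP-style surrogate (dummy atoms contribute 0). Any
  atom-contribution logP would do for the filter contract; survivor
  counts for the logP filter are estimator-dependent.

Thresholds: MW < 300 (strict), logP ≤ 3, HBD ≤ 3, HBA ≤ 3, rotatable
≤ 3; the combined filter is the conjunction of all five. Filters are
per-fragment and order-independent.

## Synthetic fixtures

* `chain_molecule(m)` — para-phenylene units joined by ester links.
  Each link contributes exactly one RECAP cut (the ester oxygen is
  excluded from the ether rule), so the fragment graph is a path of
  m+1 nodes and every base fragment has ≥ 5 heavy atoms; the n = 5
  filter never interferes with combinatorics tests.
* `benzene_pattern_count(lo, hi)` — enumerates dummy-capped benzene
  patterns by brute-force position subsets and canonical-SMILES
  deduplication; cross-checked against a chemistry-free orbit count
  under the dihedral group D6 (1+3+3+3+1 = 11 patterns for 1–5 cut
  points).
* `worked_examples()` — ~14 molecules exercising each rule family:
  amides, esters, amines, sulphonamides, N- and C-linked morpholines,
  a CCQ substrate, multiply substituted benzyl esters, and a
  macrocyclic peptide-like ring that no rule can open.
* `drug_like_library()` — 50 molecules generated from core × linker ×
  tail motif pools (aryl/heteroaryl cores; amide, ester, sulphonamide,
  amine, ether, ketone linkers; aliphatic and heteroaryl tails).

The generated library emulates the *motif variety* of a small-molecule
drug collection, not its size, scaffold diversity or property
distributions. Tests on it establish the algorithmic invariants
(monotonicity in k, refinement under x, conservation under
aggregation) and qualitative patterns (exhaustive ≫ simple unique
counts); absolute counts, medians and top-fragment identities on real
drug collections depend on the input database and on the exact
extendedRECAP SMARTS, and are not reproduced by these fixtures. The
acceptance run uses the 50-molecule library with k ≤ 8, sizes chosen so
the whole suite completes in seconds.

## Numerical and interface choices

* Output order: fragments sorted by (heavy atoms, capped canonical
  SMILES); top-N ties broken by SMILES ascending; repeated runs are
  byte-identical.
* `k ≤ 0` or `k ≥` node count triggers unlimited enumeration.
* Per-record failures (unparsable molecule, guard cap) are logged and
  skipped; processing continues. Missing input or zero parseable
  records is fatal (exit 2).
* Output dialect: TSV without quoting; per-compound fragments are
  space-joined; `*` is the dummy-atom token.

## Known limitations

* The extendedRECAP SMARTS are an approximation (see above).
* No reaction-based recombination or BRICS link typing; fragments are
  substructures, not synthons.
* Stereochemistry is discarded; enantiomeric fragments collapse.
* logP-filter survivor counts depend on the Crippen estimator.
* Fragment clustering / enrichment analysis over libraries is out of
  scope; only counting statistics are provided.
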