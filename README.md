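# fragspace

Exhaustive sampling of the fragment space associated with a molecule.

Deconstructing a hit compound into "deletion analogues" is the usual way
to locate its pharmacophore, and fragment libraries for fragment-based
drug discovery (FBDD) are routinely built by cutting known actives at
retrosynthetically sensible bonds. Standard fragmentation (RECAP, BRICS,
CCQ) emits only the *smallest* fragments, which often destroys the very
feature pattern responsible for binding — an amide, for instance, is cut
into an amine and an acid, neither of which keeps the amide
pharmacophore. `fragspace` addresses this in two ways:

1. **Exhaustive fragmentation.** After cutting every rule-matched bond,
   the smallest fragments become the nodes of a *fragment-adjacency
   graph* (edges = the cut bonds). The tool then emits every connected
   union of up to *k* base fragments — all intermediate fragments, not
   just the terminal ones. With *k* = 1 this reduces to classic
   extensive fragmentation; with *k* unlimited it enumerates the
   complete connected fragment space under the chosen rules.
2. **Cut-point highlighting.** Open valences created by bond cleavage
   are capped with hydrogens by default, which silently inflates
   hydrogen-bond-donor counts (an N-cut becomes an N–H). With the `-x`
   flag the caps are dummy atoms (`*` in SMILES) instead, so a
   fragment remembers where and how often it was attached.

Filters keep the output fragment-like: minimum heavy atoms (`-n`),
maximum heavy atoms (`-m`), maximum size relative to the parent (`-s`,
a value just below 1 excludes the parent itself), maximum weight
(`-w`), and an optional rule-of-three panel (MW < 300, logP ≤ 3,
HBD ≤ 3, HBA ≤ 3, rotatable non-terminal bonds ≤ 3).

Rule sets: the 11 classic **RECAP** bond types, **BRICS** (the published
link-environment bond definitions recast as two-atom cleavage
patterns), **CCQ** (C–C bonds where at least one carbon bears a
heteroatom neighbour), an **extendedRECAP**-style set (RECAP plus 16
rules for sulphur, phosphorus and further carbon environments), or any
custom rule file — one `SMARTS<TAB>rule_id` per line, where each SMARTS
matches exactly the two atoms of the bond to cut. Rings are always
preserved: only acyclic single bonds are ever cleaved.

## Worked example

Fragmenting N-phenylbenzamide with RECAP (cuts: the amide C–N bond and
the anilide N–c bond), keeping fragments of ≥ 5 heavy atoms and at most
99% of the parent:

```python
import fragspace as fs

rec = fs.MoleculeRecord.from_smiles("O=C(c1ccccc1)Nc1ccccc1", "N-phenylbenzamide")
rules = fs.builtin_ruleset("RECAP")
params = fs.FragmentationParams(k=8, n_min=5, s_rel=0.99, x=True)
for f in fs.fragment_molecule(rec, rules, params):
    print(f.capped_smiles, f.heavy_atoms, f.boundary_cuts)
```

prints

```
*c1ccccc1 6 1
*Nc1ccccc1 7 1
*C(=O)c1ccccc1 8 1
*NC(=O)c1ccccc1 9 1
```

— the four proper connected fragments: benzene, aniline, benzoyl, and
the intermediate benzamide fragment `*NC(=O)c1ccccc1`, which keeps the
complete amide pharmacophore and records (via `*`) that it was attached
through the nitrogen. With `x=False` the same four fragments appear
hydrogen-capped (`Nc1ccccc1`, `NC(=O)c1ccccc1`, ...), and the capped
aniline nitrogen now counts as an extra hydrogen-bond donor — exactly
the artefact the dummy atoms avoid. The heavy-atom filters count heavy
atoms only (caps never count), so filtering is identical with and
without `-x`.

The same run from the shell:

```sh
fragspace -i molecules.smi -o fragments.tsv -r RECAP -n 5 -k 8 -s 0.99 -x
fragspace -i molecules.smi -o freq.tsv -r extendedRECAP -n 5 -k 8 -s 0.99 -x --mode frequency
```

Library aggregation (`fragspace.aggregate`) counts, for each canonical
fragment SMILES, the number of compounds containing it (after
per-compound deduplication), and `count_distribution` summarises
fragments-per-compound as a five-number summary.

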