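# polyforge

Rule-based generation and evaluation of virtual polymer libraries.

Machine-driven polymer design pipelines need candidate repeating units that a
chemist could actually make. Generative models propose structures freely but
say nothing about synthesis; `polyforge` takes the opposite route: starting
from small organic molecules, it only emits polymers that follow from known
polymerization chemistry, so every record in the library carries its own
synthetic recipe (which reaction, which monomers).

It is aimed at polymer informatics practitioners building screening
libraries, and at anyone who needs a reproducible, auditable mapping from
monomer lists to repeating-unit structures.

## What it does

1. **Classify** (`polyforge.classify`): each input molecule is matched
   against 19 polymerizable monomer classes (vinyls, cyclic olefins,
   epoxides, lactones, lactams, hydroxy/amino acids, hindered phenols,
   activated bis-aryl sulfones/ketones, and the di/poly-functional
   step-growth families). Membership requires the class-specific functional
   group to occur between a lower and upper bound of times (1 for
   chain-growth groups, 2–4 for step-growth groups, exactly one of each of
   two groups for the bifunctional hydroxy/amino acids).
2. **Generate** (`polyforge.generate`): 22 polymerization reactions —
   addition and ring-opening chain polymerizations, polycondensations, and
   polyadditions spanning polyolefins, polyesters, polyethers, polyamides,
   polyimides, polyurethanes and polyoxazolidones — are encoded as reaction
   SMARTS transforms and applied to every applicable monomer or monomer
   pair. Products are repeating units written with wildcard attachment
   atoms, e.g. nylon-6,6 as `*C(=O)CCCCC(=O)NCCCCCCN*`. Regioisomeric
   products are kept distinct; every product obeys exact heavy-atom
   bookkeeping (reactant atoms minus the per-linkage leaving group).
3. **Post-process** (`polyforge.library`): canonicalize the wildcard SMILES,
   merge structural duplicates (counting provenance), and keep the linear
   library — units with exactly two attachment points.
4. **Evaluate** (`polyforge.evaluate`): to compare a generated set Q with a
   reference set P, each repeating unit is closed into a macrocyclic 10-mer
   (so fingerprints see the periodic chain, not end groups), hashed to a
   2048-bit Morgan fingerprint of radius 3 (ECFP6), and scored by Tanimoto
   similarity T. For a threshold grid γ ∈ {0, 0.1, …, 1}:

   - coverage(γ) = 100 · |{p ∈ P : max_q T(p, q) ≥ γ}| / |P|
   - novelty(γ)  = 100 · |{q ∈ Q : max_p T(q, p) < γ}| / |Q|

   Sweeping γ traces the coverage–novelty (CN) curve.

The rule set is data, not code: `src/polyforge/data/rules.yaml` holds all
class definitions and transforms and can be copied, edited and passed back
via `--rules` or `load_registry(path)`.

## Worked example

```python
import polyforge as pf

registry = pf.load_registry()
monomers = [
    ("caprolactam", "O=C1CCCCCN1"),
    ("adipic_acid", "OC(=O)CCCCC(=O)O"),
    ("hmda", "NCCCCCCN"),
    ("ethylene_glycol", "OCCO"),
]
table = pf.screen_library(monomers, registry)
for rec in table.records:
    print(f"{rec.monomer_id:16s} {rec.class_assignments}")

library = pf.generate_library(table)
for unit in library.records:
    print(f"rule {unit.rule_id:2d}  {unit.polymer_class:10s} "
          f"{'+'.join(unit.monomer_ids):28s} {unit.smiles}")
```

prints

```
caprolactam      {'lactam': 1}
adipic_acid      {'di/polycarboxylic acid': 2}
hmda             {'di/polyamine': 2, 'primary di/polyamine': 2}
ethylene_glycol  {'di/polyol (include thiol)': 2, 'di/polyol (without thiol)': 2}

rule  9  polyester  adipic_acid+ethylene_glycol  *OCCOC(=O)CCCCC(*)=O
rule 10  polyester  ethylene_glycol              *OCCOC(*)=O
rule 16  polyamide  caprolactam                  *NCCCCCC(*)=O
rule 19  polyamide  adipic_acid+hmda             *NCCCCCCNC(=O)CCCCC(*)=O
```

Reading the output: caprolactam ring-opens to the nylon-6 repeating unit
(rule 16); adipic acid + hexamethylenediamine condense to nylon-6,6
(rule 19, losing one OH heavy atom per amide linkage); ethylene glycol gives
both the PET-precursor polyester with adipic acid (rule 9) and a
polycarbonate with carbon monoxide as the built-in phosgene equivalent
(rule 10). HMDA never meets adipic acid under the ester rule because the
pools are class-gated.

The same pipeline is available from the shell:

```sh
polyforge fixtures --seed 1 --spec "vinyl=3,lactam=1,di/polyol (without thiol)=2" --out monomers.smi
polyforge classify --in monomers.smi --out classified.csv --summary-out summary.csv
polyforge generate --in monomers.smi --out polymers.csv
polyforge dedup    --in polymers.csv --linear-only --out unique.csv
polyforge evaluate --ref ref.smi --gen unique.csv --out cn.csv
```

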