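"""Independent brute-force enumeration oracle.

Re-derives reactant pools by raw substructure search and applies every
transform at every match combination, without any of the bookkeeping of the
classify/generate modules.  Used to cross-check library contents on small
inputs.
"""
import itertools

from rdkit import Chem
from rdkit.Chem import AllChem

STEP_CATEGORIES = {"polycondensation", "polyaddition", "addition-condensation"}


def _count(mol, smarts):
    patt = Chem.MolFromSmarts(smarts)
    return len({frozenset(m) for m in mol.GetSubstructMatches(patt, uniquify=False)})


def _is_member(mol, cls):
    if any(mol.HasSubstructMatch(Chem.MolFromSmarts(p)) for p in cls.forbidden_patterns):
        return False
    return all(
        cls.min_occurrence <= _count(mol, p) <= cls.max_occurrence
        for p in cls.detection_patterns
    )


def brute_force_library(monomers, registry, allow_self_pairs=False):
    """Set of (rule_id, monomer_id_tuple, canonical_smiles) triples.

    ``monomers`` is a sequence of (id, smiles) pairs.
    """
    mols = {ident: Chem.MolFromSmiles(smi) for ident, smi in monomers}
    out = set()
    for rule in registry.rules:
        classes = [registry.get_class(name) for name in rule.reactant_slots]
        pools = [
            [ident for ident, _ in monomers if _is_member(mols[ident], cls)]
            for cls in classes
        ]
        if (
            len(classes) == 2
            and classes[0].name != classes[1].name
            and rule.category in STEP_CATEGORIES
        ):
            pools = [
                [
                    ident
                    for ident in pool
                    if not any(
                        _count(mols[ident], p) >= 1
                        for p in classes[1 - i].detection_patterns
                    )
                ]
                for i, pool in enumerate(pools)
            ]
        if len(pools) == 1:
            combos = [(ident,) for ident in pools[0]]
        elif classes[0].name == classes[1].name:
            combos = list(itertools.combinations(pools[0], 2))
            if allow_self_pairs:
                combos += [(ident, ident) for ident in pools[0]]
        else:
            combos = list(itertools.product(pools[0], pools[1]))
        rxn = AllChem.ReactionFromSmarts(rule.transform)
        fixed = [Chem.MolFromSmiles(s) for s in rule.fixed_reactants]
        for combo in combos:
            reactants = tuple(mols[i] for i in combo) + tuple(fixed)
            for product_set in rxn.RunReactants(reactants):
                for product in product_set:
                    try:
                        Chem.SanitizeMol(product)
                    except Exception:
                        continue
                    out.add((rule.rule_id, combo, Chem.MolToSmiles(product)))
    return out
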