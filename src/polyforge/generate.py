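"""Repeating-unit generation by reaction-SMARTS enumeration.

For every rule, all applicable monomer combinations are drawn from the
pre-computed classification table and the rule's transform is applied at
every matching site combination.  Products are repeating units written with
wildcard (*) attachment atoms.  Chemically identical products arising from
equivalent sites of the *same* reactant set are collapsed; regioisomerically
distinct products (head-head vs head-tail dyads, alternative epoxide opening
directions, ...) are kept as separate records.  Everything is deterministic:
records are ordered by rule id, then the input order of the monomers, then a
site index, and no randomness enters anywhere.
"""
from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd
from rdkit import Chem

from ._chem import mol_from_smiles, wildcard_count
from .classify import ClassificationTable, MonomerRecord, count_functional_groups
from .registry import ReactionRuleDef, Registry, STEP_GROWTH_CATEGORIES

__all__ = [
    "RepeatUnit",
    "PolymerLibrary",
    "enumerate_reactant_sets",
    "apply_rule",
    "generate_library",
]

logger = logging.getLogger(__name__)


@dataclass
class RepeatUnit:
    """One generated repeating unit with its provenance."""

    smiles: str  # canonical SMILES with wildcard attachment atoms
    rule_id: int
    monomer_ids: tuple[str, ...]
    polymer_class: str
    site_index: int  # disambiguates regioisomeric products of one reactant set

    @property
    def n_attachment_points(self) -> int:
        return wildcard_count(mol_from_smiles(self.smiles))


@dataclass
class PolymerLibrary:
    """An ordered collection of repeating units.

    ``provenance_distinct_count`` counts records where identical structures
    from different reactant sets (or different sites of one set) are kept
    apart; ``structure_distinct_count`` counts distinct canonical structures.
    """

    records: list[RepeatUnit] = field(default_factory=list)

    @property
    def provenance_distinct_count(self) -> int:
        return len(self.records)

    @property
    def structure_distinct_count(self) -> int:
        return len({r.smiles for r in self.records})

    def by_class(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for rec in self.records:
            out[rec.polymer_class] = out.get(rec.polymer_class, 0) + 1
        return out

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "repeat_smiles": [r.smiles for r in self.records],
                "polymer_class": [r.polymer_class for r in self.records],
                "rule_id": [r.rule_id for r in self.records],
                "monomer_id_1": [r.monomer_ids[0] for r in self.records],
                "monomer_id_2": [
                    r.monomer_ids[1] if len(r.monomer_ids) > 1 else "" for r in self.records
                ],
                "site_index": [r.site_index for r in self.records],
            }
        )


def _cross_reactive(record: MonomerRecord, partner_patterns: Sequence[str]) -> bool:
    mol = record.mol()
    return any(count_functional_groups(mol, p) >= 1 for p in partner_patterns)


def enumerate_reactant_sets(
    classified: ClassificationTable,
    rule: ReactionRuleDef,
    allow_self_pairs: bool = False,
) -> list[tuple[MonomerRecord, ...]]:
    """All applicable monomer tuples for ``rule``, in deterministic order.

    One-slot rules yield one tuple per qualifying monomer; two-slot rules
    with distinct classes yield the cartesian product of the two pools;
    two-slot rules whose slots name the same class yield unordered distinct
    pairs (self-pairs only with ``allow_self_pairs``, since an A+A bipolymer
    duplicates the homopolymer chemistry of the one-slot rules).

    For step-growth rules pairing two *different* classes, a monomer that
    also carries the partner slot's reactive group is incompatible (it would
    self-react) and is dropped from the pool.
    """
    registry = classified.registry
    slot_classes = [registry.get_class(name) for name in rule.reactant_slots]
    pools = [classified.members(cls.name) for cls in slot_classes]

    if len(slot_classes) == 2 and slot_classes[0].name != slot_classes[1].name:
        if rule.category in STEP_GROWTH_CATEGORIES:
            pools = [
                [
                    rec
                    for rec in pool
                    if not _cross_reactive(rec, slot_classes[1 - i].detection_patterns)
                ]
                for i, pool in enumerate(pools)
            ]

    if len(pools) == 1:
        return [(rec,) for rec in pools[0]]
    if slot_classes[0].name == slot_classes[1].name:
        pairs = list(itertools.combinations(pools[0], 2))
        if allow_self_pairs:
            pairs += [(rec, rec) for rec in pools[0]]
            pairs.sort(key=lambda pair: (pools[0].index(pair[0]), pools[0].index(pair[1])))
        return pairs
    return list(itertools.product(pools[0], pools[1]))


def apply_rule(
    rule: ReactionRuleDef,
    monomers: Sequence[Chem.Mol],
    monomer_ids: Optional[Sequence[str]] = None,
) -> list[RepeatUnit]:
    """Apply one rule's transform to one reactant set.

    Returns all symmetry-distinct sanitized products over all matching site
    combinations.  Products that fail sanitization (valence-impossible
    intermediates on exotic inputs) are skipped with a logged warning.
    """
    if monomer_ids is None:
        monomer_ids = tuple(f"r{i}" for i in range(len(monomers)))
    monomer_ids = tuple(monomer_ids)
    reactants = list(monomers) + [mol_from_smiles(s) for s in rule.fixed_reactants]
    rxn = rule.reaction()
    if rxn.GetNumReactantTemplates() != len(reactants):
        raise ValueError(
            f"rule {rule.rule_id} expects {rxn.GetNumReactantTemplates()} reactants, "
            f"got {len(reactants)}"
        )
    products = rxn.RunReactants(tuple(reactants))
    units: list[RepeatUnit] = []
    seen: set[str] = set()
    for product_set in products:
        for product in product_set:
            try:
                Chem.SanitizeMol(product)
                smiles = Chem.MolToSmiles(product)
            except Exception as exc:
                logger.warning(
                    "generate: rule %d on %s: product skipped (%s)",
                    rule.rule_id,
                    "+".join(monomer_ids),
                    exc,
                )
                continue
            if smiles in seen:
                continue
            if wildcard_count(product) < 2:
                logger.warning(
                    "generate: rule %d on %s: product %s has < 2 attachment points, skipped",
                    rule.rule_id,
                    "+".join(monomer_ids),
                    smiles,
                )
                continue
            seen.add(smiles)
            units.append(
                RepeatUnit(
                    smiles=smiles,
                    rule_id=rule.rule_id,
                    monomer_ids=monomer_ids,
                    polymer_class=rule.polymer_class,
                    site_index=len(units),
                )
            )
    return units


def generate_library(
    classified: ClassificationTable,
    registry: Optional[Registry] = None,
    class_filter: Optional[set[str]] = None,
    allow_self_pairs: bool = False,
) -> PolymerLibrary:
    """Run every applicable (rule, reactant set) combination.

    ``class_filter`` restricts generation to the named polymer classes; an
    empty classification table yields an empty library.
    """
    registry = registry if registry is not None else classified.registry
    records: list[RepeatUnit] = []
    for rule in sorted(registry.rules, key=lambda r: r.rule_id):
        if class_filter is not None and rule.polymer_class not in class_filter:
            continue
        for combo in enumerate_reactant_sets(classified, rule, allow_self_pairs=allow_self_pairs):
            units = apply_rule(
                rule,
                [rec.mol() for rec in combo],
                monomer_ids=[rec.monomer_id for rec in combo],
            )
            records.extend(units)
    return PolymerLibrary(records=records)
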