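"""Monomer classification by substructure matching.

Each input molecule is assigned to zero or more of the 19 monomer classes by
counting symmetry-distinct matches of the class-specific polymerizable
groups and testing the counts against the class occurrence bounds.
Multi-class membership is allowed and expected (a thiol-free diol belongs to
both diol classes).  Classification is a pure function of the canonical
structure and the registry: the way the input SMILES is written does not
change the result.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd
from rdkit import Chem

from ._chem import compile_smarts, mol_from_smiles
from .registry import MonomerClassDef, Registry

__all__ = [
    "MonomerRecord",
    "ClassificationTable",
    "count_functional_groups",
    "classify_molecule",
    "screen_library",
]

logger = logging.getLogger(__name__)


def count_functional_groups(molecule: Chem.Mol, pattern: str) -> int:
    """Count symmetry-distinct matches of ``pattern`` in ``molecule``.

    Overlapping matches hitting the same atom set (e.g. the two directions of
    a symmetric pattern) are counted once.
    """
    query = compile_smarts(pattern)
    matches = molecule.GetSubstructMatches(query, uniquify=False, maxMatches=10000)
    return len({frozenset(match) for match in matches})


@dataclass
class MonomerRecord:
    """Classification result for one input molecule."""

    monomer_id: str
    smiles: str  # canonical SMILES; empty for parse failures
    class_assignments: dict[str, int] = field(default_factory=dict)
    excluded: bool = False
    exclusion_reason: Optional[str] = None
    error: Optional[str] = None

    def mol(self) -> Chem.Mol:
        return mol_from_smiles(self.smiles)

    def in_class(self, name: str) -> bool:
        return name in self.class_assignments


def _matches_class(mol: Chem.Mol, cls: MonomerClassDef) -> Optional[int]:
    """Occurrence count of the class-specific group, or None if not a member.

    Membership requires every detection pattern count within bounds and no
    forbidden pattern present; the reported count is that of the first
    (primary) detection pattern.
    """
    for pattern in cls.forbidden_patterns:
        if mol.HasSubstructMatch(compile_smarts(pattern)):
            return None
    counts = [count_functional_groups(mol, p) for p in cls.detection_patterns]
    if all(cls.min_occurrence <= c <= cls.max_occurrence for c in counts):
        return counts[0]
    return None


def classify_molecule(
    smiles: str, registry: Registry, monomer_id: str = "m000001"
) -> MonomerRecord:
    """Classify a single molecule into the registry's monomer classes.

    Raises ValueError on an unparseable SMILES.  If any registry-level
    exclusion pattern matches, the record is flagged ``excluded`` and carries
    no class assignments.
    """
    mol = mol_from_smiles(smiles)
    canonical = Chem.MolToSmiles(mol)
    for pattern in registry.exclusion_patterns:
        if mol.HasSubstructMatch(compile_smarts(pattern)):
            return MonomerRecord(
                monomer_id=monomer_id,
                smiles=canonical,
                excluded=True,
                exclusion_reason=f"matches exclusion pattern {pattern}",
            )
    assignments = {}
    for cls in registry.monomer_classes:
        count = _matches_class(mol, cls)
        if count is not None:
            assignments[cls.name] = count
    return MonomerRecord(monomer_id=monomer_id, smiles=canonical, class_assignments=assignments)


@dataclass
class ClassificationTable:
    """Per-molecule classification records plus the registry that made them."""

    records: list[MonomerRecord]
    registry: Registry

    @property
    def errors(self) -> list[MonomerRecord]:
        return [r for r in self.records if r.error is not None]

    @property
    def classified(self) -> list[MonomerRecord]:
        return [r for r in self.records if r.error is None]

    def members(self, class_name: str) -> list[MonomerRecord]:
        """Records assigned to ``class_name``, in input order."""
        return [r for r in self.classified if not r.excluded and r.in_class(class_name)]

    def class_counts(self) -> dict[str, int]:
        """Per-class member counts, one entry per registry class."""
        return {cls.name: len(self.members(cls.name)) for cls in self.registry.monomer_classes}

    def summary(self) -> pd.DataFrame:
        """Per-class member counts as a two-column table."""
        counts = self.class_counts()
        return pd.DataFrame(
            {"monomer class": list(counts), "no. of compounds": list(counts.values())}
        )

    def to_dataframe(self) -> pd.DataFrame:
        """One row per input molecule with one count column per class."""
        class_names = self.registry.class_names
        rows = []
        for rec in self.records:
            row = {
                "monomer_id": rec.monomer_id,
                "smiles": rec.smiles,
                "excluded": rec.excluded,
                "exclusion_reason": rec.exclusion_reason or "",
                "error": rec.error or "",
            }
            for name in class_names:
                row[name] = rec.class_assignments.get(name, 0)
            rows.append(row)
        return pd.DataFrame(rows)


def screen_library(
    smiles_list: Iterable[Sequence[str]], registry: Registry
) -> ClassificationTable:
    """Classify a list of ``(monomer_id, smiles)`` pairs.

    Unparseable entries become error records; processing continues for the
    rest of the list.  Deterministic given input order.
    """
    records: list[MonomerRecord] = []
    for monomer_id, smiles in smiles_list:
        try:
            records.append(classify_molecule(smiles, registry, monomer_id=monomer_id))
        except ValueError as exc:
            logger.warning("classify: %s (%s): %s", monomer_id, smiles, exc)
            records.append(MonomerRecord(monomer_id=monomer_id, smiles="", error=str(exc)))
    return ClassificationTable(records=records, registry=registry)
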