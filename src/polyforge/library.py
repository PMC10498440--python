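"""Library post-processing: canonicalization, dedup, linear filter.

Structural identity is canonical-SMILES equality of the repeating unit as
written, attachment points included.  Shifted-register equivalence of repeat
units (*OC(=O)R* vs the same infinite chain cut one bond later) is
deliberately NOT collapsed: the unit string, wildcards and all, is the
identity.  Wildcard atoms are kept through canonicalization rather than
capped, because the attachment topology is part of that identity.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Union

import pandas as pd
from rdkit import Chem

from ._chem import mol_from_smiles, wildcard_count
from .generate import PolymerLibrary, RepeatUnit

__all__ = [
    "CanonicalRepeatUnit",
    "canonicalize_repeat_unit",
    "dedup_library",
    "filter_linear",
]

logger = logging.getLogger(__name__)


@dataclass
class CanonicalRepeatUnit:
    """One structurally unique repeating unit."""

    canonical_smiles: str
    polymer_class: str
    n_attachment_points: int
    source_count: int  # number of provenance records collapsing to this structure


def canonicalize_repeat_unit(smiles: str) -> str:
    """Canonical wildcard-atom SMILES, independent of input atom ordering."""
    return Chem.MolToSmiles(mol_from_smiles(smiles))


def dedup_library(
    library: Union[PolymerLibrary, Iterable[RepeatUnit]]
) -> list[CanonicalRepeatUnit]:
    """Collapse a library to one record per canonical structure.

    The sum of ``source_count`` over the output equals the input record
    count, and the output order is lexicographic in the canonical SMILES, so
    the result is invariant under permutation of the input.
    """
    records = library.records if isinstance(library, PolymerLibrary) else list(library)
    groups: dict[str, CanonicalRepeatUnit] = {}
    for rec in records:
        # Accept provenance records and already-canonical units alike, so
        # dedup(dedup(L)) == dedup(L) holds literally.
        smiles = rec.canonical_smiles if isinstance(rec, CanonicalRepeatUnit) else rec.smiles
        weight = rec.source_count if isinstance(rec, CanonicalRepeatUnit) else 1
        canonical = canonicalize_repeat_unit(smiles)
        if canonical in groups:
            unit = groups[canonical]
            unit.source_count += weight
            if rec.polymer_class != unit.polymer_class:
                # Rare cross-class structural collision; keep the
                # lexicographically first label for determinism.
                kept = min(unit.polymer_class, rec.polymer_class)
                logger.warning(
                    "dedup: %s generated as both %s and %s; labeling %s",
                    canonical,
                    unit.polymer_class,
                    rec.polymer_class,
                    kept,
                )
                unit.polymer_class = kept
        else:
            groups[canonical] = CanonicalRepeatUnit(
                canonical_smiles=canonical,
                polymer_class=rec.polymer_class,
                n_attachment_points=wildcard_count(mol_from_smiles(canonical)),
                source_count=weight,
            )
    return [groups[smiles] for smiles in sorted(groups)]


def filter_linear(units: Iterable[CanonicalRepeatUnit]) -> list[CanonicalRepeatUnit]:
    """Keep exactly the units with two attachment points.

    Two asterisks mean a linear homopolymer or strictly alternating
    copolymer; units with more attachment points would require branching.
    """
    return [u for u in units if u.n_attachment_points == 2]


def units_to_dataframe(units: Iterable[CanonicalRepeatUnit]) -> pd.DataFrame:
    units = list(units)
    return pd.DataFrame(
        {
            "canonical_smiles": [u.canonical_smiles for u in units],
            "polymer_class": [u.polymer_class for u in units],
            "n_attachment_points": [u.n_attachment_points for u in units],
            "source_count": [u.source_count for u in units],
        }
    )
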