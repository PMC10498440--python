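"""Shared RDKit helpers: cached SMARTS compilation, heavy-atom counting."""
from __future__ import annotations

from functools import lru_cache

from rdkit import Chem, RDLogger
from rdkit.Chem import AllChem

# RDKit is chatty about query atoms in product templates; those messages are
# expected for the shipped transforms and would drown real warnings.
RDLogger.DisableLog("rdApp.info")
RDLogger.DisableLog("rdApp.warning")


@lru_cache(maxsize=2048)
def compile_smarts(pattern: str) -> Chem.Mol:
    """Compile a SMARTS pattern, raising ValueError naming the pattern."""
    query = Chem.MolFromSmarts(pattern)
    if query is None:
        raise ValueError(f"invalid SMARTS pattern: {pattern!r}")
    return query


@lru_cache(maxsize=256)
def compile_reaction(transform: str) -> AllChem.ChemicalReaction:
    """Compile a reaction SMARTS, raising ValueError naming the transform."""
    try:
        rxn = AllChem.ReactionFromSmarts(transform)
    except Exception as exc:  # RDKit raises bare RuntimeError subclasses
        raise ValueError(f"invalid reaction SMARTS: {transform!r} ({exc})") from exc
    if rxn is None:
        raise ValueError(f"invalid reaction SMARTS: {transform!r}")
    rxn.Initialize()
    return rxn


def mol_from_smiles(smiles: str) -> Chem.Mol:
    """Parse and sanitize a SMILES string, raising ValueError on failure."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None or mol.GetNumAtoms() == 0:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    return mol


def heavy_atom_count(mol: Chem.Mol) -> int:
    """Number of heavy (non-H, non-wildcard) atoms."""
    return sum(1 for atom in mol.GetAtoms() if atom.GetAtomicNum() > 1)


def wildcard_count(mol: Chem.Mol) -> int:
    """Number of wildcard (attachment-point) atoms."""
    return sum(1 for atom in mol.GetAtoms() if atom.GetAtomicNum() == 0)
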