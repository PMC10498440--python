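"""Coverage/novelty evaluation of a generated polymer set against a reference.

A repeating unit with two attachment points is turned into a macrocyclic
oligomer (default ten copies joined head-to-tail and ring-closed) so that
its fingerprint reflects the periodic chain environment rather than
artificial end groups.  Each macrocycle is hashed to a 2048-bit circular
(Morgan) fingerprint of radius 3, pairwise Tanimoto similarities between the
reference set P and the generated set Q are computed, and for a grid of
thresholds gamma:

* coverage(gamma)  = % of p in P whose best match in Q has T >= gamma,
* novelty(gamma)   = % of q in Q whose best match in P has T <  gamma.

Sweeping gamma from 0 to 1 traces the coverage-novelty (CN) curve.  Ties
T == gamma count toward coverage so that the two quantities complement one
event exactly.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator

from ._chem import mol_from_smiles
from .library import CanonicalRepeatUnit

__all__ = [
    "FingerprintConfig",
    "CNPoint",
    "build_cyclic_oligomer",
    "fingerprint",
    "fingerprint_units",
    "tanimoto",
    "max_similarity_profile",
    "coverage",
    "novelty",
    "cn_curve",
    "default_gamma_grid",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FingerprintConfig:
    """Circular-fingerprint and oligomer settings."""

    radius: int = 3
    n_bits: int = 2048
    n_units: int = 10  # oligomer length used for macrocyclization

    def __post_init__(self) -> None:
        if self.radius < 1:
            raise ValueError("radius must be >= 1")
        if self.n_bits < 1 or self.n_bits & (self.n_bits - 1):
            raise ValueError("n_bits must be a positive power of two")
        if self.n_units < 1:
            raise ValueError("n_units must be >= 1")


@dataclass(frozen=True)
class CNPoint:
    """One point of the coverage-novelty curve."""

    gamma: float
    coverage_pct: float
    novelty_pct: float


def build_cyclic_oligomer(
    unit: Union[CanonicalRepeatUnit, str], n_units: int = 10
) -> Chem.Mol:
    """Join ``n_units`` copies of a repeat unit head-to-tail and close the ring.

    The atoms adjacent to the two wildcard positions are bonded by single
    bonds between consecutive copies, the wildcards are removed, and a final
    single bond closes the macrocycle.  The result has exactly
    ``n_units * heavy(unit)`` heavy atoms.

    Raises ValueError for units without exactly two attachment points or
    when the ring closure cannot be sanitized.
    """
    smiles = unit.canonical_smiles if isinstance(unit, CanonicalRepeatUnit) else unit
    mol = mol_from_smiles(smiles)
    wildcards = [a.GetIdx() for a in mol.GetAtoms() if a.GetAtomicNum() == 0]
    if len(wildcards) != 2:
        raise ValueError(
            f"unit {smiles!r} has {len(wildcards)} attachment points, expected 2"
        )
    neighbors = []
    for idx in wildcards:
        nbrs = mol.GetAtomWithIdx(idx).GetNeighbors()
        if len(nbrs) != 1:
            raise ValueError(f"unit {smiles!r}: wildcard atom has {len(nbrs)} neighbors")
        neighbors.append(nbrs[0].GetIdx())
    head, tail = neighbors

    core = Chem.RWMol(mol)
    for idx in sorted(wildcards, reverse=True):
        core.RemoveAtom(idx)
        head -= head > idx
        tail -= tail > idx
    core_natoms = core.GetNumAtoms()
    if n_units == 1 and head == tail:
        raise ValueError(f"unit {smiles!r}: cannot self-close a single atom at n_units=1")

    ring = Chem.RWMol()
    first_head = last_tail = None
    for i in range(n_units):
        offset = ring.GetNumAtoms()
        ring.InsertMol(core)
        if last_tail is None:
            first_head = offset + head
        else:
            ring.AddBond(last_tail, offset + head, Chem.BondType.SINGLE)
        last_tail = offset + tail
    ring.AddBond(last_tail, first_head, Chem.BondType.SINGLE)
    out = ring.GetMol()
    try:
        Chem.SanitizeMol(out)
    except Exception as exc:
        raise ValueError(f"unit {smiles!r}: macrocycle fails sanitization ({exc})") from exc
    return out


def _generator(config: FingerprintConfig):
    return rdFingerprintGenerator.GetMorganGenerator(
        radius=config.radius, fpSize=config.n_bits
    )


def fingerprint(structure: Chem.Mol, config: FingerprintConfig = FingerprintConfig()) -> np.ndarray:
    """Circular-fingerprint bit vector of a structure as a 0/1 uint8 array."""
    fp = _generator(config).GetFingerprint(structure)
    return np.frombuffer(bytes(fp.ToBitString(), "ascii"), dtype=np.uint8) - ord("0")


def fingerprint_units(
    units: Iterable[Union[CanonicalRepeatUnit, str]],
    config: FingerprintConfig = FingerprintConfig(),
) -> tuple[np.ndarray, list[str]]:
    """Macrocyclize and fingerprint a set of repeat units.

    Units whose macrocyclization or sanitization fails (for instance an
    aromatic attachment whose ring closure breaks valence) are reported and
    skipped rather than aborting the run.  Returns the stacked fingerprint
    matrix and the list of skipped unit SMILES.
    """
    rows, skipped = [], []
    for unit in units:
        smiles = unit.canonical_smiles if isinstance(unit, CanonicalRepeatUnit) else unit
        try:
            macro = build_cyclic_oligomer(unit, n_units=config.n_units)
        except ValueError as exc:
            logger.warning("evaluate: skipping %s (%s)", smiles, exc)
            skipped.append(smiles)
            continue
        rows.append(fingerprint(macro, config))
    matrix = np.vstack(rows) if rows else np.zeros((0, config.n_bits), dtype=np.uint8)
    return matrix, skipped


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """Tanimoto similarity |a AND b| / |a OR b| of two equal-length bit vectors."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError(f"bit-vector length mismatch: {a.shape} vs {b.shape}")
    union = int(np.count_nonzero(a | b))
    if union == 0:
        return 0.0
    return int(np.count_nonzero(a & b)) / union


def _as_matrix(fps: Union[np.ndarray, Sequence[np.ndarray]]) -> np.ndarray:
    matrix = np.asarray(fps, dtype=np.int64)
    if matrix.ndim != 2:
        raise ValueError("expected a 2-D array of fingerprints (one row per polymer)")
    return matrix


def max_similarity_profile(
    targets: Union[np.ndarray, Sequence[np.ndarray]],
    pool: Union[np.ndarray, Sequence[np.ndarray]],
) -> np.ndarray:
    """For each fingerprint in ``targets``, its best Tanimoto match in ``pool``.

    Vectorized over the full pairwise similarity matrix: with popcounts
    |a AND b| = a.b and |a OR b| = |a| + |b| - a.b.
    """
    T = _as_matrix(targets)
    P = _as_matrix(pool)
    if T.shape[0] == 0 or P.shape[0] == 0:
        raise ValueError("empty fingerprint set")
    if T.shape[1] != P.shape[1]:
        raise ValueError("fingerprint length mismatch between sets")
    inter = T @ P.T
    union = T.sum(axis=1)[:, None] + P.sum(axis=1)[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(union > 0, inter / np.maximum(union, 1), 0.0)
    return sim.max(axis=1)


def coverage(reference_set, generated_set, gamma: float) -> float:
    """Percentage of reference polymers with a best match >= gamma in the generated set."""
    best = max_similarity_profile(reference_set, generated_set)
    return 100.0 * float(np.count_nonzero(best >= gamma)) / best.size


def novelty(reference_set, generated_set, gamma: float) -> float:
    """Percentage of generated polymers with a best match < gamma in the reference set."""
    best = max_similarity_profile(generated_set, reference_set)
    return 100.0 * float(np.count_nonzero(best < gamma)) / best.size


def default_gamma_grid(step: float = 0.1) -> list[float]:
    """The threshold grid {0, step, ..., 1}."""
    if not 0 < step <= 1:
        raise ValueError("gamma step must lie in (0, 1]")
    n = int(round(1.0 / step))
    return [round(i * step, 10) for i in range(n + 1)]


def cn_curve(
    reference_set,
    generated_set,
    gamma_grid: Optional[Sequence[float]] = None,
    config: FingerprintConfig = FingerprintConfig(),
) -> list[CNPoint]:
    """Coverage and novelty along a sorted threshold grid.

    Accepts fingerprint matrices or lists of repeat-unit SMILES (which are
    then macrocyclized with ``config`` and fingerprinted).  Coverage is
    non-increasing and novelty non-decreasing along the grid.
    """
    if gamma_grid is None:
        gamma_grid = default_gamma_grid()
    gamma_grid = list(gamma_grid)
    if any(g < 0 or g > 1 for g in gamma_grid):
        raise ValueError("gamma grid values must lie in [0, 1]")
    if gamma_grid != sorted(gamma_grid):
        raise ValueError("gamma grid must be sorted")

    def prepare(item):
        if isinstance(item, np.ndarray):
            return item
        items = list(item)
        if items and isinstance(items[0], (str, CanonicalRepeatUnit)):
            matrix, _ = fingerprint_units(items, config)
            return matrix
        return np.asarray(items)

    P = prepare(reference_set)
    Q = prepare(generated_set)
    best_p = max_similarity_profile(P, Q)
    best_q = max_similarity_profile(Q, P)
    points = []
    for gamma in gamma_grid:
        cov = 100.0 * float(np.count_nonzero(best_p >= gamma)) / best_p.size
        nov = 100.0 * float(np.count_nonzero(best_q < gamma)) / best_q.size
        points.append(CNPoint(gamma=gamma, coverage_pct=cov, novelty_pct=nov))
    return points
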