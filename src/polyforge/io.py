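"""File I/O: SMILES lists and the CSV interchange formats between stages."""
from __future__ import annotations

import logging
from pathlib import Path
from typing import Union

import pandas as pd

from .generate import PolymerLibrary, RepeatUnit
from .library import CanonicalRepeatUnit

__all__ = [
    "read_smiles_file",
    "read_library_csv",
    "read_units_csv",
    "write_units_csv",
]

logger = logging.getLogger(__name__)


def read_smiles_file(path: Union[str, Path]) -> list[tuple[str, str]]:
    """Read a .smi file: one record per line, ``SMILES[<TAB>ID]``.

    Blank lines and ``#`` comment lines are skipped; ids are autogenerated
    as ``m<record number>`` when absent.  Order is preserved.
    """
    path = Path(path)
    records: list[tuple[str, str]] = []
    with open(path, encoding="utf-8") as handle:
        for line in handle:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split(None, 1)
            smiles = fields[0]
            ident = fields[1].strip() if len(fields) > 1 else f"m{len(records) + 1:06d}"
            records.append((ident, smiles))
    if not records:
        logger.warning("read_smiles_file: %s contains no records", path)
    return records


def read_library_csv(path: Union[str, Path]) -> PolymerLibrary:
    """Read a generated-library CSV back into a PolymerLibrary."""
    frame = pd.read_csv(path, keep_default_na=False)
    records = [
        RepeatUnit(
            smiles=row["repeat_smiles"],
            rule_id=int(row["rule_id"]),
            monomer_ids=tuple(
                m for m in (str(row["monomer_id_1"]), str(row["monomer_id_2"])) if m
            ),
            polymer_class=row["polymer_class"],
            site_index=int(row["site_index"]),
        )
        for _, row in frame.iterrows()
    ]
    return PolymerLibrary(records=records)


def read_units_csv(path: Union[str, Path]) -> list[CanonicalRepeatUnit]:
    frame = pd.read_csv(path, keep_default_na=False)
    return [
        CanonicalRepeatUnit(
            canonical_smiles=row["canonical_smiles"],
            polymer_class=row["polymer_class"],
            n_attachment_points=int(row["n_attachment_points"]),
            source_count=int(row["source_count"]),
        )
        for _, row in frame.iterrows()
    ]


def write_units_csv(units, path: Union[str, Path]) -> None:
    from .library import units_to_dataframe

    units_to_dataframe(units).to_csv(path, index=False)
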