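"""Synthetic monomer sets with known class membership.

Real starting-molecule lists are curated by hand from vendor catalogues; for
testing and demonstration this module emits homologous-series members per
monomer class (alpha,omega-diols HO-(CH2)k-OH, diacids, diamines, linear
1-alkenes, lactams and lactones of varying ring size, diisocyanates, cyclic
anhydrides, ...) constructed so that classification provably assigns each
molecule its intended class.  Sampling of homologue indices is seeded and
fully deterministic.
"""
from __future__ import annotations

from typing import Sequence

import numpy as np

__all__ = ["generate_toy_monomer_set", "FAMILY_SIZES"]


def _vinyl(i: int) -> str:  # 1-alkenes
    return "C=C" + "C" * i


def _cyclic_olefin(i: int) -> str:  # cycloalkenes, ring size 5 + i
    return "C1=C" + "C" * (i + 2) + "C1"


def _epoxide(i: int) -> str:  # terminal alkyl epoxides
    return "C" * i + "C1CO1"


def _lactone(i: int) -> str:  # ring size 4 + i
    return "O=C1" + "C" * (i + 2) + "O1"


def _lactam(i: int) -> str:  # ring size 4 + i
    return "O=C1" + "C" * (i + 2) + "N1"


def _hydroxy_acid(i: int) -> str:  # HO-(CH2)k-COOH
    return "OC" + "C" * i + "C(=O)O"


def _amino_acid(i: int) -> str:  # H2N-(CH2)k-COOH
    return "NC" + "C" * i + "C(=O)O"


def _hindered_phenol(i: int) -> str:  # 2,6-dialkylphenols
    alkyl = "C" * (i + 1)
    return f"{alkyl}c1cccc({alkyl})c1O"


def _bis_halo_sulfone(i: int) -> str:
    halogen = ("Cl", "F", "Br", "I")[i]
    return f"{halogen}c1ccc(S(=O)(=O)c2ccc({halogen})cc2)cc1"


def _bis_fluoro_ketone(i: int) -> str:  # 4,4'-difluorobenzophenones, ring-alkylated
    extra = ("", "C", "CC", "CCC")[i]
    return f"{extra}c1cc(F)ccc1C(=O)c1ccc(F)cc1" if extra else "Fc1ccc(C(=O)c2ccc(F)cc2)cc1"


def _diepoxide(i: int) -> str:  # alkylene-bridged bis-epoxides
    return "C1OC1" + "C" * i + "C1CO1"


def _diacid(i: int) -> str:  # HOOC-(CH2)k-COOH, k >= 1
    return "OC(=O)" + "C" * (i + 1) + "C(=O)O"


def _dithiol(i: int) -> str:  # HS-(CH2)k-SH
    return "S" + "C" * (i + 2) + "S"


def _diol(i: int) -> str:  # HO-(CH2)k-OH
    return "O" + "C" * (i + 2) + "O"


def _sec_diamine(i: int) -> str:  # N,N'-dimethyl alkanediamines
    return "CN" + "C" * (i + 2) + "NC"


def _pri_diamine(i: int) -> str:  # H2N-(CH2)k-NH2
    return "N" + "C" * (i + 2) + "N"


def _diisocyanate(i: int) -> str:  # OCN-(CH2)k-NCO
    return "O=C=N" + "C" * (i + 2) + "N=C=O"


def _cyclic_anhydride(i: int) -> str:  # succinic, glutaric, ... ring size 5 + i
    return "O=C1" + "C" * (i + 2) + "C(=O)O1"


def _dianhydride(i: int) -> str:
    if i == 0:  # pyromellitic dianhydride
        return "O=C1OC(=O)c2cc3c(cc12)C(=O)OC3=O"
    # alkylene-bridged bis(succinic anhydride)s
    return "O=C1OC(=O)CC1" + "C" * i + "C1CC(=O)OC1=O"


_FAMILIES = {
    "vinyl": (_vinyl, 16),
    "cyclic olefin": (_cyclic_olefin, 8),
    "epoxide": (_epoxide, 12),
    "lactone": (_lactone, 6),
    "lactam": (_lactam, 6),
    "hydroxy carboxylic acid": (_hydroxy_acid, 10),
    "amino acid": (_amino_acid, 10),
    "hindered phenol": (_hindered_phenol, 6),
    "bis(p-halogenated aryl)sulfone": (_bis_halo_sulfone, 4),
    "bis(p-fluoroaryl)ketone": (_bis_fluoro_ketone, 4),
    "di/polyepoxide": (_diepoxide, 8),
    "di/polycarboxylic acid": (_diacid, 12),
    "di/polyol (include thiol)": (_dithiol, 10),
    "di/polyol (without thiol)": (_diol, 10),
    "di/polyamine": (_sec_diamine, 10),
    "primary di/polyamine": (_pri_diamine, 10),
    "di/polyisocyanate": (_diisocyanate, 10),
    "cyclic carboxylic acid anhydride": (_cyclic_anhydride, 5),
    "di/polycyclic carboxylic acid anhydride": (_dianhydride, 8),
}

#: Number of distinct homologues available per class.
FAMILY_SIZES = {name: size for name, (_, size) in _FAMILIES.items()}


def generate_toy_monomer_set(
    seed: int, spec: dict[str, int]
) -> list[tuple[str, str]]:
    """Emit ``(monomer_id, smiles)`` pairs per the requested class counts.

    ``spec`` maps class name -> number of molecules; each class contributes
    distinct members of its homologous series, chosen by a seeded RNG (the
    dithiols stand in for the thiol-bearing diol class so the two diol
    classes stay distinguishable).  Deterministic given ``seed``; classes are
    processed in sorted-name order so dict ordering does not matter.
    """
    rng = np.random.default_rng(seed)
    out: list[tuple[str, str]] = []
    counter = 0
    for name in sorted(spec):
        count = spec[name]
        if name not in _FAMILIES:
            raise ValueError(f"unknown monomer class: {name!r}")
        builder, size = _FAMILIES[name]
        if count > size:
            raise ValueError(
                f"class {name!r} has only {size} distinct homologues, {count} requested"
            )
        indices = rng.choice(size, size=count, replace=False)
        for i in indices:
            counter += 1
            out.append((f"m{counter:06d}", builder(int(i))))
    return out
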