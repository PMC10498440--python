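import pytest
from rdkit import Chem

import polyforge as pf
from polyforge._chem import heavy_atom_count, mol_from_smiles
from polyforge.library import canonicalize_repeat_unit

from helpers_brute import brute_force_library


def _mols(*smiles):
    return [Chem.MolFromSmiles(s) for s in smiles]


# ---------------------------------------------------------------- enumeration


def test_one_slot_rule_yields_one_tuple_per_monomer(registry):
    table = pf.screen_library([("A", "C=C"), ("B", "C=CC")], registry)
    combos = pf.enumerate_reactant_sets(table, registry.get_rule(1))
    assert [tuple(r.monomer_id for r in c) for c in combos] == [("A",), ("B",)]


def test_same_class_pair_rule_yields_unordered_distinct_pairs(registry):
    table = pf.screen_library([("A", "C=C"), ("B", "C=CC")], registry)
    combos = pf.enumerate_reactant_sets(table, registry.get_rule(3))
    assert [tuple(r.monomer_id for r in c) for c in combos] == [("A", "B")]
    with_self = pf.enumerate_reactant_sets(table, registry.get_rule(3), allow_self_pairs=True)
    assert [tuple(r.monomer_id for r in c) for c in with_self] == [
        ("A", "A"),
        ("A", "B"),
        ("B", "B"),
    ]


def test_two_slot_rule_yields_cartesian_product(registry):
    table = pf.screen_library(
        [("X", "OC(=O)CCCCC(=O)O"), ("Y", "OCCO"), ("Z", "OCCCO")], registry
    )
    combos = pf.enumerate_reactant_sets(table, registry.get_rule(9))
    assert [tuple(r.monomer_id for r in c) for c in combos] == [("X", "Y"), ("X", "Z")]


def test_cross_reactive_monomer_dropped_from_step_rule(registry):
    # a diol that also bears isocyanate groups would self-react under the
    # polyurethane rule and must not enter either pool
    hybrid = "OCC(CO)CN=C=O"
    table = pf.screen_library(
        [("diol", hybrid), ("hdi", "O=C=NCCCCCCN=C=O"), ("eg", "OCCO")], registry
    )
    assert table.records[0].in_class("di/polyol (include thiol)")
    combos = pf.enumerate_reactant_sets(table, registry.get_rule(21))
    ids = {tuple(r.monomer_id for r in c) for c in combos}
    assert ids == {("hdi", "eg")}


def test_unknown_slot_class_is_a_configuration_error(registry):
    table = pf.screen_library([("A", "C=C")], registry)
    rule = pf.ReactionRuleDef(
        rule_id=99,
        polymer_class="polyolefin",
        category="addition chain polymerization",
        reactant_slots=["no such class"],
        transform="[CX3:1]=[CX3:2]>>*-[C:1][C:2]-*",
    )
    with pytest.raises(KeyError, match="no such class"):
        pf.enumerate_reactant_sets(table, rule)


# ------------------------------------------------------------ worked chemistry


@pytest.mark.parametrize(
    "rule_id, reactants, expected",
    [
        (1, ("C=C",), ["*CC*"]),  # polyethylene
        (16, ("O=C1CCCCCN1",), ["*C(=O)CCCCCN*"]),  # nylon-6 from caprolactam
        (17, ("NCCCCCC(=O)O",), ["*C(=O)CCCCCN*"]),  # nylon-6 from 6-aminohexanoic acid
        (
            19,
            ("OC(=O)CCCCC(=O)O", "NCCCCCCN"),
            ["*C(=O)CCCCC(=O)NCCCCCCN*"],  # nylon-6,6
        ),
        (
            21,
            ("O=C=NCCCCCCN=C=O", "OCCO"),
            ["*C(=O)NCCCCCCNC(=O)OCCO*"],  # polyurethane
        ),
        (6, ("O=C1CCCCCO1",), ["*C(=O)CCCCCO*"]),  # polycaprolactone
        (12, ("C1CO1",), ["*CCO*"]),  # poly(ethylene oxide)
    ],
)
def test_apply_rule_matches_hand_derived_repeat_units(registry, rule_id, reactants, expected):
    rule = registry.get_rule(rule_id)
    units = pf.apply_rule(rule, _mols(*reactants))
    got = sorted(u.smiles for u in units)
    assert got == sorted(canonicalize_repeat_unit(s) for s in expected)
    for unit in units:
        assert unit.polymer_class == rule.polymer_class


def test_apply_rule_keeps_regioisomers_distinct(registry):
    # propylene oxide opens in two directions -> two regioisomeric ethers
    units = pf.apply_rule(registry.get_rule(12), _mols("CC1CO1"))
    assert len(units) == 2
    assert len({u.smiles for u in units}) == 2
    assert [u.site_index for u in units] == [0, 1]


def test_apply_rule_collapses_equivalent_sites(registry):
    # ethylene's two match directions give the same product once
    units = pf.apply_rule(registry.get_rule(1), _mols("C=C"))
    assert len(units) == 1


# ------------------------------------------------------------------- library


def test_generate_library_class_filter(registry):
    table = pf.screen_library(
        [("A", "C=C"), ("B", "OCCO"), ("C", "OC(=O)CCCCC(=O)O")], registry
    )
    everything = pf.generate_library(table)
    esters_only = pf.generate_library(table, class_filter={"polyester"})
    assert {r.polymer_class for r in esters_only.records} == {"polyester"}
    assert {r.rule_id for r in esters_only.records} <= {6, 7, 8, 9, 10, 11}
    assert esters_only.provenance_distinct_count < everything.provenance_distinct_count


def test_single_lactam_gives_exactly_nylon6(registry):
    table = pf.screen_library([("cap", "O=C1CCCCCN1")], registry)
    library = pf.generate_library(table)
    assert [r.smiles for r in library.records] == [canonicalize_repeat_unit("*C(=O)CCCCCN*")]


def test_empty_table_gives_empty_library(registry):
    table = pf.screen_library([("x", "c1ccccc1")], registry)
    library = pf.generate_library(table)
    assert library.records == []
    assert library.provenance_distinct_count == 0


def test_heavy_atom_conservation(registry, toy_table, toy_library):
    """heavy(product) == sum heavy(reactants) - leaving-group atoms, exactly."""
    by_id = {r.monomer_id: r for r in toy_table.records}
    assert toy_library.records
    for record in toy_library.records:
        rule = registry.get_rule(record.rule_id)
        reactant_heavy = sum(heavy_atom_count(by_id[m].mol()) for m in record.monomer_ids)
        reactant_heavy += sum(
            heavy_atom_count(mol_from_smiles(s)) for s in rule.fixed_reactants
        )
        product_heavy = heavy_atom_count(mol_from_smiles(record.smiles))
        assert product_heavy == reactant_heavy - rule.heavy_atoms_lost, record


def test_attachment_point_counts(registry, toy_library):
    """Every product has >= 2 wildcards; one-slot homopolymers exactly 2."""
    for record in toy_library.records:
        n = record.n_attachment_points
        assert n >= 2
        rule = registry.get_rule(record.rule_id)
        if len(rule.reactant_slots) == 1:
            assert n == 2


def test_enumeration_is_monotone_in_the_input(registry):
    base = [("A", "C=C"), ("B", "OCCO"), ("C", "OC(=O)CCCCC(=O)O")]
    small = pf.generate_library(pf.screen_library(base, registry))
    large = pf.generate_library(pf.screen_library(base + [("D", "O=C1CCCCCN1")], registry))
    small_keys = {(r.rule_id, r.monomer_ids, r.smiles) for r in small.records}
    large_keys = {(r.rule_id, r.monomer_ids, r.smiles) for r in large.records}
    assert small_keys <= large_keys


def test_generation_is_deterministic(registry, toy_table):
    first = pf.generate_library(toy_table)
    second = pf.generate_library(toy_table)
    assert [
        (r.rule_id, r.monomer_ids, r.site_index, r.smiles) for r in first.records
    ] == [(r.rule_id, r.monomer_ids, r.site_index, r.smiles) for r in second.records]


@pytest.mark.parametrize("seed", range(5))
def test_matches_brute_force_oracle(registry, seed):
    """Library contents equal an independent brute-force enumeration."""
    import numpy as np

    from polyforge.fixtures import FAMILY_SIZES

    rng = np.random.default_rng(seed)
    names = sorted(FAMILY_SIZES)
    chosen = rng.choice(len(names), size=5, replace=False)
    spec = {names[i]: 2 for i in chosen}
    monomers = pf.generate_toy_monomer_set(seed, spec)
    assert len(monomers) <= 10
    library = pf.generate_library(pf.screen_library(monomers, registry))
    got = {(r.rule_id, r.monomer_ids, r.smiles) for r in library.records}
    expected = brute_force_library(monomers, registry)
    assert got == expected
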