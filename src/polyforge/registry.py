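"""Machine-readable registry of monomer classes and polymerization rules.

The registry is data, not code: the shipped defaults live in
``polyforge/data/rules.yaml`` and users can supply their own rules file with
the same schema.  It encodes

* 19 polymerizable monomer classes, each defined by one or more detection
  SMARTS patterns with occurrence bounds (chain-growth classes need a single
  polymerizable group; step-growth classes need 2-4, except the
  single-molecule bifunctional classes which need exactly one of each of two
  distinct groups), and
* 22 polymerization reaction rules spanning 7 polymer classes, each carrying
  a reaction SMARTS transform whose products are repeating units written with
  wildcard (*) attachment atoms.
"""
from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Union

import yaml

from ._chem import compile_reaction, compile_smarts, wildcard_count

__all__ = [
    "MonomerClassDef",
    "ReactionRuleDef",
    "Registry",
    "RegistryError",
    "ValidationIssue",
    "ValidationReport",
    "load_registry",
    "save_registry",
    "validate_registry",
    "POLYMER_CLASSES",
    "REACTION_CATEGORIES",
    "STEP_GROWTH_CATEGORIES",
]

POLYMER_CLASSES = frozenset(
    {
        "polyolefin",
        "polyester",
        "polyether",
        "polyamide",
        "polyimide",
        "polyurethane",
        "polyoxazolidone",
    }
)

REACTION_CATEGORIES = frozenset(
    {
        "addition chain polymerization",
        "ring-opening chain polymerization",
        "polycondensation",
        "polyaddition",
        "addition-condensation",
    }
)

#: Categories in which cross-reactive partner groups make a monomer
#: incompatible with a two-slot rule (see generate.enumerate_reactant_sets).
STEP_GROWTH_CATEGORIES = frozenset(
    {"polycondensation", "polyaddition", "addition-condensation"}
)


class RegistryError(ValueError):
    """Raised when a rules file fails validation."""


@dataclass
class MonomerClassDef:
    """One polymerizable monomer class.

    A molecule belongs to the class when, for every detection pattern, the
    number of symmetry-distinct substructure matches lies within
    ``[min_occurrence, max_occurrence]`` and no forbidden pattern matches.
    """

    name: str
    detection_patterns: list[str]
    min_occurrence: int
    max_occurrence: int
    growth_mode: str  # "chain" | "step"
    forbidden_patterns: list[str] = field(default_factory=list)


@dataclass
class ReactionRuleDef:
    """One polymerization reaction rule.

    ``transform`` is a reaction SMARTS whose reactant components (counting
    parenthesized groups as one component each) correspond, in order, to
    ``reactant_slots`` followed by ``fixed_reactants``.  Fixed reactants are
    co-monomers baked into the rule (carbon monoxide for the polycarbonate
    rule) rather than drawn from a monomer-class pool.

    ``leaving_group_heavy_atoms`` is the number of heavy atoms eliminated per
    linkage formed and ``linkages_formed`` the number of linkages per
    application, so every product of the rule satisfies
    ``heavy(product) == sum(heavy(reactants)) - leaving * linkages``.
    """

    rule_id: int
    polymer_class: str
    category: str
    reactant_slots: list[str]
    transform: str
    leaving_group_heavy_atoms: int = 0
    linkages_formed: int = 2
    fixed_reactants: list[str] = field(default_factory=list)

    def reaction(self):
        """The compiled RDKit ChemicalReaction for this rule."""
        return compile_reaction(self.transform)

    @property
    def heavy_atoms_lost(self) -> int:
        """Heavy atoms eliminated per transform application."""
        return self.leaving_group_heavy_atoms * self.linkages_formed


@dataclass
class Registry:
    """The full rule registry: monomer classes, reaction rules, exclusions."""

    monomer_classes: list[MonomerClassDef]
    rules: list[ReactionRuleDef]
    exclusion_patterns: list[str] = field(default_factory=list)
    version: int = 1

    def get_class(self, name: str) -> MonomerClassDef:
        for cls in self.monomer_classes:
            if cls.name == name:
                return cls
        raise KeyError(f"unknown monomer class: {name!r}")

    def get_rule(self, rule_id: int) -> ReactionRuleDef:
        for rule in self.rules:
            if rule.rule_id == rule_id:
                return rule
        raise KeyError(f"unknown rule id: {rule_id}")

    @property
    def class_names(self) -> list[str]:
        return [cls.name for cls in self.monomer_classes]

    @property
    def polymer_classes(self) -> set[str]:
        return {rule.polymer_class for rule in self.rules}


@dataclass
class ValidationIssue:
    scope: str  # "class" | "rule" | "registry"
    ident: str  # class name or rule id
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.scope} {self.ident}] {self.message}"


@dataclass
class ValidationReport:
    issues: list[ValidationIssue] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.issues

    def add(self, scope: str, ident, message: str) -> None:
        self.issues.append(ValidationIssue(scope, str(ident), message))


def _default_rules_path() -> Path:
    return Path(str(importlib.resources.files("polyforge.data") / "rules.yaml"))


def load_registry(config_path: Union[str, Path, None] = None) -> Registry:
    """Load the registry from ``config_path`` or the built-in defaults.

    Raises
    ------
    RegistryError
        If the rules file fails validation (e.g. malformed SMARTS); the error
        message names the offending rule ids and patterns.
    """
    path = Path(config_path) if config_path is not None else _default_rules_path()
    with open(path, encoding="utf-8") as handle:
        raw = yaml.safe_load(handle)
    registry = _registry_from_dict(raw)
    report = validate_registry(registry)
    if not report.ok:
        details = "; ".join(str(issue) for issue in report.issues)
        raise RegistryError(f"invalid rules file {path}: {details}")
    return registry


def _registry_from_dict(raw: dict) -> Registry:
    classes = [
        MonomerClassDef(
            name=entry["name"],
            detection_patterns=list(entry["detection_patterns"]),
            min_occurrence=int(entry["min_occurrence"]),
            max_occurrence=int(entry["max_occurrence"]),
            growth_mode=entry["growth_mode"],
            forbidden_patterns=list(entry.get("forbidden_patterns", [])),
        )
        for entry in raw.get("monomer_classes", [])
    ]
    rules = [
        ReactionRuleDef(
            rule_id=int(entry["rule_id"]),
            polymer_class=entry["polymer_class"],
            category=entry["category"],
            reactant_slots=list(entry["reactant_slots"]),
            transform=entry["transform"],
            leaving_group_heavy_atoms=int(entry.get("leaving_group_heavy_atoms", 0)),
            linkages_formed=int(entry.get("linkages_formed", 2)),
            fixed_reactants=list(entry.get("fixed_reactants", [])),
        )
        for entry in raw.get("rules", [])
    ]
    return Registry(
        monomer_classes=classes,
        rules=rules,
        exclusion_patterns=list(raw.get("exclusion_patterns", [])),
        version=int(raw.get("version", 1)),
    )


def _registry_to_dict(registry: Registry) -> dict:
    return {
        "version": registry.version,
        "monomer_classes": [
            {
                "name": cls.name,
                "growth_mode": cls.growth_mode,
                "min_occurrence": cls.min_occurrence,
                "max_occurrence": cls.max_occurrence,
                "detection_patterns": list(cls.detection_patterns),
                **(
                    {"forbidden_patterns": list(cls.forbidden_patterns)}
                    if cls.forbidden_patterns
                    else {}
                ),
            }
            for cls in registry.monomer_classes
        ],
        "rules": [
            {
                "rule_id": rule.rule_id,
                "polymer_class": rule.polymer_class,
                "category": rule.category,
                "reactant_slots": list(rule.reactant_slots),
                **(
                    {"fixed_reactants": list(rule.fixed_reactants)}
                    if rule.fixed_reactants
                    else {}
                ),
                "leaving_group_heavy_atoms": rule.leaving_group_heavy_atoms,
                "linkages_formed": rule.linkages_formed,
                "transform": rule.transform,
            }
            for rule in registry.rules
        ],
        "exclusion_patterns": list(registry.exclusion_patterns),
    }


def save_registry(registry: Registry, path: Union[str, Path]) -> None:
    """Serialize the registry to the rules-file format (YAML)."""
    with open(path, "w", encoding="utf-8") as handle:
        yaml.safe_dump(_registry_to_dict(registry), handle, sort_keys=False)


def _check_patterns(report: ValidationReport, scope: str, ident, patterns: Iterable[str]) -> None:
    for pattern in patterns:
        try:
            compile_smarts(pattern)
        except ValueError:
            report.add(scope, ident, f"SMARTS does not parse: {pattern!r}")


def validate_registry(registry: Registry) -> ValidationReport:
    """Report-only validation of a registry.

    Checks, per monomer class, that all patterns parse and bounds are
    consistent; per rule, that the transform parses, that the number of
    reactant components matches the slot list (plus fixed reactants), that
    the slot names resolve to defined classes, and that the product templates
    carry at least two wildcard attachment atoms in total.
    """
    report = ValidationReport()
    seen_names: set[str] = set()
    for cls in registry.monomer_classes:
        if cls.name in seen_names:
            report.add("class", cls.name, "duplicate class name")
        seen_names.add(cls.name)
        if cls.growth_mode not in ("chain", "step"):
            report.add("class", cls.name, f"unknown growth_mode {cls.growth_mode!r}")
        if cls.min_occurrence < 1:
            report.add("class", cls.name, "min_occurrence must be >= 1")
        if cls.max_occurrence < cls.min_occurrence:
            report.add("class", cls.name, "max_occurrence < min_occurrence")
        if cls.growth_mode == "chain" and cls.min_occurrence != 1:
            report.add("class", cls.name, "chain-growth classes must have min_occurrence 1")
        if not cls.detection_patterns:
            report.add("class", cls.name, "no detection patterns")
        _check_patterns(report, "class", cls.name, cls.detection_patterns)
        _check_patterns(report, "class", cls.name, cls.forbidden_patterns)

    seen_ids: set[int] = set()
    for rule in registry.rules:
        if rule.rule_id in seen_ids:
            report.add("rule", rule.rule_id, "duplicate rule id")
        seen_ids.add(rule.rule_id)
        if rule.polymer_class not in POLYMER_CLASSES:
            report.add("rule", rule.rule_id, f"unknown polymer class {rule.polymer_class!r}")
        if rule.category not in REACTION_CATEGORIES:
            report.add("rule", rule.rule_id, f"unknown reaction category {rule.category!r}")
        if len(rule.reactant_slots) not in (1, 2):
            report.add("rule", rule.rule_id, "rules take 1 or 2 reactant slots")
        for slot in rule.reactant_slots:
            if slot not in seen_names:
                report.add("rule", rule.rule_id, f"slot references undefined class {slot!r}")
        try:
            rxn = compile_reaction(rule.transform)
        except ValueError:
            report.add(
                "rule", rule.rule_id, f"reaction SMARTS does not parse: {rule.transform!r}"
            )
            continue
        expected = len(rule.reactant_slots) + len(rule.fixed_reactants)
        if rxn.GetNumReactantTemplates() != expected:
            report.add(
                "rule",
                rule.rule_id,
                f"transform has {rxn.GetNumReactantTemplates()} reactant components, "
                f"expected {expected} (slots + fixed reactants)",
            )
        # In a query template a composite atom such as [O,S] also reports
        # atomic number 0, so template wildcards are the unmapped ones.
        n_wild = sum(
            1
            for i in range(rxn.GetNumProductTemplates())
            for atom in rxn.GetProductTemplate(i).GetAtoms()
            if atom.GetAtomicNum() == 0 and atom.GetAtomMapNum() == 0
        )
        if n_wild < 2:
            report.add(
                "rule",
                rule.rule_id,
                f"product templates carry {n_wild} wildcard atoms, expected >= 2",
            )
    _check_patterns(report, "registry", "exclusion_patterns", registry.exclusion_patterns)
    return report
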