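"""Stoichiometric network data model.

Conventions follow the COBRA family of genome-scale models:

* metabolite ids carry a compartment suffix, ``glc[c]`` (cytosol) /
  ``glc[e]`` (extracellular); ``_c`` / ``_e`` suffixes are tolerated on
  input and normalised,
* stoichiometric coefficients are negative for substrates and positive for
  products,
* flux bounds are in mmol/gDW/h by convention; a reversible reaction admits
  a negative lower bound,
* exchange reactions are single-metabolite boundary pseudo-reactions,
* extracellular species may be flagged ``boundary`` (SBML boundaryCondition):
  their mass balance is not enforced, so a transport touching them is itself
  an uptake/secretion route,
* gene associations are boolean expressions over opaque gene-id strings
  (annotation dialects differ between sources; identity is exact match).
"""

from __future__ import annotations

import copy
import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

__all__ = [
    "Metabolite",
    "Reaction",
    "Model",
    "ModelDelta",
    "split_compartment",
    "parse_genes",
    "parse_formula",
    "check_mass_balance",
    "expand_model",
    "diff_models",
    "model_stats",
    "metabolite_set_overlap",
    "CATEGORIES",
]

DEFAULT_LB = -1000.0
DEFAULT_UB = 1000.0

CATEGORIES = ("amino_acid", "dipeptide", "tripeptide", "transport", "exchange", "core")

_SUFFIX_RE = re.compile(r"^(?P<base>.+)\[(?P<comp>[a-zA-Z]\w*)\]$")
_UNDERSCORE_RE = re.compile(r"^(?P<base>.+)_(?P<comp>[cehmnsx])$")


def split_compartment(met_id: str) -> tuple[str, str]:
    """Split ``base[c]`` (or tolerant ``base_c``) into (base, compartment)."""
    m = _SUFFIX_RE.match(met_id)
    if m:
        return m.group("base"), m.group("comp")
    m = _UNDERSCORE_RE.match(met_id)
    if m:
        return m.group("base"), m.group("comp")
    return met_id, ""


def normalize_met_id(met_id: str) -> str:
    base, comp = split_compartment(met_id)
    return f"{base}[{comp}]" if comp else base


_GENE_SPLIT_RE = re.compile(r"[()\s]+|and|or|AND|OR", flags=0)


def parse_genes(gene_association: str) -> frozenset[str]:
    """Gene ids referenced in a boolean AND/OR association string."""
    if not gene_association:
        return frozenset()
    tokens = re.split(r"[()\s]+", gene_association)
    return frozenset(t for t in tokens if t and t.lower() not in ("and", "or"))


@dataclass
class Metabolite:
    id: str  # includes compartment tag, e.g. "pyr[c]"
    name: str = ""
    compartment: str = ""
    formula: str | None = None
    charge: int | None = None
    boundary: bool = False  # SBML boundaryCondition: balance not enforced

    def __post_init__(self):
        self.id = normalize_met_id(self.id)
        base, comp = split_compartment(self.id)
        if self.compartment and comp and self.compartment != comp:
            raise ValueError(
                f"metabolite {self.id}: compartment {self.compartment!r} "
                f"inconsistent with id suffix [{comp}]"
            )
        self.compartment = self.compartment or comp
        if not self.name:
            self.name = base


@dataclass
class Reaction:
    id: str
    stoichiometry: dict  # metabolite id -> coefficient
    reversible: bool = False
    lower_bound: float | None = None
    upper_bound: float | None = None
    gene_association: str = ""
    category: str = "core"
    name: str = ""

    def __post_init__(self):
        if not self.stoichiometry:
            raise ValueError(f"reaction {self.id}: empty stoichiometry")
        self.stoichiometry = {
            normalize_met_id(k): float(v) for k, v in self.stoichiometry.items()
        }
        if self.lower_bound is None:
            self.lower_bound = DEFAULT_LB if self.reversible else 0.0
        if self.upper_bound is None:
            self.upper_bound = DEFAULT_UB
        if self.category not in CATEGORIES:
            raise ValueError(f"reaction {self.id}: unknown category {self.category!r}")

    @property
    def genes(self) -> frozenset[str]:
        return parse_genes(self.gene_association)

    @property
    def is_exchange(self) -> bool:
        return len(self.stoichiometry) == 1

    def copy(self) -> "Reaction":
        return copy.deepcopy(self)


class Model:
    """A stoichiometric model: metabolites, reactions, genes, one objective."""

    def __init__(self, id: str = "model"):
        self.id = id
        self.metabolites: dict[str, Metabolite] = {}
        self.reactions: dict[str, Reaction] = {}
        self.objective: str | None = None  # reaction id, sense = maximize

    # -- construction -----------------------------------------------------
    def add_metabolite(self, met: Metabolite) -> None:
        if met.id in self.metabolites:
            raise ValueError(f"duplicate metabolite id: {met.id}")
        self.metabolites[met.id] = met

    def add_reaction(self, rxn: Reaction, metabolites: Iterable[Metabolite] = ()) -> None:
        """Add a reaction, creating any supplied metabolites not yet present."""
        if rxn.id in self.reactions:
            raise ValueError(f"duplicate reaction id: {rxn.id}")
        supplied = {m.id: m for m in metabolites}
        for met_id in rxn.stoichiometry:
            if met_id not in self.metabolites:
                if met_id in supplied:
                    self.add_metabolite(supplied[met_id])
                else:
                    raise KeyError(
                        f"reaction {rxn.id}: unresolved metabolite {met_id}"
                    )
        self.reactions[rxn.id] = rxn

    # -- queries ----------------------------------------------------------
    @property
    def genes(self) -> frozenset[str]:
        out: set[str] = set()
        for r in self.reactions.values():
            out |= r.genes
        return frozenset(out)

    def exchanges(self) -> list[Reaction]:
        return [r for r in self.reactions.values() if r.is_exchange]

    def copy(self) -> "Model":
        return copy.deepcopy(self)

    def __repr__(self):
        return (
            f"<Model {self.id}: {len(self.reactions)} reactions, "
            f"{len(self.metabolites)} metabolites, {len(self.genes)} genes>"
        )


@dataclass
class ModelDelta:
    """Difference between a base and an expanded model."""

    added_reactions: dict = field(default_factory=dict)  # category -> [ids]
    added_metabolites: list = field(default_factory=list)
    added_genes: list = field(default_factory=list)
    notes: list = field(default_factory=list)

    @property
    def n_reactions(self) -> int:
        return sum(len(v) for v in self.added_reactions.values())

    def category_counts(self) -> dict:
        return {k: len(v) for k, v in sorted(self.added_reactions.items())}

    def report(self) -> str:
        lines = [f"added reactions: {self.n_reactions}"]
        for cat, n in self.category_counts().items():
            lines.append(f"  {cat}: {n}")
        lines.append(f"added metabolites: {len(self.added_metabolites)}")
        lines.append(f"added genes: {len(self.added_genes)}")
        lines.extend(self.notes)
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# chemistry helpers

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> dict[str, int]:
    """Elemental composition of a Hill-style formula string."""
    out: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_RE.finditer(formula):
        if m.start() != pos:
            raise ValueError(f"cannot parse formula {formula!r}")
        pos = m.end()
        out[m.group(1)] = out.get(m.group(1), 0) + int(m.group(2) or 1)
    if pos != len(formula):
        raise ValueError(f"cannot parse formula {formula!r}")
    return out


def check_mass_balance(rxn: Reaction, model: Model) -> dict[str, float] | None:
    """Net elemental (and charge) imbalance of a reaction.

    Returns a dict of non-zero element -> net coefficient (empty dict ==
    balanced). Returns ``None``, with a warning, when any participating
    species lacks a formula — the check is skipped rather than guessed.
    """
    net: dict[str, float] = {}
    for met_id, coef in rxn.stoichiometry.items():
        met = model.metabolites[met_id]
        if met.formula is None:
            warnings.warn(
                f"mass-balance check skipped for {rxn.id}: {met_id} has no formula"
            )
            return None
        for elem, n in parse_formula(met.formula).items():
            net[elem] = net.get(elem, 0.0) + coef * n
        if met.charge is not None:
            net["charge"] = net.get("charge", 0.0) + coef * met.charge
    return {k: v for k, v in net.items() if abs(v) > 1e-9}


# ---------------------------------------------------------------------------
# expansion / diff / stats


def expand_model(
    base: Model,
    manifest: Sequence[tuple[Reaction, Sequence[Metabolite]]],
) -> tuple[Model, ModelDelta]:
    """Add manifest reactions (with their new species) to a copy of ``base``.

    The base is never modified; duplicate reaction ids — within the manifest
    or against the base — are an error. The returned delta records added
    reactions by category, added metabolites and added genes, and carries a
    note when the four headline reaction classes (amino acid, dipeptide,
    tripeptide, transport) do not sum to the total number of additions.
    """
    expanded = base.copy()
    expanded.id = base.id + "_expanded" if manifest else base.id
    delta = ModelDelta()
    seen_ids = set()
    base_genes = base.genes
    base_mets = set(base.metabolites)
    for rxn, mets in manifest:
        if rxn.id in seen_ids:
            raise ValueError(f"duplicate reaction id in manifest: {rxn.id}")
        seen_ids.add(rxn.id)
        before = set(expanded.metabolites)
        expanded.add_reaction(rxn.copy(), [copy.deepcopy(m) for m in mets])
        delta.added_reactions.setdefault(rxn.category, []).append(rxn.id)
        delta.added_metabolites.extend(sorted(set(expanded.metabolites) - before))
    delta.added_genes = sorted(expanded.genes - base_genes)
    headline = sum(
        len(delta.added_reactions.get(c, []))
        for c in ("amino_acid", "dipeptide", "tripeptide", "transport")
    )
    if manifest and headline != delta.n_reactions:
        delta.notes.append(
            f"category-sum discrepancy: the four headline classes sum to "
            f"{headline} while {delta.n_reactions} reactions were added; "
            f"the remainder is uncategorised ("
            + ", ".join(
                f"{c}={len(v)}"
                for c, v in sorted(delta.added_reactions.items())
                if c not in ("amino_acid", "dipeptide", "tripeptide", "transport")
            )
            + ")"
        )
    assert base_mets <= set(expanded.metabolites)
    return expanded, delta


def diff_models(a: Model, b: Model) -> ModelDelta:
    """Delta from ``a`` to ``b``: reactions/metabolites/genes in b but not a."""
    delta = ModelDelta()
    for rid, rxn in b.reactions.items():
        if rid not in a.reactions:
            delta.added_reactions.setdefault(rxn.category, []).append(rid)
    delta.added_metabolites = sorted(set(b.metabolites) - set(a.metabolites))
    delta.added_genes = sorted(b.genes - a.genes)
    return delta


def model_stats(model: Model) -> dict[str, int]:
    """Counts of unique reactions, metabolites (boundary included), genes."""
    return {
        "reactions": len(model.reactions),
        "metabolites": len(model.metabolites),
        "genes": len(model.genes),
    }


# ---------------------------------------------------------------------------
# metabolite-set overlap (Venn utility)

_PUNCT_RE = re.compile(r"[\s\-_,'\"()\[\]]+")


def canonical_name(name: str) -> str:
    """Case/punctuation-insensitive canonical form of a metabolite name."""
    return _PUNCT_RE.sub("", name.strip().lower())


def metabolite_set_overlap(sets: Mapping[str, Iterable[str]]) -> dict:
    """Exact intersection cardinalities over canonicalised name sets.

    Returns ``{"sizes": {name: n}, "intersections": {"A&B": n, ...,
    "A&B&C": n}}`` for every combination of two or more sets.
    """
    from itertools import combinations

    canon = {k: {canonical_name(x) for x in v} for k, v in sets.items()}
    out = {"sizes": {k: len(v) for k, v in canon.items()}, "intersections": {}}
    names = sorted(canon)
    for r in range(2, len(names) + 1):
        for combo in combinations(names, r):
            inter = set.intersection(*(canon[c] for c in combo))
            out["intersections"]["&".join(combo)] = len(inter)
    return out
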