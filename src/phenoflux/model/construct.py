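"""Reaction constructors for phenotype-driven model expansion.

Each constructor returns ``(Reaction, [Metabolite, ...])`` — the reaction
plus every species it touches, so the expansion step can create whichever
species the target model lacks. All enzymatic reactions are placed in the
cytosol (the localisation predicted for the new gene products); transport is
passive diffusion between the extracellular medium and the cytosol.

Reaction templates:

* d-amino-acid oxidation (EC 1.4.3.3 pattern)::

      d-AA + O2 + H2O -> NH4 + H2O2 + 2-oxo carboxylate

  with the 2-oxo product taken from a packaged d-AA -> oxo-acid lookup.
* d-alanine transaminase: 2-oxoglutarate + d-alanine <-> d-glutamate + pyruvate.
* peptide hydrolysis: an l-di/tripeptide + (n-1) H2O -> unit l-amino acids.
* cysteamine-S-phosphate phosphatase: hydrolysis to cysteamine + phosphate.
* racemase: generic reversible 1:1 d <-> l interconversion.
* passive transport: M[e] <-> M[c], no gene association; the extracellular
  species is created as a boundary species by default so the transport is
  itself the uptake route (an explicit exchange reaction is optional).
"""

from __future__ import annotations

import warnings
from importlib import resources

import pandas as pd

from .network import Metabolite, Model, Reaction

__all__ = [
    "AMINO_ACIDS",
    "COFACTORS",
    "load_damino_lookup",
    "peptide_metabolite",
    "make_damino_oxidation",
    "make_transaminase",
    "make_peptide_hydrolysis",
    "make_cysteamine_phosphatase",
    "make_racemase",
    "make_transport_passive",
    "make_exchange",
    "add_transport_passive",
    "unique_reaction_id",
    "DIPEPTIDE_GENE",
    "TRIPEPTIDE_GENE",
    "DAAO_GENE",
    "TRANSAMINASE_GENES",
    "CYSTEAMINE_GENE",
]

DAAO_GENE = "Cre02.g096350.t1.3"
TRANSAMINASE_GENES = (
    "XP_001698572.1 or XP_001693532.1 or XP_001701890.1 or XP_001700930.1"
)
DIPEPTIDE_GENE = "Cre02.g078650.t1.3"
TRIPEPTIDE_GENE = "Cre16.g675350.t1.3"
CYSTEAMINE_GENE = "JLM_162926"

#: shared small-molecule species (cytosolic), physiological protonation
COFACTORS = {
    "o2": ("O2", "O2", 0),
    "h2o": ("H2O", "H2O", 0),
    "h2o2": ("Hydrogen peroxide", "H2O2", 0),
    "nh4": ("Ammonium", "H4N", 1),
    "h": ("H+", "H", 1),
    "pi": ("Phosphate", "HO4P", -2),
    "atp": ("ATP", "C10H12N5O13P3", -4),
    "adp": ("ADP", "C10H12N5O10P2", -3),
    "pyr": ("Pyruvate", "C3H3O3", -1),
    "akg": ("2-Oxoglutarate", "C5H4O5", -2),
    "acald": ("Acetaldehyde", "C2H4O", 0),
}

#: the 20 proteinogenic l-amino acids: residue code -> (id, name, formula)
AMINO_ACIDS = {
    "ala": ("ala__L", "L-Alanine", "C3H7NO2"),
    "arg": ("arg__L", "L-Arginine", "C6H14N4O2"),
    "asn": ("asn__L", "L-Asparagine", "C4H8N2O3"),
    "asp": ("asp__L", "L-Aspartate", "C4H7NO4"),
    "cys": ("cys__L", "L-Cysteine", "C3H7NO2S"),
    "gln": ("gln__L", "L-Glutamine", "C5H10N2O3"),
    "glu": ("glu__L", "L-Glutamate", "C5H9NO4"),
    "gly": ("gly", "Glycine", "C2H5NO2"),
    "his": ("his__L", "L-Histidine", "C6H9N3O2"),
    "ile": ("ile__L", "L-Isoleucine", "C6H13NO2"),
    "leu": ("leu__L", "L-Leucine", "C6H13NO2"),
    "lys": ("lys__L", "L-Lysine", "C6H14N2O2"),
    "met": ("met__L", "L-Methionine", "C5H11NO2S"),
    "phe": ("phe__L", "L-Phenylalanine", "C9H11NO2"),
    "pro": ("pro__L", "L-Proline", "C5H9NO2"),
    "ser": ("ser__L", "L-Serine", "C3H7NO3"),
    "thr": ("thr__L", "L-Threonine", "C4H9NO3"),
    "trp": ("trp__L", "L-Tryptophan", "C11H12N2O2"),
    "tyr": ("tyr__L", "L-Tyrosine", "C9H11NO3"),
    "val": ("val__L", "L-Valine", "C5H11NO2"),
}


def _cof(key: str) -> Metabolite:
    name, formula, charge = COFACTORS[key]
    return Metabolite(f"{key}[c]", name=name, formula=formula, charge=charge)


def _aa_met(code: str) -> Metabolite:
    aa_id, name, formula = AMINO_ACIDS[code]
    return Metabolite(f"{aa_id}[c]", name=name, formula=formula, charge=0)


def load_damino_lookup() -> pd.DataFrame:
    """Packaged d-amino-acid -> 2-oxo-carboxylate product lookup."""
    with resources.files("phenoflux.data").joinpath(
        "d_amino_acid_oxidation.tsv"
    ).open() as fh:
        return pd.read_csv(fh, sep="\t")


_LOOKUP_CACHE: pd.DataFrame | None = None


def _lookup_row(d_amino_acid: str):
    global _LOOKUP_CACHE
    if _LOOKUP_CACHE is None:
        _LOOKUP_CACHE = load_damino_lookup()
    df = _LOOKUP_CACHE
    hit = df[
        (df["aa_id"] == d_amino_acid)
        | (df["amino_acid"].str.lower() == d_amino_acid.lower())
    ]
    return hit.iloc[0] if len(hit) else None


def make_damino_oxidation(
    d_amino_acid: str,
    oxo_product: Metabolite | None = None,
    gene: str = DAAO_GENE,
) -> tuple[Reaction, list[Metabolite]]:
    """d-AA + O2 + H2O -> NH4 + H2O2 + 2-oxo carboxylate (irreversible).

    ``d_amino_acid`` is an id (``ala__D``) or name (``D-Alanine``) resolved
    via the packaged lookup; an unknown d-amino acid requires an explicit
    ``oxo_product``.
    """
    row = _lookup_row(d_amino_acid)
    if row is None and oxo_product is None:
        raise KeyError(
            f"no 2-oxo product known for {d_amino_acid!r}; "
            "supply oxo_product explicitly"
        )
    if row is not None:
        aa = Metabolite(
            f"{row.aa_id}[c]", name=row.amino_acid,
            formula=row.aa_formula, charge=int(row.aa_charge),
        )
        if oxo_product is None:
            oxo_product = Metabolite(
                f"{row.oxo_id}[c]", name=row.oxo_name,
                formula=row.oxo_formula, charge=int(row.oxo_charge),
            )
    else:
        aa = Metabolite(f"{d_amino_acid}[c]")
    mets = [aa, _cof("o2"), _cof("h2o"), _cof("nh4"), _cof("h2o2"), oxo_product]
    rxn = Reaction(
        id=f"DAAOX_{aa.id.split('[')[0]}",
        name=f"{aa.name} oxidase",
        stoichiometry={
            aa.id: -1, "o2[c]": -1, "h2o[c]": -1,
            "nh4[c]": 1, "h2o2[c]": 1, oxo_product.id: 1,
        },
        reversible=False,
        gene_association=gene,
        category="amino_acid",
    )
    return rxn, mets


def make_transaminase() -> tuple[Reaction, list[Metabolite]]:
    """2-oxoglutarate + d-alanine <-> d-glutamate + pyruvate (reversible)."""
    ala = _lookup_row("ala__D")
    glu = _lookup_row("glu__D")
    mets = [
        _cof("akg"), _cof("pyr"),
        Metabolite("ala__D[c]", name="D-Alanine", formula=ala.aa_formula,
                   charge=int(ala.aa_charge)),
        Metabolite("glu__D[c]", name="D-Glutamate", formula=glu.aa_formula,
                   charge=int(glu.aa_charge)),
    ]
    rxn = Reaction(
        id="DALATA",
        name="D-alanine transaminase",
        stoichiometry={"akg[c]": -1, "ala__D[c]": -1, "glu__D[c]": 1, "pyr[c]": 1},
        reversible=True,
        gene_association=TRANSAMINASE_GENES,
        category="amino_acid",
    )
    return rxn, mets


def peptide_metabolite(residues: tuple[str, ...], compartment: str = "c") -> Metabolite:
    """An l-peptide species; its formula is the residue sum minus the
    condensation waters, so hydrolysis is element-balanced by construction."""
    from .network import parse_formula

    elems: dict[str, int] = {}
    for code in residues:
        for el, n in parse_formula(AMINO_ACIDS[code][2]).items():
            elems[el] = elems.get(el, 0) + n
    elems["H"] -= 2 * (len(residues) - 1)
    elems["O"] -= len(residues) - 1
    formula = "".join(
        f"{el}{elems[el] if elems[el] != 1 else ''}"
        for el in ("C", "H", "N", "O", "P", "S")
        if elems.get(el)
    )
    base = "_".join(residues)
    name = "-".join(code.capitalize() for code in residues)
    return Metabolite(f"{base}[{compartment}]", name=name, formula=formula, charge=0)


def make_peptide_hydrolysis(
    residues: tuple[str, ...] | list[str],
) -> tuple[Reaction, list[Metabolite]]:
    """Hydrolyse an l-di/tripeptide into its unit l-amino acids.

    One water is consumed per peptide bond; repeated residues accumulate
    multiplicity (Gly-Gly yields glycine with coefficient +2).
    """
    residues = tuple(r.lower() for r in residues)
    if not 2 <= len(residues) <= 3:
        raise ValueError(f"peptide length must be 2 or 3, got {len(residues)}")
    unknown = [r for r in residues if r not in AMINO_ACIDS]
    if unknown:
        raise KeyError(f"unknown residue codes: {unknown}")
    pep = peptide_metabolite(residues)
    stoich: dict[str, float] = {pep.id: -1, "h2o[c]": -(len(residues) - 1)}
    mets = [pep, _cof("h2o")]
    for code in residues:
        aa = _aa_met(code)
        stoich[aa.id] = stoich.get(aa.id, 0) + 1
        mets.append(aa)
    category = "dipeptide" if len(residues) == 2 else "tripeptide"
    gene = DIPEPTIDE_GENE if len(residues) == 2 else TRIPEPTIDE_GENE
    rxn = Reaction(
        id=f"PEPH_{'_'.join(residues)}",
        name=f"{pep.name} hydrolase",
        stoichiometry=stoich,
        reversible=False,
        gene_association=gene,
        category=category,
    )
    return rxn, mets


def make_cysteamine_phosphatase() -> tuple[Reaction, list[Metabolite]]:
    """Cysteamine-S-phosphate + H2O -> cysteamine + phosphate (irreversible).

    Protonation states: the substrate as the monoanion, cysteamine as its
    ammonium form, phosphate as HPO4(2-) — the combination that balances
    both atoms and charge.
    """
    csph = Metabolite(
        "csph[c]", name="Cysteamine-S-phosphate", formula="C2H7NO3PS", charge=-1
    )
    cysteam = Metabolite("cysteam[c]", name="Cysteamine", formula="C2H8NS", charge=1)
    mets = [csph, _cof("h2o"), cysteam, _cof("pi")]
    rxn = Reaction(
        id="CSPHH",
        name="Cysteamine-S-phosphate phosphohydrolase",
        stoichiometry={"csph[c]": -1, "h2o[c]": -1, "cysteam[c]": 1, "pi[c]": 1},
        reversible=False,
        gene_association=CYSTEAMINE_GENE,
        category="core",
    )
    return rxn, mets


def make_racemase(
    aa_base: str, gene: str = "", d_met: Metabolite | None = None,
    l_met: Metabolite | None = None,
) -> tuple[Reaction, list[Metabolite]]:
    """Generic reversible 1:1 d <-> l interconversion for one amino acid."""
    row = _lookup_row(f"{aa_base}__D")
    if d_met is None:
        if row is not None:
            d_met = Metabolite(
                f"{row.aa_id}[c]", name=row.amino_acid,
                formula=row.aa_formula, charge=int(row.aa_charge),
            )
        else:
            d_met = Metabolite(f"{aa_base}__D[c]")
    if l_met is None:
        l_met = _aa_met(aa_base) if aa_base in AMINO_ACIDS else Metabolite(
            f"{aa_base}__L[c]"
        )
    rxn = Reaction(
        id=f"RAC_{aa_base}",
        name=f"{aa_base} racemase",
        stoichiometry={d_met.id: -1, l_met.id: 1},
        reversible=True,
        gene_association=gene,
        category="amino_acid",
    )
    return rxn, [d_met, l_met]


def make_transport_passive(
    base_id: str,
    name: str = "",
    formula: str | None = None,
    charge: int | None = None,
    boundary: bool = True,
) -> tuple[Reaction, list[Metabolite]]:
    """Passive diffusion M[e] <-> M[c]; no gene association.

    The extracellular species is a boundary species by default (its mass
    balance is not enforced), so the transport itself admits uptake from the
    medium without a separate exchange reaction.
    """
    e = Metabolite(f"{base_id}[e]", name=name or base_id, formula=formula,
                   charge=charge, boundary=boundary)
    c = Metabolite(f"{base_id}[c]", name=name or base_id, formula=formula,
                   charge=charge)
    rxn = Reaction(
        id=f"TRANS_{base_id}",
        name=f"{name or base_id} transport (passive diffusion)",
        stoichiometry={e.id: -1, c.id: 1},
        reversible=True,
        category="transport",
    )
    return rxn, [e, c]


def make_exchange(base_id: str, lb: float = -1000.0, ub: float = 1000.0,
                  boundary_species: bool = False) -> tuple[Reaction, list[Metabolite]]:
    """Exchange pseudo-reaction M[e] <-> (medium)."""
    e = Metabolite(f"{base_id}[e]", name=base_id, boundary=boundary_species)
    rxn = Reaction(
        id=f"EX_{base_id}_e",
        name=f"{base_id} exchange",
        stoichiometry={e.id: -1},
        reversible=lb < 0,
        lower_bound=lb,
        upper_bound=ub,
        category="exchange",
    )
    return rxn, [e]


def add_transport_passive(
    model: Model, metabolite_base_id: str, exchange: bool = False, **met_kwargs
) -> Model:
    """Return a copy of ``model`` with a passive transport for the compound.

    Creates the [e]/[c] species when absent. Adding a transport that already
    exists is a warning no-op (idempotent). With ``exchange=True`` the
    extracellular species is non-boundary and an explicit exchange reaction
    is added instead.
    """
    out = model.copy()
    rxn, mets = make_transport_passive(
        metabolite_base_id, boundary=not exchange, **met_kwargs
    )
    if rxn.id in out.reactions:
        warnings.warn(f"transport {rxn.id} already present; no-op")
        return out
    out.add_reaction(rxn, [m for m in mets if m.id not in out.metabolites])
    if exchange:
        ex, ex_mets = make_exchange(metabolite_base_id)
        if ex.id not in out.reactions:
            out.add_reaction(ex, [m for m in ex_mets if m.id not in out.metabolites])
    return out


def unique_reaction_id(model: Model, rxn_id: str) -> str:
    """Deterministic ``_1``, ``_2``... suffixing on id collision."""
    if rxn_id not in model.reactions:
        return rxn_id
    k = 1
    while f"{rxn_id}_{k}" in model.reactions:
        k += 1
    return f"{rxn_id}_{k}"
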