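"""The study expansion manifest: the 254-reaction refinement set.

Programmatic reconstruction of the published C. reinhardtii network
expansion, in the four headline classes plus one uncategorised hydrolysis:

* 20 amino-acid reactions — 8 d-amino-acid oxidations, the d-alanine
  transaminase, 8 d/l racemases, the d-serine kinase (ATP + d-serine ->
  ADP + phospho-d-serine), a d-serine ammonia-lyase and an ethanolamine
  ammonia-lyase,
* 108 l-dipeptide and 5 l-tripeptide hydrolyses,
* 120 passive transports (the 113 peptides, cysteamine-S-phosphate and six
  of the eight d-amino acids; d-alanine and d-serine carriers are assumed
  present in the base network, reconciling the printed transport count),
* the cysteamine-S-phosphate phosphatase (phosphorus assimilation; fits
  none of the four headline classes, which is why those classes sum to 253
  while 254 reactions are added — the expansion delta surfaces this).

Only eight dipeptide identities were published (Leu-Pro, Ala-His, Asp-Leu,
Asp-Phe, Pro-Asp, Asp-Ala, Asp-Gln, Asp-Gly); the remaining pairs and the
five tripeptides are SYNTHETIC stand-ins, filled deterministically from the
20-residue enumeration. Likewise the five racemase gene ids (``racg1`` ..
``racg5``) are synthetic placeholders for curation entries whose identities
were not published; they preserve the 20-new-gene arithmetic.
"""

from __future__ import annotations

from itertools import product

from .construct import (
    AMINO_ACIDS,
    DAAO_GENE,
    make_cysteamine_phosphatase,
    make_damino_oxidation,
    make_peptide_hydrolysis,
    make_racemase,
    make_transaminase,
    make_transport_passive,
    peptide_metabolite,
    _cof,
)
from .network import Metabolite, Reaction

__all__ = [
    "D_AMINO_ACIDS",
    "NAMED_DIPEPTIDES",
    "dipeptide_pairs",
    "tripeptide_seqs",
    "study_manifest",
]

#: the eight d-amino acids with oxidation evidence (gene per reaction)
D_AMINO_ACIDS = [
    ("ala", f"{DAAO_GENE} or XP_001700222.1"),
    ("asn", f"{DAAO_GENE} or XP_001692123.1 or e_gwW.1.243.1"),
    ("asp", DAAO_GENE),
    ("glu", DAAO_GENE),
    ("lys", DAAO_GENE),
    ("ser", DAAO_GENE),
    ("val", DAAO_GENE),
    ("2abut", DAAO_GENE),
]

#: dipeptides with published identities
NAMED_DIPEPTIDES = [
    ("leu", "pro"), ("ala", "his"), ("asp", "leu"), ("asp", "phe"),
    ("pro", "asp"), ("asp", "ala"), ("asp", "gln"), ("asp", "gly"),
]

_RACEMASE_GENES = ["racg1", "racg2", "racg3", "racg4", "racg5"]


def dipeptide_pairs(n: int = 108) -> list[tuple[str, str]]:
    """Deterministic list of ``n`` dipeptides, published identities first."""
    pairs = list(NAMED_DIPEPTIDES)
    seen = set(pairs)
    codes = sorted(AMINO_ACIDS)
    for a, b in product(codes, codes):
        if len(pairs) >= n:
            break
        if (a, b) not in seen:
            pairs.append((a, b))
            seen.add((a, b))
    return pairs[:n]


def tripeptide_seqs(n: int = 5) -> list[tuple[str, str, str]]:
    """Deterministic list of ``n`` tripeptides (synthetic identities)."""
    codes = sorted(AMINO_ACIDS)
    out = []
    for combo in product(codes, repeat=3):
        out.append(combo)
        if len(out) >= n:
            break
    return out


def _damino_transport(code: str):
    from .construct import _lookup_row

    row = _lookup_row(f"{code}__D")
    return make_transport_passive(
        row.aa_id, name=row.amino_acid, formula=row.aa_formula,
        charge=int(row.aa_charge),
    )


def study_manifest(
    n_dipeptides: int = 108,
    n_tripeptides: int = 5,
    include_transports: bool = True,
) -> list[tuple[Reaction, list[Metabolite]]]:
    """Build the full 254-reaction expansion manifest.

    Returns ``(reaction, metabolites)`` entries; every entry carries all the
    species it touches so the manifest can expand any base model.
    """
    entries: list[tuple[Reaction, list[Metabolite]]] = []

    # -- 20 amino-acid reactions
    for code, gene in D_AMINO_ACIDS:
        entries.append(make_damino_oxidation(f"{code}__D", gene=gene))
    entries.append(make_transaminase())
    for i, (code, _) in enumerate(D_AMINO_ACIDS):
        entries.append(
            make_racemase(code, gene=_RACEMASE_GENES[i % len(_RACEMASE_GENES)])
        )
    # d-serine kinase: ATP + d-serine -> ADP + phospho-d-serine + H+
    pser = Metabolite(
        "pser__D[c]", name="O-Phospho-D-serine", formula="C3H6NO6P", charge=-2
    )
    ser_row_mets = make_racemase("ser")[1]  # reuse the d-serine species
    dser = ser_row_mets[0]
    entries.append(
        (
            Reaction(
                id="DSERK",
                name="D-serine kinase",
                stoichiometry={
                    "atp[c]": -1, "ser__D[c]": -1,
                    "adp[c]": 1, "pser__D[c]": 1, "h[c]": 1,
                },
                reversible=False,
                gene_association="Cre12.g486350.t1.3",
                category="amino_acid",
            ),
            [_cof("atp"), _cof("adp"), _cof("h"), dser, pser],
        )
    )
    # d-serine ammonia-lyase: d-serine -> pyruvate + NH4
    entries.append(
        (
            Reaction(
                id="DSERDA",
                name="D-serine ammonia-lyase",
                stoichiometry={"ser__D[c]": -1, "pyr[c]": 1, "nh4[c]": 1},
                reversible=False,
                gene_association="g6244.t1",
                category="amino_acid",
            ),
            [dser, _cof("pyr"), _cof("nh4")],
        )
    )
    # ethanolamine ammonia-lyase: ethanolamine + H+ -> acetaldehyde + NH4
    etha = Metabolite("etha[c]", name="Ethanolamine", formula="C2H7NO", charge=0)
    entries.append(
        (
            Reaction(
                id="ETHAAL",
                name="Ethanolamine ammonia-lyase",
                stoichiometry={
                    "etha[c]": -1, "h[c]": -1, "acald[c]": 1, "nh4[c]": 1
                },
                reversible=False,
                gene_association="au.g14655_t1",
                category="amino_acid",
            ),
            [etha, _cof("h"), _cof("acald"), _cof("nh4")],
        )
    )

    # -- peptide hydrolyses (dipeptide hydrolase gets the second annotated
    # peptidase as an alternative isozyme)
    dipeps = dipeptide_pairs(n_dipeptides)
    tripeps = tripeptide_seqs(n_tripeptides)
    for i, pair in enumerate(dipeps):
        rxn, mets = make_peptide_hydrolysis(pair)
        if i == 0:
            rxn.gene_association += " or Chlre2_kg.scaffold_14000039"
        entries.append((rxn, mets))
    for seq in tripeps:
        entries.append(make_peptide_hydrolysis(seq))

    # -- cysteamine-S-phosphate hydrolysis (the uncategorised 254th reaction)
    entries.append(make_cysteamine_phosphatase())

    # -- 120 passive transports
    if include_transports:
        for residues in list(dipeps) + list(tripeps):
            pep_c = peptide_metabolite(residues)
            pep_e = peptide_metabolite(residues, compartment="e")
            pep_e.boundary = True
            rxn = Reaction(
                id=f"TRANS_{'_'.join(residues)}",
                name=f"{pep_c.name} transport (passive diffusion)",
                stoichiometry={pep_e.id: -1, pep_c.id: 1},
                reversible=True,
                category="transport",
            )
            entries.append((rxn, [pep_e, pep_c]))
        entries.append(
            make_transport_passive(
                "csph", name="Cysteamine-S-phosphate", formula="C2H7NO3PS",
                charge=-1,
            )
        )
        # six d-amino-acid carriers; the d-alanine and d-serine carriers are
        # taken to pre-exist in the base network
        for code, _ in D_AMINO_ACIDS:
            if code in ("ala", "ser"):
                continue
            entries.append(_damino_transport(code))

    return entries
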