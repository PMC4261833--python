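"""Network types, constructors, SBML round trip, expansion and overlap."""

import numpy as np
import pytest

from phenoflux.model import (
    Metabolite,
    Model,
    Reaction,
    add_transport_passive,
    check_mass_balance,
    diff_models,
    expand_model,
    make_cysteamine_phosphatase,
    make_damino_oxidation,
    make_peptide_hydrolysis,
    make_transaminase,
    make_transport_passive,
    metabolite_set_overlap,
    model_stats,
    read_sbml,
    study_manifest,
    unique_reaction_id,
    write_sbml,
)


def _model_with(*entries):
    m = Model()
    for rxn, mets in entries:
        m.add_reaction(rxn, [x for x in mets if x.id not in m.metabolites])
    return m


class TestConstructors:
    def test_damino_oxidation_template(self):
        rxn, _ = make_damino_oxidation("ala__D")
        assert rxn.stoichiometry == {
            "ala__D[c]": -1, "o2[c]": -1, "h2o[c]": -1,
            "nh4[c]": 1, "h2o2[c]": 1, "pyr[c]": 1,
        }
        assert not rxn.reversible
        assert rxn.category == "amino_acid"

    def test_damino_oxidation_asparagine_product(self):
        rxn, mets = make_damino_oxidation("D-Asparagine")
        products = {m for m, c in rxn.stoichiometry.items() if c > 0}
        assert "2oxsucam[c]" in products  # the d-aspartate-derived oxo acid

    def test_unknown_damino_requires_product(self):
        with pytest.raises(KeyError, match="oxo_product"):
            make_damino_oxidation("nonexistine__D")

    @pytest.mark.parametrize(
        "ctor",
        [
            lambda: make_damino_oxidation("ala__D"),
            lambda: make_damino_oxidation("val__D"),
            make_transaminase,
            make_cysteamine_phosphatase,
            lambda: make_peptide_hydrolysis(("leu", "pro")),
            lambda: make_peptide_hydrolysis(("ala", "his")),
            lambda: make_peptide_hydrolysis(("gly", "gly", "gly")),
        ],
    )
    def test_constructed_reactions_element_balanced(self, ctor):
        rxn, mets = ctor()
        m = _model_with((rxn, mets))
        assert check_mass_balance(rxn, m) == {}

    def test_balance_check_skips_formula_free_species(self):
        m = Model()
        m.add_reaction(
            Reaction(id="r", stoichiometry={"a[c]": -1, "b[c]": 1}),
            [Metabolite("a[c]"), Metabolite("b[c]")],
        )
        with pytest.warns(UserWarning, match="no formula"):
            assert check_mass_balance(m.reactions["r"], m) is None

    def test_transaminase_shape(self):
        rxn, _ = make_transaminase()
        subs = [m for m, c in rxn.stoichiometry.items() if c < 0]
        prods = [m for m, c in rxn.stoichiometry.items() if c > 0]
        assert sorted(subs) == ["akg[c]", "ala__D[c]"]
        assert sorted(prods) == ["glu__D[c]", "pyr[c]"]
        assert rxn.reversible
        assert sum(rxn.stoichiometry.values()) == 0
        assert "XP_001698572.1" in rxn.genes

    def test_peptide_hydrolysis_products(self):
        rxn, _ = make_peptide_hydrolysis(("leu", "pro"))
        assert rxn.stoichiometry["h2o[c]"] == -1
        assert rxn.stoichiometry["leu__L[c]"] == 1
        assert rxn.stoichiometry["pro__L[c]"] == 1
        assert rxn.gene_association == "Cre02.g078650.t1.3"

    def test_homodipeptide_multiplicity(self):
        rxn, _ = make_peptide_hydrolysis(("gly", "gly"))
        assert rxn.stoichiometry["gly[c]"] == 2

    def test_tripeptide_water_and_gene(self):
        rxn, _ = make_peptide_hydrolysis(("ala", "gly", "ser"))
        assert rxn.stoichiometry["h2o[c]"] == -2
        assert rxn.gene_association == "Cre16.g675350.t1.3"

    @pytest.mark.parametrize("residues", [("ala",), ("ala",) * 4])
    def test_peptide_length_bounds(self, residues):
        with pytest.raises(ValueError, match="length"):
            make_peptide_hydrolysis(residues)

    def test_cysteamine_phosphatase_eq(self):
        rxn, mets = make_cysteamine_phosphatase()
        assert rxn.stoichiometry == {
            "csph[c]": -1, "h2o[c]": -1, "cysteam[c]": 1, "pi[c]": 1
        }
        assert rxn.gene_association == "JLM_162926"
        m = _model_with((rxn, mets))
        net = check_mass_balance(rxn, m)
        assert net == {}  # phosphorus (and everything else) conserved

    def test_id_collision_suffixing(self):
        m = _model_with(make_cysteamine_phosphatase())
        assert unique_reaction_id(m, "CSPHH") == "CSPHH_1"
        assert unique_reaction_id(m, "fresh") == "fresh"


class TestTransport:
    def test_new_compound_adds_two_species_two_routes(self):
        m = Model()
        m2 = add_transport_passive(m, "xyl", exchange=True)
        assert set(m2.metabolites) == {"xyl[e]", "xyl[c]"}
        assert set(m2.reactions) == {"TRANS_xyl", "EX_xyl_e"}
        assert len(m.reactions) == 0  # source untouched

    def test_boundary_mode_needs_no_exchange(self):
        m = add_transport_passive(Model(), "xyl")
        assert m.metabolites["xyl[e]"].boundary
        assert set(m.reactions) == {"TRANS_xyl"}

    def test_idempotent(self):
        m1 = add_transport_passive(Model(), "xyl")
        with pytest.warns(UserWarning, match="no-op"):
            m2 = add_transport_passive(m1, "xyl")
        assert set(m2.reactions) == set(m1.reactions)


class TestSBMLRoundTrip:
    def test_minimal_model(self, tmp_path, chain_model):
        path = tmp_path / "chain.xml"
        write_sbml(chain_model, path)
        back = read_sbml(path)
        assert model_stats(back) == model_stats(chain_model)
        assert back.objective == "biomass"
        assert back.reactions["EX_A"].lower_bound == -10.0

    def test_full_round_trip_identity(self, tmp_path, expanded):
        model, _ = expanded
        path = tmp_path / "expanded.xml"
        write_sbml(model, path)
        back = read_sbml(path)
        assert set(back.reactions) == set(model.reactions)
        assert set(back.metabolites) == set(model.metabolites)
        for rid, rxn in model.reactions.items():
            b = back.reactions[rid]
            assert b.stoichiometry == rxn.stoichiometry
            assert (b.lower_bound, b.upper_bound) == (
                rxn.lower_bound, rxn.upper_bound)
            assert b.gene_association == rxn.gene_association
            assert b.category == rxn.category
            assert b.reversible == rxn.reversible
        for mid, met in model.metabolites.items():
            assert back.metabolites[mid].boundary == met.boundary
        assert back.objective == model.objective

    def test_missing_bounds_defaulted_with_warning(self, tmp_path):
        import libsbml

        doc = libsbml.SBMLDocument(2, 1)
        sm = doc.createModel()
        sm.setId("m")
        comp = sm.createCompartment(); comp.setId("c")
        sp = sm.createSpecies(); sp.setId("M_a_c"); sp.setCompartment("c")
        r = sm.createReaction(); r.setId("R_r1"); r.setReversible(True)
        ref = r.createProduct(); ref.setSpecies("M_a_c"); ref.setStoichiometry(1)
        path = tmp_path / "nobounds.xml"
        libsbml.writeSBMLToFile(doc, str(path))
        with pytest.warns(UserWarning, match="missing flux bounds"):
            m = read_sbml(path)
        assert m.reactions["r1"].lower_bound == -1000.0
        assert m.reactions["r1"].upper_bound == 1000.0

    def test_cobrapy_reads_our_sbml(self, tmp_path, chain_model):
        """Cross-check: an independent COBRA reader agrees on the dialect."""
        import cobra.io

        path = tmp_path / "chain.xml"
        write_sbml(chain_model, path)
        cm = cobra.io.read_sbml_model(str(path))
        assert len(cm.reactions) == 2
        assert len(cm.metabolites) == 1
        ex = cm.reactions.get_by_id("EX_A")
        assert (ex.lower_bound, ex.upper_bound) == (-10.0, 0.0)


class TestExpansion:
    def test_empty_manifest_identity(self, base_model):
        out, delta = expand_model(base_model, [])
        assert model_stats(out) == model_stats(base_model)
        assert delta.n_reactions == 0
        assert delta.added_genes == []

    def test_study_manifest_counts(self, expanded, base_model):
        model, delta = expanded
        stats = model_stats(model)
        assert stats["reactions"] == 2445  # 2,191 + 254
        assert stats["genes"] == 1106  # 1,086 + 20
        assert delta.category_counts()["amino_acid"] == 20
        assert delta.category_counts()["dipeptide"] == 108
        assert delta.category_counts()["tripeptide"] == 5
        assert delta.category_counts()["transport"] == 120

    def test_category_sum_discrepancy_surfaced(self, expanded):
        _, delta = expanded
        assert delta.n_reactions == 254
        assert any("253" in note and "254" in note for note in delta.notes)

    def test_never_shrinks_and_base_preserved(self, base_model, manifest):
        before = model_stats(base_model)
        out, _ = expand_model(base_model, manifest)
        assert model_stats(base_model) == before
        after = model_stats(out)
        assert all(after[k] >= before[k] for k in before)
        assert all(r in out.reactions for r in base_model.reactions)

    def test_associative_over_disjoint_manifests(self, base_model, manifest):
        half = len(manifest) // 2
        one_shot, _ = expand_model(base_model, manifest)
        first, _ = expand_model(base_model, manifest[:half])
        two_step, _ = expand_model(first, manifest[half:])
        assert set(two_step.reactions) == set(one_shot.reactions)
        assert set(two_step.metabolites) == set(one_shot.metabolites)

    def test_diff_reproduces_manifest(self, base_model, expanded, manifest):
        model, delta = expanded
        diff = diff_models(base_model, model)
        assert diff.category_counts() == delta.category_counts()
        assert diff.added_genes == delta.added_genes

    def test_duplicate_manifest_id_rejected(self, base_model):
        entry = make_cysteamine_phosphatase()
        with pytest.raises(ValueError, match="duplicate"):
            expand_model(base_model, [entry, entry])

    def test_empty_model_stats(self):
        assert model_stats(Model()) == {
            "reactions": 0, "metabolites": 0, "genes": 0
        }


class TestMetaboliteOverlap:
    def test_disjoint(self):
        out = metabolite_set_overlap({"A": ["x"], "B": ["y"], "C": ["z"]})
        assert set(out["intersections"].values()) == {0}

    def test_identical_sets(self):
        s = ["a", "b", "c"]
        out = metabolite_set_overlap({"A": s, "B": s, "C": s})
        assert out["intersections"]["A&B&C"] == 3

    def test_canonicalisation_and_triple_overlap(self):
        """The six metabolites shared by the assay panel, the base model and
        the GC-TOF profile intersect regardless of naming conventions."""
        shared = ["adenine", "glycerol", "glycine", "myo-Inositol",
                  "putrescine", "uracil"]
        assay = shared + ["acetic acid", "D-glucose"]
        network = [s.upper() for s in shared] + ["pyruvate"]
        gctof = ["Myo Inositol"] + [s.title() for s in shared if "myo" not in s]
        out = metabolite_set_overlap(
            {"assay": assay, "model": network, "gctof": gctof}
        )
        assert out["intersections"]["assay&gctof&model"] == 6
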