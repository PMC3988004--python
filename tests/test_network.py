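"""Clock-network construction: complex enumeration, perturbations, model audit."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chronosim.network import (
    CHRONO_BINDING_RULES,
    BindingRule,
    BindingRuleSet,
    ConfigurationError,
    GeneticPerturbation,
    ModelSpec,
    apply_perturbation,
    apply_perturbations,
    enumerate_chrono_complexes,
    parse_perturbations,
)
from chronosim.models import build_reduced_model


def brute_force_chrono_complexes(base, rules, max_size):
    """Independent oracle: enumerate all subsets, filter by pairwise rules."""
    members = sorted(set(base) - {"CHRONO"})
    out = set()
    for size in range(1, max_size):
        for combo in itertools.combinations(members, size):
            group = ("CHRONO",) + combo
            ok = all(
                not (rules.has_rule(a, b) and not rules.allowed(a, b))
                for a, b in itertools.combinations(group, 2)
            )
            if ok:
                out.add(tuple(sorted(group)))
    return out


ALL_MONOMERS = ["BMAL1", "PER1", "PER2", "CRY1", "CRY2", "DEC1", "DEC2"]


class TestEnumerateChronoComplexes:
    def test_forbidden_partner_never_in_any_complex(self):
        # CHRONO binds BMAL1/PER2/CRY2/DEC2 but not PER1/CRY1/DEC1
        out = enumerate_chrono_complexes(ALL_MONOMERS, CHRONO_BINDING_RULES, 4)
        for sp in out:
            for bad in ("PER1", "CRY1", "DEC1"):
                assert bad not in sp.constituents
        # the CHRONO-CRY2 contact is deliberately not modelled either
        assert all("CRY2" not in sp.constituents for sp in out)

    def test_pairwise_dimers_match_allowed_partners(self):
        out = enumerate_chrono_complexes(ALL_MONOMERS, CHRONO_BINDING_RULES, 2)
        names = {sp.constituents for sp in out}
        assert names == {("BMAL1", "CHRONO"), ("CHRONO", "PER2"),
                         ("CHRONO", "DEC2")}

    def test_empty_base_set_yields_nothing(self):
        assert enumerate_chrono_complexes([], CHRONO_BINDING_RULES, 3) == []

    def test_four_allowed_partners_give_four_heterodimers(self):
        rules = BindingRuleSet([
            BindingRule("CHRONO", m, True, 1.0, 0.5)
            for m in ("BMAL1", "PER2", "CRY2", "DEC2")
        ])
        out = enumerate_chrono_complexes(["BMAL1", "PER2", "CRY2", "DEC2"],
                                         rules, 2)
        assert len(out) == 4
        assert {sp.constituents for sp in out} == brute_force_chrono_complexes(
            ["BMAL1", "PER2", "CRY2", "DEC2"], rules, 2)

    def test_unknown_monomer_raises(self):
        with pytest.raises(ConfigurationError, match="GRB2"):
            enumerate_chrono_complexes(["GRB2"], CHRONO_BINDING_RULES, 2)

    def test_deterministic_ordering(self):
        a = enumerate_chrono_complexes(ALL_MONOMERS, CHRONO_BINDING_RULES, 4)
        b = enumerate_chrono_complexes(reversed(ALL_MONOMERS),
                                       CHRONO_BINDING_RULES, 4)
        assert [s.name for s in a] == [s.name for s in b]

    @settings(max_examples=30, deadline=None)
    @given(
        base=st.sets(st.sampled_from(ALL_MONOMERS), max_size=6),
        allowed=st.sets(st.sampled_from(ALL_MONOMERS), max_size=7),
        max_size=st.integers(2, 4),
    )
    def test_agrees_with_brute_force_oracle(self, base, allowed, max_size):
        rules = BindingRuleSet([
            BindingRule("CHRONO", m, m in allowed, 1.0, 0.5)
            for m in ALL_MONOMERS
        ])
        got = {sp.constituents
               for sp in enumerate_chrono_complexes(base, rules, max_size)}
        assert got == brute_force_chrono_complexes(base, rules, max_size)


@pytest.fixture(scope="module")
def model():
    return build_reduced_model()


class TestPerturbations:
    def test_knockdown_scales_transcription_rates(self, model):
        kd = apply_perturbation(model, GeneticPerturbation(
            gene="Cry2", action="knockdown", fraction=0.3))
        assert kd.parameters["vmax_Cry2"] == pytest.approx(
            0.3 * model.parameters["vmax_Cry2"])
        assert kd.parameters["basal_Cry2"] == pytest.approx(
            0.3 * model.parameters["basal_Cry2"])

    def test_full_fraction_knockdown_is_identity(self, model):
        kd = apply_perturbation(model, GeneticPerturbation(
            gene="Cry1", action="knockdown", fraction=1.0))
        assert kd.parameters == model.parameters

    def test_knockout_zeroes_rates_and_preserves_species(self, model):
        ko = apply_perturbation(model, GeneticPerturbation(
            gene="Chrono", action="knockout"))
        assert ko.parameters["vmax_Chrono"] == 0.0
        assert ko.parameters["basal_Chrono"] == 0.0
        assert ko.species_names == model.species_names

    def test_knockouts_commute(self, model):
        ab = apply_perturbations(model, parse_perturbations("Cry1:ko,Cry2:ko"))
        ba = apply_perturbations(model, parse_perturbations("Cry2:ko,Cry1:ko"))
        assert ab.parameters == ba.parameters
        assert ab.species_names == ba.species_names
        assert [r.rate_param for r in ab.reactions] == \
               [r.rate_param for r in ba.reactions]

    def test_original_model_unmodified(self, model):
        before = dict(model.parameters)
        apply_perturbation(model, GeneticPerturbation(
            gene="Cry2", action="knockdown", fraction=0.3))
        assert model.parameters == before
        assert "perturbations" not in model.metadata

    def test_overexpression_adds_exactly_one_production_reaction(self, model):
        oe = apply_perturbation(model, GeneticPerturbation(
            gene="Chrono", action="overexpress", extra_production=0.1))
        assert len(oe.reactions) == len(model.reactions) + 1
        extra = oe.reactions[-1]
        assert extra.reactants == ()
        assert extra.products == (("CHRONO@cyt", 1),)
        assert oe.parameters[extra.rate_param] == pytest.approx(0.1)

    def test_unknown_gene_error_names_available_genes(self, model):
        with pytest.raises(ConfigurationError, match="Per1"):
            apply_perturbation(model, GeneticPerturbation(
                gene="Nr1d1", action="knockout"))

    @pytest.mark.parametrize("spec,expected", [
        ("Cry1:ko", [("Cry1", "knockout", None)]),
        ("Cry2:kd:0.3", [("Cry2", "knockdown", 0.3)]),
        ("Chrono:oe:0.25", [("Chrono", "overexpress", None)]),
        ("Cry1:ko, Cry2:kd:0.5", [("Cry1", "knockout", None),
                                  ("Cry2", "knockdown", 0.5)]),
        ("", []),
    ])
    def test_perturbation_grammar(self, spec, expected):
        got = [(p.gene, p.action, p.fraction) for p in parse_perturbations(spec)]
        assert got == expected

    @pytest.mark.parametrize("bad", ["Cry1", "Cry1:zz", "Cry2:kd", "Cry1:ko:3"])
    def test_malformed_specs_raise(self, bad):
        with pytest.raises(ConfigurationError):
            parse_perturbations(bad)

    def test_invalid_fractions_rejected(self):
        for frac in (0.0, -0.2, 1.5):
            with pytest.raises(ConfigurationError):
                GeneticPerturbation(gene="Cry2", action="knockdown",
                                    fraction=frac)


class TestReducedModelStructure:
    def test_chrono_species_present_and_invariants_hold(self, model):
        names = model.species_names
        assert "Chrono_mRNA" in names
        assert "BMAL1_CLOCK:CHRONO:PER@nuc" in names
        model.validate()  # raises on any invariant violation

    def test_chrono_disabled_drops_exactly_chrono_species(self):
        full = build_reduced_model()
        bare = build_reduced_model({"chrono_enabled": False})
        dropped = set(full.species_names) - set(bare.species_names)
        assert dropped == {"Chrono_mRNA", "CHRONO@cyt", "CHRONO:PER@nuc",
                           "BMAL1_CLOCK:CHRONO:PER@nuc"}
        assert all("CHRONO" not in n for n in bare.species_names)

    def test_chrono_mrna_decay_tied_to_per2(self, model):
        chrono = model.transcription_rule("Chrono")
        per2 = model.transcription_rule("Per2")
        assert chrono.degradation_param == per2.degradation_param

    def test_missing_parameter_reported_by_name(self):
        with pytest.raises(ConfigurationError, match="vmax_Per1"):
            build_reduced_model({"parameters": {"vmax_Per1": None}})

    def test_binding_reactions_conserve_monomers(self, model):
        """Every pure binding/unbinding reaction is stoichiometrically
        balanced in monomer content."""
        content = {}
        for sp in model.species:
            if sp.kind == "complex":
                content[sp.name] = dict()
                for c in sp.constituents:
                    content[sp.name][c] = content[sp.name].get(c, 0) + 1
            elif sp.kind == "monomer":
                content[sp.name] = {sp.name.split("@")[0]: 1}
        for rxn in model.reactions:
            sides = []
            for side in (rxn.reactants, rxn.products):
                total = {}
                known = True
                for name, stoich in side:
                    if name not in content:
                        known = False
                        break
                    for mono, k in content[name].items():
                        total[mono] = total.get(mono, 0) + k * stoich
                sides.append(total if known else None)
            is_binding = (len(rxn.reactants) >= 1 and len(rxn.products) >= 1
                          and sides[0] is not None and sides[1] is not None
                          and sum(dict(rxn.reactants).values()) !=
                          sum(dict(rxn.products).values()))
            if is_binding and all(
                    any(model.species[model.species_index(n)].kind == "complex"
                        for n, _ in side)
                    for side in (rxn.products,) ):
                assert sides[0] == sides[1], rxn.label

    def test_json_round_trip(self, model, tmp_path):
        path = tmp_path / "model.json"
        model.to_json(path)
        back = ModelSpec.from_json(path)
        assert back.species_names == model.species_names
        assert back.parameters == model.parameters
        assert len(back.reactions) == len(model.reactions)
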