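"""Model data structures, JSON/SBML loading, views and condition merging."""

import json
import math

import numpy as np
import pytest

from strainbench.errors import (
    ConstraintConflictError,
    ModelFormatError,
    NoObjectiveError,
    ValidationError,
)
from strainbench.model import (
    DEFAULT_BOUND,
    EnvironmentalConditions,
    FluxDistribution,
    apply_conditions,
    load_json,
    load_model,
    read_medium_tsv,
    save_json,
    stoichiometric_matrix,
)
from strainbench.simulation import fba


class TestJsonDialect:
    def test_load_toy_fixture(self, toy1, tmp_path):
        path = tmp_path / "TOY1.json"
        save_json(toy1, path)
        model = load_model(path, "json")
        assert len(model.reactions) == 6
        assert len(model.genes) == 4
        assert model.objective_id == "R_biomass"

    def test_round_trip_preserves_structure(self, toy1, tmp_path):
        path = tmp_path / "m.json"
        save_json(toy1, path)
        reloaded = load_json(path)
        assert reloaded.reaction_ids == toy1.reaction_ids
        assert reloaded.metabolite_ids == toy1.metabolite_ids
        assert reloaded.genes == toy1.genes
        assert reloaded.objective_id == toy1.objective_id
        for rid in toy1.reaction_ids:
            a, b = toy1.reaction(rid), reloaded.reaction(rid)
            assert a.bounds == b.bounds
            assert a.stoichiometry == b.stoichiometry
            ga = a.gpr.original_string if a.gpr else None
            gb = b.gpr.original_string if b.gpr else None
            assert ga == gb

    def test_malformed_gpr_names_reaction(self, toy1, tmp_path):
        path = tmp_path / "bad.json"
        save_json(toy1, path)
        doc = json.loads(path.read_text())
        doc["reactions"][1]["gpr"] = "g1 and"
        path.write_text(json.dumps(doc))
        with pytest.raises(ModelFormatError, match="R1"):
            load_json(path)

    def test_missing_objective_is_explicit(self, toy1, tmp_path):
        path = tmp_path / "noobj.json"
        save_json(toy1, path)
        doc = json.loads(path.read_text())
        doc["objective"] = None
        path.write_text(json.dumps(doc))
        with pytest.raises(NoObjectiveError):
            load_json(path)

    def test_infinite_bounds_clamp(self, toy1, tmp_path):
        path = tmp_path / "inf.json"
        save_json(toy1, path)
        doc = json.loads(path.read_text())
        doc["reactions"][0]["ub"] = 1e30
        doc["reactions"][1]["lb"] = -1e30
        path.write_text(json.dumps(doc))
        model = load_json(path)
        assert model.reaction("R_up").upper_bound == DEFAULT_BOUND
        assert model.reaction("R1").lower_bound == -DEFAULT_BOUND


class TestSbml:
    def test_sbml_round_trip_through_cobra(self, toy1, tmp_path):
        import cobra

        cm = cobra.Model("toy")
        mets = {m.id: cobra.Metabolite(m.id, compartment="c") for m in toy1.metabolites}
        for r in toy1.reactions:
            cr = cobra.Reaction(r.id)
            cr.add_metabolites({mets[k]: v for k, v in r.stoichiometry.items()})
            cr.bounds = r.bounds
            if r.gpr is not None:
                cr.gene_reaction_rule = r.gpr.original_string
            cm.add_reactions([cr])
        cm.objective = "R_biomass"
        path = tmp_path / "toy.xml"
        cobra.io.write_sbml_model(cm, str(path))

        model = load_model(path, "sbml")
        assert set(model.reaction_ids) == set(toy1.reaction_ids)
        assert model.genes == toy1.genes
        assert model.objective_id == "R_biomass"
        assert fba(model).objective_value == pytest.approx(5.0)

    def test_unparseable_file_is_a_format_error(self, tmp_path):
        path = tmp_path / "junk.xml"
        path.write_text("<sbml>this is not a model")
        with pytest.raises(ModelFormatError):
            load_model(path, "sbml")


class TestValidation:
    def test_bad_stoichiometry_reference(self, toy1):
        from strainbench.model import MetabolicModel, Reaction

        bad = Reaction("R_bad", {"Z": -1.0}, 0, 10)
        with pytest.raises(ValidationError, match="Z"):
            MetabolicModel(toy1.metabolites, toy1.reactions + [bad],
                           toy1.genes, "R_biomass")

    def test_gpr_over_unknown_gene(self, toy1):
        from strainbench.gpr import parse_gpr
        from strainbench.model import MetabolicModel, Reaction

        bad = Reaction("R_bad", {"A": -1.0}, 0, 10, parse_gpr("g9"))
        with pytest.raises(ValidationError, match="g9"):
            MetabolicModel(toy1.metabolites, toy1.reactions + [bad],
                           toy1.genes, "R_biomass")


class TestStoichiometricMatrix:
    def test_shape_and_entries(self, toy1):
        S = stoichiometric_matrix(toy1)
        assert S.shape == (len(toy1.metabolites), len(toy1.reactions))
        j = toy1.reaction_ids.index("R1")
        col = {toy1.metabolite_ids[i]: S[i, j] for i in range(S.shape[0]) if S[i, j]}
        assert col == {"A": -1.0, "B": 1.0}

    def test_exchange_column_has_one_entry(self, toy1):
        S = stoichiometric_matrix(toy1)
        for rid in ("R_up", "EX_P"):
            j = toy1.reaction_ids.index(rid)
            assert np.count_nonzero(S[:, j]) == 1

    def test_random_models_keep_shape(self, random_models):
        for model in random_models[:5]:
            S = stoichiometric_matrix(model)
            assert S.shape == (len(model.metabolites), len(model.reactions))


class TestConditions:
    def test_medium_cuts_growth(self, toy1):
        env = EnvironmentalConditions({"R_up": (0.0, 5.0)})
        view = apply_conditions(toy1, env)
        assert fba(view).objective_value == pytest.approx(2.5)
        assert fba(toy1).objective_value == pytest.approx(5.0)

    def test_empty_conditions_are_identity(self, toy1):
        view = apply_conditions(toy1)
        for rid in toy1.reaction_ids:
            assert view.bounds(rid) == toy1.reaction(rid).bounds

    def test_candidate_overrides_beat_environment(self, toy1):
        env = EnvironmentalConditions({"R1": (0.0, 10.0)})
        view = apply_conditions(toy1, env, extra={"R1": (0.0, 0.0)})
        assert view.bounds("R1") == (0.0, 0.0)

    def test_source_model_never_mutated(self, toy1):
        before = {rid: toy1.reaction(rid).bounds for rid in toy1.reaction_ids}
        apply_conditions(toy1, EnvironmentalConditions({"R_up": (0.0, 1.0)}),
                         extra={"R1": (0.0, 0.0)})
        after = {rid: toy1.reaction(rid).bounds for rid in toy1.reaction_ids}
        assert before == after

    def test_conflicting_merge_names_reaction(self, toy1):
        with pytest.raises(ConstraintConflictError, match="R1"):
            apply_conditions(toy1, extra={"R1": (5.0, 2.0)})

    def test_unknown_reaction_rejected(self, toy1):
        with pytest.raises(ValidationError):
            apply_conditions(toy1, extra={"R99": (0.0, 1.0)})

    def test_medium_tsv_round_trip(self, tmp_path):
        path = tmp_path / "medium.tsv"
        path.write_text("reaction_id\tlb\tub\nR_up\t0\t5\n")
        env = read_medium_tsv(path)
        assert env.bounds_override == {"R_up": (0.0, 5.0)}


class TestFluxDistribution:
    def test_tsv_round_trip(self, tmp_path):
        fd = FluxDistribution({"R1": 1.25, "R2": -3.5})
        path = tmp_path / "fluxes.tsv"
        fd.to_tsv(path)
        back = FluxDistribution.from_tsv(path)
        assert dict(back) == dict(fd)
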