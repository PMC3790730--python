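"""Design construction and mixed-model-equation assembly and solving."""

import numpy as np
import pandas as pd
import pytest

from dogblup import (ModelSpec, VarianceComponents, ainverse_sparse,
                     assemble_mme, build_design, build_pedigree,
                     solve_mme)
from dogblup.registry import TraitDataset
from dogblup.sparsela import SchurFactor, SpluFactor

from conftest import edited_datasets


def _dataset(trait, rows):
    """rows: (dog_id, value, breed, sex, test_year, test_month,
    birth_year, age_group)"""
    frame = pd.DataFrame(rows, columns=[
        "dog_id", "value", "breed", "sex", "test_year", "test_month",
        "birth_year", "age_group"])
    frame["score"] = frame["value"]
    return TraitDataset(trait=trait, data=frame)


def _mini_pedigree(dogs, breed="B"):
    return build_pedigree([(d, "", "", "male", breed, 1990) for d in dogs])


class TestBuildDesign:
    def test_single_trait_contributes_only_its_equations(self):
        ped = _mini_pedigree(["a", "b"])
        ds = _dataset("hip", [("a", 2.0, "B", "male", 2000, 5, 1998, "24")])
        design = build_design({"hip": ds}, ped)
        assert design.traits == ["hip"]
        assert len(design.per_trait["hip"].y) == 1

    def test_fixture_column_counts_match_level_arithmetic(self):
        # 10 dogs, 2 breeds, 2 sexes, 3 test years inside one scoring
        # era, 2 birth years, 2 age groups.  With all levels of the first
        # factor kept and references dropped elsewhere the hand count is:
        # breed 2 + sex 1 + era 0 (single observed level) + nested test
        # year 2 + birth year 1 + age group 1 = 7 columns.
        spec = [("B1", "female", 2000, 1997, "24"),
                ("B1", "male", 2000, 1997, "24"),
                ("B1", "female", 2001, 1997, "25-29"),
                ("B1", "male", 2001, 1998, "24"),
                ("B1", "female", 2002, 1998, "25-29"),
                ("B2", "male", 2000, 1997, "24"),
                ("B2", "female", 2001, 1998, "25-29"),
                ("B2", "male", 2002, 1997, "24"),
                ("B2", "female", 2002, 1998, "24"),
                ("B2", "male", 2000, 1998, "25-29")]
        rows = [(f"d{i}", 2.0 + 0.1 * i, b, s, ty, 1 + i, by, age)
                for i, (b, s, ty, by, age) in enumerate(spec)]
        ds = _dataset("hip", rows)
        ped = _mini_pedigree([f"d{i}" for i in range(10)])
        design = build_design({"hip": ds}, ped)
        labels = design.per_trait["hip"].fixed_labels
        by_factor = {}
        for factor, _ in labels:
            by_factor[factor] = by_factor.get(factor, 0) + 1
        assert by_factor == {"breed": 2, "sex": 1, "test_year": 2,
                             "birth_year": 1, "age_group": 1}
        X = design.per_trait["hip"].X.toarray()
        assert np.linalg.matrix_rank(X) == X.shape[1] == 7

    def test_identical_records_get_identical_design_rows(self):
        rows = [("a", 2.0, "B", "male", 2000, 5, 1998, "24"),
                ("b", 3.0, "B", "male", 2000, 5, 1998, "24")]
        ped = _mini_pedigree(["a", "b"])
        design = build_design({"hip": _dataset("hip", rows)}, ped)
        X = design.per_trait["hip"].X.toarray()
        assert np.array_equal(X[0], X[1])

    def test_scored_dog_missing_from_pedigree_fails(self):
        ped = _mini_pedigree(["a"])
        ds = _dataset("hip", [("ghost", 2.0, "B", "male", 2000, 5, 1998,
                               "24")])
        with pytest.raises(ValueError, match="ghost"):
            build_design({"hip": ds}, ped)

    def test_ancestors_without_records_receive_equations(self, small_system):
        system = small_system["system"]
        assert system.n_animals == small_system["pedigree"].n
        scored = {d for p in system.design.per_trait.values()
                  for d in p.dog_ids}
        assert len(scored) < system.n_animals


class TestAssembleAndSolve:
    def test_system_is_symmetric_with_expected_dimension(self, small_system):
        system = small_system["system"]
        C = system.C
        assert (C - C.T).power(2).sum() < 1e-18
        expected = (sum(system.n_fixed) + sum(system.n_u)
                    + 2 * system.n_animals)
        assert system.n_equations == expected

    def test_zero_covariances_decouple_into_single_trait_runs(self):
        rng = np.random.default_rng(1)
        dogs = [f"d{i}" for i in range(12)]
        ped = _mini_pedigree(dogs)
        rel = ainverse_sparse(ped)
        rows_h = [(d, float(rng.normal(2, 0.6)), "B", "male", 2000, 5, 1998,
                   "24") for d in dogs[:8]]
        rows_e = [(d, float(rng.normal(1, 0.2)), "B", "male", 2000, 5, 1998,
                   "24") for d in dogs[4:]]
        datasets = {"hip": _dataset("hip", rows_h),
                    "elbow": _dataset("elbow", rows_e)}
        spec = ModelSpec(fixed_factors={"hip": ["breed"],
                                        "elbow": ["breed"]},
                         include_u=False)
        vc_diag = VarianceComponents(G0=np.diag([0.08, 0.006]),
                                     R0=np.diag([0.29, 0.03]))
        both = solve_mme(assemble_mme(build_design(datasets, ped, spec),
                                      rel, vc_diag))
        single = {}
        for k, trait in enumerate(("hip", "elbow")):
            vc1 = VarianceComponents(G0=[[vc_diag.G0[k, k]]],
                                     R0=[[vc_diag.R0[k, k]]])
            d1 = build_design({trait: datasets[trait]}, ped,
                              ModelSpec(fixed_factors={trait: ["breed"]},
                                        include_u=False))
            single[trait] = solve_mme(assemble_mme(d1, rel, vc1))
        np.testing.assert_allclose(both.ebv[:, 0],
                                   single["hip"].ebv[:, 0], atol=1e-8)
        np.testing.assert_allclose(both.ebv[:, 1],
                                   single["elbow"].ebv[:, 0], atol=1e-8)

    def test_single_animal_closed_form_shrinkage(self):
        # one animal, one centred record, no fixed effects: the MME reduce
        # to (1/r + 1/g) a = y/r, i.e. a = h2 * y
        ped = _mini_pedigree(["solo"])
        rel = ainverse_sparse(ped)
        y, g, r = 0.8, 0.08, 0.32
        ds = _dataset("hip", [("solo", y, "B", "male", 2000, 5, 1998, "24")])
        spec = ModelSpec(fixed_factors={"hip": []}, include_u=False)
        system = assemble_mme(build_design({"hip": ds}, ped, spec), rel,
                              VarianceComponents(G0=[[g]], R0=[[r]]))
        sol = solve_mme(system)
        h2 = g / (g + r)
        assert sol.ebv[0, 0] == pytest.approx(h2 * y, abs=1e-12)

    def test_translation_of_one_trait_leaves_ebvs_unchanged(self,
                                                            small_system):
        system = small_system["system"]
        base = solve_mme(system)
        datasets = dict(small_system["datasets"])
        shifted = datasets["hip"].data.copy()
        shifted["value"] += 3.0
        datasets["hip"] = TraitDataset(trait="hip", data=shifted)
        design = build_design(datasets, small_system["pedigree"])
        system2 = assemble_mme(design, small_system["relationship"],
                               system.components)
        moved = solve_mme(system2)
        np.testing.assert_allclose(moved.ebv, base.ebv, atol=1e-6)
        # the shift lands in the trait-1 breed (intercept-role) estimates
        fx0 = base.fixed_effects()
        fx1 = moved.fixed_effects()
        b0 = fx0[(fx0.trait == "hip") & (fx0.factor == "breed")]["estimate"]
        b1 = fx1[(fx1.trait == "hip") & (fx1.factor == "breed")]["estimate"]
        np.testing.assert_allclose(b1.to_numpy() - b0.to_numpy(), 3.0,
                                   atol=1e-6)

    def test_component_rescaling_leaves_solutions_unchanged(self,
                                                            small_system):
        system = small_system["system"]
        base = solve_mme(system)
        doubled = assemble_mme(system.design, small_system["relationship"],
                               system.components.scaled(2.0))
        np.testing.assert_allclose(solve_mme(doubled).solution,
                                   base.solution, atol=1e-6)

    def test_direct_and_pcg_agree(self, small_system):
        system = small_system["system"]
        direct = system.solve(method="direct")
        pcg = system.solve(method="pcg", tol=1e-12)
        assert np.abs(direct.solution - pcg.solution).max() < 1e-6

    def test_singular_residual_covariance_rejected(self):
        with pytest.raises(ValueError, match="positive definite"):
            VarianceComponents(G0=np.eye(2),
                               R0=np.ones((2, 2))).validate()

    def test_block_and_monolithic_factorizations_agree(self, small_system):
        system = small_system["system"]
        factor = system.factorize()
        assert isinstance(factor, SchurFactor)
        mono = SpluFactor(system.C)
        assert factor.logdet() == pytest.approx(mono.logdet(), abs=1e-6)
        rhs = system.rhs
        np.testing.assert_allclose(factor.solve(rhs), mono.solve(rhs),
                                   atol=1e-7)

    def test_equation_index_map_roundtrip(self, small_system):
        system = small_system["system"]
        trait = system.traits[0]
        label = system.fixed_labels[0][3]
        eq = system.equation_index("fixed", trait, label)
        assert eq == system.off_fixed[0] + 3
        eq_a = system.equation_index("animal", trait, 7)
        assert eq_a == system.off_animal + 7


class TestEstimability:
    def test_ebvs_invariant_to_reference_level_choice(self):
        rng = np.random.default_rng(2)
        dogs = [f"d{i}" for i in range(16)]
        ped = _mini_pedigree(dogs)
        rel = ainverse_sparse(ped)
        rows = [(d, float(rng.normal(2, 0.6)), "B", "male" if i % 2 else
                 "female", 2000 + i % 3, 1 + i % 12, 1998, "24")
                for i, d in enumerate(dogs)]
        ds = _dataset("hip", rows)
        vc = VarianceComponents(G0=[[0.08]], R0=[[0.29]])
        specs = [ModelSpec(fixed_factors={"hip": ["breed", "sex",
                                                  "test_year"]},
                           include_u=False),
                 ModelSpec(fixed_factors={"hip": ["sex", "breed",
                                                  "test_year"]},
                           include_u=False)]
        ebvs = []
        for spec in specs:
            system = assemble_mme(build_design({"hip": ds}, ped, spec),
                                  rel, vc)
            ebvs.append(solve_mme(system).ebv[:, 0])
        np.testing.assert_allclose(ebvs[0], ebvs[1], atol=1e-9)
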