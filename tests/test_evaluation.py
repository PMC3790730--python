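"""EBVs, prediction error variances, accuracies and their summaries."""

import numpy as np
import pandas as pd
import pytest

import dogblup.model
from dogblup import (ModelSpec, SimConfig, VarianceComponents,
                     accuracy, ainverse_sparse, assemble_mme, build_design,
                     build_pedigree, compute_pev, ebv_accuracy_correlation,
                     evaluate, parent_offspring_prediction,
                     simulate_population, solve_mme)
from dogblup.registry import TraitDataset

SPEC_PLAIN = ModelSpec(fixed_factors={"hip": []}, include_u=False)


def _dataset(rows):
    frame = pd.DataFrame(rows, columns=["dog_id", "value"])
    frame["score"] = frame["value"]
    return TraitDataset(trait="hip", data=frame)


def _system(ped_rows, records, g=0.08, r=0.32):
    ped = build_pedigree(ped_rows)
    rel = ainverse_sparse(ped)
    design = build_design({"hip": _dataset(records)}, ped, SPEC_PLAIN)
    vc = VarianceComponents(G0=[[g]], R0=[[r]])
    return assemble_mme(design, rel, vc), ped


class TestAccuracyFormula:
    def test_no_information_gives_zero(self):
        assert accuracy(np.array([0.08]), 0.08)[0] == 0.0

    def test_zero_pev_gives_one(self):
        assert accuracy(np.array([0.0]), 0.08)[0] == 1.0

    def test_half_pev_gives_sqrt_half(self):
        assert accuracy(np.array([0.04]), 0.08)[0] == \
            pytest.approx(np.sqrt(0.5))

    def test_pev_above_bound_is_diagnostic_failure(self):
        with pytest.raises(ValueError, match="PEV exceeds"):
            accuracy(np.array([0.2]), 0.08)

    def test_inbred_animal_pev_above_sigma_a_is_allowed(self):
        out = accuracy(np.array([0.09]), 0.08,
                       inbreeding=np.array([0.25]))
        assert out[0] == 0.0  # clipped radicand


class TestComputePev:
    def test_unrelated_animal_without_records_has_pev_sigma_a(self):
        system, ped = _system(
            [("a", "", "", "male", "B", 1990),
             ("loner", "", "", "male", "B", 1990)],
            [("a", 0.5)])
        pev = compute_pev(system)
        i = ped.index_of(["loner"])[0]
        assert pev[i, 0] == pytest.approx(0.08, abs=1e-10)
        j = ped.index_of(["a"])[0]
        assert pev[j, 0] < 0.08

    def test_exact_pev_matches_dense_inverse(self):
        rng = np.random.default_rng(4)
        rows = [(f"f{i}", "", "", "male" if i % 2 == 0 else "female", "B",
                 1990) for i in range(8)]
        rows += [(f"k{i}", f"f{2*(i % 4)}", f"f{2*(i % 4)+1}",
                  "male", "B", 1995) for i in range(12)]
        records = [(f"k{i}", float(rng.normal(0, 0.6))) for i in range(12)]
        system, ped = _system(rows, records)
        pev = compute_pev(system, method="exact")
        dense = np.linalg.inv(system.C.toarray())
        expected = np.diag(dense)[system.off_animal:]
        np.testing.assert_allclose(pev[:, 0], expected, atol=1e-8)

    def test_selected_pev_matches_dense_inverse(self, monkeypatch):
        monkeypatch.setattr(dogblup.model, "MONOLITHIC_FACTOR_LIMIT", 0)
        rng = np.random.default_rng(5)
        rows = [(f"f{i}", "", "", "male" if i % 2 == 0 else "female", "B",
                 1990) for i in range(8)]
        rows += [(f"k{i}", f"f{2*(i % 4)}", f"f{2*(i % 4)+1}",
                  "male", "B", 1995) for i in range(12)]
        records = [(f"k{i}", float(rng.normal(0, 0.6))) for i in range(12)]
        system, ped = _system(rows, records)
        pev = compute_pev(system, method="selected")
        dense = np.linalg.inv(system.C.toarray())
        expected = np.diag(dense)[system.off_animal:]
        np.testing.assert_allclose(pev[:, 0], expected, atol=1e-8)

    def test_mc_pev_approximates_exact(self):
        rng = np.random.default_rng(6)
        rows = [(f"f{i}", "", "", "male", "B", 1990) for i in range(6)]
        records = [(f"f{i}", float(rng.normal(0, 0.6))) for i in range(6)]
        system, _ = _system(rows, records)
        exact = compute_pev(system, method="exact")
        approx = compute_pev(system, method="mc", n_samples=4000, seed=1)
        assert np.abs(approx - exact).max() / exact.max() < 0.15


class TestParentAverage:
    def test_unphenotyped_offspring_gets_midparent_ebv(self):
        rng = np.random.default_rng(7)
        rows = [("s", "", "", "male", "B", 1990),
                ("d", "", "", "female", "B", 1990),
                ("kid", "s", "d", "male", "B", 1995)]
        records = [("s", float(rng.normal())), ("d", float(rng.normal()))]
        system, ped = _system(rows, records)
        sol = solve_mme(system)
        s, d, k = ped.index_of(["s", "d", "kid"])
        assert sol.ebv[k, 0] == pytest.approx(
            0.5 * (sol.ebv[s, 0] + sol.ebv[d, 0]), abs=1e-8)

    def test_parent_accuracy_monotone_in_progeny_count(self):
        def sire_accuracy(n_prog):
            rng = np.random.default_rng(8)
            rows = [("s", "", "", "male", "B", 1990)]
            rows += [(f"d{i}", "", "", "female", "B", 1990)
                     for i in range(n_prog)]
            rows += [(f"k{i}", "s", f"d{i}", "male", "B", 1995)
                     for i in range(n_prog)]
            records = [(f"k{i}", float(rng.normal(0, 0.6)))
                       for i in range(n_prog)]
            system, ped = _system(rows, records)
            pev = compute_pev(system)
            i = ped.index_of(["s"])[0]
            return accuracy(pev[i], 0.08)[0]

        a5, a50 = sire_accuracy(5), sire_accuracy(50)
        assert 0 < a5 < a50 < 1


@pytest.fixture(scope="module")
def small_evaluation(small_system):
    from dogblup import published_components
    system = assemble_mme(small_system["design"],
                          small_system["relationship"],
                          published_components())
    sol = solve_mme(system)
    return system, sol, evaluate(system, sol)


class TestSummaries:
    def test_evaluation_table_is_complete_and_bounded(self,
                                                      small_evaluation):
        system, _, result = small_evaluation
        table = result.table
        assert len(table) == 2 * system.n_animals
        assert table["accuracy"].between(0, 1).all()
        assert (table["pev"] >= 0).all()
        scored = set(system.design.per_trait["hip"].dog_ids)
        hip = result.for_trait("hip")
        acc_scored = hip[hip.dog_id.isin(scored)]["accuracy"]
        acc_unscored = hip[~hip.dog_id.isin(scored)]["accuracy"]
        assert acc_scored.mean() > acc_unscored.mean()

    def test_ebv_accuracy_correlation_by_breed(self, small_evaluation):
        _, _, result = small_evaluation
        overall = ebv_accuracy_correlation(result, "hip")
        assert -1 <= overall <= 1
        per_breed = ebv_accuracy_correlation(result, "hip", by_breed=True)
        assert len(per_breed) == 2

    def test_zero_variance_accuracy_is_signalled(self):
        frames = pd.DataFrame({
            "dog_id": list("abc"), "breed": "B", "birth_year": 2000,
            "trait": "hip", "ebv": [0.1, 0.2, 0.3],
            "pev": 0.0, "accuracy": [0.5, 0.5, 0.5], "inbreeding": 0.0})
        from dogblup.evaluation import EvaluationResult
        with pytest.raises(ValueError, match="zero variance"):
            ebv_accuracy_correlation(EvaluationResult(frames), "hip")

    def test_midparent_ebv_predicts_better_than_phenotype(
            self, small_evaluation, small_system):
        _, _, result = small_evaluation
        pheno = small_system["records"]
        hip = pheno[pheno.trait == "hip"].rename(columns={"score": "value"})
        r_ph, r_ebv = parent_offspring_prediction(
            hip, small_system["pedigree"], result, "hip")
        assert r_ebv > r_ph

    def test_too_few_trios_signalled(self, small_evaluation):
        _, _, result = small_evaluation
        ped = build_pedigree([("x", "", "", "male", "B", 1990)])
        pheno = pd.DataFrame({"dog_id": ["x"], "value": [1.0]})
        with pytest.raises(ValueError, match="trios"):
            parent_offspring_prediction(pheno, ped, result, "hip")


class TestMidparentTheory:
    def test_fully_heritable_trait_gives_sqrt_half_correlation(self):
        """With phenotype = breeding value (h2 = 1, no environment) the
        midparent-offspring correlation tends to sqrt(1/2)."""
        cfg = SimConfig.recovery(n_breeds=1, dogs_per_breed=2400,
                                 generations=4, seed=13)
        ped, bv = simulate_population(cfg, seed=13)
        off, mid = [], []
        for i in range(ped.n):
            s, d = ped.sire[i], ped.dam[i]
            if s >= 0 and d >= 0:
                off.append(bv[i, 0])
                mid.append(0.5 * (bv[s, 0] + bv[d, 0]))
        r = np.corrcoef(off, mid)[0, 1]
        assert r == pytest.approx(np.sqrt(0.5), abs=0.06)

    def test_non_heritable_trait_gives_zero_correlation(self):
        rng = np.random.default_rng(14)
        cfg = SimConfig.recovery(n_breeds=1, dogs_per_breed=2400,
                                 generations=4, seed=13)
        ped, _ = simulate_population(cfg, seed=13)
        noise = rng.normal(size=ped.n)
        off, mid = [], []
        for i in range(ped.n):
            s, d = ped.sire[i], ped.dam[i]
            if s >= 0 and d >= 0:
                off.append(noise[i])
                mid.append(0.5 * (noise[s] + noise[d]))
        assert abs(np.corrcoef(off, mid)[0, 1]) < 0.08
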