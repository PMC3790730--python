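"""Shared fixtures: toy pedigrees, random pedigree generator, small
simulated populations reused across test modules."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from dogblup import (EditConfig, SimConfig, ainverse_sparse, assemble_mme,
                     build_design, build_pedigree, simulate_population,
                     simulate_records, published_components)
from dogblup.registry import apply_elbow_edits, apply_hip_edits


def make_records_frame(rows):
    """Rows of (dog_id, breed, sex, by, bm, ty, tm, trait, score)."""
    return pd.DataFrame(rows, columns=[
        "dog_id", "breed", "sex", "birth_year", "birth_month",
        "test_year", "test_month", "trait", "score"])


def random_pedigree(rng: np.random.Generator, n: int = 120,
                    n_breeds: int = 2, p_unknown: float = 0.25):
    """Random topological multi-breed pedigree for oracle comparisons."""
    rows = []
    per_breed = n // n_breeds
    for b in range(n_breeds):
        breed = f"B{b}"
        males, females = [], []
        for i in range(per_breed):
            dog = f"{breed}-{i:04d}"
            sex = "male" if rng.random() < 0.5 else "female"
            sire = dam = ""
            if i >= 4 and rng.random() > p_unknown and males and females:
                sire = males[rng.integers(0, len(males))]
            if i >= 4 and rng.random() > p_unknown and males and females:
                dam = females[rng.integers(0, len(females))]
            year = 1970 + i // 4
            rows.append((dog, sire, dam, sex, breed, year))
            (males if sex == "male" else females).append(dog)
    return build_pedigree(rows)


def records_with_dates(records: pd.DataFrame) -> pd.DataFrame:
    """Split the ISO date columns the generator writes into year/month."""
    out = records.copy()
    out[["birth_year", "birth_month"]] = \
        out["birth_date"].str.split("-", expand=True).astype(int)
    out[["test_year", "test_month"]] = \
        out["test_date"].str.split("-", expand=True).astype(int)
    return out


def edited_datasets(records: pd.DataFrame, **edit_kwargs):
    cfg = EditConfig(min_breed_records=1, **edit_kwargs)
    frame = records_with_dates(records)
    return {"hip": apply_hip_edits(frame, cfg),
            "elbow": apply_elbow_edits(frame, cfg)}


@pytest.fixture(scope="session")
def small_population():
    """Gaussian-recorded population (2 breeds x 800 dogs) with truth held."""
    cfg = SimConfig.recovery(n_breeds=2, dogs_per_breed=800, generations=6,
                             seed=3)
    ped, bv = simulate_population(cfg, seed=3)
    records = simulate_records(ped, bv, cfg, seed=3)
    return {"config": cfg, "pedigree": ped, "true_bv": bv,
            "records": records}


@pytest.fixture(scope="session")
def small_system(small_population):
    """Assembled MME for the small population at the true components."""
    datasets = edited_datasets(small_population["records"])
    ped = small_population["pedigree"]
    rel = ainverse_sparse(ped)
    design = build_design(datasets, ped)
    system = assemble_mme(design, rel, published_components())
    return {"datasets": datasets, "relationship": rel, "design": design,
            "system": system, **small_population}


@pytest.fixture
def trio_pedigree():
    return build_pedigree([
        ("sire", "", "", "male", "B", 1970),
        ("dam", "", "", "female", "B", 1970),
        ("kid", "sire", "dam", "male", "B", 1975),
    ])
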