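from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from rxswitch import (
    SimulationConfig,
    build_cohort,
    default_drug_dictionary,
    generate_cohort,
    phenotype_cohort,
)

DRUG_POOL = (
    ("fluoxetine", "SSRI"),
    ("sertraline", "SSRI"),
    ("citalopram", "SSRI"),
    ("amitriptyline", "TCA"),
    ("venlafaxine", "SNRI"),
    ("mirtazapine", "OTHER_AD"),
    ("ibuprofen", "NON_AD"),
)


def rx_frame(records, pid="P1"):
    """Build a sorted, deduplicated prescription table from (day, drug, class) tuples."""
    rows = sorted({(int(d), str(drug), str(cls)) for d, drug, cls in records})
    df = pd.DataFrame(
        {
            "participant_id": pid,
            "issue_date": pd.to_datetime([r[0] for r in rows], unit="D", origin="unix"),
            "drug_raw": [r[1] for r in rows],
            "drug_canonical": [r[1] for r in rows],
            "drug_class": [r[2] for r in rows],
        }
    )
    return df.sort_values(["participant_id", "issue_date", "drug_canonical"]).reset_index(drop=True)


def random_history(rng: np.random.Generator, max_records: int = 8):
    """A random small prescription history as (day, drug, class) tuples."""
    n = int(rng.integers(1, max_records + 1))
    out = []
    for _ in range(n):
        drug, cls = DRUG_POOL[int(rng.integers(0, len(DRUG_POOL)))]
        out.append((int(rng.integers(0, 121)), drug, cls))
    return out


@pytest.fixture(scope="session")
def small_cohort():
    """A modest synthetic cohort shared across read-only tests."""
    return generate_cohort(SimulationConfig(n_participants=3000), seed=7)


@pytest.fixture(scope="session")
def small_phenotyped(small_cohort):
    mem = build_cohort(small_cohort.diagnoses, set(small_cohort.prescriptions["participant_id"]))
    pheno, counts = phenotype_cohort(small_cohort.prescriptions, mem)
    return small_cohort, mem, pheno, counts


@pytest.fixture
def dictionary():
    return default_drug_dictionary()
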