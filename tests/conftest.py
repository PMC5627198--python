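import numpy as np
import pandas as pd
import pytest

import igemap as ig


@pytest.fixture(scope="session")
def small_map() -> ig.GeneticMap:
    """3 chromosomes x 8 markers, 10 cM spacing, Mb = 2 x cM + 3."""
    return ig.default_map(n_autosomes=3, include_x=False, markers_per_chrom=8, spacing_cm=10.0)


@pytest.fixture(scope="session")
def panel(small_map):
    G = ig.simulate_ri_genotypes(small_map, 32, seed=7)
    return small_map, G


def make_family_table(
    rng: np.random.Generator,
    n_families: int = 96,
    value_fn=None,
    role: str = "BXD_offspring",
    trait: str = "sucking",
    day: int = 6,
    n_lines: int = 32,
) -> ig.FamilyTable:
    """Minimal single-trait table with randomized covariates.

    ``value_fn(cov_row, rng)`` computes the trait value; default pure noise.
    Families cycle over ``n_lines`` line ids.
    """
    rows = []
    for i in range(n_families):
        cov = {
            "maternal_bodyweight": rng.normal(25, 2.5),
            "avg_B6_pup_weight": rng.normal(6, 0.7),
            "B6_litter_size": float(rng.integers(3, 6)),
            "avg_BXD_pup_weight": rng.normal(5.5, 0.7),
            "BXD_litter_size": float(rng.integers(3, 6)),
            "batch": f"batch{rng.integers(1, 5)}",
        }
        value = value_fn(cov, rng) if value_fn else rng.normal()
        rows.append(
            {
                "family_id": f"F{i}",
                "line_id": f"BXD{(i % n_lines) + 1:03d}",
                "day": day,
                "role": role,
                "trait": trait,
                "value": value,
                **cov,
            }
        )
    return ig.FamilyTable(pd.DataFrame(rows))


@pytest.fixture
def family_table_factory():
    return make_family_table
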