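import numpy as np
import pandas as pd
import pytest

from trophomode.synthetic import (
    EnvironmentScenario,
    GeneratorSpec,
    generate_training,
    scaled_down,
)


@pytest.fixture(scope="session")
def small_spec() -> GeneratorSpec:
    """A down-scaled generator spec for fast unit tests."""
    return scaled_down(GeneratorSpec(seed=7), factor=8)


@pytest.fixture(scope="session")
def small_training(small_spec):
    """(matrix, labels, truth) from the down-scaled generator."""
    return generate_training(small_spec)


@pytest.fixture(scope="session")
def full_spec() -> GeneratorSpec:
    """The default-size generator spec (387 profiles, 2000 Pfams)."""
    return GeneratorSpec(seed=1)


@pytest.fixture(scope="session")
def full_training(full_spec):
    return generate_training(full_spec)


@pytest.fixture()
def contig_table() -> pd.DataFrame:
    """Three contigs in one species bin and sample, hand-checkable."""
    return pd.DataFrame(
        {
            "contig_id": ["c1", "c2", "c3"],
            "length_nt": [500, 1000, 2000],
            "est_count": [10.0, 20.0, 30.0],
            "species_bin": ["binA"] * 3,
            "sample_id": ["s1"] * 3,
        }
    )


def make_predictions(
    modes,
    species_bin="bin1",
    grouping_unit="u1",
    excluded=None,
    replicates=None,
    size_fractions=None,
) -> pd.DataFrame:
    """Build a minimal prediction table for gating/capability tests."""
    n = len(modes)
    excluded = excluded if excluded is not None else [False] * n
    reps = replicates if replicates is not None else [f"r{i}" for i in range(n)]
    fracs = size_fractions if size_fractions is not None else ["0.2-3um"] * n
    units = [grouping_unit] * n if isinstance(grouping_unit, str) else list(grouping_unit)
    rows = []
    for i, mode in enumerate(modes):
        rows.append(
            {
                "species_bin": species_bin,
                "sample_id": f"s{i}",
                "replicate": reps[i],
                "size_fraction": fracs[i],
                "grouping_unit": units[i],
                "mode": mode,
                "p_phototrophy": np.nan,
                "p_mixotrophy": np.nan,
                "p_heterotrophy": np.nan,
                "ctg_coverage": 1.0,
                "excluded": excluded[i],
                "reason": "",
            }
        )
    return pd.DataFrame(rows)
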