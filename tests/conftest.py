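import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for helpers.py

from coevonet import (
    Msa,
    PlantedGroup,
    SyntheticConfig,
    cluster_weights,
    generate_msa,
    generate_structure,
    permutation_zscores,
    trim_msa,
)


def small_config(seed: int = 11, **overrides) -> SyntheticConfig:
    """A reduced family used by unit tests (two planted groups, 300 seqs)."""
    kwargs = dict(
        n_sequences=300,
        n_columns=24,
        planted_groups=(
            PlantedGroup(columns=tuple(range(0, 6))),
            PlantedGroup(columns=tuple(range(6, 11))),
        ),
        n_subfamilies=5,
        subfamily_size=2,
        seed=seed,
    )
    kwargs.update(overrides)
    return SyntheticConfig(**kwargs)


@pytest.fixture(scope="session")
def small_family():
    """One small synthetic family shared by read-only tests: the alignment,
    ground truth, trimmed MSA, weights, MI matrix and structure."""
    cfg = small_config()
    msa, truth = generate_msa(cfg)
    tmsa = trim_msa(msa)
    weights = cluster_weights(tmsa)
    mm = permutation_zscores(tmsa, weights, n_perm=60, seed=101)
    structure = generate_structure(truth, seed=7)
    return {
        "config": cfg,
        "msa": msa,
        "truth": truth,
        "tmsa": tmsa,
        "weights": weights,
        "mi": mm,
        "structure": structure,
    }


@pytest.fixture()
def toy_msa() -> Msa:
    """Tiny hand-written alignment with known trimming behaviour."""
    #                 0123456789
    rows = [
        "AC-DEFGHIK",  # ref: gap at column 2
        "ACWDEFGHIK",
        "AC-DEFGH--",
        "-C-DE-----",
    ]
    return Msa(ids=["ref", "s1", "s2", "s3"], rows=rows, reference_id="ref")


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
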