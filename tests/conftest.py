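import numpy as np
import pandas as pd
import pytest

from panelgp.genotype_io import GenotypeDataset, MarkerMap
from panelgp.synthetic_data import (SimulationConfig, simulate_genotypes,
                                    simulate_marker_map)


def make_map(positions, chromosomes=None, prefix="m"):
    """Small marker map from explicit positions (single chromosome default)."""
    positions = list(positions)
    if chromosomes is None:
        chromosomes = [1] * len(positions)
    return MarkerMap(pd.DataFrame({
        "marker_id": [f"{prefix}{i}" for i in range(len(positions))],
        "chromosome": chromosomes,
        "position_bp": positions,
        "allele_a": "A",
        "allele_b": "B",
    }))


def make_dataset(dosages, positions=None, chromosomes=None):
    """Dataset from an explicit dosage matrix (rows: individuals)."""
    dosages = np.asarray(dosages, dtype=np.int8)
    n, m = dosages.shape
    if positions is None:
        positions = [1000 * (i + 1) for i in range(m)]
    marker_map = make_map(positions, chromosomes)
    samples = [f"s{i}" for i in range(n)]
    return GenotypeDataset(samples, marker_map, dosages)


@pytest.fixture(scope="session")
def small_cohort():
    """120 individuals x 400 markers on 2 chromosomes, clustered spacing."""
    cfg = SimulationConfig(
        n_individuals=120, n_markers=400,
        chromosome_lengths_bp=(5_000_000, 5_000_000),
        ld_decay_lambda_bp=100_000.0, seed=42,
    )
    marker_map = simulate_marker_map(cfg)
    return simulate_genotypes(marker_map, cfg), cfg
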