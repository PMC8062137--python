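"""Shared fixtures: one small synthetic experiment reused across test modules."""

import numpy as np
import pandas as pd
import pytest

from paleompra.simulate import (
    SimConfig,
    assign_truth,
    simulate_counts,
    simulate_library,
    simulate_reference,
)


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    return SimConfig(
        seed=11,
        n_pairs=120,
        n_variants=700,
        n_positive=25,
        n_scrambled=60,
        barcodes_per_oligo=18,
        dna_mean=12.0,
        chrom_length=120_000,
    )


@pytest.fixture(scope="session")
def small_experiment(small_config):
    """(reference, library, truth, counts) at desk scale."""
    reference = simulate_reference(small_config)
    library, variants = simulate_library(reference, small_config)
    truth = assign_truth(library, small_config)
    counts = simulate_counts(library, truth, small_config)
    return {
        "config": small_config,
        "reference": reference,
        "library": library,
        "variants": variants,
        "truth": truth,
        "counts": counts,
    }


@pytest.fixture(scope="session")
def deep_experiment():
    """A better-powered experiment for parameter-recovery assertions."""
    config = SimConfig(
        seed=23,
        n_pairs=150,
        n_variants=900,
        n_positive=20,
        n_scrambled=60,
        barcodes_per_oligo=60,
        dna_mean=30.0,
        frac_active=0.25,
        chrom_length=200_000,
    )
    reference = simulate_reference(config)
    library, _ = simulate_library(reference, config)
    truth = assign_truth(library, config)
    counts = simulate_counts(library, truth, config)
    return {"config": config, "library": library, "truth": truth, "counts": counts}


@pytest.fixture()
def rng():
    return np.random.default_rng(7)


def make_counts(rows) -> pd.DataFrame:
    """Build a count table from (oligo, allele, barcode, replicate, molecule, n) tuples."""
    return pd.DataFrame(
        rows, columns=["oligo_id", "allele", "barcode", "replicate", "molecule", "umi_count"]
    )
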