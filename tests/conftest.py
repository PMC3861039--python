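"""Shared fixtures: a small simulated cohort reused across test modules."""

import pytest

from aaexchange.exchange_matrix import build_counts
from aaexchange.synthetic_data import (
    SimConfig,
    simulate_annotations,
    simulate_disease_set,
    simulate_proteome,
    simulate_variants,
)
from aaexchange.variant_ingest import (
    apply_disease_filters,
    deduplicate,
    filter_single_base,
    filter_single_population,
)


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(
        n_proteins=300,
        mean_length=400,
        n_variant_events=10_000,
        n_disease_events=10_000,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    """Proteome + annotations + filtered natural and disease sets."""
    cfg = small_config
    proteome = simulate_proteome(cfg, seed=101)
    annotations = simulate_annotations(proteome, cfg, seed=102)
    natural_raw, truth = simulate_variants(proteome, cfg, seed=103)
    natural = filter_single_base(
        deduplicate(filter_single_population(natural_raw))
    )
    disease_raw, disease_truth = simulate_disease_set(
        proteome, annotations, cfg, seed=104
    )
    disease = apply_disease_filters(deduplicate(disease_raw), natural)
    return {
        "config": cfg,
        "proteome": proteome,
        "annotations": annotations,
        "natural_raw": natural_raw,
        "natural": natural,
        "truth": truth,
        "disease_raw": disease_raw,
        "disease": disease,
        "disease_truth": disease_truth,
    }


@pytest.fixture(scope="session")
def natural_counts(small_cohort):
    return build_counts(small_cohort["natural"])


@pytest.fixture(scope="session")
def disease_counts(small_cohort):
    return build_counts(small_cohort["disease"], allow_multi_base=True)
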