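"""Shared cohort construction for the analysis scripts.

Every script regenerates the same deterministic synthetic cohort from one
seed, so the scripts can be run independently and in any order. Scale:
~200k-residue proteome, 30k natural events, 10k disease events — big enough
for stable rankings, small enough to run in seconds.
"""

from pathlib import Path

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

SEED = 1
RESULTS = Path(__file__).resolve().parent.parent / "results"
SCRATCH = Path(__file__).resolve().parent.parent / "scratch"


def study_config() -> SimConfig:
    return SimConfig(
        n_proteins=500,
        mean_length=400,
        n_variant_events=30_000,
        n_disease_events=10_000,
    )


def build_cohort(seed: int = SEED):
    cfg = study_config()
    proteome = simulate_proteome(cfg, seed=seed)
    annotations = simulate_annotations(proteome, cfg, seed=seed + 1)
    natural_raw, truth = simulate_variants(proteome, cfg, seed=seed + 2)
    natural = filter_single_base(deduplicate(filter_single_population(natural_raw)))
    disease_raw, _ = simulate_disease_set(proteome, annotations, cfg, seed=seed + 3)
    disease = apply_disease_filters(deduplicate(disease_raw), natural)
    return {
        "config": cfg,
        "proteome": proteome,
        "annotations": annotations,
        "natural_raw": natural_raw,
        "natural": natural,
        "disease_raw": disease_raw,
        "disease": disease,
        "truth": truth,
    }
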