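"""Generator properties: determinism, composition targets, known-truth biases."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from aaexchange.genetic_code import AA_ALPHABETICAL, CpGClass, cpg_class, translate
from aaexchange.comparison_stats import CellClass, classify_cells, distribution_shift_test
from aaexchange.exchange_matrix import build_counts, mutability
from aaexchange.synthetic_data import (
    SimConfig,
    build_codon_counts,
    simulate_annotations,
    simulate_disease_set,
    simulate_proteome,
    simulate_variants,
)
from aaexchange.variant_ingest import (
    Dataset,
    deduplicate,
    filter_single_base,
    filter_single_population,
)


def test_proteome_determinism(small_config):
    a = simulate_proteome(small_config, seed=7)
    b = simulate_proteome(small_config, seed=7)
    assert np.array_equal(a.codon_idx, b.codon_idx)
    assert a.protein_ids == b.protein_ids
    c = simulate_proteome(small_config, seed=8)
    assert not np.array_equal(a.codon_idx, c.codon_idx)


def test_proteome_structure(small_config):
    p = simulate_proteome(small_config, seed=7)
    assert p.n_sites == int(p.lengths.sum())
    seqs = p.aa_sequences()
    assert len(seqs) == small_config.n_proteins
    occ = p.occurrences()
    assert occ.sum() == p.n_sites
    # translated codons match the amino-acid sequence
    pid = p.protein_ids[0]
    assert all(aa in AA_ALPHABETICAL for aa in seqs[pid])


def test_proteome_frequencies_converge():
    """Uniform targets at ~1e6 residues: every frequency within 3σ of 0.05."""
    cfg = SimConfig(
        n_proteins=2000,
        mean_length=500,
        aa_freqs=pd.Series(0.05, index=list(AA_ALPHABETICAL)),
    )
    p = simulate_proteome(cfg, seed=5)
    freqs = p.occurrences() / p.n_sites
    sigma = np.sqrt(0.05 * 0.95 / p.n_sites)
    assert (np.abs(freqs - 0.05) < 3 * sigma + 1e-9).sum() >= 19  # 3σ bound
    assert np.abs(freqs - 0.05).max() < 5 * sigma


def test_variants_determinism(small_cohort, small_config):
    proteome = small_cohort["proteome"]
    a, _ = simulate_variants(proteome, small_config, seed=9)
    b, _ = simulate_variants(proteome, small_config, seed=9)
    assert a.to_frame().equals(b.to_frame())


def test_variants_are_valid_nonsynonymous(small_cohort):
    for r in small_cohort["natural_raw"].records[:500]:
        r.validate()
        assert r.n_base_changes == 1


def test_null_model_is_uniform_over_sites():
    """With λ=κ=1 event rates differ only through nonsynonymous site counts."""
    cfg = SimConfig(n_proteins=100, mean_length=300, kappa=1.0, cpg_lambda=1.0,
                    n_variant_events=20_000)
    p = simulate_proteome(cfg, seed=31)
    _, truth = simulate_variants(p, cfg, seed=32)
    from aaexchange.synthetic_data import _enumerate_candidates

    cand = _enumerate_candidates(p, cfg)
    assert np.all(cand.weight == 1.0)
    # expected mutability then equals (nonsyn neighbors per residue of X)/9 ratio
    aa_idx = p.aa_idx
    per_aa_sites = np.bincount(aa_idx[cand.site], minlength=20)
    occ = p.occurrences().to_numpy()
    expected = cfg.n_variant_events * per_aa_sites / cand.site.size / occ
    assert np.allclose(truth.expected_mutability.to_numpy(), expected)


def test_all_single_population_after_contamination_filter(small_cohort):
    filtered = filter_single_population(small_cohort["natural_raw"])
    assert all(len(r.populations) == 1 for r in filtered.records)
    removed = len(small_cohort["natural_raw"]) - len(filtered)
    n = len(small_cohort["natural_raw"])
    assert 0.005 < removed / n < 0.05  # the 2% contamination, binomial spread


def test_red_class_more_mutable_than_blue(small_cohort, natural_counts):
    occ = small_cohort["proteome"].occurrences()
    mut = mutability(natural_counts, occ)
    red = [aa for aa in AA_ALPHABETICAL if cpg_class(aa) is CpGClass.RED]
    blue = [aa for aa in AA_ALPHABETICAL if cpg_class(aa) is CpGClass.BLUE]
    assert mut[red].mean() > mut[blue].mean()


def test_mutability_rank_recovery(small_cohort, natural_counts):
    occ = small_cohort["proteome"].occurrences()
    mut = mutability(natural_counts, occ)
    truth = small_cohort["truth"].expected_mutability
    rho = spearmanr(mut.to_numpy(), truth.to_numpy())[0]
    assert rho >= 0.9
    assert mut.idxmax() == "R"  # CpG-rich arginine leads at λ=20


def test_annotations_determinism_and_targets(small_cohort, small_config):
    proteome = small_cohort["proteome"]
    a = simulate_annotations(proteome, small_config, seed=6)
    b = simulate_annotations(proteome, small_config, seed=6)
    assert a.equals(b)
    exposed = (a["rel_accessibility"] >= small_config.exposure_cutoff).mean()
    assert abs(exposed - small_config.exposed_fraction) < 0.01
    assert abs(a["conservation"].mean() - small_config.conservation_mean) < 0.01
    has_flag = (a["flags"] != "").mean()
    assert abs(has_flag - small_config.functional_rate) < 0.01


def test_annotations_zero_flag_rate(small_cohort):
    cfg = SimConfig(n_proteins=10, mean_length=100, functional_rate=0.0)
    p = simulate_proteome(cfg, seed=1)
    ann = simulate_annotations(p, cfg, seed=2)
    assert (ann["flags"] == "").all()


def test_disease_bias_shifts_conservation(small_cohort):
    """β_cons > 0 pushes the disease set towards conserved sites."""
    ann = small_cohort["annotations"]
    key = dict(
        zip(zip(ann["protein_id"], ann["position"]), ann["conservation"])
    )
    disease = small_cohort["disease_raw"]
    natural = small_cohort["natural_raw"]
    cons_d = [key[(r.protein_id, r.position)] for r in disease.records]
    cons_n = [key[(r.protein_id, r.position)] for r in natural.records]
    p, mean_d, mean_n = distribution_shift_test(cons_d, cons_n)
    assert p < 0.01 and mean_d > mean_n


def test_disease_null_betas_indistinguishable(small_cohort):
    cfg = SimConfig(
        n_proteins=300, mean_length=400, n_disease_events=10_000,
        beta_conservation=0.0, beta_mass=0.0, beta_hydro=0.0, beta_buried=0.0,
        cpg_lambda=1.0, kappa=1.0, disease_two_base_rate=0.0,
        disease_three_base_rate=0.0,
    )
    p = simulate_proteome(cfg, seed=61)
    ann = simulate_annotations(p, cfg, seed=62)
    null_a, _ = simulate_disease_set(p, ann, cfg, seed=63)
    null_b, _ = simulate_disease_set(p, ann, cfg, seed=64)
    key = dict(zip(zip(ann["protein_id"], ann["position"]), ann["conservation"]))
    cons_a = [key[(r.protein_id, r.position)] for r in null_a.records]
    cons_b = [key[(r.protein_id, r.position)] for r in null_b.records]
    p_val, _, _ = distribution_shift_test(cons_a, cons_b)
    assert p_val > 0.01


def test_disease_buried_bias(small_cohort):
    ann = small_cohort["annotations"]
    cutoff = small_cohort["config"].exposure_cutoff
    key = dict(
        zip(zip(ann["protein_id"], ann["position"]), ann["rel_accessibility"])
    )
    buried_d = np.mean(
        [key[(r.protein_id, r.position)] < cutoff
         for r in small_cohort["disease_raw"].records]
    )
    background = (ann["rel_accessibility"] < cutoff).mean()
    assert buried_d > background


def test_disease_multibase_admixture(small_cohort):
    n_changes = [r.n_base_changes for r in small_cohort["disease_raw"].records]
    counts = np.bincount(n_changes, minlength=4)
    cfg = small_cohort["config"]
    assert counts[2] == round(cfg.n_disease_events * cfg.disease_two_base_rate)
    assert counts[3] == round(cfg.n_disease_events * cfg.disease_three_base_rate)


def test_contrast_power_smoke(natural_counts, disease_counts):
    """Biased disease sampling yields at least one significant cell at n≈1e4."""
    sig = classify_cells(natural_counts, disease_counts)
    n_sig = len(sig.cells_in_class(CellClass.MORE_IN_A)) + len(
        sig.cells_in_class(CellClass.MORE_IN_B)
    )
    assert n_sig >= 1


def test_codon_counts_match_aa_counts(small_cohort, natural_counts):
    cc = build_codon_counts(small_cohort["natural"])
    assert int(cc.to_numpy().sum()) == natural_counts.total
    # collapsing codons to amino acids reproduces the 20×20 matrix
    collapsed = natural_counts.counts.copy() * 0
    for ci in cc.index:
        for cj in cc.columns:
            v = int(cc.at[ci, cj])
            if v:
                collapsed.at[translate(ci), translate(cj)] += v
    assert collapsed.equals(natural_counts.counts)
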