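"""Estimate instantaneous rate matrices and compare with published matrices.

Converts the natural exchange counts to amino-acid rate matrices (directed
and undirected) and to a 61×61 sense-codon rate matrix with per-change CpG
labels, then projects the cohort matrices together with the bundled
published matrices (WAG, JTT, LG, Dayhoff, mtREV24, mtMam, mtArt, mtZoa,
cpREV) onto principal components.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import RESULTS, SEED, build_cohort

import pandas as pd

from aaexchange.exchange_matrix import build_counts
from aaexchange.rate_matrix import (
    bundled_matrices,
    codon_rates,
    cpg_rate_summary,
    dcfreq,
    pca_compare,
)
from aaexchange.synthetic_data import build_codon_counts


def main() -> None:
    cohort = build_cohort(SEED)
    RESULTS.mkdir(exist_ok=True)
    occ = cohort["proteome"].occurrences()
    freqs = occ / occ.sum()
    natural = build_counts(cohort["natural"])

    directed = dcfreq(natural, freqs, directed=True, label="cohort_directed")
    undirected = dcfreq(natural, freqs, directed=False, label="cohort_undirected")
    directed.Q.round(6).to_csv(RESULTS / "rates_aa_directed.tsv", sep="\t",
                               index_label="from_aa")
    print(f"amino-acid rate matrix: mean rate {directed.mean_rate:.3f}, "
          f"undirected detailed-balance error "
          f"{undirected.detailed_balance_error():.2e}")

    cc = build_codon_counts(cohort["natural"])
    cf = cohort["proteome"].codon_occurrences()
    crm = codon_rates(cc, cf / cf.sum(), directed=True)
    summary = cpg_rate_summary(crm)
    print("mean codon rates by CpG effect: "
          + ", ".join(f"{k} {v:.3f}" for k, v in summary.items()))
    print(f"CpG-destroying / neutral ratio: "
          f"{summary['destroys_cpg'] / summary['cpg_neutral']:.1f}")

    collection = bundled_matrices()
    collection["cohort_directed"] = directed
    collection["cohort_undirected"] = undirected
    coords, evr = pca_compare(collection)
    out = coords[["PC1", "PC2"]].round(3)
    out["pc1_var_pct"] = round(100 * evr[0], 1)
    out["pc2_var_pct"] = round(100 * evr[1], 1)
    out.to_csv(RESULTS / "pca_rate_matrices.tsv", sep="\t", index_label="matrix")
    print(f"PCA: PC1 {100 * evr[0]:.0f}% and PC2 {100 * evr[1]:.0f}% of variance")
    print(out[["PC1", "PC2"]].to_string())


if __name__ == "__main__":
    main()
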