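"""Build the directional exchange matrices and mutability scores.

Counts ancestral→derived exchanges for the natural and disease sets, scores
per-amino-acid mutability against the proteome occurrence table, and reports
the gain/loss balance. The CpG effect should dominate: arginine (4 of 6
codons carry a CpG) tops the mutability ranking and is the strongest loser.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import RESULTS, SEED, build_cohort

from aaexchange.exchange_matrix import (
    build_counts,
    exchange_profile,
    gain_loss,
    mutability,
)
from aaexchange.genetic_code import cpg_class


def main() -> None:
    cohort = build_cohort(SEED)
    RESULTS.mkdir(exist_ok=True)
    occ = cohort["proteome"].occurrences()

    natural = build_counts(cohort["natural"])
    disease = build_counts(cohort["disease"], allow_multi_base=True)
    natural.write_tsv(RESULTS / "counts_natural.tsv")
    disease.write_tsv(RESULTS / "counts_disease.tsv")

    mut_n = mutability(natural, occ)
    mut_d = mutability(disease, occ)
    table = mut_n.rename("natural").to_frame()
    table["disease"] = mut_d
    table["cpg_class"] = [cpg_class(a).value for a in table.index]
    table.to_csv(RESULTS / "mutability.tsv", sep="\t", index_label="aa")

    gl = gain_loss(natural)
    gl.to_csv(RESULTS / "gain_loss_natural.tsv", sep="\t", index_label="aa")

    top = mut_n.sort_values(ascending=False)
    print("natural mutability ranking (top 5):")
    for aa, v in top.head(5).items():
        print(f"  {aa}  {v:.4f}  ({cpg_class(aa).value})")
    print(f"arginine / runner-up ratio: {top.iloc[0] / top.iloc[1]:.2f}")
    loser = gl["net"].idxmin()
    print(f"strongest loser (net = to - from): {loser} ({gl.at[loser, 'net']})")
    prof = exchange_profile(natural, "R").sort_values(ascending=False)
    print("arginine exchange profile (top 3 targets): "
          + ", ".join(f"{aa} {p:.1f}%" for aa, p in prof.head(3).items()))


if __name__ == "__main__":
    main()
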