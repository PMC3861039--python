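"""Contrast the natural and disease exchange matrices.

Per-cell Fisher exact tests with Benjamini–Yekutieli correction classify
where the two sets differ; correlation reports compare mutability rankings;
physicochemical summaries quantify how much more extreme the disease
exchanges are in mass and hydrophobicity.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import RESULTS, SEED, build_cohort

from aaexchange.comparison_stats import CellClass, classify_cells, correlate
from aaexchange.exchange_matrix import build_counts, mutability
from aaexchange.physchem import summarize_changes


def main() -> None:
    cohort = build_cohort(SEED)
    RESULTS.mkdir(exist_ok=True)
    occ = cohort["proteome"].occurrences()
    natural = build_counts(cohort["natural"])
    disease = build_counts(cohort["disease"], allow_multi_base=True)

    sig = classify_cells(natural, disease, alpha=0.01)
    class_map = sig.classes.map(
        lambda c: c.value if isinstance(c, CellClass) else ""
    )
    class_map.to_csv(RESULTS / "significance_classes.tsv", sep="\t",
                     index_label="from_aa")
    n_a = len(sig.cells_in_class(CellClass.MORE_IN_A))
    n_b = len(sig.cells_in_class(CellClass.MORE_IN_B))
    n_abs = len(sig.cells_in_class(CellClass.ABSENT_IN_A))
    print(f"cells with proportional excess: natural {n_a}, disease {n_b}; "
          f"absent in natural: {n_abs}")

    mut_n, mut_d = mutability(natural, occ), mutability(disease, occ)
    rep = correlate(mut_n, mut_d, method="spearman")
    print(f"mutability rank correlation natural vs disease: "
          f"r = {rep.r:.2f} ({rep.strength}, n = {rep.n})")

    lines = []
    for label, m in (("natural", natural), ("disease", disease)):
        s = summarize_changes(m)
        lines.append(
            f"{label}: hydrophobicity increases {100 * s.fraction_hydrophobicity_increase:.1f}%"
            f", mass increases {100 * s.fraction_mass_increase:.1f}%"
            f", |dmass| < 50 Da {100 * s.fraction_abs_mass_lt_50da:.1f}%"
            f", |dhydro| < 1 {100 * s.fraction_abs_hydro_lt_1unit:.1f}%"
        )
        s.deltas.to_csv(RESULTS / f"physchem_deltas_{label}.tsv", sep="\t",
                        index=False)
    print("\n".join(lines))


if __name__ == "__main__":
    main()
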