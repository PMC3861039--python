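"""Structural context of the variant sets.

Compares variant sites with the whole-proteome background: solvent exposure
at the 5% cutoff, secondary-structure composition, conservation shift, and
the fraction of sites carrying functional annotations. The disease set
should sit on more conserved and more buried sites than the natural set.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import RESULTS, SEED, build_cohort

import pandas as pd

from aaexchange.site_properties import compare_site_sets, functional_fraction


def variant_annotations(ds, annotations):
    keys = {(r.protein_id, r.position) for r in ds.records}
    mask = [
        (p, q) in keys
        for p, q in zip(annotations["protein_id"], annotations["position"])
    ]
    return annotations[mask]


def main() -> None:
    cohort = build_cohort(SEED)
    RESULTS.mkdir(exist_ok=True)
    ann = cohort["annotations"]

    rows = []
    for label in ("natural", "disease"):
        sites = variant_annotations(cohort[label], ann)
        rep = compare_site_sets(sites, ann)
        frac, counts = functional_fraction(sites)
        rows.append(
            {
                "set": label,
                "n_sites": len(sites),
                "exposed_pct": round(100 * rep.exposed_fraction_variants, 1),
                "background_exposed_pct": round(
                    100 * rep.exposed_fraction_background, 1
                ),
                "exposure_p": rep.exposure_p,
                "mean_conservation": round(rep.mean_conservation_variants, 3),
                "background_conservation": round(
                    rep.mean_conservation_background, 3
                ),
                "conservation_p": rep.conservation_p,
                "functional_pct": round(100 * frac, 1),
            }
        )
        print(
            f"{label}: {rows[-1]['exposed_pct']}% exposed "
            f"(background {rows[-1]['background_exposed_pct']}%), "
            f"mean conservation {rows[-1]['mean_conservation']} "
            f"(background {rows[-1]['background_conservation']}, "
            f"p = {rep.conservation_p:.2e}), "
            f"functional {rows[-1]['functional_pct']}%"
        )
    pd.DataFrame(rows).to_csv(RESULTS / "site_properties.tsv", sep="\t",
                              index=False)


if __name__ == "__main__":
    main()
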