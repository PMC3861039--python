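"""Structural-context contrasts from per-residue annotation tables.

The annotations (relative solvent accessibility, secondary structure,
conservation, functional flags) are taken as given — computed upstream by
structure-based tools — and this module only classifies and contrasts them:
variant sites against the background of all sites. Residues with relative
accessibility below 5% are classed buried, at or above it exposed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportions_ztest

from .comparison_stats import distribution_shift_test

EXPOSURE_CUTOFF = 5.0  # percent relative solvent accessibility
FUNCTIONAL_CATEGORIES = ("site", "ligand", "metal", "catalytic")
SECONDARY_STRUCTURES = ("helix", "strand", "coil")

ANNOTATION_COLUMNS = [
    "protein_id",
    "position",
    "rel_accessibility",
    "secondary_structure",
    "conservation",
    "flags",
]


def classify_exposure(rel_accessibility: float, cutoff: float = EXPOSURE_CUTOFF) -> str:
    """``"exposed"`` iff relative accessibility ≥ cutoff (boundary exposed)."""
    v = float(rel_accessibility)
    if not 0.0 <= v <= 100.0:
        raise ValueError(f"relative accessibility out of range: {v}")
    return "exposed" if v >= cutoff else "buried"


def read_annotations(path) -> pd.DataFrame:
    """Read a per-site annotation TSV, rejecting rows with invalid fields."""
    frame = pd.read_csv(path, sep="\t", dtype={"flags": str})
    missing = [c for c in ANNOTATION_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"annotation table missing columns: {missing}")
    ok = (
        frame["rel_accessibility"].between(0, 100)
        & frame["conservation"].between(0, 1)
        & frame["secondary_structure"].isin(SECONDARY_STRUCTURES)
    )
    frame = frame[ok].copy()
    frame["flags"] = frame["flags"].fillna("")
    return frame


def functional_fraction(sites: pd.DataFrame) -> tuple[float, pd.Series]:
    """Non-redundant functional fraction plus per-category counts.

    A site is functional when it carries at least one flag; category counts
    overlap, so their sum can exceed the non-redundant union.
    """
    if len(sites) == 0:
        raise ValueError("empty site table")
    flag_sets = sites["flags"].fillna("").map(
        lambda s: frozenset(f for f in str(s).split(",") if f)
    )
    counts = pd.Series(
        {c: int(flag_sets.map(lambda fs: c in fs).sum()) for c in FUNCTIONAL_CATEGORIES}
    )
    union = int(flag_sets.map(bool).sum())
    return union / len(sites), counts


@dataclass(frozen=True)
class SiteSetComparison:
    exposed_fraction_variants: float
    exposed_fraction_background: float
    exposure_p: float
    secondary_structure: pd.DataFrame  # fraction per class, both sets
    mean_conservation_variants: float
    mean_conservation_background: float
    conservation_p: float
    functional_fraction_variants: float
    functional_fraction_background: float


def compare_site_sets(
    variant_sites: pd.DataFrame,
    all_sites: pd.DataFrame,
    cutoff: float = EXPOSURE_CUTOFF,
    proportion_test: str = "ztest",
) -> SiteSetComparison:
    """Contrast variant-site annotations with the full-site background."""
    if len(variant_sites) == 0 or len(all_sites) == 0:
        raise ValueError("both site sets must be nonempty")

    exp_v = (variant_sites["rel_accessibility"] >= cutoff).to_numpy()
    exp_b = (all_sites["rel_accessibility"] >= cutoff).to_numpy()
    if proportion_test == "ztest":
        _, p_exp = proportions_ztest(
            [exp_v.sum(), exp_b.sum()], [len(exp_v), len(exp_b)]
        )
    elif proportion_test == "fisher":
        p_exp = stats.fisher_exact(
            [
                [int(exp_v.sum()), int(len(exp_v) - exp_v.sum())],
                [int(exp_b.sum()), int(len(exp_b) - exp_b.sum())],
            ]
        )[1]
    else:
        raise ValueError(f"unknown proportion test {proportion_test!r}")

    ss = pd.DataFrame(
        {
            "variants": variant_sites["secondary_structure"]
            .value_counts(normalize=True)
            .reindex(SECONDARY_STRUCTURES, fill_value=0.0),
            "background": all_sites["secondary_structure"]
            .value_counts(normalize=True)
            .reindex(SECONDARY_STRUCTURES, fill_value=0.0),
        }
    )

    p_cons, mean_v, mean_b = distribution_shift_test(
        variant_sites["conservation"], all_sites["conservation"]
    )
    func_v, _ = functional_fraction(variant_sites)
    func_b, _ = functional_fraction(all_sites)
    return SiteSetComparison(
        exposed_fraction_variants=float(exp_v.mean()),
        exposed_fraction_background=float(exp_b.mean()),
        exposure_p=float(p_exp),
        secondary_structure=ss,
        mean_conservation_variants=mean_v,
        mean_conservation_background=mean_b,
        conservation_p=p_cons,
        functional_fraction_variants=func_v,
        functional_fraction_background=func_b,
    )
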