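"""Physicochemical consequences of an exchange set.

Summaries are event-weighted: a cell with 500 events contributes 500 deltas,
so the fractions read as "% of mutations", not "% of exchange types".
Thresholds follow the conventional strict reading: a change counts as small
when |Δmass| < 50 Da or |Δhydrophobicity| < 1 unit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genetic_code import delta_properties
from .exchange_matrix import ExchangeCountMatrix

MASS_THRESHOLD_DA = 50.0
HYDRO_THRESHOLD = 1.0


@dataclass(frozen=True)
class ChangeSummary:
    fraction_hydrophobicity_increase: float
    fraction_mass_increase: float
    fraction_abs_mass_lt_50da: float
    fraction_abs_hydro_lt_1unit: float
    deltas: pd.DataFrame  # one row per exchange type with its event count

    def as_dict(self) -> dict[str, float]:
        return {
            "fraction_hydrophobicity_increase": self.fraction_hydrophobicity_increase,
            "fraction_mass_increase": self.fraction_mass_increase,
            "fraction_abs_mass_lt_50da": self.fraction_abs_mass_lt_50da,
            "fraction_abs_hydro_lt_1unit": self.fraction_abs_hydro_lt_1unit,
        }


def summarize_changes(m: ExchangeCountMatrix) -> ChangeSummary:
    """Event-weighted fractions of property changes across a count matrix."""
    total = m.total
    if total == 0:
        raise ValueError("empty exchange matrix")
    rows = []
    for x in m.counts.index:
        for y in m.counts.columns:
            n = int(m.counts.at[x, y])
            if n == 0:
                continue
            dh, dm = delta_properties(x, y)
            rows.append({"from_aa": x, "to_aa": y, "count": n, "d_hydro": dh, "d_mass": dm})
    deltas = pd.DataFrame(rows)
    w = deltas["count"].to_numpy(float)
    dh = deltas["d_hydro"].to_numpy(float)
    dm = deltas["d_mass"].to_numpy(float)
    return ChangeSummary(
        fraction_hydrophobicity_increase=float(w[dh > 0].sum() / total),
        fraction_mass_increase=float(w[dm > 0].sum() / total),
        fraction_abs_mass_lt_50da=float(w[np.abs(dm) < MASS_THRESHOLD_DA].sum() / total),
        fraction_abs_hydro_lt_1unit=float(w[np.abs(dh) < HYDRO_THRESHOLD].sum() / total),
        deltas=deltas,
    )
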