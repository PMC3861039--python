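"""Statistical contrast of two exchange matrices and correlation reporting.

Each cell of a natural matrix A is compared with the corresponding cell of a
disease matrix B via Fisher's exact test on the 2×2 table

    [[A_xy, A_total − A_xy],
     [B_xy, B_total − B_xy]]

i.e. the cell's share of all events in each dataset. P-values over all tested
cells are corrected with the Benjamini–Yekutieli step-up procedure (valid
under arbitrary dependence, correction factor c(m) = Σ 1/i), and cells are
classified by direction of proportional excess at the chosen significance
level. Cells empty in A but reachable by a single base change form their own
class, since absence in a much larger dataset is itself informative.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genetic_code import AA_ALPHABETICAL, single_base_exchanges
from .exchange_matrix import ExchangeCountMatrix

DEFAULT_ALPHA = 0.01


class CellClass(Enum):
    MORE_IN_A = "more_in_a"
    MORE_IN_B = "more_in_b"
    NOT_SIGNIFICANT = "not_significant"
    ABSENT_IN_A = "absent_in_a"


def fisher_cell_test(a_xy: int, a_total: int, b_xy: int, b_total: int) -> float:
    """Two-sided Fisher exact p for one cell's share of each dataset."""
    if min(a_xy, a_total, b_xy, b_total) < 0:
        raise ValueError("negative counts")
    if a_xy > a_total or b_xy > b_total:
        raise ValueError("cell count exceeds dataset total")
    if a_total == 0 or b_total == 0:
        raise ValueError("dataset totals must be positive")
    table = [[a_xy, a_total - a_xy], [b_xy, b_total - b_xy]]
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def bhy_adjust(pvalues) -> np.ndarray:
    """Benjamini–Yekutieli adjusted p-values (step-up, c(m) = Σ 1/i)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_by")[1]


@dataclass
class SignificanceMatrix:
    p: pd.DataFrame
    p_adjusted: pd.DataFrame
    classes: pd.DataFrame  # CellClass values; None where untested/unreachable
    alpha: float

    def cells_in_class(self, cls: CellClass) -> list[tuple[str, str]]:
        out = []
        for x in self.classes.index:
            for y in self.classes.columns:
                if self.classes.at[x, y] is cls:
                    out.append((x, y))
        return out


def classify_cells(
    a: ExchangeCountMatrix,
    b: ExchangeCountMatrix,
    alpha: float = DEFAULT_ALPHA,
    conditioning: str = "total",
) -> SignificanceMatrix:
    """Per-cell Fisher + Benjamini–Yekutieli contrast of two count matrices.

    ``conditioning="total"`` tests each cell against all other events in the
    dataset; ``"row"`` conditions on the events leaving the same source amino
    acid, asking whether the *profile* of that amino acid differs.
    """
    if conditioning not in {"total", "row"}:
        raise ValueError(f"unknown conditioning {conditioning!r}")
    idx = list(AA_ALPHABETICAL)
    reachable = single_base_exchanges()
    tested: list[tuple[str, str]] = []
    for x in idx:
        for y in idx:
            if x == y:
                continue
            if (x, y) in reachable or a.counts.at[x, y] > 0 or b.counts.at[x, y] > 0:
                tested.append((x, y))

    a_tot, b_tot = a.total, b.total
    raw = {}
    for x, y in tested:
        if conditioning == "row":
            na, nb = int(a.counts.loc[x].sum()), int(b.counts.loc[x].sum())
        else:
            na, nb = a_tot, b_tot
        if na == 0 or nb == 0:
            raw[(x, y)] = 1.0
        else:
            raw[(x, y)] = fisher_cell_test(
                int(a.counts.at[x, y]), na, int(b.counts.at[x, y]), nb
            )

    adj = dict(zip(tested, bhy_adjust([raw[c] for c in tested])))

    p = pd.DataFrame(np.nan, index=idx, columns=idx)
    p_adj = pd.DataFrame(np.nan, index=idx, columns=idx)
    classes = pd.DataFrame(None, index=idx, columns=idx, dtype=object)
    for x, y in tested:
        p.at[x, y] = raw[(x, y)]
        p_adj.at[x, y] = adj[(x, y)]
        axy, bxy = int(a.counts.at[x, y]), int(b.counts.at[x, y])
        if axy == 0 and (x, y) in reachable:
            cls = CellClass.ABSENT_IN_A
        elif adj[(x, y)] < alpha:
            # direction of proportional excess
            cls = (
                CellClass.MORE_IN_A
                if axy / a_tot > bxy / b_tot
                else CellClass.MORE_IN_B
            )
        else:
            cls = CellClass.NOT_SIGNIFICANT
        classes.at[x, y] = cls
    return SignificanceMatrix(p=p, p_adjusted=p_adj, classes=classes, alpha=alpha)


@dataclass(frozen=True)
class CorrelationReport:
    r: float
    n: int
    strength: str  # strong / moderate / weak
    method: str
    excluded: tuple[str, ...] = ()


def _strength(r: float) -> str:
    if abs(r) > 0.7:
        return "strong"
    if abs(r) > 0.4:
        return "moderate"
    # the 0.3–0.4 band is conventionally unnamed; reported as weak here
    return "weak"


def correlate(x, y, method: str = "pearson", exclusions=()) -> CorrelationReport:
    """Correlation with conventional strength labels and named exclusions.

    *x* and *y* may be pandas Series (aligned on index, exclusions by label)
    or plain sequences (exclusions by integer position).
    """
    if method not in {"pearson", "spearman"}:
        raise ValueError(f"unknown method {method!r}")
    if isinstance(x, pd.Series) and isinstance(y, pd.Series):
        x, y = x.align(y, join="inner")
        keep = ~x.index.isin(list(exclusions))
        xv, yv = x[keep].to_numpy(float), y[keep].to_numpy(float)
    else:
        xv = np.asarray([v for i, v in enumerate(x) if i not in set(exclusions)], float)
        yv = np.asarray([v for i, v in enumerate(y) if i not in set(exclusions)], float)
    if len(xv) != len(yv):
        raise ValueError("length mismatch")
    if len(xv) < 3:
        raise ValueError("need at least 3 points after exclusions")
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        raise ValueError("degenerate (constant) vector")
    fn = stats.pearsonr if method == "pearson" else stats.spearmanr
    r = float(fn(xv, yv)[0])
    return CorrelationReport(
        r=r, n=len(xv), strength=_strength(r), method=method,
        excluded=tuple(map(str, exclusions)),
    )


def distribution_shift_test(
    sample_a, sample_b, method: str = "mannwhitney"
) -> tuple[float, float, float]:
    """Two-sample shift test; returns (p, mean_a, mean_b).

    Mann–Whitney U (two-sided) by default, Kolmogorov–Smirnov as an option.
    """
    a = np.asarray(sample_a, float)
    b = np.asarray(sample_b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty sample")
    if method == "mannwhitney":
        p = float(stats.mannwhitneyu(a, b, alternative="two-sided")[1])
    elif method == "ks":
        p = float(stats.ks_2samp(a, b)[1])
    else:
        raise ValueError(f"unknown method {method!r}")
    return p, float(a.mean()), float(b.mean())
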