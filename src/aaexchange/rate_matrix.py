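"""Instantaneous rate matrices from exchange counts, and matrix comparison.

Counts are converted to a continuous-time Markov generator Q following the
Dayhoff-counts-with-frequencies family of estimators (DCFreq): off-diagonal
rates proportional to the observed count scaled by the source-state frequency,

    Q_ij ∝ C_ij / π_i          (directed counts)
    Q_ij ∝ (C_ij + C_ji) / π_i (direction ignored; reversible by construction)

with the diagonal set to minus the row sum and the whole matrix scaled so the
expected number of events per unit time, −Σ_i π_i Q_ii, equals 1. The same
algebra applies to 20 amino-acid states or 61 sense-codon states; at codon
level each single-base change additionally carries a CpG label (creates /
destroys / neutral) to expose the hypermutability structure.

Published empirical matrices (WAG, LG, JTT, Dayhoff, mtREV24, mtMam, mtArt,
mtZoa, cpREV) are bundled in the standard lower-triangular exchangeability
text format and can be projected together with data-derived matrices by PCA
on their vectorized off-diagonal rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib.resources import files

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .genetic_code import (
    AA_ALPHABETICAL,
    SENSE_CODONS,
    codon_pair_hamming,
    cpg_change_label,
    translate,
)
from .exchange_matrix import ExchangeCountMatrix

BUNDLED_MATRICES = (
    "wag",
    "jtt",
    "lg",
    "dayhoff",
    "mtrev24",
    "mtmam",
    "mtart",
    "mtzoa",
    "cprev",
)

# order of states in the lower-triangular empirical-matrix file format
DAT_AA_ORDER = tuple("ARNDCQEGHILKMFPSTWYV")


@dataclass
class RateMatrix:
    """Normalized instantaneous rate matrix with its frequency vector."""

    Q: pd.DataFrame
    freqs: pd.Series
    directed: bool
    normalized: bool = True
    label: str = ""
    scale: float = 1.0  # factor applied to reach mean rate 1
    change_labels: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        q = self.Q.to_numpy(float)
        off = q[~np.eye(q.shape[0], dtype=bool)]
        if (off < -1e-12).any():
            raise ValueError("negative off-diagonal rate")
        if np.abs(q.sum(axis=1)).max() > 1e-9:
            raise ValueError("rows of Q must sum to zero")

    @property
    def mean_rate(self) -> float:
        return float(-np.diag(self.Q.to_numpy()) @ self.freqs.to_numpy())

    def detailed_balance_error(self) -> float:
        """max |π_i Q_ij − π_j Q_ji|; ~0 for reversible matrices."""
        q = self.Q.to_numpy(float)
        pi = self.freqs.to_numpy(float)
        flux = pi[:, None] * q
        return float(np.max(np.abs(flux - flux.T)))

    def offdiag_vector(self) -> np.ndarray:
        """Off-diagonal rates in fixed row-major order (PCA coordinates)."""
        q = self.Q.to_numpy(float)
        return q[~np.eye(q.shape[0], dtype=bool)]


def _as_freqs(freqs, index) -> pd.Series:
    s = pd.Series(freqs, index=index) if not isinstance(freqs, pd.Series) else freqs
    s = s.reindex(index).astype(float)
    if s.isna().any() or (s <= 0).any():
        raise ValueError("frequencies must be strictly positive over all states")
    if abs(s.sum() - 1.0) > 1e-6:
        s = s / s.sum()
    return s


def _counts_to_q(counts: np.ndarray, pi: np.ndarray, directed: bool) -> tuple[np.ndarray, float]:
    if counts.sum() == 0:
        raise ValueError("all-zero count matrix")
    c = counts.astype(float)
    if not directed:
        c = c + c.T
    q = c / pi[:, None]
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    mean_rate = float(-np.diag(q) @ pi)
    return q / mean_rate, 1.0 / mean_rate


def dcfreq(
    counts: ExchangeCountMatrix, freqs, directed: bool = True, label: str = ""
) -> RateMatrix:
    """Convert a 20×20 exchange count matrix to a normalized rate matrix."""
    idx = list(AA_ALPHABETICAL)
    pi = _as_freqs(freqs, idx)
    q, scale = _counts_to_q(counts.counts.to_numpy(), pi.to_numpy(), directed)
    return RateMatrix(
        Q=pd.DataFrame(q, index=idx, columns=idx),
        freqs=pi,
        directed=directed,
        label=label or counts.label,
        scale=scale,
    )


def codon_rates(
    codon_counts: pd.DataFrame, codon_freqs, directed: bool = True, label: str = ""
) -> RateMatrix:
    """61×61 sense-codon rate matrix with per-change CpG labels.

    Counts must lie on single-base changes between sense codons; anything
    else is a data error at codon resolution.
    """
    idx = list(SENSE_CODONS)
    counts = codon_counts.reindex(index=idx, columns=idx, fill_value=0)
    arr = counts.to_numpy(float)
    labels = pd.DataFrame("", index=idx, columns=idx, dtype=object)
    for i, ci in enumerate(idx):
        for j, cj in enumerate(idx):
            if i == j:
                continue
            if codon_pair_hamming(ci, cj) == 1:
                labels.at[ci, cj] = cpg_change_label(ci, cj)
            elif arr[i, j] != 0:
                raise ValueError(f"count on non-adjacent codon pair {ci}->{cj}")
    pi = _as_freqs(codon_freqs, idx)
    q, scale = _counts_to_q(arr, pi.to_numpy(), directed)
    return RateMatrix(
        Q=pd.DataFrame(q, index=idx, columns=idx),
        freqs=pi,
        directed=directed,
        label=label,
        scale=scale,
        change_labels=labels,
    )


def cpg_rate_summary(rm: RateMatrix) -> pd.Series:
    """Mean rate over nonsynonymous single-base codon changes per CpG label."""
    if rm.change_labels is None:
        raise ValueError("rate matrix carries no CpG change labels")
    q = rm.Q
    sums: dict[str, list[float]] = {"destroys_cpg": [], "creates_cpg": [], "cpg_neutral": []}
    for ci in q.index:
        for cj in q.columns:
            lab = rm.change_labels.at[ci, cj]
            if lab and translate(ci) != translate(cj):
                sums[lab].append(float(q.at[ci, cj]))
    return pd.Series({k: float(np.mean(v)) if v else np.nan for k, v in sums.items()})


def pca_compare(collection: dict[str, RateMatrix], standardize: bool = True):
    """Project a set of equally-sized rate matrices onto principal components.

    Returns ``(coordinates, explained_variance_ratio)`` where coordinates is a
    DataFrame (one row per matrix, columns PC1, PC2, ...). Off-diagonal rates
    are vectorized in fixed order, centered and (by default) standardized;
    component signs are fixed by making the largest-magnitude loading
    positive.
    """
    if len(collection) < 3:
        raise ValueError("need at least 3 matrices")
    dims = {rm.Q.shape[0] for rm in collection.values()}
    if len(dims) != 1:
        raise ValueError(f"matrices of mixed dimension: {sorted(dims)}")
    names = list(collection)
    X = np.vstack([collection[n].offdiag_vector() for n in names])
    if standardize:
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        X = (X - X.mean(axis=0)) / sd
    pca = PCA()
    coords = pca.fit_transform(X)
    # deterministic sign: largest-|loading| positive per component
    for k in range(pca.components_.shape[0]):
        i = np.argmax(np.abs(pca.components_[k]))
        if pca.components_[k, i] < 0:
            pca.components_[k] *= -1
            coords[:, k] *= -1
    cols = [f"PC{i + 1}" for i in range(coords.shape[1])]
    return (
        pd.DataFrame(coords, index=names, columns=cols),
        pca.explained_variance_ratio_,
    )


def read_empirical_matrix(path, label: str = "") -> RateMatrix:
    """Read a published matrix in the lower-triangular ``.dat`` text format.

    The format is 19 rows of exchangeabilities s_ij (row i lists s against the
    i−1 preceding amino acids in ARNDCQEGHILKMFPSTWYV order) followed by a
    line of 20 stationary frequencies. Returns the reversible rate matrix
    Q_ij = s_ij π_j normalized to mean rate 1, re-indexed alphabetically.
    """
    text = path.read_text() if hasattr(path, "read_text") else open(path).read()
    rows = [line.split() for line in text.splitlines() if line.strip()]
    if len(rows) < 20:
        raise ValueError("malformed empirical matrix file")
    tri, freq_line = rows[:19], [v for r in rows[19:] for v in r]
    s = np.zeros((20, 20))
    for i, row in enumerate(tri, start=1):
        if len(row) != i:
            raise ValueError(f"triangle row {i} has {len(row)} values, expected {i}")
        s[i, : i] = [float(v) for v in row]
    s = s + s.T
    if len(freq_line) != 20:
        raise ValueError("expected 20 stationary frequencies")
    pi = np.array([float(v) for v in freq_line])
    if abs(pi.sum() - 1.0) > 0.01:
        raise ValueError(f"frequencies sum to {pi.sum():.4f}, not 1")
    if s.max() == 0:
        raise ValueError("degenerate matrix: all exchangeabilities zero")
    pi = pi / pi.sum()
    q = s * pi[None, :]
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    mean_rate = float(-np.diag(q) @ pi)
    q /= mean_rate
    order = list(DAT_AA_ORDER)
    Q = pd.DataFrame(q, index=order, columns=order)
    pi_s = pd.Series(pi, index=order)
    alpha = list(AA_ALPHABETICAL)
    return RateMatrix(
        Q=Q.loc[alpha, alpha],
        freqs=pi_s.loc[alpha],
        directed=False,
        label=label,
        scale=1.0 / mean_rate,
    )


def write_empirical_matrix(rm: RateMatrix, path) -> None:
    """Write a reversible rate matrix in the ``.dat`` exchangeability format."""
    order = list(DAT_AA_ORDER)
    q = rm.Q.loc[order, order].to_numpy(float)
    pi = rm.freqs.loc[order].to_numpy(float)
    s = q / pi[None, :]
    lines = []
    for i in range(1, 20):
        lines.append(" ".join(f"{s[i, j]:.10g}" for j in range(i)))
    lines.append("")
    lines.append(" ".join(f"{v:.10g}" for v in pi))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def bundled_matrices(names=BUNDLED_MATRICES) -> dict[str, RateMatrix]:
    """Load the bundled published matrices by name."""
    out = {}
    for name in names:
        res = files("aaexchange.data.matrices").joinpath(f"{name}.dat")
        out[name] = read_empirical_matrix(res, label=name)
    return out
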