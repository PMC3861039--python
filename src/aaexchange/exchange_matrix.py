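"""Directional amino-acid exchange count matrices and mutability scores.

The central object is a 20×20 integer matrix of ancestral→derived exchange
counts. Because variant direction is known (the allele shared by all
populations is ancestral), the matrix is asymmetric: cell (X, Y) counts events
in which X mutated to Y, and in general counts(X, Y) != counts(Y, X).

Mutability of an amino acid is its total number of outgoing variant events
divided by its occurrence count in the proteome — events per residue. The
occurrence-weighted mean mutability is therefore exactly
total_events / total_residues, which is the mechanism behind proteome-wide
average mutability scores of ~0.01 on human-scale data.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib.resources import files

import numpy as np
import pandas as pd

from .genetic_code import AA_ALPHABETICAL, single_base_exchanges
from .variant_ingest import Dataset


@dataclass
class ExchangeCountMatrix:
    """Directional exchange counts with zero diagonal, alphabetical order."""

    counts: pd.DataFrame  # rows = from_aa, columns = to_aa
    label: str = ""
    allow_multi_base: bool = False

    def __post_init__(self) -> None:
        idx = list(AA_ALPHABETICAL)
        self.counts = self.counts.reindex(index=idx, columns=idx, fill_value=0).astype(
            np.int64
        )
        if np.any(np.diag(self.counts.to_numpy()) != 0):
            raise ValueError("diagonal of an exchange matrix must be zero")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        if not self.allow_multi_base:
            reachable = single_base_exchanges()
            bad = [
                (x, y)
                for x in idx
                for y in idx
                if self.counts.at[x, y] > 0 and (x, y) not in reachable
            ]
            if bad:
                raise ValueError(f"counts on multi-base cells: {bad}")

    @property
    def total(self) -> int:
        return int(self.counts.to_numpy().sum())

    def write_tsv(self, path) -> None:
        self.counts.to_csv(path, sep="\t", index_label="from_aa")

    @classmethod
    def read_tsv(cls, path, label: str = "", allow_multi_base: bool = False):
        frame = pd.read_csv(path, sep="\t", index_col=0)
        frame.index.name = None
        return cls(frame, label=label, allow_multi_base=allow_multi_base)


def build_counts(ds: Dataset, allow_multi_base: bool = False) -> ExchangeCountMatrix:
    """Count ancestral→derived exchanges of a deduplicated dataset."""
    idx = list(AA_ALPHABETICAL)
    mat = pd.DataFrame(0, index=idx, columns=idx, dtype=np.int64)
    offenders = []
    for r in ds.records:
        if not allow_multi_base and r.n_base_changes != 1:
            offenders.append(r)
            continue
        mat.at[r.ref_aa, r.alt_aa] += 1
    if offenders:
        raise ValueError(
            f"{len(offenders)} multi-base records in a single-base matrix, "
            f"e.g. {offenders[0]}"
        )
    return ExchangeCountMatrix(mat, label=ds.label, allow_multi_base=allow_multi_base)


def load_occurrences(path=None) -> pd.Series:
    """Per-amino-acid occurrence counts (residues) in the proteome.

    Without a path, returns the bundled human-like table: published human
    proteome composition scaled to 10.5 million residues.
    """
    if path is None:
        path = files("aaexchange.data").joinpath("human_aa_occurrences.tsv")
        with path.open() as fh:
            table = pd.read_csv(fh, sep="\t", index_col=0)["count"]
    else:
        table = pd.read_csv(path, sep="\t", index_col=0)["count"]
    table = table.reindex(list(AA_ALPHABETICAL))
    if table.isna().any() or (table <= 0).any():
        raise ValueError("occurrence table must cover all 20 amino acids with counts > 0")
    return table.astype(float)


def mutability(
    m: ExchangeCountMatrix, occurrences: pd.Series, as_proportions: bool = False
) -> pd.Series:
    """Mutability(X) = outgoing events of X / occurrence count of X.

    With ``as_proportions=True`` the denominator is the amino acid's
    proportion of the proteome instead of its absolute count (sensitivity
    analysis; values then scale by total_residues).
    """
    occ = occurrences.reindex(list(AA_ALPHABETICAL))
    if occ.isna().any() or (occ <= 0).any():
        raise ValueError("occurrences must be positive for all 20 amino acids")
    denom = occ / occ.sum() if as_proportions else occ
    return m.counts.sum(axis=1) / denom


def gain_loss(m: ExchangeCountMatrix) -> pd.DataFrame:
    """Raw gain/loss balance: events from, events to, and net = to − from."""
    from_total = m.counts.sum(axis=1)
    to_total = m.counts.sum(axis=0)
    return pd.DataFrame(
        {"from_total": from_total, "to_total": to_total, "net": to_total - from_total}
    )


def exchange_profile(m: ExchangeCountMatrix, aa: str) -> pd.Series:
    """Percentage of events from *aa* going to each target; sums to 100."""
    if aa not in AA_ALPHABETICAL:
        raise ValueError(f"unknown amino acid {aa!r}")
    row = m.counts.loc[aa].astype(float)
    if row.sum() == 0:
        raise ValueError(f"no events from {aa}; profile undefined")
    return 100.0 * row / row.sum()


def aggregate_protein_mutability(sequence: str, mutability_table: pd.Series) -> float:
    """Mean per-residue mutability of a protein sequence."""
    if not sequence:
        raise ValueError("empty sequence")
    try:
        values = [mutability_table[aa] for aa in sequence]
    except KeyError as exc:
        raise ValueError(f"unknown residue in sequence: {exc}") from exc
    return float(np.mean(values))
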