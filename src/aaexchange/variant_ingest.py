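"""Reading and filtering nonsynonymous variant records.

The unit of analysis is one nonsynonymous change event in one protein:
ancestral codon → derived codon at a 1-based residue position, together with
the set of population labels in which the derived allele was seen. Filtering
follows the design of large population-variant studies:

* keep only variants observed in a single population, taking the allele shared
  by all populations as ancestral — this orients each exchange and enriches
  for recent mutation events;
* count a site only once per derived amino acid, because the same inherited
  event appears in many individuals;
* for a "natural" (population) set, drop records needing more than one base
  change — such exchanges cannot arise from one SNP;
* for a disease set, drop the (error-prone) triple-base changes and any record
  that also occurs in the natural set.

All filters have set semantics: they are idempotent and independent of record
order.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import pandas as pd

from .genetic_code import AMINO_ACIDS, STOP, codon_pair_hamming, translate

TSV_COLUMNS = [
    "protein_id",
    "position",
    "ref_codon",
    "alt_codon",
    "ref_aa",
    "alt_aa",
    "populations",
    "dataset",
]

DEFAULT_POPULATIONS = frozenset({"AFR", "AMR", "ASN", "EUR", "SAS"})


@dataclass(frozen=True)
class VariantRecord:
    """One nonsynonymous variant event (ancestral → derived)."""

    protein_id: str
    position: int  # 1-based residue index in the protein
    ref_codon: str
    alt_codon: str
    ref_aa: str
    alt_aa: str
    populations: frozenset[str]
    dataset: str = "natural"

    @property
    def n_base_changes(self) -> int:
        return codon_pair_hamming(self.ref_codon, self.alt_codon)

    @property
    def site_key(self) -> tuple[str, int, str]:
        """Deduplication key: one event per (protein, position, derived aa)."""
        return (self.protein_id, self.position, self.alt_aa)

    def validate(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be 1-based positive: {self.position}")
        if translate(self.ref_codon) != self.ref_aa:
            raise ValueError(
                f"ref codon {self.ref_codon} translates to "
                f"{translate(self.ref_codon)}, not {self.ref_aa}"
            )
        if translate(self.alt_codon) != self.alt_aa:
            raise ValueError(
                f"alt codon {self.alt_codon} translates to "
                f"{translate(self.alt_codon)}, not {self.alt_aa}"
            )
        if self.alt_aa == STOP or self.ref_aa == STOP:
            raise ValueError("stop codons are not amino-acid variants")
        if self.ref_aa == self.alt_aa:
            raise ValueError(f"synonymous change {self.ref_codon}->{self.alt_codon}")
        if self.ref_aa not in AMINO_ACIDS or self.alt_aa not in AMINO_ACIDS:
            raise ValueError(f"unknown amino acid in {self.ref_aa}->{self.alt_aa}")


@dataclass
class Dataset:
    """A labelled collection of variant records plus a filtering audit trail."""

    records: list[VariantRecord]
    label: str = ""
    log: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def note(self, message: str) -> None:
        self.log.append(message)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "protein_id": r.protein_id,
                "position": r.position,
                "ref_codon": r.ref_codon,
                "alt_codon": r.alt_codon,
                "ref_aa": r.ref_aa,
                "alt_aa": r.alt_aa,
                "populations": ",".join(sorted(r.populations)),
                "dataset": r.dataset,
            }
            for r in self.records
        ]
        return pd.DataFrame(rows, columns=TSV_COLUMNS)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _records_from_frame(
    frame: pd.DataFrame, label: str
) -> tuple[list[VariantRecord], list[str]]:
    records, errors = [], []
    for idx, row in frame.iterrows():
        pops = frozenset(
            p for p in str(row["populations"]).split(",") if p and p != "nan"
        )
        try:
            rec = VariantRecord(
                protein_id=str(row["protein_id"]),
                position=int(row["position"]),
                ref_codon=str(row["ref_codon"]).upper(),
                alt_codon=str(row["alt_codon"]).upper(),
                ref_aa=str(row["ref_aa"]).upper(),
                alt_aa=str(row["alt_aa"]).upper(),
                populations=pops,
                dataset=str(row.get("dataset", label) or label),
            )
            rec.validate()
        except (ValueError, KeyError) as exc:
            errors.append(f"row {idx}: {exc}")
            continue
        records.append(rec)
    return records, errors


def read_variants(path_or_buffer, format: str = "tsv", label: str = "") -> Dataset:
    """Read a variant table; rows failing codon/amino-acid checks are dropped.

    ``format="tsv"`` is the native dialect (tab-separated, header required).
    ``format="vcf-min"`` accepts the same columns from a pre-annotated
    VCF-derived table with a ``#``-prefixed header line.
    """
    if format not in {"tsv", "vcf-min"}:
        raise ValueError(f"unknown format: {format!r}")
    if format == "vcf-min":
        text = (
            path_or_buffer.read()
            if hasattr(path_or_buffer, "read")
            else open(path_or_buffer).read()
        )
        text = text.lstrip("#")
        frame = pd.read_csv(io.StringIO(text), sep="\t", dtype=str)
    else:
        frame = pd.read_csv(path_or_buffer, sep="\t", dtype=str)
    missing = [c for c in TSV_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"malformed header, missing columns: {missing}")
    records, errors = _records_from_frame(frame, label)
    ds = Dataset(records, label=label or "variants")
    ds.note(f"read {len(records)} records, rejected {len(errors)} rows")
    ds.log.extend(errors)
    if not records:
        ds.note("warning: empty dataset")
    return ds


def filter_single_population(
    ds: Dataset, all_populations: frozenset[str] = DEFAULT_POPULATIONS
) -> Dataset:
    """Keep records whose derived allele occurs in exactly one population.

    Records seen in several populations (or none) are removed: for those the
    ancestral state, and hence the direction of the exchange, is uncertain.
    """
    kept, n_multi, n_empty = [], 0, 0
    for r in ds.records:
        if not r.populations <= all_populations:
            raise ValueError(
                f"record carries unknown population labels: "
                f"{sorted(r.populations - all_populations)}"
            )
        if len(r.populations) == 1:
            kept.append(r)
        elif r.populations:
            n_multi += 1
        else:
            n_empty += 1
    out = Dataset(kept, label=ds.label, log=list(ds.log))
    out.note(
        f"single-population filter: kept {len(kept)}, "
        f"removed {n_multi} multi-population and {n_empty} unlabelled"
    )
    return out


def deduplicate(ds: Dataset) -> Dataset:
    """Collapse records sharing (protein, position, derived aa) to one event."""
    seen: dict[tuple, VariantRecord] = {}
    for r in ds.records:
        seen.setdefault(r.site_key, r)
    out = Dataset(list(seen.values()), label=ds.label, log=list(ds.log))
    out.note(f"deduplicate: removed {len(ds) - len(out)} duplicate records")
    return out


def filter_single_base(ds: Dataset) -> Dataset:
    """Drop records requiring more than one base change (natural sets only)."""
    kept = [r for r in ds.records if r.n_base_changes == 1]
    out = Dataset(kept, label=ds.label, log=list(ds.log))
    out.note(f"single-base filter: removed {len(ds) - len(out)} multi-base records")
    return out


def apply_disease_filters(ds: Dataset, natural: Dataset) -> Dataset:
    """Clean a disease set against the natural background.

    Removes triple-base changes (curation errors in practice), removes records
    whose site key also occurs in the natural set, and keeps two-base changes
    tagged ``multi_base`` in their dataset field.
    """
    natural_keys = {r.site_key for r in natural.records}
    kept, n_triple, n_overlap = [], 0, 0
    for r in ds.records:
        if r.n_base_changes == 3:
            n_triple += 1
            continue
        if r.site_key in natural_keys:
            n_overlap += 1
            continue
        if r.n_base_changes == 2 and "multi_base" not in r.dataset:
            r = replace(r, dataset=f"{r.dataset}:multi_base")
        kept.append(r)
    out = Dataset(kept, label=ds.label, log=list(ds.log))
    out.note(
        f"disease filters: removed {n_triple} triple-base and "
        f"{n_overlap} natural-overlap records"
    )
    return out
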