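"""Standard genetic code, single-base mutation neighborhoods and amino-acid scales.

Everything downstream — exchange matrices, mutability scores, codon rate
matrices, the synthetic mutation model — is anchored in the standard nuclear
genetic code (translation table 1, DNA alphabet) and two per-residue scales:

* Fauchère–Pliska hydrophobicity (octanol/water partition of side-chain
  analogues, dimensionless), used both for ordering amino acids in displays
  and for Δhydrophobicity of an exchange;
* molecular weight of the free amino acid in daltons, used for Δsize.

CpG dinucleotides are the dominant hypermutable context in human DNA
(spontaneous deamination of methylated cytosine), so amino acids are also
classified by the CpG content of their codons: RED if any codon contains the
CG dinucleotide, else YELLOW if any codon starts with G (a preceding C in the
reading frame can complete a CpG across the codon boundary), else BLUE.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from enum import Enum
from functools import lru_cache
from importlib.resources import files

from Bio.Data import CodonTable

__all__ = [
    "AminoAcid",
    "CpGClass",
    "AA_ALPHABETICAL",
    "AMINO_ACIDS",
    "SENSE_CODONS",
    "STOP_CODONS",
    "STOP",
    "translate",
    "codons_of",
    "contains_cpg",
    "cpg_class",
    "single_base_exchanges",
    "single_base_neighbors",
    "delta_properties",
    "hydrophobicity_order",
    "is_transition",
]

_BASES = "ACGT"
STOP = "*"

_TABLE = CodonTable.unambiguous_dna_by_id[1]
SENSE_CODONS: tuple[str, ...] = tuple(sorted(_TABLE.forward_table))
STOP_CODONS: tuple[str, ...] = tuple(sorted(_TABLE.stop_codons))

# transitions: purine<->purine, pyrimidine<->pyrimidine
_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


def _load_scale(name: str) -> dict[str, float]:
    text = files("aaexchange.data").joinpath(name).read_text()
    out: dict[str, float] = {}
    for line in text.splitlines()[1:]:
        code, value = line.split("\t")
        out[code] = float(value)
    return out


_HYDROPHOBICITY = _load_scale("fp_hydrophobicity.tsv")
_MASS_DA = _load_scale("aa_mass.tsv")


class CpGClass(Enum):
    """CpG classification of an amino acid via its codons."""

    RED = "red"  # some codon contains the CG dinucleotide
    YELLOW = "yellow"  # no CG inside a codon, but some codon starts with G
    BLUE = "blue"  # neither


@dataclass(frozen=True)
class AminoAcid:
    one_letter: str
    hydrophobicity: float
    mass: float  # free amino acid, Da


AA_ALPHABETICAL: tuple[str, ...] = tuple(sorted(set(_TABLE.forward_table.values())))
AMINO_ACIDS: dict[str, AminoAcid] = {
    aa: AminoAcid(aa, _HYDROPHOBICITY[aa], _MASS_DA[aa]) for aa in AA_ALPHABETICAL
}

assert len(AA_ALPHABETICAL) == 20 and len(SENSE_CODONS) == 61


def _check_codon(codon: str) -> str:
    if not isinstance(codon, str) or len(codon) != 3 or any(b not in _BASES for b in codon):
        raise ValueError(f"not a DNA codon: {codon!r}")
    return codon


def _check_aa(aa: str) -> str:
    if aa not in AMINO_ACIDS:
        raise ValueError(f"unknown amino acid code: {aa!r}")
    return aa


def translate(codon: str) -> str:
    """Translate a DNA codon under the standard code; stops return ``"*"``."""
    _check_codon(codon)
    return _TABLE.forward_table.get(codon, STOP)


@lru_cache(maxsize=None)
def codons_of(aa: str) -> tuple[str, ...]:
    """All sense codons encoding *aa*, in lexicographic order."""
    _check_aa(aa)
    return tuple(c for c in SENSE_CODONS if _TABLE.forward_table[c] == aa)


def contains_cpg(codon: str) -> bool:
    """True iff the CG dinucleotide occurs within the codon's three bases."""
    return "CG" in _check_codon(codon)


@lru_cache(maxsize=None)
def cpg_class(aa: str) -> CpGClass:
    _check_aa(aa)
    codons = codons_of(aa)
    if any(contains_cpg(c) for c in codons):
        return CpGClass.RED
    if any(c.startswith("G") for c in codons):
        return CpGClass.YELLOW
    return CpGClass.BLUE


def single_base_neighbors(codon: str) -> list[str]:
    """The nine codons reachable from *codon* by one base substitution."""
    _check_codon(codon)
    out = []
    for pos in range(3):
        for b in _BASES:
            if b != codon[pos]:
                out.append(codon[:pos] + b + codon[pos + 1 :])
    return out


@lru_cache(maxsize=None)
def single_base_exchanges() -> frozenset[tuple[str, str]]:
    """Ordered amino-acid pairs (X, Y), X != Y, reachable by one base change.

    A pair is included when some sense codon of X differs from some sense
    codon of Y at exactly one position; changes through stop codons are
    excluded. Adjacency is symmetric at the codon level, so (Y, X) is present
    whenever (X, Y) is.
    """
    pairs = set()
    for codon in SENSE_CODONS:
        x = translate(codon)
        for nb in single_base_neighbors(codon):
            y = translate(nb)
            if y != STOP and y != x:
                pairs.add((x, y))
    return frozenset(pairs)


def delta_properties(x: str, y: str) -> tuple[float, float]:
    """(Δhydrophobicity, Δmass in Da) for the exchange x → y.

    Antisymmetric: ``delta_properties(x, y) == -delta_properties(y, x)``.
    """
    a, b = AMINO_ACIDS[_check_aa(x)], AMINO_ACIDS[_check_aa(y)]
    return (b.hydrophobicity - a.hydrophobicity, b.mass - a.mass)


def hydrophobicity_order() -> tuple[str, ...]:
    """Amino acids sorted by increasing Fauchère–Pliska hydrophobicity."""
    return tuple(sorted(AA_ALPHABETICAL, key=lambda a: AMINO_ACIDS[a].hydrophobicity))


def is_transition(ref_base: str, alt_base: str) -> bool:
    return (ref_base, alt_base) in _TRANSITIONS


def codon_pair_hamming(ref: str, alt: str) -> int:
    """Number of base differences between two codons (1–3 for a real change)."""
    _check_codon(ref), _check_codon(alt)
    return sum(a != b for a, b in zip(ref, alt))


def cpg_change_label(ref: str, alt: str) -> str:
    """Classify a codon change by its effect on internal CpG content.

    Returns ``"destroys_cpg"``, ``"creates_cpg"`` or ``"cpg_neutral"``.
    Only the CG dinucleotide inside the codon is considered; boundary-spanning
    contexts need flanking sequence and are handled by the simulator.
    """
    before, after = contains_cpg(ref), contains_cpg(alt)
    if before and not after:
        return "destroys_cpg"
    if after and not before:
        return "creates_cpg"
    return "cpg_neutral"
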