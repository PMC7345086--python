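"""Validated data model of the standard genetic code and its annotations.

This module owns the three packaged reference tables every other module
consumes:

* the standard (universal) genetic code — 64 codons mapping to 20 amino
  acids plus three stop codons;
* the aminoacyl-tRNA synthetase (aaRS) class map — each amino acid is
  charged by a class I enzyme (2'-OH aminoacylation), a class II enzyme
  (3'-OH aminoacylation), or, uniquely for Lys, by both;
* prebiotic amino-acid abundance ranges relative to glycine, from
  simulation/observation compilations for two kinds of environment
  (atmospheric/hydrothermal and interstellar/meteorite panels).

All tables ship as plain TSV inside the package and are validated on load;
downstream code never re-parses raw text.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "AMINO_ACIDS",
    "STOP",
    "STOP_CODONS",
    "CodonTableError",
    "CodonTable",
    "AaRSClassMap",
    "AbundanceRange",
    "AbundanceTable",
    "normalize_codon",
    "aa_to_three",
    "aa_to_one",
    "load_standard_code",
    "degeneracy",
    "load_aars_classes",
    "load_abundance",
]

STOP = "STOP"
STOP_CODONS = frozenset({"UAA", "UAG", "UGA"})

_THREE_TO_ONE = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C",
    "Gln": "Q", "Glu": "E", "Gly": "G", "His": "H", "Ile": "I",
    "Leu": "L", "Lys": "K", "Met": "M", "Phe": "F", "Pro": "P",
    "Ser": "S", "Thr": "T", "Trp": "W", "Tyr": "Y", "Val": "V",
}
_ONE_TO_THREE = {v: k for k, v in _THREE_TO_ONE.items()}

#: The 20 canonical amino acids, three-letter codes, alphabetical.
AMINO_ACIDS = tuple(sorted(_THREE_TO_ONE))

_RNA_BASES = frozenset("ACGU")


class CodonTableError(ValueError):
    """Raised when a packaged table fails validation."""


def normalize_codon(codon: str) -> str:
    """Normalize a codon to the canonical RNA alphabet (A/C/G/U, upper case).

    DNA-alphabet input is accepted (T mapped to U). Anything that is not a
    triplet over {A,C,G,U,T} is rejected.
    """
    c = codon.strip().upper().replace("T", "U")
    if len(c) != 3 or not set(c) <= _RNA_BASES:
        raise CodonTableError(f"invalid codon {codon!r}")
    return c


def aa_to_three(aa: str) -> str:
    """Accept a 1- or 3-letter amino-acid code; return the 3-letter code."""
    s = aa.strip()
    if len(s) == 1 and s.upper() in _ONE_TO_THREE:
        return _ONE_TO_THREE[s.upper()]
    t = s[:1].upper() + s[1:].lower()
    if t in _THREE_TO_ONE:
        return t
    raise CodonTableError(f"unknown amino acid {aa!r}")


def aa_to_one(aa: str) -> str:
    """Return the 1-letter code for a 1- or 3-letter amino-acid code."""
    return _THREE_TO_ONE[aa_to_three(aa)]


@dataclass(frozen=True)
class CodonTable:
    """The standard genetic code: codon -> amino acid (3-letter) or STOP."""

    entries: Mapping[str, str]

    def __post_init__(self) -> None:
        if len(self.entries) != 64:
            raise CodonTableError(
                f"expected 64 codons, got {len(self.entries)}"
            )
        for codon, label in self.entries.items():
            if normalize_codon(codon) != codon:
                raise CodonTableError(f"non-normalized codon {codon!r}")
            if label != STOP and label not in _THREE_TO_ONE:
                raise CodonTableError(
                    f"unknown label {label!r} for codon {codon}"
                )
        if self.stops != STOP_CODONS:
            raise CodonTableError(f"stop codons {sorted(self.stops)} != "
                                  f"{sorted(STOP_CODONS)}")
        if set(self.amino_acids) != set(AMINO_ACIDS):
            raise CodonTableError("labels do not cover the 20 amino acids")

    @property
    def stops(self) -> frozenset[str]:
        return frozenset(c for c, a in self.entries.items() if a == STOP)

    @property
    def amino_acids(self) -> tuple[str, ...]:
        return tuple(sorted({a for a in self.entries.values() if a != STOP}))

    def family(self, aa: str) -> frozenset[str]:
        """All codons encoding ``aa`` (the codon family)."""
        aa3 = aa_to_three(aa)
        fam = frozenset(c for c, a in self.entries.items() if a == aa3)
        if not fam:
            raise CodonTableError(f"{aa3} not encoded by this table")
        return fam

    def translate(self, codon: str) -> str:
        return self.entries[normalize_codon(codon)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.entries.items()), columns=["codon", "label"]
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_records(cls, records: Iterable[tuple[str, str]]) -> "CodonTable":
        entries = {}
        for codon, label in records:
            c = normalize_codon(codon)
            if c in entries:
                raise CodonTableError(f"duplicate codon {c}")
            entries[c] = label if label == STOP else aa_to_three(label)
        return cls(entries)

    @classmethod
    def from_tsv(cls, path) -> "CodonTable":
        df = pd.read_csv(path, sep="\t", dtype=str)
        return cls.from_records(df[["codon", "label"]].itertuples(index=False))


def degeneracy(table: CodonTable, aa: str) -> int:
    """Number of codons encoding ``aa`` (1 for Trp/Met, up to 6 for Leu)."""
    return len(table.family(aa))


@dataclass(frozen=True)
class AaRSClassMap:
    """aaRS class membership per amino acid: subset of {"I", "II"}.

    ``sep_route`` flags amino acids reachable through a noncanonical
    class II route (Cys via SepRS/SepCysS in some prokaryotes); the flag is
    annotation only and never enters the class counts.
    """

    class_of: Mapping[str, frozenset[str]]
    sep_route: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if set(self.class_of) != set(AMINO_ACIDS):
            raise CodonTableError("class map must cover all 20 amino acids")
        for aa, cls in self.class_of.items():
            if not cls or not cls <= {"I", "II"}:
                raise CodonTableError(f"bad class set {set(cls)} for {aa}")

    def classes(self, aa: str) -> frozenset[str]:
        return self.class_of[aa_to_three(aa)]

    def members(self, cls: str) -> frozenset[str]:
        return frozenset(a for a, s in self.class_of.items() if cls in s)

    @property
    def dual(self) -> frozenset[str]:
        return self.members("I") & self.members("II")


@dataclass(frozen=True)
class AbundanceRange:
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (0 < self.lo <= self.hi) or not math.isfinite(self.hi):
            raise CodonTableError(f"malformed range {self.lo}–{self.hi}")

    @property
    def midpoint(self) -> float:
        """Derived point summary of the printed range (not a datum)."""
        return 0.5 * (self.lo + self.hi)


@dataclass(frozen=True)
class AbundanceTable:
    """Prebiotic abundance relative to Gly, per panel.

    Panel ``a``: atmospheric / hydrothermal-vent simulation experiments.
    Panel ``b``: interstellar-medium simulations and meteorite analyses.
    Amino acids the compilation does not report are simply absent from the
    panel mapping; they are never imputed.
    """

    panels: Mapping[str, Mapping[str, AbundanceRange]]

    def __post_init__(self) -> None:
        if set(self.panels) != {"a", "b"}:
            raise CodonTableError("expected exactly panels 'a' and 'b'")
        for name, rows in self.panels.items():
            if not set(rows) <= set(AMINO_ACIDS):
                raise CodonTableError(f"unknown amino acid in panel {name}")
            gly = rows.get("Gly")
            if gly is None or gly.lo != 1.0 or gly.hi != 1.0:
                raise CodonTableError(
                    f"panel {name} must anchor Gly at 1.0"
                )

    def panel(self, name: str) -> Mapping[str, AbundanceRange]:
        return self.panels[name]

    def reported(self, name: str) -> frozenset[str]:
        return frozenset(self.panels[name])

    def range(self, name: str, aa: str) -> AbundanceRange:
        rows = self.panels[name]
        aa3 = aa_to_three(aa)
        if aa3 not in rows:
            raise KeyError(f"{aa3} not reported in panel {name}")
        return rows[aa3]


def _data_path(name: str):
    return resources.files("codonchron.data").joinpath(name)


def load_standard_code() -> CodonTable:
    """Load and validate the packaged standard genetic code."""
    with resources.as_file(_data_path("codon_table.tsv")) as p:
        return CodonTable.from_tsv(p)


def load_aars_classes() -> AaRSClassMap:
    """Load the packaged aaRS class map (11 class I, 10 class II, Lys dual)."""
    with resources.as_file(_data_path("aars_classes.tsv")) as p:
        df = pd.read_csv(p, sep="\t", dtype=str)
    class_of = {}
    sep = set()
    for row in df.itertuples(index=False):
        aa = aa_to_three(row.aa)
        if aa in class_of:
            raise CodonTableError(f"duplicate class entry for {aa}")
        class_of[aa] = frozenset(row.classes.split(","))
        if row.noncanonical_sep_route == "1":
            sep.add(aa)
    m = AaRSClassMap(class_of, frozenset(sep))
    # the published lists: 11 class I, 10 class II, only Lys in both
    if len(m.members("I")) != 11 or len(m.members("II")) != 10:
        raise CodonTableError("class membership counts do not match the "
                              "published 11 (I) / 10 (II) lists")
    if m.dual != {"Lys"}:
        raise CodonTableError("exactly Lys must be dual-class")
    return m


def load_abundance() -> AbundanceTable:
    """Load the packaged prebiotic abundance ranges (relative to Gly)."""
    with resources.as_file(_data_path("abundance.tsv")) as p:
        df = pd.read_csv(p, sep="\t", dtype={"aa": str, "panel": str})
    panels: dict[str, dict[str, AbundanceRange]] = {"a": {}, "b": {}}
    for row in df.itertuples(index=False):
        aa = aa_to_three(row.aa)
        if aa in panels.setdefault(row.panel, {}):
            raise CodonTableError(f"duplicate abundance row {aa}/{row.panel}")
        panels[row.panel][aa] = AbundanceRange(float(row.lo), float(row.hi))
    return AbundanceTable({k: dict(v) for k, v in panels.items()})
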