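"""Chronological arrangement of codons and amino acids by GC-richness.

The arrangement follows two rules. Rule 1 (grouping): what matters most is
whether the middle base of a codon is G/C, then whether the first (5')
base is; the middle base takes precedence. This splits the code into three
chronological groups — GC-rich (middle and first base G/C for some codon),
middle (middle base G/C, first base A/U), and AU-rich (middle base A/U in
every codon). Rule 2 (within-group order): an amino acid whose codon
family is larger claimed more of the available sequence space and is
placed earlier; entries with the same family size are tied and share a
column. The flattening of the resulting column structure into a total
order is a deterministic convenience for downstream statistics, not part
of the model: in-column order is scientifically meaningless.

Amino acids with codons in more than one block (Arg, Ser, Leu) are grouped
by their highest-priority block — e.g. Arg is GC-rich via CGN even though
AGA/AGG exist.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Literal, Sequence

import pandas as pd

from .code_tables import (
    AMINO_ACIDS,
    STOP,
    CodonTable,
    CodonTableError,
    aa_to_three,
    normalize_codon,
)

__all__ = [
    "GCKey",
    "ChronoGroup",
    "ChronoEntry",
    "ChronoOrder",
    "codon_key",
    "best_key",
    "assign_group",
    "arrange",
    "flatten",
]

_GC = frozenset("GC")

#: Merged-stops entry id for the two late stop codons.
UAA_UAG = "UAA/UAG"


class ChronoGroup(str, Enum):
    """The three chronological groups, early to late."""

    GC_RICH = "GC_RICH"
    MIDDLE = "MIDDLE"
    AU_RICH = "AU_RICH"

    @property
    def order(self) -> int:
        return ("GC_RICH", "MIDDLE", "AU_RICH").index(self.value)


@dataclass(frozen=True, order=True)
class GCKey:
    """Positional G/C indicators of one codon, priority order.

    Sorting keys compare middle first, then first (5'), then wobble —
    matching rule 1's precedence.
    """

    middle_gc: int
    first_gc: int
    third_gc: int

    @property
    def gc_count(self) -> int:
        return self.middle_gc + self.first_gc + self.third_gc


def codon_key(codon: str) -> GCKey:
    """Positional GC indicators of a codon."""
    c = normalize_codon(codon)
    return GCKey(
        middle_gc=int(c[1] in _GC),
        first_gc=int(c[0] in _GC),
        third_gc=int(c[2] in _GC),
    )


@dataclass(frozen=True)
class ChronoEntry:
    """One placed entry: an amino acid or a stop-codon entry."""

    id: str                    # 3-letter aa code, or "UGA" / "UAA/UAG" / ...
    is_stop: bool
    codons: tuple[str, ...]    # the entry's codon family, sorted
    best_key: GCKey
    group: ChronoGroup
    column: int = -1           # filled in by arrange()
    rank: int = -1             # filled in by arrange()

    @property
    def n_codons(self) -> int:
        return len(self.codons)


@dataclass(frozen=True)
class ChronoOrder:
    """Column structure (ties) plus its deterministic flattening."""

    columns: tuple[tuple[ChronoEntry, ...], ...]
    provenance: dict = field(default_factory=dict, compare=False)

    @property
    def flattened(self) -> tuple[ChronoEntry, ...]:
        return tuple(e for col in self.columns for e in col)

    def entry(self, entry_id: str) -> ChronoEntry:
        for e in self.flattened:
            if e.id == entry_id:
                return e
        raise KeyError(entry_id)

    @property
    def amino_acid_column_ranks(self) -> dict[str, int]:
        """Column index per amino acid (stops dropped); ties share a rank."""
        return {e.id: e.column for e in self.flattened if not e.is_stop}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "entry": e.id,
                "group": e.group.value,
                "column": e.column,
                "rank": e.rank,
                "n_codons": e.n_codons,
                "codons": ";".join(e.codons),
                "middle_gc": e.best_key.middle_gc,
                "first_gc": e.best_key.first_gc,
                "third_gc": e.best_key.third_gc,
            }
            for e in self.flattened
        ]
        return pd.DataFrame(rows)


def best_key(codons: Iterable[str]) -> GCKey:
    """Highest-priority GCKey over a codon family (rule 1 precedence)."""
    keys = sorted((codon_key(c) for c in codons), reverse=True)
    if not keys:
        raise CodonTableError("empty codon family")
    return keys[0]


def _entry_codons(entry_id: str, table: CodonTable,
                  stops: str) -> tuple[tuple[str, ...], bool]:
    if entry_id == UAA_UAG:
        return ("UAA", "UAG"), True
    if entry_id in table.stops:
        if stops == "merged" and entry_id in ("UAA", "UAG"):
            raise CodonTableError(
                f"{entry_id} is part of the merged {UAA_UAG} entry"
            )
        return (entry_id,), True
    return tuple(sorted(table.family(entry_id))), False


def assign_group(aa_or_stop: str, table: CodonTable) -> ChronoGroup:
    """Chronological group of an amino acid or stop codon.

    GC-rich: some codon has both middle and first base G/C. Middle: the
    best codon has a G/C middle base but an A/U first base. AU-rich: every
    codon has an A/U middle base.
    """
    try:
        entry_id = aa_to_three(aa_or_stop)
    except CodonTableError:
        entry_id = aa_or_stop if aa_or_stop == UAA_UAG else \
            normalize_codon(aa_or_stop)
        if entry_id != UAA_UAG and entry_id not in table.stops:
            raise CodonTableError(f"{aa_or_stop!r} is neither an amino acid "
                                  "nor a stop codon")
    codons, _ = _entry_codons(entry_id, table, stops="split")
    key = best_key(codons)
    if key.middle_gc and key.first_gc:
        return ChronoGroup.GC_RICH
    if key.middle_gc:
        return ChronoGroup.MIDDLE
    return ChronoGroup.AU_RICH


def _wobble_degeneracy(codons: Sequence[str]) -> int:
    """Size of the highest-priority same-first-two-bases codon block."""
    blocks: dict[str, list[str]] = {}
    for c in codons:
        blocks.setdefault(c[:2], []).append(c)
    best_prefix = max(
        blocks,
        key=lambda p: (p[1] in _GC, p[0] in _GC, len(blocks[p]), p),
    )
    return len(blocks[best_prefix])


def arrange(
    table: CodonTable,
    *,
    stops: Literal["merged", "split"] = "merged",
    tie_rule: Literal["total-codons", "wobble-only"] = "total-codons",
) -> ChronoOrder:
    """Arrange all amino acids and stop entries from GC-rich to AU-rich.

    ``stops="merged"`` treats the two late stop codons UAA/UAG as a single
    2-codon entry (UGA is always its own entry); ``"split"`` keeps three
    1-codon stop entries. ``tie_rule`` selects the within-group size
    measure: total codon-family size (default) or the wobble-block size of
    the best codon block only (sensitivity variant).
    """
    entry_ids: list[str] = list(AMINO_ACIDS) + ["UGA"]
    entry_ids += [UAA_UAG] if stops == "merged" else ["UAA", "UAG"]

    entries = []
    for eid in entry_ids:
        codons, is_stop = _entry_codons(eid, table, stops)
        key = best_key(codons)
        entries.append(
            ChronoEntry(
                id=eid, is_stop=is_stop, codons=codons, best_key=key,
                group=assign_group(eid, table),
            )
        )

    def size(e: ChronoEntry) -> int:
        if tie_rule == "wobble-only":
            return _wobble_degeneracy(e.codons)
        return e.n_codons

    # columns: group ascending (early first), size descending; ties share
    # a column; in-column flattening alphabetical, stop entries last.
    entries.sort(key=lambda e: (e.group.order, -size(e), e.is_stop, e.id))
    columns: list[list[ChronoEntry]] = []
    prev = None
    for e in entries:
        col_key = (e.group.order, size(e))
        if col_key != prev:
            columns.append([])
            prev = col_key
        columns[-1].append(e)

    placed: list[tuple[ChronoEntry, ...]] = []
    rank = 0
    for ci, col in enumerate(columns):
        placed_col = []
        for e in col:
            placed_col.append(replace(e, column=ci, rank=rank))
            rank += 1
        placed.append(tuple(placed_col))

    return ChronoOrder(
        columns=tuple(placed),
        provenance={"stops": stops, "tie_rule": tie_rule},
    )


def flatten(order: ChronoOrder) -> tuple[ChronoEntry, ...]:
    """The deterministic total order (alphabetical in ties, stops last)."""
    return order.flattened
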