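"""Tie-aware comparison of amino-acid chronologies.

A chronology ranks amino acids by inferred order of incorporation into
the genetic code; parenthesized groups in published lists denote the same
period and are stored as shared ranks. Two published chronologies ship
with the package — Trifonov's 60-criteria consensus order and the single
criterion N6' ("stability of complementary interactions") order — and the
GC-derived order is built from the arrangement module with column index
as rank (so ties are preserved) over amino acids only.

Because every list involved contains ties, the headline statistic is
Kendall's tau-b (tie-corrected), with Spearman's rho on mid-ranks
reported alongside.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from typing import Literal, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .code_tables import (
    AMINO_ACIDS,
    AbundanceTable,
    CodonTableError,
    aa_to_three,
    load_standard_code,
)
from .gc_ordering import ChronoOrder, arrange

__all__ = [
    "Chronology",
    "RankComparison",
    "packaged_chronologies",
    "gc_order_chronology",
    "kendall_tau_b",
    "abundance_vs_gc",
]


@dataclass(frozen=True)
class Chronology:
    """Named ranking of amino acids; tied entries share a rank."""

    name: str
    ranks: Mapping[str, float]

    def __post_init__(self) -> None:
        if not set(self.ranks) <= set(AMINO_ACIDS):
            bad = set(self.ranks) - set(AMINO_ACIDS)
            raise CodonTableError(f"{self.name}: unknown amino acids {bad}")
        vals = sorted(set(self.ranks.values()))
        if not vals:
            raise CodonTableError(f"{self.name}: empty chronology")

    @property
    def coverage(self) -> frozenset[str]:
        return frozenset(self.ranks)


@dataclass(frozen=True)
class RankComparison:
    """Tie-corrected rank agreement between two rankings."""

    name_a: str
    name_b: str
    n: int
    tau_b: float
    rho: float


def _load_published() -> dict[str, Chronology]:
    path = resources.files("codonchron.data").joinpath("chronologies.tsv")
    with resources.as_file(path) as p:
        df = pd.read_csv(p, sep="\t", dtype={"name": str, "aa": str})
    out = {}
    for name, sub in df.groupby("name", sort=False):
        ranks = {aa_to_three(r.aa): float(r.rank)
                 for r in sub.itertuples(index=False)}
        if len(ranks) != len(sub):
            raise CodonTableError(f"duplicate amino acid in {name}")
        out[name] = Chronology(name=name, ranks=ranks)
    # both published lists cover the full canonical set
    for name, chrono in out.items():
        if chrono.coverage != frozenset(AMINO_ACIDS):
            raise CodonTableError(f"{name} does not cover all 20 amino acids")
    return out


def gc_order_chronology(order: ChronoOrder | None = None) -> Chronology:
    """The GC-derived chronology: column index as rank, stops dropped."""
    if order is None:
        order = arrange(load_standard_code())
    return Chronology(
        name="gc_order",
        ranks={aa: float(c) for aa, c in
               order.amino_acid_column_ranks.items()},
    )


def packaged_chronologies(
    order: ChronoOrder | None = None,
) -> dict[str, Chronology]:
    """The two published chronologies plus the GC-derived one."""
    out = _load_published()
    out["gc_order"] = gc_order_chronology(order)
    return out


def kendall_tau_b(a: Chronology, b: Chronology) -> RankComparison:
    """Kendall tau-b and Spearman rho over the coverage intersection."""
    common = sorted(a.coverage & b.coverage)
    if len(common) < 3:
        raise CodonTableError(
            f"need >= 3 shared amino acids, got {len(common)}"
        )
    x = np.array([a.ranks[aa] for aa in common])
    y = np.array([b.ranks[aa] for aa in common])
    if np.all(x == x[0]) or np.all(y == y[0]):
        warnings.warn(
            "all-tied ranking: tau_b undefined, reported as 0.0",
            stacklevel=2,
        )
        return RankComparison(a.name, b.name, len(common), 0.0, 0.0)
    tau = stats.kendalltau(x, y, variant="b").statistic
    rho = stats.spearmanr(x, y).statistic
    return RankComparison(a.name, b.name, len(common),
                          float(tau), float(rho))


def abundance_vs_gc(
    abund: AbundanceTable,
    order: ChronoOrder,
    panel: Literal["a", "b"] = "a",
    summary: Literal["midpoint", "lo", "hi"] = "midpoint",
) -> RankComparison:
    """Rank agreement between prebiotic abundance and the GC order.

    Abundance ranges are summarized to a point (midpoint by default — a
    derived convenience, not a printed value) and compared, as ranks,
    against the GC-order column ranks over the amino acids the panel
    reports. The result is a report only: positive tau means abundant
    amino acids tend to sit late in the GC order, negative means early.
    """
    rows = abund.panel(panel)
    gc = gc_order_chronology(order)
    common = sorted(set(rows) & gc.coverage)
    if not common:
        raise CodonTableError("no amino acids shared with the panel")
    if len(common) < 3:
        raise CodonTableError(
            f"panel {panel!r} shares only {len(common)} amino acids "
            "with the order; comparison is degenerate"
        )
    values = {aa: getattr(rows[aa], summary) if summary != "midpoint"
              else rows[aa].midpoint for aa in common}
    abund_chrono = Chronology(name=f"abundance_{panel}_{summary}",
                              ranks=values)
    return kendall_tau_b(abund_chrono, Chronology("gc_order_subset", {
        aa: gc.ranks[aa] for aa in common}))
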