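"""aaRS class overlay on the chronological order and zone statistics.

Overlaying the aminoacyl-tRNA synthetase class of each amino acid onto the
GC-richness order produces contiguous same-class stretches ("zones"): a
solitary class I Arg, a class II zone (Gly, Ala, Pro, Ser, Thr), a class I
zone (Cys, Trp, Leu, Val, Ile), and a mixed late region. The run
detection here makes that structure explicit, and a Monte-Carlo
permutation test quantifies how unlikely so few runs would be if class
labels were assigned to positions at random (one-sided, clustering
alternative: fewer runs than random).

Stop entries carry no synthetase and the dual-class amino acid (Lys) has
no single label, so by default both are dropped from the effective
sequence before runs are counted; alternative dual-label policies are
available.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .code_tables import AaRSClassMap, CodonTableError
from .gc_ordering import ChronoEntry, ChronoOrder

__all__ = [
    "ClassSequence",
    "ZonePartition",
    "ClusterStat",
    "BoundaryAnnotation",
    "overlay",
    "effective_labels",
    "detect_runs",
    "clustering_pvalue",
    "preluca_boundary",
]

DualPolicy = Literal["exclude", "either", "own"]


@dataclass(frozen=True)
class ClassSequence:
    """The flattened chronological order relabeled with aaRS classes."""

    items: tuple[tuple[ChronoEntry, str], ...]  # label in {I, II, BOTH, STOP}

    def labels(self) -> tuple[str, ...]:
        return tuple(lbl for _, lbl in self.items)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"entry": e.id, "rank": e.rank, "column": e.column,
                 "group": e.group.value, "aars_class": lbl}
                for e, lbl in self.items
            ]
        )


@dataclass(frozen=True)
class ZonePartition:
    """Maximal same-class runs over the effective sequence."""

    runs: tuple[tuple[str, tuple[str, ...]], ...]  # (label, member ids)

    @property
    def n_runs(self) -> int:
        return len(self.runs)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"zone": i, "aars_class": lbl, "members": ";".join(ids),
                 "size": len(ids)}
                for i, (lbl, ids) in enumerate(self.runs)
            ]
        )


@dataclass(frozen=True)
class ClusterStat:
    """Monte-Carlo clustering statistic for the run count."""

    observed_runs: int
    n_permutations: int
    seed: int
    p_value: float
    n_effective: int


@dataclass(frozen=True)
class BoundaryAnnotation:
    """Where UGA sits relative to the class II -> class I transition."""

    uga_rank: int
    uga_column: int
    prev_label: str | None       # nearest effective label before UGA
    next_label: str | None       # nearest effective label after UGA
    class_ii_zone: tuple[str, ...]
    class_i_zone: tuple[str, ...]
    near_boundary: bool
    note: str


def overlay(order: ChronoOrder, classes: AaRSClassMap) -> ClassSequence:
    """Relabel the flattened order with aaRS classes; no reordering."""
    items = []
    for e in order.flattened:
        if e.is_stop:
            label = "STOP"
        else:
            cls = classes.classes(e.id)
            label = "BOTH" if cls == {"I", "II"} else next(iter(cls))
        items.append((e, label))
    return ClassSequence(tuple(items))


def _apply_dual_policy(labels: Sequence[str],
                       dual_policy: DualPolicy) -> list[str]:
    """Reduce a raw label sequence to run-countable labels.

    STOP positions are always dropped. ``exclude`` drops BOTH too;
    ``either`` lets BOTH continue whatever run precedes it (the most
    clustering-friendly reading); ``own`` keeps BOTH as its own label.
    """
    out: list[str] = []
    for lbl in labels:
        if lbl == "STOP":
            continue
        if lbl == "BOTH":
            if dual_policy == "exclude":
                continue
            if dual_policy == "either":
                if out:
                    out.append(out[-1])
                continue  # leading BOTH attaches to nothing; drop it
        out.append(lbl)
    return out


def effective_labels(seq: ClassSequence,
                     dual_policy: DualPolicy = "exclude") -> list[str]:
    return _apply_dual_policy(seq.labels(), dual_policy)


def _count_runs(labels: Sequence[str]) -> int:
    return 1 + sum(
        1 for i in range(1, len(labels)) if labels[i] != labels[i - 1]
    )


def detect_runs(seq: ClassSequence,
                dual_policy: DualPolicy = "exclude") -> ZonePartition:
    """Maximal same-class runs of the effective sequence."""
    eff: list[tuple[str, str]] = []  # (entry id, effective label)
    for e, lbl in seq.items:
        if lbl == "STOP":
            continue
        if lbl == "BOTH":
            if dual_policy == "exclude":
                continue
            if dual_policy == "either":
                if not eff:
                    continue
                lbl = eff[-1][1]
        eff.append((e.id, lbl))
    if not eff:
        raise CodonTableError("effective sequence is empty")
    runs: list[tuple[str, list[str]]] = []
    for eid, lbl in eff:
        if runs and runs[-1][0] == lbl:
            runs[-1][1].append(eid)
        else:
            runs.append((lbl, [eid]))
    return ZonePartition(tuple((lbl, tuple(ids)) for lbl, ids in runs))


def clustering_pvalue(
    seq: ClassSequence,
    n_permutations: int = 10_000,
    seed: int = 0,
    dual_policy: DualPolicy = "exclude",
) -> ClusterStat:
    """One-sided permutation p-value for zonal clustering.

    Labels of the effective sequence are permuted uniformly over
    positions; p = (1 + #{permutations with runs <= observed}) /
    (n_permutations + 1). Small p means fewer runs (stronger clustering)
    than label-exchangeable chance.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    labels = effective_labels(seq, dual_policy)
    if len(labels) < 2 or len(set(labels)) < 2:
        raise CodonTableError(
            "run statistic undefined: need >= 2 positions and both labels"
        )
    observed = detect_runs(seq, dual_policy).n_runs
    arr = np.asarray(labels)
    codes = np.unique(arr, return_inverse=True)[1].astype(np.int8)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(codes)
        runs = 1 + int(np.count_nonzero(perm[1:] != perm[:-1]))
        if runs <= observed:
            hits += 1
    p = (1 + hits) / (n_permutations + 1)
    return ClusterStat(
        observed_runs=observed,
        n_permutations=n_permutations,
        seed=seed,
        p_value=p,
        n_effective=len(labels),
    )


def preluca_boundary(seq: ClassSequence,
                     order: ChronoOrder) -> BoundaryAnnotation:
    """Annotate UGA's position relative to the class II / class I zones.

    The first stop codon UGA is expected to sit in the transition span
    between the early class II zone (ending at Thr) and the first pure
    class I zone (Cys ... Ile): ``near_boundary`` is true when UGA's
    column lies between the last column of that class II zone and the
    last column of that class I zone, inclusive.
    """
    try:
        uga = order.entry("UGA")
    except KeyError:
        raise CodonTableError("order contains no UGA entry") from None

    pos = {e.id: i for i, (e, _) in enumerate(seq.items)}
    i_uga = pos["UGA"]
    labels = seq.labels()

    def nearest(idxs) -> str | None:
        for j in idxs:
            if labels[j] in ("I", "II"):
                return labels[j]
        return None

    prev_label = nearest(range(i_uga - 1, -1, -1))
    next_label = nearest(range(i_uga + 1, len(labels)))

    zones = detect_runs(seq, dual_policy="exclude")
    ii_zone: tuple[str, ...] = ()
    i_zone: tuple[str, ...] = ()
    for k, (lbl, ids) in enumerate(zones.runs):
        if lbl == "II" and not ii_zone:
            ii_zone = ids
            for lbl2, ids2 in zones.runs[k + 1:]:
                if lbl2 == "I":
                    i_zone = ids2
                    break
            break

    if prev_label is None:
        return BoundaryAnnotation(
            uga_rank=uga.rank, uga_column=uga.column,
            prev_label=None, next_label=next_label,
            class_ii_zone=ii_zone, class_i_zone=i_zone,
            near_boundary=False, note="degenerate: no preceding run",
        )

    near = False
    note = "UGA outside the II->I transition span"
    if ii_zone and i_zone:
        col = {e.id: e.column for e in order.flattened}
        lo = max(col[a] for a in ii_zone)
        hi = max(col[a] for a in i_zone)
        near = lo <= uga.column <= hi
        if near:
            note = ("UGA lies in the transition span between the class II "
                    "zone and the first class I zone")
    return BoundaryAnnotation(
        uga_rank=uga.rank, uga_column=uga.column,
        prev_label=prev_label, next_label=next_label,
        class_ii_zone=ii_zone, class_i_zone=i_zone,
        near_boundary=near, note=note,
    )
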