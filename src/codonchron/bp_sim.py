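"""Stochastic simulator of the bridge-peptide (BP) feedback mechanism.

The model is a deliberately minimal caricature of an RNA–peptide world:

* a pool of short RNAs is synthesized with a GC-biased base composition
  (G or C with probability ``p_gc`` per base, split evenly G/C);
* each cycle, every uncharged RNA is aminoacylated. With probability
  ``q = min(1, beta * n_bp / n_rna * gc_fraction)`` the charging is
  BP-mediated and delivers Arg (bridge peptides bind GC-rich RNA via Arg
  and recruit free Arg via Asp); otherwise an amino acid is drawn from
  the prebiotic-abundance weights — the "chemical code";
* charged RNAs hybridize in random groups and their amino acids condense
  into one peptide per group (hybridization-dependent peptides, HDPs);
  a peptide containing both Arg and Asp at length >= 3 is itself a BP;
* peptides and RNAs survive to the next cycle stochastically — BPs get a
  survival bonus, GC-rich RNAs a stability bonus — and the RNA pool is
  replenished to its fixed size with fresh synthesis.

With ``beta = 0`` the model reduces exactly to chemical-code
incorporation; with ``beta > 0`` and any standing BPs, Arg charging is
up-biased on GC-rich RNAs, which makes new BPs more likely, which raises
the bias: the positive feedback loop the mechanism proposes. All rates
and functional forms are free parameters of this package — the mechanism
itself is qualitative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .code_tables import AMINO_ACIDS, aa_to_three, load_abundance

__all__ = [
    "SimConfig",
    "RNAMolecule",
    "Peptide",
    "SimState",
    "Trajectory",
    "default_aa_weights",
    "is_bridge_peptide",
    "init_pool",
    "aminoacylate_step",
    "hdp_step",
    "degrade_replenish_step",
    "run_simulation",
]

_BASES = np.array(list("ACGU"))
_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
_ARG = _AA_INDEX["Arg"]
_ASP = _AA_INDEX["Asp"]

#: Default BP seed sequence (Arg-Gly-Gly-Ala-Asp).
RGGAD = ("Arg", "Gly", "Gly", "Ala", "Asp")


def default_aa_weights(floor: float = 0.005) -> dict[str, float]:
    """Chemical-code sampling weights: abundance panel (a) midpoints.

    Amino acids the panel does not report get a small floor weight so no
    canonical amino acid is structurally impossible to incorporate.
    """
    panel = load_abundance().panel("a")
    return {
        aa: (panel[aa].midpoint if aa in panel else floor)
        for aa in AMINO_ACIDS
    }


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the BP-world simulation (all free parameters)."""

    n_rna: int = 1000                  # fixed RNA pool size
    rna_length: int = 20               # bases per RNA
    p_gc: float = 0.7                  # per-base probability of G or C
    aa_weights: Mapping[str, float] | None = None   # None -> default table
    beta: float = 5.0                  # strength of BP-mediated Arg charging
    peptide_len_range: tuple[int, int] = (2, 6)     # residues per HDP
    base_survival: float = 0.8         # per-cycle survival probability
    survival_bonus: float = 1.25       # multiplier for BP-containing peptides
    gc_stability_slope: float = 0.5    # RNA survival slope in gc_fraction
    n_cycles: int = 200
    n_bp_seeds: int = 5                # RGGAD peptides present at cycle 0
    bp_requires_asp: bool = True       # BP motif: Arg AND Asp (else Arg only)
    bp_min_length: int = 3
    seed: int = 0

    def validate(self) -> None:
        if self.n_rna < 1 or self.rna_length < 1 or self.n_cycles < 0:
            raise ValueError("n_rna, rna_length >= 1 and n_cycles >= 0")
        for name in ("p_gc", "base_survival"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.beta < 0 or self.survival_bonus < 0:
            raise ValueError("beta and survival_bonus must be >= 0")
        lo, hi = self.peptide_len_range
        if not (1 <= lo <= hi):
            raise ValueError(f"bad peptide_len_range {self.peptide_len_range}")
        w = self.weights_array()
        if np.any(w < 0) or w.sum() <= 0:
            raise ValueError("aa_weights must be >= 0 with positive sum")

    def weights_array(self) -> np.ndarray:
        weights = self.aa_weights
        if weights is None:
            weights = default_aa_weights()
        arr = np.zeros(len(AMINO_ACIDS))
        for aa, w in weights.items():
            arr[_AA_INDEX[aa_to_three(aa)]] = float(w)
        return arr


@dataclass(frozen=True)
class RNAMolecule:
    """One pool RNA; object view of a row of the vectorized state."""

    sequence: str
    charged_with: str | None = None

    @property
    def gc_fraction(self) -> float:
        return sum(b in "GC" for b in self.sequence) / len(self.sequence)


@dataclass(frozen=True)
class Peptide:
    """An HDP: the residues carried by one hybridized RNA group."""

    residues: tuple[str, ...]

    def is_bp(self, requires_asp: bool = True, min_length: int = 3) -> bool:
        return is_bridge_peptide(self, requires_asp, min_length)


def is_bridge_peptide(p: Peptide, requires_asp: bool = True,
                      min_length: int = 3) -> bool:
    """BP motif predicate: length >= min and Arg present (and Asp if required)."""
    if not p.residues:
        raise ValueError("empty peptide")
    if len(p.residues) < min_length:
        return False
    if "Arg" not in p.residues:
        return False
    return (not requires_asp) or ("Asp" in p.residues)


@dataclass
class SimState:
    """Vectorized simulation state.

    RNA sequences are a (n_rna, rna_length) base-code matrix
    (0=A, 1=C, 2=G, 3=U); ``charged`` holds amino-acid indices, -1 for
    uncharged. The peptide pool keeps only each peptide's BP flag (its
    residues are consumed by the statistics at formation time);
    per-amino-acid incorporation counts accumulate in
    ``incorporated_counts``.
    """

    bases: np.ndarray
    charged: np.ndarray
    peptide_is_bp: np.ndarray
    rng: np.random.Generator
    incorporated_counts: np.ndarray = field(
        default_factory=lambda: np.zeros(len(AMINO_ACIDS), dtype=np.int64)
    )
    cycle_arg_fraction: float = 0.0    # Arg share of this cycle's residues

    @property
    def gc_fraction(self) -> np.ndarray:
        return ((self.bases == 1) | (self.bases == 2)).mean(axis=1)

    @property
    def n_bp(self) -> int:
        return int(self.peptide_is_bp.sum())

    @property
    def n_peptides(self) -> int:
        return len(self.peptide_is_bp)

    def molecules(self) -> list[RNAMolecule]:
        """Object view of the RNA pool (for inspection; not used in steps)."""
        out = []
        for row, ch in zip(self.bases, self.charged):
            seq = "".join(_BASES[row])
            out.append(RNAMolecule(seq, AMINO_ACIDS[ch] if ch >= 0 else None))
        return out


@dataclass(frozen=True)
class Trajectory:
    """Per-cycle summaries; record 0 is the initial state."""

    records: tuple[dict, ...]
    config: SimConfig

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(list(self.records))

    @property
    def final(self) -> dict:
        return self.records[-1]


def _fresh_bases(n: int, cfg: SimConfig,
                 rng: np.random.Generator) -> np.ndarray:
    """Sample i.i.d. bases: G/C with prob p_gc (split evenly), A/U likewise."""
    p = np.array([(1 - cfg.p_gc) / 2, cfg.p_gc / 2,
                  cfg.p_gc / 2, (1 - cfg.p_gc) / 2])
    return rng.choice(4, size=(n, cfg.rna_length), p=p).astype(np.int8)


def init_pool(cfg: SimConfig) -> SimState:
    """Initial state: uncharged GC-biased pool plus seeded BP peptides."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    bases = _fresh_bases(cfg.n_rna, cfg, rng)
    charged = np.full(cfg.n_rna, -1, dtype=np.int16)
    peptide_is_bp = np.ones(cfg.n_bp_seeds, dtype=bool)
    return SimState(bases=bases, charged=charged,
                    peptide_is_bp=peptide_is_bp, rng=rng)


def aminoacylate_step(state: SimState, cfg: SimConfig) -> SimState:
    """Charge every uncharged RNA: BP-mediated Arg or chemical code."""
    unch = np.flatnonzero(state.charged < 0)
    if unch.size == 0:
        return state
    rng = state.rng
    q = np.minimum(
        1.0, cfg.beta * state.n_bp / cfg.n_rna * state.gc_fraction[unch]
    )
    bp_mediated = rng.random(unch.size) < q
    w = cfg.weights_array()
    chem = rng.choice(len(AMINO_ACIDS), size=unch.size, p=w / w.sum())
    state.charged[unch] = np.where(bp_mediated, _ARG, chem).astype(np.int16)
    return state


def _group_lengths(n: int, lo: int, hi: int,
                   rng: np.random.Generator) -> list[int]:
    """Group sizes L ~ Uniform{lo..hi} until fewer than lo RNAs remain."""
    lengths: list[int] = []
    remaining = n
    while remaining >= lo:
        L = min(int(rng.integers(lo, hi + 1)), remaining)
        lengths.append(L)
        remaining -= L
    return lengths


def hdp_step(state: SimState, cfg: SimConfig) -> SimState:
    """Condense charged RNAs into hybridization-dependent peptides.

    Charged RNAs are shuffled and partitioned into groups of random size;
    each group's amino acids form one peptide and the RNAs return to the
    pool uncharged. Leftover charged RNAs (fewer than the minimum peptide
    length) stay charged for the next cycle.
    """
    idx = np.flatnonzero(state.charged >= 0)
    lo, hi = cfg.peptide_len_range
    state.cycle_arg_fraction = 0.0
    if idx.size < max(2, lo):
        return state
    rng = state.rng
    perm = rng.permutation(idx)
    lengths = _group_lengths(perm.size, lo, hi, rng)
    used = int(np.sum(lengths))
    members = perm[:used]
    residues = state.charged[members].astype(np.int64)

    # per-group BP detection without Python-level peptide objects
    group_id = np.repeat(np.arange(len(lengths)), lengths)
    has_arg = np.zeros(len(lengths), dtype=bool)
    has_asp = np.zeros(len(lengths), dtype=bool)
    np.logical_or.at(has_arg, group_id, residues == _ARG)
    np.logical_or.at(has_asp, group_id, residues == _ASP)
    long_enough = np.asarray(lengths) >= cfg.bp_min_length
    new_bp = has_arg & long_enough
    if cfg.bp_requires_asp:
        new_bp &= has_asp

    state.peptide_is_bp = np.concatenate([state.peptide_is_bp, new_bp])
    np.add.at(state.incorporated_counts, residues, 1)
    state.cycle_arg_fraction = float(np.mean(residues == _ARG))
    state.charged[members] = -1
    return state


def degrade_replenish_step(state: SimState, cfg: SimConfig) -> SimState:
    """Stochastic survival of peptides and RNAs; pool refilled to n_rna.

    Peptide survival is base_survival, multiplied by survival_bonus for
    BPs (capped at 1). RNA survival is base_survival plus a linear
    GC-stability term, ``clip(base + slope * (gc_fraction - 1/2), 0, 1)``;
    dead RNAs are replaced by fresh synthesis, so the pool size is
    conserved exactly.
    """
    rng = state.rng
    if state.n_peptides:
        p = np.where(
            state.peptide_is_bp,
            min(1.0, cfg.base_survival * cfg.survival_bonus),
            cfg.base_survival,
        )
        state.peptide_is_bp = state.peptide_is_bp[
            rng.random(state.n_peptides) < p
        ]
    p_rna = np.clip(
        cfg.base_survival
        + cfg.gc_stability_slope * (state.gc_fraction - 0.5),
        0.0, 1.0,
    )
    dead = np.flatnonzero(rng.random(cfg.n_rna) >= p_rna)
    if dead.size:
        state.bases[dead] = _fresh_bases(dead.size, cfg, rng)
        state.charged[dead] = -1
    return state


def _record(state: SimState, cycle: int) -> dict:
    n_pep = state.n_peptides
    return {
        "cycle": cycle,
        "n_bp": state.n_bp,
        "n_peptides": n_pep,
        "bp_fraction": state.n_bp / n_pep if n_pep else 0.0,
        "arg_fraction": state.cycle_arg_fraction,
        "mean_gc_fraction": float(state.gc_fraction.mean()),
        "pool_size": int(state.bases.shape[0]),
    }


def run_simulation(cfg: SimConfig) -> Trajectory:
    """Run the full cycle loop; reproducible given ``cfg.seed``."""
    state = init_pool(cfg)
    records = [_record(state, 0)]
    for cycle in range(1, cfg.n_cycles + 1):
        aminoacylate_step(state, cfg)
        hdp_step(state, cfg)
        degrade_replenish_step(state, cfg)
        records.append(_record(state, cycle))
    return Trajectory(records=tuple(records), config=cfg)
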