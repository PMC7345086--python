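"""Properties of the bridge-peptide world simulator."""

import math

import numpy as np
import pytest
from scipy import stats

from codonchron import (
    Peptide,
    SimConfig,
    default_aa_weights,
    is_bridge_peptide,
    run_simulation,
)
from codonchron.bp_sim import (
    aminoacylate_step,
    degrade_replenish_step,
    hdp_step,
    init_pool,
)
from codonchron.code_tables import AMINO_ACIDS

ARG = AMINO_ACIDS.index("Arg")
GLY = AMINO_ACIDS.index("Gly")


class TestBridgePeptidePredicate:
    def test_canonical_motif(self):
        assert is_bridge_peptide(Peptide(("Arg", "Gly", "Gly", "Ala",
                                          "Asp")))

    def test_requires_arg(self):
        assert not is_bridge_peptide(Peptide(("Gly", "Gly", "Ala")))

    def test_length_boundary(self):
        short = Peptide(("Arg", "Asp"))
        assert not is_bridge_peptide(short)
        assert is_bridge_peptide(short, min_length=2)

    def test_arg_only_variant(self):
        p = Peptide(("Arg", "Gly", "Gly"))
        assert not is_bridge_peptide(p)
        assert is_bridge_peptide(p, requires_asp=False)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            is_bridge_peptide(Peptide(()))


class TestInitPool:
    def test_pure_gc_pool(self):
        state = init_pool(SimConfig(n_rna=50, p_gc=1.0, seed=0))
        assert np.all(state.gc_fraction == 1.0)

    def test_mean_gc_matches_binomial(self):
        cfg = SimConfig(n_rna=10_000, rna_length=20, p_gc=0.5, seed=2)
        state = init_pool(cfg)
        se = math.sqrt(0.25 / (cfg.n_rna * cfg.rna_length))
        assert abs(state.gc_fraction.mean() - 0.5) <= 3 * se

    def test_seed_reproducibility(self):
        a = init_pool(SimConfig(seed=5))
        b = init_pool(SimConfig(seed=5))
        assert np.array_equal(a.bases, b.bases)

    def test_bp_seeds(self):
        state = init_pool(SimConfig(n_bp_seeds=3, seed=0))
        assert state.n_bp == 3

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(p_gc=1.5).validate()
        with pytest.raises(ValueError):
            SimConfig(peptide_len_range=(4, 2)).validate()
        with pytest.raises(ValueError):
            SimConfig(beta=-1.0).validate()


class TestAminoacylateStep:
    def test_beta_zero_is_chemical_code(self):
        cfg = SimConfig(n_rna=20_000, beta=0.0, seed=3)
        state = init_pool(cfg)
        aminoacylate_step(state, cfg)
        assert np.all(state.charged >= 0)
        w = cfg.weights_array()
        p_arg = w[ARG] / w.sum()
        share = np.mean(state.charged == ARG)
        se = math.sqrt(p_arg * (1 - p_arg) / cfg.n_rna)
        assert abs(share - p_arg) <= 4 * se

    def test_saturated_bp_charging(self):
        cfg = SimConfig(n_rna=100, p_gc=1.0, beta=1e6, n_bp_seeds=1, seed=0)
        state = init_pool(cfg)
        aminoacylate_step(state, cfg)
        assert np.all(state.charged == ARG)

    def test_one_cycle_arg_share_matches_mixture_expectation(self):
        """E[Arg share] = E[q] + (1 - E[q]) * w_Arg for the charged pool."""
        cfg = SimConfig(n_rna=100_000, p_gc=0.7, beta=2.0, n_bp_seeds=50,
                        seed=8)
        state = init_pool(cfg)
        q = np.minimum(
            1.0, cfg.beta * state.n_bp / cfg.n_rna * state.gc_fraction
        )
        w = cfg.weights_array()
        p_arg = w[ARG] / w.sum()
        expected = float(np.mean(q + (1 - q) * p_arg))
        aminoacylate_step(state, cfg)
        share = float(np.mean(state.charged == ARG))
        se = math.sqrt(expected * (1 - expected) / cfg.n_rna)
        assert abs(share - expected) <= 4 * se


class TestHdpStep:
    def test_fixed_length_grouping(self):
        cfg = SimConfig(n_rna=4, peptide_len_range=(2, 2), n_bp_seeds=0,
                        seed=1)
        state = init_pool(cfg)
        state.charged[:] = GLY
        hdp_step(state, cfg)
        assert state.n_peptides == 2
        assert np.all(state.charged == -1)

    def test_all_gly_makes_no_bps(self):
        cfg = SimConfig(n_rna=100, n_bp_seeds=0, seed=1)
        state = init_pool(cfg)
        state.charged[:] = GLY
        hdp_step(state, cfg)
        assert state.n_peptides > 0
        assert state.n_bp == 0

    def test_leftover_below_min_length_persists(self):
        cfg = SimConfig(n_rna=5, peptide_len_range=(3, 3), n_bp_seeds=0,
                        seed=1)
        state = init_pool(cfg)
        state.charged[:] = GLY
        hdp_step(state, cfg)
        assert state.n_peptides == 1
        assert np.count_nonzero(state.charged >= 0) == 2

    def test_group_length_distribution_uniform(self):
        from codonchron.bp_sim import _group_lengths

        rng = np.random.default_rng(4)
        lengths = _group_lengths(40_000, 2, 6, rng)
        # drop the final truncated group; the rest are iid Uniform{2..6}
        lengths = np.asarray(lengths[:-1])
        counts = np.bincount(lengths, minlength=7)[2:7]
        chi = stats.chisquare(counts)
        assert chi.pvalue > 0.01

    def test_incorporation_conservation(self):
        """No residue enters a peptide without having been charged."""
        cfg = SimConfig(n_rna=500, seed=6, n_bp_seeds=0)
        state = init_pool(cfg)
        aminoacylate_step(state, cfg)
        charged_total = int(np.count_nonzero(state.charged >= 0))
        hdp_step(state, cfg)
        leftover = int(np.count_nonzero(state.charged >= 0))
        assert state.incorporated_counts.sum() == charged_total - leftover


class TestDegradeReplenish:
    def test_no_attrition_at_full_survival(self):
        cfg = SimConfig(n_rna=200, base_survival=1.0, survival_bonus=1.0,
                        gc_stability_slope=0.0, seed=0)
        state = init_pool(cfg)
        bases_before = state.bases.copy()
        n_pep = state.n_peptides
        degrade_replenish_step(state, cfg)
        assert np.array_equal(state.bases, bases_before)
        assert state.n_peptides == n_pep

    def test_total_decay_empties_peptides(self):
        cfg = SimConfig(n_rna=200, base_survival=0.0, survival_bonus=1.0,
                        gc_stability_slope=0.0, seed=0)
        state = init_pool(cfg)
        degrade_replenish_step(state, cfg)
        assert state.n_peptides == 0

    def test_pool_size_conserved(self):
        cfg = SimConfig(n_rna=300, seed=7)
        state = init_pool(cfg)
        for _ in range(3):
            aminoacylate_step(state, cfg)
            hdp_step(state, cfg)
            degrade_replenish_step(state, cfg)
            assert state.bases.shape[0] == cfg.n_rna

    def test_gc_biased_survival_enriches_pool(self):
        """One selection+replenish step raises the pool GC mean above the
        synthesis mean (size-biased survival of GC-rich molecules)."""
        cfg = SimConfig(n_rna=50_000, p_gc=0.5, base_survival=0.5,
                        gc_stability_slope=1.0, n_bp_seeds=0, seed=9)
        state = init_pool(cfg)
        before = state.gc_fraction.mean()
        degrade_replenish_step(state, cfg)
        # survivors are GC-enriched, replacements are at the synthesis
        # mean, so the mixture must sit clearly above the pre-step mean
        assert state.gc_fraction.mean() > before + 0.005


class TestRunSimulation:
    def test_zero_cycles(self):
        traj = run_simulation(SimConfig(n_cycles=0, seed=0))
        assert len(traj.records) == 1
        assert traj.records[0]["cycle"] == 0

    def test_record_count_and_ranges(self):
        traj = run_simulation(SimConfig(n_cycles=30, seed=2))
        assert len(traj.records) == 31
        df = traj.to_frame()
        for col in ("bp_fraction", "arg_fraction", "mean_gc_fraction"):
            assert df[col].between(0, 1).all()
        assert (df["pool_size"] == 1000).all()

    def test_seed_determinism(self):
        a = run_simulation(SimConfig(n_cycles=20, seed=13)).to_frame()
        b = run_simulation(SimConfig(n_cycles=20, seed=13)).to_frame()
        assert a.equals(b)

    def test_beta_zero_arg_fraction_matches_weights(self):
        cfg = SimConfig(n_cycles=40, beta=0.0, seed=4, n_bp_seeds=0)
        traj = run_simulation(cfg)
        w = cfg.weights_array()
        p_arg = w[ARG] / w.sum()
        df = traj.to_frame().iloc[1:]
        # ~1000 incorporations per cycle; average over cycles
        n_total = 1000 * len(df)
        se = math.sqrt(p_arg * (1 - p_arg) / n_total)
        assert abs(df["arg_fraction"].mean() - p_arg) <= 4 * se

    def test_default_weights_follow_abundance(self):
        w = default_aa_weights()
        assert w["Gly"] == 1.0
        assert w["Ala"] == pytest.approx(1.15)
        assert w["Trp"] == 0.005          # unreported floor
        assert set(w) == set(AMINO_ACIDS)
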