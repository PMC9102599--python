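"""Linking/unlinking network, SSA, mean-field ODEs and rate fitting."""

from collections import Counter

import numpy as np
import pytest

from wpbribbon import (
    RateParams,
    ReactionState,
    SizeDistribution,
    ValidationError,
    fit_rates,
    length_frequencies,
    reaction_network,
    ssa_simulate,
    steady_state,
)
from wpbribbon.breathing import SPECIES, SPECIES_LENGTH, ssa_event_count

from _oracles import enumerate_channels


class TestReactionNetwork:
    @pytest.mark.parametrize("toggle", [True, False])
    def test_every_channel_conserves_ministacks(self, toggle):
        for ch in reaction_network(toggle):
            assert int(SPECIES_LENGTH @ ch.stoichiometry()) == 0

    def test_no_products_longer_than_five(self):
        lengths = dict(zip(SPECIES, SPECIES_LENGTH))
        for ch in reaction_network():
            if len(ch.reactants) == 2:
                assert sum(lengths[s] for s in ch.reactants) <= 5

    @pytest.mark.parametrize("toggle", [True, False])
    def test_matches_bond_layout_enumeration(self, toggle):
        """The channel set equals an independent symbolic enumeration over
        the species' explicit monomer/bond layouts (same channels, same
        multiplicities)."""
        ours = Counter()
        for ch in reaction_network(toggle):
            key = (tuple(sorted(ch.reactants)), tuple(sorted(ch.products)), ch.rate)
            ours[key] += ch.multiplier
        oracle = enumerate_channels(toggle)
        assert set(ours) == set(oracle)
        for key in oracle:
            assert ours[key] == pytest.approx(oracle[key]), key


class TestSSA:
    def test_zero_binding_rate_is_absorbing(self):
        init = ReactionState.all_monomers(500)
        rates = RateParams(r=0.0, d1=5.0, d2=1.0, M=500)
        final = ssa_simulate(init, rates, t_end=10.0, seed=1)
        assert np.array_equal(final.counts, init.counts)

    def test_aggregation_only_stalls_in_large_pieces(self):
        """With no unbinding, binding proceeds until no reactive pair is
        left: at most one monomer and one dimer remain and nearly all mass
        sits in length-4/5 species."""
        M = 2000
        init = ReactionState.all_monomers(M)
        rates = RateParams(r=1.0, d1=0.0, d2=0.0, M=M)
        final = ssa_simulate(init, rates, t_end=500.0, seed=2)
        assert final["MONO"] <= 1
        assert final["DIM"] <= 1
        mass_45 = 4 * (final["TET_DD"] + final["TET_MDM"]) + 5 * (
            final["PENT_END"] + final["PENT_MID"]
        )
        assert mass_45 >= 0.9 * M
        # and it is genuinely stalled: nothing changes afterwards
        rates2 = RateParams(r=1.0, d1=0.0, d2=0.0, M=M)
        again = ssa_simulate(final, rates2, t_end=10.0, seed=3)
        assert np.array_equal(again.counts, final.counts)

    def test_conservation_and_determinism(self):
        M = 5000
        rates = RateParams(r=0.001, d1=10.0, d2=1.0, M=M)
        init = ReactionState.all_monomers(M)
        a = ssa_simulate(init, rates, t_end=50.0, seed=11)
        b = ssa_simulate(init, rates, t_end=50.0, seed=11)
        assert a.ministacks == M
        assert np.array_equal(a.counts, b.counts)
        c = ssa_simulate(init, rates, t_end=50.0, seed=12)
        assert not np.array_equal(a.counts, c.counts)

    def test_dimer_peak_in_stable_dimer_regime(self):
        """With d2 << d1 at r*M/d1 = 1 the fragment-length distribution
        peaks at dimers (scaled-down ribbon-breathing regime)."""
        M = 10_000
        rates = RateParams(r=0.001, d1=10.0, d2=1.0, M=M)
        final = ssa_simulate(ReactionState.all_monomers(M), rates,
                             t_end=500.0, seed=5)
        freqs = length_frequencies(final).mass
        assert np.argmax(freqs) == 1  # length 2
        # the mean-field prediction agrees that dimers dominate
        ode_freqs, _ = steady_state(rates)
        assert np.argmax(ode_freqs) == 1

    def test_mismatched_initial_state_rejected(self):
        with pytest.raises(ValidationError):
            ssa_simulate(
                ReactionState.all_monomers(10),
                RateParams(r=1, d1=1, d2=1, M=20),
                t_end=1.0,
                seed=1,
            )

    def test_seed_required(self):
        with pytest.raises(ValidationError):
            ssa_simulate(
                ReactionState.all_monomers(10),
                RateParams(r=1, d1=1, d2=1, M=10),
                t_end=1.0,
                seed=None,
            )


class TestMeanField:
    def test_steady_state_conserves_ministacks(self):
        rates = RateParams(r=0.001, d1=10, d2=1, M=10_000)
        _, state = steady_state(rates)
        assert state.ministacks == pytest.approx(rates.M, rel=1e-6)

    def test_agrees_with_ssa_within_mc_error(self):
        """Mean-field steady-state frequencies sit within 3 standard errors
        of replicated SSA endpoint frequencies."""
        rates = RateParams(r=0.001, d1=10.0, d2=1.0, M=5000)
        ode_freqs, _ = steady_state(rates)
        init = ReactionState.all_monomers(rates.M)
        reps = np.array([
            length_frequencies(
                ssa_simulate(init, rates, t_end=200.0, seed=1000 + i)
            ).mass
            for i in range(8)
        ])
        mean = reps.mean(axis=0)
        se = reps.std(axis=0, ddof=1) / np.sqrt(len(reps))
        assert np.all(np.abs(mean - ode_freqs) <= 3 * se + 1e-4)

    def test_invariant_under_joint_rate_rescaling(self):
        """(r, d1, d2) -> (c r, c d1, c d2) is a pure time rescaling."""
        a, _ = steady_state(RateParams(r=0.001, d1=10, d2=1, M=10_000))
        b, _ = steady_state(RateParams(r=0.002, d1=20, d2=2, M=10_000))
        np.testing.assert_allclose(a, b, atol=1e-6)

    def test_depends_only_on_dimensionless_groups(self):
        """Fixing r*M/d1 and d1/d2 while changing M leaves frequencies
        unchanged (up to mean-field finite-size-free exactness)."""
        a, _ = steady_state(RateParams(r=0.001, d1=10, d2=1, M=10_000))
        b, _ = steady_state(RateParams(r=0.0005, d1=10, d2=1, M=20_000))
        np.testing.assert_allclose(a, b, atol=1e-6)

    def test_initial_condition_invariance(self):
        rates = RateParams(r=0.001, d1=10, d2=1, M=10_000)
        a, _ = steady_state(rates, ReactionState.all_monomers(rates.M))
        b, _ = steady_state(rates, ReactionState.all_dimers(rates.M))
        np.testing.assert_allclose(a, b, atol=1e-7)

    def test_equal_rates_lose_the_dimer_excess(self):
        """d2 = d1 makes fragmentation size-independent: monomers dominate
        again at parameters where d2 << d1 gives a dimer peak."""
        stable, _ = steady_state(RateParams(r=0.001, d1=10, d2=1, M=10_000))
        equal, _ = steady_state(RateParams(r=0.001, d1=10, d2=10, M=10_000))
        assert stable[1] > stable[0]
        assert equal[0] > equal[1]
        assert np.all(np.diff(equal) < 0)  # monotone decreasing in length

    def test_trimer_tetramer_order_depends_on_parameters(self):
        """Both orderings of length-3 vs length-4 frequencies occur."""
        a, _ = steady_state(RateParams(r=0.001, d1=10, d2=1, M=10_000))
        b, _ = steady_state(RateParams(r=0.001, d1=1, d2=0.01, M=10_000))
        assert a[2] > a[3]
        assert b[3] > b[2]


class TestLengthFrequencies:
    def test_monomer_dimer_split(self):
        state = ReactionState(np.array([50, 50, 0, 0, 0, 0, 0]))
        np.testing.assert_allclose(
            length_frequencies(state).mass, [0.5, 0.5, 0, 0, 0]
        )

    def test_tetramer_isomers_pool(self):
        state = ReactionState(np.array([0, 0, 0, 3, 1, 0, 0]))
        np.testing.assert_allclose(
            length_frequencies(state).mass, [0, 0, 0, 1.0, 0]
        )

    def test_random_states_normalize(self, rng):
        for _ in range(20):
            counts = rng.integers(0, 50, size=7)
            if counts.sum() == 0:
                counts[0] = 1
            f = length_frequencies(ReactionState(counts))
            assert f.mass.sum() == pytest.approx(1.0)

    def test_empty_state_rejected(self):
        with pytest.raises(ValidationError):
            length_frequencies(ReactionState(np.zeros(7, dtype=int)))


class TestFitRates:
    def test_degenerate_all_monomers_drives_d2_up(self):
        """Observed pure monomers: the fit picks the largest d2 (no stable
        dimers at all)."""
        obs = SizeDistribution(np.array([1.0, 0, 0, 0, 0]))
        fit = fit_rates(
            obs, d1_grid=[50.0], d2_grid=[1.0, 10.0, 100.0],
            M=2000, t_end=30.0, seed=3,
        )
        assert fit.params["d2"] == 100.0
        assert any("boundary" in w for w in fit.warnings)

    def test_monomer_dimer_balance_implies_stable_dimers(self):
        """Equal monomer/dimer proportions (the microtubule-depolymerized
        readout) force d2/d1 << 1."""
        obs = SizeDistribution(np.array([0.5, 0.5, 0, 0, 0]))
        fit = fit_rates(
            obs, d1_grid=[100.0], d2_grid=[1.0, 10.0, 100.0],
            M=5000, t_end=50.0, seed=4,
        )
        assert fit.params["d2"] / fit.params["d1"] <= 0.1

    def test_self_recovery_within_one_grid_step(self):
        """Frequencies generated at (d1, d2) = (300, 12) are re-fit with a
        different seed to within one grid step; d2 (the dimer-bond rate) is
        strongly identified, d1 only weakly in this unbinding-dominated
        regime."""
        M, t_end = 10_000, 50.0
        truth = RateParams(r=0.001, d1=300.0, d2=12.0, M=M)
        observed = length_frequencies(
            ssa_simulate(ReactionState.all_monomers(M), truth, t_end, seed=101)
        )
        d1_grid = [150.0, 300.0, 600.0]
        d2_grid = [3.0, 6.0, 12.0, 24.0, 48.0]
        fit = fit_rates(
            observed, d1_grid, d2_grid, M=M, t_end=t_end, seed=202
        )
        assert abs(d2_grid.index(fit.params["d2"]) - d2_grid.index(12.0)) <= 1
        assert abs(d1_grid.index(fit.params["d1"]) - d1_grid.index(300.0)) <= 1


def test_specialized_kernel_agrees_with_reference_loop():
    """The scalar (accelerated) Gillespie kernel and the generic
    channel-table reference loop sample the same process: replicate means
    of the endpoint frequencies agree within 3 standard errors."""
    from wpbribbon.breathing import _compile_network, _run_segment, _ssa_loop

    M = 200
    rates = RateParams(r=0.02, d1=5.0, d2=0.5, M=M)
    channels = reaction_network()
    tables = _compile_network(channels)
    fast, ref = [], []
    for i in range(6):
        x = ReactionState.all_monomers(M).counts.copy()
        _run_segment(x, channels, rates, 0.0, 15.0, 10**9, 1000 + i)
        fast.append(length_frequencies(ReactionState(x)).mass)
        y = ReactionState.all_monomers(M).counts.copy()
        _ssa_loop(y, *tables, rates.as_array(), 0.0, 15.0, 10**9, 2000 + i)
        ref.append(length_frequencies(ReactionState(y)).mass)
    fast, ref = np.array(fast), np.array(ref)
    diff = fast.mean(0) - ref.mean(0)
    se = np.sqrt(fast.var(0, ddof=1) / 6 + ref.var(0, ddof=1) / 6)
    assert np.all(np.abs(diff) <= 3 * se + 0.02)


def test_event_counter_reports_progress():
    M = 2000
    rates = RateParams(r=0.001, d1=10, d2=1, M=M)
    final, n_events = ssa_event_count(
        ReactionState.all_monomers(M), rates, 20.0, seed=9
    )
    assert n_events > 0
    assert final.ministacks == M
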