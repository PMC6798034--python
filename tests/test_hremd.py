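import numpy as np
import pytest

from enmremd.bias import ReplicaLadder, build_ladder, centroid_distances, BiasSpec
from enmremd.constants import KB
from enmremd.engine import SimState
from enmremd.errors import ConfigurationError
from enmremd.fixtures import DoubleWell
from enmremd.hremd import (
    CentroidBias,
    ControllerState,
    GaussianBias,
    adapt_amplitudes,
    adapt_ladder_gaps,
    attempt_exchanges,
    exchange_probability,
    run_hremd,
    update_reference_distances,
)


class TestExchangeProbability:
    def test_equal_energies_accept_always(self):
        assert exchange_probability(1.0, 1.0, 1.0, 1.0) == 1.0

    def test_forbidden_swap_rejected(self):
        assert exchange_probability(0.0, np.inf, 0.0, 0.0) == 0.0

    def test_favourable_swap_accepted(self):
        assert exchange_probability(5.0, 1.0, 1.0, 5.0) == 1.0

    def test_empirical_frequency_matches_probability(self):
        """Bernoulli oracle: accept/reject at Δ = 1 kcal/mol, 300 K."""
        delta = 1.0
        p = exchange_probability(0.0, delta, 0.0, 0.0, temperature=300.0)
        assert p == pytest.approx(np.exp(-delta / (KB * 300.0)))
        rng = np.random.default_rng(123)
        n = 100_000
        freq = np.mean(rng.random(n) < p)
        se = np.sqrt(p * (1 - p) / n)
        assert abs(freq - p) < 3 * se


def _double_well_states(n, x0=1.0, seed=0):
    seqs = np.random.SeedSequence(seed).spawn(n)
    return [
        SimState(
            coords=np.full((1, 1), x0),
            velocities=np.zeros((1, 1)),
            replica_index=i,
            rng=np.random.default_rng(seqs[i]),
        )
        for i in range(n)
    ]


class TestAttemptExchanges:
    def test_zero_scales_accept_every_attempt(self):
        ladder = ReplicaLadder(np.zeros(4), unit_level=2.25)
        biases = [GaussianBias(1.0, 1.0) for _ in range(4)]
        states = _double_well_states(4)
        for parity in (0, 1):
            _, recs = attempt_exchanges(
                states, ladder, biases, parity, np.random.default_rng(0)
            )
            assert all(r.accepted and r.probability == 1.0 for r in recs)

    def test_no_pairs_for_odd_parity_of_two_replicas(self):
        ladder = build_ladder(2, 1.0)
        biases = [GaussianBias(1.0, 1.0) for _ in range(2)]
        states = _double_well_states(2)
        out, recs = attempt_exchanges(
            states, ladder, biases, 1, np.random.default_rng(0)
        )
        assert recs == []
        assert np.array_equal(out[0].coords, states[0].coords)

    def test_state_count_mismatch_rejected(self):
        ladder = build_ladder(3, 1.0)
        biases = [GaussianBias(1.0, 1.0) for _ in range(3)]
        with pytest.raises(ConfigurationError):
            attempt_exchanges(
                _double_well_states(2), ladder, biases, 0, np.random.default_rng(0)
            )

    def test_accepted_swap_exchanges_coordinates(self):
        # make swapping always favourable: the biased replica's (negative,
        # barrier-lowering) bias is centred where x_0 sits, so the swap
        # strictly lowers the total energy and p = 1
        ladder = ReplicaLadder(np.array([0.0, 1.0]), unit_level=50.0)
        biases = [GaussianBias(1.0, 0.5, center=-1.0) for _ in range(2)]
        states = _double_well_states(2)
        states[0] = SimState(
            coords=np.full((1, 1), -1.0), velocities=np.zeros((1, 1)),
            rng=states[0].rng,
        )
        out, recs = attempt_exchanges(
            states, ladder, biases, 0, np.random.default_rng(1)
        )
        assert recs[0].accepted
        assert out[0].coords[0, 0] == pytest.approx(1.0)
        assert out[1].coords[0, 0] == pytest.approx(-1.0)


class TestController:
    def make(self):
        return ControllerState(n_pairs=3)

    def test_low_acceptance_lowers_by_exactly_ten_percent(self):
        lad = build_ladder(4, 2.0)
        new = adapt_amplitudes(self.make(), lad, np.array([0.15, 0.4, 0.4]))
        assert np.allclose(new.scales[1:] / lad.scales[1:], 0.90)

    def test_high_acceptance_raises_by_exactly_ten_percent(self):
        lad = build_ladder(4, 2.0)
        new = adapt_amplitudes(self.make(), lad, np.array([0.70, 0.4, 0.4]))
        assert np.allclose(new.scales[1:] / lad.scales[1:], 1.10)

    def test_inside_window_unchanged(self):
        lad = build_ladder(4, 2.0)
        assert adapt_amplitudes(self.make(), lad, np.array([0.4, 0.3, 0.55])) is lad

    def test_lowering_has_priority(self):
        lad = build_ladder(4, 2.0)
        new = adapt_amplitudes(self.make(), lad, np.array([0.15, 0.4, 0.9]))
        assert np.allclose(new.scales[1:] / lad.scales[1:], 0.90)

    def test_scales_never_negative(self):
        lad = build_ladder(4, 2.0)
        for _ in range(100):
            lad = adapt_amplitudes(self.make(), lad, np.array([0.1, 0.1, 0.1]))
        assert np.all(lad.scales >= 0)
        assert lad.scales[0] == 0.0

    def test_per_pair_gap_adjustment(self):
        lad = build_ladder(4, 2.0)
        new = adapt_ladder_gaps(self.make(), lad, np.array([0.1, 0.4, 0.9]))
        gaps_old = np.diff(lad.scales)
        gaps_new = np.diff(new.scales)
        assert gaps_new[0] == pytest.approx(0.9 * gaps_old[0])
        assert gaps_new[1] == pytest.approx(gaps_old[1])
        assert gaps_new[2] == pytest.approx(1.1 * gaps_old[2])
        assert new.scales[0] == 0.0
        assert np.all(np.diff(new.scales) > 0)

    def test_nan_rates_ignored(self):
        lad = build_ladder(4, 2.0)
        assert (
            adapt_amplitudes(self.make(), lad, np.array([np.nan] * 3)) is lad
        )

    def test_window_validation(self):
        with pytest.raises(ConfigurationError):
            ControllerState(n_pairs=2, window_low=0.7, window_high=0.6)


class TestReferenceDistanceUpdates:
    def spec(self):
        return BiasSpec.from_level(
            1.0, d0=np.full(6, 10.0), halfwidth=np.full(6, 2.0)
        )

    def test_constant_history_leaves_d0_unchanged(self):
        t = np.linspace(0, 10, 51)
        d = np.full((51, 6), 10.0)
        new = update_reference_distances(t, d, self.spec(), window=4.0)
        assert np.allclose(new.d0, 10.0)

    def test_linear_drift_gives_midpoint_mean(self):
        """d(t) = a + b·t averaged over [t_end − w, t_end] is a + b(t_end − w/2)."""
        a, b, w = 10.0, 0.3, 4.0
        t = np.linspace(0, 10, 1001)
        d = (a + b * t)[:, None].repeat(6, axis=1)
        new = update_reference_distances(t, d, self.spec(), window=w)
        assert np.allclose(new.d0, a + b * (10.0 - w / 2), atol=1e-9)

    def test_insufficient_history_skips_update(self, caplog):
        t = np.linspace(0, 1.0, 11)
        d = np.full((11, 6), 12.0)
        spec = self.spec()
        new = update_reference_distances(t, d, spec, window=4.0)
        assert new is spec

    def test_window_of_two_control_periods(self):
        """With the averaging window twice the control period, the update
        averages exactly the last two control intervals."""
        control = 2.0
        t = np.arange(0, 8.001, 0.1)
        d = np.where(t >= 4.0, 20.0, 10.0)[:, None].repeat(6, axis=1)
        new = update_reference_distances(
            t, d, self.spec(), window=2 * control
        )
        # trailing 4 ps covers t in [4, 8] where d = 20
        assert np.allclose(new.d0, 20.0)


class TestRunHremd:
    def test_zero_bias_ladder_accepts_everything(self):
        dw = DoubleWell(1.0, 1.0)
        ladder = ReplicaLadder(np.zeros(3), unit_level=2.25)
        biases = [GaussianBias(1.0, 1.0) for _ in range(3)]
        res = run_hremd(
            dw, biases, ladder, init_coords=np.full((3, 1, 1), 1.0),
            masses=np.array([20.0]), n_steps=2000, exchange_period_steps=50,
            control_period_steps=1000, d0_window_steps=2000,
            dt=0.01, friction=1.0, output_stride=100, seed=3,
            adapt=False, update_d0=False,
        )
        assert all(r.accepted for r in res.exchange_records)
        assert all(r.probability == 1.0 for r in res.exchange_records)

    def test_reproducible_from_seed(self, toy, toy_model):
        structure, partition = toy
        from enmremd.engine import NetworkPotential

        d0 = centroid_distances(structure.coords, partition)
        spec = BiasSpec.from_level(1.0, d0=d0, halfwidth=np.full(6, 3.0))
        out = []
        for _ in range(2):
            biases = [CentroidBias(spec, partition) for _ in range(3)]
            res = run_hremd(
                NetworkPotential(toy_model), biases, build_ladder(3, 1.0),
                init_coords=structure.coords, masses=structure.masses,
                n_steps=400, exchange_period_steps=10,
                control_period_steps=200, d0_window_steps=400,
                dt=0.01, friction=1.0, output_stride=50, seed=42,
            )
            out.append(res)
        a, b = out
        assert np.array_equal(a.frames[0].coords, b.frames[0].coords)
        assert [r.accepted for r in a.exchange_records] == [
            r.accepted for r in b.exchange_records
        ]
        assert np.array_equal(a.ladder.scales, b.ladder.scales)

    def test_controller_level_jumps_are_exactly_ten_percent(self, toy, toy_model):
        """Every biasing-level change in the run's audit trail is exactly
        ×0.9 or ×1.1 of a neighbour gap."""
        structure, partition = toy
        from enmremd.engine import NetworkPotential

        d0 = centroid_distances(structure.coords, partition)
        spec = BiasSpec.from_level(1.0, d0=d0, halfwidth=np.full(6, 3.0))
        biases = [CentroidBias(spec, partition) for _ in range(4)]
        res = run_hremd(
            NetworkPotential(toy_model), biases, build_ladder(4, 2.25),
            init_coords=structure.coords, masses=structure.masses,
            n_steps=2000, exchange_period_steps=10,
            control_period_steps=200, d0_window_steps=400,
            dt=0.01, friction=1.0, output_stride=200, seed=7,
        )
        levels = np.array([lv for _, lv in res.level_history])
        gaps = np.diff(levels, axis=1)
        changed_any = False
        for i in range(1, len(gaps)):
            ratio = gaps[i] / gaps[i - 1]
            for r in ratio:
                assert (
                    np.isclose(r, 1.0)
                    or np.isclose(r, 0.9)
                    or np.isclose(r, 1.1)
                )
                if not np.isclose(r, 1.0):
                    changed_any = True
        assert changed_any  # the transient must actually trigger the rule

    def test_unknown_modes_rejected(self, toy, toy_model):
        structure, partition = toy
        from enmremd.engine import NetworkPotential

        d0 = centroid_distances(structure.coords, partition)
        spec = BiasSpec.from_level(1.0, d0=d0, halfwidth=np.full(6, 3.0))
        biases = [CentroidBias(spec, partition) for _ in range(2)]
        with pytest.raises(ConfigurationError):
            run_hremd(
                NetworkPotential(toy_model), biases, build_ladder(2, 1.0),
                init_coords=structure.coords, masses=structure.masses,
                n_steps=10, exchange_period_steps=5, control_period_steps=5,
                d0_window_steps=10, seed=0, d0_mode="nope",
            )

    def test_diagnostics_tables_have_expected_shape(self):
        dw = DoubleWell(1.0, 1.0)
        biases = [GaussianBias(1.0, 1.0) for _ in range(3)]
        res = run_hremd(
            dw, biases, build_ladder(3, 0.5),
            init_coords=np.full((3, 1, 1), 1.0), masses=np.array([20.0]),
            n_steps=1000, exchange_period_steps=20, control_period_steps=200,
            d0_window_steps=400, dt=0.01, output_stride=100, seed=1,
        )
        acc_lines = res.acceptance_tsv().strip().splitlines()
        lvl_lines = res.levels_tsv().strip().splitlines()
        assert acc_lines[0].startswith("time_ps\tpair_0_1")
        assert len(acc_lines) == 1 + len(res.acceptance_history)
        assert lvl_lines[0].count("replica_") == 3
        assert len(res.exchange_records) > 0
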