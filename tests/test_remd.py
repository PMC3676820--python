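"""Replica-exchange engine: swap criterion, bookkeeping, thermodynamics."""

import numpy as np
import pytest

from foldscale import cg_sampler, protocol, remd, seeding
from foldscale.cg_sampler import MCParams, TwoLevelSystem, mc_sample_states
from foldscale.fixtures import KB_KCAL, TwoLevelModel, boltzmann_fraction
from foldscale.remd import ExchangeRecord, acceptance_stats, energy_histograms, exchange_probability, remd_run, round_trips


class TestExchangeProbability:
    def test_equal_energies_always_swap(self):
        assert exchange_probability(-5.0, -5.0, 300.0, 320.0, KB_KCAL) == 1.0

    def test_favorable_swap_is_certain(self):
        # hot replica holds the lower energy: swapping moves it down-ladder
        assert exchange_probability(-5.0, -10.0, 300.0, 320.0, KB_KCAL) == 1.0

    def test_high_precision_oracle(self):
        """sympy evaluation of exp[(1/kT_i - 1/kT_j)(E_i - E_j)] at 50
        digits for E_i=-10, E_j=-5 kcal/mol, T_i=300 K, T_j=320 K."""
        import sympy

        k = sympy.Rational(19872, 10**7)
        expected = float(
            sympy.exp((1 / (k * 300) - 1 / (k * 320)) * sympy.Integer(-5)).evalf(50)
        )
        assert exchange_probability(-10.0, -5.0, 300.0, 320.0, KB_KCAL) == pytest.approx(
            expected, rel=1e-12
        )

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            exchange_probability(0.0, 0.0, -1.0, 300.0)
        with pytest.raises(ValueError):
            exchange_probability(float("nan"), 0.0, 300.0, 310.0)

    def test_record_invariants(self):
        with pytest.raises(ValueError):
            ExchangeRecord(sweep=1, pair=(0, 2), delta=0.0, accepted=True)
        with pytest.raises(ValueError):
            ExchangeRecord(sweep=1, pair=(0, 1), delta=float("inf"), accepted=True)


@pytest.fixture(scope="module")
def two_level_run():
    model = TwoLevelModel(e_folded=-2.0, e_unfolded=0.0, g_folded=1, g_unfolded=20)
    ladder = seeding.make_geometric_ladder(250.0, 600.0, 3)
    system = TwoLevelSystem(model)
    result = remd_run(
        system, ladder, [model.g_folded] * 3, n_sweeps=60_000, exchange_interval=10, seed=3
    )
    return model, system, ladder, result


class TestEngineBookkeeping:
    def test_no_exchange_when_interval_exceeds_run(self):
        """Degenerate limit: the run is plain independent isothermal MC."""
        model = TwoLevelModel(e_folded=-2.0, e_unfolded=0.0, g_folded=1, g_unfolded=5)
        system = TwoLevelSystem(model)
        ladder = seeding.make_geometric_ladder(300.0, 400.0, 2)
        result = remd_run(system, ladder, [0, 0], n_sweeps=50, exchange_interval=100, seed=7)
        assert result.exchange_records == []
        p = MCParams(n_sweeps=50, temperature=300.0, seed=7)
        _, states, _ = mc_sample_states(system, 0, p)
        assert result.slot_states[0][-1] == states[-1]

    def test_walker_identity_conservation(self, two_level_run):
        *_, result = two_level_run
        ident = np.arange(result.n_slots)
        for row in result.walker_slots:
            np.testing.assert_array_equal(np.sort(row), ident)

    def test_fixed_seed_reproducibility(self):
        model = TwoLevelModel(e_folded=-1.0, e_unfolded=0.0, g_folded=2, g_unfolded=8)
        system = TwoLevelSystem(model)
        ladder = seeding.make_geometric_ladder(280.0, 500.0, 4)
        kw = dict(n_sweeps=2000, exchange_interval=5, seed=11)
        r1 = remd_run(system, ladder, [0] * 4, **kw)
        r2 = remd_run(system, ladder, [0] * 4, **kw)
        np.testing.assert_array_equal(r1.slot_energies, r2.slot_energies)
        np.testing.assert_array_equal(r1.walker_slots, r2.walker_slots)
        assert [(r.sweep, r.pair, r.accepted) for r in r1.exchange_records] == [
            (r.sweep, r.pair, r.accepted) for r in r2.exchange_records
        ]

    def test_even_odd_alternation(self, two_level_run):
        *_, result = two_level_run
        sweeps = sorted({r.sweep for r in result.exchange_records})
        first_pairs = {r.pair for r in result.exchange_records if r.sweep == sweeps[0]}
        second_pairs = {r.pair for r in result.exchange_records if r.sweep == sweeps[1]}
        assert first_pairs == {(0, 1)}  # even pairs first (3 slots: just 0-1)
        assert second_pairs == {(1, 2)}

    def test_mismatched_starts_rejected(self):
        model = TwoLevelModel(e_folded=-1.0, e_unfolded=0.0)
        ladder = seeding.make_geometric_ladder(280.0, 500.0, 3)
        with pytest.raises(ValueError, match="start states"):
            remd_run(TwoLevelSystem(model), ladder, [0, 0], n_sweeps=10, exchange_interval=5)


class TestThermodynamics:
    def test_two_level_slots_match_boltzmann(self, two_level_run):
        """Composite-chain detailed balance: per-slot folded fractions agree
        with the closed form within Monte-Carlo error on a 3-slot ladder."""
        model, system, ladder, result = two_level_run
        for slot, t in enumerate(ladder.temperatures):
            flags = np.array(
                [system.is_folded(s) for s in result.slot_states[slot]], dtype=float
            )
            exact = boltzmann_fraction(model, t)
            se = flags.std(ddof=1) / np.sqrt(len(flags) / 5.0)
            assert abs(flags.mean() - exact) < 3 * max(se, 1e-3)

    def test_neighbor_acceptance_matches_stationary_average(self, two_level_run):
        """Brute-force oracle: average exchange_probability over the product
        Boltzmann distribution of the four (folded/unfolded)^2 state pairs."""
        model, system, ladder, result = two_level_run
        stats = acceptance_stats(result)
        for _, row in stats.iterrows():
            ti = ladder.temperatures[int(row.pair_low)]
            tj = ladder.temperatures[int(row.pair_high)]
            fi = boltzmann_fraction(model, ti)
            fj = boltzmann_fraction(model, tj)
            expected = 0.0
            for pi, ei in ((fi, model.e_folded), (1 - fi, model.e_unfolded)):
                for pj, ej in ((fj, model.e_folded), (1 - fj, model.e_unfolded)):
                    expected += pi * pj * exchange_probability(ei, ej, ti, tj, KB_KCAL)
            n = row.attempted
            se = np.sqrt(expected * (1 - expected) / n) * 3  # generous 3 SE
            assert abs(row.rate - expected) < max(3 * se, 0.02)


class TestDiagnostics:
    def test_acceptance_stats_match_hand_count(self):
        records = [
            ExchangeRecord(sweep=s, pair=(0, 1), delta=0.0, accepted=(s % 3 == 0))
            for s in range(1, 31)
        ]
        result = _synthetic_result(n_slots=2, records=records)
        stats = acceptance_stats(result)
        assert stats.loc[0, "attempted"] == 30
        assert stats.loc[0, "accepted"] == 10
        assert stats.loc[0, "rate"] == pytest.approx(10 / 30)

    def test_zero_attempts_reported_missing_not_zero(self):
        result = _synthetic_result(n_slots=3, records=[])
        stats = acceptance_stats(result)
        assert stats["attempted"].tolist() == [0, 0]
        assert stats["rate"].isna().all()

    @pytest.mark.parametrize(
        "path,expected",
        [
            ([0, 1, 2, 1, 0], 1),
            ([0, 1, 0, 1, 0], 0),  # never reaches the top
            ([0, 1, 2, 1, 0, 1, 2, 2, 1, 0], 2),
            ([1, 2, 1, 0, 1, 2, 1, 0], 1),  # must arm at the bottom first
        ],
    )
    def test_round_trips_state_machine(self, path, expected):
        result = _synthetic_result(n_slots=3, walker_path=path)
        assert round_trips(result, walker_id=0) == expected

    def test_round_trips_match_independent_scan(self, rng):
        path = list(rng.integers(0, 4, size=400))
        result = _synthetic_result(n_slots=4, walker_path=path)

        # oracle: explicit scan for 0 -> ... -> top -> ... -> 0 episodes
        trips = 0
        k = 0
        n = len(path)
        while k < n:
            if path[k] == 0:
                try:
                    top = next(i for i in range(k + 1, n) if path[i] == 3)
                    back = next(i for i in range(top + 1, n) if path[i] == 0)
                except StopIteration:
                    break
                trips += 1
                k = back
            else:
                k += 1
        assert round_trips(result, walker_id=0) == trips

    def test_unknown_walker_rejected(self, two_level_run):
        *_, result = two_level_run
        with pytest.raises(ValueError):
            round_trips(result, walker_id=99)

    def test_histogram_overlap_bounds(self):
        same = _synthetic_result(n_slots=2, energies=[[1.0, 2.0, 3.0] * 10] * 2)
        _, _, overlap = energy_histograms(same, bins=10)
        assert overlap[0] == pytest.approx(1.0)
        disjoint = _synthetic_result(
            n_slots=2, energies=[[0.0, 1.0] * 10, [100.0, 101.0] * 10]
        )
        _, _, overlap = energy_histograms(disjoint, bins=50)
        assert overlap[0] == pytest.approx(0.0)

    def test_histogram_width_grows_with_temperature(self, go_model, hairpin16):
        """Equipartition trend on the Gō model: hotter slots sample broader
        energy distributions (the basis of Fig-2-style overlap plots)."""
        ladder = seeding.make_geometric_ladder(0.3, 1.0, 4)
        result = remd_run(
            go_model, ladder, [hairpin16] * 4, n_sweeps=6000, exchange_interval=50, seed=2
        )
        variances = result.slot_energies[:, 20:].var(axis=1)
        assert variances[0] < variances[-1]


class TestGoREMDSmoke:
    def test_go_model_exchange_round_trip(self, go_model, hairpin16):
        ladder = protocol.HairpinStudy().ladder()
        starts = [hairpin16] * len(ladder)
        result = remd_run(go_model, ladder, starts, n_sweeps=2000, exchange_interval=50, seed=1)
        assert result.slot_energies.shape[0] == len(ladder)
        rates = acceptance_stats(result)["rate"]
        assert (rates > 0).all()  # neighbouring slots overlap
        traj = result.slot_trajectory(0, go_model)
        assert len(traj) == len(result.record_sweeps)


def _synthetic_result(n_slots, records=None, walker_path=None, energies=None):
    """Minimal hand-built REMDResult for diagnostics tests."""
    if walker_path is not None:
        n_rec = len(walker_path)
        walker_slots = np.zeros((n_rec, n_slots), dtype=int)
        for k, slot in enumerate(walker_path):
            walker_slots[k, 0] = slot
            others = [s for s in range(n_slots) if s != slot]
            for w, s in zip(range(1, n_slots), others):
                walker_slots[k, w] = s
    else:
        n_rec = len(energies[0]) if energies else 5
        walker_slots = np.tile(np.arange(n_slots), (n_rec, 1))
    if energies is None:
        energies = [[float(s)] * n_rec for s in range(n_slots)]
    return remd.REMDResult(
        temperatures=np.linspace(300.0, 400.0, n_slots),
        record_sweeps=np.arange(1, n_rec + 1),
        slot_states=[[0] * n_rec for _ in range(n_slots)],
        slot_energies=np.array(energies, dtype=float),
        walker_slots=walker_slots,
        exchange_records=records or [],
    ).validate()
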