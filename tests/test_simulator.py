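"""Kinetic Monte Carlo simulator: distributional oracles and invariants."""

import numpy as np
import pytest
from scipy import stats

from helpers import ensemble_net_rates, recompute_concentration
from peptube.errors import ConfigError, ModeError
from peptube.kinetics import FF_KINETICS, critical_concentration
from peptube.simulator import (
    ATTACH,
    CAP,
    DETACH,
    END_N,
    END_O,
    BathConfig,
    EndKinetics,
    FilamentConfig,
    concentration_time_stats,
    cycloff_filament,
    equilibrium_concentration,
    ff_filament,
    read_trace,
    simulate,
    turnover_summary,
    write_trace,
)


def symmetric_filament(k_on, k_off, layer_um=0.01, L0=50.0):
    e = EndKinetics(k_on, k_off)
    return FilamentConfig(end_O=e, end_N=e, layer_um=layer_um, initial_length_um=L0)


class TestDeterminism:
    def test_same_seed_reproduces_trace(self):
        fil = ff_filament(initial_length_um=20.0)
        bath = BathConfig("open", 2.5, 5.0, seed=99)
        a, b = simulate(fil, bath), simulate(fil, bath)
        np.testing.assert_array_equal(a.times, b.times)
        np.testing.assert_array_equal(a.ends, b.ends)
        np.testing.assert_array_equal(a.etypes, b.etypes)
        np.testing.assert_array_equal(a.pos_A, b.pos_A)
        assert a.status == b.status and a.t_final == b.t_final

    def test_closed_mode_same_seed_reproduces_trace(self):
        fil = symmetric_filament(1.0, 2.0)
        bath = BathConfig("closed", 3.0, 5.0, seed=5)
        a, b = simulate(fil, bath), simulate(fil, bath)
        np.testing.assert_array_equal(a.times, b.times)
        np.testing.assert_array_equal(a.conc, b.conc)

    def test_different_seeds_differ(self):
        fil = ff_filament(initial_length_um=20.0)
        a = simulate(fil, BathConfig("open", 2.5, 5.0, seed=1))
        b = simulate(fil, BathConfig("open", 2.5, 5.0, seed=2))
        assert a.n_events != b.n_events or not np.array_equal(a.times, b.times)


class TestPoissonOracles:
    def test_growth_only_rate_matches_superposed_poisson(self):
        """With k_off = 0 each end is a pure Poisson attachment process, so
        the ensemble mean growth rate is (k_on_O + k_on_N) * c."""
        fil = FilamentConfig(
            end_O=EndKinetics(k_on=2.0),
            end_N=EndKinetics(k_on=0.5),
            layer_um=0.01,
            initial_length_um=1.0,
        )
        c = 1.5
        rates = ensemble_net_rates(fil, c, n_seeds=100, t_max=5.0, seed_base=300)
        expected = (2.0 + 0.5) * c
        sem = rates.std(ddof=1) / np.sqrt(rates.size)
        assert abs(rates.mean() - expected) < 3 * sem

    def test_balanced_ends_at_critical_concentration_do_not_drift(self):
        fil = symmetric_filament(2.0, 3.0, L0=100.0)
        rates = ensemble_net_rates(fil, 1.5, n_seeds=100, t_max=5.0, seed_base=400)
        sem = rates.std(ddof=1) / np.sqrt(rates.size)
        assert abs(rates.mean()) < 3 * sem

    def test_waiting_times_are_exponential(self):
        """Detach-only filament: inter-event times follow Exp(k_off/layer)."""
        fil = FilamentConfig(
            end_O=EndKinetics(k_off=5.0),
            end_N=EndKinetics(),
            layer_um=0.01,
            initial_length_um=50.0,
        )
        tr = simulate(fil, BathConfig("open", 0.0, 4.0, seed=7))
        waits = np.diff(np.concatenate(([0.0], tr.times)))
        res = stats.kstest(waits, "expon", args=(0, 0.01 / 5.0))
        assert res.pvalue > 0.01

    def test_layer_refinement_leaves_mean_rate_unchanged(self):
        c, t_max, n = 3.2, 5.0, 100
        r_coarse = ensemble_net_rates(
            ff_filament(layer_um=0.02, initial_length_um=100.0), c, n, t_max, 500
        )
        r_fine = ensemble_net_rates(
            ff_filament(layer_um=0.01, initial_length_um=100.0), c, n, t_max, 900
        )
        sem = np.hypot(
            r_coarse.std(ddof=1) / np.sqrt(n), r_fine.std(ddof=1) / np.sqrt(n)
        )
        assert abs(r_coarse.mean() - r_fine.mean()) < 3 * sem


class TestAbsorbingStates:
    def test_subcritical_open_run_fully_dissolves(self):
        fil = FilamentConfig(
            end_O=EndKinetics(k_off=5.0),
            end_N=EndKinetics(),
            layer_um=0.01,
            initial_length_um=2.0,
        )
        tr = simulate(fil, BathConfig("open", 0.0, 60.0, seed=3))
        assert tr.status == "fully_dissolved"
        assert tr.length_um[-1] == pytest.approx(0.0)
        assert tr.counts(etype=DETACH) == fil.initial_layers
        assert tr.t_final < 60.0
        assert tr.times[-1] == tr.t_final  # nothing after dissolution

    def test_capping_absorbs_both_ends(self):
        fil = FilamentConfig(
            end_O=EndKinetics(3.36, 7.4, cap_rate=2.0),
            end_N=EndKinetics(1.0, 1.0, cap_rate=2.0),
            layer_um=0.01,
            initial_length_um=50.0,
        )
        tr = simulate(fil, BathConfig("open", 3.0, 500.0, seed=21))
        assert tr.status == "both_capped"
        assert tr.counts(etype=CAP) == 2
        cap_times = tr.times[tr.etypes == CAP]
        assert tr.t_final == pytest.approx(cap_times.max())
        # no attach/detach at an end after its cap
        for end in (END_N, END_O):
            t_cap = tr.times[(tr.etypes == CAP) & (tr.ends == end)][0]
            later = (tr.times > t_cap) & (tr.ends == end)
            assert not np.any(later)

    def test_length_never_negative(self):
        fil = symmetric_filament(0.5, 4.0, L0=1.0)
        for seed in range(5):
            tr = simulate(fil, BathConfig("open", 0.5, 30.0, seed=seed))
            if tr.n_events:
                assert tr.length_um.min() >= -1e-12

    def test_zero_rate_end_never_fires(self):
        fil = ff_filament(initial_length_um=20.0)  # N face silent
        tr = simulate(fil, BathConfig("open", 3.0, 5.0, seed=8))
        assert tr.counts(end=END_N) == 0
        summ = turnover_summary(tr)
        assert summ.end_N.n_attach == summ.end_N.n_detach == 0


class TestClosedPool:
    def test_mass_conservation_is_exact(self):
        fil = symmetric_filament(2.0, 3.0, L0=10.0)
        tr = simulate(fil, BathConfig("closed", 2.5, 10.0, seed=13))
        np.testing.assert_allclose(
            tr.conc, recompute_concentration(tr), rtol=0, atol=1e-12
        )

    def test_full_dissolution_returns_all_mass(self):
        fil = symmetric_filament(1.0, 5.0, layer_um=0.01, L0=1.0)
        gamma = 1e-4
        bath = BathConfig("closed", 0.5, 1000.0, seed=4, depletion_quantum_mM=gamma)
        tr = simulate(fil, bath)
        assert tr.status == "fully_dissolved"
        expected = 0.5 + gamma * fil.initial_layers
        assert tr.conc[-1] == pytest.approx(expected, abs=1e-12)

    def test_equilibrium_independent_of_face_speed(self):
        """Faces with equal k_off/k_on ratios but 10x different magnitudes
        share the fixed point c = k_off/k_on."""
        slowfast = FilamentConfig(
            end_O=EndKinetics(2.0, 3.0),
            end_N=EndKinetics(0.2, 0.3),
            layer_um=0.01,
            initial_length_um=10.0,
        )
        tr = simulate(slowfast, BathConfig("closed", 2.5, 300.0, seed=17))
        eq = equilibrium_concentration(tr, tail_fraction=0.25)
        _, sd = concentration_time_stats(tr, 0.75 * tr.t_final, tr.t_final)
        assert eq == pytest.approx(1.5, abs=5 * max(sd, 1e-3))

    def test_equilibrium_requires_closed_mode(self):
        tr = simulate(ff_filament(), BathConfig("open", 2.5, 1.0, seed=1))
        with pytest.raises(ModeError):
            equilibrium_concentration(tr)
        with pytest.raises(ConfigError):
            equilibrium_concentration(
                simulate(ff_filament(), BathConfig("closed", 2.5, 1.0, seed=1)),
                tail_fraction=0.0,
            )


class TestTurnoverAndWindows:
    def test_empty_window_rejected(self):
        tr = simulate(ff_filament(), BathConfig("open", 2.5, 2.0, seed=1))
        with pytest.raises(ConfigError):
            turnover_summary(tr, (1.0, 1.0))
        with pytest.raises(ConfigError):
            turnover_summary(tr, (0.0, 100.0))

    def test_counts_match_recorded_events(self):
        tr = simulate(
            cycloff_filament(initial_length_um=30.0),
            BathConfig("open", 10.0, 20.0, seed=2),
        )
        summ = turnover_summary(tr)
        assert summ.end_O.n_attach == tr.counts(end=END_O, etype=ATTACH)
        assert summ.end_N.n_detach == tr.counts(end=END_N, etype=DETACH)
        net = (
            summ.end_O.n_attach
            - summ.end_O.n_detach
            + summ.end_N.n_attach
            - summ.end_N.n_detach
        )
        assert tr.length_um[-1] - (tr.pos_B0 - tr.pos_A0) == pytest.approx(
            net * tr.filament.layer_um
        )


class TestConfigValidation:
    def test_bad_configs_rejected(self):
        with pytest.raises(ConfigError):
            FilamentConfig(EndKinetics(), EndKinetics(), layer_um=0.0)
        with pytest.raises(ConfigError):
            EndKinetics(k_on=-1.0)
        with pytest.raises(ConfigError):
            BathConfig("open", -1.0, 1.0, seed=0)
        with pytest.raises(ConfigError):
            BathConfig("closed", 1.0, 1.0, seed=0, depletion_quantum_mM=0.0)
        with pytest.raises(ConfigError):
            BathConfig("weird", 1.0, 1.0, seed=0)


class TestTraceIO:
    def test_round_trip(self, tmp_path):
        tr = simulate(
            ff_filament(initial_length_um=20.0), BathConfig("open", 2.8, 2.0, seed=6)
        )
        path = tmp_path / "trace.csv"
        write_trace(tr, path)
        back = read_trace(path)
        np.testing.assert_allclose(back.times, tr.times)
        np.testing.assert_array_equal(back.ends, tr.ends)
        np.testing.assert_array_equal(back.etypes, tr.etypes)
        np.testing.assert_allclose(back.pos_A, tr.pos_A)
        np.testing.assert_allclose(back.pos_B, tr.pos_B)
        assert back.status == tr.status
        assert back.filament == tr.filament
        assert back.bath == tr.bath
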