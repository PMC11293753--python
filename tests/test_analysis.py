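import numpy as np
import pandas as pd
import pytest

import edmcontrol as ec
from edmcontrol.errors import ConfigurationError
from edmcontrol.scans import CoefficientSeries


def _counts_table(active, population=1200):
    active = np.asarray(active, dtype=float)
    n = len(active)
    return ec.table_from_columns({
        "Quiet": population - active, "Active": active,
        "Jailed": np.zeros(n),
        "Legitimacy": np.full(n, 0.8), "Propaganda": np.full(n, 0.1),
    })


class TestEpisodes:
    def test_flat_series_has_no_episodes(self):
        ep = ec.detect_episodes(_counts_table(np.zeros(300)))
        assert ep.n_episodes == 0

    def test_rectangular_pulse_is_one_episode(self):
        active = np.zeros(200)
        active[50:80] = 120
        ep = ec.detect_episodes(_counts_table(active))
        assert ep.n_episodes == 1
        row = ep.episodes.iloc[0]
        assert (row.start, row.end, row.peak) == (51, 80, 120.0)

    def test_nearby_runs_merge_and_waits_are_start_to_start(self):
        active = np.zeros(400)
        active[50:60] = 100
        active[65:75] = 100   # closer than min_gap: same episode
        active[200:210] = 100
        ep = ec.detect_episodes(_counts_table(active), min_gap=20)
        assert ep.n_episodes == 2
        assert ep.waiting_times.tolist() == [150]

    def test_segmentation_invariant_to_appended_quiet_steps(self):
        active = np.zeros(300)
        active[100:130] = 90
        base = ec.detect_episodes(_counts_table(active))
        extended = ec.detect_episodes(
            _counts_table(np.concatenate([active, np.zeros(100)])))
        assert base.episodes.equals(extended.episodes)


class TestTrappedState:
    def test_constructed_plateau_trips_detector(self):
        table = _counts_table(np.full(300, 600))
        assert ec.detect_trapped_state(table) == (True, 1)

    def test_short_plateau_does_not(self):
        active = np.zeros(400)
        active[100:250] = 600  # 150 < 200 consecutive steps
        assert ec.detect_trapped_state(_counts_table(active))[0] is False

    def test_threshold_is_a_fraction_of_population(self):
        table = _counts_table(np.full(250, 299))  # 299/1200 < 0.25
        assert ec.detect_trapped_state(table)[0] is False
        table = _counts_table(np.full(250, 305))
        assert ec.detect_trapped_state(table)[0] is True


class TestSkillProtocol:
    @staticmethod
    def _predictable_table(n=800, seed=0):
        """Active is an exact linear readout of lagged Quiet/Jailed, so
        the s-map protocol must reach perfect correlation."""
        rng = np.random.default_rng(seed)
        quiet = 700 + 100 * np.sin(np.arange(n) / 7) + rng.normal(0, 5, n)
        jailed = 200 + 80 * np.cos(np.arange(n) / 11)
        # A(t) = 0.5 Q(t-5) - 0.3 J(t-5), i.e. the target 5 steps ahead
        # is an exact linear readout of the present state vector
        active = np.roll(0.5 * quiet - 0.3 * jailed, 5)
        return ec.table_from_columns({
            "Quiet": quiet, "Active": active, "Jailed": jailed,
            "Legitimacy": np.full(n, 0.8),
            "Propaganda": np.full(n, 0.1)})

    def test_perfectly_predictable_table_gives_rho_one(self):
        table = self._predictable_table()
        res = ec.skill_protocol(table, split_train=(1, 400),
                                split_test=(451, 790), theta=0.0)
        assert res.skill == pytest.approx(1.0, abs=1e-6)

    def test_shuffled_target_has_no_skill(self):
        table = self._predictable_table()
        rng = np.random.default_rng(1)
        frame = table.frame.copy()
        frame["Active"] = rng.permutation(frame["Active"].to_numpy())
        shuffled = ec.TimeSeriesTable(frame.reset_index())
        res = ec.skill_protocol(shuffled, split_train=(1, 400),
                                split_test=(451, 790), theta=0.0)
        assert abs(res.skill) < 0.2

    def test_overlapping_splits_rejected(self, benchmark_table):
        with pytest.raises(ConfigurationError):
            ec.skill_protocol(benchmark_table, split_train=(1, 1700),
                              split_test=(1601, 3100))

    def test_library_never_reads_test_rows(self, benchmark_table):
        """Poisoning the test range must leave the training library
        byte-identical."""
        spec = ec.default_embedding(Tp=5)
        frame = benchmark_table.frame.copy()
        frame.iloc[1600:, frame.columns.get_loc("Active")] += 1e6
        frame.iloc[1600:, frame.columns.get_loc("Quiet")] -= 1e6
        poisoned = ec.TimeSeriesTable(frame.reset_index())
        build = lambda t: ec.embed(t.rows(1, 1500), spec)
        a, b = build(benchmark_table), build(poisoned)
        np.testing.assert_array_equal(a.rows, b.rows)
        np.testing.assert_array_equal(a.target_futures, b.target_futures)


class TestJacobianVarianceByRegime:
    @staticmethod
    def _coeffs(values):
        frame = pd.DataFrame({"Propaganda(t-0)": values},
                             index=pd.Index(range(len(values)),
                                            name="time"))
        return CoefficientSeries(frame=frame, unreliable={})

    def test_constant_coefficients_have_zero_variance(self):
        cs = self._coeffs(np.full(500, 1.3))
        leg = np.where(np.arange(500) < 250, 0.65, 0.8)
        rv = ec.jacobian_variance_by_regime(cs, leg, window=50, stride=10)
        assert np.allclose(rv.low_variances, 0)
        assert np.allclose(rv.high_variances, 0)

    def test_three_fold_noise_gives_nine_fold_variance(self):
        rng = np.random.default_rng(2)
        n = 4000
        leg = np.where(np.arange(n) < n // 2, 0.62, 0.82)
        noise = np.where(leg < 0.7, 3.0, 1.0) * rng.standard_normal(n)
        rv = ec.jacobian_variance_by_regime(self._coeffs(noise), leg,
                                            window=100, stride=10)
        ratio = np.median(rv.low_variances) / np.median(rv.high_variances)
        assert ratio == pytest.approx(9.0, rel=0.35)
        stat, p = rv.rank_test()
        assert p < 1e-6

    def test_threshold_tie_goes_to_high_regime(self):
        cs = self._coeffs(np.arange(200.0))
        rv = ec.jacobian_variance_by_regime(cs, np.full(200, 0.7),
                                            window=50, stride=25)
        assert rv.low_variances.size == 0
        assert rv.high_variances.size > 0

    def test_every_window_in_exactly_one_regime(self):
        rng = np.random.default_rng(3)
        leg = rng.uniform(0.6, 0.85, 1000)
        rv = ec.jacobian_variance_by_regime(
            self._coeffs(rng.standard_normal(1000)), leg,
            window=100, stride=50)
        n_windows = len(range(0, 1000 - 100 + 1, 50))
        assert rv.low_variances.size + rv.high_variances.size == n_windows

    def test_window_longer_than_series_rejected(self):
        with pytest.raises(ConfigurationError):
            ec.jacobian_variance_by_regime(
                self._coeffs(np.zeros(50)), np.full(50, 0.8), window=100)
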