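"""Interval and outcome decoding, permutation statistics, McNemar."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from seqtrack import decode
from seqtrack._seeding import substream
from seqtrack.behavior import SequenceTrial
from seqtrack.decode import (
    DecodeConfig,
    InsufficientTrialsError,
    best_interval_assignment,
    boxcox_features,
    build_interval_features,
    decode_intervals_ensemble,
    decode_intervals_single_unit,
    decode_outcome,
    exclude_sparse_units,
    interval_shuffle_null,
    mcnemar_chi2,
    permutation_p,
    summarize_ensemble_runs,
)

FAST = DecodeConfig(single_unit_repeats=5, outcome_repeats=20)


def _trial(press_times, pe=None):
    press_times = np.asarray(press_times, float)
    return SequenceTrial(
        press_times=press_times,
        port_entry_time=pe if pe is not None else press_times[-1] + 1.0,
        rewarded=True, complete=True, lp1_latency=1.0,
    )


def _step_tables(n_units_per_interval=1, n_trials=26, K=5, rate=10.0):
    """Noiseless units each firing only in its own interval: perfectly separable."""
    tables = {}
    for k in range(K):
        for j in range(n_units_per_interval):
            tab = np.zeros((n_trials, K))
            tab[:, k] = rate
            tables[f"u{k}_{j}"] = tab
    return tables


class TestFeatures:
    def test_interval_rates_from_spikes(self):
        trials = [_trial(np.linspace(0, 10, 6))] * 26
        table = build_interval_features(trials, np.array([3.0]), 5, 26)
        assert table.shape == (26, 5)
        np.testing.assert_allclose(table[:, 1], 0.5)  # 1 spike / 2 s in interval 2
        assert table[:, [0, 2, 3, 4]].sum() == 0

    def test_no_spikes_zero_row(self):
        table = build_interval_features([_trial(np.linspace(0, 10, 6))] * 26, np.array([]), 5, 26)
        assert not table.any()

    def test_insufficient_trials(self):
        with pytest.raises(InsufficientTrialsError):
            build_interval_features([_trial(np.linspace(0, 10, 6))] * 20, np.array([]), 5, 26)

    def test_constant_rate_expectation(self):
        rng = np.random.default_rng(0)
        trials = [_trial(np.linspace(0, 10, 6))] * 26
        spikes = np.sort(rng.uniform(0, 10, rng.poisson(10.0 * 10 * 50)))  # 50x overlay
        table = build_interval_features(trials, spikes, 5, 26) / 50
        np.testing.assert_allclose(table.mean(axis=0), 10.0, atol=0.5)

    def test_sparse_exclusion_threshold(self):
        keep = np.ones((26, 5))
        keep[:18] = 0.0  # ~69% zeros: kept
        drop = np.zeros((26, 5))
        drop[:2] = 1.0  # ~92% zeros: dropped
        kept, dropped = exclude_sparse_units({"keep": keep, "drop": drop, "zero": np.zeros((26, 5))})
        assert set(kept) == {"keep"} and set(dropped) == {"drop", "zero"}

    def test_sparse_poisson_unit_dropped(self):
        """A 0.05 Hz unit over ~1 s intervals is zero in ~95% of cells."""
        rng = np.random.default_rng(1)
        tab = rng.poisson(0.05, size=(26, 5)).astype(float)
        kept, dropped = exclude_sparse_units({"sparse": tab})
        assert dropped == ["sparse"]


class TestBoxCox:
    def test_normal_data_near_affine(self):
        rng = np.random.default_rng(2)
        x = rng.normal(50.0, 2.0, size=(500, 1))  # ML lambda ~ 1
        xt, info = boxcox_features(x)
        assert abs(np.corrcoef(x[:, 0], xt[:, 0])[0, 1]) > 0.999
        assert not info["constant"].any()

    def test_lognormal_symmetrized(self):
        rng = np.random.default_rng(3)
        x = rng.lognormal(0.0, 0.5, size=(1000, 1))
        xt, info = boxcox_features(x)
        assert abs(stats.skew(xt[:, 0])) < 0.2
        assert info.loc[0, "lmbda"] == pytest.approx(0.0, abs=0.15)

    def test_zero_offset_and_constant_flag(self):
        x = np.column_stack([np.array([0.0, 1.0, 2.0, 4.0]), np.full(4, 3.0)])
        xt, info = boxcox_features(x)
        assert info.loc[0, "offset"] == pytest.approx(0.5)
        assert info.loc[1, "constant"] and np.all(xt[:, 1] == 3.0)


class TestIntervalDecoding:
    def test_separable_ensemble_perfect(self):
        runs = decode_intervals_ensemble(
            _step_tables(), FAST, substream(0, "a"), ensemble_sizes=[5], draws_per_size=1
        )
        res = runs[0].result
        np.testing.assert_allclose(res.per_class_accuracy, 1.0)
        assert res.overall_accuracy == 1.0
        np.testing.assert_allclose(res.confusion.sum(axis=1), 1.0)

    def test_random_forest_mirrors_contract(self):
        cfg = DecodeConfig(classifier="random_forest", rf_ntree=25, boxcox=False)
        runs = decode_intervals_ensemble(
            _step_tables(), cfg, substream(0, "rf"), ensemble_sizes=[5], draws_per_size=1
        )
        assert runs[0].result.overall_accuracy == 1.0

    def test_oversized_ensemble_rejected(self):
        with pytest.raises(ValueError):
            decode_intervals_ensemble(
                _step_tables(), FAST, substream(0, "b"), ensemble_sizes=[6], draws_per_size=1
            )

    def test_shuffle_null_centers_at_chance(self, interval_tables):
        rng = substream(1, "null")
        ids = rng.choice(sorted(interval_tables), 10, replace=False)
        cube = decode.assemble_pseudo_ensemble(interval_tables, ids, rng)
        overall, per_class = interval_shuffle_null(cube, FAST, rng, n_shuffles=30)
        assert np.mean(overall) == pytest.approx(0.2, abs=0.05)
        assert per_class.shape == (30, 5)

    def test_fold_partition_disjoint_exhaustive(self):
        groups = np.repeat(np.arange(26), 5)
        folds = decode._leave_one_trial_folds(groups)
        assert len(folds) == 26
        allidx = np.sort(np.concatenate(folds))
        np.testing.assert_array_equal(allidx, np.arange(26 * 5))
        for i, f in enumerate(folds):
            for g in folds[i + 1 :]:
                assert not set(f) & set(g)

    def test_confusion_gradient_on_ramps(self, interval_tables, experiment):
        """Misclassification follows the ramp: P(predicted first) falls and
        P(predicted last) rises with the true interval index."""
        ramp_ids = [
            u for u in interval_tables
            if experiment.unit_manifest.loc[u, "profile"] in ("ramp_up", "ramp_down")
        ]
        rng = substream(2, "conf")
        ids = rng.choice(ramp_ids, 50, replace=False)
        cube = decode.assemble_pseudo_ensemble(interval_tables, ids, rng)
        res = decode._run_interval_cv(cube, DecodeConfig(), rng)
        truth = np.arange(5)
        assert stats.spearmanr(res.confusion[:, 0], truth).statistic < 0
        assert stats.spearmanr(res.confusion[:, 4], truth).statistic > 0

    def test_ensemble_beats_mean_single_unit(self, interval_tables):
        """Pooling units never loses information relative to the average unit."""
        rng = substream(3, "vs")
        ids = sorted(rng.choice(sorted(interval_tables), 15, replace=False))
        cube = decode.assemble_pseudo_ensemble(interval_tables, ids, rng)
        ens = decode._run_interval_cv(cube, DecodeConfig(), rng).overall_accuracy
        singles = [
            decode_intervals_single_unit(interval_tables[u], FAST, substream(3, "su", u)).mean()
            for u in ids
        ]
        assert ens >= np.mean(singles)


class TestSingleUnit:
    def test_flat_unit_at_chance(self):
        rng = np.random.default_rng(4)
        table = rng.poisson(8.0, size=(40, 5)).astype(float)
        acc = decode_intervals_single_unit(table, FAST, substream(4, "flat"))
        assert acc.mean() == pytest.approx(0.2, abs=0.07)

    def test_ramp_unit_ends_beat_middle(self):
        rng = np.random.default_rng(5)
        means = np.array([2.0, 6.0, 10.0, 14.0, 18.0])
        table = rng.poisson(means * 2, size=(40, 5)).astype(float) / 2
        acc = decode_intervals_single_unit(table, FAST, substream(5, "ramp"))
        assert min(acc[0], acc[4]) > max(acc[1:4])


class TestBestInterval:
    def test_explicit_assignments(self):
        accs = pd.DataFrame(
            [[0.6, 0.2, 0.2, 0.2, 0.2], [0.2, 0.2, 0.2, 0.2, 0.2], [0.5, 0.2, 0.5, 0.2, 0.2]],
            index=["first_only", "never", "tie"],
        )
        null = np.full((200, 5), 0.2) + np.linspace(0, 0.1, 200)[:, None]
        out = best_interval_assignment(accs, null, alpha=0.01)
        assert out.loc["first_only", "best_interval"] == 0
        assert np.isnan(out.loc["never", "best_interval"])
        assert out.loc["tie", "best_interval"] == 0  # earliest wins on ties

    def test_planted_tuning_recovered(self):
        """Units with an elevated rate in one planted interval are assigned to it."""
        rng = np.random.default_rng(6)
        planted = rng.integers(0, 5, size=40)
        tables = {}
        for i, k in enumerate(planted):
            means = np.full(5, 4.0)
            means[k] *= 3.0
            tables[f"u{i:02d}"] = rng.poisson(means, size=(30, 5)).astype(float)
        cfg = DecodeConfig(single_unit_repeats=5)
        accs = pd.DataFrame(
            [decode_intervals_single_unit(tables[u], cfg, substream(6, "su", u)) for u in sorted(tables)],
            index=sorted(tables),
        )
        shuffled = np.vstack(
            [
                decode_intervals_single_unit(
                    tables[u], cfg, substream(6, "sh", u), shuffle=True
                )
                for u in sorted(tables)
            ]
        )
        out = best_interval_assignment(accs, shuffled, alpha=0.01)
        best = out["best_interval"].to_numpy()
        assigned = ~np.isnan(best)
        assert assigned.mean() >= 0.8
        assert (best[assigned] == planted[assigned]).mean() >= 0.8


class TestOutcomeDecoding:
    def test_reward_responders_perfect(self):
        rng = np.random.default_rng(7)
        tables = {
            f"u{i}": (rng.uniform(5, 10, 15), np.zeros(15)) for i in range(5)
        }
        res = decode_outcome(tables, "reward", FAST, substream(7, "o"))
        assert res.mean_accuracy == 1.0

    def test_label_independent_near_chance(self):
        rng = np.random.default_rng(8)
        tables = {f"u{i}": (rng.poisson(5.0, 15).astype(float), rng.poisson(5.0, 15).astype(float)) for i in range(12)}
        res = decode_outcome(tables, "lever_approach", FAST, substream(8, "o"))
        assert 0.35 < res.mean_accuracy < 0.65

    def test_all_zero_unit_dropped(self):
        rng = np.random.default_rng(9)
        tables = {
            "good": (rng.uniform(5, 10, 12), rng.uniform(0, 2, 12)),
            "silent": (np.zeros(12), np.zeros(12)),
        }
        res = decode_outcome(tables, "reward", FAST, substream(9, "o"))
        assert res.dropped_units == ["silent"]

    def test_attenuated_port_approach_above_null(self):
        """With motivational gain g=0.7 on incomplete trials, port-approach
        activity decodes outcome above the shuffle null's 95th percentile."""
        from seqtrack import synth

        bcfg = synth.BehaviorGenConfig(n_trials=80, p_complete=0.6, seed=21)
        ucfg = synth.UnitGenConfig(n_units=25, attenuation=0.7, seed=21)
        exp = synth.simulate_experiment(bcfg, ucfg)
        trials = [t for t in exp.trials if t.valid]
        comp = [t for t in trials if t.complete]
        inc = [t for t in trials if not t.complete]
        tables = {
            u: (
                decode.build_epoch_features(s, comp, "port_approach"),
                decode.build_epoch_features(s, inc, "port_approach"),
            )
            for u, s in exp.spikes.items()
        }
        res = decode_outcome(tables, "port_approach", FAST, substream(21, "pa"))
        null = decode_outcome(tables, "port_approach", FAST, substream(21, "pa0"), shuffle=True)
        assert res.mean_accuracy > np.quantile(null.accuracies, 0.95)

    def test_insufficient_trials_raise(self):
        with pytest.raises(InsufficientTrialsError):
            decode_outcome({"u": (np.ones(5), np.ones(12))}, "reward", FAST, substream(9, "x"))


class TestStatistics:
    def test_permutation_p_examples(self):
        null = np.linspace(0, 0.998, 999)
        assert permutation_p(1.0, null) == pytest.approx(1 / 1000)
        assert permutation_p(float(np.median(null)), null) == pytest.approx(0.5, abs=0.01)
        assert 0 < permutation_p(-1.0, null) <= 1.0

    def test_permutation_p_uniform_under_null(self):
        """When the observation comes from the null, p is ~Uniform(0,1)."""
        rng = np.random.default_rng(10)
        ps = [
            permutation_p(rng.random(), rng.random(199)) for _ in range(500)
        ]
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_mcnemar_closed_form(self):
        assert mcnemar_chi2(10, 2) == pytest.approx(64 / 12)
        assert mcnemar_chi2(7, 7) == 0.0
        assert mcnemar_chi2(10, 2) == mcnemar_chi2(2, 10)
        assert mcnemar_chi2(10, 2, continuity_correction=True) == pytest.approx(49 / 12)
        with pytest.raises(ValueError):
            mcnemar_chi2(0, 0)

    def test_summarize_runs_table(self):
        runs = decode_intervals_ensemble(
            _step_tables(), FAST, substream(11, "s"), ensemble_sizes=[5], draws_per_size=2
        )
        df = summarize_ensemble_runs(runs)
        assert len(df) == 2
        assert set(df.columns) >= {"ensemble_size", "overall_accuracy", "acc_interval_1"}
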