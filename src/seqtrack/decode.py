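"""Decoding sequence progress and trial outcome from firing rates.

Interval decoding: each complete trial's press sequence is cut into K equal
consecutive relative-time intervals (K in {3, 5, 7}); the rate of every unit
in every interval forms the feature table.  A linear discriminant model
(or a random forest) is trained to predict the interval position, with
leave-one-trial-out cross-validation over 26 trials per unit.  Units
recorded in different sessions are pooled into pseudo-ensembles by randomly
pairing their trials.  Chance level is estimated by re-running the analysis
with shuffled interval labels; significance uses a one-sided permutation
p-value.

Outcome decoding: scalar mean rates per unit in a fixed task epoch (lever
approach, post-LP1, pre-LLP, port approach, reward) are used to classify
trials as complete or incomplete (10 + 10 trials, 10-fold CV, repeated over
trial re-draws).

Box-Cox normalization (maximum-likelihood lambda per feature) is applied to
the predictors before the discriminant fit; zero rates are offset by half
the smallest positive rate of that feature.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.covariance import LedoitWolf
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

EPOCHS = ("lever_approach", "post_lp1", "pre_llp", "port_approach", "reward")


class InsufficientTrialsError(ValueError):
    """Raised when a unit's session has too few eligible trials."""


@dataclass(frozen=True)
class DecodeConfig:
    """Parameters of the decoding analyses."""

    n_intervals: int = 5  # K
    n_trials: int = 26  # trials drawn per unit for interval decoding
    ensemble_sizes: tuple[int, ...] = (10, 50, 100, 500, 900)
    draws_per_size: int = 50
    single_unit_repeats: int = 20
    outcome_trials_per_class: int = 10
    outcome_cv_folds: int = 10
    outcome_repeats: int = 100
    classifier: str = "lda"  # or "random_forest"
    rf_ntree: int = 500
    n_shuffles: int = 1000
    boxcox: bool = True


DEFAULT_CONFIG = DecodeConfig()


@dataclass
class DecodeResult:
    """Accuracies and confusion fractions of one decoding run."""

    overall_accuracy: float
    per_class_accuracy: np.ndarray
    confusion: np.ndarray  # rows: true class, cols: predicted; rows sum to 1
    null_accuracies: np.ndarray | None = None
    p_value: float | None = None


# ---------------------------------------------------------------------------
# feature construction
# ---------------------------------------------------------------------------

def build_interval_features(
    trials: Sequence,
    spikes: np.ndarray,
    n_intervals: int = 5,
    n_trials: int = 26,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Per-trial firing rates (Hz) in K equal relative-time sequence intervals.

    ``n_trials`` trials are drawn uniformly without replacement (seeded via
    ``rng``); a session with fewer eligible trials raises
    :class:`InsufficientTrialsError` so the caller can exclude the unit.
    Returns an (n_trials, K) array.
    """
    trials = list(trials)
    if len(trials) < n_trials:
        raise InsufficientTrialsError(
            f"{len(trials)} eligible trials < required {n_trials}"
        )
    if len(trials) == n_trials:
        chosen = trials
    else:
        if rng is None:
            rng = np.random.default_rng()
        idx = rng.choice(len(trials), size=n_trials, replace=False)
        chosen = [trials[i] for i in idx]
    spikes = np.asarray(spikes, dtype=float)
    out = np.empty((n_trials, n_intervals))
    for i, tr in enumerate(chosen):
        edges = np.linspace(tr.t_first_press, tr.t_last_press, n_intervals + 1)
        counts, _ = np.histogram(
            spikes[(spikes >= edges[0]) & (spikes <= edges[-1])], bins=edges
        )
        out[i] = counts / np.diff(edges)
    return out


def exclude_sparse_units(
    tables: Mapping[str, np.ndarray], zero_fraction: float = 0.75
) -> tuple[dict[str, np.ndarray], list[str]]:
    """Drop units with null rates in more than ``zero_fraction`` of trial x interval cells."""
    kept, dropped = {}, []
    for uid, tab in tables.items():
        if np.mean(tab == 0) > zero_fraction:
            dropped.append(uid)
        else:
            kept[uid] = tab
    return kept, dropped


def boxcox_features(X: np.ndarray) -> tuple[np.ndarray, pd.DataFrame]:
    """Box-Cox transform each feature column with its maximum-likelihood lambda.

    The transform requires positive inputs: any column containing zeros is
    offset by half its smallest positive value first.  Constant columns are
    left untransformed and flagged.  Returns the transformed matrix and a
    per-feature info table (lambda, offset, flag).
    """
    X = np.asarray(X, dtype=float)
    out = X.copy()
    info = []
    for j in range(X.shape[1]):
        col = X[:, j]
        if np.ptp(col) == 0:
            info.append({"lmbda": np.nan, "offset": 0.0, "constant": True})
            continue
        offset = 0.0
        if col.min() <= 0:
            positive = col[col > 0]
            offset = positive.min() / 2.0
            col = col + offset
        transformed, lmbda = stats.boxcox(col)
        out[:, j] = transformed
        info.append({"lmbda": float(lmbda), "offset": offset, "constant": False})
    return out, pd.DataFrame(info)


def epoch_rate(spikes: np.ndarray, trial, epoch: str) -> float:
    """Mean firing rate (Hz) of one unit in one task epoch of one trial.

    Epochs: ``lever_approach`` [LP1-1s, LP1), ``post_lp1`` [LP1, LP1+0.5s),
    ``pre_llp`` [LLP-0.5s, LLP), ``port_approach`` [LLP, PE) (the full
    relative-time span, equivalent to the mean of the 25 warped bins), and
    ``reward`` [PE, PE+1s).
    """
    lp1, llp, pe = trial.t_first_press, trial.t_last_press, trial.port_entry_time
    windows = {
        "lever_approach": (lp1 - 1.0, lp1),
        "post_lp1": (lp1, lp1 + 0.5),
        "pre_llp": (llp - 0.5, llp),
        "port_approach": (llp, pe),
        "reward": (pe, pe + 1.0),
    }
    lo, hi = windows[epoch]
    if hi <= lo:
        raise ValueError(f"empty {epoch!r} window")
    spikes = np.asarray(spikes, dtype=float)
    n = int(np.count_nonzero((spikes >= lo) & (spikes < hi)))
    return n / (hi - lo)


def build_epoch_features(spikes: np.ndarray, trials: Sequence, epoch: str) -> np.ndarray:
    """Vector of epoch rates, one per trial."""
    return np.array([epoch_rate(spikes, tr, epoch) for tr in trials])


# ---------------------------------------------------------------------------
# classifiers and cross-validation
# ---------------------------------------------------------------------------

class _RidgedLedoitWolf(LedoitWolf):
    """Ledoit-Wolf covariance with a tiny ridge floor.

    The analytic shrinkage target is the scaled identity, which is itself the
    zero matrix when the within-class scatter is exactly zero (noiseless,
    perfectly separable features); the floor keeps the discriminant defined
    there while being negligible (1e-9 of the mean variance + 1) otherwise.
    """

    def fit(self, X, y=None):
        super().fit(X)
        d = self.covariance_.shape[0]
        floor = 1e-9 * (np.trace(self.covariance_) / d + 1.0)
        self.covariance_ = self.covariance_ + floor * np.eye(d)
        return self


def _make_classifier(config: DecodeConfig, rng: np.random.Generator):
    if config.classifier == "lda":
        # pooled within-class covariance with always-on analytic
        # (Ledoit-Wolf) shrinkage; required whenever p >= n per fold
        return LinearDiscriminantAnalysis(
            solver="lsqr", covariance_estimator=_RidgedLedoitWolf()
        )
    if config.classifier == "random_forest":
        return RandomForestClassifier(
            n_estimators=config.rf_ntree,
            max_features="sqrt",  # mtry = floor(sqrt(p))
            random_state=int(rng.integers(2**31)),
            n_jobs=1,
        )
    raise ValueError(f"unknown classifier {config.classifier!r}")


def _confusion_counts_cv(
    X: np.ndarray,
    y: np.ndarray,
    folds: Sequence[np.ndarray],
    clf_factory: Callable[[], object],
    n_classes: int,
) -> np.ndarray:
    counts = np.zeros((n_classes, n_classes))
    for test in folds:
        mask = np.zeros(len(y), dtype=bool)
        mask[test] = True
        clf = clf_factory()
        clf.fit(X[~mask], y[~mask])
        pred = clf.predict(X[mask])
        np.add.at(counts, (y[mask], pred), 1)
    return counts


def _result_from_counts(counts: np.ndarray) -> DecodeResult:
    row_tot = counts.sum(axis=1, keepdims=True)
    confusion = counts / row_tot
    per_class = np.diag(confusion)
    overall = counts.trace() / counts.sum()
    return DecodeResult(
        overall_accuracy=float(overall),
        per_class_accuracy=per_class,
        confusion=confusion,
    )


def _interval_samples(table3: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(trials, K, units) feature cube -> flat samples, labels, trial groups."""
    n_trials, K, _ = table3.shape
    X = table3.reshape(n_trials * K, -1)
    y = np.tile(np.arange(K), n_trials)
    groups = np.repeat(np.arange(n_trials), K)
    return X, y, groups


def _leave_one_trial_folds(groups: np.ndarray) -> list[np.ndarray]:
    return [np.flatnonzero(groups == g) for g in np.unique(groups)]


def _run_interval_cv(
    table3: np.ndarray,
    config: DecodeConfig,
    rng: np.random.Generator,
    *,
    shuffle: bool = False,
) -> DecodeResult:
    X, y, groups = _interval_samples(table3)
    if config.boxcox:
        X, _ = boxcox_features(X)
    if shuffle:
        y = rng.permutation(y)
    counts = _confusion_counts_cv(
        X, y, _leave_one_trial_folds(groups), lambda: _make_classifier(config, rng),
        config.n_intervals,
    )
    return _result_from_counts(counts)


# ---------------------------------------------------------------------------
# interval decoding
# ---------------------------------------------------------------------------

@dataclass
class EnsembleDecodeRun:
    ensemble_size: int
    draw: int
    shuffled: bool
    result: DecodeResult


def assemble_pseudo_ensemble(
    tables: Mapping[str, np.ndarray],
    unit_ids: Sequence[str],
    rng: np.random.Generator,
) -> np.ndarray:
    """Column-bind units after independently permuting each unit's trials.

    The random re-pairing of trials across separately recorded units
    destroys any spurious within-session trial correlation symmetrically.
    Returns a (trials, K, units) cube.
    """
    cols = []
    for uid in unit_ids:
        tab = tables[uid]
        cols.append(tab[rng.permutation(len(tab))])
    return np.stack(cols, axis=-1)


def decode_intervals_ensemble(
    tables: Mapping[str, np.ndarray],
    config: DecodeConfig = DEFAULT_CONFIG,
    rng: np.random.Generator | None = None,
    *,
    shuffle: bool = False,
    ensemble_sizes: Sequence[int] | None = None,
    draws_per_size: int | None = None,
) -> list[EnsembleDecodeRun]:
    """Cross-validated interval decoding on random pseudo-ensembles.

    For every ensemble size, ``draws_per_size`` random unit subsets are
    drawn; each draw is decoded with leave-one-trial-out CV.  With
    ``shuffle`` the interval labels are permuted per run (chance control).
    """
    if rng is None:
        rng = np.random.default_rng()
    sizes = tuple(ensemble_sizes if ensemble_sizes is not None else config.ensemble_sizes)
    draws = draws_per_size if draws_per_size is not None else config.draws_per_size
    all_ids = np.array(sorted(tables))
    runs = []
    for size in sizes:
        if size > len(all_ids):
            raise ValueError(f"ensemble size {size} exceeds available units ({len(all_ids)})")
        for d in range(draws):
            ids = rng.choice(all_ids, size=size, replace=False)
            cube = assemble_pseudo_ensemble(tables, ids, rng)
            res = _run_interval_cv(cube, config, rng, shuffle=shuffle)
            runs.append(EnsembleDecodeRun(size, d, shuffle, res))
    return runs


def interval_shuffle_null(
    cube: np.ndarray,
    config: DecodeConfig = DEFAULT_CONFIG,
    rng: np.random.Generator | None = None,
    n_shuffles: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Label-permutation null accuracies for one pseudo-ensemble.

    The Box-Cox transform does not depend on the labels, so the feature cube
    is transformed once and only the interval labels are re-permuted per
    shuffle run.  Returns (overall accuracies, per-interval accuracies) over
    ``n_shuffles`` runs.
    """
    if rng is None:
        rng = np.random.default_rng()
    n = n_shuffles if n_shuffles is not None else config.n_shuffles
    X, y, groups = _interval_samples(cube)
    if config.boxcox:
        X, _ = boxcox_features(X)
    folds = _leave_one_trial_folds(groups)
    overall = np.empty(n)
    per_class = np.empty((n, config.n_intervals))
    for i in range(n):
        yp = rng.permutation(y)
        counts = _confusion_counts_cv(
            X, yp, folds, lambda: _make_classifier(config, rng), config.n_intervals
        )
        res = _result_from_counts(counts)
        overall[i] = res.overall_accuracy
        per_class[i] = res.per_class_accuracy
    return overall, per_class


def summarize_ensemble_runs(runs: Sequence[EnsembleDecodeRun]) -> pd.DataFrame:
    """Per-run accuracies as a tidy table (one row per run)."""
    rows = []
    for r in runs:
        row = {
            "ensemble_size": r.ensemble_size,
            "draw": r.draw,
            "shuffled": r.shuffled,
            "overall_accuracy": r.result.overall_accuracy,
        }
        for k, a in enumerate(r.result.per_class_accuracy):
            row[f"acc_interval_{k + 1}"] = a
        rows.append(row)
    return pd.DataFrame(rows)


def decode_intervals_single_unit(
    table: np.ndarray,
    config: DecodeConfig = DEFAULT_CONFIG,
    rng: np.random.Generator | None = None,
    *,
    shuffle: bool = False,
) -> np.ndarray:
    """Per-interval accuracy of one unit, averaged over CV folds and trial re-draws.

    ``table`` holds all eligible trials (rows) x K intervals; each repeat
    draws ``config.n_trials`` rows, runs leave-one-trial-out CV on the
    scalar rate feature, and accuracies are averaged over
    ``config.single_unit_repeats`` repeats.
    """
    if rng is None:
        rng = np.random.default_rng()
    n_all = len(table)
    accs = np.zeros((config.single_unit_repeats, config.n_intervals))
    for r in range(config.single_unit_repeats):
        idx = (
            np.arange(n_all)
            if n_all == config.n_trials
            else rng.choice(n_all, size=config.n_trials, replace=False)
        )
        cube = table[idx][:, :, None]  # (trials, K, 1 feature)
        if shuffle:
            cube = _shuffle_intervals_within_trials(cube, rng)
        res = _run_interval_cv(cube, config, rng, shuffle=False)
        accs[r] = res.per_class_accuracy
    return accs.mean(axis=0)


def _shuffle_intervals_within_trials(cube: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Independently permute each trial's interval rates (null for tuning)."""
    out = cube.copy()
    n_trials, K, n_units = cube.shape
    for u in range(n_units):
        for t in range(n_trials):
            out[t, :, u] = cube[t, rng.permutation(K), u]
    return out


def best_interval_assignment(
    unit_accuracies: pd.DataFrame,
    shuffled_accuracies: np.ndarray,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Significant intervals and best-decoded interval per unit.

    ``unit_accuracies``: units x K per-interval accuracies.
    ``shuffled_accuracies``: pooled population accuracies after shuffling
    each unit's activity across intervals (rows: shuffled units, cols: K).
    An interval is significant when the unit's accuracy exceeds the
    (1 - alpha) quantile of the pooled shuffled accuracies for that
    interval; the best interval is the significant one with maximal
    accuracy, earliest on ties; units with no significant interval get
    ``best_interval = NaN``.
    """
    acc = unit_accuracies.to_numpy(dtype=float)
    thresholds = np.quantile(shuffled_accuracies, 1 - alpha, axis=0)
    sig = acc > thresholds[None, :]
    best = np.full(len(acc), np.nan)
    for i in range(len(acc)):
        if sig[i].any():
            masked = np.where(sig[i], acc[i], -np.inf)
            best[i] = int(np.argmax(masked))  # argmax takes the earliest on ties
    out = pd.DataFrame(
        sig, index=unit_accuracies.index,
        columns=[f"sig_interval_{k + 1}" for k in range(acc.shape[1])],
    )
    out["best_interval"] = best  # 0-based, NaN when never significant
    return out


# ---------------------------------------------------------------------------
# outcome decoding
# ---------------------------------------------------------------------------

@dataclass
class OutcomeDecodeResult:
    """Complete-vs-incomplete decoding accuracies for one epoch."""

    epoch: str
    accuracies: np.ndarray  # one per repeat
    mean_accuracy: float
    dropped_units: list[str]


def decode_outcome(
    tables: Mapping[str, tuple[np.ndarray, np.ndarray]],
    epoch: str,
    config: DecodeConfig = DEFAULT_CONFIG,
    rng: np.random.Generator | None = None,
    *,
    shuffle: bool = False,
) -> OutcomeDecodeResult:
    """Classify trials as complete (1) or incomplete (0) from epoch rates.

    ``tables`` maps unit id to a pair of rate vectors (complete trials,
    incomplete trials), each with at least
    ``config.outcome_trials_per_class`` entries.  Every repeat draws that
    many trials per class per unit (independent draws re-pair trials across
    units), applies Box-Cox, and runs stratified
    ``config.outcome_cv_folds``-fold CV.  Units whose rates are all zero in
    this epoch are dropped.  With ``shuffle`` the outcome labels are
    permuted per repeat.
    """
    if rng is None:
        rng = np.random.default_rng()
    n_per = config.outcome_trials_per_class
    kept, dropped = {}, []
    for uid, (rc, ri) in tables.items():
        if len(rc) < n_per or len(ri) < n_per:
            raise InsufficientTrialsError(f"unit {uid!r}: fewer than {n_per} trials per class")
        if np.all(rc == 0) and np.all(ri == 0):
            dropped.append(uid)
        else:
            kept[uid] = (np.asarray(rc, float), np.asarray(ri, float))
    if not kept:
        raise ValueError("no units with non-zero rates in this epoch")
    uids = sorted(kept)
    y_base = np.concatenate([np.ones(n_per, int), np.zeros(n_per, int)])
    accs = np.empty(config.outcome_repeats)
    for rep in range(config.outcome_repeats):
        cols = []
        for uid in uids:
            rc, ri = kept[uid]
            c_idx = rng.choice(len(rc), size=n_per, replace=False)
            i_idx = rng.choice(len(ri), size=n_per, replace=False)
            cols.append(np.concatenate([rc[c_idx], ri[i_idx]]))
        X = np.stack(cols, axis=1)
        if config.boxcox:
            X, _ = boxcox_features(X)
        y = rng.permutation(y_base) if shuffle else y_base
        skf = StratifiedKFold(
            n_splits=config.outcome_cv_folds, shuffle=True,
            random_state=int(rng.integers(2**31)),
        )
        correct = 0
        for train, test in skf.split(X, y):
            clf = _make_classifier(config, rng)
            clf.fit(X[train], y[train])
            correct += int(np.sum(clf.predict(X[test]) == y[test]))
        accs[rep] = correct / len(y)
    return OutcomeDecodeResult(
        epoch=epoch, accuracies=accs, mean_accuracy=float(accs.mean()), dropped_units=dropped
    )


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

def permutation_p(observed: float, null: np.ndarray) -> float:
    """One-sided permutation p-value: (1 + #{null >= observed}) / (1 + n)."""
    null = np.asarray(null, dtype=float)
    return (1.0 + np.count_nonzero(null >= observed)) / (1.0 + len(null))


def mcnemar_chi2(b: int, c: int, *, continuity_correction: bool = False) -> float:
    """McNemar chi-square statistic for paired discordant counts b and c.

    chi2 = (b - c)^2 / (b + c); with the optional continuity correction the
    numerator is (|b - c| - 1)^2.  Undefined (raises) when b + c = 0.
    """
    if b + c == 0:
        raise ValueError("McNemar statistic undefined for b + c = 0")
    num = (abs(b - c) - 1) ** 2 if continuity_correction else (b - c) ** 2
    return num / (b + c)
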