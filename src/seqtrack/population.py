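"""Population-level characterization of warped unit traces.

Assembles the neuron x time matrix of trial-averaged z-scored traces,
computes principal-component score time courses (time bins as observations,
neurons as variables), mean +/- SEM traces for the excited/inhibited split,
the complete-versus-incomplete modulation contrast, and the per-interval
quartile grouping of units (Inh / Mid / Exc).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .warp import DEFAULT_CONFIG, WarpConfig, WarpedTrace, smooth_half_normal, warp_trial


@dataclass
class PopulationMatrix:
    """Rows: units (z-scored trial-averaged traces); columns: time bins."""

    values: np.ndarray  # (n_units, n_bins)
    unit_ids: list[str]
    meta: pd.DataFrame  # indexed by unit_id; e.g. label, session, trial_set
    segments: dict[str, slice]

    @property
    def n_units(self) -> int:
        return self.values.shape[0]


def build_population_matrix(
    traces: Sequence[WarpedTrace],
    meta: pd.DataFrame | None = None,
) -> PopulationMatrix:
    """Stack non-degenerate trial-averaged traces into a matrix.

    Degenerate (constant) traces are skipped.  Raises if no usable trace
    remains.
    """
    usable = [t for t in traces if not t.degenerate]
    if not usable:
        raise ValueError("no non-degenerate traces to assemble")
    values = np.stack([t.zscore for t in usable])
    unit_ids = [t.unit_id for t in usable]
    if meta is None:
        meta = pd.DataFrame(index=pd.Index(unit_ids, name="unit_id"))
    else:
        meta = meta.loc[unit_ids]
    return PopulationMatrix(values=values, unit_ids=unit_ids, meta=meta, segments=usable[0].segments)


@dataclass
class PCResult:
    """Principal-component score time courses and variance shares."""

    scores: np.ndarray  # (n_bins, n_components)
    explained_variance_pct: np.ndarray  # non-increasing, sums to <= 100
    components: np.ndarray  # (n_components, n_units) loadings


def pca_time_courses(m: PopulationMatrix, n_components: int = 2) -> PCResult:
    """PCA with time bins as observations and neurons as variables.

    The data matrix is the transpose of the population matrix (bins x units);
    columns are centered across bins, no rescaling (rows are already
    z-scored).  Returns the first ``n_components`` score time courses and
    percent variance explained.
    """
    if m.n_units < 2:
        raise ValueError("PCA requires at least 2 units")
    X = m.values.T  # (n_bins, n_units)
    if np.isnan(X).any():
        raise ValueError("population matrix contains NaN (degenerate rows?)")
    if n_components > min(X.shape):
        raise ValueError(
            f"cannot extract {n_components} components from a {X.shape} matrix"
        )
    pca = PCA(n_components=n_components)
    scores = pca.fit_transform(X)
    return PCResult(
        scores=scores,
        explained_variance_pct=pca.explained_variance_ratio_ * 100.0,
        components=pca.components_,
    )


def group_mean_traces(
    m: PopulationMatrix, by: str = "label"
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Mean and SEM trace per group of units (SEM across units).

    ``by`` names a column of ``m.meta``.  Raises for an empty matrix or a
    group with no members (cannot happen with groupby, but a missing column
    does raise).
    """
    if by not in m.meta.columns:
        raise KeyError(f"no metadata column {by!r}")
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for g, idx in m.meta.groupby(by, sort=True).groups.items():
        rows = m.values[[m.unit_ids.index(u) for u in idx]]
        mean = rows.mean(axis=0)
        sem = rows.std(axis=0, ddof=1) / np.sqrt(len(rows)) if len(rows) > 1 else np.zeros_like(mean)
        out[str(g)] = (mean, sem)
    if not out:
        raise ValueError("no groups found")
    return out


@dataclass
class ModulationContrast:
    """Per-unit complete-vs-incomplete sequence-modulation comparison."""

    table: pd.DataFrame  # z_complete, z_incomplete, label, attenuation, gain_ratio
    excluded: pd.Series  # unit_id -> reason


def modulation_contrast(
    unit_spikes: Mapping[str, np.ndarray],
    complete_trials: Sequence,
    incomplete_trials: Sequence,
    config: WarpConfig = DEFAULT_CONFIG,
    *,
    min_trials: int = 5,
) -> ModulationContrast:
    """Compare sequence-segment modulation on complete versus incomplete trials.

    For each unit the raw warped rates are averaged per condition and
    smoothed.  Each condition's trace is centered on its own mean (removing
    baseline offsets) and both are scaled by the *complete-trial* SD, so the
    two conditions are expressed in a common modulation unit and their
    magnitudes are directly comparable; a per-condition SD would make the
    measure invariant to a uniform scaling of the modulation and blind to
    attenuation.  Reported per unit: mean z over the sequence bins for each
    condition, the excited/inhibited label (from complete trials),
    ``attenuation`` = \\|z_complete\\| - \\|z_incomplete\\|, and ``gain_ratio``,
    the regression slope of the incomplete on the complete sequence-segment
    deviations (an estimate of the planted modulation-gain ratio).

    Units from sessions with fewer than ``min_trials`` trials per condition,
    or with a constant complete-trial trace, are excluded with a reason.
    """
    table_rows = {}
    excluded = {}
    seq = config.segments["sequence"]
    if len(complete_trials) < min_trials or len(incomplete_trials) < min_trials:
        excluded = {u: "insufficient_trials" for u in unit_spikes}
        return ModulationContrast(
            table=pd.DataFrame(
                columns=["z_complete", "z_incomplete", "label", "attenuation", "gain_ratio"]
            ),
            excluded=pd.Series(excluded, dtype=object),
        )
    for uid, spikes in unit_spikes.items():
        s_c = _condition_trace(spikes, complete_trials, config)
        s_i = _condition_trace(spikes, incomplete_trials, config)
        sd_c = s_c.std()
        if sd_c <= 1e-12:
            excluded[uid] = "degenerate"
            continue
        z_c = (s_c - s_c.mean()) / sd_c
        z_i = (s_i - s_i.mean()) / sd_c
        zc_seq = float(z_c[seq].mean())
        zi_seq = float(z_i[seq].mean())
        dc = z_c[seq] - z_c[seq].mean()
        di = z_i[seq] - z_i[seq].mean()
        denom = float(dc @ dc)
        gain_ratio = float(dc @ di) / denom if denom > 0 else np.nan
        table_rows[uid] = {
            "z_complete": zc_seq,
            "z_incomplete": zi_seq,
            "label": "excited" if zc_seq > 0 else "inhibited",
            "attenuation": abs(zc_seq) - abs(zi_seq),
            "gain_ratio": gain_ratio,
        }
    table = pd.DataFrame.from_dict(table_rows, orient="index")
    table.index.name = "unit_id"
    return ModulationContrast(table=table, excluded=pd.Series(excluded, dtype=object))


def _condition_trace(spikes: np.ndarray, trials: Sequence, config: WarpConfig) -> np.ndarray:
    raws = [
        warp_trial(spikes, tr.t_first_press, tr.t_last_press, tr.port_entry_time, config)
        for tr in trials
    ]
    return smooth_half_normal(
        np.mean(raws, axis=0), config.smooth_sigma, config.kernel_truncate_sigmas,
        causal=config.causal,
    )


def sequence_interval_slice(config: WarpConfig, n_intervals: int, interval: int) -> slice:
    """Bin range of one of K equal consecutive intervals of the sequence segment."""
    seq = config.segments["sequence"]
    n = config.n_bins_sequence
    lo = seq.start + round(n * interval / n_intervals)
    hi = seq.start + round(n * (interval + 1) / n_intervals)
    return slice(lo, hi)


def interval_mean_z(
    m: PopulationMatrix, n_intervals: int, interval: int, config: WarpConfig = DEFAULT_CONFIG
) -> pd.Series:
    """Per-unit mean z-score during one sequence interval."""
    sl = sequence_interval_slice(config, n_intervals, interval)
    return pd.Series(m.values[:, sl].mean(axis=1), index=m.unit_ids, name=f"interval_{interval}")


def quartile_groups(interval_z: pd.Series) -> pd.Series:
    """Assign units to Inh / Mid / Exc by their interval z-score quartile.

    Units strictly below the lower quartile are Inh, strictly above the upper
    quartile Exc, the rest Mid (boundary ties therefore fall into Mid, and
    all-equal distributions are entirely Mid).  Requires >= 8 units.  The
    output preserves a stable unit-id ordering.
    """
    if len(interval_z) < 8:
        raise ValueError("quartile grouping requires at least 8 units")
    z = interval_z.sort_index(kind="stable")
    q1, q3 = np.quantile(z.to_numpy(), [0.25, 0.75])
    labels = np.where(z < q1, "Inh", np.where(z > q3, "Exc", "Mid"))
    return pd.Series(labels, index=z.index, name="quartile_group")
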