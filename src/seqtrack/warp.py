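"""Relative-time warping of spike trains onto the behavioral sequence axis.

Trials vary in duration, so firing during the press sequence is expressed in
relative time: each spike time between the first (LP1) and last (LLP) lever
press is divided by the sequence duration, mapping the sequence onto [0, 1],
and binned into 100 equal bins whose counts are divided by the real bin
duration to give Hz.  The port approach (LLP to port entry) is warped the
same way onto 25 bins.  The 1-s lever-approach window before LP1 and the 1-s
reward window after the port entry are binned in real time (25 bins of
40 ms).  Concatenation gives a 175-bin trace: lever approach | sequence |
port approach | reward.

The concatenated trace is smoothed with a causal half-normal kernel
(sigma = 5 bins, truncated at 3 sigma and renormalized, so output bin i
mixes only bins <= i) and z-scored across its bins:
z_i = (F_i - F_mean) / F_sd.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np


class ZeroDurationError(ValueError):
    """Raised when a warp is requested over a non-positive time span."""


class DegenerateTraceError(ValueError):
    """Raised when z-scoring a constant (zero-variance) trace."""


@dataclass(frozen=True)
class WarpConfig:
    """Binning and smoothing parameters for the concatenated trace."""

    n_bins_sequence: int = 100
    n_bins_approach: int = 25
    fixed_window: float = 1.0  # seconds
    n_bins_fixed: int = 25  # 40-ms bins at defaults
    smooth_sigma: float = 5.0  # bins
    kernel_truncate_sigmas: float = 3.0
    causal: bool = True
    mode: str = "relative_time"  # or "event_centered"

    @property
    def total_bins(self) -> int:
        return 2 * self.n_bins_fixed + self.n_bins_sequence + self.n_bins_approach

    @property
    def segments(self) -> dict[str, slice]:
        """Bin ranges of the four concatenated segments."""
        a = self.n_bins_fixed
        b = a + self.n_bins_sequence
        c = b + self.n_bins_approach
        d = c + self.n_bins_fixed
        return {
            "lever_approach": slice(0, a),
            "sequence": slice(a, b),
            "port_approach": slice(b, c),
            "reward": slice(c, d),
        }


DEFAULT_CONFIG = WarpConfig()


@dataclass
class WarpedTrace:
    """One unit's concatenated firing-rate vector (single trial or trial mean)."""

    unit_id: str
    trial: int | str  # trial index or "mean"
    raw_rate: np.ndarray  # Hz
    smoothed_rate: np.ndarray  # Hz
    zscore: np.ndarray  # NaN-filled when degenerate
    degenerate: bool
    segments: dict[str, slice]


def warp_sequence(
    spikes: np.ndarray, t_first_press: float, t_last_press: float, n_bins: int = 100
) -> np.ndarray:
    """Firing rate (Hz) over ``n_bins`` equal relative-time bins of the sequence.

    Spikes outside [t_first_press, t_last_press] are ignored; a spike exactly
    at the last press falls in the final bin.  Raises
    :class:`ZeroDurationError` for a non-positive span (single-press runs).
    """
    duration = t_last_press - t_first_press
    if duration <= 0:
        raise ZeroDurationError("sequence duration must be positive to warp")
    spikes = np.asarray(spikes, dtype=float)
    rel = (spikes - t_first_press) / duration
    counts, _ = np.histogram(rel[(rel >= 0) & (rel <= 1)], bins=n_bins, range=(0.0, 1.0))
    return counts / (duration / n_bins)


def warp_approach(
    spikes: np.ndarray, t_last_press: float, t_port_entry: float, n_bins: int = 25
) -> np.ndarray:
    """Relative-time firing rate between the last press and the port entry."""
    return warp_sequence(spikes, t_last_press, t_port_entry, n_bins=n_bins)


def fixed_window_rate(
    spikes: np.ndarray,
    t0: float,
    window: float = 1.0,
    n_bins: int = 25,
    *,
    before: bool = False,
) -> np.ndarray:
    """Real-time binned rate over [t0, t0+window) or, with ``before``, [t0-window, t0).

    Bins are half-open; a spike exactly at the window end is excluded.
    """
    spikes = np.asarray(spikes, dtype=float)
    lo, hi = (t0 - window, t0) if before else (t0, t0 + window)
    sel = spikes[(spikes >= lo) & (spikes < hi)]
    counts, _ = np.histogram(sel, bins=n_bins, range=(lo, hi))
    return counts / (window / n_bins)


def half_normal_kernel(sigma: float = 5.0, truncate: float = 3.0) -> np.ndarray:
    """Normalized one-sided half-normal kernel over lags 0..floor(truncate*sigma)."""
    k = np.arange(int(np.floor(truncate * sigma)) + 1)
    w = np.exp(-(k**2) / (2.0 * sigma**2))
    return w / w.sum()


def smooth_half_normal(
    x: np.ndarray, sigma: float = 5.0, truncate: float = 3.0, *, causal: bool = True
) -> np.ndarray:
    """Half-normal smoothing; causal by default (bin i mixes bins <= i).

    The kernel is renormalized at the leading edge so a constant input stays
    exactly constant; the operation is linear in ``x``.
    """
    w = half_normal_kernel(sigma, truncate)
    if not causal:
        x = x[::-1]
    y = np.convolve(x, w)[: len(x)]
    # renormalize the first len(w)-1 bins where the kernel is truncated
    norm = np.cumsum(w)
    m = min(len(w) - 1, len(x))
    y[:m] /= norm[:m]
    if not causal:
        y = y[::-1]
    return y


def concatenate_smooth_zscore(
    la: np.ndarray,
    seq: np.ndarray,
    pa: np.ndarray,
    rew: np.ndarray,
    config: WarpConfig = DEFAULT_CONFIG,
    *,
    unit_id: str = "",
    trial: int | str = 0,
) -> WarpedTrace:
    """Concatenate the four segment rate vectors, smooth, and z-score.

    A constant smoothed trace has zero SD; it is flagged ``degenerate`` and
    its z-score vector is NaN so downstream steps can exclude the unit.
    """
    expected = (
        config.n_bins_fixed,
        config.n_bins_sequence,
        config.n_bins_approach,
        config.n_bins_fixed,
    )
    got = (len(la), len(seq), len(pa), len(rew))
    if got != expected:
        raise ValueError(f"segment lengths {got} do not match config {expected}")
    raw = np.concatenate([la, seq, pa, rew]).astype(float)
    smoothed = smooth_half_normal(
        raw, config.smooth_sigma, config.kernel_truncate_sigmas, causal=config.causal
    )
    return _zscore_trace(raw, smoothed, config.segments, unit_id=unit_id, trial=trial)


def _zscore_trace(
    raw: np.ndarray,
    smoothed: np.ndarray,
    segments: dict[str, slice],
    *,
    unit_id: str,
    trial: int | str,
) -> WarpedTrace:
    f_mean = smoothed.mean()
    f_sd = smoothed.std()  # population SD so the z-trace has SD exactly 1
    degenerate = f_sd <= 1e-12
    z = np.full_like(smoothed, np.nan) if degenerate else (smoothed - f_mean) / f_sd
    return WarpedTrace(
        unit_id=unit_id,
        trial=trial,
        raw_rate=raw,
        smoothed_rate=smoothed,
        zscore=z,
        degenerate=degenerate,
        segments=segments,
    )


def warp_trial(
    spikes: np.ndarray,
    t_first_press: float,
    t_last_press: float,
    t_port_entry: float,
    config: WarpConfig = DEFAULT_CONFIG,
) -> np.ndarray:
    """Raw concatenated 175-bin rate vector for one trial (no smoothing)."""
    la = fixed_window_rate(
        spikes, t_first_press, config.fixed_window, config.n_bins_fixed, before=True
    )
    seq = warp_sequence(spikes, t_first_press, t_last_press, config.n_bins_sequence)
    pa = warp_approach(spikes, t_last_press, t_port_entry, config.n_bins_approach)
    rew = fixed_window_rate(spikes, t_port_entry, config.fixed_window, config.n_bins_fixed)
    return np.concatenate([la, seq, pa, rew])


def trial_average_trace(
    spikes: np.ndarray,
    trials: Sequence,
    config: WarpConfig = DEFAULT_CONFIG,
    *,
    unit_id: str = "",
) -> WarpedTrace:
    """Trial-averaged warped trace of one unit: average raw rates, then smooth and z-score.

    ``trials`` supplies ``t_first_press``, ``t_last_press`` and
    ``port_entry_time`` attributes (e.g. :class:`~seqtrack.behavior.SequenceTrial`).
    """
    if not trials:
        raise ValueError("need at least one trial")
    raws = [
        warp_trial(spikes, tr.t_first_press, tr.t_last_press, tr.port_entry_time, config)
        for tr in trials
    ]
    raw = np.mean(raws, axis=0)
    smoothed = smooth_half_normal(
        raw, config.smooth_sigma, config.kernel_truncate_sigmas, causal=config.causal
    )
    return _zscore_trace(raw, smoothed, config.segments, unit_id=unit_id, trial="mean")


def event_centered_trace(
    spikes: np.ndarray,
    press_times: np.ndarray,
    t_port_entry: float,
    rng: np.random.Generator,
    config: WarpConfig = DEFAULT_CONFIG,
    *,
    half_window: float = 0.4,
    n_bins_per_event: int = 20,
    unit_id: str = "",
    trial: int | str = 0,
) -> WarpedTrace:
    """Event-centered alternative to relative-time warping.

    Rates in 40-ms bins over [t-0.4 s, t+0.4 s) around six events: the first
    press, the second press, one randomly selected intermediate press
    (seeded via ``rng``), the second-to-last press, the last press, and the
    port entry.  The 6 x 20 = 120-bin concatenation is smoothed and z-scored
    like the relative-time trace.  Bins are half-open, so a spike exactly at
    an event time falls in the first bin after the event.  Requires >= 5
    presses.
    """
    press_times = np.asarray(press_times, dtype=float)
    if len(press_times) < 5:
        raise ValueError("event-centered trace requires at least 5 presses")
    candidates = press_times[2:-2]
    intermediate = float(rng.choice(candidates))
    events = [
        press_times[0],
        press_times[1],
        intermediate,
        press_times[-2],
        press_times[-1],
        t_port_entry,
    ]
    names = ["lp1", "lp2", "intermediate", "second_to_last", "llp", "port_entry"]
    window = 2 * half_window
    raws = [
        fixed_window_rate(spikes, ev - half_window, window, n_bins_per_event)
        for ev in events
    ]
    raw = np.concatenate(raws)
    segments = {
        name: slice(i * n_bins_per_event, (i + 1) * n_bins_per_event)
        for i, name in enumerate(names)
    }
    smoothed = smooth_half_normal(
        raw, config.smooth_sigma, config.kernel_truncate_sigmas, causal=config.causal
    )
    return _zscore_trace(raw, smoothed, segments, unit_id=unit_id, trial=trial)


def excitation_label(trace: WarpedTrace) -> str:
    """'excited' if the mean z-score over the sequence segment is > 0, else 'inhibited'."""
    if trace.degenerate:
        raise DegenerateTraceError(f"unit {trace.unit_id!r}: constant trace")
    seq = trace.segments["sequence"]
    return "excited" if float(trace.zscore[seq].mean()) > 0 else "inhibited"
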