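"""Putative cell-type classification of sorted striatal units.

Units are assigned to putative medium spiny neurons (MSN), fast-spiking
interneurons (FSI), tonically active interneurons (TAN), or an excluded
intermediate class, from three scalar metrics: session-wide mean firing
rate (Hz), spike-waveform half-valley width (ms), and the coefficient of
variation of inter-spike intervals.  Thresholds:

* FSI:  rate > 20 Hz and half-valley width < 0.15 ms
* TAN:  rate < 5 Hz and half-valley width > 0.45 ms and ISI CV < 1
* excluded intermediate: neither interneuron rule, but rate in [12.5, 20] Hz
  or width in [0.4, 0.45] ms
* MSN: everything else

The interneuron rules take precedence over the intermediate exclusion.
All inequalities are applied literally (strict where written strict,
closed intervals for the intermediate bands); the boundaries have measure
zero for real-valued metrics.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

LABELS = ("MSN", "FSI", "TAN", "excluded_intermediate")

FSI_MIN_RATE_HZ = 20.0
FSI_MAX_WIDTH_MS = 0.15
TAN_MAX_RATE_HZ = 5.0
TAN_MIN_WIDTH_MS = 0.45
TAN_MAX_ISI_CV = 1.0
INTERMEDIATE_RATE_HZ = (12.5, 20.0)
INTERMEDIATE_WIDTH_MS = (0.4, 0.45)


class UnclassifiableUnitError(ValueError):
    """Raised when classification is requested for a unit without defined metrics."""


@dataclass
class UnitRecord:
    """One sorted unit's spike times, waveform metrics and (optional) label."""

    unit_id: str
    session_id: str
    spike_times: np.ndarray
    mean_rate: float  # Hz
    half_valley_width: float  # ms
    isi_cv: float  # dimensionless; NaN when < 3 spikes
    label: str | None = None

    @property
    def classifiable(self) -> bool:
        return np.isfinite(self.isi_cv)


def compute_unit_metrics(
    spike_times: np.ndarray,
    session_duration: float,
    half_valley_width: float,
    *,
    unit_id: str = "",
    session_id: str = "",
) -> UnitRecord:
    """Build an unlabeled :class:`UnitRecord` from spike times.

    ``mean_rate`` is spike count / session duration; ``isi_cv`` is the sample
    SD of successive inter-spike intervals divided by their mean, undefined
    (NaN, unit unclassifiable) with fewer than 3 spikes.
    """
    if session_duration <= 0:
        raise ValueError("session_duration must be positive")
    spike_times = np.asarray(spike_times, dtype=float)
    if np.any(np.diff(spike_times) < 0):
        raise ValueError("spike_times must be sorted")
    mean_rate = len(spike_times) / session_duration
    if len(spike_times) < 3:
        isi_cv = float("nan")
    else:
        isi = np.diff(spike_times)
        isi_cv = float(np.std(isi, ddof=1) / np.mean(isi))
    return UnitRecord(
        unit_id=unit_id,
        session_id=session_id,
        spike_times=spike_times,
        mean_rate=mean_rate,
        half_valley_width=half_valley_width,
        isi_cv=isi_cv,
    )


def classify_unit(u: UnitRecord) -> str:
    """Assign the putative cell-type label; also stored on ``u.label``."""
    if not u.classifiable:
        raise UnclassifiableUnitError(f"unit {u.unit_id!r}: ISI CV undefined (<3 spikes)")
    label = classify_metrics(u.mean_rate, u.half_valley_width, u.isi_cv)
    u.label = label
    return label


def classify_metrics(mean_rate: float, half_valley_width: float, isi_cv: float) -> str:
    """The threshold rule on raw metric values (see module docstring)."""
    if mean_rate > FSI_MIN_RATE_HZ and half_valley_width < FSI_MAX_WIDTH_MS:
        return "FSI"
    if mean_rate < TAN_MAX_RATE_HZ and half_valley_width > TAN_MIN_WIDTH_MS and isi_cv < TAN_MAX_ISI_CV:
        return "TAN"
    if (
        INTERMEDIATE_RATE_HZ[0] <= mean_rate <= INTERMEDIATE_RATE_HZ[1]
        or INTERMEDIATE_WIDTH_MS[0] <= half_valley_width <= INTERMEDIATE_WIDTH_MS[1]
    ):
        return "excluded_intermediate"
    return "MSN"


def half_valley_width_from_waveform(waveform: np.ndarray, sample_interval_ms: float) -> float:
    """Half-valley width (ms) of a mean spike waveform.

    Width of the (negative) trough at half its depth, with linear
    interpolation between samples.  The waveform is assumed baseline-zeroed;
    the trough is its global minimum.  Provided as an optional helper for
    metadata not supplied by the spike sorter.
    """
    w = np.asarray(waveform, dtype=float)
    i_min = int(np.argmin(w))
    depth = w[i_min]
    if depth >= 0:
        raise ValueError("waveform has no negative trough")
    half = depth / 2.0

    def _cross(idx_range) -> float:
        prev = i_min
        for i in idx_range:
            if w[i] >= half:
                # linear interpolation between sample i and the previous one
                frac = (half - w[i]) / (w[prev] - w[i])
                return i + (prev - i) * frac
            prev = i
        return float(idx_range[-1]) if len(idx_range) else float(i_min)

    left = _cross(range(i_min - 1, -1, -1))
    right = _cross(range(i_min + 1, len(w)))
    return (right - left) * sample_interval_ms
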