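"""Parsing of operant event logs into lever-press sequence trials.

The task (fixed-sequence-5, FS5): a rat earns a sucrose reward by making at
least five consecutive lever presses before entering the reward port.  A
premature port entry (fewer than five preceding presses) resets the response
requirement and the preceding press run counts as an *incomplete* sequence;
presses beyond the fifth are consequence-free and belong to the same
*complete* sequence.  A session's raw record is a time-ordered stream of
``lever_press``, ``port_entry`` and ``reward_delivery`` events; this module
segments that stream into trials and computes session-level behavioral
summaries (percent complete, sequence length/duration distributions,
inter-press-interval scalloping, and initiation/termination latencies split
by outcome).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

EVENT_KINDS = ("lever_press", "port_entry", "reward_delivery")

#: trials with a press sequence longer than this are excluded from analysis
MAX_SEQUENCE_DURATION_S = 20.0
#: trials whose port-entry latency (port entry - last press) exceeds this are excluded
MAX_PE_LATENCY_S = 10.0
#: a reward delivery within this window after a port entry marks the trial rewarded
REWARD_ATTRIBUTION_WINDOW_S = 0.5
#: minimum press count for a complete sequence
SEQUENCE_LENGTH = 5


class MalformedEventLogError(ValueError):
    """Raised when an event file violates the event-log contract."""


class EmptySessionError(ValueError):
    """Raised when a summary is requested for an empty trial list."""


@dataclass
class EventLog:
    """Timestamped behavioral events of one session.

    ``events`` is a DataFrame with columns ``time_s`` (seconds from session
    start, non-negative and non-decreasing) and ``event`` (one of
    :data:`EVENT_KINDS`).  Every reward delivery must coincide with, or
    immediately follow, a port entry.
    """

    session_id: str
    events: pd.DataFrame

    def __post_init__(self) -> None:
        validate_event_log(self.events)

    @property
    def times(self) -> np.ndarray:
        return self.events["time_s"].to_numpy(dtype=float)

    @property
    def kinds(self) -> np.ndarray:
        return self.events["event"].to_numpy(dtype=object)


def validate_event_log(events: pd.DataFrame) -> None:
    """Check the event-log invariants, raising :class:`MalformedEventLogError`."""
    required = {"time_s", "event"}
    if not required.issubset(events.columns):
        raise MalformedEventLogError(f"event log must have columns {sorted(required)}")
    t = events["time_s"].to_numpy(dtype=float)
    kinds = events["event"].to_numpy(dtype=object)
    if len(t) and t[0] < 0:
        raise MalformedEventLogError("negative event time")
    if np.any(np.diff(t) < 0):
        raise MalformedEventLogError("event times must be non-decreasing")
    bad = set(kinds) - set(EVENT_KINDS)
    if bad:
        raise MalformedEventLogError(f"unknown event kinds: {sorted(bad)}")
    # every reward must sit on, or immediately after, a port entry
    last_pe = -np.inf
    presses_since_pe = 0
    for ti, ki in zip(t, kinds):
        if ki == "port_entry":
            last_pe = ti
            presses_since_pe = 0
        elif ki == "lever_press":
            presses_since_pe += 1
        elif ki == "reward_delivery":
            if presses_since_pe > 0 or not (0.0 <= ti - last_pe <= REWARD_ATTRIBUTION_WINDOW_S):
                raise MalformedEventLogError(
                    f"reward_delivery at {ti:.3f}s is not attached to a port entry"
                )


@dataclass
class SequenceTrial:
    """One parsed press sequence ending at a port entry.

    ``lp1_latency`` is measured from the preceding port entry (session start
    for the first trial).  ``complete`` means >= 5 presses *and* rewarded;
    trials are invalid when the sequence lasts over 20 s, the port-entry
    latency exceeds 10 s, or the session ended before a port entry
    (``invalid_reason`` says which).
    """

    press_times: np.ndarray
    port_entry_time: float | None
    rewarded: bool
    complete: bool
    lp1_latency: float
    valid: bool = True
    invalid_reason: str | None = None

    @property
    def n_presses(self) -> int:
        return len(self.press_times)

    @property
    def t_first_press(self) -> float:
        return float(self.press_times[0])

    @property
    def t_last_press(self) -> float:
        return float(self.press_times[-1])

    @property
    def sequence_duration(self) -> float:
        return self.t_last_press - self.t_first_press

    @property
    def pe_latency(self) -> float:
        if self.port_entry_time is None:
            return float("nan")
        return self.port_entry_time - self.t_last_press

    @property
    def ipis(self) -> np.ndarray:
        return np.diff(self.press_times)


def parse_events(
    log: EventLog,
    *,
    max_sequence_duration: float = MAX_SEQUENCE_DURATION_S,
    max_pe_latency: float = MAX_PE_LATENCY_S,
    reward_window: float = REWARD_ATTRIBUTION_WINDOW_S,
) -> list[SequenceTrial]:
    """Segment an event log into sequence trials.

    Every maximal run of lever presses terminated by a port entry becomes one
    trial; port entries with no preceding press produce no trial (a warning
    count is logged); a trailing press run with no terminating port entry is
    emitted with ``valid=False, invalid_reason="truncated"``.
    """
    t = log.times
    kinds = log.kinds
    reward_times = t[kinds == "reward_delivery"]

    trials: list[SequenceTrial] = []
    pending: list[float] = []
    anchor = 0.0  # previous port entry (or session start)
    n_empty_entries = 0

    for ti, ki in zip(t, kinds):
        if ki == "lever_press":
            pending.append(ti)
        elif ki == "port_entry":
            if not pending:
                n_empty_entries += 1
                anchor = ti
                continue
            i = np.searchsorted(reward_times, ti, side="left")
            rewarded = i < len(reward_times) and reward_times[i] <= ti + reward_window
            trials.append(
                _build_trial(
                    np.asarray(pending),
                    ti,
                    rewarded,
                    anchor,
                    max_sequence_duration,
                    max_pe_latency,
                )
            )
            pending = []
            anchor = ti

    if pending:
        trial = SequenceTrial(
            press_times=np.asarray(pending),
            port_entry_time=None,
            rewarded=False,
            complete=False,
            lp1_latency=pending[0] - anchor,
            valid=False,
            invalid_reason="truncated",
        )
        trials.append(trial)
    if n_empty_entries:
        logger.warning(
            "session %s: %d port entries with no preceding press (no trial emitted)",
            log.session_id,
            n_empty_entries,
        )
    return trials


def _build_trial(
    presses: np.ndarray,
    t_pe: float,
    rewarded: bool,
    anchor: float,
    max_sequence_duration: float,
    max_pe_latency: float,
) -> SequenceTrial:
    complete = len(presses) >= SEQUENCE_LENGTH and rewarded
    duration = presses[-1] - presses[0]
    pe_latency = t_pe - presses[-1]
    valid, reason = True, None
    if duration > max_sequence_duration:
        valid, reason = False, "sequence_too_long"
    elif pe_latency > max_pe_latency:
        valid, reason = False, "port_entry_too_slow"
    return SequenceTrial(
        press_times=presses,
        port_entry_time=t_pe,
        rewarded=rewarded,
        complete=complete,
        lp1_latency=presses[0] - anchor,
        valid=valid,
        invalid_reason=reason,
    )


@dataclass
class BehaviorSummary:
    """Session-level behavioral metrics over valid trials."""

    n_trials: int
    n_complete: int
    n_incomplete: int
    percent_complete: float
    length_counts: pd.Series  # index: sequence length, values: trial counts
    sequence_durations: np.ndarray  # one per trial, seconds
    mean_duration_by_length: pd.Series
    mean_ipi_by_position: pd.DataFrame  # index: length, columns: IPI position (1-based)
    outcome_means: pd.DataFrame  # index complete/incomplete; cols lp1_latency, mean_ipi, pe_latency

    def to_text(self) -> str:
        lines = [
            f"n_trials\t{self.n_trials}",
            f"n_complete\t{self.n_complete}",
            f"n_incomplete\t{self.n_incomplete}",
            f"percent_complete\t{self.percent_complete:.2f}",
            "",
            "# sequence length counts",
            self.length_counts.to_string(),
            "",
            "# mean duration by length (s)",
            self.mean_duration_by_length.to_string(),
            "",
            "# mean IPI by press position (s), rows = sequence length",
            self.mean_ipi_by_position.to_string(),
            "",
            "# outcome means (s)",
            self.outcome_means.to_string(),
        ]
        return "\n".join(lines) + "\n"


def behavioral_metrics(trials: Sequence[SequenceTrial], *, only_valid: bool = True) -> BehaviorSummary:
    """Summarize parsed trials (valid ones by default).

    Raises :class:`EmptySessionError` if no (valid) trials are present.
    """
    use = [tr for tr in trials if tr.valid] if only_valid else list(trials)
    if not use:
        raise EmptySessionError("no valid trials to summarize")

    lengths = np.array([tr.n_presses for tr in use])
    complete = np.array([tr.complete for tr in use])
    durations = np.array([tr.sequence_duration for tr in use])

    length_counts = pd.Series(lengths).value_counts().sort_index()
    length_counts.index.name = "length"

    mean_dur = pd.Series(durations).groupby(lengths).mean()
    mean_dur.index.name = "length"

    rows = {}
    for L in sorted(set(lengths[lengths >= 2])):
        ipis = np.stack([tr.ipis for tr in use if tr.n_presses == L])
        rows[L] = pd.Series(ipis.mean(axis=0), index=np.arange(1, L))
    mean_ipi = pd.DataFrame(rows).T
    mean_ipi.index.name = "length"
    mean_ipi.columns.name = "ipi_position"

    def _group(mask: np.ndarray) -> dict[str, float]:
        sel = [tr for tr, m in zip(use, mask) if m]
        if not sel:
            return {"lp1_latency": np.nan, "mean_ipi": np.nan, "pe_latency": np.nan}
        all_ipis = np.concatenate([tr.ipis for tr in sel]) if any(tr.n_presses > 1 for tr in sel) else np.array([])
        return {
            "lp1_latency": float(np.mean([tr.lp1_latency for tr in sel])),
            "mean_ipi": float(all_ipis.mean()) if all_ipis.size else np.nan,
            "pe_latency": float(np.nanmean([tr.pe_latency for tr in sel])),
        }

    outcome = pd.DataFrame(
        [_group(complete), _group(~complete)], index=["complete", "incomplete"]
    )

    return BehaviorSummary(
        n_trials=len(use),
        n_complete=int(complete.sum()),
        n_incomplete=int((~complete).sum()),
        percent_complete=100.0 * complete.mean(),
        length_counts=length_counts,
        sequence_durations=durations,
        mean_duration_by_length=mean_dur,
        mean_ipi_by_position=mean_ipi,
        outcome_means=outcome,
    )
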