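"""Synthetic sessions and spike trains with known ground truth.

The generator emulates the statistical structure the analyses assume, so
every estimator can be tested against planted parameters:

* Behavior: fixed-sequence-5 trials with a complete-trial probability,
  a sequence-length distribution peaked at five presses, "scalloped"
  inter-press intervals (each IPI a fixed fraction rho of the previous one,
  with lognormal noise), and slower initiation/execution/termination on
  incomplete trials.
* Spiking: inhomogeneous-Poisson spike trains whose intensity profiles are
  defined on the *relative-time* axis of the warping analysis (ramp up,
  ramp down, phasic port-entry transient, or flat) and mapped onto each
  trial's real-time landmarks; modulation depth is multiplied by an
  attenuation factor g on incomplete trials.  Rates are rectified at a
  small floor so Box-Cox and ISI statistics stay well defined.
* Waveform metrics: per-unit (rate, half-valley width, ISI CV) triples drawn
  from class-typical regions for MSN / FSI / TAN / intermediate units, with
  the class mix matching the recorded proportions.

Everything is deterministic under the config seeds, and the planted truth is
available as tables for recovery tests.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._seeding import substream
from .behavior import SEQUENCE_LENGTH, EventLog, SequenceTrial

PROFILES = ("ramp_up", "ramp_down", "phasic_pe", "flat")
CELL_CLASSES = ("MSN", "FSI", "TAN", "excluded_intermediate")


@dataclass(frozen=True)
class BehaviorGenConfig:
    """Study conditions of the simulated FS5 sessions.

    Defaults: 80% complete trials (the behavioral asymptote of a trained
    animal), first IPI ~1.4 s shrinking geometrically by ``scallop_rho`` per
    press with lognormal noise, ~1 s port-entry latency, and a 1.6x slowdown
    of all latencies on incomplete trials.
    """

    n_trials: int = 100
    p_complete: float = 0.8
    complete_lengths: tuple[int, ...] = (5, 6, 7, 8, 9)
    complete_length_probs: tuple[float, ...] = (0.55, 0.25, 0.12, 0.05, 0.03)
    incomplete_lengths: tuple[int, ...] = (2, 3, 4)
    incomplete_length_probs: tuple[float, ...] = (0.30, 0.45, 0.25)
    ipi_first: float = 1.4  # seconds, mean of the first inter-press interval
    scallop_rho: float = 0.85  # IPI(j+1) = rho * IPI(j) in expectation
    ipi_noise_sigma: float = 0.25  # lognormal sigma on every IPI
    lp1_latency_median: float = 4.0  # seconds from previous port entry
    lp1_latency_sigma: float = 0.4
    lp1_latency_floor: float = 2.5  # keeps lever-approach and reward windows disjoint
    pe_latency_median: float = 1.0
    pe_latency_sigma: float = 0.3
    incomplete_slowdown: float = 1.6  # multiplies all latencies on incomplete trials
    max_session_s: float | None = None  # optional session limits
    max_rewards: int | None = None
    seed: int = 0


@dataclass(frozen=True)
class UnitGenConfig:
    """Planted unit population: firing profiles and waveform-metric classes."""

    n_units: int = 100
    profile_probs: tuple[float, ...] = (0.35, 0.35, 0.15, 0.15)  # ramp_up/down/phasic/flat
    baseline_rate: float = 5.0  # Hz
    gain: float = 3.0  # upward modulation, peak = baseline * (1 + gain)
    down_fraction: float = 0.9  # downward modulation floor fraction of baseline
    attenuation: float = 1.0  # g: modulation multiplier on incomplete trials
    phasic_sigma_s: float = 0.2  # width of the port-entry transient
    rate_floor: float = 0.1  # Hz, rectification floor
    cell_class_probs: tuple[float, ...] = (0.88, 0.04, 0.02, 0.06)  # MSN/FSI/TAN/intermediate
    seed: int = 0


# ---------------------------------------------------------------------------
# behavior
# ---------------------------------------------------------------------------

def simulate_session(
    cfg: BehaviorGenConfig, *, session_id: str | None = None
) -> tuple[EventLog, pd.DataFrame]:
    """Generate one session's event stream plus its ground-truth trial table.

    A port entry is rewarded iff at least five presses precede it; the truth
    table mirrors the fields the parser recovers (field-for-field
    round-trip).
    """
    rng = substream(cfg.seed, "behavior")
    rows = []
    events: list[tuple[float, str]] = []
    anchor = 0.0  # previous port entry (session start for trial 1)
    n_rewards = 0
    for i in range(cfg.n_trials):
        complete = rng.random() < cfg.p_complete
        if complete:
            length = int(rng.choice(cfg.complete_lengths, p=cfg.complete_length_probs))
        else:
            length = int(rng.choice(cfg.incomplete_lengths, p=cfg.incomplete_length_probs))
        slow = 1.0 if complete else cfg.incomplete_slowdown
        lp1_latency = cfg.lp1_latency_floor + slow * cfg.lp1_latency_median * np.exp(
            rng.normal(0.0, cfg.lp1_latency_sigma)
        )
        t_lp1 = anchor + lp1_latency
        ipis = (
            slow
            * cfg.ipi_first
            * cfg.scallop_rho ** np.arange(length - 1)
            * np.exp(rng.normal(0.0, cfg.ipi_noise_sigma, size=length - 1))
        )
        press_times = t_lp1 + np.concatenate([[0.0], np.cumsum(ipis)])
        pe_latency = slow * cfg.pe_latency_median * np.exp(
            rng.normal(0.0, cfg.pe_latency_sigma)
        )
        t_pe = press_times[-1] + pe_latency
        rewarded = length >= SEQUENCE_LENGTH
        if cfg.max_session_s is not None and t_pe > cfg.max_session_s:
            break
        events.extend((tp, "lever_press") for tp in press_times)
        events.append((t_pe, "port_entry"))
        if rewarded:
            events.append((t_pe, "reward_delivery"))
            n_rewards += 1
        duration = press_times[-1] - press_times[0]
        valid, reason = True, None
        if duration > 20.0:
            valid, reason = False, "sequence_too_long"
        elif pe_latency > 10.0:
            valid, reason = False, "port_entry_too_slow"
        rows.append(
            {
                "trial": i,
                "n_presses": length,
                "press_times": press_times,
                "t_lp1": t_lp1,
                "t_llp": press_times[-1],
                "t_pe": t_pe,
                "lp1_latency": lp1_latency,
                "sequence_duration": duration,
                "pe_latency": pe_latency,
                "ipis": ipis,
                "rewarded": rewarded,
                "complete": complete and rewarded,
                "valid": valid,
                "invalid_reason": reason,
            }
        )
        anchor = t_pe
        if cfg.max_rewards is not None and n_rewards >= cfg.max_rewards:
            break
    sid = session_id if session_id is not None else f"synth-{cfg.seed}"
    df = pd.DataFrame(
        [(t, k) for t, k in events], columns=["time_s", "event"]
    ).sort_values("time_s", kind="stable", ignore_index=True)
    return EventLog(session_id=sid, events=df), pd.DataFrame(rows)


def truth_to_trials(truth: pd.DataFrame) -> list[SequenceTrial]:
    """Materialize the ground-truth table as :class:`SequenceTrial` objects."""
    trials = []
    for _, r in truth.iterrows():
        trials.append(
            SequenceTrial(
                press_times=np.asarray(r["press_times"]),
                port_entry_time=float(r["t_pe"]),
                rewarded=bool(r["rewarded"]),
                complete=bool(r["complete"]),
                lp1_latency=float(r["lp1_latency"]),
                valid=bool(r["valid"]),
                invalid_reason=r["invalid_reason"],
            )
        )
    return trials


# ---------------------------------------------------------------------------
# spiking
# ---------------------------------------------------------------------------

# segment codes in the piecewise-constant intensity grid
_SEG_BASELINE, _SEG_LA, _SEG_SEQ, _SEG_PA, _SEG_REW = range(5)


def _session_grid(truth: pd.DataFrame, *, n_seq: int = 100, n_pa: int = 25, n_fixed: int = 25):
    """Piecewise-constant time grid covering the whole session.

    Returns arrays (t0, dur, code, u, dt_pe, complete) where ``u`` is the
    relative position of the sub-bin center within its segment and
    ``dt_pe`` the center time minus the trial's port entry.
    """
    t0s, durs, codes, us, dts, comp = [], [], [], [], [], []

    def add(lo, hi, n, code, t_pe, is_complete):
        edges = np.linspace(lo, hi, n + 1)
        centers = 0.5 * (edges[:-1] + edges[1:])
        t0s.append(edges[:-1])
        durs.append(np.diff(edges))
        codes.append(np.full(n, code))
        u = (centers - lo) / (hi - lo) if hi > lo else np.zeros(n)
        us.append(u)
        dts.append(centers - t_pe)
        comp.append(np.full(n, is_complete))

    prev_end = 0.0
    for _, r in truth.iterrows():
        lp1, llp, pe = r["t_lp1"], r["t_llp"], r["t_pe"]
        c = bool(r["complete"])
        if lp1 - 1.0 > prev_end:
            add(prev_end, lp1 - 1.0, 1, _SEG_BASELINE, pe, c)
        add(lp1 - 1.0, lp1, n_fixed, _SEG_LA, pe, c)
        add(lp1, llp, n_seq, _SEG_SEQ, pe, c)
        add(llp, pe, n_pa, _SEG_PA, pe, c)
        add(pe, pe + 1.0, n_fixed, _SEG_REW, pe, c)
        prev_end = pe + 1.0
    return (
        np.concatenate(t0s),
        np.concatenate(durs),
        np.concatenate(codes),
        np.concatenate(us),
        np.concatenate(dts),
        np.concatenate(comp),
    )


def _profile_rate(
    profile: str,
    grid,
    cfg: UnitGenConfig,
) -> np.ndarray:
    """Intensity (Hz) on the session grid for one firing profile."""
    _, _, codes, u, dt_pe, complete = grid
    g_eff = np.where(complete, 1.0, cfg.attenuation)
    base = cfg.baseline_rate
    delta = np.zeros_like(u)
    if profile == "ramp_up":
        amp = cfg.gain * base
        delta = np.where(codes == _SEG_SEQ, amp * u, delta)
        delta = np.where(codes == _SEG_PA, amp * (1.0 - u), delta)
    elif profile == "ramp_down":
        amp = cfg.down_fraction * base
        delta = np.where(codes == _SEG_SEQ, -amp * u, delta)
        delta = np.where(codes == _SEG_PA, -amp * (1.0 - u), delta)
    elif profile == "phasic_pe":
        bump = cfg.gain * base * np.exp(-(dt_pe**2) / (2.0 * cfg.phasic_sigma_s**2))
        in_peri = (codes == _SEG_PA) | (codes == _SEG_REW)
        delta = np.where(in_peri, bump, delta)
    elif profile != "flat":
        raise ValueError(f"unknown profile {profile!r}")
    return np.maximum(base + g_eff * delta, cfg.rate_floor)


def simulate_unit_spikes(
    profile: str,
    truth: pd.DataFrame,
    cfg: UnitGenConfig,
    rng: np.random.Generator,
    *,
    grid=None,
) -> np.ndarray:
    """Sample one unit's session-wide spike train from its intensity profile.

    The intensity is piecewise constant on a fine grid (100 sub-bins across
    the warped sequence span), so Poisson counts per sub-bin with uniform
    placement give an exact inhomogeneous-Poisson draw.
    """
    if grid is None:
        grid = _session_grid(truth)
    t0, dur, *_ = grid
    rate = _profile_rate(profile, grid, cfg)
    counts = rng.poisson(rate * dur)
    starts = np.repeat(t0, counts)
    widths = np.repeat(dur, counts)
    spikes = starts + widths * rng.random(counts.sum())
    return np.sort(spikes)


_METRIC_SAMPLERS = {
    # (rate Hz, half-valley width ms, ISI CV) drawn within each class's rule region
    "MSN": lambda rng: (
        float(np.clip(rng.lognormal(np.log(4.0), 0.5), 0.3, 12.4)),
        float(np.clip(rng.normal(0.3, 0.05), 0.16, 0.39)),
        float(np.clip(rng.normal(1.3, 0.2), 1.01, None)),
    ),
    "FSI": lambda rng: (
        float(rng.uniform(21.0, 45.0)),
        float(rng.uniform(0.05, 0.14)),
        float(np.clip(rng.normal(1.2, 0.2), 0.5, None)),
    ),
    "TAN": lambda rng: (
        float(rng.uniform(1.0, 4.8)),
        float(rng.uniform(0.46, 0.60)),
        float(rng.uniform(0.4, 0.9)),
    ),
    "excluded_intermediate": lambda rng: (
        float(rng.uniform(12.6, 19.9)),
        float(rng.uniform(0.16, 0.39)),
        float(np.clip(rng.normal(1.3, 0.2), 1.01, None)),
    )
    if rng.random() < 0.5
    else (
        float(rng.uniform(5.5, 12.4)),
        float(rng.uniform(0.401, 0.449)),
        float(np.clip(rng.normal(1.3, 0.2), 1.01, None)),
    ),
}


def draw_unit_metrics(n_units: int, cfg: UnitGenConfig) -> pd.DataFrame:
    """Planted waveform-metric triples with the configured class mix."""
    rng = substream(cfg.seed, "metrics")
    classes = rng.choice(CELL_CLASSES, size=n_units, p=cfg.cell_class_probs)
    rows = []
    for i, cc in enumerate(classes):
        rate, width, cv = _METRIC_SAMPLERS[cc](rng)
        rows.append(
            {
                "unit_id": f"u{i:04d}",
                "cell_class": cc,
                "planted_rate_hz": rate,
                "half_valley_width_ms": width,
                "planted_isi_cv": cv,
            }
        )
    return pd.DataFrame(rows).set_index("unit_id")


# ---------------------------------------------------------------------------
# experiment assembly
# ---------------------------------------------------------------------------

@dataclass
class Experiment:
    """One simulated session with its unit population and planted truth."""

    event_log: EventLog
    trial_truth: pd.DataFrame
    unit_manifest: pd.DataFrame
    spikes: dict[str, np.ndarray]

    @property
    def trials(self) -> list[SequenceTrial]:
        return truth_to_trials(self.trial_truth)


def simulate_experiment(bcfg: BehaviorGenConfig, ucfg: UnitGenConfig) -> Experiment:
    """Simulate a session and a unit population spiking through it."""
    event_log, truth = simulate_session(bcfg)
    grid = _session_grid(truth)
    rng_profiles = substream(ucfg.seed, "profiles")
    profiles = rng_profiles.choice(PROFILES, size=ucfg.n_units, p=ucfg.profile_probs)
    metrics = draw_unit_metrics(ucfg.n_units, ucfg)
    spikes = {}
    rows = []
    for i, prof in enumerate(profiles):
        uid = f"u{i:04d}"
        spikes[uid] = simulate_unit_spikes(
            prof, truth, ucfg, substream(ucfg.seed, "spikes", i), grid=grid
        )
        rows.append(
            {
                "unit_id": uid,
                "profile": prof,
                "baseline_hz": ucfg.baseline_rate,
                "gain": ucfg.gain,
                "attenuation": ucfg.attenuation,
            }
        )
    manifest = pd.DataFrame(rows).set_index("unit_id").join(metrics)
    return Experiment(
        event_log=event_log, trial_truth=truth, unit_manifest=manifest, spikes=spikes
    )


def ground_truth_manifest(bcfg: BehaviorGenConfig, ucfg: UnitGenConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Re-derive the planted trial and unit tables from the config seeds alone."""
    exp = simulate_experiment(bcfg, ucfg)
    return exp.trial_truth, exp.unit_manifest
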