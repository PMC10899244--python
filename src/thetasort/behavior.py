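"""Behavioral epoch statistics and chronic-session tracking.

Epoch statistics count spikes in half-open [start, end) behavioral
epochs and convert them to firing rates; turn bias summarizes left/right
spiking preference across paired trials; the LFP trend slope is an
ordinary least-squares line over an epoch (negative during left-turn
depolarization); session tracking follows peak-to-peak amplitude,
recording yield and normalized-waveform stability across weeks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import EventTable, SnippetArray

__all__ = [
    "TurnBias",
    "SessionTrack",
    "epoch_stats",
    "turn_bias",
    "lfp_trend_slope",
    "recording_yield",
    "track_sessions",
]


def epoch_stats(
    spike_times_by_unit: dict[str, np.ndarray], events: EventTable
) -> pd.DataFrame:
    """Per (unit, epoch) spike counts and firing rates.

    Epochs are half-open [t_start, t_end): a spike exactly at an epoch's
    end belongs to the following epoch.  Spikes outside all epochs are
    tallied under the label ``"unassigned"`` (rate reported as NaN).
    """
    rows = []
    for unit, times in spike_times_by_unit.items():
        times = np.asarray(times)
        assigned = np.zeros(times.size, dtype=bool)
        for label, t0, t1 in events.epochs():
            in_epoch = (times >= t0) & (times < t1)
            assigned |= in_epoch
            count = int(in_epoch.sum())
            dur = t1 - t0
            rows.append((unit, label, t0, t1, count, dur, count / dur))
        n_out = int((~assigned).sum())
        rows.append((unit, "unassigned", np.nan, np.nan, n_out, np.nan, np.nan))
    return pd.DataFrame(
        rows,
        columns=["unit", "label", "t_start", "t_end", "count", "duration", "rate"],
    )


@dataclass(frozen=True)
class TurnBias:
    """Left-turn spiking preference of one unit over paired trials.

    ``mean_fraction`` is the mean over trials of n_L / (n_L + n_R);
    0.5 = no bias, 1.0 = all spikes during left turns.
    """

    unit_id: str
    mean_fraction: float
    sd_fraction: float
    n_trials: int
    trial_fractions: tuple[float, ...]
    n_excluded: int


def turn_bias(
    unit_id: str,
    spike_times: np.ndarray,
    left_epochs: list[tuple[float, float]],
    right_epochs: list[tuple[float, float]],
) -> TurnBias:
    """Per-trial left fraction n_L/(n_L+n_R), paired trial by trial.

    Trials with no spikes in either epoch are excluded (and counted in
    ``n_excluded``).  Raises if every trial is empty.
    """
    if len(left_epochs) != len(right_epochs):
        raise ValueError("left and right trials must be paired 1:1")
    times = np.asarray(spike_times)
    fractions = []
    excluded = 0
    for (l0, l1), (r0, r1) in zip(left_epochs, right_epochs):
        n_l = int(((times >= l0) & (times < l1)).sum())
        n_r = int(((times >= r0) & (times < r1)).sum())
        if n_l + n_r == 0:
            excluded += 1
            continue
        fractions.append(n_l / (n_l + n_r))
    if not fractions:
        raise ValueError(f"unit {unit_id}: no spikes in any trial; bias undefined")
    arr = np.asarray(fractions)
    return TurnBias(
        unit_id=unit_id,
        mean_fraction=float(arr.mean()),
        sd_fraction=float(arr.std()),
        n_trials=len(fractions),
        trial_fractions=tuple(float(f) for f in arr),
        n_excluded=excluded,
    )


def lfp_trend_slope(
    lfp_trace: np.ndarray, rate: float, epoch: tuple[float, float]
) -> tuple[float, float]:
    """OLS linear-fit slope (µV/s) and intercept of an LFP over an epoch."""
    t0, t1 = epoch
    i0, i1 = int(round(t0 * rate)), int(round(t1 * rate))
    seg = np.asarray(lfp_trace[i0:i1], dtype=np.float64)
    if seg.size < 2:
        raise ValueError(f"epoch ({t0}, {t1}) spans fewer than 2 samples")
    t = i0 / rate + np.arange(seg.size) / rate
    slope, intercept = np.polyfit(t, seg, 1)
    return float(slope), float(intercept)


def recording_yield(n_sortable: int, n_channels: int) -> int:
    """Percent of channels with sortable units, rounded half away from zero."""
    if n_channels < 1:
        raise ValueError("need at least one channel")
    if not 0 <= n_sortable <= n_channels:
        raise ValueError(f"n_sortable={n_sortable} outside [0, {n_channels}]")
    import math

    return int(math.floor(100.0 * n_sortable / n_channels + 0.5))


@dataclass
class SessionTrack:
    """Chronic-tracking summary, one row per session.

    ``amplitude_uV`` is the session mean amplitude over units (None when
    the session has no spikes); ``similarity`` maps unit -> Pearson
    correlation of the session's peak-normalized mean waveform with the
    first session in which that unit appears.
    """

    weeks: list[float]
    amplitude_uV: list[float | None]
    yield_percent: list[int]
    mean_waveforms: list[dict[str, np.ndarray]]
    similarity: list[dict[str, float]]

    def to_frame(self) -> pd.DataFrame:
        mean_sim = [
            float(np.mean(list(s.values()))) if s else np.nan for s in self.similarity
        ]
        return pd.DataFrame(
            {
                "week": self.weeks,
                "amplitude_uV": [
                    np.nan if a is None else a for a in self.amplitude_uV
                ],
                "yield_percent": self.yield_percent,
                "similarity": mean_sim,
            }
        )


def unit_amplitude(
    snippets: SnippetArray, n_sample_spikes: int = 10,
    rng: np.random.Generator | int = 0,
) -> float:
    """Template-anchored peak-to-peak amplitude (µV) of one unit.

    The extremal sample indices are located on the unit's mean waveform
    (where noise is averaged down), then the trough-to-peak difference is
    read at those fixed indices from ``n_sample_spikes`` randomly sampled
    spikes and averaged.  Reading at fixed indices keeps the estimate
    unbiased at low SNR, where a per-snippet max-minus-min range is
    inflated by the noise's own excursions.
    """
    if len(snippets) == 0:
        raise ValueError("amplitude undefined without spikes")
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    mean_w = snippets.waveforms.mean(axis=0)
    i_min, i_max = int(np.argmin(mean_w)), int(np.argmax(mean_w))
    pick = rng.choice(
        len(snippets), size=min(n_sample_spikes, len(snippets)), replace=False
    )
    w = snippets.waveforms[pick]
    return float((w[:, i_max] - w[:, i_min]).mean())


def track_sessions(
    weeks: list[float],
    session_snippets: list[dict[str, SnippetArray]],
    session_sortable: list[int],
    n_channels: int,
    n_sample_spikes: int = 10,
    seed: int = 0,
) -> SessionTrack:
    """Track amplitude, yield and waveform stability across sessions.

    ``session_snippets`` holds, per session, the snippets of each sorted
    unit (unit id -> :class:`SnippetArray`).  The session amplitude is
    the mean over units of :func:`unit_amplitude` (each averaging
    ``n_sample_spikes`` sampled spikes); each unit's mean waveform is
    normalized to its maximum absolute potential and compared with the
    unit's first appearance by Pearson correlation.
    """
    rng = np.random.default_rng(seed)
    amps: list[float | None] = []
    waves: list[dict[str, np.ndarray]] = []
    yields: list[int] = []
    for snips, n_sort in zip(session_snippets, session_sortable):
        yields.append(recording_yield(n_sort, n_channels))
        unit_amps, unit_waves = [], {}
        for uid, snip in snips.items():
            if len(snip) == 0:
                continue
            unit_amps.append(unit_amplitude(snip, n_sample_spikes, rng))
            mean_w = snip.waveforms.mean(axis=0)
            unit_waves[uid] = mean_w / np.abs(mean_w).max()
        amps.append(float(np.mean(unit_amps)) if unit_amps else None)
        waves.append(unit_waves)
    ref: dict[str, np.ndarray] = {}
    sims: list[dict[str, float]] = []
    for unit_waves in waves:
        s = {}
        for uid, w in unit_waves.items():
            if uid in ref:
                s[uid] = float(np.corrcoef(ref[uid], w)[0, 1])
            else:
                ref[uid] = w
                s[uid] = 1.0
        sims.append(s)
    return SessionTrack(
        weeks=list(weeks),
        amplitude_uV=amps,
        yield_percent=yields,
        mean_waveforms=waves,
        similarity=sims,
    )
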