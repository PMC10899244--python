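"""Ground-truth extracellular recording simulator.

Generates the statistical structure the analysis pipeline assumes:

* theta-band (4–8 Hz) LFP oscillation with a per-channel propagation
  delay, pink (1/f) background confined below 300 Hz, white noise, and
  optional 60 Hz mains interference;
* single units firing as inhomogeneous Poisson processes whose intensity
  is modulated by behavioral state (epoch-dependent rate gain) and by
  theta phase through a von Mises factor
  ``exp(kappa * cos(phase - mu)) / I0(kappa)`` (the ``I0`` division makes
  the factor average to one over a uniform phase cycle, so the time-average
  rate stays at ``base_rate * state_gain``);
* biphasic spike templates (negative trough, positive rebound) with
  configurable peak-to-peak amplitude, added at the ground-truth times;
* multi-week session series with an amplitude trajectory and a
  sortable-channel schedule, emulating chronic-implant yield curves.

Everything is driven by a single integer seed and is bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import special

from .core import EventTable, Recording, SessionManifest, write_events, write_recording

__all__ = [
    "UnitSpec",
    "LfpSpec",
    "GroundTruth",
    "electrode_exposed_area",
    "make_template",
    "simulate_spike_train",
    "simulate_recording",
    "simulate_session_series",
]


def electrode_exposed_area(width: float, height: float) -> float:
    """Exposed electrode area (µm²) of a half-cylinder tip opening.

    The opening is modelled as half the lateral surface of a cylinder of
    diameter ``width`` and exposed height ``height``:
    ``pi * (width / 2) * height``.  For the default 5 µm x 7.5 µm probe
    tip this gives ~58.9 µm².
    """
    if width <= 0 or height <= 0:
        raise ValueError(f"dimensions must be positive, got ({width}, {height})")
    return math.pi * (width / 2.0) * height


@dataclass(frozen=True)
class UnitSpec:
    """Generative parameters of one single unit.

    Attributes
    ----------
    channel_id
        Channel the unit's waveform appears on.
    base_rate
        Mean firing rate in spikes/s before state/phase modulation.
    amplitude
        Template peak-to-peak amplitude, µV.
    trough_width_ms, repol_width_ms
        Widths (FWHM, ms) of the negative trough and positive rebound.
    preferred_phase
        Preferred theta angle, degrees in [0, 360).
    kappa
        von Mises concentration of phase locking (0 = no locking).
    state_gain
        Epoch label -> rate multiplier (unlisted epochs get gain 1).
    refractory
        Absolute refractory period, s.
    """

    channel_id: str
    base_rate: float
    amplitude: float = 100.0
    trough_width_ms: float = 0.3
    repol_width_ms: float = 0.6
    preferred_phase: float = 0.0
    kappa: float = 0.0
    state_gain: dict[str, float] = field(default_factory=dict)
    refractory: float = 0.002

    def __post_init__(self) -> None:
        if self.base_rate < 0:
            raise ValueError("base_rate must be >= 0")
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")
        if self.refractory <= 0:
            raise ValueError("refractory must be > 0")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be > 0")


@dataclass(frozen=True)
class LfpSpec:
    """Generative parameters of the field potential.

    ``delays`` maps channel id -> theta propagation delay in seconds
    (channels not listed get zero delay).
    """

    theta_freq: float = 6.0
    theta_amp: float = 150.0
    delays: dict[str, float] = field(default_factory=dict)
    pink_rms: float = 20.0
    mains_amp: float = 0.0

    def __post_init__(self) -> None:
        if not 4.0 <= self.theta_freq <= 8.0:
            raise ValueError(f"theta_freq must be in [4, 8] Hz, got {self.theta_freq}")
        if any(not math.isfinite(d) for d in self.delays.values()):
            raise ValueError("delays must be finite")


@dataclass
class GroundTruth:
    """Everything the simulator knows: enables parameter-recovery tests."""

    spike_times: dict[str, np.ndarray]  # unit id -> times (s)
    unit_channels: dict[str, str]  # unit id -> channel id
    unit_specs: dict[str, UnitSpec]
    lfp: LfpSpec
    noise_rms: float
    clean: np.ndarray | None = None  # noise-free signal (theta+mains+spikes)


# ---------------------------------------------------------------------------
# templates


def make_template(
    amplitude: float,
    trough_width_ms: float,
    repol_width_ms: float,
    rate: float,
    pre_s: float = 0.0008,
    post_s: float = 0.0016,
) -> np.ndarray:
    """Biphasic spike template sampled at ``rate``.

    Negative Gaussian trough (FWHM ``trough_width_ms``) at the alignment
    index ``round(pre_s * rate)``, followed by a positive rebound (FWHM
    ``repol_width_ms``); scaled so peak-to-peak equals ``amplitude``.
    """
    if trough_width_ms <= 0 or repol_width_ms <= 0:
        raise ValueError("widths must be positive")
    if amplitude <= 0:
        raise ValueError("amplitude must be positive")
    pre = int(round(pre_s * rate))
    post = int(round(post_s * rate))
    sigma_t = trough_width_ms / 1000.0 / 2.355  # FWHM -> sigma
    sigma_r = repol_width_ms / 1000.0 / 2.355
    delta = (trough_width_ms + repol_width_ms) / 2.0 / 1000.0
    if delta + sigma_r > post_s or 1.5 * sigma_t > pre_s:
        raise ValueError(
            f"template widths ({trough_width_ms}, {repol_width_ms} ms) "
            f"exceed the ({pre_s * 1e3:.2f}, {post_s * 1e3:.2f}) ms window"
        )
    t = (np.arange(pre + post + 1) - pre) / rate
    w = -np.exp(-0.5 * (t / sigma_t) ** 2) + 0.4 * np.exp(
        -0.5 * ((t - delta) / sigma_r) ** 2
    )
    # keep the trough exactly at the alignment index
    shift = pre - int(np.argmin(w))
    if shift:
        w = np.roll(w, shift)
        if shift > 0:
            w[:shift] = 0.0
        else:
            w[shift:] = 0.0
    return w * (amplitude / np.ptp(w))


# ---------------------------------------------------------------------------
# spike trains


def _epoch_gain_fn(unit: UnitSpec, events: EventTable | None):
    if events is None or not unit.state_gain:
        return lambda t: np.ones_like(t)
    starts = events.table["t_start"].to_numpy()
    ends = events.table["t_end"].to_numpy()
    gains = np.array(
        [unit.state_gain.get(lbl, 1.0) for lbl in events.table["label"]]
    )

    def gain(t: np.ndarray) -> np.ndarray:
        out = np.ones_like(t, dtype=float)
        for s, e, g in zip(starts, ends, gains):
            out[(t >= s) & (t < e)] = g
        return out

    return gain


def simulate_spike_train(
    unit: UnitSpec,
    theta_phase,
    events: EventTable | None,
    duration: float,
    rng: np.random.Generator | int,
) -> np.ndarray:
    """Spike times of one unit over ``[0, duration)`` seconds.

    Inhomogeneous Poisson process simulated by thinning with intensity
    ``lambda(t) = base_rate * state_gain(epoch(t)) *
    exp(kappa * cos(phase(t) - mu)) / I0(kappa)``, followed by deletion of
    spikes violating the absolute refractory period.

    ``theta_phase`` is a callable mapping times (s, array) to theta phase
    in radians (cosine convention: 0 at the theta peak), or ``None`` for
    no phase modulation.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    gain_fn = _epoch_gain_fn(unit, events)
    max_gain = max([1.0, *unit.state_gain.values()]) if unit.state_gain else 1.0
    i0k = special.i0(unit.kappa)
    lam_max = unit.base_rate * max_gain * math.exp(unit.kappa) / i0k
    if lam_max == 0:
        return np.empty(0)
    n = rng.poisson(lam_max * duration)
    cand = np.sort(rng.uniform(0.0, duration, n))
    lam = unit.base_rate * gain_fn(cand)
    if unit.kappa > 0 and theta_phase is not None:
        mu = math.radians(unit.preferred_phase)
        lam = lam * np.exp(unit.kappa * np.cos(theta_phase(cand) - mu)) / i0k
    keep = rng.uniform(0.0, lam_max, n) < lam
    times = cand[keep]
    # absolute refractory period: drop spikes following too closely
    if len(times) > 1:
        kept = [times[0]]
        for t in times[1:]:
            if t - kept[-1] >= unit.refractory:
                kept.append(t)
        times = np.array(kept)
    return times


# ---------------------------------------------------------------------------
# recordings


def _pink_noise(n: int, rate: float, rms: float, rng: np.random.Generator) -> np.ndarray:
    """1/f-shaped noise confined below 300 Hz, scaled to the requested rms."""
    if rms <= 0 or n == 0:
        return np.zeros(n)
    freqs = np.fft.rfftfreq(n, 1.0 / rate)
    spec = np.fft.rfft(rng.standard_normal(n))
    shape = np.zeros_like(freqs)
    band = (freqs > 0) & (freqs <= 300.0)
    shape[band] = 1.0 / np.sqrt(freqs[band])
    x = np.fft.irfft(spec * shape, n)
    sd = x.std()
    return x * (rms / sd) if sd > 0 else x


def theta_phase_fn(lfp: LfpSpec, channel_id: str):
    """Theta phase (radians, cosine convention) on one channel as f(t)."""
    delay = lfp.delays.get(channel_id, 0.0)
    omega = 2.0 * math.pi * lfp.theta_freq
    return lambda t: omega * (np.asarray(t) - delay)


def simulate_recording(
    channel_ids: list[str],
    units: dict[str, UnitSpec],
    lfp: LfpSpec,
    events: EventTable | None,
    duration: float,
    noise_rms: float = 15.0,
    rate: float = 24414.0,
    seed: int = 0,
    regions: list[str] | None = None,
) -> tuple[Recording, GroundTruth]:
    """Simulate a multichannel recording plus its ground truth.

    Each channel is the sum of a delayed theta sinusoid, pink background,
    white noise of broadband rms ``noise_rms`` (µV), optional 60 Hz mains,
    and spike templates placed at the ground-truth times.  ``units`` maps
    unit ids to their :class:`UnitSpec`.  Identical seed and configuration
    give a bit-identical recording.
    """
    for uid, u in units.items():
        if u.channel_id not in channel_ids:
            raise ValueError(f"unit {uid!r} references unknown channel {u.channel_id!r}")
    rng = np.random.default_rng(seed)
    n = int(round(duration * rate))
    t = np.arange(n) / rate
    clean = np.zeros((len(channel_ids), n))
    noisy = np.zeros_like(clean)
    omega = 2.0 * math.pi * lfp.theta_freq
    for ci, ch in enumerate(channel_ids):
        theta = lfp.theta_amp * np.cos(omega * (t - lfp.delays.get(ch, 0.0)))
        clean[ci] = theta
        if lfp.mains_amp > 0:
            clean[ci] += lfp.mains_amp * np.sin(2.0 * math.pi * 60.0 * t)
        noisy[ci] = _pink_noise(n, rate, lfp.pink_rms, rng)
        if noise_rms > 0:
            noisy[ci] += noise_rms * rng.standard_normal(n)

    spike_times: dict[str, np.ndarray] = {}
    unit_channels: dict[str, str] = {}
    for uid, unit in units.items():
        phase = theta_phase_fn(lfp, unit.channel_id)
        times = simulate_spike_train(unit, phase, events, duration, rng)
        spike_times[uid] = times
        unit_channels[uid] = unit.channel_id
        template = make_template(
            unit.amplitude, unit.trough_width_ms, unit.repol_width_ms, rate
        )
        pre = int(np.argmin(template))
        ci = channel_ids.index(unit.channel_id)
        idx = np.round(times * rate).astype(int)
        for i in idx:
            lo, hi = i - pre, i - pre + len(template)
            tlo, thi = max(0, -lo), len(template) - max(0, hi - n)
            clean[ci, max(0, lo) : min(n, hi)] += template[tlo:thi]

    rec = Recording(
        samples=clean + noisy,
        rate=rate,
        channel_ids=list(channel_ids),
        regions=regions,
    )
    gt = GroundTruth(
        spike_times=spike_times,
        unit_channels=unit_channels,
        unit_specs=dict(units),
        lfp=lfp,
        noise_rms=noise_rms,
        clean=clean,
    )
    return rec, gt


# ---------------------------------------------------------------------------
# chronic session series


def simulate_session_series(
    out_dir,
    channel_ids: list[str],
    units: dict[str, UnitSpec],
    lfp: LfpSpec,
    events: EventTable | None,
    weeks: list[float],
    amplitude_trajectory: list[float],
    sortable_channels: list[list[str]] | None,
    duration: float = 60.0,
    noise_rms: float = 15.0,
    rate: float = 20000.0,
    seed: int = 0,
) -> tuple[SessionManifest, list[GroundTruth]]:
    """Simulate a chronic multi-week series and write it to ``out_dir``.

    One recording per week: unit template peak-to-peak amplitudes follow
    ``amplitude_trajectory`` (µV per week) while the template *shape*
    stays fixed (same neuron), and only units on that week's sortable
    channels are present.  Emulates the slow amplitude recovery and yield
    growth seen over months of chronic implantation.
    """
    from pathlib import Path

    if len(amplitude_trajectory) != len(weeks):
        raise ValueError(
            f"{len(amplitude_trajectory)} trajectory entries for {len(weeks)} weeks"
        )
    if sortable_channels is not None and len(sortable_channels) != len(weeks):
        raise ValueError("sortable_channels schedule must align with weeks")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(seed)
    week_seeds = ss.generate_state(len(weeks)) % (2**31)
    sessions = []
    truths = []
    for wi, (week, amp) in enumerate(zip(weeks, amplitude_trajectory)):
        allowed = (
            set(channel_ids) if sortable_channels is None else set(sortable_channels[wi])
        )
        week_units = {
            uid: replace(u, amplitude=float(amp))
            for uid, u in units.items()
            if u.channel_id in allowed
        }
        rec, gt = simulate_recording(
            channel_ids,
            week_units,
            lfp,
            events,
            duration,
            noise_rms=noise_rms,
            rate=rate,
            seed=int(week_seeds[wi]),
        )
        rec_path = write_recording(rec, out_dir / f"week_{wi:02d}")
        ev_path = None
        if events is not None:
            ev_path = str(write_events(events, out_dir / f"week_{wi:02d}_events.tsv"))
        sessions.append((float(week), str(rec_path), ev_path))
        truths.append(gt)
    return SessionManifest(sessions), truths
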