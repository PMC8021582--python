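"""Seeded synthetic SEEG channels, regularity traces, and ground-truth labels.

The generator emulates the statistical structure the detection pipeline
assumes, so every stage is testable without patient recordings:

* background — a sum of band-limited oscillations (theta/alpha/beta-like
  sinusoids with per-channel random phases) plus AR(1) noise whose amplitude
  is modulated by a slow Ornstein-Uhlenbeck log-envelope. The lognormal
  envelope produces the episodic noise-floor excursions (vigilance changes,
  movement artifact bouts) that make one global static threshold misfire.
* ictal events — rhythmic spike-wave trains (default 4 Hz) built from a
  Gaussian-windowed impulse train convolved with a biphasic kernel, with
  amplitude building up over the first part of the event. A stand-in for
  epileptiform morphology, not a biophysical model.
* video regularity traces — a near-1 baseline with deep drops during true
  events and shallower nuisance dips (nurse-visit-like) that are *not* in the
  truth labels, so false-positive behavior is measurable.
* patient families — groups of synthetic patients sharing a spectral
  signature; recordings across families differ in band frequencies, which is
  what crossover experiments probe.

All generators are pure functions of (parameters, seed); event supports and
signal modifications coincide exactly (half-open [start, end) sample
intervals).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps

from .core import ChannelSeries, EventLabelSet, ParameterError
from .video import RegularitySeries

__all__ = [
    "BackgroundSpec",
    "SeizureSpec",
    "NuisanceSpec",
    "FamilySpec",
    "gen_seeg_channel",
    "gen_regularity_trace",
    "gen_patient_family",
    "default_families",
    "emu_default_benchmark",
]


@dataclass(frozen=True)
class BackgroundSpec:
    """Non-ictal SEEG background.

    ``bands`` lists (frequency Hz, amplitude) oscillations, each waxing and
    waning under its own slow lognormal envelope (``band_mod`` log-sd, time
    constant ``band_mod_tau_s`` — the familiar bursty character of cortical
    rhythms); ``noise_scale`` is the stationary AR(1) noise sd;
    ``noise_floor_drift`` is the sd of the slow OU log-amplitude envelope on
    the noise (0 disables the drift) with time constant ``drift_tau_s``;
    ``slow_drift`` adds a minutes-scale OU log-envelope on the *whole*
    background (vigilance-state / electrode-impedance level changes), the
    kind of nonstationarity a single global threshold cannot follow.
    """

    fs: float = 256.0
    duration_s: float = 600.0
    bands: tuple = ((7.0, 1.0), (11.0, 0.6), (23.0, 0.25))
    band_mod: float = 0.5
    band_mod_tau_s: float = 12.0
    noise_scale: float = 0.5
    noise_ar: float = 0.95
    noise_floor_drift: float = 0.5
    drift_tau_s: float = 45.0
    slow_drift: float = 0.0
    slow_drift_tau_s: float = 300.0

    def __post_init__(self) -> None:
        if self.fs <= 0 or self.duration_s <= 0:
            raise ParameterError("fs and duration_s must be positive")
        if self.bands and self.fs <= 2.0 * max(f for f, _ in self.bands):
            raise ParameterError("fs must exceed twice the highest band frequency")

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.duration_s))


@dataclass(frozen=True)
class SeizureSpec:
    """Rhythmic spike-wave ictal events superimposed on the background.

    ``spike_rate_hz`` defaults to 4 (generalized spike-and-wave discharges);
    ``amplitude_gain`` sets the sustained event RMS as a multiple of the
    background RMS; ``buildup_fraction`` of each event ramps up gradually;
    ``fast_activity`` is the fraction of event amplitude carried by
    superimposed low-voltage fast (desynchronized) activity. ``min_gap_s``
    keeps events minutes-scale apart, as clinical seizures are.
    """

    n_events: int = 2
    event_duration_s: tuple = (10.0, 20.0)
    spike_rate_hz: float = 4.0
    amplitude_gain: float = 5.0
    buildup_fraction: float = 0.3
    fast_activity: float = 0.12
    event_region: tuple = (0.35, 0.98)
    min_gap_s: float = 60.0

    def __post_init__(self) -> None:
        if self.n_events < 0:
            raise ParameterError("n_events must be >= 0")
        if self.n_events and self.amplitude_gain <= 1.0:
            raise ParameterError("amplitude_gain must exceed 1")
        lo, hi = self.event_duration_s
        if not (0 < lo <= hi):
            raise ParameterError("event durations must be positive and ordered")
        if not (0.0 <= self.buildup_fraction < 1.0):
            raise ParameterError("buildup_fraction must lie in [0, 1)")


@dataclass(frozen=True)
class NuisanceSpec:
    """Shallow regularity-score dips that are not true events (nurse visits)."""

    n_dips: int = 2
    dip_depth: float = 0.35
    dip_duration_s: tuple = (5.0, 15.0)

    def __post_init__(self) -> None:
        if not (0.0 < self.dip_depth < 1.0):
            raise ParameterError("dip_depth must lie in (0, 1)")


@dataclass(frozen=True)
class FamilySpec:
    """A spectral signature shared (up to jitter) by a family of patients.

    ``distant_gain`` is the range of event-amplitude attenuation on
    non-focus channels: the ictal discharge renders at the nominal
    ``amplitude_gain`` on the patient's focus channel and attenuated by a
    factor drawn from this range elsewhere, the spatial falloff every
    multi-lead SEEG implant shows.
    """

    name: str
    background: BackgroundSpec
    freq_jitter: float = 0.03
    amp_jitter: float = 0.10
    distant_gain: tuple = (0.25, 0.5)


# -- building blocks -----------------------------------------------------------

def _ou_envelope(n: int, fs: float, tau_s: float, log_sd: float,
                 rng: np.random.Generator) -> np.ndarray:
    """exp(OU) amplitude envelope, stationary log-sd ``log_sd``, mean log 0."""
    if log_sd <= 0:
        return np.ones(n)
    a = float(np.exp(-1.0 / (fs * tau_s)))
    innov_sd = float(np.sqrt(1.0 - a * a))
    u0 = rng.standard_normal()
    shocks = rng.standard_normal(n - 1) * innov_sd
    u = sps.lfilter([1.0], [1.0, -a], np.concatenate(([u0], shocks)))
    return np.exp(log_sd * u)


def _ar1_noise(n: int, rho: float, scale: float, rng: np.random.Generator) -> np.ndarray:
    innov = rng.standard_normal(n) * scale * np.sqrt(1.0 - rho * rho)
    x0 = rng.standard_normal() * scale
    return sps.lfilter([1.0], [1.0, -rho], np.concatenate(([x0], innov[1:])))


def _biphasic_kernel(fs: float, width_s: float = 0.02) -> np.ndarray:
    """Derivative-of-Gaussian spike kernel (sharp biphasic transient)."""
    half = int(round(3 * width_s * fs))
    t = np.arange(-half, half + 1) / fs
    kernel = -t / width_s ** 2 * np.exp(-0.5 * (t / width_s) ** 2)
    return kernel / np.max(np.abs(kernel))


def _spike_wave(n: int, fs: float, rate_hz: float, buildup_fraction: float,
                rng: np.random.Generator, fast_activity: float = 0.35) -> np.ndarray:
    """Unit-RMS (over the sustained part) rhythmic spike-wave segment.

    Spike-to-spike amplitude and timing jitter reproduce the cycle-to-cycle
    variability of real discharges — it is exactly this unpredictability that
    a one-step forecaster cannot learn away.
    """
    impulses = np.zeros(n)
    period = fs / rate_hz
    phase = rng.uniform(0, period)
    centers = np.arange(phase, n, period)
    centers = centers + rng.uniform(-0.15 * period, 0.15 * period, centers.size)
    amps = np.clip(1.0 + 0.4 * rng.standard_normal(centers.size), 0.2, None)
    idx = centers.astype(int)
    keep = (idx >= 0) & (idx < n)
    impulses[idx[keep]] = amps[keep]
    spikes = np.convolve(impulses, _biphasic_kernel(fs), mode="same")
    wave = np.sin(2 * np.pi * rate_hz * np.arange(n) / fs + rng.uniform(0, 2 * np.pi))
    seg = spikes + 0.6 * wave
    if fast_activity > 0:  # superimposed low-voltage fast activity
        fast = rng.standard_normal(n)
        fast = np.convolve(fast, np.ones(3) / 3.0, mode="same")  # keep < ~40 Hz
        seg += fast_activity * np.max(np.abs(seg)) * fast / max(np.std(fast), 1e-12)
    envelope = np.ones(n)
    ramp = int(round(buildup_fraction * n))
    if ramp > 0:
        envelope[:ramp] = np.linspace(0.0, 1.0, ramp, endpoint=False)
    taper = max(1, int(round(0.05 * n)))
    envelope[-taper:] *= np.linspace(1.0, 0.2, taper)
    seg *= envelope
    sustained = seg[ramp:] if ramp < n else seg
    rms = float(np.sqrt(np.mean(sustained ** 2)))
    return seg / rms if rms > 0 else seg


def _place_events(n: int, fs: float, spec: SeizureSpec,
                  rng: np.random.Generator) -> np.ndarray:
    lo = int(spec.event_region[0] * n)
    hi = int(spec.event_region[1] * n)
    gap = int(round(spec.min_gap_s * fs))
    intervals = []
    for _ in range(spec.n_events):
        dur = int(round(rng.uniform(*spec.event_duration_s) * fs))
        for _attempt in range(200):
            start = int(rng.integers(lo, max(lo + 1, hi - dur)))
            end = start + dur
            if end > hi:
                continue
            if all(end + gap <= s or e + gap <= start for s, e in intervals):
                intervals.append((start, end))
                break
        else:
            raise ParameterError(
                "could not place all events without overlap; shorten events or "
                "extend the recording"
            )
    return np.asarray(sorted(intervals), dtype=np.int64).reshape(-1, 2)


# -- public generators ---------------------------------------------------------

def gen_seeg_channel(background: BackgroundSpec = BackgroundSpec(),
                     seizures: SeizureSpec = SeizureSpec(),
                     seed: int = 0,
                     patient_id: str = "sim", channel_id: str = "ch0",
                     event_intervals: np.ndarray | None = None
                     ) -> tuple[ChannelSeries, EventLabelSet]:
    """One synthetic SEEG channel plus exact ground-truth event labels.

    ``event_intervals`` (sample pairs) reuses fixed event times — the way all
    channels of one synthetic patient share the patient's seizures.
    """
    rng = np.random.default_rng(seed)
    n = background.n_samples
    t = np.arange(n) / background.fs
    signal = np.zeros(n)
    for freq, amp in background.bands:
        tone = amp * np.sin(2 * np.pi * freq * t + rng.uniform(0, 2 * np.pi))
        tone *= _ou_envelope(n, background.fs, background.band_mod_tau_s,
                             background.band_mod, rng)
        signal += tone
    envelope = _ou_envelope(n, background.fs, background.drift_tau_s,
                            background.noise_floor_drift, rng)
    signal += envelope * _ar1_noise(n, background.noise_ar,
                                    background.noise_scale, rng)
    if background.slow_drift > 0:
        # minutes-scale level state applied to the whole background; ictal
        # events below are superimposed at absolute amplitude
        signal *= _ou_envelope(n, background.fs, background.slow_drift_tau_s,
                               background.slow_drift, rng)
    background_rms = float(np.sqrt(np.mean(signal ** 2)))

    if event_intervals is not None:
        intervals = np.asarray(event_intervals, dtype=np.int64).reshape(-1, 2)
        if intervals.shape[0] and intervals.max() > n:
            raise ParameterError("event intervals exceed the recording")
    else:
        intervals = _place_events(n, background.fs, seizures, rng)

    for start, end in intervals:
        seg = _spike_wave(end - start, background.fs, seizures.spike_rate_hz,
                          seizures.buildup_fraction, rng,
                          fast_activity=seizures.fast_activity)
        signal[start:end] += seizures.amplitude_gain * background_rms * seg

    series = ChannelSeries(values=signal, fs=background.fs,
                           patient_id=patient_id, channel_id=channel_id)
    labels = EventLabelSet(intervals=intervals, fs=background.fs,
                           source="synthetic-truth")
    return series, labels


def gen_regularity_trace(duration_s: float, fps: float,
                         events: EventLabelSet,
                         nuisance: NuisanceSpec = NuisanceSpec(),
                         seed: int = 0,
                         event_depth: float = 0.8,
                         noise_sd: float = 0.05,
                         event_jitter: float = 0.12,
                         nuisance_jitter: float = 0.05
                         ) -> tuple[RegularitySeries, EventLabelSet]:
    """Synthetic regularity-score series with truth drops and nuisance dips.

    ``events`` may be in any time base (its ``fs`` converts to frames). True
    events drop s(t) by ``event_depth``; nuisance dips are shallower
    (``nuisance.dip_depth``) and excluded from the returned truth labels by
    design, so downstream false-positive behavior is measurable. During any
    dip the score also fluctuates erratically (``*_jitter``) — irregular
    motion reconstructs irregularly, which is what makes dips forecastable
    neither in level nor in detail.
    """
    if not (0 < nuisance.dip_depth < event_depth <= 1.0):
        raise ParameterError("need 0 < dip_depth < event_depth <= 1")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fps))
    s = 1.0 - np.abs(rng.standard_normal(n)) * noise_sd

    factor = fps / events.fs
    frame_events = []
    for start, end in events.intervals:
        fstart = int(np.floor(start * factor))
        fend = min(n, int(np.ceil(end * factor)))
        if fend > n or fstart >= n:
            raise ParameterError("events exceed the trace duration")
        frame_events.append((fstart, fend))

    def dip(lo: int, hi: int, depth: float, jitter: float) -> None:
        m = hi - lo
        rise = max(1, min(int(round(2.0 * fps)), m // 5))  # seconds-scale onset
        profile = np.full(m, depth, dtype=float)
        profile[:rise] = depth * np.linspace(0, 1, rise, endpoint=False)
        profile[-rise:] = depth * np.linspace(1, 0, rise)
        s[lo:hi] -= profile
        s[lo:hi] -= np.abs(rng.standard_normal(m)) * jitter

    for lo, hi in frame_events:
        dip(lo, hi, event_depth, event_jitter)

    occupied = list(frame_events)
    for _ in range(nuisance.n_dips):
        dur = int(round(rng.uniform(*nuisance.dip_duration_s) * fps))
        for _attempt in range(200):
            lo = int(rng.integers(0, max(1, n - dur)))
            hi = lo + dur
            if all(hi <= a or b <= lo for a, b in occupied):
                dip(lo, hi, nuisance.dip_depth, nuisance_jitter)
                occupied.append((lo, hi))
                break

    s = np.clip(s, 0.0, 1.0)
    trace = RegularitySeries(e_t=1.0 - s, a_t=1.0 - s, s_t=s, fps=fps)
    truth = EventLabelSet(
        intervals=np.asarray(frame_events, dtype=np.int64).reshape(-1, 2),
        fs=fps, source="synthetic-truth",
    )
    return trace, truth


def gen_patient_family(family: FamilySpec, n_patients: int, seed: int = 0,
                       seizures: SeizureSpec = SeizureSpec(),
                       channels_per_patient: int = 2) -> list[dict]:
    """Synthetic patients sharing a family spectral signature.

    Each patient gets jittered band parameters, per-channel phases/noise, and
    patient-level seizure times rendered on every channel. Returns one dict
    per patient: ``{"patient_id", "channels", "labels"}``.
    """
    if n_patients < 1:
        raise ParameterError("n_patients must be >= 1")
    rng = np.random.default_rng(seed)
    patients = []
    for p in range(n_patients):
        jitter_bands = tuple(
            (f * (1.0 + rng.uniform(-family.freq_jitter, family.freq_jitter)),
             a * (1.0 + rng.uniform(-family.amp_jitter, family.amp_jitter)))
            for f, a in family.background.bands
        )
        bg = replace(family.background, bands=jitter_bands)
        pid = f"{family.name}-p{p}"
        n_events = int(rng.integers(1, seizures.n_events + 1)) \
            if seizures.n_events >= 1 else 0
        pat_seizures = replace(seizures, n_events=n_events)
        place_rng_seed = int(rng.integers(0, 2 ** 31 - 1))
        intervals = _place_events(bg.n_samples, bg.fs, pat_seizures,
                                  np.random.default_rng(place_rng_seed))
        channels = []
        labels = None
        for ch in range(channels_per_patient):
            chan_seed = int(rng.integers(0, 2 ** 31 - 1))
            if ch == 0:  # focus channel carries the full discharge
                chan_seizures = pat_seizures
            else:
                atten = rng.uniform(*family.distant_gain)
                chan_seizures = replace(
                    pat_seizures,
                    amplitude_gain=max(1.001, pat_seizures.amplitude_gain * atten),
                )
            series, labels = gen_seeg_channel(
                bg, chan_seizures, seed=chan_seed, patient_id=pid,
                channel_id=f"ch{ch}", event_intervals=intervals,
            )
            channels.append(series)
        patients.append({"patient_id": pid, "channels": channels,
                         "labels": labels, "family": family.name})
    return patients


def default_families(fs: float = 256.0, duration_s: float = 600.0) -> tuple[FamilySpec, FamilySpec]:
    """Two spectrally distinct families (theta/alpha-weighted vs delta/beta-weighted).

    Both carry the nonstationarities of real EMU recordings: deeply waxing
    and waning rhythms (band_mod), a wobbling fast noise floor, and a
    minutes-scale global amplitude state (slow_drift) from vigilance changes
    and movement bouts.
    """
    shared = dict(fs=fs, duration_s=duration_s, band_mod=1.1,
                  band_mod_tau_s=35.0, noise_floor_drift=0.3, drift_tau_s=45.0,
                  slow_drift=1.2, slow_drift_tau_s=150.0)
    fam_a = FamilySpec(
        name="A",
        background=BackgroundSpec(bands=((6.5, 1.0), (10.5, 0.7), (21.0, 0.25)),
                                  **shared),
    )
    fam_b = FamilySpec(
        name="B",
        background=BackgroundSpec(bands=((3.0, 0.9), (15.5, 0.8), (29.0, 0.45)),
                                  **shared),
    )
    return fam_a, fam_b


def emu_default_benchmark(seed: int = 0, fs: float = 256.0,
                          duration_s: float = 600.0,
                          seizures: SeizureSpec = SeizureSpec(n_events=3)
                          ) -> list[dict]:
    """The default desk-scale benchmark: 4 patients (2 families) x 2 channels,
    10 minutes at 256 Hz, 1-3 patient-level events each."""
    fam_a, fam_b = default_families(fs=fs, duration_s=duration_s)
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2 ** 31 - 1, size=2)
    patients = gen_patient_family(fam_a, 2, seed=int(seeds[0]), seizures=seizures)
    patients += gen_patient_family(fam_b, 2, seed=int(seeds[1]), seizures=seizures)
    return patients
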