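"""Synthetic chest-wall displacement and radar-phase signals with ground truth.

Respiration is modelled as a periodic piecewise curve — a parabolic
inspiratory segment followed by an exponential expiratory decay — and the
heartbeat as a train of Gaussian pulses whose inter-pulse intervals are
normally distributed around the mean beat period. The composite displacement
(respiration + heartbeat + additive white Gaussian noise) is what a radar
observes, up to the phase scale 4*pi/lambda.

All amplitudes are in millimetres, times in seconds, rates in hertz unless a
field name says otherwise.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import h5py
import numpy as np

__all__ = [
    "RespirationParams",
    "HeartbeatParams",
    "VitalRecord",
    "TABLE_RANGES",
    "simulate_respiration",
    "simulate_heartbeat",
    "compose_displacement",
    "two_sine_displacement",
    "add_noise",
    "displacement_to_phase",
    "sample_dataset",
    "save_dataset",
    "load_dataset",
    "write_record_text",
    "read_record_text",
    "wavelength_mm",
]

# Published parameter ranges for resting adults: respiration amplitude /
# rate / inhale:exhale ratio, heartbeat amplitude / rate.
TABLE_RANGES = {
    "Ar_mm": (4.0, 12.0),
    "fr_hz": (0.12, 0.48),
    "ratio": (1.5, 2.5),
    "Ah_mm": (0.1, 0.6),
    "fh_hz": (0.8, 1.6),
}

#: Fraction of the respiratory cycle below which the expiratory time constant
#: tau is not sampled (the tau -> 0 limit is an instantaneous exhale).
TAU_FLOOR_FRAC = 0.05


class ParameterError(ValueError):
    """A generative parameter lies outside its physiological range."""


def _check(cond: bool, name: str, msg: str) -> None:
    if not cond:
        raise ParameterError(f"{name}: {msg}")


@dataclass(frozen=True)
class RespirationParams:
    """Parameters of the respiratory displacement component.

    ``inhale_exhale_ratio`` is the r in an inhale:exhale duration ratio of
    1:r, so the inspiratory time is Ti = Tr/(1+r).
    """

    amplitude_mm: float
    rate_hz: float
    inhale_exhale_ratio: float
    tau_s: float

    def __post_init__(self) -> None:
        lo, hi = TABLE_RANGES["Ar_mm"]
        _check(lo <= self.amplitude_mm <= hi, "amplitude_mm",
               f"{self.amplitude_mm} outside [{lo}, {hi}] mm")
        lo, hi = TABLE_RANGES["fr_hz"]
        _check(lo <= self.rate_hz <= hi, "rate_hz",
               f"{self.rate_hz} outside [{lo}, {hi}] Hz")
        lo, hi = TABLE_RANGES["ratio"]
        _check(lo <= self.inhale_exhale_ratio <= hi, "inhale_exhale_ratio",
               f"{self.inhale_exhale_ratio} outside [{lo}, {hi}]")
        _check(0.0 < self.tau_s <= self.cycle_s, "tau_s",
               f"{self.tau_s} outside (0, Tr={self.cycle_s:.3f}] s")

    @property
    def cycle_s(self) -> float:
        """Respiratory period Tr = 1/fr."""
        return 1.0 / self.rate_hz

    @property
    def inhale_s(self) -> float:
        """Inspiratory duration Ti = Tr / (1 + r)."""
        return self.cycle_s / (1.0 + self.inhale_exhale_ratio)

    @property
    def exhale_s(self) -> float:
        """Expiratory duration Te = Tr - Ti."""
        return self.cycle_s - self.inhale_s


@dataclass(frozen=True)
class HeartbeatParams:
    """Parameters of the Gaussian-pulse-train heartbeat component.

    ``interval_jitter_ms`` is the SD of the normal distribution the
    beat-to-beat intervals are drawn from (population resting default 46 ms).
    ``amp_jitter_rel`` is a relative per-pulse amplitude jitter SD, applied
    only when ``amp_jitter_on`` is set.
    """

    amplitude_mm: float
    rate_hz: float
    interval_jitter_ms: float = 46.0
    pulse_width_s: float = 0.05
    amp_jitter_rel: float = 0.1
    amp_jitter_on: bool = False

    def __post_init__(self) -> None:
        lo, hi = TABLE_RANGES["Ah_mm"]
        _check(lo <= self.amplitude_mm <= hi, "amplitude_mm",
               f"{self.amplitude_mm} outside [{lo}, {hi}] mm")
        lo, hi = TABLE_RANGES["fh_hz"]
        _check(lo <= self.rate_hz <= hi, "rate_hz",
               f"{self.rate_hz} outside [{lo}, {hi}] Hz")
        _check(self.interval_jitter_ms >= 0.0, "interval_jitter_ms",
               "must be >= 0")
        _check(self.pulse_width_s > 0.0, "pulse_width_s", "must be > 0")

    @property
    def mean_interval_s(self) -> float:
        """Mean beat period Th = 1/fh."""
        return 1.0 / self.rate_hz


@dataclass
class VitalRecord:
    """A sampled displacement or phase window plus its ground truth."""

    samples: np.ndarray
    fs: float
    duration: float
    truth_beat_times: np.ndarray | None = None
    truth_fh: float | None = None
    snr_db: float = np.inf
    units: str = "mm"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        n_expected = int(round(self.duration * self.fs))
        if self.samples.size != n_expected:
            raise ValueError(
                f"samples length {self.samples.size} != round(duration*fs)="
                f"{n_expected}")
        if self.truth_beat_times is not None:
            self.truth_beat_times = np.asarray(self.truth_beat_times,
                                               dtype=float)

    @property
    def t(self) -> np.ndarray:
        """Sample times in seconds."""
        return np.arange(self.samples.size) / self.fs

    def replace(self, **kw) -> "VitalRecord":
        return dataclasses.replace(self, **kw)


def respiration_waveform(params: RespirationParams, t: np.ndarray) -> np.ndarray:
    """Evaluate the periodic respiration curve at times ``t`` (seconds).

    Within one cycle: a parabola rising from 0 to the peak amplitude over the
    inspiratory phase [0, Ti], then an exponential decay back to 0 over the
    expiratory phase [Ti, Tr]. Continuous at Ti and at the cycle boundary.
    """
    Ar = params.amplitude_mm
    Tr, Ti, Te, tau = (params.cycle_s, params.inhale_s, params.exhale_s,
                       params.tau_s)
    tc = np.asarray(t, dtype=float) % Tr
    out = np.empty_like(tc)
    inh = tc <= Ti
    out[inh] = (-Ar / (Ti * Te)) * tc[inh] ** 2 + (Ar * Tr / (Ti * Te)) * tc[inh]
    ex = ~inh
    denom = 1.0 - np.exp(-Te / tau)
    out[ex] = Ar * (np.exp(-(tc[ex] - Ti) / tau) - np.exp(-Te / tau)) / denom
    return out


def simulate_respiration(params: RespirationParams, fs: float,
                         duration: float, t0: float = 0.0) -> VitalRecord:
    """Sample the respiration displacement at ``fs`` Hz for ``duration`` s.

    ``t0`` shifts the cycle phase (useful for drawing independent windows).
    """
    if fs <= 2.0 * params.rate_hz:
        raise ParameterError(f"fs={fs} must exceed twice the rate "
                             f"{params.rate_hz} Hz")
    if duration <= 0:
        raise ParameterError("duration must be > 0")
    n = int(round(duration * fs))
    t = np.arange(n) / fs + t0
    return VitalRecord(respiration_waveform(params, t), fs, duration)


def simulate_heartbeat(params: HeartbeatParams, fs: float, duration: float,
                       seed: int | np.random.Generator = 0) -> VitalRecord:
    """Sample a jittered Gaussian-pulse heartbeat train.

    Beat-to-beat intervals are i.i.d. normal(Th, jitter); non-positive draws
    are rejected and redrawn. Pulses whose centres fall just outside the
    window still contribute their truncated tails. The attached truth is the
    set of beat times inside [0, duration) and the reciprocal of their mean
    interval.
    """
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator) else seed
    Th = params.mean_interval_s
    jit = params.interval_jitter_ms / 1000.0
    sig = params.pulse_width_s
    pad = 4.0 * sig

    def draw_interval() -> float:
        for _ in range(1000):
            iv = rng.normal(Th, jit) if jit > 0 else Th
            if iv > 0:
                return iv
        raise RuntimeError("interval rejection did not terminate")

    # Random phase for the first beat, then cumulative jittered intervals;
    # extend past both window edges so edge pulses are naturally truncated.
    beats = [rng.uniform(0.0, Th)]
    while beats[0] > -pad:
        beats.insert(0, beats[0] - draw_interval())
    while beats[-1] < duration + pad:
        beats.append(beats[-1] + draw_interval())
    beats_arr = np.array(beats)

    amps = np.full(beats_arr.size, params.amplitude_mm)
    if params.amp_jitter_on and params.amp_jitter_rel > 0:
        amps = amps * (1.0 + params.amp_jitter_rel
                       * rng.standard_normal(beats_arr.size))

    n = int(round(duration * fs))
    t = np.arange(n) / fs
    x = np.zeros(n)
    for bt, a in zip(beats_arr, amps):
        x += a * np.exp(-((t - bt) ** 2) / (2.0 * sig ** 2))

    in_win = beats_arr[(beats_arr >= 0.0) & (beats_arr < duration)]
    truth_fh = None
    if in_win.size >= 2:
        truth_fh = 1.0 / float(np.mean(np.diff(in_win)))
    return VitalRecord(x, fs, duration, truth_beat_times=in_win,
                       truth_fh=truth_fh)


def compose_displacement(resp: VitalRecord, heart: VitalRecord) -> VitalRecord:
    """Superpose respiratory and cardiac displacement on a common grid."""
    if resp.fs != heart.fs or resp.duration != heart.duration:
        raise ValueError("respiration and heartbeat records must share fs "
                         "and duration")
    return VitalRecord(resp.samples + heart.samples, heart.fs, heart.duration,
                       truth_beat_times=heart.truth_beat_times,
                       truth_fh=heart.truth_fh, snr_db=heart.snr_db,
                       units=heart.units)


def two_sine_displacement(Ar: float, fr: float, Ah: float, fh: float,
                          fs: float, duration: float) -> VitalRecord:
    """Idealised two-sine chest model Ar*sin(2*pi*fr*t) + Ah*sin(2*pi*fh*t)."""
    if Ar < 0 or Ah < 0 or fr <= 0 or fh <= 0:
        raise ParameterError("amplitudes must be >= 0 and frequencies > 0")
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    x = Ar * np.sin(2 * np.pi * fr * t) + Ah * np.sin(2 * np.pi * fh * t)
    return VitalRecord(x, fs, duration, truth_fh=fh)


def add_noise(rec: VitalRecord, snr_db: float,
              seed: int | np.random.Generator = 0) -> VitalRecord:
    """Add white Gaussian noise at the requested SNR.

    Signal power is measured on the mean-detrended clean samples; the noise
    variance is set so 10*log10(P_signal/P_noise) = snr_db. Truth fields are
    untouched. ``snr_db=inf`` returns the record unchanged.
    """
    if np.isinf(snr_db):
        return rec.replace(snr_db=np.inf)
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator) else seed
    x = rec.samples
    p_sig = float(np.mean((x - x.mean()) ** 2))
    if p_sig <= 0:
        raise ValueError("signal power is zero; SNR undefined")
    p_noise = p_sig / (10.0 ** (snr_db / 10.0))
    noisy = x + rng.normal(0.0, np.sqrt(p_noise), x.size)
    return rec.replace(samples=noisy, snr_db=float(snr_db))


def wavelength_mm(carrier_hz: float) -> float:
    """Carrier wavelength in mm (c / f0)."""
    return 299_792_458.0 * 1000.0 / carrier_hz


def displacement_to_phase(rec: VitalRecord, wavelength: float) -> VitalRecord:
    """Convert displacement (mm) to radar phase (rad): phi = 4*pi*x/lambda.

    The factor 4*pi/lambda is the two-way path: a displacement of lambda/4
    produces a phase excursion of pi.
    """
    if wavelength <= 0:
        raise ParameterError("wavelength must be > 0")
    return rec.replace(samples=rec.samples * (4.0 * np.pi / wavelength),
                       units="rad")


def _draw_params(rng: np.random.Generator) -> tuple[RespirationParams,
                                                    HeartbeatParams]:
    Ar = rng.uniform(*TABLE_RANGES["Ar_mm"])
    fr = rng.uniform(*TABLE_RANGES["fr_hz"])
    r = rng.uniform(*TABLE_RANGES["ratio"])
    Tr = 1.0 / fr
    tau = rng.uniform(TAU_FLOOR_FRAC * Tr, Tr)
    Ah = rng.uniform(*TABLE_RANGES["Ah_mm"])
    fh = rng.uniform(*TABLE_RANGES["fh_hz"])
    return (RespirationParams(Ar, fr, r, tau), HeartbeatParams(Ah, fh))


def sample_dataset(n: int, split_seed: int,
                   snr_range: tuple[float, float] = (5.0, 20.0),
                   fs: float = 100.0, duration: float = 4.0,
                   as_phase: bool = False,
                   carrier_hz: float = 77e9) -> list[VitalRecord]:
    """Draw ``n`` independent noisy composite windows with ground truth.

    Generative parameters are uniform over the published resting-adult
    ranges; the SNR of each window is uniform over ``snr_range`` (pass a
    degenerate range such as ``(20, 20)`` for a fixed SNR, or ``(inf, inf)``
    for clean windows). Fully reproducible from ``split_seed``. When
    ``as_phase`` is set the displacement is scaled to radar phase at the
    given carrier.
    """
    if n <= 0:
        raise ValueError("n must be > 0")
    rng = np.random.default_rng(split_seed)
    out: list[VitalRecord] = []
    lam = wavelength_mm(carrier_hz)
    while len(out) < n:
        rp, hp = _draw_params(rng)
        # random respiratory phase so windows are not cycle-aligned
        t0 = rng.uniform(0.0, rp.cycle_s)
        resp = simulate_respiration(rp, fs, duration, t0=t0)
        heart = simulate_heartbeat(hp, fs, duration, seed=rng)
        if heart.truth_fh is None:
            continue  # fewer than 2 beats landed in the window; redraw
        rec = compose_displacement(resp, heart)
        snr = (np.inf if np.isinf(snr_range[0])
               else rng.uniform(snr_range[0], snr_range[1]))
        rec = add_noise(rec, snr, seed=rng)
        if as_phase:
            rec = displacement_to_phase(rec, lam)
        out.append(rec)
    return out


def save_dataset(records: list[VitalRecord], path: str, seed: int | None = None,
                 extra_attrs: dict | None = None) -> None:
    """Write a dataset to an HDF5 container.

    Layout: /signals [n x L], /labels_fh [n], /beat_times (ragged, one
    variable-length row per record), /snr_db [n]; fs, duration and the
    generative ranges stored as root attributes.
    """
    n = len(records)
    if n == 0:
        raise ValueError("empty dataset")
    L = records[0].samples.size
    with h5py.File(path, "w") as f:
        f.create_dataset("signals",
                         data=np.stack([r.samples for r in records]))
        f.create_dataset("labels_fh", data=np.array(
            [r.truth_fh if r.truth_fh is not None else np.nan
             for r in records]))
        f.create_dataset("snr_db", data=np.array(
            [r.snr_db for r in records]))
        vlen = h5py.vlen_dtype(np.dtype("float64"))
        bt = f.create_dataset("beat_times", (n,), dtype=vlen)
        for i, r in enumerate(records):
            bt[i] = (r.truth_beat_times if r.truth_beat_times is not None
                     else np.array([]))
        f.attrs["fs"] = records[0].fs
        f.attrs["duration"] = records[0].duration
        f.attrs["units"] = records[0].units
        f.attrs["n"] = n
        f.attrs["window_len"] = L
        if seed is not None:
            f.attrs["seed"] = seed
        for k, (lo, hi) in TABLE_RANGES.items():
            f.attrs[f"range_{k}"] = (lo, hi)
        for k, v in (extra_attrs or {}).items():
            f.attrs[k] = v


def load_dataset(path: str) -> list[VitalRecord]:
    """Read a dataset written by :func:`save_dataset`."""
    with h5py.File(path, "r") as f:
        sig = f["signals"][...]
        fh = f["labels_fh"][...]
        snr = f["snr_db"][...]
        bt = f["beat_times"]
        fs = float(f.attrs["fs"])
        dur = float(f.attrs["duration"])
        units = str(f.attrs.get("units", "mm"))
        out = []
        for i in range(sig.shape[0]):
            out.append(VitalRecord(
                sig[i], fs, dur,
                truth_beat_times=np.asarray(bt[i]),
                truth_fh=None if np.isnan(fh[i]) else float(fh[i]),
                snr_db=float(snr[i]), units=units))
    return out


def write_record_text(rec: VitalRecord, path: str) -> None:
    """Two-column delimited text (time_s, value) for a single record."""
    np.savetxt(path, np.column_stack([rec.t, rec.samples]),
               header=f"time_s value_{rec.units} fs={rec.fs}", comments="# ")


def read_record_text(path: str, fs: float | None = None) -> VitalRecord:
    """Read a record written by :func:`write_record_text`.

    If the file has a single column, ``fs`` must be given; with two columns
    the sampling rate is inferred from the time axis.
    """
    arr = np.loadtxt(path)
    if arr.ndim == 1:
        if fs is None:
            raise ValueError("single-column input needs an explicit fs")
        vals = arr
    else:
        t, vals = arr[:, 0], arr[:, 1]
        if fs is None:
            fs = 1.0 / float(np.median(np.diff(t)))
    return VitalRecord(vals, fs, vals.size / fs)
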