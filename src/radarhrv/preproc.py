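"""Radar baseband to network-ready window: demodulation, filtering, windowing.

The chain mirrors the standard vital-sign pipeline for FMCW/CW radar: a
range FFT over fast time, selection of the chest range bin, arctangent
demodulation of the slow-time complex samples, phase unwrapping, a 4th-order
Butterworth band-pass (0.67-15 Hz) to reject the respiratory fundamental,
optional differentiation to tilt the spectrum toward the faster heartbeat
component, resampling to a common rate, [0,1] normalization, and sliding
4-s windows.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .vitalsim import VitalRecord

__all__ = [
    "IqSeries",
    "RangeCube",
    "PhaseSeries",
    "range_fft",
    "select_range_bin",
    "arctan_demodulate",
    "unwrap_phase",
    "bandpass",
    "differentiate",
    "resample_to",
    "normalize_unit",
    "window_stream",
    "preprocess_window",
    "synthetic_range_cube",
]

BAND_DEFAULT = (0.67, 15.0)
ORDER_DEFAULT = 4
VITAL_BAND = (0.1, 2.0)       # slow-time band used to score candidate bins
VALID_RANGE_M = (0.3, 2.0)    # radial interval where a subject may sit


@dataclass
class IqSeries:
    """In-phase / quadrature baseband pair at a common sampling rate."""

    i_channel: np.ndarray
    q_channel: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.i_channel = np.asarray(self.i_channel, dtype=float)
        self.q_channel = np.asarray(self.q_channel, dtype=float)
        if self.i_channel.size != self.q_channel.size:
            raise ValueError("I and Q channels must have equal length")
        if self.fs <= 0:
            raise ValueError("fs must be > 0")


@dataclass
class RangeCube:
    """Complex frames x fast-time matrix (or its fast-time spectrum)."""

    data: np.ndarray            # (n_frames, n_fast)
    frame_rate: float
    range_res_m: float = 1.0    # metres per bin after the range FFT
    spectral: bool = False

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data))
        if self.data.shape[0] < 1 or self.data.shape[1] < 1:
            raise ValueError("cube must contain at least one frame and one "
                             "fast-time sample")


@dataclass
class PhaseSeries:
    """A real phase signal with provenance flags for each pipeline stage."""

    phase: np.ndarray
    fs: float
    unwrapped: bool = False
    filtered: bool = False
    differentiated: bool = False
    normalized: bool = False

    def __post_init__(self) -> None:
        self.phase = np.asarray(self.phase, dtype=float)
        if not np.all(np.isfinite(self.phase)):
            raise ValueError("phase contains non-finite values")

    def replace(self, **kw) -> "PhaseSeries":
        return dataclasses.replace(self, **kw)


from functools import lru_cache


@lru_cache(maxsize=32)
def _butter_sos(order: int, low: float, high: float, fs: float) -> np.ndarray:
    return sps.butter(order, [low, high], btype="bandpass", fs=fs,
                      output="sos")


def range_fft(cube: RangeCube) -> RangeCube:
    """Per-frame DFT along fast time (the range dimension)."""
    if cube.data.shape[1] < 2:
        raise ValueError("need at least 2 fast-time samples per frame")
    spec = np.fft.fft(cube.data, axis=1)
    return RangeCube(spec, cube.frame_rate, cube.range_res_m, spectral=True)


def select_range_bin(spectral: RangeCube, k: int = 3,
                     valid_range_m: tuple[float, float] = VALID_RANGE_M,
                     vital_band: tuple[float, float] = VITAL_BAND) -> int:
    """Pick the chest range bin.

    Among the ``k`` largest peaks of the time-averaged range magnitude inside
    ``valid_range_m``, return the bin whose slow-time phase carries maximal
    band-limited power in ``vital_band`` (a static reflector has a strong
    magnitude but a flat phase; the breathing chest modulates its phase).
    """
    if not spectral.spectral:
        raise ValueError("select_range_bin expects a range-FFT cube")
    if k < 1:
        raise ValueError("k must be >= 1")
    mag = np.abs(spectral.data).mean(axis=0)
    n_bins = mag.size
    rng_m = np.arange(n_bins) * spectral.range_res_m
    valid = (rng_m >= valid_range_m[0]) & (rng_m <= valid_range_m[1])
    if not valid.any() or not np.any(mag[valid] > 0):
        raise ValueError("no spectral peak inside the valid range interval")
    cand = np.flatnonzero(valid)
    cand = cand[np.argsort(mag[cand])[::-1][:k]]
    cand = np.sort(cand)  # deterministic tie handling
    if cand.size == 1 or spectral.data.shape[0] < 8:
        # too few frames to score vitality; fall back to strongest magnitude
        return int(cand[np.argmax(mag[cand])])
    fs = spectral.frame_rate
    lo, hi = vital_band
    hi = min(hi, 0.49 * fs)
    sos = sps.butter(2, [lo, hi], btype="bandpass", fs=fs, output="sos")
    best, best_p = int(cand[0]), -np.inf
    for b in cand:
        ph = np.unwrap(np.angle(spectral.data[:, b]))
        p = float(np.mean(sps.sosfiltfilt(sos, ph - ph.mean()) ** 2))
        if p > best_p:
            best, best_p = int(b), p
    return best


def arctan_demodulate(iq: IqSeries, literal_two_quadrant: bool = False) -> PhaseSeries:
    """Recover the baseband phase from the I/Q pair.

    With I = sin(phi) and Q = cos(phi), the four-quadrant angle of Q + jI
    equals phi over the full circle (default). ``literal_two_quadrant``
    applies atan(I/Q) instead, which folds the angle into (-pi/2, pi/2] and
    is kept only for fidelity checks.
    """
    mag = np.hypot(iq.i_channel, iq.q_channel)
    zero = np.flatnonzero(mag == 0.0)
    if zero.size:
        raise ValueError(f"zero-magnitude I/Q samples at indices "
                         f"{zero[:10].tolist()}")
    if literal_two_quadrant:
        ph = np.arctan(iq.i_channel / iq.q_channel)
    else:
        ph = np.angle(iq.q_channel + 1j * iq.i_channel)
    return PhaseSeries(ph, iq.fs)


def unwrap_phase(p: PhaseSeries) -> PhaseSeries:
    """Remove 2*pi jumps so the phase is continuous."""
    if p.unwrapped:
        raise ValueError("phase is already unwrapped")
    return p.replace(phase=np.unwrap(p.phase), unwrapped=True)


def bandpass(p: PhaseSeries, low: float = BAND_DEFAULT[0],
             high: float = BAND_DEFAULT[1],
             order: int = ORDER_DEFAULT) -> PhaseSeries:
    """Zero-phase Butterworth band-pass.

    Defaults pass the cardiac band and reject the respiratory fundamental
    (<= 0.48 Hz) and DC. Applied forward-backward so beat timing is not
    skewed by group delay. ``high`` is clipped to Nyquist when the signal is
    sampled too slowly for the default 15-Hz edge.
    """
    nyq = p.fs / 2.0
    if high >= nyq:
        high = 0.99 * nyq
    if not (0 < low < high):
        raise ValueError(f"cutoffs ({low}, {high}) invalid for fs={p.fs}")
    sos = _butter_sos(order, low, high, p.fs)
    return p.replace(phase=sps.sosfiltfilt(sos, p.phase), filtered=True)


def differentiate(p: PhaseSeries) -> PhaseSeries:
    """First derivative by central differences (one-sided at the ends).

    Differentiation multiplies a tone of frequency f by 2*pi*f, boosting the
    heartbeat relative to the slower respiration by fh/fr.
    """
    if p.phase.size < 2:
        raise ValueError("need at least 2 samples to differentiate")
    d = np.gradient(p.phase) * p.fs
    return p.replace(phase=d, differentiated=True)


def resample_to(p: PhaseSeries, fs_target: float) -> PhaseSeries:
    """Anti-aliased downsampling to ``fs_target`` (upsampling unsupported)."""
    if fs_target > p.fs:
        raise ValueError("upsampling is not supported")
    if fs_target == p.fs:
        return p.replace()
    from fractions import Fraction
    frac = Fraction(fs_target / p.fs).limit_denominator(1000)
    out = sps.resample_poly(p.phase, frac.numerator, frac.denominator)
    return p.replace(phase=out, fs=fs_target)


def normalize_unit(p: PhaseSeries) -> PhaseSeries:
    """Min-max map to [0, 1]; errors on a constant window."""
    lo, hi = float(p.phase.min()), float(p.phase.max())
    if hi == lo:
        raise ValueError("constant window cannot be normalized")
    return p.replace(phase=(p.phase - lo) / (hi - lo), normalized=True)


def window_stream(p: PhaseSeries, window_s: float = 4.0,
                  stride_s: float = 0.05) -> list[VitalRecord]:
    """Slice a phase series into half-open sliding windows.

    Window count is floor((T - window_s)/stride_s) + 1; a signal shorter
    than one window yields an empty list with a warning.
    """
    n = p.phase.size
    w = int(round(window_s * p.fs))
    s = max(1, int(round(stride_s * p.fs)))
    if w > n:
        warnings.warn("signal shorter than one window; no windows emitted")
        return []
    starts = range(0, n - w + 1, s)
    return [VitalRecord(p.phase[i:i + w], p.fs, w / p.fs, units="rad")
            for i in starts]


def preprocess_window(samples: np.ndarray, fs: float,
                      band: tuple[float, float] = BAND_DEFAULT,
                      order: int = ORDER_DEFAULT,
                      diff: bool = True,
                      normalize: bool = True) -> np.ndarray:
    """Apply the band-pass / differentiate / normalize chain to one window.

    This is the conditioning the network input sees, for measured phase and
    simulated displacement alike (both carry the same vital modulation up to
    a constant scale, which normalization removes).
    """
    p = PhaseSeries(np.asarray(samples, dtype=float), fs, unwrapped=True)
    p = bandpass(p, band[0], band[1], order)
    if diff:
        p = differentiate(p)
    if normalize:
        p = normalize_unit(p)
    return p.phase


def synthetic_range_cube(displacement_mm: np.ndarray, fs: float,
                         target_bin: int, n_bins: int = 16,
                         wavelength: float = 3.9,
                         range_res_m: float = 0.2,
                         static_bins: dict[int, float] | None = None,
                         noise_sd: float = 0.0,
                         seed: int = 0) -> RangeCube:
    """Build a minimal fast-time/slow-time cube with one vibrating scatterer.

    Used to exercise range-bin selection: the target bin carries a unit
    reflector whose phase follows the given displacement; ``static_bins``
    maps extra bin indices to static reflector amplitudes.
    """
    rng = np.random.default_rng(seed)
    n_frames = displacement_mm.size
    phases = 4.0 * np.pi * displacement_mm / wavelength
    n_fast = 2 * n_bins
    t_fast = np.arange(n_fast)
    cube = np.zeros((n_frames, n_fast), dtype=complex)
    # a scatterer at bin b is a fast-time tone at normalized frequency b/n_fast
    cube += np.exp(1j * (2 * np.pi * target_bin * t_fast / n_fast))[None, :] \
        * np.exp(1j * phases)[:, None]
    for b, amp in (static_bins or {}).items():
        cube += amp * np.exp(1j * (2 * np.pi * b * t_fast / n_fast))[None, :]
    if noise_sd > 0:
        cube += noise_sd * (rng.standard_normal(cube.shape)
                            + 1j * rng.standard_normal(cube.shape))
    return RangeCube(cube, fs, range_res_m)
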