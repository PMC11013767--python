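"""Beat-to-beat intervals and the HRV evaluation statistics.

A per-window frequency estimate maps to a beat-to-beat interval (BBI) by
reciprocity, BBI = 1000/fh ms. Against a paired reference series the report
carries the mean BBI, its population SD (SDBB), the detection accuracy HRD
(fraction of windows with relative BBI error within a threshold d, default
2%), the mean absolute error percentage AAEP, the absolute difference of the
mean BBIs APPE, the RMSE, and the success rate P (fraction of windows whose
heart-rate error is within a tolerance, default 4 BPM).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .vitalsim import VitalRecord

__all__ = [
    "BbiSeries",
    "MetricsReport",
    "bbi_from_fh",
    "reference_bbi",
    "sdbb",
    "compute_metrics",
    "write_report",
]

log = logging.getLogger(__name__)

D_DEFAULT = 0.02       # permissible relative BBI error
DELTA_F_DEFAULT = 4.0  # permissible HR error, beats per minute


@dataclass
class BbiSeries:
    """Beat-to-beat intervals (ms), one per analysis window."""

    intervals_ms: np.ndarray
    source: str = "radar"
    window_times_s: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.intervals_ms = np.asarray(self.intervals_ms, dtype=float)
        if np.any(self.intervals_ms <= 0):
            raise ValueError("all intervals must be > 0")
        if self.window_times_s is not None:
            self.window_times_s = np.asarray(self.window_times_s, dtype=float)

    def __len__(self) -> int:
        return self.intervals_ms.size

    @property
    def hr_bpm(self) -> np.ndarray:
        """Heart rate in beats per minute: 60000 / BBI(ms)."""
        return 60000.0 / self.intervals_ms


@dataclass
class MetricsReport:
    """The seven evaluation statistics for a radar-vs-reference pair."""

    mean_bbi_ms: float
    sdbb_ms: float
    hrd_pct: float
    aaep_pct: float
    appe_ms: float
    rmse_ms: float
    success_p_pct: float
    n_windows: int
    threshold_d: float = D_DEFAULT
    delta_f_bpm: float = DELTA_F_DEFAULT

    @property
    def error_pct(self) -> float:
        """Detection error percentage, 100 - HRD."""
        return 100.0 - self.hrd_pct

    def as_dict(self) -> dict:
        return {
            "mean_bbi_ms": self.mean_bbi_ms, "sdbb_ms": self.sdbb_ms,
            "hrd_pct": self.hrd_pct, "aaep_pct": self.aaep_pct,
            "appe_ms": self.appe_ms, "rmse_ms": self.rmse_ms,
            "success_p_pct": self.success_p_pct, "n_windows": self.n_windows,
            "threshold_d": self.threshold_d, "delta_f_bpm": self.delta_f_bpm,
        }


def bbi_from_fh(fh: float | np.ndarray) -> float | np.ndarray:
    """Beat-to-beat interval in ms from a heartbeat frequency in Hz."""
    fh = np.asarray(fh, dtype=float)
    if np.any(fh <= 0):
        raise ValueError("fh must be > 0")
    out = 1000.0 / fh
    return float(out) if out.ndim == 0 else out


def reference_bbi(beat_times_s: "np.ndarray | list[np.ndarray]",
                  windows: "list[tuple[float, float]] | list[VitalRecord] | None" = None,
                  ) -> tuple[BbiSeries, np.ndarray]:
    """Per-window mean beat interval from reference beat times.

    Either pass one beat-time vector plus a list of (start, end) windows /
    VitalRecords, or a list of per-window beat-time vectors with
    ``windows=None``. Returns the valid-window BBI series and a boolean mask
    of which windows had at least 2 beats (invalid windows are excluded and
    logged).
    """
    per_window: list[np.ndarray] = []
    times: list[float] = []
    if windows is None:
        per_window = [np.asarray(b, dtype=float) for b in beat_times_s]
        times = list(np.arange(len(per_window), dtype=float))
    else:
        beats = np.asarray(beat_times_s, dtype=float)
        for w in windows:
            if isinstance(w, VitalRecord):
                lo, hi = 0.0, w.duration
                sel = w.truth_beat_times
                per_window.append(np.asarray(sel, dtype=float)
                                  if sel is not None else np.array([]))
                times.append(lo)
                continue
            lo, hi = w
            per_window.append(beats[(beats >= lo) & (beats < hi)])
            times.append(lo)
    valid = np.array([b.size >= 2 for b in per_window])
    n_bad = int((~valid).sum())
    if n_bad:
        log.warning("excluding %d window(s) with < 2 reference beats", n_bad)
    ivals = np.array([1000.0 * float(np.mean(np.diff(b)))
                      for b, ok in zip(per_window, valid) if ok])
    return (BbiSeries(ivals, source="reference",
                      window_times_s=np.asarray(times)[valid]), valid)


def sdbb(series: BbiSeries, sample: bool = False) -> float:
    """Standard deviation of the BBIs in ms (population divisor N).

    ``sample`` switches to the N-1 divisor.
    """
    if len(series) < 2:
        raise ValueError("need at least 2 intervals")
    return float(np.std(series.intervals_ms, ddof=1 if sample else 0))


def compute_metrics(radar: BbiSeries, refer: BbiSeries,
                    d: float = D_DEFAULT,
                    deltaF: float = DELTA_F_DEFAULT) -> MetricsReport:
    """All seven statistics for paired radar / reference BBI series."""
    if len(radar) == 0 or len(refer) == 0:
        raise ValueError("empty BBI series")
    if len(radar) != len(refer):
        raise ValueError("radar and reference series must be paired 1:1")
    r = radar.intervals_ms
    ref = refer.intervals_ms
    n = r.size
    rel_err = np.abs(r - ref) / ref
    hrd = 100.0 * float(np.mean(rel_err <= d))
    aaep = 100.0 * float(np.mean(rel_err))
    appe = float(abs(r.mean() - ref.mean()))
    rmse = float(np.sqrt(np.mean((r - ref) ** 2)))
    hr_err = np.abs(radar.hr_bpm - refer.hr_bpm)
    p = 100.0 * float(np.mean(hr_err <= deltaF))
    return MetricsReport(
        mean_bbi_ms=float(r.mean()),
        sdbb_ms=sdbb(radar) if n >= 2 else 0.0,
        hrd_pct=hrd, aaep_pct=aaep, appe_ms=appe, rmse_ms=rmse,
        success_p_pct=p, n_windows=n, threshold_d=d, delta_f_bpm=deltaF)


def write_report(reports: "dict[str, MetricsReport] | MetricsReport",
                 path: str) -> pd.DataFrame:
    """Delimited-text report, one row per run/subject."""
    if isinstance(reports, MetricsReport):
        reports = {"run": reports}
    df = pd.DataFrame({k: v.as_dict() for k, v in reports.items()}).T
    df.index.name = "run"
    df.to_csv(path, sep="\t")
    return df
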