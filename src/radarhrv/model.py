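"""Model / Results objects tying the pipeline together.

``HeartRateEstimator`` is constructed from training data (simulated windows
or preprocessed measured windows); ``fit()`` trains the frequency network
and returns a ``HeartRateResults`` carrying the trained network, the loss
history, prediction and evaluation methods, and a ``summary()`` table.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np

from . import freqnet, hrv, preproc, vitalsim
from .freqnet import FrequencyNet, NetConfig, TrainConfig
from .vitalsim import VitalRecord

__all__ = ["HeartRateEstimator", "HeartRateResults", "records_to_matrix"]


def records_to_matrix(records: list[VitalRecord], preprocess: bool = True,
                      diff: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Stack records into a (n, N) design matrix plus truth frequencies.

    With ``preprocess`` each window goes through the band-pass /
    differentiate / [0,1]-normalize conditioning chain; otherwise it is only
    min-max normalized.
    """
    fs = records[0].fs
    X = []
    for r in records:
        if preprocess:
            X.append(preproc.preprocess_window(r.samples, fs, diff=diff))
        else:
            s = r.samples
            rng_ = s.max() - s.min()
            if rng_ == 0:
                raise ValueError("constant window")
            X.append((s - s.min()) / rng_)
    fh = np.array([r.truth_fh if r.truth_fh is not None else np.nan
                   for r in records])
    return np.stack(X), fh


class HeartRateEstimator:
    """Heartbeat-frequency estimation model over 4-s radar windows.

    Parameters
    ----------
    X : (n, N) array
        Conditioned, [0,1]-normalized training windows.
    fh : (n,) array
        True mean heartbeat frequency of each window (Hz).
    net_config : NetConfig, optional
        Architecture; defaults to the 400-sample / [0,2]-Hz / 200-bin setup.
    """

    def __init__(self, X: np.ndarray, fh: np.ndarray,
                 net_config: NetConfig | None = None):
        self.X = np.atleast_2d(np.asarray(X, dtype=float))
        self.fh = np.asarray(fh, dtype=float)
        if self.X.shape[0] != self.fh.size:
            raise ValueError("X and fh must have matching first dimension")
        if np.any(~np.isfinite(self.fh)):
            raise ValueError("fh contains non-finite entries")
        self.net_config = net_config or NetConfig(n_input=self.X.shape[1])
        if self.net_config.n_input != self.X.shape[1]:
            raise ValueError("net_config.n_input does not match X")

    @classmethod
    def from_records(cls, records: list[VitalRecord],
                     net_config: NetConfig | None = None,
                     preprocess: bool = True, diff: bool = True,
                     ) -> "HeartRateEstimator":
        X, fh = records_to_matrix(records, preprocess=preprocess, diff=diff)
        grid = (net_config or NetConfig()).grid
        # drop windows whose truth cannot be labelled on the grid (rare
        # heavy-jitter draws land just above f2)
        keep = np.isfinite(fh) & (fh >= grid.f1) & (fh <= grid.f2)
        return cls(X[keep], fh[keep], net_config=net_config)

    @classmethod
    def from_simulation(cls, n: int, seed: int,
                        snr_range: tuple[float, float] = (5.0, 20.0),
                        fs: float = 100.0, duration: float = 4.0,
                        net_config: NetConfig | None = None,
                        preprocess: bool = True, diff: bool = True,
                        ) -> "HeartRateEstimator":
        recs = vitalsim.sample_dataset(n, seed, snr_range=snr_range, fs=fs,
                                       duration=duration)
        est = cls.from_records(recs, net_config=net_config,
                               preprocess=preprocess, diff=diff)
        est._sim = {"n": n, "seed": seed, "snr_range": snr_range, "fs": fs,
                    "duration": duration, "preprocess": preprocess,
                    "diff": diff}
        return est

    def fit(self, train_config: TrainConfig | None = None,
            X_val: np.ndarray | None = None,
            fh_val: np.ndarray | None = None,
            fresh_per_epoch: bool = False,
            verbose: bool = False) -> "HeartRateResults":
        """Train the network with SGD + MSE on Gaussian spectral labels.

        ``fresh_per_epoch`` (simulation-backed models only) redraws the
        training windows from the simulator every epoch, so the network
        never revisits a window — the simulated population, not a finite
        sample of it, is the training distribution.
        """
        cfg = train_config or TrainConfig()
        net = FrequencyNet(self.net_config)
        data_fn = None
        if fresh_per_epoch:
            sim = getattr(self, "_sim", None)
            if sim is None:
                raise ValueError("fresh_per_epoch requires a model built by "
                                 "from_simulation")

            def data_fn(epoch: int):
                recs = vitalsim.sample_dataset(
                    sim["n"], (sim["seed"] + 7919 * epoch) & 0x7FFFFFFF,
                    snr_range=sim["snr_range"], fs=sim["fs"],
                    duration=sim["duration"])
                X, fh = records_to_matrix(recs, preprocess=sim["preprocess"],
                                          diff=sim["diff"])
                grid = self.net_config.grid
                keep = (np.isfinite(fh) & (fh >= grid.f1)
                        & (fh <= grid.f2))
                return X[keep], fh[keep]

        hist = freqnet.train(net, self.X, self.fh, cfg, X_val=X_val,
                             fh_val=fh_val, data_fn=data_fn, verbose=verbose)
        return HeartRateResults(self, net, cfg, hist)

    def untrained(self) -> "HeartRateResults":
        """Results wrapper around the CZT-initialized (analytic) network."""
        return HeartRateResults(self, FrequencyNet(self.net_config), None,
                                {"train_loss": [], "val_loss": []})


@dataclass
class HeartRateResults:
    """Trained estimator: predictions, metrics, and a summary table."""

    model: HeartRateEstimator
    net: FrequencyNet
    train_config: TrainConfig | None
    history: dict

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Per-window heartbeat-frequency estimates (Hz)."""
        fh, _ = freqnet.predict_fh(self.net, X)
        return fh

    def predict_spectrum(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        return freqnet.predict_fh(self.net, X)

    def evaluate(self, X: np.ndarray, fh_true: np.ndarray,
                 d: float = hrv.D_DEFAULT,
                 deltaF: float = hrv.DELTA_F_DEFAULT) -> hrv.MetricsReport:
        """BBI metrics of the predictions against the true frequencies."""
        fh_hat = self.predict(X)
        radar = hrv.BbiSeries(hrv.bbi_from_fh(fh_hat), source="radar")
        refer = hrv.BbiSeries(hrv.bbi_from_fh(np.asarray(fh_true)),
                              source="reference")
        return hrv.compute_metrics(radar, refer, d=d, deltaF=deltaF)

    def evaluate_records(self, records: list[VitalRecord],
                         preprocess: bool = True, diff: bool = True,
                         **kw) -> hrv.MetricsReport:
        X, fh = records_to_matrix(records, preprocess=preprocess, diff=diff)
        keep = np.isfinite(fh)
        return self.evaluate(X[keep], fh[keep], **kw)

    def summary(self, X_test: np.ndarray | None = None,
                fh_test: np.ndarray | None = None) -> str:
        """Plain-text summary in the spirit of a regression results table."""
        cfg, net = self.model.net_config, self.net
        buf = io.StringIO()
        w = buf.write
        w("Heart-rate frequency network results\n")
        w("=" * 52 + "\n")
        w(f"{'training windows':<28}{self.model.X.shape[0]:>24}\n")
        w(f"{'window length (samples)':<28}{cfg.n_input:>24}\n")
        w(f"{'sampling rate (Hz)':<28}{cfg.fs:>24.1f}\n")
        w(f"{'grid [f1, f2) Hz / bins':<28}"
          f"{f'[{cfg.grid.f1}, {cfg.grid.f2}) / {cfg.grid.M}':>24}\n")
        w(f"{'grid resolution (Hz)':<28}{cfg.grid.df:>24.4f}\n")
        w(f"{'residual groups x RCABs':<28}"
          f"{f'{cfg.n_groups} x {cfg.n_rcab}':>24}\n")
        w(f"{'channels / kernel':<28}{f'{cfg.channels} / {cfg.kernel}':>24}\n")
        n_par = sum(p.data.size for p in net.parameters())
        w(f"{'trainable parameters':<28}{n_par:>24}\n")
        if self.train_config is not None:
            tc = self.train_config
            w(f"{'optimizer':<28}{'SGD + momentum':>24}\n")
            w(f"{'lr / momentum / batch':<28}"
              f"{f'{tc.lr} / {tc.momentum} / {tc.batch_size}':>24}\n")
            w(f"{'epochs / seed':<28}{f'{tc.epochs} / {tc.seed}':>24}\n")
        if self.history.get("train_loss"):
            w(f"{'initial train MSE':<28}"
              f"{self.history['train_loss'][0]:>24.4f}\n")
            w(f"{'final train MSE':<28}"
              f"{self.history['train_loss'][-1]:>24.4f}\n")
        if self.history.get("val_loss"):
            w(f"{'final validation MSE':<28}"
              f"{self.history['val_loss'][-1]:>24.4f}\n")
        if X_test is not None and fh_test is not None:
            rep = self.evaluate(X_test, fh_test)
            w("-" * 52 + "\n")
            w(f"{'test windows':<28}{rep.n_windows:>24}\n")
            w(f"{'HRD (%, d=2%)':<28}{rep.hrd_pct:>24.2f}\n")
            w(f"{'AAEP (%)':<28}{rep.aaep_pct:>24.2f}\n")
            w(f"{'APPE (ms)':<28}{rep.appe_ms:>24.2f}\n")
            w(f"{'RMSE (ms)':<28}{rep.rmse_ms:>24.2f}\n")
            w(f"{'success P (%, 4 BPM)':<28}{rep.success_p_pct:>24.2f}\n")
        w("=" * 52 + "\n")
        return buf.getvalue()

    def save(self, path: str) -> None:
        freqnet.save_checkpoint(self.net, path, self.train_config)

    def plot_spectrum(self, x: np.ndarray, fh_true: float | None = None,
                      ax=None):
        """Plot the normalized output spectrum of one window."""
        import matplotlib.pyplot as plt
        fh_hat, spec = freqnet.predict_fh(self.net, np.atleast_2d(x))
        if ax is None:
            _, ax = plt.subplots()
        f = self.net.cfg.grid.frequencies
        ax.plot(f, spec[0], label="network output")
        ax.axvline(fh_hat[0], color="k", ls="--",
                   label=f"estimate {fh_hat[0]:.2f} Hz")
        if fh_true is not None:
            ax.axvline(fh_true, color="r", ls=":",
                       label=f"truth {fh_true:.2f} Hz")
        ax.set_xlabel("frequency (Hz)")
        ax.set_ylabel("normalized magnitude")
        ax.legend()
        return ax
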