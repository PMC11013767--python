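"""Frequency-representation network with a chirp-Z-transform front end.

The first layer is a fully connected map whose weights are initialized from
the real and imaginary chirp-Z-transform (CZT) sampling kernels, so that
before any training the layer computes a zoomed spectrum of the input window
on an M-point grid over a narrow band [f1, f2]. A magnitude stage, a small
convolutional denoiser, and a residual-in-residual stack of channel-attention
blocks then sharpen that spectrum. Training minimizes the MSE against
Gaussian-shaped spectral labels centred at the true heartbeat frequency,
using plain SGD with momentum.

The residual branches end in zero-initialized convolutions, so an untrained
network reproduces the analytic zoom spectrum exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .autodiff import SGD, Tensor

__all__ = [
    "FrequencyGrid",
    "CztInit",
    "GaussianLabel",
    "NetConfig",
    "TrainConfig",
    "FrequencyNet",
    "build_czt_matrix",
    "gaussian_label",
    "train",
    "predict_fh",
    "fft_baseline",
    "save_checkpoint",
    "load_checkpoint",
]

_MAG_EPS = 1e-12


@dataclass(frozen=True)
class FrequencyGrid:
    """M-point half-open zoom grid over [f1, f2): f_k = f1 + k*(f2-f1)/M."""

    f1: float = 0.0
    f2: float = 2.0
    M: int = 200

    def __post_init__(self) -> None:
        if not self.f1 < self.f2:
            raise ValueError("need f1 < f2")
        if self.M < 2:
            raise ValueError("need M >= 2")

    @property
    def df(self) -> float:
        """Grid resolution (f2 - f1) / M."""
        return (self.f2 - self.f1) / self.M

    @property
    def frequencies(self) -> np.ndarray:
        return self.f1 + np.arange(self.M) * self.df


@dataclass(frozen=True)
class CztInit:
    """Zoom-transform sampling kernel specification.

    With ``spiral_W0 = start_radius_A0 = 1`` the z-plane samples lie on the
    unit-circle arc covering the grid; the per-bin phase increment is
    phi0 = 2*pi*df/fs and the start angle theta0 = 2*pi*f1/fs.
    """

    N: int
    grid: FrequencyGrid
    fs: float
    spiral_W0: float = 1.0
    start_radius_A0: float = 1.0

    def __post_init__(self) -> None:
        if self.grid.f2 > self.fs:
            raise ValueError(
                f"grid end {self.grid.f2} Hz beyond sampling rate {self.fs}")

    @property
    def theta0(self) -> float:
        return 2.0 * np.pi * self.grid.f1 / self.fs

    @property
    def phi0(self) -> float:
        return 2.0 * np.pi * self.grid.df / self.fs


def build_czt_matrix(init: CztInit, literal_phase: bool = False,
                     scale: float | None = None) -> np.ndarray:
    """Real/imaginary zoom-transform kernel, shape (2M, N).

    Rows 0..M-1 hold the cosine (real) kernels, rows M..2M-1 the -sine
    (imaginary) kernels, so that for an input x the complex zoom spectrum is
    ``(W @ x)[:M] + 1j * (W @ x)[M:]``. Row k samples the sinusoid at grid
    frequency f1 + k*df.

    ``literal_phase`` uses the phase indexing n*theta0 + k*phi0 (the
    non-swept form) instead of the frequency sweep n*(theta0 + k*phi0); it
    exists only for fidelity comparisons. ``scale`` multiplies the matrix
    (default 2/N so a unit tone has unit magnitude).
    """
    M, N = init.grid.M, init.N
    n = np.arange(N)[None, :]
    k = np.arange(M)[:, None]
    if literal_phase:
        ang = n * init.theta0 + k * init.phi0
    else:
        ang = n * (init.theta0 + k * init.phi0)
    radial = (init.start_radius_A0 ** (-n)) * (init.spiral_W0 ** (n * k))
    if scale is None:
        scale = 2.0 / N
    W = np.vstack([radial * np.cos(ang), -radial * np.sin(ang)])
    return scale * W


@dataclass(frozen=True)
class GaussianLabel:
    """Gaussian spectral label g(f) = alpha * exp(-(f-fh)^2 / sigma^2).

    ``alpha`` >= 1 penalizes mass away from the true frequency; ``sigma``
    follows the main-lobe rule 2*sigma = P*df (P grid cells at the label's
    one-sigma width) unless given explicitly.
    """

    alpha: float = 20.0
    P: int = 5
    sigma: float | None = None

    def __post_init__(self) -> None:
        if self.alpha < 1.0:
            raise ValueError("alpha must be >= 1")

    def sigma_for(self, grid: FrequencyGrid) -> float:
        return self.sigma if self.sigma is not None else self.P * grid.df / 2.0


def gaussian_label(fh: float, grid: FrequencyGrid,
                   lbl: GaussianLabel | None = None) -> np.ndarray:
    """Evaluate the Gaussian label on the grid; errors if fh is off-grid."""
    lbl = lbl or GaussianLabel()
    if not (grid.f1 <= fh <= grid.f2):
        raise ValueError(f"fh={fh} outside grid [{grid.f1}, {grid.f2}]")
    sig = lbl.sigma_for(grid)
    f = grid.frequencies
    return lbl.alpha * np.exp(-((f - fh) ** 2) / sig ** 2)


@dataclass(frozen=True)
class NetConfig:
    """Architecture of the frequency network.

    The super-resolution stage is ``n_groups`` residual groups of ``n_rcab``
    residual channel-attention blocks each, with 1-D convolutions of width
    ``kernel`` over the frequency-bin axis and squeeze ratio ``reduction``
    in the attention bottleneck.
    """

    n_input: int = 400
    fs: float = 100.0
    grid: FrequencyGrid = field(default_factory=FrequencyGrid)
    channels: int = 16
    kernel: int = 3
    n_groups: int = 2
    n_rcab: int = 3
    reduction: int = 4
    # RCAB conv dilations, cycled within each group: widely spaced taps let
    # the stack relate spectral peaks a respiratory-harmonic spacing apart
    # (up to ~0.5 Hz = 50 bins) without large kernels
    dilations: tuple[int, ...] = (1, 4, 16)
    train_dt: bool = True          # domain-transform weights trainable?
    spiral_W0: float = 1.0
    init_seed: int = 0


@dataclass(frozen=True)
class TrainConfig:
    """SGD + MSE training hyper-parameters."""

    lr: float = 0.01
    momentum: float = 0.9
    batch_size: int = 64
    epochs: int = 50
    clip_norm: float = 1.0         # per-parameter gradient-norm clip
                                   # (0 disables); keeps any one layer from
                                   # monopolizing the step
    keep_best: bool = True         # restore the best-validation-loss weights
                                   # at the end (needs a validation set)
    seed: int = 0
    label: GaussianLabel = field(default_factory=GaussianLabel)

    def __post_init__(self) -> None:
        if self.lr <= 0 or self.batch_size <= 0 or self.epochs <= 0:
            raise ValueError("rates and sizes must be positive")


def _he(rng: np.random.Generator, shape: tuple[int, ...],
        fan_in: int) -> np.ndarray:
    return rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)


class FrequencyNet:
    """Domain transform + residual-in-residual channel-attention refiner."""

    def __init__(self, cfg: NetConfig):
        self.cfg = cfg
        M, N, C, K = cfg.grid.M, cfg.n_input, cfg.channels, cfg.kernel
        rng = np.random.default_rng(cfg.init_seed)
        czt = build_czt_matrix(
            CztInit(N, cfg.grid, cfg.fs, spiral_W0=cfg.spiral_W0))
        # stored transposed: forward is x (B,N) @ W_dt (N,2M)
        self.W_dt = Tensor(czt.T.copy(), requires_grad=cfg.train_dt)

        def conv_param(cout, cin, zero=False):
            # channels-last conv weights: (K, cin, cout)
            w = (np.zeros((K, cin, cout)) if zero
                 else _he(rng, (K, cin, cout), cin * K))
            return Tensor(w, requires_grad=True), Tensor(
                np.zeros(cout), requires_grad=True)

        # domain-transform conv stage (residual, zero-init tail)
        self.dt_c1 = conv_param(C, 1)
        self.dt_c2 = conv_param(1, C, zero=True)
        # super-resolution stage
        self.head = conv_param(C, 1)
        self.groups = []
        for _ in range(cfg.n_groups):
            rcabs = []
            for i in range(cfg.n_rcab):
                ca_w1 = Tensor(_he(rng, (C, C // cfg.reduction), C),
                               requires_grad=True)
                ca_w2 = Tensor(_he(rng, (C // cfg.reduction, C),
                                   C // cfg.reduction), requires_grad=True)
                rcabs.append({"c1": conv_param(C, C), "c2": conv_param(C, C),
                              "ca1": ca_w1, "ca2": ca_w2,
                              "dilation": cfg.dilations[
                                  i % len(cfg.dilations)]})
            self.groups.append({"rcabs": rcabs, "tail": conv_param(C, C)})
        self.body_tail = conv_param(C, C)
        self.out_conv = conv_param(1, C, zero=True)

    # ------------------------------------------------------------- plumbing
    def parameters(self) -> list[Tensor]:
        ps = [self.dt_c1[0], self.dt_c1[1], self.dt_c2[0], self.dt_c2[1],
              self.head[0], self.head[1], self.body_tail[0],
              self.body_tail[1], self.out_conv[0], self.out_conv[1]]
        if self.cfg.train_dt:
            ps.insert(0, self.W_dt)
        for g in self.groups:
            for r in g["rcabs"]:
                ps += [r["c1"][0], r["c1"][1], r["c2"][0], r["c2"][1],
                       r["ca1"], r["ca2"]]
            ps += [g["tail"][0], g["tail"][1]]
        return ps

    # -------------------------------------------------------------- forward
    def domain_transform(self, x: Tensor, conv: bool = True,
                         normalize: bool | None = None) -> Tensor:
        """Zoom-spectrum magnitude of the input, optionally conv-refined.

        Input (B, N) -> magnitude (B, M, 1); with ``conv`` the residual
        denoising conv pair of the domain-transform module is applied.
        ``normalize`` (default: same as ``conv``) divides each window's
        spectrum by its mean over bins — the scale the rest of the network
        expects; the analytic path returns the raw magnitude.
        """
        M = self.cfg.grid.M
        # the [0,1] normalization reintroduces a constant offset that carries
        # no vital information; remove it so the DC bin does not swamp the
        # zoom spectrum
        x = x - x.mean(axis=1, keepdims=True)
        y = x @ self.W_dt                      # (B, 2M)
        yR = y.slice((slice(None), slice(0, M)))
        yI = y.slice((slice(None), slice(M, 2 * M)))
        mag = (yR.square() + yI.square()).sqrt(eps=_MAG_EPS)
        mag = mag.reshape(-1, M, 1)
        if normalize is None:
            normalize = conv
        if normalize:
            # per-window spectral normalization: a common scale regardless of
            # input amplitude; a lone peak over M bins then reaches
            # O(M/peak-width), commensurate with the Gaussian label amplitude
            mag = mag * mag.mean(axis=(1, 2), keepdims=True).reciprocal()
        if not conv:
            return mag
        h = mag.conv1d(*self.dt_c1).relu()
        return mag + h.conv1d(*self.dt_c2)

    def _rcab(self, x: Tensor, r: dict) -> Tensor:
        dil = r["dilation"]
        b = x.conv1d(*r["c1"], dilation=dil).relu().conv1d(*r["c2"],
                                                           dilation=dil)
        # channel attention: squeeze over bins, 2-layer bottleneck, sigmoid
        z = b.mean(axis=1)                     # (B, C)
        s = (z @ r["ca1"]).relu() @ r["ca2"]
        s = s.sigmoid().reshape(-1, 1, self.cfg.channels)
        return x + b * s

    def forward(self, x: Tensor | np.ndarray) -> Tensor:
        """Full network: (B, N) normalized windows -> (B, M) spectrum."""
        if not isinstance(x, Tensor):
            x = Tensor(np.atleast_2d(x))
        if x.shape[-1] != self.cfg.n_input:
            raise ValueError(f"input length {x.shape[-1]} != "
                             f"{self.cfg.n_input}")
        d = self.domain_transform(x)           # (B, M, 1)
        f0 = d.conv1d(*self.head)              # (B, M, C)
        f = f0
        for g in self.groups:
            h = f
            for r in g["rcabs"]:
                h = self._rcab(h, r)
            f = f + h.conv1d(*g["tail"])       # short skip around the group
        body = f0 + f.conv1d(*self.body_tail)  # long skip around all groups
        out = d + body.conv1d(*self.out_conv)  # (B, M, 1)
        return out.reshape(-1, self.cfg.grid.M)

    __call__ = forward


def train(model: FrequencyNet, X: np.ndarray, fh: np.ndarray,
          cfg: TrainConfig, X_val: np.ndarray | None = None,
          fh_val: np.ndarray | None = None,
          data_fn=None, verbose: bool = False) -> dict:
    """Mini-batch SGD on the MSE against Gaussian labels.

    ``data_fn(epoch) -> (X, fh)``, when given, replaces the training windows
    at the start of every epoch (streaming freshly simulated data instead of
    revisiting a fixed set). Returns a history dict with per-epoch mean
    training loss (and validation loss when a validation set is given).
    Aborts with a diagnostic if the loss diverges.
    """
    grid = model.cfg.grid
    X = np.asarray(X, dtype=float)
    labels = np.stack([gaussian_label(f, grid, cfg.label) for f in fh])
    val_labels = None
    if X_val is not None and fh_val is not None:
        val_labels = np.stack(
            [gaussian_label(f, grid, cfg.label) for f in fh_val])
    rng = np.random.default_rng(cfg.seed)
    opt = SGD(model.parameters(), lr=cfg.lr, momentum=cfg.momentum)
    n = X.shape[0]
    hist: dict = {"train_loss": [], "val_loss": []}
    for epoch in range(cfg.epochs):
        if data_fn is not None and epoch > 0:
            X, fh = data_fn(epoch)
            X = np.asarray(X, dtype=float)
            labels = np.stack(
                [gaussian_label(f, grid, cfg.label) for f in fh])
            n = X.shape[0]
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            xb = Tensor(X[idx])
            yb = labels[idx]
            pred = model.forward(xb)
            diff = pred - Tensor(yb)
            loss = diff.square().mean()
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"training diverged at epoch {epoch} (loss={loss.data})")
            opt.zero_grad()
            loss.backward()
            if cfg.clip_norm > 0:
                for p in opt.params:
                    if p.grad is None:
                        continue
                    gn = float(np.sqrt((p.grad ** 2).sum()))
                    if gn > cfg.clip_norm:
                        p.grad *= cfg.clip_norm / gn
            opt.step()
            losses.append(float(loss.data))
        hist["train_loss"].append(float(np.mean(losses)))
        if val_labels is not None:
            pv = model.forward(Tensor(X_val)).data
            vl = float(np.mean((pv - val_labels) ** 2))
            hist["val_loss"].append(vl)
            if cfg.keep_best and vl <= min(hist["val_loss"]):
                best_state = [p.data.copy() for p in model.parameters()]
                hist["best_epoch"] = epoch + 1
        if verbose:
            msg = f"epoch {epoch + 1}/{cfg.epochs} train={hist['train_loss'][-1]:.4f}"
            if val_labels is not None:
                msg += f" val={hist['val_loss'][-1]:.4f}"
            print(msg)
    if cfg.keep_best and val_labels is not None:
        # model selection: keep the weights from the best-validation epoch
        for p, d in zip(model.parameters(), best_state):
            p.data[...] = d
    return hist


def evaluate_loss(model: FrequencyNet, X: np.ndarray, fh: np.ndarray,
                  label: GaussianLabel | None = None) -> float:
    """Mean MSE of the network output against the Gaussian labels."""
    labels = np.stack([gaussian_label(f, model.cfg.grid,
                                      label or GaussianLabel()) for f in fh])
    pred = model.forward(Tensor(np.asarray(X, dtype=float))).data
    return float(np.mean((pred - labels) ** 2))


def predict_fh(model: FrequencyNet, x: np.ndarray) -> tuple[np.ndarray,
                                                            np.ndarray]:
    """Estimated heartbeat frequency per window plus the output spectrum.

    The spectrum is min-max normalized for reporting; the estimate is the
    grid frequency of its global argmax (ties resolve to the lowest bin).
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    spec = model.forward(Tensor(x)).data
    rng_ = spec.max(axis=1, keepdims=True) - spec.min(axis=1, keepdims=True)
    if np.any(rng_ == 0):
        raise ValueError("degenerate (constant) output spectrum")
    norm = (spec - spec.min(axis=1, keepdims=True)) / rng_
    fh = model.cfg.grid.frequencies[np.argmax(norm, axis=1)]
    return fh, norm


def fft_baseline(x: np.ndarray, fs: float,
                 band: tuple[float, float] = (0.67, 2.0),
                 pad_to_df: float = 0.01) -> float:
    """Classical estimator: argmax of the zero-padded DFT magnitude in band.

    A 4-s window has a native resolution of 0.25 Hz; zero padding refines
    the spectral grid to ``pad_to_df`` (interpolation of the same spectrum,
    not extra information).
    """
    x = np.asarray(x, dtype=float)
    if band[1] > fs / 2:
        raise ValueError("band beyond Nyquist")
    n_pad = max(x.size, int(round(fs / pad_to_df)))
    spec = np.abs(np.fft.rfft(x - x.mean(), n=n_pad))
    freqs = np.fft.rfftfreq(n_pad, d=1.0 / fs)
    sel = (freqs >= band[0]) & (freqs <= band[1])
    return float(freqs[sel][np.argmax(spec[sel])])


# ------------------------------------------------------------- persistence
def _flat_params(model: FrequencyNet) -> dict[str, np.ndarray]:
    out = {"W_dt": model.W_dt.data}
    out["dt_c1.w"], out["dt_c1.b"] = (t.data for t in model.dt_c1)
    out["dt_c2.w"], out["dt_c2.b"] = (t.data for t in model.dt_c2)
    out["head.w"], out["head.b"] = (t.data for t in model.head)
    for gi, g in enumerate(model.groups):
        for ri, r in enumerate(g["rcabs"]):
            p = f"g{gi}.r{ri}"
            out[f"{p}.c1.w"], out[f"{p}.c1.b"] = (t.data for t in r["c1"])
            out[f"{p}.c2.w"], out[f"{p}.c2.b"] = (t.data for t in r["c2"])
            out[f"{p}.ca1"] = r["ca1"].data
            out[f"{p}.ca2"] = r["ca2"].data
        out[f"g{gi}.tail.w"], out[f"g{gi}.tail.b"] = (t.data
                                                      for t in g["tail"])
    out["body_tail.w"], out["body_tail.b"] = (t.data for t in model.body_tail)
    out["out_conv.w"], out["out_conv.b"] = (t.data for t in model.out_conv)
    return out


def save_checkpoint(model: FrequencyNet, path: str,
                    train_cfg: TrainConfig | None = None) -> None:
    """Weights plus full architecture / training config in one npz file."""
    import json
    meta = {"net": dataclasses.asdict(model.cfg)}
    if train_cfg is not None:
        meta["train"] = dataclasses.asdict(train_cfg)
    np.savez(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **_flat_params(model))


def load_checkpoint(path: str) -> FrequencyNet:
    import json
    with np.load(path) as z:
        meta = json.loads(bytes(z["__meta__"]).decode())
        nc = meta["net"]
        nc["grid"] = FrequencyGrid(**nc["grid"])
        if "dilations" in nc:
            nc["dilations"] = tuple(nc["dilations"])
        model = FrequencyNet(NetConfig(**nc))
        params = _flat_params(model)
        for k, arr in params.items():
            arr[...] = z[k]
    return model
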