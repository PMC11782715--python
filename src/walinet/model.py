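"""Y-Net nuisance-signal identification network.

The network Y maps two spectral inputs to one output of the same
length:

    Y(x1, x2) = D(E1(x1), E2(x2)) = y ~= l + w,     m~ = x1 - y,

where x1 = m + l + w is the contaminated spectrum and
x2 = (1 - L) x1 its projection onto the lipid subspace.  Each encoder
and the decoder consist of four convolutional blocks (two same-padded
convolutions of kernel size 7, each followed by PReLU and dropout 0.01)
separated by max-pooling / linear-upsampling with factor 2; channels
start at 16 and double after every pooling (halve after upsampling).
One extra block sits in the bottleneck, where the two encoder streams
are concatenated, and one after the decoder.  Skip connections from
both encoders are channel-concatenated into the decoder at matching
scales.  Complex spectra travel through the network as separate real
and imaginary channels.

Training follows the published recipe: a shared random phase e^{i w}
multiplies x1, x2 and the target of every example (online
augmentation); each pair is normalized by the root-sum-squared
difference E = ||x1 - x2|| which approximates the energy of the
non-lipid signal; the loss is the MSE between the network output and
the normalized target on the separated real/imaginary channels; Adam
with learning rate 0.01 quartered every 50 epochs (the quartering
interval scales with the epoch budget for scaled presets).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from . import nn
from .axis import SpectralAxis
from .lipid_l2 import LipidSubspace, lipid_project
from .spectrum import Spectrum

__all__ = [
    "YNetConfig",
    "TrainConfig",
    "YNet",
    "build_ynet",
    "normalize_pair",
    "augment_phase",
    "train",
    "infer_nuisance",
    "learning_rate",
]


@dataclass(frozen=True)
class YNetConfig:
    """Architecture hyperparameters (defaults mirror the published net)."""

    depth: int = 4
    base_channels: int = 16
    kernel_size: int = 7
    dropout_rate: float = 0.01
    pool_factor: int = 2
    in_channels: int = 2  # real, imaginary
    out_channels: int = 2
    upsample: str = "linear"  # or "nearest"

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.base_channels < 1:
            raise ValueError("base_channels must be >= 1")
        if self.kernel_size < 1 or self.kernel_size % 2 == 0:
            raise ValueError("kernel_size must be a positive odd integer")
        if self.pool_factor != 2:
            raise ValueError("only pool_factor 2 is supported")
        if self.upsample not in ("linear", "nearest"):
            raise ValueError("upsample must be 'linear' or 'nearest'")

    @property
    def encoder_channels(self) -> list[int]:
        return [self.base_channels * 2**i for i in range(self.depth)]


@dataclass
class TrainConfig:
    """Optimization hyperparameters.

    The published schedule is 400 epochs at lr 0.01 quartered every 50
    epochs; ``lr_decay_every`` defaults to ``max(1, epochs * 50 // 400)``
    so scaled epoch budgets keep the same schedule shape.
    """

    epochs: int = 400
    lr: float = 0.01
    lr_decay: float = 0.25
    lr_decay_every: int | None = None
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    batch_size: int = 64
    seed: int = 0
    mode: str = "walinet"  # or "lipnet"
    val_fraction: float = 0.1
    eps: float = 1e-12
    grad_clip: float = 1.0  # global gradient-norm clip; 0 disables

    def __post_init__(self) -> None:
        if self.mode not in ("walinet", "lipnet"):
            raise ValueError("mode must be 'walinet' or 'lipnet'")
        if self.lr_decay_every is None:
            self.lr_decay_every = max(1, self.epochs * 50 // 400)


def learning_rate(config: TrainConfig, epoch: int) -> float:
    return config.lr * config.lr_decay ** (epoch // config.lr_decay_every)


# ----------------------------------------------------------------------
# network
# ----------------------------------------------------------------------

class _ConvBlock:
    """conv -> PReLU -> dropout, twice."""

    def __init__(self, cin: int, cout: int, k: int, rate: float,
                 rng: np.random.Generator, dtype):
        def make_conv(ci, co):
            bound = 1.0 / np.sqrt(ci * k)
            w = nn.Parameter(rng.uniform(-bound, bound, (co, ci, k)).astype(dtype))
            b = nn.Parameter(rng.uniform(-bound, bound, co).astype(dtype))
            return w, b

        self.w1, self.b1 = make_conv(cin, cout)
        self.w2, self.b2 = make_conv(cout, cout)
        self.a1 = nn.Parameter(np.full(cout, 0.25, dtype=dtype))
        self.a2 = nn.Parameter(np.full(cout, 0.25, dtype=dtype))
        self.rate = rate

    def params(self) -> list[nn.Parameter]:
        return [self.w1, self.b1, self.a1, self.w2, self.b2, self.a2]

    def __call__(self, x, rng, training):
        x = nn.dropout(nn.prelu(nn.conv1d(x, self.w1, self.b1), self.a1),
                       self.rate, rng, training)
        x = nn.dropout(nn.prelu(nn.conv1d(x, self.w2, self.b2), self.a2),
                       self.rate, rng, training)
        return x


class YNet:
    """Two-encoder, one-decoder 1-D convolutional network."""

    def __init__(self, config: YNetConfig, seed: int = 0, dtype=np.float32):
        self.config = config
        self.dtype = dtype
        rng = np.random.default_rng(seed)
        c = config.encoder_channels
        k, r = config.kernel_size, config.dropout_rate

        def blocks(cin):
            chain, prev = [], cin
            for ch in c:
                chain.append(_ConvBlock(prev, ch, k, r, rng, dtype))
                prev = ch
            return chain

        self.enc1 = blocks(config.in_channels)
        self.enc2 = blocks(config.in_channels)
        self.bottleneck = _ConvBlock(2 * c[-1], c[-1], k, r, rng, dtype)
        # decoder: upsample, concat skips from both encoders, conv block
        self.dec = []
        prev = c[-1]
        for i in range(config.depth - 1, -1, -1):
            cout = max(c[i] // 2, config.base_channels)
            self.dec.append(_ConvBlock(prev + 2 * c[i], cout, k, r, rng, dtype))
            prev = cout
        self.final = _ConvBlock(prev, prev, k, r, rng, dtype)
        bound = 1.0 / np.sqrt(prev * k)
        self.out_w = nn.Parameter(
            rng.uniform(-bound, bound, (config.out_channels, prev, k)).astype(dtype)
        )
        self.out_b = nn.Parameter(
            rng.uniform(-bound, bound, config.out_channels).astype(dtype)
        )

    # -- parameters ---------------------------------------------------
    def parameters(self) -> list[nn.Parameter]:
        ps: list[nn.Parameter] = []
        for blk in (*self.enc1, *self.enc2, self.bottleneck, *self.dec, self.final):
            ps.extend(blk.params())
        ps.extend([self.out_w, self.out_b])
        return ps

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def state_dict(self) -> dict[str, np.ndarray]:
        return {f"p{i}": p.data for i, p in enumerate(self.parameters())}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.parameters()):
            arr = np.asarray(state[f"p{i}"], dtype=self.dtype)
            if arr.shape != p.data.shape:
                raise ValueError(f"parameter p{i} has shape {arr.shape}, "
                                 f"expected {p.data.shape}")
            p.data = arr.copy()

    # -- forward ------------------------------------------------------
    def _padded_length(self, length: int) -> int:
        div = self.config.pool_factor ** self.config.depth
        return ((length + div - 1) // div) * div

    def forward(
        self,
        x1: np.ndarray,
        x2: np.ndarray,
        training: bool = False,
        rng: np.random.Generator | None = None,
    ) -> nn.Tensor:
        """Map (B, 2, L) input pairs to a (B, 2, L) output."""
        if x1.shape != x2.shape or x1.ndim != 3:
            raise ValueError("x1 and x2 must share shape (batch, channels, length)")
        rng = rng or np.random.default_rng()
        length = x1.shape[2]
        pad = self._padded_length(length) - length
        up = nn.upsample_linear2 if self.config.upsample == "linear" else nn.upsample_nearest2

        def encode(x, chain):
            t = nn.pad_right(nn.Tensor(np.ascontiguousarray(x, dtype=self.dtype)), pad)
            skips = []
            for blk in chain:
                t = blk(t, rng, training)
                skips.append(t)
                t = nn.maxpool2(t)
            return t, skips

        t1, skips1 = encode(x1, self.enc1)
        t2, skips2 = encode(x2, self.enc2)
        t = self.bottleneck(nn.concat([t1, t2]), rng, training)
        for blk, s1, s2 in zip(self.dec, skips1[::-1], skips2[::-1]):
            t = blk(nn.concat([up(t), s1, s2]), rng, training)
        t = self.final(t, rng, training)
        t = nn.conv1d(t, self.out_w, self.out_b)
        return nn.crop_right(t, length)

    def predict(self, x1: np.ndarray, x2: np.ndarray) -> np.ndarray:
        return self.forward(x1, x2, training=False).data


def build_ynet(config: YNetConfig | None = None, seed: int = 0) -> YNet:
    """Construct a randomly initialized Y-Net."""
    return YNet(config or YNetConfig(), seed=seed)


# ----------------------------------------------------------------------
# data plumbing
# ----------------------------------------------------------------------

def normalize_pair(
    x1: np.ndarray, x2: np.ndarray, eps: float = 1e-12
) -> tuple[np.ndarray, np.ndarray, float]:
    """Scale a spectrum pair by E = ||x1 - x2|| (root-sum-squared).

    Returns the normalized pair and E, which the caller keeps to undo
    the scaling after inference.  An eps floor guards x1 == x2.
    """
    x1 = np.asarray(x1)
    x2 = np.asarray(x2)
    if x1.shape != x2.shape:
        raise ValueError("x1 and x2 must have equal length")
    e = float(np.linalg.norm(x1 - x2))
    d = max(e, eps)
    return x1 / d, x2 / d, e


def augment_phase(
    arrays: tuple[np.ndarray, ...],
    rng: np.random.Generator | None = None,
    omega: float | None = None,
) -> tuple[tuple[np.ndarray, ...], float]:
    """Multiply every array by one shared random phase e^{i omega}.

    omega ~ U[0, 2 pi) unless given explicitly.  Magnitudes are
    unchanged; the network must therefore learn phase-equivariant
    behavior.
    """
    if omega is None:
        rng = rng or np.random.default_rng()
        omega = float(rng.uniform(0.0, 2.0 * np.pi))
    phase = np.exp(1j * omega)
    return tuple(a * phase for a in arrays), omega


def _to_channels(z: np.ndarray, dtype=np.float32) -> np.ndarray:
    """(B, L) complex -> (B, 2, L) real/imaginary channels."""
    return np.stack([z.real, z.imag], axis=1).astype(dtype)


def _from_channels(x: np.ndarray) -> np.ndarray:
    return x[:, 0, :].astype(np.float64) + 1j * x[:, 1, :].astype(np.float64)


# ----------------------------------------------------------------------
# training
# ----------------------------------------------------------------------

def _prepare_batch(x1, x2, y, rng, eps, dtype):
    """Phase-augment and normalize a complex batch; return channel arrays."""
    batch = x1.shape[0]
    omegas = rng.uniform(0.0, 2.0 * np.pi, size=batch)
    phases = np.exp(1j * omegas)[:, None]
    x1p, x2p, yp = x1 * phases, x2 * phases, y * phases
    e = np.linalg.norm(x1p - x2p, axis=1)
    e = np.maximum(e, eps)[:, None]
    return (
        _to_channels(x1p / e, dtype),
        _to_channels(x2p / e, dtype),
        _to_channels(yp / e, dtype),
    )


def train(
    network: YNet,
    dataset,
    config: TrainConfig,
    callback=None,
) -> tuple[YNet, list[dict]]:
    """Train in place; returns the network and per-epoch loss history.

    ``dataset`` provides complex arrays ``x1, x2`` and targets via
    ``dataset.arrays(mode)`` -> (x1, x2, y) plus ``subject_ids``; the
    validation split is subject-wise so no synthetic subject appears in
    both partitions.
    """
    x1, x2, y = dataset.arrays(config.mode)
    subjects = np.asarray(dataset.subject_ids)
    if x1.shape[0] == 0:
        raise ValueError("dataset is empty")
    rng = np.random.default_rng(config.seed)
    train_idx, val_idx = _subject_split(subjects, config.val_fraction, rng)
    opt = nn.Adam(
        network.parameters(),
        lr=config.lr,
        beta1=config.adam_beta1,
        beta2=config.adam_beta2,
    )
    history: list[dict] = []
    for epoch in range(config.epochs):
        opt.lr = learning_rate(config, epoch)
        order = rng.permutation(train_idx)
        total, count = 0.0, 0
        for start in range(0, order.size, config.batch_size):
            sel = order[start : start + config.batch_size]
            b1, b2, by = _prepare_batch(
                x1[sel], x2[sel], y[sel], rng, config.eps, network.dtype
            )
            out = network.forward(b1, b2, training=True, rng=rng)
            loss = nn.mse_loss(out, by)
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}: {loss.data!r}"
                )
            opt.zero_grad()
            loss.backward()
            if config.grad_clip > 0:
                _clip_gradients(network.parameters(), config.grad_clip)
            opt.step()
            total += float(loss.data) * sel.size
            count += sel.size
        record = {
            "epoch": epoch,
            "lr": opt.lr,
            "train_loss": total / max(count, 1),
            "val_loss": _evaluate_loss(network, x1, x2, y, val_idx, config),
        }
        history.append(record)
        if callback is not None:
            callback(record)
    return network, history


def _clip_gradients(params, max_norm: float) -> None:
    total = np.sqrt(sum(float(np.sum(p.grad**2)) for p in params if p.grad is not None))
    if total > max_norm:
        scale = max_norm / total
        for p in params:
            if p.grad is not None:
                p.grad *= scale


def _subject_split(subjects, val_fraction, rng):
    unique = np.unique(subjects)
    if unique.size > 1 and val_fraction > 0:
        n_val = max(1, int(round(val_fraction * unique.size)))
        val_subj = set(rng.choice(unique, size=n_val, replace=False).tolist())
        val = np.flatnonzero([s in val_subj for s in subjects])
        tr = np.flatnonzero([s not in val_subj for s in subjects])
        return tr, val
    return np.arange(len(subjects)), np.array([], dtype=int)


def _evaluate_loss(network, x1, x2, y, idx, config) -> float:
    if idx.size == 0:
        return float("nan")
    rng = np.random.default_rng(config.seed + 1)
    total, count = 0.0, 0
    for start in range(0, idx.size, config.batch_size):
        sel = idx[start : start + config.batch_size]
        b1, b2, by = _prepare_batch(
            x1[sel], x2[sel], y[sel], rng, config.eps, network.dtype
        )
        out = network.forward(b1, b2, training=False)
        total += float(np.mean((out.data - by) ** 2)) * sel.size
        count += sel.size
    return total / count


# ----------------------------------------------------------------------
# inference
# ----------------------------------------------------------------------

def infer_nuisance(
    network: YNet, x1: Spectrum, sub: LipidSubspace, eps: float = 1e-12
) -> tuple[Spectrum, Spectrum]:
    """Predict the nuisance spectrum y ~= l + w and return (y, m~).

    Computes x2 = (1 - L) x1, normalizes the pair by E, runs the
    network, undoes the normalization, and subtracts: m~ = x1 - y.
    """
    if x1.axis != sub.axis:
        raise ValueError("spectrum axis does not match the lipid subspace axis")
    x1f = x1.to_freq().data
    y = infer_nuisance_batch(network, x1f[None, :], sub, eps)[0]
    y_spec = Spectrum(y, sub.axis, "freq")
    return y_spec, Spectrum(x1f - y, sub.axis, "freq")


def infer_nuisance_batch(
    network: YNet,
    x1: np.ndarray,
    sub: LipidSubspace,
    eps: float = 1e-12,
    batch_size: int = 256,
) -> np.ndarray:
    """Vectorized inference on an (n, n_points) complex array of spectra."""
    x2 = sub.project(x1.T).T
    e = np.maximum(np.linalg.norm(x1 - x2, axis=1), eps)[:, None]
    out = np.empty_like(x1)
    for start in range(0, x1.shape[0], batch_size):
        stop = start + batch_size
        b1 = _to_channels(x1[start:stop] / e[start:stop], network.dtype)
        b2 = _to_channels(x2[start:stop] / e[start:stop], network.dtype)
        out[start:stop] = _from_channels(network.predict(b1, b2)) * e[start:stop]
    return out


# ----------------------------------------------------------------------
# persistence
# ----------------------------------------------------------------------

def save_checkpoint(path, network: YNet, train_config: TrainConfig | None = None,
                    axis: SpectralAxis | None = None, history=None) -> None:
    """npz checkpoint plus a JSON sidecar with configs and axis metadata."""
    import pathlib

    path = pathlib.Path(path)
    np.savez(path, **network.state_dict())
    meta = {"ynet": asdict(network.config)}
    if train_config is not None:
        meta["train"] = asdict(train_config)
    if axis is not None:
        meta["axis"] = {
            "n_points": axis.n_points,
            "bandwidth_hz": axis.bandwidth_hz,
            "carrier_ppm": axis.carrier_ppm,
            "field_mhz": axis.field_mhz,
        }
    if history is not None:
        meta["history"] = history
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_checkpoint(path) -> tuple[YNet, dict]:
    import pathlib

    path = pathlib.Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    network = YNet(YNetConfig(**meta["ynet"]))
    with np.load(path if path.suffix == ".npz" else path.with_suffix(".npz")) as st:
        network.load_state_dict(dict(st))
    return network, meta
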