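"""Unrolled convolutional-recurrent network for undersampled DWI reconstruction.

The reconstruction is an N-fold unrolled iteration

    X_rec^(i) = DC( X_rec^(i-1) + CRNN(X_rec^(i-1)); X_u, y )

starting from the zero-filled image series X_u.  The CRNN box stacks, in
order: one bidirectional CRNN-b-i layer whose hidden state evolves over both
the b-value sequence and the unrolled iteration, three CRNN-i layers whose
hidden state evolves over the iteration only, and one plain linear CNN layer
projecting back to 2 channels (real, imaginary).  All convolutions are
same-padded with a shared odd kernel size; hidden states are zero at
iteration 0 and at both sequence boundaries.

Layer recursions (ReLU activations):

    CRNN-i:    H_l^(i)   = ReLU(Wc * H_{l-1}^(i) + Wr * H_l^(i-1) + B_l)
    CRNN-b-i:  H_b^(i)-> = ReLU(Wc * H_in,b + Wb * H_{b-1}^(i)-> + Wr * H_b^(i-1) + B->)
               H_b^(i)<- = ReLU(Wc * H_in,b + Wb * H_{b+1}^(i)<- + Wr * H_b^(i-1) + B<-)
               H_b^(i)   = H_b^(i)-> + H_b^(i)<-

Wc, Wb, Wr are shared between the two directions; only the biases differ.
Weights are shared across the N unrolled iterations by default (the Wr
recurrence implements iteration evolution); independent per-iteration
weights are available behind a config flag.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .kspace import KSpaceFrameSet, SamplingMask, kspace_to_image
from .scheme import BValueScheme
from .series import DWISeries

__all__ = [
    "NetworkConfig",
    "CRNNModel",
    "ReconResult",
    "crnn_i_step",
    "crnn_b_i_step",
    "crnn_block",
    "reconstruct",
    "train",
]

N_CRNN_I_LAYERS = 3


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture hyperparameters (none are prescribed by the model; all
    are exposed and recorded with every checkpoint)."""

    n_iterations: int = 5
    n_hidden: int = 64
    kernel_size: int = 3
    share_across_iterations: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.n_hidden < 1:
            raise ValueError("n_hidden must be >= 1")
        if self.kernel_size % 2 != 1:
            raise ValueError("kernel_size must be odd")


def _uniform_fan_in(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    fan_in = int(np.prod(shape[1:]))
    bound = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=shape).astype(np.float32)


def _init_layer_stack(config: NetworkConfig, rng: np.random.Generator) -> dict[str, Tensor]:
    """One CRNN box: weights for the b-i layer, the i layers and the CNN."""
    h, k = config.n_hidden, config.kernel_size
    w: dict[str, Tensor] = {}

    def par(name: str, shape: tuple[int, ...]) -> None:
        w[name] = Tensor(_uniform_fan_in(rng, shape), requires_grad=True)

    def zeros(name: str, n: int) -> None:
        w[name] = Tensor(np.zeros(n, dtype=np.float32), requires_grad=True)

    par("bcrnn.Wc", (h, 2, k, k))
    par("bcrnn.Wb", (h, h, k, k))
    par("bcrnn.Wr", (h, h, k, k))
    zeros("bcrnn.Bf", h)
    zeros("bcrnn.Bb", h)
    for l in range(N_CRNN_I_LAYERS):
        par(f"crnn{l}.Wc", (h, h, k, k))
        par(f"crnn{l}.Wr", (h, h, k, k))
        zeros(f"crnn{l}.B", h)
    par("cnn.W", (2, h, k, k))
    zeros("cnn.B", 2)
    return w


@dataclass
class CRNNModel:
    """Network weights plus configuration.

    ``stacks`` holds one weight dictionary when weights are shared across
    iterations, otherwise one per unrolled iteration.
    """

    config: NetworkConfig
    stacks: list[dict[str, Tensor]]

    @classmethod
    def initialize(cls, config: NetworkConfig) -> "CRNNModel":
        rng = np.random.default_rng(config.seed)
        n = 1 if config.share_across_iterations else config.n_iterations
        return cls(config=config, stacks=[_init_layer_stack(config, rng) for _ in range(n)])

    def stack_for_iteration(self, i: int) -> dict[str, Tensor]:
        return self.stacks[0] if self.config.share_across_iterations else self.stacks[i]

    def parameters(self) -> list[tuple[str, Tensor]]:
        return [
            (f"stack{si}.{name}", t)
            for si, stack in enumerate(self.stacks)
            for name, t in stack.items()
        ]

    def zero_like_(self) -> None:
        """Zero every weight in place (used by identity tests)."""
        for _, t in self.parameters():
            t.data[...] = 0

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: t.data.copy() for name, t in self.parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for name, t in self.parameters():
            t.data[...] = state[name]

    def save(self, path: str | Path, manifest: dict | None = None) -> None:
        """Portable checkpoint: weights (.npz) + config/manifest (.json)."""
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        np.savez(path.with_suffix(".npz"), **self.state_dict())
        meta = {"config": asdict(self.config), "manifest": manifest or {}}
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "CRNNModel":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        model = cls.initialize(NetworkConfig(**meta["config"]))
        with np.load(path.with_suffix(".npz")) as state:
            model.load_state_dict({k: state[k] for k in state.files})
        return model


# -- layer operations -------------------------------------------------------


def crnn_i_step(
    h_below: Tensor, h_prev_iter: Tensor, wc: Tensor, wr: Tensor, bias: Tensor
) -> Tensor:
    """CRNN-i layer: ReLU(Wc * H_below + Wr * H_prev_iter + B)."""
    return ad.relu(ad.add_bias(ad.conv2d(h_below, wc) + ad.conv2d(h_prev_iter, wr), bias))


def crnn_b_i_step(
    h_below_seq: list[Tensor],
    h_prev_iter_seq: list[Tensor],
    wc: Tensor,
    wb: Tensor,
    wr: Tensor,
    bias_fwd: Tensor,
    bias_bwd: Tensor,
    hidden_shape: tuple[int, ...],
) -> list[Tensor]:
    """Bidirectional CRNN-b-i layer over the b-value frame sequence.

    Boundary hidden states (before the first and after the last frame) are
    zero; forward and backward passes share Wc, Wb, Wr and differ only in
    their biases.  Output is the elementwise sum of the two passes.
    """
    T = len(h_below_seq)
    if T == 0:
        raise ValueError("empty frame sequence")
    zero = Tensor(np.zeros(hidden_shape, dtype=np.float32))

    fwd: list[Tensor] = []
    h = zero
    for t in range(T):
        pre = ad.conv2d(h_below_seq[t], wc) + ad.conv2d(h, wb)
        pre = pre + ad.conv2d(h_prev_iter_seq[t], wr)
        h = ad.relu(ad.add_bias(pre, bias_fwd))
        fwd.append(h)

    bwd: list[Tensor | None] = [None] * T
    h = zero
    for t in reversed(range(T)):
        pre = ad.conv2d(h_below_seq[t], wc) + ad.conv2d(h, wb)
        pre = pre + ad.conv2d(h_prev_iter_seq[t], wr)
        h = ad.relu(ad.add_bias(pre, bias_bwd))
        bwd[t] = h

    return [fwd[t] + bwd[t] for t in range(T)]


def crnn_block(
    x_seq: list[Tensor],
    prev_hidden: list[list[Tensor]] | None,
    stack: dict[str, Tensor],
    n_hidden: int,
) -> tuple[list[Tensor], list[list[Tensor]]]:
    """One CRNN box applied to a T-frame sequence of 2-channel images.

    Returns the residual update X + CRNN(X) per frame together with the new
    per-layer hidden states (CRNN-b-i first, then the three CRNN-i layers)
    for the next unrolled iteration.  ``prev_hidden=None`` means iteration 0
    (all-zero hidden states).
    """
    T = len(x_seq)
    b, _, hh, ww = x_seq[0].shape
    hidden_shape = (b, n_hidden, hh, ww)
    if prev_hidden is None:
        zero = Tensor(np.zeros(hidden_shape, dtype=np.float32))
        prev_hidden = [[zero] * T for _ in range(1 + N_CRNN_I_LAYERS)]

    new_hidden: list[list[Tensor]] = []
    seq = crnn_b_i_step(
        x_seq, prev_hidden[0],
        stack["bcrnn.Wc"], stack["bcrnn.Wb"], stack["bcrnn.Wr"],
        stack["bcrnn.Bf"], stack["bcrnn.Bb"], hidden_shape,
    )
    new_hidden.append(seq)
    for l in range(N_CRNN_I_LAYERS):
        seq = [
            crnn_i_step(
                seq[t], prev_hidden[1 + l][t],
                stack[f"crnn{l}.Wc"], stack[f"crnn{l}.Wr"], stack[f"crnn{l}.B"],
            )
            for t in range(T)
        ]
        new_hidden.append(seq)
    out = [
        x_seq[t] + ad.add_bias(ad.conv2d(seq[t], stack["cnn.W"]), stack["cnn.B"])
        for t in range(T)
    ]
    return out, new_hidden


def _crnn_block_stacked(
    x_st: Tensor,
    prev_hidden: list[Tensor] | None,
    stack: dict[str, Tensor],
    n_hidden: int,
    T: int,
) -> tuple[Tensor, list[Tensor]]:
    """Frame-batched CRNN box: frames stacked frame-major along axis 0.

    Numerically identical to :func:`crnn_block` (a test pins this), but all
    frame-parallel convolutions run as single batched calls; only the Wb
    sequence recurrence of the CRNN-b-i layer walks frames one by one.
    """
    TB = x_st.shape[0]
    B = TB // T
    hidden_shape = (TB, n_hidden) + x_st.shape[2:]
    if prev_hidden is None:
        zero_st = Tensor(np.zeros(hidden_shape, dtype=np.float32))
        prev_hidden = [zero_st] * (1 + N_CRNN_I_LAYERS)

    pre_static = ad.conv2d(x_st, stack["bcrnn.Wc"]) + ad.conv2d(
        prev_hidden[0], stack["bcrnn.Wr"]
    )
    stat = ad.split0(pre_static, T)
    zero = Tensor(np.zeros((B, n_hidden) + x_st.shape[2:], dtype=np.float32))
    h = zero
    fwd: list[Tensor] = []
    for t in range(T):
        h = ad.relu(ad.add_bias(stat[t] + ad.conv2d(h, stack["bcrnn.Wb"]), stack["bcrnn.Bf"]))
        fwd.append(h)
    h = zero
    bwd: list[Tensor | None] = [None] * T
    for t in reversed(range(T)):
        h = ad.relu(ad.add_bias(stat[t] + ad.conv2d(h, stack["bcrnn.Wb"]), stack["bcrnn.Bb"]))
        bwd[t] = h
    seq = ad.concat0([fwd[t] + bwd[t] for t in range(T)])
    new_hidden = [seq]
    for l in range(N_CRNN_I_LAYERS):
        seq = ad.relu(
            ad.add_bias(
                ad.conv2d(seq, stack[f"crnn{l}.Wc"])
                + ad.conv2d(prev_hidden[1 + l], stack[f"crnn{l}.Wr"]),
                stack[f"crnn{l}.B"],
            )
        )
        new_hidden.append(seq)
    out = x_st + ad.add_bias(ad.conv2d(seq, stack["cnn.W"]), stack["cnn.B"])
    return out, new_hidden


def unrolled_forward(
    model: CRNNModel,
    xu: np.ndarray,
    y_k: np.ndarray,
    line_mask: np.ndarray,
) -> list[Tensor]:
    """Full unrolled pass on a batch of sequences.

    ``xu``: (B, T, 2, H, W) zero-filled input; ``y_k``: (B, T, H, W) acquired
    k-space (zero off-mask).  Returns the final per-frame 2-channel images
    (a list of T tensors of shape (B, 2, H, W)).
    """
    B, T = xu.shape[:2]
    # frame-major stacking: rows [t*B:(t+1)*B] hold frame t
    x_st = Tensor(np.concatenate([xu[:, t] for t in range(T)], axis=0))
    y_st = np.concatenate([y_k[:, t] for t in range(T)], axis=0)
    hidden = None
    for i in range(model.config.n_iterations):
        stack = model.stack_for_iteration(i)
        x_st, hidden = _crnn_block_stacked(x_st, hidden, stack, model.config.n_hidden, T)
        x_st = ad.dc_project(x_st, y_st, line_mask)
    return ad.split0(x_st, T)


@dataclass
class ReconResult:
    """Reconstruction output with provenance."""

    series: DWISeries
    config: NetworkConfig
    mask: SamplingMask


def _sequence_batches(
    frames: KSpaceFrameSet,
) -> tuple[np.ndarray, np.ndarray, list[tuple[int, list[int]]]]:
    """All (slice, direction) sequences of a frame set as batch arrays.

    Returns (xu, y_k, index) where index[j] = (slice, frame list) of batch
    element j.  Sequences follow ascending b; the shared b = 0 frame leads
    every sequence.
    """
    scheme = frames.scheme
    n_slices = frames.kdata.shape[1]
    seqs: list[tuple[int, list[int]]] = []
    for s in range(n_slices):
        for d in range(scheme.n_directions):
            seqs.append((s, scheme.frames_for_direction(d)))
    T = scheme.n_bvalues
    H, W = frames.kdata.shape[-2:]
    xu = np.zeros((len(seqs), T, 2, H, W), dtype=np.float32)
    yk = np.zeros((len(seqs), T, H, W), dtype=np.complex128)
    for j, (s, fr) in enumerate(seqs):
        k = frames.kdata[fr, s]
        yk[j] = k
        img = kspace_to_image(k)
        xu[j, :, 0] = img.real
        xu[j, :, 1] = img.imag
    return xu, yk, seqs


def reconstruct(frames: KSpaceFrameSet, model: CRNNModel) -> ReconResult:
    """Reconstruct a full undersampled frame set.

    Every (slice, direction) b-sequence is a batch element; the b = 0 frame,
    reconstructed once per direction, is averaged across directions when the
    output series is reassembled.  Deterministic given weights and input.
    """
    scheme = frames.scheme
    xu, yk, seqs = _sequence_batches(frames)
    out = unrolled_forward(model, xu, yk, frames.mask.line_pattern)
    rec = np.stack([t.data for t in out], axis=1)  # (B, T, 2, H, W)

    data = np.zeros(frames.kdata.shape, dtype=np.complex128)
    b0_acc = np.zeros((frames.kdata.shape[1],) + frames.kdata.shape[-2:], dtype=np.complex128)
    for j, (s, fr) in enumerate(seqs):
        cplx = rec[j, :, 0].astype(np.complex128) + 1j * rec[j, :, 1]
        b0_acc[s] += cplx[0] / scheme.n_directions
        for t, f in enumerate(fr[1:], start=1):
            data[f, s] = cplx[t]
    data[0] = b0_acc
    series = DWISeries(data=data, scheme=scheme)
    return ReconResult(series=series, config=model.config, mask=frames.mask)


# -- training ---------------------------------------------------------------


@dataclass
class TrainConfig:
    epochs: int = 20
    lr: float = 1e-3
    batch_size: int = 8
    seed: int = 0
    adam_betas: tuple[float, float] = (0.9, 0.999)
    adam_eps: float = 1e-8


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    best_epoch: int = -1
    best_val_loss: float = np.inf


class _Adam:
    def __init__(self, params: list[tuple[str, Tensor]], cfg: TrainConfig) -> None:
        self.params = params
        self.cfg = cfg
        self.m = {n: np.zeros_like(t.data) for n, t in params}
        self.v = {n: np.zeros_like(t.data) for n, t in params}
        self.t = 0

    def step(self) -> None:
        b1, b2 = self.cfg.adam_betas
        self.t += 1
        for name, p in self.params:
            if p.grad is None:
                continue
            g = p.grad
            self.m[name] = b1 * self.m[name] + (1 - b1) * g
            self.v[name] = b2 * self.v[name] + (1 - b2) * g * g
            mhat = self.m[name] / (1 - b1**self.t)
            vhat = self.v[name] / (1 - b2**self.t)
            p.data -= self.cfg.lr * mhat / (np.sqrt(vhat) + self.cfg.adam_eps)

    def zero_grad(self) -> None:
        for _, p in self.params:
            p.zero_grad()


def _dataset_arrays(
    subjects: list[DWISeries], mask: SamplingMask
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack every (slice, direction) sequence of a subject list.

    Returns (xu, y_k, target) with target the fully sampled 2-channel
    magnitude reference (imaginary part zero).
    """
    from .kspace import series_to_kspace, undersample

    xus, yks, tgts = [], [], []
    for series in subjects:
        k_full = series_to_kspace(series)
        frames = undersample(k_full, mask, series.scheme)
        xu, yk, seqs = _sequence_batches(frames)
        mag = series.magnitude()
        tgt = np.zeros_like(xu)
        for j, (s, fr) in enumerate(seqs):
            tgt[j, :, 0] = mag[fr, s]
        xus.append(xu)
        yks.append(yk)
        tgts.append(tgt)
    return np.concatenate(xus), np.concatenate(yks), np.concatenate(tgts)


def train(
    model: CRNNModel,
    train_subjects: list[DWISeries],
    val_subjects: list[DWISeries],
    mask: SamplingMask,
    config: TrainConfig | None = None,
    verbose: bool = False,
) -> TrainHistory:
    """Train by MSE against fully sampled references; keep best-validation weights.

    Training pairs are built by undersampling each subject's pseudo k-space
    with the given mask.  Fully reproducible for a fixed seed.  Epoch 0 of
    the history records the validation loss of the initial weights.
    """
    cfg = config or TrainConfig()
    xu, yk, tgt = _dataset_arrays(train_subjects, mask)
    vxu, vyk, vtgt = _dataset_arrays(val_subjects, mask)
    rng = np.random.default_rng(cfg.seed)
    opt = _Adam(model.parameters(), cfg)
    hist = TrainHistory()

    def val_loss() -> float:
        out = unrolled_forward(model, vxu, vyk, mask.line_pattern)
        pred = np.stack([t.data for t in out], axis=1)
        return float(np.mean((pred - vtgt) ** 2))

    v0 = val_loss()
    hist.val_loss.append(v0)
    hist.train_loss.append(np.nan)
    best_state = model.state_dict()
    hist.best_val_loss = v0
    hist.best_epoch = 0

    n = xu.shape[0]
    for epoch in range(1, cfg.epochs + 1):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for lo in range(0, n, cfg.batch_size):
            idx = order[lo : lo + cfg.batch_size]
            out = unrolled_forward(model, xu[idx], yk[idx], mask.line_pattern)
            losses = [ad.mse_loss(out[t], tgt[idx][:, t]) for t in range(len(out))]
            total = losses[0]
            for l in losses[1:]:
                total = total + l
            loss = Tensor(total.data / len(losses), parents=(total,))
            scale = 1.0 / len(losses)
            loss._bwd = lambda g, tt=total, s=scale: tt._accum(g * s)
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}, batch {lo // cfg.batch_size}"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data) * len(idx)
        hist.train_loss.append(epoch_loss / n)
        v = val_loss()
        hist.val_loss.append(v)
        if v < hist.best_val_loss:
            hist.best_val_loss = v
            hist.best_epoch = epoch
            best_state = model.state_dict()
        if verbose:
            print(f"epoch {epoch:3d}  train {hist.train_loss[-1]:.3e}  val {v:.3e}")

    model.load_state_dict(best_state)
    return hist
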