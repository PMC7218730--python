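"""Multi-task residual saliency network.

One shared convolutional encoder and P person-specific three-layer decoders
learn, for each person in a panel, the *difference map* between that
person's attention map (PSM) and the universal saliency map (USM).  A 1×1
convolution head after every decoder layer emits an intermediate difference
map, and training minimizes the summed squared Frobenius loss over all
three levels, persons and images:

    L = Σ_l Σ_p Σ_n ‖Δ̂_l(p, X_n) − Δ(p, X_n)‖²_F .

Prediction for person p on a target image adds the final-level head output
to the USM and clips at zero:

    S_out(p, X) = max(0, Δ̂_3(p, X, S_USM(X)) + S_USM(X)).

The USM enters the network as an extra input channel concatenated to the
image, so every head sees both the image and the person-agnostic prior.

The tensor machinery (im2col convolution, 2×2 max-pool, nearest-neighbour
upsampling, bilinear resize, SGD with classical momentum) is implemented
directly on numpy arrays with hand-written backward passes; the model is
small by design — the method's point is the few-shot adaptation around it,
not network scale.  All randomness is driven by explicit seeds and runs are
bitwise reproducible.
"""

from __future__ import annotations

import io
import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .attention_maps import DifferenceMap, ImageRecord, SaliencyMap

logger = logging.getLogger("persalmap")

CHECKPOINT_SCHEMA = 1


class ConfigError(ValueError):
    """Network configuration is internally inconsistent."""


class DivergenceError(RuntimeError):
    """Training loss became non-finite."""

    def __init__(self, iteration: int):
        super().__init__(f"training diverged (non-finite loss) at iteration {iteration}")
        self.iteration = iteration


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture hyper-parameters.

    ``encoder_channels`` gives the width of each conv+maxpool block (the
    spatial size halves per block); ``decoder_channels`` the width of each
    upsample+conv block of every person-specific decoder.  ``in_channels``
    counts image channels plus one USM channel.
    """

    num_persons: int
    input_height: int
    input_width: int
    in_channels: int = 4
    num_levels: int = 3
    encoder_channels: tuple[int, ...] = (8, 16, 16)
    decoder_channels: tuple[int, ...] = (16, 16, 8)

    def __post_init__(self) -> None:
        if self.num_persons < 1:
            raise ConfigError("num_persons must be >= 1")
        if not self.encoder_channels or not self.decoder_channels:
            raise ConfigError("channel lists must be non-empty")
        if len(self.decoder_channels) != self.num_levels:
            raise ConfigError(
                f"decoder has {len(self.decoder_channels)} layers but "
                f"num_levels={self.num_levels}; one head per decoder layer"
            )
        factor = 2 ** len(self.encoder_channels)
        if self.input_height % factor or self.input_width % factor:
            raise ConfigError(
                f"input {self.input_height}x{self.input_width} must be divisible "
                f"by {factor} (one 2x2 maxpool per encoder block)"
            )


@dataclass(frozen=True)
class TrainConfig:
    """SGD settings (classical momentum)."""

    batch_size: int = 9
    learning_rate: float = 3e-5
    momentum: float = 0.9
    iterations: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.batch_size, self.iterations) < 1 or self.learning_rate < 0:
            raise ConfigError("batch_size, iterations must be >=1 and lr >= 0")


@dataclass
class TrainedModel:
    config: NetworkConfig
    params: dict[str, np.ndarray]
    training_log: list[tuple[int, float]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Tensor primitives (forward + backward)
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray) -> np.ndarray:
    """(B,C,H,W) -> (B, 9*C, H*W) columns of the 3x3 neighbourhood, zero-padded."""
    b, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    cols = np.empty((b, 9 * c, h * w), dtype=x.dtype)
    k = 0
    for dr in range(3):
        for dc in range(3):
            cols[:, k * c:(k + 1) * c, :] = xp[:, :, dr:dr + h, dc:dc + w].reshape(b, c, h * w)
            k += 1
    return cols


def _col2im(dcols: np.ndarray, shape: tuple[int, int, int, int]) -> np.ndarray:
    b, c, h, w = shape
    dxp = np.zeros((b, c, h + 2, w + 2), dtype=dcols.dtype)
    k = 0
    for dr in range(3):
        for dc in range(3):
            dxp[:, :, dr:dr + h, dc:dc + w] += dcols[:, k * c:(k + 1) * c, :].reshape(b, c, h, w)
            k += 1
    return dxp[:, :, 1:-1, 1:-1]


def _conv_forward(x, W, b):
    bs, c, h, w = x.shape
    cols = _im2col(x)
    out = np.einsum("fk,bkn->bfn", W, cols).reshape(bs, -1, h, w) + b[None, :, None, None]
    return out, (cols, x.shape, W)


def _conv_backward(dout, cache):
    cols, xshape, W = cache
    bs, f = dout.shape[:2]
    dflat = dout.reshape(bs, f, -1)
    dW = np.einsum("bfn,bkn->fk", dflat, cols)
    db = dflat.sum(axis=(0, 2))
    dcols = np.einsum("fk,bfn->bkn", W, dflat)
    return _col2im(dcols, xshape), dW, db


def _relu_forward(x):
    return np.maximum(x, 0.0), x > 0


def _pool_forward(x):
    b, c, h, w = x.shape
    xr = x.reshape(b, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(
        b, c, h // 2, w // 2, 4
    )
    idx = xr.argmax(axis=-1)
    out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
    return out, (idx, h, w)


def _pool_backward(dout, cache):
    idx, h, w = cache
    b, c, hh, ww = dout.shape
    dxr = np.zeros((b, c, hh, ww, 4), dtype=dout.dtype)
    np.put_along_axis(dxr, idx[..., None], dout[..., None], axis=-1)
    return dxr.reshape(b, c, hh, ww, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(b, c, h, w)


def _upsample_forward(x):
    return x.repeat(2, axis=2).repeat(2, axis=3)


def _upsample_backward(dout):
    b, c, h, w = dout.shape
    return dout.reshape(b, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


def _interp_matrix(n_out: int, n_in: int) -> np.ndarray:
    """1-D bilinear interpolation matrix (half-pixel-centre convention)."""
    M = np.zeros((n_out, n_in))
    if n_in == 1:
        M[:, 0] = 1.0
        return M
    src = np.clip((np.arange(n_out) + 0.5) * n_in / n_out - 0.5, 0, n_in - 1)
    i0 = np.floor(src).astype(int)
    i1 = np.minimum(i0 + 1, n_in - 1)
    frac = src - i0
    np.add.at(M, (np.arange(n_out), i0), 1.0 - frac)
    np.add.at(M, (np.arange(n_out), i1), frac)
    return M


def _resize_forward(x, R, C):
    # out = R @ x @ C.T over the trailing two axes
    return np.einsum("oh,bchw,pw->bcop", R, x, C, optimize=True)


def _resize_backward(dout, R, C):
    return np.einsum("oh,bcop,pw->bchw", R, dout, C, optimize=True)


# ---------------------------------------------------------------------------
# Model construction and forward/backward
# ---------------------------------------------------------------------------

def build_model(config: NetworkConfig, seed: int = 0) -> TrainedModel:
    """Initialize an untrained model with He-normal weights (seed-deterministic)."""
    rng = np.random.default_rng(seed)
    params: dict[str, np.ndarray] = {}

    def he(fan_in, shape):
        return rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)

    c_prev = config.in_channels
    for i, c_out in enumerate(config.encoder_channels):
        params[f"enc{i}/W"] = he(c_prev * 9, (c_out, c_prev * 9))
        params[f"enc{i}/b"] = np.zeros(c_out)
        c_prev = c_out
    enc_out = c_prev
    for p in range(config.num_persons):
        c_prev = enc_out
        for l, c_out in enumerate(config.decoder_channels):
            params[f"dec{p}_{l}/W"] = he(c_prev * 9, (c_out, c_prev * 9))
            params[f"dec{p}_{l}/b"] = np.zeros(c_out)
            params[f"head{p}_{l}/W"] = he(c_out, (1, c_out))
            params[f"head{p}_{l}/b"] = np.zeros(1)
            c_prev = c_out
    return TrainedModel(config=config, params=params, training_log=[])


def _resize_mats(config: NetworkConfig) -> list[tuple[np.ndarray, np.ndarray]]:
    """Bilinear matrices taking each decoder level's resolution to full size."""
    depth = len(config.encoder_channels)
    mats = []
    for l in range(config.num_levels):
        # level l output is at 1 / 2^(depth - l - 1) of full resolution
        scale = 2 ** (depth - l - 1)
        h = config.input_height // scale
        w = config.input_width // scale
        mats.append((_interp_matrix(config.input_height, h), _interp_matrix(config.input_width, w)))
    return mats


def forward(model: TrainedModel, x: np.ndarray, want_cache: bool = False):
    """Run the network on a batch ``x`` of shape (B, in_channels, H, W).

    Returns ``preds[l][p]``, an (B, H, W) difference-map prediction per
    decoding level l and person p (bilinearly resized to full resolution),
    and, when ``want_cache``, the intermediate activations for backprop.
    """
    cfg = model.config
    P, L = cfg.num_persons, cfg.num_levels
    mats = _resize_mats(cfg)
    cache: dict = {"enc": [], "dec": {}, "mats": mats}

    h = x
    for i in range(len(cfg.encoder_channels)):
        z, cc = _conv_forward(h, model.params[f"enc{i}/W"], model.params[f"enc{i}/b"])
        a, mask = _relu_forward(z)
        h, pc = _pool_forward(a)
        cache["enc"].append((cc, mask, pc))
    enc_out = h
    cache["enc_out"] = enc_out

    preds: list[list[np.ndarray]] = [[None] * P for _ in range(L)]
    for p in range(P):
        h = enc_out
        for l in range(L):
            u = _upsample_forward(h)
            z, cc = _conv_forward(u, model.params[f"dec{p}_{l}/W"], model.params[f"dec{p}_{l}/b"])
            a, mask = _relu_forward(z)
            # 1x1 head
            hw = model.params[f"head{p}_{l}/W"]
            hb = model.params[f"head{p}_{l}/b"]
            head = np.einsum("fc,bchw->bfhw", hw, a) + hb[None, :, None, None]
            R, C = mats[l]
            preds[l][p] = _resize_forward(head, R, C)[:, 0]
            cache["dec"][(p, l)] = (cc, mask, a, head.shape)
            h = a
    if want_cache:
        return preds, cache
    return preds


def _backward(model: TrainedModel, cache, dpreds) -> dict[str, np.ndarray]:
    """Gradient of the loss w.r.t. every parameter, given d(loss)/d(pred)."""
    cfg = model.config
    P, L = cfg.num_persons, cfg.num_levels
    mats = cache["mats"]
    grads = {k: np.zeros_like(v) for k, v in model.params.items()}
    denc_out = np.zeros_like(cache["enc_out"])

    for p in range(P):
        dh_next = None  # gradient flowing into decoder layer l's activation from layer l+1
        for l in range(L - 1, -1, -1):
            cc, mask, a, head_shape = cache["dec"][(p, l)]
            R, C = mats[l]
            dhead = _resize_backward(dpreds[l][p][:, None], R, C)
            hw = model.params[f"head{p}_{l}/W"]
            grads[f"head{p}_{l}/W"] += np.einsum("bfhw,bchw->fc", dhead, a)
            grads[f"head{p}_{l}/b"] += dhead.sum(axis=(0, 2, 3))
            da = np.einsum("fc,bfhw->bchw", hw, dhead)
            if dh_next is not None:
                da = da + dh_next
            dz = da * mask
            du, dW, db = _conv_backward(dz, cc)
            grads[f"dec{p}_{l}/W"] += dW
            grads[f"dec{p}_{l}/b"] += db
            dh_next = _upsample_backward(du)
        denc_out += dh_next

    dh = denc_out
    for i in range(len(cfg.encoder_channels) - 1, -1, -1):
        cc, mask, pc = cache["enc"][i]
        da = _pool_backward(dh, pc)
        dz = da * mask
        dh, dW, db = _conv_backward(dz, cc)
        grads[f"enc{i}/W"] += dW
        grads[f"enc{i}/b"] += db
    return grads


# ---------------------------------------------------------------------------
# Loss
# ---------------------------------------------------------------------------

def _target_array(target) -> np.ndarray:
    if isinstance(target, DifferenceMap):
        return target.values
    return np.asarray(target, dtype=float)


def multilevel_loss(predicted, target, levels: list[int] | None = None) -> float:
    """Summed squared Frobenius loss over levels, persons and images.

    ``predicted`` is indexed ``[level][person]`` with each entry an
    (N, H, W) array (or a list of 2-D maps); ``target`` is indexed
    ``[person]`` the same way and is shared by all levels.  ``levels``
    restricts the sum (default: all levels).
    """
    L = len(predicted)
    use = range(L) if levels is None else levels
    total = 0.0
    for l in use:
        for p, pred in enumerate(predicted[l]):
            pr = np.asarray(pred, dtype=float)
            tg = np.asarray([_target_array(t) for t in target[p]]) if isinstance(
                target[p], (list, tuple)
            ) else _target_array(target[p])
            if pr.shape != tg.shape:
                raise ValueError(f"level {l} person {p}: shape {pr.shape} vs target {tg.shape}")
            total += float(np.sum((pr - tg) ** 2))
    return total


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def _stack_inputs(images: list[ImageRecord], usms: list[SaliencyMap], cfg: NetworkConfig) -> np.ndarray:
    xs = []
    for img, usm in zip(images, usms):
        px = np.moveaxis(img.pixels, -1, 0)  # (C, H, W)
        x = np.concatenate([px, usm.values[None]], axis=0)
        if x.shape[0] != cfg.in_channels:
            raise ConfigError(
                f"image {img.image_id!r}: {x.shape[0]} input channels "
                f"(image + USM) but config expects {cfg.in_channels}"
            )
        xs.append(x)
    return np.asarray(xs)


def train(
    model: TrainedModel,
    images: list[ImageRecord],
    usms: list[SaliencyMap],
    difference_targets,
    train_config: TrainConfig,
) -> TrainedModel:
    """SGD with momentum on the multi-level Frobenius loss.

    ``difference_targets`` is indexed ``[person][image]`` (DifferenceMap or
    2-D array), covering all P persons on every training image.  The same
    full-resolution target supervises every level.  Identical seeds and
    data give bitwise-identical training logs.
    """
    cfg = model.config
    P = cfg.num_persons
    N = len(images)
    targets = np.asarray(
        [[_target_array(difference_targets[p][n]) for n in range(N)] for p in range(P)]
    )  # (P, N, H, W)
    if targets.shape[0] != P:
        raise ValueError("targets must cover all persons")
    X = _stack_inputs(images, usms, cfg)

    rng = np.random.default_rng(train_config.seed)
    velocity = {k: np.zeros_like(v) for k, v in model.params.items()}
    log: list[tuple[int, float]] = []
    bs = min(train_config.batch_size, N)

    for it in range(train_config.iterations):
        idx = rng.choice(N, size=bs, replace=False)
        xb = X[idx]
        preds, cache = forward(model, xb, want_cache=True)
        loss = 0.0
        dpreds = [[None] * P for _ in range(cfg.num_levels)]
        for l in range(cfg.num_levels):
            for p in range(P):
                resid = preds[l][p] - targets[p][idx]
                loss += float(np.sum(resid ** 2))
                dpreds[l][p] = 2.0 * resid
        if not np.isfinite(loss):
            raise DivergenceError(it)
        grads = _backward(model, cache, dpreds)
        lr = train_config.learning_rate
        mu = train_config.momentum
        for k in model.params:
            velocity[k] = mu * velocity[k] - lr * grads[k]
            model.params[k] = model.params[k] + velocity[k]
        log.append((it, loss))
    model.training_log = model.training_log + log
    return model


# ---------------------------------------------------------------------------
# Prediction
# ---------------------------------------------------------------------------

def predict_difference(model: TrainedModel, image: ImageRecord, usm: SaliencyMap) -> list[np.ndarray]:
    """Final-level difference-map predictions, one (H, W) array per person."""
    x = _stack_inputs([image], [usm], model.config)
    preds = forward(model, x)
    return [preds[-1][p][0] for p in range(model.config.num_persons)]


def predict_psm(
    model: TrainedModel, image: ImageRecord, usm: SaliencyMap, person_index: int
) -> SaliencyMap:
    """Predicted PSM: final difference head + USM, clipped at zero.

    ``person_index`` is 0-based into the panel the model was trained on.
    """
    P = model.config.num_persons
    if not (0 <= person_index < P):
        raise IndexError(f"person_index {person_index} out of range [0, {P})")
    if usm.shape != (image.height, image.width):
        raise ValueError("USM dimensions do not match the image")
    delta = predict_difference(model, image, usm)[person_index]
    return SaliencyMap(image.image_id, np.clip(delta + usm.values, 0.0, None), "raw")


# ---------------------------------------------------------------------------
# Checkpoint I/O (single-file npz archive)
# ---------------------------------------------------------------------------

def save_checkpoint(path, model: TrainedModel) -> None:
    cfg = model.config
    meta = {
        "schema": CHECKPOINT_SCHEMA,
        "config": {
            "num_persons": cfg.num_persons,
            "input_height": cfg.input_height,
            "input_width": cfg.input_width,
            "in_channels": cfg.in_channels,
            "num_levels": cfg.num_levels,
            "encoder_channels": list(cfg.encoder_channels),
            "decoder_channels": list(cfg.decoder_channels),
        },
    }
    arrays = {f"param/{k}": v for k, v in model.params.items()}
    arrays["meta"] = np.array(json.dumps(meta))
    arrays["training_log"] = np.asarray(model.training_log, dtype=float).reshape(-1, 2)
    np.savez(path, **arrays)


def load_checkpoint(path) -> TrainedModel:
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["meta"]))
        if meta.get("schema") != CHECKPOINT_SCHEMA:
            raise ValueError(f"unsupported checkpoint schema {meta.get('schema')}")
        c = meta["config"]
        cfg = NetworkConfig(
            num_persons=c["num_persons"],
            input_height=c["input_height"],
            input_width=c["input_width"],
            in_channels=c["in_channels"],
            num_levels=c["num_levels"],
            encoder_channels=tuple(c["encoder_channels"]),
            decoder_channels=tuple(c["decoder_channels"]),
        )
        params = {k[len("param/"):]: z[k] for k in z.files if k.startswith("param/")}
        log = [(int(i), float(v)) for i, v in z["training_log"]]
    return TrainedModel(config=cfg, params=params, training_log=log)
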