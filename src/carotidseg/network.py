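"""Multi-scale 3D patch-based segmentation network.

A tailored patch-wise convolutional network for multi-class carotid
segmentation: a full-resolution pathway plus down-sampled pathways
(default sub-sampling factors 3 and 5) give each output voxel both fine
detail and wide spatial context; per-pathway features are upsampled to
the common resolution, concatenated, passed through two fully-connected
(1x1x1 convolution) layers and a softmax classifier.  Kernels may be
anisotropic (rectangular prisms elongated along z, matching the tubular,
z-running vessels); deeper layers carry fewer feature maps.  All
convolutions are valid (unpadded), which makes tiled full-volume
inference exact: the sub-sampled pathways read the volume on a fixed
absolute grid, so the prediction is independent of the tile partition.

The cost is a differentiable soft F_beta (default beta=2) aggregated
over foreground classes; with precision/recall rates this is the
Tversky-style formulation whose beta=1 case is the Dice loss.  A literal
specificity/sensitivity form is available behind a switch — on
class-imbalanced volumes specificity saturates near 1 and that form is
nearly non-informative, so it is not the default.

Everything runs on plain NumPy: forward passes use einsum over sliding
windows, gradients are computed analytically, and stochastic gradient
descent with momentum drives training.  All problem sizes are chosen for
single-CPU execution.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .io_core import ImageVolume, LabelMap, same_grid


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class NetworkConfig:
    """Architecture parameters.

    ``kernel_shapes`` lists one (kx, ky, kz) extent per convolutional
    layer (all extents odd — the valid-convolution contract needs a
    well-defined centre); ``feature_maps`` gives the channel count per
    layer, by default decreasing in the deeper layers; the same layer
    stack is instantiated (with independent weights) on every pathway.
    ``input_segment_shape`` is the training-time input extent of the
    full-resolution pathway; the output extent follows from receptive-
    field arithmetic, and the sub-sampled pathways derive their own
    (coarser, physically larger) input extents from it.
    """

    pathway_subsampling: tuple[int, ...] = (1, 3, 5)
    kernel_shapes: tuple[tuple[int, int, int], ...] = (
        (3, 3, 5), (3, 3, 5), (3, 3, 3), (3, 3, 3),
        (3, 3, 3), (3, 3, 3), (3, 3, 3), (3, 3, 3))
    feature_maps: tuple[int, ...] = (32, 32, 24, 24, 24, 24, 16, 16)
    fc_widths: tuple[int, int] = (150, 150)
    n_classes: int = 4
    input_segment_shape: tuple[int, int, int] = (25, 25, 29)
    beta: float = 2.0
    loss_variant: str = "precision_recall"

    @property
    def n_layers_conv(self) -> int:
        return len(self.kernel_shapes)

    def __post_init__(self):
        self.pathway_subsampling = tuple(int(f) for f in self.pathway_subsampling)
        self.kernel_shapes = tuple(tuple(int(k) for k in ks)
                                   for ks in self.kernel_shapes)
        self.feature_maps = tuple(int(c) for c in self.feature_maps)
        if 1 not in self.pathway_subsampling:
            raise ValueError("pathway_subsampling must contain 1 "
                             "(the full-resolution pathway)")
        if any(f < 1 for f in self.pathway_subsampling):
            raise ValueError("sub-sampling factors must be >= 1")
        if len(self.feature_maps) != len(self.kernel_shapes):
            raise ValueError("feature_maps and kernel_shapes lengths differ")
        for ks in self.kernel_shapes:
            if len(ks) != 3 or any(k < 1 or k % 2 == 0 for k in ks):
                raise ValueError(f"kernel extents must be odd and >= 1, got {ks}")
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if self.loss_variant not in ("precision_recall",
                                     "specificity_sensitivity"):
            raise ValueError(f"unknown loss_variant {self.loss_variant!r}")
        out = self.output_shape()
        if any(o < 1 for o in out):
            raise ValueError(
                "input segment too small: input "
                f"{self.input_segment_shape} minus receptive-field margin "
                f"{tuple(r - 1 for r in self._rf())} leaves output {out}")

    def _rf(self) -> tuple[int, int, int]:
        """Per-axis receptive field of the shared layer stack (factor 1)."""
        return tuple(1 + sum(k[a] - 1 for k in self.kernel_shapes)
                     for a in range(3))

    def output_shape(self) -> tuple[int, int, int]:
        rf = self._rf()
        return tuple(self.input_segment_shape[a] - (rf[a] - 1)
                     for a in range(3))

    @classmethod
    def toy(cls, **overrides) -> "NetworkConfig":
        """Small configuration sized for desk-scale CPU experiments."""
        defaults = dict(
            pathway_subsampling=(1, 3, 5),
            kernel_shapes=((3, 3, 5), (3, 3, 3)),
            feature_maps=(8, 8),
            fc_widths=(16, 16),
            input_segment_shape=(17, 17, 19),
        )
        defaults.update(overrides)
        return cls(**defaults)


@dataclass
class TrainingConfig:
    """Optimization parameters.

    The default optimizer is Adam: the soft-F_beta gradients scale
    inversely with batch soft-count denominators, so fixed-step SGD needs
    careful per-problem rate tuning while per-parameter adaptive scaling
    converges robustly at these problem sizes.  ``optimizer='sgd'``
    selects plain momentum SGD with the decayed rate schedule instead.
    """

    epochs: int = 20
    batch_size: int = 8
    segments_per_volume: int = 64
    foreground_fraction: float = 0.5
    optimizer: str = "adam"
    learning_rate: float = 0.003
    momentum: float = 0.9
    lr_decay: float = 0.97
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not (0.0 < self.foreground_fraction < 1.0):
            raise ValueError("foreground_fraction must lie in (0, 1)")
        if self.batch_size < 1 or self.segments_per_volume < 1:
            raise ValueError("batch_size and segments_per_volume must be >= 1")
        if self.optimizer not in ("adam", "sgd"):
            raise ValueError("optimizer must be 'adam' or 'sgd'")


def receptive_field(config: NetworkConfig) -> dict[int, tuple[int, int, int]]:
    """Input extent seen by one output voxel, per pathway, in full-resolution
    voxels: ``(1 + sum(kernel-1))`` per axis times the sub-sampling factor."""
    rf = config._rf()
    return {f: tuple(r * f for r in rf) for f in config.pathway_subsampling}


# ---------------------------------------------------------------------------
# Layers
# ---------------------------------------------------------------------------

class _Conv3D:
    """Valid (unpadded) 3D convolution layer with optional ReLU."""

    def __init__(self, c_in: int, c_out: int, kernel, rng, relu: bool = True):
        kx, ky, kz = kernel
        fan_in = c_in * kx * ky * kz
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                            size=(c_out, c_in, kx, ky, kz))
        self.b = np.zeros(c_out)
        self.relu = relu
        self.kernel = (kx, ky, kz)
        self._x = None
        self._pre = None
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        win = sliding_window_view(x, self.kernel, axis=(2, 3, 4))
        y = np.einsum("bcdhwxyz,ocxyz->bodhw", win, self.W,
                      optimize=True) + self.b[None, :, None, None, None]
        if self.relu:
            self._pre = y
            y = np.maximum(y, 0.0)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self.relu:
            dy = dy * (self._pre > 0)
        win = sliding_window_view(self._x, self.kernel, axis=(2, 3, 4))
        self.dW += np.einsum("bodhw,bcdhwxyz->ocxyz", dy, win, optimize=True)
        self.db += dy.sum(axis=(0, 2, 3, 4))
        kx, ky, kz = self.kernel
        pad = ((0, 0), (0, 0), (kx - 1, kx - 1), (ky - 1, ky - 1),
               (kz - 1, kz - 1))
        dyp = np.pad(dy, pad)
        winp = sliding_window_view(dyp, self.kernel, axis=(2, 3, 4))
        w_flip = self.W[:, :, ::-1, ::-1, ::-1]
        return np.einsum("bodhwxyz,ocxyz->bcdhw", winp, w_flip, optimize=True)

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]


class MultiScaleNet:
    """The assembled network; see the module docstring for the contract."""

    def __init__(self, config: NetworkConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        self.pathways: list[list[_Conv3D]] = []
        for _ in config.pathway_subsampling:
            layers, c_in = [], 1
            for ks, c_out in zip(config.kernel_shapes, config.feature_maps):
                layers.append(_Conv3D(c_in, c_out, ks, rng))
                c_in = c_out
            self.pathways.append(layers)
        concat = config.feature_maps[-1] * len(config.pathway_subsampling)
        self.fc1 = _Conv3D(concat, config.fc_widths[0], (1, 1, 1), rng)
        self.fc2 = _Conv3D(config.fc_widths[0], config.fc_widths[1],
                           (1, 1, 1), rng)
        self.classifier = _Conv3D(config.fc_widths[1], config.n_classes,
                                  (1, 1, 1), rng, relu=False)
        # background-prior bias: most voxels are background, so start the
        # softmax there instead of uniform (shortens the over-segmenting
        # transient under the foreground-only cost)
        self.classifier.b[0] = 2.0
        self._cache = None

    # -- forward / backward -------------------------------------------------

    def forward(self, inputs: list[np.ndarray],
                phases: np.ndarray) -> np.ndarray:
        """Per-voxel class probabilities for a batch of segments.

        ``inputs[p]`` has shape (B, 1, *extent_p); ``phases[b, p, a]`` is
        the sub-sampling phase (tile start modulo factor) that aligns
        pathway p of sample b to the absolute voxel grid.  Returns
        (B, n_classes, *output_shape) softmax probabilities.
        """
        cfg = self.config
        out_shape = cfg.output_shape()
        feats, ups = [], []
        for p, (f, layers) in enumerate(zip(cfg.pathway_subsampling,
                                            self.pathways)):
            y = inputs[p]
            for layer in layers:
                y = layer.forward(y)
            if f == 1:
                if y.shape[2:] != out_shape:
                    raise ValueError(f"pathway output {y.shape[2:]} != "
                                     f"expected {out_shape}")
                feats.append(y)
                ups.append(None)
            else:
                B = y.shape[0]
                up = np.empty(y.shape[:2] + out_shape)
                maps = []
                for b in range(B):
                    m = [((phases[b, p, a] + np.arange(out_shape[a])) // f)
                         for a in range(3)]
                    up[b] = y[b][:, m[0]][:, :, m[1]][:, :, :, m[2]]
                    maps.append(m)
                feats.append(up)
                ups.append((y.shape, maps))
        z = np.concatenate(feats, axis=1)
        z = self.fc1.forward(z)
        z = self.fc2.forward(z)
        logits = self.classifier.forward(z)
        shifted = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(shifted)
        probs = e / e.sum(axis=1, keepdims=True)
        self._cache = (probs, ups)
        return probs

    def backward(self, dlogits: np.ndarray) -> None:
        """Backpropagate pre-softmax gradients and accumulate parameter grads."""
        _, ups = self._cache
        cfg = self.config
        d = self.classifier.backward(dlogits)
        d = self.fc2.backward(d)
        d = self.fc1.backward(d)
        c = cfg.feature_maps[-1]
        for p, (f, layers) in enumerate(zip(cfg.pathway_subsampling,
                                            self.pathways)):
            dp = d[:, p * c:(p + 1) * c]
            if f != 1:
                shape, maps = ups[p]
                dcoarse = np.zeros(shape)
                for b in range(dp.shape[0]):
                    g = dp[b]
                    used = []
                    # the upsampling map is runs of equal cell indices, so
                    # its adjoint is a segment sum along each axis
                    for axis, m in zip((1, 2, 3), maps[b]):
                        starts = np.r_[0, np.flatnonzero(np.diff(m)) + 1]
                        g = np.add.reduceat(g, starts, axis=axis)
                        used.append(int(m[-1]) + 1)
                    dcoarse[b][:, :used[0], :used[1], :used[2]] = g
                dp = dcoarse
            for layer in reversed(layers):
                dp = layer.backward(dp)

    def params(self):
        out = []
        for layers in self.pathways:
            for layer in layers:
                out.extend(layer.params())
        for layer in (self.fc1, self.fc2, self.classifier):
            out.extend(layer.params())
        return out

    def zero_grad(self):
        for _, g in self.params():
            g[...] = 0.0


def build_network(config: NetworkConfig, seed: int = 0) -> MultiScaleNet:
    """Instantiate the network, validating the shape arithmetic first."""
    return MultiScaleNet(config, seed=seed)


# ---------------------------------------------------------------------------
# Loss
# ---------------------------------------------------------------------------

def _soft_fbeta(probs, onehot, beta, variant):
    """Soft F_beta loss and its gradient w.r.t. the probabilities.

    Aggregates soft confusion counts per foreground class over the whole
    batch; the loss is 1 minus the mean F_beta over foreground classes
    present in the truth (all foreground classes when none is present).
    """
    b2 = beta * beta
    n_cls = probs.shape[1]
    axes = (0,) + tuple(range(2, probs.ndim))
    present = [c for c in range(1, n_cls)
               if np.any(onehot[:, c] > 0)] or list(range(1, n_cls))
    loss_terms, grad = [], np.zeros_like(probs)
    for c in present:
        p, t = probs[:, c], onehot[:, c]
        if variant == "precision_recall":
            tp = float((p * t).sum())
            fp = float((p * (1 - t)).sum())
            fn = float(((1 - p) * t).sum())
            denom = (1 + b2) * tp + b2 * fn + fp
            f = (1 + b2) * tp / denom if denom > 0 else 1.0
            loss_terms.append(f)
            if denom > 0:
                num = (1 + b2) * tp
                d_tp = (1 + b2) * (denom - num) / denom**2
                d_fp = -num / denom**2
                d_fn = -b2 * num / denom**2
                grad[:, c] -= d_tp * t + d_fp * (1 - t) - d_fn * t
        else:  # specificity_sensitivity (literal alternative form)
            n_pos = float(t.sum())
            n_neg = float((1 - t).sum())
            tp = float((p * t).sum())
            tn = float(((1 - p) * (1 - t)).sum())
            sens = tp / n_pos if n_pos > 0 else 1.0
            spec = tn / n_neg if n_neg > 0 else 1.0
            denom = b2 * spec + sens
            f = (1 + b2) * spec * sens / denom if denom > 0 else 0.0
            loss_terms.append(f)
            if denom > 0:
                d_spec = (1 + b2) * sens**2 / denom**2
                d_sens = (1 + b2) * b2 * spec**2 / denom**2
                if n_neg > 0:
                    grad[:, c] -= d_spec * (-(1 - t) / n_neg)
                if n_pos > 0:
                    grad[:, c] -= d_sens * (t / n_pos)
    loss = 1.0 - float(np.mean(loss_terms))
    grad /= len(present)
    return loss, grad


def fbeta_loss(probs: np.ndarray, truth_onehot: np.ndarray,
               beta: float = 2.0,
               variant: str = "precision_recall") -> float:
    """1 − soft-F_beta of per-voxel class probabilities against one-hot truth.

    Lies in [0, 1]; zero for a perfect prediction; on hard {0,1}
    probabilities it equals the F_beta formula on hard confusion counts
    (so beta=1 reproduces 1 − Dice).
    """
    probs = np.asarray(probs, dtype=float)
    truth_onehot = np.asarray(truth_onehot, dtype=float)
    if probs.shape != truth_onehot.shape:
        raise ValueError(f"shape mismatch: {probs.shape} vs {truth_onehot.shape}")
    if probs.min() < -1e-9 or probs.max() > 1 + 1e-9:
        raise ValueError("probabilities must lie in [0, 1]")
    if variant not in ("precision_recall", "specificity_sensitivity"):
        raise ValueError(f"unknown variant {variant!r}")
    loss, _ = _soft_fbeta(probs, truth_onehot, beta, variant)
    return loss


def _onehot(labels: np.ndarray, n_classes: int) -> np.ndarray:
    out = np.zeros((labels.shape[0], n_classes) + labels.shape[1:])
    for c in range(n_classes):
        out[:, c] = labels == c
    return out


# ---------------------------------------------------------------------------
# Segment extraction and sampling
# ---------------------------------------------------------------------------

def _gather_pathway(data: np.ndarray, start, ncfg: NetworkConfig, factor: int):
    """Input patch for one pathway of a tile starting at ``start``.

    The sub-sampled pathways read the volume on the absolute coarse grid
    (cells of ``factor`` voxels anchored at index 0, sampled at cell
    centres), which is what makes tiled inference partition-independent.
    Out-of-volume indices are clamped (edge replication).
    """
    rf = ncfg._rf()
    out = ncfg.output_shape()
    n = data.shape
    idx, phase = [], []
    for a in range(3):
        h = (rf[a] - 1) // 2
        if factor == 1:
            ids = np.arange(start[a] - h, start[a] + out[a] + h)
        else:
            j0 = start[a] // factor
            m = (out[a] - 1) // factor + 2
            cells = np.arange(j0 - h, j0 + m + h)
            ids = cells * factor + factor // 2
        idx.append(np.clip(ids, 0, n[a] - 1))
        phase.append(start[a] % factor)
    patch = data[np.ix_(idx[0], idx[1], idx[2])]
    return patch[None, :, :, :], np.asarray(phase)


def extract_segment(data: np.ndarray, start, ncfg: NetworkConfig):
    """Per-pathway input patches and phases for one output tile."""
    inputs, phases = [], []
    for f in ncfg.pathway_subsampling:
        patch, ph = _gather_pathway(data, start, ncfg, f)
        inputs.append(patch)
        phases.append(ph)
    return inputs, np.asarray(phases)


def sample_training_segments(vol: ImageVolume, labels: LabelMap,
                             ncfg: NetworkConfig, tcfg: TrainingConfig,
                             seed: int, n_segments: int | None = None):
    """Draw training segments, a configured fraction centred on foreground.

    Each segment is an output tile plus the per-pathway input patches
    that feed it.  With probability ``foreground_fraction`` the tile is
    centred on a uniformly drawn foreground voxel, otherwise on a
    background voxel; tiles are clamped inside the volume.  Deterministic
    given ``seed``.  Returns ``(inputs, phases, targets)`` where
    ``inputs[p]`` stacks the pathway-p patches (B, 1, ...), ``phases``
    is (B, n_pathways, 3) and ``targets`` is (B, *output_shape) int.
    """
    if not same_grid(vol, labels):
        raise ValueError("volume and labels are on different grids")
    out = ncfg.output_shape()
    shape = vol.data.shape
    if any(shape[a] < out[a] for a in range(3)):
        raise ValueError(f"volume {shape} smaller than the minimum extent "
                         f"{out} required by one output tile")
    n_segments = tcfg.segments_per_volume if n_segments is None else n_segments
    rng = np.random.default_rng(seed)
    fg_idx = np.argwhere(labels.labels > 0)
    bg_idx = np.argwhere(labels.labels == 0)
    if len(fg_idx) == 0:
        raise ValueError("no foreground to sample")
    if len(bg_idx) == 0:
        bg_idx = fg_idx

    data = np.asarray(vol.data, dtype=np.float64)
    all_inputs = [[] for _ in ncfg.pathway_subsampling]
    phases, targets = [], []
    for _ in range(n_segments):
        pool = fg_idx if rng.random() < tcfg.foreground_fraction else bg_idx
        center = pool[rng.integers(len(pool))]
        start = [int(np.clip(center[a] - out[a] // 2, 0, shape[a] - out[a]))
                 for a in range(3)]
        inputs, ph = extract_segment(data, start, ncfg)
        for p, patch in enumerate(inputs):
            all_inputs[p].append(patch)
        phases.append(ph)
        targets.append(labels.labels[start[0]:start[0] + out[0],
                                     start[1]:start[1] + out[1],
                                     start[2]:start[2] + out[2]])
    inputs = [np.stack(parts) for parts in all_inputs]
    return inputs, np.stack(phases), np.stack(targets)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def train(model: MultiScaleNet, dataset, tcfg: TrainingConfig,
          validation=None):
    """Train on (volume, labels) pairs; returns ``(model, history)``.

    ``history['train_loss']`` has one mean segment loss per epoch (and
    ``history['val_loss']`` likewise when validation pairs are given).
    All randomness is seeded from ``tcfg.seed``; non-finite loss aborts
    with the epoch index.
    """
    if len(dataset) < 1:
        raise ValueError("need at least one training pair")
    cfg = model.config
    velocity = [np.zeros_like(w) for w, _ in model.params()]
    m1 = [np.zeros_like(w) for w, _ in model.params()]
    m2 = [np.zeros_like(w) for w, _ in model.params()]
    step = 0
    history = {"train_loss": []}
    if validation:
        history["val_loss"] = []
    lr = tcfg.learning_rate
    for epoch in range(tcfg.epochs):
        losses = []
        order = np.random.default_rng(tcfg.seed * 1000003 + epoch).permutation(
            len(dataset))
        for vi in order:
            vol, labels = dataset[vi]
            seed = (tcfg.seed * 7654321 + epoch * 101 + int(vi)) % (2**31 - 1)
            inputs, phases, targets = sample_training_segments(
                vol, labels, cfg, tcfg, seed)
            n = targets.shape[0]
            for lo in range(0, n, tcfg.batch_size):
                sl = slice(lo, min(lo + tcfg.batch_size, n))
                batch_in = [x[sl] for x in inputs]
                probs = model.forward(batch_in, phases[sl])
                onehot = _onehot(targets[sl], cfg.n_classes)
                loss, dprobs = _soft_fbeta(probs, onehot, cfg.beta,
                                           cfg.loss_variant)
                if not np.isfinite(loss):
                    raise RuntimeError(f"divergence (non-finite loss) at "
                                       f"epoch {epoch}")
                losses.append(loss)
                inner = (probs * dprobs).sum(axis=1, keepdims=True)
                dlogits = probs * (dprobs - inner)
                model.zero_grad()
                model.backward(dlogits)
                step += 1
                for k, (w, g) in enumerate(model.params()):
                    if tcfg.optimizer == "adam":
                        m1[k] = 0.9 * m1[k] + 0.1 * g
                        m2[k] = 0.999 * m2[k] + 0.001 * g * g
                        mh = m1[k] / (1.0 - 0.9**step)
                        vh = m2[k] / (1.0 - 0.999**step)
                        w -= lr * mh / (np.sqrt(vh) + 1e-8)
                    else:
                        velocity[k] = tcfg.momentum * velocity[k] - lr * g
                        w += velocity[k]
        history["train_loss"].append(float(np.mean(losses)))
        if validation:
            vlosses = []
            for vi, (vol, labels) in enumerate(validation):
                seed = (tcfg.seed * 31337 + epoch * 17 + vi) % (2**31 - 1)
                inputs, phases, targets = sample_training_segments(
                    vol, labels, cfg, tcfg, seed,
                    n_segments=max(4, tcfg.segments_per_volume // 4))
                probs = model.forward(inputs, phases)
                onehot = _onehot(targets, cfg.n_classes)
                vloss, _ = _soft_fbeta(probs, onehot, cfg.beta,
                                       cfg.loss_variant)
                vlosses.append(vloss)
            history["val_loss"].append(float(np.mean(vlosses)))
        lr *= tcfg.lr_decay
    return model, history


# ---------------------------------------------------------------------------
# Inference
# ---------------------------------------------------------------------------

def predict_volume(model: MultiScaleNet, vol: ImageVolume,
                   batch_tiles: int = 8) -> LabelMap:
    """Full-volume class map by overlapping-tile inference.

    The volume is covered by output tiles on a regular grid (the last
    tile per axis is shifted inward to fit); because convolutions are
    valid and the coarse pathways read an absolute grid, overlapping
    tiles agree exactly and every voxel gets one deterministic label
    (argmax, ties to the lowest class code).
    """
    cfg = model.config
    out = cfg.output_shape()
    shape = vol.data.shape
    if any(shape[a] < out[a] for a in range(3)):
        raise ValueError(f"volume {shape} smaller than minimum tile {out}")
    starts_per_axis = []
    for a in range(3):
        s = list(range(0, shape[a] - out[a] + 1, out[a]))
        if s[-1] != shape[a] - out[a]:
            s.append(shape[a] - out[a])
        starts_per_axis.append(s)
    tiles = [(i, j, k) for i in starts_per_axis[0]
             for j in starts_per_axis[1] for k in starts_per_axis[2]]
    data = np.asarray(vol.data, dtype=np.float64)
    result = np.zeros(shape, dtype=np.int16)
    for lo in range(0, len(tiles), batch_tiles):
        chunk = tiles[lo:lo + batch_tiles]
        batch_inputs = [[] for _ in cfg.pathway_subsampling]
        batch_phases = []
        for start in chunk:
            inputs, phases = extract_segment(data, start, cfg)
            for p, patch in enumerate(inputs):
                batch_inputs[p].append(patch)
            batch_phases.append(phases)
        probs = model.forward([np.stack(b) for b in batch_inputs],
                              np.stack(batch_phases))
        pred = np.argmax(probs, axis=1).astype(np.int16)
        for b, start in enumerate(chunk):
            result[start[0]:start[0] + out[0], start[1]:start[1] + out[1],
                   start[2]:start[2] + out[2]] = pred[b]
    return LabelMap(result, vol.spacing, vol.origin)


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(model: MultiScaleNet, path: str) -> None:
    """Serialize weights with the architecture config embedded."""
    arrays = {f"p{i}": w for i, (w, _) in enumerate(model.params())}
    cfg = asdict(model.config)
    np.savez_compressed(path, config=json.dumps(cfg), **arrays)


def load_checkpoint(path: str) -> MultiScaleNet:
    with np.load(path, allow_pickle=False) as data:
        cfg_dict = json.loads(str(data["config"]))
        for key in ("pathway_subsampling", "feature_maps", "fc_widths",
                    "input_segment_shape"):
            cfg_dict[key] = tuple(cfg_dict[key])
        cfg_dict["kernel_shapes"] = tuple(tuple(k) for k
                                          in cfg_dict["kernel_shapes"])
        model = MultiScaleNet(NetworkConfig(**cfg_dict))
        for i, (w, _) in enumerate(model.params()):
            w[...] = data[f"p{i}"]
    return model
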