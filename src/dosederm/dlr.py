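"""Deep radiomic features from a frozen 13-conv-layer VGG-16-topology CNN.

Each of the 13 convolutional layers (3x3 kernels, stride 1, padding 1,
ReLU; 2x2 max-pooling after layers 2, 4, 7, 10 and 13) is tapped with
global average pooling (GAP) over its post-activation map; the 13 pooled
blocks concatenate to a 4224-dimensional per-slice vector
(64+64+128+128+256x3+512x6).  Per-patient features are the element-wise
mean over eligible slices.

Weights are frozen.  The default ``weights_mode='seeded-random'`` draws
He-normal weights from a seed, which makes extraction fully reproducible
offline; externally supplied pretrained weights can be plugged in via
``VggGapExtractor.set_weights``.

The extractor also implements the exact backward pass (through GAP, ReLU,
max-pool routing and transposed convolution) used for Grad-CAM saliency.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from dosederm.core import ImageGrid, StructureMask

LAYER_CHANNELS = (64, 64, 128, 128, 256, 256, 256, 512, 512, 512, 512, 512, 512)
POOL_AFTER = frozenset({2, 4, 7, 10, 13})  # 1-based conv layer indices
N_FEATURES = sum(LAYER_CHANNELS)  # 4224


@dataclass
class ExtractorConfig:
    """Frozen-extractor settings (13 conv layers summing to 4224 taps)."""

    input_size: int = 512
    weights_mode: str = "seeded-random"
    seed: int = 0
    hu_window: tuple[float, float] = (-1000.0, 1000.0)
    # identity normalization keeps the masked background at exactly 0, so
    # off-ROI pixels contribute nothing through the ReLU stack; pretrained
    # weights would instead install their own training-time constants here
    channel_mean: tuple[float, float, float] = (0.0, 0.0, 0.0)
    channel_std: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        if self.weights_mode not in ("seeded-random", "pretrained"):
            raise ValueError("weights_mode must be 'seeded-random' or 'pretrained'")


@dataclass
class InputDesign:
    """One of the four input-source designs.

    ``original`` feeds the unmasked slice; the masked designs
    (``skin5mm``, ``ptv100``, ``v5gy``) zero everything outside their ROI.
    """

    name: str
    roi: StructureMask | None = None

    def __post_init__(self) -> None:
        if self.name not in ("original", "skin5mm", "ptv100", "v5gy"):
            raise ValueError(f"unknown design {self.name!r}")
        if self.name == "original" and self.roi is not None:
            raise ValueError("original design takes no ROI")
        if self.name != "original" and self.roi is None:
            raise ValueError(f"design {self.name!r} requires an ROI")


def feature_names(design: str) -> list[str]:
    names = []
    for layer, ch in enumerate(LAYER_CHANNELS, start=1):
        names.extend(f"dlr_{design}_conv{layer}_{c}" for c in range(ch))
    return names


def _conv2d(x: np.ndarray, w: np.ndarray, row_chunk: int = 128) -> np.ndarray:
    """3x3 stride-1 same-padding convolution; x (H,W,Cin), w (3,3,Cin,Cout)."""
    h, wd, _ = x.shape
    pad = np.pad(x, ((1, 1), (1, 1), (0, 0)))
    out = np.empty((h, wd, w.shape[3]), dtype=np.float32)
    windows = np.lib.stride_tricks.sliding_window_view(pad, (3, 3), axis=(0, 1))
    # windows: (H, W, Cin, 3, 3); contract (Cin, kh, kw) against w (kh, kw, Cin, Cout)
    for r0 in range(0, h, row_chunk):
        r1 = min(h, r0 + row_chunk)
        out[r0:r1] = np.tensordot(windows[r0:r1], w,
                                  axes=([2, 3, 4], [2, 0, 1])).astype(np.float32)
    return out


def _maxpool2(x: np.ndarray):
    """2x2 stride-2 max pool; returns pooled map and argmax for routing."""
    h, w, c = x.shape
    h2, w2 = h // 2, w // 2
    blocks = x[: h2 * 2, : w2 * 2].reshape(h2, 2, w2, 2, c)
    flat = blocks.transpose(0, 2, 1, 3, 4).reshape(h2, w2, 4, c)
    arg = flat.argmax(axis=2)
    pooled = np.take_along_axis(flat, arg[:, :, None, :], axis=2)[:, :, 0, :]
    return pooled, arg


def _unpool2(grad: np.ndarray, arg: np.ndarray, shape) -> np.ndarray:
    """Route pooled gradients back to the argmax positions."""
    h2, w2, c = grad.shape
    flat = np.zeros((h2, w2, 4, c), dtype=grad.dtype)
    np.put_along_axis(flat, arg[:, :, None, :], grad[:, :, None, :], axis=2)
    blocks = flat.reshape(h2, w2, 2, 2, c).transpose(0, 2, 1, 3, 4)
    out = np.zeros(shape, dtype=grad.dtype)
    out[: h2 * 2, : w2 * 2] = blocks.reshape(h2 * 2, w2 * 2, c)
    return out


class VggGapExtractor:
    """Frozen convolutional feature extractor with per-layer GAP taps."""

    def __init__(self, config: ExtractorConfig | None = None):
        self.config = config or ExtractorConfig()
        if self.config.weights_mode == "seeded-random":
            rng = np.random.default_rng(self.config.seed)
            self.weights = []
            self.biases = []
            c_in = 3
            for c_out in LAYER_CHANNELS:
                fan_in = 9 * c_in
                w = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                               size=(3, 3, c_in, c_out)).astype(np.float32)
                self.weights.append(w)
                self.biases.append(np.zeros(c_out, dtype=np.float32))
                c_in = c_out
        else:
            self.weights = None  # must be supplied via set_weights
            self.biases = None
        self._cache = None

    def set_weights(self, weights, biases) -> None:
        """Install externally provided (e.g. pretrained) frozen weights."""
        if len(weights) != 13 or len(biases) != 13:
            raise ValueError("expected 13 weight/bias pairs")
        for w, c_out in zip(weights, LAYER_CHANNELS):
            if w.shape[3] != c_out:
                raise ValueError("channel counts do not match the topology")
        self.weights = [np.asarray(w, dtype=np.float32) for w in weights]
        self.biases = [np.asarray(b, dtype=np.float32) for b in biases]

    def forward(self, x: np.ndarray, keep_activations: bool = False) -> np.ndarray:
        """GAP feature vector (4224,) for one prepared input (H,W,3)."""
        if self.weights is None:
            raise RuntimeError("no weights installed")
        size = self.config.input_size
        if x.shape != (size, size, 3):
            raise ValueError(
                f"shape mismatch: expected ({size},{size},3), got {x.shape}")
        x = x.astype(np.float32)
        gaps = []
        activations = []
        pool_args = []
        for layer, (w, b) in enumerate(zip(self.weights, self.biases), start=1):
            a = np.maximum(_conv2d(x, w) + b, 0.0)
            gaps.append(a.mean(axis=(0, 1)))
            if keep_activations:
                activations.append(a)
            if layer in POOL_AFTER:
                x, arg = _maxpool2(a)
                if keep_activations:
                    pool_args.append(arg)
            else:
                x = a
                if keep_activations:
                    pool_args.append(None)
        if keep_activations:
            self._cache = (activations, pool_args)
        return np.concatenate(gaps).astype(np.float64)

    def backward_to_layer(self, gap_grads: np.ndarray, layer_index: int) -> np.ndarray:
        """Gradient of ``sum_l gap_grads[l] . GAP_l`` w.r.t. one layer's map.

        ``gap_grads`` is a 4224-vector of upstream gradients on the
        concatenated GAP features; ``layer_index`` is 1-based.  Requires a
        preceding ``forward(..., keep_activations=True)``.
        """
        if self._cache is None:
            raise RuntimeError("run forward(keep_activations=True) first")
        if not (1 <= layer_index <= 13):
            raise ValueError("no such layer")
        activations, pool_args = self._cache
        blocks = np.split(gap_grads, np.cumsum(LAYER_CHANNELS)[:-1])

        def inject(layer: int) -> np.ndarray:
            a = activations[layer - 1]
            hw = a.shape[0] * a.shape[1]
            return np.broadcast_to(blocks[layer - 1].astype(np.float32) / hw,
                                   a.shape).copy()

        g = inject(13)
        for layer in range(13, layer_index, -1):
            a = activations[layer - 1]
            g = g * (a > 0)  # through ReLU of layer `layer`
            w = self.weights[layer - 1]
            w_t = w[::-1, ::-1].transpose(0, 1, 3, 2)  # rotate + swap channels
            g = _conv2d(g, w_t)  # grad w.r.t. conv input of `layer`
            if (layer - 1) in POOL_AFTER:
                g = _unpool2(g, pool_args[layer - 2],
                             activations[layer - 2].shape)
            g = g + inject(layer - 1)
        return g


def prepare_slice(ct_slice: np.ndarray, design: InputDesign,
                  config: ExtractorConfig, roi_slice: np.ndarray | None = None):
    """Window, scale, mask and normalize one CT slice into network input.

    HU are clipped to the window and scaled to [0,1]; for masked designs
    voxels outside the ROI slice are set to 0 (after scaling); the single
    channel is replicated to 3 and per-channel normalization applied.  The
    slice is resampled to ``input_size`` squared (bilinear; nearest for the
    mask).
    """
    lo, hi = config.hu_window
    img = (np.clip(ct_slice.astype(np.float64), lo, hi) - lo) / (hi - lo)
    if design.name != "original":
        if roi_slice is None:
            raise ValueError("masked design requires an ROI slice")
        if not roi_slice.any():
            raise ValueError("empty roi slice")
        img = np.where(roi_slice, img, 0.0)
    size = config.input_size
    if img.shape != (size, size):
        img = ndimage.zoom(img, (size / img.shape[0], size / img.shape[1]),
                           order=1, mode="nearest", grid_mode=True)
        img = img[:size, :size]
    out = np.empty((size, size, 3), dtype=np.float32)
    for c in range(3):
        out[:, :, c] = (img - config.channel_mean[c]) / config.channel_std[c]
    return out


def extract_slice_features(extractor: VggGapExtractor, prepared: np.ndarray) -> np.ndarray:
    """4224-dimensional GAP vector for one prepared slice."""
    return extractor.forward(prepared)


def aggregate_patient(slice_vectors) -> np.ndarray:
    """Element-wise mean of per-slice vectors (slice-order invariant)."""
    vecs = np.asarray(list(slice_vectors), dtype=np.float64)
    if vecs.ndim != 2 or vecs.shape[0] == 0:
        raise ValueError("no eligible slices")
    return vecs.mean(axis=0)


def eligible_slices(ct: ImageGrid, design: InputDesign,
                    body: StructureMask | None = None,
                    min_roi_pixels: int = 16) -> list[int]:
    """Slice eligibility: ROI area >= 16 px (masked) or body extent (original)."""
    nz = ct.shape[0]
    if design.name == "original":
        if body is None:
            return list(range(nz))
        return [k for k in range(nz) if body.mask[k].any()]
    return [k for k in range(nz) if design.roi.mask[k].sum() >= min_roi_pixels]


def extract_patient(extractor: VggGapExtractor, ct: ImageGrid,
                    design: InputDesign, body: StructureMask | None = None) -> np.ndarray:
    """Per-patient DLR vector: slice-wise extraction then averaging.

    Raises ``no eligible slices`` when every slice fails the eligibility
    rule (the patient is flagged upstream, mirroring ROI-size exclusions).
    """
    idx = eligible_slices(ct, design, body)
    if not idx:
        raise ValueError("no eligible slices")
    vecs = []
    for k in idx:
        roi_slice = design.roi.mask[k] if design.roi is not None else None
        prepared = prepare_slice(ct.values[k], design, extractor.config, roi_slice)
        vecs.append(extractor.forward(prepared))
    return aggregate_patient(vecs)
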