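"""Model explainability: sampling Shapley attributions and Grad-CAM.

The stacked ensemble is not differentiable end-to-end, so feature
attributions use a model-agnostic permutation-sampling Shapley estimator
over the full predictor: for each sampled (permutation, background row)
pair the explained point's features are switched in one at a time in
permutation order and the prediction deltas accumulated.  The telescoping
sum makes local additivity exact: base value + sum of attributions equals
the model output for every explained row.

Grad-CAM saliency uses a differentiable scalar head -- a logistic probe on
(selected) deep GAP features -- attached to the frozen convolutional
extractor.  Channel weights are the spatial mean of the logit gradient
w.r.t. the chosen layer's activation map; the map is the ReLU of the
weighted activation sum, normalized to [0, 1] and bilinearly upsampled to
input resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from sklearn.linear_model import LogisticRegression

from dosederm.core import StructureMask
from dosederm.dlr import N_FEATURES, VggGapExtractor


@dataclass
class ShapReport:
    """Per-(row, feature) attributions with the exact-additivity contract."""

    values: np.ndarray  # (n_explain, n_features)
    base_value: float
    feature_names: list[str]
    predictions: np.ndarray

    def ranking(self) -> list[tuple[str, float]]:
        """Features sorted by mean |attribution| (descending)."""
        imp = np.abs(self.values).mean(axis=0)
        order = np.argsort(imp)[::-1]
        return [(self.feature_names[i], float(imp[i])) for i in order]


def shap_attributions(predict_fn, X_background: np.ndarray,
                      X_explain: np.ndarray, n_permutations: int = 32,
                      seed: int = 0,
                      feature_names: list[str] | None = None) -> ShapReport:
    """Permutation-sampling Shapley values of ``predict_fn`` (probabilities).

    ``predict_fn`` maps an (n, m) array to (n,) outputs (e.g. the positive-
    class probability of a fitted stacked model).  Backgrounds are drawn
    from ``X_background``; attribution noise shrinks as ``n_permutations``
    grows while additivity holds exactly at any sample size.
    """
    X_background = np.asarray(X_background, dtype=float)
    X_explain = np.atleast_2d(np.asarray(X_explain, dtype=float))
    if X_background.shape[0] == 0:
        raise ValueError("no background")
    rng = np.random.default_rng(seed)
    n, m = X_explain.shape
    names = feature_names or [f"f{j}" for j in range(m)]

    bg_idx = rng.integers(0, X_background.shape[0], size=n_permutations)
    perms = [rng.permutation(m) for _ in range(n_permutations)]
    values = np.zeros((n, m))
    base_acc = 0.0
    preds = predict_fn(X_explain)
    for r in range(n):
        x = X_explain[r]
        rows = np.empty((n_permutations * (m + 1), m))
        for s in range(n_permutations):
            z = X_background[bg_idx[s]].copy()
            block = rows[s * (m + 1): (s + 1) * (m + 1)]
            block[0] = z
            for k, j in enumerate(perms[s], start=1):
                z = z.copy()
                z[j] = x[j]
                block[k] = z
        f = predict_fn(rows)
        for s in range(n_permutations):
            fs = f[s * (m + 1): (s + 1) * (m + 1)]
            deltas = np.diff(fs)
            values[r, perms[s]] += deltas
            if r == 0:
                base_acc += fs[0]
    values /= n_permutations
    base = float(base_acc / n_permutations)
    return ShapReport(values=values, base_value=base, feature_names=names,
                      predictions=np.asarray(preds, dtype=float))


@dataclass
class SaliencyMap:
    """One layer's Grad-CAM heat map aligned to the network input."""

    map: np.ndarray  # (input_size, input_size) in [0, 1]
    layer_index: int
    channel_weights: np.ndarray
    degenerate: bool = False  # all-zero gradient -> all-zero map, flagged


def logistic_probe(gap_features: np.ndarray, y, selected: np.ndarray | None = None,
                   seed: int = 0) -> tuple[np.ndarray, float]:
    """Train a logistic scalar head on (selected) GAP features.

    Returns a weight vector in the full 4224-feature space (zeros off the
    selected set, standardization folded into the weights) and the bias.
    """
    gap_features = np.asarray(gap_features, dtype=float)
    y = np.asarray(y).astype(int)
    if selected is None:
        selected = np.arange(gap_features.shape[1])
    sub = gap_features[:, selected]
    mu, sd = sub.mean(axis=0), sub.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    lr = LogisticRegression(max_iter=2000, random_state=seed)
    lr.fit((sub - mu) / sd, y)
    w_full = np.zeros(gap_features.shape[1])
    w_full[selected] = lr.coef_[0] / sd
    bias = float(lr.intercept_[0] - np.sum(lr.coef_[0] * mu / sd))
    return w_full, bias


def grad_cam(extractor: VggGapExtractor, probe_weights: np.ndarray,
             prepared_slice: np.ndarray, layer_index: int) -> SaliencyMap:
    """Grad-CAM of the probe logit at one convolutional layer.

    Channel weights are the GAP of the logit gradient w.r.t. the layer's
    post-activation map (gradients flow through all deeper layers as well
    as the layer's own GAP tap).
    """
    probe_weights = np.asarray(probe_weights, dtype=float)
    if probe_weights.shape != (N_FEATURES,):
        raise ValueError(f"probe weights must have length {N_FEATURES}")
    if not (1 <= layer_index <= 13):
        raise ValueError("no such layer")
    extractor.forward(prepared_slice, keep_activations=True)
    grad = extractor.backward_to_layer(probe_weights, layer_index)
    activations = extractor._cache[0][layer_index - 1]
    weights = grad.mean(axis=(0, 1))  # GAP of the gradient
    raw = np.maximum((activations * weights[None, None, :]).sum(axis=2), 0.0)
    degenerate = bool(np.all(grad == 0) or raw.max() == 0)
    if raw.max() > 0:
        raw = raw / raw.max()
    size = extractor.config.input_size
    if raw.shape != (size, size):
        raw = ndimage.zoom(raw, (size / raw.shape[0], size / raw.shape[1]),
                           order=1, mode="nearest", grid_mode=True)
        raw = np.clip(raw[:size, :size], 0.0, 1.0)
    return SaliencyMap(map=raw, layer_index=layer_index,
                       channel_weights=weights, degenerate=degenerate)


def save_heatmap(saliency: SaliencyMap | np.ndarray, path) -> None:
    """Export a saliency map as a PNG (jet colormap, fixed [0,1] range)."""
    import matplotlib

    matplotlib.use("Agg")
    from matplotlib import image as mpimg
    from matplotlib import pyplot as plt

    m = saliency.map if isinstance(saliency, SaliencyMap) else np.asarray(saliency)
    mpimg.imsave(path, m, vmin=0.0, vmax=1.0, cmap=plt.get_cmap("jet"))


def overlap_score(saliency: SaliencyMap | np.ndarray, reference: np.ndarray,
                  quantile: float = 0.8) -> float:
    """Dice overlap between the map's top-(1-quantile) pixels and a mask."""
    m = saliency.map if isinstance(saliency, SaliencyMap) else np.asarray(saliency)
    ref = reference.mask if isinstance(reference, StructureMask) else np.asarray(reference)
    ref = ref.astype(bool)
    if m.shape != ref.shape:
        raise ValueError("map and reference are not congruent")
    if not ref.any():
        raise ValueError("empty reference")
    thr = np.quantile(m, quantile)
    top = m > thr
    denom = top.sum() + ref.sum()
    if denom == 0:
        return 0.0
    return float(2.0 * np.sum(top & ref) / denom)
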