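"""Visual explanation of the trained AIO classifier.

Two gradient-complementary methods attribute a prediction to AIO pixels:

* **Saliency map** — |∂ logit(target class) / ∂ input|, reduced over the 3
  channels (max by default, L2 optional) and normalized to [0, 1] by the
  map's maximum (an all-zero map stays zero).
* **Score-CAM** — gradient-free class activation mapping: each activation
  map of a chosen convolution layer is upsampled to the input size
  (nearest-neighbor, preserving the blocky AIO geometry), min–max
  normalized, used to mask the input (baseline: all-zero image), and scored
  by a forward pass on the target class; the maps are combined with
  softmax weights and rectified.

Maps are computed per accession and can be averaged per flowering-time
class. :func:`block_attribution_summary` splits a map's mass between the
genotype and climate blocks (padding pixels excluded) and ranks pixels with
their SNP or (factor, day) annotation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .aio import N_ROWS, N_CLIMATE_COLS, aio_width, snp_position
from .io import CLIMATE_FACTORS, WINDOW_DAYS


@dataclass
class ExplanationMap:
    """Non-negative per-pixel attribution aligned to an AIO (6 × width)."""

    values: np.ndarray
    kind: str                      # "saliency" | "score_cam"
    target_class: int
    accession_id: str = "unknown"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != N_ROWS:
            raise ValueError(f"explanation map must be 6×width, got {self.values.shape}")
        if (self.values < 0).any():
            raise ValueError("explanation map must be non-negative")


def _to_batch(aio_tensor):
    x = np.asarray(aio_tensor, dtype=float)
    if x.ndim == 3:
        x = x[None]
    return x


def saliency_map(net, aio_tensor, target_class: int, channel_reduce: str = "max",
                 accession_id: str = "unknown") -> ExplanationMap:
    """Input-gradient saliency for one AIO tensor (6 × width × 3, scaled to
    [0, 1])."""
    x = _to_batch(aio_tensor)
    grad = net.input_gradient(x, target_class)[0]
    mag = np.abs(grad)
    if channel_reduce == "max":
        sal = mag.max(axis=-1)
    elif channel_reduce == "l2":
        sal = np.sqrt((mag ** 2).sum(axis=-1))
    else:
        raise ValueError("channel_reduce must be 'max' or 'l2'")
    peak = sal.max()
    if peak > 0:
        sal = sal / peak
    return ExplanationMap(sal, "saliency", target_class, accession_id)


def _upsample_nearest(act: np.ndarray, out_shape) -> np.ndarray:
    """Nearest-neighbor upsample of a 2-D map to ``out_shape``."""
    h, w = act.shape
    H, W = out_shape
    rows = (np.arange(H) * h) // H
    cols = (np.arange(W) * w) // W
    return act[np.ix_(rows, cols)]


def score_cam(net, aio_tensor, target_class: int, layer_index: int = -1,
              accession_id: str = "unknown") -> ExplanationMap:
    """Score-CAM explanation using the activation maps of a convolution
    layer (default: the last one).

    Each activation map is upsampled to the input size, min–max normalized,
    multiplied elementwise into the input (all-zero baseline), and the
    masked input's softmax-weighted target-class scores combine the maps:
    out = ReLU(Σ_k w_k A_k), normalized to [0, 1].
    """
    x = _to_batch(aio_tensor)
    acts = net.conv_activations(x)
    if not acts:
        raise ValueError("network has no convolution layers")
    act = acts[layer_index][0]          # H' × W' × F
    H, W = x.shape[1], x.shape[2]
    n_maps = act.shape[-1]
    masks = np.empty((n_maps, H, W))
    valid = np.zeros(n_maps, dtype=bool)
    for k in range(n_maps):
        up = _upsample_nearest(act[..., k], (H, W))
        lo, hi = up.min(), up.max()
        if hi > lo:
            masks[k] = (up - lo) / (hi - lo)
            valid[k] = True
        else:
            masks[k] = 0.0
    if not valid.any():
        warnings.warn("all activation maps are constant; Score-CAM map is zero", stacklevel=2)
        return ExplanationMap(np.zeros((H, W)), "score_cam", target_class, accession_id)
    masked = x * masks[:, :, :, None]   # n_maps × H × W × 3
    logits = net.forward(masked, training=False)
    scores = logits[:, target_class]
    scores = np.where(valid, scores, -np.inf)
    w = np.exp(scores - scores[np.isfinite(scores)].max())
    w[~np.isfinite(w)] = 0.0
    w = w / w.sum()
    cam = np.tensordot(w, masks, axes=1)
    cam = np.maximum(cam, 0.0)
    peak = cam.max()
    if peak > 0:
        cam = cam / peak
    return ExplanationMap(cam, "score_cam", target_class, accession_id)


def average_by_class(maps, labels):
    """Elementwise mean of explanation maps within each class label; empty
    classes are skipped with a warning. Returns {label: ExplanationMap}."""
    maps = list(maps)
    labels = np.asarray(labels)
    if len(maps) != len(labels):
        raise ValueError("one label per map required")
    shapes = {m.values.shape for m in maps}
    if len(shapes) > 1:
        raise ValueError(f"maps have inconsistent shapes: {shapes}")
    out = {}
    for lab in np.unique(labels):
        members = [m for m, l in zip(maps, labels) if l == lab]
        if not members:
            warnings.warn(f"class {lab} has no maps; skipped", stacklevel=2)
            continue
        mean = np.mean([m.values for m in members], axis=0)
        out[int(lab)] = ExplanationMap(mean, members[0].kind, int(lab), "class-average")
    return out


def block_attribution_summary(emap: ExplanationMap, K: int, top: int = 10):
    """Split attribution mass between genotype and climate blocks and rank
    the top pixels.

    Padding pixels (genotype cells beyond K) are excluded from both the
    genotype mass and the ranking. Returns a dict with ``genotype_share``,
    ``climate_share`` and ``top_pixels`` (list of (row, col, value,
    annotation)); the shares sum to 1 for a nonzero map.
    """
    values = emap.values
    width = values.shape[1]
    if width != aio_width(K):
        raise ValueError(f"map width {width} inconsistent with K={K} (expected {aio_width(K)})")
    g_cols = width - N_CLIMATE_COLS
    informative = np.zeros_like(values, dtype=bool)
    for k in range(K):
        r, c = snp_position(k)
        informative[r, c] = True
    genotype_mass = float(values[informative].sum())
    climate_mass = float(values[:, g_cols:].sum())
    total = genotype_mass + climate_mass
    if total > 0:
        shares = (genotype_mass / total, climate_mass / total)
    else:
        shares = (0.0, 0.0)

    annotated = []
    for r in range(N_ROWS):
        for c in range(width):
            if c < g_cols:
                if not informative[r, c]:
                    continue
                k = c * N_ROWS + r
                ann = f"snp:{k}"
            else:
                day = WINDOW_DAYS[c - g_cols]
                ann = f"{CLIMATE_FACTORS[r]}@day{day:+d}"
            annotated.append((r, c, float(values[r, c]), ann))
    annotated.sort(key=lambda t: (-t[2], t[0], t[1]))
    return {
        "genotype_share": shares[0],
        "climate_share": shares[1],
        "top_pixels": annotated[:top],
    }
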