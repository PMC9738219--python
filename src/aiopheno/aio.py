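"""Artificial Image Objects: encoding genotype + climate into RGB rasters.

An AIO is a 6-row, 8-bit RGB image with two side-by-side blocks:

* **genotype block** — ⌈K/6⌉ columns for K selected SNPs, filled
  column-major (SNP k at row k mod 6, column k div 6); each dosage is a
  one-hot pixel: 0 → red, 1 → green, 2 → blue (channel value 255). Unused
  padding cells are black (0,0,0).
* **climate block** — 25 columns × 6 factor rows (150 informative pixels);
  a factor value f is bit-packed by magnitude: v = round(|f|),
  R = v div 255, B = v mod 255, and the G channel flags the sign
  (G = 0 for f > 0, G = 255 for f ≤ 0). Column y holds day d = y − 4
  relative to planting (the window starts 4 days before planting day 0).

Total image width is ⌈K/6⌉ + 25. Stored channels are 8-bit; the network
input divides by 255 so one-hot genotype channels become exactly 1.0.
Images persist as lossless PNG with a JSON sidecar carrying K, SNP ids,
factor order, day range and a format-version tag (the fill order is a
convention of this format, not recoverable from pixel content).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from sklearn.base import BaseEstimator, TransformerMixin

from .io import ClimateWindow, CLIMATE_FACTORS, WINDOW_DAYS

FORMAT_VERSION = "aio-v1-colmajor"

#: Largest encodable climate magnitude: R and B are single bytes, so
#: round(|f|) must fit 255·255 + 254.
MAX_CLIMATE_MAGNITUDE = 255 * 255 + 254

N_ROWS = 6
N_CLIMATE_COLS = 25


def aio_width(K: int) -> int:
    """Image width in pixel columns for K SNPs: ⌈K/6⌉ + 25."""
    if K < 1:
        raise ValueError("K must be ≥ 1")
    return math.ceil(K / N_ROWS) + N_CLIMATE_COLS


def encode_snp_pixel(fg: int) -> tuple[int, int, int]:
    """One-hot dosage pixel: 0→(255,0,0), 1→(0,255,0), 2→(0,0,255)."""
    if fg == 0:
        return (255, 0, 0)
    if fg == 1:
        return (0, 255, 0)
    if fg == 2:
        return (0, 0, 255)
    raise ValueError(f"SNP dosage must be 0, 1 or 2 (impute missing first); got {fg}")


def encode_climate_pixel(fc: float) -> tuple[int, int, int]:
    """Bit-packed climate pixel: v = round(|fc|); R = v div 255,
    B = v mod 255; G flags non-positive values (0 if fc > 0 else 255)."""
    v = int(round(abs(float(fc))))
    if v > MAX_CLIMATE_MAGNITUDE:
        raise ValueError(f"climate magnitude {v} exceeds the encodable maximum {MAX_CLIMATE_MAGNITUDE}")
    g = 0 if fc > 0 else 255
    return (v // 255, g, v % 255)


def decode_climate_pixel(pixel) -> float:
    """Inverse of :func:`encode_climate_pixel` up to integer rounding of the
    magnitude: returns sign · (R·255 + B)."""
    r, g, b = (int(c) for c in pixel)
    if g not in (0, 255):
        raise ValueError(f"climate pixel sign channel must be 0 or 255, got G={g}")
    sign = 1.0 if g == 0 else -1.0
    return sign * (r * 255 + b)


def decode_snp_pixel(pixel) -> int:
    r, g, b = (int(c) for c in pixel)
    mapping = {(255, 0, 0): 0, (0, 255, 0): 1, (0, 0, 255): 2}
    if (r, g, b) not in mapping:
        raise ValueError(f"not a one-hot genotype pixel: {(r, g, b)}")
    return mapping[(r, g, b)]


@dataclass
class AIO:
    """One accession's encoded image: pixels (6 × width × 3, uint8) plus the
    SNP count K defining the genotype/climate block boundary."""

    pixels: np.ndarray
    K: int
    snp_ids: list | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.uint8)
        expected = (N_ROWS, aio_width(self.K), 3)
        if self.pixels.shape != expected:
            raise ValueError(f"pixel array must be {expected} for K={self.K}, got {self.pixels.shape}")

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def g_cols(self) -> int:
        return self.width - N_CLIMATE_COLS

    def genotype_block(self) -> np.ndarray:
        return self.pixels[:, : self.g_cols]

    def climate_block(self) -> np.ndarray:
        return self.pixels[:, self.g_cols:]

    def as_network_input(self) -> np.ndarray:
        """Float tensor scaled to [0, 1] (one-hot channels exactly 1.0)."""
        return self.pixels.astype(np.float64) / 255.0


def snp_position(k: int) -> tuple[int, int]:
    """Row/column of SNP k in the genotype block (column-major fill)."""
    return k % N_ROWS, k // N_ROWS


def build_aio(genotypes, window: ClimateWindow, snp_ids=None) -> AIO:
    """Encode a length-K dosage vector and a complete climate window."""
    g = np.asarray(genotypes)
    if g.ndim != 1 or g.size < 1:
        raise ValueError("genotypes must be a non-empty 1-D dosage vector")
    K = g.size
    width = aio_width(K)
    pixels = np.zeros((N_ROWS, width, 3), dtype=np.uint8)
    for k, fg in enumerate(g):
        row, col = snp_position(k)
        pixels[row, col] = encode_snp_pixel(int(fg))
    g_cols = width - N_CLIMATE_COLS
    values = window.values if isinstance(window, ClimateWindow) else np.asarray(window, dtype=float)
    if values.shape != (N_ROWS, N_CLIMATE_COLS):
        raise ValueError("climate window must be 6×25")
    for x in range(N_ROWS):
        for y in range(N_CLIMATE_COLS):
            pixels[x, g_cols + y] = encode_climate_pixel(values[x, y])
    return AIO(pixels, K, snp_ids=list(snp_ids) if snp_ids is not None else None,
               meta={"format": FORMAT_VERSION})


def decode_aio(aio: AIO, K: int | None = None):
    """Recover (genotypes, climate magnitudes-with-sign) from an AIO.

    Genotypes decode exactly; climate values to the rounded-integer magnitude
    carrying the original sign (f ≤ 0 decodes non-positive).
    """
    K = aio.K if K is None else K
    pixels = aio.pixels
    g = np.empty(K, dtype=np.int64)
    for k in range(K):
        row, col = snp_position(k)
        try:
            g[k] = decode_snp_pixel(pixels[row, col])
        except ValueError as e:
            raise ValueError(f"genotype pixel at ({row},{col}): {e}") from None
    g_cols = aio_width(K) - N_CLIMATE_COLS
    # padding cells must be black
    for k in range(K, g_cols * N_ROWS):
        row, col = snp_position(k)
        if pixels[row, col].any():
            raise ValueError(f"padding pixel at ({row},{col}) is not black")
    climate = np.empty((N_ROWS, N_CLIMATE_COLS))
    for x in range(N_ROWS):
        for y in range(N_CLIMATE_COLS):
            try:
                climate[x, y] = decode_climate_pixel(pixels[x, g_cols + y])
            except ValueError as e:
                raise ValueError(f"climate pixel at ({x},{g_cols + y}): {e}") from None
    return g, climate


def write_image(aio: AIO, path) -> None:
    """Persist as lossless 8-bit RGB PNG plus a JSON sidecar (`.json`)."""
    path = Path(path)
    if path.suffix.lower() not in {".png"}:
        raise ValueError(f"lossless PNG required, got {path.suffix!r}")
    Image.fromarray(aio.pixels, mode="RGB").save(path, format="PNG")
    sidecar = {
        "K": aio.K,
        "snp_ids": aio.snp_ids,
        "factors": list(CLIMATE_FACTORS),
        "days": [WINDOW_DAYS[0], WINDOW_DAYS[-1]],
        "format": FORMAT_VERSION,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar))


def read_image(path) -> AIO:
    path = Path(path)
    pixels = np.asarray(Image.open(path).convert("RGB"), dtype=np.uint8)
    sidecar_path = path.with_suffix(".json")
    if sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text())
        K = sidecar["K"]
        snp_ids = sidecar.get("snp_ids")
        meta = {"format": sidecar.get("format", FORMAT_VERSION)}
    else:
        raise ValueError(f"missing sidecar {sidecar_path}; K is not recoverable from pixels alone")
    return AIO(pixels, K, snp_ids=snp_ids, meta=meta)


class AIOEncoder(BaseEstimator, TransformerMixin):
    """Transformer turning (genotype rows, per-record climate windows) into a
    stack of AIO image tensors.

    ``fit`` records the SNP count/ids; ``transform`` takes a genotype matrix
    restricted to the selected SNPs (n × K dosages) and a matching sequence
    of :class:`ClimateWindow` (one per record) and returns an
    (n × 6 × width × 3) float tensor scaled to [0, 1].
    """

    def __init__(self, snp_ids=None):
        self.snp_ids = snp_ids

    def fit(self, X, y=None):
        X = np.asarray(X)
        self.K_ = X.shape[1]
        self.width_ = aio_width(self.K_)
        return self

    def transform(self, X, windows=None):
        if windows is None:
            raise ValueError("AIOEncoder.transform needs the climate windows")
        X = np.asarray(X)
        if X.shape[1] != self.K_:
            raise ValueError(f"expected {self.K_} SNPs, got {X.shape[1]}")
        out = np.empty((X.shape[0], N_ROWS, self.width_, 3))
        for i in range(X.shape[0]):
            w = windows[i] if not isinstance(windows, ClimateWindow) else windows
            out[i] = build_aio(X[i], w, snp_ids=self.snp_ids).as_network_input()
        return out

    def fit_transform(self, X, y=None, windows=None):
        return self.fit(X).transform(X, windows=windows)
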