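"""Trace-to-image rasterization and horizontal-shift augmentation.

A clean trace is clipped to the [80, 200] bpm band and drawn as a
monochrome curve on a fixed 120-row x 2400-column raster: 200 bpm maps to
row 0, 80 bpm to row 119, linearly in between with half-up rounding.
Consecutive samples are connected by a vertical pixel span so the curve is
visually continuous, as on a paper CTG strip.  Augmentation is restricted
to bounded horizontal shifts — vertical moves or flips would change the
clinical meaning of the curve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

N_ROWS = 120
N_COLS = 2400
BPM_LO = 80.0
BPM_HI = 200.0
#: bpm per pixel row: 120 rows span the 120-bpm clip band on a 119-step grid
BPM_PER_ROW = (BPM_HI - BPM_LO) / (N_ROWS - 1)


@dataclass
class FHRImage:
    """120 x 2400 binary raster; every column contains the curve."""

    pixels: np.ndarray
    source_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.uint8)
        if self.pixels.shape != (N_ROWS, N_COLS):
            raise ValueError(f"image must be {N_ROWS} x {N_COLS}")
        if not np.all((self.pixels == 0) | (self.pixels == 1)):
            raise ValueError("pixels must be binary")
        if not np.all(self.pixels.any(axis=0)):
            raise ValueError("every column must contain the curve")


@dataclass
class AugmentConfig:
    width_shift_fraction: float = 0.2
    fill_mode: str = "nearest-column"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.width_shift_fraction <= 1.0:
            raise ValueError("width_shift_fraction must be in [0, 1]")
        if self.fill_mode != "nearest-column":
            raise ValueError("only nearest-column fill is supported")


def clip_range(values) -> np.ndarray:
    """Standardize the bpm range: below 80 -> 80, above 200 -> 200."""
    v = np.asarray(values, dtype=float)
    if np.any(v == 0):
        raise ValueError("clip_range requires a gap-free trace")
    return np.clip(v, BPM_LO, BPM_HI)


def row_of_bpm(values) -> np.ndarray:
    """Pixel row per sample: round-half-up((200 - v) / (120/119))."""
    v = np.asarray(values, dtype=float)
    return np.floor((BPM_HI - v) / BPM_PER_ROW + 0.5).astype(int)


def bpm_of_row(rows) -> np.ndarray:
    """Inverse of the row map (to row-center precision)."""
    return BPM_HI - np.asarray(rows, dtype=float) * BPM_PER_ROW


def render_image(values, source_id: str = "") -> FHRImage:
    """Rasterize a clipped trace of length 2400.

    Column t carries the pixel at row r(t); column t+1 additionally carries
    the span from r(t+1) toward r(t), excluding r(t) itself, so the curve
    is connected while each column's span still ends at the sample's own
    row (which makes the trace recoverable from the image).
    """
    v = np.asarray(values, dtype=float)
    if len(v) != N_COLS:
        raise ValueError(f"trace must have exactly {N_COLS} samples")
    if np.any(v < BPM_LO) or np.any(v > BPM_HI):
        raise ValueError("values must be clipped to [80, 200] bpm first")
    rows = row_of_bpm(v)
    img = np.zeros((N_ROWS, N_COLS), dtype=np.uint8)
    img[rows[0], 0] = 1
    for t in range(1, N_COLS):
        r_prev, r = rows[t - 1], rows[t]
        if r == r_prev:
            img[r, t] = 1
        elif r > r_prev:
            img[r_prev + 1 : r + 1, t] = 1
        else:
            img[r : r_prev, t] = 1
    return FHRImage(pixels=img, source_id=source_id)


def trace_from_image(image: FHRImage) -> np.ndarray:
    """Recover the clipped trace (to within half a pixel row in bpm).

    Each column's set pixels form an interval with the sample's row at the
    end farther from the previous column's sample row.
    """
    px = image.pixels
    rows = np.zeros(N_COLS, dtype=int)
    first = np.flatnonzero(px[:, 0])
    rows[0] = first[0]
    for t in range(1, N_COLS):
        on = np.flatnonzero(px[:, t])
        lo, hi = int(on[0]), int(on[-1])
        prev = rows[t - 1]
        rows[t] = lo if abs(lo - prev) >= abs(hi - prev) else hi
    return bpm_of_row(rows)


def shift_augment(
    image: FHRImage, cfg: AugmentConfig, rng: np.random.Generator
) -> FHRImage:
    """Random horizontal translation up to ±width_shift_fraction of the
    width; vacated columns replicate the nearest surviving column."""
    max_shift = int(np.floor(cfg.width_shift_fraction * N_COLS))
    d = int(rng.integers(-max_shift, max_shift + 1)) if max_shift > 0 else 0
    return FHRImage(pixels=shift_columns(image.pixels, d),
                    source_id=image.source_id)


def shift_columns(pixels: np.ndarray, d: int) -> np.ndarray:
    """Translate columns by d (positive = rightward), edge-replicating."""
    w = pixels.shape[1]
    if d == 0:
        return pixels.copy()
    out = np.empty_like(pixels)
    if d > 0:
        out[:, d:] = pixels[:, : w - d]
        out[:, :d] = pixels[:, [0]]
    else:
        out[:, : w + d] = pixels[:, -d:]
        out[:, w + d :] = pixels[:, [w - 1]]
    return out


def downsample(pixels: np.ndarray, row_block: int, col_block: int) -> np.ndarray:
    """Block max-pool a binary raster (used for reduced-scale training)."""
    h, w = pixels.shape
    if h % row_block or w % col_block:
        raise ValueError("block sizes must divide the image shape")
    return (
        pixels.reshape(h // row_block, row_block, w // col_block, col_block)
        .max(axis=(1, 3))
        .astype(np.float32)
    )


def save_png(image: FHRImage, path) -> None:
    """8-bit grayscale PNG: background 0, curve 255."""
    from PIL import Image

    Image.fromarray((image.pixels * 255).astype(np.uint8), mode="L").save(path)
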