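"""Grey level entropy matrix (GLEM) computation.

The GLEM of a nucleus is a joint probability matrix ``P(i, j | w)``: the
estimated probability that a nuclear pixel has grey level ``i`` while the
first-order entropy of the grey levels inside the ``w x w`` window centred on
it falls in entropy bin ``j``.  Homogeneous chromatin gives low local
entropies, heterogeneous chromatin high ones, so the matrix captures both the
grey-level distribution and the spatial organisation of chromatin in one
object.

Local first-order entropy at a pixel is ``-sum_i P(i) log2 P(i)`` where
``P(i)`` is the normalised frequency of grey level ``i`` among the *counted*
pixels of the window: windows are clipped at the image border, and only
mask-true (nuclear) pixels are counted, so background glass never enters the
statistics.  Entropies are measured in bits and binned into ``B`` equal-width
bins on ``[0, entropy_max]`` with ``entropy_max = log2 G`` by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import log2

import numpy as np

from .gallery import NucleusImage


@dataclass(frozen=True)
class GlemParams:
    """Parameters of the GLEM computation.

    window
        Odd side length ``w`` of the square entropy window (default 9 px).
    grey_levels
        Number of grey levels ``G`` after re-quantisation (default 64).
    entropy_bins
        Number of bins ``B`` on the entropy axis (default 64, keeping the
        matrix square).
    entropy_max
        Upper edge of the entropy axis in bits; ``log2(grey_levels)`` when
        omitted, the largest entropy a G-level window can attain.
    """

    window: int = 9
    grey_levels: int = 64
    entropy_bins: int = 64
    entropy_max: float | None = None

    def __post_init__(self) -> None:
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError(f"window must be odd and >= 3, got {self.window}")
        if self.grey_levels < 2 or self.entropy_bins < 2:
            raise ValueError("grey_levels and entropy_bins must be >= 2")
        if self.entropy_max is None:
            object.__setattr__(self, "entropy_max", log2(self.grey_levels))
        if self.entropy_max <= 0:
            raise ValueError("entropy_max must be positive")


@dataclass
class Glem:
    """A normalised G x B grey level entropy matrix for one nucleus."""

    P: np.ndarray
    params: GlemParams
    n_pixels_counted: int


def _xlog2x_table(max_count: int) -> np.ndarray:
    k = np.arange(max_count + 1, dtype=np.float64)
    out = np.zeros_like(k)
    out[1:] = k[1:] * np.log2(k[1:])
    return out


def _box_sum(a: np.ndarray, w: int) -> np.ndarray:
    """Sum of ``a`` over w x w windows clipped at the borders (zero outside).

    Works on the trailing two axes via a summed-area table.
    """
    h = w // 2
    pad = [(0, 0)] * (a.ndim - 2) + [(h + 1, h), (h + 1, h)]
    s = np.cumsum(np.cumsum(np.pad(a, pad), axis=-2, dtype=np.int64), axis=-1)
    return (
        s[..., w:, w:] - s[..., :-w, w:] - s[..., w:, :-w] + s[..., :-w, :-w]
    )


def _mask_entropies(
    pixels: np.ndarray, mask: np.ndarray, window: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Local entropy (bits) at every mask-true pixel.

    Returns the row indices, column indices and entropies of the mask-true
    pixels.  Only grey levels actually present inside the mask are expanded
    into indicator layers, which keeps the summed-area tables small.
    """
    rr, cc = np.nonzero(mask)
    vals = pixels[rr, cc]
    levels, inv = np.unique(vals, return_inverse=True)
    ind = np.zeros((levels.size,) + pixels.shape, dtype=np.int32)
    ind[inv, rr, cc] = 1
    counts = _box_sum(ind, window)[:, rr, cc]  # (n_levels, n_mask_pixels)
    counted = counts.sum(axis=0)
    lut = _xlog2x_table(window * window)
    # H = log2(n) - sum_i c_i log2 c_i / n   with n = counted pixels
    ent = np.log2(counted) - lut[counts].sum(axis=0) / counted
    return rr, cc, np.maximum(ent, 0.0)


def local_entropy(
    pixels: np.ndarray,
    mask: np.ndarray,
    center: tuple[int, int],
    params: GlemParams | None = None,
) -> float:
    """First-order grey-level entropy (bits) of the window centred at a pixel.

    The window is clipped at the image border and only mask-true pixels are
    counted; the centre pixel must itself be mask-true, so at least one pixel
    is always counted.
    """
    params = params or GlemParams()
    pixels = np.asarray(pixels)
    mask = np.asarray(mask).astype(bool)
    r, c = center
    if not mask[r, c]:
        raise ValueError(f"window centre {center} is not a nuclear (mask-true) pixel")
    h = params.window // 2
    win = pixels[max(0, r - h) : r + h + 1, max(0, c - h) : c + h + 1]
    wmask = mask[max(0, r - h) : r + h + 1, max(0, c - h) : c + h + 1]
    vals = win[wmask]
    counts = np.bincount(vals)
    p = counts[counts > 0] / vals.size
    return float(-(p * np.log2(p)).sum())


def local_entropy_map(
    pixels: np.ndarray, mask: np.ndarray, params: GlemParams | None = None
) -> np.ndarray:
    """Local entropy at every mask-true pixel; NaN outside the mask."""
    params = params or GlemParams()
    pixels = np.asarray(pixels)
    mask = np.asarray(mask).astype(bool)
    out = np.full(pixels.shape, np.nan)
    if mask.any():
        rr, cc, ent = _mask_entropies(pixels, mask, params.window)
        out[rr, cc] = ent
    return out


def entropy_bin(entropy: np.ndarray | float, params: GlemParams) -> np.ndarray:
    """Map entropies (bits) to bin indices ``floor(E * B / entropy_max)``,
    clamped to ``B - 1`` at the upper edge."""
    j = np.floor(
        np.asarray(entropy, dtype=np.float64) * params.entropy_bins / params.entropy_max
    ).astype(np.int64)
    return np.clip(j, 0, params.entropy_bins - 1)


def compute_glem(nucleus: NucleusImage, params: GlemParams | None = None) -> Glem:
    """Compute the grey level entropy matrix of a re-quantised nucleus.

    Every mask-true pixel contributes one count at (its grey level, the bin of
    its local windowed entropy); the matrix is normalised by the nuclear area
    so its entries sum to one.
    """
    params = params or GlemParams()
    pixels = np.asarray(nucleus.pixels)
    mask = np.asarray(nucleus.mask).astype(bool)
    if pixels.min() < 0 or pixels.max() >= params.grey_levels:
        raise ValueError(
            f"nucleus {nucleus.nucleus_id!r}: grey levels outside "
            f"[0, {params.grey_levels - 1}]; re-quantise first"
        )
    rr, cc, ent = _mask_entropies(pixels, mask, params.window)
    i = pixels[rr, cc].astype(np.int64)
    j = entropy_bin(ent, params)
    counts = np.bincount(
        i * params.entropy_bins + j,
        minlength=params.grey_levels * params.entropy_bins,
    ).reshape(params.grey_levels, params.entropy_bins)
    n = rr.size
    return Glem(P=counts / n, params=params, n_pixels_counted=n)
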