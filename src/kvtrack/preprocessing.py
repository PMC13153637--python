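"""Image conditioning before registration.

Three steps are applied to the 2D projection images:

1. A radial bandpass sharpening filter in the discrete Fourier domain,
   gain ``1 + g f`` from DC up to half the Nyquist bin and a mirrored ramp
   back down above it (gradient ``g = 0.02`` by default).
2. Fiducial-marker removal: the brightest 0.5% of pixels in the central
   half of the image, together with their 8-neighbourhoods, are replaced
   by the mean of the four pixels 10 px to the left/right/above/below.
3. Intensity equalisation of the DRR to the treatment image: the 25th and
   75th percentiles are measured in the four corner regions of a 5x5
   partition of each image, interpolated bilinearly over the frame, and
   the DRR interquartile range is rescaled pixelwise to the treatment one.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = [
    "bandpass_filter",
    "remove_fiducials",
    "equalize",
    "DegenerateContrastError",
]


class DegenerateContrastError(ValueError):
    """Raised when a corner region has zero interquartile range."""


def _radial_gain(n: int, g: float, literal_high_branch: bool) -> np.ndarray:
    """Radial frequency gain on the n x n DFT grid (bin-index units).

    ``f_max`` is the Nyquist bin ``n/2``.  The low branch is ``1 + g f``
    for ``f <= f_max/2``.  The high branch as commonly printed,
    ``1 + g (f - f_max)``, is discontinuous at ``f_max/2`` and dips below
    unity; the default continuous reading ``1 + g (f_max - f)`` joins the
    low branch and relaxes back to 1 at ``f_max``.
    """
    idx = np.fft.fftfreq(n) * n  # signed bin indices
    fx, fy = np.meshgrid(idx, idx, indexing="ij")
    f = np.hypot(fx, fy)
    f_max = n / 2.0
    if literal_high_branch:
        high = 1.0 + g * (f - f_max)
    else:
        high = 1.0 + g * (f_max - f)
    gain = np.where(f <= 0.5 * f_max, 1.0 + g * f, high)
    # corner bins lie beyond the Nyquist radius; hold them at unity
    gain[f > f_max] = np.maximum(gain[f > f_max], 1.0)
    return gain


def bandpass_filter(
    image: np.ndarray,
    g: float = 0.02,
    literal_high_branch: bool = False,
) -> np.ndarray:
    """Sharpen a square image with the radial frequency ramp.

    Gain is 1 at DC (the image mean is preserved exactly) and peaks at
    ``1 + g n/4`` at half the Nyquist radius (2.6 for n = 320, g = 0.02).
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2 or image.shape[0] != image.shape[1]:
        raise ValueError(f"bandpass_filter requires a square image, got {image.shape}")
    spec = np.fft.fft2(image)
    spec *= _radial_gain(image.shape[0], g, literal_high_branch)
    return np.fft.ifft2(spec).real


def central_region_slices(n: int) -> tuple[slice, slice]:
    """Central region spanning 0.25 to 0.75 of width and height."""
    lo, hi = n // 4, (3 * n) // 4
    return slice(lo, hi), slice(lo, hi)


def remove_fiducials(
    image: np.ndarray,
    top_fraction: float = 0.005,
    neighbour_offset: int = 10,
) -> np.ndarray:
    """Suppress bright fiducial markers in the central half of the image.

    The ``top_fraction`` brightest pixels of the central region (ties
    broken in raster order) and their 8-neighbourhoods are assigned the
    mean of the four pixels ``neighbour_offset`` px left, right, above and
    below the selected pixel (offsets clamped to the image bounds; means
    taken from the unmodified input).
    """
    image = np.asarray(image, dtype=float)
    n_rows, n_cols = image.shape
    if min(n_rows, n_cols) < 4 * neighbour_offset:
        raise ValueError(
            f"image of shape {image.shape} too small for neighbour_offset "
            f"{neighbour_offset}"
        )
    rs, cs = central_region_slices(n_rows)[0], central_region_slices(n_cols)[1]
    central = image[rs, cs]
    k = math.ceil(top_fraction * central.size)
    if k <= 0:
        return image.copy()

    flat = central.ravel()
    # stable sort descending by intensity; equal values keep raster order
    order = np.argsort(-flat, kind="stable")[:k]
    rows = order // central.shape[1] + rs.start
    cols = order % central.shape[1] + cs.start

    out = image.copy()
    for r, c in zip(rows.tolist(), cols.tolist()):
        up = image[max(r - neighbour_offset, 0), c]
        down = image[min(r + neighbour_offset, n_rows - 1), c]
        left = image[r, max(c - neighbour_offset, 0)]
        right = image[r, min(c + neighbour_offset, n_cols - 1)]
        m = 0.25 * (up + down + left + right)
        r0, r1 = max(r - 1, 0), min(r + 2, n_rows)
        c0, c1 = max(c - 1, 0), min(c + 2, n_cols)
        out[r0:r1, c0:c1] = m
    return out


_CORNERS = ((0, 0), (0, 4), (4, 0), (4, 4))


def _partition_bounds(n: int, k: int = 5) -> np.ndarray:
    """Integer bounds of a k-way partition of [0, n)."""
    return np.linspace(0, n, k + 1).round().astype(int)


def _corner_percentiles(image: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """25th/75th percentiles in the four corner regions of the 5x5 grid.

    Returns (p25 2x2, p75 2x2, anchor_rows, anchor_cols) where the anchors
    are the centres of the corner regions.
    """
    rb = _partition_bounds(image.shape[0])
    cb = _partition_bounds(image.shape[1])
    p25 = np.empty((2, 2))
    p75 = np.empty((2, 2))
    anchor_r = np.empty(2)
    anchor_c = np.empty(2)
    for a, gi in enumerate((0, 4)):
        for b, gj in enumerate((0, 4)):
            block = image[rb[gi] : rb[gi + 1], cb[gj] : cb[gj + 1]]
            p25[a, b] = np.percentile(block, 25)
            p75[a, b] = np.percentile(block, 75)
    anchor_r[:] = [(rb[0] + rb[1] - 1) / 2.0, (rb[4] + rb[5] - 1) / 2.0]
    anchor_c[:] = [(cb[0] + cb[1] - 1) / 2.0, (cb[4] + cb[5] - 1) / 2.0]
    return p25, p75, anchor_r, anchor_c


def _bilinear_surface(values: np.ndarray, anchor_r: np.ndarray, anchor_c: np.ndarray, shape) -> np.ndarray:
    """Bilinear interpolation of a 2x2 anchor grid over the whole image.

    Outside the anchor rectangle the surface is extended by clamping
    (constant continuation), so the correction stays bounded at the frame
    edges.
    """
    r = np.arange(shape[0], dtype=float)
    c = np.arange(shape[1], dtype=float)
    wr = np.clip((r - anchor_r[0]) / (anchor_r[1] - anchor_r[0]), 0.0, 1.0)
    wc = np.clip((c - anchor_c[0]) / (anchor_c[1] - anchor_c[0]), 0.0, 1.0)
    top = values[0, 0] + (values[0, 1] - values[0, 0]) * wc[None, :]
    bot = values[1, 0] + (values[1, 1] - values[1, 0]) * wc[None, :]
    return top + (bot - top) * wr[:, None]


def equalize(drr: np.ndarray, treatment: np.ndarray) -> np.ndarray:
    """Match the DRR's local interquartile intensity range to the treatment image.

    Percentile surfaces d_min/d_max (DRR 25th/75th) and t_min/t_max
    (treatment) are interpolated from the four corner regions of a 5x5
    partition; each DRR pixel is mapped to
    ``(D - d_min) * s + t_min`` with ``s = (t_max - t_min)/(d_max - d_min)``.
    """
    drr = np.asarray(drr, dtype=float)
    treatment = np.asarray(treatment, dtype=float)
    if drr.shape != treatment.shape:
        raise ValueError(f"shape mismatch: {drr.shape} vs {treatment.shape}")
    d25, d75, ar, ac = _corner_percentiles(drr)
    t25, t75, _, _ = _corner_percentiles(treatment)
    iqr = d75 - d25
    if np.any(iqr <= 0):
        a, b = np.argwhere(iqr <= 0)[0]
        corner = ("top-left", "top-right", "bottom-left", "bottom-right")[a * 2 + b]
        raise DegenerateContrastError(
            f"DRR interquartile range is zero in the {corner} corner region"
        )
    d_min = _bilinear_surface(d25, ar, ac, drr.shape)
    d_max = _bilinear_surface(d75, ar, ac, drr.shape)
    t_min = _bilinear_surface(t25, ar, ac, drr.shape)
    t_max = _bilinear_surface(t75, ar, ac, drr.shape)
    s = (t_max - t_min) / (d_max - d_min)
    return (drr - d_min) * s + t_min
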