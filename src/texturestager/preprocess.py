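"""ROI intensity normalization and gray-level quantization.

Pixel intensities inside the ROI are normalized to the window
``[mu - 3*sigma, mu + 3*sigma]`` — ``mu`` and ``sigma`` being the mean and
(population) standard deviation of the intensities inside the mask — and
linearly quantized to ``n_levels`` integer gray levels.  Because the
window is defined from the ROI's own statistics, the quantized output
(and hence every downstream texture feature) is invariant to positive
affine transforms of the raw intensities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from texturestager.image_io import ROISample

#: Value carried by outside-mask pixels in the quantized level array.
OUTSIDE = -1


@dataclass
class QuantizedROI:
    """Masked pixel set after mu+/-3sigma clipping and integer quantization.

    ``levels`` holds integers in ``[0, n_levels - 1]`` inside the mask and
    the sentinel :data:`OUTSIDE` elsewhere; outside-mask pixels are
    excluded from every downstream computation.
    """

    levels: np.ndarray = field(repr=False)
    mask: np.ndarray = field(repr=False)
    n_levels: int
    mu: float
    sigma: float

    @property
    def inside_levels(self) -> np.ndarray:
        """1D array of the quantized levels inside the mask."""
        return self.levels[self.mask]

    @classmethod
    def from_levels(
        cls, levels, mask=None, n_levels: int | None = None
    ) -> "QuantizedROI":
        """Wrap an already-quantized integer level array (no normalization).

        Convenient for constructing small worked examples; ``mu`` and
        ``sigma`` are set to NaN since no raw intensities exist.
        """
        levels = np.asarray(levels, dtype=np.int32)
        if mask is None:
            mask = levels != OUTSIDE
        mask = np.asarray(mask).astype(bool)
        inside = levels[mask]
        if inside.size == 0:
            raise ValueError("empty ROI")
        if inside.min() < 0:
            raise ValueError("inside-mask levels must be >= 0")
        if n_levels is None:
            n_levels = int(inside.max()) + 1
        out = np.full(levels.shape, OUTSIDE, dtype=np.int32)
        out[mask] = inside
        return cls(levels=out, mask=mask, n_levels=n_levels, mu=np.nan, sigma=np.nan)


def quantize_values(
    x: np.ndarray, mu: float, sigma: float, n_levels: int
) -> np.ndarray:
    """The bare intensity-to-level map for a given window center and width.

    ``q = floor((x - (mu - 3 sigma)) / (6 sigma) * n_levels)`` clipped to
    ``[0, n_levels - 1]`` (half-open bins, closed top bin); ``sigma = 0``
    maps everything to ``n_levels // 2``.
    """
    x = np.asarray(x, dtype=np.float64)
    if sigma == 0.0:
        return np.full(x.shape, n_levels // 2, dtype=np.int32)
    lo = mu - 3.0 * sigma
    q = np.floor((x - lo) / (6.0 * sigma) * n_levels)
    return np.clip(q, 0, n_levels - 1).astype(np.int32)


def quantize(image: np.ndarray, mask: np.ndarray, n_levels: int = 256) -> QuantizedROI:
    """Clip a masked image to mu +/- 3 sigma and quantize to ``n_levels``.

    The map is ``q = floor((x - (mu - 3 sigma)) / (6 sigma) * n_levels)``
    with half-open bins and a closed top bin (values at ``mu + 3 sigma``
    map to ``n_levels - 1``); values beyond the window saturate.  A
    constant ROI (sigma = 0) maps every inside pixel to ``n_levels // 2``.

    ``sigma`` uses the population denominator ``n``.
    """
    image = np.asarray(image, dtype=np.float64)
    mask = np.asarray(mask).astype(bool)
    if image.shape != mask.shape:
        raise ValueError(f"image/mask shape mismatch: {image.shape} vs {mask.shape}")
    if not mask.any():
        raise ValueError("empty ROI: mask selects no pixels")
    if n_levels < 2:
        raise ValueError("n_levels must be >= 2")
    inside = image[mask]
    if not np.all(np.isfinite(inside)):
        raise ValueError("non-finite intensities inside the ROI")

    mu = float(inside.mean())
    sigma = float(inside.std())  # population denominator

    levels = np.full(image.shape, OUTSIDE, dtype=np.int32)
    levels[mask] = quantize_values(inside, mu, sigma, n_levels)
    return QuantizedROI(levels=levels, mask=mask, n_levels=n_levels, mu=mu, sigma=sigma)


def normalize_quantize(sample: ROISample, n_levels: int = 256) -> QuantizedROI:
    """Quantize one :class:`~texturestager.image_io.ROISample`.

    ``n_levels`` defaults to 256 gray levels (8 bits/pixel); smaller
    values are often preferable on small ROIs, where a 256-level
    co-occurrence matrix is extremely sparse.
    """
    return quantize(sample.image, sample.mask, n_levels=n_levels)
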