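"""Spatial-frequency / orientation band-energy features of grayscale images.

An image is summarized by 384 nonnegative values: the 2-D Fourier magnitude
spectrum is partitioned into 24 spatial-frequency bands (log-spaced from
1 cycle/image to the corner of the spectrum) crossed with 16 orientation
bands of 11.25 degrees each on [0, 180).  Phase is discarded, so the
description is insensitive to where in the image the energy sits.

The DC coefficient (mean luminance) is excluded from every bin.  Orientation
is folded modulo 180 degrees, so a conjugate-symmetric pair of coefficients
always lands in the same bin and the 384 values sum exactly to the total
non-DC magnitude of the spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

N_FREQ_BANDS = 24
N_ORIENT_BANDS = 16
N_FEATURES = N_FREQ_BANDS * N_ORIENT_BANDS

_ORIENT_WIDTH_DEG = 180.0 / N_ORIENT_BANDS  # 11.25


@dataclass(frozen=True)
class ImageFeatureVector:
    """384 band energies plus the binning metadata that produced them."""

    values: np.ndarray  # shape (384,), order: freq_band * 16 + orient_band
    freq_edges: np.ndarray  # shape (25,), cycles/image
    image_id: str | None = None
    window: str = "none"

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (N_FEATURES,):
            raise ValueError(f"expected {N_FEATURES} values, got {v.shape}")
        if not np.all(np.isfinite(v)) or np.any(v < 0):
            raise ValueError("band energies must be finite and nonnegative")
        object.__setattr__(self, "values", v)

    def as_matrix(self) -> np.ndarray:
        """Return the energies as a (24, 16) frequency x orientation array."""
        return self.values.reshape(N_FREQ_BANDS, N_ORIENT_BANDS)

    @staticmethod
    def bin_index(position: int) -> tuple[int, int]:
        """Map a flat feature position 0..383 to (frequency_band, orientation_band)."""
        if not 0 <= position < N_FEATURES:
            raise ValueError("position out of range")
        return divmod(position, N_ORIENT_BANDS)


def _check_image(image) -> np.ndarray:
    img = np.asarray(image)
    if img.ndim != 2:
        raise ValueError(f"expected a 2-D grayscale image, got ndim={img.ndim}")
    if np.iscomplexobj(img):
        raise ValueError("expected a real-valued image")
    if min(img.shape) < 8:
        raise ValueError("image must be at least 8 pixels along each axis")
    return img.astype(float)


def frequency_band_edges(height: int, width: int,
                         n_bands: int = N_FREQ_BANDS) -> np.ndarray:
    """Logarithmically spaced radial-frequency band edges in cycles/image.

    The lowest edge is 1 cycle/image (the lowest non-DC frequency) and the
    highest is the spectrum corner sqrt((W/2)^2 + (H/2)^2) so every non-DC
    coefficient falls inside some band.
    """
    r_max = float(np.hypot(width / 2.0, height / 2.0))
    return np.geomspace(1.0, r_max, n_bands + 1)


def bin_masks(height: int, width: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Assign every Fourier coefficient of an HxW image to a feature bin.

    Returns ``(freq_band, orient_band, freq_edges)`` where the two band
    arrays have shape (H, W) and hold indices into the 24 frequency and 16
    orientation bands; the DC coefficient is marked -1 in both.  The bins
    partition the non-DC coefficients: each belongs to exactly one
    (frequency, orientation) pair.
    """
    if height < 8 or width < 8:
        raise ValueError("dimensions must be >= 8")
    ky = np.fft.fftfreq(height, d=1.0 / height)  # integer cycles/image
    kx = np.fft.fftfreq(width, d=1.0 / width)
    KX, KY = np.meshgrid(kx, ky)
    radius = np.hypot(KX, KY)

    edges = frequency_band_edges(height, width)
    freq_band = np.searchsorted(edges, radius, side="right") - 1
    freq_band = np.clip(freq_band, 0, N_FREQ_BANDS - 1)

    theta = np.degrees(np.arctan2(KY, KX)) % 180.0
    # first band centered on 0 degrees: shift by half a band width
    orient_band = np.floor(((theta + _ORIENT_WIDTH_DEG / 2.0) % 180.0)
                           / _ORIENT_WIDTH_DEG).astype(int)

    dc = radius == 0
    freq_band = freq_band.astype(int)
    freq_band[dc] = -1
    orient_band[dc] = -1
    return freq_band, orient_band, edges


def fourier_features(image, image_id: str | None = None) -> ImageFeatureVector:
    """Compute the 384-value band-energy description of a grayscale image.

    The raw 2-D FFT magnitudes are summed within each frequency x orientation
    bin; no windowing or per-image normalization is applied (recorded in the
    output metadata).
    """
    img = _check_image(image)
    h, w = img.shape
    mag = np.abs(np.fft.fft2(img))
    freq_band, orient_band, edges = bin_masks(h, w)
    flat = (freq_band * N_ORIENT_BANDS + orient_band).ravel()
    keep = flat >= 0  # drop DC
    values = np.bincount(flat[keep], weights=mag.ravel()[keep],
                         minlength=N_FEATURES)
    return ImageFeatureVector(values=values, freq_edges=edges,
                              image_id=image_id)


def features_table(images: dict[str, np.ndarray]):
    """Compute features for a mapping image_id -> image; returns a DataFrame
    with columns image_id, f000..f383."""
    import pandas as pd

    rows = []
    for image_id, img in images.items():
        fv = fourier_features(img, image_id=image_id)
        rows.append([image_id, *fv.values])
    cols = ["image_id"] + [f"f{i:03d}" for i in range(N_FEATURES)]
    return pd.DataFrame(rows, columns=cols)
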