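"""Image reconstruction from ring-array channel data.

The primary algorithm is universal filtered back-projection (UBP): each
trace is filtered into the back-projection term

    b(t) = 2 p(t) - 2 t dp/dt

and smeared over circular shells ``t = |r - r0| / v_s`` around its
detector with uniform per-element aperture weights.  A plain
delay-and-sum (DAS) beamformer is provided as an independent cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from .sigproc import envelope as _envelope

__all__ = [
    "ImageGrid",
    "ReconImage",
    "ubp_reconstruct",
    "das_reconstruct",
    "normalize",
]


@dataclass
class ImageGrid:
    """Reconstruction grid, concentric with the ring by default."""

    nx: int
    ny: int
    pixel_size: float            # metres
    center: tuple = (0.0, 0.0)   # metres, offset of grid centre from ring centre

    def __post_init__(self):
        if self.nx < 1 or self.ny < 1 or self.pixel_size <= 0:
            raise ValueError("grid dimensions and pixel size must be positive")

    def pixel_centers(self):
        x = ((np.arange(self.nx) + 0.5) * self.pixel_size
             - self.nx * self.pixel_size / 2 + self.center[0])
        y = ((np.arange(self.ny) + 0.5) * self.pixel_size
             - self.ny * self.pixel_size / 2 + self.center[1])
        return x, y

    def max_radius(self):
        """Largest distance from the ring centre to any pixel centre."""
        x, y = self.pixel_centers()
        X, Y = np.meshgrid(x, y, indexing="ij")
        return float(np.hypot(X, Y).max())

    def index_of(self, point):
        """Nearest pixel index ``(i, j)`` for a physical point (metres)."""
        x, y = self.pixel_centers()
        return (int(np.argmin(np.abs(x - point[0]))),
                int(np.argmin(np.abs(y - point[1]))))


@dataclass
class ReconImage:
    """Reconstructed map with its grid and provenance."""

    pixels: np.ndarray
    pixel_size: float
    origin: tuple = (0.0, 0.0)
    normalization: str = "none"
    provenance: dict = dc_field(default_factory=dict)

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=float)
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("image contains non-finite pixels")

    def peak_position(self):
        """Physical coordinates (metres) of the maximum pixel."""
        i, j = np.unravel_index(np.argmax(self.pixels), self.pixels.shape)
        nx, ny = self.pixels.shape
        x = (i + 0.5) * self.pixel_size - nx * self.pixel_size / 2 + self.origin[0]
        y = (j + 0.5) * self.pixel_size - ny * self.pixel_size / 2 + self.origin[1]
        return np.array([x, y])


def _check_inputs(data, v_s, grid):
    if v_s <= 0:
        raise ValueError("sound speed must be positive")
    if grid.max_radius() >= data.geometry.ring_radius:
        raise ValueError("reconstruction grid extends outside the detector ring")


def _backproject(term, data, v_s, grid):
    """Sum per-element filtered terms over circular shells onto the grid."""
    x, y = grid.pixel_centers()
    X, Y = np.meshgrid(x, y, indexing="ij")
    img = np.zeros(X.shape)
    t = data.times
    for k, pos in enumerate(data.geometry.positions):
        tof = np.hypot(X - pos[0], Y - pos[1]) / v_s
        img += np.interp(tof.ravel(), t, term[k], left=0.0,
                         right=0.0).reshape(X.shape)
    return img / data.n_elements


def ubp_reconstruct(data, v_s, grid, use_envelope=False):
    """Universal filtered back-projection onto an image grid.

    Parameters
    ----------
    data : ChannelData
    v_s : float
        Sound speed used for the circular back-projection shells, m/s.
    grid : ImageGrid
        Must lie inside the detector ring.
    use_envelope : bool
        If True, back-project the Hilbert envelope of the filtered term
        ``b(t)`` (display mode yielding non-negative images); default
        back-projects ``b(t)`` directly.
    """
    _check_inputs(data, v_s, grid)
    dt = 1.0 / data.sampling_rate
    t = data.times
    dp = np.gradient(data.traces, dt, axis=1)
    b = 2 * data.traces - 2 * t[None, :] * dp
    if use_envelope:
        b = _envelope(b)
    img = _backproject(b, data, v_s, grid)
    return ReconImage(pixels=img, pixel_size=grid.pixel_size,
                      origin=grid.center,
                      provenance={"algorithm": "ubp", "v_s": v_s,
                                  "envelope": bool(use_envelope),
                                  **{k: data.meta[k] for k in ("form", "snr_db")
                                     if k in data.meta}})


def das_reconstruct(data, v_s, grid, use_envelope=True):
    """Delay-and-sum beamforming (cross-check for UBP).

    Delays each (optionally envelope-detected) trace by the pixel-element
    flight time and sums over elements, with no ramp filtering.
    """
    _check_inputs(data, v_s, grid)
    term = _envelope(data.traces) if use_envelope else data.traces
    img = _backproject(term, data, v_s, grid)
    return ReconImage(pixels=img, pixel_size=grid.pixel_size,
                      origin=grid.center,
                      provenance={"algorithm": "das", "v_s": v_s,
                                  "envelope": bool(use_envelope)})


def normalize(image, mode="max1"):
    """Normalise an image; ``max1`` divides by the global maximum.

    An all-zero image is returned unchanged (no 0/0).
    """
    if mode not in ("none", "max1"):
        raise ValueError("mode must be 'none' or 'max1'")
    pixels = image.pixels.copy()
    if mode == "max1":
        peak = pixels.max()
        if peak != 0:
            pixels = pixels / peak
    return ReconImage(pixels=pixels, pixel_size=image.pixel_size,
                      origin=image.origin, normalization=mode,
                      provenance=dict(image.provenance))
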