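"""Synthetic source maps and reference waveforms.

Generators for the standard test objects: anti-aliased disc sources,
Gaussian blobs, paired-electrode deposition patterns (through the field
solver), and ideal N-shaped pressure transients for trace-level tests.
"""

from __future__ import annotations

import numpy as np

from .field import ElectrodePair, Medium, PulseWaveform, simulate_field

__all__ = [
    "disc_map",
    "gaussian_map",
    "point_map",
    "nwave",
    "electrode_pair_p0",
]


def _grid_coords(grid_shape, pixel_size):
    nx, ny = grid_shape
    x = (np.arange(nx) + 0.5) * pixel_size - nx * pixel_size / 2
    y = (np.arange(ny) + 0.5) * pixel_size - ny * pixel_size / 2
    return np.meshgrid(x, y, indexing="ij")


def disc_map(grid_shape, pixel_size, center, radius, amplitude=1.0,
             supersample=4):
    """Uniform disc with sub-pixel edge coverage (anti-aliased rasterisation).

    Edge pixels carry the fraction of their area inside the disc, estimated
    on a ``supersample x supersample`` sub-grid, which suppresses staircase
    artefacts in forward-model comparisons.
    """
    X, Y = _grid_coords(grid_shape, pixel_size)
    d2 = (X - center[0]) ** 2 + (Y - center[1]) ** 2
    img = (d2 <= radius ** 2).astype(float)
    if supersample > 1:
        edge = np.abs(np.sqrt(d2) - radius) <= pixel_size
        if edge.any():
            off = (np.arange(supersample) + 0.5) / supersample - 0.5
            ox, oy = np.meshgrid(off * pixel_size, off * pixel_size,
                                 indexing="ij")
            xe, ye = X[edge], Y[edge]
            sub = ((xe[:, None] + ox.ravel()[None, :] - center[0]) ** 2
                   + (ye[:, None] + oy.ravel()[None, :] - center[1]) ** 2
                   <= radius ** 2)
            img[edge] = sub.mean(axis=1)
    return amplitude * img


def gaussian_map(grid_shape, pixel_size, center, fwhm, amplitude=1.0):
    """Isotropic Gaussian blob with the given FWHM (metres)."""
    X, Y = _grid_coords(grid_shape, pixel_size)
    s = fwhm / (2 * np.sqrt(2 * np.log(2)))
    return amplitude * np.exp(-((X - center[0]) ** 2 + (Y - center[1]) ** 2)
                              / (2 * s ** 2))


def point_map(grid_shape, pixel_size, center, amplitude=1.0):
    """Single-pixel source at the pixel nearest ``center``."""
    nx, ny = grid_shape
    i = int(round(center[0] / pixel_size + nx / 2 - 0.5))
    j = int(round(center[1] / pixel_size + ny / 2 - 0.5))
    img = np.zeros(grid_shape)
    img[i, j] = amplitude
    return img


def nwave(t, center, half_duration, amplitude=1.0):
    """Ideal bipolar N-wave: linear ramp through zero at ``center``.

    ``p(t) = -A (t - center)/half_duration`` inside the support
    ``|t - center| < half_duration``, zero outside — the far-field pulse of
    a uniform compact thermoacoustic source.  A half-duration of ~250 ns
    puts the spectral peak in the low-MHz band of the receiving transducer.
    """
    t = np.asarray(t, dtype=float)
    u = (t - center) / half_duration
    return np.where(np.abs(u) < 1, -amplitude * u, 0.0)


def electrode_pair_p0(grid_shape=(200, 200), pixel_size=0.25e-3, gap=4e-3,
                      radius=0.5e-3, mode="1p1g", voltage=1000.0, sigma=0.5,
                      pulse=None, tol=1e-8):
    """Initial-pressure map of a two-electrode deposition pattern.

    Solves the electrode-pair field in a homogeneous muscle-like medium
    (conductivity ``sigma`` S/m) and converts it to p0.  Electrodes are
    placed symmetrically about the centre along x, edge-to-edge ``gap``
    apart.  Returns ``(p0, medium, solution)``.
    """
    medium = Medium.homogeneous(grid_shape, pixel_size, sigma=sigma)
    half = gap / 2 + radius
    electrodes = ElectrodePair(centers=[[-half, 0.0], [half, 0.0]],
                               radius=radius, mode=mode, voltage=voltage)
    if pulse is None:
        pulse = PulseWaveform(amplitude=voltage)
    sol = simulate_field(medium, electrodes, pulse, tol=tol)
    return sol.p0, medium, sol
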