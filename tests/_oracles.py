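"""Independent closed-form oracles used by the test suite.

These are deliberately written from textbook formulas, not from the
package's own discretisations, so that agreement is evidence and not
tautology.
"""

import numpy as np
import scipy.signal as sps

# Effective electrostatic radius of a single fixed node of the 5-point
# discrete Laplacian: a = h * exp(-gamma - (3/2) ln 2), from the constant
# term of the 2-D lattice Green's function G(r) ~ (ln(r/h) + gamma +
# (3/2) ln 2) / (2 pi).
LATTICE_POINT_RADIUS = float(np.exp(-np.euler_gamma) / (2 * np.sqrt(2)))


def two_line_charge_potential(X, Y, centers, d, a, V):
    """Exact free-space potential of two parallel wires at +-V/2.

    Wires of electrostatic radius ``a``, centre separation ``d``; the
    image line charges sit at ``+-b`` with ``b = sqrt((d/2)^2 - a^2)`` and
    the potential is ``K ln(r-/r+)`` with ``K = V / (2 acosh(d/(2a)))``.
    ``centers`` is the midpoint between the wires; the wires lie along x.
    """
    b = np.sqrt((d / 2) ** 2 - a ** 2)
    K = V / (2 * np.arccosh(d / (2 * a)))
    cx, cy = centers
    r_neg = np.hypot(X - (cx + b), Y - cy)   # distance to negative charge
    r_pos = np.hypot(X - (cx - b), Y - cy)   # distance to positive charge
    return K * np.log(r_neg / r_pos)


def uniform_disc_trace(t, d, a, v_s, p0=1.0):
    """Retarded-potential pressure of a uniform disc source (chord-arc form).

    For an in-plane detector at distance ``d`` from the centre of a
    uniform disc of radius ``a``, the shell integral reduces to the arc
    length ``L(r) = 2 r arccos((d^2 + r^2 - a^2)/(2 d r))`` of the circle
    ``r = v_s t`` inside the disc:

        p(t) = p0 * L(v_s t) / (4 pi v_s^2 t)
    """
    r = v_s * np.asarray(t, dtype=float)
    out = np.zeros_like(r)
    m = (r > d - a) & (r < d + a) & (r > 0)
    cosal = (d ** 2 + r[m] ** 2 - a ** 2) / (2 * d * r[m])
    alpha = np.arccos(np.clip(cosal, -1.0, 1.0))
    out[m] = p0 * 2 * r[m] * alpha / (4 * np.pi * v_s ** 2 * t[m])
    return out


def uniform_disc_derivative_trace(t0, n_samples, fs, d, a, v_s, p0=1.0,
                                  oversample=16):
    """Band-limited N-wave reference: derivative of the disc trace.

    The exact time derivative has integrable inverse-square-root
    singularities at the disc shoulders and is not square-integrable, so
    the reference is built by sampling the continuous chord-arc waveform
    at ``oversample * fs``, decimating with a zero-phase FIR filter, and
    applying the same central-difference derivative stencil used on
    measured records.
    """
    t_hi = t0 + np.arange(n_samples * oversample) / (fs * oversample)
    p_hi = uniform_disc_trace(t_hi, d, a, v_s, p0)
    p = sps.decimate(p_hi, oversample, ftype="fir",
                     zero_phase=True)[:n_samples]
    return np.gradient(p, 1.0 / fs)


def smooth_nwave(t, center, scale, amplitude=1.0):
    """Derivative-of-Gaussian bipolar pulse (band-limited N-wave)."""
    u = (np.asarray(t, dtype=float) - center) / scale
    return -amplitude * u * np.exp(-(u ** 2) / 2)
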