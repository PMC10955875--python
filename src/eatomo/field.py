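"""Quasi-static electric field, Joule energy deposition, and initial pressure.

A pair of electrodes held at fixed potentials drives a current through a
2-D conductive medium.  In the quasi-static limit the potential obeys the
continuity equation ``div(sigma grad phi) = 0`` with Dirichlet values on the
electrode footprints and on the grounded outer boundary.  The local Joule
heat deposited by one pulse is ``H = sigma |E|^2 tau_eff`` and converts to an
initial acoustic pressure through the Grueneisen-like factor
``p0 = beta / (kappa rho C_v) * H``.

All maps are ``(nx, ny)`` arrays in SI units on a uniform grid; pixel ``i``
is centred at ``(i + 0.5) * pixel_size`` relative to the lower-left corner,
with the coordinate origin at the domain centre.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

__all__ = [
    "Medium",
    "ElectrodePair",
    "PulseWaveform",
    "FieldSolution",
    "ConvergenceError",
    "solve_potential",
    "nominal_field_strength",
    "energy_deposition",
    "initial_pressure",
    "simulate_field",
]


class ConvergenceError(RuntimeError):
    """Raised when the iterative Laplace solve does not reach tolerance."""


def _as_map(value, grid_shape):
    arr = np.broadcast_to(np.asarray(value, dtype=float), grid_shape).copy()
    return arr


@dataclass
class Medium:
    """Gridded material maps of a 2-D imaging slice.

    Parameters
    ----------
    grid_shape : tuple of int
        ``(nx, ny)`` pixels.
    pixel_size : float
        Pixel edge length in metres.
    sigma : array or float
        Electrical conductivity, S/m.
    beta : array or float
        Volumetric thermal expansion coefficient, 1/K.
    kappa : array or float
        Isothermal compressibility, 1/Pa.
    rho : array or float
        Mass density, kg/m^3.
    c_v : array or float
        Specific heat capacity, J/(kg K).
    v_s : array or float
        Speed of sound, m/s.
    """

    grid_shape: tuple
    pixel_size: float
    sigma: np.ndarray
    beta: np.ndarray = 2.07e-4
    kappa: np.ndarray = 4.48e-10
    rho: np.ndarray = 1000.0
    c_v: np.ndarray = 4181.0
    v_s: np.ndarray = 1497.0

    def __post_init__(self):
        self.grid_shape = tuple(int(n) for n in self.grid_shape)
        if len(self.grid_shape) != 2:
            raise ValueError("grid_shape must be (nx, ny)")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        for name in ("sigma", "beta", "kappa", "rho", "c_v", "v_s"):
            setattr(self, name, _as_map(getattr(self, name), self.grid_shape))
        if np.any(self.sigma < 0):
            raise ValueError("conductivity must be non-negative")
        for name in ("rho", "c_v", "v_s"):
            if np.any(getattr(self, name) <= 0):
                raise ValueError(f"{name} must be positive everywhere")

    @property
    def extent(self):
        """Physical size ``(Lx, Ly)`` in metres."""
        return (self.grid_shape[0] * self.pixel_size,
                self.grid_shape[1] * self.pixel_size)

    def pixel_centers(self):
        """Coordinate arrays ``(x, y)`` of pixel centres, origin at centre."""
        nx, ny = self.grid_shape
        x = (np.arange(nx) + 0.5) * self.pixel_size - nx * self.pixel_size / 2
        y = (np.arange(ny) + 0.5) * self.pixel_size - ny * self.pixel_size / 2
        return x, y

    @classmethod
    def homogeneous(cls, grid_shape, pixel_size, sigma=0.5, **kwargs):
        """Uniform medium; default conductivity is muscle-like (0.5 S/m)."""
        return cls(grid_shape, pixel_size, sigma=sigma, **kwargs)

    def grueneisen(self):
        """Dimensionless conversion factor beta / (kappa rho c_v)."""
        return self.beta / (self.kappa * self.rho * self.c_v)


@dataclass
class ElectrodePair:
    """Two disc electrodes at fixed potential in the imaging plane.

    ``mode`` selects the polarity wiring: ``"1p1g"`` drives the first
    electrode at ``voltage`` and grounds the second; ``"2p"`` drives both at
    ``voltage`` (the grounded domain boundary provides the return path).
    ``gap`` is the edge-to-edge distance between the discs.
    """

    centers: np.ndarray          # (2, 2) metres, origin at domain centre
    radius: float                # exposed-tip footprint radius, metres
    mode: str = "1p1g"
    voltage: float = 1000.0

    def __post_init__(self):
        self.centers = np.asarray(self.centers, dtype=float).reshape(2, 2)
        if self.radius <= 0:
            raise ValueError("electrode radius must be positive")
        if self.mode not in ("1p1g", "2p"):
            raise ValueError("mode must be '1p1g' or '2p'")
        if self.gap <= 0:
            raise ValueError("electrodes overlap: gap must be positive")

    @property
    def gap(self):
        """Edge-to-edge spacing between the two discs, metres."""
        d = float(np.linalg.norm(self.centers[0] - self.centers[1]))
        return d - 2 * self.radius

    @property
    def potentials(self):
        if self.mode == "1p1g":
            return (self.voltage, 0.0)
        return (self.voltage, self.voltage)


@dataclass
class PulseWaveform:
    """Near-square high-voltage pulse: amplitude, FWHM width, rise time.

    The effective width ``tau_eff`` used for per-pulse energy deposition is
    the integral of the normalised squared waveform; for a trapezoidal pulse
    with linear edges of duration ``rise_time`` and FWHM ``width`` this is
    ``width - rise_time / 3`` (about 95 ns for the default 100 ns / 15 ns
    pulse).
    """

    amplitude: float = 1000.0    # volts
    width: float = 100e-9        # seconds, FWHM
    rise_time: float = 15e-9     # seconds
    rep_rate: float = 1000.0     # Hz

    def __post_init__(self):
        if self.width <= 0:
            raise ValueError("pulse width must be positive")
        if not 0 <= self.rise_time < self.width:
            raise ValueError("rise_time must lie in [0, width)")
        if self.rep_rate < 0:
            raise ValueError("rep_rate must be non-negative")

    @property
    def tau_eff(self):
        """Integral of the normalised squared trapezoidal waveform, seconds."""
        return self.width - self.rise_time / 3.0

    def energy_per_pulse(self, load_ohms=50.0):
        """Delivered energy V^2 tau_eff / R for a resistive load, joules."""
        if load_ohms <= 0:
            raise ValueError("load resistance must be positive")
        return self.amplitude ** 2 * self.tau_eff / load_ohms


@dataclass
class FieldSolution:
    """Solved potential with derived field, dose, and initial pressure."""

    potential: np.ndarray        # volts, (nx, ny)
    e_field: np.ndarray          # V/m, (2, nx, ny): (Ex, Ey)
    dose: np.ndarray = None      # J/m^3
    p0: np.ndarray = None        # Pa
    residual: float = np.nan
    meta: dict = dc_field(default_factory=dict)

    @property
    def e_magnitude(self):
        return np.hypot(self.e_field[0], self.e_field[1])


def _electrode_masks(medium, electrodes):
    x, y = medium.pixel_centers()
    X, Y = np.meshgrid(x, y, indexing="ij")
    masks = []
    for c in electrodes.centers:
        masks.append((X - c[0]) ** 2 + (Y - c[1]) ** 2 <= electrodes.radius ** 2)
    if masks[0].any() and masks[1].any() and np.any(masks[0] & masks[1]):
        raise ValueError("electrode discs overlap on the grid")
    nx, ny = medium.grid_shape
    half = (nx * medium.pixel_size / 2, ny * medium.pixel_size / 2)
    for c in electrodes.centers:
        if (abs(c[0]) + electrodes.radius >= half[0]
                or abs(c[1]) + electrodes.radius >= half[1]):
            raise ValueError("electrode disc extends outside the domain")
    return masks


def solve_potential(medium, electrodes, tol=1e-8, maxiter=None,
                    return_solution=False):
    """Solve ``div(sigma grad phi) = 0`` for an electrode pair.

    Five-point finite differences with harmonic-mean face conductivities;
    Dirichlet conditions on the rasterised electrode discs (applied
    potentials) and on the outer boundary ring (phi = 0, a grounded bath).
    The reduced symmetric positive-definite system is solved by conjugate
    gradients with a Jacobi preconditioner.

    Parameters
    ----------
    medium : Medium
    electrodes : ElectrodePair
    tol : float
        Relative residual tolerance of the CG solve.
    maxiter : int, optional
        Iteration cap; default scales with the number of unknowns.
    return_solution : bool
        If True return a :class:`FieldSolution` (potential + E field);
        otherwise return the potential map alone.

    Raises
    ------
    ConvergenceError
        If CG stops before reaching ``tol``; the message reports the
        attained relative residual.
    ValueError
        Overlapping or out-of-domain electrodes.
    """
    nx, ny = medium.grid_shape
    h = medium.pixel_size
    masks = _electrode_masks(medium, electrodes)
    pots = electrodes.potentials

    fixed = np.zeros((nx, ny), dtype=bool)
    phi = np.zeros((nx, ny))
    fixed[0, :] = fixed[-1, :] = True
    fixed[:, 0] = fixed[:, -1] = True
    for m, v in zip(masks, pots):
        fixed |= m
        phi[m] = v

    sigma = np.maximum(medium.sigma, 1e-12 * max(medium.sigma.max(), 1.0))
    # harmonic-mean conductivity on the four faces of each pixel
    def hmean(a, b):
        return 2 * a * b / (a + b)

    w_e = np.zeros((nx, ny)); w_w = np.zeros((nx, ny))
    w_n = np.zeros((nx, ny)); w_s = np.zeros((nx, ny))
    w_e[:-1, :] = hmean(sigma[:-1, :], sigma[1:, :])
    w_w[1:, :] = w_e[:-1, :]
    w_n[:, :-1] = hmean(sigma[:, :-1], sigma[:, 1:])
    w_s[:, 1:] = w_n[:, :-1]

    free = ~fixed
    idx = -np.ones((nx, ny), dtype=np.int64)
    idx[free] = np.arange(free.sum())
    n_free = int(free.sum())
    if n_free == 0:
        sol = phi
    else:
        diag = (w_e + w_w + w_n + w_s)[free]
        rows, cols, vals = [np.arange(n_free)], [np.arange(n_free)], [diag]
        rhs = np.zeros(n_free)

        def couple(weight, shift):
            # neighbour of each free pixel along `shift`
            src_i, src_j = np.nonzero(free)
            ni, nj = src_i + shift[0], src_j + shift[1]
            w = weight[free]
            nb_fixed = fixed[ni, nj]
            nb_free = ~nb_fixed
            rows.append(idx[src_i[nb_free], src_j[nb_free]])
            cols.append(idx[ni[nb_free], nj[nb_free]])
            vals.append(-w[nb_free])
            np.add.at(rhs, idx[src_i[nb_fixed], src_j[nb_fixed]],
                      w[nb_fixed] * phi[ni[nb_fixed], nj[nb_fixed]])

        couple(w_e, (1, 0))
        couple(w_w, (-1, 0))
        couple(w_n, (0, 1))
        couple(w_s, (0, -1))
        A = sp.csr_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(n_free, n_free))
        M = sp.diags(1.0 / A.diagonal())
        if maxiter is None:
            maxiter = max(2000, 20 * int(np.sqrt(n_free)))
        u, info = spla.cg(A, rhs, rtol=tol, atol=0.0, maxiter=maxiter, M=M)
        res = np.linalg.norm(rhs - A @ u) / max(np.linalg.norm(rhs), 1e-300)
        if info != 0 and res > tol * 10:
            raise ConvergenceError(
                f"CG did not converge in {maxiter} iterations "
                f"(relative residual {res:.3e} > tol {tol:.1e})")
        sol = phi.copy()
        sol[free] = u

    ex = np.zeros_like(sol)
    ey = np.zeros_like(sol)
    ex[1:-1, :] = -(sol[2:, :] - sol[:-2, :]) / (2 * h)
    ey[:, 1:-1] = -(sol[:, 2:] - sol[:, :-2]) / (2 * h)
    ex[0, :] = -(sol[1, :] - sol[0, :]) / h
    ex[-1, :] = -(sol[-1, :] - sol[-2, :]) / h
    ey[:, 0] = -(sol[:, 1] - sol[:, 0]) / h
    ey[:, -1] = -(sol[:, -1] - sol[:, -2]) / h
    if not return_solution:
        return sol
    residual = _interior_residual(sol, medium, fixed)
    return FieldSolution(potential=sol, e_field=np.stack([ex, ey]),
                         residual=residual,
                         meta={"mode": electrodes.mode,
                               "voltage": electrodes.voltage})


def _interior_residual(phi, medium, fixed):
    """RMS of div(sigma grad phi) over free pixels, relative to scale."""
    sigma = medium.sigma
    h = medium.pixel_size
    r = np.zeros_like(phi)
    w_e = 2 * sigma[:-1, :] * sigma[1:, :] / (sigma[:-1, :] + sigma[1:, :] + 1e-300)
    w_n = 2 * sigma[:, :-1] * sigma[:, 1:] / (sigma[:, :-1] + sigma[:, 1:] + 1e-300)
    flux = np.zeros_like(phi)
    flux[:-1, :] += w_e * (phi[1:, :] - phi[:-1, :])
    flux[1:, :] += w_e * (phi[:-1, :] - phi[1:, :])
    flux[:, :-1] += w_n * (phi[:, 1:] - phi[:, :-1])
    flux[:, 1:] += w_n * (phi[:, :-1] - phi[:, 1:])
    r = flux / h ** 2
    free = ~fixed
    scale = sigma.max() * (np.abs(phi).max() + 1e-300) / h ** 2
    return float(np.sqrt(np.mean(r[free] ** 2)) / scale)


def nominal_field_strength(voltage, gap):
    """Nominal (plate-approximation) field V/gap in V/m.

    This is the label convention used to quote field intensities, e.g.
    1200 V across a 5 mm gap -> 2.4 kV/cm.
    """
    if gap <= 0:
        raise ValueError("gap must be positive")
    return voltage / gap


def energy_deposition(e_field, medium, pulse):
    """Per-pulse Joule heat density ``H = sigma |E|^2 tau_eff`` in J/m^3.

    ``e_field`` may be a vector map ``(2, nx, ny)`` or a magnitude map
    ``(nx, ny)``.
    """
    e = np.asarray(e_field, dtype=float)
    if e.ndim == 3 and e.shape[0] == 2:
        e2 = e[0] ** 2 + e[1] ** 2
    elif e.shape == medium.grid_shape:
        e2 = e ** 2
    else:
        raise ValueError("e_field must be (2, nx, ny) vector or (nx, ny) magnitude")
    if e2.shape != medium.grid_shape:
        raise ValueError("e_field grid does not match medium grid")
    if np.any(medium.sigma < 0):
        raise ValueError("conductivity must be non-negative")
    return medium.sigma * e2 * pulse.tau_eff


def initial_pressure(dose, medium):
    """Initial acoustic pressure ``p0 = beta/(kappa rho c_v) * H`` in Pa."""
    dose = np.asarray(dose, dtype=float)
    if dose.shape != medium.grid_shape:
        raise ValueError("dose grid does not match medium grid")
    denom = medium.kappa * medium.rho * medium.c_v
    if np.any(denom == 0):
        raise ValueError("kappa, rho and c_v must be nonzero everywhere")
    return medium.beta / denom * dose


def simulate_field(medium, electrodes, pulse, tol=1e-8):
    """End-to-end: potential -> E -> dose -> p0 as one :class:`FieldSolution`."""
    sol = solve_potential(medium, electrodes, tol=tol, return_solution=True)
    sol.dose = energy_deposition(sol.e_field, medium, pulse)
    sol.p0 = initial_pressure(sol.dose, medium)
    sol.meta.update({"tau_eff": pulse.tau_eff})
    return sol
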