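"""End-to-end experiment drivers.

Each driver wires the field solver, acoustic forward model, trace
processing, and reconstruction into one of the characterisation or
imaging scenarios: a transducer distance sweep yielding the sound speed,
a voltage sweep yielding the amplitude-voltage and amplitude-energy laws,
ring-array imaging videos with a ramping voltage or a moving source, and
the centre-gain curve of the ring geometry.

All scenarios run at desk scale by default (64 elements, 500 raw video
frames, coarse grids); ``profile="full"`` restores the full 128-element /
3000-frame acquisition.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from . import phantoms
from .field import Medium, PulseWaveform
from .forward import ArrayGeometry, TransducerResponse, add_noise, apply_response, propagate
from .recon import ImageGrid, normalize, ubp_reconstruct
from .sigproc import FrameStack, estimate_tof, fit_sound_speed, frame_average

__all__ = [
    "ExperimentConfig",
    "SweepResult",
    "VideoResult",
    "run_distance_sweep",
    "run_voltage_sweep",
    "run_video",
    "center_gain_curve",
    "run_experiment",
]

SCENARIOS = ("distance_sweep", "voltage_sweep", "phantom_1p1g", "phantom_2p",
             "voltage_ramp_video", "moving_source_video")


@dataclass
class ExperimentConfig:
    """Named scenario plus seed and parameter overrides."""

    scenario: str
    seed: int = 0
    overrides: dict = dc_field(default_factory=dict)

    def __post_init__(self):
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}; "
                             f"choose from {SCENARIOS}")


@dataclass
class SweepResult:
    """Tabulated sweep with fit parameters and goodness of fit."""

    table: pd.DataFrame
    fit: dict
    seed: int = 0


@dataclass
class VideoResult:
    """Reconstructed frame sequence with per-frame metadata."""

    images: np.ndarray           # (n_frames, nx, ny), normalised
    frame_table: pd.DataFrame    # per reconstructed frame
    frame_interval: float        # seconds
    grid: ImageGrid
    seed: int = 0
    meta: dict = dc_field(default_factory=dict)


def _r2(y, y_fit):
    y = np.asarray(y, float)
    ss_res = np.sum((y - y_fit) ** 2)
    ss_tot = np.sum((y - y.mean()) ** 2)
    return 1.0 - ss_res / ss_tot


def run_distance_sweep(distances=None, v_s=1497.0, t0_offset=0.0,
                       snr_db=np.inf, seed=0, sampling_rate=40e6,
                       source_radius=0.4e-3):
    """Single-detector distance sweep: simulate, pick TOFs, fit sound speed.

    A compact disc source sits at the origin; one detector is placed at
    each requested distance (default 30-55 mm in 5 mm steps).  Arrival
    times come from the band-passed trace's leading-edge half-maximum
    envelope crossing; an optional instrumental delay ``t0_offset`` shifts
    every recorded TOF.

    Returns a :class:`SweepResult` whose ``fit`` holds ``speed_m_per_s``
    and ``intercept_s``.
    """
    if distances is None:
        distances = np.arange(0.030, 0.0551, 0.005)
    distances = np.asarray(distances, dtype=float)
    if distances.size < 2:
        raise ValueError("need at least two distances")
    px = 0.05e-3
    n = 96
    medium = Medium.homogeneous((n, n), px, v_s=v_s)
    p0 = phantoms.disc_map((n, n), px, (0.0, 0.0), source_radius)
    rows = []
    for i, d in enumerate(np.sort(distances)):
        n_samp = int(np.ceil(d / v_s * sampling_rate)) + 256
        geom = ArrayGeometry(n_elements=1, ring_radius=d,
                             sampling_rate=sampling_rate, n_samples=n_samp,
                             element_angles=np.array([0.0]))
        data = propagate(p0, medium, geom, form="derivative")
        data = apply_response(data, TransducerResponse())
        if np.isfinite(snr_db):
            data = add_noise(data, snr_db, seed + i)
        # leading-edge picker: the N-wave envelope is bimodal (it peaks at
        # the compression and rarefaction edges), so the half-maximum
        # crossing is the distance-consistent arrival mark; its constant
        # offset lands in the regression intercept, not the slope.
        tof = estimate_tof(data.traces[0], sampling_rate,
                           method="threshold", threshold=0.5)
        rows.append({"distance_m": d, "tof_s": tof + t0_offset,
                     "peak_amplitude": float(np.abs(data.traces).max())})
    table = pd.DataFrame(rows).sort_values("distance_m", ignore_index=True)
    speed, intercept = fit_sound_speed(table["distance_m"], table["tof_s"])
    pred = speed * (table["tof_s"] - intercept)
    fit = {"speed_m_per_s": speed, "intercept_s": intercept,
           "r_squared": _r2(table["distance_m"], pred)}
    return SweepResult(table=table, fit=fit, seed=seed)


def run_voltage_sweep(voltages=None, gap=4e-3, electrode_radius=0.5e-3,
                      sigma=0.5, load_ohms=50.0, seed=0, n_elements=8,
                      grid_shape=(160, 160), pixel_size=0.25e-3,
                      tol=1e-7):
    """Voltage sweep of the end-to-end electroacoustic amplitude.

    For each voltage (default 100-900 V in 100 V steps) the electrode-pair
    field is solved, converted to p0, propagated to a small ring, and
    band-passed; the peak |trace| is tabulated.  Two fits are reported:

    * power law ``amplitude = a V^b`` (log-log least squares) with its
      exponent ``b`` and R^2 — the quadratic deposition law predicts b = 2;
    * straight line of amplitude against per-pulse energy ``V^2 tau / R``
      with its R^2.
    """
    if voltages is None:
        voltages = np.arange(100.0, 901.0, 100.0)
    voltages = np.asarray(voltages, dtype=float)
    if voltages.size < 2:
        raise ValueError("need at least two voltages for the sweep fits")
    if np.any(voltages <= 0):
        raise ValueError("voltages must be positive")
    geom = ArrayGeometry(n_elements=n_elements, ring_radius=0.050,
                         n_samples=2304)
    rows = []
    for v in np.sort(voltages):
        pulse = PulseWaveform(amplitude=v)
        p0, medium, _ = phantoms.electrode_pair_p0(
            grid_shape=grid_shape, pixel_size=pixel_size, gap=gap,
            radius=electrode_radius, mode="1p1g", voltage=v, sigma=sigma,
            pulse=pulse, tol=tol)
        data = apply_response(propagate(p0, medium, geom))
        rows.append({"voltage_V": v,
                     "energy_J": pulse.energy_per_pulse(load_ohms),
                     "peak_amplitude": float(np.abs(data.traces).max())})
    table = pd.DataFrame(rows)
    logv, loga = np.log(table["voltage_V"]), np.log(table["peak_amplitude"])
    b, log_a0 = np.polyfit(logv, loga, 1)
    r2_power = _r2(loga, b * logv + log_a0)
    c1, c0 = np.polyfit(table["energy_J"], table["peak_amplitude"], 1)
    r2_lin = _r2(table["peak_amplitude"], c1 * table["energy_J"] + c0)
    fit = {"exponent_b": float(b), "prefactor_a": float(np.exp(log_a0)),
           "r_squared_power": float(r2_power),
           "slope_per_joule": float(c1), "offset": float(c0),
           "r_squared_energy_linear": float(r2_lin),
           "load_ohms": load_ohms}
    return SweepResult(table=table, fit=fit, seed=seed)


def _video_setup(profile, n_elements, n_raw_frames):
    if profile == "full":
        return 128, 3000
    if profile != "desk":
        raise ValueError("profile must be 'desk' or 'full'")
    return n_elements, n_raw_frames


def run_video(scenario="voltage_ramp", seed=0, profile="desk",
              n_elements=64, n_raw_frames=500, frame_interval=1e-3,
              average_k=10, snr_db=25.0, v_s=1497.0,
              v_start=100.0, v_stop=1000.0, noise_ref_voltage=1000.0,
              trajectory=((-12e-3, 0.0), (0.0, 0.0)),
              grid=None, element_width=None):
    """Frame-sequence imaging of a ramping voltage or a moving source.

    ``voltage_ramp``: a fixed 1p1g electrode pair is pulsed while the
    amplitude ramps linearly from ``v_start`` to ``v_stop`` over the raw
    frames (100 -> 1000 V over 3 s at 1 kHz in the full profile).  The
    thermal noise floor is fixed in absolute terms; ``snr_db`` sets it
    relative to the peak signal of a ``noise_ref_voltage`` acquisition,
    so early low-voltage frames sit at or below the noise floor (and a
    ramp held at 0 V records pure noise).

    ``moving_source``: a compact deposition spot (the point-like exposed
    electrode tip, a 0.25 mm disc at the electrode-pair pattern's peak
    amplitude) is translated along a straight ``trajectory``
    (grid-snapped) at fixed drive amplitude.

    Raw frames are block-averaged in non-overlapping groups of
    ``average_k``, envelope-UBP reconstructed, and jointly normalised to a
    unit global maximum.  The per-frame table records voltage or
    programmed source position and the pre-normalisation peak intensity.
    """
    n_elements, n_raw_frames = _video_setup(profile, n_elements, n_raw_frames)
    rng = np.random.default_rng(seed)
    if grid is None:
        grid = ImageGrid(132, 132, 0.25e-3)
    fs = 40e6
    # acquisition window bracketing the grid's flight times
    r_max = grid.max_radius()
    ring = 0.050
    t_lo = (ring - r_max) / v_s * 0.95
    t_hi = (ring + r_max) / v_s * 1.05
    n_samp = int(np.ceil((t_hi - t_lo) * fs)) + 64
    geom = ArrayGeometry(n_elements=n_elements, ring_radius=ring,
                         sampling_rate=fs, n_samples=n_samp, t0=t_lo)
    medium = Medium.homogeneous((grid.nx, grid.ny), grid.pixel_size, v_s=v_s)

    # electrode-pair deposition pattern, cropped to its effective support
    # (the dipole-like field decays fast, so an 8 mm window holds it all)
    solve_n, patch_n = 64, 32
    full_patch, _, _ = phantoms.electrode_pair_p0(
        grid_shape=(solve_n, solve_n), pixel_size=grid.pixel_size,
        gap=1.5e-3, radius=0.4e-3, mode="1p1g", voltage=noise_ref_voltage,
        tol=1e-7)
    lo = solve_n // 2 - patch_n // 2
    patch = full_patch[lo:lo + patch_n, lo:lo + patch_n]
    if scenario == "moving_source":
        # compact tip-sized spot at the pattern's peak deposition level
        patch = phantoms.disc_map((patch_n, patch_n), grid.pixel_size,
                                  (0.0, 0.0), 0.25e-3,
                                  amplitude=float(full_patch.max()))
    patch_peak_ij = np.unravel_index(np.argmax(patch), patch.shape)

    def embed(offset_px):
        m = np.zeros((grid.nx, grid.ny))
        i0 = grid.nx // 2 - patch_n // 2 + offset_px[0]
        j0 = grid.ny // 2 - patch_n // 2 + offset_px[1]
        if i0 < 0 or j0 < 0 or i0 + patch_n > grid.nx or j0 + patch_n > grid.ny:
            raise ValueError("trajectory exits the reconstruction grid")
        m[i0:i0 + patch_n, j0:j0 + patch_n] = patch
        return m

    frame_meta = []
    if scenario == "voltage_ramp":
        base = propagate(embed((0, 0)), medium, geom,
                         element_width=element_width)
        base = apply_response(base)
        volts = np.linspace(v_start, v_stop, n_raw_frames)
        scale = (volts / noise_ref_voltage) ** 2
        noise_std = np.abs(base.traces).max() / 10 ** (snr_db / 20)
        raw = np.empty((n_raw_frames, n_elements, n_samp), dtype=np.float32)
        for f in range(n_raw_frames):
            raw[f] = (base.traces * scale[f]
                      + rng.normal(0.0, noise_std, base.traces.shape))
        for f in range(n_raw_frames):
            frame_meta.append({"voltage_V": volts[f]})
    elif scenario == "moving_source":
        p_a = np.asarray(trajectory[0], float)
        p_b = np.asarray(trajectory[1], float)
        noise_std = None
        raw = np.empty((n_raw_frames, n_elements, n_samp), dtype=np.float32)
        for f in range(n_raw_frames):
            frac = f / max(n_raw_frames - 1, 1)
            pos = p_a + frac * (p_b - p_a)
            off = (int(round(pos[0] / grid.pixel_size)),
                   int(round(pos[1] / grid.pixel_size)))
            data = apply_response(propagate(embed(off), medium, geom,
                                            element_width=element_width))
            if noise_std is None:
                noise_std = np.abs(data.traces).max() / 10 ** (snr_db / 20)
            raw[f] = data.traces + rng.normal(0.0, noise_std,
                                              data.traces.shape)
            # programmed peak position: patch maximum translated to `off`
            px = grid.pixel_size
            peak_xy = (
                (patch_peak_ij[0] - patch_n / 2 + 0.5 + off[0]) * px,
                (patch_peak_ij[1] - patch_n / 2 + 0.5 + off[1]) * px)
            frame_meta.append({"source_x_m": peak_xy[0],
                               "source_y_m": peak_xy[1]})
    else:
        raise ValueError("scenario must be 'voltage_ramp' or 'moving_source'")

    stack = FrameStack(frames=raw, frame_interval=frame_interval,
                       sampling_rate=fs, meta={"seed": seed,
                                               "scenario": scenario})
    avg = frame_average(stack, average_k)
    images = np.empty((avg.n_frames, grid.nx, grid.ny))
    peaks, peak_pos = [], []
    for f in range(avg.n_frames):
        data = base.copy_with(avg.frames[f].astype(float)) \
            if scenario == "voltage_ramp" else \
            _as_channel_data(avg.frames[f].astype(float), geom)
        img = ubp_reconstruct(data, v_s, grid, use_envelope=True)
        images[f] = img.pixels
        peaks.append(float(img.pixels.max()))
        peak_pos.append(img.peak_position())
    global_max = max(peaks)
    if global_max > 0:
        images /= global_max
    rows = []
    for f in range(avg.n_frames):
        # averaged data mixes its whole block, so per-frame metadata is
        # the block mean (voltage, programmed source position)
        block = frame_meta[f * average_k: (f + 1) * average_k]
        row = {key: float(np.mean([b[key] for b in block]))
               for key in block[0]}
        row.update({"frame": f, "time_s": (f + 1) * avg.frame_interval,
                    "peak_intensity": peaks[f],
                    "recon_peak_x_m": peak_pos[f][0],
                    "recon_peak_y_m": peak_pos[f][1]})
        rows.append(row)
    return VideoResult(images=images, frame_table=pd.DataFrame(rows),
                       frame_interval=avg.frame_interval, grid=grid,
                       seed=seed,
                       meta={"scenario": scenario, "n_raw_frames": n_raw_frames,
                             "average_k": average_k, "n_elements": n_elements,
                             "noise_std": float(noise_std),
                             "snr_db": snr_db})


def _as_channel_data(traces, geom):
    from .forward import ChannelData
    return ChannelData(traces=traces, sampling_rate=geom.sampling_rate,
                       geometry=geom, t0=geom.t0)


def center_gain_curve(offsets=None, n_elements=64, v_s=1497.0,
                      element_width=1.5e-3, source_radius=0.5e-3,
                      window=24, pixel_size=0.25e-3):
    """Reconstructed peak of a fixed source versus its off-centre distance.

    A fixed-amplitude disc source is placed at radial offsets (default
    40 mm down to 0) and envelope-UBP reconstructed on a small window
    around its known position.  With the elements' finite aperture
    (viewing-angle directivity), off-centre sources are seen effectively
    by fewer elements, so the peak grows towards the ring centre.

    Returns a DataFrame with columns ``offset_m`` and ``peak_intensity``
    sorted from largest offset to the centre.
    """
    if offsets is None:
        offsets = np.arange(0.040, -0.001, -0.005)
    offsets = np.sort(np.asarray(offsets, float))[::-1]
    fs = 40e6
    ring = 0.050
    n = 48
    rows = []
    for a in offsets:
        medium = Medium.homogeneous((n, n), pixel_size, v_s=v_s)
        p0 = phantoms.disc_map((n, n), pixel_size, (0.0, 0.0), source_radius)
        # place the small source grid at the offset via detector-side shift:
        # equivalently shift all element positions by -a along x
        t_lo = max((ring - a - n * pixel_size) / v_s * 0.9, 0.0)
        t_hi = (ring + a + n * pixel_size) / v_s * 1.05
        n_samp = int(np.ceil((t_hi - t_lo) * fs)) + 64
        geom = ArrayGeometry(n_elements=n_elements, ring_radius=ring,
                             sampling_rate=fs, n_samples=n_samp, t0=t_lo)
        data = propagate(p0, medium, geom, form="derivative",
                         element_width=element_width, source_offset=(a, 0.0))
        data = apply_response(data)
        grid = ImageGrid(window, window, pixel_size, center=(a, 0.0))
        img = ubp_reconstruct(data, v_s, grid, use_envelope=True)
        rows.append({"offset_m": float(a),
                     "peak_intensity": float(img.pixels.max())})
    return pd.DataFrame(rows)


def run_experiment(config):
    """Dispatch an :class:`ExperimentConfig` to its scenario driver."""
    ov = dict(config.overrides)
    if config.scenario == "distance_sweep":
        return run_distance_sweep(seed=config.seed, **ov)
    if config.scenario == "voltage_sweep":
        return run_voltage_sweep(seed=config.seed, **ov)
    if config.scenario in ("phantom_1p1g", "phantom_2p"):
        mode = "1p1g" if config.scenario == "phantom_1p1g" else "2p"
        ov.setdefault("mode", mode)
        return phantoms.electrode_pair_p0(**ov)
    if config.scenario == "voltage_ramp_video":
        return run_video(scenario="voltage_ramp", seed=config.seed, **ov)
    if config.scenario == "moving_source_video":
        return run_video(scenario="moving_source", seed=config.seed, **ov)
    raise ValueError(f"unknown scenario {config.scenario!r}")
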