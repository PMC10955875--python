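"""Container formats, configuration, and run manifests.

Channel data and frame stacks travel in a self-describing HDF5 layout:

    /traces     float32, (elements, samples)         -- ChannelData
    /frames     float32, (frames, elements, samples) -- FrameStack
    /geometry/element_angles, /geometry/ring_radius
    attrs: sampling_rate, t0, frame_interval, plus provenance (seed, ...)

Images are written as 32-bit float TIFF with a JSON sidecar carrying the
pixel size and provenance; configurations are plain YAML; every CLI run
emits a JSON manifest sufficient to re-execute it.
"""

from __future__ import annotations

import datetime
import json
from dataclasses import asdict, dataclass, field as dc_field
from pathlib import Path

import h5py
import numpy as np
import tifffile
import yaml

from .field import ElectrodePair, Medium, PulseWaveform
from .forward import ArrayGeometry, ChannelData
from .sigproc import FrameStack

__all__ = [
    "SchemaError",
    "RunManifest",
    "write_container",
    "read_container",
    "write_image",
    "read_image",
    "write_video",
    "read_trace_csv",
    "read_config",
    "medium_from_config",
    "electrodes_from_config",
    "pulse_from_config",
    "geometry_from_config",
    "load_zenodo_waveforms",
]


class SchemaError(ValueError):
    """Container does not match the documented layout."""


@dataclass
class RunManifest:
    """Everything needed to re-execute a run byte-for-byte."""

    command: str
    config: dict
    seed: int
    inputs: list = dc_field(default_factory=list)
    outputs: list = dc_field(default_factory=list)
    version: str = None
    timestamp: str = None

    def __post_init__(self):
        if self.version is None:
            from . import __version__
            self.version = __version__
        if self.timestamp is None:
            self.timestamp = datetime.datetime.now(
                datetime.timezone.utc).isoformat()

    def write(self, path):
        path = Path(path)
        path.write_text(json.dumps(asdict(self), indent=2, default=str))
        return path


def write_container(data, path, manifest=None):
    """Write ChannelData or FrameStack to the HDF5 container.

    A manifest sidecar ``<path>.manifest.json`` is written when a
    :class:`RunManifest` is supplied.
    """
    path = Path(path)
    with h5py.File(path, "w") as f:
        if isinstance(data, ChannelData):
            f.create_dataset("traces", data=data.traces.astype(np.float32))
            g = f.create_group("geometry")
            g.create_dataset("element_angles", data=data.geometry.element_angles)
            g.attrs["ring_radius"] = data.geometry.ring_radius
            f.attrs["sampling_rate"] = data.sampling_rate
            f.attrs["t0"] = data.t0
            for k, v in data.meta.items():
                if isinstance(v, (int, float, str, bool)):
                    f.attrs[f"meta_{k}"] = v
        elif isinstance(data, FrameStack):
            f.create_dataset("frames", data=data.frames.astype(np.float32))
            f.attrs["sampling_rate"] = data.sampling_rate
            f.attrs["frame_interval"] = data.frame_interval
            for k, v in data.meta.items():
                if isinstance(v, (int, float, str, bool)):
                    f.attrs[f"meta_{k}"] = v
        else:
            raise TypeError("data must be ChannelData or FrameStack")
    if manifest is not None:
        manifest.outputs.append(str(path))
        manifest.write(str(path) + ".manifest.json")
    return path


def read_container(path):
    """Read the HDF5 container back into ChannelData or FrameStack."""
    path = Path(path)
    try:
        f = h5py.File(path, "r")
    except OSError as exc:
        raise SchemaError(f"not a readable HDF5 container: {path} ({exc})")
    with f:
        meta = {k[5:]: f.attrs[k] for k in f.attrs if k.startswith("meta_")}
        if "traces" in f:
            for key in ("sampling_rate", "t0"):
                if key not in f.attrs:
                    raise SchemaError(f"missing required attribute '{key}'")
            if "geometry" not in f:
                raise SchemaError("missing required group 'geometry'")
            g = f["geometry"]
            if "element_angles" not in g or "ring_radius" not in g.attrs:
                raise SchemaError(
                    "geometry group must hold 'element_angles' and "
                    "attribute 'ring_radius'")
            traces = f["traces"][()].astype(float)
            angles = g["element_angles"][()]
            geom = ArrayGeometry(n_elements=traces.shape[0],
                                 ring_radius=float(g.attrs["ring_radius"]),
                                 sampling_rate=float(f.attrs["sampling_rate"]),
                                 n_samples=traces.shape[1],
                                 element_angles=angles,
                                 t0=float(f.attrs["t0"]))
            return ChannelData(traces=traces,
                               sampling_rate=float(f.attrs["sampling_rate"]),
                               geometry=geom, t0=float(f.attrs["t0"]),
                               meta=meta)
        if "frames" in f:
            for key in ("sampling_rate", "frame_interval"):
                if key not in f.attrs:
                    raise SchemaError(f"missing required attribute '{key}'")
            return FrameStack(frames=f["frames"][()].astype(float),
                              frame_interval=float(f.attrs["frame_interval"]),
                              sampling_rate=float(f.attrs["sampling_rate"]),
                              meta=meta)
    raise SchemaError("container holds neither /traces nor /frames")


def write_image(image, path, preview=False):
    """Write a ReconImage (or bare map) as float32 TIFF + JSON sidecar."""
    path = Path(path)
    pixels = getattr(image, "pixels", image)
    tifffile.imwrite(path, np.asarray(pixels, dtype=np.float32))
    sidecar = {"pixel_size_m": getattr(image, "pixel_size", None),
               "origin_m": list(getattr(image, "origin", (0.0, 0.0))),
               "normalization": getattr(image, "normalization", "none"),
               "provenance": getattr(image, "provenance", {})}
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2,
                                                    default=str))
    if preview:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        fig, ax = plt.subplots()
        ax.imshow(np.asarray(pixels).T, origin="lower", cmap="inferno")
        ax.set_xlabel("x [px]"); ax.set_ylabel("y [px]")
        fig.savefig(str(path) + ".png", dpi=120)
        plt.close(fig)
    return path


def read_image(path):
    """Read a float TIFF and its sidecar; returns (pixels, sidecar dict)."""
    pixels = tifffile.imread(path).astype(float)
    sidecar_path = Path(str(path) + ".json")
    sidecar = json.loads(sidecar_path.read_text()) if sidecar_path.exists() else {}
    return pixels, sidecar


def write_video(images, path, frame_interval, pixel_size):
    """Write a frame sequence as multi-page float32 TIFF with metadata."""
    path = Path(path)
    tifffile.imwrite(path, np.asarray(images, dtype=np.float32))
    Path(str(path) + ".json").write_text(json.dumps(
        {"frame_interval_s": frame_interval, "pixel_size_m": pixel_size,
         "n_frames": int(np.asarray(images).shape[0])}, indent=2))
    return path


def read_trace_csv(path, sampling_rate, t0=0.0):
    """Import a legacy single-trace CSV (one sample per line, pascals)."""
    trace = np.loadtxt(path, delimiter=",", ndmin=1).ravel()
    geom = ArrayGeometry(n_elements=1, ring_radius=0.050,
                         sampling_rate=sampling_rate, n_samples=trace.size,
                         element_angles=np.array([0.0]), t0=t0)
    return ChannelData(traces=trace[None, :], sampling_rate=sampling_rate,
                       geometry=geom, t0=t0,
                       meta={"source": str(path), "format": "csv"})


def read_config(path):
    """Load a YAML configuration file into a dict."""
    with open(path) as f:
        cfg = yaml.safe_load(f)
    if not isinstance(cfg, dict):
        raise SchemaError("configuration must be a YAML mapping")
    return cfg


def medium_from_config(cfg):
    """Build a Medium from a config mapping (section ``medium``)."""
    c = cfg.get("medium", cfg)
    for key in ("grid_shape", "pixel_size"):
        if key not in c:
            raise SchemaError(f"medium config missing '{key}'")
    kwargs = {k: c[k] for k in ("sigma", "beta", "kappa", "rho", "c_v", "v_s")
              if k in c}
    return Medium(grid_shape=tuple(c["grid_shape"]),
                  pixel_size=float(c["pixel_size"]), **kwargs)


def electrodes_from_config(cfg):
    c = cfg.get("electrodes", cfg)
    for key in ("centers", "radius"):
        if key not in c:
            raise SchemaError(f"electrodes config missing '{key}'")
    return ElectrodePair(centers=np.asarray(c["centers"], float),
                         radius=float(c["radius"]),
                         mode=c.get("mode", "1p1g"),
                         voltage=float(c.get("voltage", 1000.0)))


def pulse_from_config(cfg):
    c = cfg.get("pulse", cfg)
    return PulseWaveform(amplitude=float(c.get("amplitude", 1000.0)),
                         width=float(c.get("width", 100e-9)),
                         rise_time=float(c.get("rise_time", 15e-9)),
                         rep_rate=float(c.get("rep_rate", 1000.0)))


def geometry_from_config(cfg):
    c = cfg.get("array", cfg)
    return ArrayGeometry(n_elements=int(c.get("n_elements", 128)),
                         ring_radius=float(c.get("ring_radius", 0.050)),
                         sampling_rate=float(c.get("sampling_rate", 40e6)),
                         n_samples=int(c.get("n_samples", 2048)),
                         t0=float(c.get("t0", 0.0)))


def load_zenodo_waveforms(path):
    """Import adapter for externally deposited raw waveforms (not implemented).

    The deposit's internal layout is not specified by its record; this hook
    exists so a concrete adapter can be slotted in once the layout is known.
    """
    raise NotImplementedError(
        "No adapter for the deposited waveform layout is bundled; convert "
        "the data to the documented HDF5 container (/traces + /geometry) "
        "and use read_container() instead.")
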