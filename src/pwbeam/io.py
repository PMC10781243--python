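"""File formats, run configuration and the end-to-end pipeline.

Two HDF5 layouts are read:

* the native cube layout written by this package
  (``/data_real``, ``/data_imag``, ``/angles``, ``/fs``, ``/f0``, ``/c``,
  ``/element_x``, ``/t0``, optional ``/fd`` for IQ data), and
* PICMUS-style files from the IEEE IUS 2016 plane-wave imaging challenge,
  whose group names varied across releases; a dialect probe walks known
  spellings.  RF data are converted to analytic form on load; IQ data pass
  through with the demodulation frequency kept for carrier-correct delays.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import yaml

from .admas import AdmasThresholds, CoherenceMaps, beamform_txmv_admas
from .beamformers import BeamformedImage, get_beamformer
from .geometry import (
    AnalyticDataCube,
    PixelGrid,
    PlaneWaveSequence,
    TransducerGeometry,
    analytic_signal,
)
from .metrics import MetricsReport, RoiCircle, evaluate_image

__all__ = [
    "PwbeamIOError",
    "write_cube",
    "read_cube",
    "read_picmus",
    "write_image",
    "write_maps",
    "RunConfig",
    "run_pipeline",
]

log = logging.getLogger("pwbeam")


class PwbeamIOError(RuntimeError):
    """Raised when a data file is missing required fields or is unreadable."""


# ---------------------------------------------------------------------------
# native cube layout
# ---------------------------------------------------------------------------

def write_cube(path: str | Path, cube: AnalyticDataCube) -> None:
    """Write a cube in the native HDF5 layout."""
    with h5py.File(path, "w") as f:
        f.create_dataset("data_real", data=cube.data.real)
        f.create_dataset("data_imag", data=cube.data.imag)
        f.create_dataset("angles", data=cube.sequence.angles)
        f.create_dataset("t0", data=cube.sequence.t0)
        f.create_dataset("fs", data=cube.geometry.sampling_frequency)
        f.create_dataset("f0", data=cube.geometry.center_frequency)
        f.create_dataset("c", data=cube.geometry.sound_speed)
        f.create_dataset("element_x", data=cube.geometry.element_x)
        f.create_dataset("fd", data=cube.demodulation_frequency)


def read_cube(path: str | Path) -> AnalyticDataCube:
    """Read a cube from the native HDF5 layout."""
    try:
        with h5py.File(path, "r") as f:
            required = ["data_real", "angles", "fs", "f0", "c", "element_x"]
            for name in required:
                if name not in f:
                    raise PwbeamIOError(f"{path}: missing dataset /{name}")
            real = f["data_real"][()]
            imag = f["data_imag"][()] if "data_imag" in f else np.zeros_like(real)
            geom = TransducerGeometry(
                f["element_x"][()],
                float(f["f0"][()]),
                float(f["fs"][()]),
                float(f["c"][()]),
            )
            t0 = f["t0"][()] if "t0" in f else None
            seq = PlaneWaveSequence(f["angles"][()], t0)
            fd = float(f["fd"][()]) if "fd" in f else 0.0
            return AnalyticDataCube(real + 1j * imag, geom, seq, fd)
    except OSError as exc:
        raise PwbeamIOError(f"cannot read HDF5 file {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# PICMUS layout
# ---------------------------------------------------------------------------

_PICMUS_ROOTS = ["US/US_DATASET0000", "US/US_DATASET0001", "US"]


def _picmus_root(f: h5py.File) -> h5py.Group:
    for name in _PICMUS_ROOTS:
        if name in f:
            g = f[name]
            if isinstance(g, h5py.Group) and "angles" in g:
                return g
    # last resort: first group anywhere that holds an 'angles' dataset
    found: list[h5py.Group] = []

    def visit(_, obj):
        if isinstance(obj, h5py.Group) and "angles" in obj and not found:
            found.append(obj)

    f.visititems(visit)
    if found:
        return found[0]
    raise PwbeamIOError("no PICMUS-style group with an 'angles' dataset found")


def _require(group: h5py.Group, names: list[str]) -> h5py.Dataset:
    for name in names:
        if name in group:
            return group[name]
    raise PwbeamIOError(
        f"{group.file.filename}: missing dataset "
        f"{group.name}/{{{' | '.join(names)}}}"
    )


def read_picmus(path: str | Path) -> AnalyticDataCube:
    """Read a PICMUS-style HDF5 acquisition into an analytic cube."""
    try:
        with h5py.File(path, "r") as f:
            g = _picmus_root(f)
            angles = np.asarray(_require(g, ["angles"])[()], dtype=float).ravel()
            fs = float(np.asarray(_require(g, ["sampling_frequency"])[()]).ravel()[0])
            c = float(np.asarray(_require(g, ["sound_speed"])[()]).ravel()[0])
            t0 = 0.0
            for name in ("initial_time", "t0"):
                if name in g:
                    t0 = float(np.asarray(g[name][()]).ravel()[0])
            fmod = 0.0
            for name in ("modulation_frequency", "demodulation_frequency"):
                if name in g:
                    fmod = float(np.asarray(g[name][()]).ravel()[0])
            probe = np.asarray(_require(g, ["probe_geometry", "probe"])[()])
            if probe.ndim == 2:
                element_x = probe[0] if probe.shape[0] in (2, 3) else probe[:, 0]
            else:
                element_x = probe
            data_grp = _require(g, ["data"])
            if "real" not in data_grp:
                raise PwbeamIOError(f"{path}: missing dataset {data_grp.name}/real")
            real = np.asarray(data_grp["real"][()], dtype=float)
            imag = np.asarray(data_grp["imag"][()], dtype=float) if "imag" in data_grp else None

            f0 = fmod if fmod > 0 else fs / 4.0  # PICMUS probe: fs = 4 f0
            geom = TransducerGeometry(element_x, f0, fs, c)
            seq = PlaneWaveSequence(angles, np.full(angles.size, t0))
            if imag is None or (fmod == 0.0 and not np.any(imag)):
                data = analytic_signal(real, axis=-1)
                fd = 0.0
            else:
                data = real + 1j * imag
                fd = fmod
            return AnalyticDataCube(data, geom, seq, fd)
    except OSError as exc:
        raise PwbeamIOError(f"cannot read HDF5 file {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# result writers
# ---------------------------------------------------------------------------

def write_image(
    path_stem: str | Path,
    image: BeamformedImage,
    dynamic_range_db: float = 60.0,
) -> list[Path]:
    """Write the numeric image (NPZ) and a log-compressed grayscale PNG."""
    from matplotlib import pyplot as plt

    from .metrics import envelope_log

    stem = Path(path_stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    npz = stem.with_suffix(".npz")
    np.savez(
        npz,
        data=image.data,
        lateral_x=image.grid.lateral_x,
        axial_z=image.grid.axial_z,
        method=image.method,
    )
    png = stem.with_suffix(".png")
    db = envelope_log(image, dynamic_range_db)
    plt.imsave(png, db, cmap="gray", vmin=-dynamic_range_db, vmax=0.0)
    return [npz, png]


def write_maps(path_stem: str | Path, maps: CoherenceMaps) -> list[Path]:
    """Write the adaptive-p diagnostic maps (NPZ plus grayscale PNGs)."""
    from matplotlib import pyplot as plt

    stem = Path(path_stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    d = maps.as_dict()
    npz = Path(str(stem) + "_maps.npz")
    np.savez(npz, **d)
    written = [npz]
    for name, arr in d.items():
        p = Path(f"{stem}_{name}.png")
        plt.imsave(p, np.asarray(arr, dtype=float), cmap="gray")
        written.append(p)
    return written


# ---------------------------------------------------------------------------
# run configuration and pipeline
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Everything one reconstruction run needs; serializable to/from YAML."""

    input: str | None = None  # cube file (native or PICMUS); None -> synthetic
    synth: str = "cyst"  # 'point' or 'cyst' when input is None
    method: str = "cpwc"
    f_number: float = 1.75
    L: int = 25
    T: int | None = None  # None -> 5.4-wavelength rule on the grid in use
    delta: float | None = None  # None -> per-method default
    p: float = 2.0
    p_min: float = 1.0
    p_max: float = 2.0
    thresholds: AdmasThresholds | None = None
    x_range: tuple[float, float] | None = None
    z_range: tuple[float, float] | None = None
    dynamic_range_db: float = 60.0
    output_dir: str = "pwbeam_out"
    seed: int = 0
    save_maps: bool = False
    fwhm_targets: list[tuple[float, float]] = field(default_factory=list)
    cyst_rois: list[RoiCircle] = field(default_factory=list)
    background_rois: list[RoiCircle] = field(default_factory=list)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "thresholds" in raw and isinstance(raw["thresholds"], dict):
            raw["thresholds"] = AdmasThresholds(**raw["thresholds"])
        for key in ("x_range", "z_range"):
            if raw.get(key) is not None:
                raw[key] = tuple(raw[key])
        for key, role in (("cyst_rois", "cyst"), ("background_rois", "background")):
            raw[key] = [
                RoiCircle(tuple(r["center"]), r["radius"], role)
                for r in raw.get(key, [])
            ]
        raw["fwhm_targets"] = [tuple(t) for t in raw.get("fwhm_targets", [])]
        return cls(**raw)

    def effective_params(self) -> dict:
        d = dataclasses.asdict(self)
        if self.thresholds is not None:
            d["thresholds"] = dataclasses.asdict(self.thresholds)
        d["cyst_rois"] = [dataclasses.asdict(r) for r in self.cyst_rois]
        d["background_rois"] = [dataclasses.asdict(r) for r in self.background_rois]
        return d


_METHOD_DELTA = {"dcr-mvdr": 1.0}


def _load_or_simulate(config: RunConfig) -> AnalyticDataCube:
    from .synth import (
        make_cyst_phantom,
        make_point_phantom,
        reduced_geometry,
        reduced_sequence,
        simulate_cube,
    )

    if config.input is not None:
        path = Path(config.input)
        with h5py.File(path, "r") as f:
            native = "data_real" in f
        return read_cube(path) if native else read_picmus(path)
    geom = reduced_geometry()
    seq = reduced_sequence()
    if config.synth == "point":
        phantom = make_point_phantom(positions=[(0.0, 25e-3)])
    elif config.synth == "cyst":
        phantom = make_cyst_phantom(seed=config.seed)
    else:
        raise ValueError("synth must be 'point' or 'cyst'")
    return simulate_cube(phantom, geom, seq, seed=config.seed)


def run_pipeline(config: RunConfig):
    """Cube -> image -> metrics, with every artifact written to disk.

    Returns ``(image, report)``; the report is None when the config names no
    point targets and no ROI pairs.  Deterministic given config and seed."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    cube = _load_or_simulate(config)

    if config.x_range is None:
        ex = cube.geometry.element_x
        x_range = (float(ex[0]) * 0.8, float(ex[-1]) * 0.8)
    else:
        x_range = config.x_range
    z_range = config.z_range or (10e-3, 40e-3)
    grid = PixelGrid.for_cube(cube, x_range, z_range)

    delta = config.delta if config.delta is not None else _METHOD_DELTA.get(config.method, 0.1)
    kwargs: dict = {"f_number": config.f_number}
    maps = None
    if config.method == "txmv-admas":
        th = config.thresholds or AdmasThresholds(p_min=config.p_min, p_max=config.p_max)
        image, maps = beamform_txmv_admas(
            cube, grid, f_number=config.f_number, thresholds=th,
            L=min(config.L, cube.n_angles), T=config.T, delta=delta,
        )
    else:
        fn = get_beamformer(config.method)
        if config.method in ("txmv", "txmv-dmas"):
            kwargs.update(L=min(config.L, cube.n_angles), T=config.T, delta=delta)
        if config.method in ("txmv-dmas", "tx-dmas"):
            kwargs.update(p=config.p)
        if config.method in ("rxmv", "dcr-mvdr"):
            kwargs.update(delta=delta)
        image = fn(cube, grid, **kwargs)

    written = write_image(out / config.method, image, config.dynamic_range_db)
    if maps is not None and config.save_maps:
        written += write_maps(out / config.method, maps)

    report = None
    if config.fwhm_targets or (config.cyst_rois and config.background_rois):
        report = evaluate_image(
            image, config.fwhm_targets, config.cyst_rois, config.background_rois
        )
        (out / f"{config.method}_metrics.json").write_text(report.to_json())

    run_log = {"effective_config": config.effective_params(),
               "outputs": [str(p) for p in written]}
    (out / f"{config.method}_run.json").write_text(json.dumps(run_log, indent=2))
    log.info("run complete: %s", config.method)
    return image, report
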