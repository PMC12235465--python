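"""File formats: HDF5 scan containers, TIFF images/volumes, delimited tables.

One hierarchical container layout is the canonical interchange format for
mesh scans (one group per scan point holding the 2D frame plus motor
positions, beam geometry as root attributes); feature maps go out as
32-bit float TIFF with a plain-text sidecar header, CT volumes as TIFF
slice stacks, element maps as single-page TIFFs, and 1D curves as 2-3
column delimited text.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .ct_quant import Volume
from .dosimetry import BeamGeometry
from .feature_maps import FeatureMap, MeshScan
from .saxs_reduce import Curve1D
from .xrf_maps import ElementMap

__all__ = [
    "RunConfig",
    "write_mesh_scan",
    "read_mesh_scan",
    "write_feature_map",
    "read_feature_map",
    "write_volume",
    "read_volume",
    "write_element_map",
    "read_element_map",
    "write_curve",
    "read_curve",
]


@dataclass
class RunConfig:
    """Declarative run configuration, loadable from YAML.

    Validated on construction; its hash and seed are echoed into every
    output header so any product can be traced to the exact settings that
    made it.
    """

    energy_kev: float = 20.129
    sample_detector_mm: float = 8000.0
    pixel_um: float = 300.0
    beam_center: tuple[float, float] = (31.5, 31.5)
    q_window: tuple[float, float] = (0.004, 0.022)
    n_q: int = 40
    n_theta: int = 36
    stability_band: float = 0.10
    qmax_rg_limit: float = 1.3
    seed: int = 0
    out_dir: str = "."

    def __post_init__(self) -> None:
        errors = []
        if self.energy_kev <= 0:
            errors.append("energy_kev must be positive")
        if self.sample_detector_mm <= 0:
            errors.append("sample_detector_mm must be positive")
        if self.pixel_um <= 0:
            errors.append("pixel_um must be positive")
        if not self.q_window[0] < self.q_window[1]:
            errors.append("q_window must be increasing")
        if self.n_q < 2 or self.n_theta < 2:
            errors.append("n_q and n_theta must be >= 2")
        if not 0 <= self.stability_band < 1:
            errors.append("stability_band must lie in [0, 1)")
        if errors:
            raise ValueError("invalid config: " + "; ".join(errors))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("beam_center", "q_window"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def beam(self) -> BeamGeometry:
        return BeamGeometry(
            energy_kev=self.energy_kev,
            sample_detector_mm=self.sample_detector_mm,
            pixel_um=self.pixel_um,
            beam_center=self.beam_center,
        )

    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


# ---------------------------------------------------------------------------
# HDF5 mesh-scan container
# ---------------------------------------------------------------------------


def write_mesh_scan(path: str | Path, scan: MeshScan, config_hash: str = "") -> None:
    """Write a mesh scan to the hierarchical container layout.

    Layout: root attrs carry the beam geometry; group ``points/r###_c###``
    per scan point with dataset ``frame`` and motor-position attrs.
    """
    import h5py

    with h5py.File(path, "w") as fh:
        fh.attrs["energy_kev"] = scan.beam.energy_kev
        fh.attrs["sample_detector_mm"] = scan.beam.sample_detector_mm
        fh.attrs["pixel_um"] = scan.beam.pixel_um
        fh.attrs["beam_center"] = scan.beam.beam_center
        fh.attrs["step_mm"] = scan.step_mm
        fh.attrs["mesh_shape"] = scan.shape
        if config_hash:
            fh.attrs["config_hash"] = config_hash
        points = fh.create_group("points")
        rows, cols = scan.shape
        for r in range(rows):
            for c in range(cols):
                grp = points.create_group(f"r{r:03d}_c{c:03d}")
                grp.create_dataset("frame", data=scan.frames[r, c], compression="gzip")
                grp.attrs["y_mm"] = r * scan.step_mm[0]
                grp.attrs["x_mm"] = c * scan.step_mm[1]
                grp.attrs["valid"] = bool(scan.valid[r, c])


def read_mesh_scan(path: str | Path) -> MeshScan:
    import h5py

    with h5py.File(path, "r") as fh:
        beam = BeamGeometry(
            energy_kev=float(fh.attrs["energy_kev"]),
            sample_detector_mm=float(fh.attrs["sample_detector_mm"]),
            pixel_um=float(fh.attrs["pixel_um"]),
            beam_center=tuple(fh.attrs["beam_center"]),
        )
        rows, cols = (int(v) for v in fh.attrs["mesh_shape"])
        step = tuple(float(v) for v in fh.attrs["step_mm"])
        first = fh["points/r000_c000/frame"]
        frames = np.empty((rows, cols) + first.shape, dtype=float)
        valid = np.ones((rows, cols), dtype=bool)
        for r in range(rows):
            for c in range(cols):
                grp = fh[f"points/r{r:03d}_c{c:03d}"]
                frames[r, c] = grp["frame"][()]
                valid[r, c] = bool(grp.attrs.get("valid", True))
    return MeshScan(frames=frames, beam=beam, step_mm=step, valid=valid)


# ---------------------------------------------------------------------------
# TIFF products
# ---------------------------------------------------------------------------


def write_feature_map(path: str | Path, fmap: FeatureMap, config_hash: str = "") -> None:
    """32-bit float TIFF plus a sidecar text header (statistic, q-window)."""
    path = Path(path)
    tifffile.imwrite(path, fmap.values.astype(np.float32))
    sidecar = path.with_suffix(path.suffix + ".txt")
    lines = [
        f"statistic: {fmap.statistic}",
        f"q_window_invA: {fmap.q_window[0]} {fmap.q_window[1]}",
        f"step_mm: {fmap.step_mm[0]} {fmap.step_mm[1]}",
    ]
    if config_hash:
        lines.append(f"config_hash: {config_hash}")
    sidecar.write_text("\n".join(lines) + "\n")


def read_feature_map(path: str | Path) -> FeatureMap:
    path = Path(path)
    values = tifffile.imread(path).astype(float)
    meta = {}
    sidecar = path.with_suffix(path.suffix + ".txt")
    if sidecar.exists():
        for line in sidecar.read_text().splitlines():
            key, _, val = line.partition(":")
            meta[key.strip()] = val.strip()
    statistic = meta.get("statistic", "total_scattering")
    qw = tuple(float(v) for v in meta.get("q_window_invA", "0 0").split())
    step = tuple(float(v) for v in meta.get("step_mm", "0.05 0.05").split())
    return FeatureMap(values=values, statistic=statistic, q_window=qw, step_mm=step)


def write_volume(path: str | Path, vol: Volume) -> None:
    """CT volume as a multi-page TIFF slice stack (float32)."""
    tifffile.imwrite(
        path,
        vol.gray.astype(np.float32),
        metadata={"voxel_size_um": vol.voxel_size_um, "description": vol.description},
    )


def read_volume(path: str | Path, voxel_size_um: float | None = None) -> Volume:
    gray = tifffile.imread(path).astype(float)
    if voxel_size_um is None:
        voxel_size_um = 1.0
        with tifffile.TiffFile(path) as tf:
            meta = tf.shaped_metadata or tf.imagej_metadata
            if meta:
                block = meta[0] if isinstance(meta, (list, tuple)) else meta
                voxel_size_um = float(block.get("voxel_size_um", 1.0))
    return Volume(gray=gray, voxel_size_um=voxel_size_um)


def write_element_map(path: str | Path, emap: ElementMap) -> None:
    """Single-page TIFF per element; element symbol stored in metadata."""
    tifffile.imwrite(
        path,
        emap.intensity.astype(np.float32),
        metadata={"element": emap.element, "pixel_size_um": emap.pixel_size_um},
    )


def read_element_map(path: str | Path, element: str | None = None) -> ElementMap:
    intensity = tifffile.imread(path).astype(float)
    pixel = 20.0
    if element is None:
        element = "?"
        with tifffile.TiffFile(path) as tf:
            meta = tf.shaped_metadata
            if meta:
                block = meta[0] if isinstance(meta, (list, tuple)) else meta
                element = str(block.get("element", "?"))
                pixel = float(block.get("pixel_size_um", 20.0))
    return ElementMap(element=element, intensity=intensity, pixel_size_um=pixel)


# ---------------------------------------------------------------------------
# Delimited curves
# ---------------------------------------------------------------------------


def write_curve(path: str | Path, curve: Curve1D) -> None:
    """2-3 column whitespace-delimited text: q, I[, sigma]."""
    if curve.sigma is not None:
        data = np.column_stack([curve.q, curve.intensity, curve.sigma])
        header = "q_invA intensity sigma"
    else:
        data = np.column_stack([curve.q, curve.intensity])
        header = "q_invA intensity"
    np.savetxt(path, data, header=header)


def read_curve(path: str | Path) -> Curve1D:
    data = np.loadtxt(path)
    if data.ndim != 2 or data.shape[1] not in (2, 3):
        raise ValueError("curve file must have 2 or 3 columns (q, I[, sigma])")
    sigma = data[:, 2] if data.shape[1] == 3 else None
    return Curve1D(q=data[:, 0], intensity=data[:, 1], sigma=sigma)
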