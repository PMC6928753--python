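"""File formats: PLY/PCD point clouds, spectral cubes (TIFF / ENVI), depth PNG,
channel stacks, and validated pipeline configuration.

Point clouds are serialized with coordinates in meters; per-point reflectance
travels as extra float properties named ``refl_<wavelength>`` (NaN encodes an
invalid entry), so clouds from external scanners without reflectance load fine.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile
import yaml
from pydantic import BaseModel, ConfigDict

from .cloud import MultispectralPointCloud
from .errors import Npk3dError
from .registration import ChannelStack, SpectralCube

__all__ = [
    "read_pointcloud",
    "write_pointcloud",
    "read_spectral_cube",
    "write_spectral_cube",
    "read_channel_stack",
    "write_channel_stack",
    "read_depth_png",
    "write_depth_png",
    "PipelineConfig",
    "load_config",
]


class PlyParseError(Npk3dError, ValueError):
    def __init__(self, msg: str, line: int | None = None):
        super().__init__(f"PLY parse error{f' at line {line}' if line else ''}: {msg}")


_PLY_TYPES = {
    "float": "<f4", "float32": "<f4", "double": "<f8", "float64": "<f8",
    "uchar": "u1", "uint8": "u1", "char": "i1", "int8": "i1",
    "short": "<i2", "int16": "<i2", "ushort": "<u2", "uint16": "<u2",
    "int": "<i4", "int32": "<i4", "uint": "<u4", "uint32": "<u4",
}


def _cloud_fields(cloud: MultispectralPointCloud):
    """(name, dtype token, column) triples for serialization."""
    fields = [("x", "float", cloud.coords[:, 0]),
              ("y", "float", cloud.coords[:, 1]),
              ("z", "float", cloud.coords[:, 2])]
    if cloud.rgb is not None:
        for k, name in enumerate(("red", "green", "blue")):
            fields.append((name, "uchar", np.clip(cloud.rgb[:, k], 0, 255)))
    if cloud.reflectance is not None:
        refl = np.where(cloud.refl_valid, cloud.reflectance, np.nan)
        for b, w in enumerate(cloud.wavelengths_nm):
            fields.append((f"refl_{w:g}", "float", refl[:, b]))
    if cloud.view_id is not None:
        fields.append(("view_id", "int", cloud.view_id))
    return fields


def write_pointcloud(path: str | Path, cloud: MultispectralPointCloud) -> None:
    """Write PLY (ascii) or PCD (ascii) depending on the file extension."""
    path = Path(path)
    if path.suffix.lower() == ".pcd":
        _write_pcd(path, cloud)
    else:
        _write_ply(path, cloud)


def _write_ply(path: Path, cloud: MultispectralPointCloud) -> None:
    fields = _cloud_fields(cloud)
    header = ["ply", "format ascii 1.0", "comment npk3d point cloud",
              f"element vertex {len(cloud)}"]
    header += [f"property {t} {n}" for n, t, _ in fields]
    header.append("end_header")
    cols = []
    for _, t, col in fields:
        if t == "uchar" or t == "int":
            cols.append(np.asarray(col).astype(int).astype(str))
        else:
            cols.append(np.char.mod("%.9g", np.asarray(col, dtype=float)))
    body = [" ".join(row) for row in zip(*cols)] if fields and len(cloud) else []
    path.write_text("\n".join(header + body) + "\n")


def _write_pcd(path: Path, cloud: MultispectralPointCloud) -> None:
    fields = _cloud_fields(cloud)
    names = [n for n, _, _ in fields]
    types = ["U" if t == "uchar" else ("I" if t == "int" else "F") for _, t, _ in fields]
    sizes = ["1" if t == "uchar" else "4" for _, t, _ in fields]
    n = len(cloud)
    header = (
        "# .PCD v0.7 - Point Cloud Data file format\nVERSION 0.7\n"
        f"FIELDS {' '.join(names)}\nSIZE {' '.join(sizes)}\n"
        f"TYPE {' '.join(types)}\nCOUNT {' '.join(['1'] * len(names))}\n"
        f"WIDTH {n}\nHEIGHT 1\nVIEWPOINT 0 0 0 1 0 0 0\nPOINTS {n}\nDATA ascii\n"
    )
    cols = []
    for _, t, col in fields:
        if t in ("uchar", "int"):
            cols.append(np.asarray(col).astype(int).astype(str))
        else:
            cols.append(np.char.mod("%.9g", np.asarray(col, dtype=float)))
    body = "\n".join(" ".join(row) for row in zip(*cols)) if n else ""
    path.write_text(header + body + ("\n" if body else ""))


def read_pointcloud(path: str | Path) -> MultispectralPointCloud:
    path = Path(path)
    if path.suffix.lower() == ".pcd":
        return _read_pcd(path)
    return _read_ply(path)


def _assemble_cloud(names: list[str], columns: dict[str, np.ndarray]) -> MultispectralPointCloud:
    for req in ("x", "y", "z"):
        if req not in columns:
            raise PlyParseError(f"missing coordinate property '{req}'")
    n = len(columns["x"])
    if n == 0:
        return MultispectralPointCloud(coords=np.empty((0, 3)))
    coords = np.column_stack([columns["x"], columns["y"], columns["z"]])
    rgb = None
    if all(c in columns for c in ("red", "green", "blue")):
        rgb = np.column_stack([columns["red"], columns["green"], columns["blue"]])
    refl_names = [nm for nm in names if nm.startswith("refl_")]
    reflectance = wavelengths = refl_valid = None
    if refl_names:
        wavelengths = np.array([float(nm[5:]) for nm in refl_names])
        order = np.argsort(wavelengths)
        wavelengths = wavelengths[order]
        reflectance = np.column_stack([columns[refl_names[k]] for k in order])
        refl_valid = np.isfinite(reflectance)
        reflectance = np.nan_to_num(reflectance)
    view_id = columns.get("view_id")
    return MultispectralPointCloud(
        coords=coords, rgb=rgb, reflectance=reflectance, refl_valid=refl_valid,
        wavelengths_nm=wavelengths, view_id=view_id,
    )


def _read_ply(path: Path) -> MultispectralPointCloud:
    raw = path.read_bytes()
    try:
        end = raw.index(b"end_header")
    except ValueError:
        raise PlyParseError("no end_header found", line=1)
    header_bytes = raw[: raw.index(b"\n", end) + 1]
    lines = header_bytes.decode("ascii", errors="replace").splitlines()
    if not lines or lines[0].strip() != "ply":
        raise PlyParseError("missing 'ply' magic", line=1)
    fmt, n_vertex, props = None, None, []
    for ln, line in enumerate(lines[1:], start=2):
        parts = line.split()
        if not parts or parts[0] == "comment":
            continue
        if parts[0] == "format":
            fmt = parts[1]
        elif parts[0] == "element":
            if parts[1] == "vertex":
                try:
                    n_vertex = int(parts[2])
                except (IndexError, ValueError):
                    raise PlyParseError("bad vertex count", line=ln)
            elif n_vertex is not None and props:
                raise PlyParseError(f"unsupported element '{parts[1]}' after vertex", line=ln)
        elif parts[0] == "property":
            if parts[1] == "list":
                raise PlyParseError("list properties not supported", line=ln)
            if parts[1] not in _PLY_TYPES:
                raise PlyParseError(f"unknown property type '{parts[1]}'", line=ln)
            if n_vertex is not None:
                props.append((parts[2], _PLY_TYPES[parts[1]]))
    if fmt is None or n_vertex is None:
        raise PlyParseError("header lacks format or vertex element", line=len(lines))
    names = [n for n, _ in props]
    body = raw[len(header_bytes):]
    if fmt == "ascii":
        text_rows = body.decode("ascii").split()
        data = np.array(text_rows, dtype=float) if text_rows else np.empty(0)
        if n_vertex and data.size != n_vertex * len(props):
            raise PlyParseError(
                f"expected {n_vertex * len(props)} values, found {data.size}")
        data = data.reshape(n_vertex, len(props)) if n_vertex else np.empty((0, len(props)))
        columns = {nm: data[:, k] for k, (nm, _) in enumerate(props)}
    elif fmt == "binary_little_endian":
        dtype = np.dtype([(nm, dt) for nm, dt in props])
        rec = np.frombuffer(body[: dtype.itemsize * n_vertex], dtype=dtype)
        if len(rec) != n_vertex:
            raise PlyParseError(f"binary body truncated ({len(rec)}/{n_vertex} vertices)")
        columns = {nm: rec[nm].astype(float) for nm, _ in props}
    else:
        raise PlyParseError(f"unsupported format '{fmt}'")
    return _assemble_cloud(names, columns)


def _read_pcd(path: Path) -> MultispectralPointCloud:
    lines = path.read_text().splitlines()
    meta, body_start = {}, 0
    for k, line in enumerate(lines):
        parts = line.split()
        if not parts or parts[0].startswith("#"):
            continue
        meta[parts[0]] = parts[1:]
        if parts[0] == "DATA":
            body_start = k + 1
            break
    if meta.get("DATA", [""])[0] != "ascii":
        raise PlyParseError("only ascii PCD supported")
    names = meta["FIELDS"]
    n = int(meta["POINTS"][0])
    vals = np.array(" ".join(lines[body_start:]).split(), dtype=float)
    vals = vals.reshape(n, len(names)) if n else np.empty((0, len(names)))
    return _assemble_cloud(names, {nm: vals[:, k] for k, nm in enumerate(names)})


# ---------------------------------------------------------------------------
# spectral cubes and channel stacks

def write_spectral_cube(path: str | Path, cube: SpectralCube, interleave: str = "tiff") -> None:
    """Multi-page TIFF + JSON sidecar, or ENVI header + raw (bsq / bil).

    Invalid pixels are stored as NaN, which round-trips into the cube mask.
    """
    path = Path(path)
    bands = np.where(cube.mask, cube.bands, np.nan).astype(np.float32)
    if interleave == "tiff":
        tifffile.imwrite(path, bands)
        sidecar = {"wavelengths_nm": cube.wavelengths_nm.tolist()}
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))
        return
    if interleave not in ("bsq", "bil"):
        raise ValueError("interleave must be 'tiff', 'bsq' or 'bil'")
    b, h, w = bands.shape
    raw = bands if interleave == "bsq" else np.ascontiguousarray(np.moveaxis(bands, 0, 1))
    raw.tofile(path)
    hdr = (
        "ENVI\ndescription = {npk3d spectral cube}\n"
        f"samples = {w}\nlines = {h}\nbands = {b}\n"
        "header offset = 0\nfile type = ENVI Standard\ndata type = 4\n"
        f"interleave = {interleave}\nbyte order = 0\n"
        "wavelength units = nm\n"
        "wavelength = {" + ", ".join(f"{v:g}" for v in cube.wavelengths_nm) + "}\n"
    )
    path.with_suffix(".hdr").write_text(hdr)


def read_spectral_cube(path: str | Path) -> SpectralCube:
    path = Path(path)
    hdr = path.with_suffix(".hdr")
    if path.suffix.lower() in (".tif", ".tiff"):
        sidecar = path.with_suffix(path.suffix + ".json")
        if not sidecar.exists():
            raise FileNotFoundError(f"missing wavelength sidecar {sidecar}")
        meta = json.loads(sidecar.read_text())
        bands = tifffile.imread(path).astype(float)
        if bands.ndim == 2:
            bands = bands[None]
        wl = np.asarray(meta["wavelengths_nm"], float)
    elif hdr.exists():
        meta = _parse_envi_header(hdr)
        b, h, w = meta["bands"], meta["lines"], meta["samples"]
        raw = np.fromfile(path, dtype="<f4")
        if raw.size != b * h * w:
            raise ValueError(f"ENVI raw size {raw.size} != bands*lines*samples")
        if meta["interleave"] == "bsq":
            bands = raw.reshape(b, h, w).astype(float)
        elif meta["interleave"] == "bil":
            bands = np.moveaxis(raw.reshape(h, b, w), 1, 0).astype(float)
        else:
            raise ValueError(f"unsupported interleave {meta['interleave']}")
        wl = np.asarray(meta["wavelength"], float)
    else:
        raise FileNotFoundError(f"no readable cube at {path} (need TIFF+sidecar or ENVI hdr)")
    if wl.size != bands.shape[0]:
        raise ValueError(f"{bands.shape[0]} bands but {wl.size} wavelengths in metadata")
    mask = np.all(np.isfinite(bands), axis=0)
    return SpectralCube(bands=np.nan_to_num(bands), wavelengths_nm=wl, mask=mask)


def _parse_envi_header(hdr: Path) -> dict:
    text = hdr.read_text()
    meta = {}
    import re

    for key in ("samples", "lines", "bands"):
        m = re.search(rf"{key}\s*=\s*(\d+)", text)
        if not m:
            raise ValueError(f"ENVI header missing '{key}'")
        meta[key] = int(m.group(1))
    m = re.search(r"interleave\s*=\s*(\w+)", text)
    meta["interleave"] = m.group(1).lower() if m else "bsq"
    m = re.search(r"wavelength\s*=\s*\{([^}]*)\}", text, re.S)
    if not m:
        raise ValueError("ENVI header missing wavelength list")
    meta["wavelength"] = [float(v) for v in m.group(1).replace("\n", " ").split(",")]
    return meta


def write_channel_stack(path: str | Path, stack: ChannelStack) -> None:
    """Channel stack as multi-page TIFF (one page per channel, plus a validity
    page when a spectral mask exists) with a JSON sidecar of channel metadata."""
    path = Path(path)
    pages = np.moveaxis(stack.data.astype(np.float32), -1, 0)
    if stack.spectral_mask is not None:
        pages = np.concatenate([pages, stack.spectral_mask[None].astype(np.float32)])
    tifffile.imwrite(path, pages)
    sidecar = {
        "channel_names": stack.channel_names,
        "wavelengths_nm": None if stack.wavelengths_nm is None else stack.wavelengths_nm.tolist(),
        "has_mask": stack.spectral_mask is not None,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def read_channel_stack(path: str | Path) -> ChannelStack:
    path = Path(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    if not sidecar.exists():
        raise FileNotFoundError(f"missing channel metadata sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    pages = tifffile.imread(path).astype(np.float32)
    if pages.ndim == 2:
        pages = pages[None]
    mask = None
    if meta.get("has_mask"):
        mask = pages[-1] > 0.5
        pages = pages[:-1]
    wl = meta.get("wavelengths_nm")
    return ChannelStack(
        data=np.moveaxis(pages, 0, -1),
        channel_names=list(meta["channel_names"]),
        wavelengths_nm=None if wl is None else np.asarray(wl, float),
        spectral_mask=mask,
    )


def write_depth_png(path: str | Path, depth_mm: np.ndarray) -> None:
    """16-bit PNG, millimeters."""
    iio.imwrite(Path(path), np.round(depth_mm).astype(np.uint16))


def read_depth_png(path: str | Path) -> np.ndarray:
    return iio.imread(Path(path)).astype(float)


# ---------------------------------------------------------------------------
# configuration

class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class IntrinsicsConfig(_Strict):
    cx: float = 256.0
    cy: float = 212.0
    fx: float = 365.0
    fy: float = 365.0


class IcpConfig(_Strict):
    max_iter: int = 50
    tol: float = 1e-6
    max_corr_dist: float = 0.01
    voxel_size: float | None = None


class RegistrationConfig(_Strict):
    subpixel: bool = False
    angular_bins: int = 720
    radial_bins: int = 400


class WavelengthConfig(_Strict):
    smoothing_window: int = 6
    interference_bands_nm: list[float] = [841.42, 846.85, 852.30, 857.74, 863.19, 868.65]
    n_components: int = 8
    rf_iterations: int = 1000
    rf_subset_size: int = 8
    adjacency_r_threshold: float = 0.9
    min_abs_corr: float = 0.2


class ModelConfig(_Strict):
    hidden_nodes: int = 15
    max_iter: int = 500
    kernel_scale: float = 0.56
    n_calib: int = 42


class PipelineConfig(_Strict):
    """Top-level validated configuration; unknown keys are rejected."""

    seed: int = 0
    verbosity: int = 1
    calibration_path: str | None = None
    roi_m: list[list[float]] | None = None
    intrinsics: IntrinsicsConfig = IntrinsicsConfig()
    icp: IcpConfig = IcpConfig()
    registration: RegistrationConfig = RegistrationConfig()
    wavelengths: WavelengthConfig = WavelengthConfig()
    models: ModelConfig = ModelConfig()


def load_config(path: str | Path | None = None, **overrides) -> PipelineConfig:
    """Load YAML configuration; keyword overrides win over file values."""
    data = {}
    if path is not None:
        data = yaml.safe_load(Path(path).read_text()) or {}
    data.update({k: v for k, v in overrides.items() if v is not None})
    return PipelineConfig(**data)
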