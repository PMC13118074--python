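"""File formats: ENVI-style cubes, multi-page TIFF, label PNGs, bundles.

Cubes are written either as band-sequential ENVI pairs (a text ``.hdr``
plus a float32 ``.raw``) or as multi-page TIFF with one band per page.
Label and decision maps are single-channel PNGs with values {0, 1, 2}.
Ground-truth and model bundles are directories holding the arrays plus a
YAML manifest describing them.
"""

from __future__ import annotations

import pickle
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile
import yaml

from .phantom import PhantomConfig, PhantomTruth
from .spectra import ReflectanceCube, SpectralCube, SpectralGrid

__all__ = [
    "write_envi", "read_envi", "write_tiff_cube", "read_tiff_cube",
    "write_label_png", "read_label_png",
    "write_truth_bundle", "read_truth_bundle",
    "save_model_bundle", "load_model_bundle",
]


# ---------------------------------------------------------------------------
# ENVI band-sequential cubes
# ---------------------------------------------------------------------------

def write_envi(path: str | Path, cube: SpectralCube) -> Path:
    """Write header + raw float32 BSQ pair; returns the header path."""
    path = Path(path)
    hdr = path.with_suffix(".hdr")
    raw = path.with_suffix(".raw")
    H, W, B = cube.data.shape
    wl = ", ".join(f"{w:g}" for w in cube.grid.wavelengths)
    hdr.write_text(
        "ENVI\n"
        f"samples = {W}\n"
        f"lines = {H}\n"
        f"bands = {B}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        "data type = 4\n"
        "interleave = bsq\n"
        "byte order = 0\n"
        "wavelength units = Nanometers\n"
        f"wavelength = {{ {wl} }}\n"
    )
    np.ascontiguousarray(
        cube.data.transpose(2, 0, 1).astype("<f4")).tofile(raw)
    return hdr


def read_envi(path: str | Path) -> SpectralCube:
    """Read a cube written by :func:`write_envi`."""
    path = Path(path)
    hdr = path.with_suffix(".hdr")
    fields: dict[str, str] = {}
    text = hdr.read_text()
    # fold the brace-wrapped wavelength list onto one logical line
    text = text.replace("{", "{ ").replace("}", " }")
    for line in text.splitlines():
        if "=" in line:
            key, _, value = line.partition("=")
            fields[key.strip().lower()] = value.strip()
    H = int(fields["lines"])
    W = int(fields["samples"])
    B = int(fields["bands"])
    if fields.get("interleave", "bsq").lower() != "bsq":
        raise ValueError("only BSQ interleave is supported")
    if int(fields.get("data type", 4)) != 4:
        raise ValueError("only float32 (data type 4) is supported")
    wl = np.array([float(tok) for tok in
                   fields["wavelength"].strip("{} ").split(",")])
    data = np.fromfile(path.with_suffix(".raw"), dtype="<f4",
                       count=H * W * B).reshape(B, H, W).transpose(1, 2, 0)
    return SpectralCube(np.ascontiguousarray(data), SpectralGrid(wl))


# ---------------------------------------------------------------------------
# TIFF and PNG
# ---------------------------------------------------------------------------

def write_tiff_cube(path: str | Path, cube: SpectralCube) -> Path:
    """Multi-page TIFF, one band per page; wavelengths in the description."""
    path = Path(path)
    wl = ",".join(f"{w:g}" for w in cube.grid.wavelengths)
    tifffile.imwrite(path, cube.data.transpose(2, 0, 1).astype(np.float32),
                     photometric="minisblack",
                     description=f"wavelengths_nm={wl}")
    return path


def read_tiff_cube(path: str | Path) -> SpectralCube:
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        desc = tf.pages[0].description or ""
    if not desc.startswith("wavelengths_nm="):
        raise ValueError("TIFF lacks the wavelength description tag")
    wl = np.array([float(tok) for tok in
                   desc.removeprefix("wavelengths_nm=").split(",")])
    return SpectralCube(data.transpose(1, 2, 0), SpectralGrid(wl))


def write_label_png(path: str | Path, labels: np.ndarray) -> Path:
    path = Path(path)
    arr = np.asarray(getattr(labels, "values", labels))
    if arr.max(initial=0) > 2:
        raise ValueError("label maps hold values {0, 1, 2}")
    iio.imwrite(path, arr.astype(np.uint8))
    return path


def read_label_png(path: str | Path) -> np.ndarray:
    return np.asarray(iio.imread(path)).astype(np.uint8)


# ---------------------------------------------------------------------------
# bundles
# ---------------------------------------------------------------------------

def write_truth_bundle(directory: str | Path, truth: PhantomTruth) -> Path:
    """Directory bundle: manifest, labels PNG, component cubes/maps."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_label_png(directory / "labels.png", truth.labels)
    write_envi(directory / "r_vol", SpectralCube(truth.r_vol, truth.grid))
    tifffile.imwrite(directory / "eps.tif", truth.eps.astype(np.float32),
                     photometric="minisblack")
    tifffile.imwrite(directory / "shading.tif", truth.shading.astype(np.float32),
                     photometric="minisblack")
    np.savetxt(directory / "r_surf.csv",
               np.column_stack([truth.grid.wavelengths, truth.r_surf]),
               delimiter=",", header="wavelength_nm,r_surf", comments="")
    manifest = {
        "kind": "phantom_truth",
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in vars(truth.config).items()},
        "files": {"labels": "labels.png", "r_vol": "r_vol.hdr",
                  "r_surf": "r_surf.csv", "eps": "eps.tif",
                  "shading": "shading.tif"},
        "fruit_centers": truth.fruit_centers.tolist(),
    }
    (directory / "manifest.yaml").write_text(yaml.safe_dump(manifest))
    return directory


def read_truth_bundle(directory: str | Path) -> PhantomTruth:
    directory = Path(directory)
    manifest = yaml.safe_load((directory / "manifest.yaml").read_text())
    cfg_dict = dict(manifest["config"])
    if cfg_dict.get("defect_radius_range") is not None:
        cfg_dict["defect_radius_range"] = tuple(cfg_dict["defect_radius_range"])
    config = PhantomConfig(**cfg_dict)
    labels = read_label_png(directory / "labels.png")
    r_vol_cube = read_envi(directory / "r_vol")
    r_surf = np.loadtxt(directory / "r_surf.csv", delimiter=",",
                        skiprows=1)[:, 1]
    eps = tifffile.imread(directory / "eps.tif")
    shading = tifffile.imread(directory / "shading.tif")
    # fruit ids are re-derived from labels + centers
    centers = np.asarray(manifest.get("fruit_centers", []), dtype=float)
    H, W = labels.shape
    fruit_id = np.full((H, W), -1, dtype=np.int32)
    if centers.size:
        yy, xx = np.mgrid[0:H, 0:W]
        d2 = ((yy[None] - centers[:, 0, None, None]) ** 2
              + (xx[None] - centers[:, 1, None, None]) ** 2)
        nearest = d2.argmin(axis=0)
        fruit_id[labels != 0] = nearest[labels != 0]
    return PhantomTruth(config=config, grid=r_vol_cube.grid, labels=labels,
                        fruit_id=fruit_id, r_vol=r_vol_cube.data,
                        r_surf=r_surf, eps=eps, shading=shading,
                        fruit_centers=centers.reshape(-1, 2))


def save_model_bundle(directory: str | Path, model, extra: dict | None = None) -> Path:
    """Serialize a fitted classifier with a YAML manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {
        "kind": "classifier",
        "class": type(model).__name__,
        "params": model.get_params(),
        "metadata": extra or {},
    }
    for attr in ("oob_error_", "kernel_scale_", "n_train_used_",
                 "final_loss_", "n_parameters_", "converged_"):
        if hasattr(model, attr):
            manifest["metadata"][attr.rstrip("_")] = _plain(getattr(model, attr))
    (directory / "manifest.yaml").write_text(yaml.safe_dump(manifest))
    with open(directory / "model.pkl", "wb") as fh:
        pickle.dump(model, fh)
    return directory


def _plain(value):
    if isinstance(value, (np.floating, np.integer)):
        return value.item()
    return value


def load_model_bundle(directory: str | Path):
    with open(Path(directory) / "model.pkl", "rb") as fh:
        return pickle.load(fh)


def write_reflectance(path: str | Path, cube: ReflectanceCube) -> Path:
    """ENVI pair plus a sidecar recording the recovery mode."""
    hdr = write_envi(path, cube)
    Path(path).with_suffix(".mode.yaml").write_text(
        yaml.safe_dump({"mode": cube.mode}))
    return hdr


def read_reflectance(path: str | Path) -> ReflectanceCube:
    cube = read_envi(path)
    sidecar = Path(path).with_suffix(".mode.yaml")
    mode = "local"
    if sidecar.exists():
        mode = yaml.safe_load(sidecar.read_text())["mode"]
    return ReflectanceCube(cube.data, cube.grid, mode=mode)
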