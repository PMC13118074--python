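"""Synthetic multi-angle hyperspectral scenes with known ground truth.

The phantom emulates the statistical structure of a multi-lamp fruit
imaging session: sphere-like fruits with a smooth tissue reflectance rising
toward the red/NIR (tomato-like), darkened and spectrally flattened defect
patches, a low-amplitude specular spectrum with per-lamp localized glare
lobes, Lambertian shading from a fixed 45-degree lamp zenith, a
halogen-shaped reference spectrum and signal-proportional detector noise.

Every random draw is fixed by ``PhantomConfig.seed``, so scenes are
bit-reproducible and every pixel carries a known volume reflectance,
specular amplitude and class label.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .spectra import IlluminationSet, SpectralCube, SpectralGrid, default_grid

__all__ = [
    "PhantomConfig",
    "PhantomTruth",
    "make_phantom_scene",
    "render_illumination_set",
    "halogen_spectrum",
    "healthy_spectrum",
    "defect_spectrum",
]

BACKGROUND, HEALTHY, DEFECT = 0, 1, 2


@dataclass(frozen=True)
class PhantomConfig:
    """Scene layout, optics and noise settings for one phantom frame."""

    height: int = 240
    width: int = 240
    n_fruits: int = 4
    fruit_radius: float = 40.0
    defect_fruit_fraction: float = 0.5
    defects_per_fruit: int = 1
    defect_radius_range: tuple[float, float] | None = None
    n_lamps: int = 3
    lamp_zenith_deg: float = 45.0
    lobe_amplitude: float = 1.0
    lobe_core_frac: float = 0.18         # flat-top (saturated glint) radius
    lobe_width_frac: float = 0.10        # Gaussian falloff beyond the core
    lobe_offset_frac: float = 0.45
    lobe_floor: float = 0.05
    noise_sd: float = 0.01
    shading: str = "lambertian"
    shading_floor: float = 0.25
    background_reflectance: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height <= 0 or self.width <= 0:
            raise ValueError("frame size must be positive")
        if self.n_fruits < 0 or self.fruit_radius <= 0:
            raise ValueError("fruit count/radius must be positive")
        if not 0.0 <= self.defect_fruit_fraction <= 1.0:
            raise ValueError("defect_fruit_fraction must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.shading not in ("lambertian", "none"):
            raise ValueError("shading must be 'lambertian' or 'none'")
        rng = self.resolved_defect_radius_range()
        if rng[1] >= self.fruit_radius:
            raise ValueError("defect radius must be smaller than fruit radius")

    def resolved_defect_radius_range(self) -> tuple[float, float]:
        if self.defect_radius_range is not None:
            lo, hi = self.defect_radius_range
        else:
            lo, hi = 0.25 * self.fruit_radius, 0.45 * self.fruit_radius
        if not 0 < lo <= hi:
            raise ValueError("invalid defect radius range")
        return float(lo), float(hi)


@dataclass
class PhantomTruth:
    """Ground truth for one phantom scene.

    ``labels`` holds {0 background, 1 healthy, 2 defect}; ``fruit_id`` maps
    each fruit pixel to its fruit index (-1 on background).  ``eps`` and
    ``shading`` are stacked per-lamp maps of shape (n_lamps, H, W).
    """

    config: PhantomConfig
    grid: SpectralGrid
    labels: np.ndarray
    fruit_id: np.ndarray
    r_vol: np.ndarray            # (H, W, B) in [0, 1]
    r_surf: np.ndarray           # (B,) in [0, 0.1]
    eps: np.ndarray              # (n_lamps, H, W) in [0, 1]
    shading: np.ndarray          # (n_lamps, H, W) in (0, 1]
    fruit_centers: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))

    @property
    def fruit_mask(self) -> np.ndarray:
        return self.labels != BACKGROUND


def healthy_spectrum(wavelengths: np.ndarray) -> np.ndarray:
    """Smooth tomato-like tissue curve: dark blue/green, red-edge rise."""
    wl = np.asarray(wavelengths, dtype=float)
    base = 0.05 + 0.35 / (1.0 + np.exp(-(wl - 585.0) / 20.0))
    bump = 0.03 * np.exp(-(((wl - 550.0) / 30.0) ** 2))
    return base + bump


def defect_spectrum(wavelengths: np.ndarray) -> np.ndarray:
    """Darkened, spectrally flattened tissue (bruise / developing rot)."""
    h = healthy_spectrum(wavelengths)
    return 0.12 + 0.35 * (h - h.mean())


def halogen_spectrum(grid: SpectralGrid, temperature_k: float = 3000.0) -> np.ndarray:
    """Relative halogen lamp spectrum (Planck shape, peak-normalized)."""
    wl_m = grid.wavelengths * 1e-9
    h, c, kb = 6.626e-34, 2.998e8, 1.381e-23
    radiance = (2 * h * c**2 / wl_m**5) / np.expm1(h * c / (wl_m * kb * temperature_k))
    return radiance / radiance.max()


def _smooth_field(shape: tuple[int, int], rng: np.random.Generator,
                  scale_px: float, amplitude: float) -> np.ndarray:
    """Smooth multiplicative field 1 +- amplitude (within-class variation)."""
    noise = rng.standard_normal(shape)
    smooth = ndimage.gaussian_filter(noise, sigma=scale_px)
    span = np.abs(smooth).max()
    if span < 1e-12:
        return np.ones(shape)
    return 1.0 + amplitude * smooth / span


def _place_fruits(config: PhantomConfig, rng: np.random.Generator) -> np.ndarray:
    """Deterministic jittered grid layout; fruits never touch the border."""
    n, r = config.n_fruits, config.fruit_radius
    margin = r + 2
    if 2 * margin >= min(config.height, config.width) and n > 0:
        raise ValueError("fruit radius too large for the frame")
    ncols = int(np.ceil(np.sqrt(n * config.width / max(config.height, 1))))
    ncols = max(1, min(n, ncols))
    nrows = int(np.ceil(n / ncols))
    ys = np.linspace(margin, config.height - margin, nrows)
    xs = np.linspace(margin, config.width - margin, ncols)
    spacing = min(xs[1] - xs[0] if ncols > 1 else np.inf,
                  ys[1] - ys[0] if nrows > 1 else np.inf)
    if spacing < 2 * r + 2:
        raise ValueError("fruits do not fit the frame without overlap")
    centers = []
    jitter = max(0.0, min(spacing, 4 * r) / 2 - r) * 0.8
    for k in range(n):
        cy = ys[k // ncols] + rng.uniform(-jitter, jitter)
        cx = xs[k % ncols] + rng.uniform(-jitter, jitter)
        centers.append((np.clip(cy, margin, config.height - margin),
                        np.clip(cx, margin, config.width - margin)))
    return np.asarray(centers, dtype=float).reshape(n, 2)


def make_phantom_scene(config: PhantomConfig,
                       grid: SpectralGrid | None = None) -> PhantomTruth:
    """Generate labels, true reflectance components and per-lamp fields.

    Half of the fruits (rounded) carry defect patches by default; the rest
    are healthy.  Deterministic given ``config.seed``.
    """
    grid = grid or default_grid()
    rng = np.random.default_rng(config.seed)
    H, W = config.height, config.width
    yy, xx = np.mgrid[0:H, 0:W].astype(float)

    labels = np.zeros((H, W), dtype=np.uint8)
    fruit_id = np.full((H, W), -1, dtype=np.int32)
    centers = _place_fruits(config, rng)

    n_defective = int(round(config.n_fruits * config.defect_fruit_fraction))
    defective = np.zeros(config.n_fruits, dtype=bool)
    if n_defective:
        defective[rng.choice(config.n_fruits, size=n_defective, replace=False)] = True

    lo, hi = config.resolved_defect_radius_range()
    r = config.fruit_radius
    dist2_stack = []
    for k, (cy, cx) in enumerate(centers):
        d2 = (yy - cy) ** 2 + (xx - cx) ** 2
        dist2_stack.append(d2)
        inside = d2 <= r * r
        labels[inside] = HEALTHY
        fruit_id[inside] = k
    for k, (cy, cx) in enumerate(centers):
        if not defective[k]:
            continue
        for _ in range(config.defects_per_fruit):
            dr = rng.uniform(lo, hi)
            # keep the defect patch fully inside the fruit disk
            rho = rng.uniform(0.0, max(r - dr - 1, 0.0))
            theta = rng.uniform(0.0, 2 * np.pi)
            dy, dx = cy + rho * np.sin(theta), cx + rho * np.cos(theta)
            patch = (yy - dy) ** 2 + (xx - dx) ** 2 <= dr * dr
            labels[patch & (fruit_id == k)] = DEFECT

    # --- spectral ground truth -------------------------------------------
    wl = grid.wavelengths
    h_spec = healthy_spectrum(wl).astype(np.float32)
    d_spec = defect_spectrum(wl).astype(np.float32)
    amp = _smooth_field((H, W), rng, scale_px=max(4.0, r / 4), amplitude=0.08)
    r_vol = np.empty((H, W, grid.band_count), dtype=np.float32)
    r_vol[...] = config.background_reflectance
    r_vol[labels == HEALTHY] = h_spec[None, :]
    r_vol[labels == DEFECT] = d_spec[None, :]
    fruit = labels != BACKGROUND
    r_vol[fruit] *= amp[fruit, None].astype(np.float32)
    np.clip(r_vol, 0.0, 1.0, out=r_vol)

    # glints on glossy skin sit near the model's specular ceiling
    r_surf = (0.07 + 0.02 * (wl - wl[0]) / max(wl[-1] - wl[0], 1.0)).astype(np.float32)
    np.clip(r_surf, 0.0, 0.1, out=r_surf)

    # --- per-lamp glare lobes and shading --------------------------------
    azimuths = np.deg2rad(np.arange(config.n_lamps) * 360.0 / max(config.n_lamps, 1))
    eps = np.zeros((config.n_lamps, H, W), dtype=np.float32)
    rho = config.lobe_core_frac * r
    sigma = config.lobe_width_frac * r
    for i, az in enumerate(azimuths):
        for k, (cy, cx) in enumerate(centers):
            ly = cy + config.lobe_offset_frac * r * np.sin(az)
            lx = cx + config.lobe_offset_frac * r * np.cos(az)
            d = np.sqrt((yy - ly) ** 2 + (xx - lx) ** 2)
            # saturated flat-top glint with a Gaussian rim
            lobe = config.lobe_amplitude * np.exp(
                -np.maximum(d - rho, 0.0) ** 2 / (2 * sigma**2))
            lobe[lobe < config.lobe_floor] = 0.0     # localized, hard edge
            lobe[fruit_id != k] = 0.0                # glare only on the fruit
            eps[i] = np.maximum(eps[i], lobe.astype(np.float32))

    shading = np.ones((config.n_lamps, H, W), dtype=np.float32)
    if config.shading == "lambertian":
        zen = np.deg2rad(config.lamp_zenith_deg)
        for i, az in enumerate(azimuths):
            lamp_dir = np.array([np.sin(zen) * np.sin(az),
                                 np.sin(zen) * np.cos(az),
                                 np.cos(zen)])
            for k, (cy, cx) in enumerate(centers):
                on = fruit_id == k
                d2 = dist2_stack[k][on]
                z = np.sqrt(np.maximum(r * r - d2, 0.0))
                ny, nx = (yy[on] - cy) / r, (xx[on] - cx) / r
                cosang = ny * lamp_dir[0] + nx * lamp_dir[1] + (z / r) * lamp_dir[2]
                shading[i][on] = np.clip(cosang, config.shading_floor, 1.0)

    return PhantomTruth(config=config, grid=grid, labels=labels,
                        fruit_id=fruit_id, r_vol=r_vol, r_surf=r_surf,
                        eps=eps, shading=shading, fruit_centers=centers)


def render_illumination_set(truth: PhantomTruth,
                            grid: SpectralGrid | None = None,
                            lamp_spectrum: np.ndarray | None = None,
                            noise_sd: float | None = None,
                            seed: int | None = None) -> IlluminationSet:
    """Forward-render object and reference cubes for every lamp.

    The reference cube is the lamp spectrum over a unit-reflectance white
    plate filling the frame.  The object cube follows the additive
    diffuse + specular model with per-lamp shading, plus multiplicative
    (signal-proportional) Gaussian noise clipped at zero.
    """
    grid = grid or truth.grid
    if grid.band_count != truth.grid.band_count:
        raise ValueError("grid inconsistent with truth")
    if lamp_spectrum is None:
        lamp_spectrum = halogen_spectrum(grid)
    lamp_spectrum = np.asarray(lamp_spectrum, dtype=np.float32)
    if lamp_spectrum.shape != (grid.band_count,):
        raise ValueError("lamp_spectrum must have one weight per band")
    if np.any(lamp_spectrum <= 0):
        raise ValueError("lamp_spectrum must be strictly positive")
    if noise_sd is None:
        noise_sd = truth.config.noise_sd
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    rng = np.random.default_rng(
        seed if seed is not None else truth.config.seed + 7_919)

    H, W = truth.labels.shape
    obj_cubes, ref_cubes = [], []
    ref_data = np.broadcast_to(lamp_spectrum, (H, W, grid.band_count))
    for i in range(truth.config.n_lamps):
        refl = (truth.shading[i][:, :, None] * truth.r_vol
                + truth.eps[i][:, :, None] * truth.r_surf[None, None, :])
        signal = lamp_spectrum[None, None, :] * refl
        if noise_sd > 0:
            signal = signal * (1.0 + noise_sd * rng.standard_normal(signal.shape,
                                                                    dtype=np.float32))
            np.clip(signal, 0.0, None, out=signal)
        obj_cubes.append(SpectralCube(signal.astype(np.float32), grid))
        ref_cubes.append(SpectralCube(np.ascontiguousarray(ref_data), grid))
    return IlluminationSet(obj=obj_cubes, ref=ref_cubes, grid=grid)


def replicate_config(config: PhantomConfig, seed: int) -> PhantomConfig:
    """Same scene statistics, fresh randomness (independent replicate)."""
    return replace(config, seed=seed)
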