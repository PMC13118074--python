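"""Spectral grids and hyperspectral cube containers.

A hyperspectral cube is a stack of co-registered images ``I(x, y, lambda)``
stored as a ``(H, W, B)`` array together with the band-center grid.  The
default grid covers 450-850 nm at 5 nm steps (81 bands), the working range
of a visible/NIR acousto-optic imager.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SpectralGrid",
    "SpectralCube",
    "ReflectanceCube",
    "IlluminationSet",
    "default_grid",
]


@dataclass(frozen=True)
class SpectralGrid:
    """Ordered band centers in nanometres."""

    wavelengths: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        if wl.ndim != 1 or wl.size == 0:
            raise ValueError("wavelengths must be a non-empty 1-D sequence")
        if not np.all(np.diff(wl) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        object.__setattr__(self, "wavelengths", wl)

    @property
    def band_count(self) -> int:
        return int(self.wavelengths.size)

    def index_of(self, band_nm: float) -> int:
        """Index of the band closest to ``band_nm`` (must lie on the grid)."""
        idx = int(np.argmin(np.abs(self.wavelengths - band_nm)))
        if abs(self.wavelengths[idx] - band_nm) > 1e-6:
            raise ValueError(f"{band_nm} nm is not on the spectral grid")
        return idx

    def __len__(self) -> int:  # pragma: no cover - convenience
        return self.band_count


def default_grid() -> SpectralGrid:
    """450-850 nm inclusive at 5 nm steps: 81 bands."""
    return SpectralGrid(np.arange(450.0, 850.0 + 2.5, 5.0))


@dataclass
class SpectralCube:
    """Raw digital-number image stack ``I(x, y, lambda)``, shape (H, W, B)."""

    data: np.ndarray
    grid: SpectralGrid

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("cube data must be 3-D (H, W, B)")
        if self.data.shape[2] != self.grid.band_count:
            raise ValueError(
                f"cube has {self.data.shape[2]} bands, grid has "
                f"{self.grid.band_count}"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def band(self, band_nm: float) -> np.ndarray:
        """The (H, W) image at the given band center."""
        return self.data[:, :, self.grid.index_of(band_nm)]


REFLECTANCE_MODES = ("local", "simultaneous", "sequential")


@dataclass
class ReflectanceCube(SpectralCube):
    """Unitless reflectance with a recovery-mode tag.

    ``invalid`` marks pixels where the reference signal was not positive;
    they are excluded from downstream masks and classification.
    """

    mode: str = "local"
    invalid: np.ndarray | None = None

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.mode not in REFLECTANCE_MODES:
            raise ValueError(f"mode must be one of {REFLECTANCE_MODES}")
        if self.invalid is None:
            self.invalid = np.zeros(self.data.shape[:2], dtype=bool)
        else:
            self.invalid = np.asarray(self.invalid, dtype=bool)
            if self.invalid.shape != self.data.shape[:2]:
                raise ValueError("invalid mask shape must match frame shape")


@dataclass
class IlluminationSet:
    """Per-angle object and reference cubes for three lamp positions."""

    obj: list[SpectralCube]
    ref: list[SpectralCube]
    grid: SpectralGrid = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if len(self.obj) != len(self.ref):
            raise ValueError("need one reference cube per object cube")
        if not self.obj:
            raise ValueError("empty illumination set")
        if self.grid is None:
            self.grid = self.obj[0].grid
        shapes = {c.shape for c in self.obj} | {c.shape for c in self.ref}
        if len(shapes) != 1:
            raise ValueError("all cubes must share one frame size and grid")

    @property
    def n_angles(self) -> int:
        return len(self.obj)

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.obj[0].shape[:2]
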