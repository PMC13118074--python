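"""Specular/diffuse separation of multi-angle reflectance.

Per pixel, the measured per-lamp reflectance is modeled as

    R_i(lambda) = R_vol(lambda) + eps_i * R_surf(lambda),  i = 1..n_lamps,

where ``R_vol`` is the volume (diffuse) component carrying tissue
information, ``R_surf`` is a low-amplitude specular spectrum bounded to
[0, 0.1], and ``eps_i`` in [0, 1] is the lamp-dependent glare amplitude.
The fit minimizes the summed squared misfit over lamps and bands subject
to those box bounds (``R_vol`` in [0, 1]).

The model is bilinear, so the constrained problem is solved by block
coordinate descent: with the other blocks held fixed, each of ``R_vol``
(per band), ``R_surf`` (per band) and ``eps`` (per lamp) minimizes a
separable 1-D quadratic whose box-projected solution is exact.  Every
sweep therefore decreases the objective monotonically, and the whole
solve vectorizes over all pixels at once.

The decomposition carries a gauge freedom: ``(R_vol + b*R_surf,
a*R_surf, (eps - b)/a)`` fits equally well.  The products
``eps_i * R_surf`` are gauge-invariant; to make ``R_vol`` itself
identifiable the fitted result is canonicalized to the representative
with ``min_i eps_i = 0`` at every pixel (the physically motivated gauge
in which at least one lamp sees no glare), a shift that leaves the
residual unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .spectra import ReflectanceCube

__all__ = ["SpecularDecomposition", "DecompositionResult",
           "fit_specular_decomposition"]

R_SURF_MAX = 0.1
R_SURF_INIT = 0.05


@dataclass
class DecompositionResult:
    """Per-pixel decomposition over a frame.

    ``r_vol`` and ``r_surf`` have shape (H, W, B); ``eps`` is
    (n_lamps, H, W); ``residual`` is the per-pixel RMS misfit over all
    lamps and bands; ``converged`` flags pixels that met the tolerance
    (non-converged pixels keep their best iterate).
    """

    r_vol: np.ndarray
    r_surf: np.ndarray
    eps: np.ndarray
    residual: np.ndarray
    converged: np.ndarray
    mask: np.ndarray
    n_iter: int

    def volume_cube(self, grid) -> ReflectanceCube:
        return ReflectanceCube(self.r_vol, grid, mode="sequential",
                               invalid=~self.mask)


def _objective(R: np.ndarray, v: np.ndarray, s: np.ndarray,
               e: np.ndarray) -> np.ndarray:
    model = v[:, None, :] + e[:, :, None] * s[:, None, :]
    return np.sum((R - model) ** 2, axis=(1, 2))


def _solve_pixels(R: np.ndarray, max_iter: int, tol: float,
                  fix_gauge: bool) -> tuple[np.ndarray, ...]:
    """Constrained fit for flattened pixels; R has shape (P, n_lamps, B)."""
    P, A, B = R.shape
    # initialization: angle-averaged spectrum, flat 0.05 specular, then
    # amplitudes by regressing each lamp's residual onto the initial R_surf
    v = np.clip(R.mean(axis=1), 0.0, 1.0)
    s = np.full((P, B), R_SURF_INIT)
    resid0 = R - v[:, None, :]
    e = np.clip(np.sum(resid0 * s[:, None, :], axis=2)
                / np.sum(s * s, axis=1)[:, None], 0.0, 1.0)

    obj = _objective(R, v, s, e)
    converged = np.zeros(P, dtype=bool)
    it = 0
    for it in range(1, max_iter + 1):
        # R_vol block: per-band mean of (R_i - eps_i * s), box-projected
        v = np.clip(np.mean(R - e[:, :, None] * s[:, None, :], axis=1), 0.0, 1.0)
        # R_surf block: per-band regression of (R_i - v) on eps
        num = np.einsum("pab,pa->pb", R - v[:, None, :], e)
        den = np.sum(e * e, axis=1)
        upd = den > 1e-12
        s[upd] = np.clip(num[upd] / den[upd, None], 0.0, R_SURF_MAX)
        # eps block: per-lamp regression of (R_i - v) on s
        num_e = np.einsum("pab,pb->pa", R - v[:, None, :], s)
        den_e = np.sum(s * s, axis=1)
        upd_e = den_e > 1e-12
        e[upd_e] = np.clip(num_e[upd_e] / den_e[upd_e, None], 0.0, 1.0)

        new_obj = _objective(R, v, s, e)
        drop = obj - new_obj
        obj = new_obj
        converged = drop <= tol * np.maximum(obj, 1.0e-30) + 1e-18
        if converged.all():
            break

    if fix_gauge:
        # shift to the min-eps = 0 representative; residual is unchanged
        m = e.min(axis=1)
        if np.any(m > 0):
            # largest shift keeping R_vol within its upper bound
            with np.errstate(divide="ignore", invalid="ignore"):
                headroom = np.where(s > 1e-12, (1.0 - v) / np.maximum(s, 1e-12),
                                    np.inf).min(axis=1)
            m_eff = np.minimum(m, np.maximum(headroom, 0.0))
            v = np.clip(v + m_eff[:, None] * s, 0.0, 1.0)
            e = np.clip(e - m_eff[:, None], 0.0, 1.0)

    rms = np.sqrt(obj / (A * B))
    return v, s, e, rms, converged, it


class SpecularDecomposition(BaseEstimator):
    """Box-constrained pixel-wise specular/diffuse separation.

    Parameters
    ----------
    max_iter : int
        Maximum block-coordinate sweeps per fit (all pixels together).
    tol : float
        Relative objective-decrease tolerance declaring a pixel converged.
    fix_gauge : bool
        Canonicalize to the ``min_i eps_i = 0`` representative after
        fitting (see module docstring).

    Attributes
    ----------
    result_ : DecompositionResult
        Full per-pixel decomposition of the last ``fit``.
    """

    def __init__(self, max_iter: int = 500, tol: float = 1e-12,
                 fix_gauge: bool = True):
        self.max_iter = max_iter
        self.tol = tol
        self.fix_gauge = fix_gauge

    def fit(self, R_angles: list[ReflectanceCube],
            mask: np.ndarray | None = None) -> "SpecularDecomposition":
        """Fit the decomposition on per-lamp reflectance cubes.

        ``mask`` restricts the fit to foreground pixels; outside it
        ``R_vol`` falls back to the angle-average and ``eps`` to zero.
        """
        if len(R_angles) < 2:
            raise ValueError("need at least two lamp angles to separate "
                             "specular from diffuse reflectance")
        shape = R_angles[0].data.shape
        for cube in R_angles[1:]:
            if cube.data.shape != shape:
                raise ValueError("per-angle cubes must share one shape")
        H, W, B = shape
        stack = np.stack([np.asarray(c.data, dtype=np.float64)
                          for c in R_angles], axis=2)  # (H, W, A, B)
        valid = ~np.logical_or.reduce([c.invalid for c in R_angles])
        if mask is None:
            mask = valid
        else:
            mask = np.asarray(mask, dtype=bool) & valid
        if not mask.any():
            raise ValueError("mask excludes every pixel")

        pix = stack[mask]                               # (P, A, B)
        v, s, e, rms, conv, n_iter = _solve_pixels(
            pix, self.max_iter, self.tol, self.fix_gauge)

        r_vol = stack.mean(axis=2)
        r_surf = np.zeros((H, W, B))
        eps = np.zeros((len(R_angles), H, W))
        residual = np.zeros((H, W))
        converged = np.zeros((H, W), dtype=bool)
        r_vol[mask] = v
        r_surf[mask] = s
        for i in range(len(R_angles)):
            eps[i][mask] = e[:, i]
        residual[mask] = rms
        converged[mask] = conv
        self.result_ = DecompositionResult(
            r_vol=r_vol, r_surf=r_surf, eps=eps, residual=residual,
            converged=converged, mask=mask, n_iter=n_iter)
        self.grid_ = R_angles[0].grid
        return self

    def transform(self, R_angles: list[ReflectanceCube] | None = None,
                  mask: np.ndarray | None = None) -> ReflectanceCube:
        """Volume-reflectance cube (mode ``sequential``) of the fit."""
        if R_angles is not None:
            self.fit(R_angles, mask=mask)
        if not hasattr(self, "result_"):
            raise ValueError("decomposition has not been fitted")
        return self.result_.volume_cube(self.grid_)

    def fit_transform(self, R_angles: list[ReflectanceCube],
                      mask: np.ndarray | None = None) -> ReflectanceCube:
        return self.fit(R_angles, mask=mask).transform()


def fit_specular_decomposition(R_angles: list[ReflectanceCube],
                               mask: np.ndarray | None = None,
                               **options) -> DecompositionResult:
    """Functional wrapper around :class:`SpecularDecomposition`."""
    return SpecularDecomposition(**options).fit(R_angles, mask=mask).result_
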