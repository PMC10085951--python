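"""Voxel lattice, brain mask, and the sample-size-dependent Gaussian kernel.

Coordinate-based meta-analysis operates on a regular voxel grid covering the
brain.  Each reported peak ("focus") is smoothed with an isotropic 3D Gaussian
whose width reflects the spatial uncertainty of the peak location: a
template-registration component that is independent of the study, plus a
between-subject component that shrinks with the number of subjects,

    sigma(n) = sqrt(a**2 + b**2 / n).

The shipped defaults for ``a`` and ``b`` derive from the empirical spatial
uncertainty estimates of Eickhoff et al. (2009): mean Euclidean displacements
of 5.7 mm (template) and 11.6 mm (between subject), converted to the sigma of
a 3D isotropic Gaussian via E|X| = 2 * sigma * sqrt(2/pi).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = [
    "UncertaintyConfig",
    "DEFAULT_UNCERTAINTY",
    "BrainGrid",
    "KernelSpec",
    "sigma_from_sample_size",
    "build_kernel",
]

_EUCLIDEAN_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 / math.pi))


@dataclass(frozen=True)
class UncertaintyConfig:
    """Spatial-uncertainty constants of the kernel width model, in mm.

    ``a_mm`` is the template (registration) uncertainty, ``b_mm`` the
    between-subject uncertainty; both on the sigma scale.
    """

    a_mm: float = 5.7 * _EUCLIDEAN_TO_SIGMA
    b_mm: float = 11.6 * _EUCLIDEAN_TO_SIGMA

    def __post_init__(self) -> None:
        if not (self.a_mm > 0 and self.b_mm > 0):
            raise ValueError("uncertainty constants must be positive")


DEFAULT_UNCERTAINTY = UncertaintyConfig()


def sigma_from_sample_size(
    n_subjects: int, uncertainty: UncertaintyConfig = DEFAULT_UNCERTAINTY
) -> float:
    """Kernel width sigma (mm) for an experiment with ``n_subjects`` subjects.

    Strictly decreasing in ``n_subjects``; tends to ``a_mm`` as n -> inf.
    """
    if n_subjects < 1:
        raise ValueError(f"n_subjects must be >= 1, got {n_subjects}")
    return math.sqrt(uncertainty.a_mm**2 + uncertainty.b_mm**2 / n_subjects)


class BrainGrid:
    """A voxel lattice with an affine and a boolean in-brain mask.

    Voxel indices are 0-based; the affine maps voxel *centres* to mm
    coordinates.  Voxel spacing is isotropic by default (anisotropic grids are
    accepted but the kernel builder uses the first axis spacing).
    """

    def __init__(self, shape, affine, mask) -> None:
        shape = tuple(int(s) for s in shape)
        if len(shape) != 3 or any(s < 1 for s in shape):
            raise ValueError("shape must be three positive integers")
        affine = np.asarray(affine, dtype=float)
        if affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
            raise ValueError("affine must be invertible")
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != shape:
            raise ValueError("mask shape does not match grid shape")
        if not mask.any():
            raise ValueError("mask must contain at least one in-brain voxel")
        self.shape = shape
        self.affine = affine
        self.mask = mask
        self._inv_affine = np.linalg.inv(affine)

    # -- constructors -----------------------------------------------------

    @classmethod
    def from_mask_img(cls, img: nib.Nifti1Image) -> "BrainGrid":
        """Build a grid from a NIfTI mask image (nonzero voxels are in-brain)."""
        data = np.asanyarray(img.dataobj)
        return cls(data.shape, img.affine, data != 0)

    @classmethod
    def synthetic(
        cls,
        spacing_mm: float = 2.0,
        semi_axes_mm=(60.0, 80.0, 65.0),
        center_mm=(0.0, -15.0, 10.0),
        margin_mm: float = 6.0,
    ) -> "BrainGrid":
        """MNI-like grid with a synthetic ellipsoid brain mask.

        The default ellipsoid (semi-axes 60 x 80 x 65 mm) has roughly the
        volume of an adult human brain (~1.3 L) inside an MNI-scale bounding
        box, so tests and simulations need no external template.
        """
        semi = np.asarray(semi_axes_mm, dtype=float)
        ctr = np.asarray(center_mm, dtype=float)
        lo = ctr - semi - margin_mm
        hi = ctr + semi + margin_mm
        shape = tuple(int(math.ceil((h - l) / spacing_mm)) + 1 for l, h in zip(lo, hi))
        affine = np.diag([spacing_mm] * 3 + [1.0])
        affine[:3, 3] = lo
        ii, jj, kk = np.meshgrid(
            *(np.arange(s) for s in shape), indexing="ij", sparse=True
        )
        xs = lo[0] + ii * spacing_mm
        ys = lo[1] + jj * spacing_mm
        zs = lo[2] + kk * spacing_mm
        mask = (
            ((xs - ctr[0]) / semi[0]) ** 2
            + ((ys - ctr[1]) / semi[1]) ** 2
            + ((zs - ctr[2]) / semi[2]) ** 2
        ) <= 1.0
        return cls(shape, affine, mask)

    # -- coordinate transforms --------------------------------------------

    @property
    def spacing(self) -> float:
        return float(np.linalg.norm(self.affine[:3, 0]))

    @property
    def n_mask_voxels(self) -> int:
        return int(self.mask.sum())

    def mm_to_voxel(self, coords_mm):
        """Nearest-voxel indices for mm coordinates, with an in-grid flag.

        Returns ``(indices, in_grid)``: integer array (..., 3) and a boolean
        array flagging coordinates whose nearest voxel lies inside the grid.
        Out-of-grid coordinates are flagged, never raised on.
        """
        coords = np.atleast_2d(np.asarray(coords_mm, dtype=float))
        hom = np.c_[coords, np.ones(len(coords))]
        vox = (self._inv_affine @ hom.T).T[:, :3]
        idx = np.rint(vox).astype(int)
        in_grid = np.all((idx >= 0) & (idx < np.array(self.shape)), axis=1)
        if np.ndim(coords_mm) == 1:
            return idx[0], bool(in_grid[0])
        return idx, in_grid

    def voxel_to_mm(self, indices):
        idx = np.atleast_2d(np.asarray(indices, dtype=float))
        hom = np.c_[idx, np.ones(len(idx))]
        mm = (self.affine @ hom.T).T[:, :3]
        if np.ndim(indices) == 1:
            return mm[0]
        return mm

    def mask_voxel_centers_mm(self) -> np.ndarray:
        """Mm coordinates of all in-mask voxel centres, in C order."""
        idx = np.argwhere(self.mask)
        return self.voxel_to_mm(idx)

    def to_nifti(self) -> nib.Nifti1Image:
        return nib.Nifti1Image(self.mask.astype(np.uint8), self.affine)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, BrainGrid)
            and self.shape == other.shape
            and np.allclose(self.affine, other.affine)
            and np.array_equal(self.mask, other.mask)
        )

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"BrainGrid(shape={self.shape}, spacing={self.spacing:g} mm, "
            f"{self.n_mask_voxels} in-mask voxels)"
        )


@dataclass(frozen=True)
class KernelSpec:
    """A normalized truncated isotropic Gaussian sampled on the voxel grid.

    ``values`` sums to exactly 1 over its (odd-sized) support: the kernel is a
    probability mass function for the true peak location given a reported
    focus.
    """

    sigma_mm: float
    truncation_radius_mm: float
    values: np.ndarray = field(repr=False)

    @property
    def radius_vox(self) -> int:
        return (self.values.shape[0] - 1) // 2


def build_kernel(
    sigma_mm: float, voxel_spacing_mm: float, truncation_sigmas: float = 5.0
) -> KernelSpec:
    """Sample an isotropic Gaussian at voxel centres, truncate and normalize.

    Truncation is spherical at ``truncation_sigmas * sigma_mm``; the support
    is odd along every axis and the mass is renormalized to 1 so that no
    probability is lost to the cut tails.
    """
    if sigma_mm <= 0:
        raise ValueError("sigma_mm must be positive")
    if truncation_sigmas < 3:
        raise ValueError("truncation_sigmas must be >= 3")
    if sigma_mm < 1e-3 * voxel_spacing_mm:
        raise ValueError(
            f"sigma {sigma_mm} mm degenerate at spacing {voxel_spacing_mm} mm"
        )
    radius_mm = truncation_sigmas * sigma_mm
    r = int(math.ceil(radius_mm / voxel_spacing_mm))
    ax = np.arange(-r, r + 1) * voxel_spacing_mm
    xx, yy, zz = np.meshgrid(ax, ax, ax, indexing="ij", sparse=True)
    d2 = xx**2 + yy**2 + zz**2
    vals = np.exp(-d2 / (2.0 * sigma_mm**2))
    vals[d2 > radius_mm**2] = 0.0
    vals /= vals.sum()
    return KernelSpec(sigma_mm=sigma_mm, truncation_radius_mm=radius_mm, values=vals)
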