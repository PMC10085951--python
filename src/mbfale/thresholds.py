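"""Canonical frequentist thresholds for ALE maps.

Three procedures are provided, matching common CBMA practice:

* **uncorrected** — voxel survives iff p(v) < alpha (strict);
* **voxel-level FWE** — the null distribution of the *maximum* ALE value is
  built by Monte-Carlo: in each permutation every focus of every experiment is
  relocated to a uniformly random in-mask voxel (foci counts and subject
  numbers preserved) and the maximum recomputed ALE value is recorded.  The
  threshold is the empirical (1 - alpha) quantile (type 7) of the maxima;
  voxels survive on strict exceedance;
* **cluster-level FWE** — voxels with p < cluster_forming_p form connected
  clusters (26-connectivity by default); the permutation null of the maximum
  cluster *extent* (same relocation scheme, same cluster-forming step) gives a
  critical size at the (1 - alpha) quantile; clusters at or above that size
  survive.

Permuted ALE values are converted to p with the observed analytic null: the
per-experiment MA histograms — hence the null — are invariant under uniform
relocation, so nothing needs re-deriving per permutation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .engine import ALE, VolumeMap

__all__ = [
    "ThresholdSpec",
    "ThresholdedMap",
    "UncorrectedThreshold",
    "VoxelFWEThreshold",
    "ClusterFWEThreshold",
    "threshold_uncorrected",
    "threshold_voxel_fwe",
    "threshold_cluster_fwe",
    "binarize",
]

_CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}


@dataclass(frozen=True)
class ThresholdSpec:
    """Parameters of a thresholding procedure."""

    method: str  # {"uncorrected", "voxel_fwe", "cluster_fwe"}
    alpha: float = 0.05
    cluster_forming_p: float = 0.001
    n_permutations: int = 1000
    seed: int = 0
    connectivity: int = 26

    def __post_init__(self) -> None:
        if self.method not in ("uncorrected", "voxel_fwe", "cluster_fwe"):
            raise ValueError(f"unknown method {self.method!r}")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if not (0 < self.cluster_forming_p < 1):
            raise ValueError("cluster_forming_p must be in (0, 1)")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if self.connectivity not in _CONNECTIVITY_RANK:
            raise ValueError("connectivity must be 6, 18 or 26")


@dataclass
class ThresholdedMap:
    """Result of thresholding: a binary mask plus surviving statistic values."""

    binary_mask: np.ndarray
    surviving_values: np.ndarray
    spec: ThresholdSpec
    null_summary: dict = field(default_factory=dict)

    @property
    def n_surviving(self) -> int:
        return int(self.binary_mask.sum())


def binarize(thresholded: ThresholdedMap) -> np.ndarray:
    """Boolean volume: True where surviving, False elsewhere. Idempotent."""
    return thresholded.binary_mask.copy()


# ---------------------------------------------------------------------------
# Permutation machinery


def _relocated_foci(ale_fit: ALE, rng: np.random.Generator):
    """Uniform random in-mask voxel indices, one array per experiment."""
    mask_vox = np.argwhere(ale_fit.grid_.mask)
    out = []
    for exp in ale_fit.dataset_:
        pick = rng.integers(0, len(mask_vox), size=exp.n_foci)
        out.append(mask_vox[pick])
    return out


def _cluster_sizes(binary: np.ndarray, connectivity: int) -> np.ndarray:
    structure = ndimage.generate_binary_structure(3, _CONNECTIVITY_RANK[connectivity])
    labels, n = ndimage.label(binary, structure=structure)
    if n == 0:
        return np.zeros(0, dtype=int)
    return np.bincount(labels.ravel())[1:]


def _permutation_nulls(
    ale_fit: ALE,
    n_permutations: int,
    seed: int,
    cluster_forming_p: float | None = None,
    connectivity: int = 26,
):
    """Max-ALE (and optionally max-cluster-size) null via random relocation."""
    rng = np.random.default_rng(seed)
    grid = ale_fit.grid_
    max_ale = np.empty(n_permutations)
    max_cluster = np.empty(n_permutations, dtype=int) if cluster_forming_p else None
    if cluster_forming_p is not None:
        # ALE value above which the observed-null right tail drops below the
        # cluster-forming p; thresholding permuted ALE at this value is the
        # same as forming clusters at p < cluster_forming_p.
        tail = ale_fit.null_.sf(ale_fit.null_.bin_edges)
        above = np.flatnonzero(tail < cluster_forming_p)
        crit_idx = above[0] if len(above) else len(tail)
    for b in range(n_permutations):
        vals = ale_fit._masked_ale_for_voxel_foci(_relocated_foci(ale_fit, rng))
        max_ale[b] = vals.max()
        if cluster_forming_p is not None:
            idx = np.rint(vals / ale_fit.null_.bin_width).astype(int)
            binary = np.zeros(grid.shape, dtype=bool)
            binary[grid.mask] = idx >= crit_idx
            sizes = _cluster_sizes(binary, connectivity)
            max_cluster[b] = int(sizes.max()) if len(sizes) else 0
    return max_ale, max_cluster


# ---------------------------------------------------------------------------
# Estimators


class UncorrectedThreshold(BaseEstimator):
    """Voxel-wise uncorrected threshold: survive iff p(v) < alpha (strict)."""

    def __init__(self, alpha: float = 0.05) -> None:
        self.alpha = alpha

    def fit(self, ale_fit: ALE, y=None) -> "UncorrectedThreshold":
        check_is_fitted(ale_fit, "p_")
        spec = ThresholdSpec(method="uncorrected", alpha=self.alpha)
        mask = (ale_fit.p_.values < self.alpha) & ale_fit.grid_.mask
        self.result_ = ThresholdedMap(
            binary_mask=mask,
            surviving_values=ale_fit.ale_.values[mask],
            spec=spec,
        )
        self.mask_ = self.result_.binary_mask
        return self


class VoxelFWEThreshold(BaseEstimator):
    """Voxel-level FWE correction via the max-statistic permutation null."""

    def __init__(
        self, alpha: float = 0.05, n_permutations: int = 1000, seed: int = 0
    ) -> None:
        self.alpha = alpha
        self.n_permutations = n_permutations
        self.seed = seed

    def fit(self, ale_fit: ALE, y=None) -> "VoxelFWEThreshold":
        check_is_fitted(ale_fit, "ale_")
        spec = ThresholdSpec(
            method="voxel_fwe",
            alpha=self.alpha,
            n_permutations=self.n_permutations,
            seed=self.seed,
        )
        max_ale, _ = _permutation_nulls(ale_fit, self.n_permutations, self.seed)
        threshold = float(np.quantile(max_ale, 1.0 - self.alpha))
        mask = (ale_fit.ale_.values > threshold) & ale_fit.grid_.mask
        self.threshold_ = threshold
        self.max_stat_null_ = max_ale
        self.result_ = ThresholdedMap(
            binary_mask=mask,
            surviving_values=ale_fit.ale_.values[mask],
            spec=spec,
            null_summary={
                "ale_threshold": threshold,
                "max_ale_quantiles": {
                    q: float(np.quantile(max_ale, q)) for q in (0.5, 0.9, 0.95, 0.99)
                },
            },
        )
        self.mask_ = self.result_.binary_mask
        return self


class ClusterFWEThreshold(BaseEstimator):
    """Cluster-level FWE: cluster-forming p threshold + max-extent null."""

    def __init__(
        self,
        alpha: float = 0.05,
        cluster_forming_p: float = 0.001,
        n_permutations: int = 1000,
        seed: int = 0,
        connectivity: int = 26,
    ) -> None:
        self.alpha = alpha
        self.cluster_forming_p = cluster_forming_p
        self.n_permutations = n_permutations
        self.seed = seed
        self.connectivity = connectivity

    def fit(self, ale_fit: ALE, y=None) -> "ClusterFWEThreshold":
        check_is_fitted(ale_fit, "p_")
        spec = ThresholdSpec(
            method="cluster_fwe",
            alpha=self.alpha,
            cluster_forming_p=self.cluster_forming_p,
            n_permutations=self.n_permutations,
            seed=self.seed,
            connectivity=self.connectivity,
        )
        grid = ale_fit.grid_
        forming = (ale_fit.p_.values < self.cluster_forming_p) & grid.mask
        structure = ndimage.generate_binary_structure(
            3, _CONNECTIVITY_RANK[self.connectivity]
        )
        labels, n_clusters = ndimage.label(forming, structure=structure)

        _, max_cluster = _permutation_nulls(
            ale_fit,
            self.n_permutations,
            self.seed,
            cluster_forming_p=self.cluster_forming_p,
            connectivity=self.connectivity,
        )
        crit_size = float(np.quantile(max_cluster, 1.0 - self.alpha))

        mask = np.zeros(grid.shape, dtype=bool)
        sizes = np.bincount(labels.ravel())[1:] if n_clusters else np.zeros(0, int)
        surviving_labels = np.flatnonzero(sizes >= crit_size) + 1
        if len(surviving_labels):
            mask = np.isin(labels, surviving_labels)

        voxel_mm3 = float(abs(np.linalg.det(grid.affine[:3, :3])))
        self.threshold_size_ = crit_size
        self.max_cluster_null_ = max_cluster
        self.cluster_sizes_ = sizes
        self.result_ = ThresholdedMap(
            binary_mask=mask,
            surviving_values=ale_fit.ale_.values[mask],
            spec=spec,
            null_summary={
                "critical_cluster_size_voxels": crit_size,
                "critical_cluster_size_mm3": crit_size * voxel_mm3,
                "max_cluster_quantiles": {
                    q: float(np.quantile(max_cluster, q)) for q in (0.5, 0.9, 0.95, 0.99)
                },
            },
        )
        self.mask_ = self.result_.binary_mask
        return self


# ---------------------------------------------------------------------------
# Functional wrappers


def threshold_uncorrected(p: VolumeMap, alpha: float = 0.05) -> ThresholdedMap:
    """Survive iff p(v) < alpha; no correction, no permutations."""
    if p.kind != "p":
        raise ValueError("expected a p map")
    spec = ThresholdSpec(method="uncorrected", alpha=alpha)
    mask = (p.values < alpha) & p.grid.mask
    return ThresholdedMap(binary_mask=mask, surviving_values=p.values[mask], spec=spec)


def threshold_voxel_fwe(
    ale_fit: ALE, alpha: float = 0.05, n_permutations: int = 1000, seed: int = 0
) -> ThresholdedMap:
    est = VoxelFWEThreshold(alpha=alpha, n_permutations=n_permutations, seed=seed)
    return est.fit(ale_fit).result_


def threshold_cluster_fwe(
    ale_fit: ALE,
    alpha: float = 0.05,
    cluster_forming_p: float = 0.001,
    n_permutations: int = 1000,
    seed: int = 0,
    connectivity: int = 26,
) -> ThresholdedMap:
    est = ClusterFWEThreshold(
        alpha=alpha,
        cluster_forming_p=cluster_forming_p,
        n_permutations=n_permutations,
        seed=seed,
        connectivity=connectivity,
    )
    return est.fit(ale_fit).result_
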