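"""Equivalence between mBF cutoffs and canonical frequentist thresholds.

The bridge between the Bayesian and frequentist readings of an ALE analysis is
built in four steps, per canonical threshold: (i) threshold the ALE map the
frequentist way, (ii) binarize the surviving set, (iii) convert the Z map into
an mBF10 map, (iv) mask the mBF10 map with the binary set and take the lowest
surviving value — the *equivalent mBF*, the Bayes-Factor cutoff that admits
exactly the voxels the frequentist threshold admits (plus any non-overlapping
voxels of equal evidence elsewhere).

For a purely p-based threshold p < p_t, the equivalent mBF has the analytic
floor exp(z(p_t)^2 / 2) with z(p_t) = Phi^{-1}(1 - p_t): the surviving voxel
closest to the cut has p just under p_t, so its mBF sits just above the floor
(~3.87 for p<0.05; ~118.5 for p<0.001).

Two follow-up analyses probe how faithful the mBF cutoff is to the canonical
map: a Pearson-correlation curve between the binarized log10(mBF) map and the
binary ALE map over a grid of cutoffs, and an overlap/suppression analysis
counting voxels only in the mBF map, only in the ALE map, or in both, up to
the smallest cutoff that suppresses every mBF-only voxel.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import NamedTuple

import numpy as np

from .bayes import mbf_map_from_z_map
from .engine import ALE, VolumeMap
from .grid import BrainGrid
from .io import FociDataset
from .thresholds import (
    ThresholdSpec,
    ThresholdedMap,
    threshold_cluster_fwe,
    threshold_uncorrected,
    threshold_voxel_fwe,
)

__all__ = [
    "EquivalenceReport",
    "SuppressionResult",
    "equivalent_mbf",
    "correlation_curve",
    "overlap_counts",
    "suppression_threshold",
    "run_equivalence_study",
    "round_sig",
]


def round_sig(x: float, sig: int = 4) -> float:
    """Round to ``sig`` significant figures (reporting convention)."""
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, sig - 1 - int(math.floor(math.log10(abs(x)))))


class SuppressionResult(NamedTuple):
    threshold: float
    percent_overlap_lost: float
    achieved: bool  # False if mBF-only voxels persist up to the map maximum


@dataclass
class EquivalenceReport:
    """Per-threshold summary of the equivalence and sensitivity analyses."""

    canonical_threshold_name: str
    equivalent_mbf: float
    equivalent_log10_mbf: float
    threshold_spec: dict
    n_surviving_voxels: int
    correlation_thresholds: list = field(default_factory=list)
    correlation_r: list = field(default_factory=list)
    peak_threshold: float = float("nan")
    peak_r: float = float("nan")
    overlap_table: list = field(default_factory=list)  # rows: (t, only_mbf, only_ale, both)
    suppression_threshold: float = float("nan")
    suppression_achieved: bool = True
    percent_overlap_lost: float = float("nan")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, default=float)


def equivalent_mbf(bf10_map: VolumeMap, binary_ale_mask: np.ndarray) -> float:
    """Minimum mBF10 over the surviving voxels (4 significant figures)."""
    if bf10_map.kind != "mBF10":
        raise ValueError("expected an mBF10 map")
    binary_ale_mask = np.asarray(binary_ale_mask, dtype=bool)
    if not binary_ale_mask.any():
        raise ValueError("empty surviving set: no equivalent threshold exists")
    return round_sig(float(bf10_map.values[binary_ale_mask].min()), 4)


def _binary_pearson(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson r of two binary vectors = phi coefficient of the 2x2 table."""
    n = a.size
    n11 = int(np.sum(a & b))
    n10 = int(np.sum(a & ~b))
    n01 = int(np.sum(~a & b))
    n00 = n - n11 - n10 - n01
    r1, r0 = n11 + n10, n01 + n00
    c1, c0 = n11 + n01, n10 + n00
    denom = float(r1) * r0 * c1 * c0
    if denom == 0:
        return float("nan")  # one of the maps is constant
    return (n11 * n00 - n10 * n01) / math.sqrt(denom)


def correlation_curve(
    log10_bf_map: VolumeMap,
    binary_ale_mask: np.ndarray,
    threshold_grid: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Pearson r between the cutoff-binarized log10(mBF) map and the ALE mask.

    At each grid value t the Bayesian map is binarized at >= t and correlated
    with the binary ALE map over all in-brain voxels.  r is NaN where either
    binary map is constant.
    """
    grid = log10_bf_map.grid
    thresholds = np.asarray(threshold_grid, dtype=float)
    if thresholds.ndim != 1 or np.any(np.diff(thresholds) <= 0):
        raise ValueError("threshold_grid must be strictly increasing")
    if grid.n_mask_voxels < 2:
        raise ValueError("need at least 2 in-brain voxels")
    bf_vals = log10_bf_map.masked()
    ale_bin = np.asarray(binary_ale_mask, dtype=bool)[grid.mask]
    r = np.array([_binary_pearson(bf_vals >= t, ale_bin) for t in thresholds])
    return thresholds, r


def overlap_counts(
    log10_bf_map: VolumeMap,
    binary_ale_mask: np.ndarray,
    threshold_grid: np.ndarray,
) -> np.ndarray:
    """Per-cutoff voxel counts (only_mbf, only_ale, both) as an (n, 3) array."""
    grid = log10_bf_map.grid
    thresholds = np.asarray(threshold_grid, dtype=float)
    bf_vals = log10_bf_map.masked()
    ale_bin = np.asarray(binary_ale_mask, dtype=bool)[grid.mask]
    rows = []
    for t in thresholds:
        mbf_bin = bf_vals >= t
        rows.append(
            (
                int(np.sum(mbf_bin & ~ale_bin)),
                int(np.sum(~mbf_bin & ale_bin)),
                int(np.sum(mbf_bin & ale_bin)),
            )
        )
    return np.array(rows, dtype=int)


def suppression_threshold(
    log10_bf_map: VolumeMap,
    binary_ale_mask: np.ndarray,
    equivalent_log10_mbf: float,
    threshold_grid: np.ndarray | None = None,
    grid_step: float = 0.1,
) -> SuppressionResult:
    """Smallest cutoff removing every voxel present only in the Bayesian map.

    Also reports the percentage of overlapping voxels lost when raising the
    cutoff from the equivalent threshold to the suppression threshold.  If
    mBF-only voxels persist up to the map maximum, the maximum is returned
    with ``achieved=False``.
    """
    if threshold_grid is None:
        top = float(log10_bf_map.masked().max())
        start = min(equivalent_log10_mbf, top)
        threshold_grid = np.arange(start, top + grid_step, grid_step)
    counts = overlap_counts(log10_bf_map, binary_ale_mask, threshold_grid)
    both_eq = overlap_counts(
        log10_bf_map, binary_ale_mask, np.array([equivalent_log10_mbf])
    )[0, 2]
    if both_eq == 0:
        raise ValueError("no overlap at the equivalent threshold: nothing to lose")
    zero = np.flatnonzero(counts[:, 0] == 0)
    if len(zero) == 0:
        t_star = float(np.asarray(threshold_grid)[-1])
        both_star = counts[-1, 2]
        achieved = False
    else:
        t_star = float(np.asarray(threshold_grid)[zero[0]])
        both_star = counts[zero[0], 2]
        achieved = True
    lost = 100.0 * (both_eq - both_star) / both_eq
    return SuppressionResult(t_star, float(lost), achieved)


_LN10 = math.log(10.0)


def run_equivalence_study(
    dataset: FociDataset,
    grid: BrainGrid | None = None,
    threshold_specs: list[ThresholdSpec] | None = None,
    ale_fit: ALE | None = None,
    curve_step: float = 0.1,
    **ale_params,
) -> list[EquivalenceReport]:
    """Run the full four-step equivalence + sensitivity analysis.

    One ALE fit is shared across all requested canonical thresholds.  For each
    spec the thresholded set is binarized, the Z map converted to mBF10, the
    masked minimum taken, then the correlation curve and overlap/suppression
    analyses run over a log10 cutoff grid from 0 to the map maximum in steps
    of ``curve_step``.
    """
    if threshold_specs is None:
        threshold_specs = [
            ThresholdSpec(method="uncorrected"),
            ThresholdSpec(method="cluster_fwe"),
            ThresholdSpec(method="voxel_fwe"),
        ]
    if ale_fit is None:
        ale_fit = ALE(grid=grid, **ale_params).fit(dataset)
    bf10_map, log10_map = mbf_map_from_z_map(ale_fit.z_)
    top = float(log10_map.masked().max())
    curve_grid = np.arange(0.0, top + curve_step, curve_step)

    reports = []
    for spec in threshold_specs:
        if spec.method == "uncorrected":
            tm = threshold_uncorrected(ale_fit.p_, spec.alpha)
        elif spec.method == "voxel_fwe":
            tm = threshold_voxel_fwe(
                ale_fit, spec.alpha, spec.n_permutations, spec.seed
            )
        else:
            tm = threshold_cluster_fwe(
                ale_fit,
                spec.alpha,
                spec.cluster_forming_p,
                spec.n_permutations,
                spec.seed,
                spec.connectivity,
            )
        binary = tm.binary_mask
        report = EquivalenceReport(
            canonical_threshold_name=spec.method,
            equivalent_mbf=float("nan"),
            equivalent_log10_mbf=float("nan"),
            threshold_spec=asdict(spec),
            n_surviving_voxels=tm.n_surviving,
        )
        if tm.n_surviving == 0:
            reports.append(report)
            continue
        eq = equivalent_mbf(bf10_map, binary)
        eq_log10 = float(log10_map.values[binary].min())
        thresholds, r = correlation_curve(log10_map, binary, curve_grid)
        finite = np.isfinite(r)
        if finite.any():
            peak_i = int(np.nanargmax(np.where(finite, r, -np.inf)))
            report.peak_threshold = float(thresholds[peak_i])
            report.peak_r = float(r[peak_i])
        counts = overlap_counts(log10_map, binary, curve_grid)
        supp = suppression_threshold(
            log10_map, binary, eq_log10, grid_step=curve_step
        )
        report.equivalent_mbf = eq
        report.equivalent_log10_mbf = eq_log10
        report.correlation_thresholds = thresholds.tolist()
        report.correlation_r = [float(x) for x in r]
        report.overlap_table = [
            (float(t), int(a), int(b), int(c))
            for t, (a, b, c) in zip(curve_grid, counts)
        ]
        report.suppression_threshold = supp.threshold
        report.suppression_achieved = supp.achieved
        report.percent_overlap_lost = supp.percent_overlap_lost
        reports.append(report)
    return reports
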