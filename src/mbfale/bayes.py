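"""Minimum Bayes Factor thresholding of Z maps.

For a Gaussian test statistic, the Bayes Factor for the null against the
best-supported point alternative (mu equal to the observed effect) is

    mBF01 = exp(-Z**2 / 2),

the smallest Bayes Factor in favour of H0 over all point alternatives; its
reciprocal mBF10 = exp(Z**2 / 2) quantifies the evidence for an effect.  The
sigma of the sampling model cancels in the ratio, so the transform needs only
the Z map.  No permutation or randomization is involved.

Evidence strength follows the Kass–Raftery convention:

    BF10 in (1, 3]    very weak
    BF10 in (3, 20]   positive
    BF10 in (20, 150] strong
    BF10 > 150        very strong

BF10 <= 1 favours the null and is labelled separately.  Because mBF10 grows as
exp(Z^2/2), maps are also provided on the log10 scale, computed directly in
the log domain (log10 mBF10 = Z^2 / (2 ln 10)) so that arbitrarily large Z
never overflows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .engine import VolumeMap

__all__ = [
    "EvidenceCategory",
    "EVIDENCE_CATEGORIES",
    "mbf01_from_z",
    "mbf10_from_mbf01",
    "log10_mbf10_from_z",
    "mbf_map_from_z_map",
    "categorize_evidence",
]

_LN10 = math.log(10.0)


@dataclass(frozen=True)
class EvidenceCategory:
    """A Kass–Raftery evidence band: a label and a half-open BF10 interval."""

    label: str
    lower: float  # exclusive (inclusive under boundary="upper")
    upper: float  # inclusive (exclusive under boundary="upper")

    def __contains__(self, bf10: float) -> bool:
        return self.lower < bf10 <= self.upper


EVIDENCE_CATEGORIES = (
    EvidenceCategory("very_weak", 1.0, 3.0),
    EvidenceCategory("positive", 3.0, 20.0),
    EvidenceCategory("strong", 20.0, 150.0),
    EvidenceCategory("very_strong", 150.0, math.inf),
)


def mbf01_from_z(z):
    """mBF01 = exp(-z^2/2): evidence for H0 against the best point alternative."""
    arr = np.asarray(z, dtype=float)
    if np.any(~np.isfinite(arr)):
        raise ValueError("z must be finite")
    out = np.exp(-0.5 * arr**2)
    return float(out) if np.ndim(z) == 0 else out


def mbf10_from_mbf01(mbf01):
    """Reciprocal evidence for H1: mBF10 = 1 / mBF01."""
    arr = np.asarray(mbf01, dtype=float)
    if np.any(arr <= 0):
        raise ValueError("mbf01 must be positive")
    out = 1.0 / arr
    return float(out) if np.ndim(mbf01) == 0 else out


def log10_mbf10_from_z(z):
    """log10(mBF10) = z^2 / (2 ln 10), computed without exponentiation."""
    arr = np.asarray(z, dtype=float)
    if np.any(~np.isfinite(arr)):
        raise ValueError("z must be finite")
    out = arr**2 / (2.0 * _LN10)
    return float(out) if np.ndim(z) == 0 else out


def mbf_map_from_z_map(z_map: VolumeMap) -> tuple[VolumeMap, VolumeMap]:
    """Voxel-wise mBF10 and log10(mBF10) maps from a Z map.

    The log10 map is exact for any Z; the linear mBF10 map saturates at inf
    past |Z| ~ 38 (double-precision exp overflow), which is why the log map is
    the recommended reporting scale.
    """
    if z_map.kind != "Z":
        raise ValueError("expected a Z map")
    grid = z_map.grid
    log10_vals = np.zeros(grid.shape)
    log10_vals[grid.mask] = log10_mbf10_from_z(z_map.values[grid.mask])
    with np.errstate(over="ignore"):
        mbf10_vals = np.power(10.0, log10_vals)
    mbf10_vals[~grid.mask] = 0.0
    log10_vals[~grid.mask] = 0.0
    return (
        VolumeMap(grid=grid, values=mbf10_vals, kind="mBF10"),
        VolumeMap(grid=grid, values=log10_vals, kind="log10mBF"),
    )


def categorize_evidence(bf10: float, boundary: str = "lower") -> str:
    """Kass–Raftery evidence label for a BF10 value.

    Values <= 1 favour the null ("favors_h0").  ``boundary`` controls which
    band receives the exact cut points 3, 20, 150: "lower" (default) assigns
    them to the weaker category, "upper" to the stronger one.
    """
    if boundary not in ("lower", "upper"):
        raise ValueError("boundary must be 'lower' or 'upper'")
    if not (bf10 > 0):
        raise ValueError("bf10 must be positive")
    if bf10 <= 1.0:
        return "favors_h0"
    for cat in EVIDENCE_CATEGORIES:
        if boundary == "lower":
            if cat.lower < bf10 <= cat.upper:
                return cat.label
        else:
            if cat.lower <= bf10 < cat.upper or (
                cat.upper == math.inf and bf10 >= cat.lower
            ):
                return cat.label
    raise AssertionError("unreachable")  # pragma: no cover
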