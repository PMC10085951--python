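import numpy as np
import pytest
from scipy.stats import pearsonr

from mbfale import (
    ThresholdSpec,
    VolumeMap,
    correlation_curve,
    equivalent_mbf,
    overlap_counts,
    run_equivalence_study,
    suppression_threshold,
    threshold_uncorrected,
    z_from_p,
)
from mbfale.bayes import mbf_map_from_z_map
from mbfale.equivalence import _binary_pearson, round_sig


def _vol(grid, in_mask_values, kind):
    vals = np.zeros(grid.shape) if kind != "p" else np.ones(grid.shape)
    vals[grid.mask] = in_mask_values
    return VolumeMap(grid=grid, values=vals, kind=kind)


def _mask_from_flags(grid, flags):
    m = np.zeros(grid.shape, dtype=bool)
    m[grid.mask] = flags
    return m


class TestEquivalentMbf:
    def test_masked_minimum(self, small_grid):
        n = small_grid.n_mask_voxels
        vals = np.ones(n)
        vals[:3] = [10.0, 119.0, 3e5]
        bf = _vol(small_grid, vals, "mBF10")
        flags = np.zeros(n, bool)
        flags[:3] = True
        assert equivalent_mbf(bf, _mask_from_flags(small_grid, flags)) == 10.0

    def test_empty_mask_error(self, small_grid):
        bf = _vol(small_grid, np.ones(small_grid.n_mask_voxels), "mBF10")
        with pytest.raises(ValueError, match="empty"):
            equivalent_mbf(bf, np.zeros(small_grid.shape, bool))

    def test_analytic_floor_for_p_thresholds(self, planted_fit):
        """The equivalent mBF of a p < alpha threshold can never undercut
        exp(z(alpha)^2 / 2): the weakest survivor has p just below alpha."""
        bf10, _ = mbf_map_from_z_map(planted_fit.z_)
        for alpha in (0.05, 0.01):
            tm = threshold_uncorrected(planted_fit.p_, alpha)
            if tm.n_surviving == 0:
                continue
            floor = np.exp(z_from_p(alpha) ** 2 / 2.0)
            assert equivalent_mbf(bf10, tm.binary_mask) >= floor * (1 - 1e-4)

    def test_round_sig(self):
        assert round_sig(118.4828, 4) == 118.5
        assert round_sig(3.86813, 4) == 3.868
        assert round_sig(0.0084401, 3) == 0.00844


class TestCorrelationCurve:
    def test_perfect_and_inverse_agreement(self, small_grid):
        n = small_grid.n_mask_voxels
        rng = np.random.default_rng(1)
        flags = rng.random(n) < 0.3
        log10bf = np.where(flags, 5.0, 0.0)
        vol = _vol(small_grid, log10bf, "log10mBF")
        t, r = correlation_curve(vol, _mask_from_flags(small_grid, flags), np.array([1.0]))
        assert r[0] == pytest.approx(1.0)
        t, r = correlation_curve(vol, _mask_from_flags(small_grid, ~flags), np.array([1.0]))
        assert r[0] == pytest.approx(-1.0)

    def test_matches_independent_pearson(self, small_grid):
        rng = np.random.default_rng(7)
        n = small_grid.n_mask_voxels
        log10bf = rng.exponential(2.0, size=n)
        ale_flags = rng.random(n) < 0.4
        vol = _vol(small_grid, log10bf, "log10mBF")
        grid_t = np.array([0.5, 1.0, 2.0, 4.0])
        _, r = correlation_curve(vol, _mask_from_flags(small_grid, ale_flags), grid_t)
        for t, r_pkg in zip(grid_t, r):
            r_ref = pearsonr((log10bf >= t).astype(float), ale_flags.astype(float))[0]
            assert r_pkg == pytest.approx(r_ref, abs=1e-12)

    def test_constant_map_gives_nan(self, small_grid):
        n = small_grid.n_mask_voxels
        vol = _vol(small_grid, np.zeros(n), "log10mBF")
        flags = np.zeros(n, bool)
        flags[0] = True
        _, r = correlation_curve(vol, _mask_from_flags(small_grid, flags), np.array([99.0]))
        assert np.isnan(r[0])

    def test_nonmonotone_grid_rejected(self, small_grid):
        vol = _vol(small_grid, np.zeros(small_grid.n_mask_voxels), "log10mBF")
        with pytest.raises(ValueError, match="increasing"):
            correlation_curve(vol, np.zeros(small_grid.shape, bool), np.array([1.0, 1.0]))

    def test_phi_equals_pearson_closed_form(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            a = rng.random(200) < rng.uniform(0.1, 0.9)
            b = rng.random(200) < rng.uniform(0.1, 0.9)
            if a.all() or (~a).all() or b.all() or (~b).all():
                continue
            assert _binary_pearson(a, b) == pytest.approx(
                pearsonr(a.astype(float), b.astype(float))[0], abs=1e-12
            )


class TestOverlapCounts:
    def test_toy_enumeration(self, small_grid):
        n = small_grid.n_mask_voxels
        bf = np.zeros(n)
        bf[:3] = 5.0
        ale_flags = np.zeros(n, bool)
        ale_flags[1:4] = True
        vol = _vol(small_grid, bf, "log10mBF")
        counts = overlap_counts(vol, _mask_from_flags(small_grid, ale_flags), np.array([1.0]))
        only_mbf, only_ale, both = counts[0]
        assert (only_mbf, only_ale, both) == (1, 1, 2)

    def test_above_map_maximum(self, small_grid):
        n = small_grid.n_mask_voxels
        bf = np.zeros(n)
        bf[:5] = 3.0
        ale_flags = np.zeros(n, bool)
        ale_flags[:7] = True
        vol = _vol(small_grid, bf, "log10mBF")
        counts = overlap_counts(vol, _mask_from_flags(small_grid, ale_flags), np.array([4.0]))
        assert tuple(counts[0]) == (0, 7, 0)

    def test_monotonicity_on_random_maps(self, small_grid):
        rng = np.random.default_rng(11)
        n = small_grid.n_mask_voxels
        for _ in range(5):
            bf = rng.exponential(1.5, size=n)
            ale_flags = rng.random(n) < 0.3
            vol = _vol(small_grid, bf, "log10mBF")
            grid_t = np.linspace(0.1, 6.0, 25)
            counts = overlap_counts(vol, _mask_from_flags(small_grid, ale_flags), grid_t)
            assert np.all(np.diff(counts[:, 0]) <= 0)  # only-mBF nonincreasing
            assert np.all(np.diff(counts[:, 1]) >= 0)  # only-ALE nondecreasing
            assert np.all(np.diff(counts[:, 2]) <= 0)  # both nonincreasing


class TestSuppression:
    def _maps(self, small_grid, bf, ale_flags):
        return _vol(small_grid, bf, "log10mBF"), _mask_from_flags(small_grid, ale_flags)

    def test_constructed_arithmetic(self, small_grid):
        """100 overlapping voxels at the equivalent cutoff; mBF-only voxels
        vanish at t=4 where only 51 overlapping voxels remain -> 49% lost."""
        n = small_grid.n_mask_voxels
        bf = np.zeros(n)
        ale_flags = np.zeros(n, bool)
        bf[:100] = np.r_[np.full(51, 9.0), np.full(49, 3.5)]
        ale_flags[:100] = True
        bf[100:110] = 3.5  # mBF-only voxels, gone at t=4
        vol, mask = self._maps(small_grid, bf, ale_flags)
        res = suppression_threshold(vol, mask, equivalent_log10_mbf=3.0,
                                    threshold_grid=np.array([3.0, 4.0, 9.0]))
        assert res.achieved
        assert res.threshold == 4.0
        assert res.percent_overlap_lost == pytest.approx(49.0)

    def test_contained_bf_map_loses_nothing(self, small_grid):
        n = small_grid.n_mask_voxels
        bf = np.zeros(n)
        bf[:20] = 5.0
        ale_flags = np.zeros(n, bool)
        ale_flags[:30] = True
        vol, mask = self._maps(small_grid, bf, ale_flags)
        res = suppression_threshold(vol, mask, equivalent_log10_mbf=2.0,
                                    threshold_grid=np.array([2.0, 3.0]))
        assert res.achieved and res.threshold == 2.0
        assert res.percent_overlap_lost == 0.0

    def test_flagged_when_never_suppressed(self, small_grid):
        n = small_grid.n_mask_voxels
        bf = np.zeros(n)
        bf[0] = 8.0  # mBF-only voxel at the global maximum
        bf[1:5] = 4.0
        ale_flags = np.zeros(n, bool)
        ale_flags[1:5] = True
        vol, mask = self._maps(small_grid, bf, ale_flags)
        res = suppression_threshold(vol, mask, equivalent_log10_mbf=4.0,
                                    threshold_grid=np.array([4.0, 8.0]))
        assert not res.achieved
        assert res.threshold == 8.0

    def test_no_overlap_error(self, small_grid):
        n = small_grid.n_mask_voxels
        bf = np.zeros(n)
        ale_flags = np.zeros(n, bool)
        ale_flags[0] = True
        vol, mask = self._maps(small_grid, bf, ale_flags)
        with pytest.raises(ValueError, match="overlap"):
            suppression_threshold(vol, mask, 1.0, threshold_grid=np.array([1.0]))


@pytest.fixture(scope="module")
def reports(planted_fit):
    specs = [
        ThresholdSpec(method="uncorrected"),
        ThresholdSpec(method="cluster_fwe", n_permutations=40, seed=4),
    ]
    return run_equivalence_study(
        planted_fit.dataset_, ale_fit=planted_fit, threshold_specs=specs
    )


class TestStudy:
    def test_report_fields_and_spec_echo(self, reports):
        assert [r.canonical_threshold_name for r in reports] == [
            "uncorrected", "cluster_fwe",
        ]
        for r in reports:
            assert r.threshold_spec["method"] == r.canonical_threshold_name
            assert np.isfinite(r.peak_r)
            assert r.to_json()

    def test_peak_near_equivalent_threshold(self, reports):
        """On a containment fixture the correlation peak coincides (within one
        grid step) with the equivalent log10(mBF) threshold."""
        r = reports[0]
        assert r.n_surviving_voxels > 0
        assert abs(r.peak_threshold - r.equivalent_log10_mbf) <= 0.1 + 1e-9

    def test_equivalent_mbf_above_floor(self, reports):
        floor = np.exp(z_from_p(0.05) ** 2 / 2.0)
        assert reports[0].equivalent_mbf >= floor * (1 - 1e-4)

    def test_deterministic_given_seeds(self, planted_fit):
        specs = [ThresholdSpec(method="cluster_fwe", n_permutations=20, seed=9)]
        a = run_equivalence_study(planted_fit.dataset_, ale_fit=planted_fit,
                                  threshold_specs=specs)
        b = run_equivalence_study(planted_fit.dataset_, ale_fit=planted_fit,
                                  threshold_specs=specs)
        assert a[0].to_json() == b[0].to_json()
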