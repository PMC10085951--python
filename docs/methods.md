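# Methods

## The ALE model

Each experiment *i* contributes a set of peak coordinates x_ik (mm) and a
subject count n_i. A reported peak is an uncertain estimate of a true effect
location, modelled as an isotropic 3D Gaussian centred on the peak:

    L_ik(v) = c · φ₃(v | x_ik, σ_i² I),

where c renormalizes the kernel after sampling and truncation so it sums to 1
over voxels — a probability mass function for the true location. Per-focus
maps are combined into the experiment's modeled activation (MA) map L_i(v);
the ALE statistic is the probabilistic union across experiments,

    l(v) = 1 − Π_i (1 − L_i(v)).

### Kernel width

The spatial uncertainty has a template (registration) component independent
of the study and a between-subject component that averages out with sample
size:

    σ(n) = sqrt(a² + b²/n).

Defaults: a = 5.7/(2√(2/π)) ≈ 3.572 mm and b = 11.6/(2√(2/π)) ≈ 7.269 mm,
the empirical mean Euclidean displacements reported by Eickhoff et al. (2009)
for template and between-subject variability, converted to the σ of a 3D
isotropic Gaussian via E|X| = 2σ√(2/π). At n = 20 this gives σ ≈ 3.92 mm
(FWHM ≈ 9.2 mm), matching classical ALE software. Both constants are
configuration (`UncertaintyConfig`), so the engine is testable independently
of their values.

Kernels are sampled at voxel centres, truncated spherically at 5σ (config:
`truncation_sigmas`, ≥3) and renormalized; the support is odd-sized so the
peak voxel is the centre. Truncation at 5σ discards ~1e-6 of the mass before
renormalization, so doubling the truncation radius changes values by <1e-4
relative.

### Within-experiment combination

The package defaults to the voxel-wise **maximum** over the experiment's
focus kernels (modern ALE behaviour, preventing a single experiment with many
nearby peaks from dominating); the probabilistic union is available via
`combine="union"`. Foci outside the brain mask but inside the grid keep their
kernel and the MA map is masked afterwards (tolerant of imperfect input
coordinates, with a logged warning); foci outside the grid are skipped, and
an experiment whose foci are all outside the grid is an error.

## Null distribution, p and Z

The null hypothesis is spatial independence: foci fall uniformly across the
brain. At a voxel, each experiment's MA value is then a draw from that
experiment's in-mask MA value histogram (zeros included — they carry most of
the null mass). The null distribution of l(v) is computed by **histogram
convolution**: MA histograms on a value lattice of step `bin_width` (default
1e-5) are combined pairwise under the union rule — mass p·q of bins with
values u, w is deposited at 1 − (1−u)(1−w), rounded to the lattice. The
result is exact up to the discretization and requires no random sampling. A
Monte-Carlo null (random-foci datasets) is kept in the test suite as an
independent oracle; the two agree with Kolmogorov–Smirnov distance < 0.02.

p-values are the right tail with the ≥ convention (ties conservative),
clamped below at the smallest positive tail mass so p > 0 always. Z is the
one-sided quantile Φ⁻¹(1−p), computed as −ndtri(p) to keep full double
precision at small p. In the stored Z map, voxels with p ≥ 0.5 (the null
background; p = 1 at zero-ALE voxels, where the raw quantile is −∞) are
floored at Z = 0: the statistic is one-sided and such voxels carry no
evidence of convergence. The pure function `z_from_p` is exact and unfloored.

## Frequentist thresholds

* **Uncorrected**: survive iff p(v) < α (strict), default α = 0.05.
* **Voxel-level FWE**: every focus of every experiment is relocated to a
  uniformly random in-mask voxel (foci counts and subject numbers kept), the
  ALE map is recomputed and its maximum recorded; the threshold is the
  empirical (1−α) quantile (type-7) of the maxima over `n_permutations`
  (default 1000); survival is strict exceedance.
* **Cluster-level FWE**: voxels with p < cluster-forming p (default 0.001)
  form connected clusters (26-connectivity by default; 6 and 18 available);
  the same permutation scheme yields the null of the **maximum cluster
  extent**; clusters at or above the (1−α) size quantile survive. Extent (not
  mass) is the cluster statistic; sizes are reported in voxels and mm³.

Permuted ALE values are converted to p with the *observed* analytic null:
per-experiment MA histograms are invariant under uniform relocation (same
kernels, same counts, up to mask-edge effects), so the null need not be
rebuilt per permutation. All permutation procedures are driven by an explicit
seed and are bitwise reproducible.

## Minimum Bayes Factor

For a Gaussian statistic the Bayes Factor of H0 against the best-supported
point alternative (μ equal to the observed effect) is mBF01 = exp(−Z²/2); σ
cancels in the ratio, which the implementation relies on. mBF10 = exp(Z²/2)
is the evidence for an effect. The log10 map is computed directly in the log
domain, log10 mBF10 = Z²/(2 ln 10), exact for any Z (no overflow for |Z| ≤
200 and far beyond); the linear mBF10 map saturates at +inf past |Z| ≈ 38,
one reason the log scale is the recommended reporting form. Evidence labels
follow Kass–Raftery; values at the cut points 3, 20, 150 go to the weaker
band by default (`boundary="lower"`, configurable), and BF10 ≤ 1 is labelled
`favors_h0` rather than forced into the bands.

Reporting guidance implemented as defaults: thresholded Bayesian maps are
written unbinarized, with the log10 variant always alongside; no upper-bound
value cutoff is ever applied.

## Equivalent-mBF procedure

Per canonical threshold: (i) threshold the ALE map, (ii) binarize, (iii)
convert the Z map to mBF10, (iv) take the minimum mBF10 over the surviving
voxels — the equivalent mBF. For a p-based cutoff p_t this minimum has the
analytic floor exp(Φ⁻¹(1−p_t)²/2) — 3.86813 at p_t = 0.05 and 118.483 at
p_t = 0.001 — and approaches the floor from above as the surviving set
samples the threshold boundary densely. The observed gap above the floor
reflects the p-lattice of the discretized null and the granularity of the
map; equivalent mBFs are reported at 4 significant figures.

The correlation curve binarizes the log10(mBF) map at cutoffs from 0 to the
map maximum in steps of 0.1 (configurable) and computes the Pearson r against
the binary ALE map over **all in-brain voxels** (a documented choice; r on
binary maps equals the phi coefficient of the 2×2 overlap table, which is how
it is computed, and is cross-checked against an independent correlation
routine in the tests). r is undefined (NaN) when either map is constant. The
overlap analysis counts voxels only in the mBF map, only in the ALE map, and
in both, at each cutoff; the suppression threshold is the smallest cutoff
with zero mBF-only voxels, reported with the percentage of overlapping voxels
lost relative to the equivalent cutoff, and flagged if never reached.

## Synthetic data

The synthetic grid is an MNI-scale ellipsoid mask (semi-axes 60×80×65 mm,
~1.3 L — about an adult brain volume) on a 2 mm isotropic lattice by default;
any NIfTI mask is accepted. Generators:

* **random foci** (null): each focus a uniform draw over in-mask voxel
  centres. Placement over voxels (not continuous mm) makes null datasets
  exchangeable with the FWE permutation scheme. Defaults per experiment: 5–15
  foci, 10–30 subjects, both uniform — typical of meta-analytic pools.
* **planted signal**: a fraction of each experiment's foci is assigned
  round-robin to shared centres, displaced by isotropic Gaussian jitter
  (default sd 4 mm) and snapped to the nearest in-mask voxel centre; the rest
  are uniform.

What the generators do **not** emulate: anatomically structured foci
distributions (real foci concentrate in grey matter), inter-study reporting
biases, coordinate-space (Talairach vs MNI) mixtures, and correlated foci
within experiments beyond the planted centres. Passing benchmarks on these
datasets therefore validates the statistical machinery — null calibration,
threshold definitions, the equivalence constants, which are properties of the
threshold definitions rather than of any dataset — but not claims about any
particular cognitive domain.

The robustness experiment runs the full pipeline on a 21-experiment
random-foci dataset and counts in-mask voxels at or above log10(mBF) cutoffs
2 and 5 (configurable): cutoff 5 yields empty maps while cutoff 2 admits
hundreds of spurious voxels, so 10² must not be treated as a c-FWE
equivalent even though its equivalent-mBF value is ≈119.

## Numerical choices and problem sizes

* Null lattice `bin_width` = 1e-5 (allowed range (0, 0.01]); unit tests use
  1e-4 on small grids.
* Tail convention ≥; quantiles type-7; cluster survival ≥ the size quantile,
  voxel-FWE survival strict.
* The acceptance script and end-to-end tests use the 2 mm synthetic grid
  (~163k in-mask voxels), 50–60-experiment pools, and 100 permutations — a
  desk-scale setting at which the pipeline completes in seconds while the
  equivalence constants are already stable; permutation counts and pool sizes
  are configurable upwards.
* Equivalent mBFs at 4 significant figures; scientific notation above 1e4.

## Known limitations

* No Talairach↔MNI conversion: coordinates are used in the dataset's declared
  space, and the space label is carried verbatim.
* Isotropic kernels only; no surface-based analysis; no FDR thresholding.
* The discretized null makes achievable p-values a finite set; equivalent
  mBFs therefore sit slightly above their analytic floors, by an amount that
  shrinks as maps grow denser. Exact numerical parity with any specific
  legacy ALE binary (its binning and tie conventions) is not claimed.
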