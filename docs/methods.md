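# Methods

`cardiomics` implements the quantitative readouts used to characterise
in-vitro cardiomyocyte differentiation across three arms — fluorescence
lifetime imaging (FLIM), fluorescence-image morphometry, and GC-MS
chemometrics — each paired with a seeded synthetic-data generator so that
every stage can be validated against planted ground truth without any
external data.

## FLIM: model and forward simulation

Time-correlated single photon counting records, per pixel, a histogram of
photon arrival times within one laser repetition period (12.5 ns at
80 MHz; 256 timing bins by default). The decay of cellular
autofluorescence is modelled as a two-component exponential

    I(t) = a1 exp(-t/tau1) + a2 exp(-t/tau2),    a1 + a2 = 100 %,

where `a1, a2` are the fractional pre-exponential amplitudes and
`tau1 < tau2` the lifetimes of the short- and long-lived species. The
amplitude-weighted mean lifetime is `tau_m = (a1 tau1 + a2 tau2)/100`.
For the coenzyme channels the bound fractions carry the metabolic
information: NAD(P)H is long-lived when protein-bound (`a2` = bound
fraction) while FAD is short-lived when bound (`a1` = bound fraction).
The fluorescence-lifetime redox ratio

    FLIRR = NADH a2 / FAD a1

is a concentration-independent index that rises as metabolism shifts from
glycolysis towards oxidative phosphorylation.

The simulator integrates the decay analytically over each timing bin and
wraps incomplete decays periodically at the laser period, so the expected
histogram of `exp(-t/tau)` observed in steady state is
`tau (e^{-t0/tau} - e^{-t1/tau}) / (1 - e^{-T/tau})` per bin. An optional
Gaussian instrument response (FWHM configurable, default 0 = delta) is
applied by circular convolution. Per-bin counts are independent Poisson
draws scaled to a photon budget per pixel; background pixels are dark
(optional uniform dark rate). Scenes are circular cells with a nuclear
disk excluded from the cytoplasm annulus; lipofuscin-like granules are
planted as 2-px-radius disks (Poisson count per cell) whose parameters
are rescaled so `tau_m` is half the cytoplasm value — no canonical
granule lifetime exists, so the contrast factor is a parameter.

No published lifetime values exist for these channels in this system, so
the defaults are literature-typical pairs exposed as configuration:
NAD(P)H (0.4, 2.5) ns, FAD (0.35, 2.8) ns.

## FLIM: fitting

Histograms are pooled over a square sliding window before fitting
(default 5x5, matching the "bin 5" convention of vendor TCSPC software
for 512x512 frames); the window is a config field. Fitting starts at the
histogram peak (tail fit) and uses variable projection: for any
`(tau1, tau2)` the optimal non-negative amplitudes solve a 2-column
weighted least-squares problem exactly (non-negative least squares),
leaving a 2-parameter bounded search over log-lifetimes
(`scipy.optimize.least_squares`). The model integrates per bin and
includes the periodic wrap term, so long-lifetime tails are unbiased.

Weighting matters at these photon budgets. Classic Neyman weighting
(1/max(counts, 1)) over-weights downward-fluctuating bins and biases the
recovered bound fraction upward by about +3 percentage points at 5x10^3
photons per binned pixel spread over 256 bins. The default objective
therefore refits with model-based weights 1/max(model, 1) for
`n_reweight - 1` additional passes (default 3 passes total), which brings
the amplitude bias below 0.5 points and lifetime bias below 1 %.
`n_reweight = 1` recovers the classic Neyman objective; a Poisson
maximum-likelihood polish is available as `noise_model="poisson_mle"`.

Numerical choices: pixels with fewer than 100 photons after binning are
flagged invalid (never silently zeroed); lifetimes within 1 % of each
other, or a minor component below 0.5 % amplitude, are collapsed to a
mono-exponential report (`a2 = 0`), since such pairs are statistically
indistinguishable from a single decay; amplitudes are renormalised to
percent so `a1 + a2 = 100` holds to machine precision; lifetimes are
reported in ascending order, giving `tau1 <= tau_m <= tau2` always.

## FLIM: readouts

Pixel statistics inside an ROI use the population formulas (mean, SD with
divisor N); summaries across cells use the sample (n-1) convention, the
usual Mean±SD reporting. Cohen's d is `(m1 - m2)/s_pooled` with the
(n-1)-weighted pooled SD by default; the unweighted variant is kept
because both conventions appear in practice and differ at unequal n.
Per-cell FLIRR is the mean of per-pixel ratios over the cytoplasm mask
(the ratio-of-ROI-means variant is exposed as `mode="ratio_of_means"`);
with uniform maps the two coincide. Granules are connected components of
sub-threshold `tau_m` pixels (area >= 4 px by default) assigned to the
cell containing their centroid; the threshold defaults to an Otsu split
of the pooled `tau_m` histogram and should sit below the cytoplasm mode —
a threshold above the ROI median triggers a warning.

## Morphometry

Mitochondria are segmented by global Otsu thresholding (adaptive
optional), size-filtered, and labelled. Per object: area, Crofton
perimeter (chosen over pixel-edge counting so a rasterised circle scores
form factor ~1.0), form factor `P^2/(4 pi A)` (inverse circularity; 1 for
a circle), aspect ratio from image-moment axis lengths, and branch count
from the skeleton as junction-clusters + 1 (a straight filament counts
1). Ki67 positivity follows the 30 %-coverage rule: a nucleus is positive
when thresholded Ki67 signal covers at least 30 % of its area. Foci are
counted as local maxima of a Laplacian-of-Gaussian response (sigma
matched to the spot size, prominence cutoff relative to the response
maximum); spots closer than about two sigma merge into one detection, a
property the tests pin down explicitly. ROS readout is the per-cell mean
fluorescence intensity; focus counts divided by the group-mean ROS give
DNA damage per unit oxidative load.

The image generators render nuclei and cells as disks, Ki67-positive
regions as compact blobs grown to the requested pixel count (coverage
exact to rasterisation), foci as Gaussian spots with enforced minimum
separation (default 4 sigma), and mitochondria as ellipses (unbranched)
or constant-thickness dilated polylines with the requested number of side
arms, iterating the skeleton length so rendered area lands within ~5 % of
the request.

## Chemometrics

The feature-table generator emulates a triplicate two-group (or
multi-group) design with pooled QC injections: log-normal baselines,
multiplicative group effects in log2 units (scaled linearly along the
group sequence), log-normal replicate noise (CV 0.25 default), QC values
built from the per-feature biological mean with noise calibrated to a
target QC RSD (0.12 default), and missingness enriched in low-intensity
features (mean rate 0.15 default). These defaults mirror the structure of
a GC-MS endometabolome screen at desk scale.

Processing follows standard metabolomics practice: features missing in
>= 65 % of samples are dropped, then features with QC RSD >= 30 %;
remaining gaps are imputed with half the feature minimum; samples are
median-normalised, square-root transformed and autoscaled (log2 transform
available; the square root is the default transform). PCA is delegated to
scikit-learn. PLS-DA fits `PLSRegression` against a one-hot class
response on the biological samples; VIP scores are computed from the
x-weights and the per-component explained response variance,

    VIP_j = sqrt( p * sum_a SSY_a (w_aj/||w_a||)^2 / sum_a SSY_a ),

so that `sum_j VIP_j^2 = p` identically. Cross-validation reports R2 on
the full fit and Q2 = 1 - PRESS/TSS from held-out prediction,
leave-one-out whenever the smallest group has <= 3 samples (the
triplicate design makes k-fold impossible). Univariate testing is an
unpaired equal-variance t-test per feature with Benjamini-Hochberg
q-values; log2 fold changes are taken from the median-normalised,
pre-transform stage where intensities are still positive (the stage is an
interpretation choice — published fold changes rarely state it — and is
therefore configurable via `fc_table`). The combined significance rule is
FDR < 0.05 and p < 0.05 and VIP > 1.0. Over-representation analysis uses
the upper-tail hypergeometric probability `P[X >= hits]` with a lenient
default cutoff p < 0.1, compensating for the limited pathway coverage of
GC-MS-amenable metabolites; the universe defaults to the features
surviving filtering. A seeded toy-pathway generator stands in for curated
pathway databases.

## Validation strategy and problem sizes

Every generator is deterministic per seed and emits a truth record, and
every measurement is tested against that truth or against an independent
oracle: the fitter against a dense (tau1, tau2, a1) lattice search under
the identical objective and against noiseless closed forms; BH q-values
against a textbook step-up implementation on random p-vectors;
hypergeometric p against exhaustive enumeration of all query draws for
small universes; VIP against its sum-of-squares identity.

Simulation sizes are chosen to keep the full suite fast while leaving
comfortable statistical margins: end-to-end FLIM recovery uses 64x64
frames at ~6x10^3 photons per binned pixel; oracle-equivalence uses 16x16
cubes; recovery bias uses 500 independent pixels; chemometrics rate
checks use 50-100 seeds of 40-50-feature tables. The `acceptance.py`
script in `scripts/` re-runs the 64x64 end-to-end FLIRR recovery from
scratch.

## What the synthetic data does and does not show

The generators reproduce the *structure* of the real experiments — photon
statistics and decay shapes, object geometries, the triplicate/QC design
and effect magnitudes — but not their biological texture: real cytoplasm
is spatially heterogeneous, autofluorescence backgrounds are not dark,
real mitochondria are curved and overlapping, chromatographic intensities
are not exactly log-normal, and real missingness mechanisms are messier.
Passing tests therefore demonstrate that the algorithms recover known
truth under the stated noise models, not that any specific biological
conclusion transfers; study-scale quantities that depend on the original
raw chromatograms or images (total feature counts, specific metabolite
lists, granule rates per cell, survival fractions) are deliberately out
of reach at desk scale and are replaced by the planted-truth recovery
checks above.

## Known limitations

- The fitter assumes a delta instrument response when `irf_fwhm = 0`
  cubes are fitted; IRF-convolved fitting is only exercised through the
  simulator and tail fitting, not deconvolution.
- Granule detection on fitted (rather than truth) `tau_m` maps inherits
  the 5x5 binning blur, which dilates small granules; counts remain
  correct for well-separated granules but merging is possible at high
  rates.
- PLS-DA Q2 at n = 3/group is intrinsically unstable; the leave-one-out
  estimate carries large seed-to-seed variance and should be read as a
  coarse adequacy check, not a precise statistic.
- The toy pathway library is random by construction; enrichment results
  on it validate the arithmetic, not any biology.
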