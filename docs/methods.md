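# Methods

## The monitoring model

The package targets aeolian desertification: wind-driven land degradation
in dry regions, visible in reflectance imagery as bright, sparsely
vegetated surfaces whose spectra barely change through the growing
season.  The monitoring core exploits exactly that contrast in time
rather than in a single image.

**Index.** For each 8-day composite the Normalized Difference
Desertification Index is

    NDDI = (band1 − band2) / (band1 + band2),

with band1 the red band (620–670 nm) and band2 the near-infrared band
(841–876 nm).  This orientation — the negative of NDVI — is a package
convention (`nddi_mad.NDDI_SIGN`): desertified surfaces, with red ≳ NIR
and no phenology, score high and flat; vegetated surfaces dip strongly
mid-season.  Because the downstream matching uses absolute distances, a
global sign flip applied consistently to pixels and reference changes
nothing in the classification; the constant only fixes which way the
curves in plots point.  Values are masked where either band is masked or
the band sum is non-positive (the ratio is only meaningful for positive
radiometry).  An annual series has *n* = 46 composites.

**Reference curve.**  The desertified class's mean NDDI trajectory is
taken over *pure pixels*: 1 km cells whose fine-resolution desertified
fraction strictly exceeds 0.70 (vegetation/others: 0.90).  The raw
46-point curve is smoothed with a Savitzky–Golay filter, default window 5
and order 2 — the shortest window with the classic (−3, 12, 17, 12, −3)/35
weight structure, a deliberately light touch for a 46-point annual
curve.  Endpoints are handled by fitting the polynomial to the truncated
terminal window (`scipy.signal.savgol_filter(mode="interp")`).

**Matching and thresholding.**  Each pixel's Mean Absolute Distance to
the filtered reference,

    MAD_ij = (1/n) Σ_{k=1..n} |NDDI_ijk − ref_k|,

is small where annual dynamics resemble desertified land.  Missing
composites are handled by averaging over the available ones (n replaced
by the available count); pixels with under 80 % of composites present are
flagged and masked.  The binary map uses a p-tile threshold: the
empirical MAD quantile (linear interpolation, for bit-reproducibility) at
a *prior* desertified-area fraction, normally taken from official survey
totals.  Classification is inclusive at the boundary (MAD ≤ threshold →
desertified).  Area is pixel count × metric cell area; relative error
against survey figures is reported rounded half-up to two decimals.

Whether the reference curve should be rebuilt each year or frozen from a
base year is genuinely open; the pipeline rebuilds per year by default
and `DesertificationMapper` can be fitted once and reused to freeze it.

## Scale linkage

Fine-resolution class maps come from a polynomial-kernel SVM (degree 2 by
default, C = 10, inhomogeneous kernel with coef0 = 1, features
standardised) trained on ~33 labelled field points, stratified over
classes.  A coarse grid frame with unique row-major cell identities
converts the fine map into per-cell class fractions; fractions over valid
classes sum to 1 for every cell with at least one unmasked fine pixel.
The "vegetation (others)" 90 % purity rule is applied to each class
separately.  Band-pair separability — the sum over classes of the
Pearson correlation between two bands' mean pure-pixel time series,
ranked ascending — justifies using the red/NIR pair for the index: the
most complementary pair has the lowest total correlation.

## Pan-sharpening comparison

Three classical fusers are compared: PCA component substitution (pan
matched to the first component's mean/variance, and oriented to correlate
positively with it, before substitution — this makes the substitution an
exact identity when pan *is* the first component), per-pixel
multiplicative fusion, and the three-band Brovey transform (bands 2–4 by
default; the fused bands sum to pan identically).  Quality metrics are
per-band mean, standard deviation, Shannon entropy over 256 equal-width
bins spanning the observed range (invariant under affine rescaling;
consistent with 8-bit-style binning), and Pearson correlation with the
raw band.  The selection rule codifies a two-step elimination: methods
whose mean or standard deviation drift more than a factor 10 (config)
from the raw image are discarded — this removes multiplicative fusion,
whose values live on a product scale — and the survivor with the highest
mean entropy + correlation wins.  On the synthetic pairs this selects
PCA.  Note that per individual band the Brovey ratio bands can correlate
with the raw image *more* strongly than PCA's; the aggregate
entropy + correlation criterion, not a per-band dominance, is the claim
the package makes and tests.

## Convergent cross mapping

CCM tests whether X forces Y by asking whether Y's reconstructed state
space encodes X.  Y is embedded in lagged coordinates
(x_t, x_{t−τ}, …, x_{t−(E−1)τ}); for each target vector the E+1 nearest
library neighbours (Euclidean) predict the concurrent X value with
weights w_i ∝ exp(−d_i/d_min) (uniform over exact matches when
d_min = 0); skill ρ is the Pearson correlation between predictions and
observations.  Forcing is inferred when ρ *converges*: it increases as
the library grows.

Annual panels are short (15 years per site), so single-site libraries
cannot converge; lagged vectors are pooled across sites into one
composite library, and vectors never span site boundaries.  Variables
are z-scored across the panel before embedding to keep units out of the
distance metric.  τ defaults to 1 (annual sampling); E is chosen from
{2, 3, 4} by leave-one-out univariate simplex self-prediction (ties to
the smallest E; more dimensions are not supportable from 15-year
series).  Bootstrap iterations resample pooled vectors with replacement
(a flag resamples whole sites instead); skill curves report mean ± sd
over 1000 iterations by default.  Significance is the paired bootstrap
convergence test p = Pr[ρ(L_max) ≤ ρ(L_min)], the published procedure
for multispatial CCM on ecological panels.

## Synthetic data: what it emulates and what it does not

`generate_scene` builds a three-class landscape (desertified /
vegetation / others) as a smoothed Gaussian random field thresholded at
rank quantiles, so class fractions are exact by construction.  The coarse
reflectance composites are class-fraction-weighted signature mixtures —
algebraically identical to block means of the implied fine signature
field, which keeps the generator consistent with the package's own
block-mean resampler — plus i.i.d. Gaussian noise (default sd 0.05
reflectance, clipped to stay positive).  Vegetation phenology is a single
mid-season Gaussian pulse in NIR with a matching slight red darkening;
desertified signatures are flat.  The fine four-band scene and its
panchromatic mate (a weighted band sum) are produced on a ×1000
digital-number scale, as fine optical scenes are delivered, which is what
makes the multiplicative fuser's product-scale distortion visible.  The
default scene is 100 coarse cells squared at 1 km with a ×4 fine and a
further ×2 pan refinement — large enough for stable statistics, small
enough that the full chain runs in seconds.

`generate_coupled_panel` iterates the standard coupled logistic maps

    X_{t+1} = X_t (r_x − r_x X_t − β_xy Y_t)
    Y_{t+1} = Y_t (r_y − r_y Y_t − β_yx X_t)

per site (r_x = 3.8, r_y = 3.5, β_yx = 0.1 ≫ β_xy = 0.02, observation
noise sd 0.01, 100-step burn-in, 40 sites × 15 years by default), so the
true forcing direction is known.

Passing tests on these generators shows the algorithms are implemented
correctly and the pipeline recovers known truth under the stated
conditions.  It does **not** show field performance: real scenes have
mixed pixels at sub-fine scale, spatially and temporally correlated
noise, clouds and atmospheric residue, multi-modal class spectra,
geolocation error, and survey priors that are themselves uncertain.  Real
annual panels are shorter and noisier than the logistic system and their
couplings drift.  Published thresholds (such as a MAD cut of 0.051) and
P-values from real records are therefore not reproduced here.

## Numerical choices

- Pixel convention: 0-based (row, col), row 0 north, half-open cell
  extents; resampling requires exact integer nesting and shared origins —
  misalignment is an error, never silently snapped.
- Rasters are stored as TIFF with geometry, band labels, nodata value and
  optional MOD09-style scale factor in a JSON `ImageDescription` tag;
  files without geometry metadata are rejected rather than defaulted.
- Quantiles use linear interpolation; a degenerate all-equal MAD map
  returns its value with a warning.
- Zero-variance inputs raise errors (never NaN) in correlation and PCA
  fusion; Brovey zero band-sum pixels are masked and counted in the log.
- All stochastic steps take explicit seeds; identical configs and seeds
  give byte-identical CSV outputs.

## Benchmark problem sizes

The standing benchmarks (`aeoscan.evaluation`, run by
`scripts/acceptance.py`) use: 100 random series for the MAD loop oracle;
10⁴ values for p-tile calibration; five 100×100-cell scenes (noise sd
0.05, desertified fraction 0.3) for end-to-end recovery; twenty 40-site ×
15-year coupled panels at 200 bootstrap iterations for direction
recovery — sizes chosen so the whole battery completes in about two
minutes on one core while keeping the statistics stable.

## Known limitations

- No reprojection or arbitrary-polygon clipping; grids must nest.
- Fusion covers the three compared methods only (no wavelet or
  Gram-Schmidt sharpening).
- The classifier is the polynomial SVM the workflow specifies; no
  alternative classifiers.
- CCM implements simplex cross-mapping with the convergence test; Granger
  causality and S-map nonlinearity tests are out of scope.
- Severity grading of desertification is binary.
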