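"""NDDI computation, reference-curve matching and desertified-area accounting.

The monitoring core works on annual stacks of 8-day composite reflectance
(46 composites per year).  A Normalized Difference Desertification Index

    NDDI = (band1 - band2) / (band1 + band2)

(red minus near-infrared over their sum — the negative of NDVI) is computed
per pixel and composite, so that sparsely vegetated, desertified surfaces
score high and stay flat through the season while vegetated surfaces dip
strongly mid-season.  The mean NDDI trajectory over pure desertified cells,
smoothed with a Savitzky–Golay filter, is the class reference curve; each
pixel's Mean Absolute Distance (MAD) to that curve,

    MAD_ij = (1/n) * sum_k |NDDI_ijk - ref_k|,        n = 46,

measures how desert-like its annual dynamics are (lower = closer).  A
p-tile threshold — the empirical quantile at a prior desertified-area
fraction — turns the MAD map into a binary desertification map, from which
areas and relative errors against survey figures are reported.

The sign convention is a single module constant; MAD matching is invariant
under a sign flip applied consistently to cube and reference, so the
convention cannot change the classification.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter
from sklearn.base import BaseEstimator

from .landcover import PurePixelSet
from .raster_core import ClassMap, GridGeometry, Legend

__all__ = [
    "COMPOSITES_PER_YEAR",
    "NDDICube",
    "ReferenceCurve",
    "MADMap",
    "AreaRecord",
    "compute_nddi",
    "build_nddi_cube",
    "build_reference_curve",
    "savitzky_golay",
    "compute_mad",
    "ptile_threshold",
    "classify_desertified",
    "area_estimate",
    "relative_error",
    "DesertificationMapper",
]

log = logging.getLogger(__name__)

#: composites per year in the 8-day compositing calendar
COMPOSITES_PER_YEAR = 46

#: orientation of the index: +1 -> (band1 - band2)/(band1 + band2)
NDDI_SIGN = +1


@dataclass
class NDDICube:
    """Per-pixel NDDI time series over one year of composites.

    ``values`` is (n_composites, rows, cols) with NaN at masked entries;
    an entry is masked where either input band was masked or the band sum
    was non-positive.
    """

    geometry: GridGeometry
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3 or self.values.shape[1:] != self.geometry.shape:
            raise ValueError("values must be (time, rows, cols) matching the geometry")

    @property
    def n_composites(self) -> int:
        return int(self.values.shape[0])


@dataclass
class ReferenceCurve:
    """Mean NDDI trajectory of a class, raw and Savitzky–Golay filtered."""

    raw: np.ndarray
    filtered: np.ndarray
    class_label: int
    window: int
    order: int

    def __post_init__(self) -> None:
        self.raw = np.asarray(self.raw, dtype=float)
        self.filtered = np.asarray(self.filtered, dtype=float)
        if self.raw.shape != self.filtered.shape:
            raise ValueError("raw and filtered curves must have the same length")

    def __len__(self) -> int:
        return len(self.raw)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"k": np.arange(1, len(self.raw) + 1), "raw": self.raw, "filtered": self.filtered}
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


@dataclass
class MADMap:
    """Per-pixel mean absolute distance to a reference curve (NaN = masked)."""

    geometry: GridGeometry
    values: np.ndarray
    threshold: float | None = None
    prior_fraction: float | None = None
    low_coverage: np.ndarray | None = None  # pixels with <80% composites present

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.geometry.shape:
            raise ValueError("MAD plane shape does not match geometry")

    @property
    def valid_mask(self) -> np.ndarray:
        return np.isfinite(self.values)


@dataclass
class AreaRecord:
    year: int
    estimated_area_km2: float
    investigated_area_km2: float

    @property
    def relative_error_pct(self) -> float:
        return relative_error(self.estimated_area_km2, self.investigated_area_km2)


def compute_nddi(band1: np.ndarray, band2: np.ndarray) -> np.ndarray:
    """Normalized difference of two reflectance planes.

    Returns ``sign * (band1 - band2) / (band1 + band2)`` with NaN wherever
    either input is NaN or the band sum is non-positive (the ratio is only
    meaningful for positive radiometry).
    """
    band1 = np.asarray(band1, dtype=float)
    band2 = np.asarray(band2, dtype=float)
    if band1.shape != band2.shape:
        raise ValueError("band planes must share a geometry")
    total = band1 + band2
    with np.errstate(divide="ignore", invalid="ignore"):
        out = NDDI_SIGN * (band1 - band2) / total
    out = np.where(total > 0, out, np.nan)
    return out


def build_nddi_cube(series: np.ndarray, geometry: GridGeometry) -> NDDICube:
    """NDDI cube from a (time, 2, rows, cols) reflectance series (band1, band2)."""
    series = np.asarray(series, dtype=float)
    if series.ndim != 4 or series.shape[1] < 2:
        raise ValueError("series must be (time, >=2 bands, rows, cols)")
    values = compute_nddi(series[:, 0], series[:, 1])
    return NDDICube(geometry=geometry, values=values)


def savitzky_golay(series: np.ndarray, window: int = 5, order: int = 2) -> np.ndarray:
    """Savitzky–Golay smoothing of a 1-D series.

    Local least-squares polynomial fit of the given order over a sliding
    window; endpoints are handled by fitting a polynomial to the truncated
    terminal window and evaluating it there.  The filter reproduces any
    polynomial of degree <= order exactly.
    """
    series = np.asarray(series, dtype=float)
    n = series.shape[-1]
    if window % 2 == 0 or window < 3 or window > n:
        raise ValueError(f"window must be odd and within [3, {n}], got {window}")
    if order >= window:
        raise ValueError("polynomial order must be smaller than the window")
    return savgol_filter(series, window_length=window, polyorder=order, mode="interp")


def build_reference_curve(
    cube: NDDICube,
    pure: PurePixelSet,
    class_label: int = Legend.DESERTIFIED,
    window: int = 5,
    order: int = 2,
) -> ReferenceCurve:
    """Mean NDDI trajectory over a class's pure cells, then smoothed.

    ``raw[k]`` is the mean over the class's pure coarse cells of the NDDI
    at composite k (masked entries ignored).
    """
    rows, cols = pure.rowcols_of(class_label)
    if len(rows) == 0:
        raise ValueError(
            f"no pure cells of class {Legend.NAMES.get(class_label, class_label)}"
        )
    samples = cube.values[:, rows, cols]  # (time, n_cells)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        raw = np.nanmean(samples, axis=1)
    if np.any(~np.isfinite(raw)):
        raise ValueError("reference curve undefined: a composite has no valid pure-cell NDDI")
    filtered = savitzky_golay(raw, window=window, order=order)
    return ReferenceCurve(
        raw=raw, filtered=filtered, class_label=class_label, window=window, order=order
    )


def compute_mad(
    cube: NDDICube, ref: ReferenceCurve, min_coverage: float = 0.8, use_filtered: bool = True
) -> MADMap:
    """Per-pixel mean absolute distance between the cube and the reference.

    Pixels with masked composites are averaged over the available entries
    (n replaced by the available count); pixels with fewer than
    ``min_coverage`` of composites present are flagged and masked.
    """
    if cube.n_composites != len(ref):
        raise ValueError(
            f"cube has {cube.n_composites} composites but reference has {len(ref)}"
        )
    curve = ref.filtered if use_filtered else ref.raw
    diff = np.abs(cube.values - curve[:, None, None])
    present = np.isfinite(diff)
    counts = present.sum(axis=0)
    sums = np.where(present, diff, 0.0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mad = np.where(counts > 0, sums / counts, np.nan)
    low = counts < min_coverage * cube.n_composites
    mad = np.where(low, np.nan, mad)
    n_low = int(np.count_nonzero(low & (counts > 0)))
    if n_low:
        log.info("compute_mad: %d pixels below %.0f%% coverage masked", n_low, 100 * min_coverage)
    return MADMap(geometry=cube.geometry, values=mad, low_coverage=low)


def ptile_threshold(mad: MADMap, prior_fraction: float) -> float:
    """p-tile threshold: the empirical quantile of MAD at the prior fraction.

    With linear interpolation, approximately ``prior_fraction`` of the
    unmasked pixels fall at or below the returned value — the fraction of
    area assumed desertified from prior (survey) knowledge.
    """
    if not 0 < prior_fraction < 1:
        raise ValueError("prior_fraction must lie strictly between 0 and 1")
    values = mad.values[mad.valid_mask]
    if values.size == 0:
        raise ValueError("MAD map has no unmasked values")
    if values.min() == values.max():
        warnings.warn("degenerate MAD map: all values equal", stacklevel=2)
        return float(values.min())
    return float(np.quantile(values, prior_fraction))


def classify_desertified(mad: MADMap, threshold: float) -> ClassMap:
    """Binary desertification map: MAD <= threshold means desertified.

    A low MAD means the pixel's annual NDDI dynamics sit close to the
    desertified reference curve; the boundary is inclusive.  Masked MAD
    pixels stay nodata.
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    labels = np.full(mad.geometry.shape, Legend.NODATA, dtype=np.int32)
    valid = mad.valid_mask
    labels[valid & (mad.values <= threshold)] = Legend.DESERTIFIED
    labels[valid & (mad.values > threshold)] = Legend.OTHERS
    return ClassMap(geometry=mad.geometry, labels=labels)


def area_estimate(class_map: ClassMap) -> float:
    """Desertified area in km² = desertified pixel count × metric cell area."""
    cell_km2 = class_map.geometry.cell_area_km2  # raises on non-metric crs_tag
    return class_map.class_count(Legend.DESERTIFIED) * cell_km2


def relative_error(estimated_km2: float, investigated_km2: float) -> float:
    """Relative error (%) of an area estimate against survey figures.

    ``100 * |estimated - investigated| / investigated``, rounded half-up to
    two decimals for reporting.
    """
    if investigated_km2 <= 0:
        raise ValueError("investigated area must be positive")
    pct = 100.0 * abs(estimated_km2 - investigated_km2) / investigated_km2
    return float(Decimal(repr(float(pct))).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


class DesertificationMapper(BaseEstimator):
    """Reference-curve matcher: fit a class trajectory, predict a binary map.

    ``fit`` builds the smoothed desertified reference curve from an NDDI
    cube and a pure-pixel set; ``predict`` scores a cube's pixels by MAD to
    that curve and thresholds the map, either at a fixed MAD value or by
    p-tile at a prior desertified-area fraction.

    Parameters
    ----------
    prior_fraction : float or None
        Prior fraction of valid area that is desertified; used for p-tile
        threshold selection when ``threshold`` is None.
    threshold : float or None
        Fixed MAD threshold (takes precedence over the p-tile rule).
    sg_window, sg_order : Savitzky–Golay filter parameters (odd window).
    class_label : legend value whose reference curve is fitted.

    Attributes
    ----------
    reference_curve_ : ReferenceCurve
    mad_map_ : MADMap from the last ``predict`` call
    threshold_ : float, the threshold actually applied
    """

    def __init__(
        self,
        prior_fraction: float | None = None,
        threshold: float | None = None,
        sg_window: int = 5,
        sg_order: int = 2,
        class_label: int = Legend.DESERTIFIED,
    ):
        self.prior_fraction = prior_fraction
        self.threshold = threshold
        self.sg_window = sg_window
        self.sg_order = sg_order
        self.class_label = class_label

    def fit(self, cube: NDDICube, pure: PurePixelSet) -> "DesertificationMapper":
        self.reference_curve_ = build_reference_curve(
            cube, pure, class_label=self.class_label, window=self.sg_window, order=self.sg_order
        )
        return self

    def predict(self, cube: NDDICube) -> ClassMap:
        if not hasattr(self, "reference_curve_"):
            raise RuntimeError("DesertificationMapper must be fitted before predict")
        self.mad_map_ = compute_mad(cube, self.reference_curve_)
        if self.threshold is not None:
            self.threshold_ = float(self.threshold)
        elif self.prior_fraction is not None:
            self.threshold_ = ptile_threshold(self.mad_map_, self.prior_fraction)
        else:
            raise ValueError("either threshold or prior_fraction must be set")
        self.mad_map_.threshold = self.threshold_
        self.mad_map_.prior_fraction = self.prior_fraction
        return classify_desertified(self.mad_map_, self.threshold_)

    def fit_predict(self, cube: NDDICube, pure: PurePixelSet) -> ClassMap:
        return self.fit(cube, pure).predict(cube)
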