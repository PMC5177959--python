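"""Supervised land-cover classification and the fine-to-coarse linkage.

A polynomial-kernel support-vector machine labels the fine-resolution
(pan-sharpened) scene; per-grid-cell class proportions then link that fine
map to the coarse reflectance lattice.  Coarse cells dominated by a single
class — "pure pixels" — anchor the reference spectral dynamics, and a
band-pair separability ranking over pure-pixel time series justifies which
two bands enter the normalized-difference index.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

from .raster_core import BandStack, ClassMap, GridFrame, Legend

__all__ = [
    "TrainingSet",
    "PurePixelSet",
    "LandCoverClassifier",
    "train_classifier",
    "classify",
    "class_proportions",
    "select_pure_pixels",
    "band_pair_separability",
]

log = logging.getLogger(__name__)


@dataclass
class TrainingSet:
    """Labelled per-pixel spectra used as the classification interpretation key."""

    samples: np.ndarray  # (n_samples, n_bands)
    labels: np.ndarray  # (n_samples,) legend values
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.samples.ndim != 2 or len(self.samples) != len(self.labels):
            raise ValueError("samples must be (n, n_bands) with one label per row")
        if np.any(~np.isfinite(self.samples)):
            raise ValueError("training samples must not contain masked values")

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.samples, columns=[f"band{i+1}" for i in range(self.samples.shape[1])])
        df["label"] = self.labels
        if self.provenance:
            df["provenance"] = self.provenance
        return df


@dataclass
class PurePixelSet:
    """Coarse cells dominated by one class, with the thresholds that selected them."""

    table: pd.DataFrame  # columns: cell_id, row, col, class, proportion
    t_desert: float
    t_other: float

    def cells_of(self, cls: int) -> pd.DataFrame:
        return self.table[self.table["class"] == cls]

    def rowcols_of(self, cls: int) -> tuple[np.ndarray, np.ndarray]:
        sub = self.cells_of(cls)
        return sub["row"].to_numpy(), sub["col"].to_numpy()

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


class LandCoverClassifier(ClassifierMixin, BaseEstimator):
    """Maximum-margin land-cover classifier with a polynomial kernel.

    Parameters
    ----------
    kernel_degree : int, default 2
        Degree of the polynomial kernel.
    C : float, default 10.0
        Soft-margin penalty.
    scale : bool, default True
        Standardise features before the kernel; spectral bands on very
        different numeric ranges otherwise dominate the kernel.

    The classifier is deterministic given its configuration.
    """

    def __init__(self, kernel_degree: int = 2, C: float = 10.0, scale: bool = True):
        self.kernel_degree = kernel_degree
        self.C = C
        self.scale = scale

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if self.kernel_degree < 1:
            raise ValueError("kernel_degree must be >= 1")
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("training set must contain at least two classes")
        if self.scale:
            self.scaler_ = StandardScaler().fit(X)
            X = self.scaler_.transform(X)
        else:
            self.scaler_ = None
        self.svm_ = SVC(kernel="poly", degree=self.kernel_degree, coef0=1.0, C=self.C, gamma="scale")
        self.svm_.fit(X, y)
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "svm_")
        X = np.asarray(X, dtype=float)
        if self.scaler_ is not None:
            X = self.scaler_.transform(X)
        return self.svm_.predict(X)

    def classify_map(self, stack: BandStack) -> ClassMap:
        """Label every unmasked pixel of a band stack; masked pixels get nodata."""
        check_is_fitted(self, "svm_")
        if stack.n_bands != self.n_features_in_:
            raise ValueError(
                f"stack has {stack.n_bands} bands but classifier was trained on "
                f"{self.n_features_in_} features"
            )
        labels = np.full(stack.geometry.shape, Legend.NODATA, dtype=np.int32)
        valid = ~stack.nodata_mask
        if valid.any():
            X = stack.bands[:, valid].T
            labels[valid] = self.predict(X)
        return ClassMap(geometry=stack.geometry, labels=labels)


def train_classifier(train: TrainingSet, kernel_degree: int = 2, **kwargs) -> LandCoverClassifier:
    """Fit a :class:`LandCoverClassifier` on a training set."""
    return LandCoverClassifier(kernel_degree=kernel_degree, **kwargs).fit(train.samples, train.labels)


def classify(model: LandCoverClassifier, stack: BandStack) -> ClassMap:
    """Apply a fitted classifier to a band stack."""
    return model.classify_map(stack)


def class_proportions(class_map: ClassMap, frame: GridFrame) -> GridFrame:
    """Per-coarse-cell class fractions among the cell's unmasked fine pixels.

    Fractions over valid classes sum to 1 for every cell containing at
    least one unmasked pixel; cells with no unmasked pixel are flagged
    invalid and carry NaN proportions.
    """
    fine, coarse = class_map.geometry, frame.geometry
    fr = fine.n_rows // coarse.n_rows
    fc = fine.n_cols // coarse.n_cols
    if (
        coarse.n_rows * fr != fine.n_rows
        or coarse.n_cols * fc != fine.n_cols
        or abs(coarse.cell_size_x - fine.cell_size_x * fc) > 1e-6
        or abs(coarse.cell_size_y - fine.cell_size_y * fr) > 1e-6
    ):
        raise ValueError("grid frame does not nest integrally over the class map")
    blocks = (
        class_map.labels.reshape(coarse.n_rows, fr, coarse.n_cols, fc)
        .swapaxes(1, 2)
        .reshape(coarse.n_rows, coarse.n_cols, -1)
    )
    n_valid = (blocks != Legend.NODATA).sum(axis=-1)
    proportions: dict[int, np.ndarray] = {}
    for cls in Legend.VALID:
        counts = (blocks == cls).sum(axis=-1)
        proportions[cls] = np.divide(
            counts, n_valid, out=np.full(counts.shape, np.nan), where=n_valid > 0
        )
    valid = n_valid > 0
    if not valid.all():
        log.info("class_proportions: %d all-masked cells flagged", int((~valid).sum()))
    return GridFrame(
        geometry=coarse, cell_ids=frame.cell_ids.copy(), proportions=proportions, valid=valid
    )


def select_pure_pixels(
    frame: GridFrame, t_desert: float = 0.70, t_other: float = 0.90
) -> PurePixelSet:
    """Select coarse cells dominated by a single class.

    A cell is pure desertified when its desertified fraction is strictly
    greater than ``t_desert``; pure vegetation (others) when that class's
    fraction is strictly greater than ``t_other``.  Cells meeting no rule
    are left unassigned.
    """
    if not frame.proportions:
        raise ValueError("grid frame proportions are not populated")
    thresholds = {
        Legend.DESERTIFIED: t_desert,
        Legend.VEGETATION: t_other,
        Legend.OTHERS: t_other,
    }
    valid = frame.valid if frame.valid is not None else np.ones(frame.geometry.shape, bool)
    records = []
    for cls, thr in thresholds.items():
        plane = frame.proportions.get(cls)
        if plane is None:
            continue
        hit = valid & (plane > thr)
        rows, cols = np.nonzero(hit)
        for r, c in zip(rows, cols):
            records.append(
                {
                    "cell_id": int(frame.cell_ids[r, c]),
                    "row": int(r),
                    "col": int(c),
                    "class": cls,
                    "proportion": float(plane[r, c]),
                }
            )
    table = pd.DataFrame(records, columns=["cell_id", "row", "col", "class", "proportion"])
    if table.empty:
        log.warning("no pure pixels found at thresholds >%s / >%s", t_desert, t_other)
    return PurePixelSet(table=table, t_desert=t_desert, t_other=t_other)


def band_pair_separability(
    series: np.ndarray,
    pure: PurePixelSet,
    band_labels: list[str] | None = None,
) -> pd.DataFrame:
    """Rank band pairs by total cross-class correlation of their dynamics.

    ``series`` is a (time, band, row, col) reflectance array on the coarse
    grid.  For every band pair and class, the two bands' mean time series
    over that class's pure cells are correlated; the pair's total r is the
    sum over classes.  Low total r means the two bands respond differently
    across land covers — the most complementary pair (ranked first) is the
    natural choice for a normalized-difference index.  Pairs where any
    class series is constant are flagged and excluded from the ranking.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 4:
        raise ValueError("series must be (time, band, row, col)")
    n_bands = series.shape[1]
    if n_bands < 2:
        raise ValueError("need at least two bands")
    labels = band_labels or [f"band{i+1}" for i in range(n_bands)]
    classes = sorted(pure.table["class"].unique())
    if not classes:
        raise ValueError("pure pixel set is empty")
    # mean series per (class, band)
    mean_series: dict[tuple[int, int], np.ndarray] = {}
    for cls in classes:
        rows, cols = pure.rowcols_of(cls)
        for b in range(n_bands):
            mean_series[(cls, b)] = np.nanmean(series[:, b, rows, cols], axis=1)
    records = []
    for i in range(n_bands):
        for j in range(i + 1, n_bands):
            total_r = 0.0
            degenerate = False
            for cls in classes:
                si, sj = mean_series[(cls, i)], mean_series[(cls, j)]
                if si.std() == 0 or sj.std() == 0:
                    degenerate = True
                    break
                total_r += float(np.corrcoef(si, sj)[0, 1])
            records.append(
                {
                    "band_a": labels[i],
                    "band_b": labels[j],
                    "total_r": np.nan if degenerate else total_r,
                    "degenerate": degenerate,
                }
            )
    df = pd.DataFrame(records)
    df = df.sort_values(
        by=["degenerate", "total_r"], ascending=[True, True], na_position="last"
    ).reset_index(drop=True)
    df["rank"] = np.where(df["degenerate"], np.nan, np.arange(1, len(df) + 1, dtype=float))
    # ranks only count non-degenerate pairs
    n_ok = int((~df["degenerate"]).sum())
    df.loc[~df["degenerate"], "rank"] = np.arange(1, n_ok + 1, dtype=float)
    return df
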