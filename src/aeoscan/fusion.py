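"""Pan-sharpening algorithms and image-fusion quality metrics.

Three classical fusion methods are provided — PCA substitution,
multiplicative, and the Brovey transform — together with the four quality
indices commonly used to compare them: per-band mean, standard deviation,
Shannon entropy of the quantised histogram, and Pearson correlation against
the raw multispectral band.  :func:`compare_fusions` runs all three and
applies a two-step selection rule: methods whose mean or standard deviation
drift more than a configurable factor from the raw image are eliminated
(this removes the multiplicative method, whose values live on a product
scale), and the survivor with the best entropy + correlation ranking is
chosen.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .raster_core import BandStack, upsample

__all__ = [
    "FusionReport",
    "fuse_pca",
    "fuse_multiplicative",
    "fuse_brovey",
    "image_entropy",
    "band_correlation",
    "compare_fusions",
    "principal_component_scores",
]

log = logging.getLogger(__name__)


def _prepare_pair(ms: BandStack, pan: BandStack) -> tuple[BandStack, BandStack]:
    """Upsample ``ms`` onto the pan grid; validate the pair."""
    if pan.n_bands != 1:
        raise ValueError(f"pan must be single-band, got {pan.n_bands} bands")
    if ms.geometry.shape != pan.geometry.shape:
        ms = upsample(ms, pan.geometry)
    return ms, pan


def _joint_valid(ms: BandStack, pan: BandStack) -> np.ndarray:
    return ~(ms.nodata_mask | pan.nodata_mask)


def principal_component_scores(ms: BandStack) -> np.ndarray:
    """Scores of the first principal component of the band space.

    Returned as a plane on the ms grid (NaN where masked).  Useful for
    constructing a pan band that is exactly the first component, in which
    case PCA fusion is an identity.
    """
    valid = ~ms.nodata_mask
    X = ms.bands[:, valid].T
    mean = X.mean(axis=0)
    Xc = X - mean
    _, _, vt = np.linalg.svd(Xc, full_matrices=False)
    plane = np.full(ms.geometry.shape, np.nan)
    plane[valid] = Xc @ vt[0]
    return plane


def fuse_pca(ms: BandStack, pan: BandStack, upsample_method: str = "nearest") -> BandStack:
    """Component-substitution fusion.

    The multispectral bands are rotated into principal components, the pan
    band — rescaled to the first component's mean and standard deviation —
    replaces that component, and the rotation is inverted.  Band count and
    geometry are preserved.
    """
    del upsample_method  # block replication is the only nested upsampler
    ms, pan = _prepare_pair(ms, pan)
    valid = _joint_valid(ms, pan)
    X = ms.bands[:, valid].T  # (n_pixels, n_bands)
    mean = X.mean(axis=0)
    Xc = X - mean
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    if s[0] <= 1e-12 * max(1.0, abs(mean).max()):
        raise ValueError("multispectral bands have zero variance; PCA fusion undefined")
    scores = Xc @ vt.T
    p = pan.bands[0][valid]
    # orient the first component to correlate positively with pan, so the
    # substituted band injects spatial detail with the right sign
    if np.dot(scores[:, 0] - scores[:, 0].mean(), p - p.mean()) < 0:
        scores[:, 0] *= -1
        vt = vt.copy()
        vt[0] *= -1
    p_std = p.std()
    if p_std == 0:
        raise ValueError("pan band has zero variance")
    pc1 = scores[:, 0]
    matched = (p - p.mean()) / p_std * pc1.std() + pc1.mean()
    scores[:, 0] = matched
    fused = scores @ vt + mean
    out = np.zeros_like(ms.bands)
    out[:, valid] = fused.T
    return BandStack(
        geometry=ms.geometry,
        bands=out,
        band_labels=list(ms.band_labels),
        nodata_mask=~valid,
    )


def fuse_multiplicative(ms: BandStack, pan: BandStack) -> BandStack:
    """Per-pixel product ``fused_b = ms_b * pan`` (values land on a product scale)."""
    ms, pan = _prepare_pair(ms, pan)
    valid = _joint_valid(ms, pan)
    out = ms.bands * pan.bands[0][None]
    out[:, ~valid] = 0.0
    return BandStack(
        geometry=ms.geometry,
        bands=out,
        band_labels=list(ms.band_labels),
        nodata_mask=~valid,
    )


def fuse_brovey(
    ms: BandStack, pan: BandStack, band_indices: tuple[int, int, int] = (1, 2, 3)
) -> BandStack:
    """Brovey transform on three selected bands.

    ``fused_b = pan * ms_b / sum_b ms_b`` so the fused bands sum to the pan
    value at every pixel.  Pixels whose three-band sum is zero cannot be
    ratioed and are masked (counted in the log).
    """
    if len(band_indices) != 3:
        raise ValueError("Brovey transform operates on exactly three bands")
    ms, pan = _prepare_pair(ms, pan)
    sel = ms.bands[list(band_indices)]
    total = sel.sum(axis=0)
    valid = _joint_valid(ms, pan)
    zero_sum = valid & (total == 0)
    n_zero = int(np.count_nonzero(zero_sum))
    if n_zero:
        log.warning("Brovey transform: %d zero band-sum pixels masked", n_zero)
    valid = valid & ~zero_sum
    with np.errstate(divide="ignore", invalid="ignore"):
        out = pan.bands[0][None] * sel / total[None]
    out[:, ~valid] = 0.0
    labels = [ms.band_labels[i] for i in band_indices]
    return BandStack(
        geometry=ms.geometry, bands=out, band_labels=labels, nodata_mask=~valid
    )


def image_entropy(plane: np.ndarray, n_bins: int = 256, mask: np.ndarray | None = None) -> float:
    """Shannon entropy (bits) of the plane quantised into equal-width bins.

    Binning follows the observed value range, so the entropy is invariant
    under monotone affine rescaling.  A constant plane occupies one bin and
    has zero entropy.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be at least 2")
    values = np.asarray(plane, dtype=float).ravel()
    if mask is not None:
        values = values[~np.asarray(mask).ravel()]
    values = values[np.isfinite(values)]
    if values.size == 0:
        raise ValueError("entropy of an all-masked plane is undefined")
    lo, hi = values.min(), values.max()
    if lo == hi:
        return 0.0
    counts, _ = np.histogram(values, bins=n_bins, range=(lo, hi))
    p = counts[counts > 0] / values.size
    return float(-(p * np.log2(p)).sum())


def band_correlation(a: np.ndarray, b: np.ndarray, mask: np.ndarray | None = None) -> float:
    """Pearson correlation over jointly unmasked pixels."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("planes must share a geometry")
    keep = np.isfinite(a) & np.isfinite(b)
    if mask is not None:
        keep &= ~np.asarray(mask).ravel()
    a, b = a[keep], b[keep]
    if a.size < 2:
        raise ValueError("need at least two jointly unmasked pixels")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero-variance plane: correlation undefined")
    return float(np.corrcoef(a, b)[0, 1])


@dataclass
class FusionReport:
    """Per-(method, band) quality metrics plus the selected method.

    ``table`` has columns method, band, mean, std, entropy, correlation;
    the raw multispectral image appears as method ``"raw"`` (correlation
    with itself omitted).  The Brovey rows cover only its three ratio
    bands, mirroring the three-band nature of the transform.
    """

    table: pd.DataFrame
    chosen_method: str

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def compare_fusions(
    ms: BandStack,
    pan: BandStack,
    n_bins: int = 256,
    distortion_factor: float = 10.0,
    brovey_bands: tuple[int, int, int] = (1, 2, 3),
) -> FusionReport:
    """Run all three fusion methods and select one.

    Selection: a method is eliminated when any band's fused mean or
    standard deviation differs from the raw band's by more than
    ``distortion_factor`` (×), then the surviving method with the highest
    mean (entropy + correlation) across its bands is chosen.
    """
    ms_up, pan = _prepare_pair(ms, pan)
    fusers = {
        "PCA": lambda: fuse_pca(ms_up, pan),
        "multiplicative": lambda: fuse_multiplicative(ms_up, pan),
        "Brovey": lambda: fuse_brovey(ms_up, pan, band_indices=brovey_bands),
    }
    fused = {}
    for name, fn in fusers.items():
        try:
            fused[name] = fn()
        except ValueError as exc:
            log.warning("fusion method %s skipped: %s", name, exc)
    if not fused:
        raise ValueError("no fusion method applicable to this pair")
    rows = []
    valid = _joint_valid(ms_up, pan)
    for label in ms_up.band_labels:
        plane = ms_up.band(label)
        rows.append(
            {
                "method": "raw",
                "band": label,
                "mean": float(plane[valid].mean()),
                "std": float(plane[valid].std()),
                "entropy": image_entropy(plane, n_bins, mask=~valid),
                "correlation": np.nan,
            }
        )
    for name, stack in fused.items():
        ok = ~stack.nodata_mask
        for label in stack.band_labels:
            plane = stack.band(label)
            rows.append(
                {
                    "method": name,
                    "band": label,
                    "mean": float(plane[ok].mean()),
                    "std": float(plane[ok].std()),
                    "entropy": image_entropy(plane, n_bins, mask=~ok),
                    "correlation": band_correlation(plane, ms_up.band(label), mask=~ok),
                }
            )
    table = pd.DataFrame(rows)

    raw = table[table.method == "raw"].set_index("band")
    surviving = []
    for name in fused:
        sub = table[table.method == name].set_index("band")
        ratio_mean = (sub["mean"] / raw.loc[sub.index, "mean"]).abs()
        ratio_std = (sub["std"] / raw.loc[sub.index, "std"]).abs()
        distorted = bool(
            ((ratio_mean > distortion_factor) | (ratio_mean < 1 / distortion_factor)).any()
            or ((ratio_std > distortion_factor) | (ratio_std < 1 / distortion_factor)).any()
        )
        if not distorted:
            surviving.append(name)
    if not surviving:
        surviving = list(fused)
        log.warning("all fusion methods exceeded the mean/std distortion gate")
    scores = {
        name: float(
            (table[table.method == name]["entropy"] + table[table.method == name]["correlation"])
            .mean()
        )
        for name in surviving
    }
    chosen = max(scores, key=scores.get)
    return FusionReport(table=table, chosen_method=chosen)
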