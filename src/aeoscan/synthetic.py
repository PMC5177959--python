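"""Synthetic scenes and panels with known ground truth.

Everything the monitoring and attribution pipeline consumes can be
generated here with a controlled truth manifest:

* :func:`generate_scene` — a three-class landscape observed twice: as a
  fine four-band multispectral image with a panchromatic band (digital
  numbers, emulating a high-resolution optical scene) and as a coarse
  two-band reflectance time series of 46 eight-day composites per year
  (emulating 500 m surface-reflectance composites aggregated to a 1 km
  lattice).  Desertified land has high red, weak near-infrared and flat
  seasonality; vegetation has strong near-infrared with a mid-season
  phenology bump (so its red−NIR index dips sharply); "others" sit in
  between.  The coarse composites are exact block means of the implied
  fine reflectance field plus observation noise, so the generator is
  consistent with the package's own block-mean resampler.

* :func:`generate_coupled_panel` — per-site coupled logistic maps, the
  standard validation system for cross-mapping causality: the coupling
  strengths are known, so the true forcing direction is in the manifest.

* :func:`generate_training_points` — stratified labelled pixels emulating
  fieldwork interpretation keys.

All randomness flows through one seeded generator per call; identical
specs and seeds give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .landcover import TrainingSet
from .nddi_mad import COMPOSITES_PER_YEAR
from .raster_core import BandStack, ClassMap, GridGeometry, Legend

__all__ = [
    "SceneSpec",
    "CoupledSystemSpec",
    "Scene",
    "generate_scene",
    "generate_coupled_panel",
    "generate_training_points",
]

#: per-class reflectance signatures for the two coarse (index) bands.
#: band1 = red, band2 = near-infrared; "bump" is a mid-season Gaussian
#: phenology pulse added to the NIR band (single growing season).
_COARSE_SIGNATURES = {
    Legend.DESERTIFIED: {"red": 0.38, "nir": 0.30, "bump": 0.00},
    Legend.VEGETATION: {"red": 0.08, "nir": 0.25, "bump": 0.25},
    Legend.OTHERS: {"red": 0.22, "nir": 0.26, "bump": 0.06},
}

#: per-class mean digital numbers for the fine four-band scene
#: (blue, green, red, nir) — reflectance-like values on a x1000 DN scale.
_FINE_SIGNATURES = {
    Legend.DESERTIFIED: (320.0, 360.0, 420.0, 380.0),
    Legend.VEGETATION: (60.0, 120.0, 80.0, 460.0),
    Legend.OTHERS: (180.0, 230.0, 250.0, 320.0),
}

_PAN_WEIGHTS = (0.1, 0.3, 0.3, 0.3)


@dataclass
class SceneSpec:
    """Layout and radiometry of a synthetic scene.

    ``desertified_fraction``/``vegetation_fraction`` are exact coarse-cell
    fractions (the remainder is "others").  ``noise_sd`` is the Gaussian
    observation noise on coarse reflectance; ``fine_noise_sd`` the DN noise
    on the fine bands.  ``fine_mixing`` reassigns that fraction of fine
    pixels to a random class, so coarse cells are not all perfectly pure.
    """

    n_rows: int = 100
    n_cols: int = 100
    coarse_cell: float = 1000.0
    fine_factor: int = 4
    pan_factor: int = 2
    n_composites: int = COMPOSITES_PER_YEAR
    desertified_fraction: float = 0.3
    vegetation_fraction: float = 0.4
    noise_sd: float = 0.05
    fine_noise_sd: float = 15.0
    fine_mixing: float = 0.05
    patch_smoothness: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.desertified_fraction + self.vegetation_fraction <= 1:
            raise ValueError("class fractions must sum to at most 1")
        if self.fine_factor < 1 or self.pan_factor < 1:
            raise ValueError("resolution factors must be positive integers")


@dataclass
class CoupledSystemSpec:
    """Coupled logistic maps, one pair per site.

    ``beta_yx`` is the strength with which X forces Y (the coupling the
    cross-map test should detect as X → Y); ``beta_xy`` the reverse.
    """

    n_sites: int = 40
    n_years: int = 15
    r_x: float = 3.8
    r_y: float = 3.5
    beta_yx: float = 0.1
    beta_xy: float = 0.02
    noise_sd: float = 0.01
    burn_in: int = 100
    cause_name: str = "wind_speed"
    effect_name: str = "desertified_area"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.beta_xy < 0 or self.beta_yx < 0:
            raise ValueError("coupling strengths must be nonnegative")


@dataclass
class Scene:
    """A generated scene plus its truth manifest."""

    fine_ms: BandStack
    pan: BandStack
    coarse_series: np.ndarray  # (time, 2, rows, cols) reflectance
    coarse_geometry: GridGeometry
    truth_fine: ClassMap
    truth_coarse: ClassMap
    truth_area_km2: float
    manifest: dict = field(default_factory=dict)


def _seasonal_profiles(n_composites: int) -> dict[int, np.ndarray]:
    """Per-class (red, nir) signature trajectories, shape (2, n_composites)."""
    k = np.arange(1, n_composites + 1)
    mid = (n_composites + 1) / 2.0
    pulse = np.exp(-0.5 * ((k - mid) / (n_composites / 8.0)) ** 2)
    profiles = {}
    for cls, sig in _COARSE_SIGNATURES.items():
        red = np.full(n_composites, sig["red"])
        nir = sig["nir"] + sig["bump"] * pulse
        # vegetation greening also darkens the red band slightly
        red = red - 0.3 * sig["bump"] * pulse
        profiles[cls] = np.vstack([red, nir])
    return profiles


def _coarse_class_layout(spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    """Spatially correlated class map with exact class counts."""
    field_ = rng.standard_normal((spec.n_rows, spec.n_cols))
    field_ = gaussian_filter(field_, sigma=spec.patch_smoothness)
    order = np.argsort(field_.ravel())
    n = field_.size
    n_desert = round(spec.desertified_fraction * n)
    n_veg = round(spec.vegetation_fraction * n)
    labels = np.full(n, Legend.OTHERS, dtype=np.int32)
    labels[order[:n_desert]] = Legend.DESERTIFIED
    labels[order[n_desert : n_desert + n_veg]] = Legend.VEGETATION
    return labels.reshape(spec.n_rows, spec.n_cols)


def fine_reflectance_plane(
    fine_labels: np.ndarray, composite_k: int, band: int, n_composites: int = COMPOSITES_PER_YEAR
) -> np.ndarray:
    """Noise-free fine reflectance implied by a class layout.

    The coarse composites are block means of exactly this field; exposed
    so consistency with the block-mean resampler can be checked directly.
    """
    profiles = _seasonal_profiles(n_composites)
    out = np.zeros(fine_labels.shape)
    for cls, prof in profiles.items():
        out[fine_labels == cls] = prof[band, composite_k - 1]
    return out


def generate_scene(spec: SceneSpec) -> Scene:
    """Generate a scene per the spec; see the module docstring for the model."""
    rng = np.random.default_rng(spec.seed)
    coarse_labels = _coarse_class_layout(spec, rng)
    f = spec.fine_factor
    fine_labels = np.repeat(np.repeat(coarse_labels, f, axis=0), f, axis=1)
    if spec.fine_mixing > 0:
        mix = rng.random(fine_labels.shape) < spec.fine_mixing
        fine_labels = fine_labels.copy()
        fine_labels[mix] = rng.choice(
            np.asarray(Legend.VALID, dtype=np.int32), size=int(mix.sum())
        )

    coarse_geom = GridGeometry(
        origin_x=0.0,
        origin_y=spec.n_rows * spec.coarse_cell,
        cell_size_x=spec.coarse_cell,
        cell_size_y=spec.coarse_cell,
        n_rows=spec.n_rows,
        n_cols=spec.n_cols,
        crs_tag="metre:local",
    )
    fine_geom = coarse_geom.to_dict() | {
        "cell_size_x": spec.coarse_cell / f,
        "cell_size_y": spec.coarse_cell / f,
        "n_rows": spec.n_rows * f,
        "n_cols": spec.n_cols * f,
    }
    fine_geom = GridGeometry.from_dict(fine_geom)

    # ---- coarse reflectance time series: block mean of the fine field + noise
    profiles = _seasonal_profiles(spec.n_composites)
    n_fine_per_cell = f * f
    counts = {
        cls: (
            fine_labels.reshape(spec.n_rows, f, spec.n_cols, f)
            .swapaxes(1, 2)
            .reshape(spec.n_rows, spec.n_cols, -1)
            == cls
        ).sum(axis=-1)
        for cls in Legend.VALID
    }
    series = np.zeros((spec.n_composites, 2, spec.n_rows, spec.n_cols))
    for cls in Legend.VALID:
        frac = counts[cls] / n_fine_per_cell
        prof = profiles[cls]  # (2, time)
        series += frac[None, None] * prof[:, :, None, None].transpose(1, 0, 2, 3)
    if spec.noise_sd > 0:
        series = series + rng.normal(0.0, spec.noise_sd, size=series.shape)
        series = np.clip(series, 1e-3, 1.0)

    # ---- fine multispectral + pan (digital numbers)
    p = spec.pan_factor
    fine_ms_bands = np.zeros((4, fine_geom.n_rows, fine_geom.n_cols))
    for cls, sig in _FINE_SIGNATURES.items():
        sel = fine_labels == cls
        for b in range(4):
            fine_ms_bands[b, sel] = sig[b]
    if spec.fine_noise_sd > 0:
        fine_ms_bands = fine_ms_bands + rng.normal(0.0, spec.fine_noise_sd, fine_ms_bands.shape)
    fine_ms = BandStack(
        geometry=fine_geom,
        bands=fine_ms_bands,
        band_labels=["blue", "green", "red", "nir"],
    )
    pan_geom = fine_geom.to_dict() | {
        "cell_size_x": fine_geom.cell_size_x / p,
        "cell_size_y": fine_geom.cell_size_y / p,
        "n_rows": fine_geom.n_rows * p,
        "n_cols": fine_geom.n_cols * p,
    }
    pan_geom = GridGeometry.from_dict(pan_geom)
    pan_labels = np.repeat(np.repeat(fine_labels, p, axis=0), p, axis=1)
    pan_plane = np.zeros(pan_labels.shape)
    for cls, sig in _FINE_SIGNATURES.items():
        pan_plane[pan_labels == cls] = float(np.dot(_PAN_WEIGHTS, sig))
    if spec.fine_noise_sd > 0:
        pan_plane = pan_plane + rng.normal(0.0, spec.fine_noise_sd, pan_plane.shape)
    pan = BandStack(geometry=pan_geom, bands=pan_plane[None], band_labels=["pan"])

    truth_area = (
        int((coarse_labels == Legend.DESERTIFIED).sum()) * coarse_geom.cell_area_km2
    )
    manifest = {
        "seed": spec.seed,
        "desertified_fraction": spec.desertified_fraction,
        "vegetation_fraction": spec.vegetation_fraction,
        "n_composites": spec.n_composites,
        "noise_sd": spec.noise_sd,
        "truth_area_km2": truth_area,
        "coarse_shape": [spec.n_rows, spec.n_cols],
        "fine_factor": f,
        "pan_factor": p,
    }
    return Scene(
        fine_ms=fine_ms,
        pan=pan,
        coarse_series=series,
        coarse_geometry=coarse_geom,
        truth_fine=ClassMap(geometry=fine_geom, labels=fine_labels),
        truth_coarse=ClassMap(geometry=coarse_geom, labels=coarse_labels),
        truth_area_km2=truth_area,
        manifest=manifest,
    )


def generate_coupled_panel(spec: CoupledSystemSpec) -> tuple[pd.DataFrame, dict]:
    """Panel of coupled logistic maps, one (X, Y) pair per site.

    Per site and time step

        X_{t+1} = X_t (r_x - r_x X_t - beta_xy Y_t)
        Y_{t+1} = Y_t (r_y - r_y Y_t - beta_yx X_t)

    iterated from random initial conditions through a burn-in, then
    observed for ``n_years`` with additive Gaussian noise.  The returned
    manifest records the true coupling and which direction is stronger.
    """
    rng = np.random.default_rng(spec.seed)
    records = []
    for s in range(spec.n_sites):
        x = rng.uniform(0.2, 0.8)
        y = rng.uniform(0.2, 0.8)
        xs, ys = [], []
        for t in range(spec.burn_in + spec.n_years):
            x, y = (
                x * (spec.r_x - spec.r_x * x - spec.beta_xy * y),
                y * (spec.r_y - spec.r_y * y - spec.beta_yx * x),
            )
            if not (0.0 < x < 1.0 and 0.0 < y < 1.0):
                raise ValueError(
                    f"site {s}: coupled logistic map left (0, 1) at step {t}; "
                    "reduce growth rates or couplings"
                )
            if t >= spec.burn_in:
                xs.append(x)
                ys.append(y)
        xs = np.asarray(xs) + rng.normal(0.0, spec.noise_sd, spec.n_years)
        ys = np.asarray(ys) + rng.normal(0.0, spec.noise_sd, spec.n_years)
        for i in range(spec.n_years):
            records.append(
                {
                    "site_id": f"site{s:03d}",
                    "year": 2001 + i,
                    spec.cause_name: xs[i],
                    spec.effect_name: ys[i],
                }
            )
    panel = pd.DataFrame(records)
    stronger = (
        f"{spec.cause_name}->{spec.effect_name}"
        if spec.beta_yx > spec.beta_xy
        else f"{spec.effect_name}->{spec.cause_name}"
        if spec.beta_xy > spec.beta_yx
        else "none"
    )
    manifest = {
        "seed": spec.seed,
        "n_sites": spec.n_sites,
        "n_years": spec.n_years,
        "beta_yx": spec.beta_yx,
        "beta_xy": spec.beta_xy,
        "causality": "none" if spec.beta_yx == spec.beta_xy == 0 else stronger,
        "stronger_direction": stronger,
    }
    return panel, manifest


def generate_training_points(scene: Scene, n_points: int = 33, seed: int = 0) -> TrainingSet:
    """Stratified labelled pixels from the fine truth map.

    ``n_points`` is split as evenly as possible over the classes present
    (33 over 3 classes → 11 each); samples carry the fine multispectral
    band values at the drawn pixels.
    """
    rng = np.random.default_rng(seed)
    labels_plane = scene.truth_fine.labels
    classes = [c for c in Legend.VALID if np.any(labels_plane == c)]
    if not classes:
        raise ValueError("truth map contains no labelled pixels")
    base, extra = divmod(n_points, len(classes))
    samples, labels, prov = [], [], []
    for i, cls in enumerate(classes):
        n_cls = base + (1 if i < extra else 0)
        rows, cols = np.nonzero(labels_plane == cls)
        if n_cls > len(rows):
            raise ValueError(f"class {Legend.NAMES[cls]} has fewer than {n_cls} pixels")
        pick = rng.choice(len(rows), size=n_cls, replace=False)
        for j, idx in enumerate(pick):
            r, c = rows[idx], cols[idx]
            samples.append(scene.fine_ms.bands[:, r, c])
            labels.append(cls)
            prov.append(f"{Legend.NAMES[cls]}-{j:02d}@({r},{c})")
    return TrainingSet(samples=np.asarray(samples), labels=np.asarray(labels), provenance=prov)
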