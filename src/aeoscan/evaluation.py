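"""Self-contained benchmark computations for the package's core claims.

Each function runs a piece of the pipeline from scratch on generated
inputs and returns measured quantities: oracle deviations for the MAD and
Savitzky–Golay primitives, p-tile calibration error, end-to-end
desertified-area recovery on synthetic scenes, cross-map direction
recovery on coupled panels, and the fusion algebraic identities.  Used by
the acceptance checks and runnable standalone.
"""

from __future__ import annotations

import numpy as np

from .ccm import ccm_curve
from .fusion import fuse_brovey, fuse_pca, principal_component_scores
from .landcover import class_proportions, select_pure_pixels
from .nddi_mad import (
    DesertificationMapper,
    MADMap,
    ReferenceCurve,
    area_estimate,
    build_nddi_cube,
    ptile_threshold,
    relative_error,
    savitzky_golay,
)
from .raster_core import BandStack, GridGeometry, Legend, build_grid_frame
from .synthetic import CoupledSystemSpec, SceneSpec, generate_coupled_panel, generate_scene

#: published survey comparison rows: (estimated km2, investigated km2)
SURVEY_ROWS = {
    "2004": (1714806.0, 1726700.0),
    "2009": (1758942.0, 1706700.0),
    "2014": (1724094.0, 1701600.0),
}


def table2_relative_errors() -> dict[str, float]:
    """Relative errors (%) for the published area-validation rows."""
    return {year: relative_error(est, inv) for year, (est, inv) in SURVEY_ROWS.items()}


def mad_oracle_deviation(n_series: int = 100, seed: int = 0) -> float:
    """Max |vectorised MAD − direct loop| over random 46-point series."""
    rng = np.random.default_rng(seed)
    n = 46
    geom = GridGeometry(0, 1000.0 * n_series, 1000.0, 1000.0, n_series, 1)
    values = rng.uniform(-1, 1, (n, n_series, 1))
    ref_vals = rng.uniform(-1, 1, n)
    ref = ReferenceCurve(raw=ref_vals, filtered=ref_vals, class_label=1, window=5, order=2)
    from .nddi_mad import NDDICube, compute_mad

    mad = compute_mad(NDDICube(geometry=geom, values=values), ref)
    worst = 0.0
    for i in range(n_series):
        loop = sum(abs(values[k, i, 0] - ref_vals[k]) for k in range(n)) / n
        worst = max(worst, abs(mad.values[i, 0] - loop))
    return float(worst)


def savgol_checks(seed: int = 0) -> dict[str, float]:
    """Polynomial exactness error and window-5/order-2 weight deviation."""
    rng = np.random.default_rng(seed)
    t = np.linspace(0, 1, 46)
    coeffs = rng.uniform(-2, 2, 3)
    poly = coeffs[0] + coeffs[1] * t + coeffs[2] * t**2
    out = savitzky_golay(poly, 5, 2)
    poly_err = float(np.max(np.abs(out[2:-2] - poly[2:-2])))
    # impulse response reads out the interior weights; oracle solves the
    # local least-squares system directly
    A = np.vander(np.arange(-2, 3), 3, increasing=True)
    oracle = np.linalg.lstsq(A, np.eye(5), rcond=None)[0][0]
    x = np.zeros(11)
    x[5] = 1.0
    weights = savitzky_golay(x, 5, 2)[3:8]
    weight_err = float(np.max(np.abs(weights - oracle[::-1])))
    return {"poly_exactness_err": poly_err, "weight_err": weight_err}


def ptile_calibration(n: int = 10_000, prior: float = 0.3, seed: int = 0) -> dict[str, float]:
    """|fraction at-or-below threshold − prior| on random MAD values."""
    rng = np.random.default_rng(seed)
    side = int(np.sqrt(n))
    values = rng.random((side, side))
    geom = GridGeometry(0, 1000.0 * side, 1000.0, 1000.0, side, side)
    mad = MADMap(geometry=geom, values=values)
    thr = ptile_threshold(mad, prior)
    frac = float((values <= thr).mean())
    return {"fraction_at_or_below": frac, "calibration_err": abs(frac - prior),
            "tolerance": 1.0 / values.size}


def end_to_end_recovery(
    seeds: tuple[int, ...] = (0, 1, 2, 3, 4),
    n_rows: int = 100,
    n_cols: int = 100,
    desertified_fraction: float = 0.3,
    noise_sd: float = 0.05,
) -> dict[str, float]:
    """Mask agreement and area error of the full monitoring chain.

    Per seed: generate a scene, take per-cell class proportions of the
    fine truth map, select pure pixels, fit the desertified reference
    curve, score MAD, p-tile threshold at the true prior, and compare the
    recovered mask and area against the scene's truth.
    """
    agreements, area_errors = [], []
    for seed in seeds:
        scene = generate_scene(
            SceneSpec(
                n_rows=n_rows,
                n_cols=n_cols,
                desertified_fraction=desertified_fraction,
                noise_sd=noise_sd,
                seed=seed,
            )
        )
        frame = build_grid_frame(scene.truth_fine.geometry, scene.coarse_geometry.cell_size_x)
        frame = class_proportions(scene.truth_fine, frame)
        pure = select_pure_pixels(frame)
        cube = build_nddi_cube(scene.coarse_series, scene.coarse_geometry)
        mapper = DesertificationMapper(prior_fraction=desertified_fraction)
        recovered = mapper.fit_predict(cube, pure)
        truth = scene.truth_coarse.labels == Legend.DESERTIFIED
        got = recovered.labels == Legend.DESERTIFIED
        agreements.append(float(np.mean(got == truth)))
        est = area_estimate(recovered)
        area_errors.append(100.0 * abs(est - scene.truth_area_km2) / scene.truth_area_km2)
    return {
        "min_pixel_agreement": float(min(agreements)),
        "mean_pixel_agreement": float(np.mean(agreements)),
        "max_area_error_pct": float(max(area_errors)),
        "n_seeds": float(len(seeds)),
    }


def ccm_direction_recovery(
    n_replicates: int = 20,
    n_boot: int = 200,
    n_sites: int = 40,
    n_years: int = 15,
    seed: int = 0,
) -> dict[str, float]:
    """Direction recovery on coupled-logistic panels.

    The generator couples wind → area strongly (beta 0.1) and area → wind
    weakly (beta 0.02).  Per replicate both directions are cross-mapped;
    reported are the fraction of replicates where the true direction is
    significant (p < 0.05) with skill increasing in library length, and
    the fraction where the weak direction's p exceeds the true one's.
    """
    true_sig = 0
    true_increasing = 0
    weak_larger_p = 0
    for rep in range(n_replicates):
        panel, _ = generate_coupled_panel(
            CoupledSystemSpec(n_sites=n_sites, n_years=n_years, seed=seed * 1000 + rep)
        )
        fwd = ccm_curve(panel, cause="wind_speed", effect="desertified_area",
                        n_boot=n_boot, seed=seed + rep)
        rev = ccm_curve(panel, cause="desertified_area", effect="wind_speed",
                        n_boot=n_boot, seed=seed + rep)
        true_sig += fwd.p_value < 0.05
        true_increasing += fwd.rho_mean[-1] > fwd.rho_mean[0]
        weak_larger_p += rev.p_value > fwd.p_value
    return {
        "true_direction_significant_rate": true_sig / n_replicates,
        "true_direction_increasing_rate": true_increasing / n_replicates,
        "weak_direction_larger_p_rate": weak_larger_p / n_replicates,
        "n_replicates": float(n_replicates),
    }


def fusion_identity_checks(seed: int = 0) -> dict[str, float]:
    """PCA substitution identity and Brovey band-sum identity errors."""
    rng = np.random.default_rng(seed)
    geom = GridGeometry(0, 3200.0, 100.0, 100.0, 32, 32)
    base = rng.random((32, 32))
    bands = np.stack(
        [2.0 * base + rng.normal(0, 0.05, base.shape), base, 0.5 * base + 0.1,
         0.8 * base + rng.normal(0, 0.02, base.shape)]
    )
    ms = BandStack(geometry=geom, bands=bands, band_labels=["b1", "b2", "b3", "b4"])
    pan_pc1 = BandStack(geometry=geom, bands=principal_component_scores(ms)[None],
                        band_labels=["pan"])
    fused = fuse_pca(ms, pan_pc1)
    pca_err = float(np.max(np.abs(fused.bands - ms.bands)))
    pan = BandStack(geometry=geom, bands=rng.uniform(10, 300, (1, 32, 32)),
                    band_labels=["pan"])
    ms_pos = BandStack(geometry=geom, bands=rng.uniform(10, 300, (4, 32, 32)),
                       band_labels=["b1", "b2", "b3", "b4"])
    brv = fuse_brovey(ms_pos, pan)
    ok = ~brv.nodata_mask
    brovey_err = float(np.max(np.abs(brv.bands.sum(0)[ok] - pan.bands[0][ok])))
    return {"pca_identity_err": pca_err, "brovey_sum_err": brovey_err}


def pure_pixel_boundary_check() -> dict[str, float]:
    """Strict-inequality boundary: exact 0.70 / 0.90 proportions are not pure."""
    from .raster_core import GridFrame

    geom = GridGeometry(0, 200.0, 100.0, 100.0, 1, 2)
    frame = GridFrame(
        geometry=geom,
        cell_ids=np.array([[1, 2]]),
        proportions={
            Legend.DESERTIFIED: np.array([[0.70, 0.0]]),
            Legend.VEGETATION: np.array([[0.20, 0.90]]),
            Legend.OTHERS: np.array([[0.10, 0.10]]),
        },
        valid=np.ones((1, 2), bool),
    )
    pure = select_pure_pixels(frame)
    return {"cells_selected_at_exact_thresholds": float(len(pure.table))}
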