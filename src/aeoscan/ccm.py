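"""Convergent cross mapping with composite (multi-site) libraries.

Empirical-dynamic-modelling causality test for short annual panels.  If a
variable X forces Y, then Y's time-delay embedding (its "shadow manifold")
encodes information about X, and X can be estimated from the nearest
neighbours of Y's lagged vectors — with a skill (Pearson ρ between observed
and cross-map-estimated X) that converges upward as the library of vectors
grows.  With only ~15 annual observations per site, single-site libraries
are far too short, so lagged vectors are pooled across spatial replicates
into one composite library; vectors never span site boundaries.

Significance is a bootstrap convergence test: libraries of the smallest and
largest lengths are resampled in paired iterations and

    p = Pr[ rho(L_max) <= rho(L_min) ],

the probability that skill fails to increase with library length.

Variables are z-scored across the panel before embedding so Euclidean
neighbour distances are not dominated by units.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator

__all__ = [
    "EmbeddingConfig",
    "CCMResult",
    "embed",
    "embed_panel",
    "simplex_cross_map",
    "select_embedding",
    "ccm_curve",
    "convergence_test",
    "CCM",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class EmbeddingConfig:
    """Time-delay embedding parameters: dimension E, lag tau, horizon tp."""

    E: int = 2
    tau: int = 1
    tp: int = 0

    def __post_init__(self) -> None:
        if self.E < 2:
            raise ValueError("embedding dimension E must be >= 2")
        if self.tau < 1:
            raise ValueError("lag tau must be >= 1")


@dataclass
class CCMResult:
    """Cross-map skill versus library length with bootstrap bands.

    ``rho`` holds the raw bootstrap draws, shape (n_boot, n_lengths); the
    convergence p-value compares the draws at the smallest and largest
    library lengths pairwise.
    """

    cause: str
    effect: str
    library_lengths: np.ndarray
    rho_mean: np.ndarray
    rho_sd: np.ndarray
    n_boot: int
    p_value: float
    config: EmbeddingConfig
    rho: np.ndarray = field(repr=False, default=None)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cause": self.cause,
                "effect": self.effect,
                "library_length": self.library_lengths,
                "rho_mean": self.rho_mean,
                "rho_sd": self.rho_sd,
            }
        )

    def summary(self) -> dict:
        return {
            "cause": self.cause,
            "effect": self.effect,
            "E": self.config.E,
            "tau": self.config.tau,
            "n_boot": self.n_boot,
            "p_value": self.p_value,
            "rho_at_max_length": float(self.rho_mean[-1]),
        }


def embed(series: np.ndarray, cfg: EmbeddingConfig) -> np.ndarray:
    """Lagged-coordinate vectors of one series.

    Returns (N - (E-1)*tau, E) rows ``(x_t, x_{t-tau}, ..., x_{t-(E-1)tau})``
    ordered by t.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError("series must be one-dimensional")
    span = (cfg.E - 1) * cfg.tau
    if len(x) < span + 1:
        raise ValueError(
            f"series of length {len(x)} too short for E={cfg.E}, tau={cfg.tau}"
        )
    n_vec = len(x) - span
    cols = [x[span - k * cfg.tau : span - k * cfg.tau + n_vec] for k in range(cfg.E)]
    return np.column_stack(cols)


def _panel_matrix(panel: pd.DataFrame, variable: str) -> np.ndarray:
    """(n_sites, n_years) matrix for one variable; years must be contiguous per site."""
    if variable not in panel.columns:
        raise KeyError(f"panel has no variable {variable!r}")
    pieces = []
    for site, sub in panel.groupby("site_id", sort=True):
        sub = sub.sort_values("year")
        years = sub["year"].to_numpy()
        if len(years) > 1 and not np.all(np.diff(years) == 1):
            raise ValueError(f"site {site!r}: years are not contiguous")
        pieces.append(sub[variable].to_numpy(dtype=float))
    lengths = {len(p) for p in pieces}
    if len(lengths) != 1:
        raise ValueError("all sites must cover the same span of years")
    return np.vstack(pieces)


def embed_panel(
    panel: pd.DataFrame,
    effect: str,
    cause: str,
    cfg: EmbeddingConfig,
    standardize: bool = True,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pooled embedding of the effect variable with aligned cause values.

    Embeds each site's effect series separately (vectors never span site
    boundaries), pools the vectors, and aligns the cause variable at the
    vector's time t (+tp).  Returns ``(vectors, cause_values, site_index)``.
    """
    Y = _panel_matrix(panel, effect)
    X = _panel_matrix(panel, cause)
    if standardize:
        Y = (Y - Y.mean()) / Y.std()
        X = (X - X.mean()) / X.std()
    span = (cfg.E - 1) * cfg.tau
    vecs, causes, sites = [], [], []
    for s in range(Y.shape[0]):
        v = embed(Y[s], cfg)
        t = np.arange(span, Y.shape[1])  # vector times
        t_target = t + cfg.tp
        keep = (t_target >= 0) & (t_target < Y.shape[1])
        vecs.append(v[keep])
        causes.append(X[s, t_target[keep]])
        sites.append(np.full(keep.sum(), s))
    return np.vstack(vecs), np.concatenate(causes), np.concatenate(sites)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if a.std() == 0 or b.std() == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def _cross_map_from_dist(
    D: np.ndarray,
    lib_idx: np.ndarray,
    cause_values: np.ndarray,
    target_idx: np.ndarray,
    n_neighbors: int,
) -> float:
    """Cross-map skill given a precomputed target×pool distance matrix.

    ``D`` is (n_pool, n_pool); the library is the multiset of pool indices
    ``lib_idx`` (duplicates allowed, as under bootstrap resampling); each
    target excludes copies of itself from its neighbour list (leave-one-out).
    """
    Dsub = D[np.ix_(target_idx, lib_idx)].copy()
    # leave-one-out: a target never uses its own vector as a neighbour
    self_hit = lib_idx[None, :] == target_idx[:, None]
    Dsub[self_hit] = np.inf
    if Dsub.shape[1] < n_neighbors:
        raise ValueError(
            f"library of {Dsub.shape[1]} vectors cannot supply {n_neighbors} neighbours"
        )
    part = np.argpartition(Dsub, n_neighbors - 1, axis=1)[:, :n_neighbors]
    rows = np.arange(Dsub.shape[0])[:, None]
    d = Dsub[rows, part]
    order = np.argsort(d, axis=1)
    d = np.take_along_axis(d, order, axis=1)
    nbr = np.take_along_axis(part, order, axis=1)
    if not np.all(np.isfinite(d)):
        raise ValueError("a target ran out of finite-distance library neighbours")
    d_min = d[:, :1]
    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.exp(-d / d_min)
    # exact matches: all weight uniformly on zero-distance neighbours
    zero_rows = (d_min[:, 0] == 0)
    if np.any(zero_rows):
        w[zero_rows] = (d[zero_rows] == 0).astype(float)
    w /= w.sum(axis=1, keepdims=True)
    pred = (w * cause_values[lib_idx[nbr]]).sum(axis=1)
    return _pearson(pred, cause_values[target_idx])


def simplex_cross_map(
    effect_vectors: np.ndarray,
    cause_values: np.ndarray,
    library: np.ndarray | None = None,
    targets: np.ndarray | None = None,
    n_neighbors: int | None = None,
) -> float:
    """Estimate the cause from the effect manifold's nearest neighbours.

    For each target vector, the E+1 nearest library vectors (Euclidean,
    excluding the target itself) predict the cause value as an
    exponentially weighted neighbour average, ``w_i ∝ exp(-d_i/d_min)``;
    the returned skill is the Pearson correlation between predictions and
    observed cause values over the targets.  High skill means the effect's
    dynamics encode the candidate cause — evidence that the cause forces
    the effect.
    """
    V = np.asarray(effect_vectors, dtype=float)
    x = np.asarray(cause_values, dtype=float)
    if V.ndim != 2 or len(V) != len(x):
        raise ValueError("need one cause value per effect vector")
    n = len(V)
    lib = np.arange(n) if library is None else np.asarray(library, dtype=int)
    tgt = np.arange(n) if targets is None else np.asarray(targets, dtype=int)
    if lib.size == 0 or tgt.size == 0:
        raise ValueError("library and targets must be nonempty")
    k = n_neighbors if n_neighbors is not None else V.shape[1] + 1
    D = cdist(V, V)
    return _cross_map_from_dist(D, lib, x, tgt, k)


def select_embedding(
    panel: pd.DataFrame | np.ndarray,
    variable: str | None = None,
    E_range: tuple[int, ...] = (2, 3, 4),
    tau: int = 1,
    low_skill: float = 0.1,
) -> EmbeddingConfig:
    """Choose E by leave-one-out univariate simplex self-prediction.

    For each candidate E the variable's own next value (tp = 1) is
    predicted from its lagged vectors; the E with the highest skill wins,
    ties going to the smallest E.  A flat/low skill curve (all below
    ``low_skill``) triggers a warning and returns the smallest feasible E.
    """
    skills: dict[int, float] = {}
    for E in E_range:
        cfg = EmbeddingConfig(E=E, tau=tau, tp=1)
        try:
            if isinstance(panel, pd.DataFrame):
                if variable is None:
                    raise ValueError("variable required with a panel input")
                V, target, _ = embed_panel(panel, effect=variable, cause=variable, cfg=cfg)
            else:
                series = np.asarray(panel, dtype=float)
                span = (E - 1) * tau
                V_all = embed(series, cfg)
                V = V_all[:-1]
                target = series[span + 1 :]
        except ValueError:
            continue
        if len(V) < E + 2:
            continue
        skills[E] = simplex_cross_map(V, target)
    if not skills:
        raise ValueError("no feasible embedding dimension in the requested range")
    best = max(sorted(skills), key=lambda E: skills[E])
    if max(skills.values()) < low_skill:
        warnings.warn(
            "self-prediction skill is low for every E; the series may be noise",
            stacklevel=2,
        )
        best = min(skills)
    return EmbeddingConfig(E=best, tau=tau, tp=0)


def convergence_test(rhos_at_Lmin: np.ndarray, rhos_at_Lmax: np.ndarray) -> float:
    """Bootstrap convergence p-value.

    Fraction of paired bootstrap iterations in which the skill at the
    largest library length fails to exceed the skill at the smallest —
    small p means skill reliably increases with library length, the
    signature of a causal link.
    """
    a = np.asarray(rhos_at_Lmin, dtype=float)
    b = np.asarray(rhos_at_Lmax, dtype=float)
    if a.shape != b.shape:
        raise ValueError("need equally many bootstrap draws at both lengths")
    if len(a) < 100:
        warnings.warn("fewer than 100 bootstrap draws: p-value is unstable", stacklevel=2)
    return float(np.mean(b <= a))


def ccm_curve(
    panel: pd.DataFrame,
    cause: str,
    effect: str,
    cfg: EmbeddingConfig | None = None,
    lengths: list[int] | None = None,
    n_boot: int = 1000,
    seed: int | None = None,
    resample: str = "vectors",
) -> CCMResult:
    """Bootstrap cross-map skill curve for "cause forces effect".

    The effect variable is embedded per site and pooled into a composite
    library.  For each library length L and bootstrap iteration, L vectors
    are drawn with replacement from the pool (``resample="sites"`` draws
    whole sites instead), every pooled vector is cross-mapped from that
    library, and the skill recorded; the convergence p-value compares the
    draws at the smallest and largest L pairwise.
    """
    if cfg is None:
        cfg = select_embedding(panel, variable=effect)
    V, x, site_of = embed_panel(panel, effect=effect, cause=cause, cfg=cfg)
    n = len(V)
    if lengths is None:
        lengths = sorted({max(cfg.E + 2, n // 8), n // 4, n // 2, (3 * n) // 4, n})
    lengths = sorted(int(L) for L in lengths)
    if lengths[-1] > n:
        raise ValueError(f"maximum library length {lengths[-1]} exceeds pool size {n}")
    if lengths[0] < cfg.E + 2:
        raise ValueError("smallest library length cannot supply E+1 neighbours")
    rng = np.random.default_rng(seed)
    D = cdist(V, V)
    targets = np.arange(n)
    rho = np.empty((n_boot, len(lengths)))
    site_ids = np.unique(site_of)
    for it in range(n_boot):
        for j, L in enumerate(lengths):
            if resample == "sites":
                lib = []
                while len(lib) < L:
                    s = rng.choice(site_ids)
                    lib.extend(np.nonzero(site_of == s)[0])
                lib = np.asarray(lib[:L])
            else:
                lib = rng.integers(0, n, size=L)
            rho[it, j] = _cross_map_from_dist(D, lib, x, targets, cfg.E + 1)
    p = convergence_test(rho[:, 0], rho[:, -1])
    return CCMResult(
        cause=cause,
        effect=effect,
        library_lengths=np.asarray(lengths),
        rho_mean=rho.mean(axis=0),
        rho_sd=rho.std(axis=0),
        n_boot=n_boot,
        p_value=p,
        config=cfg,
        rho=rho,
    )


class CCM(BaseEstimator):
    """Scikit-learn-style wrapper around the cross-mapping analysis.

    Parameters mirror :func:`ccm_curve`; ``fit`` takes the panel DataFrame
    (columns ``site_id``, ``year`` and the named variables) and exposes the
    fitted skill curve as trailing-underscore attributes.
    """

    def __init__(
        self,
        cause: str = "wind_speed",
        effect: str = "desertified_area",
        E: int | None = None,
        tau: int = 1,
        lengths: list[int] | None = None,
        n_boot: int = 1000,
        random_state: int | None = None,
        resample: str = "vectors",
    ):
        self.cause = cause
        self.effect = effect
        self.E = E
        self.tau = tau
        self.lengths = lengths
        self.n_boot = n_boot
        self.random_state = random_state
        self.resample = resample

    def fit(self, panel: pd.DataFrame, y=None) -> "CCM":
        cfg = (
            EmbeddingConfig(E=self.E, tau=self.tau)
            if self.E is not None
            else select_embedding(panel, variable=self.effect, tau=self.tau)
        )
        self.result_ = ccm_curve(
            panel,
            cause=self.cause,
            effect=self.effect,
            cfg=cfg,
            lengths=self.lengths,
            n_boot=self.n_boot,
            seed=self.random_state,
            resample=self.resample,
        )
        self.config_ = self.result_.config
        self.library_lengths_ = self.result_.library_lengths
        self.rho_mean_ = self.result_.rho_mean
        self.rho_sd_ = self.result_.rho_sd
        self.p_value_ = self.result_.p_value
        return self
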