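"""Geographic-trend regressions against distance from the Near East.

Admixture and drift posteriors, gene diversity and pairwise F_ST are
regressed on great-circle distance from a Near East origin.  Posterior
uncertainty is propagated by resampling: per replicate one draw is taken
from each population's posterior and an ordinary least-squares line is
fitted, repeated R times (default 1,000) to give an ensemble of
regression lines.  Fitted values may leave [0, 1]; they are deliberately
not clipped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

EARTH_RADIUS_KM = 6371.0
#: Default origin for "distance from the Near East" (northern Mesopotamia).
NEAR_EAST_ORIGIN = (36.0, 40.0)

__all__ = [
    "PopulationGeo",
    "RegressionEnsemble",
    "great_circle_distance",
    "posterior_regression",
    "stat_distance_trend",
    "estimate_admixed_Ne",
    "NEAR_EAST_ORIGIN",
]


@dataclass
class PopulationGeo:
    """A population sample's location and distance from the origin."""

    label: str
    lat: float
    lon: float
    distance_km: float | None = None
    date_bp: float | None = None

    def __post_init__(self) -> None:
        if not (-90.0 <= self.lat <= 90.0) or not (-180.0 <= self.lon <= 180.0):
            raise ValueError(f"coordinates out of range for {self.label}")
        if self.distance_km is None:
            self.distance_km = great_circle_distance(NEAR_EAST_ORIGIN, (self.lat, self.lon))


def great_circle_distance(a: tuple[float, float], b: tuple[float, float]) -> float:
    """Haversine distance in km between (lat, lon) points on a 6371-km sphere."""
    (lat1, lon1), (lat2, lon2) = a, b
    for lat, lon in (a, b):
        if not (-90.0 <= lat <= 90.0) or not (-180.0 <= lon <= 180.0):
            raise ValueError("coordinates out of range")
    phi1, phi2 = np.radians(lat1), np.radians(lat2)
    dphi = phi2 - phi1
    dlam = np.radians(lon2 - lon1)
    h = np.sin(dphi / 2.0) ** 2 + np.cos(phi1) * np.cos(phi2) * np.sin(dlam / 2.0) ** 2
    return float(2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(h)))


@dataclass
class RegressionEnsemble:
    """R replicate OLS fits of resampled posterior values on distance."""

    slopes: np.ndarray
    intercepts: np.ndarray
    distances: np.ndarray
    responses: np.ndarray  # (R, n_pops) resampled values
    labels: list[str] = field(default_factory=list)

    @property
    def n_replicates(self) -> int:
        return len(self.slopes)

    def slope_summary(self, lo: float = 0.05, hi: float = 0.95) -> dict:
        return {
            "median": float(np.median(self.slopes)),
            "lo": float(np.quantile(self.slopes, lo)),
            "hi": float(np.quantile(self.slopes, hi)),
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"slope": self.slopes, "intercept": self.intercepts})


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    slope, intercept = np.polyfit(x, y, 1)
    return float(slope), float(intercept)


def posterior_regression(
    posteriors: dict[str, np.ndarray],
    geo: list[PopulationGeo],
    R: int = 1000,
    seed: int | None = None,
) -> RegressionEnsemble:
    """Ensemble OLS of posterior draws on distance from the Near East.

    Per replicate one value is drawn (with replacement) from each
    population's posterior and regressed on ``distance_km``.
    """
    if len(geo) < 3:
        raise ValueError("need at least 3 populations for a trend")
    rng = np.random.default_rng(seed)
    dist = np.array([g.distance_km for g in geo])
    draw_mat = np.empty((R, len(geo)))
    for j, g in enumerate(geo):
        pool = np.asarray(posteriors[g.label], dtype=float)
        draw_mat[:, j] = pool[rng.integers(0, len(pool), size=R)]
    X = np.column_stack([dist, np.ones_like(dist)])
    coef, *_ = np.linalg.lstsq(X, draw_mat.T, rcond=None)
    return RegressionEnsemble(
        slopes=coef[0].copy(),
        intercepts=coef[1].copy(),
        distances=dist,
        responses=draw_mat,
        labels=[g.label for g in geo],
    )


def stat_distance_trend(
    values: dict[str, float], geo: list[PopulationGeo]
) -> tuple[float, float, np.ndarray]:
    """Single OLS fit of per-population scalars on distance (no resampling)."""
    if len(geo) < 3:
        raise ValueError("need at least 3 populations for a trend")
    dist = np.array([g.distance_km for g in geo])
    y = np.array([values[g.label] for g in geo], dtype=float)
    slope, intercept = _ols(dist, y)
    return slope, intercept, slope * dist + intercept


def estimate_admixed_Ne(
    th_draws: np.ndarray, date_bp: float, gen_time: float = 25.0
) -> np.ndarray:
    """Effective size draws N_h = T / t_h with T = date_bp / gen_time.

    Non-positive drift draws carry no size information and are excluded
    (with a warning) rather than propagated as infinities.
    """
    import warnings

    if date_bp <= 0:
        raise ValueError("date_bp must be positive")
    th_draws = np.asarray(th_draws, dtype=float)
    bad = th_draws <= 0
    if bad.any():
        warnings.warn(f"excluding {bad.sum()} non-positive drift draws")
        th_draws = th_draws[~bad]
    T = date_bp / gen_time
    return T / th_draws
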