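"""ABC model choice (TP vs S vs SDG) and parameter estimation.

Rejection on the three pairwise F_ST statistics (standardised by their
reference-table median absolute deviation), Epanechnikov kernel weights,
then a post-rejection adjustment: a weighted multinomial logistic
regression (MLR) or a non-linear heteroscedastic (NCH) adjustment built on
single-hidden-layer feed-forward approximators.  A validation harness
re-assigns pseudo-observed datasets simulated under each model and reports
the confusion matrix in percent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import median_abs_deviation
from sklearn.linear_model import LogisticRegression
from sklearn.neural_network import MLPClassifier, MLPRegressor

from neodemic.sumstats import STAT_NAMES, SumStats, sumstat_vector
from neodemic.synth import StudyDesign, draw_model_params, simulate_study_panel

__all__ = [
    "ReferenceTable",
    "ModelPosterior",
    "ParamEstimate",
    "simulate_reference_table",
    "abc_reject",
    "model_posterior_mlr",
    "model_posterior_nch",
    "estimate_params_nch",
    "validate_model_choice",
    "weighted_quantile",
]

MODELS = ("TP", "S", "SDG")
STAT_COLS = STAT_NAMES


@dataclass
class ReferenceTable:
    """Per-simulation model label, parameter draw and summary statistics."""

    table: pd.DataFrame  # columns: model, param..., fst_hg_farmer, ...

    def __post_init__(self) -> None:
        missing = [c for c in ("model", *STAT_COLS) if c not in self.table.columns]
        if missing:
            raise ValueError(f"reference table misses columns {missing}")
        if self.table[list(STAT_COLS)].isna().any().any():
            raise ValueError("reference table contains missing statistics")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def stats(self) -> np.ndarray:
        return self.table[list(STAT_COLS)].to_numpy(dtype=float)

    @property
    def models(self) -> np.ndarray:
        return self.table["model"].to_numpy()

    @property
    def param_columns(self) -> list[str]:
        return [c for c in self.table.columns if c not in ("model", *STAT_COLS)]

    def only(self, model: str) -> "ReferenceTable":
        return ReferenceTable(self.table[self.table["model"] == model].reset_index(drop=True))

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "ReferenceTable":
        return cls(pd.read_csv(path))


@dataclass
class ModelPosterior:
    """Posterior model probabilities; always sum to one."""

    probs: dict[str, float]
    method: str
    tolerance: float

    def __post_init__(self) -> None:
        total = sum(self.probs.values())
        if not np.isfinite(total) or abs(total - 1.0) > 1e-9:
            raise ValueError("model probabilities must sum to 1")

    def best(self) -> str:
        return max(self.probs, key=lambda k: self.probs[k])


@dataclass
class ParamEstimate:
    """Weighted median and 5/95% percentiles per parameter."""

    summary: pd.DataFrame  # index: parameter, columns: q05, median, q95
    adjusted: pd.DataFrame = field(repr=False, default=None)


def simulate_reference_table(
    M: int,
    design: StudyDesign | None = None,
    models: tuple[str, ...] = MODELS,
    seed=None,
    mode: str = "sequence",
) -> ReferenceTable:
    """Simulate an ABC reference table with equal prior weight per model."""
    design = design or StudyDesign()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    per = M // len(models)
    rows = []
    for kind in models:
        for _ in range(per):
            params = draw_model_params(kind, design, rng)
            panel, _ = simulate_study_panel(kind, params, design, rng)
            s = sumstat_vector(panel, mode=mode)
            rows.append({
                "model": kind, "N_UP": params.N_UP, "N_N": params.N_N,
                "phi": params.phi,
                "fst_hg_farmer": s.fst_hg_farmer,
                "fst_hg_modern": s.fst_hg_modern,
                "fst_farmer_modern": s.fst_farmer_modern,
            })
    return ReferenceTable(pd.DataFrame(rows))


def _standardise(stats: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Scale by the median absolute deviation (robust to heavy tails)."""
    scale = median_abs_deviation(stats, axis=0)
    scale = np.where(scale > 0, scale, np.std(stats, axis=0))
    scale = np.where(scale > 0, scale, 1.0)
    return stats / scale, scale


def abc_reject(
    ref: ReferenceTable, obs: SumStats, tolerance: float
) -> tuple[np.ndarray, np.ndarray]:
    """Rejection step: indices of accepted simulations and kernel weights.

    Retains the ``ceil(tolerance * M)`` simulations nearest the observed
    statistics in MAD-standardised Euclidean distance, with Epanechnikov
    weights on a bandwidth equal to the maximum accepted distance.
    """
    if len(ref) == 0:
        raise ValueError("empty reference table")
    if not (0.0 < tolerance <= 1.0):
        raise ValueError("tolerance must be in (0, 1]")
    z, scale = _standardise(ref.stats)
    z_obs = obs.as_array() / scale
    d = np.sqrt(((z - z_obs) ** 2).sum(axis=1))
    n_keep = int(np.ceil(tolerance * len(ref)))
    idx = np.argsort(d, kind="stable")[:n_keep]
    d_keep = d[idx]
    d_max = d_keep.max()
    if d_max == 0.0:
        w = np.ones(n_keep)
    else:
        w = 1.0 - (d_keep / d_max) ** 2
        if w.sum() == 0.0:
            w = np.ones(n_keep)
    return idx, w


def _posterior_from_classifier(fit_predict, ref, obs, tolerance, method):
    idx, w = abc_reject(ref, obs, tolerance)
    z, scale = _standardise(ref.stats)
    z_keep = z[idx]
    labels = ref.models[idx]
    present = sorted(set(labels), key=list(MODELS).index)
    all_models = sorted(set(ref.models), key=list(MODELS).index)
    absent = [m for m in all_models if m not in present]
    if absent:
        warnings.warn(f"models absent from accepted set get probability 0: {absent}")
    if len(present) == 1:
        probs = {m: 0.0 for m in all_models}
        probs[present[0]] = 1.0
        return ModelPosterior(probs=probs, method=method, tolerance=tolerance)
    z_obs = obs.as_array() / scale
    p = fit_predict(z_keep, labels, w, z_obs, present)
    probs = {m: 0.0 for m in all_models}
    probs.update({m: float(v) for m, v in zip(present, p)})
    total = sum(probs.values())
    probs = {m: v / total for m, v in probs.items()}
    return ModelPosterior(probs=probs, method=method, tolerance=tolerance)


def model_posterior_mlr(
    ref: ReferenceTable, obs: SumStats, tolerance: float = 0.01
) -> ModelPosterior:
    """Weighted multinomial logistic regression on the accepted set."""

    def fit_predict(z, labels, w, z_obs, present):
        clf = LogisticRegression(C=1e6, max_iter=5000)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            clf.fit(z, labels, sample_weight=w)
        p = clf.predict_proba(z_obs[None, :])[0]
        order = [list(clf.classes_).index(m) for m in present]
        return p[order]

    return _posterior_from_classifier(fit_predict, ref, obs, tolerance, "MLR")


def model_posterior_nch(
    ref: ReferenceTable, obs: SumStats, tolerance: float = 0.01, seed: int = 0
) -> ModelPosterior:
    """Single-hidden-layer feed-forward classifier on the accepted set.

    Kernel weights are applied by weighted resampling of the accepted
    simulations before fitting.
    """

    def fit_predict(z, labels, w, z_obs, present):
        # ensemble of independently resampled/initialised nets, as in the
        # classical neural-net ABC implementations
        rng = np.random.default_rng(seed)
        p_w = w / w.sum() if w.sum() > 0 else None
        probs = np.zeros(len(present))
        n_nets = 5
        for i in range(n_nets):
            take = rng.choice(len(z), size=len(z), replace=True, p=p_w)
            clf = MLPClassifier(hidden_layer_sizes=(8,), max_iter=4000,
                                random_state=seed + 7919 * i, alpha=1e-4)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                clf.fit(z[take], labels[take])
            p = clf.predict_proba(z_obs[None, :])[0]
            found = list(clf.classes_)
            probs += np.array([p[found.index(m)] if m in found else 0.0
                               for m in present])
        return probs / n_nets

    return _posterior_from_classifier(fit_predict, ref, obs, tolerance, "NCH")


def weighted_quantile(values: np.ndarray, q, weights: np.ndarray) -> np.ndarray:
    """Weighted quantiles; reduces to the ordinary quantile for equal weights."""
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    order = np.argsort(values)
    v, w = values[order], weights[order]
    cw = np.cumsum(w)
    positions = (cw - 0.5 * w) / cw[-1]
    return np.interp(np.atleast_1d(q), positions, v)


class _MeanFit:
    """Conditional mean: exact linear term plus an ensemble of MLPs on
    the residuals.

    Averaging several independently initialised nets (as the classical
    neural-net ABC implementations do) suppresses the initialisation
    noise of any single fit; early stopping keeps the nets from inventing
    structure when the residuals are pure noise (uninformative
    statistics).
    """

    n_nets = 5

    def __init__(self, seed: int):
        self.seed = seed

    def fit(self, X: np.ndarray, y: np.ndarray) -> "_MeanFit":
        A = np.column_stack([X, np.ones(len(X))])
        self.beta, *_ = np.linalg.lstsq(A, y, rcond=None)
        resid = y - A @ self.beta
        self.scale = float(np.std(resid))
        self.nets = []
        if self.scale > 1e-12:
            for i in range(self.n_nets):
                net = MLPRegressor(hidden_layer_sizes=(8,), max_iter=2000,
                                   random_state=self.seed + 7919 * i,
                                   alpha=1e-4, early_stopping=True,
                                   validation_fraction=0.2,
                                   n_iter_no_change=20)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    net.fit(X, resid / self.scale)
                self.nets.append(net)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(X)
        out = np.column_stack([X, np.ones(len(X))]) @ self.beta
        if self.nets:
            out = out + self.scale * np.mean(
                [net.predict(X) for net in self.nets], axis=0)
        return out


def estimate_params_nch(
    ref_sdg: ReferenceTable,
    obs: SumStats,
    tolerance: float = 0.01,
    params: list[str] | None = None,
    log_transform: bool = True,
    seed: int = 0,
) -> ParamEstimate:
    """Non-linear heteroscedastic regression adjustment of SDG parameters.

    Adjusts each accepted draw as
    ``theta* = m(s_obs) + (theta - m(s)) * sigma(s_obs) / sigma(s)``
    with ``m`` a fitted conditional mean and ``sigma`` a fitted
    conditional standard deviation, both on MAD-standardised statistics;
    positive parameters are adjusted on the log scale and back-transformed.
    Reports the kernel-weighted median and 5/95% percentiles.
    """
    params = params or ref_sdg.param_columns
    idx, w = abc_reject(ref_sdg, obs, tolerance)
    z, scale = _standardise(ref_sdg.stats)
    X = z[idx]
    z_obs = (obs.as_array() / scale)[None, :]
    rows, adj_cols = [], {}
    for j, name in enumerate(params):
        theta = ref_sdg.table[name].to_numpy(dtype=float)[idx]
        if log_transform:
            if (theta <= 0).any():
                raise ValueError(f"cannot log-transform non-positive {name!r}")
            theta_t = np.log(theta)
        else:
            theta_t = theta
        mean_fit = _MeanFit(seed + j).fit(X, theta_t)
        resid = theta_t - mean_fit.predict(X)
        var = float(np.mean(resid**2))
        if var < 1e-24:
            adjusted_t = np.full_like(theta_t, mean_fit.predict(z_obs)[0]) + resid
        else:
            log_r2 = np.log(np.maximum(resid**2, var * 1e-12))
            var_fit = _MeanFit(seed + 1000 + j).fit(X, log_r2)
            sigma = np.exp(0.5 * var_fit.predict(X))
            sigma_obs = np.exp(0.5 * var_fit.predict(z_obs)[0])
            floor = np.quantile(sigma, 0.05)
            sigma = np.maximum(sigma, max(floor, 1e-12))
            adjusted_t = mean_fit.predict(z_obs)[0] + resid * sigma_obs / sigma
        adjusted = np.exp(adjusted_t) if log_transform else adjusted_t
        q05, med, q95 = weighted_quantile(adjusted, [0.05, 0.5, 0.95], w)
        rows.append({"parameter": name, "q05": q05, "median": med, "q95": q95})
        adj_cols[name] = adjusted
    summary = pd.DataFrame(rows).set_index("parameter")
    return ParamEstimate(summary=summary, adjusted=pd.DataFrame(adj_cols))


def validate_model_choice(
    K: int = 150,
    M: int = 20000,
    tolerance: float = 0.01,
    design: StudyDesign | None = None,
    seed: int = 0,
    mode: str = "sequence",
    ref: ReferenceTable | None = None,
) -> pd.DataFrame:
    """Confusion matrix (%) of MLR model choice on pseudo-observed data.

    For each demographic model, ``K`` pseudo-observed panels are simulated
    with parameters from the priors and assigned to the model with the
    highest MLR posterior probability against a fresh reference table of
    ``M`` simulations (equal counts per model).  Rows are the true
    models, columns the assigned models, in TP/S/SDG order.
    """
    design = design or StudyDesign()
    rng = np.random.default_rng(seed)
    if ref is None:
        ref = simulate_reference_table(M, design, seed=rng, mode=mode)
    counts = pd.DataFrame(0.0, index=list(MODELS), columns=list(MODELS))
    for kind in MODELS:
        for _ in range(K):
            params = draw_model_params(kind, design, rng)
            panel, _ = simulate_study_panel(kind, params, design, rng)
            obs = sumstat_vector(panel, mode=mode)
            with warnings.catch_warnings():
                # absent-from-accepted models are routine here
                warnings.simplefilter("ignore", UserWarning)
                post = model_posterior_mlr(ref, obs, tolerance)
            probs = np.array([post.probs[m] for m in MODELS])
            top = np.flatnonzero(probs == probs.max())
            pick = MODELS[int(rng.choice(top))]  # seeded uniform tie-break
            counts.loc[kind, pick] += 1
    return counts / K * 100.0
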