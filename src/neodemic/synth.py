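"""Synthetic inputs with known ground truth for both analysis tracks.

Stand-ins for the published datasets the real study analysed: drifted
haplogroup count tables (admixture track), serially sampled HVS-I-like
sequence panels under the TP/S/SDG demographies (ancient-DNA track) and a
geography fixture for the distance regressions.  Every generator returns a
machine-readable truth record and can write it to JSON next to the data
files; recovery tests read truth only from those records.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from neodemic.admixture import drift_lineage_pmf
from neodemic.coalescent import (
    DEFAULT_SCHEDULE,
    ModelParams,
    MutationConfig,
    build_demography,
    mutate_sequences,
    simulate_genealogy,
)
from neodemic.geo import PopulationGeo, great_circle_distance, NEAR_EAST_ORIGIN
from neodemic.io import HaplogroupCounts, SequencePanel, write_haplogroup_counts, write_sequence_panel

__all__ = [
    "StudyDesign",
    "simulate_admixture_counts",
    "simulate_study_panel",
    "draw_model_params",
    "make_geofixture",
]


@dataclass
class StudyDesign:
    """The emulated study conditions for the ancient-DNA track.

    Defaults: 20 hunter-gatherers at 330 generations BP, 25 early farmers
    at 290, 100 moderns at 0; HVS-I-like sequences (L = 360,
    5e-6 per site per generation); size priors N_UP ~ U(10, 5000) and
    N_N ~ U(1000, 100000); under SDG the farmer-deme share of N_N is a
    nuisance parameter phi ~ U(0.5, 0.95).
    """

    schedule: tuple = DEFAULT_SCHEDULE
    mutation: MutationConfig = field(default_factory=MutationConfig)
    gen_time: float = 25.0
    N_M: float = 100_000.0
    N_A: float = 10_000.0
    nup_prior: tuple[float, float] = (10.0, 5000.0)
    nn_prior: tuple[float, float] = (1000.0, 100_000.0)
    phi_prior: tuple[float, float] = (0.5, 0.95)


def _coerce_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Admixture track
# ---------------------------------------------------------------------------

def _drift_counts(x: np.ndarray, n: int, t: float, rng: np.random.Generator) -> np.ndarray:
    """Forward-generative drifted sample: founder lineages then Pólya urn."""
    K = len(x)
    if t == 0.0:
        return rng.multinomial(n, x)
    pmf = drift_lineage_pmf(n, t)
    m = int(rng.choice(n, p=pmf)) + 1
    types = list(rng.choice(K, size=m, p=x))
    for _ in range(n - m):
        types.append(types[rng.integers(0, len(types))])
    counts = np.bincount(np.asarray(types), minlength=K)
    return counts


def simulate_admixture_counts(
    p1: float,
    t1: float,
    t2: float,
    th: float,
    n_sizes: tuple[int, int, int] = (200, 200, 200),
    K: int = 10,
    seed=None,
    out_prefix: str | Path | None = None,
) -> tuple[HaplogroupCounts, dict]:
    """Haplogroup counts for P1, P2 and an admixed H with known truth.

    Ancestral frequencies x1, x2 are flat-Dirichlet draws; the admixed
    founding frequencies are ``p1*x1 + (1-p1)*x2``; each sample drifts
    independently (founder count from the lineage-death distribution,
    founder types iid, Pólya-urn family sizes).
    """
    if not (0.0 <= p1 <= 1.0):
        raise ValueError("p1 must be in [0, 1]")
    if K < 2:
        raise ValueError("need K >= 2 haplogroups")
    rng = _coerce_rng(seed)
    x1 = rng.dirichlet(np.ones(K))
    x2 = rng.dirichlet(np.ones(K))
    xh = p1 * x1 + (1.0 - p1) * x2
    rows = [
        _drift_counts(x1, n_sizes[0], t1, rng),
        _drift_counts(x2, n_sizes[1], t2, rng),
        _drift_counts(xh, n_sizes[2], th, rng),
    ]
    table = HaplogroupCounts(
        populations=["P1", "P2", "H"],
        haplogroups=[f"hg{k:02d}" for k in range(K)],
        counts=np.vstack(rows),
    )
    truth = {
        "p1": p1, "t1": t1, "t2": t2, "th": th,
        "x1": x1.tolist(), "x2": x2.tolist(), "xh": xh.tolist(),
        "n_sizes": list(n_sizes), "K": K,
    }
    if out_prefix is not None:
        out_prefix = Path(out_prefix)
        write_haplogroup_counts(table, out_prefix.with_suffix(".csv"))
        out_prefix.with_suffix(".truth.json").write_text(json.dumps(truth, indent=1))
    return table, truth


# ---------------------------------------------------------------------------
# Ancient-DNA track
# ---------------------------------------------------------------------------

def draw_model_params(kind: str, design: StudyDesign, rng) -> ModelParams:
    """Draw (N_UP, N_N[, phi]) from the study priors for one simulation."""
    rng = _coerce_rng(rng)
    nup = rng.uniform(*design.nup_prior)
    nn = rng.uniform(*design.nn_prior)
    phi = rng.uniform(*design.phi_prior) if kind == "SDG" else 0.5
    return ModelParams(N_UP=nup, N_N=nn, N_M=design.N_M, N_A=design.N_A, phi=phi)


def simulate_study_panel(
    kind: str,
    params: ModelParams,
    design: StudyDesign | None = None,
    seed=None,
    out_prefix: str | Path | None = None,
) -> tuple[SequencePanel, dict]:
    """One serially sampled sequence panel under TP, S or SDG."""
    design = design or StudyDesign()
    rng = _coerce_rng(seed)
    model = build_demography(kind, params, gen_time=design.gen_time,
                             schedule=design.schedule)
    tree = simulate_genealogy(model, rng)
    panel = mutate_sequences(tree, design.mutation, rng, gen_time=design.gen_time)
    truth = {
        "kind": kind,
        "N_UP": params.N_UP, "N_N": params.N_N,
        "N_M": params.N_M, "N_A": params.N_A, "phi": params.phi,
        "schedule": [list(s) for s in design.schedule],
        "mutation_rate": design.mutation.rate_per_site,
        "length": design.mutation.length,
        "tmrca_gen": tree.tmrca,
    }
    if out_prefix is not None:
        out_prefix = Path(out_prefix)
        write_sequence_panel(panel, out_prefix.with_suffix(".fasta"),
                             out_prefix.with_suffix(".meta.csv"))
        out_prefix.with_suffix(".truth.json").write_text(json.dumps(truth, indent=1))
    return panel, truth


# ---------------------------------------------------------------------------
# Geography fixture
# ---------------------------------------------------------------------------

def make_geofixture(
    n_pops: int = 10,
    gradient=lambda d: 0.2 + 1e-4 * d,
    noise: float = 0.05,
    n_draws: int = 1000,
    max_distance_km: float = 4000.0,
    seed=None,
    out_prefix: str | Path | None = None,
) -> tuple[list[PopulationGeo], dict[str, np.ndarray], dict]:
    """Populations along a transect from the Near East, with posterior draws.

    Populations are placed due south of the origin so the great-circle
    distance is exactly proportional to the latitude offset; per
    population the "posterior" is Gaussian around ``gradient(distance)``
    with standard deviation ``noise`` (a point mass when ``noise=0``).
    """
    if n_pops < 3:
        raise ValueError("need at least 3 populations")
    rng = _coerce_rng(seed)
    lat0, lon0 = NEAR_EAST_ORIGIN
    distances = np.linspace(0.0, max_distance_km, n_pops)
    geo, posteriors = [], {}
    for i, d in enumerate(distances):
        lat = lat0 - np.degrees(d / 6371.0)
        g = PopulationGeo(label=f"pop{i:02d}", lat=lat, lon=lon0)
        # meridian placement: haversine distance equals d exactly
        assert abs(g.distance_km - d) < 1e-6 * max(d, 1.0)
        geo.append(g)
        centre = gradient(d)
        if noise == 0.0:
            draws = np.full(n_draws, centre)
        else:
            draws = centre + noise * rng.standard_normal(n_draws)
        posteriors[g.label] = draws
    truth = {
        "distances_km": distances.tolist(),
        "means": [float(gradient(d)) for d in distances],
        "noise": noise,
    }
    if out_prefix is not None:
        import pandas as pd

        out_prefix = Path(out_prefix)
        pd.DataFrame({
            "label": [g.label for g in geo],
            "lat": [g.lat for g in geo],
            "lon": [g.lon for g in geo],
            "distance_km": [g.distance_km for g in geo],
        }).to_csv(out_prefix.with_suffix(".geo.csv"), index=False)
        pd.DataFrame(posteriors).to_csv(out_prefix.with_suffix(".draws.csv"), index=False)
        out_prefix.with_suffix(".truth.json").write_text(json.dumps(truth, indent=1))
    return geo, posteriors, truth
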