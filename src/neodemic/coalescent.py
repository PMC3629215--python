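"""Serial coalescent simulation with piecewise-exponential deme sizes.

Implements a backwards-in-time haploid (mitochondrial) coalescent in which
samples enter the genealogy at their sampling ages (ancient + modern),
deme sizes follow piecewise-exponential trajectories, and demes merge or
split at event times.  On top of the generic machinery sit builders for
the three demographies of the Central European Neolithic analysis:

TP  (total panmixia)
    One population: exponential growth from N_UP (45,000 y BP, i.e. the
    initial colonisation of Central Europe) to N_N at the Neolithic
    transition (7,500 y BP), then to the modern size N_M; founded from an
    ancestral constant-size African deme N_A.
S   (split)
    As TP, but between 45,000 and 7,500 y BP the population is structured
    into two sub-populations of equal initial size N_UP/2 growing
    independently with no gene flow to N_N1 and N_N2, which join at the
    Neolithic into a single deme of size N_N = N_N1 + N_N2.
SDG (split with differential growth)
    As S, but deme 2 (the farmers' ancestors) holds its initial size
    until 10,000 y BP and then grows to N_N2 in the 10,000–7,500 y BP
    window, while deme 1 (the hunter-gatherers) grows — possibly at a
    near-zero rate — across the whole Palaeolithic phase.

All times are handled in whole generations BP (years floor-divided by the
generation time); coalescence times within the genealogy are continuous.
A pair of lineages in a deme of current size N coalesces at rate 1/N per
generation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from neodemic.io import SequencePanel

__all__ = [
    "ModelParams",
    "MutationConfig",
    "DemographicModel",
    "Genealogy",
    "build_demography",
    "simulate_genealogy",
    "mutate_sequences",
    "DEFAULT_SCHEDULE",
]

#: Emulated sampling design: hunter-gatherers, early farmers, moderns.
DEFAULT_SCHEDULE = (("HG", 330, 20), ("farmer", 290, 25), ("modern", 0, 100))


class ScheduleError(ValueError):
    """A sample is placed in a deme that does not exist at that age."""


@dataclass
class ModelParams:
    """Sizes for the TP/S/SDG demographies (haploid female sizes).

    ``N_UP`` is the Upper-Palaeolithic size at 45,000 y BP, ``N_N`` the
    size at the Neolithic transition (7,500 y BP), ``N_M`` the modern
    size and ``N_A`` the constant ancestral (African) size.  For the
    split models ``phi`` is deme 2's share of N_N at the join
    (N_N2 = phi * N_N, N_N1 = (1 - phi) * N_N).
    """

    N_UP: float
    N_N: float
    N_M: float = 100_000.0
    N_A: float = 10_000.0
    phi: float = 0.5

    def __post_init__(self) -> None:
        for name in ("N_UP", "N_N", "N_M", "N_A"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not (0.0 < self.phi < 1.0):
            raise ValueError("phi must be in (0, 1)")


@dataclass
class MutationConfig:
    """Finite-sites neutral mutation layer (Jukes–Cantor by default)."""

    rate_per_site: float = 5e-6  # per generation, HVS-I-like
    length: int = 360

    def __post_init__(self) -> None:
        if self.rate_per_site < 0 or self.length < 1:
            raise ValueError("invalid mutation config")


@dataclass
class Epoch:
    """Size trajectory segment between two generation-BP boundaries.

    ``size_young``/``size_old`` are the deme sizes at the younger/older
    boundary; in between the size interpolates exponentially.
    """

    young: float
    old: float
    size_young: float
    size_old: float

    def size_at(self, g: float) -> float:
        if self.old == self.young or self.size_young == self.size_old:
            return self.size_young
        frac = (g - self.young) / (self.old - self.young)
        return self.size_young * (self.size_old / self.size_young) ** frac

    @property
    def forward_growth_rate(self) -> float:
        """Per-generation exponential growth rate, forwards in time."""
        if self.old == self.young:
            return 0.0
        return float(np.log(self.size_young / self.size_old) / (self.old - self.young))


@dataclass
class Deme:
    name: str
    epochs: list[Epoch]  # ordered young -> old; last may be open-ended

    def size_at(self, g: float) -> float:
        for ep in self.epochs:
            if ep.young <= g <= ep.old:
                return ep.size_at(g)
        raise ValueError(f"deme {self.name} undefined at generation {g}")

    def active_at(self, g: float) -> bool:
        return self.epochs[0].young <= g <= self.epochs[-1].old


@dataclass
class Event:
    """Backward-time structural event.

    ``kind='move'`` sends every lineage of ``source`` into ``dest[0]``;
    ``kind='split'`` (the backward view of a forward join) sends each
    lineage of ``source`` independently into ``dest[i]`` with probability
    ``probs[i]`` — proportional to the joining demes' sizes.
    """

    time: float
    kind: str
    source: str
    dest: tuple[str, ...]
    probs: tuple[float, ...] = ()


@dataclass
class DemographicModel:
    kind: str
    demes: dict[str, Deme]
    events: list[Event]
    schedule: list[tuple[str, str, float, int]]  # (label, deme, gen BP, n)
    params: ModelParams | None = None

    def validate(self) -> None:
        for label, deme, g, n in self.schedule:
            if deme not in self.demes:
                raise ScheduleError(f"unknown deme {deme!r} for sample {label!r}")
            if not self.demes[deme].active_at(g):
                raise ScheduleError(
                    f"sample {label!r} at generation {g} outside deme {deme!r}")
            for ev in self.events:
                if ev.source == deme and ev.time < g:
                    raise ScheduleError(
                        f"sample {label!r} placed in {deme!r} after its merge time")
            if n < 1:
                raise ScheduleError("sample size must be >= 1")


def build_demography(
    kind: str,
    params: ModelParams,
    gen_time: float = 25.0,
    schedule: tuple[tuple[str, float, int], ...] = DEFAULT_SCHEDULE,
    t_colonise_years: float = 45_000.0,
    t_boost_years: float = 10_000.0,
    t_neolithic_years: float = 7_500.0,
) -> DemographicModel:
    """Construct the TP, S or SDG demography.

    The event times (45,000 / 10,000 / 7,500 years BP by default) are
    floor-converted to generations (1800 / 400 / 300 at a 25-year
    generation time).  The schedule entries are (label, generations BP, n);
    samples older than the Neolithic join are placed in deme 1 (the
    hunter-gatherer deme) under the split models.
    """
    if kind not in ("TP", "S", "SDG"):
        raise ValueError(f"unknown model kind {kind!r}")
    if params.N_M < params.N_N:
        warnings.warn("N_M < N_N: modern phase shrinks; allowed but unusual")
    g_col = float(np.floor(t_colonise_years / gen_time))
    g_boost = float(np.floor(t_boost_years / gen_time))
    g_neo = float(np.floor(t_neolithic_years / gen_time))

    anc = Deme("anc", [Epoch(g_col, np.inf, params.N_A, params.N_A)])
    demes: dict[str, Deme]
    events: list[Event]
    if kind == "TP":
        pop = Deme("pop", [
            Epoch(0.0, g_neo, params.N_M, params.N_N),
            Epoch(g_neo, g_col, params.N_N, params.N_UP),
        ])
        demes = {"pop": pop, "anc": anc}
        events = [Event(g_col, "move", "pop", ("anc",))]
    else:
        N_half = params.N_UP / 2.0
        N_N2 = params.phi * params.N_N
        N_N1 = params.N_N - N_N2
        pop = Deme("pop", [Epoch(0.0, g_neo, params.N_M, params.N_N)])
        hg = Deme("hg", [Epoch(g_neo, g_col, N_N1, N_half)])
        if kind == "S":
            farm = Deme("farm", [Epoch(g_neo, g_col, N_N2, N_half)])
        else:  # SDG: deme 2 constant until the boost window
            farm = Deme("farm", [
                Epoch(g_neo, min(g_boost, g_col), N_N2, N_half),
                Epoch(min(g_boost, g_col), g_col, N_half, N_half),
            ])
        demes = {"pop": pop, "hg": hg, "farm": farm, "anc": anc}
        events = [
            Event(g_neo, "split", "pop", ("hg", "farm"),
                  (N_N1 / params.N_N, N_N2 / params.N_N)),
            Event(g_col, "move", "hg", ("anc",)),
            Event(g_col, "move", "farm", ("anc",)),
        ]

    sched = []
    for label, g, n in schedule:
        if kind == "TP":
            deme = "pop"
        else:
            deme = "hg" if g >= g_neo else "pop"
        sched.append((label, deme, float(g), int(n)))
    model = DemographicModel(kind=kind, demes=demes, events=events,
                             schedule=sched, params=params)
    model.validate()
    return model


@dataclass
class Genealogy:
    """Binary genealogy; node ages in generations BP, tips first."""

    parent: np.ndarray      # index of parent node, -1 for the root
    time: np.ndarray        # node ages (generations BP)
    n_tips: int
    tip_labels: list[str] = field(default_factory=list)
    tip_ids: list[str] = field(default_factory=list)

    @property
    def n_nodes(self) -> int:
        return len(self.time)

    @property
    def tmrca(self) -> float:
        return float(self.time[-1])

    def branch_lengths(self) -> np.ndarray:
        bl = np.zeros(self.n_nodes)
        has_parent = self.parent >= 0
        bl[has_parent] = self.time[self.parent[has_parent]] - self.time[has_parent]
        return bl

    @property
    def total_branch_length(self) -> float:
        return float(self.branch_lengths().sum())

    def newick(self) -> str:
        children: dict[int, list[int]] = {}
        for i, p in enumerate(self.parent):
            if p >= 0:
                children.setdefault(int(p), []).append(i)

        def fmt(i: int) -> str:
            bl = 0.0 if self.parent[i] < 0 else self.time[self.parent[i]] - self.time[i]
            if i < self.n_tips:
                return f"{self.tip_ids[i]}:{bl:.6f}"
            inner = ",".join(fmt(c) for c in children[i])
            return f"({inner}):{bl:.6f}"

        root = int(np.flatnonzero(self.parent < 0)[0])
        return fmt(root).rsplit(":", 1)[0] + ";"


def _segment_coalescence_time(
    k: int, N0: float, beta: float, max_s: float, rng: np.random.Generator
) -> float | None:
    """Waiting time to the next coalescence within one exponential segment.

    Backwards from the segment entry point the deme size is
    ``N(s) = N0 * exp(beta * s)``; k lineages coalesce at pair rate
    ``C(k,2)/N(s)``.  Returns the waiting time, or None if no coalescence
    occurs within ``max_s`` (exponential redraw across segments is valid
    by memorylessness).
    """
    if k < 2:
        return None
    rate0 = k * (k - 1) / 2.0 / N0
    E = rng.exponential()
    if abs(beta) < 1e-12:
        s = E / rate0
    else:
        arg = 1.0 - E * beta / rate0
        if arg <= 0.0:
            return None  # hazard integral bounded; no event in this segment
        s = -np.log(arg) / beta
    return s if s <= max_s else None


def simulate_genealogy(
    model: DemographicModel, seed: int | np.random.Generator | None = None
) -> Genealogy:
    """Backwards-in-time serial coalescent under a demographic model."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    model.validate()

    # tips, ordered as in the schedule
    tip_labels: list[str] = []
    tip_ids: list[str] = []
    tip_age: list[float] = []
    tip_deme: list[str] = []
    for label, deme, g, n in model.schedule:
        for i in range(n):
            tip_ids.append(f"{label}_{i}")
            tip_labels.append(label)
            tip_age.append(g)
            tip_deme.append(deme)
    S = len(tip_ids)

    times = list(map(float, tip_age))
    parent = [-1] * S
    active: dict[str, list[int]] = {d: [] for d in model.demes}

    # structural moments: sampling times, events, epoch boundaries
    moments: set[float] = set()
    for _, _, g, _ in model.schedule:
        moments.add(float(g))
    for ev in model.events:
        moments.add(float(ev.time))
    for deme in model.demes.values():
        for ep in deme.epochs:
            moments.add(float(ep.young))
            if np.isfinite(ep.old):
                moments.add(float(ep.old))
    timeline = sorted(moments)

    def enter_samples(g: float) -> None:
        for idx, (a, d) in enumerate(zip(tip_age, tip_deme)):
            if a == g:
                active[d].append(idx)

    def run_interval(g_from: float, g_to: float) -> float:
        """Coalesce within [g_from, g_to]; returns the reached time."""
        g = g_from
        while True:
            best: tuple[float, str] | None = None
            for dname, lin in active.items():
                k = len(lin)
                if k < 2:
                    continue
                deme = model.demes[dname]
                N0 = deme.size_at(g)
                # backward growth exponent of the current epoch
                ep = next(e for e in deme.epochs if e.young <= g < e.old or
                          (g == e.old == e.young))
                if np.isfinite(ep.old) and ep.old != ep.young:
                    beta = (np.log(ep.size_old / ep.size_young)
                            / (ep.old - ep.young))
                else:
                    beta = 0.0
                s = _segment_coalescence_time(k, N0, beta, g_to - g, rng)
                if s is not None and (best is None or g + s < best[0]):
                    best = (g + s, dname)
            if best is None:
                return g_to
            g, dname = best
            lin = active[dname]
            i, j = rng.choice(len(lin), size=2, replace=False)
            a, b = lin[i], lin[j]
            node = len(times)
            times.append(g)
            parent.append(-1)
            parent[a] = node
            parent[b] = node
            lin[:] = [x for x in lin if x not in (a, b)] + [node]

    def apply_events(g: float) -> None:
        for ev in model.events:
            if ev.time == g:
                movers = active[ev.source]
                if ev.kind == "move":
                    active[ev.dest[0]].extend(movers)
                elif movers:  # split
                    choice = rng.choice(len(ev.dest), size=len(movers), p=ev.probs)
                    for lin, c in zip(movers, choice):
                        active[ev.dest[c]].append(lin)
                active[ev.source] = []

    # main loop over structural moments
    g_now = timeline[0]
    enter_samples(g_now)
    apply_events(g_now)
    for g_next in timeline[1:]:
        g_now = run_interval(g_now, g_next)
        enter_samples(g_next)
        apply_events(g_next)

    # beyond the last structural moment: single ancestral deme
    remaining = [d for d, lin in active.items() if lin]
    if len(remaining) > 1:
        raise ScheduleError("lineages stranded in more than one terminal deme")
    if sum(len(v) for v in active.values()) > 1:
        dname = remaining[0]
        N = model.demes[dname].size_at(g_now if g_now > 0 else 0.0)
        lin = active[dname]
        g = g_now
        while len(lin) > 1:
            k = len(lin)
            g += rng.exponential() / (k * (k - 1) / 2.0 / N)
            i, j = rng.choice(k, size=2, replace=False)
            a, b = lin[i], lin[j]
            node = len(times)
            times.append(g)
            parent.append(-1)
            lin[:] = [x for x in lin if x not in (a, b)] + [node]
            parent[a] = node
            parent[b] = node

    return Genealogy(parent=np.asarray(parent), time=np.asarray(times),
                     n_tips=S, tip_labels=tip_labels, tip_ids=tip_ids)


def mutate_sequences(
    tree: Genealogy,
    mcfg: MutationConfig | None = None,
    seed: int | np.random.Generator | None = None,
    gen_time: float = 25.0,
) -> SequencePanel:
    """Drop Jukes–Cantor mutations on a genealogy and emit a panel.

    Mutations per branch are Poisson(rate_per_site * L * branch length);
    each hits a uniform site and substitutes the current base by one of
    the other three.  The root sequence is uniform random.
    """
    mcfg = mcfg or MutationConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    L = mcfg.length
    n_nodes = tree.n_nodes
    seqs = np.empty((n_nodes, L), dtype=np.uint8)
    root = int(np.flatnonzero(tree.parent < 0)[0])
    seqs[root] = rng.integers(0, 4, size=L, dtype=np.uint8)
    bl = tree.branch_lengths()
    # children-first order: process nodes by decreasing age
    order = np.argsort(-tree.time, kind="stable")
    for node in order:
        node = int(node)
        p = tree.parent[node]
        if p < 0:
            continue
        seq = seqs[p].copy()
        n_mut = rng.poisson(mcfg.rate_per_site * L * bl[node])
        for _ in range(n_mut):
            site = rng.integers(0, L)
            seq[site] = (seq[site] + rng.integers(1, 4)) % 4
        seqs[node] = seq
    tips = seqs[: tree.n_tips]
    ages_gen = tree.time[: tree.n_tips].astype(int)
    return SequencePanel(
        ids=list(tree.tip_ids),
        seqs=tips,
        labels=list(tree.tip_labels),
        ages_years=ages_gen * gen_time,
        ages_gen=ages_gen,
    )
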