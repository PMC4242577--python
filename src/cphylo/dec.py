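"""Dispersal--extinction--cladogenesis (DEC) likelihood with epoch
stratification, ML fitting, root-range profiling, and hypothesis
comparison.

The model (Ree & Smith 2008) treats a species' geographic range as a
set of discrete areas.  Along branches the range evolves by a
continuous-time Markov process: an area ``a`` is added at rate
``d * sum_{b in range} M[b, a]`` (dispersal, modulated by a per-epoch
area-pair multiplier matrix ``M``) and each occupied area is lost at
rate ``e`` (local extinction; a single-area range transitions to the
absorbing empty state).  At cladogenesis a multi-area range splits
into ordered daughter ranges by vicariance or subset sympathy, each
enumerated scenario equally likely.

All times in this module are kiloyears before present (KYA) and rates
are per kiloyear; trees supplied in years should be divided by 1000 at
the boundary.  Epoch tables are ordered youngest-first and must tile
``[0, root age]`` without gaps.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import expm
from scipy.optimize import minimize

from cphylo.chrono import Chronogram
from cphylo.errors import ArgumentError, ConfigurationError

log = logging.getLogger(__name__)

#: Default refugium fixture: six candidate glacial refugia for the
#: Cordilleran alpine flora, ordered roughly north to south.
DEFAULT_AREAS = (
    "Beringia",
    "Olympics",
    "N_Cascades",
    "S_Cascades",
    "C_Rockies",
    "S_Rockies",
)

#: Approximate central latitudes used to orient "northward" dispersal.
DEFAULT_LATITUDES = {
    "Beringia": 64.0,
    "Olympics": 47.8,
    "N_Cascades": 48.5,
    "S_Cascades": 44.0,
    "C_Rockies": 44.5,
    "S_Rockies": 38.0,
}

#: Default adjacency between refugia (editable; see data/areas_adjacency.csv).
DEFAULT_ADJACENCY = (
    ("Beringia", "N_Cascades"),
    ("Olympics", "N_Cascades"),
    ("Olympics", "S_Cascades"),
    ("N_Cascades", "S_Cascades"),
    ("N_Cascades", "C_Rockies"),
    ("S_Cascades", "C_Rockies"),
    ("C_Rockies", "S_Rockies"),
)

_COASTAL = {"Olympics", "N_Cascades", "S_Cascades"}
_ROCKIES = {"C_Rockies", "S_Rockies"}

HYPOTHESIS_NAMES = ("multiple_refugia", "northward_expansion", "southward_expansion")


# -- state space ------------------------------------------------------


@dataclass(frozen=True)
class AreaSet:
    """Ordered, unique area names; order fixes state indexing."""

    names: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.names) == 0:
            raise ArgumentError("AreaSet must contain at least one area")
        if len(set(self.names)) != len(self.names):
            raise ArgumentError("area names must be unique")

    def __len__(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        return self.names.index(name)


@dataclass
class RangeStateSpace:
    """All ranges of size <= ``max_range_size`` plus the empty range.

    State 0 is the empty (extinct) range; living states follow in
    (size, lexicographic-member-index) order, e.g. for areas (A, B)
    with max size 2: [{}, {A}, {B}, {A,B}].
    """

    areas: AreaSet
    max_range_size: int
    states: list[frozenset[str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.areas)
        if not (1 <= self.max_range_size <= n):
            raise ArgumentError(
                f"max_range_size must be in [1, {n}], got {self.max_range_size}"
            )
        if not self.states:
            states: list[frozenset[str]] = [frozenset()]
            for size in range(1, self.max_range_size + 1):
                for combo in itertools.combinations(range(n), size):
                    states.append(frozenset(self.areas.names[i] for i in combo))
            self.states = states
        self._index = {s: i for i, s in enumerate(self.states)}

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def n_living(self) -> int:
        return len(self.states) - 1

    @property
    def living_states(self) -> list[frozenset[str]]:
        return self.states[1:]

    def state_index(self, state: Iterable[str]) -> int:
        key = frozenset(state)
        if key not in self._index:
            raise ArgumentError(f"range {sorted(key)} not in state space")
        return self._index[key]

    def label(self, state: frozenset[str]) -> str:
        if not state:
            return "(extinct)"
        order = {a: i for i, a in enumerate(self.areas.names)}
        return "+".join(sorted(state, key=order.__getitem__))


def build_state_space(areas: AreaSet | Sequence[str], max_range_size: int = 2) -> RangeStateSpace:
    if not isinstance(areas, AreaSet):
        areas = AreaSet(tuple(areas))
    return RangeStateSpace(areas=areas, max_range_size=max_range_size)


# -- hypotheses -------------------------------------------------------


@dataclass
class Epoch:
    """One time slice with its dispersal multiplier matrix.

    ``start_kya < end_kya`` (younger bound first); ``multipliers`` is an
    (n_areas, n_areas) non-negative matrix with zero diagonal.
    """

    start_kya: float
    end_kya: float
    glacial: bool
    multipliers: np.ndarray

    def __post_init__(self) -> None:
        self.multipliers = np.asarray(self.multipliers, dtype=float)
        if np.any(self.multipliers < 0):
            raise ArgumentError("dispersal multipliers must be non-negative")
        np.fill_diagonal(self.multipliers, 0.0)
        if self.start_kya >= self.end_kya:
            raise ArgumentError("epoch start_kya must be < end_kya")


@dataclass
class BiogeoHypothesis:
    """Named biogeographic scenario as an ordered (young-first) epoch list."""

    name: str
    areas: AreaSet
    epochs: list[Epoch]

    def __post_init__(self) -> None:
        t = 0.0
        for ep in self.epochs:
            if not math.isclose(ep.start_kya, t, abs_tol=1e-9):
                raise ConfigurationError(
                    f"epoch table has a gap/overlap at {ep.start_kya} KYA (expected {t})"
                )
            t = ep.end_kya

    @property
    def span_kya(self) -> float:
        return self.epochs[-1].end_kya

    def epoch_at(self, t_kya: float) -> int:
        """Index of the epoch in force at time ``t_kya`` before present."""
        for i, ep in enumerate(self.epochs):
            if ep.start_kya <= t_kya < ep.end_kya or (
                i == len(self.epochs) - 1 and math.isclose(t_kya, ep.end_kya)
            ):
                return i
        raise ConfigurationError(f"time {t_kya} KYA outside epoch table [0, {self.span_kya}]")


#: Interglacial intervals (KYA) used by the default epoch table; the most
#: recent one carries present-day connectivity, older ones last-interglacial
#: connectivity, and every remaining interval is glacial.  The boundaries
#: are a documented package default, configurable per run.
DEFAULT_INTERGLACIALS = ((0.0, 14.0), (115.0, 130.0), (190.0, 245.0), (320.0, 340.0), (405.0, 425.0))


def default_epoch_intervals(root_age_kya: float) -> list[tuple[float, float, bool, str]]:
    """Tile [0, root_age] into (start, end, glacial, connectivity) tuples."""
    marks = [0.0]
    for a, b in DEFAULT_INTERGLACIALS:
        if a < root_age_kya:
            marks.extend([a, min(b, root_age_kya)])
    marks.append(root_age_kya)
    marks = sorted(set(marks))
    out = []
    for a, b in zip(marks[:-1], marks[1:]):
        inter = any(ia <= a and b <= ib for ia, ib in DEFAULT_INTERGLACIALS)
        if inter:
            conn = "present" if b <= DEFAULT_INTERGLACIALS[0][1] else "lig"
        else:
            conn = "lgm"
        out.append((a, b, not inter, conn))
    return out


def _base_pair_matrix(
    name: str,
    areas: AreaSet,
    adjacency: Iterable[tuple[str, str]],
    latitudes: dict[str, float],
) -> np.ndarray:
    """Directed base dispersal multipliers for one hypothesis.

    multiple_refugia: 1.0 both ways between adjacent areas.
    northward_expansion: 1.0 for adjacent south-to-north moves, 0.001
    for the reverse; southward_expansion mirrors it.
    """
    n = len(areas)
    M = np.zeros((n, n))
    for a, b in adjacency:
        i, j = areas.index(a), areas.index(b)
        if name == "multiple_refugia":
            M[i, j] = M[j, i] = 1.0
        else:
            north_first = latitudes[a] > latitudes[b]
            hi, lo = (i, j) if north_first else (j, i)
            if name == "northward_expansion":
                M[lo, hi], M[hi, lo] = 1.0, 0.001
            elif name == "southward_expansion":
                M[hi, lo], M[lo, hi] = 1.0, 0.001
            else:
                raise ArgumentError(f"unknown hypothesis {name!r}")
    return M


def _apply_connectivity(M: np.ndarray, conn: str, areas: AreaSet) -> np.ndarray:
    """Zero out area pairs that a given climate state disconnects.

    Glacial (lgm): the northern refugium is cut off from everything
    south of the ice sheets.  Older interglacials (lig): the coastal
    ranges are cut off from the Rockies (southern fragmentation).
    Present connectivity leaves the base matrix unchanged.
    """
    out = M.copy()
    if conn == "present":
        return out
    for i, a in enumerate(areas.names):
        for j, b in enumerate(areas.names):
            if conn == "lgm" and ("Beringia" in (a, b)) and a != b:
                out[i, j] = 0.0
            if conn == "lig" and {a, b} & _COASTAL and {a, b} & _ROCKIES:
                out[i, j] = 0.0
    return out


def make_hypothesis(
    name: str,
    root_age_kya: float,
    areas: AreaSet | Sequence[str] = DEFAULT_AREAS,
    adjacency: Iterable[tuple[str, str]] = DEFAULT_ADJACENCY,
    latitudes: dict[str, float] | None = None,
    intervals: Sequence[tuple[float, float, bool, str]] | None = None,
) -> BiogeoHypothesis:
    """Build one of the three named hypotheses over the epoch table."""
    if name not in HYPOTHESIS_NAMES:
        raise ArgumentError(f"hypothesis must be one of {HYPOTHESIS_NAMES}, got {name!r}")
    if not isinstance(areas, AreaSet):
        areas = AreaSet(tuple(areas))
    latitudes = latitudes or DEFAULT_LATITUDES
    base = _base_pair_matrix(name, areas, adjacency, latitudes)
    if intervals is None:
        intervals = default_epoch_intervals(root_age_kya)
    epochs = [
        Epoch(a, b, glacial, _apply_connectivity(base, conn, areas))
        for a, b, glacial, conn in intervals
    ]
    return BiogeoHypothesis(name=name, areas=areas, epochs=epochs)


# -- rate matrices and branch propagation -----------------------------


def anagenetic_rate_matrix(
    space: RangeStateSpace, multipliers: np.ndarray, d: float, e: float
) -> np.ndarray:
    """Instantaneous rate matrix over the full state space.

    rate(R -> R + {a}) = d * sum_{b in R} multipliers[b, a] for a not in
    R with |R + {a}| <= max size; rate(R -> R - {a}) = e per occupied
    area (single-area ranges go extinct); the empty state is absorbing.
    """
    if d < 0 or e < 0:
        raise ArgumentError("d and e must be >= 0")
    multipliers = np.asarray(multipliers, dtype=float)
    if np.any(multipliers < 0):
        raise ArgumentError("dispersal multipliers must be non-negative")
    n = space.n_states
    Q = np.zeros((n, n))
    name_idx = {a: i for i, a in enumerate(space.areas.names)}
    for si, R in enumerate(space.states):
        if not R:
            continue  # absorbing
        # dispersal
        if len(R) < space.max_range_size:
            src = [name_idx[b] for b in R]
            for a in space.areas.names:
                if a in R:
                    continue
                rate = d * float(multipliers[src, name_idx[a]].sum())
                if rate > 0:
                    Q[si, space.state_index(R | {a})] += rate
        # local extinction
        for a in R:
            Q[si, space.state_index(R - {a})] += e
    np.fill_diagonal(Q, Q.diagonal() - Q.sum(axis=1))
    return Q


class EpochPropagator:
    """Caches per-epoch rate matrices and matrix exponentials.

    One instance serves all branches of a tree for a fixed (d, e); the
    matrix exponential of a full epoch is computed once and reused.
    """

    def __init__(self, space: RangeStateSpace, hypothesis: BiogeoHypothesis, d: float, e: float):
        self.space = space
        self.hypothesis = hypothesis
        self.Q = [anagenetic_rate_matrix(space, ep.multipliers, d, e) for ep in hypothesis.epochs]
        self._cache: dict[tuple[int, float], np.ndarray] = {}

    def _segment(self, epoch_idx: int, dt: float) -> np.ndarray:
        key = (epoch_idx, round(dt, 12))
        if key not in self._cache:
            self._cache[key] = expm(self.Q[epoch_idx] * dt)
        return self._cache[key]

    def probability(self, t_start: float, t_end: float) -> np.ndarray:
        """Transition matrix along a branch from ``t_start`` (older) to
        ``t_end`` KYA; product of per-epoch exponentials ordered oldest
        to youngest."""
        if t_end < -1e-9 or t_start < t_end - 1e-9:
            raise ArgumentError(f"need t_start >= t_end >= 0, got ({t_start}, {t_end})")
        t_end = max(t_end, 0.0)
        n = self.space.n_states
        if t_start - t_end <= 1e-12:
            return np.eye(n)
        if t_start > self.hypothesis.span_kya + 1e-9:
            raise ConfigurationError(
                f"branch start {t_start} KYA outside epoch table [0, {self.hypothesis.span_kya}]"
            )
        # collect epoch segments intersecting [t_end, t_start]
        segments = []  # (epoch_idx, dt), youngest first
        for i, ep in enumerate(self.hypothesis.epochs):
            lo = max(ep.start_kya, t_end)
            hi = min(ep.end_kya, t_start)
            if hi - lo > 1e-12:
                segments.append((i, hi - lo))
        P = np.eye(n)
        for epoch_idx, dt in reversed(segments):  # oldest first
            P = P @ self._segment(epoch_idx, dt)
        return P


def branch_probability(
    space: RangeStateSpace,
    hypothesis: BiogeoHypothesis,
    d: float,
    e: float,
    t_start: float,
    t_end: float,
) -> np.ndarray:
    """Transition probabilities along one branch (see EpochPropagator)."""
    return EpochPropagator(space, hypothesis, d, e).probability(t_start, t_end)


# -- cladogenesis -----------------------------------------------------


def cladogenesis_table(
    parent_range: frozenset[str] | Iterable[str],
) -> list[tuple[frozenset[str], frozenset[str], float]]:
    """Ordered daughter-range scenarios at a speciation event.

    A single-area range is inherited identically by both daughters.
    For |R| >= 2, for every area ``a`` in R the enumeration includes
    vicariance ({a}, R - {a}) and subset sympatry ({a}, R), each in
    both daughter orders, de-duplicated; all scenarios are equally
    likely.  For |R| = 2 this yields 6 ordered scenarios of weight 1/6.
    """
    R = frozenset(parent_range)
    if not R:
        raise ArgumentError("cladogenesis undefined for the empty range")
    if len(R) == 1:
        return [(R, R, 1.0)]
    scenarios: list[tuple[frozenset[str], frozenset[str]]] = []
    for a in sorted(R):
        single = frozenset({a})
        rest = R - single
        for pair in ((single, rest), (rest, single), (single, R), (R, single)):
            if pair not in scenarios:
                scenarios.append(pair)
    p = 1.0 / len(scenarios)
    return [(l, r, p) for l, r in scenarios]


# -- pruning likelihood -----------------------------------------------


def _node_age_map(tree: Chronogram, scale: float) -> dict:
    return {node: age / scale for node, age in tree.node_ages().items()}


def _postorder_downpass(
    tree: Chronogram,
    tip_ranges: dict[str, frozenset[str]],
    space: RangeStateSpace,
    prop: EpochPropagator,
    time_scale: float,
) -> np.ndarray:
    """Conditional likelihood vector over living states at the root."""
    ages = _node_age_map(tree, time_scale)
    n_liv = space.n_living
    down: dict = {}
    clado_cache: dict[frozenset[str], list] = {}
    for node in tree.tree.postorder_node_iter():
        if node.is_leaf():
            label = node.taxon.label
            if label not in tip_ranges:
                raise ArgumentError(f"tip {label!r} missing from range table")
            vec = np.zeros(n_liv)
            vec[space.state_index(tip_ranges[label]) - 1] = 1.0
            down[node] = vec
        else:
            kids = node.child_nodes()
            if len(kids) != 2:
                raise ArgumentError("DEC likelihood requires a strictly binary tree")
            branch_vecs = []
            for kid in kids:
                P = prop.probability(ages[node], ages[kid])[1:, 1:]
                branch_vecs.append(P @ down[kid])
            wl, wr = branch_vecs
            vec = np.zeros(n_liv)
            for si, R in enumerate(space.living_states):
                table = clado_cache.setdefault(R, cladogenesis_table(R))
                total = 0.0
                for left, right, p in table:
                    total += p * wl[space.state_index(left) - 1] * wr[space.state_index(right) - 1]
                vec[si] = total
            down[node] = vec
    return down[tree.tree.seed_node]


def tree_negloglik(
    tree: Chronogram,
    tip_ranges: dict[str, frozenset[str]],
    hypothesis: BiogeoHypothesis,
    d: float,
    e: float,
    space: RangeStateSpace | None = None,
    max_range_size: int = 2,
    time_scale: float = 1.0,
) -> float:
    """-ln likelihood of the tip ranges under DEC.

    Root states are weighted uniformly over living states.  ``tree``
    must be ultrametric with branch lengths in KY (set ``time_scale``
    to 1000 for trees in years).  Returns +inf for impossible data.
    """
    if space is None:
        space = build_state_space(hypothesis.areas, max_range_size)
    prop = EpochPropagator(space, hypothesis, d, e)
    root_vec = _postorder_downpass(tree, tip_ranges, space, prop, time_scale)
    lik = float(root_vec.mean())
    if lik <= 0 or not np.isfinite(lik):
        return float("inf")
    return -math.log(lik)


def root_range_profile(
    tree: Chronogram,
    tip_ranges: dict[str, frozenset[str]],
    hypothesis: BiogeoHypothesis,
    d: float,
    e: float,
    window: float = 2.0,
    space: RangeStateSpace | None = None,
    max_range_size: int = 2,
    time_scale: float = 1.0,
) -> list[tuple[frozenset[str], float]]:
    """Per-root-state -ln likelihood, ascending, within ``window`` units
    of the best state (window = inf returns the full profile)."""
    if space is None:
        space = build_state_space(hypothesis.areas, max_range_size)
    prop = EpochPropagator(space, hypothesis, d, e)
    root_vec = _postorder_downpass(tree, tip_ranges, space, prop, time_scale)
    entries = []
    for si, R in enumerate(space.living_states):
        lik = root_vec[si]
        nll = -math.log(lik) if lik > 0 else float("inf")
        entries.append((R, nll))
    entries.sort(key=lambda t: t[1])
    best = entries[0][1]
    return [ent for ent in entries if ent[1] <= best + window]


@dataclass
class DECFit:
    """ML estimates of the DEC rates for one hypothesis.

    ``d`` and ``e`` are per kiloyear; ``root_profile`` lists root
    ranges within two log-likelihood units of the best, ascending.
    """

    hypothesis: str
    d: float
    e: float
    neg_log_lik: float
    root_profile: list[tuple[frozenset[str], float]]
    converged: bool = True


_DEFAULT_STARTS = ((0.01, 0.01), (0.1, 0.001))
_RATE_BOUNDS = (1e-10, 10.0)


def fit_hypothesis(
    tree: Chronogram,
    tip_ranges: dict[str, frozenset[str]],
    hypothesis: BiogeoHypothesis,
    starts: Sequence[tuple[float, float]] = _DEFAULT_STARTS,
    tol: float = 1e-8,
    window: float = 2.0,
    space: RangeStateSpace | None = None,
    max_range_size: int = 2,
    time_scale: float = 1.0,
) -> DECFit:
    """Maximize the DEC likelihood over (d, e) on the log scale.

    Uses bounded derivative-free (Powell) optimization from each start;
    rates are constrained to [1e-10, 10] per KY.
    """
    if space is None:
        space = build_state_space(hypothesis.areas, max_range_size)

    lo, hi = math.log(_RATE_BOUNDS[0]), math.log(_RATE_BOUNDS[1])

    def objective(x: np.ndarray) -> float:
        d, e = math.exp(x[0]), math.exp(x[1])
        nll = tree_negloglik(
            tree, tip_ranges, hypothesis, d, e, space=space, time_scale=time_scale
        )
        # keep the line search finite when the likelihood underflows
        return min(nll, 1e12)

    best = None
    converged = False
    for d0, e0 in starts:
        res = minimize(
            objective,
            x0=np.log([d0, e0]),
            method="Powell",
            bounds=[(lo, hi), (lo, hi)],
            options={"ftol": tol, "xtol": 1e-6, "maxiter": 2000},
        )
        if best is None or res.fun < best.fun:
            best = res
            converged = bool(res.success)
    if not converged:
        log.warning("DEC optimizer did not report convergence for %s; using best found", hypothesis.name)
    d_hat, e_hat = (float(math.exp(v)) for v in best.x)
    profile = root_range_profile(
        tree, tip_ranges, hypothesis, d_hat, e_hat,
        window=window, space=space, time_scale=time_scale,
    )
    return DECFit(
        hypothesis=hypothesis.name,
        d=d_hat,
        e=e_hat,
        neg_log_lik=float(best.fun),
        root_profile=profile,
        converged=converged,
    )


def compare_hypotheses(
    tree: Chronogram,
    tip_ranges: dict[str, frozenset[str]],
    hypotheses: Sequence[BiogeoHypothesis],
    **fit_kwargs,
) -> pd.DataFrame:
    """Fit every hypothesis independently; rank by -ln L ascending."""
    if len(hypotheses) < 2:
        raise ArgumentError("need at least 2 hypotheses to compare")
    fits = [fit_hypothesis(tree, tip_ranges, hyp, **fit_kwargs) for hyp in hypotheses]
    df = pd.DataFrame(
        {
            "hypothesis": [f.hypothesis for f in fits],
            "neg_log_lik": [f.neg_log_lik for f in fits],
            "d": [f.d for f in fits],
            "e": [f.e for f in fits],
        }
    ).sort_values("neg_log_lik", kind="stable", ignore_index=True)
    df["delta_neg_log_lik"] = df["neg_log_lik"] - df["neg_log_lik"].iloc[0]
    return df


# -- range-matrix I/O -------------------------------------------------


def read_range_matrix(path, areas: AreaSet | Sequence[str] = DEFAULT_AREAS) -> dict[str, frozenset[str]]:
    """Read a taxon x area 0/1 CSV into a {taxon: range set} mapping."""
    if not isinstance(areas, AreaSet):
        areas = AreaSet(tuple(areas))
    df = pd.read_csv(path, index_col=0)
    missing = [a for a in areas.names if a not in df.columns]
    if missing:
        raise ArgumentError(f"range matrix missing area columns {missing}")
    out = {}
    for taxon, row in df.iterrows():
        rng = frozenset(a for a in areas.names if int(row[a]) == 1)
        if not rng:
            raise ArgumentError(f"taxon {taxon!r} has an empty range")
        out[str(taxon)] = rng
    return out


def write_range_matrix(ranges: dict[str, frozenset[str]], areas: AreaSet | Sequence[str], path) -> None:
    if not isinstance(areas, AreaSet):
        areas = AreaSet(tuple(areas))
    rows = {
        taxon: {a: int(a in rng) for a in areas.names} for taxon, rng in ranges.items()
    }
    pd.DataFrame.from_dict(rows, orient="index").rename_axis("taxon").to_csv(path)
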