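"""Synthetic-data generators with known ground truth.

Every input the pipeline consumes can be produced here: correlated
climate rasters, presence records drawn from a parameterized niche,
Yule chronograms, geographic ranges evolved forward under the DEC
process, neutral coalescent alignments, and morphology samples drawn
from published per-taxon means/SDs and categorical levels.  All
generators are pure functions of their seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from cphylo.chrono import Chronogram, YEARS
from cphylo.dec import (
    BiogeoHypothesis,
    RangeStateSpace,
    anagenetic_rate_matrix,
    build_state_space,
    cladogenesis_table,
)
from cphylo.errors import ArgumentError, DegenerateDataError
from cphylo.raster import OccurrenceSet, RasterGrid
from cphylo.seqstats import Alignment


# -- climate rasters --------------------------------------------------


def make_climate_stack(
    seed: int,
    n_rows: int,
    n_cols: int,
    n_vars: int,
    smoothness: float = 0.5,
    correlation: float | np.ndarray | None = None,
    filter_sigma: float = 2.0,
    x_origin: float = -130.0,
    y_origin: float = 30.0,
    cell_size: float = 0.5,
) -> list[RasterGrid]:
    """Smooth, optionally correlated synthetic climate layers.

    Each variable is ``smoothness * G + N_i`` where ``G`` is a
    standardized latitudinal gradient shared by all layers and ``N_i``
    are unit-variance low-pass-filtered Gaussian noise fields mixed to
    the requested pairwise ``correlation`` (scalar applied to every
    pair, or a full matrix).  ``smoothness -> inf`` leaves the pure
    gradient with vanishing relative residual variance.
    """
    if n_rows <= 0 or n_cols <= 0:
        raise ArgumentError("grid dimensions must be positive")
    if n_vars < 2:
        raise ArgumentError("need at least 2 climate variables")
    rng = np.random.default_rng(seed)

    lat = np.linspace(1.0, -1.0, n_rows)[:, None] * np.ones((1, n_cols))
    grad = (lat - lat.mean()) / lat.std()

    noise = np.empty((n_vars, n_rows, n_cols))
    for k in range(n_vars):
        f = gaussian_filter(rng.standard_normal((n_rows, n_cols)), sigma=filter_sigma)
        sd = f.std()
        noise[k] = f / sd if sd > 0 else f

    if correlation is not None:
        C = np.asarray(correlation, dtype=float)
        if C.ndim == 0:
            rho = float(C)
            C = np.full((n_vars, n_vars), rho)
            np.fill_diagonal(C, 1.0)
        L = np.linalg.cholesky(C)
        flat = noise.reshape(n_vars, -1)
        noise = (L @ flat).reshape(n_vars, n_rows, n_cols)

    if math.isinf(smoothness):
        fields = [grad.copy() for _ in range(n_vars)]
    else:
        fields = [smoothness * grad + noise[k] for k in range(n_vars)]
    return [
        RasterGrid(
            n_rows=n_rows,
            n_cols=n_cols,
            x_origin=x_origin,
            y_origin=y_origin,
            cell_size=cell_size,
            values=f,
        )
        for f in fields
    ]


# -- species occurrences ----------------------------------------------


@dataclass
class NicheSpec:
    """Logistic climate response: suitability = expit(intercept + c.x)."""

    coefficients: np.ndarray
    intercept: float = 0.0

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)

    def suitability(self, climate: np.ndarray) -> np.ndarray:
        """Suitability in [0, 1] for an (n, n_vars) climate table."""
        from scipy.special import expit

        eta = np.asarray(climate, dtype=float) @ self.coefficients + self.intercept
        return expit(eta)


def sample_species_occurrences(
    stack: list[RasterGrid],
    niche: NicheSpec,
    n: int,
    seed: int,
    taxon: str = "synthetic",
    jitter: bool = False,
) -> OccurrenceSet:
    """Draw ``n`` presence cells with probability proportional to suitability.

    Points are placed at cell centers (optionally jittered within the
    cell); cells may repeat, so thin before single-record-per-pixel
    analyses.
    """
    from cphylo.raster import stack_table

    if n < 1:
        raise ArgumentError("n must be >= 1")
    rng = np.random.default_rng(seed)
    table, flat_idx = stack_table(stack)
    suit = niche.suitability(table)
    total = suit.sum()
    if total <= 0 or not np.isfinite(total):
        raise DegenerateDataError("niche has zero suitability everywhere")
    p = suit / total
    chosen = rng.choice(len(flat_idx), size=n, replace=True, p=p)
    grid = stack[0]
    points = []
    for c in chosen:
        row, col = divmod(int(flat_idx[c]), grid.n_cols)
        lon, lat = grid.cell_center(row, col)
        if jitter:
            lon += (rng.random() - 0.5) * grid.cell_size * 0.98
            lat += (rng.random() - 0.5) * grid.cell_size * 0.98
        points.append((lon, lat))
    return OccurrenceSet(taxon=taxon, points=points)


# -- Yule chronograms -------------------------------------------------


def simulate_yule_tree(n_tips: int, birth_rate: float, seed: int, unit: str = YEARS) -> Chronogram:
    """Pure-birth chronogram with ``n_tips`` extant tips.

    Inter-event waiting times while k lineages exist are Exp(k * birth
    rate); the tree is sampled immediately before the event that would
    create tip n_tips + 1, so for n_tips = 2 the expected root height
    is 1 / (2 * birth_rate).
    """
    if n_tips < 2:
        raise ArgumentError("n_tips must be >= 2")
    if birth_rate <= 0:
        raise ArgumentError("birth_rate must be > 0")
    rng = np.random.default_rng(seed)

    taxon_namespace = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxon_namespace)
    root = tree.seed_node
    root.edge.length = 0.0
    active = [root]
    # split immediately at the root; n grows from 2 upward
    for child in range(2):
        node = dendropy.Node()
        node.edge.length = 0.0
        root.add_child(node)
        active = [c for c in root.child_nodes()]
    k = 2
    while k < n_tips:
        wait = rng.exponential(1.0 / (k * birth_rate))
        for node in active:
            node.edge.length += wait
        split = active[rng.integers(len(active))]
        for _ in range(2):
            node = dendropy.Node()
            node.edge.length = 0.0
            split.add_child(node)
        active.remove(split)
        active.extend(split.child_nodes())
        k += 1
    # final stub so the last interval is Exp(n * birth_rate)
    wait = rng.exponential(1.0 / (k * birth_rate))
    for node in active:
        node.edge.length += wait
    for i, node in enumerate(active):
        node.taxon = taxon_namespace.new_taxon(label=f"t{i + 1}")
    return Chronogram(tree, unit=unit)


# -- forward DEC simulation -------------------------------------------


@dataclass
class DECSimulation:
    """Forward-simulated tip ranges plus bookkeeping."""

    tip_ranges: dict[str, frozenset[str]]
    root_range: frozenset[str]
    restarts: int = 0

    def as_frame(self, areas) -> pd.DataFrame:
        names = tuple(areas.names) if hasattr(areas, "names") else tuple(areas)
        rows = {
            taxon: {a: int(a in rng) for a in names}
            for taxon, rng in self.tip_ranges.items()
        }
        return pd.DataFrame.from_dict(rows, orient="index").rename_axis("taxon")


def _gillespie_branch(
    state: frozenset[str],
    t_start: float,
    t_end: float,
    space: RangeStateSpace,
    hypothesis: BiogeoHypothesis,
    Q_by_epoch: list[np.ndarray],
    rng: np.random.Generator,
) -> frozenset[str]:
    """Evolve a range from t_start (older) to t_end KYA; rates are
    piecewise constant within epochs."""
    t = t_start
    si = space.state_index(state)
    while t > t_end + 1e-12:
        if not space.states[si]:
            break  # extinct, absorbing
        ep_idx = hypothesis.epoch_at(max(t - 1e-12, 0.0))
        ep = hypothesis.epochs[ep_idx]
        seg_end = max(ep.start_kya, t_end)
        Q = Q_by_epoch[ep_idx]
        rates = Q[si].copy()
        rates[si] = 0.0
        total = rates.sum()
        while t > seg_end + 1e-12:
            if total <= 0:
                t = seg_end
                break
            wait = rng.exponential(1.0 / total)
            if t - wait <= seg_end:
                t = seg_end
                break
            t -= wait
            si = int(rng.choice(len(rates), p=rates / total))
            if not space.states[si]:
                return frozenset()
            rates = Q[si].copy()
            rates[si] = 0.0
            total = rates.sum()
        t = seg_end
    return space.states[si]


def simulate_dec_tip_ranges(
    tree: Chronogram,
    hypothesis: BiogeoHypothesis,
    d: float,
    e: float,
    seed: int,
    root_range: frozenset[str] | None = None,
    max_range_size: int = 2,
    time_scale: float = 1.0,
    max_retries: int = 100,
) -> DECSimulation:
    """Evolve ranges forward along an ultrametric tree under DEC.

    Anagenetic events use Gillespie simulation with the epoch in force
    at each time; cladogenetic daughters are drawn from the same
    scenario enumeration as the likelihood engine.  If any lineage goes
    globally extinct the whole simulation restarts (up to
    ``max_retries``); the restart count is reported because the
    likelihood does not condition on survival.
    """
    if d < 0 or e < 0:
        raise ArgumentError("d and e must be >= 0")
    rng = np.random.default_rng(seed)
    space = build_state_space(hypothesis.areas, max_range_size)
    Q_by_epoch = [
        anagenetic_rate_matrix(space, ep.multipliers, d, e) for ep in hypothesis.epochs
    ]
    ages = {node: age / time_scale for node, age in tree.node_ages().items()}
    root = tree.tree.seed_node

    living = space.living_states
    for attempt in range(max_retries + 1):
        if root_range is None:
            start = living[rng.integers(len(living))]
        else:
            start = frozenset(root_range)
        tip_ranges: dict[str, frozenset[str]] = {}
        failed = False

        # iterative preorder with per-node incoming range
        stack = []
        table = cladogenesis_table(start)
        probs = [p for _, _, p in table]
        pick = int(rng.choice(len(table), p=probs))
        for child, rng_in in zip(root.child_nodes(), table[pick][:2]):
            stack.append((child, rng_in))
        while stack and not failed:
            node, state_in = stack.pop()
            state_out = _gillespie_branch(
                state_in, ages[node.parent_node], ages[node], space, hypothesis, Q_by_epoch, rng
            )
            if not state_out:
                failed = True
                break
            if node.is_leaf():
                tip_ranges[node.taxon.label] = state_out
            else:
                table = cladogenesis_table(state_out)
                probs = [p for _, _, p in table]
                pick = int(rng.choice(len(table), p=probs))
                for child, rng_in in zip(node.child_nodes(), table[pick][:2]):
                    stack.append((child, rng_in))
        if not failed:
            return DECSimulation(tip_ranges=tip_ranges, root_range=start, restarts=attempt)
    raise DegenerateDataError(
        f"forward DEC simulation went extinct in all {max_retries + 1} attempts"
    )


# -- neutral coalescent alignments ------------------------------------


def _kingman_branches(n: int, rng: np.random.Generator) -> list[tuple[frozenset[int], float]]:
    """Simulate a Kingman genealogy; returns (tip set below, length) per branch."""
    lineages: list[frozenset[int]] = [frozenset({i}) for i in range(n)]
    births = {lin: 0.0 for lin in lineages}  # time each lineage appeared
    t = 0.0
    branches: list[tuple[frozenset[int], float]] = []
    while len(lineages) > 1:
        k = len(lineages)
        t += rng.exponential(2.0 / (k * (k - 1)))
        i, j = rng.choice(k, size=2, replace=False)
        a, b = lineages[i], lineages[j]
        for lin in (a, b):
            branches.append((lin, t - births[lin]))
        merged = a | b
        lineages = [l for l in lineages if l not in (a, b)] + [merged]
        births[merged] = t
    return branches


def simulate_coalescent_alignment(
    n: int,
    S: int,
    L: int,
    seed: int,
    theta: float | None = None,
) -> Alignment:
    """Neutral coalescent sample under the infinite-sites model.

    By default exactly ``S`` mutations are placed uniformly on the total
    branch length of a Kingman genealogy (fixed-S mode, as used for
    neutrality-test null distributions).  If ``theta`` is given, S is
    instead Poisson with mean ``theta / 2 *`` total branch length
    (coalescent time units of 2N generations).  Each mutation occupies
    its own site; ancestral state 'A', derived state 'C'.
    """
    if n < 2:
        raise ArgumentError("n must be >= 2")
    if S < 0 or S > L:
        raise ArgumentError(f"need 0 <= S <= L, got S={S}, L={L}")
    rng = np.random.default_rng(seed)
    branches = _kingman_branches(n, rng)
    lengths = np.array([b[1] for b in branches])
    total = lengths.sum()
    if theta is not None:
        S = int(rng.poisson(theta / 2.0 * total))
        if S > L:
            raise ArgumentError(f"theta-mode drew S={S} > L={L}; increase L")
    seqs = np.full((n, L), "A", dtype="U1")
    if S > 0:
        sites = rng.choice(L, size=S, replace=False)
        carriers = rng.choice(len(branches), size=S, p=lengths / total)
        for site, bi in zip(sites, carriers):
            for tip in branches[bi][0]:
                seqs[tip, site] = "C"
    return Alignment(
        ids=[f"s{i + 1}" for i in range(n)],
        seqs=["".join(row) for row in seqs],
    )


def simulate_segregating_counts(n: int, S: int, rng: np.random.Generator) -> np.ndarray:
    """Derived-allele counts of S infinite-sites mutations on a Kingman
    genealogy of n tips (fast path for null distributions)."""
    branches = _kingman_branches(n, rng)
    lengths = np.array([b[1] for b in branches])
    sizes = np.array([len(b[0]) for b in branches])
    if S == 0:
        return np.zeros(0, dtype=int)
    picks = rng.choice(len(branches), size=S, p=lengths / lengths.sum())
    return sizes[picks]


# -- morphology -------------------------------------------------------


@dataclass
class MorphSpec:
    """Per-taxon morphology parameters.

    continuous: {taxon: {character: (mean, sd)}}
    categorical: {taxon: {character: level}}
    sample_sizes: {taxon: n}
    """

    continuous: dict[str, dict[str, tuple[float, float]]]
    categorical: dict[str, dict[str, str]]
    sample_sizes: dict[str, int]

    def __post_init__(self) -> None:
        taxa = set(self.sample_sizes)
        for name, table in (("continuous", self.continuous), ("categorical", self.categorical)):
            if set(table) != taxa:
                raise ArgumentError(f"MorphSpec {name} table does not cover all taxa")
        for taxon, n in self.sample_sizes.items():
            if n < 1:
                raise ArgumentError(f"sample size for {taxon!r} must be >= 1")
            for char, (mean, sd) in self.continuous[taxon].items():
                if sd < 0:
                    raise ArgumentError(f"negative SD for {taxon!r} / {char!r}")


def sample_morphology(
    spec: MorphSpec, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Draw individuals from a MorphSpec.

    Continuous characters are independent normal(mean, sd) draws
    (diagonal covariance; between-character correlations are not
    modeled).  Categorical rows replicate each taxon's levels exactly.
    Returns (continuous table, categorical table, label series).
    """
    rng = np.random.default_rng(seed)
    cont_rows, cat_rows, labels = [], [], []
    for taxon in spec.sample_sizes:
        n = spec.sample_sizes[taxon]
        cont = spec.continuous[taxon]
        cat = spec.categorical[taxon]
        for _ in range(n):
            cont_rows.append(
                {char: rng.normal(mean, sd) for char, (mean, sd) in cont.items()}
            )
            cat_rows.append(dict(cat))
            labels.append(taxon)
    return (
        pd.DataFrame(cont_rows),
        pd.DataFrame(cat_rows),
        pd.Series(labels, name="taxon"),
    )
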