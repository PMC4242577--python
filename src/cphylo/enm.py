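"""Ensemble niche modeling, thresholding, vote maps, and refugium mapping.

The ensemble logic is the computation of interest here, not any single
learner: presence records are modeled against the full study-area
background (weighted so total background weight equals total presence
weight), learners are gated by mean verification AUC over bootstrapped
70/30 splits, final models are refit on all data, continuous
suitability is binarized under two threshold rules
(sensitivity = specificity, and mean background probability), binary
maps are combined into per-pixel vote percentages, and a refugium is a
pixel whose vote percentage clears a stability level in all four time
slices and that lies outside the glacial ice mask.

Three reference learners satisfy the learner contract (predictions
finite, in [0, 1]): a percentile envelope, a Mahalanobis-distance
model, and a weighted logistic regression fitted by IRLS.  Additional
learners can be registered via :data:`LEARNER_REGISTRY`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.stats import rankdata

from cphylo.errors import ArgumentError
from cphylo.raster import RasterGrid

log = logging.getLogger(__name__)


# -- predictor pruning ------------------------------------------------


def prune_predictors(
    importance: dict[str, float],
    rho: "object",
    threshold: float = 0.7,
) -> list[str]:
    """Greedy correlation pruning: walk variables by descending
    importance and keep one iff |rho| <= threshold against everything
    already kept.  ``rho`` is a symmetric pandas DataFrame with unit
    diagonal over the same variables."""
    import pandas as pd

    if not isinstance(rho, pd.DataFrame):
        rho = pd.DataFrame(rho)
    if set(importance) != set(rho.columns) or set(rho.index) != set(rho.columns):
        raise ArgumentError("importance and rho must cover the same variables")
    if not np.allclose(rho.values, rho.values.T, atol=1e-12):
        raise ArgumentError("rho matrix must be symmetric")
    kept: list[str] = []
    for var in sorted(importance, key=lambda v: (-importance[v], list(importance).index(v))):
        if all(abs(rho.loc[var, k]) <= threshold for k in kept):
            kept.append(var)
    return kept


def weighted_background(n_presence: int, n_background: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-record weights equalizing total presence and background weight.

    Presences weigh 1 each; each background record weighs
    n_presence / n_background.
    """
    if n_presence < 1 or n_background < 1:
        raise ArgumentError("both record counts must be >= 1")
    return np.ones(n_presence), np.full(n_background, n_presence / n_background)


# -- learners ---------------------------------------------------------


@dataclass
class LearnerModel:
    """Fitted suitability model: climate table -> suitability in [0, 1]."""

    name: str
    _predict: Callable[[np.ndarray], np.ndarray]

    def predict(self, climate: np.ndarray) -> np.ndarray:
        out = np.asarray(self._predict(np.atleast_2d(np.asarray(climate, dtype=float))))
        if not np.all(np.isfinite(out)):
            raise ArgumentError(f"learner {self.name!r} produced non-finite predictions")
        return np.clip(out, 0.0, 1.0)


def _fit_envelope(presences: np.ndarray, background: np.ndarray, weights) -> Callable:
    """Percentile-box envelope: suitability 1 inside the per-variable
    [5, 95] percentile box, decaying linearly to 0 over one
    inter-percentile width outside."""
    lo = np.percentile(presences, 5, axis=0)
    hi = np.percentile(presences, 95, axis=0)
    width = np.maximum(hi - lo, 1e-12)

    def predict(X: np.ndarray) -> np.ndarray:
        below = np.maximum(lo - X, 0.0) / width
        above = np.maximum(X - hi, 0.0) / width
        dist = np.maximum(below, above)  # in units of box width, per variable
        per_var = np.clip(1.0 - dist, 0.0, 1.0)
        return per_var.min(axis=1)

    return predict


def _fit_mahalanobis(presences: np.ndarray, background: np.ndarray, weights) -> Callable:
    """Mahalanobis distance to the presence centroid mapped to [0, 1]
    by exp(-d^2 / 2); maximal (1) at the centroid."""
    n, p = presences.shape
    if n <= p:
        raise ArgumentError(
            f"mahalanobis needs more presences ({n}) than variables ({p})"
        )
    mu = presences.mean(axis=0)
    cov = np.cov(presences, rowvar=False)
    cov = np.atleast_2d(cov) + 1e-10 * np.eye(p)
    inv = np.linalg.inv(cov)

    def predict(X: np.ndarray) -> np.ndarray:
        diff = X - mu
        d2 = np.einsum("ij,jk,ik->i", diff, inv, diff)
        return np.exp(-0.5 * d2)

    return predict


def _fit_logistic(presences: np.ndarray, background: np.ndarray, weights) -> Callable:
    """Weighted binomial regression on linear terms via IRLS."""
    import statsmodels.api as sm

    X = np.vstack([presences, background])
    y = np.concatenate([np.ones(len(presences)), np.zeros(len(background))])
    w_pres, w_bg = weights
    w = np.concatenate([w_pres, w_bg])
    design = sm.add_constant(X, has_constant="add")
    model = sm.GLM(y, design, family=sm.families.Binomial(), var_weights=w)
    res = model.fit()  # IRLS
    params = res.params

    def predict(Xnew: np.ndarray) -> np.ndarray:
        eta = sm.add_constant(Xnew, has_constant="add") @ params
        return 1.0 / (1.0 + np.exp(-eta))

    return predict


LEARNER_REGISTRY: dict[str, Callable] = {
    "envelope": _fit_envelope,
    "mahalanobis": _fit_mahalanobis,
    "logistic": _fit_logistic,
}


def fit_learner(
    name: str,
    presences: np.ndarray,
    background: np.ndarray,
    weights: tuple[np.ndarray, np.ndarray] | None = None,
) -> LearnerModel:
    if name not in LEARNER_REGISTRY:
        raise ArgumentError(f"unknown learner {name!r}; registered: {sorted(LEARNER_REGISTRY)}")
    presences = np.atleast_2d(np.asarray(presences, dtype=float))
    background = np.atleast_2d(np.asarray(background, dtype=float))
    if weights is None:
        weights = weighted_background(len(presences), len(background))
    return LearnerModel(name=name, _predict=LEARNER_REGISTRY[name](presences, background, weights))


# -- AUC and bootstrap gating -----------------------------------------


def auc(presence_scores: Sequence[float], background_scores: Sequence[float]) -> float:
    """Rank-based (Mann-Whitney) AUC with midranks for ties."""
    pres = np.asarray(presence_scores, dtype=float)
    bg = np.asarray(background_scores, dtype=float)
    if len(pres) == 0 or len(bg) == 0:
        raise ArgumentError("both score lists must be nonempty")
    ranks = rankdata(np.concatenate([pres, bg]))
    r_pres = ranks[: len(pres)].sum()
    u = r_pres - len(pres) * (len(pres) + 1) / 2.0
    return float(u / (len(pres) * len(bg)))


def bootstrap_gate(
    learners: Sequence[str],
    presences: np.ndarray,
    background: np.ndarray,
    n_reps: int = 10,
    train_frac: float = 0.7,
    auc_min: float = 0.7,
    seed: int = 0,
) -> tuple[dict[str, LearnerModel], "object"]:
    """Gate learners on mean verification AUC, then refit on all data.

    Each replicate splits presences and background independently
    (stratified) into ``train_frac`` training and the rest
    verification.  Learners whose mean verification AUC across
    replicates falls below ``auc_min`` are removed; retained learners
    are refit on 100% of the data.  Returns (retained models, AUC
    table as a DataFrame with mean/per-rep columns).
    """
    import pandas as pd

    if n_reps < 1:
        raise ArgumentError("n_reps must be >= 1")
    presences = np.atleast_2d(np.asarray(presences, dtype=float))
    background = np.atleast_2d(np.asarray(background, dtype=float))
    rng = np.random.default_rng(seed)
    scores: dict[str, list[float]] = {name: [] for name in learners}
    failures: dict[str, int] = {name: 0 for name in learners}
    for rep in range(n_reps):
        p_idx = rng.permutation(len(presences))
        b_idx = rng.permutation(len(background))
        np_tr = max(1, int(round(train_frac * len(presences))))
        nb_tr = max(1, int(round(train_frac * len(background))))
        p_tr, p_ver = presences[p_idx[:np_tr]], presences[p_idx[np_tr:]]
        b_tr, b_ver = background[b_idx[:nb_tr]], background[b_idx[nb_tr:]]
        if len(p_ver) == 0 or len(b_ver) == 0:
            raise ArgumentError("train_frac leaves an empty verification set")
        for name in learners:
            try:
                model = fit_learner(name, p_tr, b_tr)
                scores[name].append(auc(model.predict(p_ver), model.predict(b_ver)))
            except Exception as exc:  # pragma: no cover - rare fit failures
                failures[name] += 1
                log.warning("learner %s failed on replicate %d: %s", name, rep, exc)
    rows = []
    retained: dict[str, LearnerModel] = {}
    for name in learners:
        reps_ok = scores[name]
        mean_auc = float(np.mean(reps_ok)) if reps_ok else float("nan")
        keep = bool(reps_ok) and mean_auc >= auc_min
        rows.append(
            {"learner": name, "mean_auc": mean_auc, "n_reps": len(reps_ok),
             "failures": failures[name], "retained": keep}
        )
        if keep:
            retained[name] = fit_learner(name, presences, background)
    return retained, pd.DataFrame(rows)


# -- thresholding -----------------------------------------------------


def select_threshold(
    model: LearnerModel,
    presences: np.ndarray,
    background: np.ndarray,
    rule: str,
) -> float:
    """Binarization cutoff under one of the two threshold rules.

    ``sens_eq_spec`` scans every unique predicted value as a candidate
    cutoff (prediction >= cutoff counts as presence) and returns the
    lowest cutoff minimizing |sensitivity - specificity|;
    ``mean_probability`` returns the mean prediction over the
    background cells.
    """
    pres_scores = model.predict(np.atleast_2d(presences))
    bg_scores = model.predict(np.atleast_2d(background))
    if rule == "mean_probability":
        return float(bg_scores.mean())
    if rule != "sens_eq_spec":
        raise ArgumentError(f"unknown threshold rule {rule!r}")
    candidates = np.unique(np.concatenate([pres_scores, bg_scores]))
    if len(candidates) == 1:
        log.warning("constant predictions from %s; degenerate threshold", model.name)
        return float(candidates[0])
    best_cut, best_gap = None, np.inf
    for cut in candidates:  # ascending; ties keep the lowest cutoff
        sens = float(np.mean(pres_scores >= cut))
        spec = float(np.mean(bg_scores < cut))
        gap = abs(sens - spec)
        if gap < best_gap - 1e-12:
            best_gap, best_cut = gap, cut
    return float(best_cut)


def binarize(model: LearnerModel, stack_table: np.ndarray, cutoff: float) -> np.ndarray:
    """0/1 suitability calls for a flattened climate table."""
    return (model.predict(stack_table) >= cutoff).astype(float)


# -- vote and refugia maps --------------------------------------------


@dataclass
class VoteMap:
    """Per-pixel percentage of 'suitable' votes in [0, 100]."""

    grid: RasterGrid
    total_votes: int


def vote_map(binary_maps: Sequence[RasterGrid]) -> VoteMap:
    """Combine binary suitability maps into per-pixel vote percentages.

    Percentages are over non-missing votes at each pixel; invariant to
    map order.
    """
    if not binary_maps:
        raise ArgumentError("need at least one binary map")
    base = binary_maps[0]
    votes = np.zeros((base.n_rows, base.n_cols))
    n_valid = np.zeros((base.n_rows, base.n_cols))
    for g in binary_maps:
        if not g.same_geometry(base):
            raise ArgumentError("binary maps have mismatched geometry")
        m = g.mask
        vals = g.values
        if not np.all(np.isin(vals[m], [0.0, 1.0])):
            raise ArgumentError("binary maps must contain only 0/1/nodata")
        votes[m] += vals[m]
        n_valid[m] += 1
    pct = np.full_like(votes, base.nodata_value)
    ok = n_valid > 0
    pct[ok] = 100.0 * votes[ok] / n_valid[ok]
    return VoteMap(grid=base.with_values(pct), total_votes=len(binary_maps))


#: RefugiaMap category codes.
REFUGIA_NONE, REFUGIA_STABLE50, REFUGIA_STABLE75 = 0, 1, 2


@dataclass
class RefugiaMap:
    """Categorical stability map: 0 none, 1 stable at >=50%, 2 at >=75%."""

    grid: RasterGrid
    ice_masked: bool
    levels: tuple[float, float] = (50.0, 75.0)


def refugia_map(
    slices: Sequence[VoteMap],
    ice: RasterGrid | None = None,
    levels: tuple[float, float] = (50.0, 75.0),
) -> RefugiaMap:
    """Stability across all four time slices, excluding glaciated pixels.

    A pixel is stable at level L iff its vote percentage is >= L in
    every slice; pixels under ice (ice value > 0) are never refugial.
    """
    if len(slices) != 4:
        raise ArgumentError(f"refugia mapping requires exactly 4 time slices, got {len(slices)}")
    base = slices[0].grid
    for vm in slices[1:]:
        if not vm.grid.same_geometry(base):
            raise ArgumentError("vote maps have mismatched geometry")
    lo, hi = sorted(levels)
    stacked = np.stack([vm.grid.values for vm in slices])
    valid = np.logical_and.reduce([vm.grid.mask for vm in slices])
    minimum = np.where(valid, stacked.min(axis=0), -1.0)
    cat = np.zeros(minimum.shape)
    cat[minimum >= lo] = REFUGIA_STABLE50
    cat[minimum >= hi] = REFUGIA_STABLE75
    if ice is not None:
        if not ice.same_geometry(base):
            raise ArgumentError("ice mask geometry mismatch")
        cat[(ice.values > 0) & ice.mask] = REFUGIA_NONE
    cat[~valid] = base.nodata_value
    return RefugiaMap(grid=base.with_values(cat), ice_masked=ice is not None, levels=(lo, hi))


# -- end-to-end ensemble ----------------------------------------------


@dataclass
class EnsembleResult:
    models: dict[str, LearnerModel]
    auc_table: "object"
    thresholds: dict[tuple[str, str], float]  # (learner, rule) -> cutoff
    vote_maps: dict[str, VoteMap]  # per time slice


def run_ensemble(
    presence_climate: np.ndarray,
    background_climate: np.ndarray,
    projection_stacks: dict[str, list[np.ndarray]],
    grid: RasterGrid,
    flat_index: np.ndarray,
    learners: Sequence[str] = ("envelope", "mahalanobis", "logistic"),
    n_reps: int = 10,
    auc_min: float = 0.7,
    seed: int = 0,
) -> EnsembleResult:
    """Full ensemble: gate, threshold (both rules), project, and vote.

    ``projection_stacks`` maps each time-slice name to a list of
    flattened climate tables (one per circulation-model replicate);
    every retained learner contributes one binary map per threshold
    rule per replicate table, so the vote count per slice is
    data-driven: len(retained) * 2 * n_replicates.
    """
    retained, auc_table = bootstrap_gate(
        learners, presence_climate, background_climate,
        n_reps=n_reps, auc_min=auc_min, seed=seed,
    )
    thresholds: dict[tuple[str, str], float] = {}
    for name, model in retained.items():
        for rule in ("sens_eq_spec", "mean_probability"):
            thresholds[(name, rule)] = select_threshold(
                model, presence_climate, background_climate, rule
            )
    vote_maps: dict[str, VoteMap] = {}
    for slice_name, tables in projection_stacks.items():
        binaries = []
        for table in tables:
            for (name, rule), cutoff in thresholds.items():
                calls = binarize(retained[name], table, cutoff)
                values = np.full(grid.n_rows * grid.n_cols, grid.nodata_value)
                values[flat_index] = calls
                binaries.append(grid.with_values(values.reshape(grid.n_rows, grid.n_cols)))
        vote_maps[slice_name] = vote_map(binaries)
    return EnsembleResult(
        models=retained, auc_table=auc_table, thresholds=thresholds, vote_maps=vote_maps
    )
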