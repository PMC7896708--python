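"""Random survival forest with log-rank splits and Nelson-Aalen leaves.

Each tree is grown on a bootstrap sample of the (duration, event) records:
at every node a random subset of predictors is scored by the two-sample
log-rank statistic over candidate thresholds, the best split is taken, and
every leaf stores the Nelson-Aalen cumulative-hazard estimate of its
records evaluated on the shared grid of training event times.  A record's
predicted risk ("mortality") is the ensemble-averaged cumulative hazard
summed over the grid; prediction error is measured out-of-bag as
1 - Harrell's concordance index, and variable importance as the increase in
out-of-bag error after permuting one predictor.

There is no fixed/random distinction: grouping variables (insecticide mode
of action, taxonomic family) enter as categorical predictors.  Categorical
levels are ordered by their marginal event rate per exposure-year and split
as an ordered variable — the classical approximation to exhaustive level
subset search.

Records are canonicalised (sorted by duration, event and feature values)
before any random draw, so results depend on the seed but not on input row
order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ForestSpec",
    "ForestFit",
    "fit_forest",
    "harrells_c",
    "permutation_importance",
    "compare_predictions",
    "predict_risk",
]


@dataclass(frozen=True)
class ForestSpec:
    """Forest hyperparameters; all exposed, none prescribed by the model."""

    n_trees: int = 500
    mtry: int | None = None          # default ceil(sqrt(p))
    min_node_size: int = 15          # records needed to attempt a split
    min_leaf_size: int = 5
    split_rule: str = "logrank"
    bootstrap_fraction: float = 1.0  # sampled with replacement
    seed: int = 0
    max_thresholds: int = 16
    max_categories: int = 32

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.split_rule != "logrank":
            raise ValueError("only the log-rank split rule is implemented")


@dataclass
class ForestFit:
    """Fitted ensemble plus out-of-bag quantities."""

    spec: ForestSpec
    predictors: list[str]
    encoders: dict[str, dict]        # categorical col -> {level: ordered code}
    grid: np.ndarray                 # training event-time grid
    trees: list[dict]
    oob_masks: list[np.ndarray]
    oob_risk: np.ndarray             # per (canonical) record OOB mortality
    oob_error: float                 # 1 - Harrell's C on OOB predictions
    risk: np.ndarray                 # in-sample ensemble mortality, input order
    n_resampled: int                 # all-censored bootstrap draws redrawn
    # canonical training data (used by permutation importance)
    X_: np.ndarray = field(repr=False, default=None)
    t_: np.ndarray = field(repr=False, default=None)
    d_: np.ndarray = field(repr=False, default=None)
    canon_: np.ndarray = field(repr=False, default=None)  # input -> canonical map


def harrells_c(score, durations, events) -> float:
    """Harrell's concordance index for right-censored data.

    A pair is comparable when one record's event is known to precede the
    other's follow-up (earlier event vs. a record still at risk; a censored
    record tied in time with an event counts as surviving past it).  The
    index is the fraction of comparable pairs in which the higher risk score
    belongs to the earlier event; score ties count 0.5.  Raises if no pair
    is comparable.
    """
    s = np.asarray(score, float)
    t = np.asarray(durations, float)
    d = np.asarray(events, int)
    if not (len(s) == len(t) == len(d)):
        raise ValueError("score/duration/event lengths differ")
    conc = tied = comp = 0
    for i in np.flatnonzero(d == 1):
        later = (t > t[i]) | ((t == t[i]) & (d == 0))
        later[i] = False
        comp += int(later.sum())
        conc += int((s[i] > s[later]).sum())
        tied += int((s[i] == s[later]).sum())
    if comp == 0:
        raise ValueError("no comparable pairs: concordance undefined")
    return (conc + 0.5 * tied) / comp


def _nelson_aalen_on_grid(t: np.ndarray, d: np.ndarray, grid: np.ndarray) -> np.ndarray:
    order = np.argsort(t, kind="stable")
    ts, ds = t[order], d[order]
    uniq, first = np.unique(ts, return_index=True)
    dj = np.add.reduceat(ds, first)
    Yj = len(ts) - first
    keep = dj > 0
    if not keep.any():
        return np.zeros(len(grid))
    cum = np.cumsum(dj[keep] / Yj[keep])
    pos = np.searchsorted(uniq[keep], grid, side="right")
    return np.concatenate([[0.0], cum])[pos]


def _logrank_stats(v, t, d, thresholds, min_leaf):
    """Squared standardized log-rank statistic for each candidate threshold."""
    m = len(t)
    order = np.argsort(t, kind="stable")
    ts, ds, vs = t[order], d[order], v[order]
    M = vs[:, None] <= thresholds[None, :]          # left membership, (m, k)
    nL = M.sum(axis=0)
    valid = (nL >= min_leaf) & (m - nL >= min_leaf)
    if not valid.any():
        return np.full(len(thresholds), -np.inf)
    uniq, first = np.unique(ts, return_index=True)
    dj = np.add.reduceat(ds, first)
    Yj = (m - first).astype(float)
    Y1 = np.cumsum(M[::-1], axis=0)[::-1][first]    # at-risk in left group
    d1 = np.add.reduceat(M * ds[:, None], first, axis=0)
    ev = dj > 0
    frac = Y1[ev] / Yj[ev, None]
    num = (d1[ev] - frac * dj[ev, None]).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        adj = np.where(Yj[ev] > 1, (Yj[ev] - dj[ev]) / (Yj[ev] - 1), 0.0)
        var = (frac * (1 - frac) * (dj[ev] * adj)[:, None]).sum(axis=0)
        stat = np.where(var > 0, num**2 / var, -np.inf)
    return np.where(valid, stat, -np.inf)


def _grow_tree(rng, X, t, d, spec: ForestSpec, mtry: int, grid: np.ndarray) -> dict:
    """Grow one tree; returns flat arrays plus the per-leaf CHF matrix."""
    feature, threshold, left, right, leaf_id = [], [], [], [], []
    leaf_chfs: list[np.ndarray] = []

    def build(idx: np.ndarray) -> int:
        node = len(feature)
        feature.append(-1)
        threshold.append(np.nan)
        left.append(-1)
        right.append(-1)
        leaf_id.append(-1)
        n_ev = int(d[idx].sum())
        if len(idx) >= spec.min_node_size and n_ev >= 1 and len(np.unique(t[idx])) > 1:
            feats = rng.choice(X.shape[1], size=mtry, replace=False)
            best = (-np.inf, None, None)
            for f in feats:
                v = X[idx, f]
                uv = np.unique(v)
                if len(uv) < 2:
                    continue
                mids = (uv[:-1] + uv[1:]) / 2.0
                if len(mids) > spec.max_thresholds:
                    qs = np.linspace(0, 1, spec.max_thresholds + 2)[1:-1]
                    mids = np.unique(np.quantile(v, qs))
                stats_ = _logrank_stats(v, t[idx], d[idx], mids, spec.min_leaf_size)
                j = int(np.argmax(stats_))
                if stats_[j] > best[0]:
                    best = (stats_[j], int(f), float(mids[j]))
            if best[1] is not None and best[0] > 0:
                f, thr = best[1], best[2]
                mask = X[idx, f] <= thr
                feature[node], threshold[node] = f, thr
                left[node] = build(idx[mask])
                right[node] = build(idx[~mask])
                return node
        leaf_id[node] = len(leaf_chfs)
        leaf_chfs.append(_nelson_aalen_on_grid(t[idx], d[idx], grid))
        return node

    build(np.arange(len(t)))
    return {
        "feature": np.asarray(feature),
        "threshold": np.asarray(threshold),
        "left": np.asarray(left),
        "right": np.asarray(right),
        "leaf_id": np.asarray(leaf_id),
        "leaf_chfs": np.vstack(leaf_chfs),
    }


def _apply_tree(tree: dict, X: np.ndarray) -> np.ndarray:
    """Per-row CHF matrix (n, len(grid)) from one tree."""
    n = X.shape[0]
    leaf_of = np.zeros(n, dtype=int)
    stack = [(0, np.arange(n))]
    while stack:
        node, idx = stack.pop()
        if len(idx) == 0:
            continue
        if tree["feature"][node] < 0:
            leaf_of[idx] = tree["leaf_id"][node]
            continue
        mask = X[idx, tree["feature"][node]] <= tree["threshold"][node]
        stack.append((tree["left"][node], idx[mask]))
        stack.append((tree["right"][node], idx[~mask]))
    return tree["leaf_chfs"][leaf_of]


def _build_encoders(design, predictors, categorical, durations, events):
    encoders: dict[str, dict] = {}
    for col in categorical:
        if col not in predictors:
            continue
        grp = pd.DataFrame(
            {"level": design[col].astype(str), "d": events, "exp": durations + 1.0}
        ).groupby("level")
        rate = (grp["d"].sum() / grp["exp"].sum()).sort_values(kind="stable")
        encoders[col] = {lev: float(r) for lev, r in rate.items()}
        encoders[col]["__default__"] = float(events.sum() / (durations + 1.0).sum())
    return encoders


def _encode(design, predictors, encoders) -> np.ndarray:
    cols = []
    for c in predictors:
        if c in encoders:
            enc = encoders[c]
            cols.append(
                design[c].astype(str).map(lambda v: enc.get(v, enc["__default__"])).to_numpy(float)
            )
        else:
            cols.append(design[c].to_numpy(float))
    return np.column_stack(cols)


def fit_forest(
    design: pd.DataFrame,
    spec: ForestSpec | None = None,
    predictors: Sequence[str] | None = None,
    categorical: Sequence[str] = ("moa_class", "family"),
    duration_col: str = "duration",
    event_col: str = "event",
) -> ForestFit:
    """Fit the random survival forest and compute its out-of-bag error.

    ``predictors`` defaults to every column except the duration/event pair.
    Categorical columns present among the predictors are event-rate encoded
    (see module docstring); their cardinality is checked against
    ``spec.max_categories``.
    """
    spec = spec or ForestSpec()
    t = design[duration_col].to_numpy(float)
    d = design[event_col].to_numpy(int)
    if predictors is None:
        numeric = design.select_dtypes(include=[np.number]).columns
        predictors = [c for c in numeric if c not in (duration_col, event_col)] + [
            c for c in categorical if c in design.columns
        ]
    predictors = list(predictors)
    categorical = [c for c in categorical if c in predictors]
    for col in categorical:
        card = design[col].nunique()
        if card > spec.max_categories:
            warnings.warn(
                f"{col} has {card} levels (> {spec.max_categories}); "
                "event-rate ordering is used for all of them",
                stacklevel=2,
            )
    encoders = _build_encoders(design, predictors, categorical, t, d)
    X_input = _encode(design, predictors, encoders)

    # canonical internal order: seed-reproducible and row-order invariant
    canon = np.lexsort(tuple(X_input.T) + (d, t))
    X, tc, dc = X_input[canon], t[canon], d[canon]
    n, p = X.shape
    mtry = spec.mtry or int(np.ceil(np.sqrt(p)))
    mtry = min(max(mtry, 1), p)
    grid = np.unique(tc[dc == 1])
    n_boot = max(2, int(round(spec.bootstrap_fraction * n)))

    seeds = np.random.SeedSequence(spec.seed).spawn(spec.n_trees)
    trees, oob_masks = [], []
    chf_sum = np.zeros((n, len(grid)))
    chf_cnt = np.zeros(n)
    ins_sum = np.zeros((n, len(grid)))
    n_resampled = 0
    for sseq in seeds:
        rng = np.random.default_rng(sseq)
        for _try in range(100):
            boot = rng.integers(0, n, size=n_boot)
            if dc[boot].sum() > 0:
                break
            n_resampled += 1
        tree = _grow_tree(rng, X[boot], tc[boot], dc[boot], spec, mtry, grid)
        inbag = np.zeros(n, dtype=bool)
        inbag[boot] = True
        oob = ~inbag
        trees.append(tree)
        oob_masks.append(oob)
        chf_all = _apply_tree(tree, X)
        ins_sum += chf_all
        if oob.any():
            chf_sum[oob] += chf_all[oob]
            chf_cnt[oob] += 1

    has_oob = chf_cnt > 0
    oob_risk = np.full(n, np.nan)
    oob_risk[has_oob] = (chf_sum[has_oob] / chf_cnt[has_oob, None]).sum(axis=1)
    oob_error = 1.0 - harrells_c(oob_risk[has_oob], tc[has_oob], dc[has_oob])

    risk_canon = (ins_sum / spec.n_trees).sum(axis=1)
    risk_input = np.empty(n)
    risk_input[canon] = risk_canon

    return ForestFit(
        spec=spec,
        predictors=predictors,
        encoders=encoders,
        grid=grid,
        trees=trees,
        oob_masks=oob_masks,
        oob_risk=oob_risk,
        oob_error=float(oob_error),
        risk=risk_input,
        n_resampled=n_resampled,
        X_=X,
        t_=tc,
        d_=dc,
        canon_=canon,
    )


def predict_risk(fit: ForestFit, design: pd.DataFrame) -> np.ndarray:
    """Ensemble mortality (summed averaged CHF) for new records."""
    X = _encode(design, fit.predictors, fit.encoders)
    chf = np.zeros((X.shape[0], len(fit.grid)))
    for tree in fit.trees:
        chf += _apply_tree(tree, X)
    return (chf / len(fit.trees)).sum(axis=1)


def _oob_error_for_matrix(fit: ForestFit, X: np.ndarray) -> float:
    n = X.shape[0]
    chf_sum = np.zeros((n, len(fit.grid)))
    cnt = np.zeros(n)
    for tree, oob in zip(fit.trees, fit.oob_masks):
        if not oob.any():
            continue
        chf_sum[oob] += _apply_tree(tree, X[oob])
        cnt[oob] += 1
    has = cnt > 0
    risk = (chf_sum[has] / cnt[has, None]).sum(axis=1)
    return 1.0 - harrells_c(risk, fit.t_[has], fit.d_[has])


def permutation_importance(
    fit: ForestFit, seed: int = 0, n_repeats: int = 5
) -> pd.DataFrame:
    """Permutation variable importance on out-of-bag predictions.

    For each predictor, its column is permuted (breaking its association
    with survival while preserving its marginal distribution), out-of-bag
    error is recomputed, and importance is the mean error increase over
    ``n_repeats`` permutations.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for j, name in enumerate(fit.predictors):
        deltas = []
        for _ in range(n_repeats):
            Xp = fit.X_.copy()
            Xp[:, j] = fit.X_[rng.permutation(len(fit.X_)), j]
            deltas.append(_oob_error_for_matrix(fit, Xp) - fit.oob_error)
        rows.append({"variable": name, "importance": float(np.mean(deltas))})
    return (
        pd.DataFrame(rows).sort_values("importance", ascending=False).reset_index(drop=True)
    )


def compare_predictions(forest_risk, cox_linear_predictor) -> tuple[float, float]:
    """Pearson correlation between forest and Cox per-record predictions."""
    a = np.asarray(forest_risk, float)
    b = np.asarray(cox_linear_predictor, float)
    if len(a) != len(b):
        raise ValueError("prediction vectors differ in length")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("zero variance in a prediction vector")
    r, p = sps.pearsonr(a, b)
    return float(r), float(p)
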