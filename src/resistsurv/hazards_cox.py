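"""Mixed-effect proportional-hazards (Cox) engine.

The hazard of pest *i* evolving resistance to insecticide *j* is modelled as

    h_ij(t) = h0(t) * exp( x_ij' beta + b_moa(j) + b_family(i) + b_species(i) )

with an unspecified baseline h0, fixed effects beta on the transformed
covariates (including quadratic terms for diet breadth, chemical similarity
and voltinism) and independent Gaussian random effects on the log-hazard for
insecticide mode of action and for species nested within taxonomic family.

Estimation is by penalized partial likelihood: for fixed random-effect
variances theta the partial log-likelihood plus the Gaussian penalty
-0.5 * sum_k b_k' b_k / theta_k is maximized jointly in (beta, b) by
Newton-Raphson with step-halving; the variances themselves are profiled on
an outer loop that maximizes the Laplace approximation to the integrated
partial likelihood.  With all variances fixed at zero the fit reduces
exactly to an ordinary Cox model.

Ties in the year-granular durations are handled by the Efron approximation
by default (Breslow available).  The partial-likelihood derivatives are
assembled with cumulative risk-set sums, so one Newton iteration costs one
pass over the data plus a handful of BLAS products.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .dataset_builder import FIXED_EFFECT_COLUMNS

__all__ = [
    "CoxSpec",
    "HazardFit",
    "ConvergenceError",
    "SeparationError",
    "fit_cox",
    "forest_table",
    "predict_relative_risk",
    "breslow_cumulative_hazard",
]

_LOG_THETA_MIN, _LOG_THETA_MAX = np.log(1e-4), np.log(25.0)


class ConvergenceError(RuntimeError):
    pass


class SeparationError(RuntimeError):
    """Monotone likelihood: some coefficient diverges (complete separation)."""


@dataclass
class CoxSpec:
    """Model specification for :func:`fit_cox`.

    fixed_effects
        Design columns entering with coefficients.
    random_effects
        Categorical grouping columns, one Gaussian variance per column.
        Species-within-family nesting is expressed by listing both the
        family column and a globally unique species column.
    ties
        "efron" (default) or "breslow".
    """

    fixed_effects: Sequence[str] = tuple(FIXED_EFFECT_COLUMNS)
    random_effects: Sequence[str] = ()
    ties: str = "efron"
    tol: float = 1e-8
    max_iter: int = 100
    theta_init: float = 0.2
    outer_maxiter: int = 60
    outer_fatol: float = 1e-3
    outer_xatol: float = 0.03


@dataclass
class HazardFit:
    """Coefficients, uncertainty and variance components from a Cox fit."""

    terms: list[str]
    beta: pd.Series
    se: pd.Series
    variances: dict[str, float]
    random_effects: dict[str, pd.Series]
    loglik: float            # penalized partial log-likelihood at the optimum
    integrated_loglik: float  # Laplace approximation (equals loglik when no random terms)
    aic: float
    n_events: int
    n_censored: int
    converged: bool
    n_iter: int
    ties: str
    trace: list[float] = field(default_factory=list)
    spec: CoxSpec | None = None


def _partial_lik_parts(ts, ds, Xs, eta, efron: bool):
    """(loglik, gradient, observed information) of the partial likelihood.

    Inputs are sorted ascending by duration.  Uses reverse cumulative
    risk-set sums; Efron tie corrections are applied through fractional
    weights on the tied-death sums.
    """
    n, P = Xs.shape
    shift = eta.max()
    w = np.exp(eta - shift)
    wX = w[:, None] * Xs

    ev_pos = np.flatnonzero(ds == 1)
    t_ev = ts[ev_pos]
    uniq, first_ev = np.unique(t_ev, return_index=True)
    counts = np.diff(np.append(first_ev, len(ev_pos)))
    start = np.searchsorted(ts, uniq, side="left")

    rc_w = np.cumsum(w[::-1])[::-1]
    rc_wX = np.cumsum(wX[::-1], axis=0)[::-1]
    S0 = rc_w[start]
    S1 = rc_wX[start]
    s0d = np.add.reduceat(w[ev_pos], first_ev)
    s1d = np.add.reduceat(wX[ev_pos], first_ev, axis=0)

    rep = np.repeat(np.arange(len(uniq)), counts)
    l_idx = np.arange(len(ev_pos)) - np.repeat(first_ev, counts)
    frac = (l_idx / counts[rep]) if efron else np.zeros(len(ev_pos))

    S0l = S0[rep] - frac * s0d[rep]
    S1l = S1[rep] - frac[:, None] * s1d[rep]

    ll = eta[ev_pos].sum() - np.log(S0l).sum() - len(ev_pos) * shift
    B = S1l / S0l[:, None]
    grad = Xs[ev_pos].sum(axis=0) - B.sum(axis=0)

    inv0 = 1.0 / S0l
    alpha = np.add.reduceat(inv0, first_ev)
    gamma = np.add.reduceat(frac * inv0, first_ev)
    cum_alpha = np.cumsum(alpha)
    pos = np.searchsorted(uniq, ts, side="right") - 1
    A = np.where(pos >= 0, cum_alpha[np.clip(pos, 0, None)], 0.0)
    c = w * A
    c[ev_pos] -= w[ev_pos] * gamma[rep]
    info = Xs.T @ (c[:, None] * Xs) - B.T @ B
    return ll, grad, info


def _inner_newton(ts, ds, Xs, pen_diag, params0, tol, max_iter, efron):
    """Maximize the penalized partial likelihood in all coefficients.

    pen_diag holds 1/theta on random-effect coordinates (0 on fixed ones).
    Returns (params, ll_pen, grad, info_pen, trace, converged).
    """
    params = params0.copy()
    eta = Xs @ params
    ll, grad, info = _partial_lik_parts(ts, ds, Xs, eta, efron)
    ll_pen = ll - 0.5 * np.sum(pen_diag * params**2)
    trace = [ll_pen]
    converged = False
    for _ in range(max_iter):
        g = grad - pen_diag * params
        H = info + np.diag(pen_diag)
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, g, rcond=None)[0]
        new_ll_pen = -np.inf
        for _half in range(30):
            cand = params + step
            eta = Xs @ cand
            ll_c, grad_c, info_c = _partial_lik_parts(ts, ds, Xs, eta, efron)
            new_ll_pen = ll_c - 0.5 * np.sum(pen_diag * cand**2)
            if np.isfinite(new_ll_pen) and new_ll_pen >= ll_pen - 1e-12:
                break
            step = step / 2.0
        if not np.isfinite(new_ll_pen):
            raise ConvergenceError("penalized likelihood became non-finite")
        params, grad, info = cand, grad_c, info_c
        delta = new_ll_pen - ll_pen
        ll_pen = new_ll_pen
        trace.append(ll_pen)
        if np.max(np.abs(params)) > 80:
            raise SeparationError(
                "diverging coefficient: data are (quasi-)completely separated"
            )
        if abs(delta) < tol:
            converged = True
            break
    H = info + np.diag(pen_diag)
    return params, ll_pen, grad - pen_diag * params, H, trace, converged


def _build_random_blocks(df: pd.DataFrame, random_effects: Sequence[str]):
    """One-hot blocks for each grouping column; returns (Z, slices, levels)."""
    mats, slices, levels = [], {}, {}
    offset = 0
    for col in random_effects:
        codes, lev = pd.factorize(df[col].astype(str), sort=True)
        q = len(lev)
        Z = np.zeros((len(df), q))
        Z[np.arange(len(df)), codes] = 1.0
        mats.append(Z)
        slices[col] = slice(offset, offset + q)
        levels[col] = list(lev)
        offset += q
    Zfull = np.hstack(mats) if mats else np.zeros((len(df), 0))
    return Zfull, slices, levels


def fit_cox(
    design: pd.DataFrame,
    spec: CoxSpec | None = None,
    duration_col: str = "duration",
    event_col: str = "event",
) -> HazardFit:
    """Fit the mixed-effect proportional-hazards model.

    ``design`` holds the transformed fixed-effect columns, the grouping
    columns named in ``spec.random_effects``, a duration and a 0/1 event
    flag.  With ``spec.random_effects`` empty this is an ordinary Cox fit.
    """
    spec = spec or CoxSpec()
    if spec.ties not in ("efron", "breslow"):
        raise ValueError(f"unknown tie method {spec.ties!r}")
    efron = spec.ties == "efron"

    t = design[duration_col].to_numpy(float)
    d = design[event_col].to_numpy(int)
    if np.any(t < 0):
        raise ValueError("negative durations")
    if len(np.unique(t[d == 1])) < 2:
        raise ValueError("need at least two distinct event times")
    X = design[list(spec.fixed_effects)].to_numpy(float)
    spans = X.max(axis=0) - X.min(axis=0)
    if np.any(spans == 0):
        bad = [c for c, s in zip(spec.fixed_effects, spans) if s == 0]
        raise ValueError(f"constant fixed-effect column(s): {bad}")
    if {"family", "pest_id"} <= set(design.columns):
        fam_per_pest = design.groupby("pest_id")["family"].nunique()
        if (fam_per_pest > 1).any():
            raise ValueError("nesting ill-formed: a pest maps to multiple families")

    Z, rand_slices, rand_levels = _build_random_blocks(design, spec.random_effects)
    p, q = X.shape[1], Z.shape[1]
    Xfull = np.hstack([X, Z])

    order = np.argsort(t, kind="stable")
    ts, ds, Xs = t[order], d[order], Xfull[order]

    def pen_from_theta(theta: Mapping[str, float]) -> np.ndarray:
        pen = np.zeros(p + q)
        for col, sl in rand_slices.items():
            pen[p + sl.start : p + sl.stop] = 1.0 / theta[col]
        return pen

    params = np.zeros(p + q)
    if q == 0:
        params, ll_pen, _, H, trace, conv = _inner_newton(
            ts, ds, Xs, np.zeros(p), params, spec.tol, spec.max_iter, efron
        )
        theta_hat: dict[str, float] = {}
        ill = ll_pen
        n_iter = len(trace) - 1
    else:
        state = {"params": params, "best": None}

        def neg_integrated(log_theta: np.ndarray) -> float:
            theta = {
                col: float(np.exp(lt))
                for col, lt in zip(spec.random_effects, log_theta)
            }
            pen = pen_from_theta(theta)
            pars, ll_pen, _, H, trace, conv = _inner_newton(
                ts, ds, Xs, pen, state["params"], spec.tol, spec.max_iter, efron
            )
            state["params"] = pars
            Hbb = H[p:, p:]
            sign, logdet = np.linalg.slogdet(Hbb)
            if sign <= 0:
                return np.inf
            log_det_D = sum(
                (sl.stop - sl.start) * np.log(theta[col])
                for col, sl in rand_slices.items()
            )
            # Laplace: additive (q/2) log 2pi constant omitted (theta-free)
            ill = ll_pen - 0.5 * log_det_D - 0.5 * logdet
            val = -ill
            if state["best"] is None or val < state["best"][0]:
                state["best"] = (val, theta, pars, ll_pen, H, trace, conv)
            return val

        x0 = np.full(len(spec.random_effects), np.log(spec.theta_init))
        res = optimize.minimize(
            neg_integrated,
            x0,
            method="Nelder-Mead",
            options={
                "maxfev": spec.outer_maxiter,
                "xatol": spec.outer_xatol,
                "fatol": spec.outer_fatol,
            },
        )
        _, theta_hat, params, ll_pen, H, trace, conv = state["best"]
        theta_hat = {
            col: float(np.clip(v, np.exp(_LOG_THETA_MIN), np.exp(_LOG_THETA_MAX)))
            for col, v in theta_hat.items()
        }
        ill = -state["best"][0]
        n_iter = res.nfev

    cov = np.linalg.inv(H)
    se_all = np.sqrt(np.clip(np.diag(cov), 0, None))

    beta = pd.Series(params[:p], index=list(spec.fixed_effects))
    se = pd.Series(se_all[:p], index=list(spec.fixed_effects))
    # monotone-likelihood diagnostic: a large coefficient whose SE dwarfs it
    # means the partial likelihood has no interior maximum in that direction
    runaway = (beta.abs() > 10) & (se > 50 * beta.abs())
    if runaway.any():
        raise SeparationError(
            f"(quasi-)complete separation in term(s): {list(beta.index[runaway])}"
        )
    rand = {
        col: pd.Series(params[p + sl.start : p + sl.stop], index=rand_levels[col])
        for col, sl in rand_slices.items()
    }
    n_params = p + len(theta_hat)
    fit = HazardFit(
        terms=list(spec.fixed_effects),
        beta=beta,
        se=se,
        variances=theta_hat,
        random_effects=rand,
        loglik=float(ll_pen),
        integrated_loglik=float(ill),
        aic=float(-2 * ill + 2 * n_params),
        n_events=int(ds.sum()),
        n_censored=int((ds == 0).sum()),
        converged=bool(conv),
        n_iter=int(n_iter),
        ties=spec.ties,
        trace=list(trace),
        spec=spec,
    )
    if not conv:
        warnings.warn("Cox fit did not reach the inner convergence tolerance", stacklevel=2)
    return fit


def forest_table(fit: HazardFit) -> pd.DataFrame:
    """Fixed-effect estimates with normal 95% CIs and two-sided p-values."""
    z = np.where(fit.se > 0, fit.beta / fit.se, np.nan)
    p = 2 * stats.norm.sf(np.abs(z))
    return pd.DataFrame(
        {
            "term": fit.terms,
            "estimate": fit.beta.to_numpy(),
            "se": fit.se.to_numpy(),
            "lower95": fit.beta.to_numpy() - 1.96 * fit.se.to_numpy(),
            "upper95": fit.beta.to_numpy() + 1.96 * fit.se.to_numpy(),
            "z": z,
            "p": p,
        }
    )


def predict_relative_risk(fit: HazardFit, design: pd.DataFrame) -> pd.DataFrame:
    """Linear predictors, relative risks and a descending risk ranking.

    New rows must already be on the training covariate scale (apply the
    stored transform constants first).  Random-effect levels seen in
    training contribute their estimated effect; unseen levels contribute 0
    with a warning.
    """
    eta = design[fit.terms].to_numpy(float) @ fit.beta.to_numpy()
    for col, effects in fit.random_effects.items():
        vals = design[col].astype(str)
        unseen = sorted(set(vals) - set(effects.index))
        if unseen:
            warnings.warn(
                f"unseen {col} level(s) treated as average (effect 0): {unseen}",
                stacklevel=2,
            )
        eta = eta + vals.map(effects).fillna(0.0).to_numpy()
    out = design.copy()
    out["linear_predictor"] = eta
    out["relative_risk"] = np.exp(eta)
    out["risk_rank"] = (
        pd.Series(-eta, index=out.index).rank(method="first").astype(int)
    )
    return out.sort_values("risk_rank")


def breslow_cumulative_hazard(
    durations: np.ndarray, events: np.ndarray, eta: np.ndarray
) -> pd.DataFrame:
    """Breslow estimate of the cumulative baseline hazard (diagnostics only)."""
    t = np.asarray(durations, float)
    d = np.asarray(events, int)
    w = np.exp(np.asarray(eta, float) - np.max(eta))
    order = np.argsort(t, kind="stable")
    ts, ds, ws = t[order], d[order], w[order]
    rc_w = np.cumsum(ws[::-1])[::-1]
    uniq = np.unique(ts[ds == 1])
    start = np.searchsorted(ts, uniq, side="left")
    d_k = np.array([ds[ts == u].sum() for u in uniq])
    increments = d_k / rc_w[start] * np.exp(-np.max(eta))
    return pd.DataFrame({"time": uniq, "cumulative_hazard": np.cumsum(increments)})
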