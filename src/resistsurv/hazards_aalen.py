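"""Aalen additive-hazards engine.

The additive model writes the hazard as a sum of time-varying effects,

    h_i(t) = b0(t) + b1(t) * x_i1 + ... + bp(t) * x_ip,

and estimates the *cumulative* regression functions B_k(t) = int_0^t bk(s) ds
by least squares: at every ordered event time, the vector of event
indicators over the at-risk set is regressed on the at-risk covariates and
the resulting increment added to B.  The curves are step functions that
change only at event times, start at B(0) = 0, and — with an
intercept-only design — reduce exactly to the Nelson-Aalen estimator.

Unlike the proportional-hazards model, covariate effects are allowed to
change over time, at the cost of a simpler random structure: a single
grouping (here insecticide mode of action) can be absorbed as a "liability"
block of dummy columns with a shared ridge shrinkage weight.

Estimation is truncated once the at-risk set drops below p + 5 rows, a
standard guard against the exploding variance of late increments;
rank-deficient risk-set designs skip their increment with a warning count.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["AalenFit", "fit_aalen", "aalen_tests"]


@dataclass
class AalenFit:
    """Cumulative regression functions and their pointwise variances."""

    times: np.ndarray          # event-time grid, starting at 0
    columns: list[str]         # "intercept" + covariates
    cum_coef: np.ndarray       # (len(times), p) cumulative effects, row 0 = 0
    cum_var: np.ndarray        # pointwise variance estimates, same shape
    n_skipped: int             # increments skipped for rank deficiency
    truncated_at: float | None  # first event time beyond the risk-set guard
    n_events_used: int
    liability_group: str | None = None
    liability_levels: list[str] | None = None
    liability_cum: np.ndarray | None = None  # shrunken group effects (diagnostics)


def fit_aalen(
    design: pd.DataFrame,
    covariates: Sequence[str],
    duration_col: str = "duration",
    event_col: str = "event",
    liability_group: str | None = None,
    ridge: float = 1.0,
    min_risk_margin: int = 5,
) -> AalenFit:
    """Fit the additive-hazards model by least-squares increments.

    Parameters
    ----------
    covariates
        Fixed-effect columns; an intercept (baseline hazard) is always
        included first.
    liability_group
        Optional categorical column absorbed as a dummy block with ridge
        weight ``ridge`` on its coordinates (shrunken toward zero, mirroring
        a single random term).
    min_risk_margin
        Estimation stops once fewer than p + ``min_risk_margin`` rows remain
        at risk.
    """
    t = design[duration_col].to_numpy(float)
    d = design[event_col].to_numpy(int)
    X_main = np.column_stack(
        [np.ones(len(design))] + [design[c].to_numpy(float) for c in covariates]
    )
    lev: list[str] = []
    if liability_group is not None:
        codes, levels = pd.factorize(design[liability_group].astype(str), sort=True)
        lev = list(levels)
        D = np.zeros((len(design), len(lev)))
        D[np.arange(len(design)), codes] = 1.0
        X = np.hstack([X_main, D])
    else:
        X = X_main
    p_main = X_main.shape[1]
    p_tot = X.shape[1]
    pen = np.zeros(p_tot)
    pen[p_main:] = ridge

    order = np.argsort(t, kind="stable")
    ts, ds, Xs = t[order], d[order], X[order]
    event_times = np.unique(ts[ds == 1])
    if len(event_times) < 2:
        raise ValueError("need at least two distinct event times")

    times = [0.0]
    B = [np.zeros(p_main)]
    V = [np.zeros(p_main)]
    Bliab = [np.zeros(p_tot - p_main)] if p_tot > p_main else None
    n_skipped = 0
    truncated_at = None
    n_events_used = 0

    for u in event_times:
        s = np.searchsorted(ts, u, side="left")
        n_risk = len(ts) - s
        if n_risk < p_tot + min_risk_margin:
            truncated_at = float(u)
            break
        Xr = Xs[s:]
        dN = ((ts[s:] == u) & (ds[s:] == 1)).astype(float)
        M = Xr.T @ Xr + np.diag(pen)
        try:
            Minv = np.linalg.inv(M)
        except np.linalg.LinAlgError:
            n_skipped += 1
            continue
        # guard against numerically singular risk-set designs
        if not np.all(np.isfinite(Minv)) or np.linalg.cond(M) > 1e10:
            n_skipped += 1
            continue
        A = Minv @ Xr.T                      # (p_tot, n_risk)
        dB = A @ dN
        Ad = A[:, dN > 0]
        dV = np.einsum("ij,ij->i", Ad, Ad)   # diag(A diag(dN) A')
        times.append(float(u))
        B.append(B[-1] + dB[:p_main])
        V.append(V[-1] + dV[:p_main])
        if Bliab is not None:
            Bliab.append(Bliab[-1] + dB[p_main:])
        n_events_used += int(dN.sum())

    return AalenFit(
        times=np.asarray(times),
        columns=["intercept"] + list(covariates),
        cum_coef=np.vstack(B),
        cum_var=np.vstack(V),
        n_skipped=n_skipped,
        truncated_at=truncated_at,
        n_events_used=n_events_used,
        liability_group=liability_group,
        liability_levels=lev or None,
        liability_cum=np.vstack(Bliab) if Bliab is not None else None,
    )


def aalen_tests(fit: AalenFit) -> pd.DataFrame:
    """Per-covariate tests of zero cumulative effect.

    The statistic is the cumulative coefficient at the final estimated event
    time divided by its standard error (normal reference, two-sided); the
    ``slope`` column rescales the cumulative effect to a per-time rate,
    B(tau)/tau, the scale on which additive coefficients are conventionally
    quoted.
    """
    tau = fit.times[-1]
    B_tau = fit.cum_coef[-1]
    se = np.sqrt(fit.cum_var[-1])
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, B_tau / se, np.nan)
    p = 2 * stats.norm.sf(np.abs(z))
    return pd.DataFrame(
        {
            "term": fit.columns,
            "cumulative_effect": B_tau,
            "se": se,
            "slope": B_tau / tau,
            "z": z,
            "p": p,
        }
    )


def curve_table(fit: AalenFit) -> pd.DataFrame:
    """Long-format (time, term, cumulative_estimate, se) for curve plotting."""
    rows = []
    se = np.sqrt(fit.cum_var)
    for j, term in enumerate(fit.columns):
        for i, u in enumerate(fit.times):
            rows.append(
                {"time": u, "term": term, "cumulative_estimate": fit.cum_coef[i, j], "se": se[i, j]}
            )
    return pd.DataFrame(rows)
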