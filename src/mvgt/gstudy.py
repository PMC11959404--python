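"""Multivariate G-study estimation for the trainees x procedures design.

Two estimators share one output type:

* :func:`estimate_balanced` — exact expected-mean-square (EMS) solution of
  the two-way crossed ANOVA with one observation per cell, extended to
  mean cross-products for the covariance components.
* :func:`estimate_unbalanced` — per-variable REML for the two-way crossed
  random-effects model with missing cells; covariance components are
  recovered from REML fits of pairwise sums and differences:
  cov = (var(u + v) - var(u - v)) / 4, effect by effect.

On balanced data the two agree (REML of the balanced crossed design with
an interior optimum coincides with the ANOVA estimator).
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy import optimize

from .errors import (
    ConvergenceError,
    IdentifiabilityError,
    MvgtError,
    UnbalancedDesignError,
    UndefinedStatisticError,
)
from .tables import SCORE_COLUMNS, VARIABLE_NAMES, is_fully_crossed, score_matrix

logger = logging.getLogger(__name__)

EFFECTS = ("t", "p", "tp")


@dataclasses.dataclass
class GStudyComponents:
    """Estimated 4x4 variance/covariance component matrices per effect.

    Variable order is fixed: faculty autonomy, trainee autonomy, faculty
    performance, trainee performance.  Diagonals are truncated at zero and
    off-diagonals clipped to the Cauchy-Schwarz bound; the raw
    (pre-truncation) matrices are kept in ``raw``.
    """

    sigma_t: np.ndarray
    sigma_p: np.ndarray
    sigma_tp: np.ndarray
    n_trainees: int
    n_procedures_mean: float
    estimator_tag: str
    raw: dict = dataclasses.field(default_factory=dict, repr=False)

    def matrix(self, effect: str) -> np.ndarray:
        return {"t": self.sigma_t, "p": self.sigma_p, "tp": self.sigma_tp}[effect]

    def to_dict(self) -> dict:
        return {
            "variables": list(VARIABLE_NAMES),
            "sigma_t": self.sigma_t.tolist(),
            "sigma_p": self.sigma_p.tolist(),
            "sigma_tp": self.sigma_tp.tolist(),
            "n_trainees": int(self.n_trainees),
            "n_procedures_mean": float(self.n_procedures_mean),
            "estimator_tag": self.estimator_tag,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GStudyComponents":
        return cls(
            sigma_t=np.asarray(d["sigma_t"], dtype=float),
            sigma_p=np.asarray(d["sigma_p"], dtype=float),
            sigma_tp=np.asarray(d["sigma_tp"], dtype=float),
            n_trainees=int(d["n_trainees"]),
            n_procedures_mean=float(d["n_procedures_mean"]),
            estimator_tag=str(d["estimator_tag"]),
        )


def _truncate(mat: np.ndarray) -> np.ndarray:
    """Zero negative diagonals, then clip covariances to Cauchy-Schwarz."""
    m = (mat + mat.T) / 2.0
    d = np.clip(np.diag(m), 0.0, None)
    bound = np.sqrt(np.outer(d, d))
    out = np.clip(m, -bound, bound)
    np.fill_diagonal(out, d)
    return out


def _finalize(raw_t, raw_p, raw_tp, n_trainees, n_proc_mean, tag):
    raw = {"t": raw_t.copy(), "p": raw_p.copy(), "tp": raw_tp.copy()}
    for eff, m in raw.items():
        if np.any(np.diag(m) < 0):
            logger.debug("negative raw variance in effect %s: %s", eff, np.diag(m))
    return GStudyComponents(
        sigma_t=_truncate(raw_t),
        sigma_p=_truncate(raw_p),
        sigma_tp=_truncate(raw_tp),
        n_trainees=n_trainees,
        n_procedures_mean=n_proc_mean,
        estimator_tag=tag,
        raw=raw,
    )


# ---------------------------------------------------------------------------
# balanced EMS estimator

def estimate_balanced(table: pd.DataFrame) -> GStudyComponents:
    """EMS estimator for a fully crossed table (one observation per cell).

    For each variable pair, mean squares/cross-products are formed from the
    trainee marginal means, procedure marginal means, and the interaction
    residual, then the EMS equations are solved:

        sigma_tp = MS_tp
        sigma_t  = (MS_t - MS_tp) / n_p
        sigma_p  = (MS_p - MS_tp) / n_t
    """
    if table.duplicated(subset=["trainee_id", "procedure_id"]).any():
        raise MvgtError("at most one observation per (trainee, procedure) cell")
    if not is_fully_crossed(table):
        raise UnbalancedDesignError(
            "table is not fully crossed; use estimate_unbalanced"
        )
    n_t = table["trainee_id"].nunique()
    n_p = table["procedure_id"].nunique()
    if n_t < 2 or n_p < 2:
        raise IdentifiabilityError(
            f"need >= 2 trainees and >= 2 procedures (got {n_t} x {n_p})"
        )

    wide = table.sort_values(["trainee_id", "procedure_id"])
    y = score_matrix(wide).reshape(n_t, n_p, 4)

    grand = y.mean(axis=(0, 1))
    a = y.mean(axis=1) - grand  # trainee deviations, (n_t, 4)
    b = y.mean(axis=0) - grand  # procedure deviations, (n_p, 4)
    resid = y - grand - a[:, None, :] - b[None, :, :]

    ms_t = n_p * (a.T @ a) / (n_t - 1)
    ms_p = n_t * (b.T @ b) / (n_p - 1)
    r = resid.reshape(-1, 4)
    ms_tp = (r.T @ r) / ((n_t - 1) * (n_p - 1))

    raw_tp = ms_tp
    raw_t = (ms_t - ms_tp) / n_p
    raw_p = (ms_p - ms_tp) / n_t
    return _finalize(raw_t, raw_p, raw_tp, n_t, float(n_p), "balanced-EMS")


# ---------------------------------------------------------------------------
# unbalanced REML estimator

def _reml_two_way(y, ti, pi, n_t, n_p, max_iter=200):
    """REML variance components (t, p, residual) for one response vector.

    Dense-matrix REML with analytic gradient, maximized by L-BFGS-B from a
    method-of-moments start.  Suitable for designs up to a few thousand
    rows.  Returns (theta, trace) where theta = (var_t, var_p, var_e).
    """
    n = len(y)
    y = np.asarray(y, dtype=float)
    var_y = float(np.var(y, ddof=1))
    if var_y == 0.0:
        return np.zeros(3), []

    same_t = (ti[:, None] == ti[None, :]).astype(float)
    same_p = (pi[:, None] == pi[None, :]).astype(float)
    eye = np.eye(n)
    ones = np.ones(n)
    trace: list[tuple] = []

    def neg_reml(theta):
        vt, vp, ve = theta
        v = ve * eye + vt * same_t + vp * same_p
        try:
            c = np.linalg.cholesky(v)
        except np.linalg.LinAlgError:
            return np.inf, np.zeros(3)
        logdet = 2.0 * float(np.log(np.diag(c)).sum())
        vi = np.linalg.inv(v)
        vi_x = vi @ ones
        xtvix = float(ones @ vi_x)
        beta = float(vi_x @ y) / xtvix
        py = vi @ y - vi_x * beta  # P y
        dev = logdet + np.log(xtvix) + float(y @ py)
        # gradient of dev: tr(P Vk) - (Py)' Vk (Py) with Vk in {same_t, same_p, I}
        grad = np.empty(3)
        for k, g in enumerate((ti, pi, None)):
            if g is None:
                tr_pv = float(np.trace(vi)) - float(vi_x @ vi_x) / xtvix
                quad = float(py @ py)
            else:
                agg_vi = np.zeros((max(g) + 1, n))
                np.add.at(agg_vi, g, vi)
                tr_vi = float(agg_vi[g, np.arange(n)].sum())
                s = np.bincount(g, weights=vi_x)
                tr_px = float(s @ s) / xtvix
                tr_pv = tr_vi - tr_px
                q = np.bincount(g, weights=py)
                quad = float(q @ q)
            grad[k] = tr_pv - quad
        trace.append((tuple(theta), dev))
        return dev, grad

    # t and p components may go (slightly) negative — on balanced data the
    # REML optimum then coincides with the ANOVA solution even when a raw
    # mean square falls below the residual; V just has to stay PD, which the
    # inf-on-Cholesky-failure objective enforces.  Truncation to the
    # parameter space happens downstream in _finalize.
    # Stage 1: bounded L-BFGS-B over the nonnegative orthant (robust; keeps
    # the line search away from the non-PD region where the objective is
    # infinite).
    start = np.array([0.25, 0.15, 0.60]) * var_y
    ve_floor = 1e-12 * var_y
    res = optimize.minimize(
        neg_reml,
        start,
        jac=True,
        method="L-BFGS-B",
        bounds=[(0.0, None), (0.0, None), (ve_floor, None)],
        options={"maxiter": max_iter, "ftol": 1e-13, "gtol": 1e-9},
    )
    theta = np.asarray(res.x, dtype=float)

    # Stage 2: damped Newton polish, now allowing t/p components to go
    # negative.  On balanced data the REML optimum coincides with the ANOVA
    # solution even when that is slightly negative (V stays PD near the
    # optimum), and L-BFGS-B alone stops short of the 1e-6-relative
    # agreement promised there.  Central-difference Hessian of the analytic
    # gradient; step halving guards the non-PD region.  For sum/difference
    # fits the unconstrained optimum can lie outside the PD cone — the
    # deviance then decreases monotonically toward the feasibility boundary
    # and no improving step exists there; that is accepted as the
    # (boundary-constrained) solution rather than flagged as failure.
    h = np.maximum(1e-7 * var_y, 1e-7 * np.abs(theta))

    def try_step(theta, dev, step):
        """Backtracking along a descent step; returns improved theta or None."""
        for _ in range(25):
            new = theta - step
            new[2] = max(new[2], ve_floor)
            new_dev = neg_reml(new)[0]
            if np.isfinite(new_dev) and new_dev < dev - 1e-13 * max(1.0, abs(dev)):
                return new, new_dev
            step = step / 2.0
        return None

    dev = neg_reml(theta)[0]
    if not np.isfinite(dev):
        raise ConvergenceError("REML deviance not finite at start", trace=trace)
    for _ in range(60):
        dev, grad = neg_reml(theta)
        if np.linalg.norm(grad) < 1e-10 * max(1.0, abs(dev)):
            break
        hess = np.zeros((3, 3))
        for k in range(3):
            tp, tm = theta.copy(), theta.copy()
            tp[k] += h[k]
            tm[k] -= h[k]
            if k == 2:
                tm[k] = max(tm[k], ve_floor)
            gp, gm = neg_reml(tp)[1], neg_reml(tm)[1]
            hess[k] = (gp - gm) / (tp[k] - tm[k])
        hess = (hess + hess.T) / 2.0
        moved = None
        try:
            moved = try_step(theta, dev, np.linalg.solve(hess, grad))
        except np.linalg.LinAlgError:
            pass
        if moved is None:
            # fall back to scaled steepest descent before giving up
            g_norm = np.linalg.norm(grad)
            scale = max(np.abs(theta).max(), 1e-3 * var_y) / max(g_norm, 1e-300)
            moved = try_step(theta, dev, grad * scale)
        if moved is None:
            break
        theta, dev = moved

    if not np.isfinite(neg_reml(theta)[0]):
        raise ConvergenceError(
            "REML failed to reach a finite deviance", trace=trace
        )
    return theta, trace


def _check_connectivity(ti, pi, n_t, n_p):
    """Union-find on the trainee-procedure incidence graph."""
    parent = np.arange(n_t + n_p)

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in zip(ti, pi + n_t):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra
    roots = {find(x) for x in range(n_t + n_p)}
    return len(roots) == 1


def estimate_unbalanced(table: pd.DataFrame) -> GStudyComponents:
    """REML estimator for designs with missing cells.

    Per-variable variance components come from the two-way crossed
    random-effects REML fit; cross-variable covariance components use the
    sum/difference identity cov = (var(u+v) - var(u-v)) / 4 per effect.
    """
    trainees, ti = np.unique(table["trainee_id"].to_numpy(), return_inverse=True)
    procedures, pi = np.unique(table["procedure_id"].to_numpy(), return_inverse=True)
    n_t, n_p = len(trainees), len(procedures)
    if n_t < 2:
        raise IdentifiabilityError("need >= 2 trainees")
    if n_p < 2:
        raise IdentifiabilityError(
            "a single procedure cannot identify a procedure variance component"
        )
    if table.duplicated(subset=["trainee_id", "procedure_id"]).any():
        raise MvgtError("at most one observation per (trainee, procedure) cell")
    if not _check_connectivity(ti, pi, n_t, n_p):
        logger.warning(
            "trainee-procedure incidence graph is disconnected; variance "
            "components may be weakly identified"
        )

    y = score_matrix(table)
    single = [_reml_two_way(y[:, u], ti, pi, n_t, n_p)[0] for u in range(4)]

    raw = {eff: np.zeros((4, 4)) for eff in EFFECTS}
    for u in range(4):
        for k, eff in enumerate(EFFECTS):
            raw[eff][u, u] = single[u][k]
    for u in range(4):
        for v in range(u + 1, 4):
            th_sum = _reml_two_way(y[:, u] + y[:, v], ti, pi, n_t, n_p)[0]
            th_diff = _reml_two_way(y[:, u] - y[:, v], ti, pi, n_t, n_p)[0]
            cov = (th_sum - th_diff) / 4.0
            for k, eff in enumerate(EFFECTS):
                raw[eff][u, v] = raw[eff][v, u] = cov[k]

    n_proc_mean = float(np.bincount(ti).mean())
    return _finalize(
        raw["t"], raw["p"], raw["tp"], n_t, n_proc_mean, "unbalanced-iterative"
    )


def estimate(table: pd.DataFrame) -> GStudyComponents:
    """Dispatch to the balanced or unbalanced estimator as appropriate."""
    if is_fully_crossed(table):
        return estimate_balanced(table)
    return estimate_unbalanced(table)


# ---------------------------------------------------------------------------
# reporting

def proportion_table(
    components: GStudyComponents, variable: int
) -> tuple[float, float, float]:
    """Percent of total variance due to (t, p, tp) for one variable.

    Each value is 100 * sigma2(effect) / total, rounded to one decimal for
    reporting.
    """
    parts = np.array(
        [components.matrix(eff)[variable, variable] for eff in EFFECTS]
    )
    total = parts.sum()
    if total <= 0:
        raise UndefinedStatisticError(
            f"total variance for variable {VARIABLE_NAMES[variable]} is zero; "
            "proportions undefined"
        )
    return tuple(round(100.0 * p / total, 1) for p in parts)
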