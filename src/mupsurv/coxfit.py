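"""Penalized cubic-spline Cox proportional-hazards regression.

Continuous exposures (a marker's %TFI, total energy intake, optionally
other continuous covariates) enter the Cox log-hazard as cubic B-spline
expansions — eight basis functions over the observed exposure range, hence
twelve knots once boundary multiplicity is counted — with a second-order
difference penalty on adjacent coefficients (a P-spline).  The penalty
weight of each spline term is tuned so the term attains a target effective
degrees of freedom (default 4); the penalty's null space contains the
linear trend, so as the penalty grows the fitted curve collapses onto the
best-fitting linear log-hazard.

Estimation maximizes the penalized Cox partial log-likelihood (Breslow
ties by default, Efron available) by Newton–Raphson with step-halving.
Two covariances are kept: the inverse penalized information (used for
curve confidence intervals and the penalized Wald test) and the sandwich
form H_pen^-1 H H_pen^-1, the sampling covariance of the penalized
estimator (used for the linear-effect test).  Each spline term's effect is
decomposed into a linear component — a precision-weighted projection of
the coefficients onto the linear trend across the basis-function centres,
tested with 1-df Wald — and a non-linear remainder, tested as the total
penalized Wald chi-square minus its linear share on effective df − 1.
Proportional-hazards diagnostics use per-covariate score tests on scaled
Schoenfeld residuals against a survival-time transform; covariates with
Holm-significant violations are moved to baseline-hazard strata in a
single refit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import interpolate, linalg
from scipy.stats import chi2 as chi2_dist
from statsmodels.stats.multitest import multipletests

__all__ = [
    "SplineBasis",
    "SplineTermSpec",
    "CoxSplineFit",
    "EffectTests",
    "ConvergenceError",
    "build_basis",
    "fit_cox_pspline",
    "ph_diagnose_and_stratify",
    "decompose",
    "holm_adjust",
    "bh_adjust",
]


class ConvergenceError(RuntimeError):
    """Newton iteration failed to converge; carries the iteration trace."""

    def __init__(self, message: str, trace: list[float] | None = None):
        super().__init__(message)
        self.trace = trace or []


# ---------------------------------------------------------------------------
# spline basis


@dataclass(frozen=True)
class SplineBasis:
    """Cubic B-spline basis over an exposure's observed range.

    ``n_basis`` functions of order 4 (cubic) over ``n_basis + 4`` equally
    spaced knots extending past the data range, so the basis is complete
    (partition of unity) on [x_min, x_max] and the Greville abscissae are
    equally spaced — which makes the difference penalty's null space
    exactly the functions linear in x.  Evaluation outside the data range
    clamps to the boundary (flat extension).
    """

    knots: np.ndarray
    n_basis: int
    order: int = 4

    @property
    def x_min(self) -> float:
        """Lower end of the interval on which the basis is complete."""
        return float(self.knots[self.order - 1])

    @property
    def x_max(self) -> float:
        return float(self.knots[self.n_basis])

    @property
    def centers(self) -> np.ndarray:
        """Greville abscissae: the natural x-location of each basis function."""
        k = self.order - 1
        t = self.knots
        return np.array([t[j + 1 : j + 1 + k].mean() for j in range(self.n_basis)])

    def evaluate(self, x: np.ndarray) -> np.ndarray:
        """Dense (n, n_basis) design matrix, clamped to [x_min, x_max]."""
        x = np.asarray(x, dtype=float)
        xc = np.clip(x, self.x_min, self.x_max)
        return interpolate.BSpline.design_matrix(
            xc, self.knots, self.order - 1
        ).toarray()


def build_basis(x: np.ndarray, n_basis: int = 8) -> SplineBasis:
    """Basis over the range of observed exposures with equally spaced knots.

    Eight basis functions yield twelve knots: ``n_basis - order + 1``
    spans cover [min(x), max(x)] and three knots extend beyond each end.
    """
    x = np.asarray(x, dtype=float)
    lo, hi = float(np.min(x)), float(np.max(x))
    if not hi > lo:
        raise ValueError("exposure is constant; cannot place spline knots")
    if n_basis < 4:
        raise ValueError("need at least 4 basis functions for a cubic spline")
    order = 4
    h = (hi - lo) / (n_basis - order + 1)
    knots = lo + h * np.arange(-(order - 1), n_basis + 1)
    return SplineBasis(knots=knots, n_basis=n_basis, order=order)


def _difference_penalty(n_basis: int, order: int = 2) -> np.ndarray:
    d = np.diff(np.eye(n_basis), n=order, axis=0)
    return d.T @ d


# ---------------------------------------------------------------------------
# partial likelihood machinery


def _prepare(time: np.ndarray, event: np.ndarray, X: np.ndarray, strata: np.ndarray):
    """Sort each stratum by ascending time; return per-stratum views."""
    out = []
    for s in np.unique(strata):
        m = strata == s
        order = np.argsort(time[m], kind="stable")
        out.append((time[m][order], event[m][order].astype(bool), X[m][order]))
    return out


def _stratum_quantities(beta, t, e, X, ties, need_hess=True):
    """Breslow/Efron log partial likelihood, score and information.

    Rows are sorted by ascending time; the risk set at an event time
    comprises all rows with time >= that value.
    """
    n, p = X.shape
    eta = X @ beta
    shift = eta.max() if n else 0.0
    w = np.exp(eta - shift)
    S0r = np.cumsum(w[::-1])[::-1]
    S1r = np.cumsum((X * w[:, None])[::-1], axis=0)[::-1]
    if need_hess:
        outer = X[:, :, None] * X[:, None, :] * w[:, None, None]
        S2r = np.cumsum(outer[::-1], axis=0)[::-1]
    if not e.any():
        return 0.0, np.zeros(p), np.zeros((p, p))

    et = t[e]
    Xe = X[e]
    we = w[e]
    uniq, gstart = np.unique(et, return_index=True)
    d = np.diff(np.append(gstart, len(et))).astype(float)
    pos = np.searchsorted(t, uniq, side="left")
    s0 = S0r[pos]
    if not np.all(s0 > 0):
        # risk-set weights underflowed (wild trial step): reject the step
        return -np.inf, np.zeros(p), np.zeros((p, p))
    s1 = S1r[pos]
    sx = np.add.reduceat(Xe, gstart, axis=0)

    ll = float((eta[e]).sum())
    grad = sx.sum(axis=0)
    hess = np.zeros((p, p))

    if ties == "efron":
        wd0 = np.add.reduceat(we, gstart)
        wd1 = np.add.reduceat(Xe * we[:, None], gstart, axis=0)
        if need_hess:
            oute = Xe[:, :, None] * Xe[:, None, :] * we[:, None, None]
            wd2 = np.add.reduceat(oute, gstart, axis=0)
        s2 = S2r[pos] if need_hess else None
        for g in range(len(uniq)):
            dg = int(d[g])
            for l in range(dg):
                f = l / dg
                den0 = s0[g] - f * wd0[g]
                den1 = s1[g] - f * wd1[g]
                ll -= np.log(den0) + shift
                xb = den1 / den0
                grad -= xb
                if need_hess:
                    den2 = s2[g] - f * wd2[g]
                    hess += den2 / den0 - np.outer(xb, xb)
        return ll, grad, hess

    # Breslow
    ll -= float((d * (np.log(s0) + shift)).sum())
    xbar = s1 / s0[:, None]
    grad -= (d[:, None] * xbar).sum(axis=0)
    if need_hess:
        s2 = S2r[pos]
        hess = (
            d[:, None, None] * (s2 / s0[:, None, None] - xbar[:, :, None] * xbar[:, None, :])
        ).sum(axis=0)
    return ll, grad, hess


def _cox_quantities(beta, strata_data, ties, need_hess=True):
    p = len(beta)
    ll, grad, hess = 0.0, np.zeros(p), np.zeros((p, p))
    for t, e, X in strata_data:
        l_, g_, h_ = _stratum_quantities(beta, t, e, X, ties, need_hess)
        ll += l_
        grad += g_
        hess += h_
    return ll, grad, hess


def _newton(strata_data, Pmat, p, ties, max_iter=50, tol=1e-9, beta0=None):
    beta = np.zeros(p) if beta0 is None else beta0.copy()
    trace: list[float] = []
    ll, grad, hess = _cox_quantities(beta, strata_data, ties)
    pll = ll - 0.5 * beta @ Pmat @ beta
    for it in range(max_iter):
        g_pen = grad - Pmat @ beta
        H_pen = hess + Pmat
        try:
            step = linalg.solve(H_pen, g_pen, assume_a="pos")
        except linalg.LinAlgError:
            step = linalg.lstsq(H_pen, g_pen)[0]
        # quadratic model predicts the remaining gain; stop when negligible
        if 0.5 * abs(g_pen @ step) < tol * (abs(pll) + 1.0):
            return beta, ll, grad, hess, pll, it, trace
        # step halving on the penalized objective; tolerate rounding noise
        ok = False
        noise = 1e-10 * (abs(pll) + 1.0)
        for _ in range(30):
            cand = beta + step
            ll_c, grad_c, hess_c = _cox_quantities(cand, strata_data, ties)
            pll_c = ll_c - 0.5 * cand @ Pmat @ cand
            if np.isfinite(pll_c) and pll_c >= pll - noise:
                ok = True
                break
            step = step / 2.0
        if not ok:
            if 0.5 * abs(g_pen @ step) < 1e-6 * (abs(pll) + 1.0):
                return beta, ll, grad, hess, pll, it, trace
            raise ConvergenceError("step halving failed to improve objective", trace)
        delta = pll_c - pll
        beta, ll, grad, hess, pll = cand, ll_c, grad_c, hess_c, pll_c
        trace.append(pll)
        if abs(delta) < tol * (abs(pll) + 1.0):
            return beta, ll, grad, hess, pll, it + 1, trace
    raise ConvergenceError(
        f"no convergence after {max_iter} Newton iterations", trace
    )


# ---------------------------------------------------------------------------
# model assembly


@dataclass(frozen=True)
class SplineTermSpec:
    """Configuration of one penalized spline term."""

    col: str
    n_basis: int = 8
    target_df: float = 4.0
    lambda_fixed: float | None = None


@dataclass
class CoxSplineFit:
    """A converged penalized spline Cox fit."""

    beta: np.ndarray
    cov: np.ndarray  # inverse penalized information
    cov_sandwich: np.ndarray  # H_pen^-1 H H_pen^-1: sampling covariance
    info: np.ndarray  # unpenalized observed information at the optimum
    penalty: np.ndarray  # lambda-weighted total penalty matrix
    lambdas: dict[str, float]
    edf: dict[str, float]
    term_slices: dict[str, slice]
    bases: dict[str, SplineBasis]
    x_observed: dict[str, np.ndarray]
    column_names: list[str]
    loglik: float
    n_iter: int
    ties: str
    strata_cols: tuple[str, ...]
    covariate_cols: tuple[str, ...]
    duration_col: str
    event_col: str
    spline_specs: tuple[SplineTermSpec, ...]
    n: int
    n_events: int

    def spline_beta_full(self, term: str) -> np.ndarray:
        """Spline coefficients including the identifiability-fixed first one."""
        return np.concatenate([[0.0], self.beta[self.term_slices[term]]])

    def spline_cov_full(self, term: str, which: str = "penalized") -> np.ndarray:
        sl = self.term_slices[term]
        nb = self.bases[term].n_basis
        src = self.cov if which == "penalized" else self.cov_sandwich
        out = np.zeros((nb, nb))
        out[1:, 1:] = src[sl, sl]
        return out


def _design(
    data: pd.DataFrame,
    spline_specs: Sequence[SplineTermSpec],
    covariates: Sequence[str],
):
    """Assemble the design matrix: spline blocks then categorical dummies.

    The first column of each spline basis is dropped (the Cox partial
    likelihood cannot identify a constant shift of the linear predictor)
    and all columns are centred.
    """
    blocks: list[np.ndarray] = []
    names: list[str] = []
    term_slices: dict[str, slice] = {}
    bases: dict[str, SplineBasis] = {}
    x_obs: dict[str, np.ndarray] = {}
    pen_blocks: list[tuple[slice, np.ndarray]] = []
    start = 0
    for spec in spline_specs:
        x = data[spec.col].to_numpy(dtype=float)
        basis = build_basis(x, spec.n_basis)
        B = basis.evaluate(x)[:, 1:]
        sl = slice(start, start + B.shape[1])
        term_slices[spec.col] = sl
        bases[spec.col] = basis
        x_obs[spec.col] = x
        pen_blocks.append((sl, _difference_penalty(spec.n_basis)[1:, 1:]))
        blocks.append(B - B.mean(axis=0))
        names += [f"ps({spec.col}){j}" for j in range(1, spec.n_basis)]
        start += B.shape[1]
    cov_slices: dict[str, slice] = {}
    for col in covariates:
        dummies = pd.get_dummies(data[col], prefix=col, drop_first=True, dtype=float)
        if dummies.shape[1] == 0:
            raise ValueError(f"covariate {col!r} has a single level; drop it")
        arr = dummies.to_numpy()
        zero_var = arr.std(axis=0) == 0
        if zero_var.any():
            bad = [dummies.columns[i] for i in np.where(zero_var)[0]]
            raise ValueError(f"degenerate covariate level(s): {bad}")
        cov_slices[col] = slice(start, start + arr.shape[1])
        blocks.append(arr - arr.mean(axis=0))
        names += list(dummies.columns)
        start += arr.shape[1]
    X = np.hstack(blocks) if blocks else np.empty((len(data), 0))
    return X, names, term_slices, cov_slices, bases, x_obs, pen_blocks


def _penalty_matrix(p, pen_blocks, lambdas_by_slice):
    P = np.zeros((p, p))
    for (sl, Pb), lam in zip(pen_blocks, lambdas_by_slice):
        P[sl, sl] += lam * Pb
    return P


def _term_edf(H, P, term_slices):
    """Effective df per spline term: block trace of (H + P)^{-1} H."""
    try:
        M = linalg.solve(H + P, H, assume_a="gen")
    except linalg.LinAlgError:
        M = linalg.lstsq(H + P, H)[0]
    diag = np.diag(M)
    return {name: float(diag[sl].sum()) for name, sl in term_slices.items()}


def fit_cox_pspline(
    data: pd.DataFrame,
    *,
    duration_col: str = "time_years",
    event_col: str = "event",
    spline_terms: Sequence[SplineTermSpec] | None = None,
    covariates: Sequence[str] = (),
    strata: Sequence[str] = (),
    ties: str = "breslow",
    max_iter: int = 50,
    tol: float = 1e-9,
) -> CoxSplineFit:
    """Fit the penalized spline Cox model.

    ``spline_terms`` lists the continuous terms entering as P-splines (the
    exposure, total energy intake, ...); ``covariates`` are categorical
    adjustment covariates expanded into treatment-coded dummies;
    ``strata`` name columns defining baseline-hazard strata.  Each spline
    term's penalty is tuned by root-finding so its effective df matches
    the term's configured target, unless ``lambda_fixed`` pins it.
    """
    if ties not in ("breslow", "efron"):
        raise ValueError(f"unknown tie method {ties!r}")
    spline_terms = tuple(spline_terms or ())
    time = data[duration_col].to_numpy(dtype=float)
    event = data[event_col].to_numpy(dtype=float)
    if (event == 1).sum() < 2:
        raise ValueError("need at least 2 events")
    X, names, term_slices, cov_slices, bases, x_obs, pen_blocks = _design(
        data, spline_terms, covariates
    )
    p = X.shape[1]
    if strata:
        strat_ids = (
            data[list(strata)].astype(str).agg("|".join, axis=1).to_numpy()
        )
    else:
        strat_ids = np.zeros(len(data), dtype=int)
    strata_data = _prepare(time, event, X, strat_ids)

    # --- penalty tuning ----------------------------------------------------
    lambdas = np.array(
        [spec.lambda_fixed if spec.lambda_fixed is not None else 1.0 for spec in spline_terms]
    )
    free = [i for i, spec in enumerate(spline_terms) if spec.lambda_fixed is None]
    beta_ws: np.ndarray | None = None

    def fit_at(lams) -> tuple:
        nonlocal beta_ws
        P = _penalty_matrix(p, pen_blocks, lams)
        out = _newton(strata_data, P, p, ties, max_iter, tol, beta0=beta_ws)
        beta_ws = out[0]
        return out, P

    if free:
        for _ in range(2):  # two coordinate passes are ample for weak coupling
            for i in free:
                spec = spline_terms[i]
                target = min(spec.target_df, spec.n_basis - 1 - 1e-6)

                def df_gap(loglam: float) -> float:
                    lams = lambdas.copy()
                    lams[i] = 10.0 ** loglam
                    (beta, ll, g, H, pll, nit, tr), P = fit_at(lams)
                    return _term_edf(H, P, term_slices)[spec.col] - target

                lo, hi = -6.0, 10.0
                if df_gap(hi) > 0:
                    lambdas[i] = 10.0 ** hi
                elif df_gap(lo) < 0:
                    lambdas[i] = 10.0 ** lo
                else:
                    from scipy.optimize import brentq

                    lambdas[i] = 10.0 ** brentq(df_gap, lo, hi, xtol=1e-3)
            if len(free) == 1:
                break

    (beta, ll, grad, H, pll, n_iter, trace), P = fit_at(lambdas)
    try:
        cov = linalg.inv(H + P)
    except linalg.LinAlgError:
        cov = linalg.pinvh(H + P)
    edf = _term_edf(H, P, term_slices) if spline_terms else {}

    return CoxSplineFit(
        beta=beta,
        cov=cov,
        cov_sandwich=cov @ H @ cov,
        info=H,
        penalty=P,
        lambdas={spec.col: float(lam) for spec, lam in zip(spline_terms, lambdas)},
        edf=edf,
        term_slices=term_slices | cov_slices,
        bases=bases,
        x_observed=x_obs,
        column_names=names,
        loglik=ll,
        n_iter=n_iter,
        ties=ties,
        strata_cols=tuple(strata),
        covariate_cols=tuple(covariates),
        duration_col=duration_col,
        event_col=event_col,
        spline_specs=spline_terms,
        n=len(data),
        n_events=int((event == 1).sum()),
    )


# ---------------------------------------------------------------------------
# effect decomposition


@dataclass
class EffectTests:
    """Linear / non-linear Wald tests per spline term."""

    p_linear: dict[str, float]
    p_nonlinear: dict[str, float]
    slope: dict[str, float]
    slope_se: dict[str, float]
    chi2_linear: dict[str, float] = field(default_factory=dict)
    chi2_nonlinear: dict[str, float] = field(default_factory=dict)
    df_nonlinear: dict[str, float] = field(default_factory=dict)


def decompose(fit: CoxSplineFit) -> EffectTests:
    """Split each spline term into linear and non-linear effects.

    The coefficient vector is projected onto the linear trend across the
    basis-function centres (B-splines reproduce linear functions exactly
    when coefficients are linear in the Greville abscissae), yielding a
    log-HR slope with a 1-df Wald test; the orthogonal residual gives the
    non-linear Wald test on effective df − 1.  Both use the penalized
    covariance.  The constant direction is unidentifiable in a Cox model
    and both functionals are invariant to it.
    """
    out = EffectTests({}, {}, {}, {})
    for spec in fit.spline_specs:
        term = spec.col
        basis = fit.bases[term]
        c = basis.centers
        T = np.column_stack([np.ones_like(c), c])
        beta_full = fit.spline_beta_full(term)
        cov_pen = fit.spline_cov_full(term, which="penalized")
        cov_sand = fit.spline_cov_full(term, which="sandwich")

        # precision-weighted (GLS) projection onto intercept + linear trend;
        # down-weights the poorly determined exterior basis functions.  Both
        # functionals are invariant to the unidentifiable constant direction.
        W = linalg.pinvh(cov_pen, rtol=1e-11)
        A = linalg.solve(T.T @ W @ T, np.eye(2), assume_a="pos")
        proj = A @ T.T @ W  # (2, n_basis)
        coef = proj @ beta_full
        slope = float(coef[1])
        # sampling (sandwich) variance for the calibrated linear test
        var = float((proj @ cov_sand @ proj.T)[1, 1])
        if var <= 0:
            raise ValueError(f"singular covariance for spline term {term!r}")
        chi2_lin = slope ** 2 / var
        p_lin = float(chi2_dist.sf(chi2_lin, 1))

        # non-linear component: total penalized Wald chi-square (expectation
        # = effective df under the null) minus its linear share, on edf-1 df
        chi2_total = float(beta_full @ W @ beta_full)
        var_pen = float((proj @ cov_pen @ proj.T)[1, 1])
        chi2_nl = max(chi2_total - slope ** 2 / var_pen, 0.0)
        df_nl = max(fit.edf.get(term, basis.n_basis - 1) - 1.0, 0.5)
        p_nl = float(chi2_dist.sf(chi2_nl, df_nl))

        out.slope[term] = slope
        out.slope_se[term] = float(np.sqrt(var))
        out.chi2_linear[term] = chi2_lin
        out.p_linear[term] = p_lin
        out.chi2_nonlinear[term] = chi2_nl
        out.df_nonlinear[term] = df_nl
        out.p_nonlinear[term] = p_nl
    return out


# ---------------------------------------------------------------------------
# proportional-hazards diagnostics


def _km_transform(time: np.ndarray, event: np.ndarray) -> np.ndarray:
    """Left-continuous Kaplan–Meier transform evaluated at each event time."""
    order = np.argsort(time, kind="stable")
    t_s, e_s = time[order], event[order]
    uniq = np.unique(t_s)
    n = len(t_s)
    at_risk = n - np.searchsorted(t_s, uniq, side="left")
    deaths = np.array([(e_s[t_s == u] == 1).sum() for u in uniq], dtype=float)
    surv = np.cumprod(1.0 - deaths / at_risk)
    surv_left = np.concatenate([[1.0], surv[:-1]])  # S(t-)
    lookup = dict(zip(uniq, surv_left))
    ev_times = time[event == 1]
    return np.array([1.0 - lookup[t] for t in ev_times])


def schoenfeld_tests(
    fit: CoxSplineFit,
    data: pd.DataFrame,
    transform: str = "km",
) -> pd.DataFrame:
    """Score tests for proportional hazards, one per categorical covariate.

    For each covariate term (all its dummy columns jointly) the statistic
    contrasts Schoenfeld residuals against a centred time transform
    (Kaplan–Meier by default, or "rank"/"identity"); under proportional
    hazards it is approximately chi-square with the term's column count as
    df.  Returns a frame with chi2, df and p per covariate.
    """
    time = data[fit.duration_col].to_numpy(dtype=float)
    event = data[fit.event_col].to_numpy(dtype=float)
    X, names, term_slices, cov_slices, *_ = _design(
        data, fit.spline_specs, fit.covariate_cols
    )
    if fit.strata_cols:
        strat_ids = data[list(fit.strata_cols)].astype(str).agg("|".join, axis=1).to_numpy()
    else:
        strat_ids = np.zeros(len(data), dtype=int)

    # Schoenfeld residuals per event, computed stratum-wise
    resid_rows = []
    g_rows = []
    for s in np.unique(strat_ids):
        m = strat_ids == s
        t_, e_, X_ = time[m], event[m], X[m]
        order = np.argsort(t_, kind="stable")
        t_, e_, X_ = t_[order], e_[order].astype(bool), X_[order]
        if not e_.any():
            continue
        w = np.exp(np.clip(X_ @ fit.beta, -500, 500))
        S0r = np.cumsum(w[::-1])[::-1]
        S1r = np.cumsum((X_ * w[:, None])[::-1], axis=0)[::-1]
        pos = np.searchsorted(t_, t_[e_], side="left")
        xbar = S1r[pos] / S0r[pos][:, None]
        resid_rows.append(X_[e_] - xbar)
        if transform == "km":
            g_all = _km_transform(t_, e_.astype(float))
        elif transform == "rank":
            g_all = np.argsort(np.argsort(t_[e_])).astype(float)
        elif transform == "identity":
            g_all = t_[e_]
        else:
            raise ValueError(f"unknown transform {transform!r}")
        g_rows.append(g_all)
    resid = np.vstack(resid_rows)
    g = np.concatenate(g_rows)
    g = g - g.mean()
    m_events = len(g)

    rows = []
    for cov_name, sl in cov_slices.items():
        U = resid[:, sl].T @ g
        # Var(U) ~ sum((g-gbar)^2) * Vbar_JJ with Vbar = I/m
        Vjj = fit.info[sl, sl] / m_events
        V = float((g ** 2).sum()) * Vjj
        try:
            stat = float(U @ linalg.solve(V, U, assume_a="pos"))
        except linalg.LinAlgError:
            stat = float(U @ linalg.pinvh(V) @ U)
        df = sl.stop - sl.start
        rows.append(
            {"covariate": cov_name, "chi2": stat, "df": df,
             "p": float(chi2_dist.sf(stat, df))}
        )
    return pd.DataFrame(rows).set_index("covariate")


def ph_diagnose_and_stratify(
    fit: CoxSplineFit,
    data: pd.DataFrame,
    alpha: float = 0.05,
    transform: str = "km",
) -> tuple[tuple[str, ...], CoxSplineFit, pd.DataFrame]:
    """Single-pass stratification of proportional-hazards violators.

    Runs the Schoenfeld score test per covariate, Holm-adjusts across
    covariates, moves every significant violator from the regression part
    to baseline-hazard strata, and refits once.  Returns the violator set,
    the (possibly unchanged) final fit, and the diagnostics table.
    """
    tests = schoenfeld_tests(fit, data, transform=transform)
    if tests.empty:
        return (), fit, tests
    tests = tests.assign(p_holm=holm_adjust(tests["p"].to_numpy()))
    violators = tuple(tests.index[tests["p_holm"] < alpha])
    if not violators:
        return (), fit, tests
    keep = tuple(c for c in fit.covariate_cols if c not in violators)
    refit = fit_cox_pspline(
        data,
        duration_col=fit.duration_col,
        event_col=fit.event_col,
        spline_terms=fit.spline_specs,
        covariates=keep,
        strata=tuple(fit.strata_cols) + violators,
        ties=fit.ties,
    )
    return violators, refit, tests


# ---------------------------------------------------------------------------
# multiple-testing adjustment


def holm_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Holm step-down adjusted p-values, clipped to [0, 1]."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="holm")[1]


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (FDR)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]
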