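"""Penalized additive logistic model for gridded extinction fates.

Smooth terms are cubic B-splines with knots at data quantiles and a
second-order difference penalty on the coefficients; the spatial term is a
tensor product of marginal lon/lat bases.  Fitting is penalized IRLS; the
single global smoothing multiplier (scaled per term so penalties are
comparable) is chosen by generalized cross-validation,

    GCV(lambda) = n * D(lambda) / (n - edf(lambda))^2 .

Reported diagnostics follow additive-model conventions: per-term effective
degrees of freedom, Wald chi-square tests on the penalized coefficients,
deviance explained (1 - D_model / D_null) and an adjusted R-squared.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import BSpline

__all__ = [
    "SmoothTerm",
    "GamSpec",
    "GamFit",
    "fit_gam",
    "partial_effect",
    "screen_collinear_predictors",
    "GamConvergenceError",
]

_ETA_CAP = 30.0  # |linear predictor| beyond this flags quasi-separation


class GamConvergenceError(RuntimeError):
    def __init__(self, message: str, deviance_trace: list[float]):
        super().__init__(message)
        self.deviance_trace = deviance_trace


@dataclass(frozen=True)
class SmoothTerm:
    """One smooth: a univariate spline or a 2-D tensor product."""

    variables: tuple[str, ...]
    n_basis: int = 10  # per-axis basis size for tensors

    def __post_init__(self) -> None:
        if len(self.variables) not in (1, 2):
            raise ValueError("smooth terms take 1 or 2 variables")
        if self.n_basis < 3:
            raise ValueError("basis size must be >= 3")

    @property
    def label(self) -> str:
        return "s(" + ",".join(self.variables) + ")"


@dataclass
class GamSpec:
    """Model specification: smooth terms, binomial-logit family fixed."""

    terms: list[SmoothTerm]
    lambda_grid: tuple[float, ...] = (1e-3, 1e-2, 1e-1, 1.0, 1e1, 1e2, 1e4)
    fixed_lambda: float | None = None  # bypass GCV when set

    @classmethod
    def default(cls, covariates: list[str], spatial: bool = True,
                n_basis: int = 10, tensor_basis: int = 5) -> "GamSpec":
        terms = [SmoothTerm((v,), n_basis) for v in covariates]
        if spatial:
            terms.append(SmoothTerm(("lon", "lat"), tensor_basis))
        return cls(terms)


def _knot_vector(x: np.ndarray, n_basis: int) -> np.ndarray:
    """Cubic B-spline knots: boundary knots repeated, interior at quantiles."""
    lo, hi = float(x.min()), float(x.max())
    if hi <= lo:
        hi = lo + 1.0
    pad = 1e-6 * (hi - lo)
    n_interior = n_basis - 4
    if n_interior > 0:
        qs = np.quantile(x, np.linspace(0, 1, n_interior + 2)[1:-1])
        interior = np.clip(np.sort(qs), lo + pad, hi - pad)
    else:
        interior = np.empty(0)
    return np.concatenate([[lo - pad] * 4, interior, [hi + pad] * 4])


def _design(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    xc = np.clip(x, knots[0], knots[-1])
    return BSpline.design_matrix(xc, knots, 3).toarray()


def _diff_penalty(n: int, order: int = 2) -> np.ndarray:
    d = np.diff(np.eye(n), n=order, axis=0)
    return d.T @ d


@dataclass
class _TermBasis:
    term: SmoothTerm
    knots: list[np.ndarray]
    col_means: np.ndarray
    penalty: np.ndarray

    def design(self, data: pd.DataFrame | dict) -> np.ndarray:
        mats = [_design(np.asarray(data[v], dtype=float), kn)
                for v, kn in zip(self.term.variables, self.knots)]
        if len(mats) == 1:
            b = mats[0]
        else:  # row-wise Kronecker product for the tensor smooth
            b = (mats[0][:, :, None] * mats[1][:, None, :]).reshape(len(mats[0]), -1)
        return b - self.col_means


def _build_basis(term: SmoothTerm, data: pd.DataFrame) -> _TermBasis:
    knots = [_knot_vector(data[v].to_numpy(dtype=float), term.n_basis)
             for v in term.variables]
    if len(term.variables) == 1:
        n = len(knots[0]) - 4
        pen = _diff_penalty(n)
    else:
        n1, n2 = (len(k) - 4 for k in knots)
        pen = np.kron(_diff_penalty(n1), np.eye(n2)) + np.kron(np.eye(n1), _diff_penalty(n2))
    tb = _TermBasis(term, knots, np.zeros(pen.shape[0]), pen)
    tb.col_means = tb.design(data).mean(axis=0) + tb.col_means
    return tb


@dataclass
class GamFit:
    """Fitted additive logistic model."""

    spec: GamSpec
    bases: list[_TermBasis]
    coef: np.ndarray
    cov: np.ndarray  # Bayesian posterior covariance (X'WX + S)^-1
    term_slices: list[slice]
    lambda_used: list
    n: int
    deviance: float
    null_deviance: float
    fitted: np.ndarray
    edf_total: float
    term_table: pd.DataFrame  # label, edf, chi_sq, p_value
    gcv_score: float
    separation_warning: bool = False
    deviance_trace: list[float] = field(default_factory=list)

    @property
    def deviance_explained(self) -> float:
        return 1.0 - self.deviance / self.null_deviance if self.null_deviance > 0 else 0.0

    @property
    def adjusted_r2(self) -> float:
        r2 = self.deviance_explained
        denom = self.n - self.edf_total - 1.0
        if denom <= 0:
            return float("nan")
        return 1.0 - (1.0 - r2) * (self.n - 1.0) / denom

    @property
    def aic(self) -> float:
        return self.deviance + 2.0 * self.edf_total

    def summary(self) -> dict:
        return {
            "n": self.n,
            "deviance_explained": self.deviance_explained,
            "adjusted_r2": self.adjusted_r2,
            "aic": self.aic,
            "edf_total": self.edf_total,
            "lambda": list(self.lambda_used),
            "terms": self.term_table.to_dict(orient="records"),
        }


def _binomial_deviance(y: np.ndarray, mu: np.ndarray) -> float:
    mu = np.clip(mu, 1e-12, 1 - 1e-12)
    return float(-2.0 * np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu)))


def _pirls(X, y, S, max_iter=100, tol=1e-7):
    """Penalized IRLS for binomial-logit; returns coefs, mu, traces."""
    n = len(y)
    mu = np.clip((y + 0.5) / 2.0, 0.01, 0.99)
    eta = np.log(mu / (1 - mu))
    dev = _binomial_deviance(y, mu)
    trace = [dev]
    beta = np.zeros(X.shape[1])
    separation = False
    for _ in range(max_iter):
        w = np.clip(mu * (1 - mu), 1e-10, None)
        z = eta + (y - mu) / w
        xw = X * w[:, None]
        A = X.T @ xw + S
        try:
            beta = np.linalg.solve(A, xw.T @ z)
        except np.linalg.LinAlgError:
            beta = np.linalg.solve(A + 1e-8 * np.eye(A.shape[0]), xw.T @ z)
        eta = X @ beta
        if np.abs(eta).max() > _ETA_CAP:
            if not separation:
                warnings.warn("quasi-separation detected; applying ridge fallback and capping the linear predictor")
                separation = True
                S = S + 1e-6 * np.eye(S.shape[0])
            eta = np.clip(eta, -_ETA_CAP, _ETA_CAP)
        mu = 1.0 / (1.0 + np.exp(-eta))
        new_dev = _binomial_deviance(y, mu)
        trace.append(new_dev)
        if abs(new_dev - dev) < tol * (abs(dev) + 1.0):
            dev = new_dev
            break
        dev = new_dev
    else:
        raise GamConvergenceError(f"IRLS did not converge in {max_iter} iterations", trace)
    return beta, mu, eta, S, trace, separation


def fit_gam(rows: pd.DataFrame, spec: GamSpec, response: str = "fate") -> GamFit:
    """Fit the additive logistic extinction model to fate rows.

    ``rows`` must contain the response column (0/1) and every variable named
    by the spec's smooth terms.  The smoothing multiplier is selected by GCV
    over ``spec.lambda_grid`` unless ``spec.fixed_lambda`` is set.
    """
    y = rows[response].to_numpy(dtype=float)
    n = len(y)
    if n < 3:
        raise ValueError("need at least 3 rows")
    bases = [_build_basis(t, rows) for t in spec.terms]
    blocks = [np.ones((n, 1))] + [tb.design(rows) for tb in bases]
    X = np.hstack(blocks)
    total_basis = X.shape[1]
    if n < 10 * total_basis:
        warnings.warn(f"only {n} rows for {total_basis} basis functions; fit may be unstable")

    slices, start = [], 1
    for tb in bases:
        k = tb.penalty.shape[0]
        slices.append(slice(start, start + k))
        start += k

    # per-term scale so comparable multipliers penalize all terms comparably
    scales = []
    for tb, sl in zip(bases, slices):
        xtx = X[:, sl].T @ X[:, sl]
        pf = np.linalg.norm(tb.penalty)
        scales.append(np.linalg.norm(xtx) / pf if pf > 0 else 1.0)

    x_scale = float(np.mean(np.sum(X * X, axis=0)))
    n_terms = len(bases)

    def assemble_S(lams) -> np.ndarray:
        # small fixed ridge keeps the penalized Hessian invertible when a
        # term's design is rank-deficient (few distinct covariate values);
        # the intercept is never penalized
        S = 1e-7 * x_scale * np.eye(total_basis)
        S[0, 0] = 0.0
        for tb, sl, sc, lam in zip(bases, slices, scales, lams):
            S[sl, sl] += lam * sc * tb.penalty
        return S

    def fit_at(lams):
        beta, mu, eta, S_used, trace, sep = _pirls(X, y, assemble_S(lams))
        w = np.clip(mu * (1 - mu), 1e-10, None)
        A = X.T @ (X * w[:, None]) + S_used
        Ainv = np.linalg.inv(A)
        F = Ainv @ (X.T @ (X * w[:, None]))
        edf = float(np.trace(F))
        dev = _binomial_deviance(y, mu)
        gcv = n * dev / max(n - edf, 1e-6) ** 2
        return dict(lams=list(lams), beta=beta, mu=mu, S=S_used, Ainv=Ainv, F=F,
                    edf=edf, dev=dev, gcv=gcv, trace=trace, sep=sep)

    grid = [spec.fixed_lambda] if spec.fixed_lambda is not None else list(spec.lambda_grid)
    best = None
    for lam in grid:  # stage 1: one shared multiplier
        try:
            cand = fit_at([float(lam)] * n_terms)
        except GamConvergenceError:
            continue
        if best is None or cand["gcv"] < best["gcv"]:
            best = cand
    if best is None:
        raise GamConvergenceError("no smoothing value converged", [])


    p_bar = y.mean()
    null_dev = _binomial_deviance(y, np.full(n, p_bar if 0 < p_bar < 1 else np.clip(p_bar, 1e-12, 1 - 1e-12)))

    rows_out = []
    for tb, sl in zip(bases, slices):
        edf_k = float(np.trace(best["F"][sl, sl]))
        beta_k = best["beta"][sl]
        V_k = best["Ainv"][sl, sl]
        stat = float(beta_k @ np.linalg.pinv(V_k, rcond=1e-10) @ beta_k)
        df_k = max(round(edf_k), 1)
        rows_out.append({
            "term": tb.term.label, "edf": edf_k, "chi_sq": stat,
            "p_value": float(stats.chi2.sf(stat, df_k)),
        })
    table = pd.DataFrame(rows_out, columns=["term", "edf", "chi_sq", "p_value"])

    return GamFit(
        spec, bases, best["beta"], best["Ainv"], slices, best["lams"], n,
        best["dev"], null_dev, best["mu"], best["edf"], table, best["gcv"],
        best["sep"], best["trace"],
    )


def partial_effect(fit: GamFit, var: str, values: np.ndarray) -> pd.DataFrame:
    """Centered smooth effect of one univariate term on the logit scale.

    Returns columns ``value, effect, se, lower, upper`` with a pointwise
    +-2 SE band from the penalized posterior covariance.
    """
    for tb, sl in zip(fit.bases, fit.term_slices):
        if tb.term.variables == (var,):
            values = np.atleast_1d(np.asarray(values, dtype=float))
            B = tb.design({var: values})
            eff = B @ fit.coef[sl]
            se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", B, fit.cov[sl, sl], B), 0.0))
            return pd.DataFrame({
                "value": values, "effect": eff, "se": se,
                "lower": eff - 2 * se, "upper": eff + 2 * se,
            })
    raise KeyError(f"no univariate smooth for variable '{var}' in the model")


def screen_collinear_predictors(
    rows: pd.DataFrame,
    candidates: list[str],
    response: str = "fate",
    r_threshold: float = 0.95,
) -> tuple[list[str], list[dict]]:
    """Drop one member of each highly correlated predictor pair.

    For each pair with Pearson |r| above the threshold, single-smooth models
    are fit for both members and the one with the worse fit (lower adjusted
    R-squared; AIC as tiebreaker) is excluded.  Constant predictors are
    excluded outright.  The log records r, its p-value and both criteria.
    """
    if len(candidates) < 2:
        raise ValueError("need at least 2 candidate predictors")
    if len(rows) < 3:
        raise ValueError("need at least 3 rows")
    log: list[dict] = []
    retained = []
    for v in candidates:
        if rows[v].std() == 0:
            log.append({"dropped": v, "reason": "zero variance"})
        else:
            retained.append(v)

    def single_fit(v: str) -> GamFit:
        return fit_gam(rows, GamSpec([SmoothTerm((v,), 10)]), response)

    fits: dict[str, GamFit] = {}
    pairs = []
    for i in range(len(retained)):
        for j in range(i + 1, len(retained)):
            r, p = stats.pearsonr(rows[retained[i]], rows[retained[j]])
            pairs.append((abs(r), r, p, retained[i], retained[j]))
    pairs.sort(key=lambda t: -t[0])
    alive = set(retained)
    for abs_r, r, p, a, b in pairs:
        if abs_r <= r_threshold or a not in alive or b not in alive:
            continue
        for v in (a, b):
            if v not in fits:
                fits[v] = single_fit(v)
        crit = {}
        for v in (a, b):
            crit[v] = (fits[v].adjusted_r2, -fits[v].aic)
        loser = a if crit[a] < crit[b] else b
        winner = b if loser == a else a
        alive.discard(loser)
        log.append({
            "dropped": loser, "kept": winner, "r": float(r), "p": float(p),
            f"adj_r2_{a}": fits[a].adjusted_r2, f"adj_r2_{b}": fits[b].adjusted_r2,
            f"aic_{a}": fits[a].aic, f"aic_{b}": fits[b].aic,
            "reason": "collinear",
        })
    return [v for v in retained if v in alive], log
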