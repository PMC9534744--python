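"""Maximum-entropy presence/background extinction-risk model.

An L1-regularized Gibbs distribution over background cells whose feature
expectations match the presence means: maximize

    (1/m) sum_i lambda . f(x_i)  -  log Z_bg(lambda)  -  sum_j beta_j |lambda_j|

where Z_bg = sum over background of exp(lambda . f) and
beta_j = reg_multiplier * s_j / sqrt(m) with s_j the background standard
deviation of feature j and m the presence count.  Features per variable are
linear, quadratic and hinge (knots at background deciles), each scaled to
[0, 1] over the background.

Fitting is cyclic coordinate-wise proximal Newton with backtracking, which
both converges on this convex objective and yields the path-dependent
per-variable training-gain bookkeeping behind "percent contribution".
The raw output q(x) = exp(lambda.f(x)) / Z sums to 1 over background; the
logistic output is p = q e^H / (1 + q e^H) with H the entropy of q.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import rankdata

from .grids import GridSpec
from .io import CovariateStack

__all__ = [
    "FeatureSet",
    "SdmModel",
    "ReplicateResult",
    "ConvergenceError",
    "sample_background",
    "fit_maxent",
    "prescreen_variables",
    "correlation_filter",
    "replicate_fit",
    "permutation_importance",
    "auc",
]


class ConvergenceError(RuntimeError):
    def __init__(self, message: str, trace: list[float]):
        super().__init__(message)
        self.trace = trace


def auc(pos_scores, neg_scores) -> float:
    """Mann-Whitney AUC: P(pos > neg) + 0.5 P(tie), computed exactly."""
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("auc requires nonempty score sets")
    ranks = rankdata(np.concatenate([pos, neg]))
    r_pos = ranks[: len(pos)].sum()
    return float((r_pos - len(pos) * (len(pos) + 1) / 2.0) / (len(pos) * len(neg)))


@dataclass
class FeatureSet:
    """Linear + quadratic + hinge feature expansion, scaled over background."""

    variables: list[str]
    mins: dict[str, float]
    maxs: dict[str, float]
    knots: dict[str, np.ndarray]
    feature_names: list[str] = field(default_factory=list)
    feature_var: np.ndarray | None = None  # index into `variables` per feature

    @classmethod
    def from_background(cls, background: pd.DataFrame, n_hinge_knots: int = 9) -> "FeatureSet":
        """Build feature definitions from the background sample.

        Hinge knots sit at the interior empirical deciles (for the default
        9 knots: the 10%..90% quantiles), deduplicated and kept strictly
        below the variable maximum.
        """
        variables = list(background.columns)
        mins, maxs, knots = {}, {}, {}
        for v in variables:
            col = background[v].to_numpy(dtype=float)
            mins[v], maxs[v] = float(col.min()), float(col.max())
            qs = np.quantile(col, np.linspace(0, 1, n_hinge_knots + 2)[1:-1])
            qs = np.unique(qs)
            knots[v] = qs[qs < maxs[v]]
        fs = cls(variables, mins, maxs, knots)
        names, owner = [], []
        for i, v in enumerate(variables):
            names += [f"{v}:linear", f"{v}:quadratic"]
            owner += [i, i]
            for k in fs.knots[v]:
                names.append(f"{v}:hinge@{k:.6g}")
                owner.append(i)
        fs.feature_names = names
        fs.feature_var = np.asarray(owner)
        return fs

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    def transform(self, env: pd.DataFrame) -> np.ndarray:
        """(n, n_features) matrix; values clamped to the background range."""
        cols = []
        for v in self.variables:
            x = env[v].to_numpy(dtype=float)
            lo, hi = self.mins[v], self.maxs[v]
            span = (hi - lo) or 1.0
            z = np.clip((x - lo) / span, 0.0, 1.0)
            cols.append(z)
            cols.append(z * z)
            for k in self.knots[v]:
                kz = (k - lo) / span
                cols.append(np.clip((z - kz) / (1.0 - kz), 0.0, 1.0))
        return np.column_stack(cols)


@dataclass
class SdmModel:
    """Fitted maximum-entropy model with its diagnostics."""

    features: FeatureSet
    lam: np.ndarray  # feature weights
    betas: np.ndarray  # per-feature L1 penalties
    log_z: float  # log sum over background of exp(lam.f)
    entropy: float  # H of the background Gibbs distribution
    gains: np.ndarray  # per-variable accumulated training gain
    objective_trace: list[float] = field(default_factory=list)

    def raw(self, env: pd.DataFrame | np.ndarray) -> np.ndarray:
        f = env if isinstance(env, np.ndarray) else self.features.transform(env)
        return np.exp(f @ self.lam - self.log_z)

    def logistic(self, env: pd.DataFrame | np.ndarray) -> np.ndarray:
        q = self.raw(env)
        qe = q * np.exp(self.entropy)
        return qe / (1.0 + qe)

    def percent_contribution(self) -> dict[str, float]:
        """Share of training-gain improvement per variable, summing to 100."""
        g = np.maximum(self.gains, 0.0)
        tot = g.sum()
        if tot <= 0:
            return {v: 0.0 for v in self.features.variables}
        return {v: float(100.0 * g[i] / tot) for i, v in enumerate(self.features.variables)}


def sample_background(
    stack: CovariateStack,
    n: int,
    rng: np.random.Generator,
    variables: list[str] | None = None,
    slice_index: int = 0,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Uniform sample of valid cells without replacement (all cells if n is larger)."""
    cells = stack.valid_cell_ids()
    if len(cells) == 0:
        raise ValueError("no valid cells to sample background from")
    if n < len(cells):
        cells = np.sort(rng.choice(cells, size=n, replace=False))
    return cells, stack.env_matrix(cells, variables, slice_index)


def fit_maxent(
    presence_f: np.ndarray,
    background_f: np.ndarray,
    features: FeatureSet,
    reg_multiplier: float = 1.0,
    tol: float = 1e-6,
    max_cycles: int = 2000,
    weight_bound: float = 200.0,
) -> SdmModel:
    """Fit the L1-penalized Gibbs model by coordinate-wise prox-Newton.

    Convergence is declared at KKT stationarity of the penalized objective:
    every feature's presence mean matches its model background expectation
    to within its penalty beta_j (active features at equality).  Weights are
    bounded at +-``weight_bound``: with separable data the penalized
    objective has no finite maximizer (the presence mean of a feature can
    exceed any achievable background expectation), so features pinned at the
    bound are exempt from the stationarity check.
    """
    if not (np.isfinite(presence_f).all() and np.isfinite(background_f).all()):
        raise ValueError("non-finite feature values")
    m, p = presence_f.shape
    pbar = presence_f.mean(axis=0)
    s = background_f.std(axis=0)
    betas = reg_multiplier * np.maximum(s, 1e-4) / np.sqrt(max(m, 1))

    lam = np.zeros(p)
    u = np.zeros(background_f.shape[0])  # background linear predictor
    gains = np.zeros(len(features.variables))
    trace: list[float] = []

    def lse(vec):
        return float(logsumexp(vec))

    cur_lse = lse(u)

    def objective(lam_, lse_):
        return float(pbar @ lam_ - lse_ - betas @ np.abs(lam_))

    trace.append(objective(lam, cur_lse))
    order = np.arange(p)
    for cycle in range(max_cycles):
        w = np.exp(u - u.max())
        w /= w.sum()
        max_delta = 0.0
        for j in order:
            fj = background_f[:, j]
            ef = float(w @ fj)
            g = pbar[j] - ef
            h = max(float(w @ (fj * fj)) - ef * ef, 1e-12)
            z = lam[j] * h + g
            target = np.sign(z) * max(abs(z) - betas[j], 0.0) / h
            target = float(np.clip(target, -weight_bound, weight_bound))
            delta = target - lam[j]
            if delta == 0.0:
                continue
            # backtrack on the true penalized objective; tolerate rounding
            # noise near the optimum so progress does not stall
            base_pen = betas[j] * abs(lam[j])
            for _ in range(40):
                new_lse = lse(u + delta * fj)
                gain = (
                    pbar[j] * delta - (new_lse - cur_lse)
                    - betas[j] * abs(lam[j] + delta) + base_pen
                )
                if gain >= -1e-13 or abs(delta) < 1e-15:
                    break
                delta *= 0.5
            else:
                continue
            if gain < -1e-13:
                continue
            lam[j] += delta
            u += delta * fj
            cur_lse = new_lse
            gains[features.feature_var[j]] += max(gain, 0.0)
            max_delta = max(max_delta, abs(delta))
            # refresh weights after a move so gradients stay current
            w = np.exp(u - u.max())
            w /= w.sum()
        trace.append(objective(lam, cur_lse))
        # KKT stationarity check
        ef_all = w @ background_f
        g_all = pbar - ef_all
        viol = np.where(
            lam == 0.0,
            np.maximum(np.abs(g_all) - betas, 0.0),
            np.abs(g_all - betas * np.sign(lam)),
        )
        viol[np.abs(lam) >= weight_bound] = 0.0  # pinned by the bound
        if viol.max() < tol:
            break
        if viol.max() < 1e-3:
            # near the optimum coordinate descent zigzags on correlated
            # hinge features; a joint Newton step on the active set
            # (nonzero weights, fixed signs) finishes the job
            for _ in range(50):
                active = np.flatnonzero((lam != 0.0) & (np.abs(lam) < weight_bound))
                if len(active) == 0:
                    break
                w = np.exp(u - u.max())
                w /= w.sum()
                fa = background_f[:, active]
                ef = w @ fa
                resid = pbar[active] - ef - betas[active] * np.sign(lam[active])
                if np.abs(resid).max() < 0.5 * tol:
                    break
                cov = (fa * w[:, None]).T @ fa - np.outer(ef, ef)
                step = np.linalg.solve(cov + 1e-10 * np.eye(len(active)), resid)
                # backtrack on the objective; zero out sign flips
                old_obj = objective(lam, cur_lse)
                scale = 1.0
                for _ in range(30):
                    cand = lam.copy()
                    cand[active] = lam[active] + scale * step
                    flipped = cand[active] * lam[active] < 0
                    cand[active[flipped]] = 0.0
                    u_cand = background_f @ cand
                    lse_cand = lse(u_cand)
                    if objective(cand, lse_cand) >= old_obj - 1e-13:
                        lam, u, cur_lse = cand, u_cand, lse_cand
                        break
                    scale *= 0.5
                else:
                    break
            w = np.exp(u - u.max())
            w /= w.sum()
            g_all = pbar - w @ background_f
            viol = np.where(
                lam == 0.0,
                np.maximum(np.abs(g_all) - betas, 0.0),
                np.abs(g_all - betas * np.sign(lam)),
            )
            viol[np.abs(lam) >= weight_bound] = 0.0
            if viol.max() < tol:
                break
    else:
        raise ConvergenceError(
            f"coordinate descent did not reach KKT tolerance {tol} in {max_cycles} cycles "
            f"(max violation {viol.max():.3g})",
            trace,
        )

    log_z = cur_lse
    q = np.exp(u - log_z)
    entropy = float(-(q * np.log(np.maximum(q, 1e-300))).sum())
    return SdmModel(features, lam, betas, log_z, entropy, gains, trace)


def permutation_importance(
    model: SdmModel,
    presence_env: pd.DataFrame,
    background_env: pd.DataFrame,
    rng: np.random.Generator,
) -> dict[str, float]:
    """Normalized training-AUC drop after permuting each variable's raw values.

    The variable's column is permuted jointly across presence + background,
    features are rebuilt with the fitted definitions, and the drop in
    training AUC is recorded; negative drops floor at 0 before normalizing
    to percentages.
    """
    base_auc = auc(
        model.raw(presence_env), model.raw(background_env)
    )
    n_pres = len(presence_env)
    combined = pd.concat([presence_env, background_env], ignore_index=True)
    drops = {}
    for v in model.features.variables:
        perm = combined.copy()
        perm[v] = rng.permutation(perm[v].to_numpy())
        scores = model.raw(perm)
        drops[v] = max(base_auc - auc(scores[:n_pres], scores[n_pres:]), 0.0)
    total = sum(drops.values())
    if total <= 0:
        return {v: 0.0 for v in drops}
    return {v: 100.0 * d / total for v, d in drops.items()}


def prescreen_variables(
    presence_env: pd.DataFrame,
    background_env: pd.DataFrame,
    n_runs: int = 25,
    reg_multiplier: float = 1.0,
    train_fraction: float = 0.75,
    rng: np.random.Generator | None = None,
) -> tuple[list[str], pd.DataFrame]:
    """Drop variables with 0% contribution AND 0 permutation importance in all runs.

    Each run fits on a random presence subsample (the pre-experiment
    protocol); the rule is literal: a variable survives if any run gives it
    a nonzero contribution or importance.
    """
    rng = rng or np.random.default_rng()
    variables = list(presence_env.columns)
    ever_nonzero = {v: False for v in variables}
    log = []
    for run in range(n_runs):
        idx = rng.permutation(len(presence_env))
        take = max(int(round(train_fraction * len(presence_env))), 1)
        pres = presence_env.iloc[idx[:take]]
        fs = FeatureSet.from_background(background_env)
        model = fit_maxent(fs.transform(pres), fs.transform(background_env), fs, reg_multiplier)
        contrib = model.percent_contribution()
        imp = permutation_importance(model, pres, background_env, rng)
        for v in variables:
            if contrib[v] > 0.0 or imp[v] > 0.0:
                ever_nonzero[v] = True
        log.append({"run": run, **{f"contrib_{v}": contrib[v] for v in variables}})
    retained = [v for v in variables if ever_nonzero[v]]
    if not retained:
        raise ValueError("prescreening dropped every variable")
    return retained, pd.DataFrame(log)


def correlation_filter(
    env: pd.DataFrame, contributions: dict[str, float], r_threshold: float = 0.7
) -> tuple[list[str], list[dict]]:
    """Resolve collinear pairs: for |r| > threshold keep the higher contribution.

    Pairs are visited by descending |Pearson r|; a drop only happens when
    both members are still retained.  Deterministic.
    """
    variables = list(env.columns)
    corr = env.corr().to_numpy()
    pairs = []
    for i in range(len(variables)):
        for j in range(i + 1, len(variables)):
            pairs.append((abs(corr[i, j]), i, j))
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
    retained = set(variables)
    dropped_log = []
    for r, i, j in pairs:
        a, b = variables[i], variables[j]
        if r <= r_threshold or a not in retained or b not in retained:
            continue
        loser = b if contributions.get(a, 0.0) >= contributions.get(b, 0.0) else a
        winner = a if loser == b else b
        retained.discard(loser)
        dropped_log.append({"dropped": loser, "kept": winner, "r": float(r)})
    return [v for v in variables if v in retained], dropped_log


@dataclass
class ReplicateResult:
    """Aggregate of replicated fits plus the averaged risk surface."""

    mean_auc: float
    sd_auc: float
    test_aucs: list[float]
    mean_contributions: dict[str, float]
    mean_importance: dict[str, float]
    surface: np.ndarray  # (n_y, n_x) mean logistic output, NaN off-domain
    models: list[SdmModel] = field(default_factory=list)


def replicate_fit(
    presence_env: pd.DataFrame,
    background_env: pd.DataFrame,
    stack: CovariateStack,
    variables: list[str],
    replicates: int = 100,
    test_fraction: float = 0.25,
    reg_multiplier: float = 1.0,
    rng: np.random.Generator | None = None,
    slice_index: int = 0,
    keep_models: bool = False,
) -> ReplicateResult:
    """Replicated subsample fits; mean/SD of test AUC and mean logistic surface.

    Per replicate the presences are split (1 - test_fraction) train /
    test_fraction test; the model is fit on the training split and evaluated
    by test AUC against the background; the logistic surface over all valid
    cells is averaged across replicates.
    """
    rng = rng or np.random.default_rng()
    m = len(presence_env)
    n_test = int(round(test_fraction * m))
    if replicates > 1 and n_test == 0:
        raise ValueError("test split is empty; reduce replicates or supply more presences")
    pres = presence_env[variables]
    bg = background_env[variables]
    grid: GridSpec = stack.grid
    cells = stack.valid_cell_ids()
    cell_env = stack.env_matrix(cells, variables, slice_index)

    aucs, contribs, imps = [], [], []
    surface_sum = np.zeros(len(cells))
    models = []
    for _ in range(replicates):
        idx = rng.permutation(m)
        test_idx, train_idx = idx[:n_test], idx[n_test:]
        if len(train_idx) == 0:
            raise ValueError("training split is empty")
        fs = FeatureSet.from_background(bg)
        model = fit_maxent(fs.transform(pres.iloc[train_idx]), fs.transform(bg), fs, reg_multiplier)
        test = pres.iloc[test_idx] if n_test else pres.iloc[train_idx]
        aucs.append(auc(model.raw(test), model.raw(bg)))
        contribs.append(model.percent_contribution())
        imps.append(permutation_importance(model, pres.iloc[train_idx], bg, rng))
        surface_sum += model.logistic(cell_env)
        if keep_models:
            models.append(model)

    surface = np.full((grid.n_y, grid.n_x), np.nan)
    surface[cells // grid.n_x, cells % grid.n_x] = surface_sum / replicates
    mean_c = {v: float(np.mean([c[v] for c in contribs])) for v in variables}
    mean_i = {v: float(np.mean([c[v] for c in imps])) for v in variables}
    return ReplicateResult(
        float(np.mean(aucs)), float(np.std(aucs)), [float(a) for a in aucs],
        mean_c, mean_i, surface, models,
    )
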