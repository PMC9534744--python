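"""Risk-surface thresholding and classification.

Converts a continuous extinction-risk surface into management categories:
the maximum training sensitivity-plus-specificity (max SSS) threshold
separates "no risk" sites from at-risk sites, and Fisher-Jenks natural
breaks partition the at-risk probabilities into low / moderate / high
levels.  "Notable" risk is moderate + high.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .grids import GridSpec, OutOfDomainError

__all__ = [
    "ThresholdResult",
    "RiskClasses",
    "max_sss_threshold",
    "jenks_breaks",
    "classify_sites",
    "report_accounting",
    "round_half_up",
]

AT_RISK_LABELS = ["low", "moderate", "high"]


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding (0.125 -> 0.13), as used for reported shares."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ThresholdResult:
    threshold: float
    sensitivity: float
    specificity: float


def max_sss_threshold(presence_scores, background_scores) -> ThresholdResult:
    """Threshold maximizing sensitivity + specificity.

    Candidates are the distinct observed scores (both sets pooled);
    sensitivity = fraction of presences with score >= t, specificity =
    fraction of background with score < t.  Ties on the sum resolve to the
    smallest threshold.
    """
    pos = np.asarray(presence_scores, dtype=float)
    neg = np.asarray(background_scores, dtype=float)
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("max_sss_threshold requires nonempty score sets")
    cand = np.unique(np.concatenate([pos, neg]))
    sens = (pos[None, :] >= cand[:, None]).mean(axis=1)
    spec = (neg[None, :] < cand[:, None]).mean(axis=1)
    total = sens + spec
    # smallest threshold within rounding error of the maximum
    best = int(np.flatnonzero(total >= total.max() - 1e-12)[0])
    return ThresholdResult(float(cand[best]), float(sens[best]), float(spec[best]))


def jenks_breaks(values, k: int) -> list[float]:
    """Fisher-Jenks natural breaks: optimal 1-D classification into k classes.

    Dynamic program minimizing the total within-class sum of squared
    deviations over all partitions of the sorted values into k contiguous
    classes.  Returns the k class maxima (ascending); the last break is
    max(values).  Deterministic; ties broken toward the smallest boundary
    index.
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = len(x)
    if not 1 <= k <= n:
        raise ValueError(f"need 1 <= k <= n, got k={k}, n={n}")
    # prefix sums for O(1) within-class SSD of x[i:j]
    cs = np.concatenate([[0.0], np.cumsum(x)])
    cs2 = np.concatenate([[0.0], np.cumsum(x * x)])

    def ssd(i: int, j: int) -> float:  # class x[i:j], j exclusive
        m = j - i
        s = cs[j] - cs[i]
        return max((cs2[j] - cs2[i]) - s * s / m, 0.0)

    cost = np.full((k + 1, n + 1), np.inf)
    split = np.zeros((k + 1, n + 1), dtype=int)
    cost[0, 0] = 0.0
    for c in range(1, k + 1):
        for j in range(c, n + 1):
            best, best_i = np.inf, c - 1
            for i in range(c - 1, j):
                v = cost[c - 1, i] + ssd(i, j)
                if v < best - 1e-15:  # strict improvement keeps smallest boundary
                    best, best_i = v, i
            cost[c, j] = best
            split[c, j] = best_i
    # recover class boundaries
    bounds = [n]
    j = n
    for c in range(k, 0, -1):
        j = split[c, j]
        bounds.append(j)
    bounds.reverse()  # [0, ..., n]
    return [float(x[b - 1]) for b in bounds[1:]]


@dataclass
class RiskClasses:
    """Per-site risk classes with counts, shares and regional tallies."""

    threshold: float
    breaks: list[float]
    sites: pd.DataFrame  # columns: site index, risk, risk_class
    counts: dict[str, int] = field(default_factory=dict)
    percentages: dict[str, float] = field(default_factory=dict)
    notable_percentage: float = 0.0
    regional: pd.DataFrame | None = None
    n_excluded: int = 0

    def to_report(self) -> dict:
        rep = {
            "threshold": self.threshold,
            "breaks": self.breaks,
            "counts": self.counts,
            "percentages": self.percentages,
            "notable_percentage": self.notable_percentage,
            "n_excluded": self.n_excluded,
        }
        if self.regional is not None:
            rep["regional"] = self.regional.to_dict(orient="records")
        return rep


def classify_sites(
    surface: np.ndarray,
    grid: GridSpec,
    sites: pd.DataFrame,
    threshold: float,
    k: int = 3,
    region_col: str | None = None,
) -> RiskClasses:
    """Classify extant sites by the risk surface value at their cell.

    Sites with risk below ``threshold`` are "none"; Fisher-Jenks with ``k``
    classes on the remaining risks defines the at-risk levels (labelled from
    ``low`` up).  Sites outside the surface domain or on nodata cells are
    excluded from all denominators (counted in ``n_excluded``).
    """
    lon = sites["lon"].to_numpy(dtype=float)
    lat = sites["lat"].to_numpy(dtype=float)
    risk = np.full(len(sites), np.nan)
    for i in range(len(sites)):
        try:
            ix, iy = grid.assign_xy(lon[i], lat[i])
            risk[i] = surface[int(iy), int(ix)]
        except OutOfDomainError:
            pass
    ok = np.isfinite(risk)
    n_excluded = int((~ok).sum())
    df = sites.loc[ok].copy()
    df["risk"] = risk[ok]

    if k > len(AT_RISK_LABELS):
        raise ValueError(f"k must be <= {len(AT_RISK_LABELS)} for labelled classes")
    labels = np.full(len(df), "none", dtype=object)
    at_risk = df["risk"].to_numpy() >= threshold
    breaks: list[float] = []
    if at_risk.any():
        vals = df["risk"].to_numpy()[at_risk]
        k_eff = min(k, len(np.unique(vals)))
        breaks = jenks_breaks(vals, k_eff)
        cls = np.searchsorted(np.asarray(breaks[:-1]), vals, side="left")
        labels[at_risk] = np.asarray(AT_RISK_LABELS[:k_eff], dtype=object)[cls]
    df["risk_class"] = labels

    all_labels = ["none"] + AT_RISK_LABELS
    counts = {c: int((labels == c).sum()) for c in all_labels}
    total = len(df)
    percentages = {
        c: round_half_up(100.0 * counts[c] / total) if total else 0.0 for c in all_labels
    }
    notable = round_half_up(
        100.0 * (counts["moderate"] + counts["high"]) / total
    ) if total else 0.0

    regional = None
    if region_col is not None and region_col in df.columns:
        regional = (
            df.groupby([region_col, "risk_class"], observed=True).size()
            .rename("count").reset_index()
        )
    return RiskClasses(float(threshold), breaks, df.reset_index(drop=True),
                       counts, percentages, notable, regional, n_excluded)


def report_accounting(parts: dict[str, float], total: float | None = None) -> dict:
    """Bin sums and percentage shares, rounded half-up to 2 decimals.

    With ``total`` omitted it is the sum of the parts.  Shares are
    100 * part / total.  A zero total with nonzero parts is an error.
    """
    values = {k: float(v) for k, v in parts.items()}
    if any(v < 0 for v in values.values()):
        raise ValueError("bins must be nonnegative")
    tot = float(sum(values.values())) if total is None else float(total)
    if tot == 0 and any(v != 0 for v in values.values()):
        raise ValueError("zero total with nonzero parts")
    shares = {k: round_half_up(100.0 * v / tot) if tot else 0.0 for k, v in values.items()}
    return {"parts": values, "total": round_half_up(tot), "shares_pct": shares}
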