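"""Small-cohort nonparametric statistics.

Group summaries (mean, sample SD), tie-corrected Kruskal-Wallis with the
chi-square approximation, *exact* two-sided Mann-Whitney by enumeration at
small n, Spearman rank correlation, and the effective-dose helper.  All
tests are two-sided; no multiple-testing adjustment is applied, matching
common practice for exploratory pilot cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
from scipy import stats as sps

from .core import ValidationError

__all__ = [
    "GroupSummary",
    "TestResult",
    "summarize_group",
    "kruskal_wallis",
    "mann_whitney_exact",
    "spearman",
    "effective_dose",
]

#: above this pooled size Mann-Whitney switches to the normal approximation
EXACT_ENUMERATION_MAX_N = 16


@dataclass(frozen=True)
class GroupSummary:
    label: str
    n: int
    mean: float
    sd: float | None  # None for n < 2


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    tie_correction: bool = False
    sidedness: str = "two-sided"
    note: str = ""

    def __post_init__(self):
        if not (np.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValidationError("p-value outside [0, 1]")


def summarize_group(values, label: str = "") -> GroupSummary:
    """Arithmetic mean and sample SD (n-1 denominator)."""
    v = np.asarray(values, dtype=float)
    if v.size < 1:
        raise ValidationError("summarize_group needs at least one value")
    sd = float(np.std(v, ddof=1)) if v.size >= 2 else None
    return GroupSummary(label=label, n=int(v.size), mean=float(np.mean(v)), sd=sd)


def kruskal_wallis(groups: list) -> TestResult:
    """Kruskal-Wallis H with mid-rank ties, tie correction, chi-square p.

    H = 12/(N(N+1)) * sum R_i^2/n_i - 3(N+1), divided by
    1 - sum(t^3 - t)/(N^3 - N); p from the upper chi-square tail with
    (groups - 1) degrees of freedom.
    """
    if len(groups) < 2 or any(len(g) < 1 for g in groups):
        raise ValidationError("need >= 2 non-empty groups")
    pooled = np.concatenate([np.asarray(g, float) for g in groups])
    if pooled.size < 3:
        raise ValidationError("need at least 3 observations in total")
    if np.all(pooled == pooled[0]):
        return TestResult(0.0, 1.0, "kruskal-wallis", tie_correction=True,
                          note="degenerate: all observations identical")
    h, p = sps.kruskal(*groups)
    return TestResult(float(h), float(p), "kruskal-wallis", tie_correction=True)


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U for x: number of (x_i, y_j) pairs with x_i > y_j, ties counting 1/2."""
    gt = np.sum(x[:, None] > y[None, :])
    eq = np.sum(x[:, None] == y[None, :])
    return float(gt) + 0.5 * float(eq)


def mann_whitney_exact(x, y, sidedness: str = "two-sided") -> TestResult:
    """Mann-Whitney U; exact by enumeration when n_x + n_y <= 16.

    The exact two-sided p is P(|U - mu_U| >= |u_obs - mu_U|) over all
    C(n_x+n_y, n_x) equally likely group assignments of the pooled values
    (ties kept as observed).  Larger samples fall back to the normal
    approximation with tie-corrected variance (no continuity correction).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 1 or y.size < 1:
        raise ValidationError("both samples must be non-empty")
    nx, ny = x.size, y.size
    u_obs = _u_statistic(x, y)
    mu = nx * ny / 2.0

    if nx + ny <= EXACT_ENUMERATION_MAX_N:
        pooled = np.concatenate([x, y])
        total = comb(nx + ny, nx)
        hits = 0
        obs_dev = abs(u_obs - mu) - 1e-9
        for idx in combinations(range(nx + ny), nx):
            xs = pooled[list(idx)]
            mask = np.ones(nx + ny, bool)
            mask[list(idx)] = False
            u = _u_statistic(xs, pooled[mask])
            if sidedness == "two-sided":
                if abs(u - mu) >= obs_dev:
                    hits += 1
            elif sidedness == "greater":
                if u >= u_obs - 1e-9:
                    hits += 1
            else:
                if u <= u_obs + 1e-9:
                    hits += 1
        return TestResult(u_obs, hits / total, "mann-whitney-exact",
                          tie_correction=True, sidedness=sidedness)

    # tie-corrected normal approximation
    pooled = np.concatenate([x, y])
    n = nx + ny
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts ** 3 - counts) / (n * (n - 1))
    var = nx * ny / 12.0 * (n + 1 - tie_term)
    if var == 0:
        return TestResult(u_obs, 1.0, "mann-whitney-normal",
                          note="degenerate: zero variance")
    z = (u_obs - mu) / np.sqrt(var)
    if sidedness == "two-sided":
        p = 2.0 * sps.norm.sf(abs(z))
    elif sidedness == "greater":
        p = sps.norm.sf(z)
    else:
        p = sps.norm.cdf(z)
    return TestResult(u_obs, float(min(p, 1.0)), "mann-whitney-normal",
                      tie_correction=True, sidedness=sidedness)


def spearman(x, y) -> TestResult:
    """Spearman rank correlation with the two-sided t-approximation p."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 3:
        raise ValidationError("spearman needs >= 3 paired observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return TestResult(np.nan, np.nan, "spearman",
                          note="degenerate: zero rank variance")
    rho, p = sps.spearmanr(x, y)
    return TestResult(float(rho), float(p), "spearman")


def effective_dose(activity_MBq: float, coefficient_uSv_per_MBq: float) -> float:
    """Effective dose in mSv from injected activity and a uSv/MBq coefficient."""
    if activity_MBq < 0 or coefficient_uSv_per_MBq < 0:
        raise ValidationError("inputs must be non-negative")
    return activity_MBq * coefficient_uSv_per_MBq / 1000.0
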