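"""Group descriptive statistics and Mann-Whitney U comparisons.

Alert vs. fatigued segments are compared feature by feature, for the pooled
cohort and separately per sex.  The U test is implemented directly: rank-sum
U with midranks for ties, a tie-corrected normal approximation with
continuity correction for moderate samples, and exact enumeration of all
C(n1+n2, n1) labelings for very small samples (n1 + n2 <= 12).

Segments from overlapping windows are statistically dependent; the tests
are nevertheless applied segment-wise (the study design), without any
multiple-testing correction across the 20 features.  Quartiles use linear
interpolation between order statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .features import FEATURE_NAMES

__all__ = [
    "GroupDescriptives",
    "UTestResult",
    "describe",
    "mann_whitney_u",
    "compare_states",
    "direction_summary",
]

EXACT_MAX_N = 12  # exact-enumeration path when n1 + n2 <= this


@dataclass(frozen=True)
class GroupDescriptives:
    mean: float
    sd: float
    q1: float
    median: float
    q3: float
    n: int


@dataclass(frozen=True)
class UTestResult:
    """Two-sided Mann-Whitney comparison of y (fatigued) against x (alert).

    ``direction`` reports the median shift of y relative to x when the test
    is significant at the supplied alpha, else 'none'.
    """

    U: float
    z: float
    p_two_sided: float
    tie_corrected: bool
    exact: bool
    direction: str


def describe(values) -> GroupDescriptives:
    """Mean, sample SD, quartiles (linear interpolation), and n."""
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size == 0:
        raise ValueError("cannot describe an empty sample")
    sd = float(np.std(x, ddof=1)) if x.size > 1 else 0.0
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return GroupDescriptives(
        mean=float(np.mean(x)), sd=sd, q1=float(q1), median=float(med),
        q3=float(q3), n=int(x.size),
    )


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U for sample x via midranks of the pooled data."""
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    r1 = ranks[: x.size].sum()
    return float(r1 - x.size * (x.size + 1) / 2)


def _exact_p(x: np.ndarray, y: np.ndarray, u_obs: float) -> float:
    """Two-sided exact p by enumerating all C(n, n1) group assignments of the
    pooled (midrank) values; ties handled naturally through the ranks."""
    n1, n = x.size, x.size + y.size
    ranks = rankdata(np.concatenate([x, y]))
    offset = n1 * (n1 + 1) / 2
    us = np.fromiter(
        (ranks[list(idx)].sum() - offset for idx in combinations(range(n), n1)),
        dtype=float,
        count=comb(n, n1),
    )
    mean_u = n1 * (n - n1) / 2
    dev = abs(u_obs - mean_u)
    p = np.mean(np.abs(us - mean_u) >= dev - 1e-12)
    return float(min(1.0, p))


def mann_whitney_u(x, y, alpha: float = 0.01) -> UTestResult:
    """Two-sided Mann-Whitney U test of x (alert) vs y (fatigued).

    Uses exact enumeration when n1 + n2 <= 12, otherwise the tie-corrected
    normal approximation with continuity correction.  Two samples with zero
    pooled variance give p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x, y = x[np.isfinite(x)], y[np.isfinite(y)]
    n1, n2 = x.size, y.size
    if n1 < 1 or n2 < 1:
        raise ValueError("both samples must be non-empty")
    u = _u_statistic(x, y)
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        return UTestResult(U=u, z=0.0, p_two_sided=1.0, tie_corrected=True,
                           exact=False, direction="none")

    _, tie_counts = np.unique(pooled, return_counts=True)
    has_ties = bool(np.any(tie_counts > 1))
    n = n1 + n2
    if n <= EXACT_MAX_N:
        p = _exact_p(x, y, u)
        mean_u = n1 * n2 / 2
        var_u = n1 * n2 * (n + 1) / 12
        z = (u - mean_u) / np.sqrt(var_u) if var_u > 0 else 0.0
        exact = True
    else:
        mean_u = n1 * n2 / 2
        tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (n * (n - 1))
        var_u = n1 * n2 / 12 * ((n + 1) - tie_term)
        if var_u <= 0:
            return UTestResult(U=u, z=0.0, p_two_sided=1.0, tie_corrected=True,
                               exact=False, direction="none")
        cc = 0.5 if u != mean_u else 0.0  # continuity correction toward the mean
        z = (u - mean_u - np.sign(u - mean_u) * cc) / np.sqrt(var_u)
        p = float(min(1.0, 2 * norm.sf(abs(z))))
        exact = False

    direction = "none"
    if p <= alpha:
        med_x, med_y = np.median(x), np.median(y)
        if med_y > med_x:
            direction = "increase"
        elif med_y < med_x:
            direction = "decrease"
    return UTestResult(U=u, z=float(z), p_two_sided=p, tie_corrected=has_ties,
                       exact=exact, direction=direction)


# ---------------------------------------------------------------------------
# per-feature state comparison tables
# ---------------------------------------------------------------------------

_ARROW = {"increase": "↑", "decrease": "↓", "none": "NS"}


def compare_states(
    features: pd.DataFrame,
    group: str = "all",
    alpha: float = 0.01,
    feature_names=FEATURE_NAMES,
) -> pd.DataFrame:
    """Alert-vs-fatigued comparison table for one group.

    ``features`` holds one row per segment with columns ``sex``, ``label``
    and the feature columns.  Returns one row per feature with descriptives
    for both states, the U test, and the direction arrow.
    """
    if group not in ("all", "male", "female"):
        raise ValueError(f"group must be 'all', 'male' or 'female', got {group!r}")
    df = features if group == "all" else features[features["sex"] == group]
    rows = []
    for label in ("alert", "fatigued"):
        if not (df["label"] == label).any():
            raise ValueError(f"no '{label}' segments in group '{group}'")
    alert = df[df["label"] == "alert"]
    fatigued = df[df["label"] == "fatigued"]
    for feat in feature_names:
        da = describe(alert[feat])
        dfat = describe(fatigued[feat])
        res = mann_whitney_u(
            alert[feat].to_numpy(), fatigued[feat].to_numpy(), alpha=alpha
        )
        rows.append({
            "feature": feat,
            "alert_mean": da.mean, "alert_sd": da.sd, "alert_q1": da.q1,
            "alert_median": da.median, "alert_q3": da.q3, "alert_n": da.n,
            "fatigued_mean": dfat.mean, "fatigued_sd": dfat.sd,
            "fatigued_q1": dfat.q1, "fatigued_median": dfat.median,
            "fatigued_q3": dfat.q3, "fatigued_n": dfat.n,
            "U": res.U, "z": res.z, "p": res.p_two_sided,
            "significant": res.p_two_sided <= alpha,
            "direction": res.direction,
            "arrow": _ARROW[res.direction],
        })
    return pd.DataFrame(rows)


def direction_summary(tables: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Cross-group direction-of-change summary (arrow notation per group)."""
    out = None
    for group, table in tables.items():
        col = table[["feature", "arrow"]].rename(columns={"arrow": group})
        out = col if out is None else out.merge(col, on="feature")
    return out
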