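"""Univariate survival statistics: Kaplan–Meier curves, log-rank tests,
single-covariate Cox hazard ratios, median-split screening with
Holm–Bonferroni correction, and the rank/chi-square tests used for
feature–biology comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats as sps

__all__ = [
    "SurvivalRecord",
    "SurvivalCurve",
    "TestResult",
    "kaplan_meier",
    "logrank_test",
    "hazard_ratio",
    "cox_single_covariate",
    "median_split",
    "holm_bonferroni",
    "univariate_screen",
    "wilcoxon_rank_sum",
    "kruskal_wallis",
    "chi_square_2x2",
]


@dataclass(frozen=True)
class SurvivalRecord:
    """Overall survival in days; event = 1 for observed death, 0 censored."""

    time: float
    event: int

    def __post_init__(self) -> None:
        if not (np.isfinite(self.time) and self.time > 0):
            raise ValueError("survival time must be finite and positive")
        if self.event not in (0, 1):
            raise ValueError("event must be 0 or 1")


@dataclass
class SurvivalCurve:
    event_times: np.ndarray
    survival_probs: np.ndarray
    at_risk: np.ndarray
    median_survival: float  # nan when S never reaches 0.5


@dataclass
class TestResult:
    statistic: float
    p_value: float
    p_adjusted: float | None = None
    hr: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    flags: list[str] = field(default_factory=list)


def _to_arrays(records) -> tuple[np.ndarray, np.ndarray]:
    times = np.array([r.time for r in records], dtype=float)
    events = np.array([r.event for r in records], dtype=int)
    return times, events


def kaplan_meier(records: list[SurvivalRecord]) -> SurvivalCurve:
    """Product-limit survival estimate; censored subjects leave the risk set
    after their time."""
    if not records:
        raise ValueError("no survival records")
    times, events = _to_arrays(records)
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    event_times = np.unique(times[events == 1])
    probs = kmf.survival_function_at_times(event_times).to_numpy()
    at_risk = np.array([(times >= t).sum() for t in event_times])
    med = kmf.median_survival_time_
    return SurvivalCurve(
        event_times=event_times,
        survival_probs=probs,
        at_risk=at_risk,
        median_survival=float(med) if np.isfinite(med) else float("nan"),
    )


def logrank_test(
    group_a: list[SurvivalRecord], group_b: list[SurvivalRecord]
) -> TestResult:
    """Two-group log-rank chi-square (1 df), two-sided."""
    if not group_a or not group_b:
        raise ValueError("both groups must be nonempty")
    ta, ea = _to_arrays(group_a)
    tb, eb = _to_arrays(group_b)
    if ea.sum() + eb.sum() == 0:
        raise ValueError("log-rank test undefined: no events in either group")
    res = _ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return TestResult(statistic=float(res.test_statistic), p_value=float(res.p_value))


def cox_single_covariate(
    x: np.ndarray, times: np.ndarray, events: np.ndarray,
    max_iter: int = 50, tol: float = 1e-10,
) -> tuple[float, float, bool]:
    """Maximize the single-covariate Cox partial likelihood (Breslow ties)
    by Newton iteration. Returns (beta_hat, se, converged)."""
    x = np.asarray(x, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    beta = 0.0
    event_times = np.unique(times[events == 1])
    converged = False
    for _ in range(max_iter):
        score = 0.0
        info = 0.0
        for t in event_times:
            at_risk = times >= t
            d_mask = (times == t) & (events == 1)
            d = int(d_mask.sum())
            w = np.exp(beta * x[at_risk])
            sw = w.sum()
            m1 = (w * x[at_risk]).sum() / sw
            m2 = (w * x[at_risk] ** 2).sum() / sw
            score += x[d_mask].sum() - d * m1
            info += d * (m2 - m1**2)
        if info <= 1e-12:
            break  # flat likelihood (e.g. complete separation)
        step = score / info
        beta += step
        if abs(step) < tol:
            converged = True
            break
        if abs(beta) > 20:
            break  # monotone likelihood: estimate diverging
    se = 1.0 / np.sqrt(info) if info > 1e-12 else float("inf")
    return float(beta), float(se), converged


def hazard_ratio(groups: np.ndarray, records: list[SurvivalRecord]) -> TestResult:
    """Hazard ratio of group 1 vs group 0 with a 95% Wald CI, from a
    single-covariate Cox fit. Non-convergence (complete separation) is
    flagged with an infinite confidence bound."""
    groups = np.asarray(groups, dtype=int)
    if set(np.unique(groups)) != {0, 1}:
        raise ValueError("groups must contain both labels 0 and 1")
    times, events = _to_arrays(records)
    if events.sum() == 0:
        raise ValueError("hazard ratio undefined: no events")
    beta, se, converged = cox_single_covariate(groups.astype(float), times, events)
    z = sps.norm.ppf(0.975)
    with np.errstate(over="ignore"):
        hr = float(np.exp(beta))
        ci_low = float(np.exp(beta - z * se))
        ci_high = float(np.exp(beta + z * se))
    wald = beta / se if se > 0 and np.isfinite(se) else 0.0
    p = float(2 * sps.norm.sf(abs(wald)))
    flags = [] if converged else ["nonconverged"]
    return TestResult(
        statistic=float(wald), p_value=p, hr=hr, ci_low=ci_low, ci_high=ci_high,
        flags=flags,
    )


def median_split(values: np.ndarray) -> np.ndarray:
    """Binary labels at the sample median: 1 iff value >= median (ties at
    the median go to the high group)."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 values")
    if np.ptp(values) == 0:
        raise ValueError("degenerate split: all values identical")
    med = float(np.median(values))
    labels = (values >= med).astype(int)
    if labels.all() or not labels.any():
        raise ValueError("degenerate split: one group empty")
    return labels


def holm_bonferroni(pvals) -> np.ndarray:
    """Holm step-down adjusted p-values, returned in input order.

    Sort ascending, multiply the k-th smallest by (m - k), enforce
    monotonicity with a running maximum, cap at 1.
    """
    p = np.asarray(pvals, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 0.0
    for k, idx in enumerate(order):
        running = max(running, (m - k) * p[idx])
        adj[idx] = min(1.0, running)
    return adj


def univariate_screen(
    features: pd.DataFrame, records: list[SurvivalRecord]
) -> pd.DataFrame:
    """Median-split survival screen of every feature column.

    For each feature: split the cohort at its median, log-rank test the two
    groups, estimate the hazard ratio (high vs low), then Holm-adjust the
    log-rank p-values across the whole feature family. Degenerate features
    (constant, or splitting into one group) are flagged and excluded from
    the correction family.
    """
    rows = []
    for name in features.columns:
        vals = features[name].to_numpy(dtype=float)
        try:
            labels = median_split(vals)
            lr = logrank_test(
                [r for r, g in zip(records, labels) if g == 0],
                [r for r, g in zip(records, labels) if g == 1],
            )
            hr = hazard_ratio(labels, records)
            rows.append(
                dict(feature=name, statistic=lr.statistic, p_value=lr.p_value,
                     hr=hr.hr, ci_low=hr.ci_low, ci_high=hr.ci_high,
                     flag="|".join(hr.flags))
            )
        except ValueError as exc:
            rows.append(
                dict(feature=name, statistic=np.nan, p_value=np.nan,
                     hr=np.nan, ci_low=np.nan, ci_high=np.nan, flag=str(exc))
            )
    out = pd.DataFrame(rows).set_index("feature")
    ok = out["p_value"].notna()
    out["p_adjusted"] = np.nan
    if ok.any():
        out.loc[ok, "p_adjusted"] = holm_bonferroni(out.loc[ok, "p_value"].to_numpy())
    return out


def _exact_rank_sum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Exact two-sided rank-sum p by enumerating all group assignments."""
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    n, nx = len(pooled), len(x)
    obs = ranks[:nx].sum()
    mean_stat = nx * (n + 1) / 2.0
    count = 0
    total = 0
    for comb in combinations(range(n), nx):
        stat = ranks[list(comb)].sum()
        total += 1
        if abs(stat - mean_stat) >= abs(obs - mean_stat) - 1e-12:
            count += 1
    return count / total


def wilcoxon_rank_sum(x, y) -> TestResult:
    """Two-sample Wilcoxon rank-sum (Mann–Whitney) test with midranks.

    Exact enumeration when the combined sample size is ≤ 10, normal
    approximation otherwise. All-tied input gives p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        return TestResult(statistic=0.0, p_value=1.0)
    if x.size + y.size <= 10:
        ranks = sps.rankdata(pooled)
        stat = float(ranks[: x.size].sum())
        return TestResult(statistic=stat, p_value=_exact_rank_sum_p(x, y))
    res = sps.mannwhitneyu(
        x, y, alternative="two-sided", method="asymptotic", use_continuity=False
    )
    return TestResult(statistic=float(res.statistic), p_value=float(res.pvalue))


def kruskal_wallis(groups: list) -> TestResult:
    """Kruskal–Wallis H test across k groups (midrank ties)."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValueError("every group must be nonempty")
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        return TestResult(statistic=0.0, p_value=1.0)
    res = sps.kruskal(*arrays)
    return TestResult(statistic=float(res.statistic), p_value=float(res.pvalue))


def chi_square_2x2(table) -> TestResult:
    """Pearson chi-square on a 2×2 count table, 1 df, no continuity
    correction."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a 2x2 table of non-negative counts")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("zero margin in 2x2 table")
    stat, p, _, _ = sps.chi2_contingency(t, correction=False)
    return TestResult(statistic=float(stat), p_value=float(p))
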