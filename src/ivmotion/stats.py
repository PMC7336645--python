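"""Statistical tests used by the imaging analyses, implemented from their
formulas.

Four procedures cover every comparison the pipeline reports: Student's
two-tailed two-sample t test (pooled variance), one-way ANOVA, the
two-sample Kolmogorov-Smirnov test with the classical asymptotic p value,
and the two-group log-rank test with hypergeometric variance.  Only the
reference distribution functions (t, F, chi-square, Kolmogorov) come from
scipy; every statistic is computed here so its definition is explicit and
auditable.

Group summaries are emitted as mean +/- SD and mean +/- SEM, labelled
explicitly, since figure conventions differ between the two.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TestResult",
    "t_test_two_tailed",
    "anova_oneway",
    "ks_two_sample",
    "log_rank",
    "kolmogorov_sf",
    "group_summary",
]


@dataclass(frozen=True)
class TestResult:
    name: str
    statistic: float
    pvalue: float
    df: float | tuple[float, float] | None = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.pvalue <= 1.0:
            raise ValueError("p value out of [0, 1]")

    def to_dict(self) -> dict:
        return {
            "test": self.name,
            "statistic": self.statistic,
            "pvalue": self.pvalue,
            "df": self.df,
            **self.extras,
        }


def _as_sample(x, min_n: int, label: str) -> np.ndarray:
    a = np.asarray(x, dtype=float).ravel()
    if a.size < min_n:
        raise ValueError(f"{label}: need at least {min_n} observations")
    if not np.isfinite(a).all():
        raise ValueError(f"{label}: non-finite values")
    return a


def t_test_two_tailed(a, b) -> TestResult:
    """Student's two-sample t test, pooled variance, two-sided p.

    t = (mean_a - mean_b) / (s_p * sqrt(1/n_a + 1/n_b)) with the pooled
    variance s_p^2 = ((n_a-1) s_a^2 + (n_b-1) s_b^2) / (n_a + n_b - 2) and
    n_a + n_b - 2 degrees of freedom.
    """
    a = _as_sample(a, 2, "group a")
    b = _as_sample(b, 2, "group b")
    na, nb = a.size, b.size
    df = na + nb - 2
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / df
    diff = a.mean() - b.mean()
    if sp2 == 0:
        if diff == 0:
            return TestResult("t (pooled, two-tailed)", 0.0, 1.0, df,
                              {"degenerate": "zero variance, equal means"})
        warnings.warn("zero pooled variance with unequal means; p -> 0")
        return TestResult("t (pooled, two-tailed)", math.inf, 0.0, df,
                          {"degenerate": "zero variance, unequal means"})
    t = diff / math.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    p = 2.0 * float(sps.t.sf(abs(t), df))
    return TestResult("t (pooled, two-tailed)", float(t), min(p, 1.0), df)


def anova_oneway(groups: dict[str, np.ndarray] | list[np.ndarray]) -> TestResult:
    """One-way fixed-effects ANOVA: F = MS_between / MS_within.

    With k groups and N observations total the degrees of freedom are
    (k - 1, N - k).
    """
    if isinstance(groups, dict):
        arrays = [_as_sample(v, 1, str(k)) for k, v in sorted(groups.items())]
    else:
        arrays = [_as_sample(v, 1, f"group {i}") for i, v in enumerate(groups)]
    k = len(arrays)
    if k < 2:
        raise ValueError("need at least two groups")
    N = sum(a.size for a in arrays)
    if N <= k:
        raise ValueError("total n must exceed the number of groups")
    grand = np.concatenate(arrays).mean()
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    df_b, df_w = k - 1, N - k
    if ss_within == 0:
        if ss_between == 0:
            return TestResult("one-way ANOVA", 0.0, 1.0, (df_b, df_w),
                              {"degenerate": "all values identical"})
        warnings.warn("zero within-group variance; F degenerate")
        return TestResult("one-way ANOVA", math.inf, 0.0, (df_b, df_w),
                          {"degenerate": "zero within-group variance"})
    F = (ss_between / df_b) / (ss_within / df_w)
    p = float(sps.f.sf(F, df_b, df_w))
    return TestResult("one-way ANOVA", float(F), p, (df_b, df_w))


def kolmogorov_sf(lam: float) -> float:
    """Survival function of the Kolmogorov distribution.

    Q(lam) = 2 * sum_{k>=1} (-1)^(k-1) exp(-2 k^2 lam^2), the limiting
    distribution of sqrt(n) * D under the null.
    """
    if lam <= 0:
        return 1.0
    total = 0.0
    for k in range(1, 101):
        term = 2.0 * (-1.0) ** (k - 1) * math.exp(-2.0 * k * k * lam * lam)
        total += term
        if abs(term) < 1e-16:
            break
    return min(max(total, 0.0), 1.0)


def ks_two_sample(a, b) -> TestResult:
    """Two-sample Kolmogorov-Smirnov test.

    D = sup_x |ECDF_a(x) - ECDF_b(x)| with right-continuous ECDFs; the
    p value is the classical asymptotic Q_KS(sqrt(ne) * D) with effective
    sample size ne = n_a n_b / (n_a + n_b).  Below 10 observations per
    group the asymptotic p is inaccurate and a warning is issued.
    """
    a = np.sort(_as_sample(a, 1, "group a"))
    b = np.sort(_as_sample(b, 1, "group b"))
    na, nb = a.size, b.size
    if min(na, nb) < 10:
        warnings.warn("fewer than 10 observations per group; asymptotic "
                      "KS p value is approximate")
    pooled = np.concatenate([a, b])
    cdf_a = np.searchsorted(a, pooled, side="right") / na
    cdf_b = np.searchsorted(b, pooled, side="right") / nb
    D = float(np.max(np.abs(cdf_a - cdf_b)))
    ne = na * nb / (na + nb)
    p = kolmogorov_sf(math.sqrt(ne) * D)
    return TestResult("Kolmogorov-Smirnov (two-sample)", D, p,
                      extras={"n_a": na, "n_b": nb})


def log_rank(surv: pd.DataFrame) -> TestResult:
    """Two-group log-rank test on a (time, event, group) survival table.

    At each distinct event time t_j with d_j deaths among n_j subjects at
    risk (n_1j in group 1), the observed group-1 deaths are compared with
    the hypergeometric expectation e_1j = d_j n_1j / n_j and variance
    v_1j = d_j (n_1j/n_j) (1 - n_1j/n_j) (n_j - d_j) / (n_j - 1); the
    statistic (sum O - sum E)^2 / sum V is chi-square with 1 df.  Tied
    event times share one risk-table row.
    """
    cols = {c.lower(): c for c in surv.columns}
    time_col = cols.get("time_days", cols.get("time"))
    if time_col is None or "event" not in cols or "group" not in cols:
        raise ValueError("survival table needs time(_days), event, group columns")
    t = surv[time_col].to_numpy(dtype=float)
    e = surv[cols["event"]].to_numpy(dtype=int)
    g = surv[cols["group"]].to_numpy()
    if (t <= 0).any():
        raise ValueError("survival times must be > 0")
    if not np.isin(e, (0, 1)).all():
        raise ValueError("event must be 0 (censored) or 1 (died)")
    labels = sorted(pd.unique(g))
    if len(labels) != 2:
        raise ValueError("log-rank test requires exactly two groups")
    in1 = g == labels[0]
    if in1.all() or not in1.any():
        raise ValueError("each group needs at least one subject")
    if e.sum() == 0:
        raise ValueError("no events: log-rank test undefined")

    event_times = np.unique(t[e == 1])
    O = E = V = 0.0
    for tj in event_times:
        at_risk = t >= tj
        nj = int(at_risk.sum())
        n1j = int((at_risk & in1).sum())
        dj = int(((t == tj) & (e == 1)).sum())
        d1j = int(((t == tj) & (e == 1) & in1).sum())
        O += d1j
        E += dj * n1j / nj
        if nj > 1:
            V += dj * (n1j / nj) * (1 - n1j / nj) * (nj - dj) / (nj - 1)
    if V == 0:
        return TestResult("log-rank", 0.0, 1.0, 1,
                          {"degenerate": "zero variance", "groups": labels})
    chi2 = (O - E) ** 2 / V
    p = float(sps.chi2.sf(chi2, 1))
    return TestResult("log-rank", float(chi2), p, 1,
                      {"observed": O, "expected": E, "groups": labels})


def group_summary(values_by_group: dict[str, np.ndarray]) -> pd.DataFrame:
    """Mean, SD and SEM per group, both dispersion measures labelled."""
    rows = []
    for g, v in sorted(values_by_group.items()):
        v = _as_sample(v, 1, str(g))
        sd = float(v.std(ddof=1)) if v.size > 1 else 0.0
        rows.append(
            {
                "group": g,
                "n": int(v.size),
                "mean": float(v.mean()),
                "sd": sd,
                "sem": sd / math.sqrt(v.size) if v.size > 1 else 0.0,
            }
        )
    return pd.DataFrame(rows)
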