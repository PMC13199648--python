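"""Association statistics for burden metrics versus the death dichotomy.

The battery mirrors a small-cohort (n ~ 17) observational analysis:
Spearman and Pearson correlation of each burden metric with the 0/1 death
indicator, Welch's t and Mann-Whitney U comparing metric distributions
between outcome groups, a chi-square test of a dichotomized metric against
death, and ROC analysis of each metric as a death score.

Everything is implemented from the textbook formulas so that small-sample
behaviour (midranks under ties, exact Mann-Whitney enumeration, the
min-U convention, tie-grouped ROC cutpoints) is fully under the package's
control; SciPy supplies only reference distributions (Student t, chi-square,
normal) and midrank computation.

Conventions:

* all p-values are two-sided; no multiplicity adjustment is applied by
  default (a Holm adjustment is available but off), matching the raw-alpha
  reporting style of small exploratory cohorts;
* Mann-Whitney reports U = min(U_a, U_b); the exact null distribution is
  used automatically for n_a + n_b <= 12 without ties, otherwise the
  tie-corrected normal approximation with continuity correction;
* ROC ties are grouped into a single cutpoint, which makes the trapezoidal
  AUC identical to the pairwise concordance probability with ties counted
  one half.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .burden import BurdenSummary
from .exceptions import DegenerateDataError
from .io import OutcomeRecord

__all__ = [
    "TestResult",
    "RocResult",
    "AssociationReport",
    "spearman",
    "pearson",
    "welch_t",
    "student_t",
    "chi_square_2x2",
    "mann_whitney_u",
    "roc",
    "holm_adjust",
    "run_association_suite",
]


@dataclass
class TestResult:
    """A single test: statistic, two-sided p, sample sizes, auxiliaries."""

    name: str
    statistic: float
    p_value: float
    n: tuple[int, ...]
    details: dict = field(default_factory=dict)
    computable: bool = True

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "statistic": None if math.isnan(self.statistic) else self.statistic,
            "p_value": None if math.isnan(self.p_value) else self.p_value,
            "n": list(self.n),
            "details": self.details,
            "computable": self.computable,
        }


@dataclass
class RocResult:
    """ROC curve (descending cutpoints) and its trapezoidal AUC."""

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float

    def to_dict(self) -> dict:
        return {
            "thresholds": [float(x) for x in self.thresholds],
            "fpr": [float(x) for x in self.fpr],
            "tpr": [float(x) for x in self.tpr],
            "auc": self.auc,
        }


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be 1-D")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} must be finite")
    return arr


def _t_two_sided_p(t: float, df: float) -> float:
    return float(2.0 * sps.t.sf(abs(t), df))


# ---------------------------------------------------------------------------
# correlation


def pearson(x, y, name: str = "pearson") -> TestResult:
    """Product-moment correlation with the t-based two-sided p-value."""
    x = _as_float_array(x, "x")
    y = _as_float_array(y, "y")
    n = x.size
    if y.size != n or n < 4:
        raise ValueError("x and y must have equal length >= 4")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = math.sqrt(float(xc @ xc) * float(yc @ yc))
    if denom == 0:
        raise DegenerateDataError("correlation undefined: zero variance")
    r = float(xc @ yc) / denom
    r = min(1.0, max(-1.0, r))
    if abs(r) == 1.0:
        t, p = math.inf if r > 0 else -math.inf, 0.0
    else:
        t = r * math.sqrt((n - 2) / (1.0 - r * r))
        p = _t_two_sided_p(t, n - 2)
    return TestResult(name, r, p, (n,), details={"t": t, "df": n - 2})


def spearman(x, y) -> TestResult:
    """Rank correlation: Pearson on midranks, t-approximate two-sided p."""
    x = _as_float_array(x, "x")
    y = _as_float_array(y, "y")
    if x.size != y.size or x.size < 4:
        raise ValueError("x and y must have equal length >= 4")
    rx = sps.rankdata(x)  # midranks for ties
    ry = sps.rankdata(y)
    res = pearson(rx, ry, name="spearman")
    return res


# ---------------------------------------------------------------------------
# two-group location tests


def _t_test(a, b, name: str, welch: bool) -> TestResult:
    a = _as_float_array(a, "group_a")
    b = _as_float_array(b, "group_b")
    na, nb = a.size, b.size
    if na < 2 or nb < 2:
        raise DegenerateDataError("each group needs >= 2 observations")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va + vb == 0:
        raise DegenerateDataError("t statistic undefined: zero variance in both groups")
    diff = a.mean() - b.mean()
    if welch:
        se2 = va / na + vb / nb
        t = diff / math.sqrt(se2)
        df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    else:
        sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        t = diff / math.sqrt(sp2 * (1 / na + 1 / nb))
        df = na + nb - 2
    return TestResult(name, float(t), _t_two_sided_p(t, df), (na, nb), details={"df": float(df)})


def welch_t(group_a, group_b) -> TestResult:
    """Welch's unequal-variance t-test (Welch-Satterthwaite df), two-sided."""
    return _t_test(group_a, group_b, "welch_t", welch=True)


def student_t(group_a, group_b) -> TestResult:
    """Classic pooled-variance t-test, provided for comparison."""
    return _t_test(group_a, group_b, "student_t", welch=False)


# ---------------------------------------------------------------------------
# 2x2 association


def chi_square_2x2(table, yates: bool = False) -> TestResult:
    """Pearson chi-square on a 2x2 count table, 1 df.

    Uses the closed form n(ad - bc)^2 / (row and column products); the Yates
    continuity correction subtracts n/2 from \\|ad - bc\\| (floored at 0).
    """
    tab = np.asarray(table, dtype=float)
    if tab.shape != (2, 2) or np.any(tab < 0) or np.any(tab != np.round(tab)):
        raise ValueError("table must be 2x2 non-negative integer counts")
    a, b = tab[0]
    c, d = tab[1]
    n = tab.sum()
    if n == 0:
        raise DegenerateDataError("empty table")
    margins = [(a + b), (c + d), (a + c), (b + d)]
    if any(m == 0 for m in margins):
        raise DegenerateDataError(
            "chi-square undefined: a row or column marginal is zero "
            "(one category was never observed)"
        )
    det = abs(a * d - b * c)
    if yates:
        det = max(det - n / 2.0, 0.0)
    stat = n * det**2 / (margins[0] * margins[1] * margins[2] * margins[3])
    p = float(sps.chi2.sf(stat, 1))
    return TestResult(
        "chi_square_2x2", float(stat), p, (int(n),),
        details={"df": 1, "yates": yates, "table": tab.astype(int).tolist()},
    )


# ---------------------------------------------------------------------------
# Mann-Whitney U


def _rank_sum_counts(n1: int, total: int) -> np.ndarray:
    """counts[s] = number of n1-subsets of ranks 1..total with rank sum s."""
    max_s = sum(range(total - n1 + 1, total + 1))
    dp = np.zeros((n1 + 1, max_s + 1), dtype=float)
    dp[0, 0] = 1.0
    for rank in range(1, total + 1):
        for j in range(min(rank, n1), 0, -1):
            dp[j, rank:] += dp[j - 1, :-rank]
    return dp[n1]


def mann_whitney_u(group_a, group_b, exact: bool | None = None) -> TestResult:
    """Mann-Whitney U with the min-U convention and two-sided p.

    ``exact=None`` (auto) enumerates the exact null distribution when
    n_a + n_b <= 12 and there are no ties; otherwise the tie-corrected
    normal approximation with continuity correction is used.  ``exact=True``
    forces enumeration (ties still fall back to the approximation).
    """
    a = _as_float_array(group_a, "group_a")
    b = _as_float_array(group_b, "group_b")
    na, nb = a.size, b.size
    if na == 0 or nb == 0:
        raise DegenerateDataError("both groups must be non-empty")
    combined = np.concatenate([a, b])
    ranks = sps.rankdata(combined)
    ra = float(ranks[:na].sum())
    ua = ra - na * (na + 1) / 2.0
    ub = na * nb - ua
    u = min(ua, ub)
    mu = na * nb / 2.0

    _, tie_counts = np.unique(combined, return_counts=True)
    has_ties = bool(np.any(tie_counts > 1))
    use_exact = (exact is True or (exact is None and na + nb <= 12)) and not has_ties

    if use_exact:
        counts = _rank_sum_counts(na, na + nb)
        total = counts.sum()
        offset = na * (na + 1) // 2  # U = rank sum - offset
        u_counts = counts[offset:]
        k = int(round(u))
        p = min(1.0, 2.0 * float(u_counts[: k + 1].sum()) / total)
        method = "exact"
    else:
        n = na + nb
        tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (n * (n - 1))
        sigma2 = na * nb / 12.0 * ((n + 1) - tie_term)
        if sigma2 <= 0:
            # all observations identical: no evidence either way
            return TestResult(
                "mann_whitney_u", u, 1.0, (na, nb),
                details={"U_a": ua, "U_b": ub, "method": "degenerate"},
            )
        z = (u + 0.5 - mu) / math.sqrt(sigma2)
        p = min(1.0, 2.0 * float(sps.norm.cdf(z)))
        method = "normal_approx"
    return TestResult(
        "mann_whitney_u", float(u), float(p), (na, nb),
        details={"U_a": ua, "U_b": ub, "method": method, "ties": has_ties},
    )


# ---------------------------------------------------------------------------
# ROC


def roc(scores, labels) -> RocResult:
    """ROC curve of a score against boolean labels (higher = more positive).

    Equal scores are grouped into a single cutpoint, so the trapezoidal AUC
    equals the concordance probability P(score+ > score-) + 0.5 P(tie).
    """
    s = _as_float_array(scores, "scores")
    y = np.asarray(labels, dtype=bool)
    if y.shape != s.shape:
        raise ValueError("scores and labels must have equal length")
    n_pos = int(y.sum())
    n_neg = int(y.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise DegenerateDataError("ROC undefined: both classes must be present")

    order = np.argsort(-s, kind="mergesort")
    s_sorted = s[order]
    y_sorted = y[order]
    tp_cum = np.cumsum(y_sorted)
    fp_cum = np.cumsum(~y_sorted)
    # index of the last element of each tie group
    last = np.flatnonzero(np.diff(s_sorted) != 0)
    last = np.concatenate([last, [s.size - 1]])

    tpr = np.concatenate([[0.0], tp_cum[last] / n_pos])
    fpr = np.concatenate([[0.0], fp_cum[last] / n_neg])
    thresholds = s_sorted[last]
    auc = float(np.trapezoid(tpr, fpr))
    return RocResult(thresholds=thresholds, fpr=fpr, tpr=tpr, auc=auc)


# ---------------------------------------------------------------------------
# multiplicity (optional, off by default)


def holm_adjust(p_values: Mapping[str, float]) -> dict[str, float]:
    """Holm step-down adjusted p-values for a named family of tests."""
    items = sorted(p_values.items(), key=lambda kv: kv[1])
    m = len(items)
    adjusted: dict[str, float] = {}
    running = 0.0
    for i, (name, p) in enumerate(items):
        running = max(running, (m - i) * p)
        adjusted[name] = min(1.0, running)
    return adjusted


# ---------------------------------------------------------------------------
# the full battery


@dataclass
class AssociationReport:
    """Keyed test results and ROC curves for one cohort."""

    n_patients: int
    n_dead: int
    thresholds: tuple[float, ...]
    tests: dict[str, TestResult]
    rocs: dict[str, RocResult]
    holm: dict[str, float] | None = None

    def to_dict(self) -> dict:
        out = {
            "n_patients": self.n_patients,
            "n_dead": self.n_dead,
            "thresholds": list(self.thresholds),
            "tests": {k: v.to_dict() for k, v in sorted(self.tests.items())},
            "rocs": {k: v.to_dict() for k, v in sorted(self.rocs.items())},
        }
        if self.holm is not None:
            out["holm_adjusted_p"] = dict(sorted(self.holm.items()))
        return out


def _not_computable(name: str, n: tuple[int, ...], reason: str) -> TestResult:
    return TestResult(name, math.nan, math.nan, n, details={"reason": reason}, computable=False)


def run_association_suite(
    summaries: Mapping[str, BurdenSummary],
    outcomes: Mapping[str, OutcomeRecord],
    thresholds: Sequence[float] = (15.0, 20.0),
    frac_cutoff: float = 0.30,
    use_welch: bool = True,
    yates: bool = False,
    mw_exact: bool | None = None,
    holm: bool = False,
) -> AssociationReport:
    """Run the whole battery on the summaries/outcomes intersection.

    For each burden metric (normalized AUC, max ICP, mean ICP, total AUC,
    and the per-threshold dose and time-fraction): Spearman and Pearson
    against the death indicator, a two-group t-test and Mann-Whitney U
    (survivors vs. dead), and a ROC curve of the metric as a death score.
    Per threshold, a chi-square test of (frac_above > ``frac_cutoff``)
    against death.  Degenerate inputs mark the affected test as
    not-computable; the suite continues.
    """
    ids = sorted(set(summaries) & set(outcomes))
    if len(ids) < 2:
        raise ValueError("need >= 2 patients with both summary and outcome")
    dead = np.array([outcomes[i].poor_outcome for i in ids], dtype=bool)
    death01 = dead.astype(float)
    thresholds = tuple(float(t) for t in thresholds)

    metrics: dict[str, np.ndarray] = {
        "normalized_auc": np.array([summaries[i].normalized_auc for i in ids]),
        "max_icp": np.array([summaries[i].max_icp for i in ids]),
        "mean_icp": np.array([summaries[i].mean_icp for i in ids]),
        "auc_mmHg_h": np.array([summaries[i].auc_mmHg_h for i in ids]),
    }
    for theta in thresholds:
        metrics[f"dose_above_{theta:g}"] = np.array(
            [summaries[i].dose_above[theta] for i in ids]
        )
        metrics[f"frac_above_{theta:g}"] = np.array(
            [summaries[i].frac_above[theta] for i in ids]
        )

    t_test = welch_t if use_welch else student_t
    tests: dict[str, TestResult] = {}
    rocs: dict[str, RocResult] = {}

    def attempt(key, fn, *args, n=(len(ids),), **kwargs):
        try:
            res = fn(*args, **kwargs)
            res.name = key
            tests[key] = res
        except DegenerateDataError as exc:
            tests[key] = _not_computable(key, n, str(exc))

    for name, x in metrics.items():
        attempt(f"spearman:{name}", spearman, x, death01)
        attempt(f"pearson:{name}", pearson, x, death01)
        survivors, died = x[~dead], x[dead]
        n2 = (int((~dead).sum()), int(dead.sum()))
        attempt(f"t_test:{name}", t_test, survivors, died, n=n2)
        attempt(f"mann_whitney:{name}", mann_whitney_u, survivors, died, n=n2, exact=mw_exact)
        try:
            rocs[name] = roc(x, dead)
        except DegenerateDataError:
            pass

    for theta in thresholds:
        frac = metrics[f"frac_above_{theta:g}"]
        above = frac > frac_cutoff
        table = [
            [int(np.sum(above & dead)), int(np.sum(above & ~dead))],
            [int(np.sum(~above & dead)), int(np.sum(~above & ~dead))],
        ]
        key = f"chi2:frac_above_{theta:g}_gt_{frac_cutoff:g}"
        attempt(key, chi_square_2x2, table, yates=yates)

    adjusted = None
    if holm:
        adjusted = holm_adjust(
            {k: t.p_value for k, t in tests.items() if t.computable}
        )
    return AssociationReport(
        n_patients=len(ids),
        n_dead=int(dead.sum()),
        thresholds=thresholds,
        tests=tests,
        rocs=rocs,
        holm=adjusted,
    )
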