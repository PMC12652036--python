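"""Classical tests and the simplified hurdle-Gamma abundance model.

Houses the remaining inference used by the pipeline: paired and independent
t-tests (including a two-group ANOVA reconstructed from printed summary
statistics), the Wilcoxon signed-rank test, Kruskal-Wallis with Dunn's
post hoc z-tests, and a two-part ("hurdle") Gamma model for zero-inflated
abundances with cluster-robust (by subject) standard errors standing in for
a subject random effect.  All p-values are reported without multiple-
comparison adjustment; formatted output prints values below 0.001 as
"<0.001" while machine output retains the raw numbers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "TestResult",
    "HurdleGammaFit",
    "paired_t",
    "independent_t",
    "anova_from_summary",
    "wilcoxon_signed_rank",
    "kruskal_dunn",
    "hurdle_gamma_fit",
    "format_p",
]

_METHODS = frozenset(
    {
        "paired_t",
        "independent_t",
        "anova_summary",
        "wilcoxon_signed_rank",
        "kruskal_wallis",
        "dunn",
        "hurdle_gamma",
    }
)


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p: float
    method: str
    df: float | tuple | None = None

    def __post_init__(self) -> None:
        if self.method not in _METHODS:
            raise ValueError(f"unknown method tag {self.method!r}")
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("p-value outside [0, 1]")

    def as_row(self, comparison: str = "") -> dict:
        return {
            "comparison": comparison,
            "method": self.method,
            "statistic": self.statistic,
            "df": self.df,
            "p": self.p,
            "p_formatted": format_p(self.p),
        }


def format_p(p: float) -> str:
    return "<0.001" if p < 0.001 else f"{p:.4g}"


def paired_t(x, y) -> TestResult:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if len(x) < 2:
        raise ValueError("paired t-test needs >= 2 complete pairs")
    d = x - y
    if (d == 0).all():
        # identical vectors: no difference and no evidence of one
        return TestResult(0.0, 1.0, "paired_t", df=len(x) - 1)
    if np.allclose(d.std(ddof=1), 0):
        raise ValueError("zero variance of paired differences")
    t, p = stats.ttest_rel(x, y)
    return TestResult(float(t), float(p), "paired_t", df=len(x) - 1)


def independent_t(x, y, pooled: bool = True) -> TestResult:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    x, y = x[~np.isnan(x)], y[~np.isnan(y)]
    if len(x) < 2 or len(y) < 2:
        raise ValueError("independent t-test needs >= 2 observations per group")
    if np.allclose(x.std(ddof=1), 0) and np.allclose(y.std(ddof=1), 0):
        raise ValueError("zero variance in both groups")
    t, p = stats.ttest_ind(x, y, equal_var=pooled)
    df = len(x) + len(y) - 2 if pooled else None
    return TestResult(float(t), float(p), "independent_t", df=df)


def anova_from_summary(m1, sd1, n1, m2, sd2, n2) -> TestResult:
    """Two-group one-way ANOVA from printed means/SDs/counts (F = t^2)."""
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be positive")
    df2 = n1 + n2 - 2
    sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df2
    t = (m1 - m2) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    F = t**2
    p = float(stats.f.sf(F, 1, df2))
    return TestResult(float(F), p, "anova_summary", df=(1, df2))


def wilcoxon_signed_rank(x, y) -> TestResult:
    """Wilcoxon signed-rank: exact for n <= 25 without ties, else normal
    approximation with continuity and tie correction.  Zero differences are
    dropped."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    ok = ~(np.isnan(x) | np.isnan(y))
    d = x[ok] - y[ok]
    d = d[d != 0]
    if len(d) == 0:
        raise ValueError("all paired differences are zero")
    has_ties = len(np.unique(np.abs(d))) < len(d)
    method = "approx" if (len(d) > 25 or has_ties) else "exact"
    res = stats.wilcoxon(d, correction=(method == "approx"), method=method)
    return TestResult(float(res.statistic), float(res.pvalue), "wilcoxon_signed_rank")


@dataclass
class DunnResult:
    pair: tuple
    z: float
    p: float


def kruskal_dunn(groups: dict | list) -> tuple[TestResult, list[DunnResult]]:
    """Tie-corrected Kruskal-Wallis H plus Dunn pairwise z-tests (unadjusted p).

    Dunn's z compares mean ranks on the pooled ranking with the tie-corrected
    variance N(N+1)/12 - sum(t^3 - t)/(12(N-1)).
    """
    if isinstance(groups, dict):
        names = list(groups.keys())
        data = [np.asarray(groups[k], float) for k in names]
    else:
        data = [np.asarray(g, float) for g in groups]
        names = list(range(len(data)))
    data = [g[~np.isnan(g)] for g in data]
    if len(data) < 2 or any(len(g) < 1 for g in data):
        raise ValueError("need >= 2 non-empty groups")
    pooled = np.concatenate(data)
    if np.allclose(pooled, pooled[0]):
        raise ValueError("all observations identical; ranks degenerate")
    H, p = stats.kruskal(*data)
    kw = TestResult(float(H), float(p), "kruskal_wallis", df=len(data) - 1)

    ranks = stats.rankdata(pooled)
    N = len(pooled)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (12.0 * (N - 1)))
    var_unit = N * (N + 1) / 12.0 - tie_term
    offsets = np.cumsum([0] + [len(g) for g in data])
    mean_ranks = [
        ranks[offsets[i] : offsets[i + 1]].mean() for i in range(len(data))
    ]
    dunn = []
    for i, j in combinations(range(len(data)), 2):
        se = np.sqrt(var_unit * (1.0 / len(data[i]) + 1.0 / len(data[j])))
        z = (mean_ranks[i] - mean_ranks[j]) / se
        dunn.append(
            DunnResult(
                pair=(names[i], names[j]),
                z=float(z),
                p=float(2.0 * stats.norm.sf(abs(z))),
            )
        )
    return kw, dunn


@dataclass
class HurdleGammaFit:
    """Two-part zero/positive abundance model with cluster-robust inference.

    The zero part is a logistic regression for presence; the positive part a
    Gamma GLM with log link on the nonzero values.  Robust (subject-cluster)
    standard errors approximate the subject random effect of the full mixed
    model.
    """

    zero_params: pd.Series
    zero_bse: pd.Series
    zero_p: pd.Series
    positive_params: pd.Series
    positive_bse: pd.Series
    positive_p: pd.Series
    shape: float
    zero_degenerate: bool  # no zeros observed: presence fitted as identically 1
    note: str = ""

    def wald(self, term: str, part: str = "positive") -> TestResult:
        params = self.positive_params if part == "positive" else self.zero_params
        bse = self.positive_bse if part == "positive" else self.zero_bse
        z = float(params[term] / bse[term])
        return TestResult(z, float(2.0 * stats.norm.sf(abs(z))), "hurdle_gamma")


def hurdle_gamma_fit(
    abundance, design: pd.DataFrame, subject_ids, add_intercept: bool = True
) -> HurdleGammaFit:
    """Fit the hurdle Gamma model of abundance on a responder/time design.

    ``design`` holds the covariate columns (e.g. responder indicator, time
    indicator and their interaction); an intercept column is prepended unless
    disabled.  Requires some positive observations; with no zeros the
    presence part is degenerate and reported as such.
    """
    y = np.asarray(abundance, float)
    if (y < 0).any():
        raise ValueError("abundance must be non-negative")
    X = design.copy()
    if add_intercept:
        X.insert(0, "const", 1.0)
    if np.linalg.matrix_rank(X.to_numpy(float)) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    groups = pd.Series(np.asarray(subject_ids), index=X.index)

    positive = y > 0
    if not positive.any():
        raise ValueError("no positive abundances; Gamma part cannot be fit")

    zero_degenerate = positive.all()
    if zero_degenerate:
        idx = X.columns
        zero_params = pd.Series(np.nan, index=idx)
        zero_bse = pd.Series(np.nan, index=idx)
        zero_p = pd.Series(np.nan, index=idx)
        note = "no zeros observed; presence fitted as identically 1"
    else:
        zmod = sm.GLM(positive.astype(float), X, family=sm.families.Binomial())
        zres = zmod.fit(cov_type="cluster", cov_kwds={"groups": groups})
        zero_params, zero_bse, zero_p = zres.params, zres.bse, zres.pvalues
        note = ""

    Xp = X.loc[positive]
    gmod = sm.GLM(
        y[positive], Xp, family=sm.families.Gamma(link=sm.families.links.Log())
    )
    gres = gmod.fit(cov_type="cluster", cov_kwds={"groups": groups.loc[positive]})
    shape = 1.0 / float(gres.scale)  # Gamma shape from the estimated dispersion

    return HurdleGammaFit(
        zero_params=zero_params,
        zero_bse=zero_bse,
        zero_p=zero_p,
        positive_params=gres.params,
        positive_bse=gres.bse,
        positive_p=gres.pvalues,
        shape=shape,
        zero_degenerate=zero_degenerate,
        note=note,
    )


def results_table(rows: list[dict]) -> pd.DataFrame:
    """Tidy results frame (comparison, method, statistic, df, p)."""
    return pd.DataFrame(rows, columns=["comparison", "method", "statistic", "df", "p", "p_formatted"])
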