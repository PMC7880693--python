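"""The statistical battery used throughout the gland measurements.

The conventions mirror common practice in fly immunity papers:

* normality screened by the Shapiro–Wilk test and by a parametric
  bootstrap of the Kolmogorov–Smirnov distance under the fitted normal;
* pairwise group comparisons by Student's t-test, gated on Bartlett's
  variance test: equal-variance (pooled) t when Bartlett does not reject
  at ``alpha_var``, Welch's t otherwise;
* multi-group ordinal outcomes (the reporter assay's per-replicate 'None'
  fractions) by the Kruskal–Wallis rank-sum test with tie correction,
  followed by Dunn's pairwise z-tests;
* significance stars: *** p<0.001, ** p<0.01, * p<0.05, n.s. p≥0.05.

All tests are two-sided.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TestResult",
    "ReporterCounts",
    "KruskalDunnResult",
    "significance_stars",
    "shapiro_wilk",
    "bootstrap_normal_fit",
    "bartlett",
    "t_test_auto",
    "kruskal_dunn",
    "reporter_assay_test",
]


def significance_stars(p: float) -> str:
    """Map a p-value to the star convention (boundaries are half-open:
    p = 0.05 is n.s., p = 0.01 is *, p = 0.001 is **)."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p-value {p} outside [0, 1]")
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "n.s."


@dataclass
class TestResult:
    method: str
    statistic: float
    df: float | tuple[float, ...] | None
    p_value: float
    sidedness: str = "two-sided"
    detail: dict = field(default_factory=dict)

    @property
    def stars(self) -> str:
        return significance_stars(self.p_value)


@dataclass(frozen=True)
class ReporterCounts:
    """Phenotype counts of one reporter-assay replicate (a batch of larvae
    scored as Full / Partial / None reporter pattern)."""

    genotype: str
    full: int
    partial: int
    none: int
    replicate_size: int | None = 24

    def __post_init__(self) -> None:
        if min(self.full, self.partial, self.none) < 0:
            raise ValueError("phenotype counts must be non-negative")
        total = self.full + self.partial + self.none
        if total == 0:
            raise ValueError("replicate with zero scored larvae")
        if self.replicate_size is not None and total != self.replicate_size:
            raise ValueError(
                f"counts sum to {total}, expected replicate size "
                f"{self.replicate_size}"
            )

    @property
    def none_fraction(self) -> float:
        return self.none / (self.full + self.partial + self.none)


# ---------------------------------------------------------------------------
# normality


def shapiro_wilk(x: Sequence[float]) -> TestResult:
    """Shapiro–Wilk W test of normality (3 ≤ n ≤ 5000)."""
    x = np.asarray(x, dtype=float)
    if not 3 <= len(x) <= 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.ptp(x) == 0:
        raise ValueError("all values identical; W undefined")
    res = sps.shapiro(x)
    return TestResult(
        method="shapiro-wilk", statistic=float(res.statistic), df=None,
        p_value=float(res.pvalue), detail={"n": len(x)},
    )


def bootstrap_normal_fit(
    x: Sequence[float], n_boot: int = 1000, seed: int = 0
) -> TestResult:
    """Parametric bootstrap of normal goodness-of-fit.

    A normal is fit to the data (MLE); the observed KS distance to that fit
    is compared with the KS distances of ``n_boot`` parametric resamples,
    each measured against its *own* refitted normal.  The p-value is the
    fraction of resamples whose distance exceeds the observed one.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 5:
        raise ValueError("parametric bootstrap requires n >= 5")
    sd = x.std(ddof=0)
    if sd == 0:
        raise ValueError("zero variance; normal fit undefined")
    mu = x.mean()
    d_obs = _ks_distance_rows(np.sort(x)[None, :], np.array([mu]), np.array([sd]))[0]

    rng = np.random.default_rng(seed)
    resamples = rng.normal(mu, sd, size=(n_boot, n))
    mus = resamples.mean(axis=1)
    sds = resamples.std(axis=1, ddof=0)
    d_boot = _ks_distance_rows(np.sort(resamples, axis=1), mus, sds)
    p = float(np.mean(d_boot > d_obs))
    return TestResult(
        method="parametric-ks-bootstrap", statistic=float(d_obs), df=None,
        p_value=p, detail={"n": n, "n_boot": n_boot, "seed": seed},
    )


def _ks_distance_rows(sorted_rows: np.ndarray, mu: np.ndarray, sd: np.ndarray) -> np.ndarray:
    """Row-wise KS distance of sorted samples to N(mu, sd)."""
    n = sorted_rows.shape[1]
    u = sps.norm.cdf((sorted_rows - mu[:, None]) / sd[:, None])
    i = np.arange(1, n + 1)
    d_plus = (i / n - u).max(axis=1)
    d_minus = (u - (i - 1) / n).max(axis=1)
    return np.maximum(d_plus, d_minus)


# ---------------------------------------------------------------------------
# variance gate and t-tests


def bartlett(groups: Sequence[Sequence[float]]) -> TestResult:
    """Bartlett's K² test of equal variances across ≥2 groups."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("Bartlett needs at least two groups")
    for g in arrays:
        if len(g) < 2:
            raise ValueError("every group needs at least two observations")
        if g.var(ddof=1) == 0:
            raise ValueError("a group has zero variance; Bartlett undefined")
    stat, p = sps.bartlett(*arrays)
    return TestResult(
        method="bartlett", statistic=float(stat), df=len(arrays) - 1,
        p_value=float(p),
    )


def t_test_auto(
    x: Sequence[float], y: Sequence[float], alpha_var: float = 0.05
) -> TestResult:
    """Student's t-test with a Bartlett variance gate.

    Bartlett's test on the two groups decides the branch: pooled-variance
    Student's t when the variances are compatible (p ≥ ``alpha_var``),
    Welch's t otherwise.  Two-sided; the result records which branch ran
    and the gate p-value.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("both groups need at least two observations")
    if np.ptp(np.concatenate([x, y])) == 0:
        return TestResult(
            method="student-t (pooled)", statistic=0.0,
            df=len(x) + len(y) - 2, p_value=1.0,
            detail={"branch": "student", "variance_gate_p": 1.0},
        )
    gate = bartlett([x, y])
    equal_var = gate.p_value >= alpha_var
    res = sps.ttest_ind(x, y, equal_var=equal_var)
    method = "student-t (pooled)" if equal_var else "welch-t"
    return TestResult(
        method=method,
        statistic=float(res.statistic),
        df=float(res.df),
        p_value=float(res.pvalue),
        detail={
            "branch": "student" if equal_var else "welch",
            "variance_gate_p": gate.p_value,
            "alpha_var": alpha_var,
        },
    )


# ---------------------------------------------------------------------------
# Kruskal–Wallis + Dunn


@dataclass
class KruskalDunnResult:
    omnibus: TestResult
    pairwise: pd.DataFrame  # group_a, group_b, z, p, p_adjusted, stars


def kruskal_dunn(
    groups: Mapping[str, Sequence[float]] | Sequence[Sequence[float]],
    adjust: str | None = None,
) -> KruskalDunnResult:
    """Tie-corrected Kruskal–Wallis omnibus test plus Dunn's pairwise z-tests.

    Dunn's z for groups i, j compares mean ranks under the pooled ranking:
    ``z = (R̄_i − R̄_j) / sqrt((N(N+1)/12 − T/(12(N−1)))·(1/n_i + 1/n_j))``
    with tie correction ``T = Σ(t³ − t)``.  Pairwise p-values are unadjusted
    by default; ``adjust="holm"`` applies Holm's step-down correction.
    """
    if isinstance(groups, Mapping):
        names = list(groups)
        arrays = [np.asarray(groups[k], dtype=float) for k in names]
    else:
        arrays = [np.asarray(g, dtype=float) for g in groups]
        names = [f"group{i}" for i in range(len(arrays))]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    pooled = np.concatenate(arrays)
    if len(pooled) < 5:
        raise ValueError("need at least 5 observations in total")

    k = len(arrays)
    if np.ptp(pooled) == 0:  # all observations identical: no evidence, H = 0
        omnibus = TestResult(
            method="kruskal-wallis", statistic=0.0, df=k - 1, p_value=1.0
        )
    else:
        stat, p = sps.kruskal(*arrays)
        omnibus = TestResult(
            method="kruskal-wallis", statistic=float(stat), df=k - 1,
            p_value=float(p),
        )

    ranks = sps.rankdata(pooled)
    n_total = len(pooled)
    sizes = [len(a) for a in arrays]
    mean_ranks = []
    start = 0
    for sz in sizes:
        mean_ranks.append(ranks[start : start + sz].mean())
        start += sz
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_sum = float(np.sum(tie_counts**3 - tie_counts))
    var_factor = n_total * (n_total + 1) / 12.0 - tie_sum / (12.0 * (n_total - 1))

    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            se2 = var_factor * (1.0 / sizes[i] + 1.0 / sizes[j])
            if se2 <= 0:  # every pooled value tied: no discrimination possible
                z, p_ij = 0.0, 1.0
            else:
                z = (mean_ranks[i] - mean_ranks[j]) / np.sqrt(se2)
                p_ij = 2.0 * sps.norm.sf(abs(z))
            rows.append(
                {"group_a": names[i], "group_b": names[j], "z": z, "p": p_ij}
            )
    pairwise = pd.DataFrame(rows)
    if adjust is None:
        pairwise["p_adjusted"] = pairwise["p"]
    elif adjust == "holm":
        pairwise["p_adjusted"] = _holm(pairwise["p"].to_numpy())
    else:
        raise ValueError(f"unknown adjustment {adjust!r}")
    pairwise["stars"] = pairwise["p_adjusted"].map(significance_stars)
    return KruskalDunnResult(omnibus=omnibus, pairwise=pairwise)


def _holm(p: np.ndarray) -> np.ndarray:
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj


# ---------------------------------------------------------------------------
# reporter assay


def reporter_assay_test(
    replicates: Sequence[ReporterCounts], adjust: str | None = None
) -> tuple[pd.DataFrame, KruskalDunnResult]:
    """Score the 'None'-phenotype fraction per replicate and test genotypes.

    Per-replicate fractions None/(Full+Partial+None) are summarized as mean
    ± sd per genotype and compared across genotypes with Kruskal–Wallis
    followed by Dunn's test (the published convention for this assay).
    """
    by_genotype: dict[str, list[float]] = {}
    for rep in replicates:
        by_genotype.setdefault(rep.genotype, []).append(rep.none_fraction)
    if len(by_genotype) < 2:
        raise ValueError("need at least two genotypes")
    for genotype, fracs in by_genotype.items():
        if len(fracs) < 2:
            raise ValueError(f"genotype {genotype!r} has fewer than 2 replicates")
    summary = pd.DataFrame(
        [
            {
                "genotype": g,
                "n_replicates": len(f),
                "none_fraction_mean": float(np.mean(f)),
                "none_fraction_sd": float(np.std(f, ddof=1)),
            }
            for g, f in by_genotype.items()
        ]
    )
    result = kruskal_dunn(by_genotype, adjust=adjust)
    return summary, result
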