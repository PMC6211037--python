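"""The statistical battery for the comparative duet analysis.

Two kinds of inputs coexist.  Raw per-duet measurements feed the usual
tests, while several published comparisons can only be reconstructed from
printed (mean, SEM, n) triples; for those, group variance is recovered as
s^2 = n * SEM^2 and the classical F and t statistics are computed directly
from the summaries, which is algebraically identical to running the test on
any raw sample having exactly those moments.

Exact nonparametric tests are computed from the true permutation null:
the signed-rank null distribution by convolution over ranks (equivalent to
enumerating all 2^n sign assignments), the rank-sum null by the
subset-sum recursion over ranks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from scipy.optimize import minimize_scalar

__all__ = [
    "GroupSummary",
    "TestResult",
    "LmmFit",
    "anova_from_summary",
    "t_from_summary",
    "signed_rank_null_pmf",
    "wilcoxon_signed_rank_exact",
    "wilcoxon_rank_sum",
    "kruskal_wallis",
    "assumption_checks",
    "outlier_flags",
    "bonferroni",
    "lmm_random_intercept",
    "manova_tests",
    "pearson_correlation",
]

log = logging.getLogger(__name__)

#: largest n for which the signed-rank null is built exactly
EXACT_SIGNED_RANK_N = 25


@dataclass(frozen=True)
class GroupSummary:
    """A printed (mean, SEM, n) triple for one group."""

    mean: float
    sem: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.sem < 0:
            raise ValueError("SEM must be non-negative")

    @property
    def sd(self) -> float:
        return self.sem * np.sqrt(self.n)

    @property
    def variance(self) -> float:
        return self.n * self.sem**2

    @classmethod
    def from_sample(cls, x) -> "GroupSummary":
        x = np.asarray(x, dtype=float)
        return cls(float(x.mean()), float(x.std(ddof=1) / np.sqrt(len(x))),
                   len(x))


@dataclass(frozen=True)
class TestResult:
    statistic: str                    # F | t | V | W | chi2 | Lambda | Pillai | r
    value: float
    df: float | tuple | None
    p: float
    adjusted_p: float | None = None
    method: str = ""

    def __post_init__(self) -> None:
        if self.p is not None and not (0 <= self.p <= 1 + 1e-12):
            raise ValueError(f"p must lie in [0, 1], got {self.p}")


# ------------------------------------------------------- summary reconstruction

def anova_from_summary(groups: list[GroupSummary]) -> TestResult:
    """One-way ANOVA F from printed (mean, SEM, n) group summaries."""
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least two groups")
    if any(g.n < 2 for g in groups):
        raise ValueError("every group needs n >= 2")
    ns = np.array([g.n for g in groups], dtype=float)
    means = np.array([g.mean for g in groups])
    variances = np.array([g.variance for g in groups])
    total = ns.sum()
    grand = (ns * means).sum() / total
    df_b = len(groups) - 1
    df_w = int(total) - len(groups)
    ms_between = (ns * (means - grand) ** 2).sum() / df_b
    ms_within = ((ns - 1) * variances).sum() / df_w
    f = ms_between / ms_within
    return TestResult("F", float(f), (df_b, df_w), float(sps.f.sf(f, df_b, df_w)),
                      method="one-way ANOVA from summaries")


def t_from_summary(a: GroupSummary, b: GroupSummary,
                   kind: str = "pooled") -> TestResult:
    """Two-sample t from summaries: classical pooled or Welch."""
    if a.n < 2 or b.n < 2:
        raise ValueError("both groups need n >= 2")
    diff = a.mean - b.mean
    if kind == "pooled":
        df = a.n + b.n - 2
        sp2 = ((a.n - 1) * a.variance + (b.n - 1) * b.variance) / df
        se2 = sp2 * (1 / a.n + 1 / b.n)
        method = "Student two-sample t (pooled) from summaries"
    elif kind == "welch":
        va, vb = a.variance / a.n, b.variance / b.n
        se2 = va + vb
        if se2 > 0:
            df = se2**2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1))
        else:
            df = a.n + b.n - 2
        method = "Welch two-sample t from summaries"
    else:
        raise ValueError(f"kind must be pooled|welch, got {kind!r}")
    if se2 == 0:
        if diff == 0:
            return TestResult("t", 0.0, df, 1.0, method=method)
        t = np.inf if diff > 0 else -np.inf
        return TestResult("t", float(t), df, 0.0, method=method + " (zero variance)")
    t = diff / np.sqrt(se2)
    return TestResult("t", float(t), float(df) if kind == "welch" else df,
                      float(2 * sps.t.sf(abs(t), df)), method=method)


# ------------------------------------------------------- exact nonparametrics

def signed_rank_null_pmf(ranks) -> tuple[np.ndarray, np.ndarray]:
    """Null pmf of the positive-rank sum over all 2^n sign assignments.

    ``ranks`` may contain midranks (half-integers from ties); values are
    doubled internally so the support grid is integer.  Returns (support,
    probability) with support on the original (possibly half-integer) scale.
    """
    doubled = np.round(np.asarray(ranks, dtype=float) * 2).astype(int)
    counts = np.zeros(doubled.sum() + 1)
    counts[0] = 1.0
    for r in doubled:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: len(counts) - r]
        counts = counts + shifted
    support = np.arange(len(counts)) / 2.0
    return support, counts / counts.sum()


def wilcoxon_signed_rank_exact(differences=None, *, v: float | None = None,
                               n: int | None = None) -> TestResult:
    """Exact two-sided Wilcoxon signed-rank test.

    Accepts either the paired differences (zeros dropped with a warning,
    midranks for tied magnitudes) or the published (V, n) pair, in which
    case untied ranks 1..n are assumed.  Exact for n <= 25, normal
    approximation with continuity correction beyond.
    """
    if differences is not None:
        d = np.asarray(differences, dtype=float)
        nz = d[d != 0]
        if len(nz) < len(d):
            log.warning("dropped %d zero difference(s)", len(d) - len(nz))
        if len(nz) == 0:
            raise ValueError("all differences are zero")
        ranks = sps.rankdata(np.abs(nz))
        v = float(ranks[nz > 0].sum())
        n = len(nz)
    elif v is None or n is None:
        raise ValueError("provide differences or both v and n")
    else:
        ranks = np.arange(1, n + 1, dtype=float)
        v = float(v)
    if n < 1:
        raise ValueError("n must be >= 1")

    total = float(np.sum(ranks))
    if n <= EXACT_SIGNED_RANK_N:
        support, pmf = signed_rank_null_pmf(ranks)
        p_le = pmf[support <= v + 1e-9].sum()
        p_ge = pmf[support >= v - 1e-9].sum()
        p = min(1.0, 2 * min(p_le, p_ge))
        method = f"exact signed-rank null over 2^{n} sign assignments"
    else:
        mean = total / 2.0
        var = np.sum(np.asarray(ranks) ** 2) / 4.0
        z = (v - mean - 0.5 * np.sign(v - mean)) / np.sqrt(var)
        p = float(min(1.0, 2 * sps.norm.sf(abs(z))))
        method = "signed-rank normal approximation with continuity correction"
    return TestResult("V", v, n, float(p), method=method)


def _rank_sum_exact_cdf(n1: int, n2: int, u: float) -> tuple[float, float]:
    """P(U <= u) and P(U >= u) for untied ranks via subset-sum counting."""
    total = n1 + n2
    max_sum = n1 * total  # upper bound on a rank-sum of n1 of 1..total
    # ways[k, s]: subsets of size k of ranks seen so far with rank-sum s
    ways = np.zeros((n1 + 1, max_sum + 1))
    ways[0, 0] = 1.0
    for r in range(1, total + 1):
        ways[1:, r:] += ways[:-1, :-r or None].copy()
    counts = ways[n1]
    u_support = np.arange(max_sum + 1) - n1 * (n1 + 1) / 2.0
    norm = counts.sum()
    p_le = counts[u_support <= u + 1e-9].sum() / norm
    p_ge = counts[u_support >= u - 1e-9].sum() / norm
    return float(p_le), float(p_ge)


def wilcoxon_rank_sum(x, y, exact_threshold: int = 25) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    W is reported as the rank sum of ``x`` minus its minimum, so complete
    separation with every x below every y yields W = 0.  The p-value is
    exact (subset-sum enumeration) when there are no ties and the combined
    sample size does not exceed ``exact_threshold``; otherwise a normal
    approximation with tie correction and continuity correction is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    combined = np.concatenate([x, y])
    ranks = sps.rankdata(combined)
    n1, n2 = len(x), len(y)
    total = n1 + n2
    w = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)

    _, tie_counts = np.unique(combined, return_counts=True)
    has_ties = np.any(tie_counts > 1)
    if not has_ties and total <= exact_threshold:
        p_le, p_ge = _rank_sum_exact_cdf(n1, n2, w)
        p = min(1.0, 2 * min(p_le, p_ge))
        method = "exact rank-sum null by enumeration"
    else:
        mean = n1 * n2 / 2.0
        tie_term = np.sum(tie_counts**3 - tie_counts) / (total * (total - 1))
        var = n1 * n2 / 12.0 * (total + 1 - tie_term)
        if var == 0:
            return TestResult("W", w, None, 1.0,
                              method="rank-sum: all observations tied")
        z = (w - mean - 0.5 * np.sign(w - mean)) / np.sqrt(var)
        p = float(min(1.0, 2 * sps.norm.sf(abs(z))))
        method = "rank-sum normal approximation with tie/continuity correction"
    return TestResult("W", w, None, float(p), method=method)


def kruskal_wallis(groups: list) -> TestResult:
    """Kruskal-Wallis rank test with tie correction, df = k - 1."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    combined = np.concatenate(arrays)
    n_total = len(combined)
    ranks = sps.rankdata(combined)
    h = 0.0
    i = 0
    for g in arrays:
        r = ranks[i:i + len(g)]
        h += len(g) * (r.mean() - (n_total + 1) / 2.0) ** 2
        i += len(g)
    h *= 12.0 / (n_total * (n_total + 1))
    _, tie_counts = np.unique(combined, return_counts=True)
    correction = 1.0 - np.sum(tie_counts**3 - tie_counts) / (n_total**3 - n_total)
    if correction == 0:  # every observation identical
        return TestResult("chi2", 0.0, len(groups) - 1, 1.0,
                          method="Kruskal-Wallis (degenerate: all tied)")
    h /= correction
    df = len(groups) - 1
    return TestResult("chi2", float(h), df, float(sps.chi2.sf(h, df)),
                      method="Kruskal-Wallis rank sum with tie correction")


# ------------------------------------------------------- assumptions, outliers

def assumption_checks(groups: list) -> list[TestResult]:
    """Shapiro-Wilk normality per group plus mean-centered Levene test."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    results = []
    for i, g in enumerate(arrays):
        if len(g) < 3:
            raise ValueError(f"group {i}: Shapiro-Wilk needs n >= 3")
        if np.ptp(g) == 0:
            raise ValueError(f"group {i}: zero variance, normality undefined")
        w, p = sps.shapiro(g)
        results.append(TestResult("W", float(w), len(g), float(p),
                                  method=f"Shapiro-Wilk, group {i}"))
    if len(arrays) >= 2:
        f, p = sps.levene(*arrays, center="mean")
        df = (len(arrays) - 1, sum(map(len, arrays)) - len(arrays))
        results.append(TestResult("F", float(f), df, float(p),
                                  method="Levene (mean-centered)"))
    return results


def outlier_flags(x) -> np.ndarray:
    """1.5 x IQR outlier flags on standardized values (boxplot rule)."""
    x = np.asarray(x, dtype=float)
    sd = x.std(ddof=1)
    if sd == 0:
        return np.zeros(len(x), dtype=bool)
    z = (x - x.mean()) / sd
    q1, q3 = np.percentile(z, [25, 75])
    iqr = q3 - q1
    return (z < q1 - 1.5 * iqr) | (z > q3 + 1.5 * iqr)


def bonferroni(p_values, m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment: min(1, m * p)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if m is None:
        m = len(p)
    return np.minimum(1.0, m * p)


# ------------------------------------------------------- mixed model

@dataclass(frozen=True)
class LmmFit:
    """REML fit of a Gaussian random-intercept model."""

    fixed_effects: dict = field(default_factory=dict)
    cov_fixed: np.ndarray | None = None
    sigma_b2: float = 0.0     # random-intercept variance
    sigma_e2: float = 0.0     # residual variance
    wald_chi2: float = 0.0
    wald_df: int = 0
    wald_p: float = 1.0
    reml: float = 0.0

    @property
    def sigma_b(self) -> float:
        return float(np.sqrt(self.sigma_b2))


def _reml_pieces(lam: float, y, X, group_idx, group_sizes):
    """GLS quantities for V = I + lam * ZZ' using the block Woodbury form."""
    shrink = lam / (1.0 + lam * group_sizes)       # per group
    # V^-1 a = a - shrink_g * sum_g(a) within each group
    def vinv(a):
        sums = np.zeros((len(group_sizes),) + a.shape[1:])
        np.add.at(sums, group_idx, a)
        return a - (shrink[group_idx, None] * sums[group_idx]
                    if a.ndim == 2 else shrink[group_idx] * sums[group_idx])

    Xv = vinv(X)
    yv = vinv(y)
    xtvx = X.T @ Xv
    xtvy = X.T @ yv
    beta = np.linalg.solve(xtvx, xtvy)
    resid = y - X @ beta
    quad = float(resid @ vinv(resid))
    logdet_v = float(np.sum(np.log1p(lam * group_sizes)))
    return beta, xtvx, quad, logdet_v


def lmm_random_intercept(values, duet, species) -> LmmFit:
    """Random-intercept linear mixed model, REML, with a Wald test.

    ``values`` are repeated measurements (e.g. per-sequence durations),
    ``duet`` the id of the recording each came from (the random effect),
    ``species`` the fixed categorical factor.  The variance ratio
    sigma_b^2/sigma_e^2 is profiled out and optimized on a log grid; fixed
    effects are generalized least squares at the optimum.  The analysis of
    deviance for the species factor is a Wald chi-square on the non-
    intercept coefficients.
    """
    y = np.asarray(values, dtype=float)
    duet = np.asarray(duet)
    species = np.asarray(species)
    if not (len(y) == len(duet) == len(species)):
        raise ValueError("values, duet and species must have equal length")
    groups, group_idx = np.unique(duet, return_inverse=True)
    if len(groups) < 2:
        raise ValueError("need measurements from at least two duets")
    group_sizes = np.bincount(group_idx).astype(float)
    levels = sorted(set(species.tolist()))
    X = np.ones((len(y), len(levels)))
    for j, level in enumerate(levels[1:], start=1):
        X[:, j] = (species == level).astype(float)
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("singular fixed-effects design")

    def neg_reml(theta):
        lam = np.exp(theta)
        _, xtvx, quad, logdet_v = _reml_pieces(lam, y, X, group_idx, group_sizes)
        sigma_e2 = quad / (n - p)
        sign, logdet_x = np.linalg.slogdet(xtvx)
        return ((n - p) * np.log(sigma_e2) + logdet_v + logdet_x
                + (n - p))

    res = minimize_scalar(neg_reml, bounds=(-12.0, 12.0), method="bounded")
    lam = float(np.exp(res.x))
    # boundary check: with one measurement per duet the criterion is flat in
    # lambda and the intercept variance is not identified; take sigma_b2 = 0
    if neg_reml(-30.0) <= res.fun + 1e-8:
        lam = 0.0
    beta, xtvx, quad, _ = _reml_pieces(lam, y, X, group_idx, group_sizes)
    sigma_e2 = quad / (n - p)
    sigma_b2 = lam * sigma_e2
    cov = sigma_e2 * np.linalg.inv(xtvx)
    idx = np.arange(1, p)
    if len(idx):
        bs = beta[idx]
        chi2 = float(bs @ np.linalg.solve(cov[np.ix_(idx, idx)], bs))
        wald_df = len(idx)
        wald_p = float(sps.chi2.sf(chi2, wald_df))
    else:
        chi2, wald_df, wald_p = 0.0, 0, 1.0
    names = ["intercept"] + [f"species[{lv}]" for lv in levels[1:]]
    return LmmFit(fixed_effects=dict(zip(names, beta.tolist())),
                  cov_fixed=cov, sigma_b2=float(sigma_b2),
                  sigma_e2=float(sigma_e2), wald_chi2=chi2,
                  wald_df=wald_df, wald_p=wald_p,
                  reml=float(res.fun))


# ------------------------------------------------------- multivariate

def manova_tests(features, groups) -> list[TestResult]:
    """Wilks Lambda and Pillai trace with their F approximations.

    Both statistics derive from the eigenvalues of W^-1 B, where W and B
    are the within- and between-group scatter matrices.  For a two-group
    comparison there is a single discriminant dimension and Pillai = 1 -
    Lambda.
    """
    X = np.asarray(features, dtype=float)
    g = np.asarray(groups)
    if X.ndim != 2:
        raise ValueError("features must be an (n, p) matrix")
    n, p = X.shape
    levels = sorted(set(g.tolist()))
    k = len(levels)
    if k < 2:
        raise ValueError("need at least two groups")
    if n <= p + k:
        raise ValueError("too few samples for a p-variate MANOVA")
    grand = X.mean(axis=0)
    W = np.zeros((p, p))
    B = np.zeros((p, p))
    for level in levels:
        sub = X[g == level]
        m = sub.mean(axis=0)
        centered = sub - m
        W += centered.T @ centered
        B += len(sub) * np.outer(m - grand, m - grand)
    if np.linalg.matrix_rank(W) < p:
        raise ValueError("singular within-group scatter matrix")
    eigvals = np.linalg.eigvals(np.linalg.solve(W, B))
    eigvals = np.clip(eigvals.real, 0.0, None)

    q = k - 1               # hypothesis df
    v = n - k               # error df
    wilks = float(np.prod(1.0 / (1.0 + eigvals)))
    t = (np.sqrt((p**2 * q**2 - 4) / (p**2 + q**2 - 5))
         if p**2 + q**2 - 5 > 0 else 1.0)
    w_ = v + q - (p + q + 1) / 2.0
    df1_w = p * q
    df2_w = w_ * t - (p * q - 2) / 2.0
    lam_t = wilks ** (1.0 / t)
    f_wilks = (1 - lam_t) / lam_t * df2_w / df1_w
    p_wilks = float(sps.f.sf(f_wilks, df1_w, df2_w))

    s = min(p, q)
    pillai = float(np.sum(eigvals / (1.0 + eigvals)))
    m_ = (abs(p - q) - 1) / 2.0
    n_ = (v - p - 1) / 2.0
    df1_p = s * (2 * m_ + s + 1)
    df2_p = s * (2 * n_ + s + 1)
    f_pillai = (pillai / (s - pillai)) * (df2_p / df1_p)
    p_pillai = float(sps.f.sf(f_pillai, df1_p, df2_p))

    return [
        TestResult("Lambda", wilks, (df1_w, df2_w), p_wilks,
                   method=f"Wilks Lambda, Rao F approx (F={f_wilks:.3f})"),
        TestResult("Pillai", pillai, (df1_p, df2_p), p_pillai,
                   method=f"Pillai trace, F approx (F={f_pillai:.3f})"),
    ]


def pearson_correlation(x, y) -> TestResult:
    """Pearson r with its t statistic on n - 2 df."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need paired samples of length >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance: correlation undefined")
    r = float(np.corrcoef(x, y)[0, 1])
    df = len(x) - 2
    if abs(r) >= 1.0:
        return TestResult("r", r, df, 0.0, method="Pearson (perfect correlation)")
    t = r * np.sqrt(df / (1.0 - r**2))
    return TestResult("r", r, df, float(2 * sps.t.sf(abs(t), df)),
                      method=f"Pearson correlation (t={t:.3f})")
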