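"""Fixed-effects ANOVA with Tukey post hoc tests and assumption checks.

One-way ANOVA and a blocked two-way layout (two crossed factors plus an
additive subject block) are fitted by least squares on explicit design
matrices; Tukey (Tukey–Kramer on unbalanced cells) uses the studentized
range distribution.  Diagnostics cover Shapiro–Wilk normality, Levene
homogeneity (center = mean) and Mauchly sphericity on orthonormal
contrasts.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class TermResult:
    name: str
    df: int
    ss: float
    f: float
    p: float


@dataclass
class AnovaResult:
    terms: list[TermResult]
    residual_df: int
    residual_ss: float
    tukey: pd.DataFrame | None
    residuals: np.ndarray

    def term(self, name: str) -> TermResult:
        for t in self.terms:
            if t.name == name:
                return t
        raise KeyError(name)


def _tukey_table(means: dict, ns: dict, mse: float, df_error: int,
                 alpha: float = 0.05) -> pd.DataFrame:
    """Tukey–Kramer pairwise comparisons from cell means and sizes."""
    k = len(means)
    rows = []
    q_crit = sps.studentized_range.ppf(1 - alpha, k, df_error) if k >= 2 else np.nan
    for g1, g2 in itertools.combinations(means, 2):
        diff = means[g1] - means[g2]
        se = math.sqrt(mse / 2.0 * (1.0 / ns[g1] + 1.0 / ns[g2]))
        q = abs(diff) / se if se > 0 else np.inf
        p = float(sps.studentized_range.sf(q, k, df_error))
        half = q_crit * se
        rows.append({"group1": g1, "group2": g2, "diff": diff, "p_adj": p,
                     "ci_low": diff - half, "ci_high": diff + half})
    return pd.DataFrame(rows)


def one_way_anova_tukey(values, groups, tukey: bool = True,
                        alpha: float = 0.05) -> AnovaResult:
    """Classical one-way fixed-effects ANOVA with optional Tukey HSD."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if values.shape != groups.shape:
        raise ValueError("values and groups must align")
    names, inverse = np.unique(groups, return_inverse=True)
    if names.size < 2:
        raise ValueError("need >= 2 groups")
    ns = np.bincount(inverse)
    if (ns < 1).any():
        raise ValueError("every group needs >= 1 observation")
    n = values.size
    grand = values.mean()
    group_means = np.array([values[inverse == i].mean() for i in range(names.size)])
    ss_between = float((ns * (group_means - grand) ** 2).sum())
    residuals = values - group_means[inverse]
    ss_within = float((residuals ** 2).sum())
    df_between = names.size - 1
    df_within = n - names.size
    if df_within < 1:
        raise ValueError("no residual degrees of freedom")
    ms_between = ss_between / df_between
    ms_within = ss_within / df_within
    f = ms_between / ms_within if ms_within > 0 else np.inf
    p = float(sps.f.sf(f, df_between, df_within))
    table = None
    if tukey:
        if (ns < 2).any():
            raise ValueError("Tukey requires >= 2 observations per group")
        means = {g: m for g, m in zip(names, group_means)}
        sizes = {g: int(c) for g, c in zip(names, ns)}
        table = _tukey_table(means, sizes, ms_within, df_within, alpha)
    return AnovaResult(
        terms=[TermResult("group", df_between, ss_between, float(f), p)],
        residual_df=df_within, residual_ss=ss_within, tukey=table,
        residuals=residuals,
    )


def _dummies(codes: np.ndarray, n_levels: int) -> np.ndarray:
    """Treatment-coded dummies dropping the first level."""
    out = np.zeros((codes.size, n_levels - 1))
    for j in range(1, n_levels):
        out[codes == j, j - 1] = 1.0
    return out


def _rss(x: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    beta, _, rank, _ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    return float(resid @ resid), int(rank)


class AliasedDesignError(ValueError):
    """Raised when the block is confounded with a treatment factor."""


def two_way_anova_blocked(table: pd.DataFrame, *, factor_a: str = "marker",
                          factor_b: str = "region", block: str = "subject",
                          value: str = "value", ss_type: str = "II",
                          tukey: bool = True, alpha: float = 0.05) -> AnovaResult:
    """Two crossed fixed factors plus an additive block term.

    The model is value ~ block + A + B + A:B with a single residual
    stratum.  Sums of squares default to Type II; Type I (sequential) is
    available.  Tukey compares A-level cell means within each B level
    using the model MSE (Tukey–Kramer on unbalanced cells).
    """
    y = table[value].to_numpy(dtype=float)
    a_names, a_codes = np.unique(table[factor_a], return_inverse=True)
    b_names, b_codes = np.unique(table[factor_b], return_inverse=True)
    s_names, s_codes = np.unique(table[block], return_inverse=True)
    n = y.size
    xa = _dummies(a_codes, a_names.size)
    xb = _dummies(b_codes, b_names.size)
    xs = _dummies(s_codes, s_names.size)
    inter_codes = a_codes * b_names.size + b_codes
    cells = np.unique(inter_codes)
    xab = np.zeros((n, (a_names.size - 1) * (b_names.size - 1)))
    k = 0
    for i in range(1, a_names.size):
        for j in range(1, b_names.size):
            xab[:, k] = xa[:, i - 1] * xb[:, j - 1]
            k += 1
    icpt = np.ones((n, 1))

    def model(*parts):
        return np.hstack([icpt, *parts])

    # aliasing check first: the block must not absorb a factor
    _, rank_sab = _rss(model(xs, xa, xb), y)
    _, rank_sb = _rss(model(xs, xb), y)
    _, rank_sa = _rss(model(xs, xa), y)
    if rank_sab - rank_sb < a_names.size - 1:
        raise AliasedDesignError(f"block {block!r} is aliased with {factor_a!r}")
    if rank_sab - rank_sa < b_names.size - 1:
        raise AliasedDesignError(f"block {block!r} is aliased with {factor_b!r}")

    rss_full, rank_full = _rss(model(xs, xa, xb, xab), y)
    df_error = n - rank_full
    if df_error < 1:
        raise ValueError("design leaves no residual degrees of freedom")

    if ss_type == "II":
        rss_sb, _ = _rss(model(xs, xb), y)
        rss_sa, _ = _rss(model(xs, xa), y)
        rss_ab, _ = _rss(model(xa, xb), y)
        rss_sab, rank_sab_m = _rss(model(xs, xa, xb), y)
        ss_a = rss_sb - rss_sab
        ss_b = rss_sa - rss_sab
        ss_s = rss_ab - rss_sab
        ss_inter = rss_sab - rss_full
    elif ss_type == "I":
        rss0, _ = _rss(icpt, y)
        rss_s, _ = _rss(model(xs), y)
        rss_sa2, _ = _rss(model(xs, xa), y)
        rss_sab2, _ = _rss(model(xs, xa, xb), y)
        ss_s = rss0 - rss_s
        ss_a = rss_s - rss_sa2
        ss_b = rss_sa2 - rss_sab2
        ss_inter = rss_sab2 - rss_full
    else:
        raise ValueError("ss_type must be 'I' or 'II'")

    mse = rss_full / df_error
    df_a = a_names.size - 1
    df_b = b_names.size - 1
    df_s = s_names.size - 1
    df_ab = rank_full - (1 + df_s + df_a + df_b)

    def mk(name, ss, df):
        ss = max(ss, 0.0)
        if df <= 0:
            return TermResult(name, df, ss, np.nan, np.nan)
        f = (ss / df) / mse if mse > 0 else np.inf
        return TermResult(name, df, ss, float(f), float(sps.f.sf(f, df, df_error)))

    terms = [
        mk(block, ss_s, df_s),
        mk(factor_a, ss_a, df_a),
        mk(factor_b, ss_b, df_b),
        mk(f"{factor_a}:{factor_b}", ss_inter, df_ab),
    ]

    beta, _, _, _ = np.linalg.lstsq(model(xs, xa, xb, xab), y, rcond=None)
    residuals = y - model(xs, xa, xb, xab) @ beta

    tk = None
    if tukey:
        frames = []
        for j, b_level in enumerate(b_names):
            sel = b_codes == j
            sub = table[sel]
            means = sub.groupby(factor_a, observed=True)[value].mean().to_dict()
            sizes = sub.groupby(factor_a, observed=True)[value].size().to_dict()
            if len(means) >= 2 and all(v >= 1 for v in sizes.values()):
                t = _tukey_table(means, sizes, mse, df_error, alpha)
                t.insert(0, factor_b, b_level)
                frames.append(t)
        tk = pd.concat(frames, ignore_index=True) if frames else None

    return AnovaResult(terms=terms, residual_df=df_error, residual_ss=rss_full,
                       tukey=tk, residuals=residuals)


# ------------------------------------------------------------- diagnostics

@dataclass
class Diagnostics:
    shapiro_w: float | None = None
    shapiro_p: float | None = None
    levene_f: float | None = None
    levene_p: float | None = None
    mauchly_w: float | None = None
    mauchly_p: float | None = None
    notes: list[str] = field(default_factory=list)


def shapiro_w_statistic(x, coefficients) -> float:
    """Shapiro–Wilk W from explicit published coefficients.

    ``coefficients`` are the a_{n-i+1} weights for i = 1..floor(n/2) as
    tabulated (largest first).
    """
    x = np.sort(np.asarray(x, dtype=float))
    n = x.size
    a = np.asarray(coefficients, dtype=float)
    if a.size != n // 2:
        raise ValueError("need floor(n/2) coefficients")
    b = float((a * (x[::-1][: n // 2] - x[: n // 2])).sum())
    ss = float(((x - x.mean()) ** 2).sum())
    return b ** 2 / ss


def mauchly_test(wide: np.ndarray) -> tuple[float, float]:
    """Mauchly's sphericity W and chi-square p on orthonormal contrasts.

    ``wide`` is subjects × conditions.  With two conditions sphericity
    holds trivially (W = 1, p = 1).
    """
    wide = np.asarray(wide, dtype=float)
    n, k = wide.shape
    if k < 2:
        raise ValueError("need >= 2 within-subject conditions")
    if k == 2:
        return 1.0, 1.0
    # orthonormal contrasts spanning the space orthogonal to the unit vector
    q, _ = np.linalg.qr(np.hstack([np.ones((k, 1)), np.eye(k)[:, : k - 1]]))
    contrasts = q[:, 1:]
    z = wide @ contrasts
    s = np.cov(z, rowvar=False, ddof=1)
    d = k - 1
    w = float(np.linalg.det(s) / (np.trace(s) / d) ** d)
    w = min(max(w, np.finfo(float).tiny), 1.0)
    df = k * (k - 1) // 2 - 1
    factor = 1.0 - (2 * d * d + d + 2) / (6.0 * d * (n - 1))
    chi2 = -(n - 1) * factor * math.log(w)
    p = float(sps.chi2.sf(chi2, df))
    return w, p


def assumption_checks(residuals=None, groups=None, within=None) -> Diagnostics:
    """Run whichever diagnostics the supplied data allow.

    Insufficient data for one test leaves that test missing while the
    others still run.
    """
    diag = Diagnostics()
    if residuals is not None:
        residuals = np.asarray(residuals, dtype=float)
        if residuals.size >= 3:
            w, p = sps.shapiro(residuals)
            diag.shapiro_w, diag.shapiro_p = float(w), float(p)
        else:
            diag.notes.append("shapiro: need >= 3 residuals")
    if groups is not None:
        groups = [np.asarray(g, dtype=float) for g in groups]
        if len(groups) >= 2 and all(g.size >= 2 for g in groups):
            f, p = sps.levene(*groups, center="mean")
            diag.levene_f, diag.levene_p = float(f), float(p)
        else:
            diag.notes.append("levene: need >= 2 groups with >= 2 values")
    if within is not None:
        wide = np.asarray(within, dtype=float)
        if wide.ndim == 2 and wide.shape[1] >= 2 and wide.shape[0] >= 3:
            diag.mauchly_w, diag.mauchly_p = mauchly_test(wide)
        else:
            diag.notes.append("mauchly: need >= 3 subjects and >= 2 conditions")
    return diag
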