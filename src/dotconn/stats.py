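"""Group-level inference: normality-routed tests, effect sizes, FDR, ANOVA.

The layer's contribution is the *composition* the analysis needs — a
normality gate (Shapiro–Wilk per group at α = 0.05) that routes between
parametric and non-parametric tests, Hedges' g effect sizes with the
small-sample correction, Benjamini–Hochberg FDR over each family of
pairwise comparisons, an Aligned-Rank-Transform factorial ANOVA, partial
correlation, and the QC–FC motion diagnostic.  The canonical tests
themselves (Shapiro–Wilk, Welch t, Mann–Whitney, Kruskal–Wallis, one-way
ANOVA, χ², Tukey HSD) come from scipy/statsmodels.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "StatResult",
    "CorrelationResult",
    "ComparisonResult",
    "auto_compare_groups",
    "hedges_g",
    "bh_fdr",
    "chi_squared",
    "correlate",
    "partial_correlation",
    "two_way_anova",
    "art_anova",
    "qc_fc",
]


@dataclass
class StatResult:
    """One test: statistic, dof, raw and adjusted p, effect size, routing."""

    test: str
    statistic: float
    df: float | tuple | None
    p: float
    p_fdr: float | None = None
    effect: float | None = None
    effect_name: str | None = None
    routing: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("p must lie in [0, 1]")
        if self.p_fdr is not None and self.p_fdr < self.p - 1e-12:
            raise ValueError("adjusted p cannot be below raw p")


@dataclass
class CorrelationResult:
    """A (possibly partial) correlation with its test."""

    method: str
    coefficient: float
    p: float
    covariate: str | None = None

    def __post_init__(self) -> None:
        if not -1.0 <= self.coefficient <= 1.0:
            raise ValueError("coefficient must lie in [-1, 1]")


@dataclass
class ComparisonResult:
    """Omnibus result plus the FDR-corrected pairwise table."""

    omnibus: StatResult
    pairwise: pd.DataFrame  # group_a, group_b, test, statistic, p, p_fdr, g
    parametric: bool
    shapiro_p: dict[str, float]


def hedges_g(a: np.ndarray, b: np.ndarray) -> float:
    """Hedges' g: Cohen's d with the small-sample correction J = 1 − 3/(4N−9).

    Sign follows (mean(a) − mean(b)); location- and scale-invariant.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise ValueError("need at least two values per sample")
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if sp2 <= 0:
        raise ValueError("pooled standard deviation is zero")
    d = (a.mean() - b.mean()) / np.sqrt(sp2)
    j = 1.0 - 3.0 / (4.0 * (na + nb) - 9.0)
    return float(j * d)


def bh_fdr(p: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def chi_squared(table: np.ndarray | list[list[float]]) -> StatResult:
    """Pearson χ² of independence on a contingency table (no continuity correction)."""
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("need a table with at least 2 rows and 2 columns")
    if np.any(table < 0):
        raise ValueError("counts must be non-negative")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("table has a zero row or column margin")
    res = sps.chi2_contingency(table, correction=False)
    return StatResult(test="chi-squared", statistic=float(res.statistic), df=int(res.dof), p=float(res.pvalue))


def _shapiro_p(x: np.ndarray) -> float:
    if np.ptp(x) == 0:
        return 0.0  # degenerate; force the nonparametric route
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(sps.shapiro(x).pvalue)


def auto_compare_groups(
    groups: dict[str, np.ndarray], alpha_normality: float = 0.05
) -> ComparisonResult:
    """Compare ≥2 independent groups with normality-routed tests.

    All groups Gaussian by Shapiro–Wilk (p > ``alpha_normality``) → one-way
    ANOVA (Welch t for two groups); otherwise Kruskal–Wallis (Mann–Whitney
    for two).  Pairwise post-hocs use the same route, are BH-FDR corrected
    as one family, and carry Hedges' g.  A zero-variance group forces the
    non-parametric route with a warning.
    """
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need at least two groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for k, v in arrays.items():
        if len(v) < 3:
            raise ValueError(f"group {k!r} has fewer than three values")
        if np.ptp(v) == 0:
            warnings.warn(f"group {k!r} has zero variance: non-parametric route", stacklevel=2)

    shapiro = {k: _shapiro_p(v) for k, v in arrays.items()}
    parametric = all(p > alpha_normality for p in shapiro.values())
    routing = {"shapiro_p": shapiro, "parametric": parametric}

    vals = [arrays[k] for k in names]
    if parametric:
        if len(names) == 2:
            res = sps.ttest_ind(vals[0], vals[1], equal_var=False)
            omnibus = StatResult(
                test="welch-t", statistic=float(res.statistic), df=float(res.df), p=float(res.pvalue), routing=routing
            )
        else:
            res = sps.f_oneway(*vals)
            omnibus = StatResult(
                test="anova", statistic=float(res.statistic), df=(len(names) - 1, sum(map(len, vals)) - len(names)), p=float(res.pvalue), routing=routing
            )
    else:
        if len(names) == 2:
            res = sps.mannwhitneyu(vals[0], vals[1], alternative="two-sided")
            omnibus = StatResult(test="mann-whitney", statistic=float(res.statistic), df=None, p=float(res.pvalue), routing=routing)
        else:
            res = sps.kruskal(*vals)
            omnibus = StatResult(test="kruskal-wallis", statistic=float(res.statistic), df=len(names) - 1, p=float(res.pvalue), routing=routing)

    rows = []
    for a, b in itertools.combinations(names, 2):
        xa, xb = arrays[a], arrays[b]
        if parametric:
            r = sps.ttest_ind(xa, xb, equal_var=False)
            test, stat, p = "welch-t", float(r.statistic), float(r.pvalue)
        else:
            r = sps.mannwhitneyu(xa, xb, alternative="two-sided")
            test, stat, p = "mann-whitney", float(r.statistic), float(r.pvalue)
        try:
            g = hedges_g(xa, xb)
        except ValueError:
            g = float("nan")
        rows.append({"group_a": a, "group_b": b, "test": test, "statistic": stat, "p": p, "g": g})
    pairwise = pd.DataFrame(rows)
    if len(pairwise):
        pairwise["p_fdr"] = bh_fdr(pairwise["p"].to_numpy())
    return ComparisonResult(omnibus=omnibus, pairwise=pairwise, parametric=parametric, shapiro_p=shapiro)


def correlate(x: np.ndarray, y: np.ndarray, route: str = "auto") -> CorrelationResult:
    """Pearson or Spearman correlation; ``auto`` routes via per-variable Shapiro–Wilk."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("x and y must share a length of at least 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant input")
    if route == "auto":
        route = "pearson" if (_shapiro_p(x) > 0.05 and _shapiro_p(y) > 0.05) else "spearman"
    if route == "pearson":
        r = sps.pearsonr(x, y)
        return CorrelationResult(method="pearson", coefficient=float(r.statistic), p=float(r.pvalue))
    if route == "spearman":
        r = sps.spearmanr(x, y)
        return CorrelationResult(method="spearman", coefficient=float(r.statistic), p=float(r.pvalue))
    raise ValueError(f"unknown route {route!r}")


def partial_correlation(
    x: np.ndarray, y: np.ndarray, z: np.ndarray, covariate: str = "z"
) -> CorrelationResult:
    """First-order partial correlation of x and y controlling for z.

    r_xy·z = (r_xy − r_xz·r_yz) / sqrt((1−r_xz²)(1−r_yz²)); the p-value is
    the t-test on n−3 degrees of freedom.
    """
    x, y, z = (np.asarray(v, dtype=float) for v in (x, y, z))
    if not (x.shape == y.shape == z.shape) or x.size < 4:
        raise ValueError("x, y, z must share a length of at least 4")
    r_xy = float(np.corrcoef(x, y)[0, 1])
    r_xz = float(np.corrcoef(x, z)[0, 1])
    r_yz = float(np.corrcoef(y, z)[0, 1])
    if abs(r_xz) >= 1 - 1e-12 or abs(r_yz) >= 1 - 1e-12:
        raise ValueError("covariate is collinear with an input")
    r = (r_xy - r_xz * r_yz) / np.sqrt((1 - r_xz**2) * (1 - r_yz**2))
    n = x.size
    df = n - 3
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(df / (1 - r**2))
        p = float(2 * sps.t.sf(abs(t), df))
    return CorrelationResult(method="partial", coefficient=r, p=p, covariate=covariate)


def _anova_on(y: np.ndarray, a: np.ndarray, b: np.ndarray) -> pd.DataFrame:
    """Two-way factorial ANOVA table (A, B, A:B, residual) on ``y``.

    Uses a closed-form balanced decomposition when every cell has equal n,
    and a statsmodels type-II fit otherwise.
    """
    la, ua = pd.factorize(a, sort=True)
    lb, ub = pd.factorize(b, sort=True)
    n = len(y)
    cells = pd.DataFrame({"y": y, "a": la, "b": lb})
    counts = cells.groupby(["a", "b"]).size()
    if len(counts) < len(ua) * len(ub) or counts.min() < 2:
        raise ValueError("every factor cell needs at least two observations")
    balanced = counts.nunique() == 1

    if balanced:
        nc = int(counts.iloc[0])
        grand = y.mean()
        mean_a = cells.groupby("a")["y"].mean().to_numpy()
        mean_b = cells.groupby("b")["y"].mean().to_numpy()
        mean_ab = cells.groupby(["a", "b"])["y"].mean().unstack().to_numpy()
        ss_a = nc * len(ub) * np.sum((mean_a - grand) ** 2)
        ss_b = nc * len(ua) * np.sum((mean_b - grand) ** 2)
        ss_cells = nc * np.sum((mean_ab - grand) ** 2)
        ss_ab = ss_cells - ss_a - ss_b
        ss_tot = np.sum((y - grand) ** 2)
        ss_e = ss_tot - ss_cells
        df_a, df_b = len(ua) - 1, len(ub) - 1
        df_ab = df_a * df_b
        df_e = n - len(ua) * len(ub)
        rows = []
        for name, ss, df in (("A", ss_a, df_a), ("B", ss_b, df_b), ("A:B", ss_ab, df_ab)):
            ms = ss / df if df else np.nan
            mse = ss_e / df_e
            f = ms / mse if mse > 0 else np.inf
            p = float(sps.f.sf(f, df, df_e)) if np.isfinite(f) else 0.0
            rows.append({"effect": name, "ss": ss, "df": df, "F": f, "p": p, "eta2": ss / ss_tot if ss_tot > 0 else np.nan})
        rows.append({"effect": "residual", "ss": ss_e, "df": df_e, "F": np.nan, "p": np.nan, "eta2": np.nan})
        return pd.DataFrame(rows)

    import statsmodels.api as sm
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    df = pd.DataFrame({"y": y, "a": pd.Categorical(a), "b": pd.Categorical(b)})
    fit = smf.ols("y ~ C(a) * C(b)", data=df).fit()
    tab = anova_lm(fit, typ=2)
    ss_tot = tab["sum_sq"].sum()
    rows = []
    mapping = {"C(a)": "A", "C(b)": "B", "C(a):C(b)": "A:B", "Residual": "residual"}
    for key, name in mapping.items():
        row = tab.loc[key]
        rows.append(
            {
                "effect": name,
                "ss": float(row["sum_sq"]),
                "df": float(row["df"]),
                "F": float(row["F"]) if name != "residual" else np.nan,
                "p": float(row["PR(>F)"]) if name != "residual" else np.nan,
                "eta2": float(row["sum_sq"] / ss_tot) if name != "residual" else np.nan,
            }
        )
    return pd.DataFrame(rows)


def two_way_anova(
    y: np.ndarray, a: np.ndarray, b: np.ndarray, tukey_on: str = "a"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Plain two-way factorial ANOVA with η² plus Tukey HSD on one factor."""
    y = np.asarray(y, dtype=float)
    a = np.asarray(a)
    b = np.asarray(b)
    table = _anova_on(y, a, b)

    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    factor = a if tukey_on == "a" else b
    tk = pairwise_tukeyhsd(y, factor)
    tukey = pd.DataFrame(tk.summary().data[1:], columns=tk.summary().data[0])
    return table, tukey


def art_anova(y: np.ndarray, a: np.ndarray, b: np.ndarray) -> dict[str, StatResult]:
    """Aligned-Rank-Transform factorial ANOVA for two factors.

    For each effect the responses are aligned — the full cell mean is
    subtracted and the estimate of the effect of interest (from unweighted
    cell means) added back — then ranked, and a factorial ANOVA is run on
    the ranks; only the effect of interest's row is kept.  This gives a
    rank-based test of main effects and the interaction that preserves the
    nominal type-I error.
    """
    y = np.asarray(y, dtype=float)
    a = np.asarray(a)
    b = np.asarray(b)
    la, ua = pd.factorize(a, sort=True)
    lb, ub = pd.factorize(b, sort=True)
    cells = pd.DataFrame({"y": y, "a": la, "b": lb})
    counts = cells.groupby(["a", "b"]).size()
    if len(counts) < len(ua) * len(ub) or counts.min() < 2:
        raise ValueError("every factor cell needs at least two observations")

    cell_mean = cells.groupby(["a", "b"])["y"].mean().unstack().to_numpy()  # (la, lb)
    mu = cell_mean.mean()
    alpha = cell_mean.mean(axis=1) - mu
    beta = cell_mean.mean(axis=0) - mu
    gamma = cell_mean - mu - alpha[:, None] - beta[None, :]
    resid = y - cell_mean[la, lb]

    estimates = {"A": alpha[la], "B": beta[lb], "A:B": gamma[la, lb]}
    out: dict[str, StatResult] = {}
    for effect, est in estimates.items():
        aligned = resid + est
        ranks = sps.rankdata(aligned)
        tab = _anova_on(ranks, a, b)
        row = tab[tab["effect"] == effect].iloc[0]
        out[effect] = StatResult(
            test=f"art-anova[{effect}]",
            statistic=float(row["F"]),
            df=(float(row["df"]), float(tab[tab["effect"] == "residual"]["df"].iloc[0])),
            p=float(row["p"]),
            effect=float(row["eta2"]),
            effect_name="eta2_rank",
        )
    return out


def qc_fc(
    cms: list,
    burdens: np.ndarray | list[float],
    centroids: dict[int, np.ndarray],
) -> pd.DataFrame:
    """QC–FC diagnostic: per-edge correlation of strength with motion burden.

    For every edge observed in ≥ 4 subjects, the across-subject Pearson r
    between its Fisher-z value and the subjects' motion burden is computed
    and paired with the inter-centroid Euclidean distance.  Constant
    burdens make every correlation undefined: an empty table is returned
    with a warning.  Output rows are sorted by distance.
    """
    burdens = np.asarray(burdens, dtype=float)
    if len(cms) != len(burdens):
        raise ValueError("one burden per subject required")
    if len(cms) < 4:
        raise ValueError("QC-FC needs at least four subjects")
    if np.ptp(burdens) == 0:
        warnings.warn("motion burdens are constant: QC-FC undefined", stacklevel=2)
        return pd.DataFrame(columns=["parcel_i", "parcel_j", "distance", "r"])

    edge_vals: dict[tuple[int, int], list[tuple[float, float]]] = {}
    for cm, burden in zip(cms, burdens):
        ids = [int(p) for p in cm.parcel_ids]
        for ai in range(len(ids)):
            for bi in range(ai + 1, len(ids)):
                key = (min(ids[ai], ids[bi]), max(ids[ai], ids[bi]))
                edge_vals.setdefault(key, []).append((float(cm.z[ai, bi]), float(burden)))

    rows = []
    for (i, j), vals in edge_vals.items():
        if len(vals) < 4:
            continue
        zs = np.array([v[0] for v in vals])
        bs = np.array([v[1] for v in vals])
        if np.ptp(zs) == 0 or np.ptp(bs) == 0:
            continue
        r = float(np.corrcoef(zs, bs)[0, 1])
        dist = float(np.linalg.norm(np.asarray(centroids[i]) - np.asarray(centroids[j])))
        rows.append({"parcel_i": i, "parcel_j": j, "distance": dist, "r": r})
    out = pd.DataFrame(rows, columns=["parcel_i", "parcel_j", "distance", "r"])
    return out.sort_values("distance", kind="stable").reset_index(drop=True)
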