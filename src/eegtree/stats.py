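"""Group/condition statistics and behavior correlations.

The analysis route per metric follows a normality gate: metrics are
log-transformed, Shapiro-Wilk is run per group x band cell, and any
rejection at alpha = 0.05 sends the metric down the aligned-rank-transform
(ART) route; otherwise a parametric 2 (condition, within) x 3 (group,
between) mixed ANOVA is used.  Age and IQ enter both routes by
residualizing the response on them (pooled OLS) before the factorial
model — ANCOVA has no canonical aligned-rank form, so the same adjustment
is applied on both routes for comparability.

The ART route implements the classic align-then-rank recipe: for each
effect (group, condition, interaction), the response is aligned by
stripping the estimates of every *other* effect, the aligned values are
ranked across the whole dataset, and the full factorial ANOVA is run on
the ranks; only the row for the aligned-for effect is interpreted.

Behavior correlations are Pearson r with a permutation null (subject
labels reshuffled), two-sided, with Bonferroni correction across the
tested metric family.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "transform_and_gate",
    "mixed_anova",
    "art_anova",
    "posthoc_bonferroni",
    "perm_correlation",
    "bonferroni",
    "StatReport",
]

ALPHA = 0.05


def bonferroni(p: float, n_family: int) -> float:
    """min(1, p * family size)."""
    if n_family < 1:
        raise ValueError("empty comparison family")
    return min(1.0, float(p) * n_family)


def transform_and_gate(
    df: pd.DataFrame,
    metric: str,
    cell_cols: tuple[str, ...] = ("group",),
    alpha: float = ALPHA,
) -> tuple[str, pd.DataFrame]:
    """Log-transform, Shapiro-Wilk per cell, and choose the ANOVA route.

    Returns ``(route, gate_table)`` where route is ``"parametric"`` if no
    cell rejects normality at ``alpha`` and ``"ART"`` otherwise.  Cells
    with fewer than 3 observations or zero variance are flagged
    non-testable (they do not trigger the ART route on their own).

    Raises
    ------
    ValueError
        If any value is non-positive (the log transform presumes strictly
        positive connectivity/topology metrics).
    """
    vals = df[metric].to_numpy(dtype=float)
    if np.any(~np.isfinite(vals)):
        raise ValueError(f"non-finite values in {metric!r}")
    if np.any(vals <= 0):
        raise ValueError(
            f"non-positive values in {metric!r}; log transform undefined"
        )
    work = df.assign(_log=np.log(vals))
    rows = []
    any_reject = False
    for keys, cell in work.groupby(list(cell_cols), observed=True):
        keys = keys if isinstance(keys, tuple) else (keys,)
        x = cell["_log"].to_numpy()
        if len(x) < 3 or np.ptp(x) == 0:
            rows.append((*keys, len(x), np.nan, np.nan, "non-testable"))
            continue
        w, p = sps.shapiro(x)
        reject = p < alpha
        any_reject |= bool(reject)
        rows.append((*keys, len(x), float(w), float(p),
                     "reject" if reject else "normal"))
    gate = pd.DataFrame(
        rows, columns=[*cell_cols, "n", "W", "p", "status"]
    )
    return ("ART" if any_reject else "parametric"), gate


def _residualize(
    df: pd.DataFrame, dv: str, covariates: tuple[str, ...]
) -> np.ndarray:
    """Residuals of dv on the covariates (pooled OLS, intercept included),
    re-centered at the grand mean so the scale is preserved."""
    y = df[dv].to_numpy(dtype=float)
    if not covariates:
        return y
    X = np.column_stack(
        [np.ones(len(df))] + [df[c].to_numpy(dtype=float) for c in covariates]
    )
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(f"rank-deficient covariates {covariates}")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return resid + y.mean()


def _check_design(
    df: pd.DataFrame, subject: str, within: str, between: str
) -> None:
    counts = df.groupby(subject, observed=True)[within].nunique()
    n_levels = df[within].nunique()
    if (counts != n_levels).any():
        missing = counts[counts != n_levels].index.tolist()
        raise ValueError(f"missing {within} rows for subject(s) {missing}")
    if df[between].nunique() < 2:
        raise ValueError("need at least 2 groups")


def _pg_mixed(df: pd.DataFrame, dv: str, within: str, subject: str,
              between: str) -> pd.DataFrame:
    import pingouin as pg

    aov = pg.mixed_anova(data=df, dv=dv, within=within, subject=subject,
                         between=between)
    aov = aov.rename(columns={"Source": "effect", "p-unc": "p",
                              "p_unc": "p", "np2": "eta_sq"})
    aov["effect"] = aov["effect"].replace({
        between: "group", within: "condition", "Interaction": "interaction",
    })
    return aov[["effect", "F", "DF1", "DF2", "p", "eta_sq"]]


def mixed_anova(
    df: pd.DataFrame,
    metric: str,
    covariates: tuple[str, ...] = ("age", "iq"),
    subject: str = "subject_id",
    within: str = "condition",
    between: str = "group",
) -> pd.DataFrame:
    """Parametric 2 x 3 mixed ANOVA on the covariate-adjusted metric.

    Returns one row per effect (group, condition, interaction) with
    columns ``effect, F, DF1, DF2, p, eta_sq, route``.
    """
    _check_design(df, subject, within, between)
    work = df.copy()
    work["_adj"] = _residualize(work, metric, covariates)
    aov = _pg_mixed(work, "_adj", within, subject, between)
    aov["route"] = "parametric"
    return aov


def art_anova(
    df: pd.DataFrame,
    metric: str,
    covariates: tuple[str, ...] = ("age", "iq"),
    subject: str = "subject_id",
    within: str = "condition",
    between: str = "group",
    effects: tuple[str, ...] = ("group", "condition", "interaction"),
) -> pd.DataFrame:
    """Aligned-rank-transform mixed ANOVA (nonparametric route).

    For each effect the response is aligned by subtracting the cell mean
    and adding back that effect's own estimate, ranked over the full
    dataset, and the standard mixed ANOVA is applied to the ranks; the
    returned table keeps only each effect's own row.  ``effects`` can
    restrict which effects are aligned and tested.
    """
    _check_design(df, subject, within, between)
    work = df.copy()
    y = _residualize(work, metric, covariates)
    work["_y"] = y

    grand = y.mean()
    cell_mean = work.groupby([between, within], observed=True)["_y"].transform("mean")
    a_mean = work.groupby(between, observed=True)["_y"].transform("mean")
    b_mean = work.groupby(within, observed=True)["_y"].transform("mean")

    estimates = {
        "group": a_mean - grand,
        "condition": b_mean - grand,
        "interaction": cell_mean - a_mean - b_mean + grand,
    }
    resid = work["_y"] - cell_mean
    rows = []
    for name in effects:
        aligned = (resid + estimates[name]).to_numpy()
        if np.ptp(aligned) == 0:
            # every aligned value ties (e.g. constant data): no evidence
            rows.append(pd.DataFrame(
                [[name, 0.0, np.nan, np.nan, 1.0, 0.0]],
                columns=["effect", "F", "DF1", "DF2", "p", "eta_sq"],
            ))
            continue
        work["_rank"] = sps.rankdata(aligned)
        aov = _pg_mixed(work, "_rank", within, subject, between)
        rows.append(aov[aov["effect"] == name])
    out = pd.concat(rows, ignore_index=True)
    out["route"] = "ART"
    return out


def posthoc_bonferroni(
    df: pd.DataFrame,
    metric: str,
    covariates: tuple[str, ...] = ("age", "iq"),
    within: str = "condition",
    between: str = "group",
) -> pd.DataFrame:
    """Pairwise group comparisons within each condition, Bonferroni-corrected.

    Welch two-sample t-tests on the covariate-adjusted metric; the
    correction family is the set of group pairs within one condition.
    """
    work = df.copy()
    work["_adj"] = _residualize(work, metric, covariates)
    groups = sorted(work[between].unique())
    pairs = [(a, b) for k, a in enumerate(groups) for b in groups[k + 1:]]
    if not pairs:
        raise ValueError("need at least two groups for post-hoc tests")
    rows = []
    for cond, sub in work.groupby(within, observed=True):
        for a, b in pairs:
            xa = sub.loc[sub[between] == a, "_adj"].to_numpy()
            xb = sub.loc[sub[between] == b, "_adj"].to_numpy()
            t, p = sps.ttest_ind(xa, xb, equal_var=False)
            rows.append((cond, a, b, float(t), float(p),
                         bonferroni(p, len(pairs))))
    return pd.DataFrame(
        rows, columns=[within, "group_a", "group_b", "t", "p", "p_corr"]
    )


def perm_correlation(
    x: np.ndarray,
    y: np.ndarray,
    n_perm: int = 5000,
    seed: int | np.random.Generator | None = None,
) -> tuple[float, float]:
    """Pearson r with a two-sided permutation p-value.

    The null reshuffles the pairing of subjects ``n_perm`` times;
    p = (1 + #{|r_perm| >= |r_obs|}) / (1 + n_perm), which is a valid
    (conservative) p-value for any number of permutations.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and equally long")
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in x or y")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    xc = (x - x.mean()) / x.std()
    yc = (y - y.mean()) / y.std()
    r_obs = float(np.dot(xc, yc) / n)
    perms = np.empty(n_perm)
    for k in range(n_perm):
        perms[k] = np.dot(xc, rng.permutation(yc)) / n
    p = (1.0 + np.count_nonzero(np.abs(perms) >= abs(r_obs) - 1e-12)) / (1.0 + n_perm)
    return r_obs, float(p)


@dataclass
class StatReport:
    """Bundle of the statistical stage's outputs for one analysis run."""

    routes: pd.DataFrame        # metric x band -> route + gate detail
    anova: pd.DataFrame         # one row per metric x band x effect
    posthoc: pd.DataFrame       # pairwise tables for significant interactions
    correlations: pd.DataFrame  # metric x band vs behavior, permutation p
    alpha: float = ALPHA
    n_perm: int = 5000
    seed: int | None = None

    def significant(self, effect: str = "interaction") -> pd.DataFrame:
        a = self.anova
        return a[(a["effect"] == effect) & (a["p"] < self.alpha)]
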