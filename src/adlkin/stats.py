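"""Group comparisons, inter-task correlations and frailty-score regression.

The cohort table — one row per participant, the nine kinematic
parameters per task plus a per-participant task average — is compared
across frailty groups with classical one-way ANOVAs (partial η² effect
sizes, Tukey HSD post hoc with Cohen's d), supplemented by a
permutation-based multivariate group test (sum of per-parameter F
statistics, group labels shuffled).  Task specificity is estimated by
Pearson correlations of each parameter between the two tasks, and the
0–5 frailty score is modelled by forward-stepwise multiple linear
regression with standardized coefficients and a variance-inflation
guard.

Tests are two-sided; no correction is applied across the nine
parameters.  Analyses are complete-case per comparison; undefined
feature values (NaN) drop the affected rows only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .errors import ValidationError
from .features import PARAMETERS

GROUP_ORDER = ("R", "P", "F")
SCOPES = ("task_average", "TEA", "GARDEN")


def scope_column(parameter: str, scope: str) -> str:
    """Column name of a parameter under a scope (task or task average)."""
    if scope == "task_average":
        return f"{parameter}_avg"
    if scope in ("TEA", "GARDEN"):
        return f"{parameter}_{scope}"
    raise ValidationError(f"unknown scope {scope!r}")


@dataclass
class GroupComparison:
    parameter: str
    F: float
    df: tuple[int, int]
    p: float
    eta2p: float
    posthoc: list[tuple[str, float, float]] = field(default_factory=list)


@dataclass
class InterTaskCorrelation:
    parameter: str
    r: float
    p: float
    n: int


@dataclass
class RegressionModel:
    response: str
    scope: str
    selected: list[str]
    beta_std: dict[str, float]
    R2: float
    R2_adj: float
    model_p: float
    vif: dict[str, float]


def build_cohort_table(features: pd.DataFrame, manifest: pd.DataFrame) -> pd.DataFrame:
    """Pivot per-recording features into one row per participant.

    ``features`` has columns participant_id, task and the nine
    parameters; ``manifest`` supplies group and fried_score.  Duplicate
    participant×task rows are an error (each task is performed once).
    """
    if features.duplicated(["participant_id", "task"]).any():
        raise ValidationError("duplicate participant×task rows in features")
    wide = features.pivot(index="participant_id", columns="task", values=list(PARAMETERS))
    wide.columns = [f"{param}_{task}" for param, task in wide.columns]
    meta = (
        manifest[["participant_id", "group", "fried_score"]]
        .drop_duplicates("participant_id")
        .set_index("participant_id")
    )
    table = meta.join(wide, how="inner").reset_index()
    return table


def task_average(table: pd.DataFrame, tasks: tuple[str, str] = ("TEA", "GARDEN")) -> pd.DataFrame:
    """Add per-participant ``<param>_avg`` columns (mean of the two tasks).

    Rows missing either task keep NaN in the averaged columns and are
    flagged in a boolean ``complete`` column, which excludes them from
    averaged analyses downstream.
    """
    out = table.copy()
    complete = pd.Series(True, index=out.index)
    for param in PARAMETERS:
        a, b = f"{param}_{tasks[0]}", f"{param}_{tasks[1]}"
        out[f"{param}_avg"] = (out[a] + out[b]) / 2.0
        complete &= out[a].notna() & out[b].notna()
    out["complete"] = complete
    return out


def one_way_anova(values: np.ndarray, groups: np.ndarray, parameter: str = "") -> GroupComparison:
    """Classical one-way ANOVA with partial η² = SSB / (SSB + SSW)."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    keep = np.isfinite(values)
    values, groups = values[keep], groups[keep]
    labels, counts = np.unique(groups, return_counts=True)
    if labels.size < 2:
        raise ValidationError("ANOVA requires at least 2 groups")
    if (counts < 2).any():
        small = labels[counts < 2].tolist()
        raise ValidationError(f"groups with < 2 observations: {small}")
    grand = values.mean()
    ssb = ssw = 0.0
    for lab in labels:
        x = values[groups == lab]
        ssb += x.size * (x.mean() - grand) ** 2
        ssw += np.sum((x - x.mean()) ** 2)
    dfb, dfw = labels.size - 1, values.size - labels.size
    if ssw == 0.0:
        F = np.inf if ssb > 0 else 0.0
        p = 0.0 if ssb > 0 else 1.0
    else:
        F = (ssb / dfb) / (ssw / dfw)
        p = float(sps.f.sf(F, dfb, dfw))
    eta2p = ssb / (ssb + ssw) if (ssb + ssw) > 0 else 0.0
    return GroupComparison(parameter, float(F), (dfb, dfw), p, float(eta2p))


def cohen_d(x: np.ndarray, y: np.ndarray) -> float:
    """Standardized mean difference with pooled (n−2) SD denominator."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    nx, ny = x.size, y.size
    pooled = np.sqrt(((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2))
    if pooled == 0:
        return 0.0 if x.mean() == y.mean() else float("inf")
    return float((x.mean() - y.mean()) / pooled)


def tukey_posthoc(values: np.ndarray, groups: np.ndarray) -> list[tuple[str, float, float]]:
    """Tukey HSD pairwise tests with Cohen's d per pair.

    Returns (pair, p_adjusted, d) tuples; pairs follow the canonical
    R-P, R-F, P-F order where those labels are present.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    keep = np.isfinite(values)
    values, groups = values[keep], groups[keep]
    labels = [g for g in GROUP_ORDER if g in groups] or sorted(set(groups))
    samples = [values[groups == lab] for lab in labels]
    if any(s.size < 2 for s in samples):
        raise ValidationError("Tukey HSD requires >= 2 observations per group")
    res = sps.tukey_hsd(*samples)
    out = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            out.append(
                (
                    f"{labels[i]}-{labels[j]}",
                    float(res.pvalue[i, j]),
                    cohen_d(samples[i], samples[j]),
                )
            )
    return out


def _sum_of_f(X: np.ndarray, onehot: np.ndarray) -> np.ndarray:
    """Sum over columns of ANOVA F, for a stack of label assignments.

    ``onehot`` has shape (n_assignments, n, k); returns one statistic
    per assignment.  Group sizes are constant across permutations, so
    everything reduces to group sums.
    """
    n, p = X.shape
    k = onehot.shape[2]
    counts = onehot[0].sum(axis=0)  # same for every permutation
    tot = X.sum(axis=0)
    ss_tot = np.sum(X**2, axis=0) - tot**2 / n
    S = np.einsum("ang,np->agp", onehot, X)
    ssb = np.sum(S**2 / counts[None, :, None], axis=1) - tot[None, :] ** 2 / n
    ssw = ss_tot[None, :] - ssb
    dfb, dfw = k - 1, n - k
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ssb / dfb) / (ssw / dfw)
    F = np.nan_to_num(F, nan=0.0, posinf=0.0)
    return F.sum(axis=1)


def multivariate_group_test(
    table: pd.DataFrame,
    columns: list[str] | None = None,
    group_col: str = "group",
    n_perm: int = 10_000,
    seed: int | None = None,
) -> tuple[float, float]:
    """Permutation multivariate group test.

    The statistic is the sum over parameters of the one-way ANOVA F
    statistic (each parameter standardized, which leaves F unchanged but
    keeps the statistic's scale interpretable); its null distribution is
    obtained by shuffling group labels.  Returns (statistic, p) with the
    add-one permutation p-value.
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives a very coarse p-value", stacklevel=2)
    if columns is None:
        columns = [scope_column(p, "task_average") for p in PARAMETERS]
    sub = table[columns + [group_col]].dropna()
    X = sub[columns].to_numpy(float)
    X = (X - X.mean(axis=0)) / np.where(X.std(axis=0) > 0, X.std(axis=0), 1.0)
    labels = sub[group_col].to_numpy()
    uniq = [g for g in GROUP_ORDER if g in labels] or sorted(set(labels))
    lab_idx = np.array([uniq.index(g) for g in labels])
    n, k = X.shape[0], len(uniq)
    base = np.eye(k)[lab_idx]  # n × k one-hot

    obs = float(_sum_of_f(X, base[None])[0])
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(n) for _ in range(n_perm)])
    onehot = base[perms]  # (n_perm, n, k)
    null = _sum_of_f(X, onehot)
    p = float((1 + np.sum(null >= obs)) / (1 + n_perm))
    return obs, p


def inter_task_correlation(table: pd.DataFrame, parameter: str) -> InterTaskCorrelation:
    """Pearson correlation of a parameter between the TEA and GARDEN task."""
    a = table[scope_column(parameter, "TEA")]
    b = table[scope_column(parameter, "GARDEN")]
    keep = a.notna() & b.notna()
    x, y = a[keep].to_numpy(float), b[keep].to_numpy(float)
    if x.size < 3:
        raise ValidationError("inter-task correlation requires >= 3 complete pairs")
    if x.std() == 0 or y.std() == 0:
        return InterTaskCorrelation(parameter, float("nan"), float("nan"), x.size)
    r, p = sps.pearsonr(x, y)
    return InterTaskCorrelation(parameter, float(r), float(p), x.size)


def _vifs(X: pd.DataFrame) -> dict[str, float]:
    """Variance inflation factors of the predictors (with intercept)."""
    if X.shape[1] < 2:
        return {c: 1.0 for c in X.columns}
    from statsmodels.stats.outliers_influence import variance_inflation_factor

    Z = sm.add_constant(X.to_numpy(float))
    return {
        c: float(variance_inflation_factor(Z, i + 1)) for i, c in enumerate(X.columns)
    }


def stepwise_mlr(
    table: pd.DataFrame,
    predictors: list[str] | None = None,
    scope: str = "task_average",
    response: str = "fried_score",
    entry_p: float = 0.05,
    removal_p: float = 0.10,
    vif_limit: float = 5.0,
) -> RegressionModel:
    """Forward-stepwise multiple linear regression of the frailty score.

    Candidates enter by smallest partial p-value while p ≤ ``entry_p``
    and no variance inflation factor of the resulting model reaches
    ``vif_limit``; after each entry, predictors whose p-value has risen
    to ``removal_p`` or beyond are removed.  Coefficients are reported
    standardized (fit on z-scored response and predictors).
    """
    if predictors is None:
        predictors = list(PARAMETERS)
    cols = {p: scope_column(p, scope) for p in predictors}
    sub = table[[response, *cols.values()]].dropna()
    y = sub[response].astype(float)
    X = sub[list(cols.values())].astype(float)
    X.columns = list(cols)  # short parameter names
    X = X.loc[:, X.std() > 0]
    if sub.shape[0] <= 2:
        raise ValidationError("too few complete rows for regression")

    selected: list[str] = []
    while True:
        remaining = [c for c in X.columns if c not in selected]
        best, best_p = None, np.inf
        scores = []
        for cand in remaining:
            fit = sm.OLS(y, sm.add_constant(X[selected + [cand]])).fit()
            scores.append((fit.pvalues[cand], cand))
        for p_val, cand in sorted(scores):
            if p_val > entry_p:
                break
            if max(_vifs(X[selected + [cand]]).values()) >= vif_limit:
                continue  # collinear candidate: excluded
            best, best_p = cand, p_val
            break
        if best is None:
            break
        selected.append(best)
        # backward pass
        while len(selected) > 1:
            fit = sm.OLS(y, sm.add_constant(X[selected])).fit()
            pvals = fit.pvalues.drop("const")
            worst = pvals.idxmax()
            if pvals[worst] < removal_p:
                break
            selected.remove(worst)
        if len(selected) >= sub.shape[0] - 2:
            break

    if not selected:
        return RegressionModel(response, scope, [], {}, 0.0, 0.0, float("nan"), {})

    fit = sm.OLS(y, sm.add_constant(X[selected])).fit()
    z = lambda s: (s - s.mean()) / s.std(ddof=1)
    zfit = sm.OLS(z(y), sm.add_constant(X[selected].apply(z))).fit()
    beta = {c: float(zfit.params[c]) for c in selected}
    return RegressionModel(
        response=response,
        scope=scope,
        selected=list(selected),
        beta_std=beta,
        R2=float(fit.rsquared),
        R2_adj=float(fit.rsquared_adj),
        model_p=float(fit.f_pvalue),
        vif=_vifs(X[selected]),
    )


def pooled_mean(means, ns) -> float:
    """Size-weighted pooled mean of subgroup means."""
    means = np.asarray(means, float)
    ns = np.asarray(ns, float)
    return float(np.sum(means * ns) / np.sum(ns))


def compare_groups(table: pd.DataFrame, scope: str) -> list[GroupComparison]:
    """One-way ANOVA + Tukey post hoc for every parameter under a scope."""
    out = []
    for param in PARAMETERS:
        col = scope_column(param, scope)
        sub = table[[col, "group"]].dropna()
        gc = one_way_anova(sub[col].to_numpy(), sub["group"].to_numpy(), parameter=param)
        gc.posthoc = tukey_posthoc(sub[col].to_numpy(), sub["group"].to_numpy())
        out.append(gc)
    return out
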