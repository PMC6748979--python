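"""Cohort-level statistics for the 40 Minkowski features.

The analysis layer mirrors how morphometric feature tables are related to age:
features are z-scored, summarized by PCA (with biplot loadings), compared
between age groups by pairwise one-way ANOVA with Bonferroni correction, and
screened for age-predictive subsets by a bootstrapped, repeated form of
classical forward–backward stepwise linear regression.  Feature importance is
read from the frequency at which each feature is selected across resamples,
restricted to "conservative" models of 2–4 variables.

All procedures are deterministic given (data, seed); repeat seeds are split
with a counter-based scheme.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA as _SkPCA

from .core_io import FEATURE_NAMES, SampleTable

__all__ = [
    "PCAResult",
    "StepwiseReport",
    "zscore",
    "pca",
    "age_groups",
    "AGE_GROUP_EDGES",
    "anova_pairwise",
    "stepwise_ols",
    "bootstrap_stepwise",
]

#: Default age-group bin edges (years); half-open bins [lo, hi) giving the six
#: groups 5–44, 45–54, 55–69, 70–74, 75–79 and 80–84.
AGE_GROUP_EDGES = (5.0, 45.0, 55.0, 70.0, 75.0, 80.0, 85.0)

#: Default lower age bound for the age-regression analysis (near-linear range).
REGRESSION_MIN_AGE = 40.0


def zscore(table: SampleTable) -> SampleTable:
    """Standardize every feature column to mean 0, SD 1 (sample SD, n−1).

    Raises on constant columns, naming the offender.  Idempotent to floating
    precision.
    """
    if len(table) < 2:
        raise ValueError("z-scoring needs at least 2 samples")
    df = table.data.copy()
    feats = df[list(FEATURE_NAMES)]
    sd = feats.std(ddof=1)
    constant = sd.index[sd == 0].tolist()
    if constant:
        raise ValueError(f"constant feature column(s): {constant}")
    df[list(FEATURE_NAMES)] = (feats - feats.mean()) / sd
    # var/std entries are themselves features here; the z-scored table is a
    # plain numeric matrix, so bypass FeatureVector-style invariants
    out = SampleTable.__new__(SampleTable)
    out.data = df
    return out


@dataclass
class PCAResult:
    """Principal-component decomposition of the z-scored feature table."""

    scores: pd.DataFrame            # samples x components
    loadings: pd.DataFrame          # features x components (orthonormal)
    explained_variance_ratio: np.ndarray

    def __post_init__(self):
        evr = np.asarray(self.explained_variance_ratio, dtype=np.float64)
        if np.any(evr < -1e-12) or evr.sum() > 1 + 1e-9:
            raise ValueError("explained-variance fractions must lie in [0,1], sum <= 1")
        L = self.loadings.to_numpy()
        if not np.allclose(L.T @ L, np.eye(L.shape[1]), atol=1e-9):
            raise ValueError("loading vectors must be orthonormal")
        self.explained_variance_ratio = evr


def pca(table: SampleTable, n_components: int | None = None) -> PCAResult:
    """PCA of the feature columns (call on a z-scored table).

    Sign convention: within each component the largest-magnitude loading is
    made positive, so results are reproducible across LAPACK builds.
    """
    n = len(table)
    if n < 3:
        raise ValueError("PCA needs at least 3 samples")
    X = table.features.to_numpy(dtype=np.float64)
    k = n_components or min(X.shape[0] - 1, X.shape[1])
    model = _SkPCA(n_components=k, svd_solver="full")
    scores = model.fit_transform(X)
    loadings = model.components_.T  # features x components
    for j in range(loadings.shape[1]):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    comp_names = [f"PC{j + 1}" for j in range(loadings.shape[1])]
    return PCAResult(
        scores=pd.DataFrame(scores, index=table.data.index, columns=comp_names),
        loadings=pd.DataFrame(loadings, index=list(FEATURE_NAMES), columns=comp_names),
        explained_variance_ratio=model.explained_variance_ratio_,
    )


def age_groups(ages, edges=AGE_GROUP_EDGES) -> np.ndarray:
    """Assign ages to half-open bins [lo, hi); default: the six study groups."""
    ages = np.asarray(ages, dtype=np.float64)
    edges = np.asarray(edges, dtype=np.float64)
    bad = (ages < edges[0]) | (ages >= edges[-1])
    if bad.any():
        idx = np.nonzero(bad)[0]
        raise ValueError(
            f"age(s) outside [{edges[0]}, {edges[-1]}): samples {idx.tolist()} "
            f"with ages {ages[bad].tolist()}"
        )
    return (np.digitize(ages, edges[1:-1], right=False)).astype(int)


def anova_pairwise(table: SampleTable, groups, correction: str = "bonferroni") -> pd.DataFrame:
    """One-way ANOVA per feature for every pair of groups, Bonferroni-adjusted.

    The correction family is every (feature, group-pair) test performed in
    this call: p_adj = min(1, m·p) with m = n_features × n_pairs.  Returns a
    tidy frame with columns feature, group_a, group_b, F, p, p_adj.
    """
    groups = np.asarray(groups)
    uniq = np.unique(groups)
    counts = {g: int((groups == g).sum()) for g in uniq}
    small = [g for g, c in counts.items() if c < 2]
    if len(uniq) < 2 or small:
        raise ValueError(f"need >= 2 groups with >= 2 samples each (degenerate: {small})")
    X = table.features
    pairs = [(a, b) for i, a in enumerate(uniq) for b in uniq[i + 1:]]
    m = len(pairs) * len(FEATURE_NAMES)
    rows = []
    for feat in FEATURE_NAMES:
        x = X[feat].to_numpy()
        for a, b in pairs:
            xa, xb = x[groups == a], x[groups == b]
            if np.var(xa) == 0 and np.var(xb) == 0 and xa.mean() == xb.mean():
                F, p = 0.0, 1.0
            else:
                F, p = stats.f_oneway(xa, xb)
                if np.isnan(F) or np.isnan(p) or F < 1e-12:
                    # identical group means cancel to float dust; clamp
                    F, p = 0.0, 1.0
            p_adj = min(1.0, m * p) if correction == "bonferroni" else p
            rows.append((feat, a, b, float(F), float(p), float(p_adj)))
    return pd.DataFrame(rows, columns=["feature", "group_a", "group_b", "F", "p", "p_adj"])


# ---------------------------------------------------------------------------
# Stepwise regression
# ---------------------------------------------------------------------------


def _ols_pvalues(X: np.ndarray, y: np.ndarray):
    """OLS fit with intercept: returns (coef p-values, rss, r2, F, F_p).

    p-values are the partial two-sided t tests of each (non-intercept)
    coefficient, equivalent to partial-F tests for single-column additions.
    """
    n, k = X.shape
    A = np.column_stack([np.ones(n), X])
    coef, _, rank, _ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    rss = float(resid @ resid)
    dof = n - rank
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    if dof <= 0 or rank < A.shape[1]:
        return None  # degenerate design
    sigma2 = rss / dof
    XtX_inv = np.linalg.pinv(A.T @ A)
    se = np.sqrt(np.maximum(np.diag(XtX_inv) * sigma2, 1e-300))
    tvals = coef / se
    pvals = 2.0 * stats.t.sf(np.abs(tvals[1:]), dof)
    if k > 0 and tss > 0 and rss > 0:
        F = (tss - rss) / k / sigma2
        F_p = float(stats.f.sf(F, k, dof))
    else:
        F, F_p = np.inf if rss == 0 and k > 0 else 0.0, 0.0 if rss == 0 else 1.0
    return pvals, rss, r2, float(F), F_p


@dataclass
class StepwiseFit:
    """Result of one forward–backward stepwise selection."""

    selected: list[int]
    r2: float
    F: float
    F_p: float
    p_values: dict[int, float]
    cycled: bool = False


def stepwise_ols(X, y, p_enter: float = 0.05, p_remove: float = 0.1,
                 max_iter: int | None = None) -> StepwiseFit:
    """Classical forward–backward stepwise OLS on partial-F p-values.

    At each cycle the candidate with the smallest partial p-value enters if it
    is below ``p_enter``; then included terms with p-values above ``p_remove``
    are removed (worst first).  Iterations are capped at 2 × n_features; a
    detected entry/removal cycle stops the search keeping the better-fitting
    of the cycling models (flagged in the result).
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    n, m = X.shape
    if n <= 5:
        raise ValueError("stepwise regression needs n > 5 samples")
    if np.isnan(X).any() or np.isnan(y).any():
        raise ValueError("missing values are not allowed")
    max_iter = max_iter or 2 * m
    selected: list[int] = []
    seen_states: dict[tuple, tuple] = {}
    best_cycle = None
    cycled = False
    for _ in range(max_iter):
        changed = False
        # forward step
        remaining = [j for j in range(m) if j not in selected]
        best_j, best_p = None, np.inf
        for j in remaining:
            fit = _ols_pvalues(X[:, selected + [j]], y)
            if fit is None:
                continue
            pj = fit[0][-1]
            if pj < best_p:
                best_j, best_p = j, pj
        if best_j is not None and best_p < p_enter:
            selected.append(best_j)
            changed = True
        # backward step(s)
        while selected:
            fit = _ols_pvalues(X[:, selected], y)
            if fit is None:
                selected.pop()
                changed = True
                continue
            pvals = fit[0]
            worst = int(np.argmax(pvals))
            if pvals[worst] > p_remove:
                selected.pop(worst)
                changed = True
            else:
                break
        state = tuple(sorted(selected))
        if state in seen_states and changed:
            cycled = True
            fit_now = _ols_pvalues(X[:, selected], y) if selected else None
            r2_now = fit_now[2] if fit_now else 0.0
            if best_cycle is None or r2_now > best_cycle[1]:
                best_cycle = (list(selected), r2_now)
            break
        seen_states[state] = state
        if not changed:
            break
    if cycled and best_cycle is not None:
        selected = best_cycle[0]
    if selected:
        fit = _ols_pvalues(X[:, selected], y)
        pvals, _, r2, F, F_p = fit
        pmap = {j: float(p) for j, p in zip(selected, pvals)}
    else:
        r2, F, F_p, pmap = 0.0, 0.0, 1.0, {}
    return StepwiseFit(selected=list(selected), r2=float(r2), F=F, F_p=F_p,
                       p_values=pmap, cycled=cycled)


@dataclass
class StepwiseReport:
    """Aggregate of the bootstrapped stepwise-selection procedure.

    ``frequency`` / ``frequency_sd`` are per-feature selection percentages
    (mean ± SD across repeats) among models passing the size filter;
    ``model_size_percentiles`` are the 25th/50th/75th percentiles of the
    number of selected features over all resamples; ``r2_mean`` ± ``r2_se``
    and ``median_F`` summarize the filtered ("conservative") models;
    ``median_p`` is each feature's median partial p-value in models where it
    was selected.
    """

    frequency: pd.Series
    frequency_sd: pd.Series
    model_size_percentiles: tuple[float, float, float]
    r2_mean: float
    r2_se: float
    median_F: float
    median_p: pd.Series
    n_boot: int
    n_repeats: int
    model_size_filter: tuple[int, int]
    n_filtered_models: int
    n_degenerate: int = 0
    frequency_per_repeat: pd.DataFrame | None = None  # repeats x features

    def __post_init__(self):
        if ((self.frequency < 0) | (self.frequency > 100)).any():
            raise ValueError("frequencies must lie in [0, 100]")
        p25, p50, p75 = self.model_size_percentiles
        if not (p25 <= p50 <= p75):
            raise ValueError("model-size percentiles must be non-decreasing")

    def top(self, k: int = 10) -> pd.DataFrame:
        df = pd.DataFrame({
            "frequency_pct": self.frequency,
            "sd": self.frequency_sd,
            "median_p": self.median_p,
        })
        return df.sort_values("frequency_pct", ascending=False).head(k)

    def to_dict(self) -> dict:
        return {
            "frequency_pct": self.frequency.to_dict(),
            "frequency_sd": self.frequency_sd.to_dict(),
            "model_size_percentiles": list(self.model_size_percentiles),
            "r2_mean": self.r2_mean,
            "r2_se": self.r2_se,
            "median_F": self.median_F,
            "median_p": {k: (None if np.isnan(v) else v)
                         for k, v in self.median_p.items()},
            "n_boot": self.n_boot,
            "n_repeats": self.n_repeats,
            "model_size_filter": list(self.model_size_filter),
            "n_filtered_models": self.n_filtered_models,
            "n_degenerate": self.n_degenerate,
        }


def bootstrap_stepwise(table: SampleTable, n_boot: int = 3000, n_repeats: int = 6,
                       model_size_filter=(2, 4), seed: int = 0,
                       p_enter: float = 0.05, p_remove: float = 0.1,
                       min_age: float | None = REGRESSION_MIN_AGE) -> StepwiseReport:
    """Bootstrapped, repeated stepwise regression of age on the 40 features.

    Per repeat, ``n_boot`` resamples of subjects (with replacement) are each
    run through :func:`stepwise_ols`; selection frequencies are tallied over
    models whose size falls inside ``model_size_filter`` (the conservative
    models).  Samples younger than ``min_age`` are excluded first (the
    age range where the features are near-linear in age); pass None to keep
    everyone.  Resamples with degenerate designs (e.g. a constant feature
    after resampling) are skipped and counted.
    """
    df = table.data
    if min_age is not None:
        df = df[df["age"] >= min_age]
    n = len(df)
    if n < 10:
        raise ValueError(f"bootstrap needs >= 10 samples after age filtering, got {n}")
    X_all = df[list(FEATURE_NAMES)].to_numpy(dtype=np.float64)
    y_all = df["age"].to_numpy(dtype=np.float64)
    lo, hi = model_size_filter
    m = len(FEATURE_NAMES)
    root = np.random.SeedSequence(seed)
    repeat_seqs = root.spawn(n_repeats)

    freqs = np.zeros((n_repeats, m))
    sizes_all: list[int] = []
    r2_filtered: list[float] = []
    F_filtered: list[float] = []
    p_per_feature: list[list[float]] = [[] for _ in range(m)]
    n_filtered = 0
    n_degenerate = 0
    for rep, seq in enumerate(repeat_seqs):
        rng = np.random.default_rng(seq)
        hits = np.zeros(m)
        n_kept = 0
        for _ in range(n_boot):
            idx = rng.integers(0, n, size=n)
            Xb, yb = X_all[idx], y_all[idx]
            if np.ptp(yb) == 0:
                n_degenerate += 1
                continue
            const = np.ptp(Xb, axis=0) == 0
            if const.all():
                n_degenerate += 1
                continue
            fit = stepwise_ols(Xb, yb, p_enter=p_enter, p_remove=p_remove)
            k = len(fit.selected)
            sizes_all.append(k)
            if lo <= k <= hi:
                n_kept += 1
                for j in fit.selected:
                    hits[j] += 1
                    p_per_feature[j].append(fit.p_values[j])
                r2_filtered.append(fit.r2)
                F_filtered.append(fit.F)
        freqs[rep] = 100.0 * hits / max(n_kept, 1)
        n_filtered += n_kept

    names = list(FEATURE_NAMES)
    r2_arr = np.asarray(r2_filtered)
    return StepwiseReport(
        frequency=pd.Series(freqs.mean(axis=0), index=names),
        frequency_sd=pd.Series(freqs.std(axis=0, ddof=1) if n_repeats > 1
                               else np.zeros(m), index=names),
        model_size_percentiles=tuple(np.percentile(sizes_all, [25, 50, 75]))
        if sizes_all else (0.0, 0.0, 0.0),
        r2_mean=float(r2_arr.mean()) if r2_arr.size else np.nan,
        r2_se=float(r2_arr.std(ddof=1) / np.sqrt(r2_arr.size))
        if r2_arr.size > 1 else np.nan,
        median_F=float(np.median(F_filtered)) if F_filtered else np.nan,
        median_p=pd.Series([float(np.median(p)) if p else np.nan
                            for p in p_per_feature], index=names),
        n_boot=n_boot,
        n_repeats=n_repeats,
        model_size_filter=(lo, hi),
        n_filtered_models=n_filtered,
        n_degenerate=n_degenerate,
        frequency_per_repeat=pd.DataFrame(freqs, columns=names),
    )
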