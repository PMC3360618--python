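"""Multivariate shape statistics: PCA reduction, canonical discriminant
analysis, Hotelling T² group inference and size–shape analyses.

The discriminant machinery follows the classical canonical variate
construction: axes are generalized eigenvectors of the between-group
versus pooled within-group covariance, scaled so that the pooled
within-group variance of each canonical projection is one.  The score on
the single axis of a two-group analysis is the quantitative shape
phenotype used downstream for QTL mapping, oriented so the designated
reference group takes the higher mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import linalg, stats as sps

from morphoqtl.geometry import outline_area


# ---------------------------------------------------------------------------
# PCA


@dataclass
class ShapeSpace:
    """Centered PCA basis over coefficient vectors."""

    mean: np.ndarray  # (p,)
    loadings: np.ndarray  # (K, p), orthonormal rows
    scores: np.ndarray  # (n, K)
    variance_fraction: np.ndarray  # (K,)
    eigenvalues: np.ndarray  # (K,)

    @property
    def n_components(self) -> int:
        return self.loadings.shape[0]

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Project new coefficient vectors into the retained PC space."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return (X - self.mean) @ self.loadings.T


def pca_fit(coeff_matrix: np.ndarray, n_components: int | None = None) -> ShapeSpace:
    """Centered PCA of a specimens × variables coefficient matrix.

    ``n_components`` beyond the matrix rank raises, naming the achievable
    rank.  Variance fractions are relative to the total variance.
    """
    X = np.asarray(coeff_matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with >= 2 specimens")
    mean = X.mean(axis=0)
    Xc = X - mean
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    tol = s.max(initial=0.0) * max(X.shape) * np.finfo(float).eps
    rank = int(np.sum(s > tol))
    if n_components is None:
        n_components = rank
    if n_components > rank:
        raise ValueError(
            f"requested {n_components} components but achievable rank is {rank}"
        )
    eigvals = s**2 / (X.shape[0] - 1)
    total = eigvals.sum()
    K = n_components
    return ShapeSpace(
        mean=mean,
        loadings=Vt[:K],
        scores=(U[:, :K] * s[:K]),
        variance_fraction=eigvals[:K] / total if total > 0 else eigvals[:K],
        eigenvalues=eigvals[:K],
    )


def n_components_for_variance(coeff_matrix: np.ndarray, fraction: float = 0.99) -> int:
    """Smallest K whose cumulative variance fraction reaches ``fraction``."""
    space = pca_fit(coeff_matrix)
    cum = np.cumsum(space.variance_fraction)
    return int(np.searchsorted(cum, fraction - 1e-12) + 1)


# ---------------------------------------------------------------------------
# Canonical discriminant analysis


@dataclass
class DiscriminantModel:
    """Canonical axes and group statistics of an LDA.

    ``axes`` columns are canonical axis coefficients in the input
    (PC-score) space, scaled to unit pooled within-group variance.
    """

    groups: list
    axes: np.ndarray  # (p, n_axes)
    axis_variance_fraction: np.ndarray  # (n_axes,)
    group_means: np.ndarray  # (g, n_axes), canonical space
    pooled_cov: np.ndarray  # (p, p), within-group, input space
    grand_mean: np.ndarray  # (p,)
    group_sizes: np.ndarray = field(default=None)

    @property
    def n_axes(self) -> int:
        return self.axes.shape[1]

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return (X - self.grand_mean) @ self.axes


def _group_stats(X, labels):
    labels = np.asarray(labels)
    groups = sorted(pd.unique(labels).tolist())
    idx = {g: np.flatnonzero(labels == g) for g in groups}
    return groups, idx


def pooled_within_cov(X: np.ndarray, labels) -> np.ndarray:
    """Pooled within-group covariance (denominator n - g)."""
    X = np.asarray(X, dtype=float)
    groups, idx = _group_stats(X, labels)
    n, p = X.shape
    S = np.zeros((p, p))
    for g in groups:
        Xg = X[idx[g]]
        S += (Xg - Xg.mean(axis=0)).T @ (Xg - Xg.mean(axis=0))
    return S / (n - len(groups))


def lda_fit(scores: np.ndarray, labels, positive_group=None) -> DiscriminantModel:
    """Canonical discriminant analysis of grouped PC scores.

    Axes maximize the between/within variance ratio; the number of axes is
    ``min(n_groups - 1, p)``.  Each axis is oriented so that
    ``positive_group`` (default: first group in sort order) has a mean
    projection above the grand mean; for a two-strain analysis pass the
    recipient-strain label so its pole is positive.
    """
    X = np.asarray(scores, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    labels = np.asarray(labels)
    groups, idx = _group_stats(X, labels)
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    for g in groups:
        if idx[g].size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 specimens")
    n, p = X.shape
    grand = X.mean(axis=0)
    Sw = pooled_within_cov(X, labels) * (n - len(groups))
    means = np.vstack([X[idx[g]].mean(axis=0) for g in groups])
    sizes = np.array([idx[g].size for g in groups])
    Sb = ((means - grand).T * sizes) @ (means - grand)
    try:
        evals, evecs = linalg.eigh(Sb, Sw)
    except linalg.LinAlgError as exc:
        raise ValueError(
            "singular pooled within-group covariance; reduce the number of "
            "retained PCs below the within-group degrees of freedom"
        ) from exc
    order = np.argsort(evals)[::-1]
    n_axes = min(len(groups) - 1, p)
    evals = np.clip(evals[order][:n_axes], 0.0, None)
    W = evecs[:, order][:, :n_axes]
    # scale axes to unit pooled within-group variance of projections
    Sw_pooled = Sw / (n - len(groups))
    scale = np.sqrt(np.einsum("ij,jk,ki->i", W.T, Sw_pooled, W))
    W = W / scale
    if positive_group is None:
        positive_group = groups[0]
    if positive_group not in groups:
        raise ValueError(f"positive_group {positive_group!r} not among groups")
    gmeans_c = (means - grand) @ W
    ref = groups.index(positive_group)
    flip = np.where(gmeans_c[ref] < 0, -1.0, 1.0)
    W = W * flip
    gmeans_c = gmeans_c * flip
    total = evals.sum()
    frac = evals / total if total > 0 else evals
    return DiscriminantModel(
        groups=groups,
        axes=W,
        axis_variance_fraction=frac,
        group_means=gmeans_c,
        pooled_cov=Sw_pooled,
        grand_mean=grand,
        group_sizes=sizes,
    )


def lda_score(model: DiscriminantModel, new_scores: np.ndarray, axis: int | None = None):
    """Scalar discriminant score per specimen.

    For a two-group model this is the quantitative shape phenotype; a
    model with several axes requires an explicit ``axis``.
    """
    if model.n_axes > 1 and axis is None:
        raise ValueError(
            f"model has {model.n_axes} canonical axes; select one explicitly"
        )
    axis = 0 if axis is None else axis
    return model.transform(new_scores)[:, axis]


def _assign_nearest(model: DiscriminantModel, canonical: np.ndarray):
    d2 = np.sum((canonical[:, None, :] - model.group_means[None]) ** 2, axis=2)
    # ties broken toward the group with lower label sort order (argmin does)
    return [model.groups[j] for j in np.argmin(d2, axis=1)]


def classify(model: DiscriminantModel, scores: np.ndarray):
    """Nearest-group-mean assignment in canonical space, equal priors."""
    return _assign_nearest(model, model.transform(scores))


def loocv_rate(scores: np.ndarray, labels, positive_group=None):
    """Leave-one-out cross-validated classification.

    Refits the discriminant n times leaving one specimen out, assigning by
    nearest group mean in canonical space with equal priors.  Returns the
    percent correct and the misclassification table (rows: true group,
    columns: assigned group).
    """
    X = np.asarray(scores, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    labels = np.asarray(labels)
    groups, idx = _group_stats(X, labels)
    for g in groups:
        if idx[g].size < 3:
            raise ValueError(f"group {g!r} needs >= 3 specimens for leave-one-out")
    assigned = []
    mask = np.ones(len(labels), dtype=bool)
    for i in range(len(labels)):
        mask[i] = False
        sub = lda_fit(X[mask], labels[mask], positive_group=positive_group)
        assigned.append(_assign_nearest(sub, sub.transform(X[i]))[0])
        mask[i] = True
    assigned = np.asarray(assigned, dtype=object)
    correct = float(np.mean(assigned == labels)) * 100.0
    table = pd.crosstab(
        pd.Series(labels, name="true"), pd.Series(assigned, name="assigned")
    ).reindex(index=groups, columns=groups, fill_value=0)
    return correct, table


# ---------------------------------------------------------------------------
# Hotelling T² and power


@dataclass
class GroupTestResult:
    t2: float
    f: float
    df: tuple
    p_raw: float
    p_bonferroni: float
    d2: float
    power: float | None = None
    power_reported: bool = False


def hotelling_t2(
    X1,
    X2,
    df_convention: str = "standard",
    n_groups: int | None = None,
    n_comparisons: int = 1,
    alpha: float = 0.05,
) -> GroupTestResult:
    """Two-sample Hotelling T² with Mahalanobis D².

    D² = (m1 - m2)' S⁻¹ (m1 - m2) with S the pooled covariance; T² =
    n1 n2/(n1 + n2) · D².  The default F conversion uses the number of
    variables p with (p, n1+n2-p-1) degrees of freedom.  The historical
    alternative ``df_convention="groups"`` substitutes the number of groups
    in the analysis batch (``n_groups``) for p in the degrees of freedom.
    Bonferroni multiplies the raw p by ``n_comparisons`` (capped at 1).
    Power against the observed effect (noncentrality λ = T²) is always
    computed; ``power_reported`` flags raw p in the 0.05–0.1 band, the
    range in which it is conventionally quoted.
    """
    X1 = np.asarray(X1, dtype=float)
    X2 = np.asarray(X2, dtype=float)
    if X1.ndim == 1:
        X1 = X1[:, None]
    if X2.ndim == 1:
        X2 = X2[:, None]
    if X1.shape[1] != X2.shape[1]:
        raise ValueError("groups must share dimensionality")
    n1, p = X1.shape
    n2 = X2.shape[0]
    if n1 + n2 <= p + 2:
        raise ValueError("n1 + n2 must exceed p + 2 for valid degrees of freedom")
    S = ((X1 - X1.mean(0)).T @ (X1 - X1.mean(0)) +
         (X2 - X2.mean(0)).T @ (X2 - X2.mean(0))) / (n1 + n2 - 2)
    diff = X1.mean(0) - X2.mean(0)
    try:
        sol = np.linalg.solve(S, diff)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular pooled covariance") from exc
    d2 = float(diff @ sol)
    t2 = n1 * n2 / (n1 + n2) * d2
    if df_convention == "standard":
        t = p
    elif df_convention == "groups":
        if n_groups is None:
            raise ValueError("df_convention='groups' requires n_groups")
        t = n_groups
    else:
        raise ValueError(f"unknown df_convention {df_convention!r}")
    df1, df2 = t, n1 + n2 - t - 1
    if df2 <= 0:
        raise ValueError("non-positive error degrees of freedom")
    f = t2 * df2 / ((n1 + n2 - 2) * df1)
    p_raw = float(sps.f.sf(f, df1, df2))
    power = hotelling_power(t2, n1, n2, t, alpha=alpha)
    return GroupTestResult(
        t2=t2,
        f=f,
        df=(df1, df2),
        p_raw=p_raw,
        p_bonferroni=min(1.0, p_raw * n_comparisons),
        d2=d2,
        power=power,
        power_reported=0.05 <= p_raw <= 0.1,
    )


def hotelling_power(
    t2_observed: float, n1: int, n2: int, p_dims: int, alpha: float = 0.05
) -> float:
    """Observed-effect plug-in power of the Hotelling T² test.

    The alternative is noncentral F with noncentrality λ equal to the
    observed T²; power is P(F' >= F_crit) at level ``alpha``.  Monotone
    increasing in λ.
    """
    df1, df2 = p_dims, n1 + n2 - p_dims - 1
    if df1 < 1 or df2 < 1:
        raise ValueError("invalid degrees of freedom")
    fcrit = sps.f.isf(alpha, df1, df2)
    if t2_observed == 0.0:
        return float(alpha)
    return float(sps.ncf.sf(fcrit, df1, df2, t2_observed))


def mahalanobis_d2(X1, X2, cov: np.ndarray | None = None) -> float:
    """Squared Mahalanobis distance between two group means.

    Defaults to the two-group pooled covariance; pass ``cov`` (e.g. the
    pooled within-group covariance of a wider analysis batch, or the
    canonical-space identity) to override.
    """
    X1 = np.asarray(X1, float)
    X2 = np.asarray(X2, float)
    if X1.ndim == 1:
        X1 = X1[:, None]
    if X2.ndim == 1:
        X2 = X2[:, None]
    diff = X1.mean(0) - X2.mean(0)
    if cov is None:
        n1, n2 = X1.shape[0], X2.shape[0]
        cov = ((X1 - X1.mean(0)).T @ (X1 - X1.mean(0)) +
               (X2 - X2.mean(0)).T @ (X2 - X2.mean(0))) / (n1 + n2 - 2)
    return float(diff @ np.linalg.solve(np.atleast_2d(cov), diff))


# ---------------------------------------------------------------------------
# Size analyses


def size_table_and_anova(outlines, groups):
    """Per-group size summary with one-way ANOVA and pairwise Welch tests.

    Size is the square root of the outline surface.  Returns a dict with a
    tidy table (group, n, mean, sem), the ANOVA F and p, and the
    Bonferroni-corrected pairwise comparisons.  Groups of size 1 are kept
    in the table but excluded from pairwise tests with a warning.
    """
    groups = np.asarray(groups)
    sizes = np.array([np.sqrt(outline_area(o)) for o in outlines])
    names = sorted(pd.unique(groups).tolist())
    if len(names) < 2:
        raise ValueError("need >= 2 groups")
    rows = []
    by_group = {}
    for g in names:
        s = sizes[groups == g]
        by_group[g] = s
        rows.append(
            {
                "group": g,
                "n": len(s),
                "mean": s.mean(),
                "sem": s.std(ddof=1) / np.sqrt(len(s)) if len(s) > 1 else np.nan,
            }
        )
    table = pd.DataFrame(rows)
    testable = [g for g in names if len(by_group[g]) > 1]
    excluded = set(names) - set(testable)
    if excluded:
        warnings.warn(f"groups of size 1 excluded from pairwise tests: {sorted(excluded)}")
    F, p = sps.f_oneway(*[by_group[g] for g in testable])
    if np.isnan(F):  # identical values in every group
        F, p = 0.0, 1.0
    pairs = list(combinations(testable, 2))
    pw = []
    for a, b in pairs:
        t, pr = sps.ttest_ind(by_group[a], by_group[b], equal_var=False)
        pw.append(
            {
                "group_a": a,
                "group_b": b,
                "t": t,
                "p_raw": pr,
                "p_bonferroni": min(1.0, pr * len(pairs)),
            }
        )
    return {
        "table": table,
        "anova_f": float(F),
        "anova_p": float(p),
        "pairwise": pd.DataFrame(pw),
    }


def size_shape_regression(pc_scores: np.ndarray, sizes: np.ndarray):
    """Regression of each retained PC on size plus an omnibus test.

    Per component: correlation R, R² and p of the score-on-size
    regression, Bonferroni-corrected across components.  The omnibus row
    regresses size on all K components jointly and reports the multiple
    correlation R and overall F-test p.  Requires n > K + 1.
    """
    import statsmodels.api as sm

    X = np.asarray(pc_scores, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    sizes = np.asarray(sizes, dtype=float).ravel()
    n, K = X.shape
    if n <= K + 1:
        raise ValueError(f"need n > K+1 observations (n={n}, K={K})")
    if np.ptp(sizes) == 0.0:
        raise ValueError("constant size vector")
    rows = []
    design = sm.add_constant(sizes)
    for k in range(K):
        fit = sm.OLS(X[:, k], design).fit()
        r2 = fit.rsquared
        rows.append(
            {
                "component": k + 1,
                "R": np.sqrt(r2) * np.sign(fit.params[1]),
                "R2": r2,
                "p_raw": fit.pvalues[1],
                "p_bonferroni": min(1.0, fit.pvalues[1] * K),
            }
        )
    omni = sm.OLS(sizes, sm.add_constant(X)).fit()
    return {
        "per_component": pd.DataFrame(rows),
        "omnibus_R": float(np.sqrt(omni.rsquared)),
        "omnibus_R2": float(omni.rsquared),
        "omnibus_p": float(omni.f_pvalue),
    }
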