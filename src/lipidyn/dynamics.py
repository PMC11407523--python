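"""Selection and clustering of developmentally dynamic features.

A feature (lipid or gene) is *developmentally dynamic* when its time course —
replicate samples at coded developmental stages — is fit significantly better
by a degree-3 polynomial in time than by a constant.  The selection follows
the standard single-series time-course workflow:

1. per feature, center and scale the values, then fit ordinary least squares
   on {1, t, t^2, t^3} (t = integer stage code by default) and take the global
   F-test p-value of the polynomial terms;
2. Benjamini–Hochberg adjust the global p-values across features;
3. for features passing the FDR cut, backward-eliminate polynomial terms whose
   partial p-value exceeds ``alpha_step``, refitting after each drop;
4. keep the feature when the stepwise model's R^2 exceeds ``r2_min``.

Defaults (FDR < 0.05, R^2 > 0.7, alpha_step = 0.05) are the thresholds used
throughout this package's analyses.

Selected profiles are partitioned either by agglomerative (Ward) clustering of
z-scored per-stage medians or by fuzzy c-means on the same profiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .quantify import AbundanceMatrix, STAGE_LABELS

__all__ = [
    "TimeCourseFit",
    "DynamicSelectionResult",
    "DynamicFeatureModel",
    "ProfileClustering",
    "fit_polynomial_timecourse",
    "backward_stepwise",
    "benjamini_hochberg",
    "select_dynamic_features",
    "hierarchical_cluster_profiles",
    "fuzzy_cmeans",
    "encode_times",
]

_TERM_NAMES = ("t", "t2", "t3")

# Approximate day-scale encoding: embryonic stages at their gestational day,
# postnatal day d at 19.5 + d (C57BL/6 gestation ~19.5 days).
_DAY_ENCODING = {
    "E10.5": 10.5, "E11.5": 11.5, "E12.5": 12.5, "E13.5": 13.5, "E14.5": 14.5,
    "E15.5": 15.5, "E16.5": 16.5, "E17.5": 17.5, "E18.5": 18.5,
    "P0": 19.5, "P1": 20.5, "P3": 22.5, "P7": 26.5, "P14": 33.5, "P21": 40.5,
}


def encode_times(matrix: AbundanceMatrix, encoding: str = "stage_code") -> np.ndarray:
    """Numeric time covariate per sample.

    ``stage_code``: the shared 1–15 integer codes (default, matching the GP
    module); ``ordinal``: consecutive ranks of the stages actually sampled;
    ``day``: approximate chronological day.
    """
    if encoding == "stage_code":
        return matrix.stage_codes.astype(float)
    if encoding == "ordinal":
        codes = matrix.stage_codes
        rank = {c: i + 1 for i, c in enumerate(sorted(set(codes)))}
        return np.array([rank[c] for c in codes], dtype=float)
    if encoding == "day":
        return np.array([_DAY_ENCODING[lab] for lab in matrix.stage_labels])
    raise ValueError(f"unknown time encoding {encoding!r}")


@dataclass
class TimeCourseFit:
    """OLS fit of one feature's time course on a cubic polynomial basis."""

    feature: str
    coefficients: dict[str, float]
    term_pvalues: dict[str, float]
    f_statistic: float
    global_pvalue: float
    r_squared: float
    retained_terms: tuple[str, ...]
    n_obs: int
    testable: bool = True

    @property
    def is_intercept_only(self) -> bool:
        return not any(t in self.retained_terms for t in _TERM_NAMES)


def _design(times: np.ndarray, terms: Sequence[str]) -> np.ndarray:
    # centered powers keep the cubic design well conditioned on codes 1..15
    tc = times - times.mean()
    cols = {"t": tc, "t2": tc**2, "t3": tc**3}
    X = np.column_stack([np.ones_like(tc)] + [cols[t] for t in terms])
    return X


def _ols(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray, float, float, float]:
    """Least squares with per-term t-test p-values, global F-test and R^2."""
    n, p = X.shape
    model = sm.OLS(y, X).fit()
    return (
        model.params,
        model.pvalues,
        float(model.fvalue) if p > 1 else np.nan,
        float(model.f_pvalue) if p > 1 else np.nan,
        float(model.rsquared),
    )


def fit_polynomial_timecourse(
    y: Sequence[float],
    times: Sequence[float],
    degree: int = 3,
    feature: str = "",
    standardize: bool = True,
) -> TimeCourseFit:
    """Fit one feature's values against a degree-3 polynomial in time.

    Missing values are dropped pairwise.  Constant (zero-variance) responses
    are flagged non-testable rather than raising.  Requires at least
    ``degree + 2`` distinct time points.
    """
    if degree != 3:
        raise ValueError("only the cubic (degree=3) model is supported")
    y = np.asarray(y, dtype=float)
    t = np.asarray(times, dtype=float)
    ok = np.isfinite(y) & np.isfinite(t)
    y, t = y[ok], t[ok]
    if len(np.unique(t)) < degree + 2:
        raise ValueError(
            f"need at least {degree + 2} distinct time points, got {len(np.unique(t))}"
        )
    if y.std(ddof=1) == 0 or len(y) < degree + 2:
        return TimeCourseFit(
            feature, {}, {}, np.nan, np.nan, np.nan, (), len(y), testable=False
        )
    if standardize:
        y = (y - y.mean()) / y.std(ddof=1)
    terms = _TERM_NAMES[:degree]
    X = _design(t, terms)
    params, pvals, fstat, fp, r2 = _ols(y, X)
    names = ("intercept",) + terms
    return TimeCourseFit(
        feature=feature,
        coefficients=dict(zip(names, params)),
        term_pvalues=dict(zip(names, pvals)),
        f_statistic=fstat,
        global_pvalue=fp,
        r_squared=r2,
        retained_terms=terms,
        n_obs=len(y),
    )


def backward_stepwise(
    y: Sequence[float],
    times: Sequence[float],
    alpha: float = 0.05,
    feature: str = "",
    standardize: bool = True,
) -> TimeCourseFit:
    """Backward elimination from the full cubic model.

    Repeatedly drops the non-intercept term with the largest p-value above
    ``alpha`` and refits, until all retained terms are significant or only the
    intercept remains.  The reported R^2 is the reduced model's, so it never
    exceeds the full model's.
    """
    y = np.asarray(y, dtype=float)
    t = np.asarray(times, dtype=float)
    ok = np.isfinite(y) & np.isfinite(t)
    y, t = y[ok], t[ok]
    if y.std(ddof=1) == 0:
        return TimeCourseFit(feature, {}, {}, np.nan, np.nan, np.nan, (), len(y), False)
    if standardize:
        y = (y - y.mean()) / y.std(ddof=1)
    terms = list(_TERM_NAMES)
    while True:
        X = _design(t, terms)
        params, pvals, fstat, fp, r2 = _ols(y, X)
        if not terms:
            break
        worst_i = int(np.argmax(pvals[1:]))  # skip intercept
        if pvals[1:][worst_i] <= alpha:
            break
        del terms[worst_i]
    names = ("intercept",) + tuple(terms)
    return TimeCourseFit(
        feature=feature,
        coefficients=dict(zip(names, params)),
        term_pvalues=dict(zip(names, pvals)),
        f_statistic=fstat,
        global_pvalue=fp,
        r_squared=float(r2) if terms else 0.0,
        retained_terms=tuple(terms),
        n_obs=len(y),
    )


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (order-preserving, in [0,1])."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class DynamicSelectionResult:
    """Per-feature time-course statistics and the dynamic-feature verdict."""

    table: pd.DataFrame
    fits: dict[str, TimeCourseFit]
    fdr: float
    r2_min: float
    alpha_step: float
    time_encoding: str

    @property
    def dynamic_features(self) -> list[str]:
        return list(self.table.index[self.table["is_dynamic"]])

    @property
    def n_dynamic(self) -> int:
        return int(self.table["is_dynamic"].sum())

    def summary(self) -> str:
        t = self.table
        lines = [
            "Dynamic feature selection (cubic time-course regression)",
            "=" * 58,
            f"features tested          {int(t['testable'].sum())} of {len(t)}",
            f"FDR threshold (BH)       {self.fdr}",
            f"stepwise alpha           {self.alpha_step}",
            f"R^2 threshold            {self.r2_min}",
            f"time encoding            {self.time_encoding}",
            f"passing FDR              {int((t['adj_p'] < self.fdr).sum())}",
            f"dynamic features         {self.n_dynamic}",
        ]
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out.insert(0, "feature", out.index)
        out.to_csv(path, sep="\t", index=False, na_rep="NA")


def select_dynamic_features(
    matrix: AbundanceMatrix,
    fdr: float = 0.05,
    r2_min: float = 0.7,
    alpha_step: float = 0.05,
    time_encoding: str = "stage_code",
) -> DynamicSelectionResult:
    """Run the full dynamic-feature selection over an abundance matrix.

    Returns a per-feature ledger (global p, BH-adjusted p, full and stepwise
    R^2, retained terms, verdict) with ``is_dynamic`` true iff the BH-adjusted
    global p-value is below ``fdr`` and the stepwise model's R^2 exceeds
    ``r2_min``.  Zero-variance features are flagged non-testable and excluded
    from the BH adjustment.
    """
    times = encode_times(matrix, time_encoding)
    feats = matrix.features
    cols = ["global_p", "adj_p", "r2_full", "r2_step", "retained_terms",
            "is_dynamic", "testable"]
    if not feats:
        table = pd.DataFrame(columns=cols)
        return DynamicSelectionResult(table, {}, fdr, r2_min, alpha_step, time_encoding)

    fits: dict[str, TimeCourseFit] = {}
    rows = []
    for f in feats:
        fit = fit_polynomial_timecourse(matrix.values.loc[f].to_numpy(), times, feature=f)
        fits[f] = fit
        rows.append(fit)
    global_p = np.array([f.global_pvalue for f in rows])
    testable = np.array([f.testable for f in rows])
    adj = np.full(len(rows), np.nan)
    if testable.any():
        adj[testable] = benjamini_hochberg(global_p[testable])

    r2_step = np.full(len(rows), np.nan)
    retained: list[str] = ["" for _ in rows]
    is_dyn = np.zeros(len(rows), dtype=bool)
    for i, f in enumerate(feats):
        if not testable[i] or not (adj[i] < fdr):
            continue
        sfit = backward_stepwise(
            matrix.values.loc[f].to_numpy(), times, alpha=alpha_step, feature=f
        )
        fits[f] = sfit
        r2_step[i] = sfit.r_squared
        retained[i] = "+".join(sfit.retained_terms)
        is_dyn[i] = sfit.r_squared > r2_min

    table = pd.DataFrame(
        {
            "global_p": global_p,
            "adj_p": adj,
            "r2_full": [f.r_squared for f in rows],
            "r2_step": r2_step,
            "retained_terms": retained,
            "is_dynamic": is_dyn,
            "testable": testable,
        },
        index=pd.Index(feats, name="feature"),
    )
    return DynamicSelectionResult(table, fits, fdr, r2_min, alpha_step, time_encoding)


class DynamicFeatureModel:
    """Model-style front end: ``DynamicFeatureModel(matrix).fit()``.

    Thin wrapper over :func:`select_dynamic_features` holding the data and
    thresholds; ``fit`` returns a :class:`DynamicSelectionResult`.
    """

    def __init__(
        self,
        matrix: AbundanceMatrix,
        fdr: float = 0.05,
        r2_min: float = 0.7,
        alpha_step: float = 0.05,
        time_encoding: str = "stage_code",
    ):
        self.matrix = matrix
        self.fdr = fdr
        self.r2_min = r2_min
        self.alpha_step = alpha_step
        self.time_encoding = time_encoding

    def fit(self) -> DynamicSelectionResult:
        return select_dynamic_features(
            self.matrix, self.fdr, self.r2_min, self.alpha_step, self.time_encoding
        )


@dataclass
class ProfileClustering:
    """Hard or soft partition of per-stage trajectory profiles."""

    method: str  # "hierarchical" or "fuzzy_cmeans"
    n_clusters: int
    assignments: pd.Series  # feature -> cluster label in 1..k
    centers: pd.DataFrame  # cluster x stage mean profiles
    membership: pd.DataFrame | None = None  # soft memberships, rows sum to 1
    params: dict = field(default_factory=dict)


def hierarchical_cluster_profiles(
    profiles: pd.DataFrame,
    k: int = 5,
    linkage: str = "ward",
    metric: str = "euclidean",
) -> ProfileClustering:
    """Agglomerative clustering of trajectory profiles cut at ``k`` clusters.

    ``profiles`` holds one row per feature (typically z-scored per-stage
    medians).  Deterministic given inputs; labels are relabelled 1..k in order
    of first appearance so the partition is invariant to feature order up to
    label names.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(profiles):
        raise ValueError(f"k={k} exceeds number of features {len(profiles)}")
    X = profiles.to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("profiles must be finite")
    if len(profiles) == 1 or k == 1:
        labels = np.ones(len(profiles), dtype=int)
    else:
        Z = sch.linkage(X, method=linkage, metric=metric)
        labels = sch.fcluster(Z, t=k, criterion="maxclust")
    assignments = pd.Series(labels, index=profiles.index, name="cluster")
    centers = profiles.groupby(assignments).mean()
    return ProfileClustering(
        "hierarchical", int(assignments.nunique()), assignments, centers,
        params={"linkage": linkage, "metric": metric, "k": k},
    )


def _fcm_once(
    X: np.ndarray, c: int, m: float, rng: np.random.Generator,
    tol: float, max_iter: int,
) -> tuple[np.ndarray, np.ndarray, float, bool]:
    n = X.shape[0]
    U = rng.dirichlet(np.ones(c), size=n)
    trace: list[float] = []
    converged = False
    for _ in range(max_iter):
        W = U**m
        centers = (W.T @ X) / W.sum(axis=0)[:, None]
        d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        d2 = np.maximum(d2, 1e-12)
        inv = d2 ** (-1.0 / (m - 1.0))
        U = inv / inv.sum(axis=1, keepdims=True)
        trace.append(float((U**m * d2).sum()))
        if len(trace) > 1 and abs(trace[-2] - trace[-1]) < tol:
            converged = True
            break
    return U, centers, trace, converged


def fuzzy_cmeans(
    profiles: pd.DataFrame,
    c: int,
    m: float = 2.0,
    seed: int = 0,
    tol: float = 1e-8,
    max_iter: int = 300,
    restarts: int = 5,
) -> ProfileClustering:
    """Fuzzy c-means clustering of trajectory profiles.

    Minimizes the standard FCM objective sum_ij u_ij^m ||x_i - v_j||^2 with
    fuzzifier ``m`` by alternating center and membership updates; the best of
    ``restarts`` random initializations (seeded) is kept.  Membership rows sum
    to 1.  A non-converged best run emits a warning with its final objective.
    """
    if c < 2:
        raise ValueError("c must be >= 2")
    if m <= 1:
        raise ValueError("fuzzifier m must be > 1")
    X = profiles.to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(restarts):
        U, centers, trace, conv = _fcm_once(X, c, m, rng, tol, max_iter)
        if best is None or trace[-1] < best[2][-1]:
            best = (U, centers, trace, conv)
    U, centers, trace, conv = best
    obj = trace[-1]
    if not conv:
        warnings.warn(
            f"fuzzy c-means did not converge in {max_iter} iterations "
            f"(final objective {obj:.6g})"
        )
    membership = pd.DataFrame(
        U, index=profiles.index, columns=[f"cluster_{j+1}" for j in range(c)]
    )
    labels = pd.Series(U.argmax(axis=1) + 1, index=profiles.index, name="cluster")
    centers_df = pd.DataFrame(
        centers, index=range(1, c + 1), columns=profiles.columns
    )
    return ProfileClustering(
        "fuzzy_cmeans", c, labels, centers_df, membership,
        params={"m": m, "seed": seed, "tol": tol, "max_iter": max_iter,
                "restarts": restarts, "objective": obj, "objective_trace": trace},
    )
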