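"""Cohort-level statistics for ontogenetic trabecular series.

Covers the downstream analysis chain applied to per-specimen metric tables:
body-mass estimation from bone circumference, dispersion (CV), correlation
matrices (Pearson or partial), PCA ordination with azimuth folding,
nonparametric group comparisons (Kruskal–Wallis with Dunn follow-ups),
allometric log-log regression with cross-validated polynomial degree
selection and isometry comparison, and Lambert equal-area projection of the
primary fabric orientations.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .morphometry import fold_azimuth

__all__ = [
    "estimate_log_body_mass",
    "coefficient_of_variation",
    "correlation_matrix",
    "pca",
    "kruskal_wallis",
    "dunn_posthoc",
    "scaling_regression",
    "stereographic_projection",
    "run_cohort_analysis",
    "RegressionFit",
    "ISOMETRIC_SLOPES",
]

# Expected log-log exponents against body mass under geometric similarity:
# unitless ratios scale as mass^0, linear dimensions as mass^(1/3), and
# counts per unit length as mass^(-1/3).
ISOMETRIC_SLOPES = {
    "bvtv": 0.0,
    "da": 0.0,
    "tbth": 1.0 / 3.0,
    "tbsp": 1.0 / 3.0,
    "tbn": -1.0 / 3.0,
}


def estimate_log_body_mass(circumference_mm: float | Sequence[float],
                           coefficients: tuple[float, float]) -> float:
    """log10 body mass (kg) from long-bone circumference (mm).

    logBM = a * log10(C) + b with (a, b) supplied from an external scaling
    equation (no defaults: the coefficients are study-specific).  When
    circumferences of both elements are given, the estimates are averaged.
    """
    if coefficients is None:
        raise ValueError("body-mass scaling coefficients must be supplied")
    a, b = coefficients
    c = np.atleast_1d(np.asarray(circumference_mm, dtype=float))
    if np.any(c <= 0):
        raise ValueError("circumference must be positive")
    return float(np.mean(a * np.log10(c) + b))


def coefficient_of_variation(values: Sequence[float]) -> float:
    """100 × sample standard deviation / mean (percent)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("CV needs at least two values")
    mean = v.mean()
    if mean == 0:
        raise ValueError("CV undefined for zero mean")
    return float(100.0 * v.std(ddof=1) / mean)


# ---------------------------------------------------------------------------
# Correlation


def correlation_matrix(table: pd.DataFrame, mode: str = "pearson",
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise correlation of the table's columns.

    pearson: product-moment r with two-sided p from the t distribution.
    partial: r_ij = -p_ij / sqrt(p_ii p_jj) from the inverse covariance
    matrix, i.e. each pair controlled for all remaining columns, with p
    values on n - k - 2 residual degrees of freedom.
    """
    if mode not in ("pearson", "partial"):
        raise ValueError(f"mode must be pearson or partial, got {mode!r}")
    data = table.dropna()
    n, k = data.shape
    if n < 4:
        raise ValueError("need at least 4 complete rows")
    cols = list(data.columns)
    x = data.to_numpy(dtype=float)
    if mode == "pearson":
        r = np.corrcoef(x, rowvar=False)
        dof = n - 2
    else:
        cov = np.cov(x, rowvar=False)
        if np.linalg.cond(cov) > 1e12:
            raise ValueError("singular covariance: partial correlation undefined")
        prec = np.linalg.inv(cov)
        d = np.sqrt(np.diag(prec))
        r = -prec / np.outer(d, d)
        np.fill_diagonal(r, 1.0)
        dof = n - (k - 2) - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = r * np.sqrt(dof / (1.0 - r ** 2))
    p = 2.0 * sps.t.sf(np.abs(tstat), dof)
    np.fill_diagonal(p, 0.0)
    return (pd.DataFrame(r, index=cols, columns=cols),
            pd.DataFrame(p, index=cols, columns=cols))


# ---------------------------------------------------------------------------
# PCA


def pca(table: pd.DataFrame, columns: Sequence[str] | None = None,
        scale: bool = False) -> dict[str, Any]:
    """Principal component analysis via eigendecomposition of the
    covariance of the (centered, optionally unit-scaled) columns.

    Raw azimuth must not be ordinated (it is circular); callers pass the
    folded azimuth column instead.  The sign of each component is fixed so
    its largest-magnitude loading is positive.  Returns scores, loadings
    (columns = components), explained variance, and the column means/scales
    needed for exact reconstruction.
    """
    cols = list(columns) if columns is not None else list(table.columns)
    if "azimuth" in cols:
        raise ValueError("pass the folded azimuth, not the raw circular azimuth")
    data = table[cols].dropna()
    if len(data) < 3:
        raise ValueError("need at least 3 complete rows")
    x = data.to_numpy(dtype=float)
    means = x.mean(axis=0)
    xc = x - means
    if scale:
        sd = x.std(axis=0, ddof=1)
        if np.any(sd == 0):
            raise ValueError("constant column cannot be unit-scaled")
        xc = xc / sd
    else:
        sd = np.ones(len(cols))
    cov = np.cov(xc, rowvar=False)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    for j in range(evecs.shape[1]):
        if evecs[np.abs(evecs[:, j]).argmax(), j] < 0:
            evecs[:, j] *= -1
    scores = xc @ evecs
    comp_names = [f"PC{j + 1}" for j in range(len(cols))]
    return {
        "scores": pd.DataFrame(scores, index=data.index, columns=comp_names),
        "loadings": pd.DataFrame(evecs, index=cols, columns=comp_names),
        "explained_variance": pd.Series(evals, index=comp_names),
        "explained_ratio": pd.Series(evals / evals.sum(), index=comp_names),
        "means": pd.Series(means, index=cols),
        "scales": pd.Series(sd, index=cols),
        "scaled": scale,
    }


# ---------------------------------------------------------------------------
# Nonparametric group tests


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Tie-corrected Kruskal–Wallis H and its chi-squared p-value.

    The degenerate all-tied cohort (zero rank variance) returns H = 0,
    p = 1 instead of erroring.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need >= 2 nonempty groups")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = sps.kruskal(*groups)
    return float(h), float(p)


def _dunn_z(groups: list[np.ndarray]) -> pd.DataFrame:
    """Pairwise Dunn z statistics on midranks with tie correction."""
    pooled = np.concatenate(groups)
    n_total = len(pooled)
    ranks = sps.rankdata(pooled)
    mean_ranks = []
    start = 0
    for g in groups:
        mean_ranks.append(ranks[start:start + len(g)].mean())
        start += len(g)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts ** 3 - tie_counts).sum()) / (12.0 * (n_total - 1)))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term
    rows = []
    for i, j in itertools.combinations(range(len(groups)), 2):
        se = np.sqrt(var_base * (1.0 / len(groups[i]) + 1.0 / len(groups[j])))
        z = 0.0 if se == 0 else (mean_ranks[i] - mean_ranks[j]) / se
        rows.append({"group_i": i, "group_j": j, "z": z,
                     "p_raw": 2.0 * sps.norm.sf(abs(z))})
    return pd.DataFrame(rows)


def dunn_posthoc(groups: Sequence[Sequence[float]], adjustment: str = "none",
                 labels: Sequence[str] | None = None,
                 omnibus_p: float | None = None, alpha: float = 0.05,
                 force: bool = False) -> pd.DataFrame:
    """Pairwise Dunn post-hoc comparisons on the pooled midranks.

    In pipeline use the omnibus Kruskal–Wallis p must be below alpha or the
    call is refused; a standalone call (``omnibus_p=None``) or ``force``
    runs anyway and records a warning flag in the table.
    """
    if adjustment not in ("none", "bonferroni", "holm"):
        raise ValueError(f"unknown adjustment {adjustment!r}")
    if omnibus_p is not None and omnibus_p >= alpha and not force:
        raise ValueError(
            f"omnibus test not significant (p={omnibus_p:.3g} >= alpha={alpha}); "
            "Dunn post-hoc refused (pass force=True to override)")
    gs = [np.asarray(g, dtype=float) for g in groups]
    out = _dunn_z(gs)
    m = len(out)
    if adjustment == "bonferroni":
        out["p_adjusted"] = np.minimum(1.0, out["p_raw"] * m)
    elif adjustment == "holm":
        order = np.argsort(out["p_raw"].to_numpy())
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * out["p_raw"].iloc[idx])
            adj[idx] = min(1.0, running)
        out["p_adjusted"] = adj
    else:
        out["p_adjusted"] = out["p_raw"]
    if labels is not None:
        out["group_i"] = [labels[i] for i in out["group_i"]]
        out["group_j"] = [labels[j] for j in out["group_j"]]
    out.attrs["unsanctioned"] = omnibus_p is None or (omnibus_p >= alpha)
    return out


# ---------------------------------------------------------------------------
# Allometric regression


@dataclass
class RegressionFit:
    """Polynomial + linear allometric fit of one metric against logBM."""

    response: str
    candidate_degrees: tuple[int, ...]
    cv_mse: dict[int, float]
    chosen_degree: int
    poly_coefficients: np.ndarray  # of the chosen degree, highest power first
    slope: float
    slope_ci: tuple[float, float]  # 95%
    intercept: float
    isometric_reference: float | None
    isometry_rejected: bool | None = None
    extras: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        best = min(self.cv_mse.values())
        tol = self.extras.get("mse_tol", 1e-12)
        if self.cv_mse[self.chosen_degree] > best + tol:
            raise ValueError("chosen_degree does not minimize cross-validated MSE")


def _kfold_indices(n: int, k: int, rng: np.random.Generator) -> list[np.ndarray]:
    idx = rng.permutation(n)
    return [fold for fold in np.array_split(idx, k)]


def scaling_regression(x: Sequence[float], y: Sequence[float], response: str = "",
                       candidate_degrees: Sequence[int] = (1, 2, 3, 4),
                       k: int = 10, seed: int = 0,
                       isometric_reference: float | None = None) -> RegressionFit:
    """Allometric regression of a metric on log body mass.

    Fits ordinary least squares polynomials of each candidate degree,
    selects the degree with the lowest mean k-fold held-out MSE (seeded
    shuffling), and separately fits the linear model, reporting the slope
    with its 95% confidence interval and — when an isometric reference
    exponent is given — whether that reference falls outside the CI.

    Callers pass log10-transformed x and y for slope/isometry work (the
    isometric references are log-log exponents); raw y gives descriptive
    polynomial curves.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if not candidate_degrees:
        raise ValueError("candidate_degrees must be nonempty")
    if k > n:
        raise ValueError(f"k={k} folds exceed n={n} points")
    if n < 2 * k:
        raise ValueError(f"need at least 2k={2 * k} points, got {n}")
    rng = np.random.default_rng(seed)
    folds = _kfold_indices(n, k, rng)
    cv_mse: dict[int, float] = {}
    for deg in candidate_degrees:
        errs = []
        for fold in folds:
            train = np.setdiff1d(np.arange(n), fold)
            coef = np.polyfit(x[train], y[train], deg)
            pred = np.polyval(coef, x[fold])
            errs.append(float(np.mean((y[fold] - pred) ** 2)))
        cv_mse[deg] = float(np.mean(errs))
    # smallest degree whose CV MSE is within numerical noise of the minimum
    # (exact low-degree data should not select a higher degree on round-off)
    mse_tol = 1e-10 * max(1.0, float(np.var(y)))
    best = min(cv_mse.values())
    chosen = min(d for d in cv_mse if cv_mse[d] <= best + mse_tol)
    poly_coef = np.polyfit(x, y, chosen)

    # linear fit with a 95% CI on the slope
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    dof = n - 2
    sxx = float(((x - x.mean()) ** 2).sum())
    se = np.sqrt(float((resid ** 2).sum()) / dof / sxx)
    tcrit = sps.t.ppf(0.975, dof)
    ci = (float(slope - tcrit * se), float(slope + tcrit * se))
    rejected = None
    if isometric_reference is not None:
        rejected = not (ci[0] <= isometric_reference <= ci[1])
    return RegressionFit(
        response=response, candidate_degrees=tuple(candidate_degrees),
        cv_mse=cv_mse, chosen_degree=chosen, poly_coefficients=poly_coef,
        slope=float(slope), slope_ci=ci, intercept=float(intercept),
        isometric_reference=isometric_reference, isometry_rejected=rejected,
        extras={"slope_se": float(se), "n": n, "k": k, "seed": seed,
                "mse_tol": mse_tol})


# ---------------------------------------------------------------------------
# Orientation projection


def stereographic_projection(azimuth: float | np.ndarray,
                             plunge: float | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Lambert equal-area lower-hemisphere projection onto the unit disk.

    A vertical axis (plunge 90) plots at the center; a horizontal axis on
    the primitive circle with px = sin(azimuth), py = cos(azimuth) (compass
    convention: azimuth 0 plots toward +y).
    """
    az = np.radians(np.asarray(azimuth, dtype=float))
    pl = np.asarray(plunge, dtype=float)
    r = np.sqrt(2.0) * np.sin(np.radians(90.0 - pl) / 2.0)
    return r * np.sin(az), r * np.cos(az)


# ---------------------------------------------------------------------------
# Cohort pipeline


METRIC_COLUMNS = ["da", "bvtv", "tbth", "tbsp", "tbn"]


def run_cohort_analysis(table: pd.DataFrame, alpha: float = 0.05,
                        adjustment: str = "none", k: int = 10, seed: int = 0,
                        candidate_degrees: Sequence[int] = (1, 2, 3, 4),
                        pca_scale: bool = False,
                        correlation_mode: str = "pearson") -> dict[str, Any]:
    """Full statistics stage on a cohort table.

    Expects one row per specimen × element with columns specimen_id,
    age_group, element, logbm, azimuth, plunge, and the metric columns.
    Produces per-group means and CVs, Kruskal–Wallis p per metric with Dunn
    follow-ups gated at alpha, correlation matrices per element, PCA
    (with folded azimuth), allometric regressions per metric × element, and
    projection coordinates.
    """
    required = {"specimen_id", "age_group", "element", "logbm", "azimuth", "plunge",
                *METRIC_COLUMNS}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"cohort table is missing columns: {sorted(missing)}")
    if table.empty:
        raise ValueError("empty cohort table")
    table = table.copy()
    table["azimuth_folded"] = fold_azimuth(table["azimuth"].to_numpy())
    groups_order = list(dict.fromkeys(table["age_group"]))
    angle_cols = ["azimuth_folded", "plunge"]
    report: dict[str, Any] = {"alpha": alpha, "seed": seed, "pca_scaled": pca_scale,
                              "correlation_mode": correlation_mode}

    means_rows, cv_rows, kw_rows, dunn_tables = [], [], [], {}
    correlations, pcas, regressions, projections = {}, {}, {}, {}
    for element, sub in table.groupby("element"):
        for metric in METRIC_COLUMNS + angle_cols:
            by_group = [sub.loc[sub.age_group == g, metric].to_numpy()
                        for g in groups_order]
            for g, vals in zip(groups_order, by_group):
                means_rows.append({"element": element, "metric": metric,
                                   "age_group": g, "mean": float(np.mean(vals)),
                                   "n": len(vals)})
                if len(vals) >= 2 and np.mean(vals) != 0:
                    cv_rows.append({"element": element, "metric": metric,
                                    "age_group": g,
                                    "cv_percent": coefficient_of_variation(vals)})
            h, p = kruskal_wallis(by_group)
            kw_rows.append({"element": element, "metric": metric, "H": h, "p": p})
            if p < alpha:
                dunn_tables[(element, metric)] = dunn_posthoc(
                    by_group, adjustment=adjustment, labels=groups_order,
                    omnibus_p=p, alpha=alpha)

        corr_cols = METRIC_COLUMNS + ["logbm"]
        correlations[element] = correlation_matrix(sub[corr_cols], mode=correlation_mode)
        pcas[element] = pca(sub, columns=["logbm"] + METRIC_COLUMNS + angle_cols,
                            scale=pca_scale)
        fits = {}
        for metric in METRIC_COLUMNS:
            # logbm is already log10 mass; metrics go to log10 for exponents
            fits[metric] = scaling_regression(
                sub["logbm"].to_numpy(),
                np.log10(sub[metric].to_numpy()),
                response=f"{element}:{metric}", candidate_degrees=candidate_degrees,
                k=min(k, len(sub) // 2), seed=seed,
                isometric_reference=ISOMETRIC_SLOPES[metric])
        regressions[element] = fits
        px, py = stereographic_projection(sub["azimuth"].to_numpy(),
                                          sub["plunge"].to_numpy())
        projections[element] = pd.DataFrame(
            {"specimen_id": sub["specimen_id"], "age_group": sub["age_group"],
             "px": px, "py": py})

    # logBM group test pooled over specimens (one row per specimen)
    one_per_spec = table.drop_duplicates("specimen_id")
    h, p = kruskal_wallis([one_per_spec.loc[one_per_spec.age_group == g, "logbm"].to_numpy()
                           for g in groups_order])
    kw_rows.append({"element": "both", "metric": "logbm", "H": h, "p": p})

    report.update({
        "group_means": pd.DataFrame(means_rows),
        "group_cvs": pd.DataFrame(cv_rows),
        "kruskal_wallis": pd.DataFrame(kw_rows),
        "dunn": dunn_tables,
        "correlations": correlations,
        "pca": pcas,
        "regressions": regressions,
        "projections": projections,
    })
    return report
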