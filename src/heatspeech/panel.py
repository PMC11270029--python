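"""High-dimensional fixed-effects panel estimation with clustered errors.

Implements the exposure-response regression

    Y_ipct = sum_j beta_j TEMP_ct^j + X_ct gamma + delta_mc + upsilon_d
             + mu_p + eps_ipct

where Y is a speech-level complexity score, TEMP^j are temperature-bin
dummies relative to the 12-18 deg C comfort zone, X are meteorological
controls, and the fixed effects are politician (mu_p), month-by-city
(delta_mc) and day-of-week (upsilon_d). The fixed effects are absorbed
by alternating-projections (iterative) demeaning rather than dense dummy
columns, so the estimator scales to panels with many thousands of
politician and month-by-city levels; on any given data set its
coefficients coincide with dense dummy-variable least squares.

Inference uses the CR1 cluster-robust sandwich estimator with clusters at
the month-by-city level (or at the politician level for the interaction
models), with the small-sample scale G/(G-1) * (N-1)/(N-K). Confidence
intervals use the normal 95% critical value.

The demographic-interaction variant replaces each bin dummy with the full
set of bin x level dummies; since the demographic trait is constant
within speaker its main effect is absorbed by the politician fixed
effect, and the marginal effect of a bin for a level is read directly off
the corresponding interaction coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.linalg import qr as _qr
from scipy.sparse.csgraph import connected_components
from scipy.stats import norm

__all__ = [
    "ConvergenceError",
    "PanelDesign",
    "FEEstimate",
    "demean_multiway",
    "fit_fe_ols",
    "cluster_robust_vcov",
    "fit_interaction",
    "assign_age_quartile",
    "assign_period",
    "build_design",
]

#: normal 95% two-sided critical value
Z_95 = float(norm.ppf(0.975))

DEFAULT_CONTROLS = ("precip", "rh", "wind_speed")


class ConvergenceError(RuntimeError):
    """Alternating-projections demeaning failed to reach tolerance."""

    def __init__(self, msg: str, residual: float):
        super().__init__(msg)
        self.residual = residual


# ---------------------------------------------------------------------------
# design container


@dataclass
class PanelDesign:
    """Assembled estimation table.

    ``X`` stacks exposure dummies (named in ``exposure_cols``) and control
    columns. ``fe`` maps a dimension name to a label vector (any dtype);
    labels are factorized to dense integer codes on construction.
    """

    y: np.ndarray
    X: np.ndarray
    colnames: list[str]
    fe: dict[str, np.ndarray]
    clusters: np.ndarray
    exposure_cols: list[str] = field(default_factory=list)
    row_ids: np.ndarray | None = None
    cluster_scheme: str = "custom"

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        n = self.y.shape[0]
        if n < 1:
            raise ValueError("empty design")
        if self.X.shape[0] != n or len(self.clusters) != n:
            raise ValueError("row count mismatch")
        if self.X.shape[1] != len(self.colnames):
            raise ValueError("colnames/X mismatch")
        unknown = set(self.exposure_cols) - set(self.colnames)
        if unknown:
            raise ValueError(f"exposure_cols not in colnames: {sorted(unknown)}")
        self.fe_codes: dict[str, np.ndarray] = {}
        self.fe_levels: dict[str, int] = {}
        for name, labels in self.fe.items():
            labels = np.asarray(labels)
            if len(labels) != n:
                raise ValueError(f"FE dimension {name!r}: row count mismatch")
            codes, uniques = pd.factorize(labels)
            if len(uniques) < 2:
                raise ValueError(f"FE dimension {name!r} has fewer than 2 levels")
            self.fe_codes[name] = codes.astype(np.int64)
            self.fe_levels[name] = len(uniques)
        ccodes, cuniq = pd.factorize(np.asarray(self.clusters))
        self.cluster_codes = ccodes.astype(np.int64)
        self.n_clusters = len(cuniq)

    @property
    def n_obs(self) -> int:
        return len(self.y)


@dataclass
class FEEstimate:
    """Fitted coefficients with cluster-robust inference and fit metadata."""

    beta: pd.Series
    vcov: pd.DataFrame
    se: pd.Series
    ci_low: pd.Series
    ci_high: pd.Series
    n_obs: int
    n_clusters: int
    fe_levels: dict[str, int]
    df_model: int
    demeaning_iterations: int
    converged: bool
    dropped_columns: list[str]
    singleton_fe_groups: dict[str, int]
    cluster_scheme: str = "custom"

    def to_frame(self) -> pd.DataFrame:
        """Coefficient table: term, estimate, clustered SE, 95% CI."""
        return pd.DataFrame(
            {
                "term": self.beta.index,
                "estimate": self.beta.to_numpy(),
                "se": self.se.to_numpy(),
                "ci_low": self.ci_low.to_numpy(),
                "ci_high": self.ci_high.to_numpy(),
                "n_obs": self.n_obs,
                "n_clusters": self.n_clusters,
                "cluster_scheme": self.cluster_scheme,
            }
        )


# ---------------------------------------------------------------------------
# demeaning


def _group_means(M: np.ndarray, codes: np.ndarray, counts: np.ndarray) -> np.ndarray:
    out = np.empty((len(counts), M.shape[1]))
    for j in range(M.shape[1]):
        out[:, j] = np.bincount(codes, weights=M[:, j], minlength=len(counts))
    out /= counts[:, None]
    return out


def demean_multiway(
    M: np.ndarray,
    groups: Sequence[np.ndarray],
    tol: float = 1e-10,
    max_iter: int = 10_000,
) -> tuple[np.ndarray, int, bool]:
    """Within-transformation across several crossed grouping dimensions.

    Iteratively subtracts group means, sweeping the dimensions in their
    declared order, until the largest absolute column-wise group mean
    across all dimensions falls below ``tol``. With a single dimension
    one sweep is exact.

    Returns ``(demeaned, n_sweeps, converged)``; raises
    :class:`ConvergenceError` (carrying the residual deviation) if the
    tolerance is not met within ``max_iter`` sweeps.
    """
    M = np.array(M, dtype=float, copy=True)
    vec = M.ndim == 1
    if vec:
        M = M[:, None]
    codes_list = [np.asarray(c, dtype=np.int64) for c in groups]
    if not codes_list:
        raise ValueError("need at least one grouping dimension")
    counts_list = [np.bincount(c) for c in codes_list]
    scale = max(float(np.max(np.abs(M))), 1.0)
    dev = np.inf
    for sweep in range(1, max_iter + 1):
        for codes, counts in zip(codes_list, counts_list):
            gm = _group_means(M, codes, counts)
            M -= gm[codes]
        dev = 0.0
        for codes, counts in zip(codes_list, counts_list):
            gm = _group_means(M, codes, counts)
            dev = max(dev, float(np.max(np.abs(gm))))
        if dev < tol * scale:
            return (M[:, 0] if vec else M), sweep, True
    raise ConvergenceError(
        f"demeaning did not converge in {max_iter} sweeps "
        f"(residual group-mean deviation {dev:.3e})",
        residual=dev,
    )


def _absorbed_dof(codes_list: list[np.ndarray], levels: list[int]) -> int:
    """Rank of the implicit fixed-effect dummy block.

    Exact for one or two dimensions (two crossed dimensions lose one
    degree of freedom per connected component of their bipartite graph);
    each further dimension contributes the standard levels-1 count.
    """
    if len(codes_list) == 1:
        return levels[0]
    c1, c2 = codes_list[0], codes_list[1]
    l1, l2 = levels[0], levels[1]
    adj = sparse.coo_matrix(
        (np.ones(len(c1)), (c1, l1 + c2)), shape=(l1 + l2, l1 + l2)
    )
    ncomp, _ = connected_components(adj, directed=False)
    dof = l1 + l2 - ncomp
    for lv in levels[2:]:
        dof += lv - 1
    return dof


def _singleton_counts(design: PanelDesign) -> dict[str, int]:
    out = {}
    for name, codes in design.fe_codes.items():
        out[name] = int(np.sum(np.bincount(codes) == 1))
    return out


# ---------------------------------------------------------------------------
# estimation


def cluster_robust_vcov(
    X: np.ndarray,
    residuals: np.ndarray,
    cluster_codes: np.ndarray,
    n_clusters: int,
    df_model: int,
) -> np.ndarray:
    """CR1 sandwich variance on (demeaned) regressors.

    (X'X)^-1 [ sum_g X_g' e_g e_g' X_g ] (X'X)^-1 scaled by
    G/(G-1) * (N-1)/(N-K), where K = ``df_model`` counts slope columns
    plus absorbed fixed-effect levels. With every row its own cluster
    this reduces to the HC1-type estimator up to the scalar
    N/(N-1) * (G-... ) bookkeeping of the two corrections. Clusters with
    a single row are allowed; fewer than two clusters are not.
    """
    if n_clusters < 2:
        raise ValueError("cluster-robust variance requires at least 2 clusters")
    n, k = X.shape
    if n - df_model <= 0:
        raise ValueError("no residual degrees of freedom")
    bread = np.linalg.inv(X.T @ X)
    scores = X * residuals[:, None]
    S = np.empty((n_clusters, k))
    for j in range(k):
        S[:, j] = np.bincount(cluster_codes, weights=scores[:, j], minlength=n_clusters)
    meat = S.T @ S
    g = n_clusters
    scale = (g / (g - 1.0)) * ((n - 1.0) / (n - df_model))
    vcov = scale * bread @ meat @ bread
    return (vcov + vcov.T) / 2.0


def fit_fe_ols(
    design: PanelDesign,
    demean_tol: float = 1e-10,
    max_iter: int = 10_000,
) -> FEEstimate:
    """Least squares on outcome and regressors demeaned over all FE dims.

    Collinear columns (after demeaning) are pruned via a pivoted QR
    decomposition and reported in ``dropped_columns``; the coefficients
    equal a dense regression with explicit dummy columns for every fixed
    effect level on the same rows.
    """
    codes_list = [design.fe_codes[name] for name in design.fe]
    levels = [design.fe_levels[name] for name in design.fe]
    Z = np.column_stack([design.y, design.X])
    Zd, iters, converged = demean_multiway(Z, codes_list, demean_tol, max_iter)
    yd, Xd = Zd[:, 0], Zd[:, 1:]

    _, R, piv = _qr(Xd, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    if diag.size == 0 or diag[0] == 0.0:
        raise ValueError("no identifying variation left after demeaning")
    rank = int(np.sum(diag > diag[0] * 1e-9))
    keep = np.sort(piv[:rank])
    dropped = [design.colnames[i] for i in np.sort(piv[rank:])]
    if rank == 0:
        raise ValueError(
            f"rank-deficient design; offending columns: {dropped}"
        )
    Xk = Xd[:, keep]
    names = [design.colnames[i] for i in keep]

    beta, *_ = np.linalg.lstsq(Xk, yd, rcond=None)
    resid = yd - Xk @ beta

    df_model = rank + _absorbed_dof(codes_list, levels)
    vcov = cluster_robust_vcov(
        Xk, resid, design.cluster_codes, design.n_clusters, df_model
    )
    se = np.sqrt(np.diag(vcov))
    beta_s = pd.Series(beta, index=names, name="estimate")
    se_s = pd.Series(se, index=names, name="se")
    return FEEstimate(
        beta=beta_s,
        vcov=pd.DataFrame(vcov, index=names, columns=names),
        se=se_s,
        ci_low=beta_s - Z_95 * se_s,
        ci_high=beta_s + Z_95 * se_s,
        n_obs=design.n_obs,
        n_clusters=design.n_clusters,
        fe_levels=dict(design.fe_levels),
        df_model=df_model,
        demeaning_iterations=iters,
        converged=converged,
        dropped_columns=dropped,
        singleton_fe_groups=_singleton_counts(design),
        cluster_scheme=design.cluster_scheme,
    )


def fit_interaction(
    design: PanelDesign,
    demographic: np.ndarray,
    speaker_fe: str = "politician",
    speaker_constant: bool = True,
    demean_tol: float = 1e-10,
    max_iter: int = 10_000,
) -> tuple[FEEstimate, pd.DataFrame]:
    """Exposure x demographic interaction model with marginal effects.

    Each exposure dummy is expanded into one column per demographic
    level (``bin:level``); controls are carried through unchanged. For a
    speaker-constant trait (``speaker_constant=True``, validated against
    the speaker FE dimension) the level main effect is absorbed by the
    speaker fixed effect; traits that evolve within speaker (age
    quartile, calendar period) set ``speaker_constant=False``, matching a
    specification with interaction terms only. Either way the marginal
    effect of a bin at a level is the interaction coefficient itself,
    with its clustered SE (a unit linear combination under the delta
    rule).

    Returns the fitted model and a marginal-effects table keyed by
    (bin, level); a (bin, level) cell with no observations appears in
    the table with missing estimate/SE rather than being dropped
    silently. With a single-level demographic the model reduces exactly
    to :func:`fit_fe_ols`.
    """
    demo = np.asarray(demographic)
    if len(demo) != design.n_obs:
        raise ValueError("demographic length mismatch")
    if pd.isna(demo).any():
        raise ValueError("demographic contains missing values")
    if speaker_constant and speaker_fe in design.fe:
        df = pd.DataFrame({"s": design.fe_codes[speaker_fe], "d": demo})
        if (df.groupby("s")["d"].nunique() > 1).any():
            raise ValueError(
                f"demographic varies within {speaker_fe!r}; must be speaker-constant"
            )
    if isinstance(demo.dtype, pd.CategoricalDtype):  # pragma: no cover
        levels = list(demo.dtype.categories)
    else:
        levels = sorted(pd.unique(demo).tolist())

    exposure = [c for c in design.colnames if c in design.exposure_cols]
    if not exposure:
        raise ValueError("design has no exposure columns to interact")
    controls = [c for c in design.colnames if c not in design.exposure_cols]
    col_idx = {c: i for i, c in enumerate(design.colnames)}

    if len(levels) == 1:
        est = fit_fe_ols(design, demean_tol, max_iter)
        me = _marginal_table(est, exposure, levels, sep=None)
        return est, me

    cols, names = [], []
    for b in exposure:
        base = design.X[:, col_idx[b]]
        for lev in levels:
            cols.append(base * (demo == lev))
            names.append(f"{b}:{lev}")
    for c in controls:
        cols.append(design.X[:, col_idx[c]])
        names.append(c)
    inter = PanelDesign(
        y=design.y,
        X=np.column_stack(cols),
        colnames=names,
        fe=design.fe,
        clusters=design.clusters,
        exposure_cols=[n for n in names if ":" in n],
        row_ids=design.row_ids,
        cluster_scheme=design.cluster_scheme,
    )
    est = fit_fe_ols(inter, demean_tol, max_iter)
    me = _marginal_table(est, exposure, levels, sep=":")
    return est, me


def _marginal_table(
    est: FEEstimate, exposure: list[str], levels: list, sep: str | None
) -> pd.DataFrame:
    rows = []
    for b in exposure:
        for lev in levels:
            term = b if sep is None else f"{b}{sep}{lev}"
            if term in est.beta.index:
                rows.append(
                    {
                        "bin": b,
                        "level": lev,
                        "estimate": est.beta[term],
                        "se": est.se[term],
                        "ci_low": est.ci_low[term],
                        "ci_high": est.ci_high[term],
                        "missing": False,
                    }
                )
            else:
                rows.append(
                    {
                        "bin": b,
                        "level": lev,
                        "estimate": np.nan,
                        "se": np.nan,
                        "ci_low": np.nan,
                        "ci_high": np.nan,
                        "missing": True,
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# demographic groupers


def assign_age_quartile(age):
    """Age-quartile label: Q1 <=44, Q2 45-50, Q3 51-56, Q4 >=57.

    Integer ages are expected (ages are validated to be >= 18); missing
    ages yield a missing label.
    """
    a = np.asarray(age, dtype=float)
    scalar = a.ndim == 0
    a = np.atleast_1d(a)
    valid = ~np.isnan(a)
    if np.any(a[valid] < 18):
        raise ValueError("age below 18")
    out = np.select(
        [a <= 44, a <= 50, a <= 56, a >= 57],
        ["Q1", "Q2", "Q3", "Q4"],
        default=None,
    ).astype(object)
    out[~valid] = None
    return out[0] if scalar else out


PERIODS = ((1950, 1967), (1968, 1985), (1986, 2003), (2004, 2019))


def assign_period(year):
    """Study-period label for a calendar year (closed ranges)."""
    y = np.asarray(year, dtype=int)
    scalar = y.ndim == 0
    y = np.atleast_1d(y)
    if np.any(y < PERIODS[0][0]) or np.any(y > PERIODS[-1][1]):
        raise ValueError(
            f"year outside study span {PERIODS[0][0]}-{PERIODS[-1][1]}"
        )
    labels = [f"{lo}-{hi}" for lo, hi in PERIODS]
    conds = [(y >= lo) & (y <= hi) for lo, hi in PERIODS]
    out = np.select(conds, labels, default="").astype(object)
    return out[0] if scalar else out


# ---------------------------------------------------------------------------
# design assembly


def build_design(
    speeches: pd.DataFrame,
    weather: pd.DataFrame,
    scheme,
    outcome: str = "flesch_kincaid",
    controls: Sequence[str] = DEFAULT_CONTROLS,
    extra_controls: Sequence[str] = (),
    month_fe: str = "month_of_year",
    cluster_scheme: str = "month_by_city",
    cluster_month: str = "month_of_year",
    speaker_col: str = "speaker_id",
    city_col: str = "city",
    date_col: str = "date",
    id_col: str = "speech_id",
) -> tuple[PanelDesign, dict]:
    """Join scored speeches to weather features and assemble the design.

    Exposure dummies encode ``temp_bin`` against the scheme's reference
    (comfort) bin; all non-reference bins get a column even if empty in
    the data (empty columns are pruned, and reported, at fit time).
    ``month_fe`` selects the month-by-city convention: calendar
    month-of-year x city (seasonal, the default) or year-month x city.
    ``cluster_scheme`` is ``month_by_city`` (at ``cluster_month``
    granularity) or ``politician``. Rows that fail to join to a weather
    day or have missing required fields are dropped with logged counts.
    """
    if month_fe not in ("month_of_year", "year_month"):
        raise ValueError("month_fe must be 'month_of_year' or 'year_month'")
    if cluster_scheme not in ("month_by_city", "politician"):
        raise ValueError("cluster_scheme must be 'month_by_city' or 'politician'")

    sp = speeches.copy()
    sp[date_col] = pd.to_datetime(sp[date_col])
    wx = weather.copy()
    wx[date_col] = pd.to_datetime(wx[date_col])

    wx_cols = [city_col, date_col, "temp_bin"] + [
        c for c in list(controls) + list(extra_controls) if c in wx.columns
    ]
    merged = sp.merge(
        wx[wx_cols], on=[city_col, date_col], how="left", indicator=True
    )
    n_read = len(merged)
    unjoined = merged["_merge"] != "both"
    n_unjoined = int(unjoined.sum())
    merged = merged.loc[~unjoined].drop(columns="_merge")

    all_controls = list(controls) + list(extra_controls)
    required = [outcome, "temp_bin"] + all_controls
    missing_cols = [c for c in required if c not in merged.columns]
    if missing_cols:
        raise ValueError(f"missing required columns: {missing_cols}")
    bad = merged[required].isna().any(axis=1)
    n_missing = int(bad.sum())
    merged = merged.loc[~bad]
    if merged.empty:
        raise ValueError("all rows dropped while building the design")

    tb = np.asarray(merged["temp_bin"], dtype=object)
    exposure_labels = scheme.non_reference_labels
    dummies = np.column_stack([(tb == lab).astype(float) for lab in exposure_labels])
    Xc = merged[all_controls].to_numpy(dtype=float)

    dates = merged[date_col]
    city_s = merged[city_col].astype(str)
    moy_city = (city_s + "|m" + dates.dt.month.astype(str)).to_numpy()
    ym_city = (city_s + "|" + dates.dt.strftime("%Y-%m")).to_numpy()
    fe = {
        "politician": merged[speaker_col].to_numpy(),
        "month_city": moy_city if month_fe == "month_of_year" else ym_city,
        "day_of_week": dates.dt.dayofweek.to_numpy(),
    }

    if cluster_scheme == "politician":
        clusters = merged[speaker_col].to_numpy()
    else:
        clusters = moy_city if cluster_month == "month_of_year" else ym_city

    design = PanelDesign(
        y=merged[outcome].to_numpy(dtype=float),
        X=np.column_stack([dummies, Xc]),
        colnames=list(exposure_labels) + all_controls,
        fe=fe,
        clusters=clusters,
        exposure_cols=list(exposure_labels),
        row_ids=merged[id_col].to_numpy() if id_col in merged.columns else None,
        cluster_scheme=cluster_scheme,
    )
    log = {
        "read": n_read,
        "unjoined": n_unjoined,
        "missing_field": n_missing,
        "estimated": design.n_obs,
    }
    return design, log
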