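"""Doctor-week panel construction and fixed-effects estimation.

The validation model regresses weekly patient demand on the previous
week's five dimension-sentiment scores plus controls:

    Y_it = α + Γ X_{i,t−1} + Ctrl_it + θ_t + μ_i + ε_it

with week effects θ_t, doctor effects μ_i, and errors clustered by
doctor. Two estimation modes are exposed:

* ``twoway_fe`` — the within estimator absorbing doctor and week
  intercepts by alternating demeaning; time-invariant controls cannot
  be identified and are dropped with a notice. Numerically identical to
  least squares on full doctor and week indicator columns.
* ``pooled_weekfe`` — pooled OLS with week indicators only, keeping
  time-invariant doctor controls identifiable.

Clustered covariance is the CR1 sandwich with the small-sample factor
G/(G−1) · (N−1)/(N−K), G the number of doctors and K the column count
of the equivalent dummy-variable regression.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from hsq5d.constants import DIMENSIONS

logger = logging.getLogger(__name__)

#: Count-valued controls, entered as log(1 + count).
COUNT_CONTROLS = ("visits", "votes", "thanks", "gifts")


@dataclass(frozen=True)
class FEResult:
    """Fitted coefficients with doctor-clustered inference."""

    params: pd.Series
    se: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    r2: float
    n: int
    n_doctors: int
    n_weeks: int
    mode: str
    dropped: tuple[str, ...] = ()

    def summary(self) -> str:
        lines = [f"mode={self.mode}  n={self.n}  doctors={self.n_doctors} "
                 f"weeks={self.n_weeks}  R2={self.r2:.4f}"]
        lines.append(f"{'variable':<16}{'coef':>10}{'se':>10}{'t':>8}{'p':>8}")
        for name in self.params.index:
            lines.append(
                f"{name:<16}{self.params[name]:>10.4f}{self.se[name]:>10.4f}"
                f"{self.tvalues[name]:>8.2f}{self.pvalues[name]:>8.3f}"
            )
        if self.dropped:
            lines.append(f"dropped (time-invariant): {', '.join(self.dropped)}")
        return "\n".join(lines)


@dataclass(frozen=True)
class MarginalEffect:
    """Demand response to a one-SD increase in a dimension score.

    With log-transformed demand, a one-SD rise changes log demand by
    γσ, i.e. demand by exp(γσ) − 1 (as a fraction)."""

    dimension: str
    coefficient: float
    sd: float

    @property
    def log_effect(self) -> float:
        return self.coefficient * self.sd

    @property
    def percent_effect(self) -> float:
        return math.exp(self.log_effect) - 1.0


def marginal_effect(gamma: float, sigma: float, dimension: str = "") -> MarginalEffect:
    """One-SD marginal effect of a dimension on (log) demand."""
    if sigma < 0:
        raise ValueError("sd must be non-negative")
    return MarginalEffect(dimension=dimension, coefficient=gamma, sd=sigma)


def build_panel(
    dimension_scores: pd.DataFrame,
    demand: pd.DataFrame,
    controls: pd.DataFrame | None = None,
    *,
    lag: int = 1,
    missing_policy: str = "drop",
) -> pd.DataFrame:
    """Join demand at week t with dimension scores at week t − lag.

    ``dimension_scores`` is long (doctor_id, week, dimension, score);
    ``demand`` has (doctor_id, week, demand); ``controls`` is keyed by
    doctor_id (time-invariant) or (doctor_id, week). Count controls
    (visits, votes, thanks, gifts) are transformed to log(1+count).
    Rows are kept only where Y and all five lagged scores are defined;
    ``missing_policy`` "carry_forward" fills a missing score week with
    the doctor's most recent earlier score before applying that rule.
    """
    if missing_policy not in ("drop", "carry_forward"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    wide = dimension_scores.pivot_table(
        index=["doctor_id", "week"], columns="dimension", values="score", aggfunc="first"
    )
    for dim in DIMENSIONS:
        if dim not in wide.columns:
            wide[dim] = np.nan
    wide = wide[list(DIMENSIONS)].reset_index()
    if missing_policy == "carry_forward":
        # expand to the full week range per doctor so gap weeks exist to fill
        lo = int(min(wide["week"].min(), demand["week"].min() - lag))
        hi = int(max(wide["week"].max(), demand["week"].max() - lag))
        full = pd.MultiIndex.from_product(
            [wide["doctor_id"].unique(), range(lo, hi + 1)], names=["doctor_id", "week"]
        )
        wide = (
            wide.set_index(["doctor_id", "week"]).reindex(full).reset_index()
            .sort_values(["doctor_id", "week"])
        )
        wide[list(DIMENSIONS)] = wide.groupby("doctor_id")[list(DIMENSIONS)].ffill()

    if demand.duplicated(["doctor_id", "week"]).any():
        raise ValueError("duplicate (doctor_id, week) keys in demand table")
    if wide.duplicated(["doctor_id", "week"]).any():
        raise ValueError("duplicate (doctor_id, week, dimension) keys in scores")

    lagged = wide.copy()
    lagged["week"] = lagged["week"] + lag  # score at t−lag aligns with demand at t
    panel = demand.merge(lagged, on=["doctor_id", "week"], how="inner")
    panel = panel.dropna(subset=list(DIMENSIONS))

    if controls is not None:
        keys = ["doctor_id", "week"] if "week" in controls.columns else ["doctor_id"]
        if controls.duplicated(keys).any():
            raise ValueError("duplicate keys in controls table")
        controls = controls.copy()
        for col in controls.columns:
            if col in COUNT_CONTROLS:
                controls[f"log_{col}"] = np.log1p(controls[col])
                controls = controls.drop(columns=[col])
        panel = panel.merge(controls, on=keys, how="inner")
    return panel.sort_values(["doctor_id", "week"]).reset_index(drop=True)


def _demean_two_way(df: pd.DataFrame, cols: list[str], tol: float = 1e-12) -> pd.DataFrame:
    """Alternating projections: subtract doctor and week means until both
    group means vanish. Exact in one pass on balanced panels."""
    work = df[cols].astype(float).copy()
    for _ in range(200):
        work -= work.groupby(df["doctor_id"]).transform("mean")
        work -= work.groupby(df["week"]).transform("mean")
        gmax = max(
            work.groupby(df["doctor_id"]).mean().abs().to_numpy().max(),
            work.groupby(df["week"]).mean().abs().to_numpy().max(),
        )
        if gmax < tol:
            break
    return work


def _cluster_cov(
    X: np.ndarray, resid: np.ndarray, groups: np.ndarray, k_model: int
) -> np.ndarray:
    """CR1 clustered sandwich covariance."""
    n = X.shape[0]
    XtX_inv = np.linalg.inv(X.T @ X)
    meat = np.zeros((X.shape[1], X.shape[1]))
    for g in np.unique(groups):
        idx = groups == g
        s = X[idx].T @ resid[idx]
        meat += np.outer(s, s)
    G = len(np.unique(groups))
    c = (G / (G - 1)) * ((n - 1) / (n - k_model))
    return c * XtX_inv @ meat @ XtX_inv


def fit_fe(
    panel: pd.DataFrame,
    *,
    mode: str = "twoway_fe",
    regressors: list[str] | None = None,
    y: str = "demand",
    log_y: bool = False,
) -> FEResult:
    """Fit the demand model on a built panel.

    ``regressors`` defaults to the five dimensions plus every column
    that is neither a key, the outcome, nor a dimension (the controls).
    ``log_y=True`` regresses log(1 + Y) for count-valued demand.
    """
    if mode not in ("twoway_fe", "pooled_weekfe"):
        raise ValueError(f"unknown mode {mode!r}")
    if panel["doctor_id"].nunique() < 2 or panel["week"].nunique() < 2:
        raise ValueError("need at least 2 doctors and 2 weeks")

    panel = panel.reset_index(drop=True)
    if regressors is None:
        skip = {"doctor_id", "week", y}
        regressors = [d for d in DIMENSIONS if d in panel.columns] + [
            c for c in panel.columns if c not in skip and c not in DIMENSIONS
        ]
    yv = panel[y].astype(float).to_numpy()
    if log_y:
        yv = np.log1p(yv)
    groups = panel["doctor_id"].to_numpy()
    G = panel["doctor_id"].nunique()
    T = panel["week"].nunique()
    n = len(panel)
    dropped: tuple[str, ...] = ()

    if mode == "twoway_fe":
        # time-invariant columns are collinear with the doctor effects
        invariant = [
            c for c in regressors
            if panel.groupby("doctor_id")[c].nunique(dropna=False).le(1).all()
        ]
        if invariant:
            logger.info("dropping time-invariant controls in twoway_fe: %s", invariant)
            dropped = tuple(invariant)
            regressors = [c for c in regressors if c not in invariant]
        work = panel[regressors].astype(float).copy()
        work["__y"] = yv
        dm = _demean_two_way(work.assign(doctor_id=panel["doctor_id"], week=panel["week"]),
                             regressors + ["__y"])
        X = dm[regressors].to_numpy()
        yd = dm["__y"].to_numpy()
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            _raise_collinear(X, regressors)
        beta, *_ = np.linalg.lstsq(X, yd, rcond=None)
        resid = yd - X @ beta
        k_model = X.shape[1] + 1 + (G - 1) + (T - 1)  # dummy-regression column count
        cov = _cluster_cov(X, resid, groups, k_model)
        names = list(regressors)
        # overall R2 including the fixed effects themselves
        r2 = 1.0 - float(resid @ resid) / float(((yv - yv.mean()) ** 2).sum())
    else:
        week_d = pd.get_dummies(panel["week"], prefix="week", drop_first=True, dtype=float)
        X = np.column_stack(
            [np.ones(n), panel[regressors].astype(float).to_numpy(), week_d.to_numpy()]
        )
        names = ["const"] + list(regressors) + list(week_d.columns)
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            _raise_collinear(X, names)
        beta, *_ = np.linalg.lstsq(X, yv, rcond=None)
        resid = yv - X @ beta
        cov = _cluster_cov(X, resid, groups, X.shape[1])
        r2 = 1.0 - float(resid @ resid) / float(((yv - yv.mean()) ** 2).sum())

    se = np.sqrt(np.diag(cov))
    tvals = beta / se
    pvals = 2 * stats.norm.sf(np.abs(tvals))  # normal reference; G large in intended use
    keep = [i for i, nm in enumerate(names) if not nm.startswith("week_")]
    return FEResult(
        params=pd.Series(beta[keep], index=[names[i] for i in keep]),
        se=pd.Series(se[keep], index=[names[i] for i in keep]),
        tvalues=pd.Series(tvals[keep], index=[names[i] for i in keep]),
        pvalues=pd.Series(pvals[keep], index=[names[i] for i in keep]),
        r2=r2,
        n=n,
        n_doctors=G,
        n_weeks=T,
        mode=mode,
        dropped=dropped,
    )


def _raise_collinear(X: np.ndarray, names: list[str]) -> None:
    """Identify a minimal set of columns involved in exact collinearity."""
    bad = []
    kept: list[int] = []
    for j in range(X.shape[1]):
        trial = X[:, kept + [j]]
        if np.linalg.matrix_rank(trial) < trial.shape[1]:
            bad.append(names[j])
        else:
            kept.append(j)
    raise ValueError(f"rank-deficient design; collinear columns: {bad}")


def stepwise_r2(
    panel: pd.DataFrame,
    *,
    order: tuple[str, ...] = DIMENSIONS,
    mode: str = "twoway_fe",
    y: str = "demand",
    log_y: bool = False,
) -> list[float]:
    """Information load: R² of the controls-only model, then of models
    adding the dimensions one at a time in ``order``. The sequence has
    length ``len(order) + 1`` and is non-decreasing (nested models)."""
    skip = {"doctor_id", "week", y}
    controls = [c for c in panel.columns if c not in skip and c not in DIMENSIONS]
    out: list[float] = []
    for i in range(len(order) + 1):
        regs = list(order[:i]) + controls
        if regs:
            try:
                res = fit_fe(panel, mode=mode, regressors=regs, y=y, log_y=log_y)
                out.append(res.r2)
            except ValueError:
                # the newly added regressor is collinear with the current
                # model: it carries no new information, R² is unchanged
                if not out:
                    raise
                out.append(out[-1])
        else:
            out.append(_fe_only_r2(panel, mode=mode, y=y, log_y=log_y))
    return out


def _fe_only_r2(panel: pd.DataFrame, *, mode: str, y: str, log_y: bool) -> float:
    yv = panel[y].astype(float).to_numpy()
    if log_y:
        yv = np.log1p(yv)
    if mode == "twoway_fe":
        dm = _demean_two_way(
            panel.assign(__y=yv)[["doctor_id", "week", "__y"]], ["__y"]
        )
        resid = dm["__y"].to_numpy()
    else:
        resid = yv - pd.Series(yv).groupby(panel["week"]).transform("mean").to_numpy()
    return 1.0 - float(resid @ resid) / float(((yv - yv.mean()) ** 2).sum())


def censor_dependent(panel: pd.DataFrame, fraction: float = 0.10, y: str = "demand") -> pd.DataFrame:
    """Outlier robustness: drop the ⌊fN⌋ lowest and ⌊fN⌋ highest rows by
    the dependent variable (stable sort, so ties resolve by row order)."""
    if not 0 <= fraction < 0.5:
        raise ValueError("fraction must be in [0, 0.5)")
    n = len(panel)
    k = int(np.floor(fraction * n))
    if k == 0:
        return panel.copy()
    order = panel[y].to_numpy().argsort(kind="stable")
    keep = np.sort(order[k : n - k])
    return panel.iloc[keep].reset_index(drop=True)
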