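"""Seemingly unrelated regression (SUR) cost-effectiveness analysis.

The short-term (12-month) analysis jointly estimates, per therapy system, a
cost equation and an effect (QALY) equation on therapy indicator variables:

    cost_i   = alpha_0 + sum_t alpha_t * D_{ti} + u_{1i}
    effect_i = beta_0  + sum_t beta_t  * D_{ti} + u_{2i}

where D_{ti} = 1 if child i receives therapy t in addition to standard care.
The two disturbances are cross-correlated (shared unobserved factors), so the
system is estimated by feasible generalized least squares (FGLS): per-equation
OLS, residual cross-covariance, then GLS with the Kronecker-structured weight.
Because both equations share an identical regressor matrix the FGLS point
estimates coincide with per-equation OLS -- a classical identity the test
suite asserts on every fit -- but the joint coefficient covariance carries the
cross-equation correlation that the acceptability curves and confidence
ellipses require.

The intercepts estimate the standard-care means; each therapy coefficient pair
(alpha_t, beta_t) is the incremental cost and incremental effect feeding the
therapy's ICER.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import ERT_THERAPIES, IRT_THERAPIES
from .errors import EstimationError, InputError
from .icer import EFFECT_TOLERANCE, IcerResult, classify_icer
from .qaly import add_qaly_column


@dataclass(frozen=True)
class SureSpec:
    """Specification of one two-equation cost/effect system."""

    cost_outcome: str = "cost_total"
    effect_outcome: str = "qaly"
    regressors: tuple[str, ...] = IRT_THERAPIES
    include_intercept: bool = True

    def __post_init__(self) -> None:
        if len(set(self.regressors)) != len(self.regressors):
            raise InputError("regressor names must be distinct")
        if not self.include_intercept:
            raise InputError("the cost/effect system always includes an intercept")


IRT_SPEC = SureSpec(regressors=IRT_THERAPIES)
ERT_SPEC = SureSpec(regressors=ERT_THERAPIES)


@dataclass
class SureFit:
    """Jointly estimated cost/effect system.

    ``alpha``/``beta`` are indexed by ``const`` plus the therapy regressors.
    ``coef_cov`` is the full 2k x 2k coefficient covariance, rows/columns
    labelled ``cost:<name>`` then ``effect:<name>``.  ``resid_cov`` is the 2x2
    residual cross-covariance (divisor n).
    """

    spec: SureSpec
    alpha: pd.Series
    beta: pd.Series
    coef_cov: pd.DataFrame
    resid_cov: np.ndarray
    n_used: int
    se: pd.DataFrame = field(repr=False)
    p_values: pd.DataFrame = field(repr=False)

    def delta_block(self, therapy: str) -> tuple[np.ndarray, np.ndarray]:
        """Mean vector (d_cost, d_effect) and 2x2 covariance for one therapy."""
        if therapy not in self.spec.regressors:
            raise InputError(f"{therapy!r} is not a regressor of this system")
        labels = [f"cost:{therapy}", f"effect:{therapy}"]
        mu = np.array([self.alpha[therapy], self.beta[therapy]])
        cov = self.coef_cov.loc[labels, labels].to_numpy()
        return mu, cov

    def to_dict(self) -> dict:
        """JSON-serialisable representation (coefficients and covariances)."""
        return {
            "cost_outcome": self.spec.cost_outcome,
            "effect_outcome": self.spec.effect_outcome,
            "regressors": list(self.spec.regressors),
            "n_used": self.n_used,
            "alpha": self.alpha.to_dict(),
            "beta": self.beta.to_dict(),
            "se_cost": self.se["cost"].to_dict(),
            "se_effect": self.se["effect"].to_dict(),
            "p_cost": self.p_values["cost"].to_dict(),
            "p_effect": self.p_values["effect"].to_dict(),
            "coef_cov": self.coef_cov.to_dict(),
            "resid_cov": self.resid_cov.tolist(),
        }


def fit_sure(
    cohort: pd.DataFrame,
    spec: SureSpec,
    iterate: bool = False,
    max_iter: int = 50,
    tol: float = 1e-10,
) -> SureFit:
    """Fit a two-equation cost/effect system by feasible GLS.

    Complete-case: rows with ``completed_followup == 0`` are dropped first.
    ``iterate=True`` re-estimates the residual covariance and GLS step until
    convergence (iterated FGLS); the default is the one-step estimator.
    """
    df = cohort
    if "completed_followup" in df.columns:
        df = df[df["completed_followup"] == 1]
    names = ["const", *spec.regressors]
    k = len(names)
    if len(df) < k + 2:
        raise EstimationError(
            f"n_used = {len(df)} is insufficient for k = {k} regressors"
        )
    for col in (*spec.regressors, spec.cost_outcome, spec.effect_outcome):
        if col not in df.columns:
            raise InputError(f"cohort table lacks column {col!r}")

    X = np.column_stack(
        [np.ones(len(df))] + [df[r].to_numpy(dtype=float) for r in spec.regressors]
    )
    for j, r in enumerate(spec.regressors, start=1):
        if np.all(X[:, j] == 0):
            raise EstimationError(f"therapy column {r!r} has zero recipients")
    if np.linalg.matrix_rank(X) < k:
        raise EstimationError(
            f"design matrix is rank deficient (regressors {list(spec.regressors)})"
        )
    Y = np.column_stack(
        [
            df[spec.cost_outcome].to_numpy(dtype=float),
            df[spec.effect_outcome].to_numpy(dtype=float),
        ]
    )
    n = len(df)

    # Stage (i): per-equation least squares.
    XtX = X.T @ X
    B = np.linalg.solve(XtX, X.T @ Y)  # k x 2

    for _ in range(max_iter if iterate else 1):
        # Stage (ii): residual cross-covariance, small-sample divisor n.
        R = Y - X @ B
        S = (R.T @ R) / n
        # Stage (iii): GLS with the Kronecker weight (S^-1 kron I_n).  With a
        # common regressor matrix, A = S^-1 kron X'X and the solution reduces
        # to OLS; the general stacked form is solved anyway so the coefficient
        # covariance comes straight from the GLS normal equations.
        S_inv = np.linalg.inv(S)
        A = np.kron(S_inv, XtX)
        XtY = X.T @ Y  # k x 2
        b = np.concatenate([XtY @ S_inv[:, j] for j in range(2)])
        coefs = np.linalg.solve(A, b)
        B_new = coefs.reshape(2, k).T  # k x 2, equation-major unstacked
        if np.max(np.abs(B_new - B)) < tol:
            B = B_new
            break
        B = B_new

    R = Y - X @ B
    S = (R.T @ R) / n
    cov = np.linalg.inv(np.kron(np.linalg.inv(S), XtX))  # 2k x 2k

    labels = [f"cost:{nm}" for nm in names] + [f"effect:{nm}" for nm in names]
    coef_cov = pd.DataFrame(cov, index=labels, columns=labels)
    se_all = np.sqrt(np.diag(cov))
    se = pd.DataFrame(
        {"cost": se_all[:k], "effect": se_all[k:]}, index=pd.Index(names)
    )
    alpha = pd.Series(B[:, 0], index=pd.Index(names), name="alpha")
    beta = pd.Series(B[:, 1], index=pd.Index(names), name="beta")
    zc = alpha.to_numpy() / se["cost"].to_numpy()
    ze = beta.to_numpy() / se["effect"].to_numpy()
    p_values = pd.DataFrame(
        {
            "cost": 2 * stats.norm.sf(np.abs(zc)),
            "effect": 2 * stats.norm.sf(np.abs(ze)),
        },
        index=pd.Index(names),
    )
    return SureFit(
        spec=spec,
        alpha=alpha,
        beta=beta,
        coef_cov=coef_cov,
        resid_cov=S,
        n_used=n,
        se=se,
        p_values=p_values,
    )


def icer_from_fit(
    fit: SureFit, therapy: str, effect_tolerance: float = EFFECT_TOLERANCE
) -> IcerResult:
    """Therapy-level ICER from the fitted system's coefficient pair."""
    if therapy not in fit.spec.regressors:
        raise InputError(f"{therapy!r} is not a regressor of this system")
    return classify_icer(
        therapy,
        float(fit.alpha[therapy]),
        float(fit.beta[therapy]),
        effect_tolerance=effect_tolerance,
    )


@dataclass
class ShortTermResult:
    """Fits and therapy-level ICERs of the 12-month analysis."""

    fits: dict[str, SureFit]
    icers: list[IcerResult]

    def icer_table(self) -> pd.DataFrame:
        """Therapy-level results table (one row per therapy, no pooled rows)."""
        rows = []
        for system, fit in self.fits.items():
            for therapy in fit.spec.regressors:
                res = next(r for r in self.icers if r.therapy == therapy)
                rows.append(
                    {
                        "system": system,
                        "therapy": therapy,
                        "cost_coef": fit.alpha[therapy],
                        "cost_se": fit.se.loc[therapy, "cost"],
                        "cost_p": fit.p_values.loc[therapy, "cost"],
                        "effect_coef": fit.beta[therapy],
                        "effect_se": fit.se.loc[therapy, "effect"],
                        "effect_p": fit.p_values.loc[therapy, "effect"],
                        "icer": res.icer_value,
                        "classification": res.label,
                    }
                )
        return pd.DataFrame(rows)


def run_short_term(
    cohort: pd.DataFrame,
    irt_spec: SureSpec = IRT_SPEC,
    ert_spec: SureSpec = ERT_SPEC,
    iterate: bool = False,
) -> ShortTermResult:
    """Run the full 12-month analysis: one two-equation system per subsystem.

    Emits one ICER per therapy (7 with the default specs) and never a pooled
    group-level ratio, since aggregating heterogeneous overlapping therapies
    would bias the comparison.
    """
    df = cohort
    if "qaly" not in df.columns:
        df = add_qaly_column(df)
    fits = {
        "irt": fit_sure(df, irt_spec, iterate=iterate),
        "ert": fit_sure(df, ert_spec, iterate=iterate),
    }
    icers = [
        icer_from_fit(fit, therapy)
        for fit in fits.values()
        for therapy in fit.spec.regressors
    ]
    return ShortTermResult(fits=fits, icers=icers)
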