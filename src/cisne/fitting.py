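"""Estimate MEE parameters (m, D) from a dose-effect dataset.

Two estimators are provided. ``fit_linear`` is the conventional approach
(CalcuSyn / CompuSyn lineage): ordinary least squares of y' = ln(f_a/f_u)
on x' = ln x, discarding observations with f_a outside (0, 1), then
m = slope and D = exp(-intercept/slope). ``fit_nonlinear`` fits the MEE
directly by unweighted nonlinear least squares on f_a, retaining every
observation — including those pushed past 0 or 1 by measurement noise.
Under constant noise on f_a the linearized regression implicitly
up-weights near-boundary points (their y' variance diverges), biasing m
downward for steep curves; the direct fit has no such distortion.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import least_squares
from scipy.special import expit

from .errors import DegenerateFitError, FitFailureError, FitInfeasibleError
from .model import DoseEffectDataset, MEEParameters, linearize

__all__ = ["fit_linear", "fit_nonlinear", "initial_guess"]

# relative parameter/cost tolerances; fits are 2-parameter, so tight is cheap
_TOL = 1e-10


def fit_linear(data: DoseEffectDataset) -> MEEParameters:
    """Linearized least-squares fit (the standard method).

    Returns parameters with standard errors propagated to (m, D): the
    regression gives Var(m), Var(b) and Cov(m, b) in closed form, and
    Var(D) follows by the delta method on D = exp(-b/m). ``r`` is the
    Pearson correlation of the retained (x', y') points.

    Raises
    ------
    FitInfeasibleError
        Fewer than 2 observations with 0 < f_a < 1.
    DegenerateFitError
        Non-positive slope (m must be positive) or zero dose spread.
    """
    pts = linearize(data)
    n_dropped = len(data) - len(pts)
    if len(pts) < 2:
        raise FitInfeasibleError(
            f"{data.label}: only {len(pts)} observations with 0 < fa < 1; "
            "need at least 2 for the linearized fit"
        )
    x = np.array([p.x_prime for p in pts])
    y = np.array([p.y_prime for p in pts])
    n = len(x)
    xbar = x.mean()
    sxx = float(np.sum((x - xbar) ** 2))
    if sxx == 0.0:
        raise DegenerateFitError(f"{data.label}: all retained doses identical")

    # closed-form OLS normal equations
    m = float(np.sum((x - xbar) * (y - y.mean())) / sxx)
    b = float(y.mean() - m * xbar)
    if m <= 0:
        raise DegenerateFitError(
            f"{data.label}: linearized slope {m:.4g} <= 0; the MEE requires m > 0"
        )
    D = float(np.exp(-b / m))

    resid = y - (m * x + b)
    rss = float(resid @ resid)
    dof = n - 2
    s2 = rss / dof if dof > 0 else 0.0
    var_m = s2 / sxx
    var_b = s2 * (1.0 / n + xbar**2 / sxx)
    cov_mb = -xbar * s2 / sxx
    # delta method through D(m, b) = exp(-b/m)
    dD_dm = D * b / m**2
    dD_db = -D / m
    jac = np.array([[1.0, 0.0], [dD_dm, dD_db]])
    cov_mb_mat = np.array([[var_m, cov_mb], [cov_mb, var_b]])
    cov = jac @ cov_mb_mat @ jac.T

    sy = float(np.sum((y - y.mean()) ** 2))
    r = float(np.sum((x - xbar) * (y - y.mean())) / np.sqrt(sxx * sy)) if sy > 0 else 0.0

    return MEEParameters(
        m=m,
        D=D,
        method="linear",
        se_m=float(np.sqrt(cov[0, 0])),
        se_D=float(np.sqrt(cov[1, 1])),
        cov=cov,
        n_used=n,
        n_dropped=n_dropped,
        r=r,
        rss=rss,
        diagnostics={"intercept": b, "perfect_fit": rss <= 1e-24},
    )


def _residual_factory(data: DoseEffectDataset):
    lnx = np.log(data.doses)
    y = data.fa

    def resid(theta):
        m = np.exp(theta[0])
        t = m * (lnx - theta[1])
        return expit(t) - y

    def jac(theta):
        m = np.exp(theta[0])
        t = m * (lnx - theta[1])
        p = expit(t)
        w = p * (1.0 - p)
        # derivatives w.r.t. (ln m, ln D-as-theta1): theta = (ln m, ln D)
        return np.column_stack([w * t, -w * m])

    return resid, jac


def fit_nonlinear(
    data: DoseEffectDataset, init: tuple[float, float] | None = None
) -> MEEParameters:
    """Direct unweighted nonlinear least-squares fit of the MEE.

    Minimizes sum_i (f_a,i - MEE(m, D; x_i))^2 over m, D > 0 with every
    observation weighted equally; positivity is enforced by optimizing
    (ln m, ln D) with Levenberg-Marquardt and an analytic Jacobian. On
    non-convergence the fit restarts from (1, median dose) and then
    (2, geometric-mean dose) before giving up.

    The (m, D) covariance is the usual Gauss-Markov estimate
    (J^T J)^{-1} s^2 at the optimum, mapped from log-parameter space; a
    zero-residual fit reports a zero covariance with a ``perfect_fit``
    diagnostic rather than NaNs.
    """
    y = data.fa
    if np.all(y == y[0]):
        raise DegenerateFitError(f"{data.label}: all fa values identical")

    resid, jac = _residual_factory(data)
    if init is None:
        init = initial_guess(data)
    starts = [
        init,
        (1.0, float(np.median(data.doses))),
        (2.0, float(np.exp(np.mean(np.log(data.doses))))),
    ]
    attempts = []
    result = None
    for m0, D0 in starts:
        res = least_squares(
            resid,
            x0=[np.log(m0), np.log(D0)],
            jac=jac,
            method="lm",
            ftol=_TOL,
            xtol=_TOL,
            gtol=_TOL,
        )
        attempts.append(
            {"start": (m0, D0), "status": res.status, "cost": float(res.cost)}
        )
        if res.status > 0 and np.all(np.isfinite(res.x)):
            result = res
            break
    if result is None:
        raise FitFailureError(
            f"{data.label}: nonlinear fit failed to converge from all starts",
            diagnostics=attempts,
        )

    m = float(np.exp(result.x[0]))
    D = float(np.exp(result.x[1]))
    r_vec = result.fun
    rss = float(r_vec @ r_vec)
    n = len(data)
    dof = n - 2
    s2 = rss / dof if dof > 0 else 0.0
    J = result.jac
    JtJ = J.T @ J
    try:
        cov_log = np.linalg.inv(JtJ) * s2
    except np.linalg.LinAlgError:
        cov_log = np.linalg.pinv(JtJ) * s2
    scale = np.diag([m, D])
    cov = scale @ cov_log @ scale

    return MEEParameters(
        m=m,
        D=D,
        method="nonlinear",
        se_m=float(np.sqrt(max(cov[0, 0], 0.0))),
        se_D=float(np.sqrt(max(cov[1, 1], 0.0))),
        cov=cov,
        n_used=n,
        n_dropped=0,
        r=None,
        rss=rss,
        diagnostics={"attempts": attempts, "perfect_fit": rss <= 1e-24},
    )


def initial_guess(data: DoseEffectDataset) -> tuple[float, float]:
    """Starting point for the nonlinear fit.

    The linearized fit, where feasible, is an excellent seed. When it is
    not (too few interior points, or a non-positive slope), fall back to
    m = 1 with D at the dose whose observed f_a is nearest 0.5 (ties
    resolved toward the lower dose).
    """
    try:
        p = fit_linear(data)
        return p.m, p.D
    except (FitInfeasibleError, DegenerateFitError):
        order = np.lexsort((data.doses, np.abs(data.fa - 0.5)))
        return 1.0, float(data.doses[order[0]])
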