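"""Two-drug combination index, confidence bands and classification.

For drugs A and B mixed at fixed ratio R_A:R_B, the combination index at
effect level f_a compares the constituent doses the combination needs with
the doses each drug needs alone:

    CI(f_a) = x_A^C / x_A^0 + x_B^C / x_B^0

Substituting the MEE inversion x = D (f_a/f_u)^(1/m) for the three fitted
curves (A alone, B alone, A+B at the fixed ratio, whose dose axis is the
*total* dose) gives the closed form evaluated here:

    CI(f_a) = D_AB / (R_A + R_B) * (f_a/f_u)^(1/m_AB)
              * [ R_A/D_A * (f_u/f_a)^(1/m_A) + R_B/D_B * (f_u/f_a)^(1/m_B) ]

CI = 1 is additivity; CI < 1 synergy; CI > 1 antagonism. Verdicts use
CI(f_a = 0.5) with thresholds 0.8 and 1.2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logit

from .errors import DomainError, UsageError
from .model import CombinationRatio, MEEParameters

__all__ = [
    "CICurve",
    "SynergyVerdict",
    "combination_index",
    "ci_curve",
    "ci_confidence",
    "ci_standard_error",
    "classify",
    "default_fa_grid",
    "SYNERGY_THRESHOLD",
    "ANTAGONISM_THRESHOLD",
]

SYNERGY_THRESHOLD = 0.8
ANTAGONISM_THRESHOLD = 1.2


def default_fa_grid() -> np.ndarray:
    """f_a grid 0.01 ... 0.99 in steps of 0.01."""
    return np.round(np.arange(1, 100) * 0.01, 2)


@dataclass
class CICurve:
    """Combination index evaluated on a grid of effect levels, with
    optional pointwise confidence bounds."""

    fa_grid: np.ndarray
    ci: np.ndarray
    ci_lo: np.ndarray | None = None
    ci_hi: np.ndarray | None = None
    level: float | None = None
    method: str = "point"

    def __post_init__(self) -> None:
        self.fa_grid = np.asarray(self.fa_grid, dtype=float)
        self.ci = np.asarray(self.ci, dtype=float)

    def at(self, fa: float) -> float:
        """CI at a grid value (exact match required)."""
        idx = np.nonzero(np.isclose(self.fa_grid, fa))[0]
        if len(idx) == 0:
            raise UsageError(f"fa={fa} is not on the grid")
        return float(self.ci[idx[0]])


@dataclass(frozen=True)
class SynergyVerdict:
    """Classification of a combination from its CI at f_a = 0.5."""

    ci_at_half: float
    category: str  # 'synergistic' | 'additive' | 'antagonistic'


def _check_grid(fa) -> np.ndarray:
    fa = np.asarray(fa, dtype=float)
    if fa.size == 0:
        raise UsageError("fa grid is empty")
    if np.any(fa <= 0) or np.any(fa >= 1):
        raise DomainError("fa must lie strictly inside (0, 1)")
    return fa


def _ci_formula(ma, Da, mb, Db, mab, Dab, ra, rb, fa):
    lo = logit(fa)  # ln(fa/fu)
    total_needed = Dab / (ra + rb) * np.exp(lo / mab)
    return total_needed * (
        ra / Da * np.exp(-lo / ma) + rb / Db * np.exp(-lo / mb)
    )


def combination_index(
    pa: MEEParameters,
    pb: MEEParameters,
    pab: MEEParameters,
    ratio: CombinationRatio,
    fa,
):
    """Combination index at effect level(s) ``fa``.

    ``pa``, ``pb``, ``pab`` are the fitted MEE parameters of drug A, drug B
    and the fixed-ratio combination (total-dose convention). Scalar in,
    scalar out; array in, array out.
    """
    fa_arr = _check_grid(fa)
    out = _ci_formula(
        pa.m, pa.D, pb.m, pb.D, pab.m, pab.D, ratio.r_a, ratio.r_b, fa_arr
    )
    return float(out) if np.isscalar(fa) or np.ndim(fa) == 0 else out


def ci_curve(
    pa: MEEParameters,
    pb: MEEParameters,
    pab: MEEParameters,
    ratio: CombinationRatio,
    fa_grid=None,
) -> CICurve:
    """Pointwise CI over a grid of effect levels (default 0.01...0.99)."""
    grid = default_fa_grid() if fa_grid is None else _check_grid(fa_grid)
    return CICurve(fa_grid=grid, ci=combination_index(pa, pb, pab, ratio, grid))


def ci_confidence(
    pa: MEEParameters,
    pb: MEEParameters,
    pab: MEEParameters,
    ratio: CombinationRatio,
    fa_grid=None,
    level: float = 0.95,
    n_draws: int = 4000,
    seed: int | None = None,
) -> CICurve:
    """CI curve with pointwise confidence bounds by parametric bootstrap.

    Each fit's (m, D) is resampled from its asymptotic bivariate normal in
    (ln m, ln D) coordinates — sampling in log space keeps every draw
    positive — and CI is re-evaluated per draw; the bounds are the
    (1-level)/2 and 1-(1-level)/2 percentiles at each grid point.
    Deterministic for a given ``seed``.
    """
    grid = default_fa_grid() if fa_grid is None else _check_grid(fa_grid)
    if n_draws < 100:
        raise UsageError("n_draws must be at least 100")
    if not (0 < level < 1):
        raise UsageError("level must lie in (0, 1)")
    for name, p in (("A", pa), ("B", pb), ("A+B", pab)):
        if p.cov is None:
            raise UsageError(
                f"fit for {name} carries no covariance; fit the data first "
                "(fit_linear / fit_nonlinear) before requesting intervals"
            )

    rng = np.random.default_rng(seed)

    def draws(p: MEEParameters) -> np.ndarray:
        mean = np.array([np.log(p.m), np.log(p.D)])
        cov = p.log_cov
        sample = rng.multivariate_normal(mean, cov, size=n_draws, method="svd")
        return np.exp(sample)  # columns: m, D

    da, db, dab = draws(pa), draws(pb), draws(pab)
    # (n_draws, n_grid) matrix of CI evaluations
    sims = _ci_formula(
        da[:, :1], da[:, 1:], db[:, :1], db[:, 1:], dab[:, :1], dab[:, 1:],
        ratio.r_a, ratio.r_b, grid[None, :],
    )
    alpha = (1.0 - level) / 2.0
    lo, hi = np.percentile(sims, [100 * alpha, 100 * (1 - alpha)], axis=0)
    point = combination_index(pa, pb, pab, ratio, grid)
    return CICurve(
        fa_grid=grid,
        ci=point,
        ci_lo=np.minimum(lo, point),
        ci_hi=np.maximum(hi, point),
        level=level,
        method="parametric-bootstrap",
    )


def ci_standard_error(
    pa: MEEParameters,
    pb: MEEParameters,
    pab: MEEParameters,
    ratio: CombinationRatio,
    fa: float,
    rel_step: float = 1e-6,
) -> float:
    """Delta-method standard error of CI at one effect level.

    Propagates the three fits' (m, D) covariances (independent fits, so the
    joint covariance is block diagonal) through a central-difference
    gradient of the CI formula. At f_a = 0.5 the m-derivatives vanish
    exactly and only the D uncertainties contribute.
    """
    for p in (pa, pb, pab):
        if p.cov is None:
            raise UsageError("all three fits must carry covariance")
    theta = np.array([pa.m, pa.D, pb.m, pb.D, pab.m, pab.D])

    def f(t):
        return _ci_formula(t[0], t[1], t[2], t[3], t[4], t[5],
                           ratio.r_a, ratio.r_b, fa)

    grad = np.empty(6)
    for i in range(6):
        h = rel_step * theta[i]
        tp, tm = theta.copy(), theta.copy()
        tp[i] += h
        tm[i] -= h
        grad[i] = (f(tp) - f(tm)) / (2 * h)
    cov = np.zeros((6, 6))
    cov[0:2, 0:2] = pa.cov
    cov[2:4, 2:4] = pb.cov
    cov[4:6, 4:6] = pab.cov
    var = float(grad @ cov @ grad)
    return float(np.sqrt(max(var, 0.0)))


def classify(ci_at_half: float) -> SynergyVerdict:
    """Classify a combination from CI(f_a = 0.5).

    Below 0.8 → synergistic; above 1.2 → antagonistic; the closed middle
    interval [0.8, 1.2] (boundaries included) → additive.
    """
    if not np.isfinite(ci_at_half) or ci_at_half <= 0:
        raise UsageError(f"CI must be positive and finite, got {ci_at_half}")
    if ci_at_half < SYNERGY_THRESHOLD:
        category = "synergistic"
    elif ci_at_half > ANTAGONISM_THRESHOLD:
        category = "antagonistic"
    else:
        category = "additive"
    return SynergyVerdict(ci_at_half=float(ci_at_half), category=category)
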