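"""The median-effect equation (MEE), its inversion and linearization.

The MEE describes the dose-effect relationship of a single agent:

    f_a / f_u = (x / D) ** m,      f_u = 1 - f_a

where ``x`` is the dose, ``f_a`` the fraction of the population affected,
``D`` the median-effect dose (the dose at which f_a = 0.5) and ``m`` the
sigmoidality: m = 1 gives a hyperbolic curve, m > 1 sigmoidal, m < 1 flat
sigmoidal. Solving for f_a gives the logistic form in log-dose,

    f_a = 1 / (1 + (D / x) ** m),

which is how this module evaluates it (numerically stable at extreme
doses). Taking natural logarithms linearizes the MEE:

    y' = m x' + b,   y' = ln(f_a / f_u),   x' = ln x,   b = -m ln D,

so D = exp(-b / m). Measured f_a values at or beyond the boundaries 0 and 1
have no finite y' and cannot enter the linearized regression; they are kept
in the dataset and handled per fitting method.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, logit

from .errors import DomainError, ValidationError

__all__ = [
    "CombinationRatio",
    "DoseEffectDataset",
    "MEEParameters",
    "LinearizedPoint",
    "predict_fa",
    "dose_for_effect",
    "linearize",
    "linearization_noise_amplification",
]


@dataclass(frozen=True)
class CombinationRatio:
    """Fixed mixing ratio R_A:R_B of a two-drug combination.

    A combination dataset's dose column holds the *total* dose; a total
    dose x splits into constituents x * r_a / (r_a + r_b) of drug A and
    x * r_b / (r_a + r_b) of drug B.
    """

    r_a: float
    r_b: float

    def __post_init__(self) -> None:
        if not (self.r_a > 0 and np.isfinite(self.r_a)):
            raise ValidationError(f"r_a must be positive and finite, got {self.r_a}")
        if not (self.r_b > 0 and np.isfinite(self.r_b)):
            raise ValidationError(f"r_b must be positive and finite, got {self.r_b}")

    @property
    def total(self) -> float:
        return self.r_a + self.r_b

    @classmethod
    def parse(cls, text: str) -> "CombinationRatio":
        """Parse 'a:b' (e.g. '1:1', '2:3.5')."""
        parts = text.split(":")
        if len(parts) != 2:
            raise ValidationError(f"ratio must look like 'A:B', got {text!r}")
        return cls(float(parts[0]), float(parts[1]))

    def __str__(self) -> str:
        return f"{self.r_a:g}:{self.r_b:g}"


@dataclass
class DoseEffectDataset:
    """Labelled dose / fraction-affected observations for one drug or one
    fixed-ratio combination.

    ``fa`` values may fall outside [0, 1]: measurement noise produces such
    points routinely and they are legal data here. Doses must be strictly
    positive and finite; at least two observations are required.
    """

    label: str
    doses: np.ndarray
    fa: np.ndarray
    is_combination: bool = False
    ratio: CombinationRatio | None = None

    def __post_init__(self) -> None:
        self.doses = np.asarray(self.doses, dtype=float)
        self.fa = np.asarray(self.fa, dtype=float)
        if self.doses.ndim != 1 or self.fa.ndim != 1:
            raise ValidationError("doses and fa must be one-dimensional")
        if len(self.doses) != len(self.fa):
            raise ValidationError(
                f"{self.label}: doses ({len(self.doses)}) and fa ({len(self.fa)}) "
                "differ in length"
            )
        if len(self.doses) < 2:
            raise ValidationError(f"{self.label}: need at least 2 observations")
        if not np.all(np.isfinite(self.doses)) or np.any(self.doses <= 0):
            raise ValidationError(f"{self.label}: doses must be finite and > 0")
        if not np.all(np.isfinite(self.fa)):
            raise ValidationError(f"{self.label}: fa values must be finite")
        if self.is_combination and self.ratio is None:
            raise ValidationError(f"{self.label}: combination dataset needs a ratio")

    def __len__(self) -> int:
        return len(self.doses)


@dataclass
class MEEParameters:
    """Fitted MEE parameters with uncertainty.

    ``cov`` is the 2x2 covariance of (m, D); ``se_m``/``se_D`` its square
    roots. ``r`` is the Pearson correlation of the linearized regression and
    is defined only for ``method == "linear"``. ``n_dropped`` counts the
    observations a linearized fit had to exclude (f_a outside (0, 1));
    nonlinear fits never drop points.
    """

    m: float
    D: float
    method: str
    se_m: float | None = None
    se_D: float | None = None
    cov: np.ndarray | None = None
    n_used: int = 0
    n_dropped: int = 0
    r: float | None = None
    rss: float | None = None
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (np.isfinite(self.m) and self.m > 0):
            raise ValidationError(f"m must be positive and finite, got {self.m}")
        if not (np.isfinite(self.D) and self.D > 0):
            raise ValidationError(f"D must be positive and finite, got {self.D}")
        if self.method not in ("linear", "nonlinear"):
            raise ValidationError(f"unknown method tag {self.method!r}")
        if self.cov is not None:
            self.cov = np.asarray(self.cov, dtype=float)
            if self.cov.shape != (2, 2):
                raise ValidationError("cov must be 2x2")

    @property
    def log_cov(self) -> np.ndarray | None:
        """Covariance of (ln m, ln D), by the delta method from ``cov``."""
        if self.cov is None:
            return None
        g = np.diag([1.0 / self.m, 1.0 / self.D])
        return g @ self.cov @ g


@dataclass(frozen=True)
class LinearizedPoint:
    """One observation mapped to the linearized coordinates
    (x' = ln x, y' = ln(f_a/f_u)); only defined for 0 < f_a < 1."""

    x_prime: float
    y_prime: float
    source_index: int


def _as_params(params) -> tuple[float, float]:
    if isinstance(params, MEEParameters):
        return params.m, params.D
    m, D = params
    return float(m), float(D)


def predict_fa(params, x):
    """Fraction affected at dose ``x`` under the MEE.

    ``params`` may be an :class:`MEEParameters` or a plain ``(m, D)`` pair;
    ``x`` may be a scalar or array of strictly positive doses. Returns
    values strictly inside (0, 1), increasing in x.
    """
    m, D = _as_params(params)
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0) or not np.all(np.isfinite(x)):
        raise DomainError("dose must be positive and finite")
    out = expit(m * (np.log(x) - np.log(D)))
    return out if out.ndim else float(out)


def dose_for_effect(params, fa):
    """Dose producing effect ``fa``: the MEE inverted, x = D (f_a/f_u)^(1/m).

    ``fa`` must lie strictly inside (0, 1) — the dose is undefined (zero or
    infinite) at the boundaries.
    """
    m, D = _as_params(params)
    fa = np.asarray(fa, dtype=float)
    if np.any(fa <= 0) or np.any(fa >= 1):
        raise DomainError("fa must lie strictly inside (0, 1)")
    out = D * np.exp(logit(fa) / m)
    return out if out.ndim else float(out)


def linearize(data: DoseEffectDataset) -> list[LinearizedPoint]:
    """Map a dataset to linearized coordinates, omitting boundary points.

    Observations with f_a <= 0 or f_a >= 1 have no finite log-odds and are
    skipped; callers can count them as ``len(data) - len(result)``.
    """
    points = []
    for i, (x, fa) in enumerate(zip(data.doses, data.fa)):
        if 0.0 < fa < 1.0:
            points.append(
                LinearizedPoint(
                    x_prime=float(np.log(x)),
                    y_prime=float(np.log(fa / (1.0 - fa))),
                    source_index=i,
                )
            )
    return points


def linearization_noise_amplification(fa: float, sigma_fa: float) -> float:
    """First-order standard deviation of y' = ln(f_a/f_u) given sd(f_a).

    sigma(y') ~= sigma(f_a) / (f_a f_u): minimal at f_a = 0.5 and divergent
    toward either boundary — the reason the linearized regression gives
    runaway weight to near-boundary observations under constant
    measurement noise.
    """
    if not (0.0 < fa < 1.0):
        raise DomainError("fa must lie strictly inside (0, 1)")
    if not (sigma_fa > 0 and np.isfinite(sigma_fa)):
        raise DomainError("sigma_fa must be positive and finite")
    return sigma_fa / (fa * (1.0 - fa))
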