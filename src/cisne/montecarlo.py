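"""Monte-Carlo validation studies of the two fitting methods.

Synthetic dose-effect data are generated from a known MEE curve with
additive Gaussian noise on f_a, mimicking replicate plate measurements:
9 doses geometrically spaced around the median-effect dose (factor 2
between neighbours), sd(f_a) = 0.05, and — deliberately — no clipping of
f_a to [0, 1]: real assays produce such values and they carry information.

Two study designs are provided:

* a parameter-recovery study (fit each simulated dataset with each method
  and summarize the estimate distributions), and
* an additive-truth combination study (blocks of three identically
  distributed datasets play drug A, drug B and their 1:1 combination, so
  the true CI is exactly 1 and any non-additive verdict is a
  classification error).

All randomness flows through one seeded generator in a fixed order
(doses within a dataset, then datasets within a block, then blocks), so a
study is bit-reproducible from its config.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import CisneError, UsageError, ValidationError
from .fitting import fit_linear, fit_nonlinear
from .model import CombinationRatio, DoseEffectDataset, predict_fa
from .synergy import ci_standard_error, classify, combination_index

__all__ = [
    "DoseDesign",
    "SimulationConfig",
    "MethodSummary",
    "SimulationStudyResult",
    "generate_dataset",
    "run_parameter_study",
    "run_additive_ci_study",
    "table3_report",
]

_FITTERS = {"linear": fit_linear, "nonlinear": fit_nonlinear}
_CATEGORIES = ("synergistic", "additive", "antagonistic")


@dataclass(frozen=True)
class DoseDesign:
    """Geometric dose ladder centred on one dose.

    Defaults give the 9-point design used throughout the validation
    studies: the centre dose plus 4 doses above and 4 below, neighbours
    differing by a factor of 2.
    """

    center_dose: float = 10.0
    n_each_side: int = 4
    fold: float = 2.0

    def __post_init__(self) -> None:
        if not (self.center_dose > 0 and np.isfinite(self.center_dose)):
            raise ValidationError("center_dose must be positive and finite")
        if self.n_each_side < 0:
            raise ValidationError("n_each_side must be >= 0")
        if not (self.fold > 1):
            raise ValidationError("fold must exceed 1")

    def doses(self) -> np.ndarray:
        k = np.arange(-self.n_each_side, self.n_each_side + 1)
        return self.center_dose * self.fold ** k.astype(float)


@dataclass(frozen=True)
class SimulationConfig:
    """One simulation condition.

    ``true_m``/``true_D`` are the generating MEE parameters (the expected
    values the fits should recover); ``sigma_fa`` is the per-point noise
    sd; ``design`` defaults to the 9-dose ladder centred on ``true_D``.
    """

    true_m: float
    true_D: float = 10.0
    sigma_fa: float = 0.05
    design: DoseDesign | None = None
    n_reps: int = 10000
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.true_m > 0 and self.true_D > 0):
            raise ValidationError("true_m and true_D must be positive")
        if self.sigma_fa < 0:
            raise ValidationError("sigma_fa must be >= 0")
        if self.n_reps < 1:
            raise ValidationError("n_reps must be >= 1")
        if self.design is None:
            object.__setattr__(self, "design", DoseDesign(center_dose=self.true_D))


@dataclass
class MethodSummary:
    """Per-method accumulation over replicates."""

    method: str
    n_ok: int = 0
    n_failed: int = 0
    m_hat: list = field(default_factory=list)
    D_hat: list = field(default_factory=list)
    se_m: list = field(default_factory=list)
    se_D: list = field(default_factory=list)
    ci_values: list = field(default_factory=list)
    ci_se: list = field(default_factory=list)
    category_counts: dict = field(
        default_factory=lambda: {c: 0 for c in _CATEGORIES}
    )

    # -- summaries -------------------------------------------------------
    def _stat(self, values, fn):
        return float(fn(values)) if values else float("nan")

    @property
    def mean_m(self):
        return self._stat(self.m_hat, np.mean)

    @property
    def sd_m(self):
        return self._stat(self.m_hat, np.std)

    @property
    def mean_D(self):
        return self._stat(self.D_hat, np.mean)

    @property
    def sd_D(self):
        return self._stat(self.D_hat, np.std)

    @property
    def mean_se_m(self):
        return self._stat(self.se_m, np.mean)

    @property
    def mean_se_D(self):
        return self._stat(self.se_D, np.mean)

    @property
    def mean_ci(self):
        return self._stat(self.ci_values, np.mean)

    @property
    def sd_ci(self):
        return self._stat(self.ci_values, np.std)

    @property
    def mean_ci_se(self):
        return self._stat(self.ci_se, np.mean)

    def category_fractions(self) -> dict:
        """Fractions over classified (non-failed) blocks; sums to 1."""
        total = sum(self.category_counts.values())
        if total == 0:
            return {c: float("nan") for c in _CATEGORIES}
        return {c: n / total for c, n in self.category_counts.items()}


@dataclass
class SimulationStudyResult:
    """Outcome of one study: a :class:`MethodSummary` per method plus the
    config that produced it. ``kind`` is 'parameter' or 'additive_ci'."""

    config: SimulationConfig
    kind: str
    methods: dict[str, MethodSummary]

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for name, s in self.methods.items():
            row = {
                "method": name,
                "n_ok": s.n_ok,
                "n_failed": s.n_failed,
                "mean_m": s.mean_m,
                "sd_m": s.sd_m,
                "mean_D": s.mean_D,
                "sd_D": s.sd_D,
                "mean_se_m": s.mean_se_m,
                "mean_se_D": s.mean_se_D,
            }
            if self.kind == "additive_ci":
                row.update(
                    mean_ci=s.mean_ci,
                    sd_ci=s.sd_ci,
                    mean_ci_se=s.mean_ci_se,
                    **{
                        f"frac_{c}": f
                        for c, f in s.category_fractions().items()
                    },
                )
            rows.append(row)
        return pd.DataFrame(rows).set_index("method")


def generate_dataset(
    config: SimulationConfig,
    rng: np.random.Generator,
    label: str = "sim",
    is_combination: bool = False,
    ratio: CombinationRatio | None = None,
) -> DoseEffectDataset:
    """Draw one synthetic dataset: true MEE values plus N(0, sigma_fa)
    noise per dose, in dose order, *not* clipped to [0, 1]."""
    doses = config.design.doses()
    fa_true = predict_fa((config.true_m, config.true_D), doses)
    noise = rng.normal(0.0, config.sigma_fa, size=len(doses)) if config.sigma_fa > 0 \
        else np.zeros(len(doses))
    return DoseEffectDataset(
        label=label,
        doses=doses,
        fa=np.atleast_1d(fa_true) + noise,
        is_combination=is_combination,
        ratio=ratio,
    )


def _check_methods(methods) -> tuple[str, ...]:
    methods = tuple(methods)
    for m in methods:
        if m not in _FITTERS:
            raise UsageError(f"unknown method {m!r}; choose from {sorted(_FITTERS)}")
    return methods


def run_parameter_study(
    config: SimulationConfig, methods=("linear", "nonlinear")
) -> SimulationStudyResult:
    """Fit each of ``n_reps`` simulated datasets with each method and
    accumulate the estimate and reported-standard-error distributions.
    Fit failures are counted, never raised."""
    methods = _check_methods(methods)
    rng = np.random.default_rng(config.seed)
    summaries = {m: MethodSummary(method=m) for m in methods}
    for _ in range(config.n_reps):
        data = generate_dataset(config, rng)
        for name in methods:
            try:
                p = _FITTERS[name](data)
            except CisneError:
                summaries[name].n_failed += 1
                continue
            s = summaries[name]
            s.n_ok += 1
            s.m_hat.append(p.m)
            s.D_hat.append(p.D)
            s.se_m.append(p.se_m)
            s.se_D.append(p.se_D)
    return SimulationStudyResult(config=config, kind="parameter", methods=summaries)


def run_additive_ci_study(
    config: SimulationConfig, methods=("linear", "nonlinear")
) -> SimulationStudyResult:
    """Additive-truth combination study.

    Each block draws three datasets from the same generating curve (drug A,
    drug B, and their 1:1 combination), fits all three with each method,
    evaluates CI at f_a = 0.5 with its delta-method standard error, and
    classifies the block. A block where any of the three fits fails is
    excluded from that method's percentages and counted as failed.
    """
    methods = _check_methods(methods)
    ratio = CombinationRatio(1.0, 1.0)
    rng = np.random.default_rng(config.seed)
    summaries = {m: MethodSummary(method=m) for m in methods}
    for _ in range(config.n_reps):
        block = [
            generate_dataset(config, rng, label=lbl,
                             is_combination=(lbl == "A+B"),
                             ratio=ratio if lbl == "A+B" else None)
            for lbl in ("A", "B", "A+B")
        ]
        for name in methods:
            s = summaries[name]
            try:
                fits = [_FITTERS[name](d) for d in block]
            except CisneError:
                s.n_failed += 1
                continue
            ci = combination_index(*fits, ratio, 0.5)
            se = ci_standard_error(*fits, ratio, 0.5)
            verdict = classify(ci)
            s.n_ok += 1
            s.ci_values.append(ci)
            s.ci_se.append(se)
            s.category_counts[verdict.category] += 1
            for p, lbl in zip(fits, ("A", "B", "A+B")):
                s.m_hat.append(p.m)
                s.D_hat.append(p.D)
                s.se_m.append(p.se_m)
                s.se_D.append(p.se_D)
    return SimulationStudyResult(config=config, kind="additive_ci", methods=summaries)


def table3_report(results) -> str:
    """Percentage table of synergistic / additive / antagonistic verdicts.

    ``results`` is a sequence of additive-truth study results (typically
    one per generating m); rows are (E[m], method), percentages printed to
    two decimals.
    """
    results = list(results)
    if not results:
        raise UsageError("no study results supplied")
    rows = []
    for res in results:
        if res.kind != "additive_ci":
            raise UsageError(
                f"table3_report needs additive_ci studies, got {res.kind!r}"
            )
        for name, s in res.methods.items():
            fracs = s.category_fractions()
            rows.append(
                {
                    "E[m]": res.config.true_m,
                    "method": name,
                    **{c: f"{100 * fracs[c]:.2f}%" for c in _CATEGORIES},
                }
            )
    frame = pd.DataFrame(rows).sort_values(["E[m]", "method"])
    return frame.to_string(index=False)
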