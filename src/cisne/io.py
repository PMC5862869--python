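"""Reading dose-effect tables and writing analysis reports.

The delimited format mirrors how dose-effect data are tabulated in
practice: one ``dose`` column plus one effect column per drug, named by
the drug label. Effect columns hold the fraction affected (f_a) by
default; files that tabulate the fraction unaffected instead (a common
plotting convention) are read with ``fa_or_fu="fu"`` and converted via
f_a = 1 - f_u. A column whose label contains ``+`` is treated as a
fixed-ratio combination; its ratio comes from a ``# ratio: A:B`` header
comment or from the caller (caller wins on conflict, with a warning).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import asdict
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .errors import UsageError, ValidationError
from .model import CombinationRatio, DoseEffectDataset, MEEParameters
from .synergy import CICurve, SynergyVerdict

__all__ = [
    "read_dose_effect",
    "write_report",
    "read_report",
    "fixture_path",
    "load_fixture",
]

log = logging.getLogger("cisne")

_FIXTURES = {"table1": "table1.csv", "table2": "table2.csv"}


def _parse_header_comments(path: Path) -> tuple[int, CombinationRatio | None]:
    """Count leading comment lines and extract an optional ratio tag."""
    n_comments = 0
    ratio = None
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n_comments += 1
            body = line.lstrip("#").strip()
            if body.lower().startswith("ratio:"):
                ratio = CombinationRatio.parse(body.split(":", 1)[1].strip())
    return n_comments, ratio


def read_dose_effect(
    path,
    fa_or_fu: str = "fa",
    delimiter: str = ",",
    combination_ratio: CombinationRatio | str | None = None,
    dose_convention: str = "total",
) -> list[DoseEffectDataset]:
    """Read one or more dose-effect datasets from a delimited text file.

    Parameters
    ----------
    path : file path
        Header row required: a ``dose`` column plus one column per drug.
    fa_or_fu : {'fa', 'fu'}
        Whether effect columns hold fraction affected or fraction
        unaffected (converted on load).
    combination_ratio : CombinationRatio, str like '2:1', or None
        Ratio for combination columns; overrides any ``# ratio:`` header
        comment (with a warning on conflict).
    dose_convention : {'total', 'per_unit'}
        'total': a combination's dose column is the total mixture dose
        (native convention). 'per_unit': doses are per unit of the ratio
        and are multiplied by r_a + r_b on load.
    """
    path = Path(path)
    if fa_or_fu not in ("fa", "fu"):
        raise UsageError("fa_or_fu must be 'fa' or 'fu'")
    if dose_convention not in ("total", "per_unit"):
        raise UsageError("dose_convention must be 'total' or 'per_unit'")
    if isinstance(combination_ratio, str):
        combination_ratio = CombinationRatio.parse(combination_ratio)

    n_comments, header_ratio = _parse_header_comments(path)
    if combination_ratio is not None and header_ratio is not None and (
        combination_ratio.r_a != header_ratio.r_a
        or combination_ratio.r_b != header_ratio.r_b
    ):
        warnings.warn(
            f"{path.name}: ratio flag {combination_ratio} overrides header "
            f"ratio {header_ratio}",
            stacklevel=2,
        )
    ratio = combination_ratio or header_ratio

    try:
        frame = pd.read_csv(path, sep=delimiter, comment="#")
    except pd.errors.ParserError as exc:
        raise ValidationError(f"{path.name}: malformed delimited file: {exc}") from exc
    if "dose" not in frame.columns:
        raise UsageError(f"{path.name}: missing required 'dose' column")
    drug_cols = [c for c in frame.columns if c != "dose"]
    if not drug_cols:
        raise UsageError(f"{path.name}: no effect columns besides 'dose'")

    doses = frame["dose"].to_numpy(dtype=float)
    for i, d in enumerate(doses):
        if not (np.isfinite(d) and d > 0):
            # +2: 1-based line numbers plus the header row
            raise ValidationError(
                f"{path.name} line {i + 2 + n_comments}: dose must be "
                f"positive and finite, got {d}"
            )

    datasets = []
    for col in drug_cols:
        fa = frame[col].to_numpy(dtype=float)
        if fa_or_fu == "fu":
            fa = 1.0 - fa
        is_combo = "+" in col
        if is_combo and ratio is None:
            raise UsageError(
                f"{path.name}: column {col!r} is a combination but no ratio "
                "was given (header comment '# ratio: A:B' or flag)"
            )
        col_doses = doses
        if is_combo and dose_convention == "per_unit":
            col_doses = doses * ratio.total
        datasets.append(
            DoseEffectDataset(
                label=col,
                doses=col_doses,
                fa=fa,
                is_combination=is_combo,
                ratio=ratio if is_combo else None,
            )
        )
        if is_combo:
            log.info("read combination dataset %s with ratio %s", col, ratio)
    return datasets


def _params_record(p: MEEParameters) -> dict:
    return {
        "m": p.m,
        "D": p.D,
        "se_m": p.se_m,
        "se_D": p.se_D,
        "cov": None if p.cov is None else p.cov.tolist(),
        "method": p.method,
        "r": p.r,
        "n_used": p.n_used,
        "n_dropped": p.n_dropped,
        "rss": p.rss,
    }


def write_report(
    fits: dict[str, MEEParameters],
    curve: CICurve | None,
    verdict: SynergyVerdict | None,
    path,
    config_echo: dict | None = None,
    seed: int | None = None,
    curve_path=None,
) -> dict:
    """Write a JSON analysis report (and the CI curve as CSV alongside).

    Returns the report dict that was written. Numbers round-trip exactly
    through ``read_report``.
    """
    path = Path(path)
    report = {
        "tool": "cisne",
        "version": __version__,
        "seed": seed,
        "config": config_echo or {},
        "fits": {label: _params_record(p) for label, p in fits.items()},
    }
    if curve is not None:
        report["ci_curve"] = {
            "fa": curve.fa_grid.tolist(),
            "ci": curve.ci.tolist(),
            "ci_lo": None if curve.ci_lo is None else np.asarray(curve.ci_lo).tolist(),
            "ci_hi": None if curve.ci_hi is None else np.asarray(curve.ci_hi).tolist(),
            "level": curve.level,
            "method": curve.method,
        }
    if verdict is not None:
        report["verdict"] = asdict(verdict)
    try:
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(json.dumps(report, indent=2) + "\n")
    except OSError as exc:
        raise UsageError(f"cannot write report to {path}: {exc}") from exc

    if curve is not None:
        if curve_path is None:
            curve_path = path.with_name(path.stem + "_ci_curve.csv")
        cols = {"fa": curve.fa_grid, "ci": curve.ci}
        if curve.ci_lo is not None:
            cols["ci_lo"] = curve.ci_lo
            cols["ci_hi"] = curve.ci_hi
        pd.DataFrame(cols).to_csv(curve_path, index=False)
    return report


def read_report(path) -> dict:
    """Load a JSON report written by :func:`write_report`."""
    return json.loads(Path(path).read_text())


def fixture_path(name: str):
    """Path-like handle on a packaged example table ('table1' or 'table2').

    table1: two drugs with purely additive 1:1 combination (true CI = 1);
    table2: two drugs with a synergistic 1:1 combination (true CI = 0.6).
    Both tabulate the fraction *unaffected* at 9 doses, as printed.
    """
    if name not in _FIXTURES:
        raise UsageError(f"unknown fixture {name!r}; choose from {sorted(_FIXTURES)}")
    return resources.files("cisne.data") / _FIXTURES[name]


def load_fixture(name: str) -> list[DoseEffectDataset]:
    """Read a packaged example table into datasets (converting f_u to f_a)."""
    with resources.as_file(fixture_path(name)) as p:
        return read_dose_effect(p, fa_or_fu="fu")
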