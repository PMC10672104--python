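"""Four-parameter logistic (4PL) dose-response fitting and relative reactivity.

ELISA titrations of a purified clone against the immobilised antigen are
fitted with the 4PL model

    y(x) = lower + (upper - lower) / (1 + (x / ec50)^hill)

by unweighted least squares on the linear concentration scale.  Replicates
are averaged per concentration before fitting (the triplicate SD is reported
but not used as weights).  The hill slope is free in sign, so both rising
and falling sigmoids are representable; two starts (hill = +/-1) guard
against the optimizer stalling on the wrong branch.

Relative reactivity compares one clone's EC50 under the normal assay
condition with its EC50 under a perturbed condition:

    relative reactivity (%) = 100 x EC50(normal) / EC50(condition)

A value above 100% means the perturbation *improved* apparent binding
(lower EC50 under the condition).
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

#: EC50 may drift this far beyond the tested range before the fit is
#: declared unconverged (extrapolation beyond it is meaningless).
EC50_RANGE_SLACK = 100.0


@dataclass(frozen=True)
class DoseResponse:
    """One titration series: molar concentrations and OD450 responses."""

    concentrations: tuple[float, ...]
    responses: tuple[float, ...]
    condition_label: str = ""

    def __post_init__(self) -> None:
        if len(self.concentrations) != len(self.responses):
            raise ValueError("concentrations and responses differ in length")
        if len(self.concentrations) < 4:
            raise ValueError("a 4-parameter fit needs at least 4 points")
        if any(c <= 0 for c in self.concentrations):
            raise ValueError("concentrations must be strictly positive")

    @classmethod
    def from_replicates(
        cls,
        concentrations: Sequence[float],
        replicate_responses: Sequence[Sequence[float]],
        condition_label: str = "",
    ) -> "DoseResponse":
        """Average replicate OD readings per concentration."""
        means = [float(np.mean(r)) for r in replicate_responses]
        return cls(tuple(float(c) for c in concentrations), tuple(means), condition_label)


@dataclass(frozen=True)
class FourPLFit:
    lower: float
    upper: float
    ec50: float
    hill: float
    rss: float
    converged: bool

    def summary(self) -> str:
        if not self.converged:
            return "4PL fit: not converged"
        return f"4PL fit: EC50 = {self.ec50:.2g} M, hill = {self.hill:.2f}"


def _model(x, lower, upper, ec50, hill):
    return lower + (upper - lower) / (1.0 + (x / ec50) ** hill)


def fit_4pl(data: DoseResponse) -> FourPLFit:
    """Least-squares 4PL fit; flags non-convergence instead of raising.

    Initialisation: asymptotes from the min/max response, EC50 from the
    concentration nearest mid-response, hill from +/-1 (better start kept).
    Degenerate (flat) data and EC50 escaping the tested concentration range
    by more than 100x are reported as unconverged.
    """
    x_raw = np.asarray(data.concentrations, dtype=float)
    y = np.asarray(data.responses, dtype=float)
    y_span = float(np.ptp(y))
    if y_span <= 1e-12 or y_span <= 1e-6 * max(1.0, abs(float(np.mean(y)))):
        return FourPLFit(float(y.mean()), float(y.mean()), math.nan, math.nan, 0.0, False)

    # normalise concentrations by their geometric mean: the optimiser then
    # works near unit scale regardless of units, and the fit is exactly
    # scale-equivariant
    scale = float(np.exp(np.mean(np.log(x_raw))))
    x = x_raw / scale

    mid = (y.min() + y.max()) / 2.0
    ec50_init = float(x[np.argmin(np.abs(y - mid))])
    best = None
    for hill0 in (1.0, -1.0):
        p0 = (float(y.min()), float(y.max()), ec50_init, hill0)
        try:
            popt, _ = curve_fit(
                _model,
                x,
                y,
                p0=p0,
                bounds=([-np.inf, -np.inf, 1e-300, -50.0], [np.inf, np.inf, np.inf, 50.0]),
                maxfev=20000,
            )
        except (RuntimeError, ValueError):
            continue
        rss = float(np.sum((_model(x, *popt) - y) ** 2))
        if best is None or rss < best[1]:
            best = (popt, rss)
    if best is None:
        return FourPLFit(math.nan, math.nan, math.nan, math.nan, math.inf, False)
    (lower, upper, ec50, hill), rss = best
    ec50 *= scale
    x = x_raw
    in_range = x.min() / EC50_RANGE_SLACK <= ec50 <= x.max() * EC50_RANGE_SLACK
    return FourPLFit(
        float(lower), float(upper), float(ec50), float(hill), rss, bool(in_range)
    )


@dataclass(frozen=True)
class RelativeReactivity:
    clone: str
    condition: str
    value_pct: float


def relative_reactivity(
    ec50_normal: float, ec50_condition: float, clone: str = "", condition: str = ""
) -> RelativeReactivity:
    """100 x EC50(normal) / EC50(condition); >100% = improved reactivity."""
    if not (ec50_normal > 0 and ec50_condition > 0):
        raise ValueError("EC50 values must be positive (from converged fits)")
    return RelativeReactivity(clone, condition, 100.0 * ec50_normal / ec50_condition)


def simulate_dose_response(
    ec50: float,
    rng: np.random.Generator,
    hill: float = 1.0,
    lower: float = 0.05,
    upper: float = 2.0,
    concentrations: Sequence[float] | None = None,
    noise_sd_frac: float = 0.02,
    replicates: int = 3,
    condition_label: str = "",
) -> DoseResponse:
    """Synthetic rising ELISA curve with Gaussian noise, replicate-averaged.

    ``noise_sd_frac`` is the per-well SD as a fraction of the response
    range.  The default design is a 7-point, 6-fold serial dilution from
    1e-4 M, matching a plate titration.
    """
    if concentrations is None:
        concentrations = [1e-4 / 6.0**k for k in range(7)]
    x = np.asarray(concentrations, dtype=float)
    # rising curve: response grows with concentration (negative hill in the
    # model parameterisation above)
    clean = _model(x, lower, upper, ec50, -abs(hill))
    noise = rng.normal(0.0, noise_sd_frac * (upper - lower), size=(replicates, len(x)))
    return DoseResponse.from_replicates(x, (clean + noise).T, condition_label)


def fit_reactivity_table(df: pd.DataFrame) -> pd.DataFrame:
    """Fit every (clone, condition) series of a long-format titration table.

    Expects columns clone, condition, concentration_M, od450 (and optionally
    replicate).  Returns one row per series with the 4PL parameters and,
    where a 'normal' condition converged for the clone, the relative
    reactivity of each other condition.
    """
    required = {"clone", "condition", "concentration_M", "od450"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"titration table lacks columns {sorted(missing)}")
    rows = []
    for (clone, condition), grp in df.groupby(["clone", "condition"], sort=True):
        means = grp.groupby("concentration_M")["od450"].mean().sort_index()
        fit = fit_4pl(DoseResponse(tuple(means.index), tuple(means.values), condition))
        rows.append(
            {
                "clone": clone,
                "condition": condition,
                "ec50_M": fit.ec50,
                "hill": fit.hill,
                "lower": fit.lower,
                "upper": fit.upper,
                "rss": fit.rss,
                "converged": fit.converged,
            }
        )
    out = pd.DataFrame(rows)
    normal = {
        r["clone"]: r["ec50_M"]
        for r in rows
        if r["condition"] == "normal" and r["converged"]
    }
    rel = []
    for r in rows:
        base = normal.get(r["clone"])
        if base is not None and r["converged"] and r["condition"] != "normal":
            rel.append(100.0 * base / r["ec50_M"])
        else:
            rel.append(np.nan)
    out["relative_reactivity_pct"] = rel
    return out
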