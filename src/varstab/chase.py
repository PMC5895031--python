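"""Cycloheximide-chase densitometry: normalisation and decay kinetics.

A chase experiment blocks translation and follows the remaining target
protein by quantitative western blot.  Band densities are divided by a
loading control, expressed as percent of each replicate's t = 0 level, and
fitted with first-order decay N(t) = 100 * exp(-k t); the half-life is
ln(2)/k.  Replicates are summarised as mean +/- SEM per time point.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import InputError, InsufficientDataError, NormalizationError

#: Rate constants below this (per hour) are reported as "no detectable decay".
K_TOLERANCE = 1e-4


@dataclass(frozen=True)
class ChaseTimepoint:
    """One densitometry measurement of one replicate."""

    time_h: float
    target_density: float
    loading_density: float
    replicate: str = "r1"

    def __post_init__(self) -> None:
        if self.time_h < 0:
            raise InputError(f"negative chase time {self.time_h}")
        if self.target_density <= 0 or self.loading_density <= 0:
            raise InputError(
                f"non-positive density at t={self.time_h} h "
                f"(replicate {self.replicate})"
            )


@dataclass
class NormalizedSeries:
    """Loading-normalised percent-of-initial values per replicate.

    ``data`` has columns (replicate, time_h, percent); ``summary`` has the
    across-replicate mean +/- SEM per time point.
    """

    data: pd.DataFrame
    summary: pd.DataFrame

    @property
    def times(self) -> np.ndarray:
        return self.summary["time_h"].to_numpy()


def load_chase_table(path: str | Path) -> list[ChaseTimepoint]:
    """Read a TSV chase table (replicate, time_h, target_density, loading_density)."""
    df = pd.read_csv(path, sep="\t")
    needed = {"replicate", "time_h", "target_density", "loading_density"}
    missing = needed - set(df.columns)
    if missing:
        raise InputError(f"{path}: missing columns {sorted(missing)}")
    if df.empty:
        raise InputError(f"{path}: no data rows")
    return [
        ChaseTimepoint(
            time_h=float(r.time_h),
            target_density=float(r.target_density),
            loading_density=float(r.loading_density),
            replicate=str(r.replicate),
        )
        for r in df.itertuples()
    ]


def normalize_chase(raw: Iterable[ChaseTimepoint]) -> NormalizedSeries:
    """Normalise each replicate to its loading control and its t = 0 level.

    value(r, t) = 100 * (target(r,t)/loading(r,t)) / (target(r,0)/loading(r,0)).
    """
    points = list(raw)
    if not points:
        raise InputError("empty chase series")
    by_rep: dict[str, list[ChaseTimepoint]] = {}
    for p in points:
        by_rep.setdefault(p.replicate, []).append(p)
    rows = []
    for rep, reps in sorted(by_rep.items()):
        zeros = [p for p in reps if p.time_h == 0.0]
        if not zeros:
            raise NormalizationError(f"replicate {rep!r} has no t = 0 point")
        anchor = zeros[0].target_density / zeros[0].loading_density
        for p in sorted(reps, key=lambda q: q.time_h):
            ratio = p.target_density / p.loading_density
            rows.append(
                {"replicate": rep, "time_h": p.time_h, "percent": 100.0 * ratio / anchor}
            )
    data = pd.DataFrame(rows)
    summary = (
        data.groupby("time_h")["percent"]
        .agg(
            mean="mean",
            sem=lambda x: x.std(ddof=1) / math.sqrt(len(x)) if len(x) > 1 else 0.0,
            n="count",
        )
        .reset_index()
    )
    return NormalizedSeries(data=data, summary=summary)


@dataclass
class DecayFit:
    """First-order decay fit on the percent-of-initial scale."""

    k: float  # per hour
    half_life: float  # hours; inf when no detectable decay
    rss: float
    k_ci: tuple[float, float]
    n_points: int

    @property
    def detectable(self) -> bool:
        return self.k >= K_TOLERANCE

    def to_dict(self) -> dict:
        return {
            "k_per_h": self.k,
            "half_life_h": self.half_life if math.isfinite(self.half_life) else None,
            "detectable_decay": self.detectable,
            "rss": self.rss,
            "k_ci95": list(self.k_ci),
            "n_points": self.n_points,
        }


def fit_decay(
    series: NormalizedSeries | tuple[Sequence[float], Sequence[float]],
    fix_intercept: bool = True,
) -> DecayFit:
    """Nonlinear least-squares fit of N(t) = 100 * exp(-k t), k >= 0.

    The intercept is pinned at 100 (the normalisation anchors t = 0 there);
    ``fix_intercept=False`` frees it.  A fitted k below 1e-4 /h is reported
    as no detectable decay within the chase window (half-life = inf).
    """
    if isinstance(series, NormalizedSeries):
        t = series.data["time_h"].to_numpy(dtype=float)
        y = series.data["percent"].to_numpy(dtype=float)
    else:
        t = np.asarray(series[0], dtype=float)
        y = np.asarray(series[1], dtype=float)
    if np.unique(t).size < 3:
        raise InsufficientDataError(
            f"decay fit needs >= 3 distinct time points, got {np.unique(t).size}"
        )
    if fix_intercept:
        model = lambda tt, k: 100.0 * np.exp(-k * tt)  # noqa: E731
        p0, bounds = [0.01], (0.0, np.inf)
    else:
        model = lambda tt, k, n0: n0 * np.exp(-k * tt)  # noqa: E731
        p0, bounds = [0.01, 100.0], ([0.0, 0.0], [np.inf, np.inf])
    popt, pcov = curve_fit(model, t, y, p0=p0, bounds=bounds, maxfev=10000)
    k = float(popt[0])
    resid = y - model(t, *popt)
    rss = float((resid**2).sum())
    k_var = float(pcov[0, 0]) if np.isfinite(pcov[0, 0]) else 0.0
    half = 1.959963984540054 * math.sqrt(max(k_var, 0.0))
    k_ci = (max(0.0, k - half), k + half)
    half_life = math.log(2) / k if k >= K_TOLERANCE else math.inf
    return DecayFit(k=k, half_life=half_life, rss=rss, k_ci=k_ci, n_points=int(t.size))


def percent_remaining(fit: DecayFit, t: float) -> float:
    """Model-predicted percent of initial protein at time t (hours)."""
    if t < 0:
        raise InputError(f"negative time {t}")
    return 100.0 * math.exp(-fit.k * t)


@dataclass
class HalfLifeComparison:
    """Percent change in half-life; positive = faster degradation."""

    percent_reduction: float
    flag: str | None = None

    def to_dict(self) -> dict:
        value = self.percent_reduction
        return {
            "percent_reduction": value if math.isfinite(value) else None,
            "flag": self.flag,
        }


def compare_halflife(reference: DecayFit, mutant: DecayFit) -> HalfLifeComparison:
    """100 * (1 - t_half(mutant) / t_half(reference)).

    A non-decaying reference with a decaying mutant gives 100% (the mutant
    turns over within the window, the reference does not); a non-decaying
    mutant against a decaying reference is flagged and reported as <= 0.
    """
    ref_dec, mut_dec = reference.detectable, mutant.detectable
    if not ref_dec and not mut_dec:
        return HalfLifeComparison(0.0, flag="neither_decays")
    if not ref_dec:
        return HalfLifeComparison(100.0, flag="reference_non_decaying")
    if not mut_dec:
        return HalfLifeComparison(-math.inf, flag="mutant_non_decaying")
    return HalfLifeComparison(100.0 * (1.0 - mutant.half_life / reference.half_life))


def kinetics_report(
    series: NormalizedSeries,
    fit: DecayFit,
    comparisons: dict[str, HalfLifeComparison] | None = None,
) -> str:
    """JSON report with the fit, endpoint predictions and comparisons."""
    payload = {
        "fit": fit.to_dict(),
        "summary": series.summary.to_dict(orient="records"),
        "predicted_percent_at_24h": percent_remaining(fit, 24.0),
    }
    if comparisons:
        payload["comparisons"] = {k: c.to_dict() for k, c in comparisons.items()}
    return json.dumps(payload, indent=2)
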