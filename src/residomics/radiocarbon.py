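"""Radiocarbon calibration to calendar-year highest-posterior-density ranges.

A conventional radiocarbon age (yr BP with 1-sigma error) is mapped
through a calibration curve: on a calendar grid the likelihood of the
measured age given the curve is a normal density with variance equal to
the sum of measurement and curve variances; normalizing over the grid
gives the calibrated posterior, and HPD intervals are built by ranking
grid cells by density until the requested coverage (default 0.954,
i.e. 2-sigma) is reached — the behavior of the classic CALIB-style
calibrators.

Curve files use the 3+-column ``.14c`` dialect (cal BP, 14C age BP,
curve sigma; ``#`` comments; comma or whitespace separated); only the
first three columns are read.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.stats import norm

__all__ = ["CalCurve", "CalResult", "read_14c", "calibrate"]


@dataclass(frozen=True)
class CalCurve:
    """A calibration curve on a strictly ordered cal BP grid; linear
    interpolation applies between knots."""

    cal_bp: np.ndarray
    c14_age: np.ndarray
    sigma: np.ndarray
    name: str = ""

    def __post_init__(self):
        cal = np.asarray(self.cal_bp, dtype=float)
        age = np.asarray(self.c14_age, dtype=float)
        sig = np.asarray(self.sigma, dtype=float)
        order = np.argsort(cal)
        cal, age, sig = cal[order], age[order], sig[order]
        if np.any(np.diff(cal) <= 0):
            raise ValueError("cal BP knots must be strictly ordered")
        if np.any(sig < 0):
            raise ValueError("curve sigmas must be >= 0")
        object.__setattr__(self, "cal_bp", cal)
        object.__setattr__(self, "c14_age", age)
        object.__setattr__(self, "sigma", sig)

    @classmethod
    def identity(cls, lo: float = 0.0, hi: float = 5000.0,
                 sigma: float = 0.0) -> "CalCurve":
        """A synthetic curve with curve(t) = t (testing/teaching aid)."""
        grid = np.arange(lo, hi + 1.0)
        return cls(grid, grid.copy(), np.full(grid.size, sigma), name="identity")


def read_14c(path: str | Path, name: str | None = None) -> CalCurve:
    """Read a ``.14c`` calibration curve file (first three columns)."""
    path = Path(path)
    cal, age, sig = [], [], []
    with path.open() as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", " ").split()
            if len(parts) < 3:
                continue
            cal.append(float(parts[0]))
            age.append(float(parts[1]))
            sig.append(float(parts[2]))
    return CalCurve(np.array(cal), np.array(age), np.array(sig),
                    name=name or path.stem)


@dataclass(frozen=True)
class CalResult:
    """Calibrated posterior over the calendar grid plus HPD intervals.

    ``intervals`` are disjoint (lo cal BP, hi cal BP, probability mass)
    tuples whose total mass is at least ``coverage``; ``p`` is the mass of
    each interval as a fraction of the covered mass (1.0 when a single
    interval carries everything).
    """

    grid: np.ndarray
    density: np.ndarray
    intervals: tuple[tuple[float, float, float], ...]
    coverage: float

    @property
    def single_interval(self) -> bool:
        return len(self.intervals) == 1

    def summary(self) -> str:
        parts = [
            f"{lo:.0f}-{hi:.0f} cal BP (p = {mass / self.total_mass:.3f})"
            for lo, hi, mass in self.intervals
        ]
        return f"{self.coverage:.1%} HPD: " + "; ".join(parts)

    @property
    def total_mass(self) -> float:
        return float(sum(m for *_, m in self.intervals))


def calibrate(
    age: float,
    sigma: float,
    curve: CalCurve,
    coverage: float = 0.954,
    grid_step: float = 1.0,
) -> CalResult:
    """Calibrate ``age +/- sigma`` (conventional yr BP) against ``curve``.

    The posterior at calendar year t is proportional to
    ``Normal(age; curve(t), sqrt(sigma^2 + curve_sigma(t)^2))``, normalized
    to sum to 1 over the grid.  HPD intervals are grid cells ranked by
    density until ``coverage`` is reached, merged when contiguous.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    lo_sup, hi_sup = float(curve.c14_age.min()), float(curve.c14_age.max())
    guard = 5.0 * (sigma + float(curve.sigma.max(initial=0.0)))
    if not (lo_sup - guard <= age <= hi_sup + guard):
        raise ValueError(
            f"age {age} yr BP outside curve support "
            f"[{lo_sup:.0f}, {hi_sup:.0f}] 14C yr BP")
    grid = np.arange(curve.cal_bp[0], curve.cal_bp[-1] + grid_step / 2, grid_step)
    mu = np.interp(grid, curve.cal_bp, curve.c14_age)
    tau = np.sqrt(sigma ** 2 + np.interp(grid, curve.cal_bp, curve.sigma) ** 2)
    density = norm.pdf(age, loc=mu, scale=tau)
    total = density.sum()
    if total <= 0:
        raise ValueError("posterior mass underflow: age incompatible with curve")
    density = density / total

    order = np.argsort(density)[::-1]
    cum = np.cumsum(density[order])
    n_take = int(np.searchsorted(cum, coverage) + 1)
    chosen = np.sort(order[:n_take])
    intervals = []
    start = prev = chosen[0]
    for idx in chosen[1:]:
        if idx == prev + 1:
            prev = idx
            continue
        intervals.append((start, prev))
        start = prev = idx
    intervals.append((start, prev))
    hpd = tuple(
        (float(grid[a]), float(grid[b]), float(density[a:b + 1].sum()))
        for a, b in intervals
    )
    return CalResult(grid=grid, density=density, intervals=hpd, coverage=coverage)
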