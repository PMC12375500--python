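"""Thermal shift (CETSA) melt-curve fitting.

The soluble fraction of a protein after a brief heat pulse, normalised to
the lowest temperature, decays sigmoidally with temperature.  We fit a
descending Boltzmann model

    f(T) = bottom + (top - bottom) / (1 + exp((T - Tm) / slope))

by least squares; Tm is the inflection point — the temperature at which
half of the protein has been lost — and a 95% confidence interval comes
from the asymptotic covariance of the fit (a residual bootstrap is
available as an alternative).  Ligand engagement shows up as a positive Tm
shift between the treated and vehicle curves with non-overlapping CIs.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
from scipy import optimize, stats

__all__ = [
    "MeltCurveData",
    "MeltFit",
    "MeltFitError",
    "boltzmann",
    "fit_melt",
    "compare_tm",
]


class MeltFitError(RuntimeError):
    """The melt curve could not be fit (no melting, too few points, ...)."""


@dataclass(frozen=True)
class MeltCurveData:
    """One replicate's soluble-fraction measurements across a thermal gradient."""

    temperatures: tuple[float, ...]
    fractions: tuple[float, ...]
    condition: str = ""
    replicate: int = 1

    def __post_init__(self) -> None:
        t = np.asarray(self.temperatures, dtype=float)
        f = np.asarray(self.fractions, dtype=float)
        if t.size != f.size:
            raise ValueError("temperatures and fractions differ in length")
        if t.size < 5:
            raise ValueError("need at least 5 temperature points")
        if not np.all(np.diff(t) > 0):
            raise ValueError("temperatures must be strictly increasing")
        if t.min() < 30 or t.max() > 70:
            raise ValueError("temperatures outside the plausible 30-70 C range")


@dataclass(frozen=True)
class MeltFit:
    top: float
    bottom: float
    tm: float
    slope: float
    r2: float
    tm_ci: tuple[float, float]
    rss: float

    def __post_init__(self) -> None:
        if self.bottom > self.top:
            raise ValueError("bottom exceeds top")
        lo, hi = self.tm_ci
        if not (lo <= self.tm <= hi):
            raise ValueError("Tm outside its confidence interval")


def boltzmann(
    t: np.ndarray, top: float, bottom: float, tm: float, slope: float
) -> np.ndarray:
    return bottom + (top - bottom) / (1.0 + np.exp((t - tm) / slope))


def fit_melt(
    data: MeltCurveData,
    ci_level: float = 0.95,
    bootstrap: bool = False,
    n_boot: int = 500,
    seed: int = 0,
) -> MeltFit:
    """Least-squares Boltzmann fit with Tm confidence interval.

    Initialisation takes top/bottom from the data extremes, the slope at
    2 degrees C, and tries every observed temperature as a Tm start, keeping
    the lowest residual sum of squares.  Raises :class:`MeltFitError` for
    constant or monotone-increasing fractions (no melting) or if the fitted
    Tm falls outside the measured temperature range.
    """
    t = np.asarray(data.temperatures, dtype=float)
    f = np.asarray(data.fractions, dtype=float)
    if np.ptp(f) == 0:
        raise MeltFitError("constant fractions: nothing to fit")
    if np.all(np.diff(f) >= 0):
        raise MeltFitError("fractions increase with temperature: no melting")

    top0, bottom0 = float(f.max()), float(f.min())
    spread = top0 - bottom0
    bounds = (
        [bottom0 - spread, bottom0 - spread, t.min() - 5.0, 1e-3],
        [top0 + spread, top0 + spread, t.max() + 5.0, 50.0],
    )
    best = None
    for tm0 in t:
        try:
            popt, pcov = optimize.curve_fit(
                boltzmann,
                t,
                f,
                p0=[top0, bottom0, float(tm0), 2.0],
                bounds=bounds,
                maxfev=5000,
            )
        except (RuntimeError, ValueError):
            continue
        rss = float(((f - boltzmann(t, *popt)) ** 2).sum())
        if best is None or rss < best[0]:
            best = (rss, popt, pcov)
    if best is None:
        raise MeltFitError("curve fit failed from every initialisation")
    rss, popt, pcov = best
    top, bottom, tm, slope = (float(v) for v in popt)
    if top < bottom:
        top, bottom = bottom, top
    if not (t.min() <= tm <= t.max()):
        raise MeltFitError(f"fitted Tm {tm:.2f} outside the measured range")

    sst = float(((f - f.mean()) ** 2).sum())
    r2 = 1.0 - rss / sst if sst > 0 else float("nan")

    df = max(t.size - 4, 1)
    if bootstrap:
        rng = np.random.default_rng(seed)
        resid = f - boltzmann(t, *popt)
        tms = []
        for _ in range(n_boot):
            fb = boltzmann(t, *popt) + rng.choice(resid, size=resid.size)
            try:
                pb, _ = optimize.curve_fit(
                    boltzmann, t, fb, p0=popt, bounds=bounds, maxfev=2000
                )
            except (RuntimeError, ValueError):
                continue
            tms.append(pb[2])
        lo, hi = np.quantile(tms, [(1 - ci_level) / 2, (1 + ci_level) / 2])
        ci = (float(min(lo, tm)), float(max(hi, tm)))
    else:
        se_tm = float(np.sqrt(max(pcov[2, 2], 0.0)))
        tcrit = stats.t.ppf((1 + ci_level) / 2, df)
        ci = (tm - tcrit * se_tm, tm + tcrit * se_tm)

    return MeltFit(
        top=top, bottom=bottom, tm=tm, slope=float(abs(popt[3])),
        r2=float(r2), tm_ci=ci, rss=rss,
    )


def compare_tm(fit_a: MeltFit, fit_b: MeltFit) -> tuple[float, bool, bool]:
    """Tm shift of condition b over condition a.

    Returns ``(delta_tm, ci_overlap, stabilized)`` where ``stabilized`` means
    a positive shift with non-overlapping confidence intervals.
    """
    delta = fit_b.tm - fit_a.tm
    lo_a, hi_a = fit_a.tm_ci
    lo_b, hi_b = fit_b.tm_ci
    ci_overlap = (lo_a <= hi_b) and (lo_b <= hi_a)
    return float(delta), bool(ci_overlap), bool(delta > 0 and not ci_overlap)


def fit_melt_table(df, **kwargs) -> list[tuple[str, int, MeltFit]]:
    """Fit every (condition, replicate) curve in a melt-curve table.

    ``df`` has columns temperature, fraction, condition, replicate.
    """
    fits = []
    for (cond, rep), grp in df.groupby(["condition", "replicate"], sort=True):
        grp = grp.sort_values("temperature")
        data = MeltCurveData(
            tuple(grp["temperature"]), tuple(grp["fraction"]),
            condition=str(cond), replicate=int(rep),
        )
        fits.append((str(cond), int(rep), fit_melt(data, **kwargs)))
    return fits
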