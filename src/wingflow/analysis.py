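"""Time-series statistics for force-coefficient traces.

Simulated force records arrive on the solver's uneven time grid, so every
statistic here first resamples the trace onto a uniform grid in the stroke
phase tau (linear interpolation) before averaging or comparing.  The
root-mean-square difference between a section's trace and the reference
section's trace,

    RMSD = sqrt( (1/n) * sum_i (a_i - ref_i)^2 ),

quantifies the instantaneous disagreement between cross-sections over a
shared analysis window (canonically 1600 uniform samples on tau in [3, 15));
the comparison report collects per-case mean C_L / C_D, RMSDs against the
reference case and per-cycle lift-peak counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidParameterError

__all__ = [
    "CoefficientSeries",
    "ComparisonReport",
    "resample",
    "time_average",
    "rmsd",
    "count_lift_peaks",
    "build_report",
]


@dataclass(frozen=True)
class CoefficientSeries:
    """A scalar coefficient sampled against stroke phase tau."""

    tau: np.ndarray
    values: np.ndarray
    name: str = "series"

    def __post_init__(self):
        tau = np.asarray(self.tau, dtype=float)
        val = np.asarray(self.values, dtype=float)
        if tau.ndim != 1 or tau.shape != val.shape:
            raise InvalidParameterError("tau and values must be equal-length 1D arrays")
        if len(tau) < 2:
            raise InvalidParameterError("series needs at least two samples")
        if np.any(np.diff(tau) <= 0):
            raise InvalidParameterError("tau must be strictly increasing")
        object.__setattr__(self, "tau", tau)
        object.__setattr__(self, "values", val)

    @classmethod
    def from_records(cls, records, column: str, name: str = "") -> "CoefficientSeries":
        tau = np.array([r.tau for r in records])
        vals = np.array([getattr(r, column) for r in records])
        return cls(tau, vals, name=name or column)


def _window(series: CoefficientSeries, tau_window) -> tuple[float, float]:
    lo, hi = float(tau_window[0]), float(tau_window[1])
    if not hi > lo:
        raise InvalidParameterError(f"empty tau window ({lo}, {hi})")
    if lo < series.tau[0] - 1e-9 or hi > series.tau[-1] + 1e-9:
        raise InvalidParameterError(
            f"window [{lo}, {hi}) outside the recorded range "
            f"[{series.tau[0]:.4g}, {series.tau[-1]:.4g}]"
        )
    return lo, hi


def resample(series: CoefficientSeries, tau_window, n: int = 1600) -> CoefficientSeries:
    """Linear resampling onto ``n`` uniform tau samples on [lo, hi)."""
    lo, hi = _window(series, tau_window)
    tau_u = lo + (hi - lo) * np.arange(n) / n
    vals = np.interp(tau_u, series.tau, series.values)
    return CoefficientSeries(tau_u, vals, name=series.name)


def time_average(series: CoefficientSeries, tau_window, n: int = 1600) -> float:
    """Mean of the trace over tau in [lo, hi), resampled uniformly first.

    Warns (and records nothing else) when the window does not span an integer
    number of flap cycles, since partial cycles bias flapping-force means.
    """
    lo, hi = _window(series, tau_window)
    span = hi - lo
    if abs(span - round(span)) > 1e-9:
        warnings.warn(
            f"averaging window spans {span:.4g} cycles (non-integer); "
            "the mean of a periodic trace will be biased",
            stacklevel=2,
        )
    return float(resample(series, tau_window, n=n).values.mean())


def rmsd(
    series_a: CoefficientSeries,
    series_ref: CoefficientSeries,
    tau_window,
    n: int = 1600,
) -> float:
    """Root-mean-square difference between two traces on a shared tau grid."""
    a = resample(series_a, tau_window, n=n).values
    b = resample(series_ref, tau_window, n=n).values
    if a.shape != b.shape:
        raise InvalidParameterError("resampled series have mismatched grids")
    return float(np.sqrt(np.mean((a - b) ** 2)))


def count_lift_peaks(
    series: CoefficientSeries,
    cycle_index: int,
    prominence_frac: float = 0.10,
    smooth_frac: float = 0.05,
):
    """Local maxima of a coefficient trace within one flap cycle.

    The cycle ``tau in [cycle_index, cycle_index+1)`` is resampled
    uniformly, smoothed with a moving average of width ``smooth_frac`` of
    the cycle (physical lift events are half-stroke scale; solver traces
    carry step-scale chatter from the moving solid mask), and peaks are
    counted with a prominence threshold of ``prominence_frac`` of the
    smoothed cycle's value range.  Returns ``(count, tau_locations)``.
    """
    from scipy.signal import find_peaks

    cyc = resample(series, (cycle_index, cycle_index + 1), n=400)
    vals = cyc.values
    w = max(int(round(smooth_frac * len(vals))), 1)
    if w > 1:
        kernel = np.ones(w) / w
        padded = np.concatenate([vals[:w][::-1], vals, vals[-w:][::-1]])
        vals = np.convolve(padded, kernel, mode="same")[w:-w]
    rng = float(vals.max() - vals.min())
    if rng == 0.0:
        return 0, np.array([])
    idx, _ = find_peaks(vals, prominence=prominence_frac * rng)
    return len(idx), cyc.tau[idx]


@dataclass
class ComparisonReport:
    """Cross-section comparison statistics over a shared window."""

    tau_window: tuple[float, float]
    n: int
    reference: str
    rows: list[dict] = field(default_factory=list)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.9g")

    def __str__(self) -> str:
        return self.to_frame().to_string(index=False, float_format=lambda x: f"{x:.4f}")


def build_report(
    cases: dict[str, dict[str, CoefficientSeries]],
    reference_case: str,
    tau_window,
    n: int = 1600,
) -> ComparisonReport:
    """Means plus RMSDs versus a reference for every case.

    ``cases`` maps a case label to ``{"CL": series, "CD": series}``; the
    RMSD columns compare each case's traces to ``reference_case``'s.
    """
    if reference_case not in cases:
        raise InvalidParameterError(
            f"reference case {reference_case!r} not among {sorted(cases)}"
        )
    ref = cases[reference_case]
    report = ComparisonReport(tau_window=tuple(tau_window), n=n, reference=reference_case)
    for label, series_map in cases.items():
        cl, cd = series_map["CL"], series_map["CD"]
        lo = int(np.floor(tau_window[0]))
        n_peaks, _ = count_lift_peaks(cl, lo)
        report.rows.append(
            {
                "case": label,
                "mean_CL": time_average(cl, tau_window, n=n),
                "mean_CD": time_average(cd, tau_window, n=n),
                "rmsd_CL": rmsd(cl, ref["CL"], tau_window, n=n),
                "rmsd_CD": rmsd(cd, ref["CD"], tau_window, n=n),
                "n_peaks_per_cycle": n_peaks,
            }
        )
    return report
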