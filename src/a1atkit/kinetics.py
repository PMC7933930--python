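"""Association kinetics from intrinsic-fluorescence progress curves.

Compound binding to the serpin quenches tryptophan fluorescence; under
pseudo-first-order conditions (compound in large excess over protein) each
progress curve decays as a single exponential

    F(t) = baseline + amplitude * exp(-k_obs * t),
    k_obs = k_on * [compound] + k_off,

so the second-order association rate constant k_on is the slope of k_obs
against compound concentration.  Dissociation rate constants are derived
from k_on and an independently measured affinity via k_off = k_on * Kd.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.optimize import curve_fit

__all__ = [
    "AssociationTrace",
    "KineticsResult",
    "ExponentialFit",
    "NoSignalError",
    "fit_single_exponential",
    "fit_kon",
    "derive_koff",
    "selectivity_fold",
    "association_half_time",
    "DEAD_TIME_S",
]

#: stopped-flow apparatus dead time; half-times below this are unresolvable
DEAD_TIME_S = 10.0


class NoSignalError(ValueError):
    """Trace amplitude indistinguishable from zero (distinct from non-convergence)."""


@dataclass
class AssociationTrace:
    """One stopped-flow progress curve at a single compound concentration."""

    times: np.ndarray  # s, strictly increasing
    intensity: np.ndarray  # arbitrary fluorescence units
    compound_concentration: float  # M
    variant_label: str = "Z"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if len(self.times) < 10:
            raise ValueError("association trace needs >= 10 points")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if not self.compound_concentration > 0:
            raise ValueError("compound concentration must be > 0")


@dataclass
class ExponentialFit:
    kobs: float  # s^-1
    amplitude: float
    baseline: float
    kobs_stderr: float | None = None
    residual_rms: float = float("nan")


@dataclass
class KineticsResult:
    """Pseudo-first-order analysis across a concentration series."""

    kobs_by_concentration: dict[float, float]
    kon: float  # M^-1 s^-1
    kobs_intercept: float  # s^-1
    koff_derived: float | None = None
    pKD_used: float | None = None
    half_time: float | None = None
    negative_slope_flag: bool = False
    fit_diagnostics: dict = field(default_factory=dict)


def _exp_model(t, kobs, amplitude, baseline):
    return baseline + amplitude * np.exp(-kobs * t)


def fit_single_exponential(
    trace: AssociationTrace, noise_floor_sigma: float = 3.0
) -> ExponentialFit:
    """Least-squares single-exponential fit of one progress curve.

    Initialization is taken from a log-linearization of the first and last
    quartiles of the trace.  Raises :class:`NoSignalError` when the apparent
    amplitude does not exceed ``noise_floor_sigma`` times the local noise
    level estimated from first differences.
    """
    t, y = trace.times, trace.intensity
    n = len(t)
    q = max(n // 4, 2)
    head = float(np.mean(y[:q]))
    tail = float(np.mean(y[-q:]))
    amp0 = head - tail
    # local noise from lag-1 differences (differencing doubles the variance)
    noise = float(np.std(np.diff(y)) / math.sqrt(2.0)) if n > 2 else 0.0
    if abs(amp0) <= noise_floor_sigma * noise or amp0 == 0.0:
        raise NoSignalError(
            f"amplitude {amp0:.3g} within noise floor ({noise:.3g})"
        )

    # log-linearized rate guess from the quartile means
    t_head = float(np.mean(t[:q]))
    t_tail = float(np.mean(t[-q:]))
    mid = np.searchsorted(t, 0.5 * (t_head + t_tail))
    mid = min(max(mid, q), n - q)
    y_mid = float(np.mean(y[mid - q // 2 : mid + max(q // 2, 1)]))
    frac = (y_mid - tail) / amp0
    if 0 < frac < 1:
        k0 = -math.log(frac) / (float(t[mid]) - t_head + 1e-12)
    else:
        k0 = 1.0 / max(t_tail - t_head, 1e-6)
    k0 = abs(k0) or 1e-3

    popt, pcov = curve_fit(
        _exp_model,
        t,
        y,
        p0=[k0, amp0, tail],
        maxfev=10000,
        xtol=1e-10,
        ftol=1e-10,
    )
    kobs, amplitude, baseline = (float(v) for v in popt)
    if kobs <= 0:
        raise RuntimeError(f"exponential fit returned non-positive kobs={kobs:.3g}")
    stderr = None
    if np.all(np.isfinite(pcov)):
        stderr = float(np.sqrt(pcov[0, 0]))
    rms = float(np.sqrt(np.mean((_exp_model(t, *popt) - y) ** 2)))
    return ExponentialFit(kobs, amplitude, baseline, stderr, rms)


def fit_kon(
    kobs_list: "np.ndarray | list[float]",
    concentrations: "np.ndarray | list[float]",
) -> KineticsResult:
    """Ordinary least-squares slope of k_obs vs concentration.

    The slope is k_on (M^-1 s^-1) and the intercept estimates k_off.  A
    negative fitted slope sets ``negative_slope_flag`` and the result is
    retained for inspection rather than discarded.
    """
    kobs = np.asarray(kobs_list, dtype=float)
    conc = np.asarray(concentrations, dtype=float)
    if len(kobs) != len(conc):
        raise ValueError("kobs and concentrations must have equal length")
    if len(conc) < 2:
        raise ValueError("need >= 2 concentrations")
    if np.allclose(conc, conc[0]):
        raise ValueError("concentrations must not all be equal")
    res = stats.linregress(conc, kobs)
    slope = float(res.slope)
    return KineticsResult(
        kobs_by_concentration=dict(zip(conc.tolist(), kobs.tolist())),
        kon=slope,
        kobs_intercept=float(res.intercept),
        negative_slope_flag=slope <= 0,
        fit_diagnostics={
            "r_value": float(res.rvalue),
            "slope_stderr": float(res.stderr) if res.stderr is not None else None,
        },
    )


def derive_koff(kon: float, pKD: float) -> float:
    """First-order dissociation rate constant: k_off = k_on * Kd = k_on * 10^-pKD."""
    if not kon > 0:
        raise ValueError("kon must be > 0")
    return kon * 10.0 ** (-pKD)


def selectivity_fold(pKD_a: float, pKD_b: float) -> float:
    """Affinity ratio Kd_b / Kd_a = 10^(pKD_a - pKD_b)."""
    return 10.0 ** (pKD_a - pKD_b)


def association_half_time(
    trace: AssociationTrace, dead_time_s: float = DEAD_TIME_S
) -> tuple[float, bool]:
    """Half-time of association, t1/2 = ln 2 / k_obs.

    Returns ``(half_time_s, faster_than_dead_time)``; the flag marks traces
    whose half-time falls below the instrument dead time and which should
    therefore be excluded from k_on regressions.
    """
    fit = fit_single_exponential(trace)
    t_half = math.log(2.0) / fit.kobs
    return t_half, t_half < dead_time_s
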