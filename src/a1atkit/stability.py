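"""Conformational stability and serpin inhibitory stoichiometry.

Three analyses used to characterise stabilisation of the serpin native
state by a bound small molecule:

* **Thermal shift** — an environment-sensitive dye (SYPRO Orange) reports
  the native-to-intermediate transition over a temperature ramp; the
  Boltzmann sigmoid midpoint Tm is the comparative readout.
* **Chemical denaturation** — equilibrium unfolding in GdnHCl through a
  three-state scheme N <-> I <-> U with linear free-energy dependence
  ``dG_i(D) = dG_i - m_i * D``.  A dye (bis-ANS) reports the partially
  folded intermediate, so intensity peaks where the intermediate is
  maximally populated; a stabilising ligand moves this peak to higher
  denaturant.
* **Stoichiometry of inhibition (SI)** — moles of serpin needed to inhibit
  one mole of protease.  Residual protease activity falls linearly with
  the serpin:protease molar ratio and the x-intercept is the SI; a compound
  that blocks the inhibitory conformational change inflates the SI.

The intermediate-fraction peak has a closed form: along the denaturant
axis, d(fI)/dD = 0 exactly where ``K1*K2 = m1/m2``, i.e.

    D_peak = (dG1 + dG2 + RT*ln(m1/m2)) / (m1 + m2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.optimize import curve_fit, least_squares

__all__ = [
    "RT_KCAL",
    "ThreeStateParams",
    "UnfoldingCurve",
    "ThermalCurve",
    "SITitration",
    "SIResult",
    "NoIntermediateError",
    "NoTransitionError",
    "three_state_fractions",
    "intermediate_peak_denaturant",
    "params_for_peak",
    "unfolding_intensity",
    "fit_three_state",
    "fit_thermal_midpoint",
    "fit_si",
    "percent_activity_loss",
]

#: RT at 25 degC in kcal/mol
RT_KCAL = 0.0019872041 * 298.15


class NoIntermediateError(ValueError):
    """Unfolding curve shows no rise-and-fall (no populated intermediate)."""


class NoTransitionError(ValueError):
    """Thermal curve shows no sigmoidal transition."""


@dataclass(frozen=True)
class ThreeStateParams:
    """N <-> I <-> U equilibrium with linear denaturant dependence.

    ``dG1``/``dG2`` are the unfolding free energies (kcal/mol) of the two
    steps at zero denaturant and ``m1``/``m2`` (kcal/mol/M) their denaturant
    sensitivities.  ``amp_I`` scales the intermediate's dye response;
    ``base_N``/``base_U`` are the native/unfolded baselines (optionally with
    linear denaturant slopes ``slope_N``/``slope_U``).
    """

    dG1: float
    dG2: float
    m1: float
    m2: float
    amp_I: float = 1.0
    base_N: float = 0.0
    base_U: float = 0.0
    slope_N: float = 0.0
    slope_U: float = 0.0

    def __post_init__(self) -> None:
        if not (self.m1 > 0 and self.m2 > 0):
            raise ValueError("m-values must be > 0")


@dataclass
class UnfoldingCurve:
    denaturant: np.ndarray  # M GdnHCl, increasing from >= 0
    intensity: np.ndarray  # normalized dye fluorescence

    def __post_init__(self) -> None:
        self.denaturant = np.asarray(self.denaturant, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if np.any(self.denaturant < 0) or np.any(np.diff(self.denaturant) <= 0):
            raise ValueError("denaturant grid must be >= 0 and increasing")


@dataclass
class ThermalCurve:
    temperatures: np.ndarray  # degC, increasing
    dye_fluorescence: np.ndarray
    ramp_rate: float = 1.0  # degC/min

    def __post_init__(self) -> None:
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.dye_fluorescence = np.asarray(self.dye_fluorescence, dtype=float)
        if len(self.temperatures) < 20:
            raise ValueError("thermal curve needs >= 20 points")
        if np.ptp(self.temperatures) < 20:
            raise ValueError("thermal curve must span >= 20 degC")


def three_state_fractions(
    params: ThreeStateParams, denaturant: "float | np.ndarray"
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Boltzmann-weighted (fN, fI, fU) at the given denaturant concentration.

    Fractions sum to 1 identically.  Computed in a numerically safe form:
    weights are exponentials of the shifted free-energy surface.
    """
    d = np.asarray(denaturant, dtype=float)
    g1 = (params.dG1 - params.m1 * d) / RT_KCAL  # N -> I
    g12 = g1 + (params.dG2 - params.m2 * d) / RT_KCAL  # N -> U
    # log-weights relative to N: 0, -g1, -g12; subtract max for stability
    lw = np.stack([np.zeros_like(g1), -g1, -g12])
    lw -= lw.max(axis=0)
    w = np.exp(lw)
    z = w.sum(axis=0)
    return w[0] / z, w[1] / z, w[2] / z


def intermediate_peak_denaturant(params: ThreeStateParams) -> float:
    """Denaturant concentration maximising the intermediate fraction.

    Setting d(fI)/dD = 0 gives K1*K2 = m1/m2, hence the closed form
    ``(dG1 + dG2 + RT*ln(m1/m2)) / (m1 + m2)``.
    """
    return (params.dG1 + params.dG2 + RT_KCAL * math.log(params.m1 / params.m2)) / (
        params.m1 + params.m2
    )


def params_for_peak(
    peak_denaturant: float,
    m1: float = 3.0,
    m2: float = 2.0,
    midpoint_separation: float = 0.5,
    **dye_kwargs,
) -> ThreeStateParams:
    """Construct parameters whose intermediate peak sits exactly at ``peak_denaturant``.

    The two transition midpoints ``D1 = dG1/m1`` and ``D2 = dG2/m2`` are
    placed symmetrically ``midpoint_separation/2`` below/above the requested
    peak (up to the small RT*ln(m1/m2) correction shared between them).
    """
    total = peak_denaturant * (m1 + m2) - RT_KCAL * math.log(m1 / m2)
    # split so that D1 < D2 by roughly midpoint_separation
    d1 = (total - m2 * midpoint_separation) / (m1 + m2)
    d2 = d1 + midpoint_separation
    params = ThreeStateParams(
        dG1=m1 * d1, dG2=m2 * d2, m1=m1, m2=m2, **dye_kwargs
    )
    assert abs(intermediate_peak_denaturant(params) - peak_denaturant) < 1e-9
    return params


def unfolding_intensity(
    params: ThreeStateParams, denaturant: "float | np.ndarray"
) -> np.ndarray:
    """Dye intensity: intermediate-weighted response plus N/U baselines."""
    d = np.asarray(denaturant, dtype=float)
    fn, fi, fu = three_state_fractions(params, d)
    return (
        (params.base_N + params.slope_N * d) * fn
        + params.amp_I * fi
        + (params.base_U + params.slope_U * d) * fu
    )


def fit_three_state(
    curve: UnfoldingCurve, fit_baselines: bool = False
) -> tuple[ThreeStateParams, float]:
    """Fit the three-state model to a bis-ANS profile.

    Returns ``(params, peak_denaturant)`` where the peak is the analytic
    maximum of the fitted intermediate occupancy.  Raises
    :class:`NoIntermediateError` for curves without an interior
    rise-and-fall.  Baselines are held at zero by default (the dye reports
    only the intermediate and profiles are normalised); ``fit_baselines``
    frees flat N/U baselines.
    """
    d, y = curve.denaturant, curve.intensity
    i_max = int(np.argmax(y))
    span = np.ptp(y)
    if span <= 0 or i_max == 0 or i_max == len(d) - 1:
        raise NoIntermediateError("no interior intensity maximum in profile")
    rise = y[i_max] - y[0]
    fall = y[i_max] - y[-1]
    if rise < 0.1 * span or fall < 0.1 * span:
        raise NoIntermediateError("profile lacks a clear rise-and-fall")

    d_pk = float(d[i_max])
    # crude width -> m-value scale: half-maximum crossings
    half = y[i_max] / 2.0
    left = d[: i_max + 1]
    right = d[i_max:]
    yl = y[: i_max + 1]
    yr = y[i_max:]
    d_lo = float(np.interp(half, yl, left)) if yl[0] < half else float(left[0])
    d_hi = (
        float(np.interp(half, yr[::-1], right[::-1])) if yr[-1] < half else float(right[-1])
    )
    width = max(d_hi - d_lo, 0.2)
    m0 = 4.0 * RT_KCAL / max(width / 4.0, 0.05)
    m0 = float(np.clip(m0, 0.5, 8.0))

    def pack(x):
        dG1, dG2, lm1, lm2, amp = x[:5]
        base = x[5] if fit_baselines else 0.0
        return ThreeStateParams(
            dG1=dG1, dG2=dG2, m1=math.exp(lm1), m2=math.exp(lm2),
            amp_I=amp, base_N=base, base_U=base,
        )

    def resid(x):
        return unfolding_intensity(pack(x), d) - y

    x0 = [m0 * (d_pk - width / 4), m0 * (d_pk + width / 4) * 0.8,
          math.log(m0), math.log(m0 * 0.8), float(y[i_max])]
    if fit_baselines:
        x0.append(float(min(y[0], y[-1])))
    sol = least_squares(resid, x0, xtol=1e-13, ftol=1e-13, max_nfev=20000)
    if not sol.success:
        raise RuntimeError("three-state fit did not converge")
    params = pack(sol.x)
    return params, intermediate_peak_denaturant(params)


def _boltzmann(t, tm, slope, low, high):
    return low + (high - low) / (1.0 + np.exp((tm - t) / slope))


def fit_thermal_midpoint(
    curve: ThermalCurve, min_dynamic_range: float = 0.2
) -> tuple[float, dict]:
    """Boltzmann sigmoid midpoint (Tm, degC) of a thermal-shift trace.

    Raises :class:`NoTransitionError` for flat or non-sigmoidal input.
    """
    t, y = curve.temperatures, curve.dye_fluorescence
    span = np.ptp(y)
    scale = max(abs(float(np.mean(y))), span, 1e-30)
    if span < min_dynamic_range * scale:
        raise NoTransitionError("no sigmoidal transition: flat trace")
    half = (y.max() + y.min()) / 2.0
    tm0 = float(t[np.argmin(np.abs(y - half))])
    try:
        popt, _ = curve_fit(
            _boltzmann, t, y,
            p0=[tm0, np.ptp(t) / 20.0, float(y.min()), float(y.max())],
            maxfev=10000,
        )
    except RuntimeError as exc:
        raise NoTransitionError(f"sigmoid fit failed: {exc}") from exc
    tm, slope, low, high = (float(v) for v in popt)
    if not (t.min() <= tm <= t.max()):
        raise NoTransitionError(f"fitted midpoint {tm:.1f} degC outside ramp")
    return tm, {"slope": slope, "low": low, "high": high}


# ---------------------------------------------------------------------------
# stoichiometry of inhibition


@dataclass
class SITitration:
    """Residual protease activity vs serpin:protease molar ratio."""

    ratios: np.ndarray
    residual_activity: np.ndarray

    def __post_init__(self) -> None:
        self.ratios = np.asarray(self.ratios, dtype=float)
        self.residual_activity = np.asarray(self.residual_activity, dtype=float)
        if np.any(self.ratios < 0):
            raise ValueError("molar ratios must be >= 0")


@dataclass
class SIResult:
    SI: float
    slope: float
    intercept: float
    n_points_used: int
    stderr: float | None = None


def fit_si(
    titration: SITitration, activity_band: tuple[float, float] = (0.1, 0.9)
) -> SIResult:
    """SI from the x-intercept of the linear region of the titration.

    Points with residual activity inside ``activity_band`` form the linear
    region (avoids the upper plateau and the x-axis censoring at zero
    activity); ordinary least squares gives slope and intercept and
    SI = -intercept/slope.
    """
    r, a = titration.ratios, titration.residual_activity
    lo, hi = activity_band
    mask = (a >= lo) & (a <= hi)
    if mask.sum() < 2:
        # fall back to all strictly descending, uncensored points
        mask = a > lo
    if mask.sum() < 2:
        raise ValueError("no descending linear region in titration")
    res = stats.linregress(r[mask], a[mask])
    if res.slope >= 0:
        raise ValueError("titration does not descend: cannot place x-intercept")
    si = -float(res.intercept) / float(res.slope)
    stderr = None
    if res.stderr and res.slope != 0:
        # first-order error propagation of the intercept ratio
        stderr = abs(si) * math.sqrt(
            (res.stderr / res.slope) ** 2
            + (res.intercept_stderr / res.intercept) ** 2
            if res.intercept != 0
            else (res.stderr / res.slope) ** 2
        )
    return SIResult(
        SI=si,
        slope=float(res.slope),
        intercept=float(res.intercept),
        n_points_used=int(mask.sum()),
        stderr=stderr,
    )


def percent_activity_loss(SI_ref: float, SI_treated: float) -> float:
    """Percent loss of inhibitory activity: 100 * (1 - SI_ref / SI_treated)."""
    if SI_ref < 1 or SI_treated < 1:
        raise ValueError("SI values must be >= 1")
    if math.isinf(SI_treated):
        return 100.0
    return 100.0 * (1.0 - SI_ref / SI_treated)
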