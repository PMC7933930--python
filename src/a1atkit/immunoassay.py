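"""Sandwich TR-FRET immunoassay model, hook-effect deconvolution, 4PL fitting.

The sandwich assay reads out analyte that is simultaneously bound by a
capture (donor-side) and a detection (acceptor-side) antibody.  At analyte
concentrations well above the antibody totals, capture and detection
antibodies end up on *different* analyte molecules and the FRET signal
collapses — the high-dose hook effect.  Plotting signal against sample
dilution therefore gives a bell-shaped curve whose peak position scales
linearly with the analyte concentration in the undiluted sample; comparing
peak positions against calibration standards quantifies the analyte even
though no single dilution is in the linear range.

Two assay configurations matter for Z alpha-1-antitrypsin plasma samples:

* a polymer-specific assay (capture mAb recognises only the pathological
  polymer, so monomer contributes no signal), and
* a total assay (both antibodies recognise every conformer).

Polymer is quantified from the polymer assay; its contribution to the total
assay is then removed to recover the monomer concentration.

Model: each analyte subunit carries one epitope per antibody class and the
two epitopes are independent.  For each antibody, the free concentration
solves the single-site conservation

    ab_total = ab_free * (1 + sum_s [s] / (Kd_s + ab_free)),

and the doubly-bound (signal-generating) analyte is
``sum_s [s] * p_cap(s) * p_det(s)`` with ``p = ab_free / (ab_free + Kd)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.optimize import brentq, curve_fit

__all__ = [
    "AssayDefinition",
    "SpeciesMix",
    "DilutionSeries",
    "PeakEstimate",
    "CalibrationModel",
    "DoseResponseCurve",
    "FourPLFit",
    "NoInteriorPeakError",
    "FlatCurveError",
    "sandwich_signal",
    "find_hook_peak",
    "calibrate_peaks",
    "quantify_polymer",
    "deconvolve_monomer",
    "fit_4pl",
    "normalize_response",
    "polymer_assay",
    "total_assay",
]

INF = float("inf")


class NoInteriorPeakError(ValueError):
    """Dilution series has no interior signal maximum."""


class FlatCurveError(ValueError):
    """Dose-response curve shows insufficient dynamic range."""


@dataclass(frozen=True)
class SpeciesMix:
    """Monomer and polymer concentrations in subunit equivalents (M)."""

    monomer: float = 0.0
    polymer: float = 0.0

    def __post_init__(self) -> None:
        if self.monomer < 0 or self.polymer < 0:
            raise ValueError("species concentrations must be >= 0")

    def diluted(self, factor: float) -> "SpeciesMix":
        return SpeciesMix(self.monomer / factor, self.polymer / factor)

    def scaled(self, factor: float) -> "SpeciesMix":
        return SpeciesMix(self.monomer * factor, self.polymer * factor)


@dataclass(frozen=True)
class AssayDefinition:
    """Effective two-antibody sandwich assay.

    The physical assay uses a primary antibody plus a labelled secondary on
    each side; because the secondaries are in excess the four-antibody
    sandwich is collapsed to an effective capture/detection pair whose
    totals are the limiting (primary) concentrations.  ``inf`` for a Kd
    encodes a species the antibody does not recognise.
    """

    capture_antibody_total: float  # M
    detection_antibody_total: float  # M
    Kd_capture_monomer: float
    Kd_capture_polymer: float
    Kd_detection_monomer: float
    Kd_detection_polymer: float
    signal_scale: float = 1.0  # FRET-ratio units per M doubly-bound analyte
    background: float = 0.0

    def __post_init__(self) -> None:
        if not (self.capture_antibody_total > 0 and self.detection_antibody_total > 0):
            raise ValueError("antibody totals must be > 0")
        both_mono = math.isfinite(self.Kd_capture_monomer) and math.isfinite(
            self.Kd_detection_monomer
        )
        both_poly = math.isfinite(self.Kd_capture_polymer) and math.isfinite(
            self.Kd_detection_polymer
        )
        if not (both_mono or both_poly):
            raise ValueError("at least one species must bind both antibodies")

    def capture_kds(self) -> tuple[float, float]:
        return (self.Kd_capture_monomer, self.Kd_capture_polymer)

    def detection_kds(self) -> tuple[float, float]:
        return (self.Kd_detection_monomer, self.Kd_detection_polymer)


def polymer_assay(
    capture_antibody_total: float = 1.25e-9,  # 2C1 mAb
    detection_antibody_total: float = 14.3e-9,  # limited by anti-rabbit APC
    Kd: float = 1e-9,
    signal_scale: float = 1e9,
    background: float = 0.01,
    detection_sees_monomer: bool = False,
) -> AssayDefinition:
    """Polymer-specific configuration: the capture mAb does not see monomer.

    By default the assay is idealised as fully polymer-specific.  In the
    physical assay the polyclonal detection side binds every conformer, so
    monomer silently depletes detection antibody and shifts the hook peak
    of mixtures; enable ``detection_sees_monomer`` to model (and quantify)
    that cross-reactivity bias.
    """
    return AssayDefinition(
        capture_antibody_total=capture_antibody_total,
        detection_antibody_total=detection_antibody_total,
        Kd_capture_monomer=INF,
        Kd_capture_polymer=Kd,
        Kd_detection_monomer=Kd if detection_sees_monomer else INF,
        Kd_detection_polymer=Kd,
        signal_scale=signal_scale,
        background=background,
    )


def total_assay(
    capture_antibody_total: float = 1.5e-9,  # 3C11-side effective total
    detection_antibody_total: float = 14.3e-9,
    Kd: float = 1e-9,
    signal_scale: float = 1e9,
    background: float = 0.01,
) -> AssayDefinition:
    """Total assay: both antibodies recognise monomer and polymer equally."""
    return AssayDefinition(
        capture_antibody_total=capture_antibody_total,
        detection_antibody_total=detection_antibody_total,
        Kd_capture_monomer=Kd,
        Kd_capture_polymer=Kd,
        Kd_detection_monomer=Kd,
        Kd_detection_polymer=Kd,
        signal_scale=signal_scale,
        background=background,
    )


@dataclass
class DilutionSeries:
    """FRET ratio vs dilution factor (>= 1, increasing = more dilute)."""

    dilution_factors: np.ndarray
    fret_ratios: np.ndarray

    def __post_init__(self) -> None:
        self.dilution_factors = np.asarray(self.dilution_factors, dtype=float)
        self.fret_ratios = np.asarray(self.fret_ratios, dtype=float)
        if self.dilution_factors.shape != self.fret_ratios.shape:
            raise ValueError("dilution factors and ratios must have equal length")
        if np.any(self.dilution_factors < 1):
            raise ValueError("dilution factors must be >= 1")
        if np.any(np.diff(self.dilution_factors) <= 0):
            raise ValueError("dilution factors must be strictly increasing")


@dataclass
class PeakEstimate:
    peak_dilution: float
    peak_signal: float
    method: str  # "grid-max" or "quadratic-interp"
    interior: bool


@dataclass
class CalibrationModel:
    """Peak-position calibration against standards of known concentration.

    ``slope``/``intercept`` describe the log-log regression of the peak
    *dilution fraction* (1/dilution factor) on the standard concentration;
    the theoretical slope is -1 because the analyte concentration at the
    signal peak is a property of the assay alone.  The model also stores
    the pooled net signal vs *assay* (in-well) concentration relation from
    the standards, used when a signal must be converted to a concentration.
    """

    slope: float
    intercept: float
    conc_range: tuple[float, float]  # valid stock-concentration range, M
    peak_assay_concentration: float  # analyte conc in the well at the peak, M
    peak_net_signal: float  # mean net (background-subtracted) peak signal
    background: float
    # pooled ascending-branch samples of net signal vs assay concentration
    _curve_conc: np.ndarray = field(repr=False, default=None)
    _curve_signal: np.ndarray = field(repr=False, default=None)
    excluded_standards: list = field(default_factory=list)

    def predict_peak_dilution(self, concentration: float) -> float:
        """Peak dilution factor expected for a stock concentration."""
        log_frac = self.intercept + self.slope * math.log10(concentration)
        return 10.0 ** (-log_frac)

    def concentration_from_peak(self, peak_dilution: float) -> float:
        """Invert the peak-position regression."""
        log_frac = -math.log10(peak_dilution)
        return 10.0 ** ((log_frac - self.intercept) / self.slope)

    def net_signal_at(self, assay_concentration: float) -> float:
        """Net signal expected at an in-well concentration (ascending branch)."""
        c = np.clip(assay_concentration, self._curve_conc[0], self._curve_conc[-1])
        return float(
            np.interp(np.log10(c), np.log10(self._curve_conc), self._curve_signal)
        )

    def assay_concentration_from_signal(self, net_signal: float) -> float:
        """Invert the ascending branch; signals above the peak map to the peak."""
        if net_signal >= self._curve_signal[-1]:
            return float(self._curve_conc[-1])
        if net_signal <= self._curve_signal[0]:
            return float(self._curve_conc[0])
        lc = np.interp(net_signal, self._curve_signal, np.log10(self._curve_conc))
        return float(10.0**lc)

    def to_dict(self) -> dict:
        """JSON-serialisable form (round trips through :meth:`from_dict`)."""
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "conc_range": list(self.conc_range),
            "peak_assay_concentration": self.peak_assay_concentration,
            "peak_net_signal": self.peak_net_signal,
            "background": self.background,
            "curve_conc": self._curve_conc.tolist(),
            "curve_signal": self._curve_signal.tolist(),
            "excluded_standards": [list(e) for e in self.excluded_standards],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationModel":
        return cls(
            slope=d["slope"],
            intercept=d["intercept"],
            conc_range=tuple(d["conc_range"]),
            peak_assay_concentration=d["peak_assay_concentration"],
            peak_net_signal=d["peak_net_signal"],
            background=d["background"],
            _curve_conc=np.asarray(d["curve_conc"], dtype=float),
            _curve_signal=np.asarray(d["curve_signal"], dtype=float),
            excluded_standards=[tuple(e) for e in d.get("excluded_standards", [])],
        )


def _free_antibody(ab_total: float, species_conc, kds) -> float:
    """Free antibody from single-site conservation over all analyte epitopes."""
    def balance(free: float) -> float:
        bound = 0.0
        for c, kd in zip(species_conc, kds):
            if c <= 0.0 or math.isinf(kd):
                continue
            bound += c * free / (kd + free)
        return free + bound - ab_total

    if balance(ab_total) <= 0:  # no depletion
        return ab_total
    return brentq(balance, 0.0, ab_total, xtol=1e-30, rtol=1e-14)


def sandwich_signal(mix: SpeciesMix, assay: AssayDefinition) -> float:
    """Equilibrium FRET ratio for a monomer/polymer mixture."""
    species = (mix.monomer, mix.polymer)
    cap_free = _free_antibody(assay.capture_antibody_total, species, assay.capture_kds())
    det_free = _free_antibody(
        assay.detection_antibody_total, species, assay.detection_kds()
    )
    doubly_bound = 0.0
    for c, kd_c, kd_d in zip(species, assay.capture_kds(), assay.detection_kds()):
        if c <= 0.0 or math.isinf(kd_c) or math.isinf(kd_d):
            continue
        p_cap = cap_free / (cap_free + kd_c)
        p_det = det_free / (det_free + kd_d)
        doubly_bound += c * p_cap * p_det
    return assay.background + assay.signal_scale * doubly_bound


def dilution_curve(
    mix: SpeciesMix, assay: AssayDefinition, dilution_factors: np.ndarray
) -> np.ndarray:
    """Noiseless signal across a dilution series."""
    return np.array(
        [sandwich_signal(mix.diluted(d), assay) for d in np.asarray(dilution_factors)]
    )


def find_hook_peak(series: DilutionSeries, window: int = 1) -> PeakEstimate:
    """Locate the hook-curve maximum; quadratic refinement in log-dilution.

    ``window`` is the half-width (in grid points) of the local quadratic:
    the default 1 gives exact 3-point interpolation, which is the most
    accurate choice on noiseless curves; noisy plate data benefit from a
    wider least-squares window (e.g. 3) that averages the readout noise.

    Raises :class:`NoInteriorPeakError` when the grid maximum sits on an
    edge (monotone or clipped series).  Ties are broken toward the lower
    dilution.
    """
    d, y = series.dilution_factors, series.fret_ratios
    if len(d) < 5:
        raise ValueError("need >= 5 dilution points")
    if window < 1:
        raise ValueError("window must be >= 1")
    i = int(np.argmax(y))  # argmax takes the first (lowest-dilution) tie
    if i == 0 or i == len(d) - 1:
        raise NoInteriorPeakError(
            f"signal maximum at grid edge (index {i}); no interior peak"
        )
    lo = max(i - window, 0)
    hi = min(i + window + 1, len(d))
    x = np.log10(d[lo:hi])
    z = y[lo:hi]
    a, b, c0 = np.polyfit(x, z, 2)
    interior = True
    if a >= 0:  # degenerate curvature; fall back to the grid point
        return PeakEstimate(float(d[i]), float(y[i]), "grid-max", True)
    xv = -b / (2 * a)
    if not (x[0] <= xv <= x[-1]):
        xv = float(np.clip(xv, x[0], x[-1]))
        interior = False
    peak_signal = a * xv**2 + b * xv + c0
    method = "quadratic-interp" if window == 1 else f"quadratic-ls-w{window}"
    return PeakEstimate(float(10.0**xv), float(peak_signal), method, interior)


def calibrate_peaks(
    standards: "list[tuple[float, DilutionSeries]]",
    background: float = 0.0,
) -> CalibrationModel:
    """Fit the peak-position calibration from (concentration, series) standards.

    Standards without an interior peak are excluded with a warning entry;
    at least three usable standards spanning a decade are required.
    """
    if len(standards) < 2:
        raise ValueError("need >= 2 calibration standards")
    concs, peaks, peak_signals, excluded = [], [], [], []
    curve_c, curve_s = [], []
    for conc, series in standards:
        try:
            pk = find_hook_peak(series)
        except NoInteriorPeakError as exc:
            excluded.append((conc, str(exc)))
            continue
        concs.append(conc)
        peaks.append(pk.peak_dilution)
        peak_signals.append(pk.peak_signal - background)
        # ascending branch of net signal vs in-well concentration
        mask = series.dilution_factors >= pk.peak_dilution
        curve_c.extend(conc / series.dilution_factors[mask])
        curve_s.extend(series.fret_ratios[mask] - background)
    if len(concs) < 2:
        raise ValueError("fewer than 2 standards with interior peaks")
    concs_a = np.array(concs)
    log_frac = -np.log10(np.array(peaks))  # log10 of dilution fraction
    res = stats.linregress(np.log10(concs_a), log_frac)
    peak_conc = float(np.mean(concs_a / np.array(peaks)))
    # anchor the ascending branch at the interpolated peak so inversion is
    # not limited by the dilution-grid granularity near the maximum
    curve_c.append(peak_conc)
    curve_s.append(float(np.mean(peak_signals)))
    order = np.argsort(curve_c)
    cc = np.array(curve_c)[order]
    cs = np.array(curve_s)[order]
    below = cc <= peak_conc
    cc, cs = cc[below], cs[below]
    # enforce a single-valued ascending branch for interpolation
    keep = np.concatenate(([True], np.diff(cc) > 0))
    cc, cs = cc[keep], np.maximum.accumulate(cs[keep])
    return CalibrationModel(
        slope=float(res.slope),
        intercept=float(res.intercept),
        conc_range=(float(concs_a.min()), float(concs_a.max())),
        peak_assay_concentration=peak_conc,
        peak_net_signal=float(np.mean(peak_signals)),
        background=background,
        _curve_conc=cc,
        _curve_signal=cs,
        excluded_standards=excluded,
    )


def quantify_polymer(
    sample: DilutionSeries, cal: CalibrationModel, peak_window: int = 1
) -> tuple[float, bool]:
    """Polymer concentration from the sample's hook-peak position.

    Returns ``(concentration_M, extrapolated)``; the flag is set when the
    inverted concentration falls outside the calibration range.
    ``peak_window`` is forwarded to :func:`find_hook_peak`.
    """
    pk = find_hook_peak(sample, window=peak_window)
    conc = cal.concentration_from_peak(pk.peak_dilution)
    lo, hi = cal.conc_range
    inside = lo * (1 - 1e-6) <= conc <= hi * (1 + 1e-6)
    return conc, not inside


def deconvolve_monomer(
    total_series: DilutionSeries,
    polymer_conc: float,
    cal_total_polymer: CalibrationModel,
    cal_total_monomer: CalibrationModel,
    method: str = "peak_inversion",
    noise_allowance: float = 0.15,
    peak_window: int = 1,
) -> tuple[float, bool]:
    """Monomer concentration from the total-assay series given the polymer.

    ``method="peak_inversion"`` (default) reads the combined analyte
    concentration off the sample's total-assay peak position through the
    calibration's peak-position regression and subtracts the polymer in
    concentration space; this is exact when monomer and polymer are
    equivalent analytes in the total assay (shared anti-total antibodies),
    which the default configuration assumes.  It is also well-conditioned:
    peak position moves linearly with concentration, whereas the signal
    value at a maximum is stationary and inverts poorly.

    ``method="signal_subtraction"`` follows the classical recipe: the
    polymer's expected net signal at the sample's peak dilution is
    subtracted from the observed peak signal and the residual inverted
    through the monomer calibration.  Because antibody depletion couples
    the two species this carries a small negative bias that grows with the
    polymer fraction.

    Returns ``(monomer_M, clipped)``; results below zero are clipped with
    the flag set.  Raises ``ValueError`` when the predicted polymer
    contribution exceeds the observed peak signal by more than
    ``noise_allowance`` (fractional).
    """
    pk = find_hook_peak(total_series, window=peak_window)
    d_star = pk.peak_dilution
    net_peak = pk.peak_signal - cal_total_monomer.background
    pol_in_well = polymer_conc / d_star

    if method == "peak_inversion":
        total_conc = cal_total_monomer.concentration_from_peak(d_star)
        monomer = total_conc - polymer_conc
    elif method == "signal_subtraction":
        pol_signal = cal_total_polymer.net_signal_at(pol_in_well)
        residual = net_peak - pol_signal
        if residual < -noise_allowance * max(net_peak, 1e-30):
            raise ValueError(
                "inconsistent composition: predicted polymer contribution "
                f"({pol_signal:.3g}) exceeds observed peak signal ({net_peak:.3g})"
            )
        if residual <= 0:
            return 0.0, True
        mono_in_well = cal_total_monomer.assay_concentration_from_signal(residual)
        monomer = mono_in_well * d_star
    else:
        raise ValueError(f"unknown method {method!r}")

    if monomer < 0:
        if monomer < -noise_allowance * max(polymer_conc, 1e-30):
            raise ValueError(
                "inconsistent composition: inferred monomer "
                f"{monomer:.3g} M below zero beyond noise allowance"
            )
        return 0.0, True
    return monomer, False


# ---------------------------------------------------------------------------
# dose-response (4PL)


@dataclass
class DoseResponseCurve:
    doses: np.ndarray  # M
    responses: np.ndarray

    def __post_init__(self) -> None:
        self.doses = np.asarray(self.doses, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if self.doses.shape != self.responses.shape:
            raise ValueError("doses and responses must have equal length")
        if np.any(self.doses <= 0):
            raise ValueError("doses must be > 0")


@dataclass
class FourPLFit:
    """Four-parameter logistic fit.

    ``top``/``bottom`` are the zero-dose and infinite-dose plateaus under the
    fitted Hill sign; ``plateau_low_dose``/``plateau_high_dose`` resolve the
    direction explicitly.  ``pXC50`` is -log10 of the midpoint (M).
    """

    pXC50: float
    hill: float
    top: float
    bottom: float
    pXC50_stderr: float | None
    within_dosed_range: bool
    flat: bool = False

    @property
    def plateau_low_dose(self) -> float:
        return self.top if self.hill > 0 else self.bottom

    @property
    def plateau_high_dose(self) -> float:
        return self.bottom if self.hill > 0 else self.top

    @property
    def fold_change(self) -> float:
        """Maximal fold effect: high-dose plateau over low-dose plateau."""
        return self.plateau_high_dose / self.plateau_low_dose


def four_pl(doses, pXC50: float, hill: float, top: float, bottom: float):
    """4PL response: ``bottom + (top-bottom)/(1+(dose/XC50)^hill)``.

    With ``hill > 0`` the curve descends from ``top`` (zero dose) to
    ``bottom`` (saturating dose); dose at the midpoint is ``10**-pXC50``.
    """
    doses = np.asarray(doses, dtype=float)
    xc50 = 10.0 ** (-pXC50)
    return bottom + (top - bottom) / (1.0 + (doses / xc50) ** hill)


def fit_4pl(
    curve: DoseResponseCurve,
    min_dynamic_range: float = 0.2,
    fix_top: float | None = None,
    fix_bottom: float | None = None,
) -> FourPLFit:
    """Least-squares 4PL fit of a dose-response curve.

    ``fix_top``/``fix_bottom`` constrain the plateaus, appropriate for
    responses already normalised to controls (e.g. percent activity with
    known 0/100 anchors); by default all four parameters are free.

    Raises :class:`FlatCurveError` when the response range is below
    ``min_dynamic_range`` of the mean absolute response.
    """
    x, y = curve.doses, curve.responses
    if len(x) < 6:
        raise ValueError("need >= 6 doses for a 4PL fit")
    span = np.ptp(y)
    scale = max(abs(float(np.mean(y))), np.ptp(y), 1e-30)
    if span < min_dynamic_range * scale:
        raise FlatCurveError(
            f"dynamic range {span:.3g} below {min_dynamic_range:.0%} of scale"
        )
    # midpoint guess: dose where response crosses the half-range
    half = (y.max() + y.min()) / 2.0
    idx = int(np.argmin(np.abs(y - half)))
    p0_pxc50 = -math.log10(x[idx])
    descending = y[np.argsort(x)][0] > y[np.argsort(x)][-1]
    hill0 = 1.0 if descending else -1.0
    top0 = float(y.max()) if descending else float(y.min())
    bot0 = float(y.min()) if descending else float(y.max())

    if fix_top is None and fix_bottom is None:
        popt, pcov = curve_fit(
            four_pl, x, y,
            p0=[p0_pxc50, hill0, top0, bot0],
            maxfev=20000, xtol=1e-12, ftol=1e-12,
        )
        pxc50, hill, top, bottom = (float(v) for v in popt)
    else:
        top_v = top0 if fix_top is None else fix_top
        bot_v = bot0 if fix_bottom is None else fix_bottom

        def model(xx, pxc50_, hill_, *rest):
            it = iter(rest)
            t_ = next(it) if fix_top is None else fix_top
            b_ = next(it) if fix_bottom is None else fix_bottom
            return four_pl(xx, pxc50_, hill_, t_, b_)

        p0 = [p0_pxc50, hill0]
        if fix_top is None:
            p0.append(top_v)
        if fix_bottom is None:
            p0.append(bot_v)
        popt, pcov = curve_fit(
            model, x, y, p0=p0, maxfev=20000, xtol=1e-12, ftol=1e-12
        )
        pxc50, hill = float(popt[0]), float(popt[1])
        rest = list(popt[2:])
        top = float(rest.pop(0)) if fix_top is None else float(fix_top)
        bottom = float(rest.pop(0)) if fix_bottom is None else float(fix_bottom)
    stderr = None
    if np.all(np.isfinite(pcov)):
        stderr = float(np.sqrt(pcov[0, 0]))
    lo, hi = -math.log10(x.max()), -math.log10(x.min())
    return FourPLFit(
        pXC50=pxc50,
        hill=hill,
        top=top,
        bottom=bottom,
        pXC50_stderr=stderr,
        within_dosed_range=lo <= pxc50 <= hi,
    )


def normalize_response(
    raw: "float | np.ndarray", vehicle_level: float, saturating_control_level: float
) -> "float | np.ndarray":
    """Percent effect: 100 * (raw - vehicle) / (control - vehicle)."""
    denom = saturating_control_level - vehicle_level
    if denom == 0:
        raise ZeroDivisionError("saturating control equals vehicle level")
    return 100.0 * (np.asarray(raw, dtype=float) - vehicle_level) / denom
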