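"""Exact ternary competitive-binding equilibrium and competition-curve fitting.

A receptor R (here a serpin monomer) binds a fluorescent tracer L with
dissociation constant ``Kd_L`` and an unlabelled competitor C with ``Kd_C``:

    R + L <-> RL      Kd_L = [R][L]/[RL]
    R + C <-> RC      Kd_C = [R][C]/[RC]

Given total concentrations the coupled mass-balance system is cubic in the
free receptor concentration.  Rather than a discriminant-based case analysis
the unique physical root is found by bracketed scalar root-finding on free
receptor in ``[0, receptor_total]``, which is unconditionally convergent.

The fluorescence-polarization signal is an affine function of the bound
tracer fraction; fitting a competition curve for the competitor pKD uses the
exact equilibrium at every point, so ligand depletion is handled without a
Cheng-Prusoff approximation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, least_squares

__all__ = [
    "EquilibriumState",
    "CompetitionCurve",
    "AffinityResult",
    "solve_competitive_equilibrium",
    "fp_signal",
    "fit_competition_pKD",
    "NoDisplacementError",
]


class NoDisplacementError(ValueError):
    """Competition curve shows no usable dynamic range."""


@dataclass(frozen=True)
class EquilibriumState:
    """Species concentrations (M) at equilibrium."""

    free_receptor: float
    free_tracer: float
    free_competitor: float
    receptor_tracer_complex: float
    receptor_competitor_complex: float

    @property
    def bound_tracer_fraction(self) -> float:
        tot = self.free_tracer + self.receptor_tracer_complex
        return self.receptor_tracer_complex / tot if tot > 0 else 0.0


@dataclass
class CompetitionCurve:
    """A competitor titration read out by fluorescence polarization."""

    competitor_concentrations: np.ndarray  # M
    signals: np.ndarray
    receptor_total: float  # M
    tracer_total: float  # M
    tracer_Kd: float  # M
    signal_free: float = 0.0
    signal_bound: float = 1.0

    def __post_init__(self) -> None:
        self.competitor_concentrations = np.asarray(
            self.competitor_concentrations, dtype=float
        )
        self.signals = np.asarray(self.signals, dtype=float)
        if self.competitor_concentrations.shape != self.signals.shape:
            raise ValueError("concentrations and signals must have equal length")


@dataclass
class AffinityResult:
    """Fitted competitor affinity."""

    pKD: float
    stderr: float | None
    converged: bool
    signal_free: float
    signal_bound: float
    residual_rms: float = field(default=float("nan"))


def _occupancy_sum(r_free: float, lig_totals, lig_kds) -> float:
    """Total receptor bound in complexes given free receptor."""
    s = 0.0
    for tot, kd in zip(lig_totals, lig_kds):
        if tot <= 0.0 or math.isinf(kd):
            continue
        s += tot * r_free / (kd + r_free)
    return s


def solve_competitive_equilibrium(
    receptor_total: float,
    tracer_total: float,
    competitor_total: float,
    tracer_Kd: float,
    competitor_Kd: float,
) -> EquilibriumState:
    """Solve the receptor-tracer-competitor system exactly.

    Parameters are molar totals and dissociation constants; an infinite Kd
    encodes a non-binding species (e.g. a compound that does not recognise
    the polymeric conformation).  Mass conservation and both Kd relations
    hold to better than 1e-9 relative.
    """
    for name, v in (
        ("receptor_total", receptor_total),
        ("tracer_total", tracer_total),
        ("competitor_total", competitor_total),
    ):
        if v < 0:
            raise ValueError(f"{name} must be >= 0, got {v}")
    for name, kd in (("tracer_Kd", tracer_Kd), ("competitor_Kd", competitor_Kd)):
        if not kd > 0:
            raise ValueError(f"{name} must be > 0, got {kd}")

    totals = (tracer_total, competitor_total)
    kds = (tracer_Kd, competitor_Kd)

    if receptor_total == 0.0:
        return EquilibriumState(0.0, tracer_total, competitor_total, 0.0, 0.0)

    def balance(r_free: float) -> float:
        return r_free + _occupancy_sum(r_free, totals, kds) - receptor_total

    # balance(0) = -receptor_total < 0, balance(receptor_total) >= 0:
    # the bracket always contains the unique physical root.
    r_free = brentq(balance, 0.0, receptor_total, xtol=1e-30, rtol=1e-14)

    def complex_conc(tot: float, kd: float) -> float:
        if tot <= 0.0 or math.isinf(kd):
            return 0.0
        return tot * r_free / (kd + r_free)

    rl = complex_conc(tracer_total, tracer_Kd)
    rc = complex_conc(competitor_total, competitor_Kd)
    return EquilibriumState(
        free_receptor=r_free,
        free_tracer=tracer_total - rl,
        free_competitor=competitor_total - rc,
        receptor_tracer_complex=rl,
        receptor_competitor_complex=rc,
    )


def fp_signal(state: EquilibriumState, signal_free: float, signal_bound: float) -> float:
    """Polarization-like readout: affine in the bound tracer fraction."""
    return signal_free + (signal_bound - signal_free) * state.bound_tracer_fraction


def competition_signal(
    competitor_concentrations: np.ndarray,
    pKD: float,
    receptor_total: float,
    tracer_total: float,
    tracer_Kd: float,
    signal_free: float,
    signal_bound: float,
) -> np.ndarray:
    """Noiseless model curve for a competitor of affinity ``pKD``."""
    kd_c = 10.0 ** (-pKD)
    out = np.empty(len(competitor_concentrations))
    for i, c in enumerate(np.asarray(competitor_concentrations, dtype=float)):
        st = solve_competitive_equilibrium(
            receptor_total, tracer_total, c, tracer_Kd, kd_c
        )
        out[i] = fp_signal(st, signal_free, signal_bound)
    return out


def fit_competition_pKD(
    curve: CompetitionCurve,
    fit_plateaus: bool = True,
    min_dynamic_range: float = 0.2,
) -> AffinityResult:
    """Fit the competitor pKD by nonlinear least squares on the exact model.

    Plateau signal levels are fitted by default because polarization units
    are instrument-specific; set ``fit_plateaus=False`` to hold the curve's
    declared ``signal_free``/``signal_bound``.

    Raises :class:`NoDisplacementError` when the observed dynamic range is
    below ``min_dynamic_range`` of the assay's full signal window.
    """
    y = curve.signals
    window = abs(curve.signal_bound - curve.signal_free)
    if window <= 0:
        window = max(np.ptp(y), 1e-12)
    if np.ptp(y) < min_dynamic_range * window:
        raise NoDisplacementError(
            "competition curve shows "
            f"{np.ptp(y):.3g} dynamic range (< {min_dynamic_range:.0%} of window)"
        )

    conc = curve.competitor_concentrations
    pos = conc[conc > 0]
    p0 = -math.log10(np.sqrt(pos.min() * pos.max())) if len(pos) else 7.0

    if fit_plateaus:
        x0 = np.array([p0, float(y.max()), float(y.min())])

        def resid(x):
            top, bottom = x[1], x[2]
            return (
                competition_signal(
                    conc, x[0], curve.receptor_total, curve.tracer_total,
                    curve.tracer_Kd, bottom, top,
                )
                - y
            )
    else:
        x0 = np.array([p0])

        def resid(x):
            return (
                competition_signal(
                    conc, x[0], curve.receptor_total, curve.tracer_total,
                    curve.tracer_Kd, curve.signal_free, curve.signal_bound,
                )
                - y
            )

    sol = least_squares(resid, x0, method="lm", xtol=1e-12, ftol=1e-12)
    converged = bool(sol.success)
    # stderr of pKD from the Jacobian (Gauss-Newton covariance)
    stderr = None
    dof = len(y) - len(sol.x)
    if converged and dof > 0:
        try:
            jtj_inv = np.linalg.inv(sol.jac.T @ sol.jac)
            s2 = 2 * sol.cost / dof
            stderr = float(np.sqrt(s2 * jtj_inv[0, 0]))
        except np.linalg.LinAlgError:
            stderr = None
    if fit_plateaus:
        sb, sf = float(sol.x[1]), float(sol.x[2])
    else:
        sb, sf = curve.signal_bound, curve.signal_free
    return AffinityResult(
        pKD=float(sol.x[0]),
        stderr=stderr,
        converged=converged,
        signal_free=sf,
        signal_bound=sb,
        residual_rms=float(np.sqrt(np.mean(sol.fun**2))),
    )
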