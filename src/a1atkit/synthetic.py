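"""Seeded generators for every assay data type, with known ground truth.

Each generator draws from a ``numpy`` Generator seeded via
:class:`GeneratorConfig`, so a fixed seed reproduces byte-identical data.
Noise is multiplicative log-normal with a configurable coefficient of
variation (plate-reader-like); the log-normal is mean-one so noisy data are
unbiased around the model curve.  Generators return ``(data, truth)``
pairs: the truth dictionary records every generative parameter so recovery
tests never have to re-derive it.

Default scenario constants are the study's printed assay conditions (5 nM
analyte incubated 72 h at 37 C for the polymerisation end-point, 1 C/min
thermal ramp, hepatocyte depletion time points 0-240 min, and the
association/affinity/potency parameters of the lead compound).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from . import equilibrium as eq
from . import immunoassay as ia
from . import pk as pkmod
from . import stability as st
from .kinetics import AssociationTrace

__all__ = [
    "GeneratorConfig",
    "gen_association_traces",
    "gen_competition_curve",
    "gen_dilution_series",
    "gen_dose_response",
    "gen_unfolding_curve",
    "gen_thermal_curve",
    "gen_si_titration",
    "gen_depletion_series",
    "gen_pk_truth_fixture",
    "scenario",
    "SCENARIOS",
]

# ---------------------------------------------------------------------------
# study-condition constants (lead-compound campaign defaults)

#: second-order association rate constants, M^-1 s^-1
Z_KON = 4.1e4
M_KON = 2.1e2
#: competition-binding affinities, -log10 M
Z_PKD = 8.5
M_PKD = 6.8
#: polymerisation end-point potency of the lead compound, -log10 M
POLYMERISATION_PIC50 = 8.3
#: cellular potencies, -log10 M
CHO_PIC50 = 6.3
CHO_PEC50 = 6.2
IPSC_PIC50 = 6.4
IPSC_PEC50 = 6.5
#: maximal secreted-level fold increase in the iPSC model
SECRETION_FOLD = 3.0
#: bis-ANS intermediate peaks, M GdnHCl
APO_PEAK_M = 1.3
COMPOUND_PEAK_M = 1.9
#: hepatocyte intrinsic clearances, ml/min/g tissue
MOUSE_CLINT = 4.56
HUMAN_CLINT = 0.31
#: CYP3A4 time-dependent-inhibition IC50 fold shift
TDI_SHIFT = 1.59
#: hepatocyte incubation cell density, cells/ml
DEPLETION_CELL_DENSITY = 0.5e6
#: depletion sampling times, min
DEPLETION_TIMES_MIN = (0.0, 20.0, 40.0, 60.0, 120.0, 240.0)
#: TR-FRET analyte concentration, M
ANALYTE_CONC = 5e-9

SCENARIOS = {
    "Z": {"kon": Z_KON, "pKD": Z_PKD},
    "M": {"kon": M_KON, "pKD": M_PKD},
}


def scenario(variant: str) -> dict:
    """Default kinetic/affinity truth for a protein variant ('Z' or 'M')."""
    return dict(SCENARIOS[variant])


@dataclass
class GeneratorConfig:
    """Seed, noise level, replicate count and optional sampling grids.

    ``grid`` entries override the assay-specific defaults; every grid must
    be strictly monotone.  ``noise_cv`` is the coefficient of variation of
    the multiplicative log-normal noise.
    """

    seed: int = 0
    noise_cv: float = 0.0
    replicate_count: int = 1
    grid: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.replicate_count < 1:
            raise ValueError("replicate_count must be >= 1")
        for key, g in self.grid.items():
            arr = np.asarray(g, dtype=float)
            if len(arr) > 1 and not (
                np.all(np.diff(arr) > 0) or np.all(np.diff(arr) < 0)
            ):
                raise ValueError(f"grid {key!r} must be strictly monotone")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _noise_factors(rng: np.random.Generator, shape, cv: float) -> np.ndarray:
    """Mean-one multiplicative log-normal factors with the given CV."""
    if cv <= 0:
        return np.ones(shape)
    sigma = math.sqrt(math.log1p(cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=shape)


# ---------------------------------------------------------------------------
# kinetics


def gen_association_traces(
    truth: dict,
    concentrations,
    cfg: GeneratorConfig,
    n_points: int = 200,
) -> tuple[list[AssociationTrace], dict]:
    """Pseudo-first-order quenching traces at several compound concentrations.

    ``truth`` needs ``kon`` and ``koff`` (s^-1 units as usual); optional
    ``amplitude`` (default 0.5) and ``baseline`` (default 0.5).  Each trace
    follows ``F(t) = baseline + amplitude * exp(-(kon*[C]+koff) * t)``.
    The time grid defaults to ~5 observed half-lives of the slowest trace.
    """
    kon, koff = truth["kon"], truth["koff"]
    if not (kon > 0 and koff > 0):
        raise ValueError("rate constants kon and koff must be > 0")
    amplitude = truth.get("amplitude", 0.5)
    baseline = truth.get("baseline", 0.5)
    concentrations = np.asarray(concentrations, dtype=float)
    if np.any(concentrations <= 0):
        raise ValueError("concentrations must be > 0")
    rng = cfg.rng()
    traces = []
    kobs_true = {}
    for c in concentrations:
        kobs = kon * c + koff
        kobs_true[float(c)] = kobs
        if "times_s" in cfg.grid:
            t = np.asarray(cfg.grid["times_s"], dtype=float)
        else:
            t = np.linspace(0.0, 5.0 / kobs, n_points)
        f = baseline + amplitude * np.exp(-kobs * t)
        f = f * _noise_factors(rng, f.shape, cfg.noise_cv)
        traces.append(AssociationTrace(t, f, float(c), truth.get("variant", "Z")))
    truth_out = {
        "kon": kon, "koff": koff, "amplitude": amplitude, "baseline": baseline,
        "kobs_by_concentration": kobs_true,
    }
    return traces, truth_out


# ---------------------------------------------------------------------------
# competition binding


def gen_competition_curve(
    truth: dict,
    assay: dict | None = None,
    cfg: GeneratorConfig | None = None,
) -> tuple[eq.CompetitionCurve, dict]:
    """Fluorescence-polarization competition curve from the exact ternary model.

    ``truth['pKD_competitor']`` sets the competitor affinity (``inf`` Kd,
    i.e. ``pKD = -inf``, encodes a non-binder).  The default assay uses
    receptor 10 nM, tracer 2 nM with Kd 5 nM and twelve 3-fold dilutions
    of competitor from 10 uM.
    """
    cfg = cfg or GeneratorConfig()
    assay = assay or {}
    receptor_total = assay.get("receptor_total", 10e-9)
    tracer_total = assay.get("tracer_total", 2e-9)
    tracer_Kd = assay.get("tracer_Kd", 5e-9)
    signal_free = assay.get("signal_free", 50.0)
    signal_bound = assay.get("signal_bound", 250.0)
    if "competitor_M" in cfg.grid:
        conc = np.asarray(cfg.grid["competitor_M"], dtype=float)
    else:
        conc = 10e-6 / 3.0 ** np.arange(12)
    pkd = truth["pKD_competitor"]
    kd_c = float("inf") if math.isinf(pkd) and pkd < 0 else 10.0 ** (-pkd)

    # warn when the grid cannot bracket the displacement transition
    if math.isfinite(kd_c):
        ic50_guess = kd_c * (1 + tracer_total / tracer_Kd) + receptor_total / 2
        if ic50_guess < conc.min() or ic50_guess > conc.max():
            warnings.warn(
                "competitor grid does not span the tracer-displacement range",
                stacklevel=2,
            )
    signals = np.empty(len(conc))
    for i, c in enumerate(conc):
        stt = eq.solve_competitive_equilibrium(
            receptor_total, tracer_total, c, tracer_Kd, kd_c
        )
        signals[i] = eq.fp_signal(stt, signal_free, signal_bound)
    rng = cfg.rng()
    signals = signals * _noise_factors(rng, signals.shape, cfg.noise_cv)
    curve = eq.CompetitionCurve(
        conc, signals, receptor_total, tracer_total, tracer_Kd,
        signal_free, signal_bound,
    )
    truth_out = {
        "pKD_competitor": pkd, "receptor_total": receptor_total,
        "tracer_total": tracer_total, "tracer_Kd": tracer_Kd,
        "signal_free": signal_free, "signal_bound": signal_bound,
    }
    return curve, truth_out


# ---------------------------------------------------------------------------
# sandwich immunoassay


def gen_dilution_series(
    mix: ia.SpeciesMix,
    assay: ia.AssayDefinition,
    dilutions,
    cfg: GeneratorConfig,
) -> tuple[ia.DilutionSeries, dict]:
    """Hook-effect dilution series from the equilibrium sandwich model."""
    d = np.asarray(dilutions, dtype=float)
    signals = ia.dilution_curve(mix, assay, d)
    rng = cfg.rng()
    signals = signals * _noise_factors(rng, signals.shape, cfg.noise_cv)
    truth = {"monomer": mix.monomer, "polymer": mix.polymer}
    return ia.DilutionSeries(d, signals), truth


def gen_calibration_standards(
    assay: ia.AssayDefinition,
    stock_concentrations,
    species: str,
    dilutions,
    cfg: GeneratorConfig,
) -> list[tuple[float, ia.DilutionSeries]]:
    """Single-species dilution-series standards for peak calibration.

    ``species`` is ``"monomer"`` or ``"polymer"``.  Each standard draws its
    noise from an independent substream of the configured seed.
    """
    seeds = cfg.rng().integers(1, 2**31 - 1, size=len(stock_concentrations))
    out = []
    for s, conc in zip(seeds, stock_concentrations):
        sub = GeneratorConfig(seed=int(s), noise_cv=cfg.noise_cv)
        series, _ = gen_dilution_series(
            ia.SpeciesMix(**{species: conc}), assay, dilutions, sub
        )
        out.append((conc, series))
    return out


# ---------------------------------------------------------------------------
# dose-response


def gen_dose_response(
    truth: dict,
    doses=None,
    cfg: GeneratorConfig | None = None,
) -> tuple[ia.DoseResponseCurve, dict]:
    """4PL dose-response data; default 11-point 3-fold dilution from 10 uM."""
    cfg = cfg or GeneratorConfig()
    pxc50 = truth["pXC50"]
    hill = truth.get("hill", 1.0)
    bottom = truth.get("bottom", 0.0)
    top = truth.get("top", 100.0)
    if top == bottom:
        raise ValueError("top and bottom plateaus must differ")
    if doses is None:
        doses = cfg.grid.get("doses_M", 10e-6 / 3.0 ** np.arange(11))
    doses = np.asarray(doses, dtype=float)
    if np.any(doses <= 0):
        raise ValueError("doses must be > 0")
    y = ia.four_pl(doses, pxc50, hill, top, bottom)
    rng = cfg.rng()
    y = y * _noise_factors(rng, y.shape, cfg.noise_cv)
    truth_out = {"pXC50": pxc50, "hill": hill, "bottom": bottom, "top": top}
    return ia.DoseResponseCurve(doses, y), truth_out


# ---------------------------------------------------------------------------
# stability


def gen_unfolding_curve(
    truth: st.ThreeStateParams,
    denaturant_grid=None,
    cfg: GeneratorConfig | None = None,
) -> tuple[st.UnfoldingCurve, dict]:
    """bis-ANS unfolding profile; truth includes the analytic peak position."""
    cfg = cfg or GeneratorConfig()
    if denaturant_grid is None:
        denaturant_grid = cfg.grid.get("denaturant_M", np.arange(0.0, 4.05, 0.1))
    d = np.asarray(denaturant_grid, dtype=float)
    y = st.unfolding_intensity(truth, d)
    rng = cfg.rng()
    y = y * _noise_factors(rng, y.shape, cfg.noise_cv)
    truth_out = {
        "dG1": truth.dG1, "dG2": truth.dG2, "m1": truth.m1, "m2": truth.m2,
        "amp_I": truth.amp_I,
        "peak_denaturant": st.intermediate_peak_denaturant(truth),
    }
    return st.UnfoldingCurve(d, y), truth_out


def gen_thermal_curve(
    truth: dict,
    temperatures=None,
    cfg: GeneratorConfig | None = None,
) -> tuple[st.ThermalCurve, dict]:
    """SYPRO-style sigmoid melt; ``truth`` has Tm (degC) and optional slope."""
    cfg = cfg or GeneratorConfig()
    tm = truth["Tm"]
    slope = truth.get("slope", 2.0)
    low = truth.get("low", 0.1)
    high = truth.get("high", 1.0)
    if temperatures is None:
        temperatures = cfg.grid.get("temperatures_C", np.arange(25.0, 80.0, 0.5))
    t = np.asarray(temperatures, dtype=float)
    y = low + (high - low) / (1.0 + np.exp((tm - t) / slope))
    rng = cfg.rng()
    y = y * _noise_factors(rng, y.shape, cfg.noise_cv)
    return (
        st.ThermalCurve(t, y, ramp_rate=truth.get("ramp_rate", 1.0)),
        {"Tm": tm, "slope": slope, "low": low, "high": high},
    )


# ---------------------------------------------------------------------------
# stoichiometry of inhibition


def gen_si_titration(
    truth: dict,
    ratios=None,
    cfg: GeneratorConfig | None = None,
) -> tuple[st.SITitration, dict]:
    """Residual-activity titration: activity = max(0, 1 - ratio/SI) + noise."""
    cfg = cfg or GeneratorConfig()
    si = truth["SI"]
    if si < 1:
        raise ValueError("SI must be >= 1")
    if ratios is None:
        ratios = cfg.grid.get("ratios", np.linspace(0.0, 1.25 * si, 11))
    r = np.asarray(ratios, dtype=float)
    if np.any(r < 0):
        raise ValueError("molar ratios must be >= 0")
    a = np.maximum(0.0, 1.0 - r / si)
    rng = cfg.rng()
    a = a * _noise_factors(rng, a.shape, cfg.noise_cv)
    return st.SITitration(r, a), {"SI": si}


# ---------------------------------------------------------------------------
# in vitro PK


def gen_depletion_series(
    truth: dict,
    cell_density: float = DEPLETION_CELL_DENSITY,
    hepatocellularity: float = pkmod.DEFAULT_HEPATOCELLULARITY,
    times=None,
    cfg: GeneratorConfig | None = None,
) -> tuple[pkmod.DepletionSeries, dict]:
    """Log-linear substrate-depletion series implied by a CLint truth.

    The slope follows the scaling chain
    ``CLint_per_cell = CLint_per_g / hepatocellularity`` and
    ``slope = -CLint_per_cell * cell_density`` (ml/min/cell x cells/ml =
    1/min).  Noise is applied multiplicatively to the peak-area ratio, so
    it is additive on the log scale.
    """
    cfg = cfg or GeneratorConfig()
    if not (cell_density > 0 and hepatocellularity > 0):
        raise ValueError("cell_density and hepatocellularity must be > 0")
    clint_g = truth["CLint_per_g"]
    if times is None:
        times = cfg.grid.get("times_min", np.array(DEPLETION_TIMES_MIN))
    t = np.asarray(times, dtype=float)
    if len(t) < 3:
        raise ValueError("need >= 3 depletion time points")
    slope = -clint_g / hepatocellularity * cell_density  # 1/min
    ratio = np.exp(slope * t)
    rng = cfg.rng()
    ratio = ratio * _noise_factors(rng, ratio.shape, cfg.noise_cv)
    return (
        pkmod.DepletionSeries(t, np.log(ratio)),
        {"CLint_per_g": clint_g, "slope": slope,
         "cell_density": cell_density, "hepatocellularity": hepatocellularity},
    )


def gen_pk_truth_fixture(
    params: pkmod.PKParams,
    sink: pkmod.SinkParams,
    regimen: pkmod.DoseRegimen,
    **kwargs,
) -> pkmod.ConcentrationProfile:
    """Deterministic PK profile fixture (thin wrapper over the simulator)."""
    return pkmod.simulate_tid_pk(params, sink, regimen, **kwargs)
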