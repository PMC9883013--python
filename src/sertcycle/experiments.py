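"""In-silico pharmacology protocols on top of the transport-cycle model.

These routines reproduce the model-interrogation experiments that motivate
state-selective inhibitor binding as the mechanism of uncompetitive
transport inhibition:

* simulated uptake-inhibition dose-response curves and the IC50 shift ratio
  IC50(low 5-HT)/IC50(high 5-HT) - the fingerprint of use-dependent block,
* steady-state TiK occupancy versus substrate (the mechanistic driver of
  that shift),
* a scan over all eight binding-state hypotheses,
* calibration of the inhibitor KD against an experimental IC50 table,
* the mixed-binding scan over KD(ToNa)/KD(TiK) ratios,
* simulated saturation kinetics (Km, Vmax) as a function of inhibitor.

All concentrations at this interface are micromolar; conversion to the
molar/seconds units of :mod:`sertcycle.model_core` happens at the boundary.
Uptake is evaluated at steady state: at the published rate constants the
cycle relaxes within well under a second, so the one-minute experimental
uptake window is quasi-stationary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .model_core import (
    CYCLE_STATES,
    InhibitorScheme,
    LigandConditions,
    RateConstantSet,
    TransportCycleModel,
    build_sert_cycle,
    extend_with_inhibitor,
    integrate,
    steady_state,
    uptake_rate,
)
from .pharm_fits import FitError, FitResult, fit_inhibition_curve, fit_hyperbola

__all__ = [
    "ShiftResult",
    "StateScanResult",
    "MixedScanResult",
    "SaturationScanResult",
    "TikOccupancyResult",
    "simulate_uptake_dose_response",
    "ic50_shift_ratio",
    "tik_occupancy_ratio",
    "scan_state_preference",
    "calibrate_kd",
    "mixed_binding_scan",
    "saturation_under_inhibitor",
]

UM = 1e-6  # micromolar -> molar

#: KD search window for calibration: 1 nM to 10 mM, in micromolar.
KD_SEARCH_BOUNDS_UM = (1e-3, 1e4)


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ShiftResult:
    """IC50s at two substrate levels and their ratio (use-dependence index)."""

    ic50_low_uM: float
    ic50_high_uM: float
    s_low_uM: float
    s_high_uM: float
    hypothesis: tuple[str, ...]
    kd_uM: Mapping[str, float]

    @property
    def ratio(self) -> float:
        return self.ic50_low_uM / self.ic50_high_uM


@dataclass(frozen=True)
class TikOccupancyResult:
    """Steady-state TiK occupancy per substrate level, plus time courses."""

    s_levels_uM: tuple[float, ...]
    occupancy: tuple[float, ...]
    ratio: float  # occupancy(last level) / occupancy(first level); NaN if undefined
    trajectories: pd.DataFrame | None = None


@dataclass(frozen=True)
class StateScanResult:
    """Shift ratio (and optionally calibrated KD) per binding-state hypothesis."""

    shift_ratio: dict[str, float]
    calibrated_kd_uM: dict[str, float] = field(default_factory=dict)

    def as_frame(self) -> pd.DataFrame:
        rows = []
        for state in CYCLE_STATES:
            rows.append(
                {
                    "state": state,
                    "shift_ratio": self.shift_ratio.get(state, np.nan),
                    "calibrated_kd_uM": self.calibrated_kd_uM.get(state, np.nan),
                }
            )
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class MixedScanResult:
    """Shift ratio as a function of the KD(ToNa)/KD(TiK) fold-excess."""

    folds: tuple[float, ...]
    shift_ratios: tuple[float, ...]
    target_shift: float | None = None
    threshold_fold: float | None = None


@dataclass(frozen=True)
class SaturationScanResult:
    """Fitted Km and Vmax of simulated uptake at each inhibitor level."""

    i_levels_uM: tuple[float, ...]
    km_uM: tuple[float, ...]
    vmax: tuple[float, ...]
    fits: tuple[FitResult, ...] = ()

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "inhibitor_uM": self.i_levels_uM,
                "km_uM": self.km_uM,
                "vmax_per_s": self.vmax,
            }
        )


# ---------------------------------------------------------------------------
# shared plumbing
# ---------------------------------------------------------------------------


def _base_model(
    rates: RateConstantSet | None,
    conditions: LigandConditions | None,
    scheme: InhibitorScheme | None,
) -> TransportCycleModel:
    model = build_sert_cycle(rates, conditions)
    if scheme is not None:
        model = extend_with_inhibitor(model, scheme)
    return model


def _flux(model: TransportCycleModel, s_out_uM: float, i_out_uM: float) -> float:
    m = model.with_conditions(S_out=s_out_uM * UM, I_out=i_out_uM * UM)
    return float(uptake_rate(steady_state(m), m))


def scheme_from_kd(
    kd_per_state_uM: Mapping[str, float],
    name: str = "inhibitor",
    kon_I: float = 1e6,
) -> InhibitorScheme:
    """Build an :class:`InhibitorScheme` from micromolar KDs."""
    return InhibitorScheme(
        name, {s: kd * UM for s, kd in kd_per_state_uM.items()}, kon_I
    )


# ---------------------------------------------------------------------------
# dose-response simulation
# ---------------------------------------------------------------------------


def simulate_uptake_dose_response(
    scheme: InhibitorScheme,
    s_out_uM: float,
    i_grid_uM: Sequence[float] | None = None,
    rates: RateConstantSet | None = None,
    conditions: LigandConditions | None = None,
    n_points: int = 25,
    decades: float = 6.0,
) -> tuple[pd.DataFrame, FitResult]:
    """Steady-state uptake versus inhibitor, normalized and IC50-fitted.

    If no ``i_grid_uM`` is given, a coarse bracketing pre-scan locates the
    50%-inhibition region and a log-spaced grid of ``n_points`` over
    ``decades`` decades is centered on it.  Raises :class:`FitError` when no
    tested concentration reaches 50% inhibition (e.g. vanishing affinity).
    """
    model = _base_model(rates, conditions, scheme)
    f0 = _flux(model, s_out_uM, 0.0)
    if f0 <= 0:
        raise FitError("no uptake in the absence of inhibitor")
    if i_grid_uM is None:
        coarse = np.logspace(-6, 6, 25)  # 1 pM .. 1 M, in uM
        frac = np.array([_flux(model, s_out_uM, i) / f0 for i in coarse])
        below = np.nonzero(frac < 0.5)[0]
        if below.size == 0:
            raise FitError(
                "pre-scan never reached 50% inhibition; grid fails to "
                "bracket the IC50"
            )
        k = below[0]
        center = np.sqrt(coarse[k] * coarse[k - 1]) if k > 0 else coarse[0]
        i_grid_uM = np.logspace(
            np.log10(center) - decades / 2, np.log10(center) + decades / 2, n_points
        )
    i_grid_uM = np.asarray(i_grid_uM, dtype=float)
    response = np.array(
        [_flux(model, s_out_uM, i) / f0 * 100.0 for i in i_grid_uM]
    )
    if response.min() > 50.0 or response.max() < 50.0:
        raise FitError("inhibitor grid fails to bracket 50% inhibition")
    fit = fit_inhibition_curve(i_grid_uM, response, ci_method="wald")
    table = pd.DataFrame(
        {"conc_uM": i_grid_uM, "response": response, "s_out_uM": s_out_uM}
    )
    return table, fit


def ic50_shift_ratio(
    scheme: InhibitorScheme,
    s_low_uM: float = 0.1,
    s_high_uM: float = 10.0,
    rates: RateConstantSet | None = None,
    conditions: LigandConditions | None = None,
) -> ShiftResult:
    """IC50(low substrate) / IC50(high substrate) for one binding scheme.

    A ratio above 1 marks substrate-enhanced (use-dependent) inhibition;
    below 1, the classical competitive right-shift.
    """
    _, fit_low = simulate_uptake_dose_response(scheme, s_low_uM, rates=rates,
                                               conditions=conditions)
    _, fit_high = simulate_uptake_dose_response(scheme, s_high_uM, rates=rates,
                                                conditions=conditions)
    return ShiftResult(
        ic50_low_uM=fit_low["ic50"],
        ic50_high_uM=fit_high["ic50"],
        s_low_uM=s_low_uM,
        s_high_uM=s_high_uM,
        hypothesis=scheme.target_states,
        kd_uM={s: kd / UM for s, kd in scheme.kd_per_state.items()},
    )


# ---------------------------------------------------------------------------
# occupancy
# ---------------------------------------------------------------------------


def tik_occupancy_ratio(
    s_levels_uM: Sequence[float] = (0.1, 10.0),
    rates: RateConstantSet | None = None,
    conditions: LigandConditions | None = None,
    t_grid: Sequence[float] | None = None,
) -> TikOccupancyResult:
    """Steady-state TiK occupancy per substrate level (inhibitor-free).

    The ratio is occupancy at the last level over the first; with a zero
    substrate level in either position the ratio is reported as NaN (the
    basal TiK occupancy is substrate-independent, so a ratio against it is
    not the use-dependence index).  Optional ``t_grid`` adds relaxation time
    courses from the substrate-free resting distribution.
    """
    model = build_sert_cycle(rates, conditions)
    occ = []
    traj_frames = []
    rest = steady_state(model.with_conditions(S_out=0.0))
    for s in s_levels_uM:
        m = model.with_conditions(S_out=s * UM)
        occ.append(float(steady_state(m)[m.state_index("TiK")]))
        if t_grid is not None:
            tr = integrate(m, t_grid, rest)
            traj_frames.append(
                pd.DataFrame(
                    {
                        "time_s": tr.times,
                        "TiK": tr.state_series("TiK"),
                        "s_out_uM": s,
                    }
                )
            )
    s_levels = tuple(float(s) for s in s_levels_uM)
    if s_levels[0] == 0.0 or s_levels[-1] == 0.0:
        ratio = float("nan")
    else:
        ratio = occ[-1] / occ[0]
    return TikOccupancyResult(
        s_levels_uM=s_levels,
        occupancy=tuple(occ),
        ratio=ratio,
        trajectories=pd.concat(traj_frames, ignore_index=True)
        if traj_frames
        else None,
    )


# ---------------------------------------------------------------------------
# state-preference scan and KD calibration
# ---------------------------------------------------------------------------


def scan_state_preference(
    kd_uM: float = 12.0,
    s_low_uM: float = 0.1,
    s_high_uM: float = 10.0,
    rates: RateConstantSet | None = None,
    conditions: LigandConditions | None = None,
    calibration_table: Sequence[tuple[float, float]] | None = None,
) -> StateScanResult:
    """Shift ratio for every single-state binding hypothesis at one KD.

    Inward-facing hypotheses (Ti, TiS, TiNaS, TiK) and the allosteric ToNaS
    complex give ratios above 1; the outward-facing hypotheses give ratios
    at or below 1.  With ``calibration_table`` (list of
    ``(s_out_uM, ic50_uM)``) each hypothesis additionally gets the KD that
    best reproduces the experimental IC50s.
    """
    ratios: dict[str, float] = {}
    kds: dict[str, float] = {}
    for state in CYCLE_STATES:
        scheme = scheme_from_kd({state: kd_uM})
        ratios[state] = ic50_shift_ratio(
            scheme, s_low_uM, s_high_uM, rates, conditions
        ).ratio
        if calibration_table is not None:
            kds[state] = calibrate_kd(state, calibration_table, rates, conditions)
    return StateScanResult(shift_ratio=ratios, calibrated_kd_uM=kds)


def calibrate_kd(
    hypothesis: str | Sequence[str] | Mapping[str, float],
    ic50_table_uM: Sequence[tuple[float, float]],
    rates: RateConstantSet | None = None,
    conditions: LigandConditions | None = None,
    kon_I: float = 1e6,
) -> float:
    """KD (micromolar) minimizing the summed squared log10-IC50 discrepancy.

    ``hypothesis`` names the bound state(s); a mapping gives per-state
    multiples of the optimized KD (e.g. ``{"ToNa": 10, "TiK": 1}``).
    ``ic50_table_uM`` lists experimental ``(s_out_uM, ic50_uM)`` pairs.  The
    search runs over log10 KD within 1 nM - 10 mM; an optimum pinned to a
    boundary raises :class:`FitError`.
    """
    if isinstance(hypothesis, str):
        factors = {hypothesis: 1.0}
    elif isinstance(hypothesis, Mapping):
        factors = dict(hypothesis)
    else:
        factors = {s: 1.0 for s in hypothesis}
    table = [(float(s), float(i)) for s, i in ic50_table_uM]
    if not table:
        raise ValueError("calibration table is empty")
    lo, hi = KD_SEARCH_BOUNDS_UM

    def objective(log10_kd: float) -> float:
        kd = 10.0**log10_kd
        total = 0.0
        for s_uM, target_uM in table:
            scheme = scheme_from_kd(
                {st: f * kd for st, f in factors.items()}, kon_I=kon_I
            )
            try:
                _, fit = simulate_uptake_dose_response(
                    scheme, s_uM, rates=rates, conditions=conditions
                )
            except FitError:
                return 1e6  # off-scale KD: count as a very poor match
            total += (np.log10(fit["ic50"]) - np.log10(target_uM)) ** 2
        return total

    res = minimize_scalar(
        objective, bounds=(np.log10(lo), np.log10(hi)), method="bounded",
        options={"xatol": 1e-3},
    )
    best = 10.0**res.x
    if best <= lo * 1.05 or best >= hi / 1.05:
        raise FitError(
            f"KD optimum {best:g} uM sits at the search boundary "
            f"[{lo:g}, {hi:g}] uM"
        )
    return float(best)


# ---------------------------------------------------------------------------
# mixed binding
# ---------------------------------------------------------------------------


def mixed_binding_scan(
    fold_grid: Sequence[float] | None = None,
    kd_tik_uM: float = 12.0,
    target_shift: float | None = None,
    s_low_uM: float = 0.1,
    s_high_uM: float = 10.0,
    rates: RateConstantSet | None = None,
    conditions: LigandConditions | None = None,
) -> MixedScanResult:
    """Shift ratio versus the fold-excess of KD(ToNa) over KD(TiK).

    At fold 1 the inhibitor behaves almost like a pure outward-state binder
    plus inward sink (low shift); as the ToNa affinity weakens, the shift
    climbs towards the pure-TiK limit.  The default grid is half-decade
    log-spaced over 1..10000.  With ``target_shift`` the smallest grid fold
    whose shift reaches the target is reported; an unreachable target raises
    :class:`FitError`.
    """
    if fold_grid is None:
        fold_grid = np.logspace(0, 4, 9)
    folds = tuple(float(f) for f in fold_grid)
    shifts = []
    for fold in folds:
        scheme = scheme_from_kd({"ToNa": fold * kd_tik_uM, "TiK": kd_tik_uM})
        shifts.append(
            ic50_shift_ratio(scheme, s_low_uM, s_high_uM, rates, conditions).ratio
        )
    threshold = None
    if target_shift is not None:
        reached = [f for f, r in zip(folds, shifts) if r >= target_shift]
        if not reached:
            raise FitError(
                f"target shift {target_shift:g} not reached on the fold grid "
                f"(max {max(shifts):g})"
            )
        threshold = min(reached)
    return MixedScanResult(
        folds=folds,
        shift_ratios=tuple(shifts),
        target_shift=target_shift,
        threshold_fold=threshold,
    )


# ---------------------------------------------------------------------------
# saturation kinetics under inhibitor
# ---------------------------------------------------------------------------


def saturation_under_inhibitor(
    scheme: InhibitorScheme,
    i_levels_uM: Sequence[float],
    s_grid_uM: Sequence[float] | None = None,
    rates: RateConstantSet | None = None,
    conditions: LigandConditions | None = None,
) -> SaturationScanResult:
    """Simulated saturation kinetics: Km(I) and Vmax(I) curves.

    Steady-state flux versus substrate is computed at each inhibitor level
    and fitted with a rectangular hyperbola.  ``i_levels_uM`` must include
    the uninhibited control (0).
    """
    levels = [float(i) for i in i_levels_uM]
    if 0.0 not in levels:
        raise ValueError("inhibitor levels must include the control (0)")
    if s_grid_uM is None:
        s_grid_uM = np.logspace(-1, 2, 12)
    s_grid_uM = np.asarray(s_grid_uM, dtype=float)
    model = _base_model(rates, conditions, scheme)
    kms, vmaxs, fits = [], [], []
    for i_uM in levels:
        flux = np.array([_flux(model, s, i_uM) for s in s_grid_uM])
        fit = fit_hyperbola(s_grid_uM, flux, ci_method="wald")
        kms.append(fit["x50"])
        vmaxs.append(fit["ymax"])
        fits.append(fit)
    return SaturationScanResult(
        i_levels_uM=tuple(levels),
        km_uM=tuple(kms),
        vmax=tuple(vmaxs),
        fits=tuple(fits),
    )
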