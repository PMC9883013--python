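"""Curve fitting and classification for transporter pharmacology assays.

Covers the standard analyses of uptake-inhibition, saturation-uptake,
radioligand-displacement and current-block experiments:

* monophasic (Hill slope 1) inhibition curves -> IC50,
* rectangular hyperbolae -> Km/Vmax (or EC50/Emax),
* Dixon transformation (reciprocal bound vs inhibitor) and the
  mutually-exclusive vs mutually-non-exclusive binding diagnostic,
* mono-exponential current-block onset -> k_app, and the linear
  k_app-vs-concentration regression -> kon/koff with a zero-slope F-test,
* classification of inhibition mode (competitive / non-competitive /
  uncompetitive / mixed) from Km/Vmax trends across inhibitor levels.

Fits use unweighted least squares (lmfit); confidence intervals are
profile-likelihood at 95% where the data support them, with a Wald
(+-1.96 SE) fallback.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import lmfit
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AssayDataset",
    "FitResult",
    "DixonSeries",
    "FitError",
    "normalize_to_control",
    "fit_inhibition_curve",
    "fit_hyperbola",
    "dixon_transform",
    "classify_exclusivity",
    "fit_exp_decay",
    "fit_kapp_linear",
    "classify_inhibition_mode",
]

ASSAY_KINDS = (
    "uptake_inhibition",
    "saturation",
    "binding_displacement",
    "current_block",
)

#: Successive parameter changes below this fraction of the control value are
#: treated as ties when judging monotone trends.
TREND_TIE_FRACTION = 0.05

#: Minimum relative change of the extreme level vs control for a trend to
#: count as a real rise/fall (mode signatures move parameters severalfold;
#: ordinary fit jitter stays in the few-percent range).
TREND_EFFECT_FLOOR = 0.10

#: Coefficient-of-variation threshold under which pairwise Dixon-line
#: intersections count as clustering at a common point.
INTERSECTION_CV_THRESHOLD = 0.25


class FitError(RuntimeError):
    """A curve fit failed to converge or produced an invalid estimate."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class AssayDataset:
    """Tidy dose-response (or time-series) table for one assay.

    ``data`` columns: ``conc_uM``, ``response``, ``replicate``, ``condition``
    for the three dose-response kinds; the ``current_block`` kind adds a
    ``time_s`` column (``conc_uM`` then labels the inhibitor concentration of
    each trace).
    """

    kind: str
    data: pd.DataFrame

    REQUIRED = ("conc_uM", "response", "replicate", "condition")

    def __post_init__(self) -> None:
        if self.kind not in ASSAY_KINDS:
            raise ValueError(f"unknown assay kind {self.kind!r}")
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if self.kind == "current_block" and "time_s" not in self.data.columns:
            missing.append("time_s")
        if missing:
            raise ValueError(f"dataset is missing columns {missing}")
        if (self.data["conc_uM"] < 0).any():
            raise ValueError("concentrations must be non-negative")
        if self.kind != "current_block":
            for cond, grp in self.data.groupby("condition"):
                if grp["conc_uM"].nunique() < 4:
                    raise ValueError(
                        f"condition {cond!r} has fewer than 4 distinct "
                        "concentrations"
                    )

    def condition(self, label: str) -> pd.DataFrame:
        return self.data[self.data["condition"] == label]

    def conditions(self) -> list[str]:
        return list(dict.fromkeys(self.data["condition"]))


@dataclass
class FitResult:
    """Point estimates, 95% CIs and goodness of fit for one curve fit."""

    model: str
    params: dict[str, float]
    ci95: dict[str, tuple[float, float]]
    rss: float
    converged: bool
    n_points: int
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.converged:
            raise FitError(f"{self.model} fit did not converge")
        for name, value in self.params.items():
            lo, hi = self.ci95.get(name, (value, value))
            if not (lo <= value <= hi):
                raise ValueError(
                    f"CI ({lo:g}, {hi:g}) does not bracket estimate "
                    f"{value:g} for {name!r}"
                )

    def __getitem__(self, name: str) -> float:
        return self.params[name]


@dataclass
class DixonSeries:
    """One Dixon line: 1/bound vs inhibitor at a fixed second-ligand level."""

    level: float
    label: str
    inhibitor_conc: np.ndarray
    reciprocal_bound: np.ndarray
    slope: float
    intercept: float
    slope_ci: tuple[float, float]
    x_intercept: float

    @property
    def ic50(self) -> float:
        return -self.x_intercept


# ---------------------------------------------------------------------------
# lmfit plumbing
# ---------------------------------------------------------------------------


def _confidence_intervals(
    minimizer: lmfit.Minimizer,
    result: lmfit.minimizer.MinimizerResult,
    names: Sequence[str],
    method: Literal["profile", "wald"],
) -> dict[str, tuple[float, float]]:
    ci: dict[str, tuple[float, float]] = {}
    profiled: dict[str, tuple[float, float]] = {}
    if method == "profile":
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                report = lmfit.conf_interval(minimizer, result, sigmas=[2])
            for name in names:
                bounds = [v for _prob, v in report[name]]
                profiled[name] = (min(bounds), max(bounds))
        except Exception:
            profiled = {}
    for name in names:
        value = result.params[name].value
        if name in profiled:
            lo, hi = profiled[name]
            ci[name] = (min(lo, value), max(hi, value))
            continue
        stderr = result.params[name].stderr
        if stderr is None or not np.isfinite(stderr):
            stderr = 0.0
        ci[name] = (value - 1.96 * stderr, value + 1.96 * stderr)
    return ci


def _fit(
    model_name: str,
    residual,
    params: lmfit.Parameters,
    n_points: int,
    ci_method: Literal["profile", "wald"],
    extra: dict | None = None,
) -> FitResult:
    minimizer = lmfit.Minimizer(residual, params)
    result = minimizer.minimize(method="leastsq")
    if not result.success:
        raise FitError(f"{model_name} fit did not converge: {result.message}")
    names = [n for n in result.params if result.params[n].vary]
    ci = _confidence_intervals(minimizer, result, names, ci_method)
    estimates = {n: float(result.params[n].value) for n in names}
    return FitResult(
        model=model_name,
        params=estimates,
        ci95={n: ci[n] for n in names},
        rss=float(np.sum(np.asarray(result.residual) ** 2)),
        converged=True,
        n_points=n_points,
        extra=extra or {},
    )


# ---------------------------------------------------------------------------
# dose-response fits
# ---------------------------------------------------------------------------


def normalize_to_control(
    conc: np.ndarray, response: np.ndarray
) -> np.ndarray:
    """Express responses as percent of the mean zero-concentration response."""
    conc = np.asarray(conc, dtype=float)
    response = np.asarray(response, dtype=float)
    control = response[conc == 0]
    if control.size == 0:
        raise ValueError("no zero-concentration control present")
    return response / control.mean() * 100.0


def fit_inhibition_curve(
    conc: Sequence[float],
    response_percent: Sequence[float],
    free_hill: bool = False,
    free_floor: bool = False,
    ci_method: Literal["profile", "wald"] = "profile",
) -> FitResult:
    """Monophasic inhibition fit: response = 100 / (1 + [I]/IC50).

    ``response_percent`` must already be normalized so the uninhibited level
    is 100 (use :func:`normalize_to_control`).  The Hill slope is fixed at 1
    and the floor at 0 unless freed.  The fitted IC50 is reported in the
    units of ``conc``; an IC50 outside the tested (positive) concentration
    range is flagged ``extrapolated`` in ``extra``.
    """
    conc = np.asarray(conc, dtype=float)
    y = np.asarray(response_percent, dtype=float)
    if conc.shape != y.shape or conc.size < 4:
        raise ValueError("need >= 4 (conc, response) points of equal length")
    positive = conc[conc > 0]
    if positive.size == 0:
        raise ValueError("need at least one positive inhibitor concentration")
    params = lmfit.Parameters()
    params.add("ic50", value=float(np.median(positive)), min=1e-12)
    params.add("hill", value=1.0, vary=free_hill, min=0.1, max=5.0)
    params.add("floor", value=0.0, vary=free_floor, min=0.0, max=100.0)

    def residual(p):
        top = 100.0 - p["floor"]
        yhat = p["floor"] + top / (1.0 + (conc / p["ic50"]) ** p["hill"])
        return yhat - y

    fit = _fit("inhibition_curve", residual, params, conc.size, ci_method)
    ic50 = fit["ic50"]
    fit.extra["extrapolated"] = bool(
        ic50 < positive.min() or ic50 > positive.max()
    )
    return fit


def fit_hyperbola(
    x: Sequence[float],
    y: Sequence[float],
    ci_method: Literal["profile", "wald"] = "profile",
) -> FitResult:
    """Rectangular hyperbola fit: y = Ymax * x / (x + X50).

    Parameter names are generic (``ymax``, ``x50``); for a saturation assay
    they are Vmax and Km, for a pharmacochaperone dose-response Emax and EC50.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 4:
        raise ValueError("need >= 4 (x, y) points of equal length")
    if (x < 0).any():
        raise ValueError("x values must be non-negative")
    ymax0 = float(y.max())
    if ymax0 <= 0:
        raise FitError("degenerate data: no positive response to fit")
    half = ymax0 / 2.0
    x50_0 = float(x[np.argmin(np.abs(y - half))]) or float(np.median(x[x > 0]))
    params = lmfit.Parameters()
    params.add("ymax", value=ymax0, min=0)
    params.add("x50", value=max(x50_0, 1e-12), min=1e-12)

    def residual(p):
        return p["ymax"] * x / (x + p["x50"]) - y

    fit = _fit("hyperbola", residual, params, x.size, ci_method)
    if fit["ymax"] <= 0 or fit["x50"] <= 0:
        raise FitError("hyperbola fit produced non-positive parameters")
    return fit


# ---------------------------------------------------------------------------
# Dixon analysis
# ---------------------------------------------------------------------------


def dixon_transform(
    inhibitor_conc: Sequence[float],
    bound: Sequence[float],
    levels: Sequence[float],
    labels: Sequence[str] | None = None,
) -> list[DixonSeries]:
    """Reciprocal-bound transform plus per-level least-squares line.

    ``levels`` assigns each point its fixed second-ligand concentration; one
    Dixon line is fitted per level.  The x-intercept of each line is
    ``-intercept/slope`` and equals -IC50 of the variable inhibitor.  The
    line is fitted by weighted least squares with weights proportional to
    the bound signal (sd(1/B) scales as 1/B under proportional measurement
    noise, so the reciprocal transform would otherwise let the smallest
    signals dominate).  A non-positive slope (no inhibition) is flagged by
    raising :class:`FitError`.
    """
    conc = np.asarray(inhibitor_conc, dtype=float)
    b = np.asarray(bound, dtype=float)
    lv = np.asarray(levels, dtype=float)
    if not (conc.shape == b.shape == lv.shape):
        raise ValueError("inhibitor_conc, bound and levels must align")
    if (b <= 0).any():
        raise ValueError("bound values must be positive before the reciprocal")
    series: list[DixonSeries] = []
    for level in np.unique(lv):
        mask = lv == level
        x, y, w = conc[mask], 1.0 / b[mask], b[mask]
        if x.size < 3:
            raise ValueError(f"level {level:g} has fewer than 3 points")
        design = w[:, None] * np.column_stack([np.ones_like(x), x])
        coeffs, *_ = np.linalg.lstsq(design, w * y, rcond=None)
        intercept, slope = coeffs
        if slope <= 0:
            raise FitError(
                f"Dixon line at level {level:g} has non-positive slope "
                "(no inhibition)"
            )
        dof = x.size - 2
        resid = w * y - design @ coeffs
        sigma2 = float(resid @ resid) / dof if dof > 0 else 0.0
        cov = sigma2 * np.linalg.inv(design.T @ design)
        t_crit = stats.t.ppf(0.975, dof) if dof > 0 else 0.0
        stderr = float(np.sqrt(cov[1, 1]))
        slope_ci = (slope - t_crit * stderr, slope + t_crit * stderr)
        label = labels[int(np.argmax(mask))] if labels is not None else f"{level:g}"
        series.append(
            DixonSeries(
                level=float(level),
                label=str(label),
                inhibitor_conc=x,
                reciprocal_bound=y,
                slope=float(slope),
                intercept=float(intercept),
                slope_ci=slope_ci,
                x_intercept=float(-intercept / slope),
            )
        )
    series.sort(key=lambda s: s.level)
    return series


def classify_exclusivity(
    series: Sequence[DixonSeries],
) -> tuple[str, dict]:
    """Diagnose mutually exclusive vs non-exclusive binding from Dixon lines.

    Mutually *non-exclusive* binding of the variable inhibitor and the fixed
    ligand produces lines of progressively increasing slope that intersect at
    a common point (-IC50); mutually *exclusive* (same-site) binding produces
    homogeneous slopes with x-intercepts shifting to more negative values as
    the fixed ligand rises.  Returns ``(verdict, diagnostics)`` with verdict
    one of ``"exclusive"``, ``"non_exclusive"``, ``"indeterminate"``.
    """
    if len(series) < 2:
        raise ValueError("need at least two Dixon series")
    ordered = sorted(series, key=lambda s: s.level)
    slopes = np.array([s.slope for s in ordered])
    x_ints = np.array([s.x_intercept for s in ordered])

    slopes_increase = bool(np.all(np.diff(slopes) > 0))
    cis = [s.slope_ci for s in ordered]
    # intersections of nearly parallel lines are ill-determined; only pairs
    # whose slope CIs are disjoint contribute to the clustering statistic
    pairwise_x = []
    for i in range(len(ordered)):
        for j in range(i + 1, len(ordered)):
            if cis[i][1] < cis[j][0] or cis[j][1] < cis[i][0]:
                dm = ordered[i].slope - ordered[j].slope
                pairwise_x.append(
                    (ordered[j].intercept - ordered[i].intercept) / dm
                )
    if pairwise_x:
        px = np.asarray(pairwise_x)
        cv = float(np.std(px) / np.abs(np.mean(px))) if np.mean(px) != 0 else np.inf
    else:
        cv = np.inf
    intersections_cluster = bool(cv < INTERSECTION_CV_THRESHOLD)

    slopes_homogeneous = all(
        cis[i][0] <= cis[j][1] and cis[j][0] <= cis[i][1]
        for i in range(len(cis))
        for j in range(i + 1, len(cis))
    )
    intercepts_shift_negative = bool(np.all(np.diff(x_ints) < 0))

    diagnostics = {
        "slopes": slopes.tolist(),
        "x_intercepts": x_ints.tolist(),
        "slopes_increase": slopes_increase,
        "intersection_cv": cv,
        "intersections_cluster": intersections_cluster,
        "slopes_homogeneous": slopes_homogeneous,
        "intercepts_shift_negative": intercepts_shift_negative,
    }
    # same-site evidence (homogeneous slopes) takes precedence: chance slope
    # orderings in parallel-line data would otherwise mimic the
    # ternary-complex pattern
    if slopes_homogeneous and intercepts_shift_negative:
        return "exclusive", diagnostics
    if slopes_increase and intersections_cluster:
        return "non_exclusive", diagnostics
    return "indeterminate", diagnostics


# ---------------------------------------------------------------------------
# current-block kinetics
# ---------------------------------------------------------------------------


def fit_exp_decay(
    time_s: Sequence[float],
    current: Sequence[float],
    ci_method: Literal["profile", "wald"] = "wald",
) -> FitResult:
    """Mono-exponential block onset: I(t) = I_inf + (I_0 - I_inf) e^(-k t).

    ``time_s`` starts at inhibitor application.  Returns ``k_app`` (s^-1)
    plus the two amplitudes; a trace without decay (k_app <= 0 or no
    amplitude) raises :class:`FitError`.
    """
    t = np.asarray(time_s, dtype=float)
    y = np.asarray(current, dtype=float)
    if t.shape != y.shape or t.size < 4:
        raise ValueError("need >= 4 (time, current) samples")
    amplitude = y[: max(3, t.size // 20)].mean() - y[-max(3, t.size // 20):].mean()
    if abs(amplitude) < 1e-12 * max(1.0, np.abs(y).max()):
        raise FitError("trace shows no decay (constant current)")
    span = t[-1] - t[0]
    params = lmfit.Parameters()
    params.add("i_inf", value=float(y[-max(3, t.size // 20):].mean()))
    params.add("i_0", value=float(y[0]))
    params.add("k_app", value=2.0 / span, min=1e-9)

    def residual(p):
        return p["i_inf"] + (p["i_0"] - p["i_inf"]) * np.exp(
            -p["k_app"] * (t - t[0])
        ) - y

    fit = _fit("exp_decay", residual, params, t.size, ci_method)
    if fit["k_app"] <= 0:
        raise FitError("fitted k_app is non-positive")
    return fit


def fit_kapp_linear(
    conc: Sequence[float], k_app: Sequence[float]
) -> FitResult:
    """OLS of k_app vs inhibitor concentration: slope kon, intercept koff.

    For a direct bimolecular binding step k_app = kon*[I] + koff, so the
    slope estimates kon (per-molar per-second if ``conc`` is molar) and the
    intercept koff (s^-1).  Also reports the p-value of the zero-slope F-test
    (equivalent to the slope t-test in simple regression); a non-significant
    slope is the signature of an inhibitor whose binding is gated by the
    transporter's conformational cycle rather than direct.
    """
    x = np.asarray(conc, dtype=float)
    y = np.asarray(k_app, dtype=float)
    if x.shape != y.shape or np.unique(x).size < 3:
        raise ValueError("need k_app at >= 3 distinct concentrations")
    reg = stats.linregress(x, y)
    t_crit = stats.t.ppf(0.975, x.size - 2)
    ci = {
        "k_on": (reg.slope - t_crit * reg.stderr, reg.slope + t_crit * reg.stderr),
        "k_off": (
            reg.intercept - t_crit * reg.intercept_stderr,
            reg.intercept + t_crit * reg.intercept_stderr,
        ),
    }
    return FitResult(
        model="kapp_linear",
        params={"k_on": float(reg.slope), "k_off": float(reg.intercept)},
        ci95=ci,
        rss=float(np.sum((reg.intercept + reg.slope * x - y) ** 2)),
        converged=True,
        n_points=x.size,
        extra={"f_test_p": float(reg.pvalue), "r_squared": float(reg.rvalue**2)},
    )


# ---------------------------------------------------------------------------
# inhibition-mode classification
# ---------------------------------------------------------------------------


def _pseudo_ci(value: float) -> tuple[float, float]:
    return (value - 0.15 * abs(value), value + 0.15 * abs(value))


def _sane_ci(
    value: float, ci: tuple[float, float] | None
) -> tuple[float, float]:
    """A usable interval: the supplied CI if it brackets its estimate,
    otherwise a nominal +-15% band (guards against absent or misprinted
    intervals)."""
    if ci is not None and ci[0] <= value <= ci[1]:
        return ci
    return _pseudo_ci(value)


def _trend(
    estimates: Sequence[float],
    cis: Sequence[tuple[float, float] | None],
    control: float,
    control_ci: tuple[float, float],
) -> str:
    """Classify one parameter's course across inhibitor levels.

    ``"up"``/``"down"``: estimates monotone after merging changes smaller
    than 5% of the control (ties), with the extreme level's CI disjoint
    from the control CI on the trend side.  ``"flat"``: the extreme level's
    CI overlaps the control CI (the extreme level carries the largest
    expected effect, so it is the single highest-powered comparison;
    intermediate levels only contribute to the monotonicity judgment).
    ``"none"`` otherwise.
    """
    values = [control, *estimates]
    tie = TREND_TIE_FRACTION * abs(control)
    diffs = [b - a for a, b in zip(values, values[1:])]
    signs = {int(np.sign(d)) for d in diffs if abs(d) > tie}
    monotone_up = signs == {1}
    monotone_down = signs == {-1}
    lo_c, hi_c = control_ci
    last_lo, last_hi = _sane_ci(estimates[-1], cis[-1])
    meaningful = abs(estimates[-1] - control) > TREND_EFFECT_FLOOR * abs(control)
    if monotone_up and meaningful and last_lo > hi_c:
        return "up"
    if monotone_down and meaningful and last_hi < lo_c:
        return "down"
    if not meaningful or (last_lo <= hi_c and lo_c <= last_hi):
        return "flat"
    return "none"


def classify_inhibition_mode(
    inhibitor_levels: Sequence[float],
    km: Sequence[float],
    vmax: Sequence[float],
    km_ci: Sequence[tuple[float, float] | None] | None = None,
    vmax_ci: Sequence[tuple[float, float] | None] | None = None,
) -> tuple[str, dict]:
    """Inhibition mode from Km/Vmax courses across inhibitor concentrations.

    The classical signatures: a competitive inhibitor raises the apparent Km
    and spares Vmax; a non-competitive one lowers Vmax and spares Km; an
    uncompetitive one lowers both (its binding requires the substrate-driven
    accumulation of a cycling intermediate).  Levels must include the
    uninhibited control (0) and be strictly increasing.
    """
    levels = np.asarray(inhibitor_levels, dtype=float)
    if levels.size < 3:
        raise ValueError("need >= 3 inhibitor levels including 0")
    if np.any(np.diff(levels) <= 0):
        raise ValueError("inhibitor levels must be strictly increasing")
    if levels[0] != 0:
        raise ValueError("the first inhibitor level must be the control (0)")
    km = list(map(float, km))
    vmax = list(map(float, vmax))
    if not (len(km) == len(vmax) == levels.size):
        raise ValueError("km and vmax must have one entry per level")
    km_ci = list(km_ci) if km_ci is not None else [None] * levels.size
    vmax_ci = list(vmax_ci) if vmax_ci is not None else [None] * levels.size
    km_c_ci = km_ci[0] if km_ci[0] is not None else _pseudo_ci(km[0])
    vm_c_ci = vmax_ci[0] if vmax_ci[0] is not None else _pseudo_ci(vmax[0])

    km_trend = _trend(km[1:], km_ci[1:], km[0], km_c_ci)
    vmax_trend = _trend(vmax[1:], vmax_ci[1:], vmax[0], vm_c_ci)
    diagnostics = {"km_trend": km_trend, "vmax_trend": vmax_trend}

    if km_trend == "up" and vmax_trend == "flat":
        return "competitive", diagnostics
    if vmax_trend == "down" and km_trend == "flat":
        return "non_competitive", diagnostics
    if km_trend == "down" and vmax_trend == "down":
        return "uncompetitive", diagnostics
    return "mixed", diagnostics
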