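"""Seeded synthetic assay datasets with the noise structure of real plates.

Each generator emulates one of the four assay designs the fitting pipeline
consumes: uptake inhibition, saturation uptake, radioligand displacement
and current block.  Measurements carry multiplicative lognormal noise of a
stated coefficient of variation, an additive nonspecific background (a
fraction of the control signal, itself measured with noise and subtracted
before normalization - as a paroxetine-defined blank would be), and
triplicate replicates.  Every generator takes an explicit seed through
:class:`NoiseSpec`; there is no global random state, and identical inputs
give byte-identical datasets.

The generating parameters are returned alongside the data as a
:class:`GroundTruth`, so parameter-recovery and classifier-fidelity checks
never need external data.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .pharm_fits import AssayDataset

__all__ = [
    "NoiseSpec",
    "GroundTruth",
    "gen_uptake_inhibition",
    "gen_saturation",
    "gen_binding_displacement",
    "gen_current_block",
]


@dataclass(frozen=True)
class NoiseSpec:
    """Noise model of one synthetic assay.

    ``cv``: coefficient of variation of the multiplicative lognormal noise
    (0.10 emulates triplicate plate assays).  ``background_fraction``:
    nonspecific signal as a fraction of the control (about 0.05 for uptake,
    0.10 for binding).  ``additive_floor``: optional extra additive Gaussian
    noise, as a fraction of the control signal.  ``seed`` is mandatory.
    """

    seed: int
    cv: float = 0.10
    background_fraction: float = 0.05
    additive_floor: float = 0.0
    replicates: int = 3

    def __post_init__(self) -> None:
        if self.cv < 0:
            raise ValueError("cv must be non-negative")
        if not 0 <= self.background_fraction <= 0.5:
            raise ValueError("background_fraction must lie in [0, 0.5]")
        if self.replicates < 1:
            raise ValueError("need at least one replicate")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass(frozen=True)
class GroundTruth:
    """Generating parameters of a synthetic dataset (for recovery tests)."""

    assay_kind: str
    params: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, default=float))


def _lognormal_factor(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Unit-mean multiplicative noise with the requested CV."""
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log(1 + cv**2))
    return rng.lognormal(mean=-(sigma**2) / 2, sigma=sigma, size=size)


def _noisy_signal(
    rng: np.random.Generator,
    clean: np.ndarray,
    control_level: float,
    noise: NoiseSpec,
) -> np.ndarray:
    """Measurement model: noisy total minus a noisily measured blank.

    total = clean * f1 + background * f2;  blank = background * f3;
    response = total - blank.  With cv = 0 the background cancels exactly
    and the clean curve is returned.
    """
    bg = noise.background_fraction * control_level
    total = clean * _lognormal_factor(rng, noise.cv, clean.shape) + bg * (
        _lognormal_factor(rng, noise.cv, clean.shape)
    )
    blank = bg * _lognormal_factor(rng, noise.cv, clean.shape)
    out = total - blank
    if noise.additive_floor > 0:
        out = out + rng.normal(
            0.0, noise.additive_floor * control_level, clean.shape
        )
    return out


def _tile_design(grid: Sequence[float], replicates: int) -> tuple[np.ndarray, np.ndarray]:
    conc = np.repeat(np.asarray(grid, dtype=float), replicates)
    rep = np.tile(np.arange(1, replicates + 1), len(grid))
    return conc, rep


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------


def gen_uptake_inhibition(
    ic50s_uM: Mapping[str, float],
    i_grid_uM: Sequence[float],
    noise: NoiseSpec,
) -> tuple[AssayDataset, GroundTruth]:
    """Uptake-inhibition plates: percent uptake vs inhibitor per condition.

    ``ic50s_uM`` maps condition labels (e.g. fixed 5-HT levels) to the true
    IC50; responses follow 100 / (1 + I/IC50) before noise.
    """
    if len(list(i_grid_uM)) == 0:
        raise ValueError("empty inhibitor grid")
    rng = noise.rng()
    frames = []
    for label, ic50 in ic50s_uM.items():
        conc, rep = _tile_design(i_grid_uM, noise.replicates)
        clean = 100.0 / (1.0 + conc / ic50)
        resp = _noisy_signal(rng, clean, 100.0, noise)
        frames.append(
            pd.DataFrame(
                {
                    "conc_uM": conc,
                    "response": resp,
                    "replicate": rep,
                    "condition": label,
                }
            )
        )
    data = pd.concat(frames, ignore_index=True)
    truth = GroundTruth(
        "uptake_inhibition",
        {"ic50s_uM": dict(ic50s_uM), "noise": asdict(noise)},
    )
    return AssayDataset("uptake_inhibition", data), truth


def gen_saturation(
    km_vmax_per_level: Mapping[str, tuple[float, float]],
    s_grid_uM: Sequence[float],
    noise: NoiseSpec,
) -> tuple[AssayDataset, GroundTruth]:
    """Saturation-uptake plates: velocity vs substrate per inhibitor level.

    ``km_vmax_per_level`` maps condition labels (inhibitor concentrations)
    to true ``(Km_uM, Vmax)``; responses follow Vmax*S/(S+Km) before noise.
    """
    if len(list(s_grid_uM)) == 0:
        raise ValueError("empty substrate grid")
    rng = noise.rng()
    control_vmax = max(v for _k, v in km_vmax_per_level.values())
    frames = []
    for label, (km, vmax) in km_vmax_per_level.items():
        conc, rep = _tile_design(s_grid_uM, noise.replicates)
        clean = vmax * conc / (conc + km)
        resp = _noisy_signal(rng, clean, control_vmax, noise)
        frames.append(
            pd.DataFrame(
                {
                    "conc_uM": conc,
                    "response": resp,
                    "replicate": rep,
                    "condition": label,
                }
            )
        )
    data = pd.concat(frames, ignore_index=True)
    truth = GroundTruth(
        "saturation",
        {
            "km_vmax_per_level": {
                k: list(v) for k, v in km_vmax_per_level.items()
            },
            "noise": asdict(noise),
        },
    )
    return AssayDataset("saturation", data), truth


def gen_binding_displacement(
    truth_params: Mapping[str, object],
    mode: str,
    i_grid_uM: Sequence[float],
    fixed_levels_uM: Sequence[float],
    noise: NoiseSpec,
    b0: float = 100.0,
) -> tuple[AssayDataset, GroundTruth]:
    """Radioligand displacement at several fixed second-ligand levels.

    ``mode="exclusive"`` (same-site competition): per level, bound follows
    ``B0(S) / (1 + I/IC50(S))`` with ``B0(S)`` scaled inversely to
    ``IC50(S)`` - the single-site competition law with a shared radioligand,
    which makes Dixon lines parallel with x-intercepts at -IC50(S).
    ``truth_params`` must carry ``ic50s_uM``: a mapping of fixed level ->
    IC50.

    ``mode="non_exclusive"`` (ternary complex, interaction factor 1): bound
    follows ``B0 / ((1 + I/Ki) (1 + S/Ks))``, so Dixon lines steepen with S
    and intersect at -Ki.  ``truth_params`` must carry ``ki_uM`` and
    ``ks_uM``.
    """
    if mode not in ("exclusive", "non_exclusive"):
        raise ValueError(f"invalid mode {mode!r}")
    rng = noise.rng()
    frames = []
    if mode == "exclusive":
        ic50s = {float(k): float(v) for k, v in truth_params["ic50s_uM"].items()}
        ic50_ref = min(ic50s.values())
        for level in fixed_levels_uM:
            ic50 = ic50s[float(level)]
            conc, rep = _tile_design(i_grid_uM, noise.replicates)
            clean = b0 * (ic50_ref / ic50) / (1.0 + conc / ic50)
            resp = _noisy_signal(rng, clean, b0, noise)
            frames.append(
                pd.DataFrame(
                    {
                        "conc_uM": conc,
                        "response": resp,
                        "replicate": rep,
                        "condition": f"S={level:g}",
                        "level_uM": float(level),
                    }
                )
            )
    else:
        ki = float(truth_params["ki_uM"])
        ks = float(truth_params["ks_uM"])
        for level in fixed_levels_uM:
            conc, rep = _tile_design(i_grid_uM, noise.replicates)
            clean = b0 / ((1.0 + conc / ki) * (1.0 + float(level) / ks))
            resp = _noisy_signal(rng, clean, b0, noise)
            frames.append(
                pd.DataFrame(
                    {
                        "conc_uM": conc,
                        "response": resp,
                        "replicate": rep,
                        "condition": f"S={level:g}",
                        "level_uM": float(level),
                    }
                )
            )
    data = pd.concat(frames, ignore_index=True)
    truth = GroundTruth(
        "binding_displacement",
        {"mode": mode, "params": dict(truth_params), "noise": asdict(noise)},
    )
    return AssayDataset("binding_displacement", data), truth


def gen_current_block(
    k_on: float,
    k_off: float,
    i_levels_uM: Sequence[float],
    noise: NoiseSpec,
    sample_rate_hz: float = 200.0,
    duration_s: float = 5.0,
    steady_current: float = -100.0,
) -> tuple[AssayDataset, GroundTruth]:
    """Current-block traces: mono-exponential onset per inhibitor level.

    The block develops at ``k_app = k_on * [I] + k_off`` (``k_on`` in
    M^-1 s^-1, ``[I]`` converted from micromolar) towards the equilibrium
    unblocked fraction ``k_off / k_app``.  Additive Gaussian noise of
    ``cv * |steady_current|`` emulates recording noise.  Requires
    ``sample_rate_hz >= 20 * max(k_app)``.
    """
    levels = [float(i) for i in i_levels_uM]
    if not levels:
        raise ValueError("need at least one inhibitor level")
    k_apps = [k_on * c * 1e-6 + k_off for c in levels]
    if sample_rate_hz < 20.0 * max(k_apps):
        raise ValueError(
            f"undersampled design: sample rate {sample_rate_hz:g} Hz < 20 x "
            f"max k_app ({max(k_apps):g} s^-1)"
        )
    rng = noise.rng()
    t = np.arange(0.0, duration_s, 1.0 / sample_rate_hz)
    frames = []
    for conc, k_app in zip(levels, k_apps):
        unblocked_inf = k_off / k_app
        for rep in range(1, noise.replicates + 1):
            clean = steady_current * (
                unblocked_inf + (1.0 - unblocked_inf) * np.exp(-k_app * t)
            )
            trace = clean + rng.normal(0.0, noise.cv * abs(steady_current), t.shape)
            frames.append(
                pd.DataFrame(
                    {
                        "time_s": t,
                        "response": trace,
                        "conc_uM": conc,
                        "replicate": rep,
                        "condition": f"I={conc:g}",
                    }
                )
            )
    data = pd.concat(frames, ignore_index=True)
    truth = GroundTruth(
        "current_block",
        {
            "k_on": k_on,
            "k_off": k_off,
            "k_app_per_level": dict(zip(map(str, levels), k_apps)),
            "noise": asdict(noise),
        },
    )
    return AssayDataset("current_block", data), truth
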