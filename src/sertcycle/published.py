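"""Reported experimental estimates for cocaine, noribogaine and ECSI#6.

These are the published pharmacological fit results for the three
reference inhibitors of SERT.  They are *inputs* to this package: ground
truths for the synthetic-data generators, targets for KD calibration and
fixtures for the inhibition-mode classifier.  They are not recomputed here.

Concentrations are micromolar; Vmax values are pmol min^-1 per 10^6 cells;
95% confidence intervals are given as (low, high) tuples.
"""

from __future__ import annotations

__all__ = [
    "ECSI6_UPTAKE_IC50_UM",
    "ECSI6_UPTAKE_IC50_CI_UM",
    "COCAINE_UPTAKE_IC50_UM",
    "NORIBOGAINE_UPTAKE_IC50_UM",
    "COCAINE_BINDING_IC50_UM",
    "SATURATION_SERIES",
    "ECSI6_CURRENT_BLOCK",
    "NORIBOGAINE_CURRENT_BLOCK",
]

#: Uptake-inhibition IC50s of ECSI#6 at fixed 5-HT concentrations
#: (5-HT_uM -> IC50_uM).  The calibration of KD(TiK) runs against this table.
ECSI6_UPTAKE_IC50_UM: dict[float, float] = {
    0.1: 440.5,
    1.0: 74.1,
    3.0: 25.6,
    10.0: 19.3,
}

#: 95% CIs of the same fits (5-HT_uM -> (low, high), micromolar).
ECSI6_UPTAKE_IC50_CI_UM: dict[float, tuple[float, float]] = {
    0.1: (325.8, 595.6),
    1.0: (55.4, 99.2),
    3.0: (19.1, 34.2),
    10.0: (13.2, 28.1),
}

#: Cocaine uptake-inhibition IC50s (competitive right-shift with 5-HT).
COCAINE_UPTAKE_IC50_UM: dict[float, float] = {0.1: 9.9, 1.0: 9.8, 10.0: 34.6}

#: Noribogaine uptake-inhibition IC50s (left-shift with 5-HT).
NORIBOGAINE_UPTAKE_IC50_UM: dict[float, float] = {0.1: 5.7, 1.0: 2.4, 10.0: 1.9}

#: Radioligand-displacement IC50s of cocaine at fixed 5-HT levels
#: (5-HT_uM -> IC50_uM); the classic mutually-exclusive Dixon pattern.
COCAINE_BINDING_IC50_UM: dict[float, float] = {0.0: 0.66, 1.0: 0.94, 10.0: 2.48}

#: Saturation-uptake fit series per inhibitor: inhibitor levels (uM), apparent
#: Km (uM) and Vmax with 95% CIs, the control (level 0) first.  Note the Km CI
#: printed for the highest cocaine level does not bracket its estimate in the
#: source report (an evident misprint); it is carried verbatim.
SATURATION_SERIES: dict[str, dict[str, tuple]] = {
    "cocaine": {
        "levels_uM": (0.0, 3.0, 10.0, 30.0),
        "km_uM": (2.3, 2.2, 3.7, 8.1),
        "km_ci": ((1.5, 3.2), (1.1, 3.3), (1.9, 5.5), (1.9, 5.5)),
        "vmax": (137.3, 118.3, 121.1, 120.1),
        "vmax_ci": (
            (117.4, 157.3),
            (117.4, 157.3),
            (105.5, 136.8),
            (104.6, 135.6),
        ),
    },
    "noribogaine": {
        "levels_uM": (0.0, 1.0, 3.0, 10.0),
        "km_uM": (2.3, 2.4, 1.9, 2.4),
        "km_ci": ((1.5, 3.2), (1.4, 3.5), (0.6, 3.3), (0.6, 5.5)),
        "vmax": (137.3, 82.4, 39.9, 19.5),
        "vmax_ci": (
            (117.4, 157.3),
            (69.3, 95.4),
            (30.6, 49.2),
            (13.9, 24.9),
        ),
    },
    "ecsi6": {
        "levels_uM": (0.0, 10.0, 30.0, 100.0),
        "km_uM": (2.3, 1.7, 1.1, 0.4),
        "km_ci": ((1.5, 3.2), (0.5, 2.9), (0.2, 1.9), (0.0, 0.8)),
        "vmax": (137.3, 89.5, 49.9, 20.8),
        "vmax_ci": (
            (117.4, 157.3),
            (68.5, 110.0),
            (37.5, 62.3),
            (15.6, 26.0),
        ),
    },
}

#: Current-block kinetics (slope/intercept of k_app vs concentration):
#: k_on in M^-1 s^-1 with SE, k_off in s^-1 with SE.
ECSI6_CURRENT_BLOCK = {"k_on": 2.1e4, "k_on_se": 3.5e3, "k_off": 1.7, "k_off_se": 0.5}
NORIBOGAINE_CURRENT_BLOCK = {
    "k_on": 1.7e5,
    "k_on_se": 1.6e4,
    "k_off": 1.4,
    "k_off_se": 0.3,
}
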