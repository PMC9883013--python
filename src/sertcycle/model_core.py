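"""Kinetic model of the serotonin-transporter (SERT) transport cycle.

The transporter is described as a continuous-time Markov chain over eight
conformational/binding states arranged in a single closed cycle::

    To -> ToNa -> ToNaS -> TiNaS -> TiS -> Ti -> TiK -> ToK -> To

``To``/``Ti`` denote the outward-/inward-facing apo transporter; suffixes
``Na``, ``S`` and ``K`` denote bound sodium, substrate (5-HT) and potassium.
Extracellular Na+ and then substrate bind on the outward side, the loaded
transporter isomerizes, Na+ and then substrate are released inside, K+ binds
inside and the K+-bound transporter returns to the outward face where K+ is
released.  All bimolecular steps are reversible and become pseudo-first-order
by multiplying the relevant ligand concentration on the relevant side of the
membrane; the four isomerizations carry their own first-order rates.

An inhibitor may be attached to any subset of cycle states as a *dead end*:
an inhibitor-bound companion state reachable only by inhibitor association
(``kon_I * I_out``) and dissociation (``koff_I = KD * kon_I``).  While the
inhibitor is bound, no transport-cycle transition proceeds - this encodes
mutually exclusive binding of inhibitor and substrate at the orthosteric site
(and, for the loaded ToNaS/TiNaS states, a dead-end allosteric complex).

Internal units are molar and seconds throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import linalg
from scipy.integrate import solve_ivp

__all__ = [
    "CYCLE_STATES",
    "RateConstantSet",
    "LigandConditions",
    "InhibitorScheme",
    "Transition",
    "TransportCycleModel",
    "OccupancyTrajectory",
    "build_sert_cycle",
    "extend_with_inhibitor",
    "assemble_rate_matrix",
    "integrate",
    "steady_state",
    "steady_state_flux",
    "uptake_rate",
]

#: The eight inhibitor-free cycle states, in cycle order.
CYCLE_STATES = ("To", "ToNa", "ToNaS", "TiNaS", "TiS", "Ti", "TiK", "ToK")

#: Suffix marking a dead-end inhibitor-bound companion state.
INHIBITOR_SUFFIX = "*I"

#: Occupancies are clipped to zero down to this threshold; anything more
#: negative coming out of a linear solve is treated as a genuine failure.
NEGATIVE_OCCUPANCY_TOLERANCE = -1e-12


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RateConstantSet:
    """Microscopic rate constants of the transport cycle.

    Defaults are the published parameterization of the model.  Bimolecular
    association constants are in M^-1 s^-1, everything else in s^-1.  The same
    kon/koff pair describes a ligand's binding on either side of the membrane
    (the model carries one constant per ligand).
    """

    kon_K: float = 1e6
    koff_K: float = 5000.0
    kon_Na: float = 1e6
    koff_Na: float = 1000.0
    kon_S: float = 1e7
    koff_S: float = 500.0
    k_ToNaS_TiNaS: float = 60.0
    k_TiNaS_ToNaS: float = 75.0
    k_TiK_ToK: float = 5.0
    k_ToK_TiK: float = 4.0

    def __post_init__(self) -> None:
        for name, value in self.__dict__.items():
            if not (value > 0 and np.isfinite(value)):
                raise ValueError(
                    f"rate constant {name!r} must be strictly positive and "
                    f"finite, got {value!r}"
                )


@dataclass(frozen=True)
class LigandConditions:
    """Fixed ligand concentrations (molar) on both sides of the membrane.

    Defaults emulate a cellular uptake experiment: Krebs-HEPES-like bath
    (120 mM Na+, 3 mM K+) outside, K+-rich/low-Na+ cytosol inside, no
    intracellular substrate and extracellular inhibitor only.
    """

    Na_out: float = 120e-3
    K_out: float = 3e-3
    S_out: float = 0.0
    Na_in: float = 6e-3
    K_in: float = 133e-3
    S_in: float = 0.0
    I_out: float = 0.0
    I_in: float = 0.0

    def __post_init__(self) -> None:
        for name, value in self.__dict__.items():
            if value < 0 or not np.isfinite(value):
                raise ValueError(
                    f"concentration {name!r} must be non-negative and finite, "
                    f"got {value!r}"
                )

    @classmethod
    def from_micromolar(cls, **concentrations_uM: float) -> "LigandConditions":
        """Build conditions from micromolar values (user-facing unit)."""
        return cls(**{k: v * 1e-6 for k, v in concentrations_uM.items()})

    def with_(self, **changes: float) -> "LigandConditions":
        return replace(self, **changes)


@dataclass(frozen=True)
class InhibitorScheme:
    """State-selective inhibitor binding: which states, how tightly.

    ``kd_per_state`` maps cycle-state names to dissociation constants (molar).
    All states share one association rate ``kon_I``; the per-state
    dissociation rate is derived as ``koff_I = KD * kon_I`` so that
    koff/kon reproduces the requested KD exactly.
    """

    name: str
    kd_per_state: Mapping[str, float]
    kon_I: float = 1e6

    def __post_init__(self) -> None:
        if not self.kd_per_state:
            raise ValueError("inhibitor scheme needs at least one target state")
        if not (self.kon_I > 0 and np.isfinite(self.kon_I)):
            raise ValueError(f"kon_I must be positive, got {self.kon_I!r}")
        for state, kd in self.kd_per_state.items():
            if state not in CYCLE_STATES:
                raise ValueError(
                    f"unknown target state {state!r}; valid states are "
                    f"{CYCLE_STATES}"
                )
            if not (kd > 0 and np.isfinite(kd)):
                raise ValueError(f"KD for state {state!r} must be positive")
        object.__setattr__(self, "kd_per_state", dict(self.kd_per_state))

    @property
    def target_states(self) -> tuple[str, ...]:
        return tuple(self.kd_per_state)

    def koff_I(self, state: str) -> float:
        return self.kd_per_state[state] * self.kon_I


@dataclass(frozen=True)
class Transition:
    """One directed reaction step.

    ``ligand`` / ``side`` name the concentration that multiplies ``rate`` for
    a bimolecular association (pseudo-first-order regime); both are ``None``
    for conformational steps and unimolecular dissociations.
    """

    source: str
    target: str
    rate: float
    ligand: str | None = None
    side: str | None = None

    def pseudo_first_order_rate(self, conditions: LigandConditions) -> float:
        if self.ligand is None:
            return self.rate
        attr = f"{self.ligand}_{self.side}"
        try:
            concentration = getattr(conditions, attr)
        except AttributeError:
            raise ValueError(
                f"conditions lack concentration {attr!r} required by "
                f"transition {self.source}->{self.target}"
            ) from None
        return self.rate * concentration


@dataclass(frozen=True)
class TransportCycleModel:
    """States, transitions and parameterization of one model instance."""

    states: tuple[str, ...]
    transitions: tuple[Transition, ...]
    rates: RateConstantSet
    conditions: LigandConditions
    inhibitor: InhibitorScheme | None = None

    def __post_init__(self) -> None:
        known = set(self.states)
        for t in self.transitions:
            if t.source not in known or t.target not in known:
                raise ValueError(
                    f"transition {t.source}->{t.target} references a state "
                    "missing from the model"
                )

    @property
    def n_states(self) -> int:
        return len(self.states)

    def state_index(self, name: str) -> int:
        return self.states.index(name)

    def with_conditions(self, **changes: float) -> "TransportCycleModel":
        """Copy of the model with some ligand concentrations replaced."""
        return replace(self, conditions=self.conditions.with_(**changes))


@dataclass(frozen=True)
class OccupancyTrajectory:
    """Time-resolved (or steady) state occupancies.

    ``occupancy`` has shape (n_times, n_states); every row sums to 1.
    """

    times: np.ndarray
    occupancy: np.ndarray
    states: tuple[str, ...]
    steady: bool = False

    def __post_init__(self) -> None:
        occ = np.asarray(self.occupancy, dtype=float)
        if occ.ndim != 2 or occ.shape[1] != len(self.states):
            raise ValueError("occupancy must be (n_times, n_states)")
        row_sums = occ.sum(axis=1)
        if not np.allclose(row_sums, 1.0, atol=1e-8):
            worst = float(np.abs(row_sums - 1.0).max())
            raise ValueError(f"occupancy rows must sum to 1 (max dev {worst:g})")
        if occ.min() < NEGATIVE_OCCUPANCY_TOLERANCE or occ.max() > 1 + 1e-8:
            raise ValueError("occupancies must lie in [0, 1]")

    def state_series(self, name: str) -> np.ndarray:
        return self.occupancy[:, self.states.index(name)]

    def final(self) -> np.ndarray:
        return self.occupancy[-1]


# ---------------------------------------------------------------------------
# model construction
# ---------------------------------------------------------------------------


def build_sert_cycle(
    rates: RateConstantSet | None = None,
    conditions: LigandConditions | None = None,
) -> TransportCycleModel:
    """Assemble the eight-state SERT cycle.

    Binding order is sequential: Na+ before substrate outside, Na+ released
    before substrate inside.  Returns a model with 16 directed transitions
    (each of the eight steps is reversible).
    """
    rates = rates if rates is not None else RateConstantSet()
    conditions = conditions if conditions is not None else LigandConditions()
    r = rates
    transitions = (
        # extracellular Na+ binding
        Transition("To", "ToNa", r.kon_Na, "Na", "out"),
        Transition("ToNa", "To", r.koff_Na),
        # extracellular substrate binding
        Transition("ToNa", "ToNaS", r.kon_S, "S", "out"),
        Transition("ToNaS", "ToNa", r.koff_S),
        # translocation of the loaded transporter
        Transition("ToNaS", "TiNaS", r.k_ToNaS_TiNaS),
        Transition("TiNaS", "ToNaS", r.k_TiNaS_ToNaS),
        # intracellular Na+ release (Na+ leaves before substrate)
        Transition("TiNaS", "TiS", r.koff_Na),
        Transition("TiS", "TiNaS", r.kon_Na, "Na", "in"),
        # intracellular substrate release
        Transition("TiS", "Ti", r.koff_S),
        Transition("Ti", "TiS", r.kon_S, "S", "in"),
        # intracellular K+ binding
        Transition("Ti", "TiK", r.kon_K, "K", "in"),
        Transition("TiK", "Ti", r.koff_K),
        # return step of the K+-bound transporter (rate-limiting)
        Transition("TiK", "ToK", r.k_TiK_ToK),
        Transition("ToK", "TiK", r.k_ToK_TiK),
        # extracellular K+ release
        Transition("ToK", "To", r.koff_K),
        Transition("To", "ToK", r.kon_K, "K", "out"),
    )
    return TransportCycleModel(CYCLE_STATES, transitions, rates, conditions)


def extend_with_inhibitor(
    model: TransportCycleModel, scheme: InhibitorScheme
) -> TransportCycleModel:
    """Attach one dead-end inhibitor-bound companion per target state.

    Association runs at ``kon_I * I_out`` (the inhibitor is extracellular in
    all emulated assays), dissociation at ``KD * kon_I``.  The original cycle
    is untouched; with ``I_out = 0`` the extension is a no-op at steady state.
    """
    if model.inhibitor is not None:
        raise ValueError("model already carries an inhibitor scheme")
    for state in scheme.target_states:
        if state not in model.states:
            raise ValueError(f"target state {state!r} not present in model")
        if INHIBITOR_SUFFIX in state:
            raise ValueError(f"state {state!r} is already inhibitor-bound")
    new_states = model.states + tuple(
        s + INHIBITOR_SUFFIX for s in scheme.target_states
    )
    new_transitions = list(model.transitions)
    for state in scheme.target_states:
        bound = state + INHIBITOR_SUFFIX
        new_transitions.append(Transition(state, bound, scheme.kon_I, "I", "out"))
        new_transitions.append(Transition(bound, state, scheme.koff_I(state)))
    return TransportCycleModel(
        new_states, tuple(new_transitions), model.rates, model.conditions, scheme
    )


# ---------------------------------------------------------------------------
# solving
# ---------------------------------------------------------------------------


def assemble_rate_matrix(model: TransportCycleModel) -> np.ndarray:
    """Generator matrix Q of the master equation dp/dt = Q p.

    Entry Q[i, j] (i != j) is the pseudo-first-order rate of the j -> i
    transition at the model's fixed ligand concentrations; diagonal entries
    make every column sum to zero (probability conservation).
    """
    n = model.n_states
    index = {s: i for i, s in enumerate(model.states)}
    Q = np.zeros((n, n))
    for t in model.transitions:
        k = t.pseudo_first_order_rate(model.conditions)
        i, j = index[t.target], index[t.source]
        Q[i, j] += k
        Q[j, j] -= k
    return Q


def steady_state(model: TransportCycleModel) -> np.ndarray:
    """Stationary occupancy vector of the master equation.

    Solves the null-space problem Q p = 0 with the normalization sum(p) = 1
    appended as an extra equation (least squares on the stacked system,
    which stays well behaved even when a deeply trapped inhibitor pool
    makes the relaxation spectrum nearly degenerate).  A transition graph
    that splits into disconnected components has no unique stationary
    distribution and is rejected with the components named.
    """
    components = _connected_components(model)
    if len(components) > 1:
        raise ValueError(
            "stationary distribution is not unique; the transition graph "
            f"splits into components {components}"
        )
    Q = assemble_rate_matrix(model)
    n = model.n_states
    # states without any inflow are transient: exactly unpopulated at steady
    # state.  Prune them (repeatedly, for chains) so the linear solve cannot
    # smear numerical noise onto them - e.g. inhibitor-bound states at
    # I_out = 0.
    keep = np.ones(n, dtype=bool)
    while True:
        off_diag = Q[np.ix_(keep, keep)].copy()
        np.fill_diagonal(off_diag, 0.0)
        inflow = off_diag.sum(axis=1)
        dead = inflow <= 0
        if not dead.any() or dead.all():
            break
        kept_idx = np.flatnonzero(keep)
        keep[kept_idx[dead]] = False
    Qr = Q[np.ix_(keep, keep)]
    # the pruned sub-generator: outflow towards pruned states is irrelevant
    # at steady state, so re-set the diagonal to conserve within the kept set
    np.fill_diagonal(Qr, 0.0)
    np.fill_diagonal(Qr, -Qr.sum(axis=0))
    m = Qr.shape[0]
    scale = np.abs(Qr).max()
    A = np.vstack([Qr / scale, np.ones((1, m))])
    b = np.zeros(m + 1)
    b[-1] = 1.0
    pr, *_ = np.linalg.lstsq(A, b, rcond=None)
    for _ in range(2):  # iterative refinement sharpens tiny occupancies
        correction, *_ = np.linalg.lstsq(A, b - A @ pr, rcond=None)
        pr = pr + correction
    p = np.zeros(n)
    p[keep] = pr
    residual = np.abs(Qr @ pr).max() / scale
    if residual > 1e-8:
        raise ValueError(
            f"steady-state solve left a relative residual of {residual:g}"
        )
    p = p / p.sum()
    if p.min() < NEGATIVE_OCCUPANCY_TOLERANCE:
        raise ValueError(
            f"steady-state solve produced occupancy {p.min():g} below the "
            "numerical tolerance"
        )
    return np.clip(p, 0.0, 1.0)


def _connected_components(model: TransportCycleModel) -> list[list[str]]:
    """Undirected components of the transition graph (for error messages)."""
    adjacency: dict[str, set[str]] = {s: set() for s in model.states}
    for t in model.transitions:
        if t.pseudo_first_order_rate(model.conditions) > 0:
            adjacency[t.source].add(t.target)
            adjacency[t.target].add(t.source)
    seen: set[str] = set()
    components = []
    for start in model.states:
        if start in seen:
            continue
        stack, comp = [start], []
        while stack:
            s = stack.pop()
            if s in seen:
                continue
            seen.add(s)
            comp.append(s)
            stack.extend(adjacency[s] - seen)
        components.append(sorted(comp))
    return components


def integrate(
    model: TransportCycleModel,
    t_grid: Sequence[float],
    initial: Sequence[float] | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> OccupancyTrajectory:
    """Integrate the master equation over ``t_grid`` (seconds).

    Uses a stiff-capable implicit solver; the system is stiff because ion
    binding (1e5-1e6 s^-1 pseudo-rates) coexists with the ~5 s^-1 return
    step.  ``initial`` defaults to all mass in the outward-facing apo state.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or len(t_grid) < 2 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be strictly increasing with >= 2 points")
    n = model.n_states
    if initial is None:
        p0 = np.zeros(n)
        p0[model.state_index("To")] = 1.0
    else:
        p0 = np.asarray(initial, dtype=float)
        if p0.shape != (n,):
            raise ValueError(f"initial occupancy must have length {n}")
        if not np.isclose(p0.sum(), 1.0, atol=1e-8) or p0.min() < 0:
            raise ValueError("initial occupancy must be a probability vector")
    Q = assemble_rate_matrix(model)
    sol = solve_ivp(
        lambda _t, p: Q @ p,
        (t_grid[0], t_grid[-1]),
        p0,
        t_eval=t_grid,
        method="BDF",
        jac=lambda _t, _p: Q,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise RuntimeError(
            f"ODE integration failed over t=[{t_grid[0]:g}, {t_grid[-1]:g}] s: "
            f"{sol.message}"
        )
    occ = sol.y.T
    # renormalize away solver drift (conservation is enforced to 1e-8 by the
    # trajectory container)
    occ = np.clip(occ, 0.0, None)
    occ = occ / occ.sum(axis=1, keepdims=True)
    return OccupancyTrajectory(t_grid, occ, model.states)


def uptake_rate(
    occupancy: Sequence[float] | np.ndarray, model: TransportCycleModel
) -> float | np.ndarray:
    """Net inward substrate flux per transporter (s^-1).

    flux = occ(TiS) * koff_S - occ(Ti) * kon_S * S_in: intracellular substrate
    release minus rebinding.  Accepts a single occupancy vector or a
    trajectory matrix (flux per row).
    """
    occ = np.asarray(occupancy, dtype=float)
    i_tis = model.state_index("TiS")
    i_ti = model.state_index("Ti")
    r, c = model.rates, model.conditions
    return occ[..., i_tis] * r.koff_S - occ[..., i_ti] * r.kon_S * c.S_in


def steady_state_flux(model: TransportCycleModel) -> float:
    """Convenience: substrate flux at the stationary distribution."""
    return float(uptake_rate(steady_state(model), model))
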