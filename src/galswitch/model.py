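"""Deterministic ODE models of the yeast GAL switch and their dynamical analyses.

The circuit couples a positive feedback loop (galactose-activated Gal1p, G1*,
sequesters the repressor Gal80p and thereby frees the activator Gal4p, which
drives further *GAL1* expression) to a negative feedback loop (Gal4p also
drives *GAL80* expression) and to catabolite repression (a glucose-activated
repressor R* shuts down the *GAL1* and *GAL4* promoters).  Protein-protein
sequestration is treated as a fast binding equilibrium, so the dynamical state
is the total concentrations (G1_T, G80_T, G4_T) plus the active repressor R*.

Three variants are provided:

``repressor``
    the reference model: glucose acts through the repressor R*.
``gal80_open_loop``
    *GAL80* expression decoupled from Gal4p (constitutive production).
``dilution``
    no repressor; glucose instead scales the first-order decay (dilution)
    rate of every species.

All concentrations are in nM and all times in hours.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root
from scipy.stats import qmc

__all__ = [
    "SpeciesState",
    "AlgebraicState",
    "StateDerivative",
    "ModelParams",
    "SugarSchedule",
    "Equilibrium",
    "Trajectory",
    "BifurcationDiagram",
    "RegimeMap",
    "MONO_ON",
    "MONO_OFF",
    "BISTABLE",
    "default_params",
    "reduced_inputs",
    "rhs",
    "simulate",
    "find_equilibria",
    "jacobian",
    "dominant_eigenvalue",
    "basin_fraction_on",
    "bifurcation_scan",
    "regime_map",
    "quasi_static_regimes",
    "delta_b",
]

MONO_ON = "mono_ON"
MONO_OFF = "mono_OFF"
BISTABLE = "bistable"

VARIANTS = ("repressor", "dilution", "gal80_open_loop")


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class SpeciesState:
    """Total species concentrations (nM): G1_T, G80_T, G4_T and active repressor R*."""

    g1_total: float
    g80_total: float
    g4_total: float
    r_active: float = 0.0

    def __post_init__(self):
        vals = (self.g1_total, self.g80_total, self.g4_total, self.r_active)
        if not all(np.isfinite(v) for v in vals):
            raise ValueError("species concentrations must be finite")
        if any(v < 0 for v in vals):
            raise ValueError("species concentrations must be nonnegative")

    def as_array(self, dim: int = 4) -> np.ndarray:
        v = [self.g1_total, self.g80_total, self.g4_total, self.r_active]
        return np.asarray(v[:dim], dtype=float)

    @staticmethod
    def from_array(y: np.ndarray) -> "SpeciesState":
        y = np.asarray(y, dtype=float)
        r = float(y[3]) if y.size > 3 else 0.0
        return SpeciesState(float(y[0]), float(y[1]), float(y[2]), max(r, 0.0))


@dataclass(frozen=True)
class StateDerivative:
    """Time derivative of a :class:`SpeciesState`, nM/h per field."""

    g1_total: float
    g80_total: float
    g4_total: float
    r_active: float = 0.0

    def as_array(self, dim: int = 4) -> np.ndarray:
        v = [self.g1_total, self.g80_total, self.g4_total, self.r_active]
        return np.asarray(v[:dim], dtype=float)


@dataclass(frozen=True)
class AlgebraicState:
    """Fast-equilibrium quantities: activated Gal1p (G1*), free Gal80p, free Gal4p."""

    g1_star: float
    g80_free: float
    g4_free: float


@dataclass
class ModelParams:
    """Kinetic parameters of the GAL ODE model (nM, 1/h).

    ``alpha*``/``b*`` are maximal and basal production rates, ``d`` the
    first-order decay rate shared by all species.  ``k_a``/``n_a`` set the
    activation of the *GAL* promoters by free Gal4p; ``k_r1``/``k_r4``/``n_r``
    the repression of the *GAL1* and *GAL4* promoters by active repressor R*;
    ``k_gal``/``m`` the galactose dependence of Gal1p activation;
    ``k_seq80``/``k_seq4`` the G1*-G80 and G4-G80 sequestration dissociation
    constants; ``k_r``/``k_rd``/``r_total`` the glucose-driven repressor
    activation cycle.  Variant-specific fields (``g80_const``; ``s1``,
    ``s80``, ``s4``, ``k_g``, ``n_g``) are ignored when inapplicable.
    """

    alpha1: float = 500.0
    alpha80: float = 12.0
    alpha4: float = 16.0
    b1: float = 1.0
    b80: float = 8.0
    b4: float = 3.2
    d: float = 0.4
    k_a: float = 4.0
    n_a: float = 2.0
    k_r1: float = 64.64
    k_r4: float = 32.48
    n_r: float = 2.0
    k_gal: float = 150.0
    m: float = 2.0
    k_seq80: float = 0.15
    k_seq4: float = 0.15
    k_r: float = 0.02
    k_rd: float = 1.0
    r_total: float = 350.0
    variant: str = "repressor"
    # gal80_open_loop variant: constitutive GAL80 production (nM/h)
    g80_const: float = 0.0
    # dilution variant: per-species dilution scaling and glucose threshold
    s1: float = 2.0
    s80: float = 2.0
    s4: float = 2.0
    k_g: float = 100.0
    n_g: float = 2.0
    # ON/OFF call for a lone stable equilibrium when no bistable reference
    # branch is available (nM of G1_T)
    g1_on_threshold: float = 40.0

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(
                f"unknown variant {self.variant!r}; expected one of {VARIANTS}"
            )
        positive = {
            "alpha1": self.alpha1, "alpha80": self.alpha80, "alpha4": self.alpha4,
            "d": self.d, "k_a": self.k_a, "k_r1": self.k_r1, "k_r4": self.k_r4,
            "k_gal": self.k_gal, "k_seq80": self.k_seq80, "k_seq4": self.k_seq4,
            "k_r": self.k_r, "k_rd": self.k_rd, "r_total": self.r_total,
            "k_g": self.k_g,
        }
        for name, v in positive.items():
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"parameter {name} must be positive, got {v}")
        for name, v in (("b1", self.b1), ("b80", self.b80), ("b4", self.b4),
                        ("g80_const", self.g80_const)):
            if not (np.isfinite(v) and v >= 0):
                raise ValueError(f"parameter {name} must be >= 0, got {v}")
        for name, v in (("n_a", self.n_a), ("n_r", self.n_r), ("m", self.m),
                        ("n_g", self.n_g)):
            if not (np.isfinite(v) and v >= 1):
                raise ValueError(f"Hill coefficient {name} must be >= 1, got {v}")

    @property
    def dim(self) -> int:
        return 3 if self.variant == "dilution" else 4

    def state_bounds(self) -> np.ndarray:
        """Per-species sampling bounds, (dim, 2): production/decay balance caps
        reachable totals at (alpha_i + b_i)/d; a 2x margin is applied."""
        hi = [
            2.0 * (self.alpha1 + self.b1) / self.d,
            2.0 * (max(self.alpha80, self.g80_const) + self.b80) / self.d,
            2.0 * (self.alpha4 + self.b4) / self.d,
        ]
        if self.dim == 4:
            hi.append(self.r_total)
        return np.array([[0.0, h] for h in hi])

    def replace(self, **kw) -> "ModelParams":
        return dataclasses.replace(self, **kw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown parameter fields: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "ModelParams":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def default_params(variant: str = "repressor") -> ModelParams:
    """Reference parameter set for a model variant.

    The repressor variant exhibits a bistable glucose band at intermediate
    galactose (e.g. 150 nM); the perturbed-affinity set used in sensitivity
    analyses corresponds to ``k_r1``/``k_r4`` scaled by 1.25 (a 20% reduction
    in repressor-promoter affinity, giving K_R1 = 80.8 nM, K_R4 = 40.6 nM).
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
    p = ModelParams()
    if variant == "gal80_open_loop":
        # constitutive GAL80 production tuned so the OFF-state G80_T sits at
        # ~40% of the fully induced wild-type level (alpha80 + b80)/d
        p = p.replace(variant=variant, g80_const=0.4 * (p.alpha80 + p.b80))
    elif variant == "dilution":
        p = p.replace(variant=variant)
    return p


# --------------------------------------------------------------------------
# schedules
# --------------------------------------------------------------------------


@dataclass
class SugarSchedule:
    """Extracellular glucose/galactose input as a function of time.

    ``events`` is a list of ``(time_h, glucose_add, galactose_add)`` step
    additions.  Each sugar optionally decays exponentially (``*_decay_rate``,
    1/h) from the moment it is added, or follows a tabulated trajectory
    ``(times, values)`` that overrides the event-based construction for that
    sugar.  ``t0`` marks the stimulus time used by downstream timing metrics.
    """

    events: Sequence[tuple] = field(default_factory=list)
    glu_decay_rate: Optional[float] = None
    gal_decay_rate: Optional[float] = None
    glu_table: Optional[tuple] = None  # (t array, conc array)
    gal_table: Optional[tuple] = None
    t0: float = 0.0

    def __post_init__(self):
        times = [e[0] for e in self.events]
        if any(t2 < t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("event times must be non-decreasing")
        for e in self.events:
            if e[1] < 0 or e[2] < 0:
                raise ValueError("sugar additions must be nonnegative")

    def _eval(self, t, which: int, rate, table):
        t = np.asarray(t, dtype=float)
        if table is not None:
            tt, vv = np.asarray(table[0], float), np.asarray(table[1], float)
            return np.maximum(np.interp(t, tt, vv), 0.0)
        out = np.zeros_like(t, dtype=float)
        k = 0.0 if rate is None else float(rate)
        for (te, gadd, galadd) in self.events:
            add = (gadd, galadd)[which - 1]
            if add <= 0:
                continue
            dt = t - te
            out = out + np.where(dt >= 0, add * np.exp(-k * np.maximum(dt, 0.0)), 0.0)
        return np.maximum(out, 0.0)

    def glu(self, t):
        return self._eval(t, 1, self.glu_decay_rate, self.glu_table)

    def gal(self, t):
        return self._eval(t, 2, self.gal_decay_rate, self.gal_table)

    @staticmethod
    def constant(glu: float, gal: float, t0: float = 0.0) -> "SugarSchedule":
        return SugarSchedule(events=[(min(0.0, t0), glu, gal)], t0=t0)


# --------------------------------------------------------------------------
# fast sequestration equilibrium
# --------------------------------------------------------------------------


def hill_act(x, k, n):
    """Activating Hill function x^n / (k^n + x^n), safe at x = 0."""
    x = np.maximum(np.asarray(x, dtype=float), 0.0)
    xn = (x / k) ** n
    return xn / (1.0 + xn)


def hill_rep(x, k, n):
    """Repressing Hill function k^n / (k^n + x^n)."""
    x = np.maximum(np.asarray(x, dtype=float), 0.0)
    xn = (x / k) ** n
    return 1.0 / (1.0 + xn)


def _free_g80(g1_star, g80_total, g4_total, k80, k4, iters: int = 70):
    """Free Gal80p from the two competing binding equilibria.

    Solves  x + A x/(k80 + x) + C x/(k4 + x) = B  for x = [G80]_free, where
    A = G1* and C = G4_T compete for B = G80_T.  The left side is strictly
    increasing in x, so the root in [0, B] is unique; it is found by
    vectorized bisection (relative precision ~2^-iters).
    """
    a, b, c = np.broadcast_arrays(
        np.maximum(g1_star, 0.0), np.maximum(g80_total, 0.0), np.maximum(g4_total, 0.0)
    )
    lo = np.zeros_like(b, dtype=float)
    hi = np.array(b, dtype=float, copy=True)
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        f = mid + a * mid / (k80 + mid) + c * mid / (k4 + mid) - b
        take_hi = f > 0
        hi = np.where(take_hi, mid, hi)
        lo = np.where(take_hi, lo, mid)
    return 0.5 * (lo + hi)


def reduced_inputs(
    state: SpeciesState, params: ModelParams, glu: float, gal: float
) -> AlgebraicState:
    """Fast-equilibrium reduction: G1*, free Gal80p and free Gal4p.

    Galactose converts a Hill fraction of total Gal1p to its activated form
    G1*; G1* and Gal4p then compete for Gal80p with dissociation constants
    ``k_seq80`` and ``k_seq4``.
    """
    if glu < 0 or gal < 0:
        raise ValueError("sugar concentrations must be nonnegative")
    g1s = state.g1_total * float(hill_act(gal, params.k_gal, params.m))
    bfree = float(
        _free_g80(g1s, state.g80_total, state.g4_total, params.k_seq80, params.k_seq4)
    )
    g4f = state.g4_total * params.k_seq4 / (params.k_seq4 + bfree)
    return AlgebraicState(g1_star=g1s, g80_free=bfree, g4_free=g4f)


# --------------------------------------------------------------------------
# vector field
# --------------------------------------------------------------------------


def _rhs_core(y: np.ndarray, p: ModelParams, glu, gal) -> np.ndarray:
    """Vectorized right-hand side; y has shape (..., dim)."""
    y = np.asarray(y, dtype=float)
    yc = np.maximum(y, 0.0)  # nonlinear terms see clipped state
    g1, g80, g4 = yc[..., 0], yc[..., 1], yc[..., 2]
    g1s = g1 * hill_act(gal, p.k_gal, p.m)
    bfree = _free_g80(g1s, g80, g4, p.k_seq80, p.k_seq4)
    g4f = g4 * p.k_seq4 / (p.k_seq4 + bfree)
    act = hill_act(g4f, p.k_a, p.n_a)

    if p.variant == "dilution":
        hg = hill_act(glu, p.k_g, p.n_g)
        dg1 = p.b1 + p.alpha1 * act - p.d * (1.0 + p.s1 * hg) * y[..., 0]
        dg80 = p.b80 + p.alpha80 * act - p.d * (1.0 + p.s80 * hg) * y[..., 1]
        dg4 = p.b4 + p.alpha4 - p.d * (1.0 + p.s4 * hg) * y[..., 2]
        return np.stack([dg1, dg80, dg4], axis=-1)

    r = yc[..., 3]
    rep1 = hill_rep(r, p.k_r1, p.n_r)
    rep4 = hill_rep(r, p.k_r4, p.n_r)
    dg1 = p.b1 + p.alpha1 * act * rep1 - p.d * y[..., 0]
    if p.variant == "gal80_open_loop":
        dg80 = p.g80_const - p.d * y[..., 1]
    else:
        dg80 = p.b80 + p.alpha80 * act - p.d * y[..., 1]
    dg4 = p.b4 + p.alpha4 * rep4 - p.d * y[..., 2]
    dr = p.k_r * glu * (p.r_total - r) - p.k_rd * y[..., 3]
    return np.stack([dg1, dg80, dg4, dr], axis=-1)


def rhs(
    state: SpeciesState, params: ModelParams, glu: float, gal: float
) -> StateDerivative:
    """Time derivative of the state at constant sugar inputs (nM/h)."""
    y = state.as_array(params.dim)
    if not np.all(np.isfinite(y)):
        raise ValueError("state must be finite")
    dy = _rhs_core(y, params, glu, gal)
    if params.dim == 3:
        return StateDerivative(float(dy[0]), float(dy[1]), float(dy[2]), 0.0)
    return StateDerivative(*map(float, dy))


# --------------------------------------------------------------------------
# simulation
# --------------------------------------------------------------------------


@dataclass
class Trajectory:
    """Result of :func:`simulate`: states over ``t`` plus the G1_T readout."""

    t: np.ndarray
    states: np.ndarray  # (len(t), dim)
    params: ModelParams

    @property
    def g1_total(self) -> np.ndarray:
        return self.states[:, 0]

    def state_at(self, i: int) -> SpeciesState:
        return SpeciesState.from_array(np.maximum(self.states[i], 0.0))

    def to_frame(self):
        import pandas as pd

        names = ["g1_total", "g80_total", "g4_total", "r_active"][: self.params.dim]
        rows = []
        for j, name in enumerate(names):
            rows.append(
                pd.DataFrame({"t": self.t, "variable": name, "value": self.states[:, j]})
            )
        return pd.concat(rows, ignore_index=True)


def simulate(
    params: ModelParams,
    schedule: SugarSchedule,
    state0: SpeciesState,
    t_grid: np.ndarray,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> Trajectory:
    """Integrate the model under a sugar schedule, reporting states on ``t_grid``."""
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or t_grid.size < 2 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be strictly increasing with >= 2 points")

    def fun(t, y):
        return _rhs_core(y, params, float(schedule.glu(t)), float(schedule.gal(t)))

    sol = solve_ivp(
        fun,
        (t_grid[0], t_grid[-1]),
        state0.as_array(params.dim),
        method="LSODA",
        t_eval=t_grid,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise RuntimeError(
            f"integration failed at t = {sol.t[-1] if sol.t.size else t_grid[0]:.4g} h: "
            f"{sol.message}"
        )
    return Trajectory(t=sol.t, states=sol.y.T, params=params)


# --------------------------------------------------------------------------
# equilibria
# --------------------------------------------------------------------------


@dataclass
class Equilibrium:
    state: SpeciesState
    stable: bool
    eigenvalues: np.ndarray
    residual_norm: float

    @property
    def g1_total(self) -> float:
        return self.state.g1_total


def jacobian(
    params: ModelParams, glu: float, gal: float, state: SpeciesState
) -> np.ndarray:
    """Jacobian of the vector field by central finite differences (relative step 1e-6)."""
    y0 = state.as_array(params.dim)
    n = y0.size
    J = np.empty((n, n))
    for j in range(n):
        h = 1e-6 * (abs(y0[j]) + 1.0)
        yp, ym = y0.copy(), y0.copy()
        yp[j] += h
        ym[j] -= h
        J[:, j] = (_rhs_core(yp, params, glu, gal) - _rhs_core(ym, params, glu, gal)) / (
            2.0 * h
        )
    return J


def _make_equilibrium(params, glu, gal, y) -> Equilibrium:
    y = np.maximum(np.asarray(y, dtype=float), 0.0)
    st = SpeciesState.from_array(y)
    res = float(np.linalg.norm(_rhs_core(y, params, glu, gal)))
    eig = np.linalg.eigvals(jacobian(params, glu, gal, st))
    stable = bool(np.all(eig.real < 0))
    return Equilibrium(state=st, stable=stable, eigenvalues=eig, residual_norm=res)


def find_equilibria(
    params: ModelParams,
    glu: float,
    gal: float,
    n_starts: int = 32,
    seed: int = 0,
    residual_tol: float = 1e-8,
    dedup_rel: float = 1e-4,
) -> list[Equilibrium]:
    """All equilibria of the model at constant inputs, sorted by G1_T.

    Multistart damped root solving (Powell hybrid) from Latin-Hypercube starts
    within the reachable-concentration box, supplemented by the box corners in
    the (G1_T, G80_T) plane.  Roots are deduplicated at ``dedup_rel`` relative
    distance and annotated with linear stability from the Jacobian spectrum.
    """
    bounds = params.state_bounds()
    dim = params.dim
    # R* relaxes independently at constant inputs, so its equilibrium value is
    # known in closed form; the root search runs over the remaining totals.
    r_eq = (
        params.r_total * params.k_r * glu / (params.k_r * glu + params.k_rd)
        if dim == 4
        else None
    )
    sampler = qmc.LatinHypercube(d=3, seed=seed)
    starts = qmc.scale(sampler.random(n_starts), bounds[:3, 0], bounds[:3, 1])
    # deterministic extremal starts help pin down the outer stable branches
    extra = []
    for f1 in (0.01, 0.9):
        for f4 in (0.01, 0.9):
            s = bounds[:3, 1] * 0.25
            s[0] = bounds[0, 1] * f1
            s[2] = bounds[2, 1] * f4
            extra.append(s)
    starts = np.vstack([starts, extra])

    def embed(y3):
        return y3 if r_eq is None else np.append(y3, r_eq)

    def fun(y3):
        return _rhs_core(embed(y3), params, glu, gal)[:3]

    scale = np.maximum(bounds[:3, 1], 1.0)
    roots: list[np.ndarray] = []
    for y0 in starts:
        sol = root(fun, y0, method="hybr", options={"xtol": 1e-12})
        if not sol.success:
            continue
        y = np.maximum(sol.x, 0.0)
        if np.linalg.norm(fun(y)) > residual_tol:
            continue
        if any(np.linalg.norm((y - r[:3]) / scale) < dedup_rel for r in roots):
            continue
        roots.append(embed(y))
    # saddles sit between the outer branches and are easy to miss from random
    # starts: re-solve from points interpolated between each pair of roots
    if len(roots) >= 2:
        ordered = sorted(roots, key=lambda r: r[0])
        seg_starts = []
        for a, b in zip(ordered, ordered[1:]):
            la, lb = np.log(a[:3] + 1e-9), np.log(b[:3] + 1e-9)
            for f in (0.15, 0.3, 0.4, 0.5, 0.6, 0.7, 0.85):
                seg_starts.append((1 - f) * a[:3] + f * b[:3])
                seg_starts.append(np.exp((1 - f) * la + f * lb))
        for y0 in seg_starts:
            sol = root(fun, y0, method="hybr", options={"xtol": 1e-12})
            if not sol.success:
                continue
            y = np.maximum(sol.x, 0.0)
            if np.linalg.norm(fun(y)) > residual_tol:
                continue
            if any(np.linalg.norm((y - r[:3]) / scale) < dedup_rel for r in roots):
                continue
            roots.append(embed(y))
    if not roots:
        raise RuntimeError(
            f"no equilibria found at glu={glu:.4g} nM, gal={gal:.4g} nM; "
            "root solver failed from all starts"
        )
    eqs = [_make_equilibrium(params, glu, gal, y) for y in roots]
    eqs.sort(key=lambda e: e.g1_total)
    return eqs


def _on_equilibrium(eqs: list[Equilibrium]) -> Equilibrium:
    stable = [e for e in eqs if e.stable]
    if not stable:
        raise RuntimeError("no stable equilibrium at this input")
    return max(stable, key=lambda e: e.g1_total)


def dominant_eigenvalue(
    params: ModelParams, glu: float, gal: float, **kw
) -> float:
    """|lambda| of the smallest-magnitude Jacobian eigenvalue at the ON equilibrium.

    The ON equilibrium is the stable equilibrium of highest G1_T; its slowest
    linear mode sets the local relaxation time of the induced state.
    """
    eqs = find_equilibria(params, glu, gal, **kw)
    on = _on_equilibrium(eqs)
    if len([e for e in eqs if e.stable]) == 1 and not _is_on(on, params):
        raise RuntimeError(
            f"no ON equilibrium at glu={glu:.4g}, gal={gal:.4g}: the only stable "
            "state is OFF"
        )
    return float(np.min(np.abs(on.eigenvalues)))


def _is_on(eq: Equilibrium, params: ModelParams, threshold: Optional[float] = None) -> bool:
    thr = params.g1_on_threshold if threshold is None else threshold
    return eq.g1_total >= thr


# --------------------------------------------------------------------------
# basins of attraction
# --------------------------------------------------------------------------


def _simulate_batch(
    params: ModelParams,
    glu: float,
    gal: float,
    y0: np.ndarray,
    checkpoints=(5.0, 10.0, 20.0, 40.0, 80.0, 140.0, 200.0),
    rtol: float = 1e-6,
    atol: float = 1e-9,
    residual_tol: float = 1e-4,
):
    """Integrate many initial conditions at once under constant inputs.

    Samples are integrated in time chunks; any sample whose vector-field norm
    has dropped below ``residual_tol`` (nM/h) at a checkpoint is frozen and
    removed from the batch.  The threshold is set above the solver's own error
    floor (~rtol * |y| * d), so settled samples actually register; at a decay
    rate d the state is then within ~residual_tol/d of the equilibrium, far
    inside the attraction-assignment resolution.  Returns (final states,
    early-exit mask).
    """
    n, dim = y0.shape
    final = np.array(y0, dtype=float, copy=True)
    converged = np.zeros(n, dtype=bool)
    active = np.arange(n)
    t_prev = 0.0

    def fun(t, yflat):
        return _rhs_core(yflat.reshape(-1, dim), params, glu, gal).ravel()

    for t_next in checkpoints:
        if active.size == 0:
            break
        sol = solve_ivp(
            fun,
            (t_prev, t_next),
            final[active].ravel(),
            method="RK45",
            rtol=rtol,
            atol=atol,
        )
        if not sol.success:
            raise RuntimeError(f"batch integration failed: {sol.message}")
        y_end = np.maximum(sol.y[:, -1].reshape(-1, dim), 0.0)
        final[active] = y_end
        res = np.linalg.norm(_rhs_core(y_end, params, glu, gal), axis=-1)
        done = res < residual_tol
        converged[active[done]] = True
        active = active[~done]
        t_prev = t_next
    return final, converged


def basin_fraction_on(
    params: ModelParams,
    glu: float,
    gal: float,
    n_samples: int = 5000,
    seed: int = 0,
    max_unconverged_frac: float = 1e-3,
) -> float:
    """Fraction of Latin-Hypercube initial conditions attracted to the ON state.

    Initial conditions are sampled within the reachable-concentration box
    (production/decay balance bounds; R* within [0, R_total]) and integrated
    forward; each converged sample is assigned to the nearest stable
    equilibrium in log-scaled state space.  Deterministic for a fixed seed.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    eqs = find_equilibria(params, glu, gal, seed=seed)
    stable = [e for e in eqs if e.stable]
    if not stable:
        raise RuntimeError("no stable equilibrium: basin fraction undefined")
    if len(stable) == 1:
        return 1.0 if _is_on(stable[0], params) else 0.0

    on = max(stable, key=lambda e: e.g1_total)
    bounds = params.state_bounds()
    sampler = qmc.LatinHypercube(d=params.dim, seed=seed)
    y0 = qmc.scale(sampler.random(n_samples), bounds[:, 0], bounds[:, 1])
    final, _ = _simulate_batch(params, glu, gal, y0)
    targets = np.log10(np.stack([e.state.as_array(params.dim) for e in stable]) + 1.0)
    pts = np.log10(final + 1.0)
    dist = np.linalg.norm(pts[:, None, :] - targets[None, :, :], axis=-1)
    nearest = np.min(dist, axis=1)
    # a sample counts as converged when it has settled near one of the stable
    # equilibria in log-scaled state space by the end of the horizon
    converged = nearest < 0.2
    n_unconv = int(np.sum(~converged))
    if n_unconv > max_unconverged_frac * n_samples:
        raise RuntimeError(
            f"{n_unconv}/{n_samples} samples failed to converge within the "
            "integration horizon"
        )
    assigned = np.argmin(dist, axis=1)
    on_idx = stable.index(on)
    return float(np.sum(assigned[converged] == on_idx) / n_samples)


# --------------------------------------------------------------------------
# bifurcation structure
# --------------------------------------------------------------------------


@dataclass
class BifurcationDiagram:
    gal_fixed: float
    glu_grid: np.ndarray
    equilibria_per_point: list
    regime_per_point: list
    glu_low_star: Optional[float]
    glu_high_star: Optional[float]
    g1_branch_threshold: float

    def regime_at(self, glu: float) -> str:
        i = int(np.argmin(np.abs(self.glu_grid - glu)))
        return self.regime_per_point[i]


@dataclass
class RegimeMap:
    glu_grid: np.ndarray
    gal_grid: np.ndarray
    labels: np.ndarray  # (len(gal_grid), len(glu_grid)) of str

    @property
    def bistable_area(self) -> int:
        return int(np.sum(self.labels == BISTABLE))

    def to_frame(self):
        import pandas as pd

        gg, ll = np.meshgrid(self.glu_grid, self.gal_grid)
        return pd.DataFrame(
            {"glu": gg.ravel(), "gal": ll.ravel(), "regime": self.labels.ravel()}
        )


def _branch_threshold(
    eq_lists: list[list[Equilibrium]], params: ModelParams
) -> float:
    """Geometric mean of ON/OFF branch G1_T over bistable points, or the
    configured fallback threshold when the scan contains no bistable point."""
    lo, hi = [], []
    for eqs in eq_lists:
        stable = [e for e in eqs if e.stable]
        if len(stable) >= 2:
            lo.append(min(e.g1_total for e in stable))
            hi.append(max(e.g1_total for e in stable))
    if lo:
        return float(np.sqrt(np.mean(lo) * np.mean(hi)))
    return params.g1_on_threshold


def _label(eqs: list[Equilibrium], threshold: float) -> str:
    stable = [e for e in eqs if e.stable]
    if len(stable) >= 2:
        return BISTABLE
    if len(stable) == 1:
        return MONO_ON if stable[0].g1_total >= threshold else MONO_OFF
    raise RuntimeError("no stable equilibrium found; cannot label regime")


def bifurcation_scan(
    params: ModelParams,
    gal_fixed: float,
    glu_grid: np.ndarray,
    bisect_rel: float = 1e-3,
    **eq_kw,
) -> BifurcationDiagram:
    """Regime structure along a glucose axis at fixed galactose.

    Labels each grid point (mono_ON / bistable / mono_OFF) from the stable
    equilibrium count and locates the saddle-node glucose thresholds
    bounding the bistable band by bisection between neighbouring points of
    different regime (relative precision ``bisect_rel``).
    """
    glu_grid = np.asarray(glu_grid, dtype=float)
    if glu_grid.size < 3 or np.any(np.diff(glu_grid) <= 0):
        raise ValueError("glu_grid must be ordered with >= 3 points")
    eq_lists = [find_equilibria(params, g, gal_fixed, **eq_kw) for g in glu_grid]
    thr = _branch_threshold(eq_lists, params)
    labels = [_label(eqs, thr) for eqs in eq_lists]

    def n_stable(glu):
        return len([e for e in find_equilibria(params, glu, gal_fixed, **eq_kw) if e.stable])

    def bisect(g_lo, g_hi, want_bistable_low: bool):
        # locate boundary where stable count changes between g_lo and g_hi
        for _ in range(200):
            mid = 0.5 * (g_lo + g_hi)
            if (g_hi - g_lo) <= bisect_rel * max(mid, 1e-12):
                break
            if (n_stable(mid) >= 2) == want_bistable_low:
                g_lo = mid
            else:
                g_hi = mid
        return 0.5 * (g_lo + g_hi)

    glu_low = glu_high = None
    for i in range(len(labels) - 1):
        a, b = labels[i], labels[i + 1]
        if a == b:
            continue
        if BISTABLE in (a, b):
            bistable_low = a == BISTABLE
            boundary = bisect(glu_grid[i], glu_grid[i + 1], bistable_low)
            if (a, b) in ((MONO_ON, BISTABLE),):
                glu_low = boundary
            elif (a, b) in ((BISTABLE, MONO_OFF),):
                glu_high = boundary
            elif (a, b) == (MONO_OFF, BISTABLE):
                glu_low = boundary  # decreasing-glucose entry (unusual ordering)
            elif (a, b) == (BISTABLE, MONO_ON):
                glu_high = boundary
    if glu_low is not None and glu_high is not None and glu_low >= glu_high:
        glu_low, glu_high = glu_high, glu_low
    return BifurcationDiagram(
        gal_fixed=float(gal_fixed),
        glu_grid=glu_grid,
        equilibria_per_point=eq_lists,
        regime_per_point=labels,
        glu_low_star=glu_low,
        glu_high_star=glu_high,
        g1_branch_threshold=thr,
    )


def regime_map(
    params: ModelParams,
    glu_grid: np.ndarray,
    gal_grid: np.ndarray,
    **eq_kw,
) -> RegimeMap:
    """Regime labels over a (glucose, galactose) grid; the bistable cell count
    serves as the bistability 'area' statistic."""
    glu_grid = np.asarray(glu_grid, dtype=float)
    gal_grid = np.asarray(gal_grid, dtype=float)
    if np.any(np.diff(glu_grid) <= 0) or np.any(np.diff(gal_grid) <= 0):
        raise ValueError("grids must be strictly increasing")
    eq_rows = [
        [find_equilibria(params, glu, gal, **eq_kw) for glu in glu_grid]
        for gal in gal_grid
    ]
    thr = _branch_threshold([e for row in eq_rows for e in row], params)
    labels = np.array(
        [[_label(eqs, thr) for eqs in row] for row in eq_rows], dtype=object
    )
    return RegimeMap(glu_grid=glu_grid, gal_grid=gal_grid, labels=labels)


# --------------------------------------------------------------------------
# quasi-steady-state trajectory analysis
# --------------------------------------------------------------------------


@dataclass
class QuasiStaticResult:
    t: np.ndarray
    regimes: list
    activation_time: Optional[float]
    bimodal_onset_time: Optional[float]
    predicted_delta_g: Optional[float]


def quasi_static_regimes(
    params: ModelParams,
    glu_series: tuple,
    gal_series: tuple,
    **eq_kw,
) -> QuasiStaticResult:
    """Regime label at each time of a decaying-sugar trajectory.

    Treats the system as traversing quasi-steady-states of the frozen-input
    model.  The predicted coherent-activation time is the first entry into
    mono_ON after a bistable or mono_OFF epoch (glucose has decayed through
    the lower saddle-node); the predicted duration of bimodality delta_g is
    that time minus the first entry into the bistable regime.
    """
    t_glu, glu = map(np.asarray, glu_series)
    t_gal, gal = map(np.asarray, gal_series)
    if t_glu.shape != t_gal.shape or not np.allclose(t_glu, t_gal):
        raise ValueError("glucose and galactose series must share a time grid")
    eq_lists = [
        find_equilibria(params, float(g), float(ga), **eq_kw)
        for g, ga in zip(glu, gal)
    ]
    thr = _branch_threshold(eq_lists, params)
    labels = [_label(eqs, thr) for eqs in eq_lists]

    activation = None
    onset = None
    seen_non_on = False
    for ti, lab in zip(t_glu, labels):
        if lab in (BISTABLE, MONO_OFF):
            seen_non_on = True
        if lab == BISTABLE and onset is None:
            onset = float(ti)
        if lab == MONO_ON and seen_non_on and activation is None:
            activation = float(ti)
    if activation is None and labels and labels[0] == MONO_ON and not seen_non_on:
        activation = float(t_glu[0])  # already coherently ON throughout
    delta_g = None
    if activation is not None and onset is not None:
        delta_g = max(activation - onset, 0.0)
    return QuasiStaticResult(
        t=t_glu,
        regimes=labels,
        activation_time=activation,
        bimodal_onset_time=onset,
        predicted_delta_g=delta_g,
    )


def delta_b(
    params: ModelParams,
    glu_trajectory: tuple,
    gal_level: float,
    gal_delay: float = 0.0,
    glu_scan_grid: Optional[np.ndarray] = None,
    glu_low_star: Optional[float] = None,
    **eq_kw,
) -> float:
    """Remaining bistable window after a delayed galactose addition (h).

    delta_b is the time for the glucose trajectory to decay to the lower
    saddle-node threshold glu* at the given galactose level, minus the
    galactose delay (floored at zero): max(0, t* - delay), with t* located by
    linear interpolation between trajectory samples.
    """
    if gal_delay < 0:
        raise ValueError("gal_delay must be >= 0")
    t, glu = (np.asarray(a, dtype=float) for a in glu_trajectory)
    if glu_low_star is None:
        if glu_scan_grid is None:
            lo = min(max(glu.min(), 1e-3), 1.0)
            glu_scan_grid = np.geomspace(lo, max(glu.max(), 10.0 * lo), 25)
        diag = bifurcation_scan(params, gal_level, glu_scan_grid, **eq_kw)
        if diag.glu_low_star is None:
            raise ValueError(
                "no bifurcation crossing: scan found no lower saddle-node threshold"
            )
        glu_low_star = diag.glu_low_star
    glu_star = glu_low_star
    below = glu <= glu_star
    if not np.any(below):
        raise ValueError(
            "no bifurcation crossing: glucose trajectory never reaches the "
            f"bifurcation threshold ({glu_star:.4g} nM)"
        )
    i = int(np.argmax(below))
    if i == 0:
        t_star = float(t[0])
    else:
        f = (glu[i - 1] - glu_star) / (glu[i - 1] - glu[i])
        t_star = float(t[i - 1] + f * (t[i] - t[i - 1]))
    return max(0.0, t_star - gal_delay)
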