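"""Independent brute-force oracles used to validate the model-core numerics.

These deliberately avoid the implementation paths they check:

* ``equilibria_1d`` reduces the steady-state problem to a single
  self-consistency equation in free Gal4p and locates every root by dense
  sign-change scanning + bisection (vs the package's multistart root solver
  on the full system).
* ``binding_equilibrium_ode`` integrates an explicit mass-action binding
  network to its long-time limit (vs the package's algebraic fast-equilibrium
  reduction).
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from galswitch.model import ModelParams, hill_act, hill_rep, _free_g80


def _r_equilibrium(p: ModelParams, glu: float) -> float:
    return p.r_total * p.k_r * glu / (p.k_r * glu + p.k_rd)


def equilibria_1d(p: ModelParams, glu: float, gal: float, n_grid: int = 3000):
    """All steady states via the 1-D reduction; returns a list of dicts with
    g1_total and a slope-based stability flag for the reduced map."""
    if p.variant == "dilution":
        raise NotImplementedError("oracle covers the repressor-family variants")
    r = _r_equilibrium(p, glu)
    g4t = (p.b4 + p.alpha4 * float(hill_rep(r, p.k_r4, p.n_r))) / p.d
    hg = float(hill_act(gal, p.k_gal, p.m))
    rep1 = float(hill_rep(r, p.k_r1, p.n_r))

    def g1_of(u):
        act = hill_act(u, p.k_a, p.n_a)
        return (p.b1 + p.alpha1 * act * rep1) / p.d

    def g80_of(u):
        act = hill_act(u, p.k_a, p.n_a)
        if p.variant == "gal80_open_loop":
            return p.g80_const / p.d * np.ones_like(np.asarray(act))
        return (p.b80 + p.alpha80 * act) / p.d

    def F(u):
        g1s = g1_of(u) * hg
        bfree = _free_g80(g1s, g80_of(u), g4t, p.k_seq80, p.k_seq4)
        return g4t * p.k_seq4 / (p.k_seq4 + bfree) - u

    us = np.linspace(0.0, g4t * 1.001, n_grid)
    vals = np.asarray(F(us))
    out = []
    for i in range(n_grid - 1):
        if vals[i] == 0.0 or vals[i] * vals[i + 1] < 0:
            u = brentq(lambda x: float(F(x)), us[i], us[i + 1], xtol=1e-13)
            h = 1e-7 * (u + 1.0)
            slope = (float(F(u + h)) - float(F(max(u - h, 0.0)))) / (u + h - max(u - h, 0.0))
            out.append(
                {
                    "g1_total": float(g1_of(u)),
                    "g4_free": float(u),
                    "stable_1d": slope < 0,
                }
            )
    out.sort(key=lambda d: d["g1_total"])
    return out


def binding_equilibrium_ode(
    g1_star: float,
    g80_total: float,
    g4_total: float,
    k_seq80: float,
    k_seq4: float,
    k_on: float = 100.0,
):
    """Free G80 and free G4 from explicit mass-action binding kinetics.

    Integrates d[C1]/dt = k_on·A_free·B_free - k_on·K80·C1 (and likewise for
    the G4-G80 complex) until equilibrium, then reports the free pools.
    """

    def rhs(_, y):
        c1, c2 = y
        a_free = g1_star - c1
        b_free = g80_total - c1 - c2
        c_free = g4_total - c2
        return [
            k_on * a_free * b_free - k_on * k_seq80 * c1,
            k_on * c_free * b_free - k_on * k_seq4 * c2,
        ]

    sol = solve_ivp(
        rhs, (0.0, 2000.0 / k_on), [0.0, 0.0], method="LSODA", rtol=1e-12, atol=1e-14
    )
    c1, c2 = sol.y[:, -1]
    return g80_total - c1 - c2, g4_total - c2
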