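"""Seeded generator of synthetic diauxic-shift experiments with known truth.

The generator emulates the statistical structure of an automated
flow-cytometry time course on a yeast culture fed a glucose/galactose
mixture, at robot cadence (a sample every 20 min for 14 h):

* two cohorts of cells — an early-activated (ON) fraction whose log
  fluorescence rises logistically soon after induction, and a repressed
  (OFF) cohort that stays at the basal level until glucose runs out and then
  activates coherently — so snapshots are transiently bimodal;
* glucose consumed in proportion to cell density, galactose essentially
  untouched before glucose depletion (a small configurable leak), then
  consumed after a diauxic lag;
* exponential growth with a diauxic pause of the repressed cohort at
  depletion, the repressed cohort growing slightly faster than the induced
  one while glucose lasts;
* per-event fluorescence and side scatter drawn so that the ratio-based
  normalization of the analysis pipeline inverts the construction exactly.

Every metric the analysis pipeline estimates has an analytic ground-truth
counterpart in ``SyntheticExperiment.truth``; cohort trajectories are
deterministic functions of the configuration, with sampling noise only in
the drawn events.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .population import DEFAULT_THRESHOLD

__all__ = ["SyntheticConfig", "SyntheticExperiment", "generate_experiment", "generate_condition_grid"]


@dataclass
class SyntheticConfig:
    """Ground-truth parameters of one synthetic mixed-sugar experiment.

    Sugars in % w/v, densities in cells/ul, times in hours, rates in 1/h.
    ``p_on`` is the early-activated fraction as measured at the F_ON-mid
    read-out time (the initial cohort split is back-computed so that the
    differentially growing cohorts hit ``p_on`` exactly there).
    ``gal_leak`` scales pre-depletion galactose consumption by ON cells
    relative to their post-depletion rate.
    """

    glu0: float = 0.1
    gal0: float = 0.1
    n0: float = 200.0
    mu_glu: float = 0.45  # repressed-cohort growth rate on glucose
    mu_gal: float = 0.35  # growth rate on galactose after the shift
    growth_ratio_off_on: float = 1.15  # OFF vs ON growth-rate ratio on glucose
    c_glu: float = 1.6e-5  # % w/v per h per (cell/ul)
    c_gal: float = 1.2e-5
    p_on: float = 0.5
    lag: float = 0.6  # diauxic pause of the repressed cohort (h)
    rise_half_on: float = 1.5  # half-rise of the ON-cohort mean (h after t0)
    rise_half_off: float = 1.2  # half-rise of the OFF-cohort mean (h after depletion)
    rise_rate: float = 3.0  # logistic steepness of both rises (1/h)
    mean_off_log: float = -0.8  # basal log10 fluorescence/SSC
    mean_on_log: float = 0.6  # induced log10 fluorescence/SSC
    sd_log: float = 0.12  # per-event spread in log10 units
    gal_leak: float = 0.10
    ss_mean_ln: float = np.log(100.0)  # side-scatter lognormal location
    ss_sd_ln: float = 0.4
    od_scale: float = 2.5e4  # cells/ul per OD600 unit
    od_noise_cv: float = 0.0
    sample_interval: float = 1.0 / 3.0
    horizon: float = 14.0
    events_per_sample: int = 5000
    condition: str = "synthetic"
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.p_on <= 1.0):
            raise ValueError("p_on must lie in [0, 1]")
        if self.sample_interval <= 0:
            raise ValueError("sample_interval must be positive")
        for name in ("glu0", "gal0", "n0", "mu_glu", "mu_gal", "c_glu", "c_gal",
                     "lag", "rise_half_on", "rise_half_off", "rise_rate", "sd_log"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if not (0.0 <= self.gal_leak <= 1.0):
            raise ValueError("gal_leak must lie in [0, 1]")
        if self.growth_ratio_off_on <= 0:
            raise ValueError("growth_ratio_off_on must be positive")

    def replace(self, **kw) -> "SyntheticConfig":
        return dataclasses.replace(self, **kw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class SyntheticExperiment:
    """A fully specified experiment: config, analytic truth, and data tables."""

    config: SyntheticConfig
    truth: dict
    events: pd.DataFrame  # condition, time_h, fluorescence, side_scatter, events_per_ul
    sugars: pd.DataFrame  # condition, sugar, time_h, concentration
    od: pd.DataFrame  # condition, time_h, od600

    def write(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.events.to_csv(out / "events.csv", index=False)
        self.sugars.to_csv(out / "sugars.csv", index=False)
        self.od.to_csv(out / "od.csv", index=False)
        payload = {"config": self.config.to_dict(), "truth": self.truth}
        (out / "truth.json").write_text(json.dumps(payload, indent=2, sort_keys=True))


def _logistic(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


def _cohort_trajectories(cfg: SyntheticConfig, p0: float, t: np.ndarray):
    """Deterministic cohort sizes and the glucose-depletion time.

    Pre-depletion both cohorts grow exponentially (OFF faster by the
    configured ratio); at depletion the OFF cohort pauses for the diauxic
    lag, the already-induced ON cohort switches straight to the galactose
    rate.  Glucose falls as c_glu times the cumulative cell-hours.
    """
    mu_off = cfg.mu_glu
    mu_on = cfg.mu_glu / cfg.growth_ratio_off_on
    dt = t[1] - t[0]

    n_on = cfg.n0 * p0 * np.exp(mu_on * t)
    n_off = cfg.n0 * (1 - p0) * np.exp(mu_off * t)
    n_tot = n_on + n_off
    consumed = np.concatenate([[0.0], np.cumsum(0.5 * (n_tot[1:] + n_tot[:-1]) * dt)])
    glu = cfg.glu0 - cfg.c_glu * consumed
    if glu[-1] > 0:
        raise ValueError(
            "infeasible configuration: glucose never depletes within the horizon"
        )
    i_dep = int(np.argmax(glu <= 0))
    f = glu[i_dep - 1] / (glu[i_dep - 1] - glu[i_dep]) if i_dep > 0 else 0.0
    t_dep = float(t[max(i_dep - 1, 0)] + f * dt)

    # rebuild cohorts with the post-depletion regime
    post_on = t > t_dep
    n_on = np.where(
        post_on,
        cfg.n0 * p0 * np.exp(mu_on * t_dep) * np.exp(cfg.mu_gal * (t - t_dep)),
        n_on,
    )
    off_at_dep = cfg.n0 * (1 - p0) * np.exp(mu_off * t_dep)
    n_off = np.where(t > t_dep, off_at_dep, n_off)
    resume = t > t_dep + cfg.lag
    n_off = np.where(resume, off_at_dep * np.exp(cfg.mu_gal * (t - t_dep - cfg.lag)), n_off)
    return n_on, n_off, np.maximum(glu, 0.0), t_dep


def _mean_tracks(cfg: SyntheticConfig, t: np.ndarray, t_dep: float):
    span = cfg.mean_on_log - cfg.mean_off_log
    mean_on = cfg.mean_off_log + span * _logistic(cfg.rise_rate * (t - cfg.rise_half_on))
    mean_off = np.where(
        t < t_dep,
        cfg.mean_off_log,
        cfg.mean_off_log
        + span * _logistic(cfg.rise_rate * (t - t_dep - cfg.rise_half_off)),
    )
    return mean_on, mean_off


def generate_experiment(config: SyntheticConfig) -> SyntheticExperiment:
    """Generate one synthetic experiment; deterministic for a fixed seed."""
    cfg = config
    dt = 0.005
    t_fine = np.arange(0.0, cfg.horizon + dt, dt)

    # The initial cohort split p0 is chosen so that the ON share of the
    # population equals p_on at the F_ON-mid read-out time; because t_dep
    # depends (weakly) on the split, solve by fixed-point iteration.
    p0 = cfg.p_on
    mu_off = cfg.mu_glu
    mu_on = cfg.mu_glu / cfg.growth_ratio_off_on
    for _ in range(8):
        n_on, n_off, glu_fine, t_dep = _cohort_trajectories(cfg, p0, t_fine)
        t_mid = 0.5 * (cfg.rise_half_on + t_dep + cfg.rise_half_off)
        i_mid = int(np.argmin(np.abs(t_fine - t_mid)))
        if p0 in (0.0, 1.0):
            break
        if cfg.p_on in (0.0, 1.0):
            p0 = cfg.p_on
            break
        # cohort ratio n_off/n_on = ((1-p0)/p0) * S(t) with S independent of
        # the split; choose p0 so the ON share at t_mid equals p_on exactly
        shape = (n_off[i_mid] / n_on[i_mid]) * (p0 / (1.0 - p0))
        p0 = 1.0 / (1.0 + (1.0 - cfg.p_on) / (cfg.p_on * shape))
    n_on, n_off, glu_fine, t_dep = _cohort_trajectories(cfg, p0, t_fine)
    n_tot = n_on + n_off

    mean_on, mean_off = _mean_tracks(cfg, t_fine, t_dep)
    z_on = (mean_on - DEFAULT_THRESHOLD) / cfg.sd_log
    z_off = (mean_off - DEFAULT_THRESHOLD) / cfg.sd_log
    f_on_true = (n_on * ndtr(z_on) + n_off * ndtr(z_off)) / n_tot

    # galactose: leak-scaled consumption by ON cells before depletion, full
    # consumption by ON cells during the OFF-cohort lag, whole population after
    gal_rate = np.where(
        t_fine < t_dep,
        cfg.gal_leak * cfg.c_gal * n_tot * f_on_true,
        np.where(t_fine <= t_dep + cfg.lag, cfg.c_gal * n_on, cfg.c_gal * n_tot),
    )
    gal_fine = cfg.gal0 - np.concatenate(
        [[0.0], np.cumsum(0.5 * (gal_rate[1:] + gal_rate[:-1]) * dt)]
    )
    gal_fine = np.maximum(gal_fine, 0.0)

    i_dep = int(np.argmin(np.abs(t_fine - t_dep)))
    gal_consumed_predep = float((cfg.gal0 - gal_fine[i_dep]) / cfg.gal0) if cfg.gal0 > 0 else 0.0
    # galactose consumed by the time 78% of the glucose is gone — the
    # benchmark for how little the induced cohort actually metabolises
    glu_frac = 1.0 - glu_fine / cfg.glu0 if cfg.glu0 > 0 else np.ones_like(glu_fine)
    t78 = float(np.interp(0.78, glu_frac, t_fine))
    gal_at_t78 = float(np.interp(t78, t_fine, gal_fine))
    gal_consumed_at_78 = (
        float((cfg.gal0 - gal_at_t78) / cfg.gal0) if cfg.gal0 > 0 else 0.0
    )

    truth = {
        "t_depletion": t_dep,
        "delta_a_true": cfg.rise_half_on,
        "delta_g_true": (t_dep + cfg.rise_half_off) - cfg.rise_half_on,
        "f_on_mid_true": cfg.p_on,
        "p0_initial_on_fraction": float(p0),
        "on_rate_log2_per_h": mu_on / np.log(2.0),
        "off_rate_log2_per_h": mu_off / np.log(2.0),
        "growth_ratio_off_on": cfg.growth_ratio_off_on,
        "gal_consumed_predep_frac": gal_consumed_predep,
        "gal_consumed_at_78pct_glu_frac": gal_consumed_at_78,
    }

    rng = np.random.default_rng(cfg.seed)
    t_samples = np.arange(0.0, cfg.horizon + 1e-9, cfg.sample_interval)
    rows = []
    for ts in t_samples:
        i = int(np.argmin(np.abs(t_fine - ts)))
        share_on = n_on[i] / n_tot[i]
        k_on = rng.binomial(cfg.events_per_sample, share_on)
        k_off = cfg.events_per_sample - k_on
        log_ratio = np.concatenate(
            [
                rng.normal(mean_on[i], cfg.sd_log, size=k_on),
                rng.normal(mean_off[i], cfg.sd_log, size=k_off),
            ]
        )
        ssc = np.exp(rng.normal(cfg.ss_mean_ln, cfg.ss_sd_ln, size=cfg.events_per_sample))
        rows.append(
            pd.DataFrame(
                {
                    "condition": cfg.condition,
                    "time_h": ts,
                    "fluorescence": 10.0**log_ratio * ssc,
                    "side_scatter": ssc,
                    "events_per_ul": n_tot[i],
                }
            )
        )
    events = pd.concat(rows, ignore_index=True)

    idx = np.array([int(np.argmin(np.abs(t_fine - ts))) for ts in t_samples])
    sugars = pd.concat(
        [
            pd.DataFrame(
                {
                    "condition": cfg.condition,
                    "sugar": "glucose",
                    "time_h": t_samples,
                    "concentration": glu_fine[idx],
                }
            ),
            pd.DataFrame(
                {
                    "condition": cfg.condition,
                    "sugar": "galactose",
                    "time_h": t_samples,
                    "concentration": gal_fine[idx],
                }
            ),
        ],
        ignore_index=True,
    )
    od_vals = n_tot[idx] / cfg.od_scale
    if cfg.od_noise_cv > 0:
        od_vals = od_vals * np.exp(
            rng.normal(0.0, cfg.od_noise_cv, size=od_vals.size)
        )
    od = pd.DataFrame(
        {"condition": cfg.condition, "time_h": t_samples, "od600": od_vals}
    )
    return SyntheticExperiment(config=cfg, truth=truth, events=events, sugars=sugars, od=od)


def grid_p_on(glu: float, gal: float) -> float:
    """Early-activated fraction across the input matrix: increasing in
    galactose, decreasing in glucose (saturating forms)."""
    return 0.95 * (gal / (gal + 0.05)) * (0.12 / (0.12 + glu))


def generate_condition_grid(
    glu_levels: Sequence[float],
    gal_levels: Sequence[float],
    seeds: Sequence[int],
    base_config: Optional[SyntheticConfig] = None,
) -> list[SyntheticExperiment]:
    """One experiment per (glucose, galactose, seed) combination.

    The early-activated fraction rises with galactose and falls with
    glucose; the glucose-depletion time (hence the duration of bimodality)
    rises with the initial glucose dose — reproducing the qualitative phase
    diagram of the mixed-sugar response.
    """
    if not (len(glu_levels) and len(gal_levels) and len(seeds)):
        raise ValueError("glu_levels, gal_levels and seeds must be non-empty")
    base = base_config or SyntheticConfig()
    out = []
    for gi, glu in enumerate(glu_levels):
        for gj, gal in enumerate(gal_levels):
            for sk, seed in enumerate(seeds):
                cfg = base.replace(
                    glu0=float(glu),
                    gal0=float(gal),
                    p_on=float(np.clip(grid_p_on(glu, gal), 0.02, 0.98)),
                    seed=int(seed) * 10007 + gi * 101 + gj * 11,
                    condition=f"glu{glu:g}_gal{gal:g}_seed{seed}",
                )
                out.append(generate_experiment(cfg))
    return out
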