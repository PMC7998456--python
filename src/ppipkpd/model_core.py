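"""Deterministic structural model for PPI acid suppression.

PK: two-compartment disposition with linear elimination and zero-order IV
infusion input,

    Vc dCp/dt = -CLp Cp - CLt (Cp - Ct) + Rin(t),   Cp(0) = 0
    Vt dCt/dt =  CLt (Cp - Ct),                     Ct(0) = 0

solved in closed form (bi-exponential infusion response, superposed over
dose events).

PD: proton-pump turnover with irreversible second-order inactivation by the
drug, coupled to intragastric H+ balance with a circadian secretion surge,

    dE/dt = kdeg (1 - E) - kd E Cp(t),                   E(0) = 1
    dH/dt = kout HBASE f_circ(clock t) E - kout H,       H(0) = HBASE

where E is pump activity relative to baseline.  Meals dilute the observed
H+ (Hobs = H * Fe) without feeding back into the state equations.  pH is
carried as -log10(H in mM), so HBASE = 0.033 mM maps to a fasting minimum
pH of ~1.48.

Time convention: simulation time t = 0 is the 08:00 dose on day 1
(``CLOCK_OF_DOSE``); meals recur daily at 4 h and 10 h after 08:00.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

from ._kernels import cp_profile, pd_integrate_many
from .params import PDParameters, PKParameters

__all__ = [
    "CLOCK_OF_DOSE",
    "MEAL_TIMES",
    "DoseEvent",
    "Regimen",
    "IndividualPK",
    "IndividualPD",
    "IndividualState",
    "SimulatedProfile",
    "circadian_factor",
    "food_effect",
    "pk_concentration",
    "individual_parameters",
    "individual_pd_parameters",
    "pd_rhs",
    "observed_h",
    "ph_from_h",
    "h_from_ph",
    "simulate_individual",
    "daily_regimen",
]

CLOCK_OF_DOSE = 8.0     # clock hour mapped to simulation time 0
MEAL_TIMES = (4.0, 10.0)  # h after the 08:00 dose (12:00 and 18:00 clock)


@dataclass(frozen=True)
class DoseEvent:
    """One IV infusion: ``amount`` mg delivered over ``duration`` h starting
    at simulation time ``start_time`` h."""

    start_time: float
    amount: float
    duration: float = 0.5
    route: str = "iv-infusion"

    def __post_init__(self):
        if self.amount < 0:
            raise ValueError("dose amount must be non-negative")
        if self.duration <= 0:
            raise ValueError("infusion duration must be positive")
        if self.route != "iv-infusion":
            raise ValueError(f"unsupported route {self.route!r}")


@dataclass(frozen=True)
class Regimen:
    label: str
    events: tuple[DoseEvent, ...]
    horizon: float

    def __post_init__(self):
        if not self.events:
            raise ValueError("regimen must contain at least one dose event")
        ev = tuple(sorted(self.events, key=lambda e: e.start_time))
        object.__setattr__(self, "events", ev)
        last_end = max(e.start_time + e.duration for e in ev)
        if self.horizon < last_end:
            raise ValueError("horizon must cover the last dose event")

    def scaled(self, factor: float, label: str | None = None) -> "Regimen":
        ev = tuple(
            DoseEvent(e.start_time, e.amount * factor, e.duration, e.route) for e in self.events
        )
        return Regimen(label or self.label, ev, self.horizon)


def daily_regimen(amounts: Sequence[float], label: str = "", duration: float = 0.5,
                  horizon: float | None = None) -> Regimen:
    """One infusion per day at 08:00 with the given daily amounts (mg)."""
    events = tuple(
        DoseEvent(24.0 * day, amt, duration) for day, amt in enumerate(amounts)
    )
    if horizon is None:
        horizon = 24.0 * len(amounts)
    return Regimen(label or "/".join(f"{a:g}" for a in amounts) + " mg", events, horizon)


@dataclass(frozen=True)
class IndividualPK:
    CLp: float
    CLt: float
    Vc: float
    Vt: float

    def __post_init__(self):
        for n in ("CLp", "CLt", "Vc", "Vt"):
            if getattr(self, n) <= 0:
                raise ValueError(f"individual {n} must be positive")


@dataclass(frozen=True)
class IndividualPD:
    kdeg: float
    kd: float
    kout: float
    HBASE: float
    MA: float
    MW: float
    MTmax: float
    FE4h: float
    FE10h: float
    kFE: float


@dataclass
class IndividualState:
    """State of one subject: concentrations, pump activity and latent H+."""

    Cp: float
    Ct: float
    E_rel: float
    H: float


@dataclass(frozen=True)
class SimulatedProfile:
    """Noiseless trajectories on a user grid."""

    times: np.ndarray
    cp: np.ndarray      # ng/mL
    e_rel: np.ndarray   # pump activity, fraction of baseline
    h: np.ndarray       # latent H+, mM
    ph: np.ndarray      # observed-scale pH, -log10(H * Fe)

    def __post_init__(self):
        for a in (self.cp, self.e_rel, self.h, self.ph):
            if not np.all(np.isfinite(a)):
                raise RuntimeError("PD integration produced non-finite values")


# ---------------------------------------------------------------------------
# forcing functions and conversions


def circadian_factor(t, pd: PDParameters):
    """Nocturnal acid-secretion surge factor at clock time ``t`` (h).

    f(t) = 1 + MA / (((t - MTmax)/MW)^4 + 1), with t - MTmax wrapped to
    [-12, 12) so the surge recurs every 24 h.  f >= 1, maximal at MTmax.
    """
    t = np.asarray(t, dtype=float)
    delta = (t - pd.MTmax + 12.0) % 24.0 - 12.0
    out = 1.0 + pd.MA / ((delta / pd.MW) ** 4 + 1.0)
    return out if out.ndim else float(out)


def food_effect(t, pd: PDParameters):
    """Meal dilution factor Fe at time ``t`` (h) since the 08:00 dose.

    Fe = 1 before lunch; after the meals at 4 h and 10 h (within each day)
    the observed H+ is diluted by 1/(1 + sum of washing-out meal boluses).
    Fe is in (0, 1] and recovers toward 1 at rate kFE.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("food_effect is defined for t >= 0")
    td = t % 24.0
    denom = np.ones_like(td)
    lunch = td >= MEAL_TIMES[0]
    dinner = td >= MEAL_TIMES[1]
    # exponents clipped at 0 (exact: positive values only arise where masked)
    e4 = np.minimum(-pd.kFE * (td - MEAL_TIMES[0]), 0.0)
    e10 = np.minimum(-pd.kFE * (td - MEAL_TIMES[1]), 0.0)
    denom = np.where(lunch, denom + pd.FE4h * np.exp(e4), denom)
    denom = np.where(dinner, denom + pd.FE10h * np.exp(e10), denom)
    out = 1.0 / denom
    return out if out.ndim else float(out)


def observed_h(H, Fe):
    """Observed H+ after meal dilution: Hobs = H * Fe (mM)."""
    H = np.asarray(H, dtype=float)
    if np.any(H <= 0):
        raise ValueError("H must be positive")
    out = H * np.asarray(Fe, dtype=float)
    return out if out.ndim else float(out)


def ph_from_h(Hobs):
    """pH = -log10(H in mM); strictly decreasing bijection on (0, inf)."""
    Hobs = np.asarray(Hobs, dtype=float)
    if np.any(Hobs <= 0):
        raise ValueError("H must be positive")
    out = -np.log10(Hobs)
    return out if out.ndim else float(out)


def h_from_ph(ph):
    """Inverse of :func:`ph_from_h`."""
    ph = np.asarray(ph, dtype=float)
    out = np.power(10.0, -ph)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# PK


def individual_parameters(pk: PKParameters, weight: float, sex: int,
                          eta: Sequence[float] = (0.0, 0.0, 0.0, 0.0)) -> IndividualPK:
    """Individual PK values from fixed effects, covariates and etas.

    CLp_i = theta_CLp exp(eta1) theta_sex^sex ;
    Vc_i  = theta_Vc  exp(eta3) (WT/70)^theta_wt ;
    CLt_i, Vt_i = theta exp(eta).
    """
    if weight <= 0:
        raise ValueError("weight must be positive")
    if sex not in (0, 1):
        raise ValueError("sex must be coded 0 or 1")
    eta = np.asarray(eta, dtype=float)
    if eta.shape != (4,):
        raise ValueError("eta must have length 4 (CLp, CLt, Vc, Vt)")
    return IndividualPK(
        CLp=pk.CLp * math.exp(eta[0]) * pk.theta_sex**sex,
        CLt=pk.CLt * math.exp(eta[1]),
        Vc=pk.Vc * math.exp(eta[2]) * (weight / 70.0) ** pk.theta_wt,
        Vt=pk.Vt * math.exp(eta[3]),
    )


def individual_pd_parameters(pd: PDParameters,
                             eta: Sequence[float] = (0.0, 0.0, 0.0)) -> IndividualPD:
    """Individual PD values; BSV acts on kdeg, kd and kout."""
    eta = np.asarray(eta, dtype=float)
    if eta.shape != (3,):
        raise ValueError("eta must have length 3 (kdeg, kd, kout)")
    return IndividualPD(
        kdeg=pd.kdeg * math.exp(eta[0]),
        kd=pd.kd * math.exp(eta[1]),
        kout=pd.kout * math.exp(eta[2]),
        HBASE=pd.HBASE,
        MA=pd.MA,
        MW=pd.MW,
        MTmax=pd.MTmax,
        FE4h=pd.FE4h,
        FE10h=pd.FE10h,
        kFE=pd.kFE,
    )


def _event_arrays(doses: Sequence[DoseEvent]):
    t0 = np.array([e.start_time for e in doses], dtype=float)
    amt = np.array([e.amount for e in doses], dtype=float)
    dur = np.array([e.duration for e in doses], dtype=float)
    return t0, amt, dur


def pk_concentration(t, doses: Sequence[DoseEvent], pk_ind: IndividualPK):
    """Central concentration (ng/mL) at times ``t`` (closed form)."""
    scalar = np.isscalar(t)
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    t0, amt, dur = _event_arrays(doses)
    out = cp_profile(t_arr, t0, amt, dur, pk_ind.CLp, pk_ind.CLt, pk_ind.Vc, pk_ind.Vt, 2)
    return float(out[0]) if scalar else out


# ---------------------------------------------------------------------------
# PD


def pd_rhs(t: float, state, cp_fn, pd_ind: IndividualPD,
           clock_offset: float = CLOCK_OF_DOSE):
    """Right-hand side (dE/dt, dH/dt) of the PD system at time ``t``.

    ``state`` is (E_rel, H); ``cp_fn`` maps time to Cp (ng/mL).  The
    circadian factor is evaluated at clock time ``t + clock_offset``.
    """
    E, H = float(state[0]), float(state[1])
    cp = float(cp_fn(t))
    fc = 1.0 + pd_ind.MA / ((((t + clock_offset - pd_ind.MTmax + 12.0) % 24.0 - 12.0)
                             / pd_ind.MW) ** 4 + 1.0)
    dE = pd_ind.kdeg * (1.0 - E) - pd_ind.kd * E * cp
    dH = pd_ind.kout * pd_ind.HBASE * fc * E - pd_ind.kout * H
    return dE, dH


def _fine_grid(grid: np.ndarray, doses: Sequence[DoseEvent], dt: float,
               refine: int = 20):
    """Fine integration grid: uniform dt, refined ``refine``-fold around each
    infusion (where pump activity collapses over minutes), plus the output
    times and the infusion start/end discontinuities."""
    horizon = float(grid[-1])
    pieces = [np.arange(0.0, horizon + 0.5 * dt, dt), grid]
    for e in doses:
        start = max(e.start_time, 0.0)
        end = min(e.start_time + e.duration + 1.0, horizon)
        if end > start:
            pieces.append(np.arange(start, end, dt / refine))
            pieces.append(np.array([end]))
    fine = np.unique(np.round(np.concatenate(pieces), 9))
    fine = fine[(fine >= 0.0) & (fine <= horizon + 1e-9)]
    return fine


def _circadian_on(times_clock, pd_ind):
    delta = (times_clock - pd_ind.MTmax + 12.0) % 24.0 - 12.0
    return 1.0 + pd_ind.MA / ((delta / pd_ind.MW) ** 4 + 1.0)


def _pd_grid_solution(fine, cp_node, cp_mid, pd_ind: IndividualPD, out_idx,
                      clock_offset: float = CLOCK_OF_DOSE):
    fc_node = _circadian_on(fine + clock_offset, pd_ind)
    E, H = pd_integrate_many(
        np.diff(fine),
        cp_node[None, :],
        cp_mid[None, :],
        fc_node,
        np.array([pd_ind.kdeg]),
        np.array([pd_ind.kd]),
        np.array([pd_ind.kout]),
        pd_ind.HBASE,
        out_idx,
    )
    return E[0], H[0]


def simulate_individual(regimen: Regimen, pk_ind: IndividualPK, pd_ind: IndividualPD,
                        grid, *, method: str = "exp", dt: float = 0.005,
                        food: bool = True, rtol: float = 1e-8,
                        clock_offset: float = CLOCK_OF_DOSE) -> SimulatedProfile:
    """Noiseless individual trajectories (Cp, E, H, observed-scale pH).

    ``method="exp"`` (default) uses the L-stable exponential-midpoint stepper
    on a fine grid of width ``dt``; ``method="bdf"`` integrates the same
    system with SciPy's implicit BDF solver, split at infusion
    discontinuities (used as a cross-check; slower).
    """
    grid = np.round(np.asarray(grid, dtype=float), 9)
    if grid.ndim != 1 or grid.size == 0 or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be a non-empty strictly increasing 1-D array")
    if grid[0] < 0:
        raise ValueError("grid times must be non-negative")

    doses = regimen.events
    cp = pk_concentration(grid, doses, pk_ind)

    if method == "exp":
        fine = _fine_grid(grid, doses, dt)
        out_idx = np.searchsorted(fine, grid)
        if not np.allclose(fine[out_idx], grid, atol=1e-8):
            raise RuntimeError("output grid is not embedded in the fine grid")
        cp_node = pk_concentration(fine, doses, pk_ind)
        cp_mid = pk_concentration(0.5 * (fine[:-1] + fine[1:]), doses, pk_ind)
        E, H = _pd_grid_solution(fine, cp_node, cp_mid, pd_ind, out_idx, clock_offset)
    elif method == "bdf":
        E, H = _pd_bdf_solution(grid, doses, pk_ind, pd_ind, rtol, clock_offset)
    else:
        raise ValueError(f"unknown method {method!r}")

    fe = food_effect(grid, _fe_params(pd_ind)) if food else np.ones_like(grid)
    ph = ph_from_h(observed_h(H, fe))
    return SimulatedProfile(times=grid, cp=cp, e_rel=E, h=H, ph=ph)


def _fe_params(pd_ind: IndividualPD) -> PDParameters:
    return PDParameters(
        kdeg=pd_ind.kdeg, kd=pd_ind.kd, kout=pd_ind.kout, HBASE=pd_ind.HBASE,
        MA=pd_ind.MA, MW=pd_ind.MW, MTmax=pd_ind.MTmax,
        FE4h=pd_ind.FE4h, FE10h=pd_ind.FE10h, kFE=pd_ind.kFE,
    )


def _pd_bdf_solution(grid, doses, pk_ind, pd_ind, rtol, clock_offset):
    """Reference stiff integration with breakpoints at infusion edges."""
    horizon = float(grid[-1])
    breaks = {0.0, horizon}
    for e in doses:
        if e.start_time < horizon:
            breaks.add(e.start_time)
            breaks.add(min(e.start_time + e.duration, horizon))
    breaks = sorted(breaks)

    def rhs(t, y):
        return pd_rhs(t, y, lambda tt: pk_concentration(float(tt), doses, pk_ind),
                      pd_ind, clock_offset)

    E = np.empty_like(grid)
    H = np.empty_like(grid)
    state = np.array([1.0, pd_ind.HBASE])
    if grid[0] == 0.0:
        E[0], H[0] = state
    for a, b in zip(breaks[:-1], breaks[1:]):
        mask = (grid > a + 1e-12) & (grid <= b + 1e-12)
        t_eval = np.unique(np.concatenate([grid[mask], [b]]))
        sol = solve_ivp(rhs, (a, b), state, method="BDF", rtol=rtol,
                        atol=[1e-12, 1e-14], t_eval=t_eval)
        if not sol.success:
            raise RuntimeError(f"BDF integration failed on [{a}, {b}]: {sol.message}")
        state = sol.y[:, -1]
        if np.any(mask):
            idx = np.searchsorted(t_eval, grid[mask])
            E[mask] = sol.y[0][idx]
            H[mask] = sol.y[1][idx]
    return E, H
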