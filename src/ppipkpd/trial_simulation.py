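"""Population-level stochastic simulation of dosing trials.

Virtual subjects carry standard-normal random-effect scores; a simulation
scales them by the omegas of the parameter set in force, so the same
population can be pushed through different regimens (or different candidate
parameters) with perfectly paired between-subject variability.  All
randomness flows from explicit integer seeds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import model_core as mc
from ._kernels import cp_profile, pd_integrate_many
from .dataset import DV_CONC, DV_PH, StudyDataset
from .params import Demographics, PDParameters, PKParameters, SIMULATION_DEMOGRAPHICS

__all__ = [
    "VirtualSubject",
    "SimulationSummary",
    "DEFAULT_CONC_TIMES",
    "DEFAULT_PH_INTERVAL",
    "sample_population",
    "simulate_trial",
    "simulate_population_profiles",
    "regimen_metrics",
    "population_metrics",
    "ceiling_analysis",
    "compare_regimens",
    "standard_regimens",
    "day_windows",
]

#: Plasma sampling offsets (h) after each dose start.
DEFAULT_CONC_TIMES = (0.0, 0.25, 0.5, 0.75, 1.0, 1.5, 2.0, 3.0, 4.0, 6.0, 8.0, 12.0, 24.0)
#: Continuous pH-metry emulation: one record every 15 min.
DEFAULT_PH_INTERVAL = 0.25
#: Night window in simulation time (20:00-08:00 with the dose at 08:00 = 0 h).
NIGHT_WINDOW = (12.0, 24.0)


@dataclass(frozen=True)
class VirtualSubject:
    """One virtual subject; eta fields hold standard-normal scores that are
    scaled by the omegas of the parameter set at simulation time."""

    id: int
    weight: float
    sex: int
    eta_pk: np.ndarray  # 4 scores: CLp, CLt, Vc, Vt
    eta_pd: np.ndarray  # 3 scores: kdeg, kd, kout


@dataclass
class SimulationSummary:
    """Percentile bands over time plus per-subject acid-suppression metrics."""

    label: str
    bands: pd.DataFrame    # columns: time, variable, p5, p50, p95
    metrics: pd.DataFrame  # per (subject, window) metric values
    medians: pd.DataFrame  # per-window medians of the metrics

    def __post_init__(self):
        b = self.bands
        if not ((b["p5"] <= b["p50"] + 1e-12).all() and (b["p50"] <= b["p95"] + 1e-12).all()):
            raise ValueError("percentile bands must be ordered p5 <= p50 <= p95")


def sample_population(n: int, demographics: Demographics = SIMULATION_DEMOGRAPHICS,
                      seed: int | None = 0) -> list[VirtualSubject]:
    """Draw ``n`` virtual subjects: alternating sex (exact 1:1 for even n)
    and truncated-normal body weight within the configured bounds."""
    if n < 1:
        raise ValueError("n must be >= 1")
    d = demographics
    rng = np.random.default_rng(seed)
    a = (d.weight_min - d.weight_mean) / d.weight_sd
    b = (d.weight_max - d.weight_mean) / d.weight_sd
    weights = stats.truncnorm.rvs(a, b, loc=d.weight_mean, scale=d.weight_sd,
                                  size=n, random_state=rng)
    z_pk = rng.standard_normal((n, 4))
    z_pd = rng.standard_normal((n, 3))
    return [
        VirtualSubject(
            id=i + 1,
            weight=float(weights[i]),
            sex=1 - (i % 2),  # 1, 0, 1, 0, ... -> exact 1:1 for even n
            eta_pk=z_pk[i],
            eta_pd=z_pd[i],
        )
        for i in range(n)
    ]


def _individuals(subjects, pk: PKParameters, pd_params: PDParameters,
                 scale_bsv: bool = True):
    """Individual PK/PD parameter objects for each subject."""
    om_pk = np.array(pk.omegas())
    om_pd = np.array(pd_params.omegas())
    pk_ind, pd_ind = [], []
    for s in subjects:
        e_pk = om_pk * s.eta_pk if scale_bsv else np.zeros(4)
        e_pd = om_pd * s.eta_pd if scale_bsv else np.zeros(3)
        pk_ind.append(mc.individual_parameters(pk, s.weight, s.sex, e_pk))
        pd_ind.append(mc.individual_pd_parameters(pd_params, e_pd))
    return pk_ind, pd_ind


def simulate_population_profiles(subjects, regimen: mc.Regimen, pk: PKParameters,
                                 pd_params: PDParameters, out_times,
                                 *, dt: float = 0.02, scale_bsv: bool = True):
    """Noiseless per-subject trajectories on a shared output grid.

    Returns (cp, e_rel, h, ph) arrays of shape (n_subjects, n_times).
    """
    out_times = np.round(np.asarray(out_times, dtype=float), 9)
    pk_ind, pd_ind = _individuals(subjects, pk, pd_params, scale_bsv)
    t0, amt, dur = mc._event_arrays(regimen.events)
    fine = mc._fine_grid(out_times, regimen.events, dt)
    mid = 0.5 * (fine[:-1] + fine[1:])
    out_idx = np.searchsorted(fine, out_times)
    n = len(subjects)
    cp_node = np.empty((n, fine.size))
    cp_mid = np.empty((n, mid.size))
    cp_out = np.empty((n, out_times.size))
    for i, ind in enumerate(pk_ind):
        cp_node[i] = cp_profile(fine, t0, amt, dur, ind.CLp, ind.CLt, ind.Vc, ind.Vt, 2)
        cp_mid[i] = cp_profile(mid, t0, amt, dur, ind.CLp, ind.CLt, ind.Vc, ind.Vt, 2)
        cp_out[i] = cp_node[i][out_idx]
    fc_node = mc._circadian_on(fine + mc.CLOCK_OF_DOSE, pd_ind[0])
    E, H = pd_integrate_many(
        np.diff(fine), cp_node, cp_mid, fc_node,
        np.array([p.kdeg for p in pd_ind]),
        np.array([p.kd for p in pd_ind]),
        np.array([p.kout for p in pd_ind]),
        pd_params.HBASE,
        out_idx,
    )
    fe = mc.food_effect(out_times, pd_params)
    ph = mc.ph_from_h(H * fe[None, :])
    return cp_out, E, H, ph


def simulate_trial(subjects, regimen: mc.Regimen, pk: PKParameters,
                   pd_params: PDParameters, conc_times, ph_times,
                   seed: int | None = 0, with_noise: bool = True,
                   *, occ: int = 1, dt: float = 0.02) -> StudyDataset:
    """Simulate one trial arm and return it as a record dataset.

    Concentration observations get proportional error ``Cp (1 + eps)``,
    eps ~ N(0, sigma_prop^2); pH observations get additive error
    ``pH + eps``, eps ~ N(0, sigma_add^2).  The pre-dose (t = 0)
    concentration record is emitted with MDV=1 since Cp(0) = 0 carries no
    information under a proportional error model.  pH records are stored
    unclipped.
    """
    conc_times = np.round(np.asarray(conc_times, dtype=float), 9)
    ph_times = np.round(np.asarray(ph_times, dtype=float), 9)
    horizon = regimen.horizon
    for nm, arr in [("conc_times", conc_times), ("ph_times", ph_times)]:
        if arr.size and (arr.min() < 0 or arr.max() > horizon + 1e-9):
            raise ValueError(f"{nm} must lie within the regimen horizon [0, {horizon}]")
    all_times = np.unique(np.concatenate([conc_times, ph_times]))
    cp, _, _, ph = simulate_population_profiles(
        subjects, regimen, pk, pd_params, all_times, dt=dt
    )
    ci = np.searchsorted(all_times, conc_times)
    pi = np.searchsorted(all_times, ph_times)
    rng = np.random.default_rng(seed)
    rows = []
    for i, s in enumerate(subjects):
        for ev in regimen.events:
            rows.append((s.id, occ, ev.start_time, ev.amount, ev.duration,
                         0.0, DV_CONC, 1, s.weight, s.sex))
        eps_c = rng.standard_normal(conc_times.size) * pk.sigma_prop if with_noise else 0.0
        dv_c = cp[i][ci] * (1.0 + eps_c)
        for j, t in enumerate(conc_times):
            mdv = 1 if cp[i][ci[j]] <= 0.0 else 0
            rows.append((s.id, occ, t, 0.0, 0.0, dv_c[j] if not mdv else 0.0,
                         DV_CONC, mdv, s.weight, s.sex))
        eps_p = rng.standard_normal(ph_times.size) * pd_params.sigma_add if with_noise else 0.0
        dv_p = ph[i][pi] + eps_p
        for j, t in enumerate(ph_times):
            rows.append((s.id, occ, t, 0.0, 0.0, dv_p[j], DV_PH, 0, s.weight, s.sex))
    df = pd.DataFrame(rows, columns=["ID", "OCC", "TIME", "AMT", "DUR", "DV",
                                     "DVTYPE", "MDV", "WT", "SEX"])
    return StudyDataset(df)


# ---------------------------------------------------------------------------
# metrics


def regimen_metrics(times, ph, windows=None, thresholds=(4.0, 6.0),
                    night=NIGHT_WINDOW) -> pd.DataFrame:
    """Acid-suppression metrics per time window for one pH series.

    Per window: time-weighted (trapezoidal) mean pH, percentage of time with
    pH above each threshold (piecewise-constant, left-held), and the
    nocturnal percentage above 4 over the 20:00-08:00 sub-window.  A window
    not fully covered by the series yields NaN metrics (flagged, never
    extrapolated).
    """
    times = np.asarray(times, dtype=float)
    ph = np.asarray(ph, dtype=float)
    if windows is None:
        windows = [(float(times[0]), float(times[-1]))]
    out = []
    for (w0, w1) in windows:
        covered = times[0] <= w0 + 1e-9 and times[-1] >= w1 - 1e-9 and w1 > w0
        if not covered:
            out.append({"window_start": w0, "window_end": w1, "mean_ph": np.nan,
                        **{f"pct_above_{g:g}": np.nan for g in thresholds},
                        "nocturnal_pct_above_4": np.nan, "complete": False})
            continue
        t, y = _window_series(times, ph, w0, w1)
        row = {"window_start": w0, "window_end": w1,
               "mean_ph": float(np.trapezoid(y, t) / (w1 - w0))}
        for g in thresholds:
            row[f"pct_above_{g:g}"] = _pct_above(t, y, g)
        nt, ny = [], []
        day0 = int(math.floor(w0 / 24.0))
        day1 = int(math.floor((w1 - 1e-9) / 24.0))
        frac = 0.0
        tot = 0.0
        for day in range(day0, day1 + 1):
            n0 = max(w0, 24.0 * day + night[0])
            n1 = min(w1, 24.0 * day + night[1])
            if n1 > n0:
                tn, yn = _window_series(times, ph, n0, n1)
                frac += _pct_above(tn, yn, 4.0) / 100.0 * (n1 - n0)
                tot += n1 - n0
        row["nocturnal_pct_above_4"] = 100.0 * frac / tot if tot > 0 else np.nan
        row["complete"] = True
        out.append(row)
    return pd.DataFrame(out)


def _window_series(times, ph, w0, w1):
    inside = (times > w0) & (times < w1)
    t = np.concatenate([[w0], times[inside], [w1]])
    y = np.concatenate([[np.interp(w0, times, ph)], ph[inside], [np.interp(w1, times, ph)]])
    return t, y


def _pct_above(t, y, thr):
    dt = np.diff(t)
    return float(100.0 * np.sum(dt * (y[:-1] > thr)) / np.sum(dt))


def day_windows(horizon: float) -> list[tuple[float, float]]:
    """Consecutive 24-h windows covering the horizon."""
    n = int(round(horizon / 24.0))
    return [(24.0 * k, 24.0 * (k + 1)) for k in range(n)]


def population_metrics(times, ph_matrix, windows) -> pd.DataFrame:
    """Stack :func:`regimen_metrics` over subjects (rows of ``ph_matrix``)."""
    frames = []
    for i in range(ph_matrix.shape[0]):
        m = regimen_metrics(times, ph_matrix[i], windows)
        m.insert(0, "subject", i + 1)
        frames.append(m)
    return pd.concat(frames, ignore_index=True)


def _percentile_bands(times, arrays: dict) -> pd.DataFrame:
    frames = []
    for name, a in arrays.items():
        p5, p50, p95 = np.percentile(a, [5, 50, 95], axis=0)
        frames.append(pd.DataFrame({"time": times, "variable": name,
                                    "p5": p5, "p50": p50, "p95": p95}))
    return pd.concat(frames, ignore_index=True)


def _summarise(label, subjects, regimen, pk, pd_params, *, grid_step=0.25, dt=0.02):
    times = np.arange(0.0, regimen.horizon + grid_step / 2, grid_step)
    # include infusion end times so Cmax is sampled exactly
    ends = [min(e.start_time + e.duration, regimen.horizon) for e in regimen.events]
    times = np.unique(np.round(np.concatenate([times, ends]), 9))
    cp, _, _, ph = simulate_population_profiles(subjects, regimen, pk, pd_params,
                                                times, dt=dt)
    windows = day_windows(regimen.horizon)
    metrics = population_metrics(times, ph, windows)
    for day, (w0, w1) in enumerate(windows, start=1):
        sel = (times >= w0) & (times <= w1)
        metrics.loc[metrics["window_start"] == w0, "cmax"] = np.repeat(
            np.max(cp[:, sel], axis=1), 1
        )
    med = metrics.groupby(["window_start", "window_end"]).median(numeric_only=True)
    med = med.drop(columns=["subject"]).reset_index()
    bands = _percentile_bands(times, {"cp": cp, "ph": ph})
    overall = regimen_metrics(times, np.median(ph, axis=0))  # median-curve summary
    summary = SimulationSummary(label=label, bands=bands, metrics=metrics, medians=med)
    summary.median_curve_overall = overall
    summary.mean_ph_total = float(np.median(
        population_metrics(times, ph, [(0.0, regimen.horizon)])["mean_ph"]
    ))
    return summary, cp, ph, times


# ---------------------------------------------------------------------------
# study-level analyses


def ceiling_analysis(pk: PKParameters, pd_params: PDParameters,
                     doses: Sequence[float] = (10.0, 20.0, 30.0, 40.0),
                     n_subjects: int = 2000, days: int = 3, seed: int | None = 1,
                     *, demographics: Demographics = SIMULATION_DEMOGRAPHICS,
                     dt: float = 0.02,
                     ceiling_fraction: float = 0.2):
    """Dose-ceiling comparison across once-daily regimens sharing subjects.

    Returns ``(table, gains)``: per-dose medians of exposure and pH metrics
    on the final 24-h window, and the incremental gains between consecutive
    doses for each pH metric, including the ratio of the top-dose gain to
    the first-dose gain (``ceiling_fraction`` is the reference fraction the
    caller may compare against).
    """
    subjects = sample_population(n_subjects, demographics, seed)
    rows = {}
    per_dose = {}
    for d in doses:
        reg = mc.daily_regimen([d] * days, f"{d:g} mg x {days} d")
        summary, cp, ph, times = _summarise(f"{d:g}", subjects, reg, pk, pd_params, dt=dt)
        last = summary.metrics[summary.metrics["window_start"] == 24.0 * (days - 1)]
        rows[d] = {
            "dose_mg": d,
            "median_cmax": float(np.median(np.max(cp, axis=1))),
            "median_mean_ph_24h": float(last["mean_ph"].median()),
            "median_pct_above_4": float(last["pct_above_4"].median()),
            "median_pct_above_6": float(last["pct_above_6"].median()),
            "median_nocturnal_pct_above_4": float(last["nocturnal_pct_above_4"].median()),
        }
        per_dose[d] = summary
    table = pd.DataFrame([rows[d] for d in doses]).set_index("dose_mg")
    gains = {"ceiling_fraction": ceiling_fraction}
    for metric in ("median_mean_ph_24h", "median_pct_above_4", "median_pct_above_6"):
        g = {}
        vals = table[metric]
        for lo, hi in zip(doses[:-1], doses[1:]):
            g[f"{lo:g}->{hi:g}"] = float(vals[hi] - vals[lo])
        first = g[f"{doses[0]:g}->{doses[1]:g}"]
        top = float(vals[doses[-1]] - vals[doses[1]])
        g["top_vs_first_ratio"] = top / first if first != 0 else (0.0 if top == 0 else np.inf)
        gains[metric] = g
    return table, gains


def standard_regimens(days: int = 3) -> list[mc.Regimen]:
    """The four loading/maintenance regimens compared in the optimisation
    analysis: 10/10/10, 20/5/5, 20/10/10 and 20/20/20 mg once daily."""
    return [
        mc.daily_regimen([10.0] * days, "regimen 1: 10 mg qd"),
        mc.daily_regimen([20.0] + [5.0] * (days - 1), "regimen 2: 20 mg + 5 mg qd"),
        mc.daily_regimen([20.0] + [10.0] * (days - 1), "regimen 3: 20 mg + 10 mg qd"),
        mc.daily_regimen([20.0] * days, "regimen 4: 20 mg qd"),
    ]


def compare_regimens(regimens: Sequence[mc.Regimen], pk: PKParameters,
                     pd_params: PDParameters, n_subjects: int = 2000,
                     seed: int | None = 1, *, shared_eta: bool = True,
                     demographics: Demographics = SIMULATION_DEMOGRAPHICS,
                     dt: float = 0.02) -> dict[str, SimulationSummary]:
    """Per-regimen summaries; with ``shared_eta`` every arm reuses the same
    virtual subjects, removing between-arm Monte-Carlo noise."""
    out = {}
    for k, reg in enumerate(regimens):
        s = seed if shared_eta else (None if seed is None else seed + 1000 * k)
        subjects = sample_population(n_subjects, demographics, s)
        summary, _, _, _ = _summarise(reg.label, subjects, reg, pk, pd_params, dt=dt)
        out[reg.label] = summary
    return out
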