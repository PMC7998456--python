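"""Model evaluation: visual predictive checks, goodness-of-fit tables and
external validation overlays.

A VPC re-simulates the full study design ``n_rep`` times from the population
model (new random effects and residual errors each replicate), pools the
simulated observations per nominal time bin, and compares the observed
percentiles with the simulated 5th/50th/95th percentile bands.  Designs here
use nominal sampling times, so bins are exact (ID, OCC, TIME) time points
pooled within occasion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import solve_triangular

from . import model_core as mc
from ._kernels import cp_profile
from .dataset import DV_CONC, DV_PH, StudyDataset
from .estimation import FitResult, ModelSpec, empirical_bayes
from .params import PDParameters, PKParameters

__all__ = ["VPCResult", "vpc", "gof", "external_validation", "plot_vpc"]


@dataclass
class VPCResult:
    """Observed and simulated percentiles per time bin plus coverage."""

    bins: pd.DataFrame        # per (OCC, TIME): obs/sim percentiles, envelopes
    coverage: float           # fraction of observations inside sim 5-95 band
    n_rep: int
    dvtype: int

    def __post_init__(self):
        b = self.bins
        for lo, hi in [("sim_p5", "sim_p50"), ("sim_p50", "sim_p95")]:
            if not (b[lo] <= b[hi] + 1e-12).all():
                raise ValueError("simulated percentile bands must be ordered")


def _simulate_replicate(dataset: StudyDataset, pk: PKParameters,
                        pd_params: PDParameters | None, rng, dvtype: int,
                        dt: float = 0.04):
    """One full-design replicate: DataFrame (ID, OCC, TIME, DV) matching the
    observed records of ``dvtype``."""
    cov = dataset.covariates()
    om_pk = np.array(pk.omegas())
    om_pd = np.array(pd_params.omegas()) if pd_params is not None else np.zeros(3)
    etas_pk = {sid: om_pk * rng.standard_normal(4) for sid in cov.index}
    etas_pd = {sid: om_pd * rng.standard_normal(3) for sid in cov.index}
    out = []
    for (sid, occ), g in dataset.profiles():
        obs = g[(g["MDV"] == 0) & (g["DVTYPE"] == dvtype)]
        if len(obs) == 0:
            continue
        doses = g[g["AMT"] > 0]
        events = tuple(mc.DoseEvent(r.TIME, r.AMT, r.DUR) for r in doses.itertuples())
        t = obs["TIME"].to_numpy(dtype=float)
        ind = mc.individual_parameters(pk, float(cov.loc[sid, "WT"]),
                                       int(cov.loc[sid, "SEX"]), etas_pk[sid])
        if dvtype == DV_CONC:
            t0, amt, dur = mc._event_arrays(events)
            f = cp_profile(t, t0, amt, dur, ind.CLp, ind.CLt, ind.Vc, ind.Vt, 2)
            dv = f * (1.0 + pk.sigma_prop * rng.standard_normal(t.size))
        else:
            if pd_params is None:
                raise ValueError("pd parameters required for a pH VPC")
            pdi = mc.individual_pd_parameters(pd_params, etas_pd[sid])
            reg = mc.Regimen("vpc", events, max(float(t.max()), *(e.start_time + e.duration for e in events)))
            prof = mc.simulate_individual(reg, ind, pdi, t, dt=dt)
            dv = prof.ph + pd_params.sigma_add * rng.standard_normal(t.size)
        out.append(pd.DataFrame({"ID": sid, "OCC": occ, "TIME": t, "DV": dv}))
    return pd.concat(out, ignore_index=True)


def vpc(dataset: StudyDataset, pk: PKParameters,
        pd_params: PDParameters | None = None, *, dvtype: int = DV_CONC,
        n_rep: int = 500, seed: int | None = 0, dt: float = 0.04) -> VPCResult:
    """Visual predictive check of ``dvtype`` records against the model.

    Returns per-bin observed percentiles, simulated percentile bands with
    2.5-97.5% replicate envelopes, and the fraction of observed points
    inside the simulated 5th-95th band.
    """
    obs = dataset.observations(dvtype)
    if len(obs) == 0:
        raise ValueError("dataset has no observations of the requested type")
    rng = np.random.default_rng(seed)
    sims = []
    for r in range(n_rep):
        rep = _simulate_replicate(dataset, pk, pd_params, rng, dvtype)
        rep["rep"] = r
        sims.append(rep)
    sim = pd.concat(sims, ignore_index=True)

    rows = []
    n_inside = 0
    for (occ, t), g in obs.groupby(["OCC", "TIME"]):
        s = sim[(sim["OCC"] == occ) & (sim["TIME"] == t)]
        pooled = s["DV"].to_numpy()
        lo, mid, hi = np.percentile(pooled, [5, 50, 95])
        rep_med = s.groupby("rep")["DV"].median()
        env_lo, env_hi = np.percentile(rep_med, [2.5, 97.5])
        o = g["DV"].to_numpy()
        olo, omid, ohi = np.percentile(o, [5, 50, 95])
        inside = int(np.sum((o >= lo) & (o <= hi)))
        n_inside += inside
        rows.append({"OCC": occ, "TIME": t, "n_obs": len(o),
                     "obs_p5": olo, "obs_p50": omid, "obs_p95": ohi,
                     "sim_p5": lo, "sim_p50": mid, "sim_p95": hi,
                     "median_env_lo": env_lo, "median_env_hi": env_hi,
                     "n_inside": inside})
        if len(o) == 0:
            raise ValueError(f"empty bin at OCC={occ}, TIME={t}")
    bins = pd.DataFrame(rows)
    return VPCResult(bins=bins, coverage=n_inside / len(obs), n_rep=n_rep,
                     dvtype=dvtype)


def gof(dataset: StudyDataset, fit: FitResult) -> pd.DataFrame:
    """Goodness-of-fit table for a PK fit: per concentration record the
    population prediction (PRED, etas = 0), individual prediction (IPRED,
    empirical Bayes etas), residuals, and conditional weighted residuals
    (CWRES, residuals scaled by the FOCE-linearised marginal covariance).
    """
    if fit.stage != "pk":
        raise ValueError("gof currently supports PK fits")
    spec = fit.spec or ModelSpec()
    p = fit.estimates
    etas = fit.etas if fit.etas is not None else empirical_bayes(dataset, spec, p)
    cov = dataset.covariates()
    sigma = p["sigma_prop"]
    omegas = np.array([p.get(f"omega_{n}", 0.0) for n in spec.bsv])
    rows = []
    for (sid, occ), g in dataset.profiles():
        obs = g[(g["MDV"] == 0) & (g["DVTYPE"] == DV_CONC)]
        if len(obs) == 0:
            continue
        doses = g[g["AMT"] > 0]
        events = tuple(mc.DoseEvent(r.TIME, r.AMT, r.DUR) for r in doses.itertuples())
        t = obs["TIME"].to_numpy(dtype=float)
        y = obs["DV"].to_numpy(dtype=float)
        wt = float(cov.loc[sid, "WT"])
        sx = int(cov.loc[sid, "SEX"])
        eta_hat = np.zeros(4)
        for k, n in enumerate(spec.bsv):
            eta_hat[["CLp", "CLt", "Vc", "Vt"].index(n)] = etas.loc[sid, f"eta_{n}"]

        def f_of(eta4):
            ind = mc.individual_parameters(_as_pk(p, spec), wt, sx, eta4)
            return mc.pk_concentration(t, events, ind)

        pred = f_of(np.zeros(4))
        ipred = f_of(eta_hat)
        # FOCE linearisation: G = df/deta at the conditional mode
        G = np.zeros((t.size, len(spec.bsv)))
        h = 1e-4
        for k, n in enumerate(spec.bsv):
            slot = ["CLp", "CLt", "Vc", "Vt"].index(n)
            ep = eta_hat.copy()
            ep[slot] += h
            em = eta_hat.copy()
            em[slot] -= h
            G[:, k] = (f_of(ep) - f_of(em)) / (2 * h)
        V = G @ np.diag(omegas**2) @ G.T + np.diag((sigma * np.maximum(ipred, 1e-10))**2)
        res = y - pred
        cres = y - ipred + G @ (eta_hat[[["CLp", "CLt", "Vc", "Vt"].index(n) for n in spec.bsv]]
                                if len(spec.bsv) else np.zeros(0))
        L = np.linalg.cholesky(V)
        cwres = solve_triangular(L, cres, lower=True)
        iwres = (y - ipred) / (sigma * np.maximum(ipred, 1e-10))
        for j in range(t.size):
            rows.append({"ID": sid, "OCC": occ, "TIME": t[j], "DV": y[j],
                         "PRED": pred[j], "IPRED": ipred[j], "RES": res[j],
                         "IWRES": iwres[j], "CWRES": cwres[j]})
    out = pd.DataFrame(rows)
    return out


def _as_pk(p: dict, spec: ModelSpec) -> PKParameters:
    return PKParameters(
        CLp=p.get("CLp", 1.0), CLt=p.get("CLt", 1.0), Vc=p["Vc"], Vt=p.get("Vt", 1.0),
        theta_wt=p.get("theta_wt", 0.0) if spec.covariate_wt_vc else 0.0,
        theta_sex=p.get("theta_sex", 1.0) if spec.covariate_sex_clp else 1.0,
    )


def external_validation(dataset_external: StudyDataset, pk: PKParameters,
                        pd_params: PDParameters | None = None, *,
                        dvtype: int = DV_CONC, n_rep: int = 200,
                        seed: int | None = 0) -> dict:
    """Overlay an external study on model-simulated percentile bands.

    The external design (doses, schedules, covariates) is taken from the
    dataset itself; the model parameters come from the fit to the original
    study.  Returns the VPC-style band table, per-record inside/outside
    flags and the overall coverage.
    """
    if dataset_external.n_observations(dvtype) == 0:
        raise ValueError("external dataset has no observations to validate against")
    res = vpc(dataset_external, pk, pd_params, dvtype=dvtype, n_rep=n_rep, seed=seed)
    obs = dataset_external.observations(dvtype).copy()
    key = res.bins.set_index(["OCC", "TIME"])
    lo = key["sim_p5"]
    hi = key["sim_p95"]
    idx = list(zip(obs["OCC"], obs["TIME"]))
    obs["inside_band"] = [(lo.loc[k] <= dv <= hi.loc[k]) for k, dv in zip(idx, obs["DV"])]
    return {"bands": res.bins, "records": obs, "coverage": res.coverage,
            "n_rep": n_rep}


def plot_vpc(result: VPCResult, path=None, ax=None):
    """Plot simulated bands with observed percentile overlay (one panel per
    occasion); written as a vector graphic when ``path`` is given."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    occs = sorted(result.bins["OCC"].unique())
    fig, axes = plt.subplots(1, len(occs), figsize=(4 * len(occs), 3.2),
                             sharey=True, squeeze=False)
    for k, occ in enumerate(occs):
        a = axes[0][k]
        b = result.bins[result.bins["OCC"] == occ].sort_values("TIME")
        a.fill_between(b["TIME"], b["sim_p5"], b["sim_p95"], alpha=0.25,
                       label="sim 5-95%")
        a.plot(b["TIME"], b["sim_p50"], lw=1.5, label="sim median")
        for col, style in [("obs_p5", ":"), ("obs_p50", "-"), ("obs_p95", ":")]:
            a.plot(b["TIME"], b[col], style, color="k", lw=1)
        a.set_xlabel("time (h)")
        a.set_title(f"occasion {occ}")
    axes[0][0].set_ylabel("concentration (ng/mL)" if result.dvtype == DV_CONC else "pH")
    axes[0][0].legend(frameon=False, fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
        plt.close(fig)
    return fig
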