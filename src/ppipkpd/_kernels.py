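"""Numba kernels: closed-form disposition curves, the stiff PD stepper and
the per-subject likelihood accumulators used by the Laplace engine.

The PD stepper is an exponential (exponentially fitted, L-stable) midpoint
integrator: both state equations are linear in the state with time-varying
coefficients, so each step applies the exact solution for coefficients
frozen at the step midpoint.  This remains stable for arbitrarily large
inactivation rates kd*Cp, which reach O(1e4)/h at therapeutic exposure.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

LOG2PI = math.log(2.0 * math.pi)


@njit(cache=True)
def _disposition_constants(CL, Q, Vc, Vt, ncpt):
    """Macro constants (l1, l2, c1, c2) of the bi-exponential unit response."""
    if ncpt == 1:
        return CL / Vc, 1.0, 1.0, 0.0
    k10 = CL / Vc
    k12 = Q / Vc
    k21 = Q / Vt
    s = k10 + k12 + k21
    disc = math.sqrt(max(s * s - 4.0 * k10 * k21, 0.0))
    if disc < 1e-12 * s:
        disc = 1e-12 * s  # guard against a (measure-zero) repeated root
    l1 = 0.5 * (s + disc)
    l2 = 0.5 * (s - disc)
    if l2 < 1e-12 * l1:
        l2 = 1e-12 * l1  # guard against underflowed elimination

    c1 = (l1 - k21) / (l1 - l2)
    c2 = (k21 - l2) / (l1 - l2)
    return l1, l2, c1, c2


@njit(cache=True)
def _cp_single(t, t0, amt, dur, l1, l2, c1, c2, Vc):
    """Central concentration contribution of one IV infusion at time t (ng/mL).

    Dose amount in mg, volumes in L: mg/L == ug/mL, scaled by 1000 to ng/mL.
    """
    tau = t - t0
    if tau <= 0.0 or amt <= 0.0:
        return 0.0
    rate = amt / dur
    te = tau if tau < dur else dur
    post = tau - dur if tau > dur else 0.0
    acc = c1 / l1 * (1.0 - math.exp(-l1 * te)) * math.exp(-l1 * post)
    if c2 != 0.0:
        acc += c2 / l2 * (1.0 - math.exp(-l2 * te)) * math.exp(-l2 * post)
    return 1000.0 * rate / Vc * acc


@njit(cache=True)
def cp_profile(t, ev_t0, ev_amt, ev_dur, CL, Q, Vc, Vt, ncpt):
    """Central concentration (ng/mL) at times ``t`` by superposition."""
    l1, l2, c1, c2 = _disposition_constants(CL, Q, Vc, Vt, ncpt)
    out = np.zeros(t.shape[0])
    for i in range(t.shape[0]):
        acc = 0.0
        for e in range(ev_t0.shape[0]):
            acc += _cp_single(t[i], ev_t0[e], ev_amt[e], ev_dur[e], l1, l2, c1, c2, Vc)
        out[i] = acc
    return out


@njit(cache=True)
def pd_integrate_many(dt, cp_node, cp_mid, fc_node, kdeg, kd, kout, hbase, out_idx):
    """Integrate the turnover/acid system for many profiles on a shared grid.

    Each equation is linear in its state, ``y' = r(t) (yinf(t) - y)``; a step
    applies the exact decay for the midpoint rate plus a drift correction
    that reproduces the quasi-steady solution ``yinf - yinf'/r`` in the stiff
    limit (second order accurate, L-stable).

    Parameters
    ----------
    dt : (nstep,) step widths of the fine grid.
    cp_node : (m, nstep+1) central concentration at grid nodes, ng/mL.
    cp_mid : (m, nstep) central concentration at step midpoints.
    fc_node : (nstep+1,) circadian secretion factor at grid nodes.
    kdeg, kd, kout : (m,) individual rate constants.
    hbase : baseline H+ (mM), shared.
    out_idx : (nout,) fine-grid node indices at which to record the state.

    Returns
    -------
    E, H : (m, nout) pump activity and latent H+ at the requested nodes.
    """
    m = cp_node.shape[0]
    nstep = dt.shape[0]
    nout = out_idx.shape[0]
    Eout = np.empty((m, nout))
    Hout = np.empty((m, nout))
    for i in range(m):
        E = 1.0
        H = hbase
        nxt = 0
        if nout > 0 and out_idx[0] == 0:
            Eout[i, 0] = E
            Hout[i, 0] = H
            nxt = 1
        for k in range(nstep):
            h = dt[k]
            a0 = kdeg[i] + kd[i] * cp_node[i, k]
            a1 = kdeg[i] + kd[i] * cp_node[i, k + 1]
            am = kdeg[i] + kd[i] * cp_mid[i, k]
            e0 = kdeg[i] / a0
            e1 = kdeg[i] / a1
            x = math.exp(-am * h)
            Enew = e1 + (E - e0) * x - (e1 - e0) / h * (1.0 - x) / am
            if Enew < 1e-300:
                Enew = 1e-300
            s0 = hbase * fc_node[k] * E
            s1 = hbase * fc_node[k + 1] * Enew
            xh = math.exp(-kout[i] * h)
            H = s1 + (H - s0) * xh - (s1 - s0) / h * (1.0 - xh) / kout[i]
            if H < 1e-300:
                H = 1e-300
            E = Enew
            if nxt < nout and out_idx[nxt] == k + 1:
                Eout[i, nxt] = E
                Hout[i, nxt] = H
                nxt += 1
    return Eout, Hout


@njit(cache=True)
def pk_nll_kernel(
    etas,
    theta,
    wt,
    sex,
    prof_subj,
    ev_ptr,
    ev_t0,
    ev_amt,
    ev_dur,
    obs_ptr,
    obs_t,
    obs_y,
    sigma,
    ncpt,
    use_wt,
    use_sex,
):
    """Per-subject -log p(y | eta) for the proportional-error PK model.

    ``etas`` is (nbatch, nsub, 4) in the slot order (CLp, CLt, Vc, Vt);
    inactive slots are zero.  ``theta`` = (CLp, CLt, Vc, Vt, theta_wt,
    theta_sex).  Profiles (subject-occasions) index their events and
    observations through ``ev_ptr``/``obs_ptr``.  Returns (nbatch, nsub).
    """
    nbatch = etas.shape[0]
    nsub = etas.shape[1]
    nll = np.zeros((nbatch, nsub))
    for b in range(nbatch):
        for p in range(prof_subj.shape[0]):
            s = prof_subj[p]
            # etas clamped so extreme line-search trial points stay finite
            CL = theta[0] * math.exp(min(max(etas[b, s, 0], -40.0), 40.0))
            if use_sex and sex[s] == 1:
                CL *= theta[5]
            Q = theta[1] * math.exp(min(max(etas[b, s, 1], -40.0), 40.0))
            Vc = theta[2] * math.exp(min(max(etas[b, s, 2], -40.0), 40.0))
            if use_wt:
                Vc *= (wt[s] / 70.0) ** theta[4]
            Vt = theta[3] * math.exp(min(max(etas[b, s, 3], -40.0), 40.0))
            l1, l2, c1, c2 = _disposition_constants(CL, Q, Vc, Vt, ncpt)
            acc = 0.0
            for j in range(obs_ptr[p], obs_ptr[p + 1]):
                f = 0.0
                for e in range(ev_ptr[p], ev_ptr[p + 1]):
                    f += _cp_single(obs_t[j], ev_t0[e], ev_amt[e], ev_dur[e],
                                    l1, l2, c1, c2, Vc)
                if f < 1e-10:
                    f = 1e-10
                r = obs_y[j] - f
                v = (sigma * f) ** 2
                acc += 0.5 * (LOG2PI + math.log(v) + r * r / v)
            nll[b, s] += acc
    return nll


@njit(cache=True)
def pd_nll_kernel(
    etas,
    prof_subj,
    dt,
    cp_node,
    cp_mid,
    fc_node,
    kdeg_t,
    kd_t,
    kout_t,
    hbase,
    obs_idx,
    y,
    log10fe_obs,
    sigma,
):
    """Per-subject -log p(pH | eta) for the additive-error PD model.

    ``etas`` is (nbatch, nsub, 3) in the slot order (kdeg, kd, kout).
    ``y`` is (m, nobs) observed pH per profile; ``log10fe_obs`` is (nobs,),
    log10 of the meal-dilution factor at the shared observation times.
    Returns (nbatch, nsub).
    """
    nbatch = etas.shape[0]
    nsub = etas.shape[1]
    m = prof_subj.shape[0]
    nobs = obs_idx.shape[0]
    nll = np.zeros((nbatch, nsub))
    ln10 = math.log(10.0)
    v = sigma * sigma
    logv = 0.5 * (LOG2PI + math.log(v))
    kdeg = np.empty(m)
    kd = np.empty(m)
    kout = np.empty(m)
    for b in range(nbatch):
        for p in range(m):
            s = prof_subj[p]
            kdeg[p] = kdeg_t * math.exp(min(max(etas[b, s, 0], -40.0), 40.0))
            kd[p] = kd_t * math.exp(min(max(etas[b, s, 1], -40.0), 40.0))
            kout[p] = kout_t * math.exp(min(max(etas[b, s, 2], -40.0), 40.0))
        _, H = pd_integrate_many(dt, cp_node, cp_mid, fc_node, kdeg, kd, kout,
                                 hbase, obs_idx)
        for p in range(m):
            s = prof_subj[p]
            acc = 0.0
            for j in range(nobs):
                ph = -math.log(H[p, j]) / ln10 - log10fe_obs[j]
                r = y[p, j] - ph
                acc += logv + 0.5 * r * r / v
            nll[b, s] += acc
    return nll
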