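"""Nonlinear mixed-effects estimation by the Laplace approximation.

The marginal likelihood of each subject's data is an integral over that
subject's random effects.  We parameterise individual parameters as
``theta * exp(eta)`` (mu-referencing) and integrate in the standardised
variable ``u = eta / omega`` with a unit-normal prior, so the inner
optimisation problem is always well scaled:

    -2 log L_i  ~=  2 h_i(u*) - q log(2 pi) + log det H_i(u*)

with ``h_i(u) = -log p(y_i | omega u) + (u'u + q log 2 pi) / 2`` minimised
by a damped finite-difference Newton method, vectorised over subjects.  The
fixed effects, BSV variances and residual magnitude are then estimated by
Nelder-Mead on log-transformed scales.

Fitting follows the two-step (sequential) scheme: the PK model is fitted to
plasma concentrations first; the PD stage conditions on individual PK
parameters (empirical Bayes estimates or simulation truth) and estimates the
pump-turnover, inhibition and food-effect parameters from the pH records.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import minimize

from . import model_core as mc
from ._kernels import LOG2PI, cp_profile, pd_nll_kernel, pk_nll_kernel
from .dataset import DV_CONC, DV_PH, StudyDataset
from .params import PDParameters, PKParameters

__all__ = [
    "ModelSpec",
    "FitResult",
    "LaplaceResult",
    "laplace_marginal",
    "marginal_objective",
    "fit_pk",
    "empirical_bayes",
    "fit_pd_sequential",
    "fit_circadian_baseline",
    "model_compare",
    "individual_pk_from_fit",
    "individual_pk_from_manifest",
]


# ---------------------------------------------------------------------------
# model specification


@dataclass(frozen=True)
class ModelSpec:
    """Structural PK model choice and covariate/BSV configuration.

    ``elimination="mm"`` replaces the linear clearance CLp with
    Michaelis-Menten elimination (Vm mg/h, Km ng/mL); it is retained as a
    candidate model for selection experiments.
    """

    n_compartments: int = 2
    elimination: str = "linear"
    covariate_wt_vc: bool = True
    covariate_sex_clp: bool = True
    bsv: tuple[str, ...] = ("CLp", "CLt", "Vc", "Vt")

    def __post_init__(self):
        if self.n_compartments not in (1, 2):
            raise ValueError("n_compartments must be 1 or 2")
        if self.elimination not in ("linear", "mm"):
            raise ValueError("elimination must be 'linear' or 'mm'")
        allowed = set(self.structural_names())
        for name in self.bsv:
            if name not in allowed:
                raise ValueError(f"BSV on unknown parameter {name!r}; choose from {sorted(allowed)}")

    def structural_names(self) -> tuple[str, ...]:
        names = ["Vm", "Km"] if self.elimination == "mm" else ["CLp"]
        if self.n_compartments == 2:
            names += ["CLt", "Vt"]
        names += ["Vc"]
        return tuple(names)

    def fixed_effect_names(self) -> tuple[str, ...]:
        names = list(self.structural_names())
        if self.covariate_wt_vc:
            names.append("theta_wt")
        if self.covariate_sex_clp:
            names.append("theta_sex")
        return tuple(names)

    def parameter_names(self) -> tuple[str, ...]:
        return self.fixed_effect_names() + tuple(f"omega_{n}" for n in self.bsv) + ("sigma_prop",)


_PK_SLOTS = {"CLp": 0, "Vm": 0, "CLt": 1, "Vc": 2, "Vt": 3}
_PD_SLOTS = {"kdeg": 0, "kd": 1, "kout": 2}


@dataclass
class FitResult:
    """Estimates, uncertainty and bookkeeping from one estimation stage."""

    stage: str
    estimates: dict[str, float]
    ofv: float
    aic: float
    n_params: int
    n_obs: int
    n_subjects: int
    se: dict[str, float] | None = None
    ci95: dict[str, tuple[float, float]] | None = None
    etas: pd.DataFrame | None = None
    convergence: dict = field(default_factory=dict)
    dataset_signature: str = ""
    spec: ModelSpec | None = None

    def __post_init__(self):
        if not math.isclose(self.aic, self.ofv + 2 * self.n_params, rel_tol=0, abs_tol=1e-8):
            raise ValueError("AIC must equal OFV + 2 * n_params")

    def summary(self) -> str:
        """Human-readable fit report (estimate, SE, 95% CI per parameter)."""
        lines = [f"{self.stage.upper()} fit: OFV {self.ofv:.3f}, AIC {self.aic:.3f}, "
                 f"{self.n_obs} obs / {self.n_subjects} subjects",
                 f"{'parameter':<14}{'estimate':>12}{'SE':>12}{'95% CI':>26}"]
        for k, v in self.estimates.items():
            se = f"{self.se[k]:.4g}" if self.se and k in self.se else "-"
            ci = (f"({self.ci95[k][0]:.4g}, {self.ci95[k][1]:.4g})"
                  if self.ci95 and k in self.ci95 else "-")
            lines.append(f"{k:<14}{v:>12.4g}{se:>12}{ci:>26}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Laplace engine (vectorised over subjects)


@dataclass
class LaplaceResult:
    ofv: float
    ofv_by_subject: np.ndarray
    etas: np.ndarray        # modes in the standardised u variable
    hessians: np.ndarray
    n_iter: int
    converged: bool


def _fd_deltas(q, step):
    """Perturbation stencil for one batched gradient+Hessian evaluation."""
    deltas = [np.zeros(q)]
    for d in range(q):
        e = np.zeros(q)
        e[d] = step
        deltas += [e, -e]
    for a in range(q):
        ea = np.zeros(q)
        ea[a] = step
        for b in range(a + 1, q):
            eb = np.zeros(q)
            eb[b] = step
            deltas += [ea + eb, ea - eb, -ea + eb, -ea - eb]
    return np.asarray(deltas)


def _fd_grad_hess(hvec, u, step):
    """Central-difference gradient and Hessian of the per-subject objective,
    computed in a single batched evaluation.  ``hvec`` maps (B, n, q) to
    (B, n)."""
    n, q = u.shape
    deltas = _fd_deltas(q, step)
    F = hvec(u[None, :, :] + deltas[:, None, :])
    f0 = F[0]
    grad = np.empty((n, q))
    hess = np.empty((n, q, q))
    for d in range(q):
        fp, fm = F[1 + 2 * d], F[2 + 2 * d]
        grad[:, d] = (fp - fm) / (2 * step)
        hess[:, d, d] = (fp + fm - 2 * f0) / step**2
    k = 1 + 2 * q
    for a in range(q):
        for b in range(a + 1, q):
            cross = (F[k] - F[k + 1] - F[k + 2] + F[k + 3]) / (4 * step**2)
            hess[:, a, b] = cross
            hess[:, b, a] = cross
            k += 4
    return f0, grad, hess


def _nearest_pd(hess, rel_floor=1e-4):
    """Shift each subject Hessian to be positive definite (Newton damping).

    The eigenvalue floor is relative to the largest curvature so damped
    steps stay on a sane scale even for locally indefinite problems."""
    w = np.linalg.eigvalsh(hess)
    floor = np.maximum(rel_floor * np.abs(w).max(axis=1), 1e-8)
    shift = np.maximum(floor - w[:, 0], 0.0)
    out = hess.copy()
    idx = np.where(shift > 0)[0]
    for i in idx:
        out[i] += shift[i] * np.eye(hess.shape[1])
    return out


_LINE_SEARCH_T = np.array([1.0, 0.5, 0.25, 0.1, 0.04, 0.015, 0.005, 0.001,
                           2e-4, 4e-5, 8e-6, 1.5e-6, 3e-7])


def laplace_marginal(hvec: Callable[[np.ndarray], np.ndarray], n_subjects: int, q: int,
                     u0: np.ndarray | None = None, *, max_iter: int = 40,
                     gtol: float = 1e-4, fd_step: float = 1e-4) -> LaplaceResult:
    """Laplace-approximate -2 log marginal likelihood, summed over subjects.

    ``hvec`` maps a (B, n, q) batch of standardised random-effect matrices to
    the per-subject joint negative log densities ``-log p(y_i | u_i) - log
    phi(u_i)``, shape (B, n).  The inner problem is solved by a damped
    Newton method with finite-difference derivatives, vectorised over
    subjects.  Exact for models linear in the random effects.
    """
    if q == 0:
        f0 = hvec(np.zeros((1, n_subjects, 0)))[0]
        return LaplaceResult(float(2 * np.sum(f0)), 2 * f0,
                             np.zeros((n_subjects, 0)),
                             np.zeros((n_subjects, 0, 0)), 0, True)
    if u0 is None:
        u = np.zeros((n_subjects, q))
    else:
        # start each subject from the better of the warm start and the prior
        # mode, so a stale warm point cannot lock in a bad conditional mode
        both = np.stack([u0, np.zeros((n_subjects, q))])
        f_both = hvec(both)
        u = np.where((f_both[0] <= f_both[1])[:, None], u0, 0.0)
    converged = False
    it = 0
    f0, grad, hess = _fd_grad_hess(hvec, u, fd_step)
    for it in range(1, max_iter + 1):
        if np.max(np.abs(grad)) < gtol:
            converged = True
            break
        hpd = _nearest_pd(hess)
        step_dir = np.linalg.solve(hpd, grad[..., None])[..., 0]
        trials = u[None, :, :] - _LINE_SEARCH_T[:, None, None] * step_dir[None, :, :]
        F = hvec(trials)
        improved = F <= f0[None, :] - 1e-12
        first = np.argmax(improved, axis=0)
        any_imp = improved.any(axis=0)
        t = np.where(any_imp, _LINE_SEARCH_T[first], 0.0)
        u = u - t[:, None] * step_dir
        f0, grad, hess = _fd_grad_hess(hvec, u, fd_step)
        if not any_imp.any():
            break  # no subject can improve: at numerical resolution
    hpd = _nearest_pd(hess)
    sign, logdet = np.linalg.slogdet(hpd)
    ofv_i = 2 * f0 + logdet - q * LOG2PI
    return LaplaceResult(float(np.sum(ofv_i)), ofv_i, u, hess, it, converged)


def _unit_prior(u):
    return 0.5 * (np.sum(u * u, axis=-1) + u.shape[-1] * LOG2PI)


# ---------------------------------------------------------------------------
# PK objective


def _csr(groups: list[np.ndarray]):
    ptr = np.zeros(len(groups) + 1, dtype=np.int64)
    for i, g in enumerate(groups):
        ptr[i + 1] = ptr[i] + len(g)
    flat = np.concatenate(groups) if groups else np.empty(0)
    return ptr, flat


class _PKObjective:
    """Per-dataset arrays and the Laplace objective for the PK stage."""

    def __init__(self, dataset: StudyDataset, spec: ModelSpec):
        self.spec = spec
        cov = dataset.covariates()
        self.subject_ids = list(cov.index)
        sidx = {sid: i for i, sid in enumerate(self.subject_ids)}
        self.wt = cov["WT"].to_numpy(dtype=float)
        self.sex = cov["SEX"].to_numpy(dtype=np.int64)
        prof_subj, ev_t0, ev_amt, ev_dur, obs_t, obs_y = [], [], [], [], [], []
        for (sid, occ), g in dataset.profiles():
            doses = g[g["AMT"] > 0]
            obs = g[(g["MDV"] == 0) & (g["DVTYPE"] == DV_CONC)]
            if len(obs) == 0:
                continue
            prof_subj.append(sidx[sid])
            ev_t0.append(doses["TIME"].to_numpy(dtype=float))
            ev_amt.append(doses["AMT"].to_numpy(dtype=float))
            ev_dur.append(doses["DUR"].to_numpy(dtype=float))
            obs_t.append(obs["TIME"].to_numpy(dtype=float))
            obs_y.append(obs["DV"].to_numpy(dtype=float))
        self.prof_subj = np.asarray(prof_subj, dtype=np.int64)
        self.ev_ptr, ev_flat = _csr(ev_t0)
        self.ev_t0 = ev_flat
        _, self.ev_amt = _csr(ev_amt)
        _, self.ev_dur = _csr(ev_dur)
        self.obs_ptr, self.obs_t = _csr(obs_t)
        _, self.obs_y = _csr(obs_y)
        self.n_obs = int(self.obs_t.size)
        self.n_subjects = len(self.subject_ids)
        self.bsv_slots = [_PK_SLOTS[n] for n in spec.bsv]
        self.q = len(self.bsv_slots)
        self._warm: np.ndarray | None = None

    def _theta6(self, p: Mapping[str, float]):
        s = self.spec
        if s.elimination == "mm":
            raise NotImplementedError  # handled by the python path
        return np.array([
            p["CLp"],
            p.get("CLt", 1.0),
            p["Vc"],
            p.get("Vt", 1.0),
            p.get("theta_wt", 0.0) if s.covariate_wt_vc else 0.0,
            p.get("theta_sex", 1.0) if s.covariate_sex_clp else 1.0,
        ])

    def _nll(self, etas4: np.ndarray, p: Mapping[str, float]) -> np.ndarray:
        """Batched per-subject -log p(y|eta): (B, n, 4) -> (B, n)."""
        if self.spec.elimination == "mm":
            return np.stack([self._nll_mm(e, p) for e in etas4])
        return pk_nll_kernel(
            etas4, self._theta6(p), self.wt, self.sex, self.prof_subj,
            self.ev_ptr, self.ev_t0, self.ev_amt, self.ev_dur,
            self.obs_ptr, self.obs_t, self.obs_y,
            max(p["sigma_prop"], 1e-6), self.spec.n_compartments,
            self.spec.covariate_wt_vc, self.spec.covariate_sex_clp,
        )

    def _nll_mm(self, etas4, p):
        """Michaelis-Menten elimination: per-profile stiff ODE integration."""
        sigma = max(p["sigma_prop"], 1e-6)
        nll = np.zeros(self.n_subjects)
        two = self.spec.n_compartments == 2
        for pr in range(self.prof_subj.size):
            s = self.prof_subj[pr]
            Vm = p["Vm"] * math.exp(etas4[s, 0])
            if self.spec.covariate_sex_clp and self.sex[s] == 1:
                Vm *= p.get("theta_sex", 1.0)
            Km = p["Km"]
            Q = p.get("CLt", 1.0) * math.exp(etas4[s, 1]) if two else 0.0
            Vc = p["Vc"] * math.exp(etas4[s, 2])
            if self.spec.covariate_wt_vc:
                Vc *= (self.wt[s] / 70.0) ** p.get("theta_wt", 0.0)
            Vt = p.get("Vt", 1.0) * math.exp(etas4[s, 3]) if two else 1.0
            ev = slice(self.ev_ptr[pr], self.ev_ptr[pr + 1])
            t0, amt, dur = self.ev_t0[ev], self.ev_amt[ev], self.ev_dur[ev]

            def rhs(t, y):
                rin = 1000.0 * np.sum(
                    np.where((t > t0) & (t <= t0 + dur), amt / dur, 0.0))
                cp, ct = y
                el = Vm * 1000.0 * cp / (Km + cp)  # Vm mg/h -> ng-scale
                dcp = (-el - Q * (cp - ct) + rin) / Vc
                dct = Q * (cp - ct) / Vt if two else 0.0
                return [dcp, dct]

            ob = slice(self.obs_ptr[pr], self.obs_ptr[pr + 1])
            tobs = self.obs_t[ob]
            tmax = float(tobs.max())
            sol = solve_ivp(rhs, (0.0, tmax), [0.0, 0.0], method="LSODA",
                            rtol=1e-8, atol=1e-6, t_eval=tobs, max_step=0.25)
            if not sol.success:
                nll[s] += 1e6
                continue
            f = np.maximum(sol.y[0], 1e-10)
            r = self.obs_y[ob] - f
            v = (sigma * f) ** 2
            nll[s] += 0.5 * np.sum(LOG2PI + np.log(v) + r * r / v)
        return nll

    def _expand(self, u: np.ndarray, omegas: np.ndarray) -> np.ndarray:
        etas4 = np.zeros(u.shape[:-1] + (4,))
        for k, slot in enumerate(self.bsv_slots):
            etas4[..., slot] = omegas[k] * u[..., k]
        return etas4

    def laplace(self, p: Mapping[str, float], *, warm: bool = True) -> LaplaceResult:
        omegas = np.array([max(p.get(f"omega_{n}", 0.0), 0.0) for n in self.spec.bsv])

        def hvec(u):
            return self._nll(self._expand(u, omegas), p) + _unit_prior(u)

        u0 = self._warm if (warm and self._warm is not None) else None
        res = laplace_marginal(hvec, self.n_subjects, self.q, u0)
        if warm:
            self._warm = res.etas
        return res

    def ofv(self, p: Mapping[str, float]) -> float:
        return self.laplace(p).ofv

    def etas_natural(self, res: LaplaceResult, p: Mapping[str, float]) -> pd.DataFrame:
        omegas = [p.get(f"omega_{n}", 0.0) for n in self.spec.bsv]
        data = {f"eta_{n}": omegas[k] * res.etas[:, k] for k, n in enumerate(self.spec.bsv)}
        return pd.DataFrame(data, index=pd.Index(self.subject_ids, name="ID"))


def marginal_objective(dataset: StudyDataset, spec: ModelSpec,
                       params: Mapping[str, float]) -> float:
    """-2 x Laplace-approximate log marginal likelihood of the PK stage."""
    return _PKObjective(dataset, spec).ofv(params)


def empirical_bayes(dataset: StudyDataset, spec: ModelSpec,
                    params: Mapping[str, float]) -> pd.DataFrame:
    """Posterior-mode etas per subject at fixed population parameters.

    Subjects without concentration records sit at the prior mode (eta = 0);
    etas shrink to zero as omegas vanish.
    """
    obj = _PKObjective(dataset, spec)
    res = obj.laplace(params, warm=False)
    return obj.etas_natural(res, params)


def individual_pk_from_fit(dataset: StudyDataset, fit: FitResult) -> pd.DataFrame:
    """Individual PK parameter table (CLp, CLt, Vc, Vt) from a fit's EBEs."""
    p = fit.estimates
    spec = fit.spec or ModelSpec()
    etas = fit.etas if fit.etas is not None else empirical_bayes(dataset, spec, p)
    cov = dataset.covariates()
    rows = {}
    for sid in cov.index:
        e = {n: etas.loc[sid].get(f"eta_{n}", 0.0) if sid in etas.index else 0.0
             for n in ("CLp", "CLt", "Vc", "Vt")}
        rows[sid] = {
            "CLp": p["CLp"] * math.exp(e["CLp"])
            * (p.get("theta_sex", 1.0) if (spec.covariate_sex_clp and cov.loc[sid, "SEX"] == 1) else 1.0),
            "CLt": p.get("CLt", 1.0) * math.exp(e["CLt"]),
            "Vc": p["Vc"] * math.exp(e["Vc"])
            * ((cov.loc[sid, "WT"] / 70.0) ** p.get("theta_wt", 0.0) if spec.covariate_wt_vc else 1.0),
            "Vt": p.get("Vt", 1.0) * math.exp(e["Vt"]),
        }
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("ID")


def individual_pk_from_manifest(ds: StudyDataset) -> pd.DataFrame:
    """Simulated-true individual PK values recorded by the generators."""
    if not ds.manifest or "subjects" not in ds.manifest:
        raise ValueError("dataset has no manifest with per-subject truth")
    rows = {s["id"]: s["pk_individual"] for s in ds.manifest["subjects"]}
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("ID")[
        ["CLp", "CLt", "Vc", "Vt"]
    ]


# ---------------------------------------------------------------------------
# outer optimisation helpers


def _pack(names, values, identity=("theta_wt",)):
    return np.array([values[n] if n in identity else math.log(values[n]) for n in names])


def _unpack(names, x, identity=("theta_wt",)):
    return {n: (x[i] if n in identity else math.exp(min(x[i], 50.0))) for i, n in enumerate(names)}


#: sane search region on the transformed scale (log for positive parameters);
#: outside it the objective is replaced by a repelling penalty, which keeps
#: Nelder-Mead out of degenerate flat basins (e.g. huge volumes with huge
#: residual error, where every prediction collapses to the numerical floor).
_X_BOUNDS = (math.log(1e-4), math.log(1e5))
_WT_BOUNDS = (-6.0, 6.0)


def _bound_penalty(names, x, identity=("theta_wt",)):
    pen = 0.0
    for i, n in enumerate(names):
        lo, hi = _WT_BOUNDS if n in identity else _X_BOUNDS
        if x[i] < lo:
            pen += (lo - x[i]) ** 2
        elif x[i] > hi:
            pen += (x[i] - hi) ** 2
    return pen


def _fit_outer(objective, names, init_values, *, maxfev=3000, restarts=1,
               xatol=1e-4, fatol=1e-3, identity=("theta_wt",), stage1=None,
               method="neldermead"):
    """Outer minimisation on the transformed scale, with a repelling penalty
    outside the sane region and an optional first stage over a subset of
    parameters.

    ``method="neldermead"``: adaptive Nelder-Mead with one polishing restart.
    ``method="lbfgs"``: finite-difference L-BFGS-B with gradient-norm
    convergence (pgtol 1e-3 on the transformed scale); on a likelihood ridge
    this stops at the nearest stationary point instead of random-walking
    along the flat direction.
    """

    def penalised(x):
        pen = _bound_penalty(names, x, identity)
        if pen > 0:
            return 1e9 * (1.0 + pen)
        return objective(x)

    x0 = _pack(names, init_values, identity)
    if stage1:
        idx = [i for i, n in enumerate(names) if n in stage1]

        def sub_obj(xs):
            x = x0.copy()
            x[idx] = xs
            return penalised(x)

        res1 = minimize(sub_obj, x0[idx], method="Nelder-Mead",
                        options={"maxfev": max(60 * len(idx), 400), "xatol": 1e-3,
                                 "fatol": 0.05, "adaptive": True,
                                 "initial_simplex": _simplex(x0[idx], 0.2)})
        x0[idx] = res1.x
    if method == "lbfgs":
        bounds = [(lo, hi) for n in names
                  for lo, hi in [_WT_BOUNDS if n in identity else _X_BOUNDS]]
        return minimize(penalised, x0, method="L-BFGS-B", bounds=bounds,
                        options={"maxfun": maxfev, "eps": 1e-4, "gtol": 1e-3,
                                 "ftol": 1e-10})
    best = None
    spread = 0.15
    for _ in range(restarts + 1):
        res = minimize(penalised, x0, method="Nelder-Mead",
                       options={"maxfev": maxfev, "xatol": xatol, "fatol": fatol,
                                "adaptive": True,
                                "initial_simplex": _simplex(x0, spread)})
        if best is None or res.fun < best.fun:
            best = res
        x0 = res.x
        spread = 0.05
    # gradient-based polish: escapes stalled simplexes at modest extra cost
    bounds = [(lo, hi) for n in names
              for lo, hi in [_WT_BOUNDS if n in identity else _X_BOUNDS]]
    pol = minimize(penalised, best.x, method="L-BFGS-B", bounds=bounds,
                   options={"maxfun": 800, "eps": 1e-4, "gtol": 1e-3,
                            "ftol": 1e-10})
    if pol.fun < best.fun:
        best = pol
    return best


def _simplex(x0, step):
    """Initial simplex with a fixed absolute step per coordinate; the scipy
    default uses relative steps and barely moves coordinates near zero
    (e.g. a multiplicative covariate initialised at 1 on the log scale)."""
    n = x0.size
    s = np.tile(x0, (n + 1, 1))
    for i in range(n):
        s[i + 1, i] += step
    return s


def _se_and_ci(objective, names, xhat, identity=("theta_wt",), step=1e-3):
    """SEs from the curvature of the OFV on the transformed scale; CIs are
    back-transformed (log-scale Wald intervals for positive parameters)."""
    n = len(xhat)
    H = np.zeros((n, n))
    f0 = objective(xhat)
    fp = np.zeros(n)
    fm = np.zeros(n)
    for i in range(n):
        e = np.zeros(n)
        e[i] = step
        fp[i] = objective(xhat + e)
        fm[i] = objective(xhat - e)
        H[i, i] = (fp[i] + fm[i] - 2 * f0) / step**2
    for i in range(n):
        ei = np.zeros(n)
        ei[i] = step
        for j in range(i + 1, n):
            ej = np.zeros(n)
            ej[j] = step
            H[i, j] = H[j, i] = (objective(xhat + ei + ej) - fp[i] - fp[j] + f0
                                 + (objective(xhat - ei - ej) - fm[i] - fm[j] + f0)) / (2 * step**2)
    try:
        cov = 2.0 * np.linalg.pinv(H)
        var = np.clip(np.diag(cov), 0.0, np.inf)
    except np.linalg.LinAlgError:
        var = np.full(n, np.nan)
    se_t = np.sqrt(var)
    se, ci = {}, {}
    for i, nme in enumerate(names):
        if nme in identity:
            est = xhat[i]
            se[nme] = se_t[i]
            ci[nme] = (est - 1.96 * se_t[i], est + 1.96 * se_t[i])
        else:
            est = math.exp(xhat[i])
            se[nme] = est * se_t[i]  # delta method
            ci[nme] = (est * math.exp(-1.96 * se_t[i]), est * math.exp(1.96 * se_t[i]))
    return se, ci


# ---------------------------------------------------------------------------
# PK fit


def _naive_pk_init(dataset: StudyDataset, spec: ModelSpec) -> dict[str, float]:
    """Naive pooled two-stage starting values (non-compartmental heuristics)."""
    cls, vcs = [], []
    for (_, _), g in dataset.profiles():
        doses = g[g["AMT"] > 0]
        obs = g[(g["MDV"] == 0) & (g["DVTYPE"] == DV_CONC)]
        if len(obs) < 4 or len(doses) != 1:
            continue
        t = obs["TIME"].to_numpy()
        y = obs["DV"].to_numpy()
        dose = float(doses["AMT"].iloc[0])
        auc = np.trapezoid(y, t)
        tail = y[-3:]
        tt = t[-3:]
        if np.all(tail > 0):
            lz = -np.polyfit(tt, np.log(tail), 1)[0]
            if lz > 1e-3:
                auc += tail[-1] / lz
        if auc > 0:
            cls.append(1000.0 * dose / auc)
        cmax = float(np.max(y))
        if cmax > 0:
            vcs.append(1000.0 * dose / cmax)  # mg/(ng/mL) -> L
    cl0 = float(np.median(cls)) if cls else 2.0
    vc0 = float(np.median(vcs)) if vcs else 10.0
    init = {"Vc": vc0, "sigma_prop": 0.2}
    if spec.elimination == "mm":
        init["Vm"] = cl0 * 0.5  # mg/h at ~500 ng/mL
        init["Km"] = 500.0
    else:
        init["CLp"] = cl0
    if spec.n_compartments == 2:
        init["CLt"] = cl0
        init["Vt"] = vc0 / 2.0
    if spec.covariate_wt_vc:
        init["theta_wt"] = 1.0
    if spec.covariate_sex_clp:
        init["theta_sex"] = 1.0
    for n in spec.bsv:
        init[f"omega_{n}"] = 0.3
    return init


def fit_pk(dataset: StudyDataset, spec: ModelSpec | None = None,
           init: Mapping[str, float] | PKParameters | None = None,
           seed: int | None = None, *, compute_se: bool = True,
           n_starts: int = 1, maxfev: int = 4000) -> FitResult:
    """Fit the population PK model to the concentration records.

    Multi-start (``n_starts > 1``) perturbs the starting values log-normally
    using ``seed``.  Non-convergence is reported in ``convergence`` with the
    partial result retained.
    """
    spec = spec or ModelSpec()
    obj = _PKObjective(dataset, spec)
    if obj.n_obs == 0:
        raise ValueError("dataset contains no concentration observations")
    names = list(spec.parameter_names())
    if isinstance(init, PKParameters):
        init = {n: getattr(init, n) for n in names if hasattr(init, n)}
    init_full = _naive_pk_init(dataset, spec)
    if init:
        init_full.update({k: v for k, v in init.items() if k in names})

    def objective(x):
        p = _unpack(names, x)
        try:
            return obj.ofv(p)
        except (np.linalg.LinAlgError, FloatingPointError, OverflowError):
            return 1e10

    rng = np.random.default_rng(seed)
    starts = [init_full]
    for _ in range(n_starts - 1):
        starts.append({k: (v if k == "theta_wt" else v * math.exp(0.3 * rng.standard_normal()))
                       for k, v in init_full.items()})
    best = None
    for s in starts:
        obj._warm = None
        res = _fit_outer(objective, names, s, maxfev=maxfev,
                         stage1=spec.fixed_effect_names())
        if best is None or res.fun < best.fun:
            best = res
    est = _unpack(names, best.x)
    lap = obj.laplace(est, warm=False)
    se = ci = None
    if compute_se:
        se, ci = _se_and_ci(objective, names, best.x)
    n_params = len(names)
    return FitResult(
        stage="pk",
        estimates=est,
        ofv=lap.ofv,
        aic=lap.ofv + 2 * n_params,
        n_params=n_params,
        n_obs=obj.n_obs,
        n_subjects=obj.n_subjects,
        se=se,
        ci95=ci,
        etas=obj.etas_natural(lap, est),
        convergence={"success": bool(best.success), "n_fev": int(best.nfev),
                     "message": str(best.message), "inner_converged": lap.converged},
        dataset_signature=dataset.design_signature(),
        spec=spec,
    )


# ---------------------------------------------------------------------------
# PD objective and sequential fit


class _PDObjective:
    """Laplace objective of the PD stage, conditioning on individual PK."""

    def __init__(self, dataset: StudyDataset, pk_individual: pd.DataFrame,
                 base: PDParameters, bsv: tuple[str, ...], dt: float = 0.04,
                 refine: int = 10):
        self.base = base
        self.bsv = bsv
        cov = dataset.covariates()
        self.subject_ids = list(cov.index)
        sidx = {sid: i for i, sid in enumerate(self.subject_ids)}
        prof_subj, schedules, ys, events = [], [], [], []
        for (sid, occ), g in dataset.profiles():
            obs = g[(g["MDV"] == 0) & (g["DVTYPE"] == DV_PH)]
            if len(obs) == 0:
                continue
            prof_subj.append(sidx[sid])
            schedules.append(np.round(obs["TIME"].to_numpy(dtype=float), 9))
            ys.append(obs["DV"].to_numpy(dtype=float))
            d = g[g["AMT"] > 0]
            events.append(tuple(mc.DoseEvent(r.TIME, r.AMT, r.DUR)
                                for r in d.itertuples()))
        if not prof_subj:
            raise ValueError("dataset contains no pH observations")
        self.obs_times = schedules[0]
        for s in schedules[1:]:
            if s.shape != self.obs_times.shape or not np.allclose(s, self.obs_times):
                raise ValueError("PD stage requires a shared pH sampling schedule across profiles")
        self.prof_subj = np.asarray(prof_subj, dtype=np.int64)
        self.y = np.vstack(ys)
        self.n_obs = int(self.y.size)
        self.n_subjects = len(self.subject_ids)
        self.q = len(bsv)
        self.slots = [_PD_SLOTS[n] for n in bsv]

        all_events = [e for ev in events for e in ev]
        self.fine = mc._fine_grid(self.obs_times, all_events, dt, refine)
        mid = 0.5 * (self.fine[:-1] + self.fine[1:])
        self.dt = np.diff(self.fine)
        self.obs_idx = np.searchsorted(self.fine, self.obs_times)
        if not np.allclose(self.fine[self.obs_idx], self.obs_times, atol=1e-8):
            raise RuntimeError("observation times not embedded in the fine grid")
        m = self.prof_subj.size
        self.cp_node = np.empty((m, self.fine.size))
        self.cp_mid = np.empty((m, mid.size))
        for p in range(m):
            sid = self.subject_ids[self.prof_subj[p]]
            row = pk_individual.loc[sid]
            ind = mc.IndividualPK(row["CLp"], row["CLt"], row["Vc"], row["Vt"])
            t0, amt, dur = mc._event_arrays(events[p])
            self.cp_node[p] = cp_profile(self.fine, t0, amt, dur,
                                         ind.CLp, ind.CLt, ind.Vc, ind.Vt, 2)
            self.cp_mid[p] = cp_profile(mid, t0, amt, dur,
                                        ind.CLp, ind.CLt, ind.Vc, ind.Vt, 2)
        self._warm: np.ndarray | None = None

    def _fc_node(self, p: Mapping[str, float]) -> np.ndarray:
        ind = self.base.replace(MA=p.get("MA", self.base.MA),
                                MW=p.get("MW", self.base.MW),
                                MTmax=p.get("MTmax", self.base.MTmax))
        return mc._circadian_on(self.fine + mc.CLOCK_OF_DOSE, ind)

    def _log10fe(self, p: Mapping[str, float]) -> np.ndarray:
        fe_pars = self.base.replace(FE4h=p.get("FE4h", self.base.FE4h),
                                    FE10h=p.get("FE10h", self.base.FE10h),
                                    kFE=p.get("kFE", self.base.kFE))
        return np.log10(mc.food_effect(self.obs_times, fe_pars))

    def laplace(self, p: Mapping[str, float], *, warm: bool = True) -> LaplaceResult:
        fc = self._fc_node(p)
        lfe = self._log10fe(p)
        sigma = max(p.get("sigma_add", self.base.sigma_add), 1e-4)
        kdeg = p.get("kdeg", self.base.kdeg)
        kd = p.get("kd", self.base.kd)
        kout = p.get("kout", self.base.kout)
        hbase = p.get("HBASE", self.base.HBASE)
        omegas = np.array([max(p.get(f"omega_{n}", 0.0), 0.0) for n in self.bsv])

        def hvec(u):
            etas3 = np.zeros(u.shape[:-1] + (3,))
            for k, slot in enumerate(self.slots):
                etas3[..., slot] = omegas[k] * u[..., k]
            nll = pd_nll_kernel(etas3, self.prof_subj, self.dt, self.cp_node,
                                self.cp_mid, fc, kdeg, kd, kout, hbase,
                                self.obs_idx, self.y, lfe, sigma)
            return nll + _unit_prior(u)

        u0 = self._warm if (warm and self._warm is not None) else None
        res = laplace_marginal(hvec, self.n_subjects, self.q, u0)
        if warm:
            self._warm = res.etas
        return res

    def ofv(self, p: Mapping[str, float]) -> float:
        return self.laplace(p).ofv

    def etas_natural(self, res: LaplaceResult, p: Mapping[str, float]) -> pd.DataFrame:
        omegas = [p.get(f"omega_{n}", 0.0) for n in self.bsv]
        data = {f"eta_{n}": omegas[k] * res.etas[:, k] for k, n in enumerate(self.bsv)}
        return pd.DataFrame(data, index=pd.Index(self.subject_ids, name="ID"))


def fit_pd_sequential(dataset: StudyDataset, pk_individual: pd.DataFrame,
                      init: PDParameters | None = None, seed: int | None = None, *,
                      estimate: tuple[str, ...] = ("kdeg", "kd", "kout",
                                                   "FE4h", "FE10h", "kFE"),
                      bsv: tuple[str, ...] = ("kdeg", "kd", "kout"),
                      compute_se: bool = False, maxfev: int = 2500,
                      dt: float = 0.04, method: str = "lbfgs") -> FitResult:
    """Sequential PD stage: fit the acid-suppression system to pH records.

    ``pk_individual`` supplies per-subject PK parameters (empirical Bayes
    estimates via :func:`individual_pk_from_fit`, or the simulated truth via
    :func:`individual_pk_from_manifest`).  HBASE and the circadian
    parameters are fixed at their values in ``init`` (HBASE is fixed in the
    reference parameterisation; the circadian surge is pre-fit from
    baseline data with :func:`fit_circadian_baseline` when needed).
    """
    base = init or PDParameters(kdeg=0.1, kd=1.0, kout=5.0, HBASE=0.033,
                                MA=28.0, MW=1.0, MTmax=22.0,
                                FE4h=40.0, FE10h=100.0, kFE=0.6, sigma_add=1.0)
    for n in estimate:
        if n not in ("kdeg", "kd", "kout", "FE4h", "FE10h", "kFE"):
            raise ValueError(f"cannot estimate {n!r} in the PD stage")
    for n in bsv:
        if n not in _PD_SLOTS:
            raise ValueError(f"BSV supported only on kdeg/kd/kout, got {n!r}")
    obj = _PDObjective(dataset, pk_individual, base, tuple(bsv), dt=dt)
    names = list(estimate) + [f"omega_{n}" for n in bsv] + ["sigma_add"]
    init_vals = {n: getattr(base, n) for n in estimate}
    for n in bsv:
        v = getattr(base, f"omega_{n}")
        init_vals[f"omega_{n}"] = v if v > 0 else 0.5
    init_vals["sigma_add"] = base.sigma_add if base.sigma_add > 0 else 0.5

    def objective(x):
        p = _unpack(names, x, identity=())
        try:
            return obj.ofv(p)
        except (np.linalg.LinAlgError, FloatingPointError, OverflowError):
            return 1e10

    obj._warm = None
    best = _fit_outer(objective, names, init_vals, maxfev=maxfev,
                      identity=(),
                      stage1=tuple(estimate) if method == "neldermead" else None,
                      restarts=0, method=method)
    est = _unpack(names, best.x, identity=())
    lap = obj.laplace(est, warm=False)
    se = ci = None
    if compute_se:
        se, ci = _se_and_ci(objective, names, best.x, identity=())
    n_params = len(names)
    full = dict(est)
    for n in ("HBASE", "MA", "MW", "MTmax", "kdeg", "kd", "kout", "FE4h", "FE10h", "kFE"):
        full.setdefault(n, getattr(base, n))
    return FitResult(
        stage="pd",
        estimates=full,
        ofv=lap.ofv,
        aic=lap.ofv + 2 * n_params,
        n_params=n_params,
        n_obs=obj.n_obs,
        n_subjects=obj.n_subjects,
        se=se,
        ci95=ci,
        etas=obj.etas_natural(lap, est),
        convergence={"success": bool(best.success), "n_fev": int(best.nfev),
                     "message": str(best.message), "inner_converged": lap.converged},
        dataset_signature=dataset.design_signature(),
    )


def fit_circadian_baseline(times, mean_ph, init: PDParameters, *,
                           fit_food: bool = False, dt: float = 0.02) -> PDParameters:
    """Least-squares pre-fit of the circadian surge (MA, MW, MTmax) to a
    drug-free mean baseline pH profile; food parameters are held at their
    ``init`` values unless ``fit_food``."""
    times = np.asarray(times, dtype=float)
    mean_ph = np.asarray(mean_ph, dtype=float)
    pk_dummy = mc.IndividualPK(1.0, 1.0, 10.0, 10.0)
    reg = mc.Regimen("baseline", (mc.DoseEvent(0.0, 0.0, 0.5),), float(times[-1]))
    names = ["MA", "MW", "MTmax"] + (["FE4h", "FE10h", "kFE"] if fit_food else [])

    def objective(x):
        vals = dict(zip(names, x))
        vals = {k: (v if k == "MTmax" else math.exp(min(v, 20.0))) for k, v in vals.items()}
        try:
            pdp = init.replace(**vals)
        except ValueError:
            return 1e10
        prof = mc.simulate_individual(reg, pk_dummy, mc.individual_pd_parameters(pdp),
                                      times, dt=dt)
        return float(np.sum((prof.ph - mean_ph) ** 2))

    x0 = np.array([math.log(max(getattr(init, n), 1e-3)) if n != "MTmax" else init.MTmax
                   for n in names])
    res = minimize(objective, x0, method="Nelder-Mead",
                   options={"maxfev": 2000, "xatol": 1e-5, "fatol": 1e-10, "adaptive": True})
    vals = dict(zip(names, res.x))
    vals = {k: (v if k == "MTmax" else math.exp(v)) for k, v in vals.items()}
    vals["MTmax"] = vals["MTmax"] % 24.0
    return init.replace(**vals)


def model_compare(fits: Sequence[FitResult]) -> pd.DataFrame:
    """Rank fits of the same dataset by AIC (lowest first)."""
    if not fits:
        raise ValueError("no fits to compare")
    sig = {f.dataset_signature for f in fits}
    if len(sig) > 1:
        raise ValueError("fits were obtained on different datasets")
    rows = []
    for f in fits:
        label = f.stage
        if f.spec is not None:
            s = f.spec
            label = (f"{s.n_compartments}cpt-{s.elimination}"
                     f"{'+wt' if s.covariate_wt_vc else ''}"
                     f"{'+sex' if s.covariate_sex_clp else ''}")
        rows.append({"model": label, "ofv": f.ofv, "n_params": f.n_params, "aic": f.aic})
    out = pd.DataFrame(rows).sort_values("aic", kind="stable").reset_index(drop=True)
    out["delta_aic"] = out["aic"] - out["aic"].iloc[0]
    return out
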